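"""Dataset builders and evaluation for the three filler-training regimes.

* limited_seen: train and test stories drawn from one small pool of six
  fillers per role (test stories are new permutations, not new words).
* limited_unseen: same training set, but test fillers come from a pool
  disjoint from training — the regime in which every network collapses
  to predicting training fillers.
* unlimited: every story is filled with freshly generated vectors, for
  both splits, forcing generalization to novel fillers; the retrieval
  corpus is assembled per validation batch (30 base words + 6 fresh
  fillers per story).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .embeddings import (BASE_VOCAB_30, EMBED_DIM, DISTRIBUTION_Z, Lexicon,
                         RetrievalCorpus, build_corpus)
from .model import RecurrentFillerBinder
from .schema import (PAD_TOKEN, QUERY_TOKENS, ROLES, SchemaGraph, StoryFrame,
                     StoryInstance, build_coffee_shop_graph,
                     default_sequence_length, enumerate_paths,
                     enumerate_query_frames, instantiate_story, path_roles)


@dataclass
class ExperimentSpec:
    """Sizes and seeds for one training-regime experiment."""

    regime: str = "limited_seen"  # limited_seen | limited_unseen | unlimited
    fillers_per_role: int = 6
    stories_per_path: int = 5000
    test_stories_per_path: int = 250
    split: float = 0.8
    validation_batch: int = 16
    trials: int = 3
    seed: int = 0
    n_paths: int | None = None  # restrict to the first n enumerated paths

    def __post_init__(self):
        if self.regime not in {"limited_seen", "limited_unseen", "unlimited"}:
            raise ValueError(f"unknown regime {self.regime!r}")


@dataclass
class EvalReport:
    """Overall and per-query retrieval accuracy with the corpus chance rate."""

    overall: float
    per_query: dict[str, float]
    chance: float
    n: int
    curves: pd.DataFrame | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"query": "overall", "accuracy": self.overall}]
        rows += [{"query": q, "accuracy": a} for q, a in self.per_query.items()]
        df = pd.DataFrame(rows)
        df["chance"] = self.chance
        return df


def _pool_tokens(prefix: str, n: int) -> dict[str, list[str]]:
    return {role: [f"{role.lower()}_{prefix}{i}" for i in range(n)] for role in ROLES}


def limited_lexicon(train_pool: dict[str, list[str]],
                    test_pool: dict[str, list[str]] | None,
                    rng: np.random.Generator) -> Lexicon:
    """Fixed embeddings for keywords, queries, pad, and all pool fillers."""
    tokens = list(BASE_VOCAB_30[:18])  # keywords + queries + pad
    for pool in (train_pool, test_pool or {}):
        for role in ROLES:
            tokens.extend(pool.get(role, []))
    return Lexicon.build(tokens, rng)


def _sample_limited(graph: SchemaGraph, paths, pool: dict[str, list[str]],
                    per_path: int, length: int, rng: np.random.Generator
                    ) -> list[StoryInstance]:
    out: list[StoryInstance] = []
    for path in paths:
        roles = path_roles(graph, path)
        for _ in range(per_path):
            fillers = {r: pool[r][rng.integers(len(pool[r]))] for r in roles}
            query = roles[rng.integers(len(roles))]
            out.append(instantiate_story(graph, StoryFrame(path, query),
                                         fillers, length, rng))
    return out


def _dedup(stories: list[StoryInstance]) -> list[StoryInstance]:
    seen: set[tuple[str, ...]] = set()
    unique = []
    for s in stories:
        key = tuple(s.tokens)
        if key not in seen:
            seen.add(key)
            unique.append(s)
    return unique


def build_limited_datasets(spec: ExperimentSpec, rng: np.random.Generator,
                           graph: SchemaGraph | None = None
                           ) -> tuple[list[StoryInstance], list[StoryInstance], Lexicon]:
    """Sample, deduplicate, and split stories for the limited regimes."""
    graph = graph or build_coffee_shop_graph()
    paths = enumerate_paths(graph)
    if spec.n_paths is not None:
        paths = paths[: spec.n_paths]
    length = default_sequence_length(graph)
    train_pool = _pool_tokens("a", spec.fillers_per_role)

    stories = _dedup(_sample_limited(graph, paths, train_pool,
                                     spec.stories_per_path, length, rng))
    rng.shuffle(stories)
    n_train = int(round(spec.split * len(stories)))

    if spec.regime == "limited_seen":
        lexicon = limited_lexicon(train_pool, None, rng)
        return stories[:n_train], stories[n_train:], lexicon

    # disjoint-pool test set; training uses every deduplicated story
    test_pool = _pool_tokens("b", spec.fillers_per_role)
    test = _dedup(_sample_limited(graph, paths, test_pool,
                                  spec.test_stories_per_path, length, rng))
    lexicon = limited_lexicon(train_pool, test_pool, rng)
    return stories[:n_train], test, lexicon


def unlimited_lexicon(rng: np.random.Generator) -> Lexicon:
    """The 30-word base corpus with fixed embeddings."""
    return Lexicon.build(BASE_VOCAB_30, rng)


def sample_unlimited_stories(frames: list[StoryFrame], length: int,
                             rng: np.random.Generator,
                             graph: SchemaGraph | None = None,
                             distribution=DISTRIBUTION_Z,
                             role_distributions: dict | None = None
                             ) -> list[StoryInstance]:
    """One story per frame, each with six freshly generated filler vectors.

    Fresh vectors are drawn for all six roles even when a role is absent
    from the frame's path, so a batch of b stories always contributes
    6*b new corpus words.
    """
    graph = graph or build_coffee_shop_graph()
    out = []
    for i, frame in enumerate(frames):
        fillers = {r: f"s{i}_{r.lower()}" for r in ROLES}
        vectors = {}
        for r in ROLES:
            dist = (role_distributions or {}).get(r, distribution)
            vectors[fillers[r]] = dist.sample(rng)
        roles = path_roles(graph, frame.path)
        inst = instantiate_story(graph, frame,
                                 {r: fillers[r] for r in roles}, length, rng)
        inst.filler_vectors = vectors
        out.append(inst)
    return out


def build_unlimited_datasets(spec: ExperimentSpec, rng: np.random.Generator,
                             graph: SchemaGraph | None = None):
    """Frames, a per-epoch resampler, one test draw, and the base lexicon."""
    graph = graph or build_coffee_shop_graph()
    frames = enumerate_query_frames(graph)
    if spec.n_paths is not None:
        keep = set(enumerate_paths(graph)[: spec.n_paths])
        frames = [f for f in frames if f.path in keep]
    length = default_sequence_length(graph)
    lexicon = unlimited_lexicon(rng)

    def resample(r: np.random.Generator) -> list[StoryInstance]:
        return sample_unlimited_stories(frames, length, r, graph=graph)

    test = sample_unlimited_stories(frames, length, rng, graph=graph)
    return frames, resample, test, lexicon


def train(model: RecurrentFillerBinder, stories, lexicon,
          validation=None, resample=None) -> RecurrentFillerBinder:
    """Thin functional wrapper over the estimator's fit."""
    return model.fit(stories, lexicon, validation=validation, resample=resample)


def evaluate(model: RecurrentFillerBinder, stories, lexicon: Lexicon,
             corpus: RetrievalCorpus | None = None,
             batch_size: int | None = None) -> EvalReport:
    """Retrieval accuracy, overall and split by query token.

    With no fixed corpus, candidates are assembled per batch from the
    lexicon plus the batch's fresh fillers, and the reported chance rate
    is 1/|corpus| averaged over batches.
    """
    bs = batch_size or model.batch_size
    hits: dict[str, list[bool]] = {}
    chances = []
    for start in range(0, len(stories), bs):
        batch = list(stories[start:start + bs])
        c = corpus if corpus is not None else build_corpus(lexicon, batch)
        chances.append(c.chance_rate)
        for pred, inst in zip(model.predict(batch, lexicon, corpus=c), batch):
            hits.setdefault(inst.query_token, []).append(pred == inst.target_token)
    per_query = {q: float(np.mean(v)) for q, v in sorted(hits.items())}
    allhits = [h for v in hits.values() for h in v]
    history = getattr(model, "history_", None)
    curves = pd.DataFrame(history) if history else None
    return EvalReport(overall=float(np.mean(allhits)), per_query=per_query,
                      chance=float(np.mean(chances)), n=len(allhits),
                      curves=curves)
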