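"""Ridge-regression decoding of fillers from network activity.

For a set of stories sharing one frame (identical frame text, distinct
fillers) we record every memory component after each input word, fit one
ridge map (regularization strength 1.0) per (role, timestep, component)
from activity to the correct filler vector on 80 training sequences, and
score held-out predictions by the cosine ranking of the true filler in
the retrieval corpus (max 1, chance 0.5).

The DNC read/write-weight analysis asks where the network writes when a
role's filler arrives and where it reads when that role is queried; a
location-based binding strategy shows up as matched write/read argmax
histograms with high Pearson correlation on the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from .embeddings import Lexicon, RetrievalCorpus, ranking_score
from .model import RecurrentFillerBinder
from .schema import (ROLES, SchemaGraph, StoryFrame, StoryInstance,
                     build_coffee_shop_graph, default_sequence_length,
                     path_roles)
from .training import sample_unlimited_stories

#: the maximal-coverage traversal: every one of the six roles appears
FULL_COVERAGE_PATH = ("BEGIN", "ORDER_DRINK", "SIT", "INTRO", "POETRY",
                      "PERFORM", "ORDER_DESSERT", "END")


@dataclass
class DecodingSet:
    """Stories sharing one frame plus their recorded activation traces.

    ``traces[component]`` has shape (n_sequences, n_timesteps, dim);
    ``targets[role]`` has shape (n_sequences, embed_dim).
    """

    instances: list[StoryInstance]
    traces: dict[str, np.ndarray]
    targets: dict[str, np.ndarray]
    n_train: int

    @property
    def n_timesteps(self) -> int:
        return next(iter(self.traces.values())).shape[1]


def build_decoding_set(model: RecurrentFillerBinder, lexicon: Lexicon,
                       rng: np.random.Generator,
                       n_sequences: int = 100, train_fraction: float = 0.8,
                       graph: SchemaGraph | None = None,
                       path: tuple[str, ...] = FULL_COVERAGE_PATH,
                       query_role: str = "Subject") -> DecodingSet:
    """Instantiate one frame ``n_sequences`` times and record activity.

    The frame text (path, pad position, query) is pinned so only the
    fillers differ between sequences; fillers are freshly generated
    vectors as in the unlimited regime.
    """
    graph = graph or build_coffee_shop_graph()
    length = default_sequence_length(graph)
    frame = StoryFrame(path, query_role)
    body_len = sum(1 + len(graph.states[n].role_slots) for n in path)
    pad_pos = int(rng.integers(body_len + 1))

    instances = []
    for inst in sample_unlimited_stories([frame] * n_sequences, length, rng, graph=graph):
        instances.append(inst)
    # re-pin the pad position so the frame text is identical across sequences
    roles = path_roles(graph, frame.path)
    from .schema import instantiate_story
    pinned = []
    for inst in instances:
        fillers = inst.binding
        p = instantiate_story(graph, frame, fillers, length, rng, pad_position=pad_pos)
        p.filler_vectors = inst.filler_vectors
        pinned.append(p)

    traces = record_traces(model, pinned, lexicon)
    targets = {
        role: np.stack([inst.filler_vectors[inst.binding[role]] for inst in pinned])
        for role in roles
    }
    return DecodingSet(instances=pinned, traces=traces, targets=targets,
                       n_train=int(round(train_fraction * n_sequences)))


def record_traces(model: RecurrentFillerBinder, instances: list[StoryInstance],
                  lexicon: Lexicon) -> dict[str, np.ndarray]:
    """Per-component activity, shape (n_sequences, n_timesteps, dim).

    Components: always ``hidden`` (50-d); plus ``memory`` for external
    memory (fast weights flattened to 2,500-d, DNC buffer to 2,560-d) and
    ``read_w``/``write_w`` for the DNC head weightings.
    """
    out: dict[str, list[np.ndarray]] = {}
    bs = model.batch_size
    for start in range(0, len(instances), bs):
        batch = list(instances[start:start + bs])
        _, steps = model.forward(batch, lexicon, record=True)
        for comp in steps[0]:
            stacked = np.stack([s[comp] for s in steps], axis=1)  # (B, T, d)
            out.setdefault(comp, []).append(stacked)
    return {comp: np.concatenate(parts, axis=0) for comp, parts in out.items()}


@dataclass
class DecoderBank:
    """Fitted ridge decoders keyed by (role, timestep, component)."""

    decoders: dict[tuple[str, int, str], Ridge] = field(default_factory=dict)
    alpha: float = 1.0

    def predict(self, role: str, t: int, component: str,
                activity: np.ndarray) -> np.ndarray:
        return self.decoders[(role, t, component)].predict(activity)


def fit_decoders(dset: DecodingSet, alpha: float = 1.0,
                 components: list[str] | None = None) -> DecoderBank:
    """Closed-form ridge fit per (role, timestep, component) on the train split."""
    comps = components or [c for c in dset.traces if c in ("hidden", "memory")]
    bank = DecoderBank(alpha=alpha)
    ntr = dset.n_train
    for comp in comps:
        tr = dset.traces[comp]
        for role, Y in dset.targets.items():
            for t in range(dset.n_timesteps):
                ridge = Ridge(alpha=alpha)
                ridge.fit(tr[:ntr, t, :], Y[:ntr])
                bank.decoders[(role, t, comp)] = ridge
    return bank


def decoding_curve(bank: DecoderBank, dset: DecodingSet,
                   corpus: RetrievalCorpus) -> pd.DataFrame:
    """Mean held-out ranking score per (role, timestep, component).

    The corpus for ranking is the experiment corpus extended with the
    held-out sequences' own filler vectors, so the true filler is always
    a candidate.
    """
    ntr = dset.n_train
    rows = []
    held = dset.instances[ntr:]
    ext_tokens = list(corpus.tokens)
    ext_vecs = [corpus.matrix]
    for inst in held:
        for tok, vec in inst.filler_vectors.items():
            ext_tokens.append(tok)
            ext_vecs.append((vec / np.linalg.norm(vec))[None])
    ext = RetrievalCorpus(tokens=ext_tokens, matrix=np.concatenate(ext_vecs, axis=0))

    for (role, t, comp), ridge in bank.decoders.items():
        acts = dset.traces[comp][ntr:, t, :]
        preds = ridge.predict(acts)
        scores = []
        for i, inst in enumerate(held):
            target_tok = inst.binding[role]
            scores.append(ranking_score(preds[i], target_tok, ext))
        rows.append({"role": role, "timestep": t, "component": comp,
                     "score": float(np.mean(scores))})
    return pd.DataFrame(rows)


def dnc_rw_analysis(traces: dict[str, np.ndarray],
                    instances: list[StoryInstance],
                    lexicon_roles: dict[str, str] | None = None,
                    n_slots: int | None = None) -> dict:
    """Write/read location histograms and their Pearson correlations.

    For every instance, the argmax write-weight slot at the timestep each
    role's filler is input, and the argmax read-weight slot at the query
    timestep, are histogrammed per role. Ties take the lowest slot index
    (numpy argmax convention). Returns ``{"write": DataFrame,
    "read": DataFrame, "correlation": DataFrame}`` with roles as rows.
    """
    write_w, read_w = traces["write_w"], traces["read_w"]
    slots = n_slots or write_w.shape[-1]
    write_hist: dict[str, np.ndarray] = {}
    read_hist: dict[str, np.ndarray] = {}

    for i, inst in enumerate(instances):
        qrole = inst.query_token[1:].capitalize()
        qt = len(inst.tokens) - 1
        slot = int(np.argmax(read_w[i, qt]))
        read_hist.setdefault(qrole, np.zeros(slots))[slot] += 1
        for t, tok in enumerate(inst.tokens):
            for role, filler in inst.binding.items():
                if tok == filler:
                    slot = int(np.argmax(write_w[i, t]))
                    write_hist.setdefault(role, np.zeros(slots))[slot] += 1

    roles = [r for r in ROLES if r in write_hist]
    qroles = [r for r in ROLES if r in read_hist]
    corr = np.zeros((len(qroles), len(roles)))
    for a, qr in enumerate(qroles):
        for b, wr in enumerate(roles):
            corr[a, b] = np.corrcoef(read_hist[qr], write_hist[wr])[0, 1]
    return {
        "write": pd.DataFrame({r: write_hist[r] for r in roles}).T,
        "read": pd.DataFrame({r: read_hist[r] for r in qroles}).T,
        "correlation": pd.DataFrame(corr, index=qroles, columns=roles),
    }
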