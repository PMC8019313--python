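"""Correlation-violation and correlation-retention experiments.

Both experiments use the fixed 13-token linear story frame. The
violation design imposes strong role-filler correlations during training
(each filler is excluded from exactly one of the four varied roles) and
then tests exclusively on the excluded, correlation-breaking bindings.
The retention design draws training fillers from role-specific vector
distributions (X for Dessert/Emcee/Poet, Y for Subject/Friend/Drink) and
probes whether a trained network both generalizes to arbitrary fillers
and retains the trained distributional bias — measured by Welch
t-statistics comparing even- against odd-index components of its
predictions (ambiguous zero-vector probe) or of prediction minus target
(all-Z probe).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .embeddings import (DISTRIBUTION_X, DISTRIBUTION_Y, DISTRIBUTION_Z,
                         DISTRIBUTIONS, Lexicon, build_corpus,
                         corpus_from_lexicon)
from .model import RecurrentFillerBinder
from .schema import (PAD_TOKEN, QUERY_TOKENS, ROLES, StoryInstance,
                     build_linear_frame, instantiate_template, shuffle_stages,
                     template_roles)

#: roles whose fillers vary in the violation design; the rest stay constant
VARIED_ROLES = ("Subject", "Friend", "Emcee", "Poet")

#: fixed tokens bound to the constant roles of the violation design
CONSTANT_FILLERS = {"Dessert": "cake", "Drink": "latte"}

#: role -> training distribution of the retention design
RETENTION_TRAIN_DISTS = {"Dessert": "X", "Emcee": "X", "Poet": "X",
                         "Subject": "Y", "Friend": "Y", "Drink": "Y"}

LINEAR_LENGTH = 15  # 13-token body + one inserted pad + query


@dataclass
class ViolationDesign:
    """Exclusion design: filler i is excluded from varied role i mod 4."""

    universe: int = 1000
    varied_roles: tuple[str, ...] = VARIED_ROLES
    n_train: int = 4000
    n_test: int = 400

    def __post_init__(self):
        if self.universe % len(self.varied_roles):
            raise ValueError("universe size must divide evenly over varied roles")

    @property
    def fillers(self) -> list[str]:
        return [f"filler{i:04d}" for i in range(self.universe)]

    def excluded_role(self, index: int) -> str:
        return self.varied_roles[index % len(self.varied_roles)]

    def train_pool(self, role: str) -> list[str]:
        return [f for i, f in enumerate(self.fillers) if self.excluded_role(i) != role]

    def test_pool(self, role: str) -> list[str]:
        return [f for i, f in enumerate(self.fillers) if self.excluded_role(i) == role]


def violation_lexicon(design: ViolationDesign, rng: np.random.Generator) -> Lexicon:
    keywords = [item for item in build_linear_frame() if isinstance(item, str)]
    tokens = (keywords + [PAD_TOKEN]
              + [QUERY_TOKENS[r] for r in ROLES]
              + list(CONSTANT_FILLERS.values()) + design.fillers)
    return Lexicon.build(tokens, rng)


def build_violation_datasets(design: ViolationDesign, rng: np.random.Generator
                             ) -> tuple[list[StoryInstance], list[StoryInstance], Lexicon]:
    """Train on allowed bindings only; test on excluded bindings only."""
    template = build_linear_frame()
    lexicon = violation_lexicon(design, rng)
    train_pools = {r: design.train_pool(r) for r in design.varied_roles}
    test_pools = {r: design.test_pool(r) for r in design.varied_roles}

    def sample(pools, n):
        out = []
        for _ in range(n):
            fillers = dict(CONSTANT_FILLERS)
            for r in design.varied_roles:
                fillers[r] = pools[r][rng.integers(len(pools[r]))]
            query = design.varied_roles[rng.integers(len(design.varied_roles))]
            out.append(instantiate_template(template, fillers, LINEAR_LENGTH,
                                            rng, query))
        return out

    return sample(train_pools, design.n_train), sample(test_pools, design.n_test), lexicon


def run_violation_eval(model: RecurrentFillerBinder,
                       test: list[StoryInstance], lexicon: Lexicon) -> dict:
    """Accuracy on the correlation-breaking test set, with chance rate."""
    corpus = corpus_from_lexicon(lexicon)
    acc = model.score(test, lexicon, corpus)
    return {"accuracy": acc, "chance": corpus.chance_rate, "n": len(test)}


# -- retention ----------------------------------------------------------------


@dataclass
class RetentionDesign:
    """Role-correlated filler distributions with unlimited fresh vectors."""

    role_distributions: dict[str, str] = field(
        default_factory=lambda: dict(RETENTION_TRAIN_DISTS))
    n_train: int = 1000
    n_test: int = 300
    trials: int = 5


def retention_lexicon(rng: np.random.Generator) -> Lexicon:
    """Frame words (all drawn from distribution Z) for the linear template."""
    keywords = [item for item in build_linear_frame() if isinstance(item, str)]
    tokens = keywords + [PAD_TOKEN] + [QUERY_TOKENS[r] for r in ROLES]
    return Lexicon.build(tokens, rng, distribution=DISTRIBUTION_Z)


def sample_retention_stories(n: int, rng: np.random.Generator,
                             setting: str = "train",
                             template: tuple | None = None,
                             queries: tuple[str, ...] | None = None
                             ) -> list[StoryInstance]:
    """Linear-frame stories with fresh filler vectors per story.

    ``setting`` selects the filler distributions: "train" uses the
    role->X/Y training mapping; "all-X", "all-Y", "all-Z" draw every
    filler from one distribution; "mixed-XY" flips a fair coin per
    filler.
    """
    template = template or build_linear_frame()
    roles = template_roles(template)
    queries = queries or tuple(roles)
    out = []
    for i in range(n):
        fillers = {r: f"s{i}_{r.lower()}" for r in roles}
        vectors = {}
        for r in roles:
            if setting == "train":
                dist = DISTRIBUTIONS[RETENTION_TRAIN_DISTS[r]]
            elif setting == "mixed-XY":
                dist = DISTRIBUTION_X if rng.random() < 0.5 else DISTRIBUTION_Y
            elif setting in ("all-X", "all-Y", "all-Z"):
                dist = DISTRIBUTIONS[setting[-1]]
            else:
                raise ValueError(f"unknown setting {setting!r}")
            vectors[fillers[r]] = dist.sample(rng)
        query = queries[rng.integers(len(queries))]
        inst = instantiate_template(template, fillers, LINEAR_LENGTH, rng, query)
        inst.filler_vectors = vectors
        out.append(inst)
    return out


def build_retention_datasets(design: RetentionDesign, rng: np.random.Generator):
    """Training resampler, the four test settings, and the frame lexicon."""
    lexicon = retention_lexicon(rng)

    def resample(r: np.random.Generator) -> list[StoryInstance]:
        return sample_retention_stories(design.n_train, r, "train")

    tests = {s: sample_retention_stories(design.n_test, rng, s)
             for s in ("all-X", "all-Y", "mixed-XY", "all-Z")}
    return resample, tests, lexicon


@dataclass
class BiasReport:
    """Per-role Welch t-statistics on even vs odd probe components.

    Positive t means the even indices are elevated relative to the odd
    ones — the signature of distribution X.
    """

    t_by_role: dict[str, float]
    accuracy: float | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"role": list(self.t_by_role),
                           "t_statistic": list(self.t_by_role.values())})
        df["trained_distribution"] = df["role"].map(RETENTION_TRAIN_DISTS)
        return df


def _even_odd_t(vectors: np.ndarray) -> float:
    """Welch t between pooled even-index and odd-index values."""
    even = vectors[:, 0::2].ravel()
    odd = vectors[:, 1::2].ravel()
    if np.allclose(even, odd) and np.ptp(even) == 0 and np.ptp(odd) == 0:
        return 0.0
    t, _ = stats.ttest_ind(even, odd, equal_var=False)
    return float(t)


def ambiguous_probe(model: RecurrentFillerBinder, test: list[StoryInstance],
                    lexicon: Lexicon) -> BiasReport:
    """Zero out the queried filler's input vector and test prediction bias.

    The zero vector is input-side only (never a corpus candidate), so any
    even/odd asymmetry in the prediction reflects role statistics the
    network absorbed during training.
    """
    probed = []
    for inst in test:
        p = StoryInstance(tokens=inst.tokens, query_token=inst.query_token,
                          target_token=inst.target_token, binding=inst.binding,
                          frame=inst.frame,
                          filler_vectors=dict(inst.filler_vectors))
        queried = inst.binding[_role_of_query(inst.query_token)]
        p.input_overrides = {queried: np.zeros(lexicon.dim)}
        probed.append(p)
    preds = model.predict_vectors(probed, lexicon)
    t_by_role = {}
    for role in sorted({_role_of_query(i.query_token) for i in test}):
        mask = np.array([_role_of_query(i.query_token) == role for i in test])
        t_by_role[role] = _even_odd_t(preds[mask])
    return BiasReport(t_by_role=t_by_role)


def residual_bias(model: RecurrentFillerBinder, test_z: list[StoryInstance],
                  lexicon: Lexicon) -> BiasReport:
    """Even/odd bias of prediction minus target on all-Z fillers, plus accuracy."""
    preds = model.predict_vectors(test_z, lexicon)
    targets = np.stack([lexicon.lookup(i.target_token, i) for i in test_z])
    resid = preds - targets
    t_by_role = {}
    for role in sorted({_role_of_query(i.query_token) for i in test_z}):
        mask = np.array([_role_of_query(i.query_token) == role for i in test_z])
        t_by_role[role] = _even_odd_t(resid[mask])
    hits = 0
    bs = model.batch_size
    for start in range(0, len(test_z), bs):
        batch = test_z[start:start + bs]
        corpus = build_corpus(lexicon, batch)
        for p, inst in zip(model.predict(batch, lexicon, corpus=corpus), batch):
            hits += p == inst.target_token
    return BiasReport(t_by_role=t_by_role, accuracy=hits / len(test_z))


def shuffled_story_eval(model: RecurrentFillerBinder, lexicon: Lexicon,
                        rng: np.random.Generator, n: int = 200,
                        setting: str = "all-Z") -> dict:
    """Accuracy on the fixed stage-shuffled template vs the trained order."""
    shuffled = sample_retention_stories(
        n, rng, setting, template=shuffle_stages(build_linear_frame()))
    control = sample_retention_stories(n, rng, setting)

    def acc(stories):
        hits = 0
        for start in range(0, len(stories), model.batch_size):
            batch = stories[start:start + model.batch_size]
            corpus = build_corpus(lexicon, batch)
            for p, inst in zip(model.predict(batch, lexicon, corpus=corpus), batch):
                hits += p == inst.target_token
        return hits / len(stories)

    shuffled_acc = acc(shuffled)
    control_acc = acc(control)
    chance = 1.0 / (len(lexicon) + 6 * min(model.batch_size, n))
    return {"shuffled_accuracy": shuffled_acc, "control_accuracy": control_acc,
            "chance": chance}


def _role_of_query(query_token: str) -> str:
    for role, q in QUERY_TOKENS.items():
        if q == query_token:
            return role
    raise ValueError(f"not a query token: {query_token!r}")
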