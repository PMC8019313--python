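"""Random word embeddings, filler distributions, and retrieval scoring.

Words are represented by randomly generated 50-d vectors normalized to
unit Euclidean norm — no pretrained semantics. Predictions are read out
by cosine-similarity retrieval against a corpus of candidate words.

The correlation experiments draw filler vectors from three distributions
that share N(0,1) coordinates but differ in a ±0.5 shift applied jointly
to all even (0-based) coordinates: X shifts up with probability 0.9,
Y with probability 0.1, Z applies no shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .schema import PAD_TOKEN, QUERY_TOKENS, ROLES, StoryInstance

EMBED_DIM = 50

#: keywords of the coffee-shop schema states
STATE_KEYWORDS = (
    "begin", "order_drink", "too_expensive", "sit", "emcee_intro",
    "poet_performs", "subject_declines", "subject_performs", "say_goodbye",
    "order_dessert", "end",
)

#: the 30-token base story corpus of the unlimited-filler experiment:
#: 11 state keywords + 6 query tokens + padding + 12 reserved slots
BASE_VOCAB_30 = (
    STATE_KEYWORDS
    + tuple(QUERY_TOKENS[r] for r in ROLES)
    + (PAD_TOKEN,)
    + tuple(f"reserved{i:02d}" for i in range(12))
)


@dataclass
class FillerDistribution:
    """Unit-norm vectors from N(0,1) with an optional joint even-index shift."""

    label: str  # "X", "Y", or "Z"
    shift_up_prob: float

    def sample(self, rng: np.random.Generator, dim: int = EMBED_DIM) -> np.ndarray:
        v = rng.standard_normal(dim)
        if self.label != "Z":
            # one coin per vector: every even coordinate moves together
            shift = 0.5 if rng.random() < self.shift_up_prob else -0.5
            v[0::2] += shift
        return v / np.linalg.norm(v)


DISTRIBUTION_X = FillerDistribution("X", 0.9)
DISTRIBUTION_Y = FillerDistribution("Y", 0.1)
DISTRIBUTION_Z = FillerDistribution("Z", 0.0)

DISTRIBUTIONS = {"X": DISTRIBUTION_X, "Y": DISTRIBUTION_Y, "Z": DISTRIBUTION_Z}


def sample_vector(dist: FillerDistribution, rng: np.random.Generator,
                  dim: int = EMBED_DIM) -> np.ndarray:
    return dist.sample(rng, dim)


@dataclass
class Lexicon:
    """Fixed token -> unit-vector mapping for one experiment."""

    vectors: dict[str, np.ndarray] = field(default_factory=dict)
    dim: int = EMBED_DIM

    @classmethod
    def build(cls, tokens, rng: np.random.Generator, dim: int = EMBED_DIM,
              distribution: FillerDistribution = DISTRIBUTION_Z,
              role_distributions: dict[str, FillerDistribution] | None = None,
              token_roles: dict[str, str] | None = None) -> "Lexicon":
        """Draw one fixed vector per token.

        ``role_distributions``/``token_roles`` let filler tokens of a given
        role be drawn from a role-specific distribution (frame words always
        come from the symmetric distribution Z).
        """
        lex = cls(dim=dim)
        for tok in tokens:
            dist = distribution
            if role_distributions and token_roles and tok in token_roles:
                dist = role_distributions[token_roles[tok]]
            lex.vectors[tok] = dist.sample(rng, dim)
        return lex

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    def tokens(self) -> list[str]:
        return list(self.vectors)

    def lookup(self, token: str, instance: StoryInstance | None = None) -> np.ndarray:
        """Vector for a token, honouring per-story fresh fillers."""
        if instance is not None and token in instance.filler_vectors:
            return instance.filler_vectors[token]
        return self.vectors[token]

    def save(self, token_path, matrix_path) -> None:
        toks = self.tokens()
        with open(token_path, "w") as fh:
            fh.write("\n".join(toks) + "\n")
        np.savetxt(matrix_path, np.stack([self.vectors[t] for t in toks]))

    @classmethod
    def load(cls, token_path, matrix_path) -> "Lexicon":
        with open(token_path) as fh:
            toks = [line.strip() for line in fh if line.strip()]
        mat = np.loadtxt(matrix_path)
        return cls(vectors={t: mat[i] for i, t in enumerate(toks)}, dim=mat.shape[1])


@dataclass
class RetrievalCorpus:
    """Ordered candidate set for nearest-word retrieval."""

    tokens: list[str]
    matrix: np.ndarray  # (n_tokens, dim), rows unit-norm

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def chance_rate(self) -> float:
        return 1.0 / len(self.tokens)

    def index(self, token: str) -> int:
        return self.tokens.index(token)


def corpus_from_lexicon(lexicon: Lexicon) -> RetrievalCorpus:
    toks = lexicon.tokens()
    mat = np.stack([lexicon.vectors[t] for t in toks])
    mat = mat / np.linalg.norm(mat, axis=1, keepdims=True)
    return RetrievalCorpus(tokens=toks, matrix=mat)


def build_corpus(lexicon: Lexicon, batch: list[StoryInstance] | None = None) -> RetrievalCorpus:
    """Candidate words for one evaluation batch.

    Fixed-embedding experiments pass no batch (or batches without fresh
    fillers) and get the full experiment vocabulary. In the unlimited
    regime every freshly generated filler vector of the batch joins the
    corpus, e.g. 30 base words + 16 stories x 6 fillers = 126 candidates.
    """
    toks = lexicon.tokens()
    vecs = [lexicon.vectors[t] for t in toks]
    if batch:
        for inst in batch:
            for tok, vec in inst.filler_vectors.items():
                toks.append(tok)
                vecs.append(vec)
    mat = np.stack(vecs)
    mat = mat / np.linalg.norm(mat, axis=1, keepdims=True)
    return RetrievalCorpus(tokens=toks, matrix=mat)


def _cosine_to_corpus(prediction: np.ndarray, corpus: RetrievalCorpus) -> np.ndarray:
    norm = np.linalg.norm(prediction)
    if norm == 0:
        raise ValueError("zero prediction vector has no direction")
    return corpus.matrix @ (prediction / norm)


def nearest_word(prediction: np.ndarray, corpus: RetrievalCorpus) -> str:
    """Corpus word with highest cosine similarity; ties -> lowest index."""
    return corpus.tokens[int(np.argmax(_cosine_to_corpus(prediction, corpus)))]


def ranking_score(prediction: np.ndarray, target_token: str,
                  corpus: RetrievalCorpus) -> float:
    """1 - rank/|corpus| of the target under cosine ordering.

    Rank is 0-based with ties broken in favour of the earliest corpus
    index, so an exact hit scores 1 and a uniformly random prediction
    scores 0.5 + 1/(2|corpus|) in expectation.
    """
    sims = _cosine_to_corpus(prediction, corpus)
    t = corpus.index(target_token)
    rank = int(np.sum(sims > sims[t]) + np.sum((sims == sims[t]).nonzero()[0] < t))
    return 1.0 - rank / len(corpus)
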