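"""Trainable role-filler binding networks with a scikit-learn-style surface.

`RecurrentFillerBinder` wraps one of the four recurrent cells behind
fit/predict/score. Training minimizes the mean squared error between the
network's 50-d output (a linear readout of the final recurrent state,
produced after the query token) and the embedding of the correct filler;
prediction retrieves the corpus word with highest cosine similarity to
the output vector.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from ._autodiff import Adam, Tensor, glorot, zeros
from .cells import make_cell
from .embeddings import (EMBED_DIM, Lexicon, RetrievalCorpus, build_corpus,
                         nearest_word)
from .schema import StoryInstance


def encode_batch(instances: Sequence[StoryInstance], lexicon: Lexicon) -> np.ndarray:
    """Stack token embeddings into a (batch, length, dim) array.

    Per-story fresh filler vectors and input-side overrides (the
    zero-vector ambiguous probe) take precedence over the fixed lexicon.
    """
    lengths = {len(inst.tokens) for inst in instances}
    if len(lengths) != 1:
        raise ValueError("all instances in a batch must share one length")
    L = lengths.pop()
    X = np.empty((len(instances), L, lexicon.dim))
    for b, inst in enumerate(instances):
        for t, tok in enumerate(inst.tokens):
            if tok in inst.input_overrides:
                X[b, t] = inst.input_overrides[tok]
            elif tok in inst.filler_vectors:
                X[b, t] = inst.filler_vectors[tok]
            elif tok in lexicon:
                X[b, t] = lexicon.vectors[tok]
            else:
                raise KeyError(f"token {tok!r} not in lexicon or story fillers")
    return X


def target_matrix(instances: Sequence[StoryInstance], lexicon: Lexicon) -> np.ndarray:
    return np.stack([lexicon.lookup(inst.target_token, inst) for inst in instances])


class RecurrentFillerBinder(BaseEstimator):
    """Recurrent network that recalls the filler bound to a queried role.

    Parameters
    ----------
    architecture : {"rnn", "lstm", "fastweights", "dnc"}
    hidden : hidden units of the recurrent core (50 throughout the study).
    learning_rate : Adam step size (1e-4 throughout the study).
    batch_size : minibatch size for training and per-batch corpora.
    max_epochs : hard cap on training epochs.
    patience : epochs without monitored-accuracy improvement before stopping.
    stop_accuracy : optional monitored accuracy at which training stops early.
    dnc_slots, dnc_word, temporal_links : DNC buffer geometry (128 x 20).
    fastweights_decay, fastweights_lr, settle_steps : fast-weight update
        constants (lambda, eta, S).
    random_state : seed for parameter init and minibatch shuffling.

    Attributes
    ----------
    cell_ : the fitted recurrent cell.
    readout_W_, readout_b_ : linear readout onto embedding space.
    history_ : per-epoch records (loss, monitored accuracy).
    n_epochs_ : epochs actually run.
    """

    def __init__(self, architecture: str = "lstm", hidden: int = 50,
                 embed_dim: int = EMBED_DIM, learning_rate: float = 1e-4,
                 batch_size: int = 16, max_epochs: int = 200,
                 patience: int = 10, stop_accuracy: float | None = None,
                 dnc_slots: int = 128, dnc_word: int = 20,
                 temporal_links: bool = True, fastweights_decay: float = 0.95,
                 fastweights_lr: float = 0.5, settle_steps: int = 1,
                 eval_every: int = 1, random_state: int = 0, verbose: int = 0):
        self.architecture = architecture
        self.hidden = hidden
        self.embed_dim = embed_dim
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.stop_accuracy = stop_accuracy
        self.dnc_slots = dnc_slots
        self.dnc_word = dnc_word
        self.temporal_links = temporal_links
        self.fastweights_decay = fastweights_decay
        self.fastweights_lr = fastweights_lr
        self.settle_steps = settle_steps
        self.eval_every = eval_every
        self.random_state = random_state
        self.verbose = verbose

    # -- construction ---------------------------------------------------------

    def _build(self, rng: np.random.Generator) -> None:
        kwargs = {}
        if self.architecture == "dnc":
            kwargs = {"slots": self.dnc_slots, "word": self.dnc_word,
                      "temporal_links": self.temporal_links}
        elif self.architecture == "fastweights":
            kwargs = {"decay": self.fastweights_decay,
                      "fast_lr": self.fastweights_lr,
                      "settle_steps": self.settle_steps}
        self.cell_ = make_cell(self.architecture, rng, input_dim=self.embed_dim,
                               hidden=self.hidden, **kwargs)
        self.readout_W_ = glorot((self.cell_.feature_dim, self.embed_dim), rng)
        self.readout_b_ = zeros(self.embed_dim)

    def _params(self) -> list[Tensor]:
        return self.cell_.params() + [self.readout_W_, self.readout_b_]

    # -- forward --------------------------------------------------------------

    def _forward(self, X: np.ndarray, record: bool = False):
        """Feed tokens one per step; read out from the final (query) state."""
        batch, length, _ = X.shape
        state = self.cell_.init_state(batch)
        traces: list[dict[str, np.ndarray]] = []
        for t in range(length):
            state = self.cell_.step(state, Tensor(X[:, t, :]))
            if record:
                traces.append(self.cell_.trace(state))
        pred = self.cell_.output(state) @ self.readout_W_ + self.readout_b_
        return (pred, traces) if record else pred

    def forward(self, instances: Sequence[StoryInstance], lexicon: Lexicon,
                record: bool = False):
        """Prediction vectors (and optional per-timestep activation traces)."""
        out = self._forward(encode_batch(instances, lexicon), record=record)
        if record:
            pred, traces = out
            return pred.data, traces
        return out.data

    # -- training -------------------------------------------------------------

    def fit(self, stories: Sequence[StoryInstance], lexicon: Lexicon,
            validation: Sequence[StoryInstance] | None = None,
            resample: Callable[[np.random.Generator], list[StoryInstance]] | None = None):
        """Train with Adam on MSE to the target filler embedding.

        ``resample`` supports the unlimited-filler regime: when given, it
        draws a fresh training set (new filler vectors) every epoch.
        Training stops at ``max_epochs``, when the monitored accuracy
        (validation if provided, else training) plateaus for ``patience``
        evaluations, or once it reaches ``stop_accuracy``.
        """
        rng = np.random.default_rng(self.random_state)
        self._build(rng)
        opt = Adam(self._params(), lr=self.learning_rate)
        monitor = validation if validation is not None else stories
        best, stale = -1.0, 0
        self.history_: list[dict] = []
        self.n_epochs_ = 0

        for epoch in range(self.max_epochs):
            train = list(resample(rng)) if resample is not None else list(stories)
            order = rng.permutation(len(train))
            losses = []
            for start in range(0, len(train), self.batch_size):
                batch = [train[i] for i in order[start:start + self.batch_size]]
                X = encode_batch(batch, lexicon)
                Y = target_matrix(batch, lexicon)
                pred = self._forward(X)
                loss = ((pred - Tensor(Y)) ** 2).mean()
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}; training diverged")
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            self.n_epochs_ = epoch + 1
            rec = {"epoch": epoch, "loss": float(np.mean(losses))}
            if (epoch + 1) % self.eval_every == 0:
                acc = self.score(monitor, lexicon)
                rec["accuracy"] = acc
                if self.verbose:
                    print(f"epoch {epoch}: loss {rec['loss']:.5f} acc {acc:.3f}")
                if self.stop_accuracy is not None and acc >= self.stop_accuracy:
                    self.history_.append(rec)
                    break
                if acc > best + 1e-12:
                    best, stale = acc, 0
                else:
                    stale += 1
                    if stale >= self.patience:
                        self.history_.append(rec)
                        break
            self.history_.append(rec)
        return self

    # -- inference ------------------------------------------------------------

    def predict_vectors(self, stories: Sequence[StoryInstance],
                        lexicon: Lexicon) -> np.ndarray:
        preds = []
        for start in range(0, len(stories), self.batch_size):
            batch = list(stories[start:start + self.batch_size])
            preds.append(self.forward(batch, lexicon))
        return np.concatenate(preds, axis=0)

    def predict(self, stories: Sequence[StoryInstance], lexicon: Lexicon,
                corpus: RetrievalCorpus | None = None) -> list[str]:
        """Nearest-corpus-word prediction per story.

        Without an explicit corpus, each minibatch is scored against the
        lexicon plus that batch's fresh filler vectors (the unlimited
        regime's per-batch corpus).
        """
        out: list[str] = []
        for start in range(0, len(stories), self.batch_size):
            batch = list(stories[start:start + self.batch_size])
            c = corpus if corpus is not None else build_corpus(lexicon, batch)
            for vec in self.forward(batch, lexicon):
                out.append(nearest_word(vec, c))
        return out

    def score(self, stories: Sequence[StoryInstance], lexicon: Lexicon,
              corpus: RetrievalCorpus | None = None) -> float:
        """Retrieval accuracy: fraction of stories whose filler is recalled."""
        predicted = self.predict(stories, lexicon, corpus=corpus)
        hits = sum(p == s.target_token for p, s in zip(predicted, stories))
        return hits / len(stories)

    # -- persistence ----------------------------------------------------------

    def save(self, archive_path, config_path=None) -> None:
        """Parameter archive (.npz) plus a JSON config sidecar."""
        import json
        from pathlib import Path

        arrays = {f"p{i}": p.data for i, p in enumerate(self._params())}
        np.savez(archive_path, **arrays)
        cfg = {"format_version": 1, "params": self.get_params(),
               "n_epochs": getattr(self, "n_epochs_", None)}
        config_path = config_path or Path(archive_path).with_suffix(".json")
        with open(config_path, "w") as fh:
            json.dump(cfg, fh, indent=1)

    @classmethod
    def load(cls, archive_path, config_path=None) -> "RecurrentFillerBinder":
        import json
        from pathlib import Path

        config_path = config_path or Path(archive_path).with_suffix(".json")
        with open(config_path) as fh:
            cfg = json.load(fh)
        est = cls(**cfg["params"])
        est._build(np.random.default_rng(est.random_state))
        with np.load(archive_path) as data:
            for i, p in enumerate(est._params()):
                p.data = data[f"p{i}"]
        est.n_epochs_ = cfg.get("n_epochs")
        est.history_ = []
        return est
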