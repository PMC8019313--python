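"""The four recurrent architectures under one step/readout contract.

Every cell maps (state, 50-d input) -> state, exposes its parameters, a
readout feature (the final hidden state; for the DNC, hidden state and
read vector concatenated), and per-timestep trace arrays for the
decoding analyses. All cells use 50 hidden units by default and layer
normalization to stabilize the recurrent dynamics.

External memory comes in two forms:

* Fast Weights: an auto-associative matrix updated by a decayed
  outer-product rule, A <- lambda*A + eta*h h^T, queried through inner
  "settling" iterations of the hidden state.
* DNC: an LSTM controller reading from and writing to a 128x20 slot
  buffer via content-based addressing (cosine keys, sharpened softmax),
  usage-driven allocation, and optional temporal links.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, concat, glorot, ones, zeros

HIDDEN = 50
DIM = 50


def _batch(n: int, d: int) -> Tensor:
    return Tensor(np.zeros((n, d)))


class RNNCell:
    """tanh RNN with layer-normalized pre-activations."""

    arch = "rnn"

    def __init__(self, input_dim: int = DIM, hidden: int = HIDDEN,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.hidden = hidden
        self.U = glorot((input_dim, hidden), rng)
        self.W = glorot((hidden, hidden), rng)
        self.ln_g = ones(hidden)
        self.ln_b = zeros(hidden)

    def params(self) -> list[Tensor]:
        return [self.U, self.W, self.ln_g, self.ln_b]

    def init_state(self, batch: int) -> dict:
        return {"h": _batch(batch, self.hidden)}

    def step(self, state: dict, x: Tensor) -> dict:
        pre = x @ self.U + state["h"] @ self.W
        return {"h": pre.layer_norm(self.ln_g, self.ln_b).tanh()}

    def output(self, state: dict) -> Tensor:
        return state["h"]

    @property
    def feature_dim(self) -> int:
        return self.hidden

    def trace(self, state: dict) -> dict[str, np.ndarray]:
        return {"hidden": state["h"].data.copy()}


class LSTMCell:
    """LSTM with layer normalization on the joint gate pre-activation."""

    arch = "lstm"

    def __init__(self, input_dim: int = DIM, hidden: int = HIDDEN,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.hidden = hidden
        self.Wx = glorot((input_dim, 4 * hidden), rng)
        self.Wh = glorot((hidden, 4 * hidden), rng)
        self.ln_g = ones(4 * hidden)
        self.ln_b = zeros(4 * hidden)

    def params(self) -> list[Tensor]:
        return [self.Wx, self.Wh, self.ln_g, self.ln_b]

    def init_state(self, batch: int) -> dict:
        return {"h": _batch(batch, self.hidden), "c": _batch(batch, self.hidden)}

    def step(self, state: dict, x: Tensor) -> dict:
        H = self.hidden
        pre = (x @ self.Wx + state["h"] @ self.Wh).layer_norm(self.ln_g, self.ln_b)
        i = pre[:, 0 * H:1 * H].sigmoid()
        f = pre[:, 1 * H:2 * H].sigmoid()
        g = pre[:, 2 * H:3 * H].tanh()
        o = pre[:, 3 * H:4 * H].sigmoid()
        c = f * state["c"] + i * g
        return {"h": o * c.tanh(), "c": c}

    def output(self, state: dict) -> Tensor:
        return state["h"]

    @property
    def feature_dim(self) -> int:
        return self.hidden

    def trace(self, state: dict) -> dict[str, np.ndarray]:
        return {"hidden": state["h"].data.copy()}


class FastWeightsCell:
    """RNN augmented with a fast-changing auto-associative weight matrix.

    The slow weights evolve by gradient descent; the fast weights A are
    written every step with the decayed outer product of the previous
    hidden state and read back through S settling iterations, giving the
    network an associative short-term memory spanning the story.
    """

    arch = "fastweights"

    def __init__(self, input_dim: int = DIM, hidden: int = HIDDEN,
                 decay: float = 0.95, fast_lr: float = 0.5,
                 settle_steps: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.hidden = hidden
        self.decay = decay
        self.fast_lr = fast_lr
        self.settle_steps = settle_steps
        self.U = glorot((input_dim, hidden), rng)
        self.W = glorot((hidden, hidden), rng)
        self.ln_g = ones(hidden)
        self.ln_b = zeros(hidden)

    def params(self) -> list[Tensor]:
        return [self.U, self.W, self.ln_g, self.ln_b]

    def init_state(self, batch: int) -> dict:
        return {"h": _batch(batch, self.hidden),
                "A": Tensor(np.zeros((batch, self.hidden, self.hidden)))}

    def step(self, state: dict, x: Tensor) -> dict:
        h_prev = state["h"]
        # store the previous pattern, then settle the new one against A
        hh = h_prev.reshape(-1, self.hidden, 1) @ h_prev.reshape(-1, 1, self.hidden)
        A = self.decay * state["A"] + self.fast_lr * hh
        z = x @ self.U + h_prev @ self.W
        h = z.tanh()
        for _ in range(self.settle_steps):
            bounce = (A @ h.reshape(-1, self.hidden, 1)).reshape(-1, self.hidden)
            h = (z + bounce).layer_norm(self.ln_g, self.ln_b).tanh()
        return {"h": h, "A": A}

    def output(self, state: dict) -> Tensor:
        return state["h"]

    @property
    def feature_dim(self) -> int:
        return self.hidden

    def trace(self, state: dict) -> dict[str, np.ndarray]:
        return {"hidden": state["h"].data.copy(),
                "memory": state["A"].data.reshape(state["A"].shape[0], -1).copy()}


class DNCCell:
    """Differentiable Neural Computer: LSTM controller + slot memory.

    One write head and one read head address a ``slots x word`` buffer by
    content (cosine similarity keys with softplus-sharpened softmax) and,
    for writing, by usage-based allocation. With ``temporal_links`` on
    (the default) the read head can also follow the order in which slots
    were written. The readout feature is [controller h; read vector].
    """

    arch = "dnc"

    def __init__(self, input_dim: int = DIM, hidden: int = HIDDEN,
                 slots: int = 128, word: int = 20, temporal_links: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.hidden = hidden
        self.slots = slots
        self.word = word
        self.temporal_links = temporal_links
        self.controller = LSTMCell(input_dim + word, hidden, rng=rng)
        # interface: read key+strength, write key+strength, erase, write vec,
        # free gate, allocation gate, write gate, 3 read modes
        self.iface_dim = word + 1 + word + 1 + word + word + 1 + 1 + 1 + 3
        self.W_iface = glorot((hidden, self.iface_dim), rng)
        self.b_iface = zeros(self.iface_dim)

    def params(self) -> list[Tensor]:
        return self.controller.params() + [self.W_iface, self.b_iface]

    def init_state(self, batch: int) -> dict:
        n, w = self.slots, self.word
        return {
            "ctrl": self.controller.init_state(batch),
            "M": Tensor(np.zeros((batch, n, w))),
            "read_w": Tensor(np.zeros((batch, n))),
            "write_w": Tensor(np.zeros((batch, n))),
            "usage": Tensor(np.zeros((batch, n))),
            "read_vec": _batch(batch, w),
            "link": Tensor(np.zeros((batch, n, n))),
            "precedence": Tensor(np.zeros((batch, n))),
        }

    @staticmethod
    def _content_weighting(M: Tensor, key: Tensor, beta: Tensor) -> Tensor:
        """Sharpened softmax over cosine similarity of each slot to the key."""
        eps = 1e-8
        m_norm = ((M * M).sum(axis=-1) + eps).sqrt()
        k_norm = ((key * key).sum(axis=-1, keepdims=True) + eps).sqrt()
        sims = (M @ key.reshape(-1, key.shape[-1], 1)).reshape(M.shape[0], M.shape[1])
        cos = sims / (m_norm * k_norm)
        return (beta * cos).softmax(axis=-1)

    def _allocation(self, usage: np.ndarray) -> np.ndarray:
        """Allocation weighting over slots (least-used first).

        Computed outside the tape: the sort makes it piecewise constant in
        usage, and gradients still reach the write path through the gates
        and content addressing.
        """
        order = np.argsort(usage, axis=-1, kind="stable")
        sorted_u = np.take_along_axis(usage, order, axis=-1)
        prods = np.cumprod(np.concatenate(
            [np.ones_like(sorted_u[:, :1]), sorted_u[:, :-1]], axis=-1), axis=-1)
        alloc_sorted = (1.0 - sorted_u) * prods
        alloc = np.zeros_like(usage)
        np.put_along_axis(alloc, order, alloc_sorted, axis=-1)
        return alloc

    def step(self, state: dict, x: Tensor) -> dict:
        w = self.word
        ctrl_in = concat([x, state["read_vec"]], axis=-1)
        ctrl = self.controller.step(state["ctrl"], ctrl_in)
        h = ctrl["h"]
        iface = h @ self.W_iface + self.b_iface

        i = 0
        def take(n):
            nonlocal i
            part = iface[:, i:i + n]
            i += n
            return part

        read_key = take(w)
        read_beta = 1.0 + take(1).softplus()
        write_key = take(w)
        write_beta = 1.0 + take(1).softplus()
        erase = take(w).sigmoid()
        write_vec = take(w)
        free_gate = take(1).sigmoid()
        alloc_gate = take(1).sigmoid()
        write_gate = take(1).sigmoid()
        read_modes = take(3).softmax(axis=-1)

        # usage update and allocation
        retention = 1.0 - free_gate * state["read_w"]
        usage = (state["usage"] + state["write_w"]
                 - state["usage"] * state["write_w"]) * retention
        alloc = Tensor(self._allocation(usage.data))

        write_content = self._content_weighting(state["M"], write_key, write_beta)
        write_w = write_gate * (alloc_gate * alloc + (1.0 - alloc_gate) * write_content)

        # erase/add memory update
        ww = write_w.reshape(-1, self.slots, 1)
        M = state["M"] * (1.0 - ww @ erase.reshape(-1, 1, w)) + ww @ write_vec.reshape(-1, 1, w)

        read_content = self._content_weighting(M, read_key, read_beta)
        if self.temporal_links:
            ww_i = write_w.reshape(-1, self.slots, 1)
            ww_j = write_w.reshape(-1, 1, self.slots)
            link = (1.0 - ww_i - ww_j) * state["link"] \
                + ww_i @ state["precedence"].reshape(-1, 1, self.slots)
            link = link * Tensor(1.0 - np.eye(self.slots)[None])
            precedence = (1.0 - write_w.sum(axis=-1, keepdims=True)) \
                * state["precedence"] + write_w
            rw_col = state["read_w"].reshape(-1, self.slots, 1)
            forward_w = (link @ rw_col).reshape(-1, self.slots)
            backward_w = (link.swapaxes(-1, -2) @ rw_col).reshape(-1, self.slots)
            read_w = (read_modes[:, 0:1] * backward_w
                      + read_modes[:, 1:2] * read_content
                      + read_modes[:, 2:3] * forward_w)
        else:
            link, precedence = state["link"], state["precedence"]
            read_w = read_content

        read_vec = (read_w.reshape(-1, 1, self.slots) @ M).reshape(-1, w)
        return {"ctrl": ctrl, "M": M, "read_w": read_w, "write_w": write_w,
                "usage": usage, "read_vec": read_vec, "link": link,
                "precedence": precedence}

    def output(self, state: dict) -> Tensor:
        return concat([state["ctrl"]["h"], state["read_vec"]], axis=-1)

    @property
    def feature_dim(self) -> int:
        return self.hidden + self.word

    def trace(self, state: dict) -> dict[str, np.ndarray]:
        return {"hidden": state["ctrl"]["h"].data.copy(),
                "memory": state["M"].data.reshape(state["M"].shape[0], -1).copy(),
                "read_w": state["read_w"].data.copy(),
                "write_w": state["write_w"].data.copy()}


CELLS = {"rnn": RNNCell, "lstm": LSTMCell, "fastweights": FastWeightsCell, "dnc": DNCCell}


def make_cell(architecture: str, rng: np.random.Generator, *,
              input_dim: int = DIM, hidden: int = HIDDEN, **kwargs):
    if architecture not in CELLS:
        raise ValueError(f"unknown architecture {architecture!r}; one of {sorted(CELLS)}")
    return CELLS[architecture](input_dim=input_dim, hidden=hidden, rng=rng, **kwargs)
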