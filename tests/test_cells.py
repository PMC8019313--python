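"""Step semantics of the four recurrent cells."""

import numpy as np
import pytest

from schemabind._autodiff import Tensor
from schemabind.cells import (DNCCell, FastWeightsCell, LSTMCell, RNNCell,
                              make_cell)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


class TestRNN:
    def test_zero_gain_outputs_tanh_of_bias(self, rng):
        cell = RNNCell(input_dim=5, hidden=4, rng=rng)
        cell.ln_g.data[:] = 0.0
        cell.ln_b.data[:] = np.array([0.3, -0.2, 0.0, 1.0])
        state = cell.init_state(2)
        out = cell.step(state, Tensor(rng.standard_normal((2, 5))))
        np.testing.assert_allclose(out["h"].data,
                                   np.tanh([0.3, -0.2, 0.0, 1.0])[None].repeat(2, 0))

    def test_matches_hand_rolled_loop(self, rng):
        """One step equals explicit per-unit arithmetic on toy weights."""
        cell = RNNCell(input_dim=5, hidden=5, rng=rng)
        x = rng.standard_normal((1, 5))
        h0 = rng.standard_normal((1, 5))
        state = {"h": Tensor(h0)}
        out = cell.step(state, Tensor(x))["h"].data[0]

        pre = np.zeros(5)
        for j in range(5):
            for i in range(5):
                pre[j] += x[0, i] * cell.U.data[i, j] + h0[0, i] * cell.W.data[i, j]
        mu, var = pre.mean(), pre.var()
        xhat = (pre - mu) / np.sqrt(var + 1e-5)
        expected = np.tanh(cell.ln_g.data * xhat + cell.ln_b.data)
        np.testing.assert_allclose(out, expected, rtol=1e-12)


class TestLSTM:
    def _forced_gate_cell(self, rng, i_gate, f_gate):
        """Zero the LN gain so gate pre-activations equal the LN bias."""
        cell = LSTMCell(input_dim=3, hidden=2, rng=rng)
        cell.ln_g.data[:] = 0.0
        big = 50.0
        cell.ln_b.data[:] = 0.0
        cell.ln_b.data[0:2] = big if i_gate else -big
        cell.ln_b.data[2:4] = big if f_gate else -big
        return cell

    def test_closed_gates_preserve_cell(self, rng):
        cell = self._forced_gate_cell(rng, i_gate=False, f_gate=True)
        c0 = rng.standard_normal((1, 2))
        state = {"h": Tensor(np.zeros((1, 2))), "c": Tensor(c0)}
        out = cell.step(state, Tensor(rng.standard_normal((1, 3))))
        np.testing.assert_allclose(out["c"].data, c0, atol=1e-12)

    def test_half_gates_match_hand_computation(self, rng):
        """All gates at 0.5 (zero pre-activations): c' = 0.5*c, h = 0.5*tanh(c')."""
        cell = LSTMCell(input_dim=3, hidden=2, rng=rng)
        cell.ln_g.data[:] = 0.0
        cell.ln_b.data[:] = 0.0  # sigmoid(0)=0.5, tanh(0)=0
        c0 = np.array([[0.8, -0.4]])
        state = {"h": Tensor(np.zeros((1, 2))), "c": Tensor(c0)}
        out = cell.step(state, Tensor(rng.standard_normal((1, 3))))
        np.testing.assert_allclose(out["c"].data, 0.5 * c0, atol=1e-12)
        np.testing.assert_allclose(out["h"].data, 0.5 * np.tanh(0.5 * c0), atol=1e-12)

    def test_hidden_state_bounded(self, rng):
        cell = LSTMCell(input_dim=4, hidden=3, rng=rng)
        state = cell.init_state(2)
        for _ in range(30):
            state = cell.step(state, Tensor(10 * rng.standard_normal((2, 4))))
            assert np.all(np.abs(state["h"].data) < 1.0)


class TestFastWeights:
    def test_stored_pattern_is_eigenvector(self, rng):
        """lambda=0, eta=1: A = h h^T, so A h = ||h||^2 h."""
        cell = FastWeightsCell(input_dim=3, hidden=4, decay=0.0, fast_lr=1.0, rng=rng)
        h = rng.standard_normal((1, 4))
        state = {"h": Tensor(h), "A": Tensor(np.zeros((1, 4, 4)))}
        out = cell.step(state, Tensor(rng.standard_normal((1, 3))))
        A = out["A"].data[0]
        np.testing.assert_allclose(A @ h[0], np.dot(h[0], h[0]) * h[0], rtol=1e-12)

    def test_zero_fast_lr_freezes_memory(self, rng):
        cell = FastWeightsCell(input_dim=3, hidden=4, decay=1.0, fast_lr=0.0, rng=rng)
        A0 = rng.standard_normal((1, 4, 4))
        state = {"h": Tensor(rng.standard_normal((1, 4))), "A": Tensor(A0.copy())}
        for _ in range(3):
            state = cell.step(state, Tensor(rng.standard_normal((1, 3))))
        np.testing.assert_allclose(state["A"].data, A0, atol=1e-12)

    def test_orthogonal_patterns_recalled_independently(self, rng):
        """After storing two orthogonal unit patterns, A h1 = h1."""
        cell = FastWeightsCell(input_dim=3, hidden=4, decay=1.0, fast_lr=1.0, rng=rng)
        h1 = np.array([1.0, 0, 0, 0])
        h2 = np.array([0, 1.0, 0, 0])
        A = np.outer(h1, h1) + np.outer(h2, h2)
        np.testing.assert_allclose(A @ h1, h1, atol=1e-12)

    def test_memory_norm_bounded_under_decay(self, rng):
        """||A|| <= eta * max||h||^2 / (1 - lambda) when lambda < 1."""
        cell = FastWeightsCell(input_dim=3, hidden=6, decay=0.9, fast_lr=0.5, rng=rng)
        state = cell.init_state(1)
        for _ in range(200):
            state = cell.step(state, Tensor(rng.standard_normal((1, 3))))
        # h is tanh-bounded so ||h||^2 <= hidden
        bound = 0.5 * 6 / (1 - 0.9)
        assert np.linalg.norm(state["A"].data[0], 2) <= bound + 1e-9


class TestDNC:
    @pytest.fixture
    def cell(self, rng):
        return DNCCell(input_dim=4, hidden=5, slots=6, word=3, rng=rng)

    def test_erase_add_replaces_slot(self, cell):
        """One-hot write with full erase makes row k exactly the add vector."""
        M = Tensor(np.arange(18, dtype=float).reshape(1, 6, 3))
        ww = np.zeros((1, 6)); ww[0, 2] = 1.0
        erase = np.ones((1, 3))
        add = np.array([[9.0, 8.0, 7.0]])
        wwc = Tensor(ww).reshape(-1, 6, 1)
        out = (M * (1.0 - wwc @ Tensor(erase).reshape(-1, 1, 3))
               + wwc @ Tensor(add).reshape(-1, 1, 3)).data[0]
        np.testing.assert_allclose(out[2], [9, 8, 7])
        np.testing.assert_allclose(out[0], M.data[0, 0])

    def test_one_hot_read_returns_slot(self, cell):
        state = cell.init_state(1)
        state["M"].data[0] = np.arange(18).reshape(6, 3)
        rw = np.zeros((1, 6)); rw[0, 4] = 1.0
        read = (Tensor(rw).reshape(-1, 1, 6) @ state["M"]).data.reshape(1, 3)
        np.testing.assert_allclose(read[0], state["M"].data[0, 4])

    def test_content_addressing_sharpens_to_match(self, cell):
        """An exact key with high strength concentrates >=0.99 on its slot."""
        M = Tensor(np.eye(3)[None][:, :, :3] * 1.0)
        M = Tensor(np.stack([np.eye(3)])[..., :3])
        key = Tensor(np.array([[0.0, 1.0, 0.0]]))
        beta = Tensor(np.array([[60.0]]))
        w = cell._content_weighting(M, key, beta).data[0]
        assert w[1] >= 0.99

    def test_weightings_stay_on_simplex(self, cell, rng):
        state = cell.init_state(2)
        for _ in range(12):
            state = cell.step(state, Tensor(rng.standard_normal((2, 4))))
            for k in ("read_w", "write_w"):
                w = state[k].data
                assert np.all(w >= -1e-12)
                assert np.all(w.sum(axis=-1) <= 1.0 + 1e-9)

    def test_trace_dimensions(self, rng):
        cell = DNCCell(input_dim=50, hidden=50, slots=128, word=20, rng=rng)
        state = cell.init_state(1)
        state = cell.step(state, Tensor(rng.standard_normal((1, 50))))
        tr = cell.trace(state)
        assert tr["memory"].shape == (1, 2560)
        assert tr["hidden"].shape == (1, 50)
        assert tr["read_w"].shape == (1, 128)


class TestContract:
    """All four architectures expose the same step/output/trace interface."""

    @pytest.mark.parametrize("arch", ["rnn", "lstm", "fastweights", "dnc"])
    def test_swap_in_equivalence(self, arch, rng):
        kwargs = {"slots": 8, "word": 4} if arch == "dnc" else {}
        cell = make_cell(arch, rng, input_dim=7, hidden=6, **kwargs)
        state = cell.init_state(3)
        for _ in range(4):
            state = cell.step(state, Tensor(rng.standard_normal((3, 7))))
        out = cell.output(state)
        assert out.data.shape == (3, cell.feature_dim)
        assert set(cell.trace(state)) >= {"hidden"}

    def test_unknown_architecture_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown architecture"):
            make_cell("transformer", rng)

    @pytest.mark.parametrize("arch", ["rnn", "lstm", "fastweights"])
    def test_fastweights_flattened_length(self, arch, rng):
        cell = make_cell(arch, rng, input_dim=50, hidden=50)
        state = cell.init_state(1)
        state = cell.step(state, Tensor(rng.standard_normal((1, 50))))
        tr = cell.trace(state)
        if arch == "fastweights":
            assert tr["memory"].shape == (1, 2500)
        else:
            assert "memory" not in tr
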