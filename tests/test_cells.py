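"""Unit and property tests for the LSTM and integrated-contextual-gate cells."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from icgn_bci.cells import (
    CellState,
    SquaredLoss,
    bidirectional_unroll,
    cell_gradients,
    gradient_check,
    icgn_step,
    init_cell_parameters,
    lstm_step,
    unroll,
)

SIG1 = 1.0 / (1.0 + np.exp(-1.0))  # sigmoid(1)
TANH1 = np.tanh(1.0)


def _ones_cell(kind: str) -> "CellParameters":
    p = init_cell_parameters(kind, 1, 1, "zeros", seed=0)
    for name in ("wxi", "wxf", "wxo", "wxc", "whi", "whf", "who", "whc"):
        getattr(p, name)[...] = 1.0
    if kind == "icgn":
        for name in ("wci", "wcf", "wco", "wcc"):
            getattr(p, name)[...] = 1.0
    return p


class TestInit:
    def test_zero_scheme_gives_all_zero_parameters(self):
        p = init_cell_parameters("lstm", 3, 2, "zeros", seed=99)
        assert all(np.all(a == 0) for a in p.named_arrays().values())

    def test_same_seed_is_bitwise_reproducible(self):
        a = init_cell_parameters("icgn", 4, 3, "uniform_scaled", seed=7)
        b = init_cell_parameters("icgn", 4, 3, "uniform_scaled", seed=7)
        for name, arr in a.named_arrays().items():
            assert np.array_equal(arr, b.named_arrays()[name])

    def test_icgn_has_cell_context_matrices(self):
        p = init_cell_parameters("icgn", 1, 1, "uniform_scaled", seed=7)
        for name in ("wci", "wcf", "wco"):
            assert getattr(p, name).shape == (1, 1)

    @pytest.mark.parametrize("kwargs", [
        dict(cell_kind="lstm", input_dim=0, hidden_dim=1),
        dict(cell_kind="lstm", input_dim=1, hidden_dim=1, init_scheme="bogus"),
    ])
    def test_invalid_arguments_raise(self, kwargs):
        with pytest.raises(ValueError):
            init_cell_parameters(**{"init_scheme": "zeros", **kwargs})

    def test_shared_candidate_aliases_forget_weights(self):
        p = init_cell_parameters("icgn", 2, 2, "uniform_scaled", seed=1,
                                 share_candidate_with_forget=True)
        assert p.wxc is p.wxf and p.whc is p.whf and p.bc is p.bf and p.wcc is p.wcf
        assert "wxc" not in p.named_arrays()


class TestStepOracles:
    @pytest.mark.parametrize("kind,step", [("lstm", lstm_step), ("icgn", icgn_step)])
    def test_zero_everything_gives_half_gates_and_zero_state(self, kind, step):
        p = init_cell_parameters(kind, 2, 3, "zeros", seed=0)
        state, trace = step(p, np.zeros(2), CellState.zeros(3))
        assert np.allclose(trace.i, 0.5) and np.allclose(trace.f, 0.5)
        assert np.allclose(trace.o, 0.5) and np.allclose(trace.candidate, 0.0)
        assert np.allclose(state.c, 0.0) and np.allclose(state.h, 0.0)

    def test_lstm_zero_weights_halve_previous_cell_state(self):
        p = init_cell_parameters("lstm", 2, 3, "zeros", seed=0)
        c0 = np.ones(3)
        state, _ = lstm_step(p, np.zeros(2), CellState(c=c0, h=np.zeros(3)))
        assert np.allclose(state.c, 0.5 * c0)
        assert np.allclose(state.h, 0.5 * np.tanh(0.5 * c0))

    def test_lstm_scalar_unit_weights(self):
        # independent scalar arithmetic: i=f=o=sig(1), g=tanh(1)
        state, trace = lstm_step(_ones_cell("lstm"), np.array([1.0]), CellState.zeros(1))
        c_expect = SIG1 * 0.0 + SIG1 * TANH1
        assert np.isclose(state.c[0], c_expect)
        assert np.isclose(state.h[0], SIG1 * np.tanh(c_expect))
        assert np.isclose(trace.i[0], SIG1)

    def test_icgn_scalar_unit_weights(self):
        # memory state = (f+i+o)*candidate with zero previous cell state
        state, trace = icgn_step(_ones_cell("icgn"), np.array([1.0]), CellState.zeros(1))
        c_expect = 3.0 * SIG1 * TANH1
        assert np.isclose(state.c[0], c_expect)
        assert np.isclose(state.h[0], SIG1 * np.tanh(c_expect))

    def test_dimension_mismatch_raises(self):
        p = init_cell_parameters("lstm", 2, 3, "zeros", seed=0)
        with pytest.raises(ValueError):
            lstm_step(p, np.zeros(5), CellState.zeros(3))
        with pytest.raises(ValueError):
            lstm_step(p, np.array([np.nan, 0.0]), CellState.zeros(3))

    def test_step_requires_matching_cell_kind(self):
        p = init_cell_parameters("lstm", 1, 1, "zeros", seed=0)
        with pytest.raises(ValueError):
            icgn_step(p, np.zeros(1), CellState.zeros(1))


class TestProperties:
    def test_icgn_state_bound_randomized(self, rng):
        """|C| < 3 and |H| < tanh(3) for random parameters, inputs and states.

        Draws are bounded so pre-activations stay below the float64
        saturation point of tanh/sigmoid, keeping the exact-arithmetic
        strict bounds observable numerically."""
        worst_c, worst_h = 0.0, 0.0
        for _ in range(1000):
            D, H = int(rng.integers(1, 4)), int(rng.integers(1, 4))
            p = init_cell_parameters("icgn", D, H, "uniform_scaled", seed=int(rng.integers(1 << 30)))
            state = CellState(c=rng.uniform(-3, 3, H), h=rng.uniform(-1, 1, H))
            state, trace = icgn_step(p, rng.uniform(-2, 2, D), state)
            worst_c = max(worst_c, np.abs(state.c).max())
            worst_h = max(worst_h, np.abs(state.h).max())
            for g in (trace.i, trace.f, trace.o):
                assert np.all((g > 0) & (g < 1))
            assert np.all(np.abs(trace.candidate) < 1)
        assert worst_c < 3.0
        assert worst_h < np.tanh(3.0)

    def test_icgn_state_bound_under_saturation(self, rng):
        """Amplified weights drive tanh/sigmoid into float saturation; the
        state bound still holds as a closed interval."""
        for _ in range(200):
            D, H = int(rng.integers(1, 4)), int(rng.integers(1, 4))
            p = init_cell_parameters("icgn", D, H, "normal_scaled", seed=int(rng.integers(1 << 30)))
            for arr in p.named_arrays().values():
                arr *= rng.uniform(5.0, 20.0)
            state = CellState(c=rng.normal(0, 2, H), h=rng.normal(0, 1, H))
            state, _ = icgn_step(p, rng.normal(0, 3, D), state)
            assert np.all(np.abs(state.c) <= 3.0)
            assert np.all(np.abs(state.h) <= np.tanh(3.0))

    def test_icgn_with_zero_context_matches_lstm_gates(self, rng):
        """Zeroed cell-context weights reduce the icgn gates to the lstm gates."""
        D, H = 3, 4
        seed = 42
        pl = init_cell_parameters("lstm", D, H, "uniform_scaled", seed=seed)
        pi = init_cell_parameters("icgn", D, H, "uniform_scaled", seed=seed)
        for name in ("wxi", "wxf", "wxo", "wxc", "whi", "whf", "who", "whc", "bi", "bf", "bo", "bc"):
            getattr(pi, name)[...] = getattr(pl, name)
        for name in ("wci", "wcf", "wco", "wcc"):
            getattr(pi, name)[...] = 0.0
        x = rng.normal(size=D)
        st0 = CellState(c=rng.normal(size=H), h=rng.normal(size=H))
        _, tl = lstm_step(pl, x, st0)
        _, ti = icgn_step(pi, x, st0)
        for a, b in zip((tl.i, tl.f, tl.o, tl.candidate), (ti.i, ti.f, ti.o, ti.candidate)):
            assert np.allclose(a, b)

    @given(seed=st.integers(0, 2**20), t=st.integers(1, 6))
    @settings(max_examples=25, deadline=None)
    def test_unroll_matches_stepwise_iteration(self, seed, t):
        rng = np.random.default_rng(seed)
        kind = "icgn" if seed % 2 else "lstm"
        p = init_cell_parameters(kind, 2, 3, "normal_scaled", seed=seed)
        X = rng.normal(size=(t, 2))
        H_seq, final = unroll(p, X)
        state = CellState.zeros(3)
        step = icgn_step if kind == "icgn" else lstm_step
        for k in range(t):
            state, _ = step(p, X[k], state)
            assert np.allclose(H_seq[k], state.h)
        assert np.allclose(final.c, state.c) and np.allclose(final.h, state.h)

    def test_unroll_rejects_empty_sequence(self):
        p = init_cell_parameters("lstm", 2, 3, "zeros", seed=0)
        with pytest.raises(ValueError):
            unroll(p, np.empty((0, 2)))

    def test_forward_is_deterministic(self, rng):
        p = init_cell_parameters("icgn", 3, 4, "uniform_scaled", seed=5)
        X = rng.normal(size=(7, 3))
        a, _ = unroll(p, X)
        b, _ = unroll(p, X)
        assert np.array_equal(a, b)


class TestBidirectional:
    def test_palindrome_with_tied_weights_is_symmetric(self):
        p = init_cell_parameters("lstm", 1, 2, "uniform_scaled", seed=3)
        X = np.array([[0.3], [0.7], [0.3]])
        out = bidirectional_unroll(p, p, X)
        T, H = 3, 2
        for t in range(T):
            assert np.allclose(out[t, :H], out[T - 1 - t, H:])

    def test_zero_parameters_give_zero_output(self):
        p = init_cell_parameters("icgn", 2, 2, "zeros", seed=0)
        out = bidirectional_unroll(p, p, np.ones((4, 2)))
        assert np.allclose(out, 0.0)

    def test_concatenation_equals_two_independent_passes(self, rng):
        pf = init_cell_parameters("lstm", 1, 1, "normal_scaled", seed=1)
        pb = init_cell_parameters("lstm", 1, 1, "normal_scaled", seed=2)
        X = rng.normal(size=(2, 1))
        out = bidirectional_unroll(pf, pb, X)
        fwd, _ = unroll(pf, X)
        bwd, _ = unroll(pb, X[::-1])
        assert np.allclose(out[:, :1], fwd)
        assert np.allclose(out[:, 1:], bwd[::-1])

    def test_mismatched_dims_raise(self):
        pf = init_cell_parameters("lstm", 2, 2, "zeros", seed=0)
        pb = init_cell_parameters("lstm", 2, 3, "zeros", seed=0)
        with pytest.raises(ValueError):
            bidirectional_unroll(pf, pb, np.ones((3, 2)))


class TestGradients:
    def test_zero_cell_zero_target_has_zero_gradients(self):
        p = init_cell_parameters("lstm", 2, 2, "zeros", seed=0)
        loss, grads = cell_gradients(p, np.zeros((3, 2)), SquaredLoss(np.zeros(2)))
        assert loss == 0.0
        assert all(np.all(g == 0) for g in grads.values())

    @pytest.mark.parametrize("kind", ["lstm", "icgn"])
    @pytest.mark.parametrize("flags", [
        {},
        {"share_candidate_with_forget": True},
    ])
    def test_bptt_matches_finite_differences(self, kind, flags, rng):
        p = init_cell_parameters(kind, 2, 3, "normal_scaled", seed=17, **flags)
        X = rng.normal(size=(4, 2))
        err = gradient_check(p, X, SquaredLoss(rng.normal(size=3)))
        assert err < 1e-5

    def test_bptt_matches_finite_differences_sequence_loss(self, rng):
        p = init_cell_parameters("icgn", 2, 2, "normal_scaled", seed=23,
                                 share_output_context_with_forget=True)
        X = rng.normal(size=(5, 2))
        err = gradient_check(p, X, SquaredLoss(np.zeros((5, 2)), on="sequence"))
        assert err < 1e-5

    def test_candidate_context_flag_changes_forward_and_keeps_gradients_exact(self, rng):
        p = init_cell_parameters("icgn", 2, 2, "normal_scaled", seed=31,
                                 candidate_uses_cell_context=False)
        X = rng.normal(size=(4, 2))
        err = gradient_check(p, X, SquaredLoss(rng.normal(size=2)))
        assert err < 1e-5
        assert "wcc" not in p.named_arrays()
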