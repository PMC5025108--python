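import numpy as np
import pytest

from spermseg.icm import DEFAULT_W, ICMParams, init_state, run_icm, step_icm


def icm_loop_reference(s, params):
    """Literal per-pixel transcription of the three coupled recurrences.

    Independent of the vectorised implementation: explicit Python loops,
    explicit zero padding for the link kernel.
    """
    h_, w_ = s.shape
    F = np.zeros((h_, w_))
    E = np.full((h_, w_), params.e_init)
    Y = np.zeros((h_, w_), dtype=np.uint8)
    history = []
    for _ in range(params.n_iterations):
        link = np.zeros((h_, w_))
        for i in range(h_):
            for j in range(w_):
                acc = 0.0
                for a in (-1, 0, 1):
                    for b in (-1, 0, 1):
                        ii, jj = i + a, j + b
                        if 0 <= ii < h_ and 0 <= jj < w_:
                            acc += params.w[a + 1, b + 1] * Y[ii, jj]
                link[i, j] = acc
        F_new = np.empty((h_, w_))
        Y_new = np.empty((h_, w_), dtype=np.uint8)
        E_new = np.empty((h_, w_))
        for i in range(h_):
            for j in range(w_):
                F_new[i, j] = params.f * F[i, j] + s[i, j] + link[i, j]
                Y_new[i, j] = 1 if F_new[i, j] > E[i, j] else 0
                E_new[i, j] = params.g * E[i, j] + params.h * Y_new[i, j]
        F, E, Y = F_new, E_new, Y_new
        history.append(Y.copy())
    return Y, history


def scalar_recurrence(s, f, g, h, e0, n_steps, self_weight=1.0):
    """Hand-rolled single-neuron recurrence (own pulse feeds back via W)."""
    F, E, Y = 0.0, e0, 0
    trace = []
    for _ in range(n_steps):
        F = f * F + s + self_weight * Y
        Y = 1 if F > E else 0
        E = g * E + h * Y
        trace.append((F, E, Y))
    return trace


def random_valid_params(rng, n_iterations=None):
    f = rng.uniform(0.1, 0.98)
    g = rng.uniform(0.02, 0.95) * f
    h = -rng.uniform(0.1, 5.0)
    n = int(n_iterations or rng.integers(1, 7))
    return ICMParams(f=f, g=g, h=h, n_iterations=n)


class TestParams:
    def test_decay_ordering_enforced(self):
        with pytest.raises(ValueError):
            ICMParams(f=0.5, g=0.6, h=-1, n_iterations=1)
        with pytest.raises(ValueError):
            ICMParams(f=1.1, g=0.5, h=-1, n_iterations=1)

    def test_positive_h_rejected(self):
        with pytest.raises(ValueError):
            ICMParams(f=0.9, g=0.5, h=0.1, n_iterations=1)

    def test_default_link_kernel(self):
        p = ICMParams(f=0.9, g=0.5, h=-1, n_iterations=1)
        np.testing.assert_array_equal(p.w, DEFAULT_W)
        assert p.w[1, 1] == 1.0 and p.w[0, 1] == 0.01


class TestInitState:
    def test_initial_grids(self):
        img = np.random.default_rng(0).uniform(0, 1, (6, 7))
        st = init_state(img, ICMParams(f=0.9, g=0.8, h=-1, n_iterations=1))
        assert (st.F == 0).all()
        assert (st.E == 5.0).all()
        assert (st.Y == 0).all()
        assert st.iteration == 0


class TestSingleNeuronDynamics:
    """Isolated-pixel firing dynamics vs the hand-rolled recurrence."""

    def test_first_firing_at_iteration_six(self):
        trace = scalar_recurrence(0.5, 0.9, 0.8, -1.0, 5.0, 8)
        first_fire = next(i for i, (_, _, y) in enumerate(trace, start=1) if y)
        assert first_fire == 6
        # the near-miss one step earlier: F = 2.04755 vs E = 2.048
        F5, E4 = trace[4][0], trace[3][1]
        assert F5 == pytest.approx(2.04755)
        assert E4 == pytest.approx(2.048)
        assert F5 < E4

    def test_threshold_drop_after_firing(self):
        trace = scalar_recurrence(0.5, 0.9, 0.8, -1.0, 5.0, 6)
        # E after the firing step: 0.8 * 1.6384 - 1 = 0.31072
        assert trace[5][1] == pytest.approx(0.31072)

    def test_refires_forever_after_first_pulse(self):
        trace = scalar_recurrence(0.5, 0.9, 0.8, -1.0, 5.0, 40)
        fired = [y for _, _, y in trace]
        first = fired.index(1)
        assert all(fired[first:])

    def test_run_icm_matches_scalar_recurrence_on_1x1(self):
        params = ICMParams(f=0.9, g=0.8, h=-1.0, n_iterations=9)
        s = np.array([[0.5]])
        _, history = run_icm(s, params)
        expected = scalar_recurrence(0.5, 0.9, 0.8, -1.0, 5.0, 9)
        assert [int(m[0, 0]) for m in history] == [y for _, _, y in expected]

    def test_any_stimulated_pixel_eventually_fires(self):
        # E decays geometrically while F climbs toward S/(1-f) > 0
        for s, f, g in [(0.05, 0.6, 0.3), (0.3, 0.9, 0.85), (0.9, 0.2, 0.1)]:
            trace = scalar_recurrence(s, f, g, -1.0, 5.0, 200)
            assert any(y for _, _, y in trace)


class TestGridDynamics:
    def test_matches_per_pixel_loop_reference(self, rng):
        for _ in range(5):
            s = rng.uniform(0, 1, size=(8, 8))
            params = random_valid_params(rng)
            mask, hist = run_icm(s, params)
            ref_mask, ref_hist = icm_loop_reference(s, params)
            np.testing.assert_array_equal(mask, ref_mask)
            for a, b in zip(hist, ref_hist):
                np.testing.assert_array_equal(a, b)

    def test_nothing_fires_on_first_iteration(self):
        s = np.random.default_rng(3).uniform(0, 1, (10, 10))
        mask, _ = run_icm(s, ICMParams(f=0.9, g=0.8, h=-1, n_iterations=1))
        assert not mask.any()

    def test_constant_image_pulses_uniformly(self):
        s = np.full((9, 9), 0.7)
        params = ICMParams(f=0.9, g=0.5, h=-1, n_iterations=6)
        _, hist = run_icm(s, params)
        for m in hist:
            # all pixels identical up to border effects of the link kernel;
            # before any firing the grid is exactly uniform
            interior = m[1:-1, 1:-1]
            assert interior.min() == interior.max()

    def test_deterministic(self):
        s = np.random.default_rng(5).uniform(0, 1, (12, 12))
        params = ICMParams(f=0.7, g=0.4, h=-2, n_iterations=5)
        m1, _ = run_icm(s, params)
        m2, _ = run_icm(s, params)
        np.testing.assert_array_equal(m1, m2)

    def test_fired_neighbour_contributes_link_weight(self):
        # one fired pixel adds exactly 0.01 to each 4-neighbour and 1 to itself
        params = ICMParams(f=0.9, g=0.8, h=-1, n_iterations=1)
        st = init_state(np.zeros((5, 5)), params)
        st.Y[2, 2] = 1
        new = step_icm(st, np.zeros((5, 5)), params)
        assert new.F[2, 2] == pytest.approx(1.0)
        for r, c in [(1, 2), (3, 2), (2, 1), (2, 3)]:
            assert new.F[r, c] == pytest.approx(0.01)
        assert new.F[1, 1] == 0.0  # diagonal weight is zero

    def test_extra_fired_neighbour_never_decreases_activation(self, rng):
        s = rng.uniform(0, 1, (7, 7))
        params = ICMParams(f=0.8, g=0.5, h=-1, n_iterations=1)
        base = init_state(s, params)
        base.Y[3, 4] = 1
        more = init_state(s, params)
        more.Y[3, 4] = 1
        more.Y[3, 3] = 1
        f_base = step_icm(base, s, params).F
        f_more = step_icm(more, s, params).F
        assert (f_more >= f_base - 1e-12).all()

    def test_shape_mismatch_rejected(self):
        params = ICMParams(f=0.9, g=0.8, h=-1, n_iterations=1)
        st = init_state(np.zeros((4, 4)), params)
        with pytest.raises(ValueError):
            step_icm(st, np.zeros((5, 5)), params)
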