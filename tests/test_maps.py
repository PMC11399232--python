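"""Normal-form map models: equilibria, eigenvalues, simulation rules."""

import numpy as np
import pytest

from bifurcell.maps import (
    MU0_RANGES,
    SIGMA_RANGE,
    BifurcationClass,
    MapModel,
    dominant_eigenvalue,
    equilibrium,
    sample_model,
    simulate_forced,
    simulate_null,
    step_map,
)

FOLD = BifurcationClass.FOLD
TC = BifurcationClass.TRANSCRITICAL
PF = BifurcationClass.PITCHFORK


def _model(bclass, alpha=None, sigma=0.01, mu0=-0.25, cubic_sign=1):
    n = 7 if bclass == PF else 8
    if alpha is None:
        alpha = np.zeros(n)
    return MapModel(bclass=bclass, alpha=alpha, sigma=sigma, mu0=mu0,
                    cubic_sign=cubic_sign)


class TestStepMap:
    def test_fold_equilibrium_is_fixed_point(self):
        # mu=-0.25: x* = 0.5, deterministic map leaves it unchanged
        m = _model(FOLD)
        assert step_map(m, 0.5, -0.25) == pytest.approx(0.5)

    def test_origin_fixed_for_transcritical_and_pitchfork(self):
        for bclass in (TC, PF):
            m = _model(bclass, mu0=-0.5)
            assert step_map(m, 0.0, -0.5) == pytest.approx(0.0)

    def test_random_alpha_preserves_equilibrium(self):
        # higher-order terms vanish at the tracked equilibrium
        rng = np.random.default_rng(0)
        for bclass in (FOLD, TC, PF):
            n = 7 if bclass == PF else 8
            m = _model(bclass, alpha=rng.standard_normal(n), mu0=-0.3)
            eq = equilibrium(m, -0.3)
            assert step_map(m, eq, -0.3) == pytest.approx(eq, abs=1e-12)

    def test_fold_rejects_positive_mu(self):
        with pytest.raises(ValueError):
            step_map(_model(FOLD), 0.1, 0.5)

    def test_noise_term_scales_with_sigma(self):
        m = _model(TC, sigma=0.01, mu0=-0.5)
        vals = [step_map(m, 0.0, -0.5, np.random.default_rng(s))
                for s in range(200)]
        assert np.std(vals) == pytest.approx(0.01, rel=0.25)


class TestEquilibriumAndEigenvalue:
    @pytest.mark.parametrize("mu,expected", [(-0.25, 0.5), (0.0, 0.0)])
    def test_fold_equilibrium(self, mu, expected):
        assert equilibrium(_model(FOLD), mu) == pytest.approx(expected)

    def test_pitchfork_equilibrium_is_origin(self):
        m = _model(PF, mu0=-0.5)
        for mu in (-1.0, -0.3, 0.0):
            assert equilibrium(m, mu) == 0.0

    @pytest.mark.parametrize("bclass,mu,expected", [
        (FOLD, -0.01, 0.8),
        (FOLD, -0.25, 0.0),
        (TC, -1.0, 0.0),
        (TC, -0.2, 0.8),
    ])
    def test_eigenvalue_examples(self, bclass, mu, expected):
        m = _model(bclass, mu0=mu)
        assert dominant_eigenvalue(m, mu) == pytest.approx(expected)

    def test_eigenvalue_is_one_at_bifurcation(self):
        for bclass in (FOLD, TC, PF):
            assert dominant_eigenvalue(_model(bclass), 0.0) == pytest.approx(1.0)


class TestSampleModel:
    def test_null_rejected(self):
        with pytest.raises(ValueError):
            sample_model(BifurcationClass.NULL, np.random.default_rng(0))

    @pytest.mark.parametrize("bclass", [FOLD, TC, PF])
    def test_draw_bounds_and_eigenvalue_window(self, bclass):
        rng = np.random.default_rng(1)
        lo, hi = MU0_RANGES[bclass]
        for _ in range(200):
            m = sample_model(bclass, rng)
            assert SIGMA_RANGE[0] <= m.sigma <= SIGMA_RANGE[1]
            assert lo <= m.mu0 <= hi
            lam = dominant_eigenvalue(m, m.mu0)
            assert 0.0 <= lam <= 0.8 + 1e-12

    def test_pitchfork_cubic_sign_both_drawn(self):
        rng = np.random.default_rng(2)
        signs = {sample_model(PF, rng).cubic_sign for _ in range(50)}
        assert signs == {-1, 1}


class TestSimulate:
    def test_forced_low_noise_keeps_full_run(self):
        # alpha = 0, sigma at the lower bound: transition essentially never
        m = _model(FOLD, sigma=0.005, mu0=-0.25)
        tr = simulate_forced(m, rng=np.random.default_rng(0))
        assert not tr.transitioned
        assert len(tr.states) == 600
        assert tr.valid and len(tr.kept_states) == 500
        np.testing.assert_allclose(tr.kept_states, tr.states[-500:])

    def test_forced_mu_schedule_linear_inclusive(self):
        m = _model(TC, sigma=0.005, mu0=-0.5)
        tr = simulate_forced(m, rng=np.random.default_rng(1))
        assert tr.mu_schedule[0] == pytest.approx(-0.5)
        diffs = np.diff(tr.mu_schedule)
        np.testing.assert_allclose(diffs, diffs[0])
        # the full (untruncated) schedule ends exactly at the bifurcation
        full = -0.5 * (1.0 - np.arange(600) / 599)
        assert full[-1] == 0.0
        np.testing.assert_allclose(tr.mu_schedule, full[:len(tr.mu_schedule)])

    def test_forced_eigenvalue_monotone_to_one(self):
        m = _model(PF, sigma=0.005, mu0=-0.8, cubic_sign=-1)
        tr = simulate_forced(m, rng=np.random.default_rng(2))
        lam = dominant_eigenvalue(m, tr.mu_schedule)
        assert np.all(np.diff(lam) >= -1e-12)
        full = m.mu0 * (1.0 - np.arange(600) / 599)
        assert dominant_eigenvalue(m, full)[-1] == pytest.approx(1.0)

    def test_null_schedule_constant_and_eigenvalue_frozen(self):
        m = _model(TC, sigma=0.005, mu0=-0.5)
        tr = simulate_null(m, rng=np.random.default_rng(3))
        assert np.all(tr.mu_schedule == -0.5)
        lam = dominant_eigenvalue(m, tr.mu_schedule)
        np.testing.assert_allclose(lam, lam[0])
        assert tr.valid and len(tr.kept_states) == 500

    def test_short_run_rejected(self):
        with pytest.raises(ValueError):
            simulate_forced(_model(FOLD), n_steps=400)

    def test_truncation_leaves_invalid_trace(self):
        # huge destabilizing cubic term forces an early transition
        alpha = np.zeros(8)
        alpha[0] = 50.0
        m = _model(TC, alpha=alpha, sigma=0.015, mu0=-0.2)
        tr = simulate_forced(m, rng=np.random.default_rng(4))
        if tr.transitioned and len(tr.states) < 500:
            assert not tr.valid
            assert tr.kept_states is None
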