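"""Bivariate designs, regression-line rotation, correlation gating."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from survddg import (
    CohortSpec,
    InformativeGene,
    fit_cox_binary,
    fit_ddg1d,
    fit_ddg2d,
    fit_regression,
    pair_correlation,
    rotate_coordinates,
    simulate_cohort,
)
from survddg.ddg2d import DESIGNS, DDgBivariate, RegressionLine


class TestPairCorrelation:
    def test_perfect_monotone(self):
        x = np.arange(20.0)
        tau, _ = pair_correlation(x, x)
        assert tau == pytest.approx(1.0)
        rho, _ = pair_correlation(x, -x, method="spearman")
        assert rho == pytest.approx(-1.0)

    def test_kendall_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(25)
        y = rng.standard_normal(25)
        tau, _ = pair_correlation(x, y)
        conc = disc = 0
        for i, j in itertools.combinations(range(25), 2):
            s = np.sign((x[i] - x[j]) * (y[i] - y[j]))
            conc += s > 0
            disc += s < 0
        brute = (conc - disc) / math.comb(25, 2)
        assert tau == pytest.approx(brute, abs=1e-10)

    def test_null_pairs_rarely_significant(self):
        sig = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            _, p = pair_correlation(rng.standard_normal(200),
                                    rng.standard_normal(200))
            sig += p < 0.05
        assert sig <= 2


class TestRegressionAndRotation:
    def test_exact_line_recovered(self):
        x = np.arange(30.0)
        line = fit_regression(x, 2.0 * x + 1.0)
        assert line.alpha == pytest.approx(1.0, abs=1e-10)
        assert line.beta == pytest.approx(2.0, abs=1e-10)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_regression(np.ones(10), np.arange(10.0))

    def test_zero_slope_is_vertical_shift(self):
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([3.0, 4.0, 5.0])
        rot = rotate_coordinates(x, y, RegressionLine(3.0, 0.0, 0.0))
        np.testing.assert_allclose(rot.xr, x)
        np.testing.assert_allclose(rot.yr, y - 3.0)

    def test_points_on_line_map_to_zero(self):
        line = RegressionLine(1.5, 0.8, 0.0)
        x = np.linspace(-5, 5, 11)
        rot = rotate_coordinates(x, line.alpha + line.beta * x, line)
        np.testing.assert_allclose(rot.yr, 0.0, atol=1e-12)

    @settings(derandomize=True, max_examples=25)
    @given(st.floats(-5, 5), st.floats(-10, 10), st.integers(0, 1000))
    def test_rotation_is_an_isometry(self, beta, alpha, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        rot = rotate_coordinates(x, y, RegressionLine(alpha, beta, 0.0))
        before = np.hypot(x[:, None] - x, y[:, None] - y)
        after = np.hypot(rot.xr[:, None] - rot.xr, rot.yr[:, None] - rot.yr)
        np.testing.assert_allclose(after, before, atol=1e-9)
        assert rot.gamma == pytest.approx(np.arctan(beta))


class TestDesignSpace:
    def test_seven_designs_cover_all_two_colourings(self):
        # every 2-colouring of 4 quadrants with both colours used, up to swap
        seen = set()
        for design in DESIGNS:
            key = frozenset(design)
            comp = frozenset(set(range(4)) - set(design))
            assert key not in seen and comp not in seen
            seen.add(key)
        assert len(seen) == (2**4 - 2) // 2

    def test_best_design_matches_brute_force(self):
        spec = CohortSpec(250, 2, (InformativeGene(0, 0.5, 1.0),
                                   InformativeGene(1, 0.5, 0.7)), seed=21)
        X, clin, _ = simulate_cohort(spec)
        x, y = X.iloc[0].to_numpy(), X.iloc[1].to_numpy()
        t, e = clin["time"].to_numpy(), clin["event"].to_numpy()
        res = fit_ddg2d(x, y, (t, e), rotate_if_correlated=False)
        # independent re-derivation: 1D cutoffs, then all designs by hand
        cx = fit_ddg1d(x, t, e).cutoff
        cy = fit_ddg1d(y, t, e).cutoff
        quad = (x > cx).astype(int) + 2 * (y > cy).astype(int)
        best_p = np.inf
        for design in DESIGNS:
            in_a = np.isin(quad, design)
            if min(in_a.sum(), (~in_a).sum()) < 25:
                continue
            p = fit_cox_binary(t, e, in_a.astype(int) + 1).wald_p
            best_p = min(best_p, p)
        assert res.p_value == pytest.approx(best_p, rel=1e-9)


class TestFitDDg2D:
    def test_reduces_to_1d_when_second_gene_constant(self, informative_cohort):
        X, clin, _ = informative_cohort
        x = X.iloc[0].to_numpy()
        t, e = clin["time"].to_numpy(), clin["event"].to_numpy()
        r1 = fit_ddg1d(x, t, e)
        r2 = fit_ddg2d(x, np.zeros_like(x), (t, e), rotate_if_correlated=False)
        assert r2.cutoff_x == pytest.approx(r1.cutoff)
        assert r2.p_value == pytest.approx(r1.p_value, rel=1e-9)
        np.testing.assert_array_equal(r2.groups, r1.groups)

    def test_identical_genes_collapse_under_rotation(self, informative_cohort):
        X, clin, _ = informative_cohort
        x = X.iloc[0].to_numpy()
        t, e = clin["time"].to_numpy(), clin["event"].to_numpy()
        res = fit_ddg2d(x, x, (t, e), rotate_if_correlated=True)
        assert res is not None and res.rotated
        assert np.isnan(res.cutoff_y)  # off-line coordinate is degenerate
        r1 = fit_ddg1d(x, t, e)
        assert res.p_value == pytest.approx(r1.p_value, rel=1e-6)

    def test_2d_refines_1d_on_informative_plus_noise(self):
        wins = 0
        for rep in range(15):
            spec = CohortSpec(300, 2, (InformativeGene(0, 0.5, 1.0),),
                              seed=500 + rep)
            X, clin, _ = simulate_cohort(spec)
            t, e = clin["time"].to_numpy(), clin["event"].to_numpy()
            r1 = fit_ddg1d(X.iloc[0].to_numpy(), t, e)
            r2 = fit_ddg2d(X.iloc[0].to_numpy(), X.iloc[1].to_numpy(), (t, e),
                           rotate_if_correlated=False)
            wins += r2.p_value <= r1.p_value * (1 + 1e-9)
        assert wins == 15  # the design space contains the pure 1D split

    def test_rotation_gate_uses_correlation_significance(self):
        spec = CohortSpec(400, 2, (InformativeGene(0, 0.5, 1.0),),
                          correlated_pairs=((0, 1, 0.8),), seed=33)
        X, clin, _ = simulate_cohort(spec)
        t, e = clin["time"].to_numpy(), clin["event"].to_numpy()
        res = fit_ddg2d(X.iloc[0].to_numpy(), X.iloc[1].to_numpy(), (t, e))
        assert res.rotated and res.line is not None
        off = fit_ddg2d(X.iloc[0].to_numpy(), X.iloc[1].to_numpy(), (t, e),
                        rotate_if_correlated=False)
        assert not off.rotated

    def test_estimator_predicts_fitted_labels(self):
        spec = CohortSpec(300, 2, (InformativeGene(0, 0.5, 1.0),
                                   InformativeGene(1, 0.5, 0.7)), seed=44)
        X, clin, _ = simulate_cohort(spec)
        est = DDgBivariate(rotate_if_correlated=False)
        est.fit(X.T, clin[["time", "event"]])
        np.testing.assert_array_equal(est.predict(X.T), est.result_.groups)
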