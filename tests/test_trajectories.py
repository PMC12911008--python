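import numpy as np
import pandas as pd
import pytest

import devconn as dc
from devconn.trajectories import natural_spline_basis

import oracles


def slope_table(rows):
    """rows: (pid, months, motor, ef)"""
    return pd.DataFrame(rows, columns=["participant_id", "months", "total_motor_pct", "ef_composite"])


class TestGrowthSlopes:
    def test_collinear_three_wave_slope(self):
        t = slope_table([(0, 0, 40, 90), (0, 6, 45, 95), (0, 12, 50, 100)])
        s = dc.growth_slopes(t)
        assert s.loc[0, "motor_slope"] == pytest.approx(10 / 12, abs=1e-9)

    def test_constant_scores_zero_slope(self):
        t = slope_table([(0, 0, 50, 90), (0, 6, 50, 90), (0, 12, 50, 90)])
        s = dc.growth_slopes(t)
        assert s.loc[0, "motor_slope"] == pytest.approx(0.0, abs=1e-12)

    def test_two_point_slope(self):
        t = slope_table([(0, 0, 38, 90), (0, 12, 52, 95)])
        s = dc.growth_slopes(t)
        assert s.loc[0, "motor_slope"] == pytest.approx(14 / 12)

    def test_single_wave_omitted_with_reason(self):
        t = slope_table([(0, 0, 38, 90), (1, 0, 40, 91), (1, 12, 45, 99)])
        s = dc.growth_slopes(t)
        assert np.isnan(s.loc[0, "motor_slope"])
        omitted = s.attrs["omitted"]
        assert (omitted["participant_id"] == 0).any()

    def test_missing_waves_use_observed_only(self):
        t = slope_table([(0, 0, 40, 90), (0, 6, np.nan, 95), (0, 12, 52, np.nan)])
        s = dc.growth_slopes(t)
        assert s.loc[0, "motor_slope"] == pytest.approx(1.0)
        assert s.loc[0, "n_waves_motor"] == 2


class TestClassifyGrowth:
    def _records(self, rho, n=40_000, seed=0):
        rng = np.random.default_rng(seed)
        z1 = rng.standard_normal(n)
        z2 = rho * z1 + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(n)
        return pd.DataFrame({"motor_slope": z1, "ef_slope": z2},
                            index=pd.RangeIndex(n, name="participant_id"))

    @pytest.mark.parametrize("rho", [0.0, 0.5, 1.0])
    def test_accelerated_fraction_matches_orthant_oracle(self, rho):
        rec = dc.classify_growth(self._records(rho))
        frac = (rec["growth_class"] == "accelerated").mean()
        expected = oracles.orthant_upper(rho)
        tol = 4 * np.sqrt(expected * (1 - expected) / len(rec)) + 0.004
        assert frac == pytest.approx(expected, abs=tol)

    def test_conjunction_rule(self):
        # high motor but average EF -> typical
        rec = self._records(0.0, n=500, seed=1)
        rec.loc[0, "motor_slope"] = rec["motor_slope"].mean() + 5 * rec["motor_slope"].std()
        rec.loc[0, "ef_slope"] = rec["ef_slope"].mean()
        out = dc.classify_growth(rec)
        assert out.loc[0, "growth_class"] == "typical"

    def test_perfect_correlation_fraction(self):
        rec = dc.classify_growth(self._records(1.0, n=60_000, seed=2))
        assert (rec["growth_class"] == "accelerated").mean() == pytest.approx(0.1587, abs=0.006)

    def test_degenerate_zero_sd_all_typical(self):
        rec = pd.DataFrame({"motor_slope": [1.0, 1.0, 1.0], "ef_slope": [2.0, 2.0, 2.0]})
        with pytest.warns(UserWarning, match="degenerate"):
            out = dc.classify_growth(rec)
        assert (out["growth_class"] == "typical").all()

    def test_needs_three_records(self):
        with pytest.raises(ValueError):
            dc.classify_growth(pd.DataFrame({"motor_slope": [1.0], "ef_slope": [1.0]}))


class TestPartialCorrelation:
    def test_orthogonal_covariates_equal_plain_pearson(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(200), rng.standard_normal(200)
        # covariate orthogonal to both by construction (residualized)
        c = rng.standard_normal(200)
        d = np.column_stack([np.ones(200), x, y])
        c = c - d @ np.linalg.lstsq(d, c, rcond=None)[0]
        res = dc.partial_correlation(x, y, c)
        assert res.r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)

    def test_variable_equal_to_covariate_errors(self):
        rng = np.random.default_rng(1)
        c = rng.standard_normal(50)
        x = rng.standard_normal(50)
        with pytest.raises(ValueError, match="zero residual"):
            dc.partial_correlation(x, c.copy(), c)

    def test_confound_removal_construction(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal(10_000)
        x = z + rng.standard_normal(10_000)
        y = z + rng.standard_normal(10_000)
        raw = np.corrcoef(x, y)[0, 1]
        res = dc.partial_correlation(x, y, z)
        assert raw > 0.4
        assert abs(res.r) < 0.05
        assert res.r == pytest.approx(oracles.brute_partial_correlation(x, y, z), abs=1e-10)

    def test_matches_residualization_oracle_with_categoricals(self):
        rng = np.random.default_rng(3)
        n = 300
        cov = pd.DataFrame({
            "age_months": rng.uniform(36, 83, n),
            "ses": rng.choice(["low", "middle", "high"], n),
            "mean_fd": rng.uniform(0.1, 0.4, n),
        })
        x = rng.standard_normal(n) + 0.02 * cov["age_months"]
        y = rng.standard_normal(n) + 0.01 * cov["age_months"]
        expanded = np.column_stack([
            cov["age_months"], pd.get_dummies(cov["ses"], drop_first=True).to_numpy(float),
            cov["mean_fd"],
        ])
        res = dc.partial_correlation(x, y, cov)
        assert res.r == pytest.approx(oracles.brute_partial_correlation(x, y, expanded), abs=1e-10)

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        n = 150
        df = pd.DataFrame({"x": rng.standard_normal(n), "y": rng.standard_normal(n),
                           "c1": rng.standard_normal(n), "c2": rng.standard_normal(n)})
        df["x"] += 0.5 * df["c1"]
        df["y"] += 0.5 * df["c1"]
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        res = dc.partial_correlation(df["x"], df["y"], df[["c1", "c2"]])
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_sample_size_floor(self):
        with pytest.raises(ValueError):
            dc.partial_correlation([1, 2, 3], [1, 2, 3], np.ones((3, 1)))


class TestSplineBasis:
    def test_natural_condition_zero_second_derivative_at_boundaries(self):
        knots = (48.0, 60.0)
        bks = (36.0, 83.0)
        h = 1e-3

        def second_deriv(x0):
            f = lambda v: natural_spline_basis(np.array([v]), knots, bks)[0]
            return (f(x0 + h) - 2 * f(x0) + f(x0 - h)) / h**2

        for bk in bks:
            np.testing.assert_allclose(second_deriv(bk), 0.0, atol=1e-4)
        # but curvature exists between the knots
        assert np.abs(second_deriv(54.0)).max() > 1e-3

    def test_three_columns_for_two_interior_knots(self):
        b = natural_spline_basis(np.linspace(36, 83, 50))
        assert b.shape == (50, 3)

    def test_knots_inside_boundaries_required(self):
        with pytest.raises(ValueError):
            natural_spline_basis(np.linspace(50, 55, 10), interior_knots=(48.0, 60.0))


def simulate_lmm(n=120, seed=0, quad_amp=0.0, slope=0.02):
    """Three-wave connectivity records with random intercepts; optional
    inverted-U age effect of amplitude quad_amp (peak at 59 months)."""
    rng = np.random.default_rng(seed)
    rows = []
    for pid in range(n):
        base_age = rng.uniform(36, 72)
        u = 0.05 * rng.standard_normal()
        for months in (0, 6, 12):
            age = base_age + months
            mu = 0.2 + slope * (age - 36) / 12
            if quad_amp:
                mu = 0.2 + quad_amp * (1 - ((age - 59) / 24) ** 2)
            rows.append({
                "participant_id": pid, "age_months": age,
                "sex": "F" if rng.random() < 0.5 else "M",
                "ses": rng.choice(["low", "middle", "high"]),
                "mean_fd": rng.uniform(0.15, 0.35),
                "scan_state": "sleep" if age < 60 else "awake",
                "connectivity": mu + u + 0.03 * rng.standard_normal(),
            })
    return pd.DataFrame(rows)


class TestSplineLmm:
    def test_linear_truth_prefers_linear(self):
        df = simulate_lmm(n=100, seed=1)
        fit_s, fit_l, delta, preferred = dc.fit_spline_lmm(df, "connectivity")
        assert preferred == "linear"
        assert delta <= 10

    def test_strong_inverted_u_prefers_spline(self):
        df = simulate_lmm(n=100, seed=2, quad_amp=0.15)
        _, _, delta, preferred = dc.fit_spline_lmm(df, "connectivity")
        assert preferred == "spline"
        assert delta > 10

    def test_parameter_recovery_linear_fixed_effect(self):
        df = simulate_lmm(n=500, seed=3, slope=0.02)
        _, fit_l, _, _ = dc.fit_spline_lmm(df, "connectivity")
        # slope per year of age
        assert fit_l.fe_params["age_years"] == pytest.approx(0.02, abs=0.005)
        assert fit_l.random_intercept_var == pytest.approx(0.05**2, rel=0.5)

    def test_knots_must_be_inside_range(self):
        df = simulate_lmm(n=30, seed=4)
        df["age_months"] = np.linspace(61, 80, len(df))
        with pytest.raises(ValueError, match="knots"):
            dc.fit_spline_lmm(df, "connectivity")

    def test_aic_accounting(self):
        df = simulate_lmm(n=60, seed=5)
        fit_s, fit_l, delta, _ = dc.fit_spline_lmm(df, "connectivity")
        assert fit_s.aic == pytest.approx(-2 * fit_s.llf + 2 * fit_s.n_params)
        assert fit_s.n_params == fit_l.n_params + 2  # two extra spline columns


class TestNetworkChangeContrasts:
    def test_identical_waves_zero_delta(self, small_cohort):
        mats = {}
        for (pid, w), m in small_cohort.matrices.items():
            if w == 1:
                mats[(pid, 1)] = m
                mats[(pid, 3)] = m
        out = dc.network_change_contrasts(mats, small_cohort.partition)
        assert np.allclose(out["mean_delta"], 0.0)
        assert np.allclose(out["t"], 0.0)

    def test_within_block_region_permutation_invariance(self, small_cohort):
        part = small_cohort.partition
        perm = np.arange(part.size)
        # swap two regions of the first network
        first = np.flatnonzero(part == 0)[:2]
        perm[first[0]], perm[first[1]] = perm[first[1]], perm[first[0]]
        mats_p = {k: dc.ConnectivityMatrix(m.values[np.ix_(perm, perm)])
                  for k, m in small_cohort.matrices.items()}
        out1 = dc.network_change_contrasts(small_cohort.matrices, part)
        out2 = dc.network_change_contrasts(mats_p, part)
        np.testing.assert_allclose(out1["mean_delta"], out2["mean_delta"], atol=1e-12)

    def test_no_complete_pairs_rejected(self, small_cohort):
        only_w1 = {k: v for k, v in small_cohort.matrices.items() if k[1] == 1}
        with pytest.raises(ValueError, match="both waves"):
            dc.network_change_contrasts(only_w1, small_cohort.partition)


class TestBenjaminiHochberg:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 25)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(dc.benjamini_hochberg(p), ref, atol=1e-12)
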