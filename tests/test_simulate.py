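import numpy as np
import pandas as pd
import pytest

import devconn as dc
from devconn.simulate import (
    BEHAVIOR_COLUMNS, COGNITIVE_COLUMNS, MOTOR_COLUMNS, ParticipantState, generate_cohort,
)


def tiny_spec(**kw):
    base = dict(n_baseline=30, n_regions=14, seed=9)
    base.update(kw)
    return dc.CohortSpec(**base)


class TestSpecValidation:
    def test_retention_must_decrease(self):
        with pytest.raises(ValueError, match="decreasing"):
            dc.CohortSpec(retention=(0.7, 0.8))

    def test_proportions_in_range(self):
        with pytest.raises(ValueError):
            dc.CohortSpec(retention=(1.2, 0.5))
        with pytest.raises(ValueError):
            dc.CohortSpec(missing_rates=(0.1, 1.4))
        with pytest.raises(ValueError):
            dc.CohortSpec(effect_size_outcome=1.5)

    def test_networks_nonempty(self):
        with pytest.raises(ValueError):
            dc.CohortSpec(n_regions=5, n_networks=7)


class TestParticipantState:
    def test_scan_state_deterministic_cutoff(self):
        young = ParticipantState(0, 59.9, "F", "middle", 0.3, 0.0)
        old = ParticipantState(1, 60.0, "M", "low", 0.3, 0.0)
        assert young.scan_state == "sleep" and old.scan_state == "awake"


class TestGenerateCohort:
    def test_wave1_complete_with_configured_n(self):
        spec = tiny_spec(n_baseline=40)
        table, mats = generate_cohort(spec)
        w1 = table[table["wave"] == 1]
        assert len(w1) == 40
        assert not w1[list(BEHAVIOR_COLUMNS)].isna().any().any()
        assert len(mats) == 40 * 3

    def test_feature_inventory(self):
        assert len(MOTOR_COLUMNS) == 16
        assert len(COGNITIVE_COLUMNS) == 12

    def test_score_ranges(self):
        table, _ = generate_cohort(tiny_spec(n_baseline=60))
        for c in ("fine_motor_pct", "gross_motor_pct", "balance_pct", "total_motor_pct"):
            assert table[c].between(0, 100).all()
        assert (table["dccs_switch_cost"] > 0).all()
        assert table["gonogo_accuracy"].between(0, 100).all()

    def test_determinism_byte_identical(self):
        spec = tiny_spec()
        t1, m1 = generate_cohort(spec)
        t2, m2 = generate_cohort(spec)
        pd.testing.assert_frame_equal(t1, t2)
        for k in m1:
            np.testing.assert_array_equal(m1[k].values, m2[k].values)

    def test_zero_effect_size_kills_baseline_outcome_coupling(self):
        spec = dc.CohortSpec(n_baseline=400, n_regions=14, seed=3,
                             effect_size_connectivity=0.0, effect_size_outcome=0.0)
        table, mats = generate_cohort(spec)
        w1 = table[table["wave"] == 1].set_index("participant_id")
        w3 = table[table["wave"] == 3].set_index("participant_id")
        change = (w3["total_motor_pct"] - w1["total_motor_pct"]).to_numpy()
        # any baseline connectivity feature vs outcome change: |r| < 3/sqrt(n)
        rng = np.random.default_rng(0)
        vec = np.array([dc.vectorize_upper(mats[(i, 1)]) for i in w1.index])
        for j in rng.choice(vec.shape[1], size=12, replace=False):
            r = np.corrcoef(vec[:, j], change)[0, 1]
            assert abs(r) < 3 / np.sqrt(len(change))

    def test_calibration_age3_fine_motor_mean(self):
        # Monte-Carlo check against the generator's own configured norms
        spec = dc.CohortSpec(n_baseline=2000, n_regions=14, seed=11,
                             effect_size_connectivity=0.8, effect_size_outcome=0.8)
        table, _ = generate_cohort(spec, include_connectivity=False)
        w1 = table[table["wave"] == 1]
        sub = w1[w1["age_group"] == 3]["fine_motor_pct"]
        se = 23.7 / np.sqrt(len(sub))
        # small positive bias (< 0.6 points) from percentile clipping at 0
        assert sub.mean() == pytest.approx(38.2, abs=2 * se + 0.6)
        assert sub.std() == pytest.approx(23.7, rel=0.12)

    def test_signal_dial_monotone_in_effect_size(self):
        # point-biserial correlation between eta and the binary outcome
        # increases with effect size
        corrs = []
        for es in (0.0, 0.5, 1.0):
            spec = dc.CohortSpec(n_baseline=500, n_regions=14, seed=21,
                                 effect_size_connectivity=es, effect_size_outcome=es)
            table, _ = generate_cohort(spec, include_connectivity=False)
            w1 = table[table["wave"] == 1].set_index("participant_id")
            w3 = table[table["wave"] == 3].set_index("participant_id")
            change = w3["total_motor_pct"] - w1["total_motor_pct"]
            lab = dc.binarize_outcomes(change)
            eta = w1.loc[lab.index, "latent_factor"]
            corrs.append(np.corrcoef(lab["label"], eta)[0, 1])
        assert corrs[0] < corrs[1] < corrs[2]
        assert abs(corrs[0]) < 0.15


class TestGenerateConnectivity:
    def test_matrix_contract(self):
        spec = tiny_spec()
        st = ParticipantState(0, 48.0, "F", "middle", 0.3, 0.5)
        m = dc.generate_connectivity(st, spec)
        assert np.all(np.diag(m.values) == 1.0)
        np.testing.assert_array_equal(m.values, m.values.T)
        off = m.values[np.triu_indices(spec.n_regions, 1)]
        assert np.all(np.abs(off) <= 1.0)

    def test_sommot_subcort_block_mean_young(self):
        # young (3-4y) sensorimotor-subcortical block mean is the configured 0.12
        spec = dc.CohortSpec(n_baseline=1, n_regions=35, seed=0,
                             effect_size_connectivity=0.0)
        part = dc.network_partition(35, 7)
        som, sub = np.flatnonzero(part == 0), np.flatnonzero(part == 6)
        means = []
        for i in range(400):
            st = ParticipantState(i, 45.0, "F", "middle", 0.3, 0.0)
            rng = np.random.default_rng(1000 + i)
            m = dc.generate_connectivity(st, spec, rng=rng)
            means.append(m.values[np.ix_(som, sub)].mean())
        se = np.std(means) / np.sqrt(len(means))
        assert np.mean(means) == pytest.approx(0.12, abs=4 * se)

    def test_awake_visual_boost(self):
        spec = dc.CohortSpec(n_baseline=1, n_regions=35, seed=0, effect_size_connectivity=0.0)
        part = dc.network_partition(35, 7)
        vis = np.flatnonzero(part == 1)
        iu, ju = np.triu_indices(vis.size, 1)

        def mean_vis(age):
            vals = []
            for i in range(300):
                st = ParticipantState(i, age, "F", "middle", 0.3, 0.0)
                m = dc.generate_connectivity(st, spec, rng=np.random.default_rng(i))
                sub = m.values[np.ix_(vis, vis)]
                vals.append(sub[iu, ju].mean())
            return np.mean(vals)

        assert mean_vis(62.0) - mean_vis(58.0) == pytest.approx(spec.visual_awake_boost, abs=0.02)


class TestTimeseries:
    def test_fc_converges_to_target(self):
        spec = dc.CohortSpec(n_baseline=1, n_regions=14, seed=4)
        st = ParticipantState(0, 50.0, "M", "high", 0.2, 0.3)
        target = dc.generate_connectivity(st, spec)
        ts = dc.generate_timeseries(st, n_timepoints=50_000, spec=spec, target=target)
        sample = dc.fc_matrix(ts)
        assert np.max(np.abs(sample.values - target.values)) < 0.05

    def test_identity_target_uncorrelated(self):
        spec = dc.CohortSpec(n_baseline=1, n_regions=10, seed=4)
        st = ParticipantState(0, 50.0, "M", "high", 0.2, 0.0)
        tgt = dc.ConnectivityMatrix(np.eye(10))
        ts = dc.generate_timeseries(st, n_timepoints=20_000, spec=spec, target=tgt)
        sample = dc.fc_matrix(ts)
        assert np.max(np.abs(sample.values[np.triu_indices(10, 1)])) < 0.05

    def test_seeded_determinism(self):
        spec = dc.CohortSpec(n_baseline=1, n_regions=10, seed=4)
        st = ParticipantState(0, 50.0, "M", "high", 0.2, 0.0)
        a = dc.generate_timeseries(st, 100, spec)
        b = dc.generate_timeseries(st, 100, spec)
        np.testing.assert_array_equal(a, b)

    def test_non_pd_target_repaired_with_warning(self):
        spec = dc.CohortSpec(n_baseline=1, n_regions=3, n_networks=3, seed=4)
        st = ParticipantState(0, 50.0, "M", "high", 0.2, 0.0)
        bad = np.array([[1, 0.9, -0.9], [0.9, 1, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.warns(UserWarning, match="nearest-PD"):
            ts = dc.generate_timeseries(st, 500, spec, target=dc.ConnectivityMatrix(bad))
        assert np.all(np.isfinite(ts))


class TestAttrition:
    def test_printed_retention_counts(self):
        spec = dc.CohortSpec(n_baseline=256, n_regions=14, seed=5)
        table, _ = generate_cohort(spec, include_connectivity=False)
        out = dc.apply_attrition(table, spec)
        counts = out["wave"].value_counts().to_dict()
        assert counts == {1: 256, 2: 227, 3: 202}

    def test_full_retention_removes_nothing(self):
        spec = tiny_spec(retention=(1.0, 0.999))
        table, _ = generate_cohort(spec, include_connectivity=False)
        out = dc.apply_attrition(table, spec)
        assert len(out) == len(table)

    def test_half_quarter_rounding(self):
        spec = dc.CohortSpec(n_baseline=100, n_regions=14, seed=6, retention=(0.5, 0.25))
        table, _ = generate_cohort(spec, include_connectivity=False)
        out = dc.apply_attrition(table, spec)
        counts = out["wave"].value_counts().to_dict()
        assert counts == {1: 100, 2: 50, 3: 25}

    def test_monotone_dropout(self):
        spec = tiny_spec(n_baseline=60)
        table, _ = generate_cohort(spec, include_connectivity=False)
        out = dc.apply_attrition(table, spec)
        w2 = set(out.loc[out["wave"] == 2, "participant_id"])
        w3 = set(out.loc[out["wave"] == 3, "participant_id"])
        assert w3 <= w2


class TestMissingness:
    def test_default_wave_fractions_match_configured(self):
        spec = dc.CohortSpec(n_baseline=256, n_regions=14, seed=7)
        table, _ = generate_cohort(spec, include_connectivity=False)
        out = dc.inject_missingness(dc.apply_attrition(table, spec), spec)
        cols = list(BEHAVIOR_COLUMNS)
        for wave, rate in ((2, 0.113), (3, 0.211)):
            present = out[out["wave"] == wave]
            n_missing_cells = (256 - len(present)) * len(cols) + present[cols].isna().sum().sum()
            frac = n_missing_cells / (256 * len(cols))
            assert abs(frac - rate) < 0.01

    def test_zero_rates_with_full_retention(self):
        spec = tiny_spec(retention=(1.0, 0.999), missing_rates=(0.0, 0.0), n_baseline=50)
        table, _ = generate_cohort(spec, include_connectivity=False)
        out = dc.inject_missingness(dc.apply_attrition(table, spec), spec)
        assert not out[list(BEHAVIOR_COLUMNS)].isna().any().any()

    def test_rate_below_dropout_floor_rejected(self):
        spec = dc.CohortSpec(n_baseline=100, n_regions=14, seed=8,
                             retention=(0.5, 0.4), missing_rates=(0.1, 0.6))
        table, _ = generate_cohort(spec, include_connectivity=False)
        with pytest.raises(ValueError, match="floor"):
            dc.inject_missingness(dc.apply_attrition(table, spec), spec)

    def test_fd_driven_mechanism_sign(self):
        # masked-cell rate must be higher in the high-FD half (MAR mechanism)
        spec = dc.CohortSpec(n_baseline=300, n_regions=14, seed=10,
                             retention=(0.95, 0.90), missing_rates=(0.20, 0.30))
        table, _ = generate_cohort(spec, include_connectivity=False)
        out = dc.inject_missingness(dc.apply_attrition(table, spec), spec)
        cols = list(BEHAVIOR_COLUMNS)
        w2 = out[out["wave"] == 2]
        med = w2["mean_fd"].median()
        rate_hi = w2[w2["mean_fd"] > med][cols].isna().mean().mean()
        rate_lo = w2[w2["mean_fd"] <= med][cols].isna().mean().mean()
        assert rate_hi > rate_lo

    def test_mar_conditional_independence(self, ):
        # given the auxiliaries, masked cells do not differ from observed in
        # their (latent) true values: compare masked vs observed truth after
        # matching on FD tertile
        spec = dc.CohortSpec(n_baseline=400, n_regions=14, seed=12,
                             retention=(0.95, 0.90), missing_rates=(0.25, 0.30))
        table, _ = generate_cohort(spec, include_connectivity=False)
        retained = dc.apply_attrition(table, spec)
        observed = dc.inject_missingness(retained, spec)
        w2_true = retained[retained["wave"] == 2].set_index("participant_id")
        w2_obs = observed[observed["wave"] == 2].set_index("participant_id")
        col = "fine_motor_pct"
        masked = w2_obs[col].isna()
        tert = pd.qcut(w2_true["mean_fd"], 3, labels=False)
        diffs = []
        for t in range(3):
            sel = tert == t
            if masked[sel].sum() >= 5 and (~masked[sel]).sum() >= 5:
                z = (w2_true.loc[sel, col] - w2_true.loc[sel, col].mean()) / w2_true.loc[sel, col].std()
                diffs.append(z[masked[sel]].mean() - z[~masked[sel]].mean())
        assert np.all(np.abs(diffs) < 0.5)


class TestSampleFlow:
    def test_default_intake_books_27_exclusions(self):
        flow = dc.sample_flow(seed=0)
        assert flow.n_scanned == 283
        assert flow.n_excluded == 27
        assert flow.n_excluded_motion == 18
        assert flow.n_final == 256

    def test_exclusions_cannot_exceed_intake(self):
        with pytest.raises(ValueError):
            dc.sample_flow(n_scanned=10, n_motion_fail=8, n_incomplete=2, n_technical=1)
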