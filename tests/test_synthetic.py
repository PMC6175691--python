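"""Synthetic cohort generator: determinism, construction recovery, implanted
effects, behavioral structure, retest pairs, and drug pairs."""

import numpy as np
import pytest
from scipy import stats as sps

from connlearn.behavior import skill_learning
from connlearn.connectome import correlation_matrix
from connlearn.nbs import edge_statistics
from connlearn.stats import icc
from connlearn.synthetic import (
    CohortConfig,
    generate_behavior,
    generate_cohort,
    generate_drug_pair,
    generate_retest_pair,
    nearest_correlation,
)
from conftest import path_edges


def implanted_mean(ts_stack, edges):
    """Mean implanted-edge correlation per subject, straight from the series."""
    out = []
    for ts in ts_stack:
        cm = correlation_matrix(ts)
        out.append(np.mean([cm.values[i, j] for i, j in edges]))
    return np.asarray(out)


class TestCohortConfig:
    def test_rejects_lower_triangle_edges(self):
        with pytest.raises(ValueError):
            CohortConfig(n_nodes=10, implanted_edges=((3, 1),))

    def test_rejects_no_clipping_headroom(self):
        with pytest.raises(ValueError):
            CohortConfig(base_correlation=0.8, effect_beta=0.1)

    def test_rejects_tiny_cohort(self):
        with pytest.raises(ValueError):
            CohortConfig(n_subjects=1)


class TestGenerateCohort:
    def test_determinism(self):
        cfg = CohortConfig(n_subjects=4, n_nodes=12, n_frames=50, implanted_edges=((0, 1),), seed=3)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        np.testing.assert_array_equal(a.timeseries, b.timeseries)
        np.testing.assert_array_equal(a.motion, b.motion)
        assert a.records.equals(b.records)

    def test_latent_score_standardized(self):
        cfg = CohortConfig(n_subjects=50, n_nodes=10, n_frames=40, seed=4)
        cohort = generate_cohort(cfg)
        assert cohort.latent_skill.mean() == pytest.approx(0.0, abs=1e-12)
        assert cohort.latent_skill.std() == pytest.approx(1.0, abs=1e-12)

    def test_null_effect_uncorrelated_with_skill(self):
        cfg = CohortConfig(
            n_subjects=200, n_nodes=24, n_frames=200,
            implanted_edges=path_edges(10), effect_beta=0.0, seed=5,
        )
        cohort = generate_cohort(cfg)
        means = implanted_mean(cohort.timeseries, cohort.implanted_edges)
        assert abs(np.corrcoef(means, cohort.latent_skill)[0, 1]) < 0.15

    def test_implanted_effect_tracks_skill(self):
        # analytic targets are the oracle: the sampled estimates track them
        cfg = CohortConfig(
            n_subjects=200, n_nodes=24, n_frames=500,
            implanted_edges=path_edges(10), effect_beta=0.1,
            edge_noise_sd=0.02, seed=6,
        )
        cohort = generate_cohort(cfg)
        target_means = np.array(
            [np.mean([cohort.target_matrices[s][i, j] for i, j in cohort.implanted_edges])
             for s in range(200)]
        )
        sampled_means = implanted_mean(cohort.timeseries, cohort.implanted_edges)
        assert np.corrcoef(target_means, cohort.latent_skill)[0, 1] > 0.9
        assert np.corrcoef(sampled_means, cohort.latent_skill)[0, 1] > 0.5
        np.testing.assert_allclose(sampled_means, target_means, atol=0.12)

    def test_construction_recovery_at_long_runs(self):
        cfg = CohortConfig(
            n_subjects=2, n_nodes=20, n_frames=5000,
            implanted_edges=path_edges(5), effect_beta=0.1, seed=7,
        )
        cohort = generate_cohort(cfg)
        for s in range(2):
            sampled = correlation_matrix(cohort.timeseries[s]).values
            target = cohort.target_matrices[s].copy()
            np.fill_diagonal(target, 0.0)
            assert np.max(np.abs(sampled - target)) < 0.05

    def test_motion_spikes_exceed_scrub_threshold(self):
        from connlearn.preprocess import framewise_displacement

        cfg = CohortConfig(n_subjects=6, n_nodes=8, n_frames=400, motion_spike_rate=0.03, seed=8)
        cohort = generate_cohort(cfg)
        n_spikes = 0
        for s in range(6):
            fd, _ = framewise_displacement(cohort.motion[s])
            n_spikes += int((fd > 0.5).sum())
        assert n_spikes > 0

    def test_records_schema(self):
        cohort = generate_cohort(CohortConfig(n_subjects=5, n_nodes=8, n_frames=40, seed=9))
        assert list(cohort.records.columns) == ["id", "age", "sex", "mean_fd", "skill_learning"]
        assert cohort.records["sex"].isin([0, 1]).all()
        assert (cohort.records["mean_fd"] >= 0).all()


class TestNearestCorrelation:
    def test_projection_is_valid_correlation_matrix(self):
        rng = np.random.default_rng(10)
        m = rng.uniform(-0.9, 0.9, size=(12, 12))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        repaired = nearest_correlation(m)
        vals = np.linalg.eigvalsh(repaired)
        assert vals.min() >= -1e-10
        np.testing.assert_allclose(np.diag(repaired), 1.0, atol=1e-12)

    def test_psd_input_unchanged(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=(30, 6))
        c = np.corrcoef(a, rowvar=False)
        np.testing.assert_allclose(nearest_correlation(c), c, atol=1e-8)


class TestNullCalibration:
    def test_edge_t_statistics_are_student_t(self):
        """Pooled edge-wise t statistics from null cohorts follow the
        Student-t reference distribution (KS p > 0.01 on ~10,000 edges).

        Edges within one cohort share subject-level sampling noise, so the
        pool draws a thin random edge sample from many independent cohorts
        to respect the KS test's independence assumption.
        """
        iu, ju = np.triu_indices(40, k=1)
        rng = np.random.default_rng(99)
        pooled = []
        df = 30 - 5
        for k in range(80):
            cfg = CohortConfig(
                n_subjects=30, n_nodes=40, n_frames=120,
                implanted_edges=(), effect_beta=0.0, seed=700 + k,
            )
            cohort = generate_cohort(cfg)
            mats = np.stack([correlation_matrix(ts).values for ts in cohort.timeseries])
            tm = edge_statistics(
                mats, cohort.records, "skill_learning", ["age", "sex", "mean_fd"]
            )
            t = tm[iu, ju]
            pooled.append(t[rng.choice(t.size, 130, replace=False)])
        pooled = np.concatenate(pooled)
        assert pooled.size >= 10_000
        ks = sps.kstest(pooled, sps.t(df).cdf)
        assert ks.pvalue > 0.01


class TestGenerateBehavior:
    def test_no_learning_keeps_block_means_level(self):
        deltas = []
        for seed in range(30):
            beh = generate_behavior(learning_rate=0.0, seed=seed)
            durs = [b.mean_duration for b in beh.record.blocks]
            deltas.append(durs[-1] - durs[0])
        assert abs(np.mean(deltas)) < 0.5

    def test_block_four_mean_matches_geometric_decay(self):
        # closed-form expectation start * 0.9^3 vs Monte-Carlo over 1,000 seeds
        means = [
            generate_behavior(learning_rate=0.1, start_duration=20.0, seed=s)
            .record.blocks[3]
            .mean_duration
            for s in range(1000)
        ]
        assert np.mean(means) == pytest.approx(20.0 * 0.9**3, rel=0.01)

    def test_gate_event_denominator(self):
        beh = generate_behavior(n_trials=35, n_gates=5, seed=0)
        assert all(b.n_gate_events == 175 for b in beh.record.blocks)
        assert all(len(beh.gates[beh.gates["block"] == b]) == 175 for b in (1, 2, 3, 4))

    def test_learning_gives_positive_skill_change_on_average(self):
        deltas = [
            skill_learning(generate_behavior(learning_rate=0.12, seed=s).record)
            for s in range(500)
        ]
        assert np.mean(deltas) > 0

    def test_invalid_learning_rate_rejected(self):
        with pytest.raises(ValueError):
            generate_behavior(learning_rate=1.0)
        with pytest.raises(ValueError):
            generate_behavior(start_error=0.0)


class TestGenerateRetestPair:
    @pytest.mark.parametrize("target,tol", [(0.0, 0.1), (0.72, 0.05)])
    def test_icc_targets_recovered(self, target, tol):
        s1, s2 = generate_retest_pair(500, icc_target=target, seed=31)
        est = icc(np.column_stack([s1, s2])).icc_2_1
        assert est == pytest.approx(target, abs=tol)

    def test_perfect_agreement_limit(self):
        rng = np.random.default_rng(32)
        vals = rng.normal(size=100)
        est = icc(np.column_stack([vals, vals])).icc_2_1
        assert est == pytest.approx(1.0)

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            generate_retest_pair(10, icc_target=1.0)


@pytest.fixture(scope="module")
def base_cohort():
    cfg = CohortConfig(
        n_subjects=60, n_nodes=30, n_frames=150,
        base_correlation=0.3, implanted_edges=path_edges(10),
        effect_beta=0.1, seed=33,
    )
    return generate_cohort(cfg)


class TestGenerateDrugPair:

    def test_null_drug_no_paired_difference(self, base_cohort):
        rng = np.random.default_rng(34)
        dose = rng.normal(46.1, 21.6, size=60).clip(5)
        placebo, drug = generate_drug_pair(base_cohort, 0.0, dose, seed=35)
        d_pl = implanted_mean(placebo.timeseries, placebo.implanted_edges)
        d_dr = implanted_mean(drug.timeseries, drug.implanted_edges)
        t = sps.ttest_rel(d_dr, d_pl)
        assert abs(t.statistic) < 3.0

    def test_dose_scaled_decrement_negative_correlation(self, base_cohort):
        rng = np.random.default_rng(36)
        dose = rng.normal(46.1, 21.6, size=60).clip(5)
        _, drug = generate_drug_pair(base_cohort, 0.004, dose, seed=37)
        means = implanted_mean(drug.timeseries, drug.implanted_edges)
        assert np.corrcoef(dose, means)[0, 1] < 0

    def test_equal_doses_flagged(self, base_cohort):
        with pytest.warns(UserWarning, match="zero variance"):
            generate_drug_pair(base_cohort, 0.002, np.full(60, 40.0), seed=38)

    def test_condition_columns_added(self, base_cohort):
        dose = np.linspace(10, 80, 60)
        placebo, drug = generate_drug_pair(base_cohort, 0.003, dose, seed=39)
        assert (placebo.records["condition"] == "placebo").all()
        assert (drug.records["condition"] == "drug").all()
        np.testing.assert_array_equal(drug.records["dose"], dose)
        assert placebo.records["order"].isin([0, 1]).all()
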