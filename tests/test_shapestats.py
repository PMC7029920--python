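"""Statistical battery: bgPCA, permutation tests, RRPP ANOVA, trajectories,
allometry, CV equality, Mahalanobis distances, plasticity, repeatability."""

import numpy as np
import pandas as pd
import pytest

from morphonorm.io import DEFAULT_GROUP_SIZES, ValidationError
from morphonorm.shapestats import (
    allometry_fit,
    bgpca,
    cv_compare,
    cva_mahalanobis,
    expand_terms,
    perm_test_group_means,
    plasticity_permutation_test,
    procrustes_anova_rrpp,
    repeatability_anova,
    trajectory_analysis,
)


def study_design_labels():
    pops, temps = [], []
    for (p, t), n in DEFAULT_GROUP_SIZES.items():
        pops += [p] * n
        temps += [t] * n
    return np.array(pops), np.array(temps)


class TestBgPCA:
    def test_each_individual_own_group_reduces_to_pca(self, rng):
        y = rng.normal(size=(20, 6))
        res = bgpca(y, np.arange(20).astype(str))
        yc = y - y.mean(axis=0)
        _, _, vt = np.linalg.svd(yc, full_matrices=False)
        for j in range(5):
            r = np.corrcoef(res.scores[:, j], yc @ vt[j])[0, 1]
            assert abs(r) > 1 - 1e-9

    def test_two_groups_single_axis_along_mean_difference(self, rng):
        y = rng.normal(size=(30, 5))
        g = np.array(["a"] * 15 + ["b"] * 15)
        res = bgpca(y, g)
        assert res.axes.shape[1] == 1
        diff = y[g == "a"].mean(0) - y[g == "b"].mean(0)
        cos = abs(res.axes[:, 0] @ diff / np.linalg.norm(diff))
        assert cos == pytest.approx(1.0, abs=1e-9)

    def test_three_group_scores_match_small_matrix_eigendecomposition(self, rng):
        y = rng.normal(size=(24, 4))
        g = np.repeat(["a", "b", "c"], 8)
        res = bgpca(y, g)
        means = np.stack([y[g == lab].mean(0) for lab in ("a", "b", "c")])
        mc = means - means.mean(0)
        evals, evecs = np.linalg.eigh(mc.T @ mc / 2)
        order = np.argsort(evals)[::-1]
        for j in range(2):
            v = evecs[:, order[j]]
            cos = abs(v @ res.axes[:, j])
            assert cos == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(np.sort(evals)[::-1][:2],
                                   res.explained_variance, atol=1e-10)

    def test_empty_group_rejected(self, rng):
        with pytest.raises(ValidationError):
            bgpca(rng.normal(size=(4, 3)), np.array(["a"] * 4))


class TestGroupMeanPermTest:
    def test_identical_configurations_give_p_one(self):
        y = np.tile(np.arange(6.0), (12, 1))
        g = np.repeat(["a", "b"], 6)
        res = perm_test_group_means(y, g, n_perm=199, seed=0)
        assert res.distances[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert res.p_values[0, 1] == 1.0

    def test_separated_groups_highly_significant(self, rng):
        y = rng.normal(size=(60, 5), scale=0.05)
        y[30:] += 5.0
        g = np.repeat(["a", "b"], 30)
        res = perm_test_group_means(y, g, n_perm=1999, seed=0)
        assert res.p_values[0, 1] <= 0.001

    def test_reproducible_given_seed(self, rng):
        y = rng.normal(size=(30, 4))
        g = np.repeat(["a", "b", "c"], 10)
        r1 = perm_test_group_means(y, g, n_perm=299, seed=7)
        r2 = perm_test_group_means(y, g, n_perm=299, seed=7)
        np.testing.assert_array_equal(r1.p_values, r2.p_values)


class TestRRPPAnova:
    def test_balanced_univariate_matches_textbook_f(self, rng):
        """One response, two balanced groups: F must equal the hand
        formula n*(mean difference)^2 / (2 * pooled variance)."""
        a = rng.normal(size=10)
        b = rng.normal(size=10) + 0.8
        y = np.concatenate([a, b])[:, None]
        g = np.repeat(["a", "b"], 10)
        table = procrustes_anova_rrpp(y, {"g": g}, ["g"], n_perm=99, seed=0)
        pooled = (a.var(ddof=1) + b.var(ddof=1)) / 2
        f_hand = 10 * (a.mean() - b.mean()) ** 2 / (2 * pooled)
        assert table.f["g"] == pytest.approx(f_hand, rel=1e-10)
        assert table.df["g"] == 1 and table.df_residual == 18

    def test_ss_decomposition(self, rng):
        pops, temps = study_design_labels()
        y = rng.normal(size=(len(pops), 7))
        table = procrustes_anova_rrpp(
            y, {"population": pops, "temperature": temps.astype(str)},
            "population*temperature", n_perm=49, seed=0,
        )
        total = sum(table.ss.values()) + table.ss_residual
        assert total == pytest.approx(table.ss_total, rel=1e-8)
        assert sum(table.df.values()) + table.df_residual == len(pops) - 1

    def test_aliased_term_rejected(self, rng):
        g = np.repeat(["a", "b"], 10)
        with pytest.raises(ValidationError, match="dup"):
            procrustes_anova_rrpp(
                rng.normal(size=(20, 3)), {"g": g, "dup": g}, ["g", "dup"],
                n_perm=9, seed=0,
            )

    def test_recovers_temperature_only_effect(self, rng):
        pops, temps = study_design_labels()
        y = rng.normal(size=(len(pops), 8), scale=0.5)
        y[temps == 16, 0] += 1.0
        y[temps == 28, 1] += 1.0
        table = procrustes_anova_rrpp(
            y, {"population": pops, "temperature": temps.astype(str)},
            "population*temperature", n_perm=199, seed=1,
        )
        assert table.p["temperature"] <= 0.01
        assert table.p["population"] > 0.05

    def test_formula_expansion(self):
        assert expand_terms("a*b") == ["a", "b", "a:b"]
        assert expand_terms("a + b") == ["a", "b"]


class TestTrajectory:
    def test_collinear_equally_spaced_geometry(self, rng):
        """Three collinear, equally spaced means with step s: path length
        2s; two identical trajectories have angle 0 and distance 0."""
        pops = np.repeat(["A", "B"], 30)
        temps = np.tile(np.repeat([16, 22, 28], 10), 2)
        s = 0.7
        y = np.zeros((60, 4))
        y[:, 0] = (temps - 22) / 6 * s  # exact collinear means, step s
        tr = trajectory_analysis(y + rng.normal(scale=1e-9, size=y.shape),
                                 pops, temps, n_perm=19, seed=0)
        assert tr.path_lengths["A"] == pytest.approx(2 * s, rel=1e-6)
        angle = tr.pairwise.query("stat == 'angle'")["value"].iloc[0]
        assert angle == pytest.approx(0.0, abs=1e-3)
        shape_d = tr.pairwise.query("stat == 'shape_distance'")["value"].iloc[0]
        assert shape_d == pytest.approx(0.0, abs=1e-6)

    def test_path_length_at_least_endpoint_distance(self, rng):
        pops = np.repeat(["A", "B", "C"], 30)
        temps = np.tile(np.repeat([16, 22, 28], 10), 3)
        y = rng.normal(size=(90, 6))
        tr = trajectory_analysis(y, pops, temps, n_perm=9, seed=0)
        for p in ("A", "B", "C"):
            means = np.stack([
                y[(pops == p) & (temps == t)].mean(0) for t in (16, 22, 28)
            ])
            endpoint = np.linalg.norm(means[-1] - means[0])
            assert tr.path_lengths[p] >= endpoint - 1e-12

    def test_doubled_reaction_norm_detected(self, rng):
        """One population with twice the thermal displacement must show a
        significant path-length difference."""
        pops, temps = study_design_labels()
        v16 = np.r_[1.0, np.zeros(5)]
        v28 = np.r_[0, 1.0, np.zeros(4)]
        y = rng.normal(size=(len(pops), 6), scale=0.3)
        for t, v in ((16, v16), (28, v28)):
            y[temps == t] += v
            y[(temps == t) & (pops == "Paris")] += v  # doubled for Paris
        tr = trajectory_analysis(y, pops, temps, n_perm=199, seed=3)
        sub = tr.pairwise.query("stat == 'path_length_diff'")
        paris_rows = sub[(sub.group_a == "Paris") | (sub.group_b == "Paris")]
        assert (paris_rows.p <= 0.05).all()

    def test_missing_cell_rejected(self, rng):
        pops = np.repeat(["A", "B"], 10)
        temps = np.r_[np.repeat([16, 22], 5), np.repeat([22, 28], 5)]
        with pytest.raises(ValidationError):
            trajectory_analysis(rng.normal(size=(20, 3)), pops, temps, n_perm=9)

    def test_angles_in_degrees_up_to_180(self, rng):
        """Opposed trajectories give angles near 180°, not folded to 90°."""
        pops = np.repeat(["A", "B"], 30)
        temps = np.tile(np.repeat([16, 22, 28], 10), 2)
        y = rng.normal(size=(60, 4), scale=0.01)
        slope = (temps - 22) / 6.0
        y[pops == "A", 0] += slope[pops == "A"]
        y[pops == "B", 0] -= slope[pops == "B"]
        tr = trajectory_analysis(y, pops, temps, n_perm=9, seed=0)
        angle = tr.pairwise.query("stat == 'angle'")["value"].iloc[0]
        assert angle > 170.0


class TestAllometry:
    def test_noiseless_recovery(self, rng):
        log_cs = rng.uniform(5.5, 6.5, 50)
        beta = rng.normal(size=8)
        y = np.outer(log_cs - log_cs.mean(), beta) + rng.normal(
            scale=1e-9, size=(50, 8)
        )
        res = allometry_fit(y, log_cs, n_perm=49, seed=0)
        cos = res.slope @ beta / np.linalg.norm(res.slope) / np.linalg.norm(beta)
        assert cos > 0.999
        assert res.anova.p["log_cs"] <= 0.05

    def test_shared_slope_homogeneity_not_significant(self, rng):
        log_cs = rng.uniform(5.5, 6.5, 90)
        groups = np.repeat(["a", "b", "c"], 30)
        beta = rng.normal(size=6)
        y = np.outer(log_cs, beta) + rng.normal(scale=0.3, size=(90, 6))
        res = allometry_fit(y, log_cs, groups, n_perm=199, seed=1)
        assert res.homogeneity.p["log_cs:group"] > 0.05
        assert res.anova.p["log_cs"] <= 0.01

    def test_zero_size_variance_rejected(self, rng):
        with pytest.raises(ValidationError):
            allometry_fit(rng.normal(size=(10, 3)), np.full(10, 6.0))


class TestCVCompare:
    def test_identical_samples_statistic_zero(self, rng):
        v = rng.normal(100, 5, 30)
        res = cv_compare({"a": v, "b": v.copy()})
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p > 0.99

    def test_cv_values(self):
        v = np.array([90.0, 100.0, 110.0])
        res = cv_compare({"a": v, "b": v * 2})
        assert res.cvs["a"] == pytest.approx(100 * 10.0 / 100.0, rel=1e-12)
        assert res.cvs["a"] == pytest.approx(res.cvs["b"], rel=1e-12)

    def test_strong_contrast_significant(self, rng):
        """CVs of 3% vs 14% at n=50: decisively significant."""
        hits = 0
        for r in range(20):
            g = np.random.default_rng(r)
            a = g.normal(100, 3, 50)
            b = g.normal(100, 14, 50)
            hits += cv_compare({"a": a, "b": b}).p <= 0.05
        assert hits == 20

    def test_type_i_calibrated_small_samples(self):
        rej = 0
        reps = 300
        g = np.random.default_rng(99)
        for _ in range(reps):
            a = g.normal(100, 5, 15)
            b = g.normal(250, 12.5, 15)  # same CV, different scale
            rej += cv_compare({"a": a, "b": b}).p <= 0.05
        assert 0.02 <= rej / reps <= 0.08

    def test_near_zero_mean_rejected(self, rng):
        with pytest.raises(ValidationError):
            cv_compare({"a": np.array([-1.0, 1.0, -1.0, 1.0]),
                        "b": rng.normal(10, 1, 5)})


class TestMahalanobis:
    def test_spherical_groups_recover_mean_separation(self, rng):
        delta = 3.0
        a = rng.normal(size=(4000, 3))
        b = rng.normal(size=(4000, 3))
        b[:, 0] += delta
        scores = np.vstack([a, b])
        g = np.repeat(["a", "b"], 4000)
        labels, d = cva_mahalanobis(scores, g)
        assert d[0, 1] == pytest.approx(delta, rel=0.05)

    def test_affine_invariance(self, rng):
        scores = rng.normal(size=(60, 5))
        g = np.repeat(["a", "b", "c"], 20)
        scores[g == "b"] += 1.0
        _, d0 = cva_mahalanobis(scores, g)
        mix = rng.normal(size=(5, 5)) + 3 * np.eye(5)
        _, d1 = cva_mahalanobis(scores @ mix, g)
        np.testing.assert_allclose(d1, d0, atol=1e-8)

    def test_matches_direct_formula(self, rng):
        scores = rng.normal(size=(45, 4))
        g = np.repeat(["a", "b", "c"], 15)
        scores[g == "c"] += [1, 0, -1, 0]
        labels, d = cva_mahalanobis(scores, g)
        means = {lab: scores[g == lab].mean(0) for lab in labels}
        w = sum(
            (scores[g == lab] - means[lab]).T @ (scores[g == lab] - means[lab])
            for lab in labels
        ) / (45 - 3)
        for i, la in enumerate(labels):
            for j, lb in enumerate(labels):
                if i < j:
                    diff = means[la] - means[lb]
                    expected = np.sqrt(diff @ np.linalg.solve(w, diff))
                    assert d[i, j] == pytest.approx(expected, abs=1e-8)

    def test_singular_covariance_rejected(self, rng):
        scores = rng.normal(size=(10, 9))
        g = np.repeat(["a", "b"], 5)
        with pytest.raises(ValidationError, match="PCs"):
            cva_mahalanobis(scores, g)


class TestPlasticityComparison:
    def test_identical_structures_statistic_zero_p_one(self, rng):
        pops, temps = study_design_labels()
        y = rng.normal(size=(len(pops), 6))
        y[temps == 16] += [1, 0, 0, 0, 0, 0]
        res = plasticity_permutation_test(y, temps, y.copy(), temps,
                                          n_perm=199, seed=0)
        assert res.observed == pytest.approx(0.0, abs=1e-12)
        assert res.p == 1.0

    def test_more_plastic_structure_detected(self, rng):
        """A 3x thermal effect in one structure must be called significant
        in nearly every replicate."""
        pops, temps = study_design_labels()
        hits = 0
        n_rep = 20
        for r in range(n_rep):
            g = np.random.default_rng(1000 + r)
            shift = np.r_[1.0, np.zeros(5)]
            ya = g.normal(size=(len(pops), 6))
            yb = g.normal(size=(len(pops), 6))
            for t, m in ((16, -1), (28, 1)):
                ya[temps == t] += m * shift
                yb[temps == t] += 3 * m * shift
            res = plasticity_permutation_test(ya, temps, yb, temps,
                                              n_perm=199, seed=r)
            hits += (res.p <= 0.05) and (res.observed < 0)
        assert hits >= int(0.9 * n_rep)

    def test_equal_pc_counts_enforced(self, rng):
        pops, temps = study_design_labels()
        ya = rng.normal(size=(len(pops), 10))
        yb = rng.normal(size=(len(pops), 4))
        res = plasticity_permutation_test(ya, temps, yb, temps, n_perm=19, seed=0)
        assert res.n_pcs == 4
        with pytest.raises(ValidationError):
            plasticity_permutation_test(ya, temps, yb, temps, n_pcs=8,
                                        n_perm=19, seed=0)

    def test_mismatched_specimens_rejected(self, rng):
        pops, temps = study_design_labels()
        with pytest.raises(ValidationError):
            plasticity_permutation_test(
                rng.normal(size=(len(pops), 4)), temps,
                rng.normal(size=(10, 4)), temps[:10], n_perm=9,
            )


class TestRepeatability:
    def test_known_variance_ratio_recovered(self):
        """Between-individual sd = 2x replicate sd with 5 replicates:
        E[MS_ind/MS_res] = 1 + 5*4 = 21."""
        ratios = []
        for r in range(120):
            g = np.random.default_rng(r)
            ind_means = g.normal(0, 2.0, size=(2, 6))
            y = np.repeat(ind_means, 5, axis=0) + g.normal(0, 1.0, (10, 6))
            labs = np.repeat(["i1", "i2"], 5)
            ratios.append(repeatability_anova(y, labs, n_perm=49, seed=r).ratio)
        assert np.mean(ratios) == pytest.approx(21.0, rel=0.25)

    def test_zero_measurement_error_flagged_infinite(self):
        y = np.repeat(np.arange(12.0).reshape(2, 6), 4, axis=0)
        labs = np.repeat(["a", "b"], 4)
        res = repeatability_anova(y, labs, n_perm=19, seed=0)
        assert res.infinite and np.isinf(res.ratio)

    def test_invariant_to_replicate_shuffling_within_individuals(self, rng):
        y = rng.normal(size=(10, 5))
        labs = np.repeat(["a", "b"], 5)
        r1 = repeatability_anova(y, labs, n_perm=49, seed=0)
        perm = np.r_[rng.permutation(5), 5 + rng.permutation(5)]
        r2 = repeatability_anova(y[perm], labs, n_perm=49, seed=0)
        assert r1.ratio == pytest.approx(r2.ratio, rel=1e-10)

    def test_replicated_landmark_sample_end_to_end(self, small_sample):
        from morphonorm.synthesis import simulate_replicates

        sample, _ = small_sample
        rep = simulate_replicates(sample.subset(range(2)), 5, 5e-4, seed=3)
        res = repeatability_anova(rep, n_perm=99, seed=0)
        assert res.ratio > 1.0
        assert res.p <= 0.05


def test_permutation_p_values_uniform_under_null():
    """The (1+count)/(1+n_perm) convention must give null p-values that
    are uniform on (0, 1]; KS test at alpha = 0.01."""
    from scipy import stats as sps

    g = np.random.default_rng(42)
    pvals = []
    for r in range(500):
        y = g.normal(size=(24, 3))
        labels = np.repeat(["a", "b"], 12)
        res = perm_test_group_means(y, labels, n_perm=199, seed=r)
        pvals.append(res.p_values[0, 1])
    ks = sps.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01
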