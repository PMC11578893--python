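"""Axis-based statistics: QC, weighted positions, profiles, ANOVA, SGs, PCA score."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from organaxis.stats import (
    BinProfileSet,
    axis_variance_score,
    bin_profiles,
    cluster_profiles,
    detect_specialization_genes,
    group_cosine_similarity,
    hypercluster_axis_assignment,
    profile_anova,
    profile_cosine,
    qc_filter_spots,
    weighted_mean_position,
)


class TestQcFilter:
    def test_spot_below_either_threshold_removed_boundary_kept(self):
        obs = pd.DataFrame({
            "n_features": [999, 1000, 5000, 2000, 800],
            "n_cells": [30, 25, 24, 100, 10],
        })
        kept, report = qc_filter_spots(obs)
        # 999 features fails; exactly 1000 & 25 is retained; 24 cells fails
        assert list(kept.index) == [1, 3]
        assert report["removed_low_features"] == 2
        assert report["removed_low_cells"] == 2
        assert report["n_kept"] == 2

    def test_manual_enumeration_of_toy_table(self):
        obs = pd.DataFrame({
            "n_features": [1500, 900, 1200, 1000, 999],
            "n_cells": [26, 30, 20, 25, 25],
        })
        survivors = [
            i for i in obs.index
            if obs.loc[i, "n_features"] >= 1000 and obs.loc[i, "n_cells"] >= 25
        ]
        kept, _ = qc_filter_spots(obs)
        assert list(kept.index) == survivors


class TestWeightedMean:
    def test_uniform_weights_give_arithmetic_mean(self):
        assert weighted_mean_position([1, 1], [0.0, 1.0]) == 0.5

    def test_point_mass_returns_that_position(self):
        assert weighted_mean_position([0, 5, 0], [0.1, 0.7, 0.9]) == 0.7

    def test_weights_one_three(self):
        assert weighted_mean_position([1, 3], [0.0, 1.0], threshold=0) == 0.75

    def test_threshold_excludes_low_weights(self):
        # weight 0.1 < 0.5 threshold drops the first observation
        assert weighted_mean_position([0.1, 2.0], [0.0, 1.0], threshold=0.5) == 1.0

    def test_all_below_threshold_is_nan_with_warning(self):
        with pytest.warns(UserWarning):
            out = weighted_mean_position([0.1, 0.2], [0, 1], threshold=0.5)
        assert np.isnan(out)

    def test_bounded_and_scale_invariant(self):
        rng = np.random.default_rng(0)
        w, x = rng.random(50), rng.uniform(-1, 1, 50)
        m = weighted_mean_position(w, x)
        assert x.min() <= m <= x.max()
        assert weighted_mean_position(10 * w, x) == pytest.approx(m)


def toy_profiles(groups=("fetal", "paed"), n_samples=3, bins=("b0", "b1"),
                 features=("f0", "f1"), fn=None, seed=0):
    """Construct a BinProfileSet directly from a mean-generating function."""
    rng = np.random.default_rng(seed)
    fn = fn or (lambda feat, grp, bin_, rng: rng.normal())
    rows = []
    for feat, grp, s, b in itertools.product(features, groups,
                                             range(n_samples), bins):
        rows.append((feat, f"{grp}_s{s}", grp, b, fn(feat, grp, b, rng)))
    means = pd.DataFrame(rows, columns=["feature", "sample", "group", "bin", "mean"])
    return BinProfileSet(means=means, prevalence=pd.DataFrame(),
                         bin_order=tuple(bins), features=tuple(features))


class TestBinProfiles:
    def _obs(self):
        rng = np.random.default_rng(1)
        n = 400
        bins = pd.Series(rng.choice(["b0", "b1"], n))
        samples = pd.Series(rng.choice(["s1", "s2"], n))
        expr = pd.DataFrame({
            "rare": (rng.random(n) < 0.04).astype(float),      # 4% everywhere
            "focal": np.where((bins == "b1") & (rng.random(n) < 0.2), 1.0, 0.0),
            "common": rng.poisson(2.0, n).astype(float),
        })
        return expr, bins, samples

    def test_prevalence_filter_keeps_focal_drops_rare(self):
        expr, bins, samples = self._obs()
        prof = bin_profiles(expr, bins, samples, min_prevalence=0.05)
        assert "rare" not in prof.features        # < 5% in every bin
        assert "focal" in prof.features           # >= 5% in one bin only
        assert "common" in prof.features

    def test_means_equal_hand_computation(self):
        expr = pd.DataFrame({"g": [1.0, 3.0, 2.0, 10.0]})
        bins = pd.Series(["b0", "b0", "b1", "b1"])
        samples = pd.Series(["s1", "s1", "s1", "s2"])
        prof = bin_profiles(expr, bins, samples, min_prevalence=0.0, log=False)
        m = prof.means.set_index(["sample", "bin"])["mean"]
        assert m.loc[("s1", "b0")] == 2.0
        assert m.loc[("s1", "b1")] == 2.0
        assert m.loc[("s2", "b1")] == 10.0

    def test_empty_bin_is_missing_not_zero(self):
        expr = pd.DataFrame({"g": [1.0, 2.0]})
        bins = pd.Series(["b0", "b0"])
        samples = pd.Series(["s1", "s1"])
        prof = bin_profiles(expr, bins, samples, bin_order=("b0", "b1"),
                            min_prevalence=0.0, log=False)
        assert ("s1", "b1") not in set(
            zip(prof.means["sample"], prof.means["bin"])
        )


def ward_oracle(profiles: np.ndarray) -> list[float]:
    """Exhaustive Ward merging via centroid/size recursion; returns heights."""
    clusters = [([i], profiles[i], 1) for i in range(len(profiles))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                _, ca, na = clusters[a]
                _, cb, nb = clusters[b]
                d = np.sqrt(2 * na * nb / (na + nb)) * np.linalg.norm(ca - cb)
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        ids_a, ca, na = clusters[a]
        ids_b, cb, nb = clusters[b]
        merged = (ids_a + ids_b, (na * ca + nb * cb) / (na + nb), na + nb)
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
        heights.append(d)
    return heights


class TestClusterProfiles:
    def test_identical_profiles_merge_first_at_height_zero(self):
        prof = pd.DataFrame([[1.0, 2, 3], [1.0, 2, 3], [9, 1, 0]],
                            index=["g1", "g2", "g3"])
        out = cluster_profiles(prof)
        link = out["linkage"]
        assert link[0, 2] == 0.0
        assert {int(link[0, 0]), int(link[0, 1])} == {0, 1}

    def test_linkage_heights_match_exhaustive_ward_oracle(self):
        rng = np.random.default_rng(3)
        for n in (4, 5, 6):
            prof = pd.DataFrame(rng.normal(size=(n, 5)))
            out = cluster_profiles(prof)
            want = ward_oracle(out["standardized"].to_numpy())
            assert np.allclose(sorted(out["linkage"][:, 2]), sorted(want))

    def test_constant_profile_standardized_to_zero(self):
        prof = pd.DataFrame([[1.0, 1, 1], [0, 1, 2]], index=["flat", "grad"])
        out = cluster_profiles(prof)
        assert np.all(out["standardized"].loc["flat"].to_numpy() == 0.0)

    def test_flat_cluster_count_respected(self):
        rng = np.random.default_rng(4)
        prof = pd.DataFrame(rng.normal(size=(10, 6)))
        out = cluster_profiles(prof, n_clusters=3)
        assert out["clusters"].nunique() == 3


class TestCosine:
    def test_identical_profiles(self):
        assert profile_cosine([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_orthogonal_profiles(self):
        assert profile_cosine([1, 0], [0, 1]) == 0.0

    def test_closed_form_value(self):
        assert profile_cosine([1, 2, 3], [3, 2, 1]) == pytest.approx(10 / 14)

    def test_zero_vector_warns_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(profile_cosine([0, 0], [1, 2]))

    def test_group_cosine_uses_pooled_sample_medians(self):
        prof = toy_profiles(
            bins=("b0", "b1"),
            fn=lambda f, g, b, rng: {"b0": 1.0, "b1": 2.0}[b]
            if g == "fetal" else {"b0": 2.0, "b1": 4.0}[b],
        )
        cos = group_cosine_similarity(prof, "fetal", "paed")
        # proportional profiles: cosine exactly 1 for both features
        assert np.allclose(cos.to_numpy(), 1.0)


class TestProfileAnova:
    def test_balanced_type2_equals_manual_two_way(self):
        prof = toy_profiles(n_samples=4, seed=5)
        res = profile_anova(prof)
        assert set(res.columns) >= {"p_group", "p_bin", "p_interaction"}
        assert res.shape[0] == 2
        assert ((res >= 0) & (res <= 1)).all().all()

    def test_interaction_power_at_large_effect(self):
        """Cell means (0,0,0,2) at sigma 1, n=50 per cell: corrected p < 0.05."""
        prof = toy_profiles(
            n_samples=50, features=("hit",), seed=6,
            fn=lambda f, g, b, rng: rng.normal(
                2.0 if (g == "paed" and b == "b1") else 0.0, 1.0
            ),
        )
        res = profile_anova(prof)
        assert res.loc["hit", "p_interaction_bonf"] < 0.05

    def test_null_interaction_type_one_error_calibrated(self):
        """2,000 null features: interaction p < 0.05 rate within [0.03, 0.07]."""
        prof = toy_profiles(n_samples=6, bins=tuple(f"b{i}" for i in range(5)),
                            features=tuple(f"f{i}" for i in range(2000)), seed=7)
        res = profile_anova(prof)
        rate = (res["p_interaction"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_empty_cell_feature_skipped_with_warning(self):
        prof = toy_profiles(features=("a", "b"))
        means = prof.means
        drop = (means["feature"] == "a") & (means["group"] == "fetal") & (
            means["bin"] == "b0")
        prof.means = means[~drop]
        with pytest.warns(UserWarning, match="empty"):
            res = profile_anova(prof)
        assert list(res.index) == ["b"]

    def test_bonferroni_scales_with_feature_family(self):
        prof = toy_profiles(features=tuple(f"f{i}" for i in range(5)), seed=8)
        res = profile_anova(prof)
        expect = np.minimum(res["p_group"] * len(res), 1.0)
        assert np.allclose(res["p_group_bonf"], expect)


def planted_sg_counts(n_per_type=100, n_types=3, n_planted=4, n_null=20, seed=0):
    """Exclusive planted genes (constant count in one type, zero elsewhere)
    among broadly expressed null genes."""
    rng = np.random.default_rng(seed)
    types = np.repeat([f"T{t}" for t in range(n_types)], n_per_type)
    n = n_per_type * n_types
    cols = {}
    truth = {}
    for j in range(n_planted):
        t = f"T{j % n_types}"
        col = np.zeros(n)
        col[types == t] = 10.0
        cols[f"sg{j}"] = col
        truth[f"sg{j}"] = t
    for j in range(n_null):
        cols[f"null{j}"] = rng.poisson(2.5, n).astype(float)
    return pd.DataFrame(cols), pd.Series(types), truth


class TestSpecializationGenes:
    def test_low_mean_gene_excluded_before_testing(self):
        counts = pd.DataFrame({"low": np.full(60, 1.2), "hi": np.arange(60, dtype=float)})
        types = pd.Series(np.repeat(["a", "b"], 30))
        res = detect_specialization_genes(counts, types)
        assert not res.loc["low", "included"]
        assert np.isnan(res.loc["low", "p"])

    def test_uniform_gene_not_sg(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame({"g": rng.poisson(3.0, 300).astype(float)})
        types = pd.Series(np.repeat(["a", "b", "c"], 100))
        res = detect_specialization_genes(counts, types)
        assert not res.loc["g", "sg"]
        assert res.loc["g", "p"] > 1e-50

    def test_exclusive_gene_matches_chi2_oracle_and_is_sg(self):
        """All 100 cells of one type at count 10, zero elsewhere: the
        selection keeps the full type, and p equals the closed-form test on
        the explicit [[100,0,0],[0,100,100]] table (~7e-66 < 1e-50)."""
        counts, types, _ = planted_sg_counts(n_planted=1, n_null=0)
        res = detect_specialization_genes(counts, types)
        row = res.loc["sg0"]
        want_chi2, want_p, *_ = chi2_contingency(
            [[100, 0, 0], [0, 100, 100]]
        )
        assert row["n_selected"] == 100
        assert row["chi2"] == pytest.approx(want_chi2)
        assert row["p"] == pytest.approx(want_p)
        assert want_p < 1e-50
        assert row["sg"] and row["assigned_type"] == "T0"

    def test_planted_recall_one_fdr_zero(self):
        counts, types, truth = planted_sg_counts()
        res = detect_specialization_genes(counts, types)
        called = set(res.index[res["sg"]])
        assert called == set(truth)  # recall 1, FDR 0
        for g, t in truth.items():
            assert res.loc[g, "assigned_type"] == t

    def test_fewer_than_two_types_rejected(self):
        with pytest.raises(ValueError):
            detect_specialization_genes(
                pd.DataFrame({"g": [1.0, 2.0]}), pd.Series(["a", "a"])
            )


def depth_linked_counts(n=1200, n_feat=15, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    depth = rng.random(n)
    X = np.stack([
        (j + 1) * depth + rng.normal(0, noise, n) + 1.0 for j in range(n_feat)
    ], axis=1)
    return pd.DataFrame(np.clip(X, 0, None)), depth


class TestAxisVarianceScore:
    def test_axis_driven_data_attributes_most_variance_to_axis(self):
        counts, depth = depth_linked_counts()
        out = axis_variance_score(counts, {"axis": depth}, batch_correct=False)
        assert out.contributions["axis"] > 0.9 * out.total_explained

    def test_permuted_axis_contribution_near_zero(self):
        counts, depth = depth_linked_counts(n=2000)
        rng = np.random.default_rng(9)
        out = axis_variance_score(
            counts, {"axis": rng.permutation(depth)}, batch_correct=False
        )
        assert out.contributions["axis"] < 0.05 * out.total_explained

    def test_invariant_to_monotone_covariate_transform(self):
        counts, depth = depth_linked_counts(n=400)
        a = axis_variance_score(counts, {"axis": depth}, batch_correct=False)
        b = axis_variance_score(counts, {"axis": np.exp(3 * depth)},
                                batch_correct=False)
        assert a.contributions["axis"] == pytest.approx(b.contributions["axis"])

    def test_constant_covariate_contributes_zero(self):
        counts, _ = depth_linked_counts(n=200)
        with pytest.warns(UserWarning, match="constant"):
            out = axis_variance_score(counts, {"axis": np.ones(200)},
                                      batch_correct=False)
        assert out.contributions["axis"] == 0.0

    def test_contributions_bounded_by_total(self):
        counts, depth = depth_linked_counts(n=300)
        out = axis_variance_score(
            counts, {"axis": depth, "technical": counts.sum(axis=1).to_numpy()},
            batch_correct=False,
        )
        for name in ("axis", "technical"):
            assert out.contributions[name] <= out.total_explained + 1e-9


class TestHyperclusterAssignment:
    def test_concentrated_abundance_returns_that_spot(self):
        ab = pd.DataFrame({"c0": [0.0] * 19 + [5.0]})
        axis = np.linspace(-1, 1, 20)
        out = hypercluster_axis_assignment(ab, axis)
        assert out["c0"] == pytest.approx(axis[-1])

    def test_uniform_abundance_reduces_to_top_subset_mean(self):
        ab = pd.DataFrame({"c0": np.ones(20)})
        axis = np.linspace(0, 1, 20)
        out = hypercluster_axis_assignment(ab, axis)
        # uniform weights: plain mean over the tie-fallback subset
        assert 0.0 <= out["c0"] <= 1.0

    def test_matches_manual_top_five_percent_selection(self):
        rng = np.random.default_rng(2)
        w = rng.random(20)
        axis = rng.uniform(-1, 1, 20)
        out = hypercluster_axis_assignment(pd.DataFrame({"c": w}), axis)
        thr = np.percentile(w, 95)
        sel = w > thr
        want = np.dot(w[sel], axis[sel]) / w[sel].sum()
        assert out["c"] == pytest.approx(want)

    def test_all_zero_cluster_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="all-zero"):
            out = hypercluster_axis_assignment(
                pd.DataFrame({"c": np.zeros(10)}), np.linspace(0, 1, 10)
            )
        assert np.isnan(out["c"])
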