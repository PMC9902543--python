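import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from diaquant import (build_profile_matrix, cluster_profiles, gap_statistic,
                      profile_similarity, within_dispersion)
from diaquant.errors import ConfigError, SizeError

from conftest import planted_blobs


def stats_frame(rows):
    """Protein-stats frame from (protein, comparison, lfc, p_adj) tuples."""
    return pd.DataFrame(rows, columns=["protein_group", "comparison",
                                       "log2fc", "p_adj"])


class TestBuildProfileMatrix:
    def test_one_qualifying_comparison_suffices(self):
        stats = stats_frame([
            ("P1", "c1", 1.2, 0.01), ("P1", "c2", 0.1, 0.9),
            ("P2", "c1", 0.5, 0.01), ("P2", "c2", 0.2, 0.9),
        ])
        out = build_profile_matrix(stats)
        assert list(out.index) == ["P1"]
        assert np.allclose(out.loc["P1"], [1.2, 0.1])

    def test_subthreshold_fold_changes_excluded(self):
        stats = stats_frame([("P1", "c1", 0.9, 1e-6), ("P1", "c2", -0.5, 1e-6)])
        assert len(build_profile_matrix(stats)) == 0

    def test_incomplete_profiles_excluded(self):
        stats = stats_frame([("P1", "c1", 2.0, 0.001)])  # missing in c2
        stats = pd.concat([stats, stats_frame([("P2", "c1", 2.0, 0.001),
                                               ("P2", "c2", 0.0, 0.9)])])
        out = build_profile_matrix(stats, comparisons=["c1", "c2"])
        assert list(out.index) == ["P2"]

    def test_row_count_matches_set_filter_oracle(self):
        rng = np.random.default_rng(21)
        rows = []
        for i in range(300):
            for c in ("c1", "c2", "c3"):
                rows.append((f"P{i:03d}", c, rng.normal(0, 1.2),
                             rng.random()))
        stats = stats_frame(rows)
        out = build_profile_matrix(stats)
        oracle = {
            p for p, grp in stats.groupby("protein_group")
            if any((abs(r.log2fc) >= 1) and (r.p_adj <= 0.05)
                   for r in grp.itertuples())
        }
        assert set(out.index) == oracle


class TestProfileSimilarity:
    def test_identical_rows_have_unit_similarity(self):
        prof = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        sim = profile_similarity(prof)
        assert sim.loc["a", "b"] == pytest.approx(1.0)

    def test_three_four_five_triangle(self):
        prof = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["a", "b"])
        sim = profile_similarity(prof)
        assert sim.loc["a", "b"] == pytest.approx(-4.0)

    def test_symmetry_and_independent_distance_oracle(self):
        rng = np.random.default_rng(22)
        prof = pd.DataFrame(rng.normal(size=(15, 4)),
                            index=[f"p{i}" for i in range(15)])
        sim = profile_similarity(prof)
        assert np.allclose(sim, sim.T)
        for i in range(15):
            for j in range(15):
                d = np.sqrt(((prof.iloc[i] - prof.iloc[j]) ** 2).sum())
                assert abs(sim.iloc[i, j] - (1 - d)) < 1e-10

    def test_single_row_rejected(self):
        with pytest.raises(SizeError):
            profile_similarity(pd.DataFrame([[1.0, 2.0]], index=["a"]))


class TestClusterProfiles:
    def test_k1_centroid_is_column_means(self):
        rng = np.random.default_rng(23)
        prof = pd.DataFrame(rng.normal(size=(10, 3)),
                            index=[f"p{i}" for i in range(10)])
        out = cluster_profiles(prof, k=1, seed=0)
        assert (out.labels == 1).all()
        assert np.allclose(out.centroids.iloc[0], prof.mean(axis=0))

    def test_planted_blobs_recovered(self):
        profiles, labels = planted_blobs(np.random.default_rng(24))
        out = cluster_profiles(profiles, k=3, seed=1)
        assert adjusted_rand_score(labels, out.labels) >= 0.99

    def test_duplicate_rows_share_a_cluster(self):
        rng = np.random.default_rng(25)
        base = rng.normal(size=(6, 3))
        arr = np.vstack([base, base[0]])
        prof = pd.DataFrame(arr, index=[f"p{i}" for i in range(7)])
        out = cluster_profiles(prof, k=3, seed=2)
        assert out.labels.iloc[0] == out.labels.iloc[6]

    def test_deterministic_under_fixed_seed(self):
        profiles, _ = planted_blobs(np.random.default_rng(26))
        a = cluster_profiles(profiles, k=3, seed=7)
        b = cluster_profiles(profiles, k=3, seed=7)
        assert a.labels.equals(b.labels)
        assert a.dispersion == b.dispersion

    def test_k_beyond_row_count_rejected(self):
        prof = pd.DataFrame(np.eye(3), index=list("abc"))
        with pytest.raises(ConfigError):
            cluster_profiles(prof, k=4, seed=0)


class TestDispersionAndGap:
    def test_square_at_k2_matches_exhaustive_partition_optimum(self):
        # unit square: best 2-partition pairs adjacent corners, W = 1.0
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        best = np.inf
        for assignment in itertools.product([0, 1], repeat=4):
            labels = np.array(assignment)
            if len(set(assignment)) < 2:
                continue
            # W via the pairwise-squared-distance definition
            w = 0.0
            for lab in (0, 1):
                sub = X[labels == lab]
                d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(axis=2)
                w += d2.sum() / (2 * len(sub))
            best = min(best, w)
        prof = pd.DataFrame(X, index=list("abcd"))
        out = cluster_profiles(prof, k=2, seed=3, restarts=10)
        assert out.dispersion == pytest.approx(best, abs=1e-12)
        assert best == pytest.approx(1.0)

    def test_pairwise_and_centroid_dispersion_forms_agree(self):
        rng = np.random.default_rng(27)
        X = rng.normal(size=(30, 3))
        labels = rng.integers(0, 4, size=30)
        w_pair = 0.0
        for lab in np.unique(labels):
            sub = X[labels == lab]
            d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(axis=2)
            w_pair += d2.sum() / (2 * len(sub))
        assert within_dispersion(X, labels) == pytest.approx(w_pair, rel=1e-12)

    def test_dispersion_nonincreasing_in_k(self):
        rng = np.random.default_rng(28)
        for _ in range(5):
            prof = pd.DataFrame(rng.normal(size=(40, 3)),
                                index=[f"p{i}" for i in range(40)])
            disp = [cluster_profiles(prof, k, seed=4, restarts=10).dispersion
                    for k in range(1, 7)]
            assert all(a >= b - 1e-9 for a, b in zip(disp, disp[1:]))

    def test_planted_blobs_select_k3(self):
        profiles, _ = planted_blobs(np.random.default_rng(29))
        gap = gap_statistic(profiles, k_max=6, B=20, seed=5, restarts=5)
        assert gap.chosen_k == 3

    def test_single_tight_blob_selects_k1(self):
        rng = np.random.default_rng(30)
        prof = pd.DataFrame(rng.normal(0, 1.0, size=(60, 3)),
                            index=[f"p{i}" for i in range(60)])
        gap = gap_statistic(prof, k_max=5, B=20, seed=6, restarts=5)
        assert gap.chosen_k == 1

    def test_gap_deterministic_under_seed(self):
        profiles, _ = planted_blobs(np.random.default_rng(31))
        a = gap_statistic(profiles, k_max=4, B=10, seed=8, restarts=3)
        b = gap_statistic(profiles, k_max=4, B=10, seed=8, restarts=3)
        assert np.array_equal(a.gap, b.gap)
        assert a.chosen_k == b.chosen_k

    def test_k_max_must_be_below_row_count(self):
        prof = pd.DataFrame(np.eye(4), index=list("abcd"))
        with pytest.raises(ConfigError):
            gap_statistic(prof, k_max=4, B=10, seed=0)
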