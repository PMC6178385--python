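"""Subclone detection: NND statistics, Richards fits, k-means stopping."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from gliaclone.model import Cell, Clone
from gliaclone.modularity import (
    ClusterConfig,
    SubcloneKMeans,
    find_subclones,
    fit_richards,
    nnd_clustering_test,
    nnd_distribution,
    richards_cdf,
    robustness_check,
    subclone_category_census,
    subclone_ratio_stats,
)


def spatial_clone(groups, sample_id="s"):
    """Build a clone from [(cell_type, center, n, sigma, rng), ...] specs."""
    cells = []
    i = 0
    for cell_type, center, offsets in groups:
        for off in offsets:
            pos = np.asarray(center, dtype=float) + np.asarray(off, dtype=float)
            cells.append(
                Cell(
                    f"c{i}", "k", cell_type, "IV-V", wall="wall_A",
                    section_index=max(1, int(pos[0] // 50) + 1),
                    coords=tuple(pos),
                )
            )
            i += 1
    return Clone(cells=cells, sample_id=sample_id)


def gaussian_offsets(rng, n, sigma):
    return rng.normal(0.0, sigma, size=(n, 3))


class TestNndDistribution:
    def test_two_points(self):
        nnd, cum = nnd_distribution([[0, 0, 0], [10, 0, 0]])
        assert nnd.tolist() == [10.0, 10.0]
        assert cum[-1] == 1.0

    def test_collinear_three_points(self):
        nnd, _ = nnd_distribution([[0, 0, 0], [10, 0, 0], [30, 0, 0]])
        assert sorted(nnd.tolist()) == [10.0, 10.0, 20.0]

    def test_duplicates_warn(self):
        with pytest.warns(UserWarning, match="duplicate"):
            nnd, _ = nnd_distribution([[0, 0, 0], [0, 0, 0], [5, 0, 0]])
        assert nnd[0] == 0.0

    def test_cumulative_monotone(self, rng):
        pts = rng.random((50, 3)) * 100
        nnd, cum = nnd_distribution(pts)
        assert np.all(np.diff(nnd) >= 0)
        assert np.all(np.diff(cum) > 0)

    def test_poisson_mean_nnd_closed_form(self, rng):
        # homogeneous Poisson: E[NND] -> 0.554 * rho^(-1/3)
        n = 4000
        pts = rng.random((n, 3))
        nnd, _ = nnd_distribution(pts)
        expected = 0.55396 * n ** (-1 / 3)
        assert nnd.mean() == pytest.approx(expected, rel=0.05)


class TestRichardsFit:
    def test_recovers_sigmoid(self, rng):
        x = np.linspace(0, 100, 80)
        y = richards_cdf(x, rate=0.2, midpoint=40.0, q=1.0, nu=1.0)
        fit = fit_richards(x, y)
        assert fit is not None
        assert fit["sse"] < 1e-6
        assert richards_cdf(40.0, **{k: fit[k] for k in ("rate", "midpoint", "q", "nu")}) == pytest.approx(0.5, abs=0.01)


class TestNndClusteringTest:
    def test_two_tight_blobs_reject(self, rng):
        pts = np.vstack(
            [
                rng.normal(0, 5, (20, 3)),
                rng.normal(0, 5, (20, 3)) + [1500, 1500, 500],
            ]
        )
        result = nnd_clustering_test(pts, (2000, 2000, 800), rng=rng)
        assert result["p_value"] < 0.001
        assert result["ks_statistic"] > 0.5

    def test_uniform_sample_usually_accepted(self, rng):
        pts = rng.random((40, 3)) * [2000, 2000, 800]
        result = nnd_clustering_test(pts, (2000, 2000, 800), rng=rng)
        assert result["p_value"] > 0.001

    def test_reference_matches_sample_size(self, rng):
        pts = rng.random((25, 3)) * 100
        result = nnd_clustering_test(pts, (100, 100, 100), rng=rng, fit_curves=False)
        assert len(result["reference_nnd"]) == len(result["empirical_nnd"]) == 25

    def test_degenerate_volume_rejected(self, rng):
        with pytest.raises(ValueError):
            nnd_clustering_test(rng.random((5, 3)), (0, 100, 100), rng=rng)


class TestSubcloneKMeans:
    def test_small_clone_excluded(self, rng):
        clone = spatial_clone(
            [("BG", (0, 0, 0), gaussian_offsets(rng, 5, 10.0))]
        )
        assert find_subclones(clone, ClusterConfig()) is None

    def test_two_separated_triplets(self, rng):
        clone = spatial_clone(
            [
                ("BG", (0, 0, 0), gaussian_offsets(rng, 3, 5.0)),
                ("GLA", (1000, 0, 0), gaussian_offsets(rng, 3, 5.0)),
            ]
        )
        a = find_subclones(clone, ClusterConfig())
        assert a is not None and a.k == 2
        sides = {tuple(sorted(sc["type_counts"])) for sc in a.subclones}
        assert sides == {("BG",), ("GLA",)}

    def test_planted_three_gaussian_subclones(self, rng):
        # 3 subclones: sigma 50 um, centers spaced 600 um, 12 cells each
        centers = [(0, 0, 0), (600, 0, 0), (1200, 0, 0)]
        groups = []
        true = []
        for idx, c in enumerate(centers):
            groups.append(("BG", c, gaussian_offsets(rng, 8, 50.0)))
            groups.append(("GLA", c, gaussian_offsets(rng, 4, 50.0)))
            true.extend([idx] * 12)
        # interleave type groups per center: rebuild in center order
        clone = spatial_clone(groups)
        a = find_subclones(clone, ClusterConfig())
        assert a is not None
        assert a.k == 3
        truth = np.repeat([0, 0, 1, 1, 2, 2], [8, 4, 8, 4, 8, 4])
        assert adjusted_rand_score(truth, a.labels) == 1.0
        for sc in a.subclones:
            assert sc["category"] == "BG+GLA"
            assert sc["n_cells"] == 12

    def test_accounted_variance_nondecreasing_in_k(self, rng):
        X = rng.random((40, 3)) * 500
        est = SubcloneKMeans(variance_threshold=1.0).fit(X)
        path = list(est.accounted_variance_path_.values())
        assert all(b >= a - 1e-9 for a, b in zip(path, path[1:]))

    def test_deterministic_and_order_invariant(self, rng):
        offs = gaussian_offsets(rng, 6, 10.0)
        offs2 = gaussian_offsets(rng, 6, 10.0)
        clone = spatial_clone(
            [("BG", (0, 0, 0), offs), ("GLA", (800, 0, 0), offs2)]
        )
        rev = Clone(cells=clone.cells[::-1], sample_id="s")
        a = find_subclones(clone, ClusterConfig())
        b = find_subclones(clone, ClusterConfig())
        c = find_subclones(rev, ClusterConfig())
        assert np.array_equal(a.labels, b.labels)
        # same partition up to label names under cell-order reversal
        assert adjusted_rand_score(a.labels, c.labels[::-1]) == 1.0

    def test_min_cells_constraint_decrements_k(self, rng):
        # an outlying single cell must not form its own cluster
        clone = spatial_clone(
            [
                ("BG", (0, 0, 0), gaussian_offsets(rng, 7, 10.0)),
                ("GLA", (3000, 0, 0), [(0, 0, 0)]),
            ]
        )
        a = find_subclones(clone, ClusterConfig())
        assert a is not None
        assert a.flagged
        assert min(sc["n_cells"] for sc in a.subclones) >= 3 or a.k == 1


class TestSubcloneRatioStats:
    def test_all_ones_degenerate(self):
        result = subclone_ratio_stats([1.0] * 10)
        assert result["mean_log"] == 0.0
        assert result["degenerate"]

    def test_uniform_log_ratios_have_kurtosis_near_minus_1p2(self, rng):
        logs = rng.uniform(-1, 1, size=4000)
        result = subclone_ratio_stats(np.exp(logs))
        assert result["excess_kurtosis"] == pytest.approx(-1.2, abs=0.1)

    def test_normal_log_ratios_recover_mean(self, rng):
        logs = rng.normal(0.57, 0.3, size=2000)
        result = subclone_ratio_stats(np.exp(logs))
        lo, hi = result["ci_ratio"]
        assert lo <= np.exp(0.57) <= hi
        assert result["wilcoxon_p"] < 1e-6

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            subclone_ratio_stats([1.0, 0.0, 2.0])


class TestCategoryCensusAndRobustness:
    def test_all_mixed_census(self, rng):
        clone = spatial_clone(
            [
                ("BG", (0, 0, 0), gaussian_offsets(rng, 4, 10.0)),
                ("GLA", (0, 0, 0), gaussian_offsets(rng, 2, 10.0)),
            ]
        )
        a = find_subclones(clone, ClusterConfig())
        census = subclone_category_census([a])
        assert census.set_index("category").loc["BG+GLA", "fraction"] == 1.0

    def test_unambiguous_clusters_are_threshold_invariant(self, rng):
        clones = []
        for i in range(4):
            clones.append(
                spatial_clone(
                    [
                        ("BG", (0, 0, 0), gaussian_offsets(rng, 5, 10.0)),
                        ("GLA", (0, 0, 0), gaussian_offsets(rng, 3, 10.0)),
                        ("BG", (1500, 0, 0), gaussian_offsets(rng, 4, 10.0)),
                        ("GLA", (1500, 0, 0), gaussian_offsets(rng, 4, 10.0)),
                    ]
                )
            )
        report = robustness_check(clones, ClusterConfig(), thresholds=(0.90, 0.99))
        assert (report["max_abs_delta_fraction"] == 0).all()
        assert (report["abs_delta_mean_log_ratio"] == 0).all()

    def test_identity_at_default_threshold(self, rng):
        clones = [
            spatial_clone(
                [
                    ("BG", (0, 0, 0), gaussian_offsets(rng, 6, 30.0)),
                    ("GLA", (700, 0, 0), gaussian_offsets(rng, 6, 30.0)),
                ]
            )
        ]
        report = robustness_check(clones, ClusterConfig(), thresholds=(0.95, 0.95))
        assert (report["max_abs_delta_fraction"] == 0).all()
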