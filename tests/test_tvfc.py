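import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tvmanifold as tm
from tvmanifold.containers import MIXED_LABEL, RoiTimeseries, TaskSchedule, WindowSpec
from tvmanifold.tvfc import (
    compute_tvfc,
    count_connections,
    count_windows,
    knn_sets,
    label_windows,
    pairwise_dissimilarity,
    zscore_rows,
)


@pytest.mark.parametrize(
    "n_rois,expected", [(157, 12246), (2, 1), (10, 45), (200, 19900)]
)
def test_connection_count_matches_pair_enumeration(n_rois, expected):
    assert count_connections(n_rois) == expected
    assert count_connections(n_rois) == len(
        [(i, j) for i in range(n_rois) for j in range(i + 1, n_rois)]
    )


def test_connection_count_rejects_single_roi():
    with pytest.raises(ValueError):
        count_connections(1)


@pytest.mark.parametrize(
    "n_acq,w,step,expected",
    [(1017, 30, 1, 988), (30, 30, 7, 1), (100, 20, 5, 17), (1024, 30, 1, 995)],
)
def test_window_count_matches_start_enumeration(n_acq, w, step, expected):
    assert count_windows(n_acq, WindowSpec(w, step)) == expected
    starts = [s for s in range(0, n_acq, step) if s + w <= n_acq]
    assert count_windows(n_acq, WindowSpec(w, step)) == len(starts)


def test_window_longer_than_scan_rejected():
    with pytest.raises(ValueError):
        count_windows(20, WindowSpec(30, 1))


class TestComputeTvfc:
    def test_identical_rois_give_clipped_unit_correlation(self):
        rng = np.random.default_rng(0)
        row = rng.standard_normal(50)
        ts = RoiTimeseries(np.vstack([row, row, rng.standard_normal(50)]), tr=1.5)
        mat = compute_tvfc(ts, WindowSpec(30, 5))
        pair01 = mat.connection_index.index((0, 1))
        assert np.allclose(mat.values[pair01], np.arctanh(1 - 1e-7))

    def test_shape_and_values_match_per_window_pearson(self):
        rng = np.random.default_rng(1)
        ts = RoiTimeseries(rng.standard_normal((3, 40)), tr=1.5)
        spec = WindowSpec(30, 5)
        mat = compute_tvfc(ts, spec)
        assert mat.values.shape == (3, 3)
        for w, s in enumerate(mat.window_starts):
            seg = ts.data[:, s : s + 30]
            for c, (i, j) in enumerate(mat.connection_index):
                r = np.corrcoef(seg[i], seg[j])[0, 1]
                assert mat.values[c, w] == pytest.approx(np.arctanh(r), abs=1e-12)

    def test_independent_noise_concentrates_near_zero(self):
        rng = np.random.default_rng(2)
        ts = RoiTimeseries(rng.standard_normal((4, 600)), tr=1.5)
        mat = compute_tvfc(ts, WindowSpec(200, 100))
        assert np.abs(mat.values).max() < 0.4

    def test_zero_variance_roi_is_named(self):
        data = np.vstack([np.ones(40), np.random.default_rng(0).standard_normal(40)])
        ts = RoiTimeseries(data, tr=1.5, roi_names=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            compute_tvfc(ts, WindowSpec(30, 1))

    def test_dimensions_satisfy_counting_identities(self, default_tvfc):
        n_rois = default_tvfc.meta["n_rois"]
        assert default_tvfc.n_cons == count_connections(n_rois)
        assert default_tvfc.n_wins == count_windows(1024, default_tvfc.spec)


def test_fisher_z_is_monotone_in_r():
    r = np.linspace(-0.99, 0.99, 101)
    z = np.arctanh(r)
    assert (np.diff(z) > 0).all()


class TestZscoreRows:
    def test_hand_computed_row(self):
        mat = tm.TvfcMatrix(
            values=np.array([[1.0, 2.0, 3.0]]),
            connection_index=[(0, 1)],
            window_starts=np.array([0, 1, 2]),
            spec=WindowSpec(2, 1),
            window_labels=["a", "a", "a"],
        )
        out = zscore_rows(mat)
        assert np.allclose(out.values, [[-1.22474487, 0.0, 1.22474487]])

    def test_idempotent_and_standardized(self, small_tvfc):
        once = zscore_rows(small_tvfc)
        twice = zscore_rows(once)
        assert np.abs(once.values.mean(axis=1)).max() < 1e-12
        assert np.abs(once.values.std(axis=1) - 1).max() < 1e-9
        assert np.allclose(once.values, twice.values, atol=1e-10)
        assert once.normalized

    def test_constant_row_is_rejected(self):
        mat = tm.TvfcMatrix(
            values=np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]]),
            connection_index=[(0, 1), (0, 2)],
            window_starts=np.array([0, 1, 2]),
            spec=WindowSpec(2, 1),
            window_labels=["a"] * 3,
        )
        with pytest.raises(ValueError, match=r"\(0, 1\)"):
            zscore_rows(mat)


class TestLabelWindows:
    def test_homogeneous_instruction_and_mixed(self):
        schedule = TaskSchedule([(0, 8, "instruction"), (8, 120, "rest"), (128, 8, "instruction"), (136, 120, "math")])
        labels = label_windows(schedule, 256, WindowSpec(30, 1))
        assert labels[8] == "rest"  # fully inside the rest block
        assert labels[0] == MIXED_LABEL  # overlaps the instruction period
        assert labels[98] == "rest" and labels[99] == MIXED_LABEL

    def test_block_of_120_acquisitions_gives_91_task_windows(self, default_tvfc):
        labels = np.array(default_tvfc.window_labels)
        for task in ("rest", "memory", "math", "attention"):
            assert (labels == task).sum() == 182  # 2 blocks x 91

    def test_gap_in_schedule_rejected(self):
        schedule = TaskSchedule([(0, 50, "rest")])
        with pytest.raises(ValueError):
            label_windows(schedule, 100, WindowSpec(30, 1))


class TestDissimilarity:
    def test_euclidean_3_4_5(self):
        ds = pairwise_dissimilarity(np.array([[0.0, 0.0], [3.0, 4.0]]), "euclidean")
        assert ds.values[0, 1] == pytest.approx(5.0)

    def test_identical_samples_zero_under_all_metrics(self):
        x = np.vstack([[1.0, 2.0, 3.0]] * 2)
        for metric in ("euclidean", "correlation", "cosine"):
            assert pairwise_dissimilarity(x, metric).values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_pair_has_correlation_distance_two(self):
        x = np.array([[1.0, 2.0, 3.0], [-1.0, -2.0, -3.0]])
        assert pairwise_dissimilarity(x, "correlation").values[0, 1] == pytest.approx(2.0)

    def test_degenerate_sample_rejected_per_metric(self):
        x = np.array([[1.0, 1.0], [0.0, 1.0]])
        with pytest.raises(ValueError):
            pairwise_dissimilarity(x, "correlation")
        with pytest.raises(ValueError):
            pairwise_dissimilarity(np.array([[0.0, 0.0], [1.0, 1.0]]), "cosine")


class TestKnn:
    def test_collinear_points(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        ds = pairwise_dissimilarity(pts, "euclidean")
        nbrs = knn_sets(ds, 1)
        assert nbrs.ravel().tolist() == [1, 0, 1]

    def test_k_equals_n_minus_one_lists_everyone(self, gaussian_cloud):
        ds = pairwise_dissimilarity(gaussian_cloud[:10], "euclidean")
        nbrs = knn_sets(ds, 9)
        for i in range(10):
            assert sorted(nbrs[i]) == sorted(set(range(10)) - {i})

    def test_ties_broken_by_lower_index(self):
        # three points equidistant from the origin point
        vals = np.array(
            [[0, 1, 1, 1], [1, 0, 2, 2], [1, 2, 0, 2], [1, 2, 2, 0]], dtype=float
        )
        ds = tm.DissimilarityMatrix(vals, "euclidean")
        assert knn_sets(ds, 2)[0].tolist() == [1, 2]

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2**31 - 1), st.integers(5, 40), st.integers(1, 4))
    def test_agrees_with_brute_force_full_sort(self, seed, n, k):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((n, 3))
        ds = pairwise_dissimilarity(x, "euclidean")
        nbrs = knn_sets(ds, min(k, n - 1))
        d = ds.values.copy()
        np.fill_diagonal(d, np.inf)
        for i in range(n):
            order = sorted(range(n), key=lambda j: (d[i, j], j))
            assert nbrs[i].tolist() == order[: min(k, n - 1)]
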