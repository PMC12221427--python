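"""Confusion-matrix statistics, sampling, and the Munich validation sample."""

import numpy as np
import pandas as pd
import pytest

import urbanfuse as uf
from urbanfuse.errors import MatrixError, SamplingError


class TestMunichSample:
    def test_structure(self):
        cm = uf.munich_confusion_matrix()
        assert cm.n == 530
        assert cm.row_totals.tolist() == [67, 16, 65, 48, 13, 13, 3, 12, 121, 59,
                                          12, 101]

    def test_published_statistics_reproduced(self):
        rep = uf.compute_report(uf.munich_confusion_matrix())
        r = rep.rounded()
        assert r["overall_accuracy"] == 0.82
        assert r["kappa"] == 0.79
        ua = r["user_accuracy"]
        assert ua["Sealed"] == 0.81 and ua["Bushes and Shrubs"] == 0.44
        assert ua["Grassland"] == 0.86 and ua["Crops"] == 0.94
        assert ua["Wetland"] == 1.0 and ua["Broadleaved deciduous trees"] == 0.83
        assert ua["Roads and Highways"] == 0.97 and ua["Buildings"] == 0.78
        pa = r["producer_accuracy"]
        assert pa["Crops"] == 1.0 and pa["Buildings"] == 0.95 and pa["Wetland"] == 0.3

    def test_row_column_duality(self):
        cm = uf.munich_confusion_matrix()
        rep = uf.compute_report(cm)
        rep_t = uf.compute_report(cm.transpose())
        pd.testing.assert_series_equal(rep.user_accuracy, rep_t.producer_accuracy)
        pd.testing.assert_series_equal(rep.producer_accuracy, rep_t.user_accuracy)
        assert rep.overall_accuracy == rep_t.overall_accuracy
        assert rep.kappa == pytest.approx(rep_t.kappa)


class TestStatistics:
    def test_perfect_agreement(self):
        cm = uf.matrix_from_counts(np.eye(12, dtype=int) * 10)
        rep = uf.compute_report(cm)
        assert rep.overall_accuracy == 1.0 and rep.kappa == 1.0
        assert (rep.user_accuracy == 1.0).all() and (rep.producer_accuracy == 1.0).all()

    def test_hand_worked_two_class_example(self):
        cm = uf.matrix_from_counts(np.array([[40, 10], [20, 30]]), labels=["A", "B"])
        rep = uf.compute_report(cm)
        assert rep.overall_accuracy == pytest.approx(0.70)
        assert rep.chance_agreement == pytest.approx(0.50)
        assert rep.kappa == pytest.approx(0.40)

    def test_independence_gives_zero_kappa(self):
        # n_ij = n_i+ * n_+j / N exactly
        row = np.array([20, 30, 50])
        col = np.array([10, 40, 50])
        counts = np.outer(row, col) // 100
        assert (np.outer(row, col) % 100 == 0).all()
        rep = uf.compute_report(uf.matrix_from_counts(counts))
        assert abs(rep.kappa) < 1e-12

    def test_kappa_bounded_by_overall_accuracy(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            counts = rng.integers(0, 30, size=(5, 5))
            counts[np.diag_indices(5)] += 1
            rep = uf.compute_report(uf.matrix_from_counts(counts))
            if rep.chance_agreement > 0:
                assert rep.kappa <= rep.overall_accuracy + 1e-12

    def test_simultaneous_permutation_invariance(self):
        cm = uf.munich_confusion_matrix()
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(cm.labels))
        permuted = uf.ConfusionMatrix([cm.labels[i] for i in perm],
                                      cm.counts[np.ix_(perm, perm)])
        rep, rep_p = uf.compute_report(cm), uf.compute_report(permuted)
        assert rep.overall_accuracy == pytest.approx(rep_p.overall_accuracy)
        assert rep.kappa == pytest.approx(rep_p.kappa)
        for label in cm.labels:
            assert rep.user_accuracy[label] == pytest.approx(rep_p.user_accuracy[label],
                                                             nan_ok=True)

    def test_degenerate_and_invalid_matrices(self):
        with pytest.raises(MatrixError):
            uf.compute_report(uf.matrix_from_counts(np.zeros((2, 2), dtype=int)))
        with pytest.raises(MatrixError):
            uf.matrix_from_counts(np.array([[1, -1], [0, 2]]))
        rep = uf.compute_report(uf.matrix_from_counts(np.array([[5]])))
        assert rep.overall_accuracy == 1.0 and rep.kappa is None  # p_e = 1

    def test_single_class_matrix(self):
        rep = uf.compute_report(uf.matrix_from_counts(np.array([[5]]), labels=["A"]))
        assert rep.overall_accuracy == 1.0


class TestBuildMatrix:
    def test_diagonal_and_off_diagonal(self):
        df = pd.DataFrame({"x": np.nan, "y": np.nan,
                           "map_class": ["A", "A", "A"],
                           "ref_class": ["A", "A", "A"]})
        cm = uf.build_matrix(uf.ValidationPoints(df), ["A", "B"])
        assert cm.counts.tolist() == [[3, 0], [0, 0]]
        df2 = pd.DataFrame({"x": np.nan, "y": np.nan,
                            "map_class": ["A", "B"], "ref_class": ["B", "A"]})
        cm2 = uf.build_matrix(uf.ValidationPoints(df2), ["A", "B"])
        assert cm2.counts.tolist() == [[0, 1], [1, 0]]

    def test_unknown_label_rejected(self):
        df = pd.DataFrame({"x": [np.nan], "y": [np.nan],
                           "map_class": ["A"], "ref_class": ["Z"]})
        with pytest.raises(MatrixError, match="Z"):
            uf.build_matrix(uf.ValidationPoints(df), ["A", "B"])

    def test_recovers_munich_row_totals_from_pairs(self):
        cm = uf.munich_confusion_matrix()
        points = uf.pairs_from_matrix(cm, seed=0)
        rebuilt = uf.build_matrix(points, cm.labels)
        assert rebuilt.row_totals.tolist() == [67, 16, 65, 48, 13, 13, 3, 12, 121,
                                               59, 12, 101]
        assert rebuilt.n == 530


class TestStratifiedSample:
    def one_class_raster(self):
        grid = uf.GridSpec(n_rows=10, n_cols=10)
        return uf.CategoricalRaster(grid, np.full((10, 10), 6, dtype=np.uint8))

    def test_single_stratum(self):
        pts = uf.stratified_sample(self.one_class_raster(), {6: 5}, seed=1)
        assert len(pts) == 5
        assert (pts.table.map_class == 6).all()
        assert len(set(zip(pts.table.x, pts.table.y))) == 5  # distinct cells

    def test_points_at_cell_centres_inside_grid(self):
        r = self.one_class_raster()
        pts = uf.stratified_sample(r, {6: 10}, seed=2)
        pts.check_inside(r.grid)
        for x in pts.table.x:
            assert (x - r.grid.origin_x - 5.0) % 10.0 == 0.0

    def test_seed_reproducibility(self):
        r = self.one_class_raster()
        a = uf.stratified_sample(r, {6: 20}, seed=42)
        b = uf.stratified_sample(r, {6: 20}, seed=42)
        pd.testing.assert_frame_equal(a.table, b.table)
        c = uf.stratified_sample(r, {6: 20}, seed=43)
        assert not a.table.equals(c.table)

    def test_oversized_request_names_class(self):
        with pytest.raises(SamplingError, match="101"):
            uf.stratified_sample(self.one_class_raster(), {6: 101}, seed=0)

    def test_respects_strata_on_multiclass_map(self, small_scene):
        expected = small_scene.expected
        available = {k: v for k, v in expected.tally().items() if k != uf.NODATA}
        request = {k: min(5, v) for k, v in available.items()}
        pts = uf.stratified_sample(expected, request, seed=7)
        got = pts.table.map_class.value_counts().to_dict()
        assert got == request

    def test_proportional_allocation_floor_and_cap(self, small_scene):
        alloc = uf.proportional_allocation(small_scene.expected, total=200, floor=3)
        tally = small_scene.expected.tally()
        for cid, n in alloc.items():
            assert 1 <= n <= tally[cid]
            assert n >= min(3, tally[cid])


class TestPairsRoundTrip:
    def test_matrix_pairs_matrix_identity_random(self):
        rng = np.random.default_rng(8)
        for trial in range(100):
            k = int(rng.integers(2, 7))
            counts = rng.integers(0, 12, size=(k, k))
            cm = uf.matrix_from_counts(counts, labels=list(range(k)))
            back = uf.build_matrix(uf.pairs_from_matrix(cm, seed=trial), cm.labels)
            assert (back.counts == cm.counts).all()

    def test_diagonal_matrix_pairs_all_agree(self):
        cm = uf.matrix_from_counts(np.diag([4, 5, 6]), labels=["a", "b", "c"])
        pts = uf.pairs_from_matrix(cm, seed=1)
        assert (pts.table.map_class == pts.table.ref_class).all()
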