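"""Voronoï tessellation, hot spots, quadrat counts and dispersion indices."""

import numpy as np
import pytest
import shapely

from histohet import (
    PointPattern,
    Region,
    detect_hot_spots,
    fisher_index,
    generate_clustered_pattern,
    generate_csr_pattern,
    normalized_density_variance,
    quadrat_counts,
    voronoi_area_variance,
    voronoi_tessellation,
)
from histohet.spatial import QuadratCounts


class TestVoronoi:
    def test_cell_areas_partition_the_roi(self, csr_pattern):
        tess = voronoi_tessellation(csr_pattern)
        total = csr_pattern.region.roi_area_um2
        assert tess.areas.sum() == pytest.approx(total, rel=1e-3)

    def test_four_quadrant_generators_give_equal_quarter_cells(self):
        region = Region(100, 100)
        pts = [(25.0, 25.0), (75.0, 25.0), (25.0, 75.0), (75.0, 75.0)]
        tess = voronoi_tessellation(PointPattern(pts, region))
        np.testing.assert_allclose(tess.areas, 2500.0, rtol=1e-9)

    def test_each_cell_contains_its_generator(self, csr_pattern):
        tess = voronoi_tessellation(csr_pattern)
        for p, cell in zip(tess.points, tess.cells):
            assert cell.buffer(1e-6).covers(shapely.Point(*p))

    def test_probe_points_assigned_to_nearest_generator(self, rng):
        # Monte-Carlo nearest-neighbour oracle on a 50-point pattern
        region = Region(1000, 1000)
        pat = generate_csr_pattern(50.0, region, seed=21)
        tess = voronoi_tessellation(pat)
        probes = rng.uniform(0, 1000, size=(2000, 2))
        from scipy.spatial import cKDTree

        nearest = cKDTree(tess.points).query(probes)[1]
        for i in range(len(tess.points)):
            sel = nearest == i
            if sel.any():
                inside = shapely.contains_xy(
                    tess.cells[i].buffer(1e-6), probes[sel, 0], probes[sel, 1]
                )
                assert inside.all()

    def test_too_few_or_collinear_points_rejected(self):
        region = Region(100, 100)
        with pytest.raises(ValueError):
            voronoi_tessellation(PointPattern([(1.0, 1.0), (2.0, 2.0)], region))
        with pytest.raises(ValueError):
            voronoi_tessellation(
                PointPattern([(10.0, 10.0), (20.0, 20.0), (30.0, 30.0)], region)
            )

    def test_translation_invariance_of_cell_area_variance(self):
        base = Region(500, 500)
        pat = generate_csr_pattern(100.0, base, seed=2)
        v1 = voronoi_area_variance(voronoi_tessellation(pat), normalized=True)
        from shapely.geometry import box

        shifted = Region(800, 800, box(200, 200, 700, 700))
        pat2 = PointPattern(pat.points + 200.0, shifted)
        v2 = voronoi_area_variance(voronoi_tessellation(pat2), normalized=True)
        assert v1 == pytest.approx(v2, rel=1e-9)


class TestVoronoiVariance:
    def test_hand_computed_example(self):
        # cells of areas {1, 2, 3} mm²: sample variance 1 mm⁴, normalized 1/4
        from histohet.spatial import VoronoiTessellation

        areas = np.array([1e6, 2e6, 3e6])  # µm²
        tess = VoronoiTessellation(np.zeros((3, 2)), [None] * 3, areas, None, [])
        assert voronoi_area_variance(tess) == pytest.approx(1e12)
        assert voronoi_area_variance(tess, normalized=True) == pytest.approx(0.25)

    def test_regular_lattice_has_vanishing_normalized_variance(self):
        region = Region(1000, 1000)
        g = np.arange(50, 1000, 100, dtype=float)
        xs, ys = np.meshgrid(g, g)
        pat = PointPattern(np.column_stack([xs.ravel(), ys.ravel()]), region)
        v = voronoi_area_variance(voronoi_tessellation(pat), normalized=True)
        assert v < 1e-6

    def test_single_cell_rejected(self):
        from histohet.spatial import VoronoiTessellation

        tess = VoronoiTessellation(np.zeros((1, 2)), [None], np.array([5.0]), None, [])
        with pytest.raises(ValueError):
            voronoi_area_variance(tess)

    def test_clustered_exceeds_csr_in_paired_replicates(self, square_mm):
        from histohet import ClusterSpec

        spec = ClusterSpec(20.0, 10.0, 50.0)
        wins = 0
        for s in range(100):
            csr = generate_csr_pattern(200.0, square_mm, seed=s)
            clu = generate_clustered_pattern(spec, square_mm, seed=50_000 + s)
            if len(clu) < 3:
                continue
            v_csr = voronoi_area_variance(voronoi_tessellation(csr), normalized=True)
            v_clu = voronoi_area_variance(voronoi_tessellation(clu), normalized=True)
            wins += v_clu > v_csr
        assert wins >= 95


class TestHotSpots:
    def test_zero_percentile_flags_nothing(self, csr_pattern):
        tess = voronoi_tessellation(csr_pattern)
        assert detect_hot_spots(tess, area_percentile=0.0, min_cluster=1) == []

    def test_single_tight_cluster_detected_as_one_hot_spot(self):
        region = Region(1000, 1000)
        bg = generate_csr_pattern(200.0, region, seed=2003)
        rng = np.random.default_rng(3)
        cluster = rng.normal(0, 15, size=(20, 2)) + [500.0, 500.0]
        pts = np.vstack([bg.points, cluster])
        pat = PointPattern(np.clip(pts, 1, 999), region)
        spots = detect_hot_spots(voronoi_tessellation(pat), 10.0, 5)
        assert len(spots) == 1
        cluster_idx = set(range(len(bg.points), len(pts)))
        assert len(cluster_idx & set(spots[0].cell_indices)) >= 15

    def test_false_positive_rate_drops_with_min_cluster(self, square_mm):
        # under CSR, chains of ≥7 small adjacent cells are much rarer than
        # chains of ≥5 — at min_cluster=5 spurious chains are common, a
        # documented property of the 10th-percentile flagging rule
        hits5 = hits7 = 0
        for s in range(100):
            tess = voronoi_tessellation(generate_csr_pattern(200.0, square_mm, seed=7000 + s))
            hits5 += bool(detect_hot_spots(tess, 10.0, 5))
            hits7 += bool(detect_hot_spots(tess, 10.0, 7))
        assert hits5 >= 10  # spurious chains of 5 are not rare
        assert hits7 <= 10  # chains of 7 are
        assert hits7 < hits5


class TestQuadratCounts:
    def test_counts_conserve_points_on_exact_tiling(self, csr_pattern):
        qc = quadrat_counts(csr_pattern, 200.0)
        assert qc.counts_all.sum() == len(csr_pattern)
        assert qc.counts.sum() == len(csr_pattern)  # full-rect ROI, exact tiling

    def test_counts_match_brute_force_binning_oracle(self, square_mm):
        for s in range(20):
            pat = generate_csr_pattern(150.0, square_mm, seed=s)
            qc = quadrat_counts(pat, 250.0)
            oracle = np.zeros((4, 4))
            for x, y in pat.points:
                oracle[min(int(y // 250), 3), min(int(x // 250), 3)] += 1
            np.testing.assert_array_equal(qc.counts_all, oracle)

    def test_empty_pattern_gives_zero_counts(self, square_mm):
        pat = generate_csr_pattern(0.0, square_mm, seed=1)
        qc = quadrat_counts(pat, 200.0)
        assert qc.counts_all.sum() == 0

    def test_too_few_quadrats_rejected(self):
        pat = generate_csr_pattern(100.0, Region(300, 300), seed=1)
        with pytest.raises(ValueError):
            quadrat_counts(pat, 300.0)

    def test_partial_quadrats_filtered_at_half_overlap(self):
        from shapely.geometry import box

        # 1000×450 ROI with 200 µm quadrats: bottom row has 50/200 = 25%
        # overlap and must be dropped
        region = Region(1000, 450, box(0, 0, 1000, 450))
        pat = generate_csr_pattern(100.0, region, seed=4)
        qc = quadrat_counts(pat, 200.0)
        assert qc.shape == (3, 5)
        assert qc.n_retained == 10


class TestDispersionIndices:
    def _qc(self, counts, areas=None):
        counts = np.asarray(counts, float)
        areas = np.full(counts.size, 1e6) if areas is None else np.asarray(areas, float)
        return QuadratCounts(1000.0, (0, 0), (1, counts.size), counts, areas, counts.reshape(1, -1), int(counts.sum()))

    def test_fisher_constant_counts_zero(self):
        assert fisher_index(self._qc([4, 4, 4, 4])) == 0.0

    def test_fisher_hand_example(self):
        # counts {1,2,3}: mean 2, sample variance 1 → 0.5
        assert fisher_index(self._qc([1, 2, 3])) == pytest.approx(0.5)

    def test_fisher_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            fisher_index(self._qc([0, 0, 0]))

    def test_ndv_hand_example(self):
        # densities {1, 3} per mm²: mean 2, sample variance 2 → 0.5
        assert normalized_density_variance(self._qc([1, 3])) == pytest.approx(0.5)

    def test_ndv_constant_counts_zero(self):
        assert normalized_density_variance(self._qc([5, 5, 5])) == 0.0

    def test_ndv_scale_invariance(self, square_mm):
        pat = generate_csr_pattern(400.0, square_mm, seed=6)
        qc = quadrat_counts(pat, 200.0)
        scaled = self._qc(qc.counts * 4, qc.overlap_um2)
        assert normalized_density_variance(scaled) == pytest.approx(
            normalized_density_variance(qc), rel=1e-9
        )

    def test_csr_fisher_calibration(self, square_mm):
        # mean VMR over 200 CSR patterns at ≥20 expected counts/quadrat
        fis = [
            fisher_index(quadrat_counts(generate_csr_pattern(600.0, square_mm, seed=s), 200.0))
            for s in range(200)
        ]
        assert 0.9 <= np.mean(fis) <= 1.1
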