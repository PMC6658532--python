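"""Voronoi tessellation, Monte-Carlo threshold, segmentation and particle analysis."""

import numpy as np
import pytest
from shapely.geometry import Polygon, box

from junctiontrack.io_tables import Rect
from junctiontrack.maps import PixelMap, binarize, dilate_binary, render_histogram
from junctiontrack.clustering import (
    candidate_localizations,
    cluster_summary,
    mc_density_threshold,
    particle_analysis,
    percent_change,
    segment_clusters,
    voronoi_field,
)
from junctiontrack.simulate import ClusterSimConfig, simulate_cluster_field


class TestVoronoiField:
    def test_quadrant_points_give_equal_areas(self, roi_4um):
        pts = np.array([[1000, 1000], [3000, 1000], [1000, 3000], [3000, 3000]], dtype=float)
        vf = voronoi_field(pts, roi_4um)
        np.testing.assert_allclose(vf.areas, roi_4um.area_nm2 / 4, rtol=1e-9)

    def test_area_conservation_on_random_fields(self, rng, roi_4um):
        for _ in range(20):
            pts = rng.uniform(0, 4000, (rng.integers(10, 300), 2))
            vf = voronoi_field(pts, roi_4um)
            assert vf.areas.sum() == pytest.approx(roi_4um.area_nm2, rel=1e-6)

    def test_matches_halfplane_intersection_oracle(self, rng, roi_4um):
        """Brute force: each cell is the ROI box cut by bisector half-planes."""
        pts = rng.uniform(200, 3800, (12, 2))
        vf = voronoi_field(pts, roi_4um)
        big = 1e6
        for i in range(12):
            cell = box(0, 0, 4000, 4000)
            for j in range(12):
                if j == i:
                    continue
                mid = (pts[i] + pts[j]) / 2
                d = pts[j] - pts[i]
                d = d / np.hypot(*d)
                perp = np.array([-d[1], d[0]])
                # half-plane containing pts[i]: rectangle behind the bisector
                corners = [
                    mid + perp * big,
                    mid - perp * big,
                    mid - perp * big - d * big,
                    mid + perp * big - d * big,
                ]
                cell = cell.intersection(Polygon(corners))
            assert vf.areas[i] == pytest.approx(cell.area, rel=1e-9)

    def test_duplicate_points_jittered(self, roi_4um):
        pts = np.array([[1000.0, 1000.0], [1000.0, 1000.0], [3000.0, 1000.0], [2000.0, 3000.0]])
        vf = voronoi_field(pts, roi_4um)
        assert vf.n_jittered >= 2
        assert np.isfinite(vf.areas).all()

    def test_collinear_points_degenerate(self, roi_4um):
        pts = np.column_stack([np.linspace(100, 3900, 6), np.full(6, 2000.0)])
        with pytest.raises(ValueError):
            voronoi_field(pts, roi_4um)

    def test_too_few_points(self, roi_4um):
        with pytest.raises(ValueError, match="at least 4"):
            voronoi_field(np.zeros((3, 2)), roi_4um)


class TestMCThreshold:
    def test_fixed_seed_reproducible(self, roi_4um):
        table, _ = simulate_cluster_field(ClusterSimConfig(seed=3))
        vf = voronoi_field(table)
        a = mc_density_threshold(vf, iterations=20, seed=7)
        b = mc_density_threshold(vf, iterations=20, seed=7)
        assert a.threshold == b.threshold

    def test_csr_input_reports_no_clustering(self, roi_4um):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            pts = np.column_stack([r.uniform(0, 4000, 800), r.uniform(0, 4000, 800)])
            vf = voronoi_field(pts, roi_4um)
            res = mc_density_threshold(vf, iterations=50, seed=seed + 900)
            hits += res.status == "no clustering detected"
        assert hits >= 9

    def test_clustered_field_detected_and_separates(self):
        table, truth = simulate_cluster_field(ClusterSimConfig(seed=0))
        vf = voronoi_field(table)
        res = mc_density_threshold(vf, iterations=100, seed=100)
        assert res.status == "ok"
        cand = candidate_localizations(vf, res.threshold)
        planted = truth.cluster_id >= 0
        assert cand[~planted].mean() < 0.10  # ≥ 90% of background excluded
        assert cand[planted].mean() > 0.5  # majority of planted localizations retained
        assert cand[planted].mean() > 5 * cand[~planted].mean()


class TestSegmentation:
    def test_empty_candidate_set_gives_zero_clusters(self, roi_4um, rng):
        pts = rng.uniform(0, 4000, (50, 2))
        vf = voronoi_field(pts, roi_4um)
        cs = segment_clusters(vf, threshold=1.0)  # nothing below 1 nm²
        assert len(cs) == 0

    def test_nonfinite_threshold_rejected(self, roi_4um, rng):
        vf = voronoi_field(rng.uniform(0, 4000, (50, 2)), roi_4um)
        with pytest.raises(ValueError):
            segment_clusters(vf, threshold=float("nan"))

    def test_two_separated_gaussian_clusters(self, roi_4um):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((80, 2)) * 50 + [1000, 1000]
        b = rng.standard_normal((80, 2)) * 50 + [3000, 3000]
        bg = np.column_stack([rng.uniform(0, 4000, 60), rng.uniform(0, 4000, 60)])
        pts = np.clip(np.vstack([a, b, bg]), 1.0, 3999.0)
        vf = voronoi_field(pts, roi_4um)
        thr = mc_density_threshold(vf, iterations=50, seed=4)
        cs = segment_clusters(vf, thr.threshold)
        assert len(cs) == 2
        labels_a = cs.assignment[:80]
        labels_b = cs.assignment[80:160]
        majorities = []
        # ≥95% of the assigned localizations of each planted cluster share one segment
        for lab in (labels_a, labels_b):
            vals, counts = np.unique(lab[lab > 0], return_counts=True)
            assert counts.max() / counts.sum() >= 0.95
            assert counts.sum() >= 40  # the cluster core is assigned
            majorities.append(vals[np.argmax(counts)])
        assert majorities[0] != majorities[1]

    def test_benchmark_17_cluster_recovery_single_seed(self):
        table, _ = simulate_cluster_field(ClusterSimConfig(seed=2))
        vf = voronoi_field(table)
        thr = mc_density_threshold(vf, iterations=100, seed=202)
        cs = segment_clusters(vf, thr.threshold)
        assert 13 <= len(cs) <= 21

    def test_400nm_fields_oversegment(self):
        """Detected count ≥ planted for 400-nm / 100-localization discs."""
        cfg = ClusterSimConfig(disc_diameter=400.0, locs_per_cluster=100, seed=0)
        table, _ = simulate_cluster_field(cfg)
        vf = voronoi_field(table)
        thr = mc_density_threshold(vf, iterations=100, seed=50)
        cs = segment_clusters(vf, thr.threshold)
        assert len(cs) >= 17


class TestParticleAnalysis:
    def test_disc_of_set_pixels(self, roi_4um):
        grid = np.zeros((400, 400), dtype=np.uint8)
        yy, xx = np.mgrid[0:400, 0:400]
        grid[(xx - 200) ** 2 + (yy - 200) ** 2 <= 25] = 1
        cs = particle_analysis(PixelMap(grid, 10.0, roi_4um))
        assert len(cs) == 1
        assert cs.clusters["n_pixels"].iloc[0] == 81

    def test_diagonal_touch_is_one_cluster_under_8_connectivity(self, roi_4um):
        grid = np.zeros((400, 400), dtype=np.uint8)
        grid[10:14, 10:14] = 1
        grid[14:18, 14:18] = 1
        cs = particle_analysis(PixelMap(grid, 10.0, roi_4um), min_pixels=10)
        assert len(cs) == 1

    def test_min_pixel_filter(self, roi_4um):
        grid = np.zeros((400, 400), dtype=np.uint8)
        grid[0:3, 0:3] = 1  # 9 px < 10
        grid[100:104, 100:104] = 1  # 16 px
        cs = particle_analysis(PixelMap(grid, 10.0, roi_4um))
        assert len(cs) == 1

    def test_cross_method_agreement_on_separated_planted_field(self):
        """Voronoi segmentation and particle analysis agree within ±2 clusters."""
        rng = np.random.default_rng(5)
        centers = [(x, y) for x in (700, 2000, 3300) for y in (700, 2000, 3300)]
        pts = []
        for cx, cy in centers:
            theta = rng.uniform(0, 2 * np.pi, 40)
            r = 100 * np.sqrt(rng.random(40))
            pts.append(np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)]))
        xy = np.vstack(pts)
        roi = Rect(0, 0, 4000, 4000)
        vf = voronoi_field(xy, roi)
        thr = mc_density_threshold(vf, iterations=50, seed=6)
        n_voronoi = len(segment_clusters(vf, thr.threshold))

        import pandas as pd

        from junctiontrack.io_tables import LocalizationTable

        table = LocalizationTable(
            pd.DataFrame({"frame": np.arange(len(xy)), "x": xy[:, 0], "y": xy[:, 1]}), roi=roi
        )
        binary = dilate_binary(binarize(render_histogram(table, 10.0)), 3)
        n_particle = len(particle_analysis(binary, table=table))
        assert n_voronoi == pytest.approx(9, abs=1)
        assert abs(n_voronoi - n_particle) <= 2


class TestSummary:
    def test_equivalent_diameter_of_200nm_disc(self, roi_4um):
        grid = np.zeros((400, 400), dtype=np.uint8)
        yy, xx = np.mgrid[0:400, 0:400]
        grid[(xx - 200) ** 2 + (yy - 200) ** 2 <= 100] = 1  # radius 10 px = 100 nm
        cs = particle_analysis(PixelMap(grid, 10.0, roi_4um))
        assert cs.clusters["equiv_diameter_nm"].iloc[0] == pytest.approx(200.0, abs=10.0)

    def test_summary_fields(self, roi_4um):
        grid = np.zeros((400, 400), dtype=np.uint8)
        grid[10:20, 10:20] = 1
        grid[200:212, 200:212] = 1
        cs = particle_analysis(PixelMap(grid, 10.0, roi_4um))
        s = cluster_summary(cs)
        assert s["n_clusters"] == 2
        assert s["clusters_per_um2"] == pytest.approx(2 / 16)
        assert s["fractional_area"] == pytest.approx((100 + 144) * 1e-4 / 16)

    @pytest.mark.parametrize("a,b,expected", [(0.031, 0.024, 23), (0.059, 0.041, 31)])
    def test_percent_reduction_arithmetic(self, a, b, expected):
        assert percent_change(a, b) == expected


class TestNullCalibration:
    def test_csr_fields_yield_at_most_one_cluster(self, roi_4um):
        counts = []
        for seed in range(6):
            r = np.random.default_rng(seed + 40)
            pts = np.column_stack([r.uniform(0, 4000, 700), r.uniform(0, 4000, 700)])
            vf = voronoi_field(pts, roi_4um)
            res = mc_density_threshold(vf, iterations=50, seed=seed)
            if res.status != "ok":
                counts.append(0)
            else:
                counts.append(len(segment_clusters(vf, res.threshold)))
        assert np.median(counts) <= 1

    def test_planted_count_sweep_slope_near_unity(self):
        planted = [5, 12, 25]
        detected = []
        for n, seed in zip(planted, (60, 61, 62)):
            cfg = ClusterSimConfig(n_clusters=n, seed=seed)
            table, _ = simulate_cluster_field(cfg)
            vf = voronoi_field(table)
            thr = mc_density_threshold(vf, iterations=40, seed=seed + 7)
            detected.append(len(segment_clusters(vf, thr.threshold)))
        slope = np.polyfit(planted, detected, 1)[0]
        assert 0.9 <= slope <= 1.1
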