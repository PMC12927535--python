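"""Fidelity, coverage, ROI retention, skeletons, viability, circularity."""
import math

import numpy as np
import pytest

import liftqc as lq
from liftqc.errors import ValidationError


class TestFidelity:
    def test_noiseless_print_is_perfect(self, noiseless_print):
        _, record = noiseless_print
        rep = lq.fidelity_from_record(record)
        assert rep.fidelity_percent == pytest.approx(100.0, abs=0.5)
        assert rep.mean_abs_deviation == pytest.approx(0.0, abs=2.0)

    def test_single_pair_deviation_formula(self):
        design = lq.PatternDesign(((0.0, 0.0), (500.0, 0.0)), nominal_spacing=500.0)
        rep = lq.fidelity({0: (0.0, 0.0), 1: (520.0, 0.0)}, design)
        assert rep.mean_abs_deviation == pytest.approx(20.0)
        assert rep.fidelity_percent == pytest.approx(96.0)

    def test_translation_rotation_invariance(self, grid_design):
        rng = np.random.default_rng(3)
        measured = {
            i: (x + rng.normal(0, 5), y + rng.normal(0, 5))
            for i, (x, y) in enumerate(grid_design.target_positions)
        }
        base = lq.fidelity(measured, grid_design)
        theta = 0.7
        R = np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])
        moved = {i: tuple(R @ np.asarray(p) + [1234.0, -77.0]) for i, p in measured.items()}
        rep = lq.fidelity(moved, grid_design)
        assert rep.fidelity_percent == pytest.approx(base.fidelity_percent, abs=1e-6)

    def test_small_jitter_keeps_high_fidelity(self, grid_design):
        ok = 0
        for seed in range(30):
            _, rec = lq.generate_print(
                lq.SynthPrintParams(
                    design=grid_design, placement_jitter_sd=5.0, pixel_size=2.0,
                    seed=500 + seed,
                )
            )
            ok += lq.fidelity_from_record(rec).fidelity_percent > 95.0
        assert ok >= 29  # ≥95% of seeds

    def test_too_few_matches_is_error(self, grid_design):
        with pytest.raises(ValidationError):
            lq.fidelity({0: (0.0, 0.0)}, grid_design)


class TestCoverage:
    def test_empty_print_covers_nothing(self):
        assert lq.coverage_fraction([], (0, 0, 100, 100)) == 0.0

    def test_fully_covered_roi(self):
        big = lq.observation_from_geometry(1, (50.0, 50.0), math.pi * 200**2, 2 * math.pi * 200)
        assert lq.coverage_fraction([big], (0, 0, 100, 100)) == pytest.approx(1.0)

    def test_additive_over_disjoint_droplets(self):
        mk = lambda i, x: lq.observation_from_geometry(
            i, (x, 50.0), math.pi * 10**2, 2 * math.pi * 10
        )
        one = lq.coverage_fraction([mk(1, 30.0)], (0, 0, 200, 100))
        two = lq.coverage_fraction([mk(1, 30.0), mk(2, 100.0)], (0, 0, 200, 100))
        assert two == pytest.approx(2 * one, rel=1e-6)

    def test_droplet_count_scales_coverage(self):
        # same droplet size: 381 vs 154 droplets → coverage ratio 381/154
        def field(n):
            side = math.ceil(math.sqrt(n))
            return [
                lq.observation_from_geometry(
                    k + 1, (50 + 100.0 * (k % side), 50 + 100.0 * (k // side)),
                    math.pi * 15**2, 2 * math.pi * 15,
                )
                for k in range(n)
            ]

        roi = (0, 0, 2000, 2000)
        ratio = lq.coverage_fraction(field(381), roi) / lq.coverage_fraction(field(154), roi)
        assert ratio == pytest.approx(381 / 154, rel=1e-6)


class TestRetention:
    def test_uniform_image_is_offset_invariant(self):
        img = np.full((500, 500), 37.0)
        rep = lq.roi_retention(img, [(100.0, 500.0), (900.0, 500.0)], pixel_size=2.0)
        assert all(v == pytest.approx(37.0) for v in rep.mean_gray.values())
        assert rep.retention_ratio == pytest.approx(1.0)

    def test_bright_centerline_gives_ratio_above_one(self):
        img = np.full((500, 500), 10.0)
        img[240:260, :] = 200.0  # stripe on the centerline (y = 500 µm at 2 µm/px)
        rep = lq.roi_retention(img, [(100.0, 500.0), (900.0, 500.0)], pixel_size=2.0)
        assert rep.retention_ratio > 1.0

    def test_offset_stripe_lights_the_matching_roi(self):
        img = np.full((500, 500), 10.0)
        img[395:405, :] = 200.0  # stripe at y = 800 µm = centerline + 300 µm
        rep = lq.roi_retention(img, [(100.0, 500.0), (900.0, 500.0)], pixel_size=2.0)
        assert rep.mean_gray[300.0] > rep.mean_gray[0.0]
        assert rep.mean_gray[300.0] > rep.mean_gray[-300.0]

    def test_roi_outside_image_is_error(self):
        img = np.zeros((50, 50))
        with pytest.raises(ValidationError):
            lq.roi_retention(img, [(0.0, 25.0), (50.0, 25.0)], pixel_size=1.0)


class TestSkeleton:
    def test_straight_bar(self):
        bar = np.zeros((30, 120), dtype=bool)
        bar[15, 10:111] = True  # 100 steps of 1 px
        m = lq.skeleton_morphometrics(bar, 1.0)
        assert m.n_junctions == 0 and m.n_segments == 1
        assert m.total_length == pytest.approx(100.0, abs=2.0)

    def test_cross(self):
        cross = np.zeros((130, 130), dtype=bool)
        cross[65, 14:115] = True
        cross[14:115, 64] = True
        m = lq.skeleton_morphometrics(cross, 1.0)
        assert m.n_junctions == 1 and m.n_segments == 4
        assert m.total_length == pytest.approx(200.0, abs=2.0)
        assert m.average_length * m.n_segments == pytest.approx(m.total_length, abs=1e-9)

    def test_empty_mask_is_zero_not_error(self):
        m = lq.skeleton_morphometrics(np.zeros((10, 10), dtype=bool), 1.0)
        assert m == lq.NetworkMetrics(0.0, 0, 0.0, 0)

    def test_length_additive_over_disjoint_components(self):
        img = np.zeros((60, 200), dtype=bool)
        img[20, 10:111] = True
        img[40, 10:61] = True
        m = lq.skeleton_morphometrics(img, 1.0)
        assert m.n_segments == 2
        assert m.total_length == pytest.approx(150.0, abs=3.0)

    def test_generated_network_recovered(self):
        segments = [
            ((50.0, 300.0), (650.0, 300.0)),
            ((350.0, 300.0), (550.0, 100.0)),
            ((350.0, 300.0), (550.0, 500.0)),
        ]
        img, truth = lq.generate_network_image(segments, thickness=12.0, pixel_size=2.0, seed=3)
        m = lq.skeleton_morphometrics(truth["mask"], 2.0)
        assert m.n_junctions == truth["n_junctions"] == 1
        assert m.total_length == pytest.approx(truth["total_length_um"], rel=0.05)

    def test_pixel_size_scales_length(self):
        bar = np.zeros((20, 60), dtype=bool)
        bar[10, 5:56] = True
        m1 = lq.skeleton_morphometrics(bar, 1.0)
        m3 = lq.skeleton_morphometrics(bar, 3.0)
        assert m3.total_length == pytest.approx(3 * m1.total_length)


class TestViabilityAndShape:
    def _blob_mask(self, n, seed=0):
        rng = np.random.default_rng(seed)
        mask = np.zeros((600, 600), dtype=np.uint16)
        placed = 0
        while placed < n:
            r, c = rng.integers(10, 590, 2)
            if mask[r - 3 : r + 4, c - 3 : c + 4].any():
                continue
            mask[r - 2 : r + 3, c - 2 : c + 3] = placed + 1
            placed += 1
        return mask

    def test_live_dead_ratio(self):
        live = self._blob_mask(97, seed=1)
        dead = self._blob_mask(3, seed=2)
        assert lq.quantify_viability(live, dead) == pytest.approx(0.97)

    def test_all_dead(self):
        live = np.zeros((600, 600), dtype=np.uint16)
        dead = self._blob_mask(10, seed=3)
        assert lq.quantify_viability(live, dead) == 0.0

    def test_plastic_control_scale(self):
        live = self._blob_mask(1, seed=4)
        dead = self._blob_mask(19, seed=5)
        assert lq.quantify_viability(live, dead) == pytest.approx(0.05)

    def test_no_objects_is_undefined(self):
        z = np.zeros((10, 10), dtype=np.uint16)
        with pytest.raises(ValidationError):
            lq.quantify_viability(z, z)

    def test_disk_cells_are_round(self, disk_mask):
        vals, summary = lq.cell_circularity(disk_mask, 1.0)
        assert vals.min() >= 0.9 and summary["n"] == 1

    def test_elongated_cells_score_low(self):
        mask = np.zeros((40, 220), dtype=np.uint16)
        mask[15:25, 10:210] = 1  # 20:1-ish aspect rectangle
        vals, _ = lq.cell_circularity(mask, 1.0)
        assert vals[0] < 0.5

    def test_closed_form_rectangle_circularity(self):
        # 10:1 rectangle: 4π·10/(22)² ≈ 0.26
        o = lq.observation_from_geometry(1, (0, 0), 10.0, 22.0)
        assert o.circularity == pytest.approx(4 * math.pi * 10 / 22**2, rel=1e-12)
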