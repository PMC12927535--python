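"""Normalisation, overall score, window maps and repeatability."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import liftqc as lq
from liftqc.droplets import PrintCriteria
from liftqc.errors import NoTransferError, ValidationError


def make_criteria(diameter=70.0, efficiency=1.0, circularity=0.95, satellite=1.0):
    return PrintCriteria(
        mean_diameter=diameter,
        diameter_values=(diameter,),
        efficiency=efficiency,
        mean_circularity=circularity,
        satellite_score=satellite,
        n_main=max(1, round(efficiency * 16)),
        n_satellite=0,
        n_expected=16,
    )


class TestDiameterNormalisation:
    def test_identity_at_reference(self):
        assert lq.normalize_diameter(70.0, 70.0) == 1.0

    def test_reciprocal_form(self):
        assert lq.normalize_diameter(140.0, 70.0) == pytest.approx(0.5)

    def test_clipped_below_reference(self):
        assert lq.normalize_diameter(35.0, 70.0) == 1.0

    def test_strictly_decreasing_above_reference(self):
        vals = [lq.normalize_diameter(d, 70.0) for d in (80, 100, 150, 300)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_linear_alternative(self):
        assert lq.normalize_diameter_linear(70.0, 70.0, 170.0) == 1.0
        assert lq.normalize_diameter_linear(120.0, 70.0, 170.0) == pytest.approx(0.5)
        assert lq.normalize_diameter_linear(400.0, 70.0, 170.0) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            lq.normalize_diameter(0.0, 70.0)


class TestReference:
    def test_tenth_percentile_linear_interpolation(self):
        # order-statistic oracle: positions 1..10, 10th pct at rank 0.9 -> 19
        assert lq.compute_reference(range(10, 101, 10)) == pytest.approx(19.0)

    def test_constant_sequence(self):
        assert lq.compute_reference([42.0] * 12) == 42.0

    def test_robust_to_large_outlier(self):
        base = list(np.linspace(60, 90, 30))
        with_outlier = base + [900.0]
        assert lq.compute_reference(with_outlier) == pytest.approx(
            lq.compute_reference(base), rel=0.02
        )

    def test_requires_ten_values(self):
        with pytest.raises(ValidationError):
            lq.compute_reference([70.0] * 9)


class TestOverallScore:
    def test_perfect_print_scores_one(self):
        cfg = lq.ScoreConfig(diameter_reference=70.0)
        s = lq.overall_score(make_criteria(circularity=1.0), cfg)
        assert s.overall == pytest.approx(1.0)

    def test_equal_weight_arithmetic_mean(self):
        cfg = lq.ScoreConfig(diameter_reference=70.0)
        s = lq.overall_score(
            make_criteria(diameter=140.0, efficiency=1.0, circularity=0.9, satellite=0.75), cfg
        )
        assert s.overall == pytest.approx((0.5 + 1.0 + 0.9 + 0.75) / 4)

    def test_acceptability_threshold_rule(self):
        cfg = lq.ScoreConfig(diameter_reference=70.0)
        s = lq.overall_score(
            make_criteria(diameter=70.0, efficiency=0.9, circularity=0.95, satellite=0.0), cfg
        )
        assert s.overall == pytest.approx(0.7125)
        assert s.acceptable(0.5)

    def test_custom_weights(self):
        cfg = lq.ScoreConfig(diameter_reference=70.0, weights=(1, 0, 0, 0))
        s = lq.overall_score(make_criteria(diameter=140.0, efficiency=0.1), cfg)
        assert s.overall == pytest.approx(0.5)

    def test_no_transfer_raises_distinct_state(self, grid_design):
        crit = PrintCriteria(
            mean_diameter=float("nan"), diameter_values=(), efficiency=0.0,
            mean_circularity=float("nan"), satellite_score=None,
            n_main=0, n_satellite=0, n_expected=16,
        )
        with pytest.raises(NoTransferError):
            lq.overall_score(crit, lq.ScoreConfig(diameter_reference=70.0))

    @settings(deadline=None, max_examples=300)
    @given(
        d=st.floats(10.0, 500.0),
        e=st.floats(0.0, 1.0),
        c=st.floats(0.0, 1.0),
        s=st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]),
    )
    def test_overall_bounded_and_equal_criteria_identity(self, d, e, c, s):
        cfg = lq.ScoreConfig(diameter_reference=70.0)
        out = lq.overall_score(make_criteria(d, e, c, s), cfg)
        assert 0.0 <= out.overall <= 1.0
        # when all four normalised components are equal, overall equals them
        ds = out.diameter_score
        out2 = lq.overall_score(make_criteria(d, ds, ds, 0.75), lq.ScoreConfig(
            diameter_reference=70.0, weights=(0.25,) * 4))
        # arithmetic-mean structure: replacing all by ds gives ds
        assert lq.overall_score(
            make_criteria(d, ds, ds, 0.75), cfg
        ).overall == pytest.approx((ds * 3 + 0.75) / 4)

    def test_monotone_in_each_criterion(self):
        rng = np.random.default_rng(0)
        cfg = lq.ScoreConfig(diameter_reference=70.0)
        for _ in range(2000):
            d = rng.uniform(30, 300)
            e, c = rng.uniform(0, 1, 2)
            s = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0])
            base = lq.overall_score(make_criteria(d, e, c, s), cfg).overall
            assert lq.overall_score(make_criteria(d * 0.9, e, c, s), cfg).overall >= base - 1e-12
            assert lq.overall_score(make_criteria(d, min(1, e + 0.1), c, s), cfg).overall >= base
            assert lq.overall_score(make_criteria(d, e, min(1, c + 0.1), s), cfg).overall >= base
            assert lq.overall_score(make_criteria(d, e, c, 1.0), cfg).overall >= base


class TestWindowMap:
    def _scored(self, energy, overall, status="scored"):
        cond = lq.PrintCondition(laser_energy=energy, status=status)
        if status != "scored":
            return (cond, None)
        s = lq.PrintabilityScores(overall, overall, overall, overall, overall)
        return (cond, s)

    def test_all_high_scores_fill_the_grid(self):
        scored = [self._scored(e, 0.9) for e in (2, 4, 6)]
        wm = lq.build_window_map(scored)
        assert len(wm.window()) == 3

    def test_all_no_transfer_gives_empty_window(self):
        scored = [self._scored(e, 0.0, status="no_transfer") for e in (2, 4)]
        wm = lq.build_window_map(scored)
        assert wm.window() == set()
        assert all(v == "no_transfer" for v in wm.cells.values())

    def test_unscreened_state_is_explicit(self):
        scored = [self._scored(2, 0.9), self._scored(4, 0.0, status="unscreened")]
        wm = lq.build_window_map(scored)
        df = wm.to_dataframe()
        assert set(df["status"]) == {"scored", "unscreened"}

    def test_duplicate_condition_rejected(self):
        scored = [self._scored(2, 0.9), self._scored(2, 0.8)]
        with pytest.raises(ValidationError):
            lq.build_window_map(scored)

    def test_planted_window_recovered_on_synthetic_sweep(self):
        from collections import defaultdict

        surf = lq.monotone_quality_surface()
        sweep = lq.generate_parameter_sweep(surf, seed=21)
        by_cond = defaultdict(list)
        for cond, _, rec in sweep:
            by_cond[cond].append(lq.compute_print_criteria(rec))
        pooled = {c: lq.pool_criteria(p) for c, p in by_cond.items()}
        d_ref = lq.compute_reference(
            [v for c, p in pooled.items() if c.key in surf.planted_window for v in p.diameter_values]
        )
        cfg = lq.ScoreConfig(diameter_reference=d_ref)
        scored = []
        for c, p in pooled.items():
            try:
                scored.append((c, lq.overall_score(p, cfg)))
            except NoTransferError:
                scored.append((c, None))
        wm = lq.build_window_map(scored)
        disagreement = wm.window() ^ set(surf.planted_window)
        # at most one boundary cell per DDR slice may flip
        per_slice = {}
        for key in disagreement:
            per_slice[key[1]] = per_slice.get(key[1], 0) + 1
        assert all(v <= 1 for v in per_slice.values())

    def test_recovered_window_is_an_energy_interval(self):
        from collections import defaultdict

        surf = lq.monotone_quality_surface()
        sweep = lq.generate_parameter_sweep(surf, seed=5)
        by_cond = defaultdict(list)
        for cond, _, rec in sweep:
            by_cond[cond].append(lq.compute_print_criteria(rec))
        cfg = lq.ScoreConfig(diameter_reference=64.0)
        scored = []
        for c, p in by_cond.items():
            try:
                scored.append((c, lq.overall_score(lq.pool_criteria(p), cfg)))
            except NoTransferError:
                scored.append((c, None))
        wm = lq.build_window_map(scored)
        for ddr in {k[1] for k in wm.cells}:
            energies = sorted(k[0] for k in wm.cells if k[1] == ddr)
            inside = [e for e in energies if any(k[0] == e and k[1] == ddr for k in wm.window())]
            if inside:
                lo, hi = min(inside), max(inside)
                assert inside == [e for e in energies if lo <= e <= hi]


class TestRepeatability:
    def test_constant_diameters_give_zero_cv(self):
        assert lq.repeatability_cv([[70.0, 70.0], [70.0]]) == 0.0

    def test_hand_arithmetic_oracle(self):
        # sample sd of [90, 110] is 14.142…, mean 100
        assert lq.repeatability_cv([[90.0, 110.0]]) == pytest.approx(0.1414213, rel=1e-5)

    def test_generator_cv_recovered(self, grid_design):
        hits = 0
        for seed in range(20):
            parts = []
            for rep in range(3):
                _, rec = lq.generate_print(
                    lq.SynthPrintParams(
                        design=grid_design, diameter_cv=0.1, placement_jitter_sd=0.0,
                        pixel_size=2.0, seed=1000 + 3 * seed + rep,
                    )
                )
                parts.append([d.equivalent_diameter for d in rec.mains])
            cv = lq.repeatability_cv(parts)
            hits += 0.06 <= cv <= 0.14
        assert hits >= 18  # ~95% of seeds

    def test_undefined_cases(self):
        with pytest.raises(ValidationError):
            lq.repeatability_cv([[1.0]])
        with pytest.raises(ValidationError):
            lq.repeatability_cv([[0.0, 0.0]])
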