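"""Normalization, control statistics, gating and grid construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hss_screen import (
    ScreenConfig,
    control_stats,
    green_off_gate,
    grid_boundaries,
    grid_fractions,
    normalize_events,
    select_on_reference,
)
from hss_screen._errors import (
    DegenerateControlError,
    DegenerateGridError,
    EmptyGateWarning,
)
from hss_screen.normalize_gate import ControlStats, GridSpec, gate_threshold

from conftest import make_pop, make_table

CFG = ScreenConfig(context="MAT_dREIII")
MAD_CFG = ScreenConfig(context="MAT_dREIII", stat_mode="mad_validation")


class TestNormalizeEvents:
    def test_on_control_identity(self):
        # every ON-control cell has green_raw == red_raw -> M_green = 1,
        # and a query cell with green == red normalizes to exactly 1
        on = make_table("on", [5.0, 7.0, 9.0], [5.0, 7.0, 9.0], [5.0, 7.0, 9.0])
        q = make_table("q", [2.0], [2.0], [2.0])
        pop = normalize_events(q, on)
        assert pop.green_norm[0] == 1.0
        assert pop.orange_norm[0] == 1.0

    def test_on_control_medians_are_one_by_construction(self, rng):
        on = make_table(
            "on",
            rng.lognormal(0, 0.3, 501),
            rng.lognormal(0, 0.3, 501),
            rng.lognormal(0, 0.3, 501),
        )
        pop = normalize_events(on, on)
        assert np.median(pop.green_norm) == 1.0
        assert np.median(pop.orange_norm) == 1.0

    def test_known_ratio(self):
        # ON ratios {0.8, 1.0, 1.2} -> median 1.0; query ratio 0.25 -> 0.25
        on = make_table(
            "on", [0.8, 1.0, 1.2], [0.8, 1.0, 1.2], [1.0, 1.0, 1.0]
        )
        q = make_table("q", [0.5], [0.5], [2.0])
        pop = normalize_events(q, on)
        assert pop.green_norm[0] == pytest.approx(0.25)

    def test_matches_brute_force_on_random_tables(self, rng):
        on = make_table(
            "on",
            rng.lognormal(2, 0.5, 400),
            rng.lognormal(2, 0.5, 400),
            rng.lognormal(2, 0.5, 400),
        )
        q = make_table(
            "q",
            rng.lognormal(2, 0.5, 300),
            rng.lognormal(2, 0.5, 300),
            rng.lognormal(2, 0.5, 300),
        )
        pop = normalize_events(q, on)
        expected = (q.green / q.red) / np.median(on.green / on.red)
        np.testing.assert_array_equal(pop.green_norm, expected)

    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_uniform_rescaling_invariance(self, c):
        rng = np.random.default_rng(7)
        on = make_table(
            "on",
            rng.lognormal(0, 0.3, 101),
            rng.lognormal(0, 0.3, 101),
            rng.lognormal(0, 0.3, 101),
        )
        q = make_table(
            "q",
            rng.lognormal(0, 0.3, 50),
            rng.lognormal(0, 0.3, 50),
            rng.lognormal(0, 0.3, 50),
        )
        a = normalize_events(q, on)
        b = normalize_events(q.scaled(c), on.scaled(c))
        np.testing.assert_allclose(a.green_norm, b.green_norm, rtol=1e-12)
        np.testing.assert_allclose(a.orange_norm, b.orange_norm, rtol=1e-12)


class TestControlStats:
    def test_constant_population(self):
        s = control_stats(make_pop("c", [0.05] * 5, [0.05] * 5), "green_norm")
        assert (s.median, s.sd, s.mad) == (0.05, 0.0, 0.0)

    def test_closed_form_sd(self):
        s = control_stats(
            make_pop("c", [0.1, 0.2, 0.3], [0, 0, 0]), "green_norm"
        )
        assert s.median == pytest.approx(0.2)
        assert s.sd == pytest.approx(0.1)

    def test_mad_is_unscaled_median_deviation(self):
        # {0, 0, 1}: median 0, |x - med| = {0, 0, 1} -> MAD 0
        s = control_stats(make_pop("c", [0, 0, 1], [0, 0, 0]), "green_norm")
        assert s.mad == 0.0

    def test_mad_brute_force_on_random_values(self, rng):
        x = rng.lognormal(0, 1, 333)
        s = control_stats(make_pop("c", x, x), "green_norm")
        assert s.mad == np.median(np.abs(x - np.median(x)))


class TestGreenOffGate:
    def test_hand_computed_threshold(self):
        off = control_stats(
            make_pop("off", [0.0, 0.1, 0.2], [0, 0, 0]), "green_norm"
        )
        pop = make_pop("q", [0.25, 0.35], [0, 0])
        res = green_off_gate(pop, off, CFG)
        assert res.threshold == pytest.approx(0.3)
        assert res.n_retained == 1

    def test_boundary_is_exclusive(self):
        off = control_stats(make_pop("off", [0.05] * 3, [0] * 3), "green_norm")
        pop = make_pop("q", [0.04, 0.05], [0, 0])
        res = green_off_gate(pop, off, CFG)
        assert res.threshold == 0.05
        assert list(res.population.green_norm) == [0.04]

    def test_mad_validation_mode_uses_3_mad(self):
        off = ControlStats("green_norm", median=0.1, sd=0.5, mad=0.02, n=100)
        assert gate_threshold(off, MAD_CFG) == pytest.approx(0.1 + 3 * 0.02)
        assert gate_threshold(off, CFG) == pytest.approx(0.1 + 2 * 0.5)

    def test_empty_gate_warns(self):
        off = control_stats(make_pop("off", [0.05] * 3, [0] * 3), "green_norm")
        pop = make_pop("q", [0.9, 1.1], [0, 0])
        with pytest.warns(EmptyGateWarning):
            res = green_off_gate(pop, off, CFG)
        assert res.n_retained == 0


class TestSelectOnReference:
    def test_all_at_one_all_retained(self):
        pop = make_pop("on", [1.0] * 4, [1.0] * 4)
        assert select_on_reference(pop, "orange_norm").n == 4

    def test_strictly_above_half(self):
        pop = make_pop("on", [0, 0, 0], [0.4, 0.5, 0.6])
        sel = select_on_reference(pop, "orange_norm")
        assert list(sel.orange_norm) == [0.6]

    def test_bimodal_retains_on_mode(self, rng):
        n = 5000
        vals = np.where(
            rng.random(n) < 0.8,
            rng.normal(1.0, 0.05, n),
            rng.normal(0.0, 0.05, n),
        )
        pop = make_pop("on", np.zeros(n), vals)
        sel = select_on_reference(pop, "orange_norm")
        assert sel.n == int((vals > 0.5).sum())
        assert sel.n / n == pytest.approx(0.8, abs=0.03)

    def test_degenerate_on_control_raises(self):
        pop = make_pop("on", [0, 0], [0.1, 0.2])
        with pytest.raises(DegenerateControlError):
            select_on_reference(pop, "orange_norm")


class TestGridBoundaries:
    def test_zero_noise_controls(self):
        off = ControlStats("orange_norm", median=0.0, sd=0.0, mad=0.0, n=10)
        on = make_pop("on", [0, 0, 0], [1.0, 1.0, 1.0])
        spec = grid_boundaries(off, on, CFG, gate_green_off=0.1)
        assert (spec.b_low, spec.b_mid, spec.b_high) == (0.0, 0.5, 1.0)

    def test_arithmetic(self):
        off = ControlStats("orange_norm", median=0.05, sd=0.025, mad=0.0, n=10)
        # {0.9, 1.0, 1.1} has median 1.0 and sample sd 0.1 exactly
        on = make_pop("on", [0, 0, 0], [0.9, 1.0, 1.1])
        spec = grid_boundaries(off, on, CFG, gate_green_off=0.1)
        assert spec.b_low == pytest.approx(0.1)
        assert spec.b_high == pytest.approx(0.8)
        assert spec.b_mid == pytest.approx(0.45)

    def test_mid_is_always_midpoint(self):
        off = ControlStats("orange_norm", median=0.02, sd=0.03, mad=0.0, n=10)
        on = make_pop("on", [0] * 3, [0.85, 0.9, 0.95])
        spec = grid_boundaries(off, on, CFG, gate_green_off=0.1)
        assert spec.b_mid == (spec.b_low + spec.b_high) / 2

    def test_overlapping_controls_raise(self):
        off = ControlStats("orange_norm", median=0.5, sd=0.3, mad=0.0, n=10)
        on = make_pop("on", [0] * 3, [0.6, 0.9, 1.2])
        with pytest.raises(DegenerateGridError):
            grid_boundaries(off, on, CFG, gate_green_off=0.1)

    def test_mad_validation_boundaries(self):
        off = ControlStats(
            "orange_norm", median=0.04, sd=9.0, mad=0.02, n=10
        )
        # on values {0.8, 1.0, 1.2}: median 1.0, mad 0.2
        on = make_pop("on", [0] * 3, [0.8, 1.0, 1.2])
        spec = grid_boundaries(off, on, MAD_CFG, gate_green_off=0.1)
        assert spec.b_low == pytest.approx(0.04 + 3 * 0.02)
        assert spec.b_high == pytest.approx(1.0 - 2 * 0.2)


SPEC = GridSpec(gate_green_off=0.1, b_low=0.1, b_mid=0.5, b_high=0.9)


def brute_force_fractions(orange, spec):
    """Independent per-cell interval classification."""
    counts = [0, 0, 0, 0]
    for x in orange:
        if x < spec.b_low:
            counts[0] += 1
        elif x < spec.b_mid:
            counts[1] += 1
        elif x < spec.b_high:
            counts[2] += 1
        else:
            counts[3] += 1
    return np.array(counts) / len(orange)


class TestGridFractions:
    def test_all_cells_in_grid_one(self):
        pop = make_pop("q", [0] * 5, [0.0] * 5)
        f = grid_fractions(pop, SPEC)
        assert (f.f1, f.f2, f.f3, f.f4) == (1.0, 0.0, 0.0, 0.0)

    def test_hand_computed_ten_cells(self):
        orange = [0.0, 0.05, 0.2, 0.3, 0.45, 0.55, 0.7, 0.85, 0.95, 1.2]
        f = grid_fractions(make_pop("q", [0] * 10, orange), SPEC)
        assert (f.f1, f.f2, f.f3, f.f4) == (0.2, 0.3, 0.3, 0.2)

    def test_cell_on_boundary_goes_to_upper_grid(self):
        f = grid_fractions(make_pop("q", [0], [SPEC.b_low]), SPEC)
        assert f.f2 == 1.0

    def test_matches_brute_force_oracle(self, rng):
        orange = rng.uniform(-0.1, 1.5, 2000)
        f = grid_fractions(make_pop("q", np.zeros(2000), orange), SPEC)
        np.testing.assert_array_equal(
            f.fractions, brute_force_fractions(orange, SPEC)
        )

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_fractions_sum_to_one_exactly(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(1, 500))
        orange = r.uniform(-0.5, 2.0, n)
        f = grid_fractions(make_pop("q", np.zeros(n), orange), SPEC)
        # counts are integers, so the sum is exact after division by n
        assert f.f1 + f.f2 + f.f3 + f.f4 == pytest.approx(1.0, abs=1e-15)

    @given(
        delta=st.floats(min_value=1e-6, max_value=1.0),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=30, deadline=None)
    def test_upward_shift_monotonicity(self, delta, seed):
        r = np.random.default_rng(seed)
        orange = r.uniform(0, 1.2, 300)
        f0 = grid_fractions(make_pop("q", np.zeros(300), orange), SPEC)
        f1 = grid_fractions(make_pop("q", np.zeros(300), orange + delta), SPEC)
        assert f1.f4 >= f0.f4
        assert f1.f1 <= f0.f1

    def test_empty_population_is_error(self):
        pop = make_pop("q", [], [])
        with pytest.raises(ValueError):
            grid_fractions(pop, SPEC)
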