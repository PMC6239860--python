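"""Binding tables, visibility-corrected fractions, and chi-square comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipocount.binding import (
    BindingTable,
    bound_fraction,
    compare_conditions,
    corrected_bound_fraction,
    corrected_bound_fraction_records,
    tabulate,
    ternary_fractions,
)
from lipocount.geometry import RodSphereGeometry, visibility_probability
from lipocount.simulate import generate_population


def make_table(bound, free, ternary=0, cls="HDL", cond="control"):
    mult = {1: bound + ternary} if bound + ternary else {}
    return BindingTable(
        class_label=cls, condition=cond,
        n_total=bound + free + ternary, n_free=free,
        n_binary=bound, n_ternary=ternary, multiplicity=mult,
    )


class TestTabulate:
    def test_hand_built_counts(self, hand_records):
        tables = tabulate(hand_records)
        t = tables[("HDL", "control")]
        assert (t.n_free, t.n_binary, t.n_ternary) == (2, 3, 1)
        assert t.multiplicity == {1: 3, 2: 1}

    def test_all_free(self, hand_records):
        rec = hand_records.copy()
        rec["observed_protrusions"] = 0
        rec["ternary_partner"] = ""
        t = tabulate(rec)[("HDL", "control")]
        assert t.n_free == 6 and t.n_binary == 0 and t.n_ternary == 0

    def test_conservation_on_simulated_population(self, small_config):
        for t in tabulate(generate_population(small_config)).values():
            assert t.n_free + t.n_binary + t.n_ternary == t.n_total
            assert sum(t.multiplicity.values()) == t.n_binary + t.n_ternary

    def test_empty_input(self, hand_records):
        with pytest.raises(ValueError, match="empty"):
            tabulate(hand_records.iloc[0:0])

    def test_invariants_enforced_on_construction(self):
        with pytest.raises(ValueError, match="equal total"):
            BindingTable("HDL", "control", n_total=5, n_free=1, n_binary=1, n_ternary=1)


class TestBoundFraction:
    def test_extremes(self):
        assert bound_fraction(make_table(0, 10)) == 0.0
        assert bound_fraction(make_table(10, 0)) == 1.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            bound_fraction(make_table(0, 0))


class TestCorrectedBoundFraction:
    def test_full_visibility_is_identity(self):
        t = make_table(10, 90)
        g = RodSphereGeometry(sphere_diameter=1e-9, rod_length=8.0)
        assert corrected_bound_fraction(t, g) == pytest.approx(bound_fraction(t))

    def test_single_rod_scaling(self):
        # observed 10%, p = 12/13 at d=10, l=8 -> 10.83%
        t = make_table(10, 90)
        g = RodSphereGeometry(sphere_diameter=10.0, rod_length=8.0)
        assert corrected_bound_fraction(t, g) == pytest.approx(0.10 * 13 / 12, abs=1e-9)

    def test_cap_with_warning(self):
        t = make_table(99, 1)
        g = RodSphereGeometry(sphere_diameter=30.0, rod_length=8.0)
        with pytest.warns(UserWarning, match="capped"):
            assert corrected_bound_fraction(t, g) == 1.0

    def test_multiplicity_reduces_the_correction(self):
        # several independent rods per particle: easier to see at least one
        t = make_table(10, 90)
        g = RodSphereGeometry(sphere_diameter=20.0, rod_length=8.0)
        single = corrected_bound_fraction(t, g)
        multi = corrected_bound_fraction(t, g, multiplicity={1: 0.5, 3: 0.5})
        assert bound_fraction(t) < multi < single

    def test_zero_visibility_undefined(self):
        g = RodSphereGeometry(sphere_diameter=10.0, rod_length=0.0)
        with pytest.raises(ValueError):
            corrected_bound_fraction(make_table(1, 9), g)

    def test_records_estimator_recovers_truth(self):
        # all bound, one rod each, fixed size: corrected fraction ~ 1.0
        rng = np.random.default_rng(21)
        n = 40_000
        p = visibility_probability(10.0, 8.0)
        visible = rng.uniform(size=n) < p
        rec = pd.DataFrame(
            {
                "particle_id": [str(i) for i in range(n)],
                "class": "HDL", "condition": "control", "time_min": 0.0,
                "diameter_long": 10.0, "diameter_perp": 10.0,
                "observed_protrusions": visible.astype(int),
                "ternary_partner": "",
            }
        )
        est = corrected_bound_fraction_records(rec, rod_length=8.0)
        assert est == pytest.approx(1.0, abs=3 * np.sqrt(p * (1 - p) / n) / p)


class TestTernaryFractions:
    def test_no_ternary(self):
        assert ternary_fractions(make_table(5, 5), make_table(3, 7, cls="LDL")) == (0, 0)

    def test_hand_arithmetic(self):
        hdl = make_table(10, 78, ternary=12)
        ldl = make_table(5, 43, ternary=12, cls="LDL")
        assert ternary_fractions(hdl, ldl) == (pytest.approx(0.12), pytest.approx(0.20))

    def test_mismatched_counts_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            ternary_fractions(make_table(1, 9, ternary=3),
                              make_table(1, 9, ternary=2, cls="LDL"))


class TestCompareConditions:
    def test_identical_proportions(self):
        r = compare_conditions(make_table(50, 50), make_table(50, 50), yates=False)
        assert r.chi_square == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)
        assert not r.significant

    def test_uncorrected_closed_form(self):
        # chi2 = n(ad - bc)^2 / (r1 r2 c1 c2) for [[10,90],[50,50]]
        a, b, c, d = 10, 90, 50, 50
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        r = compare_conditions(make_table(10, 90), make_table(50, 50), yates=False)
        assert r.chi_square == pytest.approx(expected, rel=1e-12)
        assert r.p_value == pytest.approx(stats.chi2.sf(expected, 1), rel=1e-9)
        assert r.significant and r.degrees_of_freedom == 1

    def test_yates_closed_form(self):
        # |ad - bc| reduced by n/2: [[3,7],[8,2]] -> 20*40^2/(10*10*11*9)
        expected = 20 * (abs(3 * 2 - 7 * 8) - 10) ** 2 / (10 * 10 * 11 * 9)
        r = compare_conditions(make_table(3, 7), make_table(8, 2), yates=True)
        assert r.chi_square == pytest.approx(expected, rel=1e-12)
        assert r.yates_applied

    def test_symmetric_in_table_order(self):
        a, b = make_table(12, 388), make_table(40, 360)
        r1, r2 = compare_conditions(a, b), compare_conditions(b, a)
        assert r1.chi_square == r2.chi_square and r1.p_value == r2.p_value

    def test_yates_never_exceeds_uncorrected(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            bound = rng.integers(1, 50, size=2)
            free = rng.integers(1, 50, size=2)
            a, b = make_table(bound[0], free[0]), make_table(bound[1], free[1])
            with_c = compare_conditions(a, b, yates=True).chi_square
            without = compare_conditions(a, b, yates=False).chi_square
            assert with_c <= without + 1e-12

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            compare_conditions(make_table(0, 10), make_table(0, 20))

    def test_p_value_floor_in_display_only(self):
        r = compare_conditions(make_table(10, 990), make_table(600, 400))
        assert r.p_value < 2.2e-16 and r.p_value > 0
        assert r.p_display() == "< 2.2e-16"
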