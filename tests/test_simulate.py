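"""Synthetic population generator: occlusion, determinism, and validation."""

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

from lipocount.config import (
    ClassSpec,
    ConditionSpec,
    SimulationConfig,
    TernarySpec,
    TimecourseSpec,
    default_config,
)
from lipocount.geometry import visibility_probability
from lipocount.simulate import (
    generate_population,
    generate_ternary_population,
    generate_timecourse,
    simulate_visible_fraction,
    validate_records,
)


class TestVisibleFractionMonteCarlo:
    def test_agrees_with_closed_form(self):
        p = visibility_probability(10.0, 8.0)
        n = 200_000
        est = simulate_visible_fraction(10.0, 8.0, n, seed=42)
        assert abs(est - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_zero_rod_never_visible(self):
        assert simulate_visible_fraction(15.0, 0.0, 1000, seed=0) == 0.0

    def test_point_sphere_always_visible(self):
        assert simulate_visible_fraction(1e-6, 8.0, 1000, seed=0) == pytest.approx(1.0)

    def test_reproducible_for_fixed_seed(self):
        a = simulate_visible_fraction(12.0, 8.0, 10_000, seed=5)
        b = simulate_visible_fraction(12.0, 8.0, 10_000, seed=5)
        assert a == b

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            simulate_visible_fraction(-1.0, 8.0, 100, seed=0)


class TestGeneratePopulation:
    def test_particle_conservation_and_schema(self, small_config):
        pop = generate_population(small_config)
        n_combos = len(small_config.classes) * len(small_config.conditions)
        assert len(pop) == n_combos * small_config.n_particles
        assert pop["particle_id"].is_unique
        assert (pop["diameter_long"] > 0).all() and (pop["diameter_perp"] > 0).all()
        assert (pop["observed_protrusions"] <= pop["true_protrusions"]).all()
        assert (pop["true_diameter"] > 1.0).all()
        validate_records(pop)  # must pass its own schema

    def test_zero_propensity_means_no_protrusions(self):
        cfg = SimulationConfig(
            classes=[ClassSpec(name="HDL", diameter_mean=12.0, diameter_sd=1.5)],
            conditions=[ConditionSpec(name="control", propensity={"HDL": 0.0})],
            n_particles=500,
            seed=3,
        )
        pop = generate_population(cfg)
        assert (pop["observed_protrusions"] == 0).all()
        assert (pop["true_protrusions"] == 0).all()

    def test_occlusion_rate_matches_analytic_visibility(self):
        # all particles bound with exactly one rod on a fixed-size sphere:
        # the observed-bound fraction is a Monte Carlo estimate of p(d, l)
        cfg = SimulationConfig(
            classes=[ClassSpec(name="HDL", diameter_mean=10.0, diameter_sd=0.0,
                               multiplicity={1: 1.0})],
            conditions=[ConditionSpec(name="control", propensity={"HDL": 1.0})],
            rod_length=8.0,
            n_particles=50_000,
            seed=9,
        )
        pop = generate_population(cfg)
        p = visibility_probability(10.0, 8.0)
        observed = (pop["observed_protrusions"] >= 1).mean()
        assert abs(observed - p) < 3 * np.sqrt(p * (1 - p) / len(pop))

    def test_deterministic_under_fixed_seed(self, small_config):
        a = generate_population(small_config)
        b = generate_population(small_config)
        pd.testing.assert_frame_equal(a, b)

    def test_config_validation_lists_offending_fields(self):
        with pytest.raises(ValidationError, match="propensity"):
            SimulationConfig(
                classes=[ClassSpec(name="HDL", diameter_mean=12.0, diameter_sd=1.5)],
                conditions=[ConditionSpec(name="control", propensity={"HDL": 1.2})],
            )
        with pytest.raises(ValidationError, match="sum to 1"):
            ClassSpec(name="HDL", diameter_mean=12.0, diameter_sd=1.5,
                      multiplicity={1: 0.5, 2: 0.2})


class TestTernaryPopulation:
    def test_requires_ternary_spec(self, hdl_only_config):
        with pytest.raises(ValueError, match="ternary"):
            generate_ternary_population(hdl_only_config)

    def test_bridges_cross_referenced_and_visible(self, small_config):
        pop = generate_ternary_population(small_config)
        bridged = pop[pop["ternary_partner"] != ""]
        assert (bridged["observed_protrusions"] >= 1).all()
        # partners pair up exactly: HDL <-> LDL ids reference each other
        by_id = bridged.set_index("particle_id")
        partners = by_id["ternary_partner"]
        assert (partners.map(partners).to_numpy() == partners.index.to_numpy()).all()
        hdl_n = (bridged["class"] == "HDL").sum()
        ldl_n = (bridged["class"] == "LDL").sum()
        assert hdl_n == ldl_n

    def test_zero_bridging_probability(self):
        cfg = default_config(seed=5, n_particles=300)
        cfg = cfg.model_copy(
            update={"ternary": TernarySpec(hdl_fraction=0.0)}
        )
        pop = generate_ternary_population(cfg)
        assert (pop["ternary_partner"] == "").all()

    def test_forced_bridging_matches_bound_fraction(self):
        # every bound HDL bridges: ternary fraction == bound fraction
        cfg = default_config(seed=5, n_particles=2000)
        cfg = cfg.model_copy(
            update={
                "ternary": TernarySpec(
                    hdl_fraction=0.4,
                    modulation={c: 1.0 for c in ("control", "Torcetrapib",
                                                 "Dalcetrapib", "Anacetrapib")},
                    bridge_given_bound=1.0,
                )
            }
        )
        pop = generate_ternary_population(cfg)
        hdl = pop[(pop["class"] == "HDL") & (pop["condition"] == "control")]
        tern_frac = (hdl["ternary_partner"] != "").mean()
        bound_frac = (hdl["true_protrusions"] >= 1).mean()
        assert tern_frac == bound_frac


class TestTimecourse:
    def test_requires_timecourse_spec(self, hdl_only_config):
        with pytest.raises(ValueError, match="timecourse"):
            generate_timecourse(hdl_only_config)

    def test_time_zero_uses_unscaled_mean(self, small_config):
        pop = generate_timecourse(small_config)
        t0 = pop[(pop["time_min"] == 0) & (pop["condition"] == "control")]
        mean = small_config.class_spec("HDL").diameter_mean
        sd = small_config.class_spec("HDL").diameter_sd
        se = sd / np.sqrt(len(t0))
        assert abs(t0["true_diameter"].mean() - mean) < 4 * se

    def test_shrinkage_scales_the_mean(self):
        cfg = default_config(seed=13, n_particles=5000)
        cfg = cfg.model_copy(
            update={
                "timecourse": TimecourseSpec(
                    times_min=[0.0, 480.0], decreases={"control": [0.0, 0.30]}
                ),
                "conditions": [c for c in default_config().conditions
                               if c.name == "control"],
            }
        )
        pop = generate_timecourse(cfg)
        t8h = pop[pop["time_min"] == 480.0]
        target = 12.28 * 0.70
        se = 1.91 / np.sqrt(len(t8h))
        assert abs(t8h["true_diameter"].mean() - target) < 4 * se

    def test_invalid_times_rejected(self):
        with pytest.raises(ValidationError, match="increasing"):
            TimecourseSpec(times_min=[0.0, 40.0, 40.0],
                           decreases={"control": [0.0, 0.1, 0.1]})
        with pytest.raises(ValidationError, match="time 0"):
            TimecourseSpec(times_min=[0.0, 40.0],
                           decreases={"control": [0.1, 0.2]})

    def test_piecewise_linear_interpolation(self):
        tc = TimecourseSpec(times_min=[0.0, 40.0, 120.0],
                            decreases={"control": [0.0, 0.17, 0.21]})
        assert tc.decrease_at("control", 20.0) == pytest.approx(0.085)
        assert tc.decrease_at("control", 80.0) == pytest.approx(0.19)


class TestValidateRecords:
    def test_missing_column_named(self, hand_records):
        with pytest.raises(ValueError, match="diameter_perp"):
            validate_records(hand_records.drop(columns=["diameter_perp"]))

    def test_bad_rows_addressed(self, hand_records):
        bad = hand_records.copy()
        bad.loc[2, "diameter_long"] = -1.0
        with pytest.raises(ValueError, match=r"rows \[2\]"):
            validate_records(bad)

    def test_ternary_flag_requires_protrusion(self, hand_records):
        bad = hand_records.copy()
        bad.loc[0, "ternary_partner"] = "ldl-9"
        with pytest.raises(ValueError, match="ternary_partner"):
            validate_records(bad)
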