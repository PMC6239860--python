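"""Validation harnesses: parameter recovery and chi-square calibration.

These run the full generate -> tabulate -> estimate chain against the
configured ground truth: binding propensities through the visibility-corrected
estimator, ternary fractions, and time-course diameter decreases, each with a
95% interval; and the type-I error / power of the condition comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .binding import compare_conditions, corrected_bound_fraction_records, tabulate
from .config import (
    ClassSpec,
    ConditionSpec,
    SimulationConfig,
    TernarySpec,
    TimecourseSpec,
    default_config,
)
from .simulate import (
    generate_population,
    generate_ternary_population,
    generate_timecourse,
)
from .sizes import geometric_mean_diameter

__all__ = ["run_recovery", "chi2_rejection_rate"]

_Z = {0.95: 1.959963984540054}


def _hdl_only_config(base: SimulationConfig, n: int, seed: int) -> SimulationConfig:
    hdl = base.class_spec("HDL")
    return SimulationConfig(
        classes=[hdl],
        conditions=[
            ConditionSpec(name=c.name, propensity={"HDL": c.propensity["HDL"]})
            for c in base.conditions
        ],
        rod_length=base.rod_length,
        measurement_noise_sd=base.measurement_noise_sd,
        n_particles=n,
        seed=seed,
    )


def run_recovery(
    n_particles: int = 5000,
    n_seeds: int = 100,
    base_seed: int = 0,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Recover configured truths from simulated populations, seed by seed.

    Per seed the harness checks, with ``confidence``-level intervals:

    * the four HDL binding propensities via the visibility-corrected
      bound-fraction estimator (Wilson interval scaled by the correction);
    * the control HDL- and LDL-side ternary fractions (Wilson);
    * the three non-zero control time-course diameter decreases, as percent
      change from time 0 (delta-method interval on the mean ratio).

    Returns one row per (seed, parameter) with columns ``truth``,
    ``estimate``, ``lo``, ``hi`` and ``covered``.
    """
    z = _Z.get(confidence) or float(stats.norm.ppf((1 + confidence) / 2))
    base = default_config()
    tern = TernarySpec()
    rows: list[dict] = []

    for i in range(n_seeds):
        seed = base_seed + i

        # --- binding propensities (corrected estimator) ---------------------
        cfg = _hdl_only_config(base, n_particles, seed)
        records = generate_population(cfg)
        mult = base.class_spec("HDL").multiplicity
        for cond in cfg.conditions:
            sub = records[records["condition"] == cond.name]
            est, (lo, hi) = corrected_bound_fraction_records(
                sub, cfg.rod_length, multiplicity=mult, confidence=confidence
            )
            truth = cond.propensity["HDL"]
            rows.append(
                {
                    "seed": seed,
                    "parameter": f"binding:HDL:{cond.name}",
                    "truth": truth,
                    "estimate": est,
                    "lo": lo,
                    "hi": hi,
                    "covered": lo <= truth <= hi,
                }
            )

        # --- ternary fractions (control) ------------------------------------
        tern_cfg = SimulationConfig(
            classes=[base.class_spec("HDL"), base.class_spec("LDL")],
            conditions=[
                ConditionSpec(
                    name="control",
                    propensity={
                        "HDL": base.condition_spec("control").propensity["HDL"],
                        "LDL": base.condition_spec("control").propensity["LDL"],
                    },
                )
            ],
            ternary=tern,
            rod_length=base.rod_length,
            measurement_noise_sd=base.measurement_noise_sd,
            n_particles=n_particles,
            seed=seed,
        )
        tern_records = generate_ternary_population(tern_cfg)
        tables = tabulate(tern_records)
        hdl_t = tables[("HDL", "control")]
        ldl_t = tables[("LDL", "control")]
        for label, k, n, truth in (
            ("ternary:HDL:control", hdl_t.n_ternary, hdl_t.n_total, tern.hdl_fraction),
            ("ternary:LDL:control", ldl_t.n_ternary, ldl_t.n_total,
             tern.ldl_fraction["control"]),
        ):
            ci = stats.binomtest(k, n).proportion_ci(
                confidence_level=confidence, method="wilson"
            )
            rows.append(
                {
                    "seed": seed,
                    "parameter": label,
                    "truth": truth,
                    "estimate": k / n,
                    "lo": ci.low,
                    "hi": ci.high,
                    "covered": ci.low <= truth <= ci.high,
                }
            )

        # --- time-course diameter decreases (control) ------------------------
        tc = TimecourseSpec(
            times_min=[0.0, 40.0, 120.0, 480.0],
            decreases={"control": [0.0, 0.17, 0.21, 0.30]},
        )
        tc_cfg = SimulationConfig(
            classes=[base.class_spec("HDL")],
            conditions=[
                ConditionSpec(
                    name="control",
                    propensity={"HDL": base.condition_spec("control").propensity["HDL"]},
                )
            ],
            timecourse=tc,
            rod_length=base.rod_length,
            measurement_noise_sd=base.measurement_noise_sd,
            n_particles=n_particles,
            seed=seed,
        )
        tc_records = generate_timecourse(tc_cfg)
        gmd = geometric_mean_diameter(
            tc_records["diameter_long"].to_numpy(float),
            tc_records["diameter_perp"].to_numpy(float),
        )
        times = tc_records["time_min"].to_numpy(float)
        d0 = gmd[times == 0.0]
        m0, s0, n0 = d0.mean(), d0.std(ddof=1), len(d0)
        for t, dec in zip(tc.times_min[1:], tc.decreases["control"][1:]):
            dt = gmd[times == t]
            mt, st, nt = dt.mean(), dt.std(ddof=1), len(dt)
            ratio = mt / m0
            se = ratio * np.sqrt(
                (st / mt) ** 2 / nt + (s0 / m0) ** 2 / n0
            )
            est = (ratio - 1.0) * 100.0
            lo, hi = est - z * se * 100.0, est + z * se * 100.0
            truth = -dec * 100.0
            rows.append(
                {
                    "seed": seed,
                    "parameter": f"shrinkage:HDL:control:t{t:g}",
                    "truth": truth,
                    "estimate": est,
                    "lo": lo,
                    "hi": hi,
                    "covered": lo <= truth <= hi,
                }
            )

    return pd.DataFrame(rows)


def chi2_rejection_rate(
    propensity_a: float,
    propensity_b: float,
    n_per_arm: int = 400,
    n_replicates: int = 1000,
    base_seed: int = 0,
    yates: bool = False,
    alpha: float = 0.05,
) -> float:
    """Fraction of simulated two-arm experiments the chi-square test rejects.

    Each replicate draws two HDL populations through the full generator (with
    occlusion) at the given binding propensities and compares the resulting
    bound/unbound tables.  Equal propensities estimate the type-I error rate;
    unequal ones estimate power.  Degenerate replicates (no bound particle in
    either arm) count as non-rejections.
    """
    hdl = default_config().class_spec("HDL")
    rejections = 0
    for i in range(n_replicates):
        cfg = SimulationConfig(
            classes=[hdl],
            conditions=[
                ConditionSpec(name="a", propensity={"HDL": propensity_a}),
                ConditionSpec(name="b", propensity={"HDL": propensity_b}),
            ],
            n_particles=n_per_arm,
            seed=base_seed + i,
        )
        tables = tabulate(generate_population(cfg))
        try:
            res = compare_conditions(
                tables[("HDL", "a")], tables[("HDL", "b")], yates=yates
            )
        except ValueError:
            continue
        if res.p_value < alpha:
            rejections += 1
    return rejections / n_replicates
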