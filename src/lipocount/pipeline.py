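"""Configuration-driven orchestration: simulate, analyse, report.

``run`` executes the full chain — simulate (binary, ternary, time-course
populations), tabulate complex counts, estimate bound and ternary fractions
with the visibility correction, compare every condition against the control
with the chi-square test, summarise diameter distributions — and writes all
tables as CSV plus a single deterministic JSON report.  The report is fully
regenerable from the resolved config and seed, which are embedded in it and
echoed to a provenance sidecar.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .binding import (
    BindingTable,
    bound_fraction,
    compare_conditions,
    corrected_bound_fraction_records,
    tabulate,
    ternary_fractions,
)
from .config import SimulationConfig, load_config
from .geometry import RodSphereGeometry
from .simulate import (
    RECORD_COLUMNS,
    TRUTH_COLUMNS,
    generate_population,
    generate_ternary_population,
    generate_timecourse,
    validate_records,
)
from .sizes import build_histogram, smooth_histogram, summarize

__all__ = ["run", "analyze_records", "evaluate_geometry", "ingest", "write_records"]


def ingest(records_path: str | Path) -> pd.DataFrame:
    """Read and validate a particle table from delimited text.

    Truth columns are optional; ``ternary_partner`` may be empty.  Validation
    errors name the offending columns and rows.
    """
    df = pd.read_csv(records_path, keep_default_na=False, na_values=[])
    df["time_min"] = pd.to_numeric(df.get("time_min", 0.0), errors="coerce")
    return validate_records(df)


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    """Write a particle table as comma-separated text (UTF-8, header row)."""
    cols = [c for c in RECORD_COLUMNS + TRUTH_COLUMNS if c in records.columns]
    records.to_csv(path, index=False, columns=cols)


def evaluate_geometry(config: SimulationConfig | str | Path) -> pd.DataFrame:
    """Evaluate every configured rod-on-sphere geometry.

    One row per geometry: visibility probability, correction percent, fusion
    surface fraction, maximum fused rods at half-available surface, and the
    penetration-model diameter.
    """
    if not isinstance(config, SimulationConfig):
        config = load_config(config)
    rows = []
    for g in config.geometries:
        geom = RodSphereGeometry(
            sphere_diameter=g.sphere_diameter,
            rod_length=g.rod_length,
            rod_diameter=g.rod_diameter,
            merged_length=g.merged_length,
        )
        rows.append(
            {
                "sphere_diameter": g.sphere_diameter,
                "rod_length": g.rod_length,
                "rod_diameter": g.rod_diameter,
                "merged_length": g.merged_length,
                "p_visible": geom.p_visible(),
                "correction_percent": (
                    geom.correction_percent() if g.rod_length > 0 else float("nan")
                ),
                "fusion_surface_fraction": geom.fusion_fraction(),
                "max_fused_cetps": geom.max_fused(0.5),
                "penetration_diameter": geom.diameter_after_penetration(),
            }
        )
    columns = [
        "sphere_diameter", "rod_length", "rod_diameter", "merged_length",
        "p_visible", "correction_percent", "fusion_surface_fraction",
        "max_fused_cetps", "penetration_diameter",
    ]
    return pd.DataFrame(rows, columns=columns)


def _table_dict(t: BindingTable) -> dict:
    return {
        "class": t.class_label,
        "condition": t.condition,
        "n_total": t.n_total,
        "n_free": t.n_free,
        "n_binary": t.n_binary,
        "n_ternary": t.n_ternary,
        "multiplicity": {str(k): v for k, v in sorted(t.multiplicity.items())},
    }


def _ternary_as_bound(t: BindingTable) -> BindingTable:
    """Recast a table so 'bound' means 'in a ternary complex' (for chi-square)."""
    return BindingTable(
        class_label=t.class_label,
        condition=t.condition,
        n_total=t.n_total,
        n_free=t.n_total - t.n_ternary,
        n_binary=0,
        n_ternary=t.n_ternary,
    )


def run(
    config: SimulationConfig | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
    force: bool = False,
    control: str = "control",
) -> dict:
    """Simulate, analyse and report; returns the report dict.

    Writes into ``out_dir``: particle tables (``particles.csv``, and when
    configured ``ternary_particles.csv`` / ``timecourse_particles.csv``),
    binding tables, condition comparisons, ternary fractions, diameter
    summaries and histograms as CSV, a ``provenance.json`` sidecar, and the
    full ``report.json``.  Refuses to touch a non-empty directory unless
    ``force`` is set.  Identical config + seed reproduce the outputs
    byte-for-byte.
    """
    if not isinstance(config, SimulationConfig):
        config = load_config(config)
    if seed is not None:
        config = config.model_copy(update={"seed": int(seed)})
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {out} is not empty; pass force=True to overwrite"
        )
    out.mkdir(parents=True, exist_ok=True)

    captured: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        report = _analyse(config, out, control)
        captured = [str(w.message) for w in wlist]

    report["warnings"] = captured
    provenance = {
        "seed": config.seed,
        "config": config.model_dump(mode="json"),
        "version": __version__,
    }
    _write_json(provenance, out / "provenance.json")
    report["version"] = __version__
    report["seed"] = config.seed
    report["config"] = config.model_dump(mode="json")
    _write_json(report, out / "report.json")
    return report


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=2) + "\n", encoding="utf-8")


def analyze_records(
    records: pd.DataFrame,
    config: SimulationConfig | None = None,
    out_dir: str | Path | None = None,
    force: bool = False,
    control: str = "control",
) -> dict:
    """Analyse an existing (ingested or simulated) particle table.

    Runs tabulation, bound fractions with the visibility correction,
    chi-square comparisons against the control condition, ternary fractions
    where matching HDL/LDL tables exist, and diameter summaries.  A config
    supplies the rod length and per-class multiplicity for the correction
    (defaults are used otherwise).  Writes CSV tables and ``report.json``
    into ``out_dir`` when given; returns the report dict.
    """
    records = validate_records(records)
    rod_length = config.rod_length if config is not None else 8.0
    tables = tabulate(records)

    binding_rows = []
    for (cls, cond), t in sorted(tables.items()):
        sub = records[(records["class"] == cls) & (records["condition"] == cond)]
        mult = None
        if config is not None:
            try:
                mult = config.class_spec(cls).multiplicity
            except KeyError:
                mult = None
        row = _table_dict(t)
        row["bound_fraction"] = bound_fraction(t)
        row["corrected_bound_fraction"] = corrected_bound_fraction_records(
            sub, rod_length, multiplicity=mult
        )
        binding_rows.append(row)

    condition_names = sorted({k[1] for k in tables})
    comparison_rows = []
    if control in condition_names:
        for cls in sorted({k[0] for k in tables}):
            if (cls, control) not in tables:
                continue
            for cond in condition_names:
                if cond == control or (cls, cond) not in tables:
                    continue
                try:
                    r = compare_conditions(
                        tables[(cls, cond)], tables[(cls, control)], yates=True
                    )
                except ValueError:
                    continue
                comparison_rows.append(
                    {
                        "class": cls,
                        "condition": cond,
                        "reference": control,
                        "chi_square": r.chi_square,
                        "p_value": r.p_value,
                        "p_display": r.p_display(),
                        "yates_applied": r.yates_applied,
                        "significant": r.significant,
                    }
                )

    tern_rows = []
    for cond in condition_names:
        hdl_t = tables.get(("HDL", cond))
        ldl_t = tables.get(("LDL", cond))
        if hdl_t is None or ldl_t is None or hdl_t.n_ternary != ldl_t.n_ternary:
            continue
        if hdl_t.n_ternary == 0:
            continue
        f_hdl, f_ldl = ternary_fractions(hdl_t, ldl_t)
        tern_rows.append(
            {
                "condition": cond,
                "n_ternary": hdl_t.n_ternary,
                "hdl_ternary_fraction": f_hdl,
                "ldl_ternary_fraction": f_ldl,
            }
        )

    multi_time = records["time_min"].nunique() > 1
    keys = ("class", "condition", "time_min") if multi_time else ("class", "condition")
    summaries = summarize(records, keys, percent_change=multi_time)

    report = {
        "binding_tables": binding_rows,
        "comparisons": comparison_rows,
        "ternary_fractions": tern_rows,
        "diameter_summaries": summaries.to_dict(orient="records"),
        "version": __version__,
    }
    if out_dir is not None:
        out = Path(out_dir)
        if out.exists() and any(out.iterdir()) and not force:
            raise FileExistsError(
                f"output directory {out} is not empty; pass force=True to overwrite"
            )
        out.mkdir(parents=True, exist_ok=True)
        pd.json_normalize(binding_rows).to_csv(out / "binding_tables.csv", index=False)
        pd.DataFrame(comparison_rows).to_csv(out / "comparisons.csv", index=False)
        pd.DataFrame(tern_rows).to_csv(out / "ternary_fractions.csv", index=False)
        summaries.to_csv(out / "diameter_summaries.csv", index=False)
        _write_json(report, out / "report.json")
    return report


def _analyse(config: SimulationConfig, out: Path, control: str) -> dict:
    report: dict = {}

    # --- binary populations -------------------------------------------------
    records = generate_population(config)
    write_records(records, out / "particles.csv")
    tables = tabulate(records)

    binding_rows = []
    for (cls, cond), t in sorted(tables.items()):
        sub = records[(records["class"] == cls) & (records["condition"] == cond)]
        mult = config.class_spec(cls).multiplicity
        corrected = corrected_bound_fraction_records(
            sub, config.rod_length, multiplicity=mult
        )
        row = _table_dict(t)
        row["bound_fraction"] = bound_fraction(t)
        row["corrected_bound_fraction"] = corrected
        binding_rows.append(row)
    report["binding_tables"] = binding_rows
    pd.json_normalize(binding_rows).to_csv(out / "binding_tables.csv", index=False)

    comparison_rows = []
    condition_names = [c.name for c in config.conditions]
    if control in condition_names:
        for cls in sorted({k[0] for k in tables}):
            ref = tables.get((cls, control))
            if ref is None:
                continue
            for cond in condition_names:
                if cond == control or (cls, cond) not in tables:
                    continue
                try:
                    r = compare_conditions(tables[(cls, cond)], ref, yates=True)
                except ValueError:
                    continue  # degenerate table (e.g. nothing bound anywhere)
                comparison_rows.append(
                    {
                        "class": cls,
                        "condition": cond,
                        "reference": control,
                        "chi_square": r.chi_square,
                        "degrees_of_freedom": r.degrees_of_freedom,
                        "p_value": r.p_value,
                        "p_display": r.p_display(),
                        "yates_applied": r.yates_applied,
                        "significant": r.significant,
                    }
                )
    report["comparisons"] = comparison_rows
    pd.DataFrame(comparison_rows).to_csv(out / "comparisons.csv", index=False)

    # --- diameter distributions --------------------------------------------
    summaries = summarize(records, ("class", "condition"), percent_change=False)
    summaries.to_csv(out / "diameter_summaries.csv", index=False)
    report["diameter_summaries"] = summaries.to_dict(orient="records")

    hist_rows = []
    for (cls, cond), _t in sorted(tables.items()):
        sub = records[(records["class"] == cls) & (records["condition"] == cond)]
        d = np.sqrt(
            sub["diameter_long"].to_numpy(float) * sub["diameter_perp"].to_numpy(float)
        )
        hist = smooth_histogram(build_histogram(d, 0.5), degree=6)
        for i in range(len(hist.counts)):
            hist_rows.append(
                {
                    "class": cls,
                    "condition": cond,
                    "bin_left": hist.edges[i],
                    "bin_right": hist.edges[i + 1],
                    "count": int(hist.counts[i]),
                    "smoothed": float(hist.smooth_values[i]),
                    "smooth_degree": hist.smooth_degree,
                }
            )
    pd.DataFrame(hist_rows).to_csv(out / "diameter_histograms.csv", index=False)

    # --- ternary mixture ----------------------------------------------------
    if config.ternary is not None:
        tern_records = generate_ternary_population(config)
        write_records(tern_records, out / "ternary_particles.csv")
        tern_tables = tabulate(tern_records)
        tern_rows = []
        tern_comparisons = []
        for cond in condition_names:
            hdl_t = tern_tables.get(("HDL", cond))
            ldl_t = tern_tables.get(("LDL", cond))
            if hdl_t is None or ldl_t is None:
                continue
            f_hdl, f_ldl = ternary_fractions(hdl_t, ldl_t)
            tern_rows.append(
                {
                    "condition": cond,
                    "n_ternary": hdl_t.n_ternary,
                    "n_hdl": hdl_t.n_total,
                    "n_ldl": ldl_t.n_total,
                    "hdl_ternary_fraction": f_hdl,
                    "ldl_ternary_fraction": f_ldl,
                }
            )
        if control in condition_names and ("HDL", control) in tern_tables:
            for cond in condition_names:
                if cond == control or ("HDL", cond) not in tern_tables:
                    continue
                for cls in ("HDL", "LDL"):
                    try:
                        r = compare_conditions(
                            _ternary_as_bound(tern_tables[(cls, cond)]),
                            _ternary_as_bound(tern_tables[(cls, control)]),
                            yates=True,
                        )
                    except ValueError:
                        continue
                    tern_comparisons.append(
                        {
                            "class": cls,
                            "condition": cond,
                            "reference": control,
                            "chi_square": r.chi_square,
                            "p_value": r.p_value,
                            "p_display": r.p_display(),
                            "significant": r.significant,
                        }
                    )
        report["ternary_fractions"] = tern_rows
        report["ternary_comparisons"] = tern_comparisons
        pd.DataFrame(tern_rows).to_csv(out / "ternary_fractions.csv", index=False)

    # --- time course --------------------------------------------------------
    if config.timecourse is not None:
        tc_records = generate_timecourse(config)
        write_records(tc_records, out / "timecourse_particles.csv")
        tc_summary = summarize(
            tc_records, ("class", "condition", "time_min"), percent_change=True
        )
        tc_summary.to_csv(out / "timecourse_summaries.csv", index=False)
        report["timecourse_summaries"] = tc_summary.to_dict(orient="records")

    # --- geometry models ----------------------------------------------------
    geometry = evaluate_geometry(config)
    geometry.to_csv(out / "geometry_models.csv", index=False)
    report["geometry_models"] = geometry.to_dict(orient="records")

    return report
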