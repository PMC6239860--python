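"""Counting statistics for protein-lipoprotein complex populations.

Turns per-particle protrusion counts into per-condition binding tables,
estimates bound fractions with and without the projection-visibility
correction, computes ternary-complex fractions, and compares conditions with
Pearson's chi-square test (Yates continuity correction on by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import RodSphereGeometry, visibility_probability

__all__ = [
    "BindingTable",
    "ComparisonResult",
    "tabulate",
    "bound_fraction",
    "corrected_bound_fraction",
    "corrected_bound_fraction_records",
    "ternary_fractions",
    "compare_conditions",
]

P_VALUE_FLOOR = 2.2e-16  # human-readable reporting floor; storage is full precision


@dataclass
class BindingTable:
    """Per class x condition complex counts.

    free: no observed protrusion; ternary: flagged as bridging a partner
    particle; binary: bound but not bridging.  The multiplicity histogram maps
    observed protrusion count (>= 1) to number of particles.
    """

    class_label: str
    condition: str
    n_total: int
    n_free: int
    n_binary: int
    n_ternary: int
    multiplicity: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.n_total, self.n_free, self.n_binary, self.n_ternary) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_free + self.n_binary + self.n_ternary != self.n_total:
            raise ValueError("free + binary + ternary must equal total")
        if self.multiplicity:
            if any(k < 1 or v < 0 for k, v in self.multiplicity.items()):
                raise ValueError("multiplicity histogram keys >= 1, counts >= 0")
            if sum(self.multiplicity.values()) != self.n_binary + self.n_ternary:
                raise ValueError("multiplicity histogram must cover every bound particle")

    @property
    def n_bound(self) -> int:
        return self.n_binary + self.n_ternary


@dataclass
class ComparisonResult:
    """A two-condition bound/unbound contingency comparison."""

    chi_square: float
    degrees_of_freedom: int
    p_value: float
    yates_applied: bool
    significant: bool

    def p_display(self) -> str:
        """Human-readable p-value with the conventional floor."""
        return "< 2.2e-16" if self.p_value < P_VALUE_FLOOR else f"{self.p_value:.3g}"


def tabulate(records: pd.DataFrame) -> dict[tuple[str, str], BindingTable]:
    """Binding tables keyed by (class, condition).

    A particle is free iff it shows no protrusion, ternary iff its
    ``ternary_partner`` is set, binary otherwise.
    """
    if len(records) == 0:
        raise ValueError("cannot tabulate an empty particle table")
    obs = pd.to_numeric(records["observed_protrusions"], errors="raise")
    if (obs < 0).any():
        raise ValueError("negative observed_protrusions")
    partner = records["ternary_partner"].fillna("").astype(str)

    tables: dict[tuple[str, str], BindingTable] = {}
    for (cls, cond), group in records.groupby(["class", "condition"], sort=True):
        g_obs = obs.loc[group.index]
        g_tern = partner.loc[group.index] != ""
        free = int((g_obs == 0).sum())
        ternary = int(g_tern.sum())
        binary = len(group) - free - ternary
        hist_counts = g_obs[g_obs >= 1].value_counts().sort_index()
        hist = {int(k): int(v) for k, v in hist_counts.items()}
        tables[(str(cls), str(cond))] = BindingTable(
            class_label=str(cls),
            condition=str(cond),
            n_total=len(group),
            n_free=free,
            n_binary=binary,
            n_ternary=ternary,
            multiplicity=hist,
        )
    return tables


def bound_fraction(table: BindingTable) -> float:
    """Fraction of particles in a complex: (binary + ternary) / total."""
    if table.n_total == 0:
        raise ValueError("bound_fraction undefined for an empty table")
    return table.n_bound / table.n_total


def _p_any_visible(p: float | np.ndarray, multiplicity: dict[int, float] | None):
    """P(at least one of a particle's rods clears the silhouette).

    With independent orientations and true multiplicity k the chance is
    1 - (1 - p)^k; averaged over a multiplicity distribution when given,
    otherwise the single-rod p.
    """
    if multiplicity is None:
        return p
    total = sum(multiplicity.values())
    return sum(
        (w / total) * (1.0 - (1.0 - p) ** k) for k, w in multiplicity.items()
    )


def corrected_bound_fraction(
    table: BindingTable,
    geometry: RodSphereGeometry,
    multiplicity: dict[int, float] | None = None,
) -> float:
    """Visibility-corrected bound fraction.

    Scales the observed bound fraction by the inverse probability that a bound
    particle shows at least one protrusion.  With a multiplicity distribution
    that probability is ``sum_k m_k (1 - (1-p)^k)``; without one it reduces to
    the single-rod ``p``, i.e. the plain ``1/p`` scaling.  Results above 1 are
    capped at 1.0 with a warning.
    """
    p = geometry.p_visible()
    if p <= 0:
        raise ValueError("visibility probability is zero; correction undefined")
    p_any = float(_p_any_visible(p, multiplicity))
    corrected = bound_fraction(table) / p_any
    if corrected > 1.0:
        warnings.warn(
            f"corrected bound fraction {corrected:.3f} exceeds 1; capped at 1.0",
            stacklevel=2,
        )
        corrected = 1.0
    return corrected


def corrected_bound_fraction_records(
    records: pd.DataFrame,
    rod_length: float,
    multiplicity: dict[int, float] | None = None,
    confidence: float | None = None,
):
    """Visibility-corrected bound fraction from per-particle diameters.

    Uses each particle's geometric-mean measured diameter to evaluate its own
    visibility probability, averages the per-particle chance of showing at
    least one rod, and scales the observed bound fraction by its inverse.
    This removes the bias of evaluating the correction only at the class mean
    diameter when particle sizes vary.

    Returns the corrected fraction, or ``(fraction, (lo, hi))`` when
    ``confidence`` is given (Wilson interval on the observed proportion,
    scaled by the same correction).
    """
    if len(records) == 0:
        raise ValueError("empty particle table")
    d = np.sqrt(
        records["diameter_long"].to_numpy(float)
        * records["diameter_perp"].to_numpy(float)
    )
    p = visibility_probability(d, rod_length)
    p_any = float(np.mean(_p_any_visible(p, multiplicity)))
    n = len(records)
    k = int((records["observed_protrusions"].to_numpy(int) >= 1).sum())
    corrected = min(1.0, (k / n) / p_any)
    if confidence is None:
        return corrected
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=confidence, method="wilson")
    return corrected, (ci.low / p_any, min(1.0, ci.high / p_any))


def ternary_fractions(
    hdl_table: BindingTable, ldl_table: BindingTable
) -> tuple[float, float]:
    """Ternary-complex fractions on the HDL and LDL sides.

    Each bridge contributes one HDL and one LDL, so the two tables must agree
    on ``n_ternary``; the fractions divide that shared count by each class's
    total particle count (free + binary + ternary).
    """
    if hdl_table.n_total == 0 or ldl_table.n_total == 0:
        raise ValueError("ternary fractions undefined for empty tables")
    if hdl_table.n_ternary != ldl_table.n_ternary:
        raise ValueError(
            f"inconsistent ternary counts: HDL {hdl_table.n_ternary} "
            f"vs LDL {ldl_table.n_ternary}"
        )
    n_t = hdl_table.n_ternary
    return n_t / hdl_table.n_total, n_t / ldl_table.n_total


def compare_conditions(
    table_a: BindingTable, table_b: BindingTable, yates: bool = True
) -> ComparisonResult:
    """Pearson chi-square comparison of bound/unbound proportions (2x2, 1 df).

    Yates' continuity correction is applied by default; significance is
    judged at alpha = 0.05.  Degenerate tables (a zero row or column margin)
    are rejected.
    """
    contingency = np.array(
        [
            [table_a.n_bound, table_a.n_total - table_a.n_bound],
            [table_b.n_bound, table_b.n_total - table_b.n_bound],
        ],
        dtype=float,
    )
    if (contingency.sum(axis=0) == 0).any() or (contingency.sum(axis=1) == 0).any():
        raise ValueError("degenerate contingency table: zero row or column total")
    res = stats.chi2_contingency(contingency, correction=yates)
    p = float(res.pvalue)
    return ComparisonResult(
        chi_square=float(res.statistic),
        degrees_of_freedom=int(res.dof),
        p_value=p,
        yates_applied=yates,
        significant=p < 0.05,
    )
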