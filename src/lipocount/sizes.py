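"""Particle-diameter measurement and distribution analysis.

Per-particle size is the geometric mean of the two perpendicular diameter
measurements.  Distributions are summarised as 0.5-nm histograms smoothed
with a least-squares polynomial (degree 6 by default), and as per-group
mean +/- SD tables with percent change from the time-zero group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DiameterHistogram",
    "geometric_mean_diameter",
    "build_histogram",
    "smooth_histogram",
    "summarize",
]


def geometric_mean_diameter(diameter_long, diameter_perp):
    """Per-particle diameter: sqrt(longest axis x perpendicular axis), nm."""
    a = np.asarray(diameter_long, dtype=float)
    b = np.asarray(diameter_perp, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("diameters must be strictly positive")
    out = np.sqrt(a * b)
    return out if out.ndim else float(out)


@dataclass
class DiameterHistogram:
    """A fixed-width diameter histogram with an optional polynomial smooth.

    ``edges`` are left-closed/right-open bin boundaries on a lattice anchored
    at a multiple of the bin width; ``len(edges) == len(counts) + 1``.
    Smoothing annotates (coefficients in the standard power basis, lowest
    order first, plus fitted values and residual sum of squares); it never
    mutates the counts.
    """

    edges: np.ndarray
    counts: np.ndarray
    smooth_degree: int | None = None
    smooth_coefficients: np.ndarray | None = None
    smooth_values: np.ndarray | None = None
    smooth_rss: float | None = None

    @property
    def midpoints(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def build_histogram(diameters, bin_width: float = 0.5) -> DiameterHistogram:
    """Histogram particle diameters on a lattice of `bin_width` nm steps.

    The left edge is ``floor(min / bin_width) * bin_width``; intervals are
    left-closed/right-open, so a value landing exactly on an edge counts in
    the bin to its right.
    """
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise ValueError("cannot histogram an empty diameter collection")
    if np.any(d <= 0):
        raise ValueError("diameters must be strictly positive")
    if bin_width <= 0:
        raise ValueError("bin_width must be strictly positive")
    left = np.floor(d.min() / bin_width) * bin_width
    idx = np.floor((d - left) / bin_width).astype(int)
    n_bins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_bins)
    edges = left + bin_width * np.arange(n_bins + 1)
    return DiameterHistogram(edges=edges, counts=counts)


def smooth_histogram(hist: DiameterHistogram, degree: int = 6) -> DiameterHistogram:
    """Annotate a histogram with a least-squares polynomial smooth.

    Fits counts against bin midpoints.  When fewer occupied bins than
    ``degree + 1`` are available the degree is reduced to
    ``occupied_bins - 1`` with a warning, keeping the system overdetermined.
    Returns a new annotated histogram; counts are untouched.
    """
    if degree < 0:
        raise ValueError("degree must be non-negative")
    occupied = int((hist.counts > 0).sum())
    eff_degree = degree
    if occupied < degree + 1:
        eff_degree = max(0, occupied - 1)
        warnings.warn(
            f"only {occupied} occupied bins: polynomial degree reduced "
            f"from {degree} to {eff_degree}",
            stacklevel=2,
        )
    x = hist.midpoints
    y = hist.counts.astype(float)
    # Polynomial.fit works in a scaled domain for conditioning; convert back
    poly = np.polynomial.Polynomial.fit(x, y, deg=eff_degree).convert()
    fitted = poly(x)
    rss = float(np.sum((y - fitted) ** 2))
    return DiameterHistogram(
        edges=hist.edges.copy(),
        counts=hist.counts.copy(),
        smooth_degree=eff_degree,
        smooth_coefficients=poly.coef,
        smooth_values=fitted,
        smooth_rss=rss,
    )


def summarize(
    records: pd.DataFrame,
    group_keys: tuple[str, ...] = ("class", "condition", "time_min"),
    percent_change: bool = True,
) -> pd.DataFrame:
    """Per-group diameter summaries: n, mean, SD, percent change from t0.

    The per-particle diameter is the geometric mean of the two measured axes;
    the summary reports its arithmetic mean and sample SD (n-1 denominator).
    When ``percent_change`` is requested and ``time_min`` is among the group
    keys, each group's mean is referenced to the time-0 group of the same
    remaining keys: ``(mean_t - mean_t0) / mean_t0 * 100``.
    """
    if len(records) == 0:
        raise ValueError("cannot summarize an empty particle table")
    df = records.copy()
    df["_gmd"] = geometric_mean_diameter(
        df["diameter_long"].to_numpy(float), df["diameter_perp"].to_numpy(float)
    )
    keys = list(group_keys)
    grouped = df.groupby(keys, sort=True)["_gmd"]
    out = grouped.agg(n="count", mean_diameter="mean", sd_diameter="std").reset_index()
    out["sd_diameter"] = out["sd_diameter"].fillna(0.0)

    if percent_change and "time_min" in keys:
        other = [k for k in keys if k != "time_min"]
        t0 = out[out["time_min"] == 0]
        if len(t0) == 0:
            raise ValueError("percent change requested but no time-0 group present")
        if other:
            ref = t0.set_index(other)["mean_diameter"]
            idx = pd.MultiIndex.from_frame(out[other]) if len(other) > 1 else out[other[0]]
            base = ref.reindex(idx).to_numpy()
        else:
            base = np.full(len(out), t0["mean_diameter"].iloc[0])
        if np.isnan(base).any():
            missing = out.loc[np.isnan(base), other].drop_duplicates()
            raise ValueError(f"groups lacking a time-0 reference:\n{missing}")
        out["percent_change_from_t0"] = (out["mean_diameter"] - base) / base * 100.0
    return out.rename(columns={"_gmd": "diameter"})
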