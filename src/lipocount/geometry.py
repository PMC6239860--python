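"""Closed-form geometric models for rod-shaped proteins bound to spherical particles.

A lipoprotein in a 2-D EM projection is a disc; a bound CETP is seen only when
its rod-shaped protrusion clears the disc silhouette.  Three models live here:

* **visibility** — the probability that a rod of protrusion length ``l``
  attached at a uniformly random point on a sphere of diameter ``d`` projects
  beyond the silhouette, ``p = cos(arcsin(d / (d + 2 l)))``.  Its inverse
  converts observed protrusion counts into true binding counts.
* **fusion model** — if a rod segment of diameter ``d_rod`` and length ``L``
  unfolds and spreads over the sphere surface, it occupies the surface
  fraction ``d_rod * L / (4 * D)``.
* **penetration model** — if instead the segment inserts radially as an
  intact cylinder, volume conservation grows the sphere diameter to
  ``D' = (D**3 + 1.5 * L * d_rod**2) ** (1/3)``.

All lengths are in nanometres; fractions are dimensionless.  Functions accept
scalars or numpy arrays and return full-precision values (display rounding is
the caller's business).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RodSphereGeometry",
    "visibility_probability",
    "visibility_correction_percent",
    "corrected_count",
    "fusion_surface_fraction",
    "max_fused_cetps",
    "penetration_diameter",
]


def visibility_probability(sphere_diameter, rod_length):
    """Probability that a rod protrusion clears the sphere silhouette.

    ``p = cos(arcsin(d / (d + 2 l)))`` for sphere diameter ``d`` and rod
    protrusion length ``l``, assuming no preferred attachment orientation.
    A zero-length protrusion is never visible (p = 0); as the sphere shrinks
    to a point every protrusion is visible (p -> 1).

    Parameters
    ----------
    sphere_diameter : float or array, nm, > 0
    rod_length : float or array, nm, >= 0

    Returns
    -------
    float or ndarray in [0, 1)
    """
    d = np.asarray(sphere_diameter, dtype=float)
    l = np.asarray(rod_length, dtype=float)
    if np.any(d <= 0):
        raise ValueError("sphere_diameter must be strictly positive")
    if np.any(l < 0):
        raise ValueError("rod_length must be non-negative")
    s = d / (d + 2.0 * l)
    p = np.sqrt(1.0 - s * s)  # cos(arcsin(s))
    return p if p.ndim else float(p)


def visibility_correction_percent(sphere_diameter, rod_length):
    """Percent by which an observed binding count understates the true count.

    ``100 * (1/p - 1)`` with ``p = visibility_probability(...)``.  Monotone
    increasing in sphere diameter: larger particles hide more of their bound
    rods behind the projection.

    Raises
    ------
    ValueError
        If ``rod_length`` is zero (p = 0, correction undefined).
    """
    l = np.asarray(rod_length, dtype=float)
    if np.any(l <= 0):
        raise ValueError("rod_length must be strictly positive for a finite correction")
    p = visibility_probability(sphere_diameter, rod_length)
    out = (1.0 / np.asarray(p) - 1.0) * 100.0
    return out if out.ndim else float(out)


def corrected_count(observed_count, p_visible):
    """Scale an observed protrusion count up to the true count, ``obs / p``."""
    c = np.asarray(observed_count, dtype=float)
    p = np.asarray(p_visible, dtype=float)
    if np.any(c < 0):
        raise ValueError("observed_count must be non-negative")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p_visible must lie in (0, 1]")
    out = c / p
    return out if out.ndim else float(out)


def fusion_surface_fraction(rod_diameter, merged_length, sphere_diameter):
    """Sphere-surface fraction occupied by a fused (unfolded) rod segment.

    ``d_rod * L / (4 * D)`` — the lateral surface of a cylinder of diameter
    ``d_rod`` and length ``L`` relative to the surface of a sphere of diameter
    ``D``, with all lengths in nm.
    """
    dr = np.asarray(rod_diameter, dtype=float)
    L = np.asarray(merged_length, dtype=float)
    D = np.asarray(sphere_diameter, dtype=float)
    if np.any(dr <= 0):
        raise ValueError("rod_diameter must be strictly positive")
    if np.any(L < 0):
        raise ValueError("merged_length must be non-negative")
    if np.any(D <= 0):
        raise ValueError("sphere_diameter must be strictly positive")
    out = dr * L / (4.0 * D)
    return out if out.ndim else float(out)


def max_fused_cetps(available_fraction, per_cetp_fraction):
    """How many fused rods fit in the available surface fraction.

    ``floor(available / per_rod)``; with roughly half the HDL surface taken by
    apolipoproteins (available = 0.5) and one fused CETP claiming ~0.31, at
    most one or two CETPs could bind under the fusion model.
    """
    a = float(available_fraction)
    per = float(per_cetp_fraction)
    if not 0.0 <= a <= 1.0:
        raise ValueError("available_fraction must lie in [0, 1]")
    if per <= 0:
        raise ValueError("per_cetp_fraction must be strictly positive")
    return int(math.floor(a / per))


def penetration_diameter(sphere_diameter, merged_length, rod_diameter):
    """Sphere diameter after radial insertion of an intact cylindrical segment.

    ``D' = (D**3 + 1.5 * L * d_rod**2) ** (1/3)`` — exactly the diameter of a
    sphere whose volume equals the original sphere plus a cylinder of diameter
    ``d_rod`` and length ``L`` (pi/6 D'^3 = pi/6 D^3 + pi/4 d^2 L).  Always
    >= D; equality iff nothing is inserted.
    """
    D = np.asarray(sphere_diameter, dtype=float)
    L = np.asarray(merged_length, dtype=float)
    dr = np.asarray(rod_diameter, dtype=float)
    if np.any(D <= 0):
        raise ValueError("sphere_diameter must be strictly positive")
    if np.any(L < 0) or np.any(dr < 0):
        raise ValueError("merged_length and rod_diameter must be non-negative")
    out = np.cbrt(D**3 + 1.5 * L * dr**2)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class RodSphereGeometry:
    """Geometry of one rod-on-sphere configuration.

    Attributes
    ----------
    sphere_diameter : float
        Lipoprotein diameter, nm.
    rod_length : float
        Visible rod protrusion length, nm (0 allowed: fully buried rod).
    rod_diameter : float
        Rod diameter, nm.
    merged_length : float
        Rod length merged into / under the lipid surface, nm.
    total_length : float or None
        Full rod length, nm; when given, ``merged_length`` may not exceed it.
    """

    sphere_diameter: float
    rod_length: float = 0.0
    rod_diameter: float = 2.5
    merged_length: float = 0.0
    total_length: float | None = None

    def __post_init__(self) -> None:
        if self.sphere_diameter <= 0:
            raise ValueError("sphere_diameter must be strictly positive")
        if self.rod_diameter <= 0:
            raise ValueError("rod_diameter must be strictly positive")
        if self.rod_length < 0 or self.merged_length < 0:
            raise ValueError("rod_length and merged_length must be non-negative")
        if self.total_length is not None and self.merged_length > self.total_length:
            raise ValueError("merged_length may not exceed total_length")

    def p_visible(self) -> float:
        return visibility_probability(self.sphere_diameter, self.rod_length)

    def correction_percent(self) -> float:
        return visibility_correction_percent(self.sphere_diameter, self.rod_length)

    def fusion_fraction(self) -> float:
        return fusion_surface_fraction(
            self.rod_diameter, self.merged_length, self.sphere_diameter
        )

    def max_fused(self, available_fraction: float = 0.5) -> int:
        return max_fused_cetps(available_fraction, self.fusion_fraction())

    def diameter_after_penetration(self) -> float:
        return penetration_diameter(
            self.sphere_diameter, self.merged_length, self.rod_diameter
        )
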