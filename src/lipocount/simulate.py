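"""Seeded generator of synthetic lipoprotein particle populations.

Emulates the per-particle records a human annotator would produce from
negative-stain EM micrographs of lipoprotein/CETP mixtures: spherical
particles with class-specific diameter distributions, CETP attachments drawn
with per-condition propensities and a per-class multiplicity split, uniform
random attachment orientation on the sphere, and geometric projection
occlusion (a rod protrusion is recorded only when its tip clears the particle
silhouette).  Occlusion is simulated geometrically, attachment by attachment,
so the analytic visibility probability serves as an independent oracle.

Populations are plain pandas DataFrames with one row per particle (see
``RECORD_COLUMNS``); truth columns carry the generative ground truth that a
real annotation would lack.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimulationConfig

__all__ = [
    "RECORD_COLUMNS",
    "TRUTH_COLUMNS",
    "simulate_visible_fraction",
    "generate_population",
    "generate_ternary_population",
    "generate_timecourse",
    "validate_records",
]

#: Columns an annotated (real or simulated) particle table must carry.
RECORD_COLUMNS = [
    "particle_id",
    "class",
    "condition",
    "time_min",
    "diameter_long",
    "diameter_perp",
    "observed_protrusions",
    "ternary_partner",
]

#: Simulation-only ground-truth columns.
TRUTH_COLUMNS = ["true_diameter", "true_protrusions", "attachment_angles"]


def simulate_visible_fraction(
    sphere_diameter: float, rod_length: float, n_samples: int, seed: int
) -> float:
    """Monte Carlo estimate of the rod-visibility probability.

    Attachment points are uniform on the sphere; with the viewing axis fixed,
    the polar angle theta has cos(theta) ~ Uniform(-1, 1).  A protrusion is
    visible iff ``sin(theta) > d / (d + 2 l)`` — its tip projects beyond the
    sphere silhouette.  Converges to the analytic
    ``cos(arcsin(d / (d + 2 l)))`` as n grows.
    """
    if sphere_diameter <= 0:
        raise ValueError("sphere_diameter must be strictly positive")
    if rod_length < 0:
        raise ValueError("rod_length must be non-negative")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    cos_theta = rng.uniform(-1.0, 1.0, size=n_samples)
    sin_theta = np.sqrt(1.0 - cos_theta**2)
    threshold = sphere_diameter / (sphere_diameter + 2.0 * rod_length)
    return float(np.mean(sin_theta > threshold))


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int, lower: float = 1.0
) -> np.ndarray:
    """Normal(mean, sd) resampled until all draws exceed `lower`."""
    if sd == 0:
        if mean <= lower:
            raise ValueError(f"degenerate diameter {mean} not above {lower} nm")
        return np.full(n, mean)
    out = rng.normal(mean, sd, size=n)
    bad = out <= lower
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= lower
    return out


def _noisy_measurement(
    rng: np.random.Generator, true_d: np.ndarray, noise_sd: float
) -> np.ndarray:
    """One diameter measurement: truth plus Normal noise, resampled positive."""
    out = true_d + rng.normal(0.0, noise_sd, size=true_d.shape) if noise_sd else true_d.copy()
    bad = out <= 0
    while bad.any():
        out[bad] = true_d[bad] + rng.normal(0.0, noise_sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def _simulate_class_condition(
    rng: np.random.Generator,
    *,
    class_name: str,
    condition: str,
    n: int,
    diameter_mean: float,
    diameter_sd: float,
    propensity: float,
    multiplicity: dict[int, float],
    rod_length: float,
    noise_sd: float,
    time_min: float = 0.0,
    id_prefix: str = "",
    forced_visible: np.ndarray | None = None,
) -> pd.DataFrame:
    """One class x condition population with geometric occlusion.

    ``forced_visible`` (bool mask over bound particles, optional) marks
    particles whose first attachment is always observed — used for ternary
    bridges, which lie in the image plane by construction.
    """
    true_d = _truncated_normal(rng, diameter_mean, diameter_sd, n)
    bound = rng.uniform(size=n) < propensity

    ks = np.array(sorted(multiplicity), dtype=int)
    probs = np.array([multiplicity[int(k)] for k in ks], dtype=float)
    probs = probs / probs.sum()
    true_k = np.zeros(n, dtype=int)
    n_bound = int(bound.sum())
    if n_bound:
        true_k[bound] = rng.choice(ks, size=n_bound, p=probs)

    max_k = int(true_k.max()) if n_bound else 0
    observed = np.zeros(n, dtype=int)
    angles = [""] * n
    if max_k:
        cos_theta = rng.uniform(-1.0, 1.0, size=(n, max_k))
        sin_theta = np.sqrt(1.0 - cos_theta**2)
        threshold = (true_d / (true_d + 2.0 * rod_length))[:, None]
        visible = sin_theta > threshold
        if forced_visible is not None:
            visible[forced_visible, 0] = True
        active = np.arange(max_k)[None, :] < true_k[:, None]
        observed = (visible & active).sum(axis=1)
        theta = np.arccos(cos_theta)
        bound_idx = np.flatnonzero(true_k)
        for i in bound_idx:
            angles[i] = ";".join(f"{t:.6f}" for t in theta[i, : true_k[i]])

    d_long = _noisy_measurement(rng, true_d, noise_sd)
    d_perp = _noisy_measurement(rng, true_d, noise_sd)
    # convention: diameter_long holds the larger of the two noisy axes
    lo = np.minimum(d_long, d_perp)
    hi = np.maximum(d_long, d_perp)

    prefix = id_prefix or f"{class_name}-{condition}-t{time_min:g}"
    return pd.DataFrame(
        {
            "particle_id": [f"{prefix}-{i:06d}" for i in range(n)],
            "class": class_name,
            "condition": condition,
            "time_min": float(time_min),
            "diameter_long": hi,
            "diameter_perp": lo,
            "observed_protrusions": observed,
            "ternary_partner": "",
            "true_diameter": true_d,
            "true_protrusions": true_k,
            "attachment_angles": angles,
        }
    )


def generate_population(config: SimulationConfig) -> pd.DataFrame:
    """Binary-complex populations: every class x condition, `n_particles` each.

    Deterministic for a fixed config (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    for cls in config.classes:
        for cond in config.conditions:
            if cls.name not in cond.propensity:
                continue
            frames.append(
                _simulate_class_condition(
                    rng,
                    class_name=cls.name,
                    condition=cond.name,
                    n=config.n_particles,
                    diameter_mean=cls.diameter_mean,
                    diameter_sd=cls.diameter_sd,
                    propensity=cond.propensity[cls.name],
                    multiplicity=cls.multiplicity,
                    rod_length=config.rod_length,
                    noise_sd=config.measurement_noise_sd,
                )
            )
    if not frames:
        raise ValueError("config yields no class x condition combinations")
    return pd.concat(frames, ignore_index=True)


def generate_ternary_population(config: SimulationConfig) -> pd.DataFrame:
    """HDL + LDL mixture populations with CETP bridges (ternary complexes).

    Per condition: HDL particles bind with the mixture propensity
    ``hdl_fraction * modulation / bridge_given_bound`` and each bound HDL
    bridges an LDL with probability ``bridge_given_bound``, so the expected
    HDL ternary fraction equals ``hdl_fraction * modulation``.  The LDL count
    is set from the configured LDL-side ternary fraction; bridged pairs are
    cross-referenced through ``ternary_partner``.  Bridging rods lie in the
    image plane, so a bridge always contributes one observed protrusion to
    both partners.
    """
    if config.ternary is None:
        raise ValueError("config has no ternary spec")
    tern = config.ternary
    hdl = config.class_spec("HDL")
    ldl = config.class_spec("LDL")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    frames = []
    for cond in config.conditions:
        hdl_tf = tern.hdl_ternary_fraction(cond.name)
        bound_mix = hdl_tf / tern.bridge_given_bound
        if bound_mix > 1.0:
            raise ValueError(
                f"mixture bound fraction {bound_mix:.3f} for {cond.name!r} exceeds 1; "
                "raise bridge_given_bound or lower the ternary fraction"
            )
        n_hdl = config.n_particles
        if cond.name not in tern.ldl_fraction:
            raise ValueError(f"ternary spec lacks ldl_fraction for {cond.name!r}")
        n_ldl = max(1, round(n_hdl * hdl_tf / tern.ldl_fraction[cond.name]))

        hdl_df = _simulate_class_condition(
            rng,
            class_name="HDL",
            condition=cond.name,
            n=n_hdl,
            diameter_mean=hdl.diameter_mean,
            diameter_sd=hdl.diameter_sd,
            propensity=bound_mix,
            multiplicity=hdl.multiplicity,
            rod_length=config.rod_length,
            noise_sd=config.measurement_noise_sd,
            id_prefix=f"HDL-{cond.name}-tern",
        )
        bound_mask = hdl_df["true_protrusions"].to_numpy() >= 1
        bridges = bound_mask & (
            rng.uniform(size=n_hdl) < tern.bridge_given_bound
        )
        # a bridge lies in-plane: force one observed protrusion
        obs = hdl_df["observed_protrusions"].to_numpy()
        obs[bridges] = np.maximum(obs[bridges], 1)
        hdl_df["observed_protrusions"] = obs

        n_tern = int(bridges.sum())
        if n_tern > n_ldl:
            raise ValueError(
                f"{n_tern} bridges but only {n_ldl} LDL particles for {cond.name!r}"
            )
        ldl_df = _simulate_class_condition(
            rng,
            class_name="LDL",
            condition=cond.name,
            n=n_ldl,
            diameter_mean=ldl.diameter_mean,
            diameter_sd=ldl.diameter_sd,
            propensity=cond.propensity.get("LDL", 0.0),
            multiplicity=ldl.multiplicity,
            rod_length=config.rod_length,
            noise_sd=config.measurement_noise_sd,
            id_prefix=f"LDL-{cond.name}-tern",
        )
        partner_idx = rng.choice(n_ldl, size=n_tern, replace=False)
        hdl_ids = hdl_df.loc[bridges, "particle_id"].to_numpy()
        ldl_ids = ldl_df["particle_id"].to_numpy()[partner_idx]
        hdl_df.loc[bridges, "ternary_partner"] = ldl_ids
        col = ldl_df.columns.get_loc("ternary_partner")
        ldl_df.iloc[partner_idx, col] = hdl_ids
        # bridged LDL gains the bridging rod on top of any binary attachments
        obs = ldl_df["observed_protrusions"].to_numpy()
        true_k = ldl_df["true_protrusions"].to_numpy()
        obs[partner_idx] += 1
        true_k[partner_idx] += 1
        ldl_df["observed_protrusions"] = obs
        ldl_df["true_protrusions"] = true_k

        frames.extend([hdl_df, ldl_df])
    return pd.concat(frames, ignore_index=True)


def generate_timecourse(config: SimulationConfig) -> pd.DataFrame:
    """HDL populations over incubation time with shrinking mean diameter.

    At each configured time point the HDL diameter mean is scaled by
    ``1 - fractional_decrease`` and a fresh population is sampled (time 0 uses
    the unscaled mean).  Binding uses each condition's HDL propensity.
    """
    if config.timecourse is None:
        raise ValueError("config has no timecourse spec")
    tc = config.timecourse
    hdl = config.class_spec("HDL")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    frames = []
    for cond in config.conditions:
        if cond.name not in tc.decreases:
            continue
        for t, dec in zip(tc.times_min, tc.decreases[cond.name]):
            frames.append(
                _simulate_class_condition(
                    rng,
                    class_name="HDL",
                    condition=cond.name,
                    n=config.n_particles,
                    diameter_mean=hdl.diameter_mean * (1.0 - dec),
                    diameter_sd=hdl.diameter_sd,
                    propensity=cond.propensity.get("HDL", 0.0),
                    multiplicity=hdl.multiplicity,
                    rod_length=config.rod_length,
                    noise_sd=config.measurement_noise_sd,
                    time_min=t,
                )
            )
    if not frames:
        raise ValueError("timecourse spec matches no configured condition")
    return pd.concat(frames, ignore_index=True)


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check a particle table against the record schema.

    Returns the validated frame (ternary_partner normalised to strings).
    Raises ``ValueError`` with row-addressed messages on bad data.
    """
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"particle table missing required columns: {missing}")
    if len(records) == 0:
        raise ValueError("particle table is empty")
    df = records.copy()
    df["ternary_partner"] = df["ternary_partner"].fillna("").astype(str)

    problems: list[str] = []
    for col in ("diameter_long", "diameter_perp"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals <= 0)
        if bad.any():
            rows = df.index[bad].tolist()[:5]
            problems.append(f"{col}: non-numeric or non-positive at rows {rows}")
        df[col] = vals
    obs = pd.to_numeric(df["observed_protrusions"], errors="coerce")
    bad = obs.isna() | (obs < 0) | (obs != obs.round())
    if bad.any():
        rows = df.index[bad].tolist()[:5]
        problems.append(f"observed_protrusions: non-integer or negative at rows {rows}")
    if not bad.any():
        df["observed_protrusions"] = obs.astype(int)
    tern = df["ternary_partner"] != ""
    bad = tern & (df["observed_protrusions"] < 1)
    if bad.any():
        rows = df.index[bad].tolist()[:5]
        problems.append(
            f"ternary_partner set with zero observed protrusions at rows {rows}"
        )
    if "true_protrusions" in df.columns and "observed_protrusions" in df.columns:
        tk = pd.to_numeric(df["true_protrusions"], errors="coerce")
        bad = tk.notna() & (df["observed_protrusions"] > tk)
        if bad.any():
            rows = df.index[bad].tolist()[:5]
            problems.append(f"observed_protrusions exceeds true_protrusions at rows {rows}")
    if problems:
        raise ValueError("invalid particle table:\n  " + "\n  ".join(problems))
    return df
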