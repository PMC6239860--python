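# Methods

## The measurement problem

A projection EM image reduces each lipoprotein to a disc and each bound CETP
to a rod protrusion at the disc edge. An annotator records, per particle: the
longest diameter and its perpendicular, the number of visible rod
protrusions, and whether the particle is bridged to a partner of the other
class. `lipocount` models that record (`RECORD_COLUMNS` in
`lipocount.simulate`), estimates population quantities from collections of
such records, and ships a generator that produces them synthetically with
known truth.

## Geometry models

**Visibility.** A rod attached at polar angle θ (measured from the viewing
axis) on a sphere of diameter *d* clears the silhouette iff
sin θ > *d*/(*d* + 2*l*), where *l* is the protrusion length. Under uniform
attachment (cos θ ~ U(−1, 1)) the visible fraction is
℘(d, l) = cos[arcsin(d/(d + 2l))]. Limits: ℘ → 1 as the sphere shrinks to a
point, ℘ = 0 for a zero-length protrusion; ℘ increases in *l*, decreases in
*d*. The correction percent 100·(1/℘ − 1) spans 8.3%–31.9% for *l* = 8 nm
over *d* ∈ [10, 30] nm. A particle carrying *k* independent rods shows at
least one with probability 1 − (1 − ℘)^k, which is what the bound-fraction
correction inverts; with k ≡ 1 it reduces to the plain 1/℘ scaling.

**Fusion vs. penetration.** Both models take the buried CETP segment to be a
cylinder of length *L* = 5 nm and diameter *d_rod* = 2.5 nm. The fusion model
spreads its lateral surface (π·d_rod·L) over the sphere surface (π·D²),
giving the occupancy fraction d_rod·L/(4·D); the expression is used directly
as a fraction with all lengths in nm, the convention in which its
consequences are stated (0.3125 → "at least 30%"). The penetration model
conserves volume: D′ = (D³ + 3⁄2·L·d_rod²)^(1/3) is exactly the diameter of a
sphere holding the original volume plus the cylinder's, and the test suite
verifies the closed form against that independent volume-addition route to
10⁻¹⁰ relative error. `max_fused_cetps` is the floor of available surface
fraction over per-rod occupancy — the capacity argument that falsifies the
fusion model once particles with four or more rods are seen.

## Synthetic population generator

`generate_population` draws, per class × condition: true diameters from a
Normal truncated below 1 nm (the study reports only mean ± SD per class:
HDL 12.28 ± 1.91 nm, LDL 23.6 ± 1.3 nm, VLDL 38.28 ± 7.12 nm); a Bernoulli
binding indicator with the condition's propensity (control →
HDL 9.9%, LDL 12.9%, VLDL 35.1%; the three inhibitors raise these up to
5-fold, e.g. HDL 50.5% under Torcetrapib); a per-class categorical
multiplicity for bound particles (HDL 80/15/5% for 1/2/3 rods, LDL 85/12/3%,
VLDL 40/35/25%, digitised from the reported qualitative splits); and one
independent uniform orientation per rod. Occlusion is applied geometrically
per rod using the particle's own diameter — never by thinning with the
analytic ℘ — so the closed form remains an independent oracle for the
simulator. Both diameter measurements are noisy copies of the true diameter
(Normal, SD 0.4 nm per axis by default, a realistic annotator click
precision at negative-stain pixel sizes); how a real annotator orients the
axis pair on near-circular particles is unknowable, so the two axes are
statistically exchangeable and the larger noisy copy is labelled
`diameter_long`. The default population size, 400 particles per class per
condition, is the midpoint of the 300–500 particles a typical micrograph
series yields.

**Ternary mixtures.** In HDL+LDL+CETP mixtures, bridges (one CETP connecting
an HDL to an LDL) are counted against both class totals. The generator
parametrises the HDL-side ternary fraction directly (control 12.2%,
multiplied per condition by a modulation factor: 0.566/0.795/0.534 for
Torcetrapib/Dalcetrapib/Anacetrapib) and derives the mixture bound
propensity as ternary_fraction / bridge_given_bound (default 0.8). The
mixture propensity deliberately exceeds the binary-experiment propensity for
the control arm: the study observes more HDL bound when LDL is present, and
a 12.2% ternary fraction is arithmetically impossible under a 9.9% bound
fraction. The LDL-side target fraction (control 19.5%, inhibitors
16.6–17.5%) fixes the simulated HDL:LDL count ratio. Bridging rods lie in
the image plane, so a bridge always contributes one *observed* protrusion to
each partner — which is why ternary fractions need no visibility correction.
The modulation factor is a generative knob emulating the observed
inhibitor-induced suppression of bridging; it implements no mechanistic
(allosteric) model, because the study proposes one only qualitatively.

**Time course.** HDL shrinks as cholesteryl ester leaves it: at each
configured time the HDL diameter mean is scaled by 1 − decrease
(control: 0 at 0/15 min, 17% at 40 min, 21% at 2 h, 30% at 8 h; the
Torcetrapib/Anacetrapib arms plateau near 10% at 2 h and 25% at 8 h) and a
fresh population is sampled. Decreases between configured times are
interpolated piecewise-linearly; no kinetic model is fitted. The 24 h regime,
where the distribution becomes bimodal and particles fade below detectability,
is outside scope.

**What the generator does not emulate:** image formation (stain, defocus,
contrast), annotator misclassification, spatial clustering on the grid,
IDL contamination of the VLDL density fraction, within-particle correlation
of rod orientations, and diameter-dependent binding propensity. Passing
recovery tests therefore show the estimators are unbiased and correctly
calibrated *under the stated sampling model*, not that real micrograph
annotations are free of systematic error.

## Estimators and tests

A particle is *free* iff it shows zero protrusions, *ternary* iff its bridge
flag is set, *binary* otherwise; each bridge contributes one complex to
`n_ternary` and one protrusion to each partner's multiplicity histogram, so
CETPs are never double-counted. The bound fraction is
(binary + ternary)/total. The corrected estimator divides the observed bound
fraction by the mean per-particle probability of showing at least one rod;
`corrected_bound_fraction` evaluates it at a single geometry, while
`corrected_bound_fraction_records` evaluates ℘ at each particle's measured
geometric-mean diameter and averages, removing the Jensen bias a
class-mean-diameter correction would carry when sizes vary. Corrected
fractions are capped at 1 with a warning. Ternary fractions divide the shared
bridge count by each class's total.

Condition comparisons use Pearson's χ² on the 2×2 bound/unbound table with
1 df; Yates' continuity correction is the default, matching the study's
statistics, and the uncorrected statistic is available (`yates=False`). The
Yates statistic never exceeds the uncorrected one; the type-I calibration
harness uses the uncorrected test because continuity correction is
deliberately conservative (its null rejection rate sits visibly below the
nominal 5% even with ~40 expected bound particles per arm), whereas the
uncorrected Pearson test is asymptotically calibrated. P-values are stored at
full precision and floored at 2.2 × 10⁻¹⁶ only in human-readable display.

Per-particle size is √(diameter_long × diameter_perp). Histograms use
0.5-nm, left-closed/right-open bins anchored at floor(min/0.5)·0.5 — the
anchoring and edge conventions are fixed choices, since only the step size
is prescribed. Smoothing fits a least-squares polynomial (degree 6) to raw
counts at bin midpoints, in numpy's scaled-domain basis for conditioning,
and annotates the histogram without touching the counts; with fewer occupied
bins than degree + 1 the degree drops to occupied − 1 with a warning.
Summaries report the arithmetic mean and sample SD (n − 1) of the per-group
diameters and percent change against the time-0 group of the same
class × condition.

## Validation harnesses and problem sizes

`lipocount.recovery.run_recovery` replays the full
generate → tabulate → estimate chain over seeded replicates and checks the
configured truths against 95% intervals: Wilson intervals (scaled by the
visibility correction) for the four HDL binding propensities, Wilson
intervals for the control HDL/LDL ternary fractions, and delta-method
intervals on the mean-diameter ratio for the three non-zero control
shrinkages. The acceptance suite runs 100 seeds at 5000 particles per arm
and requires ≥ 90% joint coverage. `chi2_rejection_rate` estimates the
comparison's type-I error (1000 null replicates, 400 particles per arm,
binding propensity 9.9% in both) and power (9.9% vs 50.5%). Monte Carlo
validation of ℘ uses 10⁶ orientation draws per diameter with a
3-standard-error band. These sizes keep the full suite under a minute of
simulation time while leaving binomial error well inside every asserted
tolerance.

## Numerical conventions and edge cases

All randomness flows from `numpy.random.default_rng` seeded from the config
(sub-streams for the ternary and time-course generators are spawned via
`SeedSequence([seed, k])`), and reports serialise with sorted keys and
full-precision floats, so identical config + seed reproduce every output
byte-for-byte. A rod tip exactly on the silhouette counts as invisible (a
zero-measure choice that makes the Monte Carlo match ℘ exactly). Display
rounding is one decimal for percentages and two for diameters; returned
values are never rounded. Degenerate contingency tables (a zero margin)
raise rather than return NaN, and the pipeline skips such comparisons.
Empty inputs raise `ValueError` everywhere; config violations raise pydantic
validation errors naming each offending field.

## Known limitations

The visibility model assumes a spherical particle and a radial rod; flattened
(negatively stained) particles and tilted rods would shift ℘. The fusion
occupancy expression is used in its stated nm-based form; dimensionally it is
a length ratio scaled by the chosen units, a convention inherited as-is. The
multiplicity split is digitised from coarse reported fractions; ternary
mixtures model at most one bridge per particle; and recovery guarantees are
conditional on the generator's independence assumptions listed above.
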