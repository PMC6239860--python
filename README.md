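# lipocount

Counting statistics for protein–lipoprotein complexes in projection electron
microscopy.

In negative-stain EM, lipoproteins (HDL, LDL, VLDL) appear as discs and a
bound cholesteryl ester transfer protein (CETP) is recognisable only as a
rod-shaped protrusion at the disc edge. Quantifying binding from such images
raises three coupled problems that this package solves as a tested, reusable
pipeline:

1. **Occlusion.** A rod attached on the front or back of the sphere never
   clears the silhouette. With no preferred attachment orientation, a rod of
   protrusion length *l* on a sphere of diameter *d* is visible with
   probability ℘ = cos[arcsin(*d*/(*d* + 2*l*))], so observed counts must be
   scaled by 1/℘ (for particles carrying *k* rods, by
   1/(1 − (1 − ℘)^*k*) averaged over the multiplicity distribution). For an
   8 nm protrusion this correction runs from ~8% on a 10 nm HDL to ~32% on a
   30 nm particle.
2. **Morphology models.** Two geometric hypotheses for how the CETP β-barrel
   merges with the lipid surface make testable predictions: *fusion*
   (the segment unfolds over the surface, occupying the fraction
   *d*·*L*/(4*D*) — 31.25% of a 10 nm HDL, so at most one or two CETPs could
   ever bind) versus *penetration* (the intact cylinder inserts radially,
   growing the diameter to (*D*³ + 3⁄2·*L*·*d*²)^(1/3) — 10 → 10.15 nm,
   a shift invisible next to the diameter SD).
3. **Counting statistics.** Bound fractions, CETPs-per-particle multiplicity
   histograms, HDL–CETP–LDL ternary-bridge fractions, Pearson χ² condition
   comparisons (Yates-corrected), geometric-mean particle diameters, 0.5-nm
   histograms with 6th-degree polynomial smoothing, and time-course percent
   size changes.

Because no micrographs ship with the package, a seeded synthetic-population
generator produces per-particle records with the same statistical structure —
class-specific diameter distributions, per-condition binding propensities,
geometric per-rod occlusion, measurement noise, bridging, and HDL shrinkage
over incubation time — with the generative truth retained, so every estimator
is testable for bias and coverage.

## Worked example

```sh
python examples/03_binding_statistics.py
```

```
HDL binding by condition (truth = configured propensity):
  control      observed   9.8%  corrected  10.7%  truth   9.9%
  Torcetrapib  observed  45.8%  corrected  49.8%  truth  50.5%  vs control: chi2=  643.9, p < 2.2e-16
  Dalcetrapib  observed  28.8%  corrected  31.3%  truth  29.2%  vs control: chi2=  230.6, p < 2.2e-16
  Anacetrapib  observed  41.4%  corrected  45.1%  truth  43.1%  vs control: chi2=  523.9, p < 2.2e-16
```

Each line is one simulated experiment arm of 2000 HDL particles. The
*observed* column is the raw fraction of particles showing at least one rod
protrusion — systematically below the configured binding propensity because
of occlusion. The *corrected* column applies the visibility correction using
each particle's measured diameter and recovers the truth to within sampling
error; the χ² column shows every inhibitor contrast against control is
overwhelmingly significant, as expected for 3–5-fold propensity changes.

The other examples cover the geometry models (`01`), Monte Carlo validation
of ℘ (`02`), ternary bridging (`04`), size/time-course analysis (`05`) and
the end-to-end pipeline (`06`). The same pipeline is scriptable from a shell:

```sh
lipocount run --out results/run1 --seed 5
lipocount geometry
lipocount simulate --out sim --seed 3
lipocount analyze --records sim/particles.csv --out analysis
```

`run` writes per-table CSVs plus a single `report.json` that is byte-identical
across reruns with the same config and seed.

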