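# Methods

This note documents the models implemented in `adipoflim`, the parameter
choices that matter, what the synthetic phantoms do and do not emulate,
and the numerical conventions a user must know to reproduce results.

## Decay model and phasor analysis

A pixel's time-resolved signal is modeled as a non-negative mixture of
monoexponential decays excited periodically with repetition period `T`
(default 12.5 ns, an 80 MHz Ti:sapphire oscillator) and detected in `N`
TCSPC bins (default 256).  Bin `i` covers `[iΔ, (i+1)Δ)` with
`Δ = T/N`; all Fourier sums evaluate at bin centers `(i + ½)Δ`.  The
periodized (incomplete-decay) bin integral of a lifetime-τ exponential is
the geometric profile `e^{-t_i/τ}(1-e^{-Δ/τ})/(1-e^{-T/τ})`, which the
phantom renderer uses exactly rather than sampling the continuous decay.

The phasor transform uses the first harmonic by default
(`ω = 2π·harmonic/T`; the harmonic is configurable).  Spatial binning
follows the 5×5-neighborhood convention: each pixel's phasor is computed
from the photon sum of the 5×5 window about it (truncated at edges),
producing per-pixel maps rather than downsampled blocks.  Windows with
fewer than `min_photons` (default 10) photons are flagged invalid instead
of contributing noise-dominated phasors.

**Instrument response and calibration.**  The IRF is modeled as a Gaussian
of configurable FWHM, applied by *circular* convolution over one
repetition period — this respects the periodic excitation, and makes the
IRF exactly multiplicative on the discrete Fourier coefficients.  Because
sample and reference measurements share the IRF, the complex correction
`z → z · z_theory(ref)/z_measured(ref)` removes it exactly in the binned
domain; what remains is the quadrature difference between the binned
exponential and the continuous theory, which is ≈ 2·10⁻³ relative at
τ = 0.3 ns and < 10⁻⁴ at 6.5 ns with 256 bins.  The reference standard's
lifetime is a required configuration input (the value for the
7-hydroxycoumarin standard used in practice is instrument-book knowledge,
not a package constant); synthetic sessions default to 5.4 ns and carry
their own known value, so calibration is self-consistent.

**LLIF.**  The long-lifetime intensity fraction projects a phasor
orthogonally onto the chord joining `theoretical_phasor(τ_short)` and
`theoretical_phasor(τ_long)` (defaults 0.3 ns and 6.5 ns) and divides by
the chord length.  Off-chord phasors are attributed by least squares;
values outside [0, 1] are clamped so the scale stays interpretable.
Because phasors are linear in intensity fractions, a noiseless
two-component decay recovers its generating fraction exactly — this is
the oracle the test suite leans on.

**Density maps and centroids.**  Group-level phasor distributions are
256×256 histograms over g ∈ [0, 1], s ∈ [0, 0.6], peak-normalized.
Per-phasor weighting is unweighted by default with a photon-weighting
flag; the in-vivo white-fat centroid computation uses photon weighting,
since each 5×5-binned phasor already represents its window's photon
content and bright unilocular lipid dominates those fields physically.
Phase lifetime `τ_φ = s/(g·ω)` converts centroids to nanoseconds; it is
exact for monoexponentials and a first-order summary otherwise.

## Optical redox ratio

Two-photon emission scales with the square of excitation power, so raw
counts are divided by power² before any ratio is formed (`IntensityImage`
tracks this state and refuses double normalization).  The per-image scalar
is `mean(FAD)/(mean(NADH)+mean(FAD))` over segmented cytoplasm — the
ratio of means, not the mean of ratios — which bounds it in [0, 1] and
makes it invariant to joint rescaling of both channels.  Per-pixel maps
are computed for visualization only, with lipid pixels masked.

## Segmentation

The implemented rule is declared and parameterized rather than copied
from any particular instrument workflow: (1) Otsu exclusion on the
NAD(P)H intensity histogram (256 bins) removes nuclei and other dim
structures — it presupposes a genuinely dark mode in the image, and
degrades on images with no background at all; (2) within the foreground,
lipid = (FAD below a foreground-restricted Otsu threshold) AND (LLIF
above a cut, default 0.7); (3) connected components under `min_area`
(default 10 px) are reassigned to the surrounding class; (4) optional
erosion of each compartment by a disk (default radius 5 px) suppresses
boundary cross-talk from the 5×5 lifetime binning.  The rule is validated
against phantom ground truth (Dice ≥ 0.9 on default phantoms), not
against any specific historical image set.  Pixels whose phasor window is
photon-starved still count as cytoplasm for redox but are excluded from
LLIF means.

## Synthetic phantoms

The generator produces the study conditions the analysis assumes:

* **Morphology.**  Brown fat: many small droplets (radius 2 ± 0.5 μm,
  packing 0.35); subcutaneous/epididymal white fat: fewer, larger
  droplets (6–8 μm, packing 0.45) placed by rejection sampling with a
  1 px rim clearance.  A `unilocular` mode tiles the field with
  nearest-seed "cells" separated by thin cytoplasm seams, emulating
  unilocular white fat whose droplets exceed the field of view; the
  in-vivo white-fat preset uses it (3 cells on 96 px, ≈ 94 % lipid area,
  lipid 4× brighter than cytoplasm at 460 nm).  Sparse dark nuclei at 2 %
  of the cytoplasm photon level give Otsu exclusion something to remove.
* **Decays.**  Lipid: monoexponential (6.5 ns white, 5.7 ns brown,
  6.1 ns in-vivo white, or an endpoint mixture when a target lipid LLIF
  is prescribed).  Cytoplasm: biexponential 0.3 / 6.5 ns mixture at the
  prescribed intensity fraction.  Rendering = exact binned periodic
  profiles → circular Gaussian IRF → Poisson sampling (noise can be
  disabled, leaving real-valued expectation stacks).
* **FAD channel.**  Intensity-only, set so FAD/(NADH+FAD) equals the
  prescribed redox over cytoplasm and ≈ 0 over lipid.  Phantom channels
  are generated at unit laser power (photon counts are already
  power-equivalent).
* **Group structure.**  Per-image truths are drawn hierarchically:
  cell mean (genotype × temperature × depot) + a per-mouse Normal random
  effect shared across that mouse's depots + per-image Normal noise.
  Default cell means encode the physiological directions (brown fat more
  oxidized and shorter-lived, cold exposure amplifying both, epididymal
  white fat temperature-insensitive); their magnitudes are generator
  choices, not measured values.
* **Bivariate scenarios.**  `generate_bivariate_summaries` draws
  x ~ N(μ, σ²) and y = a + b·x + ε; given a target correlation ρ the
  residual scale is solved analytically as `|b|·σ_x·√(1/ρ² − 1)`.  The
  covariate (NAD(P)H LLIF) uses mean 0.55, sd 0.06 — a mid-range LLIF
  with realistic per-image spread.  The cold-exposed *Crh*⁻/⁻ scWAT
  scenario reuses the brown-fat scenario's absolute residual scale so the
  two regression groups being compared by ANCOVA are homoscedastic.

What phantoms do **not** emulate: optical sectioning and scattering,
depth-dependent attenuation, detector afterpulsing, second-harmonic
contamination, spatially varying IRF, or motion.  Passing tests therefore
demonstrate correctness of the analysis chain under the stated model, not
robustness to every instrument artifact.

## Statistics

The canonical nested mixed-effects ANOVA uses expected-mean-squares F
tests on balanced designs: temperature against the mouse-within-
temperature mean square; depot and temperature×depot against the
residual.  The mouse×depot interaction is pooled into the residual, which
is exact when mouse effects are additive across depots (as the generator
draws them).  Variance components come from the method of moments,
clamped at zero.  Unbalanced tables fall back to unweighted cell means
with the harmonic mean of cell sizes in place of n — adequate for mild
imbalance and flagged as approximate in the result.  A single mouse per
temperature makes the random effect untestable and is signaled as an
error rather than silently absorbed.

Tukey HSD works from summary statistics (means, MS_error, df, n) via the
studentized range, with the Tukey–Kramer correction for unequal n; with
two groups it reproduces the pooled t-test exactly.  ANCOVA compares a
full model (per-group intercept and slope) to a common-slope model by an
F test on the interaction.  MANOVA reports Wilks' Λ with Rao's F
approximation and reduces exactly to one-way ANOVA for a single response.
Heterogeneity summaries report within-cell standard deviations and 95 %
Gaussian data-cloud ellipses (chi-square–scaled covariance); these are
prediction ellipses of the points, not confidence ellipses of the means.

Type-I error of the nested ANOVA and the ANCOVA interaction test is
verified by simulation (1000 null replicates, acceptance band
0.03–0.07 at nominal 0.05).

## Problem sizes and determinism

Test and demo phantoms are 48–128 px with 400–3000 photons/pixel and 256
time bins — large enough that segmentation and LLIF recovery are
photon-limited rather than geometry-limited, small enough to keep the
full suite in tens of seconds.  All randomness flows from one master seed
through named `SeedSequence` substreams; identical configuration + seed
reproduces every array bit for bit, and the pipeline manifest records
SHA-256 checksums of every stage output.

## Known limitations

* The phase-lifetime readout of a centroid is biased toward shorter
  lifetimes for multi-component fields; it is used as a summary, not an
  estimator of any single component.
* Otsu exclusion assumes a dark mode exists; fields with no nuclei or
  background will be split arbitrarily.
* The unbalanced-ANOVA path is an approximation; strongly unbalanced
  designs should use a dedicated REML mixed-model fit instead.
* Erosion by 5 px can annihilate thin compartments in small fields; the
  summary marks such compartments missing rather than guessing.
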