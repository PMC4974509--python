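# adipoflim

Label-free assessment of adipose tissue function from two-photon
intrinsic-fluorescence images: phasor-based fluorescence-lifetime
analysis, optical redox ratio, cytoplasm / lipid-droplet segmentation, and
the nested mixed-effects statistics that distinguish brown, white, and
beige fat — packaged with a synthetic phantom generator that supplies
ground truth for every stage.

## Who this is for

Adipose tissue stores energy (white fat, WAT), burns it for heat (brown
fat, BAT), and can inter-convert (beige fat, BeAT).  Two-photon excited
fluorescence of the endogenous co-enzymes NAD(P)H and FAD, and of lipid
droplets themselves, reports these functional states non-destructively and
at subcellular resolution.  `adipoflim` is for microscopists and
quantitative biologists who have (or want to simulate) two-channel
two-photon data — a time-resolved NAD(P)H/lipid channel (TCSPC photon
histograms) plus an FAD intensity channel — and want per-image metabolic
readouts with defensible statistics.

## The measurements

**Optical redox ratio.**  With intensities normalized by the square of the
incident laser power, the ratio

    redox = FAD / (NAD(P)H + FAD)

formed from mean intensities over segmented cytoplasm is bounded in
[0, 1]; higher values mean a more oxidized, thermogenically active state.

**Phasor lifetime analysis.**  Each pixel's decay I(t) maps to
first-harmonic Fourier coordinates

    g = Σ I(tᵢ) cos(ω tᵢ) / Σ I(tᵢ),   s = Σ I(tᵢ) sin(ω tᵢ) / Σ I(tᵢ),

with ω = 2π/T the angular repetition frequency.  Monoexponential decays
lie on the universal semicircle g = 1/(1+(ωτ)²), s = ωτ/(1+(ωτ)²);
mixtures combine linearly by intensity fraction.  The instrument response
cancels by complex division against a measured reference fluorophore of
known lifetime.  Adipose decays fall on a chord between a short
(0.3 ns, free-NAD(P)H-like) and a long (6.5 ns, lipid-droplet-like)
endpoint; the **long-lifetime intensity fraction (LLIF)** is the
orthogonal projection onto that chord, clamped to [0, 1].

**Segmentation.**  Dim pixels (nuclei) are excluded by Otsu thresholding
of NAD(P)H intensity; within the remaining foreground, lipid droplets are
pixels that are dark in the FAD channel and carry a high LLIF; the rest is
cytoplasm.  Compartments can be eroded by a 5-pixel disk to suppress
boundary cross-talk.

**Statistics.**  Depot and temperature are fixed effects and mouse is a
random effect nested in temperature; balanced designs get exact
expected-mean-squares F tests, with Tukey HSD post-hocs, Pearson
correlations, OLS slopes, an ANCOVA homogeneity-of-slopes test, one-way
MANOVA (Wilks' Λ), and per-group heterogeneity / 95 % ellipse summaries.

## Worked example

`examples/` holds one narrative script per capability.  The first renders
a brown-fat phantom and reads its lifetime signature off the phasor:

```bash
$ python examples/01_phantom_and_phasor.py
phantom: BAT, 128x128 px, 35% lipid area
phasor centroid (g, s) = (0.411, 0.244)
centroid phase lifetime = 1.18 ns
mean LLIF over lipid     = 0.852
mean LLIF over cytoplasm = 0.522
```

A centroid phase lifetime of ~1.2 ns is the brown-fat signature: the
distribution stretches along the 0.3–6.5 ns chord because short-lived
cytoplasmic NAD(P)H dominates the photon budget.  The lipid LLIF of 0.85
reflects droplets generated at 5.7 ns (brown-fat droplets are shorter-lived
than the 6.5 ns droplets of white fat, which project to LLIF ≈ 1).

`examples/02` recovers redox and LLIF from a white-fat phantom
(segmentation Dice 1.00, redox 0.250 against a generating truth of 0.25);
`examples/03` runs the nested ANOVA; `examples/04` the bivariate and
multivariate layer; `examples/05` the full pipeline:

```bash
adipoflim run --config examples/demo.yaml --out runs/demo --seed 7
```

which writes phantom images, per-image summaries, statistics tables, a
markdown report, and a manifest with SHA-256 checksums.  Reruns with the
same seed reproduce `summary.csv` byte for byte.

## Layout

```
src/adipoflim/      containers, io, config, phantom, experiment,
                    phasor, segmentation, stats, pipeline, cli
examples/           one runnable narrative script per capability
tests/              pytest suite (unit, property, acceptance)
scripts/            acceptance.py
docs/methods.md     models, assumptions, parameter choices, limitations
```
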