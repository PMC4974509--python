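"""Synthetic adipose-tissue FLIM phantoms with full ground truth.

A phantom emulates a single two-photon field of adipose tissue at the
NAD(P)H/lipid-droplet channel (time-resolved) and the FAD channel
(intensity only):

* lipid droplets — non-overlapping discs (large/unilocular for white fat,
  small/multilocular for brown fat; discs may be clipped by the field of
  view, as real white adipocytes often are) with near-monoexponential
  long-lifetime emission and weak-to-absent FAD signal;
* cytoplasm — everything else in the foreground, emitting a biexponential
  mixture of a short free-NAD(P)H-like component and a long bound/lipid-like
  component, with FAD intensity set so that FAD/(NAD(P)H+FAD) equals the
  prescribed redox ratio;
* nuclei — sparse dark ellipses at a few percent of the cytoplasm photon
  level, so intensity-based exclusion has something to exclude.

Decays are periodized over the laser repetition period (incomplete-decay
wrap-around), circularly convolved with a Gaussian instrument response,
binned into TCSPC bins, and Poisson-sampled.  All randomness flows from
the spec seed, so identical specs yield bit-identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
from skimage.draw import disk, ellipse

from .containers import DecayStack, IntensityImage
from .exceptions import PackingError, ValidationError

__all__ = [
    "LABEL_BACKGROUND",
    "LABEL_CYTOPLASM",
    "LABEL_LIPID",
    "TissuePhantomSpec",
    "PhantomGroundTruth",
    "TISSUE_PRESETS",
    "generate_phantom_geometry",
    "render_decay_stack",
    "generate_reference_measurement",
]

LABEL_BACKGROUND = 0
LABEL_CYTOPLASM = 1
LABEL_LIPID = 2


@dataclass
class TissuePhantomSpec:
    """Parameters of one synthetic tissue field.

    Lifetimes in ns, radii in μm, ``photons_per_pixel`` is the expected
    NAD(P)H-channel photon total of a cytoplasm pixel.  ``cyto_llif`` is the
    true long-lifetime intensity fraction of the cytoplasm biexponential;
    ``true_redox`` the cytoplasm FAD/(NAD(P)H+FAD) ratio.
    """

    tissue_type: str = "BAT"
    droplet_radius_mean: float = 2.0
    droplet_radius_sd: float = 0.5
    packing_fraction: float = 0.35
    droplet_count: int | None = None
    allow_clipping: bool = False
    unilocular: bool = False             # tile the field with droplet "cells"
                                         # separated by thin cytoplasm seams
    rim_thickness: float = 1.0           # px, min clearance between droplets
    nucleus_count: int = 4
    nucleus_axes: tuple[float, float] = (2.0, 1.2)  # μm semi-axes
    lipid_lifetime: float = 6.5
    lipid_llif: float | None = None      # if set, lipid is a tau_long/tau_short
                                         # mixture at this intensity fraction
    cyto_llif: float = 0.7
    tau_short: float = 0.3
    tau_long: float = 6.5
    true_redox: float = 0.3
    lipid_intensity_factor: float = 1.0  # lipid vs cytoplasm brightness, 460 nm
    fad_lipid_level: float = 0.0         # FAD over lipid, fraction of cyto FAD
    background_level: float = 0.02       # nuclei photons, fraction of cytoplasm
    photons_per_pixel: float = 1000.0
    irf_fwhm: float = 0.2
    irf_center: float = 1.0              # ns, mean arrival delay of the IRF
    image_size: int = 128
    pixel_size: float = 0.36
    rep_period: float = 12.5
    n_time_bins: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.cyto_llif <= 1:
            raise ValidationError("cyto_llif must lie in [0, 1]")
        if not 0 <= self.true_redox < 1:
            raise ValidationError("true_redox must lie in [0, 1)")
        if not 0 < self.tau_short < self.tau_long:
            raise ValidationError("need 0 < tau_short < tau_long")
        if self.lipid_lifetime <= 0:
            raise ValidationError("lipid_lifetime must be > 0")
        if self.photons_per_pixel < 0 or self.irf_fwhm < 0:
            raise ValidationError("photon budget and irf_fwhm must be >= 0")
        if self.image_size < 5:
            raise ValidationError("image_size must be >= 5")
        if self.droplet_count is None and not 0 <= self.packing_fraction < 1:
            raise ValidationError("packing_fraction must lie in [0, 1)")


#: Per-tissue defaults.  White depots carry few large droplets, a long lipid
#: lifetime and a reduced (more reduced ↔ lower redox) cytoplasm; brown fat
#: carries many small droplets, a shorter lipid lifetime, lower cytoplasm
#: LLIF and a higher (more oxidized) redox ratio.  ``WAT_invivo`` models the
#: in-vivo white-fat field whose cumulative phasor sits near the 6.1 ns arc
#: point: nearly unilocular bright lipid with a thin, long-lifetime rim.
TISSUE_PRESETS: dict[str, dict[str, Any]] = {
    "BAT": dict(
        tissue_type="BAT", droplet_radius_mean=2.0, droplet_radius_sd=0.5,
        packing_fraction=0.35, lipid_lifetime=5.7, cyto_llif=0.45,
        true_redox=0.45,
    ),
    "scWAT": dict(
        tissue_type="scWAT", droplet_radius_mean=6.0, droplet_radius_sd=1.5,
        packing_fraction=0.45, lipid_lifetime=6.5, cyto_llif=0.8,
        true_redox=0.25,
    ),
    "epiWAT": dict(
        tissue_type="epiWAT", droplet_radius_mean=8.0, droplet_radius_sd=2.0,
        packing_fraction=0.45, lipid_lifetime=6.5, cyto_llif=0.85,
        true_redox=0.2,
    ),
    "WAT_invivo": dict(
        tissue_type="epiWAT", droplet_radius_mean=20.0, droplet_radius_sd=3.0,
        droplet_count=3, unilocular=True, nucleus_count=0,
        lipid_lifetime=6.1, cyto_llif=0.9, true_redox=0.2,
        lipid_intensity_factor=4.0, image_size=96,
    ),
}


def tissue_spec(name: str, **overrides: Any) -> TissuePhantomSpec:
    """A :class:`TissuePhantomSpec` from a named preset plus overrides."""
    if name not in TISSUE_PRESETS:
        raise ValidationError(f"unknown tissue preset {name!r}; "
                              f"available: {sorted(TISSUE_PRESETS)}")
    params = dict(TISSUE_PRESETS[name])
    params.update(overrides)
    return TissuePhantomSpec(**params)


@dataclass
class PhantomGroundTruth:
    """True labels and generating parameters of a rendered phantom."""

    label_image: np.ndarray
    lipid_lifetime: float
    cyto_llif: float
    tau_short: float
    tau_long: float
    true_redox: float
    seed: int
    spec: TissuePhantomSpec | None = None


def _rng(seed: int, *streams: int) -> np.random.Generator:
    """Deterministic per-stage substream of one master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *streams]))


def generate_phantom_geometry(spec: TissuePhantomSpec) -> np.ndarray:
    """Draw the label image of one phantom field.

    Non-overlapping lipid discs are placed by rejection sampling until the
    target count or packing fraction is reached (a bounded attempt budget
    guards infeasible targets); discs keep a clearance of ``rim_thickness``
    pixels so every droplet is surrounded by cytoplasm.  Remaining
    foreground is cytoplasm; sparse dark nuclei are labeled background.

    ``spec.unilocular`` instead tiles the whole field with droplet "cells"
    (nearest-seed partition of ``droplet_count`` random seeds) separated by
    thin cytoplasm seams of half-width ``rim_thickness`` — the morphology of
    unilocular white fat, where single droplets larger than the field of
    view abut along thin cytoplasmic rims.  Deterministic given
    ``spec.seed``.
    """
    rng = _rng(spec.seed, 1)
    n = spec.image_size
    labels = np.full((n, n), LABEL_CYTOPLASM, dtype=np.uint8)

    if spec.unilocular:
        return _unilocular_geometry(spec, rng)

    r_mean_px = spec.droplet_radius_mean / spec.pixel_size
    r_sd_px = spec.droplet_radius_sd / spec.pixel_size
    target_area = spec.packing_fraction * n * n
    target_count = spec.droplet_count

    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    lipid_area = 0.0
    max_attempts = 1000 * max(target_count or 100, 100)
    attempts = 0
    while True:
        if target_count is not None:
            if len(centers) >= target_count:
                break
        elif lipid_area >= target_area:
            break
        if attempts >= max_attempts:
            raise PackingError(
                f"could not reach droplet target after {max_attempts} attempts "
                f"(placed {len(centers)}, lipid fraction {lipid_area / n**2:.2f})"
            )
        attempts += 1
        r = max(1.0, rng.normal(r_mean_px, r_sd_px))
        if spec.allow_clipping:
            cy, cx = rng.uniform(0, n, size=2)
        else:
            if 2 * r + 2 >= n:
                continue
            cy, cx = rng.uniform(r + 1, n - r - 1, size=2)
        ok = True
        for (oy, ox), orad in zip(centers, radii):
            if (cy - oy) ** 2 + (cx - ox) ** 2 < (r + orad + spec.rim_thickness) ** 2:
                ok = False
                break
        if not ok:
            continue
        rr, cc = disk((cy, cx), r, shape=labels.shape)
        centers.append((cy, cx))
        radii.append(r)
        labels[rr, cc] = LABEL_LIPID
        lipid_area += rr.size

    # nuclei: dark ellipses dropped into cytoplasm only
    ay = spec.nucleus_axes[0] / spec.pixel_size
    ax = spec.nucleus_axes[1] / spec.pixel_size
    placed = 0
    for _ in range(50 * max(spec.nucleus_count, 1)):
        if placed >= spec.nucleus_count:
            break
        cy, cx = rng.uniform(0, n, size=2)
        theta = rng.uniform(0, np.pi)
        rr, cc = ellipse(cy, cx, ay, ax, shape=labels.shape, rotation=theta)
        if rr.size and np.all(labels[rr, cc] == LABEL_CYTOPLASM):
            labels[rr, cc] = LABEL_BACKGROUND
            placed += 1
    return labels


def _unilocular_geometry(
    spec: TissuePhantomSpec, rng: np.random.Generator
) -> np.ndarray:
    n = spec.image_size
    k = spec.droplet_count or max(2, int(round((n / (2 * spec.droplet_radius_mean / spec.pixel_size)) ** 2)))
    seeds = rng.uniform(0, n, size=(k, 2))
    yy, xx = np.mgrid[0:n, 0:n]
    d2 = (yy[..., None] - seeds[:, 0]) ** 2 + (xx[..., None] - seeds[:, 1]) ** 2
    cell = np.argmin(d2, axis=-1)
    labels = np.full((n, n), LABEL_LIPID, dtype=np.uint8)
    # cytoplasm seam: pixels within rim_thickness of a cell boundary
    seam = np.zeros((n, n), dtype=bool)
    r = max(int(np.ceil(spec.rim_thickness)), 1)
    for dy, dx in ((0, 1), (1, 0), (1, 1), (1, -1)):
        for step in range(1, r + 1):
            shifted = np.roll(np.roll(cell, step * dy, axis=0), step * dx, axis=1)
            seam |= cell != shifted
    labels[seam] = LABEL_CYTOPLASM
    return labels


def binned_periodic_decay(
    tau: float, n_time_bins: int, rep_period: float
) -> np.ndarray:
    """Exact bin integrals of a periodized monoexponential, normalized to 1.

    The decay ``exp(-t/τ)`` is summed over all previous excitation periods
    (incomplete-decay wrap-around) and integrated over each TCSPC bin; the
    result is the geometric profile ``e^{-tᵢ/τ}(1-e^{-Δ/τ})/(1-e^{-T/τ})``.
    """
    if tau <= 0:
        raise ValidationError("tau must be > 0")
    dt = rep_period / n_time_bins
    t0 = np.arange(n_time_bins) * dt
    f = np.exp(-t0 / tau) * -np.expm1(-dt / tau)
    return f / f.sum()


def gaussian_irf_kernel(
    fwhm: float, center: float, n_time_bins: int, rep_period: float
) -> np.ndarray:
    """Circular (wrapped) Gaussian IRF kernel sampled on the bin lattice."""
    dt = rep_period / n_time_bins
    if fwhm == 0:
        k = np.zeros(n_time_bins)
        k[int(round(center / dt)) % n_time_bins] = 1.0
        return k
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    t = np.arange(n_time_bins) * dt
    d = np.abs(t - center)
    d = np.minimum(d, rep_period - d)
    k = np.exp(-0.5 * (d / sigma) ** 2)
    return k / k.sum()


def _convolve_circular(decay: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    n = decay.shape[-1]
    out = np.fft.irfft(np.fft.rfft(decay) * np.fft.rfft(kernel), n)
    return np.clip(out, 0.0, None)


def decay_template(
    tau_components: np.ndarray | list[float],
    fractions: np.ndarray | list[float],
    spec: TissuePhantomSpec,
) -> np.ndarray:
    """IRF-convolved, binned expected decay of an intensity-fraction mixture,
    normalized to unit total."""
    tau_components = np.asarray(tau_components, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    decay = np.zeros(spec.n_time_bins)
    for tau, frac in zip(tau_components, fractions):
        if frac > 0:
            decay += frac * binned_periodic_decay(tau, spec.n_time_bins, spec.rep_period)
    kernel = gaussian_irf_kernel(
        spec.irf_fwhm, spec.irf_center, spec.n_time_bins, spec.rep_period
    )
    decay = _convolve_circular(decay, kernel)
    return decay / decay.sum()


def render_decay_stack(
    labels: np.ndarray,
    spec: TissuePhantomSpec,
    noise: bool = True,
) -> tuple[DecayStack, IntensityImage, PhantomGroundTruth]:
    """Render a label image into an NAD(P)H decay stack and FAD intensity.

    Per-pixel expected decays: lipid — monoexponential ``lipid_lifetime``;
    cytoplasm — ``cyto_llif`` long + ``(1-cyto_llif)`` short intensity-
    fraction mixture; background — the cytoplasm decay at a few percent of
    its amplitude.  FAD intensity is set so that FAD/(NAD(P)H+FAD) equals
    ``true_redox`` over cytoplasm and ≈0 over lipid.  With ``noise=False``
    the stack carries the real-valued expected counts; with ``noise=True``
    both channels are Poisson-sampled from their expectations.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValidationError("labels must be a 2-D image")
    rng = _rng(spec.seed, 2)

    if spec.lipid_llif is None:
        lipid_template = decay_template([spec.lipid_lifetime], [1.0], spec)
    else:
        lipid_template = decay_template(
            [spec.tau_long, spec.tau_short],
            [spec.lipid_llif, 1.0 - spec.lipid_llif],
            spec,
        )
    templates = {
        LABEL_LIPID: lipid_template,
        LABEL_CYTOPLASM: decay_template(
            [spec.tau_long, spec.tau_short],
            [spec.cyto_llif, 1.0 - spec.cyto_llif],
            spec,
        ),
    }
    templates[LABEL_BACKGROUND] = templates[LABEL_CYTOPLASM]

    amplitude = np.zeros(labels.shape)
    amplitude[labels == LABEL_CYTOPLASM] = spec.photons_per_pixel
    amplitude[labels == LABEL_LIPID] = spec.photons_per_pixel * spec.lipid_intensity_factor
    amplitude[labels == LABEL_BACKGROUND] = spec.photons_per_pixel * spec.background_level

    expected = np.zeros(labels.shape + (spec.n_time_bins,))
    for lab, tpl in templates.items():
        m = labels == lab
        if np.any(m):
            expected[m] = amplitude[m][:, None] * tpl[None, :]

    if np.nanmax(expected) >= np.iinfo(np.uint32).max:
        raise ValidationError("expected counts overflow the uint32 container")

    if noise:
        counts = rng.poisson(expected).astype(np.uint32)
    else:
        counts = expected  # real-valued expectation stack
    stack = DecayStack(
        counts=counts,
        time_bin_width=spec.rep_period / spec.n_time_bins,
        rep_period=spec.rep_period,
        pixel_size=spec.pixel_size,
        channel_label="NADH",
    )

    # FAD channel: cytoplasm intensity solves FAD/(NADH+FAD) = true_redox
    redox_factor = spec.true_redox / (1.0 - spec.true_redox)
    fad = np.zeros(labels.shape)
    fad[labels == LABEL_CYTOPLASM] = redox_factor * spec.photons_per_pixel
    fad[labels == LABEL_LIPID] = (
        spec.fad_lipid_level * redox_factor * spec.photons_per_pixel
    )
    fad[labels == LABEL_BACKGROUND] = (
        redox_factor * spec.photons_per_pixel * spec.background_level
    )
    if noise:
        fad = rng.poisson(fad).astype(float)
    fad_image = IntensityImage(
        values=fad,
        normalization_state="raw_counts",
        channel_label="FAD",
        pixel_size=spec.pixel_size,
    )

    truth = PhantomGroundTruth(
        label_image=labels.copy(),
        lipid_lifetime=spec.lipid_lifetime,
        cyto_llif=spec.cyto_llif,
        tau_short=spec.tau_short,
        tau_long=spec.tau_long,
        true_redox=spec.true_redox,
        seed=spec.seed,
        spec=spec,
    )
    return stack, fad_image, truth


def generate_reference_measurement(
    reference_lifetime: float,
    spec: TissuePhantomSpec,
    noise: bool = False,
    shape: tuple[int, int] = (16, 16),
    photons_per_pixel: float | None = None,
) -> DecayStack:
    """Spatially uniform monoexponential reference stack.

    Shares the sample spec's IRF, binning and repetition period, emulating
    the standard-fluorophore measurement taken before each imaging session.
    """
    if reference_lifetime <= 0:
        raise ValidationError("reference_lifetime must be > 0")
    budget = spec.photons_per_pixel if photons_per_pixel is None else photons_per_pixel
    tpl = decay_template([reference_lifetime], [1.0], spec)
    expected = np.broadcast_to(budget * tpl, shape + (spec.n_time_bins,)).copy()
    if noise:
        rng = _rng(spec.seed, 3)
        counts = rng.poisson(expected).astype(np.uint32)
    else:
        counts = expected
    return DecayStack(
        counts=counts,
        time_bin_width=spec.rep_period / spec.n_time_bins,
        rep_period=spec.rep_period,
        pixel_size=spec.pixel_size,
        channel_label="NADH",
    )
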