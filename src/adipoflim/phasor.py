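"""Phasor analysis of fluorescence lifetime data.

The phasor transform maps a per-pixel fluorescence decay ``I(t)`` to the
first-harmonic Fourier coordinates

    g = Σᵢ Iᵢ cos(ω tᵢ) / Σᵢ Iᵢ,      s = Σᵢ Iᵢ sin(ω tᵢ) / Σᵢ Iᵢ,

with ``ω = 2π·harmonic / rep_period`` and ``tᵢ`` the time-bin centers.
Monoexponential decays lie on the "universal semicircle"
``g = 1/(1+(ωτ)²)``, ``s = ωτ/(1+(ωτ)²)``; mixtures fall inside it and
combine linearly with intensity-fraction weights.  The instrument response
multiplies every phasor by the same complex factor, so dividing by the
measured phasor of a reference fluorophore of known lifetime — and
multiplying by that lifetime's theoretical phasor — removes it exactly.

The long-lifetime intensity fraction (LLIF) of a two-component trajectory
is obtained by orthogonal projection of a phasor onto the chord joining the
trajectory endpoints; relative distances along the chord are exactly the
intensity fractions of the two components.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter

from .containers import DecayStack
from .exceptions import CalibrationError, ValidationError

__all__ = [
    "PhasorField",
    "PhasorDensityMap",
    "LLIFMap",
    "ReferenceCalibration",
    "angular_frequency",
    "theoretical_phasor",
    "phasor_transform",
    "calibrate",
    "llif",
    "density_map",
    "centroid",
    "lifetime_from_phasor",
]


def angular_frequency(rep_period: float, harmonic: int = 1) -> float:
    """Angular frequency ω = 2π·harmonic / rep_period, rad/ns."""
    if rep_period <= 0 or harmonic < 1:
        raise ValidationError("rep_period must be > 0 and harmonic >= 1")
    return 2.0 * np.pi * harmonic / rep_period


def theoretical_phasor(tau, omega: float):
    """Phasor of an ideal monoexponential decay of lifetime ``tau`` (ns).

    Returns ``(g, s)`` with ``g = 1/(1+(ωτ)²)`` and ``s = ωτ/(1+(ωτ)²)``;
    the point lies exactly on the universal semicircle
    ``(g - 1/2)² + s² = 1/4``.  ``tau`` may be an array.
    """
    if omega <= 0:
        raise ValidationError("omega must be > 0")
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValidationError("tau must be >= 0")
    wt = omega * tau
    denom = 1.0 + wt * wt
    g = 1.0 / denom
    s = wt / denom
    if g.ndim == 0:
        return float(g), float(s)
    return g, s


def lifetime_from_phasor(g, s, omega: float):
    """Phase lifetime τ_φ = s / (g·ω), ns.  Exact for monoexponentials."""
    g = np.asarray(g, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(g <= 0):
        raise ValidationError("phase lifetime undefined for g <= 0")
    tau = s / (g * omega)
    return float(tau) if tau.ndim == 0 else tau


@dataclass
class PhasorField:
    """Per-pixel phasor coordinates on the spatially binned grid.

    ``g``/``s`` are full-resolution maps (one value per image pixel, each
    computed from the photon sum of the ``bin_factor``×``bin_factor``
    neighborhood about that pixel, truncated at the image edge).  ``weight``
    is the photon total of each neighborhood; bins with fewer than the
    validity threshold are flagged in ``valid``.
    """

    g: np.ndarray
    s: np.ndarray
    weight: np.ndarray
    omega: float
    bin_factor: int = 5
    valid: np.ndarray | None = None
    calibrated: bool = False

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.isfinite(self.g) & np.isfinite(self.s)
        if not (self.g.shape == self.s.shape == self.weight.shape == self.valid.shape):
            raise ValidationError("g, s, weight and valid must share one shape")
        if np.any(self.weight[np.isfinite(self.weight)] < 0):
            raise ValidationError("weights must be >= 0")

    @property
    def z(self) -> np.ndarray:
        """Phasors as complex numbers g + i·s."""
        return self.g + 1j * self.s


@dataclass
class PhasorDensityMap:
    """Peak-normalized 2-D histogram of phasor coordinates."""

    hist: np.ndarray
    g_edges: np.ndarray
    s_edges: np.ndarray
    omega: float

    def __post_init__(self) -> None:
        if self.hist.size and self.hist.max() > 0:
            self.hist = self.hist / self.hist.max()


@dataclass
class LLIFMap:
    """Per-pixel long-lifetime intensity fraction, clamped to [0, 1]."""

    values: np.ndarray
    tau_short: float
    tau_long: float
    valid: np.ndarray


@dataclass
class ReferenceCalibration:
    """Measured vs. theoretical phasor of the calibration standard."""

    g_measured: float
    s_measured: float
    reference_lifetime: float
    omega: float

    def __post_init__(self) -> None:
        if self.reference_lifetime <= 0:
            raise ValidationError("reference_lifetime must be > 0")
        if abs(self.g_measured + 1j * self.s_measured) < 1e-12:
            raise CalibrationError("measured reference phasor has zero modulus")

    @property
    def correction(self) -> complex:
        """Complex factor z_theory / z_measured applied to sample phasors."""
        g_th, s_th = theoretical_phasor(self.reference_lifetime, self.omega)
        return (g_th + 1j * s_th) / (self.g_measured + 1j * self.s_measured)

    @classmethod
    def from_stack(
        cls, stack: DecayStack, reference_lifetime: float, harmonic: int = 1
    ) -> "ReferenceCalibration":
        """Calibration from a measured reference decay (all pixels pooled)."""
        omega = angular_frequency(stack.rep_period, harmonic)
        decay = stack.counts.sum(axis=(0, 1)).astype(float)
        total = decay.sum()
        if total <= 0:
            raise CalibrationError("reference stack contains no photons")
        t = stack.bin_centers
        g = float((decay * np.cos(omega * t)).sum() / total)
        s = float((decay * np.sin(omega * t)).sum() / total)
        return cls(g_measured=g, s_measured=s,
                   reference_lifetime=reference_lifetime, omega=omega)


def _window_sum(image: np.ndarray, size: int) -> np.ndarray:
    """Sum over a size×size neighborhood, truncated at image edges."""
    if size == 1:
        return image
    # uniform_filter with constant padding gives the truncated-window *sum*
    # after multiplying by size²  (zeros outside contribute nothing).
    return uniform_filter(image, size=size, mode="constant", cval=0.0) * size**2


def phasor_transform(
    stack: DecayStack,
    harmonic: int = 1,
    bin_factor: int = 5,
    min_photons: int = 10,
) -> PhasorField:
    """Phasor transform of a decay stack with spatial neighborhood binning.

    For every pixel, photon counts are accumulated over the
    ``bin_factor``×``bin_factor`` neighborhood (truncated at edges) and the
    first-harmonic sine/cosine transforms evaluated at bin centers.  Bins
    whose photon total falls below ``min_photons`` are flagged invalid.
    """
    if bin_factor < 1 or bin_factor % 2 == 0:
        raise ValidationError(f"bin_factor must be odd; got {bin_factor}")
    omega = angular_frequency(stack.rep_period, harmonic)
    t = stack.bin_centers
    counts = stack.counts.astype(float)
    total = counts.sum(axis=2)
    num = counts @ np.exp(1j * omega * t)  # per-pixel Fourier numerator

    total_b = _window_sum(total, bin_factor)
    num_b = _window_sum(num.real, bin_factor) + 1j * _window_sum(num.imag, bin_factor)

    # window sums are integers in exact arithmetic; the half-count margin
    # absorbs uniform_filter's float rounding
    valid = total_b >= max(min_photons, 1) - 0.5
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(valid, num_b / np.where(total_b > 0, total_b, 1.0), np.nan)
    return PhasorField(
        g=z.real,
        s=z.imag,
        weight=total_b,
        omega=omega,
        bin_factor=bin_factor,
        valid=valid,
        calibrated=False,
    )


def calibrate(field: PhasorField, ref: ReferenceCalibration) -> PhasorField:
    """Correct a phasor field for the instrument response.

    Treating phasors as complex numbers ``z = g + i·s``, every sample phasor
    is multiplied by ``z_theory(ref) / z_measured(ref)``.  A sample sharing
    the reference's instrument response and having lifetime τ then maps onto
    ``theoretical_phasor(τ)``.
    """
    if not np.isclose(field.omega, ref.omega, rtol=1e-9):
        raise CalibrationError(
            f"field omega {field.omega:g} != reference omega {ref.omega:g}"
        )
    z = field.z * ref.correction
    return replace(field, g=z.real, s=z.imag, calibrated=True)


def llif(field: PhasorField, tau_short: float, tau_long: float) -> LLIFMap:
    """Long-lifetime intensity fraction by projection onto the chord.

    With endpoint phasors P₀ = theoretical_phasor(tau_short) and
    P₁ = theoretical_phasor(tau_long), the fraction is the scalar projection
    of (P − P₀) onto (P₁ − P₀) divided by |P₁ − P₀|, clamped to [0, 1].
    Because phasors combine linearly with intensity fractions, a noiseless
    two-component mixture recovers its true long-component fraction exactly.
    """
    if not tau_short < tau_long:
        raise ValidationError("tau_short must be < tau_long")
    p0 = np.array(theoretical_phasor(tau_short, field.omega))
    p1 = np.array(theoretical_phasor(tau_long, field.omega))
    chord = p1 - p0
    norm2 = float(chord @ chord)
    if norm2 < 1e-20:
        raise ValidationError("degenerate trajectory endpoints")
    frac = ((field.g - p0[0]) * chord[0] + (field.s - p0[1]) * chord[1]) / norm2
    frac = np.clip(frac, 0.0, 1.0)
    frac = np.where(field.valid, frac, np.nan)
    return LLIFMap(values=frac, tau_short=tau_short, tau_long=tau_long,
                   valid=field.valid.copy())


def density_map(
    fields: PhasorField | Sequence[PhasorField],
    bins: int = 256,
    g_range: tuple[float, float] = (0.0, 1.0),
    s_range: tuple[float, float] = (0.0, 0.6),
    weighted: bool = False,
) -> PhasorDensityMap:
    """Accumulate phasors from one or more fields into a peak-normalized
    2-D histogram over (g, s).

    ``weighted=True`` weights each phasor by its photon total; the default
    counts each valid bin once.
    """
    if isinstance(fields, PhasorField):
        fields = [fields]
    if not fields:
        raise ValidationError("no phasor fields given")
    omega = fields[0].omega
    gs, ss, ws = [], [], []
    for f in fields:
        if not np.isclose(f.omega, omega, rtol=1e-9):
            raise ValidationError("all fields must share one omega")
        m = f.valid
        gs.append(f.g[m])
        ss.append(f.s[m])
        ws.append(f.weight[m])
    g = np.concatenate(gs)
    s = np.concatenate(ss)
    if g.size == 0:
        raise ValidationError("no valid phasors to accumulate")
    w = np.concatenate(ws) if weighted else None
    hist, g_edges, s_edges = np.histogram2d(
        g, s, bins=bins, range=[list(g_range), list(s_range)], weights=w
    )
    return PhasorDensityMap(hist=hist, g_edges=g_edges, s_edges=s_edges, omega=omega)


def centroid(
    obj: PhasorField | PhasorDensityMap,
    mask: np.ndarray | None = None,
    weighted: bool = False,
) -> tuple[float, float]:
    """Centroid (mean g, mean s) of a phasor field or density map.

    For a field the mean is taken over valid entries, optionally restricted
    by ``mask`` and optionally photon-weighted.  For a density map the
    histogram-weighted mean of the cell centers is returned.
    """
    if isinstance(obj, PhasorDensityMap):
        total = obj.hist.sum()
        if total <= 0:
            raise ValidationError("empty density map")
        gc = 0.5 * (obj.g_edges[:-1] + obj.g_edges[1:])
        sc = 0.5 * (obj.s_edges[:-1] + obj.s_edges[1:])
        g = float((obj.hist.sum(axis=1) * gc).sum() / total)
        s = float((obj.hist.sum(axis=0) * sc).sum() / total)
        return g, s
    m = obj.valid if mask is None else (obj.valid & mask)
    if not np.any(m):
        raise ValidationError("no valid phasors selected")
    if weighted:
        w = obj.weight[m]
        return float((obj.g[m] * w).sum() / w.sum()), float((obj.s[m] * w).sum() / w.sum())
    return float(obj.g[m].mean()), float(obj.s[m].mean())
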