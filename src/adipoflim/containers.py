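"""Core data containers for time-resolved and steady-state two-photon data.

A :class:`DecayStack` holds the TCSPC photon-count histogram of one image:
``counts[row, col, t]`` is the number of photons detected in time bin ``t``
at pixel ``(row, col)``.  Time bin ``i`` covers ``[i*dt, (i+1)*dt)`` and all
phasor integrals use bin centers ``(i + 1/2)*dt``.  Spatial indexing is
0-based ``(row, col)`` with pixel ``(0, 0)`` at the top-left.

An :class:`IntensityImage` holds a steady-state (or time-integrated)
fluorescence image together with its normalization state: raw photon counts,
or counts divided by the square of the incident laser power, which is the
quantity two-photon intensity ratios are formed from.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .exceptions import ValidationError

CHANNEL_LABELS = ("NADH", "FAD")

#: Default laser repetition period in ns (80 MHz Ti:sapphire oscillator).
DEFAULT_REP_PERIOD_NS = 12.5
#: Default number of TCSPC time bins.
DEFAULT_N_TIME_BINS = 256
#: Minimum spatial extent required by the 5x5 phasor binning.
MIN_SPATIAL_DIM = 5

NormalizationState = Literal["raw_counts", "power_normalized"]


@dataclass
class DecayStack:
    """Time-resolved photon-count image with acquisition metadata.

    Parameters
    ----------
    counts
        Non-negative integer array of shape ``(rows, cols, n_time_bins)``.
    time_bin_width
        Width of one TCSPC bin, ns.
    rep_period
        Laser repetition period (inverse repetition rate), ns.
    pixel_size
        Lateral sampling, μm / pixel.
    laser_power
        Average excitation power at the sample, mW.
    excitation_nm, emission_center_nm, emission_halfwidth_nm
        Spectral channel definition, nm.
    channel_label
        Either ``"NADH"`` (the 460 nm NAD(P)H / lipid-droplet channel) or
        ``"FAD"``.
    """

    counts: np.ndarray
    time_bin_width: float
    rep_period: float = DEFAULT_REP_PERIOD_NS
    pixel_size: float = 0.36
    laser_power: float = 1.0
    excitation_nm: float = 755.0
    emission_center_nm: float = 460.0
    emission_halfwidth_nm: float = 20.0
    channel_label: str = "NADH"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValidationError(
                f"counts must be 3-D (rows, cols, time); got ndim={self.counts.ndim}"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            # real-valued stacks are allowed in memory: they represent the
            # expected (noise-free) photon counts of a simulated decay
            self.counts = self.counts.astype(float)
        if self.counts.size and self.counts.min() < 0:
            raise ValidationError("counts must be non-negative everywhere")
        if self.counts.shape[0] < MIN_SPATIAL_DIM or self.counts.shape[1] < MIN_SPATIAL_DIM:
            raise ValidationError(
                f"spatial dimensions must be >= {MIN_SPATIAL_DIM}; got "
                f"{self.counts.shape[:2]}"
            )
        if self.time_bin_width <= 0 or self.rep_period <= 0:
            raise ValidationError("time_bin_width and rep_period must be positive")
        span = self.n_time_bins * self.time_bin_width
        if span > self.rep_period * (1 + 1e-9):
            raise ValidationError(
                f"time axis ({span:g} ns) exceeds repetition period "
                f"({self.rep_period:g} ns)"
            )
        if self.channel_label not in CHANNEL_LABELS:
            raise ValidationError(
                f"channel_label must be one of {CHANNEL_LABELS}; got "
                f"{self.channel_label!r}"
            )

    @property
    def n_time_bins(self) -> int:
        return self.counts.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    @property
    def bin_centers(self) -> np.ndarray:
        """Time-bin centers in ns (midpoint convention)."""
        return (np.arange(self.n_time_bins) + 0.5) * self.time_bin_width

    def total_photons(self) -> float:
        return float(self.counts.sum())


@dataclass
class IntensityImage:
    """A 2-D fluorescence intensity image with explicit normalization state."""

    values: np.ndarray
    normalization_state: NormalizationState = "raw_counts"
    channel_label: str = "NADH"
    pixel_size: float = 0.36
    laser_power: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("intensity values must be 2-D")
        if self.values.size and np.nanmin(self.values) < 0:
            raise ValidationError("intensity values must be non-negative")
        if self.normalization_state not in ("raw_counts", "power_normalized"):
            raise ValidationError(
                f"unknown normalization_state {self.normalization_state!r}"
            )
        if self.channel_label not in CHANNEL_LABELS:
            raise ValidationError(
                f"channel_label must be one of {CHANNEL_LABELS}; got "
                f"{self.channel_label!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class AcquisitionMetadata:
    """Session-level calibration metadata.

    ``reference_lifetime`` is the known fluorescence lifetime (ns) of the
    calibration standard measured before each imaging session;
    ``irf_fwhm`` the full width at half maximum of the Gaussian instrument
    response (ns); ``harmonic`` the Fourier harmonic of the phasor transform.
    """

    reference_lifetime: float
    irf_fwhm: float = 0.2
    harmonic: int = 1

    def __post_init__(self) -> None:
        if self.reference_lifetime <= 0:
            raise ValidationError("reference_lifetime must be > 0")
        if self.irf_fwhm < 0:
            raise ValidationError("irf_fwhm must be >= 0")
        if int(self.harmonic) != self.harmonic or self.harmonic < 1:
            raise ValidationError("harmonic must be a positive integer")
        self.harmonic = int(self.harmonic)


def integrate_decay(stack: DecayStack) -> IntensityImage:
    """Sum photon counts over the time axis to form an intensity image.

    Conserves photons exactly: the total of the returned image equals
    ``stack.counts.sum()``.
    """
    return IntensityImage(
        values=stack.counts.sum(axis=2).astype(float),
        normalization_state="raw_counts",
        channel_label=stack.channel_label,
        pixel_size=stack.pixel_size,
        laser_power=stack.laser_power,
    )


def normalize_by_power_squared(image: IntensityImage, power: float) -> IntensityImage:
    """Divide raw counts by the squared excitation power (two-photon yield).

    Two-photon emission scales with the square of the incident power, so
    intensities acquired at different powers are comparable only after this
    normalization.  Applying it twice is a state error.
    """
    if power <= 0:
        raise ValidationError(f"laser power must be > 0 mW; got {power}")
    if image.normalization_state != "raw_counts":
        raise ValidationError("image is already power-normalized")
    return replace(
        image,
        values=image.values / power**2,
        normalization_state="power_normalized",
        laser_power=power,
    )
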