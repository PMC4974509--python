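"""Compartment segmentation and per-compartment metabolic summaries.

Cytoplasm shows detectable signal in both the NAD(P)H and FAD channels;
lipid droplets fluoresce at 460 nm with a long, near-monoexponential
lifetime but are weak-to-absent in the FAD channel.  The implemented rule:

1. exclude low-intensity pixels (nuclei, weakly fluorescent compartments)
   by Otsu thresholding of the NAD(P)H intensity histogram;
2. within the remaining foreground, call a pixel *lipid* when its FAD
   intensity falls below an Otsu threshold computed over foreground FAD
   values AND its long-lifetime intensity fraction exceeds a configurable
   cut (default 0.7); everything else is cytoplasm;
3. reassign connected components smaller than a minimum area to the
   surrounding class, and optionally erode each compartment by a disk to
   suppress cross-talk at compartment boundaries.

The optical redox ratio of an image is FAD/(NAD(P)H+FAD) formed from the
*mean* power-normalized intensities over the segmented cytoplasm, which
bounds it in [0, 1] and makes it invariant to joint rescaling of both
channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy.ndimage import binary_erosion
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk

from .containers import IntensityImage
from .exceptions import ValidationError
from .phasor import LLIFMap

__all__ = [
    "LABEL_EXCLUDED",
    "LABEL_CYTO",
    "LABEL_LIPID",
    "CompartmentMask",
    "ImageSummary",
    "otsu_exclude",
    "classify_compartments",
    "erode_compartments",
    "redox_ratio",
    "summarize_image",
    "dice",
]

LABEL_EXCLUDED = 0
LABEL_CYTO = 1
LABEL_LIPID = 2


@dataclass
class CompartmentMask:
    """Per-pixel compartment labels: 0 excluded, 1 cytoplasm, 2 lipid."""

    labels: np.ndarray
    erosion_radius: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValidationError("labels must be 2-D")
        bad = set(np.unique(self.labels)) - {LABEL_EXCLUDED, LABEL_CYTO, LABEL_LIPID}
        if bad:
            raise ValidationError(f"unknown labels present: {sorted(bad)}")

    def compartment(self, lab: int) -> np.ndarray:
        return self.labels == lab

    @property
    def cytoplasm(self) -> np.ndarray:
        return self.labels == LABEL_CYTO

    @property
    def lipid(self) -> np.ndarray:
        return self.labels == LABEL_LIPID


@dataclass
class ImageSummary:
    """Per-image compartment means with grouping factors."""

    image: str = ""
    genotype: str = ""
    temperature: str = ""
    depot: str = ""
    mouse: str = ""
    mean_redox_cyto: float | None = None
    mean_nadh_llif_cyto: float | None = None
    mean_lipid_llif: float | None = None
    n_cyto_px: int = 0
    n_lipid_px: int = 0
    n_excluded_px: int = 0

    def to_row(self) -> dict[str, Any]:
        return {
            "image": self.image,
            "genotype": self.genotype,
            "temperature": self.temperature,
            "depot": self.depot,
            "mouse": self.mouse,
            "redox": self.mean_redox_cyto,
            "nadh_llif": self.mean_nadh_llif_cyto,
            "lipid_llif": self.mean_lipid_llif,
            "n_cyto_px": self.n_cyto_px,
            "n_lipid_px": self.n_lipid_px,
            "n_excluded_px": self.n_excluded_px,
        }


def otsu_exclude(nadh_intensity: IntensityImage, nbins: int = 256) -> np.ndarray:
    """Foreground mask from Otsu thresholding of the NAD(P)H intensity.

    Pixels strictly below the threshold (nuclei and other weakly
    fluorescent regions) are excluded.  A constant image has a degenerate
    histogram and raises :class:`ValidationError`.
    """
    values = nadh_intensity.values
    if np.nanmax(values) == np.nanmin(values):
        raise ValidationError("constant image: Otsu threshold undefined")
    thr = threshold_otsu(values, nbins=nbins)
    return values >= thr


def classify_compartments(
    nadh_intensity: IntensityImage,
    fad_intensity: IntensityImage,
    llif_map: LLIFMap,
    foreground: np.ndarray,
    llif_cut: float = 0.7,
    min_area: int = 10,
    nbins: int = 256,
) -> CompartmentMask:
    """Label foreground pixels as cytoplasm or lipid.

    Lipid requires *both* weak FAD signal (below a foreground-restricted
    Otsu threshold) and a high long-lifetime fraction (above ``llif_cut``).
    Connected components smaller than ``min_area`` pixels are reassigned to
    their surrounding class.
    """
    shapes = {
        nadh_intensity.values.shape,
        fad_intensity.values.shape,
        llif_map.values.shape,
        np.asarray(foreground).shape,
    }
    if len(shapes) != 1:
        raise ValidationError(f"misaligned input shapes: {shapes}")
    fg = np.asarray(foreground, dtype=bool)
    if not np.any(fg):
        return CompartmentMask(labels=np.zeros(fg.shape, dtype=np.uint8))

    fad_fg = fad_intensity.values[fg]
    if fad_fg.max() > fad_fg.min():
        fad_thr = threshold_otsu(fad_fg, nbins=nbins)
    else:
        fad_thr = np.inf  # constant FAD: treat all foreground as FAD-dark
    with np.errstate(invalid="ignore"):
        lipid = fg & (fad_intensity.values < fad_thr) & (llif_map.values > llif_cut)

    labels = np.zeros(fg.shape, dtype=np.uint8)
    labels[fg] = LABEL_CYTO
    labels[lipid] = LABEL_LIPID

    if min_area > 0:
        for lab, other in ((LABEL_LIPID, LABEL_CYTO), (LABEL_CYTO, LABEL_LIPID)):
            comp = cc_label(labels == lab, connectivity=1)
            for region in range(1, comp.max() + 1):
                m = comp == region
                if m.sum() < min_area:
                    labels[m] = other
    return CompartmentMask(labels=labels, erosion_radius=0)


def erode_compartments(mask: CompartmentMask, radius: int = 5) -> CompartmentMask:
    """Erode each compartment independently by a disk of ``radius`` pixels.

    Eroded-away pixels become excluded; a compartment thinner than twice the
    radius vanishes (its summary is then marked absent).  Radius 0 is the
    identity.
    """
    if radius < 0:
        raise ValidationError("radius must be >= 0")
    if radius == 0:
        return CompartmentMask(labels=mask.labels.copy(), erosion_radius=0)
    selem = disk(radius)
    out = np.zeros_like(mask.labels)
    for lab in (LABEL_CYTO, LABEL_LIPID):
        out[binary_erosion(mask.labels == lab, structure=selem)] = lab
    return CompartmentMask(labels=out, erosion_radius=radius)


def redox_ratio(
    fad_norm: IntensityImage,
    nadh_norm: IntensityImage,
    mask: CompartmentMask,
    compartment: int = LABEL_CYTO,
) -> tuple[float | None, np.ndarray]:
    """Optical redox ratio FAD/(NAD(P)H+FAD) over one compartment.

    Returns the scalar formed from *mean* intensities over the compartment
    (None when the compartment is empty) and a per-pixel map for
    visualization, with lipid pixels masked to NaN.  Both inputs must be
    power-normalized.
    """
    for img in (fad_norm, nadh_norm):
        if img.normalization_state != "power_normalized":
            raise ValidationError("redox requires power-normalized intensities")
    if fad_norm.values.shape != nadh_norm.values.shape:
        raise ValidationError("channel shapes differ")

    with np.errstate(invalid="ignore", divide="ignore"):
        pixel_map = fad_norm.values / (nadh_norm.values + fad_norm.values)
    pixel_map[~mask.cytoplasm] = np.nan

    m = mask.compartment(compartment)
    if not np.any(m):
        return None, pixel_map
    mean_fad = float(fad_norm.values[m].mean())
    mean_nadh = float(nadh_norm.values[m].mean())
    if mean_fad + mean_nadh <= 0:
        raise ValidationError("zero total signal in compartment: redox undefined")
    return mean_fad / (mean_nadh + mean_fad), pixel_map


def summarize_image(
    nadh_norm: IntensityImage,
    fad_norm: IntensityImage,
    llif_map: LLIFMap,
    mask: CompartmentMask,
    factors: dict[str, str] | None = None,
) -> ImageSummary:
    """One per-image summary row: cytoplasm redox & LLIF, lipid LLIF.

    LLIF means use valid phasor bins only; pixels with invalid (photon-
    starved) phasors may still count as cytoplasm for the redox scalar.
    Empty compartments yield None for the affected summaries.
    """
    factors = factors or {}
    scalar, _ = (
        redox_ratio(fad_norm, nadh_norm, mask)
        if np.any(mask.cytoplasm)
        else (None, None)
    )

    def _llif_mean(m: np.ndarray) -> float | None:
        mm = m & llif_map.valid & np.isfinite(llif_map.values)
        return float(llif_map.values[mm].mean()) if np.any(mm) else None

    return ImageSummary(
        image=factors.get("image", ""),
        genotype=factors.get("genotype", ""),
        temperature=factors.get("temperature", ""),
        depot=factors.get("depot", ""),
        mouse=factors.get("mouse", ""),
        mean_redox_cyto=scalar,
        mean_nadh_llif_cyto=_llif_mean(mask.cytoplasm),
        mean_lipid_llif=_llif_mean(mask.lipid),
        n_cyto_px=int(mask.cytoplasm.sum()),
        n_lipid_px=int(mask.lipid.sum()),
        n_excluded_px=int((mask.labels == LABEL_EXCLUDED).sum()),
    )


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap coefficient of two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
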