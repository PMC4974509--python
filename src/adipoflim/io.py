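"""File I/O: HDF5 decay containers, TIFF images, label masks.

The canonical on-disk decay format is a documented HDF5 layout: group
``/tcspc`` with a ``uint32`` dataset ``counts`` of shape (rows, cols, time)
and scalar attributes ``time_bin_width_ns``, ``rep_period_ns``,
``pixel_size_um``, ``laser_power_mw``, ``excitation_nm``,
``emission_center_nm``, ``emission_halfwidth_nm`` and ``channel_label``.
Vendor TCSPC formats (Becker & Hickl SDT, PTU) are deliberately not parsed.

Intensity, redox and LLIF images are written as 32-bit float TIFF; masks as
uint8 label TIFF (0 = excluded, 1 = cytoplasm, 2 = lipid).
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .containers import DecayStack, IntensityImage
from .exceptions import FormatError, ValidationError

_TCSPC_GROUP = "tcspc"
_ATTRS = {
    "time_bin_width_ns": "time_bin_width",
    "rep_period_ns": "rep_period",
    "pixel_size_um": "pixel_size",
    "laser_power_mw": "laser_power",
    "excitation_nm": "excitation_nm",
    "emission_center_nm": "emission_center_nm",
    "emission_halfwidth_nm": "emission_halfwidth_nm",
    "channel_label": "channel_label",
}


def write_decay_stack(stack: DecayStack, path: str | Path) -> None:
    """Write a :class:`DecayStack` to the documented HDF5 layout.

    The write is byte-stable for identical inputs (HDF5 object timestamps
    are disabled).
    """
    path = Path(path)
    with h5py.File(path, "w", track_order=False) as f:
        grp = f.create_group(_TCSPC_GROUP, track_order=False)
        counts = stack.counts
        if np.issubdtype(counts.dtype, np.integer):
            counts = counts.astype(np.uint32)
        else:
            # expectation (noise-free) stacks keep full precision
            counts = counts.astype(np.float64)
        ds = grp.create_dataset("counts", data=counts, track_times=False)
        for attr, field_name in _ATTRS.items():
            ds.attrs[attr] = getattr(stack, field_name)


def read_decay_stack(path: str | Path) -> DecayStack:
    """Read a :class:`DecayStack` written by :func:`write_decay_stack`.

    Raises :class:`FormatError` naming the first missing dataset or
    attribute; raises :class:`ValidationError` if the stored counts violate
    container invariants.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        if _TCSPC_GROUP not in f or "counts" not in f[_TCSPC_GROUP]:
            raise FormatError(f"{path}: missing dataset '/{_TCSPC_GROUP}/counts'")
        ds = f[_TCSPC_GROUP]["counts"]
        kwargs = {}
        for attr, field_name in _ATTRS.items():
            if attr not in ds.attrs:
                raise FormatError(f"{path}: missing attribute {attr!r}")
            value = ds.attrs[attr]
            if isinstance(value, bytes):
                value = value.decode()
            kwargs[field_name] = value
        counts = ds[()]
    return DecayStack(counts=counts, **kwargs)


def write_intensity_tiff(image: IntensityImage | np.ndarray, path: str | Path) -> None:
    values = image.values if isinstance(image, IntensityImage) else np.asarray(image)
    tifffile.imwrite(Path(path), values.astype(np.float32))


def read_intensity_tiff(
    path: str | Path,
    channel_label: str = "NADH",
    normalization_state: str = "raw_counts",
    pixel_size: float = 0.36,
) -> IntensityImage:
    values = tifffile.imread(Path(path)).astype(float)
    return IntensityImage(
        values=values,
        channel_label=channel_label,
        normalization_state=normalization_state,
        pixel_size=pixel_size,
    )


def write_label_tiff(labels: np.ndarray, path: str | Path) -> None:
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > 255:
        raise ValidationError("label image must fit in uint8")
    tifffile.imwrite(Path(path), labels.astype(np.uint8))


def read_label_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.uint8)


def file_checksum(path: str | Path) -> str:
    """SHA-256 of a file, used in run manifests and stage logs."""
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
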