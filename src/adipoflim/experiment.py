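"""Group-structured synthetic experiments on per-image summaries.

The study design being emulated: a genotype × temperature × depot factorial
in which each mouse (nested within genotype × temperature) contributes all
depots, and each depot of each mouse is imaged at several field locations.
Per-image true metabolic readouts are drawn hierarchically:

    y_image = cell mean + mouse random effect (between-mouse sd)
                        + image noise (within-mouse sd)

Each drawn summary can optionally be realized as a full imaging phantom
whose spec encodes it, so the entire pipeline — not just the statistics —
can be exercised against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .phantom import TISSUE_PRESETS, TissuePhantomSpec, tissue_spec

__all__ = [
    "ExperimentDesignSpec",
    "DEFAULT_CELL_MEANS",
    "generate_experiment",
    "generate_bivariate_summaries",
    "phantom_spec_for_row",
]

RESPONSES = ("redox", "nadh_llif", "lipid_llif")

#: Default per-depot true means (redox, cytoplasm NAD(P)H LLIF, lipid LLIF)
#: by temperature.  Directions follow the brown-vs-white physiology: brown
#: fat is more oxidized with shorter lifetimes, cold exposure pushes brown
#: (and browning-susceptible subcutaneous white) fat further in the same
#: direction.  Magnitudes are free generator parameters.
DEFAULT_CELL_MEANS: dict[tuple[str, str], dict[str, float]] = {
    ("BAT", "RT"): dict(redox=0.42, nadh_llif=0.50, lipid_llif=0.88),
    ("BAT", "cold"): dict(redox=0.50, nadh_llif=0.42, lipid_llif=0.84),
    ("scWAT", "RT"): dict(redox=0.28, nadh_llif=0.72, lipid_llif=0.97),
    ("scWAT", "cold"): dict(redox=0.30, nadh_llif=0.70, lipid_llif=0.96),
    ("epiWAT", "RT"): dict(redox=0.24, nadh_llif=0.78, lipid_llif=0.98),
    ("epiWAT", "cold"): dict(redox=0.24, nadh_llif=0.78, lipid_llif=0.98),
}


@dataclass
class ExperimentDesignSpec:
    """Design of a synthetic multi-mouse imaging experiment."""

    genotypes: tuple[str, ...] = ("WT",)
    temperatures: tuple[str, ...] = ("RT", "cold")
    depots: tuple[str, ...] = ("BAT", "scWAT", "epiWAT")
    mice_per_cell: int = 3          # mice per genotype × temperature
    images_per_mouse: int = 6       # fields per depot per mouse
    cell_means: dict[tuple, dict[str, float]] | None = None
    between_mouse_sd: dict[str, float] = field(
        default_factory=lambda: dict(redox=0.02, nadh_llif=0.02, lipid_llif=0.01)
    )
    within_mouse_sd: dict[str, float] = field(
        default_factory=lambda: dict(redox=0.03, nadh_llif=0.03, lipid_llif=0.015)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mice_per_cell < 1 or self.images_per_mouse < 1:
            raise ValidationError("counts must be >= 1")
        for d in (self.between_mouse_sd, self.within_mouse_sd):
            if any(v < 0 for v in d.values()):
                raise ValidationError("standard deviations must be >= 0")

    def mean_for(self, genotype: str, depot: str, temperature: str) -> dict[str, float]:
        if self.cell_means is not None:
            for key in (
                (genotype, depot, temperature),
                (depot, temperature),
            ):
                if key in self.cell_means:
                    return self.cell_means[key]
            raise ValidationError(f"no cell mean for {(genotype, depot, temperature)}")
        return DEFAULT_CELL_MEANS[(depot, temperature)]


def generate_experiment(
    design: ExperimentDesignSpec,
) -> pd.DataFrame:
    """Draw the ground-truth per-image summary table of a design.

    Returns one row per (genotype, temperature, depot, mouse, image) with
    true ``redox``, ``nadh_llif`` and ``lipid_llif`` values, clipped to
    [0, 1].  Mouse random effects are drawn once per mouse and response and
    shared across that mouse's depots, matching a mouse-nested-in-
    temperature random effect.  Deterministic given ``design.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(design.seed), 10]))
    rows: list[dict[str, Any]] = []
    for genotype in design.genotypes:
        for temperature in design.temperatures:
            for m in range(design.mice_per_cell):
                mouse_id = f"{genotype}-{temperature}-m{m + 1}"
                mouse_effect = {
                    r: rng.normal(0.0, design.between_mouse_sd[r]) for r in RESPONSES
                }
                for depot in design.depots:
                    mu = design.mean_for(genotype, depot, temperature)
                    for i in range(design.images_per_mouse):
                        row = dict(
                            genotype=genotype,
                            temperature=temperature,
                            depot=depot,
                            mouse=mouse_id,
                            image=f"{mouse_id}-{depot}-f{i + 1}",
                        )
                        for r in RESPONSES:
                            val = (
                                mu[r]
                                + mouse_effect[r]
                                + rng.normal(0.0, design.within_mouse_sd[r])
                            )
                            row[r] = float(np.clip(val, 0.0, 1.0))
                        rows.append(row)
    return pd.DataFrame(rows)


def phantom_spec_for_row(
    row: pd.Series | dict,
    seed: int,
    **overrides: Any,
) -> TissuePhantomSpec:
    """A phantom spec realizing one drawn per-image summary.

    The row's depot selects the morphology preset; its true redox, cytoplasm
    LLIF, and lipid LLIF are written into the spec (the lipid decay is
    rendered as the trajectory-endpoint mixture at the requested fraction,
    so the chord projection recovers it exactly).
    """
    depot = row["depot"]
    preset = depot if depot in TISSUE_PRESETS else "epiWAT"
    spec = tissue_spec(preset, seed=int(seed), **overrides)
    # keep several droplets per field: cap the radius at 1/8 of the field so
    # the packing target stays reachable in small demo images
    radius_cap = spec.image_size * spec.pixel_size / 8.0
    updates: dict[str, Any] = {}
    if spec.droplet_radius_mean > radius_cap:
        scale = radius_cap / spec.droplet_radius_mean
        updates["droplet_radius_mean"] = radius_cap
        updates["droplet_radius_sd"] = spec.droplet_radius_sd * scale
    if spec.droplet_count is None:
        # random sequential adsorption with rim clearance jams around
        # 0.55·(r/(r+rim))²; stay safely below so generation terminates
        r_px = updates.get("droplet_radius_mean", spec.droplet_radius_mean) / spec.pixel_size
        feasible = 0.42 * (r_px / (r_px + spec.rim_thickness)) ** 2
        updates["packing_fraction"] = min(spec.packing_fraction, feasible)
    if updates:
        spec = TissuePhantomSpec(**{**spec.__dict__, **updates})
    return TissuePhantomSpec(
        **{
            **spec.__dict__,
            "true_redox": float(np.clip(row["redox"], 0.0, 0.95)),
            "cyto_llif": float(np.clip(row["nadh_llif"], 0.0, 1.0)),
            "lipid_llif": float(np.clip(row["lipid_llif"], 0.0, 1.0)),
        }
    )


def generate_bivariate_summaries(
    slope: float,
    intercept: float,
    x_mean: float,
    x_sd: float,
    n: int,
    seed: int | np.random.Generator = 0,
    residual_sd: float | None = None,
    target_correlation: float | None = None,
) -> pd.DataFrame:
    """Draw (x, y) pairs from a linear model with Gaussian noise.

    ``x ~ Normal(x_mean, x_sd²)`` and ``y = intercept + slope·x + ε`` with
    ``ε ~ Normal(0, residual_sd²)``.  When ``target_correlation`` is given
    instead of ``residual_sd``, the residual scale is solved analytically:

        residual_sd = |slope|·x_sd·sqrt(1/ρ² − 1),

    which makes the population correlation of (x, y) equal ρ.  Used to
    emulate per-image (NAD(P)H LLIF, redox ratio) clouds with prescribed
    regression parameters.
    """
    if n < 3:
        raise ValidationError("n must be >= 3")
    if x_sd <= 0:
        raise ValidationError("x_sd must be > 0")
    if (residual_sd is None) == (target_correlation is None):
        raise ValidationError("give exactly one of residual_sd / target_correlation")
    if target_correlation is not None:
        rho = float(target_correlation)
        if not abs(rho) < 1:
            raise ValidationError("|target_correlation| must be < 1")
        if rho == 0 or slope == 0:
            raise ValidationError(
                "target_correlation requires a nonzero slope; give residual_sd"
            )
        if np.sign(rho) != np.sign(slope):
            raise ValidationError("correlation and slope must share a sign")
        residual_sd = abs(slope) * x_sd * np.sqrt(1.0 / rho**2 - 1.0)
    if residual_sd < 0:
        raise ValidationError("residual_sd must be >= 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    )
    x = rng.normal(x_mean, x_sd, size=n)
    y = intercept + slope * x + rng.normal(0.0, residual_sd, size=n)
    return pd.DataFrame({"x": x, "y": y})
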