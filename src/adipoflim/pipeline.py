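"""End-to-end pipeline: simulate → phasor → segment → summarize → stats.

One configuration and one master seed drive a full reproducible run.  In
simulation mode the experiment generator draws a group design, realizes
each per-image summary as a phantom, and the analysis stages recover the
summaries without ever seeing the truth; in load-from-files mode the same
analysis stages run on user-supplied decay containers and FAD images.

Every stage writes only declared files under the run directory and records
them (with SHA-256 checksums) in the run manifest, so a rerun with the same
seed reproduces identical summary tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import RunConfig
from .containers import integrate_decay, normalize_by_power_squared
from .exceptions import StageError, ValidationError
from .experiment import ExperimentDesignSpec, generate_experiment, phantom_spec_for_row
from .io import (
    file_checksum,
    read_decay_stack,
    read_intensity_tiff,
    write_decay_stack,
    write_intensity_tiff,
    write_label_tiff,
)
from .phantom import generate_phantom_geometry, generate_reference_measurement, render_decay_stack
from .phasor import (
    ReferenceCalibration,
    calibrate,
    density_map,
    llif,
    phasor_transform,
)
from .segmentation import (
    classify_compartments,
    erode_compartments,
    otsu_exclude,
    summarize_image,
)
from .stats import (
    ancova_slopes,
    heterogeneity,
    manova,
    nested_mixed_anova,
    ols_slope,
    pearson,
    tukey_hsd,
)

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Record of a pipeline run: config, seed, stage outputs, checksums."""

    seed: int
    config: dict[str, Any]
    version: str = __version__
    stages: list[dict[str, Any]] = field(default_factory=list)
    started: float = 0.0
    finished: float = 0.0

    def add_stage(self, name: str, outputs: list[Path]) -> None:
        self.stages.append(
            {
                "stage": name,
                "outputs": {str(p): file_checksum(p) for p in sorted(outputs)},
            }
        )

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _design_from_config(cfg: RunConfig, seed: int) -> ExperimentDesignSpec:
    sim = dict(cfg.simulate)
    sim.pop("image_size", None)
    sim.pop("photons_per_pixel", None)
    sim.pop("noise", None)
    for key in ("genotypes", "temperatures", "depots"):
        if key in sim:
            sim[key] = tuple(sim[key])
    return ExperimentDesignSpec(seed=seed, **sim)


def run_pipeline(
    cfg: RunConfig, out_dir: str | Path, seed: int | None = None
) -> RunManifest:
    """Execute every stage under ``out_dir`` and return the manifest.

    Simulation mode (default) renders a small phantom experiment; if
    ``cfg.inputs`` is non-empty those files are analyzed instead.  Any stage
    failure raises :class:`StageError` naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed if seed is None else seed
    manifest = RunManifest(seed=seed, config=cfg.to_dict(), started=time.time())
    (out / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))

    if cfg.inputs:
        images = _validate_inputs(cfg)
        truth_csv = None
    else:
        images, truth_csv = _stage_simulate(cfg, out, seed, manifest)

    summary_csv = _stage_analyze(cfg, out, images, manifest)
    _stage_stats(cfg, out, summary_csv, manifest)

    manifest.finished = time.time()
    manifest.write(out / "manifest.json")
    return manifest


def _validate_inputs(cfg: RunConfig) -> list[dict[str, Any]]:
    images = []
    for entry in cfg.inputs:
        nadh = Path(entry["nadh"])
        fad = Path(entry["fad"])
        for p in (nadh, fad):
            if not p.exists():
                raise StageError("inputs", f"missing input file {p}")
        images.append(
            {
                "nadh": str(nadh),
                "fad": str(fad),
                "nadh_power": entry.get("nadh_power", cfg.nadh_power),
                "fad_power": entry.get("fad_power", cfg.fad_power),
                **{
                    k: entry.get(k, "")
                    for k in ("image", "genotype", "temperature", "depot", "mouse")
                },
            }
        )
    return images


def _stage_simulate(
    cfg: RunConfig, out: Path, seed: int, manifest: RunManifest
) -> tuple[list[dict[str, Any]], Path]:
    try:
        stage_dir = out / "simulate"
        stage_dir.mkdir(exist_ok=True)
        design = _design_from_config(cfg, seed)
        truth = generate_experiment(design)
        sim = dict(cfg.simulate)
        image_size = int(sim.get("image_size", 48))
        photons = float(sim.get("photons_per_pixel", 500.0))
        noise = bool(sim.get("noise", True))

        images: list[dict[str, Any]] = []
        outputs: list[Path] = []
        for idx, row in truth.iterrows():
            spec = phantom_spec_for_row(
                row,
                seed=int(np.random.SeedSequence([seed, 100 + idx]).generate_state(1)[0] % (2**31)),
                image_size=image_size,
                photons_per_pixel=photons,
                irf_fwhm=cfg.irf_fwhm,
                rep_period=cfg.rep_period,
                n_time_bins=cfg.n_time_bins,
                tau_short=cfg.tau_short,
                tau_long=cfg.tau_long,
            )
            labels = generate_phantom_geometry(spec)
            stack, fad_img, _ = render_decay_stack(labels, spec, noise=noise)
            base = stage_dir / row["image"]
            write_decay_stack(stack, base.with_suffix(".h5"))
            write_intensity_tiff(fad_img, base.with_suffix(".fad.tif"))
            write_label_tiff(labels, base.with_suffix(".labels.tif"))
            outputs += [base.with_suffix(".h5"), base.with_suffix(".fad.tif"),
                        base.with_suffix(".labels.tif")]
            images.append(
                {
                    "nadh": str(base.with_suffix(".h5")),
                    "fad": str(base.with_suffix(".fad.tif")),
                    "nadh_power": 1.0,
                    "fad_power": 1.0,
                    **{k: row[k] for k in ("image", "genotype", "temperature",
                                           "depot", "mouse")},
                }
            )
        # one reference measurement shared by the session
        ref_spec = phantom_spec_for_row(
            truth.iloc[0], seed=seed, image_size=image_size,
            photons_per_pixel=photons, irf_fwhm=cfg.irf_fwhm,
            rep_period=cfg.rep_period, n_time_bins=cfg.n_time_bins,
        )
        ref_stack = generate_reference_measurement(
            cfg.reference_lifetime, ref_spec, noise=False
        )
        write_decay_stack(ref_stack, stage_dir / "reference.h5")
        outputs.append(stage_dir / "reference.h5")

        truth_csv = stage_dir / "ground_truth.csv"
        truth.to_csv(truth_csv, index=False)
        outputs.append(truth_csv)
        pd.DataFrame(images).to_csv(stage_dir / "images.csv", index=False)
        outputs.append(stage_dir / "images.csv")
        manifest.add_stage("simulate", outputs)
        log.info("simulate: wrote %d phantom image pairs", len(images))
        return images, truth_csv
    except Exception as exc:  # noqa: BLE001 — stage boundary
        raise StageError("simulate", str(exc)) from exc


def _stage_analyze(
    cfg: RunConfig, out: Path, images: list[dict[str, Any]], manifest: RunManifest
) -> Path:
    try:
        stage_dir = out / "analysis"
        stage_dir.mkdir(exist_ok=True)
        ref_path = out / "simulate" / "reference.h5"
        if ref_path.exists():
            ref_stack = read_decay_stack(ref_path)
            ref = ReferenceCalibration.from_stack(
                ref_stack, cfg.reference_lifetime, cfg.harmonic
            )
        else:
            ref = None

        rows = []
        fields_by_depot: dict[str, list] = {}
        outputs: list[Path] = []
        for entry in images:
            stack = read_decay_stack(entry["nadh"])
            field = phasor_transform(
                stack, cfg.harmonic, cfg.bin_factor, cfg.min_photons
            )
            if ref is not None:
                field = calibrate(field, ref)
            llif_map = llif(field, cfg.tau_short, cfg.tau_long)
            fields_by_depot.setdefault(entry.get("depot", ""), []).append(field)

            nadh_int = integrate_decay(stack)
            nadh_norm = normalize_by_power_squared(nadh_int, entry["nadh_power"])
            fad_img = read_intensity_tiff(entry["fad"], channel_label="FAD")
            fad_norm = normalize_by_power_squared(fad_img, entry["fad_power"])

            fg = otsu_exclude(nadh_norm)
            mask = classify_compartments(
                nadh_norm, fad_norm, llif_map, fg,
                llif_cut=cfg.llif_cut, min_area=cfg.min_area,
            )
            if cfg.erosion_radius:
                mask = erode_compartments(mask, cfg.erosion_radius)
            summary = summarize_image(
                nadh_norm, fad_norm, llif_map, mask,
                factors={k: entry.get(k, "") for k in
                         ("image", "genotype", "temperature", "depot", "mouse")},
            )
            rows.append(summary.to_row())

            base = stage_dir / str(entry.get("image", Path(entry["nadh"]).stem))
            write_intensity_tiff(np.nan_to_num(llif_map.values), base.with_suffix(".llif.tif"))
            write_label_tiff(mask.labels, base.with_suffix(".mask.tif"))
            outputs += [base.with_suffix(".llif.tif"), base.with_suffix(".mask.tif")]

        for depot, fields in fields_by_depot.items():
            dm = density_map(
                fields, bins=cfg.density_bins,
                g_range=(0.0, cfg.density_g_max), s_range=(0.0, cfg.density_s_max),
                weighted=cfg.density_weighted,
            )
            path = stage_dir / f"density_{depot or 'all'}.csv"
            np.savetxt(path, dm.hist, delimiter=",")
            outputs.append(path)

        summary_csv = stage_dir / "summary.csv"
        pd.DataFrame(rows).to_csv(summary_csv, index=False)
        outputs.append(summary_csv)
        manifest.add_stage("analyze", outputs)
        log.info("analyze: summarized %d images", len(rows))
        return summary_csv
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("analyze", str(exc)) from exc


def _stage_stats(
    cfg: RunConfig, out: Path, summary_csv: Path, manifest: RunManifest
) -> None:
    try:
        stage_dir = out / "stats"
        stage_dir.mkdir(exist_ok=True)
        table = pd.read_csv(summary_csv)
        n_before = len(table)
        table = table.dropna(subset=["redox", "nadh_llif", "lipid_llif"])
        if len(table) < n_before:
            log.info("stats: dropped %d incomplete rows", n_before - len(table))
        outputs: list[Path] = []
        for genotype, sub in table.groupby("genotype"):
            tag = genotype or "all"
            anova_rows, tukey_rows, biv_rows = [], [], []
            for response in ("redox", "nadh_llif", "lipid_llif"):
                try:
                    res = nested_mixed_anova(sub, response)
                except ValidationError as exc:
                    log.warning("stats: anova on %s/%s skipped: %s",
                                tag, response, exc)
                    continue
                eff = res.effects.assign(response=response)
                anova_rows.append(eff)
                # post-hoc on depot against the residual MS
                resid = res.effects.loc[res.effects["effect"] == "depot"].iloc[0]
                cell = sub.groupby("depot")[response]
                tk = tukey_hsd(
                    cell.mean().to_dict(),
                    float(res.variance_components["residual"]),
                    int(resid["df2"]),
                    cell.size().to_dict(),
                ).assign(response=response)
                tukey_rows.append(tk)
            for depot, dsub in sub.groupby("depot"):
                if len(dsub) < 3 or np.var(dsub["nadh_llif"]) == 0:
                    continue
                r, p = pearson(dsub["nadh_llif"], dsub["redox"])
                slope, intercept, se = ols_slope(dsub["nadh_llif"], dsub["redox"])
                biv_rows.append(dict(depot=depot, n=len(dsub), r=r, p=p,
                                     slope=slope, intercept=intercept, se=se))
            if anova_rows:
                pd.concat(anova_rows).to_csv(stage_dir / f"anova_{tag}.csv", index=False)
                outputs.append(stage_dir / f"anova_{tag}.csv")
            if tukey_rows:
                pd.concat(tukey_rows).to_csv(stage_dir / f"tukey_{tag}.csv", index=False)
                outputs.append(stage_dir / f"tukey_{tag}.csv")
            if biv_rows:
                pd.DataFrame(biv_rows).to_csv(stage_dir / f"bivariate_{tag}.csv",
                                              index=False)
                outputs.append(stage_dir / f"bivariate_{tag}.csv")
            try:
                anc = ancova_slopes(sub, "depot", "nadh_llif", "redox")
                anc.slopes.assign(
                    f_interaction=anc.f_interaction, p_interaction=anc.p_interaction
                ).to_csv(stage_dir / f"ancova_{tag}.csv", index=False)
                outputs.append(stage_dir / f"ancova_{tag}.csv")
            except ValidationError as exc:
                log.warning("stats: ancova on %s skipped: %s", tag, exc)
            try:
                mv = manova(sub, "depot")
                pd.DataFrame([asdict(mv)]).to_csv(
                    stage_dir / f"manova_{tag}.csv", index=False
                )
                outputs.append(stage_dir / f"manova_{tag}.csv")
            except ValidationError as exc:
                log.warning("stats: manova on %s skipped: %s", tag, exc)
            sd_tab, ell_tab = heterogeneity(sub)
            sd_tab.to_csv(stage_dir / f"heterogeneity_{tag}.csv", index=False)
            ell_tab.to_csv(stage_dir / f"ellipses_{tag}.csv", index=False)
            outputs += [stage_dir / f"heterogeneity_{tag}.csv",
                        stage_dir / f"ellipses_{tag}.csv"]
        manifest.add_stage("stats", outputs)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("stats", str(exc)) from exc


def report(run_dir: str | Path) -> Path:
    """Assemble a human-readable markdown report from a completed run.

    Group means ± s.e. per response, bivariate regression summaries, and
    pointers to the density-map and ellipse tables.  Every number in the
    report comes from a CSV written by a named stage.
    """
    run = Path(run_dir)
    summary_csv = run / "analysis" / "summary.csv"
    if not summary_csv.exists():
        raise StageError("report", f"missing artifact {summary_csv}")
    table = pd.read_csv(summary_csv)
    lines = ["# adipoflim run report", ""]

    lines.append("## Group means ± s.e. (per-image averages)")
    grouped = table.groupby(["genotype", "depot", "temperature"])
    means = grouped[["redox", "nadh_llif", "lipid_llif"]].agg(["mean", "sem", "count"])
    lines.append("")
    lines.append(means.to_csv())

    stats_dir = run / "stats"
    if stats_dir.exists():
        lines.append("## Statistics")
        for csv in sorted(stats_dir.glob("*.csv")):
            lines.append(f"### {csv.stem}")
            lines.append(pd.read_csv(csv).to_csv(index=False))
    else:
        lines.append("## Statistics")
        lines.append("(stats stage not run)")

    density = sorted((run / "analysis").glob("density_*.csv"))
    if density:
        lines.append("## Phasor density maps")
        for csv in density:
            png = _render_density_figure(csv)
            lines.append(f"- {csv.name} (figure: {png.name})")

    out_path = run / "report.md"
    out_path.write_text("\n".join(lines))
    return out_path


def _render_density_figure(csv_path: Path) -> Path:
    """Render one peak-normalized phasor density map with the universal
    semicircle overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hist = np.loadtxt(csv_path, delimiter=",")
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.imshow(hist.T, origin="lower", extent=(0, 1, 0, 0.6), aspect="auto",
              cmap="inferno")
    theta = np.linspace(0, np.pi, 200)
    ax.plot(0.5 + 0.5 * np.cos(theta), 0.5 * np.sin(theta), "w--", lw=0.8)
    ax.set_xlabel("g")
    ax.set_ylabel("s")
    ax.set_title(csv_path.stem)
    out = csv_path.with_suffix(".png")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out
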