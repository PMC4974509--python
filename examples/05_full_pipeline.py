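"""One-command reproducible run: simulate → phasor → segment → stats → report.

Drives the whole pipeline from a single configuration and seed, then prints
where each artifact landed.  Equivalent shell command:

    adipoflim run --config examples/demo.yaml --out runs/demo --seed 7
"""

from pathlib import Path

import pandas as pd

from adipoflim.config import RunConfig
from adipoflim.pipeline import report, run_pipeline

out = Path("runs/demo")
cfg = RunConfig(
    seed=7,
    erosion_radius=2,  # gentler erosion suits the small demo fields
    simulate=dict(
        mice_per_cell=2,
        images_per_mouse=2,
        depots=["BAT", "scWAT"],
        image_size=48,
        photons_per_pixel=400,
    ),
)
manifest = run_pipeline(cfg, out, seed=7)
report_path = report(out)

print(f"stages run: {[s['stage'] for s in manifest.stages]}")
summary = pd.read_csv(out / "analysis" / "summary.csv")
print(f"\nper-image summaries ({len(summary)} rows):")
print(summary[["image", "depot", "redox", "nadh_llif", "lipid_llif"]]
      .head(8).to_string(index=False))
print(f"\nreport: {report_path}")
print(f"manifest with checksums: {out / 'manifest.json'}")
print()
print("Re-running with the same seed reproduces summary.csv byte for byte;")
print("the stats tables under runs/demo/stats/ hold the ANOVA, Tukey,")
print("bivariate, and heterogeneity outputs for these simulated groups.")
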