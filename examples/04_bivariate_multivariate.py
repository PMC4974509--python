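"""Bivariate regression structure and MANOVA across depots.

Generates per-image (NAD(P)H LLIF, redox) clouds with the distinct
regression slopes characteristic of brown vs white fat, recovers slope and
correlation, tests slope homogeneity by ANCOVA, and contrasts the depots
with a one-way MANOVA on all three responses.
"""

import numpy as np
import pandas as pd

import adipoflim as af

X_MEAN, X_SD = 0.55, 0.06

bat = af.generate_bivariate_summaries(
    slope=-0.75, intercept=1.0, x_mean=X_MEAN, x_sd=X_SD, n=144,
    target_correlation=-0.87, seed=1,
).assign(depot="BAT")
wat = af.generate_bivariate_summaries(
    slope=-1.5, intercept=1.4, x_mean=0.7, x_sd=X_SD, n=265,
    target_correlation=-0.89, seed=2,
).assign(depot="WAT")

for name, df in (("BAT", bat), ("WAT", wat)):
    slope, intercept, se = af.ols_slope(df.x, df.y)
    r, p = af.pearson(df.x, df.y)
    print(f"{name}: n={len(df)}  slope={slope:.3f}±{se:.3f}  r={r:.3f} "
          f"(p={p:.2e})")

both = pd.concat([bat, wat])
anc = af.ancova_slopes(both, "depot", "x", "y")
print(f"\nANCOVA slope homogeneity: F({anc.df1},{anc.df2}) = "
      f"{anc.f_interaction:.1f}, p = {anc.p_interaction:.2e}")

rng = np.random.default_rng(3)
rows = []
for depot, mu in (("BAT", (0.45, 0.50, 0.87)), ("scWAT", (0.28, 0.72, 0.97))):
    for _ in range(40):
        v = np.array(mu) + rng.normal(0, 0.03, 3)
        rows.append(dict(depot=depot, redox=v[0], nadh_llif=v[1],
                         lipid_llif=v[2]))
mv = af.manova(pd.DataFrame(rows), "depot")
print(f"MANOVA (redox, NAD(P)H LLIF, lipid LLIF): Wilks' lambda = "
      f"{mv.wilks_lambda:.4f}, F({mv.df1:.0f},{mv.df2:.0f}) = "
      f"{mv.f_approx:.1f}, p = {mv.p:.2e}")
print()
print("White fat's redox-vs-LLIF slope is roughly double brown fat's, and")
print("the interaction F confirms the slopes differ; Wilks' lambda near 0")
print("means the three responses jointly separate the depots almost fully.")
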