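"""Statistical analysis of per-image summary tables.

The canonical model for group comparisons is a nested mixed-effects ANOVA
on per-image averages: adipose depot and temperature treatment are fixed
effects (with their interaction), and mouse is a random effect nested in
temperature, crossed with depot.  For balanced designs the expected-mean-
squares (EMS) F tests are exact:

* temperature is tested against the mouse-within-temperature mean square;
* depot and depot×temperature are tested against the residual mean square.

Variance components are estimated by the method of moments and clamped at
zero.  Genotypes are analyzed separately.  Post-hoc pairwise contrasts use
Tukey's HSD on the studentized range; bivariate structure is summarized by
Pearson correlations, OLS slopes, an ANCOVA homogeneity-of-slopes F test,
and a one-way MANOVA (Wilks' Λ with Rao's F approximation).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps

from .exceptions import ValidationError

__all__ = [
    "AnovaResult",
    "AncovaResult",
    "ManovaResult",
    "nested_mixed_anova",
    "tukey_hsd",
    "pearson",
    "ols_slope",
    "ancova_slopes",
    "manova",
    "heterogeneity",
    "confidence_ellipse",
]

RESPONSES = ("redox", "nadh_llif", "lipid_llif")


@dataclass
class AnovaResult:
    """Per-effect F tests plus method-of-moments variance components."""

    effects: pd.DataFrame          # effect, ss, df1, ms, denom, df2, F, p
    variance_components: dict[str, float]
    balanced: bool
    response: str

    def p(self, effect: str) -> float:
        row = self.effects.loc[self.effects["effect"] == effect]
        if row.empty:
            raise KeyError(effect)
        return float(row["p"].iloc[0])

    def f(self, effect: str) -> float:
        row = self.effects.loc[self.effects["effect"] == effect]
        if row.empty:
            raise KeyError(effect)
        return float(row["F"].iloc[0])


@dataclass
class AncovaResult:
    """Per-group slopes and the homogeneity-of-slopes interaction test."""

    slopes: pd.DataFrame           # group, n, slope, se, intercept
    f_interaction: float
    df1: int
    df2: int
    p_interaction: float


@dataclass
class ManovaResult:
    wilks_lambda: float
    f_approx: float
    df1: float
    df2: float
    p: float


def _check_columns(table: pd.DataFrame, cols: tuple[str, ...]) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValidationError(f"summary table missing columns: {missing}")


def nested_mixed_anova(
    table: pd.DataFrame,
    response: str,
    temperature: str = "temperature",
    depot: str = "depot",
    mouse: str = "mouse",
) -> AnovaResult:
    """Nested mixed-effects ANOVA of per-image averages.

    Fixed effects: temperature, depot, temperature×depot; random effect:
    mouse nested within temperature (each mouse contributes all depots).
    Balanced designs use exact EMS F ratios; unbalanced designs fall back
    to an unweighted-cell-means analysis with the harmonic mean of the cell
    sizes substituted for n (a Satterthwaite-flavored approximation —
    adequate for mild imbalance, documented as approximate).

    Rows with a missing response are dropped listwise.
    """
    _check_columns(table, (temperature, depot, mouse, response))
    df = table.dropna(subset=[response]).copy()
    if df.empty:
        raise ValidationError("no complete rows")
    temps = sorted(df[temperature].unique())
    depots = sorted(df[depot].unique())
    a, b = len(temps), len(depots)
    if a < 2 or b < 2:
        raise ValidationError("need >= 2 levels of each fixed factor")
    mice_per_temp = df.groupby(temperature)[mouse].nunique()
    if (mice_per_temp < 2).any():
        raise ValidationError(
            "random mouse effect untestable: fewer than 2 mice in a "
            "temperature group"
        )
    m = int(mice_per_temp.min())
    cell_sizes = df.groupby([temperature, mouse, depot])[response].size()
    balanced = (
        cell_sizes.nunique() == 1
        and mice_per_temp.nunique() == 1
        and len(cell_sizes) == a * b * mice_per_temp.iloc[0]
    )
    if balanced:
        n = int(cell_sizes.iloc[0])
        m = int(mice_per_temp.iloc[0])
    else:
        n = len(cell_sizes) / np.sum(1.0 / cell_sizes)  # harmonic mean

    y = df[response].to_numpy(dtype=float)

    # unweighted cell means drive both paths; for balanced data they agree
    # with the raw means exactly
    cell_mean = df.groupby([temperature, mouse, depot])[response].mean()
    t_mean = cell_mean.groupby(level=0).mean()
    d_mean = cell_mean.groupby(level=2).mean()
    td_mean = cell_mean.groupby(level=[0, 2]).mean()
    tm_mean = cell_mean.groupby(level=[0, 1]).mean()
    grand = y.mean() if balanced else cell_mean.mean()

    ss_t = b * m * n * float(((t_mean - grand) ** 2).sum())
    ss_m = b * n * float(
        (
            (tm_mean - t_mean.reindex(tm_mean.index.get_level_values(0)).to_numpy())
            ** 2
        ).sum()
    )
    ss_d = a * m * n * float(((d_mean - grand) ** 2).sum())
    td_dev = (
        td_mean
        - t_mean.reindex(td_mean.index.get_level_values(0)).to_numpy()
        - d_mean.reindex(td_mean.index.get_level_values(1)).to_numpy()
        + grand
    )
    ss_td = m * n * float((td_dev ** 2).sum())

    # residual: within-cell variation plus the pooled mouse×depot term
    fitted = (
        tm_mean.reindex(
            pd.MultiIndex.from_arrays([df[temperature], df[mouse]])
        ).to_numpy()
        + td_mean.reindex(
            pd.MultiIndex.from_arrays([df[temperature], df[depot]])
        ).to_numpy()
        - t_mean.reindex(df[temperature]).to_numpy()
    )
    ss_res = float(((y - fitted) ** 2).sum())

    n_mice = int(mice_per_temp.sum())
    df_t = a - 1
    df_m = n_mice - a
    df_d = b - 1
    df_td = (a - 1) * (b - 1)
    df_res = len(y) - n_mice - (b - 1) - (a - 1) * (b - 1)
    if df_res <= 0 or df_m <= 0:
        raise ValidationError("insufficient replication for the EMS tests")

    ms_t, ms_m = ss_t / df_t, ss_m / df_m
    ms_d, ms_td = ss_d / df_d, ss_td / df_td
    ms_res = ss_res / df_res

    rows = []
    for name, ss, d1, ms, denom_ms, d2 in (
        ("temperature", ss_t, df_t, ms_t, ms_m, df_m),
        ("mouse(temperature)", ss_m, df_m, ms_m, ms_res, df_res),
        ("depot", ss_d, df_d, ms_d, ms_res, df_res),
        ("temperature:depot", ss_td, df_td, ms_td, ms_res, df_res),
    ):
        if denom_ms <= 0:
            f_stat, p = np.inf if ms > 0 else np.nan, 0.0 if ms > 0 else np.nan
        else:
            f_stat = ms / denom_ms
            p = float(sps.f.sf(f_stat, d1, d2))
        rows.append(dict(effect=name, ss=ss, df1=d1, ms=ms, F=f_stat, df2=d2, p=p))
    effects = pd.DataFrame(rows)

    var_mouse = max((ms_m - ms_res) / (b * n), 0.0)
    return AnovaResult(
        effects=effects,
        variance_components={"mouse": var_mouse, "residual": ms_res},
        balanced=bool(balanced),
        response=response,
    )


def tukey_hsd(
    means: dict[str, float] | pd.Series,
    ms_error: float,
    df_error: int,
    n_per_cell: int | dict[str, int],
) -> pd.DataFrame:
    """Tukey HSD simultaneous pairwise comparisons from summary statistics.

    ``q = |mean_i - mean_j| / sqrt(MS_error·(1/n_i + 1/n_j)/2)`` referred
    to the studentized range distribution with ``k`` groups and
    ``df_error`` degrees of freedom (Tukey–Kramer for unequal n).  With two
    groups the adjusted p equals the pooled two-sample t-test p.
    """
    if df_error <= 0:
        raise ValidationError("df_error must be > 0")
    if ms_error <= 0:
        raise ValidationError("ms_error must be > 0")
    means = dict(means)
    k = len(means)
    if k < 2:
        raise ValidationError("need >= 2 groups")
    if isinstance(n_per_cell, int):
        n_per_cell = {g: n_per_cell for g in means}
    rows = []
    for g1, g2 in itertools.combinations(sorted(means), 2):
        diff = means[g1] - means[g2]
        se = np.sqrt(ms_error * (1.0 / n_per_cell[g1] + 1.0 / n_per_cell[g2]) / 2.0)
        q = abs(diff) / se
        p = float(np.clip(sps.studentized_range.sf(q, k, df_error), 0.0, 1.0))
        rows.append(dict(group1=g1, group2=g2, diff=diff, se=se, q=q, p_adj=p))
    return pd.DataFrame(rows)


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation with the two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValidationError("need n >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def ols_slope(x, y) -> tuple[float, float, float]:
    """Least-squares fit of y on x: (slope, intercept, slope standard error)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValidationError("need n >= 3 paired observations")
    if np.var(x) == 0:
        raise ValidationError("degenerate x: zero variance")
    fit = sps.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.stderr)


def ancova_slopes(
    table: pd.DataFrame,
    group: str,
    x: str,
    y: str,
) -> AncovaResult:
    """Homogeneity-of-regression-slopes ANCOVA.

    Fits the full model (separate intercept and slope per group) and the
    reduced model (separate intercepts, one common slope) and forms the F
    test on the group×covariate interaction.  Groups with fewer than three
    points are excluded with a warning.
    """
    _check_columns(table, (group, x, y))
    df = table.dropna(subset=[x, y])
    keep = []
    for g, sub in df.groupby(group):
        if len(sub) < 3 or np.var(sub[x]) == 0:
            warnings.warn(f"ancova: excluding group {g!r} (n < 3 or constant x)")
        else:
            keep.append(g)
    if len(keep) < 2:
        raise ValidationError("need >= 2 usable groups")
    df = df[df[group].isin(keep)]
    groups = sorted(keep)
    n_total = len(df)
    k = len(groups)

    codes = df[group].map({g: i for i, g in enumerate(groups)}).to_numpy()
    xv = df[x].to_numpy(dtype=float)
    yv = df[y].to_numpy(dtype=float)

    def rss(design: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(design, yv, rcond=None)
        resid = yv - design @ beta
        return float(resid @ resid)

    intercepts = (codes[:, None] == np.arange(k)).astype(float)
    full = np.hstack([intercepts, intercepts * xv[:, None]])
    reduced = np.hstack([intercepts, xv[:, None]])
    rss_full = rss(full)
    rss_red = rss(reduced)
    df1 = k - 1
    df2 = n_total - 2 * k
    if df2 <= 0:
        raise ValidationError("insufficient data for the interaction test")
    f_stat = ((rss_red - rss_full) / df1) / (rss_full / df2)
    p = float(sps.f.sf(f_stat, df1, df2))

    rows = []
    for g, sub in df.groupby(group):
        slope, intercept, se = ols_slope(sub[x], sub[y])
        rows.append(dict(group=g, n=len(sub), slope=slope, se=se, intercept=intercept))
    return AncovaResult(
        slopes=pd.DataFrame(rows),
        f_interaction=float(f_stat),
        df1=df1,
        df2=df2,
        p_interaction=p,
    )


def manova(
    table: pd.DataFrame,
    group: str,
    responses: tuple[str, ...] = RESPONSES,
) -> ManovaResult:
    """One-way MANOVA: Wilks' Λ with Rao's F approximation.

    ``Λ = det(W)/det(W+B)`` where W and B are the within- and between-group
    SSCP matrices.  With a single response the statistic reduces exactly to
    the one-way ANOVA F.
    """
    _check_columns(table, (group,) + tuple(responses))
    df = table.dropna(subset=list(responses))
    groups = sorted(df[group].unique())
    g = len(groups)
    p = len(responses)
    n_total = len(df)
    if g < 2:
        raise ValidationError("need >= 2 groups")
    counts = df.groupby(group).size()
    if (counts <= p).any():
        raise ValidationError("each group needs n > number of responses")

    Y = df[list(responses)].to_numpy(dtype=float)
    grand = Y.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for gname, sub in df.groupby(group):
        Yg = sub[list(responses)].to_numpy(dtype=float)
        mu = Yg.mean(axis=0)
        dev = Yg - mu
        W += dev.T @ dev
        d = (mu - grand)[:, None]
        B += len(sub) * (d @ d.T)

    sign, logdet_w = np.linalg.slogdet(W)
    sign2, logdet_t = np.linalg.slogdet(W + B)
    if sign <= 0 or sign2 <= 0:
        raise ValidationError("singular within-group covariance")
    lam = float(np.exp(logdet_w - logdet_t))

    # Rao's approximation
    dfh = g - 1
    denom = p**2 + dfh**2 - 5
    t = np.sqrt((p**2 * dfh**2 - 4) / denom) if denom > 0 else 1.0
    w = n_total - 1 - (p + g) / 2.0
    df1 = p * dfh
    df2 = w * t - (df1 - 2) / 2.0
    if df2 <= 0:
        raise ValidationError("insufficient error degrees of freedom")
    lam_t = lam ** (1.0 / t)
    f_stat = (1.0 - lam_t) / lam_t * df2 / df1
    p_val = float(sps.f.sf(f_stat, df1, df2))
    return ManovaResult(
        wilks_lambda=lam, f_approx=float(f_stat), df1=df1, df2=df2, p=p_val
    )


def confidence_ellipse(
    x, y, level: float = 0.95
) -> dict[str, float]:
    """Parameters of the Gaussian data-cloud ellipse covering ``level``.

    Returns the mean, covariance entries, semi-axes (chi-square scaled
    Mahalanobis radius) and orientation of the ellipse that contains the
    requested probability mass of a fitted bivariate normal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValidationError("need >= 3 points for an ellipse")
    cov = np.cov(x, y)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    r2 = sps.chi2.ppf(level, df=2)
    angle = float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0])))
    return dict(
        mean_x=float(x.mean()),
        mean_y=float(y.mean()),
        cov_xx=float(cov[0, 0]),
        cov_xy=float(cov[0, 1]),
        cov_yy=float(cov[1, 1]),
        semi_major=float(np.sqrt(max(evals[0], 0) * r2)),
        semi_minor=float(np.sqrt(max(evals[1], 0) * r2)),
        angle_deg=angle,
        level=level,
    )


def heterogeneity(
    table: pd.DataFrame,
    responses: tuple[str, ...] = RESPONSES,
    by: tuple[str, ...] = ("depot", "temperature"),
    ellipse_pair: tuple[str, str] = ("nadh_llif", "redox"),
    level: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-cell standard deviations and per-group 95% data ellipses.

    Returns (sd table, ellipse table); cells with fewer than three images
    are skipped with a warning.
    """
    _check_columns(table, tuple(by) + tuple(responses))
    sd_rows, ell_rows = [], []
    for key, sub in table.groupby(list(by)):
        key = key if isinstance(key, tuple) else (key,)
        if len(sub) < 3:
            warnings.warn(f"heterogeneity: skipping cell {key} (n < 3)")
            continue
        row = dict(zip(by, key))
        row["n"] = len(sub)
        for r in responses:
            row[f"sd_{r}"] = float(sub[r].std(ddof=1))
        sd_rows.append(row)
        ell = confidence_ellipse(sub[ellipse_pair[0]], sub[ellipse_pair[1]], level)
        ell_rows.append({**dict(zip(by, key)), **ell})
    return pd.DataFrame(sd_rows), pd.DataFrame(ell_rows)
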