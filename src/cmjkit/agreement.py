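"""Method-agreement and reliability statistics for paired measurements.

The battery compares two measurement methods (e.g. marker-based vs
markerless motion capture) observed on the same trials:

* Bland–Altman bias and 95% limits of agreement (LoA), each with 95% CIs;
* root mean square error and Pearson's r (Fisher-z CI) with the conventional
  magnitude labels (negligible < 0.3 <= low < 0.5 <= moderate < 0.7 <= high
  < 0.9 <= very high);
* ICC(3,1) — two-way mixed model, consistency definition, single measures —
  with an F-distribution 95% CI;
* a two-way fully repeated-measures ANOVA (method x side, case as the
  blocking unit, each within factor tested against its own case x factor
  interaction);
* Cohen's d standardised by the *harmonic* mean of the two groups' SDs,
  with a normal-approximation 95% CI, magnitude label (trivial < 0.2 <=
  small < 0.5 <= moderate < 0.8 <= large < 1.3 <= very large) and a
  clear/unclear call: the effect is unclear when its CI spans both
  substantial positive (+0.2) and substantial negative (-0.2) values.

Whole-curve comparisons first time-normalise each trial onto a common 0-100%
grid (101 stations by default) and then pool all stations of all trials into
one paired sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import StatsError

R_THRESHOLDS = ((0.3, "negligible"), (0.5, "low"), (0.7, "moderate"), (0.9, "high"), (1.01, "very high"))
D_THRESHOLDS = ((0.2, "trivial"), (0.5, "small"), (0.8, "moderate"), (1.3, "large"), (np.inf, "very large"))

#: The minimal practically important standardised effect.
SMALLEST_IMPORTANT_D = 0.20


def _label(value: float, thresholds) -> str:
    v = abs(value)
    for upper, name in thresholds:
        if v < upper:
            return name
    return thresholds[-1][1]


@dataclass(frozen=True)
class BlandAltman:
    """Bias and 95% limits of agreement of paired differences (y - x)."""

    bias: float
    bias_ci: tuple
    loa_lower: float
    loa_lower_ci: tuple
    loa_upper: float
    loa_upper_ci: tuple
    sd_diff: float
    n: int


@dataclass(frozen=True)
class PearsonR:
    r: float
    ci: tuple
    label: str
    n: int


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci: tuple
    df1: int
    df2: int


@dataclass(frozen=True)
class AnovaEffect:
    name: str
    ss: float
    df1: int
    df2: int
    f: float
    p: float


@dataclass(frozen=True)
class AnovaResult:
    method: AnovaEffect
    side: AnovaEffect
    interaction: AnovaEffect
    ss_components: dict

    @property
    def ss_total(self) -> float:
        return sum(self.ss_components.values())


@dataclass(frozen=True)
class CohenD:
    d: float
    ci: tuple
    magnitude: str
    clearness: str


def _paired(x, y, min_n=3):
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if len(x) != len(y):
        raise StatsError("paired samples must have equal length")
    if len(x) < min_n:
        raise StatsError(f"need at least {min_n} pairs, got {len(x)}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise StatsError("missing values are not allowed in paired samples")
    return x, y


def bland_altman(x, y) -> BlandAltman:
    """Bland–Altman agreement of method y against method x.

    LoA = bias +/- 1.96 sd of the differences (sample sd, n-1 denominator).
    The bias CI uses the usual t interval; each LoA CI uses the classic
    approximation SE = sd * sqrt(3/n) with the same t quantile.
    """
    x, y = _paired(x, y)
    d = y - x
    n = len(d)
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    t = float(sps.t.ppf(0.975, n - 1))
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(3.0 / n)
    lo = bias - 1.96 * sd
    hi = bias + 1.96 * sd
    return BlandAltman(
        bias=bias,
        bias_ci=(bias - t * se_bias, bias + t * se_bias),
        loa_lower=lo,
        loa_lower_ci=(lo - t * se_loa, lo + t * se_loa),
        loa_upper=hi,
        loa_upper_ci=(hi - t * se_loa, hi + t * se_loa),
        sd_diff=sd,
        n=n,
    )


def rmse(x, y) -> float:
    """Root mean square of the paired differences."""
    x, y = _paired(x, y, min_n=1)
    return float(np.sqrt(np.mean((y - x) ** 2)))


def pearson_r(x, y) -> PearsonR:
    """Pearson correlation with a Fisher-z 95% CI and magnitude label."""
    x, y = _paired(x, y, min_n=4)
    if np.std(x) == 0 or np.std(y) == 0:
        raise StatsError("correlation undefined: a sample has zero variance")
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        ci = (r, r)
    else:
        z = np.arctanh(r)
        half = 1.959963984540054 / np.sqrt(n - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    return PearsonR(r=r, ci=ci, label=_label(r, R_THRESHOLDS), n=n)


def icc_3_1(ratings) -> IccResult:
    """ICC(3,1): two-way mixed, consistency, single measures.

    ``ratings`` is an (n, k) table of n targets rated by k raters (k = 2 for
    a two-method comparison).  Computed from the two-way ANOVA mean squares
    as (BMS - EMS) / (BMS + (k-1) EMS); the CI comes from F bounds on
    BMS/EMS.  Consistency means a fixed offset between raters does not
    lower the coefficient.
    """
    r = np.asarray(ratings, float)
    if r.ndim != 2 or r.shape[1] < 2:
        raise StatsError("ratings must be an (n, k>=2) table")
    if not np.all(np.isfinite(r)):
        raise StatsError("ratings table must be complete")
    n, k = r.shape
    if n < 3:
        raise StatsError("need at least 3 targets")
    grand = r.mean()
    ss_rows = k * np.sum((r.mean(axis=1) - grand) ** 2)
    ss_cols = n * np.sum((r.mean(axis=0) - grand) ** 2)
    ss_tot = np.sum((r - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    df1, df2 = n - 1, (n - 1) * (k - 1)
    bms = ss_rows / df1
    ems = ss_err / df2
    if bms + (k - 1) * ems == 0:
        raise StatsError("ICC undefined: no variance in the table")
    icc = (bms - ems) / (bms + (k - 1) * ems)
    if ems == 0:
        return IccResult(icc=float(icc), ci=(float(icc), float(icc)), df1=df1, df2=df2)
    f0 = bms / ems
    fl = f0 / sps.f.ppf(0.975, df1, df2)
    fu = f0 * sps.f.ppf(0.975, df2, df1)
    ci = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
    return IccResult(icc=float(icc), ci=(float(ci[0]), float(ci[1])), df1=df1, df2=df2)


def rm_anova_2way(
    table: pd.DataFrame,
    value: str = "value",
    case: str = "case",
    method: str = "method",
    side: str = "side",
) -> AnovaResult:
    """Two-way fully repeated-measures ANOVA with factors method x side.

    Every case (blocking unit, typically a trial) must be observed in all
    four method x side cells exactly once.  Each within factor is tested
    against its own case x factor interaction mean square.
    """
    df = table[[case, method, side, value]].copy()
    a_levels = sorted(df[method].unique())
    b_levels = sorted(df[side].unique())
    cases = sorted(df[case].unique())
    na, nb, nc = len(a_levels), len(b_levels), len(cases)
    if na < 2 or nb < 2:
        raise StatsError("both factors need at least two levels")
    counts = df.groupby([case, method, side], observed=True)[value].count()
    if len(counts) != na * nb * nc or not (counts == 1).all():
        raise StatsError("design must be complete with one observation per cell per case")

    cube = (
        df.pivot_table(index=case, columns=[method, side], values=value)
        .to_numpy()
        .reshape(nc, na, nb)
    )
    grand = cube.mean()
    dev = lambda m: np.sum((m - grand) ** 2)

    ss_case = na * nb * dev(cube.mean(axis=(1, 2)))
    ss_a = nc * nb * dev(cube.mean(axis=(0, 2)))
    ss_b = nc * na * dev(cube.mean(axis=(0, 1)))
    ss_ab = nc * dev(cube.mean(axis=0)) - ss_a - ss_b
    ss_ca = nb * dev(cube.mean(axis=2)) - ss_case - ss_a
    ss_cb = na * dev(cube.mean(axis=1)) - ss_case - ss_b
    ss_tot = dev(cube)
    ss_cab = ss_tot - ss_case - ss_a - ss_b - ss_ab - ss_ca - ss_cb

    def effect(name, ss_eff, df_eff, ss_err, df_err):
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        if ms_err == 0:
            f = 0.0 if ms_eff == 0 else np.inf
        else:
            f = ms_eff / ms_err
        p = float(sps.f.sf(f, df_eff, df_err)) if np.isfinite(f) else 0.0
        return AnovaEffect(name=name, ss=float(ss_eff), df1=df_eff, df2=df_err, f=float(f), p=p)

    dfc = nc - 1
    res = AnovaResult(
        method=effect("method", ss_a, na - 1, ss_ca, (na - 1) * dfc),
        side=effect("side", ss_b, nb - 1, ss_cb, (nb - 1) * dfc),
        interaction=effect("method:side", ss_ab, (na - 1) * (nb - 1), ss_cab, (na - 1) * (nb - 1) * dfc),
        ss_components={
            "case": float(ss_case), "method": float(ss_a), "side": float(ss_b),
            "method:side": float(ss_ab), "case:method": float(ss_ca),
            "case:side": float(ss_cb), "case:method:side": float(ss_cab),
        },
    )
    return res


def harmonic_mean_sd(sd1: float, sd2: float) -> float:
    if sd1 <= 0 or sd2 <= 0:
        raise StatsError("standard deviations must be positive")
    return 2.0 * sd1 * sd2 / (sd1 + sd2)


def cohens_d_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> CohenD:
    """Cohen's d from group summaries, standardised by the harmonic-mean SD.

    d = (mean2 - mean1) / (2 sd1 sd2 / (sd1 + sd2)); the 95% CI uses the
    normal approximation SE = sqrt((n1+n2)/(n1 n2) + d^2 / (2 (n1+n2))).
    """
    d = (mean2 - mean1) / harmonic_mean_sd(sd1, sd2)
    se = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2)))
    ci = (d - 1.96 * se, d + 1.96 * se)
    unclear = ci[0] < -SMALLEST_IMPORTANT_D and ci[1] > SMALLEST_IMPORTANT_D
    return CohenD(
        d=float(d),
        ci=(float(ci[0]), float(ci[1])),
        magnitude=_label(d, D_THRESHOLDS),
        clearness="unclear" if unclear else "clear",
    )


def cohens_d_harmonic(group1, group2) -> CohenD:
    """Cohen's d (group2 - group1) standardised by the harmonic-mean SD."""
    g1 = np.asarray(group1, float).ravel()
    g2 = np.asarray(group2, float).ravel()
    if len(g1) < 2 or len(g2) < 2:
        raise StatsError("each group needs at least 2 values")
    return cohens_d_from_summary(
        float(np.mean(g1)), float(np.std(g1, ddof=1)), len(g1),
        float(np.mean(g2)), float(np.std(g2, ddof=1)), len(g2),
    )


def time_normalize(series, n_points: int = 101) -> np.ndarray:
    """Linearly interpolate a series onto ``n_points`` stations over 0-100%."""
    y = np.asarray(series, float)
    if len(y) < 2 or n_points < 2:
        raise ValueError("need at least 2 input samples and 2 stations")
    x_old = np.linspace(0.0, 1.0, len(y))
    x_new = np.linspace(0.0, 1.0, n_points)
    return np.interp(x_new, x_old, y)


def compare_tables(
    df_a: pd.DataFrame,
    df_b: pd.DataFrame,
    variables,
    trial_col: str = "trial",
    side_col: str = "side",
    aggregation: str = "trial",
    subject_col: str = "subject",
) -> pd.DataFrame:
    """Full agreement/reliability report between two per-trial variable tables.

    ``df_a``/``df_b`` hold one row per trial and side for method A (the
    reference, e.g. marker-based) and method B.  Rows are matched on
    ``(trial, side)``; unmatched keys raise.  For every variable and side the
    report carries Bland–Altman bias and LoA with CIs, RMSE, Pearson r with
    CI and label, ICC(3,1) with CI, and harmonic-SD Cohen's d (B vs A) with
    CI, magnitude and clearness; the method x side repeated-measures ANOVA
    is computed once per variable over trials observed on both sides.

    ``aggregation="subject_mean"`` averages trials within subject before the
    Cohen's d computation (requires a ``subject`` column in both tables).
    """
    keys = [trial_col, side_col]
    a = df_a.set_index(keys).sort_index()
    b = df_b.set_index(keys).sort_index()
    orphans = a.index.symmetric_difference(b.index)
    if len(orphans):
        raise StatsError(f"unmatched trial/side keys: {list(orphans)[:10]}")
    if aggregation not in ("trial", "subject_mean"):
        raise StatsError("aggregation must be 'trial' or 'subject_mean'")

    rows = []
    sides = sorted(a.index.get_level_values(side_col).unique())
    for var in variables:
        # ANOVA over trials complete in all four cells.
        f_res = None
        if len(sides) == 2:
            long = []
            for meth, df in (("A", a), ("B", b)):
                part = df.reset_index()[[trial_col, side_col, var]].copy()
                part["method"] = meth
                long.append(part)
            long = pd.concat(long, ignore_index=True)
            complete = long.groupby(trial_col)[var].count() == 4
            long = long[long[trial_col].map(complete)]
            if long[trial_col].nunique() >= 2:
                f_res = rm_anova_2way(
                    long.rename(columns={var: "value", trial_col: "case"}),
                    side=side_col,
                )
        for side in sides:
            xa = a.xs(side, level=side_col)[var].to_numpy(float)
            xb = b.xs(side, level=side_col)[var].to_numpy(float)
            ba = bland_altman(xa, xb)
            row = {
                "variable": var, "side": side, "n": ba.n,
                "bias": ba.bias, "bias_lo": ba.bias_ci[0], "bias_hi": ba.bias_ci[1],
                "loa_lower": ba.loa_lower, "loa_lower_lo": ba.loa_lower_ci[0],
                "loa_lower_hi": ba.loa_lower_ci[1],
                "loa_upper": ba.loa_upper, "loa_upper_lo": ba.loa_upper_ci[0],
                "loa_upper_hi": ba.loa_upper_ci[1],
                "rmse": rmse(xa, xb),
                "r": np.nan, "r_lo": np.nan, "r_hi": np.nan, "r_label": "undefined",
                "icc31": np.nan, "icc31_lo": np.nan, "icc31_hi": np.nan,
                "cohen_d": np.nan, "cohen_d_lo": np.nan, "cohen_d_hi": np.nan,
                "d_magnitude": "undefined", "d_clearness": "undefined",
            }
            # A degenerate variable (e.g. zero variance across trials) leaves
            # its correlation-family cells undefined instead of failing the
            # whole report.
            try:
                pr = pearson_r(xa, xb)
                row.update(r=pr.r, r_lo=pr.ci[0], r_hi=pr.ci[1], r_label=pr.label)
            except StatsError:
                pass
            try:
                icc = icc_3_1(np.column_stack([xa, xb]))
                row.update(icc31=icc.icc, icc31_lo=icc.ci[0], icc31_hi=icc.ci[1])
            except StatsError:
                pass
            try:
                if aggregation == "subject_mean":
                    subj = a.xs(side, level=side_col)[subject_col].to_numpy()
                    ga = pd.Series(xa).groupby(subj).mean().to_numpy()
                    gb = pd.Series(xb).groupby(subj).mean().to_numpy()
                    d = cohens_d_harmonic(ga, gb)
                else:
                    d = cohens_d_harmonic(xa, xb)
                row.update(cohen_d=d.d, cohen_d_lo=d.ci[0], cohen_d_hi=d.ci[1],
                           d_magnitude=d.magnitude, d_clearness=d.clearness)
            except StatsError:
                pass
            if f_res is not None:
                for eff in (f_res.method, f_res.side, f_res.interaction):
                    tag = eff.name.replace("method:side", "interaction")
                    row[f"f_{tag}"] = eff.f
                    row[f"df_{tag}"] = f"{eff.df1},{eff.df2}"
                    row[f"p_{tag}"] = eff.p
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TrajectoryAgreement:
    """Station-wise curve summaries plus statistics pooled over all stations."""

    mean_x: np.ndarray
    ci_x: np.ndarray  # (2, stations)
    mean_y: np.ndarray
    ci_y: np.ndarray
    pooled: BlandAltman
    pooled_rmse: float
    pooled_r: PearsonR


def trajectory_agreement(curves_x, curves_y) -> TrajectoryAgreement:
    """Compare two sets of time-normalised curves (trials x stations).

    Per-station across-trial means and 95% CIs are reported for each method;
    bias/LoA/RMSE/r are pooled over all stations of all trials concatenated.
    """
    cx = np.atleast_2d(np.asarray(curves_x, float))
    cy = np.atleast_2d(np.asarray(curves_y, float))
    if cx.shape[1] != cy.shape[1]:
        raise StatsError(
            f"station counts differ: {cx.shape[1]} vs {cy.shape[1]}"
        )

    def band(c):
        m = c.mean(axis=0)
        if c.shape[0] > 1:
            half = sps.t.ppf(0.975, c.shape[0] - 1) * c.std(axis=0, ddof=1) / np.sqrt(c.shape[0])
        else:
            half = np.zeros_like(m)
        return m, np.vstack([m - half, m + half])

    mx, bx = band(cx)
    my, by = band(cy)
    flat_x, flat_y = cx.ravel(), cy.ravel()
    return TrajectoryAgreement(
        mean_x=mx, ci_x=bx, mean_y=my, ci_y=by,
        pooled=bland_altman(flat_x, flat_y),
        pooled_rmse=rmse(flat_x, flat_y),
        pooled_r=pearson_r(flat_x, flat_y),
    )
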