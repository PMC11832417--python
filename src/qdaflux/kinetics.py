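"""Group-level methylation kinetics.

Aggregates per-site fcut into group medians along a design axis (minutes of
induction, or enzyme concentration in nM) and fits the two models the assay
rests on:

* first-order kinetics — the apparent rate constant k is minus the slope of
  ln(median unmethylated fraction) against time;
* limit digest — the saturation curve
  ``f(c) = f_bg + (f_max - f_bg) * (1 - exp(-c / c0))`` whose plateau f_max
  is the fraction of nuclei in which the site group is accessible.

Also provides rate ratios with delta-method errors, replicate Pearson
concordance, and the induction-linearity regression (population median
methylation against the fraction of induced cells — a straight line when
per-cell methylation is much faster than induction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .fragment_quant import USABLE_STATUSES

DEFAULT_U_MIN = 0.05  # drop points where ln(u) would blow up


@dataclass
class RateFit:
    k: float           # apparent rate constant, per minute
    intercept: float   # ln(u) at t = 0
    r_squared: float
    n_points: int
    se_k: float


@dataclass
class PlateauFit:
    f_max: float
    c0: float
    f_bg: float
    method: str        # "nls" or "top2_mean"
    residual_norm: float


def group_series(
    tables: dict[float, pd.DataFrame],
    group_by: str,
    value_col: str = "fcut",
    status_col: str = "status",
) -> pd.DataFrame:
    """Median fcut (with quartile band) per group at each design point.

    ``tables`` maps design-axis value -> per-site stats frame.  Sites whose
    status is not usable (excluded / no coverage) are dropped.  Quartiles use
    linear interpolation (numpy default, type 7).
    """
    rows = []
    for x in sorted(tables):
        df = tables[x]
        if status_col in df.columns:
            df = df[df[status_col].isin(USABLE_STATUSES)]
        df = df[np.isfinite(df[value_col])]
        for group, grp in df.groupby(group_by, sort=True):
            v = grp[value_col].to_numpy(float)
            if len(v) == 0:
                continue
            med = float(np.median(v))
            rows.append(
                {
                    "group": group, "x": float(x), "median_fcut": med,
                    "q25": float(np.quantile(v, 0.25)),
                    "q75": float(np.quantile(v, 0.75)),
                    "n_sites": int(len(v)), "u": 1.0 - med,
                }
            )
    return pd.DataFrame(rows)


def fit_rate(times, u, u_min: float = DEFAULT_U_MIN) -> RateFit:
    """OLS of ln(unmethylated fraction) on time; k = -slope."""
    times = np.asarray(times, float)
    u = np.asarray(u, float)
    keep = np.isfinite(u) & (u >= u_min)
    n_dropped_nonpos = int(np.sum(np.isfinite(u) & (u <= 0)))
    if n_dropped_nonpos:
        warnings.warn(
            f"dropped {n_dropped_nonpos} point(s) with u <= 0 from rate fit",
            stacklevel=2,
        )
    t, uu = times[keep], u[keep]
    if len(t) < 3:
        raise ValueError(f"need >= 3 usable points for a rate fit, got {len(t)}")
    res = stats.linregress(t, np.log(uu))
    return RateFit(
        k=-float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        n_points=int(len(t)),
        se_k=float(res.stderr),
    )


def fit_rate_series(series: pd.DataFrame, u_min: float = DEFAULT_U_MIN) -> dict[str, RateFit]:
    """Fit a rate per group from a :func:`group_series` frame over time."""
    return {
        str(group): fit_rate(grp["x"], grp["u"], u_min=u_min)
        for group, grp in series.groupby("group", sort=True)
    }


def rate_ratio(fit_a: RateFit, fit_b: RateFit) -> tuple[float, float]:
    """kA / kB with first-order (delta-method) standard error."""
    if fit_b.k == 0:
        raise ZeroDivisionError("reference rate is zero; ratio undefined")
    ratio = fit_a.k / fit_b.k
    rel = 0.0
    if fit_a.k != 0:
        rel = (fit_a.se_k / fit_a.k) ** 2 + (fit_b.se_k / fit_b.k) ** 2
    return float(ratio), float(abs(ratio) * np.sqrt(rel))


def _saturation(c, f_bg, df, c0):
    return f_bg + df * (1.0 - np.exp(-c / c0))


def fit_plateau(conc, f) -> PlateauFit:
    """Saturating-exponential fit of fcut vs enzyme concentration.

    Falls back to the mean of the two highest-concentration medians when the
    nonlinear fit cannot converge (recorded in ``method``).
    """
    conc = np.asarray(conc, float)
    f = np.asarray(f, float)
    if len(conc) < 4 or conc.min() > 0:
        raise ValueError("plateau fit needs >= 4 concentrations including 0")
    order = np.argsort(conc)
    conc, f = conc[order], f[order]
    if np.any(np.diff(f) < -0.1):
        warnings.warn("series is non-monotone beyond noise tolerance", stacklevel=2)
    top2 = float(np.mean(f[-2:]))
    spread = float(f.max() - f.min())
    if spread < 1e-9:  # flat series: nothing to fit
        return PlateauFit(f_max=top2, c0=np.inf, f_bg=float(f[0]),
                          method="top2_mean", residual_norm=0.0)
    try:
        scale0 = np.median(conc[conc > 0])
        popt, _ = optimize.curve_fit(
            _saturation, conc, f,
            p0=[max(float(f[0]), 1e-6), max(spread, 1e-6), scale0],
            bounds=([0.0, 0.0, 1e-9], [1.0, 1.0, np.inf]),
            maxfev=10_000,
        )
        f_bg, df, c0 = popt
        resid = float(np.linalg.norm(f - _saturation(conc, *popt)))
        return PlateauFit(
            f_max=float(min(f_bg + df, 1.0)), c0=float(c0), f_bg=float(f_bg),
            method="nls", residual_norm=resid,
        )
    except RuntimeError:
        return PlateauFit(
            f_max=top2, c0=np.nan, f_bg=float(f[0]),
            method="top2_mean", residual_norm=np.nan,
        )


def replicate_concordance(
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    min_sites: int = 100,
    value_col: str = "fcut",
) -> tuple[float, int]:
    """Pearson r of fcut over sites usable in both replicates."""
    a = stats_a[stats_a["status"].isin(USABLE_STATUSES)][["chrom", "start", value_col]]
    b = stats_b[stats_b["status"].isin(USABLE_STATUSES)][["chrom", "start", value_col]]
    merged = a.merge(b, on=["chrom", "start"], suffixes=("_a", "_b")).dropna()
    n = len(merged)
    if n < min_sites:
        raise ValueError(f"only {n} shared usable sites (need >= {min_sites})")
    x = merged[f"{value_col}_a"].to_numpy(float)
    y = merged[f"{value_col}_b"].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate variance: constant fcut in one replicate")
    return float(stats.pearsonr(x, y).statistic), n


def induction_linearity(times, median_fcut, induced_fraction) -> tuple[float, float, float]:
    """Regress population median fcut on the induced-cell fraction F(t).

    Returns (slope, intercept, r_squared).  A high r_squared (the study's
    consistency criterion is > 0.97) indicates that per-cell methylation is
    fast relative to induction, so population methylation simply tracks the
    fraction of cells that have switched on.
    """
    times = np.asarray(times, float)
    y = np.asarray(median_fcut, float)
    x = np.asarray(induced_fraction, float)
    if len(times) != len(y) or len(times) != len(x):
        raise ValueError("times, median_fcut and induced_fraction must align")
    if len(times) < 3:
        raise ValueError("need >= 3 matched timepoints")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue) ** 2


def fits_to_frame(fits: dict[str, RateFit | PlateauFit]) -> pd.DataFrame:
    rows = []
    for group, fit in fits.items():
        if isinstance(fit, RateFit):
            rows.append(
                {"group": group, "mode": "rate", "estimate": fit.k, "se": fit.se_k,
                 "r_squared": fit.r_squared, "n": fit.n_points, "method": "ols_log"}
            )
        else:
            rows.append(
                {"group": group, "mode": "plateau", "estimate": fit.f_max, "se": np.nan,
                 "r_squared": np.nan, "n": np.nan, "method": fit.method}
            )
    return pd.DataFrame(rows)
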