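"""Dyad-aligned nucleosome-phasing profiles.

Methylation averaged as a function of signed distance from the +1 nucleosome
dyad shows the phased nucleosome array of a gene: methylation is high in
linkers and low inside nucleosomes, so the profile is anti-phase with the
MNase dyad-density track.  This module builds those profiles (pooling all
(site, gene) pairs), smooths them with a centered boxcar (21 bp by default),
normalizes companion dyad-density tracks to a 0.1 maximum so they fit under
fcut curves, and quantifies three things:

* anti-phase score — Pearson correlation between the methylation profile and
  the dyad density (strongly negative for phased chromatin);
* array shift — the lag maximizing cross-correlation between two profiles
  over the genic array (negative = shifted toward the promoter), the readout
  for remodeler-depletion phenotypes;
* disorder index — downstream (+2..+4 nucleosome band) peak-to-trough
  amplitude relative to the +1 band; near 1 for a well-phased array, falling
  toward 0 as downstream phasing dissolves.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_OFFSETS = (-300, 1000)
DEFAULT_SMOOTH_BP = 21
DEFAULT_MIN_PAIRS = 20
NUCLEOSOME_SPACING = 165  # typical yeast repeat length, bp


def dyad_profile(
    pairs: pd.DataFrame,
    offsets: tuple[int, int] = DEFAULT_OFFSETS,
    value_col: str = "fcut",
) -> pd.DataFrame:
    """Mean fcut at each signed offset from the +1 dyad.

    ``pairs`` is the long (site, gene) table with ``dyad_offset`` and a
    methylation value per pair; a site near two genes contributes once per
    gene.  Returns a frame on the full integer offset grid with columns
    ``offset, mean_fcut, n`` (NaN mean where no pair lands).
    """
    lo, hi = offsets
    if hi <= lo:
        raise ValueError("empty offset window")
    df = pairs[np.isfinite(pairs[value_col]) & np.isfinite(pairs["dyad_offset"])]
    off = df["dyad_offset"].round().astype(int)
    df = df[(off >= lo) & (off <= hi)].assign(_off=off[(off >= lo) & (off <= hi)])
    grid = np.arange(lo, hi + 1)
    agg = df.groupby("_off")[value_col].agg(["mean", "count"])
    out = pd.DataFrame({"offset": grid})
    out["mean_fcut"] = agg["mean"].reindex(grid).to_numpy()
    out["n"] = agg["count"].reindex(grid).fillna(0).astype(int).to_numpy()
    return out


def smooth_profile(
    profile: pd.DataFrame,
    w: int = DEFAULT_SMOOTH_BP,
    min_pairs: int | None = None,
    value_col: str = "mean_fcut",
) -> pd.DataFrame:
    """Centered boxcar over defined offsets; the window shrinks at edges.

    Undefined offsets are skipped (not zero-filled).  Offsets supported by
    fewer than ``min_pairs`` (site, gene) pairs are masked before smoothing —
    GATC is sparse enough that stray single-pair offsets are noise.
    """
    if w < 1 or w % 2 == 0:
        raise ValueError("smoothing window must be a positive odd integer")
    out = profile.copy()
    v = out[value_col].to_numpy(float).copy()
    if min_pairs is not None and "n" in out.columns:
        v[out["n"].to_numpy() < min_pairs] = np.nan
    s = pd.Series(v, index=out["offset"].to_numpy())
    out["smoothed"] = s.rolling(window=w, center=True, min_periods=1).mean().to_numpy()
    return out


def normalize_density(density: pd.DataFrame, value_col: str = "density", peak: float = 0.1) -> pd.DataFrame:
    """Scale a nonnegative dyad-density track so its maximum equals ``peak``."""
    v = density[value_col].to_numpy(float)
    if np.any(v < 0):
        raise ValueError("negative dyad-density values")
    vmax = np.nanmax(v) if len(v) else 0.0
    if not np.isfinite(vmax) or vmax <= 0:
        raise ValueError("all-zero dyad-density track cannot be normalized")
    out = density.copy()
    out[value_col] = v * (peak / vmax)
    return out


def _aligned(a: pd.DataFrame, b: pd.DataFrame, col_a: str, col_b: str):
    merged = pd.merge(
        a[["offset", col_a]], b[["offset", col_b]], on="offset", how="inner"
    ).dropna()
    return merged["offset"].to_numpy(), merged[col_a].to_numpy(float), merged[col_b].to_numpy(float)


def antiphase_score(
    profile: pd.DataFrame,
    density: pd.DataFrame,
    min_offsets: int = 50,
    profile_col: str = "smoothed",
    density_col: str = "density",
) -> float:
    """Pearson r between methylation profile and dyad density over shared offsets."""
    _, x, y = _aligned(profile, density, profile_col, density_col)
    if len(x) < min_offsets:
        raise ValueError(f"only {len(x)} shared offsets (need >= {min_offsets})")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate variance in profile or density")
    return float(np.corrcoef(x, y)[0, 1])


def estimate_shift(
    profile_a: pd.DataFrame,
    profile_b: pd.DataFrame,
    max_lag: int = 60,
    offset_range: tuple[int, int] = (0, 500),
    min_overlap: int = 50,
    value_col: str = "smoothed",
) -> int:
    """Integer lag (bp) maximizing cross-correlation of B against A.

    Sign convention: a negative lag means B's array is shifted toward the
    promoter relative to A (B at offset x matches A at x - lag).  Ties are
    broken toward the smallest |lag|.
    """
    sa = pd.Series(
        profile_a[value_col].to_numpy(float), index=profile_a["offset"].to_numpy()
    )
    sb = pd.Series(
        profile_b[value_col].to_numpy(float), index=profile_b["offset"].to_numpy()
    )
    lo, hi = offset_range
    xs = np.arange(lo, hi + 1)
    best_lag, best_r = None, -np.inf
    for lag in sorted(range(-max_lag, max_lag + 1), key=abs):
        b = sb.reindex(xs).to_numpy()
        a = sa.reindex(xs - lag).to_numpy()
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < min_overlap:
            continue
        av, bv = a[ok], b[ok]
        if np.std(av) == 0 or np.std(bv) == 0:
            continue
        r = float(np.corrcoef(av, bv)[0, 1])
        if r > best_r + 1e-12:   # strict improvement keeps smallest |lag| on ties
            best_lag, best_r = lag, r
    if best_lag is None:
        raise ValueError("insufficient overlap between profiles for shift estimation")
    return int(best_lag)


def disorder_index(
    profile: pd.DataFrame,
    plus1_band: tuple[int, int] = (-60, 110),
    downstream_band: tuple[int, int] = (110, 600),
    value_col: str = "smoothed",
) -> float:
    """Downstream peak-to-trough amplitude relative to the +1 peak.

    Approximately 1 for a well-phased array (downstream oscillation as deep
    as the +1 peak), tending to 0 as spacing downstream of +1 randomizes
    while the +1 nucleosome persists.
    """
    s = pd.Series(profile[value_col].to_numpy(float), index=profile["offset"].to_numpy())

    def amp(band):
        v = s.loc[(s.index >= band[0]) & (s.index <= band[1])].dropna()
        if len(v) == 0:
            raise ValueError(f"profile has no data in band {band}")
        return float(v.max() - v.min())

    a1 = amp(plus1_band)
    if a1 == 0:
        raise ValueError("flat +1 band: disorder index undefined")
    return amp(downstream_band) / a1


def profile_table(profile: pd.DataFrame) -> pd.DataFrame:
    """Column-ordered view for TSV output."""
    cols = [c for c in ("offset", "mean_fcut", "n", "smoothed") if c in profile.columns]
    return profile[cols]
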