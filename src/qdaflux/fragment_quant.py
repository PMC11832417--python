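"""Per-site fraction-cut (fcut) from aligned fragment coordinates.

The estimator: a DpnI cut at a methylated GATC produces one fragment ending
on the site's A and one beginning on its T (blunt cut between A and T).
Because the terminal A or T is sometimes lost during library preparation,
ends one base short (on the G, or on the C) are counted too.  For each site
with bases (G, A, T, C) at positions (s, s+1, s+2, s+3):

    fcut_right = (right_ends[s+1] + right_ends[s]) / coverage[s]
    fcut_left  = (left_ends[s+2] + left_ends[s+3]) / coverage[s+3]

where coverage[b] is the number of fragments containing base b and
left/right_ends[b] count fragments whose first/last base is b.  Sites with a
neighboring site closer than 200 bp on both sides are excluded (the
connecting fragment is too short to be recovered efficiently); with a close
neighbor on one side only, that side's fcut is replaced by the far side's.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_sites import CLOSE_NEIGHBOR_BP

logger = logging.getLogger(__name__)

DEFAULT_MAX_FRAGMENT = 5000   # aligner insert-size ceiling
DEFAULT_MIN_COVERAGE = 8      # per-side gate against 0/1 quantization

STATUS_OK = "ok"
STATUS_SUB_LEFT = "substituted_left"
STATUS_SUB_RIGHT = "substituted_right"
STATUS_EXCLUDED = "excluded"
STATUS_NO_COVERAGE = "no_coverage"

USABLE_STATUSES = (STATUS_OK, STATUS_SUB_LEFT, STATUS_SUB_RIGHT)


@dataclass
class CoverageTracks:
    """Exact integer per-bp tracks: coverage and fragment end counts."""

    coverage: dict[str, np.ndarray]
    left_ends: dict[str, np.ndarray]
    right_ends: dict[str, np.ndarray]

    def n_fragments(self) -> int:
        return int(sum(a.sum() for a in self.left_ends.values()))


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_fragments(
    path,
    fmt: str | None = None,
    max_len: int = DEFAULT_MAX_FRAGMENT,
    dedup: bool = False,
) -> pd.DataFrame:
    """Read fragments from BAM/SAM (proper pairs) or BEDPE/BED.

    A paired-end fragment is the interval from the leftmost mapped base of
    the pair to one past its rightmost mapped base.  Fragments longer than
    ``max_len`` are dropped (they exceed the aligner's insert ceiling and
    are almost certainly artifacts).  Duplicates are kept by default:
    cut-site pileups are signal here, not PCR artifacts.
    """
    if fmt is None:
        ext = os.path.splitext(str(path))[1].lower()
        fmt = "bam" if ext in (".bam", ".sam", ".cram") else "bedpe"
    if fmt.lower() in ("bam", "sam"):
        frags = _load_bam(path)
    elif fmt.lower() in ("bedpe", "bed"):
        frags = _load_bedpe(path)
    else:
        raise ValueError(f"unknown fragment format {fmt!r}")
    n0 = len(frags)
    frags = frags[(frags["end"] - frags["start"]) <= max_len].reset_index(drop=True)
    if len(frags) < n0:
        logger.info("dropped %d fragment(s) longer than %d bp", n0 - len(frags), max_len)
    if dedup:
        frags = frags.drop_duplicates().reset_index(drop=True)
    return frags


def _load_bam(path) -> pd.DataFrame:
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    rows = []
    n_cross = 0
    with pysam.AlignmentFile(str(path), mode) as bam:
        so = (bam.header.get("HD") or {}).get("SO")
        if so is not None and so != "coordinate":
            raise ValueError(f"alignment file is not coordinate-sorted (SO={so})")
        for read in bam.fetch(until_eof=True):
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or not read.is_proper_pair
                or read.template_length <= 0
            ):
                continue
            if read.reference_id != read.next_reference_id:
                n_cross += 1
                continue
            rows.append(
                (read.reference_name, read.reference_start,
                 read.reference_start + read.template_length)
            )
    if n_cross:
        logger.info("skipped %d cross-chromosome pair(s)", n_cross)
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _load_bedpe(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] >= 6 and df.dtypes[3] == object:
        # chrom1 start1 end1 chrom2 start2 end2 [...]
        same = df[0] == df[3]
        n_cross = int((~same).sum())
        if n_cross:
            logger.info("skipped %d cross-chromosome BEDPE record(s)", n_cross)
        df = df[same]
        frags = pd.DataFrame(
            {
                "chrom": df[0].astype(str),
                "start": df[[1, 4]].min(axis=1).astype(int),
                "end": df[[2, 5]].max(axis=1).astype(int),
            }
        )
    else:
        frags = pd.DataFrame(
            {
                "chrom": df[0].astype(str),
                "start": df[1].astype(int),
                "end": df[2].astype(int),
            }
        )
    if (frags["start"] >= frags["end"]).any():
        raise ValueError("fragment with start >= end in input")
    return frags.reset_index(drop=True)


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

def coverage_and_ends(frags: pd.DataFrame, chrom_sizes: dict[str, int]) -> CoverageTracks:
    """Difference-array accumulation of coverage and end-count tracks."""
    coverage, left_ends, right_ends = {}, {}, {}
    for chrom, size in chrom_sizes.items():
        coverage[chrom] = np.zeros(size, dtype=np.int64)
        left_ends[chrom] = np.zeros(size, dtype=np.int64)
        right_ends[chrom] = np.zeros(size, dtype=np.int64)
    for chrom, grp in frags.groupby("chrom", sort=False):
        if chrom not in coverage:
            raise ValueError(f"fragment on unknown chromosome {chrom!r}")
        starts = grp["start"].to_numpy(np.int64)
        ends = grp["end"].to_numpy(np.int64)
        size = chrom_sizes[chrom]
        if starts.min(initial=0) < 0 or ends.max(initial=0) > size:
            bad = grp[(grp["start"] < 0) | (grp["end"] > size)].iloc[0]
            raise ValueError(
                f"out-of-bounds fragment {bad['chrom']}:{bad['start']}-{bad['end']} "
                f"(chromosome length {size})"
            )
        diff = np.zeros(size + 1, dtype=np.int64)
        np.add.at(diff, starts, 1)
        np.add.at(diff, ends, -1)
        coverage[chrom] += np.cumsum(diff[:-1])
        np.add.at(left_ends[chrom], starts, 1)
        np.add.at(right_ends[chrom], ends - 1, 1)
    return CoverageTracks(coverage, left_ends, right_ends)


# ---------------------------------------------------------------------------
# per-site statistics
# ---------------------------------------------------------------------------

def site_fcut(sites: pd.DataFrame, tracks: CoverageTracks) -> pd.DataFrame:
    """Raw per-side cut fractions for GATC sites from the tracks.

    Returns one row per site with end counts, coverage denominators and
    ``fcut_left/fcut_right`` (NaN where the denominator base has zero
    coverage).  Neighbor policy and side combination are applied separately
    by :func:`apply_neighbor_policy`.
    """
    out = sites[[c for c in sites.columns]].copy().reset_index(drop=True)
    n = len(out)
    cols = {
        k: np.zeros(n, dtype=np.int64)
        for k in ("n_right_A", "n_right_G", "n_left_T", "n_left_C", "cov_G", "cov_C")
    }
    fcr = np.full(n, np.nan)
    fcl = np.full(n, np.nan)
    for chrom, idx in out.groupby("chrom", sort=False).groups.items():
        idx = np.asarray(idx)
        s = out.loc[idx, "start"].to_numpy(np.int64)
        cov = tracks.coverage[chrom]
        le = tracks.left_ends[chrom]
        re_ = tracks.right_ends[chrom]
        cols["n_right_G"][idx] = re_[s]
        cols["n_right_A"][idx] = re_[s + 1]
        cols["n_left_T"][idx] = le[s + 2]
        cols["n_left_C"][idx] = le[s + 3]
        cols["cov_G"][idx] = cov[s]
        cols["cov_C"][idx] = cov[s + 3]
    for k, v in cols.items():
        out[k] = v
    with np.errstate(invalid="ignore", divide="ignore"):
        fcr = np.where(
            cols["cov_G"] > 0, (cols["n_right_A"] + cols["n_right_G"]) / cols["cov_G"], np.nan
        )
        fcl = np.where(
            cols["cov_C"] > 0, (cols["n_left_T"] + cols["n_left_C"]) / cols["cov_C"], np.nan
        )
    out["fcut_right"] = fcr
    out["fcut_left"] = fcl
    return out


def apply_neighbor_policy(
    stats: pd.DataFrame,
    min_gap: int = CLOSE_NEIGHBOR_BP,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Exclusion/substitution for close neighbors; combine sides into fcut.

    * both gaps < ``min_gap``  -> status ``excluded``, fcut unset;
    * one gap  < ``min_gap``   -> the close side's fcut is overwritten by the
      far side's value (status ``substituted_*``);
    * otherwise fcut is the mean of the usable sides.

    A side with coverage below ``min_coverage`` is flagged low-coverage and
    never contributes; sites with no usable side get ``no_coverage``.
    """
    out = stats.copy()
    if "left_gap" not in out.columns or "right_gap" not in out.columns:
        raise ValueError("stats must carry left_gap/right_gap (merge the sites table)")
    lg = out["left_gap"].to_numpy(float)
    rg = out["right_gap"].to_numpy(float)
    fcl = out["fcut_left"].to_numpy(float).copy()
    fcr = out["fcut_right"].to_numpy(float).copy()
    low_l = (out["cov_C"].to_numpy() < min_coverage) | np.isnan(fcl)
    low_r = (out["cov_G"].to_numpy() < min_coverage) | np.isnan(fcr)
    usable_l = ~low_l
    usable_r = ~low_r

    status = np.full(len(out), STATUS_OK, dtype=object)
    fcut = np.full(len(out), np.nan)

    both_close = (lg < min_gap) & (rg < min_gap)
    left_close = (lg < min_gap) & ~both_close
    right_close = (rg < min_gap) & ~both_close
    open_both = ~(both_close | left_close | right_close)

    status[both_close] = STATUS_EXCLUDED

    m = left_close & usable_r
    fcl[m] = fcr[m]
    fcut[m] = fcr[m]
    status[m] = STATUS_SUB_LEFT
    status[left_close & ~usable_r] = STATUS_NO_COVERAGE

    m = right_close & usable_l
    fcr[m] = fcl[m]
    fcut[m] = fcl[m]
    status[m] = STATUS_SUB_RIGHT
    status[right_close & ~usable_l] = STATUS_NO_COVERAGE

    m = open_both & usable_l & usable_r
    fcut[m] = 0.5 * (fcl[m] + fcr[m])
    m = open_both & usable_l & ~usable_r
    fcut[m] = fcl[m]
    m = open_both & ~usable_l & usable_r
    fcut[m] = fcr[m]
    status[open_both & ~usable_l & ~usable_r] = STATUS_NO_COVERAGE

    out["fcut_left"] = fcl
    out["fcut_right"] = fcr
    out["fcut"] = fcut
    out["status"] = status
    out["low_coverage_left"] = low_l
    out["low_coverage_right"] = low_r
    return out


def quantify(
    sites: pd.DataFrame,
    frags: pd.DataFrame,
    chrom_sizes: dict[str, int],
    min_gap: int = CLOSE_NEIGHBOR_BP,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Fragments -> tracks -> per-site fcut with the neighbor policy applied."""
    tracks = coverage_and_ends(frags, chrom_sizes)
    stats = site_fcut(sites, tracks)
    return apply_neighbor_policy(stats, min_gap=min_gap, min_coverage=min_coverage)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def fcut_table(
    sites: pd.DataFrame,
    stats_by_sample: dict[str, pd.DataFrame],
    drop_excluded: bool = False,
) -> pd.DataFrame:
    """Join per-sample fcut columns onto the site table (wide format)."""
    out = sites.copy()
    for sample, stats in stats_by_sample.items():
        col = f"fcut_{sample}"
        if col in out.columns:
            raise ValueError(f"sample column collision: {col}")
        sub = stats[["chrom", "start", "fcut", "status"]].rename(
            columns={"fcut": col, "status": f"status_{sample}"}
        )
        out = out.merge(sub, on=["chrom", "start"], how="left")
    if drop_excluded:
        status_cols = [c for c in out.columns if c.startswith("status_")]
        keep = np.ones(len(out), dtype=bool)
        for c in status_cols:
            keep &= out[c].isin(USABLE_STATUSES)
        out = out[keep].reset_index(drop=True)
    return out


def write_fcut_table(stats: pd.DataFrame, path) -> None:
    stats.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_fcut_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
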