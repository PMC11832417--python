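"""Long-read CpG methylation-call aggregation.

Ingests Nanopolish-style per-read methylation call tables, splits
proximity-grouped CG calls back into individual sites, classifies calls by
log-likelihood ratio, and aggregates to per-site methylation frequencies
with the low-coverage filter (sites under 10% of the median coverage are
flagged out).  Frequencies are exported on the common site-table layout
(frequency mapped onto the ``fcut`` column) so the kinetics and phasing
modules run unchanged on CG data.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = [
    "chromosome", "strand", "start", "end", "read_name",
    "log_lik_ratio", "num_motifs", "sequence",
]

DEFAULT_LLR_THRESHOLD = 2.0
DEFAULT_COVERAGE_FRACTION = 0.10

CALL_METHYLATED = "methylated"
CALL_UNMETHYLATED = "unmethylated"
CALL_AMBIGUOUS = "ambiguous"


def parse_calls(path) -> tuple[pd.DataFrame, int]:
    """Read a Nanopolish-dialect TSV; returns (records, n_skipped).

    Rows with unparseable coordinates/LLR or inconsistent spans are counted
    and dropped rather than raising.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    n0 = len(df)
    for col in ("start", "end", "num_motifs"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["log_lik_ratio"] = pd.to_numeric(df["log_lik_ratio"], errors="coerce")
    ok = (
        df[["start", "end", "num_motifs", "log_lik_ratio"]].notna().all(axis=1)
        & np.isfinite(df["log_lik_ratio"])
        & (df["num_motifs"] >= 1)
        & (df["start"] <= df["end"])
        & df["sequence"].notna()
    )
    out = df[ok].copy()
    for col in ("start", "end", "num_motifs"):
        out[col] = out[col].astype(int)
    n_skipped = n0 - len(out)
    if n_skipped:
        logger.info("skipped %d malformed call row(s) of %d", n_skipped, n0)
    return out.reset_index(drop=True), n_skipped


def classify_call(log_lik_ratio: float, threshold: float = DEFAULT_LLR_THRESHOLD) -> str:
    """Three-way call: LLR >= +thr methylated, <= -thr unmethylated, else ambiguous."""
    if not np.isfinite(log_lik_ratio):
        raise ValueError("non-finite log-likelihood ratio")
    if log_lik_ratio >= threshold:
        return CALL_METHYLATED
    if log_lik_ratio <= -threshold:
        return CALL_UNMETHYLATED
    return CALL_AMBIGUOUS


def split_groups(calls: pd.DataFrame, flank: int = 5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One provisional per-CG call per grouped record.

    CG positions are recovered from the sequence context: the first CG in the
    context anchors at ``start``, and every CG in the group inherits the
    group's LLR.  Records whose context CG count does not match
    ``num_motifs`` are quarantined, not guessed at.

    Returns ``(per_cg_calls, quarantined_records)``.
    """
    seqs = calls["sequence"].str.upper()
    cg_offsets = seqs.apply(lambda s: [i for i in range(len(s) - 1) if s[i: i + 2] == "CG"])
    n_found = cg_offsets.str.len()
    bad = n_found != calls["num_motifs"]
    quarantined = calls[bad].copy()
    if len(quarantined):
        logger.warning(
            "quarantined %d record(s): context CG count != num_motifs", len(quarantined)
        )
    good = calls[~bad]
    offs = cg_offsets[~bad]
    rows = []
    for rec, off_list in zip(good.itertuples(), offs):
        base = rec.start - off_list[0]
        for o in off_list:
            rows.append(
                (rec.chromosome, base + o, rec.read_name, rec.log_lik_ratio)
            )
    per_cg = pd.DataFrame(rows, columns=["chrom", "pos", "read_name", "log_lik_ratio"])
    return per_cg, quarantined


def site_frequencies(
    per_cg: pd.DataFrame,
    threshold: float = DEFAULT_LLR_THRESHOLD,
    coverage_fraction: float = DEFAULT_COVERAGE_FRACTION,
) -> pd.DataFrame:
    """Per-site methylation frequencies with the relative-coverage filter.

    Ambiguous calls are excluded from coverage; ``pass_filter`` is False for
    sites with coverage below ``coverage_fraction`` of the median coverage
    (over sites with any coverage).
    """
    if len(per_cg) == 0:
        raise ValueError("no per-CG calls to aggregate")
    llr = per_cg["log_lik_ratio"].to_numpy(float)
    meth = llr >= threshold
    unmeth = llr <= -threshold
    df = per_cg.assign(_m=meth.astype(int), _u=unmeth.astype(int),
                       _a=(~meth & ~unmeth).astype(int))
    agg = (
        df.groupby(["chrom", "pos"], sort=True)[["_m", "_u", "_a"]]
        .sum()
        .reset_index()
        .rename(columns={"_m": "n_methylated", "_u": "n_unmethylated", "_a": "n_ambiguous"})
    )
    agg["coverage"] = agg["n_methylated"] + agg["n_unmethylated"]
    with np.errstate(invalid="ignore"):
        agg["frequency"] = np.where(
            agg["coverage"] > 0, agg["n_methylated"] / agg["coverage"], np.nan
        )
    covered = agg.loc[agg["coverage"] > 0, "coverage"]
    median_cov = float(covered.median()) if len(covered) else 0.0
    agg["pass_filter"] = agg["coverage"] >= coverage_fraction * median_cov
    if median_cov == 0.0:
        agg["pass_filter"] = False
    return agg


def aggregate_calls(
    calls: pd.DataFrame,
    threshold: float = DEFAULT_LLR_THRESHOLD,
    coverage_fraction: float = DEFAULT_COVERAGE_FRACTION,
) -> pd.DataFrame:
    """parse -> split -> frequencies in one step (records already parsed)."""
    per_cg, _ = split_groups(calls)
    return site_frequencies(per_cg, threshold=threshold, coverage_fraction=coverage_fraction)


def to_fcut_table(freqs: pd.DataFrame, motif: str = "CG") -> pd.DataFrame:
    """Map per-site frequencies onto the common fcut table layout.

    Filtered-out sites keep their row but carry a ``no_coverage`` status so
    the kinetics/phasing modules drop them uniformly.
    """
    out = pd.DataFrame(
        {
            "chrom": freqs["chrom"],
            "start": freqs["pos"].astype(int),
            "motif": motif,
            "fcut": freqs["frequency"],
            "coverage": freqs["coverage"],
            "status": np.where(freqs["pass_filter"], "ok", "no_coverage"),
        }
    )
    return out
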