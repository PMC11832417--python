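"""Motif-site census and annotation.

Methyltransferase accessibility footprinting reads out single genomic
positions: every occurrence of the probe enzyme's recognition motif (GATC for
Dam, CG for M.SssI) is a potential reporter of local chromatin state.  This
module builds the per-genome site table that every downstream stage keys on:
motif occurrences with their cut midpoints, distances to neighboring sites
(which drive the short-fragment exclusion/substitution policy), genomic
region classes, owning genes with signed offsets from the +1 nucleosome dyad,
and transcription-activity deciles.

Coordinates are 0-based half-open throughout.  BED input is taken natively;
GFF3 starts are decremented on ingestion.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Region classes accepted by :func:`classify_sites`, in precedence order
#: (first wins when annotations overlap).  Rarer, stronger-signal classes
#: outrank broad ones; unannotated sites fall through to ``"other"``.
REGION_PRECEDENCE = ("CEN", "silenced", "tRNA", "NDR", "ARS", "TEL", "Ty", "ORF")

REGION_CLASSES = REGION_PRECEDENCE + ("other",)

#: Minimum distance (bp) between neighboring cut midpoints below which a side
#: is considered "close" for the exclusion/substitution policy.
CLOSE_NEIGHBOR_BP = 200

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

SITE_COLUMNS = [
    "chrom", "start", "motif", "midpoint", "left_gap", "right_gap",
    "region_class", "gene_id", "dyad_offset", "decile",
]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def cut_midpoint_offset(motif: str) -> int:
    """Offset of the cut midpoint from the motif start.

    For GATC the blunt DpnI cut falls between the A and the T, i.e. at
    ``start + 2``; for CG the anchor is the G/C boundary at ``start + 1``.
    Both are ``len(motif) // 2`` for these palindromic motifs.
    """
    return len(motif) // 2


def _validate_motif(motif: str) -> None:
    if not motif or any(b not in "ACGT" for b in motif):
        raise ValueError(f"invalid motif {motif!r}: must be non-empty uppercase ACGT")
    if reverse_complement(motif) != motif:
        raise ValueError(
            f"motif {motif!r} is not a reverse-complement palindrome; "
            "only palindromic motifs (GATC, CG, ...) are supported"
        )


def _as_sequences(genome) -> dict[str, str]:
    """Accept a mapping name->sequence or a pyfaidx/Bio-style record set."""
    seqs = {}
    if hasattr(genome, "keys"):
        for name in genome.keys():
            seqs[str(name)] = str(genome[name])
    else:  # iterable of records with .id / .seq (Biopython SeqRecord)
        for rec in genome:
            seqs[str(rec.id)] = str(rec.seq)
    return seqs


def scan_motif(genome, motif: str) -> pd.DataFrame:
    """Locate every forward-strand occurrence of a palindromic motif.

    Overlapping occurrences are all reported; ambiguity codes in the genome
    never match.  Returns a frame with columns ``chrom, start, motif,
    midpoint`` sorted by (chrom, start).
    """
    _validate_motif(motif)
    seqs = _as_sequences(genome)
    off = cut_midpoint_offset(motif)
    rows: list[tuple[str, int]] = []
    for chrom in seqs:
        seq = seqs[chrom].upper()
        i = seq.find(motif)
        while i != -1:
            rows.append((chrom, i))
            i = seq.find(motif, i + 1)  # step 1 so overlaps are kept
    df = pd.DataFrame(rows, columns=["chrom", "start"])
    if df.empty:
        df = pd.DataFrame({"chrom": pd.Series(dtype=str),
                           "start": pd.Series(dtype=np.int64)})
    df["motif"] = motif
    df["midpoint"] = df["start"] + off
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return df


def _require_sorted(sites: pd.DataFrame) -> None:
    by_chrom = sites.groupby("chrom", sort=False)["start"]
    if not bool(by_chrom.apply(lambda s: s.is_monotonic_increasing).all()):
        raise ValueError("sites must be sorted by (chrom, start)")


def neighbor_gaps(sites: pd.DataFrame, chrom_sizes: dict[str, int]) -> pd.DataFrame:
    """Fill ``left_gap``/``right_gap`` between adjacent cut midpoints.

    The first/last site on a chromosome takes the distance to the chromosome
    end on its unbounded side, so an end-truncated side (< 200 bp of
    recoverable flank) is treated exactly like a close neighbor downstream.
    """
    _require_sorted(sites)
    out = sites.copy()
    left = np.empty(len(out), dtype=float)
    right = np.empty(len(out), dtype=float)
    for chrom, idx in out.groupby("chrom", sort=False).groups.items():
        mids = out.loc[idx, "midpoint"].to_numpy()
        if chrom not in chrom_sizes:
            raise KeyError(f"no chromosome size for {chrom!r}")
        size = int(chrom_sizes[chrom])
        lg = np.empty(len(mids), dtype=float)
        rg = np.empty(len(mids), dtype=float)
        lg[1:] = np.diff(mids)
        rg[:-1] = np.diff(mids)
        lg[0] = mids[0]            # distance to chromosome start
        rg[-1] = size - mids[-1]   # distance to chromosome end
        left[np.asarray(idx)] = lg
        right[np.asarray(idx)] = rg
    out["left_gap"] = left
    out["right_gap"] = right
    if (out["left_gap"] < 0).any() or (out["right_gap"] < 0).any():
        raise ValueError("negative neighbor gap: sites outside chromosome bounds?")
    return out


def classify_sites(sites: pd.DataFrame, regions: pd.DataFrame | None) -> pd.DataFrame:
    """Assign each site the region class containing its cut midpoint.

    ``regions`` needs columns ``chrom, start, end, region_class`` (half-open).
    Overlaps are resolved by :data:`REGION_PRECEDENCE`; unannotated sites get
    ``"other"``.
    """
    out = sites.copy()
    out["region_class"] = "other"
    if regions is None or len(regions) == 0:
        return out
    bad = set(regions["region_class"]) - set(REGION_PRECEDENCE)
    if bad:
        offending = regions[regions["region_class"].isin(bad)]
        raise ValueError(
            f"unknown region class label(s) {sorted(bad)}; offending records:\n"
            f"{offending.head().to_string(index=False)}"
        )
    mids = out["midpoint"].to_numpy()
    chroms = out["chrom"].to_numpy()
    # Paint lowest precedence first so higher-precedence classes overwrite.
    for cls in reversed(REGION_PRECEDENCE):
        for rec in regions[regions["region_class"] == cls].itertuples():
            mask = (chroms == rec.chrom) & (mids >= rec.start) & (mids < rec.end)
            if mask.any():
                out.loc[mask, "region_class"] = cls
    return out


def assign_deciles(genes: pd.DataFrame) -> pd.DataFrame:
    """Split genes into 10 activity deciles; decile 1 is the most active.

    Genes are ranked by descending ``polII_signal`` (ties broken by
    lexicographic ``gene_id`` for determinism) and cut into 10 contiguous
    blocks whose sizes differ by at most one.
    """
    if genes["polII_signal"].isna().any():
        raise ValueError("polII_signal missing for some genes")
    n = len(genes)
    if n < 10:
        raise ValueError(f"need at least 10 genes to form deciles, got {n}")
    order = genes.sort_values(
        ["polII_signal", "gene_id"], ascending=[False, True], kind="mergesort"
    ).index
    base, rem = divmod(n, 10)
    sizes = [base + 1 if d < rem else base for d in range(10)]
    deciles = np.repeat(np.arange(1, 11), sizes)
    out = genes.copy()
    out.loc[order, "decile"] = deciles
    out["decile"] = out["decile"].astype(int)
    return out


def map_sites_to_genes(
    sites: pd.DataFrame,
    genes: pd.DataFrame,
    window: tuple[int, int] = (300, 1000),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach sites to genes by signed offset from the +1 nucleosome dyad.

    ``dyad_offset = midpoint - plus_one_dyad`` on + strand, negated on -
    strand, so positive offsets always point into the gene body.  A site
    within the window of several genes contributes one (site, gene) pair per
    gene — this is what phasing profiles average over.

    Returns ``(annotated_sites, pairs)``: the sites frame gains
    ``gene_id/dyad_offset/decile`` from its smallest-|offset| assignment, and
    ``pairs`` holds the full long-format (site, gene) table.
    """
    upstream, downstream = window
    pair_rows = []
    n_missing_dyad = 0
    for g in genes.itertuples():
        dyad = getattr(g, "plus_one_dyad", None)
        if dyad is None or (isinstance(dyad, float) and np.isnan(dyad)):
            n_missing_dyad += 1
            continue
        sel = sites[sites["chrom"] == g.chrom]
        if sel.empty:
            continue
        raw = sel["midpoint"].to_numpy() - int(dyad)
        off = raw if g.strand == "+" else -raw
        keep = (off >= -upstream) & (off <= downstream)
        if not keep.any():
            continue
        sub = sel.loc[keep, ["chrom", "start"]].copy()
        sub["gene_id"] = g.gene_id
        sub["dyad_offset"] = off[keep].astype(int)
        if "decile" in genes.columns:
            sub["decile"] = getattr(g, "decile")
        pair_rows.append(sub)
    if n_missing_dyad:
        logger.warning("skipped %d gene(s) with missing +1 dyad", n_missing_dyad)
    if pair_rows:
        pairs = pd.concat(pair_rows, ignore_index=True)
    else:
        pairs = pd.DataFrame(columns=["chrom", "start", "gene_id", "dyad_offset"])

    out = sites.copy()
    for col, default in (("gene_id", pd.NA), ("dyad_offset", np.nan), ("decile", np.nan)):
        if col not in out.columns:
            out[col] = default
    if not pairs.empty:
        best = (
            pairs.assign(absoff=pairs["dyad_offset"].abs())
            .sort_values(["chrom", "start", "absoff"], kind="mergesort")
            .drop_duplicates(["chrom", "start"])
        )
        out = out.drop(columns=[c for c in ("gene_id", "dyad_offset", "decile") if c in out.columns])
        keep_cols = ["chrom", "start", "gene_id", "dyad_offset"] + (
            ["decile"] if "decile" in best.columns else []
        )
        out = out.merge(best[keep_cols], on=["chrom", "start"], how="left")
        if "decile" not in out.columns:
            out["decile"] = np.nan
    return out, pairs


def build_site_table(
    genome,
    motif: str,
    chrom_sizes: dict[str, int] | None = None,
    regions: pd.DataFrame | None = None,
    genes: pd.DataFrame | None = None,
    window: tuple[int, int] = (300, 1000),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-call census: scan, gaps, classes, gene mapping, deciles.

    Returns ``(sites, pairs)`` where ``pairs`` is the (site, gene) long table
    (empty when ``genes`` is None).
    """
    seqs = _as_sequences(genome)
    if chrom_sizes is None:
        chrom_sizes = {c: len(s) for c, s in seqs.items()}
    sites = scan_motif(seqs, motif)
    sites = neighbor_gaps(sites, chrom_sizes)
    sites = classify_sites(sites, regions)
    pairs = pd.DataFrame(columns=["chrom", "start", "gene_id", "dyad_offset"])
    if genes is not None:
        if "decile" not in genes.columns and "polII_signal" in genes.columns and len(genes) >= 10:
            genes = assign_deciles(genes)
        sites, pairs = map_sites_to_genes(sites, genes, window=window)
    else:
        sites["gene_id"] = pd.NA
        sites["dyad_offset"] = np.nan
        sites["decile"] = np.nan
    return sites[SITE_COLUMNS + [c for c in sites.columns if c not in SITE_COLUMNS]], pairs


def read_genes_table(path) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "strand", "plus_one_dyad"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"genes table missing column(s): {sorted(missing)}")
    return genes


def read_regions_bed(path) -> pd.DataFrame:
    """BED with the class label in the name (4th) column."""
    regions = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "region_class"],
    )
    return regions


def write_sites_table(sites: pd.DataFrame, path) -> None:
    sites.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_sites_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    df["start"] = df["start"].astype(int)
    return df
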