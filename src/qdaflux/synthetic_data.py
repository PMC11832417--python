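"""Ground-truthed chromatin/methylation simulator.

Generates everything the downstream stages consume — per-cell methylation
states, DpnI-cut + sonicated fragment files, and long-read CpG call tables —
from a known chromatin model, so every estimator in the package can be tested
against its own ground truth.

Two probing regimes are modeled:

* ``nuclei`` — static chromatin titrated with increasing enzyme
  concentration.  Each (cell, site) is accessible with a class-dependent
  probability ``p``; accessible sites saturate toward full methylation as
  ``1 - exp(-c / c0)``, so the population fraction plateaus at ``p`` — the
  limit digest.
* ``in_vivo`` — dynamic chromatin probed by an induced enzyme.  Each cell
  starts methylating after an exponential induction delay (half-time ~80 min)
  with a log-normal cell-to-cell enzyme-level multiplier; each site is then
  methylated as a first-order process with a class-dependent rate ``k``
  (per minute).  Methylation is irreversible, hence monotone in time within
  a cell.

Fragmentation emulates library construction: complete DpnI cutting at every
methylated GATC (blunt cut between the A and the T), Poisson sonication
breakpoints at rate 1/L, inefficient recovery of short fragments (linear ramp
over a length window), and stochastic removal of the terminal A/T at
DpnI-cut ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import genome_sites

LN2 = float(np.log(2.0))

NUCLEOSOME_HALF_WIDTH = 73  # bp of DNA protected on each side of the dyad


# ---------------------------------------------------------------------------
# parameter bundles
# ---------------------------------------------------------------------------

@dataclass
class KineticsParams:
    """Per-class accessibility parameters for one probing regime.

    mode
        ``"nuclei"`` (concentration titration of static chromatin) or
        ``"in_vivo"`` (time course of induced methylation).
    plateau
        nuclei mode: class -> accessible fraction of cells, in [0, 1].
    rate
        in_vivo mode: class -> first-order methylation rate (per minute).
    f0
        pre-induction background methylated fraction (scalar or per class).
    c0
        nuclei mode: concentration scale (nM) of the saturation curve.
    """

    mode: str
    plateau: dict[str, float] | None = None
    rate: dict[str, float] | None = None
    f0: float | dict[str, float] = 0.0
    c0: float = 0.8

    def __post_init__(self):
        if self.mode not in ("nuclei", "in_vivo"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "nuclei" and self.plateau is None:
            raise ValueError("nuclei mode requires per-class plateau table")
        if self.mode == "in_vivo" and self.rate is None:
            raise ValueError("in_vivo mode requires per-class rate table")
        table = self.plateau if self.mode == "nuclei" else self.rate
        for cls, v in table.items():
            if self.mode == "nuclei" and not 0.0 <= v <= 1.0:
                raise ValueError(f"plateau for {cls!r} outside [0, 1]: {v}")
            if self.mode == "in_vivo" and v < 0:
                raise ValueError(f"negative rate for {cls!r}: {v}")

    def per_site(self, sites: pd.DataFrame, column: str | None = None) -> np.ndarray:
        table = self.plateau if self.mode == "nuclei" else self.rate
        classes = sites["region_class"].to_numpy()
        unknown = set(classes) - set(table)
        if unknown:
            raise KeyError(f"no kinetic parameters for class(es) {sorted(unknown)}")
        return np.array([table[c] for c in classes], dtype=float)

    def f0_per_site(self, sites: pd.DataFrame) -> np.ndarray:
        if isinstance(self.f0, dict):
            return np.array([self.f0.get(c, 0.0) for c in sites["region_class"]], float)
        return np.full(len(sites), float(self.f0))


@dataclass
class InductionModel:
    """Exponential induction delay + log-normal enzyme-level variation.

    ``half_time`` (minutes): time by which half of the cells have begun to
    express the probe enzyme; delays are Exponential(ln 2 / half_time).
    ``sigma_cell``: log-sd of the per-cell rate multiplier (median 1).
    """

    half_time: float = 80.0
    sigma_cell: float = 0.5

    def __post_init__(self):
        if self.half_time <= 0:
            raise ValueError("half_time must be > 0")
        if self.sigma_cell < 0:
            raise ValueError("sigma_cell must be >= 0")


#: Effectively instantaneous, homogeneous induction — useful for rate
#: calibration scenarios where the cell-level delay is not under study.
INSTANT_INDUCTION = InductionModel(half_time=1e-9, sigma_cell=0.0)


@dataclass
class FragmentationParams:
    mean_length: float = 350.0        # sonication scale L (bp)
    recovery_lo: float = 100.0        # recovery ramp: 0% at/below this length
    recovery_hi: float = 300.0        # 100% at/above this length
    terminal_loss_prob: float = 0.3   # q: DpnI end loses its terminal A/T

    def __post_init__(self):
        if self.mean_length <= 0:
            raise ValueError("mean_length must be > 0")
        if not 0.0 <= self.terminal_loss_prob <= 1.0:
            raise ValueError("terminal_loss_prob must be in [0, 1]")
        if self.recovery_lo >= self.recovery_hi:
            raise ValueError("recovery_lo must be < recovery_hi")

    def recovery_prob(self, lengths: np.ndarray) -> np.ndarray:
        return np.clip(
            (np.asarray(lengths, float) - self.recovery_lo)
            / (self.recovery_hi - self.recovery_lo),
            0.0, 1.0,
        )


#: Recovery ramp switched off (every fragment retained) — isolates other
#: features of the fragmentation model in tests.
NO_RECOVERY_LOSS = dict(recovery_lo=-2.0, recovery_hi=-1.0)


@dataclass
class ChromatinModel:
    """Simulator ground truth: genome, site table, genes/regions layout."""

    seqs: dict[str, str]
    sites: pd.DataFrame                       # needs chrom/start/midpoint/region_class
    genes: pd.DataFrame | None = None
    regions: pd.DataFrame | None = None
    pairs: pd.DataFrame | None = None         # (site, gene) dyad-offset table

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.seqs.items()}


@dataclass
class MethylationStates:
    """Boolean methylation states, design point x cell x site."""

    axis: str                       # "time_min" or "conc_nM"
    design: np.ndarray              # shape (D,)
    states: np.ndarray              # bool, shape (D, n_cells, n_sites)
    sites: pd.DataFrame
    expected: np.ndarray            # (D, n_sites) mean per-cell probability
    induction_delays: np.ndarray | None = None   # (n_cells,), in_vivo only
    cell_multipliers: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.states.shape[1]

    def induced_fraction(self, t: float) -> float:
        """Empirical fraction of cells induced by time t (in_vivo only)."""
        if self.induction_delays is None:
            raise ValueError("no induction delays: nuclei-mode states")
        return float(np.mean(self.induction_delays <= t))


# ---------------------------------------------------------------------------
# genome / scenario construction helpers
# ---------------------------------------------------------------------------

def random_genome(chrom_sizes: dict[str, int], seed: int, gc: float = 0.38) -> dict[str, str]:
    """I.i.d. random genome with yeast-like GC content."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.frombuffer(b"ACGT", dtype="S1")
    return {
        chrom: b"".join(rng.choice(bases, size=size, p=p)).decode()
        for chrom, size in chrom_sizes.items()
    }


def dam_rate_preset(k_orf: float = 0.01) -> dict[str, float]:
    """In-vivo Dam scenario: region rates as multiples of the ORF rate.

    NDR 1.3x, tRNA 1.2x, ARS/TEL/Ty 1x, centromeres 14-fold slower,
    silenced loci strongly protected.
    """
    return {
        "ORF": k_orf, "NDR": 1.3 * k_orf, "tRNA": 1.2 * k_orf,
        "ARS": k_orf, "TEL": k_orf, "Ty": k_orf,
        "CEN": k_orf / 14.0, "silenced": k_orf / 20.0, "other": k_orf,
    }


def cg_rate_preset(k_orf: float = 0.004) -> dict[str, float]:
    """In-vivo M.SssI scenario: NDR 2.9x faster than ORF."""
    preset = dam_rate_preset(k_orf)
    preset["NDR"] = 2.9 * k_orf
    return preset


def nuclei_plateau_preset(p_orf: float = 0.30, p_ndr: float = 0.70) -> dict[str, float]:
    """Static-nuclei limit digest: ~30% of nuclei expose an ORF site, ~70% an NDR site."""
    return {
        "ORF": p_orf, "NDR": p_ndr, "tRNA": p_ndr, "ARS": p_orf,
        "TEL": p_orf, "Ty": p_orf, "CEN": 0.05, "silenced": 0.05,
        "other": p_orf,
    }


def make_demo_model(
    seed: int,
    chrom_len: int = 60_000,
    n_genes: int = 25,
    motif: str = "GATC",
    gene_pitch: int = 2200,
    ndr_width: int = 140,
) -> ChromatinModel:
    """Toy single-chromosome genome with a regular gene layout.

    Genes are tiled every ``gene_pitch`` bp, each with a promoter NDR
    immediately upstream of its +1 dyad and an ORF body downstream; one
    centromere, one tRNA gene, one silenced locus, one ARS, one Ty element
    and telomeric margins are planted so that all region classes occur.
    """
    seqs = random_genome({"chrS": chrom_len}, seed)
    gene_rows, region_rows = [], []
    region_rows.append(("chrS", 0, 1500, "TEL"))
    region_rows.append(("chrS", chrom_len - 1500, chrom_len, "TEL"))
    rng = np.random.default_rng(seed + 1)
    first = 3000
    for i in range(n_genes):
        dyad = first + i * gene_pitch
        if dyad + 1400 > chrom_len - 1600:
            break
        strand = "+"
        gene_rows.append((f"gene{i:03d}", "chrS", strand, dyad, float(rng.gamma(2.0, 50.0))))
        region_rows.append(("chrS", dyad - ndr_width - 40, dyad - 40, "NDR"))
        region_rows.append(("chrS", dyad - 40, dyad + 1400, "ORF"))
    span = chrom_len
    region_rows.append(("chrS", span // 2 - 60, span // 2 + 60, "CEN"))
    region_rows.append(("chrS", span // 4 - 40, span // 4 + 40, "tRNA"))
    region_rows.append(("chrS", 3 * span // 4 - 100, 3 * span // 4 + 100, "ARS"))
    region_rows.append(("chrS", span // 8 - 150, span // 8 + 150, "Ty"))
    region_rows.append(("chrS", 7 * span // 8 - 200, 7 * span // 8 + 200, "silenced"))
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "strand", "plus_one_dyad", "polII_signal"]
    )
    regions = pd.DataFrame(region_rows, columns=["chrom", "start", "end", "region_class"])
    regions[["start", "end"]] = regions[["start", "end"]].clip(lower=0, upper=chrom_len)
    sites, pairs = genome_sites.build_site_table(
        seqs, motif, regions=regions, genes=genes if len(genes) >= 10 else None
    )
    return ChromatinModel(seqs=seqs, sites=sites, genes=genes, regions=regions, pairs=pairs)


def class_sites_table(
    counts: dict[str, int], spacing: int = 1000, chrom: str = "chrT", motif: str = "GATC"
) -> pd.DataFrame:
    """Abstract site table (no genome needed) for rate/plateau scenarios:
    ``counts`` maps region class -> number of sites, laid out ``spacing`` bp
    apart so the neighbor policy never triggers."""
    rows = []
    pos = spacing
    for cls, n in counts.items():
        for _ in range(n):
            rows.append((chrom, pos, motif, pos + genome_sites.cut_midpoint_offset(motif), cls))
            pos += spacing
    return pd.DataFrame(rows, columns=["chrom", "start", "motif", "midpoint", "region_class"])


# ---------------------------------------------------------------------------
# core simulation
# ---------------------------------------------------------------------------

def _cell_rng(seed: int, cell: int) -> np.random.Generator:
    # Counter-style splitting: stream depends only on (seed, cell), so
    # growing n_cells never reshuffles earlier cells.
    return np.random.default_rng([int(seed), int(cell)])


def simulate_states(
    sites_or_model,
    kinetics: KineticsParams,
    design,
    n_cells: int,
    seed: int,
    induction: InductionModel | None = None,
) -> MethylationStates:
    """Draw per-cell, per-site methylation states at every design point.

    ``design`` is a strictly increasing sequence of minutes (in_vivo) or
    enzyme concentrations in nM (nuclei).  Within a cell the states are
    coupled through a single uniform per site, so methylation is monotone
    along the design axis, as it is physically.
    """
    sites = sites_or_model.sites if isinstance(sites_or_model, ChromatinModel) else sites_or_model
    design = np.asarray(list(design), dtype=float)
    if design.ndim != 1 or len(design) == 0:
        raise ValueError("design must be a non-empty 1-D sequence")
    if np.any(np.diff(design) <= 0):
        raise ValueError("design must be strictly increasing")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    S = len(sites)
    D = len(design)
    param = kinetics.per_site(sites)
    f0 = kinetics.f0_per_site(sites)
    states = np.zeros((D, n_cells, S), dtype=bool)
    expected = np.zeros((D, S), dtype=float)
    delays = mults = None

    if kinetics.mode == "nuclei":
        for cell in range(n_cells):
            rng = _cell_rng(seed, cell)
            accessible = rng.random(S) < param
            u = rng.random(S)
            for d, c in enumerate(design):
                sat = 1.0 - np.exp(-c / kinetics.c0) if c > 0 else 0.0
                prob = f0 + (1.0 - f0) * np.where(accessible, sat, 0.0)
                states[d, cell] = u < prob
                expected[d] += prob
    else:
        if induction is None:
            induction = InductionModel()
        delays = np.empty(n_cells)
        mults = np.empty(n_cells)
        scale = induction.half_time / LN2
        for cell in range(n_cells):
            rng = _cell_rng(seed, cell)
            tau = rng.exponential(scale)
            lam = rng.lognormal(0.0, induction.sigma_cell) if induction.sigma_cell > 0 else 1.0
            delays[cell] = tau
            mults[cell] = lam
            u = rng.random(S)
            for d, t in enumerate(design):
                dt = max(0.0, t - tau)
                prob = f0 + (1.0 - f0) * (1.0 - np.exp(-param * lam * dt))
                states[d, cell] = u < prob
                expected[d] += prob
    expected /= n_cells
    return MethylationStates(
        axis="conc_nM" if kinetics.mode == "nuclei" else "time_min",
        design=design, states=states, sites=sites.reset_index(drop=True),
        expected=expected, induction_delays=delays, cell_multipliers=mults,
    )


def ground_truth_table(states: MethylationStates) -> pd.DataFrame:
    """Per-site empirical methylated fraction at each design point (long format)."""
    frac = states.states.mean(axis=1)  # (D, S)
    rows = []
    for d, x in enumerate(states.design):
        df = states.sites[["chrom", "start"]].copy()
        df[states.axis] = x
        df["true_fraction"] = frac[d]
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# fragmentation
# ---------------------------------------------------------------------------

def fragmentize(
    states: MethylationStates,
    chrom_sizes: dict[str, int],
    frag: FragmentationParams,
    seed: int,
    design_index: int = -1,
    cells: np.ndarray | None = None,
) -> pd.DataFrame:
    """Cut, sonicate and size-select one molecule per (cell, chromosome).

    Every methylated GATC is cut at its blunt midpoint; Poisson breakpoints
    at rate 1/L model sonication; fragments are retained with the recovery
    ramp probability; each DpnI end independently loses its terminal base
    with probability q (left fragments lose the A, right fragments the T).

    Returns a fragment frame (chrom, start, end) suitable for
    :mod:`qdaflux.fragment_quant`; fragments are 0-based half-open.
    """
    d = range(len(states.design))[design_index]
    sites = states.sites
    meth = states.states[d]
    if cells is None:
        cells = np.arange(states.n_cells)
    by_chrom = {
        chrom: (idx.to_numpy(), sites.loc[idx, "midpoint"].to_numpy())
        for chrom, idx in sites.groupby("chrom", sort=False).groups.items()
    }
    out_chrom: list[str] = []
    out_start: list[np.ndarray] = []
    out_end: list[np.ndarray] = []
    for cell in cells:
        rng = _cell_rng(seed + 1_000_003 * (d + 1), cell)
        for chrom, size in chrom_sizes.items():
            idx, mids = by_chrom.get(chrom, (np.array([], int), np.array([], int)))
            cuts = np.unique(mids[meth[cell, idx]]) if len(idx) else np.array([], int)
            n_son = rng.poisson(size / frag.mean_length)
            son = rng.integers(1, size, size=n_son) if n_son else np.array([], int)
            bounds = np.unique(np.concatenate([[0, size], cuts, son]))
            starts, ends = bounds[:-1].copy(), bounds[1:].copy()
            is_cut = np.isin(bounds, cuts)
            # terminal-base loss at DpnI ends only
            if frag.terminal_loss_prob > 0 and is_cut.any():
                lose_r = is_cut[1:] & (rng.random(len(ends)) < frag.terminal_loss_prob)
                lose_l = is_cut[:-1] & (rng.random(len(starts)) < frag.terminal_loss_prob)
                ends = ends - lose_r.astype(int)
                starts = starts + lose_l.astype(int)
            keep = ends > starts
            starts, ends = starts[keep], ends[keep]
            p_rec = frag.recovery_prob(ends - starts)
            keep = rng.random(len(starts)) < p_rec
            if keep.any():
                out_chrom.extend([chrom] * int(keep.sum()))
                out_start.append(starts[keep])
                out_end.append(ends[keep])
    if not out_chrom:
        import warnings

        warnings.warn("no fragments retained", stacklevel=2)
        return pd.DataFrame({"chrom": [], "start": [], "end": []})
    return pd.DataFrame(
        {
            "chrom": out_chrom,
            "start": np.concatenate(out_start),
            "end": np.concatenate(out_end),
        }
    )


def write_bedpe(frags: pd.DataFrame, path) -> None:
    """Degenerate BEDPE: both mates span the whole fragment."""
    df = pd.DataFrame(
        {
            "chrom1": frags["chrom"], "start1": frags["start"], "end1": frags["end"],
            "chrom2": frags["chrom"], "start2": frags["start"], "end2": frags["end"],
        }
    )
    df.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# long-read CG call emission
# ---------------------------------------------------------------------------

NANOPOLISH_COLUMNS = [
    "chromosome", "strand", "start", "end", "read_name",
    "log_lik_ratio", "num_calling_strands", "num_motifs", "sequence",
]


def group_cg_sites(starts: np.ndarray, group_gap: int) -> list[np.ndarray]:
    """Cluster sorted CG starts whose successive distance is <= group_gap."""
    starts = np.asarray(starts)
    if len(starts) == 0:
        return []
    breaks = np.where(np.diff(starts) > group_gap)[0] + 1
    return np.split(np.arange(len(starts)), breaks)


def emit_longread_calls(
    states: MethylationStates,
    seqs: dict[str, str],
    seed: int,
    llr_scale: float = 4.0,
    error_rate: float = 0.0,
    group_gap: int = 10,
    flank: int = 5,
    design_index: int = -1,
) -> pd.DataFrame:
    """Nanopolish-dialect per-read CG methylation call table.

    Each simulated cell contributes one read spanning its chromosome.  CG
    sites closer than ``group_gap`` are merged into one call row
    (``num_motifs`` > 1), mirroring Nanopolish's proximity grouping; the
    group inherits the methylation state of its first site.  The
    log-likelihood ratio magnitude is |Normal(llr_scale, 1)|, positive for
    methylated truth, with the sign flipped at ``error_rate``.
    """
    if (states.sites["motif"] != "CG").any():
        raise ValueError("long-read call emission requires CG sites")
    d = range(len(states.design))[design_index]
    meth = states.states[d]
    rows = []
    for chrom, idx in states.sites.groupby("chrom", sort=False).groups.items():
        idx = np.asarray(idx)
        starts = states.sites.loc[idx, "start"].to_numpy()
        seq = seqs[chrom]
        groups = group_cg_sites(starts, group_gap)
        specs = []
        for g in groups:
            s0, s1 = int(starts[g[0]]), int(starts[g[-1]])
            context = seq[max(0, s0 - flank): s1 + 2 + flank]
            specs.append((idx[g[0]], s0, s1, len(g), context))
        for cell in range(states.n_cells):
            rng = _cell_rng(seed + 777, cell)
            mags = np.abs(rng.normal(llr_scale, 1.0, size=len(specs)))
            flips = rng.random(len(specs)) < error_rate
            for (i0, s0, s1, n, context), mag, flip in zip(specs, mags, flips):
                is_meth = bool(meth[cell, i0]) ^ bool(flip)
                rows.append(
                    (chrom, "+", s0, s1, f"read_{chrom}_{cell:05d}",
                     mag if is_meth else -mag, 1, n, context)
                )
    return pd.DataFrame(rows, columns=NANOPOLISH_COLUMNS)


# ---------------------------------------------------------------------------
# positional (dyad-aware) accessibility, for phasing scenarios
# ---------------------------------------------------------------------------

def positional_accessibility(
    positions: np.ndarray,
    dyads: np.ndarray,
    jitter_sd: float | np.ndarray = 0.0,
    p_linker: float = 0.8,
    p_nucleosomal: float = 0.1,
    half_width: int = NUCLEOSOME_HALF_WIDTH,
) -> np.ndarray:
    """Expected accessible fraction at each position given a nucleosome array.

    Each dyad occludes +/- ``half_width`` bp; dyad positions jitter from cell
    to cell with a Gaussian sd (scalar, or one sd per dyad).  The returned
    value is ``p_occ * p_nucleosomal + (1 - p_occ) * p_linker`` where
    ``p_occ`` is the probability that at least one (jittered) nucleosome
    covers the position.
    """
    positions = np.asarray(positions, dtype=float)
    dyads = np.asarray(dyads, dtype=float)
    sd = np.broadcast_to(np.asarray(jitter_sd, dtype=float), dyads.shape)
    p_not_occ = np.ones_like(positions)
    for dyad, s in zip(dyads, sd):
        delta = positions - dyad
        if s > 0:
            q = norm.cdf((half_width + 0.5 - delta) / s) - norm.cdf(
                (-half_width - 0.5 - delta) / s
            )
        else:
            q = (np.abs(delta) <= half_width).astype(float)
        p_not_occ *= 1.0 - q
    p_occ = 1.0 - p_not_occ
    return p_occ * p_nucleosomal + (1.0 - p_occ) * p_linker
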