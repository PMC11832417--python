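# qdaflux

Quantitative DNA-accessibility footprinting with inducible DNA
methyltransferases, for chromatin biologists asking how accessible the
genome really is — in isolated nuclei versus living cells.

The assay this package analyses probes chromatin with a sequence-specific
methyltransferase (Dam, which methylates the A of GATC, or M.SssI, which
methylates CG). Methylated GATC sites are cut by DpnI; after sonication and
paired-end sequencing, the fraction of molecules cut at each site reports
the fraction of cells in which that site was accessible. In nuclei the
titration saturates at a *limit digest* — the site is accessible in a fixed
fraction of nuclei — whereas in living cells methylation accumulates with
first-order kinetics, the signature of chromatin in continuous flux.

## What it computes

* **Site census** (`genome_sites`) — every motif occurrence with cut
  midpoint, neighbor distances, genomic region class (ORF, promoter NDR,
  tRNA, CEN, ARS, TEL, Ty, silenced), owning gene, signed offset from the
  +1 nucleosome dyad, and transcription decile.
* **fcut** (`fragment_quant`) — per-site fraction cut from fragment ends.
  For a GATC with bases (G, A, T, C) at (s, s+1, s+2, s+3):
  `fcut_right = (right_ends[s+1] + right_ends[s]) / coverage[s]` and
  `fcut_left = (left_ends[s+2] + left_ends[s+3]) / coverage[s+3]` — ends on
  the G or C are counted too because the terminal A/T is sometimes lost
  during library preparation. Sites with neighbors closer than 200 bp on
  both sides are excluded; with one close side, that side's value is
  substituted by the far side's.
* **Kinetics** (`kinetics`) — group medians over sites; apparent rate
  constants k = −slope of ln(median unmethylated fraction) vs time; limit
  digests by saturating-exponential fit
  `f(c) = f_bg + (f_max − f_bg)(1 − e^{−c/c0})`; rate ratios with
  delta-method errors; replicate Pearson concordance; and the
  induction-linearity regression of population methylation on the
  induced-cell fraction.
* **Phasing** (`phasing`) — dyad-aligned methylation profiles (21-bp boxcar
  smoothing), dyad-density normalization to a 0.1 maximum, anti-phase
  score, nucleosome-array shift by cross-correlation (negative lag =
  promoter-ward), and a disorder index for spacing-remodeler phenotypes.
* **Long reads** (`longread_cpg`) — Nanopolish-dialect CpG call ingestion,
  proximity-group splitting, ±2.0 log-likelihood-ratio classification, and
  per-site frequencies with the <10%-of-median coverage filter.
* **Simulator** (`synthetic_data`) — ground-truthed synthetic data for all
  of the above: static-nuclei and in-vivo kinetic regimes, exponential
  induction delays with cell-to-cell enzyme variation, complete DpnI
  cutting, Poisson sonication, short-fragment recovery loss and terminal
  base loss, plus Nanopolish-style call tables.

## Worked example

Region-level methylation rates from a simulated in-vivo time course
(2,000 cells, timepoints 0/30/60/120/240 min, instant induction):

```python
import numpy as np
from qdaflux import synthetic_data as sd, kinetics as kin

sites = sd.class_sites_table({"ORF": 40, "NDR": 40, "CEN": 40}, spacing=300)
kp = sd.KineticsParams(mode="in_vivo", rate=sd.dam_rate_preset(0.01))
st = sd.simulate_states(sites, kp, [0, 30, 60, 120, 240], 2000, seed=7,
                        induction=sd.INSTANT_INDUCTION)
frac = st.states.mean(axis=1)
for cls in ("NDR", "ORF", "CEN"):
    sel = (st.sites["region_class"] == cls).to_numpy()
    fit = kin.fit_rate(st.design, 1 - np.median(frac[:, sel], axis=1))
    print(f"{cls}: k = {fit.k:.5f}/min (r^2 {fit.r_squared:.4f})")
```

prints

```
NDR: k = 0.01300/min (r^2 1.0000)
ORF: k = 0.00991/min (r^2 1.0000)
CEN: k = 0.00070/min (r^2 1.0000)
```

i.e. the fitted apparent rate constants recover the scenario's ground truth:
promoter NDRs 1.3× faster than gene bodies (`kin.rate_ratio` gives
1.31 ± 0.00 here), and the centromeric nucleosome ~14-fold protected. The
NDR fit uses 4 points because the last timepoint falls below the
u ≥ 0.05 gate for the log fit.

The same analyses run from the shell:

```sh
qdaflux run --seed 7 --out artifacts/        # simulate -> fcut -> kinetics -> phasing
qdaflux report --artifacts artifacts/        # region rate table, profile table
qdaflux sites --genome genome.fa --motif GATC --regions regions.bed \
        --genes genes.tsv --out sites.tsv    # census on real data
qdaflux fcut --sites sites.tsv --fragments sample.bam --out sample.fcut.tsv
```

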