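# Methods

## The measurement model

A site's methylation status is a per-molecule binary read out through
restriction-fragment ends. After complete DpnI digestion of methylated GATC
(blunt cut between the A and the T) and random sonication, a molecule that
was methylated at a site contributes one fragment whose last base is the
site's A and one whose first base is the T. Terminal-base loss during
library preparation moves some of those ends onto the G (right side) or the
C (left side); the estimator therefore counts A+G ends against the coverage
of the G, and T+C starts against the coverage of the C. This correction
makes fcut invariant to the terminal-loss probability q — verified in the
acceptance suite for q ∈ {0, 0.3, 1}.

Two per-side values are computed; the site-level default is the mean of the
usable sides, with both per-side columns always emitted so either
convention can be reproduced downstream.

**Background.** Without any methylation, a fragment covering the G still
ends at the G or A whenever sonication happened to break at one of those
two positions, so the expected per-side fcut is ≈ 2/L for mean fragment
length L (0.0057 at L = 350). The *observed* zero-enzyme background in real
libraries is higher (~3%) because short-fragment recovery is biased; the
2/L property is therefore tested with the recovery ramp disabled, which
isolates the uniform-breakpoint mechanism from the deliberate recovery
bias.

**Neighbor policy.** Fragments shorter than ~200 bp are recovered
inefficiently, so a site whose neighbors are both closer than 200 bp is
excluded, and a site with one close side takes the far side's value
(status `substituted_*`). Distances are measured between cut midpoints
(start+2 for GATC, start+1 for CG); chromosome-end distances stand in for
missing neighbors, so end-truncated sides are treated as close sides. The
anchor choice (midpoints rather than motif starts) is a convention of this
package; at these length scales the difference is ≤ 3 bp. Sides with
coverage below 8 are additionally flagged low-coverage and never enter
group medians, guarding against 0/1 quantization.

## Kinetic models

* **Nuclei (static chromatin).** Each (cell, site) is accessible with
  class probability p; accessible sites saturate with concentration as
  1 − e^{−c/c0}. The population fraction therefore plateaus at p — the
  limit digest. Plateaus are estimated by bounded nonlinear least squares
  of f(c) = f_bg + (f_max − f_bg)(1 − e^{−c/c0}); if the optimizer fails,
  the mean of the two highest-concentration medians is used and the method
  recorded (`top2_mean`).
* **In vivo (chromatin flux).** Methylation is irreversible first-order
  with class rate k (per minute). The population-level apparent rate is
  the negative OLS slope of ln(median unmethylated fraction u) against
  time. Points with u < 0.05 are dropped (log blow-up); t = 0 is included
  by default and no background subtraction is applied (an optional
  u/u(0) normalization exists). Quartile bands use linear interpolation
  (type 7).
* **Induction.** Cells begin methylating after an exponential delay
  (default half-time 80 min) with a log-normal per-cell rate multiplier
  (median 1, log-sd 0.5). When per-cell methylation is much faster than
  induction, the population median tracks the induced-cell fraction
  linearly; the linearity regression quantifies this. The slow-kinetics
  contrast scenario uses k = 0.002/min against the induction rate
  ln2/80 ≈ 0.0087/min, chosen by closed-form analysis of the convexity of
  the methylation-vs-induced-fraction curve.
* **Rate ratios** use the delta method:
  se(kA/kB) = (kA/kB)·√((seA/kA)² + (seB/kB)²).

## Phasing

Profiles pool all (site, gene) pairs — a site within the window
(−300, +1000) of several genes contributes once per gene — and average
fcut at each signed offset from the +1 dyad (strand-corrected). Smoothing
is a centered 21-bp boxcar whose window shrinks at edges; undefined
offsets are skipped, never zero-filled, and offsets supported by fewer
than 20 pairs are masked first (GATC is sparse; CG-mode profiles are dense
enough that the mask rarely triggers). Dyad-density tracks are max-scaled
to 0.1 so they fit under fcut curves on a single 0–1 axis.

The array shift between two conditions is the integer lag in ±60 bp that
maximizes the Pearson correlation of the two smoothed profiles over the
genic array (offsets 0..+500), ties broken toward zero; using every phased
peak rather than the +1 peak alone makes the estimate robust to
peak-finding noise. Negative lags mean the second profile is shifted
toward the promoter. The disorder index is the peak-to-trough amplitude in
the downstream band (+110..+600, the +2..+4 nucleosomes) divided by the
amplitude in the +1 band (−60..+110): ≈1 for a phased array, →0 as
downstream spacing randomizes while +1 persists.

## Long-read CpG aggregation

Calls with |LLR| < 2.0 are ambiguous and excluded from coverage (the
community-standard threshold; configurable). Proximity-grouped calls are
split by locating CG offsets in the sequence context and anchoring the
first CG at the record's start; every CG in a group inherits the group
call, and records whose context CG count disagrees with `num_motifs` are
quarantined rather than guessed at. Sites below 10% of the median
coverage are flagged out. Frequencies are exported on the fcut table
layout so kinetics and phasing run unchanged on CG data.

## The simulator, and what passing tests do not show

The simulator couples each (cell, site) through a single uniform draw, so
methylation is monotone along the design axis exactly as irreversible
chemistry requires. RNG streams are split per cell from the master seed,
so enlarging a simulated population never reshuffles earlier cells, and
identical seeds give byte-identical outputs. Default study conditions:
timepoints {0, 30, 60, 120, 240} min; concentration grid
{0, 0.77, 1.5, 2.9, 5.6} nM with c0 = 0.8 nM; 2,000 cells for estimator
recovery and 60–400 cells for fragment-level scenarios; sonication scale
L = 350 bp; recovery ramp 100→300 bp (≈50% at 200 bp); terminal-loss
q = 0.3; region rate presets NDR:ORF = 1.3 (Dam) or 2.9 (CG),
tRNA:ORF = 1.2, ARS/TEL/Ty = 1.0, CEN = 1/14, silenced = 1/20. Scenario
problem sizes (toy chromosomes of 5–60 kb, tens of sites per class) are
chosen so binomial error is small relative to the tolerances being
tested while the full suite runs in seconds.

What the simulator does **not** model — and therefore what green tests do
not establish about real data: sequencing error and mapping ambiguity;
PCR duplication (duplicates are deliberately kept by the estimator);
hemimethylation and nascent-strand effects; replication and cell-cycle
structure; the mechanistic identity of chromatin flux (removal/replacement
vs sliding vs conformational change — only the net first-order exposure
rate is simulated); and the empirical short-fragment skew that raises real
zero-enzyme background above 2/L. Parameter-recovery results certify the
estimators, not the biology.

## Degenerate inputs and numerical choices

Zero-coverage sides yield NaN and a `no_coverage` status rather than
exceptions; flat plateau series return their value directly; rate fits
require ≥3 usable points and plateau fits ≥4 concentrations including 0;
decile ties break lexicographically by gene id; region-annotation overlaps
resolve by fixed precedence CEN > silenced > tRNA > NDR > ARS > TEL > Ty >
ORF (rarer, stronger-signal classes win). All coordinates are 0-based
half-open internally.
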