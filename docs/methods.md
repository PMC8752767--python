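# Methods

This note documents the models and procedures implemented in `cardiomir`,
the parameter choices that matter, what the synthetic-data generators do
and do not emulate, and the numerical conventions.

## Canonical seed-site scanning

A miRNA seed is defined as mature-miRNA nucleotides 2–8 (1-based), a 7-nt
heptamer; miRNAs sharing a seed form one family with a common canonical
target spectrum. On the target (UTR) strand the three canonical site types
are:

| type    | target-strand sequence                       | length |
|---------|----------------------------------------------|--------|
| 7mer-m8 | reverse complement of the seed               | 7      |
| 8mer    | 7mer-m8 followed by a literal `A`            | 8      |
| 7mer-A1 | reverse complement of seed nt 1–6 + literal `A` | 7   |

The `A` opposite miRNA position 1 is required to be a literal `A` in the
UTR (the standard canonical-site definition), not "any nucleotide".
Scanning reports all maximal sites with one subsumption rule: a window
matching the 8mer is one site, and the 7mer-m8 and 7mer-A1 windows it
contains are not additionally reported — one physical site contributes one
count. Overlapping *distinct* sites are each counted; the screen counts
binding sites, not disjoint footprints. UTRs may be supplied as DNA or
RNA (`T` is normalized to `U`; `N` never matches), and coordinates are
0-based half-open on the supplied sequence. When a gene has several UTR
records, the longest is scanned (logged). Conservation is accepted as an
optional input annotation and used only as a filter; it is never computed
here, so the default scan counts all canonical sites.

A second, deliberately naive scanner (`scan_sites_bruteforce`) enumerates
every 7- and 8-nt window and applies the same hierarchy; it shares no
matching code with the fast path and serves as the oracle in equivalence
tests.

### Ranking and expression gating

The binding-site count matrix is seed families × genes; families are
ranked by row total, descending, with lexicographic family-id tie-breaks
for determinism. Expression gating takes the intersection of the top-N
(default 100) most abundant entries of two independent profiles —
modeling the requirement that a candidate miRNA be well expressed in both
stem-cell-derived cardiac myocytes and adult myocardium. Boundary ties
resolve by abundance then id. Gene-level gating keeps genes with
abundance strictly above a TPM-like threshold (default 1).

## Targetome statistics

**Enrichment.** Over-representation of a targetome in a term's gene set is
the one-sided Fisher exact test on the 2×2 classification of a declared
universe, equal to the hypergeometric upper tail
`P(X ≥ k)` with `X ~ Hypergeom(N, K, n)`. The per-term `contribution`
(overlap / term size) is the bubble-size quantity of the classic
enrichment plot. Raw p-values are the primary output (the screen uses a
plain 0.05 threshold); Benjamini–Hochberg is available but off by default
and logged when used. The universe is an explicit required argument —
whether it should be all genes, expressed genes or annotated genes is a
study-level choice the code does not silently make.

**DE filters.** A gene is differentially expressed when FDR < 0.05 and its
linear fold change differs from 1 by more than 30%. Up-regulation is
FC > 1.3. For down-regulation two readings exist: the linear one
(FC < 0.70, a 30% drop — the default) and the log-symmetric one
(FC < 1/1.3 ≈ 0.769). The choice is a logged `down_rule` option because
the two differ for genes with 23–30% drops. Reciprocal regulation
(derepression) is the set intersection of "down under the mimic" and "up
under the inhibitor".

**Shift test.** Whether predicted targets are coherently shifted relative
to the transcriptome is tested by comparing target vs non-target log2
fold-change distributions. The primary statistic is the two-sided
Wilcoxon rank-sum (Mann–Whitney U); the Kolmogorov–Smirnov statistic is
reported alongside, and the effect size is the difference of group
medians. The rank-sum was chosen as the default because it is a location
test matching the "distribution shifted down" hypothesis and is invariant
to adding a constant to all fold changes; KS is reported because a
distributional comparison is sometimes read as a shape test. The all-equal
degenerate table returns p = 1 by convention.

## Optical AP analysis

Optical traces are dimensionless ratios of two emission channels of a
voltage-sensitive dye (or membrane potential in mV); the pointwise ratio
is formed first and all analysis operates on the single ratio trace.

* **Detection.** The trace is linearly detrended; if its robust amplitude
  (1st–99th percentile range) does not exceed 8× the noise floor
  (estimated from first differences), it is declared AP-free. Candidate
  APs are prominence peaks (≥ half the robust amplitude) separated by at
  least a configurable refractory floor (default 200 ms); each AP's
  upstroke index is the maximal-derivative sample between the preceding
  near-baseline crossing and the peak, refined on the raw derivative so
  smoothing does not delay the edge.
* **Baseline and onset.** Each AP gets its own baseline — the 10th
  percentile of the preceding inter-AP segment — making APD robust to
  photobleaching drift. The takeoff point is found by back-tracking from
  the upstroke to the interpolated crossing of baseline + 10% of
  amplitude.
* **APD.** APD at level L (default 0.9) is the time from takeoff to the
  linearly interpolated crossing of baseline + (1−L)·amplitude on the
  falling limb. The falling limb is smoothed with a centered moving
  average (default 11 ms) before crossing detection; a centered average is
  bias-free on the (locally linear) repolarization while suppressing
  first-passage noise. All thresholds are relative to baseline and
  amplitude, so APD is invariant under positive affine transforms of the
  signal. APs whose repolarization is truncated by the next AP or the end
  of the trace are marked invalid and excluded.
* **Rate correction.** `cAPD90 = APD90 / sqrt(RR/1000)` (Bazett), with RR
  the interval from the previous upstroke; the first AP of a trace has no
  RR and is excluded from cAPD90 statistics. A per-cell-mean-RR mode is
  available via configuration. The same formula corrects field-potential
  durations (cFPD). Per-cell summaries are medians over valid APs; cells
  with fewer than 3 valid APs are flagged and report NaN.
* **FPD.** Field-potential durations are normally read by vendor MEA
  software; the module applies the Bazett correction to supplied
  (FPD, beat interval) tables. A best-effort spike-to-repolarization
  extractor is provided as a clearly flagged heuristic utility only.

## Patch-clamp IV analysis

Voltage-step currents are reduced per step either to the signed extremum
("peak", the inward-current convention, e.g. I_CaL) or to the mean of the
terminal 10% of the step ("end", the delayed-rectifier convention), then
normalized to cell capacitance (pA/pF). Linear leak is fitted on a
configurable sub-threshold voltage range (the range is a logged
parameter, since it is protocol-specific) and subtracted; a purely ohmic
curve subtracts to zero at all potentials. Drug-sensitive currents
(e.g. I_Ks as the chromanol-sensitive component) are pointwise differences
of control and drug IV curves on identical potential grids.

## Effective refractory period

The protocol pairs every regular stimulus (S1, 0.5 Hz) with a premature
stimulus (S2) at a programmed interval, stepping the interval down from
1000 to 250 ms in 20-s blocks (10 pairs per block); the decrement step is
a required parameter, not a silent default. A pair shows "two distinct
contractions" when two twitch peaks are found (prominence ≥ 20% of the
reference twitch, estimated as the median S1-evoked amplitude), one
attributable to each stimulus (each peak is assigned to its nearest
preceding stimulus and must fall within a 300 ms response latency), with
the inter-peak valley dropping below 50% of the smaller peak. Force is
smoothed with a 25 ms centered moving average before peak picking. Blocks
are classified by majority vote over their pairs — voting suppresses
single-pair detection noise — and blocks with no detectable S1 twitch are
excluded with a warning. The refractory period is the longest interval
whose block failed; when no block fails the result is censored below the
scanned range, when all fail it is censored above. Non-monotone block
patterns are reported but resolved by the literal longest-failing-interval
rule rather than interpolation. Paired pre/post comparisons are simple
differences of the two estimates (NaN when either is censored).

## Reporter quantification

Cells express GFP (followed by the UTR under study) and RFP (internal
control) from one construct. The per-cell GFP/RFP ratio is formed first
and arm means are compared — per-cell ratios are robust to cell-size
covariation, unlike a ratio of arm totals. The repression readout is the
treated-arm mean ratio normalized to the control arm (1 = no repression);
dispersion is the delta-method standard error of the ratio of means, and
the two-group test is the rank-sum by default (Welch t available). Cells
with non-detected RFP are rejected and counted. The native-vs-mutated-UTR
specificity contrast is the same operation applied to the mutated arms.

## Synthetic-data generators

Every generator records its ground truth *before* adding noise and is
bit-reproducible given its seed.

* **UTR sets.** Sites are planted at random non-overlapping positions
  (with a 2-nt buffer between sites — an adjacent planted nucleotide could
  otherwise extend a planted 7mer into an 8mer with no background base
  available to fix it) and the background is rejection-sampled until an
  exhaustive scan over the whole family pool finds exactly the planted
  sites. This makes count recovery an exact test, not a statistical one.
  Genuinely unresolvable plantings (e.g. one family's site inside
  another's) raise an explicit error.
* **Expression profiles.** Two abundance tables built so their top-N sets
  share exactly a requested number of ids, with strict geometric rank
  abundances (no ties).
* **AP trains.** Piecewise-linear beats: baseline → linear upstroke
  (instant allowed) → plateau → linear repolarization. The analytic APD90
  is upstroke + plateau + 0.9 × repolarization. Defaults (amplitude 1,
  plateau 150 ms, repolarization 250 ms, 1 Hz, 1 ms sampling) give
  AP shapes and rates in the range of spontaneously beating hiPSC-derived
  myocytes. White noise and linear drift (photobleaching surrogate) are
  added after truth is recorded; a sampling interval coarser than the
  upstroke is rejected.
* **Force recordings.** Each stimulus evokes an alpha-like twitch
  (rise 40 ms, decay 120 ms); an S2 evokes a full twitch iff its interval
  exceeds the true refractory period, else a twitch scaled by a
  configurable fraction (0 by default — the binary rule; a graded mode
  exists for sensitivity analyses).
* **DE tables.** Non-target log2FC ~ N(0, σ), targets ~ N(shift, σ);
  FDR values are BH-adjusted two-sided normal p-values of the observed
  fold change, so stronger shifts earn smaller FDRs. With shift 0 the
  labels are exchangeable, which is what makes the type-I-error
  calibration meaningful.
* **Reporter arms.** Per-cell ratios are mean-preserving log-normal around
  the planted factor (exact when CV = 0) over log-normally varying RFP.

What the generators do **not** emulate: real spectral bleed-through and
photon noise statistics of dye imaging (noise is Gaussian, not Poisson),
AP morphology beyond the piecewise-linear caricature (no notch, no
rate-dependent APD restitution), mechanical fatigue or run-down in force
recordings, correlated gene-gene structure in DE tables, and segmentation
artifacts in intensity tables. Passing tests therefore demonstrate
correctness of the *analysis logic* under controlled conditions, not
performance on raw laboratory data.

## Problem sizes and numerical choices

Desk-scale defaults: scanner-oracle equivalence on 10⁴ random
(UTR, seed) pairs of 100 nt; planted-site recovery on 50 sets of 20 genes
× 250 nt; APD recovery over 100 noise seeds at 5% noise; refractory-period
recovery over 100 traces with uniform true RP in (260, 990) ms at step
50 ms; shift-test calibration over 1000 null tables of 1100 genes. These
sizes give stable Monte-Carlo estimates (binomial SE ≤ ~0.7% at
n = 1000) while keeping the full run inexpensive.

Threshold crossings always use linear interpolation between samples;
ties in rankings break lexicographically; empty and degenerate inputs
(zero beats, all-equal fold changes, empty terms) return defined values
rather than erroring where a convention exists, and raise explicit errors
where none does.

## Known limitations

* The scanner implements canonical sites only — no 6mers, no
  3'-supplementary or centered sites, no context scoring, no conservation
  computation. Rankings are therefore site-count rankings, not predicted
  repression rankings.
* Bazett correction is the field's convention for hiPSC-CM work but
  over-corrects at fast rates; no alternative (Fridericia) is provided.
* The FPD extractor is a heuristic stand-in for vendor MEA software and
  should not be used for quantitative claims.
* The refractory-period reading inherits the resolution of the schedule
  step; the estimate is the largest scheduled interval at or below the
  true RP, so it is biased low by up to one step.
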