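# Methods

This note documents the models and procedures implemented in `txchromdyn`,
the assumptions behind them, the choices made where the design was open,
and what the synthetic-data validation does and does not establish.

## Coordinate and counting conventions

All coordinates are 0-based half-open (BED convention). The TSS of a
minus-strand gene is its BED `end`, the TTS its `start`; every windowed
metric is strand-oriented, with positive offsets running 5'→3'. Window
counting supports two modes: **any-overlap** (a read intersecting the
window by ≥ 1 bp counts once — `coverageBed -counts` semantics, the default
for escape indices) and **midpoint** (a read counts in the one window
containing its floor midpoint — used for binning so mass is conserved). A
**depth** density mode (mean per-base coverage) is also exposed; read-count
density and per-base depth differ only through reads that straddle a window
boundary. For a minus-strand gene the midpoint offset is `tss − 1 − m`, so
the first transcribed base (BED `end − 1`) has offset 0.

## Gene universe

Transcripts are collapsed by single-linkage clustering of TSS positions
within a 50 bp radius per (chromosome, strand); the longest transcript
represents each cluster, ties broken by smallest gene id (the tie rule is a
determinism choice; any fixed rule would do). Genes shorter than 2 kb are
dropped (inclusive threshold). For promoter-anchored analyses an extra
neighbor filter removes every gene with another TSS inside its oriented
window [TSS − 250 bp, TSS + 2 kb] — both members of an offending pair are
removed, since each contaminates the other's promoter signal.

Peaks are assigned one of four region categories from footprints TSS ± 500
bp, TTS ± 500 bp, intragenic (TSS + 500 to TTS − 500, oriented), intergenic
(everything else). A peak overlapping several footprints takes the highest
priority label (TSS > TTS > intragenic > intergenic); a multi-label mode
reports all overlapped categories instead, for workflows that count peaks
per category independently.

## Escape index

For each gene, `Dp` is the read density over the promoter-proximal window
[TSS − 250, TSS + 100) and `Db` the density over the early body
[TSS + 100, TSS + 2000), both in reads per bp per million mapped reads.
The escape index is `EI = Db / Dp`; ΔEI is treated EI over control EI, and
a gene counts as "increased" only for ΔEI strictly > 1 (an exact tie is
not an increase). Genes with `Dp = 0` in any compared condition are
excluded and counted rather than smoothed — no pseudocounts, so reported
EIs are never artifacts of a smoothing constant. Densities use read counts
by default; per-base depth is a config switch and is the mode checked
against the per-base oracle in the validation suite.

Activity classification intersects the oriented region
[TSS − 250, TSS + 2000) with elongating-RNAPII (Ser2P), H3K27ac and
H3K27me3 peak sets. Precedence: K27ac ∧ K27me3 → ambiguous (excluded
downstream); Ser2P ∧ K27ac → active; K27me3 without Ser2P or K27ac →
repressed; everything else (including partial marks such as Ser2P alone)
→ inactive. The same single region is used for all three marks.

## Elongation-wave model

After release from a DRB block, nascent transcription advances into gene
bodies as a front. Per gene, the first 100 kb (250 kb for timepoints over
30 min, where a 2 kb/min wave outruns 100 kb) is split into 100 bp bins and
the count vector is modeled by a two-state left-to-right hidden Markov
chain: ON (transcribed) emits Poisson(λ_on) per bin, OFF (not yet reached)
emits Poisson(λ_off), the single allowed transition ON→OFF has probability
1 − p per bin, and OFF is absorbing. Every state path is therefore a
changepoint k (number of ON bins) with prior P(k) = (1 − p)·p^k for k < n
and P(n) = p^n. The switch may fire before the first bin, so a silent gene
decodes to front 0; k = n means the wave passed the whole region and the
call is censored.

Fitting is exact EM pooled across genes per condition/timepoint: the
E-step posterior over k is computed in closed form from prefix/suffix
log-likelihood sums, and the M-step updates λ_on, λ_off from
posterior-weighted counts and p from expected ON→ON vs ON→OFF transitions.
The log-likelihood trace is monotone. Initialization is deterministic from
data quantiles (λ_on from the top-decile bins, λ_off from the bottom half,
p set so the prior mean front is mid-region); no random restarts are
needed because the likelihood in this changepoint family is well-behaved
at these signal-to-noise ratios. λ_off is floored at 10⁻³ during fitting:
exactly 0 is a degenerate fixed point that forces every decoded front past
the last stray nonzero bin. Decoding with an explicitly zero λ_off remains
available and then reduces exactly to the last-nonzero-bin rule.

Each gene's front is the maximum-a-posteriori changepoint (Viterbi for
this chain), in bp from the TSS. Wave speed is the least-squares slope of
the median front (kb) against time (min) with free intercept; cell lines
are compared by a paired t-test on shared-gene fronts (a Pearson
correlation test is also provided, as both appear in practice).

## Pulse-chase retention

Intronic counts are gene counts minus exonic counts, floored at zero
(boundary effects can make exonic exceed gene; floored entries are
logged). The gene universe is the strict intersection, across every
supplied condition of both cell lines, of genes whose gene count strictly
exceeds that condition's median — removing inactive and noisy genes
without an external annotation. Retention of a gene at chase time t1 is
its counts-per-million intronic signal at t1 over its CPM nascent gene
count at baseline; genes with zero baseline are dropped. Under first-order
clearance with rate λ, retention decays as exp(−λ t).

Cell-line differences are tested with a seeded permutation test whose
statistic is an **IQR-trimmed Welch t**: each group is restricted to its
own [Q1, Q3] (type-7 linear-interpolation quartiles) and Welch's t is
computed on the trimmed values. Two points required care:

* The trimming must be *part of the statistic*, recomputed inside every
  permutation. Trimming once up front and permuting the trimmed values is
  not exchangeable — the per-group trim shrinks within-group spread while
  preserving between-group sampling noise — and simulation showed it
  rejects a true null at ~5× the nominal rate.
* The "sampling instances" are balanced downsamplings **without
  replacement** of the larger group to m = min(|A|, |B|), one permutation
  null per instance, with the median statistic and median p reported over
  100 instances. With-replacement draws were measured anti-conservative
  per instance (duplicate values shrink within-group variance). With equal
  group sizes — the usual case, since both cell lines share one filtered
  gene cohort — all instances see the full data and the procedure reduces
  to a plain permutation test.

Instance p-values use the add-one rule, so p is never 0 and bottoms out at
1/(n_perm + 1) ≈ 0.001 at the default 1000 permutations. Measured type-I
at α = 0.05 over 300 null replicates is ≈ 0.05–0.06.

## Nucleosome organization

A **Vplot** accumulates fragments into a (size × midpoint-offset) matrix
around dyad anchors: rows 1–250 bp, columns ±250 bp at 1 bp resolution,
offsets strand-oriented. Density normalization divides by total
accumulated fragments; cell lines are compared by density-Vplot
subtraction with negatives zeroed, a paired t-test on the offset-wise
column sums, and a Wilcoxon signed-rank test on column sums restricted to
the mononucleosome band (147 ± 20 bp — the band width is a choice, since
"~147 bp" pins only the center).

**Dyad calling** is a deliberately simple positional estimator (not a
fragment-size signal decomposition): midpoints of mononucleosome-sized
fragments (130–180 bp) in each oriented search window (TSS→+250 bp for the
+1 nucleosome; TSS→+1 kb to also reach the +2) are smoothed with a
Gaussian kernel (SD 20 bp); each local maximum at least 100 bp from the
next, supported by ≥ 5 midpoints within ±75 bp, becomes a dyad with
occupancy = density at the peak and **fuzziness** = the SD of those
supporting midpoints (bp). Externally produced dyad BED files are accepted
so all downstream comparisons can run on other callers' output unchanged.

**Spacing** takes, per TSS, the distances to the two nearest downstream
dyad centers (distances > 1 kb excluded) and reports the mode of each
rank's integer-distance histogram, ties broken toward the smaller
distance. **Fuzziness vs ΔEI** sorts genes by ΔEI, compares +1 fuzziness
of the bottom-n vs top-n genes (default n = 1000, shrunk with a warning
when fewer qualify) by rank-sum test; the log2 transform, where wanted,
belongs to presentation, not the test.

## Synthetic study conditions

The generators plant known truth in the statistical structure each
analysis assumes; defaults are the package's study conditions and are not
adjusted per run.

* **ChIP/EI** — per-gene EI drawn log-normal(μ = 0, σ = 1): escape indices
  realistically span more than an order of magnitude across genes.
  Promoter-proximal occupancy is constant in expectation (60 reads per
  gene) and EI is expressed through body read intensity, reflecting that
  pausing load is comparatively uniform while release varies; an earlier
  fixed-total-budget design starved promoter counts on high-EI genes and
  made their ΔEI uninformative. Reads (50 bp) are placed uniformly, fully
  inside their window. The UV condition multiplies body intensity by 2 for
  a planted responder fraction (default 0.66, matching a roughly
  two-thirds genome-wide response). In the noiseless mode expected counts
  are rounded, reads evenly spaced, and the recorded truth is the achieved
  post-rounding ratio, so measured EI equals truth exactly. Because
  ΔEI > 1 is strict and noise is symmetric, non-responders split ~50/50;
  planted fractions are recovered by inverting
  percent = f·100 + (1 − f)·p₀ with the noise floor p₀ measured at
  fraction 0.
* **Wave** — fronts at speed·t plus per-gene Gaussian jitter (SD 2 kb),
  quantized to bin edges; Poisson emissions λ_on = 15, λ_off = 0.3 per
  100 bp bin; planted speeds 2.0 (normal) and 1.2 kb/min (CS-B-like).
* **Pulse-chase** — baseline abundance log-normal (median 200 counts);
  labeled intronic signal at chase time t is Poisson(gene(t₀)·exp(−λt)),
  λ = 0.4/h vs 0.1/h per cell line; exonic decays at λ/2. All tables carry
  one nominal library size (depth-equalized libraries), so planted
  retention is exactly exp(−λt).
* **ATAC** — per gene: sub-nucleosomal NFR fragments at the TSS,
  mononucleosome fragments (size ~ N(147, 10), clipped ≥ 100) around +1
  (TSS + 120) and +2 (+1 + 190) dyads with positional SD 30 bp (normal) vs
  10 bp (CS-B-like), dinucleosome fragments (~N(300, 20)) between them;
  mixture 0.3/0.55/0.15 sub/mono/di, 120 fragments per gene.
* **Peaks** — each gene's extended TSS region is hit independently with a
  configurable probability; truth records the hits.

Every generator is byte-reproducible from (config, seed), and truth files
are never read by the code under test.

**What the synthetic validation does not show.** The generators emulate
window/count-level structure, not sequencing: no mappability, GC or
fragmentation bias, no multimapping or duplicates, no overdispersion
beyond Poisson (a config option, off by default), no correlated
gene-to-gene structure, and gene layouts without overlaps unless
requested. Passing recovery tests demonstrates the estimators are correct
and calibrated on data satisfying their assumptions; it does not certify
published percentages from real libraries, which depend on upstream
alignment and peak-calling choices outside this package's scope.

## Problem sizes and runtime policy

Validation sizes are chosen so each check exercises the estimator at its
operating signal-to-noise while the whole suite stays interactive: 200–
1000 genes for EI checks (responder recovery averages 16 independent
1000-gene replicates, since a single cohort's non-responder coin-flips
leave ~2.5 points of sampling noise on the corrected fraction), 300 genes
× 1000–2500 bins per wave fit with 50 replicates for the speed-ordering
check, 2000 genes per retention cohort with 200 null replicates for test
calibration, and 150 genes for the nucleosome suite.

## Known limitations

* The wave HMM assumes a single contiguous front per gene; it does not
  model re-initiation behind the front or internal pause sites.
* The dyad caller resolves nucleosomes no closer than ~100 bp and reports
  kernel-density occupancy, not an occupancy probability.
* The activity classifier implements one published four-category rule;
  genes carrying only partial mark combinations default to inactive.
* The pipeline is single-process by design; determinism is favored over
  parallel throughput.
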