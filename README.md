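# txchromdyn

Transcription and chromatin dynamics after genotoxic stress: a Python
toolkit for quantifying how cells reorganize RNA polymerase II activity and
chromatin after UV damage, built for comparisons between repair-proficient
fibroblasts and transcription-coupled-repair-deficient (Cockayne syndrome
B) cells. It is aimed at computational genomicists who already have
aligned interval-level data (read/fragment BEDs, peak BEDs, count tables)
and want the downstream, analysis-specific metrics.

Four analyses share one interval/counting substrate:

* **Promoter-pause release.** The escape index of a gene is
  `EI = Db / Dp`, the read density over the early gene body
  [TSS + 100, TSS + 2000) divided by the density over the
  promoter-proximal region [TSS − 250, TSS + 100). `ΔEI = EI₊UV / EI₋UV`
  per gene, and the fraction of genes with ΔEI > 1 summarizes the
  genome-wide release of paused RNAPII. Gene activity
  (active / repressed / inactive / ambiguous) is classified from overlap
  of the extended promoter with RNAPII-Ser2P, H3K27ac and H3K27me3 peaks.
* **Elongation-wave progression.** After DRB release, nascent
  transcription advances as a front. Binned gene-body signal is modeled
  with a two-state left-to-right Poisson HMM (ON → OFF, OFF absorbing),
  fit by EM and decoded per gene by Viterbi; wave speed is the slope of
  the median front over time (kb/min).
* **Nascent-RNA retention.** From pulse-chase count tables,
  `retention(t₁) = CPM(intronic, t₁) / CPM(nascent gene, t₀)`; cell lines
  are compared with a seeded permutation test on an IQR-trimmed Welch t.
* **Nucleosome organization.** Dyad-anchored Vplots (fragment size ×
  midpoint offset), density-Vplot subtraction with negative zeroing,
  kernel-density dyad calling with a positional fuzziness score, and
  +1 → +2 nucleosome spacing modes.

A first-class synthetic-data module generates every input with known
ground truth (planted EIs, wave speeds, decay rates, dyad positions), so
the whole pipeline is testable end to end without downloads.

## Worked example

```python
import numpy as np
from txchromdyn.pausing_metrics import compute_ei, compute_delta_ei, percent_increased
from txchromdyn.synthetic_data import SimulationConfig, make_genome, simulate_chip_reads

cfg = SimulationConfig(seed=1, n_genes=500, responder_fraction=0.7)
rng = np.random.default_rng(cfg.seed)
genes, _ = make_genome(cfg, rng)
reads, truth = simulate_chip_reads(cfg, genes, rng)

ei_control = compute_ei(reads["NOUV"], genes)
ei_uv = compute_ei(reads["UV"], genes)
deltas = compute_delta_ei(ei_control, ei_uv)
print(f"median EI (NO UV): {np.median([r.EI for r in ei_control]):.3f}")
print(f"median EI (+UV):   {np.median([r.EI for r in ei_uv]):.3f}")
print(f"percent of genes with increased EI: {percent_increased(deltas):.1f}%")
```

prints

```
median EI (NO UV): 0.965
median EI (+UV):   1.600
percent of genes with increased EI: 85.2%
```

The median EI rises because 70% of genes carry a planted 2× body boost;
85.2% of genes show ΔEI > 1 — the 70% planted responders plus about half
of the remaining genes crossing 1 by symmetric counting noise (the strict
`> 1` rule splits a null gene 50/50). Inverting that noise floor recovers
the planted 70%.

More narrative scripts live in `examples/` (one per capability):
`escape_index.py`, `wave_progression.py`, `retention_analysis.py`,
`nucleosome_organization.py`, `end_to_end_pipeline.py`.

## Command line

A thin CLI wraps the manifest-driven pipeline:

```bash
txchromdyn run --seed 11 --outdir run_dir           # all stages, synthetic inputs
txchromdyn ei --config manifest.yaml                # a single stage
```

Stages run in dependency order (simulate → annotate → {ei, activity} and
{wave, retention, nuc}); each writes tab-delimited tables plus a
`summary.json`, and the run ends with an `index.json` listing every output
with a SHA-256 checksum. Re-running an identical manifest and seed
reproduces every file byte for byte. Input paths default to the simulate
stage's outputs and can be overridden to point at real data in the same
formats (BED3/BED6 intervals, gene tables, tab-delimited count tables and
gene × bin matrices).

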