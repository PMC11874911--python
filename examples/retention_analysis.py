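"""Pulse-chase retention: do nascent transcripts linger after UV?

Simulates pulse-chase count tables for a fast-clearing (VH10-like,
lambda = 0.4/h) and a slow-clearing (CS-B-like, lambda = 0.1/h) cell line,
applies the median-activity filter, computes per-gene retention ratios, and
tests the cell-line difference with the IQR-trimmed permutation t-test.
"""

import numpy as np

from txchromdyn.retention import (
    compute_retention,
    median_activity_filter,
    permutation_t_test_iqr,
)
from txchromdyn.synthetic_data import SimulationConfig, simulate_pulse_chase

cfg = SimulationConfig(seed=3)
rng = np.random.default_rng(cfg.seed)

retention = {}
for cell in ("VH10", "CSB"):
    nascent, chase, _ = simulate_pulse_chase(cfg, n_genes=1500,
                                             cell_line=cell, rng=rng)
    genes = median_activity_filter([nascent, *chase.values()])
    retention[cell] = {
        t: np.array([r.retention
                     for r in compute_retention(tab, nascent, genes, t)])
        for t, tab in chase.items()
    }
    lam = cfg.retention_decay[cell]
    print(f"{cell} ({len(genes)} genes past the median filter):")
    for t, vals in retention[cell].items():
        print(f"   t={t:>3.1f} h  median retention {np.median(vals):.3f}  "
              f"(planted exp(-{lam}*t) = {np.exp(-lam * t):.3f})")

for t in (6.5, 8.0):
    res = permutation_t_test_iqr(retention["VH10"][t], retention["CSB"][t],
                                 seed=cfg.seed)
    print(f"VH10 vs CSB at {t} h: t = {res.statistic:.1f}, p = {res.p_value:.4g}")
# The slow-clearing line retains far more nascent RNA at late timepoints;
# the permutation p-value bottoms out at 1/(n_perm+1) ~ 0.001.
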