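"""Escape index, ΔEI summaries, and peak-overlap activity classification."""

import numpy as np
import pytest
from scipy import stats

from txchromdyn.genome_model import GeneModel, GenomicInterval
from txchromdyn.pausing_metrics import (
    Activity,
    DeltaEIRecord,
    classify_activity,
    common_active_set,
    compute_delta_ei,
    compute_ei,
    percent_increased,
)
from txchromdyn.synthetic_data import SimulationConfig, make_genome, simulate_chip_reads

from conftest import random_genes, reads_df


def uniform_reads(gene, upstream=300, downstream=2100):
    s, e = sorted(gene.oriented_window(upstream, downstream))
    starts = np.arange(s, e)
    return reads_df(gene.chrom, starts, starts + 1)


def test_uniform_coverage_gives_ei_one():
    gene = GeneModel("g", "chr1", "+", 10_000, 20_000)
    recs = compute_ei(uniform_reads(gene), [gene])
    assert recs[0].EI == pytest.approx(1.0)


def test_ei_definitional_ratio():
    """Promoter density 4x body density -> EI 0.5 x 2 ... i.e. Db/Dp."""
    gene = GeneModel("g", "chr1", "+", 10_000, 20_000)
    ps, pe = gene.oriented_window(250, 100)
    bs, be = gene.oriented_window(-100, 2000)
    prom = np.repeat(np.arange(ps, pe), 4)
    body = np.repeat(np.arange(bs, be), 2)
    starts = np.concatenate([prom, body])
    recs = compute_ei(reads_df("chr1", starts, starts + 1), [gene])
    assert recs[0].EI == pytest.approx(0.5)


def test_ei_zero_promoter_gene_dropped():
    gene = GeneModel("g", "chr1", "+", 10_000, 20_000)
    bs, be = gene.oriented_window(-100, 2000)
    starts = np.arange(bs, be)
    recs = compute_ei(reads_df("chr1", starts, starts + 1), [gene])
    assert recs == []


def test_ei_scale_invariance(rng):
    cfg = SimulationConfig(seed=5, n_genes=30)
    genes, _ = make_genome(cfg, rng)
    reads, _ = simulate_chip_reads(cfg, genes, rng)
    r = reads["NOUV"]
    once = compute_ei(r, genes)
    tripled = compute_ei(
        reads_df(
            np.tile(r["chrom"], 3),
            np.tile(r["start"], 3),
            np.tile(r["end"], 3),
        ),
        genes,
    )
    for a, b in zip(once, tripled):
        assert a.EI == pytest.approx(b.EI)


def test_ei_matches_per_base_depth_oracle(rng):
    """Depth-mode EI equals a per-base coverage accumulation oracle."""
    cfg = SimulationConfig(seed=6, n_genes=25)
    genes, _ = make_genome(cfg, rng)
    reads, _ = simulate_chip_reads(cfg, genes, rng)
    r = reads["NOUV"]
    recs = {x.gene_id: x for x in compute_ei(r, genes, density_mode="depth")}
    starts = r["start"].to_numpy()
    ends = r["end"].to_numpy()
    for g in genes:

        def mean_depth(lo, hi):
            depth = np.zeros(hi - lo)
            for s, e in zip(starts, ends):
                a, b = max(s, lo), min(e, hi)
                if a < b:
                    depth[a - lo:b - lo] += 1
            return depth.mean()

        dp = mean_depth(*sorted(g.oriented_window(250, 100)))
        db = mean_depth(*sorted(g.oriented_window(-100, 2000)))
        if dp == 0:
            assert g.gene_id not in recs
            continue
        assert recs[g.gene_id].EI == pytest.approx(db / dp, rel=1e-12)


def test_delta_ei_tie_is_not_an_increase():
    d = DeltaEIRecord("g", 2.0, 2.0)
    assert d.delta_EI == 1.0 and not d.increased
    assert DeltaEIRecord("g", 1.0, 2.0).increased


def test_delta_ei_requires_shared_genes(rng):
    cfg = SimulationConfig(seed=7, n_genes=10)
    genes, _ = make_genome(cfg, rng)
    reads, _ = simulate_chip_reads(cfg, genes, rng)
    recs = compute_ei(reads["NOUV"], genes)
    with pytest.raises(ValueError, match="no shared genes"):
        compute_delta_ei(recs[:5], [])


def test_self_comparison_percent_increased_zero(rng):
    cfg = SimulationConfig(seed=8, n_genes=40)
    genes, _ = make_genome(cfg, rng)
    reads, _ = simulate_chip_reads(cfg, genes, rng)
    recs = compute_ei(reads["NOUV"], genes)
    deltas = compute_delta_ei(recs, recs)
    assert all(d.delta_EI == 1.0 for d in deltas)
    assert percent_increased(deltas) == 0.0


def test_percent_increased_extremes():
    up = [DeltaEIRecord("a", 1.0, 2.0)]
    down = [DeltaEIRecord("b", 2.0, 1.0)]
    assert percent_increased(up) == 100.0
    assert percent_increased(down) == 0.0


def test_planted_ei_recovery_spearman(rng):
    """With a few hundred reads per gene, estimated EI tracks planted EI."""
    cfg = SimulationConfig(seed=9, n_genes=300)
    genes, _ = make_genome(cfg, rng)
    reads, truth = simulate_chip_reads(cfg, genes, rng)
    recs = compute_ei(reads["NOUV"], genes)
    t = truth[truth.condition == "NOUV"].set_index("gene_id")["true_ei"]
    est = np.array([r.EI for r in recs])
    true = np.array([t[r.gene_id] for r in recs])
    rho = stats.spearmanr(est, true).statistic
    assert rho > 0.95


# -- activity classification ----------------------------------------------


def activity_oracle(gene, ser2p, k27ac, k27me3):
    s, e = sorted(gene.oriented_window(250, 2000))

    def hit(peaks):
        return any(p.chrom == gene.chrom and p.start < e and s < p.end
                   for p in peaks)

    has = (hit(ser2p), hit(k27ac), hit(k27me3))
    if has[1] and has[2]:
        return Activity.AMBIGUOUS
    if has[0] and has[1]:
        return Activity.ACTIVE
    if has[2] and not has[0] and not has[1]:
        return Activity.REPRESSED
    return Activity.INACTIVE


def test_active_needs_ser2p_and_k27ac():
    g = GeneModel("g", "chr1", "+", 10_000, 20_000)
    peak = [GenomicInterval("chr1", 10_100, 10_500)]
    assert classify_activity([g], peak, peak, [])["g"] is Activity.ACTIVE
    assert classify_activity([g], peak, [], [])["g"] is Activity.INACTIVE


def test_no_overlap_is_inactive_and_k27me3_only_repressed():
    g = GeneModel("g", "chr1", "+", 10_000, 20_000)
    far = [GenomicInterval("chr1", 50_000, 50_400)]
    near = [GenomicInterval("chr1", 10_100, 10_500)]
    assert classify_activity([g], far, far, far)["g"] is Activity.INACTIVE
    assert classify_activity([g], far, far, near)["g"] is Activity.REPRESSED
    assert classify_activity([g], near, near, near)["g"] is Activity.AMBIGUOUS


def test_activity_matches_truth_table_oracle(rng):
    genes = random_genes(rng, 1000, genome_span=5_000_000)
    sets = [
        [GenomicInterval("chr1", int(s), int(s) + 400)
         for s in rng.integers(0, 5_000_000, n)]
        for n in (600, 600, 300)
    ]
    labels = classify_activity(genes, *sets)
    for g in genes:
        assert labels[g.gene_id] is activity_oracle(g, *sets), g.gene_id


def test_activity_labels_partition_gene_set(rng):
    genes = random_genes(rng, 200, genome_span=1_000_000)
    sets = [
        [GenomicInterval("chr1", int(s), int(s) + 300)
         for s in rng.integers(0, 1_000_000, 150)]
        for _ in range(3)
    ]
    labels = classify_activity(genes, *sets)
    counts = {a: 0 for a in Activity}
    for lab in labels.values():
        counts[lab] += 1
    assert sum(counts.values()) == len(genes)


def test_common_active_set_intersection():
    a = {"g1": Activity.ACTIVE, "g2": Activity.ACTIVE, "g3": Activity.INACTIVE}
    b = {"g1": Activity.ACTIVE, "g2": Activity.REPRESSED, "g3": Activity.ACTIVE}
    assert common_active_set(a, b) == {"g1"}
    assert common_active_set(a, {"g9": Activity.ACTIVE}) == set()
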