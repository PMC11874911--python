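"""Gene-universe construction: TSS clustering, length and neighbor filters,
and peak region assignment, each checked against exhaustive oracles."""

import numpy as np
import pytest

from txchromdyn.genome_model import (
    GeneModel,
    GenomicInterval,
    RegionCategory,
    assign_region_category,
    cluster_tss,
    filter_clear_signal,
    filter_min_length,
)

from conftest import make_gene, random_genes, random_intervals


# -- oracles ---------------------------------------------------------------


def brute_force_clusters(transcripts, radius):
    """Single-linkage connected components over |TSS_i - TSS_j| <= radius
    on the same chromosome and strand (union-find over all pairs)."""
    parent = list(range(len(transcripts)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, a in enumerate(transcripts):
        for j, b in enumerate(transcripts):
            if i < j and a.chrom == b.chrom and a.strand == b.strand \
                    and abs(a.tss - b.tss) <= radius:
                parent[find(i)] = find(j)
    groups = {}
    for i, t in enumerate(transcripts):
        groups.setdefault(find(i), []).append(t)
    return [min(g, key=lambda t: (-t.length, t.gene_id)) for g in groups.values()]


def brute_force_clear_signal(genes, up, down):
    survivors = []
    for i, a in enumerate(genes):
        ok = True
        for j, b in enumerate(genes):
            if i == j or a.chrom != b.chrom:
                continue
            off = (b.tss - a.tss) if a.strand == "+" else (a.tss - b.tss)
            if -up <= off <= down:
                ok = False
            off_ba = (a.tss - b.tss) if b.strand == "+" else (b.tss - a.tss)
            if -up <= off_ba <= down:
                ok = False  # partner of an offending pair
        if ok:
            survivors.append(a)
    return survivors


def brute_force_category(peak, genes):
    hit = set()
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        foot = {
            RegionCategory.TSS: (g.tss - 500, g.tss + 500),
            RegionCategory.TTS: (g.tts - 500, g.tts + 500),
        }
        lo, hi = sorted((g.tss, g.tts))
        if hi - 500 > lo + 500:
            foot[RegionCategory.INTRAGENIC] = (lo + 500, hi - 500)
        for cat, (s, e) in foot.items():
            if peak.start < e and s < peak.end:
                hit.add(cat)
    for cat in (RegionCategory.TSS, RegionCategory.TTS,
                RegionCategory.INTRAGENIC):
        if cat in hit:
            return cat
    return RegionCategory.INTERGENIC


# -- cluster_tss -----------------------------------------------------------


def test_cluster_keeps_longest_within_radius():
    a = make_gene("short", start=100, end=5100)
    b = make_gene("long", start=130, end=8130)
    assert cluster_tss([a, b], radius=50) == [b]


def test_cluster_single_transcript_identity():
    g = make_gene()
    assert cluster_tss([g], radius=50) == [g]


def test_cluster_matches_brute_force_oracle(rng):
    ts = random_genes(rng, 200, genome_span=50_000)  # dense: many clusters
    got = sorted(cluster_tss(ts, 50), key=lambda g: g.gene_id)
    exp = sorted(brute_force_clusters(ts, 50), key=lambda g: g.gene_id)
    assert got == exp


def test_cluster_is_idempotent(rng):
    ts = random_genes(rng, 150, genome_span=80_000)
    once = cluster_tss(ts, 50)
    assert cluster_tss(once, 50) == once


def test_cluster_respects_strand_and_chrom():
    plus = make_gene("p", strand="+", start=5000, end=8100)
    minus = GeneModel("m", "chr1", "-", 2000, 5000)  # TSS also at 5000
    assert len(cluster_tss([plus, minus], 50)) == 2


# -- filters ---------------------------------------------------------------


def test_min_length_is_inclusive():
    genes = [make_gene(f"g{L}", start=0 + 1, end=1 + L) for L in (1999, 2000, 2001)]
    kept = filter_min_length(genes, 2000)
    assert sorted(g.gene_id for g in kept) == ["g2000", "g2001"]


def test_min_length_one_keeps_all(rng):
    genes = random_genes(rng, 20)
    assert filter_min_length(genes, 1) == genes


def test_clear_signal_removes_both_members_of_pair():
    a = make_gene("a", start=10_000, end=16_000)
    b = make_gene("b", start=11_000, end=17_000)
    assert filter_clear_signal([a, b]) == []


def test_clear_signal_keeps_isolated_gene():
    g = make_gene()
    assert filter_clear_signal([g]) == [g]


def test_clear_signal_matches_all_pairs_oracle(rng):
    genes = random_genes(rng, 500, genome_span=3_000_000)
    got = {g.gene_id for g in filter_clear_signal(genes)}
    exp = {g.gene_id for g in brute_force_clear_signal(genes, 250, 2000)}
    assert got == exp


def test_clear_signal_output_has_no_violating_pair(rng):
    genes = random_genes(rng, 300, genome_span=2_000_000)
    out = filter_clear_signal(genes)
    for a in out:
        for b in out:
            if a is b:
                continue
            off = (b.tss - a.tss) if a.strand == "+" else (a.tss - b.tss)
            assert not (-250 <= off <= 2000)


# -- region categories -----------------------------------------------------


def test_peak_at_tss_labeled_tss():
    g = make_gene(start=10_000, end=20_000)
    p = GenomicInterval("chr1", g.tss - 100, g.tss + 100)
    assert assign_region_category([p], [g])[p] == RegionCategory.TSS


def test_peak_on_unannotated_chrom_is_intergenic():
    g = make_gene(chrom="chr1")
    p = GenomicInterval("chrUn", 0, 100)
    assert assign_region_category([p], [g])[p] == RegionCategory.INTERGENIC


def test_region_assignment_matches_per_peak_oracle(rng):
    genes = random_genes(rng, 100, genome_span=1_000_000)
    peaks = random_intervals(rng, 1000, span=1_100_000)
    got = assign_region_category(peaks, genes)
    for p in peaks:
        assert got[p] == brute_force_category(p, genes), p


def test_region_labels_partition_peak_set(rng):
    genes = random_genes(rng, 50, genome_span=500_000)
    peaks = random_intervals(rng, 300, span=600_000)
    labels = assign_region_category(peaks, genes)
    counts = {c: 0 for c in RegionCategory}
    for lab in labels.values():
        counts[lab] += 1
    assert sum(counts.values()) == len(peaks)


def test_multi_label_mode_superset_of_single(rng):
    genes = random_genes(rng, 40, genome_span=300_000)
    peaks = random_intervals(rng, 200, span=350_000)
    single = assign_region_category(peaks, genes)
    multi = assign_region_category(peaks, genes, multi=True)
    for p in peaks:
        assert single[p] in multi[p]


def test_minus_strand_tss_is_bed_end():
    g = GeneModel("m", "chr1", "-", 5000, 12_000)
    assert g.tss == 12_000 and g.tts == 5000
    p = GenomicInterval("chr1", 11_900, 12_100)
    assert assign_region_category([p], [g])[p] == RegionCategory.TSS
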