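"""Vplots, dyad calling, fuzziness, and +1/+2 spacing estimation."""

import numpy as np
import pandas as pd
import pytest

from txchromdyn.genome_model import GeneModel
from txchromdyn.nucleosome import (
    annotate_fragments,
    build_vplot,
    call_dyads,
    fuzziness_by_delta_ei,
    mononucleosome_band_test,
    spacing_mode,
    subtract_vplots,
    vplot_flatten_test,
)
from txchromdyn.synthetic_data import (
    NucleosomeConfig,
    SimulationConfig,
    make_genome,
    simulate_atac,
)


def frag_df(chrom, starts, ends):
    return annotate_fragments(
        pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))


def anchors_df(chrom, pos, strand):
    return pd.DataFrame({"chrom": chrom, "pos": pos, "strand": strand})


def test_vplot_single_cell_at_anchor():
    anchors = anchors_df("chr1", [10_000, 20_000], ["+", "+"])
    starts = [10_000 - 73, 20_000 - 73]
    frags = frag_df("chr1", starts, [s + 147 for s in starts])
    vp = build_vplot(frags, anchors)
    assert vp.matrix.sum() == 2
    # midpoint of a 147 bp fragment centered on the anchor: offset 0
    assert vp.matrix[147 - vp.size_range[0], vp.flank] == 2


def test_vplot_minus_strand_orientation():
    anchors = anchors_df("chr1", [10_000], ["-"])
    frags = frag_df("chr1", [9_955], [9_985])  # midpoint 9970, 30 bp 3' of anchor
    vp = build_vplot(frags, anchors)
    assert vp.matrix[30 - vp.size_range[0], vp.flank + 30] == 1


def test_vplot_matches_brute_force_double_loop(rng):
    starts = rng.integers(0, 60_000, 10_000)
    sizes = rng.integers(30, 250, 10_000)
    frags = frag_df("chr1", starts, starts + sizes)
    anchors = anchors_df(
        "chr1", rng.integers(0, 60_000, 40),
        [("+", "-")[i % 2] for i in range(40)])
    vp = build_vplot(frags, anchors)
    exp = np.zeros_like(vp.matrix)
    for _, f in frags.iterrows():
        for _, a in anchors.iterrows():
            off = f["midpoint"] - a["pos"] if a["strand"] == "+" \
                else a["pos"] - f["midpoint"]
            if abs(off) <= vp.flank and 1 <= f["size"] <= 250:
                exp[f["size"] - 1, off + vp.flank] += 1
    assert np.array_equal(vp.matrix, exp)
    # mass conservation: every in-window (fragment, anchor) pair counted
    assert vp.matrix.sum() == exp.sum()


def random_vplots(rng, n=2000):
    starts = rng.integers(0, 20_000, n)
    sizes = rng.integers(30, 250, n)
    anchors = anchors_df("chr1", rng.integers(0, 20_000, 10), ["+"] * 10)
    a = build_vplot(frag_df("chr1", starts, starts + sizes), anchors)
    starts = rng.integers(0, 20_000, n)
    sizes = rng.integers(30, 250, n)
    b = build_vplot(frag_df("chr1", starts, starts + sizes), anchors)
    return a.to_density(), b.to_density()


def test_subtract_identical_is_zero(rng):
    a, _ = random_vplots(rng)
    d = subtract_vplots(a, a)
    assert np.all(d.matrix == 0)


def test_subtract_floors_negatives_and_bounded(rng):
    a, b = random_vplots(rng)
    d = subtract_vplots(a, b)
    assert np.all(d.matrix >= 0)
    assert np.all(d.matrix <= a.matrix)
    assert np.array_equal(d.matrix, np.maximum(a.matrix - b.matrix, 0))


def test_subtract_requires_density_normalization():
    rng = np.random.default_rng(0)
    a, _ = random_vplots(rng)
    counts = build_vplot(frag_df("chr1", [100], [200]),
                         anchors_df("chr1", [150], ["+"]))
    with pytest.raises(ValueError, match="density"):
        subtract_vplots(a, counts)


def test_flatten_test_identical_null(rng):
    a, _ = random_vplots(rng)
    r = vplot_flatten_test(a, a)
    assert r.statistic == 0.0 and r.p_value == 1.0


def test_flatten_test_direction_of_shift(rng):
    a, _ = random_vplots(rng)
    import dataclasses
    b = dataclasses.replace(a, matrix=a.matrix + 1e-5)
    r = vplot_flatten_test(b, a)
    assert r.statistic > 0 and r.p_value < 0.01


def test_mono_band_test_identical_flagged_p_one(rng):
    a, _ = random_vplots(rng)
    r = mononucleosome_band_test(a, a)
    assert r.p_value == 1.0 and r.degenerate


def test_mono_band_density_tracks_mono_fraction(rng):
    """More mononucleosome-sized fragments -> more band mass."""
    cfg_lo = SimulationConfig(
        seed=1, n_genes=30,
        nucleosome=NucleosomeConfig(
            size_mixture={"sub": 0.8, "mono": 0.1, "di": 0.1}))
    cfg_hi = SimulationConfig(
        seed=1, n_genes=30,
        nucleosome=NucleosomeConfig(
            size_mixture={"sub": 0.1, "mono": 0.8, "di": 0.1}))
    masses = {}
    for name, cfg in (("lo", cfg_lo), ("hi", cfg_hi)):
        genes, _ = make_genome(cfg, np.random.default_rng(2))
        frags, truth = simulate_atac(cfg, genes, "CSB", np.random.default_rng(3))
        anchors = anchors_df(
            "chrS", truth["plus1_dyad"],
            [g.strand for g in genes])
        vp = build_vplot(frags, anchors).to_density()
        lo = 127 - vp.size_range[0]
        masses[name] = vp.matrix[lo:lo + 41].sum()
    assert masses["hi"] > masses["lo"]


def test_dyad_point_mass_zero_fuzziness():
    starts = np.full(30, 10_120 - 73)
    frags = frag_df("chr1", starts, starts + 147)
    gene = GeneModel("g", "chr1", "+", 10_000, 20_000)
    calls = call_dyads(frags, [gene])
    assert len(calls) == 1
    assert abs(calls[0].position - 10_120) <= 1
    assert calls[0].fuzziness == 0.0


def test_dyad_recovery_and_fuzziness_estimate(rng):
    mids = rng.normal(10_120, 25, 500).astype(int)
    frags = frag_df("chr1", mids - 73, mids + 74)
    gene = GeneModel("g", "chr1", "+", 10_000, 20_000)
    calls = call_dyads(frags, [gene])
    assert len(calls) >= 1
    c = max(calls, key=lambda c: c.occupancy)
    assert abs(c.position - 10_120) <= 5
    assert c.fuzziness == pytest.approx(25, abs=5)


def test_two_planted_nucleosomes_in_wide_window(rng):
    mids1 = rng.normal(10_120, 10, 300).astype(int)
    mids2 = rng.normal(10_310, 10, 300).astype(int)
    mids = np.concatenate([mids1, mids2])
    frags = frag_df("chr1", mids - 73, mids + 74)
    gene = GeneModel("g", "chr1", "+", 10_000, 20_000)
    calls = call_dyads(frags, [gene], search_downstream=1000)
    pos = sorted(c.position for c in calls)
    assert len(pos) == 2
    assert abs(pos[0] - 10_120) <= 10 and abs(pos[1] - 10_310) <= 10


def test_uncallable_region_yields_no_call():
    frags = frag_df("chr1", [10_050], [10_197])  # single fragment < min support
    gene = GeneModel("g", "chr1", "+", 10_000, 20_000)
    assert call_dyads(frags, [gene]) == []


def test_tight_positioning_gives_lower_fuzziness(rng):
    cfg = SimulationConfig(seed=9, n_genes=80)
    genes, _ = make_genome(cfg, np.random.default_rng(9))
    fuzz = {}
    for cell in ("VH10", "CSB"):  # planted SD 30 vs 10
        frags, _ = simulate_atac(cfg, genes, cell, np.random.default_rng(10))
        calls = {c.gene_id: c.fuzziness for c in call_dyads(frags, genes)}
        fuzz[cell] = calls
    shared = fuzz["VH10"].keys() & fuzz["CSB"].keys()
    frac_lower = np.mean([fuzz["CSB"][g] < fuzz["VH10"][g] for g in shared])
    assert frac_lower > 0.95


def test_spacing_mode_exact_plant():
    genes = [GeneModel(f"g{i}", "chr1", "+", 10_000 + i * 5000,
                       14_000 + i * 5000) for i in range(50)]
    dyads = pd.DataFrame({
        "chrom": "chr1",
        "pos": [g.tss + 120 for g in genes] + [g.tss + 310 for g in genes]})
    res = spacing_mode(dyads, genes)
    modes = {r.rank: r.mode_distance for r in res}
    assert modes[1] == 120 and modes[2] == 310


def test_spacing_excludes_beyond_one_kb():
    g = GeneModel("g", "chr1", "+", 10_000, 20_000)
    dyads = pd.DataFrame({"chrom": ["chr1"], "pos": [11_500]})
    assert spacing_mode(dyads, [g]) == []


def test_spacing_mode_with_jitter(rng):
    cfg = SimulationConfig(seed=11, n_genes=150)
    genes, _ = make_genome(cfg, np.random.default_rng(11))
    frags, _ = simulate_atac(cfg, genes, "CSB", np.random.default_rng(12))
    calls = call_dyads(frags, genes, search_downstream=1000)
    gene_chrom = {g.gene_id: g.chrom for g in genes}
    dyads = pd.DataFrame(
        [(gene_chrom[c.gene_id], c.position) for c in calls],
        columns=["chrom", "pos"])
    res = {r.rank: r for r in spacing_mode(dyads, genes)}
    assert abs(res[1].mode_distance - 120) <= 10
    assert abs(res[2].mode_distance - 310) <= 10
    assert np.all(res[1].distances <= 1000)


def test_fuzziness_by_delta_ei_direction(rng):
    """Fuzziness planted to rise with ΔEI separates top from bottom group."""
    n = 400
    delta = pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)],
                          "delta_EI": np.linspace(0.5, 3.0, n)})
    from txchromdyn.nucleosome import DyadCall
    calls = [DyadCall(f"g{i}", 0, 100, 1.0,
                      10 + 20 * (i / n) + rng.normal(0, 1), 50)
             for i in range(n)]
    low, high, res = fuzziness_by_delta_ei(calls, delta, n=100)
    assert np.median(high) > np.median(low)
    assert res.p_value < 1e-6


def test_fuzziness_by_delta_ei_shrinks_n_with_warning(rng):
    delta = pd.DataFrame({"gene_id": [f"g{i}" for i in range(30)],
                          "delta_EI": rng.uniform(0.5, 2, 30)})
    from txchromdyn.nucleosome import DyadCall
    calls = [DyadCall(f"g{i}", 0, 100, 1.0, float(rng.uniform(5, 30)), 50)
             for i in range(30)]
    with pytest.warns(UserWarning, match="shrinking"):
        low, high, _ = fuzziness_by_delta_ei(calls, delta, n=100)
    assert len(low) == len(high) == 15
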