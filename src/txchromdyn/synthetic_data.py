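"""Synthetic datasets with known ground truth for every pipeline stage.

Each generator emulates the statistical structure one analysis assumes —
not raw sequencing, but the interval/count level the pipeline consumes:

* ChIP-style reads with a promoter-proximal peak and a gene-body plateau
  whose density ratio is a planted per-gene escape index; a "UV" condition
  boosts the body of a planted responder fraction.
* A nascent-transcription wave advancing at a configurable speed, observed
  as Poisson bin counts that are high behind the front and near-zero ahead.
* Pulse-chase gene/exonic/intronic count tables with exponential retention
  decay per cell line.
* ATAC fragments from a nucleosome-free region plus +1/+2 nucleosomes with
  configurable positional jitter and a sub/mono/di fragment-size mixture.
* Peak sets with controlled overlap structure for activity classification.

Every generator is deterministic given (config, seed), and returns ground
truth alongside the data; truth is never consumed by the pipeline under
test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome_model import GeneModel, GenomicInterval
from .retention import CountTable, derive_intronic
from .signal_engine import reads_from_arrays


@dataclass
class NucleosomeConfig:
    nfr_width: int = 100
    plus1_offset: int = 120
    spacing: int = 190
    positional_sd: dict = field(default_factory=lambda: {"VH10": 30.0, "CSB": 10.0})
    size_mixture: dict = field(
        default_factory=lambda: {"sub": 0.3, "mono": 0.55, "di": 0.15}
    )
    fragments_per_gene: int = 120


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiments.

    Defaults reflect the biological setting under test: a ~2/3 genome-wide
    pause-release response to UV, elongation at ~2 kb/min in normal vs
    ~1.2 kb/min in repair-deficient cells, first-order nascent-RNA clearance
    that is slowed in the deficient line, and +1 nucleosomes that are less
    positionally constrained in the normal line.
    """

    seed: int = 0
    n_genes: int = 1000
    gene_length_range: tuple[int, int] = (5_000, 20_000)
    ei_lognormal: tuple[float, float] = (0.0, 1.0)  # (mu, sigma) of log EI
    responder_fraction: float = 0.66
    uv_body_boost: float = 2.0
    promoter_reads: int = 60  # expected reads in the promoter window per gene
    read_length: int = 50
    wave_speed: dict = field(default_factory=lambda: {"VH10": 2.0, "CSB": 1.2})
    timepoints_min: tuple[float, ...] = (10.0, 20.0, 60.0)
    lambda_on: float = 15.0
    lambda_off: float = 0.3
    front_jitter_sd: float = 2000.0  # bp
    retention_decay: dict = field(default_factory=lambda: {"VH10": 0.4, "CSB": 0.1})
    chase_timepoints_h: tuple[float, ...] = (1.5, 6.5, 8.0)
    nucleosome: NucleosomeConfig = field(default_factory=NucleosomeConfig)
    library_size: int = 1_000_000

    def as_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# genome


def make_genome(
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    min_length: Optional[int] = None,
    intergenic_gap: int = 5_000,
    close_pairs: int = 0,
    close_pair_distance: int = 1_000,
) -> tuple[list[GeneModel], dict[str, int]]:
    """Random non-pathological gene layout plus chromosome sizes.

    Genes are laid end to end with >= ``intergenic_gap`` bp between them on
    one synthetic chromosome; ``close_pairs`` extra gene pairs with TSSs
    ``close_pair_distance`` apart are appended for neighbor-filter tests.
    """
    if cfg.n_genes <= 0:
        raise ValueError("n_genes must be positive")
    rng = rng or np.random.default_rng(cfg.seed)
    lo, hi = cfg.gene_length_range
    if min_length is not None:
        lo = max(lo, min_length)
        hi = max(hi, lo + 1)
    lengths = rng.integers(lo, hi + 1, size=cfg.n_genes)
    genes: list[GeneModel] = []
    pos = 10_000
    width = len(str(cfg.n_genes + 2 * close_pairs))
    for i, L in enumerate(lengths):
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"g{i:0{width}d}", "chrS", strand, pos, pos + int(L)))
        pos += int(L) + intergenic_gap + int(rng.integers(0, intergenic_gap))
    for j in range(close_pairs):
        L = int(rng.integers(lo, hi + 1))
        a = GeneModel(f"p{j}a", "chrS", "+", pos, pos + L)
        b = GeneModel(f"p{j}b", "chrS", "+", pos + close_pair_distance,
                      pos + close_pair_distance + L)
        genes.extend([a, b])
        pos += L + close_pair_distance + intergenic_gap
    chrom_sizes = {"chrS": pos + 10_000}
    return genes, chrom_sizes


# ---------------------------------------------------------------------------
# ChIP reads with planted escape indices


def _place_reads(rng, wstart, wend, n, read_len, noiseless=False):
    """Start coordinates of n reads fully contained in [wstart, wend)."""
    span = wend - wstart - read_len
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if noiseless:
        return wstart + np.arange(n) * span // n
    return wstart + rng.integers(0, span + 1, size=n)


def simulate_chip_reads(
    cfg: SimulationConfig,
    genes: Sequence[GeneModel],
    rng: Optional[np.random.Generator] = None,
    noiseless: bool = False,
    conditions: tuple[str, ...] = ("NOUV", "UV"),
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Reads for a control and a UV condition with planted per-gene EI.

    Per gene, promoter-proximal occupancy is constant (``promoter_reads``
    expected reads over [-250, +100)) while the body window [+100, +2000)
    receives reads so the analytic density ratio equals the drawn log-normal
    EI — pausing load is comparatively uniform across genes and escape
    variation is expressed through release into the body.  Responder genes
    get their body intensity multiplied by ``uv_body_boost`` in the UV
    condition.  In ``noiseless`` mode expected counts are rounded instead of
    Poisson-sampled and reads are evenly spaced, so the measured EI equals
    the recorded truth exactly.

    Returns (reads per condition, truth table with true EI per condition and
    the responder flag).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    mu, sigma = cfg.ei_lognormal
    prom_len, body_len = 350, 1900
    truth_rows = []
    starts: dict[str, list[np.ndarray]] = {c: [] for c in conditions}
    chroms: dict[str, list[np.ndarray]] = {c: [] for c in conditions}
    for g in genes:
        target_ei = float(rng.lognormal(mu, sigma))
        responder = bool(rng.random() < cfg.responder_fraction)
        for cond in conditions:
            boost = cfg.uv_body_boost if (cond != "NOUV" and responder) else 1.0
            ei_cond = target_ei * boost
            exp_prom = float(cfg.promoter_reads)
            exp_body = exp_prom * body_len * ei_cond / prom_len
            if noiseless:
                n_prom = max(int(round(exp_prom)), 1)
                n_body = int(round(exp_body))
            else:
                n_prom = int(rng.poisson(exp_prom))
                n_body = int(rng.poisson(exp_body))
            ps, pe = g.oriented_window(250, 100)
            bs, be = g.oriented_window(-100, 2000)
            s = np.concatenate([
                _place_reads(rng, ps, pe, n_prom, cfg.read_length, noiseless),
                _place_reads(rng, bs, be, n_body, cfg.read_length, noiseless),
            ])
            starts[cond].append(s)
            chroms[cond].append(np.full(len(s), g.chrom))
            if noiseless:
                # achieved ratio after integer rounding
                ei_cond = (n_body / body_len) / (n_prom / prom_len)
            truth_rows.append((g.gene_id, cond, ei_cond, responder, target_ei))
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "condition", "true_ei", "responder", "target_ei"],
    )
    out = {}
    for c in conditions:
        s = np.concatenate(starts[c]) if starts[c] else np.empty(0, int)
        ch = np.concatenate(chroms[c]) if chroms[c] else np.empty(0, object)
        out[c] = reads_from_arrays(ch, s, s + cfg.read_length)
    return out, truth


# ---------------------------------------------------------------------------
# elongation wave


def wave_region_len(timepoint_min: float) -> int:
    """Analysis-region length per timepoint: the first 100 kb of long genes
    for early timepoints, 250 kb once the wave can out-run 100 kb (> 30 min),
    mirroring the two gene-length thresholds of the wave analysis."""
    return 250_000 if timepoint_min > 30 else 100_000


def simulate_wave(
    cfg: SimulationConfig,
    n_genes: int = 300,
    region_len: Optional[int] = None,
    bin_size: int = 100,
    cell_line: str = "VH10",
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[float, pd.DataFrame], pd.DataFrame]:
    """Gene x bin Poisson count matrices per timepoint plus true fronts.

    The true front of gene g at time t is speed*t (+ per-gene Gaussian
    jitter), clipped to the region and quantized to bin boundaries; bins
    behind the front draw Poisson(lambda_on), ahead Poisson(lambda_off).
    Unless ``region_len`` is fixed, each timepoint uses
    :func:`wave_region_len`.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    speed = cfg.wave_speed[cell_line]  # kb/min
    gene_ids = [f"w{i:04d}" for i in range(n_genes)]
    matrices: dict[float, pd.DataFrame] = {}
    truth_rows = []
    for t in cfg.timepoints_min:
        rlen = region_len if region_len is not None else wave_region_len(t)
        n_bins = rlen // bin_size
        fronts_bp = speed * 1000.0 * t + rng.normal(0, cfg.front_jitter_sd, n_genes)
        front_bins = np.clip(np.round(fronts_bp / bin_size), 0, n_bins).astype(int)
        mat = rng.poisson(cfg.lambda_off, size=(n_genes, n_bins)).astype(float)
        on_mask = np.arange(n_bins)[None, :] < front_bins[:, None]
        mat[on_mask] = rng.poisson(cfg.lambda_on, size=int(on_mask.sum()))
        matrices[t] = pd.DataFrame(mat, index=gene_ids)
        for gid, fb in zip(gene_ids, front_bins):
            truth_rows.append((gid, cell_line, t, int(fb) * bin_size))
    truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "cell_line", "timepoint", "true_front_bp"]
    )
    return matrices, truth


# ---------------------------------------------------------------------------
# pulse-chase retention


def simulate_pulse_chase(
    cfg: SimulationConfig,
    n_genes: int = 2000,
    cell_line: str = "VH10",
    rng: Optional[np.random.Generator] = None,
) -> tuple[CountTable, dict[float, CountTable], pd.DataFrame]:
    """Nascent baseline and pulse-chase count tables with exponential decay.

    Gene g has baseline abundance N0 ~ log-normal; its labeled intronic
    signal at chase time t is Poisson(N0 * exp(-lambda * t)) with lambda the
    cell line's clearance rate, so the true retention is exp(-lambda * t).
    Exonic (processed) counts decay at half that rate.  All tables carry the
    configured nominal library size (depth-equalized libraries).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    lam = cfg.retention_decay[cell_line]
    gene_ids = [f"r{i:04d}" for i in range(n_genes)]
    n0 = rng.lognormal(np.log(200.0), 0.8, n_genes)

    def table(cond: str, intronic_mean, exonic_mean) -> CountTable:
        intronic = rng.poisson(intronic_mean)
        exonic = rng.poisson(exonic_mean)
        df = pd.DataFrame(
            {"gene_count": intronic + exonic, "exonic_count": exonic},
            index=pd.Index(gene_ids, name="gene_id"),
        )
        return derive_intronic(CountTable(cond, df, cfg.library_size))

    # baseline nascent: gene count is the N0 reference (intronic-dominated)
    nascent = table(f"{cell_line}_nascent_t0", n0, 0.5 * n0)
    # note gene(t0) = intronic + exonic ~ 1.5 N0; retention is defined
    # against the gene count, so the planted decay applies to 1.5 N0
    chase: dict[float, CountTable] = {}
    truth_rows = []
    for t in cfg.chase_timepoints_h:
        ret = float(np.exp(-lam * t))
        gene_t0_mean = 1.5 * n0
        chase[t] = table(
            f"{cell_line}_chase_{t}h",
            gene_t0_mean * ret,
            0.5 * n0 * np.exp(-0.5 * lam * t),
        )
        for gid in gene_ids:
            truth_rows.append((gid, cell_line, t, ret))
    truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "cell_line", "timepoint", "true_retention"]
    )
    return nascent, chase, truth


# ---------------------------------------------------------------------------
# ATAC fragments


def simulate_atac(
    cfg: SimulationConfig,
    genes: Sequence[GeneModel],
    cell_line: str = "VH10",
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ATAC fragments around each TSS plus true dyad positions.

    Per gene: sub-nucleosomal fragments over the nucleosome-free region at
    the TSS, mononucleosome fragments (size ~ N(147, 10), clipped >= 100)
    around the +1 and +2 dyads with midpoint jitter of the cell line's
    positional SD, and dinucleosome fragments (size ~ N(300, 20)) spanning
    both.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    nc = cfg.nucleosome
    sd = float(nc.positional_sd[cell_line])
    mix = nc.size_mixture
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("size_mixture proportions must sum to 1")
    rows = []
    truth_rows = []
    for g in genes:
        sign = 1 if g.strand == "+" else -1
        plus1 = g.tss + sign * nc.plus1_offset
        plus2 = plus1 + sign * nc.spacing
        truth_rows.append((g.gene_id, cell_line, plus1, plus2, sd))
        n_total = nc.fragments_per_gene
        n_sub = int(round(mix["sub"] * n_total))
        n_di = int(round(mix["di"] * n_total))
        n_mono = n_total - n_sub - n_di

        sizes = np.clip(rng.normal(60, 15, n_sub), 20, 100)
        mids = g.tss + rng.uniform(-nc.nfr_width / 2, nc.nfr_width / 2, n_sub)
        rows.append((np.full(n_sub, g.chrom), mids, sizes))

        half = n_mono // 2
        for dyad, n in ((plus1, half), (plus2, n_mono - half)):
            sizes = np.clip(rng.normal(147, 10, n), 100, None)
            mids = rng.normal(dyad, sd, n)
            rows.append((np.full(n, g.chrom), mids, sizes))

        sizes = np.clip(rng.normal(300, 20, n_di), 200, None)
        mids = rng.normal((plus1 + plus2) / 2, sd, n_di)
        rows.append((np.full(n_di, g.chrom), mids, sizes))

    chrom = np.concatenate([r[0] for r in rows])
    mid = np.concatenate([r[1] for r in rows])
    size = np.round(np.concatenate([r[2] for r in rows])).astype(int)
    start = np.round(mid).astype(int) - size // 2
    frags = pd.DataFrame(
        {"chrom": chrom, "start": start, "end": start + size}
    )
    frags["size"] = size
    frags["midpoint"] = (frags["start"] + frags["end"]) // 2
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "cell_line", "plus1_dyad", "plus2_dyad", "positional_sd"],
    )
    return frags, truth


# ---------------------------------------------------------------------------
# peak sets with controlled overlap


def simulate_peaks(
    genes: Sequence[GeneModel],
    rng: np.random.Generator,
    p_hit: float = 0.5,
    width: int = 400,
) -> tuple[list[GenomicInterval], pd.DataFrame]:
    """A peak set hitting each gene's extended TSS region independently with
    probability ``p_hit``; truth records which genes were hit."""
    peaks = []
    rows = []
    for g in genes:
        hit = bool(rng.random() < p_hit)
        rows.append((g.gene_id, hit))
        if hit:
            s, e = g.oriented_window(250, 2000)
            center = int(rng.integers(s, e))
            peaks.append(GenomicInterval(g.chrom, center - width // 2,
                                         center + width // 2))
    return peaks, pd.DataFrame(rows, columns=["gene_id", "hit"])
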