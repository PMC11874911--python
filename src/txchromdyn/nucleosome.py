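"""Nucleosome organization from ATAC-seq fragments: Vplots, dyad calling,
fuzziness, and +1/+2 spacing.

A Vplot is a 2-D histogram of fragment size against fragment-midpoint offset
from an anchor (here, +1 nucleosome dyads): mononucleosome-protected
fragments appear as a ~147 bp band centered on the dyad, sub-nucleosomal
fragments of the nucleosome-free region sit below it.  Cell lines are
compared by density-normalized Vplot subtraction (negatives zeroed) and by
paired tests on the offset-wise column sums.

Dyads are called per promoter-proximal search window as local maxima of a
Gaussian-kernel density of mononucleosome-fragment midpoints; fuzziness is
the SD of the supporting midpoints around the called dyad (well-positioned
nucleosomes are "sharp", poorly phased ones "fuzzy").  +1/+2 spacing is the
mode of the distance histogram from each TSS to its two nearest downstream
dyads within 1 kb.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .genome_model import GeneModel
from .stats_core import TestResult, paired_t, wilcoxon_rank

logger = logging.getLogger(__name__)

MONO_SIZE_RANGE = (130, 180)
MONO_BAND = (127, 167)  # ~147 +/- 20 bp Vplot band


def fragments_from_bed(path) -> pd.DataFrame:
    """Read a fragment BED3 into a DataFrame with size and midpoint columns."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end"], usecols=[0, 1, 2])
    return annotate_fragments(df)


def annotate_fragments(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["size"] = out["end"] - out["start"]
    if (out["size"] <= 0).any():
        raise ValueError("fragments must have positive length")
    out["midpoint"] = (out["start"] + out["end"]) // 2
    return out


@dataclass(frozen=True)
class Vplot:
    """Fragment-size x midpoint-offset density matrix around dyad anchors.

    Rows are sizes size_range[0]..size_range[1] (1 bp), columns offsets
    -flank..+flank (1 bp, strand-oriented: positive = downstream).
    """

    matrix: np.ndarray
    size_range: tuple[int, int]
    flank: int
    n_anchors: int
    normalization: str = "counts"  # counts | density

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(self.size_range[0], self.size_range[1] + 1)

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank + 1)

    def to_density(self) -> "Vplot":
        total = self.matrix.sum()
        if total == 0:
            return replace(self, normalization="density")
        return replace(self, matrix=self.matrix / total, normalization="density")

    def column_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=0)

    def save(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.sizes, columns=self.offsets).to_csv(
            path, sep="\t",
            index_label=f"size\\offset;n_anchors={self.n_anchors};"
                        f"norm={self.normalization}")


def build_vplot(
    fragments: pd.DataFrame,
    anchors: pd.DataFrame,
    size_range: tuple[int, int] = (1, 250),
    flank: int = 250,
) -> Vplot:
    """Accumulate fragments around dyad anchors.

    ``anchors`` needs chrom, pos, strand columns.  Cell (s, o) counts
    fragments of size s whose midpoint lies at strand-oriented offset o from
    an anchor; a fragment near several anchors contributes to each.
    """
    if len(anchors) == 0:
        raise ValueError("need at least one anchor")
    if "size" not in fragments.columns:
        fragments = annotate_fragments(fragments)
    smin, smax = size_range
    n_sizes = smax - smin + 1
    n_off = 2 * flank + 1
    mat = np.zeros((n_sizes, n_off))

    ok_size = (fragments["size"] >= smin) & (fragments["size"] <= smax)
    frag = fragments.loc[ok_size]
    for chrom, fr in frag.groupby("chrom", sort=False):
        anc = anchors[anchors["chrom"] == chrom]
        if anc.empty:
            continue
        mids = fr["midpoint"].to_numpy()
        sizes = fr["size"].to_numpy()
        for pos, strand in zip(anc["pos"].to_numpy(), anc["strand"].to_numpy()):
            off = mids - pos if strand == "+" else pos - mids
            inside = np.abs(off) <= flank
            np.add.at(mat, (sizes[inside] - smin, off[inside] + flank), 1.0)
    vp = Vplot(mat, size_range, flank, len(anchors))
    if mat.sum() == 0:
        warnings.warn("no fragments fell in the Vplot window", stacklevel=2)
    return vp


def subtract_vplots(a: Vplot, b: Vplot) -> Vplot:
    """Elementwise a - b with negatives zeroed; both must be density-normalized."""
    if a.matrix.shape != b.matrix.shape:
        raise ValueError("Vplot shape mismatch")
    if a.normalization != "density" or b.normalization != "density":
        raise ValueError("subtract_vplots expects density-normalized Vplots")
    return replace(a, matrix=np.maximum(a.matrix - b.matrix, 0.0), n_anchors=0)


def vplot_flatten_test(a: Vplot, b: Vplot) -> TestResult:
    """Paired t-test on the offset-wise column sums of the two Vplots."""
    if a.matrix.shape != b.matrix.shape:
        raise ValueError("Vplot shape mismatch")
    return paired_t(a.column_sums(), b.column_sums())


def mononucleosome_band_test(
    a: Vplot, b: Vplot, band: tuple[int, int] = MONO_BAND
) -> TestResult:
    """Wilcoxon signed-rank on column sums restricted to the
    mononucleosome-size band."""
    if a.matrix.shape != b.matrix.shape:
        raise ValueError("Vplot shape mismatch")
    lo = max(band[0], a.size_range[0]) - a.size_range[0]
    hi = min(band[1], a.size_range[1]) - a.size_range[0]
    if hi < lo:
        raise ValueError("empty mononucleosome band")
    ca = a.matrix[lo:hi + 1].sum(axis=0)
    cb = b.matrix[lo:hi + 1].sum(axis=0)
    return wilcoxon_rank(ca, cb, paired=True)


@dataclass(frozen=True)
class DyadCall:
    gene_id: str
    position: int  # genomic bp
    offset_from_tss: int  # strand-oriented bp
    occupancy: float
    fuzziness: float  # bp, SD of supporting midpoints
    n_fragments: int


def call_dyads(
    fragments: pd.DataFrame,
    genes: Sequence[GeneModel],
    search_downstream: int = 250,
    mono_size: tuple[int, int] = MONO_SIZE_RANGE,
    kernel_bw: float = 20.0,
    min_fragments: int = 5,
    min_separation: int = 100,
) -> list[DyadCall]:
    """Kernel-density dyad calls in strand-oriented TSS->+downstream windows.

    Mononucleosome-sized fragment midpoints are smoothed with a Gaussian
    kernel (SD ``kernel_bw`` bp); each sufficiently separated local maximum
    with >= ``min_fragments`` supporting midpoints within +/-75 bp is a dyad.
    Occupancy is the density at the maximum; fuzziness the SD of supporting
    midpoints.  A deliberately simple positional estimator standing in for a
    full ATAC nucleosome-occupancy decomposition; externally produced dyad
    BED files can be supplied downstream instead (read_dyad_bed).
    """
    if "size" not in fragments.columns:
        fragments = annotate_fragments(fragments)
    mono = fragments[
        (fragments["size"] >= mono_size[0]) & (fragments["size"] <= mono_size[1])
    ]
    calls: list[DyadCall] = []
    uncallable = 0
    for g in genes:
        if g.strand == "+":
            lo, hi = g.tss, g.tss + search_downstream
        else:
            lo, hi = g.tss - search_downstream, g.tss
        m = mono[(mono["chrom"] == g.chrom)
                 & (mono["midpoint"] >= lo) & (mono["midpoint"] < hi)]
        mids = m["midpoint"].to_numpy(float)
        if len(mids) < min_fragments:
            uncallable += 1
            continue
        grid = np.arange(lo, hi)
        dens = np.exp(-0.5 * ((grid[:, None] - mids[None, :]) / kernel_bw) ** 2)
        dens = dens.sum(axis=1) / (len(mids) * kernel_bw * np.sqrt(2 * np.pi))
        peaks, _ = find_peaks(dens, distance=min_separation)
        if len(peaks) == 0:
            peaks = np.array([int(np.argmax(dens))])
        for pk in peaks:
            pos = int(grid[pk])
            support = mids[np.abs(mids - pos) <= 75]
            if len(support) < min_fragments:
                continue
            fuzz = float(np.sqrt(np.mean((support - support.mean()) ** 2)))
            off = pos - g.tss if g.strand == "+" else g.tss - pos
            calls.append(DyadCall(g.gene_id, pos, int(off),
                                  float(dens[pk]), fuzz, len(support)))
    if uncallable:
        logger.info("call_dyads: %d regions without enough mononucleosome "
                    "fragments", uncallable)
    return calls


def read_dyad_bed(path) -> pd.DataFrame:
    """Read externally produced dyad calls (BED3+, optional occupancy and
    fuzziness as columns 4-5, matching nucleosome-position output ordering)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = df.iloc[:, :3].copy()
    out.columns = ["chrom", "start", "end"]
    out["pos"] = (out["start"] + out["end"]) // 2
    if df.shape[1] >= 4:
        out["occupancy"] = df.iloc[:, 3]
    if df.shape[1] >= 5:
        out["fuzziness"] = df.iloc[:, 4]
    return out


@dataclass(frozen=True)
class SpacingResult:
    cell_line: str
    rank: int  # 1 = +1 dyad, 2 = +2 dyad
    distances: np.ndarray  # kept strand-oriented distances, <= max_dist
    mode_distance: int


def spacing_mode(
    dyads: pd.DataFrame,
    genes: Sequence[GeneModel],
    k: int = 2,
    max_dist: int = 1000,
    cell_line: str = "",
) -> list[SpacingResult]:
    """Mode of the TSS->dyad distance histogram for the k nearest downstream
    dyads per TSS.  Distances beyond ``max_dist`` are excluded; histogram
    ties break toward the smaller distance.  ``dyads`` needs chrom and pos.
    """
    per_rank: dict[int, list[int]] = {r: [] for r in range(1, k + 1)}
    for g in genes:
        d = dyads[dyads["chrom"] == g.chrom]
        if d.empty:
            continue
        pos = d["pos"].to_numpy()
        dist = pos - g.tss if g.strand == "+" else g.tss - pos
        dist = np.sort(dist[(dist >= 0) & (dist <= max_dist)])
        for r in range(1, min(k, len(dist)) + 1):
            per_rank[r].append(int(dist[r - 1]))
    out = []
    for r in range(1, k + 1):
        vals = np.array(sorted(per_rank[r]), int)
        if len(vals) == 0:
            continue
        hist = np.bincount(vals, minlength=max_dist + 1)
        mode = int(np.argmax(hist))  # argmax takes the first (smallest) tie
        out.append(SpacingResult(cell_line, r, vals, mode))
    return out


def fuzziness_by_delta_ei(
    dyad_calls: Sequence[DyadCall],
    delta_ei: pd.DataFrame,
    n: int = 1000,
) -> tuple[np.ndarray, np.ndarray, TestResult]:
    """Fuzziness of the n lowest- vs n highest-ΔEI genes (rank-sum test).

    ``delta_ei`` needs gene_id and delta_EI columns.  When several dyads are
    called for a gene the first (+1, most TSS-proximal) is used.  n shrinks
    with a warning if fewer than 2n eligible genes exist.
    """
    fuzz: dict[str, float] = {}
    for c in sorted(dyad_calls, key=lambda c: c.offset_from_tss):
        fuzz.setdefault(c.gene_id, c.fuzziness)
    df = delta_ei[delta_ei["gene_id"].isin(fuzz)].sort_values(
        ["delta_EI", "gene_id"])
    if len(df) < 2 * n:
        n = len(df) // 2
        warnings.warn(f"fewer than 2n eligible genes; shrinking n to {n}",
                      stacklevel=2)
    if n < 1:
        raise ValueError("not enough genes with both a dyad call and a ΔEI")
    low = np.array([fuzz[g] for g in df["gene_id"].head(n)])
    high = np.array([fuzz[g] for g in df["gene_id"].tail(n)])
    return low, high, wilcoxon_rank(low, high, paired=False)
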