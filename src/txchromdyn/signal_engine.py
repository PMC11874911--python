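"""Window counting, fixed-width binning and library normalization.

The coverage substrate for the escape-index, wave and heatmap analyses.
Reads and fragments are held as pandas DataFrames with ``chrom``, ``start``,
``end`` (and optionally ``strand``) columns, 0-based half-open.

Two counting modes are provided: ``overlap`` counts reads intersecting a
window by at least one bp (coverageBed ``-counts`` semantics), ``midpoint``
assigns each read to the single window containing its midpoint.  Binning
uses midpoint assignment so each read lands in exactly one bin and mass is
conserved.  A ``depth`` density mode (mean per-base coverage) is exposed for
use-sites that average base-level depth rather than read counts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
import pandas as pd

from .genome_model import GeneModel, GenomicInterval

READ_COLUMNS = ["chrom", "start", "end"]


class Normalization(str, Enum):
    RAW = "raw_counts"
    RPM = "RPM"
    RPKM = "RPKM"


@dataclass(frozen=True)
class BinnedSignal:
    """Per-gene vector of bin values, ordered 5'->3' from the TSS."""

    gene_id: str
    bin_size: int
    values: np.ndarray
    normalization: Normalization = Normalization.RAW

    @property
    def region_len(self) -> int:
        return self.bin_size * len(self.values)


@dataclass(frozen=True)
class WindowDensity:
    gene_id: str
    window: GenomicInterval
    density: float  # reads per bp per million mapped reads


def reads_from_arrays(chrom, start, end, strand=None) -> pd.DataFrame:
    df = pd.DataFrame({"chrom": chrom, "start": start, "end": end})
    if strand is not None:
        df["strand"] = strand
    return df


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED6 intervals into the internal DataFrame layout."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = df.iloc[:, :3].copy()
    out.columns = READ_COLUMNS
    if df.shape[1] >= 6:
        out["strand"] = df.iloc[:, 5]
    return out


def write_bed(reads: pd.DataFrame, path) -> None:
    reads[READ_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def _midpoints(reads: pd.DataFrame) -> np.ndarray:
    return (reads["start"].to_numpy() + reads["end"].to_numpy()) // 2


def count_in_window(
    reads: pd.DataFrame, window: GenomicInterval, mode: str = "overlap"
) -> int:
    """Number of reads in a window.

    overlap: any-overlap (>= 1 bp), the coverageBed -counts convention.
    midpoint: read midpoint (floor) inside the half-open window.
    """
    on_chrom = reads["chrom"].to_numpy() == window.chrom
    s = reads["start"].to_numpy()
    e = reads["end"].to_numpy()
    if mode == "overlap":
        hit = on_chrom & (s < window.end) & (e > window.start)
    elif mode == "midpoint":
        mid = (s + e) // 2
        hit = on_chrom & (mid >= window.start) & (mid < window.end)
    else:
        raise ValueError(f"unknown counting mode {mode!r}")
    return int(hit.sum())


class ReadIndex:
    """Per-chromosome sorted read coordinates for O(log n) overlap counts.

    Counts any-overlap reads in [ws, we) as #(start < we) - #(end <= ws):
    every read ending at or before the window start also starts before the
    window end, so the difference is exactly the overlap count.
    """

    def __init__(self, reads: pd.DataFrame):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self.n_reads = len(reads)
        for chrom, grp in reads.groupby("chrom", sort=False):
            self._by_chrom[str(chrom)] = (
                np.sort(grp["start"].to_numpy()),
                np.sort(grp["end"].to_numpy()),
            )

    def count(self, chrom: str, start: int, end: int) -> int:
        if chrom not in self._by_chrom:
            return 0
        starts, ends = self._by_chrom[chrom]
        return int(np.searchsorted(starts, end, side="left")
                   - np.searchsorted(ends, start, side="right"))


def depth_in_window(reads: pd.DataFrame, window: GenomicInterval) -> int:
    """Total covered bases (sum over reads of overlap length) in the window."""
    on = reads["chrom"].to_numpy() == window.chrom
    s = np.maximum(reads["start"].to_numpy()[on], window.start)
    e = np.minimum(reads["end"].to_numpy()[on], window.end)
    return int(np.maximum(e - s, 0).sum())


def bin_gene_signal(
    reads: pd.DataFrame, gene: GeneModel, region_len: int, bin_size: int
) -> BinnedSignal:
    """Bin read midpoints over the first ``region_len`` bp of the gene.

    Bins run 5'->3' from the TSS regardless of strand: bin i covers
    strand-oriented offsets [i*bin_size, (i+1)*bin_size).  For a minus-strand
    gene the offset of a midpoint m is tss - 1 - m (the first transcribed
    base, BED end - 1, has offset 0).
    """
    if gene.length < region_len:
        raise ValueError(
            f"gene {gene.gene_id} below length threshold "
            f"({gene.length} < {region_len})"
        )
    if region_len % bin_size:
        raise ValueError("region_len must be divisible by bin_size")
    on = reads["chrom"].to_numpy() == gene.chrom
    mid = _midpoints(reads)[on]
    if gene.strand == "+":
        off = mid - gene.tss
    else:
        off = gene.tss - 1 - mid
    n_bins = region_len // bin_size
    inside = (off >= 0) & (off < region_len)
    counts = np.bincount(off[inside] // bin_size, minlength=n_bins)
    return BinnedSignal(gene.gene_id, bin_size, counts.astype(float))


def normalize_rpkm(sig: BinnedSignal, library_size: int) -> BinnedSignal:
    """Reads per kilobase of bin per million mapped reads."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if sig.normalization is not Normalization.RAW:
        raise ValueError("RPKM expects raw counts")
    scale = (sig.bin_size / 1000.0) * (library_size / 1e6)
    return replace(sig, values=sig.values / scale, normalization=Normalization.RPKM)


def window_density_rpm(
    reads: pd.DataFrame,
    window: GenomicInterval,
    library_size: int,
    gene_id: str = "",
    mode: str = "count",
) -> WindowDensity:
    """Average coverage in the window, in reads per bp per million reads.

    ``count`` mode uses the number of overlapping reads; ``depth`` mode the
    mean per-base coverage (covered bases / window length).
    """
    length = window.end - window.start
    if length <= 0:
        raise ValueError("zero-length window")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if mode == "count":
        num = count_in_window(reads, window, mode="overlap")
    elif mode == "depth":
        num = depth_in_window(reads, window)
    else:
        raise ValueError(f"unknown density mode {mode!r}")
    return WindowDensity(gene_id, window, num / length * 1e6 / library_size)


def bin_matrix(
    reads: pd.DataFrame,
    genes,
    region_len: int,
    bin_size: int,
) -> pd.DataFrame:
    """Gene x bin raw-count matrix (rows: gene_id) over eligible genes."""
    rows = {}
    for g in genes:
        if g.length >= region_len:
            rows[g.gene_id] = bin_gene_signal(reads, g, region_len, bin_size).values
    return pd.DataFrame.from_dict(rows, orient="index", dtype=float)
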