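"""Gene universe construction and peak region assignment.

Builds the filtered gene set every downstream metric is anchored on:
transcripts are collapsed by TSS proximity, short genes are dropped, and
genes whose promoter signal would be confounded by a neighboring TSS are
excluded.  Peaks are assigned to TSS / intragenic / TTS / intergenic
categories relative to that gene set.

Coordinates are 0-based half-open (BED convention) throughout.  For a
minus-strand gene the TSS is its BED ``end`` coordinate and the TTS its
``start``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd


class RegionCategory(str, Enum):
    TSS = "TSS"
    INTRAGENIC = "Intragenic"
    TTS = "TTS"
    INTERGENIC = "Intergenic"


@dataclass(frozen=True)
class GeneModel:
    """An oriented gene; all windowed metrics are defined off its TSS/TTS."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid coordinates for {self.gene_id}: [{self.start}, {self.end})"
            )

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def oriented_window(self, upstream: int, downstream: int) -> tuple[int, int]:
        """Genomic (start, end) of the strand-oriented window
        [tss - upstream, tss + downstream) where +offsets run 5'->3'."""
        if self.strand == "+":
            return self.tss - upstream, self.tss + downstream
        return self.tss - downstream, self.tss + upstream


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


def cluster_tss(transcripts: Sequence[GeneModel], radius: int = 50) -> list[GeneModel]:
    """Collapse transcripts whose TSSs lie within ``radius`` bp of each other.

    Single-linkage clustering of TSS positions per (chrom, strand); the
    longest transcript of each cluster is kept, ties broken by smallest
    gene_id.  Idempotent for radius-separated output.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    by_group: dict[tuple[str, str], list[GeneModel]] = {}
    for t in transcripts:
        by_group.setdefault((t.chrom, t.strand), []).append(t)

    kept: list[GeneModel] = []
    for members in by_group.values():
        members.sort(key=lambda g: g.tss)
        cluster: list[GeneModel] = []
        for g in members:
            if cluster and g.tss - cluster[-1].tss > radius:
                kept.append(_cluster_representative(cluster))
                cluster = []
            cluster.append(g)
        if cluster:
            kept.append(_cluster_representative(cluster))
    kept.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return kept


def _cluster_representative(cluster: list[GeneModel]) -> GeneModel:
    # longest transcript; ties broken by lexicographically smallest gene_id
    return min(cluster, key=lambda g: (-g.length, g.gene_id))


def filter_min_length(genes: Iterable[GeneModel], min_len: int = 2000) -> list[GeneModel]:
    """Keep genes of length >= min_len (inclusive)."""
    if min_len <= 0:
        raise ValueError("min_len must be positive")
    return [g for g in genes if g.length >= min_len]


def filter_clear_signal(
    genes: Sequence[GeneModel], window_up: int = 250, window_down: int = 2000
) -> list[GeneModel]:
    """Drop genes with a neighboring TSS inside their promoter/early-body window.

    A gene is removed when any other gene's TSS falls in its strand-oriented
    window [tss - window_up, tss + window_down]; both members of an offending
    pair are removed.  Guarantees clear promoter-proximal signal for EI and
    nucleosome work.
    """
    if window_up < 0 or window_down < 0:
        raise ValueError("windows must be non-negative")
    bad: set[int] = set()
    by_chrom: dict[str, list[tuple[int, GeneModel]]] = {}
    for i, g in enumerate(genes):
        by_chrom.setdefault(g.chrom, []).append((i, g))
    for members in by_chrom.values():
        for i, a in members:
            if a.strand == "+":
                lo, hi = a.tss - window_up, a.tss + window_down
            else:
                lo, hi = a.tss - window_down, a.tss + window_up
            for j, b in members:
                if i == j:
                    continue
                if lo <= b.tss <= hi:
                    bad.add(i)
                    bad.add(j)
    return [g for i, g in enumerate(genes) if i not in bad]


def _category_footprints(gene: GeneModel, flank: int = 500):
    """(category, start, end) genomic footprints for one gene."""
    out = [
        (RegionCategory.TSS, gene.tss - flank, gene.tss + flank),
        (RegionCategory.TTS, gene.tts - flank, gene.tts + flank),
    ]
    # strand-oriented (tss+flank, tts-flank) in genomic coordinates
    if gene.strand == "+":
        body = (gene.tss + flank, gene.tts - flank)
    else:
        body = (gene.tts + flank, gene.tss - flank)
    if body[0] < body[1]:
        out.append((RegionCategory.INTRAGENIC, body[0], body[1]))
    return out


_PRIORITY = {
    RegionCategory.TSS: 0,
    RegionCategory.TTS: 1,
    RegionCategory.INTRAGENIC: 2,
    RegionCategory.INTERGENIC: 3,
}


def assign_region_category(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    flank: int = 500,
    multi: bool = False,
):
    """Assign each peak one region label (priority TSS > TTS > Intragenic >
    Intergenic), or with ``multi=True`` the set of all overlapped categories.

    Genes should already be length-filtered (>= 2 kb) so that the TSS and TTS
    flanks do not swallow the whole gene body.
    """
    by_chrom: dict[str, list] = {}
    for g in genes:
        foots = _category_footprints(g, flank)
        by_chrom.setdefault(g.chrom, []).extend(foots)

    single: dict[GenomicInterval, RegionCategory] = {}
    multi_out: dict[GenomicInterval, set[RegionCategory]] = {}
    for p in peaks:
        hit: set[RegionCategory] = set()
        for cat, s, e in by_chrom.get(p.chrom, ()):
            if p.overlaps(s, e):
                hit.add(cat)
        if not hit:
            hit = {RegionCategory.INTERGENIC}
        multi_out[p] = hit
        single[p] = min(hit, key=_PRIORITY.__getitem__)
    return multi_out if multi else single


# ---------------------------------------------------------------------------
# IO


def read_gene_table(path) -> list[GeneModel]:
    """Read genes from BED6+/BED12 or 6-column tab-delimited
    (chrom, start, end, gene_id, score, strand); extra columns ignored."""
    with open(path) as fh:
        first = fh.readline()
    header = 0 if "start" in first else None
    df = pd.read_csv(path, sep="\t", header=header, comment="#")
    df.columns = range(df.shape[1])
    if df.shape[1] < 6:
        raise ValueError("gene table needs >= 6 columns (BED6)")
    return [
        GeneModel(gene_id=str(r[3]), chrom=str(r[0]), strand=str(r[5]),
                  start=int(r[1]), end=int(r[2]))
        for r in df.itertuples(index=False)
    ]


def write_gene_table(genes: Iterable[GeneModel], path) -> None:
    df = pd.DataFrame(
        [(g.chrom, g.start, g.end, g.gene_id, 0, g.strand) for g in genes],
        columns=["chrom", "start", "end", "gene_id", "score", "strand"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_peaks(path) -> list[GenomicInterval]:
    """Read a BED3+ peak file."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return [
        GenomicInterval(str(r[0]), int(r[1]), int(r[2]))
        for r in df.itertuples(index=False)
    ]


def write_peak_labels(labels: dict, path) -> None:
    rows = []
    for p, lab in labels.items():
        if isinstance(lab, set):
            lab = ",".join(sorted(c.value for c in lab))
        else:
            lab = lab.value
        rows.append((p.chrom, p.start, p.end, lab))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "category"]).to_csv(
        path, sep="\t", index=False
    )
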