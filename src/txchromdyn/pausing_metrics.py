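"""Promoter-proximal pausing metrics and gene-activity classification.

The escape index (EI) of a gene is the read density over its early gene
body (Db, strand-oriented +100 bp to +2 kb from the TSS) divided by the
density over its promoter-proximal region (Dp, -250 bp to +100 bp).  Higher
EI means more paused polymerase released into elongation.  ΔEI compares a
treated condition against a control (treated / control); the fraction of
genes with ΔEI > 1 summarizes a genome-wide pause-release response.

Genes are classified active / repressed / inactive / ambiguous from overlap
of the extended promoter region (-250 bp .. +2 kb) with elongating-RNAPII
(Ser2P), H3K27ac and H3K27me3 peak sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .genome_model import GeneModel, GenomicInterval
from .signal_engine import ReadIndex, window_density_rpm

logger = logging.getLogger(__name__)

#: strand-oriented promoter window [tss - 250, tss + 100)
PROMOTER_WINDOW = (250, 100)
#: strand-oriented body window [tss + 100, tss + 2000)
BODY_WINDOW = (-100, 2000)
#: strand-oriented activity test region [tss - 250, tss + 2000)
ACTIVITY_WINDOW = (250, 2000)


@dataclass(frozen=True)
class EIRecord:
    gene_id: str
    Dp: float
    Db: float

    @property
    def EI(self) -> float:
        return self.Db / self.Dp


@dataclass(frozen=True)
class DeltaEIRecord:
    gene_id: str
    EI_control: float
    EI_treated: float

    @property
    def delta_EI(self) -> float:
        return self.EI_treated / self.EI_control

    @property
    def increased(self) -> bool:
        # strict: an exact tie does not count as an increase
        return self.delta_EI > 1.0


class Activity(str, Enum):
    ACTIVE = "active"
    REPRESSED = "repressed"
    INACTIVE = "inactive"
    AMBIGUOUS = "ambiguous"


def _oriented_interval(gene: GeneModel, upstream: int, downstream: int) -> GenomicInterval:
    s, e = gene.oriented_window(upstream, downstream)
    return GenomicInterval(gene.chrom, s, e)


def compute_ei(
    reads: pd.DataFrame,
    genes: Sequence[GeneModel],
    library_size: int | None = None,
    density_mode: str = "count",
) -> list[EIRecord]:
    """Per-gene escape index for one condition.

    Genes with zero promoter density are excluded (no pseudocounts) and the
    number dropped is logged.  ``density_mode`` selects read-count density
    (default) or mean per-base depth for both windows.
    """
    if library_size is None:
        library_size = len(reads)
    index = ReadIndex(reads) if density_mode == "count" else None
    out: list[EIRecord] = []
    dropped = 0
    for g in genes:
        pw = _oriented_interval(g, *PROMOTER_WINDOW)
        bw = _oriented_interval(g, *BODY_WINDOW)
        if index is not None:
            dp = (index.count(pw.chrom, pw.start, pw.end)
                  / (pw.end - pw.start) * 1e6 / library_size)
            db = (index.count(bw.chrom, bw.start, bw.end)
                  / (bw.end - bw.start) * 1e6 / library_size)
        else:
            dp = window_density_rpm(reads, pw, library_size, g.gene_id,
                                    density_mode).density
            db = window_density_rpm(reads, bw, library_size, g.gene_id,
                                    density_mode).density
        if dp == 0:
            dropped += 1
            continue
        out.append(EIRecord(g.gene_id, dp, db))
    if dropped:
        logger.info("compute_ei: dropped %d genes with zero promoter density", dropped)
    return out


def compute_delta_ei(
    control: Iterable[EIRecord], treated: Iterable[EIRecord]
) -> list[DeltaEIRecord]:
    """ΔEI = treated EI / control EI on the genes shared by both conditions."""
    ctrl = {r.gene_id: r for r in control}
    out = [
        DeltaEIRecord(r.gene_id, ctrl[r.gene_id].EI, r.EI)
        for r in treated
        if r.gene_id in ctrl
    ]
    if not out:
        raise ValueError("no shared genes between conditions")
    return out


def percent_increased(deltas: Sequence[DeltaEIRecord]) -> float:
    """Percentage of genes with strictly increased EI after treatment."""
    if not deltas:
        raise ValueError("no ΔEI records")
    return 100.0 * sum(d.increased for d in deltas) / len(deltas)


def _overlaps_any(region: GenomicInterval, peaks: Sequence[GenomicInterval]) -> bool:
    return any(
        p.chrom == region.chrom and p.overlaps(region.start, region.end)
        for p in peaks
    )


def classify_activity(
    genes: Sequence[GeneModel],
    ser2p_peaks: Sequence[GenomicInterval],
    k27ac_peaks: Sequence[GenomicInterval],
    k27me3_peaks: Sequence[GenomicInterval],
) -> dict[str, Activity]:
    """Transcriptional activity labels from peak overlap of the extended TSS.

    ambiguous: K27ac AND K27me3 (evaluated first, excluded downstream);
    active: Ser2P AND K27ac; repressed: K27me3 without Ser2P or K27ac;
    inactive: none of the three.
    """
    labels: dict[str, Activity] = {}
    for g in genes:
        region = _oriented_interval(g, *ACTIVITY_WINDOW)
        ser2p = _overlaps_any(region, ser2p_peaks)
        k27ac = _overlaps_any(region, k27ac_peaks)
        k27me3 = _overlaps_any(region, k27me3_peaks)
        if k27ac and k27me3:
            labels[g.gene_id] = Activity.AMBIGUOUS
        elif ser2p and k27ac:
            labels[g.gene_id] = Activity.ACTIVE
        elif k27me3 and not ser2p and not k27ac:
            labels[g.gene_id] = Activity.REPRESSED
        else:
            # none of the three, or partial marks no category claims
            # (Ser2P alone, K27ac alone, Ser2P+K27me3)
            labels[g.gene_id] = Activity.INACTIVE
    return labels


def common_active_set(
    labels_a: dict[str, Activity], labels_b: dict[str, Activity]
) -> set[str]:
    """Gene ids labeled active in both cell lines."""
    act_a = {g for g, l in labels_a.items() if l is Activity.ACTIVE}
    act_b = {g for g, l in labels_b.items() if l is Activity.ACTIVE}
    return act_a & act_b


def ei_table(records: Iterable[EIRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene_id, r.Dp, r.Db, r.EI) for r in records],
        columns=["gene_id", "Dp", "Db", "EI"],
    )


def delta_ei_table(records: Iterable[DeltaEIRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene_id, r.EI_control, r.EI_treated, r.delta_EI, r.increased)
         for r in records],
        columns=["gene_id", "EI_control", "EI_treated", "delta_EI", "increased"],
    )
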