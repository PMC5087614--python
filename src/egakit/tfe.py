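"""Transcript far 5'-end (TFE) construction and genomic annotation.

A TFE is a cluster of 5'-tag read start positions marking a transcription
start region.  Tags on the same chromosome and strand belong to one TFE iff a
chain of tags links them with successive gaps <= ``max_gap``.  Each TFE is
annotated to a single genomic category by the position of its modal tag (the
peak), with coding-gene 5'UTRs taking precedence — most tag clusters in 5'-end
libraries fall there, and clusters without any annotation mark putative novel
TSSs.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter
from typing import Iterable, Optional, Sequence

import numpy as np

CATEGORIES = (
    "utr5_coding",
    "coding_exon",
    "intron",
    "noncoding_gene",
    "intergenic_novel",
)


@dataclass
class TFERecord:
    id: str
    chrom: str
    start: int
    end: int
    strand: str
    peak: int
    category: Optional[str] = None
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"TFE {self.id}: start must be < end")
        if not self.start <= self.peak < self.end:
            raise ValueError(f"TFE {self.id}: peak outside [start, end)")
        if self.strand not in "+-":
            raise ValueError(f"TFE {self.id}: bad strand {self.strand!r}")
        if self.category == "utr5_coding" and self.gene_id is None:
            raise ValueError(f"TFE {self.id}: utr5_coding requires a gene_id")


@dataclass
class GeneModel:
    """A transcript model: exon blocks plus an optional coding span.

    ``exons`` are sorted, non-overlapping (start, end) intervals covering the
    transcribed parts of [tx_start, tx_end).  ``cds_start``/``cds_end`` are
    None for non-coding biotypes.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.tx_start >= self.tx_end:
            raise ValueError(f"{self.gene_id}: empty transcript span")
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty exon block")
            if s < self.tx_start or e > self.tx_end:
                raise ValueError(f"{self.gene_id}: exon outside transcript span")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exon blocks unsorted/overlapping")
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.gene_id}: half-specified coding span")
        if self.cds_start is not None:
            if self.cds_start > self.cds_end:
                raise ValueError(f"{self.gene_id}: cds_start > cds_end")
            if self.cds_start < self.tx_start or self.cds_end > self.tx_end:
                raise ValueError(f"{self.gene_id}: coding span outside transcript")

    @property
    def biotype(self) -> str:
        coding = self.cds_start is not None and self.cds_end > self.cds_start
        return "coding" if coding else "noncoding"

    def exonic(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)

    def contains(self, pos: int) -> bool:
        return self.tx_start <= pos < self.tx_end

    def in_utr5(self, pos: int) -> bool:
        """True for exonic positions 5' of the coding span (strand-aware)."""
        if self.biotype != "coding" or not self.exonic(pos):
            return False
        if self.strand == "+":
            return pos < self.cds_start
        return pos >= self.cds_end

    def in_cds(self, pos: int) -> bool:
        if self.biotype != "coding":
            return False
        return self.exonic(pos) and self.cds_start <= pos < self.cds_end


def cluster_tags(
    positions: Sequence[int],
    max_gap: int,
    chrom: str = "chr1",
    strand: str = "+",
    id_prefix: str = "TFE",
    id_offset: int = 0,
) -> list[TFERecord]:
    """Single-linkage clustering of tag start positions into TFEs.

    Two tags end up in the same TFE iff a chain of tags connects them with
    successive distances <= ``max_gap``.  TFE bounds are the min/max member
    position (half-open end), the peak is the modal position, ties broken
    toward the 5'-most position on the TFE's strand.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    pos = np.asarray(sorted(positions), dtype=np.int64)
    if len(pos) == 0:
        return []
    if pos[0] < 0:
        raise ValueError("negative tag positions")

    breaks = np.nonzero(np.diff(pos) > max_gap)[0] + 1
    records = []
    for k, chunk in enumerate(np.split(pos, breaks)):
        counts = Counter(chunk.tolist())
        top = max(counts.values())
        modal = [p for p, c in counts.items() if c == top]
        peak = min(modal) if strand == "+" else max(modal)
        records.append(
            TFERecord(
                id=f"{id_prefix}{id_offset + k + 1:06d}",
                chrom=chrom,
                start=int(chunk[0]),
                end=int(chunk[-1]) + 1,
                strand=strand,
                peak=int(peak),
            )
        )
    return records


def annotate_tfe(tfe: TFERecord, models: Iterable[GeneModel]) -> TFERecord:
    """Assign a genomic category to a TFE by its peak position.

    Same-strand overlap only, with precedence: coding-gene 5'UTR > coding exon
    > intron (of a coding gene) > any part of a non-coding gene > intergenic.
    An antisense peak inside a gene body stays intergenic_novel — antisense
    tags mark novel TSSs, not the gene on the other strand.  Returns a new
    annotated record (inputs are not mutated).
    """
    pos = tfe.peak
    best = None  # (precedence_rank, gene_id)
    for g in models:
        if g.chrom != tfe.chrom or g.strand != tfe.strand or not g.contains(pos):
            continue
        if g.biotype == "coding":
            if g.in_utr5(pos):
                rank = 0
            elif g.in_cds(pos) or g.exonic(pos):
                # exonic but outside 5'UTR (CDS or 3'UTR): exon of a coding gene
                rank = 1
            else:
                rank = 2
        else:
            rank = 3
        if best is None or rank < best[0]:
            best = (rank, g.gene_id)
    if best is None:
        category, gene_id = "intergenic_novel", None
    else:
        category = ("utr5_coding", "coding_exon", "intron", "noncoding_gene")[best[0]]
        gene_id = best[1]
    return TFERecord(tfe.id, tfe.chrom, tfe.start, tfe.end, tfe.strand, tfe.peak,
                     category=category, gene_id=gene_id)


def annotate_tfes(tfes: Iterable[TFERecord], models: Sequence[GeneModel]) -> list[TFERecord]:
    """Annotate many TFEs; models are pre-bucketed by chromosome+strand."""
    buckets: dict[tuple[str, str], list[GeneModel]] = {}
    for g in models:
        buckets.setdefault((g.chrom, g.strand), []).append(g)
    return [annotate_tfe(t, buckets.get((t.chrom, t.strand), ())) for t in tfes]


def tfe_to_gene(
    tfes: Iterable[TFERecord],
    restrict: Iterable[str] = ("utr5_coding",),
) -> set[str]:
    """Deduplicated gene ids of TFEs whose category is in ``restrict``.

    The default restriction to coding-gene 5'UTR TFEs mirrors the analysis
    focus: only clusters at annotated coding-gene starts are reduced to genes.
    """
    restrict = set(restrict)
    bad = restrict - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown categories: {sorted(bad)}")
    out = set()
    for t in tfes:
        if t.category is None:
            raise ValueError(f"TFE {t.id} is not annotated")
        if t.category in restrict and t.gene_id is not None:
            out.add(t.gene_id)
    return out
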