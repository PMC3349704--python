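"""Genomic context of candidate loci: intronic, exon-overlapping, or
intergenic.

Nearly all vertebrate snoRNA genes live inside introns of host genes and
are processed from the host pre-mRNA, so full containment in a single
intron (not mere overlap) defines "intronic" here. Interval lookups are
backed by per-contig interval trees.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .records import GeneModel, GenomicInterval, LocationCall

log = logging.getLogger(__name__)


def enumerate_introns(gene: GeneModel) -> list[GenomicInterval]:
    """Introns as gaps between consecutive exons, in ascending genomic
    order. Intron ordinals (``intron_index``) follow gene orientation, so
    for a minus-strand gene index 0 is the rightmost gap."""
    introns = []
    for left, right in zip(gene.exons, gene.exons[1:]):
        if right.start > left.end:
            introns.append(
                GenomicInterval(gene.contig, left.end, right.start, gene.strand)
            )
    return introns


def intron_ordinal(gene: GeneModel, intron_genomic_index: int) -> int:
    """Map an ascending-order intron index to its gene-orientation ordinal."""
    n = len(enumerate_introns(gene))
    if gene.strand == "+":
        return intron_genomic_index
    return n - 1 - intron_genomic_index


@dataclass
class IntronIndex:
    """Per-contig interval indexes over exons and introns of a gene set."""

    genes: dict[str, GeneModel] = field(default_factory=dict)
    _exon_trees: dict[str, IntervalTree] = field(default_factory=dict)
    _intron_trees: dict[str, IntervalTree] = field(default_factory=dict)

    @classmethod
    def build(cls, genes: Iterable[GeneModel]) -> "IntronIndex":
        index = cls()
        for gene in sorted(genes, key=lambda g: g.gene_id):
            if gene.gene_id in index.genes:
                raise ValueError(f"duplicate gene id {gene.gene_id}")
            index.genes[gene.gene_id] = gene
            etree = index._exon_trees.setdefault(gene.contig, IntervalTree())
            for exon in gene.exons:
                etree[exon.start : exon.end] = gene.gene_id
            itree = index._intron_trees.setdefault(gene.contig, IntervalTree())
            for i, intron in enumerate(enumerate_introns(gene)):
                itree[intron.start : intron.end] = (gene.gene_id, i)
        return index

    def locate(self, candidate: GenomicInterval) -> LocationCall:
        """Classify a candidate interval.

        exonic_overlap: >= 1 nt overlap with any exon. intronic: full
        containment in a single intron; with overlapping host genes the
        tightest (shortest) containing intron wins, ties by gene id.
        Everything else (including unknown contigs) is intergenic.
        """
        if candidate.contig not in self._exon_trees and (
            candidate.contig not in self._intron_trees
        ):
            if self.genes:
                log.warning("contig %s absent from annotation; calling intergenic",
                            candidate.contig)
            return LocationCall(status="intergenic")
        etree = self._exon_trees.get(candidate.contig, IntervalTree())
        if etree.overlap(candidate.start, candidate.end):
            return LocationCall(status="exonic_overlap")
        itree = self._intron_trees.get(candidate.contig, IntervalTree())
        containing = [
            iv
            for iv in itree.overlap(candidate.start, candidate.end)
            if iv.begin <= candidate.start and candidate.end <= iv.end
        ]
        if not containing:
            return LocationCall(status="intergenic")
        best = min(containing, key=lambda iv: (iv.end - iv.begin, iv.data[0]))
        gene_id, genomic_idx = best.data
        gene = self.genes[gene_id]
        return LocationCall(
            status="intronic",
            host_gene=gene_id,
            intron_index=intron_ordinal(gene, genomic_idx),
            same_strand=(candidate.strand == gene.strand),
        )


def locate(candidate: GenomicInterval, index: IntronIndex) -> LocationCall:
    return index.locate(candidate)


def transcript_evidence_overlap(
    candidate: GenomicInterval, evidence_features: Sequence[GenomicInterval]
) -> bool:
    """True iff the candidate is fully contained within at least one
    transcript-evidence feature (mRNA/EST interval)."""
    return any(feat.contains(candidate) for feat in evidence_features)
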