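"""End-to-end candidate discovery and classification over a genome.

For each C/D family in the catalog, the family reference is searched
against every contig (seeded gapped local alignment, both strands); hit
loci become candidates, overlapping loci found by several family queries
are merged keeping the best-identity family, candidates below the family
identity floor are dropped, and each survivor is located against the gene
annotation and classified.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .classifier import ClassificationResult, classify, summarize_census
from .context import IntronIndex, transcript_evidence_overlap
from .motif import CandidateLayout, scan_cd_layouts
from .params import Params
from .records import (
    FamilyProfile,
    GeneModel,
    GenomicInterval,
    SequenceRecord,
    revcomp,
)
from .search import (
    AlignmentHit,
    global_identity,
    reference_coverage_identity,
    seeded_search,
)

log = logging.getLogger(__name__)


@dataclass
class Candidate:
    candidate_id: str
    interval: GenomicInterval
    seq: str  # sense-strand sequence of the candidate locus
    family: str
    identity_pct: float  # overlap identity (terminal gaps excluded)
    coverage_identity_pct: float  # matches over full reference length
    score: int


def discover_candidates(
    genome: Sequence[SequenceRecord],
    catalog: Sequence[FamilyProfile],
    params: Params | None = None,
) -> list[Candidate]:
    """Search every family reference against every contig and merge the
    hits into non-overlapping candidate loci."""
    params = params or Params()
    raw: list[Candidate] = []
    for profile in sorted(catalog, key=lambda p: p.family):
        if profile.klass != "CD":
            continue
        query = SequenceRecord(id=profile.family, seq=profile.reference_seq)
        for contig in genome:
            for hit in seeded_search(query, contig, params):
                lo, hi = hit.subject.start, hit.subject.end
                seq = contig.seq[lo:hi]
                if hit.subject.strand == "-":
                    seq = revcomp(seq)
                ident = global_identity(seq, profile.reference_seq)
                cov = reference_coverage_identity(seq, profile.reference_seq)
                raw.append(
                    Candidate(
                        candidate_id=(
                            f"{contig.id}:{lo + 1}-{hi}({hit.subject.strand})"
                        ),
                        interval=hit.subject,
                        seq=seq,
                        family=profile.family,
                        identity_pct=ident,
                        coverage_identity_pct=cov,
                        score=hit.score,
                    )
                )
    raw = [c for c in raw if c.coverage_identity_pct >= params.min_family_identity]
    # merge overlapping loci: best identity wins, then best score
    raw.sort(key=lambda c: (-c.coverage_identity_pct, -c.score, c.candidate_id))
    kept: list[Candidate] = []
    for cand in raw:
        if not any(cand.interval.overlaps(k.interval) for k in kept):
            kept.append(cand)
    kept.sort(key=lambda c: (c.interval.contig, c.interval.start))
    return kept


def classify_candidates(
    candidates: Sequence[Candidate],
    genes: Sequence[GeneModel],
    catalog: Sequence[FamilyProfile],
    targets: Sequence[SequenceRecord],
    evidence: Sequence[GenomicInterval] = (),
    params: Params | None = None,
) -> list[tuple[Candidate, ClassificationResult]]:
    params = params or Params()
    index = IntronIndex.build(genes)
    profiles = {p.family: p for p in catalog}
    out = []
    for cand in candidates:
        profile = profiles[cand.family]
        location = index.locate(cand.interval)
        layouts = scan_cd_layouts(cand.seq, params)
        layout: Optional[CandidateLayout] = layouts[0] if layouts else None
        ev = transcript_evidence_overlap(cand.interval, evidence)
        record = SequenceRecord(id=cand.candidate_id, seq=cand.seq)
        result = classify(record, layout, location, targets, profile,
                          evidence_overlap=ev, params=params)
        out.append((cand, result))
    return out


def run_pipeline(
    genome: Sequence[SequenceRecord],
    genes: Sequence[GeneModel],
    catalog: Sequence[FamilyProfile],
    targets: Sequence[SequenceRecord],
    evidence: Sequence[GenomicInterval] = (),
    params: Params | None = None,
) -> list[dict]:
    """Discover, locate and classify; return report rows (one per candidate,
    deterministic order)."""
    params = params or Params()
    candidates = discover_candidates(genome, catalog, params)
    index = IntronIndex.build(genes)
    rows = []
    for cand, result in classify_candidates(
        candidates, genes, catalog, targets, evidence, params
    ):
        location = index.locate(cand.interval)
        rows.append(
            {
                "candidate_id": cand.candidate_id,
                "contig": cand.interval.contig,
                "start": cand.interval.start + 1,  # 1-based in reports
                "end": cand.interval.end,
                "strand": cand.interval.strand,
                "family": result.family,
                "identity_pct": round(cand.identity_pct, 1),
                "score": cand.score,
                "location": location.status,
                "host_gene": location.host_gene or "",
                "intron_index": (
                    location.intron_index
                    if location.intron_index is not None
                    else ""
                ),
                "label": result.label,
                "reasons": result.reasons,
                "notes": result.notes,
            }
        )
    return rows


def census_from_rows(rows: Sequence[dict], species_label: str) -> list[dict]:
    results = [
        ClassificationResult(
            candidate_id=r["candidate_id"],
            family=r["family"],
            label=r["label"],
            reasons=list(r["reasons"]) if not isinstance(r["reasons"], str)
            else [x for x in r["reasons"].split(";") if x],
        )
        for r in rows
    ]
    return [
        {
            "family": c.family,
            "species": c.species,
            "n_genes": c.n_genes,
            "n_pseudogenes": c.n_pseudogenes,
            "n_uncertain": c.n_uncertain,
        }
        for c in summarize_census(results, species_label)
    ]
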