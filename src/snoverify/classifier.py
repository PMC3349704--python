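"""Gene / pseudogene / uncertain classification of snoRNA candidates.

A candidate counts as a gene only when it is a full-length copy with intact
conserved regions (C, D, D' boxes within tolerance), a terminal stem, an
antisense element still able to guide the family's known modification, and
an intronic, sense-strand location in a host gene -- unless the family is
one of the few transcribed from its own promoter. Sequence-intact copies
stranded in intergenic space are "uncertain" rather than genes or
pseudogenes: without transcript evidence their independent transcription is
unsupported, but nothing in the sequence itself rules function out.

All checks run against the family reference through a global alignment, so
specific reason codes (which box is hit, which end is missing) are produced
even for copies too degraded for de novo motif scanning.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .duplex import extract_guide_region, find_duplexes, predict_methylation_site
from .motif import BoxMatch, CandidateLayout, box_consensus, hamming_to_pattern, \
    find_terminal_stem, scan_cd_layouts
from .params import Params
from .records import FamilyProfile, LocationCall, SequenceRecord
from .search import (
    global_alignment,
    global_identity,
    reference_coverage_identity,
    trim_terminal_gap_columns,
)

REASON_CODES = (
    "BOX_MUT_C",
    "BOX_MUT_D",
    "BOX_MUT_DPRIME",
    "NO_STEM",
    "ASE_DISRUPTED",
    "TRUNC_5",
    "TRUNC_3",
    "INTERGENIC",
    "EXONIC_OVERLAP",
    "ANTISENSE_STRAND",
    "NO_TRANSCRIPT_EVIDENCE",
)


@dataclass
class ClassificationResult:
    candidate_id: str
    family: str
    label: str  # gene | pseudogene | uncertain
    reasons: list[str] = field(default_factory=list)
    notes: str = ""

    def __post_init__(self):
        for r in self.reasons:
            if r not in REASON_CODES:
                raise ValueError(f"unknown reason code {r!r}")
        if (self.label == "gene") != (not self.reasons):
            raise ValueError("label 'gene' iff reasons empty")


@dataclass(frozen=True)
class CensusRow:
    family: str
    species: str
    n_genes: int
    n_pseudogenes: int
    n_uncertain: int


def assign_family(
    candidate: SequenceRecord,
    catalog: Sequence[FamilyProfile],
    params: Params | None = None,
) -> tuple[Optional[FamilyProfile], float]:
    """Best family by identity to the reference sequences; returns
    (None, best_identity) when nothing reaches ``min_family_identity``.

    Ranking and the floor use coverage identity (matches over the full
    reference length), so short spurious similarities cannot claim a
    family on overlap identity alone.
    """
    params = params or Params()
    best, best_ident = None, -1.0
    for profile in sorted(catalog, key=lambda p: p.family):
        ident = reference_coverage_identity(candidate.seq, profile.reference_seq)
        if ident > best_ident:
            best, best_ident = profile, ident
    if best is None or best_ident < params.min_family_identity:
        return None, best_ident
    return best, best_ident


def _reference_layout(profile: FamilyProfile,
                      params: Params) -> Optional[CandidateLayout]:
    layouts = scan_cd_layouts(profile.reference_seq, params)
    if not layouts:
        return None
    return min(
        layouts,
        key=lambda l: (l.c_box.mismatches + l.d_box.mismatches,
                       l.c_box.start, l.d_box.start),
    )


def _alignment_map(ref: str, cand: str) -> list[Optional[int]]:
    """ref position -> candidate position (None where ref is deleted)."""
    ga, gb = global_alignment(ref, cand)
    mapping: list[Optional[int]] = []
    ri = ci = 0
    for x, y in zip(ga, gb):
        if x != "-" and y != "-":
            mapping.append(ci)
            ri += 1
            ci += 1
        elif x != "-":
            mapping.append(None)
            ri += 1
        else:
            ci += 1
    return mapping


def classify(
    candidate: SequenceRecord,
    layout: Optional[CandidateLayout],
    location: LocationCall,
    targets: Sequence[SequenceRecord],
    profile: FamilyProfile,
    evidence_overlap: bool = False,
    params: Params | None = None,
) -> ClassificationResult:
    """Apply the gene/pseudogene criteria to one family-assigned candidate.

    ``layout`` may be None for degraded candidates; box, stem and element
    checks then run through the reference alignment alone. ``targets`` must
    contain the family's target RNA for the element check to run (families
    with no recorded target skip it).
    """
    params = params or Params()
    if profile is None:
        raise ValueError(
            "candidate has no family assignment; run assign_family first"
        )
    reasons: list[str] = []
    notes: list[str] = []
    ref = profile.reference_seq
    ref_layout = _reference_layout(profile, params)
    mapping = _alignment_map(ref, candidate.seq)

    # --- truncation: is the candidate a full-length copy? ---
    five_missing = 0
    for m in mapping:
        if m is not None:
            break
        five_missing += 1
    three_missing = 0
    for m in reversed(mapping):
        if m is not None:
            break
        three_missing += 1
    truncated = len(candidate.seq) < params.full_length_frac * len(ref)
    if truncated:
        if five_missing >= three_missing:
            reasons.append("TRUNC_5")
        if three_missing >= five_missing:
            reasons.append("TRUNC_3")

    def box_region_mapped(box: BoxMatch) -> Optional[tuple[int, int]]:
        """Candidate window covering a reference box; None when the box
        lies wholly in a terminally-missing region."""
        positions = [mapping[p] for p in range(box.start, box.end)
                     if 0 <= p < len(mapping)]
        if box.end <= five_missing or box.start >= len(ref) - three_missing:
            return None
        present = [p for p in positions if p is not None]
        if not present:
            return None
        return (min(present), max(present) + 1)

    mapped_boxes: dict[str, tuple[int, int]] = {}
    if ref_layout is not None:
        for name, box in ref_layout.boxes().items():
            code = {"C": "BOX_MUT_C", "D": "BOX_MUT_D",
                    "Dprime": "BOX_MUT_DPRIME"}.get(name)
            region = box_region_mapped(box)
            if region is not None:
                mapped_boxes[name] = region
            if code is None:
                continue
            tol = {
                "C": params.c_max_mismatch,
                "D": params.d_max_mismatch,
                "Dprime": params.dprime_max_mismatch,
            }[name]
            if region is None:
                continue  # terminal truncation already carries the reason
            # per-position check against the consensus through the alignment
            pattern = box_consensus(name if name != "Dprime" else "Dprime",
                                    params).pattern
            mism = 0
            for k, p in enumerate(range(box.start, box.end)):
                cp = mapping[p] if p < len(mapping) else None
                if cp is None:
                    mism += 1  # deleted consensus position
                else:
                    mism += hamming_to_pattern(candidate.seq[cp], pattern[k])
            if mism > tol:
                reasons.append(code)

    # --- terminal stem ---
    pseudo_layout = None
    if "C" in mapped_boxes and "D" in mapped_boxes:
        c_lo, c_hi = mapped_boxes["C"]
        d_lo, d_hi = mapped_boxes["D"]
        pseudo_layout = CandidateLayout(
            seq=candidate.seq,
            c_box=BoxMatch("C", c_lo, 0, c_hi - c_lo),
            d_box=BoxMatch("D", d_lo, 0, d_hi - d_lo),
        )
        if "Dprime" in mapped_boxes:
            dp_lo, dp_hi = mapped_boxes["Dprime"]
            if c_hi <= dp_lo and dp_hi <= d_lo:
                pseudo_layout.dprime_box = BoxMatch("Dprime", dp_lo, 0,
                                                    dp_hi - dp_lo)
        if "Cprime" in mapped_boxes:
            cp_lo, cp_hi = mapped_boxes["Cprime"]
            if c_hi <= cp_lo and cp_hi <= d_lo:
                pseudo_layout.cprime_box = BoxMatch("Cprime", cp_lo, 0,
                                                    cp_hi - cp_lo)
        stem = find_terminal_stem(pseudo_layout, params)
        if stem is None:
            reasons.append("NO_STEM")
        else:
            pseudo_layout.stem = stem
    elif not truncated:
        reasons.append("NO_STEM")

    # --- antisense element still guides the family's modification? ---
    target = next(
        (t for t in targets if t.id == profile.target_rna_id), None
    )
    if profile.target_position is not None and target is not None:
        work_layout = pseudo_layout or layout
        ok = False
        if work_layout is not None:
            for via_box in ("D", "Dprime"):
                if via_box not in work_layout.boxes():
                    continue
                lo, hi = extract_guide_region(work_layout, via_box, params)
                if hi - lo < params.min_element_len:
                    continue
                for dup in find_duplexes(candidate.seq[lo:hi], lo, [target],
                                         params):
                    pred = predict_methylation_site(work_layout, dup, via_box,
                                                    params)
                    if pred and pred.position == profile.target_position:
                        ok = True
                        break
                if ok:
                    break
        if not ok:
            reasons.append("ASE_DISRUPTED")

    sequence_intact = not reasons

    # --- genomic context ---
    if not profile.independent_promoter:
        if location.status == "exonic_overlap":
            reasons.append("EXONIC_OVERLAP")
        elif location.status == "intergenic":
            if sequence_intact:
                if evidence_overlap:
                    notes.append(
                        "intergenic but fully contained in transcript "
                        "evidence; treated as independently transcribed"
                    )
                else:
                    reasons.extend(["INTERGENIC", "NO_TRANSCRIPT_EVIDENCE"])
            else:
                reasons.append("INTERGENIC")
        elif location.status == "intronic" and location.same_strand is False:
            reasons.append("ANTISENSE_STRAND")

    if not reasons:
        label = "gene"
    elif sequence_intact and "INTERGENIC" in reasons and (
        "NO_TRANSCRIPT_EVIDENCE" in reasons
    ):
        label = "uncertain"
    else:
        label = "pseudogene"
    return ClassificationResult(
        candidate_id=candidate.id,
        family=profile.family,
        label=label,
        reasons=reasons,
        notes="; ".join(notes),
    )


def summarize_census(
    results: Sequence[ClassificationResult], species_label: str
) -> list[CensusRow]:
    """Per-family gene / pseudogene / uncertain counts (the distinction a
    raw homolog census conflates)."""
    if not results:
        return []
    df = pd.DataFrame(
        [{"family": r.family, "label": r.label} for r in results]
    )
    rows = []
    for family, group in df.groupby("family", sort=True):
        counts = group["label"].value_counts()
        rows.append(
            CensusRow(
                family=family,
                species=species_label,
                n_genes=int(counts.get("gene", 0)),
                n_pseudogenes=int(counts.get("pseudogene", 0)),
                n_uncertain=int(counts.get("uncertain", 0)),
            )
        )
    return rows
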