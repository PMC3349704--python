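"""Antisense-element duplexes, the D/D'-box methylation rule, and claimed-
target validation.

A C/D snoRNA carries, immediately upstream of its D and/or D' box, an
antisense element of 9-20 nt complementary to a cellular RNA. In the
guide:target duplex, the target nucleotide paired with the guide position
that lies four nucleotides from the box (guide index = box start - 5, so
exactly four candidate nucleotides sit strictly between the partner and the
box) is 2'-O-methylated. The validator re-checks published claims against
this geometry and flags the recurrent error classes: elements reported as
whole inter-box spans, sites more than four nucleotides from the box, and
targets (eukaryotic 5S rRNA) that carry no 2'-O-methylation at all.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .motif import CandidateLayout
from .pairing import PairingWindow, find_pairing_windows
from .params import Params
from .records import SequenceRecord

VIOLATION_CODES = (
    "OFFSET_GT4",
    "ELEMENT_NOT_ADJACENT",
    "ELEMENT_IS_INTERBOX_SPAN",
    "TARGET_DISALLOWED",
    "SITE_UNPAIRED",
    "DUPLEX_TOO_SHORT",
)


@dataclass(frozen=True)
class DuplexHit:
    """An ungapped antiparallel guide:target pairing."""

    guide_interval: tuple[int, int]  # in the candidate sequence
    target_id: str
    target_interval: tuple[int, int]  # 0-based half-open in the target
    pairs: tuple[str, ...]  # per guide position, ascending; WC | GU
    gu_count: int

    @property
    def length(self) -> int:
        return self.guide_interval[1] - self.guide_interval[0]

    def target_partner_of(self, guide_index: int) -> int:
        """0-based target position paired with a guide position."""
        k = guide_index - self.guide_interval[0]
        if not 0 <= k < self.length:
            raise ValueError(f"guide index {guide_index} outside duplex")
        return self.target_interval[1] - 1 - k


@dataclass(frozen=True)
class TargetSitePrediction:
    target_id: str
    position: int  # 1-based in the target RNA
    modification: str  # "2primeOmethyl"
    via_box: str  # "D" | "Dprime"
    guide_partner_index: int  # 0-based in the candidate sequence


@dataclass
class TargetValidationResult:
    verdict: str  # consistent | inconsistent
    violations: list[str] = field(default_factory=list)

    def __post_init__(self):
        for v in self.violations:
            if v not in VIOLATION_CODES:
                raise ValueError(f"unknown violation code {v!r}")
        expected = "consistent" if not self.violations else "inconsistent"
        if self.verdict != expected:
            raise ValueError("verdict inconsistent with violation list")


def extract_guide_region(layout: CandidateLayout, via_box: str,
                         params: Params | None = None) -> tuple[int, int]:
    """Window of up to ``max_element_len`` nt ending immediately 5' of the
    named box, clipped at the end of the preceding box."""
    params = params or Params()
    boxes = layout.boxes()
    if via_box not in ("D", "Dprime"):
        raise ValueError(f"via_box must be D or Dprime, got {via_box!r}")
    if via_box not in boxes:
        raise ValueError(f"layout has no {via_box} box")
    box = boxes[via_box]
    if via_box == "D":
        preceding = boxes.get("Cprime") or boxes.get("Dprime") or boxes["C"]
    else:
        preceding = boxes["C"]
    start = max(box.start - params.max_element_len, preceding.end)
    return (start, box.start)


def find_duplexes(
    guide_region_seq: str,
    candidate_offset: int,
    targets: Sequence[SequenceRecord],
    params: Params | None = None,
) -> list[DuplexHit]:
    """All maximal ungapped antiparallel pairings between the guide region
    and any target, with every position WC or G-U (G-U pairs count toward
    element length), length in [min_element_len, max_element_len] and
    G-U count within budget. ``candidate_offset`` maps guide-region
    coordinates back into the candidate sequence. Sorted by (length desc,
    gu_count asc, target_id, target start)."""
    params = params or Params()
    guide = guide_region_seq.upper().replace("U", "T")
    hits: list[DuplexHit] = []
    for target in targets:
        for win in find_pairing_windows(
            guide,
            target.seq,
            min_len=params.min_element_len,
            max_len=params.max_element_len,
            max_gu=params.duplex_max_gu,
            max_mismatch=params.duplex_max_mismatch,
        ):
            hits.append(
                DuplexHit(
                    guide_interval=(
                        win.a_interval[0] + candidate_offset,
                        win.a_interval[1] + candidate_offset,
                    ),
                    target_id=target.id,
                    target_interval=win.b_interval,
                    pairs=win.pairs,
                    gu_count=win.gu_count,
                )
            )
    hits.sort(
        key=lambda h: (-h.length, h.gu_count, h.target_id, h.target_interval[0])
    )
    return hits


def guide_partner_index(layout: CandidateLayout, via_box: str) -> int:
    """Candidate position whose target partner is methylated: box start - 5
    (exactly four nucleotides strictly between it and the box)."""
    return layout.boxes()[via_box].start - 5


def predict_methylation_site(
    layout: CandidateLayout,
    duplex: DuplexHit,
    via_box: str,
    params: Params | None = None,
) -> Optional[TargetSitePrediction]:
    """Apply the four-nucleotide rule to a supporting duplex.

    Returns None when the guide partner position (box start - 5) falls
    outside the duplex, i.e. the element is not adjacent enough to the box
    to place any paired nucleotide at the rule's offset.
    """
    if via_box not in layout.boxes():
        raise ValueError(f"layout has no {via_box} box")
    g = guide_partner_index(layout, via_box)
    lo, hi = duplex.guide_interval
    if not lo <= g < hi:
        return None
    pos0 = duplex.target_partner_of(g)
    return TargetSitePrediction(
        target_id=duplex.target_id,
        position=pos0 + 1,
        modification="2primeOmethyl",
        via_box=via_box,
        guide_partner_index=g,
    )


def predict_all_sites(
    layout: CandidateLayout,
    targets: Sequence[SequenceRecord],
    params: Params | None = None,
) -> list[tuple[DuplexHit, TargetSitePrediction]]:
    """Scan both guide regions (via D and, when present, D') against the
    supplied targets and report every duplex that yields a site under the
    four-nucleotide rule."""
    params = params or Params()
    out = []
    for via_box in ("D", "Dprime"):
        if via_box not in layout.boxes():
            continue
        lo, hi = extract_guide_region(layout, via_box, params)
        if hi - lo < params.min_element_len:
            continue
        for duplex in find_duplexes(layout.seq[lo:hi], lo, targets, params):
            pred = predict_methylation_site(layout, duplex, via_box, params)
            if pred is not None:
                out.append((duplex, pred))
    return out


def validate_claimed_target(
    layout: CandidateLayout,
    claimed_element: tuple[int, int],
    claimed_target: SequenceRecord,
    claimed_site: Optional[int] = None,
    params: Params | None = None,
) -> TargetValidationResult:
    """Check a claimed antisense element / target / site against the guide
    geometry; 0-based half-open ``claimed_element`` in the candidate,
    1-based ``claimed_site`` in the target."""
    params = params or Params()
    el_lo, el_hi = claimed_element
    if not (0 <= el_lo < el_hi <= len(layout.seq)):
        raise ValueError(f"claimed element {claimed_element} outside candidate")
    if claimed_site is not None and not (1 <= claimed_site <= len(claimed_target)):
        raise ValueError(
            f"claimed site {claimed_site} outside target {claimed_target.id}"
        )
    violations: list[str] = []

    if any(tag.upper() in claimed_target.id.upper()
           for tag in params.disallowed_targets):
        violations.append("TARGET_DISALLOWED")

    boxes = layout.boxes()
    interbox_spans = []
    if "Dprime" in boxes:
        interbox_spans.append((boxes["C"].end, boxes["Dprime"].start))
    if "Cprime" in boxes:
        interbox_spans.append((boxes["Cprime"].end, boxes["D"].start))
    interbox_spans.append((boxes["C"].end, boxes["D"].start))
    if (el_lo, el_hi) in interbox_spans:
        violations.append("ELEMENT_IS_INTERBOX_SPAN")

    # duplexes the claimed element can actually form with the target
    duplexes = find_duplexes(
        layout.seq[el_lo:el_hi], el_lo, [claimed_target], params
    )
    if not duplexes:
        violations.append("DUPLEX_TOO_SHORT")
    else:
        # distance from the claimed element to the nearest D/D' box
        dists = [boxes[b].start - el_hi for b in ("D", "Dprime") if b in boxes
                 if boxes[b].start >= el_hi]
        if dists and min(dists) > 4:
            violations.append("ELEMENT_NOT_ADJACENT")
        if claimed_site is not None:
            site0 = claimed_site - 1
            supporting = [
                d for d in duplexes
                if d.target_interval[0] <= site0 < d.target_interval[1]
            ]
            if not supporting:
                violations.append("SITE_UNPAIRED")
            else:
                # best supporting duplex: the one whose guide partner of the
                # claimed site lands closest to a D/D' box
                def offset_of(d: DuplexHit) -> int:
                    k = d.target_interval[1] - 1 - site0
                    g = d.guide_interval[0] + k
                    offs = [
                        boxes[b].start - 1 - g
                        for b in ("D", "Dprime")
                        if b in boxes and boxes[b].start - 1 - g >= 0
                    ]
                    return min(offs) if offs else 10**9

                if min(offset_of(d) for d in supporting) > 4:
                    violations.append("OFFSET_GT4")

    verdict = "consistent" if not violations else "inconsistent"
    return TargetValidationResult(verdict=verdict, violations=violations)
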