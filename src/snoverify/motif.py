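"""Degenerate-consensus box detection and C/D / H/ACA candidate layouts.

The conserved boxes are short IUPAC consensus motifs: C = UGAUGA and
D = CUGA near the snoRNA termini, with their (often imperfect) internal
copies C' and D'; H/ACA snoRNAs carry H = ANANNA between two hairpins and
an ACA triplet near the 3' end. Detection is a Hamming scan against the
consensus with a configurable mismatch budget per box, plus a deterministic
terminal-stem finder for the short inverted repeats that bring the C and D
boxes together.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .pairing import find_pairing_windows
from .params import Params
from .records import revcomp

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# consensus patterns, DNA alphabet (U -> T)
BOX_PATTERNS = {
    "C": "TGATGA",
    "D": "CTGA",
    "Cprime": "TGATGA",
    "Dprime": "CTGA",
    "H": "ANANNA",
    "ACA": "ACA",
}


@dataclass(frozen=True)
class BoxConsensus:
    name: str
    pattern: str
    max_mismatch: int

    def __post_init__(self):
        if not self.pattern:
            raise ValueError("empty consensus pattern")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        bad = set(self.pattern.upper().replace("U", "T")) - set(_IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC letters in pattern: {sorted(bad)}")


def box_consensus(name: str, params: Params) -> BoxConsensus:
    tol = {
        "C": params.c_max_mismatch,
        "D": params.d_max_mismatch,
        "Cprime": params.cprime_max_mismatch,
        "Dprime": params.dprime_max_mismatch,
        "H": params.h_max_mismatch,
        "ACA": params.aca_max_mismatch,
    }[name]
    return BoxConsensus(name=name, pattern=BOX_PATTERNS[name], max_mismatch=tol)


@dataclass(frozen=True)
class BoxMatch:
    box: str
    start: int  # 0-based within the candidate sequence
    mismatches: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length


def hamming_to_pattern(seq: str, pattern: str) -> int:
    """Mismatches of ``seq`` against an IUPAC ``pattern`` (N free)."""
    pattern = pattern.upper().replace("U", "T")
    if len(seq) != len(pattern):
        raise ValueError("length mismatch")
    return sum(1 for s, p in zip(seq.upper(), pattern) if s not in _IUPAC[p])


def match_box(seq: str, consensus: BoxConsensus,
              window: tuple[int, int] | None = None) -> list[BoxMatch]:
    """All placements of the consensus within ``window`` of ``seq`` whose
    Hamming distance is within the mismatch budget, sorted by
    (mismatches, start)."""
    seq = seq.upper().replace("U", "T")
    lo, hi = window if window is not None else (0, len(seq))
    if not (0 <= lo <= hi <= len(seq)):
        raise ValueError(f"window ({lo},{hi}) outside sequence of length {len(seq)}")
    pat = consensus.pattern.upper().replace("U", "T")
    m = len(pat)
    hits = []
    for start in range(lo, hi - m + 1):
        d = hamming_to_pattern(seq[start : start + m], pat)
        if d <= consensus.max_mismatch:
            hits.append(BoxMatch(box=consensus.name, start=start,
                                 mismatches=d, length=m))
    hits.sort(key=lambda h: (h.mismatches, h.start))
    return hits


@dataclass(frozen=True)
class StemMatch:
    """Terminal inverted-repeat pairing between the candidate's ends."""

    five_prime: tuple[int, int]
    three_prime: tuple[int, int]
    paired_len: int
    gu_pairs: int


@dataclass
class CandidateLayout:
    seq: str
    c_box: BoxMatch
    d_box: BoxMatch
    dprime_box: Optional[BoxMatch] = None
    cprime_box: Optional[BoxMatch] = None
    stem: Optional[StemMatch] = None

    def boxes(self) -> dict[str, BoxMatch]:
        out = {"C": self.c_box, "D": self.d_box}
        if self.dprime_box:
            out["Dprime"] = self.dprime_box
        if self.cprime_box:
            out["Cprime"] = self.cprime_box
        return out


def scan_cd_layouts(seq: str, params: Params | None = None) -> list[CandidateLayout]:
    """Enumerate C/D-box layouts of a candidate-scale sequence.

    A layout pairs a C-box hit starting within ``c_window`` nt of the 5'
    end with a D-box hit ending within ``d_window`` nt of the 3' end; the
    sequence length must lie in [min_len, max_len]. Internal D'/C' copies
    between them are attached when found (relaxed tolerances); a terminal
    stem is attached when one of at least ``stem_min_pairs`` exists. No two
    layouts share the same (C start, D start).
    """
    params = params or Params()
    seq = seq.upper().replace("U", "T")
    n = len(seq)
    if n < params.min_len or n > params.max_len:
        return []
    c_cons = box_consensus("C", params)
    d_cons = box_consensus("D", params)
    c_hits = [h for h in match_box(seq, c_cons) if h.start <= params.c_window]
    d_hits = [h for h in match_box(seq, d_cons) if n - h.end <= params.d_window]
    layouts = []
    for c in c_hits:
        for d in d_hits:
            if d.start <= c.end:
                continue
            layout = CandidateLayout(seq=seq, c_box=c, d_box=d)
            _attach_internal_boxes(layout, params)
            layout.stem = find_terminal_stem(layout, params)
            layouts.append(layout)
    layouts.sort(key=lambda l: (l.c_box.start, l.d_box.start))
    return layouts


def _attach_internal_boxes(layout: CandidateLayout, params: Params) -> None:
    """Attach the best internal C' and D' copies, preserving the canonical
    5'-C ... D' ... C' ... D-3' order (C' chosen first: fewest mismatches,
    then closest to the D box; D' then restricted upstream of it)."""
    seq = layout.seq
    interior = (layout.c_box.end, layout.d_box.start)
    if interior[1] - interior[0] < 4:
        return
    cp_hits = [
        h
        for h in match_box(seq, box_consensus("Cprime", params))
        if interior[0] <= h.start and h.end <= interior[1]
    ]
    if cp_hits:
        layout.cprime_box = min(cp_hits, key=lambda h: (h.mismatches, -h.start))
        layout.cprime_box = BoxMatch("Cprime", layout.cprime_box.start,
                                     layout.cprime_box.mismatches,
                                     layout.cprime_box.length)
    dp_limit = layout.cprime_box.start if layout.cprime_box else interior[1]
    dp_hits = [
        h
        for h in match_box(seq, box_consensus("Dprime", params))
        if interior[0] <= h.start and h.end <= dp_limit
    ]
    if dp_hits:
        best = min(dp_hits, key=lambda h: (h.mismatches, h.start))
        layout.dprime_box = BoxMatch("Dprime", best.start, best.mismatches,
                                     best.length)


def find_terminal_stem(layout: CandidateLayout,
                       params: Params | None = None) -> Optional[StemMatch]:
    """Longest ungapped complementary pairing (WC + limited G-U) between a
    window of ``stem_search`` nt before the C box and after the D box.

    Ties break toward the outermost (most terminal) pairing. Returns None
    when no pairing reaches ``stem_min_pairs``.
    """
    params = params or Params()
    seq = layout.seq
    five_lo = max(0, layout.c_box.start - params.stem_search)
    five = seq[five_lo : layout.c_box.start]
    three_lo = layout.d_box.end
    three = seq[three_lo : three_lo + params.stem_search]
    if not five or not three:
        return None
    windows = find_pairing_windows(
        five, three, min_len=params.stem_min_pairs,
        max_len=max(len(five), len(three)), max_gu=params.stem_max_gu,
    )
    if not windows:
        return None
    # longest; ties -> most terminal (smallest 5' start, then largest 3' end)
    best = min(
        windows,
        key=lambda w: (-w.length, w.a_interval[0] + five_lo,
                       -(w.b_interval[1] + three_lo)),
    )
    return StemMatch(
        five_prime=(best.a_interval[0] + five_lo, best.a_interval[1] + five_lo),
        three_prime=(best.b_interval[0] + three_lo, best.b_interval[1] + three_lo),
        paired_len=best.length,
        gu_pairs=best.gu_count,
    )


def scan_haca_layouts(seq: str,
                      params: Params | None = None) -> list[tuple[BoxMatch, BoxMatch]]:
    """H/ACA layouts: an H-box (ANANNA) hit in the interior third of the
    sequence paired with an ACA hit ending exactly ``aca_offset`` nt from
    the 3' end. Hairpin structure is not verified."""
    params = params or Params()
    seq = seq.upper().replace("U", "T")
    n = len(seq)
    if n < params.haca_min_len or n > params.haca_max_len:
        return []
    aca_start = n - params.aca_offset - 3
    if aca_start < 0:
        return []
    aca_cons = box_consensus("ACA", params)
    aca_hits = [h for h in match_box(seq, aca_cons) if h.start == aca_start]
    if not aca_hits:
        return []
    h_cons = box_consensus("H", params)
    lo, hi = n // 3, (2 * n) // 3
    h_hits = [h for h in match_box(seq, h_cons) if lo <= h.start < hi]
    return [(h, aca) for h in h_hits for aca in aca_hits]
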