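"""Relaxed seeded local alignment for cross-species snoRNA homolog search.

snoRNA homologs diverge substantially between vertebrates (roughly 55-90%
identity), so the search favors sensitivity: every exact ``word_size``-mer
(default 3) seeds the two-stage extension used by word-seeded aligners.
Stage one is a cheap ungapped X-drop walk along the seed diagonal; the
best-scoring segment it finds (the HSP) anchors stage two, a banded local
Smith-Waterman (affine gaps: the first gap character costs ``gap_open``,
each further one ``gap_extend``) over the diagonals within
``xdrop / gap_extend`` of the anchor. Cells on already-reported alignment
paths are masked during later extensions, so overlapping re-discoveries of
one locus collapse while genuinely distinct copies nearby still surface
(Waterman-Eggert style). With word size 1 and an effectively unbounded
X-drop the procedure degenerates, by construction, to exhaustive local
alignment. Hits are raw-score thresholded (``min_score``); no E-value
statistics are computed -- each hit is meant to be inspected downstream
(box/stem/element checks), not trusted on score alone.

The host-gene-guided strategy searches host-gene introns first and falls
back to the whole genome, then re-checks the introns for extra gene copies.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from Bio import Align

from .context import enumerate_introns
from .params import Params
from .records import GeneModel, GenomicInterval, SequenceRecord, revcomp

log = logging.getLogger(__name__)

NEG_INF = float("-inf")


@dataclass
class AlignmentHit:
    query_interval: tuple[int, int]
    subject: GenomicInterval
    score: int
    identity_pct: float
    aligned_query: str
    aligned_subject: str
    stage: Optional[str] = None  # host_introns | genome | host_introns_extra


def _seed_positions(query: str, subject: str, w: int) -> Iterable[tuple[int, int]]:
    index: dict[str, list[int]] = {}
    for qp in range(len(query) - w + 1):
        index.setdefault(query[qp : qp + w], []).append(qp)
    for sp in range(len(subject) - w + 1):
        for qp in index.get(subject[sp : sp + w], ()):
            yield qp, sp


def _ungapped_score(query: str, subject: str, qp: int, sp: int,
                    params: Params) -> tuple[int, int, int]:
    """X-drop ungapped extension of a seed along its diagonal.

    Returns (best segment score, rightmost subject position walked, subject
    position where the best segment starts). The best segment (HSP) anchors
    the gapped stage, so a seed sitting in noise still hands the strong
    segment elsewhere on its diagonal to stage two.
    """
    match, mismatch, xdrop = params.match, params.mismatch, params.xdrop
    w = params.word_size
    diag = sp - qp
    # x-drop walk right from the seed end
    cur, best = 0, 0
    i, j = qp + w, sp + w
    right_end = j
    while i < len(query) and j < len(subject):
        cur += match if query[i] == subject[j] else mismatch
        best = max(best, cur)
        if cur < best - xdrop:
            break
        i += 1
        j += 1
        right_end = j
    # x-drop walk left from the seed start
    cur, best = 0, 0
    left_end = sp
    li, lj = qp - 1, sp - 1
    while li >= 0 and lj >= 0:
        cur += match if query[li] == subject[lj] else mismatch
        best = max(best, cur)
        if cur < best - xdrop:
            break
        left_end = lj
        li -= 1
        lj -= 1
    # best-scoring segment within the walked range (Kadane)
    best_score, best_start = 0, sp
    cur, cur_start = 0, left_end
    for j in range(left_end, right_end):
        q_i = j - diag
        cur += match if query[q_i] == subject[j] else mismatch
        if cur > best_score:
            best_score, best_start = cur, cur_start
        if cur < 0:
            cur, cur_start = 0, j + 1
    return best_score, right_end, best_start


def _banded_local_sw(
    query: str,
    subject: str,
    diag_lo: int,
    diag_hi: int,
    masked: set[tuple[int, int]],
    params: Params,
) -> Optional[dict]:
    """Best local alignment whose diagonals stay within [diag_lo, diag_hi].

    Affine-gap local DP (a k-gap costs gap_open + (k-1)*gap_extend) with
    substitution steps through ``masked`` cells disallowed, so previously
    reported alignment paths cannot be re-reported.
    """
    match, mismatch = params.match, params.mismatch
    go, ge = params.gap_open, params.gap_extend
    lq, ls = len(query), len(subject)
    best, bi, bj = 0.0, 0, 0
    ptr_s: dict[tuple[int, int], str] = {}  # D | E | F | O (local start)
    ptr_e: dict[tuple[int, int], str] = {}
    ptr_f: dict[tuple[int, int], str] = {}
    prev_S: dict[int, float] = {}
    prev_E: dict[int, float] = {}
    prev_F: dict[int, float] = {}
    for i in range(0, lq + 1):
        j_lo = max(0, i + diag_lo)
        j_hi = min(ls, i + diag_hi)
        if j_lo > j_hi:
            continue
        cur_S: dict[int, float] = {}
        cur_E: dict[int, float] = {}
        cur_F: dict[int, float] = {}
        for j in range(j_lo, j_hi + 1):
            if i == 0 or j == 0:
                cur_S[j] = 0.0
                cur_E[j] = NEG_INF
                cur_F[j] = NEG_INF
                ptr_s[(i, j)] = "O"
                continue
            e_open = cur_S.get(j - 1, NEG_INF) - go
            e_ext = cur_E.get(j - 1, NEG_INF) - ge
            e = max(e_open, e_ext)
            if e > NEG_INF:
                ptr_e[(i, j)] = "S" if e == e_open else "E"
            f_open = prev_S.get(j, NEG_INF) - go
            f_ext = prev_F.get(j, NEG_INF) - ge
            f = max(f_open, f_ext)
            if f > NEG_INF:
                ptr_f[(i, j)] = "S" if f == f_open else "F"
            if (i - 1, j - 1) not in masked:
                sub = match if query[i - 1] == subject[j - 1] else mismatch
                d = prev_S.get(j - 1, NEG_INF) + sub
            else:
                d = NEG_INF
            s = max(0.0, d, e, f)
            cur_S[j] = s
            cur_E[j] = e
            cur_F[j] = f
            if s == 0.0:
                ptr_s[(i, j)] = "O"
            elif s == d:
                ptr_s[(i, j)] = "D"
            elif s == e:
                ptr_s[(i, j)] = "E"
            else:
                ptr_s[(i, j)] = "F"
            if s > best or (s == best and s > 0 and (i + j < bi + bj)):
                best, bi, bj = s, i, j
        prev_S, prev_E, prev_F = cur_S, cur_E, cur_F
    if best <= 0:
        return None
    # traceback
    aa, ab = [], []
    i, j = bi, bj
    state = "S"
    while True:
        if state == "S":
            move = ptr_s[(i, j)]
            if move == "O":
                break
            if move == "D":
                aa.append(query[i - 1])
                ab.append(subject[j - 1])
                i, j = i - 1, j - 1
            else:
                state = move
        elif state == "E":
            src = ptr_e[(i, j)]
            aa.append("-")
            ab.append(subject[j - 1])
            j -= 1
            state = "S" if src == "S" else "E"
        else:
            src = ptr_f[(i, j)]
            aa.append(query[i - 1])
            ab.append("-")
            i -= 1
            state = "S" if src == "S" else "F"
    aq = "".join(reversed(aa))
    asub = "".join(reversed(ab))
    return dict(
        score=int(best),
        q_iv=(i, bi),
        s_iv=(j, bj),
        aq=aq,
        asub=asub,
    )


def _band_radius(params: Params, lq: int, ls: int) -> int:
    limit = lq + ls
    ge = max(params.gap_extend, 1)
    return min(limit, max(2, params.xdrop // ge + 2))


def _search_one_strand(query: str, subject: str, params: Params) -> list[dict]:
    w = params.word_size
    trigger = min(params.gapped_trigger, params.min_score)
    # stage 1: cheap ungapped extension of every seed; the survivors go to
    # stage two in descending HSP-score order, so strong HSPs claim their
    # footprint before weaker neighbours are considered
    triggered: list[tuple[int, int, int]] = []  # (-hsp score, anchor_s, anchor_q)
    diag_cov: dict[int, int] = {}  # diagonal -> subject end already walked
    for qp, sp in _seed_positions(query, subject, w):
        if qp > 0 and sp > 0 and query[qp - 1] == subject[sp - 1]:
            continue  # interior of a longer exact run; run-start seed covers it
        if diag_cov.get(sp - qp, -1) >= sp + w:
            continue
        ung, right_end, seg_start = _ungapped_score(query, subject, qp, sp, params)
        diag_cov[sp - qp] = right_end
        if ung >= trigger:
            triggered.append((-ung, seg_start, seg_start - (sp - qp)))
    triggered.sort()
    radius = _band_radius(params, len(query), len(subject))
    raw_hits: list[dict] = []
    covered: set[tuple[int, int]] = set()  # substitution cells of found hits
    seen_anchor: set[tuple[int, int]] = set()
    for _neg_ung, sp, qp in triggered:
        if (qp, sp) in seen_anchor or (qp, sp) in covered:
            continue
        seen_anchor.add((qp, sp))
        diag = sp - qp
        hit = _banded_local_sw(
            query, subject, diag - radius, diag + radius, covered, params
        )
        if hit is None or hit["score"] < params.min_score:
            continue
        qi, si = hit["q_iv"][0], hit["s_iv"][0]
        for ca, cb in zip(hit["aq"], hit["asub"]):
            if ca != "-" and cb != "-":
                covered.add((qi, si))
            if ca != "-":
                qi += 1
            if cb != "-":
                si += 1
        matches = sum(
            1 for x, y in zip(hit["aq"], hit["asub"]) if x == y and x != "-"
        )
        hit["identity"] = 100.0 * matches / len(hit["aq"])
        raw_hits.append(hit)
    # merge overlapping hits, keeping the higher score
    raw_hits.sort(key=lambda h: (-h["score"], h["s_iv"], h["q_iv"]))
    kept: list[dict] = []
    for h in raw_hits:
        clash = any(
            h["q_iv"][0] < k["q_iv"][1]
            and k["q_iv"][0] < h["q_iv"][1]
            and h["s_iv"][0] < k["s_iv"][1]
            and k["s_iv"][0] < h["s_iv"][1]
            for k in kept
        )
        if not clash:
            kept.append(h)
    return kept


def seeded_search(
    query: SequenceRecord,
    subject: SequenceRecord,
    params: Params | None = None,
    subject_offset: int = 0,
) -> list[AlignmentHit]:
    """Seeded gapped local search of ``query`` against ``subject`` (both
    strands unless disabled). Subject coordinates in the returned hits are
    forward-strand and shifted by ``subject_offset``."""
    params = params or Params()
    if len(query.seq) < params.word_size:
        raise ValueError("query shorter than word size")
    hits: list[AlignmentHit] = []
    strands = ["+", "-"] if params.both_strands else ["+"]
    n = len(subject.seq)
    for strand in strands:
        subj_seq = subject.seq if strand == "+" else revcomp(subject.seq)
        for h in _search_one_strand(query.seq, subj_seq, params):
            s_lo, s_hi = h["s_iv"]
            if strand == "-":
                s_lo, s_hi = n - s_hi, n - s_lo
            hits.append(
                AlignmentHit(
                    query_interval=h["q_iv"],
                    subject=GenomicInterval(
                        subject.id, s_lo + subject_offset, s_hi + subject_offset,
                        strand,
                    ),
                    score=h["score"],
                    identity_pct=round(h["identity"], 1),
                    aligned_query=h["aq"],
                    aligned_subject=h["asub"],
                )
            )
    hits.sort(key=lambda h: (-h.score, h.subject.start, h.subject.strand))
    return hits


def host_guided_search(
    query: SequenceRecord,
    genome: Sequence[SequenceRecord],
    host_annotation: Sequence[GeneModel] = (),
    host_gene_id: Optional[str] = None,
    params: Params | None = None,
) -> list[AlignmentHit]:
    """Search host-gene introns first, fall back genome-wide, then re-check
    the introns for extra gene copies."""
    params = params or Params()
    contigs = {c.id: c for c in genome}
    host = None
    if host_gene_id is not None:
        host = next((g for g in host_annotation if g.gene_id == host_gene_id), None)
        if host is None:
            log.warning("host gene %s not in annotation; searching genome-wide",
                        host_gene_id)

    def intron_hits(stage: str) -> list[AlignmentHit]:
        found = []
        if host is None or host.contig not in contigs:
            return found
        contig = contigs[host.contig]
        for intron in enumerate_introns(host):
            sub = SequenceRecord(
                id=contig.id, seq=contig.seq[intron.start : intron.end]
            )
            for hit in seeded_search(query, sub, params,
                                     subject_offset=intron.start):
                hit.stage = stage
                found.append(hit)
        return found

    hits = intron_hits("host_introns")
    if not hits:
        for contig in contigs.values():
            for hit in seeded_search(query, contig, params):
                hit.stage = "genome"
                hits.append(hit)
        for hit in intron_hits("host_introns_extra"):
            hits.append(hit)
    # dedupe across stages (intron hits re-found genome-wide)
    hits.sort(key=lambda h: (-h.score, h.subject.start))
    kept: list[AlignmentHit] = []
    for h in hits:
        if not any(
            h.subject.overlaps(k.subject) and h.subject.strand == k.subject.strand
            for k in kept
        ):
            kept.append(h)
    return kept


# ---------------------------------------------------------------------------
# global identity (Needleman-Wunsch with free end gaps)

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -2
_aligner.extend_gap_score = -2
try:
    _aligner.end_insertion_score = 0
    _aligner.end_deletion_score = 0
except AttributeError:  # older Bio.Align attribute names
    _aligner.target_end_gap_score = 0
    _aligner.query_end_gap_score = 0


def global_alignment(a: str, b: str) -> tuple[str, str]:
    """One optimal global alignment (deterministic first optimum) under
    match +1 / mismatch -1 / gap -2 with free end gaps."""
    aln = _aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def global_identity(a: SequenceRecord | str, b: SequenceRecord | str) -> float:
    """Percent identity over a global alignment, excluding terminal-gap
    columns from the denominator; internal gap columns count as
    non-matches.

    Among co-optimal alignments the aligner's first optimum is used; the
    sequences are oriented canonically (lexicographic order) first, so the
    value is symmetric in its arguments.
    """
    sa = a.seq if isinstance(a, SequenceRecord) else a
    sb = b.seq if isinstance(b, SequenceRecord) else b
    if not sa or not sb:
        raise ValueError("empty sequence")
    if sb < sa:
        sa, sb = sb, sa
    ga, gb = global_alignment(sa, sb)
    lo, hi = trim_terminal_gap_columns(ga, gb)
    if hi <= lo:
        return 0.0
    matches = sum(1 for x, y in zip(ga[lo:hi], gb[lo:hi]) if x == y and x != "-")
    return 100.0 * matches / (hi - lo)


def reference_coverage_identity(candidate: str, reference: str) -> float:
    """Matched columns over the FULL reference length (not just the aligned
    overlap), so short chance alignments score low while genuinely truncated
    copies of the reference keep credit for the part they retain."""
    if not candidate or not reference:
        raise ValueError("empty sequence")
    ga, gb = global_alignment(reference, candidate)
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    return 100.0 * matches / len(reference)


def trim_terminal_gap_columns(ga: str, gb: str) -> tuple[int, int]:
    """[lo, hi) column range after removing the maximal gap-containing runs
    at either end of a global alignment."""
    lo, hi = 0, len(ga)
    while lo < hi and (ga[lo] == "-" or gb[lo] == "-"):
        lo += 1
    while hi > lo and (ga[hi - 1] == "-" or gb[hi - 1] == "-"):
        hi -= 1
    return lo, hi
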