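import random

import pytest

from snoverify.motif import (
    BoxConsensus,
    box_consensus,
    find_terminal_stem,
    match_box,
    scan_cd_layouts,
    scan_haca_layouts,
)
from snoverify.params import Params
from snoverify.records import revcomp

from conftest import rand_dna

# independent IUPAC table for the test oracles
IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T", "N": "ACGT"}
PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "T"), ("T", "G")}


def oracle_box_scan(seq, pattern, max_mm, window=None):
    """Plain nested-loop Hamming scan, independent of the implementation."""
    seq = seq.upper().replace("U", "T")
    pattern = pattern.upper().replace("U", "T")
    lo, hi = window or (0, len(seq))
    out = []
    for start in range(lo, hi - len(pattern) + 1):
        mm = sum(
            1
            for s, p in zip(seq[start : start + len(pattern)], pattern)
            if s not in IUPAC[p]
        )
        if mm <= max_mm:
            out.append((start, mm))
    return sorted(out, key=lambda t: (t[1], t[0]))


def test_c_box_exact_match():
    cons = BoxConsensus("C", "UGAUGA", 0)
    hits = match_box("AAUGAUGAAA", cons)
    assert [(h.start, h.mismatches) for h in hits] == [(2, 0)]


def test_h_box_degenerate_positions_are_free():
    cons = BoxConsensus("H", "ANANNA", 0)
    hits = match_box("AGACUA", cons)
    assert [(h.start, h.mismatches) for h in hits] == [(0, 0)]


def test_d_box_far_from_poly_c():
    cons = BoxConsensus("D", "CUGA", 1)
    assert match_box("C" * 30, cons) == []


def test_match_box_window_out_of_range_rejected():
    cons = BoxConsensus("D", "CUGA", 0)
    with pytest.raises(ValueError):
        match_box("ACGTACGT", cons, window=(2, 50))


@pytest.mark.parametrize("seed", range(10))
@pytest.mark.parametrize("box,max_mm", [("C", 1), ("D", 0), ("H", 1)])
def test_match_box_agrees_with_exhaustive_scan(seed, box, max_mm):
    rng = random.Random(seed)
    seq = rand_dna(rng, 120)
    pattern = {"C": "TGATGA", "D": "CTGA", "H": "ANANNA"}[box]
    cons = BoxConsensus(box, pattern, max_mm)
    got = [(h.start, h.mismatches) for h in match_box(seq, cons)]
    assert got == oracle_box_scan(seq, pattern, max_mm)


def test_consensus_validation():
    with pytest.raises(ValueError):
        BoxConsensus("C", "", 0)
    with pytest.raises(ValueError):
        BoxConsensus("C", "UGAUGA", -1)
    with pytest.raises(ValueError):
        BoxConsensus("C", "UGAXGA", 0)


# ---------------------------------------------------------------------------
# C/D layout scanning


def oracle_cd_layouts(seq, params):
    """Exhaustive (C start, D start) enumeration under the same rules."""
    seq = seq.upper().replace("U", "T")
    n = len(seq)
    if not params.min_len <= n <= params.max_len:
        return []
    c_hits = oracle_box_scan(seq, "TGATGA", params.c_max_mismatch)
    d_hits = oracle_box_scan(seq, "CTGA", params.d_max_mismatch)
    out = []
    for cs, _ in c_hits:
        if cs > params.c_window:
            continue
        for ds, _ in d_hits:
            if n - (ds + 4) > params.d_window:
                continue
            if ds <= cs + 6:
                continue
            out.append((cs, ds))
    return sorted(out)


def test_generated_gene_yields_exactly_one_full_layout(one_family):
    profile, _target, layout = one_family
    layouts = scan_cd_layouts(profile.reference_seq)
    assert len(layouts) == 1
    assert layouts[0].dprime_box is not None
    assert layouts[0].cprime_box is not None
    assert layouts[0].stem is not None
    assert layouts[0].c_box.start < layouts[0].dprime_box.start
    assert layouts[0].dprime_box.start < layouts[0].cprime_box.start
    assert layouts[0].cprime_box.start < layouts[0].d_box.start


def test_sequence_without_c_box_yields_no_layout():
    assert scan_cd_layouts("AC" * 42 + "A") == []


def test_two_d_boxes_give_two_layouts():
    # two CTGA copies inside the 3' window, one C box at the 5' end
    seq = "AAA" + "TGATGA" + rand_dna(random.Random(0), 40) + "CTGATTCTGA" + "AA"
    seq = seq.replace("CTGA", "CTGA", 1)
    layouts = scan_cd_layouts(seq)
    pairings = {(l.c_box.start, l.d_box.start) for l in layouts}
    assert len({l.d_box.start for l in layouts}) >= 2
    assert len(pairings) == len(layouts)  # no duplicated (C, D) pairing


@pytest.mark.parametrize("seed", range(25))
def test_scan_matches_exhaustive_enumeration(seed):
    rng = random.Random(seed)
    n = rng.randint(50, 120)
    seq = list(rand_dna(rng, n))
    # plant motifs in half the draws so non-empty cases are exercised
    if seed % 2 == 0:
        pos_c = rng.randint(0, 8)
        seq[pos_c : pos_c + 6] = "TGATGA"
        pos_d = rng.randint(n - 12, n - 4)
        seq[pos_d : pos_d + 4] = "CTGA"
    seq = "".join(seq)
    params = Params()
    got = sorted((l.c_box.start, l.d_box.start) for l in scan_cd_layouts(seq, params))
    assert got == oracle_cd_layouts(seq, params)


def test_layout_count_monotone_in_mismatch_tolerance():
    rng = random.Random(5)
    for _ in range(10):
        seq = rand_dna(rng, 80)
        counts = [
            len(scan_cd_layouts(seq, Params(c_max_mismatch=c, d_max_mismatch=d)))
            for c, d in [(0, 0), (1, 0), (1, 1), (2, 1)]
        ]
        assert counts == sorted(counts)


def test_strand_flip_round_trip(one_family):
    profile, _t, _l = one_family
    seq = profile.reference_seq
    flipped_back = revcomp(revcomp(seq))
    a = [(l.c_box.start, l.d_box.start) for l in scan_cd_layouts(seq)]
    b = [(l.c_box.start, l.d_box.start) for l in scan_cd_layouts(flipped_back)]
    assert a == b


# ---------------------------------------------------------------------------
# terminal stem


def _layout_with_flanks(five, three, interior_len=50):
    """Candidate with given sequence immediately outside the C and D boxes.

    Random flanks can spawn extra near-miss box hits, so the layout whose
    boxes sit at the designed positions is selected explicitly.
    """
    seq = five + "TGATGA" + "A" * interior_len + "CTGA" + three
    layouts = scan_cd_layouts(seq, Params(min_len=40, max_len=200))
    wanted = [
        l for l in layouts
        if l.c_box.start == len(five)
        and l.d_box.start == len(five) + 6 + interior_len
    ]
    assert wanted, "fixture construction failed"
    return wanted[0]


def test_exact_inverted_repeat_stem():
    layout = _layout_with_flanks("ATGAGC", "GCTCAT")
    stem = find_terminal_stem(layout, Params(min_len=40, max_len=200))
    assert stem is not None
    assert stem.paired_len == 6
    assert stem.gu_pairs == 0


def test_stem_with_one_gu_pair():
    layout = _layout_with_flanks("GTGAGC", "GCTCAT")
    stem = find_terminal_stem(layout, Params(min_len=40, max_len=200))
    assert stem is not None
    assert stem.paired_len == 6
    assert stem.gu_pairs == 1


def test_no_stem_below_minimum_pairing():
    layout = _layout_with_flanks("AAAAAA", "AAAAAA")  # A:A never pairs
    assert find_terminal_stem(layout, Params(min_len=40, max_len=200)) is None


def oracle_best_stem(five, three, min_pairs, max_gu):
    """Enumerate every ungapped antiparallel pairing of the two flanks."""
    best = None
    for i in range(len(five)):
        for j in range(len(three)):
            for L in range(1, min(len(five) - i, j + 1) + 1):
                ok, gu = True, 0
                for k in range(L):
                    duo = (five[i + k], three[j - k])
                    if duo in WOBBLE:
                        gu += 1
                    elif duo not in PAIRS:
                        ok = False
                        break
                if ok and gu <= max_gu and L >= min_pairs:
                    cand = (L, -(i), j)
                    if best is None or (L, -i, j) > (best[0], -best[1], best[2]):
                        best = (L, i, j)
    return best


@pytest.mark.parametrize("seed", range(15))
def test_stem_length_matches_enumeration(seed):
    rng = random.Random(100 + seed)
    five, three = rand_dna(rng, 8), rand_dna(rng, 8)
    layout = _layout_with_flanks(five, three)
    stem = find_terminal_stem(layout, Params(min_len=40, max_len=200))
    best = oracle_best_stem(five, three, min_pairs=4, max_gu=1)
    if best is None:
        assert stem is None
    else:
        assert stem is not None
        assert stem.paired_len == best[0]


# ---------------------------------------------------------------------------
# H/ACA


def _haca_seq(rng, n=120, aca_offset=3, h_at_third=True):
    seq = list(rand_dna(rng, n))
    if h_at_third:
        pos = n // 2
        seq[pos : pos + 6] = "AGACTA"  # matches ANANNA
    start = n - aca_offset - 3
    seq[start : start + 3] = "ACA"
    return "".join(seq)


def test_haca_layout_found_at_configured_offset():
    rng = random.Random(3)
    seq = _haca_seq(rng)
    layouts = scan_haca_layouts(seq, Params(h_max_mismatch=0))
    assert layouts
    h_box, aca = layouts[0]
    assert aca.start == len(seq) - 3 - 3


def test_aca_at_terminus_rejected_when_offset_configured():
    rng = random.Random(4)
    n = 120
    seq = list(rand_dna(rng, n))
    seq[n // 2 : n // 2 + 6] = "AGACTA"
    seq[n - 3 :] = "ACA"
    # ensure no accidental ACA at the expected offset position
    seq[n - 6 : n - 3] = "GGG"
    assert scan_haca_layouts("".join(seq)) == []


def test_no_interior_h_box_means_no_layout():
    # poly-CG interior cannot match ANANNA
    n = 120
    seq = "CG" * ((n - 6) // 2) + "ACACGG"
    assert scan_haca_layouts(seq) == []
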