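import random

import pytest

from snoverify.duplex import (
    DuplexHit,
    extract_guide_region,
    find_duplexes,
    guide_partner_index,
    predict_all_sites,
    predict_methylation_site,
    validate_claimed_target,
)
from snoverify.motif import BoxMatch, CandidateLayout, scan_cd_layouts
from snoverify.params import Params
from snoverify.records import SequenceRecord, revcomp
from snoverify.simulate import SimConfig, make_snorna_gene, make_toy_catalog

from conftest import rand_dna

PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "T"), ("T", "G")}


def _layout(seq_len, c_start, d_start, dprime=None, cprime=None):
    layout = CandidateLayout(
        seq="A" * seq_len,
        c_box=BoxMatch("C", c_start, 0, 6),
        d_box=BoxMatch("D", d_start, 0, 4),
    )
    if dprime is not None:
        layout.dprime_box = BoxMatch("Dprime", dprime, 0, 4)
    if cprime is not None:
        layout.cprime_box = BoxMatch("Cprime", cprime, 0, 6)
    return layout


class TestExtractGuideRegion:
    def test_window_upstream_of_d_box(self):
        layout = _layout(90, 2, 70, cprime=39)  # C' ends at 45
        assert extract_guide_region(layout, "D") == (50, 70)

    def test_clipped_at_preceding_box(self):
        layout = _layout(90, 10, 70, dprime=30)  # C ends at 16
        assert extract_guide_region(layout, "Dprime") == (16, 30)

    def test_no_internal_boxes(self):
        layout = _layout(90, 4, 70)  # C ends at 10
        assert extract_guide_region(layout, "D") == (50, 70)

    def test_missing_box_rejected(self):
        layout = _layout(90, 4, 70)
        with pytest.raises(ValueError):
            extract_guide_region(layout, "Dprime")


def oracle_duplexes(guide, target, params):
    """Brute-force all-substring antiparallel complementarity scan."""
    found = set()
    for gi in range(len(guide)):
        for tj in range(len(target)):
            for L in range(params.min_element_len,
                           min(params.max_element_len,
                               len(guide) - gi, len(target) - tj) + 1):
                gu = 0
                ok = True
                for k in range(L):
                    duo = (guide[gi + k], target[tj + L - 1 - k])
                    if duo in WOBBLE:
                        gu += 1
                    elif duo not in PAIRS:
                        ok = False
                        break
                if ok and gu <= params.duplex_max_gu:
                    found.add((gi, gi + L, tj, tj + L))
    # keep only windows not extendable into another found/valid window
    def extendable(gi, ge, tj, te):
        for dgi, dge, dtj, dte in ((gi - 1, ge, tj, te + 1),
                                   (gi, ge + 1, tj - 1, te)):
            L = dge - dgi
            if dgi < 0 or dge > len(guide) or dtj < 0 or dte > len(target):
                continue
            if L > params.max_element_len:
                continue
            gu = 0
            ok = True
            for k in range(L):
                duo = (guide[dgi + k], target[dtj + L - 1 - k])
                if duo in WOBBLE:
                    gu += 1
                elif duo not in PAIRS:
                    ok = False
                    break
            if ok and gu <= params.duplex_max_gu:
                return True
        return False

    return sorted(
        (gi, ge, tj, te)
        for gi, ge, tj, te in found
        if not extendable(gi, ge, tj, te)
    )


class TestFindDuplexes:
    def test_exact_reverse_complement_element(self):
        rng = random.Random(1)
        tseq = rand_dna(rng, 60)
        guide = revcomp(tseq[20:32])
        hits = find_duplexes(guide, 0, [SequenceRecord(id="t", seq=tseq)])
        assert any(
            h.target_interval == (20, 32) and h.gu_count == 0 and
            all(p == "WC" for p in h.pairs)
            for h in hits
        )

    def test_gu_budget_controls_wobble_hit(self):
        window = "GGGGCCCCGGGG"
        target_seq = "A" * 10 + window + "A" * 10
        guide = revcomp(window)  # CCCCGGGGCCCC
        # target C (window index 5) -> T: its guide partner G now wobbles
        mutated = target_seq[:15] + "T" + target_seq[16:]
        target = SequenceRecord(id="t", seq=mutated)
        with_gu = find_duplexes(guide, 0, [target], Params(duplex_max_gu=1))
        assert any(h.gu_count == 1 and h.length == 12 for h in with_gu)
        no_gu = find_duplexes(guide, 0, [target], Params(duplex_max_gu=0))
        assert not any(h.length == 12 for h in no_gu)

    def test_elements_below_nine_nt_not_reported(self):
        rng = random.Random(2)
        tseq = rand_dna(rng, 60)
        guide = revcomp(tseq[20:28])  # 8 nt of perfect complementarity
        hits = find_duplexes(guide, 0, [SequenceRecord(id="t", seq=tseq)])
        assert all(h.length >= 9 for h in hits)

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_brute_force(self, seed):
        rng = random.Random(200 + seed)
        target = rand_dna(rng, 80)
        if seed % 2 == 0:  # implant complementarity so hits exist
            guide = revcomp(target[30:44])
        else:
            guide = rand_dna(rng, 16)
        params = Params()
        hits = find_duplexes(guide, 0, [SequenceRecord(id="t", seq=target)],
                             params)
        got = sorted(
            (h.guide_interval[0], h.guide_interval[1],
             h.target_interval[0], h.target_interval[1])
            for h in hits
        )
        assert got == oracle_duplexes(guide, target, params)


class TestPredictMethylationSite:
    def test_partner_read_off_antiparallel_map(self):
        # D box at 60; duplex pairs guide [48,60) with target [100,112)
        layout = _layout(80, 2, 60)
        duplex = DuplexHit(
            guide_interval=(48, 60),
            target_id="t",
            target_interval=(100, 112),
            pairs=("WC",) * 12,
            gu_count=0,
        )
        pred = predict_methylation_site(layout, duplex, "D")
        assert pred is not None
        # oracle: enumerate the antiparallel pairing map and read partner of 55
        pairing = {48 + k: 112 - 1 - k for k in range(12)}
        assert pred.position == pairing[60 - 5] + 1
        assert pred.guide_partner_index == 55

    def test_element_not_adjacent_returns_none(self):
        layout = _layout(80, 2, 60)
        duplex = DuplexHit(
            guide_interval=(40, 52),
            target_id="t",
            target_interval=(100, 112),
            pairs=("WC",) * 12,
            gu_count=0,
        )
        assert predict_methylation_site(layout, duplex, "D") is None

    def test_four_nt_offset_invariant_on_generated_genes(self, one_family):
        profile, target, layout = one_family
        for dup, pred in predict_all_sites(layout, [target]):
            box = layout.boxes()[pred.via_box]
            # exactly four candidate nucleotides strictly between partner and box
            assert box.start - pred.guide_partner_index - 1 == 4

    def test_homologous_genes_share_antisense_element(self):
        cfg = SimConfig(seed=21, n_families=1)
        catalog, targets = make_toy_catalog(cfg, random.Random(21), Params())
        profile, target = catalog[0], targets[0]
        for seed in (1, 2, 3):
            gene = make_snorna_gene(profile, target, cfg,
                                    rng=random.Random(seed))
            layout = scan_cd_layouts(gene.seq)[0]
            hits = [p.position for _, p in predict_all_sites(layout, [target])
                    if p.via_box == "D"]
            assert profile.target_position in hits


class TestValidateClaimedTarget:
    def test_claimed_5s_rrna_target_disallowed(self, one_family):
        profile, _t, layout = one_family
        fake_5s = SequenceRecord(id="5S_rRNA_human", seq="ACGT" * 30)
        res = validate_claimed_target(layout, (10, 22), fake_5s, None)
        assert "TARGET_DISALLOWED" in res.violations
        assert res.verdict == "inconsistent"

    def test_whole_interbox_span_claim_flagged(self, one_family):
        profile, target, layout = one_family
        span = (layout.cprime_box.end, layout.d_box.start)
        res = validate_claimed_target(layout, span, target, None)
        assert "ELEMENT_IS_INTERBOX_SPAN" in res.violations

    def test_site_more_than_four_nt_from_box(self):
        # element complementary to the target but 6 nt upstream of the D box
        rng = random.Random(31)
        target_seq = rand_dna(rng, 60)
        element = revcomp(target_seq[20:32])
        # fixed motif-free spacers keep the layout unambiguous
        seq = ("ATGAGC" + "TGATGA" + "AC" * 10 + element
               + "AAAAAA" + "CTGA" + "GCTCAT")
        layouts = scan_cd_layouts(seq)
        assert layouts
        layout = layouts[0]
        el_lo = 12 + 20
        res = validate_claimed_target(
            layout, (el_lo, el_lo + 12),
            SequenceRecord(id="toy_target", seq=target_seq),
            claimed_site=21,  # 1-based: pairs the element's innermost position
        )
        assert "OFFSET_GT4" in res.violations

    def test_true_claim_is_consistent(self, one_family):
        profile, target, layout = one_family
        (dup, pred), *_ = [
            x for x in predict_all_sites(layout, [target])
            if x[1].position == profile.target_position
        ]
        res = validate_claimed_target(
            layout, dup.guide_interval, target, claimed_site=pred.position
        )
        assert res.verdict == "consistent"
        assert res.violations == []

    def test_claimed_site_outside_target_rejected(self, one_family):
        _p, target, layout = one_family
        with pytest.raises(ValueError):
            validate_claimed_target(layout, (10, 22), target,
                                    claimed_site=len(target.seq) + 5)
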