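"""Seeded generator of snoRNA genes, pseudogenes, host genes and toy
genomes, with truth tables.

Generated C/D genes follow the canonical architecture: terminal inverted
repeat, C box, spacer, internal D' and C' copies, an antisense element
placed so the four-nucleotide rule points exactly at the family's target
position, the D box, and the complementary 3' arm. Pseudogenization modes
reproduce the degradation classes seen in real genomes: substitutions in
the conserved boxes, missing termini, scrambled antisense elements, and
intact retrogene copies stranded in intergenic space. Every construct is
validated against the package's own scanners before being emitted, and all
randomness flows from a single seeded stream, so fixtures are byte-stable.
"""
from __future__ import annotations

import random
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .duplex import extract_guide_region, find_duplexes, predict_methylation_site
from .io_formats import write_family_catalog, write_fasta, write_gff3
from .motif import scan_cd_layouts
from .params import Params
from .records import (
    FamilyProfile,
    GeneModel,
    GenomicInterval,
    SequenceRecord,
    revcomp,
)

PSEUDO_MODES = ("box_mut", "truncate5", "truncate3", "shuffle_element",
                "intergenic_retro")


@dataclass
class SimConfig:
    seed: int = 0
    n_families: int = 3
    n_host_genes: int = 1  # host genes per family contig (extras are decoys)
    introns_per_gene: int = 3
    intron_len: int = 400
    exon_len: int = 120
    n_gene_copies: int = 1
    n_pseudo_copies: int = 5
    pseudo_modes: tuple[str, ...] = PSEUDO_MODES
    element_len: int = 12
    target_len: int = 400
    pad: int = 250  # intergenic padding between placed features
    stem_len: int = 6
    spacer1_len: int = 8  # C .. D'
    spacer2_len: int = 6  # D' .. C'
    spacer3_len: int = 3  # C' .. antisense element (the element must not
    # fill the whole C'-D span, or a whole-span claim would be legitimate)

    def __post_init__(self):
        if not 9 <= self.element_len <= 20:
            raise ValueError("element_len must be within the 9-20 nt range")
        for m in self.pseudo_modes:
            if m not in PSEUDO_MODES:
                raise ValueError(f"unknown pseudogene mode {m!r}")


@dataclass
class TruthRecord:
    copy_id: str
    family: str
    location: Optional[GenomicInterval]
    truth_label: str  # gene | pseudogene | uncertain
    applied_mode: Optional[str] = None


@dataclass
class ToyStudy:
    catalog: list[FamilyProfile]
    targets: list[SequenceRecord]
    genome: list[SequenceRecord]
    genes: list[GeneModel]
    truth: list[TruthRecord]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "copy_id": t.copy_id,
                    "family": t.family,
                    "contig": t.location.contig if t.location else "",
                    "start": t.location.start if t.location else "",
                    "end": t.location.end if t.location else "",
                    "strand": t.location.strand if t.location else "",
                    "truth_label": t.truth_label,
                    "applied_mode": t.applied_mode or "",
                }
                for t in self.truth
            ]
        )


def _rand_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def make_snorna_gene(
    profile: FamilyProfile,
    target: SequenceRecord,
    cfg: SimConfig,
    rng: random.Random | None = None,
    params: Params | None = None,
) -> SequenceRecord:
    """Construct an intact C/D snoRNA gene for a family.

    The antisense element is the reverse complement of the target window
    chosen so the nucleotide four positions from the D box pairs exactly
    with ``profile.target_position``. The construct is re-scanned and must
    yield exactly one layout (with D', C' and a stem) whose predicted site
    equals the profile target position; spacers are resampled otherwise.
    """
    if profile.target_position is None:
        raise ValueError(f"family {profile.family} has no target position")
    params = params or Params()
    # stable per-family stream (zlib.crc32 is process-independent, unlike hash)
    rng = rng or random.Random(
        (cfg.seed * 1000003 + zlib.crc32(profile.family.encode())) & 0x7FFFFFFF
    )
    L = cfg.element_len
    t0 = profile.target_position - 5
    if t0 < 0 or t0 + L > len(target.seq):
        raise ValueError(
            f"target window [{t0},{t0 + L}) outside {target.id} "
            f"for position {profile.target_position}"
        )
    element = revcomp(target.seq[t0 : t0 + L])
    for _ in range(200):
        arm = _rand_seq(rng, cfg.stem_len)
        seq = (
            arm
            + "TGATGA"
            + _rand_seq(rng, cfg.spacer1_len)
            + "CTGA"
            + _rand_seq(rng, cfg.spacer2_len)
            + "TGATGA"
            + _rand_seq(rng, cfg.spacer3_len)
            + element
            + "CTGA"
            + revcomp(arm)
        )
        if _validate_gene(seq, target, profile.target_position, params,
                          cfg.element_len):
            return SequenceRecord(id=profile.family, seq=seq)
    raise RuntimeError(f"could not construct a valid gene for {profile.family}")


def _validate_gene(seq: str, target: SequenceRecord, target_position: int,
                   params: Params, element_len: int) -> bool:
    layouts = scan_cd_layouts(seq, params)
    if len(layouts) != 1:
        return False
    layout = layouts[0]
    if layout.dprime_box is None or layout.cprime_box is None:
        return False
    if layout.stem is None or layout.stem.paired_len < params.stem_min_pairs:
        return False
    lo, hi = extract_guide_region(layout, "D", params)
    element_interval = (layout.d_box.start - element_len, layout.d_box.start)
    for dup in find_duplexes(seq[lo:hi], lo, [target], params):
        if dup.guide_interval != element_interval:
            continue  # chance extension past the designed element: resample
        pred = predict_methylation_site(layout, dup, "D", params)
        if pred is not None and pred.position == target_position:
            return True
    return False


def _site_reproducible(seq: str, target: SequenceRecord, target_position: int,
                       params: Params) -> bool:
    for layout in scan_cd_layouts(seq, params):
        for via_box in ("D", "Dprime"):
            if via_box not in layout.boxes():
                continue
            lo, hi = extract_guide_region(layout, via_box, params)
            if hi - lo < params.min_element_len:
                continue
            for dup in find_duplexes(seq[lo:hi], lo, [target], params):
                pred = predict_methylation_site(layout, dup, via_box, params)
                if pred is not None and pred.position == target_position:
                    return True
    return False


def pseudogenize(
    gene: SequenceRecord,
    mode: str,
    rng: random.Random,
    cfg: SimConfig | None = None,
    params: Params | None = None,
    target: SequenceRecord | None = None,
    target_position: int | None = None,
    box: str | None = None,
) -> tuple[SequenceRecord, TruthRecord]:
    """Degrade an intact gene according to one pseudogenization mode.

    box_mut substitutes tolerance+1 positions in the C or D box;
    truncate5/truncate3 remove 40% of the sequence from the respective end;
    shuffle_element permutes the antisense element until it no longer
    reproduces the family target site; intergenic_retro leaves the sequence
    intact (placement does the damage). The truth label is recorded.
    """
    params = params or Params()
    cfg = cfg or SimConfig()
    if mode not in PSEUDO_MODES:
        raise ValueError(f"unknown pseudogene mode {mode!r}")
    seq = gene.seq
    label = "pseudogene"
    if mode == "box_mut":
        layout = scan_cd_layouts(seq, params)[0]
        box = box or rng.choice(["C", "D"])
        target_box = layout.boxes()[box]
        tol = params.c_max_mismatch if box == "C" else params.d_max_mismatch
        positions = rng.sample(range(target_box.start, target_box.end), tol + 1)
        chars = list(seq)
        for p in positions:
            chars[p] = rng.choice([c for c in "ACGT" if c != chars[p]])
        seq = "".join(chars)
    elif mode == "truncate5":
        cut = max(int(0.4 * len(seq)), int((1 - params.full_length_frac) * len(seq)) + 1)
        seq = seq[cut:]
    elif mode == "truncate3":
        cut = max(int(0.4 * len(seq)), int((1 - params.full_length_frac) * len(seq)) + 1)
        seq = seq[:-cut]
    elif mode == "shuffle_element":
        layout = scan_cd_layouts(seq, params)[0]
        el_lo, el_hi = layout.d_box.start - cfg.element_len, layout.d_box.start
        for _ in range(200):
            element = list(seq[el_lo:el_hi])
            rng.shuffle(element)
            trial = seq[:el_lo] + "".join(element) + seq[el_hi:]
            if len(scan_cd_layouts(trial, params)) != 1:
                continue
            if target is not None and target_position is not None:
                if _site_reproducible(trial, target, target_position, params):
                    continue
            seq = trial
            break
        else:
            raise RuntimeError("could not scramble element destructively")
    elif mode == "intergenic_retro":
        label = "uncertain"
    truth = TruthRecord(
        copy_id=f"{gene.id}_{mode}",
        family=gene.id,
        location=None,
        truth_label=label,
        applied_mode=mode,
    )
    return SequenceRecord(id=truth.copy_id, seq=seq), truth


def _has_spurious_hit(
    contig: SequenceRecord,
    catalog: Sequence[FamilyProfile],
    implant_spans: Sequence[tuple[int, int]],
    params: Params,
) -> bool:
    from .search import seeded_search  # local import: avoids cycle at import

    for profile in catalog:
        query = SequenceRecord(id=profile.family, seq=profile.reference_seq)
        for hit in seeded_search(query, contig, params):
            if not any(
                hit.subject.start < e and s < hit.subject.end
                for s, e in implant_spans
            ):
                return True
    return False


def make_toy_catalog(
    cfg: SimConfig, rng: random.Random, params: Params | None = None
) -> tuple[list[FamilyProfile], list[SequenceRecord]]:
    """Fictional SNORD-style families sharing one toy rRNA target."""
    params = params or Params()
    target = SequenceRecord(id="toy_28S_rRNA", seq=_rand_seq(rng, cfg.target_len))
    catalog = []
    spacing = max(40, (cfg.target_len - 80) // max(cfg.n_families, 1))
    for i in range(cfg.n_families):
        family = f"SNORD9{i + 51}"
        position = 40 + i * spacing
        skeleton = FamilyProfile(
            family=family,
            klass="CD",
            reference_seq="N",
            target_rna_id=target.id,
            target_position=position,
        )
        gene = make_snorna_gene(skeleton, target, cfg, rng, params)
        catalog.append(replace(skeleton, reference_seq=gene.seq))
    return catalog, [target]


def build_toy_genome(
    catalog: Sequence[FamilyProfile],
    targets: Sequence[SequenceRecord],
    cfg: SimConfig,
    params: Params | None = None,
) -> ToyStudy:
    """Place gene and pseudogene copies of each family on its own contig.

    Gene copies go into host-gene introns on the sense strand, at least
    50 nt from the intron boundaries; sequence-degraded pseudogene copies
    and intact retro copies land in intergenic space downstream of the
    host. Host genes alternate strand across families. Fully reproducible
    from cfg.seed.
    """
    if not catalog:
        raise ValueError("catalog must be non-empty")
    params = params or Params()
    # offset the stream so the genome background never replays the draws
    # that produced the catalog/target sequences
    rng = random.Random((cfg.seed * 7654321 + 987654321) & 0x7FFFFFFF)
    target_by_id = {t.id: t for t in targets}
    genome: list[SequenceRecord] = []
    genes: list[GeneModel] = []
    truth: list[TruthRecord] = []

    for fi, profile in enumerate(catalog):
        contig_name = f"chr{fi + 1}_{profile.family}"
        host_strand = "+" if fi % 2 == 0 else "-"
        gene_seq = profile.reference_seq
        target = target_by_id.get(profile.target_rna_id)

        # ---- plan coordinates ----
        n_exons = cfg.introns_per_gene + 1
        cursor = cfg.pad
        exons = []
        introns = []
        for e in range(n_exons):
            exons.append((cursor, cursor + cfg.exon_len))
            cursor += cfg.exon_len
            if e < cfg.introns_per_gene:
                introns.append((cursor, cursor + cfg.intron_len))
                cursor += cfg.intron_len
        gene_end = cursor
        implants: list[tuple[int, str, TruthRecord]] = []

        # gene copies: round-robin across introns, sense strand of the host
        per_intron: dict[int, int] = {}
        for c in range(cfg.n_gene_copies):
            intron_i = c % len(introns)
            k = per_intron.get(intron_i, 0)
            per_intron[intron_i] = k + 1
            pos = introns[intron_i][0] + 50 + k * (len(gene_seq) + 30)
            if pos + len(gene_seq) + 50 > introns[intron_i][1]:
                raise ValueError("intron_len too small to place gene copies")
            placed = gene_seq if host_strand == "+" else revcomp(gene_seq)
            rec = TruthRecord(
                copy_id=f"{profile.family}_gene{c + 1}",
                family=profile.family,
                location=GenomicInterval(contig_name, pos, pos + len(gene_seq),
                                         host_strand),
                truth_label="gene",
            )
            implants.append((pos, placed, rec))
            truth.append(rec)

        # pseudogene copies: intergenic, forward strand
        cursor = gene_end + cfg.pad
        gene_record = SequenceRecord(id=profile.family, seq=gene_seq)
        for c in range(cfg.n_pseudo_copies):
            mode = cfg.pseudo_modes[c % len(cfg.pseudo_modes)]
            copy, rec = pseudogenize(
                gene_record, mode, rng, cfg, params,
                target=target,
                target_position=profile.target_position,
            )
            rec.copy_id = f"{profile.family}_{mode}_{c + 1}"
            rec.location = GenomicInterval(
                contig_name, cursor, cursor + len(copy.seq), "+"
            )
            implants.append((cursor, copy.seq, rec))
            truth.append(rec)
            cursor += len(copy.seq) + cfg.pad

        # decoy host genes (no snoRNA content) when requested
        decoy_genes = []
        for d in range(1, cfg.n_host_genes):
            d_exons = []
            for e in range(2):
                d_exons.append((cursor, cursor + cfg.exon_len))
                cursor += cfg.exon_len + cfg.intron_len
            decoy_genes.append((f"DECOY{fi + 1}_{d}", d_exons))
        contig_len = cursor + cfg.pad

        # ---- realize the sequence ----
        # the background is resampled until no family reference aligns to it
        # above the search threshold anywhere outside the implants: the truth
        # table must be the complete list of snoRNA-similar loci
        contig_rec = None
        implant_spans = [(pos, pos + len(s)) for pos, s, _ in implants]
        for _attempt in range(100):
            background = list(_rand_seq(rng, contig_len))
            for pos, seqtext, _rec in implants:
                background[pos : pos + len(seqtext)] = list(seqtext)
            trial = SequenceRecord(id=contig_name, seq="".join(background))
            if not _has_spurious_hit(trial, catalog, implant_spans, params):
                contig_rec = trial
                break
        if contig_rec is None:
            raise RuntimeError(
                f"could not draw a clean background for {contig_name}"
            )
        genome.append(contig_rec)
        genes.append(
            GeneModel(
                gene_id=f"HOST_{profile.family}",
                contig=contig_name,
                strand=host_strand,
                exons=[GenomicInterval(contig_name, s, e, host_strand)
                       for s, e in exons],
            )
        )
        for gid, d_exons in decoy_genes:
            genes.append(
                GeneModel(
                    gene_id=gid,
                    contig=contig_name,
                    strand="+",
                    exons=[GenomicInterval(contig_name, s, e, "+")
                           for s, e in d_exons],
                )
            )
    return ToyStudy(
        catalog=list(catalog),
        targets=list(targets),
        genome=genome,
        genes=genes,
        truth=truth,
    )


def make_toy_study(cfg: SimConfig, params: Params | None = None) -> ToyStudy:
    """Catalog, targets, genome, annotation and truth in one call."""
    params = params or Params()
    rng = random.Random(cfg.seed)
    catalog, targets = make_toy_catalog(cfg, rng, params)
    return build_toy_genome(catalog, targets, cfg, params)


def write_fixture_dir(study: ToyStudy, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "genes": outdir / "genes.gff3",
        "truth": outdir / "truth.tsv",
        "targets": outdir / "targets.fa",
        "catalog": outdir / "catalog.tsv",
    }
    write_fasta(study.genome, paths["genome"])
    write_gff3(study.genes, paths["genes"])
    study.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
    write_fasta(study.targets, paths["targets"])
    write_family_catalog(study.catalog, paths["catalog"])
    return paths
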