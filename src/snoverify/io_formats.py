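"""Readers and writers for the formats the toolkit consumes and emits.

FASTA parsing goes through Bio.SeqIO; GFF3 parsing through gffutils with an
in-memory feature database. BED12 exon blocks and GFF3 writing are handled
directly (no installed library exposes them as gene models). Coordinates are
converted to the internal 0-based half-open convention on read and back to
the format's convention on write.
"""
from __future__ import annotations

import json
import logging
import tempfile
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

from .records import (
    FamilyProfile,
    GeneModel,
    GenomicInterval,
    ParseError,
    SequenceRecord,
)

log = logging.getLogger(__name__)

_FASTA_ALPHABET = set("ACGTUN")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly multi-record) FASTA file.

    U is normalized to T, case folded to upper; duplicate ids and illegal
    characters are errors (the offending line is named).
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ParseError(f"{path}: record with empty id")
        seq = str(rec.seq).upper()
        bad = set(seq) - _FASTA_ALPHABET
        if bad:
            lineno = _find_line(path, next(iter(bad)))
            raise ParseError(
                f"{path}:{lineno}: illegal character(s) {sorted(bad)} "
                f"in sequence {rec.id!r}"
            )
        if rec.id in seen:
            lineno = _find_line(path, f">{rec.id}", skip=seen[rec.id])
            raise ParseError(f"{path}:{lineno}: duplicate sequence id {rec.id!r}")
        seen[rec.id] = 1
        records.append(
            SequenceRecord(
                id=rec.id, seq=seq.replace("U", "T"), description=rec.description
            )
        )
    return records


def _find_line(path: Path, needle: str, skip: int = 0) -> int:
    seen = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if needle in line.upper() or needle in line:
            if seen >= skip:
                return lineno
            seen += 1
    return 0


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                as_rna: bool = False, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.description and rec.description != rec.id:
                header = rec.description
            fh.write(f">{header}\n")
            seq = rec.seq.replace("T", "U") if as_rna else rec.seq
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# gene models: GFF3 and BED12


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (gene/mRNA/exon features, Parent links).

    GFF3 1-based inclusive coordinates become 0-based half-open. Genes with
    multiple transcripts collapse to the transcript with the greatest summed
    exon length (ties: lexicographically smallest transcript id). Exons with
    no resolvable gene parent are skipped with a warning.
    """
    path = Path(path)
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise ParseError(f"{path}: not parseable as GFF3 ({exc})") from exc

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        if gene.end < gene.start:
            raise ParseError(f"{path}: gene {gene.id}: end < start")
        # transcripts with exons; exons parented directly on the gene form
        # an implicit single transcript
        transcripts: dict[str, list[GenomicInterval]] = {}
        for child in db.children(gene, level=1):
            if child.featuretype == "exon":
                transcripts.setdefault(f"__direct__{gene.id}", []).append(
                    _gff_interval(child)
                )
            else:
                exons = [
                    _gff_interval(e)
                    for e in db.children(child, featuretype="exon", level=1)
                ]
                if exons:
                    transcripts[child.id] = exons
        if not transcripts:
            log.warning("gene %s has no exons; skipped", gene.id)
            continue
        best_id = min(
            transcripts,
            key=lambda t: (-sum(len(e) for e in transcripts[t]), t),
        )
        genes.append(
            GeneModel(
                gene_id=gene.id,
                contig=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                exons=transcripts[best_id],
            )
        )
    n_orphans = sum(
        1
        for f in db.features_of_type("exon")
        if not list(db.parents(f))
    )
    if n_orphans:
        log.warning("%d exon feature(s) without a resolvable gene parent; skipped",
                    n_orphans)
    return genes


def _gff_interval(feature) -> GenomicInterval:
    if feature.end < feature.start:
        raise ParseError(
            f"feature {feature.id} on {feature.seqid}: end < start"
        )
    return GenomicInterval(
        contig=feature.seqid,
        start=feature.start - 1,
        end=feature.end,
        strand=feature.strand if feature.strand in "+-" else "+",
    )


def write_gff3(genes: Sequence[GeneModel], path: str | Path,
               source: str = "snoverify") -> None:
    """Write gene models as gene/mRNA/exon GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            span = g.span
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.contig}\t{source}\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            tid = f"{g.gene_id}.t1"
            fh.write(
                f"{g.contig}\t{source}\tmRNA\t{span.start + 1}\t{span.end}\t.\t"
                f"{g.strand}\t.\tID={tid};Parent={g.gene_id}\n"
            )
            for i, e in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.contig}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{g.strand}\t.\tID={tid}.exon{i};Parent={tid}\n"
                )


def read_bed12(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED12 (blocks become exons; 0-based half-open)."""
    path = Path(path)
    genes = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ParseError(f"{path}:{lineno}: expected 12 BED columns")
        contig, start, _end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
        strand = fields[5] if fields[5] in "+-" else "+"
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
        if len(sizes) != len(offsets):
            raise ParseError(f"{path}:{lineno}: blockSizes/blockStarts mismatch")
        exons = [
            GenomicInterval(contig, start + off, start + off + size, strand)
            for size, off in zip(sizes, offsets)
        ]
        genes.append(GeneModel(gene_id=name, contig=contig, strand=strand, exons=exons))
    return genes


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Dispatch on extension: .bed -> BED12, otherwise GFF3."""
    if str(path).lower().endswith((".bed", ".bed12")):
        return read_bed12(path)
    return read_gff3(path)


def read_evidence_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read transcript-evidence features (mRNA/EST) as plain intervals."""
    path = Path(path)
    if str(path).lower().endswith((".bed", ".bed12", ".bed6", ".bed3")):
        out = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) > 5 and f[5] in "+-" else "+"
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
        return out
    intervals = []
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 8:
            raise ParseError(f"{path}: malformed GFF line: {line[:60]}")
        strand = f[6] if f[6] in "+-" else "+"
        intervals.append(GenomicInterval(f[0], int(f[3]) - 1, int(f[4]), strand))
    return intervals


# ---------------------------------------------------------------------------
# catalog / claims TSVs

_CATALOG_COLS = ["family", "class", "reference_seq", "target_rna_id",
                 "target_position", "independent_promoter"]


def read_family_catalog(path: str | Path) -> list[FamilyProfile]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(_CATALOG_COLS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing catalog columns: {sorted(missing)}")
    profiles = []
    for _, row in df.iterrows():
        profiles.append(
            FamilyProfile(
                family=row["family"],
                klass=row["class"],
                reference_seq=row["reference_seq"].upper().replace("U", "T"),
                target_rna_id=row["target_rna_id"] or None,
                target_position=(
                    int(row["target_position"]) if row["target_position"] else None
                ),
                independent_promoter=row["independent_promoter"].lower()
                in ("1", "true", "yes"),
            )
        )
    return profiles


def write_family_catalog(profiles: Sequence[FamilyProfile], path: str | Path) -> None:
    rows = [
        {
            "family": p.family,
            "class": p.klass,
            "reference_seq": p.reference_seq,
            "target_rna_id": p.target_rna_id or "",
            "target_position": p.target_position if p.target_position else "",
            "independent_promoter": str(p.independent_promoter).lower(),
        }
        for p in profiles
    ]
    pd.DataFrame(rows, columns=_CATALOG_COLS).to_csv(path, sep="\t", index=False)


def read_claimed_targets(path: str | Path) -> pd.DataFrame:
    """Claimed-target table: candidate_id, element_start, element_end
    (1-based inclusive in the candidate), target_id, claimed_site (1-based,
    optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"candidate_id", "element_start", "element_end", "target_id"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing claim columns: {sorted(missing)}")
    df["element_start"] = df["element_start"].astype(int)
    df["element_end"] = df["element_end"].astype(int)
    if "claimed_site" not in df.columns:
        df["claimed_site"] = ""
    df["claimed_site"] = [int(x) if str(x).strip() else None
                          for x in df["claimed_site"]]
    return df


# ---------------------------------------------------------------------------
# result reports


def write_report(records: Sequence[dict], path: str | Path, format: str = "tsv",
                 columns: Sequence[str] | None = None) -> None:
    """Write result rows as TSV (deterministic column order) or JSON.

    List-valued fields are serialized as semicolon-joined strings in TSV and
    kept as lists in JSON, so JSON round-trips losslessly.
    """
    if format not in ("tsv", "json"):
        raise ValueError(f"unknown report format {format!r}")
    records = list(records)
    if columns is None:
        columns = []
        for rec in records:
            for key in rec:
                if key not in columns:
                    columns.append(key)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(records, fh, indent=2)
            fh.write("\n")
        return
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for rec in records:
            row = []
            for col in columns:
                val = rec.get(col, "")
                if isinstance(val, (list, tuple)):
                    val = ";".join(str(v) for v in val)
                elif val is None:
                    val = ""
                row.append(str(val))
            fh.write("\t".join(row) + "\n")


def read_report_json(path: str | Path) -> list[dict]:
    with open(path) as fh:
        return json.load(fh)
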