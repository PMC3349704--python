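"""Species-prefixed names for homologs of human snoRNAs.

Rather than coining a new name for every homolog described outside human,
a homolog keeps the human gene name (SNORD/SNORA/SCARNA scheme) with a
lowercase species prefix: first letter of the genus plus the first three
letters of the epithet, e.g. Mus musculus SNORD87 -> mmusSNORD87. When two
species collide on a four-letter prefix (Mus musculus / Microcebus
murinus), the later one extends with further epithet letters until unique;
the extension rule is this package's own convention.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass

log = logging.getLogger(__name__)

_HUMAN_GENE_RE = re.compile(r"^(SNORD|SNORA|SCARNA)\d+[A-Z]?(-\d+)?$")


@dataclass(frozen=True)
class SpeciesName:
    genus: str
    epithet: str

    def __post_init__(self):
        if not (self.genus.isalpha() and self.epithet.isalpha()):
            raise ValueError(
                f"genus/epithet must be non-empty alphabetic, got "
                f"{self.genus!r} {self.epithet!r}"
            )

    @classmethod
    def parse(cls, binomial: str) -> "SpeciesName":
        parts = binomial.replace("_", " ").split()
        if len(parts) != 2:
            raise ValueError(f"expected 'Genus epithet', got {binomial!r}")
        return cls(genus=parts[0], epithet=parts[1])


def species_prefix(name: SpeciesName | str, reserved: set[str] | None = None) -> str:
    """Lowercase 1+3 prefix (genus initial + three epithet letters),
    extended with further epithet letters on collision with ``reserved``.
    The caller adds the returned prefix to its reserved set."""
    if isinstance(name, str):
        name = SpeciesName.parse(name)
    reserved = reserved or set()
    genus = name.genus.lower()
    epithet = name.epithet.lower()
    if len(epithet) < 3:
        log.warning(
            "epithet %r shorter than 3 letters; padding from the genus",
            name.epithet,
        )
        epithet = (epithet + genus[1:])[:3]
    prefix = genus[0] + epithet[:3]
    k = 3
    while prefix in reserved:
        k += 1
        if k > len(epithet):
            # epithet exhausted: keep appending genus letters
            prefix = genus[0] + epithet + genus[1 : 1 + (k - len(epithet))]
            if len(prefix) == len(genus[0] + epithet + genus[1:]):
                raise ValueError(f"cannot derive unique prefix for {name}")
        else:
            prefix = genus[0] + epithet[:k]
    return prefix


def homolog_name(
    name: SpeciesName | str, human_gene: str, reserved: set[str] | None = None
) -> str:
    """Species prefix + the human gene name, verbatim."""
    if not human_gene:
        raise ValueError("human gene name must be non-empty")
    if not _HUMAN_GENE_RE.match(human_gene):
        log.warning(
            "%r does not look like a SNORD/SNORA/SCARNA name; "
            "concatenating anyway", human_gene,
        )
    return species_prefix(name, reserved) + human_gene
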