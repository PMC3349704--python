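"""Tunable parameters with their defaults, plus flat-key config loading.

Every threshold that the method leaves unquantified ("intact" boxes, "short"
inverted repeats) is surfaced here under a namespaced flat key so runs are
reproducible and re-thresholdable. Precedence when merging: defaults < config
file < explicit overrides (CLI flags).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

from .records import SnoverifyError


@dataclass
class Params:
    # --- box tolerances (max Hamming mismatches against IUPAC consensus) ---
    # D is the shortest, most constrained box; C tolerates the known RUGAUGA
    # variation; the internal C'/D' copies are often imperfect.
    c_max_mismatch: int = 1
    d_max_mismatch: int = 0
    cprime_max_mismatch: int = 2
    dprime_max_mismatch: int = 1
    h_max_mismatch: int = 0
    aca_max_mismatch: int = 0

    # --- C/D candidate layout geometry (nt) ---
    min_len: int = 50
    max_len: int = 120
    c_window: int = 12  # C box must start within this of the 5' end
    d_window: int = 12  # D box must end within this of the 3' end

    # --- terminal stem ---
    stem_min_pairs: int = 4
    stem_search: int = 8  # window outside each box searched for the stem
    stem_max_gu: int = 1

    # --- H/ACA layout ---
    haca_min_len: int = 100
    haca_max_len: int = 160
    aca_offset: int = 3  # nt between ACA box end and the 3' terminus

    # --- guide duplex / antisense element ---
    min_element_len: int = 9
    max_element_len: int = 20
    duplex_max_gu: int = 3
    duplex_max_mismatch: int = 0  # internal mismatches in the duplex
    # target identifiers (substring match, case-insensitive) whose claimed
    # methylation is rejected outright; eukaryotic 5S rRNA carries no
    # 2'-O-methylated nucleotides.
    disallowed_targets: tuple[str, ...] = ("5S",)

    # --- seeded homolog search ---
    word_size: int = 3
    match: int = 1
    mismatch: int = -1
    gap_open: int = 1  # cost of the first gap character
    gap_extend: int = 1
    xdrop: int = 10
    min_score: int = 16
    # ungapped-extension score that triggers gapped extension of a seed
    # (two-stage extension in the BLAST tradition; capped at min_score)
    gapped_trigger: int = 11
    both_strands: bool = True

    # --- classifier ---
    full_length_frac: float = 0.9
    # family assignment floor: matches over the FULL reference length, so a
    # short chance alignment cannot pass on overlap identity alone; 55% is
    # the low end of the identity range seen between vertebrate homologs
    min_family_identity: float = 55.0

    def copy(self, **overrides) -> "Params":
        return dataclasses.replace(self, **overrides)


# flat namespaced config keys <-> Params field names
_KEY_MAP = {
    "boxes.c_max_mismatch": "c_max_mismatch",
    "boxes.d_max_mismatch": "d_max_mismatch",
    "boxes.cprime_max_mismatch": "cprime_max_mismatch",
    "boxes.dprime_max_mismatch": "dprime_max_mismatch",
    "boxes.h_max_mismatch": "h_max_mismatch",
    "boxes.aca_max_mismatch": "aca_max_mismatch",
    "layout.min_len": "min_len",
    "layout.max_len": "max_len",
    "layout.c_window": "c_window",
    "layout.d_window": "d_window",
    "stem.min_pairs": "stem_min_pairs",
    "stem.search": "stem_search",
    "stem.max_gu": "stem_max_gu",
    "haca.min_len": "haca_min_len",
    "haca.max_len": "haca_max_len",
    "haca.aca_offset": "aca_offset",
    "duplex.min_element_len": "min_element_len",
    "duplex.max_element_len": "max_element_len",
    "duplex.max_gu": "duplex_max_gu",
    "duplex.max_mismatch": "duplex_max_mismatch",
    "duplex.disallowed_targets": "disallowed_targets",
    "search.word_size": "word_size",
    "search.match": "match",
    "search.mismatch": "mismatch",
    "search.gap_open": "gap_open",
    "search.gap_extend": "gap_extend",
    "search.xdrop": "xdrop",
    "search.min_score": "min_score",
    "search.gapped_trigger": "gapped_trigger",
    "search.both_strands": "both_strands",
    "classify.full_length_frac": "full_length_frac",
    "classify.min_family_identity": "min_family_identity",
}


def _coerce(field_name: str, raw: str):
    ftype = {f.name: f.type for f in dataclasses.fields(Params)}[field_name]
    raw = raw.strip()
    if field_name == "disallowed_targets":
        return tuple(x.strip() for x in raw.split(",") if x.strip())
    if "bool" in str(ftype):
        if raw.lower() in ("1", "true", "yes", "on"):
            return True
        if raw.lower() in ("0", "false", "no", "off"):
            return False
        raise SnoverifyError(f"cannot parse boolean from {raw!r}")
    if "float" in str(ftype):
        return float(raw)
    return int(raw)


def load_config(path: str | Path, base: Params | None = None) -> Params:
    """Load a flat ``section.key = value`` config file over ``base``.

    Unknown keys are rejected with the list of valid keys so typos never
    silently fall back to defaults.
    """
    params = base or Params()
    overrides = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line or line.startswith("["):
            continue
        if "=" not in line:
            raise SnoverifyError(f"{path}:{lineno}: expected key = value")
        key, _, raw = line.partition("=")
        key = key.strip().strip('"')
        if key not in _KEY_MAP:
            valid = ", ".join(sorted(_KEY_MAP))
            raise SnoverifyError(
                f"{path}:{lineno}: unknown config key {key!r}; valid keys: {valid}"
            )
        field_name = _KEY_MAP[key]
        overrides[field_name] = _coerce(field_name, raw.strip().strip('"'))
    return params.copy(**overrides)
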