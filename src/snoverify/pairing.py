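"""Antiparallel RNA base-pairing primitives (Watson-Crick + G-U wobble).

Sequences are held in the DNA alphabet, so the G-U wobble appears as G-T.
A duplex between segment A (read 5'->3') and segment B is ungapped and
antiparallel: A[i..i+L) pairs with B[j..j+L) such that A[i+k] pairs
B[j+L-1-k]. Runs of consecutive pairable positions therefore live on
anti-diagonals i+j' = const of the (A-position, B-position) grid.
"""
from __future__ import annotations

from dataclasses import dataclass

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}


def pair_kind(a: str, b: str) -> str | None:
    """'WC', 'GU', or None for an unpairable (or N-containing) duo."""
    if (a, b) in _WC:
        return "WC"
    if (a, b) in _GU:
        return "GU"
    return None


@dataclass(frozen=True)
class PairingWindow:
    """An ungapped antiparallel pairing between two sequence windows.

    ``a_interval`` and ``b_interval`` are 0-based half-open in their own
    sequences; ``pairs`` lists the pair kind for A positions in ascending
    order (so pairs[k] describes A[a_start+k] : B[b_end-1-k]).
    """

    a_interval: tuple[int, int]
    b_interval: tuple[int, int]
    pairs: tuple[str, ...]

    @property
    def length(self) -> int:
        return self.a_interval[1] - self.a_interval[0]

    @property
    def gu_count(self) -> int:
        return sum(1 for p in self.pairs if p == "GU")

    @property
    def mismatch_count(self) -> int:
        return sum(1 for p in self.pairs if p == "MM")

    def b_partner_of(self, a_index: int) -> int:
        """B position paired with A position ``a_index``."""
        k = a_index - self.a_interval[0]
        if not 0 <= k < self.length:
            raise ValueError(f"position {a_index} outside pairing window")
        return self.b_interval[1] - 1 - k


def find_pairing_windows(
    a: str,
    b: str,
    min_len: int,
    max_len: int,
    max_gu: int,
    max_mismatch: int = 0,
) -> list[PairingWindow]:
    """All maximal ungapped antiparallel pairings between ``a`` and ``b``.

    A window is reported when every position pairs (WC, G-U, or one of up to
    ``max_mismatch`` internal mismatches; windows never start or end on a
    mismatch), its G-U count is within ``max_gu`` and its length in
    [min_len, max_len]. Maximal means it cannot be grown by one position at
    either end without violating a constraint (other than max_len: longer
    compatible runs are reported as their maximal sliding sub-windows).
    """
    la, lb = len(a), len(b)
    out: list[PairingWindow] = []
    seen: set[tuple[int, int, int]] = set()
    # anti-diagonal: constant c = i + j where A[i] pairs B[j]
    for c in range(la + lb - 1):
        i_lo = max(0, c - lb + 1)
        i_hi = min(la - 1, c)
        kinds: list[str | None] = []
        for i in range(i_lo, i_hi + 1):
            j = c - i
            k = pair_kind(a[i], b[j])
            kinds.append(k if k is not None else "MM")
            # treat positions that can never pair as run breaks only if
            # mismatches are disallowed; otherwise MM is a countable state
        # split into runs of positions usable under the mismatch budget:
        # with max_mismatch == 0, MM breaks the run outright.
        for win in _maximal_windows(kinds, min_len, max_len, max_gu, max_mismatch):
            s, e = win  # offsets into kinds
            ia, ib_hi = i_lo + s, c - (i_lo + s)
            ia_end = i_lo + e
            ib_lo = c - (ia_end - 1)
            key = (ia, ia_end, ib_lo)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                PairingWindow(
                    a_interval=(ia, ia_end),
                    b_interval=(ib_lo, ib_hi + 1),
                    pairs=tuple(kinds[s:e]),
                )
            )
    return out


def _maximal_windows(
    kinds: list[str | None],
    min_len: int,
    max_len: int,
    max_gu: int,
    max_mismatch: int,
) -> list[tuple[int, int]]:
    """Maximal [s, e) windows over a kind string satisfying the budgets."""
    n = len(kinds)

    def ok(s: int, e: int) -> bool:
        if not (min_len <= e - s <= max_len):
            return False
        window = kinds[s:e]
        if kinds[s] == "MM" or kinds[e - 1] == "MM":
            return False
        if sum(1 for k in window if k == "GU") > max_gu:
            return False
        if sum(1 for k in window if k == "MM") > max_mismatch:
            return False
        return True

    def feasible(s: int, e: int) -> bool:
        # like ok() but ignoring min_len, for maximality checks
        if e - s > max_len or s < 0 or e > n:
            return False
        window = kinds[s:e]
        if kinds[s] == "MM" or kinds[e - 1] == "MM":
            return False
        if sum(1 for k in window if k == "GU") > max_gu:
            return False
        if sum(1 for k in window if k == "MM") > max_mismatch:
            return False
        return True

    if max_mismatch == 0:
        # fast path: split on unpairable positions, two-pointer within runs
        out = []
        run_start = 0
        for idx in range(n + 1):
            if idx < n and kinds[idx] != "MM":
                continue
            run_end = idx
            if run_end - run_start >= min_len:
                out.extend(
                    _maximal_in_run(kinds, run_start, run_end, min_len, max_len,
                                    max_gu)
                )
            run_start = idx + 1
        return out

    out = []
    for s in range(n):
        for e in range(s + min_len, min(n, s + max_len) + 1):
            if not ok(s, e):
                continue
            if feasible(s - 1, e) or feasible(s, e + 1):
                continue  # not maximal
            out.append((s, e))
    return out


def _maximal_in_run(kinds, run_start, run_end, min_len, max_len, max_gu):
    """Maximal windows inside a mismatch-free run under the G-U budget."""
    gu_prefix = [0]
    for i in range(run_start, run_end):
        gu_prefix.append(gu_prefix[-1] + (kinds[i] == "GU"))

    def gu(s, e):  # run-relative
        return gu_prefix[e] - gu_prefix[s]

    n = run_end - run_start
    out = []
    for s in range(n):
        e = min(n, s + max_len)
        while e > s and gu(s, e) > max_gu:
            e -= 1
        if e - s < min_len:
            continue
        # left-extensible with the same right edge?
        if s > 0 and e - (s - 1) <= max_len and gu(s - 1, e) <= max_gu:
            continue
        out.append((run_start + s, run_start + e))
    return out
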