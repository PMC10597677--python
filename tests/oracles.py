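"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results through different code paths than the
package (plain recursion, exhaustive enumeration) so that agreement is a
meaningful check.
"""

from __future__ import annotations

import re
from functools import lru_cache


def enumerate_delta_positions(carbons: int, double_bonds: int, omega: int) -> list[int]:
    """Brute-force enumeration of all bond placements that are anchored at the
    omega position (distal bond at carbons - omega), strictly 3-spaced
    (methylene-interrupted), and leave >= 2 carbons at the carboxyl end.
    Exactly one placement must survive the filter."""
    from itertools import combinations

    if double_bonds == 0:
        return []
    distal = carbons - omega
    candidates = [
        sorted(combo)
        for combo in combinations(range(2, distal + 1), double_bonds)
        if max(combo) == distal
        and all(b - a == 3 for a, b in zip(sorted(combo), sorted(combo)[1:]))
    ]
    assert len(candidates) == 1, f"expected a unique placement, got {candidates}"
    return candidates[0]


def _all_hits(protein: str, pattern: str) -> list[int]:
    rx = re.compile("(?=(" + pattern.replace("X", ".") + "))")
    return [m.start() for m in rx.finditer(protein)]


def ordered_combo_exists(protein: str, patterns: list[str], from_pos: int = 0) -> bool:
    """True iff ANY combination of hits places the patterns in order, each
    strictly after the previous hit's end (exhaustive, not greedy)."""
    if not patterns:
        return True
    pattern, rest = patterns[0], patterns[1:]
    for start in _all_hits(protein, pattern):
        if start >= from_pos and ordered_combo_exists(
            protein, rest, start + len(pattern)
        ):
            return True
    return False


def classify_oracle(protein: str) -> str:
    """Exhaustive re-implementation of the family decision procedure."""
    elovl = ["KXXEXXDT", "NXXXHXXMYXYY", "HXXHH", "TXXQXXQ"]
    if ordered_combo_exists(protein, elovl):
        return "ELOVL"
    if "HPGG" in protein:
        for third, family in (("QXXHH", "FED"), ("HXXHH", "DESATURASE_OTHER")):
            for box2 in ("HXXXHH", "HXXHH"):
                if ordered_combo_exists(protein, ["HPGG", "HXXXH", box2, third]):
                    return family
        return "UNCLASSIFIED"
    if ordered_combo_exists(protein, ["HXXXH", "HXXHH", "HXXHH"]):
        return "OMEGA_X"
    return "UNCLASSIFIED"


def global_align_oracle(
    a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2
) -> tuple[str, str, int]:
    """Global alignment by memoized recursion with the same tie-breaking as
    the package (diagonal, then up, then left, applied in a backward walk)."""
    n, m = len(a), len(b)

    def sub(i: int, j: int) -> int:
        x, y = a[i], b[j]
        return match if (x == y and x != "N") else mismatch

    @lru_cache(maxsize=None)
    def pref(i: int, j: int) -> int:
        if i == 0 and j == 0:
            return 0
        opts = []
        if i > 0 and j > 0:
            opts.append(pref(i - 1, j - 1) + sub(i - 1, j - 1))
        if i > 0:
            opts.append(pref(i - 1, j) + gap)
        if j > 0:
            opts.append(pref(i, j - 1) + gap)
        return max(opts)

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and pref(i, j) == pref(i - 1, j - 1) + sub(i - 1, j - 1):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and pref(i, j) == pref(i - 1, j) + gap:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), pref(n, m)


def identity_oracle(a: str, b: str) -> float:
    aligned_a, aligned_b, _ = global_align_oracle(a.upper(), b.upper())
    identical = sum(
        1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-" and x != "N"
    )
    return 100.0 * identical / len(aligned_a)
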