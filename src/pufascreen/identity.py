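"""Global pairwise nucleotide identity and Table-style intra/interspecific
identity matrices for homologous gene sets.

The aligner is a deterministic Needleman–Wunsch with linear gap penalties
(match +1 / mismatch −1 / gap −2, terminal gaps penalized) and fixed traceback
tie-breaking (diagonal, then up, then left), so identity values are exactly
reproducible.  Identity = 100 · identical columns / alignment length; ``N``
never counts as identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GeneSet",
    "IdentityCell",
    "IdentityReport",
    "nw_align",
    "global_percent_identity",
    "identity_table",
]

MATCH = 1
MISMATCH = -1
GAP = -2


def _substitution_matrix(a: str, b: str, match: int, mismatch: int) -> np.ndarray:
    arr_a = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    eq = arr_a[:, None] == arr_b[None, :]
    # N is never a match, even against another N
    n_code = ord("N")
    eq &= (arr_a != n_code)[:, None]
    eq &= (arr_b != n_code)[None, :]
    return np.where(eq, match, mismatch).astype(np.int32)


def _fill_matrix(sub: np.ndarray, gap: int) -> np.ndarray:
    """Fill the NW score matrix by vectorized anti-diagonal sweeps."""
    n, m = sub.shape
    score = np.empty((n + 1, m + 1), dtype=np.int32)
    score[0, :] = gap * np.arange(m + 1, dtype=np.int32)
    score[:, 0] = gap * np.arange(n + 1, dtype=np.int32)
    for d in range(2, n + m + 1):
        lo = max(1, d - m)
        hi = min(n, d - 1)
        if lo > hi:
            continue
        ii = np.arange(lo, hi + 1)
        jj = d - ii
        diag = score[ii - 1, jj - 1] + sub[ii - 1, jj - 1]
        up = score[ii - 1, jj] + gap
        left = score[ii, jj - 1] + gap
        score[ii, jj] = np.maximum(diag, np.maximum(up, left))
    return score


def nw_align(
    a: str,
    b: str,
    match: int = MATCH,
    mismatch: int = MISMATCH,
    gap: int = GAP,
) -> tuple[str, str, int]:
    """Global alignment of ``a`` and ``b``; returns (aligned_a, aligned_b, score).

    Traceback prefers diagonal over up over left, making the alignment unique.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a, b = a.upper(), b.upper()
    sub = _substitution_matrix(a, b, match, mismatch)
    score = _fill_matrix(sub, gap)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = len(a), len(b)
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + sub[i - 1, j - 1]:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and score[i, j] == score[i - 1, j] + gap:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), int(score[len(a), len(b)])


def global_percent_identity(a: str, b: str) -> float:
    """Percent identity over the full global alignment, terminal gaps included.

    Symmetric in its arguments and case-insensitive.
    """
    aligned_a, aligned_b, _ = nw_align(a, b)
    columns = len(aligned_a)
    identical = sum(
        1
        for x, y in zip(aligned_a, aligned_b)
        if x == y and x != "-" and x != "N"
    )
    return 100.0 * identical / columns


@dataclass
class GeneSet:
    """Named collection of homologous gene sequences from one sample."""

    sample_id: str
    sequences: dict[str, str]
    species: str = ""
    site: str = ""

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for gene {name!r} in {self.sample_id}")


@dataclass(frozen=True)
class IdentityCell:
    gene: str
    identity: float | None  # None: gene absent from one of the two sets

    @property
    def absent(self) -> bool:
        return self.identity is None


@dataclass
class IdentityReport:
    genes: list[str]
    rows: dict[tuple[str, str], dict[str, IdentityCell]] = field(default_factory=dict)

    def to_tsv(self) -> str:
        lines = ["\t".join(["pair"] + self.genes)]
        for (a, b), cells in self.rows.items():
            vals = []
            for gene in self.genes:
                cell = cells.get(gene)
                if cell is None or cell.absent:
                    vals.append("*")
                else:
                    vals.append(f"{cell.identity:.1f}")
            lines.append("\t".join([f"{a} vs {b}"] + vals))
        return "\n".join(lines) + "\n"


def identity_table(
    sets: Iterable[GeneSet], pairs: Sequence[tuple[str, str]]
) -> IdentityReport:
    """Pairwise per-gene identity rows for the requested sample pairs.

    Genes present in only one member of a pair appear as absent cells, never
    as 0.  Pairs with no shared genes are skipped with a warning.
    """
    by_id = {s.sample_id: s for s in sets}
    all_genes: list[str] = []
    rows: dict[tuple[str, str], dict[str, IdentityCell]] = {}
    for id_a, id_b in pairs:
        set_a, set_b = by_id[id_a], by_id[id_b]
        union = sorted(set(set_a.sequences) | set(set_b.sequences))
        shared = [g for g in union if g in set_a.sequences and g in set_b.sequences]
        if not shared:
            warnings.warn(
                f"samples {id_a!r} and {id_b!r} share no gene names; pair skipped",
                stacklevel=2,
            )
            continue
        cells: dict[str, IdentityCell] = {}
        for gene in union:
            if gene in shared:
                ident = global_percent_identity(
                    set_a.sequences[gene], set_b.sequences[gene]
                )
                cells[gene] = IdentityCell(gene, ident)
            else:
                cells[gene] = IdentityCell(gene, None)
            if gene not in all_genes:
                all_genes.append(gene)
        rows[(id_a, id_b)] = cells
    return IdentityReport(genes=all_genes, rows=rows)
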