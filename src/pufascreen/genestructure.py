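"""Exon–intron organization from GFF3 annotations, splice-site and
polypyrimidine-tract checks, and introner-like classification.

Internal coordinates are 0-based half-open on the forward strand; GFF3 input
(1-based inclusive) is converted at the boundary.  Intron sequences and
ordinals follow transcription order: for minus-strand genes introns are
numbered from the transcription start and their sequences reverse-complemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio.Seq import Seq

__all__ = [
    "GeneStructure",
    "Intron",
    "IntronerReport",
    "structures_from_gff",
    "introns_from_structure",
    "is_intronless",
    "check_splice_sites",
    "find_polypyrimidine_tract",
    "classify_introner_like",
]

PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class GeneStructure:
    gene_id: str
    scaffold_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, sorted ascending

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("gene must have at least one exon")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValueError("exon end must exceed start")
            if prev_end is not None and start < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class Intron:
    index: int  # 1-based ordinal in transcription order
    start: int  # forward-strand coordinates, 0-based half-open
    end: int
    sequence: str  # transcription orientation

    def __post_init__(self) -> None:
        if self.end - self.start < 4:
            raise ValueError("intron must be at least 4 bp")
        if len(self.sequence) != self.end - self.start:
            raise ValueError("intron sequence length mismatch")

    @property
    def length(self) -> int:
        return self.end - self.start


def structures_from_gff(gff_source: str | Path) -> list[GeneStructure]:
    """Read gene structures from GFF3, grouping exon features by Parent.

    ``gff_source`` may be a file path or GFF3 text.
    """
    text = (
        Path(gff_source).read_text()
        if isinstance(gff_source, Path) or "\t" not in str(gff_source)
        else str(gff_source)
    )
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    grouped: dict[str, list] = {}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent", [exon.id or "unparented"])
        for parent in parents:
            grouped.setdefault(parent, []).append(exon)
    structures = []
    for parent, exons in sorted(grouped.items()):
        exons.sort(key=lambda e: e.start)
        coords = tuple((e.start - 1, e.end) for e in exons)
        structures.append(
            GeneStructure(
                gene_id=parent,
                scaffold_id=exons[0].seqid,
                strand=exons[0].strand,
                exons=coords,
            )
        )
    return structures


def introns_from_structure(g: GeneStructure, scaffold: str) -> list[Intron]:
    """Introns as the gaps between consecutive exons, in transcription order."""
    scaffold = scaffold.upper()
    if g.exons[-1][1] > len(scaffold):
        raise ValueError(
            f"gene {g.gene_id}: exon coordinates exceed scaffold length {len(scaffold)}"
        )
    gaps = [
        (g.exons[k][1], g.exons[k + 1][0]) for k in range(len(g.exons) - 1)
    ]
    if g.strand == "-":
        gaps.reverse()
    introns = []
    for ordinal, (start, end) in enumerate(gaps, start=1):
        seq = scaffold[start:end]
        if g.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        introns.append(Intron(index=ordinal, start=start, end=end, sequence=seq))
    return introns


def is_intronless(g: GeneStructure) -> bool:
    return len(g.exons) == 1


def check_splice_sites(intron: Intron) -> str:
    """``"canonical"`` iff the intron starts GT and ends AG (GT–AG rule)."""
    seq = intron.sequence
    return (
        "canonical"
        if seq.startswith("GT") and seq.endswith("AG")
        else "non_canonical"
    )


def find_polypyrimidine_tract(
    intron: Intron,
    window: int = 40,
    min_len: int = 8,
    min_frac: float = 0.8,
) -> tuple[int, int] | None:
    """Longest pyrimidine-rich run near the 3' end of an intron.

    Searches the 3'-terminal ``window`` nt (final AG excluded) for the longest
    span of at least ``min_len`` nt whose C/T fraction is >= ``min_frac``;
    leftmost on length ties.  Returns (start, end) in intron coordinates, or
    ``None``.
    """
    if window <= 0 or min_len <= 0:
        raise ValueError("window and min_len must be positive")
    if not (0.5 < min_frac <= 1.0):
        raise ValueError("min_frac must lie in (0.5, 1]")
    seq = intron.sequence[:-2]  # exclude the terminal AG acceptor
    region_start = max(0, len(seq) - window)
    region = seq[region_start:]
    is_pyr = [c in PYRIMIDINES for c in region]
    prefix = [0]
    for flag in is_pyr:
        prefix.append(prefix[-1] + flag)
    best: tuple[int, int] | None = None
    n = len(region)
    for length in range(n, min_len - 1, -1):
        for start in range(0, n - length + 1):
            count = prefix[start + length] - prefix[start]
            if count / length >= min_frac:
                best = (region_start + start, region_start + start + length)
                break
        if best is not None:
            break
    return best


@dataclass
class IntronerReport:
    introner_like: bool
    canonical_sites: bool
    tract: tuple[int, int] | None
    length: int
    min_length: int
    criteria: dict[str, bool] = field(default_factory=dict)


def classify_introner_like(
    intron: Intron,
    min_length: int = 100,
    window: int = 40,
    min_len: int = 8,
    min_frac: float = 0.8,
) -> IntronerReport:
    """Introner-like iff canonical GT–AG sites, a polypyrimidine tract, and
    length at least ``min_length``; the report lists each criterion's outcome."""
    canonical = check_splice_sites(intron) == "canonical"
    tract = find_polypyrimidine_tract(
        intron, window=window, min_len=min_len, min_frac=min_frac
    )
    long_enough = intron.length >= min_length
    verdict = canonical and tract is not None and long_enough
    return IntronerReport(
        introner_like=verdict,
        canonical_sites=canonical,
        tract=tract,
        length=intron.length,
        min_length=min_length,
        criteria={
            "canonical_splice_sites": canonical,
            "polypyrimidine_tract": tract is not None,
            "min_length": long_enough,
        },
    )
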