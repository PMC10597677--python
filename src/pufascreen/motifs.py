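"""Six-frame ORF extraction and diagnostic-motif classification of translations.

Classification families:

* ``FED`` — front-end desaturase: heme-binding HPGG motif followed, in order,
  by histidine boxes HXXXH, HXXXHH (or HXXHH) and QXXHH.
* ``DESATURASE_OTHER`` — HPGG-bearing desaturase whose third box is HXXHH
  instead of QXXHH (no desaturation capacity assumed).
* ``OMEGA_X`` — methyl-end desaturase: boxes HXXXH, HXXHH, HXXHH in order and
  no HPGG anywhere.
* ``ELOVL`` — elongase: KXXEXXDT, NXXXHXXMYXYY, HXXHH and TXXQXXQ in order.

Boxes must occur sequentially and non-overlapping (each strictly after the
previous hit's end); ``X`` matches any residue.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq
from Bio import SeqIO

__all__ = [
    "OrfRecord",
    "MotifHit",
    "Family",
    "Classification",
    "CandidateGene",
    "OccurrenceSummary",
    "find_orfs",
    "scan_motif",
    "classify_protein",
    "screen_assembly",
    "FED_BOXES",
    "ELOVL_BOXES",
    "OMEGA_X_BOXES",
    "CYTB5_MOTIF",
]

CYTB5_MOTIF = "HPGG"
FED_BOX1 = "HXXXH"
FED_BOX2_LONG = "HXXXHH"
FED_BOX2_SHORT = "HXXHH"
FED_BOX3 = "QXXHH"
FED_BOXES = (FED_BOX1, FED_BOX2_LONG, FED_BOX2_SHORT, FED_BOX3)
OMEGA_X_BOXES = ("HXXXH", "HXXHH", "HXXHH")
ELOVL_BOXES = ("KXXEXXDT", "NXXXHXXMYXYY", "HXXHH", "TXXQXXQ")

_VALID_NT = frozenset("ACGTN")


class Family(str, Enum):
    FED = "FED"
    OMEGA_X = "OMEGA_X"
    ELOVL = "ELOVL"
    DESATURASE_OTHER = "DESATURASE_OTHER"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class OrfRecord:
    """A full-length ORF located on an assembly contig.

    ``nt_start``/``nt_end`` are 0-based half-open forward-strand coordinates of
    the ATG→stop span (stop codon included); ``frame`` is the reading frame on
    the scanned strand; ``protein`` excludes the stop.
    """

    contig_id: str
    strand: str
    frame: int
    nt_start: int
    nt_end: int
    protein: str

    def __post_init__(self) -> None:
        if (self.nt_end - self.nt_start) % 3 != 0:
            raise ValueError("ORF span must be a multiple of 3")
        if len(self.protein) != (self.nt_end - self.nt_start) // 3 - 1:
            raise ValueError("protein length inconsistent with span")


@dataclass(frozen=True)
class MotifHit:
    pattern_id: str
    pattern: str
    start: int
    matched: str

    @property
    def end(self) -> int:
        return self.start + len(self.pattern)


def find_orfs(
    contig: str, min_codons: int = 100, contig_id: str = "contig"
) -> list[OrfRecord]:
    """Locate ATG→stop ORFs of at least ``min_codons`` codons in all six frames.

    Nested ORFs sharing a stop codon are suppressed in favour of the longest
    (first ATG after the previous in-frame stop).  ORF spans containing ``N``
    are skipped.  Records are sorted by forward-strand position.
    """
    if min_codons < 1:
        raise ValueError("min_codons must be >= 1")
    seq = contig.upper()
    bad = set(seq) - _VALID_NT
    if bad:
        raise ValueError(f"non-IUPAC nucleotide characters: {sorted(bad)}")
    n = len(seq)
    records: list[OrfRecord] = []
    for strand, s in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
        for frame in range(3):
            start_atg: int | None = None
            for pos in range(frame, n - 2, 3):
                codon = s[pos : pos + 3]
                if codon in ("TAA", "TAG", "TGA"):
                    if start_atg is not None:
                        records.extend(
                            _make_record(
                                contig_id, strand, frame, start_atg, pos + 3, s, n, min_codons
                            )
                        )
                    start_atg = None
                elif codon == "ATG" and start_atg is None:
                    start_atg = pos
    records.sort(key=lambda r: (r.nt_start, r.nt_end, r.strand))
    return records


def _make_record(
    contig_id: str,
    strand: str,
    frame: int,
    start: int,
    end: int,
    scanned: str,
    contig_len: int,
    min_codons: int,
) -> list[OrfRecord]:
    if (end - start) // 3 < min_codons:
        return []
    span = scanned[start:end]
    if "N" in span:
        return []
    protein = str(Seq(span[:-3]).translate())
    if strand == "+":
        nt_start, nt_end = start, end
    else:
        nt_start, nt_end = contig_len - end, contig_len - start
    return [OrfRecord(contig_id, strand, frame, nt_start, nt_end, protein)]


def _pattern_regex(pattern: str) -> re.Pattern:
    return re.compile("(?=(" + re.escape(pattern).replace("X", ".") + "))")


def scan_motif(
    protein: str, pattern: str, pattern_id: str | None = None
) -> list[MotifHit]:
    """All (possibly overlapping) occurrences of an X-wildcard pattern, left to right."""
    if not pattern:
        raise ValueError("pattern must be non-empty")
    pid = pattern_id if pattern_id is not None else pattern
    rx = _pattern_regex(pattern)
    return [
        MotifHit(pid, pattern, m.start(), m.group(1)) for m in rx.finditer(protein)
    ]


def _first_hit_from(
    protein: str, pattern: str, from_pos: int = 0, pattern_id: str | None = None
) -> MotifHit | None:
    m = _pattern_regex(pattern).search(protein, from_pos)
    if m is None:
        return None
    pid = pattern_id if pattern_id is not None else pattern
    return MotifHit(pid, pattern, m.start(), m.group(1))


def _ordered_hits(
    protein: str, patterns: Sequence[str], from_pos: int = 0
) -> list[MotifHit] | None:
    """Greedy leftmost assignment of each pattern strictly after the previous hit.

    Complete for fixed-length patterns: the leftmost hit has the leftmost end,
    so it never forecloses a downstream assignment that a later hit would allow.
    """
    hits: list[MotifHit] = []
    pos = from_pos
    for pattern in patterns:
        hit = _first_hit_from(protein, pattern, pos)
        if hit is None:
            return None
        hits.append(hit)
        pos = hit.end
    return hits


@dataclass(frozen=True)
class Classification:
    family: Family
    evidence: tuple[MotifHit, ...]
    has_cytb5: bool


def classify_protein(protein: str) -> Classification:
    """Assign an enzyme family to a protein by the diagnostic-motif decision rules.

    Checked in order: ELOVL, FED, DESATURASE_OTHER, OMEGA_X, else UNCLASSIFIED.
    """
    has_cytb5 = CYTB5_MOTIF in protein

    elovl = _ordered_hits(protein, ELOVL_BOXES)
    if elovl is not None:
        return Classification(Family.ELOVL, tuple(elovl), has_cytb5)

    if has_cytb5:
        hpgg = _first_hit_from(protein, CYTB5_MOTIF)
        assert hpgg is not None
        box1 = _first_hit_from(protein, FED_BOX1, hpgg.end)
        if box1 is not None:
            # Second box may be the long or the short variant; try both since
            # their ends differ and the earlier end may be the only one leaving
            # room for a third box.  Prefer the long variant on equal starts.
            box2_candidates = [
                h
                for h in (
                    _first_hit_from(protein, FED_BOX2_LONG, box1.end),
                    _first_hit_from(protein, FED_BOX2_SHORT, box1.end),
                )
                if h is not None
            ]
            box2_candidates.sort(key=lambda h: (h.start, len(h.pattern) != 6))
            for box2 in box2_candidates:
                box3 = _first_hit_from(protein, FED_BOX3, box2.end)
                if box3 is not None:
                    return Classification(
                        Family.FED, (hpgg, box1, box2, box3), has_cytb5
                    )
            for box2 in box2_candidates:
                box3 = _first_hit_from(protein, FED_BOX2_SHORT, box2.end)
                if box3 is not None:
                    return Classification(
                        Family.DESATURASE_OTHER, (hpgg, box1, box2, box3), has_cytb5
                    )
    else:
        wx = _ordered_hits(protein, OMEGA_X_BOXES)
        if wx is not None:
            return Classification(Family.OMEGA_X, tuple(wx), has_cytb5)

    return Classification(Family.UNCLASSIFIED, (), has_cytb5)


@dataclass(frozen=True)
class CandidateGene:
    orf: OrfRecord
    family: Family
    evidence: tuple[MotifHit, ...]
    has_cytb5: bool

    def fasta_header(self) -> str:
        return (
            f"{self.orf.contig_id}|{self.orf.strand}|"
            f"{self.orf.nt_start}-{self.orf.nt_end}|{self.family.value}"
        )


@dataclass
class OccurrenceSummary:
    """Per-family counts of distinct candidate proteins in one assembly."""

    counts: dict[Family, int] = field(default_factory=dict)
    n_contigs: int = 0
    n_orfs: int = 0

    def count(self, family: Family) -> int:
        return self.counts.get(family, 0)

    def as_dict(self) -> dict[str, int]:
        return {
            fam.value: self.count(fam)
            for fam in (Family.ELOVL, Family.FED, Family.OMEGA_X, Family.DESATURASE_OTHER)
        }


def _iter_contigs(contigs) -> Iterable[tuple[str, str]]:
    if isinstance(contigs, (str, Path)):
        for rec in SeqIO.parse(str(contigs), "fasta"):
            yield rec.id, str(rec.seq)
    else:
        for item in contigs:
            if isinstance(item, tuple):
                yield item
            else:  # SeqRecord
                yield item.id, str(item.seq)


def screen_assembly(
    contigs, min_codons: int = 100
) -> tuple[list[CandidateGene], OccurrenceSummary]:
    """Screen a (multi-)FASTA of contigs for LC-PUFA enzyme candidates.

    ``contigs`` may be a FASTA path, an iterable of SeqRecords, or of
    ``(id, sequence)`` tuples.  Returns classified candidates (UNCLASSIFIED
    ORFs excluded) and a per-family summary in which ORFs with identical
    protein sequences are counted once.
    """
    candidates: list[CandidateGene] = []
    summary = OccurrenceSummary()
    seen_proteins: dict[Family, set[str]] = {}
    counts: Counter = Counter()
    for contig_id, seq in _iter_contigs(contigs):
        summary.n_contigs += 1
        for orf in find_orfs(seq, min_codons=min_codons, contig_id=contig_id):
            summary.n_orfs += 1
            cls = classify_protein(orf.protein)
            if cls.family is Family.UNCLASSIFIED:
                continue
            candidates.append(
                CandidateGene(orf, cls.family, cls.evidence, cls.has_cytb5)
            )
            pool = seen_proteins.setdefault(cls.family, set())
            if orf.protein not in pool:
                pool.add(orf.protein)
                counts[cls.family] += 1
    summary.counts = dict(counts)
    candidates.sort(key=lambda c: (c.orf.contig_id, c.orf.nt_start, c.orf.nt_end))
    return candidates, summary
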