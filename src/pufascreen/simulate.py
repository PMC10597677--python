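"""Seeded, truth-annotated synthetic fixtures: host vs contaminated samples,
motif-bearing CDSs, diverged cox1 fragments and annotated genomic scaffolds.

Every generator is deterministic under (arguments, seed), and every planted
element is verified against the corresponding screen at generation time, so
truth sets are exact oracles at divergence 0.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .motifs import (
    CYTB5_MOTIF,
    ELOVL_BOXES,
    Family,
    classify_protein,
    find_orfs,
)

__all__ = [
    "FamilyGene",
    "PlantedGene",
    "PlantedCox1",
    "TruthSet",
    "GenomeTruth",
    "make_family_protein",
    "mutate_sequence",
    "make_sample",
    "make_genome_fixture",
    "bundled_cox1_panel",
    "write_sample",
    "write_genome_fixture",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")

# family -> ordered concrete motif patterns to plant (X instantiated at random)
_FAMILY_MOTIFS: dict[str, tuple[str, ...]] = {
    "fed": (CYTB5_MOTIF, "HXXXH", "HXXXHH", "QXXHH"),
    "desaturase_other": (CYTB5_MOTIF, "HXXXH", "HXXHH", "HXXHH"),
    "wx": ("HXXXH", "HXXHH", "HXXHH"),
    "elovl": ELOVL_BOXES,
}

_FAMILY_ENUM = {
    "fed": Family.FED,
    "desaturase_other": Family.DESATURASE_OTHER,
    "wx": Family.OMEGA_X,
    "elovl": Family.ELOVL,
}

_BACK_TABLE: dict[str, list[str]] = {}
for codon, aa in sorted(standard_dna_table.forward_table.items()):
    _BACK_TABLE.setdefault(aa, []).append(codon)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _random_protein(rng: np.random.Generator, length: int) -> list[str]:
    return list(rng.choice(list(AMINO_ACIDS), size=length))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(NUCLEOTIDES), size=length))


@dataclass(frozen=True)
class FamilyGene:
    family: str
    protein: str
    cds: str  # ATG..stop, encodes protein under the standard code
    motif_positions: tuple[tuple[str, int], ...]  # (pattern, 0-based aa position)


def make_family_protein(
    family: str, length: int = 350, seed=0, max_attempts: int = 200
) -> FamilyGene:
    """Random protein of ``length`` aa with the family's diagnostic motifs
    planted in order at recorded positions, plus its reverse-translated CDS.

    The protein is re-screened with :func:`classify_protein` and resampled
    until the intended family is assigned (guards against accidental stray
    motifs in the random background).
    """
    if family not in _FAMILY_MOTIFS:
        raise ValueError(f"unknown family {family!r}")
    if length < 150:
        raise ValueError("length must be >= 150 aa")
    rng = _rng(seed)
    patterns = _FAMILY_MOTIFS[family]
    total_motif = sum(len(p) for p in patterns)
    if total_motif + 10 > length:
        raise ValueError("length too short to place the family motifs")
    expected = _FAMILY_ENUM[family]
    for _ in range(max_attempts):
        residues = _random_protein(rng, length)
        residues[0] = "M"
        positions = _place_motifs(rng, patterns, length)
        planted = []
        for pattern, pos in zip(patterns, positions):
            for offset, ch in enumerate(pattern):
                residues[pos + offset] = (
                    ch if ch != "X" else str(rng.choice(list(AMINO_ACIDS)))
                )
            planted.append((pattern, pos))
        protein = "".join(residues)
        if classify_protein(protein).family is expected:
            cds = _reverse_translate(rng, protein)
            return FamilyGene(family, protein, cds, tuple(planted))
    raise RuntimeError(f"could not synthesize a clean {family} protein")


def _place_motifs(
    rng: np.random.Generator, patterns: tuple[str, ...], length: int
) -> list[int]:
    """Random ordered non-overlapping positions in [1, length) for each pattern."""
    slack = length - 1 - sum(len(p) for p in patterns)
    cuts = np.sort(rng.integers(0, slack + 1, size=len(patterns)))
    # position_i = 1 + cut_i + total length of earlier patterns
    positions: list[int] = []
    prior = 0
    for pattern, cut in zip(patterns, cuts):
        positions.append(1 + int(cut) + prior)
        prior += len(pattern)
    return positions


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    codons = [str(rng.choice(_BACK_TABLE[aa])) for aa in protein]
    codons.append(str(rng.choice(STOP_CODONS)))
    return "".join(codons)


def mutate_sequence(
    seq: str, substitution_rate: float, seed=0
) -> tuple[str, list[tuple[int, str, str]]]:
    """i.i.d. per-site substitution to a different base; edits recorded, no indels."""
    if not 0.0 <= substitution_rate <= 0.5:
        raise ValueError("substitution_rate must lie in [0, 0.5]")
    rng = _rng(seed)
    bases = list(seq.upper())
    hit = rng.random(len(bases)) < substitution_rate
    edits: list[tuple[int, str, str]] = []
    for pos in np.flatnonzero(hit):
        old = bases[pos]
        choices = [b for b in NUCLEOTIDES if b != old]
        new = str(rng.choice(choices))
        bases[pos] = new
        edits.append((int(pos), old, new))
    return "".join(bases), edits


@dataclass
class PlantedGene:
    contig_id: str
    family: str
    cds_start: int  # forward-strand 0-based half-open, stop codon included
    cds_end: int
    strand: str
    protein: str


@dataclass
class PlantedCox1:
    contig_id: str
    reference_id: str
    fragment_start: int
    fragment_end: int
    substitutions: list[tuple[int, str, str]]  # positions within the fragment


@dataclass
class TruthSet:
    sample_id: str
    profile: str
    seed: int
    planted_genes: list[PlantedGene] = field(default_factory=list)
    planted_cox1: list[PlantedCox1] = field(default_factory=list)

    def expected_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for g in self.planted_genes:
            fam = _FAMILY_ENUM[g.family].value
            counts[fam] = counts.get(fam, 0) + 1
        return counts

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        doc = json.loads(text)
        return cls(
            sample_id=doc["sample_id"],
            profile=doc["profile"],
            seed=doc["seed"],
            planted_genes=[PlantedGene(**g) for g in doc["planted_genes"]],
            planted_cox1=[
                PlantedCox1(
                    contig_id=c["contig_id"],
                    reference_id=c["reference_id"],
                    fragment_start=c["fragment_start"],
                    fragment_end=c["fragment_end"],
                    substitutions=[tuple(e) for e in c["substitutions"]],
                )
                for c in doc["planted_cox1"]
            ],
        )


def bundled_cox1_panel() -> list[tuple[str, str]]:
    """The small synthetic cox1 reference panel shipped with the package."""
    text = resources.files("pufascreen.data").joinpath("cox1_panel.fasta").read_text()
    panel = []
    name = None
    chunks: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if name is not None:
                panel.append((name, "".join(chunks)))
            name = line[1:].split()[0]
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if name is not None:
        panel.append((name, "".join(chunks)))
    return panel


_FRESHWATER_FAMILIES = ("elovl",) + ("fed",) * 4 + ("wx",) * 2


def _host_contig(rng: np.random.Generator, length: int, min_codons: int) -> str:
    """Random contig guaranteed to yield no classified ORF at ``min_codons``."""
    while True:
        seq = _random_dna(rng, length)
        orfs = find_orfs(seq, min_codons=min_codons)
        if all(
            classify_protein(o.protein).family is Family.UNCLASSIFIED for o in orfs
        ):
            return seq


def _embed_gene(
    rng: np.random.Generator, gene: FamilyGene, min_codons: int
) -> tuple[str, int, int]:
    """Place a CDS between random flanks such that the exact planted ORF is
    recovered by ``find_orfs`` and no other classified ORF appears."""
    while True:
        left = _random_dna(rng, int(rng.integers(60, 240)))
        right = _random_dna(rng, int(rng.integers(60, 240)))
        contig = left + gene.cds + right
        start, end = len(left), len(left) + len(gene.cds)
        orfs = find_orfs(contig, min_codons=min_codons)
        classified = [
            o for o in orfs if classify_protein(o.protein).family is not Family.UNCLASSIFIED
        ]
        if (
            len(classified) == 1
            and classified[0].nt_start == start
            and classified[0].nt_end == end
            and classified[0].strand == "+"
            and classified[0].protein == gene.protein
        ):
            return contig, start, end


def make_sample(
    profile: str,
    n_host: int = 12,
    n_contaminant_genes: int | None = None,
    cox1_divergence: float = 0.004,
    seed: int = 0,
    protein_length: int = 350,
    min_codons: int = 100,
    host_length: int = 1200,
) -> tuple[list[tuple[str, str]], TruthSet]:
    """Synthetic sample: host contigs plus, for the freshwater profile, planted
    contaminant CDSs (1 elovl, 4 fed, 2 wx by default) and a diverged cox1
    fragment.  The marine profile is contamination-free by construction.
    """
    if profile not in ("freshwater", "marine"):
        raise ValueError("profile must be 'freshwater' or 'marine'")
    rng = _rng(seed)
    sample_id = f"{profile}_s{seed}"
    truth = TruthSet(sample_id=sample_id, profile=profile, seed=seed)
    contigs: list[tuple[str, str]] = []
    for i in range(n_host):
        contigs.append(
            (f"{sample_id}_host{i}", _host_contig(rng, host_length, min_codons))
        )
    if profile == "freshwater":
        families = list(_FRESHWATER_FAMILIES)
        if n_contaminant_genes is not None:
            families = families[:n_contaminant_genes]
        for i, family in enumerate(families):
            gene = make_family_protein(family, length=protein_length, seed=rng)
            contig, start, end = _embed_gene(rng, gene, min_codons)
            contig_id = f"{sample_id}_contam{i}_{family}"
            contigs.append((contig_id, contig))
            truth.planted_genes.append(
                PlantedGene(contig_id, family, start, end, "+", gene.protein)
            )
        panel = bundled_cox1_panel()
        ref_id, ref_seq = panel[int(rng.integers(0, len(panel)))]
        fragment, edits = mutate_sequence(ref_seq, cox1_divergence, seed=rng)
        left = _random_dna(rng, int(rng.integers(30, 120)))
        right = _random_dna(rng, int(rng.integers(30, 120)))
        contig_id = f"{sample_id}_cox1"
        contigs.append((contig_id, left + fragment + right))
        truth.planted_cox1.append(
            PlantedCox1(contig_id, ref_id, len(left), len(left) + len(fragment), edits)
        )
    return contigs, truth


@dataclass
class GenomeTruth:
    scaffold_id: str
    genes: dict[str, dict]

    def to_json(self) -> str:
        return json.dumps({"scaffold_id": self.scaffold_id, "genes": self.genes}, indent=1)


# 12 nt, 10 pyrimidines with pyrimidines at both ends: in a purine background
# this span is the unique longest window with C/T fraction >= 0.8, so the
# planted tract coordinates are exactly recoverable.
TRACT_SEQ = "TTCTTATCGTTC"
TRACT_LEN = len(TRACT_SEQ)
TRACT_TAIL_PAD = 6  # purines between tract and the acceptor AG


def _purine_run(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(["A", "G"], size=length))


def _make_intron(
    rng: np.random.Generator,
    length: int,
    canonical: bool = True,
    with_tract: bool = True,
) -> str:
    """Intron sequence in transcription orientation with controlled features.

    Layout: donor | purine body | tract (or purines) | purine pad | acceptor.
    The body is purine-only so no accidental pyrimidine tract can arise.
    """
    donor, acceptor = ("GT", "AG") if canonical else ("AT", "AC")
    body_len = length - len(donor) - len(acceptor) - TRACT_TAIL_PAD - TRACT_LEN
    if body_len < 0:
        raise ValueError(f"intron length {length} too short for the fixture layout")
    body = _purine_run(rng, body_len)
    tract = TRACT_SEQ if with_tract else _purine_run(rng, TRACT_LEN)
    return donor + body + tract + _purine_run(rng, TRACT_TAIL_PAD) + acceptor


def tract_span(intron_length: int) -> tuple[int, int]:
    """Planted tract coordinates within a fixture intron of ``intron_length``."""
    end = intron_length - 2 - TRACT_TAIL_PAD
    return end - TRACT_LEN, end


def make_genome_fixture(seed: int = 0):
    """One scaffold carrying an intronless gene, a 4-intron gene whose third
    intron is 940 bp with canonical sites and a planted polypyrimidine tract,
    and a minus-strand control gene with a non-canonical intron.

    Returns ``(scaffold_id, scaffold_seq, gff3_text, GenomeTruth)``.
    """
    rng = _rng(seed)
    scaffold_id = f"scaffold_sim{seed}"
    pieces: list[str] = []
    cursor = 0
    gff_rows: list[str] = []
    genes: dict[str, dict] = {}

    def emit(seq: str) -> tuple[int, int]:
        nonlocal cursor
        pieces.append(seq)
        start = cursor
        cursor += len(seq)
        return start, cursor

    def add_gene(gene_id: str, strand: str, exon_lens: list[int], intron_seqs: list[str]):
        # build gene in transcription orientation, then place on the scaffold
        segs: list[tuple[str, str]] = []
        for k, exon_len in enumerate(exon_lens):
            segs.append(("exon", _random_dna(rng, exon_len)))
            if k < len(intron_seqs):
                segs.append(("intron", intron_seqs[k]))
        gene_seq = "".join(s for _, s in segs)
        if strand == "-":
            placed = str(Seq(gene_seq).reverse_complement())
        else:
            placed = gene_seq
        g_start, g_end = emit(placed)
        # forward-strand exon coordinates
        exon_coords = []
        offset = 0
        for kind, s in segs:
            if kind == "exon":
                if strand == "+":
                    exon_coords.append((g_start + offset, g_start + offset + len(s)))
                else:
                    exon_coords.append((g_end - offset - len(s), g_end - offset))
            offset += len(s)
        exon_coords.sort()
        mrna_id = f"{gene_id}.t1"
        gff_rows.append(
            f"{scaffold_id}\tsim\tgene\t{g_start + 1}\t{g_end}\t.\t{strand}\t.\tID={gene_id}"
        )
        gff_rows.append(
            f"{scaffold_id}\tsim\tmRNA\t{g_start + 1}\t{g_end}\t.\t{strand}\t.\t"
            f"ID={mrna_id};Parent={gene_id}"
        )
        for n, (s, e) in enumerate(exon_coords, start=1):
            gff_rows.append(
                f"{scaffold_id}\tsim\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                f"ID={mrna_id}.exon{n};Parent={mrna_id}"
            )
        genes[mrna_id] = {
            "gene_id": gene_id,
            "strand": strand,
            "n_exons": len(exon_coords),
            "intron_lengths": [len(s) for kind, s in segs if kind == "intron"],
            "intronless": len(exon_coords) == 1,
        }

    emit(_random_dna(rng, 300))
    add_gene("gene_intronless", "+", [903], [])
    emit(_random_dna(rng, 250))
    introner_introns = [
        _make_intron(rng, 150),
        _make_intron(rng, 210),
        _make_intron(rng, 940),
        _make_intron(rng, 120),
    ]
    add_gene("gene_introner", "+", [220, 180, 240, 200, 160], introner_introns)
    genes_meta = genes["gene_introner.t1"]
    genes_meta["introner_intron_index"] = 3
    genes_meta["introner_intron_length"] = 940
    genes_meta["tract_span"] = list(tract_span(940))
    emit(_random_dna(rng, 250))
    control_intron = _make_intron(rng, 300, canonical=False, with_tract=False)
    add_gene("gene_control", "-", [260, 310], [control_intron])
    genes["gene_control.t1"]["non_canonical_intron"] = 1
    emit(_random_dna(rng, 300))

    scaffold = "".join(pieces)
    gff3 = "##gff-version 3\n" + "\n".join(gff_rows) + "\n"
    return scaffold_id, scaffold, gff3, GenomeTruth(scaffold_id, genes)


def write_fasta(records, path: Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_sample(profile: str, out_dir: Path, seed: int = 0, **kwargs) -> TruthSet:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    contigs, truth = make_sample(profile, seed=seed, **kwargs)
    write_fasta(contigs, out_dir / "sample.fasta")
    (out_dir / "truth.json").write_text(truth.to_json())
    return truth


def write_genome_fixture(out_dir: Path, seed: int = 0) -> GenomeTruth:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scaffold_id, scaffold, gff3, truth = make_genome_fixture(seed)
    write_fasta([(scaffold_id, scaffold)], out_dir / "genome.fasta")
    (out_dir / "annotation.gff3").write_text(gff3)
    (out_dir / "truth.json").write_text(truth.to_json())
    return truth
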