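"""Core sequence and annotation types shared by every pipeline stage.

Coordinates are 0-based half-open internally; human-readable writers emit
1-based inclusive coordinates (see :mod:`lgt_hunter.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

DNA_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# Standard (universal) genetic code, DNA codons.
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

SENSE_CODONS = tuple(sorted(c for c, aa in CODON_TABLE.items() if aa != "*"))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a DNA CDS (length divisible by 3) with the universal code."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    return "".join(CODON_TABLE.get(cds[i:i + 3], "X") for i in range(0, len(cds), 3))


def _check_alphabet(seq: str, alphabet: frozenset, record_id: str) -> None:
    for pos, ch in enumerate(seq):
        if ch not in alphabet:
            raise ValueError(
                f"illegal character {ch!r} in record {record_id!r} at position {pos + 1}"
            )


@dataclass(frozen=True)
class Scaffold:
    """A named genomic DNA sequence over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"scaffold {self.id!r} has empty sequence")
        _check_alphabet(self.seq, DNA_ALPHABET, self.id)

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence with an optional taxon / kingdom annotation.

    ``kingdom_label`` partitions reference panels into bacterial vs animal
    (plus the focal species under study); it drives the origin call made by
    the placement stage.
    """

    id: str
    seq: str
    source_taxon: str = ""
    kingdom_label: str = "other"  # bacterial | animal | focal | other

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"protein {self.id!r} has empty sequence")
        _check_alphabet(self.seq, PROTEIN_ALPHABET, self.id)
        if self.kingdom_label not in {"bacterial", "animal", "focal", "other"}:
            raise ValueError(f"bad kingdom_label {self.kingdom_label!r}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneModel:
    """An intronless gene on a scaffold; [start, end) half-open, strand +/-."""

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    cds_seq: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id!r}: bad interval [{self.start}, {self.end})")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")
        if self.cds_seq:
            if len(self.cds_seq) % 3 != 0:
                raise ValueError(f"gene {self.gene_id!r}: CDS length not divisible by 3")
            aa = translate(self.cds_seq)
            if "*" in aa[:-1]:
                raise ValueError(f"gene {self.gene_id!r}: internal stop codon in CDS")


@dataclass
class Assembly:
    """Scaffolds plus per-scaffold gene lists sorted by start coordinate."""

    scaffolds: dict[str, Scaffold] = field(default_factory=dict)
    genes: dict[str, list[GeneModel]] = field(default_factory=dict)

    def add_scaffold(self, scaffold: Scaffold) -> None:
        if scaffold.id in self.scaffolds:
            raise ValueError(f"duplicate scaffold id {scaffold.id!r}")
        self.scaffolds[scaffold.id] = scaffold

    def add_gene(self, gene: GeneModel) -> None:
        sc = self.scaffolds.get(gene.scaffold_id)
        if sc is None:
            raise ValueError(f"gene {gene.gene_id!r} references unknown scaffold {gene.scaffold_id!r}")
        if gene.end > sc.length:
            raise ValueError(
                f"gene {gene.gene_id!r} end {gene.end} exceeds scaffold "
                f"{gene.scaffold_id!r} length {sc.length}"
            )
        lst = self.genes.setdefault(gene.scaffold_id, [])
        if any(g.gene_id == gene.gene_id for genes in self.genes.values() for g in genes):
            raise ValueError(f"duplicate gene id {gene.gene_id!r}")
        lst.append(gene)
        lst.sort(key=lambda g: g.start)

    def all_genes(self) -> list[GeneModel]:
        return [g for sid in self.scaffolds for g in self.genes.get(sid, [])]

    def gene(self, gene_id: str) -> GeneModel:
        for genes in self.genes.values():
            for g in genes:
                if g.gene_id == gene_id:
                    return g
        raise KeyError(gene_id)

    def extract(self, scaffold_id: str, start: int, end: int, strand: str = "+") -> str:
        seq = self.scaffolds[scaffold_id].seq[start:end]
        return reverse_complement(seq) if strand == "-" else seq
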