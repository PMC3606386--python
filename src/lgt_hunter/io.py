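"""FASTA and gene-table readers/writers.

FASTA parsing is delegated to Biopython's ``SeqIO``; this layer adds the
alphabet validation, duplicate-id detection and case folding the pipeline
relies on.  Gene tables are 5-column TSV files (gene_id, scaffold_id,
start, end, strand) with 0-based half-open coordinates; ``#`` lines are
metadata and skipped on read.  Human-readable reports elsewhere emit
1-based inclusive coordinates; the gene table is machine-facing and stays
0-based so that read -> write -> read round-trips exactly.
"""

from __future__ import annotations

import os
from typing import Sequence

from Bio import SeqIO

from .datamodel import Assembly, GeneModel, ProteinRecord, Scaffold, reverse_complement


def read_fasta(path: str | os.PathLike, alphabet: str = "dna"):
    """Read a FASTA file into Scaffold (dna) or ProteinRecord (protein) objects.

    Sequences are uppercased; record order is preserved; duplicate ids and
    illegal characters raise ``ValueError``.
    """
    if alphabet not in {"dna", "protein"}:
        raise ValueError(f"alphabet must be 'dna' or 'protein', got {alphabet!r}")
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if alphabet == "dna":
            records.append(Scaffold(id=rec.id, seq=seq))
        else:
            records.append(ProteinRecord(id=rec.id, seq=seq))
    return records


def write_fasta(path: str | os.PathLike, records: Sequence[Scaffold | ProteinRecord],
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def read_gene_table(path: str | os.PathLike, assembly: Assembly) -> Assembly:
    """Attach genes from a 5-column TSV to an assembly, extracting CDS sequence.

    Minus-strand CDS are reverse-complemented.  Unknown scaffolds and
    out-of-bounds coordinates raise ``ValueError``.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "gene_id":  # header row
                continue
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
            gene_id, scaffold_id, start_s, end_s, strand = fields[:5]
            start, end = int(start_s), int(end_s)
            sc = assembly.scaffolds.get(scaffold_id)
            if sc is None:
                raise ValueError(f"{path}:{lineno}: unknown scaffold {scaffold_id!r}")
            if not (0 <= start < end <= sc.length):
                raise ValueError(
                    f"{path}:{lineno}: gene {gene_id!r} coordinates [{start}, {end}) "
                    f"out of bounds for scaffold of length {sc.length}"
                )
            cds = sc.seq[start:end]
            if strand == "-":
                cds = reverse_complement(cds)
            assembly.add_gene(GeneModel(gene_id=gene_id, scaffold_id=scaffold_id,
                                        start=start, end=end, strand=strand, cds_seq=cds))
    return assembly


def write_gene_table(path: str | os.PathLike, assembly: Assembly,
                     metadata: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in metadata:
            fh.write(f"# {line}\n")
        fh.write("gene_id\tscaffold_id\tstart\tend\tstrand\n")
        for sid in assembly.scaffolds:
            for g in assembly.genes.get(sid, []):
                fh.write(f"{g.gene_id}\t{g.scaffold_id}\t{g.start}\t{g.end}\t{g.strand}\n")


def write_tsv(path: str | os.PathLike, header: Sequence[str],
              rows: Sequence[Sequence], metadata: Sequence[str] = ()) -> None:
    """Generic pipeline TSV writer: '#' metadata lines, then header, then rows."""
    with open(path, "w") as fh:
        for line in metadata:
            fh.write(f"# {line}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
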