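"""Readers and writers for the on-disk formats used across the pipeline.

FASTA and FASTQ go through Biopython's SeqIO; GFF3 uses a small in-repo
parser so malformed records can be reported with their line number.
Coordinates are 1-based inclusive everywhere (the GFF3 convention); any
half-open arithmetic stays inside private helpers.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclasses.dataclass(frozen=True)
class GeneRecord:
    """One annotated CDS: 1-based inclusive coordinates on ``contig``."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    protein: str = ""

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclasses.dataclass
class AnnotatedGenome:
    """Contigs plus the ordered gene records of one genome."""

    genome_id: str
    contigs: dict[str, str]
    genes: list[GeneRecord]

    def __post_init__(self):
        seen = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id} in {self.genome_id}")
            seen.add(g.gene_id)
            if g.contig in self.contigs and g.end > len(self.contigs[g.contig]):
                raise ValueError(
                    f"gene {g.gene_id} extends past end of contig {g.contig}"
                )

    def genes_on(self, contig: str) -> list[GeneRecord]:
        """Genes on a contig ordered by start coordinate."""
        return sorted(
            (g for g in self.genes if g.contig == contig), key=lambda g: g.start
        )

    def proteins(self) -> dict[str, str]:
        return {g.gene_id: g.protein for g in self.genes if g.protein}


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA → ordered {id: sequence}. Raises on duplicate ids."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate record id {rec.id}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(path: str | Path, records: dict[str, str] | Iterable[tuple[str, str]]):
    items = records.items() if isinstance(records, dict) else records
    seqrecs = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(seqrecs, str(path), "fasta")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """FASTQ → list of (id, sequence); qualities are not retained."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]], quality: str = "I"):
    """Write reads with a flat Phred+33 quality string (default 'I' = Q40)."""
    q = ord(quality) - 33
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality * len(seq)}\n")
    _ = q  # quality is constant by design; kept for clarity


# ---------------------------------------------------------------------------
# GFF3 (CDS features with ID attributes)


def write_gff3(path: str | Path, genome: AnnotatedGenome):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cid, seq in genome.contigs.items():
            fh.write(f"##sequence-region {cid} 1 {len(seq)}\n")
        for g in genome.genes:
            fh.write(
                f"{g.contig}\toyescan\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t"
                f"ID={g.gene_id}\n"
            )


def read_gff3(path: str | Path, contigs: dict[str, str] | None = None,
              genome_id: str | None = None) -> AnnotatedGenome:
    """Parse CDS features; errors name the offending line number."""
    genes: list[GeneRecord] = []
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) == 4:
                    lengths[parts[1]] = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            contig, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "CDS":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if "ID" not in attr_map:
                raise ValueError(f"{path}:{lineno}: CDS feature without ID attribute")
            try:
                genes.append(
                    GeneRecord(attr_map["ID"], contig, start_i, end_i, strand)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if contigs is None:
        contigs = {cid: "N" * n for cid, n in lengths.items()}
    gid = genome_id or Path(path).stem
    return AnnotatedGenome(gid, contigs, genes)


def load_genome(prefix: str | Path, genome_id: str | None = None) -> AnnotatedGenome:
    """Load ``{prefix}.fna`` + ``{prefix}.gff`` + ``{prefix}.faa`` into one object."""
    prefix = Path(prefix)
    contigs = read_fasta(prefix.with_suffix(".fna"))
    genome = read_gff3(prefix.with_suffix(".gff"), contigs=contigs,
                       genome_id=genome_id or prefix.name)
    proteins = read_fasta(prefix.with_suffix(".faa"))
    genes = [
        dataclasses.replace(g, protein=proteins.get(g.gene_id, ""))
        for g in genome.genes
    ]
    return AnnotatedGenome(genome.genome_id, contigs, genes)


# ---------------------------------------------------------------------------
# TSV tables with a provenance header


def write_table(path: str | Path, df, header_comment: str | None = None):
    """Write a pandas DataFrame as TSV, optionally preceded by '# ...' lines."""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path):
    import pandas as pd

    return pd.read_csv(path, sep="\t", comment="#")
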