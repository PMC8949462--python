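"""Genome and annotation containers plus FASTA/GFF3 I/O.

Internally all coordinates are 0-based half-open; the GFF3 reader/writer is
the only place the 1-based inclusive shift happens.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end",
    "score", "strand", "phase", "attributes",
]


@dataclass
class CDSRecord:
    """One protein-coding gene: 0-based half-open span on a contig."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str  # '+' or '-'

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad CDS span [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedGenome:
    """Contig sequences plus CDS records for one strain."""

    strain: str
    contigs: dict  # contig id -> str sequence
    cds: list = field(default_factory=list)  # list of CDSRecord

    def cds_seq(self, rec: CDSRecord) -> str:
        s = self.contigs[rec.contig][rec.start:rec.end]
        if rec.strand == "-":
            s = str(Seq(s).reverse_complement())
        return s

    def protein_seq(self, rec: CDSRecord) -> str:
        return str(Seq(self.cds_seq(rec)).translate(table=11)).rstrip("*")

    def cds_by_id(self) -> dict:
        return {r.gene_id: r for r in self.cds}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


def write_fasta(records: dict, path: str, width: int = 70) -> None:
    """Write {id: sequence} to FASTA, ids in insertion order."""
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_fasta(path: str) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_gff3(genome: AnnotatedGenome, path: str) -> None:
    rows = []
    for r in genome.cds:
        attrs = f"ID={r.gene_id}"
        # 0-based half-open -> 1-based inclusive
        rows.append((r.contig, "acaryopan", "CDS", r.start + 1, r.end,
                     ".", r.strand, "0", attrs))
    df = pd.DataFrame(rows, columns=GFF3_COLUMNS)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_gff3(path: str) -> list:
    """Read CDS features from the flat GFF3 layout this package writes."""
    with open(path) as fh:
        body = "".join(ln for ln in fh if not ln.startswith("#"))
    if not body.strip():
        return []
    df = pd.read_csv(io.StringIO(body), sep="\t", names=GFF3_COLUMNS)
    out = []
    for row in df.itertuples(index=False):
        if row.type != "CDS":
            continue
        gene_id = None
        for kv in str(row.attributes).split(";"):
            if kv.startswith("ID="):
                gene_id = kv[3:]
        if gene_id is None:
            raise ValueError(f"CDS without ID attribute in {path}")
        # 1-based inclusive -> 0-based half-open
        out.append(CDSRecord(gene_id, str(row.seqid), int(row.start) - 1,
                             int(row.end), str(row.strand)))
    return out


def write_genome_dir(genome: AnnotatedGenome, out_dir: str) -> None:
    """Write genome FASTA, CDS FASTA, protein FASTA and GFF3 for one strain."""
    os.makedirs(out_dir, exist_ok=True)
    write_fasta(genome.contigs, os.path.join(out_dir, f"{genome.strain}.fna"))
    write_fasta({r.gene_id: genome.cds_seq(r) for r in genome.cds},
                os.path.join(out_dir, f"{genome.strain}.ffn"))
    write_fasta({r.gene_id: genome.protein_seq(r) for r in genome.cds},
                os.path.join(out_dir, f"{genome.strain}.faa"))
    write_gff3(genome, os.path.join(out_dir, f"{genome.strain}.gff3"))


def read_genome_dir(strain: str, in_dir: str) -> AnnotatedGenome:
    contigs = read_fasta(os.path.join(in_dir, f"{strain}.fna"))
    cds = read_gff3(os.path.join(in_dir, f"{strain}.gff3"))
    return AnnotatedGenome(strain=strain, contigs=contigs, cds=cds)
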