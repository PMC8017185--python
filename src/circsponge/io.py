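"""File I/O: FASTA/FASTQ via Biopython, GTF, and TSV matrices.

All TSV output goes through :func:`write_tsv` so that float formatting is
fixed and runs with the same seed are byte-identical.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import GeneModel, ToyGenome

FLOAT_FORMAT = "%.6g"


# --------------------------------------------------------------------------- FASTA

def write_fasta(seqs: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# --------------------------------------------------------------------------- FASTQ

def write_fastq(reads: list[tuple[str, str]], path: str | os.PathLike, quality: int = 40) -> None:
    """Write (read_id, sequence) pairs as Phred+33 FASTQ with flat quality."""
    records = []
    for read_id, seq in reads:
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


# --------------------------------------------------------------------------- GTF

def write_gtf(genome: ToyGenome, path: str | os.PathLike, source: str = "circsponge") -> None:
    """Write gene/exon annotation as GTF (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for g in genome.genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write("\t".join([
                g.chromosome, source, "gene", str(g.start + 1), str(g.end),
                ".", g.strand, ".", attrs,
            ]) + "\n")
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write("\t".join([
                    g.chromosome, source, "exon", str(s + 1), str(e),
                    ".", g.strand, ".", attrs + f' exon_number "{i}";',
                ]) + "\n")


def read_gtf_genes(path: str | os.PathLike) -> list[GeneModel]:
    """Load gene models from a GTF file (exon features grouped by gene_id)."""
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = \
                line.rstrip("\n").split("\t")
            if feature != "exon":
                continue
            gene_id = _gtf_attr(attrs, "gene_id")
            if gene_id not in exons:
                exons[gene_id] = []
                meta[gene_id] = (chrom, strand)
                order.append(gene_id)
            exons[gene_id].append((int(start) - 1, int(end)))
    genes = []
    for gid in order:
        chrom, strand = meta[gid]
        genes.append(GeneModel(gid, chrom, strand, tuple(sorted(exons[gid]))))
    return genes


def _gtf_attr(attrs: str, key: str) -> str:
    for field in attrs.split(";"):
        field = field.strip()
        if field.startswith(key + " "):
            return field.split(" ", 1)[1].strip('"')
    raise ValueError(f"attribute {key!r} not found in {attrs!r}")


def load_genome(fasta: str | os.PathLike, gtf: str | os.PathLike | None = None) -> ToyGenome:
    chroms = read_fasta(fasta)
    genes = read_gtf_genes(gtf) if gtf is not None else []
    return ToyGenome(chromosomes=chroms, genes=genes)


# --------------------------------------------------------------------------- TSV

def write_tsv(df: pd.DataFrame, path: str | os.PathLike, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a features x samples TSV matrix (first column = feature id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    """Sample sheet TSV with columns sample, stage, replicate."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "stage", "replicate"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}")
    return df
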