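"""Toy genome and gene models used throughout the pipeline.

Coordinates are 0-based half-open everywhere inside the package; GTF I/O
converts to/from the 1-based inclusive convention of that format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """A multi-exon gene on one strand of a chromosome.

    ``exons`` are (start, end) pairs in genomic coordinates, sorted and
    non-overlapping regardless of strand; exon 1 of a minus-strand gene is
    therefore the *last* tuple.
    """

    gene_id: str
    chromosome: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: a gene needs at least one exon")
        for (s, e) in self.exons:
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty exon ({s},{e})")
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Genomic intervals between consecutive exons."""
        return tuple((e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]))

    def spliced_length(self, first: int = 0, last: int | None = None) -> int:
        """Total exonic length of exons [first, last] (genomic order)."""
        last = len(self.exons) - 1 if last is None else last
        return sum(e - s for s, e in self.exons[first:last + 1])


@dataclass
class ToyGenome:
    """A small multi-chromosome genome plus its gene annotation."""

    chromosomes: dict[str, str]
    genes: list[GeneModel] = field(default_factory=list)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def spliced_seq(self, gene: GeneModel, first: int = 0, last: int | None = None) -> str:
        """Sense-strand spliced sequence of exons [first, last] in genomic order.

        For minus-strand genes the genomic concatenation is reverse
        complemented, so the result always reads 5'->3' in transcript
        orientation.
        """
        chrom = self.chromosomes[gene.chromosome]
        last = len(gene.exons) - 1 if last is None else last
        seq = "".join(chrom[s:e] for s, e in gene.exons[first:last + 1])
        return seq if gene.strand == "+" else revcomp(seq)

    def validate(self) -> None:
        """Check gene/exon bounds and canonical GT..AG intron signals."""
        for g in self.genes:
            chrom = self.chromosomes.get(g.chromosome)
            if chrom is None:
                raise ValueError(f"{g.gene_id}: unknown chromosome {g.chromosome}")
            if g.end > len(chrom):
                raise ValueError(f"{g.gene_id}: exon beyond chromosome end")
            for s, e in g.introns:
                intron = chrom[s:e] if g.strand == "+" else revcomp(chrom[s:e])
                if not (intron.startswith("GT") and intron.endswith("AG")):
                    raise ValueError(f"{g.gene_id}: non-canonical intron {s}-{e}")
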