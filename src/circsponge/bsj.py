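"""Back-splice junction (BSJ) detection, circRNA classification and RPM.

The detector re-implements the anchor-split strategy used by classic
circRNA callers: reads that fail linear mapping are split into two terminal
anchors (default 20 nt); a junction is called when both anchors align
uniquely to the same chromosome and strand in *reversed* genomic order, the
breakpoint extension reconstructs the full read, and the flanking
dinucleotides are the canonical GT..AG splice signal.

Alignment is exact-match against a k-mer index of both genome strands,
which keeps the detector equivalent to an exhaustive enumeration oracle on
small genomes.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GeneModel, ToyGenome, revcomp

logger = logging.getLogger(__name__)

DEFAULT_ANCHOR_LEN = 20
DEFAULT_MIN_SUPPORT = 2
DEFAULT_MAX_SPAN = 100_000

GENOMIC_CLASSES = ("exonic", "intronic", "antisense", "intergenic")


@dataclass(frozen=True)
class AnchorHit:
    """A unique exact placement of one terminal anchor of a read."""

    read_id: str
    end: str  # 'left' or 'right'
    chromosome: str
    position: int  # 0-based, in strand-view coordinates
    strand: str
    unique: bool


@dataclass(frozen=True)
class BackspliceJunction:
    """A circular junction: acceptor at ``start``, donor at ``end`` (half-open)."""

    chromosome: str
    start: int
    end: int
    strand: str
    splice_signal: str = "GT/AG"
    support: int = 1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"BSJ start must precede end ({self.start} >= {self.end})")

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chromosome, self.start, self.end, self.strand)


@dataclass(frozen=True)
class CircAnnotation:
    circ_id: str
    bsj: BackspliceJunction
    genomic_class: str
    spliced_length: int
    source_gene: str | None

    def __post_init__(self) -> None:
        if self.genomic_class not in GENOMIC_CLASSES:
            raise ValueError(f"unknown genomic class {self.genomic_class!r}")
        if (self.genomic_class == "intergenic") != (self.source_gene is None):
            raise ValueError("intergenic <=> no source gene")


class GenomeIndex:
    """Exact k-mer index over both strands of every chromosome.

    Minus-strand positions are expressed in the coordinates of the
    reverse-complemented chromosome ("view" coordinates); `detect_bsj`
    converts back to genomic coordinates when a junction is emitted.
    """

    def __init__(self, genome: ToyGenome, k: int = DEFAULT_ANCHOR_LEN):
        self.k = k
        self.views: dict[tuple[str, str], str] = {}
        self._index: dict[str, list[tuple[str, str, int]]] = defaultdict(list)
        for chrom, seq in genome.chromosomes.items():
            for strand, view in (("+", seq), ("-", revcomp(seq))):
                self.views[(chrom, strand)] = view
                for i in range(len(view) - k + 1):
                    self._index[view[i:i + k]].append((chrom, strand, i))

    def hits(self, kmer: str) -> list[tuple[str, str, int]]:
        return self._index.get(kmer, [])


def linear_filter(reads: list[tuple[str, str]], genome: ToyGenome) -> list[tuple[str, str]]:
    """Drop reads that map contiguously to the genome or to a spliced transcript.

    Mapping is exact substring matching on either strand; what survives is
    the candidate set for back-splice detection.
    """
    if not reads:
        logger.warning("linear_filter: empty read set")
        return []
    references = list(genome.chromosomes.values())
    references += [genome.spliced_seq(g) for g in genome.genes]
    kept = []
    for read_id, seq in reads:
        rc = revcomp(seq)
        if any(seq in ref or rc in ref for ref in references):
            continue
        kept.append((read_id, seq))
    return kept


def detect_bsj(
    reads: list[tuple[str, str]],
    genome: ToyGenome,
    anchor_len: int = DEFAULT_ANCHOR_LEN,
    min_support: int = DEFAULT_MIN_SUPPORT,
    max_span: int = DEFAULT_MAX_SPAN,
    index: GenomeIndex | None = None,
) -> list[BackspliceJunction]:
    """Call back-splice junctions from linearly-unmapped reads.

    For each read both terminal ``anchor_len``-mers must place uniquely
    (exactly one exact hit over both strands of the whole genome), on the
    same chromosome and strand, with the right-end anchor upstream of the
    left-end anchor. Every breakpoint split that reconstructs the read
    exactly and is flanked by GT (donor side) and AG (acceptor side) is a
    candidate; ties are broken toward the leftmost donor. Junctions are
    aggregated over reads and reported when supported by at least
    ``min_support`` distinct reads.
    """
    if index is None:
        index = GenomeIndex(genome, k=anchor_len)
    elif index.k != anchor_len:
        raise ValueError("index k-mer size does not match anchor_len")
    support: dict[tuple[str, int, int, str], set[str]] = defaultdict(set)
    for read_id, seq in reads:
        if len(seq) < 2 * anchor_len:
            continue
        call = _call_read(seq, index, anchor_len, max_span)
        if call is not None:
            support[call].add(read_id)
    junctions = [
        BackspliceJunction(chrom, start, end, strand, "GT/AG", len(read_ids))
        for (chrom, start, end, strand), read_ids in support.items()
        if len(read_ids) >= min_support
    ]
    junctions.sort(key=lambda j: j.key)
    return junctions


def _call_read(
    seq: str, index: GenomeIndex, anchor_len: int, max_span: int
) -> tuple[str, int, int, str] | None:
    """Junction key implied by one read, or None if no consistent breakpoint."""
    A = anchor_len
    L = len(seq)
    left_hits = index.hits(seq[:A])
    right_hits = index.hits(seq[-A:])
    if len(left_hits) != 1 or len(right_hits) != 1:  # missing or multi-mapping anchor
        return None
    (lc, ls, lp), (rc, rs, rp) = left_hits[0], right_hits[0]
    if lc != rc or ls != rs:
        return None
    view = index.views[(lc, ls)]
    candidates = []
    for b in range(A, L - A + 1):
        donor_end = lp + b            # half-open end of the circle (donor side)
        acceptor_start = rp + A - (L - b)
        if acceptor_start < 2 or donor_end + 2 > len(view):
            continue
        if acceptor_start >= donor_end:
            continue
        if donor_end - acceptor_start > max_span:
            continue
        if view[lp:donor_end] != seq[:b]:
            continue
        if view[acceptor_start:acceptor_start + L - b] != seq[b:]:
            continue
        if view[donor_end:donor_end + 2] != "GT" or view[acceptor_start - 2:acceptor_start] != "AG":
            continue
        candidates.append((donor_end, acceptor_start))
    if not candidates:
        return None
    donor_end, acceptor_start = min(candidates)
    if ls == "+":
        return (lc, acceptor_start, donor_end, "+")
    n = len(view)
    return (lc, n - donor_end, n - acceptor_start, "-")


# --------------------------------------------------------------------- classification

def classify_circ(junction: BackspliceJunction, genes: list[GeneModel]) -> CircAnnotation:
    """Assign one genomic-origin class to a junction.

    exonic: both breakpoints coincide with exon boundaries of one same-strand
    gene (spliced length = sum of the circularized exons); intronic: wholly
    inside a single intron of a same-strand gene; antisense: overlaps genes
    on the opposite strand only; intergenic otherwise.
    """
    same = [g for g in genes if g.chromosome == junction.chromosome and g.strand == junction.strand]
    anti = [g for g in genes if g.chromosome == junction.chromosome and g.strand != junction.strand]
    span = junction.end - junction.start

    for g in sorted(same, key=lambda g: (g.start, g.gene_id)):
        starts = [s for s, _ in g.exons]
        ends = [e for _, e in g.exons]
        if junction.start in starts and junction.end in ends:
            first = starts.index(junction.start)
            last = ends.index(junction.end)
            if first <= last:
                return CircAnnotation(
                    circ_id="", bsj=junction, genomic_class="exonic",
                    spliced_length=g.spliced_length(first, last), source_gene=g.gene_id,
                )
    for g in sorted(same, key=lambda g: (g.start, g.gene_id)):
        for s, e in g.introns:
            if s <= junction.start and junction.end <= e:
                return CircAnnotation("", junction, "intronic", span, g.gene_id)
    overlapping_anti = [g for g in anti if g.start < junction.end and junction.start < g.end]
    overlapping_same = [g for g in same if g.start < junction.end and junction.start < g.end]
    if overlapping_anti and not overlapping_same:
        g = min(overlapping_anti, key=lambda g: (g.start, g.gene_id))
        return CircAnnotation("", junction, "antisense", span, g.gene_id)
    return CircAnnotation("", junction, "intergenic", span, None)


def build_catalog(junctions: list[BackspliceJunction], genes: list[GeneModel]) -> list[CircAnnotation]:
    """Classify and name junctions circ_000001.. in genomic sort order."""
    ordered = sorted(junctions, key=lambda j: j.key)
    catalog = []
    for i, j in enumerate(ordered, start=1):
        ann = classify_circ(j, genes)
        catalog.append(CircAnnotation(
            circ_id=f"circ_{i:06d}", bsj=ann.bsj, genomic_class=ann.genomic_class,
            spliced_length=ann.spliced_length, source_gene=ann.source_gene,
        ))
    return catalog


# --------------------------------------------------------------------- quantification

def quantify_rpm(counts: pd.DataFrame, mapped_totals: pd.Series | dict) -> pd.DataFrame:
    """Reads-per-million: RPM[f, s] = count[f, s] / mapped_total[s] * 1e6."""
    totals = pd.Series(mapped_totals, dtype=float).reindex(counts.columns)
    if totals.isna().any():
        missing = list(totals.index[totals.isna()])
        raise ValueError(f"missing mapped totals for samples {missing}")
    zero = totals.index[totals <= 0]
    if len(zero):
        raise ZeroDivisionError(f"zero mapped-read total for sample(s) {list(zero)}")
    return counts.div(totals, axis=1) * 1e6


# --------------------------------------------------------------------- summaries

def summarize_catalog(
    catalog: list[CircAnnotation],
    chromosomes: list[str] | None = None,
    bin_width: int = 100,
) -> dict[str, pd.DataFrame]:
    """Class counts, fixed-width length histogram and per-chromosome counts."""
    if not catalog:
        raise ValueError("empty catalog")
    classes = pd.Series([c.genomic_class for c in catalog])
    class_counts = classes.value_counts().reindex(GENOMIC_CLASSES, fill_value=0)

    lengths = np.array([c.spliced_length for c in catalog])
    n_bins = int(lengths.max() // bin_width) + 1
    edges = np.arange(0, (n_bins + 1) * bin_width, bin_width)
    hist, _ = np.histogram(lengths, bins=edges)
    length_hist = pd.DataFrame({
        "bin_start": edges[:-1], "bin_end": edges[1:], "count": hist,
    })

    chrom_names = chromosomes or sorted({c.bsj.chromosome for c in catalog})
    per_chrom = pd.Series([c.bsj.chromosome for c in catalog]).value_counts()
    chrom_counts = per_chrom.reindex(chrom_names, fill_value=0)

    return {
        "class_counts": class_counts.rename_axis("genomic_class").to_frame("count"),
        "length_histogram": length_hist,
        "chromosome_counts": chrom_counts.rename_axis("chromosome").to_frame("count"),
    }


def catalog_to_frame(catalog: list[CircAnnotation]) -> pd.DataFrame:
    return pd.DataFrame({
        "circ_id": [c.circ_id for c in catalog],
        "chromosome": [c.bsj.chromosome for c in catalog],
        "start": [c.bsj.start for c in catalog],
        "end": [c.bsj.end for c in catalog],
        "strand": [c.bsj.strand for c in catalog],
        "support": [c.bsj.support for c in catalog],
        "genomic_class": [c.genomic_class for c in catalog],
        "spliced_length": [c.spliced_length for c in catalog],
        "source_gene": [c.source_gene or "." for c in catalog],
    }).set_index("circ_id")


def catalog_to_bed(catalog: list[CircAnnotation]) -> pd.DataFrame:
    """6-column BED (0-based half-open), name=circ_id, score=read support."""
    return pd.DataFrame({
        "chrom": [c.bsj.chromosome for c in catalog],
        "start": [c.bsj.start for c in catalog],
        "end": [c.bsj.end for c in catalog],
        "name": [c.circ_id for c in catalog],
        "score": [c.bsj.support for c in catalog],
        "strand": [c.bsj.strand for c in catalog],
    })
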