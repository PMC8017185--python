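"""Synthetic data with planted ground truth.

Three generators cover every input the pipeline consumes:

* :func:`simulate_genome` — a small multi-chromosome genome with multi-exon
  genes whose introns carry canonical GT..AG signals, plus planted circles
  (internal exon runs designated for back-splicing).
* :func:`simulate_reads` — error-free (or uniformly perturbed) single-end
  reads: linear spliced-transcript reads and junction-spanning reads that
  cross each planted back-splice point.
* :func:`simulate_expression` — circRNA/miRNA/mRNA count matrices over
  3 developmental stages x 4 replicates with planted differential
  expression, planted monotone trends, and planted ceRNA triplets whose
  member sequences carry matching miRNA seed sites.

Every generator returns a full truth manifest so that detection, DE, trend
and network calls can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bsj import BackspliceJunction
from .genome import GeneModel, ToyGenome, revcomp

BASES = np.array(list("ACGT"))

STAGES = ("3M", "1Y", "3Y")
CONTRASTS = (("3M", "1Y"), ("1Y", "3Y"), ("3M", "3Y"))

# profile ids follow the lexicographic rank of the transition sign pattern
# (-1 < 0 < +1) over (3M->1Y, 1Y->3Y), with the flat (0,0) pattern excluded
PROFILE_ORDER = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the study design as defaults.

    The defaults encode the emulated design: three ordered stages with four
    replicates each, 150 nt reads, two 50 kb chromosomes carrying 40 genes
    of which 30 host a planted circle with spliced length concentrated
    around 400 nt (range 200-700).
    """

    seed: int = 0
    # genome
    n_chromosomes: int = 2
    chromosome_length: int = 50_000
    n_genes: int = 40
    n_circles: int = 30
    circle_length_range: tuple[int, int] = (200, 700)
    circle_length_mode: int = 430
    exon_length_range: tuple[int, int] = (80, 250)
    intron_length_range: tuple[int, int] = (60, 150)
    # reads
    read_length: int = 150
    anchor_length: int = 20
    junction_reads_range: tuple[int, int] = (2, 8)
    n_linear_reads: int = 500
    error_rate: float = 0.0
    # expression
    stages: tuple[str, ...] = STAGES
    n_replicates: int = 4
    n_circ_features: int = 60
    n_mirna_features: int = 40
    n_mrna_features: int = 80
    nb_dispersion: float = 0.1
    noise_sd: float = 0.1          # lognormal jitter (natural-log sd) on per-sample means
    de_fold: float = 4.0           # planted one-step DE fold
    triplet_fold: float = 8.0      # per-stage fold of planted triplet trajectories
    n_planted_triplets: int = 10
    n_trend_per_profile: int = 6   # planted circ trend features per profile in trend_profiles
    trend_profiles: tuple[int, ...] = (0, 1, 6)
    n_de_per_omic: int = 8         # additional plain one-step DE features per omic
    mirna_length: int = 21
    scrub_background_sites: bool = True
    junction_site_fraction: float = 0.25  # planted circ sites placed across the BSJ

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        for name in ("n_chromosomes", "chromosome_length", "read_length",
                     "n_replicates", "n_circ_features", "n_mirna_features",
                     "n_mrna_features"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        if self.n_circles > self.n_genes:
            raise ValueError("n_circles cannot exceed n_genes")
        if self.circle_length_range[0] < self.read_length:
            raise ValueError("planted circles must be at least one read long")
        needed = self.n_planted_triplets
        if needed > min(self.n_circ_features, self.n_mirna_features, self.n_mrna_features):
            raise ValueError("n_planted_triplets exceeds available features")

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class PlantedCircle:
    """An internal exon run of one gene designated for back-splicing."""

    circle_id: str
    gene_id: str
    exon_first: int              # genomic exon indices into GeneModel.exons
    exon_last: int
    bsj: BackspliceJunction
    spliced_length: int
    n_reads: int


@dataclass
class SimulatedExpression:
    """Tri-omic count matrices plus the complete planted truth."""

    counts: dict[str, pd.DataFrame]          # omic -> features x samples
    sample_sheet: pd.DataFrame               # sample, stage, replicate
    truth: pd.DataFrame                      # one row per feature (closed over all matrices)
    triplets: pd.DataFrame                   # planted (circ, mir, mrna) triplets
    target_sites: pd.DataFrame               # planted seed sites
    mirna_seqs: dict[str, str]
    transcript_seqs: dict[str, str]          # circ + mRNA transcript sequences
    circular_ids: set[str]


# ============================================================== genome simulation

def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=n)]


def _partition(rng: np.random.Generator, total: int, parts: int, minimum: int) -> list[int]:
    """Random composition of `total` into `parts` parts each >= minimum."""
    spare = total - parts * minimum
    if spare < 0:
        raise ValueError("total too small for partition")
    cuts = np.sort(rng.integers(0, spare + 1, size=parts - 1))
    sizes = np.diff(np.concatenate([[0], cuts, [spare]]))
    return [minimum + int(s) for s in sizes]


def _circle_target_lengths(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    lo, hi = cfg.circle_length_range
    return np.rint(rng.triangular(lo, cfg.circle_length_mode, hi, size=cfg.n_circles)).astype(int)


def simulate_genome(config: SimulationConfig) -> tuple[ToyGenome, list[PlantedCircle]]:
    """Build the toy genome, its gene models and the planted circles.

    Circle-hosting genes are built around their circle: the circularized
    exon run sums exactly to a target length drawn from a triangular
    distribution over ``circle_length_range`` peaking near 400 nt, and is
    flanked by at least one exon on each side so the back-splice breakpoints
    fall on internal exon boundaries with GT/AG intron signals.
    """
    rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_seqs = {name: _random_seq(rng, config.chromosome_length) for name in chrom_names}

    targets = _circle_target_lengths(rng, config)
    host = rng.permutation(config.n_genes) < config.n_circles
    circle_idx = 0

    genes: list[GeneModel] = []
    circles: list[PlantedCircle] = []
    cursors = {name: 200 for name in chrom_names}
    gap_lo, gap_hi = 100, 300
    exon_lo, exon_hi = config.exon_length_range
    intron_lo, intron_hi = config.intron_length_range

    for gi in range(config.n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        if host[gi]:
            T = int(targets[circle_idx])
            k = min(3, max(1, T // 180))
            # terminal run exons >= 100 nt so a junction read's two flanks can
            # both lie inside them (contiguous anchor extension stays possible)
            run_lengths = _partition(rng, T, k, 100 if k > 1 else 60)
            n_pre = int(rng.integers(1, 3))
            n_post = int(rng.integers(1, 3))
            exon_lengths = (
                [int(rng.integers(exon_lo, exon_hi + 1)) for _ in range(n_pre)]
                + run_lengths
                + [int(rng.integers(exon_lo, exon_hi + 1)) for _ in range(n_post)]
            )
            run = (n_pre, n_pre + k - 1)
        else:
            n_exons = int(rng.integers(4, 8))
            exon_lengths = [int(rng.integers(exon_lo, exon_hi + 1)) for _ in range(n_exons)]
            run = None
        intron_lengths = [int(rng.integers(intron_lo, intron_hi + 1))
                          for _ in range(len(exon_lengths) - 1)]
        footprint = sum(exon_lengths) + sum(intron_lengths)

        chrom = chrom_names[gi % len(chrom_names)]
        if cursors[chrom] + footprint + 200 > config.chromosome_length:
            placed = False
            for alt in chrom_names:
                if cursors[alt] + footprint + 200 <= config.chromosome_length:
                    chrom = alt
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    "genome_length too small to place all genes; increase "
                    "chromosome_length or reduce n_genes"
                )
        start = cursors[chrom] + int(rng.integers(gap_lo, gap_hi))
        exons = []
        pos = start
        seq = chrom_seqs[chrom]
        for j, el in enumerate(exon_lengths):
            exons.append((pos, pos + el))
            pos += el
            if j < len(intron_lengths):
                il = intron_lengths[j]
                # canonical splice signal on the gene strand
                if strand == "+":
                    seq[pos:pos + 2] = list("GT")
                    seq[pos + il - 2:pos + il] = list("AG")
                else:
                    seq[pos:pos + 2] = list("CT")      # revcomp(AG)
                    seq[pos + il - 2:pos + il] = list("AC")  # revcomp(GT)
                pos += il
        cursors[chrom] = pos
        gene = GeneModel(f"gene_{gi + 1:03d}", chrom, strand, tuple(exons))
        genes.append(gene)

        if run is not None:
            first, last = run
            bsj = BackspliceJunction(
                chromosome=chrom,
                start=exons[first][0],
                end=exons[last][1],
                strand=strand,
            )
            n_reads = int(rng.integers(*config.junction_reads_range, endpoint=True))
            circles.append(PlantedCircle(
                circle_id=f"pcirc_{circle_idx + 1:02d}",
                gene_id=gene.gene_id,
                exon_first=first,
                exon_last=last,
                bsj=bsj,
                spliced_length=sum(exons[i][1] - exons[i][0] for i in range(first, last + 1)),
                n_reads=n_reads,
            ))
            circle_idx += 1

    genome = ToyGenome(chromosomes={k: "".join(v) for k, v in chrom_seqs.items()}, genes=genes)
    genome.validate()
    return genome, circles


def circles_to_frame(circles: list[PlantedCircle]) -> pd.DataFrame:
    return pd.DataFrame({
        "circle_id": [c.circle_id for c in circles],
        "gene_id": [c.gene_id for c in circles],
        "exon_first": [c.exon_first for c in circles],
        "exon_last": [c.exon_last for c in circles],
        "chromosome": [c.bsj.chromosome for c in circles],
        "start": [c.bsj.start for c in circles],
        "end": [c.bsj.end for c in circles],
        "strand": [c.bsj.strand for c in circles],
        "spliced_length": [c.spliced_length for c in circles],
        "n_reads": [c.n_reads for c in circles],
    }).set_index("circle_id")


# ================================================================ read simulation

def simulate_reads(
    genome: ToyGenome,
    circles: list[PlantedCircle],
    config: SimulationConfig,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Emit single-end reads plus a per-read origin manifest.

    Junction-spanning reads cross each planted back-splice point with both
    flanks at least ``anchor_length`` long, i.e. the read is a window of the
    circularized transcript rotated across the junction.
    """
    rng = np.random.default_rng(config.seed + 1)
    L, A = config.read_length, config.anchor_length
    reads: list[tuple[str, str]] = []
    rows = []

    for circle in circles:
        gene = genome.gene(circle.gene_id)
        circ_seq = genome.spliced_seq(gene, circle.exon_first, circle.exon_last)
        if len(circ_seq) < L:
            raise ValueError(
                f"{circle.circle_id}: circle shorter than read_length "
                f"({len(circ_seq)} < {L}); cannot span its junction"
            )
        # flank lengths bounded by the terminal circularized exons (transcript
        # order): the donor-side flank is the transcript-last exon of the run
        exon_len = [e - s for s, e in gene.exons]
        if gene.strand == "+":
            len_donor, len_acceptor = exon_len[circle.exon_last], exon_len[circle.exon_first]
        else:
            len_donor, len_acceptor = exon_len[circle.exon_first], exon_len[circle.exon_last]
        b_lo = max(A, L - len_acceptor)
        b_hi = min(L - A, len_donor)
        if b_lo > b_hi:
            raise ValueError(f"{circle.circle_id}: terminal exons too short to span junction")
        for _ in range(circle.n_reads):
            b = int(rng.integers(b_lo, b_hi + 1))  # donor-side flank length
            seq = circ_seq[-b:] + circ_seq[:L - b]
            read_id = f"read_{len(reads) + 1:06d}"
            reads.append((read_id, seq))
            rows.append(dict(read_id=read_id, origin="bsj", gene_id=gene.gene_id,
                             circle_id=circle.circle_id, chromosome=circle.bsj.chromosome,
                             start=circle.bsj.start, end=circle.bsj.end,
                             strand=circle.bsj.strand, split=b))

    eligible = [g for g in genome.genes
                if sum(e - s for s, e in g.exons) >= L]
    if config.n_linear_reads > 0 and not eligible:
        raise ValueError("no gene long enough to draw linear reads from")
    for _ in range(config.n_linear_reads):
        gene = eligible[int(rng.integers(len(eligible)))]
        tx = genome.spliced_seq(gene)
        pos = int(rng.integers(0, len(tx) - L + 1))
        seq = tx[pos:pos + L]
        read_id = f"read_{len(reads) + 1:06d}"
        reads.append((read_id, seq))
        rows.append(dict(read_id=read_id, origin="linear", gene_id=gene.gene_id,
                         circle_id=".", chromosome=gene.chromosome,
                         start=-1, end=-1, strand=gene.strand, split=-1))

    if config.error_rate > 0:
        reads = [(rid, _perturb(rng, seq, config.error_rate)) for rid, seq in reads]

    manifest = pd.DataFrame(rows).set_index("read_id")
    return reads, manifest


def _perturb(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if hit.any():
        shift = rng.integers(1, 4, size=int(hit.sum()))
        base_idx = np.searchsorted(BASES, arr[hit])
        arr[hit] = BASES[(base_idx + shift) % 4]
    return "".join(arr)


# =========================================================== expression simulation

def seed_sites(mirna_seq: str) -> tuple[str, str]:
    """The two canonical 7 nt seed-match site patterns of a miRNA.

    7mer-m8: reverse complement of miRNA positions 2-8; 7mer-A1: reverse
    complement of positions 2-7 followed by an A opposite position 1.
    """
    return revcomp(mirna_seq[1:8]), revcomp(mirna_seq[1:7]) + "A"


def _profile_means(profile: int, base: float, fold: float) -> tuple[float, float, float]:
    """Stage means realizing one trend profile with the given per-step fold."""
    s1, s2 = PROFILE_ORDER[profile]
    m1 = base
    m2 = m1 * fold ** s1
    m3 = m2 * fold ** s2
    return (m1, m2, m3)


def _sample_counts(
    rng: np.random.Generator,
    stage_means: np.ndarray,            # features x stages
    config: SimulationConfig,
) -> np.ndarray:
    """NB counts around per-sample means with lognormal jitter and library factors."""
    n_feat, n_stage = stage_means.shape
    n_rep = config.n_replicates
    lib = rng.uniform(0.7, 1.3, size=n_stage * n_rep)
    mu = np.repeat(stage_means, n_rep, axis=1) * lib[None, :]
    if config.noise_sd > 0:
        mu = mu * rng.lognormal(0.0, config.noise_sd, size=mu.shape)
    phi = config.nb_dispersion
    if phi <= 0:
        return rng.poisson(mu)
    r = 1.0 / phi
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_expression(config: SimulationConfig) -> SimulatedExpression:
    """Generate the tri-omic matrices, sequences and the full truth manifest.

    Planted structure, in feature-index order per omic:

    * triplet features (circ/miR/mRNA index t): monotone per-stage fold of
      ``triplet_fold`` with the miRNA opposing circ and mRNA; circ and mRNA
      means proportional (population Spearman -> -1, Pearson -> +1 before
      replicate noise). Direction alternates with t.
    * circ trend features: stage means realizing each profile in
      ``trend_profiles`` with fold ``de_fold``.
    * plain DE features per omic: one ``de_fold`` step at a random contrast.
    * all remaining features: flat means, log-uniform in [50, 2000].
    """
    rng = np.random.default_rng(config.seed + 2)
    stages = list(config.stages)
    n_stage = len(stages)
    samples = [f"{st}_{r + 1}" for st in stages for r in range(config.n_replicates)]
    sheet = pd.DataFrame({
        "sample": samples,
        "stage": [st for st in stages for _ in range(config.n_replicates)],
        "replicate": [r + 1 for _ in stages for r in range(config.n_replicates)],
    })

    ids = {
        "circ": [f"circ_{i + 1:03d}" for i in range(config.n_circ_features)],
        "mir": [f"mir_{i + 1:03d}" for i in range(config.n_mirna_features)],
        "mrna": [f"mrna_{i + 1:03d}" for i in range(config.n_mrna_features)],
    }
    means = {
        omic: np.tile(np.exp(rng.uniform(np.log(50), np.log(2000), size=len(ids[omic])))[:, None],
                      (1, n_stage))
        for omic in ids
    }
    trend_truth = {omic: np.full(len(ids[omic]), -1, dtype=int) for omic in ids}
    triplet_membership: dict[str, list[str]] = {f: [] for omic in ids for f in ids[omic]}

    # ---- planted triplets
    trip_rows = []
    for t in range(config.n_planted_triplets):
        down = t % 2 == 0  # circ/mRNA decreasing, miRNA increasing
        circ_base = rng.uniform(100, 400)
        mir_base = rng.uniform(50, 200)
        ratio = rng.uniform(0.5, 2.0)
        f = config.triplet_fold
        steps = np.array([f ** 2, f, 1.0]) if down else np.array([1.0, f, f ** 2])
        anti = steps[::-1]
        means["circ"][t] = circ_base * steps
        means["mrna"][t] = circ_base * ratio * steps
        means["mir"][t] = mir_base * anti
        profile = 0 if down else 7
        trend_truth["circ"][t] = profile
        trend_truth["mrna"][t] = profile
        trend_truth["mir"][t] = 7 - profile
        tid = f"triplet_{t + 1:02d}"
        for key in (ids["circ"][t], ids["mir"][t], ids["mrna"][t]):
            triplet_membership[key].append(tid)
        trip_rows.append(dict(triplet_id=tid, circ_id=ids["circ"][t],
                              mirna_id=ids["mir"][t], mrna_id=ids["mrna"][t],
                              direction="down" if down else "up"))
    triplets = pd.DataFrame(
        trip_rows, columns=["triplet_id", "circ_id", "mirna_id", "mrna_id", "direction"]
    )

    # ---- planted circ trend features
    cursor = {omic: config.n_planted_triplets for omic in ids}
    for profile in config.trend_profiles:
        for _ in range(config.n_trend_per_profile):
            i = cursor["circ"]
            if i >= len(ids["circ"]):
                raise ValueError("n_circ_features too small for planted trends")
            base = rng.uniform(100, 500)
            means["circ"][i] = _profile_means(profile, base, config.de_fold)
            trend_truth["circ"][i] = profile
            cursor["circ"] += 1

    # ---- plain one-step DE features per omic
    for omic in ids:
        for _ in range(config.n_de_per_omic):
            i = cursor[omic]
            if i >= len(ids[omic]):
                raise ValueError(f"n_{omic}_features too small for planted DE")
            step = int(rng.integers(0, n_stage - 1))       # transition index
            up = bool(rng.integers(0, 2))
            base = rng.uniform(100, 500)
            m = np.full(n_stage, base)
            factor = config.de_fold if up else 1.0 / config.de_fold
            m[step + 1:] = base * factor
            means[omic][i] = m
            signs = tuple(
                (1 if m[j + 1] > 2 * m[j] else -1 if m[j + 1] < m[j] / 2 else 0)
                for j in range(n_stage - 1)
            )
            if signs in PROFILE_ORDER:
                trend_truth[omic][i] = PROFILE_ORDER.index(signs)
            cursor[omic] += 1

    # ---- counts
    counts = {}
    for omic in ids:
        mat = _sample_counts(rng, means[omic], config)
        counts[omic] = pd.DataFrame(mat, index=ids[omic], columns=samples)

    # ---- sequences and planted seed sites
    mirna_seqs = _simulate_mirnas(rng, ids["mir"], config)
    transcript_seqs, target_sites = _simulate_transcripts(
        rng, ids, triplets, mirna_seqs, config)

    # ---- truth manifest (closed over every matrix feature)
    truth = _truth_frame(ids, means, trend_truth, triplet_membership, config)

    return SimulatedExpression(
        counts=counts,
        sample_sheet=sheet,
        truth=truth,
        triplets=triplets,
        target_sites=target_sites,
        mirna_seqs=mirna_seqs,
        transcript_seqs=transcript_seqs,
        circular_ids=set(ids["circ"]),
    )


def _simulate_mirnas(
    rng: np.random.Generator, mir_ids: list[str], config: SimulationConfig
) -> dict[str, str]:
    """Random miRNAs whose two site patterns are pairwise distinct."""
    seen: set[str] = set()
    out = {}
    for mid in mir_ids:
        for _ in range(100):
            seq = "".join(_random_seq(rng, config.mirna_length))
            m8, a1 = seed_sites(seq)
            if m8 not in seen and a1 not in seen and m8 != a1:
                seen.update((m8, a1))
                out[mid] = seq
                break
        else:
            raise RuntimeError("could not draw distinct miRNA seeds")
    return out


def _simulate_transcripts(
    rng: np.random.Generator,
    ids: dict[str, list[str]],
    triplets: pd.DataFrame,
    mirna_seqs: dict[str, str],
    config: SimulationConfig,
) -> tuple[dict[str, str], pd.DataFrame]:
    seqs: dict[str, list[str]] = {}
    for cid in ids["circ"]:
        seqs[cid] = list(_random_seq(rng, int(rng.integers(250, 601))))
    for mid in ids["mrna"]:
        seqs[mid] = list(_random_seq(rng, int(rng.integers(400, 801))))

    planted: dict[str, list[tuple[int, int]]] = {tid: [] for tid in seqs}
    site_rows = []
    for t, row in enumerate(triplets.itertuples()):
        m8, a1 = seed_sites(mirna_seqs[row.mirna_id])
        site_type = "7mer-m8" if t % 2 == 0 else "7mer-A1"
        site = m8 if t % 2 == 0 else a1
        # circ site: optionally wrapped across the back-splice junction
        cseq = seqs[row.circ_id]
        n = len(cseq)
        if rng.random() < config.junction_site_fraction:
            k = int(rng.integers(1, 7))  # bases on the donor (tail) side
            for j in range(7):
                cseq[(n - k + j) % n] = site[j]
            pos = n - k
        else:
            pos = int(rng.integers(0, n - 7))
            cseq[pos:pos + 7] = list(site)
        planted[row.circ_id].append((pos, 7))
        site_rows.append(dict(mirna_id=row.mirna_id, transcript_id=row.circ_id,
                              kind="circ", site_type=site_type, position=pos))
        rseq = seqs[row.mrna_id]
        rpos = int(rng.integers(0, len(rseq) - 7))
        rseq[rpos:rpos + 7] = list(site)
        planted[row.mrna_id].append((rpos, 7))
        site_rows.append(dict(mirna_id=row.mirna_id, transcript_id=row.mrna_id,
                              kind="mRNA", site_type=site_type, position=rpos))

    out = {tid: "".join(s) for tid, s in seqs.items()}
    if config.scrub_background_sites:
        patterns = set()
        for seq in mirna_seqs.values():
            patterns.update(seed_sites(seq))
        for tid in out:
            circular = tid in set(ids["circ"])
            out[tid] = _scrub(rng, out[tid], patterns, planted[tid], circular)
    sites = pd.DataFrame(
        site_rows, columns=["mirna_id", "transcript_id", "kind", "site_type", "position"]
    )
    return out, sites


def _scrub(
    rng: np.random.Generator,
    seq: str,
    patterns: set[str],
    planted: list[tuple[int, int]],
    circular: bool,
) -> str:
    """Mutate accidental seed-site matches, leaving planted sites untouched."""
    keep = set()
    n = len(seq)
    for pos, length in planted:
        keep.update((pos + j) % n for j in range(length))
    arr = list(seq)
    for _ in range(100):
        scan = "".join(arr) + ("".join(arr[:6]) if circular else "")
        hit = None
        for pat in patterns:
            start = scan.find(pat)
            while start != -1:
                positions = [(start + j) % n for j in range(7)]
                if not all(p in keep for p in positions):
                    hit = [p for p in positions if p not in keep]
                    break
                start = scan.find(pat, start + 1)
            if hit:
                break
        if hit is None:
            return "".join(arr)
        p = hit[len(hit) // 2]
        arr[p] = BASES[(int(np.searchsorted(BASES, arr[p])) + 1 + int(rng.integers(0, 3))) % 4]
    raise RuntimeError("failed to scrub accidental seed sites")


def _truth_frame(ids, means, trend_truth, triplet_membership, config) -> pd.DataFrame:
    rows = []
    n_stage = len(config.stages)
    for omic in ids:
        for i, fid in enumerate(ids[omic]):
            m = means[omic][i]
            row = dict(feature_id=fid, omic=omic)
            for j, st in enumerate(config.stages):
                row[f"mean_{st}"] = m[j]
            for (a, b) in CONTRASTS:
                ia, ib = config.stages.index(a), config.stages.index(b)
                fold = (m[ib] + 1e-300) / (m[ia] + 1e-300)
                row[f"de_{a}_vs_{b}"] = bool(fold > 2.0 or fold < 0.5)
            row["trend_profile"] = int(trend_truth[omic][i])
            row["triplet_ids"] = ";".join(triplet_membership[fid]) or "."
            rows.append(row)
    return pd.DataFrame(rows).set_index("feature_id")
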