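"""ceRNA (circRNA-miRNA-mRNA) network inference.

miRNA targets are predicted by transparent seed matching (7mer-m8 and
7mer-A1 sites, with circRNA sequences scanned circularly so that
junction-crossing sites are found). Candidate triplets that share a miRNA
between a circRNA and an mRNA are then filtered by the three co-expression
criteria of the emulated analysis:

1. Spearman correlation of each transcript with the miRNA < -0.7,
2. Pearson correlation between circRNA and mRNA > +0.9,
3. hypergeometric shared-sponge test p < 0.05,

with correlations computed on log2(RPM + 1). The same hypergeometric upper
tail also powers an annotation-agnostic gene-set over-representation test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .genome import revcomp

logger = logging.getLogger(__name__)

DEFAULT_SCC_MAX = -0.7
DEFAULT_PCC_MIN = 0.9
DEFAULT_SPONGE_ALPHA = 0.05


@dataclass(frozen=True)
class TargetEdge:
    mirna_id: str
    transcript_id: str
    transcript_kind: str        # 'circ' or 'mRNA'
    site_count: int
    site_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.site_count != len(self.site_positions):
            raise ValueError("site_count must equal number of site positions")
        if self.site_count < 1:
            raise ValueError("an edge needs at least one site")


# ------------------------------------------------------------------ seed matching

def seed_site_patterns(mirna_seq: str) -> dict[str, str]:
    """7 nt site patterns: 7mer-m8 (revcomp of positions 2-8) and 7mer-A1
    (revcomp of positions 2-7 followed by A opposite position 1)."""
    if len(mirna_seq) < 8:
        raise ValueError("miRNA must be at least 8 nt for seed matching")
    m = mirna_seq.upper().replace("U", "T")
    return {"7mer-m8": revcomp(m[1:8]), "7mer-A1": revcomp(m[1:7]) + "A"}


def find_seed_sites(mirna_seq: str, transcript: str, circular: bool = False) -> list[int]:
    """Start positions (0-based, transcript coordinates) of seed-match sites.

    Circular transcripts are scanned with a 6 nt wrap so sites crossing the
    back-splice junction are reported (position modulo transcript length).
    A position matching both site types is reported once.
    """
    patterns = seed_site_patterns(mirna_seq)
    t = transcript.upper().replace("U", "T")
    n = len(t)
    if n < 7:
        return []
    scan = t + (t[:6] if circular else "")
    hits: set[int] = set()
    for pat in patterns.values():
        start = scan.find(pat)
        while start != -1:
            hits.add(start % n)
            start = scan.find(pat, start + 1)
    return sorted(hits)


def predict_targets(
    mirna_seqs: dict[str, str],
    transcript_seqs: dict[str, str],
    circular_ids: set[str] | None = None,
) -> list[TargetEdge]:
    """All seed-match target edges between miRNAs and transcripts."""
    circular_ids = circular_ids or set()
    edges = []
    for mid, mseq in mirna_seqs.items():
        for tid, tseq in transcript_seqs.items():
            circ = tid in circular_ids
            sites = find_seed_sites(mseq, tseq, circular=circ)
            if sites:
                edges.append(TargetEdge(
                    mirna_id=mid, transcript_id=tid,
                    transcript_kind="circ" if circ else "mRNA",
                    site_count=len(sites), site_positions=tuple(sites),
                ))
    return edges


def edges_to_frame(edges: list[TargetEdge]) -> pd.DataFrame:
    return pd.DataFrame({
        "mirna_id": [e.mirna_id for e in edges],
        "transcript_id": [e.transcript_id for e in edges],
        "transcript_kind": [e.transcript_kind for e in edges],
        "site_count": [e.site_count for e in edges],
        "site_positions": [",".join(map(str, e.site_positions)) for e in edges],
    })


# ------------------------------------------------------------------- correlations

def _validate_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return x, y


def _midranks(x: np.ndarray) -> np.ndarray:
    """Mid-ranks (1-based, ties get the average rank)."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    sx = x[order]
    i = 0
    while i < len(sx):
        j = i
        while j + 1 < len(sx) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def pearson(x, y) -> float:
    """Product-moment correlation coefficient."""
    x, y = _validate_pair(x, y)
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.dot(xc, yc) / math.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))


def spearman(x, y) -> float:
    """Rank correlation: Pearson correlation of mid-ranks."""
    x, y = _validate_pair(x, y)
    return pearson(_midranks(x), _midranks(y))


# ---------------------------------------------------------------- sponge test

def _log_choose(n: float, k: float) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def sponge_test(N: int, K: int, n: int, x: int) -> float:
    """Upper-tail hypergeometric p-value for shared miRNA sponging.

    With N background miRNAs of which K target the circRNA, and n targeting
    the mRNA, the probability of sharing at least x miRNAs by chance is
    P(X >= x) with X ~ Hypergeometric(N, K, n), evaluated exactly in log
    space (no normal approximation).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K, n <= N")
    if x > min(K, n):
        raise ValueError("shared count x cannot exceed min(K, n)")
    if x <= 0:
        return 1.0
    log_total = _log_choose(N, n)
    # terms with n - k > N - K are impossible (probability zero)
    terms = [
        _log_choose(K, k) + _log_choose(N - K, n - k) - log_total
        for k in range(max(x, n - (N - K)), min(K, n) + 1)
    ]
    if not terms:
        return 0.0
    m = max(terms)
    p = math.exp(m) * sum(math.exp(t - m) for t in terms)
    return float(min(1.0, p))


# ---------------------------------------------------------------- network build

def build_network(
    rpm: dict[str, pd.DataFrame],
    edges: list[TargetEdge] | pd.DataFrame,
    de_features: dict[str, set] | None = None,
    scc_max: float = DEFAULT_SCC_MAX,
    pcc_min: float = DEFAULT_PCC_MIN,
    sponge_alpha: float = DEFAULT_SPONGE_ALPHA,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Evaluate every candidate (circ, miR, mRNA) triplet.

    ``rpm`` maps 'circ'/'mir'/'mrna' to RPM matrices sharing sample columns.
    A candidate exists when one miRNA has a target edge to both a circRNA
    and an mRNA; when ``de_features`` is given (omic -> feature ids),
    candidates are restricted to differentially expressed features.
    Correlations are computed on log2(RPM + 1); the sponge-test background N
    is the number of miRNAs expressed (nonzero in >= 1 sample).
    """
    if isinstance(edges, list):
        edges = edges_to_frame(edges)
    for omic in ("circ", "mir", "mrna"):
        if omic not in rpm:
            raise ValueError(f"missing {omic!r} matrix")
    samples = list(rpm["circ"].columns)
    if list(rpm["mir"].columns) != samples or list(rpm["mrna"].columns) != samples:
        raise ValueError("matrices must share identical sample columns")

    expressed_mirs = set(rpm["mir"].index[(rpm["mir"] > 0).any(axis=1)])
    N = len(expressed_mirs)

    circ_edges = edges[edges["transcript_kind"] == "circ"]
    mrna_edges = edges[edges["transcript_kind"] == "mRNA"]
    targets_of: dict[str, set] = {}          # transcript -> expressed miRNAs targeting it
    for sub in (circ_edges, mrna_edges):
        for tid, grp in sub.groupby("transcript_id"):
            targets_of[tid] = set(grp["mirna_id"]) & expressed_mirs

    def allowed(omic: str, fid: str) -> bool:
        if de_features is None:
            return True
        return fid in de_features.get(omic, set())

    mat = {k: (np.log2(v + 1.0) if log_transform else v.astype(float)) for k, v in rpm.items()}
    circ_by_mir = circ_edges.groupby("mirna_id")["transcript_id"].agg(list)
    mrna_by_mir = mrna_edges.groupby("mirna_id")["transcript_id"].agg(list)

    corr_cache: dict[tuple[str, str, str], float] = {}

    def corr(kind: str, omic1: str, f1: str, omic2: str, f2: str) -> float:
        key = (kind, f1, f2)
        if key not in corr_cache:
            func = spearman if kind == "scc" else pearson
            try:
                val = func(mat[omic1].loc[f1].to_numpy(), mat[omic2].loc[f2].to_numpy())
            except ValueError:
                val = float("nan")
            corr_cache[key] = val
        return corr_cache[key]

    sponge_cache: dict[tuple[str, str], tuple[int, float]] = {}
    rows = []
    mirs = sorted(set(circ_by_mir.index) & set(mrna_by_mir.index) & expressed_mirs)
    for mid in mirs:
        if not allowed("mir", mid):
            continue
        circs = [c for c in circ_by_mir[mid] if allowed("circ", c) and c in rpm["circ"].index]
        mrnas = [r for r in mrna_by_mir[mid] if allowed("mrna", r) and r in rpm["mrna"].index]
        for cid in circs:
            scc_cm = corr("scc", "circ", cid, "mir", mid)
            for rid in mrnas:
                scc_rm = corr("scc", "mrna", rid, "mir", mid)
                pcc = corr("pcc", "circ", cid, "mrna", rid)
                pair = (cid, rid)
                if pair not in sponge_cache:
                    shared = len(targets_of.get(cid, set()) & targets_of.get(rid, set()))
                    p = sponge_test(N, len(targets_of.get(cid, set())),
                                    len(targets_of.get(rid, set())), shared)
                    sponge_cache[pair] = (shared, p)
                shared, sponge_p = sponge_cache[pair]
                passes = (
                    not np.isnan(scc_cm) and not np.isnan(scc_rm) and not np.isnan(pcc)
                    and scc_cm < scc_max and scc_rm < scc_max
                    and pcc > pcc_min and sponge_p < sponge_alpha
                )
                rows.append(dict(
                    circ_id=cid, mirna_id=mid, mrna_id=rid,
                    scc_circ_mir=scc_cm, scc_mrna_mir=scc_rm, pcc_circ_mrna=pcc,
                    shared_mirnas=shared, sponge_p=sponge_p, passes=passes,
                ))
    if not rows:
        logger.warning("build_network: empty candidate set")
    columns = ["circ_id", "mirna_id", "mrna_id", "scc_circ_mir", "scc_mrna_mir",
               "pcc_circ_mrna", "shared_mirnas", "sponge_p", "passes"]
    return pd.DataFrame(rows, columns=columns)


def network_graph(triplets: pd.DataFrame) -> nx.Graph:
    """Undirected graph of the passing triplets (circ-miR and miR-mRNA edges)."""
    g = nx.Graph()
    for row in triplets[triplets["passes"]].itertuples():
        g.add_node(row.circ_id, kind="circ")
        g.add_node(row.mirna_id, kind="mir")
        g.add_node(row.mrna_id, kind="mrna")
        g.add_edge(row.circ_id, row.mirna_id, interaction="circ-mir",
                   scc=float(row.scc_circ_mir))
        g.add_edge(row.mirna_id, row.mrna_id, interaction="mir-mrna",
                   scc=float(row.scc_mrna_mir))
    return g


def write_sif(triplets: pd.DataFrame, path) -> None:
    """Passing subgraph in simple-interaction format (node <tab> type <tab> node)."""
    lines = set()
    for row in triplets[triplets["passes"]].itertuples():
        lines.add(f"{row.circ_id}\tsponges\t{row.mirna_id}")
        lines.add(f"{row.mirna_id}\ttargets\t{row.mrna_id}")
    with open(path, "w") as fh:
        for line in sorted(lines):
            fh.write(line + "\n")


def write_graphml(triplets: pd.DataFrame, path) -> None:
    nx.write_graphml(network_graph(triplets), str(path))


# ------------------------------------------------------------ over-representation

def overrepresentation(
    study: set[str],
    gene_sets: dict[str, set[str]],
    background: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of a study set in named gene sets.

    For each set the upper tail P(X >= x) is evaluated on (|background|,
    |set & background|, |study|, |set & study|); Benjamini-Hochberg FDR is
    reported across sets.
    """
    if not study:
        return pd.DataFrame(
            columns=["set_size", "study_size", "overlap", "p_value", "fdr"]
        ).rename_axis("gene_set")
    if not study <= background:
        raise ValueError("study set must be a subset of the background")
    N = len(background)
    n = len(study)
    names, rows = [], []
    for name, members in gene_sets.items():
        K = len(members & background)
        x = len(members & study)
        p = sponge_test(N, K, n, x)
        names.append(name)
        rows.append((K, n, x, p))
    frame = pd.DataFrame(rows, index=pd.Index(names, name="gene_set"),
                         columns=["set_size", "study_size", "overlap", "p_value"])
    from statsmodels.stats.multitest import multipletests
    frame["fdr"] = multipletests(frame["p_value"].to_numpy(), method="fdr_bh")[1]
    return frame


def read_gmt(path) -> dict[str, set[str]]:
    """Gene sets in GMT format: name <tab> description <tab> members..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3 and parts[0]:
                sets[parts[0]] = set(filter(None, parts[2:]))
    return sets
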