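"""Independent brute-force oracles shared by the test modules.

Each oracle recomputes a quantity by exhaustive enumeration or a direct
textbook formula, deliberately avoiding the code paths it checks.
"""

import itertools

import numpy as np
from scipy import stats

from circsponge.genome import revcomp


def hypergeom_enumeration(N, K, n, x):
    """Brute-force P(X >= x): enumerate every n-subset of an N-universe with
    K marked elements and count overlaps."""
    universe = range(N)
    marked = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(marked.intersection(draw)) >= x:
            hits += 1
    return hits / total


def conditional_enumeration_pvalue(sum_a, sum_b, n_a, n_b, phi):
    """Independent oracle for the NB exact test: enumerate the conditional
    law of the group-A sum given the total via scipy's NB pmf."""
    s = sum_a + sum_b
    if s == 0:
        return 1.0
    r_a, r_b = n_a / phi, n_b / phi
    p = 0.5  # arbitrary; cancels in the conditional
    k = np.arange(s + 1)
    joint = stats.nbinom.pmf(k, r_a, p) * stats.nbinom.pmf(s - k, r_b, p)
    cond = joint / joint.sum()
    return float(cond[cond <= cond[sum_a] * (1 + 1e-8)].sum())


def exhaustive_bsj_oracle(reads, genome, anchor_len=20, min_support=2, max_span=100_000):
    """Brute-force junction caller: for every read, every split position and
    every genomic placement of both fragments (direct string scanning of
    both strands), apply the published rules — unique terminal anchors,
    reversed order, full reconstruction, GT/AG flanks, span bound,
    leftmost-donor tie-break — and aggregate read support."""
    views = {}
    for chrom, seq in genome.chromosomes.items():
        views[(chrom, "+")] = seq
        views[(chrom, "-")] = revcomp(seq)

    def occurrences(sub):
        out = []
        for key, view in views.items():
            start = view.find(sub)
            while start != -1:
                out.append((key, start))
                start = view.find(sub, start + 1)
        return out

    support = {}
    for read_id, seq in reads:
        A, L = anchor_len, len(seq)
        if L < 2 * A:
            continue
        left_occ = occurrences(seq[:A])
        right_occ = occurrences(seq[-A:])
        if len(left_occ) != 1 or len(right_occ) != 1:
            continue
        candidates = []
        for b in range(A, L - A + 1):
            prefix, suffix = seq[:b], seq[b:]
            for key_p, dp in occurrences(prefix):
                for key_s, sp in occurrences(suffix):
                    if key_p != key_s:
                        continue
                    view = views[key_p]
                    donor_end = dp + b
                    acceptor_start = sp
                    if acceptor_start < 2 or donor_end + 2 > len(view):
                        continue
                    if not (acceptor_start < donor_end):
                        continue
                    if donor_end - acceptor_start > max_span:
                        continue
                    if view[donor_end:donor_end + 2] != "GT":
                        continue
                    if view[acceptor_start - 2:acceptor_start] != "AG":
                        continue
                    if (key_p, dp) != left_occ[0]:
                        continue
                    if (key_s, sp + len(suffix) - A) != right_occ[0]:
                        continue
                    candidates.append((donor_end, acceptor_start, key_p))
        if not candidates:
            continue
        donor_end, acceptor_start, (chrom, strand) = min(candidates)
        if strand == "+":
            key = (chrom, acceptor_start, donor_end, "+")
        else:
            n = len(views[(chrom, strand)])
            key = (chrom, n - donor_end, n - acceptor_start, "-")
        support.setdefault(key, set()).add(read_id)
    return {k for k, ids in support.items() if len(ids) >= min_support}
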