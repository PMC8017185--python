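"""Pairwise differential expression and three-stage trend profiling.

The test is a negative-binomial exact test with a single common dispersion,
in the spirit of classic count-based DE testing: replicate counts are
normalized to equal pseudo-library sizes, summed per group, and the group-A
sum is compared with its conditional distribution given the pooled total
(the conditional of two NB sums with sizes n_A/phi and n_B/phi, which is
free of the mean). The two-sided p-value is the total probability of all
outcomes at most as probable as the observed one.

Significance follows the printed rule of the emulated study: |fold change|
> 2 and p < 0.05, with fold change computed on normalized group means with
a pseudocount of 1. A Benjamini-Hochberg option is available but off by
default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy import stats

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-6
DEFAULT_CONTRASTS = (("3M", "1Y"), ("1Y", "3Y"), ("3M", "3Y"))

# lexicographic rank of transition sign patterns (-1 < 0 < +1), (0,0) excluded
PROFILE_ORDER = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))
N_PROFILES = len(PROFILE_ORDER)


@dataclass(frozen=True)
class Contrast:
    group_a: str
    group_b: str

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError("contrast groups must differ")

    @property
    def label(self) -> str:
        return f"{self.group_a}_vs_{self.group_b}"


def _norm_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample scale factors estimating relative effective library size.

    Median-of-ratios: each sample's size factor is the median ratio of its
    counts to the per-feature geometric mean, over features observed in
    every sample. This is robust to a minority of strongly differential
    features that would bias raw column totals. Falls back to total-count
    scaling when fewer than 10 features are usable. Factors are scaled to
    geometric mean 1 so normalized counts stay on the count scale.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"zero library size for sample(s) {bad}")
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if positive.sum() >= 10:
        logs = np.log(arr[positive])
        log_ratio = logs - logs.mean(axis=1, keepdims=True)
        log_size = np.median(log_ratio, axis=0)
    else:
        log_size = np.log(lib.to_numpy())
    log_size = log_size - log_size.mean()
    return pd.Series(np.exp(-log_size), index=counts.columns)


def estimate_dispersion(counts: pd.DataFrame, sample_sheet: pd.DataFrame) -> float:
    """Pooled method-of-moments estimate of a common NB dispersion.

    Within each stage group the normalized-count variance is v = m + phi m^2;
    the pooled ratio estimator phi = sum(v - m) / sum(m^2) over all
    feature/group cells is floored at 1e-6.
    """
    factors = _norm_factors(counts)
    norm = counts * factors
    num = 0.0
    den = 0.0
    for _stage, samples in _group_samples(sample_sheet).items():
        if len(samples) < 2:
            continue
        sub = norm[samples]
        m = sub.mean(axis=1).to_numpy()
        v = sub.var(axis=1, ddof=1).to_numpy()
        keep = m > 0
        num += float(np.sum(v[keep] - m[keep]))
        den += float(np.sum(m[keep] ** 2))
    if den == 0:
        logger.warning("all features constant; dispersion floored at %g", DISPERSION_FLOOR)
        return DISPERSION_FLOOR
    return max(DISPERSION_FLOOR, num / den)


def _group_samples(sample_sheet: pd.DataFrame) -> dict[str, list[str]]:
    return {stage: list(sub["sample"]) for stage, sub in sample_sheet.groupby("stage", sort=False)}


def nb_exact_pvalue(sum_a: int, sum_b: int, n_a: int, n_b: int, dispersion: float) -> float:
    """Exact conditional two-sided p-value for group sums of NB counts.

    Given S_A + S_B = s with S_A ~ NB(size n_a/phi) and S_B ~ NB(size
    n_b/phi) at a common mean per replicate, the conditional law of S_A is
    mean-free; the p-value sums P(S_A = k | s) over every k whose
    probability does not exceed that of the observed split.
    """
    s = sum_a + sum_b
    if s == 0:
        return 1.0
    r_a = n_a / dispersion
    r_b = n_b / dispersion
    k = np.arange(s + 1)
    logp = (gammaln(k + r_a) - gammaln(k + 1)
            + gammaln(s - k + r_b) - gammaln(s - k + 1))
    logp -= logsumexp(logp)
    obs = logp[sum_a]
    # tie slack absorbs float noise in gammaln (mirrored outcomes are equal
    # in exact arithmetic); distinct outcomes differ by >> 1e-8 in log
    mask = logp <= obs + 1e-8
    return float(min(1.0, np.exp(logsumexp(logp[mask]))))


def test_de(
    counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    contrast: Contrast,
    dispersion: float,
    alpha: float = 0.05,
    fc_cut: float = 2.0,
    fdr: bool = False,
) -> pd.DataFrame:
    """NB exact test of every feature for one stage contrast.

    Returns a frame with log2fc (group B over group A, pseudocount 1 on
    normalized means), p_value, significant and direction columns.
    """
    groups = _group_samples(sample_sheet)
    for g in (contrast.group_a, contrast.group_b):
        if g not in groups:
            raise ValueError(f"stage {g!r} not in sample sheet")
    sa, sb = groups[contrast.group_a], groups[contrast.group_b]
    factors = _norm_factors(counts)
    norm = counts * factors
    a = norm[sa].to_numpy()
    b = norm[sb].to_numpy()
    sum_a = np.rint(a.sum(axis=1)).astype(np.int64)
    sum_b = np.rint(b.sum(axis=1)).astype(np.int64)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log2fc = np.log2((mean_b + 1.0) / (mean_a + 1.0))

    pvals = np.array([
        nb_exact_pvalue(int(xa), int(xb), len(sa), len(sb), dispersion)
        for xa, xb in zip(sum_a, sum_b)
    ])
    out = pd.DataFrame({
        "feature_id": counts.index,
        "contrast": contrast.label,
        "log2fc": log2fc,
        "p_value": pvals,
    }).set_index("feature_id")
    crit = out["p_value"].to_numpy()
    if fdr:
        from statsmodels.stats.multitest import multipletests
        crit = multipletests(crit, method="fdr_bh")[1]
        out["p_adj"] = crit
    out["significant"] = (np.abs(log2fc) > np.log2(fc_cut)) & (crit < alpha)
    out["direction"] = np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none"))
    return out


def run_de(
    counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS,
    dispersion: float | None = None,
    alpha: float = 0.05,
    fc_cut: float = 2.0,
    fdr: bool = False,
) -> pd.DataFrame:
    """All pairwise contrasts; estimates the common dispersion when not given."""
    if dispersion is None:
        dispersion = estimate_dispersion(counts, sample_sheet)
    frames = [
        test_de(counts, sample_sheet, Contrast(a, b), dispersion, alpha, fc_cut, fdr)
        for a, b in contrasts
    ]
    return pd.concat(frames)


# ------------------------------------------------------------------ trend profiles

def assign_trends(
    de_results: pd.DataFrame,
    stages: tuple[str, ...] = ("3M", "1Y", "3Y"),
) -> pd.DataFrame:
    """Map features to three-point trend profiles from adjacent-contrast calls.

    Each transition sign is -1/+1 when the adjacent-stage contrast is
    significant (down/up) and 0 otherwise; the all-zero pattern is excluded,
    every other feature lands in exactly one of the 8 profiles (rank of the
    sign pattern in lexicographic order with -1 < 0 < +1).
    """
    adjacent = [f"{a}_vs_{b}" for a, b in zip(stages, stages[1:])]
    signs = {}
    for label in adjacent:
        sub = de_results[de_results["contrast"] == label]
        s = pd.Series(0, index=sub.index, dtype=int)
        sig = sub["significant"].to_numpy()
        s[sig] = np.where(sub.loc[sig, "direction"] == "up", 1, -1)
        signs[label] = s
    features = signs[adjacent[0]].index
    pattern = pd.DataFrame({lab: signs[lab].reindex(features, fill_value=0)
                            for lab in adjacent})
    tuples = [tuple(row) for row in pattern.to_numpy()]
    keep = [t != (0,) * len(adjacent) for t in tuples]
    out = pd.DataFrame({
        "feature_id": features[keep],
        "sign_3M_1Y": [t[0] for t, k in zip(tuples, keep) if k],
        "sign_1Y_3Y": [t[1] for t, k in zip(tuples, keep) if k],
        "profile_id": [PROFILE_ORDER.index(t) for t, k in zip(tuples, keep) if k],
    }).set_index("feature_id")
    return out


def profile_enrichment(trends: pd.DataFrame) -> pd.DataFrame:
    """One-sided binomial test of each profile against uniform membership.

    Observed membership of each of the 8 profiles is tested against the
    uniform expectation 1/8 of assigned features; p-values are Bonferroni
    corrected over the 8 profiles.
    """
    n = len(trends)
    if n == 0:
        return pd.DataFrame(columns=["n_members", "p_value", "p_bonferroni", "significant"]
                            ).rename_axis("profile_id")
    counts = trends["profile_id"].value_counts().reindex(range(N_PROFILES), fill_value=0)
    pvals = np.array([stats.binom.sf(k - 1, n, 1.0 / N_PROFILES) for k in counts])
    bonf = np.minimum(1.0, pvals * N_PROFILES)
    return pd.DataFrame({
        "n_members": counts.to_numpy(),
        "p_value": pvals,
        "p_bonferroni": bonf,
        "significant": bonf < 0.05,
    }, index=pd.RangeIndex(N_PROFILES, name="profile_id"))
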