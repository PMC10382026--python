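"""Elementary statistics underlying every pipeline stage.

Each routine is specified against a closed form or exhaustive enumeration
so the rest of the package can rely on it: two-sided Wilcoxon rank-sum
(exact for small tie-free samples), Welch's t, Benjamini-Hochberg and
Bonferroni adjustment, Mann-Whitney ROC/AUC with a Welch-based p-value,
Wilson score intervals for sensitivity/specificity, and the upper-tail
hypergeometric overlap test used for gene-set enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .exceptions import InputError

__all__ = [
    "TestResult",
    "RocResult",
    "wilcoxon_rank_sum",
    "welch_t",
    "adjust_pvalues",
    "roc_auc",
    "wilson_ci",
    "hypergeometric_enrichment",
    "mann_whitney_auc",
]

#: total sample size at or below which the tie-free Wilcoxon test is exact
EXACT_WILCOXON_MAX_N = 12


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample or enrichment test."""

    statistic: float
    p_value: float
    method: str

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "p_value": self.p_value, "method": self.method}


@dataclass(frozen=True)
class RocResult:
    """ROC summary for a continuous score oriented so higher => nonresponder.

    ``sensitivity``/``specificity`` are reported at the Youden-optimal
    threshold (the paper does not state its operating point; the choice is
    recorded in ``metadata``), with Wilson 95% confidence intervals.
    """

    auc: float
    p_value: float
    sensitivity: float
    specificity: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]
    threshold: float = float("nan")
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "p_value": self.p_value,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "sens_ci": list(self.sens_ci),
            "spec_ci": list(self.spec_ci),
            "threshold": self.threshold,
            "metadata": self.metadata,
        }


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise InputError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise InputError(f"{name} contains non-finite values")
    return arr


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when the combined sample size is at most 12 and the
    data are tie-free; otherwise the tie-corrected normal approximation
    (no continuity correction).  The statistic is the Mann-Whitney U of
    ``x`` (ties counted 1/2).
    """
    xa = _as_1d(x, "x")
    ya = _as_1d(y, "y")
    n = xa.size + ya.size
    has_ties = np.unique(np.concatenate([xa, ya])).size < n
    method = "exact" if (n <= EXACT_WILCOXON_MAX_N and not has_ties) else "asymptotic"
    with np.errstate(invalid="ignore"):
        res = sps.mannwhitneyu(xa, ya, alternative="two-sided", method=method, use_continuity=False)
    p = float(res.pvalue)
    if not np.isfinite(p):  # all observations tied: no evidence either way
        p = 1.0
    return TestResult(statistic=float(res.statistic), p_value=min(p, 1.0), method="wilcoxon_two_sided")


def welch_t(x, y) -> TestResult:
    """Welch's unequal-variance t-test with Satterthwaite df, two-sided."""
    xa = _as_1d(x, "x")
    ya = _as_1d(y, "y")
    if xa.size < 2 or ya.size < 2:
        raise InputError("welch_t requires at least 2 observations per group")
    vx, vy = xa.var(ddof=1), ya.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if xa.mean() == ya.mean():
            return TestResult(statistic=0.0, p_value=1.0, method="welch_t")
        # degenerate separation: treat as infinitely strong evidence but
        # keep the statistic finite by convention
        stat = np.sign(xa.mean() - ya.mean()) * np.finfo(float).max
        return TestResult(statistic=float(stat), p_value=0.0, method="welch_t")
    res = sps.ttest_ind(xa, ya, equal_var=False)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue), method="welch_t")


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment.

    ``BH``: Benjamini-Hochberg step-up with cumulative minimum;
    ``bonferroni``: min(1, m*p).  Order of the input is preserved.
    """
    parr = np.asarray(p, dtype=float).ravel()
    if parr.size == 0:
        return parr.copy()
    if np.any(parr < 0) or np.any(parr > 1) or not np.all(np.isfinite(parr)):
        raise InputError("p-values must lie in [0, 1]")
    m = parr.size
    if method == "bonferroni":
        return np.minimum(1.0, m * parr)
    if method != "BH":
        raise InputError(f"unknown adjustment method: {method!r}")
    order = np.argsort(parr, kind="stable")
    ranked = parr[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def mann_whitney_auc(scores_pos, scores_neg) -> float:
    """AUC as the Mann-Whitney concordance fraction, ties counted 1/2."""
    pos = np.asarray(scores_pos, dtype=float).ravel()
    neg = np.asarray(scores_neg, dtype=float).ravel()
    if pos.size == 0 or neg.size == 0:
        raise InputError("both score lists must be non-empty")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def wilson_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    if n < 1:
        raise InputError("n must be >= 1")
    if not 0 <= successes <= n:
        raise InputError("successes must lie in [0, n]")
    if not 0.0 < level < 1.0:
        raise InputError("level must lie in (0, 1)")
    z = sps.norm.ppf(1.0 - (1.0 - level) / 2.0)
    phat = successes / n
    denom = 1.0 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    lo = float(np.clip(center - half, 0.0, 1.0))
    hi = float(np.clip(center + half, 0.0, 1.0))
    # at the boundaries the Wilson endpoint is exactly 0 or 1; avoid
    # floating-point residue from the quadratic formula
    if successes == 0:
        lo = 0.0
    if successes == n:
        hi = 1.0
    return (lo, hi)


def roc_auc(scores_pos, scores_neg, level: float = 0.95) -> RocResult:
    """ROC/AUC for scores oriented so higher => positive (nonresponder).

    AUC is the Mann-Whitney concordance fraction; the AUC p-value is a
    Welch t-test comparing the two score lists (the convention the
    Cancerclass-style evaluation reports).  Sensitivity and specificity
    are taken at the Youden-optimal threshold with Wilson CIs.
    """
    pos = _as_1d(scores_pos, "scores_pos")
    neg = _as_1d(scores_neg, "scores_neg")
    auc = mann_whitney_auc(pos, neg)
    if pos.size >= 2 and neg.size >= 2:
        p = welch_t(pos, neg).p_value
    else:
        p = float("nan")
    # candidate thresholds: midpoints between adjacent distinct score values,
    # plus sentinels outside the observed range
    allv = np.unique(np.concatenate([pos, neg]))
    if allv.size > 1:
        cands = np.concatenate([[allv[0] - 1.0], (allv[:-1] + allv[1:]) / 2.0, [allv[-1] + 1.0]])
    else:
        cands = np.array([allv[0] - 1.0, allv[0] + 1.0])
    sens = np.array([(pos > t).mean() for t in cands])
    spec = np.array([(neg <= t).mean() for t in cands])
    best = int(np.argmax(sens + spec - 1.0))
    thr = float(cands[best])
    tp = int((pos > thr).sum())
    tn = int((neg <= thr).sum())
    return RocResult(
        auc=auc,
        p_value=p,
        sensitivity=tp / pos.size,
        specificity=tn / neg.size,
        sens_ci=wilson_ci(tp, pos.size, level),
        spec_ci=wilson_ci(tn, neg.size, level),
        threshold=thr,
        metadata={"threshold_rule": "youden", "ci_method": "wilson", "level": level},
    )


def hypergeometric_enrichment(list_genes, gene_set, universe) -> TestResult:
    """Upper-tail hypergeometric overlap test P(X >= k).

    ``statistic`` is the observed overlap k between ``list_genes`` and
    ``gene_set``; both must be subsets of ``universe``.
    """
    uni = set(universe)
    if not uni:
        raise InputError("universe must be non-empty")
    lst = set(list_genes)
    gs = set(gene_set)
    if not lst <= uni:
        raise InputError("list_genes must be a subset of the universe")
    if not gs <= uni:
        raise InputError("gene_set must be a subset of the universe")
    k = len(lst & gs)
    p = float(sps.hypergeom.sf(k - 1, len(uni), len(gs), len(lst)))
    return TestResult(statistic=float(k), p_value=min(max(p, 0.0), 1.0), method="hypergeometric")
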