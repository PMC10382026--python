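"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive quantities by brute force
(pairwise enumeration, exhaustive subset search, step-by-step running
sums) independently of the library's implementation paths.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from chemosig import SimulationConfig, evaluate, fit_centroid_model, simulate_bulk_cohort


@pytest.fixture(scope="session")
def strong_cohort():
    """Well-separated two-class cohort: delta=2, 10 planted genes in 60."""
    cfg = SimulationConfig(
        n_genes=60, n_samples_R=20, n_samples_NR=20, n_signal_genes=10, effect_size_delta=2.0, seed=11
    )
    return simulate_bulk_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """No planted signal: delta irrelevant, 100 samples per class."""
    cfg = SimulationConfig(
        n_genes=50, n_samples_R=100, n_samples_NR=100, n_signal_genes=0, seed=23
    )
    return simulate_bulk_cohort(cfg)


# -- independent oracles ---------------------------------------------------


def auc_brute_force(pos, neg) -> float:
    """Fraction of concordant (pos, neg) pairs, ties counted 1/2."""
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (pos.size * neg.size)


def resubstitution_auc(genes, expr, pheno) -> float:
    """AUC via the full classifier fit/evaluate path (no fast updates)."""
    model = fit_centroid_model(expr, pheno, list(genes))
    return evaluate(model, expr, pheno).auc


def elimination_brute_force(panel0, expr, pheno, min_size=3):
    """Exhaustive greedy elimination through the real classifier path.

    Per cycle, every size-(k-1) subset is fit and evaluated; ties (within
    1e-12 AUC) resolve by removing the lexicographically last gene.
    Returns [(panel_size, best_panel, best_auc), ...] including the
    initial full-panel cycle.
    """
    panel = list(panel0)
    cycles = [(len(panel), list(panel), resubstitution_auc(panel, expr, pheno))]
    while len(panel) > min_size:
        scored = []
        for sub in combinations(panel, len(panel) - 1):
            removed = (set(panel) - set(sub)).pop()
            scored.append((resubstitution_auc(list(sub), expr, pheno), removed, list(sub)))
        best_auc = max(s[0] for s in scored)
        tied = [s for s in scored if s[0] >= best_auc - 1e-12]
        _, removed, sub = max(tied, key=lambda s: s[1])  # remove lexicographically last
        panel = sub
        cycles.append((len(panel), list(panel), best_auc))
    return cycles


def running_walk_extrema(scores, hit_mask, weight):
    """Step-by-step weighted KS running sum; (max, min) deviations."""
    total = sum(abs(s) ** weight for s, h in zip(scores, hit_mask) if h)
    if total <= 0:
        total = float(sum(hit_mask))
        weights = [1.0 if h else 0.0 for h in hit_mask]
    else:
        weights = [abs(s) ** weight if h else 0.0 for s, h in zip(scores, hit_mask)]
    n_miss = sum(1 for h in hit_mask if not h)
    v, walk = 0.0, []
    for w, h in zip(weights, hit_mask):
        v += w / total if h else -1.0 / n_miss
        walk.append(v)
    return max(walk), min(walk)


def running_es_oracle(scores, hit_mask, weight) -> float:
    vmax, vmin = running_walk_extrema(scores, hit_mask, weight)
    return vmax if vmax >= -vmin else vmin


def gsva_oracle(mat: np.ndarray, set_idx, tau=1.0) -> np.ndarray:
    """Literal ECDF -> rank -> random-walk recipe, one score per sample."""
    p, n = mat.shape
    z = np.zeros((p, n))
    for i in range(p):
        h = mat[i].std(ddof=1) / 4.0
        for j in range(n):
            z[i, j] = sps.norm.cdf((mat[i, j] - mat[i]) / h).mean()
    in_set = np.zeros(p, dtype=bool)
    in_set[list(set_idx)] = True
    m = int(in_set.sum())
    scores = np.zeros(n)
    for j in range(n):
        order = np.argsort(-z[:, j], kind="stable")
        rank = np.empty(p, dtype=int)
        rank[order] = np.arange(1, p + 1)
        rstat = np.abs(p / 2.0 - rank)
        denom = sum(rstat[i] ** tau for i in range(p) if in_set[i])
        v, vmax, vmin = 0.0, -np.inf, np.inf
        for g in order:
            if in_set[g]:
                v += rstat[g] ** tau / denom
            else:
                v -= 1.0 / (p - m)
            vmax, vmin = max(vmax, v), min(vmin, v)
        scores[j] = vmax + vmin
    return scores


def logrank_oracle(time, event, group) -> float:
    """Two-group log-rank chi-square from the 2x2 risk tables."""
    time, event = np.asarray(time, float), np.asarray(event, int)
    group = np.asarray(group)
    labels = np.unique(group)
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        d = ((time == t) & (event == 1)).sum()
        n1 = (at_risk & (group == labels[0])).sum()
        d1 = ((time == t) & (event == 1) & (group == labels[0])).sum()
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def make_phenotype(samples, responses) -> pd.DataFrame:
    return pd.DataFrame({"response": list(responses)}, index=pd.Index(samples, name="sample_id"))
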