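"""Single-sample gene-set scoring (GSVA-style) and preranked GSEA.

GSVA assigns each sample a per-set activity score from a rank-based
weighted Kolmogorov-Smirnov random walk: a gene-wise (kernel) ECDF
across samples, a per-sample symmetric rank statistic |p/2 - rank|, and
a tau-weighted running sum whose maximum positive plus maximum negative
deviation is the score (the "mx.diff" convention).  Defaults are pinned
explicitly: Gaussian kernel with bandwidth sd/4, tau = 1, mx.diff.  An
``ecdf`` kernel is available; it makes scores exactly invariant to any
per-gene monotone transformation (the Gaussian kernel is exactly
invariant only under monotone affine transforms).

Preranked GSEA computes the weighted KS enrichment score on a ranked
gene list, a sign-stratified gene-label permutation p-value, NES
normalization by the mean |permuted ES| of the same sign, BH FDR across
sets, and the leading-edge genes up to the running-sum extremum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import InputError
from .genesets import GeneSetCollection
from .stats import adjust_pvalues

__all__ = ["GseaResult", "gsva_scores", "gsea_preranked", "refine_by_leading_edge"]

logger = logging.getLogger(__name__)


@dataclass
class GseaResult:
    """Enrichment of one gene set in a ranked list."""

    set_name: str
    es: float
    nes: float
    p_value: float
    fdr: float
    leading_edge: list[str]
    size: int


# -- GSVA ------------------------------------------------------------------


def _kernel_cdf(mat: np.ndarray, kernel: str) -> np.ndarray:
    """Gene-wise CDF estimate across samples, genes x samples."""
    p, n = mat.shape
    if kernel == "ecdf":
        # fraction of samples at or below each value, per gene
        return sps.rankdata(mat, axis=1, method="average") / n
    if kernel != "gaussian":
        raise InputError(f"unknown kernel {kernel!r}")
    sd = mat.std(axis=1, ddof=1)
    h = sd / 4.0
    out = np.empty_like(mat)
    for i in range(p):  # per gene: mean Gaussian CDF of pairwise differences
        diffs = (mat[i][:, None] - mat[i][None, :]) / h[i]
        out[i] = sps.norm.cdf(diffs).mean(axis=1)
    return out


def gsva_scores(
    expr: pd.DataFrame,
    sets: GeneSetCollection,
    tau: float = 1.0,
    kernel: str = "gaussian",
    min_genes: int = 2,
) -> pd.DataFrame:
    """Per-sample gene-set activity scores (sets x samples).

    Constant gene rows are excluded before the kernel step; sets with
    fewer than ``min_genes`` present genes are skipped with a warning.
    """
    if expr.shape[1] < 2:
        raise InputError("gsva_scores requires at least 2 samples")
    mat = expr.to_numpy(dtype=float)
    variable = mat.std(axis=1, ddof=0) > 0
    if (~variable).any():
        logger.info("excluded %d constant gene row(s) from the kernel step", int((~variable).sum()))
    genes = expr.index[variable]
    z = _kernel_cdf(mat[variable], kernel)
    p, n = z.shape
    # per-sample gene ranking by decreasing CDF statistic, and the
    # symmetric rank statistic |p/2 - rank| (rank 1 = largest z)
    order = np.argsort(-z, axis=0, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(p)
    for j in range(n):
        ranks[order[:, j], j] = rows + 1
    rank_stat = np.abs(p / 2.0 - ranks)

    gene_pos = {g: i for i, g in enumerate(genes)}
    out = {}
    for name, members in sets:
        idx = [gene_pos[g] for g in members if g in gene_pos]
        if len(idx) < min_genes:
            warnings.warn(f"set {name!r} has fewer than {min_genes} scorable genes; skipped", stacklevel=2)
            continue
        in_set = np.zeros(p, dtype=bool)
        in_set[idx] = True
        m = len(idx)
        scores = np.empty(n)
        for j in range(n):
            ordered_in = in_set[order[:, j]]
            w = rank_stat[order[:, j], j] ** tau
            w_hits = np.where(ordered_in, w, 0.0)
            denom_hits = w_hits.sum()
            hit_cdf = np.cumsum(w_hits) / denom_hits
            miss_cdf = np.cumsum(~ordered_in) / (p - m)
            v = hit_cdf - miss_cdf
            scores[j] = v.max() + v.min()  # mx.diff
        out[name] = scores
    return pd.DataFrame(out, index=expr.columns).T


# -- preranked GSEA --------------------------------------------------------


def _running_es(scores: np.ndarray, hit_mask: np.ndarray, weight: float) -> tuple[float, int]:
    """Signed ES (extremum of the running sum) and its 0-based position."""
    w = np.abs(scores) ** weight
    w_hits = np.where(hit_mask, w, 0.0)
    total = w_hits.sum()
    if total <= 0:  # all hit weights zero (e.g. zero scores): fall back to equal weights
        w_hits = hit_mask.astype(float)
        total = w_hits.sum()
    n_miss = (~hit_mask).sum()
    v = np.cumsum(w_hits) / total - np.cumsum(~hit_mask) / n_miss
    i_max, i_min = int(np.argmax(v)), int(np.argmin(v))
    if v[i_max] >= -v[i_min]:
        return float(v[i_max]), i_max
    return float(v[i_min]), i_min


def gsea_preranked(
    ranked: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
) -> list[GseaResult]:
    """Preranked GSEA over a gene -> rank-score series.

    The list is sorted by decreasing score internally.  p-values come
    from sign-stratified gene-label permutations (random same-size gene
    sets), NES = ES / mean(|permuted ES| of the same sign), FDR by BH
    across sets.  Sets with no overlap are skipped; a set covering the
    whole list has no complement and is skipped with a warning.
    """
    if n_perm < 100:
        raise InputError("n_perm must be >= 100")
    if ranked.index.has_duplicates:
        raise InputError("ranked list contains duplicate genes")
    ranked = ranked.sort_values(ascending=False, kind="stable")
    scores = ranked.to_numpy(dtype=float)
    genes = list(ranked.index)
    npos = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    rows = []
    for name, members in sets:
        idx = sorted(gene_pos[g] for g in members if g in gene_pos)
        if not idx:
            logger.info("set %s has no overlap with the ranked list; skipped", name)
            continue
        if len(idx) == npos:
            warnings.warn(f"set {name!r} covers the entire ranked list; skipped (no complement)", stacklevel=2)
            continue
        mask = np.zeros(npos, dtype=bool)
        mask[idx] = True
        es, pos = _running_es(scores, mask, weight)
        if es >= 0:
            lead = [genes[i] for i in range(pos + 1) if mask[i]]
        else:
            lead = [genes[i] for i in range(pos, npos) if mask[i]]
        null = np.empty(n_perm)
        for b in range(n_perm):
            pmask = np.zeros(npos, dtype=bool)
            pmask[rng.choice(npos, size=len(idx), replace=False)] = True
            null[b], _ = _running_es(scores, pmask, weight)
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if same_sign.size:
            p = (1 + int((np.abs(same_sign) >= abs(es)).sum())) / (1 + same_sign.size)
            nes = es / np.abs(same_sign).mean() if np.abs(same_sign).mean() > 0 else float("nan")
        else:
            p, nes = 1.0 / (1 + n_perm), float("nan")
        rows.append((name, es, nes, p, lead, len(idx)))

    fdr = adjust_pvalues([r[3] for r in rows], method="BH") if rows else []
    return [
        GseaResult(set_name=n, es=e, nes=ne, p_value=p, fdr=float(q), leading_edge=le, size=sz)
        for (n, e, ne, p, le, sz), q in zip(rows, fdr)
    ]


def refine_by_leading_edge(
    panel_name: str,
    panel_genes,
    ranked: pd.Series,
    direction: str = "positive",
    fdr_alpha: float = 0.05,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
) -> list[str]:
    """Refine a signature to its response-associated core (Sig -> Sig2).

    Runs preranked GSEA of the panel against the ranked R-vs-NR list;
    when the enrichment is significant (FDR < alpha) in the requested
    direction, returns the leading-edge genes, otherwise an empty list.
    """
    coll = GeneSetCollection(sets={panel_name: list(panel_genes)})
    res = gsea_preranked(ranked, coll, n_perm=n_perm, weight=weight, seed=seed)
    if not res:
        return []
    r = res[0]
    wanted_sign = 1.0 if direction == "positive" else -1.0
    if r.fdr < fdr_alpha and np.sign(r.es) == wanted_sign:
        return list(r.leading_edge)
    return []
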