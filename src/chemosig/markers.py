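"""Differential expression, cluster markers, and predictive-list screening.

DE between responders and nonresponders (and one-vs-rest cluster
markers) uses the two-sided Wilcoxon rank-sum test with Bonferroni
correction within each comparison's gene list.  Fold changes follow the
Seurat-style convention on de-logged means with a pseudocount of 1:

    avg_log2FC = log2((mean(2^x - 1 | group A) + 1) / (mean(2^x - 1 | group B) + 1))

since the matrices are log2-scale.  ``screen_gene_lists`` implements the
subtype-nomination rule: submit the top 500 genes of each list, rank the
collection's sets by hypergeometric enrichment (BH-filtered), evaluate
each of the top 10 surviving sets as an independent centroid-classifier
panel, and flag the list predictive when at least half of its top sets
achieve AUC p < 0.05.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centroid import evaluate, fit_centroid_model
from .exceptions import InputError, ModelError
from .genesets import GeneSetCollection
from .stats import adjust_pvalues, hypergeometric_enrichment, wilcoxon_rank_sum

__all__ = [
    "GeneList",
    "SubtypeScreenResult",
    "de_between_conditions",
    "find_cluster_markers",
    "screen_gene_lists",
]

logger = logging.getLogger(__name__)

DE_COLUMNS = ["gene", "avg_log2FC", "p_value", "p_adjusted", "pct_in", "pct_out", "direction"]


@dataclass
class GeneList:
    """An ordered, duplicate-free gene list with its ordering convention."""

    name: str
    genes: list[str]
    ordering_key: str = "abs_logFC_desc"  # or "p_adjusted_asc"

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise InputError(f"gene list {self.name!r} contains duplicates")

    @classmethod
    def from_de_table(cls, table: pd.DataFrame, name: str, ordering_key: str = "abs_logFC_desc") -> "GeneList":
        if ordering_key == "abs_logFC_desc":
            ordered = table.reindex(table["avg_log2FC"].abs().sort_values(ascending=False, kind="stable").index)
        elif ordering_key == "p_adjusted_asc":
            ordered = table.sort_values("p_adjusted", kind="stable")
        else:
            raise InputError(f"unknown ordering key {ordering_key!r}")
        return cls(name=name, genes=list(ordered["gene"]), ordering_key=ordering_key)


@dataclass
class SubtypeScreenResult:
    """Screening outcome for one DE gene list.

    ``top_sets`` holds (set_name, enrichment_p, auc_p) for at most 10
    sets; the list ``is_predictive`` iff at least half of them reach
    AUC p < 0.05.
    """

    gene_list_name: str
    top_sets: list[tuple[str, float, float]]
    n_significant: int
    is_predictive: bool
    dropped_sets: dict[str, str] = field(default_factory=dict)


def _avg_log2fc(a: np.ndarray, b: np.ndarray) -> float:
    # de-log (data are log2 of normalized counts + 1), average, re-log
    return float(np.log2((np.expm1(a * np.log(2)).mean() + 1.0) / (np.expm1(b * np.log(2)).mean() + 1.0)))


def de_between_conditions(
    expr: pd.DataFrame, labels, group_a: str = "R", group_b: str = "NR", alpha: float = 0.05
) -> pd.DataFrame:
    """Per-gene Wilcoxon DE between two label groups (genes x samples input).

    Returns one row per gene with Bonferroni-adjusted p-values and an
    ``is_de`` flag at ``p_adjusted < alpha``.  ``direction`` is
    ``up_in_<group>`` by the sign of avg_log2FC (group_a positive).
    """
    resp = labels["response"] if isinstance(labels, pd.DataFrame) else pd.Series(labels)
    resp = resp.reindex(expr.columns)
    mask_a = (resp == group_a).to_numpy()
    mask_b = (resp == group_b).to_numpy()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise InputError(f"need >= 2 samples in each of {group_a!r} and {group_b!r}")
    mat = expr.to_numpy(dtype=float)
    a, b = mat[:, mask_a], mat[:, mask_b]
    pvals = np.empty(expr.shape[0])
    lfc = np.empty(expr.shape[0])
    for i in range(expr.shape[0]):
        pvals[i] = wilcoxon_rank_sum(a[i], b[i]).p_value
        lfc[i] = _avg_log2fc(a[i], b[i])
    padj = adjust_pvalues(pvals, method="bonferroni")
    out = pd.DataFrame(
        {
            "gene": expr.index,
            "avg_log2FC": lfc,
            "p_value": pvals,
            "p_adjusted": padj,
            "pct_in": (a > 0).mean(axis=1),
            "pct_out": (b > 0).mean(axis=1),
            "direction": np.where(lfc >= 0, f"up_in_{group_a}", f"up_in_{group_b}"),
        }
    )
    out["is_de"] = out["p_adjusted"] < alpha
    return out


def find_cluster_markers(
    expr: pd.DataFrame,
    clusters,
    min_pct: float = 0.1,
    logfc_threshold: float = 0.25,
    alpha: float = 0.05,
) -> dict:
    """One-vs-rest cluster marker genes (genes x cells input).

    Candidate genes must pass the conjunctive pre-test gates
    ``pct_in >= min_pct`` and ``avg_log2FC >= logfc_threshold``; the
    surviving candidates are Wilcoxon-tested with Bonferroni correction
    and flagged markers at ``p_adjusted < alpha``.  Clusters with fewer
    than 3 cells are skipped with a warning.
    """
    cl = clusters["cluster"] if isinstance(clusters, pd.DataFrame) else pd.Series(clusters)
    cl = cl.reindex(expr.columns)
    uniq = [c for c in pd.unique(cl.dropna())]
    if len(uniq) < 2:
        raise InputError("at least two clusters are required")
    mat = expr.to_numpy(dtype=float)
    results: dict = {}
    for c in uniq:
        mask = (cl == c).to_numpy()
        if mask.sum() < 3:
            warnings.warn(f"cluster {c!r} has fewer than 3 cells; skipped", stacklevel=2)
            continue
        inside, outside = mat[:, mask], mat[:, ~mask]
        pct_in = (inside > 0).mean(axis=1)
        pct_out = (outside > 0).mean(axis=1)
        lfc = np.array([_avg_log2fc(inside[i], outside[i]) for i in range(mat.shape[0])])
        gate = (pct_in >= min_pct) & (lfc >= logfc_threshold)
        idx = np.flatnonzero(gate)
        pvals = np.array([wilcoxon_rank_sum(inside[i], outside[i]).p_value for i in idx])
        padj = adjust_pvalues(pvals, method="bonferroni") if idx.size else np.array([])
        table = pd.DataFrame(
            {
                "gene": expr.index[idx],
                "avg_log2FC": lfc[idx],
                "p_value": pvals,
                "p_adjusted": padj,
                "pct_in": pct_in[idx],
                "pct_out": pct_out[idx],
                "direction": "up_in_cluster",
            }
        )
        table["is_marker"] = table["p_adjusted"] < alpha
        results[c] = table.sort_values(["p_adjusted", "gene"], kind="stable").reset_index(drop=True)
    return results


def screen_gene_lists(
    gene_lists,
    collection: GeneSetCollection,
    expr: pd.DataFrame,
    labels,
    top_genes: int = 500,
    top_n: int = 10,
    enrichment_alpha: float = 0.05,
    auc_alpha: float = 0.05,
    min_set_genes: int = 3,
    distance: str = "euclidean",
) -> list[SubtypeScreenResult]:
    """Nominate predictive DE gene lists by enrichment + classifier AUC.

    For each list: submit its top ``top_genes`` genes (all, if shorter),
    compute hypergeometric enrichment against every collection set,
    BH-adjust and keep sets with adjusted p < ``enrichment_alpha``,
    exclude sets with fewer than ``min_set_genes`` genes present in the
    evaluation cohort, rank the survivors by (raw p, set name) and take
    the top ``top_n``.  Each surviving set is fit and evaluated as an
    independent centroid panel on the evaluation cohort; the list is
    predictive iff at least ceil(top/2) of its top sets have AUC
    p < ``auc_alpha``.
    """
    if len(collection) == 0:
        raise InputError("gene-set collection is empty")
    cohort_genes = set(expr.index)
    results = []
    for gl in gene_lists:
        query = gl.genes[:top_genes]
        universe = collection.effective_universe(extra=query)
        enrich = []
        dropped: dict[str, str] = {}
        for name, genes in collection:
            res = hypergeometric_enrichment(set(query) & universe, set(genes), universe)
            enrich.append((name, res.p_value))
        names = [n for n, _ in enrich]
        praw = np.array([p for _, p in enrich])
        padj = adjust_pvalues(praw, method="BH")
        keep = []
        for name, p, q in zip(names, praw, padj):
            if q >= enrichment_alpha:
                dropped[name] = "enrichment FDR >= alpha"
                continue
            present = [g for g in collection.sets[name] if g in cohort_genes]
            if len(present) < min_set_genes:
                dropped[name] = f"fewer than {min_set_genes} genes present in cohort"
                logger.info("set %s excluded from screen: %s", name, dropped[name])
                continue
            keep.append((p, name))
        keep.sort(key=lambda t: (t[0], t[1]))  # stable (p, name) tie-break
        top = keep[:top_n]
        top_sets = []
        for p, name in top:
            present = [g for g in collection.sets[name] if g in cohort_genes]
            try:
                model = fit_centroid_model(expr, labels, present, distance=distance)
                auc_p = evaluate(model, expr, labels).p_value
            except ModelError as exc:
                dropped[name] = f"classifier failure: {exc}"
                logger.info("set %s skipped during evaluation: %s", name, exc)
                continue
            top_sets.append((name, float(p), float(auc_p)))
        n_sig = sum(1 for _, _, ap in top_sets if ap < auc_alpha)
        is_pred = bool(top_sets) and n_sig >= math.ceil(len(top_sets) / 2)
        results.append(
            SubtypeScreenResult(
                gene_list_name=gl.name,
                top_sets=top_sets,
                n_significant=n_sig,
                is_predictive=is_pred,
                dropped_sets=dropped,
            )
        )
    return results
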