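"""Candidate-panel assembly and recursive AUC-driven gene elimination.

The signature-development workflow: merge the significantly predictive
gene sets into a union list, gate each subtype's genes by its avg_log2FC
rule, intersect the gated lists across subtypes, restrict to genes
present in the training cohort (``panel0``), then run backward
elimination: at each cycle with k genes every size-(k-1) subset is
scored by resubstitution classifier AUC on the training cohort, the best
subset survives, and the cycle repeats down to 3 genes.  The signature
is the highest-AUC panel across all cycles (ties within 1e-9 form a
plateau whose median-size panel is taken; a ``size_override`` reproduces
a manual pick from an AUC plateau).

The per-cycle leave-one-gene-out evaluation uses a running-sum update of
the centroid distances (or correlations): per-gene
standardization and centroid entries do not depend on the subset, and
the classifier's score_z is a subset-wise monotone rescaling of the raw
score, so subset AUCs computed this way equal those from refitting the
classifier on each subset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .centroid import CentroidModel, fit_centroid_model
from .exceptions import AssemblyError, InputError
from .genesets import GeneSetCollection

__all__ = [
    "LogFCGate",
    "CandidateAssembly",
    "EliminationCycle",
    "EliminationTrace",
    "SignaturePanel",
    "RecursiveAUCEliminator",
    "assemble_candidates",
    "recursive_elimination",
    "build_signature",
]

logger = logging.getLogger(__name__)

AUC_TIE_TOL = 1e-9  # panels within this AUC of the maximum count as tied


@dataclass(frozen=True)
class LogFCGate:
    """Per-subtype fold-change gate applied before intersection."""

    subtype: str
    direction: str  # "greater" or "less"
    threshold: float

    def passes(self, lfc: np.ndarray) -> np.ndarray:
        if self.direction == "greater":
            return lfc > self.threshold
        if self.direction == "less":
            return lfc < self.threshold
        raise InputError(f"unknown gate direction {self.direction!r}")


@dataclass
class CandidateAssembly:
    """Candidate panel from union/intersection assembly, with stage counts."""

    union_genelist: set
    intersect_genelist: set
    panel0: list
    counts: dict = field(default_factory=dict)


@dataclass
class EliminationCycle:
    panel_size: int
    best_panel: list
    best_auc: float
    removed_gene: str | None
    n_evaluated: int


@dataclass
class EliminationTrace:
    """Full search trace: one entry per cycle plus the selected panel."""

    cycles: list
    selected: list
    selected_auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": range(len(self.cycles)),
                "panel_size": [c.panel_size for c in self.cycles],
                "removed_gene": [c.removed_gene or "" for c in self.cycles],
                "best_auc": [c.best_auc for c in self.cycles],
                "n_evaluated": [c.n_evaluated for c in self.cycles],
            }
        )

    def panel_at(self, size: int) -> list:
        for c in self.cycles:
            if c.panel_size == size:
                return list(c.best_panel)
        raise InputError(f"no cycle with panel size {size}")


@dataclass
class SignaturePanel:
    """An ordered gene panel with assembly/selection provenance."""

    genes: list
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def write(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.genes) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "SignaturePanel":
        genes = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
        return cls(genes=genes, provenance={"source": str(path)})


def assemble_candidates(
    significant_sets: GeneSetCollection,
    de_by_subtype: dict,
    gates: list[LogFCGate],
    cohort_genes,
) -> CandidateAssembly:
    """Union of significant sets, gated per-subtype intersection, cohort filter.

    ``de_by_subtype`` maps each gated subtype to its R-vs-NR DE table
    (must cover every gate's subtype).  The final ``panel0`` is the
    lexicographically ordered intersection of the union list, the gated
    intersection list, and the cohort's gene ids.
    """
    if not gates:
        raise InputError("at least one fold-change gate is required")
    union = significant_sets.genes() if isinstance(significant_sets, GeneSetCollection) else set().union(
        *significant_sets.values()
    )
    kept_per_subtype = {}
    for gate in gates:
        if gate.subtype not in de_by_subtype:
            raise InputError(f"no DE table for gated subtype {gate.subtype!r}")
        table = de_by_subtype[gate.subtype]
        mask = gate.passes(table["avg_log2FC"].to_numpy(dtype=float))
        kept_per_subtype[gate.subtype] = set(table["gene"][mask])
    intersect = set.intersection(*kept_per_subtype.values())
    cohort = set(cohort_genes)
    panel0 = sorted(union & intersect & cohort)
    counts = {
        "union": len(union),
        "intersect": len(intersect),
        "cohort": len(cohort),
        "panel0": len(panel0),
        **{f"gate_kept[{s}]": len(g) for s, g in kept_per_subtype.items()},
    }
    if not panel0:
        raise AssemblyError(f"candidate assembly is empty; stage counts: {counts}")
    return CandidateAssembly(union_genelist=union, intersect_genelist=intersect, panel0=panel0, counts=counts)


# -- fast leave-one-out scoring -------------------------------------------


def _auc_columns(scores: np.ndarray, pos_mask: np.ndarray) -> np.ndarray:
    """Mann-Whitney AUC of each column of ``scores`` (ties 1/2)."""
    ranks = sps.rankdata(scores, axis=0)
    npos = int(pos_mask.sum())
    nneg = pos_mask.size - npos
    u = ranks[pos_mask].sum(axis=0) - npos * (npos + 1) / 2.0
    return u / (npos * nneg)


def _loo_scores(Z: np.ndarray, cpos: np.ndarray, cneg: np.ndarray, distance: str) -> np.ndarray:
    """Raw classifier scores for every leave-one-gene-out subset.

    Returns an (n_samples, k) matrix whose column g holds the scores of
    the panel with gene g removed.
    """
    n, k = Z.shape
    m = k - 1
    Z2 = Z * Z
    Sz = Z.sum(axis=1, keepdims=True)
    Szz = Z2.sum(axis=1, keepdims=True)
    if distance == "euclidean":

        def dist2(c):
            Szc = (Z @ c)[:, None]
            d_full = Szz + (c * c).sum() - 2.0 * Szc
            # remove gene g's (z - c_g)^2 term
            return d_full - (Z2 - 2.0 * Z * c + c * c)

        with np.errstate(invalid="ignore"):
            return np.sqrt(np.maximum(dist2(cneg), 0.0)) - np.sqrt(np.maximum(dist2(cpos), 0.0))

    def corr(c):
        Sc = c.sum()
        Scc = (c * c).sum()
        Szc = (Z @ c)[:, None]
        Sz_l = Sz - Z
        Szz_l = Szz - Z2
        Sc_l = Sc - c
        Scc_l = Scc - c * c
        Szc_l = Szc - Z * c
        num = Szc_l - Sz_l * Sc_l / m
        varz = Szz_l - Sz_l * Sz_l / m
        varc = Scc_l - Sc_l * Sc_l / m
        den = np.sqrt(np.maximum(varz, 0.0) * np.maximum(varc, 0.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = num / den
        return np.where(den > 0, r, 0.0)

    return corr(cpos) - corr(cneg)


def _full_scores(Z: np.ndarray, cpos: np.ndarray, cneg: np.ndarray, distance: str) -> np.ndarray:
    if distance == "euclidean":
        return np.sqrt(((Z - cneg) ** 2).sum(axis=1)) - np.sqrt(((Z - cpos) ** 2).sum(axis=1))
    zc = Z - Z.mean(axis=1, keepdims=True)
    zden = np.sqrt((zc * zc).sum(axis=1))

    def corr(c):
        cc = c - c.mean()
        den = zden * np.sqrt((cc * cc).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (zc @ cc) / den
        return np.where(den > 0, r, 0.0)

    return corr(cpos) - corr(cneg)


class RecursiveAUCEliminator(TransformerMixin, BaseEstimator):
    """Backward gene elimination maximizing nearest-centroid AUC.

    A feature selector in the sklearn mold: ``fit(X, y)`` on a
    samples x genes matrix runs the full greedy search, after which
    ``support_`` masks the selected genes, ``transform`` subsets the
    columns, and ``trace_`` holds the per-cycle search history.

    Parameters
    ----------
    min_size : int
        Smallest panel size explored (>= 3).
    size_override : int, optional
        Return the trace's best panel at this size instead of the
        global-maximum rule (mirrors a manual pick within an AUC
        plateau).
    distance : {"correlation", "euclidean"}
        Centroid score convention, as in :class:`CentroidClassifier`.
    """

    def __init__(self, min_size: int = 3, size_override: int | None = None,
                 distance: str = "euclidean", pos_label: str = "NR"):
        self.min_size = min_size
        self.size_override = size_override
        self.distance = distance
        self.pos_label = pos_label

    def fit(self, X, y):
        if self.min_size < 3:
            raise InputError("min_size must be >= 3")
        frame = X if isinstance(X, pd.DataFrame) else pd.DataFrame(
            np.asarray(X, dtype=float), columns=[f"f{i}" for i in range(np.asarray(X).shape[1])]
        )
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise InputError("exactly two classes are required")
        pos = self.pos_label if self.pos_label in classes else classes[-1]
        pos_mask = y == pos
        if pos_mask.sum() < 2 or (~pos_mask).sum() < 2:
            raise InputError("need at least 2 samples per class")

        panel = list(frame.columns)
        vals = frame.to_numpy(dtype=float)
        sd = vals.std(axis=0, ddof=0)
        if (sd == 0).any():
            dropped = [g for g, s in zip(panel, sd) if s == 0]
            warnings.warn(f"dropped {len(dropped)} zero-variance gene(s) before elimination", stacklevel=2)
            keep = sd > 0
            panel = [g for g, k in zip(panel, keep) if k]
            vals, sd = vals[:, keep], sd[keep]
        if len(panel) <= self.min_size:
            raise InputError(f"panel must exceed min_size={self.min_size} usable genes (got {len(panel)})")

        Z = (vals - vals.mean(axis=0)) / sd
        cpos_full = Z[pos_mask].mean(axis=0)
        cneg_full = Z[~pos_mask].mean(axis=0)

        cols = np.arange(len(panel))
        full_auc = float(
            _auc_columns(
                np.nan_to_num(_full_scores(Z[:, cols], cpos_full, cneg_full, self.distance))[:, None], pos_mask
            )[0]
        )
        cycles = [EliminationCycle(len(panel), list(panel), full_auc, None, 1)]
        current = list(panel)
        while len(current) > self.min_size:
            idx = np.array([panel.index(g) for g in current])
            Zs, cp, cn = Z[:, idx], cpos_full[idx], cneg_full[idx]
            scores = np.nan_to_num(_loo_scores(Zs, cp, cn, self.distance))
            aucs = np.nan_to_num(_auc_columns(scores, pos_mask))
            best = float(aucs.max())
            tied = [g for g, a in zip(current, aucs) if a >= best - 1e-12]
            removed = max(tied)  # lexicographically last among ties
            current = [g for g in current if g != removed]
            cycles.append(EliminationCycle(len(current), list(current), best, removed, len(current) + 1))

        best_overall = max(c.best_auc for c in cycles)
        contenders = sorted(
            (c for c in cycles if c.best_auc >= best_overall - AUC_TIE_TOL), key=lambda c: c.panel_size
        )
        # resubstitution AUC is uninformative within a tied plateau: the
        # smallest tied panel tends to have shed true signature genes, the
        # largest to retain noise, so take the middle of the plateau
        winner = contenders[len(contenders) // 2]
        if self.size_override is not None:
            if not self.min_size <= self.size_override <= len(panel):
                raise InputError(f"size_override must lie in [{self.min_size}, {len(panel)}]")
            winner_panel = next(c.best_panel for c in cycles if c.panel_size == self.size_override)
            winner_auc = next(c.best_auc for c in cycles if c.panel_size == self.size_override)
        else:
            winner_panel, winner_auc = winner.best_panel, winner.best_auc

        self.trace_ = EliminationTrace(cycles=cycles, selected=list(winner_panel), selected_auc=float(winner_auc))
        self.selected_panel_ = list(winner_panel)
        self.selected_auc_ = float(winner_auc)
        self.feature_names_in_ = np.asarray(frame.columns)
        self.support_ = np.isin(frame.columns, self.selected_panel_)
        self.n_features_in_ = frame.shape[1]
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X[[g for g in self.selected_panel_ if g in X.columns]]
        return np.asarray(X)[:, self.support_]


def recursive_elimination(
    panel0,
    expr: pd.DataFrame,
    labels,
    min_size: int = 3,
    distance: str = "euclidean",
) -> EliminationTrace:
    """Run the greedy backward search on a genes x samples cohort."""
    missing = [g for g in panel0 if g not in expr.index]
    if missing:
        raise InputError(f"panel genes absent from cohort: {missing[:10]}")
    resp = labels["response"] if isinstance(labels, pd.DataFrame) else pd.Series(labels)
    resp = resp.reindex(expr.columns)
    elim = RecursiveAUCEliminator(min_size=min_size, distance=distance)
    elim.fit(expr.loc[list(panel0)].T, resp.to_numpy())
    return elim.trace_


def build_signature(
    assembly,
    expr: pd.DataFrame,
    labels,
    size_override: int | None = None,
    min_size: int = 3,
    distance: str = "euclidean",
):
    """Assembly -> elimination -> final panel + fitted centroid model.

    ``assembly`` may be a :class:`CandidateAssembly` or a plain gene
    list (panel0).  Returns ``(SignaturePanel, CentroidModel,
    EliminationTrace)``.
    """
    panel0 = assembly.panel0 if isinstance(assembly, CandidateAssembly) else list(assembly)
    trace = recursive_elimination(panel0, expr, labels, min_size=min_size, distance=distance)
    if size_override is not None:
        if not min_size <= size_override <= len(panel0):
            raise InputError(f"size_override must lie in [{min_size}, {len(panel0)}]")
        genes = trace.panel_at(size_override)
        auc = next(c.best_auc for c in trace.cycles if c.panel_size == size_override)
    else:
        genes, auc = trace.selected, trace.selected_auc
    model = fit_centroid_model(expr, labels, genes, distance=distance)
    provenance = {
        "panel0_size": len(panel0),
        "selected_size": len(genes),
        "train_auc": auc,
        "size_override": size_override,
        "selection_rule": "max AUC across cycles; ties within 1e-9 -> median panel size of the tied plateau",
        "tie_break": "remove lexicographically last gene among tied removals",
        "distance": distance,
    }
    if isinstance(assembly, CandidateAssembly):
        provenance["assembly_counts"] = assembly.counts
    panel = SignaturePanel(genes=list(genes), provenance=provenance)
    model.metadata.update({"signature_provenance": provenance})
    return panel, model, trace
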