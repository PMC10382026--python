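"""Prognostic screening: univariate Cox per gene and median-split KM.

The univariate screen fits, for each gene (or score row), a
single-covariate Cox proportional-hazards model by Newton maximization
of the Breslow partial likelihood, and retains genes that are both
significant (Wald p < alpha) and on the requested side of HR = 1 (risk:
HR > 1; protective: HR < 1).  Kaplan-Meier comparison dichotomizes a
per-sample score at its median (ties to the low group) and tests the
two groups with the log-rank statistic.  The multivariate model is a
thin wrapper over lifelines' CoxPHFitter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .elimination import SignaturePanel
from .exceptions import InputError
from .stats import TestResult

__all__ = ["CoxResult", "KMComparison", "univariate_cox_screen", "km_median_split", "multivariate_cox", "cox_single"]

logger = logging.getLogger(__name__)

from scipy import stats as sps


@dataclass
class CoxResult:
    """Single-covariate proportional-hazards fit."""

    gene_or_score: str
    hazard_ratio: float
    beta: float
    se: float
    p_value: float
    ci: tuple[float, float]


@dataclass
class KMComparison:
    """Median-split survival comparison."""

    groups: pd.Series  # "high"/"low" per sample
    logrank_chi2: float
    p_value: float
    median_survival: dict
    curves: pd.DataFrame  # step-function points per group (for CSV export)

    @property
    def test(self) -> TestResult:
        return TestResult(statistic=self.logrank_chi2, p_value=self.p_value, method="log_rank")


def _check_surv(surv: pd.DataFrame) -> pd.DataFrame:
    for col in ("time_months", "event"):
        if col not in surv.columns:
            raise InputError(f"survival table lacks column {col!r}")
    t = surv["time_months"].to_numpy(dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise InputError("time_months must be finite and > 0")
    e = surv["event"].to_numpy()
    if not np.isin(e, (0, 1)).all():
        raise InputError("event must be 0/1")
    return surv


def cox_single(x, time, event, max_iter: int = 50, tol: float = 1e-10):
    """Newton maximization of the single-covariate Breslow partial likelihood.

    Returns (beta, se) or raises ``ArithmeticError`` on non-convergence
    or a degenerate information.
    """
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(-time, kind="stable")  # descending: cumulative sums give risk sets
    x, time, event = x[order], time[order], event[order]
    # group tied times so tied events share one risk set (Breslow)
    uniq, inv = np.unique(-time, return_inverse=True)
    beta = 0.0
    for _ in range(max_iter):
        w = np.exp(beta * x)
        s0 = np.cumsum(w)
        s1 = np.cumsum(w * x)
        s2 = np.cumsum(w * x * x)
        # index of the last sample sharing each row's time value
        last = np.searchsorted(inv, inv, side="right") - 1
        r0, r1, r2 = s0[last], s1[last], s2[last]
        ev = event == 1
        mu = r1[ev] / r0[ev]
        U = float((x[ev] - mu).sum())
        info = float((r2[ev] / r0[ev] - mu * mu).sum())
        if not np.isfinite(U) or not np.isfinite(info) or info <= 0:
            raise ArithmeticError("degenerate information in Cox fit")
        step = U / info
        beta += step
        if abs(step) < tol:
            return float(beta), float(1.0 / np.sqrt(info))
    raise ArithmeticError("Cox Newton iteration did not converge")


def univariate_cox_screen(
    expr_or_scores,
    surv: pd.DataFrame,
    hr_direction: str = "risk",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, SignaturePanel]:
    """Per-gene univariate Cox screen returning results and the retained panel.

    ``expr_or_scores`` is a genes x samples frame (or a single Series);
    ``surv`` must carry time_months/event indexed by sample.  Retained
    genes have Wald p < alpha with HR on the requested side of 1
    ("risk": HR > 1, "protective": HR < 1).  Non-convergent genes are
    skipped and logged.
    """
    if hr_direction not in ("risk", "protective"):
        raise InputError(f"hr_direction must be 'risk' or 'protective', got {hr_direction!r}")
    if isinstance(expr_or_scores, pd.Series):
        frame = expr_or_scores.to_frame().T
        frame.index = [expr_or_scores.name or "score"]
    else:
        frame = expr_or_scores
    surv = _check_surv(surv)
    common = [s for s in frame.columns if s in surv.index]
    if len(common) < 10:
        raise InputError("need >= 10 samples with survival data")
    sub = surv.loc[common]
    time = sub["time_months"].to_numpy(dtype=float)
    event = sub["event"].to_numpy(dtype=int)
    if event.sum() < 3:
        raise InputError("need >= 3 events")
    z = sps.norm.ppf(0.975)
    rows = []
    for gene in frame.index:
        x = frame.loc[gene, common].to_numpy(dtype=float)
        if x.std(ddof=0) == 0:
            logger.info("gene %s skipped: constant covariate", gene)
            continue
        try:
            beta, se = cox_single(x, time, event)
        except ArithmeticError as exc:
            logger.info("gene %s skipped: %s", gene, exc)
            continue
        p = 2.0 * sps.norm.sf(abs(beta / se))
        rows.append(
            CoxResult(
                gene_or_score=str(gene),
                hazard_ratio=float(np.exp(beta)),
                beta=beta,
                se=se,
                p_value=float(p),
                ci=(float(np.exp(beta - z * se)), float(np.exp(beta + z * se))),
            )
        )
    table = pd.DataFrame(
        {
            "gene_or_score": [r.gene_or_score for r in rows],
            "hazard_ratio": [r.hazard_ratio for r in rows],
            "beta": [r.beta for r in rows],
            "se": [r.se for r in rows],
            "p_value": [r.p_value for r in rows],
            "ci_low": [r.ci[0] for r in rows],
            "ci_high": [r.ci[1] for r in rows],
        }
    )
    if hr_direction == "risk":
        retained_mask = (table["p_value"] < alpha) & (table["hazard_ratio"] > 1)
    else:
        retained_mask = (table["p_value"] < alpha) & (table["hazard_ratio"] < 1)
    table["retained"] = retained_mask
    panel = SignaturePanel(
        genes=sorted(table.loc[retained_mask, "gene_or_score"]),
        provenance={"screen": "univariate_cox", "hr_direction": hr_direction, "alpha": alpha},
    )
    return table, panel


def km_median_split(scores: pd.Series, surv: pd.DataFrame) -> KMComparison:
    """Kaplan-Meier comparison of the median-split high/low score groups.

    Samples at or below the median score form the low group.  Requires
    at least 2 samples per group and 1 event overall.
    """
    surv = _check_surv(surv)
    s = pd.Series(scores, dtype=float)
    common = s.index.intersection(surv.index)
    s = s.loc[common]
    sub = surv.loc[common]
    if s.nunique() < 2:
        raise InputError("degenerate split: all scores equal")
    med = s.median()
    groups = pd.Series(np.where(s > med, "high", "low"), index=s.index, name="group")
    n_high, n_low = (groups == "high").sum(), (groups == "low").sum()
    if n_high < 2 or n_low < 2:
        raise InputError("median split leaves fewer than 2 samples in a group")
    if sub["event"].sum() < 1:
        raise InputError("no events observed")
    res = multivariate_logrank_test(sub["time_months"], groups, sub["event"])
    curves = []
    medians = {}
    for g in ("low", "high"):
        mask = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(sub.loc[mask, "time_months"], sub.loc[mask, "event"], label=g)
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time_months", "survival"]
        sf.insert(0, "group", g)
        curves.append(sf)
        med_g = kmf.median_survival_time_
        medians[g] = float(med_g) if np.isfinite(med_g) else None
    return KMComparison(
        groups=groups,
        logrank_chi2=float(res.test_statistic),
        p_value=float(res.p_value),
        median_survival=medians,
        curves=pd.concat(curves, ignore_index=True),
    )


def multivariate_cox(covariates: pd.DataFrame, surv: pd.DataFrame) -> pd.DataFrame:
    """Multivariate Cox PH fit (thin wrapper over lifelines).

    ``covariates`` is samples x covariates; returns the lifelines
    summary table (coef, HR, CI, p per covariate).
    """
    from lifelines import CoxPHFitter

    surv = _check_surv(surv)
    common = covariates.index.intersection(surv.index)
    df = covariates.loc[common].copy()
    df["time_months"] = surv.loc[common, "time_months"]
    df["event"] = surv.loc[common, "event"]
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time_months", event_col="event")
    return cph.summary
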