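"""Synthetic cohorts with planted ground truth.

Generates log-scale expression matrices (bulk two-class cohorts and
clustered single-cell-like cohorts) with planted differentially expressed
signature genes, plus exponential survival times whose hazard depends on
a gene-panel score.  Every downstream stage of the pipeline can therefore
be exercised against known truth without any external data.

Expression is generated directly on the log scale as Gaussian noise
around a baseline, matching the log-normalized convention the pipeline
consumes (library-size normalization to 10,000 counts followed by log2),
so no count model is involved.  The per-gene discriminability of a
planted signal gene with shift delta and noise sd sigma has closed-form
AUC Phi(delta / (sigma * sqrt(2))).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_bulk_cohort",
    "simulate_cell_clusters",
    "simulate_survival",
]

# fixed order of per-stage RNG substreams; adding genes or stages must not
# perturb sample labels, so each stage draws from its own child stream
_STREAMS = ("expression", "labels", "survival", "censoring")


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of a synthetic cohort.

    Defaults mirror the study conditions the pipeline targets: a
    GSE156699-sized two-class cohort (50 responders, 38 nonresponders)
    over 2,000 genes with a 43-gene planted signature shifted upward in
    nonresponders by one noise-sd, and survival with a median around
    35 months at score zero under 30% independent censoring.
    """

    n_genes: int = 2000
    n_samples_R: int = 50
    n_samples_NR: int = 38
    n_signal_genes: int = 43
    effect_size_delta: float = 1.0  # mean log2-expression shift in NR
    noise_sd: float = 1.0
    baseline_mean: float = 2.0
    seed: int = 0
    survival_baseline_hazard: float = 0.02  # events per month at score 0
    survival_beta: float = 1.0  # log-hazard per unit panel score
    censor_rate: float = 0.3

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples_R < 0 or self.n_samples_NR < 0:
            raise ConfigurationError("cohort dimensions must be positive")
        if not 0 <= self.n_signal_genes <= self.n_genes:
            raise ConfigurationError("n_signal_genes must lie in [0, n_genes]")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ConfigurationError("censor_rate must lie in [0, 1]")
        if self.survival_baseline_hazard <= 0:
            raise ConfigurationError("survival_baseline_hazard must be > 0")

    def rngs(self) -> dict[str, np.random.Generator]:
        """Deterministic named substreams derived from the single seed."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SyntheticCohort:
    """A generated cohort: expression, phenotype, and the planted truth.

    ``expression`` is genes x samples; ``phenotype`` is indexed by
    sample_id with columns ``response`` (R/NR) and, when survival was
    generated, ``time_months``/``event`` (and ``cluster`` for cell
    cohorts).  ``truth`` lists the planted signal genes (a per-cluster
    dict for cell cohorts).  ``panel_score_true`` is the standardized
    per-sample mean expression over the planted genes.
    """

    expression: pd.DataFrame
    phenotype: pd.DataFrame
    truth: list | dict
    panel_score_true: pd.Series
    config: SimulationConfig

    def write(self, outdir: str | Path) -> None:
        """Write expression.tsv / phenotype.csv / truth.json (text formats)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.expression.to_csv(out / "expression.tsv", sep="\t", index_label="gene")
        self.phenotype.to_csv(out / "phenotype.csv", index_label="sample_id")
        meta = {
            "truth": self.truth,
            "config": self.config.to_dict(),
            "censoring": "random censoring: independent exponential C with hazard scaled so P(censored)=censor_rate",
        }
        (out / "truth.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def simulate_bulk_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Two-class bulk cohort with planted signature genes.

    Expression[g, s] ~ Normal(baseline + delta * 1[g signal and s NR], sd).
    The planted signal genes are the first ``n_signal_genes`` gene ids.
    Survival times are attached to the phenotype, with hazard
    baseline_hazard * exp(beta * panel_score_true).
    """
    if config.n_samples_R < 1 or config.n_samples_NR < 1:
        raise ConfigurationError("bulk cohort needs at least one sample per class")
    rngs = config.rngs()
    genes = _gene_ids(config.n_genes)
    samples = [f"R_{i:03d}" for i in range(1, config.n_samples_R + 1)] + [
        f"NR_{i:03d}" for i in range(1, config.n_samples_NR + 1)
    ]
    response = np.array(["R"] * config.n_samples_R + ["NR"] * config.n_samples_NR)
    x = rngs["expression"].normal(config.baseline_mean, config.noise_sd, size=(config.n_genes, len(samples)))
    truth = genes[: config.n_signal_genes]
    if truth:
        x[: config.n_signal_genes, response == "NR"] += config.effect_size_delta
    expr = pd.DataFrame(x, index=pd.Index(genes, name="gene"), columns=samples)

    if truth:
        raw = expr.loc[truth].mean(axis=0)
        sd = raw.std(ddof=0)
        score = (raw - raw.mean()) / (sd if sd > 0 else 1.0)
    else:
        score = pd.Series(0.0, index=samples)
    surv = simulate_survival(score, config, rng=rngs["survival"])
    pheno = pd.DataFrame({"response": response}, index=pd.Index(samples, name="sample_id"))
    pheno = pheno.join(surv)
    return SyntheticCohort(expression=expr, phenotype=pheno, truth=list(truth), panel_score_true=score, config=config)


def simulate_cell_clusters(
    config: SimulationConfig,
    n_clusters: int,
    cells_per_cluster: int,
    markers_per_cluster: int,
    nr_enrichment: list[float] | None = None,
) -> SyntheticCohort:
    """Clustered cell cohort with planted per-cluster marker genes.

    Each cluster's markers are up-shifted by ``effect_size_delta`` only in
    that cluster's cells.  ``nr_enrichment`` gives the per-cluster
    probability that a cell carries the NR origin label (default 0.5
    everywhere); 1.0 labels every cell of that cluster NR.
    """
    if n_clusters < 1 or cells_per_cluster < 1 or markers_per_cluster < 0:
        raise ConfigurationError("cluster dimensions must be positive")
    if markers_per_cluster * n_clusters > config.n_genes:
        raise ConfigurationError(
            f"insufficient genes: need {markers_per_cluster * n_clusters} marker slots, have {config.n_genes}"
        )
    if nr_enrichment is None:
        nr_enrichment = [0.5] * n_clusters
    if len(nr_enrichment) != n_clusters or any(not 0.0 <= f <= 1.0 for f in nr_enrichment):
        raise ConfigurationError("nr_enrichment must give one probability in [0,1] per cluster")

    rngs = config.rngs()
    genes = _gene_ids(config.n_genes)
    n_cells = n_clusters * cells_per_cluster
    cells = [f"c{i:05d}" for i in range(1, n_cells + 1)]
    clusters = np.repeat(np.arange(n_clusters), cells_per_cluster)
    x = rngs["expression"].normal(config.baseline_mean, config.noise_sd, size=(config.n_genes, n_cells))
    truth: dict[str, list[str]] = {}
    for c in range(n_clusters):
        marker_rows = slice(c * markers_per_cluster, (c + 1) * markers_per_cluster)
        truth[str(c)] = genes[marker_rows]
        x[marker_rows, clusters == c] += config.effect_size_delta
    probs = np.asarray(nr_enrichment)[clusters]
    response = np.where(rngs["labels"].random(n_cells) < probs, "NR", "R")
    expr = pd.DataFrame(x, index=pd.Index(genes, name="gene"), columns=cells)
    pheno = pd.DataFrame(
        {"response": response, "cluster": clusters}, index=pd.Index(cells, name="sample_id")
    )
    score = pd.Series(0.0, index=cells)
    return SyntheticCohort(expression=expr, phenotype=pheno, truth=truth, panel_score_true=score, config=config)


def simulate_survival(
    scores: pd.Series, config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Exponential survival with hazard baseline * exp(beta * score).

    Censoring follows the classical random-censoring model: an
    independent exponential censoring time with hazard scaled by
    censor_rate / (1 - censor_rate) relative to each subject's event
    hazard, so the observation is min(T, C) with event = [T <= C] and
    every subject is censored with probability exactly ``censor_rate``
    regardless of its covariate.  C is independent of T given the
    score, keeping the Cox partial likelihood unbiased.  Returns a
    DataFrame indexed like ``scores`` with columns ``time_months``
    (> 0) and ``event`` (0/1).
    """
    s = pd.Series(scores, dtype=float)
    if not np.all(np.isfinite(s.to_numpy())):
        raise InputError("scores must be finite")
    if rng is None:
        rng = config.rngs()["survival"]
    rate = config.survival_baseline_hazard * np.exp(config.survival_beta * s.to_numpy())
    times = rng.exponential(1.0 / rate)
    if config.censor_rate >= 1.0:
        observed = rng.exponential(1.0 / rate)
        censored = np.ones(s.size, dtype=bool)
    elif config.censor_rate <= 0.0:
        observed = times
        censored = np.zeros(s.size, dtype=bool)
    else:
        k = config.censor_rate / (1.0 - config.censor_rate)
        censor_times = rng.exponential(1.0 / (k * rate))
        observed = np.minimum(times, censor_times)
        censored = times > censor_times
    observed = np.maximum(observed, np.finfo(float).tiny)
    return pd.DataFrame(
        {"time_months": observed, "event": (~censored).astype(int)},
        index=s.index.rename("sample_id"),
    )
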