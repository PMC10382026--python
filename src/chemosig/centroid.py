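"""Nearest-centroid classifier with a continuous prediction score.

The classifier standardizes each panel gene on the training cohort,
forms per-class mean profiles (centroids), and scores a sample as the
difference of its Euclidean distances to the responder and nonresponder
centroids in the standardized gene space — a continuous score oriented
so that higher means more nonresponder-like (closer to the NR profile).
Scores are z-standardized against the training-score distribution and
converted to a nonresponse probability through a two-parameter logistic
calibration fit on the training scores.  A difference-of-Pearson-
correlations score is available behind the ``distance`` switch; note
that centering makes it insensitive to a shift shared by the whole
panel, the typical geometry of a response signature, which is why the
distance difference is the default.

Prediction on new cohorts always reuses the training-time gene scaling,
score scaling, and calibration (no re-standardization on test data).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression

from .exceptions import EvaluationError, InputError, ModelError
from .stats import RocResult, roc_auc

__all__ = ["CentroidClassifier", "CentroidModel", "fit_centroid_model", "predict", "evaluate"]

MIN_PANEL_GENES = 3  # a centroid panel needs at least three genes


def _feature_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise InputError("X must be a 2-D samples x genes matrix")
    return pd.DataFrame(arr, columns=[f"f{i}" for i in range(arr.shape[1])])


class CentroidClassifier(ClassifierMixin, BaseEstimator):
    """Nearest-centroid classifier over a gene panel (samples x genes).

    Parameters
    ----------
    panel : sequence of str, optional
        Gene (column) names to use; ``None`` uses every column.  Genes
        missing from the input are dropped with a warning; fitting
        aborts if fewer than 3 usable genes remain.
    distance : {"correlation", "euclidean"}
        "correlation": score = corr(sample, NR centroid) - corr(sample,
        R centroid).  "euclidean": difference of distances, same
        orientation.
    pos_label : str
        The class treated as "positive" (higher score); defaults to the
        nonresponder label ``"NR"``.  If absent from ``y``, the
        lexicographically last class is used.

    Attributes (after fit)
    ----------------------
    panel_genes_ : list of str — retained genes, in panel order.
    gene_mean_, gene_sd_ : per-gene training standardization.
    centroid_pos_, centroid_neg_ : standardized class mean profiles.
    score_mean_, score_sd_ : training raw-score standardization.
    calib_intercept_, calib_slope_ : logistic calibration on score_z.
    threshold_ : score_z at which the calibrated probability is 0.5.
    """

    def __init__(self, panel=None, distance: str = "euclidean", pos_label: str = "NR", calibration_c: float = 1e6):
        self.panel = panel
        self.distance = distance
        self.pos_label = pos_label
        self.calibration_c = calibration_c

    # -- internals ---------------------------------------------------------

    def _select(self, frame: pd.DataFrame, genes, *, minimum=MIN_PANEL_GENES) -> pd.DataFrame:
        present = [g for g in genes if g in frame.columns]
        missing = [g for g in genes if g not in frame.columns]
        if missing:
            warnings.warn(f"{len(missing)} panel gene(s) missing from input: {missing[:10]}", stacklevel=3)
        if len(present) < minimum:
            raise ModelError(f"fewer than {minimum} panel genes present ({len(present)})")
        return frame[present]

    def _raw_scores(self, Z: np.ndarray) -> np.ndarray:
        """Continuous score per row of standardized matrix Z (samples x genes)."""
        cpos, cneg = self.centroid_pos_, self.centroid_neg_
        if self.distance == "euclidean":
            dpos = np.sqrt(((Z - cpos) ** 2).sum(axis=1))
            dneg = np.sqrt(((Z - cneg) ** 2).sum(axis=1))
            return dneg - dpos
        zc = Z - Z.mean(axis=1, keepdims=True)
        zden = np.sqrt((zc**2).sum(axis=1))

        def corr(c):
            cc = c - c.mean()
            den = zden * np.sqrt((cc**2).sum())
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (zc @ cc) / den
            return np.where(den > 0, r, 0.0)

        return corr(cpos) - corr(cneg)

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        if self.distance not in ("correlation", "euclidean"):
            raise InputError(f"unknown distance {self.distance!r}")
        frame = _feature_frame(X)
        y = np.asarray(y)
        if frame.shape[0] != y.shape[0]:
            raise InputError("X and y disagree on the number of samples")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise InputError("exactly two classes are required")
        for cls in self.classes_:
            if (y == cls).sum() < 2:
                raise InputError(f"class {cls!r} has fewer than 2 training samples")
        self.pos_class_ = self.pos_label if self.pos_label in self.classes_ else self.classes_[-1]
        self.neg_class_ = [c for c in self.classes_ if c != self.pos_class_][0]

        genes = list(self.panel) if self.panel is not None else list(frame.columns)
        sub = self._select(frame, genes)
        vals = sub.to_numpy(dtype=float)
        mean = vals.mean(axis=0)
        sd = vals.std(axis=0, ddof=0)
        keep = sd > 0
        if (~keep).any():
            dropped = [g for g, k in zip(sub.columns, keep) if not k]
            warnings.warn(f"dropped {len(dropped)} zero-variance gene(s): {dropped[:10]}", stacklevel=2)
        if keep.sum() < MIN_PANEL_GENES:
            raise ModelError(f"fewer than {MIN_PANEL_GENES} usable genes after dropping zero-variance rows")
        self.panel_genes_ = [g for g, k in zip(sub.columns, keep) if k]
        self.gene_mean_ = mean[keep]
        self.gene_sd_ = sd[keep]
        Z = (vals[:, keep] - self.gene_mean_) / self.gene_sd_
        self.centroid_pos_ = Z[y == self.pos_class_].mean(axis=0)
        self.centroid_neg_ = Z[y == self.neg_class_].mean(axis=0)

        raw = self._raw_scores(Z)
        self.score_mean_ = float(raw.mean())
        sd_raw = float(raw.std(ddof=0))
        self.score_sd_ = sd_raw if sd_raw > 0 else 1.0
        score_z = (raw - self.score_mean_) / self.score_sd_

        # near-unpenalized logistic MLE; the tiny ridge keeps perfectly
        # separated training scores from diverging
        lr = LogisticRegression(C=self.calibration_c, solver="lbfgs", max_iter=2000)
        lr.fit(score_z.reshape(-1, 1), (y == self.pos_class_).astype(int))
        self.calib_intercept_ = float(lr.intercept_[0])
        self.calib_slope_ = float(lr.coef_[0, 0])
        self.threshold_ = (
            -self.calib_intercept_ / self.calib_slope_ if self.calib_slope_ != 0 else float("inf")
        )
        self.n_features_in_ = frame.shape[1]
        return self

    def _score_frame(self, X) -> np.ndarray:
        frame = _feature_frame(X)
        present = [g for g in self.panel_genes_ if g in frame.columns]
        if len(present) < MIN_PANEL_GENES:
            raise ModelError(f"fewer than {MIN_PANEL_GENES} model genes present in prediction input")
        if len(present) < len(self.panel_genes_):
            warnings.warn(
                f"{len(self.panel_genes_) - len(present)} model gene(s) missing from prediction input",
                stacklevel=3,
            )
        idx = [self.panel_genes_.index(g) for g in present]
        Z = (frame[present].to_numpy(dtype=float) - self.gene_mean_[idx]) / self.gene_sd_[idx]
        saved = self.centroid_pos_, self.centroid_neg_
        try:
            self.centroid_pos_ = saved[0][idx]
            self.centroid_neg_ = saved[1][idx]
            raw = self._raw_scores(Z)
        finally:
            self.centroid_pos_, self.centroid_neg_ = saved
        return (raw - self.score_mean_) / self.score_sd_

    def decision_function(self, X) -> np.ndarray:
        """Standardized continuous prediction score (higher => positive class)."""
        return self._score_frame(X)

    def predict_proba(self, X) -> np.ndarray:
        z = self.decision_function(X)
        p_pos = 1.0 / (1.0 + np.exp(-(self.calib_intercept_ + self.calib_slope_ * z)))
        out = np.empty((z.size, 2))  # columns follow classes_ order
        for j, cls in enumerate(self.classes_):
            out[:, j] = p_pos if cls == self.pos_class_ else 1.0 - p_pos
        return out

    def predict(self, X) -> np.ndarray:
        z = self.decision_function(X)
        pos = z > self.threshold_
        return np.where(pos, self.pos_class_, self.neg_class_)


# -- domain surface (gene x sample frames, phenotype tables) ---------------


def _response_series(labels) -> pd.Series:
    if isinstance(labels, pd.DataFrame):
        if "response" not in labels.columns:
            raise InputError("phenotype table lacks a 'response' column")
        return labels["response"]
    return pd.Series(labels)


@dataclass
class CentroidModel:
    """A fitted centroid model plus its provenance.

    Wraps a fitted :class:`CentroidClassifier`; ``panel`` is the panel
    as requested (before drops) and ``genes`` the retained genes.
    """

    estimator: CentroidClassifier
    panel: list[str]
    metadata: dict = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.estimator.panel_genes_)

    def to_json(self, path: str | Path | None = None) -> str:
        est = self.estimator
        payload = {
            "panel": list(self.panel),
            "genes": est.panel_genes_,
            "distance": est.distance,
            "classes": [str(c) for c in est.classes_],
            "pos_class": str(est.pos_class_),
            "neg_class": str(est.neg_class_),
            "gene_mean": est.gene_mean_.tolist(),
            "gene_sd": est.gene_sd_.tolist(),
            "centroid_pos": est.centroid_pos_.tolist(),
            "centroid_neg": est.centroid_neg_.tolist(),
            "score_mean": est.score_mean_,
            "score_sd": est.score_sd_,
            "calibration": {"intercept": est.calib_intercept_, "slope": est.calib_slope_},
            "threshold": est.threshold_,
            "orientation": "higher score => " + str(est.pos_class_),
            "metadata": self.metadata,
        }
        text = json.dumps(payload, indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CentroidModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        est = CentroidClassifier(panel=d["panel"], distance=d["distance"], pos_label=d["pos_class"])
        est.classes_ = np.array(d["classes"])
        est.pos_class_ = d["pos_class"]
        est.neg_class_ = d["neg_class"]
        est.panel_genes_ = list(d["genes"])
        est.gene_mean_ = np.array(d["gene_mean"])
        est.gene_sd_ = np.array(d["gene_sd"])
        est.centroid_pos_ = np.array(d["centroid_pos"])
        est.centroid_neg_ = np.array(d["centroid_neg"])
        est.score_mean_ = d["score_mean"]
        est.score_sd_ = d["score_sd"]
        est.calib_intercept_ = d["calibration"]["intercept"]
        est.calib_slope_ = d["calibration"]["slope"]
        est.threshold_ = d["threshold"]
        return cls(estimator=est, panel=list(d["panel"]), metadata=d.get("metadata", {}))


def fit_centroid_model(expr: pd.DataFrame, labels, panel, distance: str = "euclidean") -> CentroidModel:
    """Fit a centroid model on a genes x samples matrix and R/NR labels."""
    resp = _response_series(labels).reindex(expr.columns)
    if resp.isna().any():
        raise InputError(f"labels missing for samples: {list(expr.columns[resp.isna()])[:10]}")
    est = CentroidClassifier(panel=list(panel), distance=distance)
    est.fit(expr.T, resp.to_numpy())
    return CentroidModel(estimator=est, panel=list(panel), metadata={"n_train": int(expr.shape[1])})


def predict(model: CentroidModel, expr: pd.DataFrame) -> pd.DataFrame:
    """Score a cohort with a frozen model.

    Returns one row per sample: ``score_z``, ``prob_nonresponse``
    (calibrated probability of the positive/nonresponder class) and the
    dichotomous ``call``.
    """
    est = model.estimator
    z = est.decision_function(expr.T)
    p_pos = 1.0 / (1.0 + np.exp(-(est.calib_intercept_ + est.calib_slope_ * z)))
    call = np.where(z > est.threshold_, est.pos_class_, est.neg_class_)
    return pd.DataFrame(
        {"score_z": z, "prob_nonresponse": p_pos, "call": call},
        index=pd.Index(expr.columns, name="sample_id"),
    )


def evaluate(model: CentroidModel, expr: pd.DataFrame, labels) -> RocResult:
    """ROC evaluation of a frozen model on a labeled cohort."""
    est = model.estimator
    resp = _response_series(labels).reindex(expr.columns)
    if resp.isna().any():
        raise InputError(f"labels missing for samples: {list(expr.columns[resp.isna()])[:10]}")
    scores = predict(model, expr)["score_z"].to_numpy()
    pos_mask = resp.to_numpy() == est.pos_class_
    if pos_mask.all() or (~pos_mask).all():
        raise EvaluationError("evaluation requires both classes present")
    return roc_auc(scores[pos_mask], scores[~pos_mask])
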