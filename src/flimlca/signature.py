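"""Zero-mean linear class-prediction signature with ROC / Youden thresholding.

The signature combines standardized covariates with weights w into a score
s = w . x + c, where the constant c is chosen so the mean score over the
training cohort is exactly zero.  The decision rule assigns class 2 (the
poorer-prognosis majority class) when s exceeds a threshold theta, chosen as
the Youden-index maximizer (J = sensitivity + specificity - 1) of the
empirical ROC curve, with ties broken by the smallest threshold.
Standardization parameters are frozen from the training cohort, so the
signature can be applied blind to an independent validation cohort.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .cohort import Cohort
from .preprocess import DesignInfo, apply_design, build_design
from . import survival as survival_stats

__all__ = ["SignatureModel", "RocResult", "fit_signature", "score",
           "roc_youden", "evaluate_signature"]


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_threshold: float
    youden_sensitivity: float
    youden_specificity: float
    degenerate: bool = False


@dataclass
class SignatureModel:
    covariate_names: list
    design_names: list
    weights: np.ndarray                 # per design column, standardized scale
    constant: float
    threshold: float                    # NaN until set from roc_youden
    design_info: DesignInfo
    trained_on: str = ""

    def to_json(self) -> str:
        payload = {
            "covariate_names": list(self.covariate_names),
            "design_names": list(self.design_names),
            "weights": self.weights.tolist(),
            "constant": self.constant,
            "threshold": self.threshold,
            "standardization": {
                "input_names": self.design_info.input_names,
                "names": self.design_info.names,
                "center": self.design_info.center.tolist(),
                "scale": self.design_info.scale.tolist(),
                "indicator_for": self.design_info.indicator_for,
                "impute": self.design_info._impute,
            },
            "trained_on": self.trained_on,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SignatureModel":
        d = json.loads(text)
        std = d["standardization"]
        info = DesignInfo(std["input_names"], std["names"],
                          np.array(std["center"]), np.array(std["scale"]),
                          std["indicator_for"])
        info._impute = std["impute"]
        return cls(d["covariate_names"], d["design_names"],
                   np.array(d["weights"]), d["constant"], d["threshold"],
                   info, d["trained_on"])


def fit_signature(cohort: Cohort, class_labels, covariate_names,
                  alpha: float = 1.0) -> SignatureModel:
    """Fit ridge-logistic weights for predicting class 2 membership.

    ``class_labels`` must take exactly two values; the larger one is treated
    as class 2 (high score).  The constant makes the mean training score
    exactly zero.  The decision threshold stays unset (NaN) until
    :func:`roc_youden` is consulted.
    """
    y = np.asarray(class_labels)
    uniq = np.unique(y)
    if uniq.size != 2:
        raise ValueError("class_labels must contain exactly two classes")
    y01 = (y == uniq[-1]).astype(int)
    X, info = build_design(cohort.table, list(covariate_names))
    clf = LogisticRegression(C=1.0 / alpha, max_iter=2000)
    clf.fit(X, y01)
    w = clf.coef_.ravel()
    c = -float(np.mean(X @ w))
    return SignatureModel(covariate_names=list(covariate_names),
                          design_names=info.names, weights=w, constant=c,
                          threshold=math.nan, design_info=info,
                          trained_on=cohort.name)


def score(model: SignatureModel, cohort: Cohort) -> np.ndarray:
    """Per-patient signature scores using the frozen training standardization."""
    X = apply_design(cohort.table, model.design_info)
    return X @ model.weights + model.constant


def predict_class(model: SignatureModel, cohort: Cohort) -> np.ndarray:
    """1/2 class labels: class 2 when score > threshold."""
    if not np.isfinite(model.threshold):
        raise ValueError("signature threshold is unset; run roc_youden first")
    s = score(model, cohort)
    return np.where(s > model.threshold, 2, 1)


def roc_youden(scores, labels) -> RocResult:
    """Empirical ROC over all observed cut-points, with Youden thresholding.

    ``labels`` are truthy for the positive (class 2, high-score) group.  The
    decision rule is ``score > threshold``.  AUC is the trapezoid area; the
    Youden threshold maximizes J = sens + spec - 1, smallest value on ties.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    degenerate = np.unique(s).size == 1
    # candidate cut-points: below the minimum (classify everything positive)
    # plus every observed score (>: the point itself becomes negative)
    uniq = np.unique(s)
    thresholds = np.concatenate([[uniq[0] - 1.0], uniq])
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, th in enumerate(thresholds):
        pred_pos = s > th
        sens[i] = (pred_pos & y).sum() / n_pos
        spec[i] = (~pred_pos & ~y).sum() / n_neg
    # AUC by trapezoid over the (FPR, TPR) polyline, ties ordered by TPR
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))
    auc = float(np.trapezoid(sens[order], fpr[order])) if not degenerate else 0.5
    if degenerate:
        warnings.warn("constant scores: ROC is degenerate", RuntimeWarning,
                      stacklevel=2)
        j_idx = 0
    else:
        j = sens + spec - 1.0
        j_idx = int(np.argmax(j))          # first (= smallest threshold) on ties
        best = j[j_idx]
        ties = np.flatnonzero(j >= best - 1e-15)
        j_idx = int(ties[np.argmin(thresholds[ties])])
    return RocResult(thresholds=thresholds, sensitivity=sens, specificity=spec,
                     auc=auc, youden_threshold=float(thresholds[j_idx]),
                     youden_sensitivity=float(sens[j_idx]),
                     youden_specificity=float(spec[j_idx]),
                     degenerate=degenerate)


def evaluate_signature(model: SignatureModel, cohort: Cohort,
                       arm_col: str | None = None,
                       control_level: float = 0.0) -> dict:
    """Apply the thresholded signature and summarize survival by predicted class.

    Prognostic check: log-rank between predicted classes (within the control
    arm when ``arm_col`` is given, as treatment effects would otherwise
    confound prognosis).  Predictive check: log-rank between arms within each
    predicted class.  Returns a JSON-serializable report with KM tables.
    """
    pred = predict_class(model, cohort)
    t, e = cohort.time, cohort.event
    report: dict = {"n": cohort.n,
                    "predicted_class_counts": {int(c): int((pred == c).sum())
                                               for c in (1, 2)}}

    def km_block(mask) -> dict:
        curve = survival_stats.km_estimate(t[mask], e[mask])
        return {"n": int(mask.sum()), "median": curve.median,
                "median_ci": list(curve.median_ci),
                "table": curve.table().to_dict(orient="list")}

    arm = (pd.to_numeric(cohort.table[arm_col], errors="coerce").to_numpy()
           if arm_col else None)

    # prognostic split
    prog_mask = np.ones(cohort.n, dtype=bool) if arm is None \
        else arm == control_level
    sub_pred = pred[prog_mask]
    if np.unique(sub_pred).size == 2:
        stat, p = survival_stats.logrank(t[prog_mask], e[prog_mask], sub_pred)
        report["prognostic"] = {
            "logrank_stat": stat, "p": p,
            "km": {int(c): km_block(prog_mask & (pred == c)) for c in (1, 2)}}
    else:
        warnings.warn("prognostic split skipped: one predicted class absent",
                      RuntimeWarning, stacklevel=2)

    # predictive splits
    if arm is not None:
        report["predictive"] = {}
        for c in (1, 2):
            mask = pred == c
            if np.unique(arm[mask]).size < 2:
                warnings.warn(f"predictive split skipped for class {c}: "
                              "single treatment arm", RuntimeWarning,
                              stacklevel=2)
                continue
            stat, p = survival_stats.logrank(t[mask], e[mask], arm[mask])
            report["predictive"][int(c)] = {"logrank_stat": stat, "p": p}
    return report
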