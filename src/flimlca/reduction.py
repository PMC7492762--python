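"""Backwards elimination of covariates under repeated cross-validated
survival (or class-prediction) performance.

At each step every remaining covariate is tentatively removed; each reduced
model is refit on the training folds of every (repeat, fold) split and scored
on the held-out fold.  The covariate whose removal least degrades the mean
held-out score is eliminated.  Elimination stops when even the best removal
degrades the score by more than ``stop_rule`` standard errors of the paired
fold-wise score difference (a one-standard-error-style rule).

Inner fits are Gaussian-prior MAP ("ridge") estimates: penalized Cox partial
likelihood for survival outcomes, penalized logistic regression for class
labels.  Scores are proper likelihood-based quantities: mean held-out partial
log-likelihood per event, or negative log-loss.

``selection_frequency`` reports, per covariate, the fraction of CV repeats in
which it survived: each repeat replays the consensus elimination path but
applies the stopping rule to its own folds' scores, so unstable covariates
drop out in some repeats and not others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

from ._cox import cox_partial_loglik, cox_ridge_fit
from ._rng import child_seed
from .cohort import Cohort
from .preprocess import build_design

__all__ = ["ReductionResult", "reduce_covariates"]


@dataclass
class ReductionResult:
    elimination_order: list            # covariates in order of removal (consensus)
    selected: list                     # final consensus covariate set
    selection_frequency: dict          # name -> fraction of repeats surviving
    cv_score_trace: list               # [(mean, sd)] per step, full model first
    settings: dict = field(default_factory=dict)


def _survival_scorer(X, t, d, alpha):
    def score(cols, train, test):
        if len(cols) == 0:
            beta = np.zeros(0)
        else:
            beta, _ = cox_ridge_fit(X[np.ix_(train, cols)], t[train], d[train],
                                    alpha=alpha)
        n_ev = d[test].sum()
        if n_ev == 0:
            return np.nan
        ll = cox_partial_loglik(X[np.ix_(test, cols)], t[test], d[test], beta)
        return ll / n_ev
    return score


def _class_scorer(X, y, alpha):
    def score(cols, train, test):
        if len(cols) == 0:
            p = np.full(len(test), y[train].mean())
        else:
            clf = LogisticRegression(C=1.0 / alpha, max_iter=1000)
            clf.fit(X[np.ix_(train, cols)], y[train])
            p = clf.predict_proba(X[np.ix_(test, cols)])[:, 1]
        return -log_loss(y[test], p, labels=[0, 1])
    return score


def reduce_covariates(cohort: Cohort, covariate_names, outcome: str = "survival",
                      class_labels=None, folds: int = 5, repeats: int = 20,
                      stop_rule: float = 1.0, alpha: float = 0.1,
                      seed: int = 0) -> ReductionResult:
    """Backwards elimination under repeated cross-validation.

    ``outcome`` is "survival" (uses the cohort's time/event) or "class-label"
    (requires ``class_labels``, coded as two values).  Deterministic under a
    fixed seed.
    """
    names = list(covariate_names)
    if len(names) < 2:
        raise ValueError("need at least two covariates to reduce")
    X, info = build_design(cohort.table, names)
    # map each input covariate to its design columns (incl. its indicator)
    col_groups = {n: [j for j, dn in enumerate(info.names)
                      if dn == n or info.indicator_for.get(dn) == n]
                  for n in names}
    t, d = cohort.time, cohort.event

    if outcome == "survival":
        if d.sum() < folds:
            raise ValueError("need at least `folds` events for a survival outcome")
        scorer = _survival_scorer(X, t, d, alpha)
        strat = d
    elif outcome == "class-label":
        if class_labels is None:
            raise ValueError("class_labels required for outcome='class-label'")
        y = np.asarray(class_labels)
        uniq = np.unique(y)
        if uniq.size != 2:
            raise ValueError("class_labels must take exactly two values")
        y01 = (y == uniq[1]).astype(int)
        scorer = _class_scorer(X, y01, alpha)
        strat = y01
    else:
        raise ValueError("outcome must be 'survival' or 'class-label'")

    # fold index pairs for every (repeat, fold), stratified on events/labels
    splits = []           # list of lists: splits[r] = [(train, test), ...]
    for r in range(repeats):
        kf = StratifiedKFold(n_splits=folds, shuffle=True,
                             random_state=child_seed(seed, "cv", r))
        splits.append([(tr, te) for tr, te in kf.split(X, strat)])

    def scores_for(cols) -> np.ndarray:
        """(repeats, folds) held-out scores for a covariate subset."""
        out = np.full((repeats, folds), np.nan)
        for r in range(repeats):
            for f, (tr, te) in enumerate(splits[r]):
                try:
                    out[r, f] = scorer(cols, tr, te)
                except Exception as exc:
                    warnings.warn(f"fold skipped ({exc})", RuntimeWarning,
                                  stacklevel=2)
        if np.isnan(out).all():
            raise RuntimeError("all CV folds failed")
        return out

    def cols_of(subset) -> list:
        return [j for n in subset for j in col_groups[n]]

    current = list(names)
    cur_scores = scores_for(cols_of(current))
    trace = [(float(np.nanmean(cur_scores)), float(np.nanstd(cur_scores, ddof=1)))]
    elimination_order: list[str] = []
    step_records = []      # (removed name, scores before, scores after)

    while current:
        best_name, best_scores = None, None
        for nme in current:
            cand = [c for c in current if c != nme]
            s = scores_for(cols_of(cand))
            if best_scores is None or np.nanmean(s) > np.nanmean(best_scores):
                best_name, best_scores = nme, s
        diffs = (best_scores - cur_scores).ravel()
        diffs = diffs[~np.isnan(diffs)]
        se = diffs.std(ddof=1) / np.sqrt(diffs.size) if diffs.size > 1 else 0.0
        if diffs.mean() < -stop_rule * se:
            break
        step_records.append((best_name, cur_scores.copy(), best_scores.copy()))
        elimination_order.append(best_name)
        current = [c for c in current if c != best_name]
        cur_scores = best_scores
        trace.append((float(np.nanmean(cur_scores)),
                      float(np.nanstd(cur_scores, ddof=1))))

    # per-repeat survival along the consensus path
    freq = {n: 0.0 for n in names}
    for r in range(repeats):
        surviving = list(names)
        for nme, before, after in step_records:
            db = after[r] - before[r]
            diffs_r = db[~np.isnan(db)]
            se_r = (diffs_r.std(ddof=1) / np.sqrt(diffs_r.size)
                    if diffs_r.size > 1 else 0.0)
            if diffs_r.size and diffs_r.mean() < -stop_rule * se_r:
                break
            surviving = [c for c in surviving if c != nme]
        for nme in surviving:
            freq[nme] += 1.0 / repeats

    return ReductionResult(
        elimination_order=elimination_order,
        selected=current,
        selection_frequency=freq,
        cv_score_trace=trace,
        settings={"folds": folds, "repeats": repeats, "stop_rule": stop_rule,
                  "alpha": alpha, "seed": seed, "outcome": outcome},
    )
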