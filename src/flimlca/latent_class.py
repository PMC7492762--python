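"""Latent-class survival analysis: a K-component mixture of proportional-
hazards models with class-specific piecewise-constant baseline hazards and
class-specific covariate effects.

Model.  Patient i with covariates x_i belongs to unobserved class k with
probability pi_k.  Within class k the hazard is

    h_k(t | x) = h0_k(t) * exp(beta_k . x),

with h0_k piecewise constant on shared event-time-quantile bins.  Both the
baseline hazards and the coefficients differ by class ("base hazard rate
heterogeneity"), so classes can differ in prognosis and in treatment
response.  The observed-data likelihood sums class-conditional
piecewise-exponential PH likelihoods over k, and is maximized by EM:

  E-step: posterior class memberships (responsibilities) from current
          parameters;
  M-step: pi = mean responsibility; per class, alternated closed-form
          occurrence/exposure updates for the baseline rates and Newton
          steps for beta on the responsibility-weighted Poisson likelihood.

Each conditional maximization increases the EM surrogate, so the observed
log-likelihood is non-decreasing across iterations.  The number of classes
and of baseline bins is selected by BIC, a Laplace-type proxy for Bayesian
model selection.  Patients are assigned by maximum a posteriori (MAP)
membership, and classes are ordered so class 1 has the longest
model-implied median survival at the mean covariate vector (class 1 = best
prognosis).  Wald standard errors come from the numerically evaluated
observed information of the full mixture log-likelihood.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ._rng import child_seed, substream
from .cohort import Cohort
from .preprocess import DesignInfo, build_design

__all__ = [
    "LatentClassModel", "ClassAssignment", "fit_latent_class_model",
    "select_model", "hazard_ratios", "class_proportion",
]

_Z95 = 1.959963984540054


@dataclass
class ClassAssignment:
    membership: np.ndarray      # (n, K) posterior probabilities, rows sum to 1
    map_label: np.ndarray       # (n,) 1-based class labels, ties -> lowest index

    def table(self, patient_id) -> pd.DataFrame:
        out = pd.DataFrame({"patient_id": patient_id})
        for k in range(self.membership.shape[1]):
            out[f"prob_class{k + 1}"] = self.membership[:, k]
        out["map_class"] = self.map_label
        return out


@dataclass
class LatentClassModel:
    k: int
    mixing_weights: np.ndarray          # (K,)
    cut_points: np.ndarray              # (B,) starting at 0
    baseline_rates: np.ndarray          # (K, B)
    coefs: np.ndarray                   # (K, p) on the standardized design scale
    coef_se: np.ndarray                 # (K, p), NaN when unavailable
    covariate_names: list               # input covariate names
    design_names: list                  # design columns (incl. missing indicators)
    design_info: DesignInfo
    log_likelihood: float
    n_parameters: int
    n_obs: int
    bic: float
    converged: bool
    n_iter: int
    n_restarts: int
    seed: int
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "mixing_weights": self.mixing_weights.tolist(),
            "cut_points": self.cut_points.tolist(),
            "baseline_rates": self.baseline_rates.tolist(),
            "coefs": self.coefs.tolist(),
            "coef_se": self.coef_se.tolist(),
            "covariate_names": list(self.covariate_names),
            "design_names": list(self.design_names),
            "log_likelihood": self.log_likelihood,
            "n_parameters": self.n_parameters,
            "n_obs": self.n_obs,
            "bic": self.bic,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n_restarts": self.n_restarts,
            "seed": self.seed,
        }


# --------------------------------------------------------------------------
# person-time expansion

def _event_time_cuts(t: np.ndarray, d: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin boundaries at quantiles of the observed event times, starting at 0."""
    ev = np.sort(t[d == 1])
    if ev.size == 0:
        raise ValueError("cohort has no events")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    qs = np.quantile(ev, np.arange(1, n_bins) / n_bins) if n_bins > 1 else np.array([])
    cuts = np.concatenate([[0.0], np.unique(qs)])
    return cuts


def _exposure(t: np.ndarray, d: np.ndarray, cuts: np.ndarray):
    """Per-subject exposure time in each bin and event-bin one-hot."""
    n, B = t.size, cuts.size
    upper = np.concatenate([cuts[1:], [np.inf]])
    expo = np.clip(np.minimum(t[:, None], upper[None, :]) - cuts[None, :], 0.0, None)
    # an event at an exact bin boundary belongs to the interval it closes
    bin_idx = np.clip(np.searchsorted(cuts, t, side="left") - 1, 0, B - 1)
    ev = np.zeros((n, B))
    ev[np.arange(n), bin_idx] = d
    return expo, ev


# --------------------------------------------------------------------------
# likelihood pieces

def _class_loglik(expo, ev, X, log_rates, beta):
    """(n,) class-conditional log-likelihood for one class."""
    eta = X @ beta if X.size else np.zeros(expo.shape[0])
    eta = np.clip(eta, -500, 500)
    A = expo @ np.exp(log_rates)
    return ev @ log_rates + ev.sum(axis=1) * eta - np.exp(eta) * A


def _mixture_loglik_matrix(expo, ev, X, log_pi, log_rates, betas):
    K = log_pi.size
    ll = np.empty((expo.shape[0], K))
    for k in range(K):
        ll[:, k] = log_pi[k] + _class_loglik(expo, ev, X, log_rates[k], betas[k])
    return ll


def _m_step_class(expo, ev, X, w, beta, n_inner=3):
    """Maximize the w-weighted class likelihood over (rates, beta)."""
    d_i = ev.sum(axis=1)
    for _ in range(n_inner):
        eta = np.clip(X @ beta, -500, 500) if X.size else np.zeros(expo.shape[0])
        mu = np.exp(eta)
        num = w @ ev
        den = (w * mu) @ expo
        rates = np.clip(num / np.clip(den, 1e-300, None), 1e-12, None)
        if X.size == 0:
            break
        # one damped Newton step for beta at the current rates
        A = expo @ rates
        resid = w * (d_i - mu * A)
        g = X.T @ resid
        H = (X * (w * mu * A)[:, None]).T @ X
        H_reg = H + 1e-10 * np.eye(H.shape[0])
        try:
            step = np.linalg.solve(H_reg, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H_reg, g, rcond=None)[0]

        def q(b):
            et = np.clip(X @ b, -500, 500)
            return float(w @ (d_i * et - np.exp(et) * A))

        q0 = q(beta)
        scale = 1.0
        for _half in range(30):
            cand = beta + scale * step
            if q(cand) >= q0 - 1e-12:
                beta = cand
                break
            scale *= 0.5
    # final rates consistent with final beta
    eta = np.clip(X @ beta, -500, 500) if X.size else np.zeros(expo.shape[0])
    mu = np.exp(eta)
    rates = np.clip((w @ ev) / np.clip((w * mu) @ expo, 1e-300, None), 1e-12, None)
    return rates, beta


def _init_responsibilities(t, d, X, K, rng, restart):
    """K-means on (log time, event, covariates) plus restart-dependent jitter."""
    n = t.size
    if K == 1:
        return np.ones((n, 1))
    feats = np.column_stack([np.log(t), d] + ([X] if X.size else []))
    feats = (feats - feats.mean(axis=0)) / np.clip(feats.std(axis=0), 1e-12, None)
    from sklearn.cluster import KMeans
    km = KMeans(n_clusters=K, n_init=1,
                random_state=int(rng.integers(0, 2**31 - 1)))
    labels = km.fit_predict(feats)
    r = np.full((n, K), 0.05 / max(K - 1, 1))
    r[np.arange(n), labels] = 0.95
    jitter = 0.1 + 0.4 * min(restart, 5) / 5.0   # later restarts are noisier
    g = rng.dirichlet(np.ones(K), size=n)
    r = (1 - jitter) * r + jitter * g
    return r / r.sum(axis=1, keepdims=True)


def _model_implied_medians(cuts, rates, betas, x_mean):
    """Median survival per class at the mean covariate vector."""
    K = rates.shape[0]
    med = np.empty(K)
    for k in range(K):
        mult = math.exp(float(np.clip(x_mean @ betas[k], -500, 500))) \
            if x_mean.size else 1.0
        target = math.log(2.0) / mult
        acc = 0.0
        med[k] = math.inf
        widths = np.append(np.diff(cuts), np.inf)
        for b in range(rates.shape[1]):
            step = rates[k, b] * widths[b]
            if acc + step >= target:
                med[k] = cuts[b] + (target - acc) / rates[k, b]
                break
            acc += step
    return med


def _subject_scores(expo, ev, X, pi, rates, betas):
    """Per-subject analytic scores of the mixture log-likelihood.

    Parameter order: mixing logits (K-1, relative to the last class),
    log baseline rates (K*B), betas (K*p).  Scores are the responsibility-
    weighted class-conditional scores.
    """
    K, B = rates.shape
    p = betas.shape[1]
    ll = _mixture_loglik_matrix(expo, ev, X, np.log(pi), np.log(rates), betas)
    norm = logsumexp(ll, axis=1)
    r = np.exp(ll - norm[:, None])
    d_i = ev.sum(axis=1)
    cols = []
    if K > 1:
        cols.append(r[:, :-1] - pi[None, :-1])
    for k in range(K):
        eta = np.clip(X @ betas[k], -500, 500) if p else np.zeros(expo.shape[0])
        mu = np.exp(eta)
        cols.append(r[:, [k]] * (ev - mu[:, None] * rates[k][None, :] * expo))
    for k in range(K):
        eta = np.clip(X @ betas[k], -500, 500) if p else np.zeros(expo.shape[0])
        mu = np.exp(eta)
        cols.append(X * (r[:, k] * (d_i - mu * (expo @ rates[k])))[:, None])
    return np.hstack(cols)


def _numeric_se(expo, ev, X, pi, rates, betas):
    """Robust (sandwich) Wald SEs for beta: I^-1 V I^-1 with the observed
    information I from a central finite-difference Jacobian of the analytic
    score and V the empirical outer product of per-subject scores.

    Because class membership is itself estimated, bare observed-information
    intervals are anti-conservative in finite samples; the sandwich form
    restores close-to-nominal coverage.
    """
    K, B = rates.shape
    p = betas.shape[1]

    def pack():
        parts = []
        if K > 1:
            parts.append(np.log(pi[:-1] / pi[-1]))
        parts.append(np.log(rates).ravel())
        parts.append(betas.ravel())
        return np.concatenate(parts)

    def unpack(theta):
        i = 0
        if K > 1:
            z = theta[: K - 1]
            i = K - 1
            e = np.concatenate([np.exp(z), [1.0]])
            pi_ = e / e.sum()
        else:
            pi_ = np.ones(1)
        lr = theta[i: i + K * B].reshape(K, B)
        i += K * B
        b = theta[i:].reshape(K, p)
        return pi_, lr, b

    def total_score(theta):
        pi_, lr, b = unpack(theta)
        return _subject_scores(expo, ev, X, pi_, np.exp(lr), b).sum(axis=0)

    theta0 = pack()
    m = theta0.size
    h = 1e-5 * np.maximum(np.abs(theta0), 1.0)
    J = np.empty((m, m))
    for a in range(m):
        tp = theta0.copy(); tp[a] += h[a]
        tm = theta0.copy(); tm[a] -= h[a]
        J[:, a] = (total_score(tp) - total_score(tm)) / (2 * h[a])
    info = -0.5 * (J + J.T)
    S = _subject_scores(expo, ev, X, pi, rates, betas)
    V = S.T @ S
    se = np.full((K, p), np.nan)
    try:
        iinv = np.linalg.inv(info)
        cov = iinv @ V @ iinv
        var = np.diag(cov)[-K * p:] if p else np.empty(0)
        var = np.where(var > 0, var, np.nan)
        se = np.sqrt(var).reshape(K, p)
    except np.linalg.LinAlgError:
        warnings.warn("observed information singular; coefficient SEs unavailable",
                      RuntimeWarning, stacklevel=2)
    return se


# --------------------------------------------------------------------------
# public operations

def fit_latent_class_model(cohort: Cohort, covariate_names, k: int = 2,
                           n_bins: int = 4, n_restarts: int = 20, seed: int = 0,
                           tol: float = 1e-8, max_iter: int = 500,
                           compute_se: bool = True,
                           ) -> tuple[LatentClassModel, ClassAssignment]:
    """Fit the K-class mixture by EM with multiple restarts.

    Continuous covariates are z-scored and missing values mean-imputed with a
    companion missingness-indicator column (see :mod:`flimlca.preprocess`);
    coefficients are reported on that design scale.
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    t, d = cohort.time, cohort.event
    if d.sum() == 0:
        raise ValueError("cohort has no events")
    X, info = build_design(cohort.table, list(covariate_names))
    if not np.isfinite(X).all():
        raise ValueError("non-finite covariate values after imputation")
    p = X.shape[1]
    cuts = _event_time_cuts(t, d, n_bins)
    B = cuts.size
    expo, ev = _exposure(t, d, cuts)
    rng = substream(seed, "lca", k, B)

    best = None
    n_restarts = max(1, int(n_restarts)) if k > 1 else 1
    for restart in range(n_restarts):
        r = _init_responsibilities(t, d, X, k, rng, restart)
        pi = r.mean(axis=0)
        rates = np.tile((d.sum() / expo.sum(axis=0).clip(1e-300)).reshape(1, -1),
                        (k, 1))
        betas = np.zeros((k, p))
        prev_ll = -np.inf
        converged = False
        history = []
        for it in range(max_iter):
            # M-step
            pi = np.clip(r.mean(axis=0), 1e-12, None)
            pi = pi / pi.sum()
            for kk in range(k):
                rates[kk], betas[kk] = _m_step_class(expo, ev, X, r[:, kk],
                                                     betas[kk])
            # E-step + observed log-likelihood
            ll_mat = _mixture_loglik_matrix(expo, ev, X, np.log(pi),
                                            np.log(rates), betas)
            norm = logsumexp(ll_mat, axis=1)
            ll = float(norm.sum())
            r = np.exp(ll_mat - norm[:, None])
            history.append(ll)
            if it > 0 and abs(ll - prev_ll) <= tol * (abs(prev_ll) + 1.0):
                converged = True
                prev_ll = ll
                break
            prev_ll = ll
        cand = dict(ll=prev_ll, pi=pi.copy(), rates=rates.copy(),
                    betas=betas.copy(), r=r.copy(), converged=converged,
                    n_iter=it + 1, history=history)
        if best is None or cand["ll"] > best["ll"]:
            best = cand

    if not best["converged"]:
        warnings.warn("no EM restart converged; returning best attempt",
                      RuntimeWarning, stacklevel=2)

    # order classes: class 1 = longest model-implied median survival
    x_mean = X.mean(axis=0) if p else np.empty(0)
    med = _model_implied_medians(cuts, best["rates"], best["betas"], x_mean)
    order = np.argsort(-med, kind="stable")
    pi = best["pi"][order]
    rates = best["rates"][order]
    betas = best["betas"][order]
    r = best["r"][:, order]

    se = (_numeric_se(expo, ev, X, pi, rates, betas) if compute_se
          else np.full((k, p), np.nan))
    n_params = (k - 1) + k * B + k * p
    n = cohort.n
    bic = -2.0 * best["ll"] + n_params * math.log(n)
    model = LatentClassModel(
        k=k, mixing_weights=pi, cut_points=cuts, baseline_rates=rates,
        coefs=betas, coef_se=se, covariate_names=list(covariate_names),
        design_names=info.names, design_info=info,
        log_likelihood=best["ll"], n_parameters=n_params, n_obs=n, bic=bic,
        converged=best["converged"], n_iter=best["n_iter"],
        n_restarts=n_restarts, seed=seed,
        metadata={"loglik_history": best["history"],
                  "model_implied_medians": med[order].tolist()},
    )
    assignment = ClassAssignment(membership=r,
                                 map_label=np.argmax(r, axis=1) + 1)
    return model, assignment


def select_model(cohort: Cohort, covariate_names, k_candidates=(1, 2, 3),
                 bins_candidates=(4,), seed: int = 0, n_restarts: int = 20,
                 **fit_kwargs) -> LatentClassModel:
    """Fit every (K, n_bins) candidate and return the minimum-BIC model.

    The full grid (including failed cells) is retained in
    ``model.metadata['selection_grid']``.
    """
    if not len(k_candidates) or not len(bins_candidates):
        raise ValueError("candidate grids must be non-empty")
    grid = []
    best = None
    for k in k_candidates:
        for nb in bins_candidates:
            cell = {"k": int(k), "n_bins": int(nb)}
            try:
                model, assign = fit_latent_class_model(
                    cohort, covariate_names, k=k, n_bins=nb,
                    n_restarts=n_restarts,
                    seed=child_seed(seed, "cell", k, nb), **fit_kwargs)
                cell.update(bic=model.bic, log_likelihood=model.log_likelihood,
                            converged=model.converged, failed=False)
                if best is None or model.bic < best[0].bic:
                    best = (model, assign)
            except Exception as exc:  # cell marked failed, not fatal
                cell.update(bic=math.nan, failed=True, error=str(exc))
            grid.append(cell)
    if best is None:
        raise RuntimeError("every selection cell failed")
    best[0].metadata["selection_grid"] = grid
    return best[0]


def hazard_ratios(model: LatentClassModel, alpha: float = 0.05) -> pd.DataFrame:
    """Per (class, covariate) hazard ratios with Wald CIs and two-sided p."""
    from scipy.stats import norm
    z = norm.ppf(1 - alpha / 2)
    rows = []
    for k in range(model.k):
        for j, name in enumerate(model.design_names):
            beta = model.coefs[k, j]
            se = model.coef_se[k, j]
            if np.isfinite(se):
                rows.append({
                    "class": k + 1, "covariate": name, "hr": math.exp(beta),
                    "ci_low": math.exp(beta - z * se),
                    "ci_high": math.exp(beta + z * se),
                    "p": 2 * norm.sf(abs(beta) / se) if se > 0 else math.nan,
                    "flags": "",
                })
            else:
                rows.append({"class": k + 1, "covariate": name,
                             "hr": math.exp(beta), "ci_low": math.nan,
                             "ci_high": math.nan, "p": math.nan,
                             "flags": "SE_UNAVAILABLE"})
    return pd.DataFrame(rows)


def class_proportion(assignment: ClassAssignment) -> pd.DataFrame:
    """MAP class counts and fractions."""
    if assignment.map_label.size == 0:
        raise ValueError("empty assignment")
    k = assignment.membership.shape[1]
    n = assignment.map_label.size
    rows = []
    for c in range(1, k + 1):
        count = int((assignment.map_label == c).sum())
        rows.append({"class": c, "count": count, "n": n,
                     "fraction": count / n, "percent": 100.0 * count / n})
    return pd.DataFrame(rows)
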