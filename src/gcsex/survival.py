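"""Survival analysis: quantile dichotomization, Kaplan-Meier, log-rank,
Cox proportional hazards, L1-penalized Cox with cross-validation, and the
AR x miR-125b four-group stratification.

Kaplan-Meier estimation, the log-rank test and the unpenalized Cox model
are delegated to lifelines (Efron handling of tied event times, Wald
confidence intervals). The L1-penalized Cox path is implemented here as
coordinate descent on an IRLS quadratic approximation of the Breslow
partial likelihood (the glmnet algorithm), with tenfold cross-validation
scored by the Verweij-van Houwelingen held-out partial-likelihood
deviance.

Dichotomization convention throughout: "high" means strictly above the
quantile cutoff, ties go to "low".
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import ConvergenceWarning

QUANTILE_RULES = {
    "median": 0.5,
    "upper_quartile": 0.75,
    "upper_tertile": 2.0 / 3.0,
    "lower_tertile": 1.0 / 3.0,
}


def dichotomize(values: np.ndarray, rule: str = "median") -> tuple[np.ndarray, float]:
    """Split values into high/low at a named quantile cutoff.

    Rules: median, upper_quartile, upper_tertile, lower_tertile (the
    cutoffs used for AR, miR-125b, BIK and CASP6 respectively). Returns
    (labels, cutoff) with labels "high"/"low"; high is strictly above the
    cutoff.
    """
    if rule not in QUANTILE_RULES:
        raise ValueError(f"unknown rule {rule!r}; choose from {sorted(QUANTILE_RULES)}")
    v = np.asarray(values, dtype=float)
    n_distinct = len(np.unique(v))
    if n_distinct < 2:
        raise ValueError("all values equal; cannot dichotomize")
    need = 4 if rule == "upper_quartile" else 3
    if n_distinct < need and rule != "median":
        raise ValueError(f"rule {rule!r} needs >= {need} distinct values")
    cutoff = float(np.quantile(v, QUANTILE_RULES[rule]))
    labels = np.where(v > cutoff, "high", "low")
    return labels, cutoff


@dataclass
class KMCurve:
    """Product-limit survival estimate at the distinct event times."""

    event_times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step function, S(0) = 1."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(time: np.ndarray, event: np.ndarray) -> KMCurve:
    """Kaplan-Meier estimate; censored subjects leave the risk set after
    their censoring time."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) < 1:
        raise ValueError("need at least one record")
    if (time <= 0).any():
        raise ValueError("times must be > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    tab = kmf.event_table
    ev = tab[tab["observed"] > 0]
    return KMCurve(
        event_times=ev.index.to_numpy(dtype=float),
        at_risk=ev["at_risk"].to_numpy(dtype=float),
        survival=kmf.survival_function_.loc[ev.index, "KM_estimate"].to_numpy(),
    )


def logrank(time: np.ndarray, event: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p), df=1."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {len(levels)}")
    if event.sum() < 1:
        raise ValueError("no events observed")
    res = multivariate_logrank_test(time, groups, event)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxFit:
    """Cox proportional-hazards estimates with Wald intervals.

    When ``converged`` is False (monotone likelihood / separation) the
    estimates are unreliable and should not be interpreted.
    """

    covariates: list[str]
    beta: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    log_likelihood: float
    converged: bool
    n_iterations: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.beta, "se": self.se, "hr": self.hr,
                "ci_low": self.ci_low, "ci_high": self.ci_high,
            },
            index=pd.Index(self.covariates, name="covariate"),
        )


def cox_fit(df: pd.DataFrame, covariates: list[str],
            time_col: str = "time", event_col: str = "event") -> CoxFit:
    """Fit a Cox model by partial-likelihood maximization (Efron ties).

    ``df`` carries time, event and covariate columns. Non-convergence
    (e.g. perfect separation) is flagged, not silently returned.
    """
    data = df[[time_col, event_col] + list(covariates)].copy()
    if data[event_col].sum() < 1:
        raise ValueError("no events observed")
    for c in covariates:
        if data[c].nunique() < 2:
            raise ValueError(f"degenerate covariate {c!r}")
    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(data, duration_col=time_col, event_col=event_col)
        except ConvergenceError:
            return CoxFit(
                covariates=list(covariates),
                beta=np.full(len(covariates), np.nan),
                se=np.full(len(covariates), np.nan),
                hr=np.full(len(covariates), np.nan),
                ci_low=np.full(len(covariates), np.nan),
                ci_high=np.full(len(covariates), np.nan),
                log_likelihood=np.nan,
                converged=False,
                n_iterations=0,
            )
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
    beta = cph.params_.loc[covariates].to_numpy()
    se = cph.standard_errors_.loc[covariates].to_numpy()
    return CoxFit(
        covariates=list(covariates),
        beta=beta,
        se=se,
        hr=np.exp(beta),
        ci_low=np.exp(beta - 1.96 * se),
        ci_high=np.exp(beta + 1.96 * se),
        log_likelihood=float(cph.log_likelihood_),
        converged=converged,
        n_iterations=getattr(cph, "_n_iter", 0) or 0,
    )


# ---------------------------------------------------------------------------
# L1-penalized Cox (coordinate descent on the Breslow partial likelihood)
# ---------------------------------------------------------------------------

def _breslow_eta_derivs(eta: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Gradient and diagonal Hessian of log PL(eta), Breslow ties.

    Subjects must be pre-sorted by descending time so that risk sets are
    prefix sums. Returns (loglik, grad, hess_diag) with respect to eta.
    """
    eta = eta - eta.max()          # stabilize exp
    r = np.exp(eta)
    cum_r = np.cumsum(r)           # sum over risk set (descending time order)
    # distinct handling of ties: all events at the same time share a risk set
    # (descending sort puts ties adjacent; use the largest prefix for the tie)
    s = cum_r.copy()
    i = 0
    n = len(eta)
    while i < n:
        j = i
        while j + 1 < n and time[j + 1] == time[i]:
            j += 1
        s[i: j + 1] = cum_r[j]
        i = j + 1
    ev = event == 1
    loglik = float(eta[ev].sum() - np.log(s[ev]).sum())
    inv_s = np.zeros(n)
    inv_s[ev] = 1.0 / s[ev]
    inv2 = np.zeros(n)
    inv2[ev] = 1.0 / s[ev] ** 2
    # reverse cumulative sums: subject k appears in risk sets of events with
    # time <= time_k, i.e. positions >= first index of k's tie block
    a = np.cumsum(inv_s[::-1])[::-1]
    b = np.cumsum(inv2[::-1])[::-1]
    # align tie blocks: within a tie, every member shares the block's sums
    i = 0
    while i < n:
        j = i
        while j + 1 < n and time[j + 1] == time[i]:
            j += 1
        a[i: j + 1] = a[i]
        b[i: j + 1] = b[i]
        i = j + 1
    grad = event - r * a
    hess = r * a - (r ** 2) * b
    hess = np.maximum(hess, 1e-12)
    return loglik, grad, hess


def _cox_loglik(beta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    order = np.argsort(-time, kind="mergesort")
    ll, _, _ = _breslow_eta_derivs(X[order] @ beta, time[order], event[order])
    return ll


def _lasso_cox_single(X, time, event, lam, beta0, max_iter=100, tol=1e-10):
    """Solve min -logPL(beta)/n + lam*||beta||_1 by IRLS + coordinate descent."""
    n, p = X.shape
    order = np.argsort(-time, kind="mergesort")
    Xs, ts, es = X[order], time[order], event[order]
    beta = beta0.copy()
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = Xs @ beta
        ll, g, w = _breslow_eta_derivs(eta, ts, es)
        z = eta + g / w            # working response
        resid = z - Xs @ beta
        wX = w[:, None] * Xs
        den = (wX * Xs).sum(axis=0) / n
        for _sweep in range(100):
            max_delta = 0.0
            for j in range(p):
                if den[j] <= 0:
                    continue
                num = (wX[:, j] @ resid) / n + den[j] * beta[j]
                new = np.sign(num) * max(abs(num) - lam, 0.0) / den[j]
                if new != beta[j]:
                    resid -= Xs[:, j] * (new - beta[j])
                    max_delta = max(max_delta, abs(new - beta[j]))
                    beta[j] = new
            if max_delta < 1e-8:
                break
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            break
        ll_old = ll
    return beta


@dataclass
class LassoCoxResult:
    """Coefficient path, CV curve and the selected model."""

    lambda_path: np.ndarray
    coef_path: np.ndarray            # (n_lambda, n_features), original scale
    cv_deviance: np.ndarray | None   # mean held-out deviance per lambda
    cv_se: np.ndarray | None
    best_lambda: float
    best_index: int
    selected: list[str]
    feature_names: list[str]

    def coefficients(self, index: int | None = None) -> pd.Series:
        i = self.best_index if index is None else index
        return pd.Series(self.coef_path[i], index=self.feature_names)


class LassoCox:
    """L1-penalized Cox regression along a lambda path with k-fold CV.

    sklearn-style estimator: ``fit(X, time, event)`` computes the path and
    the cross-validated deviance, storing the result in ``result_``.
    Features are standardized internally; reported coefficients are on the
    original feature scale. ``lambda_path=None`` builds a 50-point
    log-spaced path from the data-derived lambda_max down to
    0.001*lambda_max. CV-optimal lambda minimizes the mean
    Verweij-van Houwelingen deviance ("min" rule; "1se" available).
    """

    def __init__(self, lambda_path: np.ndarray | None = None, n_folds: int = 10,
                 cv_rule: str = "min", seed: int = 0):
        self.lambda_path = lambda_path
        self.n_folds = n_folds
        self.cv_rule = cv_rule
        self.seed = seed

    def fit(self, X: np.ndarray, time: np.ndarray, event: np.ndarray,
            feature_names: list[str] | None = None) -> "LassoCox":
        X = np.asarray(X, dtype=float)
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        n, p = X.shape
        if feature_names is None:
            feature_names = [f"f{j}" for j in range(p)]
        if event.sum() < self.n_folds:
            raise ValueError("fewer events than folds")
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd

        lams = self.lambda_path
        if lams is None:
            order = np.argsort(-time, kind="mergesort")
            _, g, _ = _breslow_eta_derivs(np.zeros(n), time[order], event[order])
            g_full = np.empty(n)
            g_full[order] = g
            lam_max = np.max(np.abs(Z.T @ g_full)) / n
            lams = np.geomspace(lam_max, lam_max * 1e-3, 50)
        lams = np.asarray(lams, dtype=float)
        if np.any(np.diff(lams) > 0):
            raise ValueError("lambda_path must be decreasing")

        def path_fit(Zt, tt, et):
            betas = np.zeros((len(lams), p))
            b = np.zeros(p)
            for i, lam in enumerate(lams):
                b = _lasso_cox_single(Zt, tt, et, lam, b)
                betas[i] = b
            return betas

        path_z = path_fit(Z, time, event)

        cv_dev = cv_se = None
        if self.n_folds >= 2:
            rng = np.random.default_rng(self.seed)
            folds = np.tile(np.arange(self.n_folds), n // self.n_folds + 1)[:n]
            rng.shuffle(folds)
            devs = np.zeros((self.n_folds, len(lams)))
            for k in range(self.n_folds):
                tr = folds != k
                betas_k = path_fit(Z[tr], time[tr], event[tr])
                for i in range(len(lams)):
                    ll_all = _cox_loglik(betas_k[i], Z, time, event)
                    ll_tr = _cox_loglik(betas_k[i], Z[tr], time[tr], event[tr])
                    devs[k, i] = -2.0 * (ll_all - ll_tr)
            cv_dev = devs.mean(axis=0)
            cv_se = devs.std(axis=0, ddof=1) / np.sqrt(self.n_folds)
            best = int(np.argmin(cv_dev))
            if self.cv_rule == "1se":
                thresh = cv_dev[best] + cv_se[best]
                best = int(np.flatnonzero(cv_dev <= thresh)[0])
        else:
            best = len(lams) - 1

        coef_path = path_z / sd[None, :]
        self.result_ = LassoCoxResult(
            lambda_path=lams,
            coef_path=coef_path,
            cv_deviance=cv_dev,
            cv_se=cv_se,
            best_lambda=float(lams[best]),
            best_index=best,
            selected=[feature_names[j] for j in np.flatnonzero(coef_path[best] != 0)],
            feature_names=list(feature_names),
        )
        return self


def lasso_cox(X: np.ndarray, time: np.ndarray, event: np.ndarray,
              feature_names: list[str] | None = None,
              lambda_path: np.ndarray | None = None,
              n_folds: int = 10, seed: int = 0) -> LassoCoxResult:
    """Functional wrapper over :class:`LassoCox`."""
    model = LassoCox(lambda_path=lambda_path, n_folds=n_folds, seed=seed)
    model.fit(X, time, event, feature_names=feature_names)
    return model.result_


def combo_stratify(ar_values: np.ndarray, mir_values: np.ndarray,
                   ar_rule: str = "median", mir_rule: str = "upper_quartile"
                   ) -> tuple[np.ndarray, np.ndarray]:
    """AR x miR-125b four-group stratification and its merged binary.

    Labels: both-low, AR-high/miR-low, AR-low/miR-high, both-high. The
    merged binary contrasts both-high against everything else.
    """
    ar_values = np.asarray(ar_values, dtype=float)
    mir_values = np.asarray(mir_values, dtype=float)
    if ar_values.shape != mir_values.shape:
        raise ValueError("AR and miR vectors must align")
    ar_lab, _ = dichotomize(ar_values, ar_rule)
    mir_lab, _ = dichotomize(mir_values, mir_rule)
    four = np.empty(len(ar_values), dtype=object)
    four[(ar_lab == "low") & (mir_lab == "low")] = "both-low"
    four[(ar_lab == "high") & (mir_lab == "low")] = "AR-high/miR-low"
    four[(ar_lab == "low") & (mir_lab == "high")] = "AR-low/miR-high"
    four[(ar_lab == "high") & (mir_lab == "high")] = "both-high"
    merged = np.where(four == "both-high", "both-high", "rest")
    return four.astype(str), merged
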