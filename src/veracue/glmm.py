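"""Logistic mixed-effects regression with crossed random intercepts.

Fits binomial GLMMs of the form

    logit P(y_i = 1) = x_i' beta + u_{f1(i)} + u_{f2(i)} + ...,
    u_f ~ N(0, sigma_f^2)  independently per grouping factor,

by maximum likelihood, integrating the random effects out with a Laplace
approximation (the lme4 ``glmer`` default).  Grouping factors are fully
crossed (e.g. participants and items).  The fit is deterministic: fixed
starting values (plain-logistic coefficients, unit random-effect SDs) and
a tolerance of 1e-8 on the penalized deviance.

Internals follow the standard PIRLS formulation: for a candidate
(beta, sigma) the conditional mode of the spherical random effects v
(u = Lambda v, Lambda = diag of per-factor SDs) is found by Newton
iteration on the penalized Bernoulli deviance, and the Laplace deviance

    -2 l = -2 g(v̂) + ||v̂||^2 + log det(Lambda' Z' W Z Lambda + I)

is minimized over (beta, sigma) with L-BFGS-B (sigma bounded below by 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize as sopt
import scipy.sparse as sp
from scipy.special import expit
from scipy.stats import norm
from sklearn.base import BaseEstimator

__all__ = [
    "ModelSpec",
    "FitResult",
    "SeparationError",
    "ConvergenceWarning",
    "CrossedLogisticRegression",
    "fit_glmm",
    "OUTCOME_COLUMNS",
]


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: a coefficient diverges."""


class ConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description consumed by the fitting wrappers.

    ``random`` is a tuple of (grouping column, terms) pairs where terms is
    ``("intercept",)`` for a random intercept or includes fixed-effect
    column names for independent random slopes.
    """

    outcome: str
    fixed_effects: tuple = ()
    random: tuple = ()
    family: str = "binomial"

    def label(self) -> str:
        return " + ".join(self.fixed_effects) if self.fixed_effects else "(null)"


@dataclass
class FitResult:
    """A fitted mixed model in the shape model selection consumes."""

    spec: ModelSpec
    terms: tuple
    estimates: np.ndarray
    se: np.ndarray
    stat: np.ndarray
    pvalues: np.ndarray | None
    vc: dict
    loglik: float
    k: int
    n: int
    converged: bool
    meta: dict = field(default_factory=dict)

    def coef_table(self) -> pd.DataFrame:
        tab = pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.estimates,
                "se": self.se,
                "stat": self.stat,
            }
        )
        if self.pvalues is not None:
            tab["p"] = self.pvalues
        if self.spec.family == "binomial":
            tab["odds_ratio"] = np.exp(self.estimates)
        return tab


def _bernoulli_loglik(y, eta):
    # sum_i [y eta - log(1 + e^eta)], numerically stable
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _plain_logistic(X, y, tol=1e-10, max_iter=100, ridge=0.0):
    """Newton-Raphson (IRLS) fit of a plain logistic regression."""
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - ridge * beta
        H = (X * w[:, None]).T @ X + ridge * np.eye(p)
        try:
            step = sla.solve(H, grad, assume_a="pos")
        except sla.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step-halving on the log-likelihood
        ll0 = _bernoulli_loglik(y, eta) - 0.5 * ridge * beta @ beta
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            if _bernoulli_loglik(y, X @ cand) - 0.5 * ridge * cand @ cand >= ll0 - 1e-12:
                break
            t *= 0.5
        beta = beta + t * step
        if np.max(np.abs(grad)) < tol * max(1.0, n):
            converged = True
            break
    eta = X @ beta
    mu = expit(eta)
    w = mu * (1.0 - mu)
    H = (X * w[:, None]).T @ X + ridge * np.eye(p)
    try:
        cov = sla.inv(H)
    except sla.LinAlgError:
        cov = np.linalg.pinv(H)
    return beta, cov, _bernoulli_loglik(y, eta), converged


class CrossedLogisticRegression(BaseEstimator):
    """Logistic regression with crossed Gaussian random intercepts.

    Parameters
    ----------
    fit_intercept : bool
        Prepend an intercept column.
    fix_variances : dict or None
        Map grouping-factor name -> fixed random-effect SD (0 collapses the
        factor; the factor then contributes no estimable parameter).
    tol : float
        Tolerance on the penalized deviance in the inner PIRLS solve.
    max_sd : float
        Upper optimizer bound on random-effect SDs.

    Fitted attributes (sklearn convention, trailing underscore):
    ``coef_``, ``intercept_``, ``params_`` (intercept first), ``bse_``,
    ``zvalues_``, ``pvalues_``, ``vc_`` (per-factor SD), ``loglik_``,
    ``k_`` (estimable parameters), ``n_obs_``, ``converged_``.
    """

    def __init__(self, fit_intercept=True, fix_variances=None, tol=1e-8,
                 max_sd=15.0, max_outer=500, separation_threshold=12.0):
        self.fit_intercept = fit_intercept
        self.fix_variances = fix_variances
        self.tol = tol
        self.max_sd = max_sd
        self.max_outer = max_outer
        self.separation_threshold = separation_threshold

    # -- design assembly ---------------------------------------------------
    def _design(self, X):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            M = X.to_numpy(dtype=float)
        else:
            M = np.asarray(X, dtype=float)
            if M.ndim == 1:
                M = M[:, None]
            names = [f"x{j}" for j in range(M.shape[1])]
        if self.fit_intercept:
            M = np.column_stack([np.ones(len(M)), M])
            names = ["(Intercept)"] + names
        return M, names

    @staticmethod
    def _group_design(groups, n):
        """Return (factor names, Z sparse, element->factor index, sizes)."""
        if groups is None:
            return [], sp.csr_matrix((n, 0)), np.zeros(0, dtype=int), []
        if isinstance(groups, pd.Series):
            groups = groups.to_frame()
        if isinstance(groups, pd.DataFrame):
            factor_names = list(groups.columns)
            cols = [groups[c].to_numpy() for c in groups.columns]
        else:
            arr = np.asarray(groups)
            if arr.ndim == 1:
                arr = arr[:, None]
            factor_names = [f"g{j}" for j in range(arr.shape[1])]
            cols = [arr[:, j] for j in range(arr.shape[1])]
        blocks, elem_factor, sizes = [], [], []
        for j, col in enumerate(cols):
            levels, idx = np.unique(col, return_inverse=True)
            q = len(levels)
            Zj = sp.csr_matrix((np.ones(n), (np.arange(n), idx)), shape=(n, q))
            blocks.append(Zj)
            elem_factor.append(np.full(q, j))
            sizes.append(q)
        Z = sp.hstack(blocks, format="csr") if blocks else sp.csr_matrix((n, 0))
        elem_factor = np.concatenate(elem_factor) if elem_factor else np.zeros(0, int)
        return factor_names, Z, elem_factor, sizes

    # -- inner PIRLS -------------------------------------------------------
    def _pirls(self, y, eta_fixed, Z, lam_elem, v0):
        """Conditional mode of spherical random effects v for fixed beta, sigma.

        Minimizes f(v) = -g(eta) + ||v||^2 / 2 by damped Newton.
        Returns (v̂, penalized -2*loglik part, W at mode, ZL csr).
        """
        q = Z.shape[1]
        if q == 0 or not np.any(lam_elem > 0):
            eta = eta_fixed
            mu = expit(eta)
            w = mu * (1 - mu)
            return np.zeros(q), -2.0 * _bernoulli_loglik(y, eta), w, None
        ZL = Z.multiply(lam_elem[None, :]).tocsr()
        v = v0.copy() if v0 is not None and len(v0) == q else np.zeros(q)

        def f_of(v):
            eta = eta_fixed + ZL @ v
            return -_bernoulli_loglik(y, eta) + 0.5 * v @ v, eta

        fval, eta = f_of(v)
        for _ in range(100):
            mu = expit(eta)
            w = mu * (1 - mu)
            grad = v - ZL.T @ (y - mu)
            H = (ZL.multiply(w[:, None])).T @ ZL
            H = H.toarray()
            H[np.diag_indices_from(H)] += 1.0
            c, low = sla.cho_factor(H, lower=True)
            step = sla.cho_solve((c, low), -grad)
            t = 1.0
            for _ in range(30):
                cand = v + t * step
                fc, eta_c = f_of(cand)
                if fc <= fval + 1e-13:
                    break
                t *= 0.5
            v, fval, eta = cand, fc, eta_c
            if np.max(np.abs(grad)) < self.tol:
                break
        mu = expit(eta)
        w = mu * (1 - mu)
        return v, 2.0 * fval, w, ZL

    def _laplace_neg2ll(self, params, y, X, Z, elem_factor, p, warm):
        beta = params[:p]
        sigma = params[p:]
        lam_elem = sigma[elem_factor] if len(elem_factor) else np.zeros(0)
        eta_fixed = X @ beta
        v, pen_dev, w, ZL = self._pirls(y, eta_fixed, Z, lam_elem, warm.get("v"))
        warm["v"] = v
        if ZL is None:
            logdet = 0.0
        else:
            A = (ZL.multiply(w[:, None])).T @ ZL
            A = A.toarray()
            A[np.diag_indices_from(A)] += 1.0
            c, _ = sla.cho_factor(A, lower=True)
            logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
        return pen_dev + logdet

    # -- public API --------------------------------------------------------
    def fit(self, X, y, groups=None):
        Xm, names = self._design(X)
        y = np.asarray(y, dtype=float).ravel()
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("outcome must be binary 0/1")
        n, p = Xm.shape
        factor_names, Z, elem_factor, sizes = self._group_design(groups, n)

        fixed = dict(self.fix_variances or {})
        free_factors = [f for f in factor_names if f not in fixed]

        beta0, cov0, ll0, conv0 = _plain_logistic(Xm, y)
        self._check_separation(beta0, names)

        if not free_factors and all(fixed.get(f, 0.0) == 0.0 for f in factor_names):
            # Pure logistic model: exact ML by IRLS.
            self._store(names, factor_names, beta0, np.sqrt(np.diag(cov0)),
                        {f: 0.0 for f in factor_names}, ll0, p, n, conv0, fixed)
            self._postfit_meta(Xm, y, Z, elem_factor, np.array([]))
            return self

        # Outer optimization over (beta, free sigmas).
        free_idx = [factor_names.index(f) for f in free_factors]
        sigma_full = np.array([fixed.get(f, 1.0) for f in factor_names], dtype=float)
        warm = {}

        def obj(theta):
            sig = sigma_full.copy()
            sig[free_idx] = theta[p:]
            return 0.5 * self._laplace_neg2ll(
                np.concatenate([theta[:p], sig]), y, Xm, Z, elem_factor, p, warm
            )

        x0 = np.concatenate([beta0, np.ones(len(free_factors))])
        bounds = [(-30.0, 30.0)] * p + [(0.0, self.max_sd)] * len(free_factors)
        opts = {"maxiter": self.max_outer, "ftol": 1e-13, "gtol": 1e-7,
                "finite_diff_rel_step": 1e-5}
        res = sopt.minimize(obj, x0, method="L-BFGS-B", bounds=bounds,
                            jac="3-point", options=opts)
        # sigma = 0 is a stationary point of the Laplace objective (it is
        # locally even in sigma), so the optimizer can park there even when
        # a positive SD fits better; restart once from a perturbed point.
        if len(free_factors) and np.any(res.x[p:] < 0.02):
            x1 = res.x.copy()
            x1[p:][x1[p:] < 0.02] = 0.25
            res2 = sopt.minimize(obj, x1, method="L-BFGS-B", bounds=bounds,
                                 jac="3-point", options=opts)
            if res2.fun < res.fun - 1e-10:
                res = res2
        beta = res.x[:p]
        sigma_full[free_idx] = res.x[p:]
        self._check_separation(beta, names)
        converged = bool(res.success)
        if not converged:
            warnings.warn(
                f"GLMM outer optimization did not converge: {res.message}",
                ConvergenceWarning,
            )
        neg2ll = self._laplace_neg2ll(
            np.concatenate([beta, sigma_full]), y, Xm, Z, elem_factor, p, warm
        )
        se = self._wald_se(beta, sigma_full, y, Xm, Z, elem_factor, warm)
        vc = dict(zip(factor_names, sigma_full))
        k = p + len(free_factors)
        self._store(names, factor_names, beta, se, vc, -0.5 * neg2ll, k, n, converged, fixed)
        self._postfit_meta(Xm, y, Z, elem_factor, sigma_full)
        return self

    def _check_separation(self, beta, names):
        j = int(np.argmax(np.abs(beta)))
        if np.abs(beta[j]) > self.separation_threshold:
            raise SeparationError(
                f"complete or quasi-complete separation on predictor {names[j]!r}"
            )

    def _wald_se(self, beta, sigma_full, y, X, Z, elem_factor, warm):
        lam_elem = sigma_full[elem_factor] if len(elem_factor) else np.zeros(0)
        v, _, w, ZL = self._pirls(y, X @ beta, Z, lam_elem, warm.get("v"))
        XtWX = (X * w[:, None]).T @ X
        if ZL is None:
            M = XtWX
        else:
            A = (ZL.multiply(w[:, None])).T @ ZL
            A = A.toarray()
            A[np.diag_indices_from(A)] += 1.0
            C = (ZL.multiply(w[:, None])).T @ X  # q x p
            C = np.asarray(C.todense()) if sp.issparse(C) else np.asarray(C)
            cf = sla.cho_factor(A, lower=True)
            M = XtWX - C.T @ sla.cho_solve(cf, C)
        try:
            cov = sla.inv(M)
        except sla.LinAlgError:
            cov = np.linalg.pinv(M)
        return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))

    def _store(self, names, factor_names, beta, se, vc, loglik, k, n, converged, fixed):
        self.term_names_ = tuple(names)
        self.factor_names_ = tuple(factor_names)
        self.params_ = beta
        self.bse_ = se
        with np.errstate(divide="ignore", invalid="ignore"):
            self.zvalues_ = np.where(se > 0, beta / se, np.nan)
        self.pvalues_ = 2.0 * norm.sf(np.abs(self.zvalues_))
        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = beta.copy()
        self.vc_ = vc
        self.loglik_ = float(loglik)
        self.k_ = int(k)
        self.n_obs_ = int(n)
        self.converged_ = bool(converged)
        self.fixed_variances_ = dict(fixed)
        self.n_features_in_ = len(names) - int(self.fit_intercept)
        return self

    def _postfit_meta(self, X, y, Z, elem_factor, sigma_full):
        self._X_shape = X.shape

    def predict_proba(self, X):
        """Population-level (random effects at zero) class probabilities."""
        Xm, _ = self._design(X)
        p1 = expit(Xm @ self.params_)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def result(self, spec: ModelSpec | None = None) -> FitResult:
        spec = spec or ModelSpec(outcome="y", fixed_effects=tuple(self.term_names_[1:]))
        return FitResult(
            spec=spec,
            terms=self.term_names_,
            estimates=self.params_.copy(),
            se=self.bse_.copy(),
            stat=self.zvalues_.copy(),
            pvalues=self.pvalues_.copy(),
            vc=dict(self.vc_),
            loglik=self.loglik_,
            k=self.k_,
            n=self.n_obs_,
            converged=self.converged_,
            meta={"family": "binomial", "approximation": "laplace"},
        )


#: Outcome name -> (column, level coded 1).
OUTCOME_COLUMNS = {
    "speaker_veracity": ("veracity", "truth"),
    "guesser_response": ("response", "truth"),
}


def fit_glmm(spec: ModelSpec, data: pd.DataFrame, **kwargs) -> FitResult:
    """Fit a binomial mixed model described by ``spec`` on a trial table.

    Fixed effects are columns of ``data`` (binary cues as 0/1 dummies;
    continuous predictors used as-is).  Random terms must be intercepts;
    grouping factors are columns of ``data``.  Rows with missing values in
    any used column are dropped listwise.
    """
    if spec.family != "binomial":
        raise ValueError("fit_glmm fits binomial models; use fit_lmm for gaussian")
    col, positive = OUTCOME_COLUMNS.get(spec.outcome, (spec.outcome, 1))
    used = [col] + list(spec.fixed_effects) + [f for f, _ in spec.random]
    sub = data.dropna(subset=[c for c in used if c in data.columns])
    y = (sub[col] == positive).astype(float).to_numpy()
    X = sub[list(spec.fixed_effects)] if spec.fixed_effects else pd.DataFrame(index=sub.index)
    groups = sub[[f for f, terms in spec.random]] if spec.random else None
    for f, terms in spec.random:
        if tuple(terms) != ("intercept",):
            raise ValueError("binomial models support random intercepts only")
    est = CrossedLogisticRegression(**kwargs)
    est.fit(X, y, groups=groups)
    return est.result(spec)
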