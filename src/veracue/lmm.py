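"""Linear mixed-effects regression with independent variance components.

Fits Gaussian models of the form

    y = X beta + Z u + e,   u ~ N(0, diag(sigma_1^2 I, sigma_2^2 I, ...)),
    e ~ N(0, sigma^2 I),

where each random term (an intercept or a slope for a named predictor,
per grouping factor) carries its own independent variance.  Maximum
likelihood (not REML) is used throughout so that log-likelihoods are
comparable across fixed-effect structures.

The likelihood is profiled: for variance ratios gamma_j = sigma_j^2 /
sigma^2 the GLS estimate of beta and the residual variance have closed
forms through the q x q capacitance matrix A = I + L Z'Z L (L =
diag(sqrt gamma)), so each objective evaluation costs one Cholesky of A
regardless of the number of rows.  The optimizer is L-BFGS-B over gamma
with a lower bound of zero; a ratio estimated at the boundary is reported
via ``boundary_`` rather than treated as an error.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize as sopt
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from .glmm import FitResult, ModelSpec

__all__ = ["VarianceComponentsLMM", "fit_lmm"]


class VarianceComponentsLMM(BaseEstimator):
    """ML linear mixed model with independent random intercepts/slopes.

    Parameters
    ----------
    random_effects : dict
        Map grouping-factor name -> tuple of random terms.  A term is
        ``"1"`` (intercept) or the name of a fixed-effect column whose
        coefficient varies by group (independent, uncorrelated slopes).
    fit_intercept : bool
        Prepend a fixed intercept column.
    fix_ratios : dict or None
        Map (factor, term) -> fixed variance ratio (0 removes the term's
        estimable parameter; used for oracle comparisons against OLS).

    Fitted attributes: ``params_``, ``bse_``, ``tvalues_``, ``vc_``
    (per-(factor, term) SD), ``sigma_`` (residual SD), ``loglik_``,
    ``k_``, ``n_obs_``, ``converged_``, ``boundary_``.
    """

    def __init__(self, random_effects=None, fit_intercept=True, fix_ratios=None,
                 max_ratio=1e4, max_outer=500):
        self.random_effects = random_effects
        self.fit_intercept = fit_intercept
        self.fix_ratios = fix_ratios
        self.max_ratio = max_ratio
        self.max_outer = max_outer

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

    def _random_design(self, X, names, groups, n):
        re = self.random_effects or {}
        if not re:
            return [], sp.csr_matrix((n, 0)), np.zeros(0, dtype=int)
        if groups is None:
            raise ValueError("random_effects specified but no groups passed to fit")
        if isinstance(groups, pd.Series):
            groups = groups.to_frame()
        blocks, elem_comp, comps = [], [], []
        for factor, terms in re.items():
            col = np.asarray(groups[factor])
            levels, idx = np.unique(col, return_inverse=True)
            q = len(levels)
            for term in terms:
                if term in ("1", "intercept"):
                    vals = np.ones(n)
                else:
                    if term not in names:
                        raise ValueError(f"random slope term {term!r} is not a fixed-effect column")
                    vals = X[:, names.index(term)]
                Zj = sp.csr_matrix((vals, (np.arange(n), idx)), shape=(n, q))
                blocks.append(Zj)
                elem_comp.append(np.full(q, len(comps)))
                comps.append((factor, term))
        Z = sp.hstack(blocks, format="csr")
        return comps, Z, np.concatenate(elem_comp)

    def fit(self, X, y, groups=None):
        Xm, names = self._design(X)
        y = np.asarray(y, dtype=float).ravel()
        n, p = Xm.shape
        comps, Z, elem_comp = self._random_design(Xm, names, groups, n)
        n_comp = len(comps)

        # Sufficient statistics; all later work is in q x q / p x p space.
        ZtZ = (Z.T @ Z).toarray() if n_comp else np.zeros((0, 0))
        ZtX = np.asarray((Z.T @ Xm)) if n_comp else np.zeros((0, p))
        Zty = np.asarray(Z.T @ y).ravel() if n_comp else np.zeros(0)
        XtX = Xm.T @ Xm
        Xty = Xm.T @ y
        yty = float(y @ y)

        fixed = dict(self.fix_ratios or {})
        free = [c for c in comps if c not in fixed]
        gamma_full = np.array([fixed.get(c, 1.0) for c in comps], dtype=float)
        free_idx = [comps.index(c) for c in free]

        def profile(gamma):
            """Return (-2 profiled loglik, beta, sigma2, XtVinvX)."""
            if n_comp:
                lam = np.sqrt(gamma[elem_comp])
                A = ZtZ * np.outer(lam, lam)
                A[np.diag_indices_from(A)] += 1.0
                cf = sla.cho_factor(A, lower=True)
                logdetA = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
                B = lam[:, None] * ZtX
                b = lam * Zty
                AiB = sla.cho_solve(cf, B)
                Aib = sla.cho_solve(cf, b)
                XtVinvX = XtX - B.T @ AiB
                XtVinvy = Xty - B.T @ Aib
                ytVinvy = yty - b @ Aib
            else:
                logdetA = 0.0
                XtVinvX, XtVinvy, ytVinvy = XtX, Xty, yty
            beta = sla.solve(XtVinvX, XtVinvy, assume_a="pos")
            r = max(ytVinvy - beta @ XtVinvy, 1e-300)
            sigma2 = r / n
            neg2ll = n * np.log(2.0 * np.pi * sigma2) + logdetA + n
            return neg2ll, beta, sigma2, XtVinvX

        if free:
            def obj(theta):
                g = gamma_full.copy()
                g[free_idx] = theta
                return profile(g)[0]

            x0 = np.full(len(free), 0.5)
            bounds = [(0.0, self.max_ratio)] * len(free)
            res = sopt.minimize(
                obj, x0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": self.max_outer, "ftol": 1e-13, "gtol": 1e-7},
            )
            gamma_full[free_idx] = res.x
            converged = bool(res.success)
        else:
            converged = True

        neg2ll, beta, sigma2, XtVinvX = profile(gamma_full)
        cov = sigma2 * sla.inv(XtVinvX)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))

        self.term_names_ = tuple(names)
        self.components_ = tuple(comps)
        self.params_ = beta
        self.bse_ = se
        with np.errstate(divide="ignore", invalid="ignore"):
            self.tvalues_ = np.where(se > 0, beta / se, np.nan)
        self.sigma_ = float(np.sqrt(sigma2))
        self.vc_ = {c: float(np.sqrt(gamma_full[j] * sigma2)) for j, c in enumerate(comps)}
        self.gamma_ = {c: float(gamma_full[j]) for j, c in enumerate(comps)}
        self.boundary_ = bool(any(gamma_full[j] < 1e-8 for j in free_idx))
        self.loglik_ = -0.5 * float(neg2ll)
        self.k_ = p + len(free) + 1  # fixed effects + variance ratios + residual
        self.n_obs_ = int(n)
        self.converged_ = converged
        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = beta.copy()
        self.n_features_in_ = len(names) - int(self.fit_intercept)
        return self

    def predict(self, X):
        Xm, _ = self._design(X)
        return Xm @ self.params_

    def result(self, spec: ModelSpec | None = None) -> FitResult:
        spec = spec or ModelSpec(outcome="y", fixed_effects=tuple(self.term_names_[1:]),
                                 family="gaussian")
        return FitResult(
            spec=spec,
            terms=self.term_names_,
            estimates=self.params_.copy(),
            se=self.bse_.copy(),
            stat=self.tvalues_.copy(),
            pvalues=None,  # t statistics reported without df-based p
            vc={**{f"{f}:{t}": v for (f, t), v in self.vc_.items()},
                "residual": self.sigma_},
            loglik=self.loglik_,
            k=self.k_,
            n=self.n_obs_,
            converged=self.converged_,
            meta={"family": "gaussian", "method": "ML", "boundary": self.boundary_},
        )


def fit_lmm(spec: ModelSpec, data: pd.DataFrame, outcome_col: str = "elogit_diff",
            **kwargs) -> FitResult:
    """Fit a Gaussian mixed model on a binned-trajectory table.

    ``spec.fixed_effects`` may contain interaction terms written as
    ``"a:b"`` (the product column is built on the fly).  ``spec.random``
    pairs grouping columns with tuples of random terms.
    """
    if spec.family != "gaussian":
        raise ValueError("fit_lmm fits gaussian models")
    df = data.copy()
    cols = []
    for term in spec.fixed_effects:
        if ":" in term:
            a, b = term.split(":", 1)
            df[term] = df[a] * df[b]
        cols.append(term)
    used = [outcome_col] + [c for t in cols for c in (t.split(":") if ":" in t else [t])]
    used += [f for f, _ in spec.random]
    df = df.dropna(subset=[c for c in dict.fromkeys(used) if c in df.columns])
    for term in spec.fixed_effects:
        if ":" in term:
            a, b = term.split(":", 1)
            df[term] = df[a] * df[b]
    re = {f: tuple(terms) for f, terms in spec.random}
    est = VarianceComponentsLMM(random_effects=re, **kwargs)
    est.fit(df[cols], df[outcome_col].to_numpy(), groups=df[[f for f in re]])
    return est.result(spec)
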