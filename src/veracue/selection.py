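"""AICc-based exhaustive model selection and multimodel inference.

Given a set of candidate predictors, every additive combination (including
the intercept-only null) is fitted and compared on the small-sample
Akaike information criterion

    AICc = -2 log L + 2K + 2K(K+1) / (n - K - 1),

where K counts estimable parameters and n the observations.  Per model
the table carries the AICc difference to the best model (Delta_i), the
Akaike weight w_i = exp(-Delta_i/2) / sum_r exp(-Delta_r/2) and the
evidence ratio ER_i = w_best / w_i = exp(Delta_i/2); per predictor it
carries the cumulative weight (sum of w_i over models containing it), a
variable-importance measure in [0, 1].  Models within a Delta threshold
(default 2) of the best form the competitive set.

Ties in the minimum AICc are broken toward smaller K, then enumeration
order; quantities are kept at full precision internally and rounded only
for display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone

from .glmm import FitResult, ModelSpec

__all__ = [
    "enumerate_candidates",
    "aicc",
    "SelectionTable",
    "selection_table",
    "best_model_report",
    "AICcSelector",
]


def enumerate_candidates(predictors, base_spec: ModelSpec | None = None):
    """All additive combinations of the predictors, null model included.

    Returns 2^|predictors| :class:`ModelSpec`s in deterministic order: by
    model size, then lexicographically by the position of each predictor
    in the supplied ordering.
    """
    predictors = list(predictors)
    if len(predictors) != len(set(predictors)):
        raise ValueError("duplicate predictor names")
    if len(predictors) > 20:
        raise ValueError("refusing to enumerate more than 2^20 candidate models")
    base = base_spec or ModelSpec(outcome="y")
    specs = []
    for k in range(len(predictors) + 1):
        for combo in combinations(range(len(predictors)), k):
            specs.append(replace(base, fixed_effects=tuple(predictors[i] for i in combo)))
    return specs


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 log L + 2K + 2K(K+1)/(n-K-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= K+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + (2.0 * k * (k + 1)) / (n - k - 1)


@dataclass
class SelectionTable:
    """Ranked candidate set with Akaike weights and evidence ratios."""

    entries: pd.DataFrame
    parameter_weights: pd.Series
    competitive_set: list
    threshold: float
    best_index: int

    def competitive_summary(self, focal: str | None = None) -> dict:
        comp = self.entries.loc[self.entries.index.isin(self.competitive_set)]
        out = {"n_competitive": len(comp)}
        counts = {}
        for pred in self.parameter_weights.index:
            counts[pred] = int(sum(pred in t for t in comp["terms"]))
        out["n_competitive_containing"] = counts
        if focal is not None:
            out["n_competitive_containing_focal"] = counts.get(focal, 0)
        return out


def selection_table(fits, threshold: float = 2.0, predictors=None) -> SelectionTable:
    """Build the multimodel-inference table from fitted candidates.

    Non-converged fits are excluded with a warning; fits on differing
    sample sizes are rejected as non-comparable.
    """
    fits = list(fits)
    usable = []
    for f in fits:
        if f.converged:
            usable.append(f)
        else:
            warnings.warn(
                f"excluding non-converged model {f.spec.label()!r} from the candidate set"
            )
    if len(usable) < 2:
        raise ValueError("need at least 2 converged fits")
    ns = {f.n for f in usable}
    if len(ns) != 1:
        raise ValueError(f"fits are not comparable: differing n {sorted(ns)}")

    rows = []
    for order, f in enumerate(usable):
        rows.append(
            {
                "terms": f.spec.fixed_effects,
                "model": f.spec.label(),
                "k": f.k,
                "loglik": f.loglik,
                "aicc": aicc(f.loglik, f.k, f.n),
                "_order": order,
            }
        )
    tab = pd.DataFrame(rows)
    # Best model: min AICc; ties toward smaller K, then enumeration order.
    best_index = int(tab.sort_values(["aicc", "k", "_order"]).index[0])
    best_aicc = float(tab.at[best_index, "aicc"])
    tab["delta"] = tab["aicc"] - best_aicc
    rel = np.exp(-0.5 * tab["delta"].to_numpy())
    tab["weight"] = rel / rel.sum()
    tab["evidence_ratio"] = np.exp(0.5 * tab["delta"].to_numpy())
    tab["rank"] = tab["aicc"].rank(method="first").astype(int)
    tab = tab.drop(columns="_order")

    if predictors is None:
        predictors = sorted({p for f in usable for p in f.spec.fixed_effects})
        # keep first-seen order rather than alphabetical where possible
        seen = []
        for f in usable:
            for p in f.spec.fixed_effects:
                if p not in seen:
                    seen.append(p)
        predictors = seen
    pw = pd.Series(
        {p: float(tab.loc[[p in t for t in tab["terms"]], "weight"].sum()) for p in predictors},
        name="cumulative_weight",
    )
    competitive = [int(i) for i in tab.index[tab["delta"] < threshold]]
    return SelectionTable(
        entries=tab,
        parameter_weights=pw,
        competitive_set=competitive,
        threshold=threshold,
        best_index=best_index,
    )


def best_model_report(table: SelectionTable, fits) -> dict:
    """Narrative summary of the best-supported model.

    Reports the best model's terms and weight, its AICc margin over the
    runner-up, the runner-up's evidence ratio, the competitive-set
    composition, and the best model's coefficient table with odds ratios
    exp(beta) for binomial fits.
    """
    fits = [f for f in fits if f.converged]
    tab = table.entries
    best = fits[table.best_index]
    order = tab.sort_values(["delta", "k"]).index
    runner = tab.loc[order[1]] if len(order) > 1 else None
    report = {
        "best_terms": list(best.spec.fixed_effects),
        "best_model": best.spec.label(),
        "best_weight": float(tab.at[table.best_index, "weight"]),
        "delta_to_runner_up": float(runner["delta"]) if runner is not None else None,
        "runner_up_evidence_ratio": float(runner["evidence_ratio"]) if runner is not None else None,
        "competitive": table.competitive_summary(),
        "coefficients": best.coef_table().to_dict(orient="records"),
    }
    return report


class AICcSelector(BaseEstimator):
    """Exhaustive all-subsets selection around a mixed-model estimator.

    Clones ``estimator`` for every additive combination of the columns of
    ``X`` (fitting the intercept-only null as well), scores each fit by
    AICc and exposes the full multimodel-inference table.

    The wrapped estimator must implement ``fit(X, y, groups=...)`` and
    expose ``loglik_``, ``k_``, ``n_obs_`` and ``converged_``.

    Fitted attributes: ``table_`` (:class:`SelectionTable`),
    ``parameter_weights_``, ``best_terms_``, ``best_estimator_``,
    ``fits_`` (list of :class:`FitResult`), ``report_``.
    """

    def __init__(self, estimator=None, threshold: float = 2.0, outcome: str = "y"):
        self.estimator = estimator
        self.threshold = threshold
        self.outcome = outcome

    def fit(self, X: pd.DataFrame, y, groups=None):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
            X.columns = [f"x{j}" for j in range(X.shape[1])]
        from .glmm import CrossedLogisticRegression  # default base model

        base = self.estimator if self.estimator is not None else CrossedLogisticRegression()
        random = tuple(
            (c, ("intercept",)) for c in (groups.columns if isinstance(groups, pd.DataFrame) else [])
        )
        specs = enumerate_candidates(
            list(X.columns),
            ModelSpec(outcome=self.outcome, random=random, family="binomial"),
        )
        fits, estimators = [], []
        for spec in specs:
            est = clone(base)
            est.fit(X[list(spec.fixed_effects)], y, groups=groups)
            estimators.append(est)
            fits.append(est.result(spec))
        self.fits_ = fits
        self.estimators_ = estimators
        self.table_ = selection_table(fits, threshold=self.threshold, predictors=list(X.columns))
        self.parameter_weights_ = self.table_.parameter_weights
        self.best_index_ = self.table_.best_index
        self.best_terms_ = list(fits[self.best_index_].spec.fixed_effects)
        self.best_estimator_ = estimators[self.best_index_]
        self.report_ = best_model_report(self.table_, fits)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        return self.best_estimator_.predict(X[self.best_terms_] if isinstance(X, pd.DataFrame) else X)
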