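"""Regression and multimodel inference for beta-diversity drivers.

Univariate OLS regressions of the dispersion-based beta diversity on
candidate environmental drivers, all-subsets Gaussian OLS with AICc
(small-sample corrected Akaike information criterion), Akaike model weights
and summed predictor weights ("importance"), plus Spearman and partial
Spearman correlations.

AICc = -2 logL + 2k + 2k(k+1)/(n-k-1), with k counting the intercept, the
slopes and the residual variance (the Burnham & Anderson convention, as in
MuMIn). Akaike weights w_m = exp(-delta_m/2) / sum exp(-delta/2) estimate
each model's probability of being the best in the candidate set; a
predictor's importance is the sum of weights of the models containing it.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .data_model import StructuralError, ValidationError

__all__ = [
    "ModelFit",
    "ModelTable",
    "ols_fit",
    "aicc",
    "model_select",
    "refit_excluding",
    "spearman",
    "partial_spearman",
    "AiccModelSelector",
]


@dataclasses.dataclass(frozen=True)
class ModelFit:
    predictors: tuple[str, ...]
    coefficients: Mapping[str, float]  # includes "intercept"
    k: int  # intercept + slopes + residual variance
    log_likelihood: float
    aicc: float
    r2: float
    adjusted_r2: float
    n: int
    slope_p_values: Mapping[str, float]
    delta: float = math.nan  # filled within a ModelTable
    akaike_weight: float = math.nan


@dataclasses.dataclass(frozen=True)
class ModelTable:
    fits: tuple[ModelFit, ...]  # sorted by AICc ascending
    predictor_importance: Mapping[str, float]
    table: pd.DataFrame
    top_models: tuple[ModelFit, ...]  # delta AICc < 2


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample corrected AIC; requires n - k - 1 > 0."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _design(env: pd.DataFrame, predictors: Sequence[str]) -> np.ndarray:
    missing = [p for p in predictors if p not in env.columns]
    if missing:
        raise StructuralError(f"unknown predictor(s): {missing}")
    return env[list(predictors)].to_numpy(float)


def ols_fit(y, X=None, predictors: Sequence[str] | None = None) -> ModelFit:
    """Gaussian OLS fit with AICc.

    ``X`` may be None (intercept-only), a 1-D vector, a 2-D array or a
    DataFrame. k counts intercept, slopes and the residual variance.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if X is None:
        x = np.empty((n, 0))
        names: list[str] = []
    elif isinstance(X, pd.DataFrame):
        names = [str(c) for c in (predictors or X.columns)]
        x = _design(X, names)
    else:
        x = np.asarray(X, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        names = [str(p) for p in (predictors or [f"x{i+1}" for i in range(x.shape[1])])]
    if np.isnan(y).any() or np.isnan(x).any():
        raise ValidationError("missing values in regression data")
    design = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValidationError("rank-deficient (collinear) design matrix")
    p = x.shape[1]
    k = p + 2  # intercept + slopes + residual variance
    if n <= k - 1:
        raise ValidationError(f"too few observations (n={n}) for {p} predictor(s)")
    res = sm.OLS(y, design).fit()
    coefs = {"intercept": float(res.params[0])}
    coefs.update({name: float(b) for name, b in zip(names, res.params[1:])})
    slope_p = {name: float(pv) for name, pv in zip(names, res.pvalues[1:])}
    r2 = float(res.rsquared) if p > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return ModelFit(
        predictors=tuple(names),
        coefficients=coefs,
        k=k,
        log_likelihood=float(res.llf),
        # AICc is undefined when n <= k + 1; the fit itself is still valid
        aicc=aicc(float(res.llf), k, n) if n - k - 1 > 0 else math.nan,
        r2=r2,
        adjusted_r2=float(adj),
        n=n,
        slope_p_values=slope_p,
    )


def _akaike_weights(aiccs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    delta = aiccs - aiccs.min()
    w = np.exp(-delta / 2.0)
    return delta, w / w.sum()


def model_select(
    y, env: pd.DataFrame, predictors: Sequence[str], skip_infeasible: bool = False
) -> ModelTable:
    """All-subsets OLS with AICc ranking, Akaike weights and importances.

    Fits all 2^p predictor subsets (including the intercept-only model),
    ranks by AICc, and reports per-model weights plus per-predictor summed
    weights. Models within delta AICc < 2 of the best are flagged as the
    top set. With ``skip_infeasible`` subsets too large for the sample
    (n <= k + 1, AICc undefined) are dropped instead of raising — useful
    when the analysis unit is aggregated (e.g. region means).
    """
    predictors = [str(p) for p in predictors]
    if len(predictors) > 10:
        raise ValueError("all-subsets search limited to 10 predictors")
    n_obs = len(np.asarray(y, dtype=float).ravel())
    fits = []
    for r in range(len(predictors) + 1):
        for subset in itertools.combinations(predictors, r):
            if n_obs - (len(subset) + 2) - 1 <= 0:
                if skip_infeasible:
                    continue
                raise ValidationError(
                    f"AICc undefined for subset {subset!r} at n={n_obs}; "
                    "aggregate less or pass skip_infeasible=True"
                )
            fits.append(ols_fit(y, env, predictors=list(subset)) if subset
                        else ols_fit(y, None))
    if not fits:
        raise ValidationError("no feasible model subset for this sample size")
    aiccs = np.array([f.aicc for f in fits])
    delta, weights = _akaike_weights(aiccs)
    fits = [
        dataclasses.replace(f, delta=float(d), akaike_weight=float(w))
        for f, d, w in zip(fits, delta, weights)
    ]
    fits.sort(key=lambda f: f.aicc)
    importance = {
        p: float(sum(f.akaike_weight for f in fits if p in f.predictors))
        for p in predictors
    }
    table = pd.DataFrame(
        {
            "subset": ["+".join(f.predictors) if f.predictors else "(intercept)" for f in fits],
            "k": [f.k for f in fits],
            "logLik": [f.log_likelihood for f in fits],
            "AICc": [f.aicc for f in fits],
            "delta": [f.delta for f in fits],
            "weight": [f.akaike_weight for f in fits],
            "r2": [f.r2 for f in fits],
            "adjusted_r2": [f.adjusted_r2 for f in fits],
        }
    )
    top = tuple(f for f in fits if f.delta < 2.0)
    return ModelTable(
        fits=tuple(fits),
        predictor_importance=importance,
        table=table,
        top_models=top,
    )


def refit_excluding(
    y,
    x,
    groups: Sequence[str],
    exclude: str,
    predictor: str = "x",
) -> ModelFit:
    """Univariate OLS after removing all observations of one group.

    Used for influence checks: e.g. whether one region drives an otherwise
    absent (or opposite-signed) relationship. Excluding a label absent from
    ``groups`` reproduces the full-data fit.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    groups = np.asarray([str(g) for g in groups])
    keep = groups != str(exclude)
    if keep.sum() == 0:
        raise ValidationError(f"excluding {exclude!r} removes every observation")
    return ols_fit(y[keep], x[keep], predictors=[predictor])


def spearman(x, y) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValidationError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant vector has undefined rank correlation")
    return float(stats.spearmanr(x, y).statistic)


def partial_spearman(x, y, z) -> float:
    """First-order partial Spearman correlation of x and y controlling for z.

    Computed from the pairwise rank correlations:
    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)).
    """
    r_xy = spearman(x, y)
    r_xz = spearman(x, z)
    r_yz = spearman(y, z)
    denom = math.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    if denom == 0:
        raise ValidationError("partial correlation undefined (perfect control correlation)")
    return (r_xy - r_xz * r_yz) / denom


class AiccModelSelector(BaseEstimator):
    """All-subsets AICc model selection as an sklearn-style estimator.

    Parameters
    ----------
    predictors : sequence of str, optional
        Columns of the design frame to search over (default: all columns).

    Attributes
    ----------
    table_ : ModelTable
    best_ : ModelFit
    importance_ : dict[str, float]
    """

    def __init__(self, predictors: Sequence[str] | None = None):
        self.predictors = predictors

    def fit(self, X: pd.DataFrame, y):
        predictors = list(self.predictors) if self.predictors is not None else list(X.columns)
        self.table_ = model_select(y, X, predictors)
        self.best_ = self.table_.fits[0]
        self.importance_ = dict(self.table_.predictor_importance)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predict from the best (lowest-AICc) model."""
        best = self.best_
        out = np.full(len(X), best.coefficients["intercept"], dtype=float)
        for name in best.predictors:
            out += best.coefficients[name] * X[name].to_numpy(float)
        return out
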