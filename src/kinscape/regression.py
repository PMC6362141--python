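"""Genetic diversity vs habitat availability: screening and model fits.

Correlated predictors are screened (|r| > cutoff keeps the more relevant
one), spatial autocorrelation is checked with Moran's I, and allelic
richness is regressed on percent suitable habitat with both a linear and a
logarithmic (y = a + b ln x) form; fits are compared on R-squared and
residual diagnostics rather than selected automatically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm


@dataclass
class RegressionFit:
    form: str            # "linear" or "logarithmic"
    intercept: float
    slope: float
    r2: float
    resid_se: float
    n: int

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        t = np.log(x) if self.form == "logarithmic" else x
        return self.intercept + self.slope * t


def correlation_screen(predictors: pd.DataFrame, cutoff: float = 0.7,
                       relevance_order: list[str] | None = None
                       ) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Drop the less relevant member of each highly correlated predictor pair.

    ``relevance_order`` ranks predictors from most to least biologically
    relevant (default: column order).  Constant columns are flagged
    (correlation undefined) and dropped.
    """
    if len(predictors) < 2:
        raise ValueError("need at least 2 rows")
    order = relevance_order if relevance_order is not None else list(predictors.columns)
    rank = {name: i for i, name in enumerate(order)}
    retained = [c for c in predictors.columns]
    dropped: list[tuple[str, str, float]] = []
    for c in list(retained):
        if predictors[c].nunique() <= 1:
            retained.remove(c)
            dropped.append((c, "constant", math.nan))
    for i, c1 in enumerate(list(retained)):
        for c2 in list(retained)[i + 1:]:
            if c1 not in retained or c2 not in retained:
                continue
            r = float(np.corrcoef(predictors[c1], predictors[c2])[0, 1])
            if abs(r) > cutoff:
                loser = c1 if rank.get(c1, 1e9) > rank.get(c2, 1e9) else c2
                winner = c2 if loser == c1 else c1
                retained.remove(loser)
                dropped.append((loser, winner, r))
    return retained, dropped


def morans_i(values, coords, row_standardize: bool = True
             ) -> tuple[float, float, float]:
    """Moran's I with inverse-distance weights and normal-approximation p.

    Returns (I, E[I], two-sided p).  E[I] = -1/(n-1); the variance uses the
    normality assumption.
    """
    y = np.asarray(values, dtype=float)
    pts = np.asarray(coords, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 locations")
    if np.all(y == y[0]):
        raise ValueError("constant values: Moran's I undefined")
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    if row_standardize:
        rs = w.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        w = w / rs
    z = y - y.mean()
    s0 = w.sum()
    i_obs = (n / s0) * float(z @ w @ z) / float(z @ z)
    e_i = -1.0 / (n - 1)
    s1 = 0.5 * float(((w + w.T) ** 2).sum())
    s2 = float(((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum())
    var = ((n ** 2 * s1 - n * s2 + 3 * s0 ** 2)
           / ((n ** 2 - 1) * s0 ** 2)) - e_i ** 2
    zscore = (i_obs - e_i) / math.sqrt(var)
    p = 2.0 * float(norm.sf(abs(zscore)))
    return i_obs, e_i, p


def _ols(t: np.ndarray, y: np.ndarray, form: str) -> RegressionFit:
    n = len(y)
    x_mat = np.column_stack([np.ones(n), t])
    beta, *_ = np.linalg.lstsq(x_mat, y, rcond=None)
    resid = y - x_mat @ beta
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    resid_se = math.sqrt(sse / (n - 2)) if n > 2 else math.nan
    return RegressionFit(form, float(beta[0]), float(beta[1]), r2, resid_se, n)


def fit_diversity_models(x, y) -> list[RegressionFit]:
    """OLS fits of y on x (linear) and y on ln x (logarithmic)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    fits = [_ols(x, y, "linear")]
    if np.any(x <= 0):
        raise ValueError("logarithmic form requires all x > 0")
    fits.append(_ols(np.log(x), y, "logarithmic"))
    return fits
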