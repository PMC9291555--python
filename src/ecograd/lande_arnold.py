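"""Classical linear/quadratic selection regression (Lande-Arnold).

Independent of the spline machinery: relative fitness w = W / mean(W) is
regressed by OLS on variance-standardized traits (linear gradients beta)
and, with squared terms added, on their squares (quadratic gradients
gamma, reported as 2x the fitted quadratic coefficient - the convention
under which a globally quadratic fitness surface gives gamma equal to
the averaged second derivative of relative fitness).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dataset import TRAITS, PopulationDataset

__all__ = ["ClassicalGradients", "lande_arnold", "QuadraticRegressionSurface"]


@dataclass
class ClassicalGradients:
    beta: pd.Series           # linear coefficients of the linear-only model
    beta_se: pd.Series
    gamma: pd.Series          # 2x fitted quadratic coefficient
    gamma_se: pd.Series
    beta_quadratic_model: pd.Series  # linear coefficients of the quad model
    r_squared_linear: float
    r_squared_quadratic: float
    gamma_convention: str = "2x quadratic regression coefficient"


def _standardized_traits(dataset: PopulationDataset) -> pd.DataFrame:
    Z = dataset.df[TRAITS].astype(float)
    return (Z - Z.mean()) / Z.std(ddof=1)


def lande_arnold(dataset: PopulationDataset,
                 condition_limit: float = 1e8) -> ClassicalGradients:
    """OLS selection gradients from observed fitness and traits only."""
    W = dataset.df["fruits"].to_numpy(dtype=float)
    if dataset.n <= 2 * len(TRAITS) + 1:
        raise ValueError("too few observations for the quadratic regression")
    if W.var() == 0:
        raise ValueError("fitness has zero variance")
    w = W / W.mean()
    Z = _standardized_traits(dataset)
    X1 = sm.add_constant(Z.to_numpy())
    if np.linalg.cond(X1) > condition_limit:
        raise ValueError("collinear traits (condition number too large)")
    lin = sm.OLS(w, X1).fit()
    Zsq = Z.to_numpy() ** 2
    X2 = np.column_stack([X1, Zsq])
    quad = sm.OLS(w, X2).fit()
    k = len(TRAITS)
    return ClassicalGradients(
        beta=pd.Series(lin.params[1:k + 1], index=TRAITS),
        beta_se=pd.Series(lin.bse[1:k + 1], index=TRAITS),
        gamma=pd.Series(2.0 * quad.params[k + 1:], index=TRAITS),
        gamma_se=pd.Series(2.0 * quad.bse[k + 1:], index=TRAITS),
        beta_quadratic_model=pd.Series(quad.params[1:k + 1], index=TRAITS),
        r_squared_linear=float(lin.rsquared),
        r_squared_quadratic=float(quad.rsquared))


class QuadraticRegressionSurface:
    """Identity-link globally quadratic relative-fitness surface.

    The OLS quadratic regression of relative fitness on standardized
    traits, exposed through ``predict_response`` so the average-derivative
    machinery can run on it. On this surface the averaged first and
    second derivatives reproduce the classical regression estimates
    exactly (up to finite-difference error).
    """

    def __init__(self, dataset: PopulationDataset):
        W = dataset.df["fruits"].to_numpy(dtype=float)
        self._mean_w = W.mean()
        Z = dataset.df[TRAITS].astype(float)
        self._centers = Z.mean()
        self._scales = Z.std(ddof=1)
        Zs = ((Z - self._centers) / self._scales).to_numpy()
        X = np.column_stack([np.ones(len(W)), Zs, Zs ** 2])
        self.coef = np.linalg.lstsq(X, W / self._mean_w, rcond=None)[0]

    def predict_response(self, df: pd.DataFrame) -> np.ndarray:
        Zs = ((df[TRAITS].astype(float) - self._centers)
              / self._scales).to_numpy()
        k = len(TRAITS)
        return (self.coef[0] + Zs @ self.coef[1:k + 1]
                + (Zs ** 2) @ self.coef[k + 1:])
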