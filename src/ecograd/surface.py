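"""Penalized-spline Poisson fitness surface.

The expected fruit count of a plant is modeled on the log scale as a sum
of smooth functions: one univariate smooth per trait and per environmental
variable, a tensor-product interaction smooth for every trait x environment
pair, a bivariate spatial smooth of longitude and latitude, and the
monitoring year as a parametric covariable. Smooths use cubic B-spline
bases with integrated-squared-second-derivative penalties; coefficients
are estimated by penalized IRLS and smoothing parameters by a
Fellner-Schall (REML-type) fixed-point iteration, with GCV and fixed
smoothing as alternatives.

Main-effect smooths carry sum-to-zero constraints; interaction tensors
are built from marginally centered bases, so main effects and interactions
jointly represent the full tensor-product surface for each trait x
environment pair while the design stays full rank.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .basis import MarginalBasis, marginal_basis, row_kron, sum_to_zero_transform
from .dataset import ENVS, TRAITS, PopulationDataset

log = logging.getLogger(__name__)

__all__ = ["SmoothSpec", "FittedSurface", "build_design", "fit_surface",
           "deviance_explained", "predict_profile", "annual_fitness_test",
           "FitError"]


class FitError(RuntimeError):
    """Raised when penalized IRLS fails; carries the deviance trajectory."""

    def __init__(self, message: str, trajectory=None):
        super().__init__(message)
        self.trajectory = trajectory or []


@dataclass
class SmoothSpec:
    """Which terms the fitness surface contains and their basis dimensions."""

    traits: tuple = tuple(TRAITS)
    envs: tuple = tuple(ENVS)
    k_main: int = 9          # univariate smooth basis dimension
    k_interaction: int = 5   # marginal dimension of trait x env tensors
    k_spatial: int = 5       # marginal dimension of the lon x lat tensor
    include_interactions: bool = True
    include_spatial: bool = True
    include_year: bool = True
    select: str = "reml"     # 'reml' | 'gcv' | 'fixed'
    fixed_lambda: float = 1.0
    penalty_order_note: str = "second derivative"

    def validate(self) -> None:
        for k in (self.k_main, self.k_interaction, self.k_spatial):
            if k < 4:
                raise ValueError("cubic bases need dimension >= 4 "
                                 "(penalty order + 2)")
        for t in self.traits:
            if self.include_interactions and t not in self.traits:
                raise ValueError(f"interaction names unknown trait {t}")


# ----------------------------------------------------------------- terms

class _InterceptTerm:
    name = "intercept"
    covariates: tuple = ()
    penalties: list = []

    def __init__(self):
        self.ncol = 1

    def build(self, df: pd.DataFrame) -> np.ndarray:
        return np.ones((len(df), 1))


class _YearTerm:
    name = "year"
    covariates = ("year",)
    penalties: list = []

    def __init__(self, years):
        self.levels = sorted(years)[1:]  # first level absorbed in intercept
        self.ncol = len(self.levels)

    def build(self, df: pd.DataFrame) -> np.ndarray:
        y = df["year"].to_numpy()
        return np.column_stack([(y == lv).astype(float)
                                for lv in self.levels])


class _SmoothTerm:
    """Univariate sum-to-zero cubic smooth of one covariate."""

    def __init__(self, mb: MarginalBasis):
        self.mb = mb
        self.name = f"s({mb.name})"
        self.covariates = (mb.name,)
        self.ncol = mb.ncol
        self.penalties = [mb.constrained_penalty()]

    def build(self, df: pd.DataFrame) -> np.ndarray:
        return self.mb.evaluate(df[self.mb.name].to_numpy())


class _TensorTerm:
    """Tensor-product smooth of two covariates with per-margin penalties.

    For trait x environment interactions both margins are marginally
    centered (interaction-only tensor); for the spatial smooth the raw
    tensor carries a single overall sum-to-zero constraint.
    """

    def __init__(self, m1: MarginalBasis, m2: MarginalBasis,
                 overall_Z: np.ndarray | None = None, label: str = "ti"):
        self.m1, self.m2 = m1, m2
        self.Z = overall_Z
        self.name = f"{label}({m1.name},{m2.name})"
        self.covariates = (m1.name, m2.name)
        c1, c2 = m1.ncol, m2.ncol
        P1 = np.kron(m1.constrained_penalty(), np.eye(c2))
        P2 = np.kron(np.eye(c1), m2.constrained_penalty())
        if overall_Z is not None:
            P1 = overall_Z.T @ P1 @ overall_Z
            P2 = overall_Z.T @ P2 @ overall_Z
            self.ncol = overall_Z.shape[1]
        else:
            self.ncol = c1 * c2
        self.penalties = [P1, P2]

    def build(self, df: pd.DataFrame) -> np.ndarray:
        B = row_kron(self.m1.evaluate(df[self.m1.name].to_numpy()),
                     self.m2.evaluate(df[self.m2.name].to_numpy()))
        return B if self.Z is None else B @ self.Z


class DesignBuilder:
    """Deterministic map from covariate records to the model design row."""

    def __init__(self, terms: list):
        self.terms = terms
        self.slices = []
        start = 0
        for t in terms:
            self.slices.append(slice(start, start + t.ncol))
            start += t.ncol
        self.p = start

    def build(self, df: pd.DataFrame) -> np.ndarray:
        X = np.empty((len(df), self.p))
        for t, sl in zip(self.terms, self.slices):
            X[:, sl] = t.build(df)
        return X

    def penalty_list(self) -> list:
        """[(slice, S_block)] for every penalized term component."""
        out = []
        for t, sl in zip(self.terms, self.slices):
            for S in t.penalties:
                out.append((sl, S))
        return out


def build_design(spec: SmoothSpec, dataset: PopulationDataset):
    """Build the blocked design and its penalty blocks for a dataset.

    Returns ``(X, builder)``; each smooth block's columns sum to zero over
    the training rows and every penalty block is positive semi-definite.
    """
    spec.validate()
    if dataset.n == 0:
        raise ValueError("cannot build a design for an empty dataset")
    df = dataset.df
    terms: list = [_InterceptTerm()]
    if spec.include_year and len(dataset.years) > 1:
        terms.append(_YearTerm(dataset.years))
    for name in list(spec.traits) + list(spec.envs):
        mb = marginal_basis(name, df[name].to_numpy(), spec.k_main,
                            constrain=True)
        terms.append(_SmoothTerm(mb))
    if spec.include_interactions:
        for tr in spec.traits:
            m1 = marginal_basis(tr, df[tr].to_numpy(), spec.k_interaction,
                                constrain=True)
            for en in spec.envs:
                m2 = marginal_basis(en, df[en].to_numpy(),
                                    spec.k_interaction, constrain=True)
                raw = row_kron(m1.evaluate(df[tr].to_numpy()),
                               m2.evaluate(df[en].to_numpy()))
                Z = sum_to_zero_transform(raw.sum(axis=0))
                terms.append(_TensorTerm(m1, m2, overall_Z=Z, label="ti"))
    if spec.include_spatial:
        m1 = marginal_basis("lon", df["lon"].to_numpy(), spec.k_spatial)
        m2 = marginal_basis("lat", df["lat"].to_numpy(), spec.k_spatial)
        raw = row_kron(m1.raw(df["lon"].to_numpy()),
                       m2.raw(df["lat"].to_numpy()))
        Z = sum_to_zero_transform(raw.sum(axis=0))
        terms.append(_TensorTerm(m1, m2, overall_Z=Z, label="te"))
    builder = DesignBuilder(terms)
    return builder.build(df), builder


# ------------------------------------------------------------------ fit

def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(t - (y - mu)))


def _assemble_penalty(p: int, pen_list: list, lambdas: np.ndarray,
                      ) -> np.ndarray:
    S = np.zeros((p, p))
    for (sl, Sb), lam in zip(pen_list, lambdas):
        S[sl, sl] += lam * Sb
    return S


def _pirls(X: np.ndarray, y: np.ndarray, S: np.ndarray,
           beta0: np.ndarray | None = None, ridge: float = 0.0,
           tol: float = 1e-8, max_iter: int = 200):
    """Penalized IRLS for the Poisson log link.

    Convergence and step-halving track the penalized deviance
    D + b'Sb + ridge*|b|^2. Returns (beta, H, dev, n_iter) with
    H = X'WX + S + ridge*I at convergence.
    """
    def pen(b):
        q = float(b @ S @ b) + ridge * float(b @ b)
        return q

    if beta0 is None:
        mu = np.maximum(y, 0.0) + 0.5
        eta = np.log(mu)
        beta = None
        pdev = _poisson_deviance(y, mu)  # penalty of the init is 0
    else:
        beta = np.asarray(beta0, dtype=float)
        eta = np.clip(X @ beta, -30, 30)
        mu = np.exp(eta)
        pdev = _poisson_deviance(y, mu) + pen(beta)
    trajectory = [pdev]
    H = None
    dev = np.inf
    for it in range(max_iter):
        w = mu
        zeta = eta + (y - mu) / mu
        Xw = X * w[:, None]
        H = X.T @ Xw + S
        if ridge:
            H[np.diag_indices_from(H)] += ridge
        rhs = Xw.T @ zeta
        try:
            beta_prop = np.linalg.solve(H, rhs)
        except np.linalg.LinAlgError:
            beta_prop = np.linalg.lstsq(H, rhs, rcond=None)[0]
        step = 1.0
        while True:
            beta_try = beta_prop if beta is None else \
                beta + step * (beta_prop - beta)
            eta_new = np.clip(X @ beta_try, -30, 30)
            mu_new = np.exp(eta_new)
            pdev_new = _poisson_deviance(y, mu_new) + pen(beta_try)
            if np.isfinite(pdev_new) and (pdev_new <= pdev
                                          or step < 1e-6 or beta is None):
                break
            step /= 2
        beta, eta, mu = beta_try, eta_new, mu_new
        trajectory.append(pdev_new)
        converged = abs(pdev - pdev_new) < tol * (abs(pdev_new) + 0.1)
        pdev = pdev_new
        if converged:
            dev = _poisson_deviance(y, mu)
            break
    else:
        raise FitError(f"penalized IRLS did not converge in {max_iter} "
                       "iterations", trajectory)
    if not np.isfinite(beta).all():
        raise FitError("infinite estimates (separation?)", trajectory)
    return beta, H, dev, it + 1


def _block_pseudoinverse_traces(pen_list, lambdas, Hinv):
    """Per-penalty tr(S_lambda^- S_j) and tr(H^-1 S_j) for Fellner-Schall.

    The total penalty is block diagonal over terms, so its pseudoinverse
    is computed block by block.
    """
    # group penalty components by their column slice (tensor terms share one)
    groups: dict = {}
    for idx, ((sl, Sb), lam) in enumerate(zip(pen_list, lambdas)):
        groups.setdefault((sl.start, sl.stop), []).append((idx, Sb, lam))
    tr_pinv = np.zeros(len(pen_list))
    tr_hinv = np.zeros(len(pen_list))
    for (a, b), comps in groups.items():
        Stot = sum(lam * Sb for _, Sb, lam in comps)
        vals, vecs = np.linalg.eigh(Stot)
        tol = vals.max() * 1e-10 if vals.size else 0.0
        inv_vals = np.where(vals > tol, 1.0 / np.maximum(vals, tol), 0.0)
        Spinv = (vecs * inv_vals) @ vecs.T
        Hb = Hinv[a:b, a:b]
        for idx, Sb, _ in comps:
            tr_pinv[idx] = float(np.sum(Spinv * Sb.T))
            tr_hinv[idx] = float(np.sum(Hb * Sb.T))
    return tr_pinv, tr_hinv


@dataclass
class FittedSurface:
    """A fitted penalized-spline Poisson fitness surface."""

    spec: SmoothSpec
    builder: DesignBuilder
    beta: np.ndarray
    covariance: np.ndarray
    lambdas: np.ndarray
    deviance: float
    null_deviance: float
    edf: float
    converged: bool
    ranges: dict
    X: np.ndarray = dc_field(repr=False, default=None)
    y: np.ndarray = dc_field(repr=False, default=None)
    mu: np.ndarray = dc_field(repr=False, default=None)
    ridge: float = 0.0
    n_obs: int = 0
    col_scale: np.ndarray = dc_field(repr=False, default=None)

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        return self.builder.build(df) @ self.beta

    def predict_response(self, df: pd.DataFrame) -> np.ndarray:
        """Expected fruit count at the covariates in ``df``."""
        return np.exp(self.linear_predictor(df))

    def refit_response(self, y_new: np.ndarray,
                       reselect_smoothing: bool = True,
                       max_outer: int = 12) -> "FittedSurface":
        """Refit the surface to a new response vector (design reused).

        By default smoothing parameters are re-estimated, warm-started
        from the original fit (a handful of Fellner-Schall iterations);
        with ``reselect_smoothing=False`` they are held fixed and only
        the coefficients are refitted.
        """
        Xs = self.X * self.col_scale
        pen_list = self._scaled_penalties()
        if reselect_smoothing and pen_list:
            beta_s, H, dev, lambdas, _ = _fellner_schall_fit(
                Xs, y_new, self.builder.p, pen_list, self._lam0,
                np.array(self.lambdas, dtype=float),
                beta0=self.beta / self.col_scale, ridge=self.ridge,
                max_outer=max_outer)
        else:
            S = _assemble_penalty(self.builder.p, pen_list, self.lambdas)
            beta_s, H, dev, _ = _pirls(Xs, y_new, S,
                                       beta0=self.beta / self.col_scale,
                                       ridge=self.ridge)
            lambdas = self.lambdas
        beta = beta_s * self.col_scale
        new = FittedSurface(
            spec=self.spec, builder=self.builder, beta=beta,
            covariance=self.covariance, lambdas=lambdas,
            deviance=dev, null_deviance=_null_deviance(y_new),
            edf=self.edf, converged=True, ranges=self.ranges,
            X=self.X, y=y_new, mu=np.exp(np.clip(self.X @ beta, -30, 30)),
            ridge=self.ridge, n_obs=self.n_obs,
            col_scale=self.col_scale)
        new._lam0 = self._lam0
        return new

    def _scaled_penalties(self) -> list:
        out = []
        for sl, Sb in self.builder.penalty_list():
            d = self.col_scale[sl]
            out.append((sl, Sb * d[:, None] * d[None, :]))
        return out

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"format": "ecograd-surface", "version": 1,
                         "surface": self}, fh)

    @staticmethod
    def load(path: str | Path) -> "FittedSurface":
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        if blob.get("format") != "ecograd-surface":
            raise ValueError(f"{path} is not an ecograd surface archive")
        return blob["surface"]


def _null_deviance(y: np.ndarray) -> float:
    return _poisson_deviance(y, np.full_like(y, y.mean(), dtype=float))


def _fellner_schall_fit(Xs, y, p, pen_list, lam0, lambdas, beta0, ridge,
                        max_outer):
    """PIRLS nested in Fellner-Schall smoothing updates.

    Returns (beta_s, H, dev, lambdas, settled). ``lam0`` sets the
    balanced scale whose 1e+/-6 window bounds each lambda.
    """
    def fit_at(lams, b0):
        S = _assemble_penalty(p, pen_list, lams)
        return _pirls(Xs, y, S, beta0=b0, ridge=ridge)

    beta_s, H, dev, _ = fit_at(lambdas, beta0)
    settled = False
    for _ in range(max_outer):
        Hinv = np.linalg.inv(H)
        tr_pinv, tr_hinv = _block_pseudoinverse_traces(pen_list, lambdas,
                                                       Hinv)
        factors = np.ones(len(pen_list))
        for j, ((sl, Sb), lam) in enumerate(zip(pen_list, lambdas)):
            den = float(beta_s[sl] @ Sb @ beta_s[sl])
            num = max(tr_pinv[j] - tr_hinv[j], 0.0)
            if den <= 1e-12 * max(num, 1.0):
                factors[j] = 8.0
            else:
                factors[j] = np.clip(num / den, 1 / 8, 8.0)
        new_lam = np.clip(lambdas * factors, 1e-6 * lam0, 1e6 * lam0)
        moved = np.max(np.abs(np.log(new_lam / lambdas)))
        lambdas = new_lam
        beta_s, H, dev, _ = fit_at(lambdas, beta_s)
        if moved < 0.05:
            settled = True
            break
    return beta_s, H, dev, lambdas, settled


def fit_surface(spec: SmoothSpec, dataset: PopulationDataset,
                max_outer: int = 60, ridge_scale: float = 1e-8,
                ) -> FittedSurface:
    """Fit the fitness surface to a population dataset.

    Smoothing parameters are selected by the spec's criterion: 'reml'
    (Fellner-Schall fixed point, default), 'gcv' (one common multiplier),
    or 'fixed'.
    """
    y = dataset.df["fruits"].to_numpy(dtype=float)
    X, builder = build_design(spec, dataset)
    if dataset.n < 2:
        raise ValueError("need at least 2 observations")
    # fit in a column-equilibrated parameterization (unit-RMS columns)
    # for numerical stability; results are mapped back afterwards
    col_scale = 1.0 / np.maximum(np.sqrt(np.mean(X * X, axis=0)), 1e-12)
    Xs = X * col_scale
    pen_list = []
    for sl, Sb in builder.penalty_list():
        d = col_scale[sl]
        pen_list.append((sl, Sb * d[:, None] * d[None, :]))
    n_pen = len(pen_list)
    # scale-balanced initialization: lambda_j * tr(S_j) ~ tr(X'X block)
    lam0 = np.empty(max(n_pen, 1))
    for j, (sl, Sb) in enumerate(pen_list):
        xs = float(np.sum(Xs[:, sl] ** 2))
        ts = float(np.trace(Sb))
        lam0[j] = xs / ts if ts > 0 else 1.0
    lambdas = spec.fixed_lambda * lam0[:n_pen]
    ridge = ridge_scale * dataset.n

    def fit_at(lams, beta0=None):
        S = _assemble_penalty(builder.p, pen_list, lams)
        return _pirls(Xs, y, S, beta0=beta0, ridge=ridge)

    beta_s, H, dev, _ = fit_at(lambdas)
    converged_sp = True
    if spec.select == "reml" and n_pen:
        beta_s, H, dev, lambdas, converged_sp = _fellner_schall_fit(
            Xs, y, builder.p, pen_list, lam0[:n_pen], lambdas,
            beta0=beta_s, ridge=ridge, max_outer=max_outer)
    elif spec.select == "gcv" and n_pen:
        from scipy.optimize import minimize_scalar

        n = dataset.n

        def gcv(log_rho):
            lams = np.exp(log_rho) * lam0[:n_pen]
            b, Hh, d, _ = fit_at(lams, beta0=beta_s)
            XtWX = Hh - _assemble_penalty(builder.p, pen_list, lams)
            XtWX[np.diag_indices_from(XtWX)] -= ridge
            edf = float(np.trace(np.linalg.solve(Hh, XtWX)))
            return n * d / (n - edf) ** 2

        res = minimize_scalar(gcv, bounds=(-8, 8), method="bounded",
                              options={"xatol": 0.05})
        lambdas = np.exp(res.x) * lam0[:n_pen]
        beta_s, H, dev, _ = fit_at(lambdas, beta0=beta_s)
    elif spec.select not in ("reml", "gcv", "fixed"):
        raise ValueError(f"unknown smoothing criterion {spec.select!r}")

    XtWX = H - _assemble_penalty(builder.p, pen_list, lambdas)
    XtWX[np.diag_indices_from(XtWX)] -= ridge
    Hinv = np.linalg.inv(H)
    edf = float(np.trace(Hinv @ XtWX))
    beta = beta_s * col_scale
    covariance = Hinv * col_scale[:, None] * col_scale[None, :]
    eta = np.clip(X @ beta, -30, 30)
    covs = [c for t in builder.terms for c in t.covariates if c != "year"]
    ranges = {c: (float(dataset.df[c].min()), float(dataset.df[c].max()))
              for c in set(covs)}
    surf = FittedSurface(spec=spec, builder=builder, beta=beta,
                         covariance=covariance, lambdas=lambdas,
                         deviance=dev, null_deviance=_null_deviance(y),
                         edf=edf, converged=converged_sp, ranges=ranges,
                         X=X, y=y, mu=np.exp(eta), ridge=ridge,
                         n_obs=dataset.n, col_scale=col_scale)
    surf._lam0 = lam0[:n_pen]
    return surf


def deviance_explained(surface: FittedSurface) -> float:
    """(null deviance - residual deviance) / null deviance."""
    if surface.null_deviance == 0:
        raise ValueError("null deviance is zero")
    return (surface.null_deviance - surface.deviance) / surface.null_deviance


def predict_profile(surface: FittedSurface, focal: str, grid: np.ndarray,
                    held: dict) -> pd.DataFrame:
    """Response-scale prediction curve over a focal covariate grid.

    All non-focal covariates (traits, environments, year, lon, lat) are
    held at the values in ``held``. The 95% CI is the delta-method
    interval on the link scale, exponentiated. Grid points outside the
    training range are flagged, not refused.
    """
    grid = np.asarray(grid, dtype=float)
    needed = {c for t in surface.builder.terms for c in t.covariates}
    missing = needed - {focal} - set(held)
    if missing:
        raise ValueError(f"held must assign non-focal covariates {missing}")
    df = pd.DataFrame({focal: grid})
    for k, v in held.items():
        if k != focal:
            df[k] = v
    X = surface.builder.build(df)
    eta = X @ surface.beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X,
                                      surface.covariance, X), 0.0))
    lo, hi = surface.ranges.get(focal, (-np.inf, np.inf))
    return pd.DataFrame({
        focal: grid,
        "fit": np.exp(eta),
        "lo": np.exp(eta - 1.96 * se),
        "hi": np.exp(eta + 1.96 * se),
        "extrapolated": (grid < lo) | (grid > hi),
    })


def annual_fitness_test(dataset: PopulationDataset) -> dict:
    """Poisson GLM of fruit count on year; likelihood-ratio test.

    Mirrors the preliminary check for annual fluctuation in mean fitness
    that motivates keeping year as a covariable in the surface.
    """
    import statsmodels.api as sm

    years = sorted(dataset.years)
    if len(years) < 2:
        raise ValueError("annual test needs at least two years")
    y = dataset.df["fruits"].to_numpy(dtype=float)
    dummies = np.column_stack([
        (dataset.df["year"].to_numpy() == lv).astype(float)
        for lv in years[1:]])
    X_full = sm.add_constant(dummies)
    full = sm.GLM(y, X_full, family=sm.families.Poisson()).fit()
    null = sm.GLM(y, np.ones((len(y), 1)),
                  family=sm.families.Poisson()).fit()
    lr = 2 * (full.llf - null.llf)
    df_diff = len(years) - 1
    p = float(chi2.sf(lr, df_diff))
    return {"lr_statistic": float(lr), "df": df_diff, "p_value": p,
            "year_means": {int(yv): float(y[dataset.df["year"] == yv].mean())
                           for yv in years}}
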