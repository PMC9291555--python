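"""Standardized selection gradients as averaged derivatives of relative fitness.

A fitted fitness surface predicts absolute fitness W(x) from traits,
environments, year and location. The gradients reported here are sample
averages of partial derivatives of relative fitness w = W / Wbar, where
Wbar is the mean model-predicted fitness over the sample, with every
individual's non-focal covariates held at their observed values:

  linear (beta_i):        sigma_i   * mean_j d w / d z_i
  quadratic (gamma_i):    sigma_i^2 * mean_j d^2 w / d z_i^2
  environmental (k):      sigma_k   * mean_j d w / d e_k
  ecological (i, k):      sigma_i sigma_k * mean_j d^2 w / d z_i d e_k

sigma are sample standard deviations (variance standardization). The
quadratic gradient is the averaged second derivative itself - NO
factor-of-two doubling is applied; the classical regression convention
reports 2x the fitted quadratic coefficient, which coincides with this
definition on a globally quadratic surface.

Derivatives are central finite differences with step 1e-4 x covariate SD
(mixed partials via the 4-point cross stencil). Uncertainty comes from a
parametric bootstrap: new responses are simulated from the fitted Poisson
means, the surface is refitted (smoothing parameters held fixed) and all
gradients recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .dataset import ENVS, TRAITS, PopulationDataset

__all__ = ["GradientSet", "BootstrapResult", "GradientEngine",
           "compute_gradients", "linear_gradient", "quadratic_gradient",
           "environmental_gradient", "ecological_gradient",
           "parametric_bootstrap"]

REL_STEP = 1e-4  # finite-difference step, in units of covariate SD


@dataclass
class GradientSet:
    """Standardized selection gradients with optional SEs and p-values."""

    beta: pd.Series          # per trait
    gamma: pd.Series         # per trait (diagonal quadratic)
    env: pd.Series           # per environment
    eco: pd.DataFrame        # traits x environments
    scaling_record: dict = dc_field(default_factory=dict)
    se: dict | None = None   # same shapes, keys beta/gamma/env/eco
    p: dict | None = None

    def table(self) -> pd.DataFrame:
        """Report-shaped table: gradient rows x trait columns.

        Environmental gradients have no trait dimension and are reported
        separately by the pipeline.
        """
        rows = {"beta": self.beta, "gamma": self.gamma}
        for e in self.eco.columns:
            rows[f"gamma_z.{e}"] = self.eco[e]
        return pd.DataFrame(rows).T


@dataclass
class BootstrapResult:
    """Per-gradient bootstrap replicate distributions."""

    n_boot: int
    seed: int
    method: str
    beta: np.ndarray      # (n_completed, n_traits)
    gamma: np.ndarray
    env: np.ndarray       # (n_completed, n_envs)
    eco: np.ndarray       # (n_completed, n_traits, n_envs)
    n_dropped: int = 0


def _steps(dataset: PopulationDataset, rel_step: float) -> dict:
    h = {}
    for c in TRAITS + ENVS:
        sd = float(dataset.df[c].std(ddof=1))
        scale = float(np.max(np.abs(dataset.df[c]))) or 1.0
        step = rel_step * sd
        if sd == 0 or step <= 64 * np.finfo(float).eps * scale:
            raise ValueError(
                f"finite-difference step underflow for covariate {c!r} "
                f"(sd={sd:g})")
        h[c] = step
    return h


class GradientEngine:
    """Finite-difference average-derivative machinery for one dataset.

    For log-link spline surfaces the perturbed designs differ from the
    base design only in the columns of terms involving the perturbed
    covariate, so those column deltas are precomputed once; evaluating
    all gradients for a new coefficient vector (as in the bootstrap) is
    then a handful of small matrix products. Any other predictor exposing
    ``predict_response(df)`` uses the generic path.
    """

    def __init__(self, surface, dataset: PopulationDataset,
                 rel_step: float = REL_STEP):
        self.surface = surface
        self.dataset = dataset
        self.h = _steps(dataset, rel_step)
        self.sd = {c: float(dataset.df[c].std(ddof=1))
                   for c in TRAITS + ENVS}
        self._fast = hasattr(surface, "builder") and hasattr(surface, "beta")
        df = dataset.df
        self._pair_keys = [(t, e) for t in TRAITS for e in ENVS]
        if self._fast:
            self._prepare_stencils(df)
        else:
            self._W_cache = self._generic_predictions(df)

    # ---------------------------------------------------------- fast path

    def _cols_for(self, covs: set) -> np.ndarray:
        b = self.surface.builder
        idx = []
        for t, sl in zip(b.terms, b.slices):
            if covs & set(t.covariates):
                idx.extend(range(sl.start, sl.stop))
        return np.asarray(idx, dtype=int)

    def _delta_block(self, df: pd.DataFrame, shifts: dict,
                     cols: np.ndarray, X0cols: np.ndarray) -> np.ndarray:
        b = self.surface.builder
        df2 = df.copy()
        for c, d in shifts.items():
            df2[c] = df2[c] + d
        blocks = []
        for t, sl in zip(b.terms, b.slices):
            if set(shifts) & set(t.covariates):
                blocks.append((sl, t.build(df2)))
        D = np.empty((len(df), cols.size))
        pos = 0
        for sl, blk in blocks:
            D[:, pos:pos + blk.shape[1]] = blk
            pos += blk.shape[1]
        return D - X0cols

    def _prepare_stencils(self, df: pd.DataFrame) -> None:
        b = self.surface.builder
        self._X0 = b.build(df)
        self._eta0 = self._X0 @ np.asarray(self.surface.beta)
        self._stencils: dict = {}
        for c in TRAITS + ENVS:
            cols = self._cols_for({c})
            X0c = self._X0[:, cols]
            for s in (+1, -1):
                self._stencils[(c, s)] = (
                    cols, self._delta_block(df, {c: s * self.h[c]},
                                            cols, X0c))
        for (t, e) in self._pair_keys:
            cols = self._cols_for({t, e})
            X0c = self._X0[:, cols]
            for s1 in (+1, -1):
                for s2 in (+1, -1):
                    self._stencils[(t, e, s1, s2)] = (
                        cols, self._delta_block(
                            df, {t: s1 * self.h[t], e: s2 * self.h[e]},
                            cols, X0c))

    def _fast_W(self, key, beta, W0) -> np.ndarray:
        cols, C = self._stencils[key]
        return W0 * np.exp(C @ beta[cols])

    # ------------------------------------------------------- generic path

    def _generic_predictions(self, df: pd.DataFrame) -> dict:
        pred = self.surface.predict_response
        cache = {"base": np.asarray(pred(df), dtype=float)}

        def shifted(shifts):
            df2 = df.copy()
            for c, d in shifts.items():
                df2[c] = df2[c] + d
            return np.asarray(pred(df2), dtype=float)

        for c in TRAITS + ENVS:
            for s in (+1, -1):
                cache[(c, s)] = shifted({c: s * self.h[c]})
        for (t, e) in self._pair_keys:
            for s1 in (+1, -1):
                for s2 in (+1, -1):
                    cache[(t, e, s1, s2)] = shifted(
                        {t: s1 * self.h[t], e: s2 * self.h[e]})
        return cache

    # -------------------------------------------------------- evaluation

    def evaluate(self, beta: np.ndarray | None = None) -> GradientSet:
        """All gradients, either at the surface's coefficients or at a
        replacement coefficient vector (fast path only)."""
        if self._fast:
            b = np.asarray(self.surface.beta if beta is None else beta)
            eta0 = self._X0 @ b if beta is not None else self._eta0
            W0 = np.exp(eta0)
            get = lambda key: self._fast_W(key, b, W0)  # noqa: E731
        else:
            if beta is not None:
                raise ValueError("coefficient override needs a spline "
                                 "surface")
            W0 = self._W_cache["base"]
            get = self._W_cache.__getitem__
        Wbar = W0.mean()

        beta_s, gamma_s, env_s = {}, {}, {}
        eco = np.empty((len(TRAITS), len(ENVS)))
        for c in TRAITS + ENVS:
            Wp, Wm = get((c, +1)), get((c, -1))
            first = np.mean(Wp - Wm) / (2 * self.h[c]) / Wbar
            if c in TRAITS:
                beta_s[c] = self.sd[c] * first
                second = (np.mean(Wp + Wm - 2 * W0)
                          / self.h[c] ** 2 / Wbar)
                gamma_s[c] = self.sd[c] ** 2 * second
            else:
                env_s[c] = self.sd[c] * first
        for i, t in enumerate(TRAITS):
            for j, e in enumerate(ENVS):
                mixed = (np.mean(get((t, e, 1, 1)) - get((t, e, 1, -1))
                                 - get((t, e, -1, 1))
                                 + get((t, e, -1, -1)))
                         / (4 * self.h[t] * self.h[e]) / Wbar)
                eco[i, j] = self.sd[t] * self.sd[e] * mixed
        scaling = {"trait_sd": {t: self.sd[t] for t in TRAITS},
                   "env_sd": {e: self.sd[e] for e in ENVS},
                   "mean_fitness": float(Wbar),
                   "fd_steps": dict(self.h)}
        return GradientSet(
            beta=pd.Series(beta_s)[list(TRAITS)],
            gamma=pd.Series(gamma_s)[list(TRAITS)],
            env=pd.Series(env_s)[list(ENVS)],
            eco=pd.DataFrame(eco, index=list(TRAITS), columns=list(ENVS)),
            scaling_record=scaling)


def compute_gradients(surface, dataset: PopulationDataset,
                      rel_step: float = REL_STEP) -> GradientSet:
    """Point estimates of all standardized gradients (no uncertainty)."""
    return GradientEngine(surface, dataset, rel_step=rel_step).evaluate()


def linear_gradient(surface, dataset: PopulationDataset) -> pd.Series:
    return compute_gradients(surface, dataset).beta


def quadratic_gradient(surface, dataset: PopulationDataset) -> pd.Series:
    return compute_gradients(surface, dataset).gamma


def environmental_gradient(surface, dataset: PopulationDataset) -> pd.Series:
    return compute_gradients(surface, dataset).env


def ecological_gradient(surface, dataset: PopulationDataset) -> pd.DataFrame:
    return compute_gradients(surface, dataset).eco


def _bootstrap_p(reps: np.ndarray, n_used: int) -> float:
    hi = int(np.sum(reps >= 0.0)) + 1
    lo = int(np.sum(reps <= 0.0)) + 1
    return min(1.0, 2.0 * min(hi, lo) / (n_used + 1))


def parametric_bootstrap(surface, dataset: PopulationDataset,
                         n_boot: int = 1000, seed: int = 0,
                         method: str = "resimulate",
                         max_dropped_fraction: float = 0.2,
                         ) -> tuple[BootstrapResult, GradientSet]:
    """Parametric-bootstrap SEs and p-values for every gradient.

    method 'resimulate' (default): each replicate draws new fruit counts
    from the fitted Poisson means at the observed covariates, refits the
    surface (same spec, smoothing parameters fixed) and recomputes the
    gradients. method 'coefficient': replicates draw coefficients from
    the fit's Gaussian posterior instead of refitting (fast
    approximation). SE is the replicate standard deviation; the two-sided
    p-value is 2*min(#{rep >= 0}+1, #{rep <= 0}+1)/(n+1), capped at 1,
    computed over completed replicates. Same seed, same output.
    """
    from .surface import FitError

    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if method not in ("resimulate", "coefficient"):
        raise ValueError(f"unknown bootstrap method {method!r}")
    engine = GradientEngine(surface, dataset)
    point = engine.evaluate()
    rng = np.random.default_rng(seed)
    nt, ne = len(TRAITS), len(ENVS)
    rb = np.empty((n_boot, nt))
    rg = np.empty((n_boot, nt))
    rv = np.empty((n_boot, ne))
    rc = np.empty((n_boot, nt, ne))
    dropped = 0
    if method == "coefficient":
        cov = surface.covariance
        L = np.linalg.cholesky(
            cov + 1e-12 * np.trace(cov) / cov.shape[0] * np.eye(cov.shape[0]))
    kept = 0
    for _ in range(n_boot):
        try:
            if method == "resimulate":
                y_star = rng.poisson(surface.mu).astype(float)
                refit = surface.refit_response(y_star)
                gs = engine.evaluate(beta=refit.beta)
            else:
                beta_star = surface.beta + L @ rng.standard_normal(
                    surface.beta.size)
                gs = engine.evaluate(beta=beta_star)
        except FitError:
            dropped += 1
            continue
        rb[kept] = gs.beta.to_numpy()
        rg[kept] = gs.gamma.to_numpy()
        rv[kept] = gs.env.to_numpy()
        rc[kept] = gs.eco.to_numpy()
        kept += 1
    if dropped > max_dropped_fraction * n_boot:
        raise RuntimeError(
            f"unstable model: {dropped}/{n_boot} bootstrap replicates "
            "failed to converge")
    rb, rg, rv, rc = rb[:kept], rg[:kept], rv[:kept], rc[:kept]
    result = BootstrapResult(n_boot=n_boot, seed=seed, method=method,
                             beta=rb, gamma=rg, env=rv, eco=rc,
                             n_dropped=dropped)
    se = {
        "beta": pd.Series(rb.std(axis=0, ddof=1), index=list(TRAITS)),
        "gamma": pd.Series(rg.std(axis=0, ddof=1), index=list(TRAITS)),
        "env": pd.Series(rv.std(axis=0, ddof=1), index=list(ENVS)),
        "eco": pd.DataFrame(rc.std(axis=0, ddof=1), index=list(TRAITS),
                            columns=list(ENVS)),
    }
    p = {
        "beta": pd.Series([_bootstrap_p(rb[:, i], kept)
                           for i in range(nt)], index=list(TRAITS)),
        "gamma": pd.Series([_bootstrap_p(rg[:, i], kept)
                            for i in range(nt)], index=list(TRAITS)),
        "env": pd.Series([_bootstrap_p(rv[:, j], kept)
                          for j in range(ne)], index=list(ENVS)),
        "eco": pd.DataFrame(
            [[_bootstrap_p(rc[:, i, j], kept) for j in range(ne)]
             for i in range(nt)], index=list(TRAITS), columns=list(ENVS)),
    }
    point.se = se
    point.p = p
    return result, point
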