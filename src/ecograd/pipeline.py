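"""End-to-end analysis runner: load or simulate, test, fit, report.

Stages: dataset load/simulation -> annual-fluctuation GLM -> Moran's I on
fitness -> penalized-spline surface fit -> average-derivative gradients
with parametric-bootstrap inference -> classical-regression comparison ->
prediction profiles. All stage seeds derive deterministically from the
single config seed; the report is written as CSV tables, a JSON summary
and simple plots.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate as sim
from .dataset import ENVS, TRAITS, PopulationDataset, load_dataset
from .gradients import parametric_bootstrap
from .lande_arnold import lande_arnold
from .spatial import SpatialWeights, morans_i
from .surface import (SmoothSpec, annual_fitness_test, deviance_explained,
                      fit_surface, predict_profile)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_analysis", "load_dataset"]

SIGNIFICANCE_FLAG = 1e-3  # mirror the report's bolding threshold


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    input_path: str | None = None
    simulation: sim.SimulationParams | None = None
    spec: SmoothSpec = dc_field(default_factory=SmoothSpec)
    n_boot: int = 1000
    seed: int = 0
    moran_permutations: int = 999
    moran_scheme: str = "inverse_distance"
    out_dir: str = "ecograd_report"
    make_plots: bool = True

    def validate(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("exactly one of input_path / simulation "
                             "must be set")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1 when inference is "
                             "requested")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        if "simulation" in raw and raw["simulation"] is not None:
            s = raw["simulation"]
            if isinstance(s, dict):
                base = sim.default_params(
                    n_plants=int(s.pop("n_plants", 2000)),
                    seed=int(s.pop("seed", 0)))
                for k, v in s.items():
                    setattr(base, k, v)
                cfg.simulation = base
        if "spec" in raw and raw["spec"] is not None:
            cfg.spec = SmoothSpec(**{k: tuple(v) if isinstance(v, list)
                                     else v for k, v in raw["spec"].items()})
        for k in ("input_path", "n_boot", "seed", "moran_permutations",
                  "moran_scheme", "out_dir", "make_plots"):
            if k in raw:
                setattr(cfg, k, raw[k])
        return cfg


def _stage_seeds(seed: int) -> dict:
    ss = np.random.SeedSequence(seed)
    names = ["simulate", "moran", "bootstrap"]
    return {n: int(s.generate_state(1)[0] % (2 ** 31))
            for n, s in zip(names, ss.spawn(len(names)))}


def _dataset_summary(ds: PopulationDataset) -> dict:
    desc = ds.df[TRAITS + ENVS + ["fruits"]].describe().loc[
        ["mean", "std", "min", "max"]]
    return {"n": ds.n, "years": sorted(ds.years),
            "variables": {c: {k: float(v) for k, v in desc[c].items()}
                          for c in desc.columns}}


def _gradient_tables(grads) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Table-1-shaped estimate table plus a flat tidy table."""
    est = grads.table()
    rows = []
    for name, series, ses, ps in [
            ("beta", grads.beta, grads.se["beta"], grads.p["beta"]),
            ("gamma", grads.gamma, grads.se["gamma"], grads.p["gamma"])]:
        for t in TRAITS:
            rows.append({"gradient": name, "trait": t, "environment": "",
                         "estimate": series[t], "se": ses[t], "p": ps[t]})
    for e in ENVS:
        rows.append({"gradient": "environmental", "trait": "",
                     "environment": e, "estimate": grads.env[e],
                     "se": grads.se["env"][e], "p": grads.p["env"][e]})
    for t in TRAITS:
        for e in ENVS:
            rows.append({"gradient": "ecological", "trait": t,
                         "environment": e, "estimate": grads.eco.loc[t, e],
                         "se": grads.se["eco"].loc[t, e],
                         "p": grads.p["eco"].loc[t, e]})
    tidy = pd.DataFrame(rows)
    tidy["significant"] = tidy["p"] < SIGNIFICANCE_FLAG
    return est, tidy


def _formatted_table(tidy: pd.DataFrame) -> str:
    lines = ["standardized selection gradients "
             f"(* = p < {SIGNIFICANCE_FLAG:g})"]
    for _, r in tidy.iterrows():
        label = r["trait"] or r["environment"]
        if r["gradient"] == "ecological":
            label = f"{r['trait']} x {r['environment']}"
        star = " *" if r["significant"] else ""
        lines.append(f"  {r['gradient']:>13s}  {label:<24s} "
                     f"{r['estimate']: .3f} (+/- {r['se']:.3f}) "
                     f"p={r['p']:.4f}{star}")
    return "\n".join(lines)


def _profiles(surface, ds: PopulationDataset, n_grid: int = 40,
              ) -> pd.DataFrame:
    """Fig. 1-3 analogue: fitness profile of each trait at low/mid/high
    values of each environment, all other covariates at sample means."""
    held_base = {c: float(ds.df[c].mean()) for c in
                 TRAITS + ENVS + ["lon", "lat"]}
    held_base["year"] = sorted(ds.years)[-1]
    frames = []
    for t in TRAITS:
        grid = np.linspace(ds.df[t].min(), ds.df[t].max(), n_grid)
        for e in ENVS:
            for q in (0.1, 0.5, 0.9):
                held = dict(held_base)
                held[e] = float(ds.df[e].quantile(q))
                cur = predict_profile(surface, t, grid, held)
                cur.insert(0, "env_value", held[e])
                cur.insert(0, "environment", e)
                cur.insert(0, "trait", t)
                cur = cur.rename(columns={t: "trait_value"})
                frames.append(cur)
    return pd.concat(frames, ignore_index=True)


def _plot_profiles(profiles: pd.DataFrame, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(TRAITS), len(ENVS),
                             figsize=(11, 14), sharex="row")
    for i, t in enumerate(TRAITS):
        for j, e in enumerate(ENVS):
            ax = axes[i, j]
            sub = profiles[(profiles.trait == t)
                           & (profiles.environment == e)]
            for ev, g in sub.groupby("env_value"):
                ax.plot(g.trait_value, g.fit, label=f"{e}={ev:g}")
                ax.fill_between(g.trait_value, g.lo, g.hi, alpha=0.15)
            ax.set_xlabel(t)
            if j == 0:
                ax.set_ylabel("predicted fruits")
            ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(out, dpi=100)
    plt.close(fig)


def run_full_analysis(config: RunConfig) -> dict:
    """Execute every stage and write the report; returns the JSON summary."""
    config.validate()
    seeds = _stage_seeds(config.seed)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulation is not None:
        params = dataclasses.replace(config.simulation,
                                     seed=seeds["simulate"])
        ds = sim.generate_population(params)
        log.info("simulated %d plants (seed %d)", ds.n, seeds["simulate"])
    else:
        ds = load_dataset(config.input_path)
        log.info("loaded %d plants from %s", ds.n, config.input_path)
    ds.to_csv(out / "dataset.csv")

    annual = annual_fitness_test(ds)
    weights = SpatialWeights.from_coords(ds.xy_meters(),
                                         scheme=config.moran_scheme)
    moran = morans_i(ds.df["fruits"].to_numpy(), weights,
                     n_perm=config.moran_permutations, seed=seeds["moran"])

    surface = fit_surface(config.spec, ds)
    dev_expl = deviance_explained(surface)
    log.info("surface fitted: deviance explained %.1f%%, edf %.1f",
             100 * dev_expl, surface.edf)
    surface.save(out / "model.bin")

    boot, grads = parametric_bootstrap(surface, ds, n_boot=config.n_boot,
                                       seed=seeds["bootstrap"])
    est, tidy = _gradient_tables(grads)
    est.to_csv(out / "gradients_table.csv")
    tidy.to_csv(out / "gradients.csv", index=False)
    (out / "gradients.txt").write_text(_formatted_table(tidy) + "\n")

    classical = lande_arnold(ds)
    pd.DataFrame({"beta": classical.beta, "beta_se": classical.beta_se,
                  "gamma": classical.gamma,
                  "gamma_se": classical.gamma_se}).to_csv(
        out / "classical_gradients.csv")

    profiles = _profiles(surface, ds)
    profiles.to_csv(out / "profiles.csv", index=False)
    if config.make_plots:
        try:
            _plot_profiles(profiles, out / "profiles.png")
        except Exception as exc:  # plotting must never sink a run
            log.warning("profile plot failed: %s", exc)

    summary = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "dataset": _dataset_summary(ds),
        "annual_fitness_test": annual,
        "moran": {"I": moran.I, "expected": moran.expected,
                  "p_permutation": moran.p_permutation,
                  "p_normal": moran.p_normal},
        "deviance_explained": dev_expl,
        "edf": surface.edf,
        "n_boot_completed": config.n_boot - boot.n_dropped,
        "gradients": {
            "beta": grads.beta.to_dict(),
            "gamma": grads.gamma.to_dict(),
            "env": grads.env.to_dict(),
            "eco": {t: grads.eco.loc[t].to_dict() for t in TRAITS},
            "se": {k: (v.to_dict() if isinstance(v, pd.Series)
                       else {t: v.loc[t].to_dict() for t in TRAITS})
                   for k, v in grads.se.items()},
            "p": {k: (v.to_dict() if isinstance(v, pd.Series)
                      else {t: v.loc[t].to_dict() for t in TRAITS})
                  for k, v in grads.p.items()},
            "scaling_record": grads.scaling_record,
        },
        "classical": {"beta": classical.beta.to_dict(),
                      "gamma": classical.gamma.to_dict(),
                      "gamma_convention": classical.gamma_convention},
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary
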