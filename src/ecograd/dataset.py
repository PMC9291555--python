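"""Canonical per-plant dataset: schema, validation, CSV round-trip.

One row per individual plant: identity, monitoring year, coordinates
(decimal degrees), five morphological traits, three local environmental
variables, and the fitness proxy (total fruit count).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: the five morphological traits, in canonical column order
TRAITS = ["leaves", "branches", "stems", "internode", "height"]
#: the three environmental variables
ENVS = ["substrate", "vegetation", "density"]
#: full canonical column order of the interchange CSV
COLUMNS = ["id", "year", "lon", "lat", *TRAITS, *ENVS, "fruits"]

_COUNT_COLS = ["leaves", "branches", "stems", "density", "fruits"]

# local equirectangular frame anchored at the study site; exact to within
# floating point over a ~100 m extent
SITE_LON, SITE_LAT = 2.99, 43.11
M_PER_DEG_LAT = 111320.0


def m_per_deg_lon(lat: float = SITE_LAT) -> float:
    return M_PER_DEG_LAT * np.cos(np.deg2rad(lat))


@dataclass
class PopulationDataset:
    """A validated one-record-per-individual plant table.

    ``df`` holds the canonical columns; ``provenance`` records whether the
    data were simulated (with seed/params) or read from a file.
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        self.df = self.df[COLUMNS].reset_index(drop=True)
        validate_records(self.df)

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def years(self) -> set[int]:
        return set(int(y) for y in self.df["year"].unique())

    def xy_meters(self) -> np.ndarray:
        """Planar coordinates (meters) in the local equirectangular frame."""
        x = (self.df["lon"].to_numpy() - SITE_LON) * m_per_deg_lon()
        y = (self.df["lat"].to_numpy() - SITE_LAT) * M_PER_DEG_LAT
        return np.column_stack([x, y])

    def trait_sds(self) -> pd.Series:
        return self.df[TRAITS].std(ddof=1)

    def env_sds(self) -> pd.Series:
        return self.df[ENVS].std(ddof=1)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PopulationDataset):
            return NotImplemented
        return self.df.equals(other.df)


def validate_records(df: pd.DataFrame) -> None:
    """Raise on rows violating the record invariants."""
    if len(df) == 0:
        return
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate individual id {dup!r}")
    for c in _COUNT_COLS:
        v = df[c].to_numpy()
        if np.any(v < 0) or not np.allclose(v, np.round(v)):
            raise ValueError(f"column {c!r} must hold non-negative integers")
    if df[["internode", "height"]].lt(0).any().any():
        raise ValueError("internode and height must be non-negative")
    s = df["substrate"].to_numpy()
    if np.any((s < 1) | (s > 4)):
        raise ValueError("substrate must lie in [1, 4]")
    v = df["vegetation"].to_numpy()
    if np.any((v < 0) | (v > 100)):
        raise ValueError("vegetation must lie in [0, 100]")
    if not np.isfinite(df[["lon", "lat"]].to_numpy()).all():
        raise ValueError("coordinates must be finite")


def load_dataset(path: str | Path, max_bad_fraction: float = 0.01,
                 ) -> PopulationDataset:
    """Read the canonical CSV, keeping one record per individual.

    Individuals appearing in several years keep their first-year record
    only; the number of dropped rows is logged. Rows failing numeric
    parsing are collected and the load aborts if they exceed
    ``max_bad_fraction`` of the file.
    """
    raw = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    raw = raw[COLUMNS]
    if len(raw) == 0:
        log.warning("%s: empty dataset (header only)", path)
        return PopulationDataset(raw, provenance={"path": str(path)})
    numeric = raw.drop(columns=["id"]).apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        frac = bad.mean()
        for i in raw.index[bad][:20]:
            log.warning("%s: row %d unparseable, dropped", path, i)
        if frac > max_bad_fraction:
            raise ValueError(
                f"{path}: {bad.sum()} unparseable rows "
                f"({100 * frac:.1f}% > {100 * max_bad_fraction:.0f}% limit)")
    clean = pd.concat([raw[["id"]], numeric], axis=1)[COLUMNS][~bad]
    clean = clean.sort_values(["id", "year"], kind="stable")
    first = clean.drop_duplicates(subset="id", keep="first")
    n_drop = len(clean) - len(first)
    if n_drop:
        log.info("%s: kept first-year records, dropped %d repeat rows",
                 path, n_drop)
    first = first.sort_index().reset_index(drop=True)
    first["year"] = first["year"].astype(int)
    return PopulationDataset(first, provenance={
        "path": str(path), "dropped_repeat_rows": n_drop,
        "dropped_bad_rows": int(bad.sum())})
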