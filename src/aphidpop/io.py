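"""Readers and writers for the delimited-text data formats.

All tables are UTF-8 CSV with a header row, "." decimal and empty fields for
missing values.  Census files carry the four observed stage classes; the
reader merges fourth/fifth-instar and winged counts into model stage 3 and
drops rows past the exclusion day (default: day 31; the field experiment's
day-36 censuses are excluded because plants senesced).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .demography import ARMS, TREATMENTS, CensusSeries
from .inference import LifeTable, PosteriorChains, life_table_from_frame

logger = logging.getLogger(__name__)

CENSUS_COLUMNS = ["population_id", "treatment", "arm", "removal_day", "day",
                  "n12", "n3", "n45", "nwinged", "leaves"]
LIFETABLE_COLUMNS = ["clone", "individual_id", "lifespan_days",
                     "maturation_day", "day", "offspring_count"]
FREQUENCY_COLUMNS = ["population_id", "day", "freq_clone1"]

DEFAULT_EXCLUSION_DAY = 31


def _apply_column_map(df: pd.DataFrame,
                      column_map: Mapping[str, str] | None) -> pd.DataFrame:
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    return df


def census_from_frame(df: pd.DataFrame,
                      exclusion_day: int = DEFAULT_EXCLUSION_DAY,
                      ) -> list[CensusSeries]:
    """Validate a census table and assemble per-population series.

    Stage classes n45 and nwinged are merged into stage 3.  Rows beyond the
    exclusion day are dropped with a logged count.  Negative counts, unknown
    treatments or arms, and duplicate (population, day) pairs raise with the
    offending row number (1-based, excluding the header).
    """
    missing = [c for c in CENSUS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"census table missing columns: {missing}")
    df = df.reset_index(drop=True)
    for row, rec in enumerate(df.itertuples(index=False), start=1):
        if rec.treatment not in TREATMENTS:
            raise ValueError(f"row {row}: unknown treatment {rec.treatment!r}")
        if rec.arm not in ARMS:
            raise ValueError(f"row {row}: unknown arm {rec.arm!r}")
        for col in ("n12", "n3", "n45", "nwinged"):
            if getattr(rec, col) < 0:
                raise ValueError(f"row {row}: negative count in {col}")
        if rec.leaves <= 0:
            raise ValueError(f"row {row}: leaves must be > 0")
    dup = df.duplicated(subset=["population_id", "day"])
    if dup.any():
        raise ValueError(
            f"row {int(dup.idxmax()) + 1}: duplicate (population, day)")
    n_drop = int((df["day"] > exclusion_day).sum())
    if n_drop:
        logger.warning("dropping %d census row(s) beyond day %d",
                       n_drop, exclusion_day)
        df = df[df["day"] <= exclusion_day]
    out = []
    for pop_id, grp in df.groupby("population_id", sort=True):
        grp = grp.sort_values("day")
        removal = grp["removal_day"].iloc[0]
        removal = None if pd.isna(removal) else int(removal)
        arm = grp["arm"].iloc[0]
        if arm == "uncaged" and removal is None:
            raise ValueError(
                f"population {pop_id!r}: uncaged arm requires removal_day")
        counts = np.column_stack([
            grp["n12"].to_numpy(),
            grp["n3"].to_numpy(),
            grp["n45"].to_numpy() + grp["nwinged"].to_numpy(),
        ])
        out.append(CensusSeries(
            population_id=str(pop_id),
            treatment=grp["treatment"].iloc[0],
            arm=arm,
            removal_day=removal,
            days=grp["day"].to_numpy(),
            counts=counts,
            leaves=grp["leaves"].to_numpy(dtype=float),
        ))
    return out


def read_census(path: str | Path,
                exclusion_day: int = DEFAULT_EXCLUSION_DAY,
                column_map: Mapping[str, str] | None = None,
                ) -> list[CensusSeries]:
    df = _apply_column_map(pd.read_csv(path), column_map)
    return census_from_frame(df, exclusion_day=exclusion_day)


def write_census(populations_or_frame, path: str | Path) -> None:
    """Write a census table; accepts either a raw frame in the CSV dialect or
    a list of :class:`CensusSeries` (stage 3 is then written as n45 with
    nwinged 0, which round-trips losslessly at the 3-stage level)."""
    if isinstance(populations_or_frame, pd.DataFrame):
        populations_or_frame.to_csv(path, index=False)
        return
    rows = []
    for pop in populations_or_frame:
        for i, day in enumerate(pop.days):
            rows.append({
                "population_id": pop.population_id,
                "treatment": pop.treatment,
                "arm": pop.arm,
                "removal_day": pop.removal_day,
                "day": int(day),
                "n12": int(pop.counts[i, 0]),
                "n3": int(pop.counts[i, 1]),
                "n45": int(pop.counts[i, 2]),
                "nwinged": 0,
                "leaves": pop.leaves[i],
            })
    pd.DataFrame(rows, columns=CENSUS_COLUMNS).to_csv(path, index=False)


def read_life_table(path: str | Path,
                    column_map: Mapping[str, str] | None = None) -> LifeTable:
    df = _apply_column_map(pd.read_csv(path), column_map)
    missing = [c for c in LIFETABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"life table missing columns: {missing}")
    if df.empty or df["offspring_count"].dropna().empty:
        logger.warning("life table %s has no offspring observations", path)
    if (df["lifespan_days"] < 0).any():
        raise ValueError("negative lifespan in life table")
    return life_table_from_frame(df)


def write_life_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_frequencies(path: str | Path,
                     column_map: Mapping[str, str] | None = None,
                     ) -> pd.DataFrame:
    df = _apply_column_map(pd.read_csv(path), column_map)
    missing = [c for c in FREQUENCY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"frequency table missing columns: {missing}")
    vals = df["freq_clone1"]
    bad = vals.notna() & ((vals < 0) | (vals > 1))
    if bad.any():
        raise ValueError(
            f"row {int(bad.idxmax()) + 1}: frequency outside [0, 1]")
    return df


def write_frequencies(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_posterior(chains: PosteriorChains, path: str | Path) -> None:
    """Long-format posterior sample CSV: chain, draw, parameter, value."""
    chains.to_frame().to_csv(path, index=False)


def read_posterior(path: str | Path) -> PosteriorChains:
    df = pd.read_csv(path)
    names = list(df["parameter"].unique())
    n_chains = int(df["chain"].max()) + 1
    n_draws = int(df["draw"].max()) + 1
    samples = np.empty((n_chains, n_draws, len(names)))
    pivot = df.pivot_table(index=["chain", "draw"], columns="parameter",
                           values="value", sort=False)
    pivot = pivot[names]
    samples = pivot.to_numpy().reshape(n_chains, n_draws, len(names))
    from .inference import gelman_rubin
    return PosteriorChains(samples=samples, param_names=names, seed=-1,
                           burnin=0, rhat=gelman_rubin(samples),
                           density_scale=None)


def write_results(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministically ordered tidy result table."""
    df = df.sort_values(list(df.columns[:min(4, df.shape[1])]),
                        kind="mergesort").reset_index(drop=True)
    df.to_csv(path, index=False)
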