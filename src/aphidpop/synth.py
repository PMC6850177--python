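"""Synthetic field- and glasshouse-experiment generator.

Emulates the study design: 6 clonal treatments (3 pure clones, 3 two-clone
mixtures) fully crossed with a caging treatment, 8 replicate populations
each, started from 20 third-instar individuals and censused every 3-4 days
through day 31.  Cages of the uncaged arm are removed at day 13, after which
plants decline relative to caged plants.  Individual-based daily dynamics
follow the same vital-rate regressions used by the inference module:
binomial survival, binomial stage advance of survivors, Poisson births from
the stage-3 count at the start of the day, with density recomputed daily as
total count over leaves.  Clip-cage life tables are drawn at a density of
one individual per leaf.

All randomness flows from a single seed expanded into deterministic
per-population substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .demography import (
    ARMS,
    MIXED_TREATMENTS,
    PURE_TREATMENTS,
    TREATMENTS,
    CoefficientSet,
    Covariates,
    PlantSizeSeries,
    cage_schedule,
    vital_rates_at,
)

__all__ = [
    "PlantParams",
    "ScenarioConfig",
    "SyntheticDataset",
    "default_truth",
    "gen_plant_series",
    "simulate_population",
    "simulate_mixed_population",
    "gen_life_table",
    "gen_experiment",
]


def default_truth() -> CoefficientSet:
    """True coefficients used by the default scenario.

    Chosen so that caged vital rates at average density span the realistic
    ranges for this system (survival 0.87-0.97, stage advance 0.39-0.65,
    reproduction 0.89-1.70 per day), survival increases with density while
    growth and reproduction decline, and cage removal pushes survival toward
    one while depressing growth and reproduction.  Density enters z-scored
    with mean 800 and sd 700 individuals per leaf.
    """
    betas = np.array([
        # b0    b1     A     B     C     AB    AC    BC    cage x A..BC
        [2.20, 0.25, 0.00, 0.80, 0.10, 0.30, 0.05, 0.40,
         0.90, 1.10, 1.00, 0.80, 1.20, 1.00],          # survival (logit)
        [0.00, -0.35, 0.10, -0.40, 0.00, -0.10, 0.05, -0.20,
         -0.80, -0.60, -0.70, -0.90, -0.75, -0.65],    # growth (logit)
        [0.25, -0.35, 0.25, -0.35, 0.00, 0.15, 0.05, -0.05,
         -0.90, -0.70, -0.80, -1.00, -0.85, -0.75],    # reproduction (log)
    ])
    return CoefficientSet(betas=betas, density_scale=(800.0, 700.0))


@dataclass
class PlantParams:
    """Logistic leaf-growth parameters with lognormal per-plant variation."""

    initial_leaves: float = 6.0
    growth_rate: float = 0.15        # per day
    capacity: float = 40.0           # leaves
    decline_factor: float = 0.35     # capacity multiplier after cage removal
    initial_cv: float = 0.20         # lognormal sd on log initial leaves
    rate_cv: float = 0.20            # lognormal sd on log growth rate
    capacity_cv: float = 0.20        # lognormal sd on log capacity


@dataclass
class ScenarioConfig:
    """Study-design parameters of the synthetic experiment."""

    coeffs: CoefficientSet = field(default_factory=default_truth)
    census_days: tuple[int, ...] = (0, 3, 7, 10, 14, 17, 21, 24, 28, 31)
    replicates: int = 8
    n_start: int = 20                # third-instar (stage 2) individuals
    mixed_start_each: int = 10       # per clone in mixed populations
    removal_day: int = 13
    plant: PlantParams = field(default_factory=PlantParams)
    winged_fraction: float = 0.10    # of stage-3 individuals counted as winged
    life_table_n: tuple[int, int, int] = (15, 15, 16)
    treatments: tuple[str, ...] = TREATMENTS  # subset for reduced designs
    seed: int = 0

    def __post_init__(self) -> None:
        days = np.asarray(self.census_days)
        gaps = np.diff(days)
        if np.any((gaps < 3) | (gaps > 4)):
            raise ValueError("census schedule gaps must be 3 or 4 days")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def end_day(self) -> int:
        return int(max(self.census_days))


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic substream keyed on integers."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# --------------------------------------------------------------------------
# plants
# --------------------------------------------------------------------------

def gen_plant_series(cfg: ScenarioConfig, arm: str, seed: int,
                     ) -> PlantSizeSeries:
    """Daily leaf counts: discrete logistic growth; for the uncaged arm the
    carrying capacity is multiplied by the decline factor from the removal day
    onward.  Clamped below at one leaf."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    p = cfg.plant
    rng = _rng(seed, 71)
    l0 = p.initial_leaves * float(np.exp(rng.normal(0.0, p.initial_cv)))
    r = p.growth_rate * float(np.exp(rng.normal(0.0, p.rate_cv)))
    k = p.capacity * float(np.exp(rng.normal(0.0, p.capacity_cv)))
    l0 = min(l0, k)
    values = np.empty(cfg.end_day + 1)
    leaves = max(l0, 1.0)
    for day in range(cfg.end_day + 1):
        values[day] = leaves
        k_day = k * p.decline_factor if (
            arm == "uncaged" and day >= cfg.removal_day) else k
        leaves = leaves + r * leaves * (1.0 - leaves / k_day)
        leaves = max(leaves, 1.0)
    return PlantSizeSeries(start_day=0, values=values)


# --------------------------------------------------------------------------
# population simulation
# --------------------------------------------------------------------------

def _daily_rates(coeffs: CoefficientSet, treatment: str, density: float,
                 caged_dummy: int):
    v = vital_rates_at(coeffs, Covariates(density=density, treatment=treatment,
                                          caged_dummy=caged_dummy))
    return v.sigma, v.gamma, v.phi


def _step_clone(rng: np.random.Generator, n: np.ndarray, sigma: float,
                gamma: float, phi: float) -> np.ndarray:
    """One stochastic daily update of a 3-stage integer vector."""
    births = rng.poisson(phi * n[2])
    surv = rng.binomial(n.astype(int), sigma)
    adv1 = rng.binomial(surv[0], gamma)
    adv2 = rng.binomial(surv[1], gamma)
    return np.array([surv[0] - adv1 + births,
                     surv[1] - adv2 + adv1,
                     surv[2] + adv2])


def _census_rows(pop_id: str, treatment: str, arm: str, removal_day,
                 cfg: ScenarioConfig, daily: np.ndarray,
                 plant: PlantSizeSeries, rng: np.random.Generator,
                 ) -> list[dict]:
    rows = []
    for day in cfg.census_days:
        n1, n2, n3 = (int(x) for x in daily[day])
        winged = int(rng.binomial(n3, cfg.winged_fraction))
        rows.append({
            "population_id": pop_id, "treatment": treatment, "arm": arm,
            "removal_day": removal_day if arm == "uncaged" else None,
            "day": int(day), "n12": n1, "n3": n2,
            "n45": n3 - winged, "nwinged": winged,
            "leaves": max(1, round(plant.leaves(day))),
        })
    return rows


def simulate_population(coeffs: CoefficientSet, treatment: str, arm: str,
                        cfg: ScenarioConfig, seed: int,
                        pop_id: str | None = None,
                        plant: PlantSizeSeries | None = None,
                        ) -> tuple[np.ndarray, pd.DataFrame, PlantSizeSeries]:
    """Simulate one single-clone population day by day.

    Returns (daily stage counts with shape (end_day+1, 3), census table,
    daily plant series).  Extinction is allowed; zero rows persist.
    """
    if pop_id is None:
        pop_id = f"{treatment}-{arm}-{seed}"
    if plant is None:
        plant = gen_plant_series(cfg, arm, seed)
    rng = _rng(seed, 11)
    cage = cage_schedule(arm, cfg.removal_day)
    n = np.array([0, cfg.n_start, 0])
    daily = np.zeros((cfg.end_day + 1, 3), dtype=int)
    daily[0] = n
    for day in range(cfg.end_day):
        density = n.sum() / plant.leaves(day)
        s, g, p = _daily_rates(coeffs, treatment, density, cage(day))
        n = _step_clone(rng, n, s, g, p)
        daily[day + 1] = n
    census = pd.DataFrame(_census_rows(
        pop_id, treatment, arm, cfg.removal_day, cfg, daily, plant,
        _rng(seed, 12)))
    return daily, census, plant


def simulate_mixed_population(coeffs_a: CoefficientSet, treat_a: str,
                              coeffs_b: CoefficientSet, treat_b: str,
                              mixed_treatment: str, arm: str,
                              cfg: ScenarioConfig, seed: int,
                              pop_id: str | None = None,
                              plant: PlantSizeSeries | None = None,
                              ) -> tuple[np.ndarray, pd.DataFrame,
                                         pd.DataFrame, np.ndarray,
                                         PlantSizeSeries]:
    """Simulate two clone lineages sharing one plant.

    Each lineage starts with ``mixed_start_each`` stage-2 individuals and
    responds to the *total* density through its own coefficient set and
    treatment label.  Census counts are summed across lineages; the frequency
    of the first lineage is recorded daily (truth) and on census days
    (observed).  Returns (daily summed counts, census table, census-day
    frequency table, daily true frequencies, plant series).
    """
    if mixed_treatment not in MIXED_TREATMENTS:
        raise ValueError(f"{mixed_treatment!r} is not a mixed treatment")
    if pop_id is None:
        pop_id = f"{mixed_treatment}-{arm}-{seed}"
    if plant is None:
        plant = gen_plant_series(cfg, arm, seed)
    rng = _rng(seed, 21)
    cage = cage_schedule(arm, cfg.removal_day)
    na = np.array([0, cfg.mixed_start_each, 0])
    nb = np.array([0, cfg.mixed_start_each, 0])
    daily = np.zeros((cfg.end_day + 1, 3), dtype=int)
    freq = np.full(cfg.end_day + 1, np.nan)
    daily[0] = na + nb
    freq[0] = na.sum() / (na.sum() + nb.sum())
    for day in range(cfg.end_day):
        total = na.sum() + nb.sum()
        density = total / plant.leaves(day)
        c = cage(day)
        sa, ga, pa = _daily_rates(coeffs_a, treat_a, density, c)
        sb, gb, pb = _daily_rates(coeffs_b, treat_b, density, c)
        na = _step_clone(rng, na, sa, ga, pa)
        nb = _step_clone(rng, nb, sb, gb, pb)
        daily[day + 1] = na + nb
        tot = na.sum() + nb.sum()
        freq[day + 1] = na.sum() / tot if tot > 0 else np.nan
    census = pd.DataFrame(_census_rows(
        pop_id, mixed_treatment, arm, cfg.removal_day, cfg, daily, plant,
        _rng(seed, 22)))
    freq_rows = pd.DataFrame({
        "population_id": pop_id,
        "day": list(cfg.census_days),
        "freq_clone1": [freq[d] for d in cfg.census_days],
    })
    return daily, census, freq_rows, freq, plant


# --------------------------------------------------------------------------
# life tables
# --------------------------------------------------------------------------

def gen_life_table(coeffs: CoefficientSet, clone: str, n_individuals: int,
                   seed: int, observation_horizon: int = 200) -> pd.DataFrame:
    """Clip-cage life-table records for one pure clone.

    Vital rates are evaluated at density 1 individual per leaf under caged
    conditions.  Lifespan is geometric with daily death probability
    1 - sigma, censored at the observation horizon (clip-cage experiments
    end; aphid lifespans are weeks, so the default horizon is far in the
    tail); maturation is 1 day plus two geometric(gamma) stage waits,
    recorded only when it does not exceed the lifespan; matured individuals
    produce Poisson(phi) offspring on each day from maturation to death.

    Returns one row per reproductive day plus one anchor row per individual
    (with empty day/offspring_count) so non-reproducing individuals still
    contribute their lifespan.
    """
    if clone not in PURE_TREATMENTS:
        raise ValueError(f"life tables are defined for pure clones, got {clone!r}")
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = _rng(seed, 31)
    s, g, p = _daily_rates(coeffs, clone, density=1.0, caged_dummy=0)
    horizon = int(observation_horizon)
    if s < 1.0:
        lifespans = np.minimum(rng.geometric(1.0 - s, size=n_individuals),
                               horizon)
    else:
        lifespans = np.full(n_individuals, horizon)
    maturation = 1 + rng.geometric(g, size=n_individuals) \
        + rng.geometric(g, size=n_individuals)
    matured = maturation <= lifespans
    ids = np.array([f"{clone}{i + 1}" for i in range(n_individuals)])

    anchors = pd.DataFrame({
        "clone": clone,
        "individual_id": ids,
        "lifespan_days": lifespans,
        "maturation_day": np.where(matured, maturation.astype(float), np.nan),
        "day": np.nan,
        "offspring_count": np.nan,
    })
    n_days = np.where(matured, lifespans - maturation + 1, 0)
    total = int(n_days.sum())
    if total == 0:
        return anchors
    rep = np.repeat(np.arange(n_individuals), n_days)
    offsets = np.concatenate([[0], np.cumsum(n_days)[:-1]])
    within = np.arange(total) - np.repeat(offsets, n_days)
    repro = pd.DataFrame({
        "clone": clone,
        "individual_id": ids[rep],
        "lifespan_days": lifespans[rep],
        "maturation_day": maturation[rep].astype(float),
        "day": (maturation[rep] + within).astype(float),
        "offspring_count": rng.poisson(p, size=total).astype(float),
    })
    return pd.concat([anchors, repro], ignore_index=True)


# --------------------------------------------------------------------------
# full experiment
# --------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """A complete synthetic experiment with its generating truth attached."""

    census: pd.DataFrame
    plants: dict[str, PlantSizeSeries]        # daily truth per population
    life_table: pd.DataFrame
    frequencies: pd.DataFrame                 # census-day observations
    freq_daily: dict[str, np.ndarray]         # daily truth, mixed pops only
    truth: CoefficientSet
    config: ScenarioConfig

    def population_ids(self) -> list[str]:
        return list(self.census["population_id"].unique())


def gen_experiment(cfg: ScenarioConfig | None = None,
                   mixed_as_clones: bool = False) -> SyntheticDataset:
    """Generate the full 12-treatment x replicates experiment plus life tables.

    By default every treatment (including the mixtures) is simulated from its
    own column of the true coefficient set, with mixed populations run as two
    identically parameterised lineages so that genuine drift-driven clone
    frequencies are produced.  With ``mixed_as_clones=True`` the mixed
    populations are instead generated from the two pure clones' coefficients
    responding to shared density (frequency-weighted truth), the regime used
    to study the transient decomposition.
    """
    if cfg is None:
        cfg = ScenarioConfig()
    census_parts: list[pd.DataFrame] = []
    freq_parts: list[pd.DataFrame] = []
    plants: dict[str, PlantSizeSeries] = {}
    freq_daily: dict[str, np.ndarray] = {}
    for ti, treatment in enumerate(TREATMENTS):
        if treatment not in cfg.treatments:
            continue
        for ai, arm in enumerate(ARMS):
            for rep in range(cfg.replicates):
                pop_id = f"{treatment}-{arm}-{rep + 1}"
                sub = int(np.random.SeedSequence(
                    cfg.seed, spawn_key=(ti, ai, rep)).generate_state(1)[0]
                    % (2 ** 31))
                if treatment in MIXED_TREATMENTS:
                    if mixed_as_clones:
                        ca, cb = treatment[0], treatment[1]
                    else:
                        ca = cb = treatment
                    _, census, freq_rows, fdaily, plant = \
                        simulate_mixed_population(
                            cfg.coeffs, ca, cfg.coeffs, cb, treatment, arm,
                            cfg, sub, pop_id=pop_id)
                    freq_parts.append(freq_rows)
                    freq_daily[pop_id] = fdaily
                else:
                    _, census, plant = simulate_population(
                        cfg.coeffs, treatment, arm, cfg, sub, pop_id=pop_id)
                census_parts.append(census)
                plants[pop_id] = plant
    life_parts = [
        gen_life_table(cfg.coeffs, clone, n,
                       int(np.random.SeedSequence(
                           cfg.seed, spawn_key=(99, ci)).generate_state(1)[0]
                           % (2 ** 31)))
        for ci, (clone, n) in enumerate(zip(PURE_TREATMENTS, cfg.life_table_n))
    ]
    return SyntheticDataset(
        census=pd.concat(census_parts, ignore_index=True),
        plants=plants,
        life_table=pd.concat(life_parts, ignore_index=True),
        frequencies=(pd.concat(freq_parts, ignore_index=True)
                     if freq_parts else pd.DataFrame(
                         columns=["population_id", "day", "freq_clone1"])),
        freq_daily=freq_daily,
        truth=cfg.coeffs,
        config=cfg,
    )
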