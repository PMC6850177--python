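"""Stepwise decomposition of transient growth in the evolving populations.

For every observed population structure of an evolving (two-clone) treatment
the population size is projected one census interval ahead under a ladder of
scenarios, each building on the previous one:

  reference     evolving-treatment vital rates + the population's own
                (observed) plant size -- the "true" prediction;
  step 2        50:50 response-scale average of the two pure clones' rates
                + the day-specific average plant size of the pure-clone
                replicates in the same arm (a non-evolving population);
  step 3        same averaged rates, but the evolving population's observed
                plant size (density now matches the reference);
  step 4        pure-clone rates weighted by the observed (interpolated)
                clone frequencies instead of the constant 0.5;
  step 5        starting from step 4, survival / growth / reproduction are
                replaced one at a time by the evolving-treatment rate
                (replacing all three recovers the reference exactly).

Projected sizes are converted to daily growth rates, (N_end/N_start)^(1/dt)
with dt the actual census gap, and each scenario is scored by the
proportion of variance in the reference series it explains,
1 - SSE/SST (which may be negative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .demography import (
    MIXED_TREATMENTS,
    CoefficientSet,
    Covariates,
    PlantSizeSeries,
    VitalRates,
    cage_schedule,
    project_days,
    vital_rates_at,
)
from .inference import FieldDataset
from .ltre import average_vital_rates

__all__ = [
    "SCENARIOS",
    "TransientResult",
    "daily_growth_rate",
    "transient_scenarios",
    "variance_explained",
    "default_window",
]

#: scenario identifiers in ladder order
SCENARIOS: tuple[str, ...] = (
    "reference", "pure_clone_avg", "plant_size", "frequencies",
    "replace_survival", "replace_growth", "replace_reproduction",
    "replace_all",
)


def daily_growth_rate(n_start: float, n_end: float, dt: int = 3) -> float:
    """Geometric-mean daily growth over an interval: (N_end/N_start)^(1/dt)."""
    if n_start <= 0:
        raise ValueError("starting population size must be > 0")
    if n_end < 0:
        raise ValueError("ending population size must be >= 0")
    if dt < 1:
        raise ValueError("dt must be >= 1")
    return float((n_end / n_start) ** (1.0 / dt))


def variance_explained(reference: Sequence[float],
                       scenario: Sequence[float]) -> float:
    """1 - SSE/SST of a scenario series against the reference series."""
    ref = np.asarray(reference, dtype=float)
    scen = np.asarray(scenario, dtype=float)
    if ref.shape != scen.shape or ref.size < 2:
        raise ValueError("need equal-length series with >= 2 entries")
    sst = float(np.sum((ref - ref.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("reference series has zero variance")
    sse = float(np.sum((ref - scen) ** 2))
    return 1.0 - sse / sst


def default_window(arm: str) -> tuple[int, int]:
    """Observation window: full experiment for caged populations, the
    post-removal period for uncaged ones."""
    return (0, 31) if arm == "caged" else (17, 31)


def _mean_pure_plant(dataset: FieldDataset, pair: str, arm: str,
                     ) -> PlantSizeSeries:
    """Day-specific mean leaf count over the pure-clone replicates of the
    two constituent clones in the same arm."""
    series = [dataset.plants[p.population_id] for p in dataset.populations
              if p.arm == arm and p.treatment in (pair[0], pair[1])]
    if not series:
        raise ValueError(f"no pure-clone populations for pair {pair!r}")
    start = max(s.start_day for s in series)
    end = min(s.end_day for s in series)
    days = np.arange(start, end + 1)
    values = np.mean([[s.leaves(d) for d in days] for s in series], axis=0)
    return PlantSizeSeries(start_day=start, values=values)


def _frequency_fn(dataset: FieldDataset, population_id: str,
                  ) -> Callable[[int], float]:
    """Linear interpolation of the observed clone-frequency series."""
    if dataset.frequencies is None or dataset.frequencies.empty:
        raise ValueError("dataset has no clone-frequency series")
    sub = dataset.frequencies[
        dataset.frequencies["population_id"] == population_id].dropna(
        subset=["freq_clone1"])
    if sub.empty:
        raise ValueError(f"no frequencies for population {population_id!r}")
    days = sub["day"].to_numpy(dtype=float)
    freqs = sub["freq_clone1"].to_numpy(dtype=float)
    order = np.argsort(days)
    days, freqs = days[order], freqs[order]

    def fn(day: int) -> float:
        return float(np.interp(day, days, freqs))

    return fn


@dataclass
class TransientResult:
    """Per-observation predicted daily growth rates under every scenario."""

    arm: str
    pair: str
    observations: pd.DataFrame  # population_id, day, gap, scenario, rate

    def series(self, scenario: str) -> np.ndarray:
        sub = self.observations[self.observations["scenario"] == scenario]
        return sub.sort_values(["population_id", "day"])[
            "predicted_daily_growth"].to_numpy()

    def variance_explained_table(self) -> pd.DataFrame:
        ref = self.series("reference")
        rows = []
        for scenario in SCENARIOS[1:]:
            rows.append({
                "arm": self.arm, "pair": self.pair, "scenario": scenario,
                "variance_explained": variance_explained(
                    ref, self.series(scenario)),
            })
        return pd.DataFrame(rows)


def transient_scenarios(dataset: FieldDataset, coeffs: CoefficientSet,
                        pair: str, arm: str,
                        window: tuple[int, int] | None = None,
                        reference_freqs: dict[str, Callable[[int], float] |
                                              np.ndarray] | None = None,
                        ) -> TransientResult:
    """Run the scenario ladder for one evolving treatment and arm.

    ``reference_freqs`` optionally replaces the evolving-treatment coefficient
    rates in the reference (and in the step-5 replacement source) by
    frequency-weighted pure-clone rates using the given per-population daily
    frequencies -- the generating regime of synthetic mixtures built from
    their pure clones.
    """
    if pair not in MIXED_TREATMENTS:
        raise ValueError(f"pair must be a mixed treatment, got {pair!r}")
    if window is None:
        window = default_window(arm)
    t_lo, t_hi = window
    clone1, clone2 = pair[0], pair[1]
    pure_plant = _mean_pure_plant(dataset, pair, arm)
    pops = sorted((p for p in dataset.populations
                   if p.treatment == pair and p.arm == arm),
                  key=lambda p: p.population_id)
    if not pops:
        raise ValueError(f"no populations for {pair!r} ({arm})")

    def clone_rates(day: int, density: float, cage_dummy: int,
                    ) -> tuple[VitalRates, VitalRates]:
        r1 = vital_rates_at(coeffs, Covariates(density, clone1, cage_dummy))
        r2 = vital_rates_at(coeffs, Covariates(density, clone2, cage_dummy))
        return r1, r2

    rows: list[dict] = []
    for pop in pops:
        plant = dataset.plants[pop.population_id]
        cage = cage_schedule(pop.arm, pop.removal_day)
        if reference_freqs is not None:
            rf = reference_freqs[pop.population_id]
            if callable(rf):
                ref_freq_fn = rf
            else:
                arr = np.asarray(rf, dtype=float)
                ref_freq_fn = lambda day, _a=arr: float(_a[day])
        else:
            ref_freq_fn = None
        obs_freq_fn = _frequency_fn(dataset, pop.population_id)

        def reference_rates(day: int, density: float) -> VitalRates:
            c = cage(day)
            if ref_freq_fn is not None:
                f = ref_freq_fn(day)
                r1, r2 = clone_rates(day, density, c)
                return average_vital_rates([r1, r2], weights=[f, 1.0 - f])
            return vital_rates_at(coeffs, Covariates(density, pair, c))

        def averaged_rates(day: int, density: float) -> VitalRates:
            r1, r2 = clone_rates(day, density, cage(day))
            return average_vital_rates([r1, r2])

        def freq_weighted_rates(day: int, density: float) -> VitalRates:
            f = obs_freq_fn(day)
            r1, r2 = clone_rates(day, density, cage(day))
            return average_vital_rates([r1, r2], weights=[f, 1.0 - f])

        def replaced_rates(rate_name: str):
            def fn(day: int, density: float) -> VitalRates:
                base = freq_weighted_rates(day, density)
                evo = reference_rates(day, density)
                return base.replaced(rate_name, evo.get(rate_name))
            return fn

        scenario_fns: dict[str, tuple[Callable, PlantSizeSeries]] = {
            "reference": (reference_rates, plant),
            "pure_clone_avg": (averaged_rates, pure_plant),
            "plant_size": (averaged_rates, plant),
            "frequencies": (freq_weighted_rates, plant),
            "replace_survival": (replaced_rates("survival"), plant),
            "replace_growth": (replaced_rates("growth"), plant),
            "replace_reproduction": (replaced_rates("reproduction"), plant),
            "replace_all": (reference_rates, plant),
        }

        for a in range(pop.days.size - 1):
            d0, d1 = int(pop.days[a]), int(pop.days[a + 1])
            if d0 < t_lo or d1 > t_hi:
                continue
            n0 = pop.counts[a]
            n_start = float(n0.sum())
            if n_start <= 0:
                continue  # growth rate undefined; observation skipped
            gap = d1 - d0
            for scenario, (rate_fn, p_series) in scenario_fns.items():
                n_end = project_days(n0, d0, gap, rate_fn, p_series).sum()
                rows.append({
                    "arm": arm, "pair": pair,
                    "population_id": pop.population_id,
                    "day": d0, "gap": gap, "scenario": scenario,
                    "predicted_daily_growth": daily_growth_rate(
                        n_start, float(n_end), gap),
                })
    if not rows:
        raise ValueError("no usable observations in the requested window")
    return TransientResult(arm=arm, pair=pair,
                           observations=pd.DataFrame(rows))
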