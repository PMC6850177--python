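"""Deterministic demographic machinery for stage-structured aphid populations.

The life cycle is collapsed to three stages (1st/2nd instar; 3rd instar;
4th/5th instar plus winged adults).  Daily dynamics are governed by three
vital rates -- survival probability ``sigma``, probability of advancing one
stage ``gamma`` and per-capita daily reproduction ``phi`` -- arranged in the
Lefkovitch matrix

    A = [[sigma*(1-gamma), 0,               phi  ],
         [sigma*gamma,     sigma*(1-gamma), 0    ],
         [0,               sigma*gamma,     sigma]]

Each vital rate is a linear function (on the link scale) of population
density (individuals per leaf), aphid treatment (three pure clones A, B, C
and three two-clone mixtures AB, AC, BC) and a caging-by-treatment
interaction.  Survival and stage advance use a logit link; reproduction a
log link.  Fourteen coefficients parameterise each rate: intercept, density
slope, six treatment effects and six caging-by-treatment effects.

Projection between censuses proceeds in daily steps, rebuilding the matrix
every day from the currently projected abundance divided by that day's leaf
count (a plant-size proxy interpolated to daily resolution).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.special import expit

TREATMENTS: tuple[str, ...] = ("A", "B", "C", "AB", "AC", "BC")
MIXED_TREATMENTS: tuple[str, ...] = ("AB", "AC", "BC")
PURE_TREATMENTS: tuple[str, ...] = ("A", "B", "C")
RATES: tuple[str, ...] = ("survival", "growth", "reproduction")
ARMS: tuple[str, ...] = ("caged", "uncaged")

#: number of regression coefficients per vital rate:
#: intercept, density, 6 treatment, 6 caging-by-treatment
N_COEF_PER_RATE = 14

# linear-predictor exponent guard; exp(50) ~ 5e21 keeps phi finite
_EXP_CAP = 50.0


def treatment_index(treatment: str | int) -> int:
    """Return the 0-based index of a treatment given its label or 1-based index."""
    if isinstance(treatment, str):
        try:
            return TREATMENTS.index(treatment)
        except ValueError:
            raise ValueError(f"unknown treatment {treatment!r}") from None
    idx = int(treatment) - 1
    if not 0 <= idx < len(TREATMENTS):
        raise ValueError(f"treatment index must be 1..6, got {treatment}")
    return idx


@dataclass(frozen=True)
class VitalRates:
    """Daily vital rates on the response scale.

    sigma : daily survival probability, 0 < sigma < 1
    gamma : daily probability of advancing one stage, 0 <= gamma < 1
    phi   : expected offspring per stage-3 individual per day, phi >= 0
    """

    sigma: float
    gamma: float
    phi: float

    def __post_init__(self) -> None:
        if not 0.0 < self.sigma <= 1.0:
            raise ValueError(f"sigma must be in (0, 1], got {self.sigma}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.phi < 0.0:
            raise ValueError(f"phi must be >= 0, got {self.phi}")

    def replaced(self, rate: str, value: float) -> "VitalRates":
        """Return a copy with one named rate replaced."""
        key = {"survival": "sigma", "growth": "gamma", "reproduction": "phi"}[rate]
        return replace(self, **{key: value})

    def get(self, rate: str) -> float:
        return {"survival": self.sigma, "growth": self.gamma,
                "reproduction": self.phi}[rate]


@dataclass(frozen=True)
class Covariates:
    """Covariates entering the vital-rate regressions.

    density   : individuals per leaf (raw scale, >= 0)
    treatment : label in TREATMENTS or 1-based index
    caged_dummy : 0 under caged conditions, 1 once cages are removed
    """

    density: float
    treatment: str | int
    caged_dummy: int = 0

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError(f"density must be >= 0, got {self.density}")
        if self.caged_dummy not in (0, 1):
            raise ValueError(f"caging dummy must be 0 or 1, got {self.caged_dummy}")


@dataclass
class CoefficientSet:
    """Regression coefficients for the three vital rates.

    ``betas`` has shape (3, 14); rows follow :data:`RATES` order and columns are
    [intercept, density, A, B, C, AB, AC, BC, C:A, C:B, C:C, C:AB, C:AC, C:BC].
    If ``density_scale`` is set, the density covariate is standardized as
    (D - mean) / sd before entering the linear predictor and the slope refers
    to that z-scored density; :meth:`to_raw` converts back to raw-density units.
    """

    betas: np.ndarray
    density_scale: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.shape != (len(RATES), N_COEF_PER_RATE):
            raise ValueError(
                f"betas must have shape (3, {N_COEF_PER_RATE}), got {self.betas.shape}"
            )
        if self.density_scale is not None:
            mean, sd = self.density_scale
            if sd <= 0:
                raise ValueError("density_scale sd must be > 0")
            self.density_scale = (float(mean), float(sd))

    def scaled_density(self, density: float) -> float:
        if self.density_scale is None:
            return density
        mean, sd = self.density_scale
        return (density - mean) / sd

    def to_raw(self) -> "CoefficientSet":
        """Equivalent coefficients with density entering on the raw scale."""
        if self.density_scale is None:
            return CoefficientSet(self.betas.copy())
        mean, sd = self.density_scale
        b = self.betas.copy()
        b[:, 0] = b[:, 0] - b[:, 1] * mean / sd
        b[:, 1] = b[:, 1] / sd
        return CoefficientSet(b)

    @property
    def param_names(self) -> list[str]:
        cols = (["b0", "b1_density"]
                + [f"t_{t}" for t in TREATMENTS]
                + [f"cage_{t}" for t in TREATMENTS])
        return [f"{rate}[{c}]" for rate in RATES for c in cols]


def linear_predictor(coeffs: CoefficientSet, vital: str,
                     cov: Covariates) -> float:
    """Linear predictor b0 + b1*D + b_treat + C*b_cage:treat for one vital rate."""
    if vital not in RATES:
        raise ValueError(f"unknown vital rate {vital!r}")
    r = RATES.index(vital)
    i = treatment_index(cov.treatment)
    b = coeffs.betas[r]
    d = coeffs.scaled_density(cov.density)
    return float(b[0] + b[1] * d + b[2 + i] + cov.caged_dummy * b[8 + i])


def vital_rates_at(coeffs: CoefficientSet, cov: Covariates) -> VitalRates:
    """Vital rates on the response scale: logit links for survival and growth,
    log link for reproduction. Link inverses saturate rather than overflow."""
    y_s = linear_predictor(coeffs, "survival", cov)
    y_g = linear_predictor(coeffs, "growth", cov)
    y_r = linear_predictor(coeffs, "reproduction", cov)
    return VitalRates(
        sigma=float(expit(y_s)),
        gamma=float(expit(y_g)),
        phi=float(np.exp(min(y_r, _EXP_CAP))),
    )


def build_transition_matrix(v: VitalRates) -> np.ndarray:
    """Assemble the 3x3 daily Lefkovitch matrix from vital rates."""
    s, g, p = v.sigma, v.gamma, v.phi
    return np.array([
        [s * (1.0 - g), 0.0,           p],
        [s * g,         s * (1.0 - g), 0.0],
        [0.0,           s * g,         s],
    ])


def asymptotic_growth_rate(A: np.ndarray) -> float:
    """Dominant-eigenvalue modulus of a nonnegative transition matrix."""
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ValueError("transition matrix must be nonnegative")
    return float(np.max(np.abs(np.linalg.eigvals(A))))


def mean_first_passage_time(gamma: float) -> float:
    """Expected days to first reach stage 3 conditional on survival: 1 + 2/gamma.

    An individual needs two stage transitions, each a daily Bernoulli(gamma)
    trial, plus the starting day.
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    if gamma > 1:
        raise ValueError(f"gamma must be <= 1, got {gamma}")
    return 1.0 + 2.0 / gamma


# --------------------------------------------------------------------------
# plant size
# --------------------------------------------------------------------------

@dataclass
class PlantSizeSeries:
    """Daily leaf counts over a contiguous window of experiment days."""

    start_day: int
    values: np.ndarray  # leaves per day, strictly positive

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a non-empty 1-d array")
        if np.any(self.values <= 0):
            raise ValueError("leaf counts must be strictly positive")

    @property
    def end_day(self) -> int:
        return self.start_day + self.values.size - 1

    def leaves(self, day: int) -> float:
        idx = int(day) - self.start_day
        if not 0 <= idx < self.values.size:
            raise ValueError(
                f"plant size undefined for day {day} "
                f"(window {self.start_day}..{self.end_day})"
            )
        return float(self.values[idx])

    def days(self) -> np.ndarray:
        return np.arange(self.start_day, self.end_day + 1)


def interpolate_plant_size(obs: Sequence[tuple[int, float]],
                           window: tuple[int, int] | None = None,
                           ) -> PlantSizeSeries:
    """Smooth daily leaf-count series through sparse census-day observations.

    A penalized cubic smoothing spline (GCV-selected penalty) stands in for a
    per-plant GAM; with fewer than five observations it degenerates to linear
    interpolation, and a single observation gives a constant series.  Outside
    the observed day range the series holds the boundary value.  The result is
    clamped below at one leaf.
    """
    if not obs:
        raise ValueError("at least one plant-size observation is required")
    pts = sorted((int(d), float(v)) for d, v in obs)
    days = np.array([d for d, _ in pts])
    leaves = np.array([v for _, v in pts])
    if np.any(leaves <= 0):
        raise ValueError("observed leaf counts must be > 0")
    if np.any(np.diff(days) == 0):
        raise ValueError("duplicate observation days")
    if window is None:
        window = (min(0, int(days[0])), int(days[-1]))
    t0, t1 = int(window[0]), int(window[1])
    if t1 < t0:
        raise ValueError("window end before start")
    grid = np.arange(t0, t1 + 1, dtype=float)
    inner = np.clip(grid, days[0], days[-1])  # hold boundary values outside
    if days.size == 1:
        daily = np.full(grid.size, leaves[0])
    elif days.size < 5:
        daily = np.interp(inner, days, leaves)
    else:
        spline = make_smoothing_spline(days.astype(float), leaves)
        daily = spline(inner)
    daily = np.maximum(daily, 1.0)
    return PlantSizeSeries(start_day=t0, values=daily)


# --------------------------------------------------------------------------
# projection
# --------------------------------------------------------------------------

RateFunction = Callable[[int, float], VitalRates]


def cage_schedule(arm: str, removal_day: int | None) -> Callable[[int], int]:
    """Daily caging dummy: 1 from the removal day onward for uncaged-arm
    populations, 0 otherwise (uncaged populations are caged until removal)."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    if arm == "caged":
        return lambda day: 0
    if removal_day is None:
        raise ValueError("uncaged arm requires a removal day")
    rd = int(removal_day)
    return lambda day: 1 if day >= rd else 0


def project_days(n0: Sequence[float], t0: int, dt: int,
                 rate_fn: RateFunction, plant: PlantSizeSeries) -> np.ndarray:
    """Project a stage vector ``dt`` daily steps from day ``t0``.

    Each day the density is the currently projected total abundance divided by
    that day's leaf count; ``rate_fn(day, density)`` supplies the vital rates
    and the matrix is rebuilt before the daily multiplication.
    """
    if dt < 1 or int(dt) != dt:
        raise ValueError(f"dt must be a positive integer, got {dt}")
    n = np.asarray(n0, dtype=float).copy()
    if n.shape != (3,) or np.any(n < 0):
        raise ValueError("stage vector must be 3 nonnegative entries")
    for day in range(int(t0), int(t0) + int(dt)):
        density = n.sum() / plant.leaves(day)
        v = rate_fn(day, density)
        n = build_transition_matrix(v) @ n
    return n


def project_interval(n0: Sequence[float], coeffs: CoefficientSet,
                     treatment: str | int,
                     cage: Callable[[int], int] | Mapping[int, int],
                     plant: PlantSizeSeries, t0: int, dt: int) -> np.ndarray:
    """Project an observed stage vector across a census interval under the
    regression model, recomputing density, covariates and the matrix daily."""
    if isinstance(cage, Mapping):
        sched = cage.__getitem__
    else:
        sched = cage

    def rate_fn(day: int, density: float) -> VitalRates:
        cov = Covariates(density=density, treatment=treatment,
                         caged_dummy=int(sched(day)))
        return vital_rates_at(coeffs, cov)

    return project_days(n0, t0, dt, rate_fn, plant)


# --------------------------------------------------------------------------
# census container
# --------------------------------------------------------------------------

@dataclass
class CensusSeries:
    """Census observations for one experimental population.

    counts holds the merged 3-stage counts (rows align with ``days``);
    leaves the leaf count observed on each census day.
    """

    population_id: str
    treatment: str
    arm: str
    removal_day: int | None
    days: np.ndarray
    counts: np.ndarray
    leaves: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.counts = np.asarray(self.counts, dtype=float)
        self.leaves = np.asarray(self.leaves, dtype=float)
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.counts.shape != (self.days.size, 3):
            raise ValueError("counts must have shape (n_days, 3)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("census days must be strictly increasing")

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def densities(self) -> np.ndarray:
        return self.totals / self.leaves

    def cage_fn(self) -> Callable[[int], int]:
        return cage_schedule(self.arm, self.removal_day)
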