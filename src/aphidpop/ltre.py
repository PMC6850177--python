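"""Life table response experiment (LTRE) decompositions across density.

Differences in asymptotic population growth rate (the dominant eigenvalue of
the daily transition matrix) between demographic regimes are attributed to
the individual vital rates by one-at-a-time replacement: starting from a
reference matrix built from averaged vital rates, each rate in turn is
replaced by the focal regime's rate and the change in the eigenvalue is the
contribution of that rate, evaluated along a grid of densities.

Two contrasts are provided: each pure clone against the average of the three
clones, and each evolving two-clone mixture against the 50:50 average of its
constituent pure clones (the expectation for a non-evolving population).
Averaging is done on the response scale (after the link inverses), and
uncertainty bands come from repeating the profile over random posterior
draws of the coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .demography import (
    MIXED_TREATMENTS,
    PURE_TREATMENTS,
    RATES,
    CoefficientSet,
    Covariates,
    VitalRates,
    asymptotic_growth_rate,
    build_transition_matrix,
    vital_rates_at,
)
from .inference import PosteriorChains, theta_to_coeffs

__all__ = [
    "LTREResult",
    "average_vital_rates",
    "ltre_contributions",
    "ltre_clone_profile",
    "ltre_evolution_profile",
    "ltre_uncertainty",
    "density_grid",
]


def average_vital_rates(rates: Sequence[VitalRates],
                        weights: Sequence[float] | None = None) -> VitalRates:
    """(Weighted) arithmetic mean of vital rates on the response scale."""
    if len(rates) == 0:
        raise ValueError("need at least one set of vital rates")
    if weights is None:
        w = np.full(len(rates), 1.0 / len(rates))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(rates),) or np.any(w < 0) \
                or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be nonnegative and sum to 1")
    def mean(values: list[float]) -> float:
        # identical inputs average to themselves exactly (the LTRE
        # zero-contribution contract relies on exact equality)
        if all(v == values[0] for v in values):
            return values[0]
        return float(np.dot(w, values))

    return VitalRates(
        sigma=mean([r.sigma for r in rates]),
        gamma=mean([r.gamma for r in rates]),
        phi=mean([r.phi for r in rates]),
    )


def ltre_contributions(ref: VitalRates, focal: VitalRates) -> dict[str, float]:
    """Per-rate contribution: lambda(ref with one rate from focal) - lambda(ref)."""
    lam_ref = asymptotic_growth_rate(build_transition_matrix(ref))
    out = {}
    for rate in RATES:
        replaced = ref.replaced(rate, focal.get(rate))
        out[rate] = asymptotic_growth_rate(
            build_transition_matrix(replaced)) - lam_ref
    return out


@dataclass
class LTREResult:
    """Density-profiled growth rates and per-rate contributions.

    ``contributions[focal][rate]`` is an array over the density grid;
    ``bands`` (when present) maps the same keys to (lo, hi) arrays.
    """

    densities: np.ndarray
    caged: bool
    reference_lambda: np.ndarray
    focal_lambda: dict[str, np.ndarray]
    contributions: dict[str, dict[str, np.ndarray]]
    bands: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for focal, per_rate in self.contributions.items():
            for rate, contrib in per_rate.items():
                for g, d in enumerate(self.densities):
                    row = {
                        "density": float(d),
                        "caged": bool(self.caged),
                        "focal": focal,
                        "vital_rate": rate,
                        "contribution": float(contrib[g]),
                    }
                    if self.bands is not None:
                        lo, hi = self.bands[focal][rate]
                        row["lo95"] = float(lo[g])
                        row["hi95"] = float(hi[g])
                    rows.append(row)
        return pd.DataFrame(rows)


def _rates_at(coeffs: CoefficientSet, treatment: str, density: float,
              caged: bool) -> VitalRates:
    return vital_rates_at(coeffs, Covariates(
        density=density, treatment=treatment,
        caged_dummy=0 if caged else 1))


def _profile(coeffs: CoefficientSet, grid: np.ndarray, caged: bool,
             groups: dict[str, tuple[tuple[str, ...], str]]) -> LTREResult:
    """Shared profile machinery.

    ``groups[focal_label] = (reference_treatments, focal_treatment)``: the
    reference rates are the response-scale average over the listed
    treatments, the focal rates those of the focal treatment.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 0):
        raise ValueError("densities must be nonnegative")
    ref_lambda = np.empty(grid.size)
    focal_lambda = {f: np.empty(grid.size) for f in groups}
    contributions = {f: {r: np.empty(grid.size) for r in RATES}
                     for f in groups}
    ref_cache: dict[tuple[str, ...], VitalRates] = {}
    for g, d in enumerate(grid):
        ref_cache.clear()
        first = True
        for focal, (ref_treats, focal_treat) in groups.items():
            if ref_treats not in ref_cache:
                ref_cache[ref_treats] = average_vital_rates(
                    [_rates_at(coeffs, t, d, caged) for t in ref_treats])
            ref = ref_cache[ref_treats]
            lam_ref = asymptotic_growth_rate(build_transition_matrix(ref))
            if first:
                ref_lambda[g] = lam_ref
                first = False
            focal_rates = _rates_at(coeffs, focal_treat, d, caged)
            focal_lambda[focal][g] = asymptotic_growth_rate(
                build_transition_matrix(focal_rates))
            for rate in RATES:
                if focal_rates.get(rate) == ref.get(rate):
                    contributions[focal][rate][g] = 0.0  # exact zero by contract
                    continue
                replaced = ref.replaced(rate, focal_rates.get(rate))
                contributions[focal][rate][g] = asymptotic_growth_rate(
                    build_transition_matrix(replaced)) - lam_ref
    return LTREResult(densities=grid, caged=caged,
                      reference_lambda=ref_lambda,
                      focal_lambda=focal_lambda,
                      contributions=contributions)


def ltre_clone_profile(coeffs: CoefficientSet, grid: Sequence[float],
                       caged: bool = True) -> LTREResult:
    """Each pure clone against the average clone (response-scale average of
    A, B and C at each density)."""
    groups = {clone: (PURE_TREATMENTS, clone) for clone in PURE_TREATMENTS}
    return _profile(coeffs, np.asarray(grid, dtype=float), caged, groups)


def ltre_evolution_profile(coeffs: CoefficientSet, pair: str,
                           grid: Sequence[float],
                           caged: bool = True) -> LTREResult:
    """One evolving mixture against the 50:50 average of its pure clones."""
    if pair not in MIXED_TREATMENTS:
        raise ValueError(f"pair must be one of {MIXED_TREATMENTS}, got {pair!r}")
    groups = {pair: ((pair[0], pair[1]), pair)}
    return _profile(coeffs, np.asarray(grid, dtype=float), caged, groups)


def ltre_uncertainty(posterior: PosteriorChains,
                     profile_op: Callable[[CoefficientSet], LTREResult],
                     n_draws: int = 1000, seed: int = 0) -> LTREResult:
    """Central 95% bands of the contributions over random posterior draws.

    Returns the point profile (at the posterior median coefficients) with
    ``bands`` filled in; seed-reproducible.
    """
    pooled = posterior.pooled()
    if pooled.size == 0:
        raise ValueError("empty posterior")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, pooled.shape[0], size=n_draws)
    point = profile_op(posterior.median_coeffs())
    stacks: dict[str, dict[str, list[np.ndarray]]] = {
        f: {r: [] for r in RATES} for f in point.contributions}
    for i in idx:
        coeffs = theta_to_coeffs(pooled[i], posterior.density_scale)[0]
        res = profile_op(coeffs)
        for f, per_rate in res.contributions.items():
            for r, arr in per_rate.items():
                stacks[f][r].append(arr)
    bands = {}
    for f, per_rate in stacks.items():
        bands[f] = {}
        for r, arrs in per_rate.items():
            mat = np.stack(arrs)
            lo = np.quantile(mat, 0.025, axis=0)
            hi = np.quantile(mat, 0.975, axis=0)
            bands[f][r] = (lo, hi)
    point.bands = bands
    return point


def density_grid(dataset, arm: str | None = None, n: int = 200,
                 quantile: float = 0.95) -> np.ndarray:
    """Equally spaced densities from 0 to the observed density quantile
    (per caging arm by default)."""
    dens = dataset.observed_densities(arm)
    if dens.size == 0:
        raise ValueError("no observed densities")
    return np.linspace(0.0, float(np.quantile(dens, quantile)), n)
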