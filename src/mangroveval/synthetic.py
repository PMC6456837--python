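"""Synthetic stand trajectories, tree lists and household incomes.

The generators emulate the statistical shape of a restored *Rhizophora
apiculata* stand and its dependent fishing community, so that every
pipeline stage can be exercised without field data:

* Diameter and height follow Chapman-Richards-type saturating curves
  x(t) = x_max · (1 − e^(−k·t))^p, the standard mensuration form for
  even-aged growth; stocking declines exponentially with a constant
  mortality rate (natural self-thinning); the form factor declines
  linearly with age as stems grow less cylindrical.
* Tree diameters within a stand are truncated-normal (truncated at
  zero); heights follow a deterministic power-law height-diameter
  relation h = 0.18·d^1.5 (which passes near the stand-table pairs
  D=5→H≈2 and D=15→H≈10.5).
* Household incomes are truncated-normal over a stated range, operating
  costs a fixed fraction of income, household sizes uniform integers.

All randomness flows from one integer seed per call through
``numpy.random.default_rng``; noise is off by default so the noise-free
trajectories are exact and fit-recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .economics import HouseholdRecord
from .stand_growth import StandObservation, StandTable
from .thinning import TreeRecord

__all__ = [
    "GrowthCurveParams",
    "IncomeModelParams",
    "generate_stand_trajectory",
    "generate_tree_list",
    "generate_household_incomes",
]

# height-diameter allometry used for synthetic tree lists
HD_COEF = 0.18
HD_EXP = 1.5


@dataclass(frozen=True)
class GrowthCurveParams:
    """Parameters of the synthetic stand trajectory.

    Defaults are calibrated to a restored R. apiculata stand observed
    from age 3 to 40: asymptotic diameter ~25 cm, ~2600 initial stems
    ha⁻¹ decaying to under 900 by age 40, form factor easing from 0.85
    to 0.60.  Under these defaults the MAI curve is unimodal and
    culminates near age 25.
    """

    d_max: float = 25.0   # asymptotic diameter, cm
    k_d: float = 0.05     # diameter growth rate, yr-1
    p_d: float = 1.3      # diameter shape exponent
    h_max: float = 14.0   # asymptotic branch-free height, m
    k_h: float = 0.055    # height growth rate, yr-1
    p_h: float = 1.2      # height shape exponent
    n0: float = 2600.0    # initial stocking, stems ha-1
    m: float = 0.027      # mortality rate, yr-1
    f0: float = 0.85      # form factor at the first age
    f1: float = 0.60      # form factor at the last age
    noise_cv: float = 0.0  # multiplicative CV on D and H; 0 = exact
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.d_max, self.h_max, self.n0) <= 0:
            raise ValueError("d_max, h_max and n0 must be positive")
        if min(self.k_d, self.k_h, self.m) < 0:
            raise ValueError("rates k_d, k_h, m must be non-negative")
        if not (0.0 < self.f1 <= self.f0 <= 1.0):
            raise ValueError("form factors must satisfy 0 < f1 <= f0 <= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


@dataclass(frozen=True)
class IncomeModelParams:
    """Parameters of the synthetic household-income sample.

    Defaults emulate a 30-household fishing community with net incomes
    spread over 13-36 million IDR yr⁻¹ (six Sturges classes), operating
    costs around 40% of net income, and 3-5 people per household.
    """

    n_households: int = 30
    income_mean: float = 25.0       # million IDR yr-1
    income_sd: float = 6.0          # million IDR yr-1
    income_range: tuple[float, float] = (13.0, 36.0)
    cost_fraction_mean: float = 0.40
    size_range: tuple[int, int] = (3, 5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_households < 1:
            raise ValueError("n_households must be >= 1")
        if self.income_mean <= 0 or self.income_sd < 0:
            raise ValueError("income mean must be positive and sd non-negative")
        if not (0.0 < self.cost_fraction_mean < 1.0):
            raise ValueError("cost fraction must be in (0, 1)")
        lo, hi = self.size_range
        if not (1 <= lo <= hi <= 10):
            raise ValueError("size_range must lie within [1, 10]")


def generate_stand_trajectory(
    params: GrowthCurveParams, ages: Sequence[int]
) -> StandTable:
    """Generate a stand table over ``ages`` from saturating growth curves.

    D(t) = d_max(1−e^(−k_d t))^p_d, H(t) analogous, N(t) = round(n0
    e^(−m t)), F(t) linear from f0 at the first age to f1 at the last.
    With ``noise_cv`` > 0, D and H get multiplicative lognormal-free
    gaussian noise with that coefficient of variation, reproducibly from
    the seed.
    """
    age_arr = np.asarray(list(ages), dtype=float)
    if age_arr.size == 0:
        raise ValueError("at least one age is required")
    if np.any(age_arr <= 0) or np.any(np.diff(age_arr) <= 0):
        raise ValueError("ages must be positive and strictly increasing")

    d = params.d_max * (1.0 - np.exp(-params.k_d * age_arr)) ** params.p_d
    h = params.h_max * (1.0 - np.exp(-params.k_h * age_arr)) ** params.p_h
    n = np.round(params.n0 * np.exp(-params.m * age_arr)).astype(int)
    span = age_arr[-1] - age_arr[0]
    frac = (age_arr - age_arr[0]) / span if span > 0 else np.zeros_like(age_arr)
    f = params.f0 + (params.f1 - params.f0) * frac

    if params.noise_cv > 0:
        rng = np.random.default_rng(params.seed)
        d = d * (1.0 + params.noise_cv * rng.standard_normal(d.size))
        h = h * (1.0 + params.noise_cv * rng.standard_normal(h.size))
        d = np.maximum(d, 0.1)
        h = np.maximum(h, 0.1)

    rows = tuple(
        StandObservation(t=int(t), n=int(ni), d=float(di), h=float(hi), f=float(fi))
        for t, ni, di, hi, fi in zip(age_arr, n, d, h, f)
    )
    return StandTable(rows=rows, label="synthetic")


def generate_tree_list(
    n: int, mean_d: float, sd_d: float, seed: int = 0
) -> list[TreeRecord]:
    """Draw ``n`` trees with truncated-at-zero normal diameters and
    deterministic allometric heights h = 0.18·d^1.5."""
    if n < 1:
        raise ValueError(f"need at least one tree, got n={n}")
    if mean_d <= 0:
        raise ValueError(f"mean diameter must be positive, got {mean_d}")
    if sd_d < 0:
        raise ValueError(f"diameter sd must be non-negative, got {sd_d}")
    if sd_d == 0:
        diam = np.full(n, mean_d)
    else:
        rng = np.random.default_rng(seed)
        a = (0.0 - mean_d) / sd_d  # truncate at zero
        diam = stats.truncnorm.rvs(
            a, np.inf, loc=mean_d, scale=sd_d, size=n, random_state=rng
        )
    heights = HD_COEF * diam ** HD_EXP
    return [TreeRecord(diameter=float(d), height=float(h)) for d, h in zip(diam, heights)]


def generate_household_incomes(params: IncomeModelParams) -> list[HouseholdRecord]:
    """Draw a household sample: truncated-normal net incomes over the
    stated range, costs a fixed fraction of income, uniform sizes."""
    rng = np.random.default_rng(params.seed)
    lo, hi = params.income_range
    if params.income_sd == 0:
        incomes = np.full(params.n_households, params.income_mean)
    else:
        a = (lo - params.income_mean) / params.income_sd
        b = (hi - params.income_mean) / params.income_sd
        incomes = stats.truncnorm.rvs(
            a, b, loc=params.income_mean, scale=params.income_sd,
            size=params.n_households, random_state=rng,
        )
    sizes = rng.integers(params.size_range[0], params.size_range[1] + 1,
                         size=params.n_households)
    return [
        HouseholdRecord(
            net_income=float(inc),
            household_size=int(sz),
            cost=float(inc * params.cost_fraction_mean),
        )
        for inc, sz in zip(incomes, sizes)
    ]
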