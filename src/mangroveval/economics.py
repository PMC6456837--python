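"""Direct-use valuation: rates of return, income classing, income comparison.

This layer turns household survey records and stand-level wood yields
into comparable per-person-per-day incomes:

* **Nominal rate of return** (NRR): the per-period compound growth rate
  of a nominal investment, i = (I_n / V_0)^(1/n) − 1.  For fishing
  households the gross annual return (net income + operating cost) on
  the operating cost, compounded monthly (n = 12), reproduces the
  diminishing-marginal-returns pattern of the survey.
* **Sturges classing**: household incomes are grouped into
  round(1 + 3.332·log₁₀N) contiguous integer-bounded classes whose
  common width is the income range divided by 1 + 3.332·log₁₀N.
* **Wood vs fishing**: annual wood income = area × standing volume ×
  stumpage price amortised over the rotation; both income streams are
  converted to IDR (or US$) per person per day over the dependent
  population, and the relative excess of fishing over wood income is
  reported as the overfishing rate.

Money flows in million IDR in survey records (scaled to whole rupiah on
conversion) and whole IDR in valuation outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "HouseholdRecord",
    "IncomeClassSummary",
    "NRRInput",
    "ValuationConfig",
    "nrr",
    "monthly_nrr",
    "sturges_class_count",
    "sturges_class_width",
    "classify_households",
    "wood_annual_income",
    "per_person_per_day",
    "overfishing_rate",
    "diminishing_returns_table",
]

MILLION = 1_000_000.0


@dataclass(frozen=True)
class HouseholdRecord:
    """One surveyed household: annual net income and operating cost in
    million IDR, and the number of household members."""

    net_income: float
    household_size: int
    cost: Optional[float] = None

    def __post_init__(self) -> None:
        if self.net_income <= 0:
            raise ValueError(f"net income must be positive, got {self.net_income}")
        if self.household_size < 1:
            raise ValueError(f"household size must be >= 1, got {self.household_size}")
        if self.cost is not None and self.cost < 0:
            raise ValueError(f"cost must be non-negative, got {self.cost}")


@dataclass(frozen=True)
class IncomeClassSummary:
    """One income class: integer bounds in million IDR, member counts,
    income totals and the per-person-per-day US$ conversion."""

    lower: float
    upper: float
    median_income: float
    n_households: int
    persons_per_household: float
    total_persons: int
    total_net_income: float  # million IDR yr-1
    usd_per_person_day: float


@dataclass(frozen=True)
class NRRInput:
    """Inputs of the nominal-rate-of-return formula: current (inflated)
    value I_n, initial value V_0 and the number of compounding periods."""

    inflated_value: float
    initial_value: float
    n_periods: int

    def __post_init__(self) -> None:
        if self.inflated_value <= 0 or self.initial_value <= 0:
            raise ValueError("NRR values must be strictly positive")
        if self.n_periods < 1:
            raise ValueError(f"n_periods must be >= 1, got {self.n_periods}")


@dataclass(frozen=True)
class ValuationConfig:
    """Constants of the valuation scenario.

    fx defaults to 13,300 IDR per US$; the population is the full
    dependent community (everyone whose livelihood draws on the forest),
    not only the surveyed subsample.
    """

    area_ha: float
    price_idr_per_m3: float
    population: int
    rotation_years: float
    fx: float = 13_300.0
    days_per_year: float = 365.0

    def __post_init__(self) -> None:
        for name in ("area_ha", "price_idr_per_m3", "population", "rotation_years", "fx", "days_per_year"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def nrr(inp: NRRInput) -> float:
    """Nominal rate of return per period: (I_n/V_0)^(1/n) − 1."""
    return (inp.inflated_value / inp.initial_value) ** (1.0 / inp.n_periods) - 1.0


def monthly_nrr(net: float, cost: float) -> float:
    """Monthly NRR (%) of a fishing operation.

    The gross annual return is the net income plus the operating cost;
    the rate compounds the cost into the gross return over 12 months:
    100 × [((net + cost)/cost)^(1/12) − 1].
    """
    if net <= 0:
        raise ValueError(f"net income must be positive, got {net}")
    if cost <= 0:
        raise ValueError(f"cost must be positive, got {cost}")
    return 100.0 * nrr(NRRInput(inflated_value=net + cost, initial_value=cost, n_periods=12))


def sturges_class_count(n: int) -> int:
    """Number of Sturges classes for n observations: round(1 + 3.332·log₁₀n)."""
    if n < 1:
        raise ValueError(f"sample count must be >= 1, got {n}")
    return max(1, round(1.0 + 3.332 * math.log10(n)))


def sturges_class_width(range_: float, n: int) -> float:
    """Sturges class width: range divided by 1 + 3.332·log₁₀n (unrounded)."""
    if range_ <= 0:
        raise ValueError(f"range must be positive, got {range_}")
    if n < 1:
        raise ValueError(f"sample count must be >= 1, got {n}")
    return range_ / (1.0 + 3.332 * math.log10(n))


def classify_households(
    records: Sequence[HouseholdRecord],
    config: ValuationConfig,
    income_range: Optional[tuple[float, float]] = None,
    n_classes: Optional[int] = None,
) -> list[IncomeClassSummary]:
    """Group households into Sturges income classes and summarise each.

    Classes are contiguous with integer closed bounds [l, l + w − 1] as
    conventionally printed for integer-valued incomes (13–16, 17–20, …);
    a household with income x belongs to class floor((x − l₀)/w), with
    the top class absorbing the maximum.  ``income_range`` overrides the
    data min/max when the classing range of the underlying raw survey is
    known but the records carry only class representatives.

    Per class: household and person counts, total net income (million
    IDR yr⁻¹) and US$ person⁻¹ day⁻¹ = total income in IDR / persons /
    days per year / fx.
    """
    if len(records) == 0:
        raise ValueError("cannot classify an empty record list")
    lo, hi = income_range if income_range is not None else (
        min(r.net_income for r in records),
        max(r.net_income for r in records),
    )
    if hi <= lo:
        # all incomes identical: a single degenerate class
        lo, hi = lo, lo + 1.0
    count = n_classes if n_classes is not None else sturges_class_count(len(records))
    width = max(1, round(sturges_class_width(hi - lo, len(records))))
    base = math.floor(lo)
    # extend with extra classes if the rounded width leaves the top uncovered
    while base + count * width <= hi - 1:
        count += 1

    classes: list[list[HouseholdRecord]] = [[] for _ in range(count)]
    for rec in records:
        idx = min(int((rec.net_income - base) // width), count - 1)
        if idx < 0:
            raise ValueError(
                f"income {rec.net_income} below classing range start {base}"
            )
        classes[idx].append(rec)

    summaries: list[IncomeClassSummary] = []
    for i, members in enumerate(classes):
        lower = base + i * width
        upper = lower + width - 1
        if not members:
            continue
        n_hh = len(members)
        persons = sum(r.household_size for r in members)
        total = sum(r.net_income for r in members)
        usd = total * MILLION / persons / config.days_per_year / config.fx
        summaries.append(
            IncomeClassSummary(
                lower=float(lower),
                upper=float(upper),
                median_income=(lower + upper) / 2.0,
                n_households=n_hh,
                persons_per_household=persons / n_hh,
                total_persons=persons,
                total_net_income=total,
                usd_per_person_day=usd,
            )
        )
    return summaries


def wood_annual_income(config: ValuationConfig, standing_volume: float) -> float:
    """Annual wood income, IDR yr⁻¹: the stumpage value of the standing
    stock (area × volume per ha × price) amortised over the rotation."""
    if standing_volume < 0:
        raise ValueError(f"standing volume must be non-negative, got {standing_volume}")
    return config.area_ha * standing_volume * config.price_idr_per_m3 / config.rotation_years


def per_person_per_day(
    annual_idr: float, config: ValuationConfig, in_usd: bool = False
) -> float:
    """Convert an annual IDR income stream to income per person per day,
    in IDR or (``in_usd``) US$ at the configured exchange rate."""
    value = annual_idr / config.population / config.days_per_year
    return value / config.fx if in_usd else value


def overfishing_rate(fishing_pppd: float, wood_pppd: float) -> float:
    """Relative excess (%) of fishing income over wood income per person
    per day — the proxy for fishing pressure induced by the income gap."""
    if wood_pppd <= 0:
        raise ValueError(f"wood income must be positive, got {wood_pppd}")
    return 100.0 * (fishing_pppd - wood_pppd) / wood_pppd


@dataclass(frozen=True)
class ReturnsRow:
    net: float
    cost: float
    nrr_pct: float


@dataclass(frozen=True)
class ReturnsTable:
    rows: tuple[ReturnsRow, ...]
    argmax: int = field(default=0)

    @property
    def max_row(self) -> ReturnsRow:
        return self.rows[self.argmax]


def diminishing_returns_table(records: Sequence[tuple[float, float]]) -> ReturnsTable:
    """Monthly NRR for each (net income, cost) pair, with the argmax row.

    Ties at the maximum resolve to the first occurrence.
    """
    if len(records) == 0:
        raise ValueError("cannot build a returns table from no records")
    rows = tuple(ReturnsRow(net=n, cost=c, nrr_pct=monthly_nrr(n, c)) for n, c in records)
    argmax = max(range(len(rows)), key=lambda i: (rows[i].nrr_pct, -i))
    return ReturnsTable(rows=rows, argmax=argmax)
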