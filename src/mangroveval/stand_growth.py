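"""Stand volume and increment analysis for even-aged mangrove stands.

A *stand table* summarises an even-aged stand at a series of measurement
ages: stocking N (stems ha⁻¹), mean stem diameter D (cm), branch-free
height H (m) and form factor F (the ratio of true stem volume to the
volume of a cylinder with the stem's basal area and height).  From these
the standing volume per hectare follows the classical form-factor stem
volume formula

    V = N · (π/4) · (D/100)² · H · F   [m³ ha⁻¹]

and the two standard growth proxies are

    MAI(t) = V(t) / t                      (mean annual increment)
    PAI(t) = (V(t) − V(t₋₁)) / Δt          (periodic / current annual increment)

The age at which MAI culminates marks the biologically optimal rotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

__all__ = [
    "StandObservation",
    "GrowthRow",
    "StandTable",
    "tree_volume",
    "stand_volume",
    "mai",
    "pai",
    "summarize_table",
    "peak_mai",
]


@dataclass(frozen=True)
class StandObservation:
    """One age-point of a stand table.

    Parameters
    ----------
    t : int
        Stand age in years, > 0.
    n : int
        Stocking in stems per hectare, >= 0.
    d : float
        Mean stem diameter at breast height, cm, > 0.
    h : float
        Branch-free height, m, > 0.
    f : float
        Form factor, dimensionless, in (0, 1].
    """

    t: int
    n: int
    d: float
    h: float
    f: float

    def __post_init__(self) -> None:
        if self.t <= 0:
            raise ValueError(f"stand age must be positive, got t={self.t}")
        if self.n < 0:
            raise ValueError(f"stocking must be non-negative, got n={self.n}")
        if self.d <= 0:
            raise ValueError(f"diameter must be positive, got d={self.d}")
        if self.h <= 0:
            raise ValueError(f"height must be positive, got h={self.h}")
        if not (0.0 < self.f <= 1.0):
            raise ValueError(f"form factor must be in (0, 1], got f={self.f}")


@dataclass(frozen=True)
class GrowthRow:
    """A stand observation augmented with volume and increment columns.

    ``pai`` is ``None`` for the first row of a table (no preceding
    measurement to difference against).
    """

    observation: StandObservation
    tv: float
    mai: float
    pai: Optional[float]

    @property
    def age(self) -> int:
        return self.observation.t


@dataclass(frozen=True)
class StandTable:
    """An ordered stand table: observations at strictly increasing ages."""

    rows: tuple[StandObservation, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.rows) == 0:
            raise ValueError("stand table must contain at least one row")
        object.__setattr__(self, "rows", tuple(self.rows))
        ages = [obs.t for obs in self.rows]
        for prev, cur in zip(ages, ages[1:]):
            if cur <= prev:
                raise ValueError(
                    f"ages must be strictly increasing, got {prev} followed by {cur}"
                )

    @property
    def ages(self) -> tuple[int, ...]:
        return tuple(obs.t for obs in self.rows)

    def row_at(self, age: int) -> StandObservation:
        for obs in self.rows:
            if obs.t == age:
                return obs
        raise KeyError(f"no observation at age {age} in table {self.label!r}")


def tree_volume(d: float, h: float, f: float) -> float:
    """Stem volume of a single tree, m³.

    Form-factor volume: basal area (π/4)(d/100)² times height times form
    factor.  Diameter is given in cm and converted to m here; all volumes
    are in m³.
    """
    if d <= 0:
        raise ValueError(f"diameter must be positive, got {d}")
    if h <= 0:
        raise ValueError(f"height must be positive, got {h}")
    if not (0.0 < f <= 1.0):
        raise ValueError(f"form factor must be in (0, 1], got {f}")
    return (math.pi / 4.0) * (d / 100.0) ** 2 * h * f


def stand_volume(obs: StandObservation) -> float:
    """Total standing volume, m³ ha⁻¹: stocking times mean-tree volume."""
    if obs.n == 0:
        return 0.0
    return obs.n * tree_volume(obs.d, obs.h, obs.f)


def mai(v: float, t: float) -> float:
    """Mean annual increment, m³ ha⁻¹ yr⁻¹: standing volume over stand age."""
    if t <= 0:
        raise ValueError(f"age must be positive, got t={t}")
    if v < 0:
        raise ValueError(f"volume must be non-negative, got v={v}")
    return v / t


def pai(v_t: float, v_prev: float, dt: float) -> float:
    """Periodic annual increment, m³ ha⁻¹ yr⁻¹.

    Volume difference between two consecutive measurements divided by the
    actual interval length ``dt`` (measurement ages need not be evenly
    spaced).  May be negative if volume declines.
    """
    if dt <= 0:
        raise ValueError(f"interval must be positive, got dt={dt}")
    return (v_t - v_prev) / dt


def summarize_table(table: StandTable) -> list[GrowthRow]:
    """Compute TV, MAI and PAI columns for every row of a stand table.

    PAI always uses the actual age interval between consecutive rows and
    is absent (``None``) for the first row.  Computation is carried in
    full precision; round only for presentation.
    """
    rows: list[GrowthRow] = []
    prev_tv: Optional[float] = None
    prev_age: Optional[int] = None
    for obs in table.rows:
        tv = stand_volume(obs)
        row_pai = None
        if prev_tv is not None:
            row_pai = pai(tv, prev_tv, obs.t - prev_age)
        rows.append(GrowthRow(observation=obs, tv=tv, mai=mai(tv, obs.t), pai=row_pai))
        prev_tv, prev_age = tv, obs.t
    return rows


def peak_mai(rows: Sequence[GrowthRow]) -> tuple[int, float]:
    """Age and value of the MAI culmination; ties broken by earliest age."""
    if len(rows) == 0:
        raise ValueError("cannot locate peak MAI of an empty growth series")
    best = rows[0]
    for row in rows[1:]:
        if row.mai > best.mai:
            best = row
    return best.age, best.mai
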