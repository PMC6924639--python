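"""Screening strategy definitions and per-age schedule construction.

A :class:`Strategy` describes one of three designs:

* ``none`` — no organised screening;
* ``age_based`` — quadrennial PSA testing for every man from ``start_age``
  to ``stop_age`` (default 55-69, interval 4 years);
* ``precision`` — risk-tailored: a man starts quadrennial PSA testing at
  the age his 10-year absolute prostate-cancer risk (baseline risk at his
  age times his polygenic relative risk) first crosses ``threshold``.

:func:`build_schedule` translates a strategy into the per-age vectors the
life table consumes: the screened (attender) fraction, the eligible and
ineligible strata's mean polygenic relative risks, expected screens per
cohort member, and the genotyping wave.  Eligibility is absorbing — once a
man's risk crosses the threshold he stays in the screened stratum — so the
eligible fraction is monotonised with a running maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .lifetable import RateTable, ten_year_absolute_risk
from .riskdist import RiskModel, eligible_fraction, fraction_cases_above_percentile

__all__ = ["Strategy", "Schedule", "build_schedule"]

KINDS = ("none", "age_based", "precision")


@dataclass(frozen=True)
class Strategy:
    """A screening design.

    ``threshold`` (10-year absolute risk) applies to ``precision`` only;
    ``uptake`` scales the attending fraction uniformly (eligible
    non-attenders are still genotyped in precision arms and keep their
    stratum's relative risk, but receive no screening effects).
    ``psa_cutoff`` (ng/mL) is carried for the costing cascade.
    """

    kind: str = "none"
    start_age: int = 55
    stop_age: int = 69
    interval: int = 4
    psa_cutoff: float = 3.0
    threshold: Optional[float] = None
    uptake: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if not self.start_age < self.stop_age <= 90:
            raise ValueError("require start_age < stop_age <= 90")
        if self.interval < 1:
            raise ValueError("interval must be >= 1 year")
        if not 0.0 <= self.uptake <= 1.0:
            raise ValueError("uptake must lie in [0, 1]")
        if self.kind == "precision":
            if self.threshold is None:
                raise ValueError("precision strategy requires a risk threshold")
            if self.threshold <= 0.0:
                raise ValueError(
                    "precision threshold must be > 0 (use age_based to screen everyone)"
                )

    @property
    def label(self) -> str:
        if self.kind == "none":
            return "no screening"
        if self.kind == "age_based":
            return "age-based screening"
        return f"precision {100.0 * self.threshold:g}%"

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "start_age": self.start_age, "stop_age": self.stop_age,
             "interval": self.interval, "psa_cutoff": self.psa_cutoff,
             "uptake": self.uptake}
        if self.threshold is not None:
            d["threshold"] = self.threshold
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Strategy":
        return cls(**d)


@dataclass
class Schedule:
    """Per-age screening schedule for one entry age.

    Arrays are indexed by attained age ``ages[0]..ages[-1]``:

    * ``f_attend`` — cumulative fraction of the cohort in the actively
      screened stratum (persists after screening stops: the mortality
      benefit follows the ever-screened);
    * ``f_nonattend`` — eligible non-attenders (precision with uptake < 1);
    * ``rr_eligible`` / ``rr_ineligible`` — mean polygenic relative risk of
      the ever-eligible stratum and the remainder (conserving incidence:
      ``f * rr_el + (1 - f) * rr_in = 1`` with ``f`` the eligible fraction);
    * ``screens`` — expected PSA tests per cohort member at that age
      (before attrition scaling in the life table);
    * ``newly_genotyped`` — fraction of the cohort genotyped at that age;
    * ``active`` — whether organised screening is ongoing at that age.
    """

    ages: np.ndarray
    f_attend: np.ndarray
    f_nonattend: np.ndarray
    rr_eligible: np.ndarray
    rr_ineligible: np.ndarray
    screens: np.ndarray
    newly_genotyped: np.ndarray
    active: np.ndarray
    strategy: Optional[Strategy] = None
    entry_age: Optional[int] = None

    @property
    def final_attender_fraction(self) -> float:
        """Fraction of the cohort ever screened (drives '% screened')."""
        return float(self.f_attend[-1])

    @property
    def total_screens_per_person(self) -> float:
        return float(self.screens.sum())


def _stratum_rrs_from_fraction(model: RiskModel, f: float) -> tuple:
    """Mean stratum RRs for an eligible fraction ``f`` (top-f of the
    polygenic distribution), via the case-mass split."""
    if f <= 0.0 or f >= 1.0:
        return 1.0, 1.0
    a = fraction_cases_above_percentile(model, 1.0 - f)
    return a / f, (1.0 - a) / (1.0 - f)


def build_schedule(strategy: Strategy, rates: RateTable, model: RiskModel,
                   entry_age: Optional[int] = None) -> Schedule:
    """Build the per-age schedule for ``strategy`` and one entry age.

    The schedule covers attained ages ``entry..89``.  For precision
    screening, the cumulative eligible fraction at age ``a`` is
    ``eligible_fraction(model, ten_year_absolute_risk(rates, a), threshold)``
    monotonised by running maximum; men start quadrennial screens at their
    crossing age (clipped to the cohort's entry age) and remain in the
    screened stratum thereafter.
    """
    entry = int(entry_age if entry_age is not None else strategy.start_age)
    ages = np.arange(entry, 90)
    n = len(ages)
    sched = Schedule(
        ages=ages,
        f_attend=np.zeros(n),
        f_nonattend=np.zeros(n),
        rr_eligible=np.ones(n),
        rr_ineligible=np.ones(n),
        screens=np.zeros(n),
        newly_genotyped=np.zeros(n),
        active=np.zeros(n, dtype=bool),
        strategy=strategy,
        entry_age=entry,
    )
    if strategy.kind == "none":
        return sched

    astart = max(entry, strategy.start_age)
    astop = min(strategy.stop_age, 89)
    if astart > astop:
        return sched
    window = (ages >= astart) & (ages <= astop)
    sched.active[:] = window

    if strategy.kind == "age_based":
        ever = ages >= astart
        sched.f_attend[ever] = strategy.uptake
        for a in range(astart, astop + 1, strategy.interval):
            sched.screens[a - entry] = strategy.uptake
        return sched

    # precision: eligibility from the background 10-year risk at each age
    t = strategy.threshold
    f_elig = np.zeros(n)
    running = 0.0
    for a in range(astart, astop + 1):
        f_raw = 0.0 if t >= 1.0 else eligible_fraction(
            model, ten_year_absolute_risk(rates, a), t)
        running = max(running, f_raw)  # once eligible, always eligible
        f_elig[a - entry] = running
    f_elig[ages > astop] = running

    rr_el = np.ones(n)
    rr_in = np.ones(n)
    for i in range(astart - entry, n):
        rr_el[i], rr_in[i] = _stratum_rrs_from_fraction(model, f_elig[i])

    sched.f_attend = strategy.uptake * f_elig
    sched.f_nonattend = (1.0 - strategy.uptake) * f_elig
    sched.rr_eligible = rr_el
    sched.rr_ineligible = rr_in

    # quadrennial screens from each man's crossing age
    newly = np.diff(np.concatenate([[0.0], f_elig]))
    for c in range(astart, astop + 1):
        w = newly[c - entry]
        if w <= 0:
            continue
        for a in range(c, astop + 1, strategy.interval):
            sched.screens[a - entry] += strategy.uptake * w

    # the whole cohort is genotyped when risk assessment begins
    if running > 0:
        sched.newly_genotyped[astart - entry] = 1.0
    return sched
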