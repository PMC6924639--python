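"""Annual-cycle cohort life table with competing risks and screening effects.

The cohort model follows a single-age cohort of initially cancer-free men
from an entry age to age 90 in one-year cycles.  Age-specific rates come
from a :class:`RateTable` (prostate-cancer incidence, prostate-cancer
mortality and other-cause mortality, all per person-year, in the style of
registry/DevCan population rates).  Within each cycle transitions are
applied in the order incidence -> prostate-cancer death -> other-cause
death, with no half-cycle correction.

The cohort is split into three strata driven by the screening schedule:

0. *attenders* — men in the screened stratum (elevated polygenic risk in a
   risk-tailored programme), who receive the screening effects:
   incidence inflation ``rr_incidence`` while actively screened,
   mortality reduction ``rr_mortality`` from first screen onwards, and
   age-specific overdiagnosis of their screen-detected cases;
1. *eligible non-attenders* — men above the risk threshold who decline
   screening: they carry the eligible stratum's relative risk but none of
   the screening effects;
2. *ineligible* — the below-threshold remainder.

Prostate-cancer mortality is a population rate (DevCan convention), so it
is applied to all alive, non-overdiagnosed men in a stratum, scaled by the
stratum's polygenic relative risk; overdiagnosed cases by definition never
die of prostate cancer and are exposed to other-cause mortality only.

All scalar screening-effect parameters may be NumPy arrays (a batch of
probabilistic draws); states broadcast accordingly, so one call evaluates
the whole batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "RateTable",
    "ScreeningEffects",
    "ScenarioOutcome",
    "ten_year_absolute_risk",
    "overdiagnosis_proportion",
    "run_cohort",
]

RATE_COLUMNS = ["age", "pc_incidence", "pc_mortality", "other_mortality", "population_weight"]

#: Number of years post-diagnosis during which the prostate-cancer utility
#: decrement applies (diagnosis year plus nine further years).
DX_WINDOW = 10


class RateTable:
    """Age-indexed table of per-person-year rates and population weights.

    Columns: ``age`` (integer attained age, contiguous 1-year bands),
    ``pc_incidence``, ``pc_mortality``, ``other_mortality`` (probabilities
    per person-year, in [0, 1)) and ``population_weight`` (men entering the
    cohort at that age; nonzero only for entry ages, summing to the cohort
    size).
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in RATE_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"rate table is missing columns: {missing}")
        frame = frame[RATE_COLUMNS].copy()
        frame["age"] = frame["age"].astype(int)
        frame = frame.sort_values("age").reset_index(drop=True)
        ages = frame["age"].to_numpy()
        if len(ages) == 0:
            raise ValueError("rate table is empty")
        if not np.array_equal(ages, np.arange(ages[0], ages[0] + len(ages))):
            raise ValueError("rate table ages must be contiguous integers")
        rates = frame[["pc_incidence", "pc_mortality", "other_mortality"]].to_numpy()
        if np.any(rates < 0) or np.any(rates >= 1):
            raise ValueError("all rates must lie in [0, 1) per person-year")
        if np.any(frame["population_weight"].to_numpy() < 0):
            raise ValueError("population weights must be non-negative")
        self.frame = frame
        self._age0 = int(ages[0])
        self._inc = frame["pc_incidence"].to_numpy(float)
        self._pcm = frame["pc_mortality"].to_numpy(float)
        self._oth = frame["other_mortality"].to_numpy(float)
        self._wts = frame["population_weight"].to_numpy(float)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "RateTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: Union[str, Path]) -> None:
        self.frame.to_csv(path, index=False)

    # -- lookups ----------------------------------------------------------
    @property
    def ages(self) -> np.ndarray:
        return self.frame["age"].to_numpy()

    @property
    def age_min(self) -> int:
        return self._age0

    @property
    def age_max(self) -> int:
        return self._age0 + len(self._inc) - 1

    def _index(self, age) -> np.ndarray:
        idx = np.asarray(age) - self._age0
        if np.any(idx < 0) or np.any(idx >= len(self._inc)):
            raise ValueError(
                f"age {age} outside rate table range [{self.age_min}, {self.age_max}]"
            )
        return idx

    def pc_incidence(self, age):
        return self._inc[self._index(age)]

    def pc_mortality(self, age):
        return self._pcm[self._index(age)]

    def other_mortality(self, age):
        return self._oth[self._index(age)]

    def population_weight(self, age):
        return self._wts[self._index(age)]

    @property
    def entry_ages(self) -> np.ndarray:
        """Ages with a positive population weight."""
        return self.ages[self._wts > 0]

    @property
    def cohort_size(self) -> float:
        return float(self._wts.sum())

    def validate_weights(self, expected_cohort: float, rtol: float = 1e-6) -> None:
        total = self.cohort_size
        if not np.isclose(total, expected_cohort, rtol=rtol):
            raise ValueError(
                f"population weights sum to {total:,.0f}, expected {expected_cohort:,.0f}"
            )


@dataclass
class ScreeningEffects:
    """Screening effect sizes and the opportunistic-testing adjustment.

    Point estimates follow the trial evidence used throughout: an ERSPC
    mortality relative risk of 0.79, an incidence inflation of 1.23 while
    screening is ongoing, a 0.85 relative risk of advanced stage at
    diagnosis for screen-detected cancers, and an age-linear proportion of
    screen-detected cases overdiagnosed, ``-0.62 + 0.014 * age`` (clamped
    to [0, 1]).  Registry incidence is deflated by ``opportunistic_fraction``
    to strip cases already attributable to opportunistic PSA testing.

    Any field may be an array of probabilistic draws; ``od_by_age``
    optionally overrides the linear overdiagnosis proportion with
    pre-sampled per-age values (mapping age -> proportion, broadcastable
    against the other fields).
    """

    rr_mortality: Union[float, np.ndarray] = 0.79
    rr_incidence: Union[float, np.ndarray] = 1.23
    rr_advanced: Union[float, np.ndarray] = 0.85
    overdiagnosis_intercept: Union[float, np.ndarray] = -0.62
    overdiagnosis_slope: Union[float, np.ndarray] = 0.014
    opportunistic_fraction: float = 0.10
    od_by_age: Optional[dict] = None

    @property
    def batch_shape(self) -> tuple:
        shapes = [np.shape(x) for x in (self.rr_mortality, self.rr_incidence,
                                        self.rr_advanced, self.overdiagnosis_intercept,
                                        self.overdiagnosis_slope)]
        if self.od_by_age:
            shapes.append(np.shape(next(iter(self.od_by_age.values()))))
        return np.broadcast_shapes(*shapes)


def overdiagnosis_proportion(effects: ScreeningEffects, age):
    """Proportion of screen-detected cases at ``age`` that are overdiagnosed.

    The age-linear regression ``intercept + slope * age`` clamped to
    [0, 1]; pre-sampled per-age values take precedence when present.
    """
    if effects.od_by_age is not None:
        key = int(age) if np.ndim(age) == 0 else age
        if np.ndim(key) == 0 and key in effects.od_by_age:
            return effects.od_by_age[key]
    raw = effects.overdiagnosis_intercept + np.asarray(age) * effects.overdiagnosis_slope
    return np.clip(raw, 0.0, 1.0)


def ten_year_absolute_risk(rates: RateTable, age: int):
    """Background 10-year absolute risk of prostate-cancer diagnosis.

    Competing-risk cumulative incidence over ten annual cycles:
    ``sum_t p_inc(a+t) * S(t)`` where ``S`` is the probability of remaining
    alive and undiagnosed to the start of year ``t`` (all-cause mortality
    competes, consistent with DevCan-style absolute risk).
    """
    age = int(age)
    if age < rates.age_min or age + 9 > rates.age_max:
        raise ValueError(
            f"10-year window [{age}, {age + 9}] exceeds rate table range "
            f"[{rates.age_min}, {rates.age_max}]"
        )
    surv = 1.0
    risk = 0.0
    for t in range(10):
        a = age + t
        p_inc = rates.pc_incidence(a)
        risk += p_inc * surv
        surv *= (1.0 - p_inc) * (1.0 - rates.pc_mortality(a)) * (1.0 - rates.other_mortality(a))
    return float(risk)


@dataclass
class ScenarioOutcome:
    """Per-age trajectories and totals for one scenario run.

    Trajectory arrays have shape ``(n_ages,) + batch_shape``; the economics
    layer appends discounted QALY and cost streams.  ``cohort_size`` is the
    number of men the run represents.
    """

    ages: np.ndarray
    traj: dict = field(default_factory=dict)
    cohort_size: float = 1.0
    entry_age: Optional[int] = None

    def total(self, key: str):
        return self.traj[key].sum(axis=0)

    @property
    def cases(self):
        return self.total("cases")

    @property
    def overdiagnosed(self):
        return self.total("overdiagnosed")

    @property
    def pc_deaths(self):
        return self.total("pc_deaths")

    @property
    def other_deaths(self):
        return self.total("other_deaths")

    @property
    def life_years(self):
        return self.total("life_years")

    @property
    def qalys(self):
        return self.total("qalys_disc")

    @property
    def costs(self):
        return self.total("costs_disc")

    @staticmethod
    def sum(outcomes: list["ScenarioOutcome"]) -> "ScenarioOutcome":
        """Sum outcomes (e.g. weighted single-age sub-cohorts), aligning ages."""
        lo = min(int(o.ages[0]) for o in outcomes)
        hi = max(int(o.ages[-1]) for o in outcomes)
        ages = np.arange(lo, hi + 1)
        keys = set.intersection(*[set(o.traj) for o in outcomes])
        batch = np.broadcast_shapes(*[o.traj["cases"].shape[1:] for o in outcomes])
        traj = {k: np.zeros((len(ages),) + batch) for k in keys}
        for o in outcomes:
            i0 = int(o.ages[0]) - lo
            for k in keys:
                traj[k][i0:i0 + len(o.ages)] += o.traj[k]
        return ScenarioOutcome(
            ages=ages,
            traj=traj,
            cohort_size=sum(o.cohort_size for o in outcomes),
        )


def run_cohort(rates: RateTable, schedule, effects: ScreeningEffects,
               entry_age: int, cohort_size: float = 1.0) -> ScenarioOutcome:
    """Run one single-age cohort from ``entry_age`` to age 90.

    ``schedule`` is a per-age screening schedule (see
    :func:`polyscreen.strategies.build_schedule`) covering
    ``entry_age..89``: stratum fractions, stratum relative risks, expected
    screens per cohort member and the genotyping wave.

    Returns a :class:`ScenarioOutcome` with per-age trajectories of cases,
    overdiagnoses, deaths, person-years and resource-use counts.  Raises
    ``RuntimeError`` if population conservation (alive + cumulative deaths
    = cohort) drifts beyond 1e-6 of the cohort in any cycle.
    """
    entry_age = int(entry_age)
    end_age = 90
    if entry_age >= end_age:
        raise ValueError("entry_age must be below 90")
    if rates.age_max < end_age - 1:
        raise ValueError("rate table must cover ages up to 89")
    ages = np.arange(entry_age, end_age)
    if int(schedule.ages[0]) > entry_age or int(schedule.ages[-1]) < end_age - 1:
        raise ValueError(
            f"schedule ages [{schedule.ages[0]}, {schedule.ages[-1]}] do not cover "
            f"cohort ages [{entry_age}, {end_age - 1}]"
        )
    off = entry_age - int(schedule.ages[0])

    B = effects.batch_shape
    zeros = lambda: np.zeros(B) if B else 0.0

    # healthy men per stratum (fractions of the cohort)
    H = [np.broadcast_to(np.asarray(v, float), B).copy() if B else float(v)
         for v in (0.0, 0.0, 1.0)]
    # diagnosed, alive, within the utility-decrement window: slots are years
    # since diagnosis 1..9 at cycle start; D_old holds survivors beyond it
    D_recent = [np.zeros((DX_WINDOW - 1,) + B) for _ in range(3)]
    D_old = [zeros() for _ in range(3)]
    O_recent = np.zeros((DX_WINDOW - 1,) + B)
    O_old = zeros()
    cum_deaths = zeros()

    keys = ["alive_start", "life_years", "cases", "screen_detected", "clinical_cases",
            "overdiagnosed", "pc_deaths", "other_deaths", "py_recent_dx",
            "screens", "genotyped"]
    traj = {k: np.zeros((len(ages),) + B) for k in keys}

    opp = 1.0 - effects.opportunistic_fraction

    for i, a in enumerate(ages):
        j = off + i
        f_att = schedule.f_attend[j]
        f_non = schedule.f_nonattend[j]
        f_elig = f_att + f_non
        f_prev = (schedule.f_attend[j - 1] + schedule.f_nonattend[j - 1]) if j > 0 else 0.0

        # newly eligible healthy men move out of the ineligible pool
        d_elig = max(f_elig - f_prev, 0.0)
        pool = 1.0 - f_prev
        if d_elig > 0 and pool > 1e-12:
            moved = H[2] * (d_elig / pool)
            H[2] = H[2] - moved
            d_att = f_att - (schedule.f_attend[j - 1] if j > 0 else 0.0)
            d_non = f_non - (schedule.f_nonattend[j - 1] if j > 0 else 0.0)
            H[0] = H[0] + moved * (d_att / d_elig)
            H[1] = H[1] + moved * (d_non / d_elig)

        alive = H[0] + H[1] + H[2] + sum(d.sum(axis=0) for d in D_recent) \
            + D_old[0] + D_old[1] + D_old[2] + O_recent.sum(axis=0) + O_old
        recent_start = sum(d.sum(axis=0) for d in D_recent) + O_recent.sum(axis=0)

        traj["alive_start"][i] = alive
        traj["life_years"][i] = alive

        # conservation: alive + cumulative deaths = cohort (normalised to 1)
        err = np.max(np.abs(alive + cum_deaths - 1.0))
        if err > 1e-6:
            raise RuntimeError(
                f"population conservation violated at age {a}: |error| = {err:.3e}"
            )

        active = bool(schedule.active[j])
        rr_el = schedule.rr_eligible[j]
        rr_in = schedule.rr_ineligible[j]
        rr_strat = (rr_el, rr_el, rr_in)
        base_inc = rates.pc_incidence(a) * opp

        # Registry rates are population averages over the polygenic risk
        # mixture, so stratum hazards are renormalised each cycle: the
        # risk-weighted mean hazard over the surviving healthy pool equals
        # the registry rate, and screening multipliers act within stratum.
        inc_mult = [effects.rr_incidence if active else 1.0, 1.0, 1.0]
        h_total = H[0] + H[1] + H[2]
        h_weighted = H[0] * rr_el + H[1] * rr_el + H[2] * rr_in
        c_inc = np.where(h_weighted > 1e-15, h_total / np.where(h_weighted > 1e-15, h_weighted, 1.0), 1.0)

        p_inc = [np.clip(base_inc * rr_strat[k] * inc_mult[k] * c_inc, 0.0, 1.0)
                 for k in range(3)]
        new_cases = [H[k] * p_inc[k] for k in range(3)]
        H = [H[k] - new_cases[k] for k in range(3)]

        od_frac = overdiagnosis_proportion(effects, a) if active else 0.0
        new_od = new_cases[0] * od_frac
        new_dx = [new_cases[0] - new_od, new_cases[1], new_cases[2]]

        total_new = new_cases[0] + new_cases[1] + new_cases[2]
        traj["cases"][i] = total_new
        traj["screen_detected"][i] = new_cases[0] if active else zeros()
        traj["clinical_cases"][i] = total_new - traj["screen_detected"][i]
        traj["overdiagnosed"][i] = new_od
        traj["py_recent_dx"][i] = recent_start + total_new

        # prostate-cancer death (population rate; overdiagnosed exempt),
        # renormalised the same way, separately over the healthy and the
        # diagnosed pools (their risk compositions differ once cases accrue)
        base_pcm = rates.pc_mortality(a)
        hp_total = H[0] + H[1] + H[2]
        hp_weighted = H[0] * rr_el + H[1] * rr_el + H[2] * rr_in
        c_h = np.where(hp_weighted > 1e-15, hp_total / np.where(hp_weighted > 1e-15, hp_weighted, 1.0), 1.0)
        dx = [D_recent[k].sum(axis=0) + D_old[k] + new_dx[k] for k in range(3)]
        dx_total = dx[0] + dx[1] + dx[2]
        dx_weighted = dx[0] * rr_el + dx[1] * rr_el + dx[2] * rr_in
        c_d = np.where(dx_weighted > 1e-15, dx_total / np.where(dx_weighted > 1e-15, dx_weighted, 1.0), 1.0)
        pc_deaths = zeros()
        for k in range(3):
            rrm = effects.rr_mortality if k == 0 else 1.0
            q_h = np.clip(base_pcm * rr_strat[k] * c_h * rrm, 0.0, 1.0)
            q_d = np.clip(base_pcm * rr_strat[k] * c_d * rrm, 0.0, 1.0)
            dH = H[k] * q_h
            dD = D_recent[k] * q_d
            dDo = D_old[k] * q_d
            dN = new_dx[k] * q_d
            H[k] = H[k] - dH
            D_recent[k] = D_recent[k] - dD
            D_old[k] = D_old[k] - dDo
            new_dx[k] = new_dx[k] - dN
            pc_deaths = pc_deaths + dH + dD.sum(axis=0) + dDo + dN
        traj["pc_deaths"][i] = pc_deaths

        # other-cause death (uniform across strata; applies to everyone)
        m = rates.other_mortality(a)
        other_deaths = zeros()
        for k in range(3):
            other_deaths = other_deaths + (H[k] + D_recent[k].sum(axis=0) + D_old[k] + new_dx[k]) * m
            H[k] = H[k] * (1.0 - m)
            D_recent[k] = D_recent[k] * (1.0 - m)
            D_old[k] = D_old[k] * (1.0 - m)
            new_dx[k] = new_dx[k] * (1.0 - m)
        other_deaths = other_deaths + (O_recent.sum(axis=0) + O_old + new_od) * m
        O_recent = O_recent * (1.0 - m)
        O_old = O_old * (1.0 - m)
        new_od = new_od * (1.0 - m)
        traj["other_deaths"][i] = other_deaths
        cum_deaths = cum_deaths + pc_deaths + other_deaths

        # resource use: screens scale with surviving healthy attenders
        scr = schedule.screens[j]
        if scr > 0 and f_att > 0:
            traj["screens"][i] = scr * np.minimum(H[0] / f_att, 1.0)
        geno = schedule.newly_genotyped[j]
        if geno > 0:
            traj["genotyped"][i] = geno * (H[0] + H[1] + H[2] +
                                           sum(d.sum(axis=0) for d in D_recent) +
                                           D_old[0] + D_old[1] + D_old[2] +
                                           O_recent.sum(axis=0) + O_old)

        # age the years-since-diagnosis slots
        for k in range(3):
            D_old[k] = D_old[k] + D_recent[k][-1]
            D_recent[k] = np.concatenate(
                [np.asarray(new_dx[k], float).reshape((1,) + B), D_recent[k][:-1]], axis=0
            )
        O_old = O_old + O_recent[-1]
        O_recent = np.concatenate(
            [np.asarray(new_od, float).reshape((1,) + B), O_recent[:-1]], axis=0
        )

    for k in keys:
        traj[k] = traj[k] * cohort_size

    return ScenarioOutcome(ages=ages, traj=traj, cohort_size=cohort_size,
                           entry_age=entry_age)
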