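"""Utilities, costs, discounting and cost-effectiveness summary measures.

The health-economic layer attaches quality-adjusted life-years and
health-system costs (GBP, 2016 prices) to life-table trajectories and
computes the standard decision metrics: incremental cost-effectiveness
ratios (ICER = difference in mean costs / difference in mean QALYs) and
net monetary benefit (NMB = QALYs x willingness-to-pay - costs).  Costs
and benefits are discounted at 3.5% per year from cohort entry.

Utility is age-linear (0.8639 at age 55 declining by 0.0048 per year),
multiplied by 0.93 during the ten years following a prostate-cancer
diagnosis.  Unit costs cover the full cascade: PSA test, one-off
genotyping for risk stratification, biopsy, staging, stage-specific
treatment mixes, and palliation in the year of prostate-cancer death.
Parameters may be arrays of probabilistic draws; everything broadcasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd

from .lifetable import ScenarioOutcome, ScreeningEffects

__all__ = [
    "CostSet",
    "EconParams",
    "utility_at",
    "discount_factor",
    "attach_economics",
    "icer",
    "nmb",
    "UndefinedICERError",
]

Param = Union[float, np.ndarray]

TREATMENTS = ("active_surveillance", "prostatectomy", "radiotherapy",
              "brachytherapy", "chemotherapy", "adt")


class UndefinedICERError(ZeroDivisionError):
    """Raised when an ICER is requested with a zero QALY difference."""


@dataclass
class CostSet:
    """Unit costs in 2016 GBP."""

    psa_test: Param = 11.0
    genotyping: Param = 25.0
    biopsy: Param = 388.0
    declined_biopsy: Param = 105.0
    staging: Param = 770.0
    active_surveillance: Param = 4341.0
    prostatectomy: Param = 8173.0
    radiotherapy: Param = 5385.0
    brachytherapy: Param = 1527.0
    chemotherapy: Param = 7426.0
    adt: Param = 559.0
    palliation: Param = 6837.0

    def treatment_cost(self, mix: dict) -> Param:
        """Expected treatment cost under a {treatment: share} mix."""
        total_share = sum(mix.values())
        if abs(total_share - 1.0) > 1e-9:
            raise ValueError(f"treatment mix shares sum to {total_share}, expected 1")
        out = 0.0
        for tx, share in mix.items():
            if tx not in TREATMENTS:
                raise ValueError(f"unknown treatment {tx!r}")
            out = out + share * getattr(self, tx)
        return out


def _default_mix() -> dict:
    # synthetic stand-in for the national audit treatment shares
    return {
        "early": {"active_surveillance": 0.35, "prostatectomy": 0.30,
                  "radiotherapy": 0.25, "brachytherapy": 0.10},
        "advanced": {"radiotherapy": 0.35, "adt": 0.40, "chemotherapy": 0.25},
    }


@dataclass
class EconParams:
    """Utility, cost and decision-rule parameters.

    ``treatment_mix`` maps stage ('early'/'advanced') to {treatment: share},
    each stage summing to 1.  ``advanced_fraction_clinical`` is the advanced
    (stage III/IV) share among clinically detected cancers; screen-detected
    cancers have it multiplied by the stage-shift relative risk.
    ``biopsy_positivity`` is the per-screen probability of a PSA at or above
    the cutoff (synthetic flat default — the study's per-age values are not
    public).  ``biopsy_compliance`` below 1 activates the declined-biopsy
    cost path used in adherence sensitivity analyses.
    """

    base_utility: Param = 0.8639
    utility_decline: Param = 0.0048
    utility_anchor_age: float = 55.0
    pc_utility_multiplier: Param = 0.93
    discount_rate: float = 0.035
    wtp: tuple = (20_000.0, 30_000.0)
    costs: CostSet = field(default_factory=CostSet)
    treatment_mix: dict = field(default_factory=_default_mix)
    advanced_fraction_clinical: float = 0.25
    biopsy_positivity: float = 0.12
    biopsy_compliance: float = 1.0

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be >= 0")
        for stage in ("early", "advanced"):
            if stage not in self.treatment_mix:
                raise ValueError(f"treatment_mix is missing the {stage!r} stage")
            total = sum(self.treatment_mix[stage].values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"treatment_mix[{stage!r}] shares sum to {total}, expected 1"
                )


def utility_at(params: EconParams, age, pc_diagnosed: bool = False):
    """Health-state utility at an attained age.

    ``max(0, base - decline * (age - anchor))``, times the prostate-cancer
    multiplier within ten years of a diagnosis.
    """
    u = np.maximum(
        0.0, params.base_utility - params.utility_decline
        * (np.asarray(age, float) - params.utility_anchor_age)
    )
    if pc_diagnosed:
        u = u * params.pc_utility_multiplier
    return u if np.ndim(u) else float(u)


def discount_factor(params: EconParams, years_since_entry):
    """``(1 + rate)^(-t)``; 1 at entry."""
    t = np.asarray(years_since_entry, float)
    if np.any(t < 0):
        raise ValueError("years_since_entry must be >= 0")
    out = (1.0 + params.discount_rate) ** (-t)
    return out if np.ndim(out) else float(out)


def attach_economics(outcome: ScenarioOutcome, params: EconParams,
                     effects: ScreeningEffects) -> ScenarioOutcome:
    """Attach discounted QALY and cost streams to a life-table outcome.

    Adds per-age trajectories ``qalys_disc``, ``qalys_undisc``,
    ``costs_disc`` and ``costs_undisc`` (mutating ``outcome`` in place).
    Discounting uses t = attained age - entry age, so the first cycle is
    undiscounted.

    Cost components per age: PSA tests, one-off genotyping, the biopsy
    cascade (every screen positive is biopsied at baseline; positives
    declining biopsy incur a urology appointment instead when compliance
    is below 1), staging plus a stage-mix treatment cost per diagnosed
    case (stage distribution shifted by ``rr_advanced`` for
    screen-detected cases, overdiagnosed included), and palliation in the
    year of each prostate-cancer death.
    """
    ages = outcome.ages
    entry = outcome.entry_age
    if entry is None:
        raise ValueError("economics requires a single-entry-age outcome "
                         "(attach before summing sub-cohorts)")
    traj = outcome.traj
    c = params.costs

    cost_early = c.staging + c.treatment_cost(params.treatment_mix["early"])
    cost_adv = c.staging + c.treatment_cost(params.treatment_mix["advanced"])
    adv_clin = params.advanced_fraction_clinical
    adv_sd = np.clip(effects.rr_advanced * adv_clin, 0.0, 1.0)
    case_cost_clin = (1.0 - adv_clin) * cost_early + adv_clin * cost_adv
    case_cost_sd = (1.0 - adv_sd) * cost_early + adv_sd * cost_adv

    batch = np.shape(traj["cases"][0])
    qal_u = np.zeros((len(ages),) + batch)
    cost_u = np.zeros((len(ages),) + batch)
    df = np.zeros(len(ages))

    for i, a in enumerate(ages):
        df[i] = discount_factor(params, a - entry)

        alive = traj["alive_start"][i]
        recent = traj["py_recent_dx"][i]
        u = utility_at(params, a)
        qal_u[i] = u * (alive - recent) + u * params.pc_utility_multiplier * recent

        screens = traj["screens"][i]
        positives = screens * params.biopsy_positivity
        biopsies = positives * params.biopsy_compliance
        declined = positives * (1.0 - params.biopsy_compliance)
        cost_u[i] = (
            screens * c.psa_test
            + traj["genotyped"][i] * c.genotyping
            + biopsies * c.biopsy
            + declined * c.declined_biopsy
            + traj["screen_detected"][i] * case_cost_sd
            + traj["clinical_cases"][i] * case_cost_clin
            + traj["pc_deaths"][i] * c.palliation
        )

    shape_df = df.reshape((len(ages),) + (1,) * len(batch))
    traj["qalys_undisc"] = qal_u
    traj["qalys_disc"] = qal_u * shape_df
    traj["costs_undisc"] = cost_u
    traj["costs_disc"] = cost_u * shape_df
    return outcome


def icer(delta_cost, delta_qaly):
    """Incremental cost-effectiveness ratio: ``delta_cost / delta_qaly``.

    The caller labels dominance when the signs differ.  Raises
    :class:`UndefinedICERError` on a zero QALY difference.
    """
    if np.ndim(delta_qaly) == 0:
        if delta_qaly == 0:
            raise UndefinedICERError("ICER undefined: QALY difference is zero")
        return float(delta_cost) / float(delta_qaly)
    dq = np.asarray(delta_qaly, float)
    if np.any(dq == 0):
        raise UndefinedICERError("ICER undefined: QALY difference is zero")
    return np.asarray(delta_cost, float) / dq


def nmb(qalys, cost, wtp):
    """Net monetary benefit: ``qalys * wtp - cost``."""
    if np.any(np.asarray(wtp) < 0):
        raise ValueError("willingness-to-pay must be >= 0")
    return qalys * wtp - cost


def comparison_table(outcomes: dict, reference: str,
                     schedules_pct_screened: dict = None) -> pd.DataFrame:
    """Strategy-grid summary in the style of a screening comparison table.

    One row per strategy: cases, overdiagnoses, prostate-cancer deaths,
    QALYs and costs (discounted), differences against the reference
    (no-screening) strategy, the ICER versus the reference, and — when
    supplied — the cumulative percentage of the cohort ever screened.
    """
    if reference not in outcomes:
        raise ValueError(f"reference strategy {reference!r} missing from the grid")
    ref = outcomes[reference]
    rows = []
    for label, out in outcomes.items():
        d_qaly = out.qalys - ref.qalys
        d_cost = out.costs - ref.costs
        row = {
            "strategy": label,
            "cases": out.cases,
            "cases_vs_ref": out.cases - ref.cases,
            "overdiagnosed": out.overdiagnosed,
            "pc_deaths": out.pc_deaths,
            "deaths_vs_ref": out.pc_deaths - ref.pc_deaths,
            "life_years": out.life_years,
            "qalys": out.qalys,
            "qalys_vs_ref": d_qaly,
            "costs": out.costs,
            "costs_vs_ref": d_cost,
        }
        if label == reference or np.ndim(d_qaly) > 0:
            row["icer_vs_ref"] = np.nan
        else:
            try:
                row["icer_vs_ref"] = icer(d_cost, d_qaly)
            except UndefinedICERError:
                row["icer_vs_ref"] = np.nan
        if schedules_pct_screened is not None:
            row["cumulative_pct_screened"] = schedules_pct_screened.get(label, np.nan)
        rows.append(row)
    return pd.DataFrame(rows).set_index("strategy")
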