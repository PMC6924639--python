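"""Top-level modelling objects.

:class:`ScreeningCEA` bundles the inputs of the screening
cost-effectiveness analysis — a rate table, the polygenic risk model, the
screening effect sizes, the economic parameters, and a grid of screening
strategies — in the style of a statsmodels model object.  ``fit()``
evaluates the model: deterministically at the point estimates, or
probabilistically (``method='psa'``) by propagating parameter uncertainty
through repeated draws.  Both return a results object with the estimates,
their uncertainty, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .economics import EconParams, attach_economics, comparison_table
from .lifetable import RateTable, ScenarioOutcome, ScreeningEffects, run_cohort
from .riskdist import RiskModel
from .strategies import Strategy, build_schedule

__all__ = ["ScreeningCEA", "ScreeningCEAResults", "run_scenario", "default_strategy_grid"]


def run_scenario(rates: RateTable, strategy: Strategy, risk_model: RiskModel,
                 effects: ScreeningEffects, econ: EconParams,
                 entry_ages: Optional[Sequence[int]] = None) -> ScenarioOutcome:
    """Run one strategy for the full multi-age cohort.

    The mixed-age cohort is decomposed into single-age sub-cohorts (entry
    ages taken from the rate table's population weights), each run to age
    90, costed and discounted from its own entry, then summed.  Returns the
    aggregated :class:`ScenarioOutcome`; per-draw batches broadcast through
    untouched.
    """
    if entry_ages is None:
        entry_ages = rates.entry_ages
    outs = []
    pct_num = 0.0
    total_w = 0.0
    for e in entry_ages:
        w = float(rates.population_weight(e))
        if w <= 0:
            continue
        sched = build_schedule(strategy, rates, risk_model, entry_age=int(e))
        out = run_cohort(rates, sched, effects, int(e), cohort_size=w)
        attach_economics(out, econ, effects)
        outs.append(out)
        pct_num += w * sched.final_attender_fraction
        total_w += w
    if not outs:
        raise ValueError("rate table defines no entry ages with positive weight")
    agg = ScenarioOutcome.sum(outs)
    agg.pct_screened = 100.0 * pct_num / total_w
    return agg


def default_strategy_grid(thresholds: Optional[Sequence[float]] = None,
                          **kwargs) -> list:
    """No screening, age-based, and precision at 2-10% (step 0.5%)."""
    if thresholds is None:
        thresholds = np.round(np.arange(0.02, 0.1001, 0.005), 4)
    grid = [Strategy(kind="none"), Strategy(kind="age_based", **kwargs)]
    grid += [Strategy(kind="precision", threshold=float(t), **kwargs) for t in thresholds]
    return grid


class ScreeningCEA:
    """Polygenic risk-tailored screening benefit-harm / CEA model.

    Parameters
    ----------
    rates : RateTable
        Age-specific prostate-cancer incidence, prostate-cancer mortality
        and other-cause mortality, with entry-population weights.
    strategies : sequence of Strategy, optional
        Strategy grid; defaults to no screening, age-based, and precision
        screening at 10-year risk thresholds 2-10% in 0.5% steps.
    risk_model, effects, econ : optional
        Component parameter sets; defaults are the published point values.
    """

    def __init__(self, rates: RateTable, strategies: Optional[Sequence[Strategy]] = None,
                 risk_model: Optional[RiskModel] = None,
                 effects: Optional[ScreeningEffects] = None,
                 econ: Optional[EconParams] = None,
                 reference: str = "no screening"):
        self.rates = rates
        self.strategies = list(strategies) if strategies is not None else default_strategy_grid()
        labels = [s.label for s in self.strategies]
        if len(set(labels)) != len(labels):
            raise ValueError("strategy labels must be unique")
        self.risk_model = risk_model or RiskModel()
        self.effects = effects or ScreeningEffects()
        self.econ = econ or EconParams()
        self.reference = reference
        if reference not in labels:
            raise ValueError(
                f"the strategy grid must include the reference strategy {reference!r}"
            )

    @classmethod
    def from_synthetic(cls, seed: int = 1, **kwargs) -> "ScreeningCEA":
        """Build the model on a synthetic, anchor-calibrated rate table."""
        from .synthdata import SynthConfig, generate_rates
        return cls(generate_rates(SynthConfig(seed=seed)), **kwargs)

    def fit(self, method: str = "deterministic", draws: int = 10_000,
            seed: int = 42, wtp_grid: Optional[np.ndarray] = None):
        """Evaluate the model.

        ``method='deterministic'`` runs every strategy at the point
        estimates and returns :class:`ScreeningCEAResults`;
        ``method='psa'`` propagates ``draws`` parameter draws (common
        random numbers across strategies) and returns
        :class:`polyscreen.psa.PSAResults`.
        """
        if method == "deterministic":
            outcomes = {
                s.label: run_scenario(self.rates, s, self.risk_model, self.effects, self.econ)
                for s in self.strategies
            }
            return ScreeningCEAResults(self, outcomes)
        if method == "psa":
            from .psa import run_psa
            return run_psa(self.strategies, self.rates, self.risk_model, self.econ,
                           self.effects, n=draws, seed=seed, reference=self.reference,
                           wtp_grid=wtp_grid)
        raise ValueError(f"unknown method {method!r}")


class ScreeningCEAResults:
    """Deterministic evaluation of a strategy grid.

    ``table`` holds one row per strategy (cases, overdiagnoses, deaths,
    QALYs, costs, ICER versus the reference, cumulative % screened);
    ``outcomes`` maps labels to full per-age :class:`ScenarioOutcome`
    trajectories.
    """

    def __init__(self, model: ScreeningCEA, outcomes: dict):
        self.model = model
        self.outcomes = outcomes
        pct = {lab: getattr(o, "pct_screened", np.nan) for lab, o in outcomes.items()}
        self.table = comparison_table(outcomes, model.reference, pct)

    @property
    def reference(self) -> str:
        return self.model.reference

    def benefit_harm(self) -> pd.DataFrame:
        """Overdiagnoses per prostate-cancer death averted vs the reference."""
        t = self.table
        averted = -t["deaths_vs_ref"]
        ratio = np.where(averted > 0, t["overdiagnosed"] / np.where(averted > 0, averted, np.nan), np.nan)
        return pd.DataFrame({"deaths_averted": averted,
                             "overdiagnosed": t["overdiagnosed"],
                             "overdiagnoses_per_death_averted": ratio},
                            index=t.index)

    def nmb_ranking(self, wtp: float) -> pd.Series:
        """Strategies ranked by net monetary benefit at one WTP threshold."""
        from .economics import nmb
        t = self.table
        vals = nmb(t["qalys_vs_ref"], t["costs_vs_ref"], wtp)
        return vals.sort_values(ascending=False)

    def summary(self, float_format: str = "{:,.0f}") -> str:
        cols = ["cases", "overdiagnosed", "pc_deaths", "qalys_vs_ref",
                "costs_vs_ref", "icer_vs_ref", "cumulative_pct_screened"]
        t = self.table[cols].rename(columns={
            "qalys_vs_ref": "dQALYs", "costs_vs_ref": "dCost",
            "icer_vs_ref": "ICER", "cumulative_pct_screened": "%screened"})
        body = t.to_string(float_format=lambda v: float_format.format(v)
                           if np.isfinite(v) else "-")
        head = (
            "Polygenic risk-tailored screening: deterministic evaluation\n"
            f"Cohort: {self.model.rates.cohort_size:,.0f} men, entry ages "
            f"{self.model.rates.entry_ages.min()}-{self.model.rates.entry_ages.max()}, "
            f"follow-up to 90\nReference: {self.reference}; discount rate "
            f"{self.model.econ.discount_rate:.1%}/yr\n"
        )
        return head + "\n" + body
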