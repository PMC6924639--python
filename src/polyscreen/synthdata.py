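"""Synthetic rate tables, population weights and treatment mixes.

The real study inputs — English registry incidence and mortality processed
through DevCan, national treatment shares, per-age biopsy positivity — are
not redistributable, so this module generates tables with the same
statistical structure, letting the whole pipeline run self-contained:

* other-cause mortality follows a Gompertz curve (exponential rise with
  age, the standard adult all-cause mortality shape);
* prostate-cancer incidence rises along a logistic curve to a plateau in
  the mid-70s;
* prostate-cancer mortality is a lagged fraction of the incidence hazard;
* entry-population weights decline gently across ages 55-69 and sum to
  the cohort size (4.48 million by default).

The incidence plateau is calibrated by 1-D root finding so the background
10-year absolute risk at age 55 hits the published 2.6% anchor; the 69-year
anchor (7.1%) is then *checked*, not fitted — if the shape parameters put
it outside the accepted band, generation fails loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .lifetable import RateTable, ten_year_absolute_risk

__all__ = ["SynthConfig", "CalibrationError", "generate_rates", "generate_treatment_mix"]


class CalibrationError(RuntimeError):
    """Synthetic rate calibration failed to reproduce an anchor."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic rate generator.

    ``gompertz_level`` is the other-cause mortality at ``age_min``;
    ``gompertz_slope`` its log-slope per year (default doubles roughly
    every 8 years, a realistic adult schedule).  ``inc_midpoint`` /
    ``inc_scale`` / ``inc_plateau`` parameterise the logistic incidence
    curve; a ``None`` plateau triggers calibration against
    ``anchor_risk_55``.  Prostate-cancer mortality is
    ``pc_mort_fraction`` times the incidence hazard ``pc_mort_lag`` years
    earlier.
    """

    seed: int = 1
    age_min: int = 45
    age_max: int = 90
    gompertz_level: float = 0.002
    gompertz_slope: float = 0.0866
    inc_midpoint: float = 66.5
    inc_scale: float = 6.0
    inc_plateau: float = None
    pc_mort_fraction: float = 0.35
    pc_mort_lag: int = 5
    cohort_size: float = 4_480_000.0
    entry_age_min: int = 55
    entry_age_max: int = 69
    weight_decline: float = 0.01
    anchor_risk_55: float = 0.026
    check_risk_69: tuple = (0.066, 0.076)


def _build_table(config: SynthConfig, plateau: float) -> RateTable:
    ages = np.arange(config.age_min, config.age_max + 1)
    other = np.clip(
        config.gompertz_level * np.exp(config.gompertz_slope * (ages - config.age_min)),
        0.0, 0.999,
    )
    inc = plateau / (1.0 + np.exp(-(ages - config.inc_midpoint) / config.inc_scale))
    lagged = plateau / (1.0 + np.exp(
        -(ages - config.pc_mort_lag - config.inc_midpoint) / config.inc_scale))
    pcm = config.pc_mort_fraction * lagged

    weights = np.zeros_like(ages, dtype=float)
    mask = (ages >= config.entry_age_min) & (ages <= config.entry_age_max)
    raw = np.exp(-config.weight_decline * (ages[mask] - config.entry_age_min))
    weights[mask] = raw / raw.sum() * config.cohort_size

    return RateTable(pd.DataFrame({
        "age": ages,
        "pc_incidence": np.clip(inc, 0.0, 0.999),
        "pc_mortality": np.clip(pcm, 0.0, 0.999),
        "other_mortality": other,
        "population_weight": weights,
    }))


def generate_rates(config: SynthConfig = None) -> RateTable:
    """Generate a synthetic rate table, calibrated to the risk anchors.

    Deterministic for a given configuration.  With the plateau left free
    (the default), bisection fixes it so the background 10-year absolute
    risk at 55 equals ``anchor_risk_55``; the implied risk at 69 must then
    fall inside ``check_risk_69`` or :class:`CalibrationError` is raised.
    """
    config = config or SynthConfig()
    if config.inc_plateau is not None:
        return _build_table(config, config.inc_plateau)

    def gap(plateau: float) -> float:
        table = _build_table(config, plateau)
        return ten_year_absolute_risk(table, 55) - config.anchor_risk_55

    try:
        plateau = brentq(gap, 1e-8, 0.5, xtol=1e-12)
    except ValueError as exc:
        raise CalibrationError(
            f"cannot calibrate incidence plateau to the age-55 anchor "
            f"({config.anchor_risk_55:.3%} 10-year risk): {exc}"
        ) from exc

    table = _build_table(config, plateau)
    r69 = ten_year_absolute_risk(table, 69)
    lo, hi = config.check_risk_69
    if not lo <= r69 <= hi:
        raise CalibrationError(
            f"age-69 anchor violated: 10-year risk {r69:.4f} outside [{lo}, {hi}] "
            f"after calibrating the age-55 anchor"
        )
    return table


_BASE_MIX = {
    "early": {"active_surveillance": 0.35, "prostatectomy": 0.30,
              "radiotherapy": 0.25, "brachytherapy": 0.10,
              "chemotherapy": 0.0, "adt": 0.0},
    "advanced": {"active_surveillance": 0.0, "prostatectomy": 0.0,
                 "radiotherapy": 0.35, "brachytherapy": 0.0,
                 "chemotherapy": 0.25, "adt": 0.40},
}


def generate_treatment_mix(config: SynthConfig = None, jitter: float = 0.0) -> pd.DataFrame:
    """Stage-by-treatment share table (rows sum to 1).

    Early-stage mass sits on conservative and curative local options;
    advanced-stage mass on systemic therapy.  ``jitter`` > 0 draws
    Dirichlet-perturbed shares (seeded, zero shares stay zero) for
    robustness exercises.
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    rows = {}
    for stage, mix in _BASE_MIX.items():
        shares = np.array([mix[t] for t in sorted(mix)])
        if jitter > 0:
            nz = shares > 0
            conc = shares[nz] / jitter
            shares[nz] = rng.dirichlet(conc)
        rows[stage] = dict(zip(sorted(mix), shares / shares.sum()))
    return pd.DataFrame(rows).T


def zero_hazard_config(**kwargs) -> SynthConfig:
    """A configuration whose generated table has all rates equal to zero."""
    return replace(SynthConfig(gompertz_level=0.0, inc_plateau=0.0,
                               pc_mort_fraction=0.0), **kwargs)
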