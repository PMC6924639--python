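"""Polygenic relative-risk distribution calculus.

The population distribution of prostate-cancer relative risk implied by
common susceptibility variants is modelled as log-normal: ``log r`` is
Normal(mu, variance) with ``mu = -variance/2`` so that the population mean
relative risk is exactly 1.  Everything downstream follows in closed form:

* the risk distribution *among cases* is the size-biased version of the
  population distribution, i.e. Normal(mu + variance, variance) on the log
  scale;
* an individual's 10-year absolute risk is ``baseline * r``, so the
  fraction of the population above an absolute-risk threshold ``t`` is the
  upper tail of the population distribution above ``log(t / baseline)``;
* the mean relative risk in the screened (above-threshold) and unscreened
  strata follow from the case-mass split, and conserve total incidence:
  ``f * rr_screened + (1 - f) * rr_unscreened = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.stats import norm

__all__ = [
    "RiskModel",
    "StratumRisks",
    "percentile_rr",
    "fraction_cases_above_percentile",
    "eligible_fraction",
    "stratum_relative_risks",
]

DEFAULT_VARIANCE = 0.68


@dataclass(frozen=True)
class RiskModel:
    """Log-normal polygenic relative-risk distribution.

    Parameters
    ----------
    variance : float
        Variance of log relative risk (default 0.68, the value implied by
        the known prostate-cancer susceptibility variants).

    The location ``mu`` is not free: it is fixed at ``-variance/2`` so the
    population mean relative risk equals 1, which makes total incidence
    conservation across risk strata automatic.
    """

    variance: float = DEFAULT_VARIANCE
    mu: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValueError(f"variance must be > 0, got {self.variance}")
        object.__setattr__(self, "mu", -self.variance / 2.0)

    @property
    def sigma(self) -> float:
        return float(np.sqrt(self.variance))

    def mean_rr(self) -> float:
        """Population mean relative risk, exp(mu + variance/2) == 1."""
        return float(np.exp(self.mu + self.variance / 2.0))

    def to_dict(self) -> dict:
        return {"variance": self.variance}

    @classmethod
    def from_dict(cls, d: dict) -> "RiskModel":
        return cls(variance=float(d.get("variance", DEFAULT_VARIANCE)))


class StratumRisks(NamedTuple):
    rr_screened: float
    rr_unscreened: float
    eligible_fraction: float


def percentile_rr(model: RiskModel, p):
    """Relative risk at population percentile ``p`` of the risk distribution.

    ``exp(mu + z_p * sigma)`` with ``z_p`` the standard-normal quantile.
    Strictly increasing in ``p``.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("percentile p must lie strictly inside (0, 1)")
    out = np.exp(model.mu + norm.ppf(p) * model.sigma)
    return float(out) if out.ndim == 0 else out


def fraction_cases_above_percentile(model: RiskModel, q):
    """Fraction of all cases arising above the population percentile ``q``.

    Uses the size-biased (case) distribution of log relative risk,
    Normal(mu + variance, variance): the case mass above the population
    ``q``-quantile is ``Phi(sigma - z_q)``.  Always at least ``1 - q``
    because cases are enriched at high risk.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0.0) or np.any(q >= 1.0):
        raise ValueError("population percentile q must lie strictly inside (0, 1)")
    out = norm.sf(norm.ppf(q) - model.sigma)
    return float(out) if out.ndim == 0 else out


def _log_rr_cut(baseline_risk, threshold) -> np.ndarray:
    baseline_risk = np.asarray(baseline_risk, dtype=float)
    threshold = np.asarray(threshold, dtype=float)
    if np.any(baseline_risk <= 0.0) or np.any(baseline_risk >= 1.0):
        raise ValueError("baseline_risk must lie strictly inside (0, 1)")
    if np.any(threshold <= 0.0) or np.any(threshold >= 1.0):
        raise ValueError("threshold must lie strictly inside (0, 1)")
    return np.log(threshold / baseline_risk)


def eligible_fraction(model: RiskModel, baseline_risk, threshold):
    """Population fraction whose absolute risk meets the screening threshold.

    Individual 10-year absolute risk is ``baseline_risk * r``; the eligible
    fraction is ``P(log r > log(threshold / baseline_risk))`` under the
    population distribution.  Monotone decreasing in the threshold and
    increasing in the baseline risk.
    """
    cut = _log_rr_cut(baseline_risk, threshold)
    out = norm.sf((cut - model.mu) / model.sigma)
    return float(out) if out.ndim == 0 else out


def fraction_cases_above_threshold(model: RiskModel, baseline_risk, threshold):
    """Fraction of all cases arising in the above-threshold stratum."""
    cut = _log_rr_cut(baseline_risk, threshold)
    out = norm.sf((cut - model.mu - model.variance) / model.sigma)
    return float(out) if out.ndim == 0 else out


def stratum_relative_risks(model: RiskModel, baseline_risk, threshold) -> StratumRisks:
    """Mean relative risk in the screened and unscreened strata.

    ``rr_screened`` is the case mass above the threshold divided by the
    population mass above it; ``rr_unscreened`` likewise below.  They satisfy
    the incidence conservation identity
    ``f * rr_screened + (1 - f) * rr_unscreened = 1``.

    Raises
    ------
    ValueError
        If the eligible fraction is numerically 0 or 1, in which case one
        stratum is empty and its relative risk is undefined.
    """
    f = eligible_fraction(model, baseline_risk, threshold)
    a = fraction_cases_above_threshold(model, baseline_risk, threshold)
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr <= 0.0) or np.any(f_arr >= 1.0):
        raise ValueError(
            "degenerate stratum: eligible fraction is numerically 0 or 1, "
            "so one stratum is empty and its relative risk is undefined"
        )
    rr_s = a / f
    rr_u = (1.0 - a) / (1.0 - f)
    if np.ndim(rr_s) == 0:
        return StratumRisks(float(rr_s), float(rr_u), float(f))
    return StratumRisks(rr_s, rr_u, f)
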