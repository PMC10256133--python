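"""Mixture uncertainty distribution for the treatment effect.

The design-stage uncertainty about the log hazard ratio is a two-component
normal mixture: with probability ``p_success`` the drug behaves like the
design alternative (narrow spread derived from historical data) and with
probability ``1 - p_success`` the effect is drawn from a wide "ineffective"
component whose variance is an inflated multiple of the historical variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "HistoricalCohort",
    "MixtureEffectPrior",
    "expected_events_weibull",
    "se_loghr_from_events",
    "inflate_variance",
    "success_rate",
    "alsfrs_to_hr",
    "sample_effect",
]


def expected_events_weibull(n: float, median: float, follow_up: float,
                            shape: float) -> float:
    """Expected number of events among ``n`` patients followed for
    ``follow_up`` months under Weibull survival with the given median.

    Uses the Weibull CDF with scale ``median / (ln 2)**(1/shape)``.
    """
    if min(n, median, follow_up, shape) <= 0:
        raise ValueError("all inputs must be positive")
    scale = median / math.log(2.0) ** (1.0 / shape)
    return n * (1.0 - math.exp(-((follow_up / scale) ** shape)))


def se_loghr_from_events(total_events: float) -> float:
    """Large-sample SE of the log hazard ratio from the pooled event count.

    1:1 allocation approximation ``2 / sqrt(d)``.
    """
    if total_events <= 0:
        raise ValueError("need a positive number of events")
    return 2.0 / math.sqrt(total_events)


def inflate_variance(se: float, factor: float) -> float:
    """SE after multiplying the variance by ``factor``."""
    if se <= 0 or factor <= 0:
        raise ValueError("se and factor must be positive")
    return se * math.sqrt(factor)


def success_rate(successes: int, trials: int) -> float:
    """Empirical probability of success among historical trials."""
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    return successes / trials


def alsfrs_to_hr(points: float, hazard_reduction_per_point: float = 0.119) -> float:
    """Hazard ratio implied by an ALSFRS-R point difference.

    Each point of functional benefit multiplies the hazard by
    ``1 - hazard_reduction_per_point``.
    """
    return (1.0 - hazard_reduction_per_point) ** points


@dataclass(frozen=True)
class HistoricalCohort:
    """Per-arm summaries of a historical two-arm cohort."""

    n_control: int
    n_treated: int
    median_control: float
    median_treated: float
    follow_up: float
    weibull_shape: float = 2.0

    def __post_init__(self):
        if min(self.n_control, self.n_treated, self.median_control,
               self.median_treated, self.follow_up, self.weibull_shape) <= 0:
            raise ValueError("all cohort fields must be positive")

    @property
    def expected_events(self) -> float:
        return (expected_events_weibull(self.n_control, self.median_control,
                                        self.follow_up, self.weibull_shape)
                + expected_events_weibull(self.n_treated, self.median_treated,
                                          self.follow_up, self.weibull_shape))

    @property
    def se_loghr(self) -> float:
        return se_loghr_from_events(self.expected_events)


@dataclass(frozen=True)
class MixtureEffectPrior:
    """Two-component mixture over the log hazard ratio.

    ``theta_futility`` defaults to ``theta_design``: both components are
    centered on the design effect and differ only in spread.  Set it to 0.0
    for a null-centered ineffective component.
    """

    p_success: float
    theta_design: float
    se_success: float
    se_futility: float
    theta_futility: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.p_success <= 1.0:
            raise ValueError("p_success must lie in [0, 1]")
        if self.se_success <= 0 or self.se_futility <= 0:
            raise ValueError("standard errors must be positive")
        if self.theta_futility is None:
            object.__setattr__(self, "theta_futility", self.theta_design)

    @classmethod
    def from_historical(cls, cohort: HistoricalCohort, design_hr: float,
                        p_success: float,
                        variance_inflation: float = 10.0,
                        null_centered_futility: bool = False,
                        ) -> "MixtureEffectPrior":
        """Derive both spreads from a historical cohort.

        The success component uses the cohort SE; the futility component
        inflates the cohort variance by ``variance_inflation``.
        """
        se = cohort.se_loghr
        return cls(
            p_success=p_success,
            theta_design=math.log(design_hr),
            se_success=se,
            se_futility=inflate_variance(se, variance_inflation),
            theta_futility=0.0 if null_centered_futility else None,
        )

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw ``(success, log_hr)`` pairs; vectorized when ``size`` given."""
        n = 1 if size is None else size
        success = rng.random(n) < self.p_success
        mean = np.where(success, self.theta_design, self.theta_futility)
        sd = np.where(success, self.se_success, self.se_futility)
        log_hr = rng.normal(mean, sd)
        if size is None:
            return bool(success[0]), float(log_hr[0])
        return success, log_hr

    def cdf(self, x) -> np.ndarray:
        """Analytic mixture CDF of the log hazard ratio."""
        x = np.asarray(x, dtype=float)
        return (self.p_success * norm.cdf(x, self.theta_design, self.se_success)
                + (1 - self.p_success)
                * norm.cdf(x, self.theta_futility, self.se_futility))

    @property
    def mean(self) -> float:
        return (self.p_success * self.theta_design
                + (1 - self.p_success) * self.theta_futility)

    @property
    def variance(self) -> float:
        m = self.mean
        return (self.p_success * (self.se_success**2 + (self.theta_design - m) ** 2)
                + (1 - self.p_success)
                * (self.se_futility**2 + (self.theta_futility - m) ** 2))


def sample_effect(prior: MixtureEffectPrior,
                  rng: np.random.Generator) -> tuple[bool, float]:
    """Single draw from the mixture: (success flag, log hazard ratio)."""
    return prior.sample(rng)
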