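"""Event-driven two-arm survival trial simulation.

Patients enter uniformly over the accrual window, event times are Weibull
with proportional hazards injected through the scale parameter
(``S_treated = S_control**HR``), and there is no loss to follow-up.
Analyses happen at the exact calendar time a target event count is reached;
the monitored statistic is the (signed) log-rank z with z > 0 favoring the
treated arm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize
from scipy.stats import norm

from .designs import GroupSequentialDesign, required_events

__all__ = [
    "TrialAssumptions",
    "SimulatedTrial",
    "ZTrajectory",
    "InformationCapError",
    "simulate_trial",
    "calendar_time_of_event",
    "logrank_z",
    "run_looks",
]


class InformationCapError(RuntimeError):
    """The requested event count can never be observed."""


def weibull_scale(median: float, shape: float) -> float:
    """Scale parameter of a Weibull with the given median survival."""
    return median / math.log(2.0) ** (1.0 / shape)


@dataclass(frozen=True)
class TrialAssumptions:
    """Planning inputs of an event-driven survival trial."""

    n_total: int
    accrual_duration: float          # months, constant enrollment rate
    median_control: float            # months
    design_hr: float
    allocation_ratio: float = 1.0    # treated : control
    weibull_shape: float = 2.0
    alpha_total: float = 0.025       # one-sided
    beta_total: float = 0.10
    max_events: int | None = None

    def __post_init__(self):
        if min(self.n_total, self.accrual_duration, self.median_control,
               self.design_hr, self.allocation_ratio, self.weibull_shape) <= 0:
            raise ValueError("all assumptions must be positive")

    @property
    def n_treated(self) -> int:
        r = self.allocation_ratio
        return int(round(self.n_total * r / (1.0 + r)))

    @property
    def n_control(self) -> int:
        return self.n_total - self.n_treated

    @property
    def scale_control(self) -> float:
        return weibull_scale(self.median_control, self.weibull_shape)

    def scale_treated(self, hr: float | None = None) -> float:
        hr = self.design_hr if hr is None else hr
        return self.scale_control * hr ** (-1.0 / self.weibull_shape)

    @property
    def fixed_events(self) -> int:
        """Schoenfeld fixed-design event count for the design HR."""
        return required_events(self.design_hr, self.alpha_total,
                               self.beta_total, self.allocation_ratio)

    def drift_at(self, events: float, hr: float | None = None) -> float:
        """Expected z at the given event count under ``hr`` (design HR default)."""
        hr = self.design_hr if hr is None else hr
        r = self.allocation_ratio
        return -math.log(hr) * math.sqrt(events * r) / (1.0 + r)

    # -- deterministic event-accumulation curve ---------------------------
    def expected_events(self, calendar_time: float,
                        hr: float | None = None) -> float:
        """Expected total events by ``calendar_time`` under constant accrual."""
        if calendar_time <= 0:
            return 0.0
        hr = self.design_hr if hr is None else hr
        rho, a = self.weibull_shape, self.accrual_duration
        nodes, weights = np.polynomial.legendre.leggauss(64)
        upper = min(a, calendar_time)
        e = 0.5 * upper * (nodes + 1.0)       # entry times
        w = 0.5 * upper * weights
        total = 0.0
        for n_arm, scale in ((self.n_control, self.scale_control),
                             (self.n_treated, self.scale_treated(hr))):
            cdf = 1.0 - np.exp(-(((calendar_time - e) / scale) ** rho))
            total += n_arm * float(np.sum(w * cdf)) / a
        return total

    def time_to_events(self, events: float, hr: float | None = None) -> float:
        """Calendar time at which the expected event count reaches ``events``."""
        if events >= self.n_total:
            return math.inf
        hi = self.accrual_duration + 2 * self.median_control
        while self.expected_events(hi, hr) < events:
            hi *= 2.0
            if hi > 1e7:  # pragma: no cover
                return math.inf
        return optimize.brentq(
            lambda t: self.expected_events(t, hr) - events, 1e-9, hi,
            xtol=1e-6)


@dataclass
class SimulatedTrial:
    """Per-patient records of one simulated trial."""

    entry: np.ndarray   # calendar entry times (months)
    arm: np.ndarray     # 0 = control, 1 = treated
    time: np.ndarray    # event time since entry (months); no dropout

    def __post_init__(self):
        self._entry_sorted = np.sort(self.entry)
        self._calendar_sorted = np.sort(self.calendar)

    @property
    def n(self) -> int:
        return self.entry.size

    @property
    def calendar(self) -> np.ndarray:
        return self.entry + self.time

    def to_dataframe(self, censor_at: float | None = None) -> pd.DataFrame:
        df = pd.DataFrame({
            "patient_id": np.arange(1, self.n + 1),
            "arm": np.where(self.arm == 1, "treated", "control"),
            "entry_time": self.entry,
            "time_to_event": self.time,
        })
        if censor_at is None:
            df["event_flag"] = 1
            df["censor_time"] = np.nan
        else:
            follow = censor_at - self.entry
            df["event_flag"] = (self.time <= follow).astype(int)
            df["censor_time"] = np.where(df["event_flag"] == 1, np.nan, follow)
            df = df[follow > 0].reset_index(drop=True)
        return df

    # -- operating-characteristic helpers at a stop time ------------------
    def n_enrolled(self, calendar_time: float) -> int:
        return int(np.searchsorted(self._entry_sorted, calendar_time,
                                   side="right"))

    def exposure(self, calendar_time: float) -> float:
        """Cumulative time-on-study (patient-months) at ``calendar_time``."""
        follow = np.minimum(self.time, calendar_time - self.entry)
        return float(follow[follow > 0].sum())


@dataclass
class ZTrajectory:
    """Per-look monitored statistics of one trial under one schedule."""

    information_fractions: np.ndarray
    events: np.ndarray
    calendar_times: np.ndarray
    z: np.ndarray
    log_hr: np.ndarray
    capped: np.ndarray = field(default=None)  # looks beyond reachable events

    def __post_init__(self):
        if self.capped is None:
            self.capped = np.zeros(len(self.events), dtype=bool)

    @property
    def n_looks(self) -> int:
        return len(self.events)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "look": np.arange(1, self.n_looks + 1),
            "information_fraction": self.information_fractions,
            "events": self.events,
            "calendar_time": self.calendar_times,
            "z": self.z,
            "log_hr": self.log_hr,
            "capped": self.capped,
        })


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def simulate_trial(assumptions: TrialAssumptions, log_hr: float,
                   rng: np.random.Generator) -> SimulatedTrial:
    """Simulate one trial under a true log hazard ratio."""
    n = assumptions.n_total
    n_t = assumptions.n_treated
    arm = np.zeros(n, dtype=np.int8)
    arm[rng.permutation(n)[:n_t]] = 1
    entry = rng.uniform(0.0, assumptions.accrual_duration, n)
    rho = assumptions.weibull_shape
    scale = np.where(arm == 1,
                     assumptions.scale_treated(math.exp(log_hr)),
                     assumptions.scale_control)
    time = scale * rng.exponential(1.0, n) ** (1.0 / rho)
    return SimulatedTrial(entry=entry, arm=arm, time=time)


def calendar_time_of_event(trial: SimulatedTrial, k: int) -> float:
    """Calendar time at which the k-th event occurs."""
    if not 1 <= k <= trial.n:
        raise InformationCapError(
            f"event rank {k} unreachable with {trial.n} patients")
    return float(trial._calendar_sorted[k - 1])


def logrank_z(trial: SimulatedTrial,
              at_calendar_time: float) -> tuple[float, int, float]:
    """Signed log-rank statistic on data censored at a calendar time.

    Returns ``(z, events, log_hr_estimate)`` where the estimate is the
    score-based (Peto) approximation ``(O - E) / V`` on the treated arm.
    z > 0 indicates a hazard reduction in the treated arm.
    """
    follow = at_calendar_time - trial.entry
    inc = follow > 0
    if not inc.any():
        raise ValueError("no patients under observation at this time")
    obs = np.minimum(trial.time[inc], follow[inc])
    event = trial.time[inc] <= follow[inc]
    grp = trial.arm[inc]
    if not event.any():
        raise ValueError("no events observed at this time")

    order = np.argsort(obs, kind="stable")
    obs, event, grp = obs[order], event[order], grp[order]
    n_at = obs.size

    ev_times = obs[event]
    ev_grp = grp[event]
    uniq, start = np.unique(ev_times, return_index=True)
    d = np.diff(np.append(start, ev_times.size))            # deaths per time
    d1 = np.add.reduceat(ev_grp, start)                     # treated deaths
    # risk sets: patients with obs >= u
    n_risk = n_at - np.searchsorted(obs, uniq, side="left")
    cum_treated = np.concatenate(([0], np.cumsum(grp)))
    n1_risk = cum_treated[n_at] - cum_treated[
        np.searchsorted(obs, uniq, side="left")]

    frac = n1_risk / n_risk
    o_minus_e = float(np.sum(d1 - d * frac))
    with np.errstate(invalid="ignore", divide="ignore"):
        v_terms = d * frac * (1.0 - frac) * (n_risk - d) / (n_risk - 1.0)
    v = float(np.nansum(np.where(n_risk > 1, v_terms, 0.0)))
    if v <= 0:
        raise ValueError("log-rank variance is zero (no mixed risk sets)")
    z = -o_minus_e / math.sqrt(v)
    log_hr_hat = o_minus_e / v
    return z, int(event.sum()), log_hr_hat


def run_looks(trial: SimulatedTrial, design: GroupSequentialDesign,
              max_events: int | None = None) -> ZTrajectory:
    """Monitored z-trajectory of a trial under a design's event targets.

    Looks whose event target exceeds the achievable event count are flagged
    as capped and evaluated at the exhaustion of all follow-up.
    """
    targets = design.event_targets(max_events)
    fracs = np.asarray(design.schedule.information_fractions)
    events = np.empty(len(targets), dtype=int)
    times = np.empty(len(targets))
    zs = np.empty(len(targets))
    lhr = np.empty(len(targets))
    capped = np.zeros(len(targets), dtype=bool)
    for i, k in enumerate(targets):
        if k > trial.n:
            capped[i] = True
            k = trial.n
        times[i] = calendar_time_of_event(trial, int(k))
        zs[i], events[i], lhr[i] = logrank_z(trial, times[i])
    return ZTrajectory(information_fractions=fracs, events=events,
                       calendar_times=times, z=zs, log_hr=lhr, capped=capped)
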