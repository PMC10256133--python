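"""Retrospective application of boundaries to observed per-look summaries.

Published interim summaries rarely report the monitored z-statistic
directly; this module reconstructs it from a hazard ratio and its 95%
confidence interval (Wald interval on the log scale), aligns the observed
looks to a design's planned schedule, and issues the stop/continue decision
the design would have made.  Conditional power uses the standard B-value
decomposition of the sequential score process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .designs import GroupSequentialDesign

__all__ = [
    "ObservedLook",
    "MonitorDecision",
    "z_from_hr_ci",
    "monitor",
    "conditional_power",
    "AlignmentError",
]

_Z95 = norm.ppf(0.975)


class AlignmentError(ValueError):
    """Observed looks could not be matched to the design schedule."""


@dataclass(frozen=True)
class ObservedLook:
    """One published interim summary: either (hr, lo, hi) or (z, events)."""

    hr: float | None = None
    lo: float | None = None
    hi: float | None = None
    z: float | None = None
    events: int | None = None
    calendar_time: float | None = None

    def __post_init__(self):
        if self.hr is not None:
            if self.lo is None or self.hi is None:
                raise ValueError("hazard ratio requires both CI bounds")
            if not 0 < self.lo < self.hr < self.hi:
                raise ValueError("require 0 < lo < hr < hi")
        elif self.z is None or self.events is None:
            raise ValueError("supply either (hr, lo, hi) or (z, events)")

    def resolve(self) -> tuple[float, float]:
        """(z, implied event count) regardless of input form."""
        if self.hr is not None:
            z, events = z_from_hr_ci(self.hr, self.lo, self.hi)
            return z, events
        return float(self.z), float(self.events)


@dataclass(frozen=True)
class MonitorDecision:
    """Outcome of applying a design's boundaries to observed looks."""

    stop_look: int | None               # 0-based index into observed looks
    reason: str                          # futility | superiority | continue-to-final
    design_look: int | None              # matched look in the design schedule
    z_at_decision: float | None
    futility_boundary: float | None
    efficacy_boundary: float | None

    @property
    def stopped(self) -> bool:
        return self.stop_look is not None


def z_from_hr_ci(hr: float, lo: float, hi: float) -> tuple[float, float]:
    """Reconstruct (z, implied event count) from an HR and its 95% CI.

    Assumes a Wald interval on the log-HR:  SE = log(hi/lo) / (2 * 1.96),
    z = -log(hr)/SE (positive favors treatment), implied events = 4/SE^2
    (1:1 allocation approximation).
    """
    if not 0 < lo <= hr <= hi or lo == hi:
        raise ValueError("require 0 < lo <= hr <= hi with lo < hi")
    se = math.log(hi / lo) / (2.0 * _Z95)
    z = -math.log(hr) / se
    return z, 4.0 / se**2


def hr_ci_from_z(z: float, events: float) -> tuple[float, float, float]:
    """Inverse of :func:`z_from_hr_ci` (round-trip helper)."""
    se = 2.0 / math.sqrt(events)
    hr = math.exp(-z * se)
    return hr, hr * math.exp(-_Z95 * se), hr * math.exp(_Z95 * se)


def _align(observed: list[ObservedLook], design: GroupSequentialDesign,
           align: str, tolerance: float) -> list[int]:
    fracs = np.asarray(design.schedule.information_fractions)
    if align == "index":
        if len(observed) > len(fracs):
            raise AlignmentError(
                f"{len(observed)} observed looks but design has {len(fracs)}")
        return list(range(len(observed)))
    if design.max_events is None:
        raise AlignmentError("nearest-fraction alignment needs max_events "
                             "on the design; use align='index' otherwise")
    idx = []
    report = []
    for i, look in enumerate(observed):
        _, events = look.resolve()
        frac = events / design.max_events
        j = int(np.argmin(np.abs(fracs - frac)))
        report.append((i, frac, fracs[j]))
        if abs(fracs[j] - frac) > tolerance:
            lines = "; ".join(
                f"observed look {a}: info {b:.3f} -> planned {c:.2f}"
                for a, b, c in report)
            raise AlignmentError(
                f"observed look {i} (information fraction {frac:.3f}) is "
                f"more than {tolerance} from any planned look [{lines}]")
        idx.append(j)
    if any(b <= a for a, b in zip(idx, idx[1:])):
        raise AlignmentError(f"observed looks map to non-increasing design "
                             f"looks {idx}")
    return idx


def monitor(trajectory: list[ObservedLook], design: GroupSequentialDesign,
            align: str = "index", tolerance: float = 0.05) -> MonitorDecision:
    """First boundary crossing along an observed trajectory.

    ``align='nearest'`` matches each observed look to the planned look with
    the closest information fraction (implied event count over the design's
    maximum); ``align='index'`` matches looks in order.  A futility
    crossing (z below the lower boundary) stops for futility; a superiority
    crossing (z above the upper boundary at an efficacy look) stops for
    superiority.
    """
    if not trajectory:
        raise ValueError("empty trajectory")
    if align not in ("index", "nearest"):
        raise ValueError("align must be 'index' or 'nearest'")
    mapping = _align(trajectory, design, align, tolerance)
    lower = design.futility_z
    upper = design.efficacy_z
    for i, (look, j) in enumerate(zip(trajectory, mapping)):
        z, _ = look.resolve()
        fut_b = lower[j] if np.isfinite(lower[j]) else None
        eff_b = upper[j] if np.isfinite(upper[j]) else None
        if eff_b is not None and z >= eff_b:
            return MonitorDecision(i, "superiority", j, z, fut_b, eff_b)
        if fut_b is not None and z <= fut_b:
            return MonitorDecision(i, "futility", j, z, fut_b, eff_b)
    return MonitorDecision(None, "continue-to-final", None, None, None, None)


def boundary_overlay(trajectory: list[ObservedLook],
                     design: GroupSequentialDesign,
                     align: str = "index",
                     tolerance: float = 0.05) -> pd.DataFrame:
    """Observed z-path next to the design boundaries (plot-ready table)."""
    mapping = _align(trajectory, design, align, tolerance)
    rows = []
    for i, (look, j) in enumerate(zip(trajectory, mapping)):
        z, events = look.resolve()
        rows.append({
            "observed_look": i + 1,
            "design_look": j + 1,
            "information_fraction": design.schedule.information_fractions[j],
            "implied_events": events,
            "z": z,
            "futility_z": design.futility_z[j],
            "efficacy_z": design.efficacy_z[j],
            "calendar_time": look.calendar_time,
        })
    return pd.DataFrame(rows)


def conditional_power(z_current: float, info_fraction: float,
                      assumed_hr: float, design: GroupSequentialDesign,
                      allocation_ratio: float = 1.0) -> float:
    """Probability of final-analysis significance given the current statistic.

    B-value decomposition: with B = z*sqrt(t), the remaining score increment
    is Gaussian with mean ``drift * (1 - t)`` and variance ``1 - t`` where
    ``drift = -log(hr) * sqrt(r * D) / (1 + r)`` is the expected z at the
    design's maximum event count D under ``assumed_hr``.
    """
    if not 0.0 < info_fraction < 1.0:
        raise ValueError("information fraction must lie strictly in (0, 1)")
    if design.max_events is None:
        raise ValueError("design needs max_events to translate the hazard "
                         "ratio into a drift")
    r = allocation_ratio
    drift = (-math.log(assumed_hr) * math.sqrt(design.max_events * r)
             / (1.0 + r))
    u_final = float(design.efficacy_z[-1])
    b = z_current * math.sqrt(info_fraction)
    rest = 1.0 - info_fraction
    return float(norm.sf((u_final - b - drift * rest) / math.sqrt(rest)))
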