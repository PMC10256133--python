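"""Group-sequential designs with power-family error spending.

Boundaries are computed on the z-scale by recursive numerical integration
over the joint Gaussian law of the sequential score process: with
information fractions ``t_1 < ... < t_K`` the score ``B_k = z_k * sqrt(t_k)``
has independent Gaussian increments with ``Var(B_k - B_{k-1}) = t_k - t_{k-1}``
and drift ``E[B_k] = delta * t_k``, where ``delta`` is the expected
z-statistic at full information.

Conventions
-----------
* One-sided testing: the *upper* boundary stops for efficacy, the *lower*
  (nonbinding) boundary stops for futility; z > 0 favors the treated arm.
* Efficacy boundaries spend alpha under the null and are computed ignoring
  the futility boundaries (nonbinding guarantee).
* Futility boundaries spend beta under the design-alternative drift, taking
  the fixed efficacy boundaries into account.
* The final look tests efficacy only; failure to reject at the final
  analysis counts as a futility outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.stats import norm

_SQRT2PI = math.sqrt(2.0 * math.pi)


def _phi(x):
    return np.exp(-0.5 * np.square(x)) / _SQRT2PI

__all__ = [
    "SpendingSpec",
    "LookSchedule",
    "GroupSequentialDesign",
    "CrossingProbabilities",
    "power_spending",
    "compute_boundaries",
    "crossing_probabilities",
    "required_events",
    "inflate_max_events",
    "SpendingError",
]

_TAIL_SD = 8.0  # integration cut-off for unbounded continuation regions
_DEFAULT_GRID = 401  # Simpson grid points per look (odd)


class SpendingError(RuntimeError):
    """Raised when a spending request cannot be satisfied (e.g. boundary overlap)."""


# ---------------------------------------------------------------------------
# spending family
# ---------------------------------------------------------------------------

def power_spending(t: float | np.ndarray, gamma: float, total: float):
    """Cumulative error spent at information fraction ``t``.

    Power (Kim-DeMets) family ``f(t) = total * t**gamma``.  Small ``gamma``
    spends error early (Pocock-type); large ``gamma`` spends late
    (O'Brien-Fleming-type).

    Parameters
    ----------
    t : float or array
        Information fraction(s) in [0, 1].
    gamma : float
        Family exponent, > 0.
    total : float
        Total error budget spent at ``t = 1``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0.0) or np.any(t_arr > 1.0):
        raise ValueError(f"information fraction outside [0, 1]: {t!r}")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    out = total * t_arr**gamma
    return float(out) if np.isscalar(t) else out


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpendingSpec:
    """Error budgets and power-family exponents for a design.

    ``alpha_total`` is the one-sided type-I error; for a two-sided symmetric
    design pass half the nominal two-sided alpha.
    """

    alpha_total: float = 0.025
    beta_total: float = 0.10
    gamma_alpha: float = 2.5
    gamma_beta: float = 2.5
    futility_binding: bool = False

    def __post_init__(self):
        if not 0.0 < self.alpha_total < 1.0:
            raise ValueError("alpha_total must be in (0, 1)")
        if not 0.0 < self.beta_total < 1.0:
            raise ValueError("beta_total must be in (0, 1)")
        if self.gamma_alpha <= 0 or self.gamma_beta <= 0:
            raise ValueError("spending exponents must be positive")

    def alpha_spent(self, t):
        return power_spending(t, self.gamma_alpha, self.alpha_total)

    def beta_spent(self, t):
        return power_spending(t, self.gamma_beta, self.beta_total)


@dataclass(frozen=True)
class LookSchedule:
    """Ordered analysis times as fractions of the maximum planned event count."""

    information_fractions: tuple[float, ...]
    futility_looks: tuple[float, ...]
    efficacy_looks: tuple[float, ...]

    def __post_init__(self):
        f = self.information_fractions
        if len(f) == 0:
            raise ValueError("schedule needs at least one look")
        if any(not 0.0 < x <= 1.0 for x in f):
            raise ValueError("information fractions must lie in (0, 1]")
        if any(b <= a for a, b in zip(f, f[1:])):
            raise ValueError("information fractions must be strictly increasing")
        if abs(f[-1] - 1.0) > 1e-12:
            raise ValueError("final look must be at information fraction 1.0")
        if 1.0 not in self.efficacy_looks:
            raise ValueError("final look must test efficacy")
        if 1.0 in self.futility_looks:
            raise ValueError("the final look does not carry a futility boundary")
        for x in self.futility_looks + self.efficacy_looks:
            if x not in f:
                raise ValueError(f"look {x} not in the schedule")
        for x in f[:-1]:
            if x not in self.futility_looks:
                raise ValueError(f"non-final look {x} must test futility")

    @classmethod
    def standard(
        cls,
        futility_fractions: Sequence[float],
        superiority_fraction: float | None = 0.6,
    ) -> "LookSchedule":
        """Schedule with futility at every interim and efficacy at
        ``superiority_fraction`` (if among the interims) and at 1.0."""
        fut = tuple(sorted(set(float(x) for x in futility_fractions)))
        fractions = fut + ((1.0,) if (not fut or fut[-1] < 1.0) else ())
        eff = [1.0]
        if superiority_fraction is not None and superiority_fraction in fut:
            eff.insert(0, float(superiority_fraction))
        return cls(fractions, fut, tuple(eff))

    @classmethod
    def fixed(cls) -> "LookSchedule":
        """Single analysis at full information (no interim looks)."""
        return cls((1.0,), (), (1.0,))

    @property
    def n_looks(self) -> int:
        return len(self.information_fractions)

    def tests_futility(self, k: int) -> bool:
        return self.information_fractions[k] in self.futility_looks

    def tests_efficacy(self, k: int) -> bool:
        return self.information_fractions[k] in self.efficacy_looks


@dataclass
class CrossingProbabilities:
    """Per-look stop probabilities of a design under a given drift."""

    information_fractions: np.ndarray
    efficacy: np.ndarray       # P(first stop is efficacy at look k)
    futility: np.ndarray       # P(first stop is futility at look k); final look
    # carries the "no rejection at final" mass
    drift: float

    @property
    def total_efficacy(self) -> float:
        return float(self.efficacy.sum())

    @property
    def total_futility(self) -> float:
        return float(self.futility.sum())

    @property
    def expected_information_fraction(self) -> float:
        p_stop = self.efficacy + self.futility
        return float(np.sum(self.information_fractions * p_stop))


# ---------------------------------------------------------------------------
# recursive integration engine
# ---------------------------------------------------------------------------

def _simpson_grid(lo: float, hi: float, m: int):
    if m % 2 == 0:
        m += 1
    x = np.linspace(lo, hi, m)
    w = np.ones(m)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    w *= (x[1] - x[0]) / 3.0
    return x, w


class _ScoreRecursion:
    """Sub-density of the score process over successive continuation regions.

    State after processing look k: grid ``x`` and weighted sub-density
    ``h`` of B_k restricted to the continuation region, such that
    ``sum(w * h * g(x))`` integrates ``g`` against the sub-density.
    """

    def __init__(self, drift: float, m: int = _DEFAULT_GRID):
        self.drift = drift
        self.m = m
        self.t_prev: float | None = None
        self.x: np.ndarray | None = None
        self.wh: np.ndarray | None = None  # quadrature weight * density

    def _increment(self, t: float):
        if self.t_prev is None:
            return self.drift * t, math.sqrt(t)
        dt = t - self.t_prev
        return self.drift * dt, math.sqrt(dt)

    def upper_crossing(self, t: float, z_upper: float) -> float:
        """P(continue through previous looks, B_t >= z_upper * sqrt(t))."""
        mu, sd = self._increment(t)
        b = z_upper * math.sqrt(t)
        if self.t_prev is None:
            return float(special.ndtr((mu - b) / sd))
        return float(np.sum(self.wh * special.ndtr((self.x + mu - b) / sd)))

    def lower_crossing(self, t: float, z_lower: float) -> float:
        mu, sd = self._increment(t)
        b = z_lower * math.sqrt(t)
        if self.t_prev is None:
            return float(special.ndtr((b - mu) / sd))
        return float(np.sum(self.wh * special.ndtr((b - self.x - mu) / sd)))

    def step(self, t: float, z_lower: float, z_upper: float):
        """Truncate to [z_lower, z_upper] (z-scale) at look ``t`` and advance."""
        mu, sd = self._increment(t)
        st = math.sqrt(t)
        lo = z_lower * st if np.isfinite(z_lower) else None
        hi = z_upper * st if np.isfinite(z_upper) else None
        if self.t_prev is None:
            reach_lo, reach_hi = mu - _TAIL_SD * sd, mu + _TAIL_SD * sd
        else:
            reach_lo = float(self.x[0]) + mu - _TAIL_SD * sd
            reach_hi = float(self.x[-1]) + mu + _TAIL_SD * sd
        lo = reach_lo if lo is None else max(lo, reach_lo)
        hi = reach_hi if hi is None else min(hi, reach_hi)
        if hi <= lo:  # continuation region (numerically) empty
            self.x = np.array([lo])
            self.wh = np.array([0.0])
            self.t_prev = t
            return
        xg, wg = _simpson_grid(lo, hi, self.m)
        if self.t_prev is None:
            dens = _phi((xg - mu) / sd) / sd
        else:
            dens = (self.wh[None, :] *
                    _phi((xg[:, None] - self.x[None, :] - mu) / sd) / sd).sum(axis=1)
        self.x = xg
        self.wh = wg * dens
        self.t_prev = t

    @property
    def mass(self) -> float:
        if self.wh is None:
            return 1.0
        return float(self.wh.sum())


def _solve_efficacy_boundaries(
    fractions: Sequence[float],
    efficacy_flags: Sequence[bool],
    spec: SpendingSpec,
    m: int = _DEFAULT_GRID,
) -> np.ndarray:
    """Upper z-boundaries spending alpha under the null (futility ignored).

    Looks without an efficacy test get +inf (continuation unbounded above
    for the alpha computation, preserving the nonbinding property).
    """
    rec = _ScoreRecursion(drift=0.0, m=m)
    bounds = np.full(len(fractions), np.inf)
    spent_prev = 0.0
    for k, t in enumerate(fractions):
        if efficacy_flags[k]:
            target = spec.alpha_spent(t) - spent_prev
            if target <= 0:
                raise SpendingError(f"non-positive alpha increment at t={t}")
            f = lambda u: rec.upper_crossing(t, u) - target
            try:
                bounds[k] = optimize.brentq(f, -10.0, 12.0, xtol=1e-9)
            except ValueError as exc:  # pragma: no cover - diagnostics path
                raise SpendingError(
                    f"efficacy boundary root not bracketed at t={t}: {exc}")
            spent_prev = spec.alpha_spent(t)
        rec.step(t, -np.inf, bounds[k])
    return bounds


def _solve_futility_boundaries(
    fractions: Sequence[float],
    futility_flags: Sequence[bool],
    efficacy_z: np.ndarray,
    spec: SpendingSpec,
    drift: float,
    m: int = _DEFAULT_GRID,
) -> np.ndarray:
    """Lower z-boundaries spending beta under ``drift``, efficacy bounds fixed."""
    rec = _ScoreRecursion(drift=drift, m=m)
    bounds = np.full(len(fractions), -np.inf)
    spent_prev = 0.0
    for k, t in enumerate(fractions):
        upper = efficacy_z[k]
        if futility_flags[k]:
            target = spec.beta_spent(t) - spent_prev
            if target <= 0:
                raise SpendingError(f"non-positive beta increment at t={t}")
            cap = min(upper, 12.0) - 1e-9
            f = lambda x: rec.lower_crossing(t, x) - target
            if f(cap) < 0:
                raise SpendingError(
                    f"futility boundary would cross the efficacy boundary at t={t}")
            bounds[k] = optimize.brentq(f, -12.0, cap, xtol=1e-9)
            spent_prev = spec.beta_spent(t)
        rec.step(t, bounds[k], upper)
    return bounds


def _seq_probabilities(
    fractions: Sequence[float],
    lower: np.ndarray,
    upper: np.ndarray,
    drift: float,
    m: int = _DEFAULT_GRID,
):
    """First-crossing probabilities for fixed boundary vectors under ``drift``."""
    rec = _ScoreRecursion(drift=drift, m=m)
    K = len(fractions)
    p_up = np.zeros(K)
    p_dn = np.zeros(K)
    for k, t in enumerate(fractions):
        if np.isfinite(upper[k]):
            p_up[k] = rec.upper_crossing(t, upper[k])
        if np.isfinite(lower[k]):
            p_dn[k] = rec.lower_crossing(t, lower[k])
        rec.step(t, lower[k], upper[k])
    return p_up, p_dn, rec.mass


# ---------------------------------------------------------------------------
# design object
# ---------------------------------------------------------------------------

class GroupSequentialDesign:
    """An interim-analysis scheme: schedule, z-boundaries and event inflation.

    Boundary vectors are computed lazily on first access so that large
    candidate grids can be enumerated cheaply.
    """

    def __init__(self, schedule: LookSchedule, spec: SpendingSpec,
                 grid_points: int = _DEFAULT_GRID,
                 max_events: int | None = None):
        self.schedule = schedule
        self.spec = spec
        self.grid_points = grid_points
        self.max_events = max_events

    # -- identification ----------------------------------------------------
    @property
    def scheme_id(self) -> str:
        fut = "/".join(f"{x:g}" for x in self.schedule.futility_looks)
        return (f"fut[{fut}]_gA{self.spec.gamma_alpha:g}"
                f"_gB{self.spec.gamma_beta:g}")

    def __repr__(self) -> str:  # pragma: no cover
        return f"GroupSequentialDesign({self.scheme_id}, D={self.max_events})"

    # -- boundaries --------------------------------------------------------
    @cached_property
    def efficacy_z(self) -> np.ndarray:
        flags = [self.schedule.tests_efficacy(k)
                 for k in range(self.schedule.n_looks)]
        return _solve_efficacy_boundaries(
            self.schedule.information_fractions, flags, self.spec,
            self.grid_points)

    @cached_property
    def _alternative(self) -> tuple[float, np.ndarray, float]:
        """(drift*, futility boundaries at drift*, inflation factor).

        drift* is the design-alternative drift at which, following both
        boundary families, power equals exactly 1 - beta_total; the
        inflation factor is (drift*/drift_fixed)^2.
        """
        sched, spec = self.schedule, self.spec
        delta_fixed = norm.ppf(1 - spec.alpha_total) + norm.ppf(1 - spec.beta_total)
        fut_flags = [sched.tests_futility(k) for k in range(sched.n_looks)]
        if not any(fut_flags) and sched.n_looks == 1:
            return delta_fixed, np.full(1, -np.inf), 1.0

        def shortfall(delta: float) -> float:
            lower = _solve_futility_boundaries(
                sched.information_fractions, fut_flags, self.efficacy_z,
                spec, delta, self.grid_points)
            p_up, _, _ = _seq_probabilities(
                sched.information_fractions, lower, self.efficacy_z, delta,
                self.grid_points)
            return p_up.sum() - (1 - spec.beta_total)

        lo, hi = delta_fixed, delta_fixed
        if shortfall(lo) >= 0:
            delta_star = delta_fixed
        else:
            for _ in range(30):
                hi *= 1.15
                if shortfall(hi) >= 0:
                    break
            else:  # pragma: no cover
                raise SpendingError("power cannot be recovered by inflating events")
            delta_star = optimize.brentq(shortfall, lo, hi, xtol=1e-6)
        lower = _solve_futility_boundaries(
            sched.information_fractions, fut_flags, self.efficacy_z,
            spec, delta_star, self.grid_points)
        return delta_star, lower, (delta_star / delta_fixed) ** 2

    @property
    def drift(self) -> float:
        """Design-alternative drift at full (inflated) information."""
        return self._alternative[0]

    @property
    def futility_z(self) -> np.ndarray:
        return self._alternative[1]

    @property
    def inflation_factor(self) -> float:
        return self._alternative[2]

    # -- derived tables ----------------------------------------------------
    def event_targets(self, max_events: int | None = None) -> np.ndarray:
        D = max_events if max_events is not None else self.max_events
        if D is None:
            raise ValueError("max_events not set on this design")
        return np.ceil(np.asarray(self.schedule.information_fractions) * D
                       - 1e-9).astype(int)

    def boundary_table(self) -> pd.DataFrame:
        t = np.asarray(self.schedule.information_fractions)
        rows = {
            "look": np.arange(1, self.schedule.n_looks + 1),
            "information_fraction": t,
            "events": (self.event_targets() if self.max_events is not None
                       else np.full(len(t), np.nan)),
            "efficacy_z": self.efficacy_z,
            "futility_z": self.futility_z,
            "cumulative_alpha_spent": np.where(
                np.isfinite(self.efficacy_z), self.spec.alpha_spent(t), np.nan),
            "cumulative_beta_spent": np.where(
                np.isfinite(self.futility_z), self.spec.beta_spent(t), np.nan),
        }
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "information_fractions": list(self.schedule.information_fractions),
            "futility_looks": list(self.schedule.futility_looks),
            "efficacy_looks": list(self.schedule.efficacy_looks),
            "alpha_total": self.spec.alpha_total,
            "beta_total": self.spec.beta_total,
            "gamma_alpha": self.spec.gamma_alpha,
            "gamma_beta": self.spec.gamma_beta,
            "futility_binding": self.spec.futility_binding,
            "efficacy_z": [float(x) for x in self.efficacy_z],
            "futility_z": [float(x) for x in self.futility_z],
            "inflation_factor": float(self.inflation_factor),
            "max_events": self.max_events,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroupSequentialDesign":
        sched = LookSchedule(tuple(d["information_fractions"]),
                             tuple(d["futility_looks"]),
                             tuple(d["efficacy_looks"]))
        spec = SpendingSpec(d["alpha_total"], d["beta_total"],
                            d["gamma_alpha"], d["gamma_beta"],
                            d.get("futility_binding", False))
        return cls(sched, spec, max_events=d.get("max_events"))


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def compute_boundaries(schedule: LookSchedule, spec: SpendingSpec,
                       grid_points: int = _DEFAULT_GRID) -> GroupSequentialDesign:
    """Construct a design and materialize its boundary vectors."""
    design = GroupSequentialDesign(schedule, spec, grid_points)
    design.efficacy_z  # noqa: B018 - force computation / validation
    design.futility_z
    return design


def crossing_probabilities(design: GroupSequentialDesign, drift: float,
                           respect_futility: bool = True
                           ) -> CrossingProbabilities:
    """Per-look first-crossing probabilities under an arbitrary drift.

    The final look's continue-below-boundary mass is assigned to the
    futility ("no rejection") outcome, so probabilities sum to 1.  With
    ``respect_futility=False`` the lower boundaries are ignored (the
    nonbinding alpha computation: futility stops may be overruled).
    """
    fractions = design.schedule.information_fractions
    lower = (design.futility_z if respect_futility
             else np.full(len(fractions), -np.inf))
    p_up, p_dn, final_mass = _seq_probabilities(
        fractions, lower, design.efficacy_z, drift,
        design.grid_points)
    p_dn = p_dn.copy()
    p_dn[-1] += final_mass
    return CrossingProbabilities(
        information_fractions=np.asarray(fractions),
        efficacy=p_up, futility=p_dn, drift=drift)


def required_events(design_hr: float, alpha_total: float = 0.025,
                    beta_total: float = 0.10,
                    allocation_ratio: float = 1.0) -> int:
    """Schoenfeld fixed-design event count for a log-rank comparison.

    D = (z_{1-a} + z_{1-b})^2 (1+r)^2 / (r log(HR)^2), rounded up.
    """
    if design_hr <= 0:
        raise ValueError("hazard ratio must be positive")
    if design_hr == 1.0:
        raise ValueError("event count undefined at HR = 1")
    r = allocation_ratio
    z = norm.ppf(1 - alpha_total) + norm.ppf(1 - beta_total)
    d = z**2 * (1 + r) ** 2 / (r * math.log(design_hr) ** 2)
    return int(math.ceil(d - 1e-9))


def _power_at_events(design: GroupSequentialDesign, events: float,
                     fixed_events: float) -> float:
    delta_fixed = (norm.ppf(1 - design.spec.alpha_total)
                   + norm.ppf(1 - design.spec.beta_total))
    delta = delta_fixed * math.sqrt(events / fixed_events)
    p_up, _, _ = _seq_probabilities(
        design.schedule.information_fractions, design.futility_z,
        design.efficacy_z, delta, design.grid_points)
    return float(p_up.sum())


def inflate_max_events(fixed_events: int, schedule: LookSchedule,
                       spec: SpendingSpec,
                       grid_points: int = _DEFAULT_GRID) -> tuple[int, float]:
    """Smallest integer max event count preserving 1 - beta power.

    Returns ``(max_events, inflation_factor)`` where the factor is the
    continuous events ratio before integer rounding.
    """
    design = GroupSequentialDesign(schedule, spec, grid_points)
    target = 1 - spec.beta_total
    D = int(math.ceil(design.inflation_factor * fixed_events - 1e-9))
    # integer refinement: boundaries stay fixed, drift scales with sqrt(D)
    while D > fixed_events and _power_at_events(design, D - 1, fixed_events) >= target:
        D -= 1
    while _power_at_events(design, D, fixed_events) < target - 1e-9:
        D += 1
    return D, design.inflation_factor
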