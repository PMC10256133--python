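"""Enumeration, simulation-based evaluation and selection of interim schemes.

The optimizer enumerates candidate designs (futility-look subsets crossed
with spending-exponent grids), drops those whose maximum trial duration
exceeds the no-interim design by more than a tolerance, scores the rest on
a shared set of simulated trials drawn from the treatment-effect mixture
prior (common random numbers), and selects the scheme minimizing the mean
of the chosen operating characteristic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .designs import (GroupSequentialDesign, LookSchedule, SpendingSpec,
                      inflate_max_events)
from .priors import MixtureEffectPrior
from .simulate import (SimulatedTrial, TrialAssumptions,
                       calendar_time_of_event, logrank_z, simulate_trial)

__all__ = [
    "SchemeGrid",
    "SchemeEvaluation",
    "enumerate_schemes",
    "apply_duration_exclusion",
    "size_schemes",
    "evaluate_schemes",
    "select_optimal",
    "conventional_design",
    "no_interim_design",
]

_CRITERIA = {"duration": "mean_duration",
             "sample_size": "mean_randomized",
             "exposure": "mean_exposure"}


@dataclass(frozen=True)
class SchemeGrid:
    """Search space of candidate interim-analysis schemes."""

    n_futility_looks: tuple[int, ...] = (4, 5)
    candidate_fractions: tuple[float, ...] = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
    superiority_fraction: float = 0.6
    gamma_beta_grid: tuple[float, ...] = tuple(np.arange(0.75, 3.001, 0.25))
    gamma_alpha_grid: tuple[float, ...] = tuple(np.arange(2.00, 3.001, 0.25))
    max_duration_inflation: float = 1.10

    def __post_init__(self):
        if not self.n_futility_looks or not self.gamma_alpha_grid \
                or not self.gamma_beta_grid or not self.candidate_fractions:
            raise ValueError("grid components must be nonempty")
        if any(not 0.0 < f < 1.0 for f in self.candidate_fractions):
            raise ValueError("candidate fractions must lie in (0, 1)")
        if self.superiority_fraction not in self.candidate_fractions:
            raise ValueError("superiority fraction must be a candidate fraction")


@dataclass
class SchemeEvaluation:
    """Operating characteristics of one scheme over shared replicates."""

    scheme_id: str
    design: GroupSequentialDesign
    mean_duration: float
    median_duration: float
    mean_randomized: float
    mean_exposure: float
    stop_efficacy: np.ndarray      # per look
    stop_futility: np.ndarray      # per look; final carries non-rejection
    power_success: float           # rejection rate among success replicates
    n_replicates: int = 0
    excluded: bool = False
    exclusion_reason: str | None = None

    def as_row(self) -> dict:
        row = {
            "scheme_id": self.scheme_id,
            "futility_looks": "/".join(
                f"{x:g}" for x in self.design.schedule.futility_looks),
            "gamma_alpha": self.design.spec.gamma_alpha,
            "gamma_beta": self.design.spec.gamma_beta,
            "max_events": self.design.max_events,
            "mean_duration": self.mean_duration,
            "median_duration": self.median_duration,
            "mean_randomized": self.mean_randomized,
            "mean_exposure": self.mean_exposure,
            "prob_stop_efficacy": float(np.sum(self.stop_efficacy)),
            "prob_stop_futility": float(np.sum(self.stop_futility)),
            "power_success": self.power_success,
            "excluded": self.excluded,
            "exclusion_reason": self.exclusion_reason or "",
        }
        return row


# ---------------------------------------------------------------------------
# enumeration and exclusion
# ---------------------------------------------------------------------------

def enumerate_schemes(grid: SchemeGrid,
                      spec: SpendingSpec) -> list[GroupSequentialDesign]:
    """All candidate designs, deterministic order, duplicate-free.

    Every futility-look set must contain the superiority fraction (where
    the single interim efficacy analysis is performed).  Spending exponents
    of the returned designs come from the grid, not from ``spec``.
    """
    others = [f for f in grid.candidate_fractions
              if f != grid.superiority_fraction]
    designs: list[GroupSequentialDesign] = []
    for n_looks in sorted(grid.n_futility_looks):
        for combo in itertools.combinations(others, n_looks - 1):
            fut = tuple(sorted(combo + (grid.superiority_fraction,)))
            schedule = LookSchedule.standard(fut, grid.superiority_fraction)
            for g_a in grid.gamma_alpha_grid:
                for g_b in grid.gamma_beta_grid:
                    s = SpendingSpec(spec.alpha_total, spec.beta_total,
                                     float(g_a), float(g_b),
                                     spec.futility_binding)
                    designs.append(GroupSequentialDesign(schedule, s))
    if not designs:
        raise ValueError("empty scheme grid")
    return designs


def size_schemes(designs: list[GroupSequentialDesign],
                 assumptions: TrialAssumptions,
                 n_jobs: int = 1) -> None:
    """Attach inflated maximum event counts to each design (in place)."""
    fixed = assumptions.fixed_events

    def _size(d: GroupSequentialDesign) -> int:
        return inflate_max_events(fixed, d.schedule, d.spec, d.grid_points)[0]

    if n_jobs == 1:
        sizes = [_size(d) for d in designs]
    else:
        sizes = Parallel(n_jobs=n_jobs)(delayed(_size)(d) for d in designs)
    for d, D in zip(designs, sizes):
        d.max_events = int(D)


def apply_duration_exclusion(
    designs: list[GroupSequentialDesign],
    assumptions: TrialAssumptions,
    max_duration_inflation: float = 1.10,
) -> list[GroupSequentialDesign]:
    """Drop schemes whose maximum trial duration exceeds the tolerance.

    The maximum duration of a scheme is the expected calendar time to reach
    its inflated maximum event count under the design assumptions; the
    reference is the expected time to the fixed-design event count.
    Excluded designs get ``excluded_reason`` set and are not returned.
    """
    fixed_duration = assumptions.time_to_events(assumptions.fixed_events)
    limit = max_duration_inflation * fixed_duration
    cache: dict[int, float] = {}
    retained = []
    for d in designs:
        if d.max_events is None:
            raise ValueError("size_schemes must run before exclusion")
        if d.max_events not in cache:
            cache[d.max_events] = assumptions.time_to_events(d.max_events)
        dur = cache[d.max_events]
        if dur > limit:
            d.excluded_reason = (
                f"max duration {dur:.1f} mo exceeds "
                f"{max_duration_inflation:.2f} x fixed-design {fixed_duration:.1f} mo")
        else:
            d.excluded_reason = None
            retained.append(d)
    return retained


# ---------------------------------------------------------------------------
# evaluation on shared replicates
# ---------------------------------------------------------------------------

def _prepare(design: GroupSequentialDesign):
    return (design.event_targets(),
            np.asarray(design.futility_z),
            np.asarray(design.efficacy_z),
            [design.schedule.tests_efficacy(k)
             for k in range(design.schedule.n_looks)])


def _score_replicate(trial: SimulatedTrial, prepared, z_cache: dict):
    """Outcome of every scheme on one trial; z values cached per event count."""
    out = []
    for targets, lower, upper, eff_flags in prepared:
        stop_look, reason = None, None
        for j, k in enumerate(targets):
            kk = min(int(k), trial.n)
            if kk not in z_cache:
                tt = calendar_time_of_event(trial, kk)
                zz, _, _ = logrank_z(trial, tt)
                z_cache[kk] = (tt, zz)
            t_cal, z = z_cache[kk]
            final = j == len(targets) - 1
            if eff_flags[j] and z >= upper[j]:
                stop_look, reason = j, "efficacy"
                break
            if not final and z <= lower[j]:
                stop_look, reason = j, "futility"
                break
            if final:
                stop_look, reason = j, "no_rejection"
        out.append((stop_look, reason, z_cache[min(int(targets[stop_look]), trial.n)][0]))
    return out


def _evaluate_chunk(designs_prepared, prior, assumptions, seeds, schedule_lens):
    n_schemes = len(designs_prepared)
    sums = {
        "duration": np.zeros(n_schemes),
        "randomized": np.zeros(n_schemes),
        "exposure": np.zeros(n_schemes),
    }
    durations = [[] for _ in range(n_schemes)]
    stop_eff = [np.zeros(L) for L in schedule_lens]
    stop_fut = [np.zeros(L) for L in schedule_lens]
    n_success = 0
    n_success_reject = np.zeros(n_schemes)
    for ss in seeds:
        rng = np.random.default_rng(ss)
        success, log_hr = prior.sample(rng)
        trial = simulate_trial(assumptions, log_hr, rng)
        z_cache: dict[int, tuple[float, float]] = {}
        results = _score_replicate(trial, designs_prepared, z_cache)
        n_success += int(success)
        for i, (look, reason, t_stop) in enumerate(results):
            sums["duration"][i] += t_stop
            sums["randomized"][i] += trial.n_enrolled(t_stop)
            sums["exposure"][i] += trial.exposure(t_stop)
            durations[i].append(t_stop)
            if reason == "efficacy":
                stop_eff[i][look] += 1
                n_success_reject[i] += int(success)
            else:
                stop_fut[i][look] += 1
    return sums, durations, stop_eff, stop_fut, n_success, n_success_reject


def evaluate_schemes(
    designs: list[GroupSequentialDesign],
    prior: MixtureEffectPrior,
    assumptions: TrialAssumptions,
    n_replicates: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
    n_jobs: int = 1,
) -> list[SchemeEvaluation]:
    """Score every design on the same simulated replicates.

    Each replicate draws one (success, log-HR) pair from the prior and one
    trial dataset; all schemes are evaluated on that trial (common random
    numbers).  Replicate ``i`` uses an independent child stream of the seed,
    so serial and parallel execution are bitwise identical.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    for d in designs:
        if d.max_events is None:
            raise ValueError(f"design {d.scheme_id} has no max_events; "
                             "run size_schemes first")
    prepared = [_prepare(d) for d in designs]
    lens = [d.schedule.n_looks for d in designs]
    root = (seed if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(seed))
    seeds = root.spawn(n_replicates)

    if n_jobs == 1:
        chunks = [_evaluate_chunk(prepared, prior, assumptions, seeds, lens)]
    else:
        parts = np.array_split(np.arange(n_replicates), n_jobs * 4)
        chunks = Parallel(n_jobs=n_jobs)(
            delayed(_evaluate_chunk)(prepared, prior, assumptions,
                                     [seeds[i] for i in part], lens)
            for part in parts if part.size)

    evals = []
    n_success = sum(c[4] for c in chunks)
    for i, d in enumerate(designs):
        dur = np.concatenate([np.asarray(c[1][i]) for c in chunks])
        s_eff = sum(c[2][i] for c in chunks)
        s_fut = sum(c[3][i] for c in chunks)
        reject_success = sum(float(c[5][i]) for c in chunks)
        evals.append(SchemeEvaluation(
            scheme_id=d.scheme_id,
            design=d,
            mean_duration=float(dur.mean()),
            median_duration=float(np.median(dur)),
            mean_randomized=float(sum(c[0]["randomized"][i] for c in chunks)
                                  / n_replicates),
            mean_exposure=float(sum(c[0]["exposure"][i] for c in chunks)
                                / n_replicates),
            stop_efficacy=s_eff / n_replicates,
            stop_futility=s_fut / n_replicates,
            power_success=(reject_success / n_success if n_success else math.nan),
            n_replicates=n_replicates,
        ))
    return evals


def select_optimal(evaluations: list[SchemeEvaluation],
                   criterion: str = "duration"
                   ) -> tuple[SchemeEvaluation, list[SchemeEvaluation]]:
    """Minimize the mean of the chosen criterion; deterministic tie-breaks.

    Ties break on smaller mean sample size, then fewer looks, then
    lexicographic futility timing.  Returns ``(optimum, full ranking)``.
    """
    if criterion not in _CRITERIA:
        raise ValueError(f"criterion must be one of {sorted(_CRITERIA)}")
    pool = [e for e in evaluations if not e.excluded]
    if not pool:
        raise ValueError("all schemes were excluded; relax the duration cap "
                         "or widen the grid")
    attr = _CRITERIA[criterion]

    def key(e: SchemeEvaluation):
        return (getattr(e, attr), e.mean_randomized,
                e.design.schedule.n_looks, e.design.schedule.futility_looks)

    ranked = sorted(pool, key=key)
    return ranked[0], ranked


# ---------------------------------------------------------------------------
# reference designs
# ---------------------------------------------------------------------------

def conventional_design(assumptions: TrialAssumptions,
                        interim_fraction: float = 0.6,
                        gamma: float = 3.0) -> GroupSequentialDesign:
    """Single interim (futility + efficacy) at 60% with O'Brien-Fleming-type
    spending — the conventional comparator design."""
    schedule = LookSchedule.standard((interim_fraction,), interim_fraction)
    spec = SpendingSpec(assumptions.alpha_total, assumptions.beta_total,
                        gamma, gamma)
    design = GroupSequentialDesign(schedule, spec)
    design.max_events, _ = inflate_max_events(assumptions.fixed_events,
                                              schedule, spec)
    return design


def no_interim_design(assumptions: TrialAssumptions) -> GroupSequentialDesign:
    """Fixed design: one efficacy analysis at the Schoenfeld event count."""
    schedule = LookSchedule.fixed()
    spec = SpendingSpec(assumptions.alpha_total, assumptions.beta_total,
                        2.0, 2.0)
    design = GroupSequentialDesign(schedule, spec)
    design.max_events = assumptions.fixed_events
    return design


def evaluations_to_frame(evaluations: list[SchemeEvaluation]) -> pd.DataFrame:
    return pd.DataFrame([e.as_row() for e in evaluations])
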