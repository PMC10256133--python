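import math

import numpy as np
import pytest

from seqopt import (LookSchedule, SpendingSpec, TrialAssumptions,
                    calendar_time_of_event, compute_boundaries, logrank_z,
                    run_looks, simulate_trial)
from seqopt.simulate import InformationCapError, SimulatedTrial


def _big_assumptions(n=100_000, median=28.9, hr=0.667):
    return TrialAssumptions(n_total=n, accrual_duration=1.0,
                            median_control=median, design_hr=hr)


class TestSimulateTrial:
    def test_entry_times_within_accrual(self, toy_assumptions, rng):
        trial = simulate_trial(toy_assumptions, 0.0, rng)
        assert trial.entry.min() >= 0.0
        assert trial.entry.max() <= toy_assumptions.accrual_duration
        assert trial.time.min() > 0.0

    def test_allocation_counts(self, rng):
        asm = TrialAssumptions(n_total=300, accrual_duration=10,
                               median_control=20, design_hr=0.5,
                               allocation_ratio=2.0)
        trial = simulate_trial(asm, 0.0, rng)
        assert trial.arm.sum() == 200

    def test_control_median_calibrated(self, rng):
        """Empirical control median ~ 28.9 months at large n."""
        trial = simulate_trial(_big_assumptions(), 0.0, rng)
        med = np.median(trial.time[trial.arm == 0])
        assert med == pytest.approx(28.9, rel=0.01)

    def test_proportional_hazards_median_relation(self, rng):
        """HR = (28.9/43.4)^rho maps the control median to 43.4 months."""
        hr = (28.9 / 43.4) ** 2
        trial = simulate_trial(_big_assumptions(hr=hr), math.log(hr), rng)
        med_t = np.median(trial.time[trial.arm == 1])
        assert med_t == pytest.approx(43.4, rel=0.01)

    def test_null_arms_indistinguishable(self, rng):
        from scipy.stats import ks_2samp
        trial = simulate_trial(_big_assumptions(), 0.0, rng)
        p = ks_2samp(trial.time[trial.arm == 0],
                     trial.time[trial.arm == 1]).pvalue
        assert p > 0.01

    def test_reproducible(self, toy_assumptions):
        t1 = simulate_trial(toy_assumptions, -0.3, np.random.default_rng(5))
        t2 = simulate_trial(toy_assumptions, -0.3, np.random.default_rng(5))
        np.testing.assert_array_equal(t1.time, t2.time)
        np.testing.assert_array_equal(t1.entry, t2.entry)


class TestCalendarTimeOfEvent:
    def test_first_event_is_minimum(self, toy_assumptions, rng):
        trial = simulate_trial(toy_assumptions, 0.0, rng)
        assert calendar_time_of_event(trial, 1) == pytest.approx(
            trial.calendar.min())

    def test_monotone_in_rank(self, toy_assumptions, rng):
        trial = simulate_trial(toy_assumptions, 0.0, rng)
        times = [calendar_time_of_event(trial, k)
                 for k in range(1, trial.n + 1, 7)]
        assert np.all(np.diff(times) >= 0)

    def test_cap_raises(self, toy_assumptions, rng):
        trial = simulate_trial(toy_assumptions, 0.0, rng)
        with pytest.raises(InformationCapError):
            calendar_time_of_event(trial, trial.n + 1)

    def test_expected_time_to_events_oracle(self, toy_assumptions):
        """[DERIVED] deterministic event curve vs Monte-Carlo average."""
        D = 88
        expected = toy_assumptions.time_to_events(D)
        times = []
        for i in range(400):
            trial = simulate_trial(toy_assumptions,
                                   math.log(toy_assumptions.design_hr),
                                   np.random.default_rng(900 + i))
            times.append(calendar_time_of_event(trial, D))
        mc = float(np.mean(times))
        se = float(np.std(times) / math.sqrt(len(times)))
        assert abs(mc - expected) < max(3.5 * se, 0.02 * expected)


class TestLogrankZ:
    def test_null_distribution(self, toy_assumptions):
        """z ~ N(0, 1) under identical arms."""
        zs = []
        for i in range(1500):
            trial = simulate_trial(toy_assumptions, 0.0,
                                   np.random.default_rng(10_000 + i))
            t = calendar_time_of_event(trial, 90)
            zs.append(logrank_z(trial, t)[0])
        zs = np.array(zs)
        assert abs(zs.mean()) < 0.08
        assert 0.93 < zs.var() < 1.08

    def test_sign_convention(self):
        # all events in control, treated all censored -> strongly positive z
        entry = np.zeros(40)
        arm = np.repeat([0, 1], 20)
        time = np.where(arm == 0, np.linspace(1, 5, 40), 1000.0)
        trial = SimulatedTrial(entry=entry, arm=arm, time=time)
        z, d, _ = logrank_z(trial, 10.0)
        assert z > 3.0
        assert d == 20

    def test_schoenfeld_consistency(self):
        """[DERIVED] E[z] ~ -log(HR) sqrt(d)/2 under proportional hazards."""
        hr = 0.7
        asm = _big_assumptions(n=4000, hr=hr)
        zs, ds = [], []
        for i in range(60):
            trial = simulate_trial(asm, math.log(hr),
                                   np.random.default_rng(3_000 + i))
            t = calendar_time_of_event(trial, 2000)
            z, d, _ = logrank_z(trial, t)
            zs.append(z)
            ds.append(d)
        expected = -math.log(hr) * math.sqrt(np.mean(ds)) / 2.0
        assert np.mean(zs) == pytest.approx(expected, rel=0.06)

    def test_matches_lifelines(self, toy_assumptions, rng):
        """Cross-check the hand-rolled statistic against lifelines."""
        lifelines = pytest.importorskip("lifelines")
        from lifelines.statistics import logrank_test
        trial = simulate_trial(toy_assumptions, -0.5, rng)
        at = calendar_time_of_event(trial, 100)
        z, _, _ = logrank_z(trial, at)
        follow = at - trial.entry
        inc = follow > 0
        obs = np.minimum(trial.time[inc], follow[inc])
        event = trial.time[inc] <= follow[inc]
        grp = trial.arm[inc]
        res = logrank_test(obs[grp == 0], obs[grp == 1],
                           event_observed_A=event[grp == 0],
                           event_observed_B=event[grp == 1])
        assert z**2 == pytest.approx(res.test_statistic, rel=1e-6)

    def test_no_events_raises(self):
        trial = SimulatedTrial(entry=np.zeros(10), arm=np.arange(10) % 2,
                               time=np.full(10, 50.0))
        with pytest.raises(ValueError):
            logrank_z(trial, 10.0)


class TestRunLooks:
    def test_single_look_design(self, toy_assumptions, rng):
        d = compute_boundaries(LookSchedule.fixed(),
                               SpendingSpec(0.025, 0.1, 2.0, 2.0))
        d.max_events = 88
        trial = simulate_trial(toy_assumptions, 0.0, rng)
        traj = run_looks(trial, d)
        assert traj.n_looks == 1
        assert traj.events[0] == 88

    def test_event_targets_are_ceilings(self, paper_style_design,
                                        toy_assumptions, rng):
        d = paper_style_design
        targets = d.event_targets(93)
        expected = [math.ceil(t * 93) for t in
                    d.schedule.information_fractions]
        assert list(targets) == expected

    def test_recomputation_equivalence(self, paper_style_design,
                                       toy_assumptions, rng):
        """[DERIVED] one-pass trajectory equals per-look recomputation."""
        d = paper_style_design
        d93 = type(d)(d.schedule, d.spec, max_events=93)
        trial = simulate_trial(toy_assumptions, -0.4, rng)
        traj = run_looks(trial, d93)
        for k, target in enumerate(d93.event_targets()):
            t = calendar_time_of_event(trial, int(target))
            z, _, _ = logrank_z(trial, t)
            assert traj.z[k] == pytest.approx(z, abs=1e-12)

    def test_capped_looks_flagged(self, rng):
        asm = TrialAssumptions(n_total=40, accrual_duration=5,
                               median_control=20, design_hr=0.5)
        d = compute_boundaries(LookSchedule.fixed(),
                               SpendingSpec(0.025, 0.1, 2.0, 2.0))
        d.max_events = 60  # more than 40 patients can supply
        trial = simulate_trial(asm, 0.0, rng)
        traj = run_looks(trial, d)
        assert traj.capped[0]

    def test_trajectory_dataframe(self, paper_style_design, toy_assumptions,
                                  rng):
        d = type(paper_style_design)(paper_style_design.schedule,
                                     paper_style_design.spec, max_events=93)
        trial = simulate_trial(toy_assumptions, 0.0, rng)
        df = run_looks(trial, d).to_dataframe()
        assert {"look", "events", "calendar_time", "z"} <= set(df.columns)
        assert df["events"].is_monotonic_increasing


class TestFullPipelineCalibration:
    """simulate -> run_looks -> boundary decisions reproduce alpha and power."""

    @staticmethod
    def _reject_rate(design, assumptions, log_hr, n_rep, seed0):
        lower, upper = design.futility_z, design.efficacy_z
        rejected = 0
        for i in range(n_rep):
            trial = simulate_trial(assumptions, log_hr,
                                   np.random.default_rng(seed0 + i))
            traj = run_looks(trial, design)
            for k in range(traj.n_looks):
                if np.isfinite(upper[k]) and traj.z[k] >= upper[k]:
                    rejected += 1
                    break
                if np.isfinite(lower[k]) and traj.z[k] <= lower[k]:
                    break
        return rejected / n_rep

    @pytest.fixture(scope="class")
    def sized_design(self, paper_style_design, toy_assumptions):
        from seqopt import inflate_max_events
        d = paper_style_design
        sized = type(d)(d.schedule, d.spec)
        sized.max_events = inflate_max_events(
            toy_assumptions.fixed_events, d.schedule, d.spec)[0]
        return sized

    def test_null_rejection_at_most_alpha(self, sized_design,
                                          toy_assumptions):
        n = 1500
        rate = self._reject_rate(sized_design, toy_assumptions, 0.0, n, 777)
        se = math.sqrt(0.025 * 0.975 / n)
        assert rate <= 0.025 + 3 * se

    def test_power_recovered_at_design_alternative(self, sized_design,
                                                   toy_assumptions):
        n = 1500
        rate = self._reject_rate(sized_design, toy_assumptions,
                                 math.log(toy_assumptions.design_hr), n, 888)
        se = math.sqrt(0.9 * 0.1 / n)
        assert rate == pytest.approx(0.90, abs=3 * se)


class TestExportedData:
    def test_csv_round_trip(self, toy_assumptions, rng, tmp_path):
        trial = simulate_trial(toy_assumptions, 0.0, rng)
        df = trial.to_dataframe(censor_at=20.0)
        path = tmp_path / "trial.csv"
        df.to_csv(path, index=False)
        import pandas as pd
        back = pd.read_csv(path)
        assert {"patient_id", "arm", "entry_time", "time_to_event",
                "event_flag", "censor_time"} <= set(back.columns)
        assert back["event_flag"].isin([0, 1]).all()
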