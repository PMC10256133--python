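import numpy as np
import pytest

from seqopt import (LookSchedule, SpendingSpec, TrialAssumptions,
                    compute_boundaries)


@pytest.fixture(scope="session")
def paper_style_design():
    """Four futility looks at 0.3-0.6, efficacy at 0.6 and 1.0, gamma 2.5."""
    schedule = LookSchedule.standard((0.3, 0.4, 0.5, 0.6), 0.6)
    return compute_boundaries(schedule, SpendingSpec(0.025, 0.10, 2.5, 2.5))


@pytest.fixture(scope="session")
def three_look_design():
    schedule = LookSchedule.standard((0.4, 0.7), None)
    return compute_boundaries(schedule, SpendingSpec(0.025, 0.10, 2.0, 1.5))


@pytest.fixture(scope="session")
def toy_assumptions():
    return TrialAssumptions(n_total=180, accrual_duration=18.0,
                            median_control=20.0, design_hr=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(20230606)
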