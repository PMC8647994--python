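import numpy as np
import pytest

from petki import (
    DEFAULT_POPULATION_TAIL,
    BloodSample,
    InputSimParams,
    TimeActivityCurve,
    TwoTissueParams,
    build_idif,
    fine_grid,
    frame_average,
    long_protocol_schedule,
    monoexp_eval,
    short_early_schedule,
    short_late_schedule,
    simulate_input,
    simulate_tissue,
)


@pytest.fixture(scope="session")
def pop():
    return DEFAULT_POPULATION_TAIL


@pytest.fixture(scope="session")
def long_schedule():
    return long_protocol_schedule()


@pytest.fixture(scope="session")
def grid():
    return fine_grid(60.0)


def make_ideal_idif(pop, scale=1.0, schedule=None):
    """Long-protocol plasma TAC whose tail values equal the population
    model at the frame mid-times exactly (no frame-averaging bias)."""
    schedule = schedule or long_protocol_schedule()
    mids = schedule.mid_times_min
    early = 60.0 * mids * np.exp(-2.0 * mids)  # arbitrary smooth bolus shape
    tail = monoexp_eval(pop, mids)
    vals = scale * np.where(mids <= 10.0, early + tail * (1 - np.exp(-mids / 0.4)), tail)
    return TimeActivityCurve(schedule=schedule, values=vals, role="plasma")


@pytest.fixture(scope="session")
def ideal_cohort(pop):
    """Ten identical noiseless patients following the population tail
    exactly, paired with their consistent 45-min blood samples."""
    cohort = []
    for _ in range(10):
        tac = make_ideal_idif(pop)
        # sample drawn at a frame mid-time so the anchored curve value is
        # the model value itself (no interpolation chord error)
        sample = BloodSample(
            plasma_activity=float(monoexp_eval(pop, 42.5)), t_sample=42.5
        )
        cohort.append((build_idif(tac, sample), sample))
    return cohort


@pytest.fixture(scope="session")
def simulated_patient(grid):
    """One noiseless simulated patient with known kinetics (both protocols)."""
    truth = TwoTissueParams(K1=0.1, k2=0.1, k3=0.05, Vb=0.0)
    ip = InputSimParams()
    cp = simulate_input(ip, grid)
    ct = simulate_tissue(cp, truth, grid)
    sample = BloodSample(float(np.interp(45.0, grid, cp)))
    return {
        "truth": truth,
        "cp": cp,
        "ct": ct,
        "sample": sample,
        "plasma_long": frame_average(cp, long_protocol_schedule(), grid, role="plasma"),
        "tissue_long": frame_average(ct, long_protocol_schedule(), grid, role="tissue"),
        "plasma_early": frame_average(cp, short_early_schedule(), grid, role="plasma"),
        "tissue_early": frame_average(ct, short_early_schedule(), grid, role="tissue"),
        "tissue_late": frame_average(ct, short_late_schedule(), grid, role="tissue"),
    }
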