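import numpy as np
import pytest

import vtasst as v


@pytest.fixture(scope="session")
def adp_ladder_noiseless():
    """Noiseless ADP-subtype ladder with its ground truth."""
    return v.synth_trace_ladder(v.DEFAULT_SUBTYPES["ADP"], seed=0, noise_sd=0.0)


@pytest.fixture(scope="session")
def delayed_ladder_noiseless():
    return v.synth_trace_ladder(v.DEFAULT_SUBTYPES["Delayed"], seed=0, noise_sd=0.0)


@pytest.fixture(scope="session")
def cohort():
    """Default three-subtype feature table (215 / 92 / 85 cells)."""
    return v.synth_feature_table(seed=0)


@pytest.fixture(scope="session")
def patchseq_data():
    return v.synth_patchseq(seed=3)


def flat_ladder(level=-70.0, n_sweeps=5, dt=0.1, onset=100.0, duration=800.0):
    """Ladder of constant-voltage sweeps (helper for QC tests)."""
    n = int(round((onset + duration + 100.0) / dt))
    currents = np.arange(-100, -100 + 10 * n_sweeps, 10.0)
    voltages = np.full((n_sweeps, n), float(level))
    return v.SweepLadder(
        cell_id="flat",
        dt=dt,
        currents=currents,
        voltages=voltages,
        step_onset=onset,
        step_duration=duration,
    )
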