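import numpy as np
import pytest

from mtpfluor.data import MeasurementSchedule, WellCondition
from mtpfluor.layout import build_monitoring_layout
from mtpfluor.synth import (
    KineticParams,
    default_spectral_model,
    generate_experiment,
)
from mtpfluor.validate import run_default_pipeline


@pytest.fixture(scope="session")
def params():
    return KineticParams()


@pytest.fixture(scope="session")
def quiet_model():
    """Spectral model without noise or the early-cultivation artifact."""
    return default_spectral_model(
        noise_add_sd=0.0, noise_mult_sd=0.0, well_gain_sd=0.0, early_artifact_amp=0.0
    )


@pytest.fixture(scope="session")
def tiny_experiment(quiet_model):
    """Two conditions x two replicates, short horizon, coarse grids, noise-free."""
    layout = build_monitoring_layout(
        {"II": (9.0, 0.07), "VII": (2.0, 0.03)}, n_replicates=2, offline_horizon=6.0
    )
    sched = MeasurementSchedule(cycle_period=0.5, horizon=3.0, t_first=0.1, offline_horizon=3.0)
    ds, offline, otr = generate_experiment(
        layout,
        model=quiet_model,
        sched=sched,
        seed=1,
        em_step=5.0,
        offline_noise=None,
        spectral_noise=False,
    )
    return ds, offline, otr, layout


@pytest.fixture(scope="session")
def default_run():
    """The full default pipeline (seed 42, 2 LVs) with intermediate artefacts.

    Session-scoped because it takes a few seconds and several test modules
    inspect different aspects of it.
    """
    report, art = run_default_pipeline(seed=42, n_lv=2, return_data=True)
    return report, art
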