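import numpy as np
import pytest

import erk_rescale as er


@pytest.fixture(scope="session")
def design():
    return er.ExperimentDesign()


@pytest.fixture(scope="session")
def curve():
    return er.CalibrationCurve(intercept=0.08, slope=0.45)


@pytest.fixture(scope="session")
def r_p():
    return er.power_ratio(er.default_spectral_config())


@pytest.fixture(scope="session")
def quiet_truth():
    """A responder with no pulses and no noise: fully deterministic shape."""
    return er.CellGroundTruth(
        baseline_rho=0.3, responder=True, peak_rho=2.0, rise_tau=7.5,
        adapt_tau=35.0, steady_rho=0.7, pulse_rate=0.0, pulse_amp=0.0,
        pulse_duration=10.0, meki_decay_b=0.1, noise_cv=0.0,
    )


@pytest.fixture(scope="session")
def small_population(design, curve, r_p):
    """Simulated 150-cell population pushed through the forward model and
    quantified back to activity; shared across recovery tests."""
    from erk_rescale.calibration import quantify_traces

    spec = er.default_population_spec(n_cells=150, responder_fraction=0.6, seed=11)
    traces, truth = er.simulate_population(spec, design)
    raw = er.population_to_raw(traces, truth, curve, r_p)
    rho, _ = quantify_traces(raw, curve, r_p)
    return {"traces": traces, "truth": truth, "raw": raw, "rho": rho}
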