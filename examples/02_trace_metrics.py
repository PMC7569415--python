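"""Simulate a small single-cell population and extract per-cell metrics.

Each trace is normalized to its MEK-inhibitor reference window, then
decomposed into baseline, peak, amplitude, steady state, volatility and a
responder call; response frequency is summarized per experiment.
"""

import erk_rescale as er
from erk_rescale.calibration import quantify_traces

design = er.ExperimentDesign()  # stimulus at 120 min, MEKi at 270 min
curve = er.CalibrationCurve(intercept=0.08, slope=0.45)
r_p = er.power_ratio(er.default_spectral_config())

spec = er.default_population_spec(n_cells=120, responder_fraction=0.6, seed=0)
traces, truth = er.simulate_population(spec, design)
raw = er.population_to_raw(traces, truth, curve, r_p)
rho, _ = quantify_traces(raw, curve, r_p)

metrics, qc = er.compute_metrics(rho, design)
print(f"{qc.n_kept}/{qc.n_input} cells passed QC")
print(metrics[["baseline", "peak", "amplitude", "steady_state",
               "volatility", "responder", "time_to_peak"]].describe().round(3))

freq, sd, per_exp = er.response_frequency(metrics)
print(f"\nresponse frequency: {freq:.2f} +/- {sd:.2f} across "
      f"{len(per_exp)} experiments (truth: {truth['responder'].mean():.2f})")
print("responders show a stimulus-locked rise; the median time_to_peak of "
      f"{metrics['time_to_peak'].median():.0f} min reflects the ~15 min "
      "activity peak after stimulation.")
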