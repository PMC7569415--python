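"""Infer substrate-level phosphatase activity from post-MEKi decay.

With MEK inhibited the kinase flux onto the reporter stops, so the signal
relaxes exponentially at a rate proportional to the phosphatase activity
acting on it; fitting y = a exp(-b t) + c per cell recovers that rate.
"""

import erk_rescale as er
from erk_rescale.calibration import quantify_traces
from erk_rescale.phosphatase import fit_population_decays, group_decay_summary

design = er.ExperimentDesign()
curve = er.CalibrationCurve(intercept=0.08, slope=0.45)
r_p = er.power_ratio(er.default_spectral_config())

# two synthetic lines with different true decay constants
frames = []
for line, b_mean, seed in [("slow_line", 0.05, 0), ("fast_line", 0.15, 1)]:
    spec = er.default_population_spec(n_cells=60, seed=seed, cell_line=line)
    d = dict(spec.distributions)
    d["meki_decay_b"] = er.Distribution("lognormal", {"mean": b_mean, "cv": 0.2})
    import dataclasses
    spec = dataclasses.replace(spec, distributions=d)
    traces, truth = er.simulate_population(spec, design)
    traces["cell_id"] = line + "_" + traces["cell_id"]
    truth["cell_id"] = line + "_" + truth["cell_id"]
    raw = er.population_to_raw(traces, truth, curve, r_p)
    rho, _ = quantify_traces(raw, curve, r_p)
    frames.append(rho)

import pandas as pd

rho_all = pd.concat(frames, ignore_index=True)
fits = fit_population_decays(rho_all, design)
summary = group_decay_summary(fits, by=("cell_line",))
print("per-line decay constants (1/min):")
print(summary.round(4).to_string(index=False))
print("the fitted medians separate the two lines cleanly; higher b means "
      "stronger phosphatase activity on ERK substrates in that line.")
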