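"""Fit a reporter calibration curve and convert raw intensities to the
ERK:phosphatase activity ratio.

The corrected FRET signal E = 1 - (CFP/YFP)/R_P is linear in the fraction
of reporter phosphorylated; Phos-Tag immunoblots of matched conditions
pin down that line, and the mass-action cycle converts the fraction to
rho = p/(1-p), a relative ERK:phosphatase ratio.
"""

import numpy as np

import erk_rescale as er

# calibration points: (Phos-Tag phosphorylated fraction, mean corrected
# signal) for conditions spanning the observed activity range
p_phostag = np.array([0.02, 0.10, 0.35, 0.60, 0.85])
e_mean = 0.08 + 0.45 * p_phostag + np.array([0.004, -0.003, 0.002, -0.004, 0.001])

curve = er.fit_calibration(p_phostag, e_mean, provenance="example blot series")
print(f"calibration: E = {curve.intercept:.3f} + {curve.slope:.3f} * p "
      f"(residual SD {curve.residual_sd:.4f}, n={curve.n_points})")
# intercept = spontaneous-association background at p=0; slope = reporter span

r_p = er.power_ratio(er.default_spectral_config())
print(f"spectral power ratio R_P = {r_p:.4f}  (cyan/yellow collected power)")

# quantify a short raw trace: CFP/YFP falls as activity rises
cfp_over_yfp = np.array([0.30, 0.28, 0.25, 0.22, 0.21])
e = er.ekar_signal(cfp_over_yfp, np.ones(5), r_p)
res = er.activity_from_signal(e, curve)
for ratio, rho in zip(cfp_over_yfp, res.rho):
    print(f"  CFP/YFP {ratio:.2f} -> rho {rho:.3f}")
print("rho is the relative ERK:phosphatase activity ratio; rho=1 means the "
      "kinase and opposing phosphatase fluxes on the reporter balance.")
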