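# erk-rescale

Quantitative analysis of ERK/MAPK signaling downstream of single RAS
isoforms: calibrated FRET-reporter quantification, single-cell trace
metrics, a steady-state model of the internal RAS→RAF→MEK→ERK cascade,
phosphatase-activity inference, and the statistics that tie them together
— exercised end-to-end on synthetic data with known ground truth.

## Who this is for

Systems biologists working with live-cell kinase activity reporters
(EKAR-family FRET sensors) who need to (a) turn raw CFP/YFP intensity
ratios into a calibrated, linear measure of kinase activity, (b) decompose
heterogeneous single-cell time series into comparable per-cell parameters,
and (c) separate the contribution of the core GTPase/kinase cascade
("internal factors") from feedback, scaffolds and regulated phosphatases
("external factors") when interpreting mutant phenotypes.

## The model at the core

**Reporter calibration.** The corrected reporter signal is

    E = 1 − (CFP/YFP) / R_P

where `R_P` is the cyan:yellow ratio of total collected optical power,
the product of six scalar factors per channel (excitation intensity,
exposure time, extinction coefficient, quantum yield, and excitation- and
emission-side spectral overlap integrals). `E` is affine in the fraction
`p` of reporter phosphorylated, `E = E₀ + s·p` (the intercept `E₀` is
spontaneous fluorophore association), and a mass-action
phosphorylation/dephosphorylation cycle at steady state,
`k_f·ERK·(1−p) = k_r·P·p`, gives the linear activity readout

    ρ = p / (1 − p) ∝ ERK_active / phosphatase_active .

**Trace metrics.** Each cell is normalized to its MEK-inhibitor reference
window, then described by baseline (2 h pre-stimulus mean), peak and
time-to-peak, amplitude, steady state (~2 h post-stimulus), volatility
(mean-scaled mean absolute derivative — a time-resolved analogue of the
coefficient of variation), and a responder call combining a 5% magnitude
floor with a derivative criterion.

**Internal cascade model.** Per isoform: GTP loading
`f_GTP = k_ex/(k_ex + k_int + k_gap)`; RAF recruitment from the exact
binding quadratic with dissociation constant `Kd_RAF`; and two first-order
push–pull kinase tiers giving fractional ppMEK and ppERK. Oncogenic
mutants are GAP-insensitive (hydrolysis 50–800-fold lower than wild type)
with up to 7-fold weaker RAF binding; stimulation raises only `k_ex`.

**Phosphatase inference.** Two independent estimators: the
ppERK/ERK-activity ratio per condition, and the per-cell exponential
decay rate `b` of reporter signal after MEK inhibition
(`y = a·e^(−b·t) + c`).

**Statistics.** A two-level-error t-test (cell + experiment variance)
with Benjamini–Hochberg FDR, PLSR (NIPALS) with scrambled-data
significance bounds, Tjur's coefficient of discrimination, and Pearson
summaries.

## Worked example

```bash
python examples/02_trace_metrics.py
```

simulates 120 cells (60% responders), pushes them through the optical
forward model, quantifies and extracts metrics:

```
120/120 cells passed QC
       baseline     peak  amplitude  steady_state  volatility  time_to_peak
mean      0.323    1.684      1.361         0.642       0.063         18.63
...
response frequency: 0.67 +/- 0.10 across 3 experiments (truth: 0.68)
```

Baselines sit near the generated 0.3 (ERK:phosphatase ratio, relative
units), responder peaks near 2, and the estimated response frequency
matches the simulated truth. `examples/03_cascade_model.py` prints the
predicted per-isoform panel — wild type shows a ~5.4-fold stimulated
increase while GAP-insensitive mutants, already near-saturated at
baseline, show ~1.05-fold — and recovers a planted condition-dependent
suppression as the measured/predicted discrepancy. The other examples
cover calibration, phosphatase inference and the full pipeline
(`erk-rescale run --out dir/` from the shell).

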