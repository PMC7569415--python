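# Methods

## Reporter model and calibration

The package treats an EKAR-family FRET reporter as a synthetic ERK
substrate cycling between phosphorylated and unphosphorylated states.
The corrected signal `E = 1 − (CFP/YFP)/R_P` removes the optical
asymmetry between channels; `R_P` is computed as the ratio of per-channel
products of excitation intensity (relative), exposure time (ms), molar
extinction coefficient (1/M/cm), quantum yield, and two spectral overlap
integrals evaluated by trapezoidal integration on a shared wavelength
grid (1 nm by default). `E` is modeled as affine in the phosphorylated
fraction `p`; the intercept captures spontaneous fluorophore association
at `p = 0` and the slope the reporter's dynamic span, with the constraint
`intercept + slope ≤ 1` so `E` remains a fraction.

The calibration fit is unweighted ordinary least squares of `E` on `p`
(condition means; errors-in-variables in `p` are ignored because the fit
operates on replicate-averaged matched conditions). The mass-action cycle
`k_f·ERK·(1−p) = k_r·P·p` yields `ρ = p/(1−p)` with the unidentifiable
constant `k_f/k_r` fixed to 1 — all activity values are relative, and
only ratios and comparisons across conditions are meaningful.

Inversion clips `p` to `[0, 1 − 10⁻⁶)`: measurement noise routinely
pushes `E` below the intercept (negative `p`) at low activity, and the
map diverges at `p = 1`. Clip counts are reported per call and per trace;
clipping at the low end biases very low baselines slightly upward, which
is visible (and small) in the round-trip recovery numbers.

## Experiment timeline and windows

Times are minutes from experiment start. Defaults: sampling every 3 min,
stimulus at 120 min (giving the full 2 h baseline window), MEK inhibitor
at 270 min (2.5 h of stimulated recording, covering the steady-state
window at 105–135 min post-stimulus), end at 330 min (a 1 h inhibitor
window). Analysis windows: baseline `[t_stim − 120, t_stim)`;
post-stimulus mean `[t_stim, t_stim + 120]` (truncated at MEKi with a
flag); steady state `[t_stim + 105, t_stim + 135]` — a 30 min window
centred at the nominal "2 h after stimulation" point, width configurable;
peak search `(t_stim, t_stim + 60]` with ties broken to the earlier time,
because later maxima belong to the attenuation phase, not the stimulus
response.

Normalization subtracts the cell's minimum over the 1 h post-MEKi window
(mode `"min"`, the default) or the median of the whole MEKi period
(mode `"median"`), removing the cell-specific residual reporter signal.

## Single-cell metrics

Volatility is the mean of `|Δx/Δt|` over a window divided by the window
mean of `x`. The mean (rather than the sum) of the absolute derivative is
used deliberately: the sum scales with the number of samples, so only the
mean form is invariant to the sampling rate. The derivative estimator is
the forward finite difference.

The responder classifier requires both (i) the 30 min post-stimulus mean
to exceed the baseline mean by at least 5% of the dataset full scale
(99th percentile of all normalized values; a baseline-relative variant is
available via `floor_mode`), with the increase significant by a one-sided
Welch two-sample test at α = 0.05 (when both windows are exactly
constant — possible only on noiseless synthetic data — any strictly
positive increase counts as significant), and (ii) the maximum forward
derivative in the 15 min after stimulation, including the difference that
straddles the stimulation time, to exceed the maximum absolute derivative
anywhere in the baseline window. Criterion (ii) is what separates a
stimulus-locked rise from slow drift.

QC drops traces shorter than 10 finite samples or containing a missing
run longer than 3 samples, then excludes single-cell *metric values*
(not raw samples) more than 6 SD from the dataset mean, in a single pass
with moments computed once on the full input.

## Synthetic-data generator

The generator emulates the measurement campaign end to end so every
downstream stage can be tested against ground truth. Per cell: baseline
activity plus rectangular pulses with Poisson arrivals (sporadic
spontaneous activity); on stimulation, responders follow a
difference-of-exponentials trajectory whose amplitude is solved
numerically (bracketing plus Brent root find on a 0.1 min grid) so the
maximum equals the cell's `peak_rho` exactly while the long-time limit is
`steady_rho`; after MEK inhibition the trace decays exponentially from
its value at the inhibitor time. Raw intensities are produced by the
exact optical forward model with mean-one multiplicative lognormal noise
applied independently to each channel — noise is fluorescence-like,
on intensities, never additive on activity. Non-responders keep pulsing
after the stimulus and still decay after MEKi, since baseline activity is
itself MEK-dependent.

Population defaults (chosen once as the study conditions): baseline ρ
lognormal(mean 0.3, CV 0.3); responder peak lognormal(2.0, 0.25); steady
state lognormal(0.7, 0.25) clipped into [baseline, peak]; rise and
adaptation time constants lognormal(7.5, 0.15) and lognormal(35, 0.15) —
this pair puts the response maximum ~15 min after stimulation and
completes attenuation within 1.5–2 h; pulses at 1/h with amplitude
lognormal(0.1, 0.3) and 10 min duration; MEKi decay constant
lognormal(0.1/min, 0.3); intensity noise CV 2%. Three experiments by
round-robin assignment.

The generator does **not** emulate: segmentation/tracking artifacts,
photobleaching, cross-excitation or bleed-through, spatial
(nuclear/cytoplasmic) structure, receptor-level dose–response, or
correlated (e.g. autocrine) activity between cells. Passing recovery
tests therefore demonstrates correctness of the analysis chain under the
stated noise model, not robustness to those real-data pathologies.

Blot panels are generated from the cascade model itself: the noiseless
fraction-ppERK mean per line × treatment is the model steady state
(unstimulated for baseline, stimulated for the 15 min and 2 h
treatments), optionally times a treatment-dependent `external_scale`
factor representing regulation the internal model omits — this is the
planted "external factor" that the discrepancy and phosphatase-ratio
estimators are tested against. Lognormal measurement noise (CV 15% by
default) multiplies abundances and fractions, with fractions clipped to
(0, 1).

## Internal cascade model

Three composable steady states (no feedback, no regulated phosphatases,
by construction):

1. `f_GTP = k_ex/(k_ex + k_int + k_gap)` — two-state exchange/hydrolysis
   cycle; stimulation is purely `k_ex_basal → k_ex_stim` (GEF
   recruitment).
2. RAF binding from the exact quadratic for the complex, evaluated in the
   numerically stable form `2GR/(S + √(S² − 4GR))`, continuous through
   the tight-binding limit; BRAF and CRAF are pooled into one RAF species
   (the model does not resolve isoform-specific RAF dynamics; a
   per-isoform split with separate Kd values is a documented extension
   point).
3. First-order push–pull tiers,
   `f_ppMEK = a₁C/(a₁C + d_MEK)` and
   `f_ppERK = a₂·f_ppMEK·MEK_t/(a₂·f_ppMEK·MEK_t + d_ERK)` — the
   non-saturating form is justified by fractional ERK phosphorylation
   remaining well below 1 across conditions; dephosphorylation constants
   are condition-independent here because regulated phosphatase activity
   is exactly what the inference module estimates from the
   model–measurement discrepancy.

Default parameters ship in `src/erk_rescale/data/default_params.yaml`
with per-value citation tags. Mutant sets satisfy the published relative
bounds (total hydrolysis 100–800× below wild type, GAP-insensitive,
RAF Kd up to 7× wild type); the test suite relies only on those relative
bounds, never on the specific numbers. A single global set of tier rates
is used across lines. Closed forms are verified against long-time ODE
integration (LSODA, rtol 1e−10) to ≤1e−6 on random parameter grids.

One dimensional-analysis note: predictions are invariant to a common
rescaling of all concentration-unit quantities — abundances **and**
`Kd_RAF` — with `a₁, a₂` scaled inversely; `Kd_RAF` must participate
because it carries concentration units.

## Phosphatase inference

Post-MEKi decay fits use bounded nonlinear least squares of
`y = a·e^(−b(t−t_MEKi)) + c` with `a, b, c ≥ 0`, initialized from the
window endpoints (`b₀ = ln2/(window/3)`), over a 45 min window inside the
1 h inhibitor period (avoiding edge effects; configurable). The offset
`c` is included by default because traces plateau at the residual-signal
floor; a pure-exponential mode is available. A fit whose amplitude is
numerically zero leaves `b` unidentifiable; such flat fits report `b = 0`
and are flagged so group summaries can exclude them. Non-convergence is
flagged, never silent. Group summaries report medians and quartiles over
converged fits only.

The ppERK/activity ratio estimator takes replicate-level tables keyed by
(line, condition), forms the ratio of group medians, and attaches a
2.5–97.5 percentile interval from bootstrap resampling of replicates
within each group (1,000 resamples by default).

## Statistics

The two-level t-test implements the additive error model
ε_cell + ε_exp: each experiment contributes its cell mean and the
variance of that mean; a group's variance of the mean is
`var(experiment means)/J + mean(within-experiment variances)/J`, and the
test statistic is Welch-style with Satterthwaite degrees of freedom on
the two group variances (each with J−1 df). Because the across-experiment
variance already contains a within-experiment component, the procedure is
mildly conservative when cell noise dominates; Monte-Carlo calibration at
the study design (5 experiments × 100 cells) keeps the type-I error
within [0.035, 0.065] at α = 0.05.

PLSR is an in-house NIPALS PLS1 (single response, sequential deflation),
with predictors and response standardized internally so the fit is
invariant to affine rescaling of any column; reported "weights" are the
standardized regression coefficients at the chosen component count
(default 2, configurable). The scrambled-data significance bounds permute
the response rows against the predictors, refit at the chosen component
count, and take the 2.5/97.5 percentiles of each predictor's null
coefficient; percentiles use outward order-statistic interpolation
(`lower`/`higher`) because linear interpolation is anti-conservative at a
few hundred permutations. A coefficient is significant iff it falls
outside its own bounds. The permutation (rather than bootstrap) mechanism
is the natural reading of "scrambled data": it breaks the X–Y association
exactly while preserving both marginals.

Tjur's coefficient of discrimination fits a maximum-likelihood logistic
regression of the binary response on the covariate and reports the
difference in mean fitted probability between classes. Under (quasi-)
separation the ML fit diverges; the implementation falls back to an
L2-penalized fit and flags the result. BH FDR control and Pearson
correlations use the standard statsmodels/scipy routines.

## Pipeline

Stages exchange long-format CSV (one row per cell × time or per cell ×
metric) with `#`-prefixed provenance headers (stage, config hash, seed);
the manifest records package and library versions, seeds, and per-stage
counts, and deliberately contains no timestamps so identical (config,
seed) runs are byte-identical. Stimulus and inhibitor times live in the
design, never in trace files. A stage whose inputs are missing fails
naming itself and the producing stage; partial outputs are retained.

## Problem sizes and runtime

Default checks run at: 200 cells for the calibration round trip, 1,000
cells for classifier performance, 100 random parameter sets for the
ODE cross-check, 300 cells for decay recovery, 2,000 null replicates for
t-test calibration, 200–500 replications × 200 permutations for PLSR
null calibration, and a 160-cell × 8-line demo pipeline. These sizes give
stable Monte-Carlo estimates (binomial/SE arguments in the tests) while
keeping the whole suite in the low tens of seconds on one CPU.

## Known limitations

- Activity values are relative; nothing anchors absolute molar
  concentrations or the `k_f/k_r` constant.
- The responder magnitude floor references a dataset-level full scale;
  datasets containing no responding cells make that scale small and the
  floor correspondingly permissive (the derivative criterion still
  protects specificity).
- The cascade model is steady-state only; it cannot describe transient
  overshoot, and its "stimulated" condition conflates the 15 min peak
  and 2 h steady state except through the external-scale mechanism.
- The decay-based phosphatase estimate reflects phosphatases acting on
  the *reporter* substrate; transfer to endogenous substrates is an
  interpretation, not a measurement.
- Volatility compares traces on a common sampling grid; comparing
  volatilities across very different sampling rates is only meaningful
  because of the mean (not sum) convention, and remains approximate for
  strongly aliased pulses.
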