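"""Synthetic single-cell trace populations and blot panels with ground truth.

The generator emulates the measurement campaign the rest of the package
analyses: pulsatile baseline ERK activity in growth-factor-starved cells, a
stimulated peak ~15 min after EGF addition with attenuation over 1.5-2 h to
a steady state, a responder/non-responder cell mixture, exponential signal
decay after MEK inhibition, multiplicative (fluorescence-like) measurement
noise on raw intensities, and condition-level lognormal immunoblot noise.
Every emitted trace carries a ground-truth row so downstream recovery can
be tested exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import cascade
from .calibration import CalibrationCurve
from .errors import CalibrationRangeError, ValidationError
from .experiment import ExperimentDesign

_TRUTH_FIELDS = (
    "baseline_rho",
    "peak_rho",
    "rise_tau",
    "adapt_tau",
    "steady_rho",
    "pulse_rate",
    "pulse_amp",
    "pulse_duration",
    "meki_decay_b",
    "noise_cv",
)


@dataclass(frozen=True)
class CellGroundTruth:
    """True kinetic parameters of one simulated cell.

    ``baseline_rho``/``peak_rho``/``steady_rho`` are dimensionless
    ERK:phosphatase ratios; ``rise_tau``/``adapt_tau`` the response time
    constants in minutes; pulses are rectangular with Poisson arrivals at
    ``pulse_rate`` events/hour; ``meki_decay_b`` is the post-MEK-inhibitor
    exponential decay constant in 1/min.
    """

    baseline_rho: float
    responder: bool
    peak_rho: float
    rise_tau: float
    adapt_tau: float
    steady_rho: float
    pulse_rate: float
    pulse_amp: float
    pulse_duration: float
    meki_decay_b: float
    noise_cv: float

    def __post_init__(self) -> None:
        for name in _TRUTH_FIELDS:
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        if self.responder and self.peak_rho < self.baseline_rho:
            raise ValidationError("peak_rho must be >= baseline_rho for a responder")
        if self.meki_decay_b <= 0:
            raise ValidationError("meki_decay_b must be > 0")


@dataclass(frozen=True)
class Distribution:
    """One-dimensional sampling family for a ground-truth field.

    families: ``fixed`` (value), ``lognormal`` (mean, cv), ``normal``
    (mean, sd), ``uniform`` (low, high).  Lognormal is parameterized by its
    arithmetic mean and coefficient of variation, the natural description
    of positive biological heterogeneity.
    """

    family: str
    params: dict = field(default_factory=dict)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        p = self.params
        if self.family == "fixed":
            return np.full(size, float(p["value"]))
        if self.family == "lognormal":
            mean, cv = float(p["mean"]), float(p["cv"])
            if cv == 0:
                return np.full(size, mean)
            sigma2 = np.log1p(cv**2)
            mu = np.log(mean) - sigma2 / 2
            return rng.lognormal(mu, np.sqrt(sigma2), size)
        if self.family == "normal":
            return rng.normal(float(p["mean"]), float(p["sd"]), size)
        if self.family == "uniform":
            return rng.uniform(float(p["low"]), float(p["high"]), size)
        raise ValidationError(f"unknown distribution family {self.family!r}")


@dataclass(frozen=True)
class PopulationSpec:
    """Sampling plan for a heterogeneous cell population."""

    n_cells: int
    responder_fraction: float
    distributions: Mapping[str, Distribution]
    seed: int = 0
    n_experiments: int = 3
    cell_line: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        if not 0 <= self.responder_fraction <= 1:
            raise ValidationError("responder_fraction must lie in [0, 1]")
        missing = set(_TRUTH_FIELDS) - set(self.distributions)
        if missing:
            raise ValidationError(f"missing distributions for: {sorted(missing)}")


def default_population_spec(
    n_cells: int = 500,
    responder_fraction: float = 0.6,
    seed: int = 0,
    noise_cv: float = 0.02,
    cell_line: str = "synthetic",
) -> PopulationSpec:
    """Study-condition defaults.

    Baseline activity is low and heterogeneous, responder peaks sit well
    above it, rise/adapt time constants of 7.5 and 35 min place the response
    maximum ~15 min post-stimulus, attenuation completes within 1.5-2 h,
    sporadic baseline pulses arrive at ~1/h, and the post-MEKi decay
    constant centres on 0.1/min.
    """
    d = {
        "baseline_rho": Distribution("lognormal", {"mean": 0.3, "cv": 0.3}),
        "peak_rho": Distribution("lognormal", {"mean": 2.0, "cv": 0.25}),
        "rise_tau": Distribution("lognormal", {"mean": 7.5, "cv": 0.15}),
        "adapt_tau": Distribution("lognormal", {"mean": 35.0, "cv": 0.15}),
        "steady_rho": Distribution("lognormal", {"mean": 0.7, "cv": 0.25}),
        "pulse_rate": Distribution("fixed", {"value": 1.0}),
        "pulse_amp": Distribution("lognormal", {"mean": 0.1, "cv": 0.3}),
        "pulse_duration": Distribution("lognormal", {"mean": 10.0, "cv": 0.2}),
        "meki_decay_b": Distribution("lognormal", {"mean": 0.1, "cv": 0.3}),
        "noise_cv": Distribution("fixed", {"value": noise_cv}),
    }
    return PopulationSpec(
        n_cells=n_cells,
        responder_fraction=responder_fraction,
        distributions=d,
        seed=seed,
        cell_line=cell_line,
    )


def _response_curve(
    u: np.ndarray, truth: CellGroundTruth
) -> np.ndarray:
    """Deterministic stimulated trajectory at post-stimulus times u >= 0.

    Difference-of-exponentials rise/adapt shape whose amplitude is solved
    numerically so the maximum equals ``peak_rho`` and whose long-time
    limit is ``steady_rho``; the initial value is ``baseline_rho``.
    """
    b, s, pk = truth.baseline_rho, truth.steady_rho, truth.peak_rho
    r, a = truth.rise_tau, truth.adapt_tau
    if abs(a - r) < 1e-9 * max(a, r, 1.0):
        a = r * (1 + 1e-6)

    def h(uu):
        return np.exp(-uu / a) - np.exp(-uu / r)

    def base(uu):
        return s + (b - s) * np.exp(-uu / a)

    u_fine = np.arange(0.0, max(float(np.max(u, initial=0.0)), 1.0) + 0.1, 0.1)

    def overshoot(amp):
        return float(np.max(base(u_fine) + amp * h(u_fine))) - pk

    if overshoot(0.0) >= 0:  # peak not above the relaxing baseline
        amp = 0.0
    else:
        hi = 1.0
        while overshoot(hi) < 0:
            hi *= 2
            if hi > 1e12:
                raise ValidationError("response amplitude solve failed to bracket")
        amp = brentq(overshoot, 0.0, hi, xtol=1e-10)
    return base(u) + amp * h(u)


def simulate_rho_trace(
    design: ExperimentDesign, truth: CellGroundTruth, seed: int
) -> pd.DataFrame:
    """One cell's noiseless ERK:phosphatase ratio trace.

    Pre-stimulus: ``baseline_rho`` plus Poisson-timed rectangular pulses.
    Post-stimulus (responders): rise toward ``peak_rho`` with time constant
    ``rise_tau`` then relaxation toward ``steady_rho`` with ``adapt_tau``;
    non-responders keep pulsing at baseline.  Post-MEKi: exponential decay
    of the value at ``t_meki`` with rate ``meki_decay_b``.  Pulse timing is
    the only randomness; the trace is deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    t = design.times()
    rho = np.full(t.shape, truth.baseline_rho)

    pulse_end = design.t_stim if truth.responder else design.t_meki
    if truth.pulse_rate > 0 and truth.pulse_amp > 0:
        span = pulse_end - design.t_start
        n_pulses = rng.poisson(truth.pulse_rate / 60.0 * span)
        starts = np.sort(rng.uniform(design.t_start, pulse_end, n_pulses))
        for s0 in starts:
            active = (t >= s0) & (t < min(s0 + truth.pulse_duration, pulse_end))
            rho[active] += truth.pulse_amp

    if truth.responder:
        post = (t >= design.t_stim) & (t < design.t_meki)
        rho[post] = _response_curve(t[post] - design.t_stim, truth)

    # value entering the MEKi period, evaluated on the pre-MEKi rule
    if truth.responder:
        r_meki = float(_response_curve(np.array([design.t_meki - design.t_stim]), truth)[0])
    else:
        pre = t < design.t_meki
        r_meki = float(rho[pre][-1]) if np.any(pre) else truth.baseline_rho
    after = t >= design.t_meki
    rho[after] = r_meki * np.exp(-truth.meki_decay_b * (t[after] - design.t_meki))

    return pd.DataFrame({"time_min": t, "rho": rho})


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(-sigma2 / 2, np.sqrt(sigma2), size)


def rho_to_raw_intensities(
    trace: pd.DataFrame,
    curve: CalibrationCurve,
    r_p: float,
    noise_cv: float,
    seed: int,
    yfp_level: float = 1000.0,
) -> pd.DataFrame:
    """Forward model from activity ratio to raw channel intensities.

    p = rho/(1+rho), E = intercept + slope*p, CFP/YFP = R_P*(1-E); YFP is a
    per-cell constant brightness times mean-one lognormal noise and CFP the
    ratio times YFP times independent lognormal noise.  Quantifying the
    output with the same curve and R_P inverts this map up to noise.
    """
    rho = np.asarray(trace["rho"], dtype=float)
    if np.any(rho < 0):
        raise ValidationError("rho must be >= 0")
    p = rho / (1.0 + rho)
    e = curve.signal_from_phospho(p)
    if np.any(e < 0) or np.any(e >= 1):
        raise CalibrationRangeError("corrected signal E outside [0, 1) for some points")
    ratio = r_p * (1.0 - e)
    rng = np.random.default_rng(seed)
    yfp = yfp_level * _lognormal_factor(rng, noise_cv, rho.size)
    cfp = ratio * yfp * _lognormal_factor(rng, noise_cv, rho.size)
    return pd.DataFrame({"time_min": trace["time_min"].to_numpy(), "cfp": cfp, "yfp": yfp})


def simulate_population(
    spec: PopulationSpec, design: ExperimentDesign
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample a cell population and simulate every trace.

    Returns ``(traces, truth)``: a long-format frame with columns
    (cell_id, experiment_id, cell_line, time_min, rho) and a ground-truth
    frame with one row per cell.  Reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    draws = {name: spec.distributions[name].sample(rng, n) for name in _TRUTH_FIELDS}
    responders = rng.random(n) < spec.responder_fraction
    # enforce physical ordering without resampling
    draws["peak_rho"] = np.maximum(draws["peak_rho"], draws["baseline_rho"])
    draws["steady_rho"] = np.clip(
        draws["steady_rho"], draws["baseline_rho"], draws["peak_rho"]
    )
    child_seeds = rng.integers(0, 2**31 - 1, size=n)

    truth_rows, trace_frames = [], []
    for i in range(n):
        truth = CellGroundTruth(
            responder=bool(responders[i]),
            **{name: float(draws[name][i]) for name in _TRUTH_FIELDS},
        )
        tr = simulate_rho_trace(design, truth, int(child_seeds[i]))
        cell_id = f"cell{i:05d}"
        exp_id = f"exp{i % spec.n_experiments:02d}"
        tr.insert(0, "cell_line", spec.cell_line)
        tr.insert(0, "experiment_id", exp_id)
        tr.insert(0, "cell_id", cell_id)
        trace_frames.append(tr)
        truth_rows.append(
            {"cell_id": cell_id, "experiment_id": exp_id, "cell_line": spec.cell_line,
             "intensity_seed": int(child_seeds[i]) ^ 0x5A5A5A, **asdict(truth)}
        )
    traces = pd.concat(trace_frames, ignore_index=True)
    truth_df = pd.DataFrame(truth_rows)
    return traces, truth_df


def population_to_raw(
    traces: pd.DataFrame,
    truth: pd.DataFrame,
    curve: CalibrationCurve,
    r_p: float,
) -> pd.DataFrame:
    """Push every simulated rho trace through the intensity forward model.

    Per-cell noise CV and noise seed come from the ground-truth table, so
    (traces, truth) fully determine the raw output.
    """
    info = truth.set_index("cell_id")
    out = []
    for cell_id, grp in traces.groupby("cell_id", sort=False):
        row = info.loc[cell_id]
        raw = rho_to_raw_intensities(
            grp, curve, r_p, float(row["noise_cv"]), int(row["intensity_seed"])
        )
        raw.insert(0, "cell_line", grp["cell_line"].iloc[0])
        raw.insert(0, "experiment_id", grp["experiment_id"].iloc[0])
        raw.insert(0, "cell_id", cell_id)
        out.append(raw)
    return pd.concat(out, ignore_index=True)


TREATMENTS = ("baseline", "peak_15min", "steady_2h")


@dataclass(frozen=True)
class BlotPanelSpec:
    """Condition-level immunoblot panel plan.

    Each line pairs GTPase-cycle parameters with true relative abundances;
    the noiseless fraction-ppERK mean per treatment is the cascade-model
    steady state (unstimulated for baseline, stimulated otherwise), times an
    optional treatment-dependent ``external_scale`` factor representing the
    regulation the internal model omits.  Measurement noise is lognormal
    with coefficient ``measurement_cv``.
    """

    isoforms: Mapping[str, cascade.IsoformKineticParams]
    abundances: Mapping[str, cascade.Abundances]
    rates: cascade.CascadeRates
    n_replicates: int = 4
    measurement_cv: float = 0.15
    external_scale: Mapping[str, float] = field(
        default_factory=lambda: {t: 1.0 for t in TREATMENTS}
    )
    seed: int = 0
    reference_line: str | None = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.measurement_cv < 0:
            raise ValidationError("measurement_cv must be >= 0")
        if set(self.isoforms) != set(self.abundances):
            raise ValidationError("isoforms and abundances must list the same lines")


def default_blot_panel_spec(seed: int = 0, **kwargs) -> BlotPanelSpec:
    isoforms, abundances, rates, ref = cascade.load_default_params()
    return BlotPanelSpec(
        isoforms=isoforms, abundances=abundances, rates=rates,
        reference_line=ref, seed=seed, **kwargs,
    )


def simulate_blot_panel(spec: BlotPanelSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit a measured blot panel and its noiseless ground truth.

    Returns ``(panel, truth)``; the panel has one row per line x treatment
    x replicate with measured component abundances, fraction ppERK (clipped
    to (0, 1)) and relative ppERK; truth holds the noiseless means.
    """
    rng = np.random.default_rng(spec.seed)
    cv = spec.measurement_cv
    panel_rows, truth_rows = [], []
    for line in spec.isoforms:
        params, abund = spec.isoforms[line], spec.abundances[line]
        for treatment in TREATMENTS:
            stimulated = treatment != "baseline"
            ss = cascade.steady_state(params, abund, spec.rates, stimulated)
            frac = ss.f_pperk * spec.external_scale.get(treatment, 1.0)
            if not 0 < frac < 1:
                raise ValidationError(
                    f"noiseless fraction ppERK {frac:.3g} outside (0,1) for "
                    f"{line}/{treatment}; model mis-configured"
                )
            truth_rows.append(
                {"line": line, "condition": treatment, "f_pperk": frac,
                 "pperk_rel": frac * abund.erk_t}
            )
            for rep in range(spec.n_replicates):
                meas = {
                    k: v * float(_lognormal_factor(rng, cv, 1)[0])
                    for k, v in asdict(abund).items()
                }
                f_meas = float(
                    np.clip(frac * _lognormal_factor(rng, cv, 1)[0], 1e-9, 1 - 1e-9)
                )
                panel_rows.append(
                    {"line": line, "condition": treatment, "replicate": rep,
                     **meas, "f_pperk": f_meas, "pperk_rel": f_meas * meas["erk_t"]}
                )
    return pd.DataFrame(panel_rows), pd.DataFrame(truth_rows)
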