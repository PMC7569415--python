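"""Per-cell descriptors of single-cell ERK activity traces.

Each trace is normalized to its own MEK-inhibitor reference period (the
cell-specific residual reporter signal) and decomposed into: average
baseline activity over the 2 h pre-stimulus window, peak stimulated
activity and its delay, stimulated amplitude, average steady-state
activity ~2 h after stimulation, "volatility" (the mean-scaled mean
absolute derivative — a time-resolved analogue of the coefficient of
variation), and a responder classification combining a magnitude floor
with a derivative criterion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .experiment import ExperimentDesign, MEKI_WINDOW_MIN


@dataclass(frozen=True)
class QCParams:
    """Trace-quality and outlier thresholds.

    ``outlier_sd`` is the number of standard deviations from the dataset
    mean beyond which a single-cell metric value is excluded (default 6).
    """

    min_length: int = 10
    max_contiguous_gap: int = 3
    outlier_sd: float = 6.0

    def __post_init__(self) -> None:
        if self.min_length < 2:
            raise ValidationError("min_length must be >= 2")
        if self.outlier_sd <= 0:
            raise ValidationError("outlier_sd must be > 0")


@dataclass
class QCReport:
    n_input: int = 0
    n_kept: int = 0
    dropped_short: int = 0
    dropped_gap: int = 0
    outlier_values_removed: dict = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _max_gap(values: np.ndarray) -> int:
    """Longest run of consecutive missing points."""
    longest = run = 0
    for bad in ~np.isfinite(values):
        run = run + 1 if bad else 0
        longest = max(longest, run)
    return longest


def qc_filter(
    traces: pd.DataFrame, params: QCParams, value_col: str = "rho"
) -> tuple[pd.DataFrame, QCReport]:
    """Drop traces that are too short or contain long missing runs."""
    report = QCReport(outlier_values_removed={})
    keep_ids = []
    for cell_id, grp in traces.groupby("cell_id", sort=False):
        report.n_input += 1
        v = grp[value_col].to_numpy(dtype=float)
        if np.count_nonzero(np.isfinite(v)) < params.min_length:
            report.dropped_short += 1
            continue
        if _max_gap(v) > params.max_contiguous_gap:
            report.dropped_gap += 1
            continue
        keep_ids.append(cell_id)
    report.n_kept = len(keep_ids)
    kept = traces[traces["cell_id"].isin(keep_ids)].copy()
    return kept, report


METRIC_COLUMNS = (
    "baseline", "peak", "amplitude", "post_stim_mean", "steady_state",
    "volatility", "volatility_baseline", "time_to_peak", "meki_min",
)


def apply_outlier_rule(
    metrics: pd.DataFrame, params: QCParams, report: QCReport | None = None
) -> pd.DataFrame:
    """Exclude single-cell metric values > ``outlier_sd`` SDs from the
    dataset mean.

    One pass per metric, with mean and SD computed once on the full input
    (not re-estimated after removals).
    """
    out = metrics.copy()
    removed = {}
    for col in METRIC_COLUMNS:
        if col not in out.columns:
            continue
        v = out[col].to_numpy(dtype=float)
        finite = np.isfinite(v)
        if finite.sum() < 2:
            continue
        mu, sd = v[finite].mean(), v[finite].std(ddof=1)
        if sd == 0:
            continue
        bad = finite & (np.abs(v - mu) > params.outlier_sd * sd)
        if bad.any():
            out.loc[bad, col] = np.nan
            removed[col] = int(bad.sum())
    if report is not None:
        report.outlier_values_removed = removed
    else:
        out.attrs["outlier_values_removed"] = removed
    return out


def _window(times: np.ndarray, lo: float, hi: float, closed: str = "left") -> np.ndarray:
    if closed == "left":
        return (times >= lo) & (times < hi)
    if closed == "right":
        return (times > lo) & (times <= hi)
    return (times >= lo) & (times <= hi)


def normalize_trace(
    trace: pd.DataFrame,
    design: ExperimentDesign,
    mode: str = "min",
    value_col: str = "rho",
) -> pd.DataFrame:
    """Subtract the cell-specific MEK-inhibitor reference level.

    mode "min": the minimum over the 1 h window after MEKi addition;
    mode "median": the median over the whole MEKi-treated period.
    """
    t = trace["time_min"].to_numpy(dtype=float)
    v = trace[value_col].to_numpy(dtype=float)
    lo, hi = design.meki_window
    in_win = _window(t, lo, hi, closed="both")
    if not np.any(in_win & np.isfinite(v)):
        raise ValidationError(
            "trace does not cover the MEKi window; pass normalize=None to skip "
            "normalization explicitly"
        )
    if mode == "min":
        ref = np.nanmin(v[in_win])
    elif mode == "median":
        late = _window(t, design.t_meki, design.t_end, closed="both")
        ref = float(np.nanmedian(v[late]))
    else:
        raise ValidationError(f"unknown normalization mode {mode!r}")
    out = trace.copy()
    out[value_col] = v - ref
    out.attrs["normalization_mode"] = mode
    out.attrs["normalization_ref"] = float(ref)
    return out


def baseline_mean(times, values, design: ExperimentDesign) -> float:
    """Mean activity over the 2 h window before stimulation."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    lo, hi = design.baseline_window
    sel = _window(times, lo, hi, closed="left") & np.isfinite(values)
    if not sel.any():
        raise ValidationError("baseline window contains no samples")
    return float(values[sel].mean())


def peak_response(
    times, values, design: ExperimentDesign, search_horizon: float = 60.0
) -> tuple[float, float]:
    """Maximum activity within ``search_horizon`` minutes of stimulation
    and the delay to its first occurrence (ties break to the earlier time)."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    sel = _window(times, design.t_stim, design.t_stim + search_horizon, "right")
    sel &= np.isfinite(values)
    if not sel.any():
        raise ValidationError("peak search window contains no samples")
    tw, vw = times[sel], values[sel]
    i = int(np.argmax(vw))  # argmax returns the first maximum
    return float(vw[i]), float(tw[i] - design.t_stim)


def post_stim_mean(times, values, design: ExperimentDesign) -> tuple[float, bool]:
    """Mean over the 2 h window after stimulation; flags truncation by MEKi."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    hi = design.t_stim + 120.0
    truncated = hi > design.t_meki
    hi = min(hi, design.t_meki)
    sel = _window(times, design.t_stim, hi, "both") & np.isfinite(values)
    if not sel.any():
        raise ValidationError("post-stimulus window contains no samples")
    return float(values[sel].mean()), truncated


def steady_state_mean(
    times, values, design: ExperimentDesign, half_width: float = 15.0
) -> tuple[float, bool]:
    """Mean over a window centred 2 h after stimulation (default 105-135 min)."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    lo = design.t_stim + 120.0 - half_width
    hi = design.t_stim + 120.0 + half_width
    truncated = hi > design.t_meki
    hi = min(hi, design.t_meki)
    sel = _window(times, lo, hi, "both") & np.isfinite(values)
    if not sel.any():
        raise ValidationError("steady-state window contains no samples")
    return float(values[sel].mean()), truncated


def volatility(
    times, values, design: ExperimentDesign, window: str = "post"
) -> float:
    """Mean-scaled mean absolute derivative over an analysis window.

    window "post": the 2 h after stimulation; "pre": the 2 h baseline.
    The metric is scale-free (invariant to multiplying the trace by any
    c > 0) and zero iff the trace is constant on the window.  Returns NaN
    (undefined) when the window mean is nonpositive.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if window == "post":
        lo, hi = design.t_stim, design.t_stim + 120.0
        closed = "both"
    elif window == "pre":
        lo, hi = design.baseline_window
        closed = "left"
    else:
        raise ValidationError(f"unknown volatility window {window!r}")
    sel = _window(times, lo, hi, closed) & np.isfinite(values)
    tw, vw = times[sel], values[sel]
    if tw.size < 3:
        raise ValidationError("volatility window needs >= 3 samples")
    mean = vw.mean()
    if mean <= 0:
        return float("nan")
    deriv = np.abs(np.diff(vw) / np.diff(tw))
    return float(deriv.mean() / mean)


def classify_responder(
    times,
    values,
    design: ExperimentDesign,
    scale: float,
    magnitude_floor: float = 0.05,
    alpha: float = 0.05,
    floor_mode: str = "full_scale",
) -> bool:
    """Responder call combining a magnitude floor with a derivative test.

    A cell responds iff BOTH (i) its mean activity in the 30 min after
    stimulation exceeds the baseline mean by at least ``magnitude_floor``
    of ``scale`` (the dataset full-scale activity; mode "baseline" uses
    the cell's own baseline instead) AND the increase is significant by a
    Welch two-sample comparison of the two windows at ``alpha``; and (ii)
    its maximum forward-difference derivative within 15 min of stimulation
    exceeds the maximum absolute derivative anywhere in the baseline
    window.  Criterion (ii) discriminates a genuine stimulus-locked rise
    from slow drift.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    blo, bhi = design.baseline_window
    base_sel = _window(times, blo, bhi, "left") & np.isfinite(values)
    post_sel = _window(times, design.t_stim, design.t_stim + 30.0, "both")
    post_sel &= np.isfinite(values)
    if base_sel.sum() < 3 or post_sel.sum() < 3:
        raise ValidationError("baseline or post-stimulus window missing samples")
    base, post = values[base_sel], values[post_sel]

    floor_ref = scale if floor_mode == "full_scale" else base.mean()
    magnitude_ok = post.mean() - base.mean() >= magnitude_floor * floor_ref
    if magnitude_ok:
        if base.var(ddof=1) == 0 and post.var(ddof=1) == 0:
            # noiseless windows: any nonzero increase is unambiguous
            magnitude_ok = post.mean() > base.mean()
        else:
            _, p = stats.ttest_ind(post, base, equal_var=False, alternative="greater")
            magnitude_ok = p < alpha
    if not magnitude_ok:
        return False

    def _deriv(sel):
        tw, vw = times[sel], values[sel]
        return np.diff(vw) / np.diff(tw)

    d_base = _deriv(base_sel)
    rise_sel = _window(times, design.t_stim, design.t_stim + 15.0, "both")
    rise_sel &= np.isfinite(values)
    # the derivative AT stimulation is the difference straddling t_stim, so
    # include the last pre-stimulus sample in the rise window
    before = np.flatnonzero((times < design.t_stim) & np.isfinite(values))
    if before.size:
        rise_sel[before[-1]] = True
    if rise_sel.sum() < 2:
        return False
    d_rise = _deriv(rise_sel)
    return bool(np.max(d_rise) > np.max(np.abs(d_base)))


def full_scale(traces: pd.DataFrame, value_col: str = "rho", q: float = 0.99) -> float:
    """Dataset full-scale activity: an upper quantile over all samples."""
    return float(np.nanquantile(traces[value_col].to_numpy(dtype=float), q))


def compute_metrics(
    traces: pd.DataFrame,
    design: ExperimentDesign,
    value_col: str = "rho",
    normalize: str | None = "min",
    scale: float | None = None,
    qc: QCParams | None = None,
) -> tuple[pd.DataFrame, QCReport]:
    """Full per-cell metric table for a trace population.

    Applies trace-level QC, optional MEKi normalization, every per-cell
    descriptor, the responder classification (against the dataset full
    scale unless ``scale`` is given), and the 6-SD metric outlier rule.
    """
    qc = qc or QCParams()
    kept, report = qc_filter(traces, qc, value_col=value_col)
    if kept.empty:
        return pd.DataFrame(columns=["cell_id", *METRIC_COLUMNS, "responder"]), report

    norm_traces = []
    for cell_id, grp in kept.groupby("cell_id", sort=False):
        g = grp.sort_values("time_min")
        if normalize is not None:
            g = normalize_trace(g, design, mode=normalize, value_col=value_col)
        norm_traces.append(g)
    normed = pd.concat(norm_traces, ignore_index=True)
    if scale is None:
        scale = full_scale(normed, value_col=value_col)

    rows = []
    for cell_id, g in normed.groupby("cell_id", sort=False):
        t = g["time_min"].to_numpy(dtype=float)
        v = g[value_col].to_numpy(dtype=float)
        base = baseline_mean(t, v, design)
        peak, ttp = peak_response(t, v, design)
        psm, _ = post_stim_mean(t, v, design)
        ss, _ = steady_state_mean(t, v, design)
        responder = classify_responder(t, v, design, scale=scale)
        lo, hi = design.meki_window
        meki_sel = _window(t, lo, hi, "both") & np.isfinite(v)
        rows.append(
            {
                "cell_id": cell_id,
                "experiment_id": g["experiment_id"].iloc[0] if "experiment_id" in g else "exp00",
                "cell_line": g["cell_line"].iloc[0] if "cell_line" in g else "",
                "baseline": base,
                "peak": peak,
                "amplitude": peak - base,
                "post_stim_mean": psm,
                "steady_state": ss,
                "volatility": volatility(t, v, design, window="post"),
                "volatility_baseline": volatility(t, v, design, window="pre"),
                "responder": responder,
                "time_to_peak": ttp if responder else np.nan,
                "meki_min": float(np.nanmin(v[meki_sel])) if meki_sel.any() else np.nan,
            }
        )
    metrics = pd.DataFrame(rows)
    metrics = apply_outlier_rule(metrics, qc, report)
    metrics.attrs["full_scale"] = scale
    return metrics, report


def response_frequency(metrics: pd.DataFrame) -> tuple[float, float, pd.DataFrame]:
    """Fraction of responding cells, per experiment and overall.

    Returns (mean over experiments, SD over experiments, per-experiment
    table).  With no QC-passing cells the overall values are NaN.
    """
    ok = metrics.dropna(subset=["responder"]) if "responder" in metrics else metrics
    if ok.empty:
        return float("nan"), float("nan"), pd.DataFrame(columns=["experiment_id", "fraction", "n"])
    per = (
        ok.groupby("experiment_id")["responder"]
        .agg(fraction="mean", n="size")
        .reset_index()
    )
    sd = float(per["fraction"].std(ddof=1)) if len(per) > 1 else 0.0
    return float(per["fraction"].mean()), sd, per
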