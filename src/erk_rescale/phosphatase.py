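"""Inference of substrate-level phosphatase activity.

Two complementary estimators:

* the ratio of dually-phosphorylated ERK concentration to the FRET-derived
  ERK activity per condition — since the activity readout is the ratio of
  active ERK to opposing phosphatase activity, ppERK/activity isolates the
  (relative) phosphatase term; and
* the exponential decay rate of reporter signal after MEK inhibition —
  with the kinase shut off, the reporter relaxes at a rate set by the
  phosphatases acting on it, so the fitted time constant is in principle
  proportional to phosphatase activity, cell by cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ValidationError
from .experiment import ExperimentDesign


@dataclass(frozen=True)
class DecayFit:
    """Single-cell exponential decay fit y(t) = a exp(-b (t - t_meki)) + c."""

    a: float
    b: float  # decay rate constant, 1/min (constrained >= 0)
    c: float  # offset, constrained >= 0
    rss: float
    n_points: int
    converged: bool
    flat: bool = False  # amplitude indistinguishable from zero; b reported as 0
    message: str = ""


def _decay(t, a, b, c):
    return a * np.exp(-b * t) + c


def fit_meki_decay(
    trace: pd.DataFrame,
    design: ExperimentDesign,
    window: float = 45.0,
    value_col: str = "rho",
    with_offset: bool = True,
) -> DecayFit:
    """Nonlinear least-squares exponential fit over the post-MEKi window.

    Initialization: a = y(t_meki) - y_end, c = y_end, b = ln 2 / (window/3).
    The default 45 min window sits inside the 1 h MEKi period, away from
    its edges.  Non-convergence is reported, never silent.
    """
    t = trace["time_min"].to_numpy(dtype=float)
    v = trace[value_col].to_numpy(dtype=float)
    sel = (t >= design.t_meki) & (t <= design.t_meki + window) & np.isfinite(v)
    if sel.sum() < 4:
        raise ValidationError("post-MEKi window must contain >= 4 samples")
    tw = t[sel] - design.t_meki
    vw = v[sel]
    y0, y_end = vw[0], vw[-1]
    a0 = max(y0 - y_end, 1e-12)
    c0 = max(y_end, 0.0)
    b0 = np.log(2.0) / (window / 3.0)
    try:
        if with_offset:
            popt, _ = curve_fit(
                _decay, tw, vw, p0=[a0, b0, c0],
                bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=10_000, xtol=1e-13, ftol=1e-13, gtol=1e-13,
            )
            a, b, c = popt
        else:
            popt, _ = curve_fit(
                lambda tt, a, b: _decay(tt, a, b, 0.0), tw, vw, p0=[a0, b0],
                bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10_000,
                xtol=1e-13, ftol=1e-13, gtol=1e-13,
            )
            a, b = popt
            c = 0.0
        converged, message = True, ""
    except RuntimeError as exc:  # no convergence within maxfev
        a, b, c = a0, b0, c0
        converged, message = False, str(exc)
    # flat trace: with no resolvable amplitude the rate is unidentifiable
    flat = False
    span = float(np.ptp(vw))
    level = max(abs(float(np.mean(vw))), 1e-12)
    if converged and (a <= 1e-9 * level or span <= 1e-9 * level):
        b, flat = 0.0, True
    resid = vw - _decay(tw, a, b, c)
    return DecayFit(
        a=float(a), b=float(b), c=float(c),
        rss=float(np.sum(resid**2)), n_points=int(sel.sum()),
        converged=converged, flat=flat, message=message,
    )


def fit_population_decays(
    traces: pd.DataFrame, design: ExperimentDesign, window: float = 45.0,
    value_col: str = "rho",
) -> pd.DataFrame:
    """Per-cell decay fits for a long-format trace population."""
    rows = []
    for cell_id, grp in traces.groupby("cell_id", sort=False):
        fit = fit_meki_decay(grp.sort_values("time_min"), design, window, value_col)
        rows.append(
            {
                "cell_id": cell_id,
                "experiment_id": grp["experiment_id"].iloc[0] if "experiment_id" in grp else "exp00",
                "cell_line": grp["cell_line"].iloc[0] if "cell_line" in grp else "",
                "treatment": grp["treatment"].iloc[0] if "treatment" in grp else "",
                "a": fit.a, "b": fit.b, "c": fit.c, "rss": fit.rss,
                "n_points": fit.n_points, "converged": fit.converged, "flat": fit.flat,
            }
        )
    return pd.DataFrame(rows)


def group_decay_summary(
    fits: pd.DataFrame, by: tuple[str, ...] = ("cell_line", "treatment")
) -> pd.DataFrame:
    """Median and quartiles of the decay constant per group.

    Only converged fits enter the summary; the unconverged count is
    reported per group, and groups with no converged fit are omitted with
    a warning column in the output of the remaining groups.
    """
    by = [c for c in by if c in fits.columns]
    if not by:
        fits = fits.assign(_all="all")
        by = ["_all"]
    rows = []
    for key, grp in fits.groupby(by, sort=False):
        ok = grp[grp["converged"]]
        n_unconverged = int((~grp["converged"]).sum())
        if ok.empty:
            continue
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            {
                **dict(zip(by, key)),
                "median_b": float(ok["b"].median()),
                "q25_b": float(ok["b"].quantile(0.25)),
                "q75_b": float(ok["b"].quantile(0.75)),
                "n": int(len(ok)),
                "n_unconverged": n_unconverged,
            }
        )
    return pd.DataFrame(rows)


def phosphatase_ratio(
    pperk: pd.DataFrame,
    activity: pd.DataFrame,
    value_col_pperk: str = "pperk_rel",
    value_col_activity: str = "activity",
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Relative phosphatase activity as ppERK / ERK-activity per condition.

    Both inputs are replicate-level tables keyed by (line, condition); the
    point estimate is the ratio of group medians, and the 2.5/97.5
    percentile interval comes from bootstrap resampling of replicates
    within each group.  Entries whose activity median is nonpositive are
    returned flagged with NaN ratio.  The estimator is homogeneous of
    degree +1 in ppERK and -1 in activity; only relative comparisons are
    meaningful.
    """
    rng = np.random.default_rng(seed)
    keys = ["line", "condition"]
    gp = {k: g[value_col_pperk].to_numpy(dtype=float) for k, g in pperk.groupby(keys)}
    ga = {k: g[value_col_activity].to_numpy(dtype=float) for k, g in activity.groupby(keys)}
    if set(gp) != set(ga):
        raise ValidationError(
            f"mismatched (line, condition) keys: {sorted(set(gp) ^ set(ga))}"
        )
    rows = []
    for key in gp:
        num, den = gp[key], ga[key]
        med_den = np.median(den)
        if med_den <= 0:
            rows.append({"line": key[0], "condition": key[1], "ratio": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "undefined": True})
            continue
        ratio = float(np.median(num) / med_den)
        boots = np.empty(n_boot)
        for i in range(n_boot):
            bn = np.median(rng.choice(num, size=num.size, replace=True))
            bd = np.median(rng.choice(den, size=den.size, replace=True))
            boots[i] = bn / bd if bd > 0 else np.nan
        lo, hi = np.nanpercentile(boots, [2.5, 97.5])
        rows.append({"line": key[0], "condition": key[1], "ratio": ratio,
                     "ci_low": float(lo), "ci_high": float(hi), "undefined": False})
    return pd.DataFrame(rows).sort_values(keys).reset_index(drop=True)
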