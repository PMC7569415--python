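"""Ratiometric FRET-reporter correction and calibration to ERK activity.

The EKAR3 reporter is a synthetic ERK substrate whose phosphorylation
drives an intramolecular FRET interaction, read out as the CFP/YFP
intensity ratio.  The corrected signal is

    E = 1 - (CFP/YFP) / R_P

where ``R_P`` is the ratio of total optical power collected in the cyan
channel over the yellow channel, each the product of six scalar factors
(relative excitation intensity, exposure time, molar extinction
coefficient, quantum yield, and the excitation- and emission-side
spectral overlap integrals).

``E`` is linear in the fraction ``p`` of reporter molecules phosphorylated,
with a nonzero intercept from spontaneous fluorophore association.  A
mass-action phosphorylation/dephosphorylation cycle at steady state,
k_f * ERK_active * (1 - p) = k_r * P_active * p, identifies

    rho = (k_f * ERK_active) / (k_r * P_active) = p / (1 - p)

so the calibrated reporter yields a linear (relative-unit) measure of the
ERK:phosphatase activity ratio.  The constant k_f/k_r is not identifiable
and is fixed to 1; all rho values are relative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import NamedTuple, Sequence

import numpy as np
import yaml
from scipy import stats

from .errors import CalibrationRangeError, RankDeficiencyError, ValidationError

logger = logging.getLogger(__name__)

#: Phosphorylated fractions are clipped to [0, 1 - CLIP_EPS) before the
#: p -> rho map, which diverges at p = 1.
CLIP_EPS = 1e-6

_CHANNEL_FACTORS = (
    "excitation_intensity",
    "exposure_time",
    "extinction_coefficient",
    "quantum_yield",
    "excitation_overlap",
    "emission_overlap",
)


def spectral_overlap(wavelength_nm: np.ndarray, *spectra: np.ndarray) -> float:
    """Trapezoidal integral over wavelength of the product of spectra.

    Each spectrum (source emission, filter transmissivity, fluorophore
    absorption/emission) is sampled on the shared ``wavelength_nm`` grid.
    Transmissivities are expected normalized to [0, 1]; the integral itself
    carries nm units and may exceed 1.
    """
    wavelength_nm = np.asarray(wavelength_nm, dtype=float)
    product = np.ones_like(wavelength_nm)
    for s in spectra:
        s = np.asarray(s, dtype=float)
        if s.shape != wavelength_nm.shape:
            raise ValidationError("spectrum grid does not match wavelength grid")
        product = product * s
    return float(np.trapezoid(product, wavelength_nm))


@dataclass(frozen=True)
class ChannelConfig:
    """Scalar optical factors for one acquisition channel."""

    excitation_intensity: float
    exposure_time: float  # ms
    extinction_coefficient: float  # 1/M/cm
    quantum_yield: float
    excitation_overlap: float  # nm-weighted spectral integral
    emission_overlap: float

    def __post_init__(self) -> None:
        for name in _CHANNEL_FACTORS:
            if getattr(self, name) <= 0:
                raise ValidationError(f"channel factor {name} must be > 0")

    @property
    def power(self) -> float:
        p = 1.0
        for name in _CHANNEL_FACTORS:
            p *= getattr(self, name)
        return p


@dataclass(frozen=True)
class SpectralConfig:
    """Optical configuration of the cyan and yellow channels."""

    cyan: ChannelConfig
    yellow: ChannelConfig

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"cyan": asdict(self.cyan), "yellow": asdict(self.yellow)},
                fh,
                sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path) -> "SpectralConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(cyan=ChannelConfig(**raw["cyan"]), yellow=ChannelConfig(**raw["yellow"]))


def default_spectral_config() -> SpectralConfig:
    """A plausible CFP/YFP configuration; R_P is what matters downstream."""
    return SpectralConfig(
        cyan=ChannelConfig(1.0, 100.0, 32_500.0, 0.40, 12.0, 18.0),
        yellow=ChannelConfig(1.0, 100.0, 83_400.0, 0.61, 10.0, 16.0),
    )


def power_ratio(spectral: SpectralConfig) -> float:
    """Ratio of total collected power, cyan over yellow (R_P)."""
    return spectral.cyan.power / spectral.yellow.power


def ekar_signal(cfp, yfp, r_p: float):
    """Corrected reporter signal E = 1 - (CFP/YFP)/R_P, vectorized.

    Points with nonpositive YFP are returned as NaN (missing) and counted in
    a log message; negative E is allowed (it flags out-of-band measurements)
    and left unclipped.
    """
    if r_p <= 0:
        raise ValidationError("R_P must be > 0")
    cfp = np.asarray(cfp, dtype=float)
    yfp = np.asarray(yfp, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = 1.0 - (cfp / yfp) / r_p
    bad = ~(yfp > 0)
    n_bad = int(np.count_nonzero(bad))
    if n_bad:
        logger.warning("ekar_signal: %d points with nonpositive YFP set missing", n_bad)
        e = np.where(bad, np.nan, e)
    return e if e.ndim else float(e)


@dataclass(frozen=True)
class CalibrationCurve:
    """Affine map E = intercept + slope * p between corrected signal and
    phosphorylated fraction.

    The intercept is the spontaneous-association background at p = 0; the
    slope is the corrected-signal span of the reporter.  ``slope <= 0`` is
    non-physical and marked by ``warning``.
    """

    intercept: float
    slope: float
    residual_sd: float = 0.0
    n_points: int = 0
    provenance: str = ""
    stderr_intercept: float = float("nan")
    stderr_slope: float = float("nan")
    warning: str = ""

    def __post_init__(self) -> None:
        if self.intercept < 0:
            raise ValidationError("calibration intercept must be >= 0")
        if self.intercept + self.slope > 1 + 1e-12:
            raise ValidationError("intercept + slope must be <= 1 (E is a fraction)")

    def signal_from_phospho(self, p):
        return self.intercept + self.slope * np.asarray(p, dtype=float)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CalibrationCurve":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def fit_calibration(
    p_phostag: Sequence[float],
    e_mean: Sequence[float],
    provenance: str = "",
) -> CalibrationCurve:
    """Ordinary least squares of corrected signal E on phosphorylated
    fraction p (from Phos-Tag immunoblots of matched conditions).

    Mirrors a calibration design of several cell lines with and without
    growth factor, spanning the full observed activity range, with the fit
    performed on condition means.
    """
    p = np.asarray(p_phostag, dtype=float)
    e = np.asarray(e_mean, dtype=float)
    if p.size < 2 or p.size != e.size:
        raise ValidationError("need >= 2 matched (p, E) points")
    if np.ptp(p) == 0:
        raise RankDeficiencyError("all phosphorylated fractions identical; slope not identifiable")
    res = stats.linregress(p, e)
    resid = e - (res.intercept + res.slope * p)
    dof = max(p.size - 2, 1)
    warning = "" if res.slope > 0 else "non-physical calibration: slope <= 0"
    return CalibrationCurve(
        intercept=float(res.intercept),
        slope=float(res.slope),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        n_points=int(p.size),
        provenance=provenance,
        stderr_intercept=float(res.intercept_stderr),
        stderr_slope=float(res.stderr),
        warning=warning,
    )


def phospho_to_activity_ratio(p):
    """ERK:phosphatase ratio rho = p / (1 - p) for fraction p in [0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p >= 1):
        raise CalibrationRangeError("phosphorylated fraction must lie in [0, 1)")
    out = p / (1.0 - p)
    return out if out.ndim else float(out)


def activity_to_phospho(rho):
    """Inverse map p = rho / (1 + rho) for rho >= 0."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise ValidationError("rho must be >= 0")
    out = rho / (1.0 + rho)
    return out if out.ndim else float(out)


class ActivityResult(NamedTuple):
    rho: np.ndarray
    n_clipped_low: int
    n_clipped_high: int


def activity_from_signal(e, curve: CalibrationCurve) -> ActivityResult:
    """Convert corrected signal to the ERK:phosphatase ratio.

    p = (E - intercept)/slope is clipped to [0, 1 - 1e-6) — measurement
    noise routinely pushes E slightly outside the calibrated band — and the
    per-call clipping counts are reported alongside rho = p/(1-p).
    """
    if curve.slope <= 0:
        raise ValidationError("calibration slope must be > 0 to invert the curve")
    e = np.atleast_1d(np.asarray(e, dtype=float))
    p = (e - curve.intercept) / curve.slope
    low = p < 0
    high = p > 1 - CLIP_EPS
    p = np.clip(p, 0.0, 1 - CLIP_EPS)
    rho = p / (1.0 - p)
    return ActivityResult(
        rho=rho,
        n_clipped_low=int(np.count_nonzero(low & np.isfinite(e))),
        n_clipped_high=int(np.count_nonzero(high & np.isfinite(e))),
    )


def quantify_traces(raw, curve: CalibrationCurve, r_p: float):
    """Long-format (cell_id, time_min, cfp, yfp) -> (cell_id, time_min, rho).

    Returns the quantified frame and a per-trace clipping report frame.
    """
    import pandas as pd

    out = raw.copy()
    e = ekar_signal(out["cfp"].to_numpy(), out["yfp"].to_numpy(), r_p)
    res = activity_from_signal(e, curve)
    out["rho"] = res.rho
    out = out.drop(columns=["cfp", "yfp"])
    low = (np.asarray(e) - curve.intercept) / curve.slope < 0
    report = (
        out.assign(clipped_low=low)
        .groupby("cell_id", sort=False)["clipped_low"]
        .sum()
        .rename("n_clipped_low")
        .reset_index()
    )
    report.attrs["n_clipped_low_total"] = res.n_clipped_low
    report.attrs["n_clipped_high_total"] = res.n_clipped_high
    return out, report
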