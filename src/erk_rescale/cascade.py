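"""Steady-state model of the "internal" RAS -> RAF -> MEK -> ERK cascade.

The model deliberately contains only the core GTPase cycle and kinase
tiers — no feedback, scaffolds or regulated phosphatases.  Comparing its
predictions with measured ppERK isolates the contribution of those
"external" factors.

Three stages compose per cell line and condition:

1. RAS GTP loading.  A two-state exchange/hydrolysis cycle at steady
   state gives the active fraction

       f_gtp = k_ex / (k_ex + k_int + k_gap)

   where k_ex is the nucleotide-exchange rate (raised by growth-factor
   stimulation via GEF recruitment), k_int the intrinsic hydrolysis rate
   and k_gap the GAP-stimulated hydrolysis rate (near zero for
   GAP-insensitive oncogenic mutants).

2. RAF recruitment.  RAS-GTP binds RAF with dissociation constant Kd_raf;
   the bound complex C solves the exact binding quadratic

       C^2 - C (G + R + Kd) + G R = 0,   G = f_gtp * RAS_t,  R = RAF_t,

   taking the physical root C <= min(G, R).  BRAF and CRAF are pooled
   into a single RAF species.

3. Kinase tiers.  Each tier is a first-order push-pull
   (phosphorylation/dephosphorylation) cycle far from saturation:

       f_ppmek  = a1 C / (a1 C + d_mek)
       f_pperk  = a2 (f_ppmek MEK_t) / (a2 f_ppmek MEK_t + d_erk)

   justified by ppERK remaining a small-to-moderate fraction of total ERK
   across conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError


@dataclass(frozen=True)
class IsoformKineticParams:
    """Per-RAS-isoform GTPase cycle and effector-binding constants.

    Rates in 1/min; Kd_raf in the same relative concentration units as the
    immunoblot abundances.  ``provenance`` carries a citation tag for the
    biochemical source of each parameter set.
    """

    k_int: float
    k_gap: float
    k_ex_basal: float
    k_ex_stim: float
    kd_raf: float
    provenance: str = ""

    def __post_init__(self) -> None:
        for name in ("k_int", "k_gap", "k_ex_basal", "k_ex_stim"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.k_ex_stim < self.k_ex_basal:
            raise ValidationError("k_ex_stim must be >= k_ex_basal")
        if self.kd_raf <= 0:
            raise ValidationError("kd_raf must be > 0")


@dataclass(frozen=True)
class Abundances:
    """Relative pathway-component concentrations on the immunoblot scale."""

    ras_t: float
    braf_t: float
    craf_t: float
    mek_t: float
    erk_t: float

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v <= 0:
                raise ValidationError(f"abundance {name} must be > 0")

    @property
    def raf_t(self) -> float:
        return self.braf_t + self.craf_t


@dataclass(frozen=True)
class CascadeRates:
    """Composite activation/deactivation constants of the kinase tiers."""

    a_raf_mek: float = 20.0
    d_mek: float = 1.0
    a_mek_erk: float = 1.0
    d_erk: float = 1.0

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v <= 0:
                raise ValidationError(f"cascade rate {name} must be > 0")


@dataclass(frozen=True)
class SteadyState:
    f_gtp: float
    raf_active: float
    f_ppmek: float
    f_pperk: float
    pperk_rel: float


def ras_gtp_fraction(params: IsoformKineticParams, stimulated: bool) -> float:
    """Active (GTP-bound) RAS fraction at exchange/hydrolysis steady state."""
    k_ex = params.k_ex_stim if stimulated else params.k_ex_basal
    denom = k_ex + params.k_int + params.k_gap
    if denom == 0:
        raise ValidationError("all GTPase cycle rates are zero; f_gtp undefined")
    return k_ex / denom


def raf_recruitment(f_gtp: float, ras_t: float, raf_t: float, kd_raf: float) -> float:
    """Bound RAS-GTP:RAF complex from the exact binding quadratic.

    Uses the numerically stable form 2 G R / (S + sqrt(S^2 - 4 G R)) with
    S = G + R + Kd, which is continuous through the tight-binding limit.
    """
    if min(ras_t, raf_t, kd_raf) < 0 or raf_t <= 0:
        raise ValidationError("raf_recruitment inputs must be positive")
    g = f_gtp * ras_t
    if g == 0:
        return 0.0
    s = g + raf_t + kd_raf
    disc = s * s - 4.0 * g * raf_t
    if disc < 0:
        if disc < -1e-9 * s * s:
            raise ValidationError("binding quadratic discriminant negative")
        disc = 0.0
    return 2.0 * g * raf_t / (s + math.sqrt(disc))


def cascade_steady_state(
    raf_active: float, abundances: Abundances, rates: CascadeRates
) -> SteadyState:
    """Steady-state phosphorylated fractions of the MEK and ERK tiers."""
    if raf_active < 0:
        raise ValidationError("raf_active must be >= 0")
    a1, a2 = rates.a_raf_mek, rates.a_mek_erk
    f_ppmek = a1 * raf_active / (a1 * raf_active + rates.d_mek)
    active_mek = f_ppmek * abundances.mek_t
    f_pperk = a2 * active_mek / (a2 * active_mek + rates.d_erk)
    return SteadyState(
        f_gtp=float("nan"),
        raf_active=raf_active,
        f_ppmek=f_ppmek,
        f_pperk=f_pperk,
        pperk_rel=f_pperk * abundances.erk_t,
    )


def steady_state(
    params: IsoformKineticParams,
    abundances: Abundances,
    rates: CascadeRates,
    stimulated: bool,
) -> SteadyState:
    """Compose the three stages for one line and condition."""
    f_gtp = ras_gtp_fraction(params, stimulated)
    c = raf_recruitment(f_gtp, abundances.ras_t, abundances.raf_t, params.kd_raf)
    ss = cascade_steady_state(c, abundances, rates)
    return SteadyState(
        f_gtp=f_gtp,
        raf_active=ss.raf_active,
        f_ppmek=ss.f_ppmek,
        f_pperk=ss.f_pperk,
        pperk_rel=ss.pperk_rel,
    )


CONDITIONS = ("baseline", "stimulated")


def predict_panel(
    isoforms: Mapping[str, IsoformKineticParams],
    abundances: Mapping[str, Abundances],
    rates: CascadeRates,
    reference_line: str | None = None,
) -> pd.DataFrame:
    """Predicted ppERK per line under baseline and stimulated conditions.

    Returns columns (line, condition, f_gtp, f_ppmek, f_pperk, pperk_rel,
    pperk_rel_norm); the normalized column divides by the reference line's
    baseline prediction (the wild-type line by convention).  With
    ``reference_line=None`` the first line is used.
    """
    missing = set(isoforms) ^ set(abundances)
    if missing:
        raise ValidationError(f"lines without both params and abundances: {sorted(missing)}")
    lines = list(isoforms)
    if reference_line is None:
        reference_line = lines[0]
    if reference_line not in isoforms:
        raise ValidationError(f"reference line {reference_line!r} not in panel")
    rows = []
    for line in lines:
        for cond in CONDITIONS:
            ss = steady_state(isoforms[line], abundances[line], rates, cond == "stimulated")
            rows.append(
                {
                    "line": line,
                    "condition": cond,
                    "f_gtp": ss.f_gtp,
                    "f_ppmek": ss.f_ppmek,
                    "f_pperk": ss.f_pperk,
                    "pperk_rel": ss.pperk_rel,
                }
            )
    panel = pd.DataFrame(rows)
    ref = panel.loc[
        (panel["line"] == reference_line) & (panel["condition"] == "baseline"), "pperk_rel"
    ].iloc[0]
    panel["pperk_rel_norm"] = panel["pperk_rel"] / ref
    return panel


def stimulation_amplitude(panel: pd.DataFrame) -> pd.DataFrame:
    """Fold change of ppERK, stimulated over baseline, per line."""
    wide = panel.pivot(index="line", columns="condition", values="pperk_rel")
    if not {"baseline", "stimulated"} <= set(wide.columns):
        raise ValidationError("panel must contain both baseline and stimulated conditions")
    out = wide.reset_index()
    zero = out["baseline"] <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out["fold_change"] = np.where(zero, np.nan, out["stimulated"] / out["baseline"])
    out["undefined"] = zero
    return out[["line", "fold_change", "undefined"]]


def model_measurement_discrepancy(
    predicted: pd.DataFrame,
    measured: pd.DataFrame,
    reference_line: str,
    value_col: str = "pperk_rel",
) -> pd.DataFrame:
    """Measured/predicted ppERK ratio after common wild-type-baseline
    normalization.

    Both panels are first divided by their own reference-line baseline
    value, cancelling arbitrary units; the resulting per-(line, condition)
    ratio summarizes the condition-dependent "external factor" rescaling
    that the internal model omits.
    """

    def _norm(df: pd.DataFrame) -> pd.Series:
        ref_rows = df[(df["line"] == reference_line) & (df["condition"] == "baseline")]
        if ref_rows.empty:
            raise ValidationError(f"reference line {reference_line!r} baseline missing")
        return df.set_index(["line", "condition"])[value_col] / ref_rows[value_col].iloc[0]

    pred = _norm(predicted)
    meas = _norm(measured)
    if set(pred.index) != set(meas.index):
        raise ValidationError(
            f"mismatched panel keys: {sorted(set(pred.index) ^ set(meas.index))}"
        )
    ratio = (meas / pred).rename("measured_over_predicted")
    return ratio.reset_index()


def load_default_params(path=None):
    """Default per-line kinetic parameters and abundances shipped with the
    package (literature-tagged mutant GTPase/affinity values and
    immunoblot-scale abundances).

    Returns (isoforms, abundances, rates, reference_line).
    """
    if path is None:
        path = resources.files("erk_rescale.data") / "default_params.yaml"
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    isoforms = {
        line: IsoformKineticParams(**p) for line, p in raw["isoforms"].items()
    }
    abundances = {
        line: Abundances(**a) for line, a in raw["abundances"].items()
    }
    rates = CascadeRates(**raw["cascade_rates"])
    return isoforms, abundances, rates, raw["reference_line"]
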