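"""End-to-end orchestration: simulate -> quantify -> metrics -> model ->
phosphatase inference -> statistics.

Each stage reads only the long-format CSV outputs of earlier stages, writes
its own outputs with provenance headers, and records counts in the run
manifest.  Identical (config, seed) runs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cascade, io, metrics as tm, phosphatase as ph, stats as st, synthetic as syn
from .calibration import CalibrationCurve, default_spectral_config, power_ratio, quantify_traces
from .errors import DependencyError, ValidationError
from .experiment import ExperimentDesign

STAGES = ("simulate", "quantify", "metrics", "model", "phosphatase", "stats")

#: Demo panel: eight synthetic cell lines mirroring a single-RAS-isoform
#: MEF panel.  ``baseline_mean`` scales resting activity (mutants elevated),
#: ``responder_fraction`` the EGF response likelihood (lowest for the
#: severe Q61R mutant), ``decay_b_mean`` the post-MEKi decay constant.
DEFAULT_LINES = {
    "HRAS_WT":    {"baseline_mean": 0.35, "responder_fraction": 0.85, "decay_b_mean": 0.08},
    "KRAS_WT":    {"baseline_mean": 0.25, "responder_fraction": 0.90, "decay_b_mean": 0.08},
    "NRAS_WT":    {"baseline_mean": 0.28, "responder_fraction": 0.85, "decay_b_mean": 0.08},
    "KRAS_G12C":  {"baseline_mean": 0.55, "responder_fraction": 0.60, "decay_b_mean": 0.13},
    "KRAS_G12D":  {"baseline_mean": 0.45, "responder_fraction": 0.65, "decay_b_mean": 0.12},
    "KRAS_G12V":  {"baseline_mean": 0.45, "responder_fraction": 0.65, "decay_b_mean": 0.12},
    "KRAS_Q61R":  {"baseline_mean": 0.60, "responder_fraction": 0.30, "decay_b_mean": 0.14},
    "BRAF_V600E": {"baseline_mean": 0.40, "responder_fraction": 0.50, "decay_b_mean": 0.10},
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run; serializable to YAML."""

    seed: int = 0
    n_cells: int = 500
    lines: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_LINES.items()})
    design: dict = field(default_factory=dict)
    calibration: dict = field(default_factory=lambda: {"intercept": 0.08, "slope": 0.45})
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    normalize: str = "min"
    noise_cv: float = 0.02
    reference_line: str = "KRAS_WT"

    def design_obj(self) -> ExperimentDesign:
        return ExperimentDesign(**self.design)

    def curve_obj(self) -> CalibrationCurve:
        return CalibrationCurve(**self.calibration)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _line_population_spec(cfg: RunConfig, line: str, n_cells: int, seed: int):
    opts = cfg.lines[line]
    spec = syn.default_population_spec(
        n_cells=n_cells,
        responder_fraction=float(opts.get("responder_fraction", 0.6)),
        seed=seed,
        noise_cv=cfg.noise_cv,
        cell_line=line,
    )
    d = dict(spec.distributions)
    d["baseline_rho"] = syn.Distribution(
        "lognormal", {"mean": float(opts.get("baseline_mean", 0.3)), "cv": 0.3}
    )
    d["meki_decay_b"] = syn.Distribution(
        "lognormal", {"mean": float(opts.get("decay_b_mean", 0.1)), "cv": 0.3}
    )
    return dataclasses.replace(spec, distributions=d)


def _require(outdir: Path, stage: str, *names: str) -> None:
    for name in names:
        if not (outdir / name).exists():
            raise DependencyError(
                f"stage {stage!r} requires {name}; run its producing stage first"
            )


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the enabled stages in order; returns the manifest dict.

    A stage failure raises with the failing stage named; outputs written
    before the failure are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = io.config_hash(asdict(config))
    design = config.design_obj()
    curve = config.curve_obj()
    spectral = default_spectral_config()
    r_p = power_ratio(spectral)
    manifest = {
        "package_version": __version__,
        "config_hash": cfg_hash,
        "seed": config.seed,
        "stages": {},
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }

    def _write(df, name, stage):
        io.write_csv(df, outdir / name, stage=stage, cfg_hash=cfg_hash, seed=config.seed)

    enabled = {s: bool(config.stages.get(s, True)) for s in STAGES}

    try:
        if enabled["simulate"]:
            seeds = np.random.SeedSequence(config.seed).generate_state(len(config.lines) + 1)
            raw_frames, truth_frames = [], []
            for i, line in enumerate(config.lines):
                n = config.n_cells // len(config.lines)
                spec = _line_population_spec(config, line, max(n, 1), int(seeds[i] % 2**31))
                traces, truth = syn.simulate_population(spec, design)
                traces["cell_id"] = line + "_" + traces["cell_id"]
                truth["cell_id"] = line + "_" + truth["cell_id"]
                raw = syn.population_to_raw(traces, truth, curve, r_p)
                raw_frames.append(raw)
                truth_frames.append(truth)
            raw_all = pd.concat(raw_frames, ignore_index=True)
            truth_all = pd.concat(truth_frames, ignore_index=True)
            _write(raw_all, "raw.csv", "simulate")
            _write(truth_all, "truth.csv", "simulate")
            blot_spec = syn.default_blot_panel_spec(seed=int(seeds[-1] % 2**31))
            panel, blot_truth = syn.simulate_blot_panel(blot_spec)
            _write(panel, "blot_panel.csv", "simulate")
            _write(blot_truth, "blot_truth.csv", "simulate")
            manifest["stages"]["simulate"] = {
                "n_cells": int(truth_all.shape[0]),
                "n_lines": len(config.lines),
                "n_blot_rows": int(panel.shape[0]),
            }

        if enabled["quantify"]:
            _require(outdir, "quantify", "raw.csv")
            raw_all = io.read_csv(outdir / "raw.csv")
            rho, clip_report = quantify_traces(raw_all, curve, r_p)
            _write(rho, "rho.csv", "quantify")
            manifest["stages"]["quantify"] = {
                "n_points": int(rho.shape[0]),
                "n_clipped_low": clip_report.attrs["n_clipped_low_total"],
                "n_clipped_high": clip_report.attrs["n_clipped_high_total"],
            }

        if enabled["metrics"]:
            _require(outdir, "metrics", "rho.csv")
            rho = io.read_csv(outdir / "rho.csv")
            met, qc_report = tm.compute_metrics(rho, design, normalize=config.normalize)
            _write(met, "metrics.csv", "metrics")
            qc_report.to_json(outdir / "qc_report.json")
            freq_rows = []
            for line, grp in met.groupby("cell_line", sort=False):
                mean, sd, _ = tm.response_frequency(grp)
                freq_rows.append({"line": line, "response_frequency": mean, "sd": sd,
                                  "n_cells": int(grp.shape[0])})
            _write(pd.DataFrame(freq_rows), "response_frequency.csv", "metrics")
            manifest["stages"]["metrics"] = {
                "n_cells_in": qc_report.n_input,
                "n_cells_kept": qc_report.n_kept,
                "outliers_removed": qc_report.outlier_values_removed,
            }

        if enabled["model"]:
            _require(outdir, "model", "blot_panel.csv")
            isoforms, abundances, rates, ref = cascade.load_default_params()
            pred = cascade.predict_panel(isoforms, abundances, rates, reference_line=ref)
            _write(pred, "panel_predicted.csv", "model")
            amp = cascade.stimulation_amplitude(pred)
            _write(amp, "stimulation_amplitude.csv", "model")
            panel = io.read_csv(outdir / "blot_panel.csv")
            measured = (
                panel[panel["condition"].isin(["baseline", "steady_2h"])]
                .replace({"condition": {"steady_2h": "stimulated"}})
                .groupby(["line", "condition"], as_index=False)["pperk_rel"]
                .median()
            )
            disc = cascade.model_measurement_discrepancy(pred, measured, ref)
            _write(disc, "model_discrepancy.csv", "model")
            manifest["stages"]["model"] = {"n_lines": int(pred["line"].nunique())}

        if enabled["phosphatase"]:
            _require(outdir, "phosphatase", "rho.csv", "metrics.csv", "blot_panel.csv")
            rho = io.read_csv(outdir / "rho.csv")
            fits = ph.fit_population_decays(rho, design)
            _write(fits, "decays.csv", "phosphatase")
            summary = ph.group_decay_summary(fits, by=("cell_line",))
            _write(summary, "decay_summary.csv", "phosphatase")
            met = io.read_csv(outdir / "metrics.csv")
            activity = (
                met.melt(
                    id_vars=["cell_line"],
                    value_vars=["baseline", "peak", "steady_state"],
                    var_name="condition", value_name="activity",
                )
                .replace({"condition": {"peak": "peak_15min", "steady_state": "steady_2h"}})
                .rename(columns={"cell_line": "line"})
                .dropna(subset=["activity"])
            )
            panel = io.read_csv(outdir / "blot_panel.csv")
            shared = sorted(set(panel["line"]) & set(activity["line"]))
            ratios = ph.phosphatase_ratio(
                panel[panel["line"].isin(shared)],
                activity[activity["line"].isin(shared)],
                seed=config.seed,
            )
            _write(ratios, "phosphatase_ratios.csv", "phosphatase")
            manifest["stages"]["phosphatase"] = {
                "n_fits": int(fits.shape[0]),
                "n_unconverged": int((~fits["converged"]).sum()),
            }

        if enabled["stats"]:
            _require(outdir, "stats", "metrics.csv", "blot_panel.csv")
            met = io.read_csv(outdir / "metrics.csv")
            ref = config.reference_line
            ref_groups = [
                g["baseline"].dropna().to_numpy()
                for _, g in met[met["cell_line"] == ref].groupby("experiment_id")
            ]
            rows = []
            for line, grp in met.groupby("cell_line", sort=False):
                if line == ref:
                    continue
                groups = [g["baseline"].dropna().to_numpy()
                          for _, g in grp.groupby("experiment_id")]
                t, p, df = st.hierarchical_ttest(groups, ref_groups)
                rows.append({"line": line, "metric": "baseline", "t": t, "p": p, "df": df})
            tests = pd.DataFrame(rows)
            if not tests.empty:
                flags, p_adj = st.bh_fdr(tests["p"].to_numpy())
                tests["p_fdr"] = p_adj
                tests["significant"] = flags
            _write(tests, "stats_tests.csv", "stats")

            panel = io.read_csv(outdir / "blot_panel.csv")
            x = panel[["ras_t", "braf_t", "craf_t", "mek_t", "erk_t"]].to_numpy()
            egf = (panel["condition"] != "baseline").to_numpy(dtype=float)[:, None]
            x = np.hstack([egf, x])
            names = ["EGF", "RAS", "BRAF", "CRAF", "MEK", "ERK"]
            res = st.plsr_null_bounds(
                x, panel["pperk_rel"].to_numpy(), n_perm=500, seed=config.seed,
                n_components=2, predictors=names,
            )
            plsr_df = pd.DataFrame(
                {"predictor": names, "weight": res.weights,
                 "bound_low": res.null_bounds[:, 0], "bound_high": res.null_bounds[:, 1],
                 "significant": res.significant}
            )
            _write(plsr_df, "plsr_weights.csv", "stats")
            ve = pd.DataFrame(
                {"n_components": np.arange(1, res.variance_explained.size + 1),
                 "variance_explained_pct": res.variance_explained}
            )
            _write(ve, "plsr_variance_explained.csv", "stats")
            manifest["stages"]["stats"] = {
                "n_tests": int(tests.shape[0]),
                "n_significant": int(tests["significant"].sum()) if not tests.empty else 0,
            }
    except Exception as exc:
        failed = next((s for s in STAGES if enabled.get(s) and s not in manifest["stages"]), "?")
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
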