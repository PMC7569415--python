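"""Per-cell trace descriptors: windows, volatility, responder logic, QC."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import erk_rescale as er
from erk_rescale.errors import ValidationError
from erk_rescale.metrics import (
    QCParams, apply_outlier_rule, baseline_mean, classify_responder,
    full_scale, normalize_trace, peak_response, post_stim_mean, qc_filter,
    steady_state_mean, volatility,
)


def _trace(design, values):
    t = design.times()
    return pd.DataFrame({"cell_id": "c0", "time_min": t, "rho": values[: t.size]})


def _const(design, c):
    return _trace(design, np.full(design.times().size, float(c)))


class TestWindows:
    def test_baseline_mean_constant(self, design):
        tr = _const(design, 0.7)
        assert baseline_mean(tr.time_min, tr.rho, design) == pytest.approx(0.7)

    def test_baseline_mean_linear_ramp_is_midpoint(self, design):
        t = design.times()
        v = 0.01 * t  # linear in time
        lo, hi = design.baseline_window
        sel = (t >= lo) & (t < hi)
        mid = 0.01 * t[sel].mean()
        assert baseline_mean(t, v, design) == pytest.approx(mid)

    def test_peak_and_delay(self, design):
        t = design.times()
        v = np.full(t.size, 0.1)
        v[t == design.t_stim + 15] = 0.8
        peak, ttp = peak_response(t, v, design)
        assert peak == pytest.approx(0.8)
        assert ttp == pytest.approx(15.0)

    def test_peak_tie_breaks_to_earlier_time(self, design):
        t = design.times()
        v = np.full(t.size, 0.1)
        v[t == design.t_stim + 12] = 0.8
        v[t == design.t_stim + 30] = 0.8
        _, ttp = peak_response(t, v, design)
        assert ttp == pytest.approx(12.0)

    def test_constant_trace_post_and_steady(self, design):
        tr = _const(design, 0.42)
        psm, _ = post_stim_mean(tr.time_min, tr.rho, design)
        ss, _ = steady_state_mean(tr.time_min, tr.rho, design)
        assert psm == pytest.approx(0.42)
        assert ss == pytest.approx(0.42)

    def test_step_at_stimulus(self, design):
        t = design.times()
        v = np.where(t >= design.t_stim, 1.0, 0.0)
        psm, _ = post_stim_mean(t, v, design)
        assert psm == pytest.approx(1.0)

    def test_empty_window_raises(self, design):
        t = np.array([0.0, 3.0, 6.0])
        with pytest.raises(ValidationError):
            peak_response(t, np.ones(3), design)


class TestNormalization:
    def test_min_mode_shifts_by_window_minimum(self, design, quiet_truth):
        tr = er.simulate_rho_trace(design, quiet_truth, 0)
        lo, hi = design.meki_window
        m = tr[(tr.time_min >= lo) & (tr.time_min <= hi)]["rho"].min()
        out = normalize_trace(tr, design)
        assert np.allclose(out["rho"], tr["rho"] - m)
        in_win = out[(out.time_min >= lo) & (out.time_min <= hi)]
        assert in_win["rho"].min() == pytest.approx(0.0, abs=1e-15)

    def test_min_mode_idempotent(self, design, quiet_truth):
        tr = er.simulate_rho_trace(design, quiet_truth, 0)
        once = normalize_trace(tr, design)
        twice = normalize_trace(once, design)
        assert np.allclose(once["rho"], twice["rho"])

    def test_missing_meki_window_instructs_skip(self, design):
        tr = _const(design, 1.0)
        tr = tr[tr.time_min < design.t_meki]
        with pytest.raises(ValidationError, match="skip normalization"):
            normalize_trace(tr, design)

    def test_offset_removal_improves_baseline_recovery(self, design, quiet_truth):
        """Normalization removes a per-cell additive offset (residual
        reporter signal), so recovered baselines improve versus raw."""
        rng = np.random.default_rng(4)
        errs_raw, errs_norm = [], []
        for i in range(30):
            offset = rng.uniform(0.05, 0.3)
            tr = er.simulate_rho_trace(design, quiet_truth, seed=i)
            shifted = tr.assign(rho=tr["rho"] + offset)
            b_raw = baseline_mean(shifted.time_min, shifted.rho, design)
            normed = normalize_trace(shifted, design)
            b_norm = baseline_mean(normed.time_min, normed.rho, design)
            errs_raw.append(abs(b_raw - quiet_truth.baseline_rho))
            errs_norm.append(abs(b_norm - quiet_truth.baseline_rho))
        assert np.mean(errs_norm) < np.mean(errs_raw)


class TestVolatility:
    def test_constant_trace_zero(self, design):
        tr = _const(design, 1.3)
        assert volatility(tr.time_min, tr.rho, design) == 0.0

    def test_alternating_closed_form(self, design):
        a, d = 0.5, 0.2
        t = design.times()
        v = np.where((np.arange(t.size) % 2) == 0, a, a + d)
        lo, hi = design.baseline_window
        sel = (t >= lo) & (t < hi)
        # the half-open baseline window holds an even number of samples,
        # so the alternating mean is exactly a + d/2
        assert sel.sum() % 2 == 0
        expected = (d / design.sampling_interval) / (a + d / 2)
        assert volatility(t, v, design, window="pre") == pytest.approx(expected, rel=1e-12)

    @given(st.floats(0.01, 100.0), st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, c, seed):
        design = er.ExperimentDesign()
        rng = np.random.default_rng(seed)
        t = design.times()
        v = rng.uniform(0.1, 1.0, t.size)
        v1 = volatility(t, v, design)
        v2 = volatility(t, c * v, design)
        assert v2 == pytest.approx(v1, rel=1e-9)

    def test_nonpositive_mean_undefined(self, design):
        tr = _const(design, 0.0)
        assert np.isnan(volatility(tr.time_min, tr.rho, design))


class TestResponderClassification:
    def test_step_responder(self, design):
        t = design.times()
        v = np.where(t >= design.t_stim, 1.5, 1.0)
        assert classify_responder(t, v, design, scale=1.5)

    def test_flat_noise_rarely_flagged(self, design):
        rng = np.random.default_rng(0)
        t = design.times()
        false_pos = 0
        n = 300
        for _ in range(n):
            v = 1.0 + rng.normal(0, 0.01, t.size)
            false_pos += classify_responder(t, v, design, scale=2.0)
        assert false_pos / n <= 0.05

    def test_slow_drift_rejected_by_derivative_criterion(self, design):
        rng = np.random.default_rng(1)
        t = design.times()
        # +20% by 2 h, tiny noise so baseline derivative stays comparable
        drift = np.where(t >= design.t_stim, 1.0 + 0.2 * (t - design.t_stim) / 120.0, 1.0)
        v = drift + rng.normal(0, 0.005, t.size)
        assert not classify_responder(t, v, design, scale=1.0)

    def test_recovery_on_simulated_population(self, small_population, design):
        met, _ = er.compute_metrics(small_population["rho"], design)
        m = met.merge(
            small_population["truth"][["cell_id", "responder"]],
            on="cell_id", suffixes=("", "_true"),
        )
        truth = m["responder_true"].astype(bool)
        call = m["responder"].astype(bool)
        sens = (call & truth).sum() / truth.sum()
        spec = (~call & ~truth).sum() / (~truth).sum()
        assert sens >= 0.9 and spec >= 0.9

    def test_median_time_to_peak_near_fifteen(self, small_population, design):
        met, _ = er.compute_metrics(small_population["rho"], design)
        ttp = met["time_to_peak"].dropna()
        assert abs(ttp.median() - 15.0) <= 2 * design.sampling_interval


class TestQC:
    def test_clean_population_fully_kept(self, small_population):
        kept, report = qc_filter(small_population["rho"], QCParams())
        assert report.n_kept == report.n_input
        assert report.dropped_short == 0 and report.dropped_gap == 0

    def test_short_and_gappy_traces_dropped(self, design):
        t = design.times()
        good = pd.DataFrame({"cell_id": "good", "time_min": t, "rho": np.ones(t.size)})
        short = good.iloc[:5].assign(cell_id="short")
        gap_v = np.ones(t.size)
        gap_v[10:20] = np.nan
        gappy = pd.DataFrame({"cell_id": "gappy", "time_min": t, "rho": gap_v})
        kept, report = qc_filter(pd.concat([good, short, gappy]), QCParams())
        assert set(kept["cell_id"]) == {"good"}
        assert report.dropped_short == 1 and report.dropped_gap == 1

    def test_six_sd_outlier_removed(self):
        rng = np.random.default_rng(0)
        base = rng.normal(1.0, 0.1, 400)
        mu, sd = base.mean(), base.std(ddof=1)
        df = pd.DataFrame({"baseline": np.append(base, mu + 10 * sd)})
        out = apply_outlier_rule(df, QCParams())
        assert out["baseline"].isna().sum() == 1
        assert np.isnan(out["baseline"].iloc[-1])

    def test_outlier_rule_idempotent_on_simulated_metrics(self, small_population, design):
        met, _ = er.compute_metrics(small_population["rho"], design)
        once = apply_outlier_rule(met, QCParams())
        twice = apply_outlier_rule(once, QCParams())
        pd.testing.assert_frame_equal(once, twice)


class TestResponseFrequency:
    def test_all_responders(self):
        met = pd.DataFrame(
            {"experiment_id": ["e0", "e0", "e1"], "responder": [True, True, True]}
        )
        mean, sd, per = er.response_frequency(met)
        assert mean == 1.0

    def test_empty_input_flagged(self):
        mean, sd, per = er.response_frequency(
            pd.DataFrame(columns=["experiment_id", "responder"])
        )
        assert np.isnan(mean)

    def test_order_invariance(self, small_population, design):
        rho = small_population["rho"]
        met1, _ = er.compute_metrics(rho, design)
        shuffled = rho.sample(frac=1.0, random_state=0).sort_values(
            ["cell_id", "time_min"]
        )
        met2, _ = er.compute_metrics(shuffled, design)
        m1 = met1.sort_values("cell_id").reset_index(drop=True)
        m2 = met2.sort_values("cell_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(m1, m2)


class TestPulseDutyCycle:
    def test_baseline_mean_matches_expected_duty_cycle(self, design, quiet_truth):
        """Poisson pulses of rate r/h, amplitude a, duration d add a*r*d/60
        to the expected baseline mean."""
        rate, amp, dur = 2.0, 0.4, 12.0
        truth = dataclasses.replace(
            quiet_truth, responder=False, pulse_rate=rate, pulse_amp=amp,
            pulse_duration=dur,
        )
        means = []
        for i in range(200):
            tr = er.simulate_rho_trace(design, truth, seed=i)
            means.append(baseline_mean(tr.time_min, tr.rho, design))
        expected = truth.baseline_rho + amp * rate * dur / 60.0
        # Monte-Carlo tolerance: SE of the mean over 200 cells
        assert np.mean(means) == pytest.approx(expected, abs=0.02)
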