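"""Leak subtraction, persistent current, Boltzmann fits, recovery."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from navdup.ephys_analysis import (
    Sweep,
    VoltageClampTraceSet,
    gv_curve,
    leak_subtract,
    persistent_percent,
    read_traces,
    recovery_fractions,
    ssi_curve,
    write_traces,
)
from navdup.synthetic_data import TraceSimSpec, simulate_traces


def clean(spec: TraceSimSpec) -> TraceSimSpec:
    """Noise-free, leak-free copy of a trace spec (ground-truth source)."""
    return replace(spec, noise_sd=0.0, g_leak=0.0, leak_offset=0.0)


class TestLeakSubtract:
    def test_pure_leak_family_cancels_exactly(self):
        spec = TraceSimSpec(g_max=0.0, noise_sd=0.0, g_leak=0.004,
                            leak_offset=0.1, seed=0)
        ts = simulate_traces(spec, protocol="step")
        corrected, fit = leak_subtract(ts)
        assert fit.conductance == pytest.approx(0.004, rel=1e-6)
        for sw in corrected.sweeps:
            np.testing.assert_allclose(sw.current, 0.0, atol=1e-10)

    # steeper activation keeps the subthreshold fit range truly
    # channel-free, isolating the leak-subtraction arithmetic
    STEEP = dict(act_v_half=-35.0, act_k=5.0)

    def test_zero_leak_input_is_unchanged(self):
        spec = TraceSimSpec(noise_sd=0.0, g_leak=0.0, leak_offset=0.0,
                            seed=0, **self.STEEP)
        ts = simulate_traces(spec, protocol="step")
        corrected, fit = leak_subtract(ts)
        assert abs(fit.conductance) < 1e-5
        for before, after in zip(ts.sweeps, corrected.sweeps):
            np.testing.assert_allclose(after.current, before.current,
                                       atol=2e-3)

    def test_subthreshold_sweeps_zeroed_suprathreshold_keep_channel(self):
        spec = TraceSimSpec(noise_sd=0.0, seed=0, **self.STEEP)
        ts = simulate_traces(spec, protocol="step")
        truth = simulate_traces(clean(spec), protocol="step")
        corrected, _ = leak_subtract(ts)
        for sw, sw_true in zip(corrected.sweeps, truth.sweeps):
            if sw.voltage <= -100:
                np.testing.assert_allclose(sw.current, 0.0, atol=2e-3)
            else:
                np.testing.assert_allclose(sw.current, sw_true.current,
                                           atol=6e-3)

    def test_single_voltage_family_requires_explicit_params(self):
        spec = TraceSimSpec(seed=0)
        ts = simulate_traces(spec, protocol="recovery")
        with pytest.raises(ValueError, match="distinct subthreshold"):
            leak_subtract(ts)


class TestPersistentPercent:
    def test_zero_persistent_fraction_reads_near_zero(self):
        spec = TraceSimSpec(persistent_fraction=0.0, seed=1)
        ts = simulate_traces(spec, protocol="step")
        corrected, _ = leak_subtract(ts)
        res = persistent_percent(corrected)
        row = res.table.loc[res.table.voltage == -35.0]
        assert abs(float(row.pct_inap.iloc[0])) < 0.5

    def test_rectangular_current_is_one_hundred_percent(self):
        # hand-built non-inactivating square pulse
        fs = 50_000.0
        segs = [(-120.0, 2.0), (-20.0, 30.0), (-120.0, 2.0)]
        n = [int(d * fs / 1000) for _, d in segs]
        cur = np.concatenate([np.zeros(n[0]), -np.ones(n[1]), np.zeros(n[2])])
        ts = VoltageClampTraceSet(
            protocol="step", sampling_hz=fs, holding_mv=-120.0,
            sweeps=[Sweep("s0", segs, cur, voltage=-20.0)],
            meta={"pulse_segment": 1})
        res = persistent_percent(ts, noise_floor_sd=0.0)
        assert float(res.table.pct_inap.iloc[0]) == pytest.approx(100.0,
                                                                  abs=0.01)

    @pytest.mark.parametrize("p", [0.01, 0.06, 0.10])
    def test_recovers_generator_truth_after_leak_and_noise(self, p):
        spec = TraceSimSpec(persistent_fraction=p, seed=7)
        truth_ts = simulate_traces(clean(spec), protocol="step")
        truth = persistent_percent(truth_ts).table.set_index("voltage")
        ts = simulate_traces(spec, protocol="step")
        corrected, _ = leak_subtract(ts)
        est = persistent_percent(corrected).table.set_index("voltage")
        v = -35.0
        assert est.loc[v, "pct_inap"] == pytest.approx(
            truth.loc[v, "pct_inap"], abs=0.5)

    def test_subthreshold_sweeps_skipped_below_noise_floor(self):
        spec = TraceSimSpec(persistent_fraction=0.0, seed=2)
        ts = simulate_traces(spec, protocol="step")
        corrected, _ = leak_subtract(ts)
        res = persistent_percent(corrected)
        assert "step_000" in res.skipped  # -100 mV: no channel current


class TestGvCurve:
    def test_parameter_recovery(self):
        spec = TraceSimSpec(seed=4)  # act_v_half=-40, act_k=7
        ts = simulate_traces(spec, protocol="step")
        corrected, _ = leak_subtract(ts)
        fit = gv_curve(corrected, reversal_mv=50.0)
        assert fit.converged
        assert fit.v_half == pytest.approx(-40.0, abs=1.0)
        assert fit.k == pytest.approx(7.0, abs=0.5)

    def test_value_at_v_half_is_half_amplitude(self):
        spec = TraceSimSpec(seed=4)
        ts = simulate_traces(spec, protocol="step")
        corrected, _ = leak_subtract(ts)
        fit = gv_curve(corrected, reversal_mv=50.0)
        half = fit.amplitude / (1 + np.exp(0.0))
        assert half == pytest.approx(0.5 * fit.amplitude)

    def test_sweep_order_reversal_leaves_fit_unchanged(self):
        spec = TraceSimSpec(seed=4)
        ts = simulate_traces(spec, protocol="step")
        corrected, _ = leak_subtract(ts)
        reversed_ts = replace(corrected, sweeps=corrected.sweeps[::-1])
        f1 = gv_curve(corrected, reversal_mv=50.0)
        f2 = gv_curve(reversed_ts, reversal_mv=50.0)
        assert f1.v_half == pytest.approx(f2.v_half)
        assert f1.k == pytest.approx(f2.k)


class TestSsiCurve:
    def leak_params(self):
        ts = simulate_traces(TraceSimSpec(seed=0), protocol="step")
        return leak_subtract(ts)[1]

    def test_zero_pedestal_family(self):
        ts = simulate_traces(TraceSimSpec(persistent_fraction=0.0, seed=5),
                             protocol="ssi")
        corrected, _ = leak_subtract(ts, params=self.leak_params())
        fit = ssi_curve(corrected)
        assert fit.pedestal == pytest.approx(0.0, abs=0.02)
        assert fit.v_half == pytest.approx(-70.0, abs=1.0)
        assert fit.k == pytest.approx(6.0, abs=0.5)

    def test_nonzero_pedestal_recovered(self):
        # ground truth from the noiseless leak-free family: the availability
        # pedestal of the traces tracks the persistent fraction to ~0.015
        # (transient-peak attenuation and the brief gap-step drift), and
        # the estimator must match that truth closely
        spec = TraceSimSpec(persistent_fraction=0.05, seed=5)
        truth = ssi_curve(simulate_traces(clean(spec), protocol="ssi")).pedestal
        assert truth == pytest.approx(0.05, abs=0.02)
        ts = simulate_traces(spec, protocol="ssi")
        corrected, _ = leak_subtract(ts, params=self.leak_params())
        fit = ssi_curve(corrected)
        assert fit.pedestal == pytest.approx(truth, abs=0.02)

    def test_full_availability_at_most_negative_conditioning(self):
        ts = simulate_traces(TraceSimSpec(noise_sd=0.0, g_leak=0.0, seed=0),
                             protocol="ssi")
        fit = ssi_curve(ts)
        most_negative = fit.data.sort_values("voltage").iloc[0]
        assert most_negative["value"] == pytest.approx(1.0, abs=0.02)


class TestRecovery:
    def test_single_exponential_closed_form(self):
        spec = TraceSimSpec(tau_rec_ms=2.0, noise_sd=0.0, g_leak=0.0, seed=0)
        ts = simulate_traces(spec, protocol="recovery")
        res = recovery_fractions(ts)
        assert res.fraction_at(0.5) == pytest.approx(1 - np.exp(-0.25),
                                                     abs=0.01)
        assert res.fraction_at(1.0) == pytest.approx(1 - np.exp(-0.5),
                                                     abs=0.01)

    def test_long_interval_recovers_fully(self):
        spec = TraceSimSpec(noise_sd=0.0, g_leak=0.0, seed=0)
        ts = simulate_traces(spec, protocol="recovery",
                             intervals_ms=np.array([1.0, 50.0]))
        res = recovery_fractions(ts)
        assert res.fraction_at(50.0) == pytest.approx(1.0, abs=0.01)

    def test_monotone_on_noiseless_input(self):
        spec = TraceSimSpec(noise_sd=0.0, g_leak=0.0, seed=0)
        ts = simulate_traces(spec, protocol="recovery")
        res = recovery_fractions(ts)
        fracs = res.table["fraction"].to_numpy()
        assert np.all(np.diff(fracs) >= -1e-9)


class TestTraceIO:
    def test_csv_json_round_trip(self, tmp_path):
        spec = TraceSimSpec(seed=9)
        ts = simulate_traces(spec, protocol="recovery",
                             intervals_ms=np.array([0.5, 2.0]))
        write_traces(ts, tmp_path / "t.csv", tmp_path / "t.json")
        back = read_traces(tmp_path / "t.csv", tmp_path / "t.json")
        assert back.protocol == ts.protocol
        assert len(back.sweeps) == len(ts.sweeps)
        for a, b in zip(ts.sweeps, back.sweeps):
            np.testing.assert_allclose(a.current, b.current, rtol=1e-12)
            assert a.interval_ms == b.interval_ms

    def test_unordered_step_voltages_rejected(self):
        fs = 50_000.0
        segs = [(-120.0, 1.0), (-20.0, 1.0)]
        n = sum(int(d * fs / 1000) for _, d in segs)
        sweeps = [Sweep(f"s{i}", segs, np.zeros(n), voltage=v)
                  for i, v in enumerate([-20.0, -60.0, -40.0])]
        with pytest.raises(ValueError, match="ordered"):
            VoltageClampTraceSet(protocol="step", sampling_hz=fs,
                                 holding_mv=-120.0, sweeps=sweeps)
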