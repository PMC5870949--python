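"""Voltage-clamp analysis: persistent current, gating curves, recovery.

The persistent sodium current (I_NAP) is the non-inactivating component
remaining at the end of a depolarizing pulse. Per sweep it is quantified
as the mean current over the last 0.5 ms of a 30-ms pulse divided by the
peak of the transient component, after linear leak subtraction, expressed
in percent. Activation is summarized by a Boltzmann fit to normalized peak
conductance G(V) = I_peak/(V - E_rev); steady-state inactivation by a
Boltzmann with a free pedestal (the non-inactivating asymptote); recovery
from inactivation by the test/conditioning peak-current ratio as a
function of the recovery interval.

Sweeps are piecewise-constant voltage protocols: each sweep lists
(voltage_mV, duration_ms) segments and the sampled current covering them.
Protocol families:

- ``step``: holding baseline, a 30-ms step to the sweep voltage, tail;
- ``ssi``: tail of a long conditioning pulse at the sweep's conditioning
  voltage, a brief gap step, then the fixed test pulse;
- ``recovery``: baseline, conditioning pulse, a recovery interval at the
  holding potential, then the identical test pulse.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import butter, filtfilt


@dataclass
class Sweep:
    """One voltage-clamp sweep: a piecewise-constant protocol + current."""

    sweep_id: str
    segments: list[tuple[float, float]]  # (voltage mV, duration ms)
    current: np.ndarray                  # sampled current (arbitrary units)
    voltage: float                       # family variable: step or cond. V
    interval_ms: float | None = None     # recovery interval, if applicable


@dataclass
class VoltageClampTraceSet:
    """A family of sweeps sharing a protocol and sampling rate."""

    protocol: str                 # 'step' | 'ssi' | 'recovery'
    sampling_hz: float
    holding_mv: float
    sweeps: list[Sweep]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.protocol not in ("step", "ssi", "recovery"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if not self.sweeps:
            raise ValueError("trace set has no sweeps")
        for sw in self.sweeps:
            n_expected = sum(self._seg_samples(d) for _, d in sw.segments)
            if len(sw.current) != n_expected:
                raise ValueError(
                    f"sweep {sw.sweep_id}: {len(sw.current)} samples, "
                    f"expected {n_expected} from protocol segments")
        if self.protocol in ("step", "ssi") and len(self.sweeps) > 1:
            volts = [sw.voltage for sw in self.sweeps]
            ascending = all(b > a for a, b in zip(volts, volts[1:]))
            descending = all(b < a for a, b in zip(volts, volts[1:]))
            if not (ascending or descending):
                raise ValueError(
                    f"{self.protocol} sweep voltages must be strictly ordered")

    def _seg_samples(self, duration_ms: float) -> int:
        return int(round(duration_ms * self.sampling_hz / 1000.0))

    def segment_slice(self, sweep: Sweep, index: int) -> slice:
        start = sum(self._seg_samples(d) for _, d in sweep.segments[:index])
        return slice(start, start + self._seg_samples(sweep.segments[index][1]))

    def voltage_trace(self, sweep: Sweep) -> np.ndarray:
        parts = [np.full(self._seg_samples(d), v) for v, d in sweep.segments]
        return np.concatenate(parts)

    def time_ms(self, sweep: Sweep) -> np.ndarray:
        n = len(sweep.current)
        return np.arange(n) / self.sampling_hz * 1000.0


@dataclass
class LeakFit:
    """Linear (ohmic) leak: I_leak(V) = conductance * V + offset."""

    conductance: float
    offset: float
    n_points: int


@dataclass
class PersistentCurrentResult:
    """Per-sweep persistent-current percentages."""

    table: pd.DataFrame   # columns: voltage, i_peak, i_late, pct_inap
    window_ms: float
    pulse_ms: float
    skipped: list[str]    # sweep ids below the noise floor


@dataclass
class BoltzmannFit:
    """Sigmoid fit of a normalized gating curve."""

    v_half: float
    k: float
    amplitude: float
    pedestal: float
    residual_norm: float
    converged: bool
    data: pd.DataFrame    # voltage, normalized value


@dataclass
class RecoveryResult:
    """Fraction of peak current recovered as a function of interval."""

    table: pd.DataFrame   # columns: interval_ms, i_cond, i_test, fraction

    def fraction_at(self, interval_ms: float) -> float:
        row = self.table.loc[
            np.isclose(self.table["interval_ms"], interval_ms)]
        if row.empty:
            raise KeyError(f"no sweep with recovery interval {interval_ms} ms")
        return float(row["fraction"].iloc[0])


# --- helpers --------------------------------------------------------------

def _lowpass(current: np.ndarray, sampling_hz: float,
             cutoff_hz: float = 10_000.0) -> np.ndarray:
    """Zero-phase low-pass used for peak detection (mirrors acquisition
    filtering); identity if the cutoff is at/above Nyquist."""
    nyq = sampling_hz / 2.0
    if cutoff_hz >= nyq or len(current) < 16:
        return current
    b, a = butter(4, cutoff_hz / nyq)
    return filtfilt(b, a, current)


def _signed_peak(x: np.ndarray) -> float:
    """Extremum of largest magnitude, keeping its sign."""
    return float(x[np.argmax(np.abs(x))])


def _baseline_sd(ts: VoltageClampTraceSet, sweep: Sweep) -> float:
    sl = ts.segment_slice(sweep, 0)
    return float(np.std(sweep.current[sl]))


# --- operations -----------------------------------------------------------

def leak_subtract(ts: VoltageClampTraceSet, leak_below_mv: float = -105.0,
                  params: LeakFit | None = None,
                  min_segment_ms: float = 0.5,
                  ) -> tuple[VoltageClampTraceSet, LeakFit]:
    """Subtract linear leak, fitted to channel-free segments.

    Steady-state currents are collected from every protocol segment at or
    below ``leak_below_mv``, using the mean of the second half of the
    segment. A line I = g*V + b is fit and g*V(t) + b subtracted
    sample-wise from every sweep. Segments at two or more distinct
    voltages are required unless an explicit ``params`` (e.g. fitted on
    the step family of the same cell) is supplied.

    The default window keeps the fit within ~15 mV of the holding
    potential: even the far tail of a sodium-channel activation curve
    conducts a measurable fraction of peak current by -90 mV, and
    including such steps tilts the leak line enough to bias small
    persistent-current percentages.
    """
    if params is None:
        volts, currents = [], []
        for sw in ts.sweeps:
            for i, (v, dur) in enumerate(sw.segments):
                if v <= leak_below_mv and dur >= min_segment_ms:
                    sl = ts.segment_slice(sw, i)
                    seg = sw.current[sl]
                    volts.append(v)
                    currents.append(float(np.mean(seg[len(seg) // 2:])))
        if len(set(volts)) < 2:
            raise ValueError(
                "leak fit needs segments at >= 2 distinct subthreshold "
                "voltages; pass explicit leak params instead")
        g, b = np.polyfit(volts, currents, 1)
        params = LeakFit(conductance=float(g), offset=float(b),
                         n_points=len(volts))
    corrected = []
    for sw in ts.sweeps:
        leak = params.conductance * ts.voltage_trace(sw) + params.offset
        corrected.append(replace(sw, current=sw.current - leak))
    return replace(ts, sweeps=corrected), params


def persistent_percent(ts: VoltageClampTraceSet, pulse_ms: float = 30.0,
                       window_ms: float = 0.5, noise_floor_sd: float = 3.0,
                       filter_hz: float = 10_000.0) -> PersistentCurrentResult:
    """Percent persistent current per step sweep.

    %I_NAP = 100 * mean(i over the last ``window_ms`` of the pulse)
                 / peak(i over the pulse),
    computed on leak-subtracted traces, peak taken from the low-pass
    filtered trace. Sweeps whose peak is below ``noise_floor_sd`` baseline
    standard deviations are skipped with a record in ``skipped``.
    """
    if ts.protocol != "step":
        raise ValueError("persistent_percent expects the step protocol")
    if pulse_ms < window_ms:
        raise ValueError("pulse shorter than averaging window")
    pulse_idx = ts.meta.get("pulse_segment", 1)
    rows, skipped = [], []
    for sw in ts.sweeps:
        sl = ts.segment_slice(sw, pulse_idx)
        pulse = sw.current[sl]
        n_win = max(1, int(round(window_ms * ts.sampling_hz / 1000.0)))
        filtered = _lowpass(pulse, ts.sampling_hz, filter_hz)
        peak = _signed_peak(filtered)
        floor = noise_floor_sd * _baseline_sd(ts, sw)
        if abs(peak) <= floor:
            skipped.append(sw.sweep_id)
            continue
        late = float(np.mean(pulse[-n_win:]))
        rows.append({"voltage": sw.voltage, "i_peak": peak, "i_late": late,
                     "pct_inap": 100.0 * abs(late) / abs(peak)
                     * (1.0 if late * peak > 0 else -1.0)})
    return PersistentCurrentResult(
        table=pd.DataFrame(rows, columns=["voltage", "i_peak", "i_late",
                                          "pct_inap"]),
        window_ms=window_ms, pulse_ms=pulse_ms, skipped=skipped)


def _fit_boltzmann(v: np.ndarray, y: np.ndarray, free_pedestal: bool,
                   ascending: bool) -> BoltzmannFit:
    """Least-squares Boltzmann fit.

    ``ascending`` selects 1/(1+exp((V1/2 - V)/k)) (activation, rising with
    V); otherwise a + (1-a)/(1+exp((V - V1/2)/k)) (availability, falling).
    """
    if ascending:
        def model(V, vh, k, amp):
            return amp / (1.0 + np.exp((vh - V) / k))
        p0 = [float(v[np.argmin(np.abs(y - 0.5 * y.max()))]), 7.0, 1.0]
        bounds = ([-150.0, 0.5, 0.0], [50.0, 50.0, 2.0])
    elif free_pedestal:
        def model(V, vh, k, amp, a):
            return a + (amp - a) / (1.0 + np.exp((V - vh) / k))
        p0 = [float(v[np.argmin(np.abs(y - 0.5))]), 7.0, 1.0, 0.02]
        bounds = ([-150.0, 0.5, 0.0, 0.0], [50.0, 50.0, 2.0, 1.0])
    else:
        def model(V, vh, k, amp):
            return amp / (1.0 + np.exp((V - vh) / k))
        p0 = [float(v[np.argmin(np.abs(y - 0.5))]), 7.0, 1.0]
        bounds = ([-150.0, 0.5, 0.0], [50.0, 50.0, 2.0])
    try:
        popt, _ = curve_fit(model, v, y, p0=p0, bounds=bounds, maxfev=20000)
        converged = True
    except RuntimeError:
        popt = np.array(p0)
        converged = False
    resid = float(np.linalg.norm(y - model(v, *popt)))
    pedestal = float(popt[3]) if (free_pedestal and not ascending) else 0.0
    return BoltzmannFit(
        v_half=float(popt[0]), k=float(popt[1]), amplitude=float(popt[2]),
        pedestal=pedestal, residual_norm=resid, converged=converged,
        data=pd.DataFrame({"voltage": v, "value": y}))


def gv_curve(ts: VoltageClampTraceSet, reversal_mv: float = 50.0,
             filter_hz: float = 10_000.0, exclude_near_rev_mv: float = 5.0
             ) -> BoltzmannFit:
    """Activation (conductance-voltage) Boltzmann fit from step sweeps.

    Peak conductance G(V) = I_peak / (V - E_rev) is normalized to its
    maximum and fit with a pedestal-free Boltzmann rising with V. Sweeps
    within ``exclude_near_rev_mv`` of the reversal potential are excluded.
    """
    if ts.protocol != "step":
        raise ValueError("gv_curve expects the step protocol")
    pulse_idx = ts.meta.get("pulse_segment", 1)
    volts, conds = [], []
    for sw in ts.sweeps:
        if abs(sw.voltage - reversal_mv) < exclude_near_rev_mv:
            continue
        pulse = _lowpass(sw.current[ts.segment_slice(sw, pulse_idx)],
                         ts.sampling_hz, filter_hz)
        volts.append(sw.voltage)
        conds.append(_signed_peak(pulse) / (sw.voltage - reversal_mv))
    v = np.asarray(volts)
    g = np.asarray(conds)
    gmax = g.max()
    if gmax <= 0:
        raise ValueError("no positive peak conductance; check reversal "
                         "potential and leak subtraction")
    return _fit_boltzmann(v, g / gmax, free_pedestal=False, ascending=True)


def ssi_curve(ts: VoltageClampTraceSet, filter_hz: float = 10_000.0
              ) -> BoltzmannFit:
    """Steady-state inactivation Boltzmann (with free pedestal).

    Test-pulse peak currents indexed by conditioning voltage are
    normalized to the maximum (full availability at the most negative
    conditioning) and fit with a + (1-a)/(1 + exp((V - V1/2)/k)); the
    pedestal ``a`` is the non-inactivating asymptote.
    """
    if ts.protocol != "ssi":
        raise ValueError("ssi_curve expects the ssi protocol")
    test_idx = ts.meta.get("test_segment", 2)
    volts, peaks = [], []
    for sw in ts.sweeps:
        pulse = _lowpass(sw.current[ts.segment_slice(sw, test_idx)],
                         ts.sampling_hz, filter_hz)
        volts.append(sw.voltage)
        peaks.append(abs(_signed_peak(pulse)))
    v = np.asarray(volts)
    y = np.asarray(peaks)
    if y.max() <= 0:
        raise ValueError("no measurable test-pulse current")
    return _fit_boltzmann(v, y / y.max(), free_pedestal=True, ascending=False)


def recovery_fractions(ts: VoltageClampTraceSet,
                       filter_hz: float = 10_000.0) -> RecoveryResult:
    """Recovery from inactivation: test/conditioning peak ratio per
    interval, sorted by interval."""
    if ts.protocol != "recovery":
        raise ValueError("recovery_fractions expects the recovery protocol")
    cond_idx = ts.meta.get("cond_segment", 1)
    test_idx = ts.meta.get("test_segment", 3)
    rows = []
    for sw in ts.sweeps:
        if sw.interval_ms is None:
            raise ValueError(f"sweep {sw.sweep_id} has no recovery interval")
        cond = _lowpass(sw.current[ts.segment_slice(sw, cond_idx)],
                        ts.sampling_hz, filter_hz)
        test = _lowpass(sw.current[ts.segment_slice(sw, test_idx)],
                        ts.sampling_hz, filter_hz)
        i_cond = _signed_peak(cond)
        if i_cond == 0:
            raise ValueError(f"sweep {sw.sweep_id}: no conditioning current")
        rows.append({"interval_ms": sw.interval_ms, "i_cond": i_cond,
                     "i_test": _signed_peak(test),
                     "fraction": _signed_peak(test) / i_cond})
    table = pd.DataFrame(rows).sort_values("interval_ms", ignore_index=True)
    return RecoveryResult(table=table)


# --- I/O ------------------------------------------------------------------

def write_traces(ts: VoltageClampTraceSet, csv_path: str | Path,
                 json_path: str | Path) -> None:
    """Write a trace set as long-format CSV (time_ms, sweep_id, current)
    plus a JSON protocol descriptor sidecar."""
    frames = []
    for sw in ts.sweeps:
        frames.append(pd.DataFrame({
            "time_ms": ts.time_ms(sw), "sweep_id": sw.sweep_id,
            "current": sw.current}))
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
    desc = {
        "protocol": ts.protocol,
        "sampling_hz": ts.sampling_hz,
        "holding_mv": ts.holding_mv,
        "meta": ts.meta,
        "sweeps": [
            {"sweep_id": sw.sweep_id, "segments": sw.segments,
             "voltage": sw.voltage, "interval_ms": sw.interval_ms}
            for sw in ts.sweeps
        ],
    }
    Path(json_path).write_text(json.dumps(desc, indent=1))


def read_traces(csv_path: str | Path, json_path: str | Path
                ) -> VoltageClampTraceSet:
    """Read a trace set written by :func:`write_traces`."""
    desc = json.loads(Path(json_path).read_text())
    df = pd.read_csv(csv_path)
    sweeps = []
    for sd in desc["sweeps"]:
        cur = df.loc[df["sweep_id"] == sd["sweep_id"], "current"].to_numpy()
        sweeps.append(Sweep(
            sweep_id=sd["sweep_id"],
            segments=[tuple(s) for s in sd["segments"]],
            current=cur, voltage=sd["voltage"],
            interval_ms=sd.get("interval_ms")))
    return VoltageClampTraceSet(
        protocol=desc["protocol"], sampling_hz=desc["sampling_hz"],
        holding_mv=desc["holding_mv"], sweeps=sweeps,
        meta=desc.get("meta", {}))
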