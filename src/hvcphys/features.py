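"""Automated current-clamp trace analysis.

Implements the standard battery of physiologic features measured from
square-pulse current-clamp sweeps, identically applicable to simulated,
synthetic, or recorded traces:

* passive properties from -10 pA pulses: input resistance R_M (deflection /
  current), membrane time constant tau_M (single-exponential fit to the
  first 50 ms after onset), capacitance C_M = tau_M / R_M;
* resting potential V_rest (pre-onset average);
* sag metrics from a hyperpolarizing pulse: V_min, V_end (mean of the final
  5 ms of the pulse), sag ratio SR = (V_min - V_end)/V_min, and
  V_drop = V_rest - V_min;
* rebound depolarization: maximum voltage in the 150 ms after pulse offset
  minus V_rest (includes rebound spike peaks);
* spike metrics at +200 pA: amplitude (peak minus after-hyperpolarization
  trough), width at half amplitude, latency to first spike peak, mean
  frequency (count * 1000 / pulse duration), inter-spike intervals between
  successive half-amplitude rising crossings, and the adaptation ratio
  AR = last ISI / first ISI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import curve_fit

from .model import VoltageTrace


class MissingProtocolError(ValueError):
    """A required sweep (passive -10 pA or feature +/-200 pA) is absent."""


# detection defaults: chosen to separate spikes from subthreshold humps in
# all six model cells; configurable per call
SPIKE_HEIGHT_MV = -20.0
SPIKE_PROMINENCE_MV = 20.0
REBOUND_WINDOW_MS = 150.0
V_END_WINDOW_MS = 5.0
PASSIVE_FIT_MS = 50.0


@dataclass
class Pulse:
    """Square pulse location within a sweep."""

    onset_ms: float
    dur_ms: float
    amp_pA: float

    @property
    def offset_ms(self) -> float:
        return self.onset_ms + self.dur_ms


def pulse_from_trace(trace: VoltageTrace) -> Pulse:
    """Recover the square pulse from the applied-current channel."""
    nz = np.flatnonzero(trace.i_app != 0)
    if len(nz) == 0:
        raise ValueError("trace has no applied-current pulse")
    onset = trace.t[nz[0]]
    # snap the offset to the next grid point to avoid float accumulation
    offset = trace.t[nz[-1] + 1] if nz[-1] + 1 < len(trace.t) \
        else trace.t[nz[-1]] + trace.dt
    amp = float(trace.i_app[nz[len(nz) // 2]])
    return Pulse(onset_ms=float(onset), dur_ms=float(offset - onset), amp_pA=amp)


@dataclass
class SpikeEvent:
    """One detected action potential."""

    peak_time_ms: float
    peak_v: float
    trough_time_ms: float   # after-hyperpolarization minimum
    trough_v: float
    half_rise_ms: float     # rising half-amplitude crossing
    half_fall_ms: float     # falling half-amplitude crossing

    @property
    def amplitude(self) -> float:
        return self.peak_v - self.trough_v

    @property
    def width_ms(self) -> float:
        return self.half_fall_ms - self.half_rise_ms


def _interp_crossing(t0, v0, t1, v1, level):
    # linear interpolation of the time where v crosses level
    if v1 == v0:
        return t0
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def detect_spikes(trace: VoltageTrace, window: tuple[float, float],
                  height: float = SPIKE_HEIGHT_MV,
                  prominence: float = SPIKE_PROMINENCE_MV) -> list[SpikeEvent]:
    """Find action potentials in ``window`` (ms).

    A spike is a local maximum above ``height`` with at least ``prominence``
    mV of rise over the lowest point since the previous spike (or window
    start).  The after-hyperpolarization trough is the minimum between the
    peak and the next peak (or window end); half-amplitude crossings are
    linearly interpolated at (peak + trough)/2.
    """
    t, v = trace.t, trace.v
    sel = np.flatnonzero((t >= window[0]) & (t <= window[1]))
    if len(sel) < 3:
        return []
    i0, i1 = sel[0], sel[-1]

    peaks = []
    trough_run = v[i0]
    for i in range(i0 + 1, i1):
        trough_run = min(trough_run, v[i])
        if v[i] > v[i - 1] and v[i] >= v[i + 1] and v[i] > height \
                and v[i] - trough_run >= prominence:
            peaks.append(i)
            trough_run = v[i]
    if not peaks:
        return []

    events = []
    for k, ip in enumerate(peaks):
        j1 = peaks[k + 1] if k + 1 < len(peaks) else i1 + 1
        seg = slice(ip, j1)
        it = ip + int(np.argmin(v[seg]))
        trough_v = float(v[it])
        half = 0.5 * (v[ip] + trough_v)
        # rising crossing: last upward crossing of half before the peak
        jr = ip
        while jr > i0 and v[jr - 1] > half:
            jr -= 1
        half_rise = _interp_crossing(t[jr - 1], v[jr - 1], t[jr], v[jr], half) \
            if jr > i0 else float(t[i0])
        # falling crossing: first downward crossing after the peak
        jf = ip
        while jf < it and v[jf + 1] > half:
            jf += 1
        half_fall = _interp_crossing(t[jf], v[jf], t[jf + 1], v[jf + 1], half) \
            if jf < it else float(t[it])
        events.append(SpikeEvent(
            peak_time_ms=float(t[ip]), peak_v=float(v[ip]),
            trough_time_ms=float(t[it]), trough_v=trough_v,
            half_rise_ms=float(half_rise), half_fall_ms=float(half_fall)))
    return events


# ---------------------------------------------------------------------------
# scalar feature computations
# ---------------------------------------------------------------------------

def resting_potential(trace: VoltageTrace, onset_ms: float | None = None) -> float:
    """Average voltage before pulse onset."""
    if onset_ms is None:
        onset_ms = pulse_from_trace(trace).onset_ms
    pre = trace.v[trace.t < onset_ms]
    if len(pre) == 0:
        raise ValueError("no pre-onset samples")
    return float(pre.mean())


@dataclass
class PassiveProperties:
    r_input_mohm: float
    tau_m_ms: float
    c_m_pf: float
    fit_ok: bool = True
    message: str = ""


def passive_properties(sweeps: list[VoltageTrace],
                       fit_ms: float = PASSIVE_FIT_MS) -> PassiveProperties:
    """Passive membrane properties from repeated -10 pA sweeps.

    Sweeps are averaged pointwise first.  R_M is the steady voltage
    deflection divided by the 10 pA step (in MOhm); tau_M is a
    single-exponential least-squares fit to the first ``fit_ms`` after
    onset; C_M = tau_M / R_M (pF).
    """
    if not sweeps:
        raise MissingProtocolError("need at least one -10 pA sweep")
    pulse = pulse_from_trace(sweeps[0])
    if abs(pulse.amp_pA + 10.0) > 1e-6:
        raise ValueError(f"passive sweeps must be -10 pA, got {pulse.amp_pA}")
    t = sweeps[0].t
    v = np.mean([s.v for s in sweeps], axis=0)

    v_rest = float(v[t < pulse.onset_ms].mean())
    late = (t >= pulse.offset_ms - 10.0) & (t < pulse.offset_ms)
    v_ss = float(v[late].mean())
    deflection = v_ss - v_rest                     # mV, negative
    r_mohm = abs(deflection) / 10.0 * 1e3          # mV/pA = GOhm -> MOhm

    seg = (t >= pulse.onset_ms) & (t <= pulse.onset_ms + fit_ms)
    ts = t[seg] - pulse.onset_ms
    vs = v[seg]

    def model(x, v_inf, dv, tau):
        return v_inf + dv * np.exp(-x / tau)

    try:
        popt, _ = curve_fit(model, ts, vs,
                            p0=(v_ss, v_rest - v_ss, 20.0),
                            maxfev=10000)
        tau = float(popt[2])
        if not (0 < tau < 10 * fit_ms):
            raise RuntimeError(f"unphysical tau {tau:.3g} ms")
    except (RuntimeError, ValueError) as err:
        return PassiveProperties(r_mohm, float("nan"), float("nan"),
                                 fit_ok=False, message=str(err))
    c_pf = tau / r_mohm * 1e3                      # ms/MOhm = nF -> pF
    return PassiveProperties(r_mohm, tau, c_pf)


@dataclass
class SagMetrics:
    v_min: float
    v_end: float
    sr: float
    v_drop: float


def sag_metrics(trace: VoltageTrace, pulse: Pulse | None = None,
                v_rest: float | None = None) -> SagMetrics:
    """Sag ratio and voltage drop from a hyperpolarizing pulse.

    SR = (V_min - V_end)/V_min with V_min the pulse minimum and V_end the
    mean over the final 5 ms of the pulse; V_drop = V_rest - V_min.
    """
    if pulse is None:
        pulse = pulse_from_trace(trace)
    if pulse.amp_pA >= 0:
        raise ValueError("sag metrics require a hyperpolarizing pulse")
    if v_rest is None:
        v_rest = resting_potential(trace, pulse.onset_ms)
    t, v = trace.t, trace.v
    during = (t >= pulse.onset_ms) & (t < pulse.offset_ms)
    v_min = float(v[during].min())
    endw = (t >= pulse.offset_ms - V_END_WINDOW_MS) & (t < pulse.offset_ms)
    v_end = float(v[endw].mean())
    sr = (v_min - v_end) / v_min if v_min != 0 else float("nan")
    return SagMetrics(v_min=v_min, v_end=v_end, sr=sr, v_drop=v_rest - v_min)


def rebound_depolarization(trace: VoltageTrace, pulse_offset_ms: float,
                           v_rest: float,
                           window_ms: float = REBOUND_WINDOW_MS) -> float:
    """Max voltage within ``window_ms`` after offset, relative to rest."""
    t, v = trace.t, trace.v
    post = (t > pulse_offset_ms) & (t <= pulse_offset_ms + window_ms)
    if not np.any(post):
        raise ValueError("trace does not extend past the pulse offset")
    return float(v[post].max() - v_rest)


@dataclass
class SpikeMetrics:
    amplitude_mv: float
    width_ms: float
    latency_ms: float
    frequency_hz: float
    isis_ms: list[float] = field(default_factory=list)
    ar: float = float("nan")
    n_spikes: int = 0


def spike_metrics(trace: VoltageTrace, events: list[SpikeEvent],
                  pulse: Pulse | None = None) -> SpikeMetrics:
    """Spike-train features of one depolarizing sweep.

    Latency is to the first spike peak; frequency is count * 1000 / pulse
    duration; ISIs are between successive half-amplitude rising crossings;
    AR = last ISI / first ISI (NaN with fewer than two spikes).
    """
    if pulse is None:
        pulse = pulse_from_trace(trace)
    if not events:
        return SpikeMetrics(float("nan"), float("nan"), float("nan"),
                            0.0, [], float("nan"), 0)
    first = events[0]
    isis = [events[k + 1].half_rise_ms - events[k].half_rise_ms
            for k in range(len(events) - 1)]
    ar = isis[-1] / isis[0] if isis else float("nan")
    return SpikeMetrics(
        amplitude_mv=first.amplitude,
        width_ms=first.width_ms,
        latency_ms=first.peak_time_ms - pulse.onset_ms,
        frequency_hz=len(events) * 1000.0 / pulse.dur_ms,
        isis_ms=isis,
        ar=ar,
        n_spikes=len(events),
    )


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

@dataclass
class FeatureSet:
    """The physiologic feature battery of one cell (one sweep set)."""

    v_rest: float = float("nan")          # mV
    r_input_mohm: float = float("nan")    # MOhm
    tau_m_ms: float = float("nan")        # ms
    c_m_pf: float = float("nan")          # pF
    v_min: float = float("nan")           # mV
    v_end: float = float("nan")           # mV
    v_drop: float = float("nan")          # mV
    sr: float = float("nan")              # dimensionless
    rebound_depol_mv: float = float("nan")
    spike_amplitude_mv: float = float("nan")
    spike_width_ms: float = float("nan")
    spike_latency_ms: float = float("nan")
    spike_frequency_hz: float = float("nan")
    isis_ms: list[float] = field(default_factory=list)
    ar: float = float("nan")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSet":
        return cls(**d)


def extract_features(sweeps: list[VoltageTrace],
                     height: float = SPIKE_HEIGHT_MV,
                     prominence: float = SPIKE_PROMINENCE_MV) -> FeatureSet:
    """Compose the full feature battery from one sweep set.

    The set must contain at least one -10 pA passive sweep, a -200 pA
    hyperpolarizing sweep, and a +200 pA depolarizing sweep.  Spike
    amplitude and width are averaged over the first spike of every
    depolarizing sweep that fires; latency, frequency, ISIs and AR come
    from the +200 pA sweep; sag and rebound from the -200 pA sweep.
    """
    by_amp: dict[float, list[VoltageTrace]] = {}
    for s in sweeps:
        by_amp.setdefault(pulse_from_trace(s).amp_pA, []).append(s)

    if -10.0 not in by_amp:
        raise MissingProtocolError("missing -10 pA passive sweeps")
    if -200.0 not in by_amp:
        raise MissingProtocolError("missing -200 pA hyperpolarizing sweep")
    if 200.0 not in by_amp:
        raise MissingProtocolError("missing +200 pA depolarizing sweep")

    passive = passive_properties(by_amp[-10.0])

    hyp = by_amp[-200.0][0]
    hyp_pulse = pulse_from_trace(hyp)
    v_rest = resting_potential(hyp, hyp_pulse.onset_ms)
    sag = sag_metrics(hyp, hyp_pulse, v_rest)
    rebound = rebound_depolarization(hyp, hyp_pulse.offset_ms, v_rest)

    dep = by_amp[200.0][0]
    dep_pulse = pulse_from_trace(dep)
    dep_events = detect_spikes(
        dep, (dep_pulse.onset_ms, dep_pulse.offset_ms), height, prominence)
    sm = spike_metrics(dep, dep_events, dep_pulse)

    # first-spike amplitude/width averaged across all depolarizing sweeps
    amps, widths = [], []
    for amp_pa, group in sorted(by_amp.items()):
        if amp_pa <= 0:
            continue
        for s in group:
            pl = pulse_from_trace(s)
            ev = detect_spikes(s, (pl.onset_ms, pl.offset_ms), height, prominence)
            if ev:
                amps.append(ev[0].amplitude)
                widths.append(ev[0].width_ms)
    amp_mean = float(np.mean(amps)) if amps else float("nan")
    width_mean = float(np.mean(widths)) if widths else float("nan")

    return FeatureSet(
        v_rest=v_rest,
        r_input_mohm=passive.r_input_mohm,
        tau_m_ms=passive.tau_m_ms,
        c_m_pf=passive.c_m_pf,
        v_min=sag.v_min, v_end=sag.v_end, v_drop=sag.v_drop, sr=sag.sr,
        rebound_depol_mv=rebound,
        spike_amplitude_mv=amp_mean,
        spike_width_ms=width_mean,
        spike_latency_ms=sm.latency_ms,
        spike_frequency_hz=sm.frequency_hz,
        isis_ms=sm.isis_ms,
        ar=sm.ar,
    )


def standard_sweep_amplitudes() -> tuple:
    """Pulse amplitudes needed by extract_features plus the -10 pA sweep."""
    return (-200.0, -10.0, 50.0, 100.0, 150.0, 200.0)
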