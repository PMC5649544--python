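"""Synthetic current-clamp data with exact ground truth.

Two generators:

* :func:`synth_trace` builds a square-pulse voltage sweep from a waveform
  recipe (RC relaxation with an exactly attained floor, optional sag
  recovery, stereotyped spike templates, optional rebound hump, Gaussian
  noise) and returns it together with the analytically known feature
  values.  With zero noise the feature extractor recovers every value
  exactly, which validates the analysis pipeline independently of the
  biophysics.

* :func:`synth_population` draws per-cell feature values for the three
  developmental stages from Normal(mean, sd = SEM * sqrt(n)), reproducing
  reported group statistics for the population-comparison stage.

Waveform construction notes: pulse phases are built so the quantities the
extractor measures are attained exactly on the sample grid — the relaxation
is scaled to reach the target floor exactly at the start of the terminal
flat window (so the steady deflection and V_end are exact), spike templates
are half-cosine biphasic waves whose peak and trough samples lie on the
grid, and the rebound hump sits on an exactly restored baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import VoltageTrace
from .features import FeatureSet


@dataclass
class SpikeTemplate:
    """Stereotyped biphasic action-potential waveform.

    Half-cosine rise (base -> peak over rise_ms), half-cosine fall
    (peak -> ahp over fall_ms), half-cosine recovery (ahp -> base over
    recover_ms).
    """

    times_ms: tuple = ()        # peak times (absolute, ms)
    peak_v: float = 10.0        # mV
    ahp_v: float = -72.0        # mV
    rise_ms: float = 1.0
    fall_ms: float = 1.0
    recover_ms: float = 4.0

    def __post_init__(self) -> None:
        if self.times_ms and self.peak_v <= self.ahp_v:
            raise ValueError("spike peak must exceed AHP trough")


@dataclass
class ReboundHump:
    """Post-offset after-depolarization bump (sin^2 shape)."""

    amp_mv: float = 0.0
    latency_ms: float = 50.0    # bump start after pulse offset
    width_ms: float = 40.0


@dataclass
class TraceSpec:
    """Recipe for one synthetic sweep with known features."""

    v_rest: float = -67.0
    onset_ms: float = 100.0
    dur_ms: float = 300.0
    post_ms: float = 200.0
    amp_pA: float = -200.0
    r_input_mohm: float = 300.0
    tau_ms: float = 30.0
    sag_fraction: float = 0.0       # target SR for hyperpolarizing pulses
    sag_onset_frac: float = 0.5     # fraction of the pulse where V_min sits
    spikes: SpikeTemplate = field(default_factory=SpikeTemplate)
    rebound: ReboundHump = field(default_factory=ReboundHump)
    noise_sigma_mv: float = 0.0
    dt_ms: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sag_fraction < 0.5:
            raise ValueError("sag fraction must lie in [0, 0.5)")
        if self.noise_sigma_mv < 0:
            raise ValueError("noise sigma must be >= 0")
        for tk in self.spikes.times_ms:
            if not (self.onset_ms <= tk <= self.onset_ms + self.dur_ms):
                raise ValueError(
                    f"spike at {tk} ms lies outside the pulse window")

    @property
    def offset_ms(self) -> float:
        return self.onset_ms + self.dur_ms


def _scaled_relax(t, v0, v_target, tau, t_end):
    """Exponential from v0 that attains v_target exactly at t_end."""
    scale = 1.0 - math.exp(-t_end / tau) if t_end > 0 else 1.0
    return v0 + (v_target - v0) * (1.0 - np.exp(-t / tau)) / scale


def _insert_spike(v, t, tpl: SpikeTemplate, t_peak: float):
    r, f, rec = tpl.rise_ms, tpl.fall_ms, tpl.recover_ms
    t0 = t_peak - r
    base_idx = np.searchsorted(t, t0) - 1
    base = v[max(base_idx, 0)]
    seg = (t >= t0) & (t <= t_peak + f + rec)
    ts = t[seg]
    out = np.empty_like(ts)
    for i, tk in enumerate(ts):
        if tk <= t_peak:
            u = (tk - t0) / r
            out[i] = base + (tpl.peak_v - base) * 0.5 * (1 - math.cos(math.pi * u))
        elif tk <= t_peak + f:
            u = (tk - t_peak) / f
            out[i] = tpl.peak_v + (tpl.ahp_v - tpl.peak_v) * 0.5 * (1 - math.cos(math.pi * u))
        else:
            u = (tk - t_peak - f) / rec
            out[i] = tpl.ahp_v + (base - tpl.ahp_v) * 0.5 * (1 - math.cos(math.pi * u))
    v[seg] = out


def _truth_spike_scan(t, v, window, height=-20.0, prominence=20.0):
    """Independent minimal spike scan for ground-truth bookkeeping."""
    sel = np.flatnonzero((t >= window[0]) & (t <= window[1]))
    peaks = []
    if len(sel) < 3:
        return []
    trough = v[sel[0]]
    for i in sel[1:-1]:
        trough = min(trough, v[i])
        if v[i] > v[i - 1] and v[i] >= v[i + 1] and v[i] > height \
                and v[i] - trough >= prominence:
            peaks.append(i)
            trough = v[i]
    events = []
    for k, ip in enumerate(peaks):
        j1 = peaks[k + 1] if k + 1 < len(peaks) else sel[-1] + 1
        it = ip + int(np.argmin(v[ip:j1]))
        half = 0.5 * (v[ip] + v[it])
        jr = ip
        while jr > sel[0] and v[jr - 1] > half:
            jr -= 1
        tr = t[jr - 1] + (half - v[jr - 1]) * (t[jr] - t[jr - 1]) / (v[jr] - v[jr - 1])
        jf = ip
        while jf < it and v[jf + 1] > half:
            jf += 1
        tf = t[jf] + (half - v[jf]) * (t[jf + 1] - t[jf]) / (v[jf + 1] - v[jf])
        events.append(dict(peak_t=t[ip], peak_v=v[ip], trough_v=v[it],
                           half_rise=tr, half_fall=tf))
    return events


def synth_trace(spec: TraceSpec) -> tuple[VoltageTrace, FeatureSet]:
    """Build one synthetic sweep and its exact feature ground truth.

    The returned :class:`FeatureSet` is computed from the noiseless
    waveform; with ``noise_sigma_mv = 0`` the feature extractor reproduces
    it to numerical precision.
    """
    total = spec.onset_ms + spec.dur_ms + spec.post_ms
    n = int(round(total / spec.dt_ms)) + 1
    t = np.arange(n) * spec.dt_ms
    v = np.full(n, spec.v_rest, dtype=float)

    dv = spec.amp_pA * spec.r_input_mohm / 1000.0   # pA * MOhm -> mV
    v_floor = spec.v_rest + dv
    flat_ms = 10.0                                   # terminal flat window

    during = (t >= spec.onset_ms) & (t < spec.offset_ms)
    td = t[during] - spec.onset_ms

    if spec.sag_fraction > 0 and spec.amp_pA < 0:
        v_end_target = v_floor * (1.0 - spec.sag_fraction)
        t_min = spec.sag_onset_frac * spec.dur_ms
        t_knee = spec.dur_ms - flat_ms
        vv = np.empty_like(td)
        a = td <= t_min
        vv[a] = _scaled_relax(td[a], spec.v_rest, v_floor, spec.tau_ms, t_min)
        b = (td > t_min) & (td <= t_knee)
        tau_sag = (t_knee - t_min) / 4.0
        vv[b] = _scaled_relax(td[b] - t_min, v_floor, v_end_target,
                              tau_sag, t_knee - t_min)
        c = td > t_knee
        vv[c] = v_end_target
        v[during] = vv
        v_min_true, v_end_true = v_floor, v_end_target
    else:
        t_knee = spec.dur_ms - flat_ms
        vv = np.where(
            td <= t_knee,
            _scaled_relax(td, spec.v_rest, v_floor, spec.tau_ms, t_knee),
            v_floor)
        v[during] = vv
        v_min_true = v_end_true = v_floor

    # post-offset: half-cosine return to rest over 20 ms, then flat
    rec_ms = 20.0
    post = t >= spec.offset_ms
    tp = t[post] - spec.offset_ms
    v_at_off = v_end_true
    v[post] = np.where(
        tp <= rec_ms,
        spec.v_rest + (v_at_off - spec.v_rest) * 0.5 * (1 + np.cos(math.pi * np.minimum(tp, rec_ms) / rec_ms)),
        spec.v_rest)

    for tk in spec.spikes.times_ms:
        _insert_spike(v, t, spec.spikes, tk)

    if spec.rebound.amp_mv != 0.0:
        rb0 = spec.offset_ms + spec.rebound.latency_ms
        seg = (t >= rb0) & (t <= rb0 + spec.rebound.width_ms)
        u = (t[seg] - rb0) / spec.rebound.width_ms
        v[seg] = v[seg] + spec.rebound.amp_mv * np.sin(math.pi * u) ** 2

    # ---- ground truth from the clean waveform ----
    truth = FeatureSet(v_rest=spec.v_rest)
    if spec.amp_pA < 0:
        truth.v_min = v_min_true
        truth.v_end = v_end_true
        truth.sr = (v_min_true - v_end_true) / v_min_true
        truth.v_drop = spec.v_rest - v_min_true
        post_win = (t > spec.offset_ms) & (t <= spec.offset_ms + 150.0)
        truth.rebound_depol_mv = float(v[post_win].max() - spec.v_rest)
    if abs(spec.amp_pA + 10.0) < 1e-9:
        truth.r_input_mohm = abs(dv) / 10.0 * 1e3
        truth.tau_m_ms = spec.tau_ms
        truth.c_m_pf = spec.tau_ms / truth.r_input_mohm * 1e3
    if spec.spikes.times_ms:
        ev = _truth_spike_scan(t, v, (spec.onset_ms, spec.offset_ms))
        if ev:
            truth.spike_amplitude_mv = float(ev[0]["peak_v"] - ev[0]["trough_v"])
            truth.spike_width_ms = float(ev[0]["half_fall"] - ev[0]["half_rise"])
            truth.spike_latency_ms = float(ev[0]["peak_t"] - spec.onset_ms)
            truth.spike_frequency_hz = len(ev) * 1000.0 / spec.dur_ms
            truth.isis_ms = [float(ev[k + 1]["half_rise"] - ev[k]["half_rise"])
                             for k in range(len(ev) - 1)]
            truth.ar = truth.isis_ms[-1] / truth.isis_ms[0] \
                if truth.isis_ms else float("nan")
        else:
            truth.spike_frequency_hz = 0.0

    if spec.noise_sigma_mv > 0:
        rng = np.random.default_rng(spec.seed)
        v = v + rng.normal(0.0, spec.noise_sigma_mv, size=n)

    i_app = np.where(during, spec.amp_pA, 0.0)
    trace = VoltageTrace(t=t, v=v, i_app=i_app, meta={
        "source": "synthetic", "seed": spec.seed,
        "noise_sigma_mv": spec.noise_sigma_mv, "pulse_pA": spec.amp_pA,
        "pulse_onset_ms": spec.onset_ms, "pulse_ms": spec.dur_ms,
    })
    return trace, truth


def synth_sweep_set(v_rest: float = -67.0, r_input_mohm: float = 300.0,
                    tau_ms: float = 30.0, sag_fraction: float = 0.04,
                    n_spikes: int = 6, rebound_mv: float = 5.0,
                    noise_sigma_mv: float = 0.0, n_passive: int = 10,
                    seed: int = 0) -> tuple[list[VoltageTrace], FeatureSet]:
    """Full synthetic sweep set (-10, -200, +200 pA) with merged ground truth."""
    onset, dur = 100.0, 300.0
    sweeps: list[VoltageTrace] = []

    passive_truth = None
    for k in range(n_passive):
        spec = TraceSpec(v_rest=v_rest, amp_pA=-10.0, dur_ms=dur,
                         r_input_mohm=r_input_mohm, tau_ms=tau_ms,
                         noise_sigma_mv=noise_sigma_mv, seed=seed * 1000 + k)
        tr, passive_truth = synth_trace(spec)
        sweeps.append(tr)

    hyp_spec = TraceSpec(v_rest=v_rest, amp_pA=-200.0, dur_ms=dur,
                         r_input_mohm=r_input_mohm, tau_ms=tau_ms,
                         sag_fraction=sag_fraction,
                         rebound=ReboundHump(amp_mv=rebound_mv),
                         noise_sigma_mv=noise_sigma_mv, seed=seed * 1000 + 500)
    hyp, hyp_truth = synth_trace(hyp_spec)
    sweeps.append(hyp)

    gap = dur / n_spikes
    times = tuple(onset + gap * (k + 0.5) for k in range(n_spikes))
    dep_spec = TraceSpec(v_rest=v_rest, amp_pA=200.0, dur_ms=dur,
                         r_input_mohm=50.0, tau_ms=tau_ms,
                         spikes=SpikeTemplate(times_ms=times),
                         noise_sigma_mv=noise_sigma_mv, seed=seed * 1000 + 900)
    dep, dep_truth = synth_trace(dep_spec)
    sweeps.append(dep)

    truth = FeatureSet(
        v_rest=v_rest,
        r_input_mohm=passive_truth.r_input_mohm,
        tau_m_ms=passive_truth.tau_m_ms,
        c_m_pf=passive_truth.c_m_pf,
        v_min=hyp_truth.v_min, v_end=hyp_truth.v_end,
        v_drop=hyp_truth.v_drop, sr=hyp_truth.sr,
        rebound_depol_mv=hyp_truth.rebound_depol_mv,
        spike_amplitude_mv=dep_truth.spike_amplitude_mv,
        spike_width_ms=dep_truth.spike_width_ms,
        spike_latency_ms=dep_truth.spike_latency_ms,
        spike_frequency_hz=dep_truth.spike_frequency_hz,
        isis_ms=dep_truth.isis_ms,
        ar=dep_truth.ar,
    )
    return sweeps, truth


# ---------------------------------------------------------------------------
# population generator
# ---------------------------------------------------------------------------

STAGES = ("subsong", "plastic", "adult")


@dataclass
class FeaturePopulation:
    """Per-cell values of one feature in one developmental group."""

    feature: str
    group: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def synth_population(feature: str, means, sems, ns, seed: int = 0,
                     ) -> list[FeaturePopulation]:
    """Draw per-cell feature values for the three stages.

    Each group draws n values from Normal(mean, sd = sem * sqrt(n)), the
    distribution whose sampling SEM matches the reported one.
    """
    means, sems, ns = list(means), list(sems), list(ns)
    if not (len(means) == len(sems) == len(ns) == 3):
        raise ValueError("need exactly three groups (subsong/plastic/adult)")
    if min(ns) < 2:
        raise ValueError("each group needs n >= 2")
    if min(sems) <= 0:
        raise ValueError("SEMs must be > 0")
    rng = np.random.default_rng(seed)
    pops = []
    for stage, mu, sem, n in zip(STAGES, means, sems, ns):
        sd = sem * math.sqrt(n)
        pops.append(FeaturePopulation(
            feature=feature, group=stage,
            values=mu + sd * rng.standard_normal(int(n))))
    return pops


# Reported group statistics (mean, SEM) per feature and stage, with group
# sizes, used as generator targets for the population stage.  Stages are
# (subsong, plastic, adult).
REFERENCE_GROUP_STATS: dict[str, dict] = {
    "HVC_X": {
        "n": (11, 11, 11),
        "resting_potential_mv": ((-67, -68, -67), (1.51, 1.54, 1.50)),
        "time_constant_ms": ((33, 39, 43), (4.28, 7.10, 7.13)),
        "input_resistance_mohm": ((282, 115, 296), (52.65, 22.72, 39.11)),
        "capacitance_pf": ((156, 308, 167), (38.95, 38.54, 28.68)),
        "v_drop_mv": ((30, 26, 46), (2.72, 2.31, 5.37)),
        "sr": ((0.01, 0.02, 0.04), (0.0013, 0.0046, 0.0065)),
        "rebound_depol_mv": ((1.7, 3.3, 40.5), (0.39, 0.52, 11.10)),
        "spike_frequency_hz": ((27, 19, 28), (4.61, 2.31, 2.65)),
        "adaptation_ratio": ((1.55, 1.79, 1.75), (0.11, 0.21, 0.13)),
        "spike_amplitude_mv": ((65, 82, 84), (4.98, 5.61, 4.17)),
        "spike_width_ms": ((2.19, 1.56, 1.87), (0.14, 0.15, 0.16)),
        "spike_latency_ms": ((56, 36, 19), (23.69, 9.46, 3.90)),
    },
    "HVC_RA": {
        "n": (8, 11, 16),
        "resting_potential_mv": ((-61, -66, -77), (2.05, 0.94, 0.57)),
        "time_constant_ms": ((28, 17, 18), (4.09, 2.48, 2.53)),
        "input_resistance_mohm": ((364, 339, 327), (36.04, 55.66, 51.93)),
        "capacitance_pf": ((83, 66, 68), (21.28, 22.17, 12.24)),
        "v_drop_mv": ((30, 29, 28), (6.55, 6.01, 3.80)),
        "sr": ((0.01, 0.02, 0.01), (0.0041, 0.0036, 0.0009)),
        "rebound_depol_mv": ((1.2, 1.8, 1.1), (0.60, 0.55, 0.20)),
        "spike_frequency_hz": ((10, 10, 7), (5.12, 3.84, 2.12)),
        "adaptation_ratio": ((2.05, 1.01, 1.34), (0.40, 0.28, 0.18)),
        "spike_amplitude_mv": ((50, 64, 77), (6.39, 3.29, 3.59)),
        "spike_width_ms": ((1.94, 1.75, 1.82), (0.18, 0.29, 0.17)),
        "spike_latency_ms": ((15, 92, 17), (8.07, 40.53, 5.72)),
    },
    "HVC_INT": {
        "n": (6, 10, 9),
        "resting_potential_mv": ((-60, -58, -57), (5.87, 1.68, 1.44)),
        "v_drop_mv": ((40, 37, 47), (6.46, 3.21, 6.34)),
        "sr": ((0.13, 0.11, 0.13), (0.0267, 0.0190, 0.0204)),
        "rebound_depol_mv": ((68.3, 61.6, 56.0), (5.52, 9.25, 2.87)),
        "spike_frequency_hz": ((79, 77, 105), (18.06, 14.18, 13.55)),
        "adaptation_ratio": ((1.20, 1.44, 1.18), (0.08, 0.18, 0.07)),
        "spike_amplitude_mv": ((67, 64, 58), (6.00, 3.02, 2.17)),
        "spike_width_ms": ((0.85, 1.16, 0.98), (0.13, 0.15, 0.09)),
        "spike_latency_ms": ((6, 5, 4), (2.86, 1.22, 0.0001)),
    },
}


def reference_population(cell_class: str, feature: str, seed: int = 0,
                         ) -> list[FeaturePopulation]:
    """Synthetic per-cell populations at the reported group statistics."""
    entry = REFERENCE_GROUP_STATS[cell_class]
    means, sems = entry[feature]
    return synth_population(f"{cell_class}:{feature}", means, sems,
                            entry["n"], seed=seed)
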