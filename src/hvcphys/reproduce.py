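"""Desk-scale reproduction pipeline.

Runs the whole chain on one CPU in about a minute: simulate all six model
cells under the standard protocol, extract the feature battery, check the
ordinal developmental phenotypes, run the two-stage circuit comparison, and
demonstrate the population statistics on synthetic feature populations.
Returns a plain dict (JSON-serialisable) listing every check and its value.
"""

from __future__ import annotations

import numpy as np

from .params import preset, PRESET_NAMES
from .model import StimulusProtocol, simulate, steady_state
from .features import extract_features, FeatureSet
from .circuit import simulate_circuit, default_drive
from .stats import anova_oneway, bonferroni_pairwise
from .synth import reference_population, synth_sweep_set


def feature_protocol(dt_out: float = 0.02) -> StimulusProtocol:
    """Minimal sweep set for extract_features: -200, -10, +200 pA."""
    return StimulusProtocol(pre_ms=100.0, pulse_pA=(-200.0, -10.0, 200.0),
                            pulse_ms=300.0, post_ms=400.0, dt_out=dt_out)


def model_features(rtol: float = 1e-6, atol: float = 1e-8,
                   ) -> dict[str, FeatureSet]:
    """Simulate and analyse every preset under the standard protocol."""
    proto = feature_protocol()
    out = {}
    for name in PRESET_NAMES:
        sweeps = simulate(preset(name), proto, rtol=rtol, atol=atol)
        out[name] = extract_features(sweeps)
    return out


def run_report(seed: int = 0) -> dict:
    """Full desk-scale pipeline; returns the report as a dict."""
    report: dict = {"seed": seed, "checks": {}, "values": {}}
    checks = report["checks"]
    values = report["values"]

    # resting potentials
    rest = {}
    for name in ("hvc_ra@adult", "hvc_x@adult"):
        ss = steady_state(preset(name))
        rest[name] = ss.state.v
        values[f"rest:{name}"] = ss.state.v
    checks["adult_ra_rest_near_-77mV"] = bool(abs(rest["hvc_ra@adult"] + 77) <= 3)
    checks["adult_x_rest_near_-67mV"] = bool(abs(rest["hvc_x@adult"] + 67) <= 3)

    # feature battery for all six cells
    feats = model_features()
    for name, fs in feats.items():
        values[f"sr:{name}"] = fs.sr
        values[f"rebound_mv:{name}"] = fs.rebound_depol_mv
        values[f"v_rest:{name}"] = fs.v_rest
        values[f"spike_freq_hz:{name}"] = fs.spike_frequency_hz

    checks["sag_ratio_adult_gt_subsong_x"] = bool(
        feats["hvc_x@adult"].sr > feats["hvc_x@subsong"].sr)
    checks["rebound_adult_gt_subsong_x"] = bool(
        feats["hvc_x@adult"].rebound_depol_mv
        > feats["hvc_x@subsong"].rebound_depol_mv)
    checks["adult_x_rebound_spiking"] = bool(
        feats["hvc_x@adult"].rebound_depol_mv > 20)
    checks["subsong_x_no_rebound_spike"] = bool(
        feats["hvc_x@subsong"].rebound_depol_mv < 10)
    checks["ra_rest_drops_gt_10mV"] = bool(
        feats["hvc_ra@subsong"].v_rest - feats["hvc_ra@adult"].v_rest > 10)
    checks["all_presets_spike_at_200pA"] = bool(
        all(f.spike_frequency_hz > 0 for f in feats.values()))

    # circuit dichotomy
    drive = default_drive()
    _, adult = simulate_circuit("adult", drive=drive)
    _, subsong = simulate_circuit("subsong", drive=drive)
    values["circuit_ra_spikes:adult"] = adult.ra_spikes
    values["circuit_ra_spikes:subsong"] = subsong.ra_spikes
    values["circuit_x_rebound_spikes:adult"] = adult.x_rebound_spikes
    checks["circuit_dichotomy"] = bool(
        adult.ra_spikes >= 1 and subsong.ra_spikes == 0)

    # synthetic round trip
    sweeps, truth = synth_sweep_set(noise_sigma_mv=0.0, seed=seed)
    got = extract_features(sweeps)
    rt_ok = all(
        np.isclose(getattr(got, f), getattr(truth, f), rtol=1e-9, atol=1e-9)
        for f in ("v_rest", "r_input_mohm", "tau_m_ms", "c_m_pf", "v_min",
                  "v_end", "v_drop", "sr", "rebound_depol_mv",
                  "spike_amplitude_mv", "spike_width_ms", "spike_latency_ms",
                  "spike_frequency_hz", "ar"))
    checks["noiseless_round_trip_exact"] = bool(rt_ok)

    # statistics demo on reported group statistics
    pops = reference_population("HVC_RA", "resting_potential_mv", seed=seed)
    an = anova_oneway(pops)
    pw = bonferroni_pairwise(pops)
    values["anova_F:ra_rest"] = an.f
    values["anova_p:ra_rest"] = an.p
    values["p_subsong_vs_adult:ra_rest"] = pw[("subsong", "adult")]
    checks["ra_rest_anova_significant"] = bool(an.p < 0.05)

    report["all_passed"] = bool(all(checks.values()))
    return report
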