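"""Three-neuron HVC microcircuit: interneuron -| HVC_X -> HVC_RA.

A stimulated interneuron inhibits an HVC_X neuron through a GABAergic
synapse; the HVC_X neuron excites an HVC_RA neuron through an AMPA synapse.
Release of the inhibition can trigger rebound firing in the HVC_X cell,
which in turn can drive the HVC_RA cell.  Whether the chain completes
depends only on the intrinsic parameters of the two projection neurons:
synaptic kinetics and weights are identical across developmental stages.

Synaptic model: presynaptic depolarization releases transmitter

    Tr(V_pre) = T_max / (1 + exp(-(V_pre + 5)/4)),  T_max = 1.5 mM,

the bound fraction x of postsynaptic receptors follows

    dx/dt = alpha (1 - x) Tr(V_pre) - beta x,

and the postsynaptic current is I_syn = g x (V_post - V_syn).  Tr carries
units of concentration (M), matching alpha in M^-1 ms^-1.

The interneuron is represented by a scripted presynaptic voltage waveform
(a spike train driving the GABA synapse); the microcircuit conclusion
depends only on HVC_X / HVC_RA intrinsic physiology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .params import NeuronParams, preset
from .model import (ModelState, VoltageTrace, IntegrationError, _currents,
                    _rhs, relax)

TR_MAX = 0.0015        # maximal transmitter concentration (M)
TR_MID = -5.0          # half-release presynaptic voltage (mV)
TR_SLOPE = 4.0         # e-fold slope (mV)


@dataclass
class SynapseParams:
    """Kinetic constants of one transmitter system."""

    transmitter: str   # "GABA" or "AMPA"
    alpha: float       # forward binding rate (M^-1 ms^-1)
    beta: float        # unbinding rate (ms^-1)
    g: float           # maximal conductance (nS)
    V_syn: float       # reversal potential (mV)

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.g) <= 0:
            raise ValueError("alpha, beta, g must be > 0")


GABA = SynapseParams("GABA", alpha=5000.0, beta=0.18, g=180.0, V_syn=-90.0)
AMPA = SynapseParams("AMPA", alpha=1100.0, beta=0.19, g=20.0, V_syn=0.0)


def transmitter_release(v_pre: float):
    """Transmitter concentration (M) as a function of presynaptic voltage."""
    return TR_MAX / (1.0 + np.exp(-(np.asarray(v_pre, dtype=float) - TR_MID)
                                  / TR_SLOPE))


def receptor_gate_derivative(x: float, v_pre: float, s: SynapseParams) -> float:
    """dx/dt of the bound receptor fraction."""
    return s.alpha * (1.0 - x) * float(transmitter_release(v_pre)) - s.beta * x


def receptor_fixed_point(v_pre: float, s: SynapseParams) -> float:
    """Steady bound fraction under clamped presynaptic voltage."""
    atr = s.alpha * float(transmitter_release(v_pre))
    return atr / (atr + s.beta)


def synaptic_current(x: float, v_post: float, s: SynapseParams) -> float:
    """Postsynaptic current g x (V_post - V_syn), pA (positive outward)."""
    return s.g * x * (v_post - s.V_syn)


@dataclass
class SpikeTrainDrive:
    """Scripted presynaptic voltage: baseline with brief spike depolarizations.

    Each spike is a Gaussian bump (width sigma_ms) from ``v_base`` to
    ``v_peak``; at the peak the release sigmoid is saturated.
    """

    times_ms: tuple = tuple(100.0 + 10.0 * k for k in range(25))
    v_base: float = -70.0
    v_peak: float = 20.0
    sigma_ms: float = 0.5

    def __call__(self, t: float) -> float:
        v = self.v_base
        amp = self.v_peak - self.v_base
        for tk in self.times_ms:
            d = t - tk
            if abs(d) < 6.0 * self.sigma_ms:
                v += amp * math.exp(-0.5 * (d / self.sigma_ms) ** 2)
        return v

    @property
    def end_ms(self) -> float:
        if not self.times_ms:
            return 0.0
        return max(self.times_ms) + 6.0 * self.sigma_ms


def default_drive(n_spikes: int = 25, rate_hz: float = 100.0,
                  start_ms: float = 100.0) -> SpikeTrainDrive:
    """Interneuron burst: ``n_spikes`` at ``rate_hz`` starting at ``start_ms``.

    The default (25 spikes at 100 Hz) hyperpolarizes the HVC_X neuron for
    ~250 ms, comparable in duration and depth to the -200 pA single-cell
    protocol.
    """
    dt = 1000.0 / rate_hz
    return SpikeTrainDrive(times_ms=tuple(start_ms + dt * k
                                          for k in range(n_spikes)))


@dataclass
class CircuitOutcome:
    """Spike counts summarizing one circuit run."""

    stage: str
    x_rebound_spikes: int
    ra_spikes: int
    drive_end_ms: float


def _circuit_rhs(t, y, px: NeuronParams, pra: NeuronParams,
                 drive, gaba: SynapseParams, ampa: SynapseParams):
    x_state = y[0:8]
    ra_state = y[8:16]
    x_gaba, x_ampa = y[16], y[17]

    v_int = drive(t)
    v_x = x_state[0]
    v_ra = ra_state[0]

    i_gaba = synaptic_current(x_gaba, v_x, gaba)
    i_ampa = synaptic_current(x_ampa, v_ra, ampa)

    dx = list(_rhs(t, x_state, px, 0.0))
    dra = list(_rhs(t, ra_state, pra, 0.0))
    # synaptic currents add to the respective membrane equations
    dx[0] -= i_gaba / px.C
    dra[0] -= i_ampa / pra.C

    dxg = receptor_gate_derivative(x_gaba, v_int, gaba)
    dxa = receptor_gate_derivative(x_ampa, v_x, ampa)
    return dx + dra + [dxg, dxa]


def _count_spikes(t: np.ndarray, v: np.ndarray, t0: float, t1: float,
                  height: float = -20.0, prominence: float = 20.0) -> int:
    sel = (t >= t0) & (t <= t1)
    vv = v[sel]
    if len(vv) < 3:
        return 0
    count = 0
    trough = vv[0]
    for i in range(1, len(vv) - 1):
        trough = min(trough, vv[i])
        if vv[i] > vv[i - 1] and vv[i] >= vv[i + 1] \
                and vv[i] > height and vv[i] - trough >= prominence:
            count += 1
            trough = vv[i]
    return count


def simulate_circuit(stage: str, drive: SpikeTrainDrive | None = None,
                     duration_ms: float = 700.0, dt_out: float = 0.05,
                     rtol: float = 1e-6, atol: float = 1e-8,
                     gaba: SynapseParams = GABA, ampa: SynapseParams = AMPA,
                     ) -> tuple[list[VoltageTrace], CircuitOutcome]:
    """Run the three-neuron circuit at one developmental stage.

    ``stage`` is 'subsong' or 'adult' and selects the corresponding HVC_X
    and HVC_RA parameter presets; synapses and drive are stage-independent.
    Returns traces for (interneuron-drive, HVC_X, HVC_RA) and the outcome
    record (HVC_X rebound spikes after the drive ends, HVC_RA spikes).
    """
    if stage not in ("subsong", "plastic", "adult"):
        raise ValueError(f"unknown stage {stage!r}")
    if drive is None:
        drive = default_drive()
    px = preset(f"hvc_x@{stage}")
    pra = preset(f"hvc_ra@{stage}")

    x0 = relax(px, rtol=rtol, atol=atol).as_array()
    ra0 = relax(pra, rtol=rtol, atol=atol).as_array()
    y0 = np.concatenate([x0, ra0, [0.0, 0.0]])

    n_samp = int(round(duration_ms / dt_out)) + 1
    t_eval = np.arange(n_samp) * dt_out
    sol = solve_ivp(_circuit_rhs, (0.0, duration_ms), y0, method="RK23",
                    rtol=rtol, atol=atol, t_eval=t_eval, max_step=0.5,
                    args=(px, pra, drive, gaba, ampa))
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise IntegrationError(f"circuit integration failed ({sol.message})")

    t = sol.t
    v_int = np.array([drive(tk) for tk in t])
    v_x = sol.y[0]
    v_ra = sol.y[8]
    zeros = np.zeros_like(t)

    meta = {"stage": stage, "drive_spikes": len(drive.times_ms),
            "solver": {"method": "RK23", "rtol": rtol, "atol": atol}}
    traces = [
        VoltageTrace(t=t, v=v_int, i_app=zeros, meta={**meta, "cell": "INT(drive)"}),
        VoltageTrace(t=t, v=v_x, i_app=zeros, meta={**meta, "cell": "HVC_X"}),
        VoltageTrace(t=t, v=v_ra, i_app=zeros, meta={**meta, "cell": "HVC_RA"}),
    ]
    outcome = CircuitOutcome(
        stage=stage,
        x_rebound_spikes=_count_spikes(t, v_x, drive.end_ms, duration_ms),
        ra_spikes=_count_spikes(t, v_ra, 0.0, duration_ms),
        drive_end_ms=drive.end_ms,
    )
    return traces, outcome
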