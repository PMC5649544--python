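"""Single-compartment conductance-based HVC neuron models.

The membrane potential obeys

    C dV/dt = -(I_L + I_K + I_Na + I_Nap + I_CaL + I_CaT + I_A + I_SK
                + I_M + I_h - I_app)

with all currents in pA (positive = outward), C in pF, V in mV.  Gating
variables follow first-order kinetics x' = (x_inf(V) - x)/tau_x(V) and
intracellular calcium follows an influx/removal balance driven by the two
Ca currents.

Dynamic state (8 variables): V, delayed-rectifier n, Na inactivation h_Na,
M-current z, h-current slow and fast activation s_h/f_h, T-type
inactivation b_T, and [Ca].  The remaining gates (Na activation m,
persistent-Na p, L-type s, T-type activation a, A-current a_A) are treated
as instantaneous functions of voltage.  The T-type activation enters
squared; the L-type activation enters squared; the delayed rectifier enters
as n^4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .params import NeuronParams
from . import gates


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails or the state becomes non-finite."""


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------

_STATE_FIELDS = ("v", "n", "h_na", "z", "s_h", "f_h", "b_t", "ca")


@dataclass
class ModelState:
    """Instantaneous dynamical state of one model neuron."""

    v: float = -70.0   # membrane potential (mV)
    n: float = 0.0     # delayed-rectifier activation
    h_na: float = 1.0  # Na inactivation
    z: float = 0.0     # M-current activation
    s_h: float = 0.0   # h-current slow activation
    f_h: float = 0.0   # h-current fast activation
    b_t: float = 0.0   # T-type Ca inactivation
    ca: float = 0.05   # intracellular calcium (uM)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in _STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, y) -> "ModelState":
        return cls(**dict(zip(_STATE_FIELDS, map(float, y))))

    @classmethod
    def at_voltage(cls, p: NeuronParams, v: float, ca: float | None = None) -> "ModelState":
        """State with every gate (and [Ca]) at its steady value for ``v``.

        The calcium equilibrium at clamped voltage is
        b_Ca - (eps_Ca/k_Ca)(I_CaL + I_CaT), the balance of influx through
        the Ca currents against first-order removal.
        """
        state = cls(
            v=v,
            n=float(gates.boltzmann(v, p.theta_n, p.sigma_n)),
            h_na=float(gates.na_h_inf(v)),
            z=float(gates.boltzmann(v, p.theta_z, p.sigma_z)),
            s_h=float(gates.h_inf(v)),
            f_h=float(gates.h_inf(v)),
            b_t=float(gates.boltzmann(v, p.theta_bT, p.sigma_bT)),
            ca=p.b_Ca if ca is None else ca,
        )
        if ca is None:
            cur = _currents(state.v, state.n, state.h_na, state.z,
                            state.s_h, state.f_h, state.b_t, state.ca, p)
            i_ca = cur[4] + cur[5]           # I_CaL + I_CaT
            state.ca = max(0.0, p.b_Ca - p.eps_Ca / p.k_Ca * i_ca)
        return state


@dataclass
class CurrentBreakdown:
    """All ionic currents at one instant, in pA (positive = outward)."""

    I_L: float
    I_K: float
    I_Na: float
    I_Nap: float
    I_CaL: float
    I_CaT: float
    I_A: float
    I_SK: float
    I_M: float
    I_h: float

    def total(self) -> float:
        return sum(asdict(self).values())

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class StimulusProtocol:
    """Square current pulse protocol: baseline, pulse, recovery."""

    pre_ms: float = 100.0
    pulse_pA: tuple = (-200.0, 200.0)
    pulse_ms: float = 300.0
    post_ms: float = 400.0
    dt_out: float = 0.02

    def __post_init__(self) -> None:
        if min(self.pre_ms, self.pulse_ms, self.post_ms) <= 0:
            raise ValueError("all protocol durations must be > 0")
        if self.dt_out <= 0:
            raise ValueError("dt_out must be > 0")
        if len(tuple(self.pulse_pA)) == 0:
            raise ValueError("pulse amplitude list must be non-empty")
        self.pulse_pA = tuple(float(a) for a in self.pulse_pA)

    @property
    def total_ms(self) -> float:
        return self.pre_ms + self.pulse_ms + self.post_ms

    def current_at(self, t: float, amp: float) -> float:
        if self.pre_ms <= t < self.pre_ms + self.pulse_ms:
            return amp
        return 0.0


def standard_protocol(dt_out: float = 0.02) -> StimulusProtocol:
    """300 ms square pulses from -200 to +200 pA in 50 pA steps."""
    return StimulusProtocol(
        pre_ms=100.0,
        pulse_pA=tuple(float(a) for a in range(-200, 201, 50)),
        pulse_ms=300.0,
        post_ms=400.0,
        dt_out=dt_out,
    )


@dataclass
class VoltageTrace:
    """Uniformly sampled record of one current-clamp sweep."""

    t: np.ndarray       # time (ms)
    v: np.ndarray       # membrane potential (mV)
    i_app: np.ndarray   # applied current (pA)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.i_app = np.asarray(self.i_app, dtype=float)
        if not (len(self.t) == len(self.v) == len(self.i_app)):
            raise ValueError("t, v, i_app must have equal length")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("t must be strictly increasing with constant step")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


# ---------------------------------------------------------------------------
# currents and right-hand side
# ---------------------------------------------------------------------------

def _currents(v, n, h_na, z, s_h, f_h, b_t, ca, p: NeuronParams):
    """All ten ionic currents (pA, positive outward) as a tuple.

    Scalar math throughout: this is the hot path of the ODE integrator.
    """
    exp = math.exp

    i_l = p.g_L * (v - p.V_L)

    m_inf = 1.0 / (1.0 + exp((v - p.theta_m) / p.sigma_m))
    i_na = p.g_Na * m_inf * m_inf * m_inf * h_na * (v - p.V_Na)

    i_k = p.g_K * n * n * n * n * (v - p.V_K)

    p_inf = 1.0 / (1.0 + exp((v - p.theta_p) / p.sigma_p))
    i_nap = p.g_Nap * p_inf * (v - p.V_Na)

    s_inf = 1.0 / (1.0 + exp((v - p.theta_s) / p.sigma_s))
    i_cal = p.g_CaL * s_inf * s_inf * (v - p.E_Ca)

    a_inf = 1.0 / (1.0 + exp((v - p.theta_aT) / p.sigma_aT))
    i_cat = p.g_CaT * a_inf * a_inf * b_t * (v - p.E_Ca)

    aA_inf = 1.0 / (1.0 + exp((v - p.theta_aA) / p.sigma_aA))
    i_a = p.g_A * aA_inf * (v - p.V_K)

    ca2 = ca * ca
    i_sk = p.g_SK * (ca2 / (ca2 + p.k_s * p.k_s)) * (v - p.V_K)

    i_m = p.g_M * z * (v - p.V_K)

    i_h = p.g_h * (p.w_h * f_h + (1.0 - p.w_h) * s_h) * (v - p.V_h)

    return i_l, i_k, i_na, i_nap, i_cal, i_cat, i_a, i_sk, i_m, i_h


def membrane_currents(state: ModelState, p: NeuronParams) -> CurrentBreakdown:
    """Evaluate every ionic current at the given state."""
    i_l, i_k, i_na, i_nap, i_cal, i_cat, i_a, i_sk, i_m, i_h = _currents(
        state.v, state.n, state.h_na, state.z, state.s_h, state.f_h,
        state.b_t, state.ca, p)
    return CurrentBreakdown(I_L=i_l, I_K=i_k, I_Na=i_na, I_Nap=i_nap,
                            I_CaL=i_cal, I_CaT=i_cat, I_A=i_a, I_SK=i_sk,
                            I_M=i_m, I_h=i_h)


def ih_current(v: float, f_h: float, s_h: float, p: NeuronParams) -> float:
    """Hyperpolarization-activated current g_h (w_h f + (1-w_h) s)(V - V_h)."""
    return p.g_h * (p.w_h * f_h + (1.0 - p.w_h) * s_h) * (v - p.V_h)


def im_current(v: float, z: float, p: NeuronParams) -> float:
    """M-type K current g_M z (V - V_K)."""
    return p.g_M * z * (v - p.V_K)


def _rhs(t: float, y, p: NeuronParams, i_app: float):
    v, n, h_na, z, s_h, f_h, b_t, ca = y
    exp = math.exp
    cosh = math.cosh

    i_l, i_k, i_na, i_nap, i_cal, i_cat, i_a, i_sk, i_m, i_h = _currents(
        v, n, h_na, z, s_h, f_h, b_t, ca, p)
    total = i_l + i_k + i_na + i_nap + i_cal + i_cat + i_a + i_sk + i_m + i_h
    dv = -(total - i_app) / p.C

    n_inf = 1.0 / (1.0 + exp((v - p.theta_n) / p.sigma_n))
    taun = p.tau_n_bar / cosh((v - p.theta_n) / (2.0 * p.sigma_n))
    dn = (n_inf - n) / taun

    h_inf = 1.0 / (1.0 + exp((v + 38.0) / 3.5))
    tau_h = 0.3 + 4.4 / cosh((v + 38.0) / 7.0)
    dh = (h_inf - h_na) / tau_h

    z_inf = 1.0 / (1.0 + exp((v - p.theta_z) / p.sigma_z))
    dz = (z_inf - z) / p.tau_z

    hh_inf = 1.0 / (1.0 + exp((v - gates.H_THETA) / gates.H_SIGMA))
    tau_s = exp((v + 289.7) / 33.3)
    tau_f = 0.51 + 100.0 / (exp((v + 86.0) / 11.4) + exp(-(v + 86.0) / 25.6))
    ds = (hh_inf - s_h) / tau_s
    df = (hh_inf - f_h) / tau_f

    b_inf = 1.0 / (1.0 + exp((v - p.theta_bT) / p.sigma_bT))
    # recovery from inactivation is fast when hyperpolarized, inactivation
    # near the T-window is slow (classic low-threshold Ca asymmetry)
    tau_b = p.tau_bT + (p.tau_bT_depol - p.tau_bT) / (1.0 + exp(-(v + 70.0) / 4.0))
    db = (b_inf - b_t) / tau_b

    dca = -p.f_Ca * (p.eps_Ca * (i_cal + i_cat) + p.k_Ca * (ca - p.b_Ca))

    return (dv, dn, dh, dz, ds, df, db, dca)


def rhs(state: ModelState, p: NeuronParams, i_app: float = 0.0) -> ModelState:
    """Time derivative of the state (dV/dt in mV/ms, gates in ms^-1)."""
    d = _rhs(0.0, state.as_array(), p, i_app)
    return ModelState(*d)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def _integrate_segment(p, y0, t0, t1, i_app, t_eval, rtol, atol):
    sol = solve_ivp(
        _rhs, (t0, t1), y0, method="RK23", rtol=rtol, atol=atol,
        t_eval=t_eval, args=(p, i_app), dense_output=False)
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise IntegrationError(
            f"integration failed near t = {sol.t[-1] if len(sol.t) else t0:.3f} ms"
            f" ({sol.message})")
    return sol


def relax(p: NeuronParams, duration_ms: float = 2000.0, i_app: float = 0.0,
          v0: float = -70.0, state0: ModelState | None = None,
          rtol: float = 1e-6, atol: float = 1e-8) -> ModelState:
    """Integrate at constant applied current and return the final state."""
    y0 = (state0 or ModelState.at_voltage(p, v0)).as_array()
    sol = _integrate_segment(p, y0, 0.0, duration_ms, i_app,
                             np.array([duration_ms]), rtol, atol)
    return ModelState.from_array(sol.y[:, -1])


def simulate(p: NeuronParams, proto: StimulusProtocol,
             rtol: float = 1e-6, atol: float = 1e-8,
             init: ModelState | None = None,
             relax_ms: float = 2000.0) -> list[VoltageTrace]:
    """Run the protocol and return one trace per pulse amplitude.

    The initial condition is the state after ``relax_ms`` of simulated rest
    at zero applied current (shared across amplitudes), unless ``init`` is
    given.
    """
    if init is None:
        init = relax(p, duration_ms=relax_ms, rtol=rtol, atol=atol)
    dt = proto.dt_out
    n_samp = int(round(proto.total_ms / dt)) + 1
    grid = np.arange(n_samp) * dt
    bounds = (0.0, proto.pre_ms, proto.pre_ms + proto.pulse_ms, proto.total_ms)

    traces = []
    for amp in proto.pulse_pA:
        y = init.as_array()
        ts, vs = [], []
        for k, (t0, t1) in enumerate(zip(bounds[:-1], bounds[1:])):
            i_seg = amp if k == 1 else 0.0
            mask = (grid >= t0 - 1e-9) & (grid <= t1 + 1e-9)
            pts = grid[mask]
            has_t1 = len(pts) > 0 and abs(pts[-1] - t1) < 1e-9
            t_eval = pts if has_t1 else np.append(pts, t1)
            sol = _integrate_segment(p, y, t0, t1, i_seg, t_eval, rtol, atol)
            y = sol.y[:, -1].copy()
            seg_t, seg_v = sol.t[:len(pts)], sol.y[0, :len(pts)]
            if ts and len(seg_t) and abs(seg_t[0] - ts[-1][-1]) < 1e-9:
                seg_t, seg_v = seg_t[1:], seg_v[1:]
            ts.append(seg_t)
            vs.append(seg_v)
        t = np.concatenate(ts)
        v = np.concatenate(vs)
        i_app = np.where((t >= proto.pre_ms) & (t < proto.pre_ms + proto.pulse_ms),
                         amp, 0.0)
        meta = {
            "cell_class": p.cell_class, "stage": p.stage, "pulse_pA": amp,
            "pulse_onset_ms": proto.pre_ms, "pulse_ms": proto.pulse_ms,
            "solver": {"method": "RK23", "rtol": rtol, "atol": atol,
                       "dt_out": dt, "relax_ms": relax_ms},
        }
        traces.append(VoltageTrace(t=t, v=v, i_app=i_app, meta=meta))
    return traces


@dataclass
class SteadyStateResult:
    """Outcome of the equilibrium search."""

    state: ModelState
    limit_cycle: bool      # True when no fixed point was reached
    residual: float        # max |dx/dt| at the returned state


def steady_state(p: NeuronParams, i_app: float = 0.0,
                 max_ms: float = 10000.0, tol: float = 1e-6) -> SteadyStateResult:
    """Find a resting state at constant applied current.

    Long relaxation followed by a root polish of the right-hand side.  If
    the trajectory has not settled within ``max_ms`` of simulated time
    (e.g. a spontaneously spiking parameter set), the result is flagged as
    a limit cycle and carries the final trajectory state instead.
    """
    state = ModelState.at_voltage(p, -70.0)
    elapsed = 0.0
    chunk = 2000.0
    while elapsed < max_ms:
        state = relax(p, duration_ms=chunk, i_app=i_app, state0=state)
        elapsed += chunk
        resid = float(np.max(np.abs(_rhs(0.0, state.as_array(), p, i_app))))
        if resid < 1e-4:
            break
    sol = root(lambda y: np.asarray(_rhs(0.0, y, p, i_app)),
               state.as_array(), method="hybr", tol=1e-12)
    if sol.success:
        polished = ModelState.from_array(sol.x)
        resid = float(np.max(np.abs(_rhs(0.0, sol.x, p, i_app))))
        # accept the root only if the relaxation actually approached it
        if resid < tol and abs(polished.v - state.v) < 1.0:
            return SteadyStateResult(state=polished, limit_cycle=False,
                                     residual=resid)
    resid = float(np.max(np.abs(_rhs(0.0, state.as_array(), p, i_app))))
    return SteadyStateResult(state=state, limit_cycle=resid >= tol,
                             residual=resid)
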