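"""Parameter sets for single-compartment HVC neuron models.

Units used throughout the package: mV, ms, pA, nS, pF, uM.  These are
mutually consistent for membrane equations: 1 nS * 1 mV = 1 pA, and the
membrane time constant C/g is in ms when C is in pF and g in nS.

Six published parameter columns are shipped as presets, one per projection
neuron class (HVC_X -> Area X, HVC_RA -> nucleus RA) and developmental
stage (subsong, plastic song, adult song).  Fields that the published
parameter table does not vary across cells (reversal potentials of Na/K/Ca,
persistent-Na and A-current gates, T-type inactivation, calcium handling
rates) are package-level defaults, chosen once so that the six columns
reproduce the reported physiology; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Literal

CellClass = Literal["HVC_X", "HVC_RA", "HVC_INT"]
Stage = Literal["subsong", "plastic", "adult"]


@dataclass
class NeuronParams:
    """Full parameter set of one conductance-based HVC neuron model."""

    cell_class: str = "HVC_X"
    stage: str = "adult"

    # passive
    C: float = 100.0          # membrane capacitance (pF)
    g_L: float = 5.0          # leak conductance (nS)
    V_L: float = -70.0        # leak reversal (mV)

    # maximal conductances (nS)
    g_Na: float = 0.0
    g_K: float = 0.0
    g_Nap: float = 0.0
    g_CaL: float = 0.0
    g_CaT: float = 0.0
    g_A: float = 0.0
    g_SK: float = 0.0
    g_M: float = 0.0
    g_h: float = 0.0

    # reversal potentials (mV)
    V_Na: float = 55.0
    V_K: float = -90.0
    E_Ca: float = 120.0
    V_h: float = -43.0

    # h-current: fraction of conductance with fast activation
    w_h: float = 0.5

    # transient Na activation (instantaneous m_inf)
    theta_m: float = -35.0
    sigma_m: float = -5.0

    # delayed-rectifier K activation
    theta_n: float = -30.0
    sigma_n: float = -7.0
    tau_n_bar: float = 10.0   # scale of the voltage-dependent tau_n (ms)

    # M-type K current
    theta_z: float = -39.0
    sigma_z: float = -5.0     # activation increases with depolarization
    tau_z: float = 75.0       # ms

    # persistent Na (instantaneous p_inf)
    theta_p: float = -50.0
    sigma_p: float = -3.0

    # L-type Ca activation (instantaneous s_inf, squared)
    theta_s: float = -13.0
    sigma_s: float = -8.6

    # T-type Ca activation (instantaneous a_inf, cubed) and slow inactivation
    theta_aT: float = -59.0
    sigma_aT: float = -6.0
    theta_bT: float = -78.0
    sigma_bT: float = 5.0     # positive: inactivation removed by hyperpolarization
    tau_bT: float = 100.0     # recovery time constant, hyperpolarized limit (ms)
    tau_bT_depol: float = 400.0  # inactivation time constant, depolarized limit (ms)

    # A-type K activation (instantaneous)
    theta_aA: float = -20.0
    sigma_aA: float = -10.0

    # SK / calcium handling
    k_s: float = 0.4          # SK half-activation [Ca] (uM)
    f_Ca: float = 0.01        # fraction of free calcium
    b_Ca: float = 0.05        # basal [Ca] (uM)
    eps_Ca: float = 0.0035    # current-to-concentration conversion (uM pA^-1 ms^-1)
    k_Ca: float = 0.025       # calcium removal rate (ms^-1)

    def __post_init__(self) -> None:
        for name in ("g_L", "g_Na", "g_K", "g_Nap", "g_CaL", "g_CaT",
                     "g_A", "g_SK", "g_M", "g_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if not 0.0 <= self.w_h <= 1.0:
            raise ValueError("w_h must lie in [0, 1]")
        if self.tau_z <= 0 or self.tau_bT <= 0 or self.tau_n_bar <= 0:
            raise ValueError("time constants must be > 0")
        if self.k_s <= 0:
            raise ValueError("k_s must be > 0")
        if self.b_Ca < 0:
            raise ValueError("b_Ca must be >= 0")

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronParams":
        return cls(**d)

    def with_(self, **kw) -> "NeuronParams":
        """Copy with selected fields replaced."""
        return replace(self, **kw)


def leak_only(C: float = 120.0, g_L: float = 4.0, V_L: float = -70.0) -> NeuronParams:
    """Passive RC cell: every voltage-gated conductance zeroed.

    Useful as an analytically solvable reference (tau = C/g_L,
    R = 1/g_L in GOhm).
    """
    return NeuronParams(cell_class="HVC_X", stage="adult", C=C, g_L=g_L, V_L=V_L)


# ---------------------------------------------------------------------------
# Published parameter columns, one per cell class x developmental stage.
# Conductances in nS, potentials in mV, capacitance in pF, taus in ms.
# ---------------------------------------------------------------------------

_SHARED = dict(
    V_h=-43.0, g_CaL=1.0, g_A=5.0, g_Nap=3.0,
    theta_s=-13.0, sigma_s=-8.6, theta_aT=-59.0, sigma_aT=-6.0,
    k_s=0.4, f_Ca=0.01, b_Ca=0.05,
)

_COLUMNS: dict[str, dict] = {
    "hvc_ra@subsong": dict(
        cell_class="HVC_RA", stage="subsong",
        V_L=-62.0, g_L=4.0, g_Na=560.0, g_K=80.0, g_M=160.0, g_CaT=0.1,
        g_SK=1.0, g_h=0.8, w_h=0.95, C=60.0,
        sigma_m=-5.0, theta_m=-30.0, tau_n_bar=15.0, tau_z=75.0,
        theta_z=-29.0, theta_n=-32.0, sigma_n=-5.0,
    ),
    "hvc_ra@plastic": dict(
        cell_class="HVC_RA", stage="plastic",
        V_L=-62.0, g_L=7.0, g_Na=440.0, g_K=80.0, g_M=100.0, g_CaT=1.0,
        g_SK=5.0, g_h=2.2, w_h=0.95, C=55.0,
        sigma_m=-5.0, theta_m=-32.0, tau_n_bar=8.0, tau_z=75.0,
        theta_z=-30.0, theta_n=-30.0, sigma_n=-5.0,
    ),
    "hvc_ra@adult": dict(
        cell_class="HVC_RA", stage="adult",
        V_L=-77.0, g_L=7.0, g_Na=300.0, g_K=500.0, g_M=32.0, g_CaT=1.0,
        g_SK=32.0, g_h=1.6, w_h=0.95, C=58.0,
        sigma_m=-10.0, theta_m=-35.0, tau_n_bar=15.0, tau_z=75.0,
        theta_z=-45.0, theta_n=-30.0, sigma_n=-7.0,
    ),
    "hvc_x@subsong": dict(
        cell_class="HVC_X", stage="subsong",
        V_L=-72.0, g_L=5.6, g_Na=1500.0, g_K=160.0, g_M=11.8, g_CaT=2.0,
        g_SK=0.4, g_h=0.4, w_h=0.3, C=220.0,
        sigma_m=-5.0, theta_m=-36.0, tau_n_bar=10.0, tau_z=26.25,
        theta_z=-35.0, theta_n=-30.0, sigma_n=-10.0,
    ),
    "hvc_x@plastic": dict(
        cell_class="HVC_X", stage="plastic",
        V_L=-75.0, g_L=5.0, g_Na=3100.0, g_K=180.0, g_M=53.0, g_CaT=2.0,
        g_SK=2.8, g_h=4.1, w_h=0.99, C=245.0,
        sigma_m=-8.0, theta_m=-35.0, tau_n_bar=10.0, tau_z=45.0,
        theta_z=-39.0, theta_n=-30.0, sigma_n=-7.0,
    ),
    "hvc_x@adult": dict(
        cell_class="HVC_X", stage="adult",
        V_L=-63.0, g_L=5.0, g_Na=2300.0, g_K=120.0, g_M=15.4, g_CaT=3.8,
        g_SK=2.1, g_h=2.25, w_h=0.17, C=260.0,
        sigma_m=-4.0, theta_m=-38.0, tau_n_bar=10.0, tau_z=75.0,
        theta_z=-39.0, theta_n=-30.0, sigma_n=-6.0,
    ),
}

PRESET_NAMES = tuple(_COLUMNS)


def preset(name: str) -> NeuronParams:
    """Return one of the six published parameter sets by name.

    Names are '<cell>@<stage>' with cell in {hvc_x, hvc_ra} and stage in
    {subsong, plastic, adult}, e.g. 'hvc_x@adult'.
    """
    key = name.lower()
    if key not in _COLUMNS:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}")
    return NeuronParams(**{**_SHARED, **_COLUMNS[key]})
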