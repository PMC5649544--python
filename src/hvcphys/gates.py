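"""Gating functions: steady-state activation curves and time constants.

All voltage-dependent gates in the models use the Boltzmann sigmoid

    x_inf(V) = 1 / (1 + exp((V - theta) / sigma))

with midpoint theta (mV) and slope sigma (mV).  A negative sigma gives a
gate that opens with depolarization (activation); a positive sigma gives a
gate that opens with hyperpolarization (the h-current activation and the
T-type inactivation gate).
"""

from __future__ import annotations

import numpy as np

# h-current activation curve: half-activated at -87.7 mV, e-fold 6.4 mV,
# opening with hyperpolarization.
H_THETA = -87.7
H_SIGMA = 6.4


def boltzmann(v, theta: float, sigma: float):
    """Boltzmann sigmoid 1/(1+exp((v-theta)/sigma)).

    Accepts scalars or arrays.  Strictly monotone in v, range (0, 1).
    Raises ValueError when sigma == 0 (degenerate step function).
    """
    if sigma == 0:
        raise ValueError("boltzmann slope sigma must be nonzero")
    return 1.0 / (1.0 + np.exp((np.asarray(v, dtype=float) - theta) / sigma))


def h_inf(v):
    """Steady-state activation shared by both h-current components."""
    return boltzmann(v, H_THETA, H_SIGMA)


def h_time_constants(v):
    """Activation time constants (tau_slow, tau_fast) of the h-current, ms.

    The slow component shortens e-fold per 33.3 mV of hyperpolarization
    (hundreds of ms in the physiological range).  The fast component is a
    bell-shaped curve peaking at ~54 ms near -86 mV and falling off on
    either side, so tau_slow >> tau_fast throughout -120..-60 mV.
    """
    v = np.asarray(v, dtype=float)
    tau_s = np.exp((v + 289.7) / 33.3)
    tau_f = 0.51 + 100.0 / (np.exp((v + 86.0) / 11.4) + np.exp(-(v + 86.0) / 25.6))
    return tau_s, tau_f


def na_h_inf(v):
    """Na inactivation steady state: steep Boltzmann, midpoint -38 mV.

    Inactivation must be nearly complete above -25 mV (otherwise the
    Na window current locks the large-g_Na cells in depolarization block)
    yet nearly absent at spike threshold (~-48 mV).
    """
    return boltzmann(v, -38.0, 3.5)


def na_h_tau(v):
    """Na inactivation time constant (ms): bell around the midpoint."""
    v = np.asarray(v, dtype=float)
    return 0.3 + 4.4 / np.cosh((v + 38.0) / 7.0)


def na_h_rates(v):
    """Equivalent opening/closing rates alpha_h, beta_h (ms^-1).

    Defined through h_inf = alpha/(alpha+beta) and tau_h = 1.2/(alpha+beta).
    """
    hinf = na_h_inf(v)
    tau = na_h_tau(v)
    return 1.2 * hinf / tau, 1.2 * (1.0 - hinf) / tau


def tau_n(v, theta_n: float, sigma_n: float, tau_n_bar: float):
    """Delayed-rectifier activation time constant, ms.

    tau_n(V) = tau_n_bar / cosh((V - theta_n) / (2 sigma_n)): maximal at the
    activation midpoint and shorter at voltages away from it, so the gate
    tracks fast spike upstrokes while relaxing slowly near threshold.
    """
    v = np.asarray(v, dtype=float)
    return tau_n_bar / np.cosh((v - theta_n) / (2.0 * sigma_n))
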