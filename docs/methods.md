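# Methods

## Scope

`hvcphys` implements three connected pieces: (1) single-compartment
conductance-based models of HVC projection neurons at three stages of zebra
finch vocal development (subsong, plastic song, adult song), shipped as six
named parameter presets; (2) an automated current-clamp feature analysis
applied identically to simulated and synthetic voltage traces; (3) a
three-neuron microcircuit (interneuron -| HVC_X -> HVC_RA) showing that the
developmental change in projection-neuron intrinsic physiology alone, with
synapses held fixed, switches the circuit's output. A synthetic-data
generator supplies all test inputs; no recordings are required anywhere.

## Units

mV, ms, pA, nS, pF, µM throughout. These are mutually consistent:
1 nS · mV = 1 pA and τ = C/g is in ms for C in pF and g in nS, so the
published parameter table loads without conversion. 1 mV/pA = 1 GΩ; passive
properties are reported in MΩ and pF.

## Membrane model

    C dV/dt = −(I_L + I_K + I_Na + I_Nap + I_CaL + I_CaT + I_A + I_SK
                + I_M + I_h − I_app)

with positive current outward. Dynamic gates (x' = (x∞ − x)/τ_x): the
delayed-rectifier activation n, Na inactivation h_Na, M-current activation
z, h-current slow/fast activations s and f, T-type inactivation b_T, plus
intracellular calcium. Na activation m, persistent-Na p, L-type s_CaL,
T-type activation a_T and A-current activation are instantaneous. All
steady states are Boltzmann sigmoids x∞(V) = 1/(1 + exp((V − θ)/σ));
negative σ means the gate opens with depolarization.

Current forms:

| current | form |
|---|---|
| leak            | g_L (V − V_L) |
| delayed rectifier | g_K n⁴ (V − V_K), τ_n = τ̄_n / cosh((V − θ_n)/(2σ_n)) |
| transient Na    | g_Na m∞³ h_Na (V − V_Na) |
| persistent Na   | g_Nap p∞ (V − V_Na), θ_p = −50, σ_p = −3 |
| L-type Ca       | g_CaL s∞² (V − E_Ca) |
| T-type Ca       | g_CaT a∞² b_T (V − E_Ca) |
| A-type K        | g_A a_A∞ (V − V_K), θ = −20, σ = −10 |
| SK              | g_SK [Ca]²/([Ca]² + k_s²) (V − V_K) |
| M-type K        | g_M z (V − V_K), z∞ = Boltzmann(θ_z, −5), time constant τ_z |
| h-current       | g_h (w_h f + (1 − w_h) s)(V − V_h) |

Calcium balances influx through the two Ca currents against first-order
removal:

    d[Ca]/dt = −f_Ca (ε_Ca (I_CaL + I_CaT) + k_Ca ([Ca] − b_Ca))

**h-current kinetics.** Both components share the activation curve
h∞ = 1/(1 + exp((V + 87.7)/6.4)) (half-active at −87.7 mV, opening with
hyperpolarization). The slow time constant is
τ_s(V) = exp((V + 289.7)/33.3) ms (≈ 400 ms at −90 mV, shortening with
hyperpolarization); the fast one is the bell
τ_f(V) = 0.51 + 100/(exp((V + 86)/11.4) + exp(−(V + 86)/25.6)) ms, peaking
near 54 ms at −86 mV. τ_s/τ_f > 3 over the physiological range, which the
tests enforce; both closed forms are pinned by regression fixtures. The
w_h split is what distinguishes stages in HVC_X: juveniles carry mostly
fast h-conductance (w_h = 0.3–0.99), adults mostly slow (w_h = 0.17), which
simultaneously deepens the voltage drop, grows the sag, and sustains the
depolarizing tail that feeds the rebound.

**M-current convention.** z∞ half-activates at θ_z with slope −5 mV
(activation grows with depolarization). Juvenile presets carry large g_M
with depolarized θ_z — a strong brake that activates only above rest —
while the adult HVC_RA preset has θ_z = −45 mV, where the M-current
enforces its characteristic single/few-spike firing.

**Parameters the published table does not constrain** were fixed once so
that the six published columns reproduce the reported physiology (the same
role manual calibration played in producing the published columns), and are
identical across all presets:

* Reversals V_Na = +55, V_K = −90, E_Ca = +120 mV (overridable per preset).
* Na inactivation: h∞ = Boltzmann(−38, 3.5),
  τ_h = 0.3 + 4.4/cosh((V + 38)/7) ms. The steepness matters: with g_Na in
  the nS-thousands, shallower inactivation leaves a window current that
  locks the cell at ≈ −20 mV (depolarization block), while inactivation
  shifted lower blocks threshold crossing at +200 pA. Equivalent α/β rates
  (with the τ_h = 1.2/(α+β) convention) are exposed in `gates.na_h_rates`.
* Persistent Na: g_Nap = 3 nS, θ_p = −50 mV, σ_p = −3 mV. This carries the
  subthreshold depolarization from the stall point near −57 mV to Na
  threshold in the adult HVC_RA model; its upper bound is set by the
  subsong HVC_RA model, which must keep a stable rest near −62 mV.
* T-type inactivation: b∞ = Boltzmann(−78, +5) (removed by
  hyperpolarization), with the classic low-threshold-Ca asymmetry in its
  time constant — fast recovery when hyperpolarized (100 ms) and slow
  inactivation near the activation window
  (τ_b = 100 + 300/(1 + exp(−(V + 70)/4)) ms). A voltage-independent τ_b
  closes the rebound window before the large, slow adult HVC_X cell
  (C = 260 pF) can climb into the T-activation zone.
* Calcium handling: ε_Ca = 0.0035 µM pA⁻¹ ms⁻¹, k_Ca = 0.025 ms⁻¹.
  The equilibrium ratio ε/k = 0.14 µM/pA makes the standing SK current at
  rest ≈ 20 pA in the adult HVC_X model, which is what places its resting
  potential at −67 mV given its leak reversal of −63 mV. The effective
  turnover (f_Ca · k_Ca)⁻¹ = 4 s makes SK a slowly varying standing
  conductance on sweep timescales: fast enough to re-equilibrate within the
  2-s relaxations used for steady-state calibration, slow enough that the
  rebound transient is not self-quenched by SK. Relaxations start from
  `ModelState.at_voltage`, which sets [Ca] to its clamped-voltage
  equilibrium b_Ca − (ε/k)(I_CaL + I_CaT) so trajectories begin near the
  slow manifold.

## Integration and steady states

`simulate` uses an explicit low-order adaptive Runge–Kutta (SciPy RK23)
with rtol 1e-6 / atol 1e-8, integrating piecewise per protocol segment
(baseline, pulse, recovery) so the square-pulse discontinuities fall on
segment boundaries, with dense output at dt_out = 0.02 ms. The initial
condition is a 2-s relaxation at zero applied current. The standard
protocol is a 300-ms square pulse from −200 to +200 pA in 50-pA steps.
`steady_state` relaxes for up to 10 s of simulated time and polishes the
fixed point with a root solve, flagging limit cycles (e.g. spontaneously
spiking parameter sets) instead of returning a bogus fixed point.
Tightening tolerances tenfold changes every extracted feature of every
preset by < 0.03% (the suite enforces < 1%).

## Feature analysis

From repeated −10 pA, 100–300 ms pulses: sweeps are averaged pointwise;
R_M = |steady deflection|/10 pA (steady deflection from the mean of the
final 10 ms of the pulse), τ_M from a single-exponential least-squares fit
to the first 50 ms after onset, C_M = τ_M/R_M. From the −200 pA sweep:
V_min (pulse minimum), V_end (mean of the final 5 ms of the pulse — a mean
rather than a point value to suppress sample noise), SR = (V_min −
V_end)/V_min, V_drop = V_rest − V_min, and the rebound depolarization (max
V in the 150 ms after offset, minus rest; the window is a package choice —
long enough to capture rebound spikes, short enough to avoid late drift).
From the +200 pA sweep: spikes are local maxima above −20 mV with ≥ 20 mV
prominence over the trough since the previous spike (defaults chosen to
separate spikes from subthreshold humps in all six models; configurable);
amplitude = peak − AHP trough, width at half amplitude (half level midway
between peak and same-spike AHP trough), latency to the first spike peak,
frequency = count × 1000/duration, ISIs between successive half-amplitude
rising crossings, AR = last ISI / first ISI. First-spike amplitude and
width are averaged across all depolarizing sweeps that fire. Degenerate
cases flag NaN (AR with < 2 spikes; latency with none) rather than raising.

## Synthetic data

The trace generator builds sweeps from piecewise-analytic parts arranged so
the measured quantities are attained exactly on the sample grid: the RC
relaxation is rescaled to reach its floor exactly at the start of a
terminal flat window (making the deflection, V_min, V_end and the target
sag ratio exact), spikes are half-cosine biphasic templates whose peak and
trough samples lie on the grid, and the rebound hump sits on an exactly
restored baseline. Ground-truth features are computed from the clean
waveform by an independent minimal code path; Gaussian noise is added
afterwards. With zero noise the extractor inverts the generator to
numerical precision (~1e-13), which validates the analysis pipeline
independently of the biophysics. Features defined through a minimum
(V_min, hence SR and V_drop) inherit the extreme-value bias of a noisy
minimum (≈ σ√(2 ln N) over N samples); mean-based features are unbiased.
The generator emulates square-pulse current clamp sweeps only — it does not
model electrode artifacts, series-resistance error, bridge imbalance, or
biophysical interactions between features — so passing round-trip tests
validates the measurement code, not the models.

Population draws use Normal(mean, sd = SEM·√n) per stage, the distribution
whose sampling SEM matches a reported one; reported group statistics for
the three cell classes are bundled as generator targets for the statistics
stage.

## Statistics

One-way ANOVA over the three stages (scipy `f_oneway`) followed by pairwise
two-sample t tests with Bonferroni correction: each p multiplied by the
number of comparisons (three) and capped at 1. The identity of the post hoc
test is a package choice (documented, swappable); summary tables report
mean ± SEM per stage with the three corrected p values.

## Microcircuit

Transmitter release is a sigmoid of presynaptic voltage,
Tr(V_pre) = 1.5 mM / (1 + exp(−(V_pre + 5)/4)), treated as a concentration
in M so that α·Tr has units ms⁻¹ (α in M⁻¹ms⁻¹). Receptor binding:
x' = α(1 − x)Tr(V_pre) − βx; currents I_syn = g·x·(V_post − V_syn). GABA:
α = 5000 M⁻¹ms⁻¹, β = 0.18 ms⁻¹, g = 180 nS, V_syn = −90 mV; AMPA:
α = 1100 M⁻¹ms⁻¹, β = 0.19 ms⁻¹, g = 20 nS, V_syn = 0 mV. The interneuron
is a scripted presynaptic waveform (Gaussian spike bumps to +20 mV on a
−70 mV base), because the circuit conclusion depends only on projection-
neuron intrinsic physiology; an explicit interneuron model can be slotted
in by driving the GABA synapse from any voltage trace. The default drive is
25 spikes at 100 Hz, hyperpolarizing HVC_X for ~250 ms to about −89 mV —
comparable in depth-duration to the −200 pA single-cell protocol. The
stage dichotomy (adult circuit recruits HVC_RA, subsong circuit does not)
holds for bursts of roughly 200–300 ms at 100 Hz; bursts below ~150 ms
de-inactivate too little T-current for rebound firing in this model.

## Known limitations

* The plastic-song HVC_RA preset produces a rebound spike after a deep
  −200 pA hyperpolarization, stronger than the minor rebound reported for
  RA-projecting neurons; none of the package's comparative claims rest on
  it.
* Resting potentials of the juvenile HVC_X presets sit near their leak
  reversals (−72/−74 mV), a few mV below the reported population means.
* Spike frequencies at +200 pA are in the physiological range but not
  calibrated per stage; only ordinal comparisons are asserted.
* SK-mediated adaptation operates on the slow calcium timescale, so
  within-train adaptation is dominated by the M-current in this
  implementation.
* No interneuron preset is bundled (the published parameter table has no
  interneuron column); the circuit's inhibitory arm is scripted.
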