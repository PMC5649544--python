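# hvcphys

Conductance-based models of zebra finch HVC projection neurons across vocal
development, with the automated current-clamp feature analysis used to
characterize them and a three-neuron microcircuit demonstrating how
intrinsic (non-synaptic) plasticity alone can switch a circuit's output.

HVC, the cortical premotor nucleus of the song system, contains two
projection-neuron classes — HVC_X (to the basal ganglia homolog Area X) and
HVC_RA (to the vocal-motor nucleus RA) — whose intrinsic physiology changes
as juveniles progress from unpatterned subsong through plastic song to
crystallized adult song: adult HVC_X neurons acquire a voltage sag and
post-inhibitory rebound spiking, and HVC_RA neurons hyperpolarize their
resting potential by ~16 mV. This package ships the six published model
parameter sets (cell class x developmental stage), simulates them under
standard square-pulse protocols, extracts the same feature battery applied
to recordings, and reproduces the stage-dependent circuit dichotomy.

## Model

Single-compartment Hodgkin–Huxley-type membrane equation (mV, ms, pA, nS,
pF, µM):

    C dV/dt = −(I_L + I_K + I_Na + I_Nap + I_CaL + I_CaT + I_A + I_SK
                + I_M + I_h − I_app)

Gates follow x' = (x∞(V) − x)/τ_x(V) with Boltzmann steady states
x∞ = 1/(1 + exp((V − θ)/σ)). The h-current has fast and slow components
sharing one activation curve, h∞ = 1/(1 + exp((V + 87.7)/6.4)):

    I_h = g_h (w_h f + (1 − w_h) s)(V − V_h)

where w_h is the fraction of the h-conductance with fast activation — the
parameter whose developmental decrease in HVC_X underlies the growth of sag
and rebound. The M-current I_M = g_M z (V − V_K) and the SK current
I_SK = g_SK [Ca]²/([Ca]² + k_s²)(V − V_K) shape firing rate and adaptation;
the T-type Ca²⁺ current (de-inactivated by hyperpolarization) drives
rebound firing. The microcircuit couples a scripted interneuron burst to
HVC_X through a GABA synapse and HVC_X to HVC_RA through an AMPA synapse,
with kinetic receptor binding x' = α(1−x)Tr(V_pre) − βx and currents
I_syn = g x (V_post − V_syn). See `docs/methods.md` for every functional
form, parameter and design choice.

## Worked example

```python
from hvcphys import preset, simulate, steady_state
from hvcphys.features import extract_features
from hvcphys.reproduce import feature_protocol

for name in ("hvc_x@subsong", "hvc_x@adult"):
    fs = extract_features(simulate(preset(name), feature_protocol()))
    print(name, round(fs.sr, 4), round(fs.rebound_depol_mv, 1))
```

prints

```
hvc_x@subsong 0.0044 0.4
hvc_x@adult 0.0276 105.5
```

— the subsong HVC_X model shows essentially no sag (sag ratio 0.0044) and a
0.4 mV rebound, while the adult model shows a clear sag (0.028) and a
rebound depolarization of 105 mV relative to rest, i.e. a full rebound
spike. The analysis drivers run the complete study:

```
python analysis/01_simulate_models.py      # six models, resting potentials
python analysis/02_extract_features.py     # feature battery + ordinal comparisons
python analysis/03_circuit_dichotomy.py    # two-stage microcircuit
python analysis/04_population_stats.py     # ANOVA + Bonferroni demo
python analysis/05_synthetic_validation.py # extractor validation
```

`analysis/03_circuit_dichotomy.py` reports that with identical synapses and
drive the adult circuit produces 4 HVC_RA spikes while the subsong circuit
produces none. Small tables land in `results/`; bulky traces in `scratch/`.
A `hvcphys` console command exposes the same steps
(`hvcphys simulate|features|circuit|stats|synth|reproduce`).

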