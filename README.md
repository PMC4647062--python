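# fxsephys

Patch-clamp feature extraction and a conductance-based simulator for the
cell-type-specific channelopathy of layer-5 prefrontal pyramidal neurons in
the fmr1-knockout (fragile X) mouse.

## What this package is for

Slice physiologists characterize pyramidal-tract (PT) and intratelencephalic
(IT) layer-5 neurons with a standard battery: 1-second current-step families
(input resistance R_N, sag, rebound), 1–15 Hz chirp injections (the
impedance amplitude profile, ZAP, and its peak — the resonant frequency
f_R), brief-pulse trains (the functional membrane time constant τ_m), 50-Hz
simulated-EPSC trains (temporal summation), just-threshold pulses of varied
duration (spike-threshold dynamics), and outside-out voltage-clamp protocols
that split the total K⁺ current into rapidly inactivating (Kv4-like,
I_KA-fast), slowly inactivating (Kv1-like, I_K-slow) and sustained
components via a −20 mV prepulse and a −20 mV holding protocol:

    I_KA-fast = I(hold −90 → +50) − I(prepulse −20/100 ms → +50)
    I_K-slow  = I(prepulse → +50) − I(hold −20 → +50)

with Boltzmann activation fits `G/G_max = 1/(1+exp(−(V−V½)/k))`,
single/double-exponential inactivation and recovery kinetics, and an
h-current step (−30 → −140 mV) fit with a double exponential.

`fxsephys` implements this entire analysis stack as an importable library,
plus a Hodgkin–Huxley-style neuron/patch simulator whose calibrated
genotype × class presets (`wt-pt`, `ko-pt`, `wt-it`, `ko-it`) reproduce the
fragile-X phenotype pattern: in PT neurons the h-current is down (less sag
and rebound, lower f_R, longer τ_m, more summation, hyperpolarized rest) and
the somatic K⁺ balance shifts from Kv1-like toward Kv4-like current; IT
neurons are spared except for the resting potential. Every analysis routine
can therefore be validated against analytic or brute-force oracles with no
experimental data.

## Worked example

```sh
python examples/subthreshold_features.py
```

prints, for the wild-type PT preset:

```
input resistance R_N :    71.9 MOhm   (I-V fit R^2 = 0.9985)
sag ratio            :   1.220        (>1: h-current rectification)
rebound slope        :  -0.194        (mV rebound per mV deflection)
membrane tau         :    18.4 ms
resonant frequency   :    3.87 Hz     (PT_like)
temporal summation   :   1.456        (5th/1st EPSP at 50 Hz)
resting potential    :  -67.50 mV
```

The sag ratio above one, the theta-band resonance (classified PT-like
because f_R > 2.2 Hz) and the modest 50-Hz summation are the h-current
signature of a pyramidal-tract neuron. `examples/kcurrent_decomposition.py`
runs the three-protocol K⁺ decomposition on simulated somatic patches:

```
wt-pt:  I_KA-fast 671 pA (43%)   I_K-slow 803 pA (51%)   sustained (3%)
ko-pt:  I_KA-fast 877 pA (59%)   I_K-slow 506 pA (34%)   sustained (4%)
```

showing the knockout's shift from the slowly inactivating toward the
rapidly inactivating component. The other examples cover resonance-based
classification, the strength–duration (just-threshold) relation, and the
full cohort pipeline with its statistics and direction summary.

## Library layout

| module | contents |
|---|---|
| `fxsephys.trace_io` | sweep/metadata model, HDF5 + CSV containers, feature tables |
| `fxsephys.channels` | gates, channels, compartments, neuron/patch specs |
| `fxsephys.stimuli` | chirps, EPSC trains, steps, voltage commands |
| `fxsephys.simulate` | current-clamp integrator, perfect-clamp patch simulator, analytic impedance, pharmacology |
| `fxsephys.presets` | calibrated genotype × class presets, cohort sampling |
| `fxsephys.protocols` | the acquisition protocols as simulator drivers |
| `fxsephys.subthreshold` | R_N, sag, rebound, τ_m, ZAP/f_R, summation, rest |
| `fxsephys.spikes` | threshold detection, just-threshold search, phase plane |
| `fxsephys.vclamp` | leak subtraction, decomposition, Boltzmann/exponential fits |
| `fxsephys.cohort` | cohort statistics, direction summary, end-to-end pipeline |

See `docs/methods.md` for the model, the calibration choices and the known
limitations.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end pipeline from scratch at the given seed
— simulated cohorts of both genotypes and classes, the full protocol and
feature battery, the statistical comparisons and the direction summary —
and writes the acceptance JSON to `--out`.
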