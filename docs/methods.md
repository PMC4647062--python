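# Methods

`fxsephys` packages two things: (1) the analysis stack used to characterize
layer-5 prefrontal pyramidal neurons in patch-clamp experiments —
subthreshold membrane properties, ZAP resonance, action-potential threshold
dynamics, and the three-protocol decomposition of outside-out K⁺ currents —
and (2) a conductance-based neuron/patch simulator whose genotype ×
projection-class presets emulate the wild-type and fmr1-knockout phenotypes,
so every analysis stage can be exercised and validated without experimental
data.

## The biological problem

In the fmr1-/y mouse (the standard model of fragile X syndrome),
pyramidal-tract-projecting (PT) layer-5 neurons of medial prefrontal cortex
show a coordinated channelopathy: reduced h-current (I_h) at soma and
dendrite — visible as less sag and rebound, lower theta resonance, longer
functional membrane time constant, greater temporal summation, and
hyperpolarized rest — together with a somatic K⁺ shift: more rapidly
inactivating Kv4-like current (I_KA-fast), less slowly inactivating Kv1-like
current (I_K-slow), and consequently a lower spike threshold at long
stimulus durations. Neighboring intratelencephalic (IT) neurons are spared
except for a hyperpolarized resting potential. The package reproduces this
stated world and provides the measurement machinery.

## Data model and conventions

Current-clamp sweeps are (pA stimulus, mV response); voltage-clamp sweeps
are (mV command, pA current). Voltages are deliberately *not* corrected for
the liquid-junction potential, matching the recording convention the presets
are calibrated to; the metadata records the flag. The on-disk container is a
small HDF5 schema (`fxsephys-1`) with a plain-text CSV fallback; both
round-trip float64 arrays exactly. Feature tables are tidy per-(cell,
feature) CSV rows with deterministic ordering.

## The simulator

Hodgkin–Huxley first-order gates with Boltzmann steady states
`x∞(V) = 1/(1+exp(−(V−V½)/k))`; time constants constant or bell-shaped in
voltage. Channels may carry up to two parallel activation or inactivation
components (fractions summing to 1) to express multi-exponential kinetics —
the h-current uses two activation components (τ ≈ 30 and 200 ms, fractions
0.65/0.35), giving its double-exponential activation under voltage steps.

Current clamp integrates `C dV/dt = −Σ g·A·H·(V−E) + g_c(V_other−V) + I`
with a fixed-step semi-implicit exponential-Euler scheme (substep ≤ 25 µs;
numba-compiled). Gates relax exactly for the voltage frozen over one
substep; halving the step changes voltages by < 0.005 mV on the presets. The
holding bias for the −65 mV protocols is pre-solved from the steady-state
equations, so baselines are flat to < 0.1 mV. Voltage clamp of excised
patches assumes a perfect clamp: gating ODEs are solved in closed form per
piecewise-constant command segment, currents summed, 4-pole low-pass
filtered (zero-phase, 2 kHz default) and seeded Gaussian noise added.
`isolated_channel_current` gives the unfiltered noise-free single-channel
ground truth used by the decomposition oracles.

A small-signal linearization around any holding state provides the analytic
impedance (and hence R_N and f_R) of the full model; the simulated ZAP
profile agrees with it to within a few percent across 1–15 Hz, which is the
internal consistency bridge between generator and analysis.

### Presets (calibration fixtures)

The study reports no absolute conductance densities or patch areas, so the
presets were calibrated once against the printed cohort means and then
frozen: WT-PT R_N ≈ 80 MΩ and f_R ≈ 3.9 Hz, KO-PT ≈ 94 MΩ and 2.8 Hz,
IT ≈ 123 MΩ and non-resonant, component fractions ≈ 45/53/6% (WT) and
62/35/7% (KO) of the total K⁺ peak. Genotype structure: KO-PT scales
g_H × 0.6, g_KA_fast × 1.35, g_K_slow × 0.6 (somatic), carries a faster
slow-current inactivation at test potentials (τ ≈ 244 ms vs 646 ms; modeled
as a bell-shaped inactivation τ so the −20 mV prepulse behaves identically
across genotypes), and lacks the ~8 mV soma→dendrite hyperpolarizing shift
of the fast A-type activation present in WT. IT presets are identical across
genotypes except a small leak-reversal shift that reproduces the
hyperpolarized KO resting potential.

Deliberate structural choices, made so that each measured phenotype has a
mechanism while the others stay clean:

* PT neurons are two compartments (soma + lumped dendrite at 300 µm);
  h-conductance density grows linearly with distance (0.4%/µm). Dendritic K⁺
  channels carry no genotype differences.
* The transient Na⁺ channel and the delayed rectifier are treated as
  axon-initial-segment membrane: they drive spikes in current clamp but are
  excluded from excised-patch channel complements (TTX blocks Na⁺ in the
  recordings; without excluding K_DR the patch "sustained" current would be
  dominated by the spike-repolarizing conductance, contradicting the ~6%
  sustained fraction).
* The PT delayed rectifier has a slow M-like gating component near rest
  (τ ≈ 30 ms at −65 mV, fast at spike voltages). It supplies
  genotype-independent theta resonance, which is what keeps the KO still
  resonant (f_R 2.8 Hz) when its h-conductance is down 40%. IT neurons use
  the fast-only variant and are therefore non-resonant.
* K_slow (Kv1-like) activates at low threshold (V½ −45 mV, steep) with a
  voltage-dependent activation τ (≈ 20 ms near threshold, ≈ 3 ms at command
  potentials) — slow enough to set the long-duration spike threshold,
  fast enough that the decomposition prepulse protocol sees a conventional
  activating current.
* KA_fast activates steeply near −34 mV: present at spike threshold (where
  its KO up-regulation partly offsets the K_slow loss at brief pulses)
  while contributing nothing at −65 mV, so h-channel block (ZD7288)
  removes essentially all subthreshold genotype differences.

Cohorts draw per-channel lognormal density multipliers (mean-preserving) —
default CV 0.15, with tighter spread for the spike machinery (NaT 0.03,
K_DR 0.05; excitability is homeostatically regulated and the measured
threshold spread would otherwise swamp the 0.1–0.2 mV genotype effect) and
leak 0.08. Somatic and dendritic copies of a channel co-vary. Sampling is a
pure function of (spec, seed).

What the generator does *not* emulate: full dendritic morphology, axonal
spike initiation, channel stochasticity, series-resistance/space-clamp
artifacts, temperature dependence, or animal-level nesting. A green cohort
test therefore establishes that the analysis chain recovers the programmed
direction structure at realistic effect and noise scales — not that the
biological numbers are independently reproduced.

## Analysis definitions

* **R_N**: OLS slope of steady-state ΔV (last 200 ms) vs ΔI over the maximal
  contiguous amplitude run containing the smallest-|ΔI| steps with R² ≥ 0.99
  ("linear portion"); spiking sweeps excluded with a warning.
* **Sag**: peak (first 200 ms) over steady-state deflection, averaged over
  the −150…−90 pA steps. **Rebound slope**: OLS of rebound amplitude
  (400 ms post-offset) vs steady-state membrane potential.
* **τ_m**: slow component of a double-exponential fit to the averaged decay
  after 2-ms pulses (100-ms window). When one component carries < 15% of the
  amplitude the fit is effectively single-exponential and the dominant τ is
  reported — otherwise the h-current's slow creep, not the membrane decay,
  would be returned.
* **ZAP**: |FFT(V)|/|FFT(I)| on the chirp band, 0.5-Hz boxcar smoothing,
  f_R = argmax; resonant iff f_R > 2.2 Hz (strict).
* **Temporal summation**: last/first EPSP peak at 50 Hz after calibrating the
  single-event amplitude to a ~3 mV EPSP (bisection seeded by the analytic
  linear response).
* **Spike threshold**: V at the first crossing of dV/dt > 20 mV/ms (3-point
  smoothed, edge-padded) before the first AP peak; just-threshold amplitude
  by bisection to 1 pA.
* **Leak subtraction**: per-unit-ΔV template from ±5/±10 mV scaling steps,
  truncated at 10 ms (longer templates absorb slow voltage-dependent
  relaxations near holding), applied segment-wise to arbitrary
  piecewise-constant commands; exact for a linear membrane.
* **Decomposition**: I_KA_fast = total − prepulsed, I_K_slow = prepulsed −
  sustained, I_K_sustained = sustained protocol; transient peaks within
  50 ms, sustained amplitude over the last 50 ms; components sum to the
  total exactly by construction.
* **Back-extrapolation**: single-exponential fit to the late decay (5× the
  fast-τ estimate after the peak) evaluated at the peak time; if the fitted
  τ is not ≥ 3× the fast estimate the tail *is* the fast transient and only
  the sustained offset is returned. A window shorter than half the fitted τ
  is an error (a warning between 0.5 and 1 τ) — slightly softer than a hard
  one-τ floor so that 500-ms protocol steps remain analyzable.
* **Fits**: Boltzmann on conductance G = I_peak/(V−E_K) by default
  (E_K = −96 mV, configurable); exponential fits by multi-start nonlinear
  least squares with τ-ordering.
* **Statistics**: two-group t tests / one-way ANOVA, KS normality per group,
  Bonferroni within explicitly declared families, Cohen's d (pooled SD) or
  Cohen's f, Pearson correlations, rank-based fallback. Direction summary:
  "unchanged" iff adjusted p ≥ α, otherwise the sign of the KO − WT mean.

## Known limitations

* The dV/dt-criterion threshold voltage in a compact conductance-based model
  self-compensates during per-cell just-threshold searches: the bisection
  drives every variant to its own marginal state, re-equalizing the gate
  configuration at the crossing. The programmed 40% Kv1 reduction therefore
  moves the measured threshold by only ~0.15 mV, and the threshold voltage
  barely accommodates with duration (the just-threshold *current* carries
  the strength–duration structure instead). The KO threshold comes out
  reliably lower — but at *all* durations: because the slow Kv1-like
  activation is already partly engaged at the crossing of even 1.5-ms
  just-threshold pulses (spike latency of several ms), the experimental
  "difference at durations > 6 ms only" pattern is not reproduced; the
  short-pulse difference is the same size as the long-pulse one.
* With the h-current blocked, a small reverse creep from the slow
  delayed-rectifier gating leaves the sag ratio near 0.96 rather than
  exactly 1.
* Under the prescribed scalings the KO total K⁺ peak is slightly smaller
  than WT, whereas the emulated study reports it larger; the component
  directions (fast up, slow down) are reproduced.
* The recovery-from-inactivation conditioning step is 500 ms at +50 mV and
  the interval grid is {10, 30, 100, 300, 1000, 3000} ms; both are package
  choices where the experimental values are unstated.
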