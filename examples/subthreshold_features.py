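"""Extract the subthreshold membrane-property battery from one simulated cell.

Builds the wild-type PT-neuron preset, runs the current-clamp protocols a
slice physiologist would (1-s step family, brief pulses, chirp, EPSC train,
rest), and prints input resistance, sag, rebound slope, membrane time
constant, resonant frequency, temporal summation and resting potential.
"""

import warnings

warnings.filterwarnings("ignore")

import numpy as np

from fxsephys import presets, protocols, subthreshold

neuron = presets.get_preset("wt-pt")

steps = protocols.run_step_family(
    neuron, amplitudes_pA=tuple(np.arange(-150.0, 11.0, 20.0)))
r_n, iv = subthreshold.input_resistance(steps)
sag = subthreshold.sag_ratio(steps)
rebound = subthreshold.rebound_slope(steps)
tau, _ = subthreshold.membrane_time_constant(protocols.run_brief_pulses(neuron))
prof = subthreshold.zap_profile(protocols.run_chirp(neuron))
summ = subthreshold.temporal_summation(protocols.run_epsc_train(neuron))
v_rest = subthreshold.resting_potential(protocols.run_resting(neuron))

print(f"input resistance R_N : {r_n:7.1f} MOhm   (I-V fit R^2 = {iv['r2']:.4f})")
print(f"sag ratio            : {sag:7.3f}        (>1: h-current rectification)")
print(f"rebound slope        : {rebound:7.3f}        (mV rebound per mV deflection)")
print(f"membrane tau         : {tau:7.1f} ms")
print(f"resonant frequency   : {prof.f_R_Hz:7.2f} Hz     "
      f"({subthreshold.classify_resonant(prof.f_R_Hz)})")
print(f"temporal summation   : {summ:7.3f}        (5th/1st EPSP at 50 Hz)")
print(f"resting potential    : {v_rest:7.2f} mV")
print()
print("The sag ratio above 1, theta-band resonance and modest summation are")
print("the h-current signature that distinguishes pyramidal-tract neurons.")
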