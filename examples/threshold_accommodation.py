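"""Just-threshold search and the strength-duration relation.

For WT and KO PT presets, bisects the current amplitude that is just
sufficient to fire an action potential at several pulse durations, and
prints the resulting strength-duration curve (current and dV/dt-criterion
threshold voltage per duration).
"""

import warnings

warnings.filterwarnings("ignore")

from fxsephys import presets, protocols, spikes

DURATIONS = (1.5, 6.0, 12.0, 50.0)

for preset_id in ("wt-pt", "ko-pt"):
    neuron = presets.get_preset(preset_id)
    stimulate = protocols.threshold_stimulator(neuron)
    curve = spikes.threshold_accommodation_curve(stimulate, durations_ms=DURATIONS)
    print(f"{preset_id}:")
    for d, i, t in zip(curve.durations_ms, curve.currents_pA, curve.thresholds_mV):
        print(f"  {d:6.1f} ms pulse: just-threshold {i:7.1f} pA, "
              f"threshold {t:6.2f} mV")

print()
print("Just-threshold current falls with duration (strength-duration")
print("relation) and the knockout needs less current at every duration -")
print("its reduced slowly inactivating K+ current makes it more excitable.")
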