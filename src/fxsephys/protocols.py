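"""The study's protocol library as simulator drivers.

Each function runs one acquisition protocol on a neuron (or membrane patch)
and returns the Sweep/SweepSet that the analysis modules consume:

* current clamp at −65 mV holding: 1000-ms step family (−150…+50 pA in
  20-pA steps), 1–15 Hz / 15 s chirp, 2-ms brief-pulse trains, 50-Hz
  simulated-EPSC trains, just-threshold pulses of varied duration;
* outside-out voltage clamp: the three K⁺ protocols (activation from −90,
  −20 mV/100 ms prepulse, sustained from −20), the activation family
  (−70…+50 in 20-mV steps), two-pulse recovery, the h-current step
  (−30 → −140 mV, 500 ms), and small scaling steps for leak subtraction.

Outside-out patches exclude the transient Na⁺ channel (TTX in the bath).
"""

from __future__ import annotations

import numpy as np

from . import simulate, stimuli
from .channels import NeuronSpec, PatchSpec
from .trace_io import ProtocolDescriptor, RecordingMetadata, Sweep, SweepSet

CC_RATE_HZ = 10000.0
SPIKE_RATE_HZ = 50000.0

STEP_AMPLITUDES_PA = tuple(np.arange(-150.0, 51.0, 20.0))


def _metadata(neuron: NeuronSpec, site: str, hold: float | None) -> RecordingMetadata:
    gen = "WT"
    cls = "unlabeled"
    if neuron.preset_id:
        parts = neuron.preset_id.split("-")
        if parts[0].lower() in ("wt", "ko"):
            gen = parts[0].upper()
        if len(parts) > 1 and parts[1].lower() in ("pt", "it"):
            cls = parts[1].upper()
    return RecordingMetadata(
        cell_id=neuron.preset_id or "cell",
        genotype=gen,
        projection_class=cls,
        compartment=site,
        distance_um=0.0 if site == "soma" else 300.0,
        holding_potential_mV=hold,
    )


# ---------------------------------------------------------------------------
# current-clamp protocols
# ---------------------------------------------------------------------------

def run_step_family(neuron: NeuronSpec, site: str = "soma",
                    amplitudes_pA=STEP_AMPLITUDES_PA, duration_ms: float = 1000.0,
                    hold_at_mV: float = -65.0,
                    sampling_rate_Hz: float = CC_RATE_HZ) -> SweepSet:
    md = _metadata(neuron, site, hold_at_mV)
    proto = ProtocolDescriptor("step_family", {
        "amplitudes_pA": list(map(float, amplitudes_pA)),
        "duration_ms": duration_ms,
    })
    sweeps = []
    for amp in amplitudes_pA:
        stim = stimuli.make_step(amp, duration_ms, sampling_rate_Hz,
                                 onset_ms=200.0, tail_ms=400.0)
        sweeps.append(simulate.simulate_current_clamp(
            neuron, stim, site=site, hold_at_mV=hold_at_mV,
            sampling_rate_Hz=sampling_rate_Hz, metadata=md, protocol=proto,
        ))
    return SweepSet(tuple(sweeps), protocol_id="step_family")


def run_chirp(neuron: NeuronSpec, site: str = "soma",
              f_start_Hz: float = 1.0, f_end_Hz: float = 15.0,
              duration_s: float = 15.0, amplitude_pA: float = 30.0,
              hold_at_mV: float = -65.0,
              sampling_rate_Hz: float = CC_RATE_HZ) -> Sweep:
    proto = ProtocolDescriptor("chirp", {
        "f_start_Hz": f_start_Hz, "f_end_Hz": f_end_Hz,
        "duration_s": duration_s, "amplitude_pA": amplitude_pA,
    })
    pad = int(0.5 * sampling_rate_Hz)
    chirp = stimuli.make_chirp(f_start_Hz, f_end_Hz, duration_s,
                               amplitude_pA, sampling_rate_Hz)
    stim = np.concatenate([np.zeros(pad), chirp])
    sw = simulate.simulate_current_clamp(
        neuron, stim, site=site, hold_at_mV=hold_at_mV,
        sampling_rate_Hz=sampling_rate_Hz,
        metadata=_metadata(neuron, site, hold_at_mV), protocol=proto,
    )
    # analysis sees the chirp segment only
    return Sweep(sampling_rate_Hz=sampling_rate_Hz, mode="current_clamp",
                 stimulus=sw.stimulus[pad:], response=sw.response[pad:],
                 metadata=sw.metadata, protocol=proto)


def run_brief_pulses(neuron: NeuronSpec, site: str = "soma",
                     amplitude_pA: float = -200.0, pulse_ms: float = 2.0,
                     n_sweeps: int = 10, hold_at_mV: float = -65.0,
                     sampling_rate_Hz: float = CC_RATE_HZ) -> SweepSet:
    """Brief hyperpolarizing pulses for the functional membrane time
    constant (simulation is noise-free, so the sweeps are replicates)."""
    proto = ProtocolDescriptor("brief_pulse", {
        "amplitude_pA": amplitude_pA, "pulse_ms": pulse_ms,
    })
    md = _metadata(neuron, site, hold_at_mV)
    stim = stimuli.make_step(amplitude_pA, pulse_ms, sampling_rate_Hz,
                             onset_ms=50.0, tail_ms=200.0)
    sw = simulate.simulate_current_clamp(
        neuron, stim, site=site, hold_at_mV=hold_at_mV,
        sampling_rate_Hz=sampling_rate_Hz, metadata=md, protocol=proto,
    )
    return SweepSet(tuple([sw] * n_sweeps), protocol_id="brief_pulse")


def run_epsc_train(neuron: NeuronSpec, site: str = "soma",
                   frequency_Hz: float = 50.0, n_events: int = 5,
                   target_mV: float = 3.0, hold_at_mV: float = -65.0,
                   sampling_rate_Hz: float = CC_RATE_HZ,
                   amplitude_pA: float | None = None) -> Sweep:
    """Simulated-EPSC train; the single-event amplitude is calibrated to a
    ~3 mV somatic EPSP unless given explicitly.  Kinetics follow the somatic
    (0.3/4 ms) or dendritic (0.2/2 ms) waveform convention."""
    rise, decay = (0.3, 4.0) if site == "soma" else (0.2, 2.0)
    if amplitude_pA is None:
        amplitude_pA = simulate.calibrate_epsc_amplitude(
            neuron, site=site, target_mV=target_mV, rise_ms=rise, decay_ms=decay,
            hold_at_mV=hold_at_mV, sampling_rate_Hz=sampling_rate_Hz,
        )
    onset_ms = 50.0
    proto = ProtocolDescriptor("epsc_train", {
        "n_events": n_events, "frequency_Hz": frequency_Hz,
        "amplitude_pA": amplitude_pA, "onset_ms": onset_ms,
        "rise_ms": rise, "decay_ms": decay,
    })
    stim = stimuli.make_epsc_train(rise, decay, n_events, frequency_Hz,
                                   amplitude_pA, sampling_rate_Hz,
                                   onset_ms=onset_ms, tail_ms=100.0)
    return simulate.simulate_current_clamp(
        neuron, stim, site=site, hold_at_mV=hold_at_mV,
        sampling_rate_Hz=sampling_rate_Hz,
        metadata=_metadata(neuron, site, hold_at_mV), protocol=proto,
    )


def run_resting(neuron: NeuronSpec, site: str = "soma",
                duration_s: float = 1.0,
                sampling_rate_Hz: float = CC_RATE_HZ) -> Sweep:
    """Stimulus- and bias-free sweep for the resting membrane potential."""
    stim = np.zeros(int(duration_s * sampling_rate_Hz))
    return simulate.simulate_current_clamp(
        neuron, stim, site=site, hold_at_mV=None,
        sampling_rate_Hz=sampling_rate_Hz,
        metadata=_metadata(neuron, site, None),
        protocol=ProtocolDescriptor("custom", {"name": "rest"}),
    )


def threshold_stimulator(neuron: NeuronSpec, site: str = "soma",
                         hold_at_mV: float = -65.0,
                         sampling_rate_Hz: float = SPIKE_RATE_HZ,
                         onset_ms: float = 20.0, tail_ms: float = 25.0):
    """Deterministic callback ``(duration_ms, amplitude_pA) -> Sweep`` for
    the just-threshold search."""
    md = _metadata(neuron, site, hold_at_mV)

    def stimulate(duration_ms: float, amplitude_pA: float) -> Sweep:
        proto = ProtocolDescriptor("threshold_pulse", {
            "duration_ms": duration_ms, "amplitude_pA": amplitude_pA,
        })
        stim = stimuli.make_step(amplitude_pA, duration_ms, sampling_rate_Hz,
                                 onset_ms=onset_ms, tail_ms=tail_ms)
        return simulate.simulate_current_clamp(
            neuron, stim, site=site, hold_at_mV=hold_at_mV,
            sampling_rate_Hz=sampling_rate_Hz, metadata=md, protocol=proto,
        )

    return stimulate


# ---------------------------------------------------------------------------
# outside-out voltage-clamp protocols
# ---------------------------------------------------------------------------

PATCH_EXCLUDED_CHANNELS = ("NaT", "K_DR")


def patch_channels(neuron: NeuronSpec, site: str = "soma"):
    """Channel complement of an excised somatic/dendritic patch.

    The transient Na⁺ conductance is blocked by TTX in the bath, and the
    spike-repolarizing delayed rectifier is treated as axon-initial-segment
    membrane, so excised patches carry leak, H, KA_fast, K_slow and
    K_sustained.  Returns ``(channels, area_cm2)``."""
    comp = neuron.compartment(site)
    chans = tuple(ch for ch in comp.channels
                  if ch.name not in PATCH_EXCLUDED_CHANNELS)
    return chans, comp.area_cm2


def _vc_sweep(channels, patch, segments, area_cm2, kind, md) -> Sweep:
    cmd = stimuli.make_vc_segments(segments, patch.sampling_rate_Hz)
    proto = ProtocolDescriptor(kind, {"segments": [list(s) for s in segments]})
    return simulate.simulate_voltage_clamp_patch(
        channels, patch, cmd, area_cm2=area_cm2, metadata=md, protocol=proto,
    )


def run_k_current_protocols(neuron: NeuronSpec, patch: PatchSpec,
                            site: str = "soma", test_mV: float = 50.0,
                            step_ms: float = 500.0):
    """The three K⁺-decomposition protocols plus scaling sweeps, as a dict
    of SweepSets keyed ``total``/``prepulsed``/``sustained``/``scaling_*``."""
    chans, area = patch_channels(neuron, site)
    md = _metadata(neuron, site, None)

    def seeded(offset):
        return PatchSpec(patch.area_fraction, patch.noise_pA_sd,
                         patch.filter_cutoff_Hz, patch.sampling_rate_Hz,
                         seed=patch.seed + offset)

    out = {}
    out["total"] = SweepSet((_vc_sweep(
        chans, seeded(1), [(-90.0, 200.0), (test_mV, step_ms), (-90.0, 100.0)],
        area, "vc_activation", md),), protocol_id="vc_total")
    out["prepulsed"] = SweepSet((_vc_sweep(
        chans, seeded(2),
        [(-90.0, 100.0), (-20.0, 100.0), (test_mV, step_ms), (-90.0, 100.0)],
        area, "vc_prepulse", md),), protocol_id="vc_prepulse")
    out["sustained"] = SweepSet((_vc_sweep(
        chans, seeded(3), [(-20.0, 200.0), (test_mV, step_ms), (-20.0, 100.0)],
        area, "vc_sustained", md),), protocol_id="vc_sustained")
    for key, hold in (("scaling_m90", -90.0), ("scaling_m20", -20.0)):
        out[key] = SweepSet(tuple(
            _vc_sweep(chans, seeded(4 + j),
                      [(hold, 100.0), (hold + dv, 100.0), (hold, 50.0)],
                      area, "custom", md)
            for j, dv in enumerate((-5.0, -10.0))
        ), protocol_id=key)
    return out


def run_activation_family(neuron: NeuronSpec, patch: PatchSpec,
                          site: str = "soma", hold_mV: float = -90.0,
                          step_ms: float = 1000.0,
                          commands_mV=tuple(np.arange(-70.0, 51.0, 20.0))) -> SweepSet:
    chans, area = patch_channels(neuron, site)
    md = _metadata(neuron, site, hold_mV)
    sweeps = tuple(
        _vc_sweep(chans, PatchSpec(patch.area_fraction, patch.noise_pA_sd,
                                   patch.filter_cutoff_Hz, patch.sampling_rate_Hz,
                                   seed=patch.seed + 10 + j),
                  [(hold_mV, 200.0), (v, step_ms), (hold_mV, 100.0)],
                  area, "vc_activation", md)
        for j, v in enumerate(commands_mV)
    )
    return SweepSet(sweeps, protocol_id="vc_activation_family")


DEFAULT_RECOVERY_INTERVALS_MS = (10.0, 30.0, 100.0, 300.0, 1000.0, 3000.0)


def run_recovery_protocol(neuron: NeuronSpec, patch: PatchSpec,
                          site: str = "soma",
                          intervals_ms=DEFAULT_RECOVERY_INTERVALS_MS,
                          conditioning_ms: float = 500.0,
                          test_ms: float = 100.0,
                          test_mV: float = 50.0) -> SweepSet:
    """Two-pulse recovery-from-inactivation protocol, one sweep per
    interpulse interval at −90 mV."""
    chans, area = patch_channels(neuron, site)
    md = _metadata(neuron, site, -90.0)
    sweeps = tuple(
        _vc_sweep(chans, PatchSpec(patch.area_fraction, patch.noise_pA_sd,
                                   patch.filter_cutoff_Hz, patch.sampling_rate_Hz,
                                   seed=patch.seed + 30 + j),
                  [(-90.0, 100.0), (test_mV, conditioning_ms),
                   (-90.0, dt), (test_mV, test_ms), (-90.0, 50.0)],
                  area, "vc_recovery", md)
        for j, dt in enumerate(intervals_ms)
    )
    return SweepSet(sweeps, protocol_id="vc_recovery")


def run_ih_step(neuron: NeuronSpec, patch: PatchSpec,
                site: str = "dendrite", hold_mV: float = -30.0,
                step_mV: float = -140.0, step_ms: float = 500.0) -> Sweep:
    """h-current step protocol on an excised patch.

    From −30 mV the K⁺ transients are inactivated and the step to −140 mV
    develops the inward h-current."""
    comp = neuron.compartment(site)
    chans = tuple(ch for ch in comp.channels if ch.name in ("H", "leak"))
    md = _metadata(neuron, site, hold_mV)
    return _vc_sweep(chans, patch,
                     [(hold_mV, 300.0), (step_mV, step_ms), (hold_mV, 200.0)],
                     comp.area_cm2, "vc_ih_step", md)


__all__ = [
    "CC_RATE_HZ", "SPIKE_RATE_HZ", "STEP_AMPLITUDES_PA",
    "run_step_family", "run_chirp", "run_brief_pulses", "run_epsc_train",
    "run_resting", "threshold_stimulator",
    "patch_channels", "run_k_current_protocols", "run_activation_family",
    "run_recovery_protocol", "run_ih_step",
    "DEFAULT_RECOVERY_INTERVALS_MS",
]
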