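"""Neuron and outside-out patch simulation.

Current clamp integrates the compartment ODEs

    C dV/dt = -sum_ch g_ch * A_ch(V,t) * H_ch(V,t) * (V - E_ch)
              + g_c (V_other - V) + I_bias + I_stim(t)

with a fixed-step (dt <= 25 µs) semi-implicit exponential-Euler scheme
(:mod:`fxsephys._kernel`).  Voltage clamp of an excised patch assumes a
perfect clamp: the gating ODEs are solved in closed form per piecewise-
constant command segment, channel currents are summed, low-pass filtered,
and seeded Gaussian noise is added.
"""

from __future__ import annotations

from dataclasses import replace
from functools import lru_cache

import numpy as np
from scipy import optimize, signal

from . import _kernel
from .channels import ChannelSpec, NeuronSpec, PatchSpec
from .stimuli import ParameterError, epsc_kernel, make_epsc_train
from .trace_io import ProtocolDescriptor, RecordingMetadata, Sweep

MAX_DT_MS = 0.025  # 25 µs integration cap


class IntegrationError(RuntimeError):
    pass


class CalibrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# neuron flattening for the kernel
# ---------------------------------------------------------------------------

def _tau_row(tau) -> np.ndarray:
    if tau.tau_max_ms is None:
        return np.array([tau.tau_min_ms, -1.0, 0.0, 1.0])
    return np.array([tau.tau_min_ms, tau.tau_max_ms, tau.V_peak_mV, tau.width_mV])


def pack_neuron(neuron: NeuronSpec) -> dict:
    """Flatten a neuron into kernel arrays (cached; NeuronSpec is frozen)."""
    return _pack_neuron_cached(neuron)


@lru_cache(maxsize=512)
def _pack_neuron_cached(neuron: NeuronSpec) -> dict:
    neuron.validate()
    rows = []
    for ci, comp in enumerate(neuron.compartments):
        for ch in comp.channels:
            rows.append((ci, comp.g_nS(ch), ch))
    nch = len(rows)
    M = _kernel.MAX_COMPONENTS
    out = {
        "ncomp": len(neuron.compartments),
        "C_pF": np.array([c.C_pF for c in neuron.compartments]),
        "gc_nS": float(neuron.compartments[0].coupling_nS) if len(neuron.compartments) == 2 else 0.0,
        "comp": np.zeros(nch, dtype=np.int64),
        "g": np.zeros(nch),
        "E": np.zeros(nch),
        "p": np.ones(nch, dtype=np.int64),
        "na": np.zeros(nch, dtype=np.int64),
        "aVh": np.zeros((nch, M)),
        "ak": np.ones((nch, M)),
        "atau": np.ones((nch, M, 4)),
        "afrac": np.zeros((nch, M)),
        "nh": np.zeros(nch, dtype=np.int64),
        "hVh": np.zeros((nch, M)),
        "hk": np.ones((nch, M)),
        "htau": np.ones((nch, M, 4)),
        "hfrac": np.zeros((nch, M)),
    }
    for i, (ci, g_nS, ch) in enumerate(rows):
        out["comp"][i] = ci
        out["g"][i] = g_nS
        out["E"][i] = ch.E_rev_mV
        acts = ch.activation
        if len(acts) > M or len(ch.inactivation_components) > M:
            raise ParameterError(f"channel {ch.name}: at most {M} gate components supported")
        out["na"][i] = len(acts)
        if len(acts) == 1:
            out["p"][i] = acts[0][0].exponent
        for j, (gate, frac) in enumerate(acts):
            out["aVh"][i, j] = gate.V_half_mV
            out["ak"][i, j] = gate.k_mV
            out["atau"][i, j] = _tau_row(gate.tau_ms)
            out["afrac"][i, j] = frac
        out["nh"][i] = len(ch.inactivation_components)
        for j, (gate, frac) in enumerate(ch.inactivation_components):
            out["hVh"][i, j] = gate.V_half_mV
            out["hk"][i, j] = gate.k_mV
            out["htau"][i, j] = _tau_row(gate.tau_ms)
            out["hfrac"][i, j] = frac
    return out


def _steady_gate_states(packed: dict, V_comps: np.ndarray):
    nch = packed["g"].shape[0]
    M = _kernel.MAX_COMPONENTS
    a = np.zeros((nch, M))
    h = np.zeros((nch, M))
    for i in range(nch):
        V = V_comps[packed["comp"][i]]
        for j in range(packed["na"][i]):
            a[i, j] = 1.0 / (1.0 + np.exp(-(V - packed["aVh"][i, j]) / packed["ak"][i, j]))
        for j in range(packed["nh"][i]):
            h[i, j] = 1.0 / (1.0 + np.exp(-(V - packed["hVh"][i, j]) / packed["hk"][i, j]))
    return a, h


# ---------------------------------------------------------------------------
# steady states and holding
# ---------------------------------------------------------------------------

def ionic_current(neuron: NeuronSpec, comp_name: str, V: float) -> float:
    """Total steady-state ionic current (pA) leaving one compartment at V."""
    comp = neuron.compartment(comp_name)
    return float(sum(ch.current_inf(V, comp.g_nS(ch)) for ch in comp.channels))


def holding_state(neuron: NeuronSpec, site: str, hold_mV: float):
    """Bias current at ``site`` holding it at ``hold_mV``, and the implied
    steady-state voltages of all compartments."""
    V, bias = _holding_state_cached(neuron, site, float(hold_mV))
    return V.copy(), bias


@lru_cache(maxsize=2048)
def _holding_state_cached(neuron: NeuronSpec, site: str, hold_mV: float):
    idx = neuron.compartment_index(site)
    comps = neuron.compartments
    if len(comps) == 1:
        bias = ionic_current(neuron, site, hold_mV)
        return np.array([hold_mV]), bias
    gc = comps[0].coupling_nS
    other = comps[1 - idx].name

    def resid(V_other):
        return ionic_current(neuron, other, V_other) + gc * (V_other - hold_mV)

    V_other = optimize.brentq(resid, -150.0, 30.0, xtol=1e-10)
    bias = ionic_current(neuron, site, hold_mV) + gc * (hold_mV - V_other)
    V = np.zeros(2)
    V[idx] = hold_mV
    V[1 - idx] = V_other
    return V, bias


def resting_state(neuron: NeuronSpec) -> np.ndarray:
    """Bias-free steady-state voltages (the conductance-weighted rest)."""
    comps = neuron.compartments
    if len(comps) == 1:
        V = optimize.brentq(
            lambda v: ionic_current(neuron, comps[0].name, v), -150.0, 30.0, xtol=1e-10
        )
        return np.array([V])
    gc = comps[0].coupling_nS

    def resid(V):
        return [
            ionic_current(neuron, comps[0].name, V[0]) + gc * (V[0] - V[1]),
            ionic_current(neuron, comps[1].name, V[1]) + gc * (V[1] - V[0]),
        ]

    sol = optimize.fsolve(resid, np.array([-70.0, -70.0]), full_output=False, xtol=1e-12)
    return np.asarray(sol)


# ---------------------------------------------------------------------------
# current clamp
# ---------------------------------------------------------------------------

def simulate_current_clamp(
    neuron: NeuronSpec,
    stimulus: np.ndarray,
    site: str = "soma",
    hold_at_mV: float | None = -65.0,
    seed: int | None = None,
    sampling_rate_Hz: float = 10000.0,
    metadata: RecordingMetadata | None = None,
    protocol: ProtocolDescriptor | None = None,
    max_dt_ms: float = MAX_DT_MS,
) -> Sweep:
    """Integrate the neuron under a current injection at ``site``.

    When ``hold_at_mV`` is set, the bias current is pre-solved so the
    pre-stimulus voltage sits within 0.1 mV of the holding target.
    ``seed`` is accepted for interface symmetry; the integration itself is
    deterministic (no channel stochasticity).
    """
    stimulus = np.asarray(stimulus, dtype=float)
    if not np.all(np.isfinite(stimulus)):
        raise ParameterError("stimulus contains non-finite values")
    packed = pack_neuron(neuron)
    idx = neuron.compartment_index(site)
    if hold_at_mV is not None:
        V0, bias_site = holding_state(neuron, site, hold_at_mV)
    else:
        V0 = resting_state(neuron)
        bias_site = 0.0
    bias = np.zeros(packed["ncomp"])
    bias[idx] = bias_site + neuron.bias_current_pA

    dt_sample_ms = 1000.0 / sampling_rate_Hz
    substeps = max(1, int(np.ceil(dt_sample_ms / max_dt_ms - 1e-12)))
    dt_ms = dt_sample_ms / substeps

    stim2 = np.zeros((len(stimulus), packed["ncomp"]))
    stim2[:, idx] = stimulus
    V = V0.copy()
    a_state, h_state = _steady_gate_states(packed, V0)
    v_out = np.empty_like(stim2)
    fail = _kernel.integrate_cc(
        stim2, bias, substeps, dt_ms, V,
        packed["C_pF"], packed["gc_nS"], packed["comp"], packed["g"], packed["E"],
        packed["p"],
        packed["na"], packed["aVh"], packed["ak"], packed["atau"], packed["afrac"],
        packed["nh"], packed["hVh"], packed["hk"], packed["htau"], packed["hfrac"],
        a_state, h_state, v_out,
    )
    if fail >= 0:
        raise IntegrationError(
            f"numerical blow-up (|V| > 200 mV) at t = {fail / sampling_rate_Hz:.4f} s"
        )
    md = metadata or RecordingMetadata(
        cell_id=neuron.preset_id or "sim", holding_potential_mV=hold_at_mV
    )
    return Sweep(
        sampling_rate_Hz=sampling_rate_Hz,
        mode="current_clamp",
        stimulus=stimulus,
        response=v_out[:, idx],
        metadata=md,
        protocol=protocol or ProtocolDescriptor(kind="custom"),
    )


# ---------------------------------------------------------------------------
# voltage clamp (outside-out patch, perfect clamp)
# ---------------------------------------------------------------------------

def _segments(command: np.ndarray):
    """Split a piecewise-constant command into (start, stop, level) runs."""
    edges = np.flatnonzero(np.diff(command) != 0) + 1
    starts = np.concatenate(([0], edges))
    stops = np.concatenate((edges, [len(command)]))
    return [(int(s), int(e), float(command[s])) for s, e in zip(starts, stops)]


def _channel_patch_current(
    channel: ChannelSpec, g_nS: float, command: np.ndarray, dt_ms: float
) -> np.ndarray:
    """Closed-form gating solution under a piecewise-constant command."""
    acts = channel.activation
    inacts = channel.inactivation_components
    V0 = command[0]
    a = np.array([gate.x_inf(V0) for gate, _ in acts])
    h = np.array([gate.x_inf(V0) for gate, _ in inacts])
    out = np.empty_like(command)
    for start, stop, V in _segments(command):
        t = np.arange(stop - start) * dt_ms
        A = np.ones(stop - start)
        if acts:
            vals = []
            for j, (gate, frac) in enumerate(acts):
                xinf = gate.x_inf(V)
                tau = gate.tau(V)
                x = xinf + (a[j] - xinf) * np.exp(-t / tau)
                vals.append((x, frac, gate.exponent))
                a[j] = xinf + (a[j] - xinf) * np.exp(-(stop - start) * dt_ms / tau)
            if len(vals) == 1:
                A = vals[0][0] ** vals[0][2]
            else:
                A = sum(frac * x for x, frac, _ in vals)
        H = np.ones(stop - start)
        if inacts:
            H = np.zeros(stop - start)
            for j, (gate, frac) in enumerate(inacts):
                xinf = gate.x_inf(V)
                tau = gate.tau(V)
                H += frac * (xinf + (h[j] - xinf) * np.exp(-t / tau))
                h[j] = xinf + (h[j] - xinf) * np.exp(-(stop - start) * dt_ms / tau)
        out[start:stop] = g_nS * A * H * (V - channel.E_rev_mV)
    return out


DEFAULT_PATCH_AREA_CM2 = 1.5e-4  # somatic preset membrane area


def isolated_channel_current(
    channel: ChannelSpec,
    patch: PatchSpec,
    command: np.ndarray,
    area_cm2: float = DEFAULT_PATCH_AREA_CM2,
) -> np.ndarray:
    """Noise-free, unfiltered current (pA) of a single channel in the patch.

    Serves as the brute-force ground truth for component-recovery tests.
    """
    patch.validate()
    channel.validate()
    command = np.asarray(command, dtype=float)
    if not np.all(np.isfinite(command)):
        raise ParameterError("command contains non-finite values")
    g_nS = channel.g_max_density * area_cm2 * patch.area_fraction * 1e6
    dt_ms = 1000.0 / patch.sampling_rate_Hz
    return _channel_patch_current(channel, g_nS, command, dt_ms)


def simulate_voltage_clamp_patch(
    neuron_channels,
    patch: PatchSpec,
    command: np.ndarray,
    area_cm2: float = DEFAULT_PATCH_AREA_CM2,
    metadata: RecordingMetadata | None = None,
    protocol: ProtocolDescriptor | None = None,
) -> Sweep:
    """Sum of channel currents in an excised patch under perfect voltage clamp,
    low-pass filtered at ``patch.filter_cutoff_Hz`` and with seeded Gaussian
    noise of SD ``patch.noise_pA_sd`` added."""
    patch.validate()
    command = np.asarray(command, dtype=float)
    if not np.all(np.isfinite(command)):
        raise ParameterError("command contains non-finite values")
    total = np.zeros_like(command)
    for ch in neuron_channels:
        total += isolated_channel_current(ch, patch, command, area_cm2)
    if np.any(total != 0.0):
        sos = signal.butter(
            4, patch.filter_cutoff_Hz, btype="low", fs=patch.sampling_rate_Hz, output="sos"
        )
        total = signal.sosfiltfilt(sos, total)
    if patch.noise_pA_sd > 0:
        rng = np.random.default_rng(patch.seed)
        total = total + rng.normal(0.0, patch.noise_pA_sd, size=total.shape)
    md = metadata or RecordingMetadata(cell_id="patch")
    return Sweep(
        sampling_rate_Hz=patch.sampling_rate_Hz,
        mode="voltage_clamp",
        stimulus=command,
        response=total,
        metadata=md,
        protocol=protocol or ProtocolDescriptor(kind="custom"),
    )


# ---------------------------------------------------------------------------
# linearized small-signal impedance
# ---------------------------------------------------------------------------

def linearized_impedance(
    neuron: NeuronSpec,
    site: str,
    freqs_Hz: np.ndarray,
    V_hold_mV: float = -65.0,
) -> np.ndarray:
    """Complex impedance (MΩ) of the model linearized around the holding
    state — the analytic counterpart of the measured ZAP profile."""
    freqs_Hz = np.asarray(freqs_Hz, dtype=float)
    V0, _ = holding_state(neuron, site, V_hold_mV)
    omega = 2e-3 * np.pi * freqs_Hz  # rad/ms
    ncomp = len(neuron.compartments)
    Y = np.zeros((len(freqs_Hz), ncomp, ncomp), dtype=complex)
    for ci, comp in enumerate(neuron.compartments):
        V = V0[ci]
        y = 1j * omega * comp.C_pF  # pF/ms = nS
        for ch in comp.channels:
            g = comp.g_nS(ch)
            acts = ch.activation
            inacts = ch.inactivation_components
            if len(acts) == 1:
                gate, _ = acts[0]
                A0 = gate.x_inf(V) ** gate.exponent
            elif acts:
                A0 = sum(f * gate.x_inf(V) for gate, f in acts)
            else:
                A0 = 1.0
            H0 = sum(f * gate.x_inf(V) for gate, f in inacts) if inacts else 1.0
            y = y + g * A0 * H0  # chord conductance term
            drive = g * (V - ch.E_rev_mV)
            if acts:
                if len(acts) == 1:
                    gate, _ = acts[0]
                    dA = gate.exponent * gate.x_inf(V) ** (gate.exponent - 1) * gate.dxinf_dV(V)
                    y = y + drive * H0 * dA / (1.0 + 1j * omega * gate.tau(V))
                else:
                    for gate, f in acts:
                        y = y + drive * H0 * f * gate.dxinf_dV(V) / (
                            1.0 + 1j * omega * gate.tau(V)
                        )
            for gate, f in inacts:
                y = y + drive * A0 * f * gate.dxinf_dV(V) / (1.0 + 1j * omega * gate.tau(V))
        Y[:, ci, ci] += y
    if ncomp == 2:
        gc = neuron.compartments[0].coupling_nS
        Y[:, 0, 0] += gc
        Y[:, 1, 1] += gc
        Y[:, 0, 1] -= gc
        Y[:, 1, 0] -= gc
    idx = neuron.compartment_index(site)
    Z = np.linalg.inv(Y)[:, idx, idx]  # 1/nS = GΩ
    return Z * 1e3  # MΩ


def linearized_input_resistance(neuron: NeuronSpec, site: str = "soma",
                                V_hold_mV: float = -65.0) -> float:
    """DC limit of the linearized impedance, in MΩ."""
    return float(np.real(linearized_impedance(neuron, site, np.array([0.0]), V_hold_mV))[0])


def linearized_resonant_frequency(
    neuron: NeuronSpec,
    site: str = "soma",
    V_hold_mV: float = -65.0,
    band_Hz=(1.0, 15.0),
    df_Hz: float = 0.01,
) -> float:
    freqs = np.arange(band_Hz[0], band_Hz[1] + df_Hz / 2, df_Hz)
    Z = np.abs(linearized_impedance(neuron, site, freqs, V_hold_mV))
    return float(freqs[np.argmax(Z)])


# ---------------------------------------------------------------------------
# EPSC calibration and pharmacology
# ---------------------------------------------------------------------------

def calibrate_epsc_amplitude(
    neuron: NeuronSpec,
    site: str = "soma",
    target_mV: float = 3.0,
    rise_ms: float = 0.3,
    decay_ms: float = 4.0,
    hold_at_mV: float = -65.0,
    sampling_rate_Hz: float = 10000.0,
    tol: float = 0.02,
    max_iter: int = 50,
) -> float:
    """Bisection on the EPSC amplitude such that a single simulated event
    depolarizes ``site`` by ``target_mV`` (within ``tol`` relative)."""
    if target_mV == 0:
        return 0.0

    def peak_mV(amplitude_pA: float) -> float:
        stim = make_epsc_train(
            rise_ms, decay_ms, 1, 10.0, amplitude_pA, sampling_rate_Hz,
            onset_ms=20.0, tail_ms=12.0 * decay_ms,
        )
        sw = simulate_current_clamp(
            neuron, stim, site=site, hold_at_mV=hold_at_mV,
            sampling_rate_Hz=sampling_rate_Hz,
        )
        return float(np.max(sw.response) - hold_at_mV)

    # analytic starting bracket: peak EPSP per pA from the linearized
    # impulse response convolved with the EPSC kernel
    n_lin = 4096
    freqs = np.fft.rfftfreq(n_lin, d=1.0 / sampling_rate_Hz)
    Z = linearized_impedance(neuron, site, freqs, V_hold_mV=hold_at_mV)
    t_ms = np.arange(n_lin) / sampling_rate_Hz * 1e3
    kernel = epsc_kernel(rise_ms, decay_ms, t_ms)
    resp = np.fft.irfft(np.fft.rfft(kernel) * Z * 1e-3, n=n_lin)  # mV per pA
    per_pA = float(np.max(resp))
    guess = target_mV / per_pA if per_pA > 0 else 10.0
    lo, hi = 0.6 * guess, 1.6 * guess
    for _ in range(20):
        if peak_mV(hi) >= target_mV:
            break
        lo, hi = hi, hi * 2.0
    else:
        raise CalibrationError("could not bracket the target depolarization")
    if peak_mV(lo) > target_mV:
        lo = 0.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        v = peak_mV(mid)
        if abs(v - target_mV) <= tol * target_mV:
            return mid
        if v < target_mV:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(f"bisection did not converge in {max_iter} iterations")


DRUG_FACTORS = {
    # drug -> (channel name, fractional conductance remaining)
    "ZD7288": ("H", 0.0),
    "fourAP_50uM": ("K_slow", 0.1),
    "aDTX_200nM": ("K_slow", 0.1),
    "Ba_150uM": ("KA_fast", 0.2),
}


def apply_pharmacology(neuron: NeuronSpec, drug: str, factors: dict | None = None) -> NeuronSpec:
    """Return a copy of the neuron with the drug's target conductance scaled.

    ZD7288 blocks h-channels completely; 50 µM 4-AP and 200 nM α-DTX block
    most of the Kv1-like slow current; 150 µM Ba²⁺ partially blocks the
    Kv4-like fast current.  Block factors are configurable.
    """
    table = factors or DRUG_FACTORS
    if drug not in table:
        raise ParameterError(f"unknown drug {drug!r}; known: {sorted(table)}")
    target, remaining = table[drug]
    return neuron.map_channels(
        lambda ch: ch.scaled(remaining) if ch.name == target else ch
    )


__all__ = [
    "IntegrationError",
    "CalibrationError",
    "simulate_current_clamp",
    "simulate_voltage_clamp_patch",
    "isolated_channel_current",
    "linearized_impedance",
    "linearized_input_resistance",
    "linearized_resonant_frequency",
    "holding_state",
    "resting_state",
    "ionic_current",
    "calibrate_epsc_amplitude",
    "apply_pharmacology",
    "DRUG_FACTORS",
    "DEFAULT_PATCH_AREA_CM2",
    "pack_neuron",
]
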