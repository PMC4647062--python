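"""Subthreshold membrane-property extraction from current-clamp sweeps.

All features are defined against the step/chirp/pulse/train protocols
acquired at a common holding potential (−65 mV): input resistance from the
linear portion of the I–V relation, sag and rebound from hyperpolarizing
steps, the functional membrane time constant from averaged brief-pulse
decays, the impedance amplitude profile (ZAP) and resonant frequency from a
chirp response, temporal summation from a simulated-EPSC train, and the
resting potential from a stimulus-free segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .trace_io import Sweep, SweepSet, ValidationError


class InsufficientDataError(ValueError):
    pass


class FitError(RuntimeError):
    pass


class ResolutionError(ValueError):
    pass


SPIKE_PEAK_MV = -10.0  # a sweep whose response exceeds this contains an AP


@dataclass(frozen=True)
class ImpedanceProfile:
    frequencies_Hz: np.ndarray
    impedance_MOhm: np.ndarray
    f_R_Hz: float


@dataclass(frozen=True)
class SubthresholdFeatures:
    R_N_MOhm: float
    sag_ratio: float
    rebound_slope: float
    tau_slow_ms: float
    V_rest_mV: float
    f_R_Hz: float
    resonant: bool
    summation_ratio: float


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _step_window(sweep: Sweep):
    """Indices (onset, offset) of the step in the stimulus, by deviation from
    the pre-step baseline level."""
    stim = sweep.stimulus
    base = stim[0]
    dev = np.flatnonzero(np.abs(stim - base) > 1e-9)
    if len(dev) == 0:
        raise ValidationError("sweep contains no step stimulus")
    return int(dev[0]), int(dev[-1]) + 1


def _has_spike(sweep: Sweep) -> bool:
    return bool(np.max(sweep.response) > SPIKE_PEAK_MV)


# ---------------------------------------------------------------------------
# input resistance
# ---------------------------------------------------------------------------

def input_resistance(steps: SweepSet, r2_threshold: float = 0.99,
                     steady_window_ms: float = 200.0):
    """Input resistance (MΩ) from the linear portion of the I–V relation.

    Steady-state ΔV is the mean over the last ``steady_window_ms`` of each
    step versus the pre-step baseline.  The "linear portion" is the maximal
    contiguous amplitude run containing the smallest-|ΔI| points whose OLS
    fit has R² ≥ ``r2_threshold``.  Returns ``(R_N, iv_record)`` where
    ``iv_record`` maps amplitudes to steady-state deflections and flags the
    points used.
    """
    steps.validate()
    if steps.mode != "current_clamp":
        raise ValidationError("input_resistance requires current-clamp sweeps")
    amps, dvs = [], []
    n_spiking = 0
    for sw in steps:
        if _has_spike(sw):
            n_spiking += 1
            continue
        on, off = _step_window(sw)
        nw = int(round(steady_window_ms * 1e-3 * sw.sampling_rate_Hz))
        base = sw.response[:on].mean()
        amp = sw.stimulus[on:off].mean() - sw.stimulus[0]
        dv = sw.response[off - nw:off].mean() - base
        amps.append(amp)
        dvs.append(dv)
    if n_spiking:
        warnings.warn(f"excluded {n_spiking} spiking sweep(s) from the I-V fit")
    if len(amps) < 3:
        raise InsufficientDataError(
            f"need >= 3 subthreshold sweeps, got {len(amps)}"
        )
    order = np.argsort(amps)
    amps = np.asarray(amps)[order]
    dvs = np.asarray(dvs)[order]

    def fit(idx):
        x, y = amps[idx], dvs[idx]
        A = np.vstack([x, np.ones_like(x)]).T
        coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
        yhat = A @ coef
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return coef[0], r2

    # anchor: the two points closest to 0 pA must be inside the window
    anchor = np.argsort(np.abs(amps))[:2]
    lo0, hi0 = int(anchor.min()), int(anchor.max())
    best = None
    for size in range(len(amps), 2, -1):
        for lo in range(0, len(amps) - size + 1):
            hi = lo + size - 1
            if not (lo <= lo0 and hi >= hi0):
                continue
            slope, r2 = fit(slice(lo, hi + 1))
            if r2 >= r2_threshold and (best is None or size > best[0]):
                best = (size, lo, hi, slope, r2)
        if best is not None:
            break
    if best is None:  # fall back to the anchor pair's best 3-point fit
        slope, r2 = fit(slice(lo0, hi0 + 1))
        best = (hi0 - lo0 + 1, lo0, hi0, slope, r2)
    size, lo, hi, slope, r2 = best
    used = np.zeros(len(amps), dtype=bool)
    used[lo:hi + 1] = True
    iv = {"amplitudes_pA": amps, "deflections_mV": dvs, "used": used, "r2": r2}
    return float(slope * 1e3), iv  # mV/pA -> MΩ


# ---------------------------------------------------------------------------
# sag and rebound
# ---------------------------------------------------------------------------

def sag_ratio(steps: SweepSet, amplitude_range_pA=(-150.0, -90.0),
              peak_window_ms: float = 200.0,
              steady_window_ms: float = 200.0) -> float:
    """Sag ratio: peak/steady-state deflection during hyperpolarizing steps,
    averaged over sweeps with amplitudes in ``amplitude_range_pA``."""
    steps.validate()
    ratios = []
    for sw in steps:
        on, off = _step_window(sw)
        amp = sw.stimulus[on:off].mean() - sw.stimulus[0]
        if not (amplitude_range_pA[0] - 1e-9 <= amp <= amplitude_range_pA[1] + 1e-9):
            continue
        base = sw.response[:on].mean()
        npk = int(round(peak_window_ms * 1e-3 * sw.sampling_rate_Hz))
        nss = int(round(steady_window_ms * 1e-3 * sw.sampling_rate_Hz))
        peak_defl = base - sw.response[on:on + npk].min()
        ss_defl = base - sw.response[off - nss:off].mean()
        if ss_defl <= 0:
            continue
        ratios.append(peak_defl / ss_defl)
    if not ratios:
        raise InsufficientDataError("no hyperpolarizing sweeps in the stated range")
    return float(np.mean(ratios))


def rebound_slope(steps: SweepSet, max_amplitude_pA: float = -50.0,
                  rebound_window_ms: float = 400.0,
                  steady_window_ms: float = 200.0) -> float:
    """OLS slope of rebound amplitude vs steady-state membrane potential
    across hyperpolarizing sweeps (dimensionless, mV per mV)."""
    steps.validate()
    vss, reb = [], []
    for sw in steps:
        on, off = _step_window(sw)
        amp = sw.stimulus[on:off].mean() - sw.stimulus[0]
        if amp > max_amplitude_pA + 1e-9:
            continue
        base = sw.response[:on].mean()
        nss = int(round(steady_window_ms * 1e-3 * sw.sampling_rate_Hz))
        nrb = int(round(rebound_window_ms * 1e-3 * sw.sampling_rate_Hz))
        v_steady = sw.response[off - nss:off].mean()
        rebound = sw.response[off:off + nrb].max() - base
        vss.append(v_steady)
        reb.append(max(rebound, 0.0))
    if len(vss) < 2:
        raise InsufficientDataError("need >= 2 hyperpolarizing sweeps for rebound slope")
    slope = np.polyfit(vss, reb, 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# membrane time constant
# ---------------------------------------------------------------------------

def membrane_time_constant(pulses: SweepSet, fit_duration_ms: float = 100.0,
                           min_amplitude_fraction: float = 0.15):
    """Slow component of a double-exponential fit to the averaged voltage
    decay after brief (2 ms) hyperpolarizing current pulses.

    Returns ``(tau_slow_ms, fit_record)``.  Emits an ill-separated warning
    when τ_fast/τ_slow > 0.8.
    """
    pulses.validate()
    if len(pulses) < 10:
        raise InsufficientDataError("need >= 10 brief-pulse sweeps to average")
    rate = pulses.sampling_rate_Hz
    decays = []
    for sw in pulses:
        on, off = _step_window(sw)
        base = sw.response[:on].mean()
        nfit = int(round(fit_duration_ms * 1e-3 * rate))
        seg = sw.response[off:off + nfit] - base
        decays.append(seg)
    nmin = min(len(d) for d in decays)
    decay = np.mean([d[:nmin] for d in decays], axis=0)
    t = np.arange(nmin) / rate * 1e3  # ms

    def model(t, a_f, tau_f, a_s, tau_s, c):
        return a_f * np.exp(-t / tau_f) + a_s * np.exp(-t / tau_s) + c

    v0 = decay[0]
    # seed the nonlinear fit from the 1/e crossing of the dominant decay
    frac = (decay - decay[-len(decay) // 20:].mean())
    frac = frac / frac[0] if frac[0] != 0 else frac
    below = np.flatnonzero(frac < np.exp(-1))
    tau_dom = t[below[0]] if len(below) else 0.3 * fit_duration_ms
    tau_dom = float(np.clip(tau_dom, 0.5, 0.8 * fit_duration_ms))

    # a near-perfect single-exponential decay makes the two-exponential fit
    # degenerate (and slow); detect it first and report its tau directly
    def single(t, a, tau, c):
        return a * np.exp(-t / tau) + c

    try:
        popt1, _ = optimize.curve_fit(
            single, t, decay, p0=[v0, tau_dom, 0.0],
            bounds=([-np.inf, 0.05, -np.inf], [np.inf, fit_duration_ms, np.inf]),
            maxfev=5000)
        rms1 = float(np.sqrt(np.mean((single(t, *popt1) - decay) ** 2)))
        if rms1 < 4e-3 * abs(v0):
            record = {"a_fast": 0.0, "tau_fast_ms": popt1[1],
                      "a_slow": popt1[0], "tau_slow_ms": popt1[1],
                      "offset": popt1[2], "residual_rms": rms1}
            return float(popt1[1]), record
    except RuntimeError:
        pass
    best = None
    for tau_f0, tau_s0 in [(tau_dom / 5.0, tau_dom),
                           (tau_dom / 2.0, min(2.0 * tau_dom,
                                               0.9 * fit_duration_ms))]:
        try:
            popt, _ = optimize.curve_fit(
                model, t, decay,
                p0=[v0 * 0.3, tau_f0, v0 * 0.7, tau_s0, 0.0],
                bounds=([-np.inf, 0.05, -np.inf, 0.05, -np.inf],
                        [np.inf, fit_duration_ms, np.inf, fit_duration_ms, np.inf]),
                maxfev=5000,
            )
        except RuntimeError:
            continue
        rms = float(np.sqrt(np.mean((model(t, *popt) - decay) ** 2)))
        if best is None or rms < best[0]:
            best = (rms, popt)
    if best is None:
        raise FitError("double-exponential fit did not converge")
    rms, popt = best
    a_f, tau_f, a_s, tau_s, c = popt
    if tau_f > tau_s:  # enforce tau_f < tau_s by ordering
        a_f, a_s = a_s, a_f
        tau_f, tau_s = tau_s, tau_f
    if tau_s > 0 and tau_f / tau_s > 0.8:
        warnings.warn("ill-separated exponentials: tau_f/tau_s > 0.8")
    # a minor slow component (h-current creep) is not the membrane decay:
    # report the dominant component's tau when the slow amplitude is small
    total_amp = abs(a_f) + abs(a_s)
    tau_functional = tau_s
    if total_amp > 0 and abs(a_s) / total_amp < min_amplitude_fraction:
        tau_functional = tau_f
    record = {"a_fast": a_f, "tau_fast_ms": tau_f, "a_slow": a_s,
              "tau_slow_ms": tau_s, "offset": c, "residual_rms": rms}
    return float(tau_functional), record


# ---------------------------------------------------------------------------
# ZAP / resonance
# ---------------------------------------------------------------------------

def zap_profile(chirp_sweep: Sweep, smooth_Hz: float = 0.5,
                band_Hz: tuple | None = None) -> ImpedanceProfile:
    """Impedance amplitude profile Z(f) = |FFT(V)| / |FFT(I)| over the chirp
    band, boxcar-smoothed; f_R is the frequency of the smoothed maximum."""
    chirp_sweep.validate()
    if not np.any(chirp_sweep.stimulus):
        raise ValidationError("chirp stimulus is identically zero")
    params = chirp_sweep.protocol.parameters
    if band_Hz is None:
        f0 = float(params.get("f_start_Hz", 1.0))
        f1 = float(params.get("f_end_Hz", 15.0))
        band_Hz = (max(f0, 1.0), f1)
    n = chirp_sweep.n_samples
    rate = chirp_sweep.sampling_rate_Hz
    df = rate / n
    if df > 0.2:
        raise ResolutionError(
            f"frequency resolution {df:.2f} Hz coarser than 0.2 Hz; sweep too short"
        )
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    V = np.fft.rfft(chirp_sweep.response - chirp_sweep.response.mean())
    I = np.fft.rfft(chirp_sweep.stimulus - chirp_sweep.stimulus.mean())
    in_band = (freqs >= band_Hz[0]) & (freqs <= band_Hz[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(V[in_band]) / np.abs(I[in_band])  # mV/pA = GΩ
    z_MOhm = z * 1e3
    f_band = freqs[in_band]
    width = max(1, int(round(smooth_Hz / df)))
    kernel = np.ones(width) / width
    z_smooth = np.convolve(z_MOhm, kernel, mode="same")
    f_R = float(f_band[np.argmax(z_smooth)])
    return ImpedanceProfile(frequencies_Hz=f_band, impedance_MOhm=z_smooth, f_R_Hz=f_R)


def classify_resonant(f_R_Hz: float, cutoff_Hz: float = 2.2) -> str:
    """PT-like iff the resonant frequency strictly exceeds the cutoff."""
    return "PT_like" if f_R_Hz > cutoff_Hz else "IT_like"


# ---------------------------------------------------------------------------
# temporal summation and resting potential
# ---------------------------------------------------------------------------

class ContaminationError(RuntimeError):
    pass


def temporal_summation(train_sweep: Sweep, n_events: int = 5) -> float:
    """Ratio of the last to the first EPSP peak (baseline-subtracted), with
    peaks located within each inter-event window."""
    train_sweep.validate()
    if _has_spike(train_sweep):
        raise ContaminationError("spike detected during the EPSC train")
    params = train_sweep.protocol.parameters
    freq = float(params.get("frequency_Hz", 50.0))
    onset_ms = float(params.get("onset_ms", 0.0))
    rate = train_sweep.sampling_rate_Hz
    interval = 1000.0 / freq
    i_on = int(round(onset_ms * 1e-3 * rate))
    baseline = train_sweep.response[:i_on].mean() if i_on > 0 else train_sweep.response[0]
    nwin = int(round(interval * 1e-3 * rate))
    peaks = []
    for k in range(n_events):
        start = i_on + k * nwin
        stop = start + nwin if k < n_events - 1 else min(
            start + 2 * nwin, train_sweep.n_samples
        )
        seg = train_sweep.response[start:stop]
        if len(seg) == 0:
            raise InsufficientDataError("train sweep shorter than the event window")
        peaks.append(seg.max() - baseline)
    if peaks[0] <= 0:
        raise InsufficientDataError("no measurable first EPSP")
    return float(peaks[-1] / peaks[0])


def resting_potential(sweep: Sweep, min_segment_ms: float = 500.0,
                      drift_limit_mV: float = 2.0) -> float:
    """Mean V over a stimulus-free segment; warns when drift exceeds 2 mV."""
    sweep.validate()
    quiet = np.abs(sweep.stimulus) < 1e-12
    if not quiet.any():
        raise InsufficientDataError("no stimulus-free segment")
    idx = np.flatnonzero(quiet)
    # use the longest contiguous quiet run
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, breaks + 1)
    seg_idx = max(runs, key=len)
    if len(seg_idx) / sweep.sampling_rate_Hz * 1e3 < min_segment_ms:
        raise InsufficientDataError(
            f"stimulus-free segment shorter than {min_segment_ms} ms"
        )
    seg = sweep.response[seg_idx]
    k = max(1, len(seg) // 10)
    drift = abs(seg[-k:].mean() - seg[:k].mean())
    if drift > drift_limit_mV:
        warnings.warn(f"resting potential drift {drift:.2f} mV exceeds 2 mV")
    return float(seg.mean())


__all__ = [
    "SubthresholdFeatures",
    "ImpedanceProfile",
    "InsufficientDataError",
    "FitError",
    "ResolutionError",
    "ContaminationError",
    "input_resistance",
    "sag_ratio",
    "rebound_slope",
    "membrane_time_constant",
    "zap_profile",
    "classify_resonant",
    "temporal_summation",
    "resting_potential",
]
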