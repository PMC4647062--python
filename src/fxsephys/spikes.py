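"""Action-potential threshold dynamics.

Threshold is defined by a rate-of-rise criterion: the membrane potential at
which dV/dt first exceeds 20 mV/ms before the first spike peak.  The
just-threshold search reproduces, by bisection, the experimental procedure
of adjusting a current step of fixed duration until it is just sufficient to
fire a single action potential; repeating it across durations yields the
strength–duration (threshold-accommodation) curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace_io import Sweep, ValidationError


class NoSpike(Exception):
    """Signal (not an error): the sweep contains no action potential."""


class DetectionError(RuntimeError):
    pass


class BracketError(RuntimeError):
    pass


AP_PEAK_CRITERION_MV = -10.0
DVDT_CRITERION = 20.0  # mV/ms
DEFAULT_DURATIONS_MS = (1.5, 3.0, 6.0, 12.0, 25.0, 50.0, 100.0)


@dataclass(frozen=True)
class SpikeFeatures:
    threshold_mV: float
    max_dVdt_mV_per_ms: float
    ap_amplitude_mV: float  # peak − threshold
    duration_ms: float = np.nan  # of the eliciting pulse, when known
    just_threshold_current_pA: float = np.nan


@dataclass(frozen=True)
class ThresholdCurve:
    durations_ms: np.ndarray
    thresholds_mV: np.ndarray
    currents_pA: np.ndarray


SMOOTH_WINDOW_MS = 0.06  # ~3 samples at 50 kHz


def _smoothed_dvdt(sweep: Sweep, smooth_samples: int | None = None):
    """Central-difference dV/dt (mV/ms) on lightly boxcar-smoothed V.

    The default smoothing window is fixed in time (~60 µs) so the derivative
    estimate — and hence the detected threshold — is invariant to the
    acquisition rate."""
    v = sweep.response
    if smooth_samples is None:
        smooth_samples = max(1, int(round(
            SMOOTH_WINDOW_MS * 1e-3 * sweep.sampling_rate_Hz)))
    if smooth_samples > 1:
        kernel = np.ones(smooth_samples) / smooth_samples
        pad = smooth_samples // 2
        padded = np.pad(v, pad, mode="edge")
        v = np.convolve(padded, kernel, mode="same")[pad:pad + len(v)]
    dvdt = np.gradient(v) * sweep.sampling_rate_Hz * 1e-3
    return v, dvdt


def detect_threshold(sweep: Sweep, dvdt_criterion: float = DVDT_CRITERION,
                     smooth_samples: int | None = None) -> SpikeFeatures:
    """Threshold, max dV/dt and AP amplitude of the first action potential.

    Raises :class:`NoSpike` when the sweep holds no AP (peak ≤ −10 mV) and
    :class:`DetectionError` when the dV/dt criterion is never crossed before
    the peak.
    """
    sweep.validate()
    if sweep.mode != "current_clamp":
        raise ValidationError("spike detection requires a current-clamp sweep")
    v_raw = sweep.response
    if np.max(v_raw) <= AP_PEAK_CRITERION_MV:
        raise NoSpike
    v, dvdt = _smoothed_dvdt(sweep, smooth_samples)
    peak_idx = int(np.argmax(v_raw))
    # first AP only: restrict to the first suprathreshold peak
    above = np.flatnonzero(v_raw > AP_PEAK_CRITERION_MV)
    first_peak = above[0] + int(np.argmax(v_raw[above[0]:above[0] + int(
        2e-3 * sweep.sampling_rate_Hz) + 1]))
    peak_idx = first_peak
    crossings = np.flatnonzero(dvdt[:peak_idx] > dvdt_criterion)
    if len(crossings) == 0:
        raise DetectionError("dV/dt criterion never crossed before the AP peak")
    i = int(crossings[0])
    # sub-sample refinement: linear interpolation of the criterion crossing
    # keeps the threshold invariant to the acquisition rate
    if i > 0 and dvdt[i] > dvdt[i - 1]:
        frac = (dvdt_criterion - dvdt[i - 1]) / (dvdt[i] - dvdt[i - 1])
        thr = float(v_raw[i - 1] + frac * (v_raw[i] - v_raw[i - 1]))
    else:
        thr = float(v_raw[i])
    return SpikeFeatures(
        threshold_mV=thr,
        max_dVdt_mV_per_ms=float(np.max(dvdt)),
        ap_amplitude_mV=float(v_raw[peak_idx] - thr),
    )


def has_spike(sweep: Sweep) -> bool:
    return bool(np.max(sweep.response) > AP_PEAK_CRITERION_MV)


def just_threshold_search(
    stimulate,
    duration_ms: float,
    bracket_pA: tuple = (0.0, 500.0),
    tol_pA: float = 1.0,
    max_expand: int = 12,
):
    """Smallest step amplitude of the given duration that elicits a spike.

    ``stimulate(duration_ms, amplitude_pA) -> Sweep`` must be deterministic.
    The upper bracket is doubled until suprathreshold (BracketError after
    ``max_expand`` doublings); bisection then narrows to ``tol_pA``.
    Returns ``(amplitude_pA, SpikeFeatures)`` measured on the just-threshold
    sweep.
    """
    lo, hi = bracket_pA
    for _ in range(max_expand):
        if has_spike(stimulate(duration_ms, hi)):
            break
        lo, hi = hi, hi * 2.0
    else:
        raise BracketError(
            f"no spike up to {hi:.0f} pA for duration {duration_ms} ms"
        )
    while hi - lo > tol_pA:
        mid = 0.5 * (lo + hi)
        if has_spike(stimulate(duration_ms, mid)):
            hi = mid
        else:
            lo = mid
    sweep = stimulate(duration_ms, hi)
    feats = detect_threshold(sweep)
    return hi, SpikeFeatures(
        threshold_mV=feats.threshold_mV,
        max_dVdt_mV_per_ms=feats.max_dVdt_mV_per_ms,
        ap_amplitude_mV=feats.ap_amplitude_mV,
        duration_ms=duration_ms,
        just_threshold_current_pA=hi,
    )


def threshold_accommodation_curve(
    stimulate,
    durations_ms=DEFAULT_DURATIONS_MS,
    bracket_pA: tuple = (0.0, 500.0),
    tol_pA: float = 1.0,
) -> ThresholdCurve:
    """Just-threshold search at each duration; verifies the strength–duration
    monotonicity (currents non-increasing with duration)."""
    durations = np.asarray(sorted(durations_ms), dtype=float)
    thresholds, currents = [], []
    for d in durations:
        amp, feats = just_threshold_search(stimulate, d, bracket_pA, tol_pA)
        thresholds.append(feats.threshold_mV)
        currents.append(amp)
    currents = np.asarray(currents)
    # allow the bisection tolerance when checking monotonicity
    if np.any(np.diff(currents) > 2.0 * tol_pA):
        raise DetectionError("strength-duration currents are not non-increasing")
    return ThresholdCurve(
        durations_ms=durations,
        thresholds_mV=np.asarray(thresholds),
        currents_pA=currents,
    )


def phase_plane(sweep: Sweep, window_ms: float = 5.0, smooth_samples: int | None = None):
    """(V, dV/dt) trajectory within ±window_ms of the first AP peak."""
    sweep.validate()
    if not has_spike(sweep):
        raise NoSpike
    v, dvdt = _smoothed_dvdt(sweep, smooth_samples)
    above = np.flatnonzero(sweep.response > AP_PEAK_CRITERION_MV)
    peak = above[0] + int(np.argmax(
        sweep.response[above[0]:above[0] + int(2e-3 * sweep.sampling_rate_Hz) + 1]
    ))
    half = int(round(window_ms * 1e-3 * sweep.sampling_rate_Hz))
    sl = slice(max(0, peak - half), min(sweep.n_samples, peak + half))
    return sweep.response[sl], dvdt[sl]


__all__ = [
    "SpikeFeatures",
    "ThresholdCurve",
    "NoSpike",
    "DetectionError",
    "BracketError",
    "detect_threshold",
    "has_spike",
    "just_threshold_search",
    "threshold_accommodation_curve",
    "phase_plane",
    "DEFAULT_DURATIONS_MS",
    "DVDT_CRITERION",
]
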