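"""Stimulus waveform builders.

Current-clamp stimuli are in pA; voltage-clamp commands in mV.  Durations in
the public signatures follow the package convention: seconds for whole-sweep
durations, milliseconds for protocol segments (pulse widths, onsets).
"""

from __future__ import annotations

import numpy as np

from .trace_io import ValidationError


class ParameterError(ValidationError):
    """Raised for stimulus parameters outside their valid domain."""


def make_chirp(
    f_start_Hz: float,
    f_end_Hz: float,
    duration_s: float,
    amplitude_pA: float,
    sampling_rate_Hz: float,
) -> np.ndarray:
    """Linear chirp I(t) = A sin(2π(f0 t + (f1−f0) t²/(2T))).

    The instantaneous frequency f0 + (f1−f0)·t/T sweeps linearly from
    ``f_start_Hz`` at t=0 to ``f_end_Hz`` at t=T.
    """
    if not (f_start_Hz < f_end_Hz):
        raise ParameterError("f_start_Hz must be < f_end_Hz")
    if duration_s <= 0 or sampling_rate_Hz <= 0:
        raise ParameterError("duration and sampling rate must be positive")
    if amplitude_pA < 0:
        raise ParameterError("amplitude must be non-negative")
    if f_end_Hz >= sampling_rate_Hz / 2:
        raise ParameterError("f_end_Hz violates the Nyquist limit")
    n = int(round(duration_s * sampling_rate_Hz))
    t = np.arange(n) / sampling_rate_Hz
    phase = 2.0 * np.pi * (
        f_start_Hz * t + (f_end_Hz - f_start_Hz) * t**2 / (2.0 * duration_s)
    )
    return amplitude_pA * np.sin(phase)


def epsc_kernel(rise_ms: float, decay_ms: float, t_ms: np.ndarray) -> np.ndarray:
    """Difference-of-exponentials waveform normalized to unit peak.

    Peak time is t_p = ln(decay/rise)·rise·decay/(decay−rise).
    """
    if rise_ms >= decay_ms:
        raise ParameterError("rise must be < decay (waveform degenerate otherwise)")
    t = np.asarray(t_ms, dtype=float)
    w = np.where(t >= 0, np.exp(-t / decay_ms) - np.exp(-t / rise_ms), 0.0)
    t_peak = np.log(decay_ms / rise_ms) * rise_ms * decay_ms / (decay_ms - rise_ms)
    peak = np.exp(-t_peak / decay_ms) - np.exp(-t_peak / rise_ms)
    return w / peak


def epsc_peak_time_ms(rise_ms: float, decay_ms: float) -> float:
    return np.log(decay_ms / rise_ms) * rise_ms * decay_ms / (decay_ms - rise_ms)


def make_epsc_train(
    rise_ms: float,
    decay_ms: float,
    n_events: int,
    frequency_Hz: float,
    amplitude_pA: float,
    sampling_rate_Hz: float,
    onset_ms: float = 0.0,
    tail_ms: float | None = None,
) -> np.ndarray:
    """Sum of ``n_events`` simulated-EPSC waveforms at interval 1/frequency,
    each individually normalized so its own peak is ``amplitude_pA``."""
    if n_events < 1:
        raise ParameterError("n_events must be >= 1")
    if frequency_Hz <= 0:
        raise ParameterError("frequency must be positive")
    interval_ms = 1000.0 / frequency_Hz
    if tail_ms is None:
        tail_ms = 8.0 * decay_ms
    total_ms = onset_ms + (n_events - 1) * interval_ms + interval_ms + tail_ms
    n = int(round(total_ms * 1e-3 * sampling_rate_Hz))
    t_ms = np.arange(n) / sampling_rate_Hz * 1000.0
    out = np.zeros(n)
    for k in range(n_events):
        out += epsc_kernel(rise_ms, decay_ms, t_ms - onset_ms - k * interval_ms)
    return amplitude_pA * out


def make_step(
    amplitude: float,
    duration_ms: float,
    sampling_rate_Hz: float,
    onset_ms: float = 200.0,
    tail_ms: float = 400.0,
    baseline: float = 0.0,
) -> np.ndarray:
    """Rectangular step (pA or mV depending on mode) on a baseline."""
    total_ms = onset_ms + duration_ms + tail_ms
    n = int(round(total_ms * 1e-3 * sampling_rate_Hz))
    t_ms = np.arange(n) / sampling_rate_Hz * 1000.0
    out = np.full(n, baseline, dtype=float)
    out[(t_ms >= onset_ms) & (t_ms < onset_ms + duration_ms)] = baseline + amplitude
    return out


def make_vc_segments(
    segments,
    sampling_rate_Hz: float,
) -> np.ndarray:
    """Piecewise-constant voltage command from (level_mV, duration_ms) pairs."""
    parts = []
    for level, dur_ms in segments:
        n = int(round(dur_ms * 1e-3 * sampling_rate_Hz))
        parts.append(np.full(n, float(level)))
    out = np.concatenate(parts)
    if not np.all(np.isfinite(out)):
        raise ParameterError("voltage command contains non-finite values")
    return out


__all__ = [
    "ParameterError",
    "make_chirp",
    "epsc_kernel",
    "epsc_peak_time_ms",
    "make_epsc_train",
    "make_step",
    "make_vc_segments",
]
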