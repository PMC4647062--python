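"""Outside-out voltage-clamp analysis.

Implements the three-protocol decomposition of the total K⁺ current into a
rapidly inactivating (Kv4-like), slowly inactivating (Kv1-like) and
sustained component, the scaling-based leak/capacitive subtraction, the
slow-component back-extrapolation used to split transient peaks at small
commands, Boltzmann activation fits, inactivation and recovery kinetics,
h-current step analysis, and drug-subtraction currents.

Conventions: commands in mV, currents in pA; outward K⁺ current is
positive.  All protocol sweeps are expected leak-subtracted and aligned by
their command waveforms (onsets are detected from the stimulus channel).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .trace_io import Sweep, SweepSet, ValidationError


class AlignmentError(ValueError):
    pass


class FitError(RuntimeError):
    pass


class PolarityError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


TRANSIENT_WINDOW_MS = 50.0
SUSTAINED_WINDOW_MS = 50.0


@dataclass(frozen=True)
class ComponentTrace:
    trace_pA: np.ndarray
    peak_pA: float


@dataclass(frozen=True)
class CurrentComponents:
    I_K_total: ComponentTrace
    I_KA_fast: ComponentTrace
    I_K_slow: ComponentTrace
    I_K_sustained: ComponentTrace  # peak_pA holds the sustained amplitude
    fractions: dict
    sampling_rate_Hz: float


@dataclass(frozen=True)
class BoltzmannFit:
    V_half_mV: float
    k_mV: float
    G_max_nS: float
    residual_rms: float


@dataclass(frozen=True)
class ExpFit:
    amplitudes: tuple
    taus_ms: tuple  # ascending
    offset: float
    residual_rms: float


@dataclass(frozen=True)
class IhMeasurement:
    I_h_max_pA: float  # inward: <= 0
    tau_fast_ms: float
    tau_slow_ms: float
    fraction_fast: float


# ---------------------------------------------------------------------------
# alignment helpers
# ---------------------------------------------------------------------------

def _segments(command: np.ndarray):
    """(start, stop, level) runs of a piecewise-constant command."""
    edges = np.flatnonzero(np.diff(command) != 0) + 1
    starts = np.concatenate(([0], edges))
    stops = np.concatenate((edges, [len(command)]))
    return [(int(s), int(e), float(command[s])) for s, e in zip(starts, stops)]


def _test_step(command: np.ndarray):
    """(onset, end, level) of the test step: the command segment farthest
    from the initial holding level."""
    hold = command[0]
    runs = [r for r in _segments(command) if r[2] != hold]
    if not runs:
        raise AlignmentError("command contains no step")
    return max(runs, key=lambda r: abs(r[2] - hold))


def _final_step_onset(command: np.ndarray) -> int:
    return _test_step(command)[0]


def _step_onset_to(command: np.ndarray, level: float, tol: float = 0.5) -> int:
    """Onset of the first segment at ``level`` (mV)."""
    at = np.abs(command - level) < tol
    if not at.any():
        raise AlignmentError(f"command never reaches {level} mV")
    idx = np.flatnonzero(at)
    return int(idx[0])


def _average(sweeps: SweepSet) -> Sweep:
    sweeps.validate()
    n = min(s.n_samples for s in sweeps)
    resp = np.mean([s.response[:n] for s in sweeps], axis=0)
    stim = sweeps[0].stimulus[:n]
    return Sweep(
        sampling_rate_Hz=sweeps.sampling_rate_Hz,
        mode=sweeps.mode,
        stimulus=stim,
        response=resp,
        metadata=sweeps[0].metadata,
        protocol=sweeps[0].protocol,
    )


# ---------------------------------------------------------------------------
# leak subtraction
# ---------------------------------------------------------------------------

def leak_subtract(test_sweep: Sweep, scaling_sweeps: SweepSet,
                  nonlinearity_tol: float = 0.05,
                  template_ms: float = 10.0) -> np.ndarray:
    """Scaling-based leak and capacitive-transient subtraction.

    A per-unit-ΔV template is built from the scaling sweeps (each
    baseline-referenced to its own holding current and divided by its step
    size); the test trace, referenced to its holding baseline, then has the
    template — scaled by each command segment's ΔV from holding — subtracted
    segment by segment.  Exact for a purely linear membrane, for arbitrary
    piecewise-constant test commands.
    """
    test_sweep.validate()
    scaling_sweeps.validate()
    if test_sweep.mode != "voltage_clamp" or scaling_sweeps.mode != "voltage_clamp":
        raise ValidationError("leak subtraction requires voltage-clamp sweeps")
    if not np.isclose(test_sweep.sampling_rate_Hz, scaling_sweeps.sampling_rate_Hz):
        raise ValidationError("sampling rates differ between test and scaling sweeps")

    templates = []
    for sw in scaling_sweeps:
        s_on, s_end, level = _test_step(sw.stimulus)
        dv = level - sw.stimulus[0]
        if dv == 0:
            raise ValidationError("scaling command step is zero")
        if abs(dv) > 10.0 + 1e-9:
            warnings.warn(f"scaling step {dv:.1f} mV exceeds the ±10 mV convention")
        base = sw.response[:s_on].mean()
        templates.append((sw.response[s_on:s_end] - base) / dv)
    # capacitive transients settle within a few ms; a longer template would
    # pick up slow voltage-dependent relaxations in the scaling range
    n_tpl = int(round(template_ms * 1e-3 * test_sweep.sampling_rate_Hz))
    n = min(min(len(t) for t in templates), max(n_tpl, 2))
    templates = [t[:n] for t in templates]
    if len(templates) >= 2:
        ref = templates[0]
        scale = np.max(np.abs(ref)) or 1.0
        for other in templates[1:]:
            if np.max(np.abs(other - ref)) / scale > nonlinearity_tol:
                warnings.warn(
                    "voltage-dependent current detected in scaling sweeps "
                    "(scaled traces differ by more than 5%)"
                )
                break
    template = np.mean(templates, axis=0)

    hold = test_sweep.stimulus[0]
    runs = _segments(test_sweep.stimulus)
    base_t = test_sweep.response[:runs[0][1]].mean() if runs[0][2] == hold \
        else test_sweep.response[0]
    corrected = test_sweep.response.copy() - base_t
    for start, stop, level in runs:
        dv = level - hold
        if dv == 0:
            continue
        m = min(stop - start, len(template))
        corrected[start:start + m] -= template[:m] * dv
        if stop - start > m:
            corrected[start + m:stop] -= template[-1] * dv
    return corrected


def scaling_factor(dv_test_mV: float, dv_scale_mV: float) -> float:
    if dv_scale_mV == 0:
        raise ValidationError("scaling command step is zero")
    return dv_test_mV / dv_scale_mV


# ---------------------------------------------------------------------------
# three-protocol decomposition
# ---------------------------------------------------------------------------

def decompose_currents(total: SweepSet, prepulsed: SweepSet, sustained: SweepSet,
                       test_mV: float = 50.0,
                       noise_floor_sd: float = 3.0) -> CurrentComponents:
    """Kinetic decomposition of I_K at the +50 mV test command.

    ``total``: hold −90 → +50; ``prepulsed``: −90, 100 ms prepulse at −20,
    then +50; ``sustained``: hold −20 → +50.  Components:

        I_KA_fast    = total − prepulsed
        I_K_slow     = prepulsed − sustained
        I_K_sustained = sustained

    so the three components sum to the total trace exactly by construction.
    Transient peaks are taken within 50 ms of the test-step onset; the
    sustained amplitude is the mean over the last 50 ms of the step.
    """
    rate = total.sampling_rate_Hz
    if not (np.isclose(rate, prepulsed.sampling_rate_Hz)
            and np.isclose(rate, sustained.sampling_rate_Hz)):
        raise AlignmentError("protocols differ in sampling rate")
    avg = {"total": _average(total), "prepulsed": _average(prepulsed),
           "sustained": _average(sustained)}
    onsets = {k: _step_onset_to(s.stimulus, test_mV) for k, s in avg.items()}
    ends = {k: _final_step_end(s.stimulus, onsets[k]) for k, s in avg.items()}
    n = min(ends[k] - onsets[k] for k in avg)
    cut = {k: avg[k].response[onsets[k]:onsets[k] + n] for k in avg}

    w = int(round(TRANSIENT_WINDOW_MS * 1e-3 * rate))
    ws = int(round(SUSTAINED_WINDOW_MS * 1e-3 * rate))
    tot = cut["total"]
    fast = tot - cut["prepulsed"]
    slow = cut["prepulsed"] - cut["sustained"]
    sust = cut["sustained"]

    base_sd = float(np.std(avg["total"].response[:max(onsets["total"] // 2, 2)]))
    floor = noise_floor_sd * base_sd
    peak_tot = float(tot.max())
    peak_fast = float(fast[:w].max())
    peak_slow = float(slow[:w].max())
    amp_sust = float(sust[-ws:].mean())
    for name, pk in (("fast", peak_fast), ("slow", peak_slow)):
        if pk < -floor:
            warnings.warn(f"negative {name} transient peak beyond the noise floor")
    fractions = {
        "fast": max(peak_fast, 0.0) / peak_tot if peak_tot > 0 else np.nan,
        "slow": max(peak_slow, 0.0) / peak_tot if peak_tot > 0 else np.nan,
        "sustained": max(amp_sust, 0.0) / peak_tot if peak_tot > 0 else np.nan,
    }
    return CurrentComponents(
        I_K_total=ComponentTrace(tot, peak_tot),
        I_KA_fast=ComponentTrace(fast, peak_fast),
        I_K_slow=ComponentTrace(slow, peak_slow),
        I_K_sustained=ComponentTrace(sust, amp_sust),
        fractions=fractions,
        sampling_rate_Hz=rate,
    )


def _final_step_end(command: np.ndarray, onset: int) -> int:
    level = command[onset]
    after = np.flatnonzero(np.abs(command[onset:] - level) > 0.5)
    return onset + (int(after[0]) if len(after) else len(command) - onset)


# ---------------------------------------------------------------------------
# exponential fitting
# ---------------------------------------------------------------------------

def _fit_single_exp(t_ms, y, tau_starts=(10.0, 100.0, 1000.0)):
    """y(t) = A exp(-t/tau) + C by multi-start nonlinear least squares."""

    def model(t, a, tau, c):
        return a * np.exp(-t / tau) + c

    best = None
    span = max(float(y[0] - y[-1]), 1e-12)
    for tau0 in tau_starts:
        try:
            popt, _ = optimize.curve_fit(
                model, t_ms, y, p0=[span, tau0, float(y[-1])],
                bounds=([-np.inf, 1e-3, -np.inf], [np.inf, 1e5, np.inf]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        rms = float(np.sqrt(np.mean((model(t_ms, *popt) - y) ** 2)))
        if best is None or rms < best[0]:
            best = (rms, popt)
    if best is None:
        raise FitError("single-exponential fit did not converge")
    rms, (a, tau, c) = best
    return ExpFit(amplitudes=(float(a),), taus_ms=(float(tau),),
                  offset=float(c), residual_rms=rms)


def extrapolate_slow_peak(trace: np.ndarray, sampling_rate_Hz: float,
                          command_mV: float,
                          fast_tau_estimate_ms: float = 25.0,
                          fit_window_ms: tuple | None = None) -> float:
    """Back-extrapolated slow-component amplitude at the total-current peak.

    Fits a single exponential to the late decay (starting 5× the fast-τ
    estimate after the peak, so the fast component has decayed below 1%)
    and evaluates the fit at the peak time.  Intended for commands more
    hyperpolarized than −10 mV, where the prepulse protocol is not
    available per voltage.  A decay window shorter than half the fitted τ
    is a fit-window error; between 0.5 and 1 τ a warning is emitted.
    """
    if command_mV >= -10.0:
        warnings.warn("back-extrapolation is intended for commands < -10 mV")
    trace = np.asarray(trace, dtype=float)
    peak_idx = int(np.argmax(trace))
    start = peak_idx + int(round(5.0 * fast_tau_estimate_ms * 1e-3 * sampling_rate_Hz))
    if fit_window_ms is not None:
        start = peak_idx + int(round(fit_window_ms[0] * 1e-3 * sampling_rate_Hz))
        stop = peak_idx + int(round(fit_window_ms[1] * 1e-3 * sampling_rate_Hz))
    else:
        stop = len(trace)
    if stop - start < 10:
        raise FitError("decay window too short for back-extrapolation")
    t_ms = (np.arange(start, stop) - peak_idx) / sampling_rate_Hz * 1e3
    fit = _fit_single_exp(t_ms, trace[start:stop])
    tau = fit.taus_ms[0]
    window_ms = (stop - start) / sampling_rate_Hz * 1e3
    if window_ms < 0.5 * tau:
        raise FitError("decay window shorter than half the fitted time constant")
    if window_ms < tau:
        warnings.warn("decay window shorter than one fitted time constant")
    # a separable slow component must be slow relative to the fast estimate;
    # otherwise the tail is the fast transient itself and the slow peak is
    # just the sustained floor
    if tau < 3.0 * fast_tau_estimate_ms:
        return float(fit.offset)
    # amplitude of the fitted exponential evaluated at the peak time (t=0)
    return float(fit.amplitudes[0] + fit.offset)


# ---------------------------------------------------------------------------
# activation curve
# ---------------------------------------------------------------------------

def activation_curve(family: SweepSet, component: str = "KA_fast",
                     E_K_mV: float = -96.0, on_conductance: bool = True,
                     fast_tau_estimate_ms: float = 25.0) -> BoltzmannFit:
    """Single-Boltzmann fit of the voltage dependence of activation.

    ``family`` is the leak-subtracted activation family (hold −90 mV, steps
    −70…+50 mV).  For each sweep the transient peak is isolated: for the
    fast component the back-extrapolated slow amplitude is subtracted from
    the total peak (commands < −10 mV as well as the rest, uniformly).
    G(V) = I_peak/(V − E_K) is fit with G/G_max = 1/(1+exp(−(V−V_half)/k)).
    """
    family.validate()
    rate = family.sampling_rate_Hz
    volts, peaks = [], []
    for sw in family:
        on = _final_step_onset(sw.stimulus)
        end = _final_step_end(sw.stimulus, on)
        v = float(sw.stimulus[on])
        seg = sw.response[on:end]
        w = int(round(TRANSIENT_WINDOW_MS * 1e-3 * rate))
        peak_total = float(seg[:w].max())
        if component == "KA_fast":
            try:
                slow = extrapolate_slow_peak(seg, rate, min(v, -10.001),
                                             fast_tau_estimate_ms)
            except FitError:
                slow = 0.0
            peak = peak_total - max(slow, 0.0)
        elif component == "total":
            peak = peak_total
        else:
            raise ValidationError(f"unknown component selector {component!r}")
        volts.append(v)
        peaks.append(max(peak, 0.0))
    volts = np.asarray(volts)
    peaks = np.asarray(peaks)
    measurable = peaks > 0
    if measurable.sum() < 5:
        raise InsufficientDataError(
            f"only {int(measurable.sum())} voltages with measurable current (need 5)"
        )
    if on_conductance:
        with np.errstate(divide="ignore"):
            y = peaks / (volts - E_K_mV)
    else:
        y = peaks

    def model(v, gmax, vh, k):
        return gmax / (1.0 + np.exp(-(v - vh) / k))

    y_nS = y  # pA/mV = nS
    best = None
    for vh0 in (-40.0, -20.0, 0.0):
        try:
            popt, _ = optimize.curve_fit(
                model, volts, y_nS, p0=[max(y_nS.max(), 1e-6), vh0, 10.0],
                bounds=([1e-9, -120.0, 0.5], [np.inf, 60.0, 60.0]), maxfev=20000,
            )
        except RuntimeError:
            continue
        rms = float(np.sqrt(np.mean((model(volts, *popt) - y_nS) ** 2)))
        if best is None or rms < best[0]:
            best = (rms, popt)
    if best is None:
        raise FitError("Boltzmann fit did not converge")
    rms, (gmax, vh, k) = best
    if not (volts.min() <= vh <= volts.max()):
        warnings.warn("fitted V_half lies outside the command range (extrapolation)")
    return BoltzmannFit(V_half_mV=float(vh), k_mV=float(k),
                        G_max_nS=float(gmax), residual_rms=rms)


# ---------------------------------------------------------------------------
# inactivation and recovery kinetics
# ---------------------------------------------------------------------------

def inactivation_tau(trace: np.ndarray, sampling_rate_Hz: float,
                     no_decay_fraction: float = 0.05) -> ExpFit:
    """Single-exponential fit of the decay from 95% of peak to the end of
    the step.  A non-decaying trace returns τ = inf (no-decay signal)."""
    trace = np.asarray(trace, dtype=float)
    peak_idx = int(np.argmax(trace))
    peak = trace[peak_idx]
    below = np.flatnonzero(trace[peak_idx:] <= 0.95 * peak)
    end_mean = trace[-max(len(trace) // 20, 2):].mean()
    if len(below) == 0 or (peak - end_mean) < no_decay_fraction * peak:
        return ExpFit(amplitudes=(0.0,), taus_ms=(np.inf,),
                      offset=float(end_mean), residual_rms=0.0)
    start = peak_idx + int(below[0])
    t_ms = (np.arange(start, len(trace)) - start) / sampling_rate_Hz * 1e3
    return _fit_single_exp(t_ms, trace[start:])


def recovery_from_inactivation(fractions, intervals_ms) -> ExpFit:
    """Double-exponential fit of recovery fractions vs interpulse interval:

        f(Δt) = 1 − A_f·exp(−Δt/τ_f) − A_s·exp(−Δt/τ_s)
    """
    intervals_ms = np.asarray(intervals_ms, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    order = np.argsort(intervals_ms)
    intervals_ms, fractions = intervals_ms[order], fractions[order]
    if np.any(np.diff(fractions) < -0.05):
        warnings.warn("recovery fractions are non-monotone beyond noise")

    def model(dt, a_f, tau_f, a_s, tau_s):
        return 1.0 - a_f * np.exp(-dt / tau_f) - a_s * np.exp(-dt / tau_s)

    best = None
    for tau_f0, tau_s0 in [(30.0, 600.0), (10.0, 300.0), (100.0, 2000.0)]:
        try:
            popt, _ = optimize.curve_fit(
                model, intervals_ms, fractions,
                p0=[0.5, tau_f0, 0.3, tau_s0],
                bounds=([0.0, 1.0, 0.0, 1.0], [1.5, 1e4, 1.5, 1e5]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        rms = float(np.sqrt(np.mean((model(intervals_ms, *popt) - fractions) ** 2)))
        if best is None or rms < best[0]:
            best = (rms, popt)
    if best is None:
        raise FitError("recovery double-exponential fit did not converge")
    rms, (a_f, tau_f, a_s, tau_s) = best
    if tau_f > tau_s:
        a_f, a_s, tau_f, tau_s = a_s, a_f, tau_s, tau_f
    return ExpFit(amplitudes=(float(a_f), float(a_s)),
                  taus_ms=(float(tau_f), float(tau_s)),
                  offset=0.0, residual_rms=rms)


def recovery_fractions(two_pulse_sweeps, intervals_ms, test_mV: float = 50.0,
                       window_ms: float = TRANSIENT_WINDOW_MS):
    """Per-interval recovery fraction: test-pulse transient peak divided by
    the conditioning-pulse transient peak, from two-pulse sweeps."""
    fracs = []
    for sw, dt in zip(two_pulse_sweeps, intervals_ms):
        stim = sw.stimulus
        rate = sw.sampling_rate_Hz
        at = np.abs(stim - test_mV) < 0.5
        idx = np.flatnonzero(at)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        if len(breaks) == 0:
            raise AlignmentError("two-pulse sweep lacks two test-level pulses")
        runs = np.split(idx, breaks + 1)
        w = int(round(window_ms * 1e-3 * rate))
        cond = sw.response[runs[0][0]:runs[0][0] + w].max()
        test = sw.response[runs[-1][0]:runs[-1][0] + w].max()
        fracs.append(test / cond)
    return np.asarray(fracs)


# ---------------------------------------------------------------------------
# h-current step analysis
# ---------------------------------------------------------------------------

def ih_step_analysis(sweep: Sweep, sustained_window_ms: float = 50.0) -> IhMeasurement:
    """Double-exponential fit of inward h-current development during a
    hyperpolarizing step (−30 → −140 mV, 500 ms).

    I_h_max is the steady inward amplitude (mean of the last 50 ms of the
    step, sign-preserved, relative to the pre-step level).
    """
    sweep.validate()
    rate = sweep.sampling_rate_Hz
    on = _final_step_onset(sweep.stimulus)
    end = _final_step_end(sweep.stimulus, on)
    base = sweep.response[:on].mean()
    seg = sweep.response[on:end] - base
    ws = int(round(sustained_window_ms * 1e-3 * rate))
    i_max = float(seg[-ws:].mean())
    if i_max > 0:
        raise PolarityError(
            "outward current during the hyperpolarizing step; leak subtraction suspect"
        )
    t_ms = np.arange(len(seg)) / rate * 1e3

    def model(t, a_f, tau_f, a_s, tau_s, c):
        return c + a_f * np.exp(-t / tau_f) + a_s * np.exp(-t / tau_s)

    best = None
    for tau_f0, tau_s0 in [(30.0, 200.0), (10.0, 100.0), (60.0, 400.0)]:
        try:
            popt, _ = optimize.curve_fit(
                model, t_ms, seg,
                p0=[-0.6 * i_max, tau_f0, -0.4 * i_max, tau_s0, i_max],
                bounds=([-np.inf, 0.5, -np.inf, 0.5, -np.inf],
                        [np.inf, 5e3, np.inf, 5e4, np.inf]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        rms = float(np.sqrt(np.mean((model(t_ms, *popt) - seg) ** 2)))
        if best is None or rms < best[0]:
            best = (rms, popt)
    if best is None:
        raise FitError("h-current double-exponential fit did not converge")
    _, (a_f, tau_f, a_s, tau_s, c) = best
    if tau_f > tau_s:
        a_f, a_s, tau_f, tau_s = a_s, a_f, tau_s, tau_f
    denom = abs(a_f) + abs(a_s)
    frac_fast = abs(a_f) / denom if denom > 0 else np.nan
    return IhMeasurement(I_h_max_pA=i_max, tau_fast_ms=float(tau_f),
                         tau_slow_ms=float(tau_s), fraction_fast=float(frac_fast))


# ---------------------------------------------------------------------------
# drug subtraction
# ---------------------------------------------------------------------------

def drug_subtraction(before: SweepSet, after: SweepSet,
                     window_ms: float = TRANSIENT_WINDOW_MS):
    """Drug-sensitive current: averaged before − averaged after, with the
    peak reported in the transient window after the test-step onset."""
    b = _average(before)
    a = _average(after)
    if not np.allclose(b.stimulus[:min(b.n_samples, a.n_samples)],
                       a.stimulus[:min(b.n_samples, a.n_samples)]):
        raise AlignmentError("before/after command waveforms differ")
    n = min(b.n_samples, a.n_samples)
    diff = b.response[:n] - a.response[:n]
    on = _final_step_onset(b.stimulus[:n])
    w = int(round(window_ms * 1e-3 * b.sampling_rate_Hz))
    peak = float(diff[on:on + w].max()) if on + 1 < n else float(diff.max())
    return diff, peak


__all__ = [
    "CurrentComponents", "ComponentTrace", "BoltzmannFit", "ExpFit",
    "IhMeasurement",
    "AlignmentError", "FitError", "PolarityError", "InsufficientDataError",
    "leak_subtract", "scaling_factor",
    "decompose_currents", "extrapolate_slow_peak", "activation_curve",
    "inactivation_tau", "recovery_from_inactivation", "recovery_fractions",
    "ih_step_analysis", "drug_subtraction",
]
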