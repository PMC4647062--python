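import numpy as np
import pytest
from scipy import signal

from fxsephys import presets, protocols, simulate, stimuli, subthreshold
from fxsephys.trace_io import ProtocolDescriptor, SweepSet

from conftest import make_passive_neuron, make_sweep, make_two_compartment_passive


def step_family(neuron, amplitudes=tuple(np.arange(-150.0, 11.0, 20.0))):
    return protocols.run_step_family(neuron, amplitudes_pA=amplitudes)


class TestInputResistance:
    def test_perfectly_linear_iv_recovers_slope_exactly(self):
        # synthetic sweeps with ΔV = 0.08 mV/pA -> 80 MΩ exactly
        rate = 1000.0
        sweeps = []
        for amp in (-100.0, -50.0, 50.0, 100.0):
            stim = np.zeros(1500)
            stim[200:1200] = amp
            resp = np.full(1500, -65.0)
            resp[200:1200] = -65.0 + 0.08 * amp
            sweeps.append(make_sweep(stim, resp, rate=rate))
        r_n, iv = subthreshold.input_resistance(SweepSet(tuple(sweeps)))
        assert r_n == pytest.approx(80.0, abs=1e-9)
        assert iv["used"].all()

    def test_passive_cell_measured_within_half_percent(self, passive_cell):
        steps = step_family(passive_cell)
        r_n, _ = subthreshold.input_resistance(steps)
        assert r_n == pytest.approx(100.0, rel=0.005)

    def test_too_few_sweeps_rejected(self, passive_cell):
        steps = protocols.run_step_family(passive_cell, amplitudes_pA=(-50.0, 50.0))
        with pytest.raises(subthreshold.InsufficientDataError):
            subthreshold.input_resistance(steps)


class TestSagAndRebound:
    def test_passive_cell_sag_is_unity_and_rebound_zero(self, passive_cell):
        steps = step_family(passive_cell)
        assert subthreshold.sag_ratio(steps) == pytest.approx(1.0, abs=0.005)
        assert subthreshold.rebound_slope(steps) == pytest.approx(0.0, abs=0.01)

    def test_sag_matches_trace_extrema_oracle(self, wt_pt):
        # oracle computed directly from the noise-free voltage traces
        steps = step_family(wt_pt)
        expected = []
        for sw in steps:
            amp = sw.stimulus[2500] - sw.stimulus[0]
            if not (-150.0 <= amp <= -90.0):
                continue
            base = sw.response[:2000].mean()
            seg = sw.response[2000:12000]
            expected.append((base - seg.min()) / (base - seg[-2000:].mean()))
        assert subthreshold.sag_ratio(steps) == pytest.approx(np.mean(expected),
                                                              rel=1e-9)

    def test_wt_pt_sag_and_rebound_exceed_ko_pt(self, wt_pt, ko_pt):
        s_wt = step_family(wt_pt)
        s_ko = step_family(ko_pt)
        assert subthreshold.sag_ratio(s_wt) > subthreshold.sag_ratio(s_ko)
        assert abs(subthreshold.rebound_slope(s_wt)) > abs(
            subthreshold.rebound_slope(s_ko))


class TestMembraneTimeConstant:
    def test_single_compartment_rc(self, passive_cell):
        pulses = protocols.run_brief_pulses(passive_cell)
        tau, rec = subthreshold.membrane_time_constant(pulses)
        assert tau == pytest.approx(20.0, rel=0.02)  # R=100 MΩ, C=200 pF

    def test_two_compartment_matches_slowest_eigen_time_constant(self):
        neuron = make_two_compartment_passive(R1=100.0, C1=150.0, R2=200.0,
                                              C2=100.0, gc_nS=4.0)
        # analytic 2x2 system: C dV/dt = -G V with coupling
        g1, g2, gc = 10.0, 5.0, 4.0  # nS
        A = np.array([[-(g1 + gc) / 150.0, gc / 150.0],
                      [gc / 100.0, -(g2 + gc) / 100.0]])  # 1/ms
        tau_slow = -1.0 / np.max(np.linalg.eigvals(A).real)
        pulses = protocols.run_brief_pulses(neuron)
        tau, _ = subthreshold.membrane_time_constant(pulses)
        assert tau == pytest.approx(tau_slow, rel=0.05)

    def test_ko_pt_time_constant_longer_than_wt(self, wt_pt, ko_pt):
        t_wt, _ = subthreshold.membrane_time_constant(protocols.run_brief_pulses(wt_pt))
        t_ko, _ = subthreshold.membrane_time_constant(protocols.run_brief_pulses(ko_pt))
        assert t_ko > t_wt

    def test_too_few_sweeps_rejected(self, passive_cell):
        pulses = protocols.run_brief_pulses(passive_cell, n_sweeps=5)
        with pytest.raises(subthreshold.InsufficientDataError):
            subthreshold.membrane_time_constant(pulses)


def _lsim_chirp_sweep(system, rate=10000.0, amplitude_pA=20.0):
    """Simulate a linear system's chirp response with scipy.signal.lsim —
    an oracle independent of the package's integrator."""
    chirp = stimuli.make_chirp(1.0, 15.0, 15.0, amplitude_pA, rate)
    t = np.arange(len(chirp)) / rate
    _, v, _ = signal.lsim(system, chirp, t)
    return make_sweep(chirp, v, rate=rate,
                      protocol=ProtocolDescriptor("chirp", {
                          "f_start_Hz": 1.0, "f_end_Hz": 15.0,
                          "duration_s": 15.0, "amplitude_pA": amplitude_pA}))


class TestZapProfile:
    def test_passive_rc_matches_closed_form_and_is_non_resonant(self):
        R, C = 0.1, 200.0  # GΩ, pF -> tau 20 ms
        system = signal.TransferFunction([R], [R * C * 1e-3, 1.0])  # mV per pA
        sweep = _lsim_chirp_sweep(system)
        prof = subthreshold.zap_profile(sweep)
        expected = 1e3 * R / np.sqrt(
            1.0 + (2 * np.pi * prof.frequencies_Hz * R * C * 1e-3) ** 2)
        band = (prof.frequencies_Hz >= 1.5) & (prof.frequencies_Hz <= 14.0)
        rel = np.abs(prof.impedance_MOhm[band] - expected[band]) / expected[band]
        assert np.percentile(rel, 95) < 0.03
        assert prof.f_R_Hz <= 1.5  # at the band minimum
        assert subthreshold.classify_resonant(prof.f_R_Hz) == "IT_like"

    def test_resonant_linear_membrane_f_r_matches_analytic(self):
        # passive RC plus a slow negative-feedback conductance:
        # Y(s) = sC + g0 + g1/(1 + s tau1); f_R from the closed-form |Z|
        C, g0, g1, tau1 = 150.0, 8.0, 15.0, 50.0  # pF, nS, nS, ms

        def z_mag(f):
            s = 2j * np.pi * f * 1e-3  # 1/ms
            return 1e3 / np.abs(s * C + g0 + g1 / (1.0 + s * tau1))

        f_grid = np.arange(1.0, 15.0, 0.001)
        f_expected = f_grid[np.argmax(z_mag(f_grid))]
        num = [tau1 * 1e-3, 1.0]
        den = [C * tau1 * 1e-6, (C + g0 * tau1) * 1e-3, g0 + g1]
        system = signal.TransferFunction(num, den)  # GΩ
        sweep = _lsim_chirp_sweep(system)
        prof = subthreshold.zap_profile(sweep)
        assert prof.f_R_Hz == pytest.approx(f_expected, abs=0.15)

    def test_wt_pt_resonates_in_theta_band(self, wt_pt):
        prof = subthreshold.zap_profile(protocols.run_chirp(wt_pt))
        assert 3.0 <= prof.f_R_Hz <= 7.0
        assert subthreshold.classify_resonant(prof.f_R_Hz) == "PT_like"

    def test_short_sweep_resolution_rejected(self):
        sweep = make_sweep(np.sin(np.arange(500)), np.zeros(500), rate=1000.0,
                           protocol=ProtocolDescriptor("chirp", {
                               "f_start_Hz": 1.0, "f_end_Hz": 15.0,
                               "duration_s": 0.5, "amplitude_pA": 1.0}))
        with pytest.raises(subthreshold.ResolutionError):
            subthreshold.zap_profile(sweep)


class TestClassifyResonant:
    @pytest.mark.parametrize("f_r,expected", [
        (4.11, "PT_like"),   # WT PT cohort mean
        (1.01, "IT_like"),   # KO IT cohort mean
        (2.2, "IT_like"),    # boundary: strict inequality
        (2.2000001, "PT_like"),
    ])
    def test_cutoff_convention(self, f_r, expected):
        assert subthreshold.classify_resonant(f_r) == expected


class TestTemporalSummation:
    def test_low_frequency_ratio_is_unity(self, passive_cell):
        sweep = protocols.run_epsc_train(passive_cell, frequency_Hz=0.1,
                                         amplitude_pA=30.0)
        assert subthreshold.temporal_summation(sweep) == pytest.approx(1.0, abs=0.02)

    def test_passive_summation_matches_linear_superposition(self, passive_cell):
        # convolution oracle: superpose single-event responses analytically
        rate = 10000.0
        amp = 30.0
        sweep = protocols.run_epsc_train(passive_cell, amplitude_pA=amp,
                                         sampling_rate_Hz=rate)
        t_ms = np.arange(60000) / rate * 1e3
        kernel = stimuli.epsc_kernel(0.3, 4.0, t_ms)
        h = np.exp(-t_ms / 20.0) / 200.0 * (1e3 / rate)
        single = amp * np.convolve(kernel, h)[:len(t_ms)]
        superposed = np.zeros(len(t_ms))
        for k in range(5):
            shift = int(k * 20e-3 * rate)
            superposed[shift:] += single[:len(t_ms) - shift]
        expected = (superposed[int(80e-3 * rate):].max()) / single.max()
        assert subthreshold.temporal_summation(sweep) == pytest.approx(
            expected, rel=0.03)

    def test_ko_pt_summates_more_than_wt(self, wt_pt, ko_pt):
        s_wt = subthreshold.temporal_summation(protocols.run_epsc_train(wt_pt))
        s_ko = subthreshold.temporal_summation(protocols.run_epsc_train(ko_pt))
        assert s_ko > s_wt


class TestRestingPotential:
    def test_flat_trace_returns_its_level(self):
        sweep = make_sweep(np.zeros(10000), np.full(10000, -70.0), rate=10000.0)
        assert subthreshold.resting_potential(sweep) == pytest.approx(-70.0)

    def test_passive_model_rests_at_weighted_reversal(self):
        neuron = make_passive_neuron(E_leak=-62.0)
        sweep = protocols.run_resting(neuron)
        assert subthreshold.resting_potential(sweep) == pytest.approx(-62.0, abs=0.01)

    def test_ko_pt_more_hyperpolarized_than_wt(self, wt_pt, ko_pt):
        v_wt = subthreshold.resting_potential(protocols.run_resting(wt_pt))
        v_ko = subthreshold.resting_potential(protocols.run_resting(ko_pt))
        assert v_ko < v_wt


class TestZdPropertyPattern:
    def test_blocking_h_collapses_every_h_signature(self, wt_pt):
        # g_H -> 0: sag -> 1, rebound -> 0, f_R below the resonance cutoff,
        # and temporal summation increases
        blocked = simulate.apply_pharmacology(wt_pt, "ZD7288")
        steps_b = step_family(blocked)
        # the slow M-like delayed-rectifier gating leaves a small reverse
        # creep, so the blocked sag ratio sits within 5% of unity
        assert subthreshold.sag_ratio(steps_b) == pytest.approx(1.0, abs=0.05)
        assert subthreshold.rebound_slope(steps_b) == pytest.approx(0.0, abs=0.02)
        prof = subthreshold.zap_profile(protocols.run_chirp(blocked))
        assert prof.f_R_Hz <= 2.2
        s_ctrl = subthreshold.temporal_summation(protocols.run_epsc_train(wt_pt))
        s_block = subthreshold.temporal_summation(protocols.run_epsc_train(blocked))
        assert s_block > s_ctrl


class TestSamplingRateInvariance:
    def test_input_resistance_invariant_to_rate(self, passive_cell):
        r10, _ = subthreshold.input_resistance(
            protocols.run_step_family(passive_cell, sampling_rate_Hz=10000.0,
                                      amplitudes_pA=tuple(np.arange(-150.0, 11.0, 20.0))))
        r25, _ = subthreshold.input_resistance(
            protocols.run_step_family(passive_cell, sampling_rate_Hz=25000.0,
                                      amplitudes_pA=tuple(np.arange(-150.0, 11.0, 20.0))))
        assert r10 == pytest.approx(r25, rel=0.005)
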