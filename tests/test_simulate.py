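import numpy as np
import pytest
from scipy import signal

from fxsephys import presets, simulate, stimuli
from fxsephys.channels import ChannelSpec, CohortSpec, GateSpec, PatchSpec, TauSpec
from fxsephys.stimuli import ParameterError

from conftest import make_passive_neuron


class TestCurrentClamp:
    def test_passive_step_matches_rc_closed_form(self, passive_cell):
        # ΔV_ss = I·R and mono-exponential relaxation with τ = RC
        rate = 10000.0
        stim = stimuli.make_step(-100.0, 1000.0, rate)
        sw = simulate.simulate_current_clamp(
            passive_cell, stim, hold_at_mV=-65.0, sampling_rate_Hz=rate)
        base = sw.response[:1500].mean()
        ss = sw.response[10000:12000].mean()
        assert ss - base == pytest.approx(-100.0 * 0.1, rel=0.005)  # 100 MΩ
        # relaxation time constant RC = 20 ms from the 1/e point
        decay = sw.response[2000:8000] - (ss)
        frac = decay / decay[0]
        i_e = np.argmin(np.abs(frac - np.exp(-1)))
        assert i_e / rate * 1e3 == pytest.approx(20.0, rel=0.02)

    def test_holding_produces_flat_baseline(self, wt_pt):
        sw = simulate.simulate_current_clamp(
            wt_pt, np.zeros(5000), hold_at_mV=-65.0)
        assert np.max(np.abs(sw.response + 65.0)) < 0.1

    def test_wt_pt_sag_exceeds_ko_pt_sag(self, wt_pt, ko_pt):
        def sag(neuron):
            stim = stimuli.make_step(-150.0, 1000.0, 10000.0)
            v = simulate.simulate_current_clamp(neuron, stim).response
            base = v[:2000].mean()
            seg = v[2000:12000]
            return (base - seg.min()) / (base - seg[-2000:].mean())

        s_wt, s_ko = sag(wt_pt), sag(ko_pt)
        assert s_wt > s_ko > 1.0

    def test_halving_integration_step_changes_voltage_below_50uV(self, wt_pt):
        stim = stimuli.make_step(-150.0, 300.0, 10000.0, onset_ms=50, tail_ms=50)
        a = simulate.simulate_current_clamp(wt_pt, stim).response
        b = simulate.simulate_current_clamp(wt_pt, stim, max_dt_ms=0.0125).response
        assert np.max(np.abs(a - b)) < 0.05

    def test_blowup_reported_with_time(self, passive_cell):
        # an absurd current drives V past the ±200 mV guard
        with pytest.raises(simulate.IntegrationError, match="t ="):
            simulate.simulate_current_clamp(
                passive_cell, np.full(2000, 1e7), hold_at_mV=-65.0)

    def test_non_finite_stimulus_rejected(self, passive_cell):
        with pytest.raises(ParameterError):
            simulate.simulate_current_clamp(passive_cell, np.array([0.0, np.nan]))


class TestVoltageClampPatch:
    def test_k_sustained_steady_state_matches_gating_closed_form(self, quiet_patch):
        ch = presets.k_sustained_channel(0.5)
        cmd = stimuli.make_vc_segments([(-90.0, 100.0), (50.0, 300.0)], 10000.0)
        sw = simulate.simulate_voltage_clamp_patch([ch], quiet_patch, cmd,
                                                   area_cm2=1.5e-4)
        g_nS = 0.5 * 1.5e-4 * quiet_patch.area_fraction * 1e6
        gate = ch.activation[0][0]
        expected = g_nS * gate.x_inf(50.0) ** gate.exponent * (50.0 - ch.E_rev_mV)
        assert sw.response[-500:].mean() == pytest.approx(expected, rel=0.02)

    def test_zero_density_zero_noise_gives_identically_zero(self, quiet_patch):
        ch = presets.k_sustained_channel(0.0)
        cmd = stimuli.make_vc_segments([(-90.0, 50.0), (50.0, 50.0)], 10000.0)
        sw = simulate.simulate_voltage_clamp_patch([ch], quiet_patch, cmd)
        assert not np.any(sw.response)

    def test_isolated_currents_sum_to_multichannel_simulation(self, wt_pt, quiet_patch):
        from fxsephys.protocols import patch_channels

        chans, area = patch_channels(wt_pt, "soma")
        cmd = stimuli.make_vc_segments([(-90.0, 100.0), (50.0, 300.0)], 10000.0)
        total = np.zeros_like(cmd)
        for ch in chans:
            total += simulate.isolated_channel_current(ch, quiet_patch, cmd, area)
        sos = signal.butter(4, quiet_patch.filter_cutoff_Hz, btype="low",
                            fs=quiet_patch.sampling_rate_Hz, output="sos")
        sw = simulate.simulate_voltage_clamp_patch(chans, quiet_patch, cmd, area)
        np.testing.assert_allclose(sw.response, signal.sosfiltfilt(sos, total),
                                   atol=1e-9)

    def test_wt_pt_patch_shows_transient_plus_sustained(self, wt_pt, quiet_patch):
        from fxsephys.protocols import patch_channels

        chans, area = patch_channels(wt_pt, "soma")
        cmd = stimuli.make_vc_segments([(-90.0, 200.0), (50.0, 500.0)], 10000.0)
        sw = simulate.simulate_voltage_clamp_patch(chans, quiet_patch, cmd, area)
        step = sw.response[2000:]
        peak = step.max()
        late = step[-500:].mean()
        assert peak > 2.0 * late > 0.0  # decaying transient over a sustained floor

    def test_prepulse_selectively_inactivates_fast_component(self, wt_pt, quiet_patch):
        # −20 mV/100 ms prepulse: Kv4-like current nearly abolished, Kv1-like
        # current reduced by < 15% (gating-ODE oracle per channel)
        soma = wt_pt.compartment("soma")
        rate = quiet_patch.sampling_rate_Hz
        plain = stimuli.make_vc_segments([(-90.0, 200.0), (50.0, 300.0)], rate)
        prep = stimuli.make_vc_segments(
            [(-90.0, 100.0), (-20.0, 100.0), (50.0, 300.0)], rate)
        for name, max_reduction, min_reduction in (
            ("K_slow", 0.15, 0.0), ("KA_fast", 1.0, 0.85)):
            ch = soma.channel(name)
            a = simulate.isolated_channel_current(ch, quiet_patch, plain, soma.area_cm2)
            b = simulate.isolated_channel_current(ch, quiet_patch, prep, soma.area_cm2)
            peak_a = a[2000:2000 + 500].max()
            peak_b = b[2000:2000 + 500].max()
            reduction = 1.0 - peak_b / peak_a
            assert min_reduction <= reduction <= max_reduction


class TestSignConventions:
    def test_k_currents_outward_above_reversal_h_inward_below(self, wt_pt, quiet_patch):
        soma = wt_pt.compartment("soma")
        cmd = stimuli.make_vc_segments([(-90.0, 100.0), (-50.0, 200.0)], 10000.0)
        for ch in soma.channels:
            trace = simulate.isolated_channel_current(ch, quiet_patch, cmd,
                                                      soma.area_cm2)
            seg = trace[1200:]
            if ch.name.startswith("K"):
                assert np.all(seg >= -1e-9)  # V > E_K: outward
            if ch.name == "H":
                assert np.all(seg <= 1e-9)  # V < E_h: inward


class TestLinearizedImpedance:
    def test_matches_simulated_zap_within_5_percent(self, wt_pt):
        from fxsephys import protocols, subthreshold

        chirp = protocols.run_chirp(wt_pt, amplitude_pA=10.0)
        prof = subthreshold.zap_profile(chirp)
        z_lin = np.abs(simulate.linearized_impedance(
            wt_pt, "soma", prof.frequencies_Hz))
        band = (prof.frequencies_Hz >= 1.5) & (prof.frequencies_Hz <= 14.0)
        rel = np.abs(prof.impedance_MOhm[band] - z_lin[band]) / z_lin[band]
        assert np.median(rel) < 0.05
        f_lin = simulate.linearized_resonant_frequency(wt_pt)
        assert prof.f_R_Hz == pytest.approx(f_lin, abs=0.5)


class TestCohortSampling:
    def test_same_seed_reproduces_cohort_exactly(self):
        spec = CohortSpec("WT", "PT", 5, seed=42)
        a = presets.sample_cohort(spec)
        b = presets.sample_cohort(spec)
        for na, nb in zip(a, b):
            assert na == nb

    def test_different_seeds_differ(self):
        a = presets.sample_cohort(CohortSpec("WT", "PT", 3, seed=1))
        b = presets.sample_cohort(CohortSpec("WT", "PT", 3, seed=2))
        assert any(na != nb for na, nb in zip(a, b))

    def test_ko_scalings_applied_to_means(self):
        wt = presets.make_preset("WT", "PT").compartment("soma")
        ko = presets.make_preset("KO", "PT").compartment("soma")
        assert ko.channel("H").g_max_density == pytest.approx(
            0.6 * wt.channel("H").g_max_density)
        assert ko.channel("KA_fast").g_max_density == pytest.approx(
            1.35 * wt.channel("KA_fast").g_max_density)
        assert ko.channel("K_slow").g_max_density == pytest.approx(
            0.6 * wt.channel("K_slow").g_max_density)

    def test_dendritic_ka_shift_present_in_wt_absent_in_ko(self):
        wt = presets.make_preset("WT", "PT")
        ko = presets.make_preset("KO", "PT")

        def v_half(n, comp):
            return n.compartment(comp).channel("KA_fast").activation[0][0].V_half_mV

        assert v_half(wt, "dendrite") == pytest.approx(v_half(wt, "soma") - 8.0)
        assert v_half(ko, "dendrite") == pytest.approx(v_half(ko, "soma"))


class TestPharmacology:
    def test_zd7288_drives_sag_to_unity(self, wt_pt):
        blocked = simulate.apply_pharmacology(wt_pt, "ZD7288")
        stim = stimuli.make_step(-150.0, 1000.0, 10000.0)
        v = simulate.simulate_current_clamp(blocked, stim).response
        base = v[:2000].mean()
        seg = v[2000:12000]
        sag = (base - seg.min()) / (base - seg[-2000:].mean())
        assert sag == pytest.approx(1.0, abs=0.02)

    def test_drug_on_zero_density_channel_leaves_spec_unchanged(self, passive_cell):
        assert simulate.apply_pharmacology(passive_cell, "ZD7288") == passive_cell

    def test_unknown_drug_rejected(self, wt_pt):
        with pytest.raises(ParameterError, match="unknown drug"):
            simulate.apply_pharmacology(wt_pt, "TTX")


class TestEpscCalibration:
    def test_passive_cell_amplitude_matches_linear_oracle(self, passive_cell):
        # convolution oracle: peak of EPSC kernel * RC impulse response
        amp = simulate.calibrate_epsc_amplitude(passive_cell, target_mV=3.0)
        rate = 10000.0
        t_ms = np.arange(40000) / rate * 1e3
        kernel = stimuli.epsc_kernel(0.3, 4.0, t_ms)
        # RC impulse response: (1/C)·exp(-t/RC), R=100 MΩ, C=200 pF, τ=20 ms
        h = np.exp(-t_ms / 20.0) / 200.0 * (1e3 / rate)
        peak_per_pA = np.max(np.convolve(kernel, h)[:len(t_ms)])
        assert amp == pytest.approx(3.0 / peak_per_pA, rel=0.10)

    def test_zero_target_gives_zero_amplitude(self, passive_cell):
        assert simulate.calibrate_epsc_amplitude(passive_cell, target_mV=0.0) == 0.0

    def test_wt_pt_single_epsp_near_3mV(self, wt_pt):
        amp = simulate.calibrate_epsc_amplitude(wt_pt, target_mV=3.0)
        stim = stimuli.make_epsc_train(0.3, 4.0, 1, 10.0, amp, 10000.0,
                                       onset_ms=20.0, tail_ms=60.0)
        sw = simulate.simulate_current_clamp(wt_pt, stim)
        assert np.max(sw.response) + 65.0 == pytest.approx(3.0, abs=0.06)
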