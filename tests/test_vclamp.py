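import numpy as np
import pytest

from fxsephys import cohort, presets, protocols, simulate, stimuli, vclamp
from fxsephys.channels import PatchSpec
from fxsephys.trace_io import SweepSet, ValidationError

from conftest import make_sweep


def ohmic_sweep(hold, step_to, g_nS=1.0, E=-70.0, rate=10000.0,
                pre_ms=100.0, step_ms=300.0, post_ms=50.0):
    """Hand-built purely linear (leak-only) voltage-clamp sweep."""
    cmd = stimuli.make_vc_segments(
        [(hold, pre_ms), (step_to, step_ms), (hold, post_ms)], rate)
    resp = g_nS * (cmd - E)
    return make_sweep(cmd, resp, rate=rate, mode="voltage_clamp")


class TestLeakSubtract:
    def test_pure_linear_leak_cancels_exactly(self):
        test = ohmic_sweep(-90.0, 50.0)
        scaling = SweepSet((ohmic_sweep(-90.0, -95.0), ohmic_sweep(-90.0, -100.0)))
        corrected = vclamp.leak_subtract(test, scaling)
        assert np.max(np.abs(corrected)) < 1e-9

    def test_scaling_factor_ratio(self):
        assert vclamp.scaling_factor(140.0, -10.0) == pytest.approx(-14.0)
        with pytest.raises(ValidationError):
            vclamp.scaling_factor(140.0, 0.0)

    def test_leak_plus_channel_recovers_isolated_current(self, wt_pt, quiet_patch):
        # corrected steady current equals the isolated-channel oracle
        soma = wt_pt.compartment("soma")
        chans = [soma.channel("leak"), soma.channel("K_sustained")]
        rate = quiet_patch.sampling_rate_Hz
        cmd = stimuli.make_vc_segments([(-90.0, 100.0), (50.0, 400.0)], rate)
        sw = simulate.simulate_voltage_clamp_patch(chans, quiet_patch, cmd,
                                                   soma.area_cm2)
        scaling = SweepSet(tuple(
            simulate.simulate_voltage_clamp_patch(
                chans, quiet_patch,
                stimuli.make_vc_segments([(-90.0, 100.0), (-90.0 + dv, 100.0)], rate),
                soma.area_cm2)
            for dv in (-5.0, -10.0)))
        corrected = vclamp.leak_subtract(sw, scaling)
        oracle = simulate.isolated_channel_current(
            soma.channel("K_sustained"), quiet_patch, cmd, soma.area_cm2)
        assert corrected[-2000:].mean() == pytest.approx(
            oracle[-2000:].mean(), rel=0.02)


def decomposition_inputs(neuron, patch):
    prot = protocols.run_k_current_protocols(neuron, patch)
    return (cohort.leak_subtracted(prot, "total"),
            cohort.leak_subtracted(prot, "prepulsed"),
            cohort.leak_subtracted(prot, "sustained"))


class TestDecomposition:
    def test_sustained_only_patch_has_no_transient_components(self, quiet_patch):
        from conftest import make_passive_neuron
        from fxsephys.channels import CompartmentSpec, NeuronSpec

        comp = CompartmentSpec("soma", 1.5e-4, channels=(
            presets.leak_channel(0.01), presets.k_sustained_channel(0.2)))
        neuron = NeuronSpec((comp,), preset_id="sust-only")
        comps = vclamp.decompose_currents(*decomposition_inputs(neuron, quiet_patch))
        floor = 0.05 * comps.I_K_total.peak_pA
        assert comps.I_KA_fast.peak_pA <= floor
        assert comps.I_K_slow.peak_pA <= floor
        assert comps.I_K_sustained.peak_pA > 0

    def test_components_sum_to_total_exactly(self, wt_pt, quiet_patch):
        comps = vclamp.decompose_currents(*decomposition_inputs(wt_pt, quiet_patch))
        total = (comps.I_KA_fast.trace_pA + comps.I_K_slow.trace_pA
                 + comps.I_K_sustained.trace_pA)
        np.testing.assert_allclose(total, comps.I_K_total.trace_pA, atol=1e-9)

    def test_component_peaks_match_isolated_channel_oracle(self, wt_pt, quiet_patch):
        comps = vclamp.decompose_currents(*decomposition_inputs(wt_pt, quiet_patch))
        chans, area = protocols.patch_channels(wt_pt, "soma")
        rate = quiet_patch.sampling_rate_Hz
        cmd = stimuli.make_vc_segments(
            [(-90.0, 200.0), (50.0, 500.0), (-90.0, 100.0)], rate)
        on = 2000
        w = int(0.05 * rate)
        by_name = {c.name: c for c in chans}
        iso = {name: simulate.isolated_channel_current(by_name[name], quiet_patch,
                                                       cmd, area)
               for name in ("KA_fast", "K_slow", "K_sustained")}
        assert comps.I_KA_fast.peak_pA == pytest.approx(
            iso["KA_fast"][on:on + w].max(), rel=0.10)
        assert comps.I_K_slow.peak_pA == pytest.approx(
            iso["K_slow"][on:on + w].max(), rel=0.10)
        end = on + int(0.5 * rate)
        assert comps.I_K_sustained.peak_pA == pytest.approx(
            iso["K_sustained"][end - int(0.05 * rate):end].mean(), rel=0.10)

    def test_ko_shifts_fraction_balance_toward_fast(self, wt_pt, ko_pt, quiet_patch):
        f_wt = vclamp.decompose_currents(
            *decomposition_inputs(wt_pt, quiet_patch)).fractions
        f_ko = vclamp.decompose_currents(
            *decomposition_inputs(ko_pt, quiet_patch)).fractions
        assert f_ko["fast"] > f_wt["fast"]
        assert f_ko["slow"] < f_wt["slow"]


class TestExtrapolateSlowPeak:
    def test_synthetic_two_exponential_recovered_within_3_percent(self):
        rate = 10000.0
        t_ms = np.arange(9000) / rate * 1e3
        a_f, tau_f, a_s, tau_s = 900.0, 20.0, 400.0, 600.0
        trace = a_f * np.exp(-t_ms / tau_f) + a_s * np.exp(-t_ms / tau_s)
        got = vclamp.extrapolate_slow_peak(trace, rate, -30.0,
                                           fast_tau_estimate_ms=tau_f)
        assert got == pytest.approx(a_s, rel=0.03)

    def test_pure_fast_transient_extrapolates_to_near_zero(self):
        rate = 10000.0
        t_ms = np.arange(5000) / rate * 1e3
        trace = 800.0 * np.exp(-t_ms / 20.0)
        got = vclamp.extrapolate_slow_peak(trace, rate, -30.0,
                                           fast_tau_estimate_ms=20.0)
        assert abs(got) < 0.05 * 800.0

    def test_extrapolation_agrees_with_direct_prepulse_measurement(
            self, wt_pt, quiet_patch):
        # the package's internal validation: back-extrapolated slow peak vs
        # the slowly inactivating current measured directly via the prepulse;
        # long (1.5 s) steps so the decay window spans the slow tau
        prot = protocols.run_k_current_protocols(wt_pt, quiet_patch, step_ms=1500.0)
        total_ls = cohort.leak_subtracted(prot, "total")
        prep_ls = cohort.leak_subtracted(prot, "prepulsed")
        sust_ls = cohort.leak_subtracted(prot, "sustained")
        comps = vclamp.decompose_currents(total_ls, prep_ls, sust_ls)
        rate = quiet_patch.sampling_rate_Hz
        total_avg = total_ls[0]
        on = np.flatnonzero(np.abs(total_avg.stimulus - 50.0) < 0.5)[0]
        seg = total_avg.response[on:]
        slow_extrap = vclamp.extrapolate_slow_peak(seg, rate, -30.0,
                                                   fast_tau_estimate_ms=26.0)
        direct = comps.I_K_slow.peak_pA + comps.I_K_sustained.peak_pA
        assert slow_extrap == pytest.approx(direct, rel=0.05)


class TestActivationCurve:
    def test_noise_free_boltzmann_recovered_exactly(self):
        # self-consistency: data generated from a Boltzmann conductance
        rate = 10000.0
        v_half, k, gmax = -30.0, 8.0, 5.0  # nS
        sweeps = []
        for v in np.arange(-70.0, 51.0, 20.0):
            cmd = stimuli.make_vc_segments([(-90.0, 100.0), (v, 400.0)], rate)
            g = gmax / (1.0 + np.exp(-(v - v_half) / k))
            resp = np.zeros_like(cmd)
            resp[1000:] = g * (v + 96.0) * 1e-3 * 1e3  # nS·mV = pA
            sweeps.append(make_sweep(cmd, resp, rate=rate, mode="voltage_clamp"))
        fit = vclamp.activation_curve(SweepSet(tuple(sweeps)), component="total")
        assert fit.V_half_mV == pytest.approx(v_half, abs=0.1)
        assert fit.k_mV == pytest.approx(k, rel=0.01)
        assert fit.G_max_nS == pytest.approx(gmax, rel=0.01)

    def test_dendritic_shift_present_in_wt_absent_in_ko(self, wt_pt, ko_pt,
                                                        quiet_patch):
        def v_half(neuron, site):
            fam = protocols.run_activation_family(neuron, quiet_patch, site=site)
            return vclamp.activation_curve(fam).V_half_mV

        wt_shift = v_half(wt_pt, "dendrite") - v_half(wt_pt, "soma")
        ko_shift = v_half(ko_pt, "dendrite") - v_half(ko_pt, "soma")
        # the fitted shift is attenuated relative to the -8 mV gate shift by
        # the kinetic overlap of the components; the direction is unambiguous
        assert wt_shift < -3.0       # hyperpolarized in the WT dendrite
        assert abs(ko_shift) < 1.5   # no soma-dendrite shift in KO

    def test_too_few_measurable_voltages_rejected(self):
        rate = 10000.0
        sweeps = []
        for v in (-70.0, -50.0, -30.0):
            cmd = stimuli.make_vc_segments([(-90.0, 50.0), (v, 100.0)], rate)
            sweeps.append(make_sweep(cmd, np.zeros_like(cmd), rate=rate,
                                     mode="voltage_clamp"))
        with pytest.raises(vclamp.InsufficientDataError):
            vclamp.activation_curve(SweepSet(tuple(sweeps)), component="total")


class TestInactivationKinetics:
    def test_ka_fast_decay_matches_gate_tau(self, wt_pt, quiet_patch):
        soma = wt_pt.compartment("soma")
        ch = soma.channel("KA_fast")
        cmd = stimuli.make_vc_segments([(-90.0, 100.0), (50.0, 400.0)], 10000.0)
        trace = simulate.isolated_channel_current(ch, quiet_patch, cmd,
                                                  soma.area_cm2)
        fit = vclamp.inactivation_tau(trace[1000:], 10000.0)
        assert fit.taus_ms[0] == pytest.approx(26.0, rel=0.10)

    def test_k_slow_inactivates_an_order_of_magnitude_slower(self, wt_pt,
                                                             quiet_patch):
        soma = wt_pt.compartment("soma")
        rate = 10000.0
        cmd = stimuli.make_vc_segments([(-90.0, 100.0), (50.0, 2000.0)], rate)
        taus = {}
        for name in ("KA_fast", "K_slow"):
            trace = simulate.isolated_channel_current(
                soma.channel(name), quiet_patch, cmd, soma.area_cm2)
            taus[name] = vclamp.inactivation_tau(trace[1000:], rate).taus_ms[0]
        assert taus["K_slow"] > 8.0 * taus["KA_fast"]

    def test_non_inactivating_trace_flags_no_decay(self, wt_pt, quiet_patch):
        soma = wt_pt.compartment("soma")
        cmd = stimuli.make_vc_segments([(-90.0, 100.0), (50.0, 500.0)], 10000.0)
        trace = simulate.isolated_channel_current(
            soma.channel("K_sustained"), quiet_patch, cmd, soma.area_cm2)
        fit = vclamp.inactivation_tau(trace[1000:], 10000.0)
        assert np.isinf(fit.taus_ms[0])


class TestRecoveryFromInactivation:
    def test_two_channel_recovery_taus_within_15_percent(self, wt_pt, quiet_patch):
        sweeps = protocols.run_recovery_protocol(wt_pt, quiet_patch)
        fracs = vclamp.recovery_fractions(
            sweeps, protocols.DEFAULT_RECOVERY_INTERVALS_MS)
        fit = vclamp.recovery_from_inactivation(
            fracs, protocols.DEFAULT_RECOVERY_INTERVALS_MS)
        # recovery at -90 mV is governed by the gate taus: 26 ms (Kv4-like)
        # and 646 ms (Kv1-like), an order of magnitude apart
        assert fit.taus_ms[0] == pytest.approx(26.0, rel=0.15)
        assert fit.taus_ms[1] == pytest.approx(646.0, rel=0.15)
        assert fit.taus_ms[1] > 8.0 * fit.taus_ms[0]

    def test_long_interval_recovers_fully(self, wt_pt, quiet_patch):
        sweeps = protocols.run_recovery_protocol(wt_pt, quiet_patch,
                                                 intervals_ms=(5000.0,))
        fracs = vclamp.recovery_fractions(sweeps, (5000.0,))
        assert fracs[0] == pytest.approx(1.0, abs=0.02)


class TestIhStep:
    def test_known_two_component_taus_recovered(self, wt_pt, quiet_patch):
        sweep = protocols.run_ih_step(wt_pt, quiet_patch, site="dendrite")
        m = vclamp.ih_step_analysis(sweep)
        assert m.I_h_max_pA < 0
        assert m.tau_fast_ms == pytest.approx(30.0, rel=0.10)
        assert m.tau_slow_ms == pytest.approx(200.0, rel=0.10)
        assert m.fraction_fast == pytest.approx(0.65, abs=0.05)

    def test_zero_h_density_gives_zero_amplitude(self, quiet_patch):
        from fxsephys.channels import CompartmentSpec, NeuronSpec

        comp = CompartmentSpec("dendrite", 1e-4, channels=(
            presets.leak_channel(0.0), presets.h_channel(0.0)))
        neuron = NeuronSpec((comp,), preset_id="no-h")
        sweep = protocols.run_ih_step(neuron, quiet_patch, site="dendrite")
        m = vclamp.ih_step_analysis(sweep)
        assert abs(m.I_h_max_pA) < 1e-6

    def test_ko_dendritic_h_current_smaller_than_wt(self, wt_pt, ko_pt, quiet_patch):
        m_wt = vclamp.ih_step_analysis(
            protocols.run_ih_step(wt_pt, quiet_patch, site="dendrite"))
        m_ko = vclamp.ih_step_analysis(
            protocols.run_ih_step(ko_pt, quiet_patch, site="dendrite"))
        assert abs(m_ko.I_h_max_pA) < abs(m_wt.I_h_max_pA)


class TestDrugSubtraction:
    def test_identical_before_after_gives_zero_trace(self, wt_pt, quiet_patch):
        prot = protocols.run_k_current_protocols(wt_pt, quiet_patch)
        before = prot["total"]
        diff, peak = vclamp.drug_subtraction(before, before)
        assert np.max(np.abs(diff)) < 1e-12

    @pytest.mark.parametrize("drug,channel,block_frac,tol", [
        ("aDTX_200nM", "K_slow", 0.9, 0.15),
        ("Ba_150uM", "KA_fast", 0.8, 0.15),
    ])
    def test_drug_sensitive_current_matches_blocked_fraction_of_oracle(
            self, wt_pt, quiet_patch, drug, channel, block_frac, tol):
        after_neuron = simulate.apply_pharmacology(wt_pt, drug)
        before = protocols.run_k_current_protocols(wt_pt, quiet_patch)["total"]
        after = protocols.run_k_current_protocols(after_neuron, quiet_patch)["total"]
        diff, peak = vclamp.drug_subtraction(before, after)
        soma = wt_pt.compartment("soma")
        cmd = before[0].stimulus
        iso = simulate.isolated_channel_current(
            soma.channel(channel), quiet_patch, cmd, soma.area_cm2)
        on = np.flatnonzero(np.abs(cmd - 50.0) < 0.5)[0]
        w = int(0.05 * quiet_patch.sampling_rate_Hz)
        assert peak == pytest.approx(block_frac * iso[on:on + w].max(), rel=tol)
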