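"""Genotype × projection-class neuron presets and cohort sampling.

The presets are calibration fixtures: the study they emulate reports cohort
statistics (input resistance, resonant frequency, resting potential,
K⁺-current component fractions) but no absolute conductance densities or
patch areas, so densities here were tuned once so that preset cohort means
land near the printed values, then frozen.  Direction-of-effect structure
between genotypes:

* KO (fmr1-/y) PT: g_H × 0.6, g_KA_fast × 1.35, g_K_slow × 0.6 relative to
  WT PT, and a faster slow-current inactivation (τ ≈ 244 ms vs ≈ 646 ms).
* KO PT dendrite: the ~8 mV soma→dendrite hyperpolarizing shift of the fast
  A-type activation V½ present in WT is absent (dendritic V½ = somatic).
* IT presets are identical across genotypes except a small leak reversal
  shift that reproduces the hyperpolarized KO resting potential.

Channel complement: soma — leak, H, KA_fast (Kv4-like), K_slow (Kv1-like),
K_sustained, NaT, K_DR; dendrite (PT only) — leak, H, KA_fast.  The h-current
density increases linearly with distance from the soma.
"""

from __future__ import annotations

import numpy as np

from .channels import (
    ChannelSpec,
    CohortSpec,
    CompartmentSpec,
    GateSpec,
    NeuronSpec,
    PatchSpec,
    TauSpec,
)
from .stimuli import ParameterError

# Reversal potentials (mV); configurable by constructing channels directly.
E_K = -96.0
E_NA = 55.0
E_H = -30.0
E_LEAK = -70.0
E_LEAK_PT = -78.0

SOMA_AREA_CM2 = 1.5e-4     # ~150 pF soma
DEND_AREA_CM2 = 1.0e-4
IT_SOMA_AREA_CM2 = 1.2e-4
COUPLING_NS = 6.5
DEFAULT_DENDRITE_DISTANCE_UM = 300.0
H_GRADIENT_PER_UM = 0.004  # fractional g_H increase per µm from the soma

PRESET_IDS = ("wt-pt", "ko-pt", "wt-it", "ko-it")


def dendritic_h_density(soma_density: float, distance_um: float,
                        slope_per_um: float = H_GRADIENT_PER_UM) -> float:
    """Linear distance gradient of h-conductance density."""
    return soma_density * (1.0 + slope_per_um * distance_um)


# -- channel factories -------------------------------------------------------

def leak_channel(density: float, E_rev_mV: float = E_LEAK) -> ChannelSpec:
    return ChannelSpec("leak", E_rev_mV, density)


def h_channel(density: float) -> ChannelSpec:
    """Hyperpolarization-activated cation current with double-exponential
    activation (fast/slow component fractions 0.65/0.35)."""
    gate_f = GateSpec(-78.0, -9.0, TauSpec(30.0))
    gate_s = GateSpec(-78.0, -9.0, TauSpec(200.0))
    return ChannelSpec("H", E_H, density, activation=[(gate_f, 0.65), (gate_s, 0.35)])


def ka_fast_channel(density: float, V_half_act: float = -34.0,
                    tau_inact_ms: float = 26.0) -> ChannelSpec:
    """Rapidly inactivating Kv4-like A-type current."""
    return ChannelSpec(
        "KA_fast", E_K, density,
        activation=GateSpec(V_half_act, 3.0, TauSpec(1.5)),
        inactivation_components=[(GateSpec(-66.0, -6.0, TauSpec(tau_inact_ms)), 1.0)],
    )


def k_slow_channel(density: float, tau_inact: TauSpec | float = 646.0) -> ChannelSpec:
    """Slowly inactivating Kv1-like current (4-AP/α-DTX-sensitive).

    ``tau_inact`` may be a constant (ms) or a TauSpec; the KO preset uses a
    bell-shaped τ (fast at depolarized commands, slow near the prepulse
    range) reflecting its accelerated inactivation at test potentials.
    """
    if isinstance(tau_inact, (int, float)):
        tau_inact = TauSpec(float(tau_inact))
    return ChannelSpec(
        "K_slow", E_K, density,
        activation=GateSpec(-45.0, 2.0, TauSpec(3.0, 25.0, -44.0, 10.0)),
        inactivation_components=[(GateSpec(-60.0, -7.0, tau_inact), 1.0)],
    )


def k_sustained_channel(density: float) -> ChannelSpec:
    return ChannelSpec(
        "K_sustained", E_K, density,
        activation=GateSpec(10.0, 7.0, TauSpec(4.0)),
    )


def nat_channel(density: float) -> ChannelSpec:
    return ChannelSpec(
        "NaT", E_NA, density,
        activation=GateSpec(-35.0, 5.5, TauSpec(0.1), exponent=3),
        inactivation_components=[
            (GateSpec(-40.0, -5.0, TauSpec(1.5, 60.0, -55.0, 18.0)), 1.0)
        ],
    )


def k_dr_channel(density: float, slow_gating: bool = True) -> ChannelSpec:
    """Delayed rectifier (axon-initial-segment complement, absent from
    excised somatic patches).  In PT neurons it carries a slow M-like gating
    component near rest that contributes genotype-independent theta-band
    resonance; the IT preset uses the fast-only variant (IT neurons are
    non-resonant)."""
    tau = TauSpec(1.5, 40.0, -50.0, 30.0) if slow_gating else TauSpec(1.5)
    return ChannelSpec(
        "K_DR", E_K, density,
        activation=GateSpec(-12.0, 6.0, tau),
    )


# -- calibrated densities (mS/cm²) -------------------------------------------

PT_SOMA_DENSITIES = {
    "leak": 0.034,
    "H": 0.028,
    "KA_fast": 1.3,
    "K_slow": 1.35,
    "K_sustained": 0.15,
    "NaT": 25.0,
    "K_DR": 6.0,
}

IT_SOMA_DENSITIES = {
    "leak": 0.055,
    "H": 0.008,
    "KA_fast": 1.3,
    "K_slow": 1.35,
    "K_sustained": 0.15,
    "NaT": 25.0,
    "K_DR": 6.0,
}

KO_PT_SCALING = {"H": 0.6, "KA_fast": 1.35, "K_slow": 0.6}
KO_PT_KSLOW_TAU_INACT = TauSpec(244.0, 652.0, -30.0, 30.0)
WT_PT_KSLOW_TAU_INACT = TauSpec(646.0)
WT_DENDRITIC_KA_SHIFT_MV = -8.0
KO_IT_LEAK_SHIFT_MV = -3.5

DEND_KA_DENSITY = 0.8
DEND_KSLOW_DENSITY = 0.45
DEND_KSUST_DENSITY = 0.05


def _pt_soma_channels(genotype: str) -> list:
    scale = KO_PT_SCALING if genotype == "KO" else {}
    d = {k: v * scale.get(k, 1.0) for k, v in PT_SOMA_DENSITIES.items()}
    tau_ks = KO_PT_KSLOW_TAU_INACT if genotype == "KO" else WT_PT_KSLOW_TAU_INACT
    return [
        leak_channel(d["leak"], E_rev_mV=E_LEAK_PT),
        h_channel(d["H"]),
        ka_fast_channel(d["KA_fast"]),
        k_slow_channel(d["K_slow"], tau_inact=tau_ks),
        k_sustained_channel(d["K_sustained"]),
        nat_channel(d["NaT"]),
        k_dr_channel(d["K_DR"]),
    ]


def _pt_dendrite_channels(genotype: str, distance_um: float) -> list:
    h_scale = KO_PT_SCALING["H"] if genotype == "KO" else 1.0
    g_h = dendritic_h_density(PT_SOMA_DENSITIES["H"], distance_um) * h_scale
    V_half_ka = -34.0 + (0.0 if genotype == "KO" else WT_DENDRITIC_KA_SHIFT_MV)
    # dendritic K currents carry no genotype differences (somatic phenotype)
    return [
        leak_channel(0.015, E_rev_mV=E_LEAK_PT),
        h_channel(g_h),
        ka_fast_channel(DEND_KA_DENSITY, V_half_act=V_half_ka),
        k_slow_channel(DEND_KSLOW_DENSITY, tau_inact=WT_PT_KSLOW_TAU_INACT),
        k_sustained_channel(DEND_KSUST_DENSITY),
    ]


def make_preset(
    genotype: str,
    projection_class: str,
    dendrite_distance_um: float = DEFAULT_DENDRITE_DISTANCE_UM,
) -> NeuronSpec:
    """Construct the preset neuron for one genotype × projection class."""
    if genotype not in ("WT", "KO"):
        raise ParameterError(f"unknown genotype {genotype!r}")
    preset_id = f"{genotype.lower()}-{projection_class.lower()}"
    if projection_class == "PT":
        soma = CompartmentSpec(
            "soma", SOMA_AREA_CM2, channels=_pt_soma_channels(genotype),
            coupling_nS=COUPLING_NS,
        )
        dend = CompartmentSpec(
            "dendrite", DEND_AREA_CM2,
            channels=_pt_dendrite_channels(genotype, dendrite_distance_um),
            coupling_nS=COUPLING_NS,
        )
        neuron = NeuronSpec((soma, dend), preset_id=preset_id)
    elif projection_class == "IT":
        E_l = E_LEAK + (KO_IT_LEAK_SHIFT_MV if genotype == "KO" else 0.0)
        d = IT_SOMA_DENSITIES
        channels = [
            leak_channel(d["leak"], E_rev_mV=E_l),
            h_channel(d["H"]),
            ka_fast_channel(d["KA_fast"]),
            k_slow_channel(d["K_slow"]),
            k_sustained_channel(d["K_sustained"]),
            nat_channel(d["NaT"]),
            k_dr_channel(d["K_DR"], slow_gating=False),
        ]
        soma = CompartmentSpec("soma", IT_SOMA_AREA_CM2, channels=channels)
        neuron = NeuronSpec((soma,), preset_id=preset_id)
    else:
        raise ParameterError(f"unknown projection class {projection_class!r}")
    neuron.validate()
    return neuron


def get_preset(preset_id: str) -> NeuronSpec:
    mapping = {
        "wt-pt": ("WT", "PT"),
        "ko-pt": ("KO", "PT"),
        "wt-it": ("WT", "IT"),
        "ko-it": ("KO", "IT"),
    }
    if preset_id not in mapping:
        raise ParameterError(f"unknown preset {preset_id!r}; known: {sorted(mapping)}")
    return make_preset(*mapping[preset_id])


DEFAULT_DENSITY_CV = 0.15
DEFAULT_CHANNEL_CVS = {
    # spike-machinery densities are tightly co-regulated across cells
    # (threshold homeostasis); passive and modulated conductances vary more
    "NaT": 0.03,
    "K_DR": 0.05,
    "leak": 0.08,
}


def sample_cohort(spec: CohortSpec) -> list:
    """Draw ``n_cells`` neurons around the preset with lognormal density
    variability (mean-preserving), one multiplier per channel name per cell
    so somatic and dendritic copies of a channel co-vary.

    A pure function of (spec, seed)."""
    spec.validate()
    preset = make_preset(spec.genotype, spec.projection_class)
    rng = np.random.default_rng(spec.seed)
    names = sorted({ch.name for c in preset.compartments for ch in c.channels})
    cohort = []
    for i in range(spec.n_cells):
        mult = {}
        for name in names:
            cv = spec.cv_per_density.get(
                name, DEFAULT_CHANNEL_CVS.get(name, DEFAULT_DENSITY_CV)
            )
            if cv == 0:
                mult[name] = 1.0
            else:
                sigma = np.sqrt(np.log1p(cv * cv))
                mult[name] = float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))
        cell = preset.map_channels(lambda ch: ch.scaled(mult[ch.name]))
        cell = NeuronSpec(
            cell.compartments,
            preset_id=f"{preset.preset_id}-{i:03d}",
            bias_current_pA=cell.bias_current_pA,
        )
        cohort.append(cell)
    return cohort


def default_patch(seed: int = 0, noise_pA_sd: float = 2.0) -> PatchSpec:
    return PatchSpec(area_fraction=0.03, noise_pA_sd=noise_pA_sd, seed=seed)


__all__ = [
    "E_K", "E_NA", "E_H", "E_LEAK",
    "PRESET_IDS",
    "make_preset", "get_preset", "sample_cohort", "default_patch",
    "dendritic_h_density",
    "leak_channel", "h_channel", "ka_fast_channel", "k_slow_channel",
    "k_sustained_channel", "nat_channel", "k_dr_channel",
    "PT_SOMA_DENSITIES", "IT_SOMA_DENSITIES", "KO_PT_SCALING",
    "SOMA_AREA_CM2", "DEND_AREA_CM2", "IT_SOMA_AREA_CM2",
    "DEFAULT_DENSITY_CV", "DEFAULT_CHANNEL_CVS",
]
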