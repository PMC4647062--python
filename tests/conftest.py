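import numpy as np
import pytest

from fxsephys import presets
from fxsephys.channels import (
    ChannelSpec,
    CompartmentSpec,
    GateSpec,
    NeuronSpec,
    PatchSpec,
    TauSpec,
)
from fxsephys.trace_io import ProtocolDescriptor, RecordingMetadata, Sweep, SweepSet


def make_passive_neuron(R_MOhm=100.0, C_pF=200.0, E_leak=-65.0):
    """Single-compartment leak-only cell with exact R and C."""
    area = C_pF * 1e-6  # Cm = 1 µF/cm²
    g_nS = 1e3 / R_MOhm
    density = g_nS / (area * 1e6)  # mS/cm²
    comp = CompartmentSpec(
        "soma", area, channels=(ChannelSpec("leak", E_leak, density),)
    )
    return NeuronSpec((comp,), preset_id="passive")


def make_two_compartment_passive(R1=100.0, C1=150.0, R2=200.0, C2=100.0,
                                 gc_nS=5.0, E_leak=-65.0):
    a1, a2 = C1 * 1e-6, C2 * 1e-6
    soma = CompartmentSpec(
        "soma", a1,
        channels=(ChannelSpec("leak", E_leak, (1e3 / R1) / (a1 * 1e6)),),
        coupling_nS=gc_nS,
    )
    dend = CompartmentSpec(
        "dendrite", a2,
        channels=(ChannelSpec("leak", E_leak, (1e3 / R2) / (a2 * 1e6)),),
        coupling_nS=gc_nS,
    )
    return NeuronSpec((soma, dend), preset_id="passive-2c")


@pytest.fixture(scope="session")
def passive_cell():
    return make_passive_neuron()


@pytest.fixture(scope="session")
def wt_pt():
    return presets.get_preset("wt-pt")


@pytest.fixture(scope="session")
def ko_pt():
    return presets.get_preset("ko-pt")


@pytest.fixture(scope="session")
def quiet_patch():
    return PatchSpec(area_fraction=0.03, noise_pA_sd=0.0)


def make_sweep(stimulus, response, rate=10000.0, mode="current_clamp",
               cell_id="cell-0", protocol=None, **md_kwargs):
    return Sweep(
        sampling_rate_Hz=rate,
        mode=mode,
        stimulus=np.asarray(stimulus, float),
        response=np.asarray(response, float),
        metadata=RecordingMetadata(cell_id=cell_id, **md_kwargs),
        protocol=protocol or ProtocolDescriptor(kind="custom"),
    )


@pytest.fixture
def tiny_sweepset():
    rate = 1000.0
    sweeps = []
    rng = np.random.default_rng(0)
    for i in range(2):
        stim = np.zeros(50)
        stim[10:30] = -50.0 * (i + 1)
        resp = -65.0 + rng.normal(0, 0.1, 50)
        sweeps.append(make_sweep(stim, resp, rate=rate, cell_id="cell-A"))
    return SweepSet(tuple(sweeps), protocol_id="demo")
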