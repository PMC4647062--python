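"""Conductance-based model description: gates, channels, compartments.

Gating follows the Hodgkin–Huxley first-order formalism with Boltzmann
steady states:

    x_inf(V) = 1 / (1 + exp(-(V - V_half) / k))

A positive slope ``k`` gives a gate that opens with depolarization
(activation); a negative ``k`` gives a gate that closes with depolarization
(inactivation, or the hyperpolarization-activated h-gate).  Time constants
are either voltage-independent or bell-shaped:

    tau(V) = tau_min + (tau_max - tau_min) * exp(-((V - V_peak) / width)^2)

Channels may carry several parallel gate components (fractions summing to 1)
to represent multi-exponential kinetics, e.g. the double-exponential
activation of the h-current.

Units: potentials mV, time constants ms, densities mS/cm², areas cm²,
capacitance µF/cm².  Absolute conductances derived from densities are in nS
(density mS/cm² × area cm² × 1e6), so that g[nS] · V[mV] = I[pA] and
C[pF] · dV/dt[mV/ms] = I[pA].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .trace_io import ValidationError


@dataclass(frozen=True)
class TauSpec:
    """Voltage dependence of a gate time constant (ms)."""

    tau_min_ms: float
    tau_max_ms: float | None = None  # None -> constant tau_min
    V_peak_mV: float = -60.0
    width_mV: float = 20.0

    def __call__(self, V):
        if self.tau_max_ms is None:
            return np.broadcast_to(self.tau_min_ms, np.shape(V)).astype(float) \
                if np.ndim(V) else float(self.tau_min_ms)
        return self.tau_min_ms + (self.tau_max_ms - self.tau_min_ms) * np.exp(
            -(((np.asarray(V, dtype=float) - self.V_peak_mV) / self.width_mV) ** 2)
        )

    def validate(self):
        if self.tau_min_ms <= 0:
            raise ValidationError("tau_min_ms must be > 0")
        if self.tau_max_ms is not None and self.tau_max_ms <= 0:
            raise ValidationError("tau_max_ms must be > 0")
        if self.tau_max_ms is not None and self.width_mV <= 0:
            raise ValidationError("width_mV must be > 0")


@dataclass(frozen=True)
class GateSpec:
    V_half_mV: float
    k_mV: float
    tau_ms: TauSpec = field(default_factory=lambda: TauSpec(1.0))
    exponent: int = 1

    def __post_init__(self):
        if isinstance(self.tau_ms, (int, float)):
            object.__setattr__(self, "tau_ms", TauSpec(float(self.tau_ms)))

    def x_inf(self, V):
        return 1.0 / (1.0 + np.exp(-(np.asarray(V, dtype=float) - self.V_half_mV) / self.k_mV))

    def dxinf_dV(self, V):
        x = self.x_inf(V)
        return x * (1.0 - x) / self.k_mV

    def tau(self, V):
        return self.tau_ms(V)

    def validate(self):
        if self.k_mV == 0:
            raise ValidationError("Boltzmann slope k must be nonzero")
        if self.exponent < 1:
            raise ValidationError("gate exponent must be >= 1")
        self.tau_ms.validate()


def _normalize_components(spec, what: str):
    """Normalize GateSpec | [(GateSpec, fraction), ...] | None to a tuple."""
    if spec is None:
        return ()
    if isinstance(spec, GateSpec):
        return ((spec, 1.0),)
    comps = tuple((g, float(f)) for g, f in spec)
    if comps:
        total = sum(f for _, f in comps)
        if not np.isclose(total, 1.0):
            raise ValidationError(f"{what} fractions must sum to 1 (got {total})")
        for g, f in comps:
            if not (0.0 < f <= 1.0):
                raise ValidationError(f"{what} fractions must lie in (0, 1]")
    return comps


CHANNEL_NAMES = ("leak", "H", "KA_fast", "K_slow", "K_sustained", "NaT", "K_DR")


@dataclass(frozen=True)
class ChannelSpec:
    """One conductance: reversal, maximal density and its gates.

    ``activation`` may be a single :class:`GateSpec` or a list of
    ``(GateSpec, fraction)`` components (parallel activation populations with
    fractions summing to 1 — used for the double-exponential h-current
    activation).  ``inactivation_components`` likewise.
    """

    name: str
    E_rev_mV: float
    g_max_density: float  # mS/cm²
    activation: object = None
    inactivation_components: Sequence = ()

    def __post_init__(self):
        object.__setattr__(self, "activation", _normalize_components(self.activation, "activation"))
        object.__setattr__(
            self,
            "inactivation_components",
            _normalize_components(self.inactivation_components, "inactivation"),
        )

    def validate(self):
        if self.g_max_density < 0:
            raise ValidationError("g_max_density must be non-negative")
        if not np.isfinite(self.E_rev_mV):
            raise ValidationError("reversal potential must be finite")
        if self.name == "leak" and (self.activation or self.inactivation_components):
            raise ValidationError("leak channel must have no gates")
        if len(self.activation) > 1:
            for g, _ in self.activation:
                if g.exponent != 1:
                    raise ValidationError(
                        "multi-component activation requires gate exponent 1"
                    )
        for g, _ in tuple(self.activation) + tuple(self.inactivation_components):
            g.validate()

    # -- steady-state helpers ------------------------------------------------

    def open_fraction_inf(self, V) -> float:
        """Steady-state open probability (product of activation^p and the
        fraction-weighted inactivation) at voltage V."""
        out = 1.0
        if self.activation:
            if len(self.activation) == 1:
                g, _ = self.activation[0]
                out *= g.x_inf(V) ** g.exponent
            else:
                out *= sum(f * g.x_inf(V) for g, f in self.activation)
        if self.inactivation_components:
            out *= sum(f * g.x_inf(V) for g, f in self.inactivation_components)
        return out

    def current_inf(self, V, g_nS: float) -> float:
        """Steady-state current (pA) through absolute conductance g_nS at V."""
        return g_nS * self.open_fraction_inf(V) * (V - self.E_rev_mV)

    def scaled(self, factor: float) -> "ChannelSpec":
        return replace(self, g_max_density=self.g_max_density * factor)


@dataclass(frozen=True)
class CompartmentSpec:
    name: str
    area_cm2: float
    Cm_uF_per_cm2: float = 1.0
    channels: tuple = ()
    coupling_nS: float = 0.0  # to the other compartment; 0 for single-compartment

    def __post_init__(self):
        object.__setattr__(self, "channels", tuple(self.channels))

    def validate(self):
        if self.name not in ("soma", "dendrite"):
            raise ValidationError("compartment name must be 'soma' or 'dendrite'")
        if self.area_cm2 <= 0 or self.Cm_uF_per_cm2 <= 0:
            raise ValidationError("area and Cm must be positive")
        if self.coupling_nS < 0:
            raise ValidationError("coupling_nS must be non-negative")
        for ch in self.channels:
            ch.validate()

    @property
    def C_pF(self) -> float:
        return self.Cm_uF_per_cm2 * self.area_cm2 * 1e6

    def g_nS(self, channel: ChannelSpec) -> float:
        return channel.g_max_density * self.area_cm2 * 1e6

    def channel(self, name: str) -> ChannelSpec:
        for ch in self.channels:
            if ch.name == name:
                return ch
        raise KeyError(f"compartment {self.name!r} has no channel {name!r}")


@dataclass(frozen=True)
class NeuronSpec:
    compartments: tuple
    preset_id: str | None = None
    bias_current_pA: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "compartments", tuple(self.compartments))

    def validate(self):
        if not (1 <= len(self.compartments) <= 2):
            raise ValidationError("NeuronSpec needs 1 or 2 compartments")
        names = [c.name for c in self.compartments]
        if len(set(names)) != len(names):
            raise ValidationError("compartment names must be distinct")
        if len(self.compartments) == 2:
            c0, c1 = self.compartments
            if not np.isclose(c0.coupling_nS, c1.coupling_nS):
                raise ValidationError("coupling must be symmetric between compartments")
        for c in self.compartments:
            c.validate()

    def compartment(self, name: str) -> CompartmentSpec:
        for c in self.compartments:
            if c.name == name:
                return c
        raise KeyError(f"neuron has no compartment {name!r}")

    def compartment_index(self, name: str) -> int:
        for i, c in enumerate(self.compartments):
            if c.name == name:
                return i
        raise KeyError(f"neuron has no compartment {name!r}")

    def map_channels(self, fn) -> "NeuronSpec":
        """Return a copy with ``fn(channel) -> channel`` applied everywhere."""
        comps = tuple(
            replace(c, channels=tuple(fn(ch) for ch in c.channels))
            for c in self.compartments
        )
        return replace(self, compartments=comps)


@dataclass(frozen=True)
class PatchSpec:
    """Outside-out patch: a scaled-down piece of membrane under perfect clamp."""

    area_fraction: float = 0.01
    noise_pA_sd: float = 0.0
    filter_cutoff_Hz: float = 2000.0
    sampling_rate_Hz: float = 10000.0
    seed: int = 0

    def validate(self):
        if not (0.0 < self.area_fraction <= 1.0):
            raise ValidationError("area_fraction must be in (0, 1]")
        if self.noise_pA_sd < 0:
            raise ValidationError("noise_pA_sd must be >= 0")
        if not (0 < self.filter_cutoff_Hz < self.sampling_rate_Hz / 2):
            raise ValidationError("filter_cutoff_Hz must be below Nyquist")


@dataclass(frozen=True)
class CohortSpec:
    genotype: str
    projection_class: str
    n_cells: int
    cv_per_density: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self):
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        for name, cv in self.cv_per_density.items():
            if not (0.0 <= cv < 1.0):
                raise ValidationError(f"CV for {name!r} must be in [0, 1)")


__all__ = [
    "TauSpec",
    "GateSpec",
    "ChannelSpec",
    "CompartmentSpec",
    "NeuronSpec",
    "PatchSpec",
    "CohortSpec",
    "CHANNEL_NAMES",
]
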