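"""Sweep data model and container I/O.

Conventions used throughout the package:

* current-clamp sweeps: stimulus in pA, response in mV
* voltage-clamp sweeps: stimulus (command) in mV, response in pA
* protocol parameters in mV / pA / ms; array time bases in seconds
* voltages are stored uncorrected for the liquid-junction potential; the
  ``ljp_corrected`` metadata flag records this convention explicitly.

The on-disk container is a small HDF5 schema (``fxsephys-1``): one group per
cell, one group per sweep set, one dataset pair (stimulus/response) per sweep,
with sampling rate, mode and the protocol (JSON) carried as attributes.  A
documented CSV fallback (one file per sweep, ``# key=value`` header lines,
then ``stimulus,response`` columns) round-trips to the same objects.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

SCHEMA_VERSION = "fxsephys-1"

GENOTYPES = ("WT", "KO")
PROJECTION_CLASSES = ("PT", "IT", "unlabeled")
COMPARTMENTS = ("soma", "dendrite")
MODES = ("current_clamp", "voltage_clamp")
PROTOCOL_KINDS = (
    "step_family",
    "chirp",
    "brief_pulse",
    "epsc_train",
    "threshold_pulse",
    "vc_activation",
    "vc_prepulse",
    "vc_sustained",
    "vc_recovery",
    "vc_ih_step",
    "custom",
)

FEATURE_TABLE_COLUMNS = (
    "cell_id",
    "genotype",
    "projection_class",
    "compartment",
    "distance_um",
    "feature",
    "value",
    "units",
)


class ValidationError(ValueError):
    """Raised when a sweep, sweep set or table violates its invariants."""


@dataclass(frozen=True)
class RecordingMetadata:
    """Identity and recording-site information for one cell/recording."""

    cell_id: str
    genotype: str = "WT"
    projection_class: str = "unlabeled"
    compartment: str = "soma"
    distance_um: float = 0.0
    temperature_C: float = 33.0
    holding_potential_mV: float | None = None
    ljp_corrected: bool = False
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not self.cell_id:
            raise ValidationError("cell_id must be non-empty")
        if self.genotype not in GENOTYPES:
            raise ValidationError(f"genotype {self.genotype!r} not in {GENOTYPES}")
        if self.projection_class not in PROJECTION_CLASSES:
            raise ValidationError(
                f"projection_class {self.projection_class!r} not in {PROJECTION_CLASSES}"
            )
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(f"compartment {self.compartment!r} not in {COMPARTMENTS}")
        if self.distance_um < 0:
            raise ValidationError("distance_um must be non-negative")
        if self.ljp_corrected:
            raise ValidationError(
                "ljp_corrected must be False: package presets are calibrated to "
                "uncorrected voltages"
            )


@dataclass(frozen=True)
class ProtocolDescriptor:
    """Names the stimulus protocol and its defining parameters."""

    kind: str
    parameters: dict = field(default_factory=dict)

    _REQUIRED = {
        "chirp": ("f_start_Hz", "f_end_Hz", "duration_s", "amplitude_pA"),
        "step_family": ("amplitudes_pA", "duration_ms"),
        "epsc_train": ("n_events", "frequency_Hz"),
    }

    def validate(self) -> None:
        if self.kind not in PROTOCOL_KINDS:
            raise ValidationError(f"protocol kind {self.kind!r} not in {PROTOCOL_KINDS}")
        for key in self._REQUIRED.get(self.kind, ()):
            if key not in self.parameters:
                raise ValidationError(f"protocol {self.kind!r} missing parameter {key!r}")

    def to_json(self) -> str:
        params = {
            k: (list(v) if isinstance(v, (np.ndarray, tuple)) else v)
            for k, v in self.parameters.items()
        }
        return json.dumps({"kind": self.kind, "parameters": params}, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ProtocolDescriptor":
        obj = json.loads(text)
        return cls(kind=obj["kind"], parameters=obj.get("parameters", {}))


@dataclass(frozen=True)
class Sweep:
    """One time-aligned stimulus/response record."""

    sampling_rate_Hz: float
    mode: str
    stimulus: np.ndarray
    response: np.ndarray
    t0_s: float = 0.0
    metadata: RecordingMetadata = field(
        default_factory=lambda: RecordingMetadata(cell_id="unnamed")
    )
    protocol: ProtocolDescriptor = field(
        default_factory=lambda: ProtocolDescriptor(kind="custom")
    )

    def __post_init__(self):
        object.__setattr__(self, "stimulus", np.asarray(self.stimulus, dtype=np.float64))
        object.__setattr__(self, "response", np.asarray(self.response, dtype=np.float64))

    def validate(self) -> None:
        if self.sampling_rate_Hz <= 0:
            raise ValidationError("sampling_rate_Hz must be positive")
        if self.mode not in MODES:
            raise ValidationError(f"mode {self.mode!r} not in {MODES}")
        if self.stimulus.ndim != 1 or self.response.ndim != 1:
            raise ValidationError("stimulus and response must be 1-D arrays")
        if len(self.stimulus) != len(self.response):
            raise ValidationError("stimulus and response must have equal length")
        if len(self.stimulus) < 2:
            raise ValidationError("sweep must contain at least 2 samples")
        self.metadata.validate()
        self.protocol.validate()

    @property
    def n_samples(self) -> int:
        return len(self.stimulus)

    @property
    def dt_s(self) -> float:
        return 1.0 / self.sampling_rate_Hz

    @property
    def time_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.sampling_rate_Hz


@dataclass(frozen=True)
class SweepSet:
    """An ordered collection of sweeps acquired under one protocol."""

    sweeps: tuple
    protocol_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "sweeps", tuple(self.sweeps))

    def validate(self) -> None:
        if not self.sweeps:
            raise ValidationError("SweepSet must be non-empty")
        rates = {s.sampling_rate_Hz for s in self.sweeps}
        modes = {s.mode for s in self.sweeps}
        if len(rates) != 1:
            raise ValidationError(f"sweeps mix sampling rates: {sorted(rates)}")
        if len(modes) != 1:
            raise ValidationError(f"sweeps mix modes: {sorted(modes)}")
        for i, s in enumerate(self.sweeps):
            try:
                s.validate()
            except ValidationError as e:
                raise ValidationError(f"sweep {i}: {e}") from e

    def __len__(self) -> int:
        return len(self.sweeps)

    def __iter__(self):
        return iter(self.sweeps)

    def __getitem__(self, i):
        return self.sweeps[i]

    @property
    def mode(self) -> str:
        return self.sweeps[0].mode

    @property
    def sampling_rate_Hz(self) -> float:
        return self.sweeps[0].sampling_rate_Hz


# ---------------------------------------------------------------------------
# FeatureTable
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Tidy per-cell feature rows: one row per (cell_id, feature)."""

    df: pd.DataFrame

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "FeatureTable":
        df = pd.DataFrame(list(records), columns=list(FEATURE_TABLE_COLUMNS))
        table = cls(df)
        table.validate()
        return table

    def validate(self) -> None:
        missing = [c for c in FEATURE_TABLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"feature table missing columns: {missing}")
        dup = self.df.duplicated(subset=["cell_id", "feature"])
        if dup.any():
            bad = self.df.loc[dup, ["cell_id", "feature"]].values.tolist()
            raise ValidationError(f"duplicate (cell_id, feature) rows: {bad}")
        if (self.df["units"].astype(str).str.len() == 0).any():
            raise ValidationError("units must be non-empty")

    def sorted(self) -> "FeatureTable":
        df = (
            self.df.sort_values(["cell_id", "feature"], kind="mergesort")
            .reset_index(drop=True)
        )
        return FeatureTable(df[list(FEATURE_TABLE_COLUMNS)])

    def __eq__(self, other) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        a, b = self.sorted().df, other.sorted().df
        if a.shape != b.shape:
            return False
        for col in FEATURE_TABLE_COLUMNS:
            if col in ("value", "distance_um"):
                if not np.allclose(
                    a[col].astype(float), b[col].astype(float), rtol=0, atol=0, equal_nan=True
                ):
                    return False
            elif not (a[col].astype(str) == b[col].astype(str)).all():
                return False
        return True


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a feature table as CSV with fixed column order and deterministic
    (cell_id, feature) lexicographic row ordering."""
    table.validate()
    table.sorted().df.to_csv(path, index=False, lineterminator="\n")


def read_feature_table(path) -> FeatureTable:
    df = pd.read_csv(path)
    table = FeatureTable(df)
    table.validate()
    return table


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def write_container(sweepsets: Sequence[SweepSet], path) -> None:
    """Write sweep sets to the ``fxsephys-1`` HDF5 container.

    Layout: ``/<set_name>/sweep_<i>/{stimulus,response}`` with attributes
    carrying sampling rate, mode, t0, protocol JSON and metadata fields.
    """
    for i, ss in enumerate(sweepsets):
        try:
            ss.validate()
        except ValidationError as e:
            raise ValidationError(f"sweep set {i}: {e}") from e
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SCHEMA_VERSION
        for i, ss in enumerate(sweepsets):
            grp = f.create_group(f"set_{i:04d}")
            grp.attrs["protocol_id"] = ss.protocol_id
            for j, sw in enumerate(ss.sweeps):
                g = grp.create_group(f"sweep_{j:04d}")
                g.create_dataset("stimulus", data=sw.stimulus, dtype="f8")
                g.create_dataset("response", data=sw.response, dtype="f8")
                g.attrs["sampling_rate_Hz"] = float(sw.sampling_rate_Hz)
                g.attrs["mode"] = sw.mode
                g.attrs["t0_s"] = float(sw.t0_s)
                g.attrs["protocol"] = sw.protocol.to_json()
                md = sw.metadata
                g.attrs["cell_id"] = md.cell_id
                g.attrs["genotype"] = md.genotype
                g.attrs["projection_class"] = md.projection_class
                g.attrs["compartment"] = md.compartment
                g.attrs["distance_um"] = float(md.distance_um)
                g.attrs["temperature_C"] = float(md.temperature_C)
                g.attrs["ljp_corrected"] = bool(md.ljp_corrected)
                if md.holding_potential_mV is not None:
                    g.attrs["holding_potential_mV"] = float(md.holding_potential_mV)
                if md.extra:
                    g.attrs["extra"] = json.dumps(md.extra, sort_keys=True)


_REQUIRED_SWEEP_ATTRS = ("sampling_rate_Hz", "mode", "cell_id")


def _sweep_from_attrs(attrs: dict, stimulus, response) -> Sweep:
    for key in _REQUIRED_SWEEP_ATTRS:
        if key not in attrs:
            raise ValidationError(f"missing required attribute {key!r}")
    mode = str(attrs["mode"])
    if mode not in MODES:
        raise ValidationError(f"mode attribute {mode!r} is not a recognized mode")
    known = {
        "sampling_rate_Hz", "mode", "t0_s", "protocol", "cell_id", "genotype",
        "projection_class", "compartment", "distance_um", "temperature_C",
        "ljp_corrected", "holding_potential_mV", "extra",
    }
    extra = json.loads(attrs["extra"]) if "extra" in attrs else {}
    # unknown attributes are preserved in the passthrough record
    for k, v in attrs.items():
        if k not in known:
            extra[k] = v if not isinstance(v, bytes) else v.decode()
    md = RecordingMetadata(
        cell_id=str(attrs["cell_id"]),
        genotype=str(attrs.get("genotype", "WT")),
        projection_class=str(attrs.get("projection_class", "unlabeled")),
        compartment=str(attrs.get("compartment", "soma")),
        distance_um=float(attrs.get("distance_um", 0.0)),
        temperature_C=float(attrs.get("temperature_C", 33.0)),
        holding_potential_mV=(
            float(attrs["holding_potential_mV"]) if "holding_potential_mV" in attrs else None
        ),
        ljp_corrected=bool(attrs.get("ljp_corrected", False)),
        extra=extra,
    )
    protocol = (
        ProtocolDescriptor.from_json(str(attrs["protocol"]))
        if "protocol" in attrs
        else ProtocolDescriptor(kind="custom")
    )
    sweep = Sweep(
        sampling_rate_Hz=float(attrs["sampling_rate_Hz"]),
        mode=mode,
        stimulus=stimulus,
        response=response,
        t0_s=float(attrs.get("t0_s", 0.0)),
        metadata=md,
        protocol=protocol,
    )
    sweep.validate()
    return sweep


def read_container(path) -> list:
    """Read a container written by :func:`write_container`, or a CSV fallback
    directory (see :func:`read_csv_fallback`)."""
    path = Path(path)
    if path.is_dir():
        return read_csv_fallback(path)
    sweepsets = []
    with h5py.File(path, "r") as f:
        if f.attrs.get("schema") != SCHEMA_VERSION:
            raise ValidationError(
                f"not a {SCHEMA_VERSION} container (schema={f.attrs.get('schema')!r})"
            )
        for set_name in sorted(f.keys()):
            grp = f[set_name]
            sweeps = []
            for sweep_name in sorted(grp.keys()):
                g = grp[sweep_name]
                try:
                    stim = np.asarray(g["stimulus"][...], dtype=np.float64)
                    resp = np.asarray(g["response"][...], dtype=np.float64)
                except Exception as e:  # pragma: no cover - h5py raises OSError
                    raise IOError(f"corrupted array in {set_name}/{sweep_name}: {e}") from e
                sweeps.append(_sweep_from_attrs(dict(g.attrs), stim, resp))
            ss = SweepSet(sweeps=tuple(sweeps), protocol_id=str(grp.attrs.get("protocol_id", "")))
            ss.validate()
            sweepsets.append(ss)
    return sweepsets


# ---------------------------------------------------------------------------
# CSV fallback
# ---------------------------------------------------------------------------
#
# Layout: a directory holding one UTF-8 CSV per sweep, named
# ``set<ss>__sweep<jj>.csv``.  Header lines ``# key=value`` (metadata,
# sampling rate, mode, protocol JSON) precede the mandatory column header
# ``stimulus,response`` and '.'-decimal data lines.

_CSV_NAME = re.compile(r"set(\d+)__sweep(\d+)\.csv$")


def write_csv_fallback(sweepsets: Sequence[SweepSet], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, ss in enumerate(sweepsets):
        ss.validate()
        for j, sw in enumerate(ss.sweeps):
            lines = [f"# schema={SCHEMA_VERSION}", f"# protocol_id={ss.protocol_id}"]
            md = sw.metadata
            attrs = {
                "sampling_rate_Hz": repr(float(sw.sampling_rate_Hz)),
                "mode": sw.mode,
                "t0_s": repr(float(sw.t0_s)),
                "protocol": sw.protocol.to_json(),
                "cell_id": md.cell_id,
                "genotype": md.genotype,
                "projection_class": md.projection_class,
                "compartment": md.compartment,
                "distance_um": repr(float(md.distance_um)),
                "temperature_C": repr(float(md.temperature_C)),
                "ljp_corrected": str(md.ljp_corrected),
            }
            if md.holding_potential_mV is not None:
                attrs["holding_potential_mV"] = repr(float(md.holding_potential_mV))
            lines += [f"# {k}={v}" for k, v in attrs.items()]
            lines.append("stimulus,response")
            lines += [f"{float(s)!r},{float(r)!r}" for s, r in zip(sw.stimulus, sw.response)]
            (directory / f"set{i:04d}__sweep{j:04d}.csv").write_text(
                "\n".join(lines) + "\n", encoding="utf-8"
            )


def read_csv_fallback(directory) -> list:
    directory = Path(directory)
    files = {}
    for p in sorted(directory.iterdir()):
        m = _CSV_NAME.search(p.name)
        if m:
            files.setdefault(int(m.group(1)), []).append((int(m.group(2)), p))
    if not files:
        raise IOError(f"no fallback CSV sweeps found in {directory}")
    sweepsets = []
    for set_idx in sorted(files):
        sweeps = []
        protocol_id = ""
        for _, p in sorted(files[set_idx]):
            attrs = {}
            stim, resp = [], []
            in_data = False
            for line in p.read_text(encoding="utf-8").splitlines():
                if line.startswith("#"):
                    key, _, value = line[1:].strip().partition("=")
                    attrs[key.strip()] = value
                elif not in_data:
                    if line.strip() != "stimulus,response":
                        raise ValidationError(
                            f"{p.name}: expected header 'stimulus,response', got {line!r}"
                        )
                    in_data = True
                elif line.strip():
                    s, _, r = line.partition(",")
                    stim.append(float(s))
                    resp.append(float(r))
            protocol_id = attrs.pop("protocol_id", protocol_id)
            attrs.pop("schema", None)
            if "ljp_corrected" in attrs:
                attrs["ljp_corrected"] = attrs["ljp_corrected"] == "True"
            sweeps.append(
                _sweep_from_attrs(attrs, np.asarray(stim), np.asarray(resp))
            )
        ss = SweepSet(sweeps=tuple(sweeps), protocol_id=protocol_id)
        ss.validate()
        sweepsets.append(ss)
    return sweepsets


__all__ = [
    "SCHEMA_VERSION",
    "ValidationError",
    "RecordingMetadata",
    "ProtocolDescriptor",
    "Sweep",
    "SweepSet",
    "FeatureTable",
    "write_feature_table",
    "read_feature_table",
    "write_container",
    "read_container",
    "write_csv_fallback",
    "read_csv_fallback",
    "replace",
]
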