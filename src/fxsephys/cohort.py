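"""Cohort assembly, statistics, and the genotype × class direction summary.

The statistical battery mirrors standard slice-physiology practice: group
means ± SEM, two-group t tests or one-way ANOVA, Kolmogorov–Smirnov
normality checks, Bonferroni correction within explicitly declared
comparison families, Cohen's d (pooled SD) or Cohen's f effect sizes, and
Pearson correlations.  ``run_pipeline`` drives the full chain: sample
simulated cohorts → acquire protocol sweeps → extract features → compare →
summarize directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import presets, protocols, simulate, spikes, subthreshold, vclamp
from .channels import CohortSpec
from .trace_io import FeatureTable, ValidationError


class DesignError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


class DegenerateDataError(ValueError):
    pass


@dataclass(frozen=True)
class GroupDesign:
    factors: tuple = ("genotype",)
    design: str = "between"  # between | repeated | mixed
    alpha: float = 0.05
    correction: str = "bonferroni"  # bonferroni | none

    def validate(self):
        if not (0.0 < self.alpha < 1.0):
            raise DesignError("alpha must lie in (0, 1)")
        if self.design not in ("between", "repeated", "mixed"):
            raise DesignError(f"unknown design {self.design!r}")
        if self.correction not in ("bonferroni", "none"):
            raise DesignError(f"unknown correction {self.correction!r}")


@dataclass
class ComparisonResult:
    feature: str
    groups: tuple
    means: dict
    sems: dict
    ns: dict
    statistic: float
    p_value: float
    p_adjusted: float
    effect_size: float
    normality_p: dict
    test: str


@dataclass
class DirectionSummary:
    directions: dict  # (feature, projection_class) -> "up" | "down" | "unchanged"


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def _group_column(df: pd.DataFrame, factors) -> pd.Series:
    return df[list(factors)].astype(str).agg("|".join, axis=1)


def summarize_groups(table: FeatureTable, feature: str,
                     factors=("genotype",)) -> pd.DataFrame:
    """Per-group mean, SEM (= SD/√n) and n for one feature."""
    df = table.df[table.df["feature"] == feature].copy()
    if df.empty:
        raise InsufficientDataError(f"feature {feature!r} absent from the table")
    df["group"] = _group_column(df, factors)
    out = []
    for g, sub in df.groupby("group", sort=True):
        vals = sub["value"].astype(float).to_numpy()
        if len(vals) < 2:
            raise InsufficientDataError(f"group {g!r} has n < 2 for {feature!r}")
        out.append({
            "group": g, "n": len(vals), "mean": float(vals.mean()),
            "sem": float(vals.std(ddof=1) / np.sqrt(len(vals))),
        })
    return pd.DataFrame(out).set_index("group")


def _ks_normality(vals: np.ndarray) -> float:
    sd = vals.std(ddof=1)
    if sd == 0:
        return 1.0
    return float(sstats.kstest((vals - vals.mean()) / sd, "norm").pvalue)


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    if pooled == 0:
        return 0.0
    return float(abs(a.mean() - b.mean()) / pooled)


def compare_groups(table: FeatureTable, feature: str, design: GroupDesign,
                   family_size: int = 1, subject_col: str | None = None) -> ComparisonResult:
    """Two-group t test or one-way ANOVA across the groups defined by the
    design's factors, with KS normality per group, Bonferroni adjustment
    across the declared family, and Cohen's d/f effect size."""
    design.validate()
    df = table.df[table.df["feature"] == feature].copy()
    if df.empty:
        raise InsufficientDataError(f"feature {feature!r} absent from the table")
    missing = [f for f in design.factors if f not in df.columns]
    if missing:
        raise DesignError(f"factors absent from metadata: {missing}")
    df["group"] = _group_column(df, design.factors)
    groups = sorted(df["group"].unique())
    arrays = {g: df.loc[df["group"] == g, "value"].astype(float).to_numpy()
              for g in groups}
    for g, v in arrays.items():
        if len(v) < 2:
            raise InsufficientDataError(f"group {g!r} has n < 2")
    if design.design in ("repeated", "mixed") and subject_col is None:
        raise DesignError(
            f"{design.design} design requires subject identifiers"
        )
    if len(groups) == 2:
        a, b = (arrays[g] for g in groups)
        stat, p = sstats.ttest_ind(a, b)
        effect = cohens_d(a, b)
        test = "t"
    else:
        stat, p = sstats.f_oneway(*(arrays[g] for g in groups))
        # Cohen's f from the one-way ANOVA sums of squares
        grand = np.concatenate(list(arrays.values())).mean()
        ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in arrays.values())
        ss_within = sum(((v - v.mean()) ** 2).sum() for v in arrays.values())
        effect = float(np.sqrt(ss_between / ss_within)) if ss_within > 0 else 0.0
        test = "anova"
    p_adj = bonferroni(p, family_size if design.correction == "bonferroni" else 1)
    return ComparisonResult(
        feature=feature,
        groups=tuple(groups),
        means={g: float(v.mean()) for g, v in arrays.items()},
        sems={g: float(v.std(ddof=1) / np.sqrt(len(v))) for g, v in arrays.items()},
        ns={g: len(v) for g, v in arrays.items()},
        statistic=float(stat),
        p_value=float(p),
        p_adjusted=p_adj,
        effect_size=float(effect),
        normality_p={g: _ks_normality(v) for g, v in arrays.items()},
        test=test,
    )


def bonferroni(p: float, family_size: int) -> float:
    """Bonferroni-adjusted p: monotone in family size, never below raw p."""
    if family_size < 1:
        raise DesignError("family size must be >= 1")
    return float(min(1.0, p * family_size))


def mannwhitney_fallback(table: FeatureTable, feature: str,
                         design: GroupDesign, family_size: int = 1) -> float:
    """Rank-based two-group comparison offered when normality fails."""
    df = table.df[table.df["feature"] == feature].copy()
    df["group"] = _group_column(df, design.factors)
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise DesignError("nonparametric fallback implemented for two groups")
    a, b = (df.loc[df["group"] == g, "value"].astype(float).to_numpy()
            for g in groups)
    p = float(sstats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return bonferroni(p, family_size)


def correlate(table: FeatureTable, x_feature: str, y_feature: str,
              where: dict | None = None):
    """Pearson r² and two-sided p between two features, paired by cell."""
    df = table.df
    if where:
        for col, val in where.items():
            df = df[df[col] == val]
    x = df[df["feature"] == x_feature].set_index("cell_id")["value"].astype(float)
    y = df[df["feature"] == y_feature].set_index("cell_id")["value"].astype(float)
    common = x.index.intersection(y.index)
    if len(common) < 4:
        raise InsufficientDataError("need >= 4 paired observations")
    xv, yv = x[common].to_numpy(), y[common].to_numpy()
    if xv.std() == 0 or yv.std() == 0:
        raise DegenerateDataError("zero variance in a correlated variable")
    r, p = sstats.pearsonr(xv, yv)
    return float(r * r), float(p), float(r)


# ---------------------------------------------------------------------------
# direction summary
# ---------------------------------------------------------------------------

def direction_summary(comparisons, alpha: float = 0.05,
                      reference_group: str = "WT") -> DirectionSummary:
    """Map (feature, class) comparisons to up/down/unchanged for KO vs WT.

    'unchanged' iff the adjusted p is ≥ alpha; otherwise the sign of the
    KO − WT mean difference decides.
    """
    out = {}
    for comp, cls in comparisons:
        ko = next((g for g in comp.groups if g.startswith("KO")), None)
        wt = next((g for g in comp.groups if g.startswith(reference_group)), None)
        if ko is None or wt is None:
            raise DesignError(f"comparison for {comp.feature!r} lacks KO/WT groups")
        if comp.p_adjusted >= alpha:
            out[(comp.feature, cls)] = "unchanged"
        else:
            out[(comp.feature, cls)] = (
                "up" if comp.means[ko] > comp.means[wt] else "down"
            )
    return DirectionSummary(directions=out)


# ---------------------------------------------------------------------------
# feature extraction per cell
# ---------------------------------------------------------------------------

SUBTHRESHOLD_FEATURES = ("R_N", "sag", "rebound", "tau_m", "f_R", "summation", "RMP")
PATCH_FEATURES = ("I_h_max", "I_KA_fast_peak", "I_K_slow_peak", "I_K_sustained_amp")
THRESHOLD_FEATURES = ("thr_short", "thr_long", "rheo_short", "rheo_long")

FEATURE_UNITS = {
    "R_N": "MOhm", "sag": "ratio", "rebound": "mV/mV", "tau_m": "ms",
    "f_R": "Hz", "summation": "ratio", "RMP": "mV",
    "I_h_max": "pA", "I_KA_fast_peak": "pA", "I_K_slow_peak": "pA",
    "I_K_sustained_amp": "pA",
    "thr_short": "mV", "thr_long": "mV", "rheo_short": "pA", "rheo_long": "pA",
}

LONG_DURATIONS_MS = (12.0, 25.0, 50.0, 100.0)
SHORT_DURATION_MS = 1.5


def extract_cell_features(neuron, features, patch_seed: int = 0,
                          noise_pA_sd: float = 2.0,
                          long_durations_ms=LONG_DURATIONS_MS,
                          step_amplitudes_pA=None) -> dict:
    """Run the protocols a feature set needs on one simulated cell and
    return {feature: value}.

    ``thr_long``/``rheo_long`` are means over the >6 ms duration grid
    (threshold accommodation is compared across genotypes on this pooled
    measure, as in a repeated-measures design collapsed over duration).
    """
    vals = {}
    want = set(features)
    if want & {"R_N", "sag", "rebound"}:
        if step_amplitudes_pA is None:
            step_amplitudes_pA = protocols.STEP_AMPLITUDES_PA
        steps = protocols.run_step_family(neuron, amplitudes_pA=step_amplitudes_pA)
        if "R_N" in want:
            vals["R_N"], _ = subthreshold.input_resistance(steps)
        if "sag" in want:
            vals["sag"] = subthreshold.sag_ratio(steps)
        if "rebound" in want:
            vals["rebound"] = subthreshold.rebound_slope(steps)
    if "tau_m" in want:
        pulses = protocols.run_brief_pulses(neuron)
        vals["tau_m"], _ = subthreshold.membrane_time_constant(pulses)
    if "f_R" in want:
        chirp = protocols.run_chirp(neuron)
        vals["f_R"] = subthreshold.zap_profile(chirp).f_R_Hz
    if "summation" in want:
        train = protocols.run_epsc_train(neuron)
        vals["summation"] = subthreshold.temporal_summation(train)
    if "RMP" in want:
        vals["RMP"] = subthreshold.resting_potential(protocols.run_resting(neuron))
    if want & set(PATCH_FEATURES):
        patch = presets.default_patch(seed=patch_seed, noise_pA_sd=noise_pA_sd)
        if want & {"I_KA_fast_peak", "I_K_slow_peak", "I_K_sustained_amp"}:
            prot = protocols.run_k_current_protocols(neuron, patch)
            comps = vclamp.decompose_currents(
                leak_subtracted(prot, "total"), leak_subtracted(prot, "prepulsed"),
                leak_subtracted(prot, "sustained"),
            )
            vals["I_KA_fast_peak"] = comps.I_KA_fast.peak_pA
            vals["I_K_slow_peak"] = comps.I_K_slow.peak_pA
            vals["I_K_sustained_amp"] = comps.I_K_sustained.peak_pA
        if "I_h_max" in want:
            site = "dendrite" if any(
                c.name == "dendrite" for c in neuron.compartments) else "soma"
            ih_sweep = protocols.run_ih_step(neuron, patch, site=site)
            vals["I_h_max"] = vclamp.ih_step_analysis(ih_sweep).I_h_max_pA
    if want & set(THRESHOLD_FEATURES):
        stim = protocols.threshold_stimulator(neuron)
        if want & {"thr_short", "rheo_short"}:
            amp, f = spikes.just_threshold_search(stim, SHORT_DURATION_MS)
            vals["thr_short"] = f.threshold_mV
            vals["rheo_short"] = amp
        if want & {"thr_long", "rheo_long"}:
            thr, rheo = [], []
            for d in long_durations_ms:
                amp, f = spikes.just_threshold_search(stim, float(d))
                thr.append(f.threshold_mV)
                rheo.append(amp)
            vals["thr_long"] = float(np.mean(thr))
            vals["rheo_long"] = float(np.mean(rheo))
    return vals


def leak_subtracted(protocol_sweeps: dict, key: str):
    """Leak-subtract one decomposition protocol with its matched scaling
    sweeps (holding −90 for total/prepulsed, −20 for sustained)."""
    from .trace_io import Sweep, SweepSet
    scaling = protocol_sweeps["scaling_m20" if key == "sustained" else "scaling_m90"]
    subtracted = []
    for sw in protocol_sweeps[key]:
        corr = vclamp.leak_subtract(sw, scaling)
        subtracted.append(Sweep(
            sampling_rate_Hz=sw.sampling_rate_Hz, mode=sw.mode,
            stimulus=sw.stimulus, response=corr,
            metadata=sw.metadata, protocol=sw.protocol,
        ))
    return SweepSet(tuple(subtracted), protocol_id=protocol_sweeps[key].protocol_id)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "n_cells": 15,
    "classes": ("PT", "IT"),
    "features": {
        "PT": SUBTHRESHOLD_FEATURES + PATCH_FEATURES + ("thr_short", "thr_long"),
        "IT": SUBTHRESHOLD_FEATURES,
    },
    # Bonferroni families, declared explicitly per class
    "families": {
        "PT": {
            "subthreshold": ("sag", "rebound", "tau_m", "f_R", "summation",
                             "RMP", "R_N"),
            "vclamp": PATCH_FEATURES,
            "threshold": ("thr_short", "thr_long"),
        },
        "IT": {
            "subthreshold": ("sag", "rebound", "tau_m", "f_R", "summation",
                             "RMP", "R_N"),
        },
    },
    "alpha": 0.05,
    "noise_pA_sd": 2.0,
    "long_durations_ms": LONG_DURATIONS_MS,
    "step_amplitudes_pA": None,  # None -> full -150..+50 pA family
}


@dataclass
class PipelineResult:
    feature_table: FeatureTable
    comparisons: list
    summary: DirectionSummary
    log: dict = field(default_factory=dict)


def build_feature_table(config: dict, seed: int) -> FeatureTable:
    """Simulate the configured cohorts and extract their feature rows."""
    records = []
    for ci, cls in enumerate(config["classes"]):
        feats = config["features"][cls]
        unknown = [f for f in feats if f not in FEATURE_UNITS]
        if unknown:
            raise ValidationError(f"unknown feature name(s): {unknown}")
        for gi, genotype in enumerate(("WT", "KO")):
            spec = CohortSpec(genotype=genotype, projection_class=cls,
                              n_cells=config["n_cells"],
                              seed=seed * 17 + ci * 5 + gi)
            cohort = presets.sample_cohort(spec)
            for j, neuron in enumerate(cohort):
                vals = extract_cell_features(
                    neuron, feats, patch_seed=seed * 1000 + ci * 101 + gi * 53 + j,
                    noise_pA_sd=config.get("noise_pA_sd", 2.0),
                    long_durations_ms=config.get("long_durations_ms",
                                                 LONG_DURATIONS_MS),
                    step_amplitudes_pA=config.get("step_amplitudes_pA"),
                )
                for fname, value in vals.items():
                    records.append({
                        "cell_id": neuron.preset_id,
                        "genotype": genotype,
                        "projection_class": cls,
                        "compartment": "soma",
                        "distance_um": 0.0,
                        "feature": fname,
                        "value": value,
                        "units": FEATURE_UNITS[fname],
                    })
    return FeatureTable.from_records(records)


def compare_cohorts(table: FeatureTable, config: dict):
    """Genotype comparisons per class with Bonferroni within the declared
    families; returns [(ComparisonResult, class), ...]."""
    design = GroupDesign(factors=("genotype",), alpha=config["alpha"])
    comparisons = []
    for cls, families in config["families"].items():
        sub = FeatureTable(table.df[table.df["projection_class"] == cls])
        for members in families.values():
            present = [f for f in members
                       if (sub.df["feature"] == f).any()]
            for fname in present:
                comp = compare_groups(sub, fname, design,
                                      family_size=len(present))
                comparisons.append((comp, cls))
    return comparisons


def run_pipeline(config: dict | None = None, seed: int = 0) -> PipelineResult:
    """End-to-end: simulate → extract → compare → summarize.

    Fully seeded; identical config+seed give identical results.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    table = build_feature_table(cfg, seed)
    comparisons = compare_cohorts(table, cfg)
    summary = direction_summary(comparisons, alpha=cfg["alpha"])
    log = {"seed": seed, "n_cells": cfg["n_cells"],
           "classes": tuple(cfg["classes"]), "alpha": cfg["alpha"]}
    return PipelineResult(feature_table=table, comparisons=comparisons,
                          summary=summary, log=log)


__all__ = [
    "GroupDesign", "ComparisonResult", "DirectionSummary", "PipelineResult",
    "DesignError", "InsufficientDataError", "DegenerateDataError",
    "summarize_groups", "compare_groups", "bonferroni", "cohens_d",
    "mannwhitney_fallback", "correlate", "direction_summary",
    "extract_cell_features", "build_feature_table", "compare_cohorts",
    "run_pipeline", "leak_subtracted",
    "SUBTHRESHOLD_FEATURES", "PATCH_FEATURES", "THRESHOLD_FEATURES",
    "FEATURE_UNITS", "DEFAULT_CONFIG",
]
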