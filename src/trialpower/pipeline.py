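"""End-to-end orchestration: cohort -> standardize -> fit -> power -> sweep
-> bootstrap -> report.

A run is a pure function of (input table or synthetic spec, configuration,
seeds): the report bundle it writes — per-fit JSON, sample-size and sweep
tables, bootstrap comparisons, and a manifest with the config hash — is
byte-identical across repeated runs.  Per-biomarker model failures are
recorded in the manifest without aborting the other biomarkers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cohort as cohort_mod
from . import lme, power, synth
from . import inference

__all__ = ["RunConfig", "run_analysis", "run_sensitivity"]

log = logging.getLogger("trialpower")

DISEASE_GROUPS = ("preclinical_ad", "mild_ad")
#: trial durations per target group (months) in the primary scenario
DEFAULT_DURATIONS = {"preclinical_ad": 30.0, "mild_ad": 18.0}
#: per-biomarker assessment spacing (months) in the primary scenario
DEFAULT_FREQUENCIES = {
    "pnfl": 1.0,
    "temporal_composite": 3.0,
    "hippocampus": 3.0,
    "cdrsb": 3.0,
    "pacc": 3.0,
}


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on."""

    input_csv: str | None = None
    synth_sizes: dict = field(
        default_factory=lambda: {"control": 200, "preclinical_ad": 200, "mild_ad": 300}
    )
    synth_seed: int = 1
    params_yaml: str | None = None
    groups: tuple = DISEASE_GROUPS
    biomarkers: tuple = synth.BIOMARKERS
    durations: dict = field(default_factory=lambda: dict(DEFAULT_DURATIONS))
    frequencies: dict = field(default_factory=lambda: dict(DEFAULT_FREQUENCIES))
    mechanism: str = "full"
    alpha: float = 0.05
    target_power: float = 0.80
    effect_fraction: float = 0.30
    engine: str = "native"
    bootstrap_B: int = 0            # 0 disables bootstrap comparisons
    bootstrap_seed: int = 7
    reference_biomarker: str = "pnfl"
    sweep_durations: tuple = (30.0, 36.0, 42.0, 48.0, 54.0, 60.0)
    sweep_frequencies: tuple = (3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0)
    out_dir: str = "trialpower_out"

    def __post_init__(self) -> None:
        for g in self.groups:
            if g not in DISEASE_GROUPS:
                raise ValueError(f"unknown analysis group {g!r}")
            if g not in self.durations:
                raise ValueError(f"no duration configured for group {g!r}")
        for b in self.biomarkers:
            if b not in self.frequencies:
                raise ValueError(f"no sampling frequency configured for {b!r}")
        for g in self.groups:
            for b in self.biomarkers:
                # validates 0 < frequency <= duration, alpha, power, fraction
                power.TrialDesign(
                    duration=self.durations[g],
                    frequency=self.frequencies[b],
                    alpha=self.alpha,
                    target_power=self.target_power,
                    effect_fraction=self.effect_fraction,
                    mechanism=self.mechanism,
                )
        if self.reference_biomarker not in self.biomarkers:
            raise ValueError("reference biomarker must be among the biomarkers")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("groups", "biomarkers", "sweep_durations", "sweep_frequencies"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def canonical_json(self) -> str:
        d = asdict(self)
        d["groups"] = list(d["groups"])
        d["biomarkers"] = list(d["biomarkers"])
        d["sweep_durations"] = list(d["sweep_durations"])
        d["sweep_frequencies"] = list(d["sweep_frequencies"])
        return json.dumps(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]

    def design(self, group: str, biomarker: str) -> power.TrialDesign:
        return power.TrialDesign(
            duration=self.durations[group],
            frequency=self.frequencies[biomarker],
            alpha=self.alpha,
            target_power=self.target_power,
            effect_fraction=self.effect_fraction,
            mechanism=self.mechanism,
        )


def _load_table(config: RunConfig) -> pd.DataFrame:
    if config.input_csv:
        from . import io

        return io.read_visits_csv(config.input_csv)
    params = (
        synth.load_params(config.params_yaml) if config.params_yaml else None
    )
    return synth.generate_cohort(
        config.synth_sizes, params=params, seed=config.synth_seed
    ).table


def _prepare(config: RunConfig, table: pd.DataFrame, variant: str | None = None):
    """Shared cohort-building stages; returns per-group standardized tables."""
    counts = {"input_subjects": int(table.subject_id.nunique()),
              "input_rows": int(len(table))}

    assigns = cohort_mod.build_assignments(table)
    aframe = cohort_mod.assignments_frame(assigns)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aframe.to_csv(out_dir / "cohort_assignments.csv", index=False)
    counts["assigned"] = {
        g: int((aframe.group == g).sum())
        for g in ("control", *DISEASE_GROUPS, "excluded")
    }
    log.info("group assignment: %s", counts["assigned"])

    if variant == "overlapping_visits":
        keep_cols = ["subject_id", "visit_month",
                     *[c for c in table.columns if c not in ("subject_id", "visit_month")]]
        table = cohort_mod.intersect_overlapping_visits(table[keep_cols])
        counts["overlap_rows"] = int(len(table))
        log.info("overlapping-visit intersection: %d rows retained", len(table))

    eligible, reasons = cohort_mod.filter_eligibility(table)
    counts["eligible"] = len(eligible)
    counts["ineligible"] = len(reasons)
    log.info("eligibility: %d kept, %d excluded", len(eligible), len(reasons))

    agroup = aframe.set_index("subject_id")["group"]
    ptau = aframe.set_index("subject_id")["ptau_positive"]
    table = table[table.subject_id.isin(eligible)].copy()
    table["analysis_group"] = table.subject_id.map(agroup)

    if variant == "ptau_positive":
        is_disease = table.analysis_group.isin(DISEASE_GROUPS)
        tau_ok = table.subject_id.map(ptau).fillna(False).astype(bool)
        table = table[~is_disease | tau_ok]
        counts["ptau_positive_subjects"] = int(
            table.loc[table.analysis_group.isin(DISEASE_GROUPS), "subject_id"].nunique()
        )
        log.info("P-tau restriction: %d disease subjects retained",
                 counts["ptau_positive_subjects"])

    standardizations = {}
    for b in config.biomarkers:
        if b not in table.columns:
            raise ValueError(f"biomarker column {b!r} missing from input")
        table, std = cohort_mod.standardize_biomarker(table, b)
        standardizations[b] = std

    per_group = {
        g: table[table.analysis_group == g]
        for g in ("control", *config.groups)
    }
    counts["analysis_subjects"] = {
        g: int(t.subject_id.nunique()) for g, t in per_group.items()
    }
    return per_group, standardizations, counts


def _fit_stage(config: RunConfig, per_group: dict):
    """Fit the random-slope model per biomarker x (control + target groups)."""
    fits: dict = {}
    failures: list = []
    for g, tab in per_group.items():
        for b in config.biomarkers:
            try:
                fit = lme.fit_slope_model(
                    tab, b, engine=config.engine, biomarker=b, group=g
                )
                fits[(g, b)] = fit
                if not fit.converged:
                    failures.append(
                        {"group": g, "biomarker": b, "error": "did not converge"}
                    )
            except (lme.InsufficientDataError, lme.NotConvergedError) as exc:
                failures.append({"group": g, "biomarker": b, "error": str(exc)})
    return fits, failures


def _power_stage(config: RunConfig, fits: dict):
    rows = []
    power_inputs: dict = {}
    for g in config.groups:
        for b in config.biomarkers:
            fit = fits.get((g, b))
            control_fit = fits.get(("control", b))
            row = {"group": g, "biomarker": b,
                   "duration": config.durations[g],
                   "frequency": config.frequencies[b]}
            try:
                if fit is None:
                    raise lme.NotConvergedError("no fit")
                sw2, sb2, slope = lme.extract_power_inputs(
                    fit, control_fit, config.mechanism
                )
                design = config.design(g, b)
                delta = power.detectable_delta(slope, config.effect_fraction)
                res = power.n_per_arm(
                    sw2, sb2, design.schedule(), delta, config.alpha,
                    config.target_power,
                )
                row.update(
                    n_continuous=res.n_continuous, n_per_arm=res.n_per_arm,
                    sigma_w_sq=sw2, sigma_b_sq=sb2, slope=slope, delta=delta,
                    error="",
                )
                power_inputs.setdefault(g, {})[b] = power.PowerInputs(
                    biomarker=b, sigma_w_sq=sw2, sigma_b_sq=sb2,
                    slope_for_delta=slope,
                )
            except (lme.NotConvergedError, power.UnpoweredError, ValueError) as exc:
                row.update(
                    n_continuous=np.nan, n_per_arm=np.nan, sigma_w_sq=np.nan,
                    sigma_b_sq=np.nan, slope=np.nan, delta=np.nan,
                    error=str(exc) or exc.__class__.__name__,
                )
            rows.append(row)
    return pd.DataFrame(rows), power_inputs


def _sweep_stage(config: RunConfig, power_inputs: dict):
    frames = []
    for g, inputs in power_inputs.items():
        if config.reference_biomarker not in inputs:
            continue
        grid = power.sweep(
            inputs,
            durations=config.sweep_durations,
            frequencies=config.sweep_frequencies,
            reference_biomarker=config.reference_biomarker,
            reference_frequency=config.frequencies[config.reference_biomarker],
            alpha=config.alpha,
            target_power=config.target_power,
            effect_fraction=config.effect_fraction,
        )
        grid.insert(0, "group", g)
        frames.append(grid)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def _bootstrap_stage(config: RunConfig, per_group: dict):
    if config.bootstrap_B < 2:
        return pd.DataFrame()
    rows = []
    for g in config.groups:
        tab = per_group[g]
        control = per_group.get("control")
        for b in config.biomarkers:
            if b == config.reference_biomarker:
                continue
            try:
                cmp = inference.bootstrap_compare(
                    tab,
                    config.reference_biomarker,
                    b,
                    config.design(g, config.reference_biomarker),
                    config.design(g, b),
                    B=config.bootstrap_B,
                    seed=config.bootstrap_seed,
                    control_table=control,
                    engine=config.engine,
                )
                rows.append(
                    {
                        "group": g,
                        "reference": config.reference_biomarker,
                        "biomarker": b,
                        "median_diff": float(np.nanmedian(cmp.diff_distribution)),
                        "p_value": cmp.p_value,
                        "direction": cmp.direction,
                        "error": "",
                    }
                )
            except (RuntimeError, ValueError, lme.InsufficientDataError) as exc:
                rows.append(
                    {"group": g, "reference": config.reference_biomarker,
                     "biomarker": b, "median_diff": np.nan, "p_value": np.nan,
                     "direction": "", "error": str(exc)}
                )
    return pd.DataFrame(rows)


def _write_bundle(out_dir: Path, config: RunConfig, fits, failures,
                  sample_sizes, sweep_grid, boots, standardizations, counts):
    out_dir.mkdir(parents=True, exist_ok=True)
    fit_dir = out_dir / "fits"
    fit_dir.mkdir(exist_ok=True)
    for (g, b), fit in sorted(fits.items()):
        (fit_dir / f"{g}__{b}.json").write_text(fit.to_json())
    sample_sizes.to_csv(out_dir / "sample_sizes.csv", index=False)
    if len(sweep_grid):
        sweep_grid.to_csv(out_dir / "sweep.csv", index=False)
    if len(boots):
        boots.to_csv(out_dir / "bootstrap_comparisons.csv", index=False)
    manifest = {
        "package_version": __version__,
        "config": json.loads(config.canonical_json()),
        "config_hash": config.config_hash(),
        "counts": counts,
        "standardization": {
            b: {"baseline_mean": s.baseline_mean, "baseline_sd": s.baseline_sd,
                "n_reference": s.n_reference, "reference": s.reference}
            for b, s in standardizations.items()
        },
        "model_failures": failures,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def run_analysis(config: RunConfig, variant: str | None = None) -> dict:
    """Execute the full pipeline; returns the result bundle in memory.

    ``variant`` is used by :func:`run_sensitivity`; None is the primary run.
    """
    table = _load_table(config)
    per_group, standardizations, counts = _prepare(config, table, variant)
    fits, failures = _fit_stage(config, per_group)
    sample_sizes, power_inputs = _power_stage(config, fits)
    sweep_grid = _sweep_stage(config, power_inputs)
    boots = _bootstrap_stage(config, per_group)
    out_dir = Path(config.out_dir)
    manifest = _write_bundle(
        out_dir, config, fits, failures, sample_sizes, sweep_grid, boots,
        standardizations, counts,
    )
    return {
        "manifest": manifest,
        "fits": fits,
        "sample_sizes": sample_sizes,
        "sweep": sweep_grid,
        "bootstrap": boots,
        "out_dir": out_dir,
    }


SENSITIVITY_VARIANTS = ("overlapping_visits", "ptau_positive", "low_frequency")


def run_sensitivity(config: RunConfig, which: str) -> dict:
    """Re-run the pipeline under a named variation and emit a delta table.

    - overlapping_visits: keep only visit clusters with all modalities;
    - ptau_positive: additionally require disease subjects to be CSF
      P-tau181 positive;
    - low_frequency: plasma sampling every 3 months, MRI/cognition every 6.
    """
    if which not in SENSITIVITY_VARIANTS:
        raise ValueError(f"unknown sensitivity variant {which!r}")
    base = run_analysis(config)

    variant_config = replace(config, out_dir=str(Path(config.out_dir) / f"sensitivity_{which}"))
    if which == "low_frequency":
        freqs = {
            b: (3.0 if b == config.reference_biomarker else 6.0)
            for b in config.biomarkers
        }
        variant_config = replace(variant_config, frequencies=freqs)
        result = run_analysis(variant_config)
    else:
        result = run_analysis(variant_config, variant=which)

    keys = ["group", "biomarker"]
    delta = base["sample_sizes"][keys + ["n_continuous", "n_per_arm"]].merge(
        result["sample_sizes"][keys + ["n_continuous", "n_per_arm"]],
        on=keys,
        suffixes=("_base", "_variant"),
    )
    delta["delta_n_continuous"] = (
        delta.n_continuous_variant - delta.n_continuous_base
    )
    delta.to_csv(Path(variant_config.out_dir) / "delta_vs_base.csv", index=False)
    result["delta"] = delta
    result["base"] = base
    return result
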