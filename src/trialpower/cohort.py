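"""Diagnostic group construction and derived biomarker series.

Builds the three analysis groups used throughout the package from a wide
per-visit table:

- control: amyloid-negative, cognitively unimpaired (CDR global = 0);
- preclinical AD: amyloid-positive, CDR = 0;
- mild AD: amyloid-positive, CDR = 0.5 or 1;
- everything else is excluded, with a reason.

Amyloid status comes primarily from amyloid PET: a per-subject OLS
regression of longitudinal SUVR on time anchors status to baseline via the
intercept, thresholded at SUVR > 0.79.  Subjects without PET fall back to
CSF Abeta42 < 880 pg/mL.  CSF P-tau181 > 27 pg/mL defines tau positivity
for the sensitivity analysis.

The module also provides the derived outcome measures (PACC cognitive
composite, surface-area-weighted temporal cortical thickness composite),
pooled-baseline z-scoring, the per-modality eligibility filter
(at least two post-baseline observations of MRI, plasma NfL and cognition)
and the overlapping-visit intersection used as a sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import MODALITIES

__all__ = [
    "CohortConfig",
    "CohortAssignment",
    "CompositeSpec",
    "Standardization",
    "estimate_amyloid_intercept",
    "classify_amyloid",
    "assign_group",
    "build_assignments",
    "compute_pacc",
    "compute_temporal_composite",
    "standardize_biomarker",
    "filter_eligibility",
    "intersect_overlapping_visits",
]

PACC_COMPONENTS = ("mmse", "dmemory", "trailsb", "dadasc")
#: components where a larger raw value means worse cognition (sign-flipped)
PACC_NEGATIVE = ("trailsb",)

TEMPORAL_REGIONS = ("entorhinal", "fusiform", "inferiortemporal", "middletemporal")


@dataclass(frozen=True)
class CohortConfig:
    """Cutoffs and conventions for group construction."""

    suvr_cutoff: float = 0.79          # positive iff intercept strictly greater
    ab42_cutoff: float = 880.0         # pg/mL; positive iff strictly less
    ptau_cutoff: float = 27.0          # pg/mL; positive iff strictly greater
    overlap_tolerance: float = 1.5     # months, visit-cluster matching
    min_followups: int = 2             # post-baseline observations per modality
    log_pnfl: bool = False             # optional log-transform before z-scoring
    modalities: dict = field(default_factory=lambda: {k: tuple(v) for k, v in MODALITIES.items()})


@dataclass(frozen=True)
class CohortAssignment:
    subject_id: str
    group: str                 # control | preclinical_ad | mild_ad | excluded
    amyloid_status: str        # positive | negative | unknown
    amyloid_source: str        # pet_intercept | csf | none
    ptau_positive: bool | None
    eligible: bool = True
    exclusion_reason: str = ""


@dataclass(frozen=True)
class CompositeSpec:
    """A named composite: (source column, orientation sign, weight) triples."""

    name: str
    components: tuple
    reference_group: str = "pooled"

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("composite needs at least one component")
        if any(w <= 0 for _, _, w in self.components):
            raise ValueError("component weights must be strictly positive")


@dataclass(frozen=True)
class Standardization:
    """Provenance of a z-scoring transform: which baseline produced it."""

    biomarker: str
    baseline_mean: float
    baseline_sd: float
    n_reference: int
    reference: str = "pooled_baseline_eligible"


def estimate_amyloid_intercept(suvr_series) -> float:
    """OLS intercept of SUVR on time (months): estimated SUVR at baseline.

    ``suvr_series`` is an iterable of (visit_time, suvr).  A single
    observation is its own intercept; repeated observations at one time
    return their mean.  An empty series raises ``ValueError`` (caller falls
    back to CSF).
    """
    pairs = [(float(t), float(v)) for t, v in suvr_series]
    if not pairs:
        raise ValueError("empty SUVR series")
    t = np.array([p[0] for p in pairs])
    v = np.array([p[1] for p in pairs])
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
        raise ValueError("SUVR series contains non-finite values")
    if np.unique(t).size == 1:
        return float(v.mean())
    slope, intercept = np.polyfit(t, v, 1)
    return float(intercept)


def classify_amyloid(
    intercept: float | None,
    csf_ab42: float | None,
    config: CohortConfig = CohortConfig(),
) -> tuple[str, str]:
    """(amyloid_status, amyloid_source); PET intercept takes precedence."""
    if intercept is not None and not math.isnan(intercept):
        status = "positive" if intercept > config.suvr_cutoff else "negative"
        return status, "pet_intercept"
    if csf_ab42 is not None and not math.isnan(csf_ab42):
        status = "positive" if csf_ab42 < config.ab42_cutoff else "negative"
        return status, "csf"
    return "unknown", "none"


def assign_group(
    subject_id: str,
    baseline_cdr: float,
    amyloid_status: str,
    amyloid_source: str = "none",
    csf_ptau: float | None = None,
    config: CohortConfig = CohortConfig(),
) -> CohortAssignment:
    """Map (baseline CDR, amyloid status) to a diagnostic group.

    The mapping is a partition: CDR 0 splits on amyloid into control vs
    preclinical AD; CDR 0.5/1 with amyloid positivity is mild AD; anything
    else (CDR > 1, amyloid-negative impairment, unknown amyloid) is
    excluded with a reason.
    """
    ptau = None
    if csf_ptau is not None and not math.isnan(csf_ptau):
        ptau = bool(csf_ptau > config.ptau_cutoff)

    def make(group, reason=""):
        return CohortAssignment(
            subject_id=subject_id,
            group=group,
            amyloid_status=amyloid_status,
            amyloid_source=amyloid_source,
            ptau_positive=ptau,
            eligible=group != "excluded",
            exclusion_reason=reason,
        )

    if baseline_cdr is None or (isinstance(baseline_cdr, float) and math.isnan(baseline_cdr)):
        return make("excluded", "missing baseline CDR")
    if amyloid_status == "unknown":
        return make("excluded", "amyloid status unknown (no PET, no CSF)")
    if baseline_cdr == 0:
        return make("control" if amyloid_status == "negative" else "preclinical_ad")
    if baseline_cdr in (0.5, 1):
        if amyloid_status == "positive":
            return make("mild_ad")
        return make("excluded", "cognitively impaired but amyloid-negative")
    return make("excluded", f"CDR {baseline_cdr} beyond mild dementia")


def build_assignments(
    table: pd.DataFrame, config: CohortConfig = CohortConfig()
) -> list[CohortAssignment]:
    """Assign every subject in a wide per-visit table to a diagnostic group.

    Uses all non-missing SUVR observations for the PET intercept, the
    baseline CSF values, and CDR global at the earliest visit.
    """
    out = []
    for sid, sub in table.groupby("subject_id", sort=True):
        sub = sub.sort_values("visit_month")
        suvr = sub[["visit_month", "suvr"]].dropna()
        intercept = (
            estimate_amyloid_intercept(suvr.itertuples(index=False, name=None))
            if len(suvr)
            else None
        )
        base = sub.iloc[0]
        csf_ab42 = base.get("csf_ab42", np.nan)
        csf_ptau = base.get("csf_ptau", np.nan)
        status, source = classify_amyloid(
            intercept, None if pd.isna(csf_ab42) else float(csf_ab42), config
        )
        cdr = base.get("cdr_global", np.nan)
        out.append(
            assign_group(
                str(sid),
                None if pd.isna(cdr) else float(cdr),
                status,
                source,
                None if pd.isna(csf_ptau) else float(csf_ptau),
                config,
            )
        )
    return out


def assignments_frame(assignments) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": a.subject_id,
                "group": a.group,
                "amyloid_status": a.amyloid_status,
                "amyloid_source": a.amyloid_source,
                "ptau_positive": a.ptau_positive,
                "eligible": a.eligible,
                "exclusion_reason": a.exclusion_reason,
            }
            for a in assignments
        ]
    )


def compute_pacc(components: dict, reference_stats: dict) -> float:
    """Cognitive composite: equally weighted sum of four z-scored subtests.

    ``components`` maps {mmse, dmemory, trailsb, dadasc} to raw scores;
    ``reference_stats`` maps each to (baseline mean, baseline SD) of the
    reference group.  Each subtest is z-scored and oriented so that higher
    means better cognition (Trail-Making B is a completion time, so its
    z-score is sign-flipped), then the four are summed.  Any missing
    component yields NaN — partial composites are not pro-rated.
    """
    z_sum = 0.0
    for name in PACC_COMPONENTS:
        value = components.get(name)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return float("nan")
        mean, sd = reference_stats[name]
        if sd <= 0:
            raise ValueError(f"reference SD for {name!r} must be positive")
        z = (float(value) - mean) / sd
        if name in PACC_NEGATIVE:
            z = -z
        z_sum += z
    return z_sum


def compute_temporal_composite(regional: dict) -> float:
    """Surface-area-weighted mean cortical thickness over temporal regions.

    ``regional`` maps region name -> (thickness mm, surface area mm^2) for
    the entorhinal, fusiform, inferior temporal and middle temporal regions
    of both hemispheres (any consistent region keys are accepted).  A
    missing or non-positive-area region yields NaN rather than a partial
    composite.
    """
    if not regional:
        return float("nan")
    num = 0.0
    den = 0.0
    for region, pair in regional.items():
        if pair is None:
            return float("nan")
        thickness, area = pair
        if any(
            v is None or (isinstance(v, float) and math.isnan(v))
            for v in (thickness, area)
        ):
            return float("nan")
        if area <= 0:
            raise ValueError(f"surface area for {region!r} must be positive")
        num += float(thickness) * float(area)
        den += float(area)
    return num / den


def standardize_biomarker(
    table: pd.DataFrame,
    biomarker: str,
    reference_subjects=None,
    baseline_month: float = 0.0,
) -> tuple[pd.DataFrame, Standardization]:
    """Z-score a biomarker column against pooled baseline observations.

    The reference statistics are the mean and SD of the baseline
    (``visit_month == baseline_month``) values of ``reference_subjects``
    (default: all subjects present in the table).  Returns a copy of the
    table with the column transformed plus a provenance record.
    """
    ref = table if reference_subjects is None else table[
        table.subject_id.isin(reference_subjects)
    ]
    base = ref.loc[ref.visit_month == baseline_month, biomarker].dropna()
    if len(base) < 2:
        raise ValueError(
            f"need >= 2 baseline reference values for {biomarker!r}, got {len(base)}"
        )
    mean, sd = float(base.mean()), float(base.std(ddof=1))
    if sd == 0:
        raise ValueError(f"degenerate reference: baseline SD of {biomarker!r} is 0")
    out = table.copy()
    out[biomarker] = (out[biomarker] - mean) / sd
    return out, Standardization(
        biomarker=biomarker, baseline_mean=mean, baseline_sd=sd, n_reference=len(base)
    )


def filter_eligibility(
    table: pd.DataFrame, config: CohortConfig = CohortConfig()
) -> tuple[set, dict]:
    """Subjects with enough follow-up in every modality.

    A visit counts toward a modality when any of the modality's columns is
    observed; eligibility requires at least ``config.min_followups``
    post-baseline (visit_month > 0) observed visits in each of MRI, plasma
    NfL and cognition.  Returns (eligible subject set, per-subject
    exclusion reasons).
    """
    eligible: set = set()
    reasons: dict = {}
    if table.empty:
        return eligible, reasons
    for sid, sub in table.groupby("subject_id"):
        post = sub[sub.visit_month > 0]
        missing = []
        for modality, cols in config.modalities.items():
            cols = [c for c in cols if c in table.columns]
            if not cols:
                missing.append(f"{modality}: no columns present")
                continue
            n = int(post[cols].notna().any(axis=1).sum())
            if n < config.min_followups:
                missing.append(f"{modality}: {n} follow-ups")
        if missing:
            reasons[sid] = "insufficient follow-up (" + "; ".join(missing) + ")"
        else:
            eligible.add(sid)
    return eligible, reasons


def intersect_overlapping_visits(
    table: pd.DataFrame,
    nominal_schedule=None,
    config: CohortConfig = CohortConfig(),
) -> pd.DataFrame:
    """Keep only visit clusters where all modalities were observed.

    Observations are matched to the nearest nominal visit within
    ``config.overlap_tolerance`` months (unmatched rows are dropped);
    within a subject, rows mapping to the same nominal visit are merged
    (first non-missing value per column) and the cluster is retained only
    if every modality has an observation there.  Cluster rows carry the
    nominal visit time.  The output is a subset of the input's
    observations, and the operation is idempotent.
    """
    if table.empty:
        return table.copy()
    if nominal_schedule is None:
        nominal_schedule = sorted(table.visit_month.unique())
    nominal = np.asarray(sorted(nominal_schedule), dtype=float)

    months = table.visit_month.to_numpy(dtype=float)
    idx = np.clip(np.searchsorted(nominal, months), 0, nominal.size - 1)
    idx_lo = np.clip(idx - 1, 0, nominal.size - 1)
    nearer_lo = np.abs(months - nominal[idx_lo]) <= np.abs(nominal[idx] - months)
    idx = np.where(nearer_lo, idx_lo, idx)
    matched = np.abs(months - nominal[idx]) <= config.overlap_tolerance

    work = table.loc[matched].copy()
    work["_cluster"] = nominal[idx[matched]]

    value_cols = [c for c in table.columns if c not in ("subject_id", "visit_month")]
    merged = (
        work.groupby(["subject_id", "_cluster"], as_index=False, sort=True)
        .agg({c: "first" for c in value_cols})
        .rename(columns={"_cluster": "visit_month"})
    )
    modality_cols = [
        [c for c in cols if c in merged.columns]
        for cols in config.modalities.values()
    ]
    keep = np.ones(len(merged), dtype=bool)
    for cols in modality_cols:
        keep &= merged[cols].notna().any(axis=1) if cols else False
    out = merged.loc[keep].reset_index(drop=True)
    return out[["subject_id", "visit_month", *value_cols]]
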