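"""Synthetic ADNI-like longitudinal cohorts.

Generates control / preclinical AD / mild AD subjects whose biomarker
trajectories follow exactly the statistical model the analysis assumes:
per subject, a random intercept and slope drawn from a bivariate normal
around group means, plus i.i.d. within-subject noise::

    y(t) = baseline_mean + b0 + (slope_mean + b1) * t_years + eps_t

Observations sit on an ADNI-like visit grid (0/6/12/24/36/48/60 months)
thinned by monotone dropout and per-modality missingness.  Auxiliary
fields (amyloid PET SUVR observations, CSF Abeta42 / P-tau181, CDR global)
are generated consistently with group labels so the cohort-building stage
can be exercised end to end.

Biomarker values are in standardized (pooled-baseline SD) units and slopes
in SD/year; the default parameter table is illustrative, chosen to respect
the qualitative regime of the biomarkers it emulates (see
``default_params``), not to reproduce any estimate from real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GenerativeParams",
    "MissingnessModel",
    "SyntheticCohort",
    "BIOMARKERS",
    "GROUPS",
    "MODALITIES",
    "default_params",
    "default_missingness",
    "generate_subject",
    "generate_cohort",
    "load_params",
    "save_params",
]

GROUPS = ("control", "preclinical_ad", "mild_ad")
BIOMARKERS = ("pnfl", "temporal_composite", "hippocampus", "cdrsb", "pacc")
#: modality membership used for missingness and eligibility accounting
MODALITIES = {
    "mri": ("temporal_composite", "hippocampus"),
    "pnfl": ("pnfl",),
    "cognition": ("cdrsb", "pacc"),
}
ADNI_SCHEDULE = (0.0, 6.0, 12.0, 24.0, 36.0, 48.0, 60.0)

_PARAM_COLS = [
    "baseline_mean",
    "baseline_sd",
    "slope_mean",
    "slope_sd",
    "intercept_slope_corr",
    "resid_sd",
]


@dataclass(frozen=True)
class GenerativeParams:
    """Per (group, biomarker) trajectory parameters.

    ``table`` is indexed by (group, biomarker) with columns baseline_mean,
    baseline_sd (= sqrt intercept variance), slope_mean (units/year),
    slope_sd (= sqrt slope variance), intercept_slope_corr, resid_sd
    (= sqrt within-subject variance).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _PARAM_COLS if c not in self.table.columns]
        if missing:
            raise ValueError(f"params table missing columns {missing}")
        t = self.table
        if (t[["baseline_sd", "slope_sd", "resid_sd"]] < 0).any().any():
            raise ValueError("SDs must be non-negative")
        if (t["intercept_slope_corr"].abs() >= 1).any():
            raise ValueError("|intercept_slope_corr| must be < 1")

    def row(self, group: str, biomarker: str) -> pd.Series:
        return self.table.loc[(group, biomarker)]


@dataclass(frozen=True)
class MissingnessModel:
    """Schedule-based observation thinning.

    ``retention[j]`` is the probability of remaining in the study at visit j
    given presence at visit j-1 (dropout is monotone: once out, always out).
    ``modality_miss`` is an independent per-visit probability that a whole
    modality (all its biomarker columns) is unmeasured.
    """

    schedule: tuple[float, ...] = ADNI_SCHEDULE
    retention: tuple[float, ...] = (1.0, 0.97, 0.95, 0.92, 0.88, 0.82, 0.78)
    modality_miss: dict = field(
        default_factory=lambda: {"mri": 0.20, "pnfl": 0.25, "cognition": 0.05}
    )

    def __post_init__(self) -> None:
        if len(self.retention) != len(self.schedule):
            raise ValueError("retention must have one entry per scheduled visit")
        r = np.asarray(self.retention)
        if np.any((r < 0) | (r > 1)):
            raise ValueError("retention probabilities must be in [0,1]")
        for m, p in self.modality_miss.items():
            if not (0 <= p <= 1):
                raise ValueError(f"modality_miss[{m!r}] must be in [0,1]")
        if list(self.schedule) != sorted(self.schedule):
            raise ValueError("schedule must be sorted")


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated long table plus the truth that produced it."""

    table: pd.DataFrame
    truth: GenerativeParams
    missingness: MissingnessModel
    seed: int
    group_sizes: dict


def default_params() -> GenerativeParams:
    """Illustrative parameter table for 5 biomarkers x 3 groups (SD units).

    The values encode the qualitative regime of these biomarkers in early
    AD cohorts rather than estimates from any dataset:

    - plasma NfL: high within-subject (visit-to-visit) noise, the smallest
      between-subject slope spread, a substantial aging slope in controls,
      and only slightly faster progression in preclinical AD
      (+0.04 SD/year) and mild AD (+0.06 SD/year);
    - MRI measures (temporal cortical composite, hippocampal volume):
      low within-subject noise, steeper disease-group slopes than pNfL;
    - cognition (CDRSB, PACC): within-subject noise comparable to pNfL,
      small preclinical slopes, steep mild-AD slopes.

    Baseline offsets separate groups mildly for pNfL (+0.21 SD preclinical,
    +0.64 SD mild) and strongly for cognition in mild AD.
    """
    # group -> biomarker -> (baseline_mean, baseline_sd, slope_mean,
    #                        slope_sd, corr, resid_sd)
    spec = {
        "control": {
            "pnfl": (0.00, 0.90, 0.10, 0.05, 0.10, 0.65),
            "temporal_composite": (0.00, 0.95, -0.05, 0.10, 0.10, 0.15),
            "hippocampus": (0.00, 0.95, -0.05, 0.10, 0.10, 0.12),
            "cdrsb": (0.00, 0.30, 0.01, 0.10, 0.10, 0.50),
            "pacc": (0.00, 0.90, -0.02, 0.12, 0.10, 0.55),
        },
        "preclinical_ad": {
            "pnfl": (0.21, 0.90, 0.14, 0.05, 0.10, 0.65),
            "temporal_composite": (-0.20, 0.95, -0.15, 0.10, 0.15, 0.15),
            "hippocampus": (-0.20, 0.95, -0.16, 0.10, 0.15, 0.12),
            "cdrsb": (0.05, 0.35, 0.10, 0.18, 0.15, 0.50),
            "pacc": (-0.15, 0.95, -0.12, 0.15, 0.15, 0.55),
        },
        "mild_ad": {
            "pnfl": (0.64, 0.95, 0.16, 0.06, 0.10, 0.65),
            "temporal_composite": (-0.90, 1.00, -0.35, 0.16, 0.20, 0.15),
            "hippocampus": (-1.00, 1.00, -0.40, 0.16, 0.20, 0.12),
            "cdrsb": (1.60, 1.00, 0.55, 0.30, 0.20, 0.50),
            "pacc": (-1.60, 1.10, -0.50, 0.28, 0.20, 0.55),
        },
    }
    rows = []
    for group, bio in spec.items():
        for biomarker, vals in bio.items():
            rows.append((group, biomarker, *vals))
    table = pd.DataFrame(
        rows, columns=["group", "biomarker", *_PARAM_COLS]
    ).set_index(["group", "biomarker"])
    return GenerativeParams(table)


def default_missingness() -> MissingnessModel:
    return MissingnessModel()


def generate_subject(
    params_row: pd.Series, schedule_months, rng: np.random.Generator
) -> np.ndarray:
    """One subject's trajectory of a single biomarker on a visit schedule.

    Returns the vector of observations at ``schedule_months`` (no
    missingness applied at this level).
    """
    t_months = np.asarray(schedule_months, dtype=float)
    if t_months.size == 0:
        raise ValueError("schedule must be non-empty")
    if np.any(np.diff(t_months) < 0):
        raise ValueError("schedule must be sorted")
    p = params_row
    for key in ("baseline_sd", "slope_sd", "resid_sd"):
        if p[key] < 0:
            raise ValueError(f"{key} must be non-negative")
    # explicit Cholesky of the 2x2 random-effect covariance; robust to
    # zero SDs (degenerate, noise-free trajectories)
    z0, z1 = rng.standard_normal(2)
    rho = float(p.intercept_slope_corr)
    b0 = p.baseline_sd * z0
    b1 = p.slope_sd * (rho * z0 + np.sqrt(1.0 - rho**2) * z1)
    t_years = t_months / 12.0
    y = p.baseline_mean + b0 + (p.slope_mean + b1) * t_years
    if p.resid_sd > 0:
        y = y + rng.normal(0.0, p.resid_sd, t_years.size)
    return y


# auxiliary-variable regimes per group: means straddle the published
# cutoffs (SUVR 0.79, Abeta42 880, P-tau 27) with enough separation that
# generated labels match intended groups essentially always
_AUX = {
    "control": {"suvr": (0.68, 0.04), "ab42": (1450.0, 200.0), "ptau": (19.0, 6.0)},
    "preclinical_ad": {"suvr": (1.05, 0.09), "ab42": (640.0, 100.0), "ptau": (26.0, 8.0)},
    "mild_ad": {"suvr": (1.10, 0.10), "ab42": (620.0, 100.0), "ptau": (34.0, 10.0)},
}


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    # per-subject stream keyed by (seed, index): reproducible regardless of
    # generation order or group sizes
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def generate_cohort(
    group_sizes: dict[str, int] | None = None,
    params: GenerativeParams | None = None,
    missingness: MissingnessModel | None = None,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate a wide per-visit long table for all groups and biomarkers.

    Columns: subject_id, group (truth label), visit_month, cdr_global,
    suvr, csf_ab42, csf_ptau and one column per biomarker.  Missing cells
    are NaN.  Deterministic under (group_sizes, params, missingness, seed).
    """
    group_sizes = dict(group_sizes or {"control": 100, "preclinical_ad": 100, "mild_ad": 100})
    for g, n in group_sizes.items():
        if g not in GROUPS:
            raise ValueError(f"unknown group {g!r}")
        if n <= 0:
            raise ValueError("group sizes must be positive")
    params = params or default_params()
    miss = missingness or default_missingness()
    sched = np.asarray(miss.schedule, dtype=float)

    rows = []
    index = 0
    for group in GROUPS:
        if group not in group_sizes:
            continue
        for _ in range(group_sizes[group]):
            rng = _subject_rng(seed, index)
            sid = f"S{index:05d}"

            # monotone dropout: first failed retention draw ends follow-up
            present = np.ones(sched.size, dtype=bool)
            for j, r in enumerate(miss.retention):
                if rng.random() > r:
                    present[j:] = False
                    break
            n_vis = int(present.sum())
            if n_vis == 0:
                present[0] = True
                n_vis = 1
            visits = sched[present]

            traj = {
                b: generate_subject(params.row(group, b), visits, rng)
                for b in BIOMARKERS
            }
            # per-visit modality missingness
            mod_present = {
                m: rng.random(n_vis) >= p for m, p in miss.modality_miss.items()
            }

            aux = _AUX[group]
            suvr_true = rng.normal(*aux["suvr"])
            suvr_slope = rng.normal(0.01, 0.005)
            csf_ab42 = rng.normal(*aux["ab42"])
            csf_ptau = rng.normal(*aux["ptau"])
            if group == "mild_ad":
                cdr = 0.5 if rng.random() < 0.83 else 1.0
            else:
                cdr = 0.0
            # PET visits: up to three early visits carry a SUVR observation
            suvr_visits = set(visits[: min(3, n_vis)])

            for j, vm in enumerate(visits):
                row = {
                    "subject_id": sid,
                    "group": group,
                    "visit_month": vm,
                    "cdr_global": cdr,
                    "suvr": (
                        suvr_true + suvr_slope * vm / 12.0 + rng.normal(0, 0.01)
                        if vm in suvr_visits
                        else np.nan
                    ),
                    "csf_ab42": csf_ab42 if j == 0 else np.nan,
                    "csf_ptau": csf_ptau if j == 0 else np.nan,
                }
                for m, members in MODALITIES.items():
                    ok = mod_present[m][j]
                    for b in members:
                        row[b] = traj[b][j] if ok else np.nan
                rows.append(row)
            index += 1

    table = pd.DataFrame(rows)
    return SyntheticCohort(
        table=table, truth=params, missingness=miss, seed=seed,
        group_sizes=group_sizes,
    )


def save_params(params: GenerativeParams, path) -> None:
    nested: dict = {}
    for (group, biomarker), row in params.table.iterrows():
        nested.setdefault(group, {})[biomarker] = {
            c: float(row[c]) for c in _PARAM_COLS
        }
    with open(path, "w") as fh:
        yaml.safe_dump(nested, fh, sort_keys=True)


def load_params(path) -> GenerativeParams:
    with open(path) as fh:
        nested = yaml.safe_load(fh)
    rows = []
    for group, bio in nested.items():
        for biomarker, vals in bio.items():
            rows.append((group, biomarker, *[vals[c] for c in _PARAM_COLS]))
    table = pd.DataFrame(
        rows, columns=["group", "biomarker", *_PARAM_COLS]
    ).set_index(["group", "biomarker"])
    return GenerativeParams(table)
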