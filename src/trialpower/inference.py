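"""Uncertainty quantification for required sample sizes.

Three tools:

- subject-level percentile bootstrap of the per-arm n for one biomarker
  (resampling subjects, never observations, so the within/between variance
  decomposition survives resampling);
- paired bootstrap comparison of two biomarkers measured on the same
  subject pool (each replicate reuses one subject resample for both
  biomarkers, so the difference distribution reflects genuinely paired
  uncertainty);
- Monte-Carlo power validation: simulate two-arm trials at a proposed n
  under the generative truth and measure the empirical rejection rate of
  the treatment-by-time interaction — the independent check on the
  closed-form sample-size formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import lme, power
from .power import TrialDesign, UnpoweredError

__all__ = [
    "BootstrapResult",
    "ComparisonResult",
    "bootstrap_sample_size",
    "bootstrap_compare",
    "mc_power_validate",
]


@dataclass(frozen=True)
class BootstrapResult:
    biomarker: str
    group: str
    design: TrialDesign
    B: int
    n_distribution: np.ndarray  # length B; NaN where the replicate failed
    point: float                # full-data continuous n
    ci_low: float
    ci_high: float
    convergence_rate: float
    usable: bool

    def __post_init__(self) -> None:
        if self.B < 2:
            raise ValueError("need at least 2 bootstrap iterations")


@dataclass(frozen=True)
class ComparisonResult:
    biomarker_a: str
    biomarker_b: str
    diff_distribution: np.ndarray  # n_a - n_b per paired replicate
    p_value: float
    direction: str


def _n_from_table(
    table: pd.DataFrame,
    biomarker: str,
    design: TrialDesign,
    control_table: pd.DataFrame | None,
    engine: str,
    start=None,
    control_start=None,
) -> float:
    """Fit the LME(s) and evaluate the closed form; the bootstrap workhorse."""
    fit = lme.fit_slope_model(
        table, biomarker, engine=engine, biomarker=biomarker, start=start
    )
    if not fit.converged:
        raise lme.NotConvergedError(biomarker)
    control_fit = None
    if design.mechanism == "disease_specific":
        if control_table is None:
            raise ValueError("disease_specific mechanism needs a control table")
        control_fit = lme.fit_slope_model(
            control_table, biomarker, engine=engine, biomarker=biomarker,
            start=control_start,
        )
        if not control_fit.converged:
            raise lme.NotConvergedError(f"control {biomarker}")
    sw2, sb2, slope = lme.extract_power_inputs(fit, control_fit, design.mechanism)
    delta = power.detectable_delta(slope, design.effect_fraction)
    res = power.n_per_arm(
        sw2, sb2, design.schedule(), delta, design.alpha, design.target_power
    )
    return res.n_continuous


def _warm_starts(table, control_table, biomarker, design, engine):
    """Full-data variance solutions used to warm-start replicate refits."""
    if engine != "native":
        return None, None

    def _try(tab):
        if tab is None:
            return None
        try:
            fit = lme.fit_slope_model(tab, biomarker, engine=engine)
        except (lme.InsufficientDataError, lme.NotConvergedError):
            return None
        if not fit.converged or fit.method != "native:unstructured":
            return None
        return lme.start_from_fit(fit)

    control = (
        _try(control_table) if design.mechanism == "disease_specific" else None
    )
    return _try(table), control


def _resample(table: pd.DataFrame, subjects: np.ndarray, rng) -> pd.DataFrame:
    """Draw subjects with replacement; relabel duplicates as distinct subjects."""
    picks = rng.choice(subjects, size=subjects.size, replace=True)
    parts = []
    groups = dict(tuple(table.groupby("subject_id", sort=False)))
    for j, sid in enumerate(picks):
        part = groups[sid].copy()
        part["subject_id"] = f"B{j:05d}"
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def bootstrap_sample_size(
    table: pd.DataFrame,
    biomarker: str,
    design: TrialDesign,
    B: int = 250,
    seed: int = 0,
    *,
    control_table: pd.DataFrame | None = None,
    engine: str = "native",
    group: str = "",
) -> BootstrapResult:
    """Percentile 95% CI for the continuous per-arm n by subject resampling.

    Each replicate resamples subjects with replacement within the group
    (and, under the disease-specific mechanism, independently within the
    control group), refits the model and re-evaluates the closed form.
    Non-converging replicates are recorded as NaN; if more than half fail
    the result is flagged unusable.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap iterations")
    point = _n_from_table(table, biomarker, design, control_table, engine)
    start, control_start = _warm_starts(
        table, control_table, biomarker, design, engine
    )
    subjects = table.subject_id.unique()
    control_subjects = (
        control_table.subject_id.unique() if control_table is not None else None
    )
    rng = np.random.default_rng(seed)
    ns = np.full(B, np.nan)
    for b in range(B):
        boot = _resample(table, subjects, rng)
        boot_control = (
            _resample(control_table, control_subjects, rng)
            if control_table is not None and design.mechanism == "disease_specific"
            else None
        )
        try:
            ns[b] = _n_from_table(
                boot, biomarker, design, boot_control, engine, start, control_start
            )
        except (lme.NotConvergedError, lme.InsufficientDataError, UnpoweredError, ValueError):
            continue
    ok = np.isfinite(ns)
    conv = float(ok.mean())
    if ok.sum() >= 2:
        lo, hi = np.percentile(ns[ok], [2.5, 97.5])
    else:
        lo = hi = np.nan
    return BootstrapResult(
        biomarker=biomarker,
        group=group,
        design=design,
        B=B,
        n_distribution=ns,
        point=point,
        ci_low=float(lo),
        ci_high=float(hi),
        convergence_rate=conv,
        usable=conv >= 0.5,
    )


def bootstrap_compare(
    table: pd.DataFrame,
    biomarker_a: str,
    biomarker_b: str,
    design_a: TrialDesign,
    design_b: TrialDesign,
    B: int = 250,
    seed: int = 0,
    *,
    control_table: pd.DataFrame | None = None,
    engine: str = "native",
) -> ComparisonResult:
    """Paired bootstrap test of n_a vs n_b on a shared subject pool.

    Each replicate draws ONE subject resample and evaluates both biomarkers
    on it, so sampling noise cancels in the difference.  The two-sided
    add-one p-value is ``2 * min(#{diff<=0}+1, #{diff>=0}+1) / (B+1)``
    (capped at 1); its floor is 2/(B+1), so B=250 can report at most
    p < 0.008 — published "<0.0001" bounds need correspondingly large B.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap iterations")
    subjects = table.subject_id.unique()
    control_subjects = (
        control_table.subject_id.unique() if control_table is not None else None
    )
    start_a, cstart_a = _warm_starts(table, control_table, biomarker_a, design_a, engine)
    start_b, cstart_b = _warm_starts(table, control_table, biomarker_b, design_b, engine)
    rng = np.random.default_rng(seed)
    diffs = np.full(B, np.nan)
    for b in range(B):
        boot = _resample(table, subjects, rng)
        boot_control = (
            _resample(control_table, control_subjects, rng)
            if control_table is not None
            and "disease_specific" in (design_a.mechanism, design_b.mechanism)
            else None
        )
        try:
            na = _n_from_table(
                boot, biomarker_a, design_a, boot_control, engine, start_a, cstart_a
            )
            nb = _n_from_table(
                boot, biomarker_b, design_b, boot_control, engine, start_b, cstart_b
            )
            diffs[b] = na - nb
        except (lme.NotConvergedError, lme.InsufficientDataError, UnpoweredError, ValueError):
            continue
    ok = np.isfinite(diffs)
    d = diffs[ok]
    if d.size == 0:
        raise RuntimeError("all paired bootstrap replicates failed")
    n_le = int(np.sum(d <= 0))
    n_ge = int(np.sum(d >= 0))
    p = min(1.0, 2.0 * (min(n_le, n_ge) + 1) / (d.size + 1))
    med = float(np.median(d))
    if med > 0:
        direction = f"{biomarker_b} requires fewer subjects than {biomarker_a}"
    elif med < 0:
        direction = f"{biomarker_a} requires fewer subjects than {biomarker_b}"
    else:
        direction = "no direction (median difference 0)"
    return ComparisonResult(
        biomarker_a=biomarker_a,
        biomarker_b=biomarker_b,
        diff_distribution=diffs,
        p_value=float(p),
        direction=direction,
    )


def mc_power_validate(
    sigma_w_sq: float,
    sigma_b_sq: float,
    slope_mean: float,
    n_per_arm: int,
    design: TrialDesign,
    nsim: int = 2000,
    seed: int = 0,
    *,
    control_slope: float = 0.0,
    engine: str = "slope_test",
) -> tuple[float, float]:
    """Empirical power of a two-arm trial at a proposed per-arm n.

    Simulates ``nsim`` complete balanced trials on the design's schedule:
    the control arm progresses at ``slope_mean``, the treated arm at the
    mechanism-reduced slope, both with slope variance ``sigma_b_sq`` and
    residual variance ``sigma_w_sq``; each trial tests the arm to slope
    (treatment-by-time) contrast two-sided at the design's alpha.  Returns
    (rejection fraction, its binomial standard error).

    The default test exploits the balanced-complete-data identity: the
    mixed-model GLS interaction estimate equals the difference in arm means
    of per-subject OLS slopes, whose sampling variance is
    ``sigma_b_sq + sigma_w_sq/ssq``; the pooled two-sample t on per-subject
    slopes is therefore the exact-degrees-of-freedom version of the
    interaction Wald test and runs vectorised.  ``engine="lme"`` refits the
    full interaction LME per trial instead (slow; used as a cross-check).
    """
    if nsim < 100:
        raise ValueError("nsim must be at least 100")
    if n_per_arm < 2:
        raise ValueError("need at least 2 subjects per arm")
    sched = design.schedule()
    t = np.asarray(sched.times)
    f = design.effect_fraction
    if design.mechanism == "full":
        treated_slope = (1.0 - f) * slope_mean
    else:
        treated_slope = slope_mean - f * (slope_mean - control_slope)
    rng = np.random.default_rng(seed)
    n = int(n_per_arm)
    sb = np.sqrt(sigma_b_sq)
    sw = np.sqrt(sigma_w_sq)
    ssq = sched.ssq
    w = (t - t.mean()) / ssq  # per-subject OLS slope weights

    if engine == "slope_test":
        crit = stats.t.ppf(1 - design.alpha / 2, df=2 * n - 2)
        rejections = 0
        for _ in range(nsim):
            # subject-level true slopes then observation noise, both arms
            slopes0 = slope_mean + rng.normal(0, sb, n)
            slopes1 = treated_slope + rng.normal(0, sb, n)
            eps0 = rng.normal(0, sw, (n, t.size))
            eps1 = rng.normal(0, sw, (n, t.size))
            # per-subject OLS slope: intercept/random intercept drop out of w
            b0_hat = slopes0 + eps0 @ w
            b1_hat = slopes1 + eps1 @ w
            diff = b1_hat.mean() - b0_hat.mean()
            pooled = 0.5 * (b0_hat.var(ddof=1) + b1_hat.var(ddof=1))
            tstat = diff / np.sqrt(2.0 * pooled / n)
            rejections += abs(tstat) > crit
    elif engine == "lme":
        rejections = 0
        months = t * 12.0
        for _ in range(nsim):
            frames = []
            for arm, mu in ((0.0, slope_mean), (1.0, treated_slope)):
                slopes = mu + rng.normal(0, sb, n)
                icpts = rng.normal(0, 1.0, n)
                y = icpts[:, None] + slopes[:, None] * t[None, :] + rng.normal(
                    0, sw, (n, t.size)
                )
                frames.append(
                    pd.DataFrame(
                        {
                            "subject_id": np.repeat(
                                [f"A{arm:.0f}_{i}" for i in range(n)], t.size
                            ),
                            "visit_month": np.tile(months, n),
                            "value": y.ravel(),
                            "group": "treated" if arm else "control",
                        }
                    )
                )
            trial = pd.concat(frames, ignore_index=True)
            contrast = lme.fit_group_interaction(
                trial, "control", "treated", engine="native"
            )
            rejections += contrast.p_value < design.alpha
    else:
        raise ValueError(f"unknown engine {engine!r}")

    phat = rejections / nsim
    se = float(np.sqrt(phat * (1 - phat) / nsim))
    return float(phat), se
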