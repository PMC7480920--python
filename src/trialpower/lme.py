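"""Random-intercept/random-slope model fits per biomarker and group.

The model for subject i at visit time t_ij (years from baseline) is::

    y_ij = beta0 + beta1 * t_ij + b0_i + b1_i * t_ij + e_ij

with (b0_i, b1_i) ~ N(0, D) unstructured and e_ij ~ N(0, sigma_w^2),
estimated by REML.  The two quantities the power formula consumes are
``sigma_w_sq`` (residual variance: scatter of a subject's points around
their own line) and ``sigma_b_sq = D[1,1]`` (variance of subject slopes
around the group slope).  The intercept variance never enters the formula.

Two estimation engines are available and agree to optimiser tolerance:
``statsmodels`` (MixedLM, the default for one-off fits) and ``native`` (a
profiled-REML solver specialised to this model, used for bootstrap and
Monte-Carlo work where thousands of refits are needed).

Non-convergence is handled by a fallback ladder — unstructured, then
diagonal random-effect covariance, then random intercept only — and always
reported via ``LMEFit.converged`` / ``LMEFit.method``; downstream consumers
refuse non-converged fits unless forced.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import _reml

__all__ = [
    "LMEFit",
    "GroupContrast",
    "fit_slope_model",
    "fit_group_interaction",
    "extract_power_inputs",
    "NotConvergedError",
    "InsufficientDataError",
]

MONTHS_PER_YEAR = 12.0


class InsufficientDataError(ValueError):
    pass


class NotConvergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class LMEFit:
    """REML fit of the random-slope model for one biomarker x group."""

    beta0: float
    beta1: float
    se_beta1: float
    sigma_b0_sq: float
    sigma_b1_sq: float
    cov_b0b1: float
    sigma_w_sq: float
    n_subjects: int
    n_obs: int
    converged: bool
    method: str  # "<engine>:<structure>"
    biomarker: str = ""
    group: str = ""

    @property
    def sigma_b_sq(self) -> float:
        """Alias: the between-subject (slope) variance the power formula uses."""
        return self.sigma_b1_sq

    def wald_ci_beta1(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        return (self.beta1 - z * self.se_beta1, self.beta1 + z * self.se_beta1)

    def to_json(self, **extra) -> str:
        d = asdict(self)
        d.update(extra)
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass(frozen=True)
class GroupContrast:
    """Slope and baseline differences between two groups from one joint fit."""

    delta_beta: float      # slope(B) - slope(A), units/year
    se: float
    p_value: float
    baseline_diff: float   # intercept(B) - intercept(A)
    baseline_p: float
    converged: bool
    method: str


def _as_years(visit_month: np.ndarray) -> np.ndarray:
    return np.asarray(visit_month, dtype=float) / MONTHS_PER_YEAR


def _validate(
    df: pd.DataFrame,
    value_col: str,
    min_subjects: int = 2,
    extra_cols: tuple[str, ...] = (),
) -> pd.DataFrame:
    d = df[["subject_id", "visit_month", value_col, *extra_cols]].dropna(
        subset=["subject_id", "visit_month", value_col]
    )
    if d.empty:
        raise InsufficientDataError(f"no observations for {value_col!r}")
    counts = d.groupby("subject_id").size()
    keep = counts[counts >= 2].index
    d = d[d.subject_id.isin(keep)]
    if d.subject_id.nunique() < min_subjects:
        raise InsufficientDataError(
            f"need >= {min_subjects} subjects with >= 2 observations for "
            f"{value_col!r}, found {d.subject_id.nunique()}"
        )
    return d


_LADDER = ("unstructured", "diagonal", "intercept_only")


def _fit_statsmodels(groups, t, y, x_subject, structure):
    from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

    if x_subject is None:
        X = np.column_stack([np.ones_like(t), t])
    else:
        X = np.column_stack([np.ones_like(t), t, x_subject, x_subject * t])
    if structure == "intercept_only":
        exog_re = np.ones((t.size, 1))
    else:
        exog_re = np.column_stack([np.ones_like(t), t])
    model = MixedLM(y, X, groups=groups, exog_re=exog_re)
    fit_kw = {"reml": True}
    if structure == "diagonal":
        fit_kw["free"] = MixedLMParams.from_components(
            fe_params=np.ones(X.shape[1]), cov_re=np.eye(2)
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(**fit_kw)
    cov_re = np.zeros((2, 2))
    cr = np.atleast_2d(np.asarray(res.cov_re))
    cov_re[: cr.shape[0], : cr.shape[1]] = cr
    return _reml.RemlFit(
        beta=np.asarray(res.fe_params),
        cov_beta=np.asarray(res.cov_params())[: X.shape[1], : X.shape[1]],
        sigma_w_sq=float(res.scale),
        cov_re=cov_re,
        structure=structure,
        converged=bool(res.converged),
        loglike=float(res.llf),
        n_subjects=int(len(np.unique(groups))),
        n_obs=int(t.size),
    )


def _fit_native(groups, t, y, x_subject, structure, start=None):
    return _reml.reml_fit(
        groups, t, y, x_subject=x_subject, structure=structure, start=start
    )


def _fit_ladder(groups, t, y, x_subject, engine, start=None):
    fitter = {"statsmodels": _fit_statsmodels, "native": _fit_native}[engine]
    last = None
    for structure in _LADDER:
        try:
            if engine == "native":
                res = fitter(groups, t, y, x_subject, structure,
                             start if structure == "unstructured" else None)
            else:
                res = fitter(groups, t, y, x_subject, structure)
        except (np.linalg.LinAlgError, ValueError):
            continue
        last = res
        if res.converged and np.all(np.isfinite(res.beta)):
            return res, structure
    if last is None:
        raise NotConvergedError("all random-effect structures failed to fit")
    return last, last.structure


def fit_slope_model(
    df: pd.DataFrame,
    value_col: str = "value",
    *,
    engine: str = "statsmodels",
    biomarker: str = "",
    group: str = "",
    start=None,
) -> LMEFit:
    """Fit the random-slope model to one biomarker's long table.

    ``df`` needs columns ``subject_id``, ``visit_month`` and ``value_col``;
    missing values are dropped, subjects with fewer than two observations
    are excluded, and times are converted months -> years so that slopes
    and slope variances are per-year.  ``start`` (native engine only) warm
    starts the variance optimisation from a previous fit via
    :func:`start_from_fit`.
    """
    d = _validate(df, value_col)
    t = _as_years(d.visit_month.to_numpy())
    y = d[value_col].to_numpy(dtype=float)
    g = d.subject_id.to_numpy()
    res, structure = _fit_ladder(g, t, y, None, engine, start)
    return LMEFit(
        beta0=float(res.beta[0]),
        beta1=float(res.beta[1]),
        se_beta1=float(np.sqrt(max(res.cov_beta[1, 1], 0.0))),
        sigma_b0_sq=float(res.cov_re[0, 0]),
        sigma_b1_sq=float(res.cov_re[1, 1]),
        cov_b0b1=float(res.cov_re[0, 1]),
        sigma_w_sq=float(res.sigma_w_sq),
        n_subjects=res.n_subjects,
        n_obs=res.n_obs,
        converged=res.converged,
        method=f"{engine}:{structure}",
        biomarker=biomarker,
        group=group,
    )


def start_from_fit(fit: LMEFit) -> np.ndarray:
    """Scaled random-effect covariance G = D / sigma_w^2 for warm starts."""
    if fit.sigma_w_sq <= 0:
        raise ValueError("fit has non-positive residual variance")
    D = np.array(
        [[fit.sigma_b0_sq, fit.cov_b0b1], [fit.cov_b0b1, fit.sigma_b1_sq]]
    )
    return D / fit.sigma_w_sq


def fit_group_interaction(
    df: pd.DataFrame,
    group_a: str,
    group_b: str,
    value_col: str = "value",
    group_col: str = "group",
    *,
    engine: str = "statsmodels",
) -> GroupContrast:
    """Joint two-group fit with a group x time interaction.

    Fits ``y = beta0 + beta_g*g + beta_t*t + beta_gt*(g*t) + b0 + b1*t + e``
    with g = 1 for ``group_b``; returns the slope contrast beta_gt (how much
    faster group B progresses per year) and the baseline contrast beta_g,
    each with a two-sided Wald p-value.
    """
    d = df[df[group_col].isin([group_a, group_b])]
    for name in (group_a, group_b):
        if not (d[group_col] == name).any():
            raise InsufficientDataError(f"group {name!r} has no rows")
    d = _validate(
        d.assign(_g=(d[group_col] == group_b).astype(float)),
        value_col,
        extra_cols=("_g",),
    )
    t = _as_years(d.visit_month.to_numpy())
    y = d[value_col].to_numpy(dtype=float)
    g = d.subject_id.to_numpy()
    x = d["_g"].to_numpy(dtype=float)
    res, structure = _fit_ladder(g, t, y, x, engine)
    i_g, i_gt = 2, 3  # both engines order fixed effects as [1, t, g, g*t]
    beta = res.beta
    se = np.sqrt(np.maximum(np.diag(res.cov_beta), 0.0))
    z_gt = beta[i_gt] / se[i_gt] if se[i_gt] > 0 else np.inf
    z_g = beta[i_g] / se[i_g] if se[i_g] > 0 else np.inf
    return GroupContrast(
        delta_beta=float(beta[i_gt]),
        se=float(se[i_gt]),
        p_value=float(2 * stats.norm.sf(abs(z_gt))),
        baseline_diff=float(beta[i_g]),
        baseline_p=float(2 * stats.norm.sf(abs(z_g))),
        converged=res.converged,
        method=f"{engine}:{structure}",
    )


def extract_power_inputs(
    fit: LMEFit,
    control_fit: LMEFit | None = None,
    mechanism: str = "full",
    *,
    force: bool = False,
) -> tuple[float, float, float]:
    """(sigma_w_sq, sigma_b_sq, slope_for_delta) for the sample-size formula.

    mechanism "full": the treatment can abolish the whole group slope, so the
    detectable effect is a fraction of ``beta1``.  "disease_specific": only
    progression beyond normal aging is treatable, so the relevant slope is
    ``beta1(group) - beta1(control)``.
    """
    if mechanism not in ("full", "disease_specific"):
        raise ValueError(f"unknown mechanism {mechanism!r}")
    if not fit.converged and not force:
        raise NotConvergedError(
            f"fit for {fit.biomarker or 'biomarker'}/{fit.group or 'group'} "
            "did not converge; pass force=True to use it anyway"
        )
    if mechanism == "full":
        slope = fit.beta1
    else:
        if control_fit is None:
            raise ValueError("disease_specific mechanism requires a control fit")
        if not control_fit.converged and not force:
            raise NotConvergedError("control fit did not converge")
        slope = fit.beta1 - control_fit.beta1
    return fit.sigma_w_sq, fit.sigma_b1_sq, slope
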