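"""Closed-form power and per-arm sample size for slope contrasts in
random-slope longitudinal models.

The central quantity is the per-arm sample size required to detect, with
power ``1 - beta`` at two-sided level ``alpha``, a difference ``delta`` in
the mean rate of change between two trial arms measured repeatedly on the
schedule ``t_1 .. t_J``::

    n_per_arm = 2 * (z_{1-alpha/2} + z_{1-power})**2
                  * (sigma_b^2 + sigma_w^2 / ssq) / delta**2

where ``ssq = sum_j (t_j - tbar)^2`` summarises trial duration and sampling
frequency, ``sigma_w^2`` is the within-subject (residual) variance around a
subject's own line and ``sigma_b^2`` is the between-subject variance of
individual slopes.  ``sigma_b^2 + sigma_w^2/ssq`` is exactly the sampling
variance of one subject's ordinary-least-squares slope, so the formula is
the classical two-sample normal calculation applied to per-subject slopes.

All public entry points take times in *months* at the interface (matching
visit schedules as recorded in study data) and convert to years internally,
so slopes and variances are per-year quantities.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "VisitSchedule",
    "TrialDesign",
    "SampleSizeResult",
    "build_schedule",
    "schedule_ssq",
    "detectable_delta",
    "n_per_arm",
    "power_at_n",
    "sweep",
]


class UnpoweredError(ValueError):
    """Raised when the detectable effect is zero (required n is infinite)."""


@dataclass(frozen=True)
class VisitSchedule:
    """Assessment times of one biomarker within a trial, in years from baseline."""

    times: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size < 2 or np.unique(t).size < 2:
            raise ValueError("a schedule needs at least two distinct visit times")
        if not np.all(np.isfinite(t)):
            raise ValueError("visit times must be finite")

    @property
    def tbar(self) -> float:
        return float(np.mean(self.times))

    @property
    def ssq(self) -> float:
        """Sum of squared deviations of visit times from their mean (years^2)."""
        return schedule_ssq(self.times)

    @property
    def n_visits(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class TrialDesign:
    """A two-arm trial layout: duration, sampling frequency and test settings.

    duration, frequency are in months; ``effect_fraction`` is the assumed
    fractional reduction of progression under treatment; ``mechanism``
    selects which slope the reduction applies to ("full": the whole group
    slope can be abolished; "disease_specific": only slope in excess of the
    control group's).
    """

    duration: float
    frequency: float
    alpha: float = 0.05
    target_power: float = 0.80
    effect_fraction: float = 0.30
    mechanism: str = "full"
    anchor_end: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.frequency <= self.duration):
            raise ValueError(
                f"need 0 < frequency <= duration, got {self.frequency}/{self.duration}"
            )
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if not (0 < self.target_power < 1):
            raise ValueError(f"target_power must be in (0,1), got {self.target_power}")
        if not (0 < self.effect_fraction <= 1):
            raise ValueError(
                f"effect_fraction must be in (0,1], got {self.effect_fraction}"
            )
        if self.mechanism not in ("full", "disease_specific"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")

    def schedule(self) -> VisitSchedule:
        return build_schedule(self.duration, self.frequency, anchor_end=self.anchor_end)


@dataclass(frozen=True)
class SampleSizeResult:
    """Per-arm sample size with a full echo of the inputs that produced it."""

    n_continuous: float
    n_per_arm: int
    sigma_w_sq: float
    sigma_b_sq: float
    delta: float
    schedule: VisitSchedule
    alpha: float
    target_power: float
    z_alpha: float
    z_power: float

    def to_dict(self) -> dict:
        return {
            "n_continuous": self.n_continuous,
            "n_per_arm": self.n_per_arm,
            "sigma_w_sq": self.sigma_w_sq,
            "sigma_b_sq": self.sigma_b_sq,
            "delta": self.delta,
            "schedule_years": list(self.schedule.times),
            "ssq": self.schedule.ssq,
            "alpha": self.alpha,
            "target_power": self.target_power,
            "z_alpha": self.z_alpha,
            "z_power": self.z_power,
        }


def build_schedule(
    duration: float, frequency: float, *, anchor_end: bool = False
) -> VisitSchedule:
    """Visit times {0, f, 2f, ...} months up to ``duration``, returned in years.

    The last generated visit is the largest multiple of ``frequency`` that
    does not exceed ``duration``; with ``anchor_end=True`` a final visit at
    ``duration`` itself is appended when the grid does not land on it.
    """
    if not (0 < frequency <= duration):
        raise ValueError("need 0 < frequency <= duration")
    n_steps = int(math.floor(duration / frequency + 1e-9))
    months = [k * frequency for k in range(n_steps + 1)]
    if anchor_end and months[-1] < duration - 1e-9:
        months.append(float(duration))
    if len(months) < 2:
        raise ValueError(
            f"schedule ({duration}, {frequency}) yields fewer than two visits"
        )
    return VisitSchedule(tuple(m / 12.0 for m in months))


def schedule_ssq(times: Sequence[float]) -> float:
    """Sum of squared deviations of visit times from their mean."""
    t = np.asarray(times, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two visit times")
    return float(np.sum((t - t.mean()) ** 2))


def detectable_delta(slope_for_delta: float, effect_fraction: float) -> float:
    """The slope reduction a trial must detect: a fraction of the progression rate.

    Returns a magnitude; the sign of the slope is irrelevant because delta
    enters the sample-size formula squared.
    """
    if not (0 < effect_fraction <= 1):
        raise ValueError("effect_fraction must be in (0, 1]")
    if slope_for_delta == 0:
        raise UnpoweredError(
            "slope is zero: no treatment effect to detect, required n is infinite"
        )
    return abs(effect_fraction * slope_for_delta)


def _check_variances(sigma_w_sq: float, sigma_b_sq: float) -> None:
    if sigma_w_sq < 0 or sigma_b_sq < 0:
        raise ValueError("variance components must be non-negative")
    if sigma_w_sq == 0 and sigma_b_sq == 0:
        raise ValueError("sigma_w_sq and sigma_b_sq cannot both be zero")


def n_per_arm(
    sigma_w_sq: float,
    sigma_b_sq: float,
    schedule: VisitSchedule,
    delta: float,
    alpha: float = 0.05,
    power: float = 0.80,
) -> SampleSizeResult:
    """Per-arm sample size for a slope contrast under a random-slope model."""
    _check_variances(sigma_w_sq, sigma_b_sq)
    if delta == 0:
        raise UnpoweredError("delta is zero; the design is unpowered at any n")
    if delta < 0:
        delta = abs(delta)
    z_a = float(stats.norm.ppf(1 - alpha / 2))
    z_p = float(stats.norm.ppf(power))
    slope_var = sigma_b_sq + sigma_w_sq / schedule.ssq
    n_cont = 2.0 * (z_a + z_p) ** 2 * slope_var / delta**2
    return SampleSizeResult(
        n_continuous=n_cont,
        n_per_arm=max(1, math.ceil(n_cont - 1e-12)),
        sigma_w_sq=sigma_w_sq,
        sigma_b_sq=sigma_b_sq,
        delta=delta,
        schedule=schedule,
        alpha=alpha,
        target_power=power,
        z_alpha=z_a,
        z_power=z_p,
    )


def power_at_n(
    n: float,
    sigma_w_sq: float,
    sigma_b_sq: float,
    schedule: VisitSchedule,
    delta: float,
    alpha: float = 0.05,
) -> float:
    """Power at a given per-arm n; exact inverse of :func:`n_per_arm`.

    Uses the dominant-tail normal approximation
    ``power = Phi(delta * sqrt(n / (2 * slope_var)) - z_{1-alpha/2})``,
    which is standard for this formula (the neglected opposite tail is
    below 1e-6 in any realistic regime).
    """
    _check_variances(sigma_w_sq, sigma_b_sq)
    if n < 1:
        raise ValueError("n must be at least 1")
    delta = abs(delta)
    z_a = float(stats.norm.ppf(1 - alpha / 2))
    slope_var = sigma_b_sq + sigma_w_sq / schedule.ssq
    return float(stats.norm.cdf(delta * math.sqrt(n / (2.0 * slope_var)) - z_a))


@dataclass(frozen=True)
class PowerInputs:
    """Variance components and slope feeding the formula for one biomarker."""

    biomarker: str
    sigma_w_sq: float
    sigma_b_sq: float
    slope_for_delta: float


def sweep(
    inputs: Mapping[str, "PowerInputs"],
    durations: Iterable[float],
    frequencies: Iterable[float],
    reference_biomarker: str,
    reference_frequency: float,
    *,
    alpha: float = 0.05,
    target_power: float = 0.80,
    effect_fraction: float = 0.30,
) -> "pandas.DataFrame":
    """Dense duration x frequency grid of per-arm n with ratios to a reference.

    The reference biomarker (typically plasma NfL) keeps its own fixed
    sampling frequency at every duration; all other biomarkers sweep the
    frequency grid.  ``ratio = n_reference / n_biomarker`` at the same
    duration, so ratio > 1 means the biomarker needs *fewer* subjects than
    the reference.

    Per-cell failures (zero slope, degenerate variance) are recorded in the
    ``error`` column instead of aborting the grid.
    """
    import pandas as pd

    if reference_biomarker not in inputs:
        raise KeyError(f"reference biomarker {reference_biomarker!r} not in inputs")

    def _cell(pi: PowerInputs, duration: float, frequency: float):
        try:
            sched = build_schedule(duration, frequency)
            delta = detectable_delta(pi.slope_for_delta, effect_fraction)
            res = n_per_arm(
                pi.sigma_w_sq, pi.sigma_b_sq, sched, delta, alpha, target_power
            )
            return res.n_continuous, res.n_per_arm, ""
        except (ValueError, UnpoweredError) as exc:  # recorded, not raised
            return np.nan, np.nan, str(exc)

    ref = inputs[reference_biomarker]
    ref_n: dict[float, float] = {}
    rows = []
    for duration in durations:
        n_cont, n_int, err = _cell(ref, duration, reference_frequency)
        ref_n[duration] = n_cont
        rows.append(
            {
                "biomarker": reference_biomarker,
                "duration": duration,
                "frequency": reference_frequency,
                "n_continuous": n_cont,
                "n_per_arm": n_int,
                "ratio_vs_reference": 1.0 if np.isfinite(n_cont) else np.nan,
                "error": err,
            }
        )
    for name, pi in inputs.items():
        if name == reference_biomarker:
            continue
        for duration, frequency in itertools.product(durations, frequencies):
            n_cont, n_int, err = _cell(pi, duration, frequency)
            ratio = ref_n[duration] / n_cont if n_cont and np.isfinite(n_cont) else np.nan
            rows.append(
                {
                    "biomarker": name,
                    "duration": duration,
                    "frequency": frequency,
                    "n_continuous": n_cont,
                    "n_per_arm": n_int,
                    "ratio_vs_reference": ratio,
                    "error": err,
                }
            )
    return pd.DataFrame(rows)
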