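"""Profiled-REML estimation of the two-level random-intercept/random-slope model.

Fits  y_ij = x_ij' beta + b0_i + b1_i * t_ij + e_ij,  (b0, b1) ~ N(0, D),
e ~ N(0, sigma^2 I), by restricted maximum likelihood.  The random-effect
design is always Z_i = [1, t_i]; the fixed design is either the same
[1, t] or the four-column group-interaction layout [1, g, t, g*t] with a
subject-constant binary g.

Why this exists: the model is tiny (2 random effects, <=4 fixed effects) and
the package refits it thousands of times in bootstrap and Monte-Carlo work.
Subjects sharing an observation-time pattern also share every design-derived
matrix, so the REML objective reduces to a handful of 2x2 solves per unique
pattern regardless of cohort size.  Writing D = sigma^2 * G and profiling out
beta and sigma^2 leaves a 1-3 parameter optimisation over the log-Cholesky
factor of G:

    -2 l_R(G) = sum_i log|V_i| + (N - p) log RSS(G) + log|X' V^-1 X| + const,

with V_i = I + Z_i G Z_i' handled through the Woodbury identity.  Estimates
agree with statsmodels MixedLM (REML) to optimiser tolerance; the unit suite
asserts this on shared datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["RemlFit", "reml_fit"]

_I2 = np.eye(2)


@dataclass
class RemlFit:
    """REML solution in natural (data) units."""

    beta: np.ndarray            # fixed effects
    cov_beta: np.ndarray        # their covariance
    sigma_w_sq: float           # residual variance
    cov_re: np.ndarray          # 2x2 random-effect covariance (intercept, slope)
    structure: str              # "unstructured" | "diagonal" | "intercept_only"
    converged: bool
    loglike: float              # -0.5 * (-2 l_R), up to an additive constant
    n_subjects: int
    n_obs: int


class _Suff:
    """Per-pattern sufficient statistics for the profiled REML objective."""

    __slots__ = ("n_subj", "n_obs", "S", "XZ", "XX", "U", "V", "Q", "q")

    def __init__(self, Z: np.ndarray, X: np.ndarray) -> None:
        self.n_subj = 0
        self.n_obs = Z.shape[0]
        self.S = Z.T @ Z            # 2x2
        self.XZ = X.T @ Z           # k x 2
        self.XX = X.T @ X           # k x k
        k = X.shape[1]
        self.U = np.zeros(2)        # sum of Z'y
        self.V = np.zeros(k)        # sum of X'y
        self.Q = np.zeros((2, 2))   # sum of (Z'y)(Z'y)'
        self.q = 0.0                # sum of y'y

    def add(self, Z: np.ndarray, X: np.ndarray, y: np.ndarray) -> None:
        u = Z.T @ y
        self.n_subj += 1
        self.U += u
        self.V += X.T @ y
        self.Q += np.outer(u, u)
        self.q += float(y @ y)


def _collect(groups, t, y, x_subject):
    """Group observations by subject, then pool subjects by design pattern.

    Alongside the pooled sufficient statistics this gathers per-subject OLS
    summaries (estimates, residual SS, S^-1) used for moment-based starting
    values of the variance parameters.
    """
    order = np.argsort(groups, kind="stable")
    groups, t, y = groups[order], t[order], y[order]
    if x_subject is not None:
        x_subject = x_subject[order]
    patterns: dict[tuple, _Suff] = {}
    ols_theta, ols_rss_df, ols_sinv = [], [], []
    n_subjects = 0
    starts = np.flatnonzero(np.r_[True, groups[1:] != groups[:-1]])
    bounds = np.r_[starts, groups.size]
    for a, b in zip(bounds[:-1], bounds[1:]):
        ti, yi = t[a:b], y[a:b]
        Z = np.column_stack([np.ones(b - a), ti])
        if x_subject is None:
            X, gkey = Z, None
        else:
            g = float(x_subject[a])
            X = np.column_stack([Z, g * Z])
            gkey = g
        key = (tuple(np.round(ti, 10)), gkey)
        suff = patterns.get(key)
        if suff is None:
            suff = patterns[key] = _Suff(Z, X)
        suff.add(Z, X, yi)
        n_subjects += 1
        if b - a >= 2 and np.unique(ti).size >= 2:
            S = Z.T @ Z
            try:
                Sinv = np.linalg.inv(S)
            except np.linalg.LinAlgError:
                continue
            u = Z.T @ yi
            theta = Sinv @ u
            ols_theta.append(theta)
            ols_sinv.append(Sinv)
            if b - a >= 3:
                ols_rss_df.append((float(yi @ yi - theta @ u), b - a - 2))
    moments = (ols_theta, ols_rss_df, ols_sinv)
    return patterns, n_subjects, moments


def _moment_start(moments) -> tuple[np.ndarray, float] | None:
    """Initial G from the covariance of per-subject OLS estimates, corrected
    for their sampling variance.  Returns (G0, sigma_w_sq0) or None."""
    ols_theta, ols_rss_df, ols_sinv = moments
    if len(ols_theta) < 3 or not ols_rss_df:
        return None
    rss = sum(r for r, _ in ols_rss_df)
    df = sum(d for _, d in ols_rss_df)
    if df <= 0 or rss <= 0:
        return None
    sw2 = rss / df
    theta = np.asarray(ols_theta)
    emp = np.cov(theta, rowvar=False)
    infl = sw2 * np.mean(np.asarray(ols_sinv), axis=0)
    D0 = emp - infl
    # project to a safely positive-definite matrix
    w, V = np.linalg.eigh(0.5 * (D0 + D0.T))
    floor = 1e-3 * max(sw2, float(np.max(w)), 1e-8)
    D0 = V @ np.diag(np.maximum(w, floor)) @ V.T
    return D0 / sw2, sw2


class _Stacked:
    """Pattern-level sufficient statistics stacked for vectorised evaluation."""

    def __init__(self, patterns: dict) -> None:
        suffs = list(patterns.values())
        self.n_subj = np.array([s.n_subj for s in suffs], dtype=float)  # (P,)
        self.S = np.stack([s.S for s in suffs])        # (P,2,2)
        self.XZ = np.stack([s.XZ for s in suffs])      # (P,k,2)
        self.XX = np.stack([s.XX for s in suffs])      # (P,k,k)
        self.U = np.stack([s.U for s in suffs])        # (P,2)
        self.V = np.stack([s.V for s in suffs])        # (P,k)
        self.Q = np.stack([s.Q for s in suffs])        # (P,2,2)
        self.q = float(sum(s.q for s in suffs))


def _objective_terms(st: "_Stacked", G: np.ndarray, k: int):
    """X'V^-1 X, X'V^-1 y, y'V^-1 y and sum log|V_i|, batched over patterns."""
    IpSG = _I2 + st.S @ G                              # (P,2,2)
    det = IpSG[:, 0, 0] * IpSG[:, 1, 1] - IpSG[:, 0, 1] * IpSG[:, 1, 0]
    if np.any(det <= 0):
        return None
    logdet = float(st.n_subj @ np.log(det))
    inv = np.empty_like(IpSG)                          # adjugate / det
    inv[:, 0, 0] = IpSG[:, 1, 1]
    inv[:, 1, 1] = IpSG[:, 0, 0]
    inv[:, 0, 1] = -IpSG[:, 0, 1]
    inv[:, 1, 0] = -IpSG[:, 1, 0]
    inv /= det[:, None, None]
    W = G @ inv                                        # (P,2,2), = (G^-1+S)^-1
    W = 0.5 * (W + np.swapaxes(W, 1, 2))
    XZW = st.XZ @ W                                    # (P,k,2)
    A = np.einsum("p,pij->ij", st.n_subj, st.XX) - np.einsum(
        "pij,pkj->ik", XZW * st.n_subj[:, None, None], st.XZ
    )
    b = st.V.sum(axis=0) - np.einsum("pij,pj->i", XZW, st.U)
    c = st.q - float(np.sum(W * st.Q))
    return A, b, c, logdet


def _neg2_reml(stacked, G, k, n_obs):
    terms = _objective_terms(stacked, G, k)
    if terms is None:
        return np.inf, None
    A, b, c, logdet = terms
    try:
        cho = np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        return np.inf, None
    beta = np.linalg.solve(A, b)
    rss = c - float(beta @ b)
    rss = max(rss, 1e-300)
    logdet_A = 2.0 * float(np.sum(np.log(np.diag(cho))))
    crit = logdet + (n_obs - k) * np.log(rss) + logdet_A
    return crit, (A, beta, rss)


def _G_from_theta(theta: np.ndarray, structure: str) -> np.ndarray:
    if structure == "unstructured":
        l11, l21, l22 = np.exp(theta[0]), theta[1], np.exp(theta[2])
        L = np.array([[l11, 0.0], [l21, l22]])
        return L @ L.T
    if structure == "diagonal":
        return np.diag(np.exp(2.0 * theta[:2]))
    # intercept_only: slope variance pinned to zero
    return np.array([[np.exp(2.0 * theta[0]), 0.0], [0.0, 0.0]])


_N_PARAMS = {"unstructured": 3, "diagonal": 2, "intercept_only": 1}


def reml_fit(
    groups: np.ndarray,
    t: np.ndarray,
    y: np.ndarray,
    x_subject: np.ndarray | None = None,
    structure: str = "unstructured",
    start: np.ndarray | None = None,
) -> RemlFit:
    """Fit the random-intercept/slope model by profiled REML.

    Parameters
    ----------
    groups, t, y
        Observation-level subject labels, times (years) and responses.
    x_subject
        Optional observation-level binary covariate, constant within
        subject; when given the fixed design is [1, t, g, g*t] (random part
        stays [1, t]).
    structure
        Random-effect covariance structure to estimate.
    start
        Optional 2x2 scaled covariance G = D / sigma_w^2 to start from; used
        to warm-start bootstrap refits from the full-data solution.
    """
    groups = np.asarray(groups)
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if x_subject is not None:
        x_subject = np.asarray(x_subject, dtype=float)
    patterns, n_subjects, moments = _collect(groups, t, y, x_subject)
    stacked = _Stacked(patterns)
    n_obs = t.size
    k = 2 if x_subject is None else 4

    def theta_of_G(G: np.ndarray) -> np.ndarray:
        L = np.linalg.cholesky(G + 1e-10 * _I2)
        if structure == "unstructured":
            return np.array([np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])])
        if structure == "diagonal":
            return 0.5 * np.log(np.maximum(np.diag(G), 1e-12))
        return np.array([0.5 * np.log(max(G[0, 0], 1e-12))])

    # Coarse fallback start: intercept random SD on the order of the
    # residual SD (ratio 1), slope random SD scaled by the observed span.
    t_span = max(float(t.max() - t.min()), 1e-6)
    coarse = np.diag([1.0, (0.5 / t_span) ** 2])
    if start is not None:
        start_Gs = [np.asarray(start, dtype=float)]
    else:
        start_Gs = [coarse]
        mom = _moment_start(moments)
        if mom is not None:
            start_Gs.insert(0, mom[0])

    def fun(theta):
        G = _G_from_theta(theta, structure)
        crit, _ = _neg2_reml(stacked, G, k, n_obs)
        return crit

    best = None
    for G0 in start_Gs:
        res = optimize.minimize(
            fun, theta_of_G(G0), method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    # polish: restart once from the incumbent (Nelder-Mead restarts escape
    # degenerate simplices on ridge-shaped REML surfaces)
    res = optimize.minimize(
        fun, best.x, method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    if res.fun <= best.fun:
        best = res

    G = _G_from_theta(best.x, structure)
    crit, aux = _neg2_reml(stacked, G, k, n_obs)
    if aux is None:
        return RemlFit(
            beta=np.full(k, np.nan), cov_beta=np.full((k, k), np.nan),
            sigma_w_sq=np.nan, cov_re=np.full((2, 2), np.nan),
            structure=structure, converged=False, loglike=-np.inf,
            n_subjects=n_subjects, n_obs=n_obs,
        )
    A, beta, rss = aux
    sigma_w_sq = rss / (n_obs - k)
    cov_re = sigma_w_sq * G
    cov_beta = sigma_w_sq * np.linalg.inv(A)
    converged = bool(best.success and np.isfinite(crit))
    return RemlFit(
        beta=beta, cov_beta=cov_beta, sigma_w_sq=float(sigma_w_sq),
        cov_re=cov_re, structure=structure, converged=converged,
        loglike=-0.5 * float(crit), n_subjects=n_subjects, n_obs=n_obs,
    )
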