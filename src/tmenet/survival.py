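"""Survival statistics: univariate Cox regression, Kaplan-Meier curves,
log-rank tests, maximally selected rank statistics (maxstat) cutpoints, and
DerSimonian-Laird random-effects meta-analysis.

The univariate Cox partial likelihood is maximized by Newton-Raphson with the
Efron correction for tied event times; Kaplan-Meier and the k-group log-rank
test delegate to lifelines. A vectorized two-group log-rank z-statistic backs
the maxstat search and its permutation p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

Z975 = 1.959963984540054


def read_survival_csv(path) -> pd.DataFrame:
    """Read a survival table CSV with columns sample, time, event."""
    surv = pd.read_csv(path).set_index("sample")[["time", "event"]]
    validate_survival(surv)
    return surv


def validate_survival(surv: pd.DataFrame) -> None:
    if surv.index.duplicated().any():
        raise ValueError("duplicate sample ids in survival table")
    if (surv["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not surv["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 or 1")


@dataclass
class CoxFit:
    """Univariate Cox proportional-hazards fit."""

    beta: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    n: int
    n_events: int
    converged: bool = True
    warning: Optional[str] = None

    def to_dict(self) -> dict:
        return asdict(self)


def _efron_derivatives(beta: float, x: np.ndarray, starts: np.ndarray,
                       d: np.ndarray, dead: np.ndarray) -> Tuple[float, float, float]:
    """Log partial likelihood, gradient and negative Hessian at beta.

    Arrays are sorted by descending time so risk sets are prefix sums;
    ``starts`` indexes the first position of each unique time, ``d`` the death
    count there, ``dead`` flags deaths.
    """
    theta = np.exp(beta * x)
    tx = theta * x
    txx = tx * x
    # prefix sums over the risk set (descending time => risk set = prefix)
    c0 = np.cumsum(theta)
    c1 = np.cumsum(tx)
    c2 = np.cumsum(txx)
    loglik = grad = info = 0.0
    n = len(x)
    for gi, s in enumerate(starts):
        dk = int(d[gi])
        if dk == 0:
            continue
        e = starts[gi + 1] if gi + 1 < len(starts) else n
        block = slice(s, e)
        sel = dead[block]
        xd = x[block][sel]
        s0r, s1r, s2r = c0[e - 1], c1[e - 1], c2[e - 1]
        s0d = theta[block][sel].sum()
        s1d = tx[block][sel].sum()
        s2d = txx[block][sel].sum()
        loglik += beta * xd.sum()
        ls = np.arange(dk) / dk
        phi0 = s0r - ls * s0d
        phi1 = s1r - ls * s1d
        phi2 = s2r - ls * s2d
        loglik -= np.log(phi0).sum()
        grad += xd.sum() - (phi1 / phi0).sum()
        info += (phi2 / phi0 - (phi1 / phi0) ** 2).sum()
    return loglik, grad, info


def fit_cox_univariate(
    x: Sequence[float],
    surv: pd.DataFrame,
    tol: float = 1e-9,
    max_iter: int = 50,
) -> CoxFit:
    """Fit a single-covariate Cox model (Efron ties, Newton-Raphson).

    The Wald standard error comes from the observed information at the
    maximum. A monotone partial likelihood (perfectly separating covariate) is
    flagged rather than raised.
    """
    if isinstance(x, pd.Series):
        x = x.loc[surv.index]
    x = np.asarray(x, dtype=float)
    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy(dtype=int)
    if len(x) != len(time):
        raise ValueError("covariate and survival table lengths differ")
    if not np.isfinite(x).all():
        raise ValueError("covariate contains non-finite values")
    n_events = int(event.sum())
    if n_events < 2:
        raise ValueError("need at least two events to fit a Cox model")
    if x.std() == 0:
        raise ValueError("covariate has zero variance")

    order = np.argsort(-time, kind="stable")
    t_s, x_s, e_s = time[order], x[order], event[order].astype(bool)
    starts = np.flatnonzero(np.r_[True, t_s[1:] != t_s[:-1]])
    d = np.add.reduceat(e_s.astype(int), starts)

    beta, warning, converged = 0.0, None, False
    for _ in range(max_iter):
        _, grad, info = _efron_derivatives(beta, x_s, starts, d, e_s)
        if info <= 0 or not np.isfinite(info):
            warning = "singular information matrix"
            break
        step = grad / info
        step = np.clip(step, -2.0, 2.0)  # guard monotone-likelihood runaways
        beta += step
        if abs(step) < tol:
            converged = True
            break
        if abs(beta) > 50:
            warning = "monotone partial likelihood; estimate diverges"
            break
    if not converged and warning is None:
        warning = "Newton-Raphson did not converge"
    if warning is not None:
        warnings.warn(f"fit_cox_univariate: {warning}")

    _, _, info = _efron_derivatives(beta, x_s, starts, d, e_s)
    se = float(1.0 / np.sqrt(info)) if info > 0 else np.inf
    z = beta / se if se > 0 and np.isfinite(se) else 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return CoxFit(
        beta=float(beta), se=se, hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z975 * se)), ci_high=float(np.exp(beta + Z975 * se)),
        z=float(z), p=float(p), n=len(x), n_events=n_events,
        converged=converged, warning=warning,
    )


def cox_score_residual(fit: CoxFit, x: Sequence[float], surv: pd.DataFrame) -> float:
    """Score-equation residual at the fitted beta (should be ~0 at the MLE)."""
    if isinstance(x, pd.Series):
        x = x.loc[surv.index]
    x = np.asarray(x, dtype=float)
    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy(dtype=int)
    order = np.argsort(-time, kind="stable")
    t_s, x_s, e_s = time[order], x[order], event[order].astype(bool)
    starts = np.flatnonzero(np.r_[True, t_s[1:] != t_s[:-1]])
    d = np.add.reduceat(e_s.astype(int), starts)
    _, grad, _ = _efron_derivatives(fit.beta, x_s, starts, d, e_s)
    return float(grad)


def kaplan_meier(
    surv: pd.DataFrame, groups: Optional[pd.Series] = None
) -> Dict[str, pd.DataFrame]:
    """Product-limit survival curves, one per group (single group if None).

    Each curve is a DataFrame with columns ``time`` and ``survival``; the step
    function is right-continuous, non-increasing, with S(0) = 1.
    """
    if groups is None:
        groups = pd.Series("all", index=surv.index)
    groups = groups.loc[surv.index]
    curves = {}
    for g in pd.unique(groups):
        sub = surv[groups == g]
        if sub.empty:
            raise ValueError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float),
             "survival": sf.iloc[:, 0].to_numpy(dtype=float)}
        )
    return curves


def logrank_test(surv: pd.DataFrame, groups: pd.Series) -> Tuple[float, int, float]:
    """k-group log-rank test; returns (chi2, df, p)."""
    groups = groups.loc[surv.index]
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(surv["time"], groups, surv["event"])
    return float(res.test_statistic), len(labels) - 1, float(res.p_value)


# ---------------------------------------------------------------------------
# maximally selected rank statistics
# ---------------------------------------------------------------------------


def _logrank_z_thresholds(
    time: np.ndarray, event: np.ndarray, X: np.ndarray, cuts: np.ndarray
) -> np.ndarray:
    """Standardized two-group log-rank statistics for threshold splits.

    ``X`` is (n, B): B covariate assignments (e.g. permutations) of the same
    values; for each cut c the low group is ``x <= c``. Returns (n_cuts, B)
    z-statistics (O - E of the low group over the hypergeometric SD).
    """
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order].astype(float)
    Xs = X[order]
    n = len(t)
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    d = np.add.reduceat(e, starts)
    ev = d > 0
    r = (n - starts)[ev].astype(float)
    dd = d[ev]
    var_fac = (dd * (r - dd) / np.maximum(r - 1.0, 1.0))[:, None]
    zs = np.zeros((len(cuts), X.shape[1]))
    for ci, c in enumerate(cuts):
        g = (Xs <= c).astype(float)
        r1 = np.cumsum(g[::-1], axis=0)[::-1]          # at-risk in low group
        r1u = r1[starts][ev]
        d1 = np.add.reduceat(g * e[:, None], starts, axis=0)[ev]
        frac = r1u / r[:, None]
        O = d1.sum(axis=0)
        E = (dd[:, None] * frac).sum(axis=0)
        V = (var_fac * frac * (1.0 - frac)).sum(axis=0)
        good = V > 0
        zs[ci, good] = (O[good] - E[good]) / np.sqrt(V[good])
    return zs


@dataclass
class CutpointResult:
    """Maximally selected log-rank cutpoint."""

    cutpoint: float
    statistic: float      # max |standardized log-rank statistic|
    p: float              # permutation p-value
    n_low: int
    n_high: int
    candidates: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("candidates")
        return d


def maxstat_cutpoint(
    x: Sequence[float],
    surv: pd.DataFrame,
    minprop: float = 0.1,
    n_perm: int = 1000,
    seed: int = 0,
) -> CutpointResult:
    """Optimal survival cutpoint by maximally selected rank statistics.

    Candidate cutpoints are the unique covariate values whose split leaves at
    least ``minprop`` of the samples on each side; at each, the standardized
    two-group log-rank statistic is evaluated and the cut maximizing |z| is
    selected (ties -> smallest cutpoint). The p-value permutes the covariate
    against the (time, event) pairs ``n_perm`` times and compares maxima,
    with the add-one permutation estimator.
    """
    if isinstance(x, pd.Series):
        x = x.loc[surv.index]
    x = np.asarray(x, dtype=float)
    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy(dtype=int)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 samples for a cutpoint search")
    if event.sum() == 0:
        raise ValueError("no events; cutpoint search undefined")

    xs = np.sort(x)
    lo = int(np.ceil(minprop * n))
    valid = np.unique(xs[lo - 1 : n - lo])  # <=c leaves >=lo low, >=lo high
    valid = np.array([c for c in valid
                      if lo <= (x <= c).sum() <= n - lo])
    if len(valid) == 0:
        raise ValueError("no admissible cutpoints under the minprop constraint")

    z_obs = _logrank_z_thresholds(time, event, x[:, None], valid)[:, 0]
    best = int(np.argmax(np.abs(z_obs)))
    cut = float(valid[best])
    stat = float(np.abs(z_obs[best]))

    rng = np.random.default_rng(seed)
    exceed = 0
    chunk = max(1, min(n_perm, 250))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perms = np.empty((n, b))
        for j in range(b):
            perms[:, j] = rng.permutation(x)
        z_perm = np.abs(_logrank_z_thresholds(time, event, perms, valid))
        exceed += int((z_perm.max(axis=0) >= stat).sum())
        done += b
    p = (1.0 + exceed) / (n_perm + 1.0)

    n_low = int((x <= cut).sum())
    cand = pd.DataFrame({"cutpoint": valid, "z": z_obs})
    return CutpointResult(cutpoint=cut, statistic=stat, p=float(p),
                          n_low=n_low, n_high=n - n_low, candidates=cand)


# ---------------------------------------------------------------------------
# DerSimonian-Laird meta-analysis
# ---------------------------------------------------------------------------


@dataclass
class MetaResult:
    """Random-effects (DerSimonian-Laird) pooling of log hazard ratios."""

    k: int
    q: float
    tau2: float
    pooled_log_hr: float
    pooled_se: float
    pooled_hr: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    studies: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("studies")
        return d


def dl_meta(log_effects: Sequence[float], ses: Sequence[float]) -> MetaResult:
    """DerSimonian-Laird random-effects meta-analysis of log effects.

    Fixed-effect weights ``w_i = 1/SE_i^2`` give Cochran's Q; the moment
    estimator ``tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))`` feeds
    random-effects weights ``1/(SE_i^2 + tau2)``. Reduces to inverse-variance
    fixed-effect pooling when Q <= k - 1.
    """
    y = np.asarray(log_effects, dtype=float)
    s = np.asarray(ses, dtype=float)
    if y.size == 0:
        raise ValueError("meta-analysis needs at least one study")
    if (s <= 0).any():
        raise ValueError("standard errors must be positive")
    k = y.size
    w = 1.0 / s**2
    fixed = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - fixed) ** 2))
    if k > 1:
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    else:
        tau2 = 0.0
    w_star = 1.0 / (s**2 + tau2)
    pooled = float(np.sum(w_star * y) / np.sum(w_star))
    pooled_se = float(1.0 / np.sqrt(np.sum(w_star)))
    z = pooled / pooled_se
    p = 2.0 * stats.norm.sf(abs(z))
    studies = pd.DataFrame({"log_hr": y, "se": s, "weight": w_star / w_star.sum()})
    return MetaResult(
        k=int(k), q=q, tau2=float(tau2),
        pooled_log_hr=pooled, pooled_se=pooled_se, pooled_hr=float(np.exp(pooled)),
        ci_low=float(np.exp(pooled - Z975 * pooled_se)),
        ci_high=float(np.exp(pooled + Z975 * pooled_se)),
        z=float(z), p=float(p), studies=studies,
    )
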