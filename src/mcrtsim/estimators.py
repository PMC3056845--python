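"""Six estimators of the treatment effect in a multicentre trial.

All six act on the same patient-level records (centre, arm, outcome) and
return the point estimate of the treatment effect beta1, its standard error
and a 95% confidence interval:

=====  ==========================================================
A      simple linear regression (two-sample t-test), centres ignored
B      fixed-effects regression: one intercept per centre
C      random-intercept linear mixed model, REML variance components
D      GEE with exchangeable working correlation, sandwich variance
E1     centre-level fixed-effect inverse-variance pooling
E2     centre-level DerSimonian-Laird random-effects pooling
=====  ==========================================================

A-C use t intervals (with the residual degrees of freedom stated per model);
D, E1 and E2 use Wald intervals with the normal quantile 1.959964.

Implementations are written against per-centre sufficient statistics so a fit
costs O(N) regardless of centre count; this keeps Monte Carlo studies with
thousands of replicates cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .simulate import TrialData

__all__ = [
    "FitResult",
    "CentreSummary",
    "per_centre_summaries",
    "fit_model_a",
    "fit_model_b",
    "fit_model_c",
    "fit_model_d",
    "fit_model_e1",
    "fit_model_e2",
    "fit",
    "reml_neg2_criterion",
    "MODELS",
]

MODELS = ("A", "B", "C", "D", "E1", "E2")

#: Normal 97.5% quantile used for all Wald intervals.
Z975 = 1.959964


@dataclass
class FitResult:
    """Treatment-effect estimate from one model on one trial."""

    model: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    ci_kind: str  # "t" or "wald"
    df: float | None = None
    converged: bool = True
    ancillary: dict = field(default_factory=dict)


def _t_interval(estimate: float, se: float, df: float) -> tuple[float, float]:
    q = float(stats.t.ppf(0.975, df))
    return estimate - q * se, estimate + q * se


def _wald_interval(estimate: float, se: float) -> tuple[float, float]:
    return estimate - Z975 * se, estimate + Z975 * se


# ---------------------------------------------------------------------------
# per-centre sufficient statistics


class _Suff:
    """Per-centre sums of (1, x, y) cross-products; x is the 0/1 arm label."""

    __slots__ = ("J", "N", "n", "sx", "sy", "sxy", "syy")

    def __init__(self, data: TrialData):
        centre = data.centre
        # contiguous 0-based centre index (centre ids may be sparse)
        uniq, idx = np.unique(centre, return_inverse=True)
        J = uniq.size
        x = data.arm.astype(np.float64)
        y = data.y
        self.J = J
        self.N = y.size
        self.n = np.bincount(idx, minlength=J).astype(np.float64)
        self.sx = np.bincount(idx, weights=x, minlength=J)
        self.sy = np.bincount(idx, weights=y, minlength=J)
        self.sxy = np.bincount(idx, weights=x * y, minlength=J)
        self.syy = np.bincount(idx, weights=y * y, minlength=J)
        # x is binary so sum(x^2) == sum(x)


# ---------------------------------------------------------------------------
# Model A — simple linear regression / two-sample t-test


def fit_model_a(data: TrialData) -> FitResult:
    """Two-sample t-test: centres ignored, pooled residual variance."""
    x = data.arm
    y = data.y
    n_t = int(x.sum())
    n_c = y.size - n_t
    if n_t == 0 or n_c == 0:
        raise ValueError("model A requires both arms to be non-empty")
    mean_t = y[x == 1].mean()
    mean_c = y[x == 0].mean()
    est = float(mean_t - mean_c)
    rss = float(np.sum((y - np.where(x == 1, mean_t, mean_c)) ** 2))
    df = y.size - 2
    s2 = rss / df
    se = float(np.sqrt(s2 * (1.0 / n_t + 1.0 / n_c)))
    lo, hi = _t_interval(est, se, df)
    return FitResult("A", est, se, lo, hi, "t", df=df,
                     ancillary={"sigma_e2": s2})


# ---------------------------------------------------------------------------
# Model B — fixed centre intercepts


def fit_model_b(data: TrialData) -> FitResult:
    """Least squares with one fixed intercept per centre plus treatment.

    Centres whose patients all sit in one arm carry no information about the
    treatment contrast and are removed before fitting; the residual degrees
    of freedom are N_retained - J_retained - 1.
    """
    s = _Suff(data)
    usable = (s.sx > 0) & (s.sx < s.n)
    if not usable.any():
        raise ValueError("model B requires at least one centre with patients in both arms")
    n, sx, sy, sxy, syy = (a[usable] for a in (s.n, s.sx, s.sy, s.sxy, s.syy))
    sxx_w = float(np.sum(sx - sx**2 / n))  # within-centre centered sum of squares of x
    sxy_w = float(np.sum(sxy - sx * sy / n))
    syy_w = float(np.sum(syy - sy**2 / n))
    est = sxy_w / sxx_w
    rss = syy_w - est * sxy_w
    N_ret = int(n.sum())
    J_ret = int(usable.sum())
    df = N_ret - J_ret - 1
    if df <= 0:
        raise ValueError("model B has no residual degrees of freedom")
    s2 = max(rss, 0.0) / df
    se = float(np.sqrt(s2 / sxx_w))
    lo, hi = _t_interval(est, se, df)
    return FitResult("B", est, se, lo, hi, "t", df=df,
                     ancillary={"sigma_e2": s2, "n_dropped_centres": int(s.J - J_ret)})


# ---------------------------------------------------------------------------
# Model C — random-intercept linear mixed model, REML


def _profile_pieces(s: _Suff, lam: float):
    """GLS pieces at variance ratio lam = sigma_b^2 / sigma_e^2.

    Uses the Woodbury identity per centre: (I + lam J)^-1 = I - c J with
    c = lam / (1 + lam n_j), so every X' Vbar^-1 X entry is a sum over
    centres of sufficient statistics.
    """
    c = lam / (1.0 + lam * s.n)
    xtvx = np.empty((2, 2))
    xtvx[0, 0] = np.sum(s.n - c * s.n**2)
    xtvx[0, 1] = xtvx[1, 0] = np.sum(s.sx - c * s.n * s.sx)
    xtvx[1, 1] = np.sum(s.sx - c * s.sx**2)
    xtvy = np.array([np.sum(s.sy - c * s.n * s.sy), np.sum(s.sxy - c * s.sx * s.sy)])
    ytvy = float(np.sum(s.syy - c * s.sy**2))
    return xtvx, xtvy, ytvy


def _reml_neg2(s: _Suff, lam: float) -> tuple[float, np.ndarray, np.ndarray, float]:
    """-2 * restricted profile log-likelihood (additive constant dropped)."""
    xtvx, xtvy, ytvy = _profile_pieces(s, lam)
    beta = np.linalg.solve(xtvx, xtvy)
    rss = ytvy - float(beta @ xtvy)
    p = 2
    if rss <= 0:
        return -np.inf, beta, xtvx, rss  # degenerate: perfect fit
    sig_e2 = rss / (s.N - p)
    logdet_v = float(np.sum(np.log1p(lam * s.n)))
    sign, logdet_x = np.linalg.slogdet(xtvx)
    crit = (s.N - p) * np.log(sig_e2) + logdet_v + logdet_x
    return crit, beta, xtvx, rss


def reml_neg2_criterion(data: TrialData, lam: float) -> float:
    """Profiled REML criterion (-2 restricted log-likelihood, constant dropped)
    at variance ratio ``lam = sigma_b^2 / sigma_e^2``.  Lower is better."""
    return _reml_neg2(_Suff(data), lam)[0]


def fit_model_c(data: TrialData) -> FitResult:
    """Random-intercept mixed model estimated by REML.

    The REML criterion is profiled down to the single variance ratio
    lam = sigma_b^2/sigma_e^2 (closed-form GLS for the fixed effects and
    closed-form sigma_e^2 given lam) and maximized by a bounded scalar search
    in log lam, with the boundary lam = 0 admitted explicitly.  The interval
    is t-based with N - J - 1 degrees of freedom.
    """
    s = _Suff(data)
    if s.N < 3:
        raise ValueError("model C requires at least 3 observations")
    if not (0 < s.sx.sum() < s.N):
        raise ValueError("model C requires both arms to be non-empty")

    def neg2(t: float) -> float:
        return _reml_neg2(s, np.exp(t))[0]

    crit0, beta0_, xtvx0, rss0 = _reml_neg2(s, 0.0)
    if not np.isfinite(crit0) and rss0 <= 0:
        # all outcomes fit exactly (e.g. constant y): boundary fit, zero noise
        est = float(beta0_[1])
        return FitResult("C", est, 0.0, est, est, "t", df=s.N - s.J - 1,
                         ancillary={"sigma_e2": 0.0, "sigma_b2": 0.0, "icc": 0.0,
                                    "degenerate": True, "reml_neg2": crit0})
    res = optimize.minimize_scalar(neg2, bounds=(-30.0, 12.0), method="bounded",
                                   options={"xatol": 1e-10})
    lam = float(np.exp(res.x))
    crit = float(res.fun)
    if crit0 <= crit:
        lam, crit = 0.0, crit0
    crit_l, beta, xtvx, rss = _reml_neg2(s, lam)
    if not np.isfinite(crit_l):
        raise ValueError("non-finite REML optimum")
    df = s.N - s.J - 1
    sig_e2 = rss / (s.N - 2)
    cov = sig_e2 * np.linalg.inv(xtvx)
    est = float(beta[1])
    se = float(np.sqrt(cov[1, 1]))
    lo, hi = _t_interval(est, se, df)
    sig_b2 = lam * sig_e2
    return FitResult("C", est, se, lo, hi, "t", df=df, ancillary={
        "sigma_e2": sig_e2, "sigma_b2": sig_b2,
        "icc": sig_b2 / (sig_b2 + sig_e2) if sig_e2 > 0 else 0.0,
        "lambda": lam, "reml_neg2": crit,
    })


# ---------------------------------------------------------------------------
# Model D — GEE, exchangeable working correlation, sandwich variance


def _gee_beta(s: _Suff, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """GLS coefficient update under working correlation alpha; returns
    (beta, X'R^-1 X) up to the common 1/(1-alpha) factor being included."""
    d = alpha / (1.0 - alpha + alpha * s.n)
    xtrx = np.empty((2, 2))
    xtrx[0, 0] = np.sum(s.n - d * s.n**2)
    xtrx[0, 1] = xtrx[1, 0] = np.sum(s.sx - d * s.n * s.sx)
    xtrx[1, 1] = np.sum(s.sx - d * s.sx**2)
    xtry = np.array([np.sum(s.sy - d * s.n * s.sy), np.sum(s.sxy - d * s.sx * s.sy)])
    xtrx /= (1.0 - alpha)
    xtry /= (1.0 - alpha)
    return np.linalg.solve(xtrx, xtry), xtrx


def _gee_moments(s: _Suff, beta: np.ndarray) -> tuple[float, float, float]:
    """Residual moment estimates (phi, alpha) at coefficients beta.

    phi = sum r^2 / (N - 2); alpha pools within-centre residual
    cross-products over sum_j n_j (n_j - 1)/2 - 2 pairs, the small-sample
    denominators of the classical GEE implementation.
    """
    b0, b1 = beta
    # per-centre sum r and sum r^2 from sufficient statistics (x binary)
    sr = s.sy - b0 * s.n - b1 * s.sx
    srr = (s.syy - 2 * b0 * s.sy - 2 * b1 * s.sxy
           + b0**2 * s.n + 2 * b0 * b1 * s.sx + b1**2 * s.sx)
    phi = float(np.sum(srr)) / (s.N - 2)
    pair_sums = float(np.sum((sr**2 - srr) / 2.0))
    n_pairs = float(np.sum(s.n * (s.n - 1) / 2.0))
    denom = n_pairs - 2.0
    if denom <= 0 or phi <= 0:
        return phi, 0.0, n_pairs
    return phi, pair_sums / denom / phi, n_pairs


def _gee_sandwich(s: _Suff, beta: np.ndarray, alpha: float, phi: float) -> np.ndarray:
    """Information-sandwich (robust) covariance A^-1 B A^-1."""
    b0, b1 = beta
    d = alpha / (1.0 - alpha + alpha * s.n)
    sr = s.sy - b0 * s.n - b1 * s.sx
    sxr = s.sxy - b0 * s.sx - b1 * s.sx
    # g_j = X_j' V_j^-1 r_j with V_j = phi [(1-alpha) I + alpha J]
    g0 = (sr - d * s.n * sr) / (phi * (1.0 - alpha))
    g1 = (sxr - d * s.sx * sr) / (phi * (1.0 - alpha))
    meat = np.empty((2, 2))
    meat[0, 0] = np.sum(g0 * g0)
    meat[0, 1] = meat[1, 0] = np.sum(g0 * g1)
    meat[1, 1] = np.sum(g1 * g1)
    _, xtrx = _gee_beta(s, alpha)
    bread_inv = np.linalg.inv(xtrx / phi)
    return bread_inv @ meat @ bread_inv


def fit_model_d(data: TrialData, max_iter: int = 2000, tol: float = 1e-8) -> FitResult:
    """GEE with identity link and exchangeable working correlation.

    Alternates a GLS update of (beta0, beta1) under the working covariance
    phi [(1-alpha) I + alpha J] with moment updates of (phi, alpha) from the
    residuals, starting from independence (alpha = 0, OLS coefficients).
    The reported variance is the information sandwich; the interval is Wald.
    ``converged`` is False when the iteration cap is hit or the working
    correlation leaves its positive-definite range
    (alpha <= -1/(max n_j - 1) or alpha >= 1); no exception is raised, the
    caller decides the replacement policy.
    """
    s = _Suff(data)
    if not (0 < s.sx.sum() < s.N):
        raise ValueError("model D requires both arms to be non-empty")
    max_n = float(s.n.max())
    alpha_low = -1.0 / (max_n - 1.0) if max_n > 1 else -np.inf

    beta, _ = _gee_beta(s, 0.0)  # OLS start
    alpha = 0.0
    converged = False
    n_iter = 0
    phi, _, n_pairs = _gee_moments(s, beta)
    if n_pairs <= 2:
        # every centre is a singleton (or too few pairs): independence GEE
        cov = _gee_sandwich(s, beta, 0.0, phi)
        est, se = float(beta[1]), float(np.sqrt(max(cov[1, 1], 0.0)))
        lo, hi = _wald_interval(est, se)
        return FitResult("D", est, se, lo, hi, "wald", converged=True,
                         ancillary={"alpha": 0.0, "phi": phi, "n_iter": 0})

    for n_iter in range(1, max_iter + 1):
        phi, alpha_new, _ = _gee_moments(s, beta)
        if not np.isfinite(alpha_new) or alpha_new <= alpha_low or alpha_new >= 1.0:
            # non-positive-definite working correlation
            converged = False
            break
        alpha = alpha_new
        beta_new, _ = _gee_beta(s, alpha)
        delta = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        if delta < tol:
            converged = True
            break

    cov = _gee_sandwich(s, beta, alpha, phi)
    est, se = float(beta[1]), float(np.sqrt(max(cov[1, 1], 0.0)))  # guard rounding
    lo, hi = _wald_interval(est, se)
    return FitResult("D", est, se, lo, hi, "wald", converged=converged,
                     ancillary={"alpha": alpha, "phi": phi, "n_iter": n_iter})


# ---------------------------------------------------------------------------
# centre-level models


@dataclass
class CentreSummary:
    """Arm-wise summary of one centre; the unit of the centre-level models.

    ``md`` (mean difference) and its standard error ``se_md`` follow the
    meta-analytic convention se_md = sqrt(sd_t^2/n_t + sd_c^2/n_c) with
    per-arm sample SDs, and are defined only when both arms hold at least two
    patients.
    """

    centre: int
    n_t: int
    n_c: int
    mean_t: float | None
    mean_c: float | None
    sd_t: float | None
    sd_c: float | None
    md: float | None
    se_md: float | None

    @property
    def usable(self) -> bool:
        return self.md is not None

    @property
    def degenerate(self) -> bool:
        return self.se_md is not None and self.se_md == 0.0


def per_centre_summaries(data: TrialData) -> list[CentreSummary]:
    """One :class:`CentreSummary` per centre, in centre-id order."""
    out: list[CentreSummary] = []
    for cid in np.unique(data.centre):
        mask = data.centre == cid
        yt = data.y[mask & (data.arm == 1)]
        yc = data.y[mask & (data.arm == 0)]
        n_t, n_c = yt.size, yc.size
        mean_t = float(yt.mean()) if n_t else None
        mean_c = float(yc.mean()) if n_c else None
        sd_t = float(yt.std(ddof=1)) if n_t >= 2 else None
        sd_c = float(yc.std(ddof=1)) if n_c >= 2 else None
        if n_t >= 2 and n_c >= 2:
            md = mean_t - mean_c
            se_md = float(np.sqrt(sd_t**2 / n_t + sd_c**2 / n_c))
        else:
            md = se_md = None
        out.append(CentreSummary(int(cid), n_t, n_c, mean_t, mean_c, sd_t, sd_c, md, se_md))
    return out


def _usable_summaries(data_or_summaries) -> tuple[np.ndarray, np.ndarray, int]:
    if isinstance(data_or_summaries, TrialData):
        summaries = per_centre_summaries(data_or_summaries)
    else:
        summaries = list(data_or_summaries)
    usable = [c for c in summaries if c.usable]
    if not usable:
        raise ValueError("no centre has at least two patients in each arm")
    for c in usable:
        if c.se_md == 0.0:
            raise ValueError(f"centre {c.centre} has a degenerate (zero) mean-difference SE")
    md = np.array([c.md for c in usable])
    se = np.array([c.se_md for c in usable])
    return md, se, len(summaries) - len(usable)


def fit_model_e1(data: TrialData | Sequence[CentreSummary]) -> FitResult:
    """Fixed-effect inverse-variance pooling of per-centre mean differences.

    Centres lacking two patients per arm (no within-arm SD) are dropped, as
    are none others; the pooled estimate is sum(w md)/sum(w) with
    w = 1/se_md^2 and its SE is (sum w)^(-1/2).  Wald interval.
    """
    md, se, n_dropped = _usable_summaries(data)
    w = 1.0 / se**2
    est = float(np.sum(w * md) / np.sum(w))
    se_pooled = float(1.0 / np.sqrt(np.sum(w)))
    q_het = float(np.sum(w * (md - est) ** 2))
    lo, hi = _wald_interval(est, se_pooled)
    return FitResult("E1", est, se_pooled, lo, hi, "wald", ancillary={
        "Q": q_het, "n_used": int(md.size), "n_dropped_centres": int(n_dropped),
    })


def fit_model_e2(data: TrialData | Sequence[CentreSummary]) -> FitResult:
    """DerSimonian-Laird random-effects pooling of per-centre mean differences.

    The between-centre heterogeneity tau^2 is the moment estimate
    max(0, (Q - (J-1)) / (sum w - sum w^2 / sum w)) from the fixed-effect
    Cochran Q; weights become 1/(se_md^2 + tau^2).  When Q <= J - 1 the fit
    collapses exactly onto the fixed-effect model.
    """
    md, se, n_dropped = _usable_summaries(data)
    w = 1.0 / se**2
    est_fe = float(np.sum(w * md) / np.sum(w))
    q_het = float(np.sum(w * (md - est_fe) ** 2))
    j_used = md.size
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q_het - (j_used - 1)) / denom) if denom > 0 else 0.0
    i2 = max(0.0, (q_het - (j_used - 1)) / q_het) if q_het > 0 else 0.0
    w_star = 1.0 / (se**2 + tau2)
    est = float(np.sum(w_star * md) / np.sum(w_star))
    se_pooled = float(1.0 / np.sqrt(np.sum(w_star)))
    lo, hi = _wald_interval(est, se_pooled)
    return FitResult("E2", est, se_pooled, lo, hi, "wald", ancillary={
        "tau2": tau2, "Q": q_het, "I2": i2,
        "n_used": int(j_used), "n_dropped_centres": int(n_dropped),
    })


_FITTERS = {
    "A": fit_model_a,
    "B": fit_model_b,
    "C": fit_model_c,
    "D": fit_model_d,
    "E1": fit_model_e1,
    "E2": fit_model_e2,
}


def fit(data: TrialData, model: str, **kwargs) -> FitResult:
    """Dispatch to one of the six estimators by name (A, B, C, D, E1, E2)."""
    key = model.upper().replace("-", "")
    if key not in _FITTERS:
        raise ValueError(f"unknown model {model!r}: choose from {MODELS}")
    return _FITTERS[key](data, **kwargs)
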