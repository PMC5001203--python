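"""Differential methylation testing on the signal-plus-background model.

Per condition, each promoter's observed count X decomposes as
X = S + B: NB-distributed methylation signal S plus Poisson background
B measured in the promoter's dedicated low-GC windows. The background
rate is the replicate mean, lambda_i = (1/m) sum_j b_ij, and the signal
moments follow from treating S as the difference X - B:

    mu_S   = E(X) - E(B)
    var_S  = var_X + var_B - 2 rho sigma_X sigma_B

with rho the replicate-level correlation of X and B. The NB parameters
come from the method-of-moments inversion r = mu^2 / (var' - mu),
p = mu / var' using a trend-adjusted variance var' (local regression of
var_S on mu_S across promoters, taken as a floor), or from a joint
Delaporte maximum-likelihood fit when enough replicates are available
(m > 5). Conditions are then compared with a moderated Fisher's exact
test: counts are pooled per condition, the fitted Delaporte laws are
scaled to the pooled totals, and

    p = sum_{p(a,b) <= p(x,y)} p(a,b) / sum_{a+b=x+y} p(a,b)

with p(a, b) = P_A(a) P_B(b).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import digamma, gammaln, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .counts import CountMatrix, size_factors
from .delaporte import (
    _DIRECT_CONV_MAX,
    R_CAP,
    DelaporteFit,
    delaporte_loglik_grad,
    delaporte_pmf_range,
)

__all__ = [
    "BackgroundEstimate",
    "estimate_lambda",
    "signal_moments",
    "adjusted_variance",
    "np_estimate",
    "mle_estimate",
    "moderated_fisher_test",
    "bh_adjust",
    "run_dm",
]

logger = logging.getLogger(__name__)

VAR_EPS = 1e-8  # floor for variances and the var' > mu guarantee
MAX_ENUMERATION = 10**6
TIE_REL_TOL = 1e-7  # relative tolerance for p(a,b) == p(x,y) ties


@dataclass
class BackgroundEstimate:
    """Poisson background rates per promoter for one condition."""

    lam: pd.Series
    m: int
    b: pd.DataFrame  # normalized replicate-level inputs, retained


def estimate_lambda(b: pd.DataFrame) -> BackgroundEstimate:
    """Background rate per promoter: the arithmetic replicate mean."""
    b = pd.DataFrame(b)
    if b.shape[1] < 1:
        raise ValueError("need at least one replicate")
    return BackgroundEstimate(lam=b.mean(axis=1), m=b.shape[1], b=b)


def signal_moments(x: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Moment estimates of the signal component per promoter.

    Returns a frame with columns mu_s, var_x, var_b, rho, var_s and a
    clamp indicator. mu_s is clamped at 0 (background can exceed the
    observed mean by sampling noise); rho is the sample Pearson
    correlation of X and B across replicates, clamped to [0, 1] and 0
    whenever m < 3 or either variance vanishes; var_s is floored at a
    small epsilon.
    """
    x = pd.DataFrame(x)
    b = pd.DataFrame(b)
    if x.shape != b.shape:
        raise ValueError("x and b must share replicate structure")
    m = x.shape[1]
    xa, ba = x.to_numpy(float), b.to_numpy(float)
    mean_x, mean_b = xa.mean(axis=1), ba.mean(axis=1)
    if m >= 2:
        var_x, var_b = xa.var(axis=1, ddof=1), ba.var(axis=1, ddof=1)
    else:
        var_x = np.full(len(xa), np.nan)
        var_b = np.full(len(xa), np.nan)
    if m >= 3:
        xc = xa - mean_x[:, None]
        bc = ba - mean_b[:, None]
        cov = (xc * bc).sum(axis=1) / (m - 1)
        denom = np.sqrt(var_x * var_b)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.where(denom > 0, cov / denom, 0.0)
        rho = np.clip(np.nan_to_num(rho), 0.0, 1.0)
    else:
        rho = np.zeros(len(xa))
    mu_s = mean_x - mean_b
    clamped = mu_s < 0
    mu_s = np.clip(mu_s, 0.0, None)
    with np.errstate(invalid="ignore"):
        var_s = var_x + var_b - 2.0 * rho * np.sqrt(var_x * var_b)
    var_s = np.clip(var_s, VAR_EPS, None)
    return pd.DataFrame(
        {
            "mu_s": mu_s,
            "var_x": var_x,
            "var_b": var_b,
            "rho": rho,
            "var_s": var_s,
            "mu_clamped": clamped,
        },
        index=x.index,
    )


def _log_var_trend(mu, var, min_fit, frac):
    """Lowess trend of log var_s on log mu_s; returns a log-space callable
    g with g(log mu) ~ E[log var_s | mu], or None when unavailable."""
    pos = (mu > 0) & np.isfinite(var)
    if pos.sum() < min_fit:
        return None
    try:
        lx = np.log(mu[pos])
        ly = np.log(np.maximum(var[pos], VAR_EPS))
        delta = 0.01 * (lx.max() - lx.min())
        # robust local regression; with left-skewed chi-square log noise it
        # sits between the mean and the median, so the mean-based bias
        # correction leaves the trend leaning mildly conservative at small df
        sm = lowess(ly, lx, frac=frac, delta=delta, return_sorted=True)
    except Exception:  # pragma: no cover - statsmodels edge cases
        return None
    if not np.all(np.isfinite(sm)):
        return None
    gx, gy = sm[:, 0], sm[:, 1]
    return lambda lq: np.interp(lq, gx, gy)


def _trigamma_inv(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        step = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += step
        if abs(step) < 1e-8 * y:
            break
    return y


def variance_trend(mu_s, var_s, min_fit: int = 50, frac: float = 0.3, df: int | None = None):
    """Fit the smooth mean-variance trend v(mu) across promoters.

    Lowess of log var_s on log mu_s over promoters with positive signal;
    returns a callable evaluating v at arbitrary mu (edge-clamped
    outside the fitted range). Sample variances on ``df`` degrees of
    freedom are log-biased low — E[log(chi2_d / d)] = psi(d/2) - log(d/2)
    — so when ``df`` is given the fitted trend is shifted up by the
    corresponding offset (e.g. +0.577 nats at m = 3 replicates); without
    it the trend would systematically understate the variance at small
    m. When fewer than ``min_fit`` positive-signal promoters exist, or
    the fit fails, the fallback scales mu by the 75th percentile of
    var_s / mu_s.
    """
    mu = np.asarray(mu_s, dtype=float)
    var = np.asarray(var_s, dtype=float)
    bias = 0.0
    if df is not None and df >= 1:
        bias = float(np.log(df / 2.0) - digamma(df / 2.0))
    g = _log_var_trend(mu, var, min_fit, frac)
    if g is not None:

        def v(q):
            q = np.asarray(q, dtype=float)
            out = np.zeros_like(q)
            qpos = q > 0
            out[qpos] = np.exp(g(np.log(q[qpos])) + bias)
            return out

        return v
    pos = (mu > 0) & np.isfinite(var)
    if pos.sum() >= min_fit:
        logger.warning(
            "mean-variance trend fit failed; falling back to quantile scaling"
        )
    scale = np.quantile(var[pos] / mu[pos], 0.75) if pos.any() else 1.0

    def v(q):
        return scale * np.asarray(q, dtype=float)

    return v


def adjusted_variance(
    mu_s, var_s, df: int | None = None, min_fit: int = 50, frac: float = 0.3
) -> np.ndarray:
    """Moderated (empirical-Bayes) signal variance var' per promoter.

    Per-promoter sample variances on few replicates are unusably noisy,
    so they are squeezed toward the shared mean-variance trend. With
    ``df`` sampling degrees of freedom, the residual spread of
    log(var_s) around the trend beyond the chi-square sampling
    component, trigamma(df/2), estimates the genuine promoter-to-
    promoter dispersion heterogeneity; equating it to trigamma(d0/2)
    yields the prior degrees of freedom d0, and the adjusted variance is
    the standard inverse-chi-square posterior mean

        var' = (d0 * s0^2(mu) + df * var_s) / (d0 + df)

    with s0^2 the bias-corrected trend. Without ``df`` (or when the
    trend cannot be fitted) the conservative fallback
    max(var_s, v(mu_s)) is used. The result always exceeds mu_s so the
    moment inversion r = mu^2 / (var' - mu) stays defined.
    """
    mu = np.asarray(mu_s, dtype=float)
    var = np.asarray(var_s, dtype=float)
    var_adj, _ = _moderate_variance(mu, var, df, min_fit, frac)
    return var_adj


def _moderate_variance(mu, var, df, min_fit, frac):
    """EB variance moderation; returns (var_adj, prior-variance callable)."""
    g = _log_var_trend(mu, var, min_fit, frac) if df and df >= 1 else None
    if g is None:
        trend = variance_trend(mu, var, min_fit=min_fit, frac=frac, df=df)
        var_adj = np.maximum(np.nan_to_num(var, nan=0.0), trend(mu))
        return np.maximum(var_adj, mu + VAR_EPS), trend
    pos = (mu > 0) & np.isfinite(var)
    z = np.log(np.maximum(var[pos], VAR_EPS)) - g(np.log(mu[pos]))
    evar = float(np.var(z, ddof=1)) - float(polygamma(1, df / 2.0))
    d0 = 2.0 * _trigamma_inv(evar) if evar > 1e-4 else 1e6
    # E[log s^2] = log s0^2 + (log(d0/2) - psi(d0/2)) inverted, plus the
    # chi-square sampling bias of the observed variances
    offset = (
        (np.log(df / 2.0) - digamma(df / 2.0))
        + (digamma(d0 / 2.0) - np.log(d0 / 2.0))
        if np.isfinite(d0) and d0 < 1e6
        else (np.log(df / 2.0) - digamma(df / 2.0))
    )

    def prior(q):
        q = np.asarray(q, dtype=float)
        out = np.zeros_like(q)
        qpos = q > 0
        out[qpos] = np.exp(g(np.log(q[qpos])) + offset)
        return out

    s0 = prior(mu)
    var_obs = np.nan_to_num(var, nan=0.0)
    var_adj = (d0 * s0 + df * var_obs) / (d0 + df)
    # promoters without signal keep the prior alone
    var_adj = np.where(mu > 0, var_adj, s0)
    return np.maximum(var_adj, mu + VAR_EPS), prior


def np_estimate(mu_s: float, var_adj: float, lam: float = 0.0) -> DelaporteFit:
    """Non-parametric (method-of-moments) Delaporte fit.

    r = mu^2 / (var' - mu) and p = mu / var'. In the Poisson limit
    var' -> mu the size r diverges and is capped; a promoter with zero
    estimated signal gets the degenerate fit with all mass at 0.
    """
    if mu_s < 0 or lam < 0:
        raise ValueError("mu_s and lam must be non-negative")
    if mu_s == 0:
        return DelaporteFit(r=0.0, p=1.0, lam=lam, flags=("degenerate_signal",))
    if var_adj <= mu_s:
        raise ValueError("adjusted variance must exceed the mean")
    r = mu_s**2 / (var_adj - mu_s)
    p = mu_s / var_adj
    flags: tuple[str, ...] = ()
    if r > R_CAP:
        r, flags = R_CAP, ("r_capped",)
    return DelaporteFit(r=r, p=p, lam=lam, flags=flags)


def _np_estimate_arrays(mu_s, var_adj, lam):
    """Vectorized moment inversion; returns (r, p) arrays with caps applied."""
    mu = np.asarray(mu_s, float)
    va = np.asarray(var_adj, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(mu > 0, mu**2 / np.maximum(va - mu, VAR_EPS * 1e-3), 0.0)
        p = np.where(mu > 0, mu / va, 1.0)
    r = np.minimum(r, R_CAP)
    p = np.clip(p, 1e-12, 1.0)
    return r, p


def mle_estimate(
    x, b, init: DelaporteFit | None = None, min_fit: int = 50
) -> DelaporteFit:
    """Joint Delaporte maximum-likelihood fit for one promoter.

    Maximizes the product of the Delaporte likelihood of the observed
    counts and the Poisson likelihood of the background counts over
    (alpha, beta, lambda), log-parameterized for positivity, with BFGS.
    Initialization comes from the moment fit; on optimizer failure the
    moment fit is returned with a warning flag.
    """
    x = np.rint(np.asarray(x, float)).astype(np.int64)
    b = np.asarray(b, float)
    if np.any(x < 0) or np.any(b < 0):
        raise ValueError("counts must be non-negative")
    lam0 = float(np.mean(b))
    if np.all(x == 0):
        return DelaporteFit(
            r=0.0, p=1.0, lam=lam0, regime="mle", flags=("degenerate_signal",)
        )
    if init is None:
        mom = signal_moments(
            pd.DataFrame(x[None, :]), pd.DataFrame(np.atleast_2d(b))
        ).iloc[0]
        var_adj = max(mom.var_s, mom.mu_s * 1.5 + VAR_EPS)
        init = np_estimate(max(mom.mu_s, 0.5), var_adj, lam0)
    theta0 = np.log(
        [
            np.clip(init.alpha, 1e-3, 1e6),
            np.clip(init.beta, 1e-3, 1e6),
            np.clip(lam0 if lam0 > 0 else init.lam, 1e-3, None) or 1e-3,
        ]
    )

    def negloglik(theta):
        alpha, beta, lam = np.exp(np.clip(theta, -30, 30))
        ll, ga, gb, gl = delaporte_loglik_grad(x, alpha, beta, lam)
        # Poisson log-likelihood of the background counts (gamma-continuous
        # in b, which may be non-integer after normalization)
        ll += np.sum(b * np.log(lam) - lam - gammaln(b + 1))
        gl += np.sum(b / lam - 1.0)
        # chain rule through the log-parameterization
        grad = -np.array([ga * alpha, gb * beta, gl * lam])
        return -ll, grad

    try:
        res = optimize.minimize(negloglik, theta0, method="BFGS", jac=True)
        ok = np.all(np.isfinite(res.x)) and np.isfinite(res.fun)
    except (ValueError, FloatingPointError):
        ok = False
    if not ok:
        logger.warning("Delaporte MLE failed; falling back to moment fit")
        return DelaporteFit(
            r=init.r,
            p=init.p,
            lam=init.lam,
            regime="nonparametric",
            flags=init.flags + ("mle_failed",),
        )
    alpha, beta, lam = np.exp(np.clip(res.x, -30, 30))
    return DelaporteFit.from_gamma(
        alpha,
        beta,
        lam,
        regime="mle",
        loglik=-float(res.fun),
        flags=() if res.success else ("mle_not_converged",),
    )


def moderated_fisher_test(
    x: int,
    y: int,
    fit_a: DelaporteFit,
    fit_b: DelaporteFit,
    max_enumeration: int = MAX_ENUMERATION,
) -> float:
    """Exact two-condition test on pooled counts under fitted Delaporte laws.

    Enumerates every split a + b = x + y, weighting each by
    p(a, b) = P_A(a) P_B(b), and returns the total probability of splits
    no more likely than the observed one (ties included, with a small
    relative tolerance against floating-point noise in the pmf values).
    """
    x, y = int(x), int(y)
    if x < 0 or y < 0:
        raise ValueError("pooled counts must be non-negative")
    n = x + y
    if n == 0:
        return 1.0
    if n > max_enumeration:
        raise ValueError(f"enumeration length {n + 1} exceeds {max_enumeration}")
    if n <= _DIRECT_CONV_MAX:
        pa = delaporte_pmf_range(n, fit_a.alpha, fit_a.beta, fit_a.lam)
        pb = delaporte_pmf_range(n, fit_b.alpha, fit_b.beta, fit_b.lam)
        joint = pa * pb[::-1]  # joint[a] = P_A(a) * P_B(n - a)
        denom = joint.sum()
        if denom <= 0.0:
            return 1.0
        p_obs = joint[x]
        if p_obs > 0.0:
            num = joint[joint <= p_obs * (1.0 + TIE_REL_TOL)].sum()
        else:
            num = 0.0  # observed split below double-precision model support
        p = num / denom
        return float(min(max(p, 1e-300), 1.0))
    return _fisher_windowed(x, y, fit_a, fit_b)


def _joint_segment(n, lo, hi, fit_a, fit_b):
    pa = delaporte_pmf_range(hi, fit_a.alpha, fit_a.beta, fit_a.lam, kmin=lo)
    pb = delaporte_pmf_range(n - lo, fit_b.alpha, fit_b.beta, fit_b.lam, kmin=n - hi)
    return pa * pb[::-1]


def _fisher_windowed(x: int, y: int, fit_a: DelaporteFit, fit_b: DelaporteFit) -> float:
    """Large-count exact test evaluated on an adaptive window.

    The joint diagonal p(a, n - a) concentrates its mass in a narrow
    band around the null expectation; the window starts around that
    band and the observed split and grows outward until the edge terms
    fall 1e-12 below the observed probability. Neglected terms then
    change neither the numerator nor the denominator beyond ~1e-6
    relative at any enumeration length.
    """
    n = x + y
    var_a = max(fit_a.var, 1.0)
    var_b = max(fit_b.var, 1.0)
    sc = max(np.sqrt(var_a * var_b / (var_a + var_b)), 4.0)
    a_star = (fit_a.mean * var_b + (n - fit_b.mean) * var_a) / (var_a + var_b)
    a_star = min(max(a_star, 0.0), float(n))
    lo = int(max(0, min(a_star - 12 * sc, x - 6 * sc)))
    hi = int(min(n, max(a_star + 12 * sc, x + 6 * sc)))
    joint = _joint_segment(n, lo, hi, fit_a, fit_b)
    p_obs = joint[x - lo]
    if p_obs <= 0.0:
        return 1e-300  # observed split below double-precision model support
    thresh = max(p_obs * 1e-12, 5e-320)
    step = max(int(6 * sc), 128)
    while lo > 0 and joint[0] > thresh:
        new_lo = max(0, lo - step)
        joint = np.concatenate(
            [_joint_segment(n, new_lo, lo - 1, fit_a, fit_b), joint]
        )
        lo = new_lo
        step *= 2
    step = max(int(6 * sc), 128)
    while hi < n and joint[-1] > thresh:
        new_hi = min(n, hi + step)
        joint = np.concatenate(
            [joint, _joint_segment(n, hi + 1, new_hi, fit_a, fit_b)]
        )
        hi = new_hi
        step *= 2
    denom = joint.sum()
    if denom <= 0.0:
        return 1.0
    num = joint[joint <= p_obs * (1.0 + TIE_REL_TOL)].sum()
    return float(min(max(num / denom, 1e-300), 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _condition_fits(xn: pd.DataFrame, bn: pd.DataFrame, min_fit: int, use_mle: bool):
    """Per-condition estimation across all promoters.

    Returns (lam, r, p, moments frame, prior-variance callable).
    """
    bg = estimate_lambda(bn)
    moments = signal_moments(xn, bn)
    mu = moments["mu_s"].to_numpy()
    var = moments["var_s"].to_numpy()
    var_adj, prior = _moderate_variance(mu, var, xn.shape[1] - 1, min_fit, 0.3)
    moments["var_s_adj"] = var_adj
    r, p = _np_estimate_arrays(mu, var_adj, bg.lam)
    lam = bg.lam.to_numpy().copy()
    if use_mle:
        xa, ba = xn.to_numpy(float), bn.to_numpy(float)
        for i in range(len(xn)):
            init = DelaporteFit(
                r=max(r[i], 1e-6),
                p=min(max(p[i], 1e-9), 1 - 1e-9) if r[i] > 0 else 1.0,
                lam=max(lam[i], 1e-6),
            )
            fit = mle_estimate(xa[i], ba[i], init=init)
            if "mle_failed" not in fit.flags:
                r[i], p[i], lam[i] = fit.r, fit.p, fit.lam
    return lam, r, p, moments, prior


def run_dm(
    promoter_counts: CountMatrix,
    background_counts: CountMatrix,
    *,
    mle_threshold: int = 5,
    pseudocount: float = 1.0,
    min_fit: int = 50,
) -> pd.DataFrame:
    """Full differential-methylation analysis between two conditions.

    Normalizes both matrices with shared median-of-ratios factors,
    estimates per-condition background rates and Delaporte signal
    parameters (moment-based, or by MLE when a condition has more than
    ``mle_threshold`` replicates), tests each promoter with the
    moderated Fisher's exact test on pooled normalized counts, and
    reports log2 fold changes of background-subtracted means (with a
    pseudocount) alongside BH-adjusted p-values.

    Promoters absent from the background matrix (no usable background
    windows) are excluded; their ids are available under
    ``result.attrs["excluded"]``.
    """
    levels = list(dict.fromkeys(promoter_counts.conditions))
    if len(levels) != 2:
        raise ValueError(f"exactly two conditions required, got {levels}")
    cond_a, cond_b = levels
    samples = {c: promoter_counts.condition_samples(c) for c in levels}
    for c in levels:
        if len(samples[c]) < 2:
            raise ValueError(
                f"condition {c!r} has {len(samples[c])} replicate(s); "
                "at least 2 required to estimate dispersion"
            )

    shared = promoter_counts.data.index.intersection(background_counts.data.index)
    excluded = promoter_counts.data.index.difference(shared).tolist()
    if excluded:
        logger.info("excluding %d promoters without background", len(excluded))
    sf = size_factors(promoter_counts)
    xn = promoter_counts.data.loc[shared].div(sf, axis=1)
    bn = background_counts.data.loc[shared].div(sf, axis=1)

    per_cond = {}
    for c in levels:
        m = len(samples[c])
        per_cond[c] = _condition_fits(
            xn[samples[c]], bn[samples[c]], min_fit, use_mle=m > mle_threshold
        )

    lam_a, r_a, p_a, mom_a, prior_a = per_cond[cond_a]
    lam_b, r_b, p_b, mom_b, prior_b = per_cond[cond_b]
    m_a, m_b = len(samples[cond_a]), len(samples[cond_b])
    x_pool = np.rint(xn[samples[cond_a]].sum(axis=1)).astype(np.int64)
    y_pool = np.rint(xn[samples[cond_b]].sum(axis=1)).astype(np.int64)

    # Null construction for the exact test: both conditions share the
    # pooled signal mean mu0; each keeps its own dispersion (phi = 1/r
    # for an NB fit, falling back to the condition's prior variance
    # at mu0 when the condition saw no signal) and its own background
    # rate. Without a shared null mean the fitted means would reproduce
    # the observed split exactly and every p-value would be ~1.
    mu0 = np.clip(
        xn.mean(axis=1).to_numpy() - bn.mean(axis=1).to_numpy(), 0.0, None
    )
    phi = {}
    for c, (lam_c, r_c, p_c, mom_c, prior_c) in per_cond.items():
        with np.errstate(divide="ignore"):
            ph = np.where(r_c > 0, 1.0 / r_c, np.inf)
        need = ~np.isfinite(ph)
        if need.any():
            vt = prior_c(mu0[need])
            with np.errstate(divide="ignore", invalid="ignore"):
                ph[need] = np.where(
                    mu0[need] > 0,
                    np.maximum(vt - mu0[need], VAR_EPS) / mu0[need] ** 2,
                    0.0,
                )
        phi[c] = ph

    def null_fit(c: str, m: int, i: int) -> DelaporteFit:
        lam_c = per_cond[c][0]
        if mu0[i] <= 0 or phi[c][i] <= 0:
            return DelaporteFit(r=0.0, p=1.0, lam=lam_c[i] * m)
        r0 = min(1.0 / phi[c][i], R_CAP)
        p0 = 1.0 / (1.0 + phi[c][i] * mu0[i])
        return DelaporteFit(r=min(r0 * m, R_CAP), p=p0, lam=lam_c[i] * m)

    pvals = np.empty(len(shared))
    for i in range(len(shared)):
        fa = null_fit(cond_a, m_a, i)
        fb = null_fit(cond_b, m_b, i)
        pvals[i] = moderated_fisher_test(int(x_pool.iloc[i]), int(y_pool.iloc[i]), fa, fb)

    mu_a = mom_a["mu_s"].to_numpy()
    mu_b = mom_b["mu_s"].to_numpy()
    log2fc = np.log2((mu_a + pseudocount) / (mu_b + pseudocount))
    result = pd.DataFrame(
        {
            "x": x_pool,
            "y": y_pool,
            "log2fc": log2fc,
            "pvalue": pvals,
            "padj": bh_adjust(pvals),
            "mean_a": xn[samples[cond_a]].mean(axis=1),
            "mean_b": xn[samples[cond_b]].mean(axis=1),
            "mu_s_a": mu_a,
            "mu_s_b": mu_b,
            "lambda_a": lam_a,
            "lambda_b": lam_b,
        },
        index=shared,
    )
    result.index.name = "promoter"
    result.attrs["excluded"] = excluded
    result.attrs["conditions"] = (cond_a, cond_b)
    return result
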