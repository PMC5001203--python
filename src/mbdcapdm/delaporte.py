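"""Delaporte distribution: negative binomial convolved with Poisson.

The observed promoter count X decomposes as X = S + B with independent
S ~ NB(r, p) (true methylation signal) and B ~ Poisson(lambda)
(non-specific capture background), so X follows a Delaporte
distribution. In the gamma-mixture parameterization used here,
alpha = r and beta = (1 - p) / p, i.e. p = 1 / (1 + beta), and

    P(X = k) = sum_{j=0}^{k} Gamma(alpha + j) beta^j
               / (Gamma(alpha) j! (1 + beta)^(alpha + j))
               * lambda^(k - j) e^(-lambda) / (k - j)!

Either component may vanish: beta = 0 (or alpha = 0) reduces to
Poisson(lambda); lambda = 0 reduces to NB(alpha, 1/(1+beta)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.signal import fftconvolve
from scipy.special import digamma, gammaln, logsumexp

__all__ = [
    "DelaporteFit",
    "delaporte_pmf",
    "delaporte_logpmf",
    "delaporte_pmf_range",
    "delaporte_loglik_grad",
]

R_CAP = 1e8  # Poisson limit guard for the NB size parameter

# below this total support length a direct O(n^2) convolution over the full
# 0..kmax range is used, which matches the summed scalar formula in all terms
_DIRECT_CONV_MAX = 1024
_TAIL_Z = 10.0  # Gaussian z covering ~1e-18 per-component tail mass
_TAIL_NATS = 45.0  # extra nats of geometric NB right tail retained


@dataclass
class DelaporteFit:
    """Per-promoter, per-condition Delaporte parameters.

    ``r``/``p`` are the NB size and success probability of the signal
    component; ``alpha``/``beta`` the equivalent gamma-mixture
    parameters (alpha = r, p = 1/(beta+1)); ``lam`` the Poisson mean of
    the background. ``regime`` records how the fit was obtained.
    """

    r: float
    p: float
    lam: float
    regime: str = "nonparametric"
    loglik: float | None = None
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.r < 0 or not (0 < self.p <= 1):
            if not (self.r == 0 or self.p == 1):  # degenerate zero-signal fit
                raise ValueError("require r > 0 and 0 < p <= 1")

    @property
    def alpha(self) -> float:
        return self.r

    @property
    def beta(self) -> float:
        return (1.0 - self.p) / self.p

    @classmethod
    def from_gamma(cls, alpha: float, beta: float, lam: float, **kw) -> "DelaporteFit":
        return cls(r=alpha, p=1.0 / (1.0 + beta), lam=lam, **kw)

    @property
    def mean(self) -> float:
        return self.r * self.beta + self.lam

    @property
    def var(self) -> float:
        return self.r * self.beta * (1.0 + self.beta) + self.lam

    def scaled(self, m: int) -> "DelaporteFit":
        """Distribution of the sum of ``m`` iid copies (r and lambda scale)."""
        return DelaporteFit(
            r=min(self.r * m, R_CAP),
            p=self.p,
            lam=self.lam * m,
            regime=self.regime,
            flags=self.flags,
        )


def _check_params(alpha: float, beta: float, lam: float) -> None:
    if alpha < 0 or beta < 0 or lam < 0 or not np.all(
        np.isfinite([alpha, beta, lam])
    ):
        raise ValueError(
            f"invalid Delaporte parameters alpha={alpha}, beta={beta}, lam={lam}"
        )


def delaporte_logpmf(k, alpha: float, beta: float, lam: float):
    """log P(X = k), computed by log-sum-exp over the convolution index.

    ``k`` may be a scalar or array of non-negative integers. This is the
    reference (exact, per-point) evaluation; use
    :func:`delaporte_pmf_range` for whole-support vectors.
    """
    _check_params(alpha, beta, lam)
    k_arr = np.atleast_1d(np.asarray(k, dtype=np.int64))
    if np.any(k_arr < 0):
        raise ValueError("k must be non-negative")
    pure_poisson = alpha == 0 or beta == 0
    pure_nb = lam == 0
    p = 1.0 / (1.0 + beta)
    if pure_poisson and pure_nb:
        out = np.where(k_arr == 0, 0.0, -np.inf)
    elif pure_poisson:
        out = stats.poisson.logpmf(k_arr, lam)
    elif pure_nb:
        out = stats.nbinom.logpmf(k_arr, alpha, p)
    else:
        out = np.empty(k_arr.shape, dtype=float)
        for i, ki in np.ndenumerate(k_arr):
            j, terms = _conv_terms(int(ki), alpha, beta, lam)
            out[i] = logsumexp(terms)
    return out if np.ndim(k) else float(out[0])


def _j_window(k: int, alpha: float, beta: float, lam: float) -> tuple[int, int]:
    """High-mass window of the convolution index j (NB count) at total k."""
    nb_lo, nb_hi = _nb_support(alpha, beta)
    po_lo, po_hi = _poisson_support(lam)
    lo = max(0, nb_lo, k - po_hi)
    hi = min(k, nb_hi, k - po_lo)
    if hi < lo:  # k outside both central supports; fall back to the full sum
        return 0, k
    return lo, hi


def _conv_terms(k: int, alpha: float, beta: float, lam: float):
    """Log summands of the NB (x) Poisson convolution at count k.

    For large k the index is restricted to the window where either
    component retains mass (per-side tails ~1e-18), matching the
    truncation of :func:`delaporte_pmf_range`.
    """
    if k <= _DIRECT_CONV_MAX:
        lo, hi = 0, k
    else:
        lo, hi = _j_window(k, alpha, beta, lam)
    j = np.arange(lo, hi + 1)
    nb_part = (
        gammaln(alpha + j)
        - gammaln(alpha)
        - gammaln(j + 1)
        + j * np.log(beta)
        - (alpha + j) * np.log1p(beta)
    )
    pois_part = (k - j) * np.log(lam) - lam - gammaln(k - j + 1)
    return j, nb_part + pois_part


def delaporte_loglik_grad(k, alpha: float, beta: float, lam: float):
    """Summed log-likelihood of counts ``k`` and its gradient.

    Returns (loglik, d/dalpha, d/dbeta, d/dlam) of
    sum_i log P(X = k_i | alpha, beta, lam), using the posterior
    weights of the convolution index for the derivatives. Requires
    strictly positive parameters.
    """
    if alpha <= 0 or beta <= 0 or lam <= 0:
        raise ValueError("gradient requires strictly positive parameters")
    k_arr = np.atleast_1d(np.asarray(k, dtype=np.int64))
    ll = 0.0
    ga = gb = gl = 0.0
    for ki in k_arr:
        j, terms = _conv_terms(int(ki), alpha, beta, lam)
        m = terms.max()
        w = np.exp(terms - m)
        s = w.sum()
        ll += m + np.log(s)
        w /= s
        ga += float(np.sum(w * (digamma(alpha + j) - digamma(alpha) - np.log1p(beta))))
        gb += float(np.sum(w * (j / beta - (alpha + j) / (1.0 + beta))))
        gl += float(np.sum(w * ((ki - j) / lam - 1.0)))
    return float(ll), ga, gb, gl


def delaporte_pmf(k, alpha: float, beta: float, lam: float):
    """P(X = k) for the Delaporte(alpha, beta, lambda) distribution."""
    return np.exp(delaporte_logpmf(k, alpha, beta, lam))


def _poisson_support(lam: float) -> tuple[int, int]:
    sd = np.sqrt(lam)
    lo = int(max(0, np.floor(lam - _TAIL_Z * sd - 10)))
    hi = int(np.ceil(lam + _TAIL_Z * sd + 60))
    return lo, hi


def _nb_support(alpha: float, beta: float) -> tuple[int, int]:
    mean = alpha * beta
    sd = np.sqrt(alpha * beta * (1.0 + beta))
    lo = int(max(0, np.floor(mean - _TAIL_Z * sd - 10)))
    # geometric right tail decays by log1p(1/beta) nats per count
    hi = int(np.ceil(mean + _TAIL_Z * sd + _TAIL_NATS / np.log1p(1.0 / beta) + 20))
    return lo, hi


def delaporte_pmf_range(
    kmax: int, alpha: float, beta: float, lam: float, kmin: int = 0
) -> np.ndarray:
    """pmf values for k = kmin .. kmax as one vector.

    Computed as the discrete convolution of the NB and Poisson component
    pmfs. For short supports (kmax below ~1000) the convolution is
    direct over the full 0..kmax range (exact); for long supports each
    component is truncated to its central mass (per-side tail around
    1e-18) and clipped to the requested window, so absolute errors are
    bounded near 1e-18 of the peak — far below any pmf value that
    influences a test at double precision.
    """
    _check_params(alpha, beta, lam)
    if kmax < kmin or kmin < 0:
        raise ValueError("need 0 <= kmin <= kmax")
    ks = np.arange(kmin, kmax + 1)
    p = 1.0 / (1.0 + beta)
    if alpha == 0 or beta == 0:
        if lam == 0:
            return np.where(ks == 0, 1.0, 0.0)
        return stats.poisson.pmf(ks, lam)
    if lam == 0:
        return stats.nbinom.pmf(ks, alpha, p)

    if kmax <= _DIRECT_CONV_MAX:
        nb = stats.nbinom.pmf(np.arange(kmax + 1), alpha, p)
        po = stats.poisson.pmf(np.arange(kmax + 1), lam)
        full = np.convolve(nb, po)[: kmax + 1]
        return full[kmin:]

    nb_lo0, nb_hi0 = _nb_support(alpha, beta)
    po_lo0, po_hi0 = _poisson_support(lam)
    # clip each component to what can contribute inside [kmin, kmax]
    nb_lo = max(nb_lo0, kmin - po_hi0)
    nb_hi = min(nb_hi0, kmax - po_lo0)
    po_lo = max(po_lo0, kmin - nb_hi0)
    po_hi = min(po_hi0, kmax - nb_lo0)
    out = np.zeros(kmax - kmin + 1)
    if nb_lo > nb_hi or po_lo > po_hi:
        return out
    nb = stats.nbinom.pmf(np.arange(nb_lo, nb_hi + 1), alpha, p)
    po = stats.poisson.pmf(np.arange(po_lo, po_hi + 1), lam)
    if len(nb) * len(po) <= 4 * _DIRECT_CONV_MAX**2:
        conv = np.convolve(nb, po)
    else:
        conv = np.clip(fftconvolve(nb, po), 0.0, None)
    # conv[i] corresponds to k = nb_lo + po_lo + i
    offset = nb_lo + po_lo
    lo = max(kmin, offset)
    hi = min(kmax, offset + len(conv) - 1)
    if hi >= lo:
        out[lo - kmin : hi - kmin + 1] = conv[lo - offset : hi - offset + 1]
    return out
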