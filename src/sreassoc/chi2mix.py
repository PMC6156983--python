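"""Tail probabilities of positive linear combinations of 1-df chi-squares.

``chi2mix_sf(q, lambdas)`` evaluates P(sum_k lambda_k * X_k > q) with
X_k ~ iid chi-square(1), the null distribution of every quadratic-form score
statistic in the association module. The primary route inverts the
characteristic function (Imhof's formula, numerically equivalent to the
Davies algorithm at the tolerances used here); when the quadrature fails to
converge the Liu et al. four-moment non-central chi-square approximation is
used as a fallback and flagged.

Imhof's representation for Q = sum lambda_k X_k:

    P(Q > q) = 1/2 + (1/pi) * Int_0^inf sin(theta(u)) / (u * rho(u)) du
    theta(u) = (1/2) * sum_k arctan(lambda_k u) - q u / 2
    rho(u)   = prod_k (1 + lambda_k^2 u^2)^(1/4)

The integrand is smooth at u=0 (limit (sum lambda - q)/2) and decays like
u^(-(m/2+1)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.stats import chi2, ncx2, norm

__all__ = [
    "chi2mix_sf",
    "chi2mix_quantile",
    "spherical_sf",
    "liu_sf",
    "liu_quantile",
    "TailResult",
]

_P_FLOOR = 1e-300


@dataclass(frozen=True)
class TailResult:
    p: float
    method: str  # "imhof" | "liu" | "exact"
    converged: bool


def _validate(q: float, lambdas) -> np.ndarray:
    lam = np.asarray(lambdas, dtype=float).ravel()
    if lam.size == 0:
        raise ValueError("lambdas must be nonempty")
    if np.any(lam <= 0):
        raise ValueError("all mixture coefficients must be > 0")
    if q < 0:
        raise ValueError("q must be >= 0")
    return lam


def liu_sf(q: float, lambdas) -> float:
    """Liu–Tang–Zhang moment-matching survival function (fallback route)."""
    lam = _validate(q, lambdas)
    c1, c2, c3, c4 = (np.sum(lam**k) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    mu_q, sigma_q = c1, np.sqrt(2 * c2)
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2 * delta
    else:
        a = 1.0 / s1
        delta = 0.0
        df = a**2
    mu_x = df + delta
    sigma_x = np.sqrt(2 * (df + 2 * delta))
    t = (q - mu_q) / sigma_q
    x = t * sigma_x + mu_x
    if delta > 0:
        p = float(ncx2.sf(x, df, delta))
    else:
        p = float(chi2.sf(x, df))
    return min(max(p, _P_FLOOR), 1.0)


def liu_quantile(p_upper: float, lambdas) -> float:
    """Quantile q with P(Q > q) = p_upper under the Liu approximation."""
    lam = _validate(0.0, lambdas)
    c1, c2, c3, c4 = (np.sum(lam**k) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
    q_x = float(ncx2.isf(p_upper, df, delta)) if delta > 0 else float(chi2.isf(p_upper, df))
    mu_x = df + delta
    sigma_x = np.sqrt(2 * (df + 2 * delta))
    return (q_x - mu_x) / sigma_x * np.sqrt(2 * c2) + c1


def chi2mix_quantile(p_upper: float, lambdas, *, rtol: float = 1e-9) -> float:
    """Quantile q with P(Q > q) = p_upper, by inverting ``chi2mix_sf``.

    Bracketed from the Liu approximation and refined with Brent's method, so
    quantile and tail probability are mutually consistent to ``rtol``.
    """
    from scipy.optimize import brentq

    lam = _validate(0.0, lambdas)
    if not 0.0 < p_upper < 1.0:
        raise ValueError("p_upper must lie in (0, 1)")
    guess = max(liu_quantile(p_upper, lam), 1e-12)
    lo, hi = guess, guess
    while chi2mix_sf(lo, lam).p < p_upper and lo > 1e-14:
        lo /= 4.0
    while chi2mix_sf(hi, lam).p > p_upper:
        hi *= 4.0
    if lo == hi:
        return lo
    return float(
        brentq(lambda q: chi2mix_sf(q, lam).p - p_upper, lo, hi, rtol=rtol)
    )


def _saddlepoint_sf(q: float, lam: np.ndarray) -> float:
    """Lugannani–Rice saddlepoint tail, accurate in the deep tail where
    characteristic-function inversion is limited by absolute error."""
    from scipy.optimize import brentq

    lmax = lam.max()
    if q <= lam.sum():
        return 1.0  # only used in the right tail

    def kprime(t):
        return float(np.sum(lam / (1.0 - 2.0 * t * lam)))

    hi = 1.0 / (2.0 * lmax)
    t = brentq(lambda t: kprime(t) - q, 0.0, hi * (1 - 1e-12), xtol=1e-16)
    if t < 1e-10:
        return liu_sf(q, lam)
    K = -0.5 * float(np.sum(np.log1p(-2.0 * t * lam)))
    K2 = float(np.sum(2.0 * lam**2 / (1.0 - 2.0 * t * lam) ** 2))
    w = np.sqrt(2.0 * (t * q - K))
    v = t * np.sqrt(K2)
    p = float(norm.sf(w + np.log(v / w) / w))
    return min(max(p, _P_FLOOR), 1.0)


def _imhof_sf(q: float, lam: np.ndarray, epsabs: float) -> tuple[float, bool]:
    """Imhof integral, split to keep the oscillatory tail accurate.

    The integrand sin(theta0(u) - qu/2) / (u rho(u)) has a bounded phase
    theta0 plus a linear oscillation of frequency q/2. Near the origin it is
    integrated directly; beyond that the sine is expanded so the linear
    oscillation becomes an explicit Fourier weight handled by the QAWF/QAWO
    quadrature, which sums oscillation cycles to convergence.
    """

    def theta0(u):
        return 0.5 * np.sum(np.arctan(lam * u))

    def inv_urho(u):
        return 1.0 / (u * np.exp(0.25 * np.sum(np.log1p((lam * u) ** 2))))

    def integrand(u: float) -> float:
        if u == 0.0:
            return 0.5 * (lam.sum() - q)
        return np.sin(theta0(u) - 0.5 * q * u) * inv_urho(u)

    w = 0.5 * q
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        if w * 20.0 < lam.max():
            # oscillation negligible over the decay range
            val, err = integrate.quad(
                integrand, 0.0, np.inf, epsabs=epsabs, epsrel=0.0, limit=500
            )
        else:
            u1 = np.pi / (2.0 * w)
            v1, e1 = integrate.quad(
                integrand, 0.0, u1, epsabs=epsabs / 3, epsrel=0.0, limit=500
            )
            v2, e2 = integrate.quad(
                lambda u: np.sin(theta0(u)) * inv_urho(u),
                u1,
                np.inf,
                weight="cos",
                wvar=w,
                epsabs=epsabs / 3,
                limit=500,
            )
            v3, e3 = integrate.quad(
                lambda u: np.cos(theta0(u)) * inv_urho(u),
                u1,
                np.inf,
                weight="sin",
                wvar=w,
                epsabs=epsabs / 3,
                limit=500,
            )
            val = v1 + v2 - v3
            err = e1 + e2 + e3
    p = 0.5 + val / np.pi
    converged = bool(np.isfinite(p)) and err < max(1e-7, 100 * epsabs)
    return p, converged


def spherical_sf(c: float, lambdas, dim: int, *, epsabs: float = 1e-11) -> float:
    """Exact tail of a quadratic-form ratio on the unit sphere.

    Computes P(sum_k lambda_k z_k^2 > c * ||z||^2) for z standard normal in
    R^dim (equivalently z/||z|| uniform on the sphere), with the remaining
    dim - m coordinates carrying coefficient zero. This is the exact null of
    a score quadratic form standardized by the residual sum of squares — the
    finite-sample analogue of the chi-square mixture, to which it converges
    as dim grows.

    Uses the indefinite-quadratic-form identity
    P(sum lambda z^2 > c sum z^2) = P(sum (lambda_k - c) z_k^2
    - c chi2_{dim-m} > 0), evaluated by characteristic-function inversion.
    """
    lam = np.asarray(lambdas, dtype=float).ravel()
    if lam.size == 0:
        raise ValueError("lambdas must be nonempty")
    if np.any(lam <= 0):
        raise ValueError("all mixture coefficients must be > 0")
    if dim < lam.size:
        raise ValueError("dim must be at least the number of coefficients")
    if c <= 0:
        return 1.0
    if c >= lam.max():
        return _P_FLOOR
    if lam.size == 1:
        # rank-1 form: lambda * u1^2 > c with u1^2 ~ Beta(1/2, (dim-1)/2)
        from scipy.stats import beta as beta_rv

        return min(max(float(beta_rv.sf(c / lam[0], 0.5, (dim - 1) / 2.0)), _P_FLOOR), 1.0)

    coeffs = lam - c
    h_rest = dim - lam.size
    if np.all(coeffs < 0):
        return _P_FLOOR
    # the event {sum a_r chi2 > 0} is scale-free: normalize so the
    # integrand's decay happens at u = O(1) and quadrature resolves it
    scale = max(float(np.abs(coeffs).max()), c)
    coeffs = coeffs / scale
    c_n = c / scale

    def integrand(u: float) -> float:
        if u == 0.0:
            return 0.5 * (coeffs.sum() - c_n * h_rest)
        au = coeffs * u
        theta = 0.5 * (np.arctan(au).sum() + h_rest * np.arctan(-c_n * u))
        log_rho = 0.25 * (
            np.log1p(au * au).sum() + h_rest * np.log1p((c_n * u) ** 2)
        )
        return np.sin(theta) * np.exp(-log_rho - np.log(u))

    # the envelope 1/(u e^log_rho) decays like u^-(dim/2+1); truncate where
    # it falls below 1e-30 so the quadrature works on a finite interval
    def log_env(u: float) -> float:
        return 0.25 * (
            np.log1p((coeffs * u) ** 2).sum() + h_rest * np.log1p((c_n * u) ** 2)
        ) + np.log(u)

    u_hi = 1.0
    while log_env(u_hi) < 69.0 and u_hi < 1e8:
        u_hi *= 2.0
    # integrate decade by decade: the integrand's support sits at u = O(1)
    # after normalization, and a single quadrature over a wide truncated
    # interval can step right over it
    edges = [0.0]
    e = 1.0
    while e < u_hi:
        edges.append(e)
        e *= 10.0
    edges.append(u_hi)
    val = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        for a, b in zip(edges[:-1], edges[1:]):
            # envelope bound: segments contributing < ~1e-15 are skipped
            if a > 0.0 and log_env(a) - np.log(b - a) > 34.0:
                continue
            v, _ = integrate.quad(
                integrand, a, b, epsabs=epsabs, epsrel=0.0, limit=200
            )
            val += v
    p = 0.5 + val / np.pi
    if p < 1e-8:
        # inversion is absolute-error limited; switch to a saddlepoint
        p = _indefinite_saddlepoint_sf(coeffs, h_rest, c_n)
    return min(max(p, _P_FLOOR), 1.0)


def _indefinite_saddlepoint_sf(coeffs: np.ndarray, h_rest: int, c: float) -> float:
    """Lugannani–Rice tail P(sum a_r chi2_{h_r} > 0) for signed coefficients.

    Used for the deep tail of the spherical ratio, where the positive part
    {lambda_k - c} is outweighed on average by the negative remainder."""
    from scipy.optimize import brentq

    a = coeffs[np.abs(coeffs) > 0]
    h = np.ones(a.size)
    if h_rest > 0 and c > 0:
        a = np.append(a, -c)
        h = np.append(h, float(h_rest))

    def kprime(t):
        return float(np.sum(h * a / (1.0 - 2.0 * t * a)))

    a_pos = a[a > 0].max()
    a_neg = a[a < 0].min()
    lo = 1.0 / (2.0 * a_neg) * (1 - 1e-12)
    hi = 1.0 / (2.0 * a_pos) * (1 - 1e-12)
    t = brentq(kprime, lo, hi, xtol=1e-16)
    if abs(t) < 1e-12:
        return 0.5
    K = -0.5 * float(np.sum(h * np.log1p(-2.0 * t * a)))
    K2 = float(np.sum(2.0 * h * a**2 / (1.0 - 2.0 * t * a) ** 2))
    w = np.sign(t) * np.sqrt(max(-2.0 * K, 0.0))
    v = t * np.sqrt(K2)
    if w == 0.0:
        return 0.5
    p = float(norm.sf(w) + norm.pdf(w) * (1.0 / v - 1.0 / w))
    return min(max(p, _P_FLOOR), 1.0)


def chi2mix_sf(q: float, lambdas, *, epsabs: float = 1e-10) -> TailResult:
    """P(sum lambda_k chi2_1 > q), clipped to (1e-300, 1].

    Exact chi-square forms are used when all coefficients are equal; Imhof
    inversion otherwise, with the Liu approximation as fallback when the
    quadrature does not converge or leaves the unit interval.
    """
    lam = _validate(q, lambdas)
    if np.allclose(lam, lam[0], rtol=1e-12, atol=0.0):
        p = float(chi2.sf(q / lam[0], df=lam.size))
        return TailResult(min(max(p, _P_FLOOR), 1.0), "exact", True)
    p, ok = _imhof_sf(q, lam, epsabs)
    if ok and p < 1e-8:
        # inversion is absolute-error limited; the saddlepoint keeps
        # relative accuracy in the deep tail
        return TailResult(_saddlepoint_sf(q, lam), "saddlepoint", True)
    if ok and _P_FLOOR <= p <= 1.0 + 1e-9:
        return TailResult(min(max(p, _P_FLOOR), 1.0), "imhof", True)
    return TailResult(liu_sf(q, lam), "liu", False)
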