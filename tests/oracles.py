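"""Independent oracles used by the test suite.

These deliberately avoid the implementation's code paths: brute-force
substring search, direct step-up FDR evaluation, an independently coded
weighted burden score test, and a residual-permutation oracle for the
grid-minimum-p SKAT-O combination.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.stats import beta as beta_dist

from sreassoc.chi2mix import spherical_sf


def brute_force_scan(window: str, hexamers) -> bool:
    """Exhaustive check over all 6 hexamer offsets of an 11-mer."""
    return any(
        window[i : i + 6] in hexamers and "N" not in window[i : i + 6]
        for i in range(len(window) - 5)
    )


def bh_stepup(pvalues) -> np.ndarray:
    """Benjamini–Hochberg from the definition: q_i = min_{j>=i} m p_(j) / j."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj[i] = running
    return adj


def burden_score_test(G, mafs, null, a1=1.0, a2=25.0) -> float:
    """Weighted burden (collapsing) score test p-value, coded independently.

    Exact under Gaussian errors: the squared correlation between the
    covariate-adjusted burden and the residual direction is Beta(1/2,
    (d-1)/2) distributed on the d-dimensional residual sphere.
    """
    w = beta_dist.pdf(np.asarray(mafs, dtype=float), a1, a2)
    burden = np.asarray(G, dtype=float) @ w
    X = null.X
    coef, *_ = np.linalg.lstsq(X, burden, rcond=None)
    b_perp = burden - X @ coef
    r = null.residuals
    u1sq = (burden @ r) ** 2 / ((b_perp @ b_perp) * (r @ r))
    d = r.size - X.shape[1]
    return float(beta_dist.sf(u1sq, 0.5, (d - 1) / 2))


def mc_chi2mix_sf(q, lambdas, n_draws, seed) -> tuple[float, float]:
    """Monte-Carlo estimate of P(sum lambda_k chi2_1 > q) and its SE."""
    rng = np.random.default_rng(seed)
    lam = np.asarray(lambdas, dtype=float)
    hits = 0
    block = 2_000_000
    left = n_draws
    while left > 0:
        k = min(block, left)
        left -= k
        draws = rng.chisquare(1, size=(k, lam.size)) @ lam
        hits += int((draws > q).sum())
    p = hits / n_draws
    return p, float(np.sqrt(max(p * (1 - p), 1e-12) / n_draws))


def skato_permutation_p(
    bin, null, config, B: int = 200_000, seed: int = 0
) -> tuple[float, float]:
    """Residual-permutation estimate of the SKAT-O grid-minimum p-value.

    Residuals are permuted, the null model is refit on the permuted vector,
    and the rho-grid minimum p is recomputed for every permutation. Because
    each per-rho p is a monotone function of its Q_rho, the grid-min-p event
    {min_rho p_rho <= p_obs} equals {exists rho: Q_rho >= q_rho(p_obs)}, so
    the per-rho thresholds are inverted once. Returns (p_hat, se).
    """
    from sreassoc.skato import skat_o

    res = skat_o(bin, null, config)
    lam = res.diagnostics["per_rho_lambdas"]
    dim = res.diagnostics["resid_dim"]
    pmin_obs = min(res.per_rho_p.values())
    thresholds = {}
    for rho, l in lam.items():
        thresholds[rho] = brentq(
            lambda c: spherical_sf(c, l, dim) - pmin_obs,
            0.0,
            float(np.max(l)),
            xtol=1e-13,
            rtol=1e-13,
        )

    w = beta_dist.pdf(bin.mafs, *config.weight_beta)
    Gw = np.asarray(bin.G, dtype=float)[null.kept] * w
    X, resid = null.X, null.residuals
    n = resid.size
    proj = X @ np.linalg.pinv(X)  # hat matrix; refit = apply I - H
    rng = np.random.default_rng(seed)
    hits, done, batch = 0, 0, 20_000
    base = np.broadcast_to(resid, (batch, n))
    while done < B:
        k = min(batch, B - done)
        done += k
        Rp = rng.permuted(base[:k], axis=1)
        Rp = Rp - Rp @ proj.T
        rss = (Rp**2).sum(axis=1)
        S = Rp @ Gw
        ssq = (S**2).sum(axis=1)
        ssum = S.sum(axis=1) ** 2
        reject = np.zeros(k, dtype=bool)
        for rho, thr in thresholds.items():
            reject |= ((1 - rho) * ssq + rho * ssum) / rss >= thr
        hits += int(reject.sum())
    p = (hits + 1) / (B + 1)
    return p, float(np.sqrt(p * (1 - p) / B))
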