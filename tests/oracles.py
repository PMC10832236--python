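"""Independent, formula-literal reference implementations used as test oracles.

Deliberately naive (explicit loops, brentq root finding instead of Newton,
no vectorization) and kept separate from the package code paths they check.
"""

import numpy as np
from scipy import optimize, special, stats


def dl_literal(y, v):
    """DerSimonian-Laird combination, written directly from the formulas."""
    y = [float(a) for a in y]
    v = [float(a) for a in v]
    k = len(y)
    w = [1.0 / vi for vi in v]
    sw = sum(w)
    y_fe = sum(wi * yi for wi, yi in zip(w, y)) / sw
    Q = sum(wi * (yi - y_fe) ** 2 for wi, yi in zip(w, y))
    denom = sw - sum(wi**2 for wi in w) / sw
    tau2 = max(0.0, (Q - (k - 1)) / denom)
    wr = [1.0 / (vi + tau2) for vi in v]
    swr = sum(wr)
    mu = sum(wi * yi for wi, yi in zip(wr, y)) / swr
    se = swr**-0.5
    z = mu / se
    p = 2.0 * stats.norm.sf(abs(z))
    i2 = max(0.0, (Q - (k - 1)) / Q) * 100.0 if Q > 0 else 0.0
    return {"mu_hat": mu, "se_mu": se, "tau2": tau2, "Q": Q, "z": z,
            "p": max(p, np.finfo(float).tiny), "I2": i2}


def bh_literal(p):
    """Benjamini-Hochberg step-up: p*m/rank with cumulative minimum."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        val = min(prev, p[idx] * m / rank)
        adj[idx] = val
        prev = val
    return adj


def prior_literal(s2, df):
    """Variance prior (d0, s0^2) by moment matching, with brentq inversion."""
    z = np.log(np.asarray(s2, dtype=float))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(e.mean()))
    half_d0 = optimize.brentq(
        lambda x: special.polygamma(1, x) - evar, 1e-8, 1e8, xtol=1e-14
    )
    d0 = 2.0 * half_d0
    s02 = np.exp(e.mean() + special.digamma(half_d0) - np.log(half_d0))
    return float(d0), float(s02)


def moderated_literal(Y, X, c, W=None):
    """Per-gene weighted least squares + moderated t, gene by gene."""
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    c = np.asarray(c, dtype=float)
    G, n = Y.shape
    p_cols = X.shape[1]
    if W is None:
        W = np.ones_like(Y)
    df = n - p_cols
    logfc = np.empty(G)
    v = np.empty(G)
    s2 = np.empty(G)
    for g in range(G):
        Wg = np.diag(W[g])
        A = X.T @ Wg @ X
        Ainv = np.linalg.inv(A)
        beta = Ainv @ X.T @ Wg @ Y[g]
        logfc[g] = c @ beta
        v[g] = c @ Ainv @ c
        r = Y[g] - X @ beta
        s2[g] = (W[g] * r**2).sum() / df
    d0, s02 = prior_literal(s2[s2 > 0], df)
    if np.isinf(d0):
        s2_post = np.full(G, s02)
        t = logfc / np.sqrt(s2_post * v)
        p = 2.0 * stats.norm.sf(np.abs(t))
        df_total = np.full(G, np.inf)
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        t = logfc / np.sqrt(s2_post * v)
        df_total = np.full(G, d0 + df)
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return {"logFC": logfc, "v": v, "s2": s2, "d0": d0, "s02": s02,
            "t": t, "p": np.clip(p, np.finfo(float).tiny, 1.0),
            "df_total": df_total}


def transfer_loop(index, targets):
    """Naive double loop over (gene, miRNA) pairs; returns raw mean scores."""
    scores = {}
    for gene in sorted({g for gs in targets.values() for g in gs}):
        vals = []
        for m, val in index.items():
            if gene in targets.get(m, set()):
                vals.append(val)
        if vals:
            scores[gene] = sum(vals) / len(vals)
    return scores


def logistic_irls(x, y, maxiter=200, tol=1e-12):
    """Reference univariate logistic fit (intercept + slope) via IRLS.

    Returns (slope, wald_p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(maxiter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / np.maximum(w, 1e-12)
        WX = X * w[:, None]
        new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    se = np.sqrt(cov[1, 1])
    zstat = beta[1] / se
    return float(beta[1]), float(2.0 * stats.norm.sf(abs(zstat)))
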