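"""Independent scalar-loop reference implementation of parametric ComBat.

Deliberately written gene-by-gene with explicit loops, directly from the
published empirical-Bayes location/scale equations, as an oracle for the
vectorized implementation. Supports batch indicators plus one optional
categorical covariate. Slow; use only on tiny matrices.
"""

import numpy as np


def _ols(X, y):
    return np.linalg.solve(X.T @ X, X.T @ y)


def reference_combat(Y, batches, covariates=None, conv=1e-8):
    """Y: genes x samples array (log scale). Returns the adjusted array."""
    Y = np.asarray(Y, dtype=float)
    G, n = Y.shape
    levels = sorted(set(batches))
    m = len(levels)
    batch_idx = {b: [j for j, x in enumerate(batches) if x == b] for b in levels}

    # design: batch indicator columns, then covariate dummies (drop first level)
    cols = []
    for b in levels:
        cols.append([1.0 if x == b else 0.0 for x in batches])
    if covariates is not None:
        cov_levels = sorted(set(covariates))[1:]
        for c in cov_levels:
            cols.append([1.0 if x == c else 0.0 for x in covariates])
    X = np.array(cols).T

    # per-gene OLS fit, grand mean, pooled variance
    beta = np.zeros((X.shape[1], G))
    for g in range(G):
        beta[:, g] = _ols(X, Y[g])
    n_per = np.array([len(batch_idx[b]) for b in levels], dtype=float)
    grand = np.zeros(G)
    for g in range(G):
        grand[g] = sum(n_per[i] / n * beta[i, g] for i in range(m))
    var_pooled = np.zeros(G)
    for g in range(G):
        resid = Y[g] - X @ beta[:, g]
        var_pooled[g] = np.mean(resid**2)

    stand_mean = np.zeros((G, n))
    for g in range(G):
        for j in range(n):
            sm = grand[g]
            for k in range(m, X.shape[1]):
                sm += X[j, k] * beta[k, g]
            stand_mean[g, j] = sm
    Z = np.zeros((G, n))
    for g in range(G):
        Z[g] = (Y[g] - stand_mean[g]) / np.sqrt(var_pooled[g])

    out = Y.copy()
    # per-batch EB shrinkage
    gamma_hat = np.zeros((m, G))
    delta_hat = np.zeros((m, G))
    for i, b in enumerate(levels):
        idx = batch_idx[b]
        for g in range(G):
            zi = Z[g, idx]
            gamma_hat[i, g] = zi.mean()
            delta_hat[i, g] = zi.var(ddof=1)
    for i, b in enumerate(levels):
        idx = batch_idx[b]
        ni = len(idx)
        g_bar = gamma_hat[i].mean()
        t2 = gamma_hat[i].var(ddof=1)
        dm, ds2 = delta_hat[i].mean(), delta_hat[i].var(ddof=1)
        a = (2 * ds2 + dm**2) / ds2
        bb = (dm * ds2 + dm**3) / ds2
        g_old = gamma_hat[i].copy()
        d_old = delta_hat[i].copy()
        for _ in range(5000):
            g_new = np.zeros(G)
            d_new = np.zeros(G)
            for g in range(G):
                g_new[g] = (t2 * ni * gamma_hat[i, g] + d_old[g] * g_bar) / (t2 * ni + d_old[g])
                s2 = float(((Z[g, idx] - g_new[g]) ** 2).sum())
                d_new[g] = (0.5 * s2 + bb) / (ni / 2.0 + a - 1.0)
            change = max(
                np.abs(g_new - g_old).max() / np.abs(g_old).max(),
                np.abs(d_new - d_old).max() / np.abs(d_old).max(),
            )
            g_old, d_old = g_new, d_new
            if change < conv:
                break
        for g in range(G):
            for j in idx:
                z_adj = (Z[g, j] - g_old[g]) / np.sqrt(d_old[g])
                out[g, j] = z_adj * np.sqrt(var_pooled[g]) + stand_mean[g, j]
    return out
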