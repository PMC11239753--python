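"""Brute-force dense oracle for the model-based covariance.

Everything is rebuilt from first principles with plain Python loops —
exposure bookkeeping, cell-by-cell correlation entries, one giant
block-diagonal covariance — and the covariance of the estimator is obtained
by explicitly inverting the stacked system.  No code is shared with the
package's structured per-cluster assembly.
"""

import numpy as np
from scipy.linalg import block_diag


def oracle_cluster_rows(layout, mspec, cluster):
    """Design rows via independent loop bookkeeping (individual-major)."""
    T = layout.n_periods
    crossover = layout.crossover_period[layout.sequence_of_cluster(cluster)]
    n0, n1 = layout.il_allocation[cluster]
    rows = []
    for k in range(n0 + n1):
        treated = k >= n0
        for j in range(1, T + 1):
            a_il = j if treated else 0
            a_cl = j - crossover + 1 if j >= crossover else 0
            a_int = 0
            for jp in range(1, j + 1):
                il_on = treated
                cl_on = jp >= crossover
                if il_on and cl_on:
                    a_int += 1
            if mspec.time_trend == "linear":
                time = [1.0, float(j)]
            elif mspec.time_trend == "categorical":
                time = [1.0] + [float(j == t) for t in range(2, T + 1)]
            else:
                time = [1.0] + [float(j) ** p for p in range(1, mspec.poly_degree + 1)]
            if mspec.effect_model == "average":
                eff = [float(a_il >= 1), float(a_cl >= 1), float(a_int >= 1)]
            else:
                c0, c1, c2 = mspec.scaling
                eff = [a_il / c0, a_cl / c1, a_int / c2]
            rows.append(time + eff)
    return np.array(rows)


def oracle_correlation(n_individuals, n_periods, a0, a1, a2):
    n = n_individuals * n_periods
    R = np.empty((n, n))
    for r in range(n):
        for c in range(n):
            ind_r, per_r = divmod(r, n_periods)
            ind_c, per_c = divmod(c, n_periods)
            if r == c:
                R[r, c] = 1.0
            elif ind_r == ind_c:
                R[r, c] = a2
            elif per_r == per_c:
                R[r, c] = a0
            else:
                R[r, c] = a1
    return R


def oracle_model_covariance(layout, mspec, cspec, vspec):
    """Omega from one giant stacked X and block-diagonal V, inverted densely."""
    X_blocks, V_blocks, D_blocks = [], [], []
    theta = np.asarray(mspec.theta)
    for i in range(layout.n_clusters):
        X = oracle_cluster_rows(layout, mspec, i)
        eta = X @ theta
        if mspec.link == "identity":
            mu, dmu = eta, np.ones_like(eta)
        elif mspec.link == "log":
            mu = np.exp(eta)
            dmu = mu
        else:
            mu = 1 / (1 + np.exp(-eta))
            dmu = mu * (1 - mu)
        if vspec.family == "gaussian":
            v = np.ones_like(mu)
        elif vspec.family == "poisson":
            v = mu
        else:
            v = mu * (1 - mu)
        R = oracle_correlation(layout.cohort_size[i], layout.n_periods, *cspec.alpha)
        A_half = np.diag(np.sqrt(v))
        V_blocks.append(vspec.dispersion * A_half @ R @ A_half)
        D_blocks.append(np.diag(dmu) @ X)
    D = np.vstack(D_blocks)
    V = block_diag(*V_blocks)
    return np.linalg.inv(D.T @ np.linalg.inv(V) @ D)
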