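"""Shared test utilities: random flat instances and a pooled objective."""

import numpy as np

from fedmorph.design import InstitutionShard


def flat_instance(seed, n=None, n_groups=None, group_size=None, n_sites=1,
                  support_frac=0.1, noise_sd=1.0):
    """Random group-LASSO instance with contiguous uniform groups.

    Returns (X, y, group_cols, weights, shards).
    """
    rng = np.random.default_rng(seed)
    n = n or int(rng.integers(40, 201))
    n_groups = n_groups or int(rng.integers(10, 201))
    u = group_size or int(rng.integers(1, 7))
    p = n_groups * u
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    k = max(1, int(round(support_frac * n_groups)))
    for g in rng.choice(n_groups, k, replace=False):
        beta[g * u : (g + 1) * u] = rng.standard_normal(u)
    y = X @ beta + noise_sd * rng.standard_normal(n)
    cols = [np.arange(g * u, (g + 1) * u) for g in range(n_groups)]
    w = np.full(n_groups, np.sqrt(u), dtype=float)
    perm = rng.permutation(n)
    shards = [
        InstitutionShard(site_id=i, X_i=X[idx], y_i=y[idx], row_ids=idx)
        for i, idx in enumerate(np.array_split(perm, n_sites))
    ]
    return X, y, cols, w, shards


def full_objective(X, y, beta, lam, cols, w):
    """Reference objective computed directly on the pooled design."""
    r = y - X @ beta
    pen = sum(wi * np.linalg.norm(beta[c]) for wi, c in zip(w, cols))
    return 0.5 * float(r @ r) + lam * pen


def oracle_active_set(beta, cols, tol=1e-10):
    return {g for g, c in enumerate(cols) if np.linalg.norm(beta[c]) > tol}
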