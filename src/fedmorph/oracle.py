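"""Centralized group-LASSO solver used as an independent cross-check.

Accelerated proximal gradient (FISTA) on the pooled design, with the
global Lipschitz constant from the largest singular value of X.  It shares
no code path with the federated block coordinate descent solver, so
agreement between the two certifies both.
"""

from __future__ import annotations

import numpy as np

__all__ = ["prox_gradient_solve"]


def _layout(group_cols):
    """(G, u) reshape parameters if groups are uniform and contiguous."""
    sizes = {len(c) for c in group_cols}
    if len(sizes) != 1:
        return None
    u = sizes.pop()
    start = 0
    for c in group_cols:
        c = np.asarray(c)
        if not np.array_equal(c, np.arange(start, start + u)):
            return None
        start += u
    return len(group_cols), u


def prox_gradient_solve(
    X: np.ndarray,
    y: np.ndarray,
    group_cols,
    weights,
    lam: float,
    tol: float = 1e-10,
    max_iter: int = 100000,
) -> np.ndarray:
    """Minimize 1/2||y - X beta||^2 + lam * sum_g w_g ||beta_g|| by FISTA."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n, p = X.shape
    weights = np.asarray(weights, dtype=np.float64)
    if min(n, p) <= 500:
        L = float(np.linalg.norm(X, 2)) ** 2
    else:
        from scipy.sparse.linalg import svds

        L = float(svds(X, k=1, return_singular_vectors=False)[0]) ** 2
    L = max(L, 1e-12)
    thr = lam * weights / L

    shape = _layout(group_cols)

    def prox(z):
        if shape is not None:
            G, u = shape
            blk = z.reshape(G, u)
            nrm = np.linalg.norm(blk, axis=1)
            factor = np.maximum(0.0, 1.0 - thr / np.maximum(nrm, 1e-300))
            return (blk * factor[:, None]).ravel()
        out = z.copy()
        for c, t in zip(group_cols, thr):
            nrm = np.linalg.norm(z[c])
            out[c] = 0.0 if nrm <= t else z[c] * (1.0 - t / nrm)
        return out

    def penalty(b):
        if shape is not None:
            G, u = shape
            return float(weights @ np.linalg.norm(b.reshape(G, u), axis=1))
        return float(
            sum(w * np.linalg.norm(b[c]) for w, c in zip(weights, group_cols))
        )

    beta = np.zeros(p)
    z = beta.copy()
    t_k = 1.0
    obj_prev = np.inf
    for it in range(max_iter):
        grad = X.T @ (X @ z - y)
        beta_new = prox(z - grad / L)
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_k * t_k))
        z = beta_new + ((t_k - 1.0) / t_next) * (beta_new - beta)
        beta, t_k = beta_new, t_next
        if it % 10 == 9:
            r = y - X @ beta
            obj = 0.5 * float(r @ r) + lam * penalty(beta)
            if abs(obj_prev - obj) <= tol * max(1.0, abs(obj)):
                break
            obj_prev = obj
    return beta
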