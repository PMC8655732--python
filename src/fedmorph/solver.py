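"""Federated block coordinate descent (BCD) for the group LASSO.

The objective is

    F(beta) = 1/2 ||y - sum_g X_g beta_g||_2^2 + lambda * sum_g w_g ||beta_g||_2

with the squared loss decomposed over institutions, each holding a private
row slice (X^i, y^i).  Each block update needs only the master-aggregated
gradient sum_i (X_g^i)^T (X^i beta - y^i) and the aggregated per-group Gram
blocks; row-level data never leave a site.

One block update is a proximal step with the blockwise Lipschitz constant
L_g (largest eigenvalue of the aggregated Gram of group g):

    beta_g <- S_{lambda w_g / L_g}( beta_g - grad_g / L_g )

where S_t is the group soft-thresholding (shrinkage) operator.  Cycling
over groups in a fixed order gives monotone descent; convergence is
declared when the relative objective change over an epoch drops below
``tol``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .design import DimensionError, InstitutionShard
from .federation import Federation

__all__ = [
    "SolverConfig",
    "Solution",
    "group_soft_threshold",
    "objective",
    "fbcd_solve",
    "DivergenceError",
]

logger = logging.getLogger(__name__)


class DivergenceError(RuntimeError):
    """The objective became non-finite."""


@dataclass(frozen=True)
class SolverConfig:
    """Settings for one group-LASSO solve.

    lambda_rel is relative to lambda_max (the smallest penalty for which
    the all-zero solution is optimal); tol is the relative objective-change
    stopping threshold per epoch.
    """

    lambda_rel: float = 0.5
    tol: float = 1e-8
    max_epochs: int = 1000
    group_order: str = "fixed"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.lambda_rel <= 1:
            raise ValueError(f"lambda_rel must be in (0, 1], got {self.lambda_rel}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.group_order not in ("fixed", "shuffled"):
            raise ValueError("group_order must be 'fixed' or 'shuffled'")


@dataclass
class Solution:
    """Result of one solve: coefficients plus convergence certificates."""

    beta: np.ndarray
    objective: float
    epochs_run: int
    converged: bool
    kkt_gap: float
    lam: float
    n_group_updates: int = 0
    active_groups: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def group_soft_threshold(z: np.ndarray, t: float) -> np.ndarray:
    """Group shrinkage: z * max(0, 1 - t/||z||_2); zero when ||z||_2 <= t."""
    if t < 0:
        raise ValueError(f"threshold must be non-negative, got {t}")
    z = np.asarray(z, dtype=np.float64)
    nz = np.linalg.norm(z)
    if nz <= t or nz == 0.0:
        return np.zeros_like(z)
    return z * (1.0 - t / nz)


def _as_federation(shards, group_cols, record=False) -> Federation:
    if isinstance(shards, Federation):
        return shards
    return Federation(shards, group_cols, record=record)


def objective(shards, beta, lam, group_cols, weights) -> float:
    """F(beta) assembled from per-site partial residual norms only."""
    fed = _as_federation(shards, group_cols)
    beta = np.asarray(beta, dtype=np.float64)
    if beta.shape[0] != fed.n_features:
        raise DimensionError(
            f"beta has length {beta.shape[0]}, expected {fed.n_features}"
        )
    fed.start_residual(beta)
    pen = sum(
        w * np.linalg.norm(beta[c]) for w, c in zip(weights, fed_group_cols(fed))
    )
    return 0.5 * fed.residual_sq() + lam * pen


def fed_group_cols(fed: Federation):
    return fed.workers[0].group_cols


def _lambda_max_from(fed: Federation, weights: np.ndarray) -> float:
    fed.start_residual(np.zeros(fed.n_features))
    corr = fed.xt_residual()  # == -X^T y stacked per group
    norms = np.linalg.norm(corr, axis=1)
    return float(np.max(norms / weights))


def fbcd_solve(
    shards,
    group_cols=None,
    weights=None,
    config: SolverConfig | None = None,
    warm_start: Solution | np.ndarray | None = None,
    lam: float | None = None,
    lam_max: float | None = None,
    candidates: np.ndarray | None = None,
    record: bool = False,
) -> Solution:
    """Solve the group LASSO by federated proximal BCD.

    ``shards`` may be a list of :class:`InstitutionShard` or a prepared
    :class:`~fedmorph.federation.Federation`.  ``candidates`` restricts the
    cycled groups (used by safe screening); groups outside it are held at
    zero.  ``lam`` overrides the relative ``config.lambda_rel`` with an
    absolute penalty.
    """
    config = config or SolverConfig()
    fed = _as_federation(shards, group_cols, record=record)
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape[0] != fed.n_groups:
        raise DimensionError("one weight per group required")

    if lam is None:
        if lam_max is None:
            lam_max = _lambda_max_from(fed, weights)
        lam = config.lambda_rel * lam_max

    L = fed.lipschitz()
    p = fed.n_features
    cols = fed_group_cols(fed)

    if isinstance(warm_start, Solution):
        beta = warm_start.beta.copy()
    elif warm_start is not None:
        beta = np.asarray(warm_start, dtype=np.float64).copy()
    else:
        beta = np.zeros(p)

    if candidates is None:
        order = np.arange(fed.n_groups)
    else:
        order = np.asarray(sorted(candidates), dtype=int)
        outside = np.setdiff1d(np.arange(fed.n_groups), order)
        for g in outside:
            beta[cols[g]] = 0.0

    rng = np.random.default_rng(config.seed)

    fed.start_residual(beta)
    bnorm = np.array([np.linalg.norm(beta[c]) for c in cols])
    active = bnorm > 0
    obj = 0.5 * fed.residual_sq() + lam * float(weights @ bnorm)
    n_updates = 0
    converged = False
    epochs = 0
    batched = fed.supports_runs()

    for epoch in range(1, config.max_epochs + 1):
        epochs = epoch
        if config.group_order == "shuffled":
            cycle = rng.permutation(order)
        else:
            cycle = order
        i = 0
        n_cycle = len(cycle)
        while i < n_cycle:
            g = int(cycle[i])
            if active[g]:
                grad = fed.gradient(g)
                bg = beta[cols[g]]
                nb = group_soft_threshold(bg - grad / L[g], lam * weights[g] / L[g])
                delta = nb - bg
                if np.any(delta):
                    fed.apply_update(g, delta)
                    beta[cols[g]] = nb
                nrm = np.linalg.norm(nb)
                bnorm[g] = nrm
                active[g] = nrm > 0
                n_updates += 1
                i += 1
                continue
            # run of currently-zero groups: batch the gradient queries
            j = i
            while j < n_cycle and not active[int(cycle[j])]:
                j += 1
            advanced = False
            k = i
            while k < j:
                # maximal stretch of consecutive group ids inside the run
                m = k
                while (
                    m + 1 < j
                    and int(cycle[m + 1]) == int(cycle[m]) + 1
                ):
                    m += 1
                g0, g1 = int(cycle[k]), int(cycle[m]) + 1
                if batched and g1 - g0 > 1:
                    stacked = fed.run_gradients(g0, g1)
                    norms = np.linalg.norm(stacked, axis=1)
                    thr = lam * weights[g0:g1]
                    # relative slack keeps groups exactly on the boundary
                    # (e.g. the argmax group at lambda_max) at zero
                    viol = np.flatnonzero(norms > thr * (1.0 + 1e-12))
                    if viol.size == 0:
                        n_updates += g1 - g0
                        k = m + 1
                        continue
                    v = int(viol[0])
                    n_updates += v + 1
                    g = g0 + v
                    nb = group_soft_threshold(
                        -stacked[v] / L[g], lam * weights[g] / L[g]
                    )
                    fed.apply_update(g, nb)
                    beta[cols[g]] = nb
                    bnorm[g] = np.linalg.norm(nb)
                    active[g] = True
                    i = k + v + 1
                    advanced = True
                    break
                else:
                    grad = fed.gradient(g0)
                    n_updates += 1
                    if np.linalg.norm(grad) > lam * weights[g0] * (1.0 + 1e-12):
                        nb = group_soft_threshold(
                            -grad / L[g0], lam * weights[g0] / L[g0]
                        )
                        fed.apply_update(g0, nb)
                        beta[cols[g0]] = nb
                        bnorm[g0] = np.linalg.norm(nb)
                        active[g0] = True
                        i = k + 1
                        advanced = True
                        break
                    k += 1
            if not advanced:
                i = j

        new_obj = 0.5 * fed.residual_sq() + lam * float(weights @ bnorm)
        if not np.isfinite(new_obj):
            raise DivergenceError(f"objective became non-finite at epoch {epoch}")
        logger.debug(
            "epoch %d objective %.10g active %d", epoch, new_obj, int(active.sum())
        )
        if abs(obj - new_obj) <= config.tol * max(1.0, abs(new_obj)):
            obj = new_obj
            converged = True
            break
        obj = new_obj

    kkt_gap = _kkt_gap(fed, order, active, lam, weights)
    logger.info(
        "solve lam=%.6g epochs=%d converged=%s active=%d kkt_gap=%.3g",
        lam,
        epochs,
        converged,
        int(active.sum()),
        kkt_gap,
    )
    return Solution(
        beta=beta,
        objective=obj,
        epochs_run=epochs,
        converged=converged,
        kkt_gap=kkt_gap,
        lam=lam,
        n_group_updates=n_updates,
        active_groups=np.flatnonzero(active),
    )


def _kkt_gap(fed: Federation, order, active, lam, weights) -> float:
    """Max optimality violation over the cycled groups.

    Active groups must satisfy ||X_g^T(y - X beta)||_2 = lam*w_g; inactive
    ones ||.|| <= lam*w_g.  Uses the maintained residual.
    """
    corr = -fed.xt_residual()  # X^T (y - X beta), stacked per group
    norms = np.linalg.norm(corr, axis=1)
    gap = 0.0
    act = norms[order][active[order]] - lam * weights[order][active[order]]
    if act.size:
        gap = float(np.max(np.abs(act)))
    inact = norms[order][~active[order]] - lam * weights[order][~active[order]]
    if inact.size:
        gap = max(gap, float(np.max(np.maximum(inact, 0.0))))
    return gap
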