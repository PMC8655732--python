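"""Federated safe screening for the group LASSO along a lambda path.

The dual of the group LASSO at penalty lambda is a projection problem over
the polytope {theta : ||X_g^T theta||_2 <= w_g for all g}; the optimal dual
point is theta(lambda) = (y - X beta(lambda)) / lambda.  A group with
||X_g^T theta(lambda)||_2 < w_g strictly is provably inactive.  Sequential
enhanced dual polytope projection (EDPP) bounds theta(lambda_new) inside a
ball built from the *exact* dual point at the previously solved lambda:

    v1      = y/lambda_prev - theta(lambda_prev)      (special-cased at
              lambda_max, where v1 = X_{g*} X_{g*}^T y for the argmax group)
    v2      = y/lambda_new  - theta(lambda_prev)
    v2perp  = v2 - (<v1, v2>/||v1||^2) v1

    discard g  if  ||X_g^T (theta + v2perp/2)||_2 < w_g - ||v2perp||_2/2 * ||X_g||_2

Every quantity crossing the wire is a per-site inner product (scalar) or a
per-group X^T-product; the dual vectors themselves stay on the sites.

Screening is *safe*: with an exact anchor solution, no discarded group is
active in the unscreened optimum, so path solutions with and without
screening coincide.  Approximate anchors are handled by rescaling the dual
point into the feasible polytope and by skipping screening entirely when
the anchor fails its optimality check.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .federation import Federation
from .solver import SolverConfig, Solution, fbcd_solve, fed_group_cols

__all__ = [
    "ScreeningState",
    "LambdaPath",
    "lambda_max",
    "screen_groups",
    "solve_path",
    "uniform_lambda_grid",
    "StalenessWarning",
]

logger = logging.getLogger(__name__)

# relative KKT violation above which the anchor solution is considered
# stale and screening is skipped for that step
STALE_RTOL = 1e-4


class StalenessWarning(UserWarning):
    """The screening anchor was not optimal to tolerance; screening skipped."""


@dataclass
class ScreeningState:
    """Anchor for sequential screening: the exact solution at lambda_prev."""

    lam_prev: float
    beta_prev: np.ndarray
    lam_max: float
    gstar: int
    u_star: np.ndarray  # aggregated X_{g*}^T y, broadcast for the anchor v1
    at_lambda_max: bool
    active_prev: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def _lambda_max_details(fed: Federation, weights: np.ndarray):
    fed.start_residual(np.zeros(fed.n_features))
    stacked = -fed.xt_residual()  # X_g^T y per group
    norms = np.linalg.norm(stacked, axis=1)
    scores = norms / np.asarray(weights)
    gstar = int(np.argmax(scores))
    lmax = float(scores[gstar])
    size = fed.group_sizes[gstar]
    return lmax, gstar, stacked[gstar, :size].copy()


def lambda_max(shards, group_cols=None, weights=None) -> float:
    """Smallest penalty with an all-zero optimum: max_g ||X_g^T y||_2 / w_g.

    Computed from master-aggregated per-group partials only.  Returns 0
    for an all-zero response (degenerate path).
    """
    fed = shards if isinstance(shards, Federation) else Federation(shards, group_cols)
    lmax, _, _ = _lambda_max_details(fed, np.asarray(weights, dtype=np.float64))
    if lmax == 0.0:
        logger.warning("response is identically zero: lambda path is degenerate")
    return lmax


def make_state_at_lambda_max(fed: Federation, weights) -> ScreeningState:
    lmax, gstar, u = _lambda_max_details(fed, np.asarray(weights, dtype=np.float64))
    return ScreeningState(
        lam_prev=lmax,
        beta_prev=np.zeros(fed.n_features),
        lam_max=lmax,
        gstar=gstar,
        u_star=u,
        at_lambda_max=True,
    )


def state_from_solution(state: ScreeningState, sol: Solution) -> ScreeningState:
    return ScreeningState(
        lam_prev=sol.lam,
        beta_prev=sol.beta,
        lam_max=state.lam_max,
        gstar=state.gstar,
        u_star=state.u_star,
        at_lambda_max=False,
        active_prev=sol.active_groups,
    )


def screen_groups(
    state: ScreeningState,
    lambda_new: float,
    shards,
    group_cols=None,
    weights=None,
) -> np.ndarray:
    """Return the group ids retained (NOT provably inactive) at lambda_new.

    The returned set is a superset of the true active set at lambda_new
    provided ``state`` holds the exact solution at ``state.lam_prev``.
    """
    fed = shards if isinstance(shards, Federation) else Federation(shards, group_cols)
    weights = np.asarray(weights, dtype=np.float64)
    all_groups = np.arange(fed.n_groups)
    if lambda_new >= state.lam_prev:
        raise ValueError(
            f"lambda_new ({lambda_new}) must be below lambda_prev ({state.lam_prev})"
        )

    # dual point at the anchor, held per site
    for w in fed.workers:
        w.set_dual(state.beta_prev, state.lam_prev)

    # anchor optimality / dual feasibility: ||X_g^T theta|| <= w_g
    stacked = fed.xt_product("theta")
    norms = np.linalg.norm(stacked, axis=1)
    feas = norms / weights
    m = float(np.max(feas))
    if not state.at_lambda_max:
        # KKT check on the anchor: active groups must sit on the boundary
        viol = m - 1.0
        for g in state.active_prev:
            viol = max(viol, abs(feas[g] - 1.0))
        if viol > STALE_RTOL:
            warnings.warn(
                f"screening anchor at lambda={state.lam_prev:.4g} is not optimal "
                f"to tolerance (KKT violation {viol:.2g}); retaining all groups",
                StalenessWarning,
                stacklevel=2,
            )
            return all_groups
    if m > 1.0:
        for w in fed.workers:
            w.scale_dual(1.0 / m)

    # EDPP geometry, assembled from per-site pieces
    if state.at_lambda_max:
        for w in fed.workers:
            w.build_v1_from_group(state.gstar, state.u_star)
    else:
        for w in fed.workers:
            w.build_v1_from_dual(state.lam_prev)
    for w in fed.workers:
        w.build_v2(lambda_new)
    v1_sq = fed.inner("v1", "v1")
    coeff = fed.inner("v1", "v2") / v1_sq if v1_sq > 0 else 0.0
    for w in fed.workers:
        w.build_v2perp(coeff)
        w.build_center()
    nv2p = np.sqrt(max(fed.inner("v2perp", "v2perp"), 0.0))

    T = np.linalg.norm(fed.xt_product("center"), axis=1)
    bound = weights - 0.5 * nv2p * fed.spectral_norms()
    retained = T >= bound - 1e-12 * weights
    retained[state.active_prev] = True
    return np.flatnonzero(retained)


@dataclass
class LambdaPath:
    """Solutions and screening bookkeeping along a decreasing lambda grid."""

    lambdas_rel: np.ndarray
    lambda_max: float
    lambdas: np.ndarray
    solutions: list[Solution]
    retained_groups: list[np.ndarray]
    n_group_updates: list[int]
    degenerate: bool = False

    @property
    def total_group_updates(self) -> int:
        return int(sum(self.n_group_updates))


def uniform_lambda_grid(start: float = 1.0, stop: float = 0.1, num: int = 100) -> np.ndarray:
    """Uniformly spaced decreasing grid, endpoints included."""
    if not (0 < stop < start <= 1 or (start > stop > 0)):
        raise ValueError("need start > stop > 0")
    if num < 2:
        raise ValueError("need at least two grid points")
    return np.linspace(start, stop, num)


def solve_path(
    shards,
    group_cols=None,
    weights=None,
    lambdas_rel=None,
    config: SolverConfig | None = None,
    screening: bool = True,
    relative: bool = True,
    record: bool = False,
) -> LambdaPath:
    """Solve the group LASSO along a decreasing lambda grid with screening.

    Each lambda is screened against the previous exact solution, solved by
    federated BCD on the retained groups only (warm-started), and embedded
    back into full coefficient space with zeros for discarded groups.  The
    first anchor is lambda_max itself, whose solution (beta = 0) is known
    in closed form.

    The default per-solve tolerance is tighter (1e-10) than a standalone
    solve's: each solution anchors the next screening step, and sequential
    screening needs anchors optimal well beyond the screening margin.
    """
    config = config or SolverConfig(tol=1e-10)
    fed = shards if isinstance(shards, Federation) else Federation(
        shards, group_cols, record=record
    )
    weights = np.asarray(weights, dtype=np.float64)
    lambdas_rel = np.asarray(lambdas_rel, dtype=np.float64)
    if lambdas_rel.ndim != 1 or lambdas_rel.size == 0:
        raise ValueError("lambdas_rel must be a non-empty 1-D sequence")
    if np.any(np.diff(lambdas_rel) >= 0):
        raise ValueError("lambda sequence must be strictly decreasing")
    if relative and (lambdas_rel[0] > 1 or lambdas_rel[-1] <= 0):
        raise ValueError("relative lambda values must lie in (0, 1]")

    state = make_state_at_lambda_max(fed, weights)
    lmax = state.lam_max
    if lmax == 0.0:
        # all-zero response: every solution is zero
        zeros = np.zeros(fed.n_features)
        sols = [
            Solution(zeros.copy(), 0.0, 0, True, 0.0, 0.0) for _ in lambdas_rel
        ]
        return LambdaPath(
            lambdas_rel, 0.0, np.zeros_like(lambdas_rel), sols,
            [np.array([], dtype=int)] * len(lambdas_rel),
            [0] * len(lambdas_rel), degenerate=True,
        )
    lambdas = lambdas_rel * lmax if relative else lambdas_rel

    sols: list[Solution] = []
    retained_list: list[np.ndarray] = []
    updates: list[int] = []
    half_ysq = None
    for lam_rel, lam in zip(lambdas_rel, lambdas):
        if lam >= lmax * (1.0 - 1e-12):
            # penalty dominates: exact zero solution, no solve needed
            if half_ysq is None:
                fed.start_residual(np.zeros(fed.n_features))
                half_ysq = 0.5 * fed.residual_sq()
            sol = Solution(
                beta=np.zeros(fed.n_features),
                objective=half_ysq,
                epochs_run=0,
                converged=True,
                kkt_gap=0.0,
                lam=lam,
            )
            retained = np.array([], dtype=int)
        else:
            try:
                if screening:
                    retained = screen_groups(state, lam, fed, weights=weights)
                else:
                    retained = np.arange(fed.n_groups)
            except Exception as exc:
                raise RuntimeError(
                    f"screening failed at lambda_rel={lam_rel:.6g}"
                ) from exc
            try:
                sol = fbcd_solve(
                    fed,
                    weights=weights,
                    config=config,
                    warm_start=state.beta_prev,
                    lam=lam,
                    candidates=retained,
                )
            except Exception as exc:
                raise RuntimeError(
                    f"solver failed at lambda_rel={lam_rel:.6g}"
                ) from exc
        logger.info(
            "lambda_rel=%.6g retained=%d active=%d objective=%.8g",
            lam_rel,
            len(retained) if len(retained) else fed.n_groups,
            len(sol.active_groups),
            sol.objective,
        )
        sols.append(sol)
        retained_list.append(np.asarray(retained, dtype=int))
        updates.append(sol.n_group_updates)
        state = state_from_solution(state, sol)
        if lam >= lmax * (1.0 - 1e-12):
            state.at_lambda_max = True
    return LambdaPath(
        lambdas_rel=lambdas_rel,
        lambda_max=lmax,
        lambdas=lambdas,
        solutions=sols,
        retained_groups=retained_list,
        n_group_updates=updates,
    )
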