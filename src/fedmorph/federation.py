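"""In-process master/worker message passing for federated solving.

Institutions never transmit row-level data.  Every message crossing the
(simulated) wire carries either a scalar statistic or per-group aggregate
vectors/matrices whose dimensions are bounded by the largest group size —
``(p_g,)`` gradients, ``(p_g, p_g)`` Gram blocks, or a stack of per-group
vectors ``(k, p_g)``.  Dual vectors used by screening live on each site and
are combined only through inner products and X^T-products.

The interface is transport-agnostic: a networked deployment would replace
:class:`Transport` with a real channel; the solver and screening code only
ever see aggregated results.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .design import InstitutionShard

__all__ = [
    "GradientMessage",
    "ScalarMessage",
    "Transport",
    "SiteWorker",
    "Federation",
    "aggregate",
    "local_gradient",
    "ProtocolError",
]


class ProtocolError(RuntimeError):
    """A site failed to participate in an aggregation round."""


class PrivacyError(RuntimeError):
    """A message payload would leak row-level data."""


ALL_GROUPS = -1


@dataclass(frozen=True)
class GradientMessage:
    """Per-group aggregate from one site.

    ``payload`` is a (p_g,) partial gradient, a (p_g, p_g) partial Gram,
    or a (k, p_g) stack of per-group partials when ``group_id`` is the
    ALL_GROUPS flag.
    """

    site_id: int
    group_id: int
    payload: np.ndarray
    kind: str = "gradient"


@dataclass(frozen=True)
class ScalarMessage:
    site_id: int
    name: str
    value: float


class Transport:
    """Records message metadata so the privacy contract can be audited."""

    def __init__(self, max_group_size: int, record: bool = False):
        self.max_group_size = int(max_group_size)
        self.record = record
        self.log: list[tuple[int, int, str, tuple[int, ...]]] = []

    def check(self, msg: GradientMessage) -> GradientMessage:
        shape = np.shape(msg.payload)
        if len(shape) == 0 or len(shape) > 2 or shape[-1] > self.max_group_size:
            raise PrivacyError(
                f"message payload shape {shape} exceeds per-group aggregate bounds "
                f"(max group size {self.max_group_size})"
            )
        if len(shape) == 2 and msg.group_id != ALL_GROUPS and shape[0] > self.max_group_size:
            raise PrivacyError(f"Gram payload shape {shape} too large for one group")
        if self.record:
            self.log.append((msg.site_id, msg.group_id, msg.kind, shape))
        return msg

    def check_scalar(self, msg: ScalarMessage) -> ScalarMessage:
        if self.record:
            self.log.append((msg.site_id, ALL_GROUPS, "scalar:" + msg.name, ()))
        return msg


class SiteWorker:
    """Holds one institution's private rows and answers aggregate queries.

    The worker maintains a local residual ``r_i = X_i beta - y_i`` during
    block coordinate descent and local dual-construction vectors during
    screening; none of those ever leave the site.
    """

    def __init__(
        self,
        shard: InstitutionShard,
        group_cols: Sequence[np.ndarray],
        transport: Transport,
    ):
        self.site_id = shard.site_id
        self.X = np.ascontiguousarray(shard.X_i)
        self.y = shard.y_i
        self.transport = transport
        self.group_cols = list(group_cols)
        self._slices = _as_slices(self.group_cols)
        # contiguous [start, stop) of a run of consecutive groups, if the
        # group layout is a contiguous ascending partition (the standard
        # group-major column order); enables batched gradient queries.
        self._starts = None
        if all(s is not None for s in self._slices):
            starts = [s.start for s in self._slices] + [self._slices[-1].stop]
            if all(
                self._slices[i].stop == self._slices[i + 1].start
                for i in range(len(self._slices) - 1)
            ) and starts[0] == 0:
                self._starts = np.asarray(starts)
        self.r: np.ndarray | None = None
        self._vec: dict[str, np.ndarray] = {}

    # -- block coordinate descent queries ---------------------------------

    def start_residual(self, beta: np.ndarray) -> None:
        if beta.shape[0] != self.X.shape[1]:
            raise ValueError(
                f"beta has length {beta.shape[0]}, expected {self.X.shape[1]}"
            )
        if np.any(beta):
            self.r = self.X @ beta - self.y
        else:
            self.r = -self.y.copy()

    def _cols(self, g: int):
        s = self._slices[g]
        return s if s is not None else self.group_cols[g]

    def group_gradient(self, g: int, beta_g: np.ndarray | None = None) -> GradientMessage:
        """(X_g^i)^T (X^i beta - y^i) from the maintained residual."""
        grad = self.X[:, self._cols(g)].T @ self.r
        return self.transport.check(
            GradientMessage(self.site_id, g, grad, "gradient")
        )

    def run_gradients(self, g0: int, g1: int) -> GradientMessage:
        """Stacked gradients for the consecutive group range [g0, g1).

        Only valid for uniform-size contiguous layouts; equivalent to (and
        checked against) per-group queries.
        """
        c0, c1 = self._starts[g0], self._starts[g1]
        flat = self.X[:, c0:c1].T @ self.r
        width = (c1 - c0) // (g1 - g0)
        stacked = flat.reshape(g1 - g0, width)
        return self.transport.check(
            GradientMessage(self.site_id, ALL_GROUPS, stacked, "gradient-block")
        )

    def apply_update(self, g: int, delta: np.ndarray) -> None:
        self.r += self.X[:, self._cols(g)] @ delta

    def residual_sq(self) -> ScalarMessage:
        return self.transport.check_scalar(
            ScalarMessage(self.site_id, "residual_sq", float(self.r @ self.r))
        )

    def group_gram(self, g: int) -> GradientMessage:
        Xg = self.X[:, self._cols(g)]
        return self.transport.check(
            GradientMessage(self.site_id, g, Xg.T @ Xg, "gram")
        )

    def all_grams(self) -> list[GradientMessage]:
        if self._starts is not None:
            sizes = np.diff(self._starts)
            if np.all(sizes == sizes[0]):
                u = int(sizes[0])
                Xr = self.X.reshape(self.X.shape[0], len(self.group_cols), u)
                grams = np.einsum("ngp,ngq->gpq", Xr, Xr, optimize=True)
                return [
                    self.transport.check(
                        GradientMessage(self.site_id, g, grams[g], "gram")
                    )
                    for g in range(len(self.group_cols))
                ]
        return [self.group_gram(g) for g in range(len(self.group_cols))]

    # -- screening-side local vectors -------------------------------------

    def set_dual(self, beta: np.ndarray, lam: float) -> None:
        """theta_i = (y_i - X_i beta)/lam, kept locally."""
        if np.any(beta):
            self._vec["theta"] = (self.y - self.X @ beta) / lam
        else:
            self._vec["theta"] = self.y / lam

    def scale_dual(self, factor: float) -> None:
        self._vec["theta"] = self._vec["theta"] * factor

    def build_v1_from_group(self, g: int, u: np.ndarray) -> None:
        """v1_i = X_{g*}^i u for the lambda_max anchor (u broadcast by master)."""
        self._vec["v1"] = self.X[:, self._cols(g)] @ u

    def build_v1_from_dual(self, lam_prev: float) -> None:
        self._vec["v1"] = self.y / lam_prev - self._vec["theta"]

    def build_v2(self, lam_new: float) -> None:
        self._vec["v2"] = self.y / lam_new - self._vec["theta"]

    def build_v2perp(self, coeff: float) -> None:
        self._vec["v2perp"] = self._vec["v2"] - coeff * self._vec["v1"]

    def build_center(self) -> None:
        self._vec["center"] = self._vec["theta"] + 0.5 * self._vec["v2perp"]

    def inner(self, a: str, b: str) -> ScalarMessage:
        val = float(self._vec[a] @ self._vec[b])
        return self.transport.check_scalar(
            ScalarMessage(self.site_id, f"<{a},{b}>", val)
        )

    def xt_product(self, name: str) -> GradientMessage:
        """Per-group stack of (X_g^i)^T v for a named local vector."""
        v = self._vec[name] if name != "y" else self.y
        return self._stacked_xtv(self.X.T @ v)

    def xt_residual(self) -> GradientMessage:
        """Per-group stack of (X_g^i)^T r for the maintained residual."""
        return self._stacked_xtv(self.X.T @ self.r)

    def _stacked_xtv(self, flat: np.ndarray) -> GradientMessage:
        if self._starts is not None:
            sizes = np.diff(self._starts)
            if np.all(sizes == sizes[0]):
                stacked = flat.reshape(len(self.group_cols), int(sizes[0]))
                return self.transport.check(
                    GradientMessage(self.site_id, ALL_GROUPS, stacked, "xtv")
                )
        # non-uniform groups: pad into a (G, max_pg) stack
        G = len(self.group_cols)
        u = self.transport.max_group_size
        stacked = np.zeros((G, u))
        for g in range(G):
            cg = flat[self._cols(g)]
            stacked[g, : cg.shape[0]] = cg
        return self.transport.check(
            GradientMessage(self.site_id, ALL_GROUPS, stacked, "xtv")
        )


def local_gradient(
    shard: InstitutionShard, beta: np.ndarray, group_cols: np.ndarray
) -> np.ndarray:
    """(X_g^i)^T (X^i beta - y^i): one site's contribution to one group's gradient."""
    beta = np.asarray(beta, dtype=np.float64)
    if beta.shape[0] != shard.X_i.shape[1]:
        raise ValueError(
            f"beta has length {beta.shape[0]}, expected {shard.X_i.shape[1]}"
        )
    r = shard.X_i @ beta - shard.y_i
    return shard.X_i[:, group_cols].T @ r


def aggregate(messages: Sequence[GradientMessage], expected_sites: Sequence[int] | None = None) -> np.ndarray:
    """Sum per-site partials in ascending site order (reproducible)."""
    if not messages:
        raise ProtocolError("no messages to aggregate")
    gids = {m.group_id for m in messages}
    if len(gids) != 1:
        raise ProtocolError(f"messages mix groups {sorted(gids)}")
    by_site = {m.site_id: m for m in messages}
    if len(by_site) != len(messages):
        raise ProtocolError("duplicate site contributions")
    if expected_sites is not None:
        missing = sorted(set(expected_sites) - set(by_site))
        if missing:
            raise ProtocolError(f"missing gradient from site(s) {missing}")
    total = None
    for sid in sorted(by_site):
        p = np.asarray(by_site[sid].payload, dtype=np.float64)
        total = p.copy() if total is None else total + p
    return total


class Federation:
    """Master-side view of a set of site workers."""

    def __init__(self, shards: Sequence[InstitutionShard], group_cols, max_group_size=None, record=False):
        if not shards:
            raise ValueError("need at least one institution")
        widths = {s.X_i.shape[1] for s in shards}
        if len(widths) != 1:
            raise ValueError("shards disagree on feature count")
        ids = sorted(s.site_id for s in shards)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate site ids")
        if max_group_size is None:
            max_group_size = max(len(c) for c in group_cols)
        self.transport = Transport(max_group_size, record=record)
        self.workers = [
            SiteWorker(s, group_cols, self.transport)
            for s in sorted(shards, key=lambda s: s.site_id)
        ]
        self.site_ids = ids
        self.n_features = widths.pop()
        self.n_groups = len(group_cols)
        self.group_sizes = np.array([len(c) for c in group_cols])
        self._grams: list[np.ndarray] | None = None
        self._lipschitz: np.ndarray | None = None

    # aggregated queries ---------------------------------------------------

    def start_residual(self, beta):
        for w in self.workers:
            w.start_residual(beta)

    def gradient(self, g) -> np.ndarray:
        return aggregate([w.group_gradient(g) for w in self.workers], self.site_ids)

    def run_gradients(self, g0, g1) -> np.ndarray:
        return aggregate([w.run_gradients(g0, g1) for w in self.workers], self.site_ids)

    def apply_update(self, g, delta):
        for w in self.workers:
            w.apply_update(g, delta)

    def residual_sq(self) -> float:
        return float(sum(w.residual_sq().value for w in self.workers))

    def grams(self) -> list[np.ndarray]:
        if self._grams is None:
            per_site = [w.all_grams() for w in self.workers]
            self._grams = [
                aggregate([ps[g] for ps in per_site], self.site_ids)
                for g in range(self.n_groups)
            ]
        return self._grams

    def lipschitz(self) -> np.ndarray:
        """Blockwise Lipschitz constants: largest eigenvalue of each
        aggregated Gram (floored away from zero for all-zero columns)."""
        if self._lipschitz is None:
            grams = self.grams()
            sizes = {g.shape[0] for g in grams}
            if len(sizes) == 1:
                eig = np.linalg.eigvalsh(np.stack(grams))[:, -1]
            else:
                eig = np.array([np.linalg.eigvalsh(g)[-1] for g in grams])
            self._lipschitz = np.maximum(eig, 1e-12)
        return self._lipschitz

    def spectral_norms(self) -> np.ndarray:
        """Per-group column-block spectral norms ||X_g||_2 from the Grams."""
        return np.sqrt(self.lipschitz())

    def xt_residual(self) -> np.ndarray:
        return aggregate([w.xt_residual() for w in self.workers], self.site_ids)

    def inner(self, a, b) -> float:
        return float(sum(w.inner(a, b).value for w in self.workers))

    def xt_product(self, name) -> np.ndarray:
        """Aggregated (G, max_pg) stack of X_g^T v partials."""
        return aggregate([w.xt_product(name) for w in self.workers], self.site_ids)

    def supports_runs(self) -> bool:
        w = self.workers[0]
        if w._starts is None:
            return False
        sizes = np.diff(w._starts)
        return bool(np.all(sizes == sizes[0]))


def _as_slices(group_cols):
    out = []
    for c in group_cols:
        c = np.asarray(c)
        if c.size and np.array_equal(c, np.arange(c[0], c[0] + c.size)):
            out.append(slice(int(c[0]), int(c[0] + c.size)))
        else:
            out.append(None)
    return out
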