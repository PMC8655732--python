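"""Grid-structured grouped designs for surface morphometry regression.

Features live on one or two rectangular vertex grids (a parameterized
anatomical surface per hemisphere).  Every vertex carries one scalar per
feature type — radial distance (RD) and tensor-based morphometry (TBM) —
and features are grouped into small rectangular vertex patches so that a
group-LASSO penalty selects whole patches at once.

Column layout convention
------------------------
Feature columns are stored *group-major*: groups are ordered by ascending
``group_id`` (hemisphere, then feature type, then patch in row-major patch
order) and each group contributes its member vertices' columns
consecutively, in row-major vertex order within the patch.  Vertex indices
are 0-based and row-major on each ``rows x cols`` grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SurfaceGrid",
    "PatchGroup",
    "GroupedDesign",
    "InstitutionShard",
    "build_patch_groups",
    "build_grouped_layout",
    "zscore_by_subject",
    "partition_rows",
    "DimensionError",
]

FEATURE_TYPES = ("RD", "TBM")


class DimensionError(ValueError):
    """Shapes or grid dimensions are inconsistent."""


@dataclass(frozen=True)
class SurfaceGrid:
    """A rectangular vertex grid covering one surface (one hemisphere)."""

    rows: int = 100
    cols: int = 150
    hemisphere: str = "left"

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise DimensionError(
                f"grid dimensions must be positive, got {self.rows}x{self.cols}"
            )
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be 'left' or 'right', got {self.hemisphere!r}")

    @property
    def n_vertices(self) -> int:
        return self.rows * self.cols

    def vertex_id(self, row: int, col: int) -> int:
        """Row-major 0-based vertex index."""
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise DimensionError(f"vertex ({row},{col}) outside {self.rows}x{self.cols} grid")
        return row * self.cols + col


def default_grids() -> tuple[SurfaceGrid, SurfaceGrid]:
    """The documented two-hemisphere layout: two 100x150 grids."""
    return (SurfaceGrid(hemisphere="left"), SurfaceGrid(hemisphere="right"))


@dataclass(frozen=True)
class PatchGroup:
    """One penalty group: a single feature type on one vertex patch.

    ``weight`` is the group-LASSO weight w_g; the default convention is
    sqrt(group size) so that groups of different sizes are penalized
    comparably.
    """

    group_id: int
    hemisphere: str
    feature_type: str
    vertex_ids: tuple[int, ...]
    weight: float

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(f"group weight must be positive, got {self.weight}")
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.feature_type!r}")

    @property
    def size(self) -> int:
        return len(self.vertex_ids)


def build_patch_groups(
    grid: SurfaceGrid,
    patch_rows: int = 2,
    patch_cols: int = 3,
    feature_types: tuple[str, ...] = FEATURE_TYPES,
    start_group_id: int = 0,
    weight: float | None = None,
) -> list[PatchGroup]:
    """Tile ``grid`` with non-overlapping patch_rows x patch_cols patches.

    Returns one group per (feature type, patch); patches are enumerated in
    row-major patch order, feature types in the given order (all patches of
    the first type first).  Groups of the same patch across feature types
    share ``vertex_ids``.  Default weight is sqrt(patch size).
    """
    if grid.rows % patch_rows != 0:
        raise DimensionError(
            f"grid rows ({grid.rows}) not divisible by patch rows ({patch_rows})"
        )
    if grid.cols % patch_cols != 0:
        raise DimensionError(
            f"grid cols ({grid.cols}) not divisible by patch cols ({patch_cols})"
        )
    p_g = patch_rows * patch_cols
    w = float(np.sqrt(p_g)) if weight is None else float(weight)
    n_pr = grid.rows // patch_rows
    n_pc = grid.cols // patch_cols

    groups: list[PatchGroup] = []
    gid = start_group_id
    for ftype in feature_types:
        for pr in range(n_pr):
            for pc in range(n_pc):
                vids = tuple(
                    grid.vertex_id(pr * patch_rows + dr, pc * patch_cols + dc)
                    for dr in range(patch_rows)
                    for dc in range(patch_cols)
                )
                groups.append(
                    PatchGroup(
                        group_id=gid,
                        hemisphere=grid.hemisphere,
                        feature_type=ftype,
                        vertex_ids=vids,
                        weight=w,
                    )
                )
                gid += 1
    return groups


def build_grouped_layout(
    grids: tuple[SurfaceGrid, ...] | list[SurfaceGrid] | SurfaceGrid = None,
    patch_rows: int = 2,
    patch_cols: int = 3,
    feature_types: tuple[str, ...] = FEATURE_TYPES,
    weight: float | None = None,
):
    """Build the full multi-grid group list plus the per-column feature index.

    Returns ``(groups, feature_index)`` where ``feature_index`` is a record
    array with fields (hemisphere_idx, vertex, feature_type_idx, group_id)
    of length p = sum of group sizes, in the group-major column order.
    """
    if grids is None:
        grids = default_grids()
    if isinstance(grids, SurfaceGrid):
        grids = (grids,)
    groups: list[PatchGroup] = []
    for grid in grids:
        groups.extend(
            build_patch_groups(
                grid,
                patch_rows,
                patch_cols,
                feature_types,
                start_group_id=len(groups),
                weight=weight,
            )
        )
    hemi_idx = {g.hemisphere: i for i, g in enumerate(grids)}
    p = sum(g.size for g in groups)
    feature_index = np.zeros(
        p,
        dtype=[
            ("hemisphere_idx", "i4"),
            ("vertex", "i4"),
            ("feature_type_idx", "i4"),
            ("group_id", "i4"),
        ],
    )
    col = 0
    for g in groups:
        for v in g.vertex_ids:
            feature_index[col] = (
                hemi_idx[g.hemisphere],
                v,
                FEATURE_TYPES.index(g.feature_type),
                g.group_id,
            )
            col += 1
    return groups, feature_index


@dataclass
class GroupedDesign:
    """A full design: feature matrix, response, groups, and column metadata."""

    X: np.ndarray
    y: np.ndarray
    groups: list[PatchGroup]
    feature_index: np.ndarray
    grids: tuple[SurfaceGrid, ...] = field(default_factory=default_grids)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64).ravel()
        if self.X.ndim != 2:
            raise DimensionError("X must be 2-D (subjects x features)")
        if self.X.shape[0] != self.y.shape[0]:
            raise DimensionError(
                f"X has {self.X.shape[0]} rows but y has {self.y.shape[0]} entries"
            )
        p = self.X.shape[1]
        sizes = sum(g.size for g in self.groups)
        if sizes != p:
            raise DimensionError(
                f"groups cover {sizes} columns but X has {p}"
            )
        if len(self.feature_index) != p:
            raise DimensionError("feature_index length does not match X columns")
        counts = np.bincount(self.feature_index["group_id"], minlength=len(self.groups))
        expected = np.array([g.size for g in self.groups])
        if not np.array_equal(counts, expected):
            raise DimensionError("groups do not exactly partition the feature columns")
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.y)):
            raise ValueError("design contains non-finite entries")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_columns(self) -> list[np.ndarray]:
        """Column indices per group (ascending group_id)."""
        order = np.argsort(self.feature_index["group_id"], kind="stable")
        cols: list[np.ndarray] = []
        start = 0
        for g in self.groups:
            cols.append(np.sort(order[start : start + g.size]))
            start += g.size
        return cols

    def weights(self) -> np.ndarray:
        return np.array([g.weight for g in self.groups], dtype=np.float64)

    def feature_type_mask(self) -> np.ndarray:
        """Per-column feature-type labels (e.g. 'RD'/'TBM')."""
        return np.array([FEATURE_TYPES[i] for i in self.feature_index["feature_type_idx"]])


@dataclass
class InstitutionShard:
    """One institution's private row slice of the design."""

    site_id: int
    X_i: np.ndarray
    y_i: np.ndarray
    row_ids: np.ndarray

    def __post_init__(self) -> None:
        self.X_i = np.asarray(self.X_i, dtype=np.float64)
        self.y_i = np.asarray(self.y_i, dtype=np.float64).ravel()
        self.row_ids = np.asarray(self.row_ids, dtype=np.int64).ravel()
        if self.X_i.shape[0] == 0:
            raise ValueError(f"institution {self.site_id} received an empty shard")
        if not (self.X_i.shape[0] == self.y_i.shape[0] == self.row_ids.shape[0]):
            raise DimensionError("shard X, y and row ids disagree in length")

    @property
    def n_subjects(self) -> int:
        return self.X_i.shape[0]


def zscore_by_subject(X: np.ndarray, feature_type_mask: np.ndarray) -> np.ndarray:
    """Standardize each subject row to zero mean / unit sd within feature type.

    Each feature type's columns are standardized separately inside every
    row, with the sample (n-1) standard deviation, so RD and TBM land on
    a common scale per subject.  A row block with zero variance is set to
    all zeros (with a warning) rather than dividing by zero.
    """
    X = np.asarray(X, dtype=np.float64)
    mask = np.asarray(feature_type_mask)
    if mask.shape[0] != X.shape[1]:
        raise DimensionError("feature_type_mask length must equal number of columns")
    out = np.empty_like(X)
    for label in np.unique(mask):
        cols = np.flatnonzero(mask == label)
        if cols.size < 2:
            raise DimensionError(
                f"feature type {label!r} has {cols.size} column(s); need at least 2"
            )
        block = X[:, cols]
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True)
        degenerate = (sd == 0).ravel()
        if degenerate.any():
            warnings.warn(
                f"{int(degenerate.sum())} subject row(s) have zero variance for "
                f"feature type {label!r}; set to zeros",
                RuntimeWarning,
                stacklevel=2,
            )
        sd_safe = np.where(sd == 0, 1.0, sd)
        z = (block - mu) / sd_safe
        z[degenerate, :] = 0.0
        out[:, cols] = z
    return out


def partition_rows(
    design: GroupedDesign, n_sites: int, seed: int
) -> list[InstitutionShard]:
    """Split subjects across institutions by a seeded random permutation.

    Shard sizes differ by at most one; identical seeds give identical
    assignments.  Concatenating shards and sorting by ``row_ids`` restores
    the design bit-exactly.
    """
    n = design.n_subjects
    if not 1 <= n_sites <= n:
        raise ValueError(f"n_sites must be in [1, {n}], got {n_sites}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    chunks = np.array_split(perm, n_sites)
    return [
        InstitutionShard(site_id=i, X_i=design.X[idx], y_i=design.y[idx], row_ids=idx)
        for i, idx in enumerate(chunks)
    ]
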