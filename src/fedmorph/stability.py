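"""Stability selection, per-vertex frequency maps, and ROI summaries.

Solving the group LASSO along a decreasing lambda grid gives a family of
models beta(lambda_1), ..., beta(lambda_kappa).  Stability selection
counts, for each vertex, how many (lambda, feature type) pairs give it a
nonzero coefficient; the count is normalized to [0, 100], smoothed with a
small averaging filter on the grid, and used to rank vertices.  The
top-ranked vertices form the ROI; their frequency-weighted RD and TBM
sums are reduced to one scalar per subject by the first principal
component.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .design import FEATURE_TYPES, DimensionError, GroupedDesign, SurfaceGrid
from .screening import LambdaPath

__all__ = [
    "FrequencyMap",
    "RoiSelection",
    "count_selection",
    "smooth_map",
    "rank_and_select",
    "roi_scalar",
    "export_map",
    "patch_scores",
    "group_patch_positions",
]

NONZERO_TOL = 1e-12


@dataclass
class FrequencyMap:
    """Per-vertex selection frequencies on one or two surface grids.

    Arrays are stacked per grid: shape (n_grids, rows, cols).  ``raw`` is
    the count of (lambda, feature type) pairs with a nonzero coefficient;
    ``normalized`` rescales it to [0, 100]; ``smoothed`` is filled by
    :func:`smooth_map`.
    """

    grids: tuple[SurfaceGrid, ...]
    raw: np.ndarray
    normalized: np.ndarray
    kappa: int
    merge: str = "sum"
    smoothed: np.ndarray | None = None

    def values(self) -> np.ndarray:
        """Smoothed values if available, else normalized."""
        return self.smoothed if self.smoothed is not None else self.normalized


@dataclass
class RoiSelection:
    """Ranked vertices and the feature columns of the top-k of them."""

    ranked_vertices: np.ndarray  # flat vertex ids, hemisphere-major row-major
    top_k: int
    selected_features: np.ndarray  # 2*top_k columns (RD and TBM per vertex)


def _check_uniform_grids(grids):
    shapes = {(g.rows, g.cols) for g in grids}
    if len(shapes) != 1:
        raise DimensionError("frequency maps require grids of equal dimensions")
    return shapes.pop()


def count_selection(
    path: LambdaPath,
    design: GroupedDesign,
    merge: str = "sum",
    threshold: float = NONZERO_TOL,
) -> FrequencyMap:
    """Count nonzero coefficients per vertex across the lambda path.

    With ``merge='sum'`` (default) the RD and TBM counts on a vertex add,
    so raw counts lie in [0, 2*kappa] and normalization divides by
    2*kappa; with ``merge='max'`` the larger of the two per-type counts is
    taken and normalization divides by kappa.
    """
    if not path.solutions:
        raise ValueError("empty lambda path")
    if merge not in ("sum", "max"):
        raise ValueError(f"merge must be 'sum' or 'max', got {merge!r}")
    grids = design.grids
    rows, cols = _check_uniform_grids(grids)
    H = len(grids)
    kappa = len(path.solutions)
    fi = design.feature_index
    slot = (
        fi["hemisphere_idx"].astype(np.int64) * (rows * cols) + fi["vertex"]
    ) * len(FEATURE_TYPES) + fi["feature_type_idx"]

    by_type = np.zeros(H * rows * cols * len(FEATURE_TYPES), dtype=np.int64)
    for sol in path.solutions:
        nz = np.flatnonzero(np.abs(sol.beta) > threshold)
        np.add.at(by_type, slot[nz], 1)
    by_type = by_type.reshape(H, rows, cols, len(FEATURE_TYPES))
    if merge == "sum":
        raw = by_type.sum(axis=-1)
        denom = len(FEATURE_TYPES) * kappa
    else:
        raw = by_type.max(axis=-1)
        denom = kappa
    normalized = 100.0 * raw / denom
    return FrequencyMap(
        grids=tuple(grids),
        raw=raw,
        normalized=normalized,
        kappa=kappa,
        merge=merge,
    )


def smooth_map(
    freq_map: FrequencyMap, filter_rows: int = 2, filter_cols: int = 3
) -> FrequencyMap:
    """Average each vertex over a filter_rows x filter_cols window.

    The window is centered on the vertex (even extents extend forward)
    and clipped at grid boundaries, so every smoothed value is a mean of
    the cells actually on the grid and stays within [0, 100].
    """
    H, rows, cols = freq_map.normalized.shape
    if filter_rows > rows or filter_cols > cols:
        raise DimensionError(
            f"{filter_rows}x{filter_cols} filter larger than {rows}x{cols} grid"
        )
    lo_r = -((filter_rows - 1) // 2)
    lo_c = -((filter_cols - 1) // 2)
    total = np.zeros_like(freq_map.normalized, dtype=np.float64)
    count = np.zeros_like(total)
    vals = freq_map.normalized
    for dr in range(lo_r, lo_r + filter_rows):
        for dc in range(lo_c, lo_c + filter_cols):
            src_r = slice(max(dr, 0), rows + min(dr, 0))
            dst_r = slice(max(-dr, 0), rows + min(-dr, 0))
            src_c = slice(max(dc, 0), cols + min(dc, 0))
            dst_c = slice(max(-dc, 0), cols + min(-dc, 0))
            total[:, dst_r, dst_c] += vals[:, src_r, src_c]
            count[:, dst_r, dst_c] += 1.0
    smoothed = total / count
    return FrequencyMap(
        grids=freq_map.grids,
        raw=freq_map.raw,
        normalized=freq_map.normalized,
        kappa=freq_map.kappa,
        merge=freq_map.merge,
        smoothed=smoothed,
    )


def _column_lookup(design: GroupedDesign):
    """col_of[h, v, t] -> feature column index."""
    grids = design.grids
    rows, cols = _check_uniform_grids(grids)
    fi = design.feature_index
    lut = np.full((len(grids), rows * cols, len(FEATURE_TYPES)), -1, dtype=np.int64)
    lut[fi["hemisphere_idx"], fi["vertex"], fi["feature_type_idx"]] = np.arange(
        len(fi)
    )
    return lut


def rank_and_select(
    freq_map: FrequencyMap, top_k: int, design: GroupedDesign
) -> RoiSelection:
    """Rank vertices by smoothed frequency and select the top-k.

    Ties break toward the lower hemisphere-major row-major vertex index,
    so the ranking is deterministic.  Each selected vertex contributes its
    RD and its TBM column, in that order.
    """
    vals = freq_map.values().reshape(-1)
    n_vertices = vals.shape[0]
    if not 1 <= top_k <= n_vertices:
        raise ValueError(f"top_k must be in [1, {n_vertices}], got {top_k}")
    order = np.argsort(-vals, kind="stable")
    lut = _column_lookup(design)
    H, VC, T = lut.shape
    flat_lut = lut.reshape(H * VC, T)
    top = order[:top_k]
    sel = flat_lut[top][:, [FEATURE_TYPES.index("RD"), FEATURE_TYPES.index("TBM")]]
    if np.any(sel < 0):
        raise ValueError("selected vertices lack RD/TBM columns in this design")
    return RoiSelection(
        ranked_vertices=order, top_k=top_k, selected_features=sel.reshape(-1)
    )


def roi_scalar(
    design: GroupedDesign, freq_map: FrequencyMap, selection: RoiSelection
) -> np.ndarray:
    """Frequency-weighted ROI summary, one scalar per subject.

    s_RD = sum over ROI vertices of freq(v) * RD(v) (TBM analogously);
    the two-column table is reduced to its first principal-component
    score, with the sign fixed so the RD loading is non-negative.
    """
    from sklearn.decomposition import PCA

    if selection.selected_features.size == 0:
        raise ValueError("empty ROI selection")
    vals = freq_map.values().reshape(-1)
    top = selection.ranked_vertices[: selection.top_k]
    freqs = vals[top]
    cols = selection.selected_features.reshape(-1, 2)
    s_rd = design.X[:, cols[:, 0]] @ freqs
    s_tbm = design.X[:, cols[:, 1]] @ freqs
    table = np.column_stack([s_rd, s_tbm])
    sd = table.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("degenerate PCA: both ROI summary columns are constant")
    pca = PCA(n_components=1)
    scores = pca.fit_transform(table).ravel()
    loading = pca.components_[0]
    if loading[0] < 0 or (loading[0] == 0 and loading[1] < 0):
        scores = -scores
    return scores


def export_map(freq_map: FrequencyMap, path, fmt: str = "text") -> list[Path]:
    """Write the smoothed map as delimited text or ASCII PLY meshes.

    Text: one row per vertex with (row, col, hemisphere, value).  PLY: one
    file per grid, the grid triangulated regularly (two triangles per
    cell) with the value as a per-vertex float property.  Values are
    printed with 9 significant digits.
    """
    if freq_map.smoothed is None:
        raise ValueError("smooth the map before exporting")
    path = Path(path)
    H, rows, cols = freq_map.smoothed.shape
    if fmt == "text":
        out = path.with_suffix(".tsv")
        lines = ["row\tcol\themisphere\tvalue"]
        for h, grid in enumerate(freq_map.grids):
            for r in range(rows):
                for c in range(cols):
                    lines.append(
                        f"{r}\t{c}\t{grid.hemisphere}\t{freq_map.smoothed[h, r, c]:.9g}"
                    )
        out.write_text("\n".join(lines) + "\n")
        return [out]
    if fmt == "ply":
        outs = []
        for h, grid in enumerate(freq_map.grids):
            out = path.with_name(f"{path.stem}_{grid.hemisphere}.ply")
            vals = freq_map.smoothed[h]
            n_v = rows * cols
            n_f = 2 * (rows - 1) * (cols - 1)
            lines = [
                "ply",
                "format ascii 1.0",
                f"element vertex {n_v}",
                "property float x",
                "property float y",
                "property float z",
                "property float quality",
                f"element face {n_f}",
                "property list uchar int vertex_indices",
                "end_header",
            ]
            for r in range(rows):
                for c in range(cols):
                    lines.append(f"{c} {r} 0 {vals[r, c]:.9g}")
            for r in range(rows - 1):
                for c in range(cols - 1):
                    v00 = r * cols + c
                    v10 = (r + 1) * cols + c
                    v01 = r * cols + c + 1
                    v11 = (r + 1) * cols + c + 1
                    lines.append(f"3 {v00} {v10} {v01}")
                    lines.append(f"3 {v10} {v11} {v01}")
            out.write_text("\n".join(lines) + "\n")
            outs.append(out)
        return outs
    raise ValueError(f"unknown export format {fmt!r}")


def patch_scores(
    freq_map: FrequencyMap, patch_rows: int = 2, patch_cols: int = 3
) -> np.ndarray:
    """Patch-averaged frequencies, flat over (grid, patch row-major)."""
    vals = freq_map.values()
    H, rows, cols = vals.shape
    n_pr, n_pc = rows // patch_rows, cols // patch_cols
    blocked = vals.reshape(H, n_pr, patch_rows, n_pc, patch_cols)
    return blocked.mean(axis=(2, 4)).reshape(-1)


def group_patch_positions(
    design: GroupedDesign, patch_rows: int = 2, patch_cols: int = 3
) -> np.ndarray:
    """Map each group id to its flat patch position (as in patch_scores).

    RD and TBM groups on the same patch share a position, so planted
    groups can be compared against patch-averaged frequency ranks.
    """
    grids = design.grids
    rows, cols = _check_uniform_grids(grids)
    n_pc = cols // patch_cols
    patches_per_grid = (rows // patch_rows) * n_pc
    hemi_idx = {g.hemisphere: i for i, g in enumerate(grids)}
    pos = np.empty(len(design.groups), dtype=np.int64)
    for g in design.groups:
        v0 = min(g.vertex_ids)
        r, c = divmod(v0, cols)
        pos[g.group_id] = (
            hemi_idx[g.hemisphere] * patches_per_grid
            + (r // patch_rows) * n_pc
            + (c // patch_cols)
        )
    return pos
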