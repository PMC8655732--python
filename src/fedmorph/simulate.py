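"""Synthetic multi-site cohorts with planted predictive surface patches.

Real surface-morphometry features are spatially smooth fields on the
vertex grid (smoothness induced by mesh-level heat-kernel smoothing of the
underlying measurements).  The generator emulates them as per-subject
Gaussian random fields convolved with a separable Gaussian kernel on each
grid (reflecting boundaries), Z-scored within subject per feature type.
The response is a linear signal carried by a small set of planted patch
groups plus additive Gaussian noise:

    y = X beta_true + eps,   eps ~ N(0, noise_sd^2 I)

with beta_true constant within each planted patch (magnitude
effect_scale / sqrt(p_g), random sign per patch) so that group norms are
comparable across patch sizes.

Four independent named RNG streams (field, support, noise, partition) are
spawned from one root seed, so any component can be varied in isolation
while the others stay fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .design import (
    FEATURE_TYPES,
    GroupedDesign,
    InstitutionShard,
    SurfaceGrid,
    build_grouped_layout,
    default_grids,
    partition_rows,
    zscore_by_subject,
)

__all__ = ["SyntheticTruth", "generate_cohort", "write_fixture"]


@dataclass
class SyntheticTruth:
    """Ground truth of a planted-signal cohort, for recovery tests."""

    support: tuple[int, ...]
    beta_true: np.ndarray
    noise_sd: float
    smoothness: float
    seed: int

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_cohort(
    n_subjects: int = 200,
    grids=None,
    n_true_patches: int = 10,
    effect_scale: float = 1.0,
    noise_sd: float = 1.0,
    smoothness: float = 3.0,
    n_sites: int = 5,
    seed: int = 0,
    patch_rows: int = 2,
    patch_cols: int = 3,
) -> tuple[GroupedDesign, list[InstitutionShard], SyntheticTruth]:
    """Simulate a grouped design, its institutional shards, and the truth.

    Defaults give the documented study-scale layout: two 100x150
    hemisphere grids, 2x3 patches, RD+TBM -> 60,000 features in 10,000
    groups, split across 5 institutions.
    """
    if n_subjects < 2:
        raise ValueError("need at least two subjects")
    if grids is None:
        grids = default_grids()
    if isinstance(grids, SurfaceGrid):
        grids = (grids,)
    groups, feature_index = build_grouped_layout(grids, patch_rows, patch_cols)
    n_groups = len(groups)
    if not 1 <= n_true_patches <= n_groups:
        raise ValueError(
            f"n_true_patches must be in [1, {n_groups}], got {n_true_patches}"
        )

    root = np.random.SeedSequence(seed)
    field_ss, support_ss, noise_ss, part_ss = root.spawn(4)
    field_rng = np.random.default_rng(field_ss)
    support_rng = np.random.default_rng(support_ss)
    noise_rng = np.random.default_rng(noise_ss)
    part_seed = int(np.random.default_rng(part_ss).integers(2**31))

    # smooth per-subject fields, one per (hemisphere, feature type), then
    # pack into the group-major column order
    blocks = []
    for grid in grids:
        n_pr, n_pc = grid.rows // patch_rows, grid.cols // patch_cols
        for _ in FEATURE_TYPES:
            field = field_rng.standard_normal((n_subjects, grid.rows, grid.cols))
            if smoothness > 0:
                field = gaussian_filter(
                    field, sigma=smoothness, axes=(1, 2), mode="reflect"
                )
            block = (
                field.reshape(n_subjects, n_pr, patch_rows, n_pc, patch_cols)
                .transpose(0, 1, 3, 2, 4)
                .reshape(n_subjects, -1)
            )
            blocks.append(block)
    X = np.concatenate(blocks, axis=1)

    ftype_mask = np.array(
        [FEATURE_TYPES[i] for i in feature_index["feature_type_idx"]]
    )
    X = zscore_by_subject(X, ftype_mask)

    support = np.sort(support_rng.choice(n_groups, size=n_true_patches, replace=False))
    signs = support_rng.choice([-1.0, 1.0], size=n_true_patches)
    beta_true = np.zeros(X.shape[1])
    gid_of_col = feature_index["group_id"]
    for g, s in zip(support, signs):
        cols = np.flatnonzero(gid_of_col == g)
        beta_true[cols] = s * effect_scale / np.sqrt(cols.size)

    y = X @ beta_true
    if noise_sd > 0:
        y = y + noise_rng.normal(0.0, noise_sd, size=n_subjects)

    design = GroupedDesign(
        X=X, y=y, groups=groups, feature_index=feature_index, grids=tuple(grids)
    )
    shards = partition_rows(design, n_sites, part_seed)
    truth = SyntheticTruth(
        support=tuple(int(g) for g in support),
        beta_true=beta_true,
        noise_sd=noise_sd,
        smoothness=smoothness,
        seed=seed,
    )
    return design, shards, truth


def write_fixture(
    design: GroupedDesign,
    shards: list[InstitutionShard],
    truth: SyntheticTruth | None,
    directory,
    matrix_format: str = "binary",
) -> dict:
    """Write a cohort as a fixture directory in the documented file dialects.

    Emits matrix (+ sidecar when binary), group index, response, site
    assignment, and (when given) the planted truth; all round-trip through
    the package readers.
    """
    from . import io as fio

    return fio.write_fixture(design, shards, truth, directory, matrix_format)
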