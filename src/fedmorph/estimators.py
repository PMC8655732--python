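"""Scikit-learn style estimators wrapping the federated pipeline.

:class:`FederatedGroupLasso` is a linear regressor fit by federated block
coordinate descent at one (relative) penalty.  :class:`StabilitySelector`
is a feature selector: it solves a screened lambda path, performs
stability selection on the surface grid, and exposes the top-ranked
vertices' columns through the usual ``transform``/``get_support`` API, so
it composes with sklearn pipelines and model selection.
"""

from __future__ import annotations

import numbers

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from .design import (
    GroupedDesign,
    InstitutionShard,
    SurfaceGrid,
    build_grouped_layout,
    partition_rows,
    zscore_by_subject,
)
from .screening import lambda_max, solve_path, uniform_lambda_grid
from .solver import SolverConfig, fbcd_solve
from .stability import count_selection, rank_and_select, roi_scalar, smooth_map

__all__ = ["FederatedGroupLasso", "StabilitySelector"]


def _flat_groups(p: int, groups) -> tuple[list[np.ndarray], np.ndarray]:
    """Normalize a group spec into (column index lists, weights)."""
    if groups is None:
        cols = [np.array([j]) for j in range(p)]
    elif isinstance(groups, numbers.Integral):
        size = int(groups)
        if p % size != 0:
            raise ValueError(f"{p} features not divisible into groups of {size}")
        cols = [np.arange(j, j + size) for j in range(0, p, size)]
    else:
        cols = [np.asarray(c, dtype=int) for c in groups]
        covered = np.concatenate(cols) if cols else np.array([], dtype=int)
        if sorted(covered.tolist()) != list(range(p)):
            raise ValueError("groups must exactly partition the feature columns")
    weights = np.sqrt([len(c) for c in cols]).astype(float)
    return cols, weights


class FederatedGroupLasso(RegressorMixin, BaseEstimator):
    """Group-LASSO linear regression fit by federated BCD.

    Parameters
    ----------
    lambda_rel : penalty as a fraction of lambda_max (the smallest penalty
        with an all-zero solution).
    groups : None (one group per feature), an integer uniform group size,
        or an explicit list of column-index arrays partitioning the
        columns.  Weights are sqrt(group size).
    n_sites : number of simulated institutions the rows are split across;
        the fit is invariant to this choice up to floating-point rounding.
    """

    def __init__(
        self,
        lambda_rel: float = 0.5,
        groups=None,
        n_sites: int = 1,
        tol: float = 1e-8,
        max_epochs: int = 1000,
        random_state: int | None = 0,
    ):
        self.lambda_rel = lambda_rel
        self.groups = groups
        self.n_sites = n_sites
        self.tol = tol
        self.max_epochs = max_epochs
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        cols, weights = _flat_groups(X.shape[1], self.groups)
        rng_seed = 0 if self.random_state is None else int(self.random_state)
        rng = np.random.default_rng(rng_seed)
        perm = rng.permutation(X.shape[0])
        chunks = np.array_split(perm, self.n_sites)
        shards = [
            InstitutionShard(site_id=i, X_i=X[idx], y_i=y[idx], row_ids=idx)
            for i, idx in enumerate(chunks)
        ]
        self.lambda_max_ = lambda_max(shards, cols, weights)
        config = SolverConfig(
            lambda_rel=self.lambda_rel, tol=self.tol, max_epochs=self.max_epochs
        )
        sol = fbcd_solve(shards, cols, weights, config=config, lam_max=self.lambda_max_)
        self.coef_ = sol.beta
        self.objective_ = sol.objective
        self.n_iter_ = sol.epochs_run
        self.kkt_gap_ = sol.kkt_gap
        self.converged_ = sol.converged
        self.active_groups_ = sol.active_groups
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=np.float64)
        return X @ self.coef_


class StabilitySelector(SelectorMixin, BaseEstimator):
    """Stability-selection feature selector on surface-grid features.

    Fits a screened group-LASSO path on features laid out on ``n_grids``
    rectangular vertex grids (two feature types per vertex, grouped into
    patch blocks), counts nonzero coefficients per vertex across the
    path, smooths the resulting frequency map, and keeps the RD and TBM
    columns of the ``top_k`` ranked vertices.

    Input columns must follow the package's group-major layout (see
    :func:`fedmorph.design.build_grouped_layout`).
    """

    def __init__(
        self,
        n_grids: int = 2,
        grid_rows: int = 100,
        grid_cols: int = 150,
        patch_rows: int = 2,
        patch_cols: int = 3,
        lambda_min: float = 0.1,
        n_lambdas: int = 100,
        top_k: int = 1500,
        merge: str = "sum",
        n_sites: int = 1,
        tol: float = 1e-10,
        max_epochs: int = 1000,
        screening: bool = True,
        normalize_subjects: bool = True,
        random_state: int | None = 0,
    ):
        self.n_grids = n_grids
        self.grid_rows = grid_rows
        self.grid_cols = grid_cols
        self.patch_rows = patch_rows
        self.patch_cols = patch_cols
        self.lambda_min = lambda_min
        self.n_lambdas = n_lambdas
        self.top_k = top_k
        self.merge = merge
        self.n_sites = n_sites
        self.tol = tol
        self.max_epochs = max_epochs
        self.screening = screening
        self.normalize_subjects = normalize_subjects
        self.random_state = random_state

    def _grids(self):
        hemis = ("left", "right")
        return tuple(
            SurfaceGrid(self.grid_rows, self.grid_cols, hemis[i])
            for i in range(self.n_grids)
        )

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        grids = self._grids()
        groups, feature_index = build_grouped_layout(
            grids, self.patch_rows, self.patch_cols
        )
        if len(feature_index) != X.shape[1]:
            raise ValueError(
                f"X has {X.shape[1]} columns; the declared grid layout needs "
                f"{len(feature_index)}"
            )
        design = GroupedDesign(
            X=X, y=y, groups=groups, feature_index=feature_index, grids=grids
        )
        if self.normalize_subjects:
            design.X = zscore_by_subject(design.X, design.feature_type_mask())
        seed = 0 if self.random_state is None else int(self.random_state)
        shards = partition_rows(design, self.n_sites, seed)
        config = SolverConfig(tol=self.tol, max_epochs=self.max_epochs)
        lambdas = uniform_lambda_grid(1.0, self.lambda_min, self.n_lambdas)
        path = solve_path(
            shards,
            design.group_columns(),
            design.weights(),
            lambdas,
            config=config,
            screening=self.screening,
        )
        fmap = smooth_map(
            count_selection(path, design, merge=self.merge),
            self.patch_rows,
            self.patch_cols,
        )
        selection = rank_and_select(fmap, self.top_k, design)
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[selection.selected_features] = True

        self.design_ = design
        self.path_ = path
        self.lambda_max_ = path.lambda_max
        self.frequency_map_ = fmap
        self.selection_ = selection
        self.support_mask_ = mask
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_mask_")
        return self.support_mask_

    def roi_scores(self, X=None) -> np.ndarray:
        """Frequency-weighted ROI scalar per subject (first PC score)."""
        check_is_fitted(self, "selection_")
        design = self.design_
        if X is not None:
            X = np.asarray(X, dtype=np.float64)
            design = GroupedDesign(
                X=zscore_by_subject(X, design.feature_type_mask())
                if self.normalize_subjects
                else X,
                y=np.zeros(X.shape[0]),
                groups=design.groups,
                feature_index=design.feature_index,
                grids=design.grids,
            )
        return roi_scalar(design, self.frequency_map_, self.selection_)
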