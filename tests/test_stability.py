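import numpy as np
import pytest

from fedmorph.design import (
    GroupedDesign,
    SurfaceGrid,
    build_grouped_layout,
)
from fedmorph.screening import LambdaPath, solve_path
from fedmorph.simulate import generate_cohort
from fedmorph.solver import Solution
from fedmorph.stability import (
    FrequencyMap,
    count_selection,
    export_map,
    group_patch_positions,
    patch_scores,
    rank_and_select,
    roi_scalar,
    smooth_map,
)


def tiny_design(rows=4, cols=6, n_subjects=5, seed=0):
    grid = SurfaceGrid(rows, cols, "left")
    groups, fi = build_grouped_layout(grid)
    rng = np.random.default_rng(seed)
    return GroupedDesign(
        X=rng.standard_normal((n_subjects, len(fi))),
        y=rng.standard_normal(n_subjects),
        groups=groups,
        feature_index=fi,
        grids=(grid,),
    )


def fake_path(design, betas):
    sols = [
        Solution(beta=b, objective=0.0, epochs_run=1, converged=True,
                 kkt_gap=0.0, lam=1.0 / (i + 1))
        for i, b in enumerate(betas)
    ]
    k = len(betas)
    return LambdaPath(
        lambdas_rel=np.linspace(1.0, 0.1, k),
        lambda_max=1.0,
        lambdas=np.linspace(1.0, 0.1, k),
        solutions=sols,
        retained_groups=[np.array([], dtype=int)] * k,
        n_group_updates=[0] * k,
    )


def cols_of_vertex(design, vertex, ftype):
    fi = design.feature_index
    from fedmorph.design import FEATURE_TYPES

    t = FEATURE_TYPES.index(ftype)
    return int(
        np.flatnonzero((fi["vertex"] == vertex) & (fi["feature_type_idx"] == t))[0]
    )


class TestCountSelection:
    def test_all_zero_path(self):
        d = tiny_design()
        fmap = count_selection(fake_path(d, [np.zeros(d.n_features)] * 3), d)
        assert np.all(fmap.normalized == 0)

    def test_upper_bound_vertex(self):
        d = tiny_design()
        v = 7
        beta = np.zeros(d.n_features)
        beta[cols_of_vertex(d, v, "RD")] = 1.0
        beta[cols_of_vertex(d, v, "TBM")] = -2.0
        fmap = count_selection(fake_path(d, [beta.copy() for _ in range(5)]), d)
        r, c = divmod(v, d.grids[0].cols)
        assert fmap.normalized[0, r, c] == 100.0

    def test_mixed_counts_hand_computed(self):
        """RD nonzero at 3 of 4 lambdas, TBM at 1: normalized 100*4/8 = 50."""
        d = tiny_design()
        v = 10
        rd, tbm = cols_of_vertex(d, v, "RD"), cols_of_vertex(d, v, "TBM")
        betas = []
        for k in range(4):
            b = np.zeros(d.n_features)
            if k < 3:
                b[rd] = 0.5
            if k == 0:
                b[tbm] = 0.5
            betas.append(b)
        fmap = count_selection(fake_path(d, betas), d)
        r, c = divmod(v, d.grids[0].cols)
        assert fmap.normalized[0, r, c] == 50.0
        fmap_max = count_selection(fake_path(d, betas), d, merge="max")
        assert fmap_max.normalized[0, r, c] == 75.0  # max(3,1)/4

    def test_empty_path_rejected(self):
        d = tiny_design()
        p = fake_path(d, [np.zeros(d.n_features)])
        p.solutions = []
        with pytest.raises(ValueError):
            count_selection(p, d)


class TestSmoothMap:
    def _map(self, vals):
        vals = np.asarray(vals, dtype=float)[None]
        return FrequencyMap(
            grids=(SurfaceGrid(vals.shape[1], vals.shape[2], "left"),),
            raw=vals.copy(),
            normalized=vals,
            kappa=1,
        )

    def test_constant_unchanged(self):
        fmap = smooth_map(self._map(np.full((6, 6), 42.0)))
        assert np.allclose(fmap.smoothed, 42.0)

    def test_interior_impulse(self):
        """A single 100 spreads as 100/6 to every window containing it."""
        vals = np.zeros((8, 9))
        vals[4, 4] = 100.0
        fmap = smooth_map(self._map(vals))
        # windows anchored with row offsets {0,1}, col offsets {-1,0,1}
        covered = fmap.smoothed[0] > 0
        exp = np.zeros((8, 9), dtype=bool)
        exp[3:5, 3:6] = True
        assert np.array_equal(covered, exp)
        assert np.allclose(fmap.smoothed[0][exp], 100.0 / 6.0)

    def test_corner_clipped_window(self):
        """At the bottom corners a 2x3 window clips to 1x2 cells."""
        vals = np.arange(12.0).reshape(3, 4)
        fmap = smooth_map(self._map(vals))
        assert fmap.smoothed[0, 2, 3] == pytest.approx((vals[2, 2] + vals[2, 3]) / 2)
        assert fmap.smoothed[0, 2, 0] == pytest.approx((vals[2, 0] + vals[2, 1]) / 2)

    def test_bounds_preserved(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 100, size=(10, 12))
        fmap = smooth_map(self._map(vals))
        assert fmap.smoothed.min() >= 0 and fmap.smoothed.max() <= 100

    def test_filter_larger_than_grid_rejected(self):
        from fedmorph.design import DimensionError

        with pytest.raises(DimensionError):
            smooth_map(self._map(np.zeros((1, 2))), 2, 3)


class TestRankSelect:
    def test_tie_breaks_to_lower_index(self):
        d = tiny_design()
        vals = np.zeros((1, 4, 6))
        vals[0, 2, 1] = 5.0
        vals[0, 0, 3] = 5.0
        fmap = FrequencyMap(grids=d.grids, raw=vals, normalized=vals, kappa=1,
                            smoothed=vals)
        sel = rank_and_select(fmap, 2, d)
        assert sel.ranked_vertices[0] == 0 * 6 + 3  # lower row-major index first
        assert sel.ranked_vertices[1] == 2 * 6 + 1

    def test_feature_count_is_twice_top_k(self):
        d = tiny_design()
        vals = np.random.default_rng(1).uniform(0, 100, (1, 4, 6))
        fmap = FrequencyMap(grids=d.grids, raw=vals, normalized=vals, kappa=1,
                            smoothed=vals)
        sel = rank_and_select(fmap, 7, d)
        assert len(sel.selected_features) == 14
        full = rank_and_select(fmap, 24, d)
        assert sorted(full.selected_features.tolist()) == list(range(d.n_features))

    def test_out_of_range_top_k(self):
        d = tiny_design()
        vals = np.zeros((1, 4, 6))
        fmap = FrequencyMap(grids=d.grids, raw=vals, normalized=vals, kappa=1,
                            smoothed=vals)
        with pytest.raises(ValueError):
            rank_and_select(fmap, 0, d)
        with pytest.raises(ValueError):
            rank_and_select(fmap, 25, d)


class TestRoiScalar:
    def test_weighted_sums_hand_computed(self):
        """freq (50,100) with RD (1,2), TBM (0,1) gives s_RD=250, s_TBM=100."""
        d = tiny_design(n_subjects=3)
        v0, v1 = 0, 1
        vals = np.zeros((1, 4, 6))
        vals[0, 0, 0] = 50.0
        vals[0, 0, 1] = 100.0
        fmap = FrequencyMap(grids=d.grids, raw=vals, normalized=vals, kappa=1,
                            smoothed=vals)
        X = d.X.copy()
        X[:, :] = 0.0
        X[:, cols_of_vertex(d, v0, "RD")] = 1.0
        X[:, cols_of_vertex(d, v1, "RD")] = 2.0
        X[:, cols_of_vertex(d, v0, "TBM")] = 0.0
        X[:, cols_of_vertex(d, v1, "TBM")] = 1.0
        d2 = GroupedDesign(X=X, y=d.y, groups=d.groups, feature_index=d.feature_index,
                           grids=d.grids)
        sel = rank_and_select(fmap, 2, d2)
        freqs = vals.reshape(-1)[sel.ranked_vertices[:2]]
        cols = sel.selected_features.reshape(-1, 2)
        s_rd = d2.X[:, cols[:, 0]] @ freqs
        s_tbm = d2.X[:, cols[:, 1]] @ freqs
        assert np.allclose(s_rd, 250.0)
        assert np.allclose(s_tbm, 100.0)
        # identical rows -> zero variance in both columns: degenerate PCA
        with pytest.raises(ValueError, match="degenerate"):
            roi_scalar(d2, fmap, sel)

    def test_rank_one_case_proportional(self):
        """Perfectly correlated s_RD and s_TBM give PC1 scores equal to either."""
        d = tiny_design(n_subjects=20, seed=5)
        vals = np.full((1, 4, 6), 10.0)
        fmap = FrequencyMap(grids=d.grids, raw=vals, normalized=vals, kappa=1,
                            smoothed=vals)
        X = d.X.copy()
        subj = np.linspace(-1, 1, 20)
        for v in range(24):
            X[:, cols_of_vertex(d, v, "RD")] = subj
            X[:, cols_of_vertex(d, v, "TBM")] = subj
        d2 = GroupedDesign(X=X, y=d.y, groups=d.groups, feature_index=d.feature_index,
                           grids=d.grids)
        sel = rank_and_select(fmap, 4, d2)
        scores = roi_scalar(d2, fmap, sel)
        s_rd = d2.X[:, sel.selected_features.reshape(-1, 2)[:, 0]] @ np.full(4, 10.0)
        corr = np.corrcoef(scores, s_rd)[0, 1]
        assert corr == pytest.approx(1.0, abs=1e-10)


class TestExportMap:
    def _smoothed_map(self, rows, cols):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 100, (1, rows, cols))
        return FrequencyMap(
            grids=(SurfaceGrid(rows, cols, "left"),),
            raw=vals, normalized=vals, kappa=1, smoothed=vals,
        )

    def test_text_round_trip(self, tmp_path):
        fmap = self._smoothed_map(5, 7)
        (out,) = export_map(fmap, tmp_path / "freq", fmt="text")
        import pandas as pd

        df = pd.read_csv(out, sep="\t")
        back = np.zeros((5, 7))
        back[df["row"], df["col"]] = df["value"]
        assert np.max(np.abs(back - fmap.smoothed[0])) < 1e-6

    def test_ply_study_scale_counts(self, tmp_path):
        """One hemisphere exports 15,000 vertices and 2*99*149 triangles."""
        fmap = self._smoothed_map(100, 150)
        (out,) = export_map(fmap, tmp_path / "freq", fmt="ply")
        text = out.read_text().splitlines()
        assert "element vertex 15000" in text[:9]
        assert f"element face {2 * 99 * 149}" in text[:9]
        n_vertex_lines = sum(1 for ln in text if ln.endswith(" 0") is False)
        body = text[text.index("end_header") + 1 :]
        assert len(body) == 15000 + 2 * 99 * 149

    def test_unknown_format(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            export_map(self._smoothed_map(3, 3), tmp_path / "x", fmt="npz")

    def test_unsmoothed_rejected(self, tmp_path):
        fmap = self._smoothed_map(3, 3)
        fmap.smoothed = None
        with pytest.raises(ValueError):
            export_map(fmap, tmp_path / "x", fmt="text")


class TestPipelineProperties:
    def test_determinism_and_bounds(self, small_cohort):
        design, shards, truth = small_cohort
        cols, w = design.group_columns(), design.weights()
        maps = []
        for _ in range(2):
            path = solve_path(shards, cols, w, np.linspace(1.0, 0.2, 6))
            fmap = smooth_map(count_selection(path, design))
            maps.append(fmap)
        assert np.array_equal(maps[0].normalized, maps[1].normalized)
        assert np.array_equal(maps[0].smoothed, maps[1].smoothed)
        for m in maps:
            assert m.normalized.min() >= 0 and m.normalized.max() <= 100
            assert m.smoothed.min() >= 0 and m.smoothed.max() <= 100

    def test_null_control_under_permutation(self):
        """Destroying the signal wipes out the planted patches' frequencies.

        With y permuted, no vertex should reach the frequencies the true
        support attains in the planted-signal runs (99th percentile).
        """
        from fedmorph.design import partition_rows

        grid = SurfaceGrid(20, 30, "left")
        true_freqs, null_freqs = [], []
        for seed in range(5):
            design, shards, truth = generate_cohort(
                n_subjects=150, grids=grid, n_true_patches=3,
                effect_scale=3.0, smoothness=1.0, n_sites=1, seed=40 + seed,
            )
            cols, w = design.group_columns(), design.weights()
            pos = group_patch_positions(design)
            sup_pos = pos[list(truth.support)]
            path = solve_path(shards, cols, w, np.linspace(1.0, 0.3, 8))
            true_freqs.append(
                patch_scores(count_selection(path, design))[sup_pos].mean()
            )
            rng = np.random.default_rng(1000 + seed)
            design.y = design.y[rng.permutation(design.n_subjects)]
            shards_null = partition_rows(design, 1, seed=0)
            path_null = solve_path(shards_null, cols, w, np.linspace(1.0, 0.3, 8))
            null_freqs.append(
                patch_scores(count_selection(path_null, design))[sup_pos].mean()
            )
        # per-seed collapse at the support, and clear aggregate separation
        assert all(n < t for n, t in zip(null_freqs, true_freqs))
        assert np.mean(null_freqs) < 0.5 * np.mean(true_freqs)
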