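"""Honeycomb grid geometry, k-NN assignment, filtering and pooling."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from spotalign import (GridConfig, assign_nearest_spots, filter_digital_spots,
                       generate_hex_grid, pool_expression)
from spotalign.preprocess import NormalizedMatrix


def brute_force_hex_count(mask, um_per_px, spacing):
    """Independent lattice enumeration: nested loops over row/column indices
    anchored at the mask bounding-box centroid, point-in-mask by pixel test."""
    ys, xs = np.nonzero(mask)
    cx = (xs.min() + xs.max()) / 2.0 * um_per_px
    cy = (ys.min() + ys.max()) / 2.0 * um_per_px
    row_pitch = spacing * np.sqrt(3) / 2.0
    count = 0
    span = max(mask.shape) * um_per_px
    jmax = int(span / row_pitch) + 2
    imax = int(span / spacing) + 2
    for j in range(-jmax, jmax + 1):
        y = cy + j * row_pitch
        off = spacing / 2.0 if j % 2 else 0.0
        for i in range(-imax, imax + 1):
            x = cx + off + i * spacing
            px, py = round(x / um_per_px), round(y / um_per_px)
            if 0 <= px < mask.shape[1] and 0 <= py < mask.shape[0] \
                    and mask[py, px]:
                count += 1
    return count


class TestHexGrid:
    def test_interior_spot_has_six_equidistant_neighbors(self):
        mask = np.ones((300, 300), dtype=np.uint8)
        cfg = GridConfig(spacing_um=150.0)
        pts = generate_hex_grid(mask, 10.0, cfg)
        tree = cKDTree(pts)
        center = pts[np.argmin(np.linalg.norm(pts - pts.mean(axis=0), axis=1))]
        d, _ = tree.query(center, k=7)
        np.testing.assert_allclose(d[1:], 150.0, rtol=1e-9)

    def test_all_zero_mask_gives_empty_grid(self):
        with pytest.warns(UserWarning, match="empty"):
            pts = generate_hex_grid(np.zeros((50, 50)), 10.0)
        assert pts.shape == (0, 2)

    def test_count_matches_bruteforce_enumeration(self):
        mask = np.zeros((140, 140), dtype=np.uint8)
        mask[20:120, 20:120] = 1                    # 1000 x 1000 um at 10 um/px
        cfg = GridConfig(spacing_um=150.0)
        pts = generate_hex_grid(mask, 10.0, cfg)
        assert len(pts) == brute_force_hex_count(mask, 10.0, 150.0)

    def test_deterministic_and_translation_invariant(self):
        mask = np.zeros((200, 220), dtype=np.uint8)
        yy, xx = np.mgrid[0:200, 0:220]
        mask[((xx - 90) / 70.0) ** 2 + ((yy - 100) / 55.0) ** 2 <= 1] = 1
        cfg = GridConfig(spacing_um=150.0)
        a = generate_hex_grid(mask, 10.0, cfg)
        b = generate_hex_grid(mask, 10.0, cfg)
        np.testing.assert_array_equal(a, b)
        # shift by one horizontal lattice vector (150 um = 15 px)
        shifted = np.zeros_like(mask)
        shifted[:, 15:] = mask[:, :-15]
        c = generate_hex_grid(shifted, 10.0, cfg)
        assert len(c) == len(a)

    def test_nearest_neighbor_pitch_across_grid(self):
        mask = np.ones((250, 250), dtype=np.uint8)
        pts = generate_hex_grid(mask, 10.0, GridConfig(spacing_um=150.0))
        tree = cKDTree(pts)
        d, _ = tree.query(pts, k=2)
        np.testing.assert_allclose(d[:, 1], 150.0, rtol=1e-9)

    def test_cap_is_three_spacings_under_defaults(self):
        cfg = GridConfig()
        assert cfg.max_distance_um == pytest.approx(3 * cfg.spacing_um)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            GridConfig(spacing_um=0)
        with pytest.raises(ValueError):
            GridConfig(k_neighbors=0)
        with pytest.raises(ValueError):
            GridConfig(spacing_um=200, max_distance_um=150)


class TestAssignment:
    def test_coincident_spots_have_zero_first_distance(self):
        pts = np.array([[0.0, 0], [150.0, 0], [300.0, 0]])
        grid = assign_nearest_spots(pts, {"s1": pts.copy()},
                                    GridConfig(k_neighbors=2))
        for idx, dist in grid.neighbors["s1"]:
            assert dist[0] == 0.0

    def test_distant_sample_yields_empty_lists(self):
        pts = np.array([[0.0, 0.0]])
        far = np.array([[10000.0, 10000.0]])
        grid = assign_nearest_spots(pts, {"s1": far})
        idx, dist = grid.neighbors["s1"][0]
        assert len(idx) == 0

    def test_zero_spot_sample_rejected(self):
        with pytest.raises(ValueError, match="zero registered"):
            assign_nearest_spots(np.array([[0.0, 0]]),
                                 {"s1": np.empty((0, 2))})

    def test_matches_exhaustive_knn_oracle(self):
        rng = np.random.default_rng(8)
        digital = rng.uniform(0, 2000, size=(40, 2))
        cfg = GridConfig(k_neighbors=7, max_distance_um=450.0)
        samples = {f"s{i}": rng.uniform(0, 2000, size=(150, 2))
                   for i in range(3)}
        grid = assign_nearest_spots(digital, samples, cfg)
        for sid, pts in samples.items():
            dmat = cdist(digital, pts)
            for d_idx in range(len(digital)):
                row = dmat[d_idx]
                order = np.lexsort((np.arange(len(row)), row))
                keep = [i for i in order if row[i] <= cfg.max_distance_um]
                keep = keep[:cfg.k_neighbors]
                idx, dist = grid.neighbors[sid][d_idx]
                np.testing.assert_array_equal(idx, keep)
                np.testing.assert_allclose(dist, row[keep])

    def test_tie_break_by_spot_index(self):
        digital = np.array([[0.0, 0.0]])
        pts = np.array([[100.0, 0.0], [0.0, 100.0], [-100.0, 0.0]])
        grid = assign_nearest_spots(digital, {"s": pts},
                                    GridConfig(k_neighbors=2,
                                               max_distance_um=450))
        idx, dist = grid.neighbors["s"][0]
        np.testing.assert_array_equal(idx, [0, 1])


class TestFilterAndPool:
    def _toy_grid(self, n_samples=3, k=2):
        digital = np.array([[0.0, 0], [1000.0, 0]])
        samples = {}
        for i in range(n_samples):
            # every sample covers spot 0 with k spots; only sample 0 covers spot 1
            pts = [[10.0 * i, 0], [20.0, 30]]
            if i == 0:
                pts += [[1000.0, 10], [1000.0, -10]]
            samples[f"s{i}"] = np.array(pts, dtype=float)
        cfg = GridConfig(spacing_um=100, k_neighbors=k, max_distance_um=450)
        return assign_nearest_spots(digital, samples, cfg), cfg

    def test_full_coverage_removes_nothing(self):
        pts = np.array([[0.0, 0], [100.0, 0]])
        cfg = GridConfig(spacing_um=100, k_neighbors=2, max_distance_um=450)
        grid = assign_nearest_spots(pts, {"a": pts, "b": pts}, cfg)
        grid, removed = filter_digital_spots(grid, cfg)
        assert removed == 0 and grid.kept.all()

    def test_uncovered_region_spots_removed(self):
        grid, cfg = self._toy_grid()
        grid, removed = filter_digital_spots(grid, cfg)
        assert removed == 1
        np.testing.assert_array_equal(grid.kept, [True, False])

    def test_removal_matches_bruteforce_recount(self, small_cohort):
        import spotalign as sa
        cfg, bundles, timg, tmask, truth = small_cohort
        res = sa.run_pipeline_bundles(
            bundles, timg, tmask,
            sa.PipelineConfig(qc=sa.QCConfig(min_spot_counts=0)),
            group_order=("NSD", "SD"))
        grid = res.grid
        need = grid.config.min_required
        expect = np.ones(grid.n_spots, dtype=bool)
        for per_spot in grid.neighbors.values():
            for j, (idx, _) in enumerate(per_spot):
                if len(idx) < need:
                    expect[j] = False
        np.testing.assert_array_equal(grid.kept, expect)

    def test_pooled_width_additive_over_samples(self):
        grid, cfg = self._toy_grid(n_samples=3, k=2)
        grid, _ = filter_digital_spots(grid, cfg)
        genes = np.array(["gA", "gB"], dtype=object)
        normalized = {}
        for sid in grid.neighbors:
            n = len(grid.neighbors[sid][0][0]) + 10
            vals = np.arange(2 * 4, dtype=float).reshape(2, 4)
            normalized[sid] = NormalizedMatrix(
                genes, np.array([f"{sid}-{i}" for i in range(4)], dtype=object),
                vals, "log2_size1")
        pooled = pool_expression(grid, normalized,
                                 {sid: ("A" if sid == "s0" else "B")
                                  for sid in grid.neighbors})
        d0 = pooled.kept_indices[0]
        assert pooled.width(0, "B") == sum(
            len(grid.neighbors[sid][d0][0]) for sid in ("s1", "s2"))
        mat = pooled.matrix(0, "B")
        assert mat.shape == (2, pooled.width(0, "B"))

    def test_empty_gene_universe_rejected(self):
        grid, cfg = self._toy_grid()
        grid, _ = filter_digital_spots(grid, cfg)
        normalized = {
            sid: NormalizedMatrix(np.array([f"only-{sid}"], dtype=object),
                                  np.array(["b"], dtype=object),
                                  np.zeros((1, 1)), "log2_size1")
            for sid in grid.neighbors}
        # pooling requires >= 1 shared gene across samples
        with pytest.raises(ValueError, match="gene universe"):
            pool_expression(grid, normalized,
                            {sid: "A" for sid in grid.neighbors})

    def test_mixed_schemes_rejected(self):
        grid, cfg = self._toy_grid()
        grid, _ = filter_digital_spots(grid, cfg)
        genes = np.array(["g"], dtype=object)
        normalized = {}
        for i, sid in enumerate(grid.neighbors):
            normalized[sid] = NormalizedMatrix(
                genes, np.array(["b"], dtype=object), np.zeros((1, 1)),
                "log2_size1" if i else "log2_cpm1")
        with pytest.raises(ValueError, match="mixed"):
            pool_expression(grid, normalized,
                            {sid: "A" for sid in grid.neighbors})
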