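"""QC filters, normalization schemes, orientation and tissue masking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spotalign import (QCConfig, compute_tissue_mask, filter_spots,
                       normalize_log2, orient_sample, qc_summary,
                       rescale_to_template)

from conftest import make_bundle


class TestFilterSpots:
    def test_count_floor_boundary(self):
        # totals 4999 / 5000 / 5001: strictly-below-floor spot removed only
        counts = np.array([[4999, 5000, 5001]])
        b = make_bundle(counts)
        fb, rep = filter_spots(b, QCConfig(min_spot_counts=5000,
                                           drop_zero_genes=False))
        assert fb.n_spots == 2
        assert rep.removed_spots == ["BC000"]
        np.testing.assert_array_equal(
            np.asarray(fb.counts_aligned().todense()), [[5000, 5001]])

    def test_zero_total_gene_removed(self):
        counts = np.array([[5, 6], [0, 0], [1, 0]])
        fb, rep = filter_spots(make_bundle(counts), QCConfig(min_spot_counts=0))
        assert list(fb.counts.genes) == ["g0", "g2"]
        assert rep.removed_genes == ["g1"]

    def test_noop_config_is_identity(self, tiny_bundle):
        fb, rep = filter_spots(tiny_bundle,
                               QCConfig(min_spot_counts=0, drop_zero_genes=False))
        assert fb.n_spots == tiny_bundle.n_spots
        assert fb.n_genes == tiny_bundle.n_genes
        assert not rep.removed_spots and not rep.removed_genes

    def test_non_tissue_spots_always_dropped(self):
        counts = np.array([[10, 10, 10]])
        b = make_bundle(counts, in_tissue=np.array([True, False, True]))
        fb, _ = filter_spots(b, QCConfig(min_spot_counts=0))
        assert fb.n_spots == 2

    def test_all_spots_removed_is_error(self):
        b = make_bundle(np.array([[1, 2]]))
        with pytest.raises(ValueError, match="unusable"):
            filter_spots(b, QCConfig(min_spot_counts=10**6))

    def test_idempotent(self, tiny_bundle):
        qc = QCConfig(min_spot_counts=50)
        once, _ = filter_spots(tiny_bundle, qc)
        twice, rep2 = filter_spots(once, qc)
        assert twice.n_spots == once.n_spots
        assert twice.n_genes == once.n_genes
        assert not rep2.removed_spots and not rep2.removed_genes


class TestNormalize:
    def test_formula_oracle_random_matrix(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 50, size=(20, 30))
        counts[:, counts.sum(axis=0) == 0] += 1
        b = make_bundle(counts)
        totals = counts.sum(axis=0)
        for scheme, expected in [
            ("log2_count1", np.log2(1 + counts)),
            ("log2_cpm1", np.log2(1 + 1e6 * counts / totals)),
            ("log2_size1", np.log2(1 + 1e4 * counts / totals)),
        ]:
            nm = normalize_log2(b.counts, scheme)
            np.testing.assert_allclose(nm.values, expected)
            assert nm.scheme == scheme

    def test_cpm_arithmetic_example(self):
        # a count of 2 in a 2-million-count spot is CPM 1 -> log2(2) = 1
        counts = np.zeros((2, 1), dtype=int)
        counts[0, 0] = 2
        counts[1, 0] = 2_000_000 - 2
        nm = normalize_log2(make_bundle(counts).counts, "log2_cpm1")
        assert nm.values[0, 0] == pytest.approx(1.0)

    def test_zero_maps_to_zero_under_all_schemes(self):
        counts = np.array([[0, 3], [5, 0]])
        for scheme in ("log2_count1", "log2_cpm1", "log2_size1"):
            nm = normalize_log2(make_bundle(counts).counts, scheme)
            assert nm.values[0, 0] == 0.0 and nm.values[1, 1] == 0.0

    def test_zero_total_spot_is_error_under_cpm(self):
        counts = np.array([[1, 0]])
        with pytest.raises(ValueError, match="zero total"):
            normalize_log2(make_bundle(counts).counts, "log2_cpm1")

    def test_monotone_in_counts_within_spot(self):
        counts = np.array([[0], [1], [5], [50]])
        for scheme in ("log2_count1", "log2_cpm1", "log2_size1"):
            v = normalize_log2(make_bundle(counts).counts, scheme).values.ravel()
            assert np.all(np.diff(v) > 0)

    @given(st.integers(min_value=2, max_value=20))
    @settings(deadline=None, max_examples=10, derandomize=True)
    def test_cpm_invariant_to_spotwise_scaling(self, factor):
        rng = np.random.default_rng(5)
        counts = rng.integers(1, 30, size=(10, 4))
        a = normalize_log2(make_bundle(counts).counts, "log2_cpm1")
        b = normalize_log2(make_bundle(counts * factor).counts, "log2_cpm1")
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)


class TestQCSummary:
    def test_hand_counted_single_spot(self):
        counts = np.array([[0], [3], [5]])
        s = qc_summary(make_bundle(counts))
        assert s["mean_genes_detected_per_spot"][0] == 2
        assert s["mean_counts_per_spot"][0] == 8

    def test_deterministic(self, tiny_bundle):
        assert qc_summary(tiny_bundle).equals(qc_summary(tiny_bundle))

    def test_matches_bruteforce_recount(self, small_cohort):
        _, bundles, *_ = small_cohort
        b = next(iter(bundles.values()))
        s = qc_summary(b)
        dense = np.asarray(b.counts_aligned().todense())
        assert s["n_spots"][0] == dense.shape[1]
        assert s["mean_counts_per_spot"][0] == pytest.approx(
            dense.sum(axis=0).mean())
        assert s["median_counts_per_spot"][0] == pytest.approx(
            np.median(dense.sum(axis=0)))
        assert s["mean_genes_detected_per_spot"][0] == pytest.approx(
            (dense > 0).sum(axis=0).mean())


class TestOrient:
    def test_rotation_zero_no_mirror_is_identity(self, tiny_bundle):
        ob = orient_sample(tiny_bundle, 0, mirror=False)
        np.testing.assert_array_equal(ob.spot_table.xy, tiny_bundle.spot_table.xy)
        np.testing.assert_array_equal(ob.image, tiny_bundle.image)

    def test_corner_mapping_90cw(self):
        img = np.zeros((30, 40))                    # H=30, W=40
        b = make_bundle(np.ones((1, 1), dtype=int),
                        xy=np.array([[0.0, 0.0]]), image=img)
        ob = orient_sample(b, 90)
        assert (ob.spot_table.x_px[0], ob.spot_table.y_px[0]) == (29.0, 0.0)
        assert ob.image.shape == (40, 30)

    def test_four_quarter_turns_compose_to_identity(self, tiny_bundle):
        b = tiny_bundle
        for _ in range(4):
            b = orient_sample(b, 90)
        np.testing.assert_allclose(b.spot_table.xy, tiny_bundle.spot_table.xy)
        np.testing.assert_array_equal(b.image, tiny_bundle.image)

    def test_mirror_twice_is_identity(self, tiny_bundle):
        b = orient_sample(orient_sample(tiny_bundle, 0, True), 0, True)
        np.testing.assert_allclose(b.spot_table.xy, tiny_bundle.spot_table.xy)
        np.testing.assert_array_equal(b.image, tiny_bundle.image)

    @pytest.mark.parametrize("rot,mirror", [(90, False), (180, False),
                                            (270, True), (0, True)])
    def test_pairwise_distances_preserved(self, tiny_bundle, rot, mirror):
        from scipy.spatial.distance import pdist
        ob = orient_sample(tiny_bundle, rot, mirror)
        np.testing.assert_allclose(pdist(ob.spot_table.xy),
                                   pdist(tiny_bundle.spot_table.xy))

    def test_invalid_rotation_rejected(self, tiny_bundle):
        with pytest.raises(ValueError):
            orient_sample(tiny_bundle, 45)


class TestTissueMask:
    def test_constant_image_is_error(self):
        with pytest.raises(ValueError, match="[Cc]onstant"):
            compute_tissue_mask(np.full((40, 40), 7.0), um_per_px=10.0)

    def test_dark_disk_phantom_iou(self):
        yy, xx = np.mgrid[0:200, 0:200]
        disk = (xx - 100) ** 2 + (yy - 100) ** 2 <= 50 ** 2
        img = np.where(disk, 60.0, 220.0)
        tm = compute_tissue_mask(img, um_per_px=10.0)
        inter = np.logical_and(tm.mask > 0, disk).sum()
        union = np.logical_or(tm.mask > 0, disk).sum()
        assert inter / union >= 0.95

    def test_contract_binary_and_shape(self):
        img = np.where(np.arange(1600).reshape(40, 40) > 800, 10.0, 240.0)
        tm = compute_tissue_mask(img, um_per_px=10.0)
        assert tm.mask.shape == img.shape
        assert set(np.unique(tm.mask)) <= {0, 1}

    def test_area_invariant_under_affine_intensity_map(self):
        yy, xx = np.mgrid[0:150, 0:150]
        blob = ((xx - 70) ** 2 / 55 ** 2 + (yy - 80) ** 2 / 40 ** 2) <= 1
        rng = np.random.default_rng(9)
        img = np.where(blob, 70.0, 220.0) + rng.normal(0, 3, blob.shape)
        a1 = compute_tissue_mask(img, 10.0).area_px
        a2 = compute_tissue_mask(2.5 * img + 40.0, 10.0).area_px
        assert abs(a1 - a2) <= 0.02 * a1


class TestRescale:
    def test_identity_at_template_resolution(self, tiny_bundle):
        b = tiny_bundle.with_(image_um_per_px=10.0)
        rb = rescale_to_template(b, 10.0)
        np.testing.assert_array_equal(rb.spot_table.xy, b.spot_table.xy)

    def test_coordinate_scaling_factor(self, tiny_bundle):
        rb = rescale_to_template(tiny_bundle, 10.0)   # 0.5 um/px -> 10 um/px
        np.testing.assert_allclose(rb.spot_table.xy,
                                   tiny_bundle.spot_table.xy * 0.05)
        assert rb.image_um_per_px == 10.0

    def test_neighbor_distance_in_template_pixels(self):
        # 100 um pitch = 200 px at 0.5 um/px -> 10 template px at 10 um/px
        b = make_bundle(np.ones((1, 2), dtype=int),
                        xy=np.array([[0.0, 0.0], [200.0, 0.0]]))
        rb = rescale_to_template(b, 10.0)
        d = np.linalg.norm(rb.spot_table.xy[1] - rb.spot_table.xy[0])
        assert d == pytest.approx(10.0)
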