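"""Shared fixtures: tiny hand-built bundles and small simulated cohorts."""

import numpy as np
import pytest
import scipy.sparse as sp

from spotalign import (CountMatrix, SampleBundle, ScaleFactors, SimConfig,
                       SpotTable, simulate_cohort)


def make_bundle(counts, xy=None, in_tissue=None, sample_id="s1", group="NSD",
                hemisphere="left", spot_diameter_fullres=110.0,
                image=None, um_per_px=0.5):
    """Hand-built bundle from a dense genes x spots count array."""
    counts = np.asarray(counts)
    n_genes, n_spots = counts.shape
    if xy is None:
        xy = np.column_stack([np.arange(n_spots) * 200.0,
                              np.zeros(n_spots)])
    if in_tissue is None:
        in_tissue = np.ones(n_spots, dtype=bool)
    barcodes = np.array([f"BC{i:03d}" for i in range(n_spots)], dtype=object)
    genes = np.array([f"g{i}" for i in range(n_genes)], dtype=object)
    table = SpotTable(barcodes, in_tissue, np.arange(n_spots),
                      np.zeros(n_spots, dtype=int), xy[:, 0], xy[:, 1])
    cm = CountMatrix(genes, barcodes, sp.csr_matrix(counts))
    if image is None:
        image = np.full((50, 60), 200.0)
    return SampleBundle(sample_id=sample_id, group=group, hemisphere=hemisphere,
                        spot_table=table, counts=cm,
                        scale=ScaleFactors(spot_diameter_fullres),
                        image=image, image_um_per_px=um_per_px)


@pytest.fixture
def tiny_bundle():
    """12 spots x 5 genes with deterministic counts."""
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 20, size=(5, 12))
    counts[0] += 1                              # gene with no zero column
    return make_bundle(counts)


@pytest.fixture(scope="session")
def small_cohort():
    """Fast simulated cohort (reduced genes/extent) for structural tests."""
    cfg = SimConfig(seed=11, n_genes=80, extent_um=(2200.0, 2000.0))
    bundles, timg, tmask, truth = simulate_cohort(cfg)
    return cfg, bundles, timg, tmask, truth
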