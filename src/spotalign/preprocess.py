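"""Spot/gene QC, normalization, orientation and template-resolution resampling.

Quality control follows the conventional Visium path: only in-tissue spots are
analysed, spots with fewer than 5000 total counts are discarded (a low total
usually indicates a capture failure rather than biology), and genes with zero
counts across the whole sample are dropped.  Two log2 normalizations are
provided: ``log2_count1`` (log2 of count + 1, used on the digital-spot path)
and ``log2_cpm1`` (log2 of CPM + 1, used on the region-of-interest path).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from skimage.filters import gaussian, threshold_otsu
from skimage.transform import rescale as _sk_rescale

from .visium_io import CountMatrix, SampleBundle, SpotTable, um_per_pixel

__all__ = [
    "QCConfig",
    "NormalizedMatrix",
    "TissueMask",
    "filter_spots",
    "normalize_log2",
    "qc_summary",
    "orient_sample",
    "compute_tissue_mask",
    "rescale_to_template",
]


@dataclass(frozen=True)
class QCConfig:
    """Spot/gene QC thresholds.

    min_spot_counts: spots with total counts strictly below this are removed
    (the boundary value itself is kept).  drop_zero_genes: remove genes with
    zero total counts across the sample.
    """

    min_spot_counts: int = 5000
    drop_zero_genes: bool = True

    def __post_init__(self) -> None:
        if self.min_spot_counts < 0:
            raise ValueError("min_spot_counts must be >= 0")


@dataclass
class NormalizedMatrix:
    """Log2-scale expression values with the scheme recorded for provenance."""

    genes: np.ndarray
    spots: np.ndarray
    values: np.ndarray           # genes x spots, dense float
    scheme: str                  # "log2_count1" | "log2_cpm1"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.spots)):
            raise ValueError("normalized value shape mismatch")
        if self.values.size and self.values.min() < 0:
            raise ValueError("log2 values must be non-negative")


@dataclass
class TissueMask:
    """Binary tissue mask aligned to an image."""

    mask: np.ndarray
    blur_sigma_um: float = 20.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(np.uint8)
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask values must be 0/1")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class QCReport:
    removed_spots: list
    removed_genes: list
    n_spots_before: int
    n_spots_after: int
    n_genes_before: int
    n_genes_after: int

    def to_frame(self) -> pd.DataFrame:
        rows = [("spot", b) for b in self.removed_spots]
        rows += [("gene", g) for g in self.removed_genes]
        return pd.DataFrame(rows, columns=["kind", "id"])


def filter_spots(bundle: SampleBundle, qc: QCConfig = QCConfig()):
    """Apply spot and gene QC; returns (filtered bundle, removal report).

    Keeps in-tissue spots whose total counts are >= ``qc.min_spot_counts``
    ("fewer than" the floor is removed, the boundary is kept) and drops genes
    with zero total counts across the sample.
    """
    aligned = bundle.counts_aligned()
    totals = np.asarray(aligned.sum(axis=0)).ravel()
    keep_spot = bundle.spot_table.in_tissue & (totals >= qc.min_spot_counts)
    removed_spots = list(bundle.spot_table.barcode[~keep_spot])
    if not keep_spot.any():
        raise ValueError(
            f"sample {bundle.sample_id}: all spots removed by QC; sample unusable")

    table = bundle.spot_table.subset(keep_spot)
    mat = aligned[:, keep_spot]
    gene_totals = np.asarray(mat.sum(axis=1)).ravel()
    keep_gene = (gene_totals > 0) if qc.drop_zero_genes \
        else np.ones(mat.shape[0], dtype=bool)
    removed_genes = list(bundle.counts.genes[~keep_gene])

    counts = CountMatrix(
        bundle.counts.genes[keep_gene],
        table.barcode,
        mat[keep_gene],
        bundle.counts.gene_symbols[keep_gene],
    )
    report = QCReport(
        removed_spots, removed_genes,
        bundle.n_spots, table.n_spots,
        bundle.counts.n_genes, counts.n_genes,
    )
    return bundle.with_(spot_table=table, counts=counts), report


def normalize_log2(counts: CountMatrix, scheme: str = "log2_size1") -> NormalizedMatrix:
    """Log2-normalize raw counts.

    log2_count1: ``log2(1 + c)`` — proportional-change scale on raw counts,
    no library-size correction.
    log2_cpm1:   ``log2(1 + 1e6 * c / total_spot_counts)`` — counts-per-
    million with a pseudocount of one on the CPM scale.
    log2_size1:  ``log2(1 + c * 1e4 / total_spot_counts)`` — counts rescaled
    to a common library size of 10,000 (the counts-per-10k convention),
    pseudocount of one on the rescaled-count scale.  At typical spot depths
    this keeps the variance profile of ``log2_count1`` (a one-count jump
    stays about one log2 unit near zero, rather than the ~100 CPM units a
    single count represents) while removing library-size differences, which
    would otherwise shift all genes between groups whose mean library sizes
    differ by chance.

    Zero counts map to zero under every scheme.
    """
    dense = np.asarray(counts.counts.todense(), dtype=float)
    if scheme == "log2_count1":
        values = np.log2(1.0 + dense)
    elif scheme in ("log2_cpm1", "log2_size1"):
        totals = dense.sum(axis=0)
        if np.any(totals <= 0):
            raise ValueError(
                f"spot with zero total counts under {scheme}; run filter_spots first")
        target = 1e6 if scheme == "log2_cpm1" else 1e4
        values = np.log2(1.0 + target * dense / totals)
    else:
        raise ValueError(f"unknown normalization scheme {scheme!r}")
    return NormalizedMatrix(counts.genes, counts.spots, values, scheme)


def qc_summary(bundle: SampleBundle) -> pd.DataFrame:
    """Per-sample QC metrics: spot count, total-count and genes-detected stats."""
    aligned = bundle.counts_aligned()
    totals = np.asarray(aligned.sum(axis=0)).ravel()
    detected = np.asarray((aligned > 0).sum(axis=0)).ravel()
    return pd.DataFrame({
        "sample_id": [bundle.sample_id],
        "n_spots": [bundle.n_spots],
        "n_genes": [bundle.n_genes],
        "median_counts_per_spot": [float(np.median(totals)) if totals.size else 0.0],
        "mean_counts_per_spot": [float(totals.mean()) if totals.size else 0.0],
        "mean_genes_detected_per_spot": [float(detected.mean()) if detected.size else 0.0],
    })


def _rotate_coords(x, y, w, h, rotation_deg):
    """Map (x, y) under clockwise image rotation; (w, h) are pre-rotation dims."""
    if rotation_deg == 0:
        return x, y
    if rotation_deg == 90:                    # (x, y) -> (H-1-y, x)
        return h - 1 - y, x
    if rotation_deg == 180:
        return w - 1 - x, h - 1 - y
    if rotation_deg == 270:
        return y, w - 1 - x
    raise ValueError("rotation must be one of 0, 90, 180, 270")


def orient_sample(bundle: SampleBundle, rotation_deg: int = 0,
                  mirror: bool = False) -> SampleBundle:
    """Rotate the image clockwise by a multiple of 90 degrees, then optionally
    mirror left-right; spot coordinates are transformed identically."""
    if rotation_deg not in (0, 90, 180, 270):
        raise ValueError("rotation must be one of 0, 90, 180, 270")
    h, w = bundle.image.shape
    image = np.rot90(bundle.image, k=-(rotation_deg // 90))
    x, y = _rotate_coords(bundle.spot_table.x_px, bundle.spot_table.y_px,
                          w, h, rotation_deg)
    if mirror:
        image = image[:, ::-1].copy()
        x = image.shape[1] - 1 - x
    table = SpotTable(
        bundle.spot_table.barcode, bundle.spot_table.in_tissue,
        bundle.spot_table.array_row, bundle.spot_table.array_col, x, y,
    )
    return bundle.with_(spot_table=table, image=np.ascontiguousarray(image))


def compute_tissue_mask(image: np.ndarray, um_per_px: float,
                        blur_sigma_um: float = 20.0) -> TissueMask:
    """Gaussian blur (sigma in um) followed by Otsu thresholding.

    The tissue side of the threshold is chosen automatically as the side with
    the lower mean intensity (tissue is dark on H&E-like brightfield images).
    """
    image = np.asarray(image, dtype=float)
    if um_per_px <= 0:
        raise ValueError("um_per_px must be positive")
    if np.ptp(image) == 0:
        raise ValueError("constant image: no Otsu threshold exists")
    sigma_px = blur_sigma_um / um_per_px
    blurred = gaussian(image, sigma=sigma_px, preserve_range=True)
    thr = threshold_otsu(blurred)
    below = blurred <= thr
    # foreground = darker side
    mean_below = blurred[below].mean() if below.any() else np.inf
    mean_above = blurred[~below].mean() if (~below).any() else np.inf
    mask = below if mean_below <= mean_above else ~below
    return TissueMask(mask.astype(np.uint8), blur_sigma_um)


def rescale_to_template(bundle: SampleBundle,
                        template_um_per_px: float = 10.0) -> SampleBundle:
    """Resample the image and spot coordinates into template resolution.

    After this step coordinates are in template pixels (10 um units by
    default), the frame shared with the registration template.
    """
    factor = bundle.image_um_per_px / template_um_per_px
    if factor <= 0:
        raise ValueError("resampling factor must be positive")
    if np.isclose(factor, 1.0):
        return bundle
    image = _sk_rescale(np.asarray(bundle.image, dtype=float), factor,
                        preserve_range=True, anti_aliasing=factor < 1)
    table = SpotTable(
        bundle.spot_table.barcode, bundle.spot_table.in_tissue,
        bundle.spot_table.array_row, bundle.spot_table.array_col,
        bundle.spot_table.x_px * factor, bundle.spot_table.y_px * factor,
    )
    return bundle.with_(spot_table=table, image=image,
                        image_um_per_px=template_um_per_px)
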