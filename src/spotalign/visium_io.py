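"""Reading and writing Space Ranger-style sample directories.

A sample directory holds the filtered feature matrix (Matrix Market plus
barcode/feature TSVs), the tissue-positions CSV, the scale-factors JSON and a
histology image.  :func:`load_sample` assembles these into a
:class:`SampleBundle`, the portable in-memory container the rest of the
pipeline operates on; :func:`save_sample` writes the same layout back so that
simulated cohorts and real data travel through identical code paths.

Coordinate convention: 0-based pixel coordinates ``(x, y)`` with x rightward
and y downward; the positions file's ``pxl_col_in_fullres`` maps to x and
``pxl_row_in_fullres`` to y.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "SpotTable",
    "CountMatrix",
    "ScaleFactors",
    "SampleBundle",
    "load_sample",
    "save_sample",
    "um_per_pixel",
]

POSITIONS_HEADER = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


@dataclass
class SpotTable:
    """Per-spot metadata: barcode, in-tissue flag, lattice indices, pixel coords."""

    barcode: np.ndarray          # str
    in_tissue: np.ndarray        # bool
    array_row: np.ndarray        # int
    array_col: np.ndarray        # int
    x_px: np.ndarray             # float, x rightward
    y_px: np.ndarray             # float, y downward

    def __post_init__(self) -> None:
        self.barcode = np.asarray(self.barcode, dtype=object)
        self.in_tissue = np.asarray(self.in_tissue, dtype=bool)
        self.array_row = np.asarray(self.array_row, dtype=int)
        self.array_col = np.asarray(self.array_col, dtype=int)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        if len(set(self.barcode)) != self.barcode.size:
            raise ValueError("spot barcodes must be unique")
        n = self.barcode.size
        for name in ("in_tissue", "array_row", "array_col", "x_px", "y_px"):
            if getattr(self, name).size != n:
                raise ValueError(f"SpotTable field {name!r} length mismatch")

    @property
    def n_spots(self) -> int:
        return self.barcode.size

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of (x, y) pixel coordinates."""
        return np.column_stack([self.x_px, self.y_px])

    def subset(self, idx: np.ndarray) -> "SpotTable":
        return SpotTable(
            self.barcode[idx], self.in_tissue[idx], self.array_row[idx],
            self.array_col[idx], self.x_px[idx], self.y_px[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "barcode": self.barcode,
            "in_tissue": self.in_tissue.astype(int),
            "array_row": self.array_row,
            "array_col": self.array_col,
            "pxl_row_in_fullres": self.y_px,
            "pxl_col_in_fullres": self.x_px,
        })


@dataclass
class CountMatrix:
    """Genes x spots raw counts with feature annotation.

    Genes are keyed by feature ID (unique); gene symbols are carried as
    annotation and may repeat.
    """

    genes: np.ndarray            # feature IDs, unique
    spots: np.ndarray            # barcodes
    counts: sp.csr_matrix        # genes x spots, non-negative integers
    gene_symbols: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.spots = np.asarray(self.spots, dtype=object)
        self.counts = sp.csr_matrix(self.counts)
        if self.gene_symbols is None:
            self.gene_symbols = self.genes.copy()
        else:
            self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        if self.counts.shape != (self.genes.size, self.spots.size):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{self.genes.size} genes x {self.spots.size} spots"
            )
        if self.genes.size == 0:
            raise ValueError("count matrix must contain at least one gene")
        if len(set(self.genes)) != self.genes.size:
            raise ValueError("duplicate feature IDs in count matrix")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.counts.nnz and np.any(self.counts.data != np.round(self.counts.data)):
            raise ValueError("counts must be integral")

    @property
    def n_genes(self) -> int:
        return self.genes.size

    @property
    def n_spots(self) -> int:
        return self.spots.size

    def spot_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def gene_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def subset(self, gene_idx=None, spot_idx=None) -> "CountMatrix":
        g = slice(None) if gene_idx is None else gene_idx
        s = slice(None) if spot_idx is None else spot_idx
        return CountMatrix(
            self.genes[g], self.spots[s], self.counts[g][:, s],
            self.gene_symbols[g],
        )


@dataclass(frozen=True)
class ScaleFactors:
    """Spot geometry linking image pixels to physical micrometres.

    ``spot_diameter_fullres`` is the capture-spot diameter in full-resolution
    image pixels; the physical diameter (55 um) and centre-to-centre pitch
    (100 um) are platform constants overridable for simulation.
    """

    spot_diameter_fullres: float
    spot_pitch_um: float = 100.0
    spot_diameter_um: float = 55.0

    def __post_init__(self) -> None:
        for name in ("spot_diameter_fullres", "spot_pitch_um", "spot_diameter_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class SampleBundle:
    """One sample: counts, spot table, scale factors, image and group label."""

    sample_id: str
    group: str
    hemisphere: str
    spot_table: SpotTable
    counts: CountMatrix
    scale: ScaleFactors
    image: np.ndarray            # 2-D grayscale
    image_um_per_px: float

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 2:
            raise ValueError("bundle image must be 2-D grayscale")
        if self.hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")
        missing = set(self.spot_table.barcode) - set(self.counts.spots)
        if missing:
            raise ValueError(
                f"{len(missing)} spot-table barcodes absent from count matrix"
            )

    @property
    def n_spots(self) -> int:
        return self.spot_table.n_spots

    @property
    def n_genes(self) -> int:
        return self.counts.n_genes

    def counts_aligned(self) -> sp.csr_matrix:
        """Counts with columns ordered to match the spot table."""
        order = {b: i for i, b in enumerate(self.counts.spots)}
        idx = np.array([order[b] for b in self.spot_table.barcode], dtype=int)
        return self.counts.counts[:, idx]

    def with_(self, **kw) -> "SampleBundle":
        return replace(self, **kw)


def um_per_pixel(scale: ScaleFactors) -> float:
    """Micrometres per full-resolution image pixel.

    Derived from the known physical spot diameter and its measured diameter
    in pixels: ``spot_diameter_um / spot_diameter_fullres``.
    """
    if scale.spot_diameter_fullres <= 0:
        raise ValueError("spot_diameter_fullres must be positive")
    return scale.spot_diameter_um / scale.spot_diameter_fullres


def _find_one(dir_path: Path, patterns: list[str], what: str) -> Path:
    for pat in patterns:
        hits = sorted(dir_path.glob(pat))
        if hits:
            return hits[0]
    raise FileNotFoundError(
        f"no {what} file found in {dir_path} (looked for {', '.join(patterns)})"
    )


def _read_positions(path: Path) -> pd.DataFrame:
    # Sniff headered (tissue_positions.csv) vs legacy headerless dialect.
    with open(path) as fh:
        first = fh.readline()
    has_header = "barcode" in first.lower()
    df = pd.read_csv(path, header=0 if has_header else None)
    if not has_header:
        df.columns = POSITIONS_HEADER[: df.shape[1]]
    df["barcode"] = df["barcode"].astype(str)
    if (df["pxl_row_in_fullres"] < 0).any() or (df["pxl_col_in_fullres"] < 0).any():
        raise ValueError(f"negative pixel coordinates in {path}")
    return df


def load_sample(dir_path, group_label: str, hemisphere: str = "left") -> SampleBundle:
    """Load one Space Ranger-style sample directory into a :class:`SampleBundle`.

    The bundle is restricted to spots present in both the positions file and
    the count matrix (a warning is emitted when the two disagree); no other
    filtering is applied here.
    """
    dir_path = Path(dir_path)
    if not dir_path.is_dir():
        raise FileNotFoundError(f"sample directory {dir_path} does not exist")

    mtx_path = _find_one(dir_path, ["matrix.mtx", "matrix.mtx.gz"], "matrix.mtx")
    bc_path = _find_one(dir_path, ["barcodes.tsv", "barcodes.tsv.gz"], "barcodes.tsv")
    ft_path = _find_one(dir_path, ["features.tsv", "features.tsv.gz", "genes.tsv"],
                        "features.tsv")
    pos_path = _find_one(
        dir_path, ["tissue_positions.csv", "tissue_positions_list.csv"],
        "tissue positions CSV")
    sf_path = _find_one(dir_path, ["scalefactors_json.json", "scalefactors.json"],
                        "scalefactors JSON")
    img_path = _find_one(dir_path, ["*.png", "*.tif", "*.tiff"], "image")

    mat = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    barcodes = pd.read_csv(bc_path, sep="\t", header=None)[0].astype(str).to_numpy()
    feats = pd.read_csv(ft_path, sep="\t", header=None)
    gene_ids = feats[0].astype(str).to_numpy()
    gene_symbols = (feats[1] if feats.shape[1] > 1 else feats[0]).astype(str).to_numpy()
    if mat.shape != (gene_ids.size, barcodes.size):
        raise ValueError(
            f"matrix shape {mat.shape} inconsistent with {gene_ids.size} features "
            f"and {barcodes.size} barcodes in {dir_path}"
        )

    pos = _read_positions(pos_path)
    with open(sf_path) as fh:
        sf = json.load(fh)
    scale = ScaleFactors(
        spot_diameter_fullres=float(sf["spot_diameter_fullres"]),
        spot_pitch_um=float(sf.get("spot_pitch_um", 100.0)),
        spot_diameter_um=float(sf.get("spot_diameter_um", 55.0)),
    )
    image = np.asarray(iio.imread(img_path))
    if image.ndim == 3:                       # collapse RGB(A) to grayscale
        image = image[..., :3].mean(axis=2)

    pos_bc = set(pos["barcode"])
    mat_bc = set(barcodes)
    only_one = (pos_bc ^ mat_bc)
    if only_one:
        warnings.warn(
            f"{len(only_one)} barcodes present in only one of positions/matrix "
            f"for {dir_path.name}; using the intersection",
            stacklevel=2,
        )
    common = pos_bc & mat_bc
    pos = pos[pos["barcode"].isin(common)].reset_index(drop=True)
    keep = np.fromiter((b in common for b in barcodes), dtype=bool, count=barcodes.size)
    counts = CountMatrix(gene_ids, barcodes[keep], mat[:, keep], gene_symbols)

    table = SpotTable(
        pos["barcode"].to_numpy(dtype=object),
        pos["in_tissue"].to_numpy().astype(bool),
        pos["array_row"].to_numpy(),
        pos["array_col"].to_numpy(),
        pos["pxl_col_in_fullres"].to_numpy(dtype=float),
        pos["pxl_row_in_fullres"].to_numpy(dtype=float),
    )
    return SampleBundle(
        sample_id=dir_path.name,
        group=group_label,
        hemisphere=hemisphere,
        spot_table=table,
        counts=counts,
        scale=scale,
        image=image,
        image_um_per_px=um_per_pixel(scale),
    )


def save_sample(bundle: SampleBundle, dir_path) -> Path:
    """Write a bundle as the on-disk layout :func:`load_sample` reads."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)

    coo = sp.coo_matrix(bundle.counts.counts)
    scipy.io.mmwrite(str(dir_path / "matrix.mtx"), coo, field="integer")
    pd.DataFrame({0: bundle.counts.spots}).to_csv(
        dir_path / "barcodes.tsv", sep="\t", header=False, index=False)
    pd.DataFrame({
        0: bundle.counts.genes,
        1: bundle.counts.gene_symbols,
        2: ["Gene Expression"] * bundle.counts.n_genes,
    }).to_csv(dir_path / "features.tsv", sep="\t", header=False, index=False)
    bundle.spot_table.to_frame().to_csv(dir_path / "tissue_positions.csv", index=False)
    with open(dir_path / "scalefactors_json.json", "w") as fh:
        json.dump({
            "spot_diameter_fullres": bundle.scale.spot_diameter_fullres,
            "spot_pitch_um": bundle.scale.spot_pitch_um,
            "spot_diameter_um": bundle.scale.spot_diameter_um,
        }, fh)
    img = bundle.image
    if img.dtype != np.uint8:
        img = np.clip(img, 0, 255).astype(np.uint8)
    iio.imwrite(dir_path / "image.png", img)
    return dir_path
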