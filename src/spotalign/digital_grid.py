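"""Honeycomb digital-spot grid construction and cross-sample spot pooling.

Once every sample's spots sit in the template frame, a fresh hexagonal
("honeycomb") lattice of *digital spots* is laid over the template tissue
mask.  Each digital spot then collects, from every registered sample, its k
nearest sample spots within a distance cap; the pooled log2-normalized values
of those neighbours form the per-group vectors tested downstream.  Spots that
fail to attract enough neighbours from every sample (typically at tissue
edges a sample does not cover) are flagged and excluded from testing.

Defaults mirror the platform geometry scaled for registration uncertainty:
150 um spacing (vs the platform's 100 um pitch), 7 neighbours (a spot plus
its 6 hexagonal neighbours) and a 450 um cap (3 grid spacings).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "GridConfig",
    "DigitalSpotGrid",
    "generate_hex_grid",
    "assign_nearest_spots",
    "filter_digital_spots",
    "pool_expression",
    "PooledExpression",
]


@dataclass(frozen=True)
class GridConfig:
    spacing_um: float = 150.0
    k_neighbors: int = 7
    max_distance_um: float = 450.0
    min_required_per_sample: int | None = None   # None -> k_neighbors

    def __post_init__(self) -> None:
        if self.spacing_um <= 0:
            raise ValueError("spacing must be > 0")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.max_distance_um < self.spacing_um:
            raise ValueError("max_distance_um must be >= spacing_um")

    @property
    def min_required(self) -> int:
        return self.k_neighbors if self.min_required_per_sample is None \
            else self.min_required_per_sample


@dataclass
class DigitalSpotGrid:
    """Digital spot coordinates (um, template frame) plus neighbour assignments.

    ``neighbors[sample_id]`` is a list over digital spots of (indices,
    distances) pairs, sorted by (distance, spot index), at most k entries,
    all distances <= the configured cap.
    """

    coords_um: np.ndarray                       # (n, 2)
    config: GridConfig
    neighbors: dict = field(default_factory=dict)
    kept: np.ndarray | None = None              # bool per digital spot

    @property
    def n_spots(self) -> int:
        return len(self.coords_um)

    @property
    def kept_indices(self) -> np.ndarray:
        if self.kept is None:
            return np.arange(self.n_spots)
        return np.nonzero(self.kept)[0]

    def to_frame(self) -> pd.DataFrame:
        kept = self.kept if self.kept is not None \
            else np.ones(self.n_spots, dtype=bool)
        return pd.DataFrame({
            "digital_spot_id": np.arange(self.n_spots),
            "x_um": self.coords_um[:, 0],
            "y_um": self.coords_um[:, 1],
            "kept": kept.astype(int),
        })

    def assignments_frame(self) -> pd.DataFrame:
        rows = []
        for sid, per_spot in self.neighbors.items():
            for d_idx, (idx, dist) in enumerate(per_spot):
                for rank, (i, d) in enumerate(zip(idx, dist)):
                    rows.append((d_idx, sid, int(i), float(d), rank))
        return pd.DataFrame(
            rows, columns=["digital_spot_id", "sample_id", "spot_index",
                           "distance_um", "rank"])


def generate_hex_grid(mask: np.ndarray, um_per_px: float,
                      cfg: GridConfig = GridConfig()) -> np.ndarray:
    """Honeycomb lattice of digital-spot coordinates inside a binary mask.

    Rows are spaced ``spacing * sqrt(3)/2`` apart with alternate rows offset
    by half a spacing, so every interior spot has 6 equidistant nearest
    neighbours at exactly ``spacing``.  The lattice phase is anchored at the
    centroid of the mask bounding box (deterministic for a given mask), and a
    lattice point is kept iff its centre pixel lies inside the mask.
    Coordinates are returned in micrometres.
    """
    mask = np.asarray(mask) > 0
    if not mask.any():
        warnings.warn("empty mask: returning an empty digital-spot grid",
                      stacklevel=2)
        return np.empty((0, 2), dtype=float)
    s = cfg.spacing_um
    row_pitch = s * np.sqrt(3.0) / 2.0

    ys, xs = np.nonzero(mask)
    x0_px, x1_px = xs.min(), xs.max()
    y0_px, y1_px = ys.min(), ys.max()
    cx = (x0_px + x1_px) / 2.0 * um_per_px     # anchor: bbox centroid, um
    cy = (y0_px + y1_px) / 2.0 * um_per_px
    x_lo, x_hi = x0_px * um_per_px, x1_px * um_per_px
    y_lo, y_hi = y0_px * um_per_px, y1_px * um_per_px

    j_min = int(np.floor((y_lo - cy) / row_pitch))
    j_max = int(np.ceil((y_hi - cy) / row_pitch))
    pts = []
    for j in range(j_min, j_max + 1):
        y = cy + j * row_pitch
        off = (s / 2.0) if (j % 2) else 0.0
        i_min = int(np.floor((x_lo - cx - off) / s))
        i_max = int(np.ceil((x_hi - cx - off) / s))
        for i in range(i_min, i_max + 1):
            pts.append((cx + off + i * s, y))
    pts = np.asarray(pts, dtype=float)

    px = np.round(pts[:, 0] / um_per_px).astype(int)
    py = np.round(pts[:, 1] / um_per_px).astype(int)
    inside = (px >= 0) & (px < mask.shape[1]) & (py >= 0) & (py < mask.shape[0])
    inside[inside] = mask[py[inside], px[inside]]
    return pts[inside]


def assign_nearest_spots(coords_um: np.ndarray, registered_spots_um: dict,
                         cfg: GridConfig = GridConfig()) -> DigitalSpotGrid:
    """For each digital spot and sample, the k nearest sample spots <= cap.

    ``registered_spots_um`` maps sample_id -> (n, 2) template-frame spot
    coordinates in micrometres.  Ties are broken by (distance, spot index);
    fewer than k neighbours are returned when fewer are available within the
    cap.
    """
    coords_um = np.atleast_2d(np.asarray(coords_um, dtype=float))
    grid = DigitalSpotGrid(coords_um, cfg)
    for sid, pts in registered_spots_um.items():
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        if pts.shape[0] == 0:
            raise ValueError(f"sample {sid!r} has zero registered spots")
        tree = cKDTree(pts)
        k = min(cfg.k_neighbors, pts.shape[0])
        dist, idx = tree.query(coords_um, k=k,
                               distance_upper_bound=cfg.max_distance_um)
        dist = np.atleast_2d(dist.reshape(len(coords_um), k))
        idx = np.atleast_2d(idx.reshape(len(coords_um), k))
        per_spot = []
        for d_row, i_row in zip(dist, idx):
            ok = np.isfinite(d_row)
            # strict cap (query's upper bound is exclusive only at inf fill)
            ok &= d_row <= cfg.max_distance_um
            d_ok, i_ok = d_row[ok], i_row[ok]
            order = np.lexsort((i_ok, d_ok))
            per_spot.append((i_ok[order].astype(int), d_ok[order]))
        grid.neighbors[sid] = per_spot
    return grid


def filter_digital_spots(grid: DigitalSpotGrid,
                         cfg: GridConfig | None = None) -> tuple[DigitalSpotGrid, int]:
    """Flag digital spots lacking sufficient neighbours; returns (grid, n removed).

    A digital spot is kept iff every sample contributes at least
    ``min_required_per_sample`` neighbours (default: the full k).
    """
    cfg = cfg or grid.config
    if not grid.neighbors:
        raise ValueError("neighbor lists not computed; run assign_nearest_spots")
    kept = np.ones(grid.n_spots, dtype=bool)
    for per_spot in grid.neighbors.values():
        counts = np.array([len(idx) for idx, _ in per_spot])
        kept &= counts >= cfg.min_required
    grid.kept = kept
    return grid, int((~kept).sum())


@dataclass
class PooledExpression:
    """Pooled per-digital-spot expression, indexed lazily by (spot, group).

    Internally stores one genes x total-spots value matrix per sample plus the
    neighbour indices, so per-spot pooled matrices are materialised on demand
    and group-level moments can be computed vectorised.
    """

    genes: np.ndarray
    groups: dict                                 # group -> [sample_id]
    values: dict                                 # sample_id -> genes x n_spots
    neighbors: dict                              # sample_id -> per-spot indices
    kept_indices: np.ndarray

    def width(self, digital_spot: int, group: str) -> int:
        return sum(len(self.neighbors[sid][digital_spot][0])
                   for sid in self.groups[group])

    def matrix(self, digital_spot: int, group: str) -> np.ndarray:
        """genes x pooled-width matrix for one digital spot and group."""
        cols = [self.values[sid][:, self.neighbors[sid][digital_spot][0]]
                for sid in self.groups[group]]
        return np.concatenate(cols, axis=1) if cols else \
            np.empty((len(self.genes), 0))

    def group_stack(self, group: str) -> tuple[np.ndarray, np.ndarray]:
        """Concatenated values (genes x sum-of-spots) and per-kept-spot column
        index lists for a group — the vectorised access path for testing."""
        mats, offsets, off = [], {}, 0
        for sid in self.groups[group]:
            mats.append(self.values[sid])
            offsets[sid] = off
            off += self.values[sid].shape[1]
        stacked = np.concatenate(mats, axis=1)
        col_lists = []
        for d in self.kept_indices:
            cols = np.concatenate([
                self.neighbors[sid][d][0] + offsets[sid]
                for sid in self.groups[group]]) if self.groups[group] else \
                np.empty(0, dtype=int)
            col_lists.append(cols.astype(int))
        return stacked, col_lists


def pool_expression(grid: DigitalSpotGrid, normalized: dict,
                    group_of: dict) -> PooledExpression:
    """Pool each sample's normalized values into digital spots, per group.

    ``normalized`` maps sample_id -> NormalizedMatrix (all the same scheme);
    ``group_of`` maps sample_id -> group label.  The gene universe is the
    intersection of all samples' gene lists, in the order of the first sample.
    """
    if grid.kept is None:
        raise ValueError("grid must be filtered before pooling")
    sids = list(normalized)
    schemes = {normalized[s].scheme for s in sids}
    if len(schemes) > 1:
        raise ValueError(f"mixed normalization schemes: {schemes}")
    common = set(normalized[sids[0]].genes)
    for s in sids[1:]:
        common &= set(normalized[s].genes)
    if not common:
        raise ValueError("gene universe (intersection across samples) is empty")
    genes = np.array([g for g in normalized[sids[0]].genes if g in common],
                     dtype=object)

    values = {}
    for s in sids:
        nm = normalized[s]
        pos = {g: i for i, g in enumerate(nm.genes)}
        ridx = np.array([pos[g] for g in genes], dtype=int)
        values[s] = nm.values[ridx]

    groups: dict = {}
    for s in sids:
        groups.setdefault(group_of[s], []).append(s)
    return PooledExpression(
        genes=genes, groups=groups, values=values,
        neighbors=grid.neighbors, kept_indices=grid.kept_indices,
    )
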