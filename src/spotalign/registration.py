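"""Point transforms and best-fit-chained cohort registration.

Each sample's spots are carried into the template frame by a
:class:`TransformChain`.  Rather than registering every sample directly to the
template (an H&E image against an atlas raster), one high-quality "best fit"
sample is registered to the template, every other sample is registered to the
best fit (H&E against H&E), and the two transforms are composed.

Transform kinds
---------------
identity
    No-op placeholder, useful for already-aligned data and tests.
similarity
    Rotation theta (radians, counterclockwise in the x-right/y-down frame),
    isotropic scale s > 0, translation t: ``p' = s R(theta) (p - c) + c + t``
    with an optional centre c.
displacement_field
    A per-pixel (dx, dy) offset raster sampled bilinearly at query points;
    the adapter for external diffeomorphic tools (e.g. ANTs SyN), whose
    internals are deliberately not reimplemented here.  The imported field is
    interpreted in the FORWARD convention: it maps moving-frame points into
    the fixed frame, ``p' = p + D(p)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import TissueMask, compute_tissue_mask
from .visium_io import SampleBundle, SpotTable

__all__ = [
    "PointTransform",
    "Similarity",
    "Identity",
    "DisplacementField",
    "TransformChain",
    "transform_points",
    "register_pair",
    "register_cohort_best_fit",
    "mask_iou",
]


@dataclass(frozen=True)
class Identity:
    kind: str = "identity"
    domain: str = "any"
    codomain: str = "any"

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=float)

    def inverse(self) -> "Identity":
        return self


@dataclass(frozen=True)
class Similarity:
    """p' = s * R(theta) @ (p - center) + center + translation."""

    theta: float
    scale: float
    translation: tuple[float, float]
    center: tuple[float, float] = (0.0, 0.0)
    kind: str = "similarity"
    domain: str = "any"
    codomain: str = "any"

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("similarity scale must be > 0")

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.theta), np.sin(self.theta)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        ctr = np.asarray(self.center, dtype=float)
        return (pts - ctr) @ self.matrix.T + ctr + np.asarray(self.translation)

    def inverse(self) -> "Similarity":
        # p = inv_mat @ (p' - ctr - t) + ctr = inv_mat @ (p' - ctr) + ctr + inv_mat @ (-t)
        inv_mat = np.linalg.inv(self.matrix)
        ctr = np.asarray(self.center, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        return Similarity(
            theta=-self.theta, scale=1.0 / self.scale,
            translation=tuple(inv_mat @ (-t)), center=tuple(ctr),
            domain=self.codomain, codomain=self.domain,
        )


@dataclass
class DisplacementField:
    """Forward displacement raster: p' = p + D(p), bilinear interpolation.

    ``field`` has shape (H, W, 2) holding (dx, dy) offsets in the same units
    as the point coordinates.  Points outside the raster are clamped to the
    nearest edge and flagged.
    """

    field: np.ndarray
    kind: str = "displacement_field"
    domain: str = "any"
    codomain: str = "any"

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=float)
        if self.field.ndim != 3 or self.field.shape[2] != 2:
            raise ValueError("displacement field must have shape (H, W, 2)")
        if not np.isfinite(self.field).all():
            raise ValueError("displacement field must be finite everywhere")
        self.out_of_bounds: np.ndarray | None = None

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        h, w = self.field.shape[:2]
        x, y = pts[:, 0], pts[:, 1]
        oob = (x < 0) | (x > w - 1) | (y < 0) | (y > h - 1)
        if oob.any():
            import warnings
            warnings.warn(
                f"{int(oob.sum())} points outside displacement-field raster; "
                "nearest-edge extrapolation used", stacklevel=2)
        self.out_of_bounds = oob
        xc = np.clip(x, 0, w - 1)
        yc = np.clip(y, 0, h - 1)
        x0 = np.floor(xc).astype(int)
        y0 = np.floor(yc).astype(int)
        x1 = np.minimum(x0 + 1, w - 1)
        y1 = np.minimum(y0 + 1, h - 1)
        fx = xc - x0
        fy = yc - y0
        d = (self.field[y0, x0] * ((1 - fx) * (1 - fy))[:, None]
             + self.field[y0, x1] * (fx * (1 - fy))[:, None]
             + self.field[y1, x0] * ((1 - fx) * fy)[:, None]
             + self.field[y1, x1] * (fx * fy)[:, None])
        return pts + d


PointTransform = Identity | Similarity | DisplacementField


@dataclass
class TransformChain:
    """Ordered composition of point transforms, applied first-to-last."""

    transforms: list
    source: str = ""
    target: str = "template"

    def __post_init__(self) -> None:
        for a, b in zip(self.transforms, self.transforms[1:]):
            if a.codomain != "any" and b.domain != "any" and a.codomain != b.domain:
                raise ValueError(
                    f"incompatible chain frames: {a.codomain!r} -> {b.domain!r}")

    def __len__(self) -> int:
        return len(self.transforms)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        out = np.atleast_2d(np.asarray(pts, dtype=float))
        for t in self.transforms:
            out = t.apply(out)
        return out


def transform_points(t, points: np.ndarray) -> np.ndarray:
    """Apply a transform or chain to an (n, 2) array of (x, y) points."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.isfinite(points).all():
        raise ValueError("points must be finite")
    return t.apply(points)


def _mask_moments(mask: np.ndarray):
    """Centroid, principal-axis angle and area of a binary mask."""
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise ValueError("empty mask")
    cx, cy = xs.mean(), ys.mean()
    dx, dy = xs - cx, ys - cy
    cov = np.array([[np.mean(dx * dx), np.mean(dx * dy)],
                    [np.mean(dx * dy), np.mean(dy * dy)]])
    # orientation of the major axis
    angle = 0.5 * np.arctan2(2 * cov[0, 1], cov[0, 0] - cov[1, 1])
    return (cx, cy), angle, xs.size


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a) > 0
    b = np.asarray(b) > 0
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def _warp_mask(mask: np.ndarray, t: Similarity, out_shape) -> np.ndarray:
    """Nearest-neighbour warp of a binary mask under a similarity (for scoring)."""
    h, w = out_shape
    inv = t.inverse()
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    src = inv.apply(pts)
    sx = np.round(src[:, 0]).astype(int)
    sy = np.round(src[:, 1]).astype(int)
    ok = (sx >= 0) & (sx < mask.shape[1]) & (sy >= 0) & (sy < mask.shape[0])
    out = np.zeros(h * w, dtype=np.uint8)
    out[ok] = mask[sy[ok], sx[ok]]
    return out.reshape(h, w)


def _moments_backend(moving_mask: np.ndarray, fixed_mask: np.ndarray) -> Similarity:
    (mcx, mcy), mang, marea = _mask_moments(moving_mask)
    (fcx, fcy), fang, farea = _mask_moments(fixed_mask)
    scale = float(np.sqrt(farea / marea))
    best = None
    # principal axis has a 180-degree ambiguity: score both candidates
    for dtheta in (fang - mang, fang - mang + np.pi):
        cand = Similarity(
            theta=float(np.arctan2(np.sin(dtheta), np.cos(dtheta))),
            scale=scale,
            translation=(fcx - mcx, fcy - mcy),
            center=(mcx, mcy),
        )
        warped = _warp_mask(moving_mask, cand, fixed_mask.shape)
        score = mask_iou(warped, fixed_mask)
        if best is None or score > best[0]:
            best = (score, cand)
    return best[1]


def _landmarks_backend(moving_pts: np.ndarray, fixed_pts: np.ndarray) -> Similarity:
    """Least-squares similarity from >= 2 point pairs (Umeyama)."""
    moving_pts = np.asarray(moving_pts, dtype=float)
    fixed_pts = np.asarray(fixed_pts, dtype=float)
    if moving_pts.shape[0] < 2 or moving_pts.shape != fixed_pts.shape:
        raise ValueError("landmarks backend needs >= 2 matched point pairs")
    mu_m = moving_pts.mean(axis=0)
    mu_f = fixed_pts.mean(axis=0)
    dm = moving_pts - mu_m
    df = fixed_pts - mu_f
    cov = df.T @ dm / moving_pts.shape[0]
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    diag = np.diag([1.0, d])
    rot = u @ diag @ vt
    var_m = (dm ** 2).sum() / moving_pts.shape[0]
    scale = float(np.trace(np.diag(s) @ diag) / var_m)
    theta = float(np.arctan2(rot[1, 0], rot[0, 0]))
    t = mu_f - scale * rot @ mu_m
    return Similarity(theta=theta, scale=scale, translation=tuple(t))


def register_pair(moving, fixed_image, fixed_mask=None, backend: str = "moments",
                  *, moving_mask=None, landmarks=None, displacement_field=None,
                  template_um_per_px: float = 10.0):
    """Estimate a transform carrying the moving sample into the fixed frame.

    backend="moments": similarity from mask centroids, principal-axis
    orientation and the square root of the area ratio (the 180-degree axis
    ambiguity is resolved by mask overlap).  backend="landmarks":
    least-squares similarity from user-supplied matched point pairs.
    backend="external": wraps a displacement-field raster produced by an
    external diffeomorphic tool (forward convention, see module docstring).
    """
    if backend == "external":
        if displacement_field is None:
            raise ValueError("external backend requires displacement_field")
        return DisplacementField(displacement_field)
    if backend == "landmarks":
        if landmarks is None:
            raise ValueError("landmarks backend requires landmarks=(moving, fixed)")
        return _landmarks_backend(*landmarks)
    if backend != "moments":
        raise ValueError(f"unknown backend {backend!r}")

    if moving_mask is None:
        if isinstance(moving, SampleBundle):
            moving_mask = compute_tissue_mask(
                moving.image, moving.image_um_per_px).mask
        else:
            moving_mask = np.asarray(moving) > 0
    elif isinstance(moving_mask, TissueMask):
        moving_mask = moving_mask.mask
    if fixed_mask is None:
        raise ValueError("moments backend requires a fixed mask")
    if isinstance(fixed_mask, TissueMask):
        fixed_mask = fixed_mask.mask
    fixed_mask = np.asarray(fixed_mask) > 0
    moving_mask = np.asarray(moving_mask) > 0
    if not moving_mask.any() or not fixed_mask.any():
        raise ValueError("empty mask passed to register_pair")
    return _moments_backend(moving_mask, fixed_mask)


def register_cohort_best_fit(bundles: dict, template_image, template_mask,
                             best_fit_id: str, backend: str = "moments",
                             template_um_per_px: float = 10.0) -> dict:
    """Register a cohort through a best-fit sample.

    The best-fit sample gets the one-step chain [bestfit -> template]; every
    other sample gets [sample -> bestfit, bestfit -> template].  Right-
    hemisphere samples are expected to have been mirrored into left-hemisphere
    space beforehand (see preprocess.orient_sample).
    """
    if best_fit_id not in bundles:
        raise ValueError(f"best_fit_id {best_fit_id!r} not among samples")
    if isinstance(template_mask, TissueMask):
        template_mask = template_mask.mask

    masks = {}
    for sid, b in bundles.items():
        masks[sid] = compute_tissue_mask(b.image, b.image_um_per_px).mask

    best = bundles[best_fit_id]
    try:
        best_to_template = register_pair(
            best, template_image, template_mask, backend,
            moving_mask=masks[best_fit_id])
    except Exception as exc:
        raise RuntimeError(
            f"registration failed for pair ({best_fit_id} -> template): {exc}"
        ) from exc
    best_to_template = _set_frames(best_to_template, best_fit_id, "template")

    chains = {best_fit_id: TransformChain([best_to_template],
                                          source=best_fit_id, target="template")}
    for sid, b in bundles.items():
        if sid == best_fit_id:
            continue
        try:
            t = register_pair(b, best.image, masks[best_fit_id], backend,
                              moving_mask=masks[sid])
        except Exception as exc:
            raise RuntimeError(
                f"registration failed for pair ({sid} -> {best_fit_id}): {exc}"
            ) from exc
        t = _set_frames(t, sid, best_fit_id)
        chains[sid] = TransformChain([t, best_to_template],
                                     source=sid, target="template")
    return chains


def _set_frames(t, domain: str, codomain: str):
    if isinstance(t, (Identity, Similarity)):
        from dataclasses import replace
        return replace(t, domain=domain, codomain=codomain)
    t.domain = domain
    t.codomain = codomain
    return t


def apply_chain_to_bundle(bundle: SampleBundle, chain: TransformChain) -> SampleBundle:
    """Return a bundle whose spot coordinates live in the chain's target frame.

    Expression values are untouched: registration only moves coordinates.
    """
    pts = chain.apply(bundle.spot_table.xy)
    table = SpotTable(
        bundle.spot_table.barcode, bundle.spot_table.in_tissue,
        bundle.spot_table.array_row, bundle.spot_table.array_col,
        pts[:, 0], pts[:, 1],
    )
    return bundle.with_(spot_table=table)
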