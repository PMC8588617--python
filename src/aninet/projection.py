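"""Depth-image rendering from normalized skull point clouds.

Two projections are provided.  The *local* (planar) projection drops the
cloud orthographically onto a plane tangent to one of three faces of the
skull — front (min y), left (min x), bottom (min z) — and rasterizes the
point-to-plane distance onto a square grid covering the in-plane bounding
box plus a margin.  The *global* (cylindrical) projection surrounds the
skull with a cylinder of radius rho = 1.3 and height h = 3 coaxial with
the Frankfurt z-axis, projects each point A radially onto the cylinder at
P = (rho cos(theta), rho sin(theta), z) and stores the distance
L = rho - sqrt(x^2 + y^2) at pixel

    i = floor((z + h/2) * H / h),   j = floor(theta * W / 360),

with theta measured counterclockwise (seen from +z) from the start ray,
the half-plane of xoz with x < 0.  Both projections keep the minimum
distance per pixel (a z-buffer selecting the outer surface) and carry a
hit-mask so background pixels stay distinguishable from true zero depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .io import PointCloud


class ProjectionError(ValueError):
    pass


@dataclass
class DepthImage:
    """H x W nonnegative depth raster plus hit-mask and provenance.

    ``values`` at background (never-hit) pixels are 0 before normalization
    and are identified by ``mask == False``; after :func:`normalize_intensity`
    hit values lie in [0, 1] and background is filled with 1 (max depth).
    """

    values: np.ndarray
    mask: np.ndarray
    kind: str  # front | left | bottom | global
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("DepthImage values must be 2-D")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values shape")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("depth values must be finite")
        if self.values.size and self.values.min() < 0:
            raise ValueError("depth values must be nonnegative")
        if self.normalized and self.values.size and self.values.max() > 1.0 + 1e-12:
            raise ValueError("normalized depth values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class PlanarProjectionSpec:
    """Tangent-plane view configuration (400 x 400 raster by default)."""

    view: str = "front"
    resolution: int = 400
    margin_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.view not in ("front", "left", "bottom"):
            raise ValueError(f"unknown view {self.view!r}")
        if self.resolution < 16:
            raise ValueError("resolution must be >= 16")
        if self.margin_fraction < 0:
            raise ValueError("margin_fraction must be >= 0")


@dataclass
class CylinderSpec:
    """Global-projection cylinder (rho = 1.3, h = 3) and raster size."""

    rho: float = 1.3
    h: float = 3.0
    H: int = 301
    W: int = 629

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.h <= 0:
            raise ValueError("rho and h must be positive")
        if self.H < 2 or self.W < 2:
            raise ValueError("raster must be at least 2 x 2")


# (depth axis, in-plane axes) per view; the tangent plane sits at the
# minimum of the depth axis so depth = coordinate - min >= 0.
_VIEW_AXES = {"front": (1, (0, 2)), "left": (0, (1, 2)), "bottom": (2, (0, 1))}


def project_planar(cloud: PointCloud, spec: PlanarProjectionSpec | None = None) -> DepthImage:
    """Orthographic min-depth projection onto a tangent plane.

    The raster's rows run along the second in-plane axis (vertical for the
    front/left views) with row 0 at its minimum, columns along the first.
    """
    spec = spec or PlanarProjectionSpec()
    pts = cloud.points
    if pts.shape[0] < 4:
        raise ProjectionError("need at least 4 points to project")
    depth_ax, (u_ax, v_ax) = _VIEW_AXES[spec.view]
    depth = pts[:, depth_ax] - pts[:, depth_ax].min()
    u, v = pts[:, u_ax], pts[:, v_ax]

    res = spec.resolution
    umin, umax = u.min(), u.max()
    vmin, vmax = v.min(), v.max()
    span = max(umax - umin, vmax - vmin, 1e-12)
    half = span * (1 + 2 * spec.margin_fraction) / 2
    uc, vc = (umin + umax) / 2, (vmin + vmax) / 2
    # square extent centred on the bounding box so pixels stay isotropic
    cols = np.clip(((u - (uc - half)) / (2 * half) * res).astype(int), 0, res - 1)
    rows = np.clip(((v - (vc - half)) / (2 * half) * res).astype(int), 0, res - 1)

    values = np.full((res, res), np.inf)
    np.minimum.at(values, (rows, cols), depth)
    mask = np.isfinite(values)
    values[~mask] = 0.0
    return DepthImage(
        values=values,
        mask=mask,
        kind=spec.view,
        meta={"extent": (uc - half, uc + half, vc - half, vc + half)},
    )


def project_cylindrical(cloud: PointCloud, spec: CylinderSpec | None = None) -> DepthImage:
    """Unroll the skull onto a surrounding cylinder as a panoramic depth map.

    Points outside the cylinder (radius > rho or |z| > h/2) are skipped;
    the count is reported in ``meta['n_skipped']``.  Row i = 0 is the
    bottom of the cylinder (z = -h/2), column j = 0 the start ray.
    """
    spec = spec or CylinderSpec()
    pts = cloud.points
    r = np.hypot(pts[:, 0], pts[:, 1])
    z = pts[:, 2]
    keep = (r <= spec.rho) & (np.abs(z) <= spec.h / 2)
    n_skipped = int((~keep).sum())
    if not keep.any():
        raise ProjectionError("every point lies outside the projection cylinder")
    x, y, z, r = pts[keep, 0], pts[keep, 1], pts[keep, 2], r[keep]

    # angle from the start ray (-1, 0), counterclockwise viewed from +z
    theta = np.degrees(np.arctan2(y, x) - np.pi) % 360.0
    L = spec.rho - r
    i = np.clip(np.floor((z + spec.h / 2) * spec.H / spec.h).astype(int), 0, spec.H - 1)
    j = np.clip(np.floor(theta * spec.W / 360.0).astype(int), 0, spec.W - 1)

    values = np.full((spec.H, spec.W), np.inf)
    np.minimum.at(values, (i, j), L)
    mask = np.isfinite(values)
    values[~mask] = 0.0
    return DepthImage(
        values=values, mask=mask, kind="global", meta={"n_skipped": n_skipped}
    )


def smooth(img: DepthImage, sigma: float = 1.0) -> DepthImage:
    """Gaussian-smooth a depth image into a dense surface-depth field.

    A rasterized point cloud hits only scattered pixels; before filtering,
    every background pixel is filled with the value of its nearest hit
    pixel, so the blur interpolates the surface instead of bleeding a
    background sentinel into it.  The output is dense: its mask is all
    true, because after in-filling every pixel carries a surface estimate.
    A constant image is a fixed point.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if not img.mask.any():
        raise ProjectionError("cannot smooth an image with no hit pixels")
    values = img.values.copy()
    if not img.mask.all():
        # indices of the nearest hit pixel for every background pixel
        _, (ii, jj) = ndimage.distance_transform_edt(~img.mask, return_indices=True)
        values = values[ii, jj]
    if sigma > 0:
        values = ndimage.gaussian_filter(values, sigma=sigma)
    values = np.maximum(values, 0.0)
    return replace(img, values=values, mask=np.ones_like(img.mask))


def normalize_intensity(img: DepthImage) -> DepthImage:
    """Affinely map hit-pixel values onto [0, 1]; background becomes 1.

    A constant image maps to all zeros (on hit pixels).  Background is
    filled with 1.0 — maximum depth, i.e. "farthest" — so empty space
    renders dark under the darker-is-farther display convention.
    """
    if not img.mask.any():
        raise ProjectionError("cannot normalize an image with no hit pixels")
    hit = img.values[img.mask]
    lo, hi = hit.min(), hit.max()
    values = np.ones_like(img.values)
    if hi > lo:
        values[img.mask] = (img.values[img.mask] - lo) / (hi - lo)
    else:
        values[img.mask] = 0.0
    return replace(img, values=values, mask=img.mask.copy(), normalized=True)


def resize_local(img: DepthImage, side: int = 160) -> DepthImage:
    """Bilinearly resample a square local view to side x side."""
    h, w = img.shape
    if h != w:
        raise ValueError(f"local projections must be square, got {h} x {w}")
    if (h, w) == (side, side):
        return replace(img, values=img.values.copy(), mask=img.mask.copy())
    values = _sk_resize(img.values, (side, side), order=1, anti_aliasing=side < h,
                        preserve_range=True)
    mask = _sk_resize(img.mask.astype(float), (side, side), order=1,
                      anti_aliasing=False, preserve_range=True) > 0.5
    return replace(img, values=np.clip(values, 0.0, 1.0 if img.normalized else np.inf),
                   mask=mask)


def resize_global(img: DepthImage, side: int = 160) -> DepthImage:
    """Aspect-preserving resize + symmetric zero-pad to side x side.

    The long side scales to ``side``, the short side proportionally
    (rounded); the short dimension is centred with an odd remainder's
    extra row/column at the high-index side.  Padding is exactly 0.
    """
    h, w = img.shape
    if h >= w:
        nh, nw = side, max(1, round(w * side / h))
    else:
        nh, nw = max(1, round(h * side / w)), side
    values = _sk_resize(img.values, (nh, nw), order=1, anti_aliasing=(nh < h or nw < w),
                        preserve_range=True)
    values = np.clip(values, 0.0, 1.0 if img.normalized else np.inf)
    mask = _sk_resize(img.mask.astype(float), (nh, nw), order=1,
                      anti_aliasing=False, preserve_range=True) > 0.5
    pad_h, pad_w = side - nh, side - nw
    pad = ((pad_h // 2, pad_h - pad_h // 2), (pad_w // 2, pad_w - pad_w // 2))
    out_values = np.pad(values, pad, constant_values=0.0)
    out_mask = np.pad(mask, pad, constant_values=False)
    meta = dict(img.meta, content_shape=(nh, nw))
    return DepthImage(values=out_values, mask=out_mask, kind=img.kind,
                      normalized=img.normalized, meta=meta)


def fuse_channels(
    local_imgs: Sequence[DepthImage] | None, global_img: DepthImage | None
) -> np.ndarray:
    """Stack normalized views into an H x W x C input tensor.

    Channel order is fixed: [front, left, bottom, global].  Three locals
    alone give 3 channels, the global alone 1, all four together 4.
    """
    imgs: list[DepthImage] = []
    if local_imgs is not None:
        if len(local_imgs) != 3:
            raise ValueError("local_imgs must be the three views [front, left, bottom]")
        order = {"front": 0, "left": 1, "bottom": 2}
        kinds = [im.kind for im in local_imgs]
        if sorted(kinds, key=order.get) != ["front", "left", "bottom"]:
            raise ValueError(f"local views must be front/left/bottom, got {kinds}")
        imgs.extend(sorted(local_imgs, key=lambda im: order[im.kind]))
    if global_img is not None:
        imgs.append(global_img)
    if not imgs:
        raise ValueError("provide local views, a global view, or both")
    shape = imgs[0].shape
    if shape[0] != shape[1]:
        raise ValueError("fused inputs must be square")
    for im in imgs:
        if im.shape != shape:
            raise ValueError(f"shape mismatch: {im.shape} vs {shape}")
        if not im.normalized:
            raise ValueError("fuse_channels requires normalized images")
    return np.stack([im.values for im in imgs], axis=-1)
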