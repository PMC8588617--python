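import numpy as np
import pytest

from aninet import (
    CylinderSpec,
    PlanarProjectionSpec,
    PointCloud,
    fuse_channels,
    normalize_intensity,
    project_cylindrical,
    project_planar,
    resize_global,
    resize_local,
    smooth,
)
from aninet.projection import DepthImage, ProjectionError


def make_image(values, normalized=False, kind="front", mask=None):
    values = np.asarray(values, dtype=float)
    mask = np.ones_like(values, dtype=bool) if mask is None else mask
    return DepthImage(values=values, mask=mask, kind=kind, normalized=normalized)


# ---------------------------------------------------------------- planar

def test_planar_tangent_point_has_zero_depth():
    # the point on the tangent plane (min y for the front view) reads depth 0
    pts = np.array([[0.0, 0.0, 0.0], [0.3, 1.0, 0.1], [-0.4, 0.8, -0.2],
                    [0.1, 0.5, 0.4]])
    img = project_planar(PointCloud(points=pts), PlanarProjectionSpec(resolution=16))
    # locate the pixel of the tangent point: depth 0 must be present
    assert img.values[img.mask].min() == 0.0


def test_planar_min_rule_same_pixel():
    # two points in the same pixel at distances 0.2 and 0.7 -> 0.2 survives
    pts = np.array([[0.0, 0.0, 0.0],  # tangent point fixes the plane at y=0
                    [0.5, 0.2, 0.5], [0.5, 0.7, 0.5],
                    [1.0, 1.0, 1.0]])
    img = project_planar(PointCloud(points=pts), PlanarProjectionSpec(resolution=16))
    hit_values = sorted(img.values[img.mask])
    assert 0.2 in hit_values
    assert 0.7 not in hit_values


def test_planar_cube_front_view_brute_force(rng):
    # oracle: per-pixel minimum over points computed by an independent loop
    n = 30_000
    # axis-aligned unit cube surface sample (all six faces)
    face = rng.integers(0, 6, size=n)
    uv = rng.uniform(0, 1, size=(n, 2))
    pts = np.empty((n, 3))
    for k in range(n):
        u, v = uv[k]
        f = face[k]
        axis, val = divmod(f, 2)
        coords = [u, v]
        coords.insert(axis, float(val))
        pts[k] = coords
    spec = PlanarProjectionSpec(view="front", resolution=32, margin_fraction=0.05)
    img = project_planar(PointCloud(points=pts), spec)
    # independent rasterization
    depth = pts[:, 1] - pts[:, 1].min()
    u, v = pts[:, 0], pts[:, 2]
    span = max(u.max() - u.min(), v.max() - v.min())
    half = span * 1.1 / 2
    uc, vc = (u.min() + u.max()) / 2, (v.min() + v.max()) / 2
    expected = np.full((32, 32), np.inf)
    for k in range(n):
        col = min(max(int((u[k] - (uc - half)) / (2 * half) * 32), 0), 31)
        row = min(max(int((v[k] - (vc - half)) / (2 * half) * 32), 0), 31)
        expected[row, col] = min(expected[row, col], depth[k])
    hit = np.isfinite(expected)
    assert np.array_equal(hit, img.mask)
    assert np.allclose(img.values[hit], expected[hit])
    # near face occludes the far face: most hit pixels read depth ~0
    interior = img.values[hit]
    assert np.quantile(interior, 0.8) < 0.05


def test_planar_permutation_and_duplication_invariance(rng, canonical_skull):
    cloud, _ = canonical_skull
    spec = PlanarProjectionSpec(resolution=64)
    base = project_planar(cloud, spec)
    perm = rng.permutation(cloud.n_points)
    shuffled = project_planar(PointCloud(points=cloud.points[perm]), spec)
    assert np.array_equal(base.values, shuffled.values)
    dup = project_planar(
        PointCloud(points=np.vstack([cloud.points, cloud.points[:100]])), spec)
    assert np.array_equal(base.values, dup.values)


# ------------------------------------------------------------ cylindrical

def test_cylindrical_hand_example():
    # (-0.8, 0, 0) with defaults: theta=0 -> j=0, i=floor(1.5*301/3)=150, L=0.5
    pts = np.array([[-0.8, 0.0, 0.0],
                    [0.5, 0.5, 1.0], [0.0, -0.6, -1.0], [0.3, 0.1, 0.5]])
    img = project_cylindrical(PointCloud(points=pts), CylinderSpec())
    assert img.mask[150, 0]
    assert img.values[150, 0] == pytest.approx(0.5)


def test_cylindrical_zero_depth_on_surface():
    pts = np.array([[1.3, 0.0, 0.2],
                    [0.5, 0.5, 1.0], [0.0, -0.6, -1.0], [0.3, 0.1, 0.5]])
    img = project_cylindrical(PointCloud(points=pts), CylinderSpec())
    assert img.values[img.mask].min() == pytest.approx(0.0)


def test_cylindrical_lower_corner():
    # z = -h/2 on the start ray maps to pixel (0, 0)
    pts = np.array([[-0.5, 0.0, -1.5],
                    [0.5, 0.5, 1.0], [0.0, -0.6, -1.0], [0.3, 0.1, 0.5]])
    img = project_cylindrical(PointCloud(points=pts), CylinderSpec())
    assert img.mask[0, 0]


def test_cylindrical_skips_and_reports_outside_points():
    pts = np.array([[2.0, 0.0, 0.0], [0.0, 0.0, 5.0],
                    [-0.5, 0.0, 0.0], [0.3, 0.1, 0.5]])
    img = project_cylindrical(PointCloud(points=pts), CylinderSpec())
    assert img.meta["n_skipped"] == 2


def test_cylindrical_all_skipped_is_error():
    pts = np.full((4, 3), 5.0)
    with pytest.raises(ProjectionError):
        project_cylindrical(PointCloud(points=pts), CylinderSpec())


def _sphere_sample(r, n, rng):
    d = rng.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return d * r


def sphere_projection_error(img, r, spec):
    """Max deviation of hit pixels from the analytic sphere depth.

    Each row of the panorama covers a z-interval; the analytic depth
    rho - sqrt(r^2 - z^2) over that interval spans a range, and the pixel
    value (a min z-buffer over the sampled points) must fall inside it, so
    the error is the distance from the value to the interval.
    """
    rows, cols = np.nonzero(img.mask)
    z_lo = rows * spec.h / spec.H - spec.h / 2
    z_hi = z_lo + spec.h / spec.H

    def depth(z):
        zc = np.clip(np.abs(z), 0, r)
        return spec.rho - np.sqrt(np.maximum(r**2 - zc**2, 0.0))

    d_lo = np.minimum(depth(z_lo), depth(z_hi))
    d_hi = np.maximum(depth(z_lo), depth(z_hi))
    # a row whose interval reaches the pole (|z| = r) can read depth up to rho
    d_hi[(z_lo < -r + 1e-12) | (z_hi > r - 1e-12)] = spec.rho
    v = img.values[rows, cols]
    return float(np.maximum(np.maximum(d_lo - v, v - d_hi), 0.0).max())


def test_cylindrical_sphere_analytic_oracle(rng):
    # hit pixels of a dense sphere sample match rho - sqrt(r^2 - z^2)
    r, spec = 0.8, CylinderSpec()
    cloud = PointCloud(points=_sphere_sample(r, 200_000, rng))
    img = project_cylindrical(cloud, spec)
    tol = 3 * max(spec.rho * 2 * np.pi / spec.W, spec.h / spec.H)
    assert sphere_projection_error(img, r, spec) <= tol


def test_cylindrical_rotation_equivariance(rng):
    # rotating about z by d_theta shifts columns by round(d_theta * W / 360);
    # a pitch-aligned angle makes the shift exact, free of rebinning noise
    spec = CylinderSpec()
    cloud = PointCloud(points=_sphere_sample(0.8, 150_000, rng)
                       * np.array([1.0, 0.8, 1.2]))
    shift = 65
    a = np.radians(shift * 360.0 / spec.W)
    R = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
    img0 = project_cylindrical(cloud, spec)
    img1 = project_cylindrical(PointCloud(points=cloud.points @ R.T), spec)
    rolled_mask = np.roll(img0.mask, shift, axis=1)
    assert np.mean(rolled_mask == img1.mask) >= 0.99
    both = rolled_mask & img1.mask
    rolled_values = np.roll(img0.values, shift, axis=1)
    assert np.max(np.abs(rolled_values[both] - img1.values[both])) <= 1e-9


def test_cylindrical_indices_in_bounds(rng):
    spec = CylinderSpec(H=19, W=23)
    pts = rng.uniform(-1, 1, size=(5000, 3)) * np.array([1.3, 1.3, 1.5])
    img = project_cylindrical(PointCloud(points=pts), spec)
    assert img.shape == (19, 23)  # all emitted indices fit the raster


# ------------------------------------------------------- smooth/normalize

def test_smooth_constant_fixed_point():
    img = make_image(np.full((12, 12), 0.4))
    out = smooth(img, sigma=2.0)
    assert np.allclose(out.values, 0.4)


def test_smooth_sigma_zero_identity_on_hits():
    mask = np.zeros((8, 8), bool)
    mask[2, 3] = mask[5, 6] = True
    values = np.zeros((8, 8))
    values[2, 3], values[5, 6] = 0.7, 0.2
    out = smooth(make_image(values, mask=mask), sigma=0.0)
    assert out.values[2, 3] == 0.7 and out.values[5, 6] == 0.2
    assert out.mask.all()  # in-filled field is dense


def test_smooth_mass_preservation_interior(rng):
    # oracle: a Gaussian kernel preserves total mass away from boundaries
    values = np.zeros((41, 41))
    values[20, 20] = 1.0
    out = smooth(make_image(values), sigma=1.0)
    assert out.values.sum() == pytest.approx(1.0, abs=1e-6)


def test_smooth_negative_sigma_rejected():
    with pytest.raises(ValueError):
        smooth(make_image(np.zeros((4, 4))), sigma=-1.0)


def test_normalize_intensity_affine_map():
    img = make_image(np.array([[0.0, 5.0], [10.0, 5.0]]))
    out = normalize_intensity(img)
    assert np.allclose(out.values, [[0.0, 0.5], [1.0, 0.5]])
    assert out.normalized


def test_normalize_intensity_constant_to_zero():
    out = normalize_intensity(make_image(np.full((4, 4), 3.0)))
    assert np.all(out.values == 0.0)


def test_normalize_intensity_extrema(rng):
    out = normalize_intensity(make_image(rng.uniform(2, 9, size=(16, 16))))
    assert out.values.min() == pytest.approx(0.0)
    assert out.values.max() == pytest.approx(1.0)


def test_normalize_intensity_background_fills_max():
    mask = np.zeros((4, 4), bool)
    mask[0, 0] = mask[1, 1] = True
    values = np.zeros((4, 4))
    values[0, 0], values[1, 1] = 1.0, 3.0
    out = normalize_intensity(make_image(values, mask=mask))
    assert out.values[2, 2] == 1.0  # background renders as max depth


# ------------------------------------------------------------- resizing

def test_resize_local_constant_preserved():
    out = resize_local(make_image(np.full((400, 400), 0.7), normalized=True), side=160)
    assert out.shape == (160, 160)
    assert np.allclose(out.values, 0.7, atol=1e-6)


def test_resize_local_checkerboard_mean(rng):
    board = np.indices((320, 320)).sum(axis=0) % 2 * 1.0
    out = resize_local(make_image(board, normalized=True), side=160)
    assert out.values.mean() == pytest.approx(board.mean(), rel=0.02)


def test_resize_local_identity_and_contract():
    img = make_image(np.zeros((160, 160)), normalized=True)
    out = resize_local(img, side=160)
    assert np.array_equal(out.values, img.values)
    with pytest.raises(ValueError, match="square"):
        resize_local(make_image(np.zeros((100, 200)), normalized=True))


def test_resize_global_aspect_and_padding(rng):
    # 301 x 629 image: long side 629 -> 160, short 301 -> 77, pad rows 41/42
    img = make_image(rng.uniform(0.1, 1.0, size=(301, 629)), normalized=True,
                     kind="global")
    out = resize_global(img, side=160)
    assert out.shape == (160, 160)
    assert out.meta["content_shape"] == (77, 160)
    assert np.all(out.values[:41] == 0.0)
    assert np.all(out.values[-42:] == 0.0)
    assert out.values[41:-42].min() > 0.0


def test_resize_global_square_no_padding(rng):
    img = make_image(rng.uniform(0.1, 1, size=(64, 64)), normalized=True,
                     kind="global")
    out = resize_global(img, side=160)
    assert out.meta["content_shape"] == (160, 160)
    assert out.values.min() > 0.0


# ---------------------------------------------------------------- fusion

def _norm_img(kind, side=32):
    return make_image(np.full((side, side), 0.5), normalized=True, kind=kind)


def test_fuse_channel_orders_and_counts():
    locals_ = [_norm_img("front"), _norm_img("left"), _norm_img("bottom")]
    both = fuse_channels(locals_, _norm_img("global"))
    assert both.shape == (32, 32, 4)
    assert fuse_channels(locals_, None).shape == (32, 32, 3)
    assert fuse_channels(None, _norm_img("global")).shape == (32, 32, 1)


def test_fuse_fixed_channel_order():
    vals = {k: i / 10 for i, k in enumerate(["front", "left", "bottom", "global"])}
    imgs = {k: make_image(np.full((8, 8), v), normalized=True, kind=k)
            for k, v in vals.items()}
    # pass locals out of order; fusion must sort to [front, left, bottom, global]
    out = fuse_channels([imgs["bottom"], imgs["front"], imgs["left"]], imgs["global"])
    assert np.allclose(out[0, 0], [0.0, 0.1, 0.2, 0.3])


def test_fuse_contract_errors():
    with pytest.raises(ValueError):
        fuse_channels(None, None)
    with pytest.raises(ValueError, match="mismatch"):
        fuse_channels([_norm_img("front"), _norm_img("left"), _norm_img("bottom")],
                      _norm_img("global", side=16))
    with pytest.raises(ValueError, match="normalized"):
        fuse_channels(None, make_image(np.zeros((8, 8)), kind="global"))
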