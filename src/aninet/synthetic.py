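"""Synthetic skull-proxy generator for end-to-end pipeline testing.

Real cranial CT data are restricted, so the pipeline is exercised on
procedurally generated closed surfaces: a superellipsoid (exponent 2.5,
which gives a rounded-box, vaguely neurocranial silhouette) with
half-widths ~ (70, 90, 60) mm (lateral, antero-posterior, vertical), a
Gaussian "nasal" bump on the front midline, isotropic coordinate noise,
and a random rigid transform standing in for arbitrary scanner pose.
Landmarks are placed analytically on the undeformed surface — porions at
the lateral extremes, glabella on the front midline, orbitale below the
front-left orbit — and move with the cloud.

The two classes differ only in the cranial index (breadth/length ratio):
a class-dependent multiplier m scales the lateral axis by sqrt(m) and the
antero-posterior axis by 1/sqrt(m), so the effect size is a pure shape
difference at constant volume, the classical ancestry-informative signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .io import LandmarkSet, PointCloud


@dataclass
class SkullShapeParams:
    """Generator configuration (lengths in mm)."""

    semi_axes: tuple[float, float, float] = (70.0, 90.0, 60.0)
    cranial_index_shift: float = 1.0  # multiplier on breadth/length
    nose_bump_amplitude: float = 0.08  # fraction of local radius
    noise_sd: float = 0.5
    n_points: int = 3000
    exponent: float = 2.5
    rigid_pose: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi-axes must be positive")
        if self.cranial_index_shift <= 0:
            raise ValueError("cranial_index_shift must be positive")
        if self.n_points < 500:
            raise ValueError("n_points must be >= 500")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _surface_radius(dirs: np.ndarray, axes: tuple[float, float, float], e: float
                    ) -> np.ndarray:
    """Distance from origin to the superellipsoid along unit directions."""
    a, b, c = axes
    t = (np.abs(dirs[:, 0] / a) ** e + np.abs(dirs[:, 1] / b) ** e
         + np.abs(dirs[:, 2] / c) ** e)
    return t ** (-1.0 / e)


def _sample_surface(params: SkullShapeParams, rng: np.random.Generator) -> np.ndarray:
    dirs = rng.normal(size=(params.n_points, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    a, b, c = params.semi_axes
    m = params.cranial_index_shift
    axes = (a * np.sqrt(m), b / np.sqrt(m), c)
    r = _surface_radius(dirs, axes, params.exponent)
    if params.nose_bump_amplitude:
        # radial protrusion centred on the front midline (+y), just below equator
        bump_dir = np.array([0.0, 1.0, -0.15])
        bump_dir /= np.linalg.norm(bump_dir)
        cosang = np.clip(dirs @ bump_dir, -1.0, 1.0)
        ang = np.arccos(cosang)
        r = r * (1.0 + params.nose_bump_amplitude * np.exp(-((ang / 0.35) ** 2)))
    return dirs * r[:, None]


def _analytic_landmarks(params: SkullShapeParams) -> np.ndarray:
    """Lp, Rp, Mp, Vp on the undeformed superellipsoid, stacked (4, 3)."""
    a, b, c = params.semi_axes
    m = params.cranial_index_shift
    axes = (a * np.sqrt(m), b / np.sqrt(m), c)
    dirs = np.array([
        [1.0, 0.0, 0.0],    # Lp: left porion (subject's left = +x)
        [-1.0, 0.0, 0.0],   # Rp: right porion
        [0.25, 0.9, -0.35],  # Mp: left orbitale, below the front orbit
        [0.0, 1.0, 0.15],   # Vp: glabella, front midline
    ])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    r = _surface_radius(dirs, axes, params.exponent)
    return dirs * r[:, None]


def generate_skull(params: SkullShapeParams) -> tuple[PointCloud, LandmarkSet]:
    """One skull proxy: surface sample + landmarks, in a random rigid pose."""
    rng = np.random.default_rng(params.seed)
    pts = _sample_surface(params, rng)
    lm = _analytic_landmarks(params)
    if params.noise_sd > 0:
        pts = pts + rng.normal(0.0, params.noise_sd, size=pts.shape)
    if params.rigid_pose:
        R = Rotation.random(random_state=np.random.RandomState(
            rng.integers(0, 2**31 - 1))).as_matrix()
        t = rng.uniform(-100.0, 100.0, size=3)
        pts = pts @ R.T + t
        lm = lm @ R.T + t
    cloud = PointCloud(points=pts, source_id=f"synthetic-{params.seed}")
    return cloud, LandmarkSet.from_array(lm)


def generate_dataset(
    n_per_class: int,
    effect: float = 0.15,
    seed: int = 0,
    base_params: SkullShapeParams | None = None,
    jitter_sd: float = 0.02,
) -> list[tuple[PointCloud, LandmarkSet, int]]:
    """Balanced two-class dataset differing only in cranial index.

    Class 0 gets a cranial-index multiplier 1 - effect/2, class 1 gets
    1 + effect/2, each perturbed per sample by lognormal jitter of sd
    ``jitter_sd`` so the classes overlap realistically.
    """
    if n_per_class < 5:
        raise ValueError("n_per_class must be >= 5")
    if effect < 0:
        raise ValueError("effect must be >= 0")
    base = base_params or SkullShapeParams()
    rng = np.random.default_rng(seed)
    samples: list[tuple[PointCloud, LandmarkSet, int]] = []
    for label in (0, 1):
        shift = 1.0 + (effect / 2 if label else -effect / 2)
        for _ in range(n_per_class):
            sample_shift = shift * float(np.exp(rng.normal(0.0, jitter_sd)))
            p = SkullShapeParams(
                semi_axes=base.semi_axes,
                cranial_index_shift=sample_shift,
                nose_bump_amplitude=base.nose_bump_amplitude,
                noise_sd=base.noise_sd,
                n_points=base.n_points,
                exponent=base.exponent,
                rigid_pose=base.rigid_pose,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            cloud, lm = generate_skull(p)
            samples.append((cloud, lm, label))
    return samples


def augment(
    cloud: PointCloud,
    landmarks: LandmarkSet,
    n_aug: int,
    max_angle_deg: float = 5.0,
    seed: int = 0,
) -> list[tuple[PointCloud, LandmarkSet]]:
    """Small random rotations applied jointly to points and landmarks.

    Emulates re-acquiring a scan after slightly re-posing the specimen:
    each copy is rotated by independent uniform angles in
    [-max_angle_deg, +max_angle_deg] about x, y and z.
    """
    if max_angle_deg < 0:
        raise ValueError("max_angle_deg must be >= 0")
    rng = np.random.default_rng(seed)
    out: list[tuple[PointCloud, LandmarkSet]] = []
    centre = cloud.points.mean(axis=0)
    for _ in range(n_aug):
        angles = rng.uniform(-max_angle_deg, max_angle_deg, size=3)
        R = Rotation.from_euler("xyz", angles, degrees=True).as_matrix()
        pts = (cloud.points - centre) @ R.T + centre
        lm = (landmarks.as_array() - centre) @ R.T + centre
        out.append((PointCloud(points=pts, source_id=cloud.source_id),
                    LandmarkSet.from_array(lm)))
    return out
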