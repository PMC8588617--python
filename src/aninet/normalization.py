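"""Frankfurt-frame construction and pose/scale normalization.

Every skull is re-expressed in a coordinate frame built from three of the
four craniometric landmarks: the inter-porion line (Rp -> Lp) is the
x-axis, the origin o' is the orthogonal projection of the glabella Vp onto
that line, the z-axis is the normal of plane(Lp, Rp, Vp) through o'
(signed away from the orbitale Mp, i.e. toward the cranial vault), and
y = z x x completes a right-handed triad.  After the rigid move the cloud
is uniformly rescaled so its maximum cylindrical radius sqrt(x^2 + y^2)
equals 1, which guarantees it fits inside the radius-1.3 projection
cylinder with margin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import LandmarkSet, PointCloud, _check_frame_landmarks


class DegenerateFrameError(ValueError):
    """Landmarks do not define a unique Frankfurt frame."""


@dataclass
class FrankfurtFrame:
    """A rigid frame plus uniform scale.

    ``apply`` maps world coordinates to frame coordinates:
    p -> scale * R^T (p - origin) where R's columns are the axes.
    """

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        for name in ("x_axis", "y_axis", "z_axis"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise DegenerateFrameError("frame axes are not orthonormal")
        if not np.allclose(np.cross(self.x_axis, self.y_axis), self.z_axis, atol=1e-9):
            raise DegenerateFrameError("frame axes are not right-handed")
        if not self.scale > 0:
            raise DegenerateFrameError("frame scale must be positive")

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix whose columns are the frame axes."""
        return np.stack([self.x_axis, self.y_axis, self.z_axis], axis=1)

    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "x_axis": self.x_axis.tolist(),
            "y_axis": self.y_axis.tolist(),
            "z_axis": self.z_axis.tolist(),
            "scale": float(self.scale),
        }


def frankfurt_frame(landmarks: LandmarkSet) -> FrankfurtFrame:
    """Construct the Frankfurt frame from the four landmarks (scale 1)."""
    lp, rp, mp, vp = landmarks.Lp, landmarks.Rp, landmarks.Mp, landmarks.Vp
    try:
        _check_frame_landmarks(lp, rp, vp)
    except ValueError as exc:
        raise DegenerateFrameError(str(exc)) from exc

    x = lp - rp
    x = x / np.linalg.norm(x)
    # o' = orthogonal projection of Vp onto line(Lp, Rp)
    origin = rp + np.dot(vp - rp, x) * x
    front = vp - origin  # perpendicular to x by construction
    front = front / np.linalg.norm(front)
    z = np.cross(x, front)
    z = z / np.linalg.norm(z)
    # sign: z points from the ear line toward the vault, away from Mp
    if np.dot(origin - mp, z) < 0:
        z = -z
    y = np.cross(z, x)
    return FrankfurtFrame(origin=origin, x_axis=x, y_axis=y, z_axis=z, scale=1.0)


def apply_frame(cloud: PointCloud, frame: FrankfurtFrame) -> PointCloud:
    """Express a cloud in the frame: p -> scale * R^T (p - origin)."""
    pts = (cloud.points - frame.origin) @ frame.rotation
    return PointCloud(points=pts * frame.scale, source_id=cloud.source_id)


def apply_frame_to_landmarks(landmarks: LandmarkSet, frame: FrankfurtFrame) -> LandmarkSet:
    arr = (landmarks.as_array() - frame.origin) @ frame.rotation * frame.scale
    return LandmarkSet.from_array(arr)


def normalize_scale(cloud: PointCloud) -> tuple[PointCloud, float]:
    """Uniformly rescale so max_i sqrt(x_i^2 + y_i^2) == 1.

    Returns the rescaled cloud and the scale factor applied.  The cloud
    must already be in the Frankfurt frame (the radius is measured about
    the frame's z-axis).
    """
    radii = np.hypot(cloud.points[:, 0], cloud.points[:, 1])
    rmax = radii.max()
    if rmax <= 0.0:
        raise DegenerateFrameError("all points lie on the z-axis; radial scale undefined")
    s = 1.0 / rmax
    return PointCloud(points=cloud.points * s, source_id=cloud.source_id), s


def normalize_skull(
    cloud: PointCloud, landmarks: LandmarkSet, cylinder_height: float = 3.0
) -> tuple[PointCloud, LandmarkSet, FrankfurtFrame]:
    """Full normalization: Frankfurt re-expression then uniform rescale.

    Returns the normalized cloud, the landmarks in the same normalized
    coordinates, and the combined frame (rigid part + scale) that maps the
    original world coordinates into them.
    """
    frame = frankfurt_frame(landmarks)
    aligned = apply_frame(cloud, frame)
    rescaled, s = normalize_scale(aligned)
    frame = FrankfurtFrame(
        origin=frame.origin,
        x_axis=frame.x_axis,
        y_axis=frame.y_axis,
        z_axis=frame.z_axis,
        scale=s,
    )
    lm = apply_frame_to_landmarks(landmarks, frame)
    zmax = np.abs(rescaled.points[:, 2]).max()
    if zmax > cylinder_height / 2:
        warnings.warn(
            f"normalized cloud extends to |z| = {zmax:.3f} > h/2 = {cylinder_height / 2}; "
            "points beyond the cylinder will be clipped by the global projection",
            stacklevel=2,
        )
    return rescaled, lm, frame
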