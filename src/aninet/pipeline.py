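"""End-to-end glue: raw (cloud, landmarks) -> normalized network input."""

from __future__ import annotations

import numpy as np

from .io import LandmarkSet, PointCloud
from .normalization import normalize_skull
from .projection import (
    CylinderSpec,
    DepthImage,
    PlanarProjectionSpec,
    fuse_channels,
    normalize_intensity,
    project_cylindrical,
    project_planar,
    resize_global,
    resize_local,
    smooth,
)

LOCAL_VIEWS = ("front", "left", "bottom")


def skull_depth_images(
    cloud: PointCloud,
    landmarks: LandmarkSet,
    mode: str = "both",
    side: int = 160,
    planar_resolution: int = 400,
    cylinder_spec: CylinderSpec | None = None,
    smooth_sigma: float = 1.0,
) -> dict[str, DepthImage]:
    """Normalize a skull and render its depth views at network resolution.

    Returns a dict keyed by view name ("front", "left", "bottom",
    "global"), each a smoothed, intensity-normalized, side x side image.
    """
    if mode not in ("local", "global", "both"):
        raise ValueError(f"mode must be local|global|both, got {mode!r}")
    norm_cloud, _, _ = normalize_skull(cloud, landmarks)
    views: dict[str, DepthImage] = {}
    if mode in ("local", "both"):
        for view in LOCAL_VIEWS:
            img = project_planar(norm_cloud, PlanarProjectionSpec(
                view=view, resolution=planar_resolution))
            img = normalize_intensity(smooth(img, smooth_sigma))
            views[view] = resize_local(img, side=side)
    if mode in ("global", "both"):
        img = project_cylindrical(norm_cloud, cylinder_spec or CylinderSpec())
        img = normalize_intensity(smooth(img, smooth_sigma))
        views["global"] = resize_global(img, side=side)
    return views


def skull_to_tensor(
    cloud: PointCloud,
    landmarks: LandmarkSet,
    mode: str = "both",
    side: int = 160,
    **kwargs,
) -> np.ndarray:
    """One skull -> H x W x C fused input (C = 3 local, 1 global, 4 both)."""
    views = skull_depth_images(cloud, landmarks, mode=mode, side=side, **kwargs)
    locals_ = [views[v] for v in LOCAL_VIEWS] if mode in ("local", "both") else None
    global_ = views.get("global")
    return fuse_channels(locals_, global_)


def dataset_to_tensors(
    samples, mode: str = "both", side: int = 160, **kwargs
) -> tuple[np.ndarray, np.ndarray]:
    """Project a labelled [(cloud, landmarks, label), ...] list to (X, y)."""
    X = np.stack([
        skull_to_tensor(cloud, lm, mode=mode, side=side, **kwargs)
        for cloud, lm, _ in samples
    ])
    y = np.array([label for _, _, label in samples], dtype=int)
    return X, y
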