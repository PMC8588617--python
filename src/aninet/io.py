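"""Reading and writing the pipeline's interchange formats.

Meshes (OBJ/PLY) are consumed as bare vertex clouds — faces, normals and
materials are discarded, and no point ordering is ever relied upon
downstream.  Landmark files carry the four craniometric points (left/right
porion ``Lp``/``Rp``, left orbitale ``Mp``, glabella ``Vp``) either as a
JSON object or as a four-line whitespace-separated table.  Depth images
travel as 8- or 16-bit grayscale PNG with linear quantization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from PIL import Image

LANDMARK_NAMES = ("Lp", "Rp", "Mp", "Vp")


class FormatError(ValueError):
    """Raised when a file parses but does not satisfy the format contract."""


class LandmarkValidationError(ValueError):
    """Raised when a landmark file is missing keys or geometrically degenerate."""


@dataclass
class PointCloud:
    """An unordered sample of a skull surface.

    Parameters
    ----------
    points:
        ``(n, 3)`` float array, millimetres for raw scans and dimensionless
        after Frankfurt normalization.
    source_id:
        Free-text identifier carried through the pipeline.
    """

    points: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got {pts.shape}")
        if pts.shape[0] < 4:
            raise ValueError(f"a point cloud needs >= 4 points, got {pts.shape[0]}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("point coordinates must be finite")
        self.points = pts

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class LandmarkSet:
    """The four cranial landmarks defining the Frankfurt frame."""

    Lp: np.ndarray
    Rp: np.ndarray
    Mp: np.ndarray
    Vp: np.ndarray

    def __post_init__(self) -> None:
        for name in LANDMARK_NAMES:
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            if not np.all(np.isfinite(v)):
                raise LandmarkValidationError(f"landmark {name} has non-finite coordinates")
            setattr(self, name, v)
        _check_frame_landmarks(self.Lp, self.Rp, self.Vp)

    def as_array(self) -> np.ndarray:
        """Landmarks stacked in (Lp, Rp, Mp, Vp) order, shape (4, 3)."""
        return np.stack([self.Lp, self.Rp, self.Mp, self.Vp])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "LandmarkSet":
        arr = np.asarray(arr, dtype=float)
        return cls(Lp=arr[0], Rp=arr[1], Mp=arr[2], Vp=arr[3])


def _check_frame_landmarks(lp: np.ndarray, rp: np.ndarray, vp: np.ndarray) -> None:
    """Lp != Rp and Lp, Rp, Vp not collinear, else the frame is undefined."""
    ear = lp - rp
    ear_len = np.linalg.norm(ear)
    if ear_len == 0.0:
        raise LandmarkValidationError("Lp and Rp coincide")
    # distance of Vp from line(Lp, Rp), relative to the ear-line length
    off = np.linalg.norm(np.cross(ear / ear_len, vp - rp))
    if off <= 1e-9 * max(1.0, ear_len):
        raise LandmarkValidationError("Lp, Rp, Vp are collinear; Frankfurt frame undefined")


def read_mesh(path: str | Path) -> PointCloud:
    """Load the vertices of an OBJ or PLY mesh as a :class:`PointCloud`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        loaded = trimesh.load(path, process=False)
    except Exception as exc:  # trimesh raises a zoo of exception types
        raise FormatError(f"{path}: unparseable geometry ({exc})") from exc
    verts = _extract_vertices(loaded)
    if verts is None or len(verts) == 0:
        raise FormatError(f"{path}: no vertex records found")
    return PointCloud(points=np.asarray(verts, dtype=float), source_id=path.stem)


def _extract_vertices(loaded) -> np.ndarray | None:
    if isinstance(loaded, trimesh.Scene):
        if not loaded.geometry:
            return None
        return np.vstack([np.asarray(g.vertices) for g in loaded.geometry.values()])
    if hasattr(loaded, "vertices") and len(loaded.vertices):
        return np.asarray(loaded.vertices)
    return None


def write_mesh(cloud: PointCloud, path: str | Path) -> None:
    """Write a point cloud as an ASCII PLY vertex list (no faces)."""
    path = Path(path)
    pc = trimesh.PointCloud(cloud.points)
    path.write_bytes(pc.export(file_type="ply", encoding="ascii"))


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read a landmark file (JSON object or 4-line ``name x y z`` text).

    The dialect is chosen by extension: ``.json`` is parsed as a JSON
    object, anything else as whitespace-separated text.  Exactly the keys
    Lp, Rp, Mp, Vp are required; extras are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        table = json.loads(path.read_text())
        if not isinstance(table, dict):
            raise LandmarkValidationError(f"{path}: expected a JSON object")
        coords = {str(k): np.asarray(v, dtype=float) for k, v in table.items()}
    else:
        coords = {}
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise LandmarkValidationError(f"{path}: bad landmark line {line!r}")
            coords[parts[0]] = np.asarray(parts[1:], dtype=float)
    missing = [k for k in LANDMARK_NAMES if k not in coords]
    if missing:
        raise LandmarkValidationError(f"{path}: missing landmark(s) {', '.join(missing)}")
    extra = [k for k in coords if k not in LANDMARK_NAMES]
    if extra:
        raise LandmarkValidationError(f"{path}: unexpected key(s) {', '.join(extra)}")
    return LandmarkSet(**{k: coords[k] for k in LANDMARK_NAMES})


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    path = Path(path)
    obj = {name: list(map(float, getattr(landmarks, name))) for name in LANDMARK_NAMES}
    path.write_text(json.dumps(obj, indent=1))


def write_depth_image(img, path: str | Path, bit_depth: int = 16) -> None:
    """Write a normalized depth image as linear-quantized grayscale PNG.

    Values must already lie in [0, 1]; v maps to ``round(v * (2**bit_depth - 1))``.
    """
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    values = np.asarray(img.values if hasattr(img, "values") else img, dtype=float)
    if values.min() < 0.0 or values.max() > 1.0:
        raise ValueError("depth image values must be normalized to [0, 1] before writing")
    scale = 2**bit_depth - 1
    quant = np.round(values * scale)
    if bit_depth == 8:
        pil = Image.fromarray(quant.astype(np.uint8))
    else:
        pil = Image.fromarray(quant.astype(np.uint16))
    pil.save(Path(path), format="PNG")


def read_depth_image(path: str | Path) -> np.ndarray:
    """Read a grayscale PNG back to float values in [0, 1]."""
    pil = Image.open(Path(path))
    arr = np.asarray(pil)
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    return arr.astype(float) / 65535.0


@dataclass
class ManifestEntry:
    """One skull in a dataset manifest."""

    sample_id: str
    mesh_path: str
    landmark_path: str
    label: int | None = None


@dataclass
class Manifest:
    entries: list = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        rows = [vars(e) for e in self.entries]
        Path(path).write_text(json.dumps(rows, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Manifest":
        rows = json.loads(Path(path).read_text())
        return cls(entries=[ManifestEntry(**r) for r in rows])
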