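"""Image-stack and mesh I/O plus the intensity/resampling steps of the VOI pipeline.

Volumes are held as :class:`ImageStack` objects with axis order ``(z, y, x)``
and per-axis voxel pitch in micrometres.  Supported on-disk formats are
multi-page TIFF (with ImageJ-style pitch metadata) and NIfTI-1; meshes go
through :mod:`trimesh` (PLY / STL / OBJ).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

#: CT voxel pitch of the high-resolution hind-paw acquisition protocol, in µm.
DEFAULT_PITCH_UM = 14.609


@dataclass
class ImageStack:
    """A 3D scalar volume with voxel-pitch metadata.

    Parameters
    ----------
    data:
        Array of shape ``(z, y, x)``.
    pitch_um:
        Per-axis voxel pitch ``(z, y, x)`` in micrometres.
    bit_depth:
        Nominal intensity scale, 8 or 16.  8-bit stacks hold values in
        ``[0, 255]`` (possibly fractional after block averaging).
    """

    data: np.ndarray
    pitch_um: tuple[float, float, float] = (DEFAULT_PITCH_UM,) * 3
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 + 1:
            raise ValueError(f"non-3D content: got {self.data.ndim} dimensions")
        if min(self.data.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        if np.isscalar(self.pitch_um) or np.ndim(self.pitch_um) == 0:
            self.pitch_um = (float(self.pitch_um),) * 3
        self.pitch_um = tuple(float(p) for p in self.pitch_um)
        if len(self.pitch_um) != 3 or any(p <= 0 for p in self.pitch_um):
            raise ValueError(f"pitch_um must be 3 positive values, got {self.pitch_um}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"unsupported bit depth {self.bit_depth}")
        if self.bit_depth == 8 and self.data.size:
            lo, hi = float(self.data.min()), float(self.data.max())
            if lo < 0 or hi > 255:
                raise ValueError(f"8-bit data outside [0, 255]: range [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3."""
        pz, py, px = self.pitch_um
        return (pz * py * px) * 1e-9


@dataclass
class TriangleMesh:
    """Triangulated surface with per-triangle outward unit normals.

    ``vertices`` are physical coordinates in µm, ordered ``(z, y, x)`` to
    match the stack axes.  ``component_id`` labels edge-connected triangle
    components (0-based, -1 allowed only on the empty mesh).
    """

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray
    component_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        self.normals = np.asarray(self.normals, dtype=np.float64).reshape(-1, 3)
        if self.component_id is None:
            self.component_id = np.zeros(len(self.faces), dtype=np.int64)
        self.component_id = np.asarray(self.component_id, dtype=np.int64).reshape(-1)
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise ValueError("triangle index out of range")
        if len(self.normals) != len(self.faces) or len(self.component_id) != len(self.faces):
            raise ValueError("normals/component labels must be per-triangle")

    def __len__(self) -> int:
        return len(self.faces)

    @property
    def n_triangles(self) -> int:
        return len(self.faces)

    def centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices[self.faces]
        return 0.5 * np.linalg.norm(np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1)

    def area(self) -> float:
        return float(self.triangle_areas().sum())


def empty_mesh() -> TriangleMesh:
    z = np.zeros((0, 3))
    return TriangleMesh(z, np.zeros((0, 3), dtype=np.int64), z, np.zeros(0, dtype=np.int64))


# ---------------------------------------------------------------------------
# volume I/O


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    return "tiff"


def load_stack(
    path: str | Path,
    format: str | None = None,
    default_pitch_um: float | tuple[float, float, float] = DEFAULT_PITCH_UM,
) -> ImageStack:
    """Read a 3D volume from multi-page TIFF or NIfTI-1.

    Pitch metadata is recovered from ImageJ TIFF tags or the NIfTI header
    zooms; when absent, ``default_pitch_um`` is used and a warning logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "tiff":
        data, pitch = _load_tiff(path)
    elif fmt == "nifti":
        data, pitch = _load_nifti(path)
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    if data.ndim == 2:
        raise ValueError("non-3D content: single 2D image")
    if data.ndim != 3:
        raise ValueError(f"non-3D content: {data.ndim} dimensions")
    if pitch is None:
        log.warning("%s: no pitch metadata; falling back to %s um", path, default_pitch_um)
        pitch = default_pitch_um
    if data.dtype == np.uint8:
        depth = 8
    elif data.dtype in (np.uint16, np.int16):
        depth = 16
        data = data.astype(np.uint16) if data.dtype == np.int16 else data
    else:
        raise ValueError(f"unsupported bit depth for dtype {data.dtype}")
    return ImageStack(data, pitch_um=pitch, bit_depth=depth)


def _load_tiff(path: Path):
    import tifffile

    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        pitch = None
        page = tf.pages[0]
        # ImageJ metadata: 'spacing' is the z step; XResolution is px per unit.
        res = page.tags.get("XResolution")
        ij = tf.imagej_metadata or {}
        if res is not None:
            num, den = res.value
            if num:
                xy = den / num  # units per pixel
                unit = (ij.get("unit") or "").lower()
                scale = {"um": 1.0, "micron": 1.0, "µm": 1.0, "mm": 1000.0}.get(unit)
                if scale is not None:
                    xy_um = xy * scale
                    z_um = float(ij.get("spacing", xy)) * scale
                    pitch = (z_um, xy_um, xy_um)
    return data, pitch


def _load_nifti(path: Path):
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        return data, None
    # nibabel gives (x, y, z); reorder to (z, y, x)
    data = np.ascontiguousarray(data.transpose(2, 1, 0))
    zooms = img.header.get_zooms()[:3]
    unit = img.header.get_xyzt_units()[0]
    scale = {"micron": 1.0, "mm": 1000.0, "meter": 1e6}.get(unit)
    if scale is None:
        return data, None
    zx, zy, zz = zooms
    return data, (zz * scale, zy * scale, zx * scale)


def save_stack(stack: ImageStack, path: str | Path, format: str | None = None) -> None:
    """Write a stack to TIFF (ImageJ pitch tags) or NIfTI-1 (micron zooms)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    dtype = np.uint8 if stack.bit_depth == 8 else np.uint16
    data = np.round(stack.data).astype(dtype) if not np.issubdtype(stack.data.dtype, np.integer) else stack.data.astype(dtype)
    pz, py, px = stack.pitch_um
    if fmt == "tiff":
        import tifffile

        tifffile.imwrite(
            path,
            data,
            imagej=True,
            resolution=(1.0 / px, 1.0 / py),
            metadata={"spacing": pz, "unit": "um", "axes": "ZYX"},
        )
    elif fmt == "nifti":
        import nibabel as nib

        img = nib.Nifti1Image(data.transpose(2, 1, 0), affine=np.diag([px, py, pz, 1.0]))
        img.header.set_zooms((px, py, pz))
        img.header.set_xyzt_units(xyz="micron")
        nib.save(img, str(path))
    else:
        raise ValueError(f"unsupported format {fmt!r}")


# ---------------------------------------------------------------------------
# intensity conversion and resampling


def to_8bit(stack: ImageStack) -> ImageStack:
    """Convert a 16-bit stack to 8-bit by linear min-max scaling.

    The observed range ``[min, max]`` maps linearly onto ``[0, 255]`` with
    round-half-up; a constant stack maps to all zeros.  The mapping is
    monotone, making downstream fixed thresholds robust to scanner offsets.
    """
    if stack.bit_depth != 16:
        raise ValueError("to_8bit expects a 16-bit stack")
    data = stack.data.astype(np.float64)
    lo, hi = data.min(), data.max()
    if hi == lo:
        out = np.zeros_like(data, dtype=np.uint8)
    else:
        scaled = (data - lo) * (255.0 / (hi - lo))
        out = np.floor(scaled + 0.5).astype(np.uint8)  # round half up
    return ImageStack(out, pitch_um=stack.pitch_um, bit_depth=8)


def downsample_xy(stack: ImageStack, factor: int) -> ImageStack:
    """Block-mean downsampling in-plane (x and y); z is untouched.

    Trailing partial blocks are averaged over the voxels they contain.
    Output data is float64 so block means are exact; the nominal bit depth
    is retained.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return ImageStack(stack.data.copy(), stack.pitch_um, stack.bit_depth)
    data = stack.data.astype(np.float64)
    for axis in (1, 2):
        n = data.shape[axis]
        idx = np.arange(0, n, factor)
        sums = np.add.reduceat(data, idx, axis=axis)
        counts = np.minimum(idx + factor, n) - idx
        shape = [1, 1, 1]
        shape[axis] = len(idx)
        data = sums / counts.reshape(shape)
    pz, py, px = stack.pitch_um
    return ImageStack(data, (pz, py * factor, px * factor), stack.bit_depth)


# ---------------------------------------------------------------------------
# mesh I/O


def save_mesh(mesh: TriangleMesh, path: str | Path, format: str | None = None) -> None:
    """Write a mesh as PLY (binary), STL, or OBJ, inferred from the suffix."""
    import trimesh

    if mesh.n_triangles == 0:
        raise ValueError("refusing to write an empty mesh")
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt not in ("ply", "stl", "obj"):
        raise ValueError(f"unsupported mesh format {fmt!r}")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(path, file_type=fmt)


def load_mesh(path: str | Path) -> TriangleMesh:
    """Load a mesh; exact duplicate vertices (e.g. from STL) are re-merged."""
    import trimesh

    tm = trimesh.load_mesh(str(path), process=False)
    from .surface import build_mesh  # deferred: avoids an import cycle

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_mesh(np.asarray(tm.vertices), np.asarray(tm.faces), merge=True)
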