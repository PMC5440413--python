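"""Triangulated cortical-bone surface reconstruction from a VOI.

Surfaces are extracted with a topologically consistent marching-cubes variant
(Lewiner's disambiguated case table) at a one-voxel grid size, on the iso
level given by Otsu's threshold for the individual VOI.  Three surfaces are
produced per VOI:

* ``cs`` — the complete cortical surface (periosteal + endosteal),
* ``os`` — the outer / periosteal surface only (medullary cavities filled
  before meshing so no inner interface exists),
* ``is`` — the inner / endosteal surface only (meshed from a field that is
  suprathreshold exactly on the cavity voxels).

Cavities are background regions not reachable by a 6-connected flood fill
seeded from the x/y borders of the VOI; the z faces are excluded from seeding
because paw bones are cut open at the VOI's z ends, so the medullary canal
must not be classified as exterior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc
from skimage import measure

from .image_io import ImageStack, TriangleMesh, empty_mesh

log = logging.getLogger(__name__)

SURFACE_KINDS = ("cs", "os", "is")


@dataclass
class SurfaceSet:
    """The three cortical surface reconstructions of one VOI."""

    cs: TriangleMesh
    outer: TriangleMesh
    inner: TriangleMesh
    threshold: float
    provenance: str = ""

    def get(self, kind: str) -> TriangleMesh:
        try:
            return {"cs": self.cs, "os": self.outer, "is": self.inner}[kind]
        except KeyError:
            raise ValueError(f"unknown surface kind {kind!r}; expected one of {SURFACE_KINDS}")


# ---------------------------------------------------------------------------
# thresholding


def otsu_threshold(voi: ImageStack) -> float:
    """Otsu's threshold over the full-bit-depth histogram of the VOI.

    Maximizes the between-class variance over all integer cut points; a
    plateau of optimal cuts returns its midpoint.  Voxels strictly above the
    returned value are foreground ("suprathreshold") everywhere downstream.
    """
    data = np.round(np.asarray(voi.data)).astype(np.int64).ravel()
    lo, hi = int(data.min()), int(data.max())
    if lo == hi:
        raise ValueError("constant image: Otsu threshold undefined")
    hist = np.bincount(data - lo, minlength=hi - lo + 1).astype(np.float64)
    p = hist / hist.sum()
    values = np.arange(lo, hi + 1, dtype=np.float64)
    w0 = np.cumsum(p)  # class "<= t"
    m0 = np.cumsum(p * values)
    mT = m0[-1]
    # between-class variance for each cut t = values[i] (classes <=t, >t)
    w0c, m0c = w0[:-1], m0[:-1]
    w1c = 1.0 - w0c
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = np.where(
            (w0c > 0) & (w1c > 0),
            (mT * w0c - m0c) ** 2 / (w0c * w1c),
            -np.inf,
        )
    best = sigma_b.max()
    plateau = np.flatnonzero(sigma_b >= best - 1e-12 * max(1.0, abs(best)))
    t = (values[plateau[0]] + values[plateau[-1]]) / 2.0
    return float(t)


# ---------------------------------------------------------------------------
# mesh construction helpers


def face_components(faces: np.ndarray, n_vertices: int | None = None) -> np.ndarray:
    """Label triangles by edge connectivity (shared undirected edge)."""
    faces = np.asarray(faces, dtype=np.int64)
    nf = len(faces)
    if nf == 0:
        return np.zeros(0, dtype=np.int64)
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    fidx = np.tile(np.arange(nf), 3)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    edges, fidx = edges[order], fidx[order]
    same = np.all(edges[1:] == edges[:-1], axis=1)
    rows = fidx[:-1][same]
    cols = fidx[1:][same]
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(nf, nf))
    _, labels = _cc(adj, directed=False)
    return labels.astype(np.int64)


def triangle_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    v = vertices[faces]
    n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return n / norm


def build_mesh(vertices: np.ndarray, faces: np.ndarray, merge: bool = False) -> TriangleMesh:
    """Assemble a :class:`TriangleMesh`, recomputing normals and components."""
    vertices = np.asarray(vertices, dtype=np.float64).reshape(-1, 3)
    faces = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
    if merge:
        vertices, faces = _merge_duplicate_vertices(vertices, faces)
    if len(faces) == 0:
        return empty_mesh()
    return TriangleMesh(
        vertices, faces, triangle_normals(vertices, faces), face_components(faces)
    )


def _merge_duplicate_vertices(vertices: np.ndarray, faces: np.ndarray):
    """Merge vertices at exactly identical coordinates (no tolerance welding);
    drops triangles degenerated by the merge."""
    uniq, inverse = np.unique(vertices, axis=0, return_inverse=True)
    faces = inverse[faces]
    ok = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 2] != faces[:, 0])
    )
    return uniq, faces[ok]


# ---------------------------------------------------------------------------
# marching cubes


def marching_cubes(
    voi: ImageStack | np.ndarray,
    threshold: float,
    pitch_um: tuple[float, float, float] | None = None,
    pad_background: bool = True,
) -> TriangleMesh:
    """Iso-surface at ``threshold`` on the native voxel grid.

    Uses the Lewiner marching-cubes variant, whose disambiguated case table
    yields closed, topologically consistent components on binary-like fields.
    With ``pad_background`` one layer of sub-threshold voxels is added on all
    faces so every component is closed.  Vertices are physical µm coordinates
    (axis order z, y, x, voxel centre i at ``i * pitch``); normals point away
    from the suprathreshold region.
    """
    if isinstance(voi, ImageStack):
        field = voi.data.astype(np.float64)
        pitch = voi.pitch_um
    else:
        field = np.asarray(voi, dtype=np.float64)
        pitch = pitch_um if pitch_um is not None else (1.0, 1.0, 1.0)
    if not (field > threshold).any():
        raise ValueError("no suprathreshold voxels at this threshold")
    if pad_background:
        pad_val = min(field.min(), threshold - 1.0)
        field = np.pad(field, 1, constant_values=pad_val)
    verts, faces, _, _ = measure.marching_cubes(
        field, level=threshold, spacing=tuple(pitch), method="lewiner",
        allow_degenerate=False,
    )
    if pad_background:
        verts = verts - np.asarray(pitch)
    # skimage's winding gives inward cross-product normals; flip to outward.
    faces = faces[:, [0, 2, 1]]
    return build_mesh(verts, faces)


def clean_mesh(
    mesh: TriangleMesh, mode: str = "keep_largest", cutoff: int = 1_900_000
) -> TriangleMesh:
    """Merge exact-duplicate vertices and drop artifact components.

    ``keep_largest`` retains only the component with the most triangles;
    ``min_triangles`` drops components smaller than ``cutoff`` (default tuned
    to full-resolution paw meshes, which exceed 1.9 million triangles).
    """
    if mesh.n_triangles == 0:
        raise ValueError("empty mesh")
    vertices, faces = _merge_duplicate_vertices(mesh.vertices, mesh.faces)
    labels = face_components(faces)
    sizes = np.bincount(labels) if len(labels) else np.zeros(0, dtype=int)
    if mode == "keep_largest":
        keep = labels == sizes.argmax()
    elif mode == "min_triangles":
        keep = sizes[labels] >= cutoff
    else:
        raise ValueError(f"unknown mode {mode!r}")
    faces = faces[keep]
    if len(faces) == 0:
        raise ValueError("cleaning removed every triangle")
    used = np.unique(faces)
    remap = np.full(len(vertices), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return build_mesh(vertices[used], remap[faces])


# ---------------------------------------------------------------------------
# periosteal / endosteal separation


def cavity_mask(suprathreshold: np.ndarray) -> np.ndarray:
    """Background voxels not reachable from the x/y borders (6-connected).

    These are medullary cavities (plus any fully enclosed pores).  The z
    faces are deliberately not used as flood seeds: bones run along z and are
    cut open at the VOI ends, so an open medullary canal would otherwise leak
    to the exterior.
    """
    bg = ~suprathreshold
    labels, n = ndimage.label(bg, structure=ndimage.generate_binary_structure(3, 1))
    if n == 0:
        return np.zeros_like(bg)
    border = np.zeros(n + 1, dtype=bool)
    for sl in (
        labels[:, 0, :], labels[:, -1, :], labels[:, :, 0], labels[:, :, -1]
    ):
        border[np.unique(sl)] = True
    border[0] = False
    exterior = border[labels]
    return bg & ~exterior


def split_surfaces(
    voi: ImageStack, threshold: float | None = None, provenance: str = ""
) -> SurfaceSet:
    """Build the complete, outer (periosteal) and inner (endosteal) surfaces.

    ``cs`` is marching cubes on the VOI at the threshold.  For ``os`` the
    cavity voxels are re-assigned a suprathreshold fill so the endosteal
    interface vanishes while the periosteal interface is untouched.  For
    ``is`` a mirrored field (``2*t - intensity`` on bone and cavity voxels,
    deep background elsewhere) is suprathreshold exactly on the cavity, which
    reproduces the endosteal interface of ``cs`` at identical sub-voxel
    positions — so area(os) + area(is) tracks area(cs).  ``is`` normals
    therefore point from the cavity into the cortical wall.  All outputs keep
    every genuine component (duplicate-vertex merge only).
    """
    if threshold is None:
        threshold = otsu_threshold(voi)
    data = voi.data.astype(np.float64)
    bone = data > threshold
    if not bone.any():
        raise ValueError("no suprathreshold voxels: cannot build surfaces")
    cav = cavity_mask(bone)
    if bone.any(axis=(1, 2))[0] or bone.any(axis=(1, 2))[-1]:
        log.debug("%s: foreground touches a z face; open canals treated as cavity",
                  provenance or "VOI")

    cs = marching_cubes(voi, threshold)

    os_field = data.copy()
    mirrored = 2.0 * threshold - data
    os_field[cav] = np.maximum(mirrored[cav], threshold + 1.0)
    outer = marching_cubes(os_field, threshold, pitch_um=voi.pitch_um)

    if cav.any():
        low = min(mirrored[bone | cav].min(), threshold) - 1.0
        is_field = np.full_like(data, low)
        sel = bone | cav
        is_field[sel] = mirrored[sel]
        inner = marching_cubes(is_field, threshold, pitch_um=voi.pitch_um)
    else:
        inner = empty_mesh()

    return SurfaceSet(cs=cs, outer=outer, inner=inner,
                      threshold=float(threshold), provenance=provenance)
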