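"""Multi-scale bone-surface roughness from normal-vector angles.

For every triangle of a surface mesh, the angles between its outward unit
normal and the normals of all triangles within a circular vicinity of radius
``r`` (in voxels, converted to µm through the voxel pitch) are averaged.
Pooling these per-triangle mean angles over a set of baseline (healthy /
pre-treatment) meshes gives a composite histogram to which a lognormal
probability density

    p(x) = 1 / (x sigma sqrt(2 pi)) * exp(-(ln x - mu)^2 / (2 sigma^2))

is fitted.  The threshold angle ``T`` is the mean plus two standard
deviations of that density; the roughness score ``R`` of a mesh is the
relative frequency of triangles whose mean vicinity angle exceeds ``T``.
Being a relative frequency, ``R`` is minimally affected by bone growth or
mesh size.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .image_io import TriangleMesh
from .surface import SURFACE_KINDS, SurfaceSet

log = logging.getLogger(__name__)

#: Vicinity radii (in voxels) at which roughness is scored by default.
DEFAULT_RADII = (1, 3, 5, 10, 15, 20)


def radius_to_um(radius_vox: float, pitch_um: float = 14.609) -> float:
    """Physical size of a roughness radius given the voxel pitch."""
    if radius_vox <= 0 or pitch_um <= 0:
        raise ValueError("radius and pitch must be positive")
    return radius_vox * pitch_um


@dataclass
class AngleField:
    """Per-triangle mean vicinity angles (degrees) of one mesh at one radius."""

    mesh_id: str
    radius_vox: float
    angles: np.ndarray
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=np.float64).reshape(-1)
        if self.angles.size and (self.angles.min() < 0 or self.angles.max() > 180):
            raise ValueError("angles must lie in [0, 180] degrees")
        if self.n_excluded < 0:
            raise ValueError("n_excluded must be >= 0")


@dataclass
class Histogram:
    """Probability-density histogram on [0, 180] degrees."""

    edges: np.ndarray
    density: np.ndarray
    bin_width_deg: float
    n_samples: int

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0


@dataclass
class RoughnessCalibration:
    """Baseline lognormal calibration for one (surface kind, radius) pair."""

    surface: str
    radius_vox: float
    histogram: Histogram
    mu: float
    sigma: float
    mu_p: float
    sigma_p: float
    T: float
    rss: float = float("nan")
    bin_width_deg: float = 0.5
    source_meshes: tuple[str, ...] = ()

    def to_json(self, path: str | Path) -> None:
        payload = {
            "surface": self.surface,
            "radius_vox": self.radius_vox,
            "mu": self.mu,
            "sigma": self.sigma,
            "mu_p": self.mu_p,
            "sigma_p": self.sigma_p,
            "T": self.T,
            "rss": self.rss,
            "bin_width_deg": self.bin_width_deg,
            "source_meshes": list(self.source_meshes),
            "histogram": {
                "edges": self.histogram.edges.tolist(),
                "density": self.histogram.density.tolist(),
                "n_samples": self.histogram.n_samples,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RoughnessCalibration":
        d = json.loads(Path(path).read_text())
        hist = Histogram(
            np.asarray(d["histogram"]["edges"]),
            np.asarray(d["histogram"]["density"]),
            d["bin_width_deg"],
            d["histogram"]["n_samples"],
        )
        return cls(
            surface=d["surface"], radius_vox=d["radius_vox"], histogram=hist,
            mu=d["mu"], sigma=d["sigma"], mu_p=d["mu_p"], sigma_p=d["sigma_p"],
            T=d["T"], rss=d["rss"], bin_width_deg=d["bin_width_deg"],
            source_meshes=tuple(d["source_meshes"]),
        )


@dataclass
class RoughnessResult:
    """Roughness score of one surface at one radius."""

    voi_id: str
    surface: str
    radius_vox: float
    R: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.R <= 1.0:
            raise ValueError("R must lie in [0, 1]")


# ---------------------------------------------------------------------------
# angle field


def mean_neighbor_angle(
    mesh: TriangleMesh, radius_vox: float, pitch_um: float | tuple = 14.609,
    mesh_id: str = "",
) -> AngleField:
    """Per-triangle mean normal angle over a metric vicinity.

    The vicinity of triangle ``t`` is every other triangle of the *same*
    edge-connected component whose centroid lies within
    ``radius_vox * pitch_um`` (Euclidean distance); restricting to the
    component prevents the vicinity from jumping across to a neighbouring
    bone.  Angles between oriented unit normals are taken in degrees.
    Triangles with an empty vicinity are excluded and counted.
    """
    if radius_vox <= 0:
        raise ValueError("radius must be positive")
    if mesh.n_triangles < 2:
        raise ValueError("mesh needs at least 2 triangles")
    if np.ndim(pitch_um) > 0:
        p = np.asarray(pitch_um, dtype=float)
        if p.max() - p.min() > 1e-9 * p.max():
            log.warning("anisotropic pitch %s: using the x pitch for the vicinity", pitch_um)
        pitch = float(p[-1])
    else:
        pitch = float(pitch_um)
    r_um = radius_vox * pitch
    centroids = mesh.centroids()
    normals = mesh.normals
    angles = np.full(mesh.n_triangles, np.nan)
    chunk = 512  # bounds the neighbor-list / distance-block memory
    for comp in np.unique(mesh.component_id):
        idx = np.flatnonzero(mesh.component_id == comp)
        cloc = centroids[idx]
        nloc = normals[idx]
        tree = cKDTree(cloc)
        # sparse tree queries win for small vicinities; when the ball covers
        # a large share of the component, blocked dense evaluation is faster
        sample = cloc[:: max(1, idx.size // 64)]
        est_pairs = float(
            np.mean(tree.query_ball_point(sample, r_um, return_length=True))
        ) * idx.size
        if est_pairs <= 3e7:
            for lo in range(0, idx.size, chunk):
                sel = slice(lo, min(lo + chunk, idx.size))
                neighbors = tree.query_ball_point(cloc[sel], r_um)
                for j, nb in zip(range(lo, idx.size), neighbors):
                    nb = [k for k in nb if k != j]
                    if not nb:
                        continue
                    d = np.clip(nloc[nb] @ nloc[j], -1.0, 1.0)
                    angles[idx[j]] = np.degrees(np.arccos(d)).mean()
        else:
            r2 = r_um * r_um
            sq = (cloc**2).sum(axis=1)
            for lo in range(0, idx.size, chunk):
                sel = slice(lo, min(lo + chunk, idx.size))
                d2 = sq[sel, None] + sq[None, :] - 2.0 * (cloc[sel] @ cloc.T)
                within = d2 <= r2
                for row, j in enumerate(range(lo, min(lo + chunk, idx.size))):
                    within[row, j] = False  # exclude the triangle itself
                counts = within.sum(axis=1)
                ang = np.degrees(
                    np.arccos(np.clip(nloc[sel] @ nloc.T, -1.0, 1.0))
                )
                sums = np.where(within, ang, 0.0).sum(axis=1)
                ok = counts > 0
                angles[idx[sel]] = np.where(ok, sums / np.maximum(counts, 1), np.nan)
    kept = angles[~np.isnan(angles)]
    return AngleField(
        mesh_id=mesh_id, radius_vox=radius_vox, angles=kept,
        n_excluded=int(mesh.n_triangles - kept.size),
    )


# ---------------------------------------------------------------------------
# calibration


def build_composite_histogram(
    angle_fields: list[AngleField], bin_width_deg: float = 0.5
) -> Histogram:
    """Pool angle fields (one sample per triangle, no per-mesh weighting)
    into a probability-density histogram on [0, 180]."""
    pooled = np.concatenate([f.angles for f in angle_fields]) if angle_fields else np.zeros(0)
    if pooled.size == 0:
        raise ValueError("no angles to histogram")
    edges = np.arange(0.0, 180.0 + bin_width_deg, bin_width_deg)
    density, edges = np.histogram(pooled, bins=edges, density=True)
    return Histogram(edges=edges, density=density, bin_width_deg=bin_width_deg,
                     n_samples=int(pooled.size))


def lognormal_pdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = np.exp(-((np.log(x[pos]) - mu) ** 2) / (2.0 * sigma**2)) / (
        x[pos] * sigma * np.sqrt(2.0 * np.pi)
    )
    return out


def fit_lognormal(
    histogram: Histogram, init: tuple[float, float] | str = "moments"
) -> tuple[float, float, float]:
    """Least-squares fit of the lognormal density to bin-centre densities.

    Initialization ``"moments"`` uses the log-moments of the histogram mass;
    an explicit ``(mu0, sigma0)`` pair may be given instead.  Returns
    ``(mu, sigma, rss)``.
    """
    nonempty = np.flatnonzero(histogram.density > 0)
    if nonempty.size < 2:
        raise ValueError("degenerate histogram: fewer than 2 non-empty bins")
    if nonempty.size < 5:
        raise ValueError("histogram has fewer than 5 non-empty bins")
    centers = histogram.centers
    if init == "moments":
        w = histogram.density[nonempty]
        lc = np.log(centers[nonempty])
        mu0 = float(np.average(lc, weights=w))
        var0 = float(np.average((lc - mu0) ** 2, weights=w))
        sigma0 = max(np.sqrt(var0), 1e-3)
    else:
        mu0, sigma0 = init
    try:
        popt, _ = curve_fit(
            lognormal_pdf, centers, histogram.density, p0=(mu0, sigma0),
            bounds=([-np.inf, 1e-9], [np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological histograms
        raise RuntimeError(f"lognormal fit did not converge: {exc}") from exc
    mu, sigma = float(popt[0]), float(popt[1])
    rss = float(((lognormal_pdf(centers, mu, sigma) - histogram.density) ** 2).sum())
    return mu, sigma, rss


def threshold_angle(mu: float, sigma: float) -> tuple[float, float, float]:
    """Closed-form lognormal PDF mean, SD, and threshold angle.

    ``mu_p = exp(mu + sigma^2/2)``,
    ``sigma_p = sqrt((exp(sigma^2) - 1) exp(2 mu + sigma^2))``,
    ``T = mu_p + 2 sigma_p``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    mu_p = float(np.exp(mu + sigma**2 / 2.0))
    sigma_p = float(np.sqrt((np.exp(sigma**2) - 1.0) * np.exp(2.0 * mu + sigma**2)))
    return mu_p, sigma_p, mu_p + 2.0 * sigma_p


def calibrate(
    angle_fields: list[AngleField], surface: str = "cs",
    bin_width_deg: float = 0.5, init: tuple[float, float] | str = "moments",
) -> RoughnessCalibration:
    """Composite histogram + lognormal fit + threshold angle, in one step."""
    radii = {f.radius_vox for f in angle_fields}
    if len(radii) != 1:
        raise ValueError(f"angle fields mix radii {sorted(radii)}")
    hist = build_composite_histogram(angle_fields, bin_width_deg)
    mu, sigma, rss = fit_lognormal(hist, init=init)
    mu_p, sigma_p, T = threshold_angle(mu, sigma)
    return RoughnessCalibration(
        surface=surface, radius_vox=radii.pop(), histogram=hist,
        mu=mu, sigma=sigma, mu_p=mu_p, sigma_p=sigma_p, T=T, rss=rss,
        bin_width_deg=bin_width_deg,
        source_meshes=tuple(f.mesh_id for f in angle_fields),
    )


# ---------------------------------------------------------------------------
# scoring


def roughness_score(
    field: AngleField, T: float, voi_id: str = "", surface: str = "cs"
) -> RoughnessResult:
    """R = relative frequency of triangles whose mean angle exceeds T."""
    if field.angles.size == 0:
        raise ValueError("empty angle field")
    R = float((field.angles > T).mean())
    return RoughnessResult(voi_id=voi_id, surface=surface,
                           radius_vox=field.radius_vox, R=R)


def multi_radius_profile(
    surfaces: SurfaceSet,
    calibrations: dict[tuple[str, float], "RoughnessCalibration | float"],
    radii: tuple[float, ...] = DEFAULT_RADII,
    pitch_um: float | tuple = 14.609,
    voi_id: str = "",
    kinds: tuple[str, ...] = SURFACE_KINDS,
) -> pd.DataFrame:
    """Score every surface kind at every radius against its calibration.

    ``calibrations`` maps ``(surface, radius)`` to a calibration (or a bare
    threshold angle).  Returns one row per combination; surfaces without
    triangles (e.g. ``is`` of a solid bone) yield ``R = NaN``.
    """
    for kind in kinds:
        for r in radii:
            if (kind, r) not in calibrations:
                raise KeyError(f"missing calibration for surface {kind!r} at radius {r}")
    rows = []
    for kind in kinds:
        mesh = surfaces.get(kind)
        for r in radii:
            cal = calibrations[(kind, r)]
            T = cal.T if isinstance(cal, RoughnessCalibration) else float(cal)
            if mesh.n_triangles < 2:
                rows.append(dict(voi_id=voi_id, surface=kind, radius_vox=r,
                                 R=np.nan, n_triangles=mesh.n_triangles,
                                 n_excluded=0, T=T))
                continue
            f = mean_neighbor_angle(mesh, r, pitch_um, mesh_id=f"{voi_id}:{kind}")
            res = roughness_score(f, T, voi_id=voi_id, surface=kind)
            rows.append(dict(voi_id=voi_id, surface=kind, radius_vox=r, R=res.R,
                             n_triangles=mesh.n_triangles,
                             n_excluded=f.n_excluded, T=T))
    return pd.DataFrame(rows)
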