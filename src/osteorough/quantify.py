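"""VOI volume and PET standardized-uptake-value quantification.

``V_VOI`` is the voxel count of the largest connected suprathreshold object
times the voxel volume; the threshold is the same per-VOI Otsu value used
for surface reconstruction, and a sweep over 80-120 % of it probes threshold
sensitivity.  SUV converts a voxelwise activity concentration (Bq/ml) into
grams per millilitre via ``SUV = concentration / injected_activity * body
weight``; within an (optional, axis-aligned) ellipsoidal VOI only voxels at
or above a fraction of the maximum SUV are kept, emulating the 40 %-of-max
segmentation used on fused PET/CT images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_io import ImageStack
from .voi import _structure

log = logging.getLogger(__name__)


def voxel_volume_mm3(pitch_um: float | tuple[float, float, float]) -> float:
    """Volume of one voxel in mm^3 from its pitch in µm."""
    p = np.atleast_1d(np.asarray(pitch_um, dtype=float))
    if (p <= 0).any():
        raise ValueError("pitch must be positive")
    if p.size == 1:
        p = np.repeat(p, 3)
    return float(np.prod(p) * 1e-9)


@dataclass
class VolumeResult:
    voi_id: str
    threshold: float
    n_voxels: int
    volume_mm3: float
    flags: tuple[str, ...] = ()


@dataclass
class SuvResult:
    voi_id: str
    threshold_frac: float
    mean_suv: float
    sd_suv: float
    n_voxels_used: int


def voi_volume(
    voi: ImageStack, threshold: float, connectivity: int = 26, voi_id: str = ""
) -> VolumeResult:
    """Volume of the biggest connected suprathreshold object in the VOI."""
    mask = voi.data > threshold
    if not mask.any():
        log.warning("%s: no suprathreshold voxels at threshold %s", voi_id, threshold)
        return VolumeResult(voi_id, float(threshold), 0, 0.0, flags=("empty",))
    labels, n = ndimage.label(mask, structure=_structure(connectivity))
    counts = np.bincount(labels.ravel())[1:]
    n_vox = int(counts.max())
    return VolumeResult(voi_id, float(threshold), n_vox,
                        n_vox * voxel_volume_mm3(voi.pitch_um))


def volume_threshold_sweep(
    voi: ImageStack,
    base_threshold: float,
    range_frac: tuple[float, float] = (0.80, 1.20),
    steps: int = 9,
    connectivity: int = 26,
    voi_id: str = "",
) -> pd.DataFrame:
    """V_VOI across a multiplicative threshold sweep (default 80-120 % of the
    Otsu threshold, 9 steps), sorted by threshold."""
    if base_threshold <= 0:
        raise ValueError("base_threshold must be positive")
    fracs = np.linspace(range_frac[0], range_frac[1], steps)
    rows = []
    for f in fracs:
        res = voi_volume(voi, f * base_threshold, connectivity, voi_id)
        rows.append(dict(voi_id=voi_id, frac=f, threshold=res.threshold,
                         n_voxels=res.n_voxels, volume_mm3=res.volume_mm3))
    return pd.DataFrame(rows).sort_values("threshold", ignore_index=True)


def ellipsoid_mask(
    shape: tuple[int, int, int],
    center: tuple[float, float, float],
    semi_axes: tuple[float, float, float],
) -> np.ndarray:
    """Axis-aligned ellipsoid membership mask ((z, y, x) voxel coordinates)."""
    if min(semi_axes) <= 0:
        raise ValueError("semi-axes must be positive")
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = center
    az, ay, ax = semi_axes
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def suv(
    activity_voi: ImageStack,
    injected_bq: float,
    body_weight_g: float,
    threshold_frac: float = 0.40,
    ellipsoid: tuple[tuple[float, float, float], tuple[float, float, float]] | None = None,
    voi_id: str = "",
) -> SuvResult:
    """Mean and SD of SUV over the brightest voxels of an activity volume.

    ``activity_voi`` holds activity concentration in Bq/ml.  Voxelwise
    ``SUV = concentration / injected_bq * body_weight_g`` (g/ml, assuming
    1 g/ml tissue density).  Analysis is restricted to an axis-aligned
    ellipsoid (``(center, semi_axes)`` in voxels) when given; voxels with
    ``SUV >= threshold_frac * max`` are retained.  The SD is the population
    SD of the retained voxels.  No decay correction is applied (fixed
    acquisition timing is assumed).
    """
    if injected_bq <= 0:
        raise ValueError("injected activity must be positive")
    if body_weight_g <= 0:
        raise ValueError("body weight must be positive")
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must lie in (0, 1)")
    suv_map = activity_voi.data.astype(np.float64) / injected_bq * body_weight_g
    if ellipsoid is not None:
        center, semi_axes = ellipsoid
        sel = ellipsoid_mask(suv_map.shape, center, semi_axes)
        if not sel.any():
            raise ValueError("ellipsoid VOI contains no voxels")
        values = suv_map[sel]
    else:
        values = suv_map.ravel()
    vmax = values.max()
    kept = values[values >= threshold_frac * vmax]
    return SuvResult(
        voi_id=voi_id, threshold_frac=float(threshold_frac),
        mean_suv=float(kept.mean()), sd_suv=float(kept.std(ddof=0)),
        n_voxels_used=int(kept.size),
    )
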