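"""Automatic hind-paw volume-of-interest extraction from whole CT stacks.

The pipeline mirrors an automated paw-finding procedure for small-animal CT:
the 16-bit scan is converted to 8-bit, downsampled in-plane, binarized at a
fixed low threshold so bone stays connected, and 3D connected components are
boxed.  Small objects and objects outside the expected z-range are discarded,
the two paws are picked as the left-most and right-most candidates in the
lower image half, each paw is trimmed at the slice where the calcaneus starts
to appear (a sustained jump in the per-slice 2D component count), and the
resulting boxes are upsampled, padded, and cut from the original stack.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_io import ImageStack, downsample_xy, to_8bit

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned voxel box with half-open intervals and a foreground count."""

    z0: int
    z1: int
    y0: int
    y1: int
    x0: int
    x1: int
    n_foreground: int = 1

    def __post_init__(self) -> None:
        for a0, a1 in ((self.z0, self.z1), (self.y0, self.y1), (self.x0, self.x1)):
            if not 0 <= a0 < a1:
                raise ValueError(f"invalid interval [{a0}, {a1})")
        if self.n_foreground < 1:
            raise ValueError("n_foreground must be >= 1")
        if self.n_foreground > self.volume:
            raise ValueError("n_foreground exceeds box volume")

    @property
    def volume(self) -> int:
        return (self.z1 - self.z0) * (self.y1 - self.y0) * (self.x1 - self.x0)

    @property
    def z_extent(self) -> int:
        return self.z1 - self.z0

    def center(self) -> tuple[float, float, float]:
        return ((self.z0 + self.z1) / 2, (self.y0 + self.y1) / 2, (self.x0 + self.x1) / 2)

    def slices(self) -> tuple[slice, slice, slice]:
        return (slice(self.z0, self.z1), slice(self.y0, self.y1), slice(self.x0, self.x1))


def box_iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two voxel boxes."""
    iz = max(0, min(a.z1, b.z1) - max(a.z0, b.z0))
    iy = max(0, min(a.y1, b.y1) - max(a.y0, b.y0))
    ix = max(0, min(a.x1, b.x1) - max(a.x0, b.x0))
    inter = iz * iy * ix
    union = a.volume + b.volume - inter
    return inter / union if union else 0.0


@dataclass
class VoiResult:
    """One extracted paw VOI in original-resolution coordinates."""

    side: str
    box: BoundingBox  # after upsampling, endpoint trim, and padding
    core_box: BoundingBox  # same but without padding
    voi: ImageStack  # 16-bit crop of the original stack
    endpoint_z: int | None
    flags: list[str] = field(default_factory=list)


def binarize(stack8: ImageStack, threshold: int = 75) -> np.ndarray:
    """Foreground mask: intensity >= threshold (inclusive at the boundary)."""
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold {threshold} outside [0, 255]")
    if stack8.bit_depth != 8:
        raise ValueError("binarize expects an 8-bit stack")
    return stack8.data >= threshold


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def connected_components_3d(mask: np.ndarray, connectivity: int = 26) -> list[BoundingBox]:
    """Bounding boxes of maximal 3D connected foreground sets.

    26-connectivity (the volumetric extension of in-plane 8-connectivity) is
    the default.  Boxes are sorted by foreground count, largest first.
    """
    labels, n = ndimage.label(mask, structure=_structure(connectivity))
    if n == 0:
        return []
    counts = np.bincount(labels.ravel())[1:]
    boxes = []
    for lab, sl in enumerate(ndimage.find_objects(labels), start=1):
        boxes.append(
            BoundingBox(
                sl[0].start, sl[0].stop, sl[1].start, sl[1].stop, sl[2].start, sl[2].stop,
                n_foreground=int(counts[lab - 1]),
            )
        )
    boxes.sort(key=lambda b: -b.n_foreground)
    return boxes


def filter_candidates(
    boxes: list[BoundingBox],
    min_pixels: int = 85000,
    z_min_cut: int = 300,
    z_extent_cut: int = 300,
) -> list[BoundingBox]:
    """Keep paw candidates: strictly more than ``min_pixels`` foreground
    voxels, starting at ``z0 >= z_min_cut``, spanning at least ``z_extent_cut``
    slices.  The defaults target full-resolution 2048x2048 acquisitions."""
    kept = []
    for b in boxes:
        ok = b.n_foreground > min_pixels and b.z0 >= z_min_cut and b.z_extent >= z_extent_cut
        log.debug(
            "candidate %s: n=%d z0=%d extent=%d -> %s",
            b, b.n_foreground, b.z0, b.z_extent, "kept" if ok else "dropped",
        )
        if ok:
            kept.append(b)
    return kept


def select_left_right(
    boxes: list[BoundingBox], stack_dims: tuple[int, int, int]
) -> tuple[BoundingBox, BoundingBox]:
    """Pick the left and right paw among candidates in the lower image half.

    Candidates whose box y-centre lies in the lower half (y >= dim_y / 2) are
    ordered by x-centre; the smallest is the left paw, the largest the right.
    Equal x-centres are broken by assigning the larger object first.
    """
    dim_y = stack_dims[1]
    lower = [b for b in boxes if (b.y0 + b.y1) / 2 >= dim_y / 2]
    if len(lower) < 2:
        raise ValueError(
            f"found {len(lower)} paw candidate(s) in the lower image half; need 2"
        )
    ordered = sorted(lower, key=lambda b: ((b.x0 + b.x1) / 2, -b.n_foreground))
    return ordered[0], ordered[-1]


def endpoint_from_counts(counts: list[int] | np.ndarray, run_length: int = 5) -> int | None:
    """Endpoint rule on a per-slice component-count sequence.

    Scanning distal to proximal, the endpoint is the first slice of the first
    run of at least ``run_length`` equal counts that exceeds the count of the
    immediately preceding run (the calcaneus appearing beside the tibia).
    Shorter count excursions are ignored.  Returns ``None`` if no such run
    exists.
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        return None
    # run-length encode
    change = np.flatnonzero(np.diff(counts)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [counts.size]))
    for i in range(1, len(starts)):
        if ends[i] - starts[i] >= run_length and counts[starts[i]] > counts[starts[i - 1]]:
            return int(starts[i])
    return None


def find_paw_endpoint(
    mask: np.ndarray, box: BoundingBox, run_length: int = 5
) -> int | None:
    """Absolute z index where the calcaneus appears inside ``box``.

    Counts 2D 8-connected foreground components per slice within the box and
    applies :func:`endpoint_from_counts`.  Returns ``None`` when no sustained
    count increase exists (callers should flag the VOI).
    """
    sub = mask[box.slices()]
    if not sub.any():
        raise ValueError("empty box: no foreground voxels")
    s2 = np.ones((3, 3), dtype=bool)
    counts = [ndimage.label(sub[z], structure=s2)[1] for z in range(sub.shape[0])]
    idx = endpoint_from_counts(counts, run_length)
    return None if idx is None else box.z0 + idx


def finalize_voi(
    box: BoundingBox,
    endpoint_z: int | None,
    original: ImageStack,
    ds_factor: int = 4,
    pad: tuple[int, int, int] = (20, 20, 10),
    side: str = "",
) -> VoiResult:
    """Upsample a candidate box to original x/y coordinates, trim its z-range
    at the detected endpoint, pad on each side, clamp, and cut the VOI out of
    the original 16-bit stack.

    ``box`` carries downsampled x/y coordinates but full-resolution z
    (downsampling is in-plane only); ``pad`` is ``(x, y, z)`` voxels applied
    on both sides of each axis.
    """
    pad_x, pad_y, pad_z = pad
    dz, dy, dx = original.shape
    flags: list[str] = []
    z1 = box.z1
    if endpoint_z is not None:
        if not box.z0 < endpoint_z <= box.z1:
            raise ValueError("endpoint outside candidate box")
        z1 = endpoint_z
    else:
        flags.append("no-endpoint")
    core = BoundingBox(
        box.z0, z1,
        box.y0 * ds_factor, box.y1 * ds_factor,
        box.x0 * ds_factor, box.x1 * ds_factor,
        n_foreground=box.n_foreground,
    )
    z0p, z1p = max(0, core.z0 - pad_z), min(dz, core.z1 + pad_z)
    y0p, y1p = max(0, core.y0 - pad_y), min(dy, core.y1 + pad_y)
    x0p, x1p = max(0, core.x0 - pad_x), min(dx, core.x1 + pad_x)
    if z0p >= z1p or y0p >= y1p or x0p >= x1p:
        raise ValueError("VOI empty after clamping to the stack bounds")
    padded = BoundingBox(z0p, z1p, y0p, y1p, x0p, x1p, n_foreground=box.n_foreground)
    crop = ImageStack(
        original.data[padded.slices()].copy(),
        pitch_um=original.pitch_um,
        bit_depth=original.bit_depth,
    )
    return VoiResult(side=side, box=padded, core_box=core, voi=crop,
                     endpoint_z=endpoint_z, flags=flags)


def extract_vois(
    stack: ImageStack,
    threshold: int = 75,
    ds_factor: int = 4,
    min_pixels: int = 85000,
    z_min_cut: int = 300,
    z_extent_cut: int = 300,
    run_length: int = 5,
    pad: tuple[int, int, int] = (20, 20, 10),
    connectivity: int = 26,
) -> dict[str, VoiResult]:
    """Run the full paw-VOI pipeline on a 16-bit CT stack.

    Returns ``{"left": VoiResult, "right": VoiResult}``.  The filter
    constants default to full-resolution scans and must be scaled for
    smaller scenes.
    """
    stack8 = to_8bit(stack) if stack.bit_depth == 16 else stack
    small = downsample_xy(stack8, ds_factor)
    mask = small.data >= threshold
    boxes = connected_components_3d(mask, connectivity=connectivity)
    candidates = filter_candidates(boxes, min_pixels, z_min_cut, z_extent_cut)
    left, right = select_left_right(candidates, small.shape)
    out = {}
    for side, b in (("left", left), ("right", right)):
        ep = find_paw_endpoint(mask, b, run_length=run_length)
        out[side] = finalize_voi(b, ep, stack, ds_factor=ds_factor, pad=pad, side=side)
        log.info("%s paw: box=%s endpoint=%s flags=%s", side, out[side].box, ep, out[side].flags)
    return out


def detection_accuracy(n_correct: int, n_total: int) -> float:
    """Per-paw detection accuracy as a percentage, rounded to one decimal."""
    if n_total <= 0 or not 0 <= n_correct <= n_total:
        raise ValueError("need 0 <= n_correct <= n_total, n_total > 0")
    return round(100.0 * n_correct / n_total, 1)
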