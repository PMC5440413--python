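"""Synthetic bone phantoms with voxel-level ground truth.

Stands in for animal µCT/PET data: hollow cortical "bones" (tubes with a
medullary cavity) whose inner and outer wall radii are independently
modulated by band-limited Gaussian noise fields of controllable amplitude
and correlation length, plus multi-object scan scenes that emulate a
two-hind-paw acquisition layout (paw objects in the lower left/right, small
distractor objects elsewhere) for end-to-end VOI-extraction tests.

All ground truths come from independent per-voxel geometry tests, never from
the analysis pipeline itself; a fixed seed makes every phantom byte-for-byte
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import gaussian_filter

from .image_io import ImageStack
from .voi import BoundingBox

#: Default 16-bit intensity model: cortical bone vs soft tissue / air.
BONE_MEAN, BONE_SD = 20000.0, 500.0
BG_MEAN, BG_SD = 2000.0, 500.0


@dataclass
class Perturbation:
    """Radial wall perturbation: band-limited noise on the (theta, z) surface."""

    amplitude_vox: float = 0.0
    correlation_length_vox: float = 3.0

    def __post_init__(self) -> None:
        if self.amplitude_vox < 0 or self.correlation_length_vox <= 0:
            raise ValueError("amplitude must be >= 0 and correlation length > 0")


@dataclass
class PhantomSpec:
    """Geometry, perturbation, and intensity model of one phantom."""

    kind: str = "tube"  # tube | solid_cylinder | sphere | scene
    shape: tuple[int, int, int] = (60, 64, 64)  # (z, y, x)
    outer_radius: float = 20.0
    inner_radius: float = 13.0
    z_margin: int = 0  # background slabs above/below the object
    capped: bool = False  # solid end caps enclose the cavity
    cap_thickness: int = 3
    cap_style: str = "flat"  # "flat" discs or rounded "dome" ends
    perturb: dict[str, Perturbation] = dc_field(default_factory=dict)  # "outer"/"inner"
    bone_mean: float = BONE_MEAN
    bone_sd: float = BONE_SD
    bg_mean: float = BG_MEAN
    bg_sd: float = BG_SD
    pitch_um: float = 14.609
    seed: int = 0

    def __post_init__(self) -> None:
        for key in self.perturb:
            if key not in ("outer", "inner"):
                raise ValueError(f"unknown perturbation surface {key!r}")
            if isinstance(self.perturb[key], tuple):
                self.perturb[key] = Perturbation(*self.perturb[key])
        if self.kind in ("tube",):
            if not 0 <= self.inner_radius < self.outer_radius:
                raise ValueError("need 0 <= inner radius < outer radius")
            wall = self.outer_radius - self.inner_radius
            amp = max((p.amplitude_vox for p in self.perturb.values()), default=0.0)
            if amp >= wall / 2.0:
                raise ValueError("perturbation amplitude must stay below wall/2")
        if self.outer_radius * 2 + 4 > min(self.shape[1], self.shape[2]):
            raise ValueError("outer radius does not fit inside the x/y extent")
        if 2 * self.z_margin + (2 * self.cap_thickness if self.capped else 0) >= self.shape[0]:
            raise ValueError("z margin / caps leave no tube interior")


@dataclass
class TubeTruth:
    """Independent per-voxel ground truth of a tube phantom."""

    foreground: np.ndarray
    cavity: np.ndarray
    n_foreground: int
    n_cavity: int


def _radial_noise_field(
    n_z: int,
    n_theta: int,
    pert: Perturbation,
    radius: float,
    rng: np.random.Generator,
    clip_vox: float = np.inf,
) -> np.ndarray:
    """Band-limited noise on the unrolled (z, theta) surface.

    Correlation length is in voxels of arc length / z distance; theta wraps.
    The field is scaled to SD = amplitude and its excursions are clipped at
    ``clip_vox`` (half the wall thickness minus half a voxel) so that rare
    extremes can never breach the cortical wall."""
    if pert.amplitude_vox == 0.0:
        return np.zeros((n_z, n_theta))
    raw = rng.standard_normal((n_z, n_theta))
    arc_per_bin = 2.0 * np.pi * max(radius, 1.0) / n_theta
    sigma = (pert.correlation_length_vox, pert.correlation_length_vox / arc_per_bin)
    smooth = gaussian_filter(raw, sigma=sigma, mode=("nearest", "wrap"))
    sd = smooth.std()
    if sd == 0:
        return np.zeros((n_z, n_theta))
    return np.clip(smooth * (pert.amplitude_vox / sd), -clip_vox, clip_vox)


def make_tube_phantom(spec: PhantomSpec) -> tuple[ImageStack, TubeTruth]:
    """Voxelize a hollow (or solid, ``inner_radius = 0``) cylinder.

    The wall is ``inner <= r <= outer`` with per-surface radial modulation
    sampled from the noise field at each voxel's (z, theta); the cavity is
    ``r < inner``.  With ``capped`` the cavity is fully enclosed at both z
    ends, either by flat solid discs (``cap_style="flat"``) or by rounded
    dome ends (``cap_style="dome"``, the bone-like choice that avoids flat
    facets); otherwise an open canal spans the object's z range.  Gaussian
    intensity noise is added on top of the two-level intensity model and
    clipped to 16 bits.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    n_theta = 256
    wall = spec.outer_radius - spec.inner_radius
    clip = max(wall / 2.0 - 0.5, 0.5)
    out_field = _radial_noise_field(
        nz, n_theta, spec.perturb.get("outer", Perturbation()), spec.outer_radius, rng,
        clip_vox=clip,
    )
    in_field = _radial_noise_field(
        nz, n_theta,
        spec.perturb.get("inner", Perturbation()) if spec.inner_radius > 0
        else Perturbation(),  # a solid rod has no inner wall to perturb
        spec.inner_radius, rng, clip_vox=clip,
    )
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    rr = np.hypot(yy - cy, xx - cx)
    theta_idx = (
        np.round((np.arctan2(yy - cy, xx - cx) + np.pi) / (2.0 * np.pi) * n_theta).astype(int)
        % n_theta
    )
    z0, z1 = spec.z_margin, nz - spec.z_margin
    fg = np.zeros(spec.shape, dtype=bool)
    cav = np.zeros(spec.shape, dtype=bool)
    cap_lo = z0 + spec.cap_thickness if spec.capped else z0
    cap_hi = z1 - spec.cap_thickness if spec.capped else z1

    def _dome_u(z: int, inset: float = 0.0) -> float:
        """Normalized depth into the end domes (0 on the cylinder part)."""
        if z < cap_lo:
            return (cap_lo - z - 0.5 + inset) / spec.cap_thickness
        if z >= cap_hi:
            return (z - cap_hi + 0.5 + inset) / spec.cap_thickness
        return 0.0

    for z in range(z0, z1):
        r_out = spec.outer_radius + out_field[z, theta_idx]
        r_in = spec.inner_radius + in_field[z, theta_idx]
        if spec.capped and spec.cap_style == "dome":
            s_out = np.sqrt(max(0.0, 1.0 - _dome_u(z) ** 2))
            # cavity dome is inset so the wall keeps its thickness at the tip
            s_in = np.sqrt(max(0.0, 1.0 - _dome_u(z, inset=3.0) ** 2))
            r_out = spec.outer_radius * s_out + out_field[z, theta_idx]
            r_in = (
                spec.inner_radius * s_in + in_field[z, theta_idx]
                if s_in > 0 else np.full_like(r_out, -1.0)
            )
            fg[z] = (rr >= r_in) & (rr <= r_out)
            cav[z] = rr < r_in
        elif spec.capped and not (cap_lo <= z < cap_hi):
            fg[z] = rr <= r_out
        else:
            fg[z] = (rr >= r_in) & (rr <= r_out)
            cav[z] = rr < r_in
    intensity = np.where(fg, spec.bone_mean, spec.bg_mean) + rng.normal(
        0.0, 1.0, spec.shape
    ) * np.where(fg, spec.bone_sd, spec.bg_sd)
    data = np.clip(np.round(intensity), 0, 65535).astype(np.uint16)
    stack = ImageStack(data, pitch_um=(spec.pitch_um,) * 3, bit_depth=16)
    return stack, TubeTruth(fg, cav, int(fg.sum()), int(cav.sum()))


def make_solid_cylinder(spec: PhantomSpec) -> tuple[ImageStack, TubeTruth]:
    """Solid cylinder: a tube with zero inner radius (no cavity)."""
    import dataclasses

    return make_tube_phantom(dataclasses.replace(spec, inner_radius=0.0, perturb=dict(spec.perturb)))


def make_sphere_phantom(
    radius: float = 14.0, shape: tuple[int, int, int] = (40, 40, 40),
    seed: int = 0, pitch_um: float = 14.609,
) -> tuple[ImageStack, np.ndarray]:
    """Solid sphere (for normal-orientation checks); returns stack + mask."""
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    cz, cy, cx = (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx]
    fg = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    intensity = np.where(fg, BONE_MEAN, BG_MEAN) + rng.normal(0, 1, shape) * np.where(
        fg, BONE_SD, BG_SD
    )
    data = np.clip(np.round(intensity), 0, 65535).astype(np.uint16)
    return ImageStack(data, pitch_um=(pitch_um,) * 3, bit_depth=16), fg


# ---------------------------------------------------------------------------
# scan scenes


#: Extraction parameters scaled to the default scene size (the full-scan
#: defaults target 2048 x 2048 acquisitions and are proportionally reduced).
SCENE_PARAMS = dict(
    threshold=75, ds_factor=2, min_pixels=2000, z_min_cut=30, z_extent_cut=40,
    run_length=5, pad=(6, 6, 4), connectivity=26,
)


def make_scan_scene(
    seed: int = 0,
    shape: tuple[int, int, int] = (200, 192, 192),
    n_distractors: int = 3,
    distractor_size: int = 14,
    rod_width: int = 24,
    pitch_um: float = 14.609,
) -> tuple[ImageStack, dict]:
    """A two-paw scan scene with distractors, plus ground truth.

    Each "paw" is a pair of parallel rods along z in the lower-left /
    lower-right image region: the main rod spans the whole object, the
    second rod appears at the true endpoint slice (the calcaneus appearing
    beside the tibia), and a proximal bridge keeps the pair 3D-connected.
    Distractor cubes sit in the upper image half and stay below the
    foreground-pixel filter; one large low-z slab exercises the z-space
    filters.  Object placements are even-valued so block averaging cannot
    blur the object boundary.

    Returns the 16-bit stack and a truth dict with, per side, the core
    bounding box (trimmed at the true endpoint), the full object box, the
    endpoint slice, and the recommended scaled extraction parameters.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    fg = np.zeros(shape, dtype=bool)

    def even(lo: int, hi: int) -> int:
        return int(rng.integers(lo // 2, hi // 2 + 1)) * 2

    z_start, z_stop = 50, nz - 10
    gap = 8
    span = 2 * rod_width + gap
    truth: dict = {"params": dict(SCENE_PARAMS), "sides": {}}
    # placement windows leave a >= 8-voxel gap between the two paws so they
    # can never merge into one 26-connected component
    for side, x_lo, x_hi in (
        ("left", 16, 40),
        ("right", nx - span - 32, nx - span - 16),
    ):
        x0 = even(x_lo, x_hi)
        y0 = even(120, ny - rod_width - 20)
        z_ep = even(100, 140)
        fg[z_start:z_stop, y0 : y0 + rod_width, x0 : x0 + rod_width] = True
        x2 = x0 + rod_width + gap
        fg[z_ep:z_stop, y0 : y0 + rod_width, x2 : x2 + rod_width] = True
        fg[z_stop - 8 : z_stop, y0 : y0 + rod_width, x0 : x0 + span] = True  # bridge
        n_core = rod_width * rod_width * (z_ep - z_start)
        truth["sides"][side] = {
            "core_box": BoundingBox(z_start, z_ep, y0, y0 + rod_width, x0, x0 + span,
                                    n_foreground=n_core),
            "full_box": BoundingBox(z_start, z_stop, y0, y0 + rod_width, x0, x0 + span,
                                    n_foreground=1),
            "endpoint_z": z_ep,
        }
    # large slab failing the z filters (z0 < z_min_cut, extent < z_extent_cut)
    fg[4:24, 20:60, 60:120] = True
    for _ in range(n_distractors):
        dz0 = int(rng.integers(40, nz - 40 - distractor_size))
        dy0 = int(rng.integers(10, 70 - distractor_size))
        dx0 = int(rng.integers(10, nx - 10 - distractor_size))
        fg[dz0 : dz0 + distractor_size, dy0 : dy0 + distractor_size,
           dx0 : dx0 + distractor_size] = True

    intensity = np.where(fg, BONE_MEAN, BG_MEAN) + rng.normal(0, 1, shape) * np.where(
        fg, BONE_SD, BG_SD
    )
    data = np.clip(np.round(intensity), 0, 65535).astype(np.uint16)
    return ImageStack(data, pitch_um=(pitch_um,) * 3, bit_depth=16), truth


def sample_lognormal(mu: float, sigma: float, n: int, seed: int | None = None) -> np.ndarray:
    """Seeded pseudo-random draws from the lognormal angle density."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.random.default_rng(seed).lognormal(mean=mu, sigma=sigma, size=n)
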