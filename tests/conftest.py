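"""Shared fixtures: phantom kits and baseline roughness calibrations.

Session-scoped so the expensive phantom -> surface -> angle-field chain is
built once and reused by the unit, property, and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from osteorough import phantoms, roughness, surface

SURFACES = ("cs", "os", "is")
BASELINE_SEEDS = (100, 101, 102, 103)
CAL_RADIUS = 3


DOME_TUBE = dict(shape=(72, 64, 64), z_margin=2, capped=True, cap_style="dome",
                 cap_thickness=8)

#: Natural surface texture of control bones (amplitude in voxels, correlation
#: length in voxels): healthy cortical surfaces are not perfectly smooth.
CONTROL_TEXTURE = 0.5
CONTROL_CORR = 2.0


def make_tube(seed: int, amp_outer: float = CONTROL_TEXTURE,
              amp_inner: float = CONTROL_TEXTURE, corr: float = CONTROL_CORR,
              **kw) -> tuple:
    """Standard study-condition bone: dome-capped hollow tube, 72x64x64,
    outer r=20, inner r=13, fully enclosed, with control-level texture."""
    perturb = {}
    if amp_outer:
        perturb["outer"] = phantoms.Perturbation(amp_outer, corr)
    if amp_inner:
        perturb["inner"] = phantoms.Perturbation(amp_inner, corr)
    params = dict(DOME_TUBE)
    params.update(kw)
    spec = phantoms.PhantomSpec(seed=seed, perturb=perturb, **params)
    return phantoms.make_tube_phantom(spec)


def tube_surfaces(seed: int, amp_outer: float = CONTROL_TEXTURE,
                  amp_inner: float = CONTROL_TEXTURE, corr: float = CONTROL_CORR,
                  **kw):
    stack, _ = make_tube(seed, amp_outer, amp_inner, corr, **kw)
    return stack, surface.split_surfaces(stack, provenance=f"tube{seed}")


def brute_force_mean_angles(mesh, radius_vox: float, pitch_um: float) -> np.ndarray:
    """All-pairs O(n^2) oracle for the vicinity mean angle (no spatial index)."""
    c = mesh.centroids()
    n = mesh.normals
    r = radius_vox * pitch_um
    d2 = ((c[:, None, :] - c[None, :, :]) ** 2).sum(-1)
    same = mesh.component_id[:, None] == mesh.component_id[None, :]
    within = (d2 <= r * r) & same
    np.fill_diagonal(within, False)
    out = np.full(len(c), np.nan)
    ang = np.degrees(np.arccos(np.clip(n @ n.T, -1.0, 1.0)))
    for i in range(len(c)):
        nb = within[i]
        if nb.any():
            out[i] = ang[i, nb].mean()
    return out


@pytest.fixture(scope="session")
def baseline_kit():
    """Control-bone baselines: per-surface angle fields at r=3, calibrations,
    and in-sample mean control roughness (the pre-perturbation reference)."""
    fields = {k: [] for k in SURFACES}
    for seed in BASELINE_SEEDS:
        stack, sset = tube_surfaces(seed)
        for k in SURFACES:
            mesh = sset.get(k)
            fields[k].append(
                roughness.mean_neighbor_angle(mesh, CAL_RADIUS, stack.pitch_um,
                                              mesh_id=f"base{seed}:{k}")
            )
    cals = {k: roughness.calibrate(fields[k], surface=k) for k in SURFACES}
    smooth_R = {
        k: float(np.mean([roughness.roughness_score(f, cals[k].T).R for f in fields[k]]))
        for k in SURFACES
    }
    return {"fields": fields, "calibrations": cals, "smooth_R": smooth_R}


SMALL_TUBE = dict(shape=(44, 40, 40), outer_radius=11.0, inner_radius=6.5,
                  cap_thickness=6, amp_outer=0.0, amp_inner=0.0)


@pytest.fixture(scope="session")
def small_tube_profile_kit():
    """Small *smooth* tubes (amplitude 0) for the full 3-surface x 6-radius
    profile matrix: two baselines for calibration plus one probe."""
    radii = roughness.DEFAULT_RADII
    fields: dict[tuple[str, float], list] = {(k, r): [] for k in SURFACES for r in radii}
    for seed in (200, 201):
        stack, sset = tube_surfaces(seed, **SMALL_TUBE)
        for k in SURFACES:
            mesh = sset.get(k)
            for r in radii:
                fields[(k, r)].append(
                    roughness.mean_neighbor_angle(mesh, r, stack.pitch_um,
                                                  mesh_id=f"sm{seed}:{k}")
                )
    cals = {key: roughness.calibrate(fl, surface=key[0]) for key, fl in fields.items()}
    probe_stack, probe = tube_surfaces(202, **SMALL_TUBE)
    return {"calibrations": cals, "probe": probe, "pitch": probe_stack.pitch_um,
            "radii": radii}
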