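"""Surface reconstruction: Otsu, marching cubes, cleaning, os/is separation."""

import numpy as np
import pytest

from osteorough import phantoms, surface
from osteorough.image_io import ImageStack
from osteorough.surface import (
    cavity_mask,
    clean_mesh,
    face_components,
    marching_cubes,
    otsu_threshold,
    split_surfaces,
)

from conftest import make_tube


def brute_force_otsu(data):
    """Exhaustive between-class-variance scan over every cut point."""
    vals = np.sort(np.unique(np.round(data).astype(int)))
    best, best_ts = -1.0, []
    flat = np.round(data).astype(int).ravel()
    for t in range(vals.min(), vals.max()):
        lo, hi = flat[flat <= t], flat[flat > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / flat.size, hi.size / flat.size
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best + 1e-12:
            best, best_ts = v, [t]
        elif v >= best - 1e-12:
            best_ts.append(t)
    return (best_ts[0] + best_ts[-1]) / 2.0


class TestOtsu:
    def test_two_delta_peaks_plateau_midpoint(self):
        data = np.array([10] * 50 + [200] * 50).reshape(2, 5, 10)
        st = ImageStack(data.astype(np.uint16), (1, 1, 1))
        t = otsu_threshold(st)
        assert t == pytest.approx(brute_force_otsu(data))
        assert t == pytest.approx((10 + 199) / 2.0)  # plateau spans every cut

    def test_constant_image_errors(self):
        with pytest.raises(ValueError, match="constant"):
            otsu_threshold(ImageStack(np.full((2, 2, 2), 7, dtype=np.uint16), (1, 1, 1)))

    def test_phantom_voi_separates_modes(self):
        stack, truth = make_tube(5)
        t = otsu_threshold(stack)
        assert 2000 < t <= 20000

    def test_matches_skimage_on_phantom(self):
        # independent cross-check: both thresholds must achieve the optimal
        # between-class variance (the optimum is a plateau across the gap
        # between the modes; scikit-image picks one point, we its midpoint)
        from skimage.filters import threshold_otsu

        stack, _ = make_tube(5)
        t = otsu_threshold(stack)
        t_ref = threshold_otsu(stack.data, nbins=int(stack.data.max()) + 1)

        def between_class_variance(data, cut):
            lo, hi = data[data <= cut], data[data > cut]
            w0, w1 = lo.size / data.size, hi.size / data.size
            return w0 * w1 * (lo.mean() - hi.mean()) ** 2

        flat = stack.data.ravel().astype(np.float64)
        v, v_ref = between_class_variance(flat, t), between_class_variance(flat, t_ref)
        assert v == pytest.approx(v_ref, rel=1e-6)

    def test_matches_exhaustive_scan_small(self):
        rng = np.random.default_rng(11)
        data = np.concatenate([rng.integers(0, 40, 60), rng.integers(120, 200, 40)])
        st = ImageStack(data.reshape(4, 5, 5).astype(np.uint16), (1, 1, 1))
        assert otsu_threshold(st) == pytest.approx(brute_force_otsu(data), abs=1e-9)


def enclosed_volume(mesh):
    """Signed-volume oracle (divergence theorem; positive for outward normals)."""
    v = mesh.vertices[mesh.faces]
    return float(np.einsum("ij,ij->i", v[:, 0], np.cross(v[:, 1], v[:, 2])).sum() / 6.0)


def edge_counts(faces):
    e = np.sort(np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1)
    _, c = np.unique(e, axis=0, return_counts=True)
    return c


class TestMarchingCubes:
    def test_single_voxel_closed_genus0(self):
        f = np.zeros((3, 3, 3))
        f[1, 1, 1] = 1.0
        mesh = marching_cubes(f, 0.5, pitch_um=(1, 1, 1))
        assert len(np.unique(mesh.component_id)) == 1
        assert (edge_counts(mesh.faces) == 2).all()
        n_edges = len(np.unique(np.sort(np.concatenate(
            [mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]]), axis=1), axis=0))
        chi = len(mesh.vertices) - n_edges + mesh.n_triangles
        assert chi == 2

    def test_solid_cube_volume_bounds(self):
        f = np.zeros((12, 12, 12))
        f[1:11, 1:11, 1:11] = 1.0
        mesh = marching_cubes(f, 0.5, pitch_um=(1, 1, 1))
        vol = enclosed_volume(mesh)
        assert 9**3 <= vol <= 10**3

    def test_hollow_capped_tube_two_components(self):
        stack, _ = make_tube(2, shape=(66, 64, 64), z_margin=3, capped=True)
        mesh = marching_cubes(stack, otsu_threshold(stack))
        assert len(np.unique(mesh.component_id)) == 2

    def test_all_meshes_closed(self):
        stack, _ = make_tube(3)
        mesh = marching_cubes(stack, otsu_threshold(stack))
        assert (edge_counts(mesh.faces) == 2).all()

    def test_sphere_normals_outward(self):
        stack, _ = phantoms.make_sphere_phantom(radius=12.0, seed=4)
        mesh = marching_cubes(stack, otsu_threshold(stack))
        center = (np.array(stack.shape) - 1) / 2.0 * np.array(stack.pitch_um)
        d = np.einsum("ij,ij->i", mesh.normals, mesh.centroids() - center)
        assert (d > 0).mean() >= 0.999

    def test_no_foreground_errors(self):
        with pytest.raises(ValueError, match="suprathreshold"):
            marching_cubes(np.zeros((3, 3, 3)), 0.5, pitch_um=(1, 1, 1))

    def test_physical_coordinates(self):
        f = np.zeros((3, 3, 3))
        f[1, 1, 1] = 1.0
        mesh = marching_cubes(f, 0.5, pitch_um=(2.0, 3.0, 4.0))
        np.testing.assert_allclose(mesh.vertices.mean(axis=0), [2.0, 3.0, 4.0], atol=1e-9)


class TestCleanMesh:
    def _two_component_mesh(self):
        f = np.zeros((3, 3, 7))
        f[1, 1, 1] = 1.0
        f[1, 1, 3:6] = 1.0
        return marching_cubes(f, 0.5, pitch_um=(1, 1, 1))

    def test_duplicate_vertex_merged(self):
        mesh = self._two_component_mesh()
        verts = np.vstack([mesh.vertices, mesh.vertices[0]])
        faces = mesh.faces.copy()
        dup = surface.build_mesh(verts, faces)
        cleaned = clean_mesh(dup, mode="min_triangles", cutoff=0)
        assert len(cleaned.vertices) == len(mesh.vertices)
        assert cleaned.n_triangles == mesh.n_triangles

    def test_keep_largest(self):
        mesh = self._two_component_mesh()
        sizes = np.bincount(mesh.component_id)
        cleaned = clean_mesh(mesh, mode="keep_largest")
        assert cleaned.n_triangles == sizes.max()
        assert len(np.unique(cleaned.component_id)) == 1

    def test_min_triangles_paper_scale_cutoff(self):
        # a component above the artifact cutoff is retained
        mesh = self._two_component_mesh()
        big = int(np.bincount(mesh.component_id).max())
        kept = clean_mesh(mesh, mode="min_triangles", cutoff=big)
        assert kept.n_triangles == big
        with pytest.raises(ValueError, match="removed every"):
            clean_mesh(mesh, mode="min_triangles", cutoff=big + 1)


class TestSplitSurfaces:
    def test_solid_cylinder_no_cavity(self):
        stack, _ = make_tube(6, inner_radius=0.0)
        ss = split_surfaces(stack)
        assert ss.inner.n_triangles == 0
        assert ss.outer.n_triangles == ss.cs.n_triangles

    def test_open_canal_is_cavity(self):
        # canal spans the full z-range; z faces are not flood seeds
        stack, truth = make_tube(7, shape=(60, 64, 64), z_margin=0, capped=False)
        t = otsu_threshold(stack)
        cav = cavity_mask(stack.data > t)
        bone = stack.data > t
        # cavity disjoint from bone, covers the true canal interior
        assert not (cav & bone).any()
        core = truth.cavity & ~bone
        assert (cav[core]).mean() > 0.99
        ss = split_surfaces(stack, t)
        assert ss.inner.n_triangles > 0

    def test_enclosed_tube_area_additivity(self):
        stack, _ = make_tube(8, shape=(66, 64, 64), z_margin=3, capped=True)
        ss = split_surfaces(stack)
        ratio = (ss.outer.area() + ss.inner.area()) / ss.cs.area()
        assert 0.98 <= ratio <= 1.02

    def test_cavity_disjoint_from_exterior_and_bone(self):
        stack, _ = make_tube(9, shape=(66, 64, 64), z_margin=3, capped=True)
        t = otsu_threshold(stack)
        bone = stack.data > t
        cav = cavity_mask(bone)
        ext = ~bone & ~cav
        assert not (cav & ext).any() and not (cav & bone).any()
        # exterior touches the x/y border, the cavity never does
        assert not cav[:, 0, :].any() and not cav[:, :, 0].any()

    def test_os_far_from_cavity_interface(self):
        # no outer-surface triangle centroid may sit at the cavity interface
        stack, truth = make_tube(10, shape=(66, 64, 64), z_margin=3, capped=True)
        ss = split_surfaces(stack)
        inner_c = ss.inner.centroids()
        outer_c = ss.outer.centroids()
        from scipy.spatial import cKDTree

        d, _ = cKDTree(inner_c).query(outer_c, k=1)
        # the closest approach is across the end caps (3 voxels thick)
        assert d.min() > 1.5 * stack.pitch_um[0]


def test_face_components_two_triangles_sharing_edge():
    faces = np.array([[0, 1, 2], [1, 2, 3], [4, 5, 6]])
    labels = face_components(faces)
    assert labels[0] == labels[1] != labels[2]
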