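"""Normal-angle roughness: vicinity statistic, calibration, scoring."""

import numpy as np
import pytest
import trimesh

from osteorough import roughness
from osteorough.roughness import (
    AngleField,
    Histogram,
    build_composite_histogram,
    calibrate,
    fit_lognormal,
    lognormal_pdf,
    mean_neighbor_angle,
    multi_radius_profile,
    radius_to_um,
    roughness_score,
    threshold_angle,
)
from osteorough.surface import build_mesh

from conftest import brute_force_mean_angles, tube_surfaces


def icosphere_mesh(subdivisions=3, radius=30.0):
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    mesh = build_mesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    # ensure outward orientation for the test's sanity
    out = np.einsum("ij,ij->i", mesh.normals, mesh.centroids())
    assert (out > 0).all() or (out < 0).all()
    if (out < 0).all():
        mesh = build_mesh(mesh.vertices, mesh.faces[:, [0, 2, 1]])
    return mesh


class TestMeanNeighborAngle:
    def test_planar_grid_all_zero(self):
        # a flat triangulated grid has identical normals everywhere
        n = 6
        xx, yy = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
        verts = np.c_[np.zeros(n * n), yy.ravel(), xx.ravel()]
        faces = []
        for i in range(n - 1):
            for j in range(n - 1):
                a = i * n + j
                faces.append([a, a + 1, a + n])
                faces.append([a + 1, a + n + 1, a + n])
        mesh = build_mesh(verts, np.asarray(faces))
        f = mean_neighbor_angle(mesh, 100.0, 1.0)
        assert f.n_excluded == 0
        np.testing.assert_allclose(f.angles, 0.0, atol=1e-9)

    def test_right_angle_fold(self):
        verts = np.array(
            [[0, 0, 0], [0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float
        )
        faces = np.array([[0, 1, 2], [0, 3, 1]])
        mesh = build_mesh(verts, faces)
        f = mean_neighbor_angle(mesh, 10.0, 1.0)
        np.testing.assert_allclose(f.angles, [90.0, 90.0], atol=1e-9)

    @pytest.mark.parametrize("radius", [2.0, 10.0])
    def test_matches_brute_force_on_icosphere(self, radius):
        mesh = icosphere_mesh()
        f = mean_neighbor_angle(mesh, radius, 1.0)
        oracle = brute_force_mean_angles(mesh, radius, 1.0)
        kept = oracle[~np.isnan(oracle)]
        assert f.angles.size == kept.size
        np.testing.assert_allclose(f.angles, kept, atol=1e-9)

    def test_larger_radius_larger_mean_on_curved_surface(self):
        mesh = icosphere_mesh()
        f1 = mean_neighbor_angle(mesh, 3.0, 1.0)
        f2 = mean_neighbor_angle(mesh, 12.0, 1.0)
        assert f2.angles.mean() > f1.angles.mean()

    def test_vicinity_respects_components(self):
        # two far-apart folded pairs: angles stay 90 even at huge radius
        verts = np.array([[0, 0, 0], [0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
        faces = np.array([[0, 1, 2], [0, 3, 1]])
        shifted = verts + [0, 0, 500.0]
        mesh = build_mesh(np.vstack([verts, shifted]), np.vstack([faces, faces + 4]))
        f = mean_neighbor_angle(mesh, 1000.0, 1.0)
        np.testing.assert_allclose(f.angles, 90.0, atol=1e-9)

    def test_invalid_radius(self):
        mesh = icosphere_mesh(1)
        with pytest.raises(ValueError):
            mean_neighbor_angle(mesh, 0.0, 1.0)


class TestHistogram:
    def test_binning_and_density(self):
        f = AngleField("m", 1, np.array([1.0, 1.0, 3.0]))
        h = build_composite_histogram([f], bin_width_deg=1.0)
        assert h.density[1] == pytest.approx(2 / 3)
        assert h.density[3] == pytest.approx(1 / 3)

    def test_pooling_equals_concatenation(self):
        a = AngleField("a", 1, np.array([1.0, 5.0]))
        b = AngleField("b", 1, np.array([2.0, 9.0, 9.5]))
        ab = AngleField("ab", 1, np.concatenate([a.angles, b.angles]))
        h2 = build_composite_histogram([a, b])
        h1 = build_composite_histogram([ab])
        np.testing.assert_array_equal(h1.density, h2.density)

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(0)
        f = AngleField("m", 1, rng.uniform(0, 180, 1000))
        h = build_composite_histogram([f])
        assert (h.density * np.diff(h.edges)).sum() == pytest.approx(1.0, abs=1e-6)

    def test_no_angles_errors(self):
        with pytest.raises(ValueError):
            build_composite_histogram([AngleField("m", 1, np.zeros(0))])


class TestLognormalFit:
    def test_recovery_from_exact_densities(self):
        mu, sigma = 2.0, 0.4
        edges = np.arange(0.0, 180.5, 0.5)
        centers = (edges[:-1] + edges[1:]) / 2
        h = Histogram(edges, lognormal_pdf(centers, mu, sigma), 0.5, 10**6)
        mu_f, sigma_f, rss = fit_lognormal(h)
        assert mu_f == pytest.approx(mu, abs=1e-3)
        assert sigma_f == pytest.approx(sigma, abs=1e-3)
        assert rss < 1e-8

    def test_recovery_from_samples(self):
        from osteorough.phantoms import sample_lognormal

        x = sample_lognormal(2.0, 0.4, 10**5, seed=42)
        h = build_composite_histogram([AngleField("s", 1, x)])
        mu_f, sigma_f, _ = fit_lognormal(h)
        assert mu_f == pytest.approx(2.0, rel=0.02)
        assert sigma_f == pytest.approx(0.4, rel=0.02)

    def test_single_bin_errors(self):
        edges = np.arange(0.0, 180.5, 0.5)
        dens = np.zeros(len(edges) - 1)
        dens[10] = 2.0
        with pytest.raises(ValueError):
            fit_lognormal(Histogram(edges, dens, 0.5, 100))


class TestThresholdAngle:
    def test_standard_lognormal(self):
        mu_p, sigma_p, T = threshold_angle(0.0, 1.0)
        assert mu_p == pytest.approx(1.6487, abs=1e-4)
        assert sigma_p == pytest.approx(2.1612, abs=1e-4)
        assert T == pytest.approx(5.9711, abs=1e-4)

    def test_matches_numeric_integration(self):
        from scipy.integrate import quad

        mu, sigma = -1.5, 0.5
        m1 = quad(lambda x: x * lognormal_pdf(np.array([x]), mu, sigma)[0], 0, 10)[0]
        m2 = quad(lambda x: x * x * lognormal_pdf(np.array([x]), mu, sigma)[0], 0, 10)[0]
        sd = np.sqrt(m2 - m1**2)
        mu_p, sigma_p, T = threshold_angle(mu, sigma)
        assert mu_p == pytest.approx(m1, rel=1e-6)
        assert sigma_p == pytest.approx(sd, rel=1e-6)
        assert T == pytest.approx(0.5223, abs=1e-4)

    def test_small_sigma_limit(self):
        mu = 1.3
        _, sigma_p, T = threshold_angle(mu, 1e-8)
        assert sigma_p == pytest.approx(0.0, abs=1e-6)
        assert T == pytest.approx(np.exp(mu), rel=1e-6)

    def test_sigma_nonpositive_errors(self):
        with pytest.raises(ValueError):
            threshold_angle(0.0, 0.0)


class TestRoughnessScore:
    def test_relative_frequency(self):
        f = AngleField("m", 1, np.array([1.0, 2.0, 3.0, 10.0]))
        assert roughness_score(f, 5.0).R == 0.25

    def test_extremes(self):
        f = AngleField("m", 1, np.array([1.0, 2.0]))
        assert roughness_score(f, 5.0).R == 0.0
        assert roughness_score(f, 0.5).R == 1.0

    def test_empty_field_errors(self):
        with pytest.raises(ValueError):
            roughness_score(AngleField("m", 1, np.zeros(0)), 5.0)

    def test_size_invariance_duplicated_mesh(self):
        # two disjoint copies (as separate components, coordinates identical
        # so the vicinity geometry is bitwise equal in both copies)
        mesh = icosphere_mesh(2)
        double = build_mesh(
            np.vstack([mesh.vertices, mesh.vertices]),
            np.vstack([mesh.faces, mesh.faces + len(mesh.vertices)]),
        )
        f1 = mean_neighbor_angle(mesh, 5.0, 1.0)
        f2 = mean_neighbor_angle(double, 5.0, 1.0)
        T = np.median(f1.angles)
        assert roughness_score(f2, T).R == pytest.approx(roughness_score(f1, T).R)


class TestMultiRadiusProfile:
    def test_cardinality_and_smoothness(self, small_tube_profile_kit):
        kit = small_tube_profile_kit
        prof = multi_radius_profile(kit["probe"], kit["calibrations"],
                                    radii=kit["radii"], pitch_um=kit["pitch"])
        assert len(prof) == 18  # 3 surfaces x 6 radii
        # a smooth phantom scored against its own smooth baseline stays
        # smooth at every radius that does not wrap around the bone (the
        # vicinity radius stays below the bone radius); beyond that the
        # angle distribution degenerates and the tail statistic is
        # meaningless, which is why vicinity radii are chosen to avoid
        # wrap-around in practice
        local = prof[prof.radius_vox <= 10]
        assert (local.R.dropna() < 0.02).all()

    def test_missing_calibration_errors(self, small_tube_profile_kit):
        kit = small_tube_profile_kit
        with pytest.raises(KeyError, match="r.*7"):
            multi_radius_profile(kit["probe"], kit["calibrations"], radii=(7,),
                                 pitch_um=kit["pitch"])


class TestPerturbationResponse:
    def test_outer_perturbation_is_surface_specific(self, baseline_kit):
        _, pert = tube_surfaces(7, amp_outer=2.0)
        cals = baseline_kit["calibrations"]
        smooth = baseline_kit["smooth_R"]
        pitch = 14.609
        d = {}
        for kind in ("os", "is"):
            f = mean_neighbor_angle(pert.get(kind), 3, pitch)
            d[kind] = roughness_score(f, cals[kind].T).R - smooth[kind]
        assert d["os"] > 4.0 * d["is"]

    def test_scale_selectivity(self, small_tube_profile_kit):
        # corr-length ~3 voxels boosts roughness at r=3 more than at r=20
        from conftest import SMALL_TUBE

        kit = small_tube_profile_kit
        smooth = {}
        for r in (3, 20):
            cal = kit["calibrations"][("cs", r)]
            fields = [
                mean_neighbor_angle(tube_surfaces(s, **SMALL_TUBE)[1].cs, r,
                                    kit["pitch"])
                for s in (200, 201)
            ]
            smooth[r] = max(
                float(np.mean([roughness_score(f, cal.T).R for f in fields])), 1e-4
            )
        geo = {k: v for k, v in SMALL_TUBE.items() if not k.startswith("amp_")}
        ratios = {3: [], 20: []}
        for seed in range(3):
            _, pert = tube_surfaces(seed, amp_outer=1.5, amp_inner=1.5, corr=3.0,
                                    **geo)
            for r in (3, 20):
                f = mean_neighbor_angle(pert.cs, r, kit["pitch"])
                T = kit["calibrations"][("cs", r)].T
                ratios[r].append(roughness_score(f, T).R / smooth[r])
        assert np.median(ratios[3]) > np.median(ratios[20])


def test_radius_to_um_conversions():
    assert radius_to_um(3) == pytest.approx(43.827)
    with pytest.raises(ValueError):
        radius_to_um(-1)


def test_calibration_json_round_trip(tmp_path, baseline_kit):
    cal = baseline_kit["calibrations"]["cs"]
    cal.to_json(tmp_path / "c.json")
    back = roughness.RoughnessCalibration.from_json(tmp_path / "c.json")
    assert back.T == pytest.approx(cal.T)
    assert back.mu == pytest.approx(cal.mu)
    np.testing.assert_allclose(back.histogram.density, cal.histogram.density)
    # densities integrate to 1
    assert (back.histogram.density * np.diff(back.histogram.edges)).sum() == pytest.approx(1.0, abs=1e-6)
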