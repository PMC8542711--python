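"""Boundary-element solver: analytic benchmarks, conservation, images."""

import numpy as np
import pytest

from pulseid.bem import (
    BemError,
    ConductivityScene,
    SceneBody,
    active_image,
    assemble_and_solve,
    basal_image,
    eod_sources,
    first_detection,
    passive_image,
)
from pulseid.mesh import (
    build_mesh,
    default_profile,
    fit_midline,
    sphere_mesh,
    straight_pose,
)

RINGS, RING_NODES = 25, 13  # working resolution for multi-solve tests


def fish_mesh(length=12.0, center=(33.0, 36.0), theta=0.0,
              rings=RINGS, ring_nodes=RING_NODES):
    pose = straight_pose(length, center=center, theta=theta)
    return build_mesh(fit_midline(pose), length, default_profile(rings),
                      ring_nodes=ring_nodes)


def sphere_enhancement(n_rings, ring_nodes=17, radius=5.0):
    """Fitted surface-potential slope of an insulating sphere in E0 = 1."""
    mesh = sphere_mesh(radius, n_rings=n_rings, ring_nodes=ring_nodes)
    scene = ConductivityScene(
        [SceneBody("s", mesh, sigma_body=0.0, skin_rho=0.0)],
        external_field=[1.0, 0.0, 0.0])
    sol = assemble_and_solve(scene)
    x = mesh.vertices[:, 0] - mesh.vertices[:, 0].mean()
    return -np.polyfit(x, sol.phi, 1)[0]  # exact value: 3/2


@pytest.fixture(scope="module")
def basal_solution():
    mesh = fish_mesh()
    sources = eod_sources(mesh, ring_nodes=RING_NODES)
    scene = ConductivityScene([SceneBody(1, mesh)], sources=sources,
                              discharging_id=1)
    return scene, assemble_and_solve(scene)


class TestSphereBenchmarks:
    def test_insulating_sphere_three_halves_factor(self):
        # classical result: surface field/potential of a nonconducting
        # sphere in a uniform field is enhanced by exactly 3/2
        enhancement = sphere_enhancement(n_rings=25)
        assert enhancement == pytest.approx(1.5, rel=0.02)

    def test_transparent_sphere_invisible(self):
        mesh = sphere_mesh(5.0, n_rings=15, ring_nodes=9)
        sigma_w = 120e-6
        scene = ConductivityScene(
            [SceneBody("s", mesh, sigma_body=sigma_w, skin_rho=0.0)],
            external_field=[1.0, 0.0, 0.0])
        sol = assemble_and_solve(scene)
        incident = -mesh.vertices[:, 0] + mesh.vertices[:, 0].mean()
        assert np.max(np.abs(sol.phi - incident)) / 5.0 < 0.01

    def test_resolution_convergence(self):
        # refining 25 -> 49 rings moves the enhancement factor < 1%
        coarse = sphere_enhancement(n_rings=25)
        fine = sphere_enhancement(n_rings=49)
        assert abs(fine - coarse) / 1.5 < 0.01


class TestConservationAndLinearity:
    def test_central_dipole_conserves_current_exactly(self):
        mesh = sphere_mesh(5.0, n_rings=15, ring_nodes=9)
        sources = [((1.0, 0.0, 0.0), 100.0), ((-1.0, 0.0, 0.0), -100.0)]
        scene = ConductivityScene([SceneBody(1, mesh)], sources=sources,
                                  discharging_id=1)
        sol = assemble_and_solve(scene)
        assert abs(sol.total_current(1)) / 100.0 < 1e-6

    def test_doubled_source_doubles_everything(self, basal_solution):
        scene, sol = basal_solution
        doubled = ConductivityScene(
            scene.bodies, scene.water_sigma_uScm,
            [(p, 2 * i) for p, i in scene.sources], 1)
        sol2 = assemble_and_solve(doubled)
        np.testing.assert_allclose(sol2.current_density,
                                   2 * sol.current_density, rtol=1e-9)
        np.testing.assert_allclose(sol2.phi, 2 * sol.phi, rtol=1e-9)

    def test_superposition_of_sources(self):
        mesh = fish_mesh(rings=15, ring_nodes=9)
        poles = eod_sources(mesh, ring_nodes=9)
        body = [SceneBody(1, mesh)]

        def solve(sources):
            return assemble_and_solve(ConductivityScene(
                body, sources=sources, discharging_id=1))

        # split the dipole into two half-amplitude dipoles and re-sum
        half = [(p, 0.5 * i) for p, i in poles]
        together = solve(poles)
        parts = solve(half)
        np.testing.assert_allclose(2 * parts.current_density,
                                   together.current_density, atol=1e-9)

    def test_mirror_symmetric_basal_image(self, basal_solution):
        # straight fish with midline sources: left/right flank symmetric
        scene, sol = basal_solution
        image = basal_image(scene, sol)
        J = image.values[1:-1].reshape(RINGS, RING_NODES)
        tol = 0.02 * np.max(np.abs(J))
        for j in range(1, RING_NODES // 2 + 1):
            np.testing.assert_allclose(J[:, j], J[:, RING_NODES - j],
                                       atol=tol)


class TestSceneValidation:
    def test_unbalanced_sources_rejected(self):
        mesh = fish_mesh(rings=15, ring_nodes=9)
        with pytest.raises(BemError):
            ConductivityScene([SceneBody(1, mesh)],
                              sources=[((30.0, 36.0, 6.0), 1.0)],
                              discharging_id=1)

    def test_open_mesh_rejected(self):
        mesh = fish_mesh(rings=15, ring_nodes=9)
        mesh.triangles = mesh.triangles[:-1]
        scene = ConductivityScene([SceneBody(1, mesh)])
        with pytest.raises(BemError):
            assemble_and_solve(scene)

    def test_receiver_must_not_discharge(self):
        mesh = fish_mesh(rings=15, ring_nodes=9)
        scene = ConductivityScene(
            [SceneBody(1, mesh)],
            sources=eod_sources(mesh, ring_nodes=9), discharging_id=1)
        with pytest.raises(BemError):
            passive_image(scene, 1)

    def test_active_image_modality_guard(self):
        from pulseid.bem import ElectricImage
        with pytest.raises(BemError):
            ElectricImage(np.zeros(3), "active", 1, 2)
        with pytest.raises(BemError):
            ElectricImage(np.zeros(3), "passive", 1, 1)


class TestTwoFishImages:
    def two_fish_scene(self, gap, emitter=1):
        m1 = fish_mesh(center=(20.0, 36.0))
        # receiver head-on, facing the emitter
        m2 = fish_mesh(center=(20.0 + 12.0 + gap, 36.0), theta=np.pi)
        meshes = {1: m1, 2: m2}
        return ConductivityScene(
            [SceneBody(1, m1), SceneBody(2, m2)],
            sources=eod_sources(meshes[emitter], ring_nodes=RING_NODES),
            discharging_id=emitter)

    @pytest.fixture(scope="class")
    def decay_series(self):
        out = []
        for gap in (4.0, 10.0, 20.0):
            scene = self.two_fish_scene(gap)
            sol = assemble_and_solve(scene)
            out.append((gap, scene, sol))
        return out

    def test_two_fish_current_conservation(self):
        # conservation holds to 0.1% at the default 49 x 17 resolution
        m1 = fish_mesh(center=(20.0, 36.0), rings=49, ring_nodes=17)
        m2 = fish_mesh(center=(36.0, 36.0), theta=np.pi,
                       rings=49, ring_nodes=17)
        scene = ConductivityScene(
            [SceneBody(1, m1), SceneBody(2, m2)],
            sources=eod_sources(m1), discharging_id=1)
        sol = assemble_and_solve(scene)
        mag = sum(abs(i) for _, i in scene.sources)
        assert abs(sol.total_current(1)) / mag < 1e-3

    def test_passive_image_decays_with_distance(self, decay_series):
        maxima = [passive_image(s, 2, sol).summary["max"]
                  for _, s, sol in decay_series]
        assert maxima[0] > maxima[1] > maxima[2]

    def test_active_image_decays_with_distance(self, decay_series):
        maxima = [active_image(s, sol).summary["max"]
                  for _, s, sol in decay_series]
        assert maxima[0] > maxima[1] > maxima[2]

    def test_passive_image_funnels_to_facing_head(self, decay_series):
        # elongated conductive body concentrates an external field at the
        # tip facing the source: the receiver faces the emitter head-on,
        # so the strongest passive stimulus sits on its rostral rings
        _, scene, sol = decay_series[0]
        image = passive_image(scene, 2, sol)
        ring_of = np.concatenate([[0], np.repeat(np.arange(RINGS),
                                                 RING_NODES) + 1,
                                  [RINGS + 1]])
        peak_ring = ring_of[int(np.argmax(np.abs(image.values)))]
        assert peak_ring <= RINGS // 4 or peak_ring == 0

    def test_far_receiver_below_noise_floor(self):
        scene = self.two_fish_scene(60.0)
        sol = assemble_and_solve(scene)
        assert passive_image(scene, 2, sol).summary["max"] < 0.1

    def test_active_image_zero_without_second_fish(self, basal_solution):
        scene, sol = basal_solution
        with pytest.raises(BemError):
            active_image(scene, sol)

    def test_reciprocity_in_mirror_scene(self, decay_series):
        # identical fish, mirror-symmetric geometry: swapping the emitter
        # mirrors the passive image
        gap, scene, sol = decay_series[1]
        swapped = self.two_fish_scene(gap, emitter=2)
        sol2 = assemble_and_solve(swapped)
        p12 = passive_image(scene, 2, sol).summary["max"]
        p21 = passive_image(swapped, 1, sol2).summary["max"]
        assert p12 == pytest.approx(p21, rel=0.05)


class TestFirstDetection:
    def test_identical_series_never_detect(self):
        series = [(1.0, 0.2), (2.0, 0.3)]
        assert first_detection(series, series) is None

    def test_constructed_example(self):
        a = [(1.0, 0.05), (2.0, 0.3), (3.0, 0.5)]
        b = [(1.0, 0.05), (2.0, 0.1), (3.0, 0.3)]
        assert first_detection(a, b) == ("A", 2.0)

    def test_all_below_floor_never_detect(self):
        a = [(1.0, 0.05), (2.0, 0.09)]
        b = [(1.0, 0.01), (2.0, 0.02)]
        assert first_detection(a, b) is None

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            first_detection([], [(1.0, 0.2)])

    def test_most_recent_value_carried(self):
        a = [(1.0, 0.5)]
        b = [(0.5, 0.1), (3.0, 0.2)]
        fish, t = first_detection(a, b)
        assert fish == "A" and t == 1.0
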