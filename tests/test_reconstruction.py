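"""Extruded-prism meshing: exact volumes, watertightness, export round trips."""

import numpy as np
import pytest

from glomorph import (
    Compartment,
    Contour,
    ContourStack,
    RigidTransform2D,
    compute_morphometrics,
    export_mesh,
    reconstruct_mesh,
)
from glomorph.reconstruction import NoGeometryError, UndefinedRatioError, import_mesh

from conftest import star_polygon


def circle_contour(radius, n=64, compartment=Compartment.MESANGIUM, section_index=0, center=(0.0, 0.0)):
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    xy = np.column_stack([center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)])
    return Contour(xy, compartment, section_index)


def square_contour(side, compartment=Compartment.MESANGIUM, section_index=0):
    return Contour(
        np.array([[0.0, 0.0], [side, 0.0], [side, side], [0.0, side]]), compartment, section_index
    )


def sphere_stack(radius, n_sections, n_gon=512):
    """Sphere sliced into slabs; each contour is the mid-plane circle."""
    t = 2.0 * radius / n_sections
    sections = []
    for i in range(n_sections):
        z_mid = -radius + (i + 0.5) * t
        r_mid = np.sqrt(max(radius**2 - z_mid**2, 0.0))
        if r_mid > 1e-9:
            sections.append((i, [circle_contour(r_mid, n_gon, section_index=i)]))
    return ContourStack(sections, t)


class TestReconstructMesh:
    def test_square_prism_closed_form(self):
        stack = ContourStack([(0, [square_contour(10.0)])], 1.0)
        mesh = reconstruct_mesh(stack)
        assert mesh.volume_um3 == pytest.approx(100.0, rel=1e-12)
        assert mesh.surface_area_um2 == pytest.approx(2 * 100 + 4 * 10 * 1, rel=1e-9)
        assert mesh.is_watertight

    def test_stacked_64gon_closed_form(self):
        r, n = 10.0, 64
        sections = [(i, [circle_contour(r, n, section_index=i)]) for i in range(6)]
        mesh = reconstruct_mesh(ContourStack(sections, 1.0))
        a64 = 0.5 * n * r**2 * np.sin(2 * np.pi / n)
        assert mesh.volume_um3 == pytest.approx(6 * a64, rel=1e-9)
        assert mesh.signed_volume() == pytest.approx(6 * a64, rel=1e-9)

    def test_sphere_matches_stacked_disc_oracle(self):
        r, n_sec, n_gon = 10.0, 20, 512
        stack = sphere_stack(r, n_sec, n_gon)
        mesh = reconstruct_mesh(stack)
        # independent quadrature: sum of mid-plane polygon areas times t
        t = 2.0 * r / n_sec
        a_gon = 0.5 * n_gon * np.sin(2 * np.pi / n_gon)  # unit-radius n-gon area
        oracle = sum(
            a_gon * max(r**2 - (-r + (i + 0.5) * t) ** 2, 0.0) * t for i in range(n_sec)
        )
        assert mesh.volume_um3 == pytest.approx(oracle, rel=1e-9)

    def test_sphere_error_decreases_as_sections_double(self):
        r = 10.0
        truth = 4.0 / 3.0 * np.pi * r**3
        errors = [
            abs(reconstruct_mesh(sphere_stack(r, n)).volume_um3 - truth) / truth
            for n in (5, 10, 20, 40, 80)
        ]
        assert all(b < a for a, b in zip(errors, errors[1:]))

    def test_volume_identity_and_watertight_on_random_stacks(self, rng):
        """Mesh volume equals sum(area*t) to 1e-9 relative on random stacks,
        and both the triangle-soup signed volume and watertightness hold."""
        for _ in range(100):
            t = rng.uniform(0.5, 3.0)
            n_sec = rng.integers(1, 5)
            sections = []
            for i in range(n_sec):
                n_contours = rng.integers(1, 3)
                contours = [
                    Contour(
                        star_polygon(rng, n_vertices=int(rng.integers(5, 25)))
                        + rng.uniform(-30, 30, 2),
                        Compartment.MESANGIUM,
                        i,
                    )
                    for _ in range(n_contours)
                ]
                sections.append((i, contours))
            stack = ContourStack(sections, t)
            mesh = reconstruct_mesh(stack)
            expected = sum(c.area() * t for _, c in stack.contours(Compartment.MESANGIUM))
            assert mesh.volume_um3 == pytest.approx(expected, rel=1e-9)
            assert mesh.signed_volume() == pytest.approx(expected, rel=1e-9)
            assert mesh.is_watertight

    def test_volume_invariant_under_global_rigid_transform(self, rng):
        sections = [
            (i, [Contour(star_polygon(rng), Compartment.MESANGIUM, i)]) for i in range(4)
        ]
        stack = ContourStack(sections, 1.5)
        base = reconstruct_mesh(stack)
        t = RigidTransform2D(0.7, (12.0, -5.0))
        moved = ContourStack(
            [(i, [c.transformed(t) for c in cs]) for i, cs in sections], 1.5
        )
        mesh = reconstruct_mesh(moved)
        assert mesh.volume_um3 == pytest.approx(base.volume_um3, rel=1e-9)
        assert mesh.surface_area_um2 == pytest.approx(base.surface_area_um2, rel=1e-6)

    def test_empty_stack_refused(self):
        stack = ContourStack([(0, [square_contour(1.0, Compartment.TUFT)])], 1.0)
        with pytest.raises(NoGeometryError):
            reconstruct_mesh(stack, Compartment.MESANGIUM)


class TestMorphometrics:
    def test_ratio_one_when_mesangium_fills_tuft(self):
        sq_m = square_contour(10.0, Compartment.MESANGIUM)
        sq_t = square_contour(10.0, Compartment.TUFT)
        stack = ContourStack([(0, [sq_m, sq_t])], 1.0)
        rec = compute_morphometrics(stack)
        assert rec.mes_to_total_ratio == pytest.approx(1.0)

    def test_ratio_zero_without_mesangium(self):
        stack = ContourStack([(0, [square_contour(10.0, Compartment.TUFT)])], 1.0)
        rec = compute_morphometrics(stack)
        assert rec.mes_to_total_ratio == 0.0
        assert rec.mesangial_volume_um3 == 0.0

    def test_zero_tuft_area_refused(self):
        stack = ContourStack([(0, [square_contour(10.0, Compartment.MESANGIUM)])], 1.0)
        with pytest.raises(UndefinedRatioError):
            compute_morphometrics(stack)

    def test_phantom_ratio_tracks_voxel_truth(self, small_phantom):
        """Contours traced from truth masks give a mes/total ratio within
        0.05 of the phantom's voxel-count Vv over the sectioned slab."""
        from glomorph.segmentation import mask_to_contours

        spec, truth = small_phantom
        sections = []
        for k, masks in truth.per_section_truth_masks.items():
            cs = mask_to_contours(masks["mesangium"], spec.pixel_size_um, Compartment.MESANGIUM, k)
            cs += mask_to_contours(masks["tuft"], spec.pixel_size_um, Compartment.TUFT, k)
            sections.append((k, cs))
        rec = compute_morphometrics(ContourStack(sections, spec.section_thickness_um))
        slab_vv = truth.slab_mesangial_volume_um3 / truth.slab_tuft_volume_um3
        assert rec.mes_to_total_ratio == pytest.approx(slab_vv, abs=0.05)


class TestExport:
    def test_cube_obj_counts(self, tmp_path):
        stack = ContourStack([(0, [square_contour(1.0)])], 1.0)
        mesh = reconstruct_mesh(stack)
        path = tmp_path / "cube.obj"
        export_mesh(mesh, path)
        assert mesh.vertices.shape[0] == 8
        assert mesh.faces.shape[0] == 12

    @pytest.mark.parametrize("ext", ["obj", "stl"])
    def test_roundtrip_volume(self, tmp_path, rng, ext):
        sections = [(i, [Contour(star_polygon(rng), Compartment.MESANGIUM, i)]) for i in range(3)]
        mesh = reconstruct_mesh(ContourStack(sections, 1.0))
        path = tmp_path / f"mesh.{ext}"
        export_mesh(mesh, path)
        back = import_mesh(path)
        assert back.volume_um3 == pytest.approx(mesh.volume_um3, rel=1e-6)

    def test_empty_mesh_refused(self, tmp_path):
        from glomorph.reconstruction import SurfaceMesh

        empty = SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), int), 0.0, 0.0, Compartment.OTHER)
        with pytest.raises(NoGeometryError):
            export_mesh(empty, tmp_path / "empty.obj")
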