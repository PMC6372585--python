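"""Point grids, Cavalieri estimation, PSI fractions, planimetry."""

import numpy as np
import pytest
from scipy import stats

from glomorph import (
    Compartment,
    Contour,
    ContourStack,
    VolumeModel,
    cavalieri_volume,
    make_grid,
    planimetry,
    psi_fractional_volume,
)
from glomorph.stereology import (
    CountingRule,
    EmptyGridError,
    UndefinedFractionError,
    WEIBEL_GOMEZ_BETA,
    WEIBEL_GOMEZ_K,
)


def square_contour(side, compartment=Compartment.MESANGIUM, section_index=0):
    return Contour(
        np.array([[0.0, 0.0], [side, 0.0], [side, side], [0.0, side]]), compartment, section_index
    )


def disc_masks(radius, n_sections, thickness, pixel_size):
    """Binary sphere slab masks (mid-plane discs) for mask-mode estimators."""
    n_px = int(np.ceil(2 * (radius + 2) / pixel_size))
    cx = cy = n_px * pixel_size / 2.0
    cols = pixel_size * (np.arange(n_px) + 0.5)
    gx, gy = np.meshgrid(cols, cols, indexing="xy")
    masks = {}
    for i in range(n_sections):
        z = -radius + (i + 0.5) * thickness
        r2 = radius**2 - z**2
        masks[i] = ((gx - cx) ** 2 + (gy - cy) ** 2) <= r2 if r2 > 0 else np.zeros((n_px, n_px), bool)
    return {"masks": masks, "pixel_size_um": pixel_size, "thickness_um": thickness}


class TestMakeGrid:
    def test_forced_offset_point_count(self):
        grid = make_grid((0, 0, 10, 10), 1.0, offset=(0.0, 0.0))
        assert grid.points().shape[0] == 11 * 11  # points at 0..10 inclusive

    def test_same_seed_reproduces_offset(self):
        g1 = make_grid((0, 0, 10, 10), 2.0, seed=99)
        g2 = make_grid((0, 0, 10, 10), 2.0, seed=99)
        assert g1.offset == g2.offset

    def test_offsets_uniform_over_seeds(self):
        s = 2.0
        offs = np.array([make_grid((0, 0, 10, 10), s, seed=k).offset for k in range(10_000)])
        for axis in range(2):
            p = stats.kstest(offs[:, axis] / s, "uniform").pvalue
            assert p > 0.01

    def test_empty_grid_refused(self):
        with pytest.raises(EmptyGridError):
            make_grid((0, 0, 1, 1), 5.0)


class TestCavalieri:
    def test_square_closed_form(self):
        stack = ContourStack([(0, [square_contour(10.0)])], 1.0)
        grid = make_grid((-1, -1, 11, 11), 1.0, offset=(0.5, 0.5))
        v, counts = cavalieri_volume(stack, grid=grid)
        assert counts.total("P") == 100
        assert v == pytest.approx(100.0)

    def test_boundary_points_count_half(self):
        """A grid aligned with the square's edges scores boundary hits at 1/2
        (Gundersen convention), keeping the estimate exact on average."""
        stack = ContourStack([(0, [square_contour(10.0)])], 1.0)
        grid = make_grid((0, 0, 10, 10), 1.0, offset=(0.0, 0.0))
        _, counts = cavalieri_volume(stack, grid=grid)
        # 9x9 interior + 36 edge points at 1/2 + 4 corners at 1/2
        assert counts.total("P") == 81 + 0.5 * 40
        _, strict = cavalieri_volume(stack, grid=grid, counting_rule=CountingRule.STRICT)
        assert strict.total("P") == 81
        _, incl = cavalieri_volume(stack, grid=grid, counting_rule=CountingRule.INCLUSIVE)
        assert incl.total("P") == 121

    def test_empty_compartment_zero(self):
        stack = ContourStack([(0, [square_contour(10.0, Compartment.TUFT)])], 1.0)
        v, _ = cavalieri_volume(stack, spacing_um=1.0, seed=0, compartment=Compartment.MESANGIUM)
        assert v == 0.0

    def test_sur_replicates_unbiased_on_disc_stack(self):
        """Mean over SUR offsets matches the pixel-mask volume (Cavalieri
        estimator is unbiased for the sectioned object)."""
        masks = disc_masks(radius=10.0, n_sections=10, thickness=2.0, pixel_size=0.25)
        pixel_volume = sum(m.sum() for m in masks["masks"].values()) * 0.25**2 * 2.0
        rng = np.random.default_rng(5)
        vs = [
            cavalieri_volume(masks, spacing_um=2.0, offset=tuple(rng.uniform(0, 2.0, 2)))[0]
            for _ in range(300)
        ]
        assert np.mean(vs) == pytest.approx(pixel_volume, rel=0.01)

    def test_fine_spacing_converges_to_mask_area(self):
        masks = disc_masks(radius=10.0, n_sections=4, thickness=5.0, pixel_size=0.5)
        pixel_volume = sum(m.sum() for m in masks["masks"].values()) * 0.5**2 * 5.0
        v, _ = cavalieri_volume(masks, spacing_um=0.5, offset=(0.25, 0.25))
        assert v == pytest.approx(pixel_volume, rel=0.001)


class TestPsi:
    def test_trivial_fractions(self):
        sq_m = square_contour(10.0, Compartment.MESANGIUM)
        sq_t = square_contour(10.0, Compartment.TUFT)
        stack = ContourStack([(0, [sq_m, sq_t])], 1.0)
        vv, _ = psi_fractional_volume(stack, spacing_um=1.0, offset=(0.5, 0.5))
        assert vv == pytest.approx(1.0)
        stack_empty = ContourStack([(0, [sq_t])], 1.0)
        vv0, _ = psi_fractional_volume(stack_empty, spacing_um=1.0, offset=(0.5, 0.5))
        assert vv0 == 0.0

    def test_zero_reference_refused(self):
        masks = {
            "masks": {0: np.zeros((4, 4), bool)},
            "reference_masks": {0: np.zeros((4, 4), bool)},
            "pixel_size_um": 1.0,
            "thickness_um": 1.0,
        }
        with pytest.raises(UndefinedFractionError):
            psi_fractional_volume(masks, spacing_um=1.0, offset=(0.5, 0.5))

    def test_phantom_vv_mean_near_truth(self, small_phantom):
        """Mean PSI Vv over SUR grids tracks the slab voxel truth within 0.02."""
        spec, truth = small_phantom
        masks = {
            "masks": {k: m["mesangium"] for k, m in truth.per_section_truth_masks.items()},
            "reference_masks": {k: m["tuft"] for k, m in truth.per_section_truth_masks.items()},
            "pixel_size_um": spec.pixel_size_um,
            "thickness_um": spec.section_thickness_um,
        }
        slab_vv = truth.slab_mesangial_volume_um3 / truth.slab_tuft_volume_um3
        rng = np.random.default_rng(11)
        vvs = [
            psi_fractional_volume(masks, spacing_um=2.0, offset=tuple(rng.uniform(0, 2.0, 2)))[0]
            for _ in range(100)
        ]
        assert np.mean(vvs) == pytest.approx(slab_vv, abs=0.02)

    def test_erosion_biases_psi_downward(self, small_phantom):
        """Eroding mesangial masks by one pixel before counting drives the
        Cavalieri estimate below the un-eroded one by at least 90% of the
        eroded-area deficit times thickness."""
        from scipy import ndimage

        spec, truth = small_phantom
        mes = {k: m["mesangium"] for k, m in truth.per_section_truth_masks.items()}
        eroded = {k: ndimage.binary_erosion(m) for k, m in mes.items()}
        base = {"masks": mes, "pixel_size_um": spec.pixel_size_um, "thickness_um": spec.section_thickness_um}
        ero = dict(base, masks=eroded)
        deficit_volume = (
            sum((mes[k].sum() - eroded[k].sum()) for k in mes)
            * spec.pixel_size_um**2
            * spec.section_thickness_um
        )
        rng = np.random.default_rng(17)
        diffs = []
        for _ in range(50):
            off = tuple(rng.uniform(0, 2.0, 2))
            v_full, _ = cavalieri_volume(base, spacing_um=2.0, offset=off)
            v_ero, _ = cavalieri_volume(ero, spacing_um=2.0, offset=off)
            diffs.append(v_full - v_ero)
        assert np.mean(diffs) >= 0.9 * deficit_volume


class TestCvMonotonicity:
    def test_replicate_cv_grows_with_spacing(self):
        masks = disc_masks(radius=10.0, n_sections=10, thickness=2.0, pixel_size=0.25)
        rng = np.random.default_rng(23)
        cvs = []
        for s in (1.0, 2.0, 4.0, 8.0):
            vs = [
                cavalieri_volume(masks, spacing_um=s, offset=tuple(rng.uniform(0, s, 2)))[0]
                for _ in range(150)
            ]
            cvs.append(np.std(vs) / np.mean(vs))
        assert all(b > a for a, b in zip(cvs, cvs[1:]))


class TestPlanimetry:
    def test_extrusion_closed_forms(self):
        res = planimetry([square_contour(10.0)], VolumeModel.EXTRUSION, t_equiv_um=1.0)
        assert res.mean_mesangial_area_um2 == pytest.approx(100.0)
        assert res.estimated_volume_um3 == pytest.approx(100.0)

    def test_mean_of_profiles(self):
        profiles = [square_contour(10.0), square_contour(np.sqrt(200.0))]
        res = planimetry(profiles, VolumeModel.EXTRUSION, t_equiv_um=2.0)
        assert res.mean_mesangial_area_um2 == pytest.approx(150.0)

    def test_weibel_gomez_against_formula_oracle(self):
        """Quasi-sphere volume from the equatorial profile of a r=10 sphere."""
        ang = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        circle = Contour(np.column_stack([10 * np.cos(ang), 10 * np.sin(ang)]))
        res = planimetry([circle], VolumeModel.WEIBEL_GOMEZ)
        area = circle.area()
        oracle = (WEIBEL_GOMEZ_BETA / WEIBEL_GOMEZ_K) * area**1.5
        assert res.estimated_volume_um3 == pytest.approx(oracle, rel=1e-12)

    def test_empty_profiles_refused(self):
        with pytest.raises(ValueError):
            planimetry([], VolumeModel.EXTRUSION, t_equiv_um=1.0)
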