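"""Validation experiments: estimator accuracy against phantom ground truth.

Each function runs one self-contained experiment on synthetic phantoms with
exact voxel truth and returns the measured quantities (biases, errors,
agreement statistics).  They back the acceptance test suite and the
stand-alone acceptance script; problem sizes are chosen so the whole battery
runs on a single CPU in a few minutes.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, stats

from glomorph.comparison_stats import MeasurementTable, posthoc_contrasts, repeated_measures_anova
from glomorph.geometry import Compartment, Contour, RigidTransform2D
from glomorph.phantom import PhantomSpec, generate_cohort, generate_phantom, render_sections
from glomorph.reconstruction import ContourStack, compute_morphometrics, reconstruct_mesh
from glomorph.registration import FiducialPairSet, build_alignment_chain, fit_rigid_transform
from glomorph.segmentation import mask_to_contours, segment_masks
from glomorph.stereology import cavalieri_volume
from glomorph.io import apply_alignment


def _sphere_masks(radius=20.0, thickness=2.0, voxel=0.25, seed=0):
    """Voxel sphere phantom sectioned into mid-plane slab masks."""
    spec = PhantomSpec(
        tuft_radii_um=(radius, radius, radius),
        n_mesangial_blobs=0,
        target_vv=0.5,
        voxel_size_um=voxel,
        section_thickness_um=thickness,
        n_sections=int(2 * radius / thickness),
        pixel_size_um=voxel,
        misalignment_sigma=(0.0, 0.0),
        noise_sigma=0.0,
        seed=seed,
    )
    truth = generate_phantom(spec)
    masks = {
        "masks": {k: m["tuft"] for k, m in truth.per_section_truth_masks.items()},
        "pixel_size_um": spec.pixel_size_um,
        "thickness_um": thickness,
    }
    return masks, 4.0 / 3.0 * np.pi * radius**3


def cavalieri_sphere_experiment(
    seed: int,
    radius: float = 20.0,
    thickness: float = 2.0,
    spacing: float = 2.0,
    n_offsets: int = 500,
    cv_spacings: tuple = (1.0, 2.0, 4.0, 8.0),
    n_cv: int = 150,
) -> dict:
    """Unbiasedness and precision of Cavalieri SUR point counting on a sphere.

    Returns the mean estimate over SUR offsets, its relative bias against the
    analytic sphere volume, and the replicate coefficient of variation at a
    ladder of grid spacings.
    """
    masks, truth_v = _sphere_masks(radius, thickness, seed=seed)
    rng = np.random.default_rng(seed)
    estimates = [
        cavalieri_volume(masks, spacing_um=spacing, offset=tuple(rng.uniform(0, spacing, 2)))[0]
        for _ in range(n_offsets)
    ]
    mean_v = float(np.mean(estimates))
    cvs = {}
    for s in cv_spacings:
        vs = [
            cavalieri_volume(masks, spacing_um=s, offset=tuple(rng.uniform(0, s, 2)))[0]
            for _ in range(n_cv)
        ]
        cvs[s] = float(np.std(vs) / np.mean(vs))
    return {
        "mean_volume_um3": mean_v,
        "true_volume_um3": truth_v,
        "bias_pct": 100.0 * (mean_v - truth_v) / truth_v,
        "cv_by_spacing": cvs,
        "n_offsets": n_offsets,
    }


def extrusion_exactness_experiment(seed: int, n_stacks: int = 100) -> dict:
    """Mesh volume vs the exact sum(area*t) identity on random stacks."""
    rng = np.random.default_rng(seed)
    max_rel = 0.0
    watertight = 0
    for _ in range(n_stacks):
        t = float(rng.uniform(0.5, 3.0))
        sections = []
        for i in range(int(rng.integers(1, 5))):
            contours = []
            for _ in range(int(rng.integers(1, 3))):
                angles = np.sort(rng.uniform(0, 2 * np.pi, 16))
                while np.any(np.diff(angles) < 1e-4):
                    angles = np.sort(rng.uniform(0, 2 * np.pi, 16))
                radii = rng.uniform(3, 10, 16)
                verts = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
                contours.append(Contour(verts + rng.uniform(-20, 20, 2), Compartment.MESANGIUM, i))
            sections.append((i, contours))
        stack = ContourStack(sections, t)
        mesh = reconstruct_mesh(stack)
        expected = sum(c.area() * t for _, c in stack.contours(Compartment.MESANGIUM))
        max_rel = max(max_rel, abs(mesh.signed_volume() - expected) / expected)
        watertight += int(mesh.is_watertight)
    return {"max_rel_error": float(max_rel), "watertight_fraction": watertight / n_stacks, "n": n_stacks}


def sphere_convergence_experiment(radius: float = 10.0, counts: tuple = (5, 10, 20, 40, 80)) -> dict:
    """Reconstruction error vs the analytic sphere volume as sections double."""
    truth = 4.0 / 3.0 * np.pi * radius**3
    n_gon = 512
    errors = []
    for n_sec in counts:
        t = 2.0 * radius / n_sec
        sections = []
        for i in range(n_sec):
            z = -radius + (i + 0.5) * t
            r_mid = np.sqrt(max(radius**2 - z**2, 0.0))
            if r_mid > 1e-9:
                ang = np.linspace(0, 2 * np.pi, n_gon, endpoint=False)
                verts = np.column_stack([r_mid * np.cos(ang), r_mid * np.sin(ang)])
                sections.append((i, [Contour(verts, Compartment.MESANGIUM, i)]))
        mesh = reconstruct_mesh(ContourStack(sections, t))
        errors.append(abs(mesh.volume_um3 - truth) / truth)
    return {"section_counts": list(counts), "rel_errors": [float(e) for e in errors]}


def registration_experiment(seed: int, n_noise_reps: int = 1000, noise_sigma: float = 0.5) -> dict:
    """Noiseless rigid recovery on phantom fiducials + noisy residual law.

    The noiseless part registers a six-section phantom stack from its
    embedded fiducials and reports worst-case angle/translation error against
    the recorded perturbations.  The noisy part fits four perturbed fiducials
    repeatedly and compares the mean per-coordinate RMS residual with the
    degrees-of-freedom expectation ``sigma * sqrt(1 - 3/(2N))``.
    """
    spec = PhantomSpec(
        tuft_radii_um=(14.0, 12.0, 10.0),
        n_mesangial_blobs=0,
        target_vv=0.5,
        voxel_size_um=0.5,
        section_thickness_um=2.0,
        n_sections=6,
        pixel_size_um=0.5,
        misalignment_sigma=(2.0, 0.05),
        noise_sigma=0.0,
        seed=seed,
    )
    truth = generate_phantom(spec)
    chain = build_alignment_chain(truth.fiducial_pair_sets())
    ref = chain.reference_index
    max_angle = max_trans = 0.0
    for k in range(spec.n_sections):
        expected = truth.true_transforms[ref].compose(truth.true_transforms[k].inverse())
        got = chain.transforms[k]
        max_angle = max(max_angle, abs(got.angle - expected.angle))
        max_trans = max(max_trans, float(np.max(np.abs(np.asarray(got.translation) - expected.translation))))

    rng = np.random.default_rng(seed + 1)
    base = np.array([[0.0, 0.0], [50.0, 0.0], [50.0, 50.0], [0.0, 50.0]])
    residuals = [
        fit_rigid_transform(FiducialPairSet(0, 1, base, base + rng.normal(0, noise_sigma, base.shape)))[1]
        for _ in range(n_noise_reps)
    ]
    expected_rms = noise_sigma * np.sqrt(1.0 - 3.0 / (2 * base.shape[0]))
    return {
        "max_angle_error_rad": float(max_angle),
        "max_translation_error_um": float(max_trans),
        "mean_rms_residual_um": float(np.mean(residuals)),
        "expected_rms_residual_um": float(expected_rms),
        "n_noise_reps": n_noise_reps,
    }


def segmentation_suite_experiment(seed: int, n_sections: int = 20) -> dict:
    """Render-and-segment fidelity on a full-depth phantom stack.

    Reports the pooled mesangial Dice coefficient over all sections and the
    end-to-end mes/total area ratio error (segment -> fiducial alignment ->
    morphometrics) against the slab voxel truth.
    """
    spec = PhantomSpec(
        tuft_radii_um=(25.0, 22.0, 20.0),
        n_mesangial_blobs=15,
        target_vv=0.5,
        voxel_size_um=0.5,
        section_thickness_um=2.0,
        n_sections=n_sections,
        pixel_size_um=0.5,
        misalignment_sigma=(1.0, 0.02),
        noise_sigma=5.0,
        seed=seed,
    )
    truth = generate_phantom(spec)
    images, fiducials = render_sections(truth, spec)
    inter = total = 0
    sections = []
    for img in images:
        masks = segment_masks(img)
        tm = truth.per_section_truth_masks[img.section_index]["mesangium"]
        inter += int(np.logical_and(masks["mesangium"], tm).sum())
        total += int(masks["mesangium"].sum() + tm.sum())
        cs = mask_to_contours(masks["mesangium"], spec.pixel_size_um, Compartment.MESANGIUM, img.section_index)
        cs += mask_to_contours(masks["tuft"], spec.pixel_size_um, Compartment.TUFT, img.section_index)
        sections.append((img.section_index, cs))
    dice = 2.0 * inter / total
    chain = build_alignment_chain(fiducials)
    aligned = apply_alignment(ContourStack(sections, spec.section_thickness_um, aligned=False), chain)
    record = compute_morphometrics(aligned)
    slab_vv = truth.slab_mesangial_volume_um3 / truth.slab_tuft_volume_um3
    return {
        "dice": float(dice),
        "vv_estimate": float(record.mes_to_total_ratio),
        "vv_truth": float(slab_vv),
        "vv_abs_error": float(abs(record.mes_to_total_ratio - slab_vv)),
        "n_sections": n_sections,
    }


def anova_oracle_experiment(seed: int, n_tables: int = 100) -> dict:
    """Within-subject ANOVA vs a brute-force sums-of-squares oracle."""
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    for _ in range(n_tables):
        n = int(rng.integers(3, 12))
        k = int(rng.integers(2, 5))
        x = rng.uniform(10, 1000, (n, k))
        rows = [(f"u{i}", f"m{j}", float(x[i, j])) for i in range(n) for j in range(k)]
        res = repeated_measures_anova(MeasurementTable.from_long(rows))
        # oracle: explicit elementwise sums of squares, coded independently
        grand = x.sum() / (n * k)
        ss_total = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
        ss_method = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
        ss_subject = sum(k * (x[i, :].mean() - grand) ** 2 for i in range(n))
        ss_error = ss_total - ss_method - ss_subject
        f_oracle = (ss_method / (k - 1)) / (ss_error / ((k - 1) * (n - 1)))
        max_diff = max(max_diff, abs(res.f_statistic - f_oracle))
        assert (res.df_between, res.df_error) == (k - 1, (k - 1) * (n - 1))
    # the common report shape: 3 methods on 9 units -> F(2, 16)
    x = rng.uniform(10, 1000, (9, 3))
    rows = [(f"u{i}", f"m{j}", float(x[i, j])) for i in range(9) for j in range(3)]
    res = repeated_measures_anova(MeasurementTable.from_long(rows))
    return {
        "max_f_abs_diff": float(max_diff),
        "df_for_9x3": (res.df_between, res.df_error),
        "n_tables": n_tables,
    }


def _phantom_three_methods(truth, spec, erode_px: int = 1, spacing: float = 2.0, seed: int = 0):
    """Mesangial volume of one phantom by the three measurement routes.

    3D: truth-mask contours extruded (the serial-reconstruction path).
    PSI: Cavalieri point counting on masks eroded by ``erode_px`` (the
    conservative-boundary counting that biases PSI low).
    TEM-style planimetry: mean mesangial profile area times slab depth.
    """
    mes_masks = {k: m["mesangium"] for k, m in truth.per_section_truth_masks.items()}
    sections = []
    for k, m in mes_masks.items():
        cs = mask_to_contours(m, spec.pixel_size_um, Compartment.MESANGIUM, k)
        sections.append((k, cs))
    stack = ContourStack(sections, spec.section_thickness_um)
    v3d = reconstruct_mesh(stack, Compartment.MESANGIUM).volume_um3

    eroded = {k: ndimage.binary_erosion(m) for k, m in mes_masks.items()}
    v_psi, _ = cavalieri_volume(
        {"masks": eroded, "pixel_size_um": spec.pixel_size_um, "thickness_um": spec.section_thickness_um},
        spacing_um=spacing,
        seed=seed,
    )
    areas = [sum(c.area() for c in cs) for _, cs in sections]
    v_tem = float(np.mean(areas)) * spec.section_thickness_um * spec.n_sections
    return v3d, float(v_psi), v_tem


def psi_bias_experiment(seed: int, n_phantoms: int = 20) -> dict:
    """Direction-of-bias study: eroded-mask PSI vs 3D reconstruction.

    Generates a phantom cohort, measures each phantom by all three routes
    (with one pixel of mask erosion injected into the PSI path only), and
    tests whether PSI falls significantly below 3D while 3D itself stays
    within a few percent of voxel truth.
    """
    rng = np.random.default_rng(seed)
    rows = []
    rel_errors_3d = []
    for i in range(n_phantoms):
        spec = PhantomSpec(
            tuft_radii_um=(12.0, 11.0, 10.0),
            n_mesangial_blobs=8,
            target_vv=float(rng.uniform(0.35, 0.65)),
            voxel_size_um=0.5,
            section_thickness_um=2.0,
            n_sections=10,
            pixel_size_um=0.5,
            misalignment_sigma=(0.0, 0.0),
            noise_sigma=0.0,
            seed=seed + 100 + i,
        )
        truth = generate_phantom(spec)
        v3d, v_psi, v_tem = _phantom_three_methods(truth, spec, seed=seed + 200 + i)
        rel_errors_3d.append(abs(v3d - truth.slab_mesangial_volume_um3) / truth.slab_mesangial_volume_um3)
        rows += [
            (f"g{i}", "TEM", v_tem),
            (f"g{i}", "PSI", v_psi),
            (f"g{i}", "THREE_D", v3d),
        ]
    table = MeasurementTable.from_long(rows)
    posthoc = posthoc_contrasts(table)
    psi_vs_3d = posthoc[(posthoc.method_a == "PSI") & (posthoc.method_b == "THREE_D")].iloc[0]
    corr = np.corrcoef(np.column_stack([table.data[m].values for m in table.methods]).T)
    psi_mean = float(table.data["PSI"].mean())
    v3d_mean = float(table.data["THREE_D"].mean())
    return {
        "psi_below_3d_pct": 100.0 * (v3d_mean - psi_mean) / v3d_mean,
        "psi_vs_3d_p_value": float(psi_vs_3d.p_value),
        "psi_mean": float(table.data["PSI"].mean()),
        "three_d_mean": float(table.data["THREE_D"].mean()),
        "three_d_max_rel_error": float(np.max(rel_errors_3d)),
        "min_pairwise_r": float(np.min(corr[np.triu_indices(3, 1)])),
        "n_phantoms": n_phantoms,
    }


def cohort_ordering_experiment(seed: int, n_replicates: int = 100, n_per_group: int = 4) -> dict:
    """Fraction of cohort replicates preserving the albuminuria-group ordering.

    Each replicate draws group-structured phantoms at the preset Vv levels
    (normo 0.47 +/- 0.15, micro 0.53 +/- 0.09, macro 0.76 +/- 0.08), measures
    every phantom's mes/total area ratio through the reconstruction path, and
    scores whether the macro-group mean exceeds the pooled normo/micro mean.
    """
    template = PhantomSpec(
        tuft_radii_um=(10.0, 9.0, 8.0),
        n_mesangial_blobs=6,
        target_vv=0.5,
        voxel_size_um=0.5,
        section_thickness_um=2.0,
        n_sections=8,
        pixel_size_um=0.75,
        misalignment_sigma=(0.0, 0.0),
        noise_sigma=0.0,
        seed=seed,
    )
    ordered = 0
    for rep in range(n_replicates):
        phantoms, _ = generate_cohort(
            n_per_group, seed=seed + 1000 * rep, spec_template=template
        )
        ratios: dict[str, list[float]] = {}
        for group, spec, truth in phantoms:
            sections = []
            for k, m in truth.per_section_truth_masks.items():
                cs = mask_to_contours(m["mesangium"], spec.pixel_size_um, Compartment.MESANGIUM, k)
                cs += mask_to_contours(m["tuft"], spec.pixel_size_um, Compartment.TUFT, k)
                sections.append((k, cs))
            rec = compute_morphometrics(ContourStack(sections, spec.section_thickness_um))
            ratios.setdefault(group, []).append(rec.mes_to_total_ratio)
        macro = np.mean(ratios["macro"])
        rest = np.mean(ratios["normo"] + ratios["micro"])
        ordered += int(macro > rest)
    return {
        "ordered_fraction": ordered / n_replicates,
        "n_replicates": n_replicates,
        "n_per_group": n_per_group,
    }
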