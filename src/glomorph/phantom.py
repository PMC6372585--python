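"""Synthetic glomerulus phantoms with exact voxel ground truth.

A phantom is a voxelized ellipsoidal tuft containing a lobulated mesangial
compartment built as a thresholded sum of Gaussian blobs; the field threshold
is tuned by bisection until the realized mesangial volume fraction Vv matches
a target.  The phantom is then "sectioned" into serial slabs of fixed
thickness and rendered as PAS-like RGB images (Beer–Lambert forward model
with the segmentation module's default stain vectors), with per-section rigid
misalignment, sensor noise and four embedded fiducial dots — emulating serial
1 µm PAS histology so every downstream estimator can be scored against exact
voxel-count truth.

All randomness flows from the spec's single seed; identical specs reproduce
bit-identical phantoms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from glomorph.geometry import Compartment, RigidTransform2D
from glomorph.segmentation import HEMATOXYLIN_VECTOR, PAS_VECTOR, SectionImage, _unit, od_to_rgb
from glomorph.registration import FiducialPairSet


class VvUnreachableError(ValueError):
    """Bisection could not realize the requested Vv with the given blob count."""

    def __init__(self, target: float, best: float):
        super().__init__(f"target Vv {target:.3f} unreachable; best achieved {best:.3f}")
        self.best = best


#: Stain concentrations used by the forward render (OD units).
RENDER_CONC = {
    "mesangium": {"pas": 0.90, "hem": 0.25},
    "tuft": {"pas": 0.10, "hem": 0.45},
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic glomerulus.

    Defaults emulate the acquisition this toolkit targets: six serial 1 µm
    PAS sections through the middle of the tuft, photographed at 0.25 µm per
    pixel, with a few-µm manual mounting misalignment between sections.  The
    tuft is a scaled-down ellipsoid (40x36x32 µm semi-axes) so that the
    oracle voxelization at 0.25 µm stays tractable.
    """

    tuft_radii_um: tuple[float, float, float] = (40.0, 36.0, 32.0)
    n_mesangial_blobs: int = 25
    target_vv: float = 0.50
    voxel_size_um: float = 0.25
    section_thickness_um: float = 1.0
    n_sections: int = 6
    pixel_size_um: float = 0.25
    misalignment_sigma: tuple[float, float] = (2.0, 0.05)  # (µm, radians)
    noise_sigma: float = 5.0  # 8-bit intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.tuft_radii_um) <= 0 or self.voxel_size_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("all lengths must be positive")
        if not 0 < self.target_vv < 1:
            raise ValueError("target_vv must lie in (0, 1)")
        if self.n_sections < 1 or self.section_thickness_um <= 0:
            raise ValueError("need at least one section of positive thickness")
        if self.n_sections * self.section_thickness_um > 2 * self.tuft_radii_um[2] + 2 * self.voxel_size_um:
            raise ValueError("sections exceed the phantom depth")


@dataclass
class PhantomTruth:
    """Exact voxel ground truth plus recorded per-section perturbations.

    ``labels`` is (nx, ny, nz) uint8: 0 background, 1 tuft, 2 mesangium
    (mesangial voxels are a subset of the tuft).  ``true_transforms[k]`` maps
    phantom-frame µm coordinates into section *k*'s rendered image frame;
    fiducial and truth masks are stored in that rendered frame so estimates
    made on the rendered stack compare directly.  Slab-restricted volumes
    (``slab_*``) cover only the sectioned depth range, for commensurable
    comparison when the sections do not span the whole tuft.
    """

    labels: np.ndarray
    voxel_size_um: float
    origin_um: tuple[float, float, float]
    z0_um: float
    true_tuft_volume_um3: float
    true_mesangial_volume_um3: float
    true_vv: float
    slab_tuft_volume_um3: float
    slab_mesangial_volume_um3: float
    per_section_truth_masks: dict
    true_transforms: dict[int, RigidTransform2D]
    fiducial_points: dict[int, np.ndarray]
    fiducial_points_phantom: np.ndarray
    image_shape: tuple[int, int]
    spec: PhantomSpec

    def fiducial_pair_sets(self) -> list[FiducialPairSet]:
        """Matched fiducial lists for every adjacent section pair."""
        n = self.spec.n_sections
        return [
            FiducialPairSet(k, k + 1, self.fiducial_points[k], self.fiducial_points[k + 1])
            for k in range(n - 1)
        ]


def _poisson_disc_in_ellipsoid(rng, radii, n, r_min):
    """Dart-throwing Poisson-disc sampling inside a shrunken ellipsoid."""
    a, b, c = [0.85 * r for r in radii]
    pts: list[np.ndarray] = []
    r = r_min
    tries = 0
    while len(pts) < n:
        cand = rng.uniform(-1, 1, size=3) * (a, b, c)
        if (cand[0] / a) ** 2 + (cand[1] / b) ** 2 + (cand[2] / c) ** 2 > 1:
            continue
        if all(np.linalg.norm(cand - p) >= r for p in pts):
            pts.append(cand)
            tries = 0
        else:
            tries += 1
            if tries > 2000:  # relax the exclusion radius rather than loop forever
                r *= 0.8
                tries = 0
    return np.asarray(pts)


def _blob_field(shape, origin, voxel, centers, sigma):
    """Sum of truncated isotropic Gaussian kernels, accumulated per blob."""
    field_arr = np.zeros(shape, dtype=np.float32)
    reach = 4.0 * sigma
    axes = [origin[d] + voxel * np.arange(shape[d]) for d in range(3)]
    for cx, cy, cz in centers:
        sl = []
        for d, cc in enumerate((cx, cy, cz)):
            lo = int(np.searchsorted(axes[d], cc - reach))
            hi = int(np.searchsorted(axes[d], cc + reach))
            sl.append(slice(lo, hi))
        if any(s.start >= s.stop for s in sl):
            continue
        dx = axes[0][sl[0]] - cx
        dy = axes[1][sl[1]] - cy
        dz = axes[2][sl[2]] - cz
        r2 = dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
        field_arr[sl[0], sl[1], sl[2]] += np.exp(-r2 / (2.0 * sigma**2)).astype(np.float32)
    return field_arr


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Build the voxel phantom and record all per-section ground truth.

    The mesangial compartment is the level set ``field >= tau`` of a sum of
    Gaussian blobs at Poisson-disc centers inside the tuft; ``tau`` is tuned
    by up to 60 bisection steps until ``|realized Vv - target_vv| <= 0.01``.
    Deterministic for a fixed spec (all randomness from ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed)
    a, b, c = spec.tuft_radii_um
    v = spec.voxel_size_um
    margin = 2 * v
    origin = (-(a + margin), -(b + margin), -(c + margin))
    shape = tuple(int(math.ceil(2 * (r + margin) / v)) + 1 for r in (a, b, c))
    xs = origin[0] + v * np.arange(shape[0])
    ys = origin[1] + v * np.arange(shape[1])
    zs = origin[2] + v * np.arange(shape[2])
    tuft = (
        (xs[:, None, None] / a) ** 2 + (ys[None, :, None] / b) ** 2 + (zs[None, None, :] / c) ** 2
    ) <= 1.0

    labels = tuft.astype(np.uint8)
    n_tuft = int(tuft.sum())

    if spec.n_mesangial_blobs > 0:
        r_min = 0.7 * ((4.0 / 3.0) * math.pi * a * b * c / spec.n_mesangial_blobs) ** (1.0 / 3.0)
        sigma = 0.5 * r_min
        centers = _poisson_disc_in_ellipsoid(rng, (a, b, c), spec.n_mesangial_blobs, r_min)
        fld = _blob_field(shape, origin, v, centers, sigma)
        fld_tuft = fld[tuft]

        def vv_at(tau: float) -> float:
            return float((fld_tuft >= tau).sum()) / n_tuft

        lo, hi = 0.0, float(fld_tuft.max()) if fld_tuft.size else 0.0
        best_tau, best_err = hi, abs(vv_at(hi) - spec.target_vv)
        if vv_at(1e-9) < spec.target_vv - 0.01:
            raise VvUnreachableError(spec.target_vv, vv_at(1e-9))
        tau = hi
        for _ in range(60):
            tau = 0.5 * (lo + hi)
            vv = vv_at(tau)
            err = abs(vv - spec.target_vv)
            if err < best_err:
                best_tau, best_err = tau, err
            if err <= 0.01:
                break
            if vv > spec.target_vv:
                lo = tau
            else:
                hi = tau
        if best_err > 0.01:
            raise VvUnreachableError(spec.target_vv, vv_at(best_tau))
        mes = tuft & (fld >= best_tau)
        labels[mes] = 2

    vol_voxel = v**3
    n_mes = int((labels == 2).sum())
    true_tuft = n_tuft * vol_voxel
    true_mes = n_mes * vol_voxel
    true_vv = (true_mes / true_tuft) if n_tuft else 0.0

    # sectioning: n slabs of thickness t centered on the tuft mid-plane
    t = spec.section_thickness_um
    n_sec = spec.n_sections
    z0 = -0.5 * n_sec * t
    iz_lo = int(np.searchsorted(zs, z0 - 1e-9))
    iz_hi = int(np.searchsorted(zs, z0 + n_sec * t - 1e-9))
    slab = labels[:, :, iz_lo:iz_hi]
    slab_tuft = float((slab >= 1).sum()) * vol_voxel
    slab_mes = float((slab == 2).sum()) * vol_voxel

    # per-section rigid perturbations and the shared image frame
    p = spec.pixel_size_um
    sig_t, sig_r = spec.misalignment_sigma
    ring_r = 1.25 * max(a, b) + 4.0
    half = ring_r + 3.0 * sig_t + 4.0
    npx = int(math.ceil(2 * half / p)) + 1
    image_shape = (npx, npx)
    center = RigidTransform2D(0.0, (half, half))  # phantom origin -> image center

    phi = rng.uniform(0, 2 * math.pi)
    fid_phantom = np.array(
        [
            (ring_r * math.cos(phi + k * math.pi / 2), ring_r * math.sin(phi + k * math.pi / 2))
            for k in range(4)
        ]
    )

    transforms: dict[int, RigidTransform2D] = {}
    fiducials: dict[int, np.ndarray] = {}
    truth_masks: dict[int, dict] = {}
    cols = p * np.arange(npx)
    rows = p * np.arange(npx)
    gx, gy = np.meshgrid(cols, rows, indexing="xy")  # image-frame µm at pixel centers
    img_pts = np.column_stack([gx.ravel(), gy.ravel()])

    for k in range(n_sec):
        ang = rng.normal(0.0, sig_r) if sig_r > 0 else 0.0
        dx, dy = (rng.normal(0.0, sig_t, size=2) if sig_t > 0 else (0.0, 0.0))
        perturb = RigidTransform2D(ang, (float(dx), float(dy)))
        q = center.compose(perturb)  # phantom -> image frame of section k
        transforms[k] = q
        fiducials[k] = q.apply(fid_phantom)

        z_mid = z0 + (k + 0.5) * t
        iz = int(round((z_mid - origin[2]) / v))
        ph = q.inverse().apply(img_pts)
        ix = np.round((ph[:, 0] - origin[0]) / v).astype(int)
        iy = np.round((ph[:, 1] - origin[1]) / v).astype(int)
        ok = (ix >= 0) & (ix < shape[0]) & (iy >= 0) & (iy < shape[1]) & (0 <= iz < shape[2])
        lab = np.zeros(img_pts.shape[0], dtype=np.uint8)
        lab[ok] = labels[ix[ok], iy[ok], iz]
        lab = lab.reshape(npx, npx)  # (row, col)
        truth_masks[k] = {"mesangium": lab == 2, "tuft": lab >= 1}

    return PhantomTruth(
        labels=labels,
        voxel_size_um=v,
        origin_um=origin,
        z0_um=z0,
        true_tuft_volume_um3=true_tuft,
        true_mesangial_volume_um3=true_mes,
        true_vv=true_vv,
        slab_tuft_volume_um3=slab_tuft,
        slab_mesangial_volume_um3=slab_mes,
        per_section_truth_masks=truth_masks,
        true_transforms=transforms,
        fiducial_points=fiducials,
        fiducial_points_phantom=fid_phantom,
        image_shape=image_shape,
        spec=spec,
    )


def render_sections(truth: PhantomTruth, spec: PhantomSpec | None = None):
    """Render PAS-like RGB images of every section of a phantom.

    Each section's truth masks are converted to optical density with the
    default PAS/hematoxylin stain vectors (mesangium strongly PAS-positive,
    remaining tuft counterstain-dominant, background white), inverted through
    Beer–Lambert to 8-bit RGB, degraded with Gaussian noise, and stamped with
    four high-contrast fiducial dots at the recorded (perturbed) coordinates.

    Returns ``(images, fiducial_pair_sets)`` where ``images`` is a list of
    :class:`SectionImage` and the pair sets feed the registration module.
    """
    spec = spec or truth.spec
    p = spec.pixel_size_um
    vp = _unit(PAS_VECTOR)
    vh = _unit(HEMATOXYLIN_VECTOR)
    images: list[SectionImage] = []
    for k in range(spec.n_sections):
        masks = truth.per_section_truth_masks[k]
        mes, tuft = masks["mesangium"], masks["tuft"]
        od = np.zeros(mes.shape + (3,), dtype=float)
        body = tuft & ~mes
        od[body] = RENDER_CONC["tuft"]["pas"] * vp + RENDER_CONC["tuft"]["hem"] * vh
        od[mes] = RENDER_CONC["mesangium"]["pas"] * vp + RENDER_CONC["mesangium"]["hem"] * vh
        rgb = od_to_rgb(od).astype(float)
        if spec.noise_sigma > 0:
            rng = np.random.default_rng([spec.seed, 1000003, k])
            rgb += rng.normal(0.0, spec.noise_sigma, size=rgb.shape)
        rgb = np.clip(np.round(rgb), 0, 255).astype(np.uint8)
        # fiducial dots: dark disks of radius 0.5 µm at the recorded positions
        rr, cc = np.mgrid[0 : mes.shape[0], 0 : mes.shape[1]]
        for fx, fy in truth.fiducial_points[k]:
            d2 = (cc * p - fx) ** 2 + (rr * p - fy) ** 2
            rgb[d2 <= 0.25] = (20, 20, 20)
        images.append(SectionImage(rgb, p, section_index=k, thickness_um=spec.section_thickness_um))
    return images, truth.fiducial_pair_sets()


#: Mean and SD of Vv(mes/glom) per albuminuria group used for cohort presets.
COHORT_VV_PRESETS = {"normo": (0.47, 0.15), "micro": (0.53, 0.09), "macro": (0.76, 0.08)}


def generate_cohort(
    n_per_group: int,
    group_vv_levels: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    spec_template: PhantomSpec | None = None,
):
    """Generate a cohort of phantoms with group-structured Vv targets.

    Each phantom's target Vv is drawn ``Normal(mean, sd)`` for its group,
    truncated to (0.05, 0.95); per-phantom child seeds are ``seed + index``.
    Returns ``(phantoms, manifest)`` where ``phantoms`` is a list of
    ``(group, spec, truth)`` and ``manifest`` a DataFrame with one row per
    phantom (group, seeds, target and realized Vv, true volumes).
    """
    groups = group_vv_levels or COHORT_VV_PRESETS
    template = spec_template or PhantomSpec()
    rng = np.random.default_rng(seed)
    phantoms = []
    rows = []
    idx = 0
    for group, (mean, sd) in groups.items():
        for _ in range(n_per_group):
            if sd > 0:
                target = float(rng.normal(mean, sd))
                while not 0.05 < target < 0.95:  # truncated normal by rejection
                    target = float(rng.normal(mean, sd))
            else:
                target = float(mean)
            child_seed = seed + 1 + idx
            spec = replace(template, target_vv=target, seed=child_seed)
            truth = generate_phantom(spec)
            phantoms.append((group, spec, truth))
            rows.append(
                {
                    "phantom_id": idx,
                    "group": group,
                    "seed": child_seed,
                    "target_vv": target,
                    "realized_vv": truth.true_vv,
                    "true_tuft_volume_um3": truth.true_tuft_volume_um3,
                    "true_mesangial_volume_um3": truth.true_mesangial_volume_um3,
                    "n_sections": spec.n_sections,
                    "section_thickness_um": spec.section_thickness_um,
                }
            )
            idx += 1
    return phantoms, pd.DataFrame(rows)
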