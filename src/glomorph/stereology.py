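"""Stereological volume estimation: Cavalieri point counting and PSI.

The Cavalieri principle states that an object's volume equals section
thickness times the sum of its profile areas over systematic parallel
sections.  Point counting replaces the areas: a systematic uniform random
(SUR) grid of pitch *s* is overlaid on each section, each grid point carries
an area ``a_p = s**2``, and the volume estimate is

    V_hat = t * a_p * sum_i P_i

with ``P_i`` the number of points hitting the compartment on section *i*.
Because the grid offset is uniform on ``[0, s)^2``, the estimator is unbiased.
The PSI fractional volume is the ratio of mesangial to reference (tuft) hits,
``Vv(mes/glom) = sum P_mes / sum P_ref``.  Planimetry measures traced profile
areas directly and converts the mean area to a volume by an explicit model.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from glomorph.geometry import BOUNDARY_TOL_UM, Compartment, Contour, classify_points
from glomorph.reconstruction import ContourStack


class EmptyGridError(ValueError):
    """Grid spacing exceeds the extent; no sampling points would be placed."""


class UndefinedFractionError(ZeroDivisionError):
    """Reference compartment received zero hits; Vv is undefined."""


class MixedThicknessError(ValueError):
    """Sections disagree on thickness; Cavalieri requires a uniform t."""


class CountingRule(enum.Enum):
    """How boundary hits are scored: the Gundersen half-point convention
    (default), strict interior only, or boundary counted as a full hit."""

    HALF = "half"
    STRICT = "strict"
    INCLUSIVE = "inclusive"


class VolumeModel(enum.Enum):
    """Planimetry area-to-volume rule: extrusion by an equivalent thickness,
    or the Weibel–Gomez shape-coefficient formula for quasi-spherical bodies."""

    EXTRUSION = "extrusion"
    WEIBEL_GOMEZ = "weibel_gomez"


#: Weibel–Gomez shape coefficient (quasi-sphere) and size-distribution factor.
WEIBEL_GOMEZ_BETA = 1.38
WEIBEL_GOMEZ_K = 1.1


@dataclass(frozen=True)
class PointGrid:
    """Systematic uniform random point grid.

    Points sit at ``(x0 + ox + i*s, y0 + oy + j*s)`` over the extent
    ``(x0, y0, x1, y1)``; the offset ``(ox, oy)`` is drawn uniformly from
    ``[0, s)^2`` by the stored seed, so regenerating with the same seed
    reproduces the grid exactly.  Area per point ``a_p = s**2`` µm².
    """

    spacing_um: float
    offset: tuple[float, float]
    extent: tuple[float, float, float, float]
    seed: int | None = None

    def __post_init__(self) -> None:
        s = self.spacing_um
        if s <= 0:
            raise ValueError("spacing_um must be positive")
        ox, oy = self.offset
        if not (0 <= ox < s and 0 <= oy < s):
            raise ValueError("offset must lie in [0, spacing)^2")

    @property
    def a_p_um2(self) -> float:
        return self.spacing_um**2

    def points(self) -> np.ndarray:
        """All grid points inside the extent as an (N, 2) array."""
        x0, y0, x1, y1 = self.extent
        s = self.spacing_um
        xs = np.arange(x0 + self.offset[0], x1 + 0.5 * s, s)
        ys = np.arange(y0 + self.offset[1], y1 + 0.5 * s, s)
        xs = xs[xs <= x1]
        ys = ys[ys <= y1]
        if xs.size == 0 or ys.size == 0:
            raise EmptyGridError("no grid points fall inside the extent")
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass
class CountResult:
    """Per-section grid hit counts backing a Cavalieri/PSI estimate."""

    per_section_counts: dict[int, dict[str, float]]
    a_p_um2: float
    thickness_um: float
    counting_rule: CountingRule = CountingRule.HALF
    seed: int | None = None

    def total(self, key: str) -> float:
        return float(sum(c.get(key, 0.0) for c in self.per_section_counts.values()))


@dataclass(frozen=True)
class PlanimetryResult:
    """Planimetry of traced profiles: areas, their mean, and a model volume."""

    profile_areas_um2: tuple
    mean_mesangial_area_um2: float
    estimated_volume_um3: float
    volume_model: VolumeModel
    t_equiv_um: float | None = None


def make_grid(
    extent: tuple[float, float, float, float],
    spacing_um: float,
    seed: int | None = None,
    offset: tuple[float, float] | None = None,
) -> PointGrid:
    """Create a SUR grid over ``extent = (x0, y0, x1, y1)``.

    ``offset`` forces a deterministic offset (exact-reproducibility mode);
    otherwise it is drawn uniformly from ``[0, spacing)^2`` with ``seed``.
    """
    x0, y0, x1, y1 = extent
    if x1 <= x0 or y1 <= y0:
        raise ValueError("extent must be a non-degenerate rectangle")
    if spacing_um > (x1 - x0) and spacing_um > (y1 - y0):
        raise EmptyGridError("spacing exceeds both extent dimensions")
    if offset is None:
        rng = np.random.default_rng(seed)
        offset = tuple(rng.uniform(0.0, spacing_um, size=2))
    return PointGrid(spacing_um, (float(offset[0]), float(offset[1])), (x0, y0, x1, y1), seed)


def _count_hits_contours(points: np.ndarray, contours: list[Contour], rule: CountingRule) -> float:
    """Score grid hits against a set of disjoint contours with the given rule."""
    inside = np.zeros(points.shape[0], dtype=bool)
    boundary = np.zeros(points.shape[0], dtype=bool)
    for c in contours:
        ins, bnd = classify_points(points, c, BOUNDARY_TOL_UM)
        inside |= ins
        boundary |= bnd
    boundary &= ~inside
    if rule is CountingRule.STRICT:
        return float(inside.sum())
    if rule is CountingRule.INCLUSIVE:
        return float(inside.sum() + boundary.sum())
    return float(inside.sum()) + 0.5 * float(boundary.sum())


def _count_hits_mask(points: np.ndarray, mask: np.ndarray, pixel_size_um: float) -> float:
    """Score hits against a binary pixel mask (a point hits the pixel it falls in)."""
    cols = np.floor(points[:, 0] / pixel_size_um).astype(int)
    rows = np.floor(points[:, 1] / pixel_size_um).astype(int)
    ok = (rows >= 0) & (rows < mask.shape[0]) & (cols >= 0) & (cols < mask.shape[1])
    return float(mask[rows[ok], cols[ok]].sum())


def _sections_from_input(stack_or_masks, compartment, reference=None):
    """Normalize input to ``[(index, payload, ref_payload)]`` plus mode/thickness.

    Accepts a :class:`ContourStack` (payloads are contour lists) or a dict
    ``{"masks": {idx: bool array}, "pixel_size_um": p, "thickness_um": t,
    "reference_masks": {...}}``.
    """
    if isinstance(stack_or_masks, ContourStack):
        items = []
        for i, _ in stack_or_masks.sections:
            cs = [c for j, c in stack_or_masks.contours(compartment) if j == i]
            ref = (
                [c for j, c in stack_or_masks.contours(reference) if j == i]
                if reference is not None
                else None
            )
            items.append((i, cs, ref))
        return "contours", items, stack_or_masks.thickness_um, None
    masks = stack_or_masks["masks"]
    refs = stack_or_masks.get("reference_masks")
    t = stack_or_masks["thickness_um"]
    if np.ndim(t) > 0:
        t = np.asarray(t, dtype=float)
        if not np.allclose(t, t.flat[0]):
            raise MixedThicknessError("sections have differing thickness")
        t = float(t.flat[0])
    p = stack_or_masks["pixel_size_um"]
    items = [(i, m, refs[i] if refs else None) for i, m in sorted(masks.items())]
    return "masks", items, float(t), float(p)


def _grid_for_input(mode, items, pixel_size, spacing_um, seed, offset):
    """Grid extent = bounding box of all payloads padded by one spacing."""
    if mode == "masks":
        h, w = next(iter(items))[1].shape
        x1, y1 = w * pixel_size, h * pixel_size
        ext = (-spacing_um, -spacing_um, x1 + spacing_um, y1 + spacing_um)
    else:
        # extent covers the reference compartment when present (PSI), else the
        # counted compartment itself
        pools = [(ref if ref is not None else cs) for _, cs, ref in items]
        pts = np.vstack([c.vertices for cs in pools for c in cs] or [np.zeros((1, 2))])
        ext = (
            pts[:, 0].min() - spacing_um,
            pts[:, 1].min() - spacing_um,
            pts[:, 0].max() + spacing_um,
            pts[:, 1].max() + spacing_um,
        )
    return make_grid(ext, spacing_um, seed=seed, offset=offset)


def cavalieri_volume(
    stack_or_masks,
    grid: PointGrid | None = None,
    compartment: Compartment = Compartment.MESANGIUM,
    counting_rule: CountingRule = CountingRule.HALF,
    spacing_um: float | None = None,
    seed: int | None = None,
    offset: tuple[float, float] | None = None,
) -> tuple[float, CountResult]:
    """Cavalieri point-count volume estimate ``V_hat = t * a_p * sum(P)``.

    ``stack_or_masks`` is a :class:`ContourStack` (points classified against
    contours; boundary handling per ``counting_rule``) or a mask dict (see
    :func:`_sections_from_input`; a point hits the pixel it falls inside).
    One grid is used for all sections; pass ``grid`` explicitly or let one be
    built with SUR offset from ``seed`` over the padded bounding box.
    """
    mode, items, t, pixel_size = _sections_from_input(stack_or_masks, compartment)
    if grid is None:
        if spacing_um is None:
            raise ValueError("either grid or spacing_um is required")
        grid = _grid_for_input(mode, items, pixel_size, spacing_um, seed, offset)
    points = grid.points()
    counts: dict[int, dict[str, float]] = {}
    for i, payload, _ in items:
        if mode == "masks":
            p_hit = _count_hits_mask(points, payload, pixel_size)
        else:
            p_hit = _count_hits_contours(points, payload, counting_rule)
        counts[i] = {"P": p_hit}
    result = CountResult(counts, grid.a_p_um2, t, counting_rule, grid.seed)
    v_hat = t * grid.a_p_um2 * result.total("P")
    return float(v_hat), result


def psi_fractional_volume(
    stack_or_masks,
    grid: PointGrid | None = None,
    compartment: Compartment = Compartment.MESANGIUM,
    reference: Compartment = Compartment.TUFT,
    counting_rule: CountingRule = CountingRule.HALF,
    spacing_um: float | None = None,
    seed: int | None = None,
    offset: tuple[float, float] | None = None,
) -> tuple[float, CountResult]:
    """PSI fractional volume ``Vv = sum(P_mes) / sum(P_ref)`` over sections.

    The compartment must be nested in the reference (tuft) so ``Vv`` lies in
    ``[0, 1]``.  Raises :class:`UndefinedFractionError` on zero reference hits.
    """
    mode, items, t, pixel_size = _sections_from_input(stack_or_masks, compartment, reference)
    if grid is None:
        if spacing_um is None:
            raise ValueError("either grid or spacing_um is required")
        grid = _grid_for_input(mode, items, pixel_size, spacing_um, seed, offset)
    points = grid.points()
    counts: dict[int, dict[str, float]] = {}
    for i, payload, ref in items:
        if mode == "masks":
            p_mes = _count_hits_mask(points, payload, pixel_size)
            p_ref = _count_hits_mask(points, ref, pixel_size) if ref is not None else p_mes
        else:
            p_mes = _count_hits_contours(points, payload, counting_rule)
            p_ref = _count_hits_contours(points, ref, counting_rule) if ref is not None else p_mes
        counts[i] = {"P_mes": p_mes, "P_ref": p_ref}
    result = CountResult(counts, grid.a_p_um2, t, counting_rule, grid.seed)
    p_ref_total = result.total("P_ref")
    if p_ref_total == 0:
        raise UndefinedFractionError("zero reference hits; Vv undefined")
    return float(result.total("P_mes") / p_ref_total), result


def planimetry(
    profiles: list[Contour],
    volume_model: VolumeModel = VolumeModel.EXTRUSION,
    t_equiv_um: float | None = None,
) -> PlanimetryResult:
    """Planimetry of traced profiles.

    Per-profile areas by the shoelace formula; the mean area is converted to
    a volume by the chosen model: EXTRUSION gives ``V = mean_area * t_equiv``
    (the default, with ``t_equiv`` = section thickness), WEIBEL_GOMEZ gives
    ``V = (beta / k) * mean_area ** 1.5`` with beta = 1.38, k = 1.1.
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    areas = tuple(c.area() for c in profiles)
    mean_area = float(np.mean(areas))
    if volume_model is VolumeModel.EXTRUSION:
        if t_equiv_um is None:
            raise ValueError("EXTRUSION model requires t_equiv_um")
        volume = mean_area * t_equiv_um
    else:
        volume = (WEIBEL_GOMEZ_BETA / WEIBEL_GOMEZ_K) * mean_area**1.5
    return PlanimetryResult(areas, mean_area, float(volume), volume_model, t_equiv_um)
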