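"""Stain-based segmentation of PAS-stained section images.

PAS stains mesangial matrix magenta against a hematoxylin counterstain.  The
camera intensities are converted to optical density (Beer–Lambert), unmixed
against known stain color vectors (color deconvolution), and the PAS-positive
channel is thresholded to yield mesangial regions; the whole-tuft outline is
the filled outer boundary of all tissue-positive pixels.  Contours are
extracted at the 0.5 iso-level of the cleaned masks with sub-pixel boundary
following, so segmentation replaces interactive tracing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import measure, morphology

from glomorph.geometry import Compartment, Contour, DegenerateGeometryError

logger = logging.getLogger(__name__)


class CollinearStainsError(ValueError):
    """Stain vectors are collinear; the unmixing system is singular."""


class NoContrastError(ValueError):
    """Channel is constant; no threshold can separate classes."""


#: Default PAS (magenta-dominant) stain vector in OD-RGB space.
PAS_VECTOR = (0.175, 0.972, 0.154)
#: Hematoxylin counterstain vector (standard H&E hematoxylin calibration).
HEMATOXYLIN_VECTOR = (0.650, 0.704, 0.286)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class SectionImage:
    """One photographed serial section: RGB raster plus physical metadata."""

    pixels: np.ndarray
    pixel_size_um: float
    section_index: int = 0
    thickness_um: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.size == 0:
            raise ValueError("pixels must be a non-empty (H, W, 3) RGB raster")
        if px.dtype != np.uint8:
            px = np.clip(np.round(px), 0, 255).astype(np.uint8)
        if self.pixel_size_um <= 0 or self.thickness_um <= 0:
            raise ValueError("pixel_size_um and thickness_um must be positive")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class StainModel:
    """Stain colors and cleanup parameters for compartment segmentation.

    Parameters
    ----------
    stain_vectors : tuple of RGB unit vectors in OD space
        First vector is the PAS-positive stain, second the counterstain; an
        optional third is the residual.  A residual completing the basis is
        added internally when only two are given.
    od_threshold : float or None
        PAS-channel OD above which a pixel is mesangial; ``None`` selects the
        threshold automatically (Otsu on tissue pixels).
    tissue_od_threshold : float
        Total-OD magnitude above which a pixel counts as tissue (vs. blank
        background); well below any stained tissue, well above sensor noise.
    """

    stain_vectors: tuple = (PAS_VECTOR, HEMATOXYLIN_VECTOR)
    od_threshold: float | None = None
    min_region_area_um2: float = 5.0
    morphology_radius_um: float = 0.5
    tuft_closing_radius_um: float = 2.0
    tissue_od_threshold: float = 0.10

    def stain_matrix(self) -> np.ndarray:
        """Rows = unit stain vectors; a residual row is appended if needed."""
        vecs = [_unit(v) for v in self.stain_vectors]
        if len(vecs) == 2:
            residual = np.cross(vecs[0], vecs[1])
            if np.linalg.norm(residual) < 1e-8:
                raise CollinearStainsError("stain vectors are collinear")
            vecs.append(_unit(residual))
        m = np.vstack(vecs)
        if np.linalg.matrix_rank(m, tol=1e-6) < m.shape[0]:
            raise CollinearStainsError("stain vectors are collinear")
        return m


def rgb_to_od(pixels: np.ndarray) -> np.ndarray:
    """Per-channel optical density: ``-log10((I + 1) / 256)``."""
    return -np.log10((pixels.astype(float) + 1.0) / 256.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse Beer–Lambert render used by the phantom: ``I = 256*10^-OD - 1``."""
    return np.clip(np.round(256.0 * np.power(10.0, -od) - 1.0), 0, 255).astype(np.uint8)


def separate_stains(img: SectionImage, model: StainModel | None = None) -> np.ndarray:
    """Unmix an RGB section into per-stain OD concentration maps.

    Returns an ``(H, W, n_stains)`` array: least-squares projection of each
    pixel's OD vector onto the stain basis, clipped at zero.  Channel order
    follows ``model.stain_vectors`` (PAS first).
    """
    model = model or StainModel()
    m = model.stain_matrix()
    od = rgb_to_od(img.pixels)
    # concentrations c solve c @ M = OD in the least-squares sense
    conc = od.reshape(-1, 3) @ np.linalg.pinv(m)
    n_given = len(model.stain_vectors)
    return np.clip(conc.reshape(od.shape[0], od.shape[1], -1), 0.0, None)[..., :n_given]


def auto_threshold(od_channel: np.ndarray) -> float:
    """Otsu threshold on an OD channel (256 bins over the observed range).

    Maximizes between-class variance over the 255 interior bin edges and
    returns the selected edge; deterministic for fixed input.
    """
    vals = np.asarray(od_channel, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0 or vals.min() == vals.max():
        raise NoContrastError("channel is constant; cannot threshold")
    counts, edges = np.histogram(vals, bins=256, range=(vals.min(), vals.max()))
    p = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(p)[:-1]
    w1 = 1.0 - w0
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mu_t * w0 - mu[:-1]) ** 2 / (w0 * w1)
    between[~np.isfinite(between)] = -np.inf
    return float(edges[1:-1][int(np.argmax(between))])


def _disk(radius_px: int) -> np.ndarray:
    return morphology.disk(max(1, radius_px))


def _drop_small_regions(mask: np.ndarray, min_px: int) -> np.ndarray:
    """Remove connected regions with fewer than ``min_px`` pixels."""
    labeled, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(labeled.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[labeled]


def segment_masks(img: SectionImage, model: StainModel | None = None) -> dict:
    """Cleaned binary masks for both compartments (pixel space).

    Returns ``{"mesangium": mask, "tuft": mask, "od_threshold": float}``.
    The mesangial mask is PAS-OD >= threshold within tissue, opened+closed at
    ``morphology_radius_um`` and hole-filled; the tuft mask is the hole-filled
    morphological closing (radius ``tuft_closing_radius_um``) of all
    tissue-positive pixels.  Regions smaller than ``min_region_area_um2`` are
    dropped from both.
    """
    model = model or StainModel()
    p = img.pixel_size_um
    conc = separate_stains(img, model)
    od = rgb_to_od(img.pixels)
    tissue = np.linalg.norm(od, axis=2) >= model.tissue_od_threshold

    if not tissue.any():
        empty = np.zeros(tissue.shape, dtype=bool)
        return {"mesangium": empty, "tuft": empty.copy(), "od_threshold": float("nan")}

    pas = conc[..., 0]
    if model.od_threshold is not None:
        thr = float(model.od_threshold)
    else:
        thr = auto_threshold(pas[tissue])

    min_px = max(1, int(round(model.min_region_area_um2 / p**2)))

    mes = (pas >= thr) & tissue
    r = int(round(model.morphology_radius_um / p))
    if r >= 1:
        selem = _disk(r)
        mes = morphology.opening(mes, selem)
        mes = morphology.closing(mes, selem)
    mes = ndimage.binary_fill_holes(mes)
    mes = _drop_small_regions(mes, min_px)

    rt = int(round(model.tuft_closing_radius_um / p))
    tuft = morphology.closing(tissue, _disk(rt)) if rt >= 1 else tissue
    tuft = ndimage.binary_fill_holes(tuft)
    tuft = _drop_small_regions(tuft, min_px)
    mes = mes & tuft

    if mes.sum() > 0.5 * mes.size:
        logger.warning(
            "section %d: mesangial-positive area exceeds 50%% of the image; "
            "stain threshold %.3f may be miscalibrated",
            img.section_index,
            thr,
        )
    return {"mesangium": mes, "tuft": tuft, "od_threshold": thr}


def mask_to_contours(
    mask: np.ndarray,
    pixel_size_um: float,
    compartment: Compartment,
    section_index: int = 0,
    min_area_um2: float = 0.0,
    simplify_tol_um: float | None = None,
) -> list[Contour]:
    """Trace a binary mask into µm-space contours at the 0.5 iso-level.

    Sub-pixel boundaries from marching squares; rings are simplified with a
    topology-preserving tolerance (default ``0.25 * pixel_size_um``) and rings
    below ``min_area_um2`` are dropped.
    """
    if simplify_tol_um is None:
        simplify_tol_um = 0.25 * pixel_size_um
    padded = np.pad(mask.astype(float), 1)
    out: list[Contour] = []
    for ring in measure.find_contours(padded, 0.5):
        # (row, col) -> (x, y): undo padding, pixel centers at integer coords
        xy = np.column_stack([(ring[:, 1] - 1.0), (ring[:, 0] - 1.0)]) * pixel_size_um
        poly = Polygon(xy)
        if not poly.is_valid:
            poly = poly.buffer(0)
            if poly.is_empty or poly.geom_type != "Polygon":
                continue
        if simplify_tol_um > 0:
            poly = poly.simplify(simplify_tol_um, preserve_topology=True)
        coords = np.asarray(poly.exterior.coords)[:-1]
        if coords.shape[0] < 3:
            continue
        try:
            c = Contour(coords, compartment, section_index)
        except DegenerateGeometryError:
            continue
        if c.area() >= min_area_um2:
            out.append(c)
    return out


def segment_compartments(img: SectionImage, model: StainModel | None = None) -> list[Contour]:
    """Segment a section into mesangial and tuft contours (µm coordinates).

    Returns MESANGIUM contours (one per connected PAS-positive region) and
    TUFT contours (outer boundary of the closed tissue union).  A blank image
    yields an empty list.
    """
    model = model or StainModel()
    masks = segment_masks(img, model)
    tol = 0.25 * img.pixel_size_um
    contours = mask_to_contours(
        masks["tuft"], img.pixel_size_um, Compartment.TUFT, img.section_index,
        min_area_um2=model.min_region_area_um2, simplify_tol_um=tol,
    )
    contours += mask_to_contours(
        masks["mesangium"], img.pixel_size_um, Compartment.MESANGIUM, img.section_index,
        min_area_um2=model.min_region_area_um2, simplify_tol_um=tol,
    )
    return contours
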