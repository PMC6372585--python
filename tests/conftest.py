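import numpy as np
import pytest

from glomorph import Compartment, Contour, PhantomSpec, generate_phantom


def star_polygon(rng, n_vertices=20, r_lo=0.5, r_hi=1.0, scale=10.0):
    """Random star-shaped (hence simple) polygon around the origin."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    # enforce distinct angles so edges are non-degenerate
    while np.any(np.diff(angles) < 1e-4):
        angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = rng.uniform(r_lo, r_hi, n_vertices) * scale
    return np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_square():
    return Contour(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))


@pytest.fixture(scope="session")
def small_phantom():
    """Small full-depth phantom shared by registration/segmentation tests."""
    spec = PhantomSpec(
        tuft_radii_um=(20.0, 18.0, 16.0),
        n_mesangial_blobs=12,
        target_vv=0.5,
        voxel_size_um=0.5,
        section_thickness_um=2.0,
        n_sections=8,
        pixel_size_um=0.5,
        misalignment_sigma=(1.0, 0.02),
        noise_sigma=5.0,
        seed=42,
    )
    return spec, generate_phantom(spec)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    denom = a.sum() + b.sum()
    return 2.0 * inter / denom if denom else 1.0
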