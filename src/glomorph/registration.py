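"""Landmark-based rigid alignment of serial sections.

Serial histology sections are cut from one block at one magnification, so
successive sections differ only by an in-plane rotation and translation.
Alignment is estimated from matched fiducial points (recognizable fixed
structures marked on both sections of an adjacent pair) by least-squares
orthogonal Procrustes without scaling and with reflection excluded, and the
pairwise fits are composed into a chain mapping every section into a common
reference frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from glomorph.geometry import RigidTransform2D


class InsufficientFiducialsError(ValueError):
    """Fewer than two distinct matched fiducial pairs were supplied."""


class GapInChainError(ValueError):
    """An adjacent section pair has no fiducial set, so the chain cannot be built."""


@dataclass(frozen=True)
class FiducialPairSet:
    """Matched fiducial points on an adjacent section pair.

    ``points_a[i]`` and ``points_b[i]`` mark the same physical structure on
    sections ``section_a`` and ``section_b = section_a + 1``; correspondence
    is by list position.
    """

    section_a: int
    section_b: int
    points_a: np.ndarray
    points_b: np.ndarray

    def __post_init__(self) -> None:
        if self.section_b != self.section_a + 1:
            raise ValueError("fiducial sets must link adjacent sections (b = a + 1)")
        a = np.asarray(self.points_a, dtype=float)
        b = np.asarray(self.points_b, dtype=float)
        if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 2:
            raise ValueError("points_a and points_b must be matching (N, 2) arrays")
        if a.shape[0] < 2:
            raise InsufficientFiducialsError("need at least 2 matched fiducial pairs")
        d = a[:, None, :] - a[None, :, :]
        dist = np.hypot(d[..., 0], d[..., 1])
        if np.any(dist[np.triu_indices(a.shape[0], k=1)] < 1e-12):
            raise InsufficientFiducialsError("fiducial points on section_a coincide")
        object.__setattr__(self, "points_a", a)
        object.__setattr__(self, "points_b", b)


@dataclass(frozen=True)
class AlignmentChain:
    """Per-section rigid transforms into a common reference frame.

    ``transforms[i]`` maps coordinates of section ``i`` into the frame of
    ``reference_index`` (identity there); ``rms_residuals[i]`` is the fit
    residual of the adjacent pair used on the path toward the reference
    (0 at the reference).
    """

    reference_index: int
    transforms: dict[int, RigidTransform2D]
    rms_residuals: dict[int, float] = field(default_factory=dict)

    def apply_to_section(self, section_index: int, pts: np.ndarray) -> np.ndarray:
        return self.transforms[section_index].apply(pts)


def fit_rigid_transform(pairs: FiducialPairSet) -> tuple[RigidTransform2D, float]:
    """Least-squares rigid transform mapping ``points_b`` onto ``points_a``.

    Solves the 2D orthogonal Procrustes problem without scaling, with the SVD
    sign-corrected so the rotation never reflects (determinant +1), and
    returns ``(transform, rms_residual)``.

    The residual is the per-coordinate RMS ``sqrt(SS / (2N))`` where ``SS`` is
    the sum of squared distances from the transformed ``points_b`` to
    ``points_a``.  With isotropic Gaussian noise of standard deviation sigma
    on one point set, its expectation is ``sigma * sqrt(1 - 3/(2N))`` — the
    2N coordinate degrees of freedom less the 3 fitted rigid parameters.
    """
    a = pairs.points_a
    b = pairs.points_b
    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    h = (b - cb).T @ (a - ca)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, d]) @ u.T
    angle = float(np.arctan2(r[1, 0], r[0, 0]))
    t = ca - r @ cb
    transform = RigidTransform2D(angle, (float(t[0]), float(t[1])))
    resid = transform.apply(b) - a
    rms = float(np.sqrt(np.sum(resid**2) / (2 * a.shape[0])))
    return transform, rms


def build_alignment_chain(
    pair_sets: list[FiducialPairSet], reference_index: int | None = None, n_sections: int | None = None
) -> AlignmentChain:
    """Compose adjacent-pair fits into a stack-wide alignment chain.

    Parameters
    ----------
    pair_sets : list of FiducialPairSet
        One set per adjacent pair; together they must cover every adjacent
        pair of the stack exactly once.
    reference_index : int, optional
        Section whose frame all others are mapped into.  Defaults to the
        middle of the stack, which minimizes the longest composition path.
    n_sections : int, optional
        Stack length; inferred from the pair sets when omitted (a
        single-section stack must pass ``n_sections=1`` since it has no pairs).
    """
    if n_sections is None:
        if not pair_sets:
            raise GapInChainError("no fiducial pair sets and no explicit stack length")
        n_sections = max(ps.section_b for ps in pair_sets) + 1
    if n_sections < 1:
        raise ValueError("stack must contain at least one section")
    if reference_index is None:
        reference_index = n_sections // 2
    if not 0 <= reference_index < n_sections:
        raise ValueError("reference_index outside the stack")

    by_pair: dict[int, FiducialPairSet] = {}
    for ps in pair_sets:
        if ps.section_a in by_pair:
            raise ValueError(f"duplicate fiducial set for pair ({ps.section_a}, {ps.section_b})")
        by_pair[ps.section_a] = ps
    for a in range(n_sections - 1):
        if a not in by_pair:
            raise GapInChainError(f"no fiducial set for adjacent pair ({a}, {a + 1})")

    # M[a] maps section a+1 coordinates into section a's frame
    fits = {a: fit_rigid_transform(ps) for a, ps in by_pair.items()}

    transforms: dict[int, RigidTransform2D] = {reference_index: RigidTransform2D.identity()}
    residuals: dict[int, float] = {reference_index: 0.0}
    # sections above the reference: map i -> i-1 -> ... -> reference
    for i in range(reference_index + 1, n_sections):
        m, rms = fits[i - 1]
        transforms[i] = transforms[i - 1].compose(m)
        residuals[i] = rms
    # sections below: map i -> i+1 -> ... -> reference via inverses
    for i in range(reference_index - 1, -1, -1):
        m, rms = fits[i]
        transforms[i] = transforms[i + 1].compose(m.inverse())
        residuals[i] = rms
    return AlignmentChain(reference_index, transforms, residuals)
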