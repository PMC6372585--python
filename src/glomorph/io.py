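"""File formats: contour JSON exchange documents, alignment chains, run
configuration, and result tables.

The contour document is the interchange currency between segmentation,
registration, reconstruction and stereology: one JSON file per specimen
holding per-section contour lists in µm, optional matched fiducial points
for adjacent section pairs, and the physical metadata (pixel size, section
thickness) needed to interpret them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from glomorph.geometry import Compartment, Contour, RigidTransform2D
from glomorph.reconstruction import ContourStack, MorphometricsRecord
from glomorph.registration import AlignmentChain, FiducialPairSet

FORMAT_VERSION = "1.0"


def write_contour_document(
    path,
    stack: ContourStack,
    pixel_size_um: float,
    fiducials: list[FiducialPairSet] | None = None,
    metadata: dict | None = None,
) -> None:
    """Write a contour stack (and optional fiducials) as a contour JSON document."""
    doc = {
        "format_version": FORMAT_VERSION,
        "pixel_size_um": pixel_size_um,
        "section_thickness_um": stack.thickness_um,
        "sections": [
            {
                "section_index": i,
                "contours": [
                    {"compartment": c.compartment.value, "vertices_um": c.vertices.tolist()}
                    for c in cs
                ],
            }
            for i, cs in stack.sections
        ],
    }
    if fiducials:
        doc["fiducials"] = [
            {
                "section_pair": [ps.section_a, ps.section_b],
                "points_a_um": ps.points_a.tolist(),
                "points_b_um": ps.points_b.tolist(),
            }
            for ps in fiducials
        ]
    if metadata:
        doc["metadata"] = metadata
    Path(path).write_text(json.dumps(doc, indent=1))


def read_contour_document(path):
    """Read a contour JSON document.

    Returns ``(stack, pixel_size_um, fiducial_pair_sets)``.
    """
    doc = json.loads(Path(path).read_text())
    version = doc.get("format_version")
    if version is None:
        raise ValueError("not a contour document: missing format_version")
    sections = []
    for sec in doc["sections"]:
        contours = [
            Contour(
                np.asarray(c["vertices_um"], dtype=float),
                Compartment(c["compartment"]),
                sec["section_index"],
            )
            for c in sec["contours"]
        ]
        sections.append((int(sec["section_index"]), contours))
    sections.sort(key=lambda s: s[0])
    stack = ContourStack(sections, float(doc["section_thickness_um"]))
    fiducials = [
        FiducialPairSet(
            int(f["section_pair"][0]),
            int(f["section_pair"][1]),
            np.asarray(f["points_a_um"], dtype=float),
            np.asarray(f["points_b_um"], dtype=float),
        )
        for f in doc.get("fiducials", [])
    ]
    return stack, float(doc["pixel_size_um"]), fiducials


def write_alignment_chain(path, chain: AlignmentChain) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "reference_index": chain.reference_index,
        "reference_rule": "middle of stack (floor(n/2)) unless overridden",
        "transforms": {
            str(i): {
                "rotation_rad": t.angle,
                "translation_um": list(t.translation),
                "rms_residual_um": chain.rms_residuals.get(i),
            }
            for i, t in chain.transforms.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_alignment_chain(path) -> AlignmentChain:
    doc = json.loads(Path(path).read_text())
    transforms = {}
    residuals = {}
    for key, t in doc["transforms"].items():
        i = int(key)
        transforms[i] = RigidTransform2D(float(t["rotation_rad"]), tuple(t["translation_um"]))
        if t.get("rms_residual_um") is not None:
            residuals[i] = float(t["rms_residual_um"])
    return AlignmentChain(int(doc["reference_index"]), transforms, residuals)


def apply_alignment(stack: ContourStack, chain: AlignmentChain) -> ContourStack:
    """Map every contour into the chain's reference frame."""
    sections = [
        (i, [c.transformed(chain.transforms[i]) for c in cs]) for i, cs in stack.sections
    ]
    return ContourStack(sections, stack.thickness_um, aligned=True)


def morphometrics_to_frame(records: list[MorphometricsRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run.

    Serialized (flat TOML) next to every output so a run is reproducible
    from its artifacts alone; CLI flags override file values.
    """

    pixel_size_um: float = 0.25
    section_thickness_um: float = 1.0
    od_threshold: float | None = None
    min_region_area_um2: float = 5.0
    morphology_radius_um: float = 0.5
    grid_spacing_um: float = 2.0
    seed: int = 0
    counting_rule: str = "half"
    planimetry_volume_model: str = "extrusion"
    output_dir: str = "."
    log_level: str = "INFO"

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_toml(self, path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            if isinstance(v, str):
                lines.append(f'{f.name} = "{v}"')
            elif isinstance(v, bool):
                lines.append(f"{f.name} = {str(v).lower()}")
            else:
                lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
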