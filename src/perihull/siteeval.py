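"""Binding-site evaluation: center-to-site vectors and their angle.

A site vector points from the protein center (the plain mean of all
C-alpha coordinates) to the mean C-alpha position of a residue set. The
angle between the vector for experimentally identified binding residues and
the vector for the predicted Likely Inserted Hydrophobe separates
predictions on the same side of the protein (< 90 degrees) from the rest.
A protein without any protruding hydrophobe has no prediction and is
reported with the sentinel angle 180 degrees and an explicit flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .config import Config, DEFAULT_CONFIG
from .errors import UndefinedAngleError
from .structure import CoarseResidue, ProteinModel, ResidueId, resolve_residue_ids

NO_LIH_SENTINEL_DEGREES = 180.0


@dataclass
class SiteVector:
    """Mean C-alpha of a residue set relative to the protein center."""

    vector: np.ndarray
    source: str  # experimental | predicted | protrusion-control
    residue_ids: tuple[ResidueId, ...]


def site_vector(
    model: ProteinModel, residues: Iterable, source: str = "experimental"
) -> SiteVector:
    """Mean C-alpha of ``residues`` minus mean C-alpha of all residues."""
    idx = _residue_indices(model, residues)
    if not idx:
        raise ValueError("site vector requires a non-empty residue set")
    ca = np.array([res.ca_coord for res in model.residues])
    center = ca.mean(axis=0)
    site = ca[idx].mean(axis=0)
    ids = tuple(model.residues[i].residue_id for i in idx)
    return SiteVector(site - center, source, ids)


def _residue_indices(model: ProteinModel, residues: Iterable) -> list[int]:
    out = []
    raw_ids = []
    for item in residues:
        if isinstance(item, CoarseResidue):
            out.append(model.residues.index(item))
        else:
            raw_ids.append(item)
    if raw_ids:
        out.extend(resolve_residue_ids(model, raw_ids))
    return out


def site_angle(v1, v2) -> float:
    """Angle in degrees, [0, 180], between two site vectors."""
    a = v1.vector if isinstance(v1, SiteVector) else np.asarray(v1, dtype=float)
    b = v2.vector if isinstance(v2, SiteVector) else np.asarray(v2, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise UndefinedAngleError("angle undefined for a zero-length site vector")
    cosang = float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


@dataclass
class PredictionEvaluation:
    """Angle comparison of the predicted LIH against an experimental site."""

    model_id: str
    lih_angle: float
    no_lih: bool
    lih_id: Optional[ResidueId]
    experimental_ids: tuple[ResidueId, ...]
    control_angles: dict = field(default_factory=dict)  # ResidueId -> degrees


def evaluate_predictions(
    model: ProteinModel,
    experimental_set: Iterable,
    config: Config = DEFAULT_CONFIG,
) -> PredictionEvaluation:
    """Compare the LIH with an experimentally identified binding site.

    ``lih_angle`` is the angle between the experimental site vector and the
    LIH site vector; per-protrusion control angles are computed for every
    protruding residue taken singly (protrusions coinciding exactly with the
    protein center are skipped). Requires geometry annotations; computes
    them on demand. Unresolvable experimental residue identifiers raise
    :class:`UnmatchedResiduesError` listing the offenders.
    """
    from .hull import annotate_geometry, likely_inserted_hydrophobe

    if model.hull is None or model.pairs is None:
        annotate_geometry(model, config)
    t_exp = site_vector(model, experimental_set, source="experimental")

    lih = next((r for r in model.residues if r.is_lih), None)
    if lih is None:
        lih = likely_inserted_hydrophobe(model, config)

    controls = {}
    for res in model.residues:
        if not res.is_protrusion:
            continue
        t_ctrl = site_vector(model, [res], source="protrusion-control")
        if np.linalg.norm(t_ctrl.vector) == 0:
            continue
        controls[res.residue_id] = site_angle(t_exp, t_ctrl)

    if lih is None:
        return PredictionEvaluation(
            model_id=model.model_id,
            lih_angle=NO_LIH_SENTINEL_DEGREES,
            no_lih=True,
            lih_id=None,
            experimental_ids=t_exp.residue_ids,
            control_angles=controls,
        )
    t_lih = site_vector(model, [lih], source="predicted")
    return PredictionEvaluation(
        model_id=model.model_id,
        lih_angle=site_angle(t_exp, t_lih),
        no_lih=False,
        lih_id=lih.residue_id,
        experimental_ids=t_exp.residue_ids,
        control_angles=controls,
    )
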