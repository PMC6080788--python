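"""Planar membrane frames and the insertion coordinate.

A membrane frame is the hydrocarbon slab of an OPM-style model: a center
point, a unit normal and the hydrocarbon half-thickness ``h`` (the boundary
planes sit at signed distance +/- h from the center along the normal). The
*insertion coordinate* of an atom is ``h - |z|`` where ``z`` is its signed
distance from the slab center along the normal: positive inside the
hydrocarbon core, zero on either boundary plane, negative on the solvated
side of the membrane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .config import Config, DEFAULT_CONFIG
from .errors import ParseError
from .structure import CoarseResidue, ProteinModel

logger = logging.getLogger(__name__)

ANGSTROM_TO_NM = 0.1


@dataclass
class MembraneFrame:
    """Hydrocarbon slab: center, unit normal, half-thickness h (nm)."""

    center: np.ndarray
    normal: np.ndarray
    half_thickness: float
    side: int = -1  # which half-space the peripheral protein occupies

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        normal = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(normal)
        if norm == 0:
            raise ValueError("membrane normal must be non-zero")
        self.normal = normal / norm
        if self.half_thickness <= 0:
            raise ValueError("hydrocarbon half-thickness must be positive")
        if self.side not in (-1, 1):
            raise ValueError("side must be +1 or -1")


def insertion_coordinate(atom_coord, frame: MembraneFrame) -> float:
    """Signed insertion depth ``h - |z|`` of a coordinate (nm).

    Positive inside the hydrocarbon slab, zero on either boundary plane,
    negative outside; both leaflet boundaries map to zero.
    """
    z = float(np.dot(np.asarray(atom_coord, dtype=float) - frame.center, frame.normal))
    return frame.half_thickness - abs(z)


def insertion_coordinates(coords: np.ndarray, frame: MembraneFrame) -> np.ndarray:
    """Vectorised :func:`insertion_coordinate` over an (N, 3) array."""
    z = (np.asarray(coords, dtype=float) - frame.center) @ frame.normal
    return frame.half_thickness - np.abs(z)


def attach_insertion_coordinates(
    model: ProteinModel, frame: MembraneFrame
) -> ProteinModel:
    """Store the C-alpha insertion coordinate on every residue."""
    ca = np.array([res.ca_coord for res in model.residues])
    ics = insertion_coordinates(ca, frame)
    for res, ic in zip(model.residues, ics):
        res.insertion_coordinate = float(ic)
    return model


def extract_nonbinding_fragment(
    model: ProteinModel,
    frame: MembraneFrame,
    config: Config = DEFAULT_CONFIG,
) -> list[CoarseResidue]:
    """Residues at least ``fragment_min_distance`` outside the hydrocarbon slab.

    Selects residues whose C-alpha insertion coordinate is <= -1.5 nm
    (inclusive boundary), i.e. the solvent-exposed caps of a transmembrane
    complex. Annotations are expected to have been computed on the entire
    complex beforehand: only the statistical selection is restricted here.
    """
    ca = np.array([res.ca_coord for res in model.residues])
    ics = insertion_coordinates(ca, frame)
    fragment = [
        res
        for res, ic in zip(model.residues, ics)
        if ic <= -config.fragment_min_distance
    ]
    if not fragment:
        logger.warning(
            "%s: non-binding surface fragment is empty", model.model_id
        )
    return fragment


def median_family_insertion(
    cohort,
    frames: Mapping[str, MembraneFrame],
    config: Config = DEFAULT_CONFIG,
    margin: Optional[float] = None,
):
    """Per-family median insertion coordinate of the LIH C-alpha.

    For each family, takes the median over member proteins of the insertion
    coordinate of the Likely Inserted Hydrophobe's C-alpha. Proteins without
    an LIH are skipped and counted; families with no LIH-bearing member are
    excluded and logged.

    Returns ``(medians, fraction_within_margin, n_skipped_proteins)`` where
    ``medians`` maps family name -> median coordinate and the fraction is
    the share of retained families whose median is >= -margin (default
    margin 0.5 nm).
    """
    from .hull import likely_inserted_hydrophobe

    margin = config.insertion_margin if margin is None else margin
    medians: dict[str, float] = {}
    skipped = 0
    for family in cohort.families:
        values = []
        for model in family.proteins:
            lih = next((r for r in model.residues if r.is_lih), None)
            if lih is None and model.pairs is None:
                lih = likely_inserted_hydrophobe(model, config)
            if lih is None:
                skipped += 1
                continue
            frame = frames[model.model_id]
            values.append(insertion_coordinate(lih.ca_coord, frame))
        if values:
            medians[family.name] = float(np.median(values))
        else:
            logger.warning(
                "family %s has no LIH-bearing members; excluded", family.name
            )
    if medians:
        fraction = float(
            np.mean([m >= -margin for m in medians.values()])
        )
    else:
        fraction = float("nan")
    return medians, fraction, skipped


def frame_from_dum_pdb(path) -> MembraneFrame:
    """Parse an OPM-flavoured PDB file with DUM pseudo-atoms into a frame.

    OPM marks the two hydrocarbon boundary planes with layers of DUM atoms.
    The frame normal is taken as the principal direction separating the two
    layers (OPM uses the z axis); the center is the midpoint between the
    layers and ``h`` half their separation.
    """
    coords = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("ATOM", "HETATM")) and line[17:20].strip() == "DUM":
                x = float(line[30:38]) * ANGSTROM_TO_NM
                y = float(line[38:46]) * ANGSTROM_TO_NM
                z = float(line[46:54]) * ANGSTROM_TO_NM
                coords.append((x, y, z))
    if len(coords) < 2:
        raise ParseError(f"{path}: fewer than two DUM atoms; no membrane planes")
    coords = np.array(coords)
    # the two layers are maximally separated along the normal; for OPM this
    # is the z axis, recovered here as the largest-variance direction of the
    # layer-mean split
    z = coords[:, 2]
    order = np.sort(z)
    gaps = np.diff(order)
    split = float(order[np.argmax(gaps)] + order[np.argmax(gaps) + 1]) / 2.0
    lower, upper = z[z <= split], z[z > split]
    if len(lower) == 0 or len(upper) == 0:
        raise ParseError(f"{path}: DUM atoms do not form two layers")
    z_lo, z_hi = float(lower.mean()), float(upper.mean())
    center = np.array([0.0, 0.0, (z_lo + z_hi) / 2.0])
    h = (z_hi - z_lo) / 2.0
    return MembraneFrame(center=center, normal=np.array([0.0, 0.0, 1.0]), half_thickness=h)
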