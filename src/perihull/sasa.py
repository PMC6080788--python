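"""Side-chain solvent-accessible surface area and the exposure flag.

Numerical SASA by quasi-uniform sphere sampling (golden-section spiral,
960 points per atom by default) over all heavy atoms, with Bondi van der
Waals radii and a 0.14 nm probe. A residue is *exposed* when the summed
accessible area of its side-chain heavy atoms (everything except backbone
N, CA, C, O, OXT; C-beta counts as side chain) is strictly greater than
0.2 nm^2. Glycine has no side-chain heavy atoms, hence area 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .config import Config, DEFAULT_CONFIG, DEFAULT_VDW_RADIUS_NM
from .structure import ProteinModel, ResidueId

logger = logging.getLogger(__name__)


@dataclass
class AtomSphere:
    """A heavy atom as a van der Waals sphere for surface integration."""

    name: str
    element: str
    center: np.ndarray  # nm
    vdw_radius: float  # nm
    owner: ResidueId
    is_sidechain: bool


def sphere_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit-sphere points (golden-section spiral)."""
    i = np.arange(n)
    golden = (1 + 5**0.5) / 2
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / golden
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack((r * np.cos(theta), r * np.sin(theta), z))


def _vdw_radius(element: str, config: Config) -> float:
    radius = config.vdw_radius_set.get(element.upper())
    if radius is None:
        logger.warning(
            "unknown element %r: using default van der Waals radius %.3f nm",
            element,
            DEFAULT_VDW_RADIUS_NM,
        )
        radius = DEFAULT_VDW_RADIUS_NM
    return radius


def atom_spheres(model: ProteinModel, config: Config = DEFAULT_CONFIG):
    """All heavy atoms of the model as :class:`AtomSphere` records."""
    spheres = []
    for res in model.residues:
        if not res.atoms:
            logger.warning(
                "%s: residue %s has no heavy atoms; excluded from SASA",
                model.model_id,
                res.residue_id,
            )
            continue
        for atom in res.atoms:
            spheres.append(
                AtomSphere(
                    atom.name,
                    atom.element,
                    np.asarray(atom.coord, dtype=float),
                    _vdw_radius(atom.element, config),
                    res.residue_id,
                    atom.is_sidechain,
                )
            )
    return spheres


def sidechain_sasa(
    model: ProteinModel,
    config: Config = DEFAULT_CONFIG,
    n_points: int | None = None,
) -> dict[ResidueId, float]:
    """Per-residue side-chain solvent-accessible area (nm^2).

    Occlusion is computed against *all* heavy atoms of the model; only
    side-chain atoms contribute area. Residues without side-chain heavy
    atoms (glycine) get area 0.0; residues with no heavy atoms at all are
    excluded with a warning.
    """
    n_points = n_points or config.sasa_points_per_atom
    probe = config.sasa_probe_radius
    spheres = atom_spheres(model, config)
    areas: dict[ResidueId, float] = {
        res.residue_id: 0.0 for res in model.residues if res.atoms
    }
    if not spheres:
        return areas

    centers = np.array([s.center for s in spheres])
    radii = np.array([s.vdw_radius for s in spheres]) + probe
    unit = sphere_points(n_points)
    tree = cKDTree(centers)
    max_reach = 2.0 * radii.max()

    for i, sphere in enumerate(spheres):
        if not sphere.is_sidechain:
            continue
        r = radii[i]
        pts = centers[i] + r * unit
        neighbor_idx = [
            j for j in tree.query_ball_point(centers[i], r + max_reach) if j != i
        ]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbor_idx:
            d2 = np.sum((pts - centers[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
            if not accessible.any():
                break
        frac = accessible.mean()
        areas[sphere.owner] += frac * 4.0 * np.pi * r * r
    return areas


def flag_exposed(
    sasa_map: dict[ResidueId, float], config: Config = DEFAULT_CONFIG
) -> dict[ResidueId, bool]:
    """Exposure flags: area strictly greater than the 0.2 nm^2 threshold."""
    return {
        rid: area > config.sasa_exposure_threshold
        for rid, area in sasa_map.items()
    }


def attach_sasa(
    model: ProteinModel,
    config: Config = DEFAULT_CONFIG,
    n_points: int | None = None,
) -> ProteinModel:
    """Compute side-chain SASA and exposure and store them on the residues."""
    areas = sidechain_sasa(model, config, n_points)
    exposed = flag_exposed(areas, config)
    for res in model.residues:
        if res.residue_id in areas:
            res.sidechain_sasa = areas[res.residue_id]
            res.is_exposed = exposed[res.residue_id]
        else:
            res.sidechain_sasa = None
            res.is_exposed = None
    return model
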