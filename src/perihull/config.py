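"""Model parameters and shared constant tables.

All lengths are in nanometres; PDB coordinates (Angstrom) are divided by 10
on input. The defaults are the protrusion model's standard values:
a residue is a *protrusion* when its C-beta is a convex-hull vertex and its
local protein density ``d`` (number of C-alpha/C-beta atoms within
``density_radius``) is below ``density_threshold``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

#: The seven interfacial hydrophobes of the Wimley-White scale (residues with
#: favourable water-to-interface transfer free energy).
HYDROPHOBES = frozenset({"LEU", "ILE", "PHE", "TYR", "TRP", "CYS", "MET"})

STANDARD_AMINO_ACIDS = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
)

#: Bondi van der Waals radii (nm) for heavy elements seen in protein files.
BONDI_RADII_NM: Mapping[str, float] = {
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
    "P": 0.180,
    "H": 0.120,
    "F": 0.147,
    "CL": 0.175,
    "BR": 0.185,
    "I": 0.198,
    "SE": 0.190,
}

#: Fallback van der Waals radius (nm) for unknown elements (carbon-like).
DEFAULT_VDW_RADIUS_NM = 0.170

#: Common non-standard residues remapped to their parent amino acid. Entries
#: not listed here are excluded from the coarse model with a warning.
NONSTANDARD_RESIDUE_MAP: Mapping[str, str] = {
    "MSE": "MET",  # selenomethionine
    "SEC": "CYS",  # selenocysteine
    "SEP": "SER",  # phosphoserine
    "TPO": "THR",  # phosphothreonine
    "PTR": "TYR",  # phosphotyrosine
    "CSO": "CYS",  # S-hydroxycysteine
    "HYP": "PRO",  # hydroxyproline
    "MLY": "LYS",  # N-dimethyl-lysine
    "M3L": "LYS",
    "KCX": "LYS",
    "PCA": "GLU",  # pyroglutamate
}

#: DSSP summary-code mapping. Note that T is reported as 'bend' and S as
#: 'turn', by the model's own definition (this swaps the
#: conventional DSSP names for those two codes; the table is configurable).
DSSP_CLASS_MAP: Mapping[str, str] = {
    "H": "helix",
    "G": "helix",
    "I": "helix",
    "B": "beta",
    "E": "beta",
    "T": "bend",
    "S": "turn",
}

SS_CLASSES = ("helix", "beta", "bend", "turn", "loop")


@dataclass(frozen=True)
class Config:
    """Tunable parameters of the protrusion model.

    Parameters
    ----------
    density_radius:
        Cutoff radius ``c`` (nm) for the local protein density count.
    density_threshold:
        Density cutoff ``n``; a vertex residue with ``d < n`` is a protrusion.
    sasa_probe_radius:
        Solvent probe radius (nm) for side-chain accessible-area integration.
    sasa_exposure_threshold:
        A residue is 'exposed' when its side-chain SASA is strictly greater
        than this area (nm^2).
    sasa_points_per_atom:
        Number of quasi-uniform sphere points per atom in the SASA
        integration (golden-section spiral).
    vdw_radius_set:
        Element -> van der Waals radius (nm); defaults to the Bondi table.
    hydrophobe_set:
        Three-letter codes treated as interfacial hydrophobes.
    fragment_min_distance:
        Minimum distance (nm) outside the hydrocarbon slab for a residue to
        enter a non-binding surface fragment.
    insertion_margin:
        Margin (nm) used when summarising family median insertion
        coordinates against the membrane boundary.
    facet_merge_tolerance:
        Angular tolerance (radians) below which adjacent hull facets are
        considered coplanar and merged before edge extraction.
    random_seed:
        Seed for tie-breaking and null-model sampling.
    """

    density_radius: float = 1.0
    density_threshold: int = 22
    sasa_probe_radius: float = 0.14
    sasa_exposure_threshold: float = 0.2
    sasa_points_per_atom: int = 960
    vdw_radius_set: Mapping[str, float] = field(
        default_factory=lambda: dict(BONDI_RADII_NM)
    )
    hydrophobe_set: frozenset = HYDROPHOBES
    fragment_min_distance: float = 1.5
    insertion_margin: float = 0.5
    facet_merge_tolerance: float = 1e-6
    random_seed: int = 0

    def __post_init__(self):
        for name in (
            "density_radius",
            "sasa_probe_radius",
            "sasa_exposure_threshold",
            "fragment_min_distance",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.density_threshold < 1:
            raise ValueError("density_threshold must be >= 1")
        if self.sasa_points_per_atom < 16:
            raise ValueError("sasa_points_per_atom too small for integration")


DEFAULT_CONFIG = Config()
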