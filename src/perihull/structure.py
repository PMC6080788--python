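"""Coarse C-alpha/C-beta protein model and PDB/DSSP input.

The protrusion model operates on a coarse point cloud containing one point
per C-alpha and one per C-beta atom; glycine (and residues with a disordered
C-beta) contributes a single point. Full heavy-atom coordinates are retained
per residue for the side-chain SASA computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .config import (
    Config,
    DEFAULT_CONFIG,
    DSSP_CLASS_MAP,
    NONSTANDARD_RESIDUE_MAP,
    STANDARD_AMINO_ACIDS,
)
from .errors import (
    EmptyStructureError,
    MismatchError,
    ParseError,
    UnknownResidueError,
)

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

ANGSTROM_TO_NM = 0.1


@dataclass(frozen=True, order=True)
class ResidueId:
    """Identity of a residue: chain, sequence number, insertion code."""

    chain: str
    number: int
    icode: str = ""

    def __str__(self) -> str:
        return f"{self.chain}:{self.number}{self.icode}"


@dataclass
class Atom:
    """A heavy atom retained for surface-area integration."""

    name: str
    element: str
    coord: np.ndarray  # nm

    @property
    def is_sidechain(self) -> bool:
        return self.name not in BACKBONE_ATOMS


@dataclass
class CoarseResidue:
    """One residue of the coarse model with all derived annotations."""

    residue_id: ResidueId
    amino_acid: str
    ca_coord: np.ndarray  # nm
    cb_coord: Optional[np.ndarray] = None  # nm; None for glycine/missing CB
    atoms: list[Atom] = field(default_factory=list)

    # annotations filled in by the pipeline
    is_hydrophobe: bool = False
    ss_class: str = "loop"
    sidechain_sasa: Optional[float] = None  # nm^2
    is_exposed: Optional[bool] = None
    local_density: Optional[int] = None
    is_vertex: bool = False
    is_protrusion: bool = False
    co_insertable_hydrophobe_count: int = 0
    is_lih: bool = False
    insertion_coordinate: Optional[float] = None

    @property
    def has_cb(self) -> bool:
        return self.cb_coord is not None


class ProteinModel:
    """An assembly of coarse residues with its C-alpha/C-beta point cloud."""

    def __init__(self, model_id: str, residues: Sequence[CoarseResidue]):
        self.model_id = model_id
        self.residues: list[CoarseResidue] = list(residues)
        self.hull = None  # set by hull_geometry.compute_hull
        self.pairs = None  # set by hull_geometry.co_insertable_pairs
        self._build_point_cloud()

    def _build_point_cloud(self) -> None:
        coords = []
        res_index = []
        is_cb = []
        cb_point = {}
        for i, res in enumerate(self.residues):
            coords.append(np.asarray(res.ca_coord, dtype=float))
            res_index.append(i)
            is_cb.append(False)
            if res.cb_coord is not None:
                cb_point[i] = len(coords)
                coords.append(np.asarray(res.cb_coord, dtype=float))
                res_index.append(i)
                is_cb.append(True)
        self.points = np.array(coords, dtype=float).reshape(-1, 3)
        self.point_residue = np.array(res_index, dtype=int)
        self.point_is_cb = np.array(is_cb, dtype=bool)
        #: residue index -> index of its C-beta point in ``points``
        self.cb_point_of_residue: dict[int, int] = cb_point

    def refresh_point_cloud(self) -> None:
        """Rebuild the point cloud after coordinate edits (drops hull cache)."""
        self.hull = None
        self.pairs = None
        self._build_point_cloud()

    def __len__(self) -> int:
        return len(self.residues)

    def __repr__(self) -> str:
        return (
            f"ProteinModel({self.model_id!r}, {len(self.residues)} residues, "
            f"{len(self.points)} points)"
        )

    def residue_by_id(self, residue_id: ResidueId) -> CoarseResidue:
        for res in self.residues:
            if res.residue_id == residue_id:
                return res
        raise KeyError(residue_id)

    def index_by_id(self) -> dict[ResidueId, int]:
        return {res.residue_id: i for i, res in enumerate(self.residues)}


def classify_hydrophobe(amino_acid: str, config: Config = DEFAULT_CONFIG) -> bool:
    """Whether a standard residue is an interfacial hydrophobe.

    Raises :class:`UnknownResidueError` for non-standard codes rather than
    silently returning False.
    """
    aa = amino_acid.upper()
    if aa not in STANDARD_AMINO_ACIDS:
        raise UnknownResidueError(f"not a standard amino acid: {amino_acid!r}")
    return aa in config.hydrophobe_set


def map_secondary_structure(
    dssp_code: str, class_map: Mapping[str, str] = DSSP_CLASS_MAP
) -> str:
    """Map a DSSP summary character to a secondary-structure class.

    Total over all characters: anything absent from the table (including
    blank and '-') is a loop. Output labels are idempotent under the
    identity extension of the table.
    """
    return class_map.get(dssp_code.strip().upper() if dssp_code else "", "loop")


def _select_conformer(atom):
    """Pick the highest-occupancy altloc conformer (tie: file order)."""
    if not atom.is_disordered():
        return atom
    children = atom.disordered_get_list()
    best = children[0]
    for child in children[1:]:
        occ_b = best.get_occupancy() or 0.0
        occ_c = child.get_occupancy() or 0.0
        if occ_c > occ_b:
            best = child
    return best


def _residue_name(residue) -> Optional[str]:
    """Standardised 3-letter code for a residue, or None to exclude."""
    name = residue.get_resname().strip().upper()
    if name in ("HOH", "WAT", "DOD"):
        return None
    if name in STANDARD_AMINO_ACIDS:
        return name
    if name in NONSTANDARD_RESIDUE_MAP:
        return NONSTANDARD_RESIDUE_MAP[name]
    return None


def _coarse_from_biopdb_model(bio_model, model_id: str) -> ProteinModel:
    residues = []
    for chain in bio_model:
        for residue in chain:
            if residue.is_disordered() == 2:  # disordered point mutation
                residue = residue.disordered_get_list()[0]
            name = _residue_name(residue)
            if name is None:
                hetflag = residue.id[0]
                if hetflag != " " and residue.get_resname().strip().upper() not in (
                    "HOH",
                    "WAT",
                    "DOD",
                ):
                    logger.warning(
                        "%s: excluding unmappable residue %s %s",
                        model_id,
                        residue.get_resname(),
                        residue.id,
                    )
                continue
            atoms = []
            ca = cb = None
            for raw_atom in residue:
                atom = _select_conformer(raw_atom)
                element = (atom.element or atom.get_name()[:1]).strip().upper()
                if element in ("H", "D"):
                    continue
                coord = np.asarray(atom.coord, dtype=float) * ANGSTROM_TO_NM
                aname = atom.get_name().strip().upper()
                atoms.append(Atom(aname, element, coord))
                if aname == "CA":
                    ca = coord
                elif aname == "CB":
                    cb = coord
            if ca is None:
                logger.warning(
                    "%s: dropping residue %s without C-alpha", model_id, residue.id
                )
                continue
            if name == "GLY":
                cb = None  # glycine never contributes a C-beta point
            hetflag, seqnum, icode = residue.id
            rid = ResidueId(chain.id, int(seqnum), icode.strip())
            res = CoarseResidue(rid, name, ca, cb, atoms)
            try:
                res.is_hydrophobe = classify_hydrophobe(name)
            except UnknownResidueError:  # pragma: no cover - names remapped
                res.is_hydrophobe = False
            residues.append(res)
    if not residues:
        raise EmptyStructureError(f"{model_id}: no residues with C-alpha atoms")
    return ProteinModel(model_id, residues)


def load_structure(
    path,
    model_policy: str = "first",
    model_id: Optional[str] = None,
):
    """Parse a PDB file into the coarse C-alpha/C-beta representation.

    Waters, unmappable heteroatoms and hydrogens are excluded; alternate
    locations are reduced to the highest-occupancy conformer; selenomethionine
    and similar modified residues are remapped to their parent amino acid.

    Parameters
    ----------
    path:
        PDB-format coordinate file.
    model_policy:
        ``"first"`` (default) reduces NMR ensembles to model 1 and returns a
        single :class:`ProteinModel`; ``"all"`` returns a list with one
        entry per model, tagged ``<id>/model<k>``.
    """
    if model_policy not in ("first", "all"):
        raise ValueError(f"unknown model_policy: {model_policy!r}")
    from Bio.PDB import PDBParser

    path = Path(path)
    base_id = model_id or path.stem
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(base_id, str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # Bio.PDB raises assorted construction errors
        raise ParseError(f"{path}: failed to parse PDB file: {exc}") from exc
    bio_models = list(structure)
    if not bio_models:
        raise EmptyStructureError(f"{path}: file contains no models")
    if model_policy == "first":
        return _coarse_from_biopdb_model(bio_models[0], base_id)
    out = []
    for k, bio_model in enumerate(bio_models, start=1):
        tag = base_id if len(bio_models) == 1 else f"{base_id}/model{k}"
        out.append(_coarse_from_biopdb_model(bio_model, tag))
    return out


def attach_dssp(
    model: ProteinModel,
    dssp_file,
    class_map: Mapping[str, str] = DSSP_CLASS_MAP,
) -> ProteinModel:
    """Attach secondary-structure classes from a classic DSSP output file.

    Residues are matched by (chain, number, insertion code); unmatched
    residues default to 'loop' and are counted in a logged warning. Raises
    :class:`MismatchError` if no residue matches at all.
    """
    from Bio.PDB.DSSP import make_dssp_dict

    try:
        dssp_dict, _keys = make_dssp_dict(str(dssp_file))
    except Exception as exc:
        raise ParseError(f"{dssp_file}: failed to parse DSSP file: {exc}") from exc

    by_key = {}
    for (chain, res_id), values in dssp_dict.items():
        _het, number, icode = res_id
        by_key[(chain, int(number), icode.strip())] = values[1]  # summary SS code

    matched = 0
    for res in model.residues:
        key = (res.residue_id.chain, res.residue_id.number, res.residue_id.icode)
        if key in by_key:
            res.ss_class = map_secondary_structure(by_key[key], class_map)
            matched += 1
        else:
            res.ss_class = "loop"
    if matched == 0:
        raise MismatchError(
            f"{model.model_id}: DSSP file shares no residue identifiers with model"
        )
    unmatched = len(model.residues) - matched
    if unmatched:
        logger.warning(
            "%s: %d residues missing from DSSP file set to 'loop'",
            model.model_id,
            unmatched,
        )
    return model


def resolve_residue_ids(
    model: ProteinModel, ids: Iterable
) -> list[int]:
    """Resolve ResidueId-like identifiers to residue indices.

    Accepts :class:`ResidueId`, ``(chain, number[, icode])`` tuples, or
    ``"A:52"``/``"A:52B"`` strings.
    """
    index = model.index_by_id()
    out = []
    unmatched = []
    for raw in ids:
        rid = _coerce_residue_id(raw)
        if rid in index:
            out.append(index[rid])
        else:
            unmatched.append(raw)
    if unmatched:
        from .errors import UnmatchedResiduesError

        raise UnmatchedResiduesError(unmatched)
    return out


def _coerce_residue_id(raw) -> ResidueId:
    if isinstance(raw, ResidueId):
        return raw
    if isinstance(raw, tuple):
        chain, number = raw[0], int(raw[1])
        icode = raw[2] if len(raw) > 2 else ""
        return ResidueId(str(chain), number, str(icode).strip())
    if isinstance(raw, str) and ":" in raw:
        chain, rest = raw.split(":", 1)
        digits = ""
        i = 0
        if rest and rest[0] == "-":
            digits, i = "-", 1
        while i < len(rest) and rest[i].isdigit():
            digits += rest[i]
            i += 1
        return ResidueId(chain, int(digits), rest[i:].strip())
    raise ValueError(f"cannot interpret residue identifier {raw!r}")
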