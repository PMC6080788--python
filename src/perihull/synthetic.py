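"""Synthetic coarse structures with known ground truth.

Fixtures are point-cloud 'proteins': a dense core sampled in a ball (high
local density everywhere, so no core residue can be a protrusion) plus
radial spikes whose tip residues are guaranteed hull vertices with low
density — the planted protrusions. Ground truth is certified at generation
time with checks independent of the Qhull pipeline: each spike C-beta is
strictly extreme along its own spike direction (an exact vertex
certificate), and densities are recounted by brute force. Generation fails
loudly rather than emit a wrong fixture.

Defaults place the core at a realistic backbone packing density (roughly 30
C-alpha/C-beta points per nm^3, matching globular protein interiors) and
spike tips 1.2 nm proud of the core, comparable to an exposed loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .config import Config, DEFAULT_CONFIG
from .errors import FixtureError
from .hull import annotate_geometry, co_insertable_pairs, likely_inserted_hydrophobe
from .membrane import MembraneFrame
from .oracle import is_hull_edge_bruteforce, is_vertex_bruteforce
from .stats import Cohort, Family
from .structure import Atom, CoarseResidue, ProteinModel, ResidueId

NM_TO_ANGSTROM = 10.0

HYDROPHOBE_CYCLE = ("LEU", "ILE", "PHE", "TRP", "MET")
FILLER_CYCLE = ("ALA", "SER")


@dataclass(frozen=True)
class MembraneSceneSpec:
    """Membrane placement: slab half-thickness and planted LIH depth (nm)."""

    half_thickness: float = 1.5
    lih_depth: float = 0.0


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a planted spiky-protein fixture."""

    n_core_residues: int = 120
    core_radius: float = 1.2  # nm
    n_spikes: int = 8
    spike_length: float = 1.2  # nm, C-beta tip height above the core surface
    cb_offset: float = 0.15  # nm, C-alpha to C-beta distance
    min_spike_angle: float = 20.0  # degrees between spike directions
    hydrophobe_placement: Union[float, Sequence[bool]] = 0.5
    n_families: int = 10
    proteins_per_family: int = 1
    membrane: Optional[MembraneSceneSpec] = None
    seed: int = 0


class _RetryableFixtureError(FixtureError):
    """A random draw violated the planted ground truth; resampling may fix it."""


@dataclass
class GroundTruth:
    """Exact expectations for a generated fixture."""

    protrusion_ids: list[ResidueId]
    hydrophobe_ids: list[ResidueId]
    densities: dict[ResidueId, int]
    adjacency: Optional[set[frozenset]] = None  # frozensets of ResidueId
    expected_lih: Optional[ResidueId] = None


def _spike_directions(
    rng: np.random.Generator, n: int, min_angle_deg: float, max_tries: int = 20000
) -> np.ndarray:
    cos_min = np.cos(np.radians(min_angle_deg))
    dirs: list[np.ndarray] = []
    tries = 0
    while len(dirs) < n:
        tries += 1
        if tries > max_tries:
            raise FixtureError(
                f"could not place {n} spikes with pairwise separation "
                f">= {min_angle_deg} degrees"
            )
        v = rng.standard_normal(3)
        v /= np.linalg.norm(v)
        if all(float(np.dot(v, u)) < cos_min for u in dirs):
            dirs.append(v)
    return np.array(dirs)


def _uniform_ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return v * r[:, None]


def _hydrophobe_labels(
    spec: FixtureSpec, rng: np.random.Generator
) -> np.ndarray:
    placement = spec.hydrophobe_placement
    if isinstance(placement, (int, float)) and not isinstance(placement, bool):
        return rng.random(spec.n_spikes) < float(placement)
    labels = np.asarray(list(placement), dtype=bool)
    if len(labels) != spec.n_spikes:
        raise FixtureError(
            "explicit hydrophobe_placement must have one flag per spike"
        )
    return labels


def make_spiky_protein(
    spec: FixtureSpec,
    rng: Optional[np.random.Generator] = None,
    model_id: str = "fixture",
    config: Config = DEFAULT_CONFIG,
    adjacency_oracle: bool = False,
    max_attempts: int = 20,
) -> tuple[ProteinModel, GroundTruth]:
    """Dense core plus ``n_spikes`` planted protrusions, with ground truth.

    The random core occasionally places a marginal low-density residue on
    the hull; such draws are rejected and resampled (deterministically from
    the same stream) so only fixtures with a certified ground truth are
    emitted. Verification does not look at the hydrophobe labels, so the
    rejection does not bias their placement. When ``adjacency_oracle`` is
    true the set of spike-tip hull edges is also computed with the
    brute-force projection oracle and an expected LIH derived from it
    (``None`` when the tie falls to the random rule).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    last_error = None
    for _attempt in range(max_attempts):
        try:
            model, truth = _build_spiky_protein(spec, rng, model_id, config)
        except _RetryableFixtureError as err:
            last_error = err
            continue
        if adjacency_oracle:
            truth.adjacency = _oracle_adjacency(model, truth.protrusion_ids)
            truth.expected_lih = _expected_lih(truth)
        return model, truth
    raise FixtureError(
        f"no valid fixture in {max_attempts} attempts; last error: {last_error}"
    )


def _build_spiky_protein(
    spec: FixtureSpec,
    rng: np.random.Generator,
    model_id: str,
    config: Config,
) -> tuple[ProteinModel, GroundTruth]:
    dirs = _spike_directions(rng, spec.n_spikes, spec.min_spike_angle)
    core_ca = _uniform_ball(rng, spec.n_core_residues, spec.core_radius)
    cb_dirs = rng.standard_normal((spec.n_core_residues, 3))
    cb_dirs /= np.linalg.norm(cb_dirs, axis=1, keepdims=True)
    core_cb = core_ca + spec.cb_offset * cb_dirs

    labels = _hydrophobe_labels(spec, rng)
    tip_radius = spec.core_radius + spec.spike_length

    residues = []
    number = 0
    for i in range(spec.n_core_residues):
        number += 1
        aa = FILLER_CYCLE[i % len(FILLER_CYCLE)]
        rid = ResidueId("A", number)
        residues.append(
            CoarseResidue(
                rid,
                aa,
                core_ca[i],
                core_cb[i],
                atoms=[
                    Atom("CA", "C", core_ca[i]),
                    Atom("CB", "C", core_cb[i]),
                ],
            )
        )
    spike_ids = []
    for k in range(spec.n_spikes):
        number += 1
        if labels[k]:
            aa = HYDROPHOBE_CYCLE[k % len(HYDROPHOBE_CYCLE)]
        else:
            aa = FILLER_CYCLE[k % len(FILLER_CYCLE)]
        ca = (tip_radius - spec.cb_offset) * dirs[k]
        cb = tip_radius * dirs[k]
        rid = ResidueId("A", number)
        spike_ids.append(rid)
        res = CoarseResidue(
            rid,
            aa,
            ca,
            cb,
            atoms=[Atom("CA", "C", ca), Atom("CB", "C", cb)],
        )
        res.is_hydrophobe = bool(labels[k])
        residues.append(res)
    model = ProteinModel(model_id, residues)

    truth = _verify_ground_truth(model, spec, dirs, spike_ids, config)
    truth.hydrophobe_ids = [rid for rid, lab in zip(spike_ids, labels) if lab]
    return model, truth


def _verify_ground_truth(
    model: ProteinModel,
    spec: FixtureSpec,
    dirs: np.ndarray,
    spike_ids: list[ResidueId],
    config: Config,
) -> GroundTruth:
    points = model.points
    tip_radius = spec.core_radius + spec.spike_length
    index = model.index_by_id()
    # exact vertex certificate: each tip is strictly extreme along its spike
    for k, rid in enumerate(spike_ids):
        tip_point = model.cb_point_of_residue[index[rid]]
        proj = points @ dirs[k]
        top = np.argsort(proj)[-1]
        if top != tip_point or proj[top] - np.partition(proj, -2)[-2] < 1e-9:
            raise _RetryableFixtureError(
                f"spike {rid} is not strictly extreme along its direction; "
                "increase spike_length or min_spike_angle"
            )
    # brute-force density recount: spikes low, everything else high
    densities = {}
    for i, res in enumerate(model.residues):
        p = model.cb_point_of_residue.get(i)
        if p is None:
            continue
        d = int(
            np.sum(
                np.linalg.norm(points - points[p], axis=1)
                <= config.density_radius
            )
        )
        densities[res.residue_id] = d
    for rid in spike_ids:
        if densities[rid] >= config.density_threshold:
            raise _RetryableFixtureError(
                f"planted spike {rid} has density {densities[rid]} >= "
                f"{config.density_threshold}"
            )
    # a low-density core residue breaks the ground truth only if its C-beta
    # is also a hull vertex; that is rare, so the exact LP test is cheap
    spike_set = set(spike_ids)
    for rid, d in densities.items():
        if rid in spike_set or d >= config.density_threshold:
            continue
        cb_point = model.cb_point_of_residue[index[rid]]
        if is_vertex_bruteforce(points, cb_point):
            raise _RetryableFixtureError(
                f"core residue {rid} is a low-density hull vertex (d={d}); "
                "raise n_core_residues or shrink core_radius"
            )
    return GroundTruth(
        protrusion_ids=list(spike_ids),
        hydrophobe_ids=[],
        densities=densities,
    )


def _oracle_adjacency(
    model: ProteinModel, spike_ids: list[ResidueId]
) -> set[frozenset]:
    index = model.index_by_id()
    tips = {rid: model.cb_point_of_residue[index[rid]] for rid in spike_ids}
    adjacency = set()
    ids = list(spike_ids)
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            if is_hull_edge_bruteforce(model.points, tips[ids[a]], tips[ids[b]]):
                adjacency.add(frozenset((ids[a], ids[b])))
    return adjacency


def _expected_lih(truth: GroundTruth) -> Optional[ResidueId]:
    hydro = set(truth.hydrophobe_ids)
    if not hydro:
        return None
    # a residue's count = number of *hydrophobic* protrusion partners
    counts = {rid: 0 for rid in hydro}
    for pair in truth.adjacency or ():
        a, b = tuple(pair)
        if a in counts and b in hydro:
            counts[a] += 1
        if b in counts and a in hydro:
            counts[b] += 1
    best = max(counts.values())
    tied = [rid for rid, c in counts.items() if c == best]
    if len(tied) == 1:
        return tied[0]
    best_d = min(truth.densities[rid] for rid in tied)
    tied = [rid for rid in tied if truth.densities[rid] == best_d]
    return tied[0] if len(tied) == 1 else None


def assign_hydrophobes(
    model: ProteinModel,
    rng: np.random.Generator,
    p: Optional[float] = None,
    labels: Optional[Sequence[bool]] = None,
    config: Config = DEFAULT_CONFIG,
) -> ProteinModel:
    """Redraw hydrophobe labels on the protrusion residues of a fixture.

    Updates amino-acid identities and hydrophobe flags on protrusions
    (everything else is left non-hydrophobic), then recomputes pair flags,
    co-insertable counts and the LIH from the cached hull.
    """
    protrusions = [r for r in model.residues if r.is_protrusion]
    if labels is None:
        if p is None:
            raise ValueError("provide either p or labels")
        labels = rng.random(len(protrusions)) < p
    if len(labels) != len(protrusions):
        raise ValueError("one label per protrusion required")
    for k, (res, lab) in enumerate(zip(protrusions, labels)):
        res.is_hydrophobe = bool(lab)
        res.amino_acid = (
            HYDROPHOBE_CYCLE[k % len(HYDROPHOBE_CYCLE)]
            if lab
            else FILLER_CYCLE[k % len(FILLER_CYCLE)]
        )
    co_insertable_pairs(model, config)
    likely_inserted_hydrophobe(model, config)
    return model


def make_cohort(
    spec: FixtureSpec,
    name: str = "cohort",
    config: Config = DEFAULT_CONFIG,
    annotate: bool = True,
) -> tuple[Cohort, dict[str, GroundTruth]]:
    """Families of spiky proteins with the spec's hydrophobe placement."""
    rng = np.random.default_rng(spec.seed)
    families = []
    truths: dict[str, GroundTruth] = {}
    for f in range(spec.n_families):
        family = Family(name=f"{name}-fam{f:03d}")
        for p in range(spec.proteins_per_family):
            model_id = f"{name}-f{f:03d}-p{p:02d}"
            model, truth = make_spiky_protein(
                spec, rng=rng, model_id=model_id, config=config
            )
            if annotate:
                annotate_geometry(model, config)
            family.proteins.append(model)
            truths[model_id] = truth
        families.append(family)
    return Cohort(name=name, families=families), truths


def _rotation_onto_z(u: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector u onto +z."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(u, z)
    c = float(np.dot(u, z))
    s = np.linalg.norm(v)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array(
        [[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]]
    )
    return np.eye(3) + vx + vx @ vx * ((1 - c) / (s * s))


def make_membrane_scene(
    spec: FixtureSpec,
    rng: Optional[np.random.Generator] = None,
    model_id: str = "scene",
    config: Config = DEFAULT_CONFIG,
) -> tuple[ProteinModel, MembraneFrame, GroundTruth, ResidueId]:
    """A spiky protein posed against a planar slab with a planted LIH depth.

    The first spike is made the only protruding hydrophobe (hence the LIH)
    and the protein is oriented and the frame placed so that this tip's
    C-alpha sits at ``spec.membrane.lih_depth`` on the insertion-coordinate
    axis. Returns (model, frame, ground truth, planted LIH residue id).
    """
    mem = spec.membrane or MembraneSceneSpec()
    planted = [True] + [False] * (spec.n_spikes - 1)
    scene_spec = replace(spec, hydrophobe_placement=planted, membrane=mem)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    model, truth = make_spiky_protein(
        scene_spec, rng=rng, model_id=model_id, config=config
    )
    lih_id = truth.protrusion_ids[0]
    index = model.index_by_id()
    lih_res = model.residues[index[lih_id]]
    rot = _rotation_onto_z(
        lih_res.cb_coord / np.linalg.norm(lih_res.cb_coord)
    )
    for res in model.residues:
        res.ca_coord = rot @ res.ca_coord
        if res.cb_coord is not None:
            res.cb_coord = rot @ res.cb_coord
        for atom in res.atoms:
            atom.coord = rot @ atom.coord
    model.refresh_point_cloud()
    annotate_geometry(model, config)

    h = mem.half_thickness
    z_tip = float(lih_res.ca_coord[2])
    center = np.array([0.0, 0.0, z_tip + (h - mem.lih_depth)])
    frame = MembraneFrame(center=center, normal=np.array([0.0, 0.0, 1.0]),
                          half_thickness=h)
    return model, frame, truth, lih_id


def make_rod_scene(
    n_residues: int = 49,
    spacing: float = 0.25,
    half_thickness: float = 1.5,
    cb_offset: float = 0.15,
    model_id: str = "rod",
) -> tuple[ProteinModel, MembraneFrame, list[ResidueId]]:
    """A straight rod crossing the slab, for fragment-extraction tests.

    Residues are spaced along the membrane normal with helically arranged
    C-betas (keeping the cloud non-degenerate). Returns the model, the
    frame centered at the origin, and the ground-truth fragment: residues
    whose C-alpha lies at least 1.5 nm outside the hydrocarbon slab.
    """
    residues = []
    expected = []
    offset = (n_residues - 1) / 2.0
    for i in range(n_residues):
        z = (i - offset) * spacing
        ca = np.array([0.0, 0.0, z])
        phi = 2.399963229728653 * i  # golden angle
        cb = ca + cb_offset * np.array([np.cos(phi), np.sin(phi), 0.0])
        rid = ResidueId("A", i + 1)
        residues.append(
            CoarseResidue(
                rid,
                FILLER_CYCLE[i % 2],
                ca,
                cb,
                atoms=[Atom("CA", "C", ca), Atom("CB", "C", cb)],
            )
        )
        if half_thickness - abs(z) <= -1.5:
            expected.append(rid)
    model = ProteinModel(model_id, residues)
    frame = MembraneFrame(
        center=np.zeros(3),
        normal=np.array([0.0, 0.0, 1.0]),
        half_thickness=half_thickness,
    )
    return model, frame, expected


def make_sphere_protein(
    n_residues: int = 500,
    radius: float = 4.0,
    cb_offset: float = 0.15,
    seed: int = 0,
    model_id: str = "sphere",
) -> ProteinModel:
    """Residues spread uniformly on a sphere: a rotation-symmetric fixture.

    With the default size every C-beta is a hull vertex and local densities
    stay below the protrusion cutoff, so essentially all residues protrude;
    useful for control-angle statistics.
    """
    rng = np.random.default_rng(seed)
    dirs = rng.standard_normal((n_residues, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    residues = []
    for i, u in enumerate(dirs):
        ca = radius * u
        cb = (radius + cb_offset) * u
        residues.append(
            CoarseResidue(
                ResidueId("A", i + 1),
                "LEU" if i % 2 else "ALA",
                ca,
                cb,
                atoms=[Atom("CA", "C", ca), Atom("CB", "C", cb)],
            )
        )
        residues[-1].is_hydrophobe = bool(i % 2)
    return ProteinModel(model_id, residues)


def write_pdb(model: ProteinModel, path) -> None:
    """Emit the coarse model as a minimal PDB file (nm -> Angstrom)."""
    with open(path, "w") as fh:
        serial = 0
        for res in model.residues:
            rid = res.residue_id
            for atom in res.atoms or []:
                serial += 1
                x, y, z = (np.asarray(atom.coord) * NM_TO_ANGSTROM).tolist()
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                fh.write(
                    f"ATOM  {serial:5d} {name}{'':1s}{res.amino_acid:>3s} "
                    f"{rid.chain:1s}{rid.number:4d}{rid.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {atom.element:>2s}\n"
                )
        fh.write("END\n")
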