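"""Convex-hull geometry: vertex residues, protrusions, co-insertable pairs.

The convex hull is taken over *all* C-alpha and C-beta points of the
assembly. A residue is a *vertex residue* when its C-beta point is a hull
vertex, and a *protrusion* when additionally its local protein density
``d`` (C-alpha/C-beta points within ``c`` = 1 nm of the C-beta, inclusive,
counting the residue's own atoms) is below ``n`` = 22. Two protrusions are
*co-insertable* when the segment between their C-beta points is an edge of
the hull polygon; facets whose normals agree within a small angular
tolerance are merged first, so edges interior to a flat polygon never count.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import ConvexHull, cKDTree

from .config import Config, DEFAULT_CONFIG
from .errors import DegenerateStructureError, UndefinedDensityError
from .structure import CoarseResidue, ProteinModel


@dataclass
class HullModel:
    """Convex hull of a model's point cloud, with polygon edges."""

    vertex_points: frozenset  # indices into model.points
    edges: frozenset  # frozensets {i, j} of point indices
    simplices: np.ndarray
    equations: np.ndarray

    def is_edge(self, i: int, j: int) -> bool:
        return frozenset((i, j)) in self.edges


@dataclass(frozen=True)
class CoInsertablePair:
    """An unordered pair of protrusions joined by a hull edge."""

    residue_a: CoarseResidue
    residue_b: CoarseResidue
    both_hydrophobe: bool
    one_hydrophobe: bool

    def __iter__(self):
        return iter((self.residue_a, self.residue_b))


def compute_hull(model: ProteinModel, config: Config = DEFAULT_CONFIG) -> HullModel:
    """Convex hull over all C-alpha/C-beta points; marks vertex residues.

    Coplanar neighbouring facets (normals within ``facet_merge_tolerance``
    radians) are merged before edge extraction, so only boundary edges of
    the merged polygons are reported.

    Raises :class:`DegenerateStructureError` for fewer than 4 points or a
    coplanar/collinear cloud, naming the affine rank.
    """
    points = model.points
    n = len(points)
    rank = _affine_rank(points)
    if n < 4 or rank < 3:
        raise DegenerateStructureError(rank, n)
    hull = ConvexHull(points)

    cos_tol = np.cos(config.facet_merge_tolerance)
    normals = hull.equations[:, :3]
    edges = set()
    simplices = hull.simplices
    neighbors = hull.neighbors
    for s in range(len(simplices)):
        for k in range(3):
            t = neighbors[s, k]
            if t < s:
                continue  # visit each facet pair once
            # ridge shared by s and t: simplex s minus its k-th vertex
            ridge = np.delete(simplices[s], k)
            cosang = float(np.clip(np.dot(normals[s], normals[t]), -1.0, 1.0))
            if cosang < cos_tol:  # facets not coplanar: a polygon edge
                edges.add(frozenset((int(ridge[0]), int(ridge[1]))))

    hull_model = HullModel(
        vertex_points=frozenset(int(v) for v in hull.vertices),
        edges=frozenset(edges),
        simplices=simplices,
        equations=hull.equations,
    )
    model.hull = hull_model

    for i, res in enumerate(model.residues):
        cb_point = model.cb_point_of_residue.get(i)
        res.is_vertex = (
            cb_point is not None and cb_point in hull_model.vertex_points
        )
    return hull_model


def _affine_rank(points: np.ndarray, tol: float = 1e-9) -> int:
    if len(points) == 0:
        return 0
    centered = points - points.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    scale = sv[0] if sv.size and sv[0] > 0 else 1.0
    return int(np.sum(sv > tol * scale))


def local_densities(model: ProteinModel, config: Config = DEFAULT_CONFIG) -> None:
    """Compute ``d`` for every residue with a C-beta (stored on residues).

    ``d`` counts all C-alpha/C-beta points within ``density_radius`` of the
    residue's C-beta, boundary inclusive, including the residue's own
    C-alpha and C-beta. Residues without a C-beta get ``local_density=None``.
    """
    tree = cKDTree(model.points)
    cb_indices = [
        (i, p) for i, p in model.cb_point_of_residue.items()
    ]
    if not cb_indices:
        return
    cb_coords = model.points[[p for _, p in cb_indices]]
    counts = tree.query_ball_point(
        cb_coords, r=config.density_radius, return_length=True
    )
    for (i, _p), d in zip(cb_indices, counts):
        model.residues[i].local_density = int(d)
    for i, res in enumerate(model.residues):
        if i not in model.cb_point_of_residue:
            res.local_density = None


def local_density(
    residue: CoarseResidue, model: ProteinModel, config: Config = DEFAULT_CONFIG
) -> int:
    """Local protein density ``d`` of one residue (requires a C-beta)."""
    if residue.cb_coord is None:
        raise UndefinedDensityError(
            f"{residue.residue_id}: local density is undefined without a C-beta"
        )
    d2 = np.sum((model.points - residue.cb_coord) ** 2, axis=1)
    return int(np.sum(d2 <= config.density_radius**2 + 0.0))


def find_protrusions(
    model: ProteinModel, config: Config = DEFAULT_CONFIG
) -> list[CoarseResidue]:
    """Mark and return protrusions: vertex residues with ``d < n``."""
    if model.hull is None:
        compute_hull(model, config)
    if any(
        res.local_density is None and res.has_cb for res in model.residues
    ):
        local_densities(model, config)
    out = []
    for res in model.residues:
        res.is_protrusion = bool(
            res.is_vertex
            and res.local_density is not None
            and res.local_density < config.density_threshold
        )
        if res.is_protrusion:
            out.append(res)
    return out


def co_insertable_pairs(
    model: ProteinModel, config: Config = DEFAULT_CONFIG
) -> list[CoInsertablePair]:
    """All unordered protrusion pairs whose C-beta points share a hull edge.

    Also writes each residue's ``co_insertable_hydrophobe_count``: the
    number of its hydrophobic protrusion partners.
    """
    if model.hull is None or any(
        res.local_density is None and res.has_cb for res in model.residues
    ):
        find_protrusions(model, config)
    point_of = model.cb_point_of_residue
    protrusion_idx = [
        i for i, res in enumerate(model.residues) if res.is_protrusion
    ]
    point_to_res = {point_of[i]: i for i in protrusion_idx}

    pairs = []
    for res in model.residues:
        res.co_insertable_hydrophobe_count = 0
    for edge in model.hull.edges:
        p, q = tuple(edge)
        if p in point_to_res and q in point_to_res:
            ra = model.residues[point_to_res[p]]
            rb = model.residues[point_to_res[q]]
            both = ra.is_hydrophobe and rb.is_hydrophobe
            one = ra.is_hydrophobe or rb.is_hydrophobe
            pairs.append(CoInsertablePair(ra, rb, both, one))
            if rb.is_hydrophobe:
                ra.co_insertable_hydrophobe_count += 1
            if ra.is_hydrophobe:
                rb.co_insertable_hydrophobe_count += 1
    model.pairs = pairs
    return pairs


def _tie_break_rng(config: Config, model_id: str) -> np.random.Generator:
    # per-protein stream so cohort runs are order-independent
    tag = zlib.crc32(model_id.encode("utf-8"))
    return np.random.default_rng([config.random_seed, tag])


def likely_inserted_hydrophobe(
    model: ProteinModel, config: Config = DEFAULT_CONFIG
) -> Optional[CoarseResidue]:
    """The protruding hydrophobe with most co-insertable hydrophobic partners.

    Ties are broken by smallest local density ``d``; remaining ties
    uniformly at random from a per-protein stream seeded by
    ``(config.random_seed, model_id)``. Returns ``None`` iff the protein has
    no protruding hydrophobes. Marks ``is_lih`` on the winner.
    """
    if model.pairs is None:
        co_insertable_pairs(model, config)
    for res in model.residues:
        res.is_lih = False
    candidates = [
        res
        for res in model.residues
        if res.is_protrusion and res.is_hydrophobe
    ]
    if not candidates:
        return None
    best_count = max(r.co_insertable_hydrophobe_count for r in candidates)
    candidates = [
        r for r in candidates if r.co_insertable_hydrophobe_count == best_count
    ]
    best_d = min(r.local_density for r in candidates)
    candidates = [r for r in candidates if r.local_density == best_d]
    if len(candidates) == 1:
        winner = candidates[0]
    else:
        rng = _tie_break_rng(config, model.model_id)
        winner = candidates[int(rng.integers(len(candidates)))]
    winner.is_lih = True
    return winner


def annotate_geometry(
    model: ProteinModel, config: Config = DEFAULT_CONFIG
) -> ProteinModel:
    """Run hull, density, protrusion, pair and LIH annotation in order."""
    compute_hull(model, config)
    local_densities(model, config)
    find_protrusions(model, config)
    co_insertable_pairs(model, config)
    likely_inserted_hydrophobe(model, config)
    return model
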