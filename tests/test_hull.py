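"""Convex hull, local density, protrusions, pairs and the LIH rules."""

import numpy as np
import pytest

import perihull as ph
from perihull.config import Config
from perihull.hull import compute_hull, local_density
from perihull.oracle import (
    hull_edges_bruteforce,
    hull_vertices_bruteforce,
    local_density_bruteforce,
)
from perihull.structure import ProteinModel

from conftest import make_residue, mock_model, random_rotation, transform_model


def cloud_model(points, model_id="cloud"):
    """One glycine-like residue per point (CA only) plus nothing else.

    Used for raw hull geometry checks where residue semantics don't matter.
    """
    residues = [
        make_residue(i + 1, ca=p) for i, p in enumerate(np.asarray(points))
    ]
    return ProteinModel(model_id, residues)


class TestComputeHull:
    def test_tetrahedron_vertices_and_edges(self):
        pts = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float
        )
        model = cloud_model(pts)
        hull = compute_hull(model)
        assert hull.vertex_points == frozenset(range(4))
        assert len(hull.edges) == 6  # simplex: every pair is an edge

    def test_interior_point_is_not_a_vertex(self):
        pts = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [0.25, 0.25, 0.25]],
            dtype=float,
        )
        hull = compute_hull(cloud_model(pts))
        assert 4 not in hull.vertex_points
        assert hull.vertex_points == frozenset(range(4))

    def test_coplanar_facets_merged_on_cube(self):
        # cube faces are triangulated by Qhull; after coplanar merging only
        # the 12 true cube edges remain (no face diagonals)
        corners = np.array(
            [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
            dtype=float,
        )
        hull = compute_hull(cloud_model(corners))
        assert hull.vertex_points == frozenset(range(8))
        assert len(hull.edges) == 12
        for edge in hull.edges:
            i, j = tuple(edge)
            # a cube edge differs in exactly one coordinate
            assert np.sum(corners[i] != corners[j]) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_lp_oracle_on_random_clouds(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((30, 3))
        model = cloud_model(pts)
        hull = compute_hull(model)
        oracle_vertices = hull_vertices_bruteforce(pts)
        assert set(hull.vertex_points) == oracle_vertices
        oracle_edges = hull_edges_bruteforce(pts, oracle_vertices)
        assert set(hull.edges) == oracle_edges

    def test_vertex_residues_defined_on_cb_only(self, spiky):
        model, truth = spiky
        for res in model.residues:
            if not res.has_cb:
                assert not res.is_vertex

    def test_degenerate_cloud_raises_with_rank(self):
        flat = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [0.3, 0.7, 0]],
            dtype=float,
        )
        with pytest.raises(ph.DegenerateStructureError) as err:
            compute_hull(cloud_model(flat))
        assert err.value.rank == 2
        with pytest.raises(ph.DegenerateStructureError):
            compute_hull(cloud_model(np.eye(3)))  # fewer than 4 points


class TestLocalDensity:
    def test_isolated_residue_counts_itself(self):
        res = make_residue(1, ca=(0, 0, 0), cb=(0.15, 0, 0))
        model = ProteinModel("solo", [res])
        assert local_density(res, model) == 2  # own CA + own CB

    def test_inclusive_boundary_at_cutoff(self):
        target = make_residue(1, ca=(0, -0.15, 0), cb=(0, 0, 0))
        near = make_residue(2, ca=(0.99, 0, 0))  # glycine-like, CA only
        far = make_residue(3, ca=(1.01, 0, 0))
        exact = make_residue(4, ca=(0, 1.0, 0))
        model = ProteinModel("bnd", [target, near, far, exact])
        # self CA + self CB + 0.99 + exactly-1.0, excluding 1.01
        assert local_density(target, model) == 4

    def test_missing_cb_raises(self):
        gly = make_residue(1, aa="GLY", ca=(0, 0, 0))
        model = ProteinModel("g", [gly])
        with pytest.raises(ph.UndefinedDensityError):
            local_density(gly, model)

    def test_matches_bruteforce_recount(self):
        rng = np.random.default_rng(42)
        residues = []
        for i in range(50):
            ca = rng.uniform(-1.5, 1.5, 3)
            cb = ca + 0.15 * rng.standard_normal(3)
            residues.append(make_residue(i + 1, ca=ca, cb=cb))
        model = ProteinModel("dense", residues)
        ph.local_densities(model)
        for i, res in enumerate(model.residues):
            expected = local_density_bruteforce(model.points, res.cb_coord, 1.0)
            assert res.local_density == expected

    def test_lowering_radius_never_increases_density(self, spiky):
        model, _ = spiky
        small = Config(density_radius=0.8)
        for res in model.residues:
            if res.has_cb:
                assert local_density(res, model, small) <= local_density(res, model)


class TestProtrusions:
    def test_planted_spikes_are_exactly_the_protrusions(self, spiky):
        model, truth = spiky
        found = {r.residue_id for r in model.residues if r.is_protrusion}
        assert found == set(truth.protrusion_ids)

    def test_threshold_is_strictly_below_n(self, spiky):
        model, _ = spiky
        # same model, thresholds bracketing the observed spike densities
        dmax = max(
            r.local_density for r in model.residues if r.is_protrusion
        )
        at_limit = ph.find_protrusions(model, Config(density_threshold=dmax))
        assert all(r.local_density < dmax for r in at_limit)
        above = ph.find_protrusions(model, Config(density_threshold=dmax + 1))
        assert any(r.local_density == dmax for r in above)
        # restore default annotations for other fixtures
        ph.annotate_geometry(model)

    def test_raising_threshold_never_removes_a_protrusion(self, spiky):
        model, _ = spiky
        low = {r.residue_id for r in ph.find_protrusions(model, Config(density_threshold=15))}
        high = {r.residue_id for r in ph.find_protrusions(model, Config(density_threshold=30))}
        assert low <= high
        ph.annotate_geometry(model)


class TestCoInsertablePairs:
    def test_pairs_match_oracle_adjacency(self, spiky):
        model, truth = spiky
        got = {
            frozenset((p.residue_a.residue_id, p.residue_b.residue_id))
            for p in model.pairs
        }
        assert got == truth.adjacency

    def test_pair_flags_consistent(self, spiky):
        model, _ = spiky
        for pair in model.pairs:
            assert pair.one_hydrophobe == (
                pair.residue_a.is_hydrophobe or pair.residue_b.is_hydrophobe
            )
            if pair.both_hydrophobe:
                assert pair.one_hydrophobe

    def test_counts_equal_hydrophobic_partner_tally(self, spiky):
        model, _ = spiky
        tally = {r.residue_id: 0 for r in model.residues}
        for pair in model.pairs:
            if pair.residue_b.is_hydrophobe:
                tally[pair.residue_a.residue_id] += 1
            if pair.residue_a.is_hydrophobe:
                tally[pair.residue_b.residue_id] += 1
        for res in model.residues:
            assert res.co_insertable_hydrophobe_count == tally[res.residue_id]

    def test_all_hydrophobic_makes_one_equal_both(self):
        spec = ph.FixtureSpec(n_spikes=6, seed=3, hydrophobe_placement=[True] * 6)
        model, _ = ph.make_spiky_protein(spec)
        ph.annotate_geometry(model)
        assert model.pairs  # fixture spikes do share hull edges
        for pair in model.pairs:
            assert pair.both_hydrophobe == pair.one_hydrophobe


class TestLikelyInsertedHydrophobe:
    def _annotated(self, counts, densities, hydrophobes=None):
        residues = []
        for i, (c, d) in enumerate(zip(counts, densities)):
            hydro = True if hydrophobes is None else hydrophobes[i]
            residues.append(
                make_residue(
                    i + 1,
                    aa="LEU" if hydro else "ALA",
                    ca=(float(i), 0, 0),
                    cb=(float(i), 0.15, 0),
                    is_hydrophobe=hydro,
                    is_protrusion=True,
                    is_vertex=True,
                    local_density=d,
                    co_insertable_hydrophobe_count=c,
                )
            )
        model = mock_model("lih", residues, pairs=[])
        return model

    def test_highest_count_wins(self):
        model = self._annotated(counts=[3, 1], densities=[12, 8])
        lih = ph.likely_inserted_hydrophobe(model)
        assert lih.residue_id.number == 1

    def test_tie_broken_by_smallest_density(self):
        model = self._annotated(counts=[2, 2], densities=[10, 15])
        lih = ph.likely_inserted_hydrophobe(model)
        assert lih.residue_id.number == 1

    def test_no_protruding_hydrophobes_returns_none(self):
        model = self._annotated(
            counts=[0, 0], densities=[10, 10], hydrophobes=[False, False]
        )
        assert ph.likely_inserted_hydrophobe(model) is None

    def test_remaining_tie_is_seeded_and_reproducible(self):
        picks = set()
        for _ in range(3):
            model = self._annotated(counts=[2, 2], densities=[10, 10])
            lih = ph.likely_inserted_hydrophobe(model)
            picks.add(lih.residue_id.number)
        assert len(picks) == 1  # same seed, same model id -> same choice
        model = self._annotated(counts=[2, 2], densities=[10, 10])
        other = ph.likely_inserted_hydrophobe(model, Config(random_seed=99))
        assert other.residue_id.number in (1, 2)


class TestRigidInvariance:
    def test_annotations_invariant_under_rotation_translation(self):
        spec = ph.FixtureSpec(n_spikes=6, seed=19, hydrophobe_placement=0.5)
        model, _ = ph.make_spiky_protein(spec)
        ph.annotate_geometry(model)
        reference = {
            r.residue_id: (
                r.is_vertex,
                r.is_protrusion,
                r.co_insertable_hydrophobe_count,
                r.is_lih,
            )
            for r in model.residues
        }
        rng = np.random.default_rng(5)
        transform_model(model, random_rotation(rng), rng.uniform(-5, 5, 3))
        ph.annotate_geometry(model)
        moved = {
            r.residue_id: (
                r.is_vertex,
                r.is_protrusion,
                r.co_insertable_hydrophobe_count,
                r.is_lih,
            )
            for r in model.residues
        }
        assert moved == reference
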