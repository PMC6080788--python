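import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import perihull as ph
from perihull.structure import Atom, CoarseResidue, ProteinModel, ResidueId

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def config():
    return ph.DEFAULT_CONFIG


@pytest.fixture
def spiky():
    """A small annotated spiky protein with its ground truth."""
    spec = ph.FixtureSpec(n_spikes=6, seed=7, hydrophobe_placement=0.5)
    model, truth = ph.make_spiky_protein(spec, adjacency_oracle=True)
    ph.annotate_geometry(model)
    return model, truth


def make_residue(
    number,
    chain="A",
    aa="ALA",
    ca=(0.0, 0.0, 0.0),
    cb=None,
    **annotations,
):
    res = CoarseResidue(
        ResidueId(chain, number),
        aa,
        np.asarray(ca, dtype=float),
        None if cb is None else np.asarray(cb, dtype=float),
    )
    for key, value in annotations.items():
        setattr(res, key, value)
    return res


def mock_model(model_id, residues, pairs=None):
    """A ProteinModel with hand-set annotations and optional pair list.

    ``pairs`` holds (index_a, index_b) tuples; hydrophobe flags are read
    from the residues.
    """
    model = ProteinModel(model_id, residues)
    if pairs is not None:
        from perihull.hull import CoInsertablePair

        model.pairs = [
            CoInsertablePair(
                residues[a],
                residues[b],
                residues[a].is_hydrophobe and residues[b].is_hydrophobe,
                residues[a].is_hydrophobe or residues[b].is_hydrophobe,
            )
            for a, b in pairs
        ]
    return model


def singleton_cohort(name, models):
    """A cohort with one protein per family."""
    return ph.Cohort(
        name=name,
        families=[
            ph.Family(name=f"{name}-f{i}", proteins=[m])
            for i, m in enumerate(models)
        ],
    )


# ---------------------------------------------------------------------------
# text-format fixtures


def dssp_line(num, resseq, icode, chain, aa, ss):
    buf = [" "] * 140
    def put(s, start):
        for k, ch in enumerate(s):
            buf[start + k] = ch
    put(f"{num:5d}", 0)
    put(f"{resseq:5d}", 5)
    put(icode or " ", 10)
    put(chain, 11)
    put(aa, 13)
    put(ss if ss.strip() else " ", 16)
    put(f"{0:4d}", 34)
    put(f"{0:7d}", 38)
    put(f"{0.0:4.1f}", 46)
    put(f"{0:6d}", 50)
    put(f"{0.0:4.1f}", 57)
    put(f"{0:6d}", 61)
    put(f"{0.0:4.1f}", 68)
    put(f"{0:6d}", 72)
    put(f"{0.0:4.1f}", 79)
    put(f"{0.0:6.1f}", 103)
    put(f"{0.0:6.1f}", 109)
    return "".join(buf)


def dssp_text(rows):
    """Classic DSSP text for (resseq, icode, chain, aa1, ss) rows."""
    header = (
        "==== Secondary Structure Definition by the program DSSP ====\n"
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N"
        "    N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI"
        "    X-CA   Y-CA   Z-CA\n"
    )
    lines = [
        dssp_line(i + 1, resseq, icode, chain, aa, ss)
        for i, (resseq, icode, chain, aa, ss) in enumerate(rows)
    ]
    return header + "\n".join(lines) + "\n"


PDB_ALA_GLY_LEU = """\
ATOM      1  N   ALA A   1       0.000   1.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  CB  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      4  CA  GLY A   2       3.000   0.000   0.000  1.00  0.00           C
ATOM      5  CA  LEU A   3       0.000   3.000   0.000  1.00  0.00           C
ATOM      6  CB  LEU A   3       0.000   4.000   1.000  1.00  0.00           C
END
"""


def random_rotation(rng):
    """A uniformly random rotation matrix."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def transform_model(model, rotation, translation):
    """Rigidly transform a model in place and refresh its point cloud."""
    for res in model.residues:
        res.ca_coord = rotation @ res.ca_coord + translation
        if res.cb_coord is not None:
            res.cb_coord = rotation @ res.cb_coord + translation
        for atom in res.atoms:
            atom.coord = rotation @ atom.coord + translation
    model.refresh_point_cloud()
    return model
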