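"""Exception types raised across the package."""


class PerihullError(Exception):
    """Base class for all package errors."""


class ParseError(PerihullError):
    """A structure or annotation file could not be parsed."""


class EmptyStructureError(ParseError):
    """A structure file contained no usable residues (no C-alpha atoms)."""


class UnknownResidueError(PerihullError):
    """An amino-acid code outside the 20 standard residues was supplied."""


class DegenerateStructureError(PerihullError):
    """The point cloud is too degenerate for a 3-D convex hull."""

    def __init__(self, rank: int, n_points: int):
        self.rank = rank
        self.n_points = n_points
        super().__init__(
            f"point cloud is degenerate: {n_points} points with affine rank "
            f"{rank} (need >= 4 points of rank 3)"
        )


class UndefinedDensityError(PerihullError):
    """Local protein density was requested for a residue without a C-beta."""


class UndefinedResultError(PerihullError):
    """A statistic is undefined (e.g. empty reference selection everywhere)."""


class MismatchError(PerihullError):
    """An annotation file shares no residue identifiers with the model."""


class UnmatchedResiduesError(PerihullError):
    """Externally supplied residue identifiers could not all be resolved."""

    def __init__(self, unmatched):
        self.unmatched = list(unmatched)
        super().__init__(
            "residue identifiers not found in model: "
            + ", ".join(str(u) for u in self.unmatched)
        )


class UndefinedAngleError(PerihullError):
    """An angle was requested for a zero-length site vector."""


class FixtureError(PerihullError):
    """A synthetic fixture could not be generated with a valid ground truth."""
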