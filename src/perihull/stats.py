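"""Family-weighted comparative statistics and the co-insertion null model.

Cohorts group proteins into families; every family contributes equally to a
data-set statistic regardless of its size. With ``G_s`` the residues of
protein ``G`` meeting selection ``s``:

* mean fraction within a family: average over members of |G_s & G_r| / |G_r|
* weighted residue count:  N̂_s = sum over families of mean |G_s|
* weighted protein count:  M̂_s = sum over families of mean 1[|G_s| > 0]
* weighted fraction:       F̂_{s|r} = N̂_{s&r} / N̂_r
* protein fraction:        Ê_s = M̂_s / |D|   (|D| = number of families)

95% confidence intervals use the normal approximation to the binomial with
the (real-valued) weighted counts standing in for trial counts. Cohorts are
compared with the log odds ratio
``ln R = ln[F̂_A (1-F̂_B)] - ln[F̂_B (1-F̂_A)]`` with a Wald interval whose
success/failure counts are the weighted counts. Analogous measures over
co-insertable pairs use pair sets: 'one' pairs have at least one protruding
hydrophobe, 'both' pairs have two. No multiple-testing correction is
applied anywhere, by design.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .config import Config, DEFAULT_CONFIG
from .errors import UndefinedResultError
from .structure import CoarseResidue, ProteinModel

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class Family:
    name: str
    proteins: list[ProteinModel] = field(default_factory=list)

    def __len__(self):
        return len(self.proteins)


@dataclass
class Cohort:
    name: str
    families: list[Family] = field(default_factory=list)

    @property
    def proteins(self):
        return [p for fam in self.families for p in fam.proteins]

    def __len__(self):
        return len(self.families)


class Selection:
    """A named residue predicate; combine with ``&`` for conjunctions."""

    def __init__(self, name: str, fn: Callable[[CoarseResidue], bool]):
        self.name = name
        self.fn = fn

    def __call__(self, residue: CoarseResidue) -> bool:
        return bool(self.fn(residue))

    def __and__(self, other: "Selection") -> "Selection":
        return Selection(f"{self.name}&{other.name}", lambda r: self.fn(r) and other.fn(r))

    def __repr__(self):
        return f"Selection({self.name!r})"

    def count(self, model: ProteinModel) -> int:
        return sum(1 for r in model.residues if self.fn(r))


def _sel(name, fn):
    return Selection(name, fn)


hydrophobe = _sel("hydrophobe", lambda r: r.is_hydrophobe)
vertex = _sel("vertex", lambda r: r.is_vertex)
protrusion = _sel("protrusion", lambda r: r.is_protrusion)
exposed = _sel("exposed", lambda r: bool(r.is_exposed))
co_insertable = _sel(
    "co_insertable", lambda r: r.is_protrusion and r.co_insertable_hydrophobe_count > 0
)
isolated_protrusion = _sel(
    "isolated", lambda r: r.is_protrusion and r.co_insertable_hydrophobe_count == 0
)
everything = _sel("all", lambda r: True)


def ss_class(name: str) -> Selection:
    return _sel(f"ss:{name}", lambda r: r.ss_class == name)


def amino_acid(code: str) -> Selection:
    code = code.upper()
    return _sel(f"aa:{code}", lambda r: r.amino_acid == code)


def density_range(lower: float, upper: float) -> Selection:
    """Residues with local density in the half-open range (lower, upper]."""
    return _sel(
        f"{lower}<d<={upper}",
        lambda r: r.local_density is not None and lower < r.local_density <= upper,
    )


@dataclass
class StatResult:
    """A point estimate with its 95% interval and the weighted counts used."""

    estimate: float
    lower: float
    upper: float
    successes: float
    failures: float
    estimator: str
    undefined: bool = False
    infinite: bool = False

    def covers(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def mean_fraction(family: Family, s: Selection, r: Selection) -> float:
    """Family mean of |G_s & G_r| / |G_r| over member proteins.

    Proteins with an empty reference selection are skipped and the mean
    renormalised (logged); raises :class:`UndefinedResultError` when every
    member has an empty reference selection.
    """
    ratios = []
    skipped = 0
    for model in family.proteins:
        n_r = 0
        n_sr = 0
        for res in model.residues:
            if r(res):
                n_r += 1
                if s(res):
                    n_sr += 1
        if n_r == 0:
            skipped += 1
            continue
        ratios.append(n_sr / n_r)
    if not ratios:
        raise UndefinedResultError(
            f"family {family.name}: no member has residues with {r.name}"
        )
    if skipped:
        logger.info(
            "family %s: skipped %d proteins with empty %s selection",
            family.name,
            skipped,
            r.name,
        )
    return float(np.mean(ratios))


def weighted_count(cohort: Cohort, s: Selection) -> float:
    """N̂_s: sum over families of the family-mean residue count of ``s``."""
    total = 0.0
    for family in cohort.families:
        if not family.proteins:
            continue
        total += sum(s.count(p) for p in family.proteins) / len(family.proteins)
    return total


def weighted_protein_count(cohort: Cohort, s: Selection) -> float:
    """M̂_s: sum over families of the family-mean indicator of any ``s``."""
    total = 0.0
    for family in cohort.families:
        if not family.proteins:
            continue
        total += sum(
            1.0 for p in family.proteins if s.count(p) > 0
        ) / len(family.proteins)
    return total


def _wald_fraction(successes: float, trials: float, estimator: str) -> StatResult:
    frac = successes / trials
    se = math.sqrt(max(frac * (1.0 - frac), 0.0) / trials)
    return StatResult(
        estimate=frac,
        lower=frac - Z95 * se,
        upper=frac + Z95 * se,
        successes=successes,
        failures=trials - successes,
        estimator=estimator,
    )


def weighted_fraction(cohort: Cohort, s: Selection, r: Selection) -> StatResult:
    """F̂_{s|r} = N̂_{s&r} / N̂_r with a Wald 95% interval (N̂_r trials)."""
    n_sr = weighted_count(cohort, s & r)
    n_r = weighted_count(cohort, r)
    if n_r == 0:
        raise UndefinedResultError(
            f"cohort {cohort.name}: weighted count of {r.name} is zero"
        )
    return _wald_fraction(n_sr, n_r, f"F[{s.name}|{r.name}]")


def protein_fraction(cohort: Cohort, s: Selection) -> StatResult:
    """Ê_s = M̂_s / |D| with a Wald 95% interval (|D| trials)."""
    n_families = len(cohort.families)
    if n_families == 0:
        raise UndefinedResultError(f"cohort {cohort.name} has no families")
    m_s = weighted_protein_count(cohort, s)
    return _wald_fraction(m_s, float(n_families), f"E[{s.name}]")


# ---------------------------------------------------------------------------
# co-insertable pair measures


def _pair_counts_for_model(model: ProteinModel) -> tuple[int, int]:
    """(both, one) pair counts of a model with computed pairs."""
    if model.pairs is None:
        raise UndefinedResultError(
            f"{model.model_id}: co-insertable pairs not computed"
        )
    both = sum(1 for p in model.pairs if p.both_hydrophobe)
    one = sum(1 for p in model.pairs if p.one_hydrophobe)
    return both, one


@dataclass
class PairStats:
    """Family-weighted measures over co-insertable pairs."""

    n_pair_one: float
    n_pair_both: float
    m_pair_both: float
    e_pair_both: StatResult
    f_both_given_one: StatResult


def pair_counts(cohort: Cohort) -> PairStats:
    """Weighted pair counts and fractions over a cohort.

    ``F̂^pair_{both|one}`` estimates the conditional probability that both
    residues of a co-insertable pair are protruding hydrophobes given that
    one of them is. When no pair has a protruding hydrophobe anywhere the
    fraction is undefined and flagged (not raised).
    """
    n_both = 0.0
    n_one = 0.0
    m_both = 0.0
    for family in cohort.families:
        if not family.proteins:
            continue
        w = 1.0 / len(family.proteins)
        for model in family.proteins:
            both, one = _pair_counts_for_model(model)
            n_both += w * both
            n_one += w * one
            m_both += w * (1.0 if both > 0 else 0.0)
    n_families = len(cohort.families)
    e_both = _wald_fraction(m_both, float(n_families), "E[pair_both]")
    if n_one == 0:
        f = StatResult(
            estimate=float("nan"),
            lower=float("nan"),
            upper=float("nan"),
            successes=0.0,
            failures=0.0,
            estimator="F[pair_both|pair_one]",
            undefined=True,
        )
    else:
        f = _wald_fraction(n_both, n_one, "F[pair_both|pair_one]")
    return PairStats(n_one, n_both, m_both, e_both, f)


# ---------------------------------------------------------------------------
# odds ratios


def odds_ratio(stat_a: StatResult, stat_b: StatResult) -> StatResult:
    """ln R comparing two weighted fractions, with a Wald 95% interval.

    The interval uses the real-valued success/failure counts carried by the
    two fraction estimates. A fraction exactly 0 or 1 yields an infinite
    estimate which is flagged, never clipped.
    """
    fa, fb = stat_a.estimate, stat_b.estimate
    if stat_a.undefined or stat_b.undefined:
        return StatResult(
            float("nan"), float("nan"), float("nan"), 0.0, 0.0,
            "lnR", undefined=True,
        )
    if not (0.0 < fa < 1.0) or not (0.0 < fb < 1.0):
        sign = 1.0 if fa > fb else -1.0
        return StatResult(
            sign * float("inf"), float("nan"), float("nan"),
            stat_a.successes, stat_a.failures, "lnR", infinite=True,
        )
    ln_r = math.log(fa / (1.0 - fa)) - math.log(fb / (1.0 - fb))
    se = math.sqrt(
        1.0 / stat_a.successes
        + 1.0 / stat_a.failures
        + 1.0 / stat_b.successes
        + 1.0 / stat_b.failures
    )
    return StatResult(
        estimate=ln_r,
        lower=ln_r - Z95 * se,
        upper=ln_r + Z95 * se,
        successes=stat_a.successes,
        failures=stat_a.failures,
        estimator="lnR",
    )


def density_range_comparison(
    cohort_a: Cohort,
    cohort_b: Cohort,
    ranges: Sequence[tuple[float, float]],
) -> list[dict]:
    """Per-density-range ln R of hydrophobe frequency on vertex residues.

    For each half-open range (l, u], compares
    ``F̂[hydrophobe | vertex & l<d<=u]`` between the two cohorts. Ranges
    that are empty in either cohort yield an undefined-flagged entry.
    """
    out = []
    for lower_d, upper_d in ranges:
        r_sel = vertex & density_range(lower_d, upper_d)
        record = {"range": (lower_d, upper_d)}
        try:
            fa = weighted_fraction(cohort_a, hydrophobe, r_sel)
            fb = weighted_fraction(cohort_b, hydrophobe, r_sel)
        except UndefinedResultError:
            record["ln_r"] = StatResult(
                float("nan"), float("nan"), float("nan"), 0.0, 0.0,
                "lnR", undefined=True,
            )
            out.append(record)
            continue
        record["fraction_a"] = fa
        record["fraction_b"] = fb
        record["ln_r"] = odds_ratio(fa, fb)
        out.append(record)
    return out


# ---------------------------------------------------------------------------
# co-insertion null model


def _null_rng(seed: int, model_id: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(model_id.encode("utf-8"))])


def co_insertion_null(
    model: ProteinModel,
    n_samples: int = 1000,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Null (both, one) pair counts from random hydrophobe reassignment.

    Each sample reassigns the protein's hydrophobic labels uniformly over
    its protrusion positions, preserving the number of hydrophobic
    protrusions, and recounts the co-insertable pairs with two / with at
    least one hydrophobe. Returns arrays of shape ``(n_samples,)``.
    """
    protrusions = [i for i, r in enumerate(model.residues) if r.is_protrusion]
    if not protrusions:
        raise UndefinedResultError(f"{model.model_id}: no protrusions")
    if model.pairs is None:
        raise UndefinedResultError(
            f"{model.model_id}: co-insertable pairs not computed"
        )
    pos = {res_idx: k for k, res_idx in enumerate(protrusions)}
    index_of = {id(res): i for i, res in enumerate(model.residues)}
    edges = np.array(
        [
            (pos[index_of[id(p.residue_a)]], pos[index_of[id(p.residue_b)]])
            for p in model.pairs
        ],
        dtype=int,
    ).reshape(-1, 2)
    k_hydro = sum(1 for i in protrusions if model.residues[i].is_hydrophobe)
    n_prot = len(protrusions)
    if rng is None:
        rng = _null_rng(seed, model.model_id)

    if len(edges) == 0 or k_hydro == 0:
        zero = np.zeros(n_samples, dtype=int)
        if len(edges) == 0:
            return zero, zero.copy()
    # uniformly random k-subsets of protrusion positions, vectorised
    ranks = np.argsort(rng.random((n_samples, n_prot)), axis=1)
    labels = ranks < k_hydro  # (n_samples, n_prot) boolean hydrophobe labels
    la = labels[:, edges[:, 0]]
    lb = labels[:, edges[:, 1]]
    both = (la & lb).sum(axis=1)
    one = (la | lb).sum(axis=1)
    return both, one


def null_pair_fraction(
    cohort: Cohort,
    n_samples: int = 1000,
    seed: int = 0,
) -> StatResult:
    """Cohort-level null F̂^pair_{both|one} under hydrophobe reassignment.

    Per-sample family-weighted 'both' and 'one' counts are averaged across
    samples; the null fraction and its Wald interval use those averaged
    real-valued counts. RNG substreams are keyed by (seed, model_id) so the
    result does not depend on evaluation order. Proteins without protrusions
    are skipped and logged.
    """
    n_both = np.zeros(n_samples)
    n_one = np.zeros(n_samples)
    for family in cohort.families:
        if not family.proteins:
            continue
        w = 1.0 / len(family.proteins)
        for model in family.proteins:
            try:
                both, one = co_insertion_null(model, n_samples, seed)
            except UndefinedResultError:
                logger.info("%s: skipped in null model", model.model_id)
                continue
            n_both += w * both
            n_one += w * one
    mean_both = float(n_both.mean())
    mean_one = float(n_one.mean())
    if mean_one == 0:
        return StatResult(
            float("nan"), float("nan"), float("nan"), 0.0, 0.0,
            "F_null[pair_both|pair_one]", undefined=True,
        )
    return _wald_fraction(mean_both, mean_one, "F_null[pair_both|pair_one]")


def co_insertion_comparison(
    cohort: Cohort, n_samples: int = 1000, seed: int = 0
) -> dict:
    """Observed vs null co-insertion: returns observed, null and ln R."""
    observed = pair_counts(cohort).f_both_given_one
    null = null_pair_fraction(cohort, n_samples=n_samples, seed=seed)
    return {
        "observed": observed,
        "null": null,
        "ln_r": odds_ratio(observed, null),
    }
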