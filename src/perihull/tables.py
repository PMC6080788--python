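"""Tabular serialization of annotations and cohort comparisons.

The per-residue annotation table uses the field's established column
names: the density column is named 'local density', the hydrophobic
co-insertable partner count 'co insertables', the side-chain area
'sidechain sasa' and the Likely Inserted Hydrophobe flag 'LIH'. Tables are
plain UTF-8 CSV with a header row and '.' decimals; row order is
deterministic (pdb id, chain id, residue number, insertion code).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import Config, DEFAULT_CONFIG
from .errors import UndefinedResultError
from .hull import annotate_geometry
from .membrane import MembraneFrame, attach_insertion_coordinates
from .sasa import attach_sasa
from .stats import (
    Cohort,
    Selection,
    StatResult,
    Z95,
    odds_ratio,
    pair_counts,
    protein_fraction,
    weighted_fraction,
)
from .structure import ProteinModel

ANNOTATION_COLUMNS = [
    "pdb id",
    "chain id",
    "residue number",
    "insertion code",
    "amino acid",
    "sidechain sasa",
    "local density",
    "co insertables",
    "is vertex",
    "is protrusion",
    "is hydrophobe",
    "is exposed",
    "ss class",
    "LIH",
    "insertion coordinate",
]


def annotate_table(
    models: Iterable[ProteinModel],
    config: Config = DEFAULT_CONFIG,
    frames: Optional[Mapping[str, MembraneFrame]] = None,
    compute: bool = True,
    with_sasa: bool = True,
    only_exposed: bool = False,
) -> pd.DataFrame:
    """Per-residue annotation table for one or more models.

    With ``compute`` the geometric pipeline (hull, density, protrusions,
    pairs, LIH) and, if heavy atoms are present, SASA/exposure are run
    first. ``only_exposed`` restricts rows to exposed residues, matching the
    published per-residue dataset; the default keeps all residues so that
    statistics recomputed from the table match in-memory values exactly.
    """
    rows = []
    for model in models:
        if compute:
            annotate_geometry(model, config)
            if with_sasa and any(res.atoms for res in model.residues):
                attach_sasa(model, config)
            if frames and model.model_id in frames:
                attach_insertion_coordinates(model, frames[model.model_id])
        for res in model.residues:
            if only_exposed and not res.is_exposed:
                continue
            rid = res.residue_id
            rows.append(
                {
                    "pdb id": model.model_id,
                    "chain id": rid.chain,
                    "residue number": rid.number,
                    "insertion code": rid.icode,
                    "amino acid": res.amino_acid,
                    "sidechain sasa": res.sidechain_sasa,
                    "local density": res.local_density,
                    "co insertables": res.co_insertable_hydrophobe_count,
                    "is vertex": res.is_vertex,
                    "is protrusion": res.is_protrusion,
                    "is hydrophobe": res.is_hydrophobe,
                    "is exposed": res.is_exposed,
                    "ss class": res.ss_class,
                    "LIH": res.is_lih,
                    "insertion coordinate": res.insertion_coordinate,
                }
            )
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    df = df.sort_values(
        ["pdb id", "chain id", "residue number", "insertion code"],
        kind="mergesort",
    ).reset_index(drop=True)
    return df


def read_annotations(path) -> pd.DataFrame:
    """Read an annotation CSV written by :func:`annotate_table`."""
    df = pd.read_csv(path, keep_default_na=True)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise UndefinedResultError(
            f"annotation table is missing columns: {missing}"
        )
    df["insertion code"] = df["insertion code"].fillna("")
    return df


def table_mask(df: pd.DataFrame, selection: str) -> pd.Series:
    """Boolean mask for a named residue selection over an annotation table."""
    named = {
        "hydrophobe": df["is hydrophobe"],
        "vertex": df["is vertex"],
        "protrusion": df["is protrusion"],
        "exposed": df["is exposed"].eq(True),
        "all": pd.Series(True, index=df.index),
    }
    if selection in named:
        return named[selection].astype(bool)
    if selection.startswith("ss:"):
        return df["ss class"] == selection[3:]
    if selection.startswith("aa:"):
        return df["amino acid"] == selection[3:]
    raise KeyError(f"unknown table selection {selection!r}")


def weighted_count_from_table(
    df: pd.DataFrame, family_of: Mapping[str, str], mask: pd.Series
) -> float:
    """N̂_s recomputed from an annotation table (family-weighted)."""
    counts = (
        df.assign(_hit=mask.astype(float))
        .groupby("pdb id", sort=True)["_hit"]
        .sum()
    )
    families: dict[str, list[float]] = {}
    for model_id, value in counts.items():
        families.setdefault(family_of[model_id], []).append(float(value))
    return float(sum(np.mean(v) for v in families.values()))


def weighted_fraction_from_table(
    df: pd.DataFrame,
    family_of: Mapping[str, str],
    mask_s: pd.Series,
    mask_r: pd.Series,
) -> StatResult:
    """F̂_{s|r} recomputed from an annotation table."""
    n_sr = weighted_count_from_table(df, family_of, mask_s & mask_r)
    n_r = weighted_count_from_table(df, family_of, mask_r)
    if n_r == 0:
        raise UndefinedResultError("weighted reference count is zero")
    frac = n_sr / n_r
    se = float(np.sqrt(max(frac * (1 - frac), 0.0) / n_r))
    return StatResult(
        estimate=frac,
        lower=frac - Z95 * se,
        upper=frac + Z95 * se,
        successes=n_sr,
        failures=n_r - n_sr,
        estimator="F(table)",
    )


def compare_cohorts(
    cohort_a: Cohort,
    cohort_b: Cohort,
    comparisons: Sequence[tuple[str, Selection, Optional[Selection]]],
    include_pairs: bool = True,
) -> pd.DataFrame:
    """Estimate table for a two-cohort contrast.

    ``comparisons`` holds (label, s, r) triples: with a reference selection
    ``r`` the weighted fraction F̂_{s|r} is compared, with ``r=None`` the
    protein fraction Ê_s. One row per cohort estimate plus one ln R row per
    comparison; with ``include_pairs`` the co-insertion fraction
    F̂^pair_{both|one} contrast is appended.
    """
    rows = []

    def fraction(cohort, s, r):
        return (
            protein_fraction(cohort, s)
            if r is None
            else weighted_fraction(cohort, s, r)
        )

    def add(label, kind, cohort_name, stat):
        rows.append(
            {
                "comparison": label,
                "quantity": kind,
                "cohort": cohort_name,
                "estimate": stat.estimate,
                "ci lower": stat.lower,
                "ci upper": stat.upper,
                "weighted successes": stat.successes,
                "weighted failures": stat.failures,
                "undefined": stat.undefined,
                "infinite": stat.infinite,
            }
        )

    for label, s, r in comparisons:
        fa = fraction(cohort_a, s, r)
        fb = fraction(cohort_b, s, r)
        add(label, "fraction", cohort_a.name, fa)
        add(label, "fraction", cohort_b.name, fb)
        add(label, "lnR", f"{cohort_a.name} vs {cohort_b.name}", odds_ratio(fa, fb))
    if include_pairs:
        pa = pair_counts(cohort_a).f_both_given_one
        pb = pair_counts(cohort_b).f_both_given_one
        add("pair co-insertion", "fraction", cohort_a.name, pa)
        add("pair co-insertion", "fraction", cohort_b.name, pb)
        add(
            "pair co-insertion",
            "lnR",
            f"{cohort_a.name} vs {cohort_b.name}",
            odds_ratio(pa, pb),
        )
    return pd.DataFrame(rows)


def evaluate_sites(
    models: Iterable[ProteinModel],
    experimental_sites: Mapping[str, Sequence],
    config: Config = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Angle table comparing LIH predictions with experimental sites.

    One row per protein: the LIH angle (the 180-degree sentinel with
    ``no LIH`` set when the protein has no protruding hydrophobe) and the
    median control angle over single protrusions.
    """
    from .siteeval import evaluate_predictions

    rows = []
    for model in models:
        result = evaluate_predictions(
            model, experimental_sites[model.model_id], config
        )
        controls = list(result.control_angles.values())
        rows.append(
            {
                "pdb id": model.model_id,
                "LIH": str(result.lih_id) if result.lih_id else "",
                "angle": result.lih_angle,
                "no LIH": result.no_lih,
                "n controls": len(controls),
                "median control angle": (
                    float(np.median(controls)) if controls else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows).sort_values("pdb id").reset_index(drop=True)
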