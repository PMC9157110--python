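"""Targeted-lipidomics peak-area quantification.

The processing chain, applied per sample to long-format MRM peak areas:

1. multiply each raw transition area by the species' isotopic correction
   factor (icf) to undo the loss of signal to naturally occurring 13C;
2. sum icf-corrected areas over the mass transitions of a species;
3. total the species areas per lipid subclass, normalize the totals to the
   mean of the reference condition (3 h growth at room temperature) to give
   relative subclass abundances, and express each species as its relative
   proportion of the subclass total (mol% subclass profile).

On top of the profiles, species are grouped into saturation classes (0 / 1 /
>=2 double bonds in their fatty-acyl residues) and, for sphingolipids, into
carriers of positional modifications (C4-OH, d4, d8, acyl C2-OH, VLCFA).
Peak areas are treated as proportional to molar amounts after icf correction;
no per-species response factors are applied.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd

from .lipid_model import (
    C4_OH,
    D4,
    D8,
    UNRESOLVED,
    LipidParseError,
    LipidSpecies,
    RegistryError,
    SubclassRegistry,
    default_registry,
    formula_of,
    icf,
    parse_species,
    P13C_DEFAULT,
)

__all__ = [
    "CONDITIONS",
    "REFERENCE_CONDITION",
    "PEAK_COLUMNS",
    "MODIFICATION_FEATURES",
    "validate_peak_table",
    "validate_sample_sheet",
    "correct_areas",
    "sum_transitions",
    "subclass_abundance",
    "species_profile",
    "saturation_profile",
    "modification_occurrence",
]

#: The five temperature regimes of the growth experiment.
CONDITIONS = ("RT3", "RT6", "HS3+3", "HS3+6", "HSR")
REFERENCE_CONDITION = "RT3"

PEAK_COLUMNS = ["sample_id", "subclass", "species", "transition_id", "area"]

#: Sphingolipid modification features reported by modification_occurrence.
MODIFICATION_FEATURES = ("c4_hydroxyl", "d4_double_bond", "d8_double_bond",
                         "c2_acyl_hydroxyl", "vlcfa")

_SATURATION_CLASSES = ("saturated", "monounsaturated", "polyunsaturated")


def validate_peak_table(peaks: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PEAK_COLUMNS if c not in peaks.columns]
    if missing:
        raise ValueError(f"peak table missing columns {missing}")
    if (peaks["area"] < 0).any():
        bad = peaks.loc[peaks["area"] < 0].index[:5].tolist()
        raise ValueError(f"negative areas at rows {bad}")
    dup = peaks.duplicated(subset=["sample_id", "species", "transition_id"])
    if dup.any():
        key = peaks.loc[dup, ["sample_id", "species", "transition_id"]].iloc[0]
        raise ValueError(
            "duplicate (sample, species, transition) key: "
            f"{tuple(key)}"
        )
    return peaks


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    for col in ("sample_id", "condition"):
        if col not in sheet.columns:
            raise ValueError(f"sample sheet missing column {col!r}")
    if sheet["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample sheet")
    unknown = set(sheet["condition"]) - set(CONDITIONS)
    if unknown:
        raise ValueError(f"unknown conditions {sorted(unknown)}")
    return sheet


def _parser_cache(registry: SubclassRegistry):
    @lru_cache(maxsize=None)
    def parse(name: str) -> LipidSpecies:
        return parse_species(name, registry)

    return parse


# ---------------------------------------------------------------------------
# step 1: isotope correction
# ---------------------------------------------------------------------------


def correct_areas(
    peaks: pd.DataFrame,
    registry: Optional[SubclassRegistry] = None,
    p13c: float = P13C_DEFAULT,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multiply raw transition areas by the species' icf.

    Returns ``(corrected, rejects)``: species that fail to parse or resolve
    to a formula are collected in ``rejects`` (with the error message), never
    silently dropped.  The icf depends only on the species' carbon count, so
    identical species receive the same factor in every sample.
    """
    registry = registry or default_registry()
    validate_peak_table(peaks)
    parse = _parser_cache(registry)

    factors: dict[str, float] = {}
    errors: dict[str, str] = {}
    for name in peaks["species"].unique():
        try:
            factors[name] = icf(formula_of(parse(name), registry), p13c)
        except (LipidParseError, RegistryError, ValueError) as exc:
            errors[name] = str(exc)

    ok = peaks["species"].isin(factors)
    rejects = peaks.loc[~ok].copy()
    if not rejects.empty:
        rejects["error"] = rejects["species"].map(errors)
    corrected = peaks.loc[ok].copy()
    corrected["icf"] = corrected["species"].map(factors)
    corrected["corrected_area"] = corrected["area"] * corrected["icf"]
    return corrected, rejects


# ---------------------------------------------------------------------------
# step 2: transition summation
# ---------------------------------------------------------------------------


def sum_transitions(corrected: pd.DataFrame) -> pd.DataFrame:
    """Sum icf-corrected areas over the mass transitions of each species."""
    col = "corrected_area" if "corrected_area" in corrected.columns else "area"
    out = (
        corrected.groupby(["sample_id", "subclass", "species"], as_index=False)[col]
        .sum()
        .rename(columns={col: "area"})
    )
    return out


# ---------------------------------------------------------------------------
# step 3a: subclass totals and reference-normalized abundances
# ---------------------------------------------------------------------------


def subclass_abundance(
    species_areas: pd.DataFrame,
    sheet: pd.DataFrame,
    reference_condition: str = REFERENCE_CONDITION,
) -> pd.DataFrame:
    """Per-sample subclass totals, normalized to the reference-condition mean.

    ``normalized = total / mean(total over reference samples)``, so the mean
    normalized abundance of the reference condition is 1 by construction.
    Subclasses whose reference mean is 0 get NaN and are listed in
    ``result.attrs["flagged"]``.
    """
    validate_sample_sheet(sheet)
    if reference_condition not in set(sheet["condition"]):
        raise ValueError(
            f"reference condition {reference_condition!r} absent from sheet"
        )
    totals = (
        species_areas.groupby(["sample_id", "subclass"], as_index=False)["area"]
        .sum()
        .rename(columns={"area": "total_area"})
    )
    totals = totals.merge(
        sheet[["sample_id", "condition"]], on="sample_id", how="left"
    )
    ref = (
        totals.loc[totals["condition"] == reference_condition]
        .groupby("subclass")["total_area"]
        .mean()
    )
    totals["reference_mean"] = totals["subclass"].map(ref)
    with np.errstate(divide="ignore", invalid="ignore"):
        totals["normalized"] = np.where(
            totals["reference_mean"] > 0,
            totals["total_area"] / totals["reference_mean"],
            np.nan,
        )
    flagged = sorted(ref.index[~(ref > 0)].tolist())
    totals.attrs["flagged"] = flagged
    return totals


# ---------------------------------------------------------------------------
# step 3b: mol% subclass profiles and the major-species mask
# ---------------------------------------------------------------------------


def species_profile(
    species_areas: pd.DataFrame,
    sheet: Optional[pd.DataFrame] = None,
    major_threshold: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative subclass profiles: each species as mol% of its subclass total.

    Returns ``(profile, major)``.  ``major`` marks species whose
    condition-mean mol% strictly exceeds ``major_threshold`` percent in at
    least one condition (the display rule for profile figures); without a
    sample sheet the overall mean is used.  Samples with a zero subclass
    total get NaN mol% and are listed in ``profile.attrs["flagged"]``.
    """
    profile = species_areas.copy()
    totals = profile.groupby(["sample_id", "subclass"])["area"].transform("sum")
    with np.errstate(divide="ignore", invalid="ignore"):
        profile["mol_percent"] = np.where(
            totals > 0, 100.0 * profile["area"] / totals, np.nan
        )
    zero = profile.loc[totals <= 0, ["sample_id", "subclass"]].drop_duplicates()
    profile.attrs["flagged"] = list(map(tuple, zero.to_numpy()))

    if sheet is not None:
        validate_sample_sheet(sheet)
        with_cond = profile.merge(
            sheet[["sample_id", "condition"]], on="sample_id", how="left"
        )
        cond_means = (
            with_cond.groupby(["subclass", "species", "condition"])["mol_percent"]
            .mean()
            .reset_index()
        )
        best = cond_means.groupby(["subclass", "species"], as_index=False)[
            "mol_percent"
        ].max()
    else:
        best = profile.groupby(["subclass", "species"], as_index=False)[
            "mol_percent"
        ].mean()
    best["is_major"] = best["mol_percent"] > major_threshold  # strict >
    major = best[["subclass", "species", "is_major"]]
    return profile, major


# ---------------------------------------------------------------------------
# saturation classes
# ---------------------------------------------------------------------------


def saturation_profile(
    species_areas: pd.DataFrame,
    registry: Optional[SubclassRegistry] = None,
) -> pd.DataFrame:
    """Molar proportions of saturated / mono- / polyunsaturated species.

    Classification is by the total double-bond count of the fatty-acyl
    residues (0, 1, >=2).  Fractions sum to 1 per (sample, subclass).
    """
    registry = registry or default_registry()
    parse = _parser_cache(registry)

    work = species_areas.copy()
    work["sat_class"] = [
        _SATURATION_CLASSES[min(parse(name).total_double_bonds, 2)]
        for name in work["species"]
    ]
    by_class = (
        work.groupby(["sample_id", "subclass", "sat_class"])["area"]
        .sum()
        .unstack("sat_class", fill_value=0.0)
        .reindex(columns=_SATURATION_CLASSES, fill_value=0.0)
    )
    totals = by_class.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fractions = by_class.div(totals.where(totals > 0), axis=0)
    fractions = fractions.reset_index()
    fractions.attrs["flagged"] = [
        tuple(row)
        for row in fractions.loc[
            totals.reset_index(drop=True) <= 0, ["sample_id", "subclass"]
        ].to_numpy()
    ]
    return fractions


# ---------------------------------------------------------------------------
# sphingolipid modification occurrence
# ---------------------------------------------------------------------------


def _feature_state(species: LipidSpecies, feature: str) -> Optional[bool]:
    """True/False if the feature is resolved for the species, None otherwise."""
    base = species.sphingoid_base
    acyls = species.acyl_chains
    if feature == "vlcfa":
        return any(a.is_vlcfa for a in acyls)
    if feature == "c2_acyl_hydroxyl":
        hydroxylated = [a for a in acyls if a.hydroxyls]
        if not hydroxylated:
            return False
        states = [a.c2_hydroxyl for a in hydroxylated]
        if any(s is True for s in states):
            return True
        if all(s is False for s in states):
            return False
        return None
    if base is None:
        return False
    unresolved = UNRESOLVED in base.positional_features
    if feature == "c4_hydroxyl":
        if base.oxygens < 3:
            return False  # no third hydroxyl to place
        return None if unresolved else (C4_OH in base.positional_features)
    if feature == "d4_double_bond":
        if base.double_bonds == 0:
            return False
        return None if unresolved else (D4 in base.positional_features)
    if feature == "d8_double_bond":
        if base.double_bonds == 0:
            return False
        return None if unresolved else (D8 in base.positional_features)
    raise ValueError(f"unknown feature {feature!r}")


def modification_occurrence(
    species_areas: pd.DataFrame,
    registry: Optional[SubclassRegistry] = None,
    weighting: str = "abundance",
) -> pd.DataFrame:
    """Percentage-wise occurrence of sphingolipid modifications.

    For each (sample, subclass) and each feature the occurrence is the share
    of the subclass carried by species bearing the feature — abundance-
    weighted by default, or the share of detected species counts with
    ``weighting="count"``.  Species whose feature state cannot be resolved
    are excluded from the numerator and reported in ``unresolved_fraction``.

    Returns a tidy frame: sample_id, subclass, feature, fraction,
    unresolved_fraction.
    """
    if weighting not in ("abundance", "count"):
        raise ValueError("weighting must be 'abundance' or 'count'")
    registry = registry or default_registry()
    parse = _parser_cache(registry)

    work = species_areas.copy()
    if weighting == "count":
        work["weight"] = (work["area"] > 0).astype(float)
    else:
        work["weight"] = work["area"].astype(float)

    records = []
    for (sample, subclass), grp in work.groupby(["sample_id", "subclass"]):
        total = grp["weight"].sum()
        for feature in MODIFICATION_FEATURES:
            states = [_feature_state(parse(n), feature) for n in grp["species"]]
            carried = sum(
                w for w, s in zip(grp["weight"], states) if s is True
            )
            unresolved = sum(
                w for w, s in zip(grp["weight"], states) if s is None
            )
            records.append(
                {
                    "sample_id": sample,
                    "subclass": subclass,
                    "feature": feature,
                    "fraction": carried / total if total > 0 else np.nan,
                    "unresolved_fraction": unresolved / total
                    if total > 0
                    else np.nan,
                }
            )
    return pd.DataFrame.from_records(records)
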