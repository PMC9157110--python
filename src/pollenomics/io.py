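"""Table readers/writers, run configuration and the pipeline orchestrator.

All tabular inputs and outputs are tidy TSV with a header row, decimal
point, UTF-8 and the missing-value token ``NA``; output files carry
provenance comment lines (``# key: value``) recording package version,
config hash and seed.  Counts matrices are wide (gene × sample).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .absolute_quant import metabolite_relative, tg_absolute
from .lipid_model import P13C_DEFAULT, default_registry
from .quantify import (
    PEAK_COLUMNS,
    REFERENCE_CONDITION,
    correct_areas,
    modification_occurrence,
    saturation_profile,
    species_profile,
    subclass_abundance,
    sum_transitions,
    validate_peak_table,
    validate_sample_sheet,
)
from .stats import ALPHA_DEFAULT, group_stats_table

__all__ = [
    "RunConfig",
    "read_peak_table",
    "read_sample_sheet",
    "read_fame_table",
    "read_metabolite_table",
    "read_counts",
    "read_go_map",
    "read_gene_lengths",
    "write_table",
    "read_table",
    "write_target_list",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """Thresholds and flags steering a pipeline run."""

    reference_condition: str = REFERENCE_CONDITION
    alpha: float = ALPHA_DEFAULT
    major_threshold_percent: float = 1.0
    p13c: float = P13C_DEFAULT
    modification_weighting: str = "abundance"
    welch: bool = False
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.major_threshold_percent <= 0 or not 0 < self.alpha < 1:
            raise ValueError("thresholds must be positive (alpha in (0,1))")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", na_values=["NA"], **kwargs
    )


def read_table(path) -> pd.DataFrame:
    """Read a provenance-headered tidy TSV."""
    return _read_tsv(path)


def write_table(df: pd.DataFrame, path, provenance: Optional[dict] = None) -> None:
    """Write a tidy TSV with ``# key: value`` provenance comment lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# pollenomics: {__version__}\n")
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_peak_table(path) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df["area"].isna().any():
        rows = df.index[df["area"].isna()].tolist()[:5]
        raise ValueError(f"{path}: non-numeric/missing areas at rows {rows}")
    return validate_peak_table(df)


def read_sample_sheet(path) -> pd.DataFrame:
    return validate_sample_sheet(_read_tsv(path))


def read_fame_table(path) -> pd.DataFrame:
    df = _read_tsv(path)
    for col in ("sample_id", "fatty_acid", "area"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df


def read_metabolite_table(path) -> pd.DataFrame:
    df = _read_tsv(path)
    for col in ("sample_id", "analyte", "area"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df


def read_counts(path) -> pd.DataFrame:
    """Wide gene × sample counts TSV; first column is the gene id."""
    df = _read_tsv(path, index_col=0)
    if (df.sum(axis=0) <= 0).any():
        bad = df.columns[df.sum(axis=0) <= 0].tolist()
        raise ValueError(f"{path}: zero-sum libraries {bad}")
    return df


def read_go_map(path) -> pd.DataFrame:
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: GO map needs two columns (gene, go_id)")
    df.columns = ["gene", "go_id"] + list(df.columns[2:])
    return df[["gene", "go_id"]]


def read_gene_lengths(path) -> pd.Series:
    df = _read_tsv(path, index_col=0)
    s = df.iloc[:, 0].astype(float)
    if (s <= 0).any():
        raise ValueError(f"{path}: gene lengths must be > 0")
    return s


def write_target_list(target_list, path, registry=None) -> None:
    """Emit a TSV target list with formulas and icfs."""
    from .lipid_model import formula_of, icf

    registry = registry or default_registry()
    rows = []
    for sp in target_list.species:
        formula = formula_of(sp, registry)
        rows.append(
            {
                "subclass": target_list.subclass,
                "display_name": sp.display_name,
                "chains": "/".join(
                    c.display() for c in sp.chains
                ) if sp.chains else "",
                "formula": str(formula),
                "icf": icf(formula),
            }
        )
    write_table(
        pd.DataFrame(rows), path, provenance=dict(target_list.provenance)
    )


# ---------------------------------------------------------------------------
# orchestrator
# ---------------------------------------------------------------------------


def run_pipeline(
    peaks: pd.DataFrame,
    sheet: pd.DataFrame,
    config: Optional[RunConfig] = None,
    out_dir=None,
) -> dict:
    """Run correct → sum → abundance → profiles → saturation → modifications
    → statistics and return (optionally write) all result tables.

    Returns a dict of DataFrames keyed by stage name; with ``out_dir`` each
    table is also written as a provenance-headered TSV.
    """
    config = config or RunConfig()
    registry = default_registry()
    validate_sample_sheet(sheet)

    corrected, rejects = correct_areas(peaks, registry, config.p13c)
    species_areas = sum_transitions(corrected)
    abundance = subclass_abundance(
        species_areas, sheet, config.reference_condition
    )
    profile, major = species_profile(
        species_areas, sheet, config.major_threshold_percent
    )
    saturation = saturation_profile(species_areas, registry)
    sphingo = species_areas.loc[
        species_areas["subclass"].map(
            lambda s: s in registry and registry.get(s).category == "sphingolipid"
        )
    ]
    modifications = (
        modification_occurrence(sphingo, registry, config.modification_weighting)
        if not sphingo.empty
        else pd.DataFrame(
            columns=["sample_id", "subclass", "feature", "fraction",
                     "unresolved_fraction"]
        )
    )
    abundance_stats = group_stats_table(
        abundance, sheet, ["subclass"], "normalized", alpha=config.alpha
    )
    saturation_long = saturation.melt(
        id_vars=["sample_id", "subclass"],
        var_name="sat_class",
        value_name="fraction",
    )
    saturation_stats = group_stats_table(
        saturation_long, sheet, ["subclass", "sat_class"], "fraction",
        alpha=config.alpha,
    )

    results = {
        "corrected": corrected,
        "rejects": rejects,
        "species_areas": species_areas,
        "subclass_abundance": abundance,
        "species_profile": profile,
        "major_species": major,
        "saturation": saturation,
        "modifications": modifications,
        "abundance_stats": abundance_stats,
        "saturation_stats": saturation_stats,
    }
    if out_dir is not None:
        provenance = {"config_hash": config.hash(), "seed": config.seed}
        out_dir = Path(out_dir)
        for name, df in results.items():
            write_table(df, out_dir / f"{name}.tsv", provenance)
    return results


def run_absolute_quant(
    fames: pd.DataFrame,
    metabolites: pd.DataFrame,
    sheet: pd.DataFrame,
    config: Optional[RunConfig] = None,
    out_dir=None,
) -> dict:
    """Internal-standard branch: TG µg/mg and metabolite folds."""
    config = config or RunConfig()
    tg_per_sample, tg_per_fa = tg_absolute(fames)
    met = metabolite_relative(
        metabolites, sheet, reference_condition=config.reference_condition
    )
    results = {
        "tg_absolute": tg_per_sample,
        "tg_fatty_acids": tg_per_fa,
        "metabolite_folds": met,
    }
    if out_dir is not None:
        provenance = {"config_hash": config.hash(), "seed": config.seed}
        out_dir = Path(out_dir)
        for name, df in results.items():
            write_table(df, out_dir / f"{name}.tsv", provenance)
    return results
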