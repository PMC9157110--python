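"""Internal-standard absolute quantification.

Triacylglycerol (TG) is quantified from GC-FID fatty-acid methyl ester
(FAME) peak areas against a spiked triheptadecanoate internal standard
(0.05 mg, appearing as the 17:0 FAME).  FID response is assumed
mass-proportional and equal across FAMEs, so

    mass_FA_i [mg] = area_i / area_IS * is_mass_mg

and the TG amount is reported as the sum of FA masses per mg dry pollen
(µg/mg), together with each fatty acid's relative contribution.

Hydrophilic metabolites measured by GC–MS are normalized to an allo-inositol
internal standard (0.0125 mg) per sample and folded to the mean of the
reference condition.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .quantify import REFERENCE_CONDITION, validate_sample_sheet

__all__ = [
    "IS_FATTY_ACID",
    "IS_MASS_TG_MG",
    "IS_METABOLITE",
    "IS_MASS_METABOLITE_MG",
    "tg_absolute",
    "metabolite_relative",
]

IS_FATTY_ACID = "17:0"          # triheptadecanoate appears as the 17:0 FAME
IS_MASS_TG_MG = 0.05
IS_METABOLITE = "allo-inositol"
IS_MASS_METABOLITE_MG = 0.0125


def tg_absolute(
    fames: pd.DataFrame,
    is_fatty_acid: str = IS_FATTY_ACID,
    is_mass_mg: float = IS_MASS_TG_MG,
    pollen_dry_mass_mg: float = 20.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Absolute TG amount (µg per mg dry pollen) from FAME peak areas.

    ``fames`` is long format with columns sample_id, fatty_acid, area.
    Returns ``(per_sample, per_fa)``: per-sample TG totals and per-fatty-acid
    masses with their relative contribution to the TG amount.  The internal
    standard is excluded from the analytes.  Rows with negative areas are
    rejected; a sample with a zero/absent IS area raises.
    """
    for col in ("sample_id", "fatty_acid", "area"):
        if col not in fames.columns:
            raise ValueError(f"FAME table missing column {col!r}")
    if pollen_dry_mass_mg <= 0:
        raise ValueError("pollen_dry_mass_mg must be > 0")
    work = fames.loc[fames["area"] >= 0].copy()

    records = []
    for sample, grp in work.groupby("sample_id"):
        is_rows = grp.loc[grp["fatty_acid"] == is_fatty_acid]
        if is_rows.empty or not (is_rows["area"] > 0).all():
            raise ValueError(
                f"sample {sample!r}: internal standard {is_fatty_acid} "
                "missing or has zero area"
            )
        area_is = float(is_rows["area"].sum())
        analytes = grp.loc[grp["fatty_acid"] != is_fatty_acid]
        for _, row in analytes.iterrows():
            records.append(
                {
                    "sample_id": sample,
                    "fatty_acid": row["fatty_acid"],
                    "mass_mg": row["area"] / area_is * is_mass_mg,
                }
            )
    per_fa = pd.DataFrame.from_records(
        records, columns=["sample_id", "fatty_acid", "mass_mg"]
    )
    totals = per_fa.groupby("sample_id")["mass_mg"].transform("sum")
    with np.errstate(divide="ignore", invalid="ignore"):
        per_fa["contribution"] = np.where(
            totals > 0, per_fa["mass_mg"] / totals, np.nan
        )
    per_sample = (
        per_fa.groupby("sample_id", as_index=False)["mass_mg"]
        .sum()
        .rename(columns={"mass_mg": "tg_mass_mg"})
    )
    # mg total FA -> µg per mg dry pollen
    per_sample["tg_ug_per_mg"] = (
        per_sample["tg_mass_mg"] / pollen_dry_mass_mg * 1000.0
    )
    return per_sample, per_fa


def metabolite_relative(
    metabolites: pd.DataFrame,
    sheet: pd.DataFrame,
    is_analyte: str = IS_METABOLITE,
    reference_condition: str = REFERENCE_CONDITION,
    dilution_column: Optional[str] = "dilution",
) -> pd.DataFrame:
    """IS-normalized metabolite responses folded to the reference mean.

    ``metabolites`` is long format with columns sample_id, analyte, area and
    an optional per-row dilution factor column (sucrose is measured in
    diluted runs; its factor undoes the dilution).  Samples lacking the
    internal standard are excluded and listed in
    ``result.attrs["excluded_samples"]``.
    """
    for col in ("sample_id", "analyte", "area"):
        if col not in metabolites.columns:
            raise ValueError(f"metabolite table missing column {col!r}")
    validate_sample_sheet(sheet)

    work = metabolites.copy()
    if dilution_column and dilution_column in work.columns:
        work["area"] = work["area"] * work[dilution_column]

    is_area = (
        work.loc[work["analyte"] == is_analyte]
        .groupby("sample_id")["area"]
        .sum()
    )
    valid = is_area[is_area > 0]
    excluded = sorted(set(work["sample_id"]) - set(valid.index))

    analytes = work.loc[
        (work["analyte"] != is_analyte) & work["sample_id"].isin(valid.index)
    ].copy()
    analytes["response"] = analytes["area"] / analytes["sample_id"].map(valid)

    analytes = analytes.merge(
        sheet[["sample_id", "condition"]], on="sample_id", how="left"
    )
    ref = (
        analytes.loc[analytes["condition"] == reference_condition]
        .groupby("analyte")["response"]
        .mean()
    )
    analytes["reference_mean"] = analytes["analyte"].map(ref)
    with np.errstate(divide="ignore", invalid="ignore"):
        analytes["fold"] = np.where(
            analytes["reference_mean"] > 0,
            analytes["response"] / analytes["reference_mean"],
            np.nan,
        )
    out = analytes[
        ["sample_id", "condition", "analyte", "response", "fold"]
    ].reset_index(drop=True)
    out.attrs["excluded_samples"] = excluded
    return out
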