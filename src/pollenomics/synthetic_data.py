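"""Synthetic study inputs with recorded ground truth.

Emulates the measurement design of the heat-stress pollen-tube experiment:
five temperature regimes (RT3, RT6, HS3+3, HS3+6, HSR) with 5 replicates
for lipidomics / FAME / metabolite tables and three regimes (RT3, RT6,
HS3+3) with 3 replicates for the counts matrix.  Replicate noise is
multiplicative lognormal (default CV 0.15); condition effects are injected
as

* subclass abundance folds relative to the RT3 baseline (defaults follow
  the reported magnitudes: SPBP 5.8x HS3+3 vs RT6, HexCer +30%, TG 2x,
  sterylglycosides up, sterol esters down),
* saturation shifts that move subclass mass from polyunsaturated to
  saturated species while preserving the subclass total,
* sphingolipid modification shifts that move mass from d4-desaturated to
  C4-hydroxylated species,
* metabolite folds (sucrose 2x, sedoheptulose 3x under HS),
* a fraction of differentially expressed genes with a fixed log2 effect,
  with the first GO terms enriched in them.

Raw MRM areas are emitted on the instrument scale: the intended (truth)
species abundance is divided by the species' isotopic correction factor and
split over 1–3 mass transitions, so the quantification chain recovers the
truth exactly in the noise-free limit.  All generators are deterministic
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .lipid_model import default_registry, formula_of, icf, parse_species
from .quantify import CONDITIONS

__all__ = [
    "TruthConfig",
    "COUNT_CONDITIONS",
    "DEFAULT_SPECIES_WEIGHTS",
    "DEFAULT_SUBCLASS_TOTALS",
    "DEFAULT_SUBCLASS_FOLDS",
    "make_sample_sheet",
    "gen_lipidome",
    "gen_counts",
    "gen_fame_and_metabolites",
]

COUNT_CONDITIONS = ("RT3", "RT6", "HS3+3")

# Baseline species weights per subclass (fractions of the subclass total).
DEFAULT_SPECIES_WEIGHTS: dict[str, dict[str, float]] = {
    "PC": {
        "PC 16:0_16:0": 0.12,
        "PC 16:0_18:0": 0.08,
        "PC 16:0_18:1": 0.20,
        "PC 18:0_18:1": 0.10,
        "PC 16:0_18:2": 0.20,
        "PC 18:1_18:2": 0.15,
        "PC 18:2_18:3": 0.10,
        "PC 16:0_18:3": 0.05,
    },
    "MGDG": {
        "MGDG 16:0_16:0": 0.15,
        "MGDG 16:0_18:1": 0.20,
        "MGDG 16:0_18:2": 0.25,
        "MGDG 18:2_18:3": 0.30,
        "MGDG 16:0_18:3": 0.10,
    },
    "DG": {
        "DG 16:0_18:1": 0.40,
        "DG 16:0_18:2": 0.35,
        "DG 18:1_18:2": 0.25,
    },
    "TG": {
        "TG 16:0_18:1_18:2": 0.40,
        "TG 16:0_16:0_18:1": 0.25,
        "TG 18:1_18:2_18:2": 0.20,
        "TG 16:0_18:2_18:3": 0.15,
    },
    "PS": {
        "PS 16:0_18:1": 0.40,
        "PS 16:0_18:2": 0.35,
        "PS 18:0_18:0": 0.25,
    },
    "SPBP": {
        "SPBP 18:1;O2(d4)": 0.60,
        "SPBP 18:0;O3(4OH)": 0.25,
        "SPBP 18:1;O2(d8)": 0.15,
    },
    "HexCer": {
        "HexCer 18:1;O2(d4)/16:0": 0.35,
        "HexCer 18:2;O2(d4,d8)/24:0;O(2OH)": 0.30,
        "HexCer 18:1;O2(d4)/24:1": 0.25,
        "HexCer 18:0;O3(4OH)/24:0": 0.08,
        "HexCer 18:2;O2/26:0": 0.02,
    },
    "SG": {
        "SG sitosterol": 0.50,
        "SG M412": 0.30,
        "SG cycloeucalenol": 0.20,
    },
    "SE": {
        "SE sitosterol/18:2": 0.60,
        "SE M398/18:1": 0.40,
    },
}

# Baseline subclass totals (arbitrary corrected-area units at RT3).
DEFAULT_SUBCLASS_TOTALS: dict[str, float] = {
    "PC": 1.0e6, "MGDG": 3.0e5, "DG": 2.0e5, "TG": 5.0e5, "PS": 1.0e5,
    "SPBP": 2.0e4, "HexCer": 8.0e4, "SG": 5.0e4, "SE": 6.0e4,
}

# Condition folds relative to RT3.  SPBP: HS3+3/RT6 = 8.7/1.5 = 5.8 and
# HS3+6/HSR = 11.0/3.93 = 2.8; HexCer: 2.6/2.0 = 1.30 (+30%);
# TG: HS3+3/RT6 = 2.0; SG: +84% vs RT6; SE decreases under HS.
DEFAULT_SUBCLASS_FOLDS: dict[str, dict[str, float]] = {
    "PC":     {"RT3": 1.0, "RT6": 1.8, "HS3+3": 1.8, "HS3+6": 2.6, "HSR": 2.8},
    "MGDG":   {"RT3": 1.0, "RT6": 1.6, "HS3+3": 2.0, "HS3+6": 2.6, "HSR": 2.6},
    "DG":     {"RT3": 1.0, "RT6": 1.4, "HS3+3": 1.5, "HS3+6": 1.8, "HSR": 1.8},
    "TG":     {"RT3": 1.0, "RT6": 1.5, "HS3+3": 3.0, "HS3+6": 4.5, "HSR": 4.0},
    "PS":     {"RT3": 1.0, "RT6": 1.7, "HS3+3": 2.9, "HS3+6": 4.3, "HSR": 3.9},
    "SPBP":   {"RT3": 1.0, "RT6": 1.5, "HS3+3": 8.7, "HS3+6": 11.0, "HSR": 3.93},
    "HexCer": {"RT3": 1.0, "RT6": 2.0, "HS3+3": 2.6, "HS3+6": 3.4, "HSR": 2.6},
    "SG":     {"RT3": 1.0, "RT6": 1.3, "HS3+3": 2.39, "HS3+6": 2.8, "HSR": 2.6},
    "SE":     {"RT3": 1.0, "RT6": 1.2, "HS3+3": 0.9, "HS3+6": 0.8, "HSR": 1.0},
}

# Saturation shift: fraction of subclass mass moved from polyunsaturated to
# saturated species, per condition (0.15 = +15 percentage points saturated).
DEFAULT_SATURATION_SHIFT: dict[str, dict[str, float]] = {
    "PC":   {"HS3+3": 0.15, "HS3+6": 0.15, "HSR": 0.05},
    "MGDG": {"HS3+3": 0.15, "HS3+6": 0.18, "HSR": 0.15},
}

# Modification shift: fraction of subclass mass moved from d4-carrying to
# C4-OH-carrying species (0.025 on a 0.08 baseline = +31% C4-OH occurrence).
DEFAULT_MODIFICATION_SHIFT: dict[str, dict[str, float]] = {
    "HexCer": {"HS3+3": 0.025, "HS3+6": 0.025, "HSR": 0.01},
}

# Metabolite baseline IS-normalized responses and condition folds vs RT3.
DEFAULT_METABOLITE_BASE: dict[str, float] = {
    "sucrose": 5.0, "sedoheptulose": 0.5, "glucose": 2.0, "fructose": 1.8,
    "gaba": 0.3, "proline": 1.0, "pipecolate": 0.2,
}
DEFAULT_METABOLITE_FOLDS: dict[str, dict[str, float]] = {
    "sucrose":       {"RT6": 1.2, "HS3+3": 2.0, "HS3+6": 2.2, "HSR": 1.8},
    "sedoheptulose": {"RT6": 1.3, "HS3+3": 3.0, "HS3+6": 3.2, "HSR": 2.5},
    "glucose":       {"RT6": 1.3, "HS3+3": 1.4, "HS3+6": 1.6, "HSR": 1.6},
    "fructose":      {"RT6": 1.2, "HS3+3": 1.3, "HS3+6": 1.5, "HSR": 1.5},
    "gaba":          {"RT6": 1.4, "HS3+3": 2.2, "HS3+6": 2.6, "HSR": 2.0},
    "proline":       {"RT6": 2.5, "HS3+3": 2.6, "HS3+6": 3.5, "HSR": 3.4},
    "pipecolate":    {"RT6": 1.5, "HS3+3": 2.5, "HS3+6": 3.0, "HSR": 2.4},
}

# GC-FID FAME design: fatty-acid composition of the TG pool.
DEFAULT_FA_COMPOSITION: dict[str, float] = {
    "16:0": 0.30, "18:1": 0.25, "18:2": 0.30, "18:3": 0.15,
}

_TRANSITION_SPLITS = {1: (1.0,), 2: (0.6, 0.4), 3: (0.5, 0.3, 0.2)}


@dataclass
class TruthConfig:
    """Ground-truth configuration for all generators."""

    seed: int = 0
    conditions: tuple = CONDITIONS
    replicates: int = 5
    cv: float = 0.15
    species_weights: Mapping = field(
        default_factory=lambda: DEFAULT_SPECIES_WEIGHTS
    )
    subclass_totals: Mapping = field(
        default_factory=lambda: DEFAULT_SUBCLASS_TOTALS
    )
    subclass_folds: Mapping = field(
        default_factory=lambda: DEFAULT_SUBCLASS_FOLDS
    )
    saturation_shift: Mapping = field(
        default_factory=lambda: DEFAULT_SATURATION_SHIFT
    )
    modification_shift: Mapping = field(
        default_factory=lambda: DEFAULT_MODIFICATION_SHIFT
    )
    metabolite_base: Mapping = field(
        default_factory=lambda: DEFAULT_METABOLITE_BASE
    )
    metabolite_folds: Mapping = field(
        default_factory=lambda: DEFAULT_METABOLITE_FOLDS
    )
    fa_composition: Mapping = field(
        default_factory=lambda: DEFAULT_FA_COMPOSITION
    )
    tg_base_ug_per_mg: float = 1.2
    pollen_dry_mass_mg: float = 20.0
    # counts design
    count_conditions: tuple = COUNT_CONDITIONS
    count_replicates: int = 3
    n_genes: int = 2000
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    de_up_share: float = 0.65
    count_dispersion: float = 0.1
    n_go_terms: int = 40

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        for sc, folds in self.subclass_folds.items():
            if any(f <= 0 for f in folds.values()):
                raise ValueError(f"non-positive fold for {sc}")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must lie in [0, 1]")


def _sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def _noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 lognormal multiplicative noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    s = _sigma(cv)
    return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=size)


def make_sample_sheet(
    conditions=CONDITIONS, replicates: int = 5, prefix: str = "S"
) -> pd.DataFrame:
    rows = [
        {
            "sample_id": f"{prefix}_{cond}_{rep}",
            "condition": cond,
            "replicate": rep,
        }
        for cond in conditions
        for rep in range(1, replicates + 1)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# lipidome
# ---------------------------------------------------------------------------


def _shift_weights(
    weights: dict[str, float],
    donors: list[str],
    receivers: list[str],
    delta: float,
    what: str,
) -> dict[str, float]:
    """Move ``delta`` of total mass from donor to receiver species pro rata."""
    if delta == 0:
        return dict(weights)
    donor_mass = sum(weights[s] for s in donors)
    recv_mass = sum(weights[s] for s in receivers)
    if donor_mass - delta < 0 or not receivers:
        raise ValueError(
            f"infeasible {what} shift of {delta}: donor mass {donor_mass}"
        )
    out = dict(weights)
    donor_scale = (donor_mass - delta) / donor_mass if donor_mass else 0.0
    recv_scale = (recv_mass + delta) / recv_mass if recv_mass else None
    for s in donors:
        out[s] = weights[s] * donor_scale
    if recv_scale is None:
        raise ValueError(f"no receiver species for {what} shift")
    for s in receivers:
        out[s] = weights[s] * recv_scale
    return out


def _condition_weights(cfg: TruthConfig, subclass: str, condition: str):
    """Species weights for a subclass under a condition, shifts applied."""
    weights = dict(cfg.species_weights[subclass])
    parsed = {name: parse_species(name) for name in weights}

    delta_sat = cfg.saturation_shift.get(subclass, {}).get(condition, 0.0)
    if delta_sat:
        sat = [n for n, sp in parsed.items() if sp.total_double_bonds == 0]
        poly = [n for n, sp in parsed.items() if sp.total_double_bonds >= 2]
        weights = _shift_weights(weights, poly, sat, delta_sat, "saturation")

    delta_mod = cfg.modification_shift.get(subclass, {}).get(condition, 0.0)
    if delta_mod:
        d4 = [
            n
            for n, sp in parsed.items()
            if sp.sphingoid_base and "d4" in sp.sphingoid_base.positional_features
        ]
        c4 = [
            n
            for n, sp in parsed.items()
            if sp.sphingoid_base and "4OH" in sp.sphingoid_base.positional_features
        ]
        weights = _shift_weights(weights, d4, c4, delta_mod, "modification")
    return weights


def gen_lipidome(
    cfg: Optional[TruthConfig] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate a long-format MRM peak table, sample sheet and truth record."""
    cfg = cfg or TruthConfig()
    rng = np.random.default_rng([cfg.seed, 1])
    registry = default_registry()
    sheet = make_sample_sheet(cfg.conditions, cfg.replicates, prefix="L")

    factors = {}
    for weights in cfg.species_weights.values():
        for name in weights:
            sp = parse_species(name, registry)
            factors[name] = icf(formula_of(sp, registry))

    rows = []
    for subclass, base_weights in cfg.species_weights.items():
        base_total = cfg.subclass_totals[subclass]
        folds = cfg.subclass_folds.get(subclass, {})
        species_names = list(base_weights)
        for _, sample in sheet.iterrows():
            cond = sample["condition"]
            weights = _condition_weights(cfg, subclass, cond)
            total = base_total * folds.get(cond, 1.0)
            noise = _noise(rng, cfg.cv, len(species_names))
            for name, eps in zip(species_names, noise):
                corrected = total * weights[name] * eps
                raw = corrected / factors[name]
                n_trans = (species_names.index(name) % 3) + 1
                for t_idx, frac in enumerate(_TRANSITION_SPLITS[n_trans], 1):
                    rows.append(
                        {
                            "sample_id": sample["sample_id"],
                            "subclass": subclass,
                            "species": name,
                            "transition_id": f"T{t_idx}",
                            "area": raw * frac,
                        }
                    )
    peaks = pd.DataFrame(rows, columns=[
        "sample_id", "subclass", "species", "transition_id", "area"
    ])
    truth = {
        "seed": cfg.seed,
        "cv": cfg.cv,
        "subclass_folds": {k: dict(v) for k, v in cfg.subclass_folds.items()},
        "saturation_shift": {
            k: dict(v) for k, v in cfg.saturation_shift.items()
        },
        "modification_shift": {
            k: dict(v) for k, v in cfg.modification_shift.items()
        },
        "species_weights": {
            k: dict(v) for k, v in cfg.species_weights.items()
        },
    }
    return peaks, sheet, truth


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def gen_counts(
    cfg: Optional[TruthConfig] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.DataFrame]:
    """Generate a counts matrix, GO map, gene lengths and DE truth table.

    Counts are negative binomial with gene-specific lognormal means and a
    common dispersion; with ``count_dispersion=0`` the expected (continuous)
    means are returned unsampled, which is the noise-free mode.  DE genes
    are shifted by ``2**de_log2fc`` in the HS3+3 condition; the first five
    GO terms are drawn from upregulated DE genes (enriched), the rest at
    random.
    """
    cfg = cfg or TruthConfig()
    rng = np.random.default_rng([cfg.seed, 2])
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    sheet = make_sample_sheet(cfg.count_conditions, cfg.count_replicates, "C")

    base_mean = rng.lognormal(mean=np.log(50.0), sigma=1.5, size=cfg.n_genes)
    lengths = pd.Series(
        rng.integers(500, 5000, size=cfg.n_genes), index=genes, name="length"
    )

    n_de = int(round(cfg.de_fraction * cfg.n_genes))
    de_idx = rng.choice(cfg.n_genes, size=n_de, replace=False)
    up_mask = rng.random(n_de) < cfg.de_up_share
    lfc = np.zeros(cfg.n_genes)
    lfc[de_idx[up_mask]] = cfg.de_log2fc
    lfc[de_idx[~up_mask]] = -cfg.de_log2fc

    data = {}
    for _, sample in sheet.iterrows():
        mean = base_mean.copy()
        if sample["condition"] == "HS3+3":
            mean = mean * np.power(2.0, lfc)
        if cfg.count_dispersion == 0:
            data[sample["sample_id"]] = mean
        else:
            r = 1.0 / cfg.count_dispersion
            p = r / (r + mean)
            data[sample["sample_id"]] = rng.negative_binomial(r, p)
    counts = pd.DataFrame(data, index=genes)

    up_genes = [genes[i] for i in de_idx[up_mask]]
    go_rows = []
    term_truth = {}
    n_enriched = min(5, cfg.n_go_terms)
    for t in range(cfg.n_go_terms):
        go_id = f"GO:{t + 1:07d}"
        if t < n_enriched and len(up_genes) >= 8:
            members = list(rng.choice(up_genes, size=8, replace=False))
            members += [genes[i] for i in rng.choice(cfg.n_genes, 4, replace=False)]
            term_truth[go_id] = "enriched_up"
        else:
            size = int(rng.integers(5, 30))
            members = [genes[i] for i in rng.choice(cfg.n_genes, size, replace=False)]
            term_truth[go_id] = "background"
        go_rows += [{"gene": g, "go_id": go_id} for g in sorted(set(members))]
    go_map = pd.DataFrame(go_rows, columns=["gene", "go_id"])

    de_truth = pd.DataFrame(
        {
            "log2FC": lfc,
            "is_de": lfc != 0,
            "FDR": np.where(lfc != 0, 1e-6, 0.5),
        },
        index=genes,
    )
    de_truth.attrs["sheet"] = sheet
    de_truth.attrs["term_truth"] = term_truth
    return counts, go_map, lengths, de_truth


# ---------------------------------------------------------------------------
# FAME + metabolites
# ---------------------------------------------------------------------------


def gen_fame_and_metabolites(
    cfg: Optional[TruthConfig] = None,
    is_area: float = 1.0e6,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Generate GC-FID FAME and GC–MS metabolite tables plus their sheet.

    The injected TG amount follows ``tg_base_ug_per_mg`` times the TG
    subclass fold of the condition; metabolite responses follow their own
    fold map.  Sucrose rows carry a dilution factor of 10 (measured in
    one-tenth runs).
    """
    from .absolute_quant import IS_FATTY_ACID, IS_MASS_TG_MG, IS_METABOLITE

    cfg = cfg or TruthConfig()
    rng = np.random.default_rng([cfg.seed, 3])
    sheet = make_sample_sheet(cfg.conditions, cfg.replicates, prefix="M")
    tg_folds = cfg.subclass_folds.get("TG", {})

    fame_rows = []
    met_rows = []
    for _, sample in sheet.iterrows():
        cond = sample["condition"]
        sid = sample["sample_id"]
        # FAMEs: total TG mass (mg) in the sample, split over fatty acids
        tg_ug_per_mg = cfg.tg_base_ug_per_mg * tg_folds.get(cond, 1.0)
        total_mass_mg = tg_ug_per_mg * cfg.pollen_dry_mass_mg / 1000.0
        fame_rows.append(
            {"sample_id": sid, "fatty_acid": IS_FATTY_ACID, "area": is_area}
        )
        noise = _noise(rng, cfg.cv, len(cfg.fa_composition))
        for (fa, frac), eps in zip(cfg.fa_composition.items(), noise):
            mass = total_mass_mg * frac * eps
            fame_rows.append(
                {
                    "sample_id": sid,
                    "fatty_acid": fa,
                    "area": mass / IS_MASS_TG_MG * is_area,
                }
            )
        # metabolites
        met_rows.append(
            {"sample_id": sid, "analyte": IS_METABOLITE, "area": is_area,
             "dilution": 1.0}
        )
        noise = _noise(rng, cfg.cv, len(cfg.metabolite_base))
        for (analyte, base), eps in zip(cfg.metabolite_base.items(), noise):
            fold = cfg.metabolite_folds.get(analyte, {}).get(cond, 1.0)
            response = base * fold * eps
            dilution = 10.0 if analyte == "sucrose" else 1.0
            met_rows.append(
                {
                    "sample_id": sid,
                    "analyte": analyte,
                    "area": response * is_area / dilution,
                    "dilution": dilution,
                }
            )
    fames = pd.DataFrame(fame_rows)
    mets = pd.DataFrame(met_rows)
    truth = {
        "tg_base_ug_per_mg": cfg.tg_base_ug_per_mg,
        "tg_folds": dict(tg_folds),
        "fa_composition": dict(cfg.fa_composition),
        "metabolite_folds": {
            k: dict(v) for k, v in cfg.metabolite_folds.items()
        },
    }
    return fames, mets, sheet, truth
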