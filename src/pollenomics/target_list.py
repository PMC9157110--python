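"""Combinatorial enumeration of the MRM target species universe.

The targeted method measures *putative* species: every combination of a
fixed residue pool, whether or not the species occurs biologically.  For
glycerolipids the pool is 25 acyl residues (16:0 … 26:1); sphingolipids
combine 5 sphingoid bases with C16–C28 fatty acids that are saturated or
monounsaturated, unhydroxylated or monohydroxylated; sterol conjugates
combine 6 mass-grouped steryl residues with the acyl pool.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .lipid_model import (
    UNRESOLVED,
    AcylChain,
    LipidSpecies,
    LipidSubclass,
    SphingoidBase,
    SubclassRegistry,
    default_registry,
)

__all__ = [
    "DEFAULT_ACYL_POOL",
    "DEFAULT_SPB_POOL",
    "DEFAULT_STERYL_POOL",
    "DEFAULT_SPHINGO_FA_LENGTHS",
    "AcylPool",
    "TargetList",
    "enumerate_glycerolipids",
    "enumerate_sphingolipids",
    "enumerate_sterol_lipids",
    "enumerate_subclass",
]

#: The 25 acyl residues measured for glycerolipid/glycerophospholipid species.
DEFAULT_ACYL_POOL: tuple = tuple(
    AcylChain(c, d)
    for c, d in (
        (16, 0), (16, 1), (16, 2), (16, 3),
        (17, 0), (17, 1), (17, 2), (17, 3),
        (18, 0), (18, 1), (18, 2), (18, 3),
        (19, 0), (19, 1), (19, 2), (19, 3),
        (20, 0), (20, 1), (20, 2),
        (22, 0), (22, 1),
        (24, 0), (24, 1),
        (26, 0), (26, 1),
    )
)

#: The five sphingoid bases measured as SPB residues.
DEFAULT_SPB_POOL: tuple = tuple(
    SphingoidBase(18, d, ox, frozenset({UNRESOLVED}))
    for d, ox in ((0, 2), (1, 2), (2, 2), (0, 3), (1, 3))
)

#: Sphingolipid N-acyl chain lengths C16–C28.
DEFAULT_SPHINGO_FA_LENGTHS: tuple = tuple(range(16, 29))

#: The six mass-grouped steryl residues.
DEFAULT_STERYL_POOL: tuple = (
    "cholesterol",
    "sitosterol",
    "campesterol",
    "M412",
    "M398",
    "cycloeucalenol",
)


@dataclass(frozen=True)
class AcylPool:
    """An ordered, duplicate-free pool of acyl residues."""

    chains: tuple = DEFAULT_ACYL_POOL

    def __post_init__(self) -> None:
        if len(set(self.chains)) != len(self.chains):
            raise ValueError("acyl pool contains duplicates")

    def __len__(self) -> int:
        return len(self.chains)

    def __iter__(self):
        return iter(self.chains)


@dataclass(frozen=True)
class TargetList:
    """Enumerated species universe for one subclass."""

    subclass: str
    species: tuple
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        names = [s.display_name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate species in {self.subclass} target list")

    def __len__(self) -> int:
        return len(self.species)

    def names(self) -> list:
        return [s.display_name for s in self.species]


def _canonical(species: Iterable[LipidSpecies]) -> tuple:
    return tuple(sorted(species, key=lambda s: s.display_name))


def enumerate_glycerolipids(
    subclass: LipidSubclass, pool: Optional[AcylPool] = None
) -> TargetList:
    """All unordered combinations (with replacement) of pool acyls.

    A diacyl subclass over the default 25-residue pool yields C(26, 2) = 325
    molecular combinations, a triacyl subclass C(27, 3) = 2925.
    """
    if pool is None:
        pool = AcylPool()
    if len(pool) == 0:
        raise ValueError("empty acyl pool")
    if subclass.n_chains not in (1, 2, 3):
        raise ValueError(
            f"{subclass.name}: glycerolipid enumeration needs 1-3 chains"
        )
    combos = itertools.combinations_with_replacement(
        sorted(pool.chains), subclass.n_chains
    )
    species = [LipidSpecies(subclass, chains=tuple(c)) for c in combos]
    return TargetList(
        subclass.name,
        _canonical(species),
        provenance={"pool_size": len(pool), "n_chains": subclass.n_chains},
    )


def enumerate_sphingolipids(
    subclass: LipidSubclass,
    spb_pool: Sequence[SphingoidBase] = DEFAULT_SPB_POOL,
    fa_lengths: Sequence[int] = DEFAULT_SPHINGO_FA_LENGTHS,
) -> TargetList:
    """Cartesian product of sphingoid bases × N-acyl variants.

    N-acyl chains run over the given lengths × {0, 1} double bonds ×
    {0, 1} hydroxyls.  Base-only subclasses (SPB, SPBP) enumerate the bases
    alone (5 species by default); two-chain subclasses yield
    5 × len(fa_lengths) × 2 × 2 species (260 for C16–C28).
    """
    if subclass.category != "sphingolipid":
        raise ValueError(f"{subclass.name} is not a sphingolipid subclass")
    if subclass.n_chains == 1:
        species = [LipidSpecies(subclass, chains=(b,)) for b in spb_pool]
    else:
        acyls = [
            AcylChain(c, d, oh)
            for c in fa_lengths
            for d in (0, 1)
            for oh in (0, 1)
        ]
        species = [
            LipidSpecies(subclass, chains=(b, a))
            for b in spb_pool
            for a in acyls
        ]
    return TargetList(
        subclass.name,
        _canonical(species),
        provenance={"spb_pool": len(spb_pool), "fa_lengths": list(fa_lengths)},
    )


def enumerate_sterol_lipids(
    subclass: LipidSubclass,
    steryl_pool: Sequence[str] = DEFAULT_STERYL_POOL,
    acyl_pool: Optional[AcylPool] = None,
) -> TargetList:
    """Steryl residues × (optionally) the acyl pool.

    FS/SG: one species per steryl residue (6 by default); SE/ASG:
    6 × pool size (150 with the default 25-acyl pool).
    """
    if subclass.category != "sterol_lipid":
        raise ValueError(f"{subclass.name} is not a sterol lipid subclass")
    if acyl_pool is None:
        acyl_pool = AcylPool()
    if subclass.n_chains == 0:
        species = [
            LipidSpecies(subclass, steryl_residue=st) for st in steryl_pool
        ]
    else:
        species = [
            LipidSpecies(subclass, chains=(a,), steryl_residue=st)
            for st in steryl_pool
            for a in acyl_pool
        ]
    return TargetList(
        subclass.name,
        _canonical(species),
        provenance={
            "steryl_pool": list(steryl_pool),
            "acyl_pool_size": len(acyl_pool),
        },
    )


def enumerate_subclass(
    name: str, registry: Optional[SubclassRegistry] = None, **kwargs
) -> TargetList:
    """Dispatch enumeration on the subclass category."""
    registry = registry or default_registry()
    sc = registry.get(name)
    if sc.category == "sphingolipid":
        return enumerate_sphingolipids(sc, **kwargs)
    if sc.category == "sterol_lipid":
        return enumerate_sterol_lipids(sc, **kwargs)
    return enumerate_glycerolipids(sc, **kwargs)
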