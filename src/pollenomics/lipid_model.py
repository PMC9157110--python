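"""Lipid species model: shorthand nomenclature, elemental formulas, isotope correction.

Species are written in the shorthand used throughout targeted plant lipidomics:

* sum composition        ``PC 34:2`` (total acyl carbons : total double bonds)
* molecular composition  ``PC 16:0_18:2`` (individual acyl residues, unordered)
* sphingolipids          ``HexCer 18:1;O2/24:0;O`` (sphingoid base / N-acyl),
  with optional positional annotations ``18:1;O2(d4)``, ``18:2;O2(d4,d8)``,
  ``18:0;O3(4OH)`` on the base and ``24:0;O(2OH)`` on the acyl chain
* sterol conjugates      ``SE cholesterol/18:2``, ``SG sitosterol``

Positional features absent from a name are recorded as unresolved, never
imputed: in the underlying MRM data the position of a hydroxyl group often
cannot be determined unambiguously.

The isotopic correction factor (icf) converts a measured monoisotopic peak
area into a total-species abundance.  Under an independent-atoms binomial
model with natural 13C abundance ``p``, the all-12C (M0) fraction of a
species with ``n`` carbons is ``(1-p)**n``, so ``icf = (1-p)**(-n)``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Optional, Union

import yaml

__all__ = [
    "AcylChain",
    "SphingoidBase",
    "LipidSubclass",
    "LipidSpecies",
    "ElementalFormula",
    "SubclassRegistry",
    "default_registry",
    "parse_species",
    "formula_of",
    "icf",
    "LipidParseError",
    "RegistryError",
    "P13C_DEFAULT",
]

#: IUPAC natural abundance of 13C.
P13C_DEFAULT = 0.0107

# canonical feature tokens
D4 = "d4"            # double bond at the Δ4 position of the sphingoid base
D8 = "d8"            # double bond at the Δ8 position of the sphingoid base
C4_OH = "4OH"        # hydroxylation at C4 of the sphingoid base
UNRESOLVED = "unresolved"

_ELEMENT_ORDER = ("C", "H", "N", "O", "P", "S")


class LipidParseError(ValueError):
    """Raised when a shorthand name does not follow the grammar."""


class RegistryError(KeyError):
    """Raised for unknown subclass codes or steryl residues."""


# ---------------------------------------------------------------------------
# elemental formulas
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ElementalFormula:
    """Immutable element→count map restricted to C, H, N, O, P, S."""

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for el, n in dict(self.counts).items():
            if el not in _ELEMENT_ORDER:
                raise ValueError(f"unsupported element {el!r}")
            n = int(n)
            if n < 0:
                raise ValueError(f"negative count for {el}: {n}")
            if n:
                clean[el] = n
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalFormula(merged)

    def subtract(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) - n
        return ElementalFormula(merged)  # validation rejects negatives

    @property
    def carbons(self) -> int:
        return self["C"]

    def __str__(self) -> str:
        parts = []
        for el in _ELEMENT_ORDER:
            n = self[el]
            if n == 0:
                continue
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)


WATER = ElementalFormula({"H": 2, "O": 1})


# ---------------------------------------------------------------------------
# chains
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class AcylChain:
    """A fatty-acyl residue, e.g. 16:0, 24:1 or hydroxylated 24:0;O."""

    carbons: int
    double_bonds: int
    hydroxyls: int = 0
    #: True if the hydroxyl is known to sit at C2, None if unresolved.
    c2_hydroxyl: Optional[bool] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError(f"acyl chain needs >=2 carbons, got {self.carbons}")
        if not 0 <= self.double_bonds <= self.carbons // 2:
            raise ValueError(
                f"{self.double_bonds} double bonds infeasible for C{self.carbons}"
            )
        if self.hydroxyls not in (0, 1):
            raise ValueError("acyl hydroxyl count must be 0 or 1")
        if self.hydroxyls == 0 and self.c2_hydroxyl:
            raise ValueError("c2_hydroxyl set on an unhydroxylated chain")

    @property
    def is_vlcfa(self) -> bool:
        """Very-long-chain fatty acid: C >= 20."""
        return self.carbons >= 20

    def free_formula(self) -> ElementalFormula:
        """Formula of the free fatty acid CnH(2n-2d)O(2+hydroxyls)."""
        return ElementalFormula(
            {"C": self.carbons, "H": 2 * self.carbons - 2 * self.double_bonds,
             "O": 2 + self.hydroxyls}
        )

    def display(self) -> str:
        s = f"{self.carbons}:{self.double_bonds}"
        if self.hydroxyls:
            s += ";O"
            if self.c2_hydroxyl:
                s += "(2OH)"
        return s


@dataclass(frozen=True, order=True)
class SphingoidBase:
    """A sphingoid base (long-chain base), e.g. 18:1;O2 or 18:0;O3."""

    carbons: int
    double_bonds: int
    oxygens: int
    positional_features: frozenset = field(
        default=frozenset({UNRESOLVED}), compare=True
    )

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError("sphingoid base needs >=2 carbons")
        if self.oxygens not in (2, 3):
            raise ValueError(f"sphingoid base oxygens must be 2 or 3, got {self.oxygens}")
        if self.double_bonds < 0:
            raise ValueError("negative double bonds")
        feats = frozenset(self.positional_features)
        allowed = {D4, D8, C4_OH, UNRESOLVED}
        if not feats <= allowed:
            raise ValueError(f"unknown positional features {feats - allowed}")
        if D4 in feats and C4_OH in feats:
            raise ValueError("d4 double bond and C4 hydroxylation are mutually exclusive")
        n_pos_db = len(feats & {D4, D8})
        if n_pos_db > self.double_bonds:
            raise ValueError("more positional double bonds than double bonds")
        if C4_OH in feats and self.oxygens < 3:
            raise ValueError("C4 hydroxylation requires three oxygens (;O3)")
        object.__setattr__(self, "positional_features", feats)

    @property
    def resolved(self) -> bool:
        return UNRESOLVED not in self.positional_features

    def free_formula(self) -> ElementalFormula:
        """Free base CnH(2n+3-2d)N O(oxygens) (sphingosine-type skeleton)."""
        return ElementalFormula(
            {"C": self.carbons, "H": 2 * self.carbons + 3 - 2 * self.double_bonds,
             "N": 1, "O": self.oxygens}
        )

    def display(self) -> str:
        s = f"{self.carbons}:{self.double_bonds};O{self.oxygens}"
        shown = [f for f in (D4, D8, C4_OH) if f in self.positional_features]
        if shown:
            s += "(" + ",".join(shown) + ")"
        return s


Chain = Union[AcylChain, SphingoidBase]


# ---------------------------------------------------------------------------
# subclass registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LipidSubclass:
    name: str
    category: str
    n_chains: int
    backbone_formula: ElementalFormula
    headgroup_formula: ElementalFormula
    ionization_mode: str

    def __post_init__(self) -> None:
        if self.n_chains < 0:
            raise ValueError("n_chains must be >= 0")


class SubclassRegistry:
    """Holds the measurable lipid subclasses and steryl residue formulas.

    Loaded from a YAML config (one record per subclass); the default registry
    ships with the package and can be replaced via :meth:`from_yaml`.
    """

    def __init__(
        self,
        subclasses: Iterable[LipidSubclass],
        steryl_residues: Mapping[str, ElementalFormula],
    ) -> None:
        self._subclasses: dict[str, LipidSubclass] = {}
        for sc in subclasses:
            if sc.name in self._subclasses:
                raise RegistryError(f"duplicate subclass {sc.name!r}")
            self._subclasses[sc.name] = sc
        self._steryls = dict(steryl_residues)

    @classmethod
    def from_yaml(cls, path_or_stream) -> "SubclassRegistry":
        if hasattr(path_or_stream, "read"):
            raw = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream, "r", encoding="utf-8") as fh:
                raw = yaml.safe_load(fh)
        subclasses = [
            LipidSubclass(
                name=name,
                category=rec["category"],
                n_chains=int(rec["n_chains"]),
                backbone_formula=ElementalFormula(rec.get("backbone") or {}),
                headgroup_formula=ElementalFormula(rec.get("headgroup") or {}),
                ionization_mode=rec.get("ionization_mode", "positive"),
            )
            for name, rec in raw["subclasses"].items()
        ]
        steryls = {
            name: ElementalFormula(counts)
            for name, counts in (raw.get("steryl_residues") or {}).items()
        }
        return cls(subclasses, steryls)

    def __contains__(self, name: str) -> bool:
        return name in self._subclasses

    def __iter__(self):
        return iter(self._subclasses.values())

    def get(self, name: str) -> LipidSubclass:
        try:
            return self._subclasses[name]
        except KeyError:
            raise RegistryError(f"unknown lipid subclass {name!r}") from None

    @property
    def steryl_residues(self) -> Mapping[str, ElementalFormula]:
        return dict(self._steryls)

    def steryl_formula(self, name: str) -> ElementalFormula:
        try:
            return self._steryls[name]
        except KeyError:
            raise RegistryError(f"unknown steryl residue {name!r}") from None


@lru_cache(maxsize=1)
def default_registry() -> SubclassRegistry:
    with resources.files("pollenomics.data").joinpath("subclasses.yaml").open(
        "r", encoding="utf-8"
    ) as fh:
        return SubclassRegistry.from_yaml(fh)


# ---------------------------------------------------------------------------
# species
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid species at sum or molecular composition level."""

    subclass: LipidSubclass
    chains: tuple = ()
    sum_carbons: Optional[int] = None
    sum_double_bonds: Optional[int] = None
    steryl_residue: Optional[str] = None

    def __post_init__(self) -> None:
        sc = self.subclass
        if self.is_molecular:
            expected = sc.n_chains
            if sc.category == "sterol_lipid":
                # acyl chains only; steryl residue handled separately
                if self.steryl_residue is None:
                    raise ValueError(f"{sc.name} species needs a steryl residue")
            if len(self.chains) != expected:
                raise ValueError(
                    f"{sc.name} expects {expected} chains, got {len(self.chains)}"
                )
        else:
            if self.sum_carbons is None or self.sum_double_bonds is None:
                if sc.n_chains > 0 and sc.category != "sterol_lipid":
                    raise ValueError("species needs chains or a sum composition")

    @property
    def is_molecular(self) -> bool:
        return bool(self.chains) or self.subclass.n_chains == 0

    @property
    def total_double_bonds(self) -> int:
        """Double bonds in the fatty-acyl residues (saturation classing).

        Sphingoid-base double bonds are not counted: saturation classes refer
        to the fatty acid residues.
        """
        if self.is_molecular:
            return sum(
                c.double_bonds for c in self.chains if isinstance(c, AcylChain)
            )
        return int(self.sum_double_bonds or 0)

    @property
    def sphingoid_base(self) -> Optional[SphingoidBase]:
        for c in self.chains:
            if isinstance(c, SphingoidBase):
                return c
        return None

    @property
    def acyl_chains(self) -> tuple:
        return tuple(c for c in self.chains if isinstance(c, AcylChain))

    @property
    def display_name(self) -> str:
        sc = self.subclass
        if sc.category == "sterol_lipid":
            parts = [self.steryl_residue or ""]
            parts += [c.display() for c in self.acyl_chains]
            return f"{sc.name} {'/'.join(p for p in parts if p)}"
        if sc.category == "sphingolipid":
            base = self.sphingoid_base
            parts = [base.display()] if base else []
            parts += [c.display() for c in self.acyl_chains]
            return f"{sc.name} {'/'.join(parts)}"
        if self.is_molecular and self.chains:
            return f"{sc.name} " + "_".join(c.display() for c in self.chains)
        return f"{sc.name} {self.sum_carbons}:{self.sum_double_bonds}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.display_name


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_ACYL_RE = re.compile(
    r"^(?P<c>\d+):(?P<d>\d+)(?P<oh>;O)?(?:\((?P<feat>[^)]*)\))?$"
)
_SPB_RE = re.compile(
    r"^(?P<c>\d+):(?P<d>\d+);O(?P<ox>[23])(?:\((?P<feat>[^)]*)\))?$"
)


def _parse_acyl(token: str) -> AcylChain:
    m = _ACYL_RE.match(token)
    if not m:
        raise LipidParseError(f"malformed acyl residue {token!r}")
    hydroxyls = 1 if m.group("oh") else 0
    c2: Optional[bool] = None
    feat = m.group("feat")
    if feat:
        feats = [f.strip() for f in feat.split(",") if f.strip()]
        for f in feats:
            if f == "2OH":
                if not hydroxyls:
                    raise LipidParseError(
                        f"annotation 2OH on unhydroxylated residue {token!r}"
                    )
                c2 = True
            else:
                raise LipidParseError(f"unknown acyl annotation {f!r} in {token!r}")
    try:
        return AcylChain(int(m.group("c")), int(m.group("d")), hydroxyls, c2)
    except ValueError as exc:
        raise LipidParseError(f"invalid acyl residue {token!r}: {exc}") from exc


def _parse_spb(token: str) -> SphingoidBase:
    m = _SPB_RE.match(token)
    if not m:
        raise LipidParseError(f"malformed sphingoid base {token!r}")
    feats: set = set()
    feat = m.group("feat")
    if feat:
        for f in (x.strip() for x in feat.split(",")):
            if f in (D4, D8, C4_OH):
                feats.add(f)
            elif f:
                raise LipidParseError(f"unknown base annotation {f!r} in {token!r}")
    else:
        feats = {UNRESOLVED}
    try:
        return SphingoidBase(
            int(m.group("c")), int(m.group("d")), int(m.group("ox")), frozenset(feats)
        )
    except ValueError as exc:
        raise LipidParseError(f"invalid sphingoid base {token!r}: {exc}") from exc


def parse_species(
    name: str, registry: Optional[SubclassRegistry] = None
) -> LipidSpecies:
    """Parse a shorthand species name into a :class:`LipidSpecies`.

    Raises :class:`LipidParseError` on malformed strings and
    :class:`RegistryError` for unknown subclass codes.
    """
    registry = registry or default_registry()
    name = name.strip()
    if " " not in name:
        raise LipidParseError(
            f"{name!r} lacks the '<SUBCLASS> <composition>' separator"
        )
    code, rest = name.split(" ", 1)
    subclass = registry.get(code)
    rest = rest.strip()
    if not rest:
        raise LipidParseError(f"{name!r} has an empty composition")

    if subclass.category == "sterol_lipid":
        parts = rest.split("/")
        steryl = parts[0]
        registry.steryl_formula(steryl)  # validates
        acyls = tuple(_parse_acyl(p) for p in parts[1:])
        if len(acyls) != subclass.n_chains:
            raise LipidParseError(
                f"{code} expects {subclass.n_chains} acyl residue(s), "
                f"got {len(acyls)} in {name!r}"
            )
        return LipidSpecies(subclass, chains=acyls, steryl_residue=steryl)

    if subclass.category == "sphingolipid":
        parts = rest.split("/")
        base = _parse_spb(parts[0])
        acyls = tuple(_parse_acyl(p) for p in parts[1:])
        chains = (base,) + acyls
        if len(chains) != subclass.n_chains:
            raise LipidParseError(
                f"{code} expects {subclass.n_chains} residue(s), got "
                f"{len(chains)} in {name!r}"
            )
        return LipidSpecies(subclass, chains=chains)

    # glycerolipid grammar: sum "34:2" or molecular "16:0_18:2"
    if "_" in rest:
        chains = tuple(sorted(_parse_acyl(p) for p in rest.split("_")))
        return LipidSpecies(subclass, chains=chains)
    m = re.match(r"^(\d+):(\d+)$", rest)
    if not m:
        raise LipidParseError(f"malformed sum composition {rest!r} in {name!r}")
    return LipidSpecies(
        subclass, sum_carbons=int(m.group(1)), sum_double_bonds=int(m.group(2))
    )


# ---------------------------------------------------------------------------
# formulas and isotope correction
# ---------------------------------------------------------------------------


def formula_of(
    species: LipidSpecies, registry: Optional[SubclassRegistry] = None
) -> ElementalFormula:
    """Assemble the elemental formula of a species.

    backbone + headgroup + steryl residue + chain contributions, minus one
    H2O of condensation per ester/amide-bound acyl chain.  Sum-composition
    species use a generic (di/tri)acyl skeleton with the stated total
    carbons and double bonds — an approximation adequate for carbon counting.
    """
    registry = registry or default_registry()
    sc = species.subclass
    total = sc.backbone_formula + sc.headgroup_formula
    if species.steryl_residue is not None:
        # headgroup residues are stored condensed and acyl chains subtract
        # their own ester water, so the free steryl formula adds as-is
        total = total + registry.steryl_formula(species.steryl_residue)
    if species.is_molecular:
        for chain in species.chains:
            total = total + chain.free_formula()
            if isinstance(chain, AcylChain):
                total = total.subtract(WATER)
    elif species.sum_carbons is not None:
        n = sc.n_chains
        chains = ElementalFormula(
            {
                "C": species.sum_carbons,
                "H": 2 * species.sum_carbons - 2 * (species.sum_double_bonds or 0),
                "O": 2 * n,
            }
        )
        total = (total + chains).subtract(
            ElementalFormula({"H": 2 * n, "O": n})
        )
    return total


def icf(
    formula: Union[ElementalFormula, int], p13c: float = P13C_DEFAULT
) -> float:
    """Isotopic correction factor ``(1 - p13c) ** (-nC)``.

    The reciprocal of the monoisotopic (all-12C) fraction under an
    independent-atoms binomial model; always >= 1.
    """
    if not 0.0 <= p13c < 1.0:
        raise ValueError(f"p13c must lie in [0, 1), got {p13c}")
    n_c = formula.carbons if isinstance(formula, ElementalFormula) else int(formula)
    if n_c < 0:
        raise ValueError("carbon count must be >= 0")
    return math.pow(1.0 - p13c, -n_c)
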