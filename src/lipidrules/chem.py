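"""Monoisotopic mass arithmetic, adduct and fragment m/z computation,
fatty-acyl mass model, and the annotation grammar.

All ion m/z values include the electron-mass correction: a singly charged
cation is lighter than its neutral formula by one electron
(:data:`ELECTRON_MASS` = 0.00054858 Da) and an anion heavier by one.
Omitting this shifts m/z at the fourth decimal place, which matters at the
sub-5-ppm accuracy of orbitrap data.

Masses are computed from the embedded :data:`MONOISOTOPIC_MASS` table so
that generated library files are reproducible bit-exact; the table follows
the IUPAC/CODATA recommended values.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "Formula",
    "formula_mass",
    "Adduct",
    "ADDUCTS",
    "ion_mz",
    "fragment_ion_mz",
    "ppm_error",
    "Linkage",
    "Terminal",
    "FattyAcyl",
    "AnnotationLevel",
    "Annotation",
    "round_half_up",
]

# Monoisotopic atomic masses, Da (IUPAC 2021 / AME2020 rounded to the
# precision conventionally used in small-molecule MS).
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
}

ELECTRON_MASS = 0.00054857990907
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS  # 1.00727645…

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero, matching printed m/z conventions
    (Python's built-in round is banker's rounding)."""
    factor = 10.0 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


class Formula:
    """An elemental composition: an immutable map from element symbol to a
    non-negative count.  Supports addition, subtraction and scalar
    multiplication so class templates can assemble lipids by composition.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | str | None = None, **kw: int):
        if isinstance(counts, str):
            counts = _parse_formula(counts)
        merged: dict[str, int] = dict(counts or {})
        for el, n in kw.items():
            merged[el] = merged.get(el, 0) + n
        for el, n in list(merged.items()):
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {el!r}")
            if n < 0:
                raise ValueError(f"negative count for element {el}: {n}")
            if n == 0:
                del merged[el]
        self._counts = dict(sorted(merged.items()))

    @property
    def counts(self) -> dict[str, int]:
        return dict(self._counts)

    @property
    def mass(self) -> float:
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self._counts.items())

    def __add__(self, other: "Formula") -> "Formula":
        c = dict(self._counts)
        for el, n in other._counts.items():
            c[el] = c.get(el, 0) + n
        return Formula(c)

    def __sub__(self, other: "Formula") -> "Formula":
        c = dict(self._counts)
        for el, n in other._counts.items():
            c[el] = c.get(el, 0) - n
        return Formula(c)  # raises if any count goes negative

    def __mul__(self, k: int) -> "Formula":
        return Formula({el: n * k for el, n in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Formula) and self._counts == other._counts

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        order = sorted(
            self._counts, key=lambda e: (e != "C", e != "H", e)
        )
        return "".join(
            f"{el}{self._counts[el] if self._counts[el] != 1 else ''}" for el in order
        )

    def __repr__(self) -> str:
        return f"Formula({str(self)!r})"


def _parse_formula(text: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        el, num = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol: {el!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r} at position {pos}")
    return counts


WATER = Formula("H2O")
AMMONIA = Formula("NH3")


def formula_mass(formula: Formula | Mapping[str, int] | str) -> float:
    """Neutral monoisotopic mass of an elemental composition, in Da."""
    if not isinstance(formula, Formula):
        formula = Formula(formula)
    return formula.mass


@dataclass(frozen=True)
class Adduct:
    """An ESI adduct/ion type.  ``mass_delta`` is the full m/z shift for a
    singly charged ion, electron mass included; for charge z the ion m/z is
    ``(M + mass_delta_total)/z`` where the per-charge electron correction is
    already folded into ``mass_delta``."""

    name: str
    polarity: str  # "positive" | "negative"
    charge: int
    mass_delta: float

    def __post_init__(self):
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive/negative, got {self.polarity!r}")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")


def _pos_delta(added: Formula, z: int = 1) -> float:
    return added.mass - z * ELECTRON_MASS


def _neg_delta(added: Formula | None, removed: Formula | None = None, z: int = 1) -> float:
    delta = (added.mass if added else 0.0) - (removed.mass if removed else 0.0)
    return delta + z * ELECTRON_MASS


ADDUCTS: dict[str, Adduct] = {
    a.name: a
    for a in [
        Adduct("[M+H]+", "positive", 1, _pos_delta(Formula("H"))),
        Adduct("[M+NH4]+", "positive", 1, _pos_delta(Formula("NH4"))),
        Adduct("[M+Na]+", "positive", 1, _pos_delta(Formula("Na"))),
        Adduct("[M-H]-", "negative", 1, _neg_delta(None, Formula("H"))),
        Adduct("[M+HCO2]-", "negative", 1, _neg_delta(Formula("CHO2"))),
        Adduct("[M+CH3CO2]-", "negative", 1, _neg_delta(Formula("C2H3O2"))),
    ]
}


def ion_mz(neutral_mass: float, adduct: Adduct | str) -> float:
    """m/z of ``adduct`` formed from a neutral of the given monoisotopic mass."""
    if isinstance(adduct, str):
        adduct = ADDUCTS[adduct]
    if neutral_mass <= 0:
        raise ValueError("neutral_mass must be > 0")
    return (neutral_mass + adduct.mass_delta) / adduct.charge


def fragment_ion_mz(formula: Formula | str, polarity: str, charge: int = 1) -> float:
    """m/z of a fragment ion whose elemental composition (protonation state
    included) is given directly: subtract ``charge`` electrons for cations,
    add them for anions."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    m = formula_mass(formula)
    if polarity == "positive":
        return (m - charge * ELECTRON_MASS) / charge
    if polarity == "negative":
        return (m + charge * ELECTRON_MASS) / charge
    raise ValueError(f"polarity must be positive/negative, got {polarity!r}")


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts-per-million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be > 0")
    return 1e6 * (observed - theoretical) / theoretical


# ---------------------------------------------------------------------------
# Fatty acyls

class Linkage(str, enum.Enum):
    ACYL = "acyl"
    ALKYL = "alkyl_plasmanyl"      # O-alkyl ether, "O-" prefix
    ALKENYL = "alkenyl_plasmenyl"  # O-alk-1-enyl (vinyl ether), "P-" prefix


class Terminal(str, enum.Enum):
    NONE = "none"
    CHO = "aldehyde_CHO"    # short-chain oxidized, terminal aldehyde
    COOH = "carboxyl_COOH"  # short-chain oxidized, terminal carboxylic acid


# Oxidation modifications and their composition deltas relative to the
# parent chain.  "O" is the ketone-or-epoxide oxygen; by default it is
# treated as epoxide-like (+O).  The keto tautomer "O(keto)" (+O, -2H) is
# available but not produced by the default generator.
OXIDATION_DELTAS: dict[str, tuple[int, int]] = {
    # name -> (delta O, delta H)
    "OH": (1, 0),
    "OOH": (2, 0),
    "O": (1, 0),
    "O(keto)": (1, -2),
}

_TERMINAL_DELTAS = {
    Terminal.NONE: (0, 0),
    Terminal.CHO: (1, -2),
    Terminal.COOH: (2, -2),
}

# Linkage deltas vs the ester (free fatty acid) composition CnH(2n-2d)O2,
# chosen so that backbone + sum(chains) - n*H2O reproduces LIPID MAPS sum
# formulas (e.g. PC(O-34:1) = PC(34:1) - O + 2H, PC(P-34:1) = PC(34:1) - O).
_LINKAGE_DELTAS = {
    Linkage.ACYL: (0, 0),
    Linkage.ALKYL: (-1, 2),
    Linkage.ALKENYL: (-1, 0),
}


@dataclass(frozen=True)
class FattyAcyl:
    """A fatty-acyl (or ether/oxidized) chain: the unit of combinatorial
    library generation.

    ``oxidation`` is a sorted tuple of modification names from
    :data:`OXIDATION_DELTAS`; ``terminal`` marks short-chain cleavage
    products (e.g. ``9:0(CHO)``).
    """

    carbons: int
    double_bonds: int = 0
    linkage: Linkage = Linkage.ACYL
    oxidation: tuple[str, ...] = ()
    terminal: Terminal = Terminal.NONE

    def __post_init__(self):
        if self.carbons < 2:
            raise ValueError(f"carbons must be >= 2, got {self.carbons}")
        if not (0 <= self.double_bonds <= self.carbons - 1):
            raise ValueError(
                f"double_bonds must be in [0, carbons-1], got "
                f"{self.double_bonds} for {self.carbons} carbons"
            )
        object.__setattr__(self, "oxidation", tuple(sorted(self.oxidation)))
        object.__setattr__(self, "linkage", Linkage(self.linkage))
        object.__setattr__(self, "terminal", Terminal(self.terminal))
        for mod in self.oxidation:
            if mod not in OXIDATION_DELTAS:
                raise ValueError(f"unknown oxidation modification: {mod!r}")

    @property
    def is_oxidized(self) -> bool:
        return bool(self.oxidation) or self.terminal is not Terminal.NONE

    @property
    def formula(self) -> Formula:
        """Composition as the corresponding free fatty acid / fatty alcohol
        analogue: CnH(2n-2d)O2 plus linkage, oxidation and terminal deltas."""
        n, d = self.carbons, self.double_bonds
        dO, dH = _LINKAGE_DELTAS[self.linkage]
        for mod in self.oxidation:
            o, h = OXIDATION_DELTAS[mod]
            dO += o
            dH += h
        o, h = _TERMINAL_DELTAS[self.terminal]
        dO += o
        dH += h
        counts = {"C": n, "H": 2 * n - 2 * d + dH, "O": 2 + dO}
        return Formula(counts)

    @property
    def mass(self) -> float:
        """Neutral monoisotopic mass of the free-acid form, Da."""
        return self.formula.mass

    @property
    def carboxylate_mz(self) -> float:
        """m/z of the [FA-H]- carboxylate anion of this chain."""
        return fragment_ion_mz(self.formula - Formula("H"), "negative")

    @property
    def acylium_mz(self) -> float:
        """m/z of the RCO+ acylium cation ([FA+H-H2O]+ equivalent)."""
        return fragment_ion_mz(self.formula - Formula("HO"), "positive")

    def render(self) -> str:
        prefix = {Linkage.ACYL: "", Linkage.ALKYL: "O-", Linkage.ALKENYL: "P-"}[
            self.linkage
        ]
        mods = list(self.oxidation)
        if self.terminal is Terminal.CHO:
            mods.append("CHO")
        elif self.terminal is Terminal.COOH:
            mods.append("COOH")
        suffix = f"({','.join(mods)})" if mods else ""
        return f"{prefix}{self.carbons}:{self.double_bonds}{suffix}"

    def __str__(self) -> str:
        return self.render()

    @property
    def sort_key(self):
        return (
            self.carbons,
            self.double_bonds,
            len(self.oxidation),
            self.render(),
        )


def fatty_acyl_mass(fa: FattyAcyl) -> float:
    """Neutral free-fatty-acid monoisotopic mass of a chain, Da."""
    return fa.mass


# ---------------------------------------------------------------------------
# Annotation grammar

class AnnotationLevel(str, enum.Enum):
    """Structural resolution of an annotation string.

    sum_composition  -> "PC(38:6)"   total carbons:double bonds only
    acyl_constituents-> "PC(16:0_22:6)"  chains known, sn-position unknown
    acyl_positions   -> "PC(16:0/22:6)"  chains and sn-position known
    """

    SUM = "sum_composition"
    ACYL = "acyl_constituents"
    POSITION = "acyl_positions"


_LEVEL_SEP = {AnnotationLevel.ACYL: "_", AnnotationLevel.POSITION: "/"}


@dataclass(frozen=True)
class Annotation:
    """A lipid annotation at a stated structural resolution.

    ``base`` is an optional backbone descriptor rendered before the chains
    (sphingoid base, e.g. "d18:1"); its carbons/double bonds are folded into
    sum-composition totals with the "d" marker (SM(d34:1) convention).
    """

    lipid_class: str
    level: AnnotationLevel
    chains: tuple[FattyAcyl, ...] = ()
    base: str = ""            # e.g. "d18:1", joined to chains with "/"
    base_carbons: int = 0
    base_double_bonds: int = 0

    def __post_init__(self):
        object.__setattr__(self, "level", AnnotationLevel(self.level))
        object.__setattr__(self, "chains", tuple(self.chains))

    @property
    def total_carbons(self) -> int:
        return self.base_carbons + sum(c.carbons for c in self.chains)

    @property
    def total_double_bonds(self) -> int:
        return self.base_double_bonds + sum(c.double_bonds for c in self.chains)

    def at_level(self, level: AnnotationLevel) -> "Annotation":
        return Annotation(
            self.lipid_class, level, self.chains,
            self.base, self.base_carbons, self.base_double_bonds,
        )

    def render(self) -> str:
        if self.level is AnnotationLevel.SUM:
            ether = any(
                c.linkage in (Linkage.ALKYL, Linkage.ALKENYL) for c in self.chains
            )
            pref = "d" if self.base else ""
            if ether:
                pref = (
                    "P-"
                    if any(c.linkage is Linkage.ALKENYL for c in self.chains)
                    else "O-"
                )
            body = f"{pref}{self.total_carbons}:{self.total_double_bonds}"
            n_ox = sum(len(c.oxidation) for c in self.chains) + sum(
                c.terminal is not Terminal.NONE for c in self.chains
            )
            if n_ox:
                body += f";O{n_ox if n_ox > 1 else ''}"
        else:
            chains = self.chains
            if self.level is AnnotationLevel.ACYL:
                # canonical order: input order must not matter for "_"
                chains = tuple(sorted(chains, key=lambda c: c.sort_key))
            body = _LEVEL_SEP[self.level].join(c.render() for c in chains)
            if self.base:
                # the sphingoid base's backbone position is always known
                body = f"{self.base}/{body}" if body else self.base
        return f"{self.lipid_class}({body})"

    def __str__(self) -> str:
        return self.render()


def render_annotation(annotation: Annotation) -> str:
    """Deterministic annotation string; acyl-constituent chains are sorted
    canonically (carbons, double bonds, #oxidations) before joining with
    "_", so chain input order never changes the rendered text."""
    return annotation.render()
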