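"""In silico fragmentation library generation.

A library is a list of :class:`LibraryEntry` objects, one per lipid
species x adduct, each carrying the theoretical precursor m/z and a list of
labelled theoretical fragment m/z values.  Entries are instantiated from
:class:`LipidClassDefinition` templates over enumerated fatty-acyl chain
sets; oxidized species come from combinatorial oxidation of the unsaturated
chains in the pool.

Libraries contain exact m/z only — no predicted intensities.
"""

from __future__ import annotations

import csv
import enum
import itertools
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

from .chem import (
    ADDUCTS,
    AMMONIA,
    WATER,
    Adduct,
    Annotation,
    AnnotationLevel,
    FattyAcyl,
    Formula,
    Linkage,
    Terminal,
    fragment_ion_mz,
    ion_mz,
)

__all__ = [
    "DEFAULT_FA_POOL",
    "DOUBLE_BOND_POSITIONS",
    "FragmentMode",
    "FragmentTemplate",
    "LipidClassDefinition",
    "LibraryEntry",
    "enumerate_chain_sets",
    "generate_oxidized_fas",
    "build_library",
    "build_class_library",
    "build_default_library",
    "default_classes",
    "write_library",
    "read_library",
    "parse_chain",
]


def _fa(c: int, d: int = 0) -> FattyAcyl:
    return FattyAcyl(carbons=c, double_bonds=d)


# Default endogenous fatty-acid pool (39 chains).  This is a curated set of
# chains commonly reported in mammalian lipidomes; it is user-replaceable
# (any list of FattyAcyl works everywhere a pool is accepted).
DEFAULT_FA_POOL: tuple[FattyAcyl, ...] = tuple(
    _fa(c, d)
    for c, d in [
        (6, 0), (8, 0), (10, 0), (11, 0), (12, 0), (13, 0),
        (14, 0), (14, 1), (15, 0), (15, 1), (16, 0), (16, 1),
        (17, 0), (17, 1), (18, 0), (18, 1), (18, 2), (18, 3), (18, 4),
        (19, 0), (20, 0), (20, 1), (20, 2), (20, 3), (20, 4), (20, 5),
        (21, 0), (22, 0), (22, 1), (22, 2), (22, 4), (22, 5), (22, 6),
        (23, 0), (24, 0), (24, 1), (26, 0), (26, 1), (28, 0),
    ]
)

# Double-bond positions (Delta nomenclature, position of the first carbon of
# each double bond counted from the carboxyl end) for the unsaturated chains
# of the default pool.  Drives short-chain oxidized-FA generation; editable
# via the CSV round trip in write/read helpers below.
DOUBLE_BOND_POSITIONS: dict[tuple[int, int], tuple[int, ...]] = {
    (14, 1): (9,),
    (15, 1): (10,),
    (16, 1): (9,),
    (17, 1): (10,),
    (18, 1): (9,),
    (18, 2): (9, 12),
    (18, 3): (9, 12, 15),
    (18, 4): (6, 9, 12, 15),
    (20, 1): (11,),
    (20, 2): (11, 14),
    (20, 3): (8, 11, 14),
    (20, 4): (5, 8, 11, 14),
    (20, 5): (5, 8, 11, 14, 17),
    (22, 1): (13,),
    (22, 2): (13, 16),
    (22, 4): (7, 10, 13, 16),
    (22, 5): (7, 10, 13, 16, 19),
    (22, 6): (4, 7, 10, 13, 16, 19),
    (24, 1): (15,),
    (26, 1): (17,),
}


# ---------------------------------------------------------------------------
# Chain-set enumeration

def enumerate_chain_sets(
    fa_pool: list[FattyAcyl] | tuple[FattyAcyl, ...],
    k: int,
    require_oxidized: bool = False,
) -> list[tuple[FattyAcyl, ...]]:
    """All size-``k`` multisets of chains from ``fa_pool`` (combinations with
    repetition; permutation duplicates like 18:0_20:0 vs 20:0_18:0 are
    excluded by construction).  With ``require_oxidized`` only multisets
    containing at least one oxidized chain are kept."""
    if not 1 <= k <= 4:
        raise ValueError(f"k must be in 1..4, got {k}")
    if not fa_pool:
        raise ValueError("fa_pool must be non-empty")
    if len(set(fa_pool)) != len(fa_pool):
        raise ValueError("fa_pool entries must be unique")
    pool = sorted(fa_pool, key=lambda f: f.sort_key)
    sets = list(itertools.combinations_with_replacement(pool, k))
    if require_oxidized:
        sets = [s for s in sets if any(fa.is_oxidized for fa in s)]
    return sets


# ---------------------------------------------------------------------------
# Oxidized fatty-acyl generation

_DEFAULT_MODS = ("O", "OH", "OOH")  # keto variant "O(keto)" opt-in


def generate_oxidized_fas(
    fa_pool: list[FattyAcyl] | tuple[FattyAcyl, ...],
    positions: dict[tuple[int, int], tuple[int, ...]] | None = None,
    modifications: tuple[str, ...] = _DEFAULT_MODS,
    max_additions: int | None = None,
) -> tuple[list[FattyAcyl], list[FattyAcyl]]:
    """Enumerate oxidized fatty acyls from the unsaturated members of a pool.

    Long-chain products add 1..double_bonds oxygen-bearing modifications
    (epoxide-like O, hydroxyl OH, hydroperoxide OOH by default) to each
    unsaturated parent; products identical in elemental composition are
    collapsed (e.g. +O from "O" and from "OH" on the same parent).

    Short-chain products cleave each double bond of parents with a known
    position table and cap the new terminus with CHO (aldehyde) or COOH
    (carboxylic acid), keeping the double bonds below the cleavage site.

    Returns ``(long_chain, short_chain)`` lists, deduplicated and sorted.
    """
    if positions is None:
        positions = DOUBLE_BOND_POSITIONS
    long_chain: list[FattyAcyl] = []
    seen_long: set[tuple] = set()
    for fa in fa_pool:
        if fa.double_bonds == 0 or fa.is_oxidized or fa.linkage is not Linkage.ACYL:
            continue
        limit = fa.double_bonds
        if max_additions is not None:
            limit = min(limit, max_additions)
        for n_mod in range(1, limit + 1):
            for mods in itertools.combinations_with_replacement(
                sorted(modifications), n_mod
            ):
                ox = FattyAcyl(
                    fa.carbons, fa.double_bonds, fa.linkage, oxidation=mods
                )
                key = (ox.carbons, ox.double_bonds, ox.formula)
                if key not in seen_long:
                    seen_long.add(key)
                    long_chain.append(ox)
    short_chain: list[FattyAcyl] = []
    seen_short: set[tuple] = set()
    for fa in fa_pool:
        if fa.double_bonds == 0 or fa.is_oxidized:
            continue
        pos = positions.get((fa.carbons, fa.double_bonds))
        if not pos:
            continue
        for p in pos:
            if p < 2:
                continue  # cannot form a 1-carbon chain
            remaining = sum(1 for q in pos if q < p)
            for terminal in (Terminal.CHO, Terminal.COOH):
                frag = FattyAcyl(p, remaining, terminal=terminal)
                key = (frag.carbons, frag.double_bonds, frag.terminal, frag.formula)
                if key not in seen_short:
                    seen_short.add(key)
                    short_chain.append(frag)
    long_chain.sort(key=lambda f: f.sort_key)
    short_chain.sort(key=lambda f: f.sort_key)
    return long_chain, short_chain


# ---------------------------------------------------------------------------
# Class templates

class FragmentMode(str, enum.Enum):
    CONSTANT_MZ = "constant_mz"
    CHAIN_CARBOXYLATE = "chain_carboxylate"          # [FAi - H]-  (negative)
    CHAIN_ACYLIUM = "chain_acylium"                  # [FAi - OH]+ (positive)
    PRECURSOR_MINUS_CONSTANT = "precursor_minus_constant"
    PRECURSOR_MINUS_CHAIN = "precursor_minus_chain"
    PRECURSOR_MINUS_CHAIN_MINUS_CONSTANT = "precursor_minus_chain_minus_constant"


_CHAIN_MODES = {
    FragmentMode.CHAIN_CARBOXYLATE,
    FragmentMode.CHAIN_ACYLIUM,
    FragmentMode.PRECURSOR_MINUS_CHAIN,
    FragmentMode.PRECURSOR_MINUS_CHAIN_MINUS_CONSTANT,
}


@dataclass(frozen=True)
class FragmentTemplate:
    """One theoretical fragment of a lipid class.

    ``label`` may contain ``{i}``, in which case the template expands once
    per chain slot (1-based).  ``constant`` is a neutral mass in Da for the
    precursor-loss modes and a ready-made m/z for ``constant_mz``; a
    negative constant in the chain-loss mode adds mass back (ketene loss =
    acid loss minus water).  ``adducts`` optionally restricts the template
    to specific adduct names; otherwise any adduct of matching polarity.
    """

    label: str
    mode: FragmentMode
    polarity: str
    constant: float = 0.0
    chain_index: int | None = None  # 1-based; None = expand over all slots
    adducts: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "mode", FragmentMode(self.mode))
        object.__setattr__(self, "adducts", tuple(self.adducts))
        if self.mode in _CHAIN_MODES and self.chain_index is None and "{i}" not in self.label:
            raise ValueError(
                f"chain-dependent template {self.label!r} needs chain_index or a "
                "'{i}' placeholder"
            )

    def applies_to(self, adduct: Adduct) -> bool:
        if self.adducts:
            return adduct.name in self.adducts
        return self.polarity == adduct.polarity

    def resolve(
        self, precursor_mz: float, chains: tuple[FattyAcyl, ...], slot: int | None
    ) -> float:
        """Theoretical fragment m/z for one chain slot (1-based)."""
        if self.mode is FragmentMode.CONSTANT_MZ:
            return self.constant
        if self.mode is FragmentMode.PRECURSOR_MINUS_CONSTANT:
            return precursor_mz - self.constant
        chain = chains[(slot or self.chain_index) - 1]
        if self.mode is FragmentMode.CHAIN_CARBOXYLATE:
            return chain.carboxylate_mz
        if self.mode is FragmentMode.CHAIN_ACYLIUM:
            return chain.acylium_mz
        if self.mode is FragmentMode.PRECURSOR_MINUS_CHAIN:
            return precursor_mz - chain.mass
        if self.mode is FragmentMode.PRECURSOR_MINUS_CHAIN_MINUS_CONSTANT:
            return precursor_mz - chain.mass - self.constant
        raise AssertionError(self.mode)


@dataclass(frozen=True)
class LipidClassDefinition:
    """A lipid class: backbone composition, chain count, adducts and
    fragment templates.  Neutral species composition is
    ``backbone + sum(chain formulas) - n_chains * H2O`` (ester/amide
    condensation; ether linkage deltas are folded into the chain formula).
    """

    class_name: str
    n_chains: int
    backbone: Formula
    adducts: tuple[str, ...]
    fragment_templates: tuple[FragmentTemplate, ...]
    annotation_level_cap: AnnotationLevel = AnnotationLevel.ACYL
    base: str = ""            # sphingoid base descriptor, e.g. "d18:1"
    base_carbons: int = 0
    base_double_bonds: int = 0
    require_oxidized: bool = False

    def __post_init__(self):
        if not 1 <= self.n_chains <= 4:
            raise ValueError("n_chains must be in 1..4")
        if not self.adducts:
            raise ValueError(f"class {self.class_name}: at least one adduct required")
        object.__setattr__(self, "adducts", tuple(self.adducts))
        object.__setattr__(
            self, "fragment_templates", tuple(self.fragment_templates)
        )
        object.__setattr__(
            self, "annotation_level_cap", AnnotationLevel(self.annotation_level_cap)
        )
        for t in self.fragment_templates:
            if t.chain_index is not None and not 1 <= t.chain_index <= self.n_chains:
                raise ValueError(
                    f"class {self.class_name}: template {t.label!r} references "
                    f"chain slot {t.chain_index} but class has {self.n_chains}"
                )

    def neutral_formula(self, chains: tuple[FattyAcyl, ...]) -> Formula:
        if len(chains) != self.n_chains:
            raise ValueError(
                f"class {self.class_name} takes {self.n_chains} chains, "
                f"got {len(chains)}"
            )
        total = self.backbone
        for c in chains:
            total = total + c.formula
        return total - self.n_chains * WATER

    def annotation(self, chains: tuple[FattyAcyl, ...]) -> Annotation:
        level = self.annotation_level_cap
        if level is AnnotationLevel.POSITION:
            level = AnnotationLevel.ACYL  # sn-position never claimed from MS/MS
        return Annotation(
            self.class_name, level, chains,
            self.base, self.base_carbons, self.base_double_bonds,
        )


@dataclass(frozen=True)
class LibraryEntry:
    """One lipid species x adduct with its theoretical fragment list."""

    annotation: Annotation
    adduct: Adduct
    precursor_mz: float
    fragments: tuple[tuple[str, float], ...]
    class_name: str

    @property
    def annotation_text(self) -> str:
        return self.annotation.render()

    def fragment_mz(self, label: str) -> float:
        for lab, mz in self.fragments:
            if lab == label:
                return mz
        raise KeyError(label)


def build_library(
    class_def: LipidClassDefinition,
    chain_sets: list[tuple[FattyAcyl, ...]],
    adducts: list[str] | None = None,
) -> list[LibraryEntry]:
    """Instantiate a class template over chain sets and adducts.

    One entry per (chain set, adduct); entries whose rendered annotation and
    adduct coincide (after canonical chain ordering) are deduplicated.
    """
    adduct_names = tuple(adducts) if adducts is not None else class_def.adducts
    entries: list[LibraryEntry] = []
    seen: set[tuple[str, str]] = set()
    for chains in chain_sets:
        chains = tuple(chains)
        annotation = class_def.annotation(chains)
        neutral = class_def.neutral_formula(chains).mass
        for name in adduct_names:
            adduct = ADDUCTS[name]
            key = (annotation.render(), adduct.name)
            if key in seen:
                continue
            seen.add(key)
            precursor = ion_mz(neutral, adduct)
            frags: list[tuple[str, float]] = []
            labels: set[str] = set()
            for t in class_def.fragment_templates:
                if not t.applies_to(adduct):
                    continue
                slots: list[int | None]
                if t.mode in _CHAIN_MODES and t.chain_index is None:
                    slots = list(range(1, class_def.n_chains + 1))
                else:
                    slots = [t.chain_index]
                for slot in slots:
                    label = t.label.format(i=slot) if "{i}" in t.label else t.label
                    try:
                        mz = t.resolve(precursor, chains, slot)
                    except Exception as exc:
                        raise ValueError(
                            f"class {class_def.class_name}: template {t.label!r} "
                            f"failed for chain set "
                            f"{'/'.join(str(c) for c in chains)}: {exc}"
                        ) from exc
                    if label in labels:
                        raise ValueError(
                            f"class {class_def.class_name}: duplicate fragment "
                            f"label {label!r}"
                        )
                    labels.add(label)
                    frags.append((label, mz))
            entries.append(
                LibraryEntry(
                    annotation=annotation,
                    adduct=adduct,
                    precursor_mz=precursor,
                    fragments=tuple(frags),
                    class_name=class_def.class_name,
                )
            )
    return entries


def build_class_library(
    class_def: LipidClassDefinition,
    fa_pool: tuple[FattyAcyl, ...] | list[FattyAcyl] = DEFAULT_FA_POOL,
    adducts: list[str] | None = None,
) -> list[LibraryEntry]:
    """Enumerate chain sets from a pool and build the class library.

    Oxidized classes combine exactly one generated oxidized chain with
    (n_chains - 1) endogenous chains — the dominant composition of oxidized
    glycerophospholipids and triacylglycerols, and the one that keeps the
    combinatorial space tractable.  Species with several oxidized chains
    can be built explicitly via :func:`build_library`.
    """
    pool = list(fa_pool)
    if class_def.require_oxidized:
        long_ox, short_ox = generate_oxidized_fas(pool)
        ox_pool = long_ox + short_ox
        rest_sets: list[tuple[FattyAcyl, ...]]
        if class_def.n_chains == 1:
            rest_sets = [()]
        else:
            rest_sets = enumerate_chain_sets(pool, class_def.n_chains - 1)
        seen: set[tuple[FattyAcyl, ...]] = set()
        chain_sets = []
        for ox in ox_pool:
            for rest in rest_sets:
                chains = tuple(
                    sorted((ox,) + tuple(rest), key=lambda f: f.sort_key)
                )
                if chains not in seen:
                    seen.add(chains)
                    chain_sets.append(chains)
    else:
        chain_sets = enumerate_chain_sets(pool, class_def.n_chains)
    return build_library(class_def, chain_sets, adducts)


def build_default_library(
    classes: list[str] | None = None,
    fa_pool: tuple[FattyAcyl, ...] | list[FattyAcyl] = DEFAULT_FA_POOL,
) -> list[LibraryEntry]:
    """Build libraries for the shipped default classes (optionally a
    subset, matched case-insensitively)."""
    defs = default_classes()
    if classes is not None:
        wanted = {c.lower() for c in classes}
        unknown = wanted - {k.lower() for k in defs}
        if unknown:
            raise ValueError(f"unknown lipid classes: {sorted(unknown)}")
        defs = {k: v for k, v in defs.items() if k.lower() in wanted}
    entries: list[LibraryEntry] = []
    for cdef in defs.values():
        entries.extend(build_class_library(cdef, fa_pool))
    return entries


# ---------------------------------------------------------------------------
# Default class definitions

_PC_HEAD_184 = fragment_ion_mz("C5H15NO4P", "positive")       # 184.0733
_GLYCEROPHOSPHATE_153 = fragment_ion_mz("C3H6O5P", "negative")  # 152.9958
_ETHANOLAMINE_HEAD_140 = fragment_ion_mz("C2H7NO4P", "negative")  # 140.0118
_INOSITOL_PHOSPHATE_241 = fragment_ion_mz("C6H10O8P", "negative")  # 241.0119
_LCB_D181_264 = fragment_ion_mz("C18H34N", "positive")         # 264.2686
_CHOLESTADIENYL_369 = fragment_ion_mz("C27H45", "positive")    # 369.3516

_NL_PHOSPHOCHOLINE = Formula("C5H14NO4P").mass     # 183.0660
_NL_METHYL_FORMATE = Formula("C2H4O2").mass        # 60.0211
_NL_PHOSPHOETHANOLAMINE = Formula("C2H8NO4P").mass  # 141.0191
_NL_SERINE = Formula("C3H5NO2").mass               # 87.0320
_NL_PHOSPHOSERINE = Formula("C3H8NO6P").mass       # 185.0089
_NL_INOSITOL_PHOSPHATE_NH3 = Formula("C6H13O9P").mass + AMMONIA.mass  # 277.0563


def _glycerophospholipid_templates(lyso: bool = False) -> dict[str, FragmentTemplate]:
    """Shared chain-derived templates for diacyl/lyso glycerophospholipids."""
    return {
        "carboxylate": FragmentTemplate(
            "FA{i}_carboxylate", FragmentMode.CHAIN_CARBOXYLATE, "negative"
        ),
        "nl_acid": FragmentTemplate(
            "NL_FA{i}_acid", FragmentMode.PRECURSOR_MINUS_CHAIN, "positive"
        ),
        "nl_ketene": FragmentTemplate(
            "NL_FA{i}_ketene",
            FragmentMode.PRECURSOR_MINUS_CHAIN_MINUS_CONSTANT,
            "positive",
            constant=-WATER.mass,
        ),
    }


def _pc_like(class_name: str, require_oxidized: bool = False) -> LipidClassDefinition:
    t = _glycerophospholipid_templates()
    return LipidClassDefinition(
        class_name=class_name,
        n_chains=2,
        backbone=Formula("C8H20NO6P"),  # glycerophosphocholine
        adducts=("[M+H]+", "[M+HCO2]-"),
        fragment_templates=(
            FragmentTemplate(
                "HeadGroup_184", FragmentMode.CONSTANT_MZ, "positive",
                constant=_PC_HEAD_184,
            ),
            FragmentTemplate(
                "NL_HeadGroup_183", FragmentMode.PRECURSOR_MINUS_CONSTANT,
                "positive", constant=_NL_PHOSPHOCHOLINE,
            ),
            t["nl_acid"],
            t["nl_ketene"],
            t["carboxylate"],
            FragmentTemplate(
                "NL_CH3_formate", FragmentMode.PRECURSOR_MINUS_CONSTANT,
                "negative", constant=_NL_METHYL_FORMATE, adducts=("[M+HCO2]-",),
            ),
        ),
        require_oxidized=require_oxidized,
    )


def _tg_like(class_name: str, require_oxidized: bool = False) -> LipidClassDefinition:
    # oxidized TGs ionize as ammonium adducts; sodiated entries only for
    # the unmodified class keeps the oxidized library size in check
    adducts = ("[M+NH4]+",) if require_oxidized else ("[M+NH4]+", "[M+Na]+")
    return LipidClassDefinition(
        class_name=class_name,
        n_chains=3,
        backbone=Formula("C3H8O3"),  # glycerol
        adducts=adducts,
        fragment_templates=(
            FragmentTemplate(
                "NL_FA{i}_NH3",
                FragmentMode.PRECURSOR_MINUS_CHAIN_MINUS_CONSTANT,
                "positive", constant=AMMONIA.mass, adducts=("[M+NH4]+",),
            ),
            FragmentTemplate(
                "NL_FA{i}", FragmentMode.PRECURSOR_MINUS_CHAIN,
                "positive", adducts=("[M+Na]+",),
            ),
        ),
        require_oxidized=require_oxidized,
    )


def default_classes() -> dict[str, LipidClassDefinition]:
    """The shipped core lipid classes.  Users add classes by constructing
    their own :class:`LipidClassDefinition` (or editing the CSV form, see
    :func:`write_class_config`)."""
    t = _glycerophospholipid_templates()
    classes: dict[str, LipidClassDefinition] = {}

    classes["PC"] = _pc_like("PC")
    classes["OxPC"] = _pc_like("OxPC", require_oxidized=True)

    classes["PE"] = LipidClassDefinition(
        "PE", 2, Formula("C5H14NO6P"), ("[M+H]+", "[M-H]-"),
        (
            FragmentTemplate(
                "NL_PhosphoEthanolamine", FragmentMode.PRECURSOR_MINUS_CONSTANT,
                "positive", constant=_NL_PHOSPHOETHANOLAMINE,
            ),
            t["nl_acid"], t["nl_ketene"], t["carboxylate"],
            FragmentTemplate(
                "HeadGroup_140", FragmentMode.CONSTANT_MZ, "negative",
                constant=_ETHANOLAMINE_HEAD_140,
            ),
        ),
    )
    classes["PS"] = LipidClassDefinition(
        "PS", 2, Formula("C6H14NO8P"), ("[M+H]+", "[M-H]-"),
        (
            FragmentTemplate(
                "NL_PhosphoSerine", FragmentMode.PRECURSOR_MINUS_CONSTANT,
                "positive", constant=_NL_PHOSPHOSERINE,
            ),
            t["nl_acid"], t["nl_ketene"], t["carboxylate"],
            FragmentTemplate(
                "NL_Serine", FragmentMode.PRECURSOR_MINUS_CONSTANT,
                "negative", constant=_NL_SERINE,
            ),
        ),
    )
    classes["PG"] = LipidClassDefinition(
        "PG", 2, Formula("C6H15O8P"), ("[M-H]-",),
        (
            t["carboxylate"],
            FragmentTemplate(
                "Glycerophosphate_153", FragmentMode.CONSTANT_MZ, "negative",
                constant=_GLYCEROPHOSPHATE_153,
            ),
        ),
    )
    classes["PI"] = LipidClassDefinition(
        "PI", 2, Formula("C9H19O11P"), ("[M-H]-", "[M+NH4]+"),
        (
            t["carboxylate"],
            FragmentTemplate(
                "InositolPhosphate_241", FragmentMode.CONSTANT_MZ, "negative",
                constant=_INOSITOL_PHOSPHATE_241,
            ),
            FragmentTemplate(
                "NL_InositolPhosphate_NH3", FragmentMode.PRECURSOR_MINUS_CONSTANT,
                "positive", constant=_NL_INOSITOL_PHOSPHATE_NH3,
                adducts=("[M+NH4]+",),
            ),
            FragmentTemplate(
                "NL_FA{i}_NH3",
                FragmentMode.PRECURSOR_MINUS_CHAIN_MINUS_CONSTANT,
                "positive", constant=AMMONIA.mass, adducts=("[M+NH4]+",),
            ),
        ),
    )
    classes["PA"] = LipidClassDefinition(
        "PA", 2, Formula("C3H9O6P"), ("[M-H]-",),
        (
            t["carboxylate"],
            FragmentTemplate(
                "Glycerophosphate_153", FragmentMode.CONSTANT_MZ, "negative",
                constant=_GLYCEROPHOSPHATE_153,
            ),
        ),
    )
    classes["LPC"] = LipidClassDefinition(
        "LPC", 1, Formula("C8H20NO6P"), ("[M+H]+", "[M+HCO2]-"),
        (
            FragmentTemplate(
                "HeadGroup_184", FragmentMode.CONSTANT_MZ, "positive",
                constant=_PC_HEAD_184,
            ),
            t["nl_acid"], t["nl_ketene"], t["carboxylate"],
            FragmentTemplate(
                "NL_CH3_formate", FragmentMode.PRECURSOR_MINUS_CONSTANT,
                "negative", constant=_NL_METHYL_FORMATE, adducts=("[M+HCO2]-",),
            ),
        ),
    )
    classes["LPE"] = LipidClassDefinition(
        "LPE", 1, Formula("C5H14NO6P"), ("[M+H]+", "[M-H]-"),
        (
            FragmentTemplate(
                "NL_PhosphoEthanolamine", FragmentMode.PRECURSOR_MINUS_CONSTANT,
                "positive", constant=_NL_PHOSPHOETHANOLAMINE,
            ),
            t["nl_acid"], t["nl_ketene"], t["carboxylate"],
            FragmentTemplate(
                "HeadGroup_140", FragmentMode.CONSTANT_MZ, "negative",
                constant=_ETHANOLAMINE_HEAD_140,
            ),
        ),
    )
    classes["SM"] = LipidClassDefinition(
        "SM", 1,
        # d18:1 sphingosine + phosphocholine (condensed); chain = N-acyl
        Formula("C23H49N2O5P"),
        ("[M+H]+",),
        (
            FragmentTemplate(
                "HeadGroup_184", FragmentMode.CONSTANT_MZ, "positive",
                constant=_PC_HEAD_184,
            ),
            FragmentTemplate(
                "NL_FA1_ketene",
                FragmentMode.PRECURSOR_MINUS_CHAIN_MINUS_CONSTANT,
                "positive", constant=-WATER.mass, chain_index=1,
            ),
        ),
        base="d18:1", base_carbons=18, base_double_bonds=1,
    )
    classes["Cer"] = LipidClassDefinition(
        "Cer", 1, Formula("C18H37NO2"), ("[M+H]+",),
        (
            FragmentTemplate(
                "LCB_264", FragmentMode.CONSTANT_MZ, "positive",
                constant=_LCB_D181_264,
            ),
            FragmentTemplate(
                "NL_H2O", FragmentMode.PRECURSOR_MINUS_CONSTANT, "positive",
                constant=WATER.mass,
            ),
            FragmentTemplate(
                "NL_FA1_ketene",
                FragmentMode.PRECURSOR_MINUS_CHAIN_MINUS_CONSTANT,
                "positive", constant=-WATER.mass, chain_index=1,
            ),
        ),
        base="d18:1", base_carbons=18, base_double_bonds=1,
    )
    classes["MG"] = LipidClassDefinition(
        "MG", 1, Formula("C3H8O3"), ("[M+NH4]+",),
        (
            FragmentTemplate(
                "FA1_acylium", FragmentMode.CHAIN_ACYLIUM, "positive",
                chain_index=1,
            ),
            FragmentTemplate(
                "NL_NH3_H2O", FragmentMode.PRECURSOR_MINUS_CONSTANT, "positive",
                constant=AMMONIA.mass + WATER.mass,
            ),
        ),
    )
    classes["DG"] = LipidClassDefinition(
        "DG", 2, Formula("C3H8O3"), ("[M+NH4]+", "[M+Na]+"),
        (
            FragmentTemplate(
                "NL_FA{i}_NH3",
                FragmentMode.PRECURSOR_MINUS_CHAIN_MINUS_CONSTANT,
                "positive", constant=AMMONIA.mass, adducts=("[M+NH4]+",),
            ),
            FragmentTemplate(
                "NL_FA{i}", FragmentMode.PRECURSOR_MINUS_CHAIN,
                "positive", adducts=("[M+Na]+",),
            ),
        ),
    )
    classes["TG"] = _tg_like("TG")
    classes["OxTG"] = _tg_like("OxTG", require_oxidized=True)
    classes["CE"] = LipidClassDefinition(
        "CE", 1, Formula("C27H46O"), ("[M+NH4]+",),
        (
            FragmentTemplate(
                "Cholestadienyl_369", FragmentMode.CONSTANT_MZ, "positive",
                constant=_CHOLESTADIENYL_369,
            ),
        ),
    )
    return classes


# ---------------------------------------------------------------------------
# Library file format (CSV)

_CORE_COLUMNS = ("class", "annotation", "adduct", "precursor_mz", "chains", "base")

_CHAIN_RE = re.compile(
    r"^(?P<link>O-|P-)?(?P<c>\d+):(?P<d>\d+)(?:\((?P<mods>[^)]*)\))?$"
)


def parse_chain(text: str) -> FattyAcyl:
    """Parse a rendered chain descriptor, e.g. "18:1", "O-16:0",
    "18:1(OH)", "9:0(CHO)"."""
    m = _CHAIN_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse chain descriptor {text!r}")
    linkage = {None: Linkage.ACYL, "O-": Linkage.ALKYL, "P-": Linkage.ALKENYL}[
        m.group("link")
    ]
    mods: list[str] = []
    terminal = Terminal.NONE
    if m.group("mods"):
        for mod in m.group("mods").split(","):
            mod = mod.strip()
            if mod == "CHO":
                terminal = Terminal.CHO
            elif mod == "COOH":
                terminal = Terminal.COOH
            else:
                mods.append(mod)
    return FattyAcyl(
        int(m.group("c")), int(m.group("d")), linkage,
        oxidation=tuple(mods), terminal=terminal,
    )


def write_library(entries: list[LibraryEntry], path: str | Path) -> None:
    """Write entries as UTF-8 CSV: core columns then one column per fragment
    label (union over entries); m/z at 6 decimals."""
    path = Path(path)
    labels: list[str] = []
    for e in entries:
        for lab, _ in e.fragments:
            if lab not in labels:
                labels.append(lab)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(list(_CORE_COLUMNS) + labels)
        for e in entries:
            frag_map = dict(e.fragments)
            w.writerow(
                [
                    e.class_name,
                    e.annotation_text,
                    e.adduct.name,
                    f"{e.precursor_mz:.6f}",
                    ";".join(str(c) for c in e.annotation.chains),
                    e.annotation.base,
                ]
                + [
                    f"{frag_map[lab]:.6f}" if lab in frag_map else ""
                    for lab in labels
                ]
            )


def read_library(path: str | Path) -> list[LibraryEntry]:
    """Read a library CSV written by :func:`write_library` (or authored by
    hand in the same layout)."""
    path = Path(path)
    defs = default_classes()
    entries: list[LibraryEntry] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty library file") from None
        missing = [c for c in _CORE_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
        idx = {c: header.index(c) for c in _CORE_COLUMNS}
        frag_cols = [
            (i, c) for i, c in enumerate(header) if c not in _CORE_COLUMNS
        ]
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                class_name = row[idx["class"]]
                adduct = ADDUCTS[row[idx["adduct"]]]
                precursor = float(row[idx["precursor_mz"]])
                chain_text = row[idx["chains"]]
                chains = tuple(
                    parse_chain(c) for c in chain_text.split(";") if c.strip()
                )
                base = row[idx["base"]]
                frags = tuple(
                    (lab, float(row[i]))
                    for i, lab in frag_cols
                    if i < len(row) and row[i].strip()
                )
            except (KeyError, ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed library row: {exc}")
            cdef = defs.get(class_name)
            if cdef is not None and not base:
                base = cdef.base
            base_c = base_d = 0
            if base:
                bm = re.match(r"^[a-z]?(\d+):(\d+)$", base)
                if bm:
                    base_c, base_d = int(bm.group(1)), int(bm.group(2))
            level = (
                cdef.annotation_level_cap if cdef is not None else AnnotationLevel.ACYL
            )
            if level is AnnotationLevel.POSITION:
                level = AnnotationLevel.ACYL
            annotation = Annotation(
                class_name, level, chains, base, base_c, base_d
            )
            entries.append(
                LibraryEntry(annotation, adduct, precursor, frags, class_name)
            )
    return entries


# ---------------------------------------------------------------------------
# Class-template config round trip (user-editable delimited text)

def write_class_config(
    classes: dict[str, LipidClassDefinition], path: str | Path
) -> None:
    """Serialize fragment templates to CSV (one row per template) so users
    can inspect or edit the class definitions outside Python.  Backbone
    composition and chain count travel in dedicated columns."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            [
                "class", "n_chains", "backbone", "adducts", "base",
                "base_carbons", "base_double_bonds", "require_oxidized",
                "label", "mode", "polarity", "constant", "chain_index",
                "template_adducts",
            ]
        )
        for cdef in classes.values():
            for t in cdef.fragment_templates:
                w.writerow(
                    [
                        cdef.class_name, cdef.n_chains, str(cdef.backbone),
                        "|".join(cdef.adducts), cdef.base, cdef.base_carbons,
                        cdef.base_double_bonds, int(cdef.require_oxidized),
                        t.label, t.mode.value, t.polarity,
                        f"{t.constant:.6f}",
                        t.chain_index if t.chain_index is not None else "",
                        "|".join(t.adducts),
                    ]
                )


def read_class_config(path: str | Path) -> dict[str, LipidClassDefinition]:
    """Read class definitions from the CSV layout of
    :func:`write_class_config`."""
    rows_by_class: dict[str, list[dict]] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"class", "n_chains", "backbone", "adducts", "label", "mode",
                    "polarity"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"{path}: class config must have columns {sorted(required)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                rows_by_class.setdefault(row["class"], []).append(row)
            except KeyError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}")
    classes: dict[str, LipidClassDefinition] = {}
    for name, rows in rows_by_class.items():
        head = rows[0]
        templates = tuple(
            FragmentTemplate(
                label=r["label"],
                mode=FragmentMode(r["mode"]),
                polarity=r["polarity"],
                constant=float(r.get("constant") or 0.0),
                chain_index=int(r["chain_index"]) if r.get("chain_index") else None,
                adducts=tuple(
                    a for a in (r.get("template_adducts") or "").split("|") if a
                ),
            )
            for r in rows
        )
        classes[name] = LipidClassDefinition(
            class_name=name,
            n_chains=int(head["n_chains"]),
            backbone=Formula(head["backbone"]),
            adducts=tuple(a for a in head["adducts"].split("|") if a),
            fragment_templates=templates,
            base=head.get("base") or "",
            base_carbons=int(head.get("base_carbons") or 0),
            base_double_bonds=int(head.get("base_double_bonds") or 0),
            require_oxidized=bool(int(head.get("require_oxidized") or 0)),
        )
    return classes
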