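"""The identification engine: precursor matching, scan assignment,
fragment profiling, thresholding, rule evaluation, confidence coding and
summed-intensity ranking.

The pipeline, per feature:

1. exact-mass precursor match against the in silico library (absolute Da
   tolerance, adducts restricted to the run's polarity);
2. MS/MS scan assignment by RT window and precursor-isolation window
   (half the isolation width each side of the feature m/z);
3. per-fragment profiling across assigned scans — scan count, maximum
   intensity, mean observed m/z, RT at the maximum (ppm tolerance);
4. thresholding: a fragment counts as observed when its maximum intensity
   and scan count meet the user thresholds;
5. rule evaluation: each class/adduct rule is a set of n-of-m groups over
   fragment labels, split into class-indicative and chain-indicative
   groups;
6. confidence coding: 1 = class and fatty-acyl constituents, 3 = class
   only, 4 = precursor m/z only (2 is reserved for data-independent
   acquisition and never emitted).  Annotations never claim more structure
   than the passing groups support: acyl-level text only at confidence 1,
   sum composition at 3 and 4;
7. ranking of co-eluting candidates by the summed maximum intensity of all
   matched in silico fragments, whether or not they were required for
   confirmation.
"""

from __future__ import annotations

import bisect
import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

from .chem import AnnotationLevel, ppm_error
from .data_io import Feature, MS2Spectrum
from .library import LibraryEntry

__all__ = [
    "EngineParams",
    "FeatureLipidPair",
    "FragmentObservation",
    "RuleGroup",
    "IdentificationRule",
    "Identification",
    "match_precursors",
    "assign_scans",
    "profile_fragments",
    "apply_thresholds",
    "evaluate_rule",
    "rank_identifications",
    "annotate_table",
    "default_rules",
    "write_rules",
    "read_rules",
]


@dataclass(frozen=True)
class EngineParams:
    """User-tunable matching parameters.

    MS1 tolerance is absolute (Da); fragment tolerance is relative (ppm).
    ``isolation_window_mz`` is the full isolation width used during
    acquisition; scans match a feature within half of it each side.
    ``min_intensity`` depends on the mass analyzer and noise level and has
    no universal default — 1000 suits orbitrap data at typical settings.
    """

    ms1_tol_da: float = 0.005
    frag_tol_ppm: float = 10.0
    rt_window_min: float = 0.3
    isolation_window_mz: float = 1.0
    min_intensity: float = 1000.0
    min_scans: int = 1
    keep_unconfirmed: bool = False  # emit confidence-4 precursor-only IDs

    def __post_init__(self):
        for name in ("ms1_tol_da", "frag_tol_ppm", "rt_window_min",
                     "isolation_window_mz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_scans < 1:
            raise ValueError("min_scans must be >= 1")


@dataclass(frozen=True)
class FeatureLipidPair:
    feature: Feature
    candidate: LibraryEntry


@dataclass(frozen=True)
class FragmentObservation:
    """Profile of one theoretical fragment across a feature's scans."""

    label: str
    theoretical_mz: float
    n_scans: int = 0
    max_intensity: float = 0.0
    mean_observed_mz: float = 0.0
    rt_at_max: float = 0.0
    passes: bool = False


@dataclass(frozen=True)
class RuleGroup:
    """n-of-m requirement over fragment labels.  ``kind`` marks whether the
    group evidences the lipid class ("class") or a fatty-acyl chain
    ("chain"); chain groups gate acyl-level annotation."""

    labels: tuple[str, ...]
    min_count: int = 1
    kind: str = "chain"

    def __post_init__(self):
        if not self.labels:
            raise ValueError("rule group needs at least one label")
        if self.min_count < 1 or self.min_count > len(self.labels):
            raise ValueError("min_count must be in 1..len(labels)")
        if self.kind not in ("class", "chain"):
            raise ValueError(f"group kind must be class/chain, got {self.kind!r}")
        object.__setattr__(self, "labels", tuple(self.labels))

    def satisfied(self, passing: set[str]) -> bool:
        return sum(1 for lab in self.labels if lab in passing) >= self.min_count


@dataclass(frozen=True)
class IdentificationRule:
    class_name: str
    adduct_name: str
    groups: tuple[RuleGroup, ...]

    def __post_init__(self):
        if not self.groups:
            raise ValueError(
                f"rule {self.class_name}/{self.adduct_name}: no groups"
            )
        object.__setattr__(self, "groups", tuple(self.groups))


@dataclass(frozen=True)
class Identification:
    annotation_text: str
    class_name: str
    adduct_name: str
    confidence: int  # 1, 3 or 4 (2 reserved for DIA)
    summed_intensity: float
    observations: tuple[FragmentObservation, ...] = ()
    rank: int = 0

    def __post_init__(self):
        if self.confidence not in (1, 2, 3, 4):
            raise ValueError(f"confidence must be 1..4, got {self.confidence}")


# ---------------------------------------------------------------------------
# Steps 1-7

def match_precursors(
    features: list[Feature],
    library: list[LibraryEntry],
    ms1_tol_da: float,
    polarity: str | None = None,
) -> list[FeatureLipidPair]:
    """Step 1: all (feature, library entry) pairs whose precursor m/z lies
    within an absolute Da tolerance of the feature m/z.  Only adducts of the
    requested polarity are considered; dimers, multimers and in-source
    fragments are not modelled."""
    if ms1_tol_da <= 0:
        raise ValueError("ms1_tol_da must be > 0")
    entries = [
        e for e in library
        if polarity is None or e.adduct.polarity == polarity
    ]
    entries.sort(key=lambda e: e.precursor_mz)
    mzs = [e.precursor_mz for e in entries]
    pairs: list[FeatureLipidPair] = []
    for feat in features:
        lo = bisect.bisect_left(mzs, feat.mz - ms1_tol_da)
        hi = bisect.bisect_right(mzs, feat.mz + ms1_tol_da)
        for e in entries[lo:hi]:
            pairs.append(FeatureLipidPair(feat, e))
    return pairs


def assign_scans(
    feature: Feature,
    spectra: list[MS2Spectrum],
    rt_window_min: float,
    isolation_window_mz: float,
) -> list[MS2Spectrum]:
    """Step 2: MS/MS scans whose RT lies within the window of the feature
    apex and whose isolation target lies within half the isolation width of
    the feature m/z."""
    if rt_window_min <= 0 or isolation_window_mz <= 0:
        raise ValueError("windows must be > 0")
    half = isolation_window_mz / 2.0
    return [
        s
        for s in spectra
        if abs(s.rt - feature.rt) <= rt_window_min
        and abs(s.precursor_mz - feature.mz) <= half
    ]


def profile_fragments(
    pair: FeatureLipidPair,
    scans: list[MS2Spectrum],
    frag_tol_ppm: float,
) -> list[FragmentObservation]:
    """Step 3: per theoretical fragment, the number of scans containing a
    peak within the ppm window, the maximum matched intensity, the mean
    observed m/z and the RT of the scan holding the maximum.  When several
    peaks of one scan fall in-window, the most intense one counts."""
    if frag_tol_ppm <= 0:
        raise ValueError("frag_tol_ppm must be > 0")
    observations: list[FragmentObservation] = []
    for label, theo in pair.candidate.fragments:
        tol = theo * frag_tol_ppm * 1e-6
        n = 0
        max_int = 0.0
        rt_at_max = 0.0
        mz_sum = 0.0
        for scan in scans:
            best: tuple[float, float] | None = None
            for mz, intensity in scan.peaks:
                if mz < theo - tol:
                    continue
                if mz > theo + tol:
                    break
                if best is None or intensity > best[1]:
                    best = (mz, intensity)
            if best is None:
                continue
            n += 1
            mz_sum += best[0]
            if best[1] > max_int:
                max_int = best[1]
                rt_at_max = scan.rt
        observations.append(
            FragmentObservation(
                label=label,
                theoretical_mz=theo,
                n_scans=n,
                max_intensity=max_int,
                mean_observed_mz=(mz_sum / n) if n else 0.0,
                rt_at_max=rt_at_max,
            )
        )
    return observations


def apply_thresholds(
    observations: list[FragmentObservation],
    min_intensity: float,
    min_scans: int = 1,
) -> list[FragmentObservation]:
    """Step 4: set the pass flag — observed above the intensity threshold in
    at least the required number of scans."""
    if min_scans < 1:
        raise ValueError("min_scans must be >= 1")
    return [
        replace(
            obs,
            passes=(obs.max_intensity >= min_intensity and obs.n_scans >= min_scans),
        )
        for obs in observations
    ]


def evaluate_rule(
    observations: list[FragmentObservation],
    rule: IdentificationRule,
) -> int | None:
    """Steps 5-6: confidence code from the rule's groups.

    Returns 1 when every group is satisfied, 3 when every class-indicative
    group is satisfied (and at least one exists) but some chain group is
    not, and None otherwise (the caller may still report confidence 4 when
    precursor-only reporting is enabled).
    """
    passing = {obs.label for obs in observations if obs.passes}
    class_groups = [g for g in rule.groups if g.kind == "class"]
    chain_groups = [g for g in rule.groups if g.kind == "chain"]
    if all(g.satisfied(passing) for g in rule.groups):
        return 1
    if class_groups and all(g.satisfied(passing) for g in class_groups):
        return 3
    return None


def summed_fragment_intensity(observations: list[FragmentObservation]) -> float:
    """Step 7 statistic: the sum over all in silico fragments observed in at
    least one scan of their maximum intensity — including fragments not
    required for confirmation and regardless of the pass threshold."""
    return sum(o.max_intensity for o in observations if o.n_scans >= 1)


def rank_identifications(
    identifications: list[Identification],
) -> list[Identification]:
    """Step 7: sort one feature's identifications by summed fragment
    intensity, descending; ties break by annotation text then adduct
    (deterministic).  Ranks are reassigned 1..n."""
    ordered = sorted(
        identifications,
        key=lambda i: (-i.summed_intensity, i.annotation_text, i.adduct_name),
    )
    return [replace(ident, rank=r) for r, ident in enumerate(ordered, start=1)]


def _rule_index(
    rules: list[IdentificationRule],
) -> dict[tuple[str, str], IdentificationRule]:
    index: dict[tuple[str, str], IdentificationRule] = {}
    for r in rules:
        key = (r.class_name, r.adduct_name)
        if key in index:
            raise ValueError(f"duplicate rule for {key}")
        index[key] = r
    return index


def annotate_table(
    features: list[Feature],
    spectra: list[MS2Spectrum],
    library: list[LibraryEntry],
    rules: list[IdentificationRule],
    params: EngineParams = EngineParams(),
    polarity: str | None = None,
) -> dict[str, list[Identification]]:
    """Run the full pipeline and return ranked identifications per
    feature id.  Candidates whose class/adduct has no rule configured are
    rejected at this stage rather than silently passed."""
    rule_map = _rule_index(rules)
    pairs = match_precursors(features, library, params.ms1_tol_da, polarity)
    scan_cache: dict[str, list[MS2Spectrum]] = {}
    per_feature: dict[str, list[Identification]] = {f.feature_id: [] for f in features}
    for pair in pairs:
        feat = pair.feature
        key = (pair.candidate.class_name, pair.candidate.adduct.name)
        rule = rule_map.get(key)
        if rule is None:
            raise ValueError(
                f"no identification rule configured for class/adduct {key}"
            )
        if feat.feature_id not in scan_cache:
            scan_cache[feat.feature_id] = assign_scans(
                feat, spectra, params.rt_window_min, params.isolation_window_mz
            )
        scans = scan_cache[feat.feature_id]
        observations = profile_fragments(pair, scans, params.frag_tol_ppm)
        observations = apply_thresholds(
            observations, params.min_intensity, params.min_scans
        )
        confidence = evaluate_rule(observations, rule) if scans else None
        if confidence is None:
            if not params.keep_unconfirmed:
                continue
            confidence = 4
        # structural resolution: acyl-level text only at confidence 1
        annotation = pair.candidate.annotation
        if confidence != 1:
            annotation = annotation.at_level(AnnotationLevel.SUM)
        per_feature[feat.feature_id].append(
            Identification(
                annotation_text=annotation.render(),
                class_name=pair.candidate.class_name,
                adduct_name=pair.candidate.adduct.name,
                confidence=confidence,
                summed_intensity=summed_fragment_intensity(observations),
                observations=tuple(observations),
            )
        )
    return {
        fid: rank_identifications(idents) for fid, idents in per_feature.items()
    }


# ---------------------------------------------------------------------------
# Default rules for the shipped classes

def _chain_slots(class_name: str) -> int:
    from .library import default_classes

    return default_classes()[class_name].n_chains


def default_rules() -> list[IdentificationRule]:
    """Identification rules for the shipped classes.

    Negative-mode diacyl phospholipids require the carboxylate of every
    constituent chain; protonated PCs require the m/z 184.0733 head-group
    ion plus at least one fatty-acyl-indicative neutral loss.  Choline
    head-group-only matches (PC/SM) yield class-level identifications
    (confidence 3).
    """
    R = RuleGroup
    rules: list[IdentificationRule] = []

    def acyl_nl_labels(i: int) -> tuple[str, ...]:
        return (f"NL_FA{i}_acid", f"NL_FA{i}_ketene")

    for pc in ("PC", "OxPC"):
        rules.append(
            IdentificationRule(
                pc, "[M+H]+",
                (
                    R(("HeadGroup_184",), 1, "class"),
                    R(acyl_nl_labels(1) + acyl_nl_labels(2), 1, "chain"),
                ),
            )
        )
        rules.append(
            IdentificationRule(
                pc, "[M+HCO2]-",
                (
                    R(("FA1_carboxylate",), 1, "chain"),
                    R(("FA2_carboxylate",), 1, "chain"),
                ),
            )
        )
    rules.append(
        IdentificationRule(
            "PE", "[M+H]+",
            (
                R(("NL_PhosphoEthanolamine",), 1, "class"),
                R(acyl_nl_labels(1) + acyl_nl_labels(2), 1, "chain"),
            ),
        )
    )
    rules.append(
        IdentificationRule(
            "PE", "[M-H]-",
            (
                R(("FA1_carboxylate",), 1, "chain"),
                R(("FA2_carboxylate",), 1, "chain"),
            ),
        )
    )
    rules.append(
        IdentificationRule(
            "PS", "[M+H]+",
            (
                R(("NL_PhosphoSerine",), 1, "class"),
                R(acyl_nl_labels(1) + acyl_nl_labels(2), 1, "chain"),
            ),
        )
    )
    rules.append(
        IdentificationRule(
            "PS", "[M-H]-",
            (
                R(("NL_Serine",), 1, "class"),
                R(("FA1_carboxylate",), 1, "chain"),
                R(("FA2_carboxylate",), 1, "chain"),
            ),
        )
    )
    for gpl in ("PG", "PA"):
        rules.append(
            IdentificationRule(
                gpl, "[M-H]-",
                (
                    R(("Glycerophosphate_153",), 1, "class"),
                    R(("FA1_carboxylate",), 1, "chain"),
                    R(("FA2_carboxylate",), 1, "chain"),
                ),
            )
        )
    rules.append(
        IdentificationRule(
            "PI", "[M-H]-",
            (
                R(("InositolPhosphate_241",), 1, "class"),
                R(("FA1_carboxylate",), 1, "chain"),
                R(("FA2_carboxylate",), 1, "chain"),
            ),
        )
    )
    rules.append(
        IdentificationRule(
            "PI", "[M+NH4]+",
            (
                R(("NL_InositolPhosphate_NH3",), 1, "class"),
                R(("NL_FA1_NH3", "NL_FA2_NH3"), 1, "chain"),
            ),
        )
    )
    rules.append(
        IdentificationRule(
            "LPC", "[M+H]+",
            (
                R(("HeadGroup_184",), 1, "class"),
                R(acyl_nl_labels(1), 1, "chain"),
            ),
        )
    )
    rules.append(
        IdentificationRule(
            "LPC", "[M+HCO2]-", (R(("FA1_carboxylate",), 1, "chain"),)
        )
    )
    rules.append(
        IdentificationRule(
            "LPE", "[M+H]+",
            (
                R(("NL_PhosphoEthanolamine",), 1, "class"),
                R(acyl_nl_labels(1), 1, "chain"),
            ),
        )
    )
    rules.append(
        IdentificationRule(
            "LPE", "[M-H]-", (R(("FA1_carboxylate",), 1, "chain"),)
        )
    )
    rules.append(
        IdentificationRule(
            "SM", "[M+H]+",
            (
                R(("HeadGroup_184",), 1, "class"),
                R(("NL_FA1_ketene",), 1, "chain"),
            ),
        )
    )
    rules.append(
        IdentificationRule(
            "Cer", "[M+H]+",
            (
                R(("LCB_264", "NL_H2O"), 1, "class"),
                R(("NL_FA1_ketene",), 1, "chain"),
            ),
        )
    )
    rules.append(
        IdentificationRule(
            "MG", "[M+NH4]+", (R(("FA1_acylium",), 1, "chain"),)
        )
    )
    rules.append(
        IdentificationRule(
            "DG", "[M+NH4]+",
            (
                R(("NL_FA1_NH3",), 1, "chain"),
                R(("NL_FA2_NH3",), 1, "chain"),
            ),
        )
    )
    rules.append(
        IdentificationRule(
            "DG", "[M+Na]+",
            (R(("NL_FA1",), 1, "chain"), R(("NL_FA2",), 1, "chain")),
        )
    )
    for tg in ("TG", "OxTG"):
        rules.append(
            IdentificationRule(
                tg, "[M+NH4]+",
                tuple(R((f"NL_FA{i}_NH3",), 1, "chain") for i in (1, 2, 3)),
            )
        )
        rules.append(
            IdentificationRule(
                tg, "[M+Na]+",
                tuple(R((f"NL_FA{i}",), 1, "chain") for i in (1, 2, 3)),
            )
        )
    rules.append(
        IdentificationRule(
            "CE", "[M+NH4]+", (R(("Cholestadienyl_369",), 1, "class"),)
        )
    )
    return rules


def write_rules(rules: list[IdentificationRule], path: str | Path) -> None:
    """Serialize rules to CSV, one row per (class, adduct, group, label)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["class", "adduct", "group", "kind", "min_count", "label"])
        for rule in rules:
            for gi, group in enumerate(rule.groups, start=1):
                for label in group.labels:
                    w.writerow(
                        [rule.class_name, rule.adduct_name, gi, group.kind,
                         group.min_count, label]
                    )


def read_rules(path: str | Path) -> list[IdentificationRule]:
    """Read rules from the CSV layout of :func:`write_rules`."""
    grouped: dict[tuple[str, str], dict[int, dict]] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"class", "adduct", "group", "kind", "min_count", "label"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: rule file must have columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                key = (row["class"], row["adduct"])
                gi = int(row["group"])
                g = grouped.setdefault(key, {}).setdefault(
                    gi, {"kind": row["kind"], "min_count": int(row["min_count"]),
                         "labels": []}
                )
                g["labels"].append(row["label"])
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed rule row: {exc}")
    rules = []
    for (class_name, adduct), groups in grouped.items():
        rules.append(
            IdentificationRule(
                class_name,
                adduct,
                tuple(
                    RuleGroup(tuple(g["labels"]), g["min_count"], g["kind"])
                    for _, g in sorted(groups.items())
                ),
            )
        )
    return rules
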