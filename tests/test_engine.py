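"""Identification engine: precursor matching, scan assignment, fragment
profiling, thresholding, rule logic, confidence coding and ranking —
including equivalence against a naive brute-force reference and the
monotonicity/soundness properties."""

import itertools

import pytest

from lipidrules.chem import FattyAcyl
from lipidrules.data_io import Feature, MS2Spectrum
from lipidrules.engine import (
    EngineParams,
    FeatureLipidPair,
    IdentificationRule,
    RuleGroup,
    annotate_table,
    apply_thresholds,
    assign_scans,
    default_rules,
    evaluate_rule,
    match_precursors,
    profile_fragments,
    rank_identifications,
    read_rules,
    summed_fragment_intensity,
    write_rules,
    Identification,
)
from lipidrules.library import build_library, default_classes


FEATURE = Feature("F1", 850.5604, 5.92)


def scan(n, rt, peaks, precursor=850.5604):
    return MS2Spectrum(n, precursor, rt, tuple(peaks))


class TestMatchPrecursors:
    def test_within_tolerance(self, pc38_6_isomer_library):
        pairs = match_precursors([FEATURE], pc38_6_isomer_library, 0.005)
        # both isobaric isomers pair with the one feature
        assert len(pairs) == 2

    def test_outside_tolerance(self, pc38_6_isomer_library):
        feat = Feature("F2", 850.62, 5.92)
        assert match_precursors([feat], pc38_6_isomer_library, 0.005) == []

    def test_polarity_restriction(self, pc_class):
        chains = (FattyAcyl(16, 0), FattyAcyl(22, 6))
        entries = build_library(pc_class, [chains])  # both adducts
        pos_feat = Feature("F3", entries[0].precursor_mz, 5.9)
        pairs = match_precursors([pos_feat], entries, 0.005, polarity="negative")
        assert all(p.candidate.adduct.polarity == "negative" for p in pairs)


class TestAssignScans:
    def test_window_logic(self):
        scans = [
            scan(1, 5.90, [], precursor=850.56),
            scan(2, 7.92, [], precursor=850.56),   # RT too far
            scan(3, 5.93, [], precursor=851.40),   # outside isolation half-width
        ]
        got = assign_scans(FEATURE, scans, rt_window_min=0.3,
                           isolation_window_mz=1.0)
        assert [s.scan_number for s in got] == [1]

    def test_empty_assignment(self):
        assert assign_scans(FEATURE, [], 0.3, 1.0) == []


class TestProfileFragments:
    def make_pair(self, pc38_6_isomer_library):
        return FeatureLipidPair(FEATURE, pc38_6_isomer_library[0])

    def test_scan_count_and_max(self, pc38_6_isomer_library):
        pair = self.make_pair(pc38_6_isomer_library)
        scans = [
            scan(1, 5.90, [(255.2330, 8e4)]),
            scan(2, 5.92, [(255.2331, 5e4)]),
            scan(3, 5.94, [(255.2329, 2e4)]),
            scan(4, 5.96, [(400.0, 1e4)]),
        ]
        obs = {o.label: o for o in profile_fragments(pair, scans, 10.0)}
        o = obs["FA1_carboxylate"]
        assert o.n_scans == 3
        assert o.max_intensity == 8e4
        assert o.rt_at_max == 5.90
        assert o.mean_observed_mz == pytest.approx(255.2330, abs=1e-4)

    def test_absent_fragment(self, pc38_6_isomer_library):
        pair = self.make_pair(pc38_6_isomer_library)
        obs = {o.label: o for o in profile_fragments(pair, [scan(1, 5.9, [])], 10.0)}
        assert obs["FA2_carboxylate"].n_scans == 0

    def test_most_intense_in_window_wins(self, pc38_6_isomer_library):
        pair = self.make_pair(pc38_6_isomer_library)
        scans = [scan(1, 5.92, [(255.2328, 1e3), (255.2333, 5e3)])]
        obs = {o.label: o for o in profile_fragments(pair, scans, 10.0)}
        o = obs["FA1_carboxylate"]
        assert o.n_scans == 1
        assert o.max_intensity == 5e3
        assert o.mean_observed_mz == pytest.approx(255.2333, abs=1e-6)

    def test_ppm_window_respected(self, pc38_6_isomer_library):
        pair = self.make_pair(pc38_6_isomer_library)
        off = 255.2330 * (1 + 20e-6)  # 20 ppm away
        obs = {o.label: o
               for o in profile_fragments(pair, [scan(1, 5.92, [(off, 1e5)])], 10.0)}
        assert obs["FA1_carboxylate"].n_scans == 0


class TestThresholds:
    def obs(self, max_intensity, n_scans):
        from lipidrules.engine import FragmentObservation

        return FragmentObservation("x", 255.233, n_scans, max_intensity,
                                   255.233, 5.9)

    @pytest.mark.parametrize(
        "max_int,n,min_int,min_scans,expected",
        [
            (1200, 1, 1000, 1, True),
            (900, 1, 1000, 1, False),
            (1200, 1, 1000, 2, False),
            (1000, 2, 1000, 2, True),
            (0, 0, 1000, 1, False),
        ],
    )
    def test_pass_logic(self, max_int, n, min_int, min_scans, expected):
        (out,) = apply_thresholds([self.obs(max_int, n)], min_int, min_scans)
        assert out.passes is expected


def _observations(passing_labels, all_labels):
    from lipidrules.engine import FragmentObservation

    return [
        FragmentObservation(lab, 100.0, 1 if lab in passing_labels else 0,
                            5e3 if lab in passing_labels else 0.0,
                            100.0, 5.9, passes=lab in passing_labels)
        for lab in all_labels
    ]


class TestEvaluateRule:
    PC_FORMATE = IdentificationRule(
        "PC", "[M+HCO2]-",
        (RuleGroup(("FA1_carboxylate",), 1, "chain"),
         RuleGroup(("FA2_carboxylate",), 1, "chain")),
    )
    PC_H = IdentificationRule(
        "PC", "[M+H]+",
        (RuleGroup(("HeadGroup_184",), 1, "class"),
         RuleGroup(("NL_FA1_acid", "NL_FA2_acid"), 1, "chain")),
    )
    LABELS = ("FA1_carboxylate", "FA2_carboxylate", "HeadGroup_184",
              "NL_FA1_acid", "NL_FA2_acid")

    def test_both_carboxylates_give_confidence_1(self):
        obs = _observations({"FA1_carboxylate", "FA2_carboxylate"}, self.LABELS)
        assert evaluate_rule(obs, self.PC_FORMATE) == 1

    def test_headgroup_only_gives_confidence_3(self):
        obs = _observations({"HeadGroup_184"}, self.LABELS)
        assert evaluate_rule(obs, self.PC_H) == 3

    def test_one_carboxylate_is_not_enough(self):
        obs = _observations({"FA1_carboxylate"}, self.LABELS)
        assert evaluate_rule(obs, self.PC_FORMATE) is None

    def test_chain_without_class_group_is_nothing(self):
        obs = _observations({"NL_FA1_acid"}, self.LABELS)
        assert evaluate_rule(obs, self.PC_H) is None


class TestRanking:
    def ident(self, text, total):
        return Identification(text, "PC", "[M+HCO2]-", 1, total)

    def test_descending_by_summed_intensity(self):
        ranked = rank_identifications(
            [self.ident("B", 3e4), self.ident("A", 8e4)]
        )
        assert [(i.rank, i.annotation_text) for i in ranked] == [(1, "A"), (2, "B")]

    def test_tie_breaks_alphabetical(self):
        ranked = rank_identifications(
            [self.ident("Z", 5e4), self.ident("A", 5e4)]
        )
        assert [i.annotation_text for i in ranked] == ["A", "Z"]
        assert [i.rank for i in ranked] == [1, 2]

    def test_summation_includes_unconfirmed_fragments(self):
        # fragments seen in >=1 scan count toward the sum even below the
        # confirmation intensity threshold
        obs = _observations({"FA1_carboxylate"}, ("FA1_carboxylate",))
        from lipidrules.engine import FragmentObservation

        weak = FragmentObservation("NL_CH3_formate", 790.5, 1, 200.0, 790.5,
                                   5.9, passes=False)
        assert summed_fragment_intensity(obs + [weak]) == 5e3 + 200.0

    def test_permutation_preserved(self):
        idents = [self.ident(t, v) for t, v in
                  [("A", 1.0), ("B", 5.0), ("C", 3.0)]]
        ranked = rank_identifications(idents)
        assert sorted(i.annotation_text for i in ranked) == ["A", "B", "C"]
        sums = [i.summed_intensity for i in ranked]
        assert sums == sorted(sums, reverse=True)


# ---------------------------------------------------------------------------
# Brute-force reference implementation (independent of the engine path)

def brute_force_annotate(features, spectra, library, rules, params):
    """Naive reference: enumerate every (candidate, scan, peak) triple."""
    rule_map = {(r.class_name, r.adduct_name): r for r in rules}
    out = {}
    for feat in features:
        idents = []
        for entry in library:
            if abs(feat.mz - entry.precursor_mz) > params.ms1_tol_da:
                continue
            scans = [
                s for s in spectra
                if abs(s.rt - feat.rt) <= params.rt_window_min
                and abs(s.precursor_mz - feat.mz) <= params.isolation_window_mz / 2
            ]
            per_frag = {}
            for label, theo in entry.fragments:
                hits = []
                for s in scans:
                    in_window = [
                        (mz, i) for mz, i in s.peaks
                        if abs(mz - theo) <= theo * params.frag_tol_ppm * 1e-6
                    ]
                    if in_window:
                        hits.append(max(in_window, key=lambda p: p[1]))
                per_frag[label] = hits
            passing = {
                lab for lab, hits in per_frag.items()
                if hits and max(i for _, i in hits) >= params.min_intensity
                and len(hits) >= params.min_scans
            }
            rule = rule_map[(entry.class_name, entry.adduct.name)]
            groups_ok = [
                sum(1 for lab in g.labels if lab in passing) >= g.min_count
                for g in rule.groups
            ]
            class_ok = [
                ok for g, ok in zip(rule.groups, groups_ok) if g.kind == "class"
            ]
            if scans and all(groups_ok):
                conf = 1
            elif scans and class_ok and all(class_ok):
                conf = 3
            else:
                continue
            total = sum(
                max(i for _, i in hits) for hits in per_frag.values() if hits
            )
            from lipidrules.chem import AnnotationLevel

            ann = entry.annotation
            if conf != 1:
                ann = ann.at_level(AnnotationLevel.SUM)
            idents.append((ann.render(), entry.adduct.name, conf, total))
        idents.sort(key=lambda t: (-t[3], t[0], t[1]))
        out[feat.feature_id] = idents
    return out


class TestBruteForceEquivalence:
    def test_engine_matches_naive_reference(self):
        # <=5 isobaric candidates, messy peak lists
        pc = default_classes()["PC"]
        chain_sets = [
            (FattyAcyl(16, 0), FattyAcyl(22, 6)),
            (FattyAcyl(18, 2), FattyAcyl(20, 4)),
            (FattyAcyl(18, 1), FattyAcyl(20, 5)),
            (FattyAcyl(18, 3), FattyAcyl(20, 3)),
            (FattyAcyl(16, 1), FattyAcyl(22, 5)),
        ]
        library = build_library(pc, chain_sets, ["[M+HCO2]-"])
        feats = [Feature("F1", 850.5604, 5.92)]
        peaks1 = [
            (255.2330, 8e4), (327.2330, 5e4), (279.2329, 4e4),
            (303.2330, 2.5e4), (281.2486, 1.5e4), (317.2486, 900.0),
            (500.0, 3e3),
        ]
        peaks2 = [
            (255.2331, 6e4), (327.2331, 3e4), (279.2326, 3.9e4),
            (303.2334, 1e4), (277.2172, 1.2e4),
        ]
        spectra = [scan(1, 5.90, peaks1), scan(2, 5.94, peaks2)]
        params = EngineParams(min_intensity=1000.0)
        rules = default_rules()
        engine = annotate_table(feats, spectra, library, rules, params,
                                polarity="negative")
        naive = brute_force_annotate(feats, spectra, library, rules, params)
        got = [
            (i.annotation_text, i.adduct_name, i.confidence,
             pytest.approx(i.summed_intensity))
            for i in engine["F1"]
        ]
        assert got == [tuple(t) for t in naive["F1"]]


class TestProperties:
    def run(self, params, pc38_6_isomer_library):
        feats = [FEATURE]
        spectra = [
            scan(1, 5.90, [(255.2330, 8e4), (327.2330, 5e4),
                           (279.2329, 4e4), (303.2330, 2e3)]),
            scan(2, 5.94, [(255.2330, 6e4), (327.2330, 3e4),
                           (279.2329, 3e4)]),
        ]
        return annotate_table(feats, spectra, pc38_6_isomer_library,
                              default_rules(), params, polarity="negative")

    def test_threshold_monotonicity(self, pc38_6_isomer_library):
        # raising min_intensity or min_scans never adds confidence-1 ids
        def conf1(params):
            res = self.run(params, pc38_6_isomer_library)
            return {
                (i.annotation_text, i.adduct_name)
                for i in res["F1"]
                if i.confidence == 1
            }

        base = EngineParams(min_intensity=1000.0, min_scans=1)
        for stricter in (
            EngineParams(min_intensity=2500.0, min_scans=1),
            EngineParams(min_intensity=1000.0, min_scans=2),
            EngineParams(min_intensity=5e4, min_scans=2),
        ):
            assert conf1(stricter) <= conf1(base)

    def test_structural_resolution_soundness(self, pc38_6_isomer_library):
        # acyl-level ("_") text appears only at confidence 1
        res = self.run(EngineParams(min_intensity=1e5, keep_unconfirmed=True),
                       pc38_6_isomer_library)
        for ident in res["F1"]:
            if "_" in ident.annotation_text:
                assert ident.confidence == 1

    def test_no_scans_only_confidence_4(self, pc38_6_isomer_library):
        res = annotate_table([FEATURE], [], pc38_6_isomer_library,
                             default_rules(),
                             EngineParams(keep_unconfirmed=True),
                             polarity="negative")
        assert res["F1"]
        assert all(i.confidence == 4 for i in res["F1"])
        assert all("_" not in i.annotation_text for i in res["F1"])

    def test_unconfirmed_dropped_by_default(self, pc38_6_isomer_library):
        res = annotate_table([FEATURE], [], pc38_6_isomer_library,
                             default_rules(), EngineParams(),
                             polarity="negative")
        assert res["F1"] == []

    def test_unknown_class_rule_rejected(self, pc38_6_isomer_library):
        with pytest.raises(ValueError, match="no identification rule"):
            annotate_table([FEATURE], [], pc38_6_isomer_library,
                           [IdentificationRule(
                               "XX", "[M+H]+",
                               (RuleGroup(("a",), 1, "class"),))],
                           EngineParams(), polarity="negative")


class TestRuleFile:
    def test_round_trip(self, tmp_path):
        rules = default_rules()
        p = tmp_path / "rules.csv"
        write_rules(rules, p)
        back = read_rules(p)
        as_key = lambda rs: {
            (r.class_name, r.adduct_name): tuple(
                (g.kind, g.min_count, g.labels) for g in r.groups
            )
            for r in rs
        }
        assert as_key(back) == as_key(rules)

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "rules.csv"
        p.write_text("class,adduct\nPC,[M+H]+\n")
        with pytest.raises(ValueError, match="columns"):
            read_rules(p)
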