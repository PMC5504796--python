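"""Library generation: chain-set combinatorics against the closed form,
oxidized fatty-acyl enumeration, class-template instantiation and the
library file round trip."""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipidrules.chem import FattyAcyl, Formula, fragment_ion_mz, round_half_up
from lipidrules.library import (
    DEFAULT_FA_POOL,
    build_class_library,
    build_default_library,
    build_library,
    default_classes,
    enumerate_chain_sets,
    generate_oxidized_fas,
    parse_chain,
    read_class_config,
    read_library,
    write_class_config,
    write_library,
)


def brute_force_multisets(pool, k):
    """Oracle: enumerate all ordered k-tuples, deduplicate as sorted
    multisets."""
    seen = set()
    for combo in itertools.product(pool, repeat=k):
        seen.add(tuple(sorted(combo, key=lambda f: f.sort_key)))
    return seen


class TestEnumerateChainSets:
    def test_default_pool_size_is_39(self):
        assert len(DEFAULT_FA_POOL) == 39

    @pytest.mark.parametrize("k,expected", [(2, 780), (3, 10660)])
    def test_39_fa_pool_counts(self, k, expected):
        # C(39+k-1, k): 780 pairs, 10660 triples
        sets = enumerate_chain_sets(list(DEFAULT_FA_POOL), k)
        assert len(sets) == expected
        assert len(set(sets)) == expected  # no permutation duplicates

    def test_pairs_match_brute_force(self):
        pool = list(DEFAULT_FA_POOL)[:12]
        assert set(enumerate_chain_sets(pool, 2)) == brute_force_multisets(pool, 2)

    @given(n=st.integers(1, 10), k=st.integers(1, 4))
    @settings(deadline=None, derandomize=True)
    def test_count_matches_closed_form(self, n, k):
        pool = [FattyAcyl(c, 0) for c in range(2, 2 + n)]
        assert len(enumerate_chain_sets(pool, k)) == math.comb(n + k - 1, k)

    def test_singleton_pool(self):
        fa = FattyAcyl(18, 0)
        assert enumerate_chain_sets([fa], 2) == [(fa, fa)]

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            enumerate_chain_sets([FattyAcyl(18, 0)], 5)

    def test_require_oxidized_filters(self):
        pool = [FattyAcyl(16, 0), FattyAcyl(18, 1, oxidation=("OH",))]
        sets = enumerate_chain_sets(pool, 2, require_oxidized=True)
        assert all(any(fa.is_oxidized for fa in s) for s in sets)
        assert len(sets) == 2  # (ox,ox) and (16:0,ox)


class TestGenerateOxidizedFas:
    def test_saturated_pool_yields_nothing(self):
        long_ox, short_ox = generate_oxidized_fas([FattyAcyl(18, 0)])
        assert long_ox == [] and short_ox == []

    def test_18_1_long_chain_collapses_by_formula(self):
        long_ox, _ = generate_oxidized_fas([FattyAcyl(18, 1)])
        # one double bond allows one addition: +O (O and OH collide) and +2O
        deltas = sorted(
            round(fa.mass - FattyAcyl(18, 1).mass, 4) for fa in long_ox
        )
        assert deltas == [15.9949, 31.9898]

    def test_18_1_cleavage_products(self):
        # Delta-9 cleavage: 9-carbon chains with CHO and COOH termini
        _, short_ox = generate_oxidized_fas([FattyAcyl(18, 1)])
        rendered = {str(fa) for fa in short_ox}
        assert rendered == {"9:0(CHO)", "9:0(COOH)"}

    def test_18_2_cleavage_keeps_lower_double_bonds(self):
        _, short_ox = generate_oxidized_fas([FattyAcyl(18, 2)])
        # Delta-9 -> 9:0 products; Delta-12 -> 12:1 products (keeps Delta-9)
        assert {str(fa) for fa in short_ox} == {
            "9:0(CHO)", "9:0(COOH)", "12:1(CHO)", "12:1(COOH)",
        }

    def test_never_modifies_saturated_parents(self):
        pool = [FattyAcyl(16, 0), FattyAcyl(18, 0), FattyAcyl(18, 1)]
        long_ox, short_ox = generate_oxidized_fas(pool)
        for fa in long_ox + short_ox:
            assert fa.is_oxidized

    def test_additions_bounded_by_unsaturation(self):
        long_ox, _ = generate_oxidized_fas([FattyAcyl(18, 2)])
        base = FattyAcyl(18, 2).mass
        # at most 2 additions, each adding at most 2 oxygens
        assert max(fa.mass - base for fa in long_ox) <= 4 * 15.99492 + 1e-4


class TestBuildLibrary:
    def test_pc_formate_entry(self, pc_class):
        chains = (FattyAcyl(16, 0), FattyAcyl(22, 6))
        (entry,) = build_library(pc_class, [chains], ["[M+HCO2]-"])
        assert entry.annotation_text == "PC(16:0_22:6)"
        assert round_half_up(entry.precursor_mz, 4) == 850.5604
        frag_mzs = {round_half_up(mz, 4) for _, mz in entry.fragments}
        assert 255.2330 in frag_mzs and 327.2330 in frag_mzs

    def test_pc_protonated_entry_contains_headgroup(self, pc_class):
        chains = (FattyAcyl(16, 0), FattyAcyl(22, 6))
        (entry,) = build_library(pc_class, [chains], ["[M+H]+"])
        assert round_half_up(entry.fragment_mz("HeadGroup_184"), 4) == 184.0733

    def test_empty_chain_sets(self, pc_class):
        assert build_library(pc_class, []) == []

    def test_no_duplicate_annotation_adduct(self, pc_class):
        # permuted chain sets must collapse to one entry
        chains = [
            (FattyAcyl(16, 0), FattyAcyl(22, 6)),
            (FattyAcyl(22, 6), FattyAcyl(16, 0)),
        ]
        entries = build_library(pc_class, chains, ["[M+HCO2]-"])
        assert len(entries) == 1

    def test_default_library_unique_keys(self):
        entries = build_default_library(["PC", "PE", "LPC"])
        keys = [(e.annotation_text, e.adduct.name) for e in entries]
        assert len(keys) == len(set(keys))

    def test_chain_fragments_match_chem_core(self):
        # cross-module oracle: carboxylate fragments equal the chain's own
        entries = build_default_library(["PE"])
        for entry in entries[:200]:
            for label, mz in entry.fragments:
                if not label.endswith("_carboxylate"):
                    continue
                i = int(label[2]) - 1
                chains = sorted(
                    entry.annotation.chains, key=lambda c: c.sort_key
                )
                assert mz == pytest.approx(
                    chains[i].carboxylate_mz, abs=1e-9
                )

    def test_neutral_loss_fragments_below_precursor(self):
        for entry in build_default_library(["TG"])[:300]:
            for label, mz in entry.fragments:
                if label.startswith("NL_"):
                    assert mz < entry.precursor_mz

    def test_oxidized_class_requires_oxidized_chain(self):
        pool = [FattyAcyl(16, 0), FattyAcyl(18, 1)]
        entries = build_class_library(default_classes()["OxPC"], pool)
        assert entries
        for e in entries:
            assert any(c.is_oxidized for c in e.annotation.chains)

    def test_sm_uses_sphingoid_base(self):
        (entry,) = build_library(
            default_classes()["SM"], [(FattyAcyl(17, 0),)], ["[M+H]+"]
        )
        assert entry.annotation_text == "SM(d18:1/17:0)"
        assert round_half_up(entry.precursor_mz, 4) == 717.5905


class TestLibraryFile:
    def test_round_trip_single_entry(self, tmp_path, pc38_6_isomer_library):
        path = tmp_path / "lib.csv"
        write_library(pc38_6_isomer_library[:1], path)
        (back,) = read_library(path)
        orig = pc38_6_isomer_library[0]
        assert back.annotation_text == orig.annotation_text
        assert back.adduct.name == orig.adduct.name
        assert back.precursor_mz == pytest.approx(orig.precursor_mz, abs=1e-6)
        assert dict(back.fragments) == pytest.approx(
            {k: round(v, 6) for k, v in orig.fragments}, abs=1e-6
        )

    def test_three_entry_fixture_order(self, tmp_path):
        entries = build_default_library(["LPC"])[:3]
        path = tmp_path / "lib.csv"
        write_library(entries, path)
        back = read_library(path)
        assert [e.annotation_text for e in back] == [
            e.annotation_text for e in entries
        ]

    def test_missing_precursor_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("class,annotation,adduct,chains,base\nPC,x,[M+H]+,,\n")
        with pytest.raises(ValueError, match="precursor_mz"):
            read_library(path)

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "class,annotation,adduct,precursor_mz,chains,base\n"
            "PC,PC(16:0_22:6),[M+HCO2]-,not_a_number,16:0;22:6,\n"
        )
        with pytest.raises(ValueError, match=":2"):
            read_library(path)


class TestClassConfigFile:
    def test_round_trip_preserves_built_libraries(self, tmp_path):
        classes = default_classes()
        path = tmp_path / "classes.csv"
        write_class_config(classes, path)
        back = read_class_config(path)
        assert set(back) == set(classes)
        pool = [FattyAcyl(16, 0), FattyAcyl(18, 1), FattyAcyl(18, 2)]
        for name in ("PC", "TG", "SM"):
            a = build_class_library(classes[name], pool)
            b = build_class_library(back[name], pool)
            assert [e.annotation_text for e in a] == [e.annotation_text for e in b]
            for ea, eb in zip(a, b):
                assert ea.precursor_mz == pytest.approx(eb.precursor_mz, abs=1e-6)
                assert dict(ea.fragments) == pytest.approx(
                    dict(eb.fragments), abs=1e-4
                )


class TestParseChain:
    @pytest.mark.parametrize(
        "text", ["18:1", "O-16:0", "P-18:0", "18:1(OH)", "9:0(CHO)",
                 "18:2(OH,OOH)", "12:1(COOH)"]
    )
    def test_round_trips_rendering(self, text):
        assert str(parse_chain(text)) == text

    def test_rejects_garbage(self):
        with pytest.raises(ValueError):
            parse_chain("PC(16:0)")
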