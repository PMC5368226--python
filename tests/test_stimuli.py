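"""Stimulus generation: inventories, templates, classification, I/O."""

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aglearn import stimuli
from aglearn.stimuli import (
    DI,
    GrammarSpec,
    StimulusSet,
    Syllable,
    SynthesisSpec,
    build_inventory,
    classify_item,
    generate_familiarization,
    generate_test_set,
    read_stimulus_csv,
    render_pho,
    syllable_universe_size,
    write_stimulus_csv,
)


class TestInventories:
    def test_each_content_category_has_24_syllables(self):
        for phase in ("familiarization", "test"):
            inv = build_inventory(phase)
            for cat in "ABCD":
                assert len(set(inv.pool(cat))) == 24

    def test_familiarization_consonant_sets(self, fam_inventory):
        ab_onsets = {s.onset for s in fam_inventory.pool("A")}
        cd_onsets = {s.onset for s in fam_inventory.pool("C")}
        assert ab_onsets == {"m", "n", "l", "r", "p", "g"}
        assert cd_onsets == {"f", "v", "s", "z", "b", "k"}

    def test_test_phase_swaps_consonants(self, test_inventory):
        # A/B categories use the obstruent consonants at test
        assert {s.onset for s in test_inventory.pool("A")} == {"f", "v", "s", "z", "b", "k"}
        assert {s.onset for s in test_inventory.pool("D")} == {"m", "n", "l", "r", "p", "g"}

    def test_phases_are_disjoint(self, fam_inventory, test_inventory):
        assert not (fam_inventory.content_syllables & test_inventory.content_syllables)

    def test_universe_has_97_syllables(self):
        assert syllable_universe_size() == 97

    def test_unknown_phase_rejected(self):
        with pytest.raises(ValueError):
            build_inventory("retention")


class TestFamiliarization:
    def test_counts_and_classification(self, grammar):
        fam = generate_familiarization(grammar, n=36, seed=7)
        assert len(fam) == 36
        assert len({it.syllables for it in fam}) == 36
        for it in fam:
            assert classify_item(it.syllables, grammar) == ("grammatical", "none")

    def test_internal_constraints(self, grammar):
        for it in generate_familiarization(grammar, n=36, seed=3):
            syls = it.syllables
            if grammar.order == "di_first":
                # /di/ A B C D D
                di_slot, (i, j) = 0, (4, 5)
                a, b = syls[1], syls[2]
                c, d = syls[3], syls[4]
            else:
                # A A B C D /di/
                di_slot, (i, j) = 5, (0, 1)
                a, b = syls[0], syls[2]
                c, d = syls[3], syls[4]
            assert syls[di_slot] == DI
            assert syls[i] == syls[j]  # exact self-repeat
            # A/B differ in both consonant and vowel; so do the two distinct
            # final-zone syllables (C/D)
            assert a.onset != b.onset and a.nucleus != b.nucleus
            assert c.onset != d.onset and c.nucleus != d.nucleus

    def test_determinism(self, grammar):
        one = generate_familiarization(grammar, n=5, seed=11)
        two = generate_familiarization(grammar, n=5, seed=11)
        assert [i.syllables for i in one] == [i.syllables for i in two]
        other = generate_familiarization(grammar, n=5, seed=12)
        assert [i.syllables for i in one] != [i.syllables for i in other]

    def test_uses_familiarization_inventory_only(self, grammar, fam_inventory):
        allowed = fam_inventory.content_syllables | {DI}
        for it in generate_familiarization(grammar, n=10, seed=5):
            assert set(it.syllables) <= allowed


@pytest.mark.parametrize("mode", stimuli.VIOLATION_MODES)
class TestTestSets:
    def test_composition_and_roundtrip(self, grammar, mode):
        ts = generate_test_set(grammar, mode, seed=13)
        assert len(ts) == 36
        counts = Counter(it.item_type for it in ts)
        assert counts == {t: 9 for t in stimuli.ITEM_TYPES}
        for it in ts:
            expected_mode = "none" if it.item_type == "grammatical" else mode
            assert classify_item(it.syllables, grammar) == (it.item_type, expected_mode)

    def test_no_unintended_adjacent_repeats(self, grammar, mode):
        for it in generate_test_set(grammar, mode, seed=17):
            template = grammar.template(it.item_type, mode if it.item_type != "grammatical" else mode)
            for k in range(5):
                if it.syllables[k] == it.syllables[k + 1]:
                    assert template[k] == template[k + 1]

    def test_disjoint_from_familiarization(self, grammar, mode, fam_inventory):
        fam_syls = fam_inventory.content_syllables
        for it in generate_test_set(grammar, mode, seed=19):
            assert not (set(it.syllables) - {DI}) & fam_syls

    def test_determinism(self, grammar, mode):
        a = generate_test_set(grammar, mode, seed=23)
        b = generate_test_set(grammar, mode, seed=23)
        assert [i.syllables for i in a] == [i.syllables for i in b]


class TestPositionTemplates:
    def test_di_violation_position_slot(self):
        """Position-mode /di/ violations put /di/ at slot 5 of 6 (di_last)."""
        ts = generate_test_set(GrammarSpec("di_last"), "position", seed=29)
        for it in ts:
            if it.item_type == "di_violation":
                assert it.syllables[4] == DI
                assert it.syllables[5] != DI

    def test_double_presence_has_no_di_and_no_repeat(self):
        ts = generate_test_set(GrammarSpec("di_last"), "presence", seed=31)
        for it in ts:
            if it.item_type == "double_violation":
                assert DI not in it.syllables
                assert all(
                    it.syllables[k] != it.syllables[k + 1] for k in range(5)
                )


class TestClassifyItem:
    def test_listed_grammatical_item(self):
        # /di gOI peI ko bA bA/: a di-first familiarization instance
        syls = (
            DI,
            Syllable("g", "OI"),
            Syllable("p", "eI"),
            Syllable("k", "o"),
            Syllable("b", "A"),
            Syllable("b", "A"),
        )
        assert classify_item(syls, GrammarSpec("di_first")) == ("grammatical", "none")

    def test_displaced_di_and_repeat_is_double_position(self):
        # A /di/ B C C D under di_first
        syls = (
            Syllable("m", "eI"),
            DI,
            Syllable("l", "aI"),
            Syllable("f", "A"),
            Syllable("f", "A"),
            Syllable("s", "U"),
        )
        assert classify_item(syls, GrammarSpec("di_first")) == (
            "double_violation",
            "position",
        )

    def test_absent_both_is_double_presence(self):
        syls = tuple(
            Syllable(c, v)
            for c, v in [("m", "eI"), ("n", "aI"), ("f", "A"), ("v", "U"), ("s", "o"), ("z", "aU")]
        )
        for order in stimuli.ORDERS:
            assert classify_item(syls, GrammarSpec(order)) == (
                "double_violation",
                "presence",
            )

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            classify_item((DI,) * 5, GrammarSpec("di_first"))

    @given(
        st.lists(
            st.sampled_from(
                [DI]
                + sorted(
                    build_inventory("familiarization").content_syllables,
                    key=lambda s: s.label,
                )[:12]
            ),
            min_size=6,
            max_size=6,
        ),
        st.sampled_from(stimuli.ORDERS),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_total_on_six_tuples(self, syls, order):
        item_type, mode = classify_item(tuple(syls), GrammarSpec(order))
        assert item_type in stimuli.ITEM_TYPES
        assert mode in ("none", "presence", "position")
        assert (mode == "none") == (item_type == "grammatical")


class TestPhoRendering:
    def test_twelve_lines_and_total_duration(self, grammar):
        item = generate_familiarization(grammar, n=1, seed=1).items[0]
        text = render_pho(item)
        lines = text.strip().splitlines()
        assert len(lines) == 12
        total = sum(float(line.split()[1]) for line in lines)
        assert total == pytest.approx(1392.0)

    def test_constant_pitch_target(self, grammar):
        item = generate_familiarization(grammar, n=1, seed=2).items[0]
        for line in render_pho(item, SynthesisSpec(pitch=135)).strip().splitlines():
            assert line.split()[-1] == "135"

    def test_invalid_duration_rejected(self):
        with pytest.raises(ValueError):
            SynthesisSpec(phone_duration=0)


class TestCsvRoundTrip:
    def test_write_read_identity(self, grammar, tmp_path):
        ts = generate_test_set(grammar, "presence", seed=37)
        path = tmp_path / "set.csv"
        write_stimulus_csv(ts, path)
        back = read_stimulus_csv(path, role="test")
        assert len(back) == 36
        for orig, rt in zip(ts, back):
            assert orig == rt
        # 36 data rows + 1 header
        assert len(path.read_text().strip().splitlines()) == 37

    def test_wrong_arity_reported_with_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        header = "item_id,phase,order,violation_mode,item_type,syl1,syl2,syl3,syl4,syl5,syl6"
        path.write_text(header + "\nx,test,di_first,none,grammatical,di,mA,nA,fO,fO\n")
        with pytest.raises(ValueError, match="row 2"):
            read_stimulus_csv(path)

    def test_unknown_phone_reported(self, tmp_path):
        path = tmp_path / "bad2.csv"
        header = "item_id,phase,order,violation_mode,item_type,syl1,syl2,syl3,syl4,syl5,syl6"
        path.write_text(
            header + "\nx,test,di_first,none,grammatical,di,qA,nA,fo,bA,bA\n"
        )
        with pytest.raises(ValueError, match="row 2"):
            read_stimulus_csv(path)
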