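"""Peptide classification: precedence, coordinates, masses, round-trips."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicepipe.classify import (UnassignableError, classify_peptide,
                                 derive_features, monoisotopic_mass,
                                 positions_string)
from splicepipe.enumeration import enumerate_search_space
from splicepipe.positions import (PositionAssignment, format_positions,
                                  parse_positions)
from splicepipe.substrates import Substrate, SubstrateError

from conftest import random_substrate

PRECEDENCE = {"PCP": 0, "cis": 1, "revCis": 2, "trans": 3}


def oracle_classify(pep, seq):
    """Exhaustive decomposition search, independent of the classifier."""
    if pep in seq:
        return "PCP"
    found = set()
    for k in range(1, len(pep)):
        p, s = pep[:k], pep[k:]
        for i in range(len(seq) - len(p) + 1):
            if seq[i : i + len(p)] != p:
                continue
            for j in range(len(seq) - len(s) + 1):
                if seq[j : j + len(s)] != s:
                    continue
                a1, a2, b1, b2 = i + 1, i + len(p), j + 1, j + len(s)
                if b1 > a2:
                    found.add("cis" if b1 - a2 >= 2 else "PCP")
                elif a1 > b2:
                    found.add("revCis")
                else:
                    found.add("trans")
    for cls in ("PCP", "cis", "revCis", "trans"):
        if cls in found:
            return cls
    return None


class TestClassify:
    @pytest.mark.parametrize(
        "pep,expect_type,expect_splice,expect_pos",
        [
            ("CDEF", "PCP", "none", "2-5"),  # substring precedence over CD+EF
            ("ACEF", "PSP", "cis", "1-2_4-5"),
            ("DEAC", "PSP", "revCis", "3-4_1-2"),
            ("CDECD", "PSP", "trans", "2-4_2-3"),
        ],
    )
    def test_examples(self, small_substrate, pep, expect_type, expect_splice, expect_pos):
        c = classify_peptide(pep, small_substrate)
        assert c.product_type == expect_type
        assert c.splice_type == expect_splice
        assert c.positions == expect_pos

    def test_cis_features(self, small_substrate):
        f = derive_features(classify_peptide("ACEF", small_substrate))
        assert (f.sr1_len, f.sr2_len, f.intervening_len) == (2, 2, 1)

    def test_revcis_intervening_zero(self, small_substrate):
        f = derive_features(classify_peptide("DEAC", small_substrate))
        assert f.intervening_len == 0

    def test_unassignable(self, small_substrate):
        with pytest.raises(UnassignableError):
            classify_peptide("AAW", small_substrate)

    def test_input_error_distinct(self, small_substrate):
        with pytest.raises(SubstrateError):
            classify_peptide("AB1", small_substrate)

    def test_pure_function(self, small_substrate):
        a = classify_peptide("ACEF", small_substrate)
        b = classify_peptide("ACEF", small_substrate)
        assert a == b

    def test_full_substrate_flag(self, small_substrate):
        assert classify_peptide("ACDEFG", small_substrate).is_full_substrate
        assert not classify_peptide("ACDEF", small_substrate).is_full_substrate

    def test_canonical_is_smallest(self, rng):
        sub = Substrate("REP", "ACACAC")
        c = classify_peptide("CA", sub)  # several PCP occurrences
        assert c.canonical == min(c.explanations, key=lambda a: a.coords)

    def test_matches_oracle_on_random_substrates(self, rng):
        """Classifier class equals the exhaustive-decomposition oracle for
        every candidate sequence of random substrates (length <= 7)."""
        for k in range(10):
            sub = random_substrate(rng, int(rng.integers(2, 8)), f"O{k}")
            seqs = {c.sequence for c in enumerate_search_space(sub)}
            for pep in sorted(seqs):
                c = classify_peptide(pep, sub)
                got = "PCP" if c.product_type == "PCP" else c.splice_type
                assert got == oracle_classify(pep, sub.sequence), (pep, sub.sequence)

    def test_enumeration_roundtrip_precedence(self, rng):
        """Re-classifying an enumerated candidate gives equal or higher
        precedence than its enumeration label."""
        sub = random_substrate(rng, 8)
        for cand in enumerate_search_space(sub):
            c = classify_peptide(cand.sequence, sub)
            got = "PCP" if c.product_type == "PCP" else c.splice_type
            assert PRECEDENCE[got] <= PRECEDENCE[cand.category]

    def test_unique_letter_substrate_exact(self, unique_substrate):
        """With unique letters every candidate has one decomposition and the
        classifier reproduces the enumeration label exactly."""
        for cand in enumerate_search_space(unique_substrate):
            c = classify_peptide(cand.sequence, unique_substrate)
            got = "PCP" if c.product_type == "PCP" else c.splice_type
            assert got == cand.category
            assert len(c.explanations) == 1
            if not cand.is_pcp_equivalent:
                # (a forward-adjacent pair's sequence is a substring, so its
                # canonical explanation is the PCP assignment instead)
                assert c.canonical == cand.assignment


class TestPositionsString:
    def test_pcp_format(self, small_substrate):
        assert positions_string(classify_peptide("CDEF", small_substrate)) == "2-5"

    def test_spliced_format(self):
        a = PositionAssignment("spliced", sr1_start=1, sr1_end=2, sr2_start=4, sr2_end=5)
        assert format_positions(a) == "1-2_4-5"

    @given(st.data())
    @settings(max_examples=200, derandomize=True)
    def test_roundtrip_property(self, data):
        """parse(format(x)) == x for random assignments."""
        if data.draw(st.booleans()):
            s = data.draw(st.integers(1, 30))
            e = data.draw(st.integers(s, 40))
            a = PositionAssignment("PCP", pcp_start=s, pcp_end=e)
        else:
            s1 = data.draw(st.integers(1, 30))
            e1 = data.draw(st.integers(s1, 40))
            s2 = data.draw(st.integers(1, 30))
            e2 = data.draw(st.integers(s2, 40))
            a = PositionAssignment("spliced", sr1_start=s1, sr1_end=e1,
                                   sr2_start=s2, sr2_end=e2)
        assert parse_positions(format_positions(a)) == a

    @pytest.mark.parametrize("variant", ["1-2_4-5", "1-2;4-5", "1-2/4-5", "1-2 4-5"])
    def test_separator_variants(self, variant):
        a = parse_positions(variant)
        assert a.coords == (1, 2, 4, 5)


class TestMass:
    def test_glycine(self):
        assert monoisotopic_mass("G") == pytest.approx(75.03203, abs=1e-4)

    def test_ag(self):
        assert monoisotopic_mass("AG") == pytest.approx(146.06914, abs=1e-4)

    def test_single_water_regardless_of_ligation(self):
        # mass is computed on the final linear sequence: exactly one water,
        # so the two-fragment sum over-counts by one water
        water = 18.010565
        assert monoisotopic_mass("ACDE") == pytest.approx(
            monoisotopic_mass("AC") + monoisotopic_mass("DE") - water, abs=1e-5
        )

    def test_rejects_bad_input(self):
        with pytest.raises(SubstrateError):
            monoisotopic_mass("")
        with pytest.raises(SubstrateError):
            monoisotopic_mass("AXB")
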