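"""HGVS c.-parsing and mutation-type classification."""

import pytest
from hypothesis import given, settings, strategies as st

from tscgp.variants import (HgvsParseError, HgvsRangeError, MutationCall,
                            MutationType, TruncationClass, UnresolvableClassError,
                            UnsupportedVariantError, classify_mutation_type,
                            classify_truncation, parse_hgvs_c, serialize_hgvs)


class TestParse:
    def test_substitution(self, tsc1):
        v = parse_hgvs_c("c.737G>A", "TSC1", ref=tsc1)
        assert (v.kind, v.cds_start, v.ref_allele, v.alt_allele) == \
            ("substitution", 737, "G", "A")
        assert v.intron_offset is None and v.length_change == 0

    def test_small_deletion(self, tsc1):
        v = parse_hgvs_c("c.1_3del", "TSC1", ref=tsc1)
        assert (v.kind, v.cds_start, v.cds_end, v.length_change) == ("deletion", 1, 3, -3)

    def test_intronic_offset(self, tsc2):
        v = parse_hgvs_c("c.5068+1G>T", "TSC2", ref=tsc2)
        assert (v.cds_start, v.intron_offset) == (5068, 1)

    @pytest.mark.parametrize("text, kind, change", [
        ("c.100_105dup", "duplication", 6),
        ("c.100_101insTG", "insertion", 2),
        ("c.100_102delinsA", "delins", -2),
        ("c.100delinsTT", "delins", 1),
    ])
    def test_other_kinds(self, text, kind, change, tsc1):
        v = parse_hgvs_c(text, "TSC1", ref=tsc1)
        assert (v.kind, v.length_change) == (kind, change)

    @pytest.mark.parametrize("text", ["737G>A", "c.", "c.10G>", "c.5_2del",
                                      "c.12delACT", "c.100insTT"])
    def test_malformed(self, text, tsc1):
        with pytest.raises(HgvsParseError):
            parse_hgvs_c(text, "TSC1", ref=tsc1)

    def test_position_beyond_cds(self, tsc1):
        with pytest.raises(HgvsRangeError):
            parse_hgvs_c("c.4000G>A", "TSC1", ref=tsc1)

    def test_unsupported_form_distinct_from_malformed(self, tsc1):
        with pytest.raises(UnsupportedVariantError):
            parse_hgvs_c("c.100_200inv", "TSC1", ref=tsc1)

    def test_whitespace_and_idempotence(self, tsc1):
        v1 = parse_hgvs_c(" c.737 G>A ", "TSC1", ref=tsc1)
        v2 = parse_hgvs_c(serialize_hgvs(v1), "TSC1", ref=tsc1)
        assert serialize_hgvs(v1) == serialize_hgvs(v2) == "c.737G>A"


@st.composite
def hgvs_variants(draw):
    cds_length = 3495
    kind = draw(st.sampled_from(["sub", "del", "dup", "ins", "delins", "splice"]))
    if kind == "sub":
        pos = draw(st.integers(1, cds_length))
        r, a = draw(st.sampled_from(["GA", "CT", "AG", "TC"]))
        return f"c.{pos}{r}>{a}"
    if kind == "splice":
        pos = draw(st.integers(2, cds_length))
        off = draw(st.sampled_from([-2, -1, 1, 2]))
        return f"c.{pos}{off:+d}G>T"
    start = draw(st.integers(1, cds_length - 10))
    end = draw(st.integers(start, min(start + 9, cds_length)))
    if kind == "del":
        return f"c.{start}_{end}del"
    if kind == "dup":
        return f"c.{start}_{end}dup"
    seq = draw(st.text(alphabet="ACGT", min_size=1, max_size=6))
    if kind == "ins":
        return f"c.{start}_{start + 1}ins{seq}"
    return f"c.{start}_{end}delins{seq}"


class TestProperties:
    @given(hgvs_variants())
    @settings(max_examples=300, deadline=None)
    def test_serialize_parse_round_trip(self, text):
        v = parse_hgvs_c(text, "TSC1", cds_length=3495)
        v2 = parse_hgvs_c(serialize_hgvs(v), "TSC1", cds_length=3495)
        assert v2 == type(v2)(**{**v.__dict__, "raw": v2.raw})

    @given(hgvs_variants())
    @settings(max_examples=300, deadline=None)
    def test_classification_total_and_case_insensitive(self, text):
        v = parse_hgvs_c(text, "TSC1", cds_length=3495)
        call = classify_mutation_type(v, "p.(Arg100Ter)")
        assert isinstance(call.type, MutationType)
        assert classify_truncation(call) in TruncationClass
        v_lower = parse_hgvs_c(" " + text.lower(), "TSC1", cds_length=3495)
        assert classify_mutation_type(v_lower, "p.(arg100ter)").type is call.type


class TestClassification:
    def test_declared_missense_substitution(self, tsc1):
        v = parse_hgvs_c("c.737G>A", "TSC1", ref=tsc1)
        assert classify_mutation_type(v, "p.Arg246Lys").type is MutationType.MISSENSE

    def test_declared_nonsense(self, tsc1):
        v = parse_hgvs_c("c.100C>T", "TSC1", ref=tsc1)
        for note in ("p.(Gln34Ter)", "p.Gln34*", "p.Q34X"):
            assert classify_mutation_type(v, note).type is MutationType.NONSENSE

    def test_frame_rules(self, tsc1):
        fs = parse_hgvs_c("c.100_101del", "TSC1", ref=tsc1)
        assert classify_mutation_type(fs).type is MutationType.FRAMESHIFT
        inf = parse_hgvs_c("c.100_105del", "TSC1", ref=tsc1)
        assert classify_mutation_type(inf).type is MutationType.IN_FRAME

    def test_splice_window(self, tsc2):
        v = parse_hgvs_c("c.5068+1G>T", "TSC2", ref=tsc2)
        assert classify_mutation_type(v).type is MutationType.SPLICE_SITE
        deep = parse_hgvs_c("c.5068+40G>T", "TSC2", ref=tsc2)
        call = classify_mutation_type(deep)
        assert call.type is MutationType.SPLICE_SITE and call.low_confidence
        with pytest.raises(UnresolvableClassError):
            classify_mutation_type(deep, strict=True)

    def test_declared_missense_overrides_splice_offset(self, tsc1):
        # a substitution reported as missense that also sits near a junction
        v = parse_hgvs_c("c.737+1G>A", "TSC1", ref=tsc1)
        assert classify_mutation_type(v, "p.(Arg246Lys)").type is MutationType.MISSENSE

    def test_large_fragment_by_span_and_by_whole_exon(self, tsc1):
        big = parse_hgvs_c("c.141_990del", "TSC1", ref=tsc1)
        assert classify_mutation_type(big, ref=tsc1).type is MutationType.LARGE_FRAGMENT
        # 51 nt deletion crosses the default length threshold even within an exon
        medium = parse_hgvs_c("c.2991_3041del", "TSC1", ref=tsc1)
        assert classify_mutation_type(medium, ref=tsc1).type is MutationType.LARGE_FRAGMENT
        assert classify_mutation_type(
            medium, ref=tsc1, large_fragment_nt=100).type is MutationType.IN_FRAME

    def test_unresolved_substitution_flagged_not_guessed(self, tsc1):
        v = parse_hgvs_c("c.100C>G", "TSC1", ref=tsc1)
        call = classify_mutation_type(v)
        assert call.low_confidence
        with pytest.raises(UnresolvableClassError):
            classify_mutation_type(v, strict=True)


def test_truncation_map_is_exhaustive_and_matches_definition():
    expected_pt = {MutationType.FRAMESHIFT, MutationType.SPLICE_SITE,
                   MutationType.NONSENSE, MutationType.LARGE_FRAGMENT}
    for t in MutationType:
        cls = classify_truncation(t)
        assert cls is (TruncationClass.PT if t in expected_pt else TruncationClass.NT)
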