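"""Variant normalization: 3'-shifting, dup detection, labels, VCF form."""

import pytest
from hypothesis import given, settings, strategies as st

from mitovar.reference import MT_LENGTH
from mitovar.variants import (
    DELETION,
    DUPLICATION,
    INSERTION,
    VariantError,
    apply_labels,
    normalize_raw,
    parse_label,
    renormalize,
    to_vcf_tuple,
    write_vcf,
)


@pytest.mark.parametrize("offset", range(0, 6))
def test_c_insertion_anywhere_in_311_315_run_is_m315dup(ref, offset):
    """A single C inserted at any point of the second poly-C run must
    normalize to the one canonical name m.315dup."""
    v = normalize_raw(311 + offset, "", "C", ref)
    assert v.label == "m.315dup"
    assert v.klass == DUPLICATION


@pytest.mark.parametrize("offset", range(0, 8))
def test_c_insertion_in_303_309_run_is_m309dup(ref, offset):
    v = normalize_raw(303 + offset, "", "C", ref)
    assert v.label == "m.309dup"


@pytest.mark.parametrize(
    "raw, label",
    [
        ((310, "T", ""), "m.310del"),
        ((310, "T", "C"), "m.310T>C"),
        ((310, "T", "CCTC"), "m.310delinsCCTC"),
        ((303, "C", ""), "m.309del"),  # 3'-shifts through the C run
        ((16519, "T", "C"), "m.16519T>C"),
    ],
)
def test_normalization_examples(ref, raw, label):
    assert normalize_raw(*raw, ref).label == label


def test_two_base_insertion_becomes_range_dup(ref):
    v = normalize_raw(303, "", "CC", ref)
    assert v.label == "m.308_309dup"
    assert v.klass == DUPLICATION


def test_trimming_reduces_delins_to_simpler_class(ref):
    # replacing C303..C304 with "C" is really a single-base deletion
    v = normalize_raw(303, "CC", "C", ref)
    assert v.klass == DELETION
    assert v.label == "m.309del"


def test_ref_disagreement_raises(ref):
    with pytest.raises(VariantError, match="disagrees"):
        normalize_raw(310, "A", "C", ref)


def test_no_change_returns_none(ref):
    assert normalize_raw(310, "T", "T", ref) is None


@pytest.mark.parametrize(
    "label",
    ["m.16519T>C", "m.310del", "m.315dup", "m.309dup", "m.310delinsCCTC",
     "m.263A>G", "m.308_309dup", "m.2145del"],
)
def test_parse_label_round_trip(ref, label):
    assert parse_label(label, ref).label == label


def test_parse_label_canonicalizes_shifted_spellings(ref):
    # a dup written at the run start re-normalizes to the 3'-most anchor
    assert parse_label("m.311dup", ref).label == "m.315dup"
    assert parse_label("m.303del", ref).label == "m.309del"


def test_parse_label_rejects_garbage(ref):
    for bad in ["m.10X>Y", "310del", "m.del", "m.10_12A>G"]:
        with pytest.raises(VariantError):
            parse_label(bad, ref)


def _apply_raw(seq: str, start: int, ref_seg: str, alt_seg: str) -> str:
    """Independent oracle: splice the raw edit directly into the string."""
    i = start - 1
    return seq[:i] + alt_seg + seq[i + len(ref_seg):]


@given(data=st.data())
@settings(max_examples=200, deadline=None)
def test_normalization_preserves_edited_sequence(ref, data):
    """apply(normalize(raw)) must equal the directly spliced raw edit, and
    normalization must be idempotent."""
    start = data.draw(st.integers(min_value=2, max_value=MT_LENGTH - 10))
    kind = data.draw(st.sampled_from(["sub", "del", "ins", "delins"]))
    alt = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=4))
    if kind == "sub":
        ref_seg = ref.base(start)
        alt_seg = data.draw(st.sampled_from("ACGT".replace(ref_seg, "")))
    elif kind == "del":
        n = data.draw(st.integers(min_value=1, max_value=3))
        ref_seg, alt_seg = ref.slice(start, start + n - 1), ""
    elif kind == "ins":
        ref_seg, alt_seg = "", alt
    else:
        n = data.draw(st.integers(min_value=1, max_value=3))
        ref_seg, alt_seg = ref.slice(start, start + n - 1), alt
    v = normalize_raw(start, ref_seg, alt_seg, ref)
    expected = _apply_raw(ref.sequence, start, ref_seg, alt_seg)
    if v is None:
        assert expected == ref.sequence
        return
    assert apply_labels([v.label], ref) == expected
    assert renormalize(v, ref) == v
    # 3'-maximality: one further shift must break reference identity
    if v.klass == DELETION and v.end_position < MT_LENGTH:
        assert ref.base(v.end_position + 1) != v.ref_allele[0]
    if v.klass in (DUPLICATION, INSERTION):
        anchor = v.end_position if v.klass == DUPLICATION else v.position
        if anchor < MT_LENGTH:
            assert ref.base(anchor + 1) != v.alt_allele[0]


@pytest.mark.parametrize(
    "label, expected",
    [
        ("m.16519T>C", (16519, "T", "C")),
        ("m.310del", (309, "CT", "C")),
        ("m.315dup", (315, "C", "CC")),
        ("m.310delinsCCTC", (310, "T", "CCTC")),
    ],
)
def test_vcf_tuple_left_padding(ref, label, expected):
    assert to_vcf_tuple(parse_label(label, ref), ref) == expected


def test_vcf_round_trip_through_pysam(ref, tmp_path):
    """Writing calls as VCF and re-applying the records must reproduce the
    same edited genome as applying the labels directly."""
    pysam = pytest.importorskip("pysam")
    labels = ["m.263A>G", "m.310del", "m.315dup", "m.16519T>C"]
    # m.310del and m.315dup never co-occur in one sample; use two files
    for subset in (labels[:2], labels[2:]):
        path = tmp_path / ("_".join(s.replace(">", "-") for s in subset) + ".vcf")
        variants = [parse_label(lab, ref) for lab in subset]
        write_vcf(str(path), "s1", variants, ref)
        edited = ref.sequence
        for rec in sorted(pysam.VariantFile(str(path)),
                          key=lambda r: -r.pos):
            i = rec.pos - 1
            assert ref.sequence[i : i + len(rec.ref)] == rec.ref
            edited = edited[:i] + rec.alts[0] + edited[i + len(rec.ref):]
        assert edited == apply_labels(subset, ref)
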