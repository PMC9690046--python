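"""Variant representation and HGVS-style normalization against the rCRS.

A :class:`Variant` is one normalized difference between a sample and the
reference, carrying a canonical m.-style label. Normalization follows the
HGVS convention for homopolymer/repeat indels: deletions and insertions are
shifted to their 3'-most equivalent placement, and an insertion whose
sequence equals the immediately preceding reference run is emitted as a
duplication. This is what turns "a C inserted anywhere in the 311-315
poly-C run" into the single canonical name m.315dup, and a C inserted in
the 303-309 run into m.309dup.

Label grammar::

    m.{pos}{REF}>{ALT}            substitution
    m.{pos}del | m.{start}_{end}del
    m.{pos}dup | m.{start}_{end}dup
    m.{pos}_{pos+1}ins{SEQ}       insertion not explained by a preceding run
    m.{pos}delins{SEQ} | m.{start}_{end}delins{SEQ}

Labels are uniquely reconstructible from the coordinate/allele fields and
vice versa (:func:`parse_label` needs the reference to recover deleted and
duplicated bases, which the label omits).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .reference import MitoReference, MT_LENGTH

SUBSTITUTION = "substitution"
DELETION = "deletion"
DUPLICATION = "duplication"
INSERTION = "insertion"
DELINS = "delins"


class VariantError(ValueError):
    pass


@dataclass(frozen=True)
class Variant:
    """One normalized difference vs. the reference.

    ``position``/``end_position`` are 1-based inclusive reference
    coordinates of the affected bases; for insertions and duplications they
    delimit the inserted/duplicated unit's anchor (the duplicated reference
    run for dup; the two flanking bases for ins).
    """

    position: int
    end_position: int
    ref_allele: str  # "" for pure insertion/duplication
    alt_allele: str  # "" for deletion
    klass: str
    label: str
    regions: tuple[str, ...] = field(default=(), compare=False)

    @property
    def span(self) -> tuple[int, int]:
        """Reference span whose coverage is required to call this variant."""
        return (self.position, self.end_position)


def _label(position: int, end: int, ref: str, alt: str, klass: str) -> str:
    if klass == SUBSTITUTION:
        return f"m.{position}{ref}>{alt}"
    if klass == DELETION:
        return f"m.{position}del" if position == end else f"m.{position}_{end}del"
    if klass == DUPLICATION:
        return f"m.{position}dup" if position == end else f"m.{position}_{end}dup"
    if klass == INSERTION:
        return f"m.{position}_{end}ins{alt}"
    if klass == DELINS:
        core = f"delins{alt}"
        return (
            f"m.{position}{core}" if position == end else f"m.{position}_{end}{core}"
        )
    raise VariantError(f"unknown variant class {klass!r}")


def _make(position: int, end: int, ref_seg: str, alt_seg: str, klass: str) -> Variant:
    return Variant(
        position=position,
        end_position=end,
        ref_allele=ref_seg,
        alt_allele=alt_seg,
        klass=klass,
        label=_label(position, end, ref_seg, alt_seg, klass),
    )


def normalize_raw(
    start: int, ref_seg: str, alt_seg: str, ref: MitoReference
) -> Variant | None:
    """Normalize a raw difference into a canonical :class:`Variant`.

    ``ref_seg`` occupies reference positions ``start..start+len(ref_seg)-1``
    and is replaced by ``alt_seg`` in the sample; either segment may be
    empty (pure insertion sits between ``start-1`` and ``start``). Returns
    ``None`` when the segments are equal (no variant). Raises if ``ref_seg``
    disagrees with the reference.
    """
    if ref_seg and ref.slice(start, start + len(ref_seg) - 1) != ref_seg:
        raise VariantError(
            f"ref allele {ref_seg!r} disagrees with reference at {start}"
        )
    # trim common suffix, then common prefix
    while ref_seg and alt_seg and ref_seg[-1] == alt_seg[-1]:
        ref_seg, alt_seg = ref_seg[:-1], alt_seg[:-1]
    while ref_seg and alt_seg and ref_seg[0] == alt_seg[0]:
        ref_seg, alt_seg = ref_seg[1:], alt_seg[1:]
        start += 1

    if not ref_seg and not alt_seg:
        return None

    if len(ref_seg) == 1 and len(alt_seg) == 1:
        return _make(start, start, ref_seg, alt_seg, SUBSTITUTION)

    if not alt_seg:  # deletion: shift 3'
        end = start + len(ref_seg) - 1
        while end < MT_LENGTH and ref.base(end + 1) == ref_seg[0]:
            ref_seg = ref_seg[1:] + ref.base(end + 1)
            start += 1
            end += 1
        return _make(start, end, ref_seg, "", DELETION)

    if not ref_seg:  # insertion after position start-1: shift 3'
        p = start - 1
        while p + 1 <= MT_LENGTH and ref.base(p + 1) == alt_seg[0]:
            alt_seg = alt_seg[1:] + alt_seg[0]
            p += 1
        n = len(alt_seg)
        if p >= n and ref.slice(p - n + 1, p) == alt_seg:
            return _make(p - n + 1, p, "", alt_seg, DUPLICATION)
        return _make(p, p + 1, "", alt_seg, INSERTION)

    end = start + len(ref_seg) - 1
    return _make(start, end, ref_seg, alt_seg, DELINS)


_LABEL_RE = re.compile(
    r"^m\.(?P<start>\d+)(?:_(?P<end>\d+))?"
    r"(?P<body>[ACGT]>[ACGT]|del(?:ins[ACGT]+)?|dup|ins[ACGT]+)$"
)


def parse_label(label: str, ref: MitoReference) -> Variant:
    """Parse an m.-style label back into a :class:`Variant`.

    The result is re-normalized, so a non-canonical spelling (e.g. a dup
    written at a non-3'-most anchor) parses to its canonical form.
    """
    m = _LABEL_RE.match(label)
    if not m:
        raise VariantError(f"cannot parse variant label {label!r}")
    start = int(m.group("start"))
    end = int(m.group("end") or start)
    body = m.group("body")
    if ">" in body:
        ref_b, alt_b = body.split(">")
        if end != start:
            raise VariantError(f"substitution label with span: {label!r}")
        v = normalize_raw(start, ref_b, alt_b, ref)
    elif body == "dup":
        unit = ref.slice(start, end)
        v = normalize_raw(end + 1, "", unit, ref)
    elif body.startswith("delins"):
        v = normalize_raw(start, ref.slice(start, end), body[len("delins"):], ref)
    elif body == "del":
        v = normalize_raw(start, ref.slice(start, end), "", ref)
    else:  # insAAA between start and end
        if end != start + 1:
            raise VariantError(f"insertion label must use adjacent anchors: {label!r}")
        v = normalize_raw(start + 1, "", body[len("ins"):], ref)
    if v is None:
        raise VariantError(f"label {label!r} describes no change")
    return v


def renormalize(v: Variant, ref: MitoReference) -> Variant:
    """Re-run normalization on a variant's own raw form (idempotence hook)."""
    if v.klass in (INSERTION, DUPLICATION):
        anchor = v.end_position if v.klass == DUPLICATION else v.position
        out = normalize_raw(anchor + 1, "", v.alt_allele, ref)
    else:
        out = normalize_raw(v.position, v.ref_allele, v.alt_allele, ref)
    if out is None:
        raise VariantError(f"variant {v.label} normalizes to no change")
    return out


# ---------------------------------------------------------------- application

def apply_variants_to_pieces(
    variants: list[Variant], ref: MitoReference
) -> list[str]:
    """Apply variants to the reference, returning a per-position piece table.

    ``pieces[p]`` (1-based; index 0 unused) holds the sample bases that
    replace reference position ``p``; insertions are appended to the piece
    of the base they follow. Joining pieces over any reference window yields
    the sample's sequence for that window, which is how fragments are cut
    without coordinate bookkeeping. Variants must not overlap.
    """
    pieces = [""] + list(ref.sequence)
    seen_spans: list[tuple[int, int]] = []
    for v in sorted(variants, key=lambda x: x.position):
        if v.klass == SUBSTITUTION:
            span = (v.position, v.position)
            pieces[v.position] = v.alt_allele
        elif v.klass == DELETION:
            span = (v.position, v.end_position)
            for p in range(v.position, v.end_position + 1):
                pieces[p] = ""
        elif v.klass == DUPLICATION:
            span = (v.end_position, v.end_position)
            pieces[v.end_position] += v.alt_allele
        elif v.klass == INSERTION:
            span = (v.position, v.position)
            pieces[v.position] += v.alt_allele
        elif v.klass == DELINS:
            span = (v.position, v.end_position)
            for p in range(v.position, v.end_position + 1):
                pieces[p] = ""
            pieces[v.position] = v.alt_allele
        else:
            raise VariantError(f"unknown class {v.klass}")
        for s, e in seen_spans:
            if span[0] <= e and s <= span[1]:
                raise VariantError(
                    f"overlapping variants at {span} vs {(s, e)}"
                )
        seen_spans.append(span)
    return pieces


def apply_labels(labels: list[str], ref: MitoReference) -> str:
    """Apply m.-style labels to the reference, returning the edited sequence."""
    variants = [parse_label(lab, ref) for lab in labels]
    return "".join(apply_variants_to_pieces(variants, ref)[1:])


# ------------------------------------------------------------------ VCF form

def to_vcf_tuple(v: Variant, ref: MitoReference) -> tuple[int, str, str]:
    """Convert to the left-padded VCF (POS, REF, ALT) representation.

    Indels receive the standard VCF anchor base to the left; the record
    keeps the 3'-shifted placement of the internal form (a left-aligning
    normalizer such as ``bcftools norm`` may move it).
    """
    if v.klass == SUBSTITUTION:
        return v.position, v.ref_allele, v.alt_allele
    if v.klass == DELINS:
        return v.position, v.ref_allele, v.alt_allele
    if v.klass == DELETION:
        if v.position > 1:
            pad = ref.base(v.position - 1)
            return v.position - 1, pad + v.ref_allele, pad
        pad = ref.base(v.end_position + 1)
        return 1, v.ref_allele + pad, pad
    if v.klass in (DUPLICATION, INSERTION):
        anchor = v.end_position if v.klass == DUPLICATION else v.position
        pad = ref.base(anchor)
        return anchor, pad, pad + v.alt_allele
    raise VariantError(f"unknown class {v.klass}")


def write_vcf(
    path: str,
    sample_id: str,
    variants: list[Variant],
    ref: MitoReference,
) -> None:
    """Write one sample's variants as an uncompressed single-sample VCF."""
    import pysam

    header = pysam.VariantHeader()
    header.contigs.add("chrM", length=MT_LENGTH)
    header.add_meta("source", "mitovar")
    header.info.add("LABEL", 1, "String", "Canonical m.-style variant label")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(sample_id)
    with pysam.VariantFile(path, "w", header=header) as out:
        for v in sorted(variants, key=lambda x: to_vcf_tuple(x, ref)[0]):
            pos, ref_a, alt_a = to_vcf_tuple(v, ref)
            rec = out.new_record(
                contig="chrM",
                start=pos - 1,
                stop=pos - 1 + len(ref_a),
                alleles=(ref_a, alt_a),
            )
            rec.info["LABEL"] = v.label.replace(">", "-")  # '>' unsafe in INFO
            rec.samples[sample_id]["GT"] = (1,)
            out.write(rec)
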