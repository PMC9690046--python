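"""Pairwise alignment to the rCRS and per-sample variant calling.

Near-complete mitogenomes (>= ``complete_min_len``, default 15,400 nt) are
aligned globally; shorter fragments (HVR1/HVR2 amplicons and similar) are
aligned semi-globally (end gaps on the reference are free) so their window
on the reference is located rather than assumed. Alignment is minimal-edit
(edlib), bounded by a maximum edit distance that starts at ``band`` and is
doubled on overflow — for the divergences seen between human mitogenomes
this is equivalent to a banded alignment and keeps a full-genome alignment
in the low milliseconds.

IUPAC ambiguity codes in the sample are alignment-neutral (they match any
of their component bases), never become variant calls, and surface instead
as :class:`HeteroplasmicSite` records; ``N`` is treated as missing.

Calling proceeds alignment -> raw differences -> HGVS-style normalization
(:mod:`mitovar.variants`) -> D310 reconciliation: normalized variants lying
wholly inside the D310 window are replaced by the canonical tract allele
(:mod:`mitovar.d310`) whenever the observed tract matches one, so that e.g.
an m.310delinsCCTC tract is reported as that single named allele rather
than as the three C insertions of its minimal edit script.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace as dc_replace

import edlib

from . import d310 as d310_mod
from .reference import MitoReference, MT_LENGTH, Region, annotate_span
from .variants import Variant, normalize_raw, parse_label

IUPAC_CODES: dict[str, str] = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
}
_EQUALITIES = [
    (code, base) for code, bases in IUPAC_CODES.items() for base in bases
] + [("N", b) for b in "ACGT"]
_ALPHABET = set("ACGT") | set(IUPAC_CODES) | {"N"}
_CIGAR_RE = re.compile(r"(\d+)([=XID])")


class AlignmentError(RuntimeError):
    pass


class UnalignableError(AlignmentError):
    pass


@dataclass(frozen=True)
class AlignParams:
    band: int = 200            # initial max edit distance (banding analogue)
    band_retries: int = 5      # doublings before giving up
    identity_floor: float = 0.90
    complete_min_len: int = 15400
    min_len: int = 100


@dataclass(frozen=True)
class Alignment:
    """A pairwise alignment of one sample against the reference.

    ``ref_aln``/``qry_aln`` are equal-length gapped strings (no gap/gap
    column); ``ref_start``/``ref_end`` is the covered 1-based inclusive
    reference span.
    """

    sample_id: str
    mode: str  # "global" | "semi-global"
    ref_start: int
    ref_end: int
    ref_aln: str
    qry_aln: str
    identity: float


@dataclass(frozen=True)
class HeteroplasmicSite:
    position: int
    code: str
    component_bases: str


@dataclass(frozen=True)
class SampleCall:
    """Per-sample calling result fed to the cohort statistics."""

    sample_id: str
    group: str | None
    footprint: tuple[int, int]
    variants: tuple[Variant, ...]
    heteroplasmies: tuple[HeteroplasmicSite, ...]
    d310: d310_mod.D310Allele | None
    censored: frozenset[int] = field(default=frozenset())  # het/N positions

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(v.label for v in self.variants)

    def callable_at(self, start: int, end: int | None = None) -> bool:
        """Is this sample informative over the whole span start..end?

        True when the coverage footprint contains the span and no position
        in it is censored (heteroplasmic or N in this sample).
        """
        end = start if end is None else end
        if not (self.footprint[0] <= start and end <= self.footprint[1]):
            return False
        return not any(p in self.censored for p in range(start, end + 1))


def _base_match(q: str, r: str) -> bool:
    return q == r or q == "N" or (q in IUPAC_CODES and r in IUPAC_CODES[q])


def align_to_reference(
    seq: str,
    ref: MitoReference,
    params: AlignParams = AlignParams(),
    sample_id: str = "",
) -> Alignment:
    """Align a sample sequence to the reference and return the alignment."""
    seq = seq.upper()
    if len(seq) < params.min_len:
        raise AlignmentError(
            f"{sample_id or 'sequence'}: length {len(seq)} below minimum "
            f"{params.min_len}"
        )
    bad = set(seq) - _ALPHABET
    if bad:
        raise AlignmentError(f"{sample_id}: invalid characters {sorted(bad)}")

    is_complete = len(seq) >= params.complete_min_len
    mode = "NW" if is_complete else "HW"
    k = params.band
    result = None
    for _ in range(params.band_retries + 1):
        result = edlib.align(
            seq, ref.sequence, mode=mode, task="path", k=k,
            additionalEqualities=_EQUALITIES,
        )
        if result["editDistance"] != -1:
            break
        k *= 2
    if result is None or result["editDistance"] == -1:
        raise UnalignableError(
            f"{sample_id}: no alignment within {k} edits (band overflow)"
        )

    t_start, t_end = result["locations"][0]
    if t_start is None:
        t_start = 0
    ref_aln_parts: list[str] = []
    qry_aln_parts: list[str] = []
    ti, qi = t_start, 0
    for n_str, op in _CIGAR_RE.findall(result["cigar"]):
        n = int(n_str)
        if op in "=X":
            ref_aln_parts.append(ref.sequence[ti : ti + n])
            qry_aln_parts.append(seq[qi : qi + n])
            ti += n
            qi += n
        elif op == "I":  # extra sample bases (gap in reference)
            ref_aln_parts.append("-" * n)
            qry_aln_parts.append(seq[qi : qi + n])
            qi += n
        else:  # "D": sample gap against reference bases
            ref_aln_parts.append(ref.sequence[ti : ti + n])
            qry_aln_parts.append("-" * n)
            ti += n
    ref_aln = "".join(ref_aln_parts)
    qry_aln = "".join(qry_aln_parts)

    n_cols = len(ref_aln)
    matches = sum(
        1 for r, q in zip(ref_aln, qry_aln)
        if r != "-" and q != "-" and _base_match(q, r)
    )
    identity = matches / n_cols if n_cols else 0.0
    if identity < params.identity_floor:
        raise UnalignableError(
            f"{sample_id}: identity {identity:.3f} below floor "
            f"{params.identity_floor}"
        )
    return Alignment(
        sample_id=sample_id,
        mode="global" if is_complete else "semi-global",
        ref_start=t_start + 1,
        ref_end=t_end + 1,
        ref_aln=ref_aln,
        qry_aln=qry_aln,
        identity=identity,
    )


def _columns(aln: Alignment):
    """Yield (ref_pos_or_None, ref_char, qry_char, prev_ref_pos) per column."""
    pos = aln.ref_start - 1  # last consumed reference position
    for r, q in zip(aln.ref_aln, aln.qry_aln):
        if r != "-":
            pos += 1
            yield pos, r, q, pos
        else:
            yield None, r, q, pos


def extract_variants(
    aln: Alignment, ref: MitoReference
) -> list[tuple[int, str, str]]:
    """Extract raw differences as (start, ref_segment, alt_segment) triples.

    Mismatch columns become one substitution each; maximal gap runs become
    one indel each; runs mixing substitutions and gaps become one delins
    candidate. IUPAC/N columns count as matches here (they are reported by
    :func:`detect_heteroplasmy` instead).
    """
    raws: list[tuple[int, str, str]] = []
    run: list[tuple[int | None, str, str, int]] = []

    def flush() -> None:
        if not run:
            return
        has_ins = any(col[0] is None for col in run)
        has_del = any(col[2] == "-" for col in run)
        ref_positions = [col[0] for col in run if col[0] is not None]
        ref_seg = "".join(col[1] for col in run if col[0] is not None)
        alt_seg = "".join(col[2] for col in run if col[2] != "-")
        if not has_ins and not has_del:  # pure mismatches: one sub per column
            for p, r, q, _ in run:
                raws.append((p, r, q))
        elif ref_positions:
            raws.append((ref_positions[0], ref_seg, alt_seg))
        else:  # pure insertion after the preceding reference base
            raws.append((run[0][3] + 1, "", alt_seg))
        run.clear()

    for pos, r, q, prev in _columns(aln):
        if pos is not None and (q == r or (q not in "ACGT-" and q != r)):
            flush()  # match or IUPAC/N column ends any run
        else:
            run.append((pos, r, q, prev))
    flush()
    return raws


def detect_heteroplasmy(aln: Alignment) -> list[HeteroplasmicSite]:
    """IUPAC ambiguity sites (excluding N) at reference positions."""
    sites = []
    for pos, r, q, _ in _columns(aln):
        if pos is not None and q in IUPAC_CODES:
            sites.append(HeteroplasmicSite(pos, q, IUPAC_CODES[q]))
    return sites


def coverage_footprint(aln: Alignment) -> tuple[int, int]:
    """The 1-based inclusive reference interval covered by the sample."""
    return (aln.ref_start, aln.ref_end)


def d310_tract(aln: Alignment) -> str:
    """The sample's literal bases across the D310 locus (303..315 plus
    insertions anchored after 302..315)."""
    lo, hi = 303, 315
    chars = []
    for pos, r, q, prev in _columns(aln):
        if q == "-":
            continue
        if pos is not None and lo <= pos <= hi:
            chars.append(q)
        elif pos is None and lo - 1 <= prev <= hi:
            chars.append(q)
    return "".join(chars)


def call_sample(
    seq: str,
    ref: MitoReference,
    regions: list[Region],
    params: AlignParams = AlignParams(),
    sample_id: str = "",
    group: str | None = None,
) -> SampleCall:
    """Align one sample and produce its normalized, D310-reconciled calls."""
    aln = align_to_reference(seq, ref, params, sample_id)
    variants = []
    for start, ref_seg, alt_seg in extract_variants(aln, ref):
        v = normalize_raw(start, ref_seg, alt_seg, ref)
        if v is not None:
            variants.append(v)

    footprint = coverage_footprint(aln)
    lo, hi = d310_mod.D310_WINDOW
    allele: d310_mod.D310Allele | None = None
    if footprint[0] <= lo and hi <= footprint[1]:
        allele = d310_mod.classify_tract(d310_tract(aln))
        if allele.category != "other":
            inside = [
                v for v in variants if lo <= v.position and v.end_position <= hi
            ]
            outside = [v for v in variants if v not in inside]
            canon = [
                parse_label(lab, ref)
                for lab in d310_mod.category_labels(allele.category)
            ]
            variants = outside + canon

    hets = detect_heteroplasmy(aln)
    censored = frozenset(h.position for h in hets) | frozenset(
        pos for pos, _r, q, _p in _columns(aln) if pos is not None and q == "N"
    )
    annotated = tuple(
        dc_replace(
            v,
            regions=tuple(
                annotate_span(v.position, min(v.end_position, MT_LENGTH), regions)
            ),
        )
        for v in sorted(variants, key=lambda v: (v.position, v.label))
    )
    return SampleCall(
        sample_id=sample_id,
        group=group,
        footprint=footprint,
        variants=annotated,
        heteroplasmies=tuple(hets),
        d310=allele,
        censored=censored,
    )
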