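"""D310 poly-C locus typing.

D310 is the mononucleotide-repeat hotspot in the control region (HVR2):
seven cytosines at 303-309, a T at 310, and five cytosines at 311-315 on
the reference. Tumour and germline length changes here are common, and the
field names the recurring alleles after their canonical variant labels:
m.309dup / m.309del (length change in the first run), m.310del / m.310T>C /
m.310delinsCCTC (changes at the interrupting T), and m.315dup (extra C in
the second run).

Because several edit scripts can explain the same observed tract (e.g.
C9TC6 is one delins at 310 or three separate C insertions), classification
works on the literal tract string: each candidate allele label is applied
to the reference tract once, and the observed string is matched against the
results. Every candidate yields a distinct string, so the category is
unambiguous; anything else is "other" (the tract is highly polymorphic and
an explicit category beats an error).
"""

from __future__ import annotations

from dataclasses import dataclass

#: 1-based window the typing logic owns: one anchor base either side of the
#: 303..315 tract so 3'-shifted indel anchors (e.g. a dup at 315) stay inside.
D310_WINDOW = (302, 318)

#: The two C runs and the interrupting T on the reference.
REFERENCE_TRACT = "C" * 7 + "T" + "C" * 5

#: category -> tract string obtained by applying that single allele to the
#: reference tract C7 T C5. All strings are pairwise distinct.
CATEGORY_TRACTS: dict[str, str] = {
    "reference": REFERENCE_TRACT,
    "m.309dup": "C" * 8 + "T" + "C" * 5,
    "m.309del": "C" * 6 + "T" + "C" * 5,
    "m.310del": "C" * 12,
    "m.310T>C": "C" * 13,
    "m.310delinsCCTC": "C" * 9 + "T" + "C" * 6,
    "m.315dup": "C" * 7 + "T" + "C" * 6,
}

_TRACT_TO_CATEGORY = {tract: cat for cat, tract in CATEGORY_TRACTS.items()}
assert len(_TRACT_TO_CATEGORY) == len(CATEGORY_TRACTS), "ambiguous tract table"

CATEGORIES = tuple(CATEGORY_TRACTS) + ("other",)


@dataclass(frozen=True)
class D310Allele:
    """One sample's D310 classification with tract-length bookkeeping."""

    category: str
    tract1_len: int  # C count of the 303-run
    tract2_len: int  # C count of the 311-run
    raw_tract: str   # the sample's literal bases across the locus
    remark: str = ""


def tract_lengths(tract: str) -> tuple[int, int]:
    """(first C-run length, last C-run length) of an observed tract string.

    For tracts without a T (e.g. after m.310del) both numbers count the
    single merged run.
    """
    t1 = 0
    while t1 < len(tract) and tract[t1] == "C":
        t1 += 1
    t2 = 0
    while t2 < len(tract) and tract[-1 - t2] == "C":
        t2 += 1
    return t1, t2


def classify_tract(tract: str) -> D310Allele:
    """Classify a sample's observed D310 tract string.

    IUPAC ambiguity characters make the tract length undefined and force
    "other" with a remark.
    """
    tract = tract.upper()
    t1, t2 = tract_lengths(tract)
    if set(tract) - set("ACGT"):
        return D310Allele("other", t1, t2, tract, remark="heteroplasmic tract")
    category = _TRACT_TO_CATEGORY.get(tract, "other")
    return D310Allele(category, t1, t2, tract)


def category_labels(category: str) -> list[str]:
    """Canonical variant label(s) a category contributes to a sample's calls."""
    if category in ("reference", "other"):
        return []
    return [category]
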