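"""Mitochondrial reference model: the rCRS coordinate system and region annotations.

All positions throughout the package are 1-based and inclusive, matching
m.-style nomenclature (m.16519T>C refers to reference position 16519). The
mitochondrial chromosome is circular; the control region wraps the origin
(16024..576) and is represented as a single interval with ``wraps_origin``
set rather than being split in two.

The packaged reference (``data/synthetic_rcrs.fa``) is a deterministic
synthetic stand-in for the rCRS (NC_012920): it has the exact 16,569 nt
length, the D310 poly-C context (C7 T C5 at positions 303-315), and the
canonical reference allele at every position this package's analyses and
documentation name. Any single-record 16,569 nt A/C/G/T FASTA — including
the real rCRS — can be supplied instead.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from importlib import resources

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MT_LENGTH = 16569

#: Reference alleles the synthetic stand-in is pinned to. These are the
#: positions named by the variants this package discusses (haplogroup-H
#: backbone sites, the Table-style association sites, MDP-region sites,
#: heteroplasmy fixtures), so that e.g. "m.263A>G" is a genuine A>G change
#: on the packaged reference.
PINNED_ALLELES: dict[int, str] = {
    # near-fixed backbone substitutional sites
    263: "A", 750: "A", 1438: "A", 4769: "A", 8860: "A", 15326: "A",
    # control-region / coding association sites
    16519: "T", 10398: "A", 16183: "A", 16189: "T", 16311: "T", 16147: "C",
    # MDP-region sites
    1346: "A", 2706: "A", 2124: "A", 2145: "C", 2146: "A",
    1709: "A", 1716: "A", 1719: "A", 1736: "A", 1811: "A",
    2445: "A", 3010: "A",
    # misc sites used in examples and fixtures
    2275: "T", 3480: "A", 8601: "A",
}

#: The D310 locus context: anchors at 301/302 and 316-318, C7 at 303-309,
#: T at 310, C5 at 311-315.
_D310_BLOCK = {301: "A", 302: "A", 310: "T", 316: "G", 317: "C", 318: "T"}
for _p in range(303, 310):
    _D310_BLOCK[_p] = "C"
for _p in range(311, 316):
    _D310_BLOCK[_p] = "C"


class ReferenceError(ValueError):
    """Raised when a reference FASTA violates the mitogenome contract."""


@dataclass(frozen=True)
class MitoReference:
    """The circular 16,569 nt mitochondrial reference with 1-based access."""

    sequence: str
    name: str = "rCRS"
    circular: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) != MT_LENGTH:
            raise ReferenceError(
                f"reference length mismatch: expected {MT_LENGTH}, "
                f"got {len(self.sequence)}"
            )
        if set(self.sequence) - set("ACGT"):
            bad = sorted(set(self.sequence) - set("ACGT"))
            raise ReferenceError(f"non-ACGT characters in reference: {bad}")

    def base(self, pos: int) -> str:
        """Base at 1-based position ``pos``."""
        if not 1 <= pos <= MT_LENGTH:
            raise IndexError(f"position {pos} outside 1..{MT_LENGTH}")
        return self.sequence[pos - 1]

    def slice(self, start: int, end: int) -> str:
        """Bases from ``start`` to ``end`` inclusive (1-based, non-wrapping)."""
        if not (1 <= start <= end <= MT_LENGTH):
            raise IndexError(f"bad interval {start}..{end}")
        return self.sequence[start - 1 : end]

    def __len__(self) -> int:
        return MT_LENGTH


@dataclass(frozen=True)
class Region:
    """A named annotation interval; ``wraps_origin`` iff start > end."""

    name: str
    start: int
    end: int
    category: str  # control | HVR1 | HVR2 | gene | MDP
    wraps_origin: bool = field(default=False)

    def __post_init__(self) -> None:
        if not (1 <= self.start <= MT_LENGTH and 1 <= self.end <= MT_LENGTH):
            raise ValueError(
                f"region {self.name}: bounds {self.start}..{self.end} "
                f"outside 1..{MT_LENGTH}"
            )
        object.__setattr__(self, "wraps_origin", self.start > self.end)

    def contains(self, pos: int) -> bool:
        if not 1 <= pos <= MT_LENGTH:
            raise IndexError(f"position {pos} outside 1..{MT_LENGTH}")
        if self.wraps_origin:
            return pos >= self.start or pos <= self.end
        return self.start <= pos <= self.end


#: name -> (start, end, category). The control region spans the replication
#: origin; HVR1/HVR2 are the two hypervariable windows within it. The MDP
#: rows are the short mitochondrial-derived-peptide ORFs inside the two
#: rRNA genes (MOTS-c in MT-RNR1; Humanin and SHLP1-6 in MT-RNR2).
DEFAULT_REGIONS: dict[str, tuple[int, int, str]] = {
    "control": (16024, 576, "control"),
    "HVR1": (16024, 16383, "HVR1"),
    "HVR2": (57, 372, "HVR2"),
    "MT-ND3": (10059, 10404, "gene"),
    "MT-RNR1": (648, 1601, "gene"),
    "MT-RNR2": (1669, 3231, "gene"),
    "MOTS-c": (1343, 1393, "MDP"),
    "Humanin": (2633, 2707, "MDP"),
    "SHLP1": (2485, 2559, "MDP"),
    "SHLP2": (2088, 2168, "MDP"),
    "SHLP3": (1703, 1819, "MDP"),
    "SHLP4": (2442, 2522, "MDP"),
    "SHLP5": (2780, 2854, "MDP"),
    "SHLP6": (2990, 3052, "MDP"),
}


def region_table(
    overrides: dict[str, tuple[int, int]] | None = None,
) -> list[Region]:
    """The default region/MDP annotation table, with optional span overrides.

    ``overrides`` maps region name -> (start, end); unknown names add new
    regions with category "gene".
    """
    table: dict[str, Region] = {
        name: Region(name, s, e, cat) for name, (s, e, cat) in DEFAULT_REGIONS.items()
    }
    for name, (s, e) in (overrides or {}).items():
        cat = table[name].category if name in table else "gene"
        table[name] = Region(name, s, e, cat)
    return list(table.values())


def annotate_position(pos: int, regions: list[Region]) -> list[str]:
    """Names of every region containing 1-based ``pos``, sorted by name."""
    if not 1 <= pos <= MT_LENGTH:
        raise IndexError(f"position {pos} outside 1..{MT_LENGTH}")
    return sorted(r.name for r in regions if r.contains(pos))


def annotate_span(start: int, end: int, regions: list[Region]) -> list[str]:
    """Regions containing any position of the (non-wrapping) span start..end."""
    names: set[str] = set()
    for p in range(start, end + 1):
        names.update(annotate_position(p, regions))
    return sorted(names)


def regions_to_bed(regions: list[Region]) -> str:
    """Export regions as BED text (0-based half-open); wrapping regions are
    split into two lines at the origin."""
    lines = []
    for r in regions:
        if r.wraps_origin:
            lines.append(f"chrM\t{r.start - 1}\t{MT_LENGTH}\t{r.name}")
            lines.append(f"chrM\t0\t{r.end}\t{r.name}")
        else:
            lines.append(f"chrM\t{r.start - 1}\t{r.end}\t{r.name}")
    return "\n".join(lines) + "\n"


def load_reference(path: str | Path) -> MitoReference:
    """Load and validate a single-record mitogenome reference FASTA."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise ReferenceError(f"no FASTA records in {path}")
    if len(records) > 1:
        raise ReferenceError(
            f"expected single sequence, found {len(records)} records in {path}"
        )
    rec = records[0]
    return MitoReference(sequence=str(rec.seq).upper(), name=rec.id)


def packaged_reference() -> MitoReference:
    """The reference FASTA shipped with the package (synthetic rCRS stand-in)."""
    with resources.as_file(
        resources.files("mitovar.data").joinpath("synthetic_rcrs.fa")
    ) as p:
        return load_reference(p)


def synthetic_reference_sequence(seed: int = 20569) -> str:
    """Deterministically generate the synthetic rCRS stand-in sequence.

    Uniform-random A/C/G/T of rCRS length, then overwritten with the D310
    context block and the pinned reference alleles. Regenerating with the
    default seed reproduces the packaged file byte-for-byte.
    """
    rng = random.Random(seed)
    bases = [rng.choice("ACGT") for _ in range(MT_LENGTH)]
    for pos, b in {**PINNED_ALLELES, **_D310_BLOCK}.items():
        bases[pos - 1] = b
    return "".join(bases)


def write_synthetic_reference(path: str | Path, seed: int = 20569) -> None:
    """Write the synthetic stand-in reference as a single-record FASTA."""
    seq = synthetic_reference_sequence(seed)
    rec = SeqRecord(
        Seq(seq),
        id="synthetic_rCRS",
        description="synthetic stand-in for NC_012920 (rCRS): length, D310 "
        "context and named variant-site alleles preserved",
    )
    SeqIO.write([rec], str(path), "fasta")
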