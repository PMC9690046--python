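"""Synthetic case/control mitogenome cohorts with a known implanted truth.

The generator emulates the structure of a GenBank-style mtDNA case-control
cohort: a near-fixed six-variant haplogroup backbone, per-variant carrier
probabilities that differ between cases and controls, a categorical D310
poly-C allele per sample (mutually exclusive by construction, so no sample
ever carries both m.310del and m.315dup), Poisson-distributed private
singleton substitutions, occasional heteroplasmic sites encoded as IUPAC
ambiguity bases (the way consensus Sanger submissions carry them),
systematic phantom artifacts implanted at fixed positions across both
groups, and a configurable fraction of samples emitted as HVR1 or HVR2
fragments instead of complete genomes.

Every sample is paired with a :class:`TruthRecord` so downstream stages
(alignment, calling, filtering, statistics) can be tested against ground
truth without any external data. Identical specs (including the seed)
produce byte-identical FASTA output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reference import MitoReference
from .variants import parse_label, apply_variants_to_pieces
from .d310 import D310_WINDOW, CATEGORY_TRACTS

log = logging.getLogger(__name__)

#: The six near-fixed backbone polymorphisms carried by almost every
#: sequence in a haplogroup-H-dominated cohort.
BACKBONE_LABELS = (
    "m.263A>G", "m.750A>G", "m.1438A>G", "m.4769A>G", "m.8860A>G",
    "m.15326A>G",
)

HVR1_WINDOW = (16024, 16383)
HVR2_WINDOW = (57, 372)

_PAIR_TO_IUPAC = {"AC": "M", "AG": "R", "AT": "W", "CG": "S", "CT": "Y",
                  "GT": "K"}


def default_backbone() -> set[str]:
    """The six common backbone polymorphism labels."""
    return set(BACKBONE_LABELS)


@dataclass(frozen=True)
class PhantomSite:
    """A systematic artifact: the same alternate allele implanted at the
    same position in a fixed number of samples across both groups."""

    position: int
    fraction: float = 0.0   # of the whole cohort; at least one sample
    alt: str | None = None  # None: transition partner of the reference base


@dataclass(frozen=True)
class CohortSpec:
    """Simulation recipe for one synthetic case/control cohort."""

    n_cases: int
    n_controls: int
    variant_freqs: dict[str, tuple[float, float]] = field(default_factory=dict)
    d310_mix: dict[str, tuple[float, float]] = field(default_factory=dict)
    backbone_prob: float = 0.98
    singleton_rate: float = 0.0      # Poisson mean per sequence
    heteroplasmy_rate: float = 0.0   # P(one IUPAC site per sequence)
    phantom_sites: tuple[PhantomSite, ...] = ()
    fragment_fraction: float = 0.0
    hvr1_share: float = 1 / 3        # of fragments; remainder are HVR2
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases + self.n_controls <= 0:
            raise ValueError("empty cohort: n_cases + n_controls must be > 0")
        for label in self.d310_mix:
            if label not in CATEGORY_TRACTS or label == "reference":
                raise ValueError(f"unknown D310 allele label {label!r}")
        if self.singleton_rate < 0:
            raise ValueError("singleton_rate must be >= 0")
        for p in [self.backbone_prob, self.heteroplasmy_rate,
                  self.fragment_fraction, self.hvr1_share] + [
                      x for pair in self.variant_freqs.values() for x in pair
                  ] + [x for pair in self.d310_mix.values() for x in pair]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for gi in (0, 1):
            total = sum(pair[gi] for pair in self.d310_mix.values())
            if total > 1.0 + 1e-9:
                raise ValueError(
                    f"d310_mix probabilities sum to {total:.4f} > 1 for "
                    f"{'cases' if gi == 0 else 'controls'}"
                )


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated sample."""

    sample_id: str
    group: str  # "case" | "control"
    implanted_labels: frozenset[str]
    d310_allele: str | None  # category label; None when not covered
    heteroplasmic_sites: tuple[tuple[int, str], ...]  # (position, code)
    phantom_labels: frozenset[str]
    is_fragment: str | None  # None | "HVR1" | "HVR2"

    @property
    def heteroplasmic_positions(self) -> frozenset[int]:
        return frozenset(p for p, _ in self.heteroplasmic_sites)

    @property
    def expected_call_labels(self) -> frozenset[str]:
        """Exactly the labels a faithful caller should report."""
        extra = (
            {self.d310_allele}
            if self.d310_allele and self.d310_allele != "reference"
            else set()
        )
        return self.implanted_labels | self.phantom_labels | extra


def _spans(labels: set[str], ref: MitoReference) -> set[int]:
    out: set[int] = set()
    for lab in labels:
        v = parse_label(lab, ref)
        out.update(range(v.position, v.end_position + 1))
    return out


def simulate_truth(
    spec: CohortSpec, ref: MitoReference
) -> list[TruthRecord]:
    """Draw the cohort's ground truth without building sequences.

    Cheap enough for replicate-heavy calibration studies; the carrier
    composition of the cohort is fully determined here.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    d310_buffer = set(range(D310_WINDOW[0] - 6, D310_WINDOW[1] + 7))
    phantom_positions = {ps.position for ps in spec.phantom_sites}

    samples: list[dict] = []
    for group, n, prefix in (
        ("case", spec.n_cases, "case"),
        ("control", spec.n_controls, "ctrl"),
    ):
        gi = 0 if group == "case" else 1
        for i in range(n):
            labels: set[str] = set()
            if spec.backbone_prob > 0:
                for lab in BACKBONE_LABELS:
                    if rng.random() < spec.backbone_prob:
                        labels.add(lab)
            for lab, pair in spec.variant_freqs.items():
                if rng.random() < pair[gi]:
                    labels.add(lab)

            u = rng.random()
            acc = 0.0
            d310_allele = "reference"
            for lab, pair in spec.d310_mix.items():
                acc += pair[gi]
                if u < acc:
                    d310_allele = lab
                    break

            blocked = (
                _spans(labels, ref) | d310_buffer | phantom_positions
            )
            singles: set[str] = set()
            for _ in range(int(rng.poisson(spec.singleton_rate))):
                for _try in range(100):
                    pos = int(rng.integers(1, len(ref) + 1))
                    if pos not in blocked:
                        break
                else:  # pragma: no cover - genome never this saturated
                    log.warning("no free position for singleton; skipped")
                    continue
                blocked.add(pos)
                r = ref.base(pos)
                alt = "ACGT".replace(r, "")[int(rng.integers(0, 3))]
                singles.add(f"m.{pos}{r}>{alt}")
            labels |= singles

            hets: list[tuple[int, str]] = []
            if rng.random() < spec.heteroplasmy_rate:
                for _try in range(100):
                    pos = int(rng.integers(1, len(ref) + 1))
                    if pos not in blocked:
                        break
                else:  # pragma: no cover
                    pos = None
                if pos is not None:
                    blocked.add(pos)
                    r = ref.base(pos)
                    other = "ACGT".replace(r, "")[int(rng.integers(0, 3))]
                    code = _PAIR_TO_IUPAC["".join(sorted(r + other))]
                    hets.append((pos, code))

            fragment = None
            if rng.random() < spec.fragment_fraction:
                fragment = "HVR1" if rng.random() < spec.hvr1_share else "HVR2"

            samples.append(dict(
                sample_id=f"{prefix}{i + 1:03d}", group=group, labels=labels,
                d310=d310_allele, hets=hets, fragment=fragment,
                phantoms=set(),
            ))

    # cohort-wide phantom implantation across both groups
    n_total = len(samples)
    for ps in spec.phantom_sites:
        n_carriers = max(1, round(ps.fraction * n_total))
        picked = rng.choice(n_total, size=min(n_carriers, n_total),
                            replace=False)
        r = ref.base(ps.position)
        alt = ps.alt or {"A": "G", "G": "A", "C": "T", "T": "C"}[r]
        lab = f"m.{ps.position}{r}>{alt}"
        for idx in picked:
            s = samples[int(idx)]
            occupied = _spans(s["labels"], ref) | {p for p, _ in s["hets"]}
            if ps.position in occupied:
                log.warning(
                    "phantom site %d conflicts with an implant in %s; skipped",
                    ps.position, s["sample_id"],
                )
                continue
            s["phantoms"].add(lab)

    truths = []
    for s in samples:
        window = {"HVR1": HVR1_WINDOW, "HVR2": HVR2_WINDOW}.get(s["fragment"])

        def in_window(lab: str) -> bool:
            if window is None:
                return True
            v = parse_label(lab, ref)
            return window[0] <= v.position and v.end_position <= window[1]

        d310_allele = s["d310"]
        if window is not None and not (
            window[0] <= D310_WINDOW[0] and D310_WINDOW[1] <= window[1]
        ):
            d310_allele = None
        truths.append(TruthRecord(
            sample_id=s["sample_id"],
            group=s["group"],
            implanted_labels=frozenset(filter(in_window, s["labels"])),
            d310_allele=d310_allele,
            heteroplasmic_sites=tuple(
                (p, c) for p, c in s["hets"]
                if window is None or window[0] <= p <= window[1]
            ),
            phantom_labels=frozenset(filter(in_window, s["phantoms"])),
            is_fragment=s["fragment"],
        ))
    return truths


def build_sequence(truth: TruthRecord, ref: MitoReference) -> str:
    """Materialize one truth record into its sample sequence."""
    labels = set(truth.implanted_labels) | set(truth.phantom_labels)
    if truth.d310_allele and truth.d310_allele != "reference":
        labels.add(truth.d310_allele)
    variants = [parse_label(lab, ref) for lab in sorted(labels)]
    pieces = apply_variants_to_pieces(variants, ref)
    for pos, code in truth.heteroplasmic_sites:
        if len(pieces[pos]) != 1:  # pragma: no cover - blocked upstream
            raise ValueError(f"heteroplasmy collides with an edit at {pos}")
        pieces[pos] = code
    window = {"HVR1": HVR1_WINDOW, "HVR2": HVR2_WINDOW}.get(truth.is_fragment)
    lo, hi = window if window else (1, len(ref))
    return "".join(pieces[lo : hi + 1])


def simulate_cohort(
    spec: CohortSpec, ref: MitoReference
) -> tuple[list[SeqRecord], list[TruthRecord]]:
    """Simulate a cohort: FASTA records plus the implanted-truth table."""
    truths = simulate_truth(spec, ref)
    records = [
        SeqRecord(Seq(build_sequence(t, ref)), id=t.sample_id,
                  description=f"group={t.group}"
                  + (f" fragment={t.is_fragment}" if t.is_fragment else ""))
        for t in truths
    ]
    return records, truths


def truth_panel(truths: list[TruthRecord]) -> dict[str, int]:
    """Occurrence counts of genuinely implanted labels (phantoms excluded);
    the truth-derived scoring panel for the phantom filter."""
    counts: dict[str, int] = {}
    for t in truths:
        labels = set(t.implanted_labels)
        if t.d310_allele and t.d310_allele != "reference":
            labels.add(t.d310_allele)
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
    return counts


# --------------------------------------------------------- paper-shaped spec

#: Case/control carrier probabilities for the recurrent association-table
#: variants (carriers over callable samples in each group).
TABLE_VARIANT_FREQS: dict[str, tuple[float, float]] = {
    "m.10398A>G": (9 / 50, 10 / 34),
    "m.16183A>C": (10 / 78, 5 / 34),
    "m.16189T>C": (17 / 90, 9 / 34),
    "m.16311T>C": (11 / 90, 8 / 34),
    "m.16519T>C": (34 / 66, 20 / 34),
}

_D310_CASE_RAW = {
    "m.310del": 27 / 78, "m.310T>C": 4 / 78, "m.310delinsCCTC": 1 / 78,
    "m.315dup": 47 / 78,
}
_D310_CTRL_RAW = {
    "m.310del": 21 / 34, "m.310T>C": 0.0, "m.310delinsCCTC": 1 / 34,
    "m.315dup": 13 / 34,
}


def _normalized_mix() -> dict[str, tuple[float, float]]:
    # The published per-allele fractions use overlapping denominators and
    # sum slightly above 1 in each group; scale each group onto the simplex.
    cs = sum(_D310_CASE_RAW.values())
    ks = sum(_D310_CTRL_RAW.values())
    return {
        lab: (_D310_CASE_RAW[lab] / max(cs, 1.0),
              _D310_CTRL_RAW[lab] / max(ks, 1.0))
        for lab in _D310_CASE_RAW
    }


#: Seven fixed artifact positions, each hitting a single sample by default.
DEFAULT_PHANTOM_SITES = tuple(
    PhantomSite(position=p, fraction=0.0)
    for p in (521, 4121, 5460, 7521, 9377, 11719, 13702)
)


def study_mirror_spec(
    n_cases: int = 78,
    n_controls: int = 34,
    seed: int = 0,
    **overrides,
) -> CohortSpec:
    """A cohort spec shaped like the breast-cancer case-control study:
    Table-style carrier frequencies, the published D310 allele mix, the
    six-variant backbone at 0.98, ~2 private singletons per sequence, a 20%
    heteroplasmy chance, seven single-carrier artifact sites, and 30%
    partial (HVR1/HVR2) sequences."""
    spec = CohortSpec(
        n_cases=n_cases,
        n_controls=n_controls,
        variant_freqs=dict(TABLE_VARIANT_FREQS),
        d310_mix=_normalized_mix(),
        backbone_prob=0.98,
        singleton_rate=2.0,
        heteroplasmy_rate=0.2,
        phantom_sites=DEFAULT_PHANTOM_SITES,
        fragment_fraction=0.3,
        hvr1_share=1 / 3,
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec
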