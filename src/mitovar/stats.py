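"""Cohort-level statistics: carrier tables, chi-square association tests,
variant spectra, shared/unique partitions, population differentiation and
the MDP-region report.

The association test is the uncorrected Pearson chi-square on a 2x2
carrier/non-carrier table with 1 degree of freedom, two-sided via the
upper-tail probability, flagged significant at alpha = 0.05. No
multiple-testing correction is applied to the flags (a Bonferroni-adjusted
alpha column is emitted for transparency in the pipeline report).

Carrier denominators are coverage-aware: a sample counts toward a
variant's denominator only if its footprint covers the variant's full
reference span and no position of the span is censored in that sample
(heteroplasmic or N). This is what lets complete genomes and HVR1/HVR2
fragments share one association table with per-variant denominators.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats as sps

from .align import SampleCall
from .reference import Region
from .variants import Variant, SUBSTITUTION

ALPHA = 0.05


class DegenerateTableError(ValueError):
    """A 2x2 table with a zero margin: the chi-square test is undefined."""


@dataclass(frozen=True)
class CarrierTable2x2:
    label: str
    case_carriers: int
    case_total: int
    control_carriers: int
    control_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.case_carriers <= self.case_total
                and 0 <= self.control_carriers <= self.control_total):
            raise ValueError(f"carriers exceed totals in table for {self.label}")

    @property
    def case_fraction(self) -> float:
        return self.case_carriers / self.case_total

    @property
    def control_fraction(self) -> float:
        return self.control_carriers / self.control_total


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass(frozen=True)
class SpectrumEntry:
    repetition_count: int  # k: number of sequences sharing the variant
    n_variants: int        # distinct variants carried by exactly k sequences
    group_scope: str       # "cases" | "controls" | "combined"


@dataclass(frozen=True)
class PopulationDiff:
    polymorphic_loci: int
    fixed_differences: int
    shared_polymorphisms: int
    monomorphic_in_a_polymorphic_in_b: int
    monomorphic_in_b_polymorphic_in_a: int
    avg_pairwise_diff: float


def chi_square(t: CarrierTable2x2) -> ChiSquareResult:
    """Uncorrected Pearson chi-square (1 df) for a carrier 2x2 table."""
    obs = np.array([
        [t.case_carriers, t.case_total - t.case_carriers],
        [t.control_carriers, t.control_total - t.control_carriers],
    ])
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise DegenerateTableError(
            f"degenerate table for {t.label}: zero row or column margin"
        )
    stat, p, df, _ = sps.chi2_contingency(obs, correction=False)
    return ChiSquareResult(statistic=float(stat), df=int(df), p_value=float(p))


def chi_square_from_counts(
    case_carriers: int, case_total: int,
    control_carriers: int, control_total: int,
    label: str = "",
) -> ChiSquareResult:
    return chi_square(CarrierTable2x2(
        label, case_carriers, case_total, control_carriers, control_total
    ))


def carrier_table(
    calls: list[SampleCall],
    label: str,
    span: tuple[int, int],
) -> CarrierTable2x2:
    """Coverage-aware carrier/non-carrier table for one variant label.

    ``span`` is the variant's full reference span; only samples callable
    across it enter the denominators.
    """
    counts = {"case": [0, 0], "control": [0, 0]}  # [carriers, total]
    for s in calls:
        if s.group not in counts or not s.callable_at(*span):
            continue
        counts[s.group][1] += 1
        if label in s.labels:
            counts[s.group][0] += 1
    if counts["case"][1] == 0 or counts["control"][1] == 0:
        raise DegenerateTableError(
            f"no callable samples for {label} in one group"
        )
    return CarrierTable2x2(
        label,
        counts["case"][0], counts["case"][1],
        counts["control"][0], counts["control"][1],
    )


def variant_spectrum(
    calls: list[SampleCall], scope: str = "combined"
) -> list[SpectrumEntry]:
    """Histogram of distinct variants by the number of sequences sharing
    them (the repetition-frequency spectrum)."""
    selected = [
        s for s in calls
        if scope == "combined"
        or (scope == "cases" and s.group == "case")
        or (scope == "controls" and s.group == "control")
    ]
    per_label = Counter()
    for s in selected:
        for lab in set(s.labels):
            per_label[lab] += 1
    hist = Counter(per_label.values())
    return [
        SpectrumEntry(k, hist[k], scope) for k in sorted(hist)
    ]


def shared_unique_partition(
    calls: list[SampleCall],
) -> tuple[set[str], set[str], set[str]]:
    """Partition distinct labels into (cases_only, controls_only, shared)."""
    in_cases = {lab for s in calls if s.group == "case" for lab in s.labels}
    in_controls = {lab for s in calls if s.group == "control" for lab in s.labels}
    return (in_cases - in_controls, in_controls - in_cases,
            in_cases & in_controls)


def _allele_map(s: SampleCall) -> dict[int, str]:
    return {
        v.position: v.alt_allele
        for v in s.variants if v.klass == SUBSTITUTION
    }


def population_diffs(
    group_a: list[SampleCall], group_b: list[SampleCall]
) -> PopulationDiff:
    """Population differentiation summaries over the jointly callable region.

    Works on the substitution allele at each reference position (indels are
    length changes, not site alleles, and are excluded); positions censored
    in any sample (heteroplasmic/N) are dropped entirely. A fixed difference
    is a position monomorphic within each group for different alleles; a
    shared polymorphism is polymorphic within both. ``avg_pairwise_diff`` is
    the mean count of differing positions over all A x B sequence pairs.
    """
    if not group_a or not group_b:
        raise ValueError("both groups need at least one sequence")
    everyone = group_a + group_b
    lo = max(s.footprint[0] for s in everyone)
    hi = min(s.footprint[1] for s in everyone)
    if lo > hi:
        raise ValueError("no overlapping callable region between the groups")
    censored = set().union(*(s.censored for s in everyone))

    positions = sorted({
        p for s in everyone for p in _allele_map(s)
        if lo <= p <= hi and p not in censored
    })
    a_maps = [_allele_map(s) for s in group_a]
    b_maps = [_allele_map(s) for s in group_b]

    fixed = shared = mono_a_poly_b = mono_b_poly_a = poly = 0
    for p in positions:
        alleles_a = {m.get(p, "ref") for m in a_maps}
        alleles_b = {m.get(p, "ref") for m in b_maps}
        poly_a, poly_b = len(alleles_a) > 1, len(alleles_b) > 1
        if poly_a or poly_b:
            poly += 1
        if poly_a and poly_b:
            shared += 1
        elif poly_b and not poly_a:
            mono_a_poly_b += 1
        elif poly_a and not poly_b:
            mono_b_poly_a += 1
        elif alleles_a != alleles_b:
            fixed += 1

    diffs = [
        sum(1 for p in positions if ma.get(p, "ref") != mb.get(p, "ref"))
        for ma, mb in product(a_maps, b_maps)
    ]
    return PopulationDiff(
        polymorphic_loci=poly,
        fixed_differences=fixed,
        shared_polymorphisms=shared,
        monomorphic_in_a_polymorphic_in_b=mono_a_poly_b,
        monomorphic_in_b_polymorphic_in_a=mono_b_poly_a,
        avg_pairwise_diff=float(np.mean(diffs)) if diffs else 0.0,
    )


def mdp_report(
    calls: list[SampleCall], regions: list[Region]
) -> pd.DataFrame:
    """Per-variant association rows for the mitochondrial-derived-peptide
    (MDP) regions, one row per variant anchored inside an MDP span; regions
    without variants keep a placeholder row (the "-" convention)."""
    mdp_regions = [r for r in regions if r.category == "MDP"]
    rows = []
    all_labels = sorted({
        (v.label, v.position, v.end_position)
        for s in calls for v in s.variants
    }, key=lambda x: x[1])
    for region in sorted(mdp_regions, key=lambda r: r.start):
        hits = [
            (lab, pos, end) for lab, pos, end in all_labels
            if region.contains(pos)
        ]
        if not hits:
            rows.append({
                "region": region.name, "span": f"{region.start}-{region.end}",
                "label": "-", "case_pct": "-", "control_pct": "-", "p": "-",
            })
            continue
        for lab, pos, end in hits:
            try:
                t = carrier_table(calls, lab, (pos, end))
                res = chi_square(t)
                row = {
                    "case_pct": format_pct(t.case_fraction),
                    "control_pct": format_pct(t.control_fraction),
                    "p": format_p(res.p_value),
                }
            except DegenerateTableError:
                row = {"case_pct": "-", "control_pct": "-", "p": "-"}
            rows.append({
                "region": region.name, "span": f"{region.start}-{region.end}",
                "label": lab, **row,
            })
    return pd.DataFrame(
        rows, columns=["region", "span", "label", "case_pct", "control_pct", "p"]
    )


def format_pct(fraction: float) -> str:
    return f"{100 * fraction:.1f}"


def format_p(p: float) -> str:
    return f"{p:.3f}"
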