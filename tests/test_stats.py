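"""Cohort statistics: chi-square against a closed-form oracle, carrier
tables with coverage-aware denominators, spectra, partitions, population
differentiation, MDP report."""

import math

import numpy as np
import pytest

from mitovar.align import call_sample
from mitovar.simulate import CohortSpec, simulate_cohort, study_mirror_spec
from mitovar.stats import (
    CarrierTable2x2,
    DegenerateTableError,
    carrier_table,
    chi_square,
    chi_square_from_counts,
    mdp_report,
    population_diffs,
    shared_unique_partition,
    variant_spectrum,
)


def _oracle_chi2(a, b, c, d):
    """Independent closed form: Pearson statistic via the determinant
    formula, upper tail via the complementary error function (df = 1)."""
    n = a + b + c + d
    stat = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return stat, math.erfc(math.sqrt(stat / 2))


@pytest.mark.parametrize(
    "counts, printed_p",
    [
        ((27, 78, 21, 34), 0.007),   # m.310del
        ((47, 78, 13, 34), 0.030),   # m.315dup
        ((1, 78, 1, 34), 0.542),     # m.310delinsCCTC
        ((1, 52, 0, 34), 0.416),     # m.1346A>G
    ],
)
def test_chi_square_reproduces_published_values(counts, printed_p):
    res = chi_square_from_counts(*counts)
    assert res.df == 1
    assert abs(res.p_value - printed_p) <= 0.002


def test_proportional_table_gives_zero_statistic():
    res = chi_square_from_counts(10, 20, 5, 10)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)
    assert not res.significant


def test_degenerate_tables_raise():
    with pytest.raises(DegenerateTableError):
        chi_square_from_counts(0, 10, 0, 5)     # zero carrier column
    with pytest.raises(DegenerateTableError):
        chi_square_from_counts(10, 10, 5, 5)    # zero non-carrier column
    with pytest.raises(ValueError):
        CarrierTable2x2("x", 11, 10, 0, 5)      # carriers > total


def test_chi_square_matches_closed_form_oracle():
    rng = np.random.default_rng(42)
    checked = 0
    while checked < 200:
        n1, n2 = rng.integers(5, 200, size=2)
        a, c = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
        if a + c == 0 or (n1 - a) + (n2 - c) == 0:
            continue
        res = chi_square_from_counts(int(a), int(n1), int(c), int(n2))
        stat, p = _oracle_chi2(a, n1 - a, c, n2 - c)
        assert abs(res.statistic - stat) < 1e-10
        assert abs(res.p_value - p) < 1e-10
        checked += 1


@pytest.fixture(scope="module")
def called_cohort(ref, regions):
    """Small mixed complete/fragment cohort with no private noise, plus its
    truth, aligned and called once for the table/spectrum tests."""
    spec = study_mirror_spec(n_cases=12, n_controls=8, seed=31,
                             singleton_rate=0.0, heteroplasmy_rate=0.0)
    records, truths = simulate_cohort(spec, ref)
    calls = [
        call_sample(str(r.seq), ref, regions, sample_id=r.id, group=t.group)
        for r, t in zip(records, truths)
    ]
    return calls, truths


def test_carrier_table_forced_extremes(ref, regions):
    spec = CohortSpec(
        n_cases=6, n_controls=4, backbone_prob=0.0,
        variant_freqs={"m.16519T>C": (1.0, 0.0)},
    )
    records, truths = simulate_cohort(spec, ref)
    calls = [call_sample(str(r.seq), ref, regions, sample_id=r.id,
                         group=t.group) for r, t in zip(records, truths)]
    t = carrier_table(calls, "m.16519T>C", (16519, 16519))
    assert (t.case_carriers, t.case_total) == (6, 6)
    assert (t.control_carriers, t.control_total) == (0, 4)


def test_carrier_denominators_follow_coverage(called_cohort):
    calls, truths = called_cohort
    n_complete = sum(1 for t in truths if t.is_fragment is None)
    n_hvr2 = sum(1 for t in truths if t.is_fragment == "HVR2")
    # 16519 sits outside both fragment windows: denominators = completes
    t = carrier_table(calls, "m.16519T>C", (16519, 16519))
    assert t.case_total + t.control_total == n_complete
    # D310 is covered by completes and HVR2 fragments
    t2 = carrier_table(calls, "m.310del", (310, 310))
    assert t2.case_total + t2.control_total == n_complete + n_hvr2


def test_carrier_table_errors_without_coverage(ref, regions):
    spec = study_mirror_spec(4, 3, seed=2, fragment_fraction=1.0,
                             hvr1_share=0.0, singleton_rate=0.0)
    records, truths = simulate_cohort(spec, ref)  # all HVR2 fragments
    calls = [call_sample(str(r.seq), ref, regions, sample_id=r.id,
                         group=t.group) for r, t in zip(records, truths)]
    with pytest.raises(DegenerateTableError):
        carrier_table(calls, "m.16519T>C", (16519, 16519))


def test_variant_spectrum_matches_truth(called_cohort):
    calls, truths = called_cohort
    from collections import Counter

    per_label = Counter()
    for t in truths:
        for lab in t.expected_call_labels:
            per_label[lab] += 1
    expected = Counter(per_label.values())
    spectrum = variant_spectrum(calls, "combined")
    assert {e.repetition_count: e.n_variants for e in spectrum} == dict(expected)
    # mass balance: sum k * n_variants = total calls
    total_calls = sum(len(set(s.labels)) for s in calls)
    assert sum(e.repetition_count * e.n_variants for e in spectrum) == total_calls


def test_spectrum_trivial_shapes(ref):
    from mitovar.align import SampleCall
    from mitovar.variants import parse_label

    def mk(sid, group, labels):
        return SampleCall(sid, group, (1, 16569),
                          tuple(parse_label(l, ref) for l in labels), (), None)

    private = [mk(f"s{i}", "case", [f"m.{1000 + i}{ref.base(1000 + i)}>"
                                    f"{'A' if ref.base(1000 + i) != 'A' else 'G'}"])
               for i in range(4)]
    spec = variant_spectrum(private)
    assert [(e.repetition_count, e.n_variants) for e in spec] == [(1, 4)]
    shared = [mk(f"s{i}", "case", ["m.16519T>C"]) for i in range(5)]
    spec2 = variant_spectrum(shared)
    assert [(e.repetition_count, e.n_variants) for e in spec2] == [(5, 1)]
    assert variant_spectrum([]) == []


def test_shared_unique_partition(called_cohort):
    calls, truths = called_cohort
    cases_only, controls_only, shared = shared_unique_partition(calls)
    assert not cases_only & controls_only
    assert not cases_only & shared and not controls_only & shared
    all_labels = {lab for s in calls for lab in s.labels}
    assert cases_only | controls_only | shared == all_labels
    in_cases = {lab for s in calls if s.group == "case" for lab in s.labels}
    in_ctrl = {lab for s in calls if s.group == "control" for lab in s.labels}
    assert shared == in_cases & in_ctrl
    # permutation invariance in sample order
    assert shared_unique_partition(calls[::-1]) == (
        cases_only, controls_only, shared)


def test_population_diffs_identity_case(ref, regions):
    calls = [call_sample(ref.sequence, ref, regions, sample_id=f"s{i}",
                         group=g)
             for i, g in enumerate(["case", "case", "control"])]
    d = population_diffs(calls[:2], calls[2:])
    assert (d.polymorphic_loci, d.fixed_differences,
            d.shared_polymorphisms, d.avg_pairwise_diff) == (0, 0, 0, 0.0)


def test_population_diffs_forced_fixed_difference(ref, regions):
    from mitovar.variants import apply_labels

    seq = apply_labels(["m.16519T>C"], ref)
    a = [call_sample(seq, ref, regions, sample_id=f"a{i}", group="case")
         for i in range(3)]
    b = [call_sample(ref.sequence, ref, regions, sample_id=f"b{i}",
                     group="control") for i in range(2)]
    d = population_diffs(a, b)
    assert d.fixed_differences == 1
    assert d.avg_pairwise_diff == 1.0
    assert d.polymorphic_loci == 0


def test_population_diffs_matches_hamming_oracle(ref, regions):
    """On substitution-only cohorts the average pairwise difference must
    equal the brute-force Hamming distance between raw sequences."""
    spec = CohortSpec(n_cases=5, n_controls=5, backbone_prob=0.9,
                      singleton_rate=3.0, seed=77,
                      variant_freqs={"m.16519T>C": (0.7, 0.2),
                                     "m.10398A>G": (0.3, 0.6)})
    records, truths = simulate_cohort(spec, ref)
    calls = [call_sample(str(r.seq), ref, regions, sample_id=r.id,
                         group=t.group) for r, t in zip(records, truths)]
    a = [c for c in calls if c.group == "case"]
    b = [c for c in calls if c.group == "control"]
    d = population_diffs(a, b)
    seqs = {r.id: str(r.seq) for r in records}
    hams = [
        sum(x != y for x, y in zip(seqs[ca.sample_id], seqs[cb.sample_id]))
        for ca in a for cb in b
    ]
    assert d.avg_pairwise_diff == pytest.approx(float(np.mean(hams)))
    assert (d.shared_polymorphisms
            + d.monomorphic_in_a_polymorphic_in_b
            + d.monomorphic_in_b_polymorphic_in_a) == d.polymorphic_loci


def test_population_diffs_contracts(ref, regions):
    c = call_sample(ref.sequence, ref, regions, sample_id="x", group="case")
    with pytest.raises(ValueError, match="at least one"):
        population_diffs([c], [])
    frag1 = call_sample(ref.slice(16024, 16383), ref, regions, sample_id="f1",
                        group="case")
    frag2 = call_sample(ref.slice(57, 372), ref, regions, sample_id="f2",
                        group="control")
    with pytest.raises(ValueError, match="no overlapping"):
        population_diffs([frag1], [frag2])


def test_mdp_report_placement(ref, regions):
    from mitovar.variants import apply_labels

    seq_case = apply_labels(["m.3010A>G", "m.1346A>G"], ref)
    calls = (
        [call_sample(seq_case, ref, regions, sample_id=f"c{i}", group="case")
         for i in range(3)]
        + [call_sample(ref.sequence, ref, regions, sample_id=f"k{i}",
                       group="control") for i in range(2)]
    )
    df = mdp_report(calls, regions)
    shlp6 = df[(df.region == "SHLP6") & (df.label == "m.3010A>G")]
    assert len(shlp6) == 1 and shlp6.iloc[0]["p"] != "-"
    mots = df[(df.region == "MOTS-c") & (df.label == "m.1346A>G")]
    assert len(mots) == 1
    # a variant outside every MDP window is absent; empty regions keep "-"
    assert not (df.label == "m.16519T>C").any()
    assert (df[df.region == "SHLP5"].label == "-").all()
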