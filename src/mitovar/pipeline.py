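"""End-to-end orchestration: simulate | run | table-stats.

``run`` executes the full analysis on a cohort FASTA plus a two-column
sample-group manifest: align every sample to the reference, call and
normalize variants, type D310, screen phantom artifacts, build
coverage-aware carrier tables, chi-square every testable label, and write
a stable set of TSV/JSON outputs. Unalignable sequences are skipped with a
logged warning and counted in the summary; every input sample ends up in
exactly one of the per-sample results or the skip list.

``table_stats`` is the direct reproduction path: it applies the chi-square
test row-wise to externally supplied carrier counts (label,
case_carriers, case_total, control_carriers, control_total), bypassing
alignment entirely.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .align import AlignParams, SampleCall, UnalignableError, call_sample
from .phantom import apply_filter, read_panel, score_variants
from .reference import MitoReference, load_reference, packaged_reference, region_table
from .simulate import CohortSpec, PhantomSite, simulate_cohort, truth_panel
from .stats import (
    ALPHA,
    DegenerateTableError,
    carrier_table,
    chi_square,
    chi_square_from_counts,
    format_p,
    format_pct,
    mdp_report,
    population_diffs,
    shared_unique_partition,
    variant_spectrum,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    fasta: str
    manifest: str
    out_dir: str
    reference: str | None = None          # None: packaged synthetic rCRS
    region_overrides: dict = field(default_factory=dict)
    align: AlignParams = field(default_factory=AlignParams)
    panel: str | None = None
    phantom_threshold: int = 3
    phantom_min_shared: int = 2
    phantom_policy: str = "exclude"
    write_vcf: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "align" in raw:
            raw["align"] = AlignParams(**raw["align"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))


def read_manifest(path: str | Path) -> dict[str, str]:
    groups: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        sample_id, group = line.split("\t")[:2]
        if group not in ("case", "control"):
            raise ValueError(
                f"manifest group for {sample_id!r} must be case|control, "
                f"got {group!r}"
            )
        groups[sample_id] = group
    return groups


def _load_ref(config: RunConfig) -> MitoReference:
    return (
        load_reference(config.reference) if config.reference
        else packaged_reference()
    )


def cmd_simulate(
    spec: CohortSpec, out_dir: str | Path, ref: MitoReference | None = None
) -> dict[str, str]:
    """Write cohort FASTA, truth TSV, manifest TSV, truth panel and the
    spec used. Returns the paths."""
    ref = ref or packaged_reference()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, truths = simulate_cohort(spec, ref)

    fasta = out / "cohort.fa"
    SeqIO.write(records, str(fasta), "fasta")

    truth_tsv = out / "truth.tsv"
    rows = []
    for t in truths:
        rows.append({
            "sample_id": t.sample_id,
            "group": t.group,
            "implanted_labels": ";".join(sorted(t.implanted_labels)),
            "d310_allele": t.d310_allele or "",
            "heteroplasmies": ";".join(
                f"{p}{c}" for p, c in t.heteroplasmic_sites
            ),
            "phantom_labels": ";".join(sorted(t.phantom_labels)),
            "fragment": t.is_fragment or "",
        })
    pd.DataFrame(rows).to_csv(truth_tsv, sep="\t", index=False)

    manifest = out / "manifest.tsv"
    manifest.write_text(
        "".join(f"{t.sample_id}\t{t.group}\n" for t in truths)
    )

    panel_tsv = out / "truth_panel.tsv"
    panel_tsv.write_text(
        "".join(f"{lab}\t{n}\n" for lab, n in sorted(truth_panel(truths).items()))
    )

    spec_yaml = out / "spec.yaml"
    raw = asdict(spec)
    raw["phantom_sites"] = [asdict(ps) for ps in spec.phantom_sites]
    spec_yaml.write_text(yaml.safe_dump(raw, sort_keys=True))
    return {
        "fasta": str(fasta), "truth": str(truth_tsv),
        "manifest": str(manifest), "panel": str(panel_tsv),
        "spec": str(spec_yaml),
    }


def load_spec(path: str | Path) -> CohortSpec:
    raw = yaml.safe_load(Path(path).read_text())
    raw["phantom_sites"] = tuple(
        PhantomSite(**ps) for ps in raw.get("phantom_sites", [])
    )
    raw["variant_freqs"] = {
        k: tuple(v) for k, v in raw.get("variant_freqs", {}).items()
    }
    raw["d310_mix"] = {
        k: tuple(v) for k, v in raw.get("d310_mix", {}).items()
    }
    return CohortSpec(**raw)


def cmd_run(config: RunConfig) -> dict:
    """Run the full pipeline; returns (and writes) the run summary."""
    ref = _load_ref(config)
    regions = region_table(
        {k: tuple(v) for k, v in config.region_overrides.items()}
    )
    groups = read_manifest(config.manifest)
    records = list(SeqIO.parse(config.fasta, "fasta"))
    if not records:
        raise ValueError(f"no sequences in {config.fasta}")
    missing = [r.id for r in records if r.id not in groups]
    if missing:
        raise ValueError(
            f"manifest missing group for sample(s): {', '.join(missing)}"
        )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    calls: list[SampleCall] = []
    skipped: list[dict] = []
    for rec in records:
        try:
            calls.append(call_sample(
                str(rec.seq), ref, regions, config.align,
                sample_id=rec.id, group=groups[rec.id],
            ))
        except UnalignableError as exc:
            log.warning("skipping %s: %s", rec.id, exc)
            skipped.append({"sample_id": rec.id, "reason": str(exc)})

    panel = read_panel(config.panel) if config.panel else None
    verdicts = score_variants(
        calls, panel, config.phantom_threshold, config.phantom_min_shared
    )
    calls, exclusions = apply_filter(calls, verdicts, config.phantom_policy)

    # ---- per-sample variants
    var_rows = [
        {
            "sample_id": s.sample_id, "group": s.group, "label": v.label,
            "position": v.position, "end_position": v.end_position,
            "class": v.klass, "regions": ";".join(v.regions),
        }
        for s in calls for v in s.variants
    ]
    pd.DataFrame(
        var_rows,
        columns=["sample_id", "group", "label", "position", "end_position",
                 "class", "regions"],
    ).to_csv(out / "per_sample_variants.tsv", sep="\t", index=False)

    # ---- D310 summary
    d310_rows = [
        {
            "sample_id": s.sample_id, "group": s.group,
            "d310_category": s.d310.category if s.d310 else "uncallable",
            "tract1_len": s.d310.tract1_len if s.d310 else "",
            "tract2_len": s.d310.tract2_len if s.d310 else "",
            "raw_tract": s.d310.raw_tract if s.d310 else "",
            "remark": s.d310.remark if s.d310 else "",
        }
        for s in calls
    ]
    pd.DataFrame(d310_rows).to_csv(out / "d310_summary.tsv", sep="\t",
                                   index=False)

    # ---- exclusion report and verdicts
    pd.DataFrame(
        exclusions, columns=["sample_id", "label", "position", "action"]
    ).to_csv(out / "exclusions.tsv", sep="\t", index=False)
    pd.DataFrame([asdict(v) for v in verdicts]).to_csv(
        out / "phantom_verdicts.tsv", sep="\t", index=False
    )

    # ---- association table over every remaining label
    spans = {
        v.label: (v.position, v.end_position)
        for s in calls for v in s.variants
    }
    n_tests = len(spans)
    assoc_rows = []
    for label in sorted(spans, key=lambda lab: spans[lab][0]):
        span = spans[label]
        regions_str = ";".join(
            sorted({r for s in calls for v in s.variants
                    if v.label == label for r in v.regions})
        )
        try:
            t = carrier_table(calls, label, span)
            res = chi_square(t)
            assoc_rows.append({
                "label": label, "regions": regions_str,
                "case_pct": format_pct(t.case_fraction),
                "case_counts": f"{t.case_carriers}/{t.case_total}",
                "control_pct": format_pct(t.control_fraction),
                "control_counts": f"{t.control_carriers}/{t.control_total}",
                "p": format_p(res.p_value),
                "significant": res.significant,
                "bonferroni_alpha": (
                    f"{ALPHA / n_tests:.2e}" if n_tests else ""
                ),
            })
        except DegenerateTableError:
            assoc_rows.append({
                "label": label, "regions": regions_str,
                "case_pct": "-", "case_counts": "-",
                "control_pct": "-", "control_counts": "-",
                "p": "-", "significant": False, "bonferroni_alpha": "",
            })
    assoc = pd.DataFrame(assoc_rows)
    assoc.to_csv(out / "association.tsv", sep="\t", index=False)

    # ---- spectrum, partition
    spec_rows = [
        asdict(e)
        for scope in ("cases", "controls", "combined")
        for e in variant_spectrum(calls, scope)
    ]
    pd.DataFrame(spec_rows).to_csv(out / "spectrum.tsv", sep="\t", index=False)
    cases_only, controls_only, shared = shared_unique_partition(calls)

    # ---- MDP report
    mdp_report(calls, regions).to_csv(out / "mdp_report.tsv", sep="\t",
                                      index=False)

    # ---- population differentiation (needs a common callable interval)
    pop = None
    case_calls = [s for s in calls if s.group == "case"]
    ctrl_calls = [s for s in calls if s.group == "control"]
    try:
        pop = asdict(population_diffs(case_calls, ctrl_calls))
    except ValueError as exc:
        log.info("population_diffs skipped: %s", exc)

    summary = {
        "n_input": len(records),
        "n_called": len(calls),
        "n_skipped": len(skipped),
        "skipped": skipped,
        "n_labels": n_tests,
        "n_excluded_calls": len(exclusions),
        "partition": {
            "cases_only": len(cases_only),
            "controls_only": len(controls_only),
            "shared": len(shared),
        },
        "population_diffs": pop,
        "significant_labels": [
            r["label"] for r in assoc_rows if r.get("significant")
        ],
        "settings": {
            "phantom_threshold": config.phantom_threshold,
            "phantom_min_shared": config.phantom_min_shared,
            "phantom_policy": config.phantom_policy,
            "identity_floor": config.align.identity_floor,
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))

    if config.write_vcf:
        from .variants import write_vcf

        vcf_dir = out / "vcf"
        vcf_dir.mkdir(exist_ok=True)
        for s in calls:
            write_vcf(str(vcf_dir / f"{s.sample_id}.vcf"), s.sample_id,
                      list(s.variants), ref)
    return summary


def table_stats(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-wise chi-square over externally supplied carrier counts.

    Expects columns label, case_carriers, case_total, control_carriers,
    control_total; extra columns (region, dbsnp, ...) pass through.
    Degenerate rows get "-" instead of a p-value.
    """
    required = ["label", "case_carriers", "case_total",
                "control_carriers", "control_total"]
    for col in required:
        if col not in counts.columns:
            raise ValueError(f"counts table missing column {col!r}")
    out = counts.copy()
    pcts, ps, sig = [], [], []
    for _, row in counts.iterrows():
        pcts.append((
            format_pct(row.case_carriers / row.case_total),
            format_pct(row.control_carriers / row.control_total),
        ))
        try:
            res = chi_square_from_counts(
                int(row.case_carriers), int(row.case_total),
                int(row.control_carriers), int(row.control_total),
                label=str(row.label),
            )
            ps.append(format_p(res.p_value))
            sig.append(res.significant)
        except DegenerateTableError:
            ps.append("-")
            sig.append(False)
    out["case_pct"] = [a for a, _ in pcts]
    out["control_pct"] = [b for _, b in pcts]
    out["p"] = ps
    out["significant"] = sig
    return out
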