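"""Phantom-polymorphism screening.

Phantom polymorphisms are systematic sequencing artifacts that masquerade
as variants. The screen scores each called label against a reference
frequency panel (occurrence counts in a collection of complete
mitogenomes) and applies a rarity + recurrence rule:

* panel score >= ``threshold`` (default 3)            -> common
* score < threshold, carried by >= ``min_shared``
  cohort samples (default 2)                          -> rare (kept, flagged)
* score < threshold and below ``min_shared`` carriers -> phantom candidate

Phantom candidates are removed from association analysis (policy
"exclude") or merely reported (policy "report-only"); rare labels are
always retained. The haplogroup-defining backbone labels are whitelisted
from exclusion by default.

The original scoring panels are compiled from thousands of complete
mitogenomes and are not redistributable, so the panel here is an input
table (two-column TSV: label, count). Without a panel the cohort's own
carrier counts are used as the score, which is logged loudly because it
weakens the rule to pure recurrence.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace as dc_replace
from pathlib import Path

from .align import SampleCall
from .simulate import default_backbone

log = logging.getLogger(__name__)

COMMON = "common"
RARE = "rare"
PHANTOM = "phantom_candidate"


@dataclass(frozen=True)
class ScoredVariant:
    label: str
    score: int         # occurrence count in the reference panel
    cohort_count: int  # carriers within this cohort
    verdict: str


def cohort_counts(calls: list[SampleCall]) -> Counter:
    """Carriers per distinct label (each sample counted once per label)."""
    c: Counter = Counter()
    for s in calls:
        for lab in set(s.labels):
            c[lab] += 1
    return c


def score_variants(
    calls: list[SampleCall],
    panel: dict[str, int] | None,
    threshold: int = 3,
    min_shared: int = 2,
) -> list[ScoredVariant]:
    """Score every distinct called label against the panel."""
    counts = cohort_counts(calls)
    if not panel:
        log.warning(
            "no reference panel provided: falling back to the cohort's own "
            "carrier counts as scores; phantom screening is then pure "
            "recurrence and cannot use external frequency evidence"
        )
    scored = []
    for label, n in sorted(counts.items()):
        score = panel.get(label, 0) if panel else n
        if score >= threshold:
            verdict = COMMON
        elif n >= min_shared:
            verdict = RARE
        else:
            verdict = PHANTOM
        scored.append(ScoredVariant(label, score, n, verdict))
    return scored


def apply_filter(
    calls: list[SampleCall],
    verdicts: list[ScoredVariant],
    policy: str = "exclude",
    whitelist: set[str] | None = None,
) -> tuple[list[SampleCall], list[dict]]:
    """Remove phantom-candidate labels from the cohort's calls.

    Returns the filtered calls and an exclusion report listing every
    removed call (one row per sample x label). With policy "report-only"
    nothing is removed but the report is still produced.
    """
    if policy not in ("exclude", "report-only"):
        raise ValueError(f"unknown policy {policy!r}")
    whitelist = default_backbone() if whitelist is None else whitelist
    to_drop = {
        sv.label for sv in verdicts
        if sv.verdict == PHANTOM and sv.label not in whitelist
    }
    report = []
    filtered = []
    for s in calls:
        hit = [v for v in s.variants if v.label in to_drop]
        for v in hit:
            report.append({
                "sample_id": s.sample_id,
                "label": v.label,
                "position": v.position,
                "action": "excluded" if policy == "exclude" else "flagged",
            })
        if policy == "exclude" and hit:
            filtered.append(dc_replace(
                s, variants=tuple(v for v in s.variants if v.label not in to_drop)
            ))
        else:
            filtered.append(s)
    return filtered, report


def read_panel(path: str | Path) -> dict[str, int]:
    """Read a two-column (label, count) TSV panel."""
    panel: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        label, count = line.split("\t")[:2]
        panel[label] = int(count)
    return panel


def write_panel(path: str | Path, panel: dict[str, int]) -> None:
    Path(path).write_text(
        "".join(f"{lab}\t{n}\n" for lab, n in sorted(panel.items()))
    )
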