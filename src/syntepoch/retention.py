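"""Gene retention patterns across the three chronological epochs.

Each subject-genome gene is scored for presence (O) or absence (X) of at
least one collinear copy in recent, young, and old segments, giving one of
eight retention indexes:

    1 OXX   2 OOX   3 OXO   4 OOO   5 XXX   6 XOX   7 XXO   8 XOO

Index 5 (no collinearity anywhere) is kept as an explicit record rather
than dropped.  Subject genes with recent-epoch copies are further grouped
into homoeologue sets of 1-4 expected copies (the triplication bound).
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .synteny import SyntenicSegment

__all__ = [
    "RetentionRecord",
    "HomoeologGroup",
    "PATTERN_TO_INDEX",
    "INDEX_TO_PATTERN",
    "classify_retention",
    "retention_report",
    "group_homoeologs",
]

#: presence over (recent, young, old) -> retention index
PATTERN_TO_INDEX: dict[tuple[bool, bool, bool], int] = {
    (True, False, False): 1,
    (True, True, False): 2,
    (True, False, True): 3,
    (True, True, True): 4,
    (False, False, False): 5,
    (False, True, False): 6,
    (False, False, True): 7,
    (False, True, True): 8,
}
INDEX_TO_PATTERN = {v: k for k, v in PATTERN_TO_INDEX.items()}

EPOCHS = ("recent", "young", "old")


def pattern_string(presence: tuple[bool, bool, bool]) -> str:
    return "".join("O" if p else "X" for p in presence)


@dataclass
class RetentionRecord:
    """Presence pattern and retention index for one subject gene."""

    subject_gene: str
    presence: tuple[bool, bool, bool]
    index: int
    copies: dict[str, list[str]] = field(default_factory=dict)  # epoch -> query genes

    @property
    def pattern(self) -> str:
        return pattern_string(self.presence)


@dataclass
class HomoeologGroup:
    """A subject gene with its recent-epoch query copies."""

    subject_gene: str
    copies: list[str]
    fate: str | None = None
    flagged: bool = False  # more copies than the triplication can explain

    @property
    def copy_count(self) -> int:
        return len(self.copies)


def classify_retention(
    subject_genes: Iterable[str],
    segments: Sequence[SyntenicSegment],
) -> list[RetentionRecord]:
    """One retention record per subject gene from epoch-labelled segments."""
    copies: dict[str, dict[str, list[str]]] = {}
    for seg in segments:
        if seg.epoch not in EPOCHS:
            raise ValueError(f"segment {seg.segment_id} has no epoch label")
        for q, s in seg.members:
            copies.setdefault(s, {e: [] for e in EPOCHS})[seg.epoch].append(q)
    records = []
    for gene in subject_genes:
        per_epoch = copies.get(gene, {e: [] for e in EPOCHS})
        presence = tuple(bool(per_epoch[e]) for e in EPOCHS)
        records.append(
            RetentionRecord(
                subject_gene=gene,
                presence=presence,  # type: ignore[arg-type]
                index=PATTERN_TO_INDEX[presence],  # type: ignore[index]
                copies={e: sorted(per_epoch[e]) for e in EPOCHS},
            )
        )
    return records


def retention_report(
    records: Sequence[RetentionRecord],
    pair_ks_map: Mapping[tuple[str, str], float] | None = None,
) -> dict:
    """Index counts/percentages and the derived retention rates.

    Returns a dict with a per-index table and scalar rates:
    ``collinear_fraction`` (indexes other than 5), ``recent_fraction``
    (indexes 1-4 among collinear), and young vs old shares among
    long-retention genes (index 2 vs 3+4).  When ``pair_ks_map`` is given,
    per-index per-epoch Ks standard deviations are included.
    """
    total = len(records)
    counts = {i: 0 for i in range(1, 9)}
    for r in records:
        counts[r.index] += 1
    rows = []
    for idx in range(1, 9):
        row = {
            "index": idx,
            "pattern": pattern_string(INDEX_TO_PATTERN[idx]),
            "count": counts[idx],
            "percent": 100.0 * counts[idx] / total if total else 0.0,
        }
        if pair_ks_map is not None:
            for ei, epoch in enumerate(EPOCHS):
                values = [
                    pair_ks_map[(q, r.subject_gene)]
                    for r in records
                    if r.index == idx and r.presence[ei]
                    for q in r.copies[epoch]
                    if (q, r.subject_gene) in pair_ks_map
                ]
                row[f"sd_ks_{epoch}"] = (
                    statistics.stdev(values) if len(values) >= 2 else math.nan
                )
        rows.append(row)
    table = pd.DataFrame(rows)

    collinear = total - counts[5]
    recent_retaining = counts[1] + counts[2] + counts[3] + counts[4]
    long_retention = counts[2] + counts[3] + counts[4]
    return {
        "table": table,
        "total": total,
        "collinear_count": collinear,
        "collinear_fraction": collinear / total if total else 0.0,
        "lost_fraction": counts[5] / total if total else 0.0,
        "recent_fraction_of_collinear": recent_retaining / collinear if collinear else 0.0,
        "young_share_of_long_retention": counts[2] / long_retention if long_retention else 0.0,
        "old_share_of_long_retention": (counts[3] + counts[4]) / long_retention if long_retention else 0.0,
    }


def group_homoeologs(records: Sequence[RetentionRecord]) -> tuple[list[HomoeologGroup], dict]:
    """Homoeologue groups (subject genes with >=1 recent copy) + histogram.

    The histogram buckets copy counts 1, 2, 3 and 4; groups exceeding four
    copies are retained but flagged.  ``pair_share`` divides each bucket's
    total copies by the total number of recent-epoch pairs.
    """
    groups = []
    for r in records:
        recent = r.copies.get("recent", [])
        if not recent:
            continue
        groups.append(
            HomoeologGroup(
                subject_gene=r.subject_gene,
                copies=list(recent),
                flagged=len(recent) > 4,
            )
        )
    hist = {1: 0, 2: 0, 3: 0, 4: 0}
    total_pairs = sum(g.copy_count for g in groups)
    pair_counts = {1: 0, 2: 0, 3: 0, 4: 0}
    for g in groups:
        bucket = min(g.copy_count, 4)
        hist[bucket] += 1
        pair_counts[bucket] += g.copy_count
    summary = {
        "histogram": hist,
        "n_groups": len(groups),
        "total_recent_pairs": total_pairs,
        "pair_share": {
            k: (pair_counts[k] / total_pairs if total_pairs else 0.0) for k in hist
        },
        "n_flagged": sum(g.flagged for g in groups),
    }
    return groups, summary
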