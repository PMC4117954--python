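"""Detect fast-evolving genes as per-segment Ks outliers.

Within each syntenic segment the member Ks values are summarized by their
mean and sample (n-1) standard deviation; each member's z-score against
its own segment is converted to an upper-tail standard-normal p-value and
genes with p below the cutoff (default 0.001) are called fast-evolving.
Segments with too few members or zero spread are skipped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import norm

from .synteny import SyntenicSegment, segment_stats

__all__ = ["FastGeneCall", "detect_fast_genes", "fast_gene_report"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FastGeneCall:
    """z-score evidence for one collinear pair within its segment."""

    query_gene: str
    subject_gene: str
    segment_id: str
    ks: float
    segment_mean: float
    segment_sd: float
    z: float
    p: float
    is_fast: bool

    @property
    def pair(self) -> tuple[str, str]:
        return (self.query_gene, self.subject_gene)


def detect_fast_genes(
    segments: Sequence[SyntenicSegment],
    pair_ks_map: Mapping[tuple[str, str], float],
    alpha: float = 0.001,
    min_pairs: int = 5,
    two_sided: bool = False,
    leave_one_out: bool = False,
) -> list[FastGeneCall]:
    """Score every member of every eligible segment.

    A segment is eligible when it has at least ``min_pairs`` members and a
    positive Ks standard deviation; ineligible segments are skipped with a
    log message.  By default the tested gene's own Ks contributes to its
    segment's mean and sd; ``leave_one_out`` recomputes both without it.
    The test is one-sided (upper tail) unless ``two_sided``.
    """
    calls: list[FastGeneCall] = []
    for seg in segments:
        if seg.n_pairs < min_pairs:
            logger.info("segment %s skipped: %d < %d pairs", seg.segment_id, seg.n_pairs, min_pairs)
            continue
        values = [float(pair_ks_map[m]) for m in seg.members]  # KeyError via segment_stats below
        mean, sd = segment_stats(seg, pair_ks_map)
        if not sd or sd <= 0:
            logger.info("segment %s skipped: zero Ks spread", seg.segment_id)
            continue
        n = len(values)
        total = sum(values)
        sumsq = sum((v - mean) ** 2 for v in values)
        for member, ks in zip(seg.members, values):
            if leave_one_out:
                if n < 3:
                    continue
                loo_mean = (total - ks) / (n - 1)
                loo_var = max((sumsq - (ks - mean) ** 2 * n / (n - 1)) / (n - 2), 0.0)
                m_, s_ = loo_mean, math.sqrt(loo_var)
                if s_ <= 0:
                    continue
            else:
                m_, s_ = mean, sd
            z = (ks - m_) / s_
            p = float(norm.sf(abs(z)) * 2) if two_sided else float(norm.sf(z))
            p = min(max(p, 5e-324), 1.0)
            is_fast = bool(p < alpha and z > 0)
            calls.append(
                FastGeneCall(
                    query_gene=member[0],
                    subject_gene=member[1],
                    segment_id=seg.segment_id,
                    ks=ks,
                    segment_mean=m_,
                    segment_sd=s_,
                    z=z,
                    p=p,
                    is_fast=is_fast,
                )
            )
    return calls


def fast_gene_report(
    calls: Iterable[FastGeneCall],
    segments: Sequence[SyntenicSegment],
    query_genes: Mapping[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Counts of fast genes by epoch, query chromosome, and block.

    ``query_genes`` optionally maps query gene id -> chromosome; when
    omitted, chromosome counts use the segment's query chromosome.  Each
    table carries a percentage column over its own total.
    """
    seg_by_id = {s.segment_id: s for s in segments}
    fast = [c for c in calls if c.is_fast]

    def tally(key_fn) -> pd.DataFrame:
        counts: dict[str, int] = {}
        seg_sets: dict[str, set[str]] = {}
        for c in fast:
            key = key_fn(c)
            counts[key] = counts.get(key, 0) + 1
            seg_sets.setdefault(key, set()).add(c.segment_id)
        total = sum(counts.values())
        rows = [
            {
                "category": k,
                "n_fast_genes": counts[k],
                "n_segments": len(seg_sets[k]),
                "percent": 100.0 * counts[k] / total if total else 0.0,
            }
            for k in sorted(counts)
        ]
        return pd.DataFrame(rows, columns=["category", "n_fast_genes", "n_segments", "percent"])

    def epoch_of(c: FastGeneCall) -> str:
        return seg_by_id[c.segment_id].epoch or "unclassified"

    def chrom_of(c: FastGeneCall) -> str:
        if query_genes is not None and c.query_gene in query_genes:
            return query_genes[c.query_gene]
        return seg_by_id[c.segment_id].query_chromosome

    def block_of(c: FastGeneCall) -> str:
        return seg_by_id[c.segment_id].block or "unassigned"

    return {
        "epoch": tally(epoch_of),
        "chromosome": tally(chrom_of),
        "block": tally(block_of),
    }


def write_fast_calls(calls: Sequence[FastGeneCall], tsv_path: str | Path) -> None:
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("query_gene\tsubject_gene\tsegment_id\tks\tsegment_mean\t"
                 "segment_sd\tz\tp\tis_fast\n")
        for c in calls:
            fh.write(f"{c.query_gene}\t{c.subject_gene}\t{c.segment_id}\t{c.ks:.6f}\t"
                     f"{c.segment_mean:.6f}\t{c.segment_sd:.6f}\t{c.z:.6f}\t"
                     f"{c.p:.6g}\t{int(c.is_fast)}\n")
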