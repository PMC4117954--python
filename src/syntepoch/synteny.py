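"""Chain homologous anchors into syntenic segments.

A syntenic segment is a run of anchor pairs strictly monotone in gene rank
on both genomes (increasing on the query; increasing or decreasing on the
subject depending on orientation), with bounded rank and physical gaps
between consecutive members.  Chains are found by dynamic programming per
chromosome pair and orientation, scored by member count, and extracted
greedily best-first without anchor reuse.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .io_formats import AnchorPair, GeneModel

__all__ = [
    "SyntenicSegment",
    "chain_anchors",
    "segment_stats",
    "attach_segment_stats",
    "write_segments",
    "read_segments",
]


@dataclass
class SyntenicSegment:
    """An ordered run of collinear anchor pairs on one chromosome pair."""

    segment_id: str
    query_chromosome: str
    subject_chromosome: str
    orientation: str  # "same" | "inverted"
    members: list[tuple[str, str]]  # (query_gene, subject_gene), query order
    query_span: tuple[int, int]  # bp, half-open
    subject_span: tuple[int, int]
    mean_ks: float | None = None
    sd_ks: float | None = None
    epoch: str | None = None
    block: str | None = None
    extras: dict = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return len(self.members)

    @property
    def query_span_bp(self) -> int:
        return self.query_span[1] - self.query_span[0]


def _index_genes(genes: Sequence[GeneModel], label: str) -> dict[str, GeneModel]:
    idx: dict[str, GeneModel] = {}
    for g in genes:
        if g.gene_id in idx:
            raise ValidationError(f"duplicate {label} gene id {g.gene_id!r}")
        idx[g.gene_id] = g
    return idx


def chain_anchors(
    anchors: Sequence[AnchorPair],
    genes_q: Sequence[GeneModel],
    genes_s: Sequence[GeneModel],
    max_gap_genes: float = 10,
    max_gap_bp: float = math.inf,
    min_anchors: int = 5,
) -> list[SyntenicSegment]:
    """Chain anchors into syntenic segments.

    ``max_gap_genes`` bounds the number of intervening genes between
    consecutive members on either genome; ``max_gap_bp`` bounds the
    physical distance between their gene spans.  Either limit is disabled
    when set to ``math.inf``.  Chains shorter than ``min_anchors`` are
    discarded.  Output is independent of the input anchor row order.
    """
    qidx = _index_genes(genes_q, "query")
    sidx = _index_genes(genes_s, "subject")
    unknown = sorted(
        {a.query_gene for a in anchors if a.query_gene not in qidx}
        | {a.subject_gene for a in anchors if a.subject_gene not in sidx}
    )
    if unknown:
        raise ValidationError(f"anchor gene ids not in gene models: {unknown}")

    # group by chromosome pair; canonical ordering for determinism
    groups: dict[tuple[str, str], list[AnchorPair]] = {}
    for a in sorted(set(anchors), key=lambda a: (a.query_gene, a.subject_gene)):
        qg, sg = qidx[a.query_gene], sidx[a.subject_gene]
        groups.setdefault((qg.chromosome, sg.chromosome), []).append(a)

    chains: list[tuple] = []
    for (qchrom, schrom), group in sorted(groups.items()):
        chains.extend(_extract_chains(group, qidx, sidx, max_gap_genes, max_gap_bp, min_anchors))

    # deterministic segment ids by genomic position
    chains.sort(key=lambda c: (c[1], c[3][0], c[2], c[4][0], c[5]))
    segments = []
    for i, (members, qchrom, schrom, qspan, sspan, orientation) in enumerate(chains, 1):
        segments.append(
            SyntenicSegment(
                segment_id=f"seg{i:05d}",
                query_chromosome=qchrom,
                subject_chromosome=schrom,
                orientation=orientation,
                members=members,
                query_span=qspan,
                subject_span=sspan,
            )
        )
    return segments


def _extract_chains(group, qidx, sidx, max_gap_genes, max_gap_bp, min_anchors):
    """Greedy best-first extraction of collinear chains from one group."""
    items = []
    for a in group:
        qg, sg = qidx[a.query_gene], sidx[a.subject_gene]
        items.append((qg.rank, sg.rank, qg, sg, a))
    out = []
    remaining = items
    while len(remaining) >= min_anchors:
        best = None
        for orientation in ("same", "inverted"):
            cand = _best_chain(remaining, orientation, max_gap_genes, max_gap_bp)
            if cand is None:
                continue
            # score by length; ties by smaller query start, then orientation
            key = (-len(cand), min(it[2].start for it in cand),
                   0 if orientation == "same" else 1)
            if best is None or key < best[0]:
                best = (key, cand, orientation)
        if best is None or len(best[1]) < min_anchors:
            break
        _, chain, orientation = best
        members = [(it[4].query_gene, it[4].subject_gene) for it in chain]
        qspan = (min(it[2].start for it in chain), max(it[2].end for it in chain))
        sspan = (min(it[3].start for it in chain), max(it[3].end for it in chain))
        qchrom = chain[0][2].chromosome
        schrom = chain[0][3].chromosome
        out.append((members, qchrom, schrom, qspan, sspan, orientation))
        used = {id(it) for it in chain}
        remaining = [it for it in remaining if id(it) not in used]
    return out


def _gap_ok(a, b, sign, max_gap_genes, max_gap_bp) -> bool:
    qrank_a, srank_a, qga, sga, _ = a
    qrank_b, srank_b, qgb, sgb, _ = b
    if qrank_b <= qrank_a:
        return False
    if sign * (srank_b - srank_a) <= 0:
        return False
    if qrank_b - qrank_a - 1 > max_gap_genes:
        return False
    if abs(srank_b - srank_a) - 1 > max_gap_genes:
        return False
    if math.isfinite(max_gap_bp):
        qgap = max(0, qgb.start - qga.end)
        s_lo, s_hi = (sga, sgb) if sgb.start >= sga.start else (sgb, sga)
        sgap = max(0, s_hi.start - s_lo.end)
        if qgap > max_gap_bp or sgap > max_gap_bp:
            return False
    return True


def _best_chain(items, orientation, max_gap_genes, max_gap_bp):
    """Longest collinear chain by DP; deterministic tie-breaking."""
    if not items:
        return None
    sign = 1 if orientation == "same" else -1
    order = sorted(items, key=lambda it: (it[0], sign * it[1]))
    n = len(order)
    best_len = [1] * n
    parent = [-1] * n
    lo = 0
    for i in range(n):
        if math.isfinite(max_gap_genes):
            # predecessors more than max_gap_genes ranks back can never link
            while order[lo][0] < order[i][0] - max_gap_genes - 1:
                lo += 1
        start = lo if math.isfinite(max_gap_genes) else 0
        for j in range(start, i):
            if best_len[j] + 1 > best_len[i] and _gap_ok(order[j], order[i], sign,
                                                         max_gap_genes, max_gap_bp):
                best_len[i] = best_len[j] + 1
                parent[i] = j
    end = max(range(n), key=lambda i: (best_len[i], -order[i][0]))
    chain = []
    i = end
    while i != -1:
        chain.append(order[i])
        i = parent[i]
    chain.reverse()
    return chain


def segment_stats(segment: SyntenicSegment,
                  pair_ks_map: Mapping[tuple[str, str], float]) -> tuple[float, float | None]:
    """Arithmetic mean and sample (n-1) standard deviation of member Ks.

    The sd is ``None`` when the segment has a single member.  A missing Ks
    for any member is an error.
    """
    values = []
    for m in segment.members:
        if m not in pair_ks_map:
            raise ValidationError(f"segment {segment.segment_id}: no Ks for pair {m}")
        values.append(float(pair_ks_map[m]))
    mean = sum(values) / len(values)
    sd = statistics.stdev(values) if len(values) >= 2 else None
    return mean, sd


def attach_segment_stats(segments: Iterable[SyntenicSegment],
                         pair_ks_map: Mapping[tuple[str, str], float]) -> None:
    """Populate mean_ks/sd_ks on every segment in place."""
    for seg in segments:
        seg.mean_ks, seg.sd_ks = segment_stats(seg, pair_ks_map)


def write_segments(segments: Sequence[SyntenicSegment], segments_tsv: str | Path,
                   members_tsv: str | Path | None = None) -> None:
    with open(segments_tsv, "w", encoding="utf-8") as fh:
        fh.write("segment_id\tquery_chromosome\tsubject_chromosome\torientation\t"
                 "query_start\tquery_end\tsubject_start\tsubject_end\tn_pairs\t"
                 "mean_ks\tsd_ks\tepoch\tblock\n")
        for s in segments:
            mean = "" if s.mean_ks is None else f"{s.mean_ks:.6f}"
            sd = "" if s.sd_ks is None else f"{s.sd_ks:.6f}"
            fh.write(f"{s.segment_id}\t{s.query_chromosome}\t{s.subject_chromosome}\t"
                     f"{s.orientation}\t{s.query_span[0]}\t{s.query_span[1]}\t"
                     f"{s.subject_span[0]}\t{s.subject_span[1]}\t{s.n_pairs}\t"
                     f"{mean}\t{sd}\t{s.epoch or ''}\t{s.block or ''}\n")
    if members_tsv is not None:
        with open(members_tsv, "w", encoding="utf-8") as fh:
            fh.write("segment_id\tquery_gene\tsubject_gene\n")
            for s in segments:
                for q, sub in s.members:
                    fh.write(f"{s.segment_id}\t{q}\t{sub}\n")


def read_segments(segments_tsv: str | Path, members_tsv: str | Path) -> list[SyntenicSegment]:
    seg_df = pd.read_csv(segments_tsv, sep="\t", comment="#", dtype=str)
    mem_df = pd.read_csv(members_tsv, sep="\t", comment="#", dtype=str)
    members: dict[str, list[tuple[str, str]]] = {}
    for row in mem_df.itertuples(index=False):
        members.setdefault(row.segment_id, []).append((row.query_gene, row.subject_gene))
    out = []
    for row in seg_df.itertuples(index=False):

        def _opt(v):
            return None if (v is None or (isinstance(v, float) and math.isnan(v)) or v == "") else v

        mean_ks = _opt(row.mean_ks)
        sd_ks = _opt(row.sd_ks)
        out.append(
            SyntenicSegment(
                segment_id=row.segment_id,
                query_chromosome=row.query_chromosome,
                subject_chromosome=row.subject_chromosome,
                orientation=row.orientation,
                members=members.get(row.segment_id, []),
                query_span=(int(row.query_start), int(row.query_end)),
                subject_span=(int(row.subject_start), int(row.subject_end)),
                mean_ks=None if mean_ks is None else float(mean_ks),
                sd_ks=None if sd_ks is None else float(sd_ks),
                epoch=_opt(row.epoch),
                block=_opt(row.block),
            )
        )
    return out
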