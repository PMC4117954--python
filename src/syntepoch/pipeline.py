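"""Run the full analysis end-to-end from a config, with resumable stages.

Stage order: chain -> kaks -> chronology -> fastgenes / retention -> fate
-> enrich -> report.  Every stage writes its result as TSV into the output
directory; a rerun with ``resume=True`` reloads finished stages from those
files, and a manifest records the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import tomllib
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .errors import ConfigError
from .io_formats import (
    read_anchor_pairs,
    read_expression,
    read_fasta,
    read_gene_models,
    read_go,
    read_kaks_table,
    write_kaks_table,
)
from .synteny import attach_segment_stats, chain_anchors, read_segments, write_segments
from .divergence import kaks_for_anchors, kaks_ratio
from .chronology import assign_blocks, assign_epochs, epoch_report, fit_epochs, read_blocks
from .fast_evolving import detect_fast_genes, fast_gene_report, write_fast_calls
from .retention import classify_retention, group_homoeologs, retention_report
from .gene_fate import call_fate, fate_report
from .enrichment import enrich, write_enrichment

logger = logging.getLogger(__name__)

STAGES = ("chain", "kaks", "chronology", "fastgenes", "retention", "fate",
          "enrich", "report")


@dataclass
class PipelineConfig:
    """Paths and tunables for a pipeline run; unknown keys are rejected."""

    # inputs
    query_gff3: str = ""
    subject_gff3: str = ""
    anchors: str = ""
    kaks_table: str = ""  # precomputed Ka/Ks TSV; empty = compute from CDS
    query_cds: str = ""
    subject_cds: str = ""
    expression: str = ""
    go: str = ""
    go_slim: str = ""
    blocks: str = ""
    outdir: str = "results"
    # tunables
    evalue_cutoff: float = 1e-5
    max_gap_genes: float = 10
    max_gap_bp: float = math.inf
    min_anchors: int = 5
    epoch_method: str = "mixture"  # or "fixed"
    epoch_cutpoints: tuple[float, ...] = ()
    fast_alpha: float = 0.001
    fast_min_pairs: int = 5
    fate_alpha: float = 0.001
    rpkm_depth: float = 1e6
    enrich_alpha: float = 0.001
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "epoch_cutpoints" in raw:
            raw["epoch_cutpoints"] = tuple(raw["epoch_cutpoints"])
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    segments: list = field(default_factory=list)
    pair_ks: dict = field(default_factory=dict)
    pair_ka: dict = field(default_factory=dict)
    epoch_model: object = None
    fast_calls: list = field(default_factory=list)
    retention_records: list = field(default_factory=list)
    homoeolog_groups: list = field(default_factory=list)
    fate_calls: list = field(default_factory=list)
    enrichment: list = field(default_factory=list)
    tables: dict = field(default_factory=dict)


def _require(path: str, what: str) -> Path:
    if not path:
        raise ConfigError(f"config is missing the {what} path")
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"{what} file not found: {p}")
    return p


def run_pipeline(config: PipelineConfig, stages: Sequence[str] = STAGES,
                 resume: bool = False) -> PipelineResult:
    """Execute the requested stages in dependency order."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res = PipelineResult()

    genes_q = read_gene_models(_require(config.query_gff3, "query GFF3"), "query")
    genes_s = read_gene_models(_require(config.subject_gff3, "subject GFF3"), "subject")
    anchors = read_anchor_pairs(_require(config.anchors, "anchors"), config.evalue_cutoff)

    seg_tsv = outdir / "segments.tsv"
    mem_tsv = outdir / "segment_members.tsv"
    if "chain" in stages:
        if resume and seg_tsv.exists() and mem_tsv.exists():
            res.segments = read_segments(seg_tsv, mem_tsv)
        else:
            res.segments = chain_anchors(
                anchors, genes_q, genes_s,
                max_gap_genes=config.max_gap_genes,
                max_gap_bp=config.max_gap_bp,
                min_anchors=config.min_anchors,
            )
        logger.info("chain: %d anchors -> %d segments", len(anchors), len(res.segments))

    kaks_tsv = outdir / "kaks_estimates.tsv"
    if "kaks" in stages:
        if config.kaks_table:
            table = read_kaks_table(_require(config.kaks_table, "Ka/Ks table"))
        elif resume and kaks_tsv.exists():
            table = read_kaks_table(kaks_tsv)
        else:
            cds_q = read_fasta(_require(config.query_cds, "query CDS"))
            cds_s = read_fasta(_require(config.subject_cds, "subject CDS"))
            chained = {m for s in res.segments for m in s.members} or {
                (a.query_gene, a.subject_gene) for a in anchors
            }
            pairs = [a for a in anchors if (a.query_gene, a.subject_gene) in chained]
            estimates = kaks_for_anchors(pairs, cds_q, cds_s)
            table = {(e.query_gene, e.subject_gene): (e.ka, e.ks) for e in estimates
                     if not (math.isnan(e.ks) or math.isnan(e.ka))}
            write_kaks_table(table, kaks_tsv)
        res.pair_ka = {p: ka for p, (ka, ks) in table.items()}
        res.pair_ks = {p: ks for p, (ka, ks) in table.items()}
        logger.info("kaks: %d pairs with estimates", len(res.pair_ks))

    if "chronology" in stages:
        # drop chained pairs without a usable Ks (saturated/missing)
        for seg in res.segments:
            seg.members = [m for m in seg.members if m in res.pair_ks]
        res.segments = [s for s in res.segments if s.n_pairs >= 2]
        attach_segment_stats(res.segments, res.pair_ks)
        res.epoch_model = fit_epochs(
            [s.mean_ks for s in res.segments],
            method=config.epoch_method,
            weights=[s.n_pairs for s in res.segments],
            cutpoints=config.epoch_cutpoints or None,
        )
        assign_epochs(res.segments, res.epoch_model)
        if config.blocks:
            block_defs = read_blocks(_require(config.blocks, "blocks"))
            assign_blocks(res.segments, block_defs)
        write_segments(res.segments, seg_tsv, mem_tsv)
        report = epoch_report(
            res.segments,
            subject_genome_size=len(genes_s),
            query_genome_size=sum(g.end - g.start for g in genes_q),
        )
        report.to_csv(outdir / "epoch_report.tsv", sep="\t", index=False)
        res.tables["epoch_report"] = report
        logger.info("chronology: cutpoints %s", res.epoch_model.cutpoints)

    if "fastgenes" in stages:
        res.fast_calls = detect_fast_genes(
            res.segments, res.pair_ks,
            alpha=config.fast_alpha, min_pairs=config.fast_min_pairs,
        )
        write_fast_calls(res.fast_calls, outdir / "fast_gene_calls.tsv")
        chrom_of = {g.gene_id: g.chromosome for g in genes_q}
        for name, df in fast_gene_report(res.fast_calls, res.segments, chrom_of).items():
            df.to_csv(outdir / f"fast_genes_by_{name}.tsv", sep="\t", index=False)
        n_fast = sum(c.is_fast for c in res.fast_calls)
        logger.info("fastgenes: %d fast of %d tested", n_fast, len(res.fast_calls))

    if "retention" in stages:
        res.retention_records = classify_retention(
            [g.gene_id for g in genes_s], res.segments
        )
        rep = retention_report(res.retention_records, res.pair_ks)
        rep["table"].to_csv(outdir / "retention_report.tsv", sep="\t", index=False)
        res.tables["retention"] = rep
        res.homoeolog_groups, hist = group_homoeologs(res.retention_records)
        res.tables["homoeolog_histogram"] = hist
        with open(outdir / "homoeolog_groups.tsv", "w", encoding="utf-8") as fh:
            fh.write("subject_gene\tcopy_count\tcopies\n")
            for g in res.homoeolog_groups:
                fh.write(f"{g.subject_gene}\t{g.copy_count}\t{','.join(g.copies)}\n")

    if "fate" in stages:
        expr = read_expression(_require(config.expression, "expression table"))
        ratios = {q: kaks_ratio(res.pair_ka.get((q, s), math.nan),
                                res.pair_ks.get((q, s), math.nan))
                  for grp in res.homoeolog_groups
                  for q, s in ((c, grp.subject_gene) for c in grp.copies)}
        res.fate_calls = []
        for grp in res.homoeolog_groups:
            call = call_fate(grp, expr, ratios, alpha=config.fate_alpha,
                             depth=config.rpkm_depth)
            grp.fate = call.fate
            res.fate_calls.append(call)
        rep = fate_report(res.fate_calls)
        rep["matrix"].to_csv(outdir / "fate_matrix.tsv", sep="\t")
        res.tables["fate"] = rep
        with open(outdir / "fate_calls.tsv", "w", encoding="utf-8") as fh:
            fh.write("subject_gene\tcopy_count\tfate\texpressed_copies\tmax_kaks\n")
            for c in res.fate_calls:
                fh.write(f"{c.subject_gene}\t{c.copy_count}\t{c.fate}\t"
                         f"{','.join(c.expressed_copies)}\t{c.max_kaks:.4f}\n")

    if "enrich" in stages:
        ann = read_go(_require(config.go, "GO annotation"),
                      config.go_slim or None)
        fast_set = {c.query_gene for c in res.fast_calls if c.is_fast}
        if fast_set:
            background = {g.gene_id for g in genes_q} - fast_set
            res.enrichment = enrich(fast_set, background, ann,
                                    alpha=config.enrich_alpha)
            write_enrichment(res.enrichment, outdir / "fast_gene_enrichment.tsv")

    if "report" in stages:
        tables = make_summary_tables(res)
        for name, df in tables.items():
            df.to_csv(outdir / f"summary_{name}.tsv", sep="\t",
                      index=isinstance(df.index, pd.MultiIndex) or df.index.name is not None)
        res.tables.update(tables)

    manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "stages": list(stages),
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return res


# ---------------------------------------------------------------------------
# publication-style tables

def round_percent(value: float) -> float:
    """Percentage rounded half-up to two decimals (display convention)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def percent_column(counts: Sequence[float]) -> list[float]:
    """Two-decimal half-up percentages of the grand total."""
    total = sum(counts)
    if total == 0:
        return [0.0 for _ in counts]
    return [round_percent(100.0 * c / total) for c in counts]


def make_summary_tables(res: PipelineResult) -> dict[str, pd.DataFrame]:
    """Epoch, retention-index and fate summary tables from stage results."""
    tables: dict[str, pd.DataFrame] = {}
    if "epoch_report" in res.tables:
        tables["epochs"] = res.tables["epoch_report"].copy()
    if res.retention_records:
        counts = {i: 0 for i in range(1, 9)}
        for r in res.retention_records:
            counts[r.index] += 1
        tables["retention_indexes"] = retention_index_table(counts)
    if res.fate_calls:
        tables["fates"] = res.tables["fate"]["matrix"].copy()
    return tables


def retention_index_table(counts: Mapping[int, int]) -> pd.DataFrame:
    """Index counts with two-decimal half-up percentage column."""
    from .retention import INDEX_TO_PATTERN, pattern_string

    idx = sorted(counts)
    values = [counts[i] for i in idx]
    return pd.DataFrame(
        {
            "index": idx,
            "pattern": [pattern_string(INDEX_TO_PATTERN[i]) for i in idx],
            "count": values,
            "percent": percent_column(values),
        }
    )


def epoch_share_table(counts: Mapping[str, int]) -> pd.DataFrame:
    """Per-category counts with half-up percentage shares of the total."""
    keys = list(counts)
    values = [counts[k] for k in keys]
    return pd.DataFrame({"category": keys, "count": values,
                         "percent": percent_column(values)})
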