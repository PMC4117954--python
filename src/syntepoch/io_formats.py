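"""Readers and writers for every external file the pipeline touches.

All coordinates are stored 0-based half-open internally; GFF3 emission and
parsing convert to/from the format's 1-based closed convention.  Tabular
files are tab-separated UTF-8 with ``#``-prefixed comment lines.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

__all__ = [
    "GeneModel",
    "AnchorPair",
    "ExpressionTable",
    "GoAnnotation",
    "read_gene_models",
    "write_gene_models",
    "read_anchor_pairs",
    "write_anchor_pairs",
    "read_expression",
    "write_expression",
    "read_go",
    "write_go",
    "read_kaks_table",
    "write_kaks_table",
    "read_fasta",
    "write_fasta",
]


@dataclass(frozen=True)
class GeneModel:
    """One gene locus: identifier, placement, and rank along its chromosome.

    ``start``/``end`` are 0-based half-open; ``rank`` is the dense 0-based
    order of the gene among all genes of the same chromosome.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    rank: int
    species: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class AnchorPair:
    """A homologous gene pair between the query and subject genomes."""

    query_gene: str
    subject_gene: str
    evalue: float
    score: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValidationError(
                f"anchor {self.query_gene}/{self.subject_gene}: negative e-value"
            )


class ExpressionTable:
    """Gene x library RPKM matrix with a tissue label per library.

    Thin wrapper over a pandas DataFrame (genes as index, libraries as
    columns) that enforces non-negativity and unique library ids.
    """

    def __init__(self, matrix: pd.DataFrame, tissues: Mapping[str, str] | None = None):
        if matrix.columns.duplicated().any():
            raise ValidationError("duplicate library ids in expression table")
        if matrix.index.duplicated().any():
            raise ValidationError("duplicate gene ids in expression table")
        if (matrix.to_numpy() < 0).any():
            raise ValidationError("negative RPKM value in expression table")
        self.matrix = matrix.astype(float)
        # default: tissue label == library id
        self.tissues = dict(tissues) if tissues else {c: c for c in matrix.columns}
        missing = set(matrix.columns) - set(self.tissues)
        if missing:
            raise ValidationError(f"libraries without tissue label: {sorted(missing)}")

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def libraries(self) -> list[str]:
        return list(self.matrix.columns)

    def row(self, gene_id: str) -> pd.Series:
        if gene_id not in self.matrix.index:
            raise KeyError(f"gene {gene_id} not in expression table")
        return self.matrix.loc[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.matrix.index

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ExpressionTable)
            and self.matrix.equals(other.matrix)
            and self.tissues == other.tissues
        )


@dataclass
class GoAnnotation:
    """Gene -> GO terms, plus the GO -> GO-slim roll-up map.

    ``namespaces`` maps each term (and slim) id to BP/MF/CC.
    """

    gene_terms: dict[str, set[str]] = field(default_factory=dict)
    slim_map: dict[str, str] = field(default_factory=dict)
    namespaces: dict[str, str] = field(default_factory=dict)

    def terms_of(self, gene_id: str) -> set[str]:
        return self.gene_terms.get(gene_id, set())

    def slims_of(self, gene_id: str) -> set[str]:
        return {self.slim_map[t] for t in self.terms_of(gene_id) if t in self.slim_map}

    def annotated_genes(self, term: str) -> set[str]:
        return {g for g, ts in self.gene_terms.items() if term in ts}

    def all_terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.gene_terms.values():
            out |= ts
        return out


# ---------------------------------------------------------------------------
# GFF3

_GFF3_COLS = 9
_ATTR_ID_RE = re.compile(r"(?:^|;)\s*ID=([^;]+)")


def read_gene_models(gff3_path: str | Path, species_tag: str) -> list[GeneModel]:
    """Read gene features from a GFF3 file.

    Returns genes sorted by (chromosome, start) with dense 0-based ranks
    per chromosome.  GFF3's 1-based closed coordinates are converted to
    0-based half-open.
    """
    records: list[tuple[str, int, int, str, str]] = []
    seen_ids: set[str] = set()
    with open(gff3_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _GFF3_COLS:
                raise ParseError(
                    f"{gff3_path}:{lineno}: expected {_GFF3_COLS} tab-separated "
                    f"columns, got {len(fields)}"
                )
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{gff3_path}:{lineno}: non-integer coordinate") from exc
            m = _ATTR_ID_RE.search(attrs)
            if not m:
                raise ParseError(f"{gff3_path}:{lineno}: gene feature without ID attribute")
            gene_id = m.group(1)
            if gene_id in seen_ids:
                raise ValidationError(f"{gff3_path}: duplicate gene_id {gene_id!r}")
            seen_ids.add(gene_id)
            records.append((seqid, start1 - 1, end1, strand, gene_id))

    records.sort(key=lambda r: (r[0], r[1], r[4]))
    genes: list[GeneModel] = []
    rank = 0
    prev_chrom: str | None = None
    for chrom, start0, end0, strand, gene_id in records:
        if chrom != prev_chrom:
            rank = 0
            prev_chrom = chrom
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chromosome=chrom,
                start=start0,
                end=end0,
                strand=strand,
                rank=rank,
                species=species_tag,
            )
        )
        rank += 1
    return genes


def write_gene_models(genes: Iterable[GeneModel], gff3_path: str | Path) -> None:
    """Emit genes as GFF3 (1-based closed coordinates)."""
    with open(gff3_path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start, g.gene_id)):
            fh.write(
                f"{g.chromosome}\tsyntepoch\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# tabular helpers

def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    return df


def read_anchor_pairs(tsv_path: str | Path, evalue_cutoff: float = 1e-5) -> list[AnchorPair]:
    """Read homologous anchor pairs, applying the e-value cutoff.

    Rows with ``evalue >= evalue_cutoff`` are dropped; exact duplicate
    (query, subject) pairs are collapsed keeping the best (highest) score.
    Many-to-many relationships are preserved.
    """
    df = _read_tsv(tsv_path, ["query", "subject", "evalue", "score"])
    best: dict[tuple[str, str], AnchorPair] = {}
    for row in df.itertuples(index=False):
        evalue = float(row.evalue)
        score = float(row.score)
        if evalue >= evalue_cutoff:
            continue
        key = (row.query, row.subject)
        prev = best.get(key)
        if prev is None or score > prev.score:
            best[key] = AnchorPair(row.query, row.subject, evalue, score)
    return sorted(best.values(), key=lambda a: (a.query_gene, a.subject_gene))


def write_anchor_pairs(pairs: Iterable[AnchorPair], tsv_path: str | Path) -> None:
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("query\tsubject\tevalue\tscore\n")
        for p in pairs:
            fh.write(f"{p.query_gene}\t{p.subject_gene}\t{p.evalue:g}\t{p.score:g}\n")


def read_expression(tsv_path: str | Path, tissues: Mapping[str, str] | None = None) -> ExpressionTable:
    """Read a gene x library RPKM table (first column ``gene``)."""
    df = _read_tsv(tsv_path, ["gene"])
    if df.columns[0] != "gene":
        raise SchemaError(f"{tsv_path}: first column must be 'gene'")
    mat = df.set_index("gene").astype(float)
    return ExpressionTable(mat, tissues)


def write_expression(table: ExpressionTable, tsv_path: str | Path) -> None:
    out = table.matrix.copy()
    out.index.name = "gene"
    out.to_csv(tsv_path, sep="\t")


def read_go(tsv_path: str | Path, slim_tsv_path: str | Path | None = None) -> GoAnnotation:
    """Read gene->term and (optionally) term->slim tables.

    The annotation TSV needs columns ``gene`` and ``term``; the slim TSV
    needs ``term``, ``slim`` and ``namespace``.
    """
    ann = GoAnnotation()
    df = _read_tsv(tsv_path, ["gene", "term"])
    for row in df.itertuples(index=False):
        ann.gene_terms.setdefault(row.gene, set()).add(row.term)
    if slim_tsv_path is not None:
        sdf = _read_tsv(slim_tsv_path, ["term", "slim", "namespace"])
        for row in sdf.itertuples(index=False):
            if not isinstance(row.namespace, str) or row.namespace not in ("BP", "MF", "CC"):
                raise ValidationError(
                    f"slim id {row.slim!r} referenced without a valid namespace record"
                )
            ann.slim_map[row.term] = row.slim
            ann.namespaces[row.term] = row.namespace
            ann.namespaces[row.slim] = row.namespace
    return ann


def write_go(ann: GoAnnotation, tsv_path: str | Path, slim_tsv_path: str | Path | None = None) -> None:
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("gene\tterm\n")
        for gene in sorted(ann.gene_terms):
            for term in sorted(ann.gene_terms[gene]):
                fh.write(f"{gene}\t{term}\n")
    if slim_tsv_path is not None:
        with open(slim_tsv_path, "w", encoding="utf-8") as fh:
            fh.write("term\tslim\tnamespace\n")
            for term in sorted(ann.slim_map):
                fh.write(f"{term}\t{ann.slim_map[term]}\t{ann.namespaces.get(term, 'BP')}\n")


def read_kaks_table(tsv_path: str | Path) -> dict[tuple[str, str], tuple[float, float]]:
    """Read a precomputed Ka/Ks table: (query, subject) -> (ka, ks)."""
    df = _read_tsv(tsv_path, ["query", "subject", "ka", "ks"])
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for row in df.itertuples(index=False):
        ka, ks = float(row.ka), float(row.ks)
        if ka < 0 or ks < 0:
            raise ValidationError(f"negative Ka/Ks for pair {row.query}/{row.subject}")
        out[(row.query, row.subject)] = (ka, ks)
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence dict."""
    from Bio import SeqIO

    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValidationError(f"{path}: duplicate sequence id {rec.id!r}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_kaks_table(kaks: Mapping[tuple[str, str], tuple[float, float]], tsv_path: str | Path) -> None:
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("query\tsubject\tka\tks\n")
        for (q, s), (ka, ks) in sorted(kaks.items()):
            fh.write(f"{q}\t{s}\t{ka:.6f}\t{ks:.6f}\n")
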