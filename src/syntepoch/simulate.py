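"""Synthetic two-genome datasets with known ground truth.

The generator emulates a mesohexaploid history: an ancestral ("subject",
Arabidopsis-like) gene order undergoes three successive polyploidy events
oldest-first — two whole-genome duplications and a final triplication —
each leaving a lineage track whose surviving gene copies pair with their
ancestral genes at a characteristic synonymous divergence (the epoch
depth).  With full retention every ancestral gene therefore leaves
3 x 2 x 2 = 12 query copies: three recent tracks, three young, six old.

Fractionation acts at two scales, as it does in real polyploids: whole
ancestral blocks are lost per track (block survival), and genes within a
surviving block are lost individually (gene retention).  Surviving blocks
become the true syntenic segments; they are shuffled and concatenated into
query chromosomes so that a chaining algorithm can rediscover them.

Per-pair Ks is Normal(epoch depth, dispersion) truncated at 0.01; a
configurable fraction of recent/young pairs is inflated to plant
fast-evolving genes.  CDS pairs are generated by mutating the ancestral
codon sequence with the expected numbers of synonymous and nonsynonymous
events.  Expression counts are Poisson (negative binomial if an
overdispersion size is set) at fixed library depth, converted to RPKM at
unit gene length so zero RPKM corresponds exactly to zero reads; fates are
planted per homoeologue group.  GO terms include one designated term with
a planted fold enrichment in a recorded truth set.
"""

from __future__ import annotations

import itertools
import json
import math
import string
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .divergence import STOP_CODONS, _syn_fraction, _translate_codon
from .errors import ConfigError
from .io_formats import (
    AnchorPair,
    ExpressionTable,
    GeneModel,
    GoAnnotation,
    write_anchor_pairs,
    write_expression,
    write_fasta,
    write_gene_models,
    write_go,
    write_kaks_table,
)

__all__ = ["EpochSpec", "SimulationConfig", "GroundTruth", "SimulatedDataset",
           "simulate_dataset", "evolve_codon_pair", "mutate_cds"]

EPOCHS = ("recent", "young", "old")

_SENSE_CODONS = sorted(
    c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
    if c not in STOP_CODONS
)


@dataclass(frozen=True)
class EpochSpec:
    """Fractionation regime for one epoch's lineage tracks."""

    depth: float  # target mean Ks of the epoch's pairs
    n_tracks: int  # surviving genome copies carrying this epoch label
    block_survival: float  # probability an ancestral block survives per track
    gene_retention: float  # per-gene retention within a surviving block
    block_length: int  # ancestral genes per block


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the study conditions.

    The three epochs correspond to the Brassica triplication (recent) and
    the two shared paleo-duplications (young, old); track counts 3/3/6
    follow from applying the events oldest-first (x2, x2, x3).
    """

    n_ancestral_genes: int = 2000
    n_subject_chromosomes: int = 5
    n_query_chromosomes: int = 10
    epochs: dict[str, EpochSpec] = field(default_factory=lambda: {
        "recent": EpochSpec(depth=0.53, n_tracks=3, block_survival=0.55,
                            gene_retention=0.70, block_length=60),
        "young": EpochSpec(depth=1.17, n_tracks=3, block_survival=0.12,
                           gene_retention=0.50, block_length=40),
        "old": EpochSpec(depth=2.19, n_tracks=6, block_survival=0.02,
                         gene_retention=0.50, block_length=30),
    })
    min_pairs_per_segment: int = 5
    ks_dispersion: float = 0.15
    ks_floor: float = 0.01
    fast_fraction: float = 0.017
    fast_inflation: float = 3.0
    ka_ks_baseline: float = 0.20
    neo_kaks: float = 1.5
    cds_codons: int = 200
    emit_cds: bool = True
    spurious_anchor_rate: float = 0.0
    # expression
    tissue_labels: tuple[str, ...] = ("leaf", "root", "stem")
    n_pool_libraries: int = 2
    expr_mean: float = 100.0
    tissue_fold: float = 60.0  # planted specific-tissue fold (log-fold ~4.1)
    nb_size: float | None = None  # None = Poisson counts
    fate_mixture: dict[str, float] = field(default_factory=lambda: {
        "dead": 0.017, "nonfunctionalization": 0.08,
        "subfunctionalization": 0.343, "neofunctionalization": 0.002,
        "neutral": 0.558,
    })
    # GO
    go_n_terms: int = 60
    go_n_slims: int = 10
    go_terms_per_gene: float = 2.0
    go_background_freq: float = 0.05
    go_planted_fold: float = 5.0
    go_planted_set_size: int = 150
    rng_seed: int = 0

    def validate(self) -> None:
        if self.fast_inflation <= 1:
            raise ConfigError("fast_inflation must be > 1")
        depths = [self.epochs[e].depth for e in EPOCHS]
        if not all(a < b for a, b in zip(depths, depths[1:])):
            raise ConfigError("epoch depths must be strictly increasing recent<young<old")
        for e, spec in self.epochs.items():
            for p in (spec.block_survival, spec.gene_retention):
                if not 0 < p <= 1:
                    raise ConfigError(f"{e}: probabilities must be in (0,1]")
        if not math.isclose(sum(self.fate_mixture.values()), 1.0, abs_tol=1e-9):
            raise ConfigError("fate_mixture proportions must sum to 1")
        if not 0 <= self.fast_fraction <= 1:
            raise ConfigError("fast_fraction must be in [0,1]")
        if self.go_planted_fold * self.go_background_freq > 1:
            raise ConfigError("planted fold times background frequency exceeds 1")


@dataclass
class TrueSegment:
    """One surviving ancestral block on one lineage track."""

    epoch: str
    track: int
    subject_chromosome: str
    subject_rank_span: tuple[int, int]  # min/max retained subject rank
    members: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed by emitted gene ids."""

    segments: list[TrueSegment]
    pair_epoch: dict[tuple[str, str], str]
    pair_ks: dict[tuple[str, str], float]
    pair_ka: dict[tuple[str, str], float]
    fast_pairs: set[tuple[str, str]]
    retention_index: dict[str, int]
    presence: dict[str, tuple[bool, bool, bool]]
    fates: dict[str, dict]  # subject gene -> {fate, copies}
    planted_term: str
    planted_set: set[str]


@dataclass
class SimulatedDataset:
    """In-memory dataset plus ground truth; ``write`` emits all files."""

    config: SimulationConfig
    genes_query: list[GeneModel]
    genes_subject: list[GeneModel]
    anchors: list[AnchorPair]
    kaks: dict[tuple[str, str], tuple[float, float]]  # (ka, ks) per pair
    cds_query: dict[str, str]
    cds_subject: dict[str, str]
    expression: ExpressionTable
    annotation: GoAnnotation
    truth: GroundTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "query_gff3": outdir / "query.gff3",
            "subject_gff3": outdir / "subject.gff3",
            "anchors": outdir / "anchors.tsv",
            "kaks": outdir / "kaks.tsv",
            "expression": outdir / "expression.tsv",
            "go": outdir / "go.tsv",
            "go_slim": outdir / "go_slim.tsv",
            "blocks": outdir / "blocks.tsv",
            "truth_pairs": outdir / "truth_pairs.tsv",
            "truth_genes": outdir / "truth_genes.tsv",
            "truth_fates": outdir / "truth_fates.tsv",
            "manifest": outdir / "manifest.json",
        }
        write_gene_models(self.genes_query, paths["query_gff3"])
        write_gene_models(self.genes_subject, paths["subject_gff3"])
        write_anchor_pairs(self.anchors, paths["anchors"])
        write_kaks_table(self.kaks, paths["kaks"])
        write_expression(self.expression, paths["expression"])
        write_go(self.annotation, paths["go"], paths["go_slim"])
        self._write_blocks(paths["blocks"])
        if self.config.emit_cds:
            paths["query_cds"] = outdir / "query_cds.fasta"
            paths["subject_cds"] = outdir / "subject_cds.fasta"
            write_fasta(self.cds_query, paths["query_cds"])
            write_fasta(self.cds_subject, paths["subject_cds"])
        self._write_truth(paths)
        manifest = {"seed": self.config.rng_seed,
                    "config": _config_to_jsonable(self.config)}
        paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return paths

    def _write_blocks(self, path: Path) -> None:
        # partition each subject chromosome into 5 labelled locus intervals
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes_subject:
            by_chrom.setdefault(g.chromosome, []).append(g)
        labels = iter(string.ascii_uppercase)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("label\tak\tstart_locus\tend_locus\n")
            for ak, chrom in enumerate(sorted(by_chrom), 1):
                genes = sorted(by_chrom[chrom], key=lambda g: g.rank)
                for part in np.array_split(np.arange(len(genes)), 5):
                    if len(part) == 0:
                        continue
                    fh.write(f"{next(labels)}\t{ak}\t{genes[part[0]].gene_id}\t"
                             f"{genes[part[-1]].gene_id}\n")

    def _write_truth(self, paths: Mapping[str, Path]) -> None:
        t = self.truth
        with open(paths["truth_pairs"], "w", encoding="utf-8") as fh:
            fh.write("query_gene\tsubject_gene\tepoch\tks\tka\tfast\n")
            for (q, s), epoch in sorted(t.pair_epoch.items()):
                fh.write(f"{q}\t{s}\t{epoch}\t{t.pair_ks[(q, s)]:.6f}\t"
                         f"{t.pair_ka[(q, s)]:.6f}\t{int((q, s) in t.fast_pairs)}\n")
        with open(paths["truth_genes"], "w", encoding="utf-8") as fh:
            fh.write("subject_gene\tpattern\tindex\n")
            for s in sorted(t.retention_index):
                pattern = "".join("O" if p else "X" for p in t.presence[s])
                fh.write(f"{s}\t{pattern}\t{t.retention_index[s]}\n")
        with open(paths["truth_fates"], "w", encoding="utf-8") as fh:
            fh.write("subject_gene\tfate\tcopies\n")
            for s in sorted(t.fates):
                rec = t.fates[s]
                fh.write(f"{s}\t{rec['fate']}\t{','.join(rec['copies'])}\n")


def _config_to_jsonable(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["epochs"] = {e: asdict(spec) for e, spec in config.epochs.items()}
    return d


# ---------------------------------------------------------------------------
# codon-sequence evolution

def _random_cds(length_codons: int, rng: np.random.Generator) -> str:
    idx = rng.integers(0, len(_SENSE_CODONS), size=length_codons)
    return "".join(_SENSE_CODONS[i] for i in idx)


def mutate_cds(cds: str, n_syn: int, n_nonsyn: int, rng: np.random.Generator) -> str:
    """Apply point substitutions of the requested classes, avoiding stops.

    Candidate changes are rejection-sampled uniformly over (codon,
    position, alternative nucleotide); a proposal creating a stop codon or
    of the wrong class is resampled.  Repeated hits at one site occur
    naturally, as in a real substitution process.
    """
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    n = len(codons)
    for want_syn, count in ((True, n_syn), (False, n_nonsyn)):
        applied = 0
        while applied < count:
            ci = int(rng.integers(n))
            pos = int(rng.integers(3))
            nuc = "ACGT"[int(rng.integers(4))]
            codon = codons[ci]
            if nuc == codon[pos]:
                continue
            alt = codon[:pos] + nuc + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            if (_translate_codon(alt) == _translate_codon(codon)) != want_syn:
                continue
            codons[ci] = alt
            applied += 1
    return "".join(codons)


def evolve_codon_pair(
    length_codons: int,
    target_ks: float,
    target_ka: float,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """A random ancestral CDS and a derived copy at the target divergence.

    The numbers of synonymous and nonsynonymous substitution events are
    Poisson with means target_ks x S and target_ka x N, where S and N are
    the ancestral sequence's synonymous/nonsynonymous site counts, so the
    counted-and-corrected estimates recover the targets in expectation.
    """
    if length_codons < 30:
        raise ConfigError("length_codons must be >= 30")
    if target_ks < 0 or target_ka < 0:
        raise ConfigError("divergence targets must be >= 0")
    ancestral = _random_cds(length_codons, rng)
    s_sites = sum(_syn_fraction(ancestral[i : i + 3]) for i in range(0, len(ancestral), 3))
    n_sites = 3 * length_codons - s_sites
    mean_events = target_ks * s_sites + target_ka * n_sites
    if 0 < mean_events < 1:
        warnings.warn(
            f"expected substitutions {mean_events:.2f} < 1 for length "
            f"{length_codons}; targets are barely resolvable",
            stacklevel=2,
        )
    n_syn = int(rng.poisson(target_ks * s_sites))
    n_nonsyn = int(rng.poisson(target_ka * n_sites))
    derived = mutate_cds(ancestral, n_syn, n_nonsyn, rng)
    return ancestral, derived


# ---------------------------------------------------------------------------
# the generator

def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Generate a full synthetic dataset with ground truth."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    genes_subject, subject_chrom_of = _make_subject_genome(config)
    subject_ids = [g.gene_id for g in genes_subject]

    segments = _sample_segments(config, rng, genes_subject)
    segments = _layout_order(config, rng, segments)
    genes_query, pair_list = _assign_query_ids(config, segments, subject_ids)

    pair_epoch: dict[tuple[str, str], str] = {}
    for seg in segments:
        for pair in seg.members:
            pair_epoch[pair] = seg.epoch

    pair_ks, pair_ka, fast_pairs = _sample_divergence(config, rng, segments)

    presence, retention_index = _true_retention(subject_ids, segments)
    fates, pair_ka = _plant_fates(config, rng, segments, pair_ka, pair_ks)
    expression = _simulate_expression(config, rng, genes_query, fates)
    annotation, planted_term, planted_set = _simulate_go(config, rng, genes_query)

    anchors = _make_anchors(config, rng, pair_list, genes_query, genes_subject)

    cds_subject: dict[str, str] = {}
    cds_query: dict[str, str] = {}
    if config.emit_cds:
        cds_subject, cds_query = _simulate_cds(config, rng, genes_subject, pair_list,
                                               pair_ks, pair_ka)

    truth = GroundTruth(
        segments=segments,
        pair_epoch=pair_epoch,
        pair_ks=pair_ks,
        pair_ka=pair_ka,
        fast_pairs=fast_pairs,
        retention_index=retention_index,
        presence=presence,
        fates=fates,
        planted_term=planted_term,
        planted_set=planted_set,
    )
    kaks = {p: (pair_ka[p], pair_ks[p]) for p in pair_ks}
    return SimulatedDataset(
        config=config,
        genes_query=genes_query,
        genes_subject=genes_subject,
        anchors=anchors,
        kaks=kaks,
        cds_query=cds_query,
        cds_subject=cds_subject,
        expression=expression,
        annotation=annotation,
        truth=truth,
    )


_GENE_SPACING = 2000
_GENE_LENGTH = 1200


def _make_subject_genome(config: SimulationConfig):
    genes: list[GeneModel] = []
    chrom_of: dict[str, str] = {}
    parts = np.array_split(np.arange(config.n_ancestral_genes), config.n_subject_chromosomes)
    for ci, part in enumerate(parts, 1):
        chrom = f"At{ci}"
        for rank, _ in enumerate(part):
            gene_id = f"At{ci}g{(rank + 1) * 10:05d}"
            start = rank * _GENE_SPACING
            genes.append(GeneModel(gene_id, chrom, start, start + _GENE_LENGTH,
                                   "+", rank, "subject"))
            chrom_of[gene_id] = chrom
    return genes, chrom_of


def _sample_segments(config: SimulationConfig, rng: np.random.Generator,
                     genes_subject: list[GeneModel]) -> list[TrueSegment]:
    by_chrom: dict[str, list[str]] = {}
    for g in sorted(genes_subject, key=lambda g: (g.chromosome, g.rank)):
        by_chrom.setdefault(g.chromosome, []).append(g.gene_id)
    segments: list[TrueSegment] = []
    for epoch in EPOCHS:
        spec = config.epochs[epoch]
        for track in range(spec.n_tracks):
            for chrom in sorted(by_chrom):
                ids = by_chrom[chrom]
                n_blocks = max(1, round(len(ids) / spec.block_length))
                for part in np.array_split(np.arange(len(ids)), n_blocks):
                    if rng.random() >= spec.block_survival:
                        continue
                    keep = part[rng.random(len(part)) < spec.gene_retention]
                    if len(keep) < config.min_pairs_per_segment:
                        continue
                    segments.append(
                        TrueSegment(
                            epoch=epoch,
                            track=track,
                            subject_chromosome=chrom,
                            subject_rank_span=(int(keep.min()), int(keep.max())),
                            members=[(None, ids[i]) for i in keep],  # query ids later
                        )
                    )
    return segments


def _layout_order(config: SimulationConfig, rng: np.random.Generator,
                  segments: list[TrueSegment]) -> list[TrueSegment]:
    """Shuffle segments, avoiding adjacencies a chainer could merge.

    Two neighbouring segments drawn from the same or consecutive ancestral
    blocks of the same subject chromosome could continue each other's
    collinearity; such neighbours are separated by swapping.
    """
    order = list(rng.permutation(len(segments)))
    margin = 25  # comfortably above typical chaining gap limits

    def conflict(a: TrueSegment, b: TrueSegment) -> bool:
        # directed: could members of b continue a collinear chain begun in a?
        if a.subject_chromosome != b.subject_chromosome:
            return False
        (alo, ahi), (blo, bhi) = a.subject_rank_span, b.subject_rank_span
        return bhi > alo and blo <= ahi + margin + 1

    for _ in range(10):  # a couple of passes always suffice in practice
        clean = True
        for i in range(len(order) - 1):
            if not conflict(segments[order[i]], segments[order[i + 1]]):
                continue
            for j in range(len(order)):
                if j in (i, i + 1):
                    continue
                ok_here = not conflict(segments[order[i]], segments[order[j]]) and (
                    i + 2 >= len(order)
                    or not conflict(segments[order[j]], segments[order[i + 2]])
                )
                prev_ok = j == 0 or j - 1 == i + 1 or not conflict(
                    segments[order[j - 1]], segments[order[i + 1]]
                )
                next_ok = j + 1 >= len(order) or j + 1 == i + 1 or not conflict(
                    segments[order[i + 1]], segments[order[j + 1]]
                )
                if ok_here and prev_ok and next_ok:
                    order[i + 1], order[j] = order[j], order[i + 1]
                    clean = False
                    break
        if clean:
            break
    return [segments[i] for i in order]


def _assign_query_ids(config: SimulationConfig, segments: list[TrueSegment],
                      subject_ids: list[str]):
    genes_query: list[GeneModel] = []
    pair_list: list[tuple[str, str]] = []
    chrom_parts = np.array_split(np.arange(len(segments)), config.n_query_chromosomes)
    counter = 1
    for ci, part in enumerate(chrom_parts, 1):
        chrom = f"A{ci:02d}"
        rank = 0
        for si in part:
            seg = segments[si]
            new_members = []
            for _, s in seg.members:
                gene_id = f"Bra{counter:06d}"
                counter += 1
                start = rank * _GENE_SPACING
                genes_query.append(GeneModel(gene_id, chrom, start, start + _GENE_LENGTH,
                                             "+", rank, "query"))
                rank += 1
                new_members.append((gene_id, s))
                pair_list.append((gene_id, s))
            seg.members = new_members
    return genes_query, pair_list


def _sample_divergence(config: SimulationConfig, rng: np.random.Generator,
                       segments: list[TrueSegment]):
    pair_ks: dict[tuple[str, str], float] = {}
    pair_ka: dict[tuple[str, str], float] = {}
    fast_pairs: set[tuple[str, str]] = set()
    for seg in segments:
        depth = config.epochs[seg.epoch].depth
        for pair in seg.members:
            ks = max(config.ks_floor, float(rng.normal(depth, config.ks_dispersion)))
            # fast-evolving genes were only ever seen in recent/young segments
            if seg.epoch in ("recent", "young") and rng.random() < config.fast_fraction:
                ks *= config.fast_inflation
                fast_pairs.add(pair)
            pair_ks[pair] = ks
            pair_ka[pair] = config.ka_ks_baseline * ks
    return pair_ks, pair_ka, fast_pairs


def _true_retention(subject_ids: list[str], segments: list[TrueSegment]):
    copies: dict[str, dict[str, list[str]]] = {}
    for seg in segments:
        for q, s in seg.members:
            copies.setdefault(s, {e: [] for e in EPOCHS})[seg.epoch].append(q)
    presence: dict[str, tuple[bool, bool, bool]] = {}
    index: dict[str, int] = {}
    pattern_map = {
        (True, False, False): 1, (True, True, False): 2, (True, False, True): 3,
        (True, True, True): 4, (False, False, False): 5, (False, True, False): 6,
        (False, False, True): 7, (False, True, True): 8,
    }
    for s in subject_ids:
        per = copies.get(s, {e: [] for e in EPOCHS})
        pres = tuple(bool(per[e]) for e in EPOCHS)
        presence[s] = pres  # type: ignore[assignment]
        index[s] = pattern_map[pres]  # type: ignore[index]
    return presence, index


def _plant_fates(config: SimulationConfig, rng: np.random.Generator,
                 segments: list[TrueSegment],
                 pair_ka: dict, pair_ks: dict):
    """Choose a fate per recent homoeologue group; neo copies get Ka/Ks>1."""
    groups: dict[str, list[str]] = {}
    for seg in segments:
        if seg.epoch != "recent":
            continue
        for q, s in seg.members:
            groups.setdefault(s, []).append(q)
    fate_names = list(config.fate_mixture)
    fate_probs = np.array([config.fate_mixture[f] for f in fate_names])
    fates: dict[str, dict] = {}
    for s in sorted(groups):
        copies = sorted(groups[s])
        if len(copies) < 2:
            fates[s] = {"fate": "single", "copies": copies}
            continue
        fate = fate_names[int(rng.choice(len(fate_names), p=fate_probs))]
        if fate == "neofunctionalization":
            # positive selection on one expressed copy
            neo_copy = copies[int(rng.integers(len(copies)))]
            pair = (neo_copy, s)
            pair_ka[pair] = config.neo_kaks * pair_ks[pair]
        fates[s] = {"fate": fate, "copies": copies}
    return fates, pair_ka


def _simulate_expression(config: SimulationConfig, rng: np.random.Generator,
                         genes_query: list[GeneModel],
                         fates: dict[str, dict]) -> ExpressionTable:
    tissues = list(config.tissue_labels)
    libraries = tissues + [f"pool{i + 1}" for i in range(config.n_pool_libraries)]
    tissue_of = {t: t for t in tissues}
    tissue_of.update({f"pool{i + 1}": "pool" for i in range(config.n_pool_libraries)})

    # per-gene mean expression per tissue; default: uniformly expressed
    base = config.expr_mean
    low = base / config.tissue_fold
    mu: dict[str, dict[str, float]] = {
        g.gene_id: {t: base for t in tissues} for g in genes_query
    }
    for s, rec in fates.items():
        copies = rec["copies"]
        fate = rec["fate"]
        if fate == "dead":
            for c in copies:
                mu[c] = {t: 0.0 for t in tissues}
        elif fate == "nonfunctionalization":
            keep = copies[0]  # deterministic: first copy stays expressed
            for c in copies:
                if c != keep:
                    mu[c] = {t: 0.0 for t in tissues}
        elif fate == "subfunctionalization":
            for i, c in enumerate(copies):
                own = tissues[i % len(tissues)]
                mu[c] = {t: (base if t == own else low) for t in tissues}
        # neutral / neofunctionalization / single: uniformly expressed

    rows = []
    gene_ids = [g.gene_id for g in genes_query]
    for gid in gene_ids:
        means = [mu[gid][t] for t in tissues]
        pool_mean = float(np.mean(means))
        lib_means = means + [pool_mean] * config.n_pool_libraries
        counts = [_draw_count(m, config.nb_size, rng) for m in lib_means]
        rows.append(counts)
    matrix = pd.DataFrame(rows, index=pd.Index(gene_ids, name="gene"),
                          columns=libraries, dtype=float)
    return ExpressionTable(matrix, tissue_of)


def _draw_count(mean: float, nb_size: float | None, rng: np.random.Generator) -> int:
    if mean <= 0:
        return 0
    if nb_size is None:
        return int(rng.poisson(mean))
    p = nb_size / (nb_size + mean)
    return int(rng.negative_binomial(nb_size, p))


def _simulate_go(config: SimulationConfig, rng: np.random.Generator,
                 genes_query: list[GeneModel]):
    terms = [f"GO:{i + 1:07d}" for i in range(config.go_n_terms)]
    planted_term = terms[0]
    other_terms = terms[1:]
    gene_ids = [g.gene_id for g in genes_query]
    planted_size = min(config.go_planted_set_size, len(gene_ids))
    planted_set = set(rng.choice(gene_ids, size=planted_size, replace=False).tolist())

    ann = GoAnnotation()
    q_bg = config.go_background_freq
    q_in = min(1.0, config.go_planted_fold * q_bg)
    for gid in gene_ids:
        k = int(rng.poisson(config.go_terms_per_gene))
        chosen = set(rng.choice(len(other_terms), size=min(k, len(other_terms)),
                                replace=False).tolist())
        ts = {other_terms[i] for i in chosen}
        p_term = q_in if gid in planted_set else q_bg
        if rng.random() < p_term:
            ts.add(planted_term)
        if ts:
            ann.gene_terms[gid] = ts
    slims = [f"SLIM:{i + 1:04d}" for i in range(config.go_n_slims)]
    for i, term in enumerate(terms):
        slim = slims[i % config.go_n_slims]
        ns = "BP" if i % config.go_n_slims < 6 else ("MF" if i % config.go_n_slims < 9 else "CC")
        ann.slim_map[term] = slim
        ann.namespaces[term] = ns
        ann.namespaces[slim] = ns
    return ann, planted_term, planted_set


def _make_anchors(config: SimulationConfig, rng: np.random.Generator,
                  pair_list: list[tuple[str, str]],
                  genes_query: list[GeneModel],
                  genes_subject: list[GeneModel]) -> list[AnchorPair]:
    anchors = []
    for q, s in pair_list:
        evalue = 10.0 ** float(rng.uniform(-180, -20))
        score = float(rng.uniform(100, 500))
        anchors.append(AnchorPair(q, s, evalue, score))
    n_spurious = int(round(config.spurious_anchor_rate * len(pair_list)))
    if n_spurious:
        true = set(pair_list)
        qids = [g.gene_id for g in genes_query]
        sids = [g.gene_id for g in genes_subject]
        added = 0
        while added < n_spurious:
            q = qids[int(rng.integers(len(qids)))]
            s = sids[int(rng.integers(len(sids)))]
            if (q, s) in true:
                continue
            true.add((q, s))
            anchors.append(AnchorPair(q, s, 10.0 ** float(rng.uniform(-20, -6)),
                                      float(rng.uniform(50, 120))))
            added += 1
    return anchors


def _simulate_cds(config: SimulationConfig, rng: np.random.Generator,
                  genes_subject: list[GeneModel],
                  pair_list: list[tuple[str, str]],
                  pair_ks: dict, pair_ka: dict):
    """Subject CDS are the ancestral sequences; each query copy is mutated
    from its subject's CDS at the pair's planted divergence."""
    cds_subject = {g.gene_id: _random_cds(config.cds_codons, rng)
                   for g in sorted(genes_subject, key=lambda g: g.gene_id)}
    cds_query: dict[str, str] = {}
    s_sites_cache: dict[str, tuple[float, float]] = {}
    for q, s in pair_list:
        anc = cds_subject[s]
        if s not in s_sites_cache:
            ssites = sum(_syn_fraction(anc[i:i + 3]) for i in range(0, len(anc), 3))
            s_sites_cache[s] = (ssites, 3 * config.cds_codons - ssites)
        ssites, nsites = s_sites_cache[s]
        n_syn = int(rng.poisson(pair_ks[(q, s)] * ssites))
        n_nonsyn = int(rng.poisson(pair_ka[(q, s)] * nsites))
        cds_query[q] = mutate_cds(anc, n_syn, n_nonsyn, rng)
    return cds_subject, cds_query
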