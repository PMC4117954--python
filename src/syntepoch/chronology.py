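"""Date syntenic segments into chronological epochs from their mean Ks.

Whole-genome duplications leave waves in the distribution of segment-mean
synonymous divergence; with three events (two paleo-WGDs and the Brassica
triplication) the distribution has three modes, ordered oldest = deepest.
Segments are classified into the recent/young/old epochs either by a
weighted Gaussian mixture fit (cutpoints at posterior-equality crossings)
or by user-supplied fixed cutpoints, and can additionally be assigned to
ancestral genomic blocks defined as intervals of subject-genome loci.
"""

from __future__ import annotations

import bisect
import math
import re
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import GeneModel
from .synteny import SyntenicSegment

__all__ = [
    "EpochModel",
    "GenomicBlockDef",
    "EPOCH_LABELS",
    "fit_epochs",
    "classify_epoch",
    "assign_epochs",
    "assign_blocks",
    "epoch_report",
    "block_report",
    "load_default_blocks",
    "read_blocks",
    "agi_sort_key",
]

#: Epoch labels in age order (youngest first) for the default k=3.
EPOCH_LABELS = ("recent", "young", "old")

#: Fixed cutpoints midway between the three canonical wave means.
DEFAULT_FIXED_CUTPOINTS = (0.85, 1.75)


@dataclass
class EpochModel:
    """A k-wave model of the segment-mean Ks distribution."""

    k: int
    means: tuple[float, ...]
    sds: tuple[float, ...]
    weights: tuple[float, ...]
    cutpoints: tuple[float, ...]
    method: str  # "mixture" | "fixed"
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = EPOCH_LABELS if self.k == 3 else tuple(
                f"epoch{i + 1}" for i in range(self.k)
            )
        if list(self.cutpoints) != sorted(self.cutpoints):
            raise ValidationError("cutpoints must be strictly increasing")


@dataclass(frozen=True)
class GenomicBlockDef:
    """One ancestral genomic block as a subject-locus interval."""

    label: str
    ak: int
    start_locus: str
    end_locus: str


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    target = q * cw[-1]
    i = int(np.searchsorted(cw, target))
    return float(v[min(i, len(v) - 1)])


def _quantile_cutpoints(values: np.ndarray, weights: np.ndarray, k: int) -> tuple[float, ...]:
    return tuple(_weighted_quantile(values, weights, (i + 1) / k) for i in range(k - 1))


def _kmeans1d_init(x: np.ndarray, w: np.ndarray, k: int):
    """Exact weighted 1-D k-means by dynamic programming (Fisher partition).

    Returns initial (means, sds, weights) for EM from the optimal
    contiguous partition of the sorted values into k groups.
    """
    order = np.argsort(x)
    v, wt = x[order], w[order]
    n = len(v)
    cw = np.concatenate([[0.0], np.cumsum(wt)])
    cwx = np.concatenate([[0.0], np.cumsum(wt * v)])
    cwx2 = np.concatenate([[0.0], np.cumsum(wt * v * v)])

    def sse(i: int, j: int) -> float:  # weighted SSE of v[i:j]
        sw = cw[j] - cw[i]
        sx = cwx[j] - cwx[i]
        sx2 = cwx2[j] - cwx2[i]
        return max(sx2 - sx * sx / sw, 0.0) if sw > 0 else 0.0

    cost = np.full((k + 1, n + 1), np.inf)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for m in range(1, k + 1):
        for j in range(m, n + 1):
            for i in range(m - 1, j):
                c = cost[m - 1, i] + sse(i, j)
                if c < cost[m, j]:
                    cost[m, j] = c
                    back[m, j] = i
    bounds = [n]
    j = n
    for m in range(k, 0, -1):
        j = back[m, j]
        bounds.append(j)
    bounds.reverse()
    means, sds, pis = [], [], []
    total_w = cw[-1]
    for m in range(k):
        i, j = bounds[m], bounds[m + 1]
        sw = cw[j] - cw[i]
        mean = (cwx[j] - cwx[i]) / sw
        var = sse(i, j) / sw
        means.append(mean)
        sds.append(max(math.sqrt(var), 1e-3))
        pis.append(sw / total_w)
    return np.array(means), np.array(sds), np.array(pis)


def _norm_logpdf(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return -0.5 * math.log(2 * math.pi) - math.log(sd) - 0.5 * ((x - mean) / sd) ** 2


def fit_epochs(
    mean_ks_values: Sequence[float],
    k: int = 3,
    method: str = "mixture",
    weights: Sequence[float] | None = None,
    cutpoints: Sequence[float] | None = None,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> EpochModel:
    """Fit a k-wave epoch model to segment-mean Ks values.

    ``weights`` (typically each segment's pair count) weight the EM fit;
    components are initialized at the k quantile midpoints, making the fit
    deterministic.  ``method="fixed"`` skips fitting and uses the supplied
    ``cutpoints`` (default 0.85, 1.75) verbatim.  A degenerate EM fit
    (vanishing component weight) falls back to quantile cutpoints with a
    warning.
    """
    x = np.asarray(mean_ks_values, dtype=float)
    if method == "fixed":
        cuts = tuple(cutpoints) if cutpoints is not None else DEFAULT_FIXED_CUTPOINTS
        if len(cuts) != k - 1:
            raise ValidationError(f"need {k - 1} cutpoints for k={k}")
        return EpochModel(k=k, means=(), sds=(), weights=(), cutpoints=cuts, method="fixed")
    if method != "mixture":
        raise ValidationError(f"unknown epoch method {method!r}")
    if len(np.unique(x)) < k:
        raise ValidationError(f"need at least {k} distinct Ks values to fit {k} waves")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != x.shape or (w <= 0).any():
        raise ValidationError("weights must be positive, one per value")

    # initialize from the exact 1-D weighted k-means partition: deterministic
    # and robust when one wave carries most of the weight
    means, sds, pis = _kmeans1d_init(x, w, k)

    prev_ll = -math.inf
    degenerate = False
    for _ in range(max_iter):
        log_resp = np.stack(
            [math.log(pis[j]) + _norm_logpdf(x, means[j], sds[j]) for j in range(k)]
        )
        log_norm = np.logaddexp.reduce(log_resp, axis=0)
        resp = np.exp(log_resp - log_norm)
        ll = float(np.sum(w * log_norm))
        rw = resp * w  # k x n
        comp_w = rw.sum(axis=1)
        if (comp_w / comp_w.sum() < 1e-6).any():
            degenerate = True
            break
        means = (rw @ x) / comp_w
        var = np.array([(rw[j] @ (x - means[j]) ** 2) / comp_w[j] for j in range(k)])
        sds = np.sqrt(np.maximum(var, 1e-10))
        pis = comp_w / comp_w.sum()
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll

    if degenerate or (np.diff(np.sort(means)) < 1e-9).any():
        warnings.warn(
            "degenerate mixture fit; falling back to quantile cutpoints",
            RuntimeWarning,
            stacklevel=2,
        )
        cuts = _quantile_cutpoints(x, w, k)
        return EpochModel(k=k, means=(), sds=(), weights=(), cutpoints=cuts, method="mixture")

    order = np.argsort(means)
    means, sds, pis = means[order], sds[order], pis[order]
    cuts = tuple(
        _posterior_crossing(means[j], sds[j], pis[j], means[j + 1], sds[j + 1], pis[j + 1])
        for j in range(k - 1)
    )
    if list(cuts) != sorted(set(cuts)):
        warnings.warn(
            "non-increasing posterior crossings; falling back to quantile cutpoints",
            RuntimeWarning,
            stacklevel=2,
        )
        cuts = _quantile_cutpoints(x, w, k)
    return EpochModel(
        k=k,
        means=tuple(float(m) for m in means),
        sds=tuple(float(s) for s in sds),
        weights=tuple(float(p) for p in pis),
        cutpoints=cuts,
        method="mixture",
    )


def _posterior_crossing(m1, s1, p1, m2, s2, p2) -> float:
    """Ks value where two adjacent weighted components are equally likely."""
    from scipy.optimize import brentq

    def diff(x):
        return (math.log(p1) + float(_norm_logpdf(np.array(x), m1, s1))) - (
            math.log(p2) + float(_norm_logpdf(np.array(x), m2, s2))
        )

    lo, hi = float(m1), float(m2)
    try:
        if diff(lo) > 0 and diff(hi) < 0:
            return float(brentq(diff, lo, hi))
    except ValueError:
        pass
    return (lo + hi) / 2.0  # no crossing between the means


def classify_epoch(mean_ks: float | SyntenicSegment, model: EpochModel) -> str:
    """Epoch label for a segment (or raw mean Ks) under the model.

    A value exactly at a cutpoint takes the younger label.
    """
    if isinstance(mean_ks, SyntenicSegment):
        if mean_ks.mean_ks is None:
            raise ValidationError(f"segment {mean_ks.segment_id} has no mean Ks")
        value = mean_ks.mean_ks
    else:
        value = float(mean_ks)
    idx = bisect.bisect_left(list(model.cutpoints), value)
    return model.labels[idx]


def assign_epochs(segments: Iterable[SyntenicSegment], model: EpochModel) -> None:
    """Label every segment's epoch in place."""
    for seg in segments:
        seg.epoch = classify_epoch(seg, model)


# ---------------------------------------------------------------------------
# genomic blocks

_AGI_RE = re.compile(r"^At(\d+)g(\d+)$", re.IGNORECASE)


def agi_sort_key(locus: str) -> tuple[int, int]:
    """(chromosome, numeric code) ordering key for AGI-style locus ids."""
    m = _AGI_RE.match(locus)
    if not m:
        raise ValidationError(f"not an AGI-style locus id: {locus!r}")
    return (int(m.group(1)), int(m.group(2)))


def read_blocks(tsv_path: str | Path) -> list[GenomicBlockDef]:
    df = pd.read_csv(tsv_path, sep="\t", comment="#", dtype=str)
    for col in ("label", "ak", "start_locus", "end_locus"):
        if col not in df.columns:
            raise ValidationError(f"{tsv_path}: blocks file missing column {col!r}")
    defs = [
        GenomicBlockDef(row.label, int(row.ak), row.start_locus, row.end_locus)
        for row in df.itertuples(index=False)
    ]
    if len({d.label for d in defs}) != len(defs):
        raise ValidationError("duplicate block labels")
    return defs


def load_default_blocks() -> list[GenomicBlockDef]:
    """The 24 refined Brassicaceae blocks (A-X) on the A. thaliana genome."""
    ref = resources.files("syntepoch.data").joinpath("genomic_blocks_athaliana.tsv")
    with resources.as_file(ref) as path:
        return read_blocks(path)


@dataclass
class BlockSlice:
    """A run of a segment's subject anchors falling in one block."""

    segment_id: str
    block: str | None  # None = unassigned
    members: list[tuple[str, str]]


def _block_intervals(block_defs: Sequence[GenomicBlockDef]):
    ivals = []
    for b in block_defs:
        k1, k2 = agi_sort_key(b.start_locus), agi_sort_key(b.end_locus)
        lo, hi = (k1, k2) if k1 <= k2 else (k2, k1)
        ivals.append((lo, hi, b.label))
    return ivals


def assign_blocks(
    segments: Iterable[SyntenicSegment],
    block_defs: Sequence[GenomicBlockDef],
) -> dict[str, list[BlockSlice]]:
    """Assign each segment to ancestral blocks by its subject anchors.

    Each segment's ``block`` attribute is set to the label holding the
    majority of its subject anchors (ties broken alphabetically); the
    returned mapping additionally splits segments spanning several blocks
    into per-block member runs for reporting.  Anchors outside every block
    are assigned ``None``.
    """
    ivals = _block_intervals(block_defs)

    def locate(subject_gene: str) -> str | None:
        try:
            key = agi_sort_key(subject_gene)
        except ValidationError:
            return None
        for lo, hi, label in ivals:
            if lo <= key <= hi:
                return label
        return None

    out: dict[str, list[BlockSlice]] = {}
    for seg in segments:
        slices: list[BlockSlice] = []
        counts: dict[str | None, int] = {}
        for q, s in seg.members:
            label = locate(s)
            counts[label] = counts.get(label, 0) + 1
            if slices and slices[-1].block == label:
                slices[-1].members.append((q, s))
            else:
                slices.append(BlockSlice(seg.segment_id, label, [(q, s)]))
        out[seg.segment_id] = slices
        assigned = {lbl: n for lbl, n in counts.items() if lbl is not None}
        if assigned:
            best = max(sorted(assigned), key=lambda lbl: assigned[lbl])
            seg.block = best
        else:
            seg.block = None
    return out


# ---------------------------------------------------------------------------
# reports

def epoch_report(
    segments: Sequence[SyntenicSegment],
    subject_genome_size: int | None = None,
    query_genome_size: int | None = None,
    labels: Sequence[str] = EPOCH_LABELS,
) -> pd.DataFrame:
    """Per-epoch genome statistics.

    ``subject_genome_size`` is the number of subject genes (for the
    fraction-in-synteny column); ``query_genome_size`` is the query genome
    length in bp (for the span fraction).  Rows for epochs with no
    segments are all zero.
    """
    rows = []
    for label in labels:
        segs = [s for s in segments if s.epoch == label]
        n_pairs = sum(s.n_pairs for s in segs)
        subj_genes = {m[1] for s in segs for m in s.members}
        span = sum(s.query_span_bp for s in segs)
        avg_ks = (
            sum(s.mean_ks * s.n_pairs for s in segs if s.mean_ks is not None) / n_pairs
            if n_pairs
            else 0.0
        )
        rows.append(
            {
                "epoch": label,
                "avg_ks": avg_ks,
                "n_segments": len(segs),
                "n_pairs": n_pairs,
                "n_subject_genes": len(subj_genes),
                "subject_gene_fraction": (
                    len(subj_genes) / subject_genome_size if subject_genome_size else float("nan")
                ),
                "query_span_bp": span,
                "query_span_fraction": (
                    span / query_genome_size if query_genome_size else float("nan")
                ),
                "pairs_per_mb": (n_pairs / (span / 1e6)) if span else 0.0,
            }
        )
    return pd.DataFrame(rows)


def block_report(
    segments: Sequence[SyntenicSegment],
    slices: Mapping[str, list[BlockSlice]],
    subject_genes: Sequence[GeneModel] | None = None,
    labels: Sequence[str] = EPOCH_LABELS,
) -> pd.DataFrame:
    """Per-epoch, per-block statistics from split block slices.

    Counts block instances (slices), summed query span (whole-segment span
    attributed to its majority block), and distinct subject genes covered.
    Anchors outside every block are reported under the label ``unassigned``.
    """
    n_subject = len(subject_genes) if subject_genes is not None else None
    rows: dict[tuple[str, str], dict] = {}
    for seg in segments:
        if seg.epoch is None:
            continue
        for sl in slices.get(seg.segment_id, []):
            label = sl.block if sl.block is not None else "unassigned"
            key = (seg.epoch, label)
            rec = rows.setdefault(
                key,
                {"epoch": seg.epoch, "block": label, "n_instances": 0,
                 "n_pairs": 0, "subject_genes": set()},
            )
            rec["n_instances"] += 1
            rec["n_pairs"] += len(sl.members)
            rec["subject_genes"].update(m[1] for m in sl.members)
    out = []
    for (epoch, label) in sorted(rows, key=lambda k: (labels.index(k[0]) if k[0] in labels else 99, k[1])):
        rec = rows[(epoch, label)]
        n_genes = len(rec["subject_genes"])
        out.append(
            {
                "epoch": epoch,
                "block": label,
                "n_instances": rec["n_instances"],
                "n_pairs": rec["n_pairs"],
                "n_subject_genes": n_genes,
                "subject_gene_fraction": (n_genes / n_subject) if n_subject else float("nan"),
            }
        )
    return pd.DataFrame(out, columns=["epoch", "block", "n_instances", "n_pairs",
                                      "n_subject_genes", "subject_gene_fraction"])
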