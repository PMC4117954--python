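"""Evolutionary fate of homoeologue groups from expression and Ka/Ks.

Expression evidence is digital: RPKM values are converted back to read
counts at a nominal library depth, a gene with zero RPKM everywhere is a
pseudo-gene, and tissue specificity comes from the Audic–Claverie exact
test of a tissue's count against the pooled count of the remaining
libraries.  Fates are then called per homoeologue group:

    dead                 no copy expressed anywhere
    nonfunctionalization exactly one expressed copy
    neofunctionalization >=2 expressed and an expressed copy with Ka/Ks > 1
    subfunctionalization >=2 expressed copies with differing tissue sets
    unclassified         everything else (co-expressed, no positive selection)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import nbinom

from .errors import ValidationError
from .io_formats import ExpressionTable
from .retention import HomoeologGroup

__all__ = [
    "audic_test",
    "tissue_specificity",
    "FateCall",
    "call_fate",
    "fate_report",
    "rpkm_to_counts",
]

FATES = ("dead", "nonfunctionalization", "subfunctionalization",
         "neofunctionalization", "unclassified")


def _audic_directional(x: int, y: int, n1: float, n2: float) -> float:
    # conditioning on x as the reference count: tails of P(.|x)
    prob = n1 / (n1 + n2)
    lower = float(nbinom.cdf(y, x + 1, prob))
    upper = float(nbinom.sf(y - 1, x + 1, prob))
    return min(lower, upper)


def audic_test(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided Audic–Claverie p-value for digital counts x vs y.

    Conditioning on ``x``, the count in the second library follows
    P(y|x) = (n2/n1)^y (x+y)! / (x! y! (1+n2/n1)^(x+y+1)), i.e. a
    negative binomial with x+1 successes and success probability
    n1/(n1+n2); the two-sided p doubles the smaller tail, capped at 1.
    The conditioning is not symmetric in the two libraries, so both
    directions are evaluated and the smaller p is reported, which makes
    audic_test(x, y, n1, n2) == audic_test(y, x, n2, n1) exactly.
    """
    if x < 0 or y < 0:
        raise ValidationError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValidationError("library sizes must be positive")
    x, y = int(x), int(y)
    tail = min(_audic_directional(x, y, n1, n2), _audic_directional(y, x, n2, n1))
    return min(1.0, 2.0 * tail)


def rpkm_to_counts(rpkm: pd.Series | float, depth: float = 1e6) -> pd.Series | int:
    """Expected read counts from RPKM at a nominal library depth.

    With unit gene length (1 kb) and ``depth`` mapped reads, the count is
    simply ``rpkm * depth / 1e6`` rounded; zero RPKM maps to exactly zero.
    """
    if isinstance(rpkm, pd.Series):
        return (rpkm * depth / 1e6).round().astype(int)
    return int(round(rpkm * depth / 1e6))


def _tissue_counts(table: ExpressionTable, gene: str, depth: float) -> dict[str, int]:
    row = table.row(gene)
    counts: dict[str, int] = {}
    for lib in table.libraries:
        tissue = table.tissues[lib]
        counts[tissue] = counts.get(tissue, 0) + rpkm_to_counts(float(row[lib]), depth)
    return counts


def _tissue_depths(table: ExpressionTable, depth: float) -> dict[str, float]:
    depths: dict[str, float] = {}
    for lib in table.libraries:
        tissue = table.tissues[lib]
        depths[tissue] = depths.get(tissue, 0.0) + depth
    return depths


def tissue_specificity(
    gene: str,
    table: ExpressionTable,
    alpha: float = 0.001,
    depth: float = 1e6,
) -> set[str]:
    """Tissues where the gene is significantly enriched over the rest.

    Libraries are aggregated by tissue label; tissue t enters the set when
    the gene is expressed in t and the Audic–Claverie contrast of t's
    count against the pooled count of all other tissues is below ``alpha``
    with the observed count above its pooled expectation.
    """
    if len(table.libraries) < 2:
        raise ValidationError("tissue specificity needs at least two libraries")
    counts = _tissue_counts(table, gene, depth)
    depths = _tissue_depths(table, depth)
    specific: set[str] = set()
    for tissue, x in counts.items():
        if x <= 0:
            continue
        y = sum(c for t, c in counts.items() if t != tissue)
        n1 = depths[tissue]
        n2 = sum(d for t, d in depths.items() if t != tissue)
        if n2 <= 0:
            continue
        enriched = x / n1 > y / n2
        if enriched and audic_test(x, y, n1, n2) < alpha:
            specific.add(tissue)
    return specific


@dataclass
class FateCall:
    """Fate call and its evidence for one homoeologue group."""

    subject_gene: str
    copy_count: int
    fate: str
    expressed_copies: list[str]
    specificity: dict[str, frozenset[str]]
    max_kaks: float  # NaN when no ratio was available


def call_fate(
    group: HomoeologGroup,
    table: ExpressionTable,
    kaks_ratios: Mapping[str, float],
    alpha: float = 0.001,
    depth: float = 1e6,
    neo_before_subfunc: bool = True,
) -> FateCall:
    """Classify one homoeologue group.

    ``kaks_ratios`` maps each query copy to its Ka/Ks ratio against the
    subject gene (NaN allowed for undefined ratios).  A copy missing from
    the expression table is an error.
    """
    missing = [c for c in group.copies if c not in table]
    if missing:
        raise ValidationError(f"copies missing from expression table: {missing}")
    expressed = [c for c in sorted(group.copies) if (table.row(c) > 0).any()]
    ratios = [kaks_ratios.get(c, math.nan) for c in expressed]
    finite = [r for r in ratios if not math.isnan(r)]
    max_kaks = max(finite) if finite else math.nan

    spec_sets: dict[str, frozenset[str]] = {}
    if len(expressed) >= 2:
        spec_sets = {
            c: frozenset(tissue_specificity(c, table, alpha=alpha, depth=depth))
            for c in expressed
        }

    if not expressed:
        fate = "dead"
    elif len(expressed) == 1:
        fate = "nonfunctionalization"
    else:
        neo = any(r > 1 for r in ratios if not math.isnan(r))
        subfunc = len(set(spec_sets.values())) > 1
        if neo_before_subfunc:
            fate = "neofunctionalization" if neo else (
                "subfunctionalization" if subfunc else "unclassified")
        else:
            fate = "subfunctionalization" if subfunc else (
                "neofunctionalization" if neo else "unclassified")
    return FateCall(
        subject_gene=group.subject_gene,
        copy_count=group.copy_count,
        fate=fate,
        expressed_copies=expressed,
        specificity=spec_sets,
        max_kaks=max_kaks,
    )


def fate_report(calls: Sequence[FateCall]) -> dict:
    """Fate x copy-count matrix, with dead/unclassified reported separately.

    The matrix rows are the three functional fates over copy counts two,
    three, and four-plus, with a totals row; single-copy groups only admit
    dead/nonfunctionalization and are tallied in ``by_copy_count``.
    """
    cols = ["two", "three", "four"]
    main = ("nonfunctionalization", "subfunctionalization", "neofunctionalization")
    matrix = {fate: {c: 0 for c in cols} for fate in main}
    separate = {"dead": 0, "unclassified": 0}
    by_copy_count: dict[int, dict[str, int]] = {}
    for c in calls:
        by_copy_count.setdefault(c.copy_count, {f: 0 for f in FATES})[c.fate] += 1
        if c.fate in separate:
            separate[c.fate] += 1
        elif c.fate in main and c.copy_count >= 2:
            matrix[c.fate][cols[min(c.copy_count, 4) - 2]] += 1
        # single-copy nonfunctionalization groups stay out of the matrix
    df = pd.DataFrame(matrix).T[cols]
    df.loc["total"] = df.sum(axis=0)
    return {"matrix": df, "dead": separate["dead"],
            "unclassified": separate["unclassified"], "by_copy_count": by_copy_count}
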