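"""GO term and GO-slim enrichment by the one-sided hypergeometric test.

A test set is compared against a background that excludes it: for each
term, the 2x2 table (a = test genes with the term, b = without, c =
background with, d = without) gives the fold ratio (a/(a+b))/(c/(c+d)) and
the over-representation p-value P(X >= a) for X hypergeometric.  No
multiple-testing correction is applied by default, matching raw-cutoff
reporting with significance stars; Benjamini-Hochberg is available as a
flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .errors import ValidationError
from .io_formats import GoAnnotation

__all__ = ["EnrichmentResult", "enrich", "rollup_to_slim", "slim_frequencies", "stars"]


@dataclass
class EnrichmentResult:
    """One term's 2x2 table, fold ratio and hypergeometric p."""

    term: str
    a: int  # test genes with term
    b: int  # test genes without
    c: int  # background genes with term
    d: int  # background genes without
    fold: float
    p: float
    p_adjusted: float | None = None

    @property
    def stars(self) -> str:
        return stars(self.p)


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _bh_adjust(results: list[EnrichmentResult]) -> None:
    m = len(results)
    order = sorted(range(m), key=lambda i: results[i].p)
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        adj = min(prev, results[i].p * m / rank)
        results[i].p_adjusted = adj
        prev = adj


def enrich(
    test_set: Iterable[str],
    background_set: Iterable[str],
    annotation: GoAnnotation,
    alpha: float = 0.001,
    min_count: int = 1,
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """Test every annotated term for over-representation in the test set.

    The background must not overlap the test set (it is the complement by
    convention).  Genes without annotation count toward b/d.  Results with
    fewer than ``min_count`` test-set genes are dropped; output is sorted
    by p-value. ``alpha`` only affects the convenience significance stars,
    not the returned list.
    """
    test = set(test_set)
    background = set(background_set)
    if not test:
        raise ValidationError("empty test set")
    overlap = test & background
    if overlap:
        raise ValidationError(
            f"test and background sets overlap ({len(overlap)} genes, e.g. "
            f"{sorted(overlap)[:3]})"
        )
    n_test = len(test)
    n_bg = len(background)
    total = n_test + n_bg

    terms: set[str] = set()
    for g in test | background:
        terms |= annotation.terms_of(g)
    results: list[EnrichmentResult] = []
    for term in sorted(terms):
        with_term = annotation.annotated_genes(term)
        a = len(test & with_term)
        if a < min_count:
            continue
        c = len(background & with_term)
        b = n_test - a
        d = n_bg - c
        fold = (a / n_test) / (c / n_bg) if c > 0 else math.inf
        p = float(hypergeom.sf(a - 1, total, a + c, n_test))
        results.append(EnrichmentResult(term, a, b, c, d, fold, min(max(p, 0.0), 1.0)))
    results.sort(key=lambda r: (r.p, r.term))
    if bh_correct:
        _bh_adjust(results)
    return results


def slim_frequencies(gene_set: Iterable[str], annotation: GoAnnotation,
                     namespace: str | None = None) -> pd.DataFrame:
    """Frequency mode: percent of a gene set annotated to each slim.

    A gene with terms under several slims counts once per slim, so the
    percentages may sum to more than 100.
    """
    genes = set(gene_set)
    if not genes:
        raise ValidationError("empty gene set")
    counts: dict[str, int] = {}
    for g in genes:
        for slim in annotation.slims_of(g):
            if namespace and annotation.namespaces.get(slim) != namespace:
                continue
            counts[slim] = counts.get(slim, 0) + 1
    rows = [
        {"slim": slim, "n_genes": n, "percent": 100.0 * n / len(genes)}
        for slim, n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["slim", "n_genes", "percent"])


def rollup_to_slim(
    enriched_terms: Iterable[str],
    annotation: GoAnnotation,
    namespace: str | None = None,
) -> pd.DataFrame:
    """Enriched-term mode: share of each slim's terms that are enriched.

    For every slim, the percentage is the number of enriched GO terms
    mapping to it divided by the total number of annotation terms mapped
    to that slim.  Terms without a slim mapping are bucketed "unmapped".
    """
    enriched = set(enriched_terms)
    totals: dict[str, int] = {}
    for term, slim in annotation.slim_map.items():
        if namespace and annotation.namespaces.get(slim) != namespace:
            continue
        totals[slim] = totals.get(slim, 0) + 1
    rows = []
    unmapped = 0
    hits: dict[str, int] = {}
    for term in enriched:
        slim = annotation.slim_map.get(term)
        if slim is None:
            unmapped += 1
            continue
        if namespace and annotation.namespaces.get(slim) != namespace:
            continue
        hits[slim] = hits.get(slim, 0) + 1
    for slim in sorted(totals):
        n = hits.get(slim, 0)
        rows.append(
            {
                "slim": slim,
                "n_enriched_terms": n,
                "n_terms_under_slim": totals[slim],
                "percent": 100.0 * n / totals[slim] if totals[slim] else 0.0,
            }
        )
    if unmapped:
        rows.append({"slim": "unmapped", "n_enriched_terms": unmapped,
                     "n_terms_under_slim": 0, "percent": math.nan})
    return pd.DataFrame(rows, columns=["slim", "n_enriched_terms",
                                       "n_terms_under_slim", "percent"])


def write_enrichment(results: Sequence[EnrichmentResult], tsv_path) -> None:
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("term\ta\tb\tc\td\tfold\tp\tstars\n")
        for r in results:
            fold = "inf" if math.isinf(r.fold) else f"{r.fold:.4f}"
            fh.write(f"{r.term}\t{r.a}\t{r.b}\t{r.c}\t{r.d}\t{fold}\t{r.p:.6g}\t{r.stars}\n")
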