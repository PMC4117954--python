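"""Ka/Ks estimation for collinear gene pairs.

Protein-guided global alignment of the two CDS, back-translated to codons,
followed by Nei–Gojobori (1986) counting of synonymous/nonsynonymous sites
and differences with the Jukes–Cantor (1969) multiple-hit correction.

Site fractions exclude single-nucleotide changes that would create a stop
codon, renormalizing the remaining changes, so s_sites + n_sites always
equals 3 x the number of counted codons.  Multi-hit codon differences are
averaged with equal weight over all minimal mutational pathways that avoid
stop-codon intermediates (falling back to all pathways when every one is
blocked).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from typing import Iterable, Mapping

from Bio.Align import PairwiseAligner
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .errors import SequenceError

__all__ = [
    "CollinearPair",
    "align_codons",
    "ng86_kaks",
    "kaks_ratio",
    "compute_pair_kaks",
    "jc69_correct",
    "SATURATION_P",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
_NUCS = "ACGT"

#: JC69 domain boundary: proportions at or above 3/4 cannot be corrected.
SATURATION_P = 0.75


@dataclass
class CollinearPair:
    """Ka/Ks estimate and NG86 bookkeeping for one collinear gene pair."""

    query_gene: str
    subject_gene: str
    ka: float  # NaN when flagged
    ks: float
    s_sites: float
    n_sites: float
    s_diffs: float
    n_diffs: float
    aligned_codons: int
    flags: set[str] = field(default_factory=set)


def _translate_codon(codon: str) -> str:
    return _TABLE.forward_table.get(codon, "*")


@lru_cache(maxsize=None)
def _syn_fraction(codon: str) -> float:
    """NG86 synonymous site count for one sense codon (0..3).

    Per position: fraction of the single-nucleotide changes that are
    synonymous, among the changes that do not create a stop codon.
    """
    if codon in STOP_CODONS:
        raise SequenceError(f"stop codon {codon} has no site count")
    aa = _translate_codon(codon)
    total = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for nuc in _NUCS:
            if nuc == codon[pos]:
                continue
            alt = codon[:pos] + nuc + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if _translate_codon(alt) == aa:
                syn += 1
        if valid:
            total += syn / valid
    return total


@lru_cache(maxsize=None)
def _pathway_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Averaged (synonymous, nonsynonymous) differences between two codons.

    Equal-weight average over all orderings of the differing positions,
    skipping orderings that pass through a stop codon; if every ordering is
    blocked, all orderings are used.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return (0.0, 0.0)

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        sd = nd = 0.0
        cur = codon_a
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                return None
            if _translate_codon(cur) == _translate_codon(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        return (sd, nd)

    paths = [walk(order) for order in permutations(diff_pos)]
    open_paths = [p for p in paths if p is not None]
    if not open_paths:  # every route crosses a stop; count them all anyway
        open_paths = []
        for order in permutations(diff_pos):
            sd = nd = 0.0
            cur = codon_a
            for pos in order:
                nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
                if _translate_codon(cur) == _translate_codon(nxt):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            open_paths.append((sd, nd))
    s = sum(p[0] for p in open_paths) / len(open_paths)
    n = sum(p[1] for p in open_paths) / len(open_paths)
    return (s, n)


def _check_cds(cds: str, name: str) -> str:
    cds = cds.upper().replace("U", "T")
    if not cds:
        raise SequenceError(f"{name}: empty CDS")
    if len(cds) % 3 != 0:
        raise SequenceError(f"{name}: CDS length {len(cds)} not divisible by 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    # a trailing stop is tolerated and trimmed; internal stops are fatal
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    for i, c in enumerate(codons):
        if c in STOP_CODONS:
            raise SequenceError(f"{name}: internal stop codon {c} at codon {i + 1}")
        if any(n not in _NUCS for n in c):
            raise SequenceError(f"{name}: ambiguous base in codon {c!r}")
    return "".join(codons)


def _make_aligner(match: float = 1.0, mismatch: float = -1.0,
                  gap_open: float = -5.0, gap_extend: float = -1.0) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_codons(cds_q: str, cds_s: str, *, query_name: str = "query",
                 subject_name: str = "subject",
                 aligner: PairwiseAligner | None = None) -> tuple[str, str]:
    """Globally align two CDS at the protein level, back-translated to codons.

    Returns two gap-padded codon strings of equal length (multiple of 3);
    gaps are always whole codons ("---").
    """
    cds_q = _check_cds(cds_q, query_name)
    cds_s = _check_cds(cds_s, subject_name)
    prot_q = str(Seq(cds_q).translate())
    prot_s = str(Seq(cds_s).translate())
    if aligner is None:
        aligner = _make_aligner()
    aln = aligner.align(prot_q, prot_s)[0]
    aligned_q_prot, aligned_s_prot = str(aln[0]), str(aln[1])

    out_q: list[str] = []
    out_s: list[str] = []
    iq = js = 0
    for a, b in zip(aligned_q_prot, aligned_s_prot):
        if a == "-":
            out_q.append("---")
        else:
            out_q.append(cds_q[3 * iq : 3 * iq + 3])
            iq += 1
        if b == "-":
            out_s.append("---")
        else:
            out_s.append(cds_s[3 * js : 3 * js + 3])
            js += 1
    return "".join(out_q), "".join(out_s)


def jc69_correct(p: float) -> float:
    """Jukes–Cantor multiple-hit correction; NaN at/beyond saturation."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= SATURATION_P:
        return math.nan
    value = -0.75 * math.log(1.0 - (4.0 / 3.0) * p)
    return 0.0 if value == 0 else value


def ng86_kaks(aligned_q: str, aligned_s: str, *, query_gene: str = "query",
              subject_gene: str = "subject") -> CollinearPair:
    """NG86 Ka/Ks from a codon alignment (gapped columns are skipped)."""
    if len(aligned_q) != len(aligned_s) or len(aligned_q) % 3 != 0:
        raise SequenceError("aligned codon strings must have equal length, multiple of 3")
    s_sites_q = s_sites_s = 0.0
    s_diffs = n_diffs = 0.0
    counted = 0
    for i in range(0, len(aligned_q), 3):
        ca, cb = aligned_q[i : i + 3], aligned_s[i : i + 3]
        if "-" in ca or "-" in cb:
            continue
        counted += 1
        s_sites_q += _syn_fraction(ca)
        s_sites_s += _syn_fraction(cb)
        sd, nd = _pathway_diffs(ca, cb)
        s_diffs += sd
        n_diffs += nd
    if counted == 0:
        raise SequenceError(
            f"{query_gene}/{subject_gene}: no aligned codons to count"
        )
    s_sites = (s_sites_q + s_sites_s) / 2.0
    n_sites = 3.0 * counted - s_sites

    flags: set[str] = set()
    if s_sites <= 0:
        flags.add("no_syn_sites")
        ks = math.nan
    else:
        ps = s_diffs / s_sites
        ks = jc69_correct(ps)
        if math.isnan(ks):
            flags.add("saturated_ks")
    if n_sites <= 0:
        flags.add("no_nonsyn_sites")
        ka = math.nan
    else:
        pn = n_diffs / n_sites
        ka = jc69_correct(pn)
        if math.isnan(ka):
            flags.add("saturated_ka")
    return CollinearPair(
        query_gene=query_gene,
        subject_gene=subject_gene,
        ka=ka,
        ks=ks,
        s_sites=s_sites,
        n_sites=n_sites,
        s_diffs=s_diffs,
        n_diffs=n_diffs,
        aligned_codons=counted,
        flags=flags,
    )


def kaks_ratio(ka: float, ks: float) -> float:
    """Ka/Ks ratio.

    ks=0 with ka>0 gives +inf (counts as >1); ka=ks=0 or any NaN input
    gives NaN, which never compares as >1.
    """
    if math.isnan(ka) or math.isnan(ks):
        return math.nan
    if ks == 0.0:
        return math.inf if ka > 0 else math.nan
    return ka / ks


def compute_pair_kaks(query_gene: str, subject_gene: str, cds_q: str, cds_s: str,
                      aligner: PairwiseAligner | None = None) -> CollinearPair:
    """Convenience: align two CDS and run NG86 counting."""
    aq, as_ = align_codons(cds_q, cds_s, query_name=query_gene,
                           subject_name=subject_gene, aligner=aligner)
    return ng86_kaks(aq, as_, query_gene=query_gene, subject_gene=subject_gene)


def kaks_for_anchors(anchors: Iterable, cds_query: Mapping[str, str],
                     cds_subject: Mapping[str, str]) -> list[CollinearPair]:
    """Estimate Ka/Ks for every anchor pair with both CDS available."""
    aligner = _make_aligner()
    out: list[CollinearPair] = []
    for a in anchors:
        q, s = a.query_gene, a.subject_gene
        if q not in cds_query:
            raise SequenceError(f"missing CDS for query gene {q}")
        if s not in cds_subject:
            raise SequenceError(f"missing CDS for subject gene {s}")
        out.append(compute_pair_kaks(q, s, cds_query[q], cds_subject[s], aligner))
    return out
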