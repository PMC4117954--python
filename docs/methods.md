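# Methods

## The model

A mesohexaploid genome carries the superimposed remains of three polyploidy
events. Treating the diploid-like relative as a fixed reference, every
surviving duplicate lineage ("track") pairs its genes with their ancestral
counterparts at a characteristic synonymous divergence: orthologues from
the most recent triplication near Ks ≈ 0.53, copies surviving from the two
older duplications near ≈ 1.17 and ≈ 2.19. Because substitution rates are
locally coherent, the *segment-mean* Ks separates into waves much more
cleanly than per-gene Ks, so the analysis works at the level of syntenic
segments: chain anchors into segments, average Ks within each, classify the
segment, and only then push labels down to genes.

## Synteny chaining

Anchors are grouped per (query chromosome, subject chromosome) and chained
by dynamic programming: a chain is strictly increasing in query gene rank
and strictly monotone in subject rank (increasing = "same" orientation,
decreasing = "inverted"); two consecutive members may be separated by at
most `max_gap_genes` intervening genes on either genome (default 10) and
`max_gap_bp` base pairs (default unlimited). Chains are scored by member
count and extracted greedily best-first without anchor reuse; chains
shorter than `min_anchors` (default 5, the conventional minimum for
collinearity evidence) are dropped. Ties are broken by smaller query start
and then orientation, making the output independent of anchor row order.
The gene-rank reading of segment adjacency is the default because plant
intergenic distances make a literal base-pair limit very restrictive; both
limits are exposed.

## Ka/Ks estimation

Each pair's CDS are aligned at the protein level (global alignment, match
+1, mismatch −1, gap open −5, extend −1), back-translated, and gapped codon
columns discarded. Counting follows NG86: per sense codon, each position
contributes the fraction of its single-nucleotide changes that are
synonymous among the changes that do not create a stop codon (renormalized,
so s_sites + n_sites = 3 × counted codons exactly); sites are averaged
between the two sequences. Codons differing at k positions are resolved by
equal-weight averaging over the k! substitution orders that avoid stop
intermediates (all orders if every one is blocked). Proportions are
corrected with JC69, K = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 is reported as
saturated rather than numeric. This counting estimator replaces
likelihood-based codon models deliberately: the downstream analysis uses
the *relative* Ks structure (waves and within-segment outliers), which the
simpler estimator preserves, and it is exactly testable against a
brute-force codon-neighbor oracle. A precomputed Ka/Ks TSV can be supplied
to use output from any external estimator instead. Ka/Ks ratios: ks = 0
with ka > 0 reports +inf (counts as positive selection); 0/0 reports NaN,
which never satisfies the Ka/Ks > 1 rule. Only the standard genetic code is
supported.

## Epoch classification

Segment-mean Ks values (weighted by pair count) are fit with a
three-component 1-D Gaussian mixture. EM is initialized from the exact
weighted k-means partition of the sorted values (computed by dynamic
programming); quantile-based starts were rejected because ~80% of the
weight sits in the recent wave, which strands two components in one
cluster. Cutpoints are placed at the posterior-equality crossings of
adjacent components (midpoint of means if densities do not cross), and a
degenerate fit falls back to weighted quantile cutpoints with a warning.
Fixed cutpoints (default 0.85 and 1.75, midway between the canonical wave
means) are available for reproducible classification without fitting. A
value exactly at a cutpoint takes the younger label. The epoch is a
property of the whole segment, not of individual pairs.

Ancestral genomic blocks are intervals of subject loci ordered by AGI code
(chromosome number, then numeric suffix); the shipped table encodes the 24
refined Brassicaceae blocks A–X. A segment takes the block holding the
majority of its subject anchors and is split at block boundaries for
per-block reporting; how segments spanning blocks should be attributed is
genuinely underdetermined, and the majority/split rule is this package's
choice.

## Fast-evolving genes

Within each segment with ≥ `min_pairs` (default 5) members and positive Ks
spread, each pair's z = (ks − x̄)/s uses the segment's own mean and sample
(n−1) sd, including the tested gene itself; p is the upper-tail normal
probability and calls use raw p < 0.001 with no multiple-testing correction
(Benjamini–Hochberg and leave-one-out variants are flags). Including the
tested gene bounds the attainable z at roughly √n — with k planted outliers
in an n-pair segment the ceiling is √((n−k)(n−1)/(kn)) — so detection of
co-occurring outliers in short segments is structurally limited; this is a
property of the method, not of the implementation, and the leave-one-out
flag removes it at the cost of deviating from the self-inclusive formula.

## Retention and fates

Presence per epoch is existence of ≥ 1 collinear pair in a segment of that
epoch; the (recent, young, old) pattern maps to indexes 1–8 with
subject genes absent from all synteny kept as index 5. Subject genes with
recent copies form homoeologue groups (1–4 copies expected after a
triplication; larger groups are kept but flagged).

Expression evidence is digital: RPKM × depth/10⁶ (unit gene length, default
depth 10⁶) rounds to counts, so RPKM = 0 is exactly zero reads — the
pseudo-gene criterion. Tissue specificity tests each tissue's count against
the pooled remainder with the Audic–Claverie exact test (negative binomial
form, computed via log-space scipy tails); a tissue enters the specificity
set when enriched above its pooled expectation at p < 0.001. The two-sided
p doubles the smaller tail of the conditional distribution; because that
conditioning is not symmetric in the two libraries, both conditionings are
evaluated and the smaller capped p reported, making the test exactly
symmetric under library swap. Fate precedence per group: no expressed copy
→ dead; exactly one → nonfunctionalization; ≥ 2 expressed and any expressed
copy with Ka/Ks > 1 → neofunctionalization; ≥ 2 expressed with differing
specificity sets → subfunctionalization; otherwise unclassified.
Neofunctionalization is tested before subfunctionalization because positive
selection is the rarer, stronger signal; the order is switchable.

## GO enrichment

One-sided hypergeometric over-representation per term, with the background
defined as the complement of the test set; fold = test frequency /
background frequency. No ancestor propagation is applied: genes count
toward exactly the annotated terms. Slim roll-ups come in two modes: the
share of a *gene set* annotated under each slim (genes may count under
several slims, so shares can exceed 100%), and the share of each slim's
*terms* that are enriched.

## The synthetic-data generator

`simulate_dataset` applies the three events oldest-first, so the track
counts are 6 old, 3 young, 3 recent (2 × 2 × 3 = 12 lineages at full
retention). Fractionation acts at two scales per track: whole ancestral
blocks survive with probability `block_survival`, and genes within a
surviving block are retained i.i.d. with `gene_retention` — mirroring how
real fractionation leaves discrete syntenic islands rather than uniformly
thinned gene rows. Defaults (recent 0.55/0.70 over 60-gene blocks; young
0.12/0.50 over 40; old 0.02/0.50 over 30) give per-gene epoch presence of
roughly 77% / 17% / 6% and paper-like segment sizes at desk scale. The old
epoch is deliberately over-retained relative to a genome-scale survey
(where old collinearity is ~0.3% of genes): at 10³–10⁴ ancestral genes the
faithful rate would leave no old segments at all, and the chronology stage
needs a populated third wave. Surviving blocks become the true segments;
they are shuffled into query chromosomes with a guard that keeps segments
whose subject spans could continue each other's collinearity (within 25
ranks) from being laid adjacently, so a chainer cannot merge distinct
truths.

Pair Ks is Normal(epoch depth, `ks_dispersion`=0.15) truncated at 0.01; a
`fast_fraction` (default 0.017, the genome-wide rate implied by ~636 of
~37k pairs) of recent/young pairs is multiplied by `fast_inflation`
(default 3). Ka is `ka_ks_baseline` (0.2) × Ks, with planted
neofunctionalized copies at 1.5 × Ks. CDS pairs are generated by mutating a
random ancestral codon sequence with Poisson(Ks·S) synonymous and
Poisson(Ka·N) nonsynonymous events (rejection-sampled, stop-free), which a
Monte-Carlo test shows the counting estimator recovers within a few percent
up to Ks ≈ 1.

Expression counts are Poisson at fixed library depth by default
(`nb_size` enables negative-binomial overdispersion); the Audic–Claverie
test assumes Poisson sampling, so the default keeps the planted-fate
recovery test a test of the calling logic rather than of a deliberately
misspecified noise model — real biological overdispersion would inflate
its significance, which is a known limitation of the original procedure,
not of this implementation. Fates are planted per multi-copy group:
dead (all copies silent), nonfunctionalization (one expressed),
subfunctionalization (copies specific to disjoint tissues at ~60-fold
contrast), neofunctionalization (co-expressed, one copy Ka/Ks > 1), and
neutral (co-expressed). Pool libraries get the mean of the tissue means.
One GO term is planted at `go_planted_fold` (5×) background frequency
inside a recorded 150-gene set.

What the generator does **not** emulate: tandem duplications, transposons,
gene conversion and homoeologous exchange, inversions within segments,
biased subgenome dominance, GO-term correlation structure, and biological
expression overdispersion (see above). Passing recovery tests therefore
demonstrate correctness of the algorithms under the stated generative
model, not robustness to all the noise of real genomes.

## Problem sizes and numerical choices

Recovery tests run at 800–7,000 ancestral genes and 10–50 seeds, chosen so
each planted structure appears in statistically useful numbers (≥ 250
segments for the wave fit, > 500 fate groups, ~23 planted fast genes per
replicate). The fast-gene recovery condition uses inflation 4.0 and
dispersion 0.05 — the "strong effect" regime in which detection is limited
only by the co-occurrence ceiling described above. Epoch-wave recovery is
asserted on the mean of per-seed estimates within ±0.08 of the planted
depths. Sample standard deviations use the n−1 denominator throughout; sd
of a single value is reported missing, and a zero-spread segment is
skipped, not scored. All randomness flows from a single integer seed
through `numpy.random.default_rng`; equal seeds give byte-identical files.

## Known limitations

- Greedy best-first chain extraction is not globally optimal when long
  chains overlap; MCScan-like tools share this behaviour.
- NG86+JC69 underestimates Ks beyond ~1.5 and saturates near 2.5–3, so
  old-epoch estimates from sequence are noisy; the precomputed-table input
  exists for exactly that case.
- The z-score test's self-inclusion ceiling (above) caps sensitivity when
  several outliers share a short segment.
- Fisher/hypergeometric enrichment treats genes as independent; planted
  recovery rates do not account for annotation correlation.
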