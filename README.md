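# syntepoch

Genome archaeology for post-polyploidy plant genomes. `syntepoch` takes two
annotated genomes — a paleopolyploid "query" (think *Brassica rapa*, which
sits on top of two whole-genome duplications and a genus-specific
triplication) and a diploid-like "subject" reference (*Arabidopsis
thaliana*) — plus a table of homologous gene anchors, and reconstructs the
chronological layers of the query genome:

1. **Synteny chaining** — anchors are chained into collinear syntenic
   segments by dynamic programming with bounded rank/physical gaps.
2. **Divergence** — per collinear pair, Ka and Ks are estimated by
   protein-guided codon alignment and Nei–Gojobori (1986) counting with the
   Jukes–Cantor multiple-hit correction (a precomputed Ka/Ks table can be
   supplied instead).
3. **Chronology** — segment-mean Ks values fall into waves, one per
   polyploidy event; a weighted three-component Gaussian mixture (or fixed
   cutpoints) classifies every segment as *recent*, *young*, or *old*, and
   segments can be mapped onto the 24 ancestral Brassicaceae genomic
   blocks (A–X).
4. **Fast-evolving genes** — within each segment, a pair with Ks far above
   the segment mean (one-sided z-score, p < 0.001) is flagged as
   fast-evolving.
5. **Retention patterns** — each subject gene is scored for presence (O)
   or absence (X) of collinear copies per epoch, one of 8 indexes
   (OXX, OOX, …, XOO); recent-epoch copies form homoeologue groups of 1–4.
6. **Homoeologue fates** — groups are classified from tissue-level RPKM
   evidence and Ka/Ks as dead / nonfunctionalized / subfunctionalized /
   neofunctionalized, using the Audic–Claverie exact test for tissue
   specificity.
7. **GO enrichment** — any gene set against its complement background by
   one-sided hypergeometric tests, with GO-slim roll-ups.

Because the original genome-scale inputs are not bundled, the package ships
a first-class **synthetic-data generator** (`syntepoch.simulate`) that
emulates the whole history — three nested polyploidy events with two-scale
fractionation, planted Ks waves, fast genes, retention patterns, expression
fates and GO enrichment — and records the ground truth, so every stage is
testable end to end.

## The statistics at the core

For a collinear pair, NG86 counts synonymous sites per codon as
S = Σ_positions (fraction of single-nucleotide changes that preserve the
amino acid, excluding changes to stop codons), averages pathway-resolved
differences over both orderings, and corrects proportions with
K = −(3/4)·ln(1 − 4p/3). A segment with pairs x₁…xₙ has mean x̄ and sample
standard deviation s (n−1 denominator); gene i is fast-evolving when
z = (xᵢ − x̄)/s has upper-tail normal p < 0.001. The Audic–Claverie
probability of seeing y reads in one library given x in another is
P(y|x) = (N₂/N₁)^y (x+y)! / (x! y! (1+N₂/N₁)^{x+y+1}); enrichment of a GO
term is P(X ≥ a) for X hypergeometric on the 2×2 table of test set vs
background.

## Worked example

```python
from syntepoch.simulate import SimulationConfig, simulate_dataset
from syntepoch.synteny import chain_anchors, attach_segment_stats
from syntepoch.chronology import fit_epochs, assign_epochs
from syntepoch.fast_evolving import detect_fast_genes
from syntepoch.retention import classify_retention, group_homoeologs

config = SimulationConfig(n_ancestral_genes=2000, emit_cds=False, rng_seed=42)
dataset = simulate_dataset(config)
segments = chain_anchors(dataset.anchors, dataset.genes_query,
                         dataset.genes_subject, max_gap_genes=20)
attach_segment_stats(segments, dataset.truth.pair_ks)
model = fit_epochs([s.mean_ks for s in segments],
                   weights=[s.n_pairs for s in segments])
assign_epochs(segments, model)
print(f"{len(segments)} segments; wave means "
      + ", ".join(f"{m:.3f}" for m in model.means))
calls = detect_fast_genes(segments, dataset.truth.pair_ks)
print(f"{sum(c.is_fast for c in calls)} fast-evolving genes "
      f"among {len(calls)} tested pairs")
records = classify_retention([g.gene_id for g in dataset.genes_subject], segments)
groups, hist = group_homoeologs(records)
print(f"{len(groups)} homoeologue groups; "
      f"copy-count histogram {hist['histogram']}")
```

prints

```
89 segments; wave means 0.548, 1.218, 2.189
36 fast-evolving genes among 2912 tested pairs
1463 homoeologue groups; copy-count histogram {1: 779, 2: 548, 3: 136, 4: 0}
```

The three wave means recover the planted epoch depths (0.53 / 1.17 / 2.19
synonymous substitutions per site — the Brassica triplication and the two
older duplications); the copy-count histogram shows the 1–4 surviving
homoeologues per ancestral gene after fractionation.

## Command line

```bash
syntepoch simulate --seed 1 --outdir data/          # synthetic dataset
syntepoch run --config pipeline.toml                # all stages
syntepoch fastgenes --config pipeline.toml          # up to fast-gene calls
```

The TOML config names the input files (GFF3 ×2, anchors TSV, CDS FASTA or
Ka/Ks TSV, expression TSV, GO TSVs, blocks TSV) and every tunable
(e-value cutoff, chaining gaps, epoch method/cutpoints, alpha levels,
RPKM depth). Stage outputs are TSVs in the output directory; reruns with
the same config and inputs are byte-identical.

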