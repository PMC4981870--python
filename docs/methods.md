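# Methods

This note documents the models and procedures `netforge` implements,
the defaults it ships, the numerical choices behind them, and what the
synthetic benchmarks do and do not demonstrate.

## Gold-standard construction

Positives pair genes co-annotated by at least one term; negatives pair
annotated genes sharing no term. Together they partition the pairs of
annotated genes. Two filters precede pairing:

- **term size** (`max_term_size`, default 300 genes): a term with k
  genes contributes C(k, 2) positives, so a handful of broad terms
  would otherwise dominate training and bias the calibration toward
  them;
- **ontology depth** (`min_level`..`max_level`, default 2..10), applied
  only to terms carrying a `level` in their metadata: very shallow
  terms are uninformatively general, very deep ones too specific.
  Pathway sources without depth metadata are filtered on size alone.
  Term depths are consumed as metadata, never recomputed from the
  ontology graph.

When gold standards from several annotation sources are merged, a pair
positive anywhere is positive in the merge: a shared annotation in any
source is positive evidence, whereas a negative label only records the
*absence* of shared annotation in that source.

## Evidence channels

All channels emit `(geneA, geneB, score)` tables on canonical unordered
pairs; higher score = more evidence.

**Mutual information (MI)** is computed in nats on the joint histogram
after independent equal-width discretization of each vector
(`n_bins = 4` by default). Binary vectors are used as categories
directly; a constant vector yields MI = 0 rather than an error. The
base and binning are implementation choices: four equal-width bins keep
cell counts usable at the 20–50-column profiles these matrices have,
and any strictly monotone rescaling of scores leaves the downstream
calibration invariant anyway.

**Phylogenetic profiles** score each gene pair by the MI of their
presence/similarity rows (entries in [0, 1]); zero-MI pairs, including
genes absent everywhere, are dropped as carrying no signal.

**Domain co-occurrence** builds weighted profiles with entry
`1/freq(domain)` for carriers (freq = carriers / proteome size) and 0
otherwise. Rare domains are better function markers than common ones,
and the inverse-frequency weight encodes exactly that before the same
MI scoring is applied.

**Gene neighborhood** provides two statistics over per-genome gene
orders:

- *distance-based*: per genome, a pair on one contig contributes
  `1/(1 + |Δposition|)` (0 across contigs); the score is the mean over
  the genomes containing both genes, reported only for pairs
  co-occurring in ≥ 2 genomes.
- *probability-based*: with a window `w` (default 1), the score is
  `−ln P(X ≥ k)` where k counts genomes with the pair within `w`
  positions on one contig, and X sums independent per-genome proximity
  indicators with `q = min(1, 2w/(L−1))` for a contig of L genes. With
  unequal contig sizes the tail is the exact Poisson-binomial tail
  (computed by dynamic programming), which reduces to the binomial tail
  when all q are equal. For a genome where the pair sits on different
  contigs, q is taken from the first gene's contig — the genome still
  counts as an opportunity for proximity that did not materialize.
  Pairs never observed in proximity score 0 and are omitted.

**Co-expression** computes Pearson correlations between expression
rows. Datasets with fewer than 12 samples are rejected outright —
correlations estimated from fewer samples are promiscuous — and a pair
is retained only when the two-sided t-test `t = r·sqrt((n−2)/(1−r²))`
with n−2 degrees of freedom reaches p < 1 − conf (conf = 0.99). The
exact t distribution matters at these n; a normal approximation would
distort the filter precisely where it is used. Constant-expression
genes are skipped with a logged count (their PCC is undefined). The
two-sidedness is a documented choice: strong negative correlation is
also treated as evidence of a functional relationship.

## LLS calibration

For each dataset the gold-overlapping pairs are ranked by score
(descending; ties broken by canonical pair order for determinism) and
split into consecutive equal-count bins (`bin_size` pairs, default
1,000; the last bin may be ragged). Each bin's LLS is

    ln[ ((n_pos + 0.5) / (n_neg + 0.5)) / (N_pos / N_neg) ]

with the Haldane 0.5 pseudocount keeping degenerate bins finite and
the prior taken over the *entire* gold standard. The continuous
mapping from score to LLS is an isotonic (monotone non-decreasing)
regression of bin LLS on bin mean score, clipped outside the observed
score range; with fewer than five bins an ordinary linear fit is used
instead, as isotonic steps on so few points are mostly artefact. The
monotone family is deliberate: within one dataset a higher intrinsic
score must never map to a lower LLS.

The 0.632 bootstrap combines, per bin, the in-sample LLS with the mean
over B resamples (default 100) of the LLS computed on that bin's
out-of-bag pairs: `0.368·in + 0.632·mean(oob)`. Bins are fixed on the
full-sample ranking; the bin, not the model, is the estimation unit.
A resample leaving a bin with no out-of-bag gold pairs is skipped for
that bin and logged. All resampling derives from one integer seed.

Component networks retain pairs whose mapped LLS reaches `min_lls`.
The pipeline default is 1.0 nat: an edge below that is supported by
less than an e-fold (~2.7×) likelihood enrichment over the prior, i.e.
carries essentially no evidence, and admitting such edges measurably
distorts degree structure (see *Limitations*).

## Weighted-sum integration

An edge supported by LLS values L₀ ≥ L₁ ≥ … (after dropping values
below T — an edge with no supporter ≥ T does not exist, it is not a
zero-weight edge) scores `WS = L0 + Σ Li/D^i`. Closed-form anchors
used in testing: a single supporter gives WS = L₀; k equal supporters
at level L with D = 2 give `L·(2 − 2^(1−k))`; and always
`L0 ≤ WS ≤ L0·D/(D−1)` for D > 1.

(D, T) are optimized by grid search (defaults D ∈ {1, 1.5, 2, 3, 4},
T ∈ {0, 0.5, 1, 1.5, 2}) maximizing the trapezoidal area under the
cumulative-LLS versus cumulative-pairs curve, evaluated per bin of
ranked integrated edges with the same bin size as the
precision–recall analysis. Ties prefer smaller D, then larger T (the
more conservative setting). Note that this cumulative-area criterion
only penalizes a noise channel whose links hit gold negatives *above*
the prior rate; a channel whose links match the prior adds a vanishing
but non-negative tail area and is not excluded by T.

## Orthology transfer

Bidirectional best hits (ties resolved by higher score, then
lexicographically smaller subject, logged) seed clusters with
confidence 1. The InParanoid-style extension admits a same-species
gene as an inparalog of a seed gene with confidence equal to its
within-species similarity to the seed gene divided by the seed pair's
cross-species score, clipped to [0, 1]; a gene qualifying for several
clusters joins the one with the stronger seed. This is a deliberate
reduction of full InParanoid (no bootstrap confidence, no overlap-rule
cluster merging): it preserves the property the transfer score needs —
a calibrated per-link confidence that is 1 for mutual best hits and
decays with divergence. Similarity tables use direction codes AB/BA for
cross-species rows and AA/BB for the within-species rows the inparalog
rule requires; without within-species rows the clustering reduces to
plain BBH.

Transferred edges score `IWLLS = LLS(src) · s(A,A′) · s(B,B′)`. The
confidence product multiplies the LLS value itself (not its exponent);
since both scores are ≤ 1 transfer never increases a weight, and an
identity mapping is a no-op. When paralog fan-out maps several source
edges onto one target pair the maximum is kept — summing would
double-count the same ancestral evidence.

## Prioritization and validation

**Neighborhood scoring**: candidate score = Σ of direct edge weights
to guide genes; guides are excluded from the candidate list; ties
break lexicographically. Scoring is additive over disjoint guide sets.

**Leave-one-out AUC**: each guide is scored against the remaining
guides and compared with all non-guide network genes scored in the
same fold; the AUC is the Mann–Whitney statistic over all (held-out
guide, non-guide) comparisons with ties credited 0.5. Guides absent
from the network are dropped with a log. AUC > 0.7 is flagged as good
predictive power.

**Context hubs**: genes with degree ≥ 50 (default) are tested for
enrichment of their neighborhoods in the DEG set with a one-tailed
Fisher's exact test (hypergeometric upper tail) over the network's
gene universe minus the hub; hubs with p ≤ 0.01 are returned by
ascending p. One-tailed because neighborhood *depletion* of DEGs is
uninformative for this use. No multiple-testing correction is applied
by default, matching the method's P ≤ 0.01 convention; a
Benjamini–Hochberg flag is available.

**Function prediction**: candidate terms for a query gene are the
terms of its direct neighbors, scored by summed edge weight, top
k = 10 returned.

**Topology diagnostics**: the degree distribution is summarized by the
slope of a log10–log10 least-squares fit (descriptive, not a
likelihood-based power-law test); clustering (mean of local
coefficients, degree < 2 contributing 0) is compared against a
degree-preserving double-edge-swap null (10·|E| swaps per replicate);
shortest-path lengths are histogrammed over sampled connected pairs.

## The synthetic world

`generate_world(seed, ...)` plants `n_modules` disjoint modules of
`module_size` genes (defaults 6 × 20 in a 300-gene universe) and makes
module-mates co-functional in every channel:

- expression: `(1 − noise)·module_factor + noise·gene_noise` per
  sample (noise = 0 gives within-module PCC exactly 1), 24 samples;
- phylogenetic profiles: a module presence pattern over 30 genome
  columns, each entry resampled uniformly with probability `noise`
  (so noise = 1 erases the signal entirely rather than inverting it);
- domains: one rare module-specific domain (each member retained with
  probability 1 − noise) plus common background domains;
- gene orders: 8 genomes × 4 contigs; each module stays syntenic in a
  genome with probability 1 − noise;
- a duplicated target proteome whose namesakes are mutual best hits,
  with a `dup_rate` fraction carrying within-species paralogs at
  50–95% of the seed similarity;
- one annotation term per module plus random decoy terms of the same
  size.

Each channel draws from its own stream sub-seeded from the master
seed, so worlds are bit-reproducible and adding a channel never
perturbs the others. The generator emulates the statistical signatures
the methods exploit — correlation, profile similarity, synteny, shared
rare domains — not platform artifacts, realistic BLAST score
distributions, overlapping modules, or annotation incompleteness.
Passing benchmarks on these worlds therefore demonstrates correctness
and calibration of the machinery, not expected performance on any real
proteome.

The end-to-end pipeline on the default world uses bin_size 100 and
B = 20 bootstrap resamples — problem sizes chosen so a full build runs
in a few seconds while every stage still has enough gold overlap to
bin; the paper-scale defaults (bin_size 1,000, B = 100) remain the
library defaults for real-data use.

## Degenerate inputs and tie-breaking

- Self-pairs are rejected everywhere; all pair containers are
  canonical (lexicographically smaller gene first), making edge sets
  simple undirected graphs by construction.
- Score ties in ranking are broken by canonical pair order; best-hit
  ties by score then subject name; optimizer ties by smaller D then
  larger T. Every stochastic routine takes an explicit seed.
- Empty bins raise; constant vectors give MI 0; constant-expression
  genes are skipped; an all-below-threshold edge is absent, not 0.
- Weights serialize with 6 significant digits; all pair files are
  half-matrix, with an optional tolerant reader that collapses
  symmetric duplicates carrying identical weights.

## Limitations

- The two neighborhood statistics are concrete instantiations of the
  physical-distance and probability-of-proximity ideas, not exact
  reproductions of any published variant; both are approximations and
  are labelled as such here.
- The (D, T) area criterion rewards coverage: prior-rate noise is not
  excluded by T (see above), only anti-enriched noise is.
- With `min_lls = 0`, no-evidence edges accumulate on background genes
  and bias degree-sensitive benchmarks (rewired-null GBA medians fall
  visibly below 0.5); the 1-nat default avoids this, but any
  degree-imbalanced guide set still carries a residual degree bias in
  LOO-AUC, as it does for all guilt-by-association methods.
- Orthology clustering omits InParanoid's bootstrap confidence and
  cluster-overlap rules; similarity tables are consumed as given, no
  alignment is performed.
- The power-law fit is a descriptive log–log regression, not a
  rigorous scale-free test.
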