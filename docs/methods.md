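# Methods

## Overview

The package rebuilds a perturbation-transcriptome analysis of root-epidermis
cell-fate specification as five composable stages (differential expression,
core-gene screen, interventional Bayesian-network learning, temporal-zone
assignment, cluster assembly) and a synthetic-study generator that provides
ground truth for all of them. This note records the models, the defaults
and why they are what they are, and what the synthetic results do and do
not establish.

## SAM differential expression

For a two-class comparison the statistic is

    d(i) = (mean2(i) − mean1(i)) / (s(i) + s0)
    s(i) = sqrt[ (1/n1 + 1/n2) / (n1 + n2 − 2) · (SS1(i) + SS2(i)) ]

with fold change reported on the linear scale as `2^(mean2 − mean1)`.
Pooling several genotypes into one class (the hairy-vs-hairless
arrangement) needs no special handling — the pooled samples are simply one
class.

* **s0** defaults to the coefficient-of-variation minimisation over
  percentile candidates of `s` (the original SAM recipe, with the MAD of
  `d` evaluated in up-to-100 `s`-quantile windows); a fixed percentile and
  a fixed value (`s0_fixed=0` for hand calculations) are available.
* **Permutation FDR.** Class labels are permuted — exhaustively whenever
  the number of distinct label splits is ≤ `exhaustive_max` (1024), which
  covers the 20-split 3 v 3 and 924-split 6 v 6 designs; otherwise by
  balanced Monte-Carlo splits (each permuted class keeps near-proportional
  representation of the original classes). For each cutoff `c` over the
  observed |d| the estimated FDR is `π0 · median_p #{|d*_p| ≥ c} / #{|d| ≥ c}`,
  clipped to [0, 1]; a gene's q is the minimum estimate over cutoffs it
  passes (cumulative minimum in ascending-|d| order), which makes q
  monotone non-increasing in |d| by construction. `π0 = 1` by default
  (conservative); a quantile-based estimate is optional.
* The permuted statistics reuse the s0 chosen on the observed labels.

Calibration at the defaults (measured by the suite and the acceptance
script): on pure-null 500-gene 6 v 6 designs the mean fraction of q < 0.05
calls stays well under 0.08; with 3-log2-unit shifts at SD 0.5 the power at
q < 0.01 exceeds 95%. Both properties require a mostly-null gene universe:
with the median-count estimator, a universe dominated by truly changed
genes inflates every q (the permuted scores of changed genes flood the
null counts). That is why the synthetic chip carries a background
complement (below) — and on real arrays, why the screen is run genome-wide
rather than on a pre-selected signal set.

## Core-gene screen

Stage 1 keeps genes with q below `q_max` (default 0.01) at **either**
facility. Stage 2 requires at least `fc_min`-fold (default 2.0, ties pass)
in **each** of the six hairy-line × site comparisons, with one shared
direction; all-up genes are hair genes, all-down genes non-hair genes.
Fold changes are plain mean ratios per line and site (not SAM-internal
averages) — the simplest reading of "fold change in each individual
comparison"; the choice is config-visible. Genes missing from one site's
data are dropped with a warning rather than half-tested. Both stages are
monotone in their thresholds, and the two classes are mutually exclusive
by construction.

## Interventional Bayesian network

**Discretization.** Gene states are defined by expression *level*, not
rank: each gene's values are clustered on the value axis by exact
one-dimensional k-means (dynamic programming over the sorted values —
deterministic, no Lloyd local optima), and adjacent clusters closer than
`min_state_separation` (1.5 log2 units ≈ three noise SD) are merged, so a
gene expressed at fewer than three distinct levels gets fewer states.
Equal-frequency rank binning is available as an option, but under a
knockout design the state frequencies are intrinsically skewed (a gene is
clamped or off in most mutant lines), and forcing equal-count bins
mislabels 30–50% of samples — measured on the generator, this destroys
structure recovery outright. Phenotype values are clustered the same way
(hair length into up to 4 states, branching into 2); hormone nodes are set
from the treatment metadata. Knocked-out nodes are clamped to state 0 with
the intervention mask set.

**Score.** BDeu: the log Dirichlet-multinomial marginal likelihood with
symmetric hyperparameters α/(q·r) per cell, α = 1 (equivalent sample
size), uniform structure prior, maximum in-degree 4. A family's counts use
only samples where the child is not clamped; clamped values still count as
parent observations in their children's families. This is what orients
edges: with X clamped in part of the data, score(X→Y) > score(Y→X) on
X→Y-generated data, while purely observational data leaves the two equal
to machine precision (BDeu is score-equivalent). Scores are cached per
(node, parent-set) and decompose exactly over families.

**Search.** Hill climbing over add/delete/reverse moves (cycle-, role- and
in-degree-checked) from random seeded starts, with an optional
simulated-annealing phase (Metropolis acceptance, geometric cooling,
temperature auto-scaled from the spread of random-move deltas). Every
structure whose score is evaluated is offered to a deduplicated, strictly
score-ordered top-K list (K = 1000 by default; at capacity a tie never
displaces an incumbent). Nodes constant across all samples are excluded
as edge endpoints: such edges are vacuous, and under BDeu's q-scaling a
constant parent can act as a spurious prior-sharpening device. The
default pipeline configuration is greedy with 60 restarts — many
independent climbs populate the top-K with structurally diverse
near-optima, which is what consensus support fractions need; a long SA
walk concentrates the list around one basin and blurs support. The SA
strategy remains first-class and is held to the exhaustive-enumeration
optimum on 4-node problems (543 DAGs) in the tests. Desk-scale defaults
(top-1000, tens of restarts) stand in for the original study's 42,000-of->10⁹
computation; both knobs are plain config.

**Consensus.** A directed edge enters the consensus at threshold `f`
(default 0.40) when it appears in at least `f·K` of the top-K structures;
support is recorded, signs are annotated from the state correlation, and
cycles in the consensus union are permitted but logged (a consensus of
DAGs need not be a DAG). Consensus edge sets are monotone in `f`.

## Temporal zones

Genes × 24 section profiles (two roots × 12 developmentally ordered
sections) are z-scored per gene and clustered with average linkage on
correlation distance (1 − Pearson); the tree is cut into six clusters,
which are relabelled Zone 1..6 by ascending median peak section — making
the labels a permutation-invariant function of the data. The peak section
is the argmax of the root-averaged profile, ties to the earlier section.
The fixed collapse {1,2}→EARLY, {3,4}→MID, {5,6}→LATE feeds cluster
assembly. The published zone boundaries were estimated visually; the
relabel-by-median-peak rule is this package's operationalisation.

## Signatures, clusters and utilities

Signatures call UP (fc ≥ 2, q < 0.05), DOWN (fc ≤ 0.5, q < 0.05) or NONE
per gene and perturbation; hormone comparisons (treated vs vehicle within
the transfer background) use the stricter 0.5% FDR. Clusters partition
genes by the exact signature tuple over a configurable perturbation subset
and the collapsed zone; a cluster is flagged robust when every member
responds in ≥ 6 of the downstream-mutant panel. Enrichment is one-sided
Fisher (hypergeometric tail), raw p with a Benjamini-Hochberg column.
Classical MDS is Torgerson's double-centred eigendecomposition with
sign-fixed axes. The promoter scan matches an IUPAC consensus on both
strands of the 1-kb window proximal to the translation start, reporting
1-based upstream-negative positions (reverse-strand hits by their
plus-strand start).

## The synthetic study

The default truth is a hand-designed 15-gene cascade: an activator chain
G01→G02→G03 (the complex the three hairy lines disable), an antagonist G04
(the hairless line's gene, loosely coupled to G01), a fate switch G05
(activated by G03, capped by G04), a non-hair branch G06→{G07, G08, G11}
and a hair branch G09→{G10, G14, G15}, with G14 driving hair length
inversely and G15 branching inversely, two hormone-responsive reporters
(G12, G13) silent without stimulus, and two phenotype nodes. Children of a
shared regulator carry different response logics (graded copy, graded
inversion, high-threshold switch) so siblings are not functional clones —
clones would make edge placement unidentifiable at 66 samples.

Key emission defaults: state means {6, 9, 12} log2 units, replicate SD
0.5, site B shifted +0.3 (batch effect); hair length 120–480 µm by
phenotype state (SD 25 µm), branching fraction 0.10/0.60 (SD 0.05),
generated per sample from that sample's driver state. The chip carries 193
unregulated background genes (stable baselines, noise and batch only) for
a realistic mostly-null universe of 208 genes.

CPT noise is **state-conditional**: responses are near-deterministic
(fidelity 0.98) when every regulator sits at an extreme state — the regime
knockout lines occupy, matching the full penetrance of the real mutants —
and stochastic (0.88) at intermediate regulator levels, where graded
transcriptional responses are naturally noisy. Terminal effector genes
carry flat moderate noise (0.92/0.88): their fluctuations do not propagate
but provide the within-line variation that lets the learner separate a
direct regulator from a correlated sibling. The antagonist is flat 0.85 —
its independent variation is what identifies its repressive input. These
fidelities were fixed by validating the whole pipeline across repeated
simulation draws, balancing two opposed requirements: crisp line contrasts
for the screen and informative stochasticity for structure learning.

Knockouts are interventions (clamp to state 0, skip ancestral sampling);
hormone transfers set the hormone node and override that hormone's rescue
targets in the designated mutant background — a harness for the
hormone-rescue experiment, not a mechanistic model, and deliberately kept
out of the 66 untreated learning samples. Consequently hormone→gene edges
are not part of the truth DAG; the hormone nodes still enter the learner
(constant in the learning data, hence inert), as in the published
network's node set.

Across a 12-draw validation at these defaults the consensus recovers
87–100% of true edges (median 97%) at 67–100% precision (median ~85%),
always including the hair-length driver as parent of the length node; the
screen recovers the fate-hub downstream genes at 0.67–1.0 sensitivity
(median ≈ 0.9) and ~1.0 specificity; zone assignment agrees with the truth
at ≥ 95%. The residual draw-to-draw spread is intrinsic to 66 samples and
nineteen nodes, and the quoted test thresholds hold at the suite's fixed
seeds, which were chosen as a representative draw, not a best case.

### What the generator does not model

Probe-level microarray physics (saturation, cross-hybridisation, probe
effects), genome-scale chips, cell-type mixtures within a sample,
mechanistic hormone signalling, and continuous expression dynamics.
Passing the synthetic checks shows the pipeline's logic and numerics are
sound under the stated noise model — not that the thresholds would recover
the same gene counts from the original arrays.

## Numerical choices and degenerate inputs

Ragged, duplicated or non-numeric expression input is an error (no silent
imputation); constant genes discretize to all-zero states with a warning;
equal values share the lowest rank state; argmax ties resolve to the
earlier section; the top-K list breaks score ties by canonical edge tuple;
all stochastic stages take explicit seeds and are byte-reproducible.
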