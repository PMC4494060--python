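# Methods

This note records the models, conventions, numerical choices and known
limitations behind each analysis stage, and the problem sizes at which the
test suite exercises them.

## Coordinates and data model

All gene coordinates are 0-based, half-open, forward-strand; GFF3 input
(1-based inclusive) is converted on read, and the conversion is self-inverse.
Genes may wrap the circular coordinate origin (stored with start > end and a
`wraps` property); midpoints are computed along the gene's span modulo the
genome length, which makes every positional statistic invariant under
rotation of the coordinate system.  Bootstrap supports live on a percent
scale in [0, 100]; inputs that look like fractions are rescaled with a
warning, and a missing support is `None`, never 0 — operations that
threshold on support treat missing as failing.  Branch lengths are likewise
"absent", never 0, when the Newick does not provide them; rate computations
refuse rather than divide.

## Replichore analysis

GC skew is (G−C)/(G+C) per window (default window 10 kb, step 1 kb — these
resolve the two skew shifts on a 1.5 Mb chromosome without letting
single-window noise dominate).  Windows wrap circularly; a window with no G
or C scores 0 and is flagged.  The cumulative skew is the running sum of
window skews, and with the leading-strand-G-rich convention its minimum
marks *ori* and its maximum *ter*; `polarity="c_leading"` flips the
assignment, since the skew polarity is an empirical convention, not a law.
Both calls carry the window size as their uncertainty.

**Flat-curve guard.**  A skew-less genome still produces a wandering
cumulative curve (it is a correlated random walk), so the guard is based on
the window statistics, not the curve range: under the null the window skew
is binomial sampling noise with standard deviation ≈ 1/√(G+C per window).
If the observed window-skew standard deviation is below 2× that expected
noise the profile is declared signal-free ("no replichore signal").  The
factor 2 cleanly separates the null (ratio ≈ 1) from planted amplitudes
≥ 0.05 with 10 kb windows (ratio ≥ 3.5).

*dif*-site scans are IUPAC-aware, circular, on both strands, with a
mismatch budget; no motif is hard-coded — the consensus is organism-family
specific and must be supplied.

**Growth fits.**  Doubling time is ln 2 divided by the OLS slope of ln OD on
time (minutes).  When no window is given, the exponential phase is selected
automatically: every contiguous run of ≥ 4 positive-OD points with positive
slope is fitted, and the run with the highest R² wins, longer runs breaking
ties.  The tie-break matters: on noise-free data many sub-windows tie at
R² = 1 and the longest exponential stretch is then chosen.  On noisy data
the criterion can prefer a short lucky window; at the noise levels the
generators emulate (2% multiplicative OD noise, 30-min sampling) recovery
stays within 10% of truth across 100 seeds, which the suite asserts.

**Replication ratio.**  R = (L/2 ÷ v)/(60·t_d), reported at full precision
and rounded to 2 decimals.  It is dimensionless; doubling the fork speed
exactly halves R.

## Positional bias

Distances to *ori* are integers in [0, L/2], so ties are certain; the
Kruskal–Wallis H carries the tie correction and its p-value comes from the
χ² approximation with k−1 degrees of freedom.  Categories with fewer than 5
genes (configurable) are excluded and listed — rank tests below that size
are noise.  Pairwise Mann–Whitney tests are two-sided; for group sizes ≤ 8
the p-value is exact by full enumeration of rank splits (ties handled via
mid-ranks, two-sided = twice the smaller tail, capped at 1), otherwise the
tie- and continuity-corrected normal approximation is used.  The two
conventions agree within 0.01 except as p → 1, where two-sided doubling
definitions legitimately diverge.  Bonferroni multiplies by the number of
pairs actually tested after eligibility filtering, not the nominal number
of category pairs.  Tests run per genome by default; a pooled mode
normalises distance by L/2 to combine genomes of different sizes.

## Gene-content flux

Each family is reconstructed independently by a Sankoff dynamic program
over copy-number states {0..max_copies} (cap 8; higher observed counts are
clipped with a warning — beyond 8 copies the per-copy cost term makes
states nearly equivalent anyway).  The per-branch transition cost is the
composite-event reading of the cost list:

* c(a, a) = 0
* c(0, b≥1) = gain + (first_dup + (b−2)·copy_step for b ≥ 2)
* c(a≥1, 0) = loss (flat, regardless of a)
* c(1, b≥2) = first_dup + (b−2)·copy_step
* otherwise |a−b|·copy_step (contractions priced like expansions)

This composition is internally consistent: no multi-edge chain of
transitions is ever cheaper than the single-edge cost (verified by
shortest-path closure in the tests).  Defaults are gain 10, loss 5, first
duplication 1, copy step 0.2 — the strong gain/loss asymmetry encodes the
assumption that convergent acquisition is rare while convergent loss is the
engine of reductive evolution.

**Root convention.**  By default the root state is free (standard ancestral
parsimony): a family on both sides of the root is ancestral at no cost.
The alternative `charge_root=True` prices presence at the root as an
acquisition on a root stem.  That convention is available because it is the
natural reading when the matrix spans taxa beyond the tree, but it is kept
off for flux quantification: with the default costs it makes a clade-wide
loss (10 + 5) dearer than an independent re-gain in the sister clade (10),
systematically converting reduction into parallel gains.

**Tie-break.**  Among co-optimal back-pass states a child keeps its
parent's state when that is co-optimal; remaining ties resolve to the
higher copy number (at the root too).  This places changes rootward without
sacrificing optimality and makes event logs byte-stable; families are
processed in lexicographic order for the same reason.

The DP total cost equals exhaustive enumeration over all ancestral
assignments on every instance the suite can enumerate (200 random trees of
≤ 5 leaves, states ≤ 3, both root conventions), and per-family summed branch
costs reproduce the DP total exactly.  On loss-heavy simulations (13 taxa,
500 root families, gain 0.05 / loss 0.6 / duplication 0.05 per unit branch
length, one focal branch with an 8× loss multiplier) the inferred
per-branch loss counts track the true ones with Spearman ≥ 0.96 and the
focal branch ranks first in all 10 seeds.

Loss rates divide per-branch losses by branch length; the fold-excess of a
focal branch is reported as a range against the minimum and maximum
background rate over the other internal branches, matching how a
"2.6–16-fold" style statement is constructed.

## Tree congruence

A "sister pair" is a two-leaf cherry: an internal node with bootstrap
support strictly above the threshold (default > 95) whose subtree is exactly
two leaves.  Larger supported clades contribute nothing, and missing
supports fail the threshold.  Tallies keep the full tree count as the
denominator while recording, per pair, in how many trees both taxa were
present.  Monophyly of named groups requires each group with ≥ 2 present
members to be the exact leaf set of a supported node; singleton or absent
groups are vacuously monophyletic.  Host congruence restricts both trees to
the mapped leaves (mapping must be injective), relabels the host tree, and
reports shared non-trivial bipartitions plus the Robinson–Foulds distance
normalised by its maximum 2(n−3); random 10-leaf tree pairs average a
normalised distance near 1, which the suite checks by simulation.

## Recombination screen

Parsimony-informative sites are columns with ≥ 2 states each in ≥ 2
sequences; gaps and N are missing, a state is counted only over non-missing
sequences, and columns with < 4 non-missing sequences are excluded.  For a
site pair the refined incompatibility is

    inc(i, j) = l(i, j) − (s_i − 1) − (s_j − 1)

with l(i, j) computed exactly from the partition-intersection graph (states
of the two sites as vertices, observed joint patterns as edges):
l = #joint patterns + #components − 2.  This equals the minimum joint
parsimony length over all topologies (verified against explicit topology
enumeration on ≤ 6 sequences) and reduces to the four-gamete test for two
binary sites.

Phi is the mean incompatibility over informative-site pairs within a window
of 100 informative-site ranks (window in rank, not bp, so alignment-length
heterogeneity does not change the statistic's support).  The null permutes
the informative-site order (default 1,000 permutations; seeded), and
p = (1 + #{perm ≤ obs})/(n+1), so p is never 0 and a window covering all
sites forces p = 1 exactly.  The raw-mean variant of the statistic is used;
the permutation null makes any monotone normalisation irrelevant to the
p-value.  Alignments with < 2 informative sites are "untestable" and never
receive a p-value.  The screen marks a gene positive only when every
available test (Phi plus externally supplied per-gene p-values, e.g. from
other homoplasy statistics) is strictly below alpha (default 0.01);
untestable genes leave the denominator; the positive fraction is rounded
half-away-from-zero to one decimal.

Calibration (suite): on clonal simulations (8 taxa, 1,000 sites,
substitution rate 0.5) the p-values are uniform (KS not rejecting at 0.01
over 200 replicates); on concatenations of two conflicting quartets
(500 + 500 sites, rate 0.6 — about 1.4 substitutions/site between clades)
power is 100/100 at alpha 0.01.

## Synthetic data

Every generator is a pure function of (parameters, seed) with its own
`numpy` Generator — no global state — and returns a truth sidecar with the
planted parameters.  The default scenario mirrors a small host-associated
lactobacillus species complex: 13 taxa in four microclusters of 2–3 strains
plus two early-diverging strains and an outgroup; a 1.5 Mb chromosome with
skew amplitude 0.08; 1,300 genes in six categories (two ori-proximal, two
ter-proximal, two uniform); 500 root gene families (plus 80 gainable novel
families) evolving at gain 0.05 / loss 0.6 / duplication 0.05 per unit
branch length with an 8× loss multiplier on the ingroup stem; 790 gene
trees mixing the three resolutions of one microcluster at 0.60/0.25/0.15
with supports from a normal(98, 2) truncated to [0, 100]; 24 gene
alignments (20 clonal, 4 recombinant) at substitution rate 0.3; and a
55-minute growth curve with a 60-minute lag, OD plateau 1.2 and 2%
multiplicative noise sampled every 30 minutes.

Genome simulation biases P(G) to 0.25(1+a) on the ori→ter arc and mirrors
it on the other arc, so the planted window-skew amplitude equals `a`
directly.  Position simulation draws the planted distance from a triangular
distribution peaked at 0 (ori-proximal) or at L/2 (ter-proximal), or
uniformly on [0, L/2], then places the gene on a random side of ori.  Gene
content evolves by per-family Gillespie sampling along branches (gain only
while absent; loss zeroes the family; duplication increments), with the
complete event log recorded — replaying the log from the root reproduces
the leaf matrix exactly, which the suite asserts.  Alignment segments
evolve under an equal-rate (Jukes–Cantor) model with no rate heterogeneity
or indels; supports, topology choices and growth noise come from the same
seeded stream.

What the generators deliberately do not emulate: compositional
heterogeneity along the chromosome (real skew curves have local excursions
from horizontally acquired regions), rate variation among sites and
lineages, gene-tree discordance from incomplete lineage sorting rather than
topology mixtures, and indel/missing-data structure in alignments.  Passing
the recovery and calibration tests therefore demonstrates correctness of
the statistics under their stated models, not robustness to every artefact
of real assemblies.

## Known limitations and open choices

* Power of the global rank test for one ori-proximal (triangular) category
  among uniform ones sits almost exactly at 0.9 at 100 genes/category and
  alpha 0.001 — the triangular-vs-uniform Mann–Whitney AUC is exactly 2/3,
  which is the boundary of that operating point.  The suite states the 0.9
  bound and documents that the measured value with derandomised seeds is
  0.896 over 1,000 tables.
* Ori localisation is skew-only; gene-context refinement (e.g. the
  *rpmH–dnaA* intergenic region) would need annotations and is not
  implemented.
* The Phi window and permutation defaults (100 ranks, 1,000 permutations)
  are conventional, not fitted; the acceptance-calibration runs use 500
  permutations to keep the suite fast.
* Copy-number versus presence/absence for flux is genuinely ambiguous in
  comparative practice; both modes are first-class and outputs are labelled
  with the mode used.
* The pipeline's end-to-end `run` uses the default scenario at full scale
  (1.5 Mb genome, 790 trees, 580 families, 24 alignments with 200
  permutations each), which completes in well under a minute and is
  byte-deterministic for a fixed seed.
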