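# Methods

This note documents the models, the numerical choices and the open design
decisions behind barcodekit, and what the synthetic-data tests do and do
not demonstrate about real libraries.

## Distances

K2P distances are computed per pair on the aligned library with **pairwise
deletion**: a site is comparable only if both sequences carry an
unambiguous A/C/G/T there; gaps and IUPAC ambiguity codes are excluded
rather than probabilistically resolved (simpler and conservative — an
excluded site can never manufacture a difference). With transition and
transversion proportions P and Q over the n comparable sites,
d = −½ ln[(1−2P−Q)√(1−2Q)]. Two degenerate situations yield an explicit
*undefined* flag instead of a number: n = 0, and saturation (logarithm
argument ≤ 0). Downstream, undefined distances contribute no clustering
edge and count as beyond any identification threshold; neighbor joining
refuses them outright and asks for imputation or pruning. The package
requires pre-aligned input for K2P (an equal-length check); multiple
sequence alignment is upstream of its scope.

LCS similarity (|longest common subsequence| / max length) serves the
short-marker assigner, which deliberately works from raw pairwise
similarities rather than model-corrected distances of a global alignment.
The implementation is the bit-parallel formulation (the DP row kept as an
integer bit vector), validated in the tests against exhaustive subsequence
enumeration on small strings. Dividing by the *longer* length was chosen
over min- or alignment-length normalisation: it is the strictest of the
three, so a truncated query can never look more similar than a full-length
one.

## Distance-based delimitation

Single-linkage clusters are the connected components of the graph joining
pairs at distance ≤ t, with t = 0.022 by default (the conventional 2.2%
COI divergence threshold). The optional refinement step runs standard
Markov clustering (expansion 2, inflation 2.0, column-stochastic
normalisation, convergence 1e-8 or 100 iterations) *within* each initial
cluster of size ≥ 4, on the similarity graph s(i,j) = max(0, t − d(i,j)).
Refinement can only split, never merge across initial clusters, so the
result always refines the single-linkage partition. This is a deliberately
local, simplified stand-in for registry-scale cluster refinement: the
output clusters are "BIN-like" for the library at hand and are never
claimed to coincide with database-registered BIN identifiers, which depend
on sequences outside the library.

Concordance classifies each nominal species against a partition as match /
split / merge / mixed from the species-by-cluster contingency table; merges
are counted once per merged cluster so a two-species merge is one event,
not two.

## Poisson Tree Process

The single-rate (two-class) PTP model is used: a delimitation is a cut of
*species roots* (an antichain covering every tip), branches strictly below
a species root are coalescent-class, all others speciation-class, and each
class gets an exponential rate MLE λ̂ = n/Σb with profile log-likelihood
n ln λ̂ − n. The two degenerate cuts (one species; every tip its own
species) leave a class empty and reduce to the single-rate null fit.
Zero-length and missing branch lengths are raised to ε = 1e-9 before
evaluation. The root's children are speciation-class whenever the null
model is rejected. Multi-rate (per-species coalescent rate) variants are
out of scope.

Search: trees of ≤ 12 tips are solved by exhaustive enumeration of all
cuts; larger trees by hill climbing from *both* ends of the cut lattice —
top-down (split the best species root) and bottom-up (merge the best full
sibling group) — keeping the better optimum. A single-direction climb can
stall when the gain from a split only materialises several levels deeper
(observed on simulated trees whose divergence is concentrated in species
stems); the two-direction climb recovers the exhaustive optimum on every
fixture tree in the test suite, but it remains a heuristic without a global
guarantee.

Support values come from Metropolis–Hastings sampling over cuts under a
uniform prior: each step proposes, with probability ½ each, splitting a
species root or merging a sibling group, with candidate-count Hastings
corrections, which gives exact detailed balance (verified against the
enumerated posterior on small trees, agreement within 0.05 at 1e5 steps).
Defaults are 5 independent runs of 1e5 steps with 20% burn-in — the run
structure of the large-scale analyses this mirrors, at a desk-scale step
count chosen so the oracle comparison completes in seconds; the convergence
diagnostic reported is the largest across-run spread of any node's support.

## Leave-one-out identification

A specimen is an eligible query iff its label has ≥ 2 representatives;
singletons stay on the reference side. The three criteria share one rule on
a match set M: correct if all of M is conspecific, incorrect if none,
ambiguous otherwise. For nearest neighbour M is the set of equally nearest
non-self specimens; best close match additionally returns *no ID* when the
nearest distance exceeds the threshold; threshold ID takes M = all
specimens within the threshold. Mixed nearest-neighbour ties are reported
as ambiguous by default; `fold_ties=True` scores them correct when at
least one tied neighbour is conspecific — the charitable convention used
by success tables that print only correct/incorrect for this criterion —
and the flag is deliberately explicit rather than silent.

Threshold optimisation scores, per eligible query and candidate t, a false
positive when no conspecific lies within t and a false negative when some
heterospecific does; the two can co-occur and both count (no exclusivity
is imposed). The objective is the summed count over queries; the grid is
0.001–0.100 in 0.001 steps by default and ties break toward the smallest
t. Undefined distances are treated as +∞ throughout.

## LCA assignment

Primary references are the argmax of similarity S to the query; secondary
references are those at least S-similar to *some* primary (the union
reading of an ambiguous singular/plural rule — the inclusive choice, which
can only coarsen the assignment, never wrongly sharpen it). The query is
assigned to the MRCA of the species of primary ∪ secondary in the rank
ladder subfamily > tribe > genus > subgenus > species; queries with
S < 0.70 are left unassigned (no published value exists for this floor;
0.70 is far below any plausible conspecific similarity for these markers
yet high enough to reject junk), and queries shorter than 50 nt are
refused. Correctness in leave-one-out mode means the assigned taxon is an
ancestor-or-self of the query's true species — by construction an
assignment cannot be "incorrect at a coarser rank" if the true species is
among the references considered.

## Synthetic libraries

The generator emulates the structure of a regional barcode campaign: a
pure-birth (Yule) species tree; within-species variation as a star
genealogy by default (each specimen at depth intra_depth/2, expected
pairwise distance intra_depth), with a Kingman coalescent option;
sequences evolved site-independently under K2P transition probabilities
with rate ratio κ (default 3.0, a typical insect-mitochondrial
transition bias; a JC69 option sets equal rates for robustness checks).
Defaults are the gapped study conditions used throughout the tests:
20 species × 4 specimens, 658 nt, intra 0.005, inter 0.08.

Divergence control is the generator's central design decision. The species
tree is rescaled so the mean between-species tip-pair distance equals
inter_depth, and every species clade then receives a stem extension making
the *minimum* between-species path 0.6 × inter_depth. A plain rescaled Yule
tree frequently places its shallowest split near zero, which would make
"the barcode gap" a property of luck rather than of the configuration; the
floor turns the gap into a controlled parameter, which is exactly the
feature threshold delimitation and identification respond to. With the
default depths, the shallowest true interspecific distance is 0.048,
roughly 3 standard errors above the 0.022 clustering threshold at 658
sites, so exact partition recovery is expected in ≈ 100% of replicates
(and measured at ≥ 95% over 20 seeds in the acceptance suite).

Pathologies are injected deterministically given the seed: a cryptic split
gives one label two deeply diverged clades (two true clusters); a merge
puts two labels inside one shallow clade (near-identical haplotypes, one
true cluster); singletons are species forced to one specimen. True cluster
count is therefore n_species + n_splits − n_merges. Note that a split
species makes the *label-based* empirical barcode gap negative by
construction — its within-label pairs span two clades — which is the
realistic signature of a cryptic complex, and is why the study-shaped
acceptance run reports a negative library-wide gap while the clean
configurations report a strongly positive one.

What passing these tests does **not** show about real data: no indels or
alignment error (sequences are generated aligned), no sequencing error or
chimeras, no rate variation among sites or lineages, no geographic
structure within species, and a taxonomy assigned by index blocks rather
than by descent — so genus-level LCA behaviour on real libraries depends
on taxonomic accuracy in ways the simulator cannot probe.

## Problem sizes

The test and acceptance runs use: 20 replicates of the 80-specimen default
configuration; one 266-specimen / 75-species study-shaped COI library
(57 × 4 + 10 × 3 + 8 × 1 specimens, one split, one merge); a 216 nt
short-marker twin for the assigner; PTP MCMC at 5 × 1e5 steps on trees of
≤ 8 tips for the posterior oracle. These sizes keep the full suite and the
acceptance script in the low tens of seconds while leaving every statistic
well inside its asymptotic regime for the comparisons made.
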