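# barcodekit

Tools for building and stress-testing DNA-barcode reference libraries, of
the kind assembled for regional inventories of morphologically difficult
groups (the motivating case: Neotropical mosquitoes barcoded with the
standard ~658 bp COI marker and a short ~216 bp 16S "insect metabarcode").
Given a library of sequences with nominal species labels, the package
answers three questions:

1. **How many molecular species does the library contain?** Distance-based
   delimitation (threshold single-linkage at 2.2% divergence with optional
   Markov-clustering refinement, producing local BIN-like clusters) and
   tree-based delimitation (the Poisson Tree Process on a rooted phylogram,
   with greedy/exhaustive search and MCMC support values).
2. **How reliably can a new specimen be identified?** Leave-one-out
   evaluation under the three standard criteria — nearest neighbour ("best
   match"), best close match, and threshold ID ("BOLD ID" / all species
   barcode) — with grid optimisation of the distance threshold by the
   false-positive + false-negative objective, and the singleton rule
   (single-specimen species are never queries but stay as potential
   matches).
3. **What can a short metabarcode resolve?** Ecotag-style assignment: the
   query joins the most recent common ancestor of its primary (most
   similar) and secondary (as-similar-to-primary) references, where
   similarity is |LCS| / max length.

A seeded simulator generates libraries with known ground truth — Yule
species tree, controllable barcode gap, K2P sequence evolution, injected
singletons, cryptic splits and merges — so every stage is testable without
any download.

## The statistics at the core

Distances are Kimura two-parameter with pairwise deletion: for transition
and transversion proportions *P*, *Q* over the comparable sites of a pair,

    d = -1/2 ln[(1 - 2P - Q) sqrt(1 - 2Q)]

Saturated or empty pairs are masked, never NaN-propagated. The Poisson Tree
Process classifies branches into speciation and coalescent classes by a cut
of species roots; each class has exponential rate MLE λ̂ = n/Σb and profile
log-likelihood n ln λ̂ − n, summed over classes.

## Worked example

```python
from barcodekit import (SimulationConfig, simulate_library, distance_matrix,
                        single_linkage_clusters, concordance,
                        LeaveOneOutIdentifier)

bundle = simulate_library(SimulationConfig(seed=7, n_species=10,
                                           specimens_per_species=3,
                                           n_merges=1))
dm = distance_matrix(bundle.library)
part = single_linkage_clusters(dm, threshold=0.022)
print(f"{len(bundle.library)} specimens, {bundle.library.species_count} species,"
      f" {part.n_clusters} clusters")
print(concordance(part, bundle.library)["counts"])

labels = dict(zip(bundle.library.ids, bundle.library.species_labels))
est = LeaveOneOutIdentifier(criterion="bcm", threshold="auto").fit(dm, labels)
r = est.report_
print(f"best close match @ t={est.threshold_}: "
      f"{r.success_rate:.1%} ({r.correct}/{r.n_evaluated} correct, "
      f"{r.ambiguous} ambiguous, {r.incorrect} incorrect, {r.no_id} no ID)")
```

prints

```
30 specimens, 10 species, 9 clusters
{'perfect_match': 8, 'split': 0, 'merge': 1, 'mixed': 0}
best close match @ t=0.007: 83.3% (25/30 correct, 0 ambiguous, 4 incorrect, 1 no ID)
```

Ten nominal species collapse into nine clusters because one injected merge
pair shares near-identical haplotypes; concordance reports exactly that one
merge. The merged pair is also what drags identification below 100%: its
specimens find equally close heterospecific neighbours, so a few are
scored incorrect, and the optimiser settles on a 0.007 threshold.

The same stages are scriptable from the shell:

```sh
barcodekit simulate --seed 7 --out run/
barcodekit distmat --fasta run/library.fasta --meta run/metadata.tsv --out run/d.tsv
barcodekit delimit --distances run/d.tsv --method sl --threshold 0.022 --out run/part.tsv
barcodekit evaluate --distances run/d.tsv --meta run/metadata.tsv --criterion bcm
barcodekit pipeline --config config.yaml --seed 7 --out run/
```

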