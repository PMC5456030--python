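"""Ecotag-style LCA taxonomic assignment for short-marker queries.

For a query against a reference library the assigner first finds the
*primary* references — those with the highest raw similarity ``S`` to the
query, where similarity is longest-common-subsequence length divided by the
longer sequence length. It then collects the *secondary* references: every
reference at least as similar to some primary reference as the primary is
to the query. The query is assigned to the most recent common ancestor
(MRCA) of the species of all primary and secondary references in the
taxonomy, trading rank specificity for reliability: uncertainty between
congeners yields a genus-level call rather than a species-level guess.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .distances import lcs_similarity
from .records import RANKS, ReferenceLibrary

__all__ = ["Taxonomy", "Assignment", "lca_assign", "batch_assign", "LCAAssigner"]

MIN_QUERY_LENGTH = 50
DEFAULT_MIN_SIMILARITY = 0.70

_RANK_ORDER = {rank: i for i, rank in enumerate(RANKS)}


class Taxonomy:
    """Rank ladder mapping each species label to its ordered lineage.

    Lineages are (rank, taxon) tuples ordered subfamily > tribe > genus >
    subgenus > species; ranks must be strictly ordered along every lineage
    and every species maps to exactly one leaf.
    """

    def __init__(self, lineages: dict[str, tuple[tuple[str, str], ...]]):
        self.lineages = {}
        for species, lineage in lineages.items():
            lineage = tuple(lineage)
            order = [_RANK_ORDER[r] for r, _ in lineage]
            if any(r not in _RANK_ORDER for r, _ in lineage):
                bad = [r for r, _ in lineage if r not in _RANK_ORDER]
                raise ValueError(f"{species}: unknown ranks {bad}")
            if order != sorted(set(order)):
                raise ValueError(f"{species}: ranks not strictly ordered in lineage")
            if not lineage or lineage[-1] != ("species", species):
                lineage = lineage + (("species", species),)
            self.lineages[species] = lineage

    @classmethod
    def from_library(cls, library: ReferenceLibrary) -> "Taxonomy":
        lineages = {}
        for rec in library.records:
            lineage = rec.lineage or (("species", rec.species_label),)
            prev = lineages.get(rec.species_label)
            if prev is not None and prev != tuple(lineage):
                raise ValueError(
                    f"species {rec.species_label!r} has conflicting lineages"
                )
            lineages[rec.species_label] = tuple(lineage)
        return cls(lineages)

    def lineage_of(self, species: str):
        try:
            return self.lineages[species]
        except KeyError:
            raise KeyError(f"taxonomy is missing species {species!r}") from None

    def mrca(self, species_set) -> tuple[str, str]:
        """(rank, taxon) of the most recent common ancestor; ("root", "all")
        when the species share no named taxon."""
        species_set = sorted(set(species_set))
        if not species_set:
            raise ValueError("mrca of an empty species set")
        common = list(self.lineage_of(species_set[0]))
        for sp in species_set[1:]:
            lineage = self.lineage_of(sp)
            k = 0
            while k < min(len(common), len(lineage)) and common[k] == lineage[k]:
                k += 1
            common = common[:k]
        if not common:
            return ("root", "all")
        return common[-1]

    def is_ancestor_or_self(self, taxon: tuple[str, str], species: str) -> bool:
        if taxon == ("root", "all"):
            return True
        return taxon in self.lineage_of(species)


@dataclass(frozen=True)
class Assignment:
    query_id: str
    assigned_taxon: str | None
    assigned_rank: str | None
    similarity: float
    primary_ids: tuple[str, ...]
    secondary_ids: tuple[str, ...]

    @property
    def assigned(self) -> bool:
        return self.assigned_taxon is not None


class LCAAssigner(BaseEstimator):
    """Similarity-based LCA assigner over a reference library.

    Parameters
    ----------
    min_similarity : float, default 0.70
        Queries whose best similarity falls below this are left unassigned.
    min_query_length : int, default 50

    Attributes
    ----------
    taxonomy_ : Taxonomy
    ref_similarity_ : ndarray
        Cached pairwise LCS similarity among references (needed for the
        secondary-reference rule).
    """

    def __init__(self, min_similarity: float = DEFAULT_MIN_SIMILARITY,
                 min_query_length: int = MIN_QUERY_LENGTH):
        self.min_similarity = min_similarity
        self.min_query_length = min_query_length

    def fit(self, X: ReferenceLibrary, y=None, taxonomy: Taxonomy | None = None):
        self.library_ = X
        self.taxonomy_ = taxonomy or Taxonomy.from_library(X)
        for rec in X.records:
            self.taxonomy_.lineage_of(rec.species_label)  # error names the species
        seqs = [rec.sequence.replace("-", "") for rec in X.records]
        n = len(seqs)
        sims = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                sims[i, j] = sims[j, i] = lcs_similarity(seqs[i], seqs[j])
        self.ref_seqs_ = seqs
        self.ref_similarity_ = sims
        return self

    def assign(self, query_id: str, query_seq: str,
               exclude: set[str] | None = None) -> Assignment:
        query_seq = query_seq.replace("-", "").upper()
        if len(query_seq) < self.min_query_length:
            raise ValueError(
                f"query {query_id}: length {len(query_seq)} below the "
                f"{self.min_query_length} nt floor"
            )
        lib = self.library_
        keep = [k for k, rec in enumerate(lib.records)
                if not exclude or rec.specimen_id not in exclude]
        if not keep:
            raise ValueError("no reference sequences left after exclusion")
        sims = np.array([lcs_similarity(query_seq, self.ref_seqs_[k]) for k in keep])
        S = float(sims.max())
        if S < self.min_similarity:
            return Assignment(query_id, None, None, S, (), ())
        primary = [keep[k] for k in np.where(sims == S)[0]]
        secondary = {
            r
            for p in primary
            for r in keep
            if self.ref_similarity_[r, p] >= S
        }
        species = {lib.records[k].species_label for k in set(primary) | secondary}
        rank, taxon = self.taxonomy_.mrca(species)
        return Assignment(
            query_id,
            taxon,
            rank,
            S,
            tuple(lib.records[k].specimen_id for k in primary),
            tuple(sorted(lib.records[k].specimen_id for k in secondary)),
        )

    def predict(self, queries) -> list[Assignment]:
        """Assign an iterable of (query_id, sequence) pairs."""
        return [self.assign(qid, seq) for qid, seq in queries]


def lca_assign(query_id: str, query_seq: str, library: ReferenceLibrary,
               taxonomy: Taxonomy | None = None,
               min_similarity: float = DEFAULT_MIN_SIMILARITY) -> Assignment:
    """One-shot LCA assignment of a single query sequence."""
    est = LCAAssigner(min_similarity=min_similarity).fit(library, taxonomy=taxonomy)
    return est.assign(query_id, query_seq)


def batch_assign(library: ReferenceLibrary, taxonomy: Taxonomy | None = None,
                 queries=None, leave_one_out: bool = False,
                 min_similarity: float = DEFAULT_MIN_SIMILARITY):
    """Assign many queries; returns (assignments, summary).

    In leave-one-out mode each library specimen is queried against the
    library minus itself and scored correct when the assigned taxon is an
    ancestor-or-self of the specimen's true species. The summary gives
    per-rank resolution counts (summing to the number of queries) and,
    in leave-one-out mode, the correct fraction.
    """
    est = LCAAssigner(min_similarity=min_similarity).fit(library, taxonomy=taxonomy)
    assignments: list[Assignment] = []
    correct_flags: list[bool] = []
    if leave_one_out:
        for rec in library.records:
            a = est.assign(rec.specimen_id, rec.sequence, exclude={rec.specimen_id})
            assignments.append(a)
            correct_flags.append(
                a.assigned
                and est.taxonomy_.is_ancestor_or_self(
                    (a.assigned_rank, a.assigned_taxon), rec.species_label
                )
            )
    else:
        if queries is None:
            raise ValueError("provide queries or set leave_one_out=True")
        assignments = est.predict(queries)
    rank_counts: dict[str, int] = {}
    for a in assignments:
        rank_counts[a.assigned_rank or "unassigned"] = (
            rank_counts.get(a.assigned_rank or "unassigned", 0) + 1
        )
    summary = {"n_queries": len(assignments), "rank_counts": rank_counts}
    if leave_one_out:
        summary["n_correct"] = sum(correct_flags)
        summary["correct_fraction"] = (
            sum(correct_flags) / len(correct_flags) if correct_flags else float("nan")
        )
    return assignments, summary
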