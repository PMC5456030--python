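"""Distance-based molecular species delimitation.

The primary delimiter is threshold single-linkage clustering: specimens are
grouped into the connected components of the graph whose edges join pairs at
distance <= threshold (default 0.022, the conventional 2.2% divergence
threshold for COI barcodes). An optional refinement step reruns standard
Markov clustering (MCL) inside each initial cluster, which can split
heterogeneous clusters but never merges across them. The refinement is a
simplified, clearly local stand-in for database-wide BIN refinement: the
clusters it produces are "BIN-like" for the library at hand, not registry
BIN identifiers.

Concordance against nominal species labels classifies each species as a
perfect match (one pure cluster), a split (several pure clusters), part of
a merge (a cluster pooling several species, each confined to it), or mixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, ClusterMixin

from .distances import DistanceMatrix
from .records import ReferenceLibrary

__all__ = [
    "Partition",
    "single_linkage_clusters",
    "mcl_refine",
    "concordance",
    "SingleLinkageDelimiter",
]

DEFAULT_THRESHOLD = 0.022


@dataclass(frozen=True)
class Partition:
    """Specimen -> cluster assignment with canonical contiguous cluster IDs.

    Cluster IDs are renumbered 0, 1, ... by first-seen specimen order, so two
    partitions are equal iff they group identically.
    """

    ids: tuple[str, ...]
    labels: tuple[int, ...]
    method: str = "SL"

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.labels):
            raise ValueError("ids and labels differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate specimen ids in partition")
        object.__setattr__(self, "labels", canonicalize(self.labels))

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels))

    @property
    def assignment(self) -> dict[str, int]:
        return dict(zip(self.ids, self.labels))

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for sid, lab in zip(self.ids, self.labels):
            out.setdefault(lab, []).append(sid)
        return out

    def same_grouping(self, other: "Partition") -> bool:
        if set(self.ids) != set(other.ids):
            return False
        theirs = other.assignment
        reordered = canonicalize([theirs[i] for i in self.ids])
        return reordered == self.labels

    def refines(self, other: "Partition") -> bool:
        """True when every cluster of self lies inside one cluster of other."""
        theirs = other.assignment
        coarse_of: dict[int, int] = {}
        for sid, lab in zip(self.ids, self.labels):
            if lab in coarse_of and coarse_of[lab] != theirs[sid]:
                return False
            coarse_of[lab] = theirs[sid]
        return True

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("specimen_id\tcluster_id\n")
            for sid, lab in zip(self.ids, self.labels):
                fh.write(f"{sid}\t{lab}\n")

    @classmethod
    def from_labels(cls, ids, labels, method: str = "TRUTH") -> "Partition":
        # labels may be arbitrary hashables (e.g. species names)
        seen: dict[object, int] = {}
        numeric = [seen.setdefault(l, len(seen)) for l in labels]
        return cls(tuple(ids), tuple(numeric), method=method)


def canonicalize(labels) -> tuple[int, ...]:
    seen: dict[object, int] = {}
    return tuple(seen.setdefault(l, len(seen)) for l in labels)


def single_linkage_clusters(
    dm: DistanceMatrix, threshold: float = DEFAULT_THRESHOLD
) -> Partition:
    """Connected components of the <=threshold graph; masked pairs add no edge."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if len(dm) == 0:
        raise ValueError("empty distance matrix")
    adj = (dm.values <= threshold) & ~dm.mask
    np.fill_diagonal(adj, True)
    _, comp = connected_components(csr_matrix(adj), directed=False)
    return Partition(dm.ids, tuple(int(c) for c in comp), method="SL")


def _mcl(sim: np.ndarray, inflation: float, tol: float = 1e-8, max_iter: int = 100):
    """Markov clustering on a similarity matrix; returns cluster labels."""
    M = sim.astype(float).copy()
    colsum = M.sum(axis=0)
    colsum[colsum == 0] = 1.0
    M /= colsum
    for _ in range(max_iter):
        expanded = M @ M
        inflated = expanded**inflation
        colsum = inflated.sum(axis=0)
        colsum[colsum == 0] = 1.0
        inflated /= colsum
        if np.abs(inflated - M).max() < tol:
            M = inflated
            break
        M = inflated
    # attractors are rows with positive diagonal mass; each column joins the
    # first attractor row giving it positive mass
    n = M.shape[0]
    attractors = [i for i in range(n) if M[i, i] > tol]
    labels = np.full(n, -1, dtype=int)
    for rank, a in enumerate(attractors):
        members = np.where(M[a] > tol)[0]
        for m in members:
            if labels[m] == -1:
                labels[m] = rank
    for j in range(n):  # isolated / numerically dead columns stay alone
        if labels[j] == -1:
            labels[j] = labels.max() + 1
    return labels


def mcl_refine(
    dm: DistanceMatrix,
    partition: Partition,
    threshold: float = DEFAULT_THRESHOLD,
    inflation: float = 2.0,
) -> Partition:
    """Markov-clustering refinement inside each single-linkage cluster.

    Within every initial cluster of size >= 4, MCL (expansion 2, the given
    inflation) is run on the similarity graph s(i, j) = max(0, threshold -
    d(i, j)) normalised column-stochastic. Clusters may split, never merge:
    the result always refines the input partition. Smaller clusters pass
    through unchanged.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    index = {sid: k for k, sid in enumerate(dm.ids)}
    new_labels: dict[str, tuple[int, int]] = {}
    for lab, members in partition.clusters().items():
        if len(members) < 4:
            for sid in members:
                new_labels[sid] = (lab, 0)
            continue
        idx = [index[sid] for sid in members]
        sub = dm.values[np.ix_(idx, idx)].copy()
        sub[dm.mask[np.ix_(idx, idx)]] = np.inf
        sim = np.maximum(0.0, threshold - sub)
        sim[~np.isfinite(sub)] = 0.0
        np.fill_diagonal(sim, threshold)
        sub_labels = _mcl(sim, inflation)
        for sid, sl in zip(members, sub_labels):
            new_labels[sid] = (lab, int(sl))
    pairs = [new_labels[sid] for sid in partition.ids]
    return Partition(partition.ids, canonicalize(pairs), method="SL+MCL")


def concordance(partition: Partition, library_or_labels) -> dict:
    """Classify nominal species against a molecular partition.

    Per species: *match* (confined to one cluster that contains it alone),
    *split* (spans >= 2 clusters, each containing it alone), *merge* (part
    of a cluster pooling >= 2 species, each confined to that cluster),
    *mixed* (anything else). Totals count matches/splits/mixed per species
    and merges once per merged cluster.
    """
    if isinstance(library_or_labels, ReferenceLibrary):
        species = dict(zip(library_or_labels.ids, library_or_labels.species_labels))
    else:
        species = dict(library_or_labels)
    if set(species) != set(partition.ids):
        raise ValueError("partition and species labels cover different specimens")

    clusters_of: dict[str, set[int]] = {}
    species_in: dict[int, set[str]] = {}
    for sid, lab in zip(partition.ids, partition.labels):
        sp = species[sid]
        clusters_of.setdefault(sp, set()).add(lab)
        species_in.setdefault(lab, set()).add(sp)

    detail: dict[str, str] = {}
    for sp, clus in clusters_of.items():
        pure = all(len(species_in[c]) == 1 for c in clus)
        if len(clus) == 1:
            c = next(iter(clus))
            if pure:
                detail[sp] = "match"
            elif all(len(clusters_of[s]) == 1 for s in species_in[c]):
                detail[sp] = "merge"
            else:
                detail[sp] = "mixed"
        else:
            detail[sp] = "split" if pure else "mixed"

    merged_clusters = [
        c
        for c, sps in species_in.items()
        if len(sps) >= 2 and all(len(clusters_of[s]) == 1 for s in sps)
    ]
    counts = {
        "perfect_match": sum(v == "match" for v in detail.values()),
        "split": sum(v == "split" for v in detail.values()),
        "merge": len(merged_clusters),
        "mixed": sum(v == "mixed" for v in detail.values()),
    }
    return {"counts": counts, "per_species": detail}


class SingleLinkageDelimiter(ClusterMixin, BaseEstimator):
    """Threshold single-linkage delimiter with optional MCL refinement.

    Parameters
    ----------
    threshold : float, default 0.022
        Maximum distance joining two specimens into one cluster.
    refine : bool, default False
        Run Markov clustering within each initial cluster.
    inflation : float, default 2.0
        MCL inflation (> 1); larger values split more aggressively.

    Attributes
    ----------
    labels_ : ndarray of int
        Cluster label per specimen, canonical order.
    partition_ : Partition
    n_clusters_ : int
    """

    def __init__(self, threshold: float = DEFAULT_THRESHOLD, refine: bool = False,
                 inflation: float = 2.0):
        self.threshold = threshold
        self.refine = refine
        self.inflation = inflation

    def fit(self, X, y=None):
        dm = X if isinstance(X, DistanceMatrix) else DistanceMatrix(
            tuple(str(i) for i in range(len(X))), np.asarray(X, dtype=float)
        )
        part = single_linkage_clusters(dm, self.threshold)
        if self.refine:
            part = mcl_refine(dm, part, threshold=self.threshold,
                              inflation=self.inflation)
        self.partition_ = part
        self.labels_ = np.asarray(part.labels)
        self.n_clusters_ = part.n_clusters
        return self
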