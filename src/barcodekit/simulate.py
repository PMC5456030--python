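"""Synthetic barcode reference libraries with known ground truth.

The generator emulates the structure of a multi-species barcode library: a
Yule (pure-birth) species tree, shallow within-species variation (star or
coalescent genealogy), sequences evolved under the Kimura two-parameter
substitution model, and injectable pathologies — singleton species, cryptic
splits (one nominal label spanning two deeply diverged clades) and merges
(two nominal labels sharing one shallow clade of near-identical
haplotypes).

Divergence control: branch lengths are in expected substitutions/site. The
species tree is rescaled so the *mean* between-species tip-pair distance
equals ``inter_depth``, and every species clade receives a stem extension
so that no between-species path falls below ``0.6 * inter_depth``. The
floor makes the barcode gap a controlled property of the library rather
than a lucky draw — gap control is what threshold-based delimitation and
identification are sensitive to. Within a species the expected pairwise
distance is ``intra_depth``.

All randomness flows from the single config seed through one numpy
generator, so a config reproduces its library byte for byte.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .cluster import Partition
from .distances import distance_matrix
from .records import ReferenceLibrary, SpecimenRecord
from .trees import tree_from_newick

__all__ = ["SimulationConfig", "TruthBundle", "simulate_library", "empirical_gap"]

#: minimum between-species divergence, as a fraction of inter_depth
GAP_FLOOR = 0.6


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic library.

    ``specimens_per_species`` is a fixed count or a per-species sequence;
    the last ``n_singletons`` species are forced to one specimen.
    ``kappa`` is the transition/transversion *rate* ratio (alpha/beta) of
    the K2P generator; ``model="jc69"`` ignores it and uses equal rates.
    ``seq_length`` defaults to the full-length COI barcode (658 nt); use
    216 for a 16S-like short marker.
    """

    seed: int
    n_species: int = 20
    specimens_per_species: int | tuple[int, ...] = 4
    seq_length: int = 658
    marker: str = "COI"
    kappa: float = 3.0
    intra_depth: float = 0.005
    inter_depth: float = 0.08
    n_singletons: int = 0
    n_cryptic_splits: int = 0
    n_merges: int = 0
    model: str = "k2p"
    within: str = "star"

    def counts(self) -> list[int]:
        if isinstance(self.specimens_per_species, int):
            counts = [self.specimens_per_species] * self.n_species
        else:
            counts = list(self.specimens_per_species)
            if len(counts) != self.n_species:
                raise ValueError("specimens_per_species length != n_species")
        for k in range(self.n_singletons):
            counts[self.n_species - 1 - k] = 1
        if min(counts) < 1:
            raise ValueError("every species needs >= 1 specimen")
        return counts

    def validate(self) -> None:
        if self.n_species < 1 or self.seq_length < 1:
            raise ValueError("n_species and seq_length must be positive")
        if min(self.n_singletons, self.n_cryptic_splits, self.n_merges) < 0:
            raise ValueError("pathology counts must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.model not in ("k2p", "jc69"):
            raise ValueError(f"unknown substitution model {self.model!r}")
        if self.within not in ("star", "coalescent"):
            raise ValueError(f"unknown within-species genealogy {self.within!r}")
        if 2 * self.n_merges + self.n_cryptic_splits + self.n_singletons > self.n_species:
            raise ValueError(
                "merge pairs, splits and singletons exceed the number of species"
            )
        counts = self.counts()
        for k in range(self.n_cryptic_splits):
            if counts[2 * self.n_merges + k] < 2:
                raise ValueError("a cryptic-split species needs >= 2 specimens")


@dataclass
class TruthBundle:
    """A simulated library plus its ground truth."""

    library: ReferenceLibrary
    true_partition: Partition
    true_tree: "object"  # dendropy.Tree
    events: list[dict] = field(default_factory=list)
    config: SimulationConfig | None = None


# --- tree shapes --------------------------------------------------------


def _yule_newick(n_tips: int, rng) -> str:
    """Ultrametric pure-birth tree in newick over tips C0..C{n-1}."""
    if n_tips == 1:
        return "C0:0.0"
    birth = {0: 0.0}
    children: dict[int, tuple[int, int]] = {}
    active = [0]
    next_id = 1
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        parent = active[k]
        c1, c2 = next_id, next_id + 1
        next_id += 2
        birth[c1] = birth[c2] = t
        children[parent] = (c1, c2)
        active[k] = c1
        active.append(c2)
    t_end = t + rng.exponential(1.0 / n_tips)  # terminal branch stretch
    tip_name = {node: f"C{i}" for i, node in enumerate(active)}

    def render(node: int) -> str:
        if node in children:
            c1, c2 = children[node]
            inner = f"({render(c1)},{render(c2)})"
            depth = birth[children[node][0]]
        else:
            inner = tip_name[node]
            depth = t_end
        return f"{inner}:{depth - birth[node]:.10f}"

    c1, c2 = children[0]
    return f"({render(c1)},{render(c2)})"


def _star_newick(sids: list[str], depth: float) -> str:
    if len(sids) == 1:
        return sids[0]
    return "(" + ",".join(f"{s}:{depth:.10f}" for s in sids) + ")"


def _coalescent_newick(sids: list[str], intra_depth: float, rng) -> str:
    """Kingman genealogy scaled so the expected pairwise distance is
    intra_depth (a random pair coalesces at mean 1 coalescent unit)."""
    if len(sids) == 1:
        return sids[0]
    scale = intra_depth / 2.0  # distance per coalescent time unit, per lineage
    nodes = [(s, 0.0) for s in sids]
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (na, ha), (nb, hb) = nodes[i], nodes[j]
        merged = (
            f"({na}:{(t - ha) * scale:.10f},{nb}:{(t - hb) * scale:.10f})",
            t,
        )
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)]
        nodes.append(merged)
    return nodes[0][0]


def _replace_tip(newick: str, tip: str, replacement: str) -> str:
    pattern = re.compile(rf"(?<![\w]){re.escape(tip)}(?=[:,\)])")
    out, n = pattern.subn(lambda _: replacement, newick)
    if n != 1:
        raise ValueError(f"tip {tip} matched {n} times in newick")
    return out


# --- sequence evolution -------------------------------------------------


def _rates(config: SimulationConfig) -> tuple[float, float]:
    if config.model == "jc69":
        return 1.0 / 3.0, 1.0 / 3.0
    beta = 1.0 / (config.kappa + 2.0)
    return config.kappa * beta, beta


def evolve_sequence(codes: np.ndarray, branch_length: float,
                    alpha: float, beta: float, rng) -> np.ndarray:
    """One K2P step along a branch (length in expected substitutions/site).

    ``alpha`` is the transition rate, ``beta`` the rate of each of the two
    transversion targets, normalised so alpha + 2*beta = 1.
    """
    d = max(0.0, branch_length)
    e_ts = np.exp(-4.0 * beta * d)
    e_all = np.exp(-2.0 * (alpha + beta) * d)
    p_ts = 0.25 + 0.25 * e_ts - 0.5 * e_all
    p_tv = 0.25 - 0.25 * e_ts  # each of the two transversion targets
    u = rng.random(codes.size)
    out = codes.copy()
    ts = u < p_ts
    out[ts] = codes[ts] ^ 2  # other base of the same purine/pyrimidine class
    tv1 = (u >= p_ts) & (u < p_ts + p_tv)
    tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    out[tv1] = codes[tv1] ^ 1
    out[tv2] = codes[tv2] ^ 3
    return out


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


# --- main entry ---------------------------------------------------------


def simulate_library(config: SimulationConfig) -> TruthBundle:
    """Simulate a reference library with ground-truth partition and tree."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = config.counts()
    n_sp = config.n_species
    n_mg, n_cs = config.n_merges, config.n_cryptic_splits

    # role layout: merge pairs first, then split species, singletons last
    merge_pairs = [(2 * k, 2 * k + 1) for k in range(n_mg)]
    split_species = list(range(2 * n_mg, 2 * n_mg + n_cs))
    singleton_species = set(range(n_sp - config.n_singletons, n_sp))

    def label(sp: int) -> str:
        return f"Gen{sp // 4:02d}_sp{sp:02d}"

    def lineage(sp: int):
        genus = f"Gen{sp // 4:02d}"
        tribe = f"Tribe{sp // 8:02d}"
        subfam = "Subfam" + ("A" if (sp // 8) % 2 == 0 else "B")
        return (
            ("subfamily", subfam),
            ("tribe", tribe),
            ("genus", genus),
            ("species", label(sp)),
        )

    # true clusters: one per species, shared by merge pairs, two per split
    clusters: list[list[tuple[int, int]]] = []  # cluster -> [(species, n)]
    events: list[dict] = []
    for a, b in merge_pairs:
        clusters.append([(a, counts[a]), (b, counts[b])])
        events.append({"type": "merge", "species": [label(a), label(b)],
                       "clusters": [len(clusters) - 1]})
    for sp in split_species:
        n1 = counts[sp] - counts[sp] // 2
        n2 = counts[sp] // 2
        clusters.append([(sp, n1)])
        clusters.append([(sp, n2)])
        events.append({"type": "split", "species": [label(sp)],
                       "clusters": [len(clusters) - 2, len(clusters) - 1]})
    taken = {s for pair in merge_pairs for s in pair} | set(split_species)
    for sp in range(n_sp):
        if sp in taken:
            continue
        clusters.append([(sp, counts[sp])])
        if sp in singleton_species:
            events.append({"type": "singleton", "species": [label(sp)],
                           "clusters": [len(clusters) - 1]})
    n_clusters = len(clusters)

    # cluster-level Yule tree, rescaled to the target mean divergence with
    # a stem extension enforcing the divergence floor
    if n_clusters > 1:
        cluster_tree = tree_from_newick(f"{_yule_newick(n_clusters, rng)};")
        pdm = cluster_tree.phylogenetic_distance_matrix()
        taxa = sorted(cluster_tree.taxon_namespace, key=lambda x: x.label)
        dists = [
            pdm.distance(taxa[i], taxa[j])
            for i in range(len(taxa))
            for j in range(i + 1, len(taxa))
        ]
        mean_d = float(np.mean(dists))
        scale = (1.0 - GAP_FLOOR) * config.inter_depth / mean_d
        stem = GAP_FLOOR * config.inter_depth / 2.0
        for edge in cluster_tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= scale
        for leaf in cluster_tree.leaf_node_iter():
            leaf.edge.length = (leaf.edge.length or 0.0) + stem
        cluster_newick = cluster_tree.as_string(
            schema="newick", unquoted_underscores=True, suppress_rooting=True
        ).strip().rstrip(";")
    else:
        cluster_newick = "(C0:0.0)"

    # specimen ids, per-cluster subtrees, truth partition bookkeeping
    part_ids: list[str] = []
    part_labels: list[int] = []
    species_of: dict[str, int] = {}
    counter = 0
    full_newick = cluster_newick
    for ci, members in enumerate(clusters):
        sids = []
        for sp, n in members:
            for _ in range(n):
                counter += 1
                sid = f"SIM{counter:04d}"
                sids.append(sid)
                species_of[sid] = sp
                part_ids.append(sid)
                part_labels.append(ci)
        if config.within == "star":
            sub = _star_newick(sids, config.intra_depth / 2.0)
        else:
            sub = _coalescent_newick(sids, config.intra_depth, rng)
        full_newick = _replace_tip(full_newick, f"C{ci}", sub)
    true_tree = tree_from_newick(full_newick + ";")

    # evolve sequences from a uniform-random root down the truth tree
    alpha, beta = _rates(config)
    root_codes = rng.integers(0, 4, size=config.seq_length).astype(np.uint8)
    tip_codes: dict[str, np.ndarray] = {}
    seq_at = {id(true_tree.seed_node): root_codes}
    for node in true_tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_seq = seq_at[id(node.parent_node)]
        seq_at[id(node)] = evolve_sequence(parent_seq, node.edge.length or 0.0,
                                           alpha, beta, rng)
        if node.is_leaf():
            tip_codes[node.taxon.label] = seq_at[id(node)]

    records = tuple(
        SpecimenRecord(
            specimen_id=sid,
            species_label=label(species_of[sid]),
            sequence=_decode(tip_codes[sid]),
            lineage=lineage(species_of[sid]),
            marker=config.marker,
        )
        for sid in part_ids
    )
    library = ReferenceLibrary(records=records, marker=config.marker, aligned=True)
    partition = Partition.from_labels(part_ids, part_labels, method="TRUTH")
    return TruthBundle(library=library, true_partition=partition,
                       true_tree=true_tree, events=events, config=config)


def empirical_gap(bundle: TruthBundle) -> dict:
    """Max intraspecific, min interspecific K2P distance and their gap.

    Computed on nominal species labels from the library's K2P matrix.
    ``max_intra`` is None (undefined) when no within-species pair exists.
    """
    lib = bundle.library
    if lib.species_count < 2:
        raise ValueError("empirical_gap needs >= 2 species")
    dm = distance_matrix(lib)
    labels = np.array(lib.species_labels)
    same = labels[:, None] == labels[None, :]
    triu = np.triu(np.ones_like(same, dtype=bool), k=1)
    defined = ~dm.mask
    intra = dm.values[same & triu & defined]
    inter = dm.values[~same & triu & defined]
    max_intra = float(intra.max()) if intra.size else None
    min_inter = float(inter.min()) if inter.size else None
    gap = (min_inter - max_intra) if (intra.size and inter.size) else None
    return {"max_intra": max_intra, "min_inter": min_inter, "gap": gap}
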