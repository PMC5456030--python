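"""Poisson Tree Process (PTP) species delimitation.

PTP classifies the branches of a rooted phylogram into two Poisson
processes: *speciation* branches (between species) and *coalescent*
branches (within species), each with its own exponential rate. A candidate
delimitation is a set of *species roots* — a cut through the tree such that
every tip lies under exactly one species root. Branches strictly below a
species root belong to the coalescent class; the branch entering a species
root, and every branch above the cut, belong to the speciation class.

For a class with ``n`` branches of total length ``B`` the rate MLE is
``lambda = n / B`` and the profile log-likelihood contribution is
``n * ln(n / B) - n``; the model log-likelihood is the sum over the two
classes. The degenerate cuts (everything one species, or every tip its own
species) leave one class empty and reduce to the single-rate null model.

Search modes: exhaustive enumeration of all cuts (small trees), greedy
splitting from the null model, and Metropolis-Hastings MCMC over cuts
(uniform prior) yielding per-node posterior support values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy
import numpy as np
from sklearn.base import BaseEstimator

from .cluster import Partition

__all__ = [
    "PtpModel",
    "PoissonTreeProcess",
    "ptp_likelihood",
    "ptp_search",
    "ptp_mcmc_support",
    "exhaustive_posterior",
]

MIN_BRANCH = 1e-9


@dataclass(frozen=True)
class PtpModel:
    """A fitted two-process branch classification.

    ``species_roots`` holds one frozenset of tip labels per species (the
    clade under each species root). Rates are ``None`` when the matching
    class is empty (degenerate single-class model).
    """

    species_roots: tuple[frozenset[str], ...]
    rate_speciation: float | None
    rate_coalescent: float | None
    log_likelihood: float

    @property
    def n_species(self) -> int:
        return len(self.species_roots)


class _TreeData:
    """Indexed view of a dendropy tree for fast cut arithmetic.

    Nodes are indexed in preorder. For each node we precompute the number
    and total length of edges *strictly below* it, so the two-class branch
    sums of any cut are O(|cut|) and the log-likelihood O(1) from there.
    """

    def __init__(self, tree: dendropy.Tree, min_branch: float = MIN_BRANCH):
        self.nodes = list(tree.preorder_node_iter())
        self.index = {id(nd): i for i, nd in enumerate(self.nodes)}
        n = len(self.nodes)
        self.parent = np.full(n, -1, dtype=int)
        self.children: list[list[int]] = [[] for _ in range(n)]
        self.edge_len = np.zeros(n)
        self.is_tip = np.zeros(n, dtype=bool)
        self.tip_label: list[str | None] = [None] * n
        for i, nd in enumerate(self.nodes):
            if nd.parent_node is not None:
                p = self.index[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                length = nd.edge.length
                if length is None or length <= 0:
                    length = min_branch  # zero/absent lengths raised to epsilon
                self.edge_len[i] = length
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise ValueError("tree has an unlabelled tip")
                self.is_tip[i] = True
                self.tip_label[i] = nd.taxon.label
        self.n_tips = int(self.is_tip.sum())
        # edges strictly below each node (postorder accumulation)
        self.sub_n = np.zeros(n, dtype=int)
        self.sub_b = np.zeros(n)
        for i in range(n - 1, -1, -1):
            for c in self.children[i]:
                self.sub_n[i] += 1 + self.sub_n[c]
                self.sub_b[i] += self.edge_len[c] + self.sub_b[c]
        self.total_n = n - 1
        self.total_b = float(self.edge_len[1:].sum())

    # --- cut arithmetic -------------------------------------------------

    def class_sums(self, cut) -> tuple[int, float, int, float]:
        coal_n = int(sum(self.sub_n[r] for r in cut))
        coal_b = float(sum(self.sub_b[r] for r in cut))
        return self.total_n - coal_n, self.total_b - coal_b, coal_n, coal_b

    def log_likelihood(self, cut) -> float:
        spec_n, spec_b, coal_n, coal_b = self.class_sums(cut)
        return _class_term(spec_n, spec_b) + _class_term(coal_n, coal_b)

    def null_log_likelihood(self) -> float:
        return _class_term(self.total_n, self.total_b)

    def tips_under(self, node: int) -> frozenset[str]:
        stack, out = [node], []
        while stack:
            i = stack.pop()
            if self.is_tip[i]:
                out.append(self.tip_label[i])
            else:
                stack.extend(self.children[i])
        return frozenset(out)

    def enumerate_cuts(self):
        """All valid cuts (antichains covering every tip), as frozensets."""

        def covers(i: int):
            if self.is_tip[i]:
                return [frozenset([i])]
            below = [
                frozenset().union(*combo)
                for combo in itertools.product(*(covers(c) for c in self.children[i]))
            ]
            return [frozenset([i])] + below

        return covers(0)

    def model_from_cut(self, cut) -> PtpModel:
        spec_n, spec_b, coal_n, coal_b = self.class_sums(cut)
        return PtpModel(
            species_roots=tuple(sorted((self.tips_under(r) for r in cut), key=sorted)),
            rate_speciation=spec_n / spec_b if spec_n else None,
            rate_coalescent=coal_n / coal_b if coal_n else None,
            log_likelihood=self.log_likelihood(cut),
        )

    def partition_from_cut(self, cut, method: str = "PTP") -> Partition:
        tips_in_order = [self.tip_label[i] for i in range(len(self.nodes)) if self.is_tip[i]]
        label_of: dict[str, int] = {}
        for k, r in enumerate(sorted(cut)):
            for t in self.tips_under(r):
                label_of[t] = k
        return Partition.from_labels(
            tips_in_order, [label_of[t] for t in tips_in_order], method=method
        )


def _class_term(n: int, b: float) -> float:
    if n == 0:
        return 0.0
    return n * np.log(n / b) - n


def _resolve_cut(data: _TreeData, species_root_set) -> frozenset[int]:
    """Map user-supplied species roots (dendropy nodes) to node indices."""
    cut = set()
    for item in species_root_set:
        if isinstance(item, dendropy.Node):
            cut.add(data.index[id(item)])
        elif isinstance(item, (int, np.integer)):
            cut.add(int(item))
        else:
            raise TypeError(f"cannot interpret species root {item!r}")
    governed = [t for r in cut for t in data.tips_under(r)]
    if len(governed) != data.n_tips or len(governed) != len(set(governed)):
        raise ValueError(
            "species_root_set must cover every tip exactly once (antichain cut)"
        )
    return frozenset(cut)


def ptp_likelihood(tree: dendropy.Tree, species_root_set) -> PtpModel:
    """Evaluate the two-process model for an explicit species-root cut."""
    data = _TreeData(tree)
    return data.model_from_cut(_resolve_cut(data, species_root_set))


class PoissonTreeProcess(BaseEstimator):
    """Single-rate PTP delimiter over a rooted tree.

    Parameters
    ----------
    mode : {"auto", "greedy", "exhaustive"}
        ``auto`` enumerates all cuts when the tree has at most
        ``exhaustive_max_tips`` tips and falls back to greedy search above.
        Greedy search starts from the null (one-species) model and
        repeatedly splits the species root whose replacement by its
        children maximally improves the log-likelihood; ties break toward
        the smallest preorder node index.
    exhaustive_max_tips : int, default 12
    min_branch : float, default 1e-9
        Floor applied to zero-length branches before likelihood evaluation.

    Attributes
    ----------
    model_ : PtpModel
    partition_ : Partition
        Tips grouped by their governing species root.
    null_log_likelihood_ : float
    """

    def __init__(self, mode: str = "auto", exhaustive_max_tips: int = 12,
                 min_branch: float = MIN_BRANCH):
        self.mode = mode
        self.exhaustive_max_tips = exhaustive_max_tips
        self.min_branch = min_branch

    def fit(self, X: dendropy.Tree, y=None):
        data = _TreeData(X, min_branch=self.min_branch)
        if self.mode not in ("auto", "greedy", "exhaustive"):
            raise ValueError(f"unknown mode {self.mode!r}")
        mode = self.mode
        if mode == "auto":
            mode = "exhaustive" if data.n_tips <= self.exhaustive_max_tips else "greedy"
        if mode == "exhaustive":
            if data.n_tips > self.exhaustive_max_tips:
                raise ValueError(
                    f"exhaustive mode limited to {self.exhaustive_max_tips} tips"
                )
            cut = max(data.enumerate_cuts(), key=lambda c: (data.log_likelihood(c),))
        else:
            cut = self._greedy(data)
        self._data = data
        self.cut_ = cut
        self.model_ = data.model_from_cut(cut)
        self.partition_ = data.partition_from_cut(cut)
        self.null_log_likelihood_ = data.null_log_likelihood()
        return self

    @staticmethod
    def _greedy(data: _TreeData) -> frozenset[int]:
        """Hill-climb from both ends of the cut lattice, keep the better.

        Top-down starts at the one-species cut and repeatedly splits the
        species root whose replacement by its children maximally improves
        the log-likelihood; bottom-up starts at the every-tip-a-species cut
        and repeatedly merges the best full sibling group. Single-direction
        hill climbing stalls on trees where the improvement from a split
        only materialises several levels deeper, so both directions are
        explored. Ties break toward the smallest preorder node index.
        """
        def _term2(coal_n: int, coal_b: float) -> float:
            return _class_term(data.total_n - coal_n, data.total_b - coal_b) \
                + _class_term(coal_n, coal_b)

        def climb(cut: set[int], direction: str) -> tuple[frozenset[int], float]:
            coal_n = sum(int(data.sub_n[r]) for r in cut)
            coal_b = sum(float(data.sub_b[r]) for r in cut)
            best = _term2(coal_n, coal_b)
            while True:
                improvement, choice, delta = 0.0, None, (0, 0.0)
                if direction == "split":
                    cands = [r for r in sorted(cut) if not data.is_tip[r]]
                    for r in cands:
                        dn = sum(int(data.sub_n[c]) for c in data.children[r]) \
                            - int(data.sub_n[r])
                        db = sum(float(data.sub_b[c]) for c in data.children[r]) \
                            - float(data.sub_b[r])
                        ll = _term2(coal_n + dn, coal_b + db)
                        if ll - best > improvement + 1e-12:
                            improvement, delta = ll - best, (dn, db)
                            choice = (r, data.children[r])
                else:
                    parents = sorted({int(data.parent[r]) for r in cut
                                      if data.parent[r] >= 0})
                    cands = [p for p in parents
                             if all(c in cut for c in data.children[p])]
                    for p in cands:
                        dn = int(data.sub_n[p]) \
                            - sum(int(data.sub_n[c]) for c in data.children[p])
                        db = float(data.sub_b[p]) \
                            - sum(float(data.sub_b[c]) for c in data.children[p])
                        ll = _term2(coal_n + dn, coal_b + db)
                        if ll - best > improvement + 1e-12:
                            improvement, delta = ll - best, (dn, db)
                            choice = (p, data.children[p])
                if choice is None:
                    return frozenset(cut), best
                node, children = choice
                if direction == "split":
                    cut.discard(node)
                    cut.update(children)
                else:
                    cut.difference_update(children)
                    cut.add(node)
                coal_n += delta[0]
                coal_b += delta[1]
                best += improvement

        top_cut, top_ll = climb({0}, "split")
        tips = {i for i in range(len(data.nodes)) if data.is_tip[i]}
        bot_cut, bot_ll = climb(tips, "merge")
        return top_cut if top_ll >= bot_ll else bot_cut

    def mcmc_support(self, steps: int = 100_000, burnin_fraction: float = 0.2,
                     n_runs: int = 5, seed: int = 0):
        """Posterior support that each node opens a species, by MCMC.

        Metropolis-Hastings over valid cuts with a uniform prior: each step
        proposes, with equal probability, splitting a species root into its
        children or merging a full sibling group back into its parent, with
        candidate-count Hastings corrections. Runs are averaged; the
        convergence diagnostic is the largest across-run spread of any
        node's support.

        Returns ``(support, diagnostic)`` where ``support`` maps the
        frozenset of tip labels under a node to its posterior frequency of
        being a species root.
        """
        if steps < 1000:
            raise ValueError("steps must be >= 1000")
        data = getattr(self, "_data", None)
        if data is None:
            raise RuntimeError("call fit before mcmc_support")
        burnin = int(steps * burnin_fraction)
        n_nodes = len(data.nodes)
        run_support = np.zeros((n_runs, n_nodes))
        for run, ss in enumerate(np.random.SeedSequence(seed).spawn(n_runs)):
            rng = np.random.default_rng(ss)
            counts = _mcmc_run(data, steps, burnin, rng)
            run_support[run] = counts / (steps - burnin)
        mean_support = run_support.mean(axis=0)
        spread = float((run_support.max(axis=0) - run_support.min(axis=0)).max())
        support = {
            data.tips_under(i): float(mean_support[i]) for i in range(n_nodes)
        }
        return support, spread


def _mcmc_run(data: _TreeData, steps: int, burnin: int, rng) -> np.ndarray:
    cut = set([0])
    ll = data.log_likelihood(cut)
    counts = np.zeros(len(data.nodes))

    def split_candidates(c):
        return [r for r in c if not data.is_tip[r]]

    def merge_candidates(c):
        parents = {data.parent[r] for r in c if data.parent[r] >= 0}
        return [p for p in sorted(parents) if all(ch in c for ch in data.children[p])]

    for step in range(steps):
        if rng.random() < 0.5:
            cands = split_candidates(cut)
            if cands:
                r = cands[int(rng.integers(len(cands)))]
                new = (cut - {r}) | set(data.children[r])
                new_ll = data.log_likelihood(new)
                hastings = len(cands) / len(merge_candidates(new))
                if rng.random() < min(1.0, np.exp(new_ll - ll) * hastings):
                    cut, ll = new, new_ll
        else:
            cands = merge_candidates(cut)
            if cands:
                p = cands[int(rng.integers(len(cands)))]
                new = (cut - set(data.children[p])) | {p}
                new_ll = data.log_likelihood(new)
                hastings = len(cands) / len(split_candidates(new))
                if rng.random() < min(1.0, np.exp(new_ll - ll) * hastings):
                    cut, ll = new, new_ll
        if step >= burnin:
            counts[list(cut)] += 1
    return counts


def ptp_search(tree: dendropy.Tree, mode: str = "auto"):
    """Fit PTP and return ``(model, partition)``."""
    est = PoissonTreeProcess(mode=mode).fit(tree)
    return est.model_, est.partition_


def ptp_mcmc_support(tree: dendropy.Tree, steps: int = 100_000,
                     burnin_fraction: float = 0.2, n_runs: int = 5, seed: int = 0):
    """Per-node species-root support from MCMC; see PoissonTreeProcess."""
    est = PoissonTreeProcess().fit(tree)
    return est.mcmc_support(steps=steps, burnin_fraction=burnin_fraction,
                            n_runs=n_runs, seed=seed)


def support_annotated_newick(tree: dendropy.Tree,
                             support: dict[frozenset[str], float]) -> str:
    """Newick string with per-node species-root support as internal labels."""
    annotated = tree.clone(depth=1)
    for node in annotated.preorder_node_iter():
        if node.is_leaf():
            continue
        tips = frozenset(l.taxon.label for l in node.leaf_iter())
        if tips in support:
            node.label = f"{support[tips]:.3f}"
    return annotated.as_string(schema="newick", unquoted_underscores=True,
                               suppress_rooting=True)


def exhaustive_posterior(tree: dendropy.Tree) -> dict[frozenset[str], float]:
    """Exact posterior support per node under a uniform prior over cuts.

    Only feasible for small trees; used to validate the MCMC sampler.
    """
    data = _TreeData(tree)
    cuts = data.enumerate_cuts()
    lls = np.array([data.log_likelihood(c) for c in cuts])
    w = np.exp(lls - lls.max())
    w /= w.sum()
    support = np.zeros(len(data.nodes))
    for weight, cut in zip(w, cuts):
        for r in cut:
            support[r] += weight
    return {data.tips_under(i): float(support[i]) for i in range(len(data.nodes))}
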