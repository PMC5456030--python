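"""Leave-one-out specimen identification against a reference library.

Each specimen whose species label has at least two representatives is used
in turn as a query against the rest of the library (singletons — species
with one specimen — are never queries, but stay on the reference side as
potential mismatches). Three criteria are evaluated on the pairwise
distance matrix:

* **nearest neighbour** ("best match"): the query takes the label(s) of its
  equally-closest specimens — *correct* if all share the query's label,
  *incorrect* if none do, *ambiguous* if mixed;
* **best close match**: as above, but a query whose nearest-neighbour
  distance exceeds a threshold gets *no ID*;
* **threshold ID** ("BOLD ID" / "all species barcode"): the rule is applied
  to *all* specimens within the threshold, not just the closest ones.

The identification threshold can be optimised by minimising, over a grid,
the summed count of false positives (queries with no conspecific within
the threshold) and false negatives (queries with a heterospecific within
it); both can hold for one query. Undefined (masked) distances count as
beyond any threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .distances import DistanceMatrix

__all__ = [
    "QueryOutcome",
    "IdentificationReport",
    "eligible_queries",
    "loo_nearest_neighbour",
    "loo_best_close_match",
    "loo_thresh_id",
    "optimize_threshold",
    "summary_table",
    "LeaveOneOutIdentifier",
    "ThresholdOptimizer",
]

CRITERIA = ("nn", "bcm", "threshid")
CATEGORIES = ("correct", "ambiguous", "incorrect", "no_id")

DEFAULT_GRID = np.round(np.arange(0.001, 0.1005, 0.001), 3)


@dataclass(frozen=True)
class QueryOutcome:
    specimen_id: str
    criterion: str
    category: str
    matched_species: tuple[str, ...]
    nn_distance: float  # nan when every non-self distance is undefined

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "no_id" and self.criterion == "nn":
            raise ValueError("nearest-neighbour identification cannot yield no_id")
        if self.category != "no_id" and not self.matched_species:
            raise ValueError("matched_species empty for an identified query")


@dataclass(frozen=True)
class IdentificationReport:
    """Counts per category for one criterion, shaped like a success table."""

    criterion: str
    level: str
    n_evaluated: int
    correct: int
    ambiguous: int
    incorrect: int
    no_id: int
    threshold: float | None

    def __post_init__(self) -> None:
        total = self.correct + self.ambiguous + self.incorrect + self.no_id
        if total != self.n_evaluated:
            raise ValueError(f"category counts {total} != n_evaluated {self.n_evaluated}")

    @property
    def success_rate(self) -> float:
        return self.correct / self.n_evaluated if self.n_evaluated else float("nan")

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion,
            "level": self.level,
            "n_evaluated": self.n_evaluated,
            "success_rate": self.success_rate,
            "correct": self.correct,
            "ambiguous": self.ambiguous,
            "incorrect": self.incorrect,
            "no_id": self.no_id,
            "threshold": self.threshold,
        }


def _labels_dict(dm: DistanceMatrix, labels) -> dict[str, str]:
    if isinstance(labels, dict):
        out = dict(labels)
    else:
        out = dict(zip(dm.ids, labels))
    missing = [i for i in dm.ids if i not in out]
    if missing:
        raise ValueError(f"labels missing for specimens {missing[:5]}")
    return out


def eligible_queries(labels: dict[str, str] | "pd.Series") -> tuple[list[str], list[str]]:
    """Split specimens into eligible queries and singletons.

    A specimen is an eligible query iff its species label has >= 2
    representatives; singleton-species specimens remain on the reference
    side of every leave-one-out comparison.
    """
    items = labels.items() if hasattr(labels, "items") else labels
    label_of = dict(items)
    counts: dict[str, int] = {}
    for lab in label_of.values():
        counts[lab] = counts.get(lab, 0) + 1
    queries = [sid for sid, lab in label_of.items() if counts[lab] >= 2]
    singletons = [sid for sid, lab in label_of.items() if counts[lab] == 1]
    return queries, singletons


def _category(match_labels: list[str], query_label: str) -> str:
    hits = sum(l == query_label for l in match_labels)
    if hits == len(match_labels):
        return "correct"
    if hits == 0:
        return "incorrect"
    return "ambiguous"


def _evaluate(dm: DistanceMatrix, labels, criterion: str,
              threshold: float | None, fold_ties: bool = False) -> list[QueryOutcome]:
    label_of = _labels_dict(dm, labels)
    queries, _ = eligible_queries({i: label_of[i] for i in dm.ids})
    if not queries:
        raise ValueError(
            "no eligible queries: every species is a singleton, so leave-one-out "
            "identification is undefined"
        )
    eff = dm.effective()
    np.fill_diagonal(eff, np.inf)
    index = {sid: k for k, sid in enumerate(dm.ids)}
    outcomes = []
    for sid in queries:
        row = eff[index[sid]]
        nn = float(row.min())
        if not np.isfinite(nn):
            warnings.warn(
                f"query {sid}: all distances undefined; excluded from evaluation",
                stacklevel=2,
            )
            continue
        if criterion == "threshid":
            within = np.where(row <= threshold)[0]
            if within.size == 0:
                outcomes.append(QueryOutcome(sid, criterion, "no_id", (), nn))
                continue
            match_idx = within
        else:
            if criterion == "bcm" and nn > threshold:
                outcomes.append(QueryOutcome(sid, criterion, "no_id", (), nn))
                continue
            match_idx = np.where(row == nn)[0]
        match_labels = [label_of[dm.ids[k]] for k in match_idx]
        cat = _category(match_labels, label_of[sid])
        if cat == "ambiguous" and fold_ties and criterion == "nn":
            cat = "correct"
        outcomes.append(
            QueryOutcome(sid, criterion, cat, tuple(sorted(set(match_labels))), nn)
        )
    return outcomes


def loo_nearest_neighbour(dm: DistanceMatrix, labels, fold_ties: bool = False):
    """Nearest-neighbour ("best match") outcomes for every eligible query.

    ``fold_ties=True`` reports a mixed tie as correct when at least one of
    the equally-nearest specimens is conspecific (the charitable reading
    used by success tables that show only correct/incorrect for this
    criterion); by default mixed ties stay ambiguous.
    """
    return _evaluate(dm, labels, "nn", threshold=None, fold_ties=fold_ties)


def loo_best_close_match(dm: DistanceMatrix, labels, threshold: float):
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return _evaluate(dm, labels, "bcm", threshold=threshold)


def loo_thresh_id(dm: DistanceMatrix, labels, threshold: float):
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return _evaluate(dm, labels, "threshid", threshold=threshold)


def optimize_threshold(dm: DistanceMatrix, labels, grid=None):
    """Minimise summed false positives + false negatives over a grid.

    For each eligible query and candidate threshold ``t``: a false positive
    is scored when no conspecific lies within ``t``, a false negative when
    at least one heterospecific does (both may hold). Returns
    ``(threshold, curve)`` with the smallest minimising ``t`` and the full
    error curve as a DataFrame.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    label_of = _labels_dict(dm, labels)
    queries, _ = eligible_queries({i: label_of[i] for i in dm.ids})
    eff = dm.effective()
    np.fill_diagonal(eff, np.inf)
    index = {sid: k for k, sid in enumerate(dm.ids)}
    arr = np.array([label_of[i] for i in dm.ids])
    min_con, min_het = [], []
    for sid in queries:
        row = eff[index[sid]]
        same = arr == label_of[sid]
        same[index[sid]] = False
        con = row[same]
        het = row[~same]
        min_con.append(con.min() if con.size else np.inf)
        min_het.append(het.min() if het.size else np.inf)
    min_con = np.asarray(min_con)
    min_het = np.asarray(min_het)
    fp = (min_con[None, :] > grid[:, None]).sum(axis=1)
    fn = (min_het[None, :] <= grid[:, None]).sum(axis=1)
    total = fp + fn
    best = float(grid[int(np.argmin(total))])  # argmin takes the first, smallest t
    curve = pd.DataFrame(
        {"threshold": grid, "false_positive": fp, "false_negative": fn, "total": total}
    )
    return best, curve


def summary_table(outcomes, level: str = "species_label",
                  threshold: float | None = None) -> IdentificationReport:
    """Aggregate per-query outcomes into a success-table row."""
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("no outcomes to summarise")
    criteria = {o.criterion for o in outcomes}
    if len(criteria) != 1:
        raise ValueError(f"outcomes mix criteria {sorted(criteria)}")
    counts = {c: sum(o.category == c for o in outcomes) for c in CATEGORIES}
    return IdentificationReport(
        criterion=criteria.pop(),
        level=level,
        n_evaluated=len(outcomes),
        correct=counts["correct"],
        ambiguous=counts["ambiguous"],
        incorrect=counts["incorrect"],
        no_id=counts["no_id"],
        threshold=threshold,
    )


class LeaveOneOutIdentifier(BaseEstimator):
    """Leave-one-out identification under one criterion.

    Parameters
    ----------
    criterion : {"nn", "bcm", "threshid"}
    threshold : float or "auto", default "auto"
        Distance threshold for the threshold criteria; ``"auto"`` optimises
        it on the library by the FP+FN objective. Ignored for ``"nn"``.
    level : str, default "species_label"
        Name of the label level being evaluated (species labels or cluster
        IDs); recorded in the report.
    fold_ties : bool, default False
        See :func:`loo_nearest_neighbour`.

    Attributes
    ----------
    outcomes_ : list of QueryOutcome
    report_ : IdentificationReport
    threshold_ : float or None
    """

    def __init__(self, criterion: str = "bcm", threshold="auto",
                 level: str = "species_label", fold_ties: bool = False):
        self.criterion = criterion
        self.threshold = threshold
        self.level = level
        self.fold_ties = fold_ties

    def fit(self, X: DistanceMatrix, y):
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.criterion == "nn":
            self.threshold_ = None
            self.outcomes_ = loo_nearest_neighbour(X, y, fold_ties=self.fold_ties)
        else:
            if self.threshold == "auto":
                self.threshold_, self.error_curve_ = optimize_threshold(X, y)
            else:
                self.threshold_ = float(self.threshold)
            fn = loo_best_close_match if self.criterion == "bcm" else loo_thresh_id
            self.outcomes_ = fn(X, y, self.threshold_)
        self.report_ = summary_table(self.outcomes_, level=self.level,
                                     threshold=self.threshold_)
        return self


class ThresholdOptimizer(BaseEstimator):
    """Grid optimiser for the identification threshold (FP+FN objective)."""

    def __init__(self, grid=None):
        self.grid = grid

    def fit(self, X: DistanceMatrix, y):
        self.threshold_, self.error_curve_ = optimize_threshold(X, y, grid=self.grid)
        return self
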