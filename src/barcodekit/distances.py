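"""Pairwise genetic distances and similarities.

Two distance regimes are used for barcode data:

* **Kimura two-parameter (K2P)** corrected distance on a multiple sequence
  alignment, distinguishing transitions (purine<->purine, pyrimidine<->
  pyrimidine) from transversions. With transition and transversion
  proportions ``P`` and ``Q`` over the comparable sites of a pair,

      d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

  Sites where either sequence carries a gap or a non-ACGT symbol are
  excluded pair by pair (pairwise deletion). A pair whose correction
  argument is non-positive (saturation), or with no comparable sites, is
  flagged *undefined* rather than returning NaN; downstream consumers treat
  undefined distances as beyond any threshold.

* **Longest-common-subsequence (LCS) similarity** for short, unaligned
  markers: |LCS(a, b)| / max(|a|, |b|), in [0, 1]. Used by the ecotag-style
  LCA assigner, which works from raw pairwise similarities rather than
  model-corrected distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .records import ReferenceLibrary

__all__ = [
    "DistanceMatrix",
    "k2p_distance",
    "p_distance",
    "distance_matrix",
    "lcs_similarity",
    "lcs_length",
    "encode_sequence",
]

# A, C, G, T -> 0..3; purines get even codes, pyrimidines odd, so a
# substitution is a transition iff the two codes share parity.
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """uint8 codes: A,C,G,T -> 0..3; gaps/ambiguity/N -> 255 (non-comparable)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _site_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(comparable sites, transitions, transversions) under pairwise deletion."""
    ok = (a < 4) & (b < 4)
    aa, bb = a[ok], b[ok]
    diff = aa != bb
    transitions = int(np.count_nonzero(diff & ((aa & 1) == (bb & 1))))
    transversions = int(np.count_nonzero(diff)) - transitions
    return int(ok.sum()), transitions, transversions


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """K2P distance between two aligned sequences; ``nan`` marks undefined.

    Undefined means no comparable site survives pairwise deletion, or the
    pair is saturated (logarithm argument <= 0).
    """
    a, b = encode_sequence(seq_a), encode_sequence(seq_b)
    if a.shape != b.shape:
        raise ValueError("k2p_distance requires equal-length (aligned) sequences")
    n, ts, tv = _site_counts(a, b)
    return _k2p_from_counts(n, ts, tv)


def _k2p_from_counts(n: int, ts: int, tv: int) -> float:
    if n == 0:
        return float("nan")
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return float("nan")
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


def p_distance(seq_a: str, seq_b: str) -> float:
    """Uncorrected proportion of differing comparable sites."""
    a, b = encode_sequence(seq_a), encode_sequence(seq_b)
    if a.shape != b.shape:
        raise ValueError("p_distance requires equal-length (aligned) sequences")
    n, ts, tv = _site_counts(a, b)
    if n == 0:
        return float("nan")
    return (ts + tv) / n


@dataclass
class DistanceMatrix:
    """Square symmetric pairwise distance (or similarity) matrix.

    ``values[i, j]`` holds the metric for specimens ``ids[i]``, ``ids[j]``;
    undefined pairs are ``nan`` with ``mask[i, j]`` True. ``metric`` is one
    of ``"k2p"``, ``"p"``, ``"lcs_sim"``.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    metric: str = "k2p"
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"values shape {self.values.shape} != ({n}, {n})")
        if self.mask is None:
            self.mask = np.isnan(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix is not symmetric")
        if not np.array_equal(self.mask, self.mask.T):
            raise ValueError("distance matrix mask is not symmetric")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def is_similarity(self) -> bool:
        return self.metric == "lcs_sim"

    def index_of(self, specimen_id: str) -> int:
        return self.ids.index(specimen_id)

    def get(self, id_a: str, id_b: str) -> float:
        return float(self.values[self.index_of(id_a), self.index_of(id_b)])

    def effective(self) -> np.ndarray:
        """Values with undefined pairs replaced by +inf (distances) or 0."""
        out = self.values.copy()
        out[self.mask] = 0.0 if self.is_similarity else np.inf
        return out

    def reorder(self, ids: Iterable[str]) -> "DistanceMatrix":
        idx = [self.index_of(i) for i in ids]
        return DistanceMatrix(
            tuple(self.ids[i] for i in idx),
            self.values[np.ix_(idx, idx)],
            metric=self.metric,
            mask=self.mask[np.ix_(idx, idx)],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="specimen_id")

    @classmethod
    def read_tsv(cls, path, metric: str = "k2p") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError(f"{path}: row and column specimen IDs differ")
        return cls(tuple(df.index), df.to_numpy(dtype=float), metric=metric)


def distance_matrix(library: ReferenceLibrary, metric: str = "k2p") -> DistanceMatrix:
    """All-pairs distance matrix over an aligned library.

    Symmetric with a zero diagonal; undefined pairs (pairwise-deleted to
    nothing, or saturated under K2P) are masked, and downstream operations
    honour the mask.
    """
    if metric not in ("k2p", "p"):
        raise ValueError(f"unsupported matrix metric {metric!r}")
    seqs = [r.sequence for r in library.records]
    n = len(seqs)
    if n and len({len(s) for s in seqs}) > 1:
        raise ValueError("distance_matrix requires an aligned (equal-length) library")
    codes = [encode_sequence(s) for s in seqs]
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            nc, ts, tv = _site_counts(codes[i], codes[j])
            if metric == "k2p":
                d = _k2p_from_counts(nc, ts, tv)
            else:
                d = (ts + tv) / nc if nc else float("nan")
            values[i, j] = values[j, i] = d
    return DistanceMatrix(library.ids, values, metric=metric)


def lcs_length(seq_a: str, seq_b: str) -> int:
    """Length of the longest common subsequence.

    Bit-parallel formulation: the DP row is kept as an integer bit vector
    (one bit per position of ``seq_a``) and each column update is a few
    word-wide arithmetic/logic operations, so the quadratic table never
    materialises.
    """
    if not seq_a or not seq_b:
        raise ValueError("lcs_length requires non-empty sequences")
    m = len(seq_a)
    masks: dict[str, int] = {}
    for i, ch in enumerate(seq_a):
        masks[ch] = masks.get(ch, 0) | (1 << i)
    ones = (1 << m) - 1
    v = ones
    for ch in seq_b:
        u = v & masks.get(ch, 0)
        v = ((v + u) | (v - u)) & ones
    return m - (v & ones).bit_count()


def lcs_similarity(seq_a: str, seq_b: str) -> float:
    """|LCS| / max length, in [0, 1]; 1.0 iff the sequences are identical."""
    if not seq_a or not seq_b:
        raise ValueError("lcs_similarity requires non-empty sequences")
    return lcs_length(seq_a, seq_b) / max(len(seq_a), len(seq_b))
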