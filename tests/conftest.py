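import numpy as np
import pytest

from barcodekit.distances import DistanceMatrix
from barcodekit.records import ReferenceLibrary, SpecimenRecord


def make_library(seq_by_id: dict[str, str], species_by_id: dict[str, str],
                 marker: str = "COI", aligned: bool = True,
                 lineage_by_species: dict | None = None) -> ReferenceLibrary:
    records = []
    for sid, seq in seq_by_id.items():
        sp = species_by_id[sid]
        lineage = ()
        if lineage_by_species and sp in lineage_by_species:
            lineage = tuple(lineage_by_species[sp]) + (("species", sp),)
        records.append(
            SpecimenRecord(specimen_id=sid, species_label=sp, sequence=seq,
                           lineage=lineage, marker=marker)
        )
    return ReferenceLibrary(records=tuple(records), marker=marker, aligned=aligned)


def matrix_from_pairs(ids, pairs: dict[tuple[str, str], float],
                      metric: str = "k2p") -> DistanceMatrix:
    """Build a DistanceMatrix from explicit upper-triangle distances."""
    n = len(ids)
    values = np.zeros((n, n))
    index = {sid: k for k, sid in enumerate(ids)}
    for (a, b), d in pairs.items():
        values[index[a], index[b]] = values[index[b], index[a]] = d
    return DistanceMatrix(tuple(ids), values, metric=metric)


def random_sequences(rng, n: int, length: int) -> list[str]:
    return ["".join(rng.choice(list("ACGT"), size=length)) for _ in range(n)]


def mutated_family(rng, n: int, length: int, n_changes: int) -> list[str]:
    """Sequences derived from one ancestor by random substitutions, so that
    pairwise divergences stay below K2P saturation."""
    base = rng.choice(list("ACGT"), size=length)
    out = []
    for _ in range(n):
        seq = base.copy()
        for pos in rng.choice(length, size=n_changes, replace=False):
            seq[pos] = rng.choice(list("ACGT"))
        out.append("".join(seq))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
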