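"""Specimen records and reference libraries.

A reference library couples one barcode marker's sequences (COI ~658 bp or
16S ~216 bp) with per-specimen metadata: a nominal species label (a Linnean
name or a morphospecies code such as ``Onirion sp.stA``), an optional
taxonomic lineage ordered subfamily > tribe > genus > subgenus > species,
and an optional life stage.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace

__all__ = [
    "SpecimenRecord",
    "ReferenceLibrary",
    "filter_incomplete",
    "IUPAC_ALPHABET",
    "RANKS",
]

IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN-")

#: Taxonomic ranks, most inclusive first.
RANKS = ("subfamily", "tribe", "genus", "subgenus", "species")

MARKERS = ("COI", "16S")

LIFE_STAGES = ("M", "F", "L")


class LibraryError(ValueError):
    """Raised when a library or record violates an integrity invariant."""


@dataclass(frozen=True)
class SpecimenRecord:
    """One voucher specimen: identifier, species label, lineage and sequence.

    Parameters
    ----------
    specimen_id : str
        Unique token within a library (per marker).
    species_label : str
        Nominal species or morphospecies label.
    sequence : str
        IUPAC nucleotide string; gaps allowed if the library is pre-aligned.
        Uppercased on construction.
    lineage : tuple of (rank, taxon) pairs, optional
        Ordered subfamily -> ... -> species. When present, its terminal
        taxon must equal ``species_label``.
    marker : {"COI", "16S"}
    life_stage : {"M", "F", "L"}, optional
    """

    specimen_id: str
    species_label: str
    sequence: str
    lineage: tuple[tuple[str, str], ...] = ()
    marker: str = "COI"
    life_stage: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.specimen_id:
            raise LibraryError("specimen_id must be a non-empty string")
        if not self.sequence:
            raise LibraryError(f"{self.specimen_id}: empty sequence")
        bad = set(self.sequence) - IUPAC_ALPHABET
        if bad:
            raise LibraryError(
                f"{self.specimen_id}: non-IUPAC symbols {sorted(bad)!r} in sequence"
            )
        if self.marker not in MARKERS:
            raise LibraryError(f"{self.specimen_id}: unknown marker {self.marker!r}")
        if self.life_stage is not None and self.life_stage not in LIFE_STAGES:
            raise LibraryError(
                f"{self.specimen_id}: unknown life stage {self.life_stage!r}"
            )
        if self.lineage:
            terminal = self.lineage[-1][1]
            if terminal != self.species_label:
                raise LibraryError(
                    f"{self.specimen_id}: terminal lineage taxon {terminal!r} "
                    f"!= species_label {self.species_label!r}"
                )

    @property
    def ungapped_length(self) -> int:
        return len(self.sequence) - self.sequence.count("-")


@dataclass(frozen=True)
class ReferenceLibrary:
    """An ordered collection of specimen records for one marker."""

    records: tuple[SpecimenRecord, ...]
    marker: str = "COI"
    aligned: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen: set[str] = set()
        for rec in self.records:
            if rec.specimen_id in seen:
                raise LibraryError(f"duplicate specimen_id {rec.specimen_id!r}")
            seen.add(rec.specimen_id)
            if rec.marker != self.marker:
                raise LibraryError(
                    f"{rec.specimen_id}: marker {rec.marker!r} != library marker "
                    f"{self.marker!r}"
                )
        if self.aligned and self.records:
            lengths = {len(r.sequence) for r in self.records}
            if len(lengths) > 1:
                raise LibraryError(
                    f"aligned library has unequal sequence lengths {sorted(lengths)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.specimen_id for r in self.records)

    @property
    def species_labels(self) -> tuple[str, ...]:
        return tuple(r.species_label for r in self.records)

    @property
    def species_count(self) -> int:
        return len(set(self.species_labels))

    def __getitem__(self, specimen_id: str) -> SpecimenRecord:
        for rec in self.records:
            if rec.specimen_id == specimen_id:
                return rec
        raise KeyError(specimen_id)

    def subset(self, specimen_ids) -> "ReferenceLibrary":
        """New library keeping only the given specimens, original order."""
        keep = set(specimen_ids)
        return replace(
            self, records=tuple(r for r in self.records if r.specimen_id in keep)
        )


def filter_incomplete(
    library: ReferenceLibrary, min_length_fraction: float = 0.95
) -> tuple[ReferenceLibrary, list[str]]:
    """Drop sequences shorter than a fraction of the modal ungapped length.

    Short-marker libraries often contain truncated reads (e.g. a few bases
    missing at the 5' end from a low-quality reverse read); those incomplete
    sequences are removed before distance analysis. A record is retained when
    its ungapped length is at least ``min_length_fraction`` times the modal
    ungapped length of the library.

    Returns the filtered library and the list of removed specimen IDs.
    Idempotent: filtering a filtered library removes nothing further
    (the mode is unchanged by removing below-cutoff records).
    """
    if not 0.0 < min_length_fraction <= 1.0:
        raise ValueError(
            f"min_length_fraction must be in (0, 1], got {min_length_fraction}"
        )
    if not library.records:
        raise LibraryError("cannot filter an empty library")
    lengths = [r.ungapped_length for r in library.records]
    mode = statistics.mode(lengths)
    cutoff = min_length_fraction * mode
    kept = tuple(r for r in library.records if r.ungapped_length >= cutoff)
    removed = [r.specimen_id for r in library.records if r.ungapped_length < cutoff]
    return replace(library, records=kept), removed
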