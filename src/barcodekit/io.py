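"""File I/O: FASTA + tab-separated metadata, partitions, distance matrices.

The metadata table is tab-separated with mandatory columns ``specimen_id``,
``species_label`` and ``marker``; optional columns are ``life_stage`` and the
rank columns ``subfamily``, ``tribe``, ``genus``, ``subgenus``, ``species``
(empty cells mean the rank is absent for that specimen). Round-tripping a
library through :func:`write_library` / :func:`read_library` reproduces the
records field by field.
"""

from __future__ import annotations

import os

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import RANKS, LibraryError, ReferenceLibrary, SpecimenRecord

__all__ = ["read_library", "write_library", "read_metadata", "write_metadata"]

_META_REQUIRED = ("specimen_id", "species_label", "marker")


def read_metadata(metadata_path: str | os.PathLike) -> pd.DataFrame:
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _META_REQUIRED if c not in meta.columns]
    if missing:
        raise LibraryError(f"metadata {metadata_path}: missing columns {missing}")
    dups = meta["specimen_id"][meta["specimen_id"].duplicated()].tolist()
    if dups:
        raise LibraryError(f"metadata {metadata_path}: duplicate specimen_id {dups}")
    return meta


def _lineage_from_row(row: pd.Series, species_label: str) -> tuple[tuple[str, str], ...]:
    pairs = []
    for rank in RANKS:
        taxon = str(row.get(rank, "") or "").strip()
        if taxon:
            pairs.append((rank, taxon))
    if pairs and pairs[-1][0] != "species":
        pairs.append(("species", species_label))
    return tuple(pairs)


def read_library(
    fasta_path: str | os.PathLike,
    metadata_path: str | os.PathLike,
    aligned: bool = False,
) -> ReferenceLibrary:
    """Build a :class:`ReferenceLibrary` from a FASTA file and metadata TSV.

    FASTA IDs must match the metadata ``specimen_id`` column exactly; a FASTA
    entry without a metadata row (or vice versa duplicated IDs) is a hard
    error naming the offending ID. Record order follows the FASTA file.
    Sequences are uppercased; IUPAC ambiguity codes are retained.
    """
    meta = read_metadata(metadata_path).set_index("specimen_id")
    records = []
    seen = set()
    marker = None
    for entry in SeqIO.parse(str(fasta_path), "fasta"):
        sid = entry.id
        if sid in seen:
            raise LibraryError(f"duplicate FASTA id {sid!r}")
        seen.add(sid)
        if sid not in meta.index:
            raise LibraryError(f"FASTA id {sid!r} has no metadata row")
        row = meta.loc[sid]
        marker = marker or str(row["marker"])
        records.append(
            SpecimenRecord(
                specimen_id=sid,
                species_label=str(row["species_label"]),
                sequence=str(entry.seq),
                lineage=_lineage_from_row(row, str(row["species_label"])),
                marker=str(row["marker"]),
                life_stage=str(row.get("life_stage") or "") or None,
            )
        )
    return ReferenceLibrary(records=tuple(records), marker=marker or "COI", aligned=aligned)


def write_metadata(library: ReferenceLibrary, metadata_path: str | os.PathLike) -> None:
    rows = []
    any_stage = any(r.life_stage for r in library.records)
    used_ranks = [
        rank
        for rank in RANKS
        if any(rank in dict(r.lineage) for r in library.records)
    ]
    for rec in library.records:
        row = {
            "specimen_id": rec.specimen_id,
            "species_label": rec.species_label,
            "marker": rec.marker,
        }
        lin = dict(rec.lineage)
        for rank in used_ranks:
            row[rank] = lin.get(rank, "")
        if any_stage:
            row["life_stage"] = rec.life_stage or ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(metadata_path, sep="\t", index=False)


def write_library(
    library: ReferenceLibrary,
    fasta_path: str | os.PathLike,
    metadata_path: str | os.PathLike,
) -> None:
    """Write FASTA + metadata TSV; inverse of :func:`read_library`."""
    entries = [
        SeqRecord(Seq(rec.sequence), id=rec.specimen_id, description="")
        for rec in library.records
    ]
    SeqIO.write(entries, str(fasta_path), "fasta")
    write_metadata(library, metadata_path)
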