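"""Labeled multiple-sequence alignments and their FASTA/TSV plumbing.

Every downstream stage (distances, trees, haplotypes, networks, diagnostics)
operates on a :class:`LabeledAlignment`: an aligned set of marker sequences
carrying a species label and a declared geographic origin per record.

Coordinate convention
---------------------
All "+N" locus positions used by the diagnostic key are **1-based alignment
column indices**: column 1 is the first character of the alignment. Queries
that are not part of the reference alignment are mapped onto it by pairwise
alignment (see :mod:`agarcode.diagnostics`) before any locus is read.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MARKERS = ("matK", "ITS2", "rbcL", "trnL-trnF", "other")

#: IUPAC nucleotide codes accepted in an alignment (upper case after read).
ALPHABET = frozenset("ACGT-NRYSWKMBDHV")

#: Unambiguous bases; everything else is treated as missing data.
UNAMBIGUOUS = frozenset("ACGT")


class AlignmentError(ValueError):
    """Raised for malformed alignments or metadata."""


@dataclasses.dataclass(frozen=True)
class SampleMetadata:
    """Provenance of one sample: id, labels, free-text source."""

    id: str
    species: str | None = None
    origin: str | None = None
    source: str | None = None


@dataclasses.dataclass(frozen=True)
class LabeledAlignment:
    """An aligned set of marker sequences with per-record labels.

    Parameters
    ----------
    marker:
        One of ``matK``, ``ITS2``, ``rbcL``, ``trnL-trnF`` or ``other``.
    ids, seqs:
        Parallel tuples; ``seqs`` are equal-length upper-case strings over
        the IUPAC alphabet plus ``-`` (gap).
    species, origin:
        Parallel label tuples; ``None`` marks an unknown.
    """

    marker: str
    ids: tuple[str, ...]
    seqs: tuple[str, ...]
    species: tuple[str | None, ...]
    origin: tuple[str | None, ...]

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise AlignmentError(f"unknown marker {self.marker!r}; expected one of {MARKERS}")
        if not self.ids:
            raise AlignmentError("alignment has no records")
        if len(set(self.ids)) != len(self.ids):
            seen: set[str] = set()
            dup = next(i for i in self.ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise AlignmentError(f"duplicate sequence id {dup!r}")
        if not (len(self.ids) == len(self.seqs) == len(self.species) == len(self.origin)):
            raise AlignmentError("ids/seqs/species/origin must have equal cardinality")
        length = len(self.seqs[0])
        if length < 1:
            raise AlignmentError(f"record {self.ids[0]!r} is empty")
        for rid, seq in zip(self.ids, self.seqs):
            if len(seq) != length:
                raise AlignmentError(
                    f"ragged alignment: record {rid!r} has length {len(seq)}, expected {length}"
                )
            for pos, char in enumerate(seq, start=1):
                if char not in ALPHABET:
                    raise AlignmentError(
                        f"record {rid!r}: unknown character {char!r} at column {pos}"
                    )

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.seqs[0])

    @property
    def n(self) -> int:
        """Number of records."""
        return len(self.ids)

    def subset(self, ids: Sequence[str]) -> "LabeledAlignment":
        """Return the alignment restricted to ``ids`` (in the given order)."""
        index = {rid: k for k, rid in enumerate(self.ids)}
        missing = [rid for rid in ids if rid not in index]
        if missing:
            raise AlignmentError(f"ids not in alignment: {missing}")
        rows = [index[rid] for rid in ids]
        return LabeledAlignment(
            marker=self.marker,
            ids=tuple(self.ids[k] for k in rows),
            seqs=tuple(self.seqs[k] for k in rows),
            species=tuple(self.species[k] for k in rows),
            origin=tuple(self.origin[k] for k in rows),
        )

    def by_species(self, label: str) -> "LabeledAlignment":
        """Records whose species label equals ``label``."""
        ids = [rid for rid, sp in zip(self.ids, self.species) if sp == label]
        if not ids:
            raise AlignmentError(f"no records with species {label!r}")
        return self.subset(ids)

    def species_set(self) -> set[str]:
        return {sp for sp in self.species if sp is not None}


def _normalize(seq: str) -> str:
    # Mixed-case NCBI downloads and RNA-style U are both common in practice.
    return seq.upper().replace("U", "T")


def _labels_from_header(header: str) -> tuple[str, str | None, str | None]:
    """Parse the documented ``id|species|origin`` header convention."""
    parts = header.split("|")
    rid = parts[0].strip()
    species = parts[1].strip() or None if len(parts) > 1 else None
    origin = parts[2].strip() or None if len(parts) > 2 else None
    return rid, species, origin


def read_metadata(path: str | Path) -> dict[str, SampleMetadata]:
    """Read a metadata TSV with columns ``id, species, origin, source``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "id" not in df.columns:
        raise AlignmentError(f"metadata {path} lacks an 'id' column")
    out: dict[str, SampleMetadata] = {}
    for row in df.itertuples(index=False):
        rec = SampleMetadata(
            id=row.id,
            species=getattr(row, "species", "") or None,
            origin=getattr(row, "origin", "") or None,
            source=getattr(row, "source", "") or None,
        )
        if rec.id in out:
            raise AlignmentError(f"duplicate id {rec.id!r} in metadata")
        out[rec.id] = rec
    return out


def read_labeled_fasta(
    fasta_path: str | Path,
    metadata_path: str | Path | None = None,
    marker: str = "other",
) -> LabeledAlignment:
    """Read an aligned FASTA plus optional metadata TSV.

    Labels come from the metadata table when given (it wins over header
    parsing); otherwise from the ``id|species|origin`` header convention.
    Sequences are upper-cased and U is normalized to T. Ragged records,
    duplicate ids and unknown characters are hard errors.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise AlignmentError(f"{fasta_path}: no FASTA records")
    meta = read_metadata(metadata_path) if metadata_path is not None else None

    ids: list[str] = []
    seqs: list[str] = []
    species: list[str | None] = []
    origin: list[str | None] = []
    for rec in records:
        rid, sp, org = _labels_from_header(rec.description)
        if meta is not None:
            if rid not in meta:
                raise AlignmentError(f"id {rid!r} absent from metadata table")
            sp, org = meta[rid].species, meta[rid].origin
        ids.append(rid)
        seqs.append(_normalize(str(rec.seq)))
        species.append(sp)
        origin.append(org)
    return LabeledAlignment(
        marker=marker, ids=tuple(ids), seqs=tuple(seqs),
        species=tuple(species), origin=tuple(origin),
    )


def write_fasta(aln: LabeledAlignment, path: str | Path) -> Path:
    """Write the alignment with ``id|species|origin`` headers.

    Round-trip guarantee: ``read_labeled_fasta(write_fasta(a))`` reproduces
    ids, order, sequences and labels exactly.
    """
    path = Path(path)
    records = []
    for rid, seq, sp, org in zip(aln.ids, aln.seqs, aln.species, aln.origin):
        header = f"{rid}|{sp or ''}|{org or ''}"
        records.append(SeqRecord(Seq(seq), id=header, description=""))
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")
    return path


def write_metadata(samples: Sequence[SampleMetadata], path: str | Path) -> Path:
    """Write a metadata TSV (columns id, species, origin, source)."""
    path = Path(path)
    pd.DataFrame(
        [
            {
                "id": s.id,
                "species": s.species or "",
                "origin": s.origin or "",
                "source": s.source or "",
            }
            for s in samples
        ]
    ).to_csv(path, sep="\t", index=False)
    return path
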