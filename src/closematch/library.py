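"""Reference-library import and quality-check tables.

A barcode reference library is a multi-FASTA of *aligned* sequences whose
headers encode a species name.  This module reads such files into a
:class:`BarcodeLibrary`, normalizes the alphabet, and produces the basic
descriptive tables used for a first quality check: per-species sequence and
haplotype counts, and per-record ungapped lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

__all__ = [
    "SequenceRecord",
    "BarcodeLibrary",
    "AlignmentError",
    "LabelError",
    "DegenerateLibraryError",
    "species_from_header",
    "read_species_map",
    "read_fasta_library",
    "write_fasta_library",
    "species_summary",
    "sequence_lengths",
]

#: Residues kept verbatim after normalization.  Any other IUPAC code is
#: collapsed to N because the distance models only distinguish A/C/G/T from
#: missing data.
ALPHABET = frozenset("ACGTN-")

_IUPAC_AMBIGUOUS = set("RYSWKMBDHV")


class AlignmentError(ValueError):
    """Raised when sequences in a library do not share one alignment length."""


class LabelError(ValueError):
    """Raised when a species name cannot be derived for a record."""


class DegenerateLibraryError(ValueError):
    """Raised for libraries on which leave-one-out identification is vacuous."""


def normalize_residues(residues: str) -> str:
    """Upper-case, map U->T, collapse non-N IUPAC ambiguity codes to N.

    Raises ``ValueError`` on characters outside the nucleotide alphabet.
    """
    s = residues.upper().replace("U", "T")
    out = []
    for ch in s:
        if ch in ALPHABET:
            out.append(ch)
        elif ch in _IUPAC_AMBIGUOUS or ch == "?":
            out.append("N")
        else:
            raise ValueError(f"illegal residue character {ch!r}")
    return "".join(out)


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned barcode with its identifier and species label."""

    id: str
    species: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if not self.species:
            raise LabelError(f"record {self.id!r}: empty species name")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: residues not normalized: {sorted(bad)}"
            )


@dataclass(frozen=True)
class BarcodeLibrary:
    """An ordered collection of aligned, species-labelled barcodes."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise DegenerateLibraryError(
                "a reference library needs at least 2 sequences"
            )
        length = len(self.records[0].residues)
        for rec in self.records:
            if len(rec.residues) != length:
                raise AlignmentError(
                    f"record {rec.id!r} has length {len(rec.residues)}, "
                    f"expected aligned length {length}"
                )
        if len({rec.species for rec in self.records}) < 2:
            raise DegenerateLibraryError(
                "a reference library needs at least 2 species; "
                "leave-one-out identification is undefined otherwise"
            )

    @property
    def alignment_length(self) -> int:
        return len(self.records[0].residues)

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    @property
    def species(self) -> list[str]:
        return [rec.species for rec in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @classmethod
    def from_sequences(
        cls, ids: Iterable[str], species: Iterable[str], residues: Iterable[str]
    ) -> "BarcodeLibrary":
        """Build a library from parallel iterables, normalizing residues."""
        recs = tuple(
            SequenceRecord(i, sp, normalize_residues(seq))
            for i, sp, seq in zip(ids, species, residues, strict=True)
        )
        return cls(recs)


def species_from_header(header: str, delimiter: str = "_") -> str:
    """Default labelling rule: everything before the last delimiter token.

    ``"Genus_species_ID123" -> "Genus_species"``.  A header without the
    delimiter is rejected because no species name can be separated from the
    record identifier.
    """
    head, sep, _ = header.rpartition(delimiter)
    if not sep or not head:
        raise LabelError(
            f"cannot derive a species name from header {header!r} "
            f"with delimiter {delimiter!r}"
        )
    return head


def read_species_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping record id -> species name."""
    mapping: dict[str, str] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise LabelError(f"{path}:{line_no}: expected two tab-separated columns")
        mapping[parts[0]] = parts[1]
    return mapping


def read_fasta_library(
    path: str | Path,
    label: Callable[[str], str] | Mapping[str, str] | None = None,
    delimiter: str = "_",
) -> BarcodeLibrary:
    """Import an aligned FASTA reference library.

    Parameters
    ----------
    path
        Multi-FASTA file of pre-aligned barcodes (wrapped or single-line).
    label
        How to obtain the species of each record: a callable
        ``header -> species``, a mapping ``id -> species`` (e.g. from
        :func:`read_species_map`), or ``None`` for the default rule
        :func:`species_from_header`.
    delimiter
        Delimiter used by the default header rule.

    Order is preserved; residues are upper-cased, U mapped to T, and
    ambiguity codes other than N collapsed to N.
    """
    bio_records = list(SeqIO.parse(str(path), "fasta"))
    if not bio_records:
        raise ValueError(f"{path}: no FASTA records found")
    records = []
    for rec in bio_records:
        header = rec.id
        if label is None:
            sp = species_from_header(header, delimiter)
        elif callable(label):
            sp = label(header)
        else:
            try:
                sp = label[header]
            except KeyError:
                raise LabelError(f"record {header!r} missing from species map")
        try:
            residues = normalize_residues(str(rec.seq))
        except ValueError as exc:
            raise ValueError(f"record {header!r}: {exc}") from exc
        records.append(SequenceRecord(header, sp, residues))
    return BarcodeLibrary(tuple(records))


def write_fasta_library(lib: BarcodeLibrary, path: str | Path) -> None:
    """Write the library back to single-line-per-sequence FASTA."""
    bio = [
        _BioRecord(Seq(rec.residues), id=rec.id, description="")
        for rec in lib.records
    ]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta-2line")


def species_summary(lib: BarcodeLibrary) -> pd.DataFrame:
    """Per-species counts of sequences and haplotypes.

    Haplotypes are distinct normalized aligned strings (gaps and N compared
    literally).  Columns: species, n_sequences, n_haplotypes, sequence_ids.
    """
    rows = {}
    for rec in lib.records:
        entry = rows.setdefault(rec.species, {"seqs": [], "haps": set()})
        entry["seqs"].append(rec.id)
        entry["haps"].add(rec.residues)
    table = pd.DataFrame(
        {
            "species": list(rows),
            "n_sequences": [len(v["seqs"]) for v in rows.values()],
            "n_haplotypes": [len(v["haps"]) for v in rows.values()],
            "sequence_ids": [",".join(v["seqs"]) for v in rows.values()],
        }
    )
    return table


def sequence_lengths(lib: BarcodeLibrary) -> pd.DataFrame:
    """Ungapped length of each record: sites not in {-, N}, in library order."""
    lengths = [
        len(rec.residues) - rec.residues.count("-") - rec.residues.count("N")
        for rec in lib.records
    ]
    return pd.DataFrame({"id": lib.ids, "ungapped_length": lengths})
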