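"""Sequence and specimen-metadata input/output.

Barcode alignments are plain FASTA; because COI barcodes of closely related
satyrine butterflies align without indels, an "alignment" here is simply a set
of equal-length sequences.  Reading is permissive (ragged sets are accepted
and flagged), but operations that require an alignment reject ragged sets.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

#: IUPAC nucleotide one-letter codes (with gap), canonical uppercase.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_ALPHABET = frozenset(IUPAC_CODES) | {"-"}

_ACCESSION_RE = re.compile(r"^([A-Za-z]+)(\d+)$")

FASTA_WRAP = 60


class SequenceError(ValueError):
    """Raised for malformed sequence input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One barcode sequence with an identifier and optional species label."""

    id: str
    residues: str
    species: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence id must be non-empty")
        if not self.residues:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        canon = self.residues.upper()
        for col, ch in enumerate(canon, start=1):
            if ch not in IUPAC_ALPHABET:
                raise SequenceError(
                    f"record {self.id!r}: non-IUPAC character {ch!r} at column {col}"
                )
        object.__setattr__(self, "residues", canon)

    def __len__(self) -> int:
        return len(self.residues)


def sequence_length(rec: SequenceRecord) -> int:
    """Number of residue characters (gaps included)."""
    return len(rec.residues)


@dataclass
class SequenceSet:
    """An ordered collection of records, aligned iff all lengths agree."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise SequenceError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, key: int | str) -> SequenceRecord:
        if isinstance(key, int):
            return self.records[key]
        for rec in self.records:
            if rec.id == key:
                return rec
        raise KeyError(key)

    @property
    def is_aligned(self) -> bool:
        lengths = {len(r) for r in self.records}
        return len(lengths) <= 1

    @property
    def alignment_length(self) -> int:
        """Number of columns; raises on ragged (unaligned) sets."""
        self.require_aligned()
        return len(self.records[0]) if self.records else 0

    def require_aligned(self) -> None:
        if not self.is_aligned:
            lengths = sorted({len(r) for r in self.records})
            raise SequenceError(
                f"sequences are not aligned (lengths {lengths}); "
                "this operation requires equal-length sequences"
            )

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def species_map(self) -> dict[str, str | None]:
        return {r.id: r.species for r in self.records}


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a FASTA file into a SequenceSet.

    Residues are uppercased.  A species label may be embedded after a ``|``
    in the header (``>id|Species name``).  Mixed-length inputs are accepted;
    alignment-requiring operations will reject them later.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    for bio in SeqIO.parse(str(path), "fasta"):
        header = bio.description or bio.id
        species = None
        ident = bio.id
        if "|" in header:
            ident, species = header.split("|", 1)
            ident, species = ident.strip(), species.strip() or None
        records.append(SequenceRecord(id=ident, residues=str(bio.seq), species=species))
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    return SequenceSet(records)


def write_fasta(seqs: SequenceSet | Iterable[SequenceRecord], path: str | Path) -> Path:
    """Write records as FASTA, wrapped at 60 columns, in input order."""
    path = Path(path)
    bio_records = []
    for rec in seqs:
        header = rec.id if rec.species is None else f"{rec.id}|{rec.species}"
        bio_records.append(_BioSeqRecord(Seq(rec.residues), id=header, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(bio_records)
    return path


@dataclass(frozen=True)
class SpecimenRecord:
    """One voucher specimen row: who, where, when."""

    species: str
    voucher: str
    accession: str | None = None
    locality: str = ""
    date: str = ""
    collector: str = ""

    def __post_init__(self) -> None:
        if not self.voucher:
            raise ValueError("voucher must be non-empty")
        if self.accession is not None and not _ACCESSION_RE.match(self.accession):
            raise ValueError(
                f"accession {self.accession!r} does not match letters-then-digits"
            )


REQUIRED_METADATA_COLUMNS = ("species", "voucher")
OPTIONAL_METADATA_COLUMNS = ("accession", "locality", "date", "collector")


def read_metadata(path: str | Path) -> list[SpecimenRecord]:
    """Read a tab-separated specimen table with a header row."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata file {path} missing required columns: {missing}")
    if df.empty:
        logger.warning("metadata file %s has a header but no rows", path)
        return []
    out: list[SpecimenRecord] = []
    for _, row in df.iterrows():
        out.append(
            SpecimenRecord(
                species=row["species"],
                voucher=row["voucher"],
                accession=row.get("accession") or None,
                locality=row.get("locality", ""),
                date=row.get("date", ""),
                collector=row.get("collector", ""),
            )
        )
    return out


@dataclass
class CollectionSummary:
    """Per-species counts, max/min count ratios, and percentage shares."""

    counts: dict[str, int]
    ratios: dict[tuple[str, str], float] = field(default_factory=dict)
    shares_percent: dict[str, float] = field(default_factory=dict)


def summarize_collection(records: Sequence[SpecimenRecord]) -> CollectionSummary:
    """Count specimens per species; report pairwise max/min ratios and shares.

    Useful for quantifying how strongly one cryptic species outnumbers
    another in a museum drawer (e.g. a >20:1 ratio).
    """
    if not records:
        raise ValueError("summarize_collection requires at least one record")
    counts: dict[str, int] = {}
    for rec in records:
        counts[rec.species] = counts.get(rec.species, 0) + 1
    total = sum(counts.values())
    species = sorted(counts)
    ratios = {
        (a, b): max(counts[a], counts[b]) / min(counts[a], counts[b])
        for i, a in enumerate(species)
        for b in species[i + 1 :]
    }
    shares = {sp: 100.0 * n / total for sp, n in counts.items()}
    return CollectionSummary(counts=counts, ratios=ratios, shares_percent=shares)


def accession_range_count(first: str, last: str) -> int:
    """Inclusive size of a GenBank-style accession range (same prefix)."""
    m1, m2 = _ACCESSION_RE.match(first), _ACCESSION_RE.match(last)
    if m1 is None or m2 is None:
        raise ValueError(f"malformed accession in range ({first!r}, {last!r})")
    if m1.group(1).upper() != m2.group(1).upper():
        raise ValueError(
            f"accession prefixes differ: {m1.group(1)!r} vs {m2.group(1)!r}"
        )
    n1, n2 = int(m1.group(2)), int(m2.group(2))
    if n2 < n1:
        raise ValueError(f"range end {last!r} precedes start {first!r}")
    return n2 - n1 + 1
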