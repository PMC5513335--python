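"""Sequence and annotation I/O, fundamental genomic types, configuration.

Coordinates are 0-based, half-open everywhere in memory.  GFF3 output
converts to 1-based inclusive; BED stays 0-based half-open.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from Bio import SeqIO

logger = logging.getLogger("teasv")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised on malformed input files."""


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize_residues(raw: str) -> tuple[str, int]:
    """Uppercase, map U->T, and map anything outside ACGTN to N.

    Returns the cleaned string and the count of replaced characters.
    Ambiguity codes become N and never seed an alignment downstream.
    """
    s = raw.upper().replace("U", "T")
    if set(s) <= _VALID:
        return s, 0
    cleaned = [c if c in _VALID else "N" for c in s]
    n_replaced = sum(1 for a, b in zip(s, cleaned) if a != b)
    return "".join(cleaned), n_replaced


@dataclass(frozen=True)
class SequenceRecord:
    """One read, chromosome or TE sequence with optional per-base quality."""

    id: str
    residues: str
    description: str = ""
    quality: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"record id must be a non-empty token, got {self.id!r}")
        if self.quality is not None and len(self.quality) != len(self.residues):
            raise ValueError(
                f"{self.id}: quality length {len(self.quality)} != "
                f"sequence length {len(self.residues)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "SequenceRecord":
        qual = tuple(reversed(self.quality)) if self.quality is not None else None
        return SequenceRecord(self.id, revcomp(self.residues), self.description, qual)


@dataclass(frozen=True)
class GenomeInterval:
    """Half-open interval [start, end) on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval", slop: int = 0) -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end + slop
            and other.start < self.end + slop
        )


class ReferenceGenome:
    """Ordered collection of chromosome records with id lookup."""

    def __init__(self, records: Iterable[SequenceRecord]):
        self.records: list[SequenceRecord] = list(records)
        self._index = {r.id: r for r in self.records}
        if len(self._index) != len(self.records):
            raise FormatError("duplicate chromosome ids in genome")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._index

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, chrom: str) -> SequenceRecord:
        try:
            return self._index[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def chrom_length(self, chrom: str) -> int:
        return len(self[chrom])

    @property
    def total_length(self) -> int:
        return sum(len(r) for r in self.records)

    def fetch(self, interval: GenomeInterval) -> str:
        """Subsequence for an in-bounds interval; '-' returns reverse complement."""
        rec = self[interval.chrom]
        if interval.end > len(rec):
            raise ValueError(
                f"interval end {interval.end} beyond {interval.chrom} "
                f"length {len(rec)}"
            )
        seq = rec.residues[interval.start : interval.end]
        return revcomp(seq) if interval.strand == "-" else seq


@dataclass(frozen=True)
class TELibraryEntry:
    """A canonical transposable-element sequence with minimal annotation.

    ``ltr_length`` is the length of the long terminal repeat for
    LTR-retrotransposon entries; DNA transposons leave it unset.
    """

    family: str
    te_class: str  # {"LTR_retrotransposon", "DNA_transposon"}
    sequence: SequenceRecord
    ltr_length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.te_class not in ("LTR_retrotransposon", "DNA_transposon"):
            raise ValueError(f"unknown te_class {self.te_class!r}")
        if len(self.sequence) < 100:
            raise ValueError(f"{self.family}: TE sequence shorter than 100 bp")
        if self.ltr_length is not None and self.ltr_length > len(self.sequence) // 2:
            raise ValueError(f"{self.family}: ltr_length exceeds half the element")


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def _check_unique_ids(records: Sequence[SequenceRecord], path) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise FormatError(f"{path}: duplicate record id {r.id!r}")
        seen.add(r.id)


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    Residues are uppercased, U mapped to T, and any other non-ACGTN
    character replaced by N (a single warning reports the count).
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                first = line
                break
        else:
            raise FormatError(f"{path}: empty file (line 1)")
        if not first.startswith(">"):
            raise FormatError(f"{path}: line {lineno}: expected FASTA header '>'")
    records: list[SequenceRecord] = []
    n_replaced = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        residues, n = _normalize_residues(str(rec.seq))
        n_replaced += n
        if not residues:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(SequenceRecord(rec.id, residues, rec.description))
    if n_replaced:
        warnings.warn(f"{path}: replaced {n_replaced} non-ACGTN characters with N")
    _check_unique_ids(records, path)
    return records


def read_fastq(path) -> list[SequenceRecord]:
    """Read a FASTQ (Sanger / Phred+33) file into SequenceRecords."""
    path = Path(path)
    records: list[SequenceRecord] = []
    n_replaced = 0
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            residues, n = _normalize_residues(str(rec.seq))
            n_replaced += n
            qual = tuple(rec.letter_annotations["phred_quality"])
            records.append(SequenceRecord(rec.id, residues, rec.description, qual))
    except ValueError as exc:  # biopython signals truncated/mismatched records
        raise FormatError(f"{path}: {exc}") from exc
    if n_replaced:
        warnings.warn(f"{path}: replaced {n_replaced} non-ACGTN characters with N")
    _check_unique_ids(records, path)
    return records


def read_fastx(path) -> list[SequenceRecord]:
    """Dispatch on extension: .fq/.fastq -> FASTQ, otherwise FASTA."""
    suffix = Path(path).suffix.lower()
    if suffix in (".fq", ".fastq"):
        return read_fastq(path)
    return read_fasta(path)


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for r in records:
            header = f">{r.id}" + (f" {r.description}" if r.description else "")
            fh.write(header + "\n")
            for i in range(0, len(r.residues), width):
                fh.write(r.residues[i : i + width] + "\n")


def write_fastq(records: Iterable[SequenceRecord], path, default_q: int = 15) -> None:
    """Write FASTQ; records lacking qualities get a flat default score."""
    with open(path, "w") as fh:
        for r in records:
            qual = r.quality if r.quality is not None else (default_q,) * len(r)
            fh.write(f"@{r.id}\n{r.residues}\n+\n")
            fh.write("".join(chr(q + 33) for q in qual) + "\n")


def load_te_library(path, te_class: str = "LTR_retrotransposon",
                    ltr_length: Optional[int] = None) -> list[TELibraryEntry]:
    """Read a TE library FASTA; every entry gets the stated class."""
    return [
        TELibraryEntry(rec.id, te_class, rec,
                       ltr_length if te_class == "LTR_retrotransposon" else None)
        for rec in read_fasta(path)
    ]


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------

def extract_window(genome: ReferenceGenome, interval: GenomeInterval,
                   pad: int) -> SequenceRecord:
    """Extract [start - pad, end + pad), clipped to the chromosome.

    The record id encodes the source coordinates so downstream steps can
    recover the genomic origin of the window.
    """
    chrom_len = genome.chrom_length(interval.chrom)
    lo = max(0, interval.start - pad)
    hi = min(chrom_len, interval.end + pad)
    seq = genome.fetch(GenomeInterval(interval.chrom, lo, hi))
    return SequenceRecord(f"{interval.chrom}:{lo}-{hi}", seq)


# ---------------------------------------------------------------------------
# Call output (BED / GFF3 / TSV)
# ---------------------------------------------------------------------------

_TSV_COLS = ("chrom", "start", "end", "family", "orientation", "status",
             "is_reference_copy", "n_support", "support")


def write_calls(calls, path, format: str = "BED") -> None:
    """Write InsertionCalls as BED6, GFF3 or TSV.

    BED is 0-based half-open; GFF3 is 1-based inclusive with feature type
    ``transposable_element_insertion_site``.
    """
    fmt = format.upper()
    path = Path(path)
    with open(path, "w") as fh:
        if fmt == "BED":
            fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
            for c in calls:
                strand = {"sense": "+", "antisense": "-"}.get(c.orientation, ".")
                name = f"{c.te_family};support={len(c.support)};status={c.status}"
                fh.write(f"{c.locus.chrom}\t{c.locus.start}\t{c.locus.end}\t"
                         f"{name}\t{len(c.support)}\t{strand}\n")
        elif fmt == "GFF3":
            fh.write("##gff-version 3\n")
            for c in calls:
                strand = {"sense": "+", "antisense": "-"}.get(c.orientation, ".")
                attrs = (f"ID=teasv_{c.locus.chrom}_{c.locus.start};"
                         f"family={c.te_family};support={len(c.support)};"
                         f"status={c.status};reference_copy={c.is_reference_copy}")
                fh.write(f"{c.locus.chrom}\tteasv\t"
                         f"transposable_element_insertion_site\t"
                         f"{c.locus.start + 1}\t{c.locus.end}\t"
                         f"{len(c.support)}\t{strand}\t.\t{attrs}\n")
        elif fmt == "TSV":
            fh.write("\t".join(_TSV_COLS) + "\n")
            for c in calls:
                fh.write("\t".join(str(x) for x in (
                    c.locus.chrom, c.locus.start, c.locus.end, c.te_family,
                    c.orientation, c.status, c.is_reference_copy,
                    len(c.support), ",".join(r for r, _ in c.support))) + "\n")
        else:
            raise ValueError(f"unknown call format {format!r}")


def read_calls_bed(path) -> list[tuple]:
    """Read back a BED written by write_calls as (chrom, start, end, name,
    score, strand) tuples (body lines only)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, name, score, strand = line.rstrip("\n").split("\t")
            out.append((chrom, int(start), int(end), name, int(score), strand))
    return out


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable bundle of scoring and detection parameters.

    Nested threshold objects live in their owning modules; this class keeps
    plain dicts so a run can be reproduced from a single JSON file.
    """

    scoring: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."
    log_level: str = "INFO"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def setup_logging(level: str = "INFO") -> None:
    """Structured logging to stderr with per-stage read counts."""
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
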