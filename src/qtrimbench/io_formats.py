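"""Sequence I/O: FASTA/FASTQ records and a strict phred+33 quality codec.

All qualities are plain integer phred scores; encoding to and from the
ASCII representation is centralized here so that every module in the
pipeline shares one exact codec. Only the Illumina 1.8+ convention
(phred+33) is supported — no auto-detection.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33
QUAL_MIN = 0
QUAL_MAX = 41
_ENC_MIN = PHRED_OFFSET + QUAL_MIN
_ENC_MAX = PHRED_OFFSET + QUAL_MAX

VALID_BASES = frozenset("ACGTN")

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Raised on malformed FASTA/FASTQ input or invalid quality strings."""


@dataclass(frozen=True)
class SeqRecord:
    """A named nucleotide sequence over the alphabet {A, C, G, T, N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        extra = set(self.sequence) - VALID_BASES
        if extra:
            raise ValueError(
                f"record {self.id!r}: invalid characters {sorted(extra)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadRecord:
    """A sequenced read: identifier, bases and per-base phred qualities."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "qualities", tuple(self.qualities))
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )
        if self.qualities and not (
            QUAL_MIN <= min(self.qualities) and max(self.qualities) <= QUAL_MAX
        ):
            raise ValueError(
                f"read {self.id!r}: qualities outside [{QUAL_MIN}, {QUAL_MAX}]"
            )
        if self.sequence:
            extra = set(self.sequence) - VALID_BASES
            if extra:
                raise ValueError(
                    f"read {self.id!r}: invalid characters {sorted(extra)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def mean_quality(self) -> float:
        if not self.qualities:
            raise ValueError(f"read {self.id!r}: empty read has no mean quality")
        return sum(self.qualities) / len(self.qualities)


def decode_quality(encoded: str) -> list[int]:
    """Decode a phred+33 quality string to integer scores.

    Raises FormatError naming the first offending position when a character
    falls outside the printable range chr(33)..chr(74).
    """
    out = []
    for i, ch in enumerate(encoded):
        cp = ord(ch)
        if not (_ENC_MIN <= cp <= _ENC_MAX):
            raise FormatError(
                f"quality character {ch!r} at position {i} outside "
                f"phred+33 range [{QUAL_MIN}, {QUAL_MAX}]"
            )
        out.append(cp - PHRED_OFFSET)
    return out


def encode_quality(qualities: Sequence[int]) -> str:
    """Encode integer phred scores as a phred+33 ASCII string."""
    for i, q in enumerate(qualities):
        if not (QUAL_MIN <= q <= QUAL_MAX):
            raise FormatError(
                f"quality value {q} at position {i} outside "
                f"[{QUAL_MIN}, {QUAL_MAX}]"
            )
    return "".join(chr(q + PHRED_OFFSET) for q in qualities)


def _open_text(path: PathLike, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: PathLike) -> Iterator[SeqRecord]:
    """Yield SeqRecords from a (possibly gzipped, possibly multi-line) FASTA."""
    with _open_text(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            yield SeqRecord(id=title.split()[0], sequence=seq.upper())


def write_fasta(records: Iterable[SeqRecord], path: PathLike) -> None:
    """Write records as single-line FASTA."""
    with _open_text(path, "wt") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n{rec.sequence}\n")


def read_fastq(path: PathLike) -> Iterator[ReadRecord]:
    """Yield ReadRecords from a 4-line FASTQ file.

    Truncated records and sequence/quality length mismatches raise
    FormatError.
    """
    with _open_text(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                yield ReadRecord(
                    id=title,
                    sequence=seq.upper(),
                    qualities=tuple(decode_quality(qual)),
                )
        except ValueError as exc:  # Biopython signals malformed records
            raise FormatError(str(exc)) from exc


def write_fastq(records: Iterable[ReadRecord], path: PathLike) -> None:
    with _open_text(path, "wt") as handle:
        for rec in records:
            handle.write(
                f"@{rec.id}\n{rec.sequence}\n+\n{encode_quality(rec.qualities)}\n"
            )
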