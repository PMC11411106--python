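"""FASTQ reading and writing with transparent gzip support.

Reads are modelled as lightweight :class:`ReadRecord` objects.  Quality
strings are carried through untouched — no downstream computation in this
package ever consults base qualities, but round-tripping a FASTQ must
preserve them.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = ["ReadRecord", "read_fastq", "write_fastq", "open_maybe_gzip"]

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class ReadRecord:
    """A single sequencing read.

    Parameters
    ----------
    read_id : str
        Identifier (FASTQ header without the leading ``@``).
    sequence : str
        DNA over the alphabet ``{A, C, G, T, N}``.
    quality : str or None
        Phred quality string of the same length, or ``None`` for
        synthetic reads that never had qualities.
    """

    read_id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def open_maybe_gzip(path: Union[str, Path], mode: str = "rt") -> IO:
    """Open *path*, decompressing transparently when it ends in ``.gz``."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: Union[str, Path]) -> Iterator[ReadRecord]:
    """Stream :class:`ReadRecord` objects from a (possibly gzipped) FASTQ.

    Malformed records raise ``ValueError`` naming the record index.
    """
    with open_maybe_gzip(path) as handle:
        index = 0
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                seq = seq.upper()
                yield ReadRecord(title.split()[0], seq, qual)
                index += 1
        except ValueError as exc:  # Biopython signals malformed records this way
            raise ValueError(f"malformed FASTQ record at index {index}: {exc}") from exc


def write_fastq(reads: Iterable[ReadRecord], path: Union[str, Path]) -> int:
    """Write *reads* as 4-line FASTQ records; returns the number written.

    Reads without qualities get a constant placeholder (``I``, Q40).
    """
    n = 0
    with open_maybe_gzip(path, "wt") as handle:
        for read in reads:
            qual = read.quality if read.quality is not None else "I" * len(read)
            handle.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")
            n += 1
    return n
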