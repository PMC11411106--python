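"""Read filtering for post-host-removal ancient-metagenome FASTQs.

Ancient-DNA metagenome pipelines keep only short fragments (long reads are
likely modern contamination, very short reads are unmappable/unclassifiable),
trim a few bases off both read ends where deamination damage concentrates,
and drop low-complexity sequence that confounds k-mer comparisons.  This
module reproduces that filtering stage with explicit bookkeeping:

1. length window (defaults 30–80 bp, bounds inclusive),
2. fixed-width trimming of both ends (default 4 bp),
3. re-application of the minimum length to the trimmed read,
4. linguistic-complexity filter (distinct k-mer fraction, default
   threshold 0.7 with k=4).

A seeded uniform subsampler is provided for depth normalisation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .fastq import ReadRecord

__all__ = [
    "QCParams",
    "QCReport",
    "linguistic_complexity",
    "filter_by_length",
    "trim_ends",
    "subsample_reads",
    "run_qc",
]


@dataclass(frozen=True)
class QCParams:
    min_len: int = 30
    max_len: int = 80
    trim_each_end: int = 4
    complexity_k: int = 4
    complexity_threshold: float = 0.7

    def __post_init__(self) -> None:
        if self.trim_each_end < 0:
            raise ValueError("trim_each_end must be >= 0")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if not 0.0 <= self.complexity_threshold <= 1.0:
            raise ValueError("complexity_threshold must lie in [0, 1]")


@dataclass
class QCReport:
    """Per-rule removal counts; ``reads_in == reads_out + sum(removals)``."""

    reads_in: int = 0
    removed_length: int = 0
    removed_short_after_trim: int = 0
    removed_complexity: int = 0
    trimmed: int = 0
    reads_out: int = 0
    params: QCParams = field(default_factory=QCParams)

    @property
    def total_removed(self) -> int:
        return self.removed_length + self.removed_short_after_trim + self.removed_complexity

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def log_lines(self) -> list[str]:
        return [
            f"reads in:                  {self.reads_in}",
            f"removed (length window):   {self.removed_length}",
            f"removed (short after trim):{self.removed_short_after_trim}",
            f"removed (low complexity):  {self.removed_complexity}",
            f"trimmed:                   {self.trimmed}",
            f"reads out:                 {self.reads_out}",
        ]


def linguistic_complexity(sequence: str, k: int = 4) -> float:
    """Distinct-k-mer fraction of a sequence, in [0, 1].

    score = (# distinct k-mers) / min(len - k + 1, 4**k).  Windows
    containing ``N`` are excluded from the numerator only; a sequence
    shorter than *k* scores 0 (flagged low-complexity).
    """
    n_windows = len(sequence) - k + 1
    if n_windows < 1:
        return 0.0
    seen = set()
    for i in range(n_windows):
        kmer = sequence[i : i + k]
        if "N" not in kmer:
            seen.add(kmer)
    return len(seen) / min(n_windows, 4**k)


def filter_by_length(
    reads: Iterable[ReadRecord], min_len: int = 30, max_len: int = 80
) -> list[ReadRecord]:
    """Keep reads with min_len <= len <= max_len (inclusive), input order."""
    return [r for r in reads if min_len <= len(r) <= max_len]


def trim_ends(read: ReadRecord, n_bases: int) -> ReadRecord | None:
    """Remove *n_bases* from both ends; ``None`` when nothing remains."""
    if n_bases == 0:
        return read
    if len(read) <= 2 * n_bases:
        return None
    seq = read.sequence[n_bases:-n_bases]
    qual = read.quality[n_bases:-n_bases] if read.quality is not None else None
    return ReadRecord(read.read_id, seq, qual)


def subsample_reads(
    reads: Sequence[ReadRecord], n: int, seed: int
) -> list[ReadRecord]:
    """Uniform sample of min(n, len(reads)) reads without replacement.

    Deterministic for a given (input, n, seed); output preserves input
    order so repeated runs are byte-identical on disk.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    total = len(reads)
    if n >= total:
        return list(reads)
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(total, size=n, replace=False))
    return [reads[i] for i in keep]


def run_qc(
    reads: Iterable[ReadRecord], params: QCParams | None = None
) -> tuple[list[ReadRecord], QCReport]:
    """Apply the full filter cascade; returns surviving reads and a report.

    Order: length window -> end trimming -> minimum-length re-check ->
    complexity filter.  The order is fixed here and exposed only through
    the parameters (set ``trim_each_end=0`` to make the stage idempotent).
    """
    params = params or QCParams()
    report = QCReport(params=params)
    out: list[ReadRecord] = []
    for read in reads:
        report.reads_in += 1
        if not params.min_len <= len(read) <= params.max_len:
            report.removed_length += 1
            continue
        trimmed = trim_ends(read, params.trim_each_end)
        if params.trim_each_end > 0:
            report.trimmed += 1
        if trimmed is None or len(trimmed) < params.min_len:
            report.removed_short_after_trim += 1
            continue
        score = linguistic_complexity(trimmed.sequence, params.complexity_k)
        if score < params.complexity_threshold:
            report.removed_complexity += 1
            continue
        out.append(trimmed)
    report.reads_out = len(out)
    # trimmed counts reads that entered the trimming step, including ones
    # later removed; reconcile so conservation always holds
    assert report.reads_in == report.reads_out + report.total_removed
    return out, report
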