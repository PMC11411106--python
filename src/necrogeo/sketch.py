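"""Abundance-weighted fractional MinHash sketches and angular similarity.

A sketch retains every canonical k-mer whose 64-bit hash falls below
``2**64 / scaled``, i.e. an unbiased ~1/scaled sample of the distinct
k-mer space, together with the observation count of each retained hash
("abundance").  Two samples are compared by the cosine of their retained
abundance vectors, mapped to the angular similarity

    A = 1 - 2 * arccos(cos_sim) / pi  in [0, 1],

so identical abundance profiles score 1 and k-mer-disjoint samples score 0.

Hashing is a splitmix64 finalizer applied to the 2-bit encoding of the
canonical k-mer (XORed with a seeded constant), computed fully vectorised
in numpy; correctness is anchored by the scaled=1 regime, where the sketch
is an exact canonical k-mer count table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

import numpy as np
import pandas as pd

from .fastq import ReadRecord

__all__ = [
    "SketchParams",
    "AbundanceSketch",
    "SimilarityMatrix",
    "canonical_kmers",
    "sketch_reads",
    "sketch_sequences",
    "angular_similarity",
    "compare_all",
]

SUPPORTED_K_SWEEP = (11, 15, 21, 25, 31)

_COMP = str.maketrans("ACGT", "TGCA")

# base -> 2-bit code; anything else (N, padding) -> 255
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass(frozen=True)
class SketchParams:
    """Sketching parameters; two sketches are comparable iff these match."""

    k: int = 21
    scaled: int = 1000
    hash_seed: int = 42
    canonical: bool = True
    track_abundance: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k > 31:
            raise ValueError("k > 31 exceeds the 64-bit 2-bit encoding")
        if self.scaled < 1:
            raise ValueError("scaled must be >= 1")

    @property
    def max_hash(self) -> int:
        """Retention threshold T = floor(2**64 / scaled)."""
        return (1 << 64) // self.scaled


@dataclass
class AbundanceSketch:
    sample_id: str
    params: SketchParams
    hash_counts: dict[int, int] = field(default_factory=dict)
    n_kmers_processed: int = 0

    def __len__(self) -> int:
        return len(self.hash_counts)

    def _arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Sorted (hashes, counts) arrays for fast set intersection."""
        if not self.hash_counts:
            return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.float64)
        hashes = np.fromiter(self.hash_counts.keys(), dtype=np.uint64, count=len(self.hash_counts))
        counts = np.fromiter(self.hash_counts.values(), dtype=np.float64, count=len(self.hash_counts))
        order = np.argsort(hashes)
        return hashes[order], counts[order]

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "sample_id": self.sample_id,
            "params": {
                "k": self.params.k,
                "scaled": self.params.scaled,
                "hash_seed": self.params.hash_seed,
                "canonical": self.params.canonical,
                "track_abundance": self.params.track_abundance,
            },
            "n_kmers_processed": self.n_kmers_processed,
            "hashes": sorted((int(h), int(c)) for h, c in self.hash_counts.items()),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "AbundanceSketch":
        payload = json.loads(Path(path).read_text())
        return cls(
            sample_id=payload["sample_id"],
            params=SketchParams(**payload["params"]),
            hash_counts={int(h): int(c) for h, c in payload["hashes"]},
            n_kmers_processed=int(payload["n_kmers_processed"]),
        )


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def canonical_kmers(sequence: str, k: int) -> Iterator[str]:
    """Yield the canonical form of every valid k-length window.

    The canonical form is the lexicographic minimum of the window and its
    reverse complement; windows containing characters outside {A,C,G,T}
    are skipped.  Reference implementation — the sketching path uses an
    equivalent vectorised 2-bit encoding.
    """
    valid = frozenset("ACGT")
    for i in range(len(sequence) - k + 1):
        window = sequence[i : i + k]
        if not valid.issuperset(window):
            continue
        rc = _revcomp(window)
        yield min(window, rc)


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """Vectorised splitmix64 finalizer (wrapping uint64 arithmetic)."""
    z = x + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


def _seed_constant(seed: int) -> np.uint64:
    return _splitmix64(np.array([seed], dtype=np.uint64))[0]


def _encode_canonical(codes: np.ndarray, k: int, canonical: bool) -> np.ndarray:
    """Canonical k-mer integer codes for every valid window of *codes*.

    *codes* is a uint8 array of 2-bit base codes with 255 marking invalid
    positions (N or record separators); windows touching an invalid
    position are dropped.
    """
    n = codes.shape[0] - k + 1
    if n < 1:
        return np.empty(0, dtype=np.uint64)
    invalid = codes == 255
    bad = np.cumsum(invalid)
    window_bad = bad[k - 1 :].copy()
    window_bad[1:] -= bad[:-k]
    valid_mask = window_bad == 0

    safe = np.where(invalid, 0, codes).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | safe[j : j + n]
    if not canonical:
        return fwd[valid_mask]
    comp = np.uint64(3) - safe
    rev = np.zeros(n, dtype=np.uint64)
    for j in range(k):  # reverse complement, read 3'->5'
        rev = (rev << np.uint64(2)) | comp[k - 1 - j : k - 1 - j + n]
    return np.minimum(fwd, rev)[valid_mask]


def _kmer_codes_from_sequences(
    sequences: Iterable[str], k: int, canonical: bool
) -> np.ndarray:
    """Concatenate sequences (separator-protected) and encode all windows."""
    joined = "\x00".join(sequences)
    if not joined:
        return np.empty(0, dtype=np.uint64)
    raw = np.frombuffer(joined.encode("ascii"), dtype=np.uint8)
    return _encode_canonical(_CODE[raw], k, canonical)


def sketch_sequences(
    sequences: Iterable[str],
    params: SketchParams,
    sample_id: str = "sample",
) -> AbundanceSketch:
    """Sketch an iterable of DNA strings (the workhorse behind sketch_reads)."""
    codes = _kmer_codes_from_sequences(sequences, params.k, params.canonical)
    n_kmers = int(codes.shape[0])
    hashes = _splitmix64(codes ^ _seed_constant(params.hash_seed))
    if params.scaled > 1:
        hashes = hashes[hashes < np.uint64(params.max_hash)]
    uniq, counts = np.unique(hashes, return_counts=True)
    if not params.track_abundance:
        counts = np.ones_like(counts)
    sketch = AbundanceSketch(
        sample_id=sample_id,
        params=params,
        hash_counts=dict(zip(uniq.tolist(), counts.tolist())),
        n_kmers_processed=n_kmers,
    )
    if n_kmers and not sketch.hash_counts:
        warnings.warn(f"sample {sample_id!r}: no hashes retained (scaled too large?)")
    return sketch


def sketch_reads(
    reads: Iterable[ReadRecord],
    params: SketchParams | None = None,
    sample_id: str = "sample",
) -> AbundanceSketch:
    """Build an abundance sketch from reads."""
    params = params or SketchParams()
    return sketch_sequences((r.sequence for r in reads), params, sample_id)


def angular_similarity(a: AbundanceSketch, b: AbundanceSketch) -> float:
    """Angular similarity 1 - 2*arccos(c)/pi of the two abundance vectors.

    The cosine c is taken over the union of retained hashes (absent
    hashes count 0); with non-negative counts c lies in [0, 1] up to
    float error, which is clamped.
    """
    if a.params != b.params:
        raise ValueError(
            f"sketch parameter mismatch between {a.sample_id!r} and {b.sample_id!r}"
        )
    if not a.hash_counts and not b.hash_counts:
        warnings.warn(
            f"both sketches empty ({a.sample_id!r}, {b.sample_id!r}); similarity defined as 0"
        )
        return 0.0
    ha, ca = a._arrays()
    hb, cb = b._arrays()
    return _angular_from_arrays(ha, ca, hb, cb)


def _angular_from_arrays(
    ha: np.ndarray, ca: np.ndarray, hb: np.ndarray, cb: np.ndarray
) -> float:
    if ha.size == 0 or hb.size == 0:
        return 0.0
    common, ia, ib = np.intersect1d(ha, hb, assume_unique=True, return_indices=True)
    dot = float(np.dot(ca[ia], cb[ib])) if common.size else 0.0
    norm = float(np.linalg.norm(ca) * np.linalg.norm(cb))
    cos = min(max(dot / norm, 0.0), 1.0)
    return 1.0 - 2.0 * np.arccos(cos) / np.pi


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise angular similarities among named samples."""

    sample_ids: list[str]
    values: np.ndarray  # (n, n) float64 in [0, 1]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match sample_ids")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.sample_ids)

    def to_csv(self, path: Union[str, Path]) -> None:
        # header row of sample ids, then the raw matrix; full float repr
        # so the round-trip is lossless
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "SimilarityMatrix":
        df = pd.read_csv(path)
        return cls(sample_ids=[str(c) for c in df.columns], values=df.to_numpy())

    def subset(self, ids: Sequence[str]) -> "SimilarityMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([index[s] for s in ids])
        return SimilarityMatrix(list(ids), self.values[np.ix_(idx, idx)])


def compare_all(sketches: Sequence[AbundanceSketch]) -> SimilarityMatrix:
    """All-vs-all angular similarity matrix; diagonal 1 for non-empty sketches."""
    if len(sketches) < 2:
        raise ValueError("need at least 2 sketches to compare")
    ids = [s.sample_id for s in sketches]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_ids among sketches")
    first = sketches[0].params
    for s in sketches[1:]:
        if s.params != first:
            raise ValueError(f"sketch parameter mismatch for {s.sample_id!r}")
    arrays = [s._arrays() for s in sketches]
    n = len(sketches)
    S = np.eye(n)
    for i in range(n):
        if arrays[i][0].size == 0:
            S[i, i] = 0.0  # empty sketch: similarity undefined, reported 0
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = _angular_from_arrays(*arrays[i], *arrays[j])
    return SimilarityMatrix(ids, S)
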