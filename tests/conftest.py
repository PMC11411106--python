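"""Shared fixtures: small simulated datasets and oracle helpers."""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pytest

from necrogeo.fastq import ReadRecord
from necrogeo.sketch import canonical_kmers


def brute_force_angular(seqs_a, seqs_b, k):
    """Independent oracle: full canonical k-mer counts, cosine -> angular.

    No hashing, no retention — pure string counting.
    """
    ca = Counter(km for s in seqs_a for km in canonical_kmers(s, k))
    cb = Counter(km for s in seqs_b for km in canonical_kmers(s, k))
    keys = set(ca) | set(cb)
    dot = sum(ca[x] * cb[x] for x in keys)
    na = math.sqrt(sum(v * v for v in ca.values()))
    nb = math.sqrt(sum(v * v for v in cb.values()))
    if na == 0 or nb == 0:
        return 0.0
    cos = min(max(dot / (na * nb), 0.0), 1.0)
    return 1.0 - 2.0 * math.acos(cos) / math.pi


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


def random_reads(rng, n, length=60, prefix="r"):
    bases = np.array(list("ACGT"))
    return [
        ReadRecord(f"{prefix}{i}", "".join(rng.choice(bases, size=length)))
        for i in range(n)
    ]


@pytest.fixture
def small_reads(rng):
    return random_reads(rng, 30)


@pytest.fixture(scope="session")
def logit_fixture():
    """Fixed 40x3 non-separable logistic fixture with known generator."""
    gen = np.random.default_rng(42)
    X = gen.standard_normal((40, 3))
    eta = 0.8 * X[:, 0] - 0.5 * X[:, 1] + 0.2
    y = (gen.random(40) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    labels = ["pos" if v else "neg" for v in y]
    return X, y, labels
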