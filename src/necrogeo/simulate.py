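"""Seeded simulator of necrobiome-like shotgun datasets.

The generator emulates the statistical structure the geographic
classifier relies on, without pretending to be a sequence-realistic read
simulator:

* a "world" of random taxon genomes with a shared Dirichlet base
  abundance profile;
* per-location profiles obtained by log-normal tilting of the base
  profile (``exp(divergence * z)`` per taxon, renormalised), so a single
  scalar controls how distinguishable two burial locations are;
* an extraction-protocol batch effect as a second log-normal tilt on a
  protocol-affected subset of taxa (drawn from non-marker taxa, so a
  marker-genus restriction suppresses it);
* an oral-contamination admixture for tooth samples;
* per-read 5' C->T deamination damage with geometric decay along the
  read, uniform sequencing error, and optional reverse-complement
  emission;
* truth manifests (per-read source taxon) for every sample.

All randomness flows from one master seed; each sample's stream is
derived from (master seed, sample index) so any sample can be
regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .fastq import ReadRecord, write_fastq
from .taxa import TaxaTable

__all__ = [
    "WorldConfig",
    "World",
    "SampleSpec",
    "SimulatedDataset",
    "make_world",
    "simulate_sample",
    "simulate_dataset",
    "simulate_taxa_table",
    "make_specs",
    "derive_sample_seed",
]

MARKER_GENUS_ID = 1883  # pseudo-id for the marker soil genus
ORAL_GENUS_ID = 724  # pseudo-id for the oral-contaminant group
OTHER_GENUS_ID = 9999

_BASE_LOOKUP = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of the simulated microbial world."""

    n_taxa: int = 150
    genome_len: int = 5000
    n_locations: int = 2
    divergence: float = 1.0
    dirichlet_concentration: float = 1.0
    marker_genus_fraction: float = 0.15
    oral_taxa_fraction: float = 0.10
    protocol_bias_strength: float = 0.0
    protocol_affected_fraction: float = 0.30
    n_protocols: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("marker_genus_fraction", "oral_taxa_fraction", "protocol_affected_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be > 0")


@dataclass
class World:
    """A realised world: genomes, labels, profiles, batch-effect factors."""

    config: WorldConfig
    genomes: np.ndarray  # (n_taxa, genome_len) uint8 2-bit codes
    taxon_ids: np.ndarray  # (n_taxa,) int, 1-based
    is_marker: np.ndarray  # (n_taxa,) bool
    is_oral: np.ndarray  # (n_taxa,) bool
    location_profiles: np.ndarray  # (n_locations, n_taxa), rows sum to 1
    protocol_factors: np.ndarray  # (n_protocols, n_taxa) multiplicative

    @property
    def lineages(self) -> dict[int, str]:
        """Minimal genus-level lineage strings for descendant matching."""
        out = {}
        for i, tid in enumerate(self.taxon_ids):
            if self.is_marker[i]:
                genus = MARKER_GENUS_ID
            elif self.is_oral[i]:
                genus = ORAL_GENUS_ID
            else:
                genus = OTHER_GENUS_ID
            out[int(tid)] = f"2;{genus};{int(tid)}"
        return out

    def effective_profile(
        self,
        location: int,
        protocol: int = 0,
        oral_mix: float = 0.0,
    ) -> np.ndarray:
        """Taxon sampling probabilities for a sample's covariates."""
        prof = self.location_profiles[location] * self.protocol_factors[protocol]
        prof = prof / prof.sum()
        if oral_mix > 0 and self.is_oral.any():
            oral = prof * self.is_oral
            oral = oral / oral.sum()
            prof = (1.0 - oral_mix) * prof + oral_mix * oral
        return prof


def make_world(config: WorldConfig) -> World:
    """Realise a world from its configuration (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_taxa
    genomes = rng.integers(0, 4, size=(n, config.genome_len), dtype=np.uint8)
    base = rng.dirichlet(np.full(n, config.dirichlet_concentration))
    z = rng.standard_normal((config.n_locations, n))
    profiles = base * np.exp(config.divergence * z)
    profiles /= profiles.sum(axis=1, keepdims=True)

    perm = rng.permutation(n)
    n_marker = int(round(config.marker_genus_fraction * n))
    n_oral = int(round(config.oral_taxa_fraction * n))
    is_marker = np.zeros(n, dtype=bool)
    is_marker[perm[:n_marker]] = True
    is_oral = np.zeros(n, dtype=bool)
    is_oral[perm[n_marker : n_marker + n_oral]] = True

    # protocol bias hits non-marker taxa only: restricting analysis to the
    # marker genus is then, by construction, batch-effect free
    factors = np.ones((config.n_protocols, n))
    if config.protocol_bias_strength > 0:
        non_marker = np.flatnonzero(~is_marker)
        n_affected = int(round(config.protocol_affected_fraction * n))
        affected = rng.choice(non_marker, size=min(n_affected, non_marker.size), replace=False)
        for p in range(1, config.n_protocols):
            zp = rng.standard_normal(affected.size)
            factors[p, affected] = np.exp(config.protocol_bias_strength * zp)
    return World(
        config=config,
        genomes=genomes,
        taxon_ids=np.arange(1, n + 1),
        is_marker=is_marker,
        is_oral=is_oral,
        location_profiles=profiles,
        protocol_factors=factors,
    )


@dataclass(frozen=True)
class SampleSpec:
    """Covariates and noise settings for one simulated sample."""

    sample_id: str
    location: int
    protocol: int = 0
    sample_type: str = "bone"
    depth: int = 10_000
    min_len: int = 30
    max_len: int = 80
    oral_mix: float = 0.0
    damage_rate: float = 0.0
    damage_decay: float = 0.5
    error_rate: float = 0.0
    emit_revcomp: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        for name in ("oral_mix", "damage_rate", "damage_decay", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def derive_sample_seed(master_seed: int, sample_index: int) -> int:
    """Per-sample seed from the master seed and the sample's index."""
    return int(np.random.SeedSequence([master_seed, sample_index]).generate_state(1)[0])


def _draw_taxa(world: World, spec: SampleSpec, rng: np.random.Generator) -> np.ndarray:
    profile = world.effective_profile(spec.location, spec.protocol, spec.oral_mix)
    return rng.choice(world.config.n_taxa, size=spec.depth, p=profile)


def simulate_sample(
    world: World, spec: SampleSpec
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Draw one sample's reads and its truth manifest.

    Returns exactly ``spec.depth`` reads (uniform lengths on
    [min_len, max_len], uniform genome start positions) and a manifest
    DataFrame with columns ``read_id, taxon_id``.
    """
    if spec.location >= world.config.n_locations or spec.protocol >= world.config.n_protocols:
        raise ValueError(f"sample {spec.sample_id!r} references unknown location/protocol")
    rng = np.random.default_rng(spec.seed)
    depth = spec.depth
    taxa = _draw_taxa(world, spec, rng)
    if depth == 0:
        return [], pd.DataFrame({"read_id": [], "taxon_id": []})

    glen = world.config.genome_len
    max_len = min(spec.max_len, glen)
    lengths = rng.integers(spec.min_len, max_len + 1, size=depth)
    starts = (rng.random(depth) * (glen - lengths + 1)).astype(np.int64)
    offsets = np.arange(max_len)
    pos = np.minimum(starts[:, None] + offsets[None, :], glen - 1)
    mat = world.genomes.reshape(-1)[taxa[:, None].astype(np.int64) * glen + pos]
    valid = offsets[None, :] < lengths[:, None]

    if spec.emit_revcomp:
        flip = rng.random(depth) < 0.5
        rev_idx = np.maximum(lengths[:, None] - 1 - offsets[None, :], 0)
        rev_mat = 3 - np.take_along_axis(mat, rev_idx, axis=1)
        mat = np.where(flip[:, None] & valid, rev_mat, mat)

    if spec.damage_rate > 0:
        # C->T at 5' offset j with probability damage_rate * decay**j
        p_dam = spec.damage_rate * spec.damage_decay ** offsets
        hit = (mat == 1) & (rng.random((depth, max_len)) < p_dam[None, :]) & valid
        mat[hit] = 3

    if spec.error_rate > 0:
        emask = (rng.random((depth, max_len)) < spec.error_rate) & valid
        shifts = rng.integers(1, 4, size=(depth, max_len), dtype=np.uint8)
        mat = np.where(emask, (mat + shifts) % 4, mat)

    bases = _BASE_LOOKUP[mat]
    read_ids = [f"{spec.sample_id}:r{i}" for i in range(depth)]
    reads = [
        ReadRecord(read_ids[i], bytes(bases[i, : lengths[i]]).decode("ascii"))
        for i in range(depth)
    ]
    manifest = pd.DataFrame(
        {"read_id": read_ids, "taxon_id": world.taxon_ids[taxa]}
    )
    return reads, manifest


def simulate_taxa_table(
    world: World,
    specs: Sequence[SampleSpec],
    classified_fraction: float = 1.0,
    seed: int = 0,
) -> TaxaTable:
    """Taxa-by-sample counts as an external read classifier would report.

    Taxon draws replay each sample's own stream, so with
    ``classified_fraction=1`` the counts equal the read manifests
    exactly; lower fractions thin each count binomially, emulating reads
    the classifier could not place.
    """
    if not 0.0 <= classified_fraction <= 1.0:
        raise ValueError("classified_fraction must lie in [0, 1]")
    thin_rng = np.random.default_rng(seed)
    cols = {}
    for spec in specs:
        rng = np.random.default_rng(spec.seed)
        counts = np.bincount(_draw_taxa(world, spec, rng), minlength=world.config.n_taxa)
        if classified_fraction < 1.0:
            counts = thin_rng.binomial(counts, classified_fraction)
        cols[spec.sample_id] = counts
    df = pd.DataFrame(cols, index=pd.Index(world.taxon_ids, name="taxon_id"))
    lineage = pd.Series(world.lineages).reindex(df.index).astype(str)
    return TaxaTable(df, lineage)


def make_specs(
    config: WorldConfig,
    n_per_location: int,
    depth: int,
    damage_rate: float = 0.0,
    error_rate: float = 0.0,
    tooth_oral_mix: float = 0.2,
    alternate_protocols: bool = True,
) -> list[SampleSpec]:
    """A balanced design: locations x alternating protocols x sample types.

    Within every location half the samples get each protocol and sample
    types alternate, so covariates correlate only partially with
    geography — mirroring the confounding structure of real
    multi-study panels.
    """
    specs = []
    idx = 0
    for loc in range(config.n_locations):
        for j in range(n_per_location):
            protocol = (j % config.n_protocols) if alternate_protocols else 0
            sample_type = "tooth" if j % 2 else "bone"
            specs.append(
                SampleSpec(
                    sample_id=f"L{loc}S{j:02d}",
                    location=loc,
                    protocol=protocol,
                    sample_type=sample_type,
                    depth=depth,
                    oral_mix=tooth_oral_mix if sample_type == "tooth" else 0.0,
                    damage_rate=damage_rate,
                    error_rate=error_rate,
                    seed=derive_sample_seed(config.seed, idx),
                )
            )
            idx += 1
    return specs


@dataclass
class SimulatedDataset:
    world: World
    specs: list[SampleSpec]
    samples: dict[str, list[ReadRecord]] = field(repr=False)
    manifests: dict[str, pd.DataFrame] = field(repr=False)
    metadata: pd.DataFrame = field(repr=False)


def simulate_dataset(
    config: WorldConfig,
    specs: Sequence[SampleSpec],
    out_dir: Union[str, Path, None] = None,
) -> SimulatedDataset:
    """Simulate all samples of a design; optionally write them to disk.

    On disk: ``<sample>.fastq`` per sample, ``metadata.tsv`` (sample_id,
    location, protocol, sample_type, read_count) and per-sample truth
    manifests under ``truth/``.  Holds all reads in memory — for large
    designs iterate :func:`simulate_sample` instead.
    """
    ids = [s.sample_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in design")
    world = make_world(config)
    samples: dict[str, list[ReadRecord]] = {}
    manifests: dict[str, pd.DataFrame] = {}
    meta_rows = []
    for spec in specs:
        reads, manifest = simulate_sample(world, spec)
        samples[spec.sample_id] = reads
        manifests[spec.sample_id] = manifest
        meta_rows.append(
            {
                "sample_id": spec.sample_id,
                "location": f"loc{spec.location}",
                "protocol": f"protocol{spec.protocol}",
                "sample_type": spec.sample_type,
                "read_count": len(reads),
            }
        )
    metadata = pd.DataFrame(meta_rows)
    dataset = SimulatedDataset(world, list(specs), samples, manifests, metadata)
    if out_dir is not None:
        out = Path(out_dir)
        (out / "truth").mkdir(parents=True, exist_ok=True)
        for sid in ids:
            write_fastq(samples[sid], out / f"{sid}.fastq")
            manifests[sid].to_csv(out / "truth" / f"{sid}.manifest.tsv", sep="\t", index=False)
        metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
        simulate_taxa_table(world, list(specs)).to_tsv(out / "truth" / "taxa_table.tsv")
    return dataset
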