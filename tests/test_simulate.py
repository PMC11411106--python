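"""Synthetic necrobiome generator: profiles, reads, damage, truth tables."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from necrogeo.simulate import (
    SampleSpec,
    WorldConfig,
    derive_sample_seed,
    make_specs,
    make_world,
    simulate_dataset,
    simulate_sample,
    simulate_taxa_table,
)

_COMP = str.maketrans("ACGT", "TGCA")


def genome_string(world, taxon_index):
    return bytes(np.frombuffer(b"ACGT", dtype=np.uint8)[world.genomes[taxon_index]]).decode()


class TestMakeWorld:
    def test_zero_divergence_gives_identical_profiles(self):
        world = make_world(WorldConfig(divergence=0.0, seed=1))
        assert np.allclose(world.location_profiles[0], world.location_profiles[1])

    def test_same_seed_same_world(self):
        a = make_world(WorldConfig(seed=9))
        b = make_world(WorldConfig(seed=9))
        assert np.array_equal(a.genomes, b.genomes)
        assert np.array_equal(a.location_profiles, b.location_profiles)

    def test_profiles_are_distributions(self):
        world = make_world(WorldConfig(seed=2))
        assert np.allclose(world.location_profiles.sum(axis=1), 1.0)
        assert (world.location_profiles >= 0).all()

    def test_profile_divergence_monotone_in_delta(self):
        """KL between location profiles grows with the divergence scale."""

        def kl(p, q):
            return float(np.sum(p * np.log(p / q)))

        mean_kl = []
        for delta in (0.0, 0.25, 0.5, 1.0):
            vals = []
            for seed in range(5):
                w = make_world(WorldConfig(n_taxa=80, divergence=delta, seed=seed))
                vals.append(kl(w.location_profiles[0], w.location_profiles[1]))
            mean_kl.append(np.mean(vals))
        assert all(a < b for a, b in zip(mean_kl, mean_kl[1:]))

    def test_protocol_bias_restricted_to_non_marker_taxa(self):
        w = make_world(WorldConfig(protocol_bias_strength=1.0, seed=3))
        biased = w.protocol_factors[1] != 1.0
        assert biased.any()
        assert not (biased & w.is_marker).any()


class TestSimulateSample:
    def test_exact_depth_and_manifest_bookkeeping(self):
        world = make_world(WorldConfig(seed=4))
        spec = SampleSpec("s0", location=0, depth=500, seed=11)
        reads, manifest = simulate_sample(world, spec)
        assert len(reads) == 500
        assert len(manifest) == 500
        assert manifest["read_id"].tolist() == [r.read_id for r in reads]

    def test_noise_free_reads_are_genome_substrings(self):
        world = make_world(WorldConfig(n_taxa=10, genome_len=800, seed=5))
        spec = SampleSpec("s0", location=0, depth=200, seed=12)
        reads, manifest = simulate_sample(world, spec)
        genomes = {int(t): genome_string(world, i) for i, t in enumerate(world.taxon_ids)}
        for read, taxon in zip(reads, manifest["taxon_id"]):
            g = genomes[int(taxon)]
            rc = read.sequence.translate(_COMP)[::-1]
            assert read.sequence in g or rc in g

    def test_read_lengths_within_window(self):
        world = make_world(WorldConfig(seed=6))
        reads, _ = simulate_sample(world, SampleSpec("s", 0, depth=300, seed=1))
        lengths = {len(r) for r in reads}
        assert min(lengths) >= 30 and max(lengths) <= 80

    def test_taxon_shares_match_effective_profile(self):
        world = make_world(WorldConfig(n_taxa=30, seed=7))
        depth = 30_000
        spec = SampleSpec("s", location=1, depth=depth, seed=2)
        _, manifest = simulate_sample(world, spec)
        counts = manifest["taxon_id"].value_counts()
        profile = world.effective_profile(1)
        # check the 5 most abundant taxa against central 99% binomial bands
        for idx in np.argsort(profile)[-5:]:
            p = profile[idx]
            lo, hi = binom.ppf([0.005, 0.995], depth, p)
            assert lo <= counts.get(world.taxon_ids[idx], 0) <= hi

    def test_damage_is_c_to_t_with_geometric_decay(self):
        world = make_world(WorldConfig(n_taxa=5, genome_len=500, seed=8))
        world.genomes[:] = 1  # all-C genomes isolate the damage channel
        spec = SampleSpec(
            "s", 0, depth=4000, damage_rate=0.8, damage_decay=0.5,
            emit_revcomp=False, seed=3,
        )
        reads, _ = simulate_sample(world, spec)
        for j, expected in enumerate([0.8, 0.4, 0.2]):
            hits = sum(r.sequence[j] == "T" for r in reads)
            lo, hi = binom.ppf([0.0005, 0.9995], len(reads), expected)
            assert lo <= hits <= hi
        # nothing but C/T can occur
        assert set("".join(r.sequence for r in reads[:100])) <= {"C", "T"}

    def test_error_rate_uniform_along_read(self):
        world = make_world(WorldConfig(n_taxa=5, genome_len=500, seed=8))
        world.genomes[:] = 1
        spec = SampleSpec("s", 0, depth=4000, error_rate=0.1, emit_revcomp=False, seed=4)
        reads, _ = simulate_sample(world, spec)
        n_bases = sum(len(r) for r in reads)
        n_err = sum(sum(b != "C" for b in r.sequence) for r in reads)
        lo, hi = binom.ppf([0.0005, 0.9995], n_bases, 0.1)
        assert lo <= n_err <= hi

    def test_unknown_location_rejected(self):
        world = make_world(WorldConfig(seed=1))
        with pytest.raises(ValueError):
            simulate_sample(world, SampleSpec("s", location=7, depth=10))


class TestTaxaTableAndDataset:
    def test_full_classification_reproduces_manifest_counts(self):
        config = WorldConfig(n_taxa=40, seed=10)
        world = make_world(config)
        specs = [
            SampleSpec(f"s{i}", location=i % 2, depth=800, seed=derive_sample_seed(10, i))
            for i in range(4)
        ]
        table = simulate_taxa_table(world, specs, classified_fraction=1.0)
        for spec in specs:
            _, manifest = simulate_sample(world, spec)
            truth = manifest["taxon_id"].value_counts()
            col = table.counts[spec.sample_id]
            for tid in world.taxon_ids:
                assert col.loc[tid] == truth.get(tid, 0)

    def test_thinning_tracks_classified_fraction(self):
        config = WorldConfig(n_taxa=40, seed=10)
        world = make_world(config)
        specs = [SampleSpec("s0", 0, depth=20_000, seed=5)]
        table = simulate_taxa_table(world, specs, classified_fraction=0.6, seed=1)
        total = int(table.counts["s0"].sum())
        lo, hi = binom.ppf([0.005, 0.995], 20_000, 0.6)
        assert lo <= total <= hi

    def test_seeded_reproducibility(self):
        config = WorldConfig(n_taxa=20, seed=3)
        world = make_world(config)
        specs = [SampleSpec("s0", 0, depth=500, seed=7)]
        a = simulate_taxa_table(world, specs, classified_fraction=0.5, seed=2)
        b = simulate_taxa_table(world, specs, classified_fraction=0.5, seed=2)
        assert a.counts.equals(b.counts)

    def test_dataset_writes_files_and_metadata(self, tmp_path):
        config = WorldConfig(n_taxa=20, seed=3)
        specs = make_specs(config, n_per_location=2, depth=100)
        ds = simulate_dataset(config, specs, out_dir=tmp_path)
        assert sorted(ds.metadata.columns) == [
            "location", "protocol", "read_count", "sample_id", "sample_type",
        ]
        assert (ds.metadata["read_count"] == 100).all()
        for spec in specs:
            assert (tmp_path / f"{spec.sample_id}.fastq").exists()
            assert (tmp_path / "truth" / f"{spec.sample_id}.manifest.tsv").exists()
        assert (tmp_path / "metadata.tsv").exists()

    def test_duplicate_sample_ids_rejected(self):
        config = WorldConfig(seed=1)
        specs = [SampleSpec("dup", 0, depth=10), SampleSpec("dup", 1, depth=10)]
        with pytest.raises(ValueError, match="duplicate"):
            simulate_dataset(config, specs)

    def test_manifest_consistent_with_read_extraction(self):
        from necrogeo.taxa import extract_taxon_reads

        config = WorldConfig(n_taxa=25, seed=12)
        world = make_world(config)
        spec = SampleSpec("s0", 0, depth=600, seed=9)
        reads, manifest = simulate_sample(world, spec)
        assignment = dict(zip(manifest["read_id"], manifest["taxon_id"]))
        target = int(manifest["taxon_id"].mode()[0])
        out = extract_taxon_reads(reads, assignment, target)
        assert len(out) == int((manifest["taxon_id"] == target).sum())
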