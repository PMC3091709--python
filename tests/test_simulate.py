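"""Synthetic genome and enriched-library generators: truth fidelity."""

import numpy as np
import pytest

from conftest import brute_force_ssrs
from ssrrep.repeatscan import find_ssrs
from ssrrep.simulate import (
    ConfigError,
    EnrichmentSimConfig,
    GenomeSimConfig,
    recovery_experiment,
    simulate_enriched_reads,
    simulate_genome,
)
from ssrrep.tabulation import length_class


class TestConfigValidation:
    def test_saturation_guard(self):
        cfg = GenomeSimConfig(
            chromosome_lengths=(10_000,), intensity_per_mb=20_000.0
        )
        with pytest.raises(ConfigError):
            simulate_genome(cfg, 1)

    def test_bad_composition(self):
        cfg = GenomeSimConfig(base_composition=(0.5, 0.5, 0.5, -0.5))
        with pytest.raises(ConfigError):
            simulate_genome(cfg, 1)

    def test_short_chromosome(self):
        with pytest.raises(ConfigError):
            simulate_genome(GenomeSimConfig(chromosome_lengths=(500,)), 1)

    def test_scale_length_mismatch(self):
        cfg = GenomeSimConfig(
            chromosome_lengths=(10_000, 10_000), chromosome_scale=(1.0,)
        )
        with pytest.raises(ConfigError):
            simulate_genome(cfg, 1)

    def test_enrichment_validation(self):
        with pytest.raises(ConfigError):
            EnrichmentSimConfig(read_count=0).validate()
        with pytest.raises(ConfigError):
            EnrichmentSimConfig(capture_weight=-1.0).validate()


class TestSimulateGenome:
    def test_zero_intensity_plants_nothing(self):
        cfg = GenomeSimConfig(chromosome_lengths=(20_000,), intensity_per_mb=0.0)
        sim = simulate_genome(cfg, 5)
        assert sim.truth.empty
        assert len(sim.sequences["chr1"]) >= 20_000

    def test_deterministic(self):
        cfg = GenomeSimConfig(chromosome_lengths=(30_000,) * 2, intensity_per_mb=50.0)
        a, b = simulate_genome(cfg, 9), simulate_genome(cfg, 9)
        assert a.sequences == b.sequences
        assert a.truth.equals(b.truth) and a.sites.equals(b.sites)
        c = simulate_genome(cfg, 10)
        assert c.sequences != a.sequences

    def test_planted_count_poisson_bound(self):
        # expected 100/Mb over 2 Mb = 200 planted AC loci
        cfg = GenomeSimConfig(
            chromosome_lengths=(2_000_000,), motifs=("AC",), intensity_per_mb=100.0
        )
        sim = simulate_genome(cfg, 3)
        n = len(sim.truth) + sim.n_dropped
        assert abs(n - 200) <= 3 * np.sqrt(200)

    def test_scanner_recovers_every_planted_locus(self):
        cfg = GenomeSimConfig(chromosome_lengths=(120_000,) * 2, intensity_per_mb=80.0)
        sim = simulate_genome(cfg, 11)
        found = {
            (name, l.start, l.end, l.motif, l.repeats)
            for name, seq in sim.sequences.items()
            for l in find_ssrs(seq)
        }
        planted = {
            (r.chromosome, r.start, r.end, r.motif, r.repeats)
            for r in sim.truth.itertuples(index=False)
        }
        assert planted <= found

    def test_planted_sites_are_cut_sites(self):
        cfg = GenomeSimConfig(chromosome_lengths=(20_000,), site_rate_per_kb=2.0)
        sim = simulate_genome(cfg, 13)
        for r in sim.sites.itertuples(index=False):
            assert sim.sequences[r.chromosome][r.position - 1 : r.position + 3] == "GTAC"

    def test_truth_matches_bruteforce_on_tiny_genome(self):
        cfg = GenomeSimConfig(chromosome_lengths=(3_000,), intensity_per_mb=600.0)
        sim = simulate_genome(cfg, 17)
        seq = sim.sequences["chr1"]
        oracle = brute_force_ssrs(seq)
        for r in sim.truth.itertuples(index=False):
            assert (r.start, r.end, r.motif, r.repeats) in oracle


@pytest.fixture(scope="module")
def genome():
    cfg = GenomeSimConfig(chromosome_lengths=(150_000,) * 2, intensity_per_mb=60.0)
    return simulate_genome(cfg, 21)


class TestSimulateReads:

    def test_deterministic(self, genome):
        cfg = EnrichmentSimConfig(read_count=300)
        a = simulate_enriched_reads(genome.sequences, cfg, 2)
        b = simulate_enriched_reads(genome.sequences, cfg, 2)
        assert [r.sequence for r in a.reads] == [r.sequence for r in b.reads]
        assert a.truth.equals(b.truth)
        assert a.hit_rows() == b.hit_rows()

    def test_neutral_sampling_matches_fragment_classes(self, genome):
        """Uniform weights: read length classes mirror fragment classes."""
        from ssrrep.digestion import digest
        from ssrrep.repstats import chi2_gof

        cfg = EnrichmentSimConfig.neutral(read_count=4000)
        lib = simulate_enriched_reads(genome.sequences, cfg, 4)
        frag_classes = []
        for name, seq in genome.sequences.items():
            for f in digest(seq, chromosome_id=name):
                k = length_class(f.length)
                if k is not None:
                    frag_classes.append(k)
        labels, counts = np.unique(frag_classes, return_counts=True)
        p = counts / counts.sum()
        read_counts = lib.truth["length"].map(length_class).value_counts()
        obs = np.array([read_counts.get(lab, 0) for lab in labels])
        assert chi2_gof(obs, p).p_asymptotic > 1e-3

    def test_probe_capture_enriches_target_reads(self, genome):
        biased = EnrichmentSimConfig(
            probe_set=("AC",), capture_weight=100.0, background_weight=1.0,
            length_bias=(("80", 1.0), ("160", 1.0), ("240", 1.0), ("320", 1.0),
                         ("400", 1.0), ("other", 0.0)),
            read_count=1500,
        )
        neutral = EnrichmentSimConfig.neutral(probe_set=("AC",), read_count=1500)
        frac = {}
        for name, cfg in (("biased", biased), ("neutral", neutral)):
            lib = simulate_enriched_reads(genome.sequences, cfg, 6)
            with_ac = sum(
                any(l.motif == "AC" for l in find_ssrs(r.sequence))
                for r in lib.reads
            )
            frac[name] = with_ac / len(lib.reads)
        assert frac["biased"] > 2 * frac["neutral"]

    def test_zero_weight_errors(self, genome):
        cfg = EnrichmentSimConfig(
            capture_weight=0.0, background_weight=0.0, read_count=10
        )
        with pytest.raises(ConfigError):
            simulate_enriched_reads(genome.sequences, cfg, 1)

    def test_truncation_clips_reads(self, genome):
        cfg = EnrichmentSimConfig(
            read_count=200, truncate_at=120,
            length_bias=(("80", 1.0), ("160", 1.0), ("240", 1.0), ("320", 1.0),
                         ("400", 1.0), ("other", 1.0)),
        )
        lib = simulate_enriched_reads(genome.sequences, cfg, 8)
        assert max(r.length for r in lib.reads) <= 120


class TestRecoveryExperiment:
    def test_accounting_and_validation(self):
        gcfg = GenomeSimConfig(
            chromosome_lengths=(200_000,) * 2, intensity_per_mb=80.0,
            region_motif_factors=((3, "AC", 4.0),),
        )
        ecfg = EnrichmentSimConfig.neutral(read_count=2500)
        rep = recovery_experiment(gcfg, ecfg, 3, "AC", n_runs=2, seed=31)
        assert len(rep.runs) == rep.n_runs == 2
        assert 0 <= rep.n_detected <= rep.n_runs
        assert rep.n_other_cells == 2 * (80 - 1)
        with pytest.raises(ValueError):
            recovery_experiment(gcfg, ecfg, 3, "AC", n_runs=0, seed=1)
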