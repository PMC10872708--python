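"""Generator invariants: determinism, calibration, signatures, truth."""

import numpy as np
import pytest

from fgikit.seq_io import reverse_complement
from fgikit.synthetic_clade import (CladeConfig, ConfigError, IslandSpec,
                                    PlacementError, ReadSimConfig,
                                    codon_aware_mutate, generate_clade,
                                    read_truth, simulate_reads, write_truth)
from tests.conftest import small_clade_config


class TestConfigValidation:
    @pytest.mark.parametrize("field,value", [
        ("within_species_divergence", 0.0),
        ("within_species_divergence", 0.2),  # > between
        ("between_species_divergence", 0.5),
        ("ancestor_length", 10_000),
        ("gc_target", 0.1),
    ])
    def test_invariant_violations_rejected(self, field, value):
        cfg = small_clade_config()
        setattr(cfg, field, value)
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_island_size_range_bounds(self):
        cfg = small_clade_config()
        cfg.island_specs = [IslandSpec("replacement", 0.5, (100, 200))]
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_additive_floor_is_330(self):
        cfg = small_clade_config()
        cfg.island_specs = [IslandSpec("additive", 0.5, (330, 2000))]
        cfg.validate()

    def test_colliding_anchors_raise_placement_error(self):
        cfg = small_clade_config()
        cfg.island_specs = [
            IslandSpec("insertion", 0.5, (1000, 2000)),
            IslandSpec("insertion", 0.5001, (1000, 2000)),
        ]
        with pytest.raises(PlacementError):
            generate_clade(cfg)


class TestGeneration:
    def test_single_genome_no_islands(self):
        cfg = CladeConfig(seed=1, n_species=1, strains_per_species=1,
                          ancestor_length=50_000, island_specs=[])
        genomes, truth = generate_clade(cfg)
        assert len(genomes) == 1
        assert truth.islands[genomes[0].id] == []
        assert any(f.kind == "CDS" for f in genomes[0].features)

    def test_deterministic_for_fixed_seed(self):
        a, _ = generate_clade(small_clade_config(seed=5))
        b, _ = generate_clade(small_clade_config(seed=5))
        assert [g.sequence for g in a] == [g.sequence for g in b]
        assert [[(f.id, f.start, f.end) for f in g.features] for g in a] == \
               [[(f.id, f.start, f.end) for f in g.features] for g in b]

    def test_gc_within_1p5_points_of_target(self, small_clade):
        genomes, _ = small_clade
        for g in genomes:
            assert abs(g.gc - 0.37) < 0.015

    def test_core_identity_tracks_divergence(self, small_clade):
        """Pairwise core identity ~ 100*(1-d), cross-checked against the
        generator's own substitution log."""
        genomes, truth = small_clade
        d = small_clade_config().within_species_divergence
        for i in range(len(genomes)):
            for j in range(i + 1, len(genomes)):
                ident = truth.core_identity(genomes[i], genomes[j])
                assert abs(ident - 100 * (1 - d)) < 0.5
        # substitution-log cross-check: the logged events per strain match
        # the per-branch expectation that yields pairwise d
        for g in genomes:
            subs = truth.substitutions[g.id]
            rate = len(subs) / len(g)
            assert 0.5 * d * 0.7 < rate < 0.5 * d * 1.3

    def test_alt_alleles_present_in_sequence(self, small_clade):
        """The last logged event at each position matches the genome (a
        site can be hit more than once; events are logged in order)."""
        genomes, truth = small_clade
        g = genomes[0]
        final = {}
        for s in truth.substitutions[g.id]:
            final[s.pos] = s.alt
        assert all(g.sequence[pos] == alt for pos, alt in final.items())


class TestIslandSignatures:
    def test_replacement_flanked_by_trnas_with_internal_tmrna(
        self, small_clade
    ):
        genomes, truth = small_clade
        for g in genomes:
            for isl in truth.islands[g.id]:
                if isl.island_type != "replacement":
                    continue
                inside = [f for f in g.features
                          if isl.start <= f.start < isl.end]
                trnas = [f for f in inside if f.kind == "tRNA"]
                assert {t.anticodon for t in trnas} >= {"gga", "cct"}
                assert any(f.kind == "tmRNA" for f in inside)

    def test_additive_has_repeats_behind_trna_lys(self, small_clade):
        genomes, truth = small_clade
        seen = 0
        for g in genomes:
            for isl in truth.islands[g.id]:
                if isl.island_type != "additive":
                    continue
                seen += 1
                inside = [f for f in g.features
                          if isl.start <= f.start < isl.end]
                assert any(f.kind == "tRNA" and f.anticodon == "ctt"
                           for f in inside)
                reps = [f for f in inside if f.kind == "repeat_region"]
                assert len(reps) >= 2
                # every repeat is the tRNA-Lys 3' 20-mer
                for r in reps:
                    assert g.feature_sequence(r) == "ACCAGCTGAGCTAATCCCCC"
        assert seen > 0

    def test_tycheposon_structure(self, small_clade):
        genomes, truth = small_clade
        seen = 0
        for g in genomes:
            for isl in truth.islands[g.id]:
                if isl.island_type != "tycheposon":
                    continue
                seen += 1
                inside = [f for f in g.features
                          if isl.start <= f.start < isl.end]
                assert any(f.kind == "tRNA" and f.anticodon == "cat"
                           for f in inside)
                assert any("XerD" in f.product for f in inside)
                after = [f for f in g.features
                         if f.start >= isl.end and f.kind == "CDS"]
                assert "GlmS" in after[0].product
        assert seen > 0

    def test_truth_records_only_for_carriers(self, small_clade):
        genomes, truth = small_clade
        # additive island: carriers 2 of 3; third strain has no record
        counts = [sum(1 for i in truth.islands[g.id]
                      if i.island_type == "additive") for g in genomes]
        assert sorted(counts) == [0, 1, 1]


class TestCodonAwareMutation:
    def test_no_stops_created_and_log_consistent(self, rng):
        coding = "ATG" + "GCT" * 200 + "TAA"
        mutated, log = codon_aware_mutate(coding, rng, rate=0.05)
        assert len(mutated) == len(coding)
        assert log, "expected substitutions at this rate"
        assert mutated[:3] == "ATG" and mutated[-3:] == "TAA"
        for i in range(3, len(mutated) - 3, 3):
            assert mutated[i:i + 3] not in {"TAA", "TAG", "TGA"}
        for off, ref, alt, _syn in log:
            assert coding[off] == ref and mutated[off] == alt

    def test_extra_syn_pass_is_synonymous_only(self, rng):
        coding = "ATG" + "CTGGCAAGA" * 100 + "TAA"
        _, log = codon_aware_mutate(coding, rng, rate=0.0,
                                    extra_syn_rate=0.05)
        assert log and all(syn for _, _, _, syn in log)


class TestReadSimulation:
    def test_error_free_reads_are_genome_substrings(self, small_clade):
        genomes, _ = small_clade
        g = genomes[0]
        reads, origins = simulate_reads(
            [g], ReadSimConfig(n_reads=500, error_rate=0.0, seed=3)
        )
        doubled = g.sequence + g.sequence
        for r in reads:
            assert (r.sequence in doubled
                    or reverse_complement(r.sequence) in doubled)

    def test_read_share_matches_weights(self, small_clade):
        genomes, _ = small_clade
        cfg = ReadSimConfig(n_reads=100_000, error_rate=0.0,
                            strain_weights=(0.5, 0.5, 0.0), seed=3)
        _, origins = simulate_reads(genomes, cfg)
        share = sum(1 for o in origins if o.genome_id == genomes[0].id) \
            / len(origins)
        assert abs(share - 0.5) <= 0.01

    def test_read_lengths_exact(self, small_clade):
        genomes, _ = small_clade
        reads, _ = simulate_reads(
            [genomes[0]], ReadSimConfig(n_reads=50, read_length=50, seed=1)
        )
        assert all(len(r.sequence) == 50 for r in reads)

    def test_zero_total_weight_rejected(self, small_clade):
        genomes, _ = small_clade
        cfg = ReadSimConfig(n_reads=10, strain_weights=(0.0, 0.0, 0.0), seed=1)
        with pytest.raises(ConfigError):
            simulate_reads(genomes, cfg)

    def test_origin_truth_matches_reads(self, small_clade):
        genomes, _ = small_clade
        g = genomes[0]
        reads, origins = simulate_reads(
            [g], ReadSimConfig(n_reads=200, error_rate=0.0, seed=8)
        )
        doubled = g.sequence + g.sequence
        for r, o in zip(reads, origins):
            seg = doubled[o.start:o.end]
            if o.strand == "-":
                seg = reverse_complement(seg)
            assert r.sequence == seg


class TestTruthSerialization:
    def test_round_trip(self, small_clade, tmp_path):
        _, truth = small_clade
        write_truth(truth, tmp_path)
        islands, fams = read_truth(tmp_path)
        orig = sorted(
            (i.genome_id, i.start, i.end, i.island_id, i.island_type,
             i.sharing_group)
            for lst in truth.islands.values() for i in lst
        )
        back = sorted(
            (i.genome_id, i.start, i.end, i.island_id, i.island_type,
             i.sharing_group)
            for i in islands
        )
        assert orig == back
        assert fams == truth.gene_families

    def test_empty_truth_gives_valid_empty_bed(self, tmp_path):
        from fgikit.synthetic_clade import PlantedTruth

        write_truth(PlantedTruth(), tmp_path)
        islands, fams = read_truth(tmp_path)
        assert islands == [] and fams == {}
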