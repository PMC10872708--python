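"""Island typing rules, signature primitives and shared-protein Venns."""

import pytest

from fgikit.island_classify import (SignatureConfig, UnannotatedGenomeError,
                                    classify_island, count_direct_repeats,
                                    extract_trna_terminal_repeat,
                                    fgi_shared_fraction, tycheposon_span)
from fgikit.island_detect import IslandCandidate
from fgikit.references import TRNA_LYS_TERMINAL_20MER
from fgikit.seq_io import (GeneFeature, GenomeRecord, ProteinRecord,
                           reverse_complement)
from fgikit.synthetic_clade import IslandSpec, generate_clade
from tests.conftest import small_clade_config

MOTIF = TRNA_LYS_TERMINAL_20MER


def _trna_genome(strand="+"):
    body = "ACGTTGCAACGGTTACGGAT" * 3  # 60 nt
    gene = body[:56] + MOTIF  # 76 nt, ends with the repeat motif
    if strand == "-":
        seq = "GG" + reverse_complement(gene) + "CC"
    else:
        seq = "GG" + gene + "CC"
    feat = GeneFeature("t1", 2, 2 + len(gene), strand, "tRNA",
                       product="tRNA-Lys(ctt)", anticodon="ctt")
    return GenomeRecord("g", seq, circular=False, features=[feat]), feat


class TestMotifExtraction:
    def test_lys_trna_yields_paper_motif(self):
        g, feat = _trna_genome("+")
        assert extract_trna_terminal_repeat(feat, g) == MOTIF

    def test_motif_length_one_is_last_base(self):
        g, feat = _trna_genome("+")
        assert extract_trna_terminal_repeat(feat, g, 1) == MOTIF[-1]

    def test_minus_strand_uses_coding_orientation(self):
        g, feat = _trna_genome("-")
        assert extract_trna_terminal_repeat(feat, g) == MOTIF

    def test_short_trna_rejected(self):
        g, feat = _trna_genome("+")
        with pytest.raises(ValueError):
            extract_trna_terminal_repeat(feat, g, motif_length=1000)


class TestDirectRepeats:
    def test_absent_motif_empty(self):
        g = GenomeRecord("g", "A" * 200, circular=False)
        assert count_direct_repeats(g, MOTIF, (0, 200)) == []

    def test_three_exact_copies_found(self):
        seq = "AC" * 30 + MOTIF + "GT" * 25 + MOTIF + "TA" * 20 + MOTIF + "CG" * 10
        g = GenomeRecord("g", seq, circular=False)
        assert len(count_direct_repeats(g, MOTIF, (0, len(seq)),
                                        max_mismatches=0)) == 3

    def test_single_mismatch_tolerance(self):
        damaged = "T" + MOTIF[1:]
        seq = "AC" * 30 + damaged + "GT" * 30
        g = GenomeRecord("g", seq, circular=False)
        assert count_direct_repeats(g, MOTIF, (0, len(seq)),
                                    max_mismatches=1) == [60]
        assert count_direct_repeats(g, MOTIF, (0, len(seq)),
                                    max_mismatches=0) == []


class TestClassification:
    def _truth_call(self, analysis, truth, island_type):
        for gid, calls in analysis.calls.items():
            for t in truth.islands[gid]:
                if t.island_type != island_type:
                    continue
                for c in calls:
                    if c.start < t.end and t.start < c.end:
                        return gid, t, c
        raise AssertionError(f"no call overlapping a {island_type} truth")

    @pytest.mark.parametrize("island_type",
                             ["replacement", "additive", "tycheposon"])
    def test_planted_islands_typed_correctly(self, small_clade,
                                             small_analysis, island_type):
        _, truth = small_clade
        _, t, call = self._truth_call(small_analysis, truth, island_type)
        assert call.island_type == island_type

    def test_replacement_evidence_recorded(self, small_clade, small_analysis):
        _, truth = small_clade
        _, _, call = self._truth_call(small_analysis, truth, "replacement")
        assert call.evidence.tmrna_present
        assert set(call.evidence.flank_trnas) == {"gga", "cct"}

    def test_tycheposon_span_extends_to_terminal_core_gene(
        self, small_clade, small_analysis
    ):
        _, truth = small_clade
        gid, t, call = self._truth_call(small_analysis, truth, "tycheposon")
        assert call.evidence.terminal_core_gene is not None
        assert abs(call.start - t.start) < 500
        assert abs(call.end - t.end) < 500

    def test_candidate_without_signatures_unclassified(self, small_clade,
                                                       small_analysis):
        genomes, _ = small_clade
        g = genomes[0]
        # a mid-core region with no island signatures at all
        cand = IslandCandidate(g.id, 5_000, 12_000, frozenset(), 1.0)
        call = classify_island(cand, g,
                               small_analysis.core_genes[g.id])
        assert call.island_type == "unclassified"

    def test_unannotated_genome_rejected(self):
        g = GenomeRecord("bare", "ACGT" * 1000, circular=False)
        cand = IslandCandidate("bare", 0, 100, frozenset(), 1.0)
        with pytest.raises(UnannotatedGenomeError):
            classify_island(cand, g, set())


class TestSignatureAblation:
    """Removing one signature demotes the call to 'unclassified'; it never
    flips to a different type."""

    def _call(self, genome, cand, core):
        return classify_island(cand, genome, core)

    def test_replacement_without_tmrna(self, small_clade, small_analysis):
        genomes, truth = small_clade
        g = genomes[0]
        t = next(i for i in truth.islands[g.id]
                 if i.island_type == "replacement")
        cand = next(c.candidate for c in small_analysis.calls[g.id]
                    if c.island_type == "replacement")
        ablated = GenomeRecord(
            g.id, g.sequence, circular=True,
            features=[f for f in g.features if f.kind != "tmRNA"],
        )
        call = self._call(ablated, cand, small_analysis.core_genes[g.id])
        assert call.island_type == "unclassified"

    def test_tycheposon_without_xerd(self, small_clade, small_analysis):
        genomes, truth = small_clade
        found = False
        for g in genomes:
            tyche = [c for c in small_analysis.calls[g.id]
                     if c.island_type == "tycheposon"]
            if not tyche:
                continue
            found = True
            ablated = GenomeRecord(
                g.id, g.sequence, circular=True,
                features=[f for f in g.features if "XerD" not in f.product],
            )
            call = self._call(ablated, tyche[0].candidate,
                              small_analysis.core_genes[g.id])
            assert call.island_type == "unclassified"
        assert found

    def test_additive_without_repeats(self, small_clade, small_analysis):
        genomes, truth = small_clade
        found = False
        for g in genomes:
            adds = [c for c in small_analysis.calls[g.id]
                    if c.island_type == "additive"]
            if not adds:
                continue
            found = True
            seq = list(g.sequence)
            for e in [e for e in small_analysis.genomes[g.id].features
                      if e.kind == "repeat_region"]:
                for i in range(e.start, e.end):
                    seq[i] = "A"
            ablated = GenomeRecord(g.id, "".join(seq), circular=True,
                                   features=list(g.features))
            call = self._call(ablated, adds[0].candidate,
                              small_analysis.core_genes[g.id])
            assert call.island_type == "unclassified"
        assert found


class TestTycheposonSpan:
    def test_trna_followed_by_core_gene_empty_cargo(self, small_clade):
        genomes, _ = small_clade
        g = genomes[-1]  # non-carrier: tRNA-Met directly precedes the core
        trna = next(f for f in g.features
                    if f.kind == "tRNA" and f.anticodon == "cat")
        core = {f.id for f in g.features if f.kind == "CDS"}
        span = tycheposon_span(g, trna, core, direction=+1)
        # no cargo: the span is just the tRNA itself
        assert span == (trna.start, trna.end)

    def test_planted_cargo_recovered(self, small_clade, small_analysis):
        genomes, truth = small_clade
        g = genomes[0]
        t = next(i for i in truth.islands[g.id]
                 if i.island_type == "tycheposon")
        trna = next(f for f in g.features
                    if f.kind == "tRNA" and f.anticodon == "cat"
                    and t.start <= f.start < t.end)
        span = tycheposon_span(g, trna, small_analysis.core_genes[g.id], +1)
        assert abs(span[0] - t.start) < 200 and abs(span[1] - t.end) < 500

    def test_reversed_orientation_scanned_other_direction(self):
        cfg = small_clade_config(seed=29)
        cfg.island_specs = [
            IslandSpec("tycheposon", 0.5, (6_000, 8_000), "subset",
                       carrier_count=2, variable_tail_bp=2_500,
                       reversed_orientation=True),
        ]
        genomes, truth = generate_clade(cfg)
        from fgikit.pipeline import analyze_islands
        from fgikit.island_detect import DetectParams

        res = analyze_islands(genomes, params=DetectParams(gap_min_span=1500))
        matched = 0
        for g in genomes:
            for t in truth.islands[g.id]:
                for c in res.calls[g.id]:
                    if c.start < t.end and t.start < c.end \
                            and c.island_type == "tycheposon":
                        matched += 1
                        assert abs(c.start - t.start) < 500
                        assert abs(c.end - t.end) < 500
        assert matched >= 1


class TestSharedFractions:
    def _sets(self, rng, n_shared, n_unique, labels):
        AA = "ACDEFGHIKLMNPQRSTVWY"
        shared = ["".join(rng.choice(list(AA), 100)) for _ in range(n_shared)]
        out = {}
        for li, label in enumerate(labels):
            prots = [
                ProteinRecord(f"{label}|s{i}", label, s, f"s{i}")
                for i, s in enumerate(shared)
            ]
            for u in range(n_unique):
                prots.append(ProteinRecord(
                    f"{label}|u{u}", label,
                    "".join(rng.choice(list(AA), 100)), f"u{u}"
                ))
            out[label] = prots
        return out

    def test_identical_sets_fully_shared(self, rng):
        sets = self._sets(rng, 5, 0, ["a", "b", "c"])
        assert fgi_shared_fraction(sets).shared_by_all == pytest.approx(1.0)

    def test_disjoint_sets_share_nothing(self, rng):
        sets = self._sets(rng, 0, 4, ["a", "b"])
        assert fgi_shared_fraction(sets).shared_by_all == 0.0

    def test_empty_set_rejected(self, rng):
        sets = self._sets(rng, 2, 0, ["a", "b"])
        sets["b"] = []
        with pytest.raises(ValueError):
            fgi_shared_fraction(sets)

    def test_conserved_tycheposon_outshAres_unique_replacement(
        self, small_clade
    ):
        """The subset-conserved tycheposon shares more of its protein pool
        across carriers than the strain-unique replacement island."""
        genomes, truth = small_clade
        from fgikit.seq_io import proteome

        def island_sets(island_type):
            sets = {}
            for g in genomes:
                isl = [i for i in truth.islands[g.id]
                       if i.island_type == island_type]
                if not isl:
                    continue
                t = isl[0]
                prots = [p for p in proteome(g)
                         for f in [next(f for f in g.features
                                        if f.id == p.source_cds)]
                         if t.start <= f.start < t.end]
                if prots:
                    sets[g.id] = prots
            return sets

        tyche = fgi_shared_fraction(island_sets("tycheposon"))
        repl = fgi_shared_fraction(island_sets("replacement"))
        assert tyche.shared_by_all > repl.shared_by_all
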