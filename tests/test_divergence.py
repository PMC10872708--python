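"""NG86 against a brute-force pathway oracle; SNP calls against the
generator's substitution log; dS profiles and border peaks."""

import math
from itertools import permutations, product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fgikit.align_core import align_nucleotide
from fgikit.divergence import (DsGeneRecord, DsProfile, SnpCall,
                               border_ds_peak_test, call_core_snps,
                               ds_profile, ng86)
from fgikit.island_detect import compute_synteny_blocks
from fgikit.seq_io import GenomeRecord
from fgikit.synthetic_clade import (_CODON_AA, codon_aware_mutate,
                                    uniform_mutate)

STOPS = {"TAA", "TAG", "TGA"}
BASES = "ACGT"
NONSTOP = [c for c in map("".join, product(BASES, repeat=3))
           if c not in STOPS]


# ---------------------------------------------------------------------------
# Independent NG86 oracle: explicit enumeration, no shared helpers
# ---------------------------------------------------------------------------

def oracle_syn_sites(codon):
    aa = _CODON_AA[codon]
    total = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            new = codon[:pos] + b + codon[pos + 1:]
            if new not in STOPS and _CODON_AA[new] == aa:
                total += 1 / 3
    return total


def oracle_pair(c1, c2):
    """(S, N, Sd, Nd) for one codon pair by full pathway enumeration."""
    S = (oracle_syn_sites(c1) + oracle_syn_sites(c2)) / 2
    N = 3 - S
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return S, N, 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur, sd, nd, blocked = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOPS:
                blocked = True
            if _CODON_AA[cur] == _CODON_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((blocked, sd, nd))
    usable = [(sd, nd) for blocked, sd, nd in paths if not blocked] \
        or [(sd, nd) for _, sd, nd in paths]
    return (S, N,
            sum(p[0] for p in usable) / len(usable),
            sum(p[1] for p in usable) / len(usable))


class TestNg86:
    def test_identical_sequences(self):
        est = ng86("ATGAAACCC", "ATGAAACCC")
        assert est.Sd == est.Nd == 0
        assert est.dS == est.dN == 0.0

    def test_single_nonsynonymous_change(self):
        a = "AAA" * 100
        b = "GAA" + "AAA" * 99
        est = ng86(a, b)
        assert est.Nd == 1 and est.Sd == 0
        assert est.dS == 0.0 and est.dN > 0

    def test_matches_pathway_oracle_on_500_random_pairs(self, rng):
        for _ in range(500):
            c1 = NONSTOP[int(rng.integers(len(NONSTOP)))]
            c2 = NONSTOP[int(rng.integers(len(NONSTOP)))]
            est = ng86(c1, c2)
            S, N, Sd, Nd = oracle_pair(c1, c2)
            assert abs(est.S - S) < 1e-9
            assert abs(est.N - N) < 1e-9
            assert abs(est.Sd - Sd) < 1e-9
            assert abs(est.Nd - Nd) < 1e-9

    def test_sites_sum_to_three_per_codon(self, rng):
        seq = "".join(NONSTOP[int(rng.integers(len(NONSTOP)))]
                      for _ in range(50))
        est = ng86(seq, seq)
        assert est.S + est.N == pytest.approx(3 * est.n_codons)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_symmetry(self, seed):
        r = np.random.default_rng(seed)
        a = "".join(NONSTOP[int(r.integers(len(NONSTOP)))] for _ in range(30))
        b = "".join(NONSTOP[int(r.integers(len(NONSTOP)))] for _ in range(30))
        ea, eb = ng86(a, b), ng86(b, a)
        assert (ea.S, ea.N, ea.Sd, ea.Nd) == (eb.S, eb.N, eb.Sd, eb.Nd)

    def test_saturation_reported_as_nan(self):
        # maximally different codons everywhere: pS blows past 3/4
        a = "TTT" * 60
        b = "GGG" * 60
        est = ng86(a, b)
        assert math.isnan(est.dN)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            ng86("ATG", "ATGAAA")

    def test_ds_recovers_planted_synonymous_rate(self, rng):
        """JC-corrected dS tracks the generator's realized synonymous event
        count per synonymous site to within 10%.  The generator plants
        distinct events (no within-branch multi-hits), so agreement
        degrades as the Poisson multiple-hit correction saturates; tested
        at a substantial but unsaturated divergence."""
        coding = "ATG" + "".join(
            NONSTOP[int(rng.integers(len(NONSTOP)))] for _ in range(600)
        ) + "TAA"
        a, log_a = codon_aware_mutate(coding, rng, rate=0.0,
                                      extra_syn_rate=0.04)
        b, log_b = codon_aware_mutate(coding, rng, rate=0.0,
                                      extra_syn_rate=0.04)
        est = ng86(a, b)
        assert not math.isnan(est.dS) and est.dS <= 0.5
        events = len(log_a) + len(log_b)
        realized_rate = events / est.S
        assert est.dS == pytest.approx(realized_rate, rel=0.10)


class TestSnpCalls:
    def test_identical_genomes_no_snps(self, small_clade):
        genomes, _ = small_clade
        g = genomes[0]
        blocks = compute_synteny_blocks(align_nucleotide(g, g))
        assert call_core_snps(g, [g], {g.id: blocks}) == []

    def test_logged_substitutions_recovered_exactly(self, rng):
        raw = "".join(rng.choice(list(BASES), 60_000))
        ref = GenomeRecord("ref", raw, circular=False)
        mutated, log = uniform_mutate(raw, rng, rate=100 / 60_000)
        query = GenomeRecord("q", mutated, circular=False)
        blocks = compute_synteny_blocks(align_nucleotide(ref, query))
        calls = call_core_snps(ref, [query], {"q": blocks})
        got = {(c.position, c.ref, c.alt) for c in calls}
        expected = {(pos, r, a) for pos, r, a, _ in log}
        assert got == expected

    def test_within_species_calls_match_sequence_differences(
        self, small_clade
    ):
        """SNP calls equal the base-level differences of block-covered
        positions, derived independently from planted element coordinates."""
        genomes, truth = small_clade
        ref, query = genomes[0], genomes[1]
        blocks = compute_synteny_blocks(align_nucleotide(ref, query))
        calls = call_core_snps(ref, [query], {query.id: blocks})
        got = {(c.position, c.ref, c.alt) for c in calls}
        els_q = {e.element_id: e for e in truth.elements[query.id]}
        expected = set()
        for e in truth.elements[ref.id]:
            eq = els_q.get(e.element_id)
            if eq is None:
                continue
            sa = ref.sequence[e.start:e.end]
            sb = query.sequence[eq.start:eq.end]
            if len(sa) != len(sb) or e.strand != eq.strand:
                continue
            for i, (x, y) in enumerate(zip(sa, sb)):
                if x != y:
                    expected.add((e.start + i, x, y))
        # every expected core difference inside a covered block is called
        covered = np.zeros(len(ref), bool)
        for b in blocks:
            for h in b.hits:
                covered[h.qstart:h.qend] = True
        expected_covered = {t for t in expected if covered[t[0]]}
        assert got >= expected_covered
        assert len(got - expected) <= 0.01 * max(len(got), 1)


def _flat_profile(n=40, value=0.02):
    recs = [DsGeneRecord(f"g{i}", 1000 * i, value, value / 10, 1, False)
            for i in range(n)]
    return DsProfile("ref", 5, recs)


class TestDsProfile:
    def test_clonal_pair_flat_zero(self, small_clade):
        genomes, _ = small_clade
        g = genomes[0]
        omap = {f.id: {"clone": f.id} for f in g.features if f.kind == "CDS"}
        clone = GenomeRecord("clone", g.sequence, circular=True,
                             features=list(g.features))
        profile = ds_profile(g, [clone], omap)
        assert all(r.ds == 0.0 for r in profile.records if not math.isnan(r.ds))

    def test_window_one_equals_raw(self, small_clade):
        genomes, _ = small_clade
        g = genomes[0]
        omap = {f.id: {"clone": f.id} for f in g.features if f.kind == "CDS"}
        clone = GenomeRecord("clone", g.sequence, circular=True,
                             features=list(g.features))
        profile = ds_profile(g, [clone], omap, window=1)
        for r in profile.records:
            if not math.isnan(r.ds):
                assert r.ds_smoothed == r.ds

    def test_missing_ortholog_gives_nan_record(self, small_clade):
        genomes, _ = small_clade
        g = genomes[0]
        clone = GenomeRecord("clone", g.sequence, circular=True,
                             features=list(g.features))
        profile = ds_profile(g, [clone], {}, window=1)
        assert all(math.isnan(r.ds) for r in profile.records)


class TestBorderPeak:
    def test_flat_profile_ratio_one(self):
        profile = _flat_profile()
        left, right = border_ds_peak_test(profile, (15_000, 25_000))
        assert left == pytest.approx(1.0) and right == pytest.approx(1.0)

    def test_elevated_flanks_detected(self):
        profile = _flat_profile()
        for r in profile.records:
            if 10_000 <= r.midpoint < 15_000 or 25_000 <= r.midpoint < 30_000:
                r.ds = 0.06
        left, right = border_ds_peak_test(profile, (15_000, 25_000))
        assert left >= 2 and right >= 2

    def test_island_at_genome_edge_wraps(self):
        profile = _flat_profile()
        left, right = border_ds_peak_test(profile, (0, 3_000))
        assert left == pytest.approx(1.0) and right == pytest.approx(1.0)

    def test_insufficient_flanks_rejected(self):
        profile = _flat_profile(n=4)
        with pytest.raises(ValueError):
            border_ds_peak_test(profile, (1_000, 2_000), flank=10)
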