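"""Core SNP calling, Nei–Gojobori (1986) dN/dS and reference dS profiles.

NG86 counting convention used throughout: synonymous site fractions are
computed per codon position over the three possible changes, with changes
that create a stop codon counted as nonsynonymous, so S + N equals three
times the codon count exactly.  Differences between codons are averaged
over all minimal substitution pathways with equal weight; pathways passing
through a stop codon are excluded unless every pathway does.  Proportions
are corrected for multiple hits with the Jukes–Cantor transform
``d = -3/4 ln(1 - 4p/3)``; ``p >= 3/4`` is reported as saturation, not a
number.

dS profiles order per-gene estimates along a reference genome and smooth
them with a centred moving median, which is how recombination-driven
synonymous peaks at island borders become visible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np

from .seq_io import GenomeRecord, circular_subsequence, reverse_complement
from .synthetic_clade import _CODON_AA  # codon -> amino acid, table 11

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# SNP calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpCall:
    reference_id: str
    position: int  # 0-based reference coordinate
    ref: str
    alt: str
    query_id: str

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")


def call_core_snps(
    reference: GenomeRecord,
    queries: list[GenomeRecord],
    blocks_by_query: dict[str, list],
) -> list[SnpCall]:
    """Substitution columns inside aligned blocks, in reference coordinates.
    Blocks must come from alignments with the reference as query; inverted
    blocks are compared after reverse complement."""
    calls: list[SnpCall] = []
    for query in queries:
        blocks = blocks_by_query.get(query.id, [])
        seen: set[int] = set()
        for block in blocks:
            for h in block.hits:
                ref_seg = reference.sequence[h.qstart : h.qend]
                span = h.qend - h.qstart  # hits are gapless
                q_seg = circular_subsequence(
                    query, h.sstart % len(query), h.sstart % len(query) + span
                )
                if h.strand == "-":
                    q_seg = reverse_complement(q_seg)
                n = min(len(ref_seg), len(q_seg))
                ra = np.frombuffer(ref_seg[:n].encode(), dtype=np.uint8)
                qa = np.frombuffer(q_seg[:n].encode(), dtype=np.uint8)
                for off in np.nonzero(ra != qa)[0]:
                    pos = h.qstart + int(off)
                    if pos in seen:
                        continue
                    seen.add(pos)
                    calls.append(SnpCall(
                        reference_id=reference.id,
                        position=pos,
                        ref=ref_seg[off],
                        alt=q_seg[off],
                        query_id=query.id,
                    ))
    calls.sort(key=lambda c: (c.query_id, c.position))
    return calls


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

class SaturationError(ValueError):
    """pS or pN >= 3/4: the Jukes–Cantor correction is undefined."""


@dataclass(frozen=True)
class DivergenceEstimate:
    S: float  # synonymous sites
    N: float  # nonsynonymous sites
    Sd: float  # synonymous differences
    Nd: float  # nonsynonymous differences
    n_codons: int

    @property
    def pS(self) -> float:
        return self.Sd / self.S if self.S else 0.0

    @property
    def pN(self) -> float:
        return self.Nd / self.N if self.N else 0.0

    @staticmethod
    def _jc(p: float) -> float:
        if p >= 0.75:
            return math.nan
        return -0.75 * math.log1p(-4.0 * p / 3.0)

    @property
    def dS(self) -> float:
        return self._jc(self.pS)

    @property
    def dN(self) -> float:
        return self._jc(self.pN)

    @property
    def saturated(self) -> bool:
        return math.isnan(self.dS) or math.isnan(self.dN)


@lru_cache(maxsize=None)
def _syn_sites(codon: str) -> float:
    """Synonymous site count of one codon (sum over positions of the
    fraction of the three changes that are synonymous; stop-creating
    changes are nonsynonymous)."""
    aa = _CODON_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            new = codon[:pos] + b + codon[pos + 1 :]
            if new not in _STOPS and _CODON_AA[new] == aa:
                syn += 1
        s += syn / 3.0
    return s


@lru_cache(maxsize=None)
def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    with equal weight over minimal substitution pathways; pathways through
    stop codons are excluded unless all are blocked."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in permutations(diff):
        cur = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            new = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if new in _STOPS:
                blocked = True
            if _CODON_AA[cur] == _CODON_AA[new]:
                sd += 1
            else:
                nd += 1
            cur = new
        results.append((blocked, sd, nd))
    open_paths = [(sd, nd) for blocked, sd, nd in results if not blocked]
    if not open_paths:
        open_paths = [(sd, nd) for _, sd, nd in results]
    sd = sum(p[0] for p in open_paths) / len(open_paths)
    nd = sum(p[1] for p in open_paths) / len(open_paths)
    return sd, nd


def ng86(seq_a: str, seq_b: str) -> DivergenceEstimate:
    """NG86 estimate for one pair of in-frame coding sequences of equal
    length.  Codon pairs containing gaps, ambiguity characters or stop
    codons are dropped.  The estimate is symmetric in its arguments."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length (gapless pairs)")
    if len(seq_a) % 3:
        raise ValueError("length not divisible by 3")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(seq_a), 3):
        c1, c2 = seq_a[i : i + 3], seq_b[i : i + 3]
        if (
            any(ch not in _BASES for ch in c1 + c2)
            or c1 in _STOPS
            or c2 in _STOPS
        ):
            continue
        n_codons += 1
        s1, s2 = _syn_sites(c1), _syn_sites(c2)
        S += (s1 + s2) / 2.0
        N += 3.0 - (s1 + s2) / 2.0
        sd, nd = _pathway_counts(c1, c2)
        Sd += sd
        Nd += nd
    return DivergenceEstimate(S=S, N=N, Sd=Sd, Nd=Nd, n_codons=n_codons)


# ---------------------------------------------------------------------------
# dS profiles along a reference
# ---------------------------------------------------------------------------

@dataclass
class DsGeneRecord:
    gene_id: str
    midpoint: int
    ds: float  # nan when missing or saturated
    dn: float
    n_pairs: int
    saturated: bool
    ds_smoothed: float = math.nan


@dataclass
class DsProfile:
    reference_id: str
    window: int
    records: list[DsGeneRecord]

    def genome_median_ds(self) -> float:
        vals = [r.ds for r in self.records if not math.isnan(r.ds)]
        if not vals:
            return math.nan
        return float(np.median(vals))


def ds_profile(
    reference: GenomeRecord,
    queries: list[GenomeRecord],
    ortholog_map: dict[str, dict[str, str]],
    window: int = 5,
) -> DsProfile:
    """Per-gene dS of the reference against each query's ortholog, averaged
    across queries and smoothed by a centred moving median of ``window``
    genes.  Saturated or ortholog-less genes carry nan and are excluded
    from smoothing."""
    if window < 1:
        raise ValueError("window must be >= 1")
    feats_by_id = {
        q.id: {f.id: f for f in q.features} for q in queries
    }
    records: list[DsGeneRecord] = []
    for feat in reference.features:
        if feat.kind != "CDS":
            continue
        ref_seq = reference.feature_sequence(feat)
        ds_vals, dn_vals = [], []
        n_pairs = 0
        any_saturated = False
        for q in queries:
            partner_id = ortholog_map.get(feat.id, {}).get(q.id)
            if partner_id is None:
                continue
            pf = feats_by_id[q.id].get(partner_id)
            if pf is None:
                continue
            q_seq = q.feature_sequence(pf)
            if len(q_seq) != len(ref_seq):
                continue  # length-mismatched pairs dropped (gapless NG86)
            est = ng86(ref_seq, q_seq)
            n_pairs += 1
            if math.isnan(est.dS):
                any_saturated = True
                continue
            ds_vals.append(est.dS)
            dn_vals.append(est.dN)
        ds = float(np.mean(ds_vals)) if ds_vals else math.nan
        dn = float(np.nanmean(dn_vals)) if dn_vals else math.nan
        records.append(DsGeneRecord(
            gene_id=feat.id,
            midpoint=(feat.start + feat.end) // 2,
            ds=ds, dn=dn, n_pairs=n_pairs,
            saturated=any_saturated and not ds_vals,
        ))
    records.sort(key=lambda r: r.midpoint)
    half = window // 2
    n = len(records)
    for i, rec in enumerate(records):
        vals = [
            records[j].ds
            for j in range(max(0, i - half), min(n, i + half + 1))
            if not math.isnan(records[j].ds)
        ]
        rec.ds_smoothed = float(np.median(vals)) if vals else math.nan
    return DsProfile(reference_id=reference.id, window=window,
                     records=records)


def border_ds_peak_test(
    profile: DsProfile,
    island_interval: tuple[int, int],
    flank: int = 5,
) -> tuple[float, float]:
    """Ratio of the median dS over ``flank`` genes on each side of an island
    to the genome-wide median dS; flanks wrap circularly at genome edges.
    Returns (left ratio, right ratio)."""
    start, end = island_interval
    recs = profile.records
    n = len(recs)
    if n == 0:
        raise ValueError("empty profile")
    left_idx = [i for i, r in enumerate(recs) if r.midpoint < start]
    right_idx = [i for i, r in enumerate(recs) if r.midpoint >= end]
    # circular flanks: walk outward from the island on the gene ring
    ring_left = (left_idx[::-1] + right_idx[::-1])[:]
    ring_right = (right_idx + left_idx)[:]

    def _flank_median(order: list[int]) -> float:
        vals = []
        for i in order:
            if math.isnan(recs[i].ds):
                continue
            vals.append(recs[i].ds)
            if len(vals) == flank:
                break
        if len(vals) < flank:
            raise ValueError("insufficient flank genes with defined dS")
        return float(np.median(vals))

    genome_median = profile.genome_median_ds()
    if math.isnan(genome_median) or genome_median == 0:
        raise ValueError("genome-wide median dS undefined or zero")
    return (
        _flank_median(ring_left) / genome_median,
        _flank_median(ring_right) / genome_median,
    )
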