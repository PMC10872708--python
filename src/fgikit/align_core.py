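"""Pairwise alignment kernels and fragment-based ANI / AAI.

Protein alignment is exact Smith–Waterman (BLOSUM62, gap open 11 / extend
1, via Biopython's C aligner) with identity counted over aligned columns;
coverage is measured on the shorter sequence so the ortholog hit graph is
undirected.  Nucleotide comparison is seed-and-extend: exact ``seed_length``
k-mer matches are grouped per (strand, diagonal) and merged into gapless
local hits — adequate for closely related genomes whose homologous segments
differ by substitutions, which is the regime island detection operates in.

ANI follows the classic fragment dialect: the query is chopped into
1020-bp windows, each mapped to the subject; fragments whose dominant seed
diagonal covers >= 70% of the window are accepted and their Hamming
identity (trimmed of the forced-match terminal seeds) is averaged, in both
directions.  A pair with no accepted fragments yields an *undefined* result,
distinct from 0 — the genomes are simply not alignable at this granularity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seq_io import GenomeRecord, ProteinRecord, reverse_complement

# ---------------------------------------------------------------------------
# Data types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentHit:
    query: str
    subject: str
    qstart: int
    qend: int
    sstart: int
    send: int
    strand: str
    identity: float  # percent of aligned columns matching
    aln_length: int
    query_coverage: float  # percent of query length aligned
    score: float

    def __post_init__(self):
        if not 0 <= self.identity <= 100:
            raise ValueError("identity outside [0,100]")
        if self.qend <= self.qstart:
            raise ValueError("qend <= qstart")


@dataclass(frozen=True)
class AniResult:
    ani: float  # percent; nan when undefined
    fraction_aligned: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.ani)


@dataclass(frozen=True)
class AaiResult:
    aai: float  # percent; nan when undefined
    n_rbh: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.aai)


# ---------------------------------------------------------------------------
# Protein alignment
# ---------------------------------------------------------------------------

def default_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(
        mode="local",
        substitution_matrix=substitution_matrices.load("BLOSUM62"),
        open_gap_score=-11.0,
        extend_gap_score=-1.0,
    )
    return aligner


def align_protein_pair(
    a: ProteinRecord,
    b: ProteinRecord,
    aligner: Align.PairwiseAligner | None = None,
) -> AlignmentHit:
    """Optimal local alignment of two proteins; identity is computed over
    aligned columns (matches + mismatches + internal gaps; local alignment
    has no end gaps)."""
    if not a.sequence or not b.sequence:
        raise ValueError("empty protein sequence")
    aligner = aligner or default_aligner()
    aln = aligner.align(a.sequence, b.sequence)[0]
    qblocks, sblocks = aln.aligned
    matches = 0
    aligned_cols = 0
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        qa = a.sequence[qs:qe]
        sa = b.sequence[ss:se]
        matches += sum(x == y for x, y in zip(qa, sa))
        aligned_cols += qe - qs
    qstart, qend = int(qblocks[0][0]), int(qblocks[-1][1])
    sstart, send = int(sblocks[0][0]), int(sblocks[-1][1])
    # internal gap columns count toward alignment length
    gaps = (qend - qstart - aligned_cols) + (send - sstart - aligned_cols)
    aln_length = aligned_cols + gaps
    identity = 100.0 * matches / aln_length if aln_length else 0.0
    return AlignmentHit(
        query=a.id, subject=b.id,
        qstart=qstart, qend=qend, sstart=sstart, send=send,
        strand="+",
        identity=identity,
        aln_length=aln_length,
        query_coverage=100.0 * (qend - qstart) / len(a.sequence),
        score=float(aln.score),
    )


def shorter_coverage(hit: AlignmentHit, len_q: int, len_s: int) -> float:
    """Percent of the shorter sequence spanned by the alignment."""
    if len_q <= len_s:
        return 100.0 * (hit.qend - hit.qstart) / len_q
    return 100.0 * (hit.send - hit.sstart) / len_s


def _kmer_sets(seq: str, k: int = 5) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def candidate_pairs(
    proteins: list[ProteinRecord], k: int = 5, min_shared: int = 2,
    max_bucket: int = 64,
) -> set[tuple[int, int]]:
    """Seed prefilter: index proteins by amino-acid k-mers and keep pairs
    sharing at least ``min_shared`` distinct k-mers.  Orthologs above the
    50%-identity floor share several exact 5-mers; unrelated pairs almost
    none.  Buckets larger than ``max_bucket`` (low-complexity words) are
    skipped — homologous pairs always share rarer words too."""
    from collections import Counter

    index: dict[str, list[int]] = {}
    for i, p in enumerate(proteins):
        for kmer in _kmer_sets(p.sequence, k):
            index.setdefault(kmer, []).append(i)
    counts: Counter[tuple[int, int]] = Counter()
    for members in index.values():
        if len(members) < 2 or len(members) > max_bucket:
            continue
        for i, j in combinations(members, 2):
            counts[(i, j)] += 1
    return {pair for pair, c in counts.items() if c >= min_shared}


def all_vs_all_protein(
    proteomes: list[list[ProteinRecord]],
    min_identity: float = 50.0,
    min_coverage: float = 50.0,
    prefilter_min_shared: int = 3,
) -> list[AlignmentHit]:
    """All-vs-all local protein alignment across >= 2 proteomes, keeping hits
    with identity >= ``min_identity`` and coverage (of the shorter sequence)
    >= ``min_coverage``.  Self-hits are excluded; the hit set is symmetric —
    both directions of every accepted pair are emitted."""
    if len(proteomes) < 2:
        raise ValueError("need at least two proteomes")
    proteins: list[ProteinRecord] = [p for prot in proteomes for p in prot]
    aligner = default_aligner()
    hits: list[AlignmentHit] = []
    for i, j in sorted(candidate_pairs(proteins, min_shared=prefilter_min_shared)):
        a, b = proteins[i], proteins[j]
        if a.id == b.id:
            continue
        hit = align_protein_pair(a, b, aligner)
        cov = shorter_coverage(hit, len(a), len(b))
        if hit.identity >= min_identity and cov >= min_coverage:
            hits.append(hit)
            hits.append(AlignmentHit(
                query=b.id, subject=a.id,
                qstart=hit.sstart, qend=hit.send,
                sstart=hit.qstart, send=hit.qend,
                strand="+", identity=hit.identity,
                aln_length=hit.aln_length,
                query_coverage=100.0 * (hit.send - hit.sstart) / len(b),
                score=hit.score,
            ))
    hits.sort(key=lambda h: (h.query, h.subject, -h.score))
    return hits


# ---------------------------------------------------------------------------
# Nucleotide seed index
# ---------------------------------------------------------------------------

_NT_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _NT_CODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _NT_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer k-mers at every offset; positions containing non-ACGT get -1."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        window = codes[j : j + n]
        out = out * 4 + np.where(window < 4, window, 0)
        bad |= window >= 4
    out[bad] = -1
    return out


class _SeedIndex:
    """Sorted k-mer index of one strand of a subject sequence."""

    def __init__(self, seq: str, k: int):
        self.k = k
        self.length = len(seq)
        kmers = _kmers(_encode(seq), k)
        self.order = np.argsort(kmers, kind="stable")
        self.sorted = kmers[self.order]

    def hits(self, query_kmers: np.ndarray, max_occ: int = 20
             ) -> tuple[np.ndarray, np.ndarray]:
        """(query positions, subject positions) of exact seed matches."""
        left = np.searchsorted(self.sorted, query_kmers, "left")
        right = np.searchsorted(self.sorted, query_kmers, "right")
        counts = right - left
        good = (query_kmers >= 0) & (counts > 0) & (counts <= max_occ)
        qpos_list = []
        spos_list = []
        idx = np.nonzero(good)[0]
        for q in idx:
            s = self.order[left[q] : right[q]]
            qpos_list.append(np.full(s.size, q))
            spos_list.append(s)
        if not qpos_list:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        return np.concatenate(qpos_list), np.concatenate(spos_list)


def _diagonal_runs(
    qpos: np.ndarray, spos: np.ndarray, k: int, max_seed_gap: int
) -> list[tuple[int, int, int]]:
    """Merge seed matches on each diagonal into runs; returns
    (qstart, qend, diagonal) with qend including the final seed."""
    if qpos.size == 0:
        return []
    diag = spos - qpos
    order = np.lexsort((qpos, diag))
    qpos, diag = qpos[order], diag[order]
    runs = []
    rs = 0
    for i in range(1, qpos.size + 1):
        if (
            i == qpos.size
            or diag[i] != diag[rs]
            or qpos[i] - qpos[i - 1] > max_seed_gap
        ):
            runs.append((int(qpos[rs]), int(qpos[i - 1]) + k, int(diag[rs])))
            rs = i
    return runs


def _hamming_identity(a: np.ndarray, b: np.ndarray) -> float:
    n = min(a.size, b.size)
    if n == 0:
        return 0.0
    return 100.0 * float(np.count_nonzero(a[:n] == b[:n])) / n


def align_nucleotide(
    genome_a: GenomeRecord,
    genome_b: GenomeRecord,
    seed_length: int = 15,
    min_hit: int = 100,
    max_seed_gap: int = 400,
) -> list[AlignmentHit]:
    """Gapless local hits between two genomes on both strands.  Circular
    subjects are searched through their doubled sequence and wrapped
    duplicates removed.  Subject coordinates are always reported on the
    forward strand of ``genome_b``."""
    if min(len(genome_a), len(genome_b)) < min_hit:
        raise ValueError("genomes shorter than min_hit")
    qcodes = _encode(genome_a.sequence)
    qk = _kmers(qcodes, seed_length)
    nb = len(genome_b)
    hits: list[AlignmentHit] = []
    for strand in "+-":
        sseq = genome_b.sequence if strand == "+" else reverse_complement(
            genome_b.sequence
        )
        if genome_b.circular:
            sseq_search = sseq + sseq[: seed_length - 1 + max_seed_gap]
        else:
            sseq_search = sseq
        index = _SeedIndex(sseq_search, seed_length)
        scodes = _encode(sseq_search)
        qpos, spos = index.hits(qk)
        # wrapped duplicates: canonicalize subject position modulo genome
        if genome_b.circular:
            keep = spos < nb
            qpos, spos = qpos[keep], spos[keep]
        for qs, qe, diag in _diagonal_runs(qpos, spos, seed_length, max_seed_gap):
            if qe - qs < min_hit:
                continue
            ss, se = qs + diag, qe + diag
            ident = _hamming_identity(qcodes[qs:qe], scodes[ss:se])
            if strand == "+":
                sstart, send = ss, se
            else:
                sstart, send = len(sseq) - se, len(sseq) - ss
            hits.append(AlignmentHit(
                query=genome_a.id, subject=genome_b.id,
                qstart=qs, qend=qe,
                sstart=int(sstart) % max(nb, 1), send=int(send),
                strand=strand,
                identity=ident,
                aln_length=qe - qs,
                query_coverage=100.0 * (qe - qs) / len(genome_a),
                score=float(qe - qs) * ident / 100.0,
            ))
    # drop hits fully contained in a longer hit on the same strand
    hits.sort(key=lambda h: (h.strand, h.qstart, -(h.qend - h.qstart)))
    kept: list[AlignmentHit] = []
    for h in hits:
        contained = any(
            k.strand == h.strand
            and k.qstart <= h.qstart
            and h.qend <= k.qend
            and k is not h
            and (k.qend - k.qstart) > (h.qend - h.qstart)
            for k in kept[-8:]
        )
        if not contained:
            kept.append(h)
    kept.sort(key=lambda h: (h.qstart, h.qend, h.strand))
    return kept


# ---------------------------------------------------------------------------
# ANI / AAI
# ---------------------------------------------------------------------------

def _ani_one_direction(
    query: GenomeRecord,
    subject: GenomeRecord,
    fragment: int,
    seed_length: int,
    min_fragment_coverage: float,
) -> tuple[float, float]:
    """(mean identity of accepted fragments, fraction accepted); identity is
    nan when nothing is accepted."""
    nq = len(query)
    n_frags = nq // fragment
    fwd = _SeedIndex(subject.sequence, seed_length)
    rc_seq = reverse_complement(subject.sequence)
    rev = _SeedIndex(rc_seq, seed_length)
    scodes = {"+": _encode(subject.sequence), "-": _encode(rc_seq)}
    qcodes = _encode(query.sequence)
    qk_all = _kmers(qcodes, seed_length)
    identities = []
    for f in range(n_frags):
        lo = f * fragment
        qk = qk_all[lo : lo + fragment - seed_length + 1]
        best = None  # (span, qs, qe, diag, strand)
        for strand, index in (("+", fwd), ("-", rev)):
            qpos, spos = index.hits(qk)
            for qs, qe, diag in _diagonal_runs(qpos, spos, seed_length,
                                               max_seed_gap=400):
                cand = (qe - qs, qs, qe, diag, strand)
                if best is None or cand[0] > best[0]:
                    best = cand
        if best is None:
            continue
        span, qs, qe, diag, strand = best
        if span / fragment < min_fragment_coverage:
            continue
        # trim the terminal seeds: their bases are exact matches by
        # construction and would bias identity upward
        tqs, tqe = qs + seed_length, qe - seed_length
        if tqe - tqs < seed_length:
            tqs, tqe = qs, qe
        a = qcodes[lo + tqs : lo + tqe]
        b = scodes[strand][tqs + diag : tqe + diag]
        identities.append(_hamming_identity(a, b))
    if not identities:
        return float("nan"), 0.0
    return float(np.mean(identities)), len(identities) / max(n_frags, 1)


def compute_ani(
    genome_a: GenomeRecord,
    genome_b: GenomeRecord,
    fragment: int = 1020,
    seed_length: int = 15,
    min_fragment_coverage: float = 0.70,
    symmetric: bool = True,
) -> AniResult:
    """Fragment-based average nucleotide identity, reported as the mean of
    the two directions.  Undefined (nan) when no fragment is accepted —
    genomes below ~80% identity share almost no exact 15-mers."""
    if min(len(genome_a), len(genome_b)) < 2 * fragment:
        raise ValueError("genomes must span at least two fragments")
    ab, frac_ab = _ani_one_direction(
        genome_a, genome_b, fragment, seed_length, min_fragment_coverage
    )
    if not symmetric:
        return AniResult(ab, frac_ab)
    ba, frac_ba = _ani_one_direction(
        genome_b, genome_a, fragment, seed_length, min_fragment_coverage
    )
    vals = [v for v in (ab, ba) if not math.isnan(v)]
    if not vals:
        return AniResult(float("nan"), 0.0)
    return AniResult(float(np.mean(vals)), float((frac_ab + frac_ba) / 2))


def ani_matrix(genomes: list[GenomeRecord], **kwargs):
    """Square symmetric ANI matrix as a pandas DataFrame (percent; nan on
    undefined pairs; 100 on the diagonal)."""
    import pandas as pd

    ids = [g.id for g in genomes]
    mat = pd.DataFrame(100.0, index=ids, columns=ids, dtype=float)
    for a, b in combinations(genomes, 2):
        r = compute_ani(a, b, **kwargs)
        mat.loc[a.id, b.id] = mat.loc[b.id, a.id] = r.ani
    return mat


def compute_aai(
    proteome_a: list[ProteinRecord],
    proteome_b: list[ProteinRecord],
    min_identity: float = 30.0,
    min_coverage: float = 50.0,
) -> AaiResult:
    """Average amino-acid identity over reciprocal-best-hit pairs meeting
    identity/coverage floors.  Undefined (nan) with zero RBH pairs."""
    if min(len(proteome_a), len(proteome_b)) < 10:
        raise ValueError("need at least 10 proteins per proteome")
    aligner = default_aligner()
    proteins = list(proteome_a) + list(proteome_b)
    na = len(proteome_a)
    pairs = candidate_pairs(proteins, min_shared=2)
    best_ab: dict[int, tuple[float, int, float]] = {}
    best_ba: dict[int, tuple[float, int, float]] = {}
    for i, j in sorted(pairs):
        if (i < na) == (j < na):
            continue  # same proteome
        i, j = (i, j) if i < na else (j, i)
        a, b = proteins[i], proteins[j]
        hit = align_protein_pair(a, b, aligner)
        if hit.identity < min_identity:
            continue
        if shorter_coverage(hit, len(a), len(b)) < min_coverage:
            continue
        # best hit: highest score, then identity, then smallest subject id
        for table, qi, sj in ((best_ab, i, j), (best_ba, j, i)):
            cand = (hit.score, hit.identity, proteins[sj].id)
            cur = table.get(qi)
            if (
                cur is None
                or cand[:2] > cur[0][:2]
                or (cand[:2] == cur[0][:2] and cand[2] < cur[0][2])
            ):
                table[qi] = (cand, sj, hit.identity)
    rbh_idents = []
    for i, (_, j, ident) in best_ab.items():
        back = best_ba.get(j)
        if back is not None and back[1] == i:
            rbh_idents.append(ident)
    if not rbh_idents:
        return AaiResult(float("nan"), 0)
    return AaiResult(float(np.mean(rbh_idents)), len(rbh_idents))
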