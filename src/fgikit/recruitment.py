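"""Metagenomic fragment recruitment onto reference genomes.

Reads are placed by exact-seed voting followed by gapless (Hamming)
rescoring of candidate placements — the model matches the simulator, whose
reads differ from their source by substitutions only.  Each read keeps its
single best location (ties to the lowest coordinate, then forward strand);
a read is accepted iff identity >= ``min_identity`` over an alignment
covering >= ``min_read_coverage`` of the read and >= ``min_len`` bases
(the classic ``-minid 0.95 -mincov 0.9 -minlen 50`` recruitment regime).

Depth is normalized to *coverage per Gb*: mean per-base depth scaled to a
one-gigabase sample (mean depth x 1e9 / total bases in the read sample), a
definition that is comparable across samples and halves exactly under
two-fold subsampling.  rRNA loci are masked before mapping: masked
positions never match a seed, accrue no depth and are excluded from means
and island calls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .seq_io import GenomeRecord, Read

_NT_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _NT_CODE[_b] = _i


class NoCoverageError(ValueError):
    """Genome median depth is zero; island gaps are undefined."""


@dataclass(frozen=True)
class ReadMapping:
    read_id: str
    genome_id: str
    start: int  # 0-based, may wrap on circular genomes
    aligned_length: int
    identity: float  # fraction in [0,1]
    strand: str


@dataclass
class RecruitmentProfile:
    genome_id: str
    depth: np.ndarray
    masked: np.ndarray  # bool, True where masked
    total_sample_bases: int

    @property
    def mean_depth(self) -> float:
        un = ~self.masked
        return float(self.depth[un].mean()) if un.any() else 0.0

    @property
    def median_depth(self) -> float:
        un = ~self.masked
        return float(np.median(self.depth[un])) if un.any() else 0.0

    @property
    def coverage_per_gb(self) -> float:
        return self.mean_depth * 1e9 / self.total_sample_bases


@dataclass(frozen=True)
class MetagenomicIsland:
    genome_id: str
    start: int
    end: int
    depth_ratio: float  # interval mean depth / genome median depth


# ---------------------------------------------------------------------------
# Subsampling
# ---------------------------------------------------------------------------

def subsample_reads(reads: list[Read], n: int, seed: int) -> list[Read]:
    """Uniform sample of ``n`` reads without replacement, deterministic per
    seed; requesting more reads than available returns everything with a
    warning."""
    if n >= len(reads):
        if n > len(reads):
            warnings.warn(
                f"requested {n} reads but only {len(reads)} available",
                stacklevel=2,
            )
        return list(reads)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(reads), size=n, replace=False)
    idx.sort()
    return [reads[i] for i in idx]


# ---------------------------------------------------------------------------
# Read mapping
# ---------------------------------------------------------------------------

def rrna_mask(genome: GenomeRecord) -> list[tuple[int, int]]:
    """Intervals of annotated rRNA features (the standard pre-recruitment
    mask)."""
    return [(f.start, f.end) for f in genome.features if f.kind == "rRNA"]


def _mask_array(n: int, intervals) -> np.ndarray:
    masked = np.zeros(n, dtype=bool)
    for s, e in intervals or []:
        masked[max(0, s) : min(n, e)] = True
    return masked


def _codes(seq: str) -> np.ndarray:
    return _NT_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_ints(mat: np.ndarray, offset: int, k: int) -> np.ndarray:
    """Integer k-mers starting at ``offset`` for each row; -1 where any base
    is non-ACGT."""
    out = np.zeros(mat.shape[0], dtype=np.int64)
    bad = np.zeros(mat.shape[0], dtype=bool)
    for j in range(k):
        col = mat[:, offset + j].astype(np.int64)
        out = out * 4 + np.where(col < 4, col, 0)
        bad |= col >= 4
    out[bad] = -1
    return out


def map_reads(
    reads: list[Read],
    genome: GenomeRecord,
    min_identity: float = 0.95,
    min_read_coverage: float = 0.90,
    min_len: int = 50,
    masked_intervals: list[tuple[int, int]] | None = None,
    seed_length: int = 15,
    max_candidates: int = 4,
) -> list[ReadMapping]:
    """Best-location-only recruitment of reads onto one genome (circular
    wrap allowed); see module docstring for the acceptance rule."""
    if not reads:
        return []
    n = len(genome)
    gcodes = _codes(genome.sequence).copy()
    masked = _mask_array(n, masked_intervals)
    gcodes[masked] = 4  # masked bases never match
    lengths = sorted({len(r.sequence) for r in reads})
    max_len = lengths[-1]
    if genome.circular:
        gext = np.concatenate([gcodes, gcodes[: max_len - 1]])
    else:
        gext = gcodes
    # sorted seed index of the (extended) genome
    ng = gext.size - seed_length + 1
    gk = np.zeros(ng, dtype=np.int64)
    bad = np.zeros(ng, dtype=bool)
    for j in range(seed_length):
        w = gext[j : j + ng].astype(np.int64)
        gk = gk * 4 + np.where(w < 4, w, 0)
        bad |= w >= 4
    gk[bad] = -1
    order = np.argsort(gk, kind="stable")
    gk_sorted = gk[order]

    results: list[ReadMapping] = []
    by_len: dict[int, list[int]] = {}
    for i, r in enumerate(reads):
        by_len.setdefault(len(r.sequence), []).append(i)

    for L, read_idx in sorted(by_len.items()):
        if L < seed_length:
            continue
        sub = [reads[i] for i in read_idx]
        fwd = np.vstack([
            _codes(r.sequence) for r in sub
        ])
        rc = 3 - fwd[:, ::-1]
        rc[fwd[:, ::-1] >= 4] = 4
        offsets = list(range(0, L - seed_length + 1, seed_length))
        cand: dict[int, dict[tuple[int, str], int]] = {}
        for strand, mat in (("+", fwd), ("-", rc)):
            for off in offsets:
                kmers = _kmer_ints(mat, off, seed_length)
                left = np.searchsorted(gk_sorted, kmers, "left")
                right = np.searchsorted(gk_sorted, kmers, "right")
                counts = right - left
                hit_rows = np.nonzero(
                    (kmers >= 0) & (counts > 0) & (counts <= 50)
                )[0]
                for row in hit_rows:
                    for pos in order[left[row] : right[row]]:
                        start = int(pos) - off
                        if start < 0 or start >= n + (0 if not genome.circular
                                                      else n):
                            continue
                        votes = cand.setdefault(int(row), {})
                        key = (start, strand)
                        votes[key] = votes.get(key, 0) + 1
        for row, votes in cand.items():
            ranked = sorted(
                votes.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1])
            )[:max_candidates]
            read = sub[row]
            best = None
            for (start, strand), _v in ranked:
                if genome.circular:
                    start_mod = start % n
                    seg = gext[start_mod : start_mod + L]
                else:
                    start_mod = start
                    seg = gext[start : start + L]
                alen = seg.size
                if alen < max(min_len, 1):
                    continue
                row_codes = fwd[row] if strand == "+" else rc[row]
                matches = int(np.count_nonzero(seg == row_codes[:alen]))
                ident = matches / alen
                key = (-ident, start_mod, 0 if strand == "+" else 1)
                if best is None or key < best[0]:
                    best = (key, start_mod, alen, ident, strand)
            if best is None:
                continue
            _, start_mod, alen, ident, strand = best
            if (
                ident >= min_identity
                and alen >= min_len
                and alen >= min_read_coverage * L
            ):
                results.append(ReadMapping(
                    read_id=read.id, genome_id=genome.id,
                    start=start_mod, aligned_length=alen,
                    identity=ident, strand=strand,
                ))
    results.sort(key=lambda m: (m.start, m.read_id))
    return results


# ---------------------------------------------------------------------------
# Profiles and derived statistics
# ---------------------------------------------------------------------------

def coverage_profile(
    mappings: list[ReadMapping],
    genome: GenomeRecord,
    total_sample_bases: int,
    masked_intervals: list[tuple[int, int]] | None = None,
) -> RecruitmentProfile:
    """Per-base depth over accepted mappings; masked positions carry zero
    depth and are excluded from the mean."""
    if total_sample_bases <= 0:
        raise ValueError("total_sample_bases must be positive")
    n = len(genome)
    delta = np.zeros(n + 1, dtype=np.int64)
    for m in mappings:
        if m.genome_id != genome.id:
            raise ValueError("mapping belongs to a different genome")
        end = m.start + m.aligned_length
        if end <= n:
            delta[m.start] += 1
            delta[end] -= 1
        else:  # circular wrap
            delta[m.start] += 1
            delta[n] -= 1
            delta[0] += 1
            delta[end - n] -= 1
    depth = np.cumsum(delta[:-1])
    masked = _mask_array(n, masked_intervals)
    depth[masked] = 0
    return RecruitmentProfile(
        genome_id=genome.id,
        depth=depth,
        masked=masked,
        total_sample_bases=total_sample_bases,
    )


def identity_histogram(
    reads: list[Read],
    genome: GenomeRecord,
    floor: float = 0.70,
    masked_intervals: list[tuple[int, int]] | None = None,
    **map_kwargs,
) -> np.ndarray:
    """Best-hit identity per read binned at 1% resolution from ``floor`` to
    100%; reads below the floor (or unmapped) are uncounted.  Bin ``i``
    holds identities in [floor*100 + i, floor*100 + i + 1), with 100%
    falling in the last bin."""
    n_bins = int(round((1.0 - floor) * 100)) + 1
    counts = np.zeros(n_bins, dtype=np.int64)
    mappings = map_reads(
        reads, genome, min_identity=floor, min_read_coverage=0.0,
        min_len=1, masked_intervals=masked_intervals, **map_kwargs,
    )
    lo = floor * 100
    for m in mappings:
        b = int(m.identity * 100 - lo)
        counts[min(b, n_bins - 1)] += 1
    return counts


def detect_metagenomic_islands(
    profile: RecruitmentProfile,
    window: int = 5000,
    depth_fraction: float = 0.2,
) -> list[MetagenomicIsland]:
    """Maximal intervals >= ``window`` where window-smoothed depth falls
    below ``depth_fraction`` x the genome median depth; masked intervals are
    never reported."""
    med = profile.median_depth
    if med <= 0:
        raise NoCoverageError("genome median depth is zero")
    if depth_fraction <= 0:
        return []
    n = profile.depth.size
    w = min(window, n)
    kernel = np.ones(w) / w
    padded = np.concatenate([profile.depth[-(w // 2):],
                             profile.depth,
                             profile.depth[: w - w // 2]])
    smoothed = np.convolve(padded, kernel, mode="valid")[:n]
    low = (smoothed < depth_fraction * med) & ~profile.masked
    out = []
    i = 0
    while i < n:
        if low[i]:
            j = i
            while j < n and low[j]:
                j += 1
            if j - i >= window:
                seg = profile.depth[i:j]
                out.append(MetagenomicIsland(
                    genome_id=profile.genome_id,
                    start=i, end=j,
                    depth_ratio=float(seg.mean()) / med,
                ))
            i = j
        else:
            i += 1
    return out


def region_relative_coverage(
    profile: RecruitmentProfile,
    regions: list[tuple[int, int]],
) -> list[float]:
    """Per-region mean depth divided by genome mean depth, masked positions
    excluded from both."""
    genome_mean = profile.mean_depth
    if genome_mean <= 0:
        raise NoCoverageError("genome mean depth is zero")
    out = []
    for s, e in regions:
        if not (0 <= s < e <= profile.depth.size):
            raise ValueError(f"region ({s},{e}) outside genome")
        un = ~profile.masked[s:e]
        if not un.any():
            raise ValueError(f"region ({s},{e}) fully masked or empty")
        out.append(float(profile.depth[s:e][un].mean()) / genome_mean)
    return out
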