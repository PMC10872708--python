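"""Island candidate detection from synteny breaks and low-score gene runs.

Two independent lines of evidence, mirroring how flexible islands reveal
themselves in closely related genomes:

* ``alignment_gap`` — regions of the focal genome not covered by >= 95%
  identity nucleotide alignment against a within-species partner (the
  island cargo differs, so the region drops out of the alignment);
* ``low_score_stretch`` — runs of consecutive genes whose best protein hit
  in a partner genome is weak or absent.

Evidence is collected per within-species partner, merged per focal genome,
and kept when it recurs in at least ``min_recurrence`` of the comparisons.
Large inversions appear as runs of inverted-orientation synteny blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align_core import AlignmentHit
from .seq_io import GenomeRecord, ProteinRecord


@dataclass
class DetectParams:
    gap_min_span: int = 5000
    low_score_identity_cutoff: float = 50.0
    min_consecutive_genes: int = 3
    min_recurrence: float = 0.5
    block_identity_floor: float = 80.0
    gap_identity_threshold: float = 95.0
    max_chain_gap: int = 2000
    max_diag_drift: int = 30
    # covered islets shorter than this (lone conserved RNA genes inside an
    # otherwise alien region) do not interrupt a gap
    min_covered_span: int = 1000

    def __post_init__(self):
        if min(self.gap_min_span, self.min_consecutive_genes) <= 0:
            raise ValueError("spans and gene counts must be positive")
        if not 0 <= self.min_recurrence <= 1:
            raise ValueError("min_recurrence must be in [0,1]")


@dataclass
class SyntenyBlock:
    query_genome: str
    subject_genome: str
    qstart: int
    qend: int
    sstart: int
    send: int
    orientation: str  # same | inverted
    mean_identity: float
    hits: list[AlignmentHit] = field(default_factory=list)


@dataclass
class IslandCandidate:
    genome_id: str
    start: int
    end: int
    evidence: frozenset[str]
    recurrence: float
    gene_span: int = 0

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


# ---------------------------------------------------------------------------
# Synteny blocks and inversions
# ---------------------------------------------------------------------------

def compute_synteny_blocks(
    hits: list[AlignmentHit], params: DetectParams | None = None
) -> list[SyntenyBlock]:
    """Chain collinear same-orientation hits of one genome pair into maximal
    blocks.  A chain breaks when the query gap exceeds ``max_chain_gap`` or
    the diagonal drifts by more than ``max_diag_drift`` (an insertion or
    deletion larger than local alignment wobble).  Blocks below
    ``block_identity_floor`` are discarded."""
    params = params or DetectParams()
    blocks: list[SyntenyBlock] = []
    for strand in "+-":
        sh = sorted(
            (h for h in hits if h.strand == strand), key=lambda h: h.qstart
        )
        chain: list[AlignmentHit] = []
        for h in sh:
            if chain:
                prev = chain[-1]
                if strand == "+":
                    drift = (h.sstart - h.qstart) - (prev.sstart - prev.qstart)
                else:
                    drift = (h.sstart + h.qend) - (prev.sstart + prev.qend)
                if (
                    h.qstart - prev.qend > params.max_chain_gap
                    or abs(drift) > params.max_diag_drift
                ):
                    blocks.extend(_finish_chain(chain, strand, params))
                    chain = []
            chain.append(h)
        blocks.extend(_finish_chain(chain, strand, params))
    blocks.sort(key=lambda b: b.qstart)
    return blocks


def _finish_chain(chain, strand, params) -> list[SyntenyBlock]:
    if not chain:
        return []
    total = sum(h.aln_length for h in chain)
    ident = sum(h.identity * h.aln_length for h in chain) / total
    if ident < params.block_identity_floor:
        return []
    sstarts = [h.sstart for h in chain]
    sends = [h.send for h in chain]
    return [SyntenyBlock(
        query_genome=chain[0].query,
        subject_genome=chain[0].subject,
        qstart=chain[0].qstart,
        qend=chain[-1].qend,
        sstart=min(sstarts),
        send=max(sends),
        orientation="same" if strand == "+" else "inverted",
        mean_identity=ident,
        hits=list(chain),
    )]


def detect_inversion(blocks: list[SyntenyBlock],
                     min_span: int = 1000) -> list[tuple[int, int, int, int]]:
    """Maximal runs of inverted-orientation blocks, reported as
    (qstart, qend, sstart, send) covering the run on both genomes."""
    ordered = sorted(blocks, key=lambda b: b.qstart)
    out = []
    run: list[SyntenyBlock] = []
    for b in ordered + [None]:
        if b is not None and b.orientation == "inverted":
            run.append(b)
            continue
        if run:
            qs, qe = run[0].qstart, run[-1].qend
            ss = min(x.sstart for x in run)
            se = max(x.send for x in run)
            if qe - qs >= min_span:
                out.append((qs, qe, ss, se))
            run = []
    return out


# ---------------------------------------------------------------------------
# Alignment gaps
# ---------------------------------------------------------------------------

def find_alignment_gaps(
    blocks: list[SyntenyBlock],
    genome: GenomeRecord,
    params: DetectParams | None = None,
) -> list[tuple[int, int]]:
    """Intervals of the focal (query) genome not covered by block hits at
    >= ``gap_identity_threshold`` identity, filtered to spans >=
    ``gap_min_span``.  Hit columns below the threshold count as uncovered."""
    params = params or DetectParams()
    covered: list[tuple[int, int]] = []
    for b in blocks:
        for h in b.hits:
            if h.identity >= params.gap_identity_threshold:
                covered.append((h.qstart, h.qend))
    covered.sort()
    merged: list[list[int]] = []
    for s, e in covered:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    merged = [iv for iv in merged if iv[1] - iv[0] >= params.min_covered_span]
    gaps = []
    prev = 0
    for s, e in merged + [[len(genome), len(genome)]]:
        if s - prev >= params.gap_min_span:
            gaps.append((prev, s))
        prev = max(prev, e)
    return gaps


# ---------------------------------------------------------------------------
# Low-score gene stretches
# ---------------------------------------------------------------------------

def _ordered_cds(genome: GenomeRecord):
    return [f for f in genome.features if f.kind == "CDS"]


def find_low_score_stretches(
    focal: GenomeRecord,
    partner_ids: list[str],
    proteomes_by_genome: dict[str, list[ProteinRecord]],
    hits: list[AlignmentHit],
    params: DetectParams | None = None,
) -> list[IslandCandidate]:
    """Runs of >= ``min_consecutive_genes`` consecutive focal genes whose
    best protein hit in a partner genome is below
    ``low_score_identity_cutoff`` (or absent).  Per-partner runs are merged;
    recurrence is the fraction of partners supporting the merged run."""
    params = params or DetectParams()
    cds = _ordered_cds(focal)
    if not cds or not partner_ids:
        return []
    protein_by_cds = {
        p.source_cds: p for p in proteomes_by_genome.get(focal.id, [])
    }
    genome_of_protein = {
        p.id: gid for gid, ps in proteomes_by_genome.items() for p in ps
    }
    best: dict[tuple[str, str], float] = {}  # (query protein, partner) -> identity
    for h in hits:
        pg = genome_of_protein.get(h.subject)
        if pg is None or pg not in partner_ids:
            continue
        key = (h.query, pg)
        if h.identity > best.get(key, -1.0):
            best[key] = h.identity
    runs_by_partner: dict[str, list[tuple[int, int]]] = {}
    for partner in partner_ids:
        low = []
        for i, feat in enumerate(cds):
            prot = protein_by_cds.get(feat.id)
            ident = best.get((prot.id, partner), None) if prot else None
            low.append(ident is None or ident < params.low_score_identity_cutoff)
        runs = []
        i = 0
        while i < len(low):
            if low[i]:
                j = i
                while j < len(low) and low[j]:
                    j += 1
                if j - i >= params.min_consecutive_genes:
                    runs.append((i, j))
                i = j
            else:
                i += 1
        runs_by_partner[partner] = runs
    # merge overlapping gene-index runs across partners
    all_runs = sorted(
        (r, p) for p, rs in runs_by_partner.items() for r in rs
    )
    merged: list[tuple[list[int], set[str]]] = []
    for (s, e), partner in all_runs:
        if merged and s <= merged[-1][0][1]:
            merged[-1][0][1] = max(merged[-1][0][1], e)
            merged[-1][1].add(partner)
        else:
            merged.append(([s, e], {partner}))
    out = []
    for (s, e), supporters in merged:
        out.append(IslandCandidate(
            genome_id=focal.id,
            start=cds[s].start,
            end=cds[e - 1].end,
            evidence=frozenset({"low_score_stretch"}),
            recurrence=len(supporters) / len(partner_ids),
            gene_span=e - s,
        ))
    return out


# ---------------------------------------------------------------------------
# Candidate merging
# ---------------------------------------------------------------------------

def gaps_to_candidates(
    gaps_by_partner: dict[str, list[tuple[int, int]]],
    genome: GenomeRecord,
) -> list[IslandCandidate]:
    """Combine per-partner alignment gaps on one focal genome into
    candidates; recurrence is the fraction of partners showing an
    overlapping gap."""
    n = len(gaps_by_partner)
    entries = sorted(
        (iv, p) for p, ivs in gaps_by_partner.items() for iv in ivs
    )
    merged: list[tuple[list[int], set[str]]] = []
    for (s, e), partner in entries:
        if merged and s <= merged[-1][0][1]:
            merged[-1][0][1] = max(merged[-1][0][1], e)
            merged[-1][1].add(partner)
        else:
            merged.append(([s, e], {partner}))
    return [
        IslandCandidate(
            genome_id=genome.id, start=s, end=e,
            evidence=frozenset({"alignment_gap"}),
            recurrence=len(supporters) / max(n, 1),
        )
        for (s, e), supporters in merged
    ]


def merge_candidates(
    candidates: list[IslandCandidate],
    params: DetectParams | None = None,
) -> list[IslandCandidate]:
    """Unite overlapping candidate intervals on one focal genome, merging
    evidence sets and keeping the highest recurrence; candidates below
    ``min_recurrence`` are dropped; output sorted by position."""
    params = params or DetectParams()
    if not candidates:
        return []
    genome_ids = {c.genome_id for c in candidates}
    if len(genome_ids) != 1:
        raise ValueError("merge_candidates expects candidates of one genome")
    ordered = sorted(candidates, key=lambda c: (c.start, c.end))
    merged: list[IslandCandidate] = []
    for c in ordered:
        if merged and c.start <= merged[-1].end:
            prev = merged[-1]
            merged[-1] = IslandCandidate(
                genome_id=c.genome_id,
                start=prev.start,
                end=max(prev.end, c.end),
                evidence=prev.evidence | c.evidence,
                recurrence=max(prev.recurrence, c.recurrence),
                gene_span=max(prev.gene_span, c.gene_span),
            )
        else:
            merged.append(c)
    return [c for c in merged if c.recurrence >= params.min_recurrence]
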