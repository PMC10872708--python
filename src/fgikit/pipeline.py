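"""End-to-end island analysis: proteomes, orthologs, detection, typing.

This is the glue used by the command-line interface and the acceptance
checks: given a set of annotated genomes of one species (or a species
assignment for a mixed set), it runs the all-vs-all protein comparison,
clusters orthologs, aligns every within-species genome pair, collects gap
and low-score evidence per focal genome, merges candidates and types them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .align_core import AlignmentHit, align_nucleotide, all_vs_all_protein
from .island_classify import IslandCall, SignatureConfig, classify_island
from .island_detect import (DetectParams, IslandCandidate, SyntenyBlock,
                            compute_synteny_blocks, detect_inversion,
                            find_alignment_gaps, find_low_score_stretches,
                            gaps_to_candidates, merge_candidates)
from .pangenome import OrthologCluster, cluster_orthologs, core_cluster_ids
from .seq_io import GenomeRecord, ProteinRecord, proteome


@dataclass
class IslandAnalysis:
    genomes: dict[str, GenomeRecord]
    proteomes: dict[str, list[ProteinRecord]]
    protein_hits: list[AlignmentHit]
    clusters: list[OrthologCluster]
    core_genes: dict[str, set[str]]  # genome id -> CDS feature ids in core clusters
    blocks: dict[tuple[str, str], list[SyntenyBlock]]
    candidates: dict[str, list[IslandCandidate]]
    calls: dict[str, list[IslandCall]]
    inversions: dict[tuple[str, str], list[tuple[int, int, int, int]]] = field(
        default_factory=dict
    )


def _core_gene_ids(
    clusters: list[OrthologCluster], genome_ids: list[str]
) -> dict[str, set[str]]:
    core = core_cluster_ids(clusters, genome_ids)
    out: dict[str, set[str]] = {g: set() for g in genome_ids}
    by_id = {c.cluster_id: c for c in clusters}
    for cid in core:
        for genome_id, protein_id in by_id[cid].members:
            if genome_id in out:
                # protein ids are "<genome>|<cds id>"
                cds_id = protein_id.split("|", 1)[1] if "|" in protein_id \
                    else protein_id
                out[genome_id].add(cds_id)
    return out


def analyze_islands(
    genomes: list[GenomeRecord],
    species_of: dict[str, str] | None = None,
    params: DetectParams | None = None,
    signatures: SignatureConfig | None = None,
) -> IslandAnalysis:
    """Detect and type flexible genomic islands across a genome set.
    ``species_of`` restricts pairwise comparisons to within-species pairs;
    by default all genomes are treated as one species."""
    params = params or DetectParams()
    signatures = signatures or SignatureConfig()
    by_id = {g.id: g for g in genomes}
    ids = sorted(by_id)
    if species_of is None:
        species_of = {g: "species1" for g in ids}
    proteomes = {g: proteome(by_id[g]) for g in ids}
    hits = all_vs_all_protein(
        [proteomes[g] for g in ids],
        min_identity=params.low_score_identity_cutoff,
        min_coverage=50.0,
    )
    proteins = [p for g in ids for p in proteomes[g]]
    clusters = cluster_orthologs(hits, proteins)
    # core membership is evaluated within each species
    core_genes: dict[str, set[str]] = {}
    for sp in sorted(set(species_of.values())):
        members = [g for g in ids if species_of[g] == sp]
        core_genes.update(_core_gene_ids(clusters, members))

    blocks: dict[tuple[str, str], list[SyntenyBlock]] = {}
    inversions: dict[tuple[str, str], list] = {}
    candidates: dict[str, list[IslandCandidate]] = {}
    calls: dict[str, list[IslandCall]] = {}
    for focal_id in ids:
        partners = [
            g for g in ids
            if g != focal_id and species_of[g] == species_of[focal_id]
        ]
        focal = by_id[focal_id]
        gaps_by_partner: dict[str, list[tuple[int, int]]] = {}
        for partner in partners:
            key = (focal_id, partner)
            if key not in blocks:
                nhits = align_nucleotide(focal, by_id[partner])
                blocks[key] = compute_synteny_blocks(nhits, params)
                inversions[key] = detect_inversion(blocks[key])
            gaps_by_partner[partner] = find_alignment_gaps(
                blocks[key], focal, params
            )
        gap_cands = gaps_to_candidates(gaps_by_partner, focal) if partners \
            else []
        stretch_cands = find_low_score_stretches(
            focal, partners, proteomes, hits, params
        )
        merged = merge_candidates(gap_cands + stretch_cands, params)
        candidates[focal_id] = merged
        calls[focal_id] = [
            classify_island(c, focal, core_genes.get(focal_id, set()),
                            signatures)
            for c in merged
        ]
    return IslandAnalysis(
        genomes=by_id,
        proteomes=proteomes,
        protein_hits=hits,
        clusters=clusters,
        core_genes=core_genes,
        blocks=blocks,
        candidates=candidates,
        calls=calls,
        inversions=inversions,
    )


def evaluate_calls(
    calls: dict[str, list[IslandCall]],
    truth_islands: dict[str, list],
    genomes: dict[str, GenomeRecord],
    min_truth_size: int = 10_000,
) -> dict[str, float]:
    """Compare island calls with planted truth: recall over truth islands
    >= ``min_truth_size``, interval-level precision, worst boundary error in
    genes, and typing accuracy over matched calls."""
    n_truth = n_recalled = 0
    n_calls = n_matched = 0
    n_typed = n_typed_correct = 0
    worst_boundary = 0
    for gid, truths in truth_islands.items():
        genome = genomes[gid]
        cds = [f for f in genome.features if f.kind == "CDS"]
        gcalls = calls.get(gid, [])
        n_calls += len(gcalls)
        for call in gcalls:
            if any(call.start < t.end and t.start < call.end for t in truths):
                n_matched += 1
        for t in truths:
            overlapping = [
                c for c in gcalls if c.start < t.end and t.start < c.end
            ]
            big = (t.end - t.start) >= min_truth_size
            if big:
                n_truth += 1
            if not overlapping:
                continue
            best = max(overlapping,
                       key=lambda c: min(c.end, t.end) - max(c.start, t.start))
            if big:
                n_recalled += 1
                for t_pos, c_pos in ((t.start, best.start), (t.end, best.end)):
                    lo, hi = sorted((t_pos, c_pos))
                    err = sum(1 for f in cds if f.start >= lo and f.end <= hi)
                    worst_boundary = max(worst_boundary, err)
            n_typed += 1
            if best.island_type == t.island_type:
                n_typed_correct += 1
    return {
        "recall": n_recalled / n_truth if n_truth else float("nan"),
        "precision": n_matched / n_calls if n_calls else float("nan"),
        "max_boundary_error_genes": float(worst_boundary),
        "typing_accuracy": n_typed_correct / n_typed if n_typed else
        float("nan"),
    }
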