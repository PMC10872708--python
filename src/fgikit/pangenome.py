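"""Ortholog clustering, core/pan-genome summaries and species delineation.

Orthologs are the connected components of the undirected protein hit graph
thresholded at >=50% identity and >=50% coverage (single-linkage — the
simplest faithful reading of an identity/coverage ortholog definition, and
directly checkable against a transitive-closure brute force).  Species are
the connected components of the genome graph with edges at ANI >= 95%, the
operational prokaryotic species boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .align_core import (AlignmentHit, align_protein_pair, default_aligner,
                         shorter_coverage, candidate_pairs)
from .seq_io import ProteinRecord


@dataclass
class OrthologCluster:
    cluster_id: str
    members: set[tuple[str, str]]  # (genome id, gene id)
    representative: tuple[str, str]

    def genomes(self) -> set[str]:
        return {g for g, _ in self.members}


@dataclass
class PangenomeSummary:
    n_core: int
    n_accessory: int
    core_curve: np.ndarray  # mean core size after adding 1..n genomes
    pan_curve: np.ndarray
    core_curve_sd: np.ndarray
    pan_curve_sd: np.ndarray

    @property
    def n_total(self) -> int:
        return self.n_core + self.n_accessory


@dataclass
class SpeciesPartition:
    ani_matrix: pd.DataFrame
    assignment: dict[str, str]
    threshold: float

    def species(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for g, s in self.assignment.items():
            out.setdefault(s, []).append(g)
        return {s: sorted(gs) for s, gs in out.items()}


def _protein_key(p: ProteinRecord) -> tuple[str, str]:
    return (p.genome_id, p.id)


def cluster_orthologs(
    hits: list[AlignmentHit],
    proteins: list[ProteinRecord],
    min_identity: float = 50.0,
    min_coverage: float = 50.0,
) -> list[OrthologCluster]:
    """Single-linkage ortholog families: connected components of the hit
    graph after re-applying the identity/coverage thresholds (coverage on
    the shorter sequence).  Genes without any accepted hit form singleton
    clusters."""
    by_id = {p.id: p for p in proteins}
    graph = nx.Graph()
    for p in proteins:
        graph.add_node(p.id)
    for h in hits:
        if h.query == h.subject:
            continue
        q, s = by_id.get(h.query), by_id.get(h.subject)
        if q is None or s is None:
            continue
        if h.identity < min_identity:
            continue
        if shorter_coverage(h, len(q), len(s)) < min_coverage:
            continue
        graph.add_edge(h.query, h.subject)
    clusters = []
    comps = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    for i, comp in enumerate(comps):
        members = {_protein_key(by_id[pid]) for pid in comp}
        rep = max(comp, key=lambda pid: (len(by_id[pid].sequence), pid))
        clusters.append(OrthologCluster(
            cluster_id=f"clu{i:05d}",
            members=members,
            representative=_protein_key(by_id[rep]),
        ))
    return clusters


def core_cluster_ids(clusters: list[OrthologCluster],
                     genome_ids: list[str]) -> set[str]:
    need = set(genome_ids)
    return {c.cluster_id for c in clusters if need <= c.genomes()}


def pangenome_summary(
    clusters: list[OrthologCluster],
    genome_ids: list[str],
    n_permutations: int = 100,
    seed: int = 0,
) -> PangenomeSummary:
    """Core/pan counts and genome-accumulation curves averaged over seeded
    permutations of genome addition order (means +- sd)."""
    if len(genome_ids) < 1:
        raise ValueError("need at least one genome")
    presence = {
        c.cluster_id: frozenset(c.genomes() & set(genome_ids))
        for c in clusters
    }
    presence = {cid: gs for cid, gs in presence.items() if gs}
    need = set(genome_ids)
    n_core = sum(1 for gs in presence.values() if need <= gs)
    n_total = len(presence)
    rng = np.random.default_rng(seed)
    n = len(genome_ids)
    cores = np.zeros((n_permutations, n))
    pans = np.zeros((n_permutations, n))
    ids = np.array(genome_ids)
    for p in range(n_permutations):
        order = ids[rng.permutation(n)]
        seen: set[str] = set()
        for i, gid in enumerate(order):
            seen.add(gid)
            core = pan = 0
            for gs in presence.values():
                inter = not seen.isdisjoint(gs)
                if inter:
                    pan += 1
                    if seen <= gs:
                        core += 1
            cores[p, i] = core
            pans[p, i] = pan
    return PangenomeSummary(
        n_core=n_core,
        n_accessory=n_total - n_core,
        core_curve=cores.mean(axis=0),
        pan_curve=pans.mean(axis=0),
        core_curve_sd=cores.std(axis=0),
        pan_curve_sd=pans.std(axis=0),
    )


def delineate_species(
    ani: pd.DataFrame, threshold: float = 95.0, atol: float = 0.5
) -> SpeciesPartition:
    """Species as connected components of the genome graph with edges where
    ANI >= threshold.  Labels are assigned in order of each component's
    smallest genome id, so they are stable under genome reordering."""
    if ani.shape[0] != ani.shape[1] or list(ani.index) != list(ani.columns):
        raise ValueError("ANI matrix must be square with matching labels")
    vals = ani.to_numpy(dtype=float)
    asym = np.nanmax(np.abs(vals - vals.T)) if vals.size else 0.0
    if asym > atol:
        raise ValueError(f"ANI matrix asymmetric beyond tolerance ({asym:.2f})")
    graph = nx.Graph()
    graph.add_nodes_from(ani.index)
    ids = list(ani.index)
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            b = ids[j]
            v = np.nanmean([vals[i, j], vals[j, i]])
            if not np.isnan(v) and v >= threshold:
                graph.add_edge(a, b)
    comps = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    assignment = {}
    for i, comp in enumerate(comps):
        label = f"species{i + 1}"
        for g in sorted(comp):
            assignment[g] = label
    return SpeciesPartition(ani_matrix=ani, assignment=assignment,
                           threshold=threshold)


def species_unique_genes(
    target_proteins: list[ProteinRecord],
    other_proteins: list[list[ProteinRecord]],
    min_identity: float = 95.0,
    min_coverage: float = 50.0,
) -> set[str]:
    """Cross-species de-replication: a target gene is unique iff no protein
    of any other species aligns to it at >= min_identity over
    >= min_coverage of the shorter sequence."""
    if not target_proteins or not other_proteins:
        raise ValueError("empty protein sets")
    others = [p for group in other_proteins for p in group]
    aligner = default_aligner()
    if min_identity <= 0:
        return set()
    pool = list(target_proteins) + list(others)
    n_t = len(target_proteins)
    pairs = candidate_pairs(pool, min_shared=2)
    matched: set[str] = set()
    for i, j in sorted(pairs):
        if (i < n_t) == (j < n_t):
            continue
        i, j = (i, j) if i < n_t else (j, i)
        t = pool[i]
        if t.id in matched:
            continue
        hit = align_protein_pair(t, pool[j], aligner)
        if hit.identity >= min_identity and shorter_coverage(
            hit, len(t), len(pool[j])
        ) >= min_coverage:
            matched.add(t.id)
    return {p.id for p in target_proteins} - matched
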