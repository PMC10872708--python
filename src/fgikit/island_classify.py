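"""Structural typing of island candidates and per-island protein sharing.

Typing rules, applied in order of decreasing signature specificity
(replacement and tycheposon signatures combine two independent features):

1. **replacement** — a tRNA-Ser(gga) and a tRNA-Arg(cct) within two genes
   of opposite candidate boundaries, plus a tmRNA inside the island;
2. **tycheposon** — a tRNA-Met(cat) reachable from a candidate boundary
   through consecutive non-core genes, with a xerD-like tyrosine
   recombinase inside; the call spans from the tRNA to the first core-
   cluster gene (the glmS analogue), in whichever orientation the element
   was inserted;
3. **additive** — at least two direct repeats of the 3'-terminal 20-mer of
   the tRNA-Lys(ctt) gene inside the candidate plus 1 kb upstream;
4. **insertion** — a xerC-like recombinase within two genes of a boundary.

All evidence is collected regardless of which rule fires, so the call is a
pure function of the recorded evidence; candidates matching nothing stay
``unclassified``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align_core import align_protein_pair, default_aligner, shorter_coverage
from .island_detect import IslandCandidate
from .references import RECOMBINASE_REFERENCES
from .seq_io import (GeneFeature, GenomeRecord, InternalStopError,
                     ProteinRecord, reverse_complement, translate_cds)


@dataclass
class SignatureConfig:
    motif_length: int = 20
    replacement_flanks: tuple[str, str] = ("gga", "cct")  # tRNA-Ser, tRNA-Arg
    additive_trna: str = "ctt"  # tRNA-Lys
    tycheposon_trna: str = "cat"  # tRNA-Met
    recombinase_references: dict[str, str] = field(
        default_factory=lambda: dict(RECOMBINASE_REFERENCES)
    )
    # 40% keeps diverged family members while staying clear of the random-
    # protein null (optimal local alignments of unrelated ~300-aa proteins
    # occasionally reach ~30% identity at 50% coverage)
    recombinase_min_identity: float = 40.0
    recombinase_min_coverage: float = 50.0
    flank_gene_window: int = 2  # "within 2 genes" of a boundary
    additive_upstream: int = 1000
    max_span_scan: int = 200_000

    def __post_init__(self):
        if self.motif_length <= 0:
            raise ValueError("motif_length must be positive")


@dataclass
class RecombinaseHit:
    label: str  # xerD | xerC
    identity: float
    cds_id: str


@dataclass
class IslandEvidence:
    flank_trnas: tuple[str | None, str | None] = (None, None)
    tmrna_present: bool = False
    repeat_positions: tuple[int, ...] = ()
    recombinases: tuple[RecombinaseHit, ...] = ()
    boundary_trna_id: str | None = None
    terminal_core_gene: str | None = None


@dataclass
class IslandCall:
    candidate: IslandCandidate
    island_type: str  # replacement | additive | tycheposon | insertion | unclassified
    start: int
    end: int
    evidence: IslandEvidence


class UnannotatedGenomeError(ValueError):
    """Classification needs tRNA annotations; run annotation (e.g.
    naive_orf_call plus tRNA features) first."""


class UnboundedSpanError(ValueError):
    """No core gene terminates the element within the scan limit."""


# ---------------------------------------------------------------------------
# Signature primitives
# ---------------------------------------------------------------------------

def extract_trna_terminal_repeat(
    trna: GeneFeature, genome: GenomeRecord, motif_length: int = 20
) -> str:
    """The 3'-terminal ``motif_length`` bases of a tRNA gene in coding
    orientation (the portion duplicated as a direct repeat at additive
    island cassette junctions)."""
    if trna.kind != "tRNA":
        raise ValueError(f"{trna.id} is not a tRNA")
    seq = genome.feature_sequence(trna)
    if len(seq) < motif_length:
        raise ValueError(f"tRNA {trna.id} shorter than motif_length")
    return seq[-motif_length:]


def count_direct_repeats(
    genome: GenomeRecord,
    motif: str,
    search_interval: tuple[int, int],
    max_mismatches: int = 1,
    orientation: str = "+",
) -> list[int]:
    """Sorted start positions of motif occurrences (<= ``max_mismatches``
    substitutions) inside the interval, in the coding orientation of the
    source tRNA only."""
    if not motif:
        raise ValueError("empty motif")
    if orientation == "-":
        motif = reverse_complement(motif)
    s, e = max(0, search_interval[0]), min(len(genome), search_interval[1])
    region = genome.sequence[s:e]
    m = len(motif)
    out = []
    for i in range(len(region) - m + 1):
        mm = 0
        for a, b in zip(region[i : i + m], motif):
            if a != b:
                mm += 1
                if mm > max_mismatches:
                    break
        else:
            out.append(s + i)
    return out


def _recombinase_hits(
    cds_feats: list[GeneFeature],
    genome: GenomeRecord,
    config: SignatureConfig,
) -> list[RecombinaseHit]:
    aligner = default_aligner()
    refs = {
        label: ProteinRecord(f"ref|{label}", "ref", seq, label)
        for label, seq in config.recombinase_references.items()
    }
    hits = []
    for feat in cds_feats:
        try:
            prot = translate_cds(feat, genome)
        except (InternalStopError, ValueError):
            continue
        best = None
        for label, ref in refs.items():
            hit = align_protein_pair(prot, ref, aligner)
            if hit.identity < config.recombinase_min_identity:
                continue
            if shorter_coverage(hit, len(prot), len(ref)) < \
                    config.recombinase_min_coverage:
                continue
            if best is None or hit.score > best[0]:
                best = (hit.score, label, hit.identity)
        if best is not None:
            hits.append(RecombinaseHit(best[1], best[2], feat.id))
    return hits


# ---------------------------------------------------------------------------
# Span resolution
# ---------------------------------------------------------------------------

def tycheposon_span(
    genome: GenomeRecord,
    boundary_trna: GeneFeature,
    core_gene_ids: set[str],
    direction: int,
    max_scan: int = 200_000,
) -> tuple[int, int]:
    """Interval from the boundary tRNA through consecutive non-core genes,
    ending immediately before the first gene in a core cluster; ``direction``
    is +1 (scan downstream) or -1 (upstream), toward the candidate."""
    feats = genome.features
    try:
        i = next(idx for idx, f in enumerate(feats) if f.id == boundary_trna.id)
    except StopIteration:
        raise ValueError("boundary tRNA not on this genome")
    j = i + direction
    last = boundary_trna
    scanned = 0
    while 0 <= j < len(feats):
        f = feats[j]
        if f.kind == "CDS" and f.id in core_gene_ids:
            if direction > 0:
                return (boundary_trna.start, last.end)
            return (last.start, boundary_trna.end)
        scanned += f.end - f.start
        if scanned > max_scan:
            raise UnboundedSpanError(
                f"no core gene within {max_scan} bp of {boundary_trna.id}"
            )
        last = f
        j += direction
    raise UnboundedSpanError("ran off the annotation without a core gene")


def _find_boundary_trna(
    genome: GenomeRecord,
    candidate: IslandCandidate,
    anticodon: str,
    core_gene_ids: set[str],
) -> tuple[GeneFeature, int] | None:
    """Scan outward from each candidate boundary through non-core genes for
    a tRNA with the given anticodon; returns (tRNA, direction toward the
    candidate)."""
    feats = genome.features
    starts = [f.start for f in feats]
    import bisect

    # upstream of candidate start
    i = bisect.bisect_left(starts, candidate.start) - 1
    while i >= 0:
        f = feats[i]
        if f.kind == "tRNA" and f.anticodon == anticodon:
            return f, +1
        if f.kind == "CDS" and f.id in core_gene_ids:
            break
        i -= 1
    # downstream of candidate end
    i = bisect.bisect_left(starts, candidate.end)
    while i < len(feats):
        f = feats[i]
        if f.kind == "tRNA" and f.anticodon == anticodon:
            return f, -1
        if f.kind == "CDS" and f.id in core_gene_ids:
            break
        i += 1
    # also allow the tRNA to sit just inside the candidate
    inside = [
        f for f in feats
        if f.kind == "tRNA" and f.anticodon == anticodon
        and candidate.start <= f.start < candidate.end
    ]
    if inside:
        mid = (candidate.start + candidate.end) / 2
        f = min(inside, key=lambda t: min(t.start - candidate.start,
                                          candidate.end - t.end))
        return f, (+1 if f.start - candidate.start < candidate.end - f.end
                   else -1)
    return None


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _features_near_boundary(
    genome: GenomeRecord, pos: int, window_genes: int
) -> list[GeneFeature]:
    """Features within ``window_genes`` gene-sized steps of a position, on
    both sides."""
    feats = genome.features
    idx = [i for i, f in enumerate(feats) if f.end > pos][:1]
    if not idx:
        idx = [len(feats) - 1]
    i = idx[0]
    lo = max(0, i - window_genes)
    hi = min(len(feats), i + window_genes + 1)
    return feats[lo:hi]


def classify_island(
    candidate: IslandCandidate,
    genome: GenomeRecord,
    core_gene_ids: set[str],
    config: SignatureConfig | None = None,
) -> IslandCall:
    """Type one candidate by its structural signatures; first matching rule
    wins, all evidence is recorded regardless."""
    config = config or SignatureConfig()
    if not any(f.kind == "tRNA" for f in genome.features):
        raise UnannotatedGenomeError(
            f"genome {genome.id} carries no tRNA annotations"
        )
    ev = IslandEvidence()

    # --- flanking tRNAs + internal tmRNA (replacement signature)
    left = _features_near_boundary(genome, candidate.start,
                                   config.flank_gene_window)
    right = _features_near_boundary(genome, candidate.end,
                                    config.flank_gene_window)
    want = set(config.replacement_flanks)
    left_ac = {f.anticodon for f in left if f.kind == "tRNA"} & want
    right_ac = {f.anticodon for f in right if f.kind == "tRNA"} & want
    flank_pair: tuple[str | None, str | None] = (None, None)
    for a in sorted(left_ac):
        for b in sorted(right_ac):
            if a != b:
                flank_pair = (a, b)
    ev.flank_trnas = flank_pair
    ev.tmrna_present = any(
        f.kind == "tmRNA" and candidate.start <= f.start < candidate.end
        for f in genome.features
    )

    # --- direct repeats of the additive tRNA terminal motif
    lys = [f for f in genome.features
           if f.kind == "tRNA" and f.anticodon == config.additive_trna]
    repeat_positions: list[int] = []
    if lys:
        near = min(lys, key=lambda f: abs(f.start - candidate.start))
        motif = extract_trna_terminal_repeat(near, genome, config.motif_length)
        window = (candidate.start - config.additive_upstream, candidate.end)
        repeat_positions = [
            p for p in count_direct_repeats(
                genome, motif, window, orientation=near.strand
            )
            # the tRNA's own 3' end is not a repeat occurrence
            if not (near.start <= p < near.end)
        ]
    ev.repeat_positions = tuple(repeat_positions)

    # --- tycheposon span + recombinases
    tyche_span = None
    found = _find_boundary_trna(genome, candidate, config.tycheposon_trna,
                                core_gene_ids)
    if found is not None:
        trna, direction = found
        try:
            span = tycheposon_span(genome, trna, core_gene_ids, direction,
                                   config.max_span_scan)
            ev.boundary_trna_id = trna.id
            feats_after = [
                f for f in genome.features
                if f.kind == "CDS" and f.id in core_gene_ids
                and (f.start >= span[1] if direction > 0 else f.end <= span[0])
            ]
            if feats_after:
                ev.terminal_core_gene = (
                    min(feats_after, key=lambda f: f.start).id
                    if direction > 0
                    else max(feats_after, key=lambda f: f.start).id
                )
            tyche_span = span
        except UnboundedSpanError:
            tyche_span = None
    scan_lo = min(candidate.start, tyche_span[0]) if tyche_span else candidate.start
    scan_hi = max(candidate.end, tyche_span[1]) if tyche_span else candidate.end
    near_cds = [
        f for f in genome.features
        if f.kind == "CDS" and f.start < scan_hi and f.end > scan_lo
    ]
    boundary_cds = {
        f.id
        for pos in (candidate.start, candidate.end)
        for f in _features_near_boundary(genome, pos, config.flank_gene_window)
        if f.kind == "CDS"
    }
    extra_cds = [f for f in genome.features
                 if f.id in boundary_cds and f not in near_cds]
    ev.recombinases = tuple(
        _recombinase_hits(near_cds + extra_cds, genome, config)
    )

    # --- rules, most specific first
    island_type = "unclassified"
    start, end = candidate.start, candidate.end
    xerd = [r for r in ev.recombinases if r.label == "xerD"]
    xerc = [r for r in ev.recombinases if r.label == "xerC"]
    if ev.flank_trnas[0] is not None and ev.tmrna_present:
        island_type = "replacement"
    elif tyche_span is not None and xerd and ev.terminal_core_gene:
        in_span = [
            r for r in xerd
            if any(f.id == r.cds_id and f.start >= tyche_span[0]
                   and f.end <= tyche_span[1] for f in genome.features)
        ]
        if in_span:
            island_type = "tycheposon"
            start, end = tyche_span
    if island_type == "unclassified" and len(ev.repeat_positions) >= 2:
        island_type = "additive"
    if island_type == "unclassified" and xerc:
        in_window = [r for r in xerc if r.cds_id in boundary_cds]
        if in_window:
            island_type = "insertion"
    return IslandCall(candidate=candidate, island_type=island_type,
                      start=start, end=end, evidence=ev)


# ---------------------------------------------------------------------------
# Shared-protein Venn fractions per island
# ---------------------------------------------------------------------------

@dataclass
class VennFractions:
    shared_by_all: float
    partition: dict[frozenset[str], int]  # label subset -> cluster count
    n_clusters: int


def fgi_shared_fraction(
    island_gene_sets: dict[str, list[ProteinRecord]],
    min_identity: float = 50.0,
    min_coverage: float = 50.0,
) -> VennFractions:
    """Pool one island's proteins across species (or strains), cluster them
    with the pangenome ortholog definition and report the fraction of
    clusters represented in every set, plus the full Venn partition."""
    from .align_core import all_vs_all_protein
    from .pangenome import cluster_orthologs

    if len(island_gene_sets) < 2:
        raise ValueError("need island gene sets from at least two groups")
    for label, ps in island_gene_sets.items():
        if not ps:
            raise ValueError(f"empty protein set for {label!r}")
    label_of = {}
    groups = []
    for label, ps in sorted(island_gene_sets.items()):
        groups.append(ps)
        for p in ps:
            label_of[p.id] = label
    proteins = [p for g in groups for p in g]
    hits = all_vs_all_protein(groups, min_identity=min_identity,
                              min_coverage=min_coverage)
    clusters = cluster_orthologs(hits, proteins, min_identity=min_identity,
                                 min_coverage=min_coverage)
    partition: dict[frozenset[str], int] = {}
    all_labels = frozenset(island_gene_sets)
    shared = 0
    for c in clusters:
        labels = frozenset(label_of[pid] for _, pid in c.members)
        partition[labels] = partition.get(labels, 0) + 1
        if labels == all_labels:
            shared += 1
    return VennFractions(
        shared_by_all=shared / len(clusters),
        partition=partition,
        n_clusters=len(clusters),
    )
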