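"""Synthetic clades of streamlined bacterial genomes with planted islands.

The generator emulates the architecture of small (~1.3 Mbp, here scaled to
50–300 kbp) circular, low-GC genomes of closely related methylotroph
species: a syntenic core of protein-coding genes, a handful of RNA genes,
and flexible genomic islands (fGIs) planted at fixed loci with the
structural signatures used downstream for typing:

* replacement islands flanked by tRNA-Ser(gga) / tRNA-Arg(cct) with an
  internal tmRNA and wholesale-swapped cargo;
* additive islands as cassettes behind a tRNA-Lys(ctt), each cassette
  preceded by a direct repeat of the tRNA's 3'-terminal 20-mer;
* tycheposons opening with tRNA-Met(cat), carrying a xerD tyrosine
  recombinase, and ending at the first conserved core gene (a glmS
  analogue);
* small xerC-bordered insertions.

Evolution model: per-site uniform substitutions, codon-aware inside CDS
(start/stop codons protected, nonsense changes excluded, each event logged
as synonymous or nonsynonymous).  RNA genes, direct repeats and the
intergenic "stop shields" are immutable, so planted signatures survive
divergence.  No indels are introduced in conserved regions, which keeps
every pair of homologous elements gap-free and alignable by coordinate.

The per-branch substitution probability ``r`` is derived from the requested
*pairwise* divergence ``d`` by inverting ``P(differ) = 2r - (4/3) r^2``
(two independent branches, substitutions always change the base, 1/3 chance
of coinciding), so realized pairwise identity tracks ``100*(1-d)``.

All randomness flows from one seeded generator; sub-seeds are derived
deterministically, so identical config+seed reproduces byte-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Seq import Seq

from .references import RECOMBINASE_REFERENCES, TRNA_LYS_TERMINAL_20MER
from .seq_io import GeneFeature, GenomeRecord, Read, reverse_complement

# stops in all three frames on both strands; palindromic under revcomp
STOP_SHIELD = "TTAATTAATTAA"

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}

_CODON_AA: dict[str, str] = {}
for _b1 in _BASES:
    for _b2 in _BASES:
        for _b3 in _BASES:
            _c = _b1 + _b2 + _b3
            _CODON_AA[_c] = str(Seq(_c).translate(table=11))


class PlacementError(ValueError):
    """Planted islands overlap after placement."""


class ConfigError(ValueError):
    """A configuration invariant is violated."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ReadSimConfig:
    n_reads: int = 100_000
    read_length: int = 150
    error_rate: float = 0.005
    strain_weights: tuple[float, ...] | None = None  # None = uniform
    seed: int = 0

    def validate(self, n_genomes: int | None = None) -> None:
        if self.read_length < 50:
            raise ConfigError("read_length must be >= 50")
        if not 0 <= self.error_rate < 0.05:
            raise ConfigError("error_rate must be in [0, 0.05)")
        if self.strain_weights is not None:
            if n_genomes is not None and len(self.strain_weights) != n_genomes:
                raise ConfigError("strain_weights length != number of genomes")
            if any(w < 0 for w in self.strain_weights):
                raise ConfigError("negative strain weight")
            if sum(self.strain_weights) <= 0:
                raise ConfigError("zero total strain weight")


@dataclass
class IslandSpec:
    island_type: str  # replacement | additive | tycheposon | insertion
    anchor_fraction: float
    size_range: tuple[int, int]
    sharing_mode: str = "clade_conserved"  # strain_unique | subset | clade_conserved
    carrier_count: int | None = None  # subset mode: strains carrying the island
    n_cassettes: int = 3  # additive only
    variable_tail_bp: int = 0  # tycheposon: strain-unique tail inside the element
    border_syn_factor: float = 1.0  # synonymous-rate multiplier in flanking core genes
    reversed_orientation: bool = False  # tycheposon planted in reverse

    def validate(self, ancestor_length: int) -> None:
        if self.island_type not in {"replacement", "additive", "tycheposon", "insertion"}:
            raise ConfigError(f"unknown island_type {self.island_type!r}")
        if self.sharing_mode not in {"strain_unique", "subset", "clade_conserved"}:
            raise ConfigError(f"unknown sharing_mode {self.sharing_mode!r}")
        lo, hi = self.size_range
        floor = 330 if self.island_type == "additive" else 300
        if not (floor <= lo <= hi <= 0.2 * ancestor_length):
            raise ConfigError(
                f"{self.island_type} size_range {self.size_range} outside "
                f"({floor}, {0.2 * ancestor_length:.0f})"
            )
        if not 0 < self.anchor_fraction < 1:
            raise ConfigError("anchor_fraction must be in (0,1)")


@dataclass
class CladeConfig:
    seed: int = 42
    n_species: int = 1
    strains_per_species: int = 5
    ancestor_length: int = 300_000
    gc_target: float = 0.37
    mean_gene_length: int = 900
    mean_intergenic: int = 120
    within_species_divergence: float = 0.02
    between_species_divergence: float = 0.08
    island_specs: list[IslandSpec] = field(default_factory=list)
    inversion: tuple[float, float] | None = None  # (anchor_fraction, length_fraction)
    inversion_strain: int = -1  # index into the flattened strain list
    border_flank_genes: int = 5
    # fraction of fixed CDS substitutions redirected to synonymous sites;
    # 0.75 emulates within-species purifying selection (dN/dS << 1)
    cds_synonymous_fraction: float = 0.75
    read_sim: ReadSimConfig = field(default_factory=ReadSimConfig)

    def validate(self) -> None:
        if not (
            0
            < self.within_species_divergence
            < self.between_species_divergence
            < 0.3
        ):
            raise ConfigError(
                "need 0 < within_species_divergence < between_species_divergence < 0.3"
            )
        if self.ancestor_length < 50_000:
            raise ConfigError("ancestor_length must be >= 50000")
        if not 0.2 < self.gc_target < 0.8:
            raise ConfigError("gc_target must be in (0.2, 0.8)")
        if self.n_species < 1 or self.strains_per_species < 1:
            raise ConfigError("need at least one species and one strain")
        for spec in self.island_specs:
            spec.validate(self.ancestor_length)
        self.read_sim.validate()


def default_island_specs() -> list[IslandSpec]:
    """One island of each major type, mirroring the contrast between a
    strain-specific replacement island, a subset-shared additive island and
    a near-ubiquitous tycheposon with a small strain-variable tail (carried
    by all but one strain, so its body genes stay out of the strict core)."""
    return [
        IslandSpec("replacement", 0.25, (25_000, 35_000), "strain_unique",
                   border_syn_factor=3.0),
        IslandSpec("additive", 0.55, (6_000, 12_000), "subset",
                   carrier_count=2, n_cassettes=3),
        IslandSpec("tycheposon", 0.80, (18_000, 24_000), "subset",
                   carrier_count=4, variable_tail_bp=6_500,
                   border_syn_factor=3.0),
    ]


def default_clade_config(**overrides) -> CladeConfig:
    """The standard test clade: one species, five strains, 300-kb genomes,
    one replacement + one additive + one tycheposon island per genome."""
    cfg = CladeConfig(island_specs=default_island_specs())
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def three_species_config(seed: int = 42, **overrides) -> CladeConfig:
    """A small three-species clade straddling the 95% ANI species border
    (within d=0.02 -> ~98% ANI; between d=0.08 -> ~92% ANI)."""
    cfg = CladeConfig(
        seed=seed,
        n_species=3,
        strains_per_species=2,
        ancestor_length=100_000,
        island_specs=[
            IslandSpec("replacement", 0.3, (8_000, 12_000), "strain_unique"),
            IslandSpec("tycheposon", 0.7, (5_000, 8_000), "clade_conserved"),
        ],
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Substitution:
    pos: int  # genome coordinate, 0-based
    ref: str
    alt: str
    synonymous: bool | None  # None for non-coding positions
    element_id: str


@dataclass(frozen=True)
class IslandTruth:
    genome_id: str
    island_id: str
    island_type: str
    start: int
    end: int
    sharing_group: str


@dataclass(frozen=True)
class ElementTruth:
    element_id: str
    kind: str
    start: int
    end: int
    strand: str
    family: str | None
    island: str | None
    tag: str


@dataclass
class PlantedTruth:
    """Machine-readable record of everything the generator planted."""

    islands: dict[str, list[IslandTruth]] = field(default_factory=dict)
    gene_families: dict[str, dict[str, str]] = field(default_factory=dict)
    substitutions: dict[str, list[Substitution]] = field(default_factory=dict)
    elements: dict[str, list[ElementTruth]] = field(default_factory=dict)
    inversions: dict[str, tuple[int, int]] = field(default_factory=dict)
    species: dict[str, str] = field(default_factory=dict)

    def islands_for(self, genome_id: str) -> list[IslandTruth]:
        return self.islands.get(genome_id, [])

    def core_identity(self, rec_a: GenomeRecord, rec_b: GenomeRecord) -> float:
        """Percent identity over shared mutable core CDS elements, computed
        directly from planted element coordinates (independent of any
        aligner)."""
        els_a = {e.element_id: e for e in self.elements[rec_a.id]}
        els_b = {e.element_id: e for e in self.elements[rec_b.id]}
        match = total = 0
        for eid, ea in els_a.items():
            eb = els_b.get(eid)
            if eb is None or ea.kind != "cds" or ea.tag != "core":
                continue
            sa = rec_a.sequence[ea.start : ea.end]
            sb = rec_b.sequence[eb.start : eb.end]
            if ea.strand != eb.strand:
                sb = reverse_complement(sb)
            if len(sa) != len(sb):
                continue
            total += len(sa)
            match += sum(x == y for x, y in zip(sa, sb))
        if total == 0:
            raise ValueError("no shared core elements")
        return 100.0 * match / total

    def substitution_summary(self, genome_id: str):
        """(synonymous, nonsynonymous, noncoding) counts per element."""
        out: dict[str, list[int]] = {}
        for s in self.substitutions[genome_id]:
            row = out.setdefault(s.element_id, [0, 0, 0])
            if s.synonymous is True:
                row[0] += 1
            elif s.synonymous is False:
                row[1] += 1
            else:
                row[2] += 1
        return out


@dataclass(frozen=True)
class ReadOrigin:
    read_id: str
    genome_id: str
    start: int  # 0-based on source genome, may wrap
    end: int
    strand: str


# ---------------------------------------------------------------------------
# Mutation kernels
# ---------------------------------------------------------------------------

def branch_rate(pairwise_divergence: float) -> float:
    """Per-branch substitution probability giving the requested expected
    pairwise difference rate under uniform site choice (inverts
    P = 2r - (4/3) r^2: two branches, substitutions always change the base,
    1/3 chance of coinciding on the same final base)."""
    return 0.75 * (1.0 - math.sqrt(1.0 - (4.0 / 3.0) * pairwise_divergence))


_SYN_STATS_CACHE: dict[float, tuple[float, float]] = {}


def _syn_site_constants(gc: float) -> tuple[float, float]:
    """(c, beta_s) for the generator's codon distribution at this GC:
    ``c`` is the fraction of CDS sites carrying at least one synonymous
    alternative, ``beta_s`` the probability that two independent synonymous
    changes at such a site land on different bases (1 - E[1/k])."""
    if gc not in _SYN_STATS_CACHE:
        p = _codon_gc_param(gc)
        base_p = {"A": (1 - p) / 2, "T": (1 - p) / 2,
                  "G": p / 2, "C": p / 2}
        total_w = capable_w = inv_k_w = 0.0
        for codon, aa in _CODON_AA.items():
            if codon in _STOPS:
                continue
            w = base_p[codon[0]] * base_p[codon[1]] * base_p[codon[2]]
            for pos in range(3):
                k = 0
                for b in _BASES:
                    if b == codon[pos]:
                        continue
                    new = codon[:pos] + b + codon[pos + 1 :]
                    if new not in _STOPS and _CODON_AA[new] == aa:
                        k += 1
                total_w += w
                if k:
                    capable_w += w
                    inv_k_w += w / k
        c = capable_w / total_w
        beta_s = 1.0 - inv_k_w / capable_w
        _SYN_STATS_CACHE[gc] = (c, beta_s)
    return _SYN_STATS_CACHE[gc]


def cds_branch_rate(pairwise_divergence: float, syn_fraction: float,
                    gc: float) -> float:
    """Per-branch event rate for CDS under synonymous redirection.

    Redirected events concentrate on the synonymous-capable fraction ``c``
    of sites, raising the odds that both branches hit the same site and
    (at two-fold degenerate sites) arrive at the same base.  The expected
    pairwise difference is therefore solved numerically from a two-class
    site model rather than the uniform closed form."""
    if syn_fraction <= 0:
        return branch_rate(pairwise_divergence)
    c, beta_s = _syn_site_constants(gc)
    f = syn_fraction

    def p_diff(r: float) -> float:
        p_s = r * ((1 - f) + f / c)  # per-branch change prob, syn-capable site
        p_o = r * (1 - f)  # other sites
        diff_s = 2 * p_s * (1 - p_s) + p_s * p_s * beta_s
        diff_o = 2 * p_o * (1 - p_o) + p_o * p_o * (2.0 / 3.0)
        return c * diff_s + (1 - c) * diff_o

    lo, hi = 0.0, 0.4
    for _ in range(80):
        mid = (lo + hi) / 2
        if p_diff(mid) < pairwise_divergence:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def codon_aware_mutate(
    coding: str,
    rng: np.random.Generator,
    rate: float,
    extra_syn_rate: float = 0.0,
    protect_ends: bool = True,
    syn_fraction: float = 0.0,
) -> tuple[str, list[tuple[int, str, str, bool]]]:
    """Mutate an in-frame CDS. Substitutions never create stop codons and
    never touch the start/stop codon; each event is logged as
    ``(offset, ref, alt, synonymous)``.

    ``syn_fraction`` redirects that fraction of events onto random
    synonymous sites (emulating purifying selection: the event count is
    preserved but changes concentrate where they leave the protein
    untouched).  ``extra_syn_rate`` adds a second, synonymous-only pass
    (used to elevate dS at island borders)."""
    seq = list(coding)
    n = len(seq)
    if n % 3:
        raise ValueError("CDS length not divisible by 3")
    lo, hi = (3, n - 3) if protect_ends else (0, n)
    log: list[tuple[int, str, str, bool]] = []

    def _alternatives(pos: int, syn_only: bool) -> list[str]:
        ci = pos // 3
        codon = "".join(seq[3 * ci : 3 * ci + 3])
        aa = _CODON_AA[codon]
        off = pos % 3
        alts = []
        for b in _BASES:
            if b == seq[pos]:
                continue
            new = codon[:off] + b + codon[off + 1 :]
            if new in _STOPS:
                continue
            if syn_only and _CODON_AA[new] != aa:
                continue
            alts.append(b)
        return alts

    used: set[int] = set()

    def _apply(pos: int, syn_only: bool) -> bool:
        if pos in used:
            return False
        alts = _alternatives(pos, syn_only)
        if not alts:
            return False
        used.add(pos)
        alt = alts[int(rng.integers(len(alts)))]
        ci = pos // 3
        old_codon = "".join(seq[3 * ci : 3 * ci + 3])
        ref = seq[pos]
        seq[pos] = alt
        new_codon = "".join(seq[3 * ci : 3 * ci + 3])
        log.append(
            (pos, ref, alt, _CODON_AA[old_codon] == _CODON_AA[new_codon])
        )
        return True

    def _apply_at_synonymous_site() -> None:
        # redirect onto a random synonymous site (rejection sampling), so
        # the per-site event rate is realized in full
        for _ in range(40):
            p2 = int(rng.integers(lo, hi))
            if _apply(p2, syn_only=True):
                return

    for syn_only, r in ((False, rate), (True, extra_syn_rate)):
        if r <= 0 or hi <= lo:
            continue
        hits = np.nonzero(rng.random(hi - lo) < r)[0] + lo
        for pos in hits:
            pos = int(pos)
            if syn_only:
                _apply_at_synonymous_site()
            elif syn_fraction > 0 and rng.random() < syn_fraction:
                _apply_at_synonymous_site()
            elif not _apply(pos, syn_only=False):
                # site already consumed by a redirected event: keep the
                # event count by re-sampling an unused site
                for _ in range(40):
                    p2 = int(rng.integers(lo, hi))
                    if _apply(p2, syn_only=False):
                        break
    return "".join(seq), log


def uniform_mutate(
    seq: str, rng: np.random.Generator, rate: float,
    protected_head: int = 0, protected_tail: int = 0
) -> tuple[str, list[tuple[int, str, str, None]]]:
    """Mutate non-coding sequence; ``protected_head``/``protected_tail``
    bases (the stop shields) are left intact."""
    s = list(seq)
    lo, hi = protected_head, len(s) - protected_tail
    log: list[tuple[int, str, str, None]] = []
    if rate <= 0 or hi <= lo:
        return seq, log
    hits = np.nonzero(rng.random(hi - lo) < rate)[0] + lo
    for pos in hits:
        pos = int(pos)
        ref = s[pos]
        choices = [b for b in _BASES if b != ref]
        alt = choices[int(rng.integers(3))]
        s[pos] = alt
        log.append((pos, ref, alt, None))
    return "".join(s), log


# ---------------------------------------------------------------------------
# Sequence building blocks
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(_BASES))[rng.choice(4, size=n, p=p)])


_GC_SOLVE_CACHE: dict[float, float] = {}


def _codon_gc_param(gc: float) -> float:
    """Pre-rejection GC parameter such that stop-codon rejection (which
    discards AT-rich codons) leaves the realized codon GC at ``gc``."""
    if gc not in _GC_SOLVE_CACHE:
        def realized(p: float) -> float:
            at = (1 - p) / 2
            p_taa = at**3
            p_tag_tga = 2 * at**2 * (p / 2)
            p_stop = p_taa + p_tag_tga
            return (3 * p - p_tag_tga) / (3 * (1 - p_stop))

        lo, hi = 0.05, 0.95
        for _ in range(60):
            mid = (lo + hi) / 2
            if realized(mid) < gc:
                lo = mid
            else:
                hi = mid
        _GC_SOLVE_CACHE[gc] = (lo + hi) / 2
    return _GC_SOLVE_CACHE[gc]


def _random_codons(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    p = _codon_gc_param(gc)
    out = []
    while len(out) < n_codons:
        c = _random_dna(rng, 3, p)
        if c not in _STOPS:
            out.append(c)
    return "".join(out)


_STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class _Element:
    eid: str
    kind: str  # cds | trna | tmrna | rrna | repeat | spacer
    seq: str  # coding-orientation sequence
    strand: str = "+"
    family: str | None = None
    product: str = ""
    anticodon: str | None = None
    mutable: bool = True
    island: str | None = None
    tag: str = ""  # core | cargo | variable | flank_trna | anchor_trna | xerD | xerC | glmS


class _Factory:
    """Builds elements with clade-wide shared reference sequences."""

    def __init__(self, cfg: CladeConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.gene_counter = 0
        self.trna_seqs: dict[str, str] = {}

    def trna(self, anticodon: str, amino_acid: str, tag: str,
             island: str | None = None) -> _Element:
        if anticodon not in self.trna_seqs:
            body = _random_dna(self.rng, 56, 0.55)
            if anticodon == "ctt":
                self.trna_seqs[anticodon] = body + TRNA_LYS_TERMINAL_20MER
            else:
                self.trna_seqs[anticodon] = body + _random_dna(self.rng, 20, 0.55)
        return _Element(
            eid=f"trna_{amino_acid}_{anticodon}",
            kind="trna",
            seq=self.trna_seqs[anticodon],
            product=f"tRNA-{amino_acid}({anticodon})",
            anticodon=anticodon,
            mutable=False,
            island=island,
            tag=tag,
        )

    def spacer(self, rng: np.random.Generator | None = None,
               length: int | None = None, island: str | None = None,
               tag: str = "") -> _Element:
        rng = rng if rng is not None else self.rng
        if length is None:
            length = max(
                20, int(rng.normal(self.cfg.mean_intergenic, self.cfg.mean_intergenic / 4))
            )
        # shields flank both sides so ORFs on either strand stop at the gene
        # border; the AT-only shields are offset by a GC-richer body
        body_len = max(0, length - 2 * len(STOP_SHIELD))
        body_gc = min(0.8, self.cfg.gc_target * length / body_len) if body_len else 0.5
        body = _random_dna(rng, body_len, body_gc)
        self.gene_counter += 1
        return _Element(
            eid=f"sp{self.gene_counter:05d}",
            kind="spacer",
            seq=STOP_SHIELD + body + STOP_SHIELD,
            island=island,
            tag=tag,
        )

    def gene(self, rng: np.random.Generator | None = None,
             n_codons: int | None = None, family: str | None = None,
             product: str = "hypothetical protein", tag: str = "core",
             island: str | None = None, strand: str | None = None,
             coding: str | None = None) -> _Element:
        rng = rng if rng is not None else self.rng
        if coding is None:
            if n_codons is None:
                mean = self.cfg.mean_gene_length / 3
                n_codons = max(60, int(rng.normal(mean, mean / 6)))
            body = _random_codons(rng, n_codons - 2, self.cfg.gc_target)
            stop = _STOP_CODONS[int(rng.integers(3))]
            coding = "ATG" + body + stop
        if strand is None:
            strand = "-" if rng.random() < 0.2 else "+"
        self.gene_counter += 1
        if family is None:
            family = f"fam{self.gene_counter:05d}"
        return _Element(
            eid=f"g{self.gene_counter:05d}",
            kind="cds",
            seq=coding,
            strand=strand,
            family=family,
            product=product,
            tag=tag,
            island=island,
        )

    def protein_gene(self, protein: str, family: str, product: str, tag: str,
                     island: str | None) -> _Element:
        """Reverse-translate a reference protein with GC-biased codon choice."""
        rng = self.rng
        codons = []
        aa_codons: dict[str, list[str]] = {}
        for c, a in _CODON_AA.items():
            if a != "*":
                aa_codons.setdefault(a, []).append(c)
        for aa in protein:
            opts = aa_codons[aa]
            codons.append(opts[int(rng.integers(len(opts)))])
        coding = "ATG" + "".join(codons[1:]) + _STOP_CODONS[int(rng.integers(3))]
        return self.gene(coding=coding, family=family, product=product,
                         tag=tag, island=island, strand="+")

    def tmrna(self, island: str | None) -> _Element:
        if not hasattr(self, "_tmrna_seq"):
            self._tmrna_seq = _random_dna(self.rng, 350, 0.45)
        return _Element(
            eid="tmrna_ssrA", kind="tmrna", seq=self._tmrna_seq,
            product="transfer-messenger RNA ssrA", mutable=False,
            island=island, tag="tmrna",
        )

    def rrna(self) -> _Element:
        if not hasattr(self, "_rrna_seq"):
            # operon scales with the (scaled-down) genome, ~1% of its length
            length = max(1000, self.cfg.ancestor_length // 100)
            self._rrna_seq = _random_dna(self.rng, length, 0.50)
        return _Element(
            eid="rrna_operon", kind="rrna", seq=self._rrna_seq,
            product="rRNA operon", mutable=False, tag="rrna",
        )

    def cargo_cluster(self, rng: np.random.Generator, total_bp: int,
                      fam_prefix: str, island: str, tag: str = "cargo"
                      ) -> list[_Element]:
        """Alternating genes and spacers totalling ~total_bp."""
        out: list[_Element] = []
        built = 0
        idx = 0
        while built < total_bp:
            remaining = total_bp - built
            mean = min(self.cfg.mean_gene_length, max(200, remaining - 150)) / 3
            n_codons = max(60, int(rng.normal(mean, mean / 6)))
            g = self.gene(rng=rng, n_codons=n_codons,
                          family=f"{fam_prefix}_c{idx:03d}", tag=tag,
                          island=island)
            sp = self.spacer(rng=rng, island=island, tag=tag)
            out.extend([g, sp])
            built += len(g.seq) + len(sp.seq)
            idx += 1
        return out


# ---------------------------------------------------------------------------
# Clade generation
# ---------------------------------------------------------------------------

def _plant_islands(cfg: CladeConfig, fac: _Factory, elements: list[_Element]
                   ) -> list[_Element]:
    """Insert island templates into the root element list at their anchor
    fractions.  Raises PlacementError if two islands collide."""
    rng = fac.rng
    lengths = np.array([len(e.seq) for e in elements])
    cum = np.concatenate([[0], np.cumsum(lengths)])
    total = cum[-1]
    specs = sorted(
        enumerate(cfg.island_specs), key=lambda kv: kv[1].anchor_fraction
    )
    inserts: list[tuple[int, list[_Element]]] = []
    for i, spec in specs:
        isl_id = f"isl{i + 1}_{spec.island_type}"
        target = spec.anchor_fraction * total
        idx = int(np.searchsorted(cum, target))
        # insert at a boundary just after a spacer so genes stay shielded
        while idx < len(elements) and elements[idx - 1].kind != "spacer":
            idx += 1
        size = int(rng.integers(spec.size_range[0], spec.size_range[1] + 1))
        tmpl: list[_Element] = []
        if spec.island_type == "replacement":
            tmpl.append(fac.trna("gga", "Ser", "flank_trna", isl_id))
            tmpl.append(fac.spacer(island=isl_id))
            cargo = fac.cargo_cluster(rng, size // 2, f"{isl_id}_a", isl_id)
            tmpl.extend(cargo)
            tmpl.append(fac.tmrna(isl_id))
            tmpl.append(fac.spacer(island=isl_id))
            tmpl.extend(fac.cargo_cluster(rng, size // 2, f"{isl_id}_b", isl_id))
            tmpl.append(fac.trna("cct", "Arg", "flank_trna", isl_id))
            tmpl.append(fac.spacer())
        elif spec.island_type == "additive":
            tmpl.append(fac.trna("ctt", "Lys", "anchor_trna", isl_id))
            per = max(400, size // spec.n_cassettes)
            for c in range(spec.n_cassettes):
                fac.gene_counter += 1
                tmpl.append(_Element(
                    eid=f"rep{fac.gene_counter:05d}", kind="repeat",
                    seq=TRNA_LYS_TERMINAL_20MER, mutable=False,
                    island=isl_id, tag=f"cassette{c}",
                    product="tRNA-Lys 3' direct repeat",
                ))
                tmpl.append(fac.spacer(island=isl_id))
                tmpl.extend(fac.cargo_cluster(
                    rng, per - 150, f"{isl_id}_k{c}", isl_id, tag=f"cassette{c}"
                ))
            tmpl.append(fac.spacer())
        elif spec.island_type == "tycheposon":
            body: list[_Element] = []
            body.append(fac.trna("cat", "Met", "anchor_trna", isl_id))
            body.append(fac.spacer(island=isl_id))
            body.append(fac.protein_gene(
                RECOMBINASE_REFERENCES["xerD"], "fam_xerD",
                "tyrosine recombinase XerD", "xerD", isl_id,
            ))
            body.append(fac.spacer(island=isl_id))
            conserved = max(1000, size - spec.variable_tail_bp - 1500)
            body.extend(fac.cargo_cluster(rng, conserved, f"{isl_id}_c", isl_id))
            if spec.variable_tail_bp:
                body.extend(fac.cargo_cluster(
                    rng, spec.variable_tail_bp, f"{isl_id}_v", isl_id,
                    tag="variable",
                ))
            if spec.reversed_orientation:
                body = [replace(e, strand=("-" if e.strand == "+" else "+"))
                        for e in reversed(body)]
            tmpl.extend(body)
            tmpl.append(fac.spacer())
            # the element terminates at the nearest conserved core gene,
            # which becomes the glmS analogue
            j, step = (idx - 1, -1) if spec.reversed_orientation else (idx, 1)
            while 0 <= j < len(elements) and not (
                elements[j].kind == "cds" and elements[j].tag == "core"
            ):
                j += step
            if 0 <= j < len(elements):
                elements[j] = replace(
                    elements[j],
                    product="glucosamine-6-phosphate synthetase GlmS",
                    tag="glmS",
                )
        elif spec.island_type == "insertion":
            tmpl.append(fac.protein_gene(
                RECOMBINASE_REFERENCES["xerC"], "fam_xerC",
                "tyrosine recombinase XerC", "xerC", isl_id,
            ))
            tmpl.append(fac.spacer(island=isl_id))
            tmpl.extend(fac.cargo_cluster(rng, size, f"{isl_id}_c", isl_id))
            tmpl.append(fac.spacer())
        inserts.append((idx, tmpl))

    for a in range(1, len(inserts)):
        if inserts[a][0] == inserts[a - 1][0]:
            raise PlacementError("island anchors collide at the same locus")

    out: list[_Element] = []
    prev = 0
    for idx, tmpl in inserts:
        out.extend(elements[prev:idx])
        out.extend(tmpl)
        prev = idx
    out.extend(elements[prev:])
    return out


def _build_root(cfg: CladeConfig, fac: _Factory) -> list[_Element]:
    elements: list[_Element] = []
    elements.append(fac.gene(
        n_codons=max(60, 450 // 3), family="fam_dnaA",
        product="chromosomal replication initiator DnaA", strand="+",
    ))
    elements.append(fac.spacer())
    core_trnas = [("gcc", "Gly"), ("tgg", "Pro"), ("gtc", "Asp"), ("ttc", "Glu")]
    length = sum(len(e.seq) for e in elements)
    gene_i = 0
    rrna_placed = False
    while length < cfg.ancestor_length:
        frac = length / cfg.ancestor_length
        if not rrna_placed and frac >= 0.65:
            elements.append(fac.rrna())
            elements.append(fac.spacer())
            rrna_placed = True
        elif gene_i % 60 == 30 and core_trnas:
            elements.append(fac.trna(*core_trnas.pop(0), "core_trna"))
            elements.append(fac.spacer())
        else:
            elements.append(fac.gene())
            elements.append(fac.spacer())
        length = sum(len(e.seq) for e in elements)
        gene_i += 1
    return _plant_islands(cfg, fac, elements)


def _mutate_elements(
    elements: list[_Element],
    rng: np.random.Generator,
    rate_cds: float,
    rate_plain: float,
    extra_syn: dict[str, float] | None = None,
    syn_fraction: float = 0.0,
) -> tuple[list[_Element], dict[str, list[tuple[int, str, str, bool | None]]]]:
    """Apply one branch of divergence; returns new elements plus per-element
    substitution logs (offsets in coding orientation).  CDS and intergenic
    sequence carry separately calibrated rates (synonymous redirection needs
    a coincidence-corrected CDS rate)."""
    extra_syn = extra_syn or {}
    out = []
    logs: dict[str, list] = {}
    for el in elements:
        if not el.mutable:
            out.append(el)
            continue
        if el.kind == "cds":
            new, log = codon_aware_mutate(
                el.seq, rng, rate_cds,
                extra_syn_rate=extra_syn.get(el.eid, 0.0),
                syn_fraction=syn_fraction,
            )
        elif el.kind == "spacer":
            # shields evolve like the rest of the spacer: a damaged stop
            # rarely matters (three reading frames are shielded) and keeping
            # them frozen would bias whole-genome identity upward
            new, log = uniform_mutate(el.seq, rng, rate_plain)
        else:
            out.append(el)
            continue
        if log:
            logs[el.eid] = log
        out.append(replace(el, seq=new))
    return out, logs


def _carriers(spec: IslandSpec, k: int) -> set[int]:
    if spec.sharing_mode == "subset":
        n = spec.carrier_count if spec.carrier_count is not None else math.ceil(k / 2)
        return set(range(min(n, k)))
    return set(range(k))


def _flip(elements: list[_Element]) -> list[_Element]:
    return [replace(e, strand=("-" if e.strand == "+" else "+"))
            for e in reversed(elements)]


def _strain_elements(
    cfg: CladeConfig,
    fac: _Factory,
    species_elements: list[_Element],
    strain_idx: int,
    strain_rng: np.random.Generator,
    genome_id: str,
) -> list[_Element]:
    """Resolve island sharing for one strain: drop islands the strain does
    not carry (keeping anchor tRNAs, which are ordinary core genes) and
    regenerate strain-unique cargo from fresh random sequence."""
    spec_by_id = {
        f"isl{i + 1}_{s.island_type}": s for i, s in enumerate(cfg.island_specs)
    }
    k = cfg.strains_per_species
    out: list[_Element] = []
    i = 0
    n = len(species_elements)
    while i < n:
        el = species_elements[i]
        if el.island is None:
            out.append(el)
            i += 1
            continue
        isl_id = el.island
        spec = spec_by_id[isl_id]
        j = i
        while j < n and species_elements[j].island == isl_id:
            j += 1
        block = species_elements[i:j]
        i = j
        carried = strain_idx in _carriers(spec, k)

        if spec.island_type == "replacement":
            # locus present in every strain; cargo swapped wholesale
            if spec.sharing_mode == "strain_unique":
                size = int(strain_rng.integers(
                    spec.size_range[0], spec.size_range[1] + 1
                ))
                out.append(block[0])  # tRNA-Ser flank
                out.append(fac.spacer(rng=strain_rng, island=isl_id))
                out.extend(fac.cargo_cluster(
                    strain_rng, size // 2, f"{isl_id}_{genome_id}_a", isl_id
                ))
                out.append(fac.tmrna(isl_id))
                out.append(fac.spacer(rng=strain_rng, island=isl_id))
                out.extend(fac.cargo_cluster(
                    strain_rng, size // 2, f"{isl_id}_{genome_id}_b", isl_id
                ))
                out.append(block[-1])  # tRNA-Arg flank
            else:
                out.extend(block)
        elif spec.island_type == "additive":
            if carried:
                out.extend(block)
            else:
                # anchor tRNA-Lys stays as an ordinary core gene
                out.append(replace(block[0], island=None, tag="core_trna"))
        elif spec.island_type == "tycheposon":
            anchor_pos = 0 if not spec.reversed_orientation else len(block) - 1
            if not carried:
                out.append(replace(block[anchor_pos], island=None,
                                   tag="core_trna"))
            elif spec.variable_tail_bp:
                regen = fac.cargo_cluster(
                    strain_rng, spec.variable_tail_bp,
                    f"{isl_id}_v_{genome_id}", isl_id, tag="variable",
                )
                if spec.reversed_orientation:
                    regen = _flip(regen)
                new_block: list[_Element] = []
                emitted = False
                for e in block:
                    if e.tag == "variable":
                        if not emitted:
                            new_block.extend(regen)
                            emitted = True
                    else:
                        new_block.append(e)
                out.extend(new_block)
            else:
                out.extend(block)
        elif spec.island_type == "insertion":
            if carried:
                out.extend(block)
        else:  # pragma: no cover
            out.extend(block)
    return out


def _apply_inversion(elements: list[_Element], cfg: CladeConfig
                     ) -> tuple[list[_Element], tuple[int, int]]:
    anchor_frac, len_frac = cfg.inversion
    lengths = [len(e.seq) for e in elements]
    total = sum(lengths)
    cum = np.concatenate([[0], np.cumsum(lengths)])
    i0 = int(np.searchsorted(cum, anchor_frac * total))
    i1 = int(np.searchsorted(cum, (anchor_frac + len_frac) * total))
    i1 = max(i1, i0 + 1)
    seg = [
        replace(e, strand=("-" if e.strand == "+" else "+"))
        for e in reversed(elements[i0:i1])
    ]
    new = elements[:i0] + seg + elements[i1:]
    start = int(cum[i0])
    end = int(cum[i1])
    return new, (start, end)


def _assemble(
    genome_id: str,
    elements: list[_Element],
    logs: dict[str, list],
    truth: PlantedTruth,
) -> tuple[GenomeRecord, dict[str, list[int]]]:
    parts: list[str] = []
    feats: list[GeneFeature] = []
    el_truth: list[ElementTruth] = []
    fams: dict[str, str] = {}
    subs: list[Substitution] = []
    isl_bounds: dict[str, list[int]] = {}
    isl_types: dict[str, str] = {}
    pos = 0
    fcount = 0
    for el in elements:
        s = el.seq if el.strand == "+" else reverse_complement(el.seq)
        start, end = pos, pos + len(s)
        kind_map = {"cds": "CDS", "trna": "tRNA", "tmrna": "tmRNA",
                    "rrna": "rRNA", "repeat": "repeat_region"}
        if el.kind in kind_map:
            fid = f"{genome_id}_f{fcount:05d}"
            fcount += 1
            feats.append(GeneFeature(
                id=fid, start=start, end=end, strand=el.strand,
                kind=kind_map[el.kind], product=el.product,
                anticodon=el.anticodon,
            ))
            if el.kind == "cds":
                fams[fid] = el.family
        el_truth.append(ElementTruth(
            element_id=el.eid, kind=el.kind, start=start, end=end,
            strand=el.strand, family=el.family, island=el.island, tag=el.tag,
        ))
        if el.island:
            isl_bounds.setdefault(el.island, [start, end])
            isl_bounds[el.island][1] = end
        for off, ref, alt, syn in logs.get(el.eid, []):
            if el.strand == "+":
                p = start + off
                r, a = ref, alt
            else:
                p = end - 1 - off
                r, a = reverse_complement(ref), reverse_complement(alt)
            subs.append(Substitution(p, r, a, syn, el.eid))
        parts.append(s)
        pos = end
    truth.gene_families[genome_id] = fams
    truth.elements[genome_id] = el_truth
    truth.substitutions[genome_id] = sorted(subs, key=lambda s: s.pos)
    return GenomeRecord(genome_id, "".join(parts), circular=True,
                        features=feats), isl_bounds


def generate_clade(cfg: CladeConfig) -> tuple[list[GenomeRecord], PlantedTruth]:
    """Generate ``n_species x strains_per_species`` annotated circular
    genomes with planted islands and full ground truth."""
    cfg.validate()
    master = np.random.default_rng(cfg.seed)
    sub = lambda: int(master.integers(2**31))  # noqa: E731
    fac = _Factory(cfg, np.random.default_rng(sub()))
    root = _build_root(cfg, fac)
    f_syn = cfg.cds_synonymous_fraction
    r_within = branch_rate(cfg.within_species_divergence)
    r_between = branch_rate(cfg.between_species_divergence)
    r_within_cds = cds_branch_rate(cfg.within_species_divergence, f_syn,
                                   cfg.gc_target)
    r_between_cds = cds_branch_rate(cfg.between_species_divergence, f_syn,
                                    cfg.gc_target)

    spec_by_id = {
        f"isl{i + 1}_{s.island_type}": s for i, s in enumerate(cfg.island_specs)
    }
    truth = PlantedTruth()
    genomes: list[GenomeRecord] = []
    flat_idx = 0
    n_total = cfg.n_species * cfg.strains_per_species
    inv_strain = (cfg.inversion_strain % n_total) if cfg.inversion else None

    for si in range(cfg.n_species):
        species = f"sp{si + 1}"
        sp_rng = np.random.default_rng(sub())
        if cfg.n_species > 1:
            sp_elements, _ = _mutate_elements(
                root, sp_rng, r_between_cds, r_between,
                syn_fraction=f_syn,
            )
        else:
            sp_elements = root
        for ki in range(cfg.strains_per_species):
            genome_id = f"{species}_s{ki + 1}"
            strain_rng = np.random.default_rng(sub())
            els = _strain_elements(cfg, fac, sp_elements, ki, strain_rng,
                                   genome_id)
            extra_syn = _border_elevation(cfg, els, r_within_cds, spec_by_id)
            els, logs = _mutate_elements(
                els, strain_rng, r_within_cds, r_within,
                extra_syn=extra_syn, syn_fraction=f_syn,
            )
            if inv_strain is not None and flat_idx == inv_strain:
                els, inv_interval = _apply_inversion(els, cfg)
                truth.inversions[genome_id] = inv_interval
            rec, isl_bounds = _assemble(genome_id, els, logs, truth)
            truth.species[genome_id] = species
            isl_list = []
            for isl_id, (s0, e0) in sorted(isl_bounds.items()):
                spec = spec_by_id[isl_id]
                if spec.sharing_mode == "strain_unique":
                    group = f"{isl_id}|{genome_id}"
                elif spec.sharing_mode == "subset":
                    group = f"{isl_id}|carriers"
                else:
                    group = isl_id
                isl_list.append(IslandTruth(
                    genome_id, isl_id, spec.island_type, s0, e0, group
                ))
            truth.islands[genome_id] = isl_list
            genomes.append(rec)
            flat_idx += 1
    return genomes, truth




def _border_elevation(cfg, elements, r_within, spec_by_id) -> dict[str, float]:
    """Extra synonymous-only per-site rate for core CDS flanking islands with
    border_syn_factor > 1: (factor-1) x the effective background synonymous
    rate (~23% of uniform CDS substitutions are synonymous; the redirected
    fraction is synonymous outright)."""
    f = cfg.cds_synonymous_fraction
    f_eff = f + (1.0 - f) * 0.23
    out: dict[str, float] = {}
    for i, el in enumerate(elements):
        if el.island is None:
            continue
        spec = spec_by_id.get(el.island)
        if spec is None or spec.border_syn_factor <= 1.0:
            continue
        extra = (spec.border_syn_factor - 1.0) * f_eff * r_within
        for direction in (-1, 1):
            count = 0
            j = i + direction
            while 0 <= j < len(elements) and count < cfg.border_flank_genes:
                e2 = elements[j]
                if e2.island is None and e2.kind == "cds":
                    out[e2.eid] = extra
                    count += 1
                elif e2.island is not None and e2.island != el.island:
                    break
                j += direction
    return out


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_reads(
    genomes: list[GenomeRecord], config: ReadSimConfig
) -> tuple[list[Read], list[ReadOrigin]]:
    """Draw reads from circular genomes (wrapping the origin) with uniform
    substitution errors; per-read origin truth is returned alongside."""
    config.validate(n_genomes=len(genomes))
    weights = config.strain_weights
    if weights is None:
        weights = tuple(1.0 for _ in genomes)
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ConfigError("zero total strain weight")
    w = w / w.sum()
    rng = np.random.default_rng(config.seed)
    counts = rng.multinomial(config.n_reads, w)
    reads: list[Read] = []
    origins: list[ReadOrigin] = []
    rid = 0
    L = config.read_length
    for g, cnt in zip(genomes, counts):
        if cnt == 0:
            continue
        n = len(g)
        if L > n:
            raise ConfigError(f"read_length > genome {g.id}")
        arr = np.frombuffer(
            (g.sequence + g.sequence[: L]).encode(), dtype=np.uint8
        )
        code = np.zeros(256, dtype=np.int8)
        for i, b in enumerate(_BASE_CODES):
            code[b] = i
        starts = rng.integers(0, n, size=cnt)
        idx = starts[:, None] + np.arange(L)[None, :]
        mat = code[arr[idx]]
        strands = rng.random(cnt) < 0.5
        # reverse complement selected rows
        mat[strands] = 3 - mat[strands][:, ::-1]
        if config.error_rate > 0:
            err = rng.random((cnt, L)) < config.error_rate
            shift = rng.integers(1, 4, size=int(err.sum()))
            flat = mat[err]
            mat[err] = (flat + shift) % 4
        seqs = _BASE_CODES[mat]
        for i in range(cnt):
            name = f"r{rid:07d}"
            reads.append(Read(name, seqs[i].tobytes().decode(), "I" * L))
            origins.append(ReadOrigin(
                name, g.id, int(starts[i]), int(starts[i]) + L,
                "-" if strands[i] else "+",
            ))
            rid += 1
    return reads, origins


# ---------------------------------------------------------------------------
# Truth serialization
# ---------------------------------------------------------------------------

def write_truth(truth: PlantedTruth, outdir) -> None:
    """Write island truth as BED (0-based half-open) and gene families as
    TSV; both round-trip losslessly through :func:`read_truth`."""
    import os

    os.makedirs(outdir, exist_ok=True)
    rows = []
    for gid in sorted(truth.islands):
        for isl in truth.islands[gid]:
            rows.append((
                gid, isl.start, isl.end,
                f"{isl.island_id}|{isl.island_type}|{isl.sharing_group}",
            ))
    from .seq_io import write_bed

    write_bed(rows, os.path.join(outdir, "islands.bed"))
    with open(os.path.join(outdir, "gene_families.tsv"), "w") as fh:
        fh.write("genome\tgene\tfamily\n")
        for gid in sorted(truth.gene_families):
            for gene, fam in sorted(truth.gene_families[gid].items()):
                fh.write(f"{gid}\t{gene}\t{fam}\n")


def read_truth(outdir) -> tuple[list[IslandTruth], dict[str, dict[str, str]]]:
    import os

    from .seq_io import read_bed

    islands = []
    for row in read_bed(os.path.join(outdir, "islands.bed")):
        gid, start, end, name = row[0], row[1], row[2], row[3]
        isl_id, isl_type, group = name.split("|", 2)
        islands.append(IslandTruth(gid, isl_id, isl_type, start, end, group))
    fams: dict[str, dict[str, str]] = {}
    with open(os.path.join(outdir, "gene_families.tsv")) as fh:
        next(fh)
        for line in fh:
            gid, gene, fam = line.rstrip("\n").split("\t")
            fams.setdefault(gid, {})[gene] = fam
    return islands, fams
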