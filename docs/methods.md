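# Methods

`fgikit` re-implements, as a tested pipeline, the comparative-genomics
workflow by which flexible genomic islands (fGIs) are identified, typed and
quantified in clades of closely related, streamlined bacterial genomes —
the situation typified by freshwater *Methylophilaceae* (~1.3 Mbp circular
chromosomes, ~37% GC, highly conserved synteny) — together with a
synthetic-clade generator that makes every stage testable against known
ground truth.  This note records the models, the defaults and why, the
numerical choices, and what the synthetic tests do and do not demonstrate.

## The synthetic clade generator

### Genome model

A root ancestor is laid out as alternating protein-coding genes (mean 900
bp, start codon ATG, stop-free bodies, ~20% on the minus strand) and
intergenic spacers (mean 120 bp), with a handful of tRNA genes, one rRNA
operon (~1% of genome length) and a dnaA-labelled replication-initiator
gene at the linearization origin.  Genomes are circular; all coordinates
are 0-based half-open with an explicit wrap flag for origin-spanning
features.  Test genomes are scaled to 50–300 kb: every per-site process is
length-independent, so the statistical behaviour of identity, detection
and recruitment carries over; absolute island counts and core-genome sizes
of course do not.

Each spacer is bracketed by a 12-bp "stop shield" (`TTAATTAATTAA`): stops
in all three frames, self-reverse-complementary, so open reading frames on
either strand always terminate at gene borders.  This makes naive ORF
calling exactly recover the planted gene coordinates, which in turn lets
annotation-free runs be tested against truth.  Shields are AT-only; spacer
bodies are drawn slightly GC-rich to compensate, and codon sampling solves
for the pre-rejection GC that leaves the post-stop-rejection codon GC on
target, so realized genomic G+C stays within ±0.5 points of `gc_target`
(default 0.37).

### Substitution model

Divergence is per-site uniform substitution, codon-aware inside CDS: start
and stop codons are protected, nonsense changes are excluded, and every
event is logged with position, alleles and synonymous/nonsynonymous
status.  A configurable fraction of CDS events
(`cds_synonymous_fraction`, default 0.75) is redirected onto randomly
chosen synonymous sites, emulating purifying selection (within-species
dN/dS ≪ 1); this is what makes amino-acid identity exceed nucleotide
identity for the same pair, as in real conspecific genomes.

The per-branch event probability is derived from the requested *pairwise*
divergence `d`.  Under uniform site choice the closed form inverts
`P(differ) = 2r − (4/3)r²`.  Synonymous redirection concentrates events on
the ~35% of sites with a synonymous alternative, which raises the chance
that both branches hit the same site and (at two-fold degenerate sites)
arrive at the same base; the CDS rate is therefore solved numerically from
a two-site-class coincidence model whose constants (capable-site fraction
and the expected 1/k over alternative counts) are computed from the
generator's own codon distribution.  Within a branch, each site is hit at
most once.  Realized calibration on simulated pairs: fragment-ANI within
±0.26 points of `100·(1−d)` over `d ∈ [0.01, 0.10]`; core-gene identity
within ±0.25.

RNA genes (tRNA, tmRNA, rRNA) and the direct-repeat copies are held
invariant — rRNA operons and tRNAs are the most conserved loci in real
genomes, and island signatures must survive divergence.  No indels are
introduced in conserved regions (a stated non-goal), which keeps
homologous elements alignable by coordinate and makes gapless comparison
exact.

### Planted islands

Anchored at fixed genome fractions, with the structural signatures used
downstream for typing:

* **replacement** (default 25–35 kb, strain-unique): tRNA-Ser(gga) …
  cargo + internal tmRNA … tRNA-Arg(cct); cargo is regenerated per strain
  from fresh random genes, so every within-species comparison breaks at
  this locus.  Flanking core genes carry a 3× synonymous-rate elevation
  (`border_syn_factor`), the footprint that homologous recombination
  leaves at replacement-island borders.
* **additive** (6–12 kb, carried by 2 of 5 strains): a tRNA-Lys(ctt)
  followed by cassettes, each preceded by a direct repeat of the tRNA's
  3′-terminal 20-mer (`ACCAGCTGAGCTAATCCCCC`); cassette content is shared
  by carriers.  Borders carry no synonymous elevation (additive islands
  grow by insertion, not recombination-replacement).
* **tycheposon** (18–24 kb, carried by 4 of 5 strains): tRNA-Met(cat),
  a xerD tyrosine-recombinase gene, conserved cargo, then a
  strain-variable tail (~6.5 kb), terminating at the first conserved core
  gene, relabelled as the glmS analogue.  Carrying the element in all but
  one strain keeps its body out of the strict core — necessary for the
  span rule below, and consistent with how a conserved-but-mobile element
  presents in a larger genome collection — while leaving it the most
  population-frequent island.  A `reversed_orientation` flag plants the
  element flipped, with the terminal core gene on the other side.
* **insertion**: a xerC-bordered cassette (not in the default clade;
  exercised in dedicated tests).

Sharing modes: `strain_unique` regenerates cargo per strain;
`subset` restricts carriage to the first `carrier_count` strains;
`clade_conserved` copies cargo everywhere and diverges it like core.
Ground truth (island intervals, gene families, per-event substitution
logs, element coordinate maps, species labels) is returned as a
machine-readable object and serialized as BED + TSV.

The xerD/xerC reference proteins in `fgikit.references` are **synthetic**
stand-ins: deterministic pseudo-random sequences with bacterial amino-acid
composition, used as homology anchors by both the generator and the
classifier.  For real genomes they should be replaced with curated
tyrosine-recombinase sequences; the classification rule (best-scoring
reference at ≥40% identity, ≥50% coverage) is unchanged.  The 40% floor
was chosen because optimal local alignments of unrelated ~300-aa proteins
sporadically reach ~30% identity at 50% coverage, while genuine family
members align far above it.

### Read simulation

Reads are drawn uniformly from circular genomes (wrapping the origin),
strain weights multinomial, substitution errors at `error_rate` (default
0.005/base, short-read scale), constant quality strings.  Per-read origin
truth is recorded.  No indel or quality-model realism — recruitment here
is substitution-identity-based, matching the mapper.

## Alignment and identity

Protein alignment is exact local Smith–Waterman (BLOSUM62, gap open 11,
extend 1, Biopython's C kernel); identity is counted over aligned columns
(internal gaps included; local alignments have no end gaps); coverage is
measured on the shorter sequence so the ortholog graph is undirected.  The
all-vs-all step prefilters candidate pairs by shared amino-acid 5-mers
(≥2 shared, skipping low-complexity words in buckets >64): pairs above the
50%-identity ortholog floor share several exact 5-mers with overwhelming
probability, and an exhaustive-alignment comparison on toy proteomes is
part of the test suite.  The practical discovery floor of the prefilter is
~40–50% identity; reciprocal-best-hit AAI is therefore reliable down to
about 50% AAI, which covers congeneric comparisons.

Nucleotide comparison is seed-and-extend: exact 15-mer matches grouped per
(strand, diagonal), merged into gapless runs (seed gaps ≤400 bp), scored
by Hamming identity.  This is exact for the generator's substitution-only
homology and appropriate for the ≥90%-identity regime island detection
operates in; it is not a general aligner for indel-rich comparisons.

ANI uses the classic fragment dialect: 1020-bp query windows, accepted
when the dominant seed diagonal spans ≥70% of the window, identity scored
after trimming the terminal seeds (whose bases are exact matches by
construction and would bias identity upward by ~0.2 points), averaged over
both directions.  Pairs sharing no 15-mers (below roughly 80–85% identity)
yield an explicitly *undefined* ANI, distinct from zero.  Species are the
connected components of the genome graph at ANI ≥95%, the operational
prokaryotic species border; the default three-species test clade plants
within-species divergence 0.02 and between-species 0.08 to straddle it
(~98% vs ~92% ANI) — the regime where a borderline genome at 93–95% ANI
sits just outside a species.

## Pangenome

Orthologs are single-linkage connected components of the thresholded hit
graph (≥50% identity, ≥50% shorter-sequence coverage) — the simplest
faithful reading of an identity/coverage ortholog definition, and directly
checkable against a transitive-closure brute force, which the acceptance
suite does.  Core = clusters present in every genome; accumulation curves
average 100 seeded permutations of genome addition order.  Species-unique
genes are the cross-species de-replication at ≥95% protein identity.
Single-linkage does not resolve paralogs; with the generator's
paralog-free genomes the recovered partition equals the planted families
exactly (adjusted Rand index 1.0).

## Island detection and typing

Two evidence lines per within-species genome pair, merged per focal
genome:

* **alignment gaps** — complement of ≥95%-identity alignment coverage,
  spans ≥`gap_min_span` (5 kb); covered islets shorter than 1 kb (a lone
  conserved tmRNA or tRNA inside an otherwise alien region) do not
  interrupt a gap;
* **low-score stretches** — runs of ≥3 consecutive genes whose best
  protein hit in a partner genome is <50% identity or absent.

Overlapping evidence is united; candidates recurring in <50% of partner
comparisons are dropped.  All thresholds live in `DetectParams`; the 95%
nucleotide identity figure is the only one inherited from the underlying
study design, the rest are this package's defaults, chosen to recover
multi-gene islands while suppressing single-gene noise.

Typing applies rules in order of signature specificity (replacement →
tycheposon → additive → insertion), recording all evidence regardless of
which rule fires, so a call is a pure function of its evidence and ablating
one signature demotes the call to `unclassified` rather than flipping it.
The tycheposon rule scans outward from a candidate boundary through
consecutive non-core genes for the boundary tRNA-Met, extends the span to
the first core-cluster gene (the glmS analogue) in the orientation of the
element, and requires a xerD hit inside the span — which is also how a
candidate that only covers the element's variable tail acquires its full
extent.  Per-island protein sharing across species pools the island's
proteins and reuses the ortholog clustering; the Venn fraction
"shared-by-all" reproduces the conserved-tycheposon > unique-replacement
ordering.

Inversions are maximal runs of inverted-orientation synteny blocks; blocks
chain collinear same-strand hits with bounded diagonal drift.

## SNPs, NG86 and dS profiles

SNPs are substitution columns inside aligned blocks, in reference
coordinates, inverted blocks compared after reverse complement; on
simulated pairs the calls equal the generator's substitution log restricted
to covered positions.

dN/dS uses Nei–Gojobori (1986) counting: per-codon synonymous-site
fractions (changes to stop codons count as nonsynonymous, so S+N = 3 ×
codons exactly), differences averaged with equal weight over minimal
substitution pathways (pathways through stops excluded unless all are),
Jukes–Cantor correction `d = −(3/4)·ln(1 − 4p/3)`, and an explicit
saturation signal (NaN) when `p ≥ 3/4` rather than extrapolation —
pairwise synonymous divergence beyond that point is not estimable by this
estimator, which is also why very high border dS values in real data
should be read qualitatively.  The implementation matches an independent
pathway-enumeration oracle to 1e-9 on 500 random codon pairs.  Against the
generator's logged events, JC-corrected dS agrees within ~2–6% for
dS ≲ 0.3; the agreement degrades toward ~10% by dS ≈ 0.4 because the
generator plants distinct events (no within-branch multiple hits) while
the correction assumes a Poisson process.

dS profiles order per-gene estimates along a reference, average across
queries, and smooth with a centred moving median (default 5 genes; robust
to isolated saturated genes).  The border peak statistic is the median dS
over 5 flank genes each side divided by the genome-wide median, flanks
resolved circularly.  With the default 3× planted elevation the measured
ratios are ~2.5–3.3 and the genome-wide median dS matches the planted
background within ~2%.

## Recruitment

Reads are placed by exact-seed voting (non-overlapping 15-mers, both
strands) plus gapless rescoring; best location only, ties to the lowest
coordinate then forward strand; accepted iff identity ≥0.95 over ≥90% of
the read and ≥50 bp — the standard recruitment regime.  At within-species
divergence 0.02 plus 0.5% sequencing error, reads from conspecific strains
pass this filter at ~97%, which is what makes population mixtures
recruit onto a single reference.  rRNA intervals are masked before
mapping: masked bases never match a seed, accrue no depth and are excluded
from means and island calls.

Coverage per Gb = mean per-base depth × 10⁹ / total bases in the read
sample — the reading that is comparable across samples and halves exactly
under two-fold subsampling; mean (not breadth-weighted) depth is used and
recorded here.  Coverage conservation (Σ depth = Σ accepted aligned bases
on unmasked positions) holds exactly and is asserted exactly.

Metagenomic islands are maximal intervals ≥5 kb where 5-kb-smoothed depth
falls below 0.2× the genome median.  Region-relative coverage divides
region mean depth by genome mean depth (both unmasked), matching how
island recruitment is conventionally reported relative to whole-genome
values.  On the default five-strain scenario this yields ~66% / ~46% /
~25% for tycheposon / additive / replacement — the qualitative ordering of
a near-ubiquitous element over a subset-shared one over a strain-private
one.  Mixture *linearity* (region recruitment ∝ carrier weight, ±0.05) is
asserted against the mean depth of the fully shared core instead: with
~20% of a 300-kb genome in variable islands the whole-genome mean is
itself depressed by ~13%, a normalization artifact rather than a linearity
failure; in real 1.3-Mb genomes with ~5% island content the two baselines
nearly coincide.

## Problem sizes and defaults

The standard scenarios are: the default clade (1 species × 5 strains,
300-kb ancestor, seed 42, one island of each major type), the
three-species clade (3 × 2 strains, 100 kb) for species delineation, an
ANI calibration grid of ten two-strain clades at 100 kb, and 200,000
150-bp reads (plus a 120,000-read focal-free mixture) for recruitment.
These sizes make every stage's statistics stable while a full test run and
the acceptance script each complete in a few minutes on one CPU.

## Known limitations

* No indel evolution in conserved regions, no GC skew, no replication
  origin or prophage sequence realism; the nucleotide kernels are
  substitution-oriented and not suited to indel-rich comparisons.
* Single-linkage orthology is paralog-blind; the generator plants no
  paralogs.
* The AAI prefilter loses sensitivity below ~50% amino-acid identity;
  inter-genus AAI values near the 40% range would need an exhaustive
  comparison.
* Tycheposon span resolution requires the element body to be absent from
  at least one genome of the set (otherwise its genes are core and the
  span collapses); a clade where every genome carries the element blends
  it into the core, as it would in any core/accessory analysis.
* Passing tests on synthetic clades demonstrate correctness of the
  algorithms under the generative model (substitutions only, intact
  signatures, uniform read sampling); they do not by themselves establish
  performance on real genomes with assembly artifacts, indels, paralogy or
  composition-driven false signals.
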