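"""Sequence containers, standard-format I/O and circular-coordinate utilities.

Internal coordinates are 0-based half-open throughout; GFF3 (1-based
inclusive) and BED (0-based half-open) dialects are converted at the
boundary.  Genomes are circular chromosomes linearized at a fixed origin;
features that span the origin carry an explicit ``wraps`` flag instead of
being split into two rows, so islands near the origin stay contiguous.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class GeneFeature:
    """A typed feature on a genome (CDS, tRNA, tmRNA, rRNA or repeat_region).

    ``start < end`` unless the feature wraps the linearization origin, in
    which case ``wraps`` is set and ``end`` is taken modulo genome length.
    """

    id: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "CDS"
    product: str = ""
    anticodon: str | None = None
    wraps: bool = False

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.wraps and self.start >= self.end:
            raise ValueError(f"feature {self.id}: start >= end without wrap flag")
        if self.anticodon is not None and self.kind != "tRNA":
            raise ValueError("anticodon only allowed on tRNA features")

    def length(self, genome_length: int | None = None) -> int:
        if not self.wraps:
            return self.end - self.start
        if genome_length is None:
            raise ValueError("wrapping feature needs genome length")
        return genome_length - self.start + self.end


@dataclass
class GenomeRecord:
    """A (possibly circular) chromosome with typed features."""

    id: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ParseError(f"genome {self.id}: illegal characters {sorted(bad)}")
        self.features.sort(key=lambda f: (f.start, f.end))
        for f in self.features:
            if f.start >= len(self.sequence) or f.end > len(self.sequence):
                raise ValueError(
                    f"feature {f.id} [{f.start},{f.end}) outside genome {self.id}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        """G+C fraction of the chromosome."""
        if not self.sequence:
            return 0.0
        gc = self.sequence.count("G") + self.sequence.count("C")
        return gc / len(self.sequence)

    def features_of_kind(self, kind: str) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == kind]

    def feature_sequence(self, feat: GeneFeature) -> str:
        """Feature sequence in coding orientation (minus strand is
        reverse-complemented)."""
        end = feat.end if not feat.wraps else len(self) + feat.end
        raw = circular_subsequence(self, feat.start, end)
        return reverse_complement(raw) if feat.strand == "-" else raw


@dataclass(frozen=True)
class ProteinRecord:
    """Translated CDS; no internal stop characters."""

    id: str
    genome_id: str
    sequence: str
    source_cds: str

    def __post_init__(self):
        if "*" in self.sequence:
            raise ValueError(f"protein {self.id} contains internal stop")

    def __len__(self) -> int:
        return len(self.sequence)


def circular_subsequence(genome: GenomeRecord, start: int, end: int) -> str:
    """Subsequence [start, end); ``end`` may exceed the genome length on a
    circular chromosome, in which case the slice wraps through the origin."""
    n = len(genome)
    if not 0 <= start < n:
        raise ValueError(f"start {start} outside [0,{n})")
    if end < start:
        raise ValueError("end < start")
    if end <= n:
        return genome.sequence[start:end]
    if not genome.circular:
        raise ValueError(f"wrap requested on non-circular genome {genome.id}")
    if end - start > n:
        raise ValueError("requested span longer than genome")
    return genome.sequence[start:] + genome.sequence[: end - n]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[GenomeRecord]:
    """Read genome FASTA (uppercased on read). Circularity is recorded in the
    description as ``circular=true|false`` and defaults to true."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        circular = "circular=false" not in rec.description.lower()
        records.append(GenomeRecord(rec.id, str(rec.seq), circular=circular))
    if not records:
        raise ParseError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[GenomeRecord], path, width: int = 70) -> None:
    seqs = [
        SeqRecord(
            Seq(g.sequence),
            id=g.id,
            description=f"circular={'true' if g.circular else 'false'}",
        )
        for g in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_KINDS = {"CDS", "tRNA", "tmRNA", "rRNA", "repeat_region"}


def write_gff3(genomes: list[GenomeRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genomes:
            fh.write(f"##sequence-region {g.id} 1 {len(g)}\n")
            for f in g.features:
                attrs = [f"ID={f.id}"]
                if f.product:
                    attrs.append(f"product={f.product}")
                if f.anticodon:
                    attrs.append(f"anticodon={f.anticodon}")
                if f.wraps:
                    attrs.append("wraps=true")
                end = f.end if not f.wraps else len(g) + f.end
                fh.write(
                    "\t".join(
                        [
                            g.id,
                            "fgikit",
                            f.kind,
                            str(f.start + 1),
                            str(end),
                            ".",
                            f.strand,
                            ".",
                            ";".join(attrs),
                        ]
                    )
                    + "\n"
                )


def read_gff3(path, genomes: list[GenomeRecord]) -> list[GenomeRecord]:
    """Attach GFF3 features to genomes (matched by seqid). Coordinates are
    converted from 1-based inclusive to internal 0-based half-open; wrapping
    features are written with end > genome length plus a ``wraps=true`` tag."""
    by_id = {g.id: g for g in genomes}
    feats: dict[str, list[GeneFeature]] = {g.id: [] for g in genomes}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns")
            seqid, _src, kind, start, end, _score, strand, _frame, attr = parts
            if seqid not in by_id:
                raise ParseError(f"{path}:{lineno}: unknown seqid {seqid!r}")
            if kind not in _GFF_KINDS:
                continue
            start_i, end_i = int(start) - 1, int(end)
            if end_i <= start_i:
                raise ParseError(f"{path}:{lineno}: end <= start")
            attrs = dict(
                kv.split("=", 1) for kv in attr.split(";") if "=" in kv
            )
            wraps = attrs.get("wraps", "").lower() == "true"
            n = len(by_id[seqid])
            if wraps:
                end_i -= n
            elif end_i > n:
                raise ParseError(f"{path}:{lineno}: feature beyond genome end")
            feats[seqid].append(
                GeneFeature(
                    id=attrs.get("ID", f"feat{lineno}"),
                    start=start_i,
                    end=end_i,
                    strand=strand,
                    kind=kind,
                    product=attrs.get("product", ""),
                    anticodon=attrs.get("anticodon"),
                    wraps=wraps,
                )
            )
    out = []
    for g in genomes:
        out.append(
            GenomeRecord(g.id, g.sequence, circular=g.circular, features=feats[g.id])
        )
    return out


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(intervals, path) -> None:
    """Write (chrom, start, end, name[, score]) tuples as BED (0-based
    half-open, deterministic order)."""
    rows = sorted(intervals, key=lambda r: (r[0], int(r[1]), int(r[2])))
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path) -> list[tuple]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            p = line.split("\t")
            out.append((p[0], int(p[1]), int(p[2]), *p[3:]))
    return out


# ---------------------------------------------------------------------------
# FASTQ (pass-through quality handling)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Read:
    id: str
    sequence: str
    quality: str = ""

    def __post_init__(self):
        if self.quality and len(self.quality) != len(self.sequence):
            raise ParseError(f"read {self.id}: quality length mismatch")


def read_fastq(path) -> list[Read]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        out.append(Read(rec.id, str(rec.seq).upper(), qual))
    return out


def write_fastq(reads: list[Read], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.quality or "I" * len(r.sequence)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Translation and naive ORF calling
# ---------------------------------------------------------------------------

class InternalStopError(ValueError):
    """CDS translates with an internal stop (pseudo-CDS); excluded from the
    proteome."""


def translate_cds(
    feature: GeneFeature, genome: GenomeRecord, table: int = 11
) -> ProteinRecord:
    """Translate a CDS feature with the bacterial code; trailing stop codon is
    trimmed; strand-aware; internal stops raise :class:`InternalStopError`."""
    if feature.kind != "CDS":
        raise ValueError(f"{feature.id} is not a CDS")
    nt = genome.feature_sequence(feature)
    if len(nt) % 3:
        raise InternalStopError(f"{feature.id}: length not divisible by 3")
    aa = str(Seq(nt).translate(table=table))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise InternalStopError(f"{feature.id}: internal stop codon")
    return ProteinRecord(
        id=f"{genome.id}|{feature.id}",
        genome_id=genome.id,
        sequence=aa,
        source_cds=feature.id,
    )


def proteome(genome: GenomeRecord, table: int = 11) -> list[ProteinRecord]:
    """All translatable CDS of a genome; pseudo-CDS (internal stops) are
    silently excluded."""
    out = []
    for f in genome.features_of_kind("CDS"):
        try:
            out.append(translate_cds(f, genome, table=table))
        except InternalStopError:
            continue
    return out


_STARTS = ("ATG", "GTG", "TTG")
_STOPS = ("TAA", "TAG", "TGA")


def _orfs_one_strand(seq: str, strand: str, n: int):
    """Candidate ORFs (longest per stop) on one strand of a linearized
    sequence; coordinates on the forward strand of the genome."""
    cands = []
    for frame in range(3):
        prev_stop = frame  # scan position after the previous in-frame stop
        pending_start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon in _STOPS:
                if pending_start is not None and i + 3 - pending_start >= 150:
                    cands.append((pending_start, i + 3))
                pending_start = None
                prev_stop = i + 3
            elif pending_start is None and codon in _STARTS:
                pending_start = i
    out = []
    for s, e in cands:
        if strand == "+":
            out.append((s, e, "+"))
        else:
            out.append((n - e, n - s, "-"))
    return out


def naive_orf_call(genome: GenomeRecord, min_length: int = 150) -> list[GeneFeature]:
    """Greedy ORF finder for genomes lacking annotations: ORFs >= min_length
    starting ATG/GTG/TTG on either strand, longest-first non-overlapping."""
    n = len(genome)
    fwd = genome.sequence
    cands = _orfs_one_strand(fwd, "+", n) + _orfs_one_strand(
        reverse_complement(fwd), "-", n
    )
    cands = [c for c in cands if c[1] - c[0] >= min_length]
    cands.sort(key=lambda c: (-(c[1] - c[0]), c[0], c[2]))
    chosen: list[tuple[int, int, str]] = []
    occupied: list[tuple[int, int]] = []
    for s, e, strand in cands:
        if any(s < oe and os_ < e for os_, oe in occupied):
            continue
        chosen.append((s, e, strand))
        occupied.append((s, e))
    chosen.sort()
    return [
        GeneFeature(
            id=f"orf{i:05d}", start=s, end=e, strand=strand, kind="CDS",
            product="predicted protein",
        )
        for i, (s, e, strand) in enumerate(chosen)
    ]
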