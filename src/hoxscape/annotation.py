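"""Gene models and region logic for the HOX clusters.

The 39 human HOX transcription-factor genes sit in four paralogous clusters
(HOXA-D) interleaved with embedded lncRNAs, several of which run antisense to
a coding neighbour.  This module parses gene annotation (GTF or BED12) into
:class:`GeneModel` objects, derives the analysis regions used throughout the
package (promoter = 1 kb upstream + 100 bp downstream of the TSS, exons and
introns numbered 5'->3' in transcript orientation, UTRs when CDS is
annotated), assigns CpG positions to regions, and detects natural-antisense
(NAT) lncRNA-gene pairs by strand-aware exonic overlap.

Coordinate conventions: all internal intervals are 0-based half-open; GTF is
read/written 1-based inclusive; BED is 0-based half-open; CpG positions (as
found in cytosine coverage files) are 1-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "RegionKey",
    "NATPair",
    "parse_annotation",
    "parse_gtf",
    "parse_bed12",
    "write_gtf",
    "write_bed12",
    "promoter_interval",
    "derive_regions",
    "RegionIndex",
    "assign_cpg",
    "find_nat_pairs",
    "regions_to_bed",
    "nat_pairs_to_tsv",
    "cluster_of_symbol",
]

PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 100

_CLUSTER_RE = re.compile(r"^HOX([ABCD])", re.IGNORECASE)


class AnnotationError(ValueError):
    """Malformed annotation input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos0: int) -> bool:
        """True if 0-based position falls inside the interval."""
        return self.start <= pos0 < self.end

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class RegionKey(NamedTuple):
    """Identifies one analysis region of one gene.

    ``ordinal`` is 1-based within region_type, numbered 5'->3' in transcript
    orientation; promoter and flank regions use ordinal 0.
    """

    gene_id: str
    region_type: str  # promoter | exon | intron | utr5 | utr3 | flank
    ordinal: int

    def __str__(self) -> str:  # e.g. HOXB9.intron1
        if self.ordinal:
            return f"{self.gene_id}.{self.region_type}{self.ordinal}"
        return f"{self.gene_id}.{self.region_type}"


@dataclass(frozen=True)
class NATPair:
    """A lncRNA running antisense to a coding gene with exonic overlap."""

    lncrna_id: str
    gene_id: str
    overlapped_exon_ordinals: tuple[int, ...]
    overlap_bp: int

    def __post_init__(self) -> None:
        if self.overlap_bp < 1:
            raise ValueError("NAT pair requires >= 1 bp exonic overlap")


def cluster_of_symbol(symbol: str) -> str:
    """Infer HOX cluster (A/B/C/D) from a gene symbol prefix; 'none' otherwise."""
    m = _CLUSTER_RE.match(symbol or "")
    return m.group(1).upper() if m else "none"


@dataclass(frozen=True)
class GeneModel:
    """One canonical gene model (single transcript per gene).

    ``exons`` are stored sorted by genomic coordinate and must not overlap.
    ``tss`` is the 1-based transcription start: leftmost exon start + 1 on the
    + strand, rightmost exon end on the - strand.  ``cds`` optionally holds
    CDS intervals (genomic order) when the annotation encodes them, enabling
    UTR derivation.
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    biotype: str = "coding"  # coding | lncRNA
    cds: tuple[GenomicInterval, ...] = ()
    cluster: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise AnnotationError(f"gene {self.gene_id}: strand required, got {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"gene {self.gene_id}: no exons")
        exs = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(exs, exs[1:]):
            if a.end > b.start:
                raise AnnotationError(f"gene {self.gene_id}: overlapping exons")
        object.__setattr__(self, "exons", tuple(exs))
        if not self.cluster:
            object.__setattr__(self, "cluster", cluster_of_symbol(self.symbol))

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def tss(self) -> int:
        """1-based transcription start position."""
        return self.start + 1 if self.strand == "+" else self.end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exons_transcript_order(self) -> tuple[GenomicInterval, ...]:
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    def introns_transcript_order(self) -> tuple[GenomicInterval, ...]:
        introns = [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        ]
        return tuple(introns) if self.strand == "+" else tuple(reversed(introns))


# ---------------------------------------------------------------------------
# parsing / writing
# ---------------------------------------------------------------------------

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def parse_gtf(path: str | Path) -> list[GeneModel]:
    """Parse exon (and optional CDS) features of a GTF file into gene models."""
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(f"{path}:{lineno}: expected 9 GTF fields, got {len(fields)}")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature not in {"exon", "CDS"}:
                continue
            try:
                s, e = int(start) - 1, int(end)
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: non-numeric coordinates") from exc
            if strand not in {"+", "-"}:
                raise AnnotationError(f"{path}:{lineno}: strandless record rejected")
            attrd = dict(_GTF_ATTR_RE.findall(attrs))
            gid = attrd.get("gene_id")
            if not gid:
                raise AnnotationError(f"{path}:{lineno}: missing gene_id attribute")
            iv = GenomicInterval(chrom, s, e, strand)
            (exons if feature == "exon" else cds).setdefault(gid, []).append(iv)
            info = meta.setdefault(gid, {})
            info["symbol"] = attrd.get("gene_name", gid)
            info["chrom"], info["strand"] = chrom, strand
            bt = attrd.get("gene_biotype", attrd.get("gene_type", ""))
            if bt:
                info["biotype"] = "lncRNA" if "lnc" in bt.lower() else "coding"
    genes = []
    for gid, exs in exons.items():
        info = meta[gid]
        genes.append(
            GeneModel(
                gene_id=gid,
                symbol=info["symbol"],
                chrom=info["chrom"],
                strand=info["strand"],
                exons=tuple(exs),
                cds=tuple(sorted(cds.get(gid, []), key=lambda c: c.start)),
                biotype=info.get("biotype", "coding"),
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def parse_bed12(path: str | Path) -> list[GeneModel]:
    """Parse a BED12 file (one transcript per line) into gene models.

    The name field is taken as gene_id/symbol; biotype is read from an
    optional 13th column, defaulting to coding.
    """
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise AnnotationError(f"{path}:{lineno}: expected >= 12 BED12 fields, got {len(f)}")
            try:
                chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
                thick_start, thick_end = int(f[6]), int(f[7])
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: malformed BED12 record") from exc
            if strand not in {"+", "-"}:
                raise AnnotationError(f"{path}:{lineno}: strandless record rejected")
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise AnnotationError(f"{path}:{lineno}: block count mismatch")
            exs = tuple(
                GenomicInterval(chrom, start + o, start + o + s, strand)
                for o, s in zip(offsets, sizes)
            )
            cds: tuple[GenomicInterval, ...] = ()
            if thick_end > thick_start:
                cds = tuple(
                    GenomicInterval(chrom, max(e.start, thick_start), min(e.end, thick_end), strand)
                    for e in exs
                    if min(e.end, thick_end) > max(e.start, thick_start)
                )
            biotype = f[12] if len(f) > 12 and f[12] else "coding"
            genes.append(
                GeneModel(
                    gene_id=name, symbol=name, chrom=chrom, strand=strand,
                    exons=exs, cds=cds, biotype=biotype,
                )
            )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def parse_annotation(path: str | Path, dialect: str | None = None) -> list[GeneModel]:
    """Parse a GTF or BED12 annotation; dialect inferred from suffix if omitted."""
    if dialect is None:
        suffix = Path(path).suffix.lower()
        dialect = "gtf" if suffix in {".gtf", ".gff"} else "bed12"
    if dialect == "gtf":
        return parse_gtf(path)
    if dialect == "bed12":
        return parse_bed12(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def write_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            bt = "lncRNA" if g.biotype == "lncRNA" else "protein_coding"
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.symbol}"; gene_biotype "{bt}";'
            for iv in g.exons:
                fh.write(
                    f"{g.chrom}\thoxscape\texon\t{iv.start + 1}\t{iv.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )
            for iv in g.cds:
                fh.write(
                    f"{g.chrom}\thoxscape\tCDS\t{iv.start + 1}\t{iv.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def write_bed12(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e.length) for e in g.exons)
            offsets = ",".join(str(e.start - g.start) for e in g.exons)
            if g.cds:
                thick_start, thick_end = g.cds[0].start, g.cds[-1].end
            else:
                thick_start = thick_end = g.start
            fh.write(
                "\t".join(
                    [
                        g.chrom, str(g.start), str(g.end), g.gene_id, "0", g.strand,
                        str(thick_start), str(thick_end), "0",
                        str(g.n_exons), sizes, offsets, g.biotype,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

def promoter_interval(
    gene: GeneModel,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> GenomicInterval:
    """Putative promoter: ``upstream`` bp before the TSS plus ``downstream``
    bp into the gene, strand-aware, clamped at position 0."""
    tss0 = gene.tss - 1  # 0-based TSS position
    if gene.strand == "+":
        start, end = tss0 - upstream, tss0 + downstream
    else:
        start, end = tss0 - downstream + 1, tss0 + upstream + 1
    return GenomicInterval(gene.chrom, max(0, start), end, gene.strand)


def _utr_intervals(gene: GeneModel) -> list[tuple[RegionKey, GenomicInterval]]:
    """5'/3' UTRs = exonic bases outside the CDS span, in transcript orientation."""
    if not gene.cds:
        return []
    cds_start, cds_end = gene.cds[0].start, gene.cds[-1].end
    left, right = [], []  # genomic-left and genomic-right UTR pieces
    for e in gene.exons:
        if e.start < cds_start:
            left.append(GenomicInterval(gene.chrom, e.start, min(e.end, cds_start), gene.strand))
        if e.end > cds_end:
            right.append(GenomicInterval(gene.chrom, max(e.start, cds_end), e.end, gene.strand))
    if gene.strand == "+":
        five, three = left, right
    else:
        five, three = list(reversed(right)), list(reversed(left))
    out = []
    for i, iv in enumerate(five, start=1):
        out.append((RegionKey(gene.gene_id, "utr5", i), iv))
    for i, iv in enumerate(three, start=1):
        out.append((RegionKey(gene.gene_id, "utr3", i), iv))
    return out


def derive_regions(
    gene: GeneModel,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> list[tuple[RegionKey, GenomicInterval]]:
    """All analysis regions of a gene: promoter, exons, introns (+UTRs if CDS).

    Exons and introns tile the gene span exactly.  The promoter may overlap
    the first ``downstream`` bp of exon 1; a CpG falling there belongs to both
    regions (summaries are computed per key independently).
    """
    regions: list[tuple[RegionKey, GenomicInterval]] = [
        (RegionKey(gene.gene_id, "promoter", 0), promoter_interval(gene, upstream, downstream))
    ]
    for i, iv in enumerate(gene.exons_transcript_order(), start=1):
        regions.append((RegionKey(gene.gene_id, "exon", i), iv))
    for i, iv in enumerate(gene.introns_transcript_order(), start=1):
        regions.append((RegionKey(gene.gene_id, "intron", i), iv))
    regions.extend(_utr_intervals(gene))
    return regions


class RegionIndex:
    """Interval index over derived regions of many genes for CpG assignment."""

    def __init__(self, genes: Sequence[GeneModel], **promoter_kw) -> None:
        self.regions: dict[RegionKey, GenomicInterval] = {}
        self._trees: dict[str, IntervalTree] = {}
        for gene in genes:
            for key, iv in derive_regions(gene, **promoter_kw):
                self.regions[key] = iv
                self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, key)

    def assign(self, chrom: str, pos: int) -> list[RegionKey]:
        """Region keys containing a 1-based CpG position (empty if intergenic)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(hit.data for hit in tree.at(pos - 1))


def assign_cpg(pos: int, chrom: str, genes: Sequence[GeneModel]) -> list[RegionKey]:
    """Convenience wrapper: assign one 1-based CpG position against gene models."""
    return RegionIndex(genes).assign(chrom, pos)


# ---------------------------------------------------------------------------
# natural-antisense pairing
# ---------------------------------------------------------------------------

def find_nat_pairs(genes: Sequence[GeneModel]) -> list[NATPair]:
    """Detect natural-antisense lncRNA-gene pairs.

    A pair is emitted iff a lncRNA exon overlaps a coding-gene exon by >= 1 bp
    on the opposite strand of the same chromosome.  Overlapped coding-gene
    exon ordinals (transcript orientation) are recorded; overlap_bp is the
    total overlapping exonic length.
    """
    coding = [g for g in genes if g.biotype != "lncRNA"]
    lncs = [g for g in genes if g.biotype == "lncRNA"]
    pairs = []
    for lnc in lncs:
        for gene in coding:
            if gene.chrom != lnc.chrom or gene.strand == lnc.strand:
                continue
            ordinals, total = [], 0
            for i, gexon in enumerate(gene.exons_transcript_order(), start=1):
                bp = sum(gexon.overlap_bp(lexon) for lexon in lnc.exons)
                if bp:
                    ordinals.append(i)
                    total += bp
            if total:
                pairs.append(NATPair(lnc.gene_id, gene.gene_id, tuple(ordinals), total))
    pairs.sort(key=lambda p: (p.lncrna_id, p.gene_id))
    return pairs


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def regions_to_bed(genes: Sequence[GeneModel], bed_path: str | Path,
                   tsv_path: str | Path | None = None) -> None:
    """Write derived regions as BED6 (+ optional TSV sidecar with ordinals)."""
    rows = []
    for gene in genes:
        for key, iv in derive_regions(gene):
            rows.append((iv.chrom, iv.start, iv.end, str(key), gene.strand, key))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(bed_path, "w") as fh:
        for chrom, start, end, name, strand, _ in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("gene_id\tregion_type\tordinal\tchrom\tstart\tend\tstrand\n")
            for chrom, start, end, _name, strand, key in rows:
                fh.write(
                    f"{key.gene_id}\t{key.region_type}\t{key.ordinal}\t{chrom}\t{start}\t{end}\t{strand}\n"
                )


def nat_pairs_to_tsv(pairs: Sequence[NATPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("lncrna_id\tgene_id\toverlapped_exon_ordinals\toverlap_bp\n")
        for p in pairs:
            ords = ",".join(map(str, p.overlapped_exon_ordinals))
            fh.write(f"{p.lncrna_id}\t{p.gene_id}\t{ords}\t{p.overlap_bp}\n")
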