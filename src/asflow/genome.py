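"""Gene/transcript/exon data model, coordinate arithmetic and GFF3 I/O.

Internal coordinates are 0-based half-open throughout; the GFF3 boundary
converts to and from the format's 1-based closed convention.  Only the
gene → mRNA → exon feature subset with ID/Parent attributes is supported.
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .errors import Gff3ParseError, InvalidInputError

__all__ = [
    "Exon",
    "Transcript",
    "GeneModel",
    "GenomeAnnotation",
    "read_gff3",
    "write_gff3",
    "exonic_union_length",
    "merge_intervals",
]

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class Exon:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InvalidInputError(f"invalid exon interval [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise InvalidInputError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class Transcript:
    id: str
    gene_id: str
    exons: list[Exon]

    def __post_init__(self) -> None:
        if not self.exons:
            raise InvalidInputError(f"transcript {self.id}: needs at least one exon")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise InvalidInputError(f"transcript {self.id}: exons span chrom/strand boundaries")
        for left, right in zip(self.exons, self.exons[1:]):
            if right.start <= left.end:
                raise InvalidInputError(
                    f"transcript {self.id}: exons [{left.start},{left.end}) and "
                    f"[{right.start},{right.end}) are not separated by an intron"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0].start, self.exons[-1].end)

    @property
    def length(self) -> int:
        """Spliced (exonic) length of the transcript."""
        return sum(e.length for e in self.exons)

    def junctions(self) -> list[tuple[int, int]]:
        """(donor, acceptor) pairs: introns as 0-based half-open intervals."""
        return [
            (left.end, right.start) for left, right in zip(self.exons, self.exons[1:])
        ]


@dataclass
class GeneModel:
    id: str
    chrom: str
    strand: str
    transcripts: list[Transcript]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise InvalidInputError(f"gene {self.id}: needs at least one transcript")
        for t in self.transcripts:
            if t.chrom != self.chrom or t.strand != self.strand:
                raise InvalidInputError(
                    f"gene {self.id}: transcript {t.id} disagrees on chrom/strand"
                )

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(t.span[0] for t in self.transcripts),
            max(t.span[1] for t in self.transcripts),
        )

    def exonic_union(self) -> list[tuple[int, int]]:
        return merge_intervals(
            e.interval for t in self.transcripts for e in t.exons
        )


@dataclass
class GenomeAnnotation:
    genes: dict[str, GeneModel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for gid, gene in self.genes.items():
            if gid != gene.id:
                raise InvalidInputError(f"gene mapping key {gid!r} != gene id {gene.id!r}")
            for t in gene.transcripts:
                if t.id in seen:
                    raise InvalidInputError(f"duplicate transcript id {t.id!r}")
                seen.add(t.id)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes.values())

    def __len__(self) -> int:
        return len(self.genes)

    def transcripts(self) -> Iterator[Transcript]:
        for gene in self:
            yield from gene.transcripts

    def chrom_sizes(self, padding: int = 1000) -> dict[str, int]:
        """Upper bounds on chromosome lengths, for SAM @SQ headers."""
        sizes: dict[str, int] = {}
        for gene in self:
            end = gene.span[1] + padding
            sizes[gene.chrom] = max(sizes.get(gene.chrom, 0), end)
        return dict(sorted(sizes.items()))


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted, disjoint list."""
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def exonic_union_length(gene: GeneModel) -> int:
    """Length of the union of all exon intervals across the gene's transcripts."""
    return sum(e - s for s, e in gene.exonic_union())


# --------------------------------------------------------------------------
# GFF3 I/O


def _parse_attributes(field9: str, line_number: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in field9.rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise Gff3ParseError(f"malformed attribute {chunk!r}", line_number)
        key, _, value = chunk.partition("=")
        attrs[key.strip()] = urllib.parse.unquote(value.strip())
    return attrs


def read_gff3(path) -> GenomeAnnotation:
    """Read gene/mRNA/exon features into a :class:`GenomeAnnotation`.

    GFF3 1-based closed coordinates become 0-based half-open internally.
    Exons whose Parent chain cannot be resolved are a hard error.
    """
    gene_rows: dict[str, tuple[str, str]] = {}  # gene_id -> (chrom, strand)
    tx_rows: dict[str, tuple[str, str, str]] = {}  # tx_id -> (gene_id, chrom, strand)
    exon_rows: list[tuple[str, int, int, str, str, int]] = []

    with open(path) as fh:
        for line_number, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise Gff3ParseError(
                    f"expected 9 tab-separated columns, got {len(fields)}", line_number
                )
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise Gff3ParseError(
                    f"non-integer coordinates {start_s!r}..{end_s!r}", line_number
                ) from None
            if end1 < start1:
                raise Gff3ParseError(f"end {end1} < start {start1}", line_number)
            start, end = start1 - 1, end1  # to 0-based half-open
            attrs = _parse_attributes(attr_s, line_number)

            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise Gff3ParseError("gene feature without ID attribute", line_number)
                gene_rows[gid] = (chrom, strand)
            elif ftype in ("mRNA", "transcript"):
                tid, parent = attrs.get("ID"), attrs.get("Parent")
                if tid is None or parent is None:
                    raise Gff3ParseError("mRNA feature requires ID and Parent", line_number)
                tx_rows[tid] = (parent, chrom, strand)
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise Gff3ParseError("exon feature without Parent attribute", line_number)
                exon_rows.append((chrom, start, end, strand, parent, line_number))
            # other feature types are ignored

    tx_exons: dict[str, list[Exon]] = {tid: [] for tid in tx_rows}
    for chrom, start, end, strand, parent, line_number in exon_rows:
        for tid in parent.split(","):
            if tid not in tx_rows:
                raise Gff3ParseError(
                    f"exon Parent {tid!r} does not name a known mRNA", line_number
                )
            tx_exons[tid].append(Exon(chrom, start, end, strand))

    genes: dict[str, GeneModel] = {}
    by_gene: dict[str, list[Transcript]] = {}
    for tid, (gene_id, chrom, strand) in tx_rows.items():
        if gene_id not in gene_rows:
            raise Gff3ParseError(f"mRNA {tid!r} has unknown Parent gene {gene_id!r}")
        if not tx_exons[tid]:
            raise Gff3ParseError(f"mRNA {tid!r} has no exons")
        by_gene.setdefault(gene_id, []).append(Transcript(tid, gene_id, tx_exons[tid]))
    for gene_id, (chrom, strand) in gene_rows.items():
        transcripts = by_gene.get(gene_id)
        if not transcripts:
            raise Gff3ParseError(f"gene {gene_id!r} has no transcripts")
        genes[gene_id] = GeneModel(gene_id, chrom, strand, transcripts)
    return GenomeAnnotation(genes)


def write_gff3(annotation: GenomeAnnotation, path) -> None:
    """Write an annotation as GFF3; inverse of :func:`read_gff3`."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in sorted(annotation, key=lambda g: (g.chrom, g.span, g.id)):
            s, e = gene.span
            fh.write(
                f"{gene.chrom}\tasflow\tgene\t{s + 1}\t{e}\t.\t{gene.strand}\t.\tID={gene.id}\n"
            )
            for t in sorted(gene.transcripts, key=lambda t: t.id):
                ts, te = t.span
                fh.write(
                    f"{gene.chrom}\tasflow\tmRNA\t{ts + 1}\t{te}\t.\t{gene.strand}\t.\t"
                    f"ID={t.id};Parent={gene.id}\n"
                )
                for i, exon in enumerate(t.exons, start=1):
                    fh.write(
                        f"{gene.chrom}\tasflow\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                        f"{gene.strand}\t.\tID={t.id}.exon{i};Parent={t.id}\n"
                    )
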