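"""Splice-junction evidence: SAM parsing, anchor filtering, redundancy filtering.

A junction is keyed by (chrom, donor, acceptor) where the intron occupies the
half-open interval [donor, acceptor).  Support is tracked per sample group
("CK" or "S"); replicates within a group are pooled before thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import pysam

from .errors import SamParseError

__all__ = [
    "AlignedRead",
    "JunctionObservation",
    "Junction",
    "JunctionTable",
    "read_sam",
    "extract_junctions",
    "nonredundant_count",
    "filter_junctions",
    "write_junctions_tsv",
]

SAMPLE_GROUPS = ("CK", "S")

#: "more than 6-nt" of perfect match on each side of the junction.
DEFAULT_MIN_ANCHOR = 7
#: ">3 non-redundant reads" required in both sample groups.
DEFAULT_MIN_NONREDUNDANT = 4

# CIGAR op codes (pysam numeric encoding)
_MATCH_OPS = {0, 7, 8}  # M, =, X consume both
_REF_ONLY = {2}  # D consumes reference within a block
_SKIP = {3}  # N opens a new block
_QUERY_ONLY = {1, 4}  # I, S consume query only
_SILENT = {5, 6}  # H, P consume nothing


@dataclass(frozen=True)
class AlignedRead:
    """A mapped read reduced to its reference-aligned blocks."""

    id: str
    chrom: str
    blocks: tuple[tuple[int, int], ...]  # sorted, 0-based half-open, N-separated
    sample_group: str
    replicate: int = 0

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def aligned_bases(self) -> int:
        return sum(e - s for s, e in self.blocks)


class JunctionObservation(NamedTuple):
    read_start: int
    left_anchor: int
    right_anchor: int


@dataclass
class Junction:
    chrom: str
    donor: int  # end of the left flanking block
    acceptor: int  # start of the right flanking block
    support: dict[str, list[JunctionObservation]] = field(
        default_factory=lambda: {g: [] for g in SAMPLE_GROUPS}
    )

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.donor, self.acceptor)


@dataclass
class JunctionTable:
    junctions: dict[tuple[str, int, int], Junction] = field(default_factory=dict)
    anchor_pass: bool = False
    redundancy_pass: bool = False

    def __len__(self) -> int:
        return len(self.junctions)

    def __contains__(self, key: tuple[str, int, int]) -> bool:
        return key in self.junctions

    def get(self, key: tuple[str, int, int]) -> Junction | None:
        return self.junctions.get(key)

    def nonredundant(self, key: tuple[str, int, int], sample_group: str) -> int:
        """NR count for a junction key, 0 when the key is absent."""
        j = self.junctions.get(key)
        return 0 if j is None else nonredundant_count(j, sample_group)

    def sorted_keys(self) -> list[tuple[str, int, int]]:
        return sorted(self.junctions)


def blocks_from_cigar(pos: int, cigartuples, read_name: str = "?") -> tuple[tuple[int, int], ...]:
    """Reference-aligned blocks from a 0-based position and pysam cigartuples.

    M/=/X extend the current block; D extends it silently (reference-consuming
    gap within a block); N closes the block; I/S/H/P consume no reference.
    """
    blocks: list[tuple[int, int]] = []
    cursor = pos
    block_start = pos
    open_block = False
    for op, length in cigartuples:
        if op in _MATCH_OPS or op in _REF_ONLY:
            if not open_block:
                block_start = cursor
                open_block = True
            cursor += length
        elif op in _SKIP:
            if open_block:
                blocks.append((block_start, cursor))
                open_block = False
            cursor += length
        elif op in _QUERY_ONLY or op in _SILENT:
            pass
        else:
            raise SamParseError(f"record {read_name!r}: unsupported CIGAR op code {op}")
    if open_block:
        blocks.append((block_start, cursor))
    if not blocks:
        raise SamParseError(f"record {read_name!r}: CIGAR consumes no reference bases")
    return tuple(blocks)


def read_sam(path, sample_group: str, replicate: int = 0) -> list[AlignedRead]:
    """Parse a SAM file into :class:`AlignedRead` records (file order kept).

    Unmapped, secondary and supplementary records are skipped.
    """
    if sample_group not in SAMPLE_GROUPS:
        raise SamParseError(f"unknown sample group {sample_group!r}")
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            blocks = blocks_from_cigar(rec.reference_start, rec.cigartuples, rec.query_name)
            reads.append(
                AlignedRead(
                    id=rec.query_name,
                    chrom=rec.reference_name,
                    blocks=blocks,
                    sample_group=sample_group,
                    replicate=replicate,
                )
            )
    return reads


def extract_junctions(
    reads: Iterable[AlignedRead], min_anchor: int = DEFAULT_MIN_ANCHOR
) -> JunctionTable:
    """Collect junction observations from gapped reads, dropping observations
    whose flanking anchor on either side is shorter than ``min_anchor``."""
    table = JunctionTable(anchor_pass=True)
    for read in reads:
        for (ls, le), (rs, re) in zip(read.blocks, read.blocks[1:]):
            left_anchor = le - ls
            right_anchor = re - rs
            if left_anchor < min_anchor or right_anchor < min_anchor:
                continue
            key = (read.chrom, le, rs)
            junction = table.junctions.get(key)
            if junction is None:
                junction = Junction(read.chrom, le, rs)
                table.junctions[key] = junction
            junction.support[read.sample_group].append(
                JunctionObservation(read.start, left_anchor, right_anchor)
            )
    return table


def nonredundant_count(junction: Junction, sample_group: str) -> int:
    """Distinct alignment start positions among the group's supporting reads."""
    return len({obs.read_start for obs in junction.support[sample_group]})


def filter_junctions(
    table: JunctionTable, min_nonredundant: int = DEFAULT_MIN_NONREDUNDANT
) -> JunctionTable:
    """Retain junctions with ≥ min_nonredundant NR reads in CK AND in S."""
    kept = {
        key: j
        for key, j in table.junctions.items()
        if all(nonredundant_count(j, g) >= min_nonredundant for g in SAMPLE_GROUPS)
    }
    return JunctionTable(junctions=kept, anchor_pass=table.anchor_pass, redundancy_pass=True)


def write_junctions_tsv(table: JunctionTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tdonor\tacceptor\tnr_CK\tnr_S\traw_CK\traw_S\tmin_anchor_seen\n")
        for key in table.sorted_keys():
            j = table.junctions[key]
            anchors = [
                min(obs.left_anchor, obs.right_anchor)
                for g in SAMPLE_GROUPS
                for obs in j.support[g]
            ]
            fh.write(
                f"{j.chrom}\t{j.donor}\t{j.acceptor}\t"
                f"{nonredundant_count(j, 'CK')}\t{nonredundant_count(j, 'S')}\t"
                f"{len(j.support['CK'])}\t{len(j.support['S'])}\t"
                f"{min(anchors) if anchors else 0}\n"
            )
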