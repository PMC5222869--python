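"""Alternative-splicing event detection on exon clusters.

Per gene, the exon union across transcripts is merged and split at every
junction boundary (annotation-derived plus observed filtered junctions — the
"reannotation"), events are enumerated from the junction graph, inclusion and
exclusion support is counted per sample group, and each event receives two
Fisher exact P-values — one from junction counts, one from alternative-region
vs gene read coverage — combined by a weighted arithmetic mean and gated by
Benjamini–Hochberg FDR.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .genome import GeneModel, GenomeAnnotation, merge_intervals
from .junctions import (
    DEFAULT_MIN_ANCHOR,
    SAMPLE_GROUPS,
    AlignedRead,
    JunctionTable,
)
from .stats import CombinationWeights, bh_fdr, combine_pvalues, fisher_exact_2x2

logger = logging.getLogger(__name__)

__all__ = [
    "ExonCluster",
    "ASEvent",
    "ASResult",
    "ReadIndex",
    "build_exon_clusters",
    "enumerate_events",
    "count_isoform_support",
    "junction_test",
    "coverage_test",
    "call_events",
    "detect_events",
]

EVENT_TYPES = ("SE", "A5SS", "A3SS", "RI", "MXE")


@dataclass
class ExonCluster:
    """Merged exon/junction structure of one gene."""

    gene_id: str
    chrom: str
    strand: str
    span: tuple[int, int]
    exons: list[tuple[int, int]]  # merged union, split at junction boundaries
    union: list[tuple[int, int]]  # merged union before splitting
    junctions: set[tuple[int, int]]  # (donor, acceptor)
    transcript_exons: list[list[tuple[int, int]]]  # per-transcript exon intervals


@dataclass
class ASEvent:
    event_id: str
    gene_id: str
    type: str
    chrom: str
    strand: str
    alt_region: tuple[int, int]
    inclusion_junctions: frozenset[tuple[int, int]]
    exclusion_junctions: frozenset[tuple[int, int]]
    inclusion_counts: dict[str, int] = field(default_factory=dict)
    exclusion_counts: dict[str, int] = field(default_factory=dict)
    alt_coverage: dict[str, int] = field(default_factory=dict)
    gene_coverage: dict[str, int] = field(default_factory=dict)
    p1: float | None = None
    p2: float | None = None
    p_combined: float | None = None
    q: float | None = None
    significant: bool = False


@dataclass
class ASResult:
    events: list[ASEvent]
    weights: CombinationWeights
    fdr_threshold: float
    include_mxe: bool = False

    def significant_events(self) -> list[ASEvent]:
        return [e for e in self.events if e.significant]

    def counts_by_type(self, significant_only: bool = True) -> dict[str, int]:
        counts = {t: 0 for t in EVENT_TYPES}
        for e in self.events:
            if not significant_only or e.significant:
                counts[e.type] += 1
        return counts

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for e in self.events:
            rows.append(
                {
                    "event_id": e.event_id,
                    "gene_id": e.gene_id,
                    "type": e.type,
                    "chrom": e.chrom,
                    "strand": e.strand,
                    "alt_start": e.alt_region[0],
                    "alt_end": e.alt_region[1],
                    "incl_CK": e.inclusion_counts.get("CK", 0),
                    "excl_CK": e.exclusion_counts.get("CK", 0),
                    "incl_S": e.inclusion_counts.get("S", 0),
                    "excl_S": e.exclusion_counts.get("S", 0),
                    "alt_cov_CK": e.alt_coverage.get("CK", 0),
                    "gene_cov_CK": e.gene_coverage.get("CK", 0),
                    "alt_cov_S": e.alt_coverage.get("S", 0),
                    "gene_cov_S": e.gene_coverage.get("S", 0),
                    "p1": e.p1,
                    "p2": e.p2,
                    "p_combined": e.p_combined,
                    "q": e.q,
                    "significant": e.significant,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "event_id", "gene_id", "type", "chrom", "strand", "alt_start", "alt_end",
                "incl_CK", "excl_CK", "incl_S", "excl_S",
                "alt_cov_CK", "gene_cov_CK", "alt_cov_S", "gene_cov_S",
                "p1", "p2", "p_combined", "q", "significant",
            ],
        )


# --------------------------------------------------------------------------
# Cluster construction


def _split_at(intervals: list[tuple[int, int]], boundaries: Iterable[int]) -> list[tuple[int, int]]:
    cuts = sorted(set(boundaries))
    out: list[tuple[int, int]] = []
    for s, e in intervals:
        inner = [b for b in cuts if s < b < e]
        prev = s
        for b in inner:
            out.append((prev, b))
            prev = b
        out.append((prev, e))
    return out


def build_exon_clusters(
    annotation: GenomeAnnotation, junctions: JunctionTable
) -> list[ExonCluster]:
    """One cluster per gene; observed filtered junctions inside the gene span
    are attached, and their boundaries split member exons (reannotation).

    Observed junctions not contained in any single gene span are logged and
    skipped.
    """
    spans: dict[str, list[tuple[int, int, str]]] = {}
    for gene in annotation:
        s, e = gene.span
        spans.setdefault(gene.chrom, []).append((s, e, gene.id))
    observed_by_gene: dict[str, set[tuple[int, int]]] = {}
    for chrom, donor, acceptor in junctions.junctions:
        hit = False
        for s, e, gid in spans.get(chrom, ()):
            if s <= donor and acceptor <= e:
                observed_by_gene.setdefault(gid, set()).add((donor, acceptor))
                hit = True
        if not hit:
            logger.debug(
                "junction %s:%d-%d is not contained in any gene span; skipped",
                chrom, donor, acceptor,
            )

    clusters: list[ExonCluster] = []
    for gid in sorted(annotation.genes):
        gene = annotation.genes[gid]
        junc: set[tuple[int, int]] = set(observed_by_gene.get(gid, set()))
        for t in gene.transcripts:
            junc.update(t.junctions())
        union = gene.exonic_union()
        boundaries = {b for d, a in junc for b in (d, a)}
        clusters.append(
            ExonCluster(
                gene_id=gid,
                chrom=gene.chrom,
                strand=gene.strand,
                span=gene.span,
                exons=_split_at(union, boundaries),
                union=union,
                junctions=junc,
                transcript_exons=[[e.interval for e in t.exons] for t in gene.transcripts],
            )
        )
    return clusters


# --------------------------------------------------------------------------
# Event enumeration


def _covered(union: list[tuple[int, int]], start: int, end: int) -> bool:
    """True when [start, end) lies entirely inside the exonic union."""
    i = bisect.bisect_right(union, (start, float("inf"))) - 1
    return i >= 0 and union[i][0] <= start and end <= union[i][1]


def _junc_tag(junctions: Iterable[tuple[int, int]]) -> str:
    return ",".join(f"{d}-{a}" for d, a in sorted(junctions))


def enumerate_events(cluster: ExonCluster, include_mxe: bool = True) -> list[ASEvent]:
    """Enumerate candidate SE/A5SS/A3SS/RI (and optionally MXE) events from
    the cluster's junction graph; counts are left unfilled."""
    events: dict[tuple, ASEvent] = {}

    def add(etype: str, alt: tuple[int, int], incl, excl) -> None:
        incl, excl = frozenset(incl), frozenset(excl)
        key = (etype, alt, incl, excl)
        if key in events:
            return
        event_id = (
            f"{cluster.gene_id}|{etype}|{cluster.chrom}:{alt[0]}-{alt[1]}"
            f"|inc={_junc_tag(incl)}|exc={_junc_tag(excl)}"
        )
        events[key] = ASEvent(
            event_id=event_id,
            gene_id=cluster.gene_id,
            type=etype,
            chrom=cluster.chrom,
            strand=cluster.strand,
            alt_region=alt,
            inclusion_junctions=incl,
            exclusion_junctions=excl,
        )

    junc = cluster.junctions

    # SE: skip junction (d, a) plus an exon E strictly inside with junctions
    # to both flanks.
    for d, a in junc:
        for es, ee in cluster.exons:
            if d < es and ee < a and (d, es) in junc and (ee, a) in junc:
                add("SE", (es, ee), [(d, es), (ee, a)], [(d, a)])

    # A5SS/A3SS: two junctions sharing one intron boundary; the variable
    # region must be fully exonic, which excludes pairs that merely reflect
    # an SE or MXE configuration.
    by_donor: dict[int, list[int]] = {}
    by_acceptor: dict[int, list[int]] = {}
    for d, a in junc:
        by_donor.setdefault(d, []).append(a)
        by_acceptor.setdefault(a, []).append(d)
    for d, accs in by_donor.items():
        accs = sorted(accs)
        for i in range(len(accs)):
            for j in range(i + 1, len(accs)):
                a1, a2 = accs[i], accs[j]
                if not _covered(cluster.union, a1, a2):
                    continue
                etype = "A3SS" if cluster.strand == "+" else "A5SS"
                add(etype, (a1, a2), [(d, a1)], [(d, a2)])
    for a, dons in by_acceptor.items():
        dons = sorted(dons)
        for i in range(len(dons)):
            for j in range(i + 1, len(dons)):
                d1, d2 = dons[i], dons[j]
                if not _covered(cluster.union, d1, d2):
                    continue
                etype = "A5SS" if cluster.strand == "+" else "A3SS"
                add(etype, (d1, d2), [(d2, a)], [(d1, a)])

    # RI: a junction whose intron is strictly inside an exon of some transcript.
    for d, a in junc:
        for exons in cluster.transcript_exons:
            if any(es < d and a < ee for es, ee in exons):
                add("RI", (d, a), [], [(d, a)])
                break

    # MXE: two non-adjacent exons sharing flanking junction partners but
    # never joined to each other.
    if include_mxe:
        flanked = []
        for es, ee in cluster.exons:
            lefts = {d for d, a in junc if a == es}
            rights = {a for d, a in junc if d == ee}
            if lefts and rights:
                flanked.append(((es, ee), lefts, rights))
        for i in range(len(flanked)):
            for j in range(i + 1, len(flanked)):
                (e1, l1, r1), (e2, l2, r2) = flanked[i], flanked[j]
                if e1[1] > e2[0]:
                    continue
                if (e1[1], e2[0]) in junc:
                    continue
                common_l = l1 & l2
                common_r = r1 & r2
                if not common_l or not common_r:
                    continue
                d = max(common_l)  # closest shared flank
                a = min(common_r)
                add(
                    "MXE",
                    e1,
                    [(d, e1[0]), (e1[1], a)],
                    [(d, e2[0]), (e2[1], a)],
                )

    return sorted(events.values(), key=lambda e: e.event_id)


# --------------------------------------------------------------------------
# Counting


class ReadIndex:
    """Per-(group, chrom) coordinate index over aligned reads for overlap counts."""

    def __init__(self, reads: Iterable[AlignedRead]):
        buckets: dict[tuple[str, str], list[AlignedRead]] = {}
        for r in reads:
            buckets.setdefault((r.sample_group, r.chrom), []).append(r)
        self._index: dict[tuple[str, str], tuple[list[int], list[AlignedRead], int]] = {}
        for key, rs in buckets.items():
            rs.sort(key=lambda r: r.start)
            starts = [r.start for r in rs]
            max_span = max(r.end - r.start for r in rs)
            self._index[key] = (starts, rs, max_span)

    def count_overlapping(
        self,
        sample_group: str,
        chrom: str,
        intervals: list[tuple[int, int]],
        min_overlap: int = 1,
    ) -> int:
        """Reads whose aligned blocks overlap the interval set by ≥ min_overlap bases."""
        entry = self._index.get((sample_group, chrom))
        if entry is None or not intervals:
            return 0
        starts, rs, max_span = entry
        lo_bound = min(s for s, _ in intervals) - max_span
        hi_bound = max(e for _, e in intervals)
        i0 = bisect.bisect_left(starts, lo_bound)
        i1 = bisect.bisect_left(starts, hi_bound)
        count = 0
        for r in rs[i0:i1]:
            overlap = 0
            for bs, be in r.blocks:
                for s, e in intervals:
                    lo, hi = max(bs, s), min(be, e)
                    if hi > lo:
                        overlap += hi - lo
            if overlap >= min_overlap:
                count += 1
        return count


def count_isoform_support(
    event: ASEvent,
    junctions: JunctionTable,
    reads: ReadIndex,
    gene: GeneModel,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
) -> ASEvent:
    """Fill per-group inclusion/exclusion junction counts and coverage counts.

    Junctions absent from the (filtered) table contribute zero support.  RI
    inclusion evidence is reads overlapping the retained-intron interior by at
    least ``min_anchor`` bases.
    """
    union = gene.exonic_union()
    for group in SAMPLE_GROUPS:
        if event.type == "RI":
            incl = reads.count_overlapping(
                group, event.chrom, [event.alt_region], min_overlap=min_anchor
            )
        else:
            incl = sum(
                junctions.nonredundant((event.chrom, d, a), group)
                for d, a in event.inclusion_junctions
            )
        excl = sum(
            junctions.nonredundant((event.chrom, d, a), group)
            for d, a in event.exclusion_junctions
        )
        event.inclusion_counts[group] = incl
        event.exclusion_counts[group] = excl
        event.alt_coverage[group] = reads.count_overlapping(
            group, event.chrom, [event.alt_region]
        )
        event.gene_coverage[group] = reads.count_overlapping(group, event.chrom, union)
    return event


# --------------------------------------------------------------------------
# Testing and calling


def junction_test(event: ASEvent) -> float:
    """p1: Fisher exact on inclusion/exclusion junction counts, CK vs S."""
    table = [
        [event.inclusion_counts["CK"], event.exclusion_counts["CK"]],
        [event.inclusion_counts["S"], event.exclusion_counts["S"]],
    ]
    return fisher_exact_2x2(table)


def coverage_test(event: ASEvent) -> float:
    """p2: Fisher exact on alternative-region vs rest-of-gene coverage, CK vs S."""
    table = [
        [
            event.alt_coverage["CK"],
            max(0, event.gene_coverage["CK"] - event.alt_coverage["CK"]),
        ],
        [
            event.alt_coverage["S"],
            max(0, event.gene_coverage["S"] - event.alt_coverage["S"]),
        ],
    ]
    return fisher_exact_2x2(table)


def call_events(
    events: list[ASEvent],
    weights: CombinationWeights | None = None,
    fdr_threshold: float = 0.05,
    include_mxe: bool = False,
) -> ASResult:
    """Combine the two P-values, BH-adjust over the whole event family, flag
    significance, and sort by (q, event_id)."""
    if weights is None:
        weights = CombinationWeights()
    if not (0.0 < fdr_threshold <= 1.0):
        raise InvalidInputError(f"fdr_threshold must lie in (0, 1], got {fdr_threshold}")
    if not events:
        return ASResult([], weights, fdr_threshold, include_mxe)
    for e in events:
        if e.p1 is None:
            e.p1 = junction_test(e)
        if e.p2 is None:
            e.p2 = coverage_test(e)
        e.p_combined = combine_pvalues(e.p1, e.p2, weights)
    qvals = bh_fdr([e.p_combined for e in events])
    for e, q in zip(events, qvals):
        e.q = float(q)
        e.significant = e.q < fdr_threshold
    ordered = sorted(events, key=lambda e: (e.q, e.event_id))
    return ASResult(ordered, weights, fdr_threshold, include_mxe)


def detect_events(
    annotation: GenomeAnnotation,
    reads: Iterable[AlignedRead],
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    min_nonredundant: int = 4,
    weights: CombinationWeights | None = None,
    fdr_threshold: float = 0.05,
    include_mxe: bool = False,
) -> tuple[ASResult, dict[str, int]]:
    """End-to-end detection from aligned reads; returns the result plus
    stage-count bookkeeping for logging."""
    from .junctions import extract_junctions, filter_junctions

    reads = list(reads)
    raw_table = extract_junctions(reads, min_anchor=min_anchor)
    table = filter_junctions(raw_table, min_nonredundant=min_nonredundant)
    clusters = build_exon_clusters(annotation, table)
    events: list[ASEvent] = []
    index = ReadIndex(reads)
    for cluster in clusters:
        cluster_events = enumerate_events(cluster, include_mxe=include_mxe)
        gene = annotation.genes[cluster.gene_id]
        for event in cluster_events:
            count_isoform_support(event, table, index, gene, min_anchor=min_anchor)
        events.extend(cluster_events)
    if not include_mxe:
        events = [e for e in events if e.type != "MXE"]
    result = call_events(events, weights=weights, fdr_threshold=fdr_threshold,
                         include_mxe=include_mxe)
    stats = {
        "reads": len(reads),
        "junctions_observed": len(raw_table),
        "junctions_filtered": len(table),
        "clusters": len(clusters),
        "events": len(result.events),
        "events_significant": len(result.significant_events()),
    }
    return result, stats
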