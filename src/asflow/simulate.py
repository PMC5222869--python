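"""Synthetic two-condition spliced-read data with planted effects.

Generates toy gene models capable of realizing SE / A5SS / A3SS / RI (and
optionally MXE) events, then draws error-free single-end reads from them with
Poisson count noise, a planted fold change on designated DE genes, and a
planted inclusion-proportion (PSI) shift on designated AS genes.  Everything
is deterministic given the config seed.

Read model: uniquely mapped, error-free reads; noise enters only through the
Poisson gene counts and the Bernoulli isoform choice.  Per-gene abundances
λ_g are drawn once and shared across conditions and replicates, so planted
fold changes are the only systematic expression difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pysam

from .errors import ConfigurationError, InvalidInputError
from .genome import Exon, GeneModel, GenomeAnnotation, Transcript
from .junctions import AlignedRead

__all__ = [
    "SimulationConfig",
    "TruthGene",
    "TruthEvent",
    "TruthTable",
    "SimRead",
    "simulate_annotation",
    "truth_table",
    "simulate_reads",
    "write_sam",
    "to_aligned_reads",
    "write_truth",
    "read_truth",
]

EVENT_TYPES = ("SE", "A5SS", "A3SS", "RI", "MXE")
CONDITIONS = ("CK", "S")
_COND_CODE = {"CK": 0, "S": 1}


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_genes: int = 100
    read_length: int = 75
    depth_per_condition: float = 50_000.0  # expected reads per sample group
    frac_de_genes: float = 0.2
    de_fold_change: float = 4.0
    frac_as_genes: float = 0.3
    psi_ck: float = 0.5
    psi_s: float = 0.5
    event_type_mix: dict[str, float] = field(
        default_factory=lambda: {"SE": 0.25, "A5SS": 0.25, "A3SS": 0.25, "RI": 0.25}
    )
    expression_meanlog: float = 0.0
    expression_sdlog: float = 1.0
    n_replicates_per_condition: int = 2

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if self.read_length <= 0:
            raise ConfigurationError("read_length must be positive")
        if self.depth_per_condition < 0:
            raise ConfigurationError("depth_per_condition must be non-negative")
        for name in ("frac_de_genes", "frac_as_genes", "psi_ck", "psi_s"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_de_genes + self.frac_as_genes > 1.0 + 1e-9:
            raise ConfigurationError("frac_de_genes + frac_as_genes must not exceed 1")
        if self.de_fold_change <= 1.0:
            raise ConfigurationError("de_fold_change must exceed 1")
        if self.n_replicates_per_condition < 1:
            raise ConfigurationError("need at least one replicate per condition")
        mix = self.event_type_mix
        if not mix or any(t not in EVENT_TYPES for t in mix):
            raise ConfigurationError(f"event_type_mix keys must be among {EVENT_TYPES}")
        if any(v < 0 for v in mix.values()) or abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("event_type_mix must be non-negative and sum to 1")


@dataclass(frozen=True)
class TruthGene:
    gene_id: str
    is_de: bool
    direction: str  # up | down | none  (S relative to CK)
    is_as: bool
    event_type: str  # one of EVENT_TYPES, or "" for non-AS genes


@dataclass(frozen=True)
class TruthEvent:
    gene_id: str
    event_type: str
    chrom: str
    alt_start: int
    alt_end: int
    psi_ck: float
    psi_s: float
    inclusion_transcript: str
    exclusion_transcript: str


@dataclass
class TruthTable:
    genes: dict[str, TruthGene]
    events: list[TruthEvent]

    def de_genes(self) -> dict[str, str]:
        return {g.gene_id: g.direction for g in self.genes.values() if g.is_de}


@dataclass(frozen=True)
class SimRead:
    name: str
    chrom: str
    blocks: tuple[tuple[int, int], ...]
    cigar: str

    @property
    def pos(self) -> int:
        return self.blocks[0][0]


# --------------------------------------------------------------------------
# Annotation + truth construction


def _gene_structure(
    gid: str, chrom: str, strand: str, cursor: int, etype: str | None, rng: np.random.Generator, rl: int
) -> tuple[GeneModel, tuple[int, int] | None, int]:
    """Build one gene starting at ``cursor``; returns (gene, alt_region, new cursor).

    Exon lengths are kept ≥ 2×read_length so every junction can carry
    anchor-compliant reads on both sides.
    """
    exlen = lambda: 2 * rl + int(rng.integers(0, 60))
    intron = lambda: int(rng.integers(80, 200))
    pos = cursor

    def ex(length: int) -> tuple[int, int]:
        nonlocal pos
        iv = (pos, pos + length)
        pos += length
        return iv

    def gap(length: int) -> None:
        nonlocal pos
        pos += length

    def mk(tid: str, ivs: list[tuple[int, int]]) -> Transcript:
        return Transcript(tid, gid, [Exon(chrom, s, e, strand) for s, e in ivs])

    alt: tuple[int, int] | None = None
    if etype is None:
        e1 = ex(exlen())
        gap(intron())
        e2 = ex(exlen())
        gap(intron())
        e3 = ex(exlen())
        transcripts = [mk(f"{gid}.t1", [e1, e2, e3])]
    elif etype == "SE":
        left = ex(exlen())
        gap(intron())
        cassette = ex(exlen())
        gap(intron())
        right = ex(exlen())
        transcripts = [
            mk(f"{gid}.t1", [left, cassette, right]),  # inclusion
            mk(f"{gid}.t2", [left, right]),
        ]
        alt = cassette
    elif etype in ("A5SS", "A3SS"):
        # A5SS varies the donor side of the intron, A3SS the acceptor side —
        # relative to transcription direction, so the varied genomic boundary
        # flips with strand.
        offset = 12 + int(rng.integers(0, 38))
        first = ex(exlen())
        gap(intron())
        second = ex(exlen())
        vary_right_end_of_first = (etype == "A5SS") == (strand == "+")
        if vary_right_end_of_first:
            long1 = first
            short1 = (first[0], first[1] - offset)
            transcripts = [
                mk(f"{gid}.t1", [long1, second]),  # inclusion: keeps the extra region
                mk(f"{gid}.t2", [short1, second]),
            ]
            alt = (short1[1], long1[1])
        else:
            long2 = second
            short2 = (second[0] + offset, second[1])
            transcripts = [
                mk(f"{gid}.t1", [first, long2]),
                mk(f"{gid}.t2", [first, short2]),
            ]
            alt = (long2[0], short2[0])
    elif etype == "RI":
        first = ex(exlen())
        retained = ex(intron())
        second = ex(exlen())
        transcripts = [
            mk(f"{gid}.t1", [(first[0], second[1])]),  # inclusion: intron retained
            mk(f"{gid}.t2", [first, second]),
        ]
        alt = retained
    elif etype == "MXE":
        left = ex(exlen())
        gap(intron())
        mx1 = ex(exlen())
        gap(intron())
        mx2 = ex(exlen())
        gap(intron())
        right = ex(exlen())
        transcripts = [
            mk(f"{gid}.t1", [left, mx1, right]),  # inclusion: first alternative exon
            mk(f"{gid}.t2", [left, mx2, right]),
        ]
        alt = mx1
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown event type {etype!r}")
    return GeneModel(gid, chrom, strand, transcripts), alt, pos


def _build(config: SimulationConfig) -> tuple[GenomeAnnotation, TruthTable]:
    config.validate()
    rng = np.random.default_rng([config.seed, 11])
    n = config.n_genes
    n_de = round(config.frac_de_genes * n)
    n_as = round(config.frac_as_genes * n)

    perm = rng.permutation(n)
    de_idx = set(perm[:n_de].tolist())
    as_idx = set(perm[n_de : n_de + n_as].tolist())
    mix_types = sorted(config.event_type_mix)
    mix_probs = np.array([config.event_type_mix[t] for t in mix_types])

    genes: dict[str, GeneModel] = {}
    truth_genes: dict[str, TruthGene] = {}
    events: list[TruthEvent] = []
    cursors = {"sim1": 1000, "sim2": 1000}
    de_seen = 0
    for i in range(n):
        gid = f"g{i:05d}"
        chrom = "sim1" if i % 2 == 0 else "sim2"
        strand = "+" if rng.random() < 0.5 else "-"
        etype = (
            str(rng.choice(mix_types, p=mix_probs)) if i in as_idx and mix_probs.size else None
        )
        gene, alt, cursor = _gene_structure(
            gid, chrom, strand, cursors[chrom], etype, rng, config.read_length
        )
        cursors[chrom] = cursor + 500  # intergenic gap
        genes[gid] = gene
        is_de = i in de_idx
        direction = "none"
        if is_de:
            direction = "up" if de_seen % 2 == 0 else "down"
            de_seen += 1
        truth_genes[gid] = TruthGene(gid, is_de, direction, etype is not None, etype or "")
        if etype is not None:
            assert alt is not None
            events.append(
                TruthEvent(
                    gid,
                    etype,
                    chrom,
                    alt[0],
                    alt[1],
                    config.psi_ck,
                    config.psi_s,
                    f"{gid}.t1",
                    f"{gid}.t2",
                )
            )
    return GenomeAnnotation(genes), TruthTable(truth_genes, events)


def simulate_annotation(config: SimulationConfig) -> GenomeAnnotation:
    """Deterministic toy annotation realizing the configured event mix."""
    return _build(config)[0]


def truth_table(config: SimulationConfig, annotation: GenomeAnnotation | None = None) -> TruthTable:
    """Ground truth paired with :func:`simulate_annotation` for the same config."""
    built_ann, truth = _build(config)
    if annotation is not None and set(annotation.genes) != set(built_ann.genes):
        raise InvalidInputError("annotation does not match this configuration")
    return truth


# --------------------------------------------------------------------------
# Read simulation


def gene_abundances(config: SimulationConfig, gene_ids: Iterable[str]) -> dict[str, float]:
    """Per-gene relative abundances λ_g, shared across conditions/replicates."""
    ids = sorted(gene_ids)
    rng = np.random.default_rng([config.seed, 1001])
    lam = rng.lognormal(config.expression_meanlog, config.expression_sdlog, size=len(ids))
    return dict(zip(ids, lam.tolist()))


def _project(transcript: Transcript, start: int, length: int) -> tuple[tuple[int, int], ...]:
    """Map transcript-coordinate interval [start, start+length) to genome blocks."""
    blocks: list[tuple[int, int]] = []
    offset = start
    remaining = length
    for exon in transcript.exons:
        if offset >= exon.length:
            offset -= exon.length
            continue
        take = min(exon.length - offset, remaining)
        blocks.append((exon.start + offset, exon.start + offset + take))
        remaining -= take
        offset = 0
        if remaining == 0:
            break
    return tuple(blocks)


def _cigar(blocks: tuple[tuple[int, int], ...]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i:
            parts.append(f"{s - blocks[i - 1][1]}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


def simulate_reads(
    annotation: GenomeAnnotation,
    truth: TruthTable,
    config: SimulationConfig,
    condition: str,
    replicate: int = 0,
) -> list[SimRead]:
    """Draw one replicate's reads for one condition, sorted by coordinate."""
    config.validate()
    if condition not in CONDITIONS:
        raise ConfigurationError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    rl = config.read_length
    for t in annotation.transcripts():
        if t.length < rl:
            raise ConfigurationError(
                f"read_length {rl} exceeds spliced length of transcript {t.id} ({t.length})"
            )
    lam = gene_abundances(config, annotation.genes)
    lam_sum = sum(lam.values())
    depth = config.depth_per_condition / config.n_replicates_per_condition
    psi = config.psi_ck if condition == "CK" else config.psi_s
    rng = np.random.default_rng([config.seed, 7000 + _COND_CODE[condition], replicate])

    reads: list[SimRead] = []
    for gid in sorted(annotation.genes):
        gene = annotation.genes[gid]
        tg = truth.genes[gid]
        mean = depth * lam[gid] / lam_sum
        if tg.is_de and condition == "S":
            mean = mean * config.de_fold_change if tg.direction == "up" else mean / config.de_fold_change
        n_reads = int(rng.poisson(mean))
        if n_reads == 0:
            continue
        if tg.is_as:
            by_id = {t.id: t for t in gene.transcripts}
            inc = by_id[f"{gid}.t1"]
            exc = by_id[f"{gid}.t2"]
            n_inc = int(rng.binomial(n_reads, psi))
            batches = [(inc, n_inc), (exc, n_reads - n_inc)]
        else:
            batches = [(gene.transcripts[0], n_reads)]
        serial = 0
        for tx, count in batches:
            if count == 0:
                continue
            starts = rng.integers(0, tx.length - rl + 1, size=count)
            for s in starts.tolist():
                blocks = _project(tx, s, rl)
                reads.append(
                    SimRead(
                        name=f"{gid}:{condition}{replicate}:{serial}",
                        chrom=gene.chrom,
                        blocks=blocks,
                        cigar=_cigar(blocks),
                    )
                )
                serial += 1
    reads.sort(key=lambda r: (r.chrom, r.pos, r.name))
    return reads


def write_sam(reads: list[SimRead], annotation: GenomeAnnotation, path) -> None:
    """Write simulated reads as coordinate-sorted plain-text SAM."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in annotation.chrom_sizes().items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = r.name
            seg.flag = 0
            seg.reference_id = out.get_tid(r.chrom)
            seg.reference_start = r.pos
            seg.mapping_quality = 60
            seg.cigarstring = r.cigar
            out.write(seg)


def to_aligned_reads(
    reads: Iterable[SimRead], sample_group: str, replicate: int = 0
) -> list[AlignedRead]:
    """Bridge simulator output to the junction module without a SAM round-trip."""
    return [
        AlignedRead(r.name, r.chrom, r.blocks, sample_group, replicate) for r in reads
    ]


# --------------------------------------------------------------------------
# Analytic expectations (used to select well-powered truth entries)


def expected_read_means(
    annotation: GenomeAnnotation, truth: TruthTable, config: SimulationConfig
) -> dict[str, dict[str, float]]:
    """Expected reads per gene per condition (summed over replicates)."""
    lam = gene_abundances(config, annotation.genes)
    lam_sum = sum(lam.values())
    out: dict[str, dict[str, float]] = {}
    for gid, l in lam.items():
        base = config.depth_per_condition * l / lam_sum
        tg = truth.genes[gid]
        s_mean = base
        if tg.is_de:
            s_mean = base * config.de_fold_change if tg.direction == "up" else base / config.de_fold_change
        out[gid] = {"CK": base, "S": s_mean}
    return out


def _junction_cross_starts(transcript: Transcript, read_length: int, min_anchor: int) -> int:
    """Number of read start positions spanning any one junction of the
    transcript with compliant anchors (identical for every junction when
    flanking exons are ≥ read_length, as generated here)."""
    return max(0, read_length - 2 * min_anchor + 1)


def expected_event_support(
    annotation: GenomeAnnotation,
    truth: TruthTable,
    config: SimulationConfig,
    min_anchor: int = 7,
) -> dict[tuple[str, str], float]:
    """Per planted event, the smaller across conditions of the expected number
    of event-informative junction reads (inclusion- plus exclusion-isoform
    evidence), used to pick well-powered events for recovery checks."""
    means = expected_read_means(annotation, truth, config)
    rl = config.read_length
    out: dict[tuple[str, str], float] = {}
    for e in truth.events:
        gene = annotation.genes[e.gene_id]
        by_id = {t.id: t for t in gene.transcripts}
        inc, exc = by_id[e.inclusion_transcript], by_id[e.exclusion_transcript]
        cross = max(0, rl - 2 * min_anchor + 1)
        if e.event_type == "RI":
            intron = e.alt_end - e.alt_start
            inc_starts = max(0, intron + rl - 2 * min_anchor + 1)  # intron-overlap reads
            n_inc_j = 1.0
        else:
            inc_starts = cross
            n_inc_j = len(inc.junctions()) and sum(
                1 for j in inc.junctions() if j not in exc.junctions()
            )
        n_exc_j = sum(1 for j in exc.junctions() if j not in inc.junctions())
        support = {}
        for cond, psi in (("CK", e.psi_ck), ("S", e.psi_s)):
            m = means[e.gene_id][cond]
            inc_rate = n_inc_j * inc_starts / max(1, inc.length - rl + 1)
            exc_rate = n_exc_j * cross / max(1, exc.length - rl + 1)
            support[cond] = m * (psi * inc_rate + (1 - psi) * exc_rate)
        out[(e.gene_id, e.event_type)] = min(support.values())
    return out


# --------------------------------------------------------------------------
# Truth table I/O (tab-separated text)


def write_truth(truth: TruthTable, genes_path, events_path) -> None:
    with open(genes_path, "w") as fh:
        fh.write("#gene_id\tis_de\tdirection\tis_as\tevent_type\n")
        for g in sorted(truth.genes.values(), key=lambda g: g.gene_id):
            fh.write(f"{g.gene_id}\t{int(g.is_de)}\t{g.direction}\t{int(g.is_as)}\t{g.event_type}\n")
    with open(events_path, "w") as fh:
        fh.write(
            "#gene_id\tevent_type\tchrom\talt_start\talt_end\tpsi_ck\tpsi_s"
            "\tinclusion_transcript\texclusion_transcript\n"
        )
        for e in truth.events:
            fh.write(
                f"{e.gene_id}\t{e.event_type}\t{e.chrom}\t{e.alt_start}\t{e.alt_end}"
                f"\t{e.psi_ck:g}\t{e.psi_s:g}\t{e.inclusion_transcript}\t{e.exclusion_transcript}\n"
            )


def read_truth(genes_path, events_path) -> TruthTable:
    genes: dict[str, TruthGene] = {}
    with open(genes_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            gid, is_de, direction, is_as, etype = line.rstrip("\n").split("\t")
            genes[gid] = TruthGene(gid, bool(int(is_de)), direction, bool(int(is_as)), etype)
    events: list[TruthEvent] = []
    with open(events_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            gid, etype, chrom, s, e, pck, ps, inc, exc = line.rstrip("\n").split("\t")
            events.append(
                TruthEvent(gid, etype, chrom, int(s), int(e), float(pck), float(ps), inc, exc)
            )
    return TruthTable(genes, events)
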