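"""Gene-level counting, RPKM, DEG calling, multi-group overlap, enrichment.

DE testing uses the exact two-proportion Fisher test on replicate-pooled
counts per group; the thresholds (|log2FC| > 1 and BH FDR < 0.05, both
configurable) define a DEG.  Term enrichment is the one-sided hypergeometric
over-representation test (Fisher path), with an optional χ² path that falls
back to Fisher on degenerate expected counts.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import DegenerateTableError, InvalidInputError, NormalizationError
from .genome import GenomeAnnotation
from .junctions import AlignedRead
from .stats import bh_fdr, chisq_2x2, fisher_exact_2x2, log2_fold_change

logger = logging.getLogger(__name__)

__all__ = [
    "SampleInfo",
    "CountTable",
    "rpkm",
    "count_gene_reads",
    "call_degs",
    "overlap_groups",
    "OverlapSummary",
    "term_enrichment",
    "read_term_map",
]

#: Minimum fraction of a read's aligned bases that must fall inside a gene's
#: exonic union for the read to count for that gene.
ASSIGN_FRACTION = 0.5


class SampleInfo(NamedTuple):
    name: str
    group: str  # CK | S
    replicate: int


@dataclass
class CountTable:
    """Gene × sample matrix of assigned read counts plus per-sample bookkeeping."""

    matrix: pd.DataFrame  # index: gene_id, columns: sample names
    samples: list[SampleInfo]
    stats: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.name for s in self.samples]
        if list(self.matrix.columns) != names:
            raise InvalidInputError("count matrix columns must match sample metadata order")
        if (self.matrix.to_numpy() < 0).any():
            raise InvalidInputError("counts must be non-negative")

    def totals(self) -> pd.Series:
        """Per-sample totals of gene-assigned reads."""
        return self.matrix.sum(axis=0)

    def group_samples(self, group: str) -> list[str]:
        return [s.name for s in self.samples if s.group == group]

    def pooled(self, group: str) -> pd.Series:
        cols = self.group_samples(group)
        if not cols:
            raise InvalidInputError(f"no samples in group {group!r}")
        return self.matrix[cols].sum(axis=1)


def count_gene_reads(
    reads: Iterable[AlignedRead], annotation: GenomeAnnotation
) -> CountTable:
    """Assign reads to genes: a read counts for gene g when ≥ 50% of its
    aligned bases fall in g's exonic union; reads satisfying this for more
    than one gene are discarded as ambiguous."""
    gene_ids = sorted(annotation.genes)
    unions = {gid: annotation.genes[gid].exonic_union() for gid in gene_ids}
    spans: dict[str, list[tuple[int, int, str]]] = {}
    for gid in gene_ids:
        gene = annotation.genes[gid]
        s, e = gene.span
        spans.setdefault(gene.chrom, []).append((s, e, gid))
    for lst in spans.values():
        lst.sort()
    max_span = {
        chrom: max(e - s for s, e, _ in lst) for chrom, lst in spans.items()
    }

    sample_keys: dict[tuple[str, int], dict[str, int]] = {}
    counts: dict[tuple[str, int], dict[str, int]] = {}
    for read in reads:
        skey = (read.sample_group, read.replicate)
        stat = sample_keys.setdefault(
            skey, {"parsed": 0, "assigned": 0, "ambiguous": 0, "intergenic": 0}
        )
        cnt = counts.setdefault(skey, {})
        stat["parsed"] += 1
        aligned = read.aligned_bases
        hits = []
        lst = spans.get(read.chrom, [])
        starts_only = [s for s, _, _ in lst]
        i0 = bisect.bisect_left(starts_only, read.start - max_span.get(read.chrom, 0))
        for s, e, gid in lst[i0:]:
            if s >= read.end:
                break
            if e <= read.start:
                continue
            overlap = 0
            for bs, be in read.blocks:
                for us, ue in unions[gid]:
                    lo, hi = max(bs, us), min(be, ue)
                    if hi > lo:
                        overlap += hi - lo
            if overlap * 2 >= aligned:
                hits.append(gid)
        if len(hits) == 1:
            cnt[hits[0]] = cnt.get(hits[0], 0) + 1
            stat["assigned"] += 1
        elif len(hits) > 1:
            stat["ambiguous"] += 1
        else:
            stat["intergenic"] += 1

    samples = [
        SampleInfo(f"{group}_{rep}", group, rep)
        for group, rep in sorted(sample_keys, key=lambda k: (k[0], k[1]))
    ]
    matrix = pd.DataFrame(
        {
            s.name: [counts[(s.group, s.replicate)].get(g, 0) for g in gene_ids]
            for s in samples
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    stats = {s.name: sample_keys[(s.group, s.replicate)] for s in samples}
    return CountTable(matrix, samples, stats)


@dataclass
class RPKMTable:
    matrix: pd.DataFrame
    gene_lengths: pd.Series


def rpkm(counts: CountTable, annotation: GenomeAnnotation) -> RPKMTable:
    """Reads per kilobase of exonic-union gene model per million assigned reads."""
    from .genome import exonic_union_length

    totals = counts.totals()
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise NormalizationError(f"sample(s) with zero assigned reads: {bad}")
    lengths = pd.Series(
        {gid: exonic_union_length(annotation.genes[gid]) for gid in counts.matrix.index},
        name="length_bp",
    )
    mat = counts.matrix.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)
    return RPKMTable(mat, lengths)


def call_degs(
    counts: CountTable,
    fc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene exact test on pooled CK vs S counts, BH-adjusted, with
    threshold-based DEG calls (strict inequalities on both thresholds).

    Returns a DataFrame indexed by gene_id with columns count_CK, count_S,
    cpm_CK, cpm_S, log2fc, p, q, direction, is_deg.  log2fc is S relative to
    CK on counts-per-million with a pseudocount.
    """
    k_ck = counts.pooled("CK")
    k_s = counts.pooled("S")
    t_ck = int(k_ck.sum())
    t_s = int(k_s.sum())
    if t_ck == 0 or t_s == 0:
        raise NormalizationError("a sample group has zero assigned reads")

    cpm_ck = k_ck / t_ck * 1e6
    cpm_s = k_s / t_s * 1e6
    lfc = np.array(
        [log2_fold_change(s, c, pseudocount) for s, c in zip(cpm_s, cpm_ck)]
    )
    pvals = np.array(
        [
            fisher_exact_2x2([[c, t_ck - c], [s, t_s - s]])
            for c, s in zip(k_ck.astype(int), k_s.astype(int))
        ]
    )
    qvals = bh_fdr(pvals)
    is_deg = (np.abs(lfc) > fc_threshold) & (qvals < fdr_threshold)
    direction = np.where(is_deg, np.where(lfc > 0, "up", "down"), "none")
    return pd.DataFrame(
        {
            "count_CK": k_ck.astype(int),
            "count_S": k_s.astype(int),
            "cpm_CK": cpm_ck,
            "cpm_S": cpm_s,
            "log2fc": lfc,
            "p": pvals,
            "q": qvals,
            "direction": direction,
            "is_deg": is_deg,
        },
        index=counts.matrix.index,
    )


@dataclass(frozen=True)
class OverlapSummary:
    n_groups: int
    all_overlap: frozenset[str]  # DEG in every group, any direction
    up_overlap: frozenset[str]  # direction "up" in every group
    down_overlap: frozenset[str]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "all": len(self.all_overlap),
            "up": len(self.up_overlap),
            "down": len(self.down_overlap),
        }


def overlap_groups(deg_tables: list[pd.DataFrame]) -> OverlapSummary:
    """Direction-aware overlap across multiple comparisons.

    A gene can be a DEG in every group yet belong to neither directional
    overlap if its direction flips between groups — which is how the total
    overlap can exceed up + down.
    """
    if not deg_tables:
        raise InvalidInputError("need at least one DEG table")
    deg_sets = [frozenset(df.index[df["is_deg"]]) for df in deg_tables]
    up_sets = [frozenset(df.index[df["direction"] == "up"]) for df in deg_tables]
    down_sets = [frozenset(df.index[df["direction"] == "down"]) for df in deg_tables]
    all_overlap = frozenset.intersection(*deg_sets)
    up = frozenset.intersection(*up_sets)
    down = frozenset.intersection(*down_sets)
    return OverlapSummary(len(deg_tables), all_overlap, up, down)


def read_term_map(path) -> dict[str, set[str]]:
    """Two-column tab-separated gene_id → term_id map (one pair per line)."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for line_number, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise InvalidInputError(
                    f"{path}, line {line_number}: expected 2 tab-separated columns"
                )
            gene, term = fields
            mapping.setdefault(gene, set()).add(term)
    return mapping


def term_enrichment(
    deg_genes: Iterable[str],
    background: Iterable[str],
    term_map: Mapping[str, set[str]],
    test: str = "fisher",
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of annotation terms among DEGs.

    Per term with K ≥ 1 annotated background genes: k = DEG hits, n = number
    of DEGs, N = background size; the Fisher path reports the one-sided
    hypergeometric tail P(X ≥ k), the χ² path the homogeneity test on the
    corresponding 2×2 table (falling back to Fisher on degenerate expected
    counts).  q-values are BH over all tested terms.
    """
    background = set(background)
    if not background:
        raise InvalidInputError("background gene set is empty")
    deg = set(deg_genes)
    if not deg <= background:
        raise InvalidInputError("deg_genes must be a subset of the background")
    if test not in ("fisher", "chisq"):
        raise InvalidInputError(f"unknown test {test!r}")

    term_genes: dict[str, set[str]] = {}
    for gene, terms in term_map.items():
        if gene not in background:
            continue
        for term in terms:
            term_genes.setdefault(term, set()).add(gene)

    N = len(background)
    n = len(deg)
    rows = []
    for term in sorted(term_genes):
        members = term_genes[term]
        K = len(members)
        k = len(members & deg)
        if test == "fisher":
            p = float(hypergeom.sf(k - 1, N, K, n))
        else:
            table = [[k, n - k], [K - k, (N - n) - (K - k)]]
            try:
                p = chisq_2x2(table).pvalue
            except DegenerateTableError:
                logger.debug("term %s: degenerate χ² table, falling back to Fisher", term)
                p = fisher_exact_2x2(table)
        fold = (k / n) / (K / N) if n > 0 else 0.0
        rows.append({"term_id": term, "k": k, "K": K, "n": n, "N": N,
                     "p": min(1.0, p), "fold_enrichment": fold})
    df = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "p", "fold_enrichment"])
    if len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
        df["significant"] = df["q"] < fdr_threshold
        df = df.sort_values(["q", "term_id"], kind="mergesort").reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df
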