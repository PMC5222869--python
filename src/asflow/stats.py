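"""Exact and adjusted statistics used by every downstream stage.

The two-sided Fisher exact test is computed from first principles (exact
integer arithmetic on the hypergeometric support whenever the table is small
enough) because its tie-handling convention — include every table whose
probability is ≤ the observed one, compared with a relative tolerance — is a
documented part of the pipeline contract and must be reproducible bit-for-bit
against an enumeration oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.stats import chi2, hypergeom

from .errors import DegenerateTableError, InvalidInputError

__all__ = [
    "ContingencyTable2x2",
    "CombinationWeights",
    "ChisqResult",
    "fisher_exact_2x2",
    "chisq_2x2",
    "bh_fdr",
    "combine_pvalues",
    "log2_fold_change",
]

#: Relative tolerance used when deciding whether a candidate table's
#: probability is "≤" the observed table's probability (guards against
#: platform-dependent exclusion of the observed table itself).
TIE_RTOL = 1e-12

#: Tables whose smallest margin is below this bound are evaluated with exact
#: integer arithmetic; larger tables fall back to log-space floats.
_EXACT_SUPPORT_LIMIT = 4096


@dataclass(frozen=True)
class ContingencyTable2x2:
    """A 2×2 table of counts.

    Row 1 is the control group (CK), row 2 the stressed group (S); column 1
    holds the "event" counts (inclusion / hit), column 2 the complement.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v) or not math.isfinite(v):
                raise InvalidInputError(
                    f"contingency table entries must be non-negative integers; {name}={v!r}"
                )
            object.__setattr__(self, name, int(v))

    @classmethod
    def coerce(cls, table) -> "ContingencyTable2x2":
        if isinstance(table, cls):
            return table
        arr = np.asarray(table)
        if arr.shape != (2, 2):
            raise InvalidInputError(f"expected a 2x2 table, got shape {arr.shape}")
        return cls(arr[0, 0], arr[0, 1], arr[1, 0], arr[1, 1])

    @property
    def row_margins(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_margins(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class CombinationWeights:
    """Weights for the arithmetic-mean P-value combination; normalized on use."""

    w1: float = 0.5
    w2: float = 0.5

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0:
            raise InvalidInputError("combination weights must be non-negative")
        if self.w1 + self.w2 <= 0:
            raise InvalidInputError("combination weights must not both be zero")


class ChisqResult(NamedTuple):
    statistic: float
    pvalue: float


def fisher_exact_2x2(table, alternative: str = "two-sided") -> float:
    """Two-sided Fisher exact P for a 2×2 table.

    Sums, over all tables sharing the observed margins, the hypergeometric
    probabilities that are ≤ the observed table's probability (ties compared
    with relative tolerance ``TIE_RTOL``).  An all-zero table carries no
    evidence and returns 1.0.
    """
    if alternative != "two-sided":
        raise InvalidInputError(f"only the two-sided alternative is supported, got {alternative!r}")
    t = ContingencyTable2x2.coerce(table)
    r1, r2 = t.row_margins
    c1, _ = t.col_margins
    n = t.total
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0  # degenerate margins: a single table in the support

    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    # exact integer arithmetic while the binomial coefficients stay cheap;
    # log-space floats otherwise (large-count tables from deep sequencing)
    if min(r1, r2, c1, n - c1) <= _EXACT_SUPPORT_LIMIT and n <= 20_000:
        return _fisher_exact_int(t.a, r1, r2, c1, lo, hi)
    return _fisher_exact_float(t.a, r1, r2, c1, n, lo, hi)


def _fisher_exact_int(a: int, r1: int, r2: int, c1: int, lo: int, hi: int) -> float:
    # Integer numerators C(r1,x)·C(r2,c1−x) share the denominator C(n,c1);
    # the ≤ comparison is then exact and the tie tolerance is moot.
    comb = math.comb
    num_obs = comb(r1, a) * comb(r2, c1 - a)
    total = 0
    acc = 0
    for x in range(lo, hi + 1):
        num = comb(r1, x) * comb(r2, c1 - x)
        total += num
        if num <= num_obs:
            acc += num
    return min(1.0, acc / total)


def _fisher_exact_float(a: int, r1: int, r2: int, c1: int, n: int, lo: int, hi: int) -> float:
    xs = np.arange(lo, hi + 1)
    logpmf = hypergeom.logpmf(xs, n, c1, r1)
    log_obs = hypergeom.logpmf(a, n, c1, r1)
    keep = logpmf <= log_obs + math.log1p(TIE_RTOL)
    p = float(np.exp(logpmf[keep]).sum())
    return min(1.0, p)


def chisq_2x2(table, continuity_correction: bool = False) -> ChisqResult:
    """Pearson χ² test of homogeneity on a 2×2 table (1 df).

    No continuity correction by default.  Raises ``DegenerateTableError``
    when any expected count is zero (the caller should use
    :func:`fisher_exact_2x2` instead).
    """
    t = ContingencyTable2x2.coerce(table)
    obs = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
    n = obs.sum()
    if n == 0:
        raise DegenerateTableError("empty table: expected counts are zero; use fisher_exact_2x2")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    if np.any(expected == 0):
        raise DegenerateTableError(
            "zero expected count (a margin is zero); use fisher_exact_2x2"
        )
    diff = np.abs(obs - expected)
    if continuity_correction:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    return ChisqResult(stat, float(chi2.sf(stat, df=1)))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, aligned to input order.

    q(i) = min over j with rank ≥ rank(i) of p(j)·m/j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise InvalidInputError("bh_fdr requires a non-empty collection of p-values")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InvalidInputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def combine_pvalues(p1: float, p2: float, weights: CombinationWeights | None = None) -> float:
    """Weighted arithmetic mean of two P-values: (w1·p1 + w2·p2)/(w1 + w2)."""
    if weights is None:
        weights = CombinationWeights()
    for p in (p1, p2):
        if not (0.0 <= p <= 1.0):
            raise InvalidInputError(f"p-value {p!r} outside [0, 1]")
    return (weights.w1 * p1 + weights.w2 * p2) / (weights.w1 + weights.w2)


def log2_fold_change(x_treat: float, x_ctrl: float, pseudocount: float = 1.0) -> float:
    """log2((x_treat + pc)/(x_ctrl + pc)) on already depth-normalized values."""
    if x_treat < 0 or x_ctrl < 0:
        raise InvalidInputError("expression values must be non-negative")
    if pseudocount < 0 or (pseudocount == 0 and (x_treat == 0 or x_ctrl == 0)):
        raise InvalidInputError("pseudocount must be positive (or both inputs > 0)")
    return math.log2((x_treat + pseudocount) / (x_ctrl + pseudocount))
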