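"""Independent brute-force oracles used by the test-suite and acceptance checks.

Everything here is written from the definitions, not from the package code:
exact rational arithmetic for the Fisher test, the literal step-up formula
for BH, direct transcript-pair structural comparison for event enumeration,
and rational hypergeometric tails for enrichment.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def fisher_two_sided_bruteforce(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact P by full enumeration with exact rationals.

    Enumerates every table with the observed margins via the column-wise
    hypergeometric parametrization and sums the probabilities that are ≤ the
    observed table's probability (exact comparison — ties are exact in
    integer arithmetic).
    """
    c1, c2 = a + c, b + d
    r1 = a + b
    n = c1 + c2
    if n == 0 or c1 == 0 or c2 == 0 or r1 == 0 or r1 == n:
        return 1.0
    denom = comb(n, r1)
    num_obs = comb(c1, a) * comb(c2, r1 - a)
    acc = 0
    for x in range(max(0, r1 - c2), min(r1, c1) + 1):
        num = comb(c1, x) * comb(c2, r1 - x)
        if num <= num_obs:
            acc += num
    p = Fraction(acc, denom)
    return float(min(p, Fraction(1)))


def bh_stepup_bruteforce(pvalues) -> list[float]:
    """BH q-values straight from the definition: q_i = min_{j: p_j ranked ≥ i}
    p_(j)·m/j, capped at 1 — computed quadratically without vectorization."""
    m = len(pvalues)
    indexed = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    # walk ranks from largest to smallest, carrying the running minimum
    running = 1.0
    for rank in range(m, 0, -1):
        i = indexed[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        q[i] = running
    return q


def hypergeom_upper_tail_bruteforce(k: int, K: int, n: int, N: int) -> float:
    """P(X ≥ k) for X ~ Hypergeometric(N, K, n), with exact rationals."""
    denom = comb(N, n)
    acc = sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(K, n) + 1))
    return float(Fraction(acc, denom))


# --------------------------------------------------------------------------
# Event enumeration by direct structural comparison of a transcript pair.


def _introns(exons):
    return [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]


def events_from_transcript_pair(exons1, exons2, strand: str):
    """AS events implied by two transcripts of one gene, as a set of
    (type, (alt_start, alt_end)) tuples.

    exons1/exons2: sorted lists of (start, end) half-open intervals.
    """
    found = set()
    for t_a, t_b in ((exons1, exons2), (exons2, exons1)):
        introns_a, introns_b = set(_introns(t_a)), set(_introns(t_b))
        # SE: t_b skips over an exon of t_a in a single intron
        for d, a in introns_b:
            for es, ee in t_a:
                if d < es and ee < a and (d, es) in introns_a and (ee, a) in introns_a:
                    found.add(("SE", (es, ee)))
        # RI: an intron of t_a lies strictly inside an exon of t_b
        for d, a in introns_a:
            if any(es < d and a < ee for es, ee in t_b):
                found.add(("RI", (d, a)))
        # A5SS/A3SS: introns sharing exactly one boundary, the variable
        # region exonic in the longer-exon transcript
        for d1, a1 in introns_a:
            for d2, a2 in introns_b:
                if a1 == a2 and d1 != d2:
                    lo, hi = min(d1, d2), max(d1, d2)
                    longer = t_a if d1 == hi else t_b
                    if any(es <= lo and hi <= ee for es, ee in longer):
                        etype = "A5SS" if strand == "+" else "A3SS"
                        found.add((etype, (lo, hi)))
                if d1 == d2 and a1 != a2:
                    lo, hi = min(a1, a2), max(a1, a2)
                    longer = t_a if a1 == lo else t_b
                    if any(es <= lo and hi <= ee for es, ee in longer):
                        etype = "A3SS" if strand == "+" else "A5SS"
                        found.add((etype, (lo, hi)))
        # MXE: flanking introns from common donor/acceptor to two exons that
        # never co-occur
        for es1, ee1 in t_a:
            for es2, ee2 in t_b:
                if ee1 > es2:
                    continue
                if (es1, ee1) in t_b or (es2, ee2) in t_a:
                    continue
                d_ok = any(
                    ia[1] == es1 and ib[1] == es2 and ia[0] == ib[0]
                    for ia in introns_a
                    for ib in introns_b
                )
                a_ok = any(
                    ia[0] == ee1 and ib[0] == ee2 and ia[1] == ib[1]
                    for ia in introns_a
                    for ib in introns_b
                )
                joined = (ee1, es2) in introns_a or (ee1, es2) in introns_b
                if d_ok and a_ok and not joined:
                    found.add(("MXE", (min(es1, es2), min(ee1, ee2))))
    return found
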