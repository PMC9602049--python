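"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (exact rational arithmetic,
plain recursion) and deliberately shares no code with the implementation it
checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def ac_pmf(y: int, x: int, n1: int, n2: int) -> Fraction:
    """Exact Audic-Claverie conditional probability of y given x.

    p(y|x) = C(x+y, y) * n1^(x+1) * n2^y / (n1+n2)^(x+y+1); for n1 == n2 this
    reduces to C(x+y, y) / 2^(x+y+1).
    """
    return Fraction(comb(x + y, y) * n1 ** (x + 1) * n2**y, (n1 + n2) ** (x + y + 1))


def ac_enum_pvalue(x: int, y: int, n1: int = 1, n2: int = 1, tail_method: str = "double") -> float:
    """Two-sided Audic-Claverie p by exact tail enumeration."""
    lower = sum(ac_pmf(k, x, n1, n2) for k in range(y + 1))
    upper = 1 - sum(ac_pmf(k, x, n1, n2) for k in range(y))
    if tail_method == "double":
        return float(min(Fraction(1), 2 * min(lower, upper)))
    # minlike: mass of all outcomes no more likely than the observed one
    cutoff = ac_pmf(y, x, n1, n2)
    mode = (x + 1) * n2 // n1 + 1
    hi = max(y, mode) + 1
    while ac_pmf(hi, x, n1, n2) >= cutoff or hi < mode:
        hi += 1
    while ac_pmf(hi, x, n1, n2) > Fraction(1, 10**30):
        hi += 50
    total = sum(ac_pmf(k, x, n1, n2) for k in range(hi + 1) if ac_pmf(k, x, n1, n2) <= cutoff)
    total += 1 - sum(ac_pmf(k, x, n1, n2) for k in range(hi + 1))  # far tail, all below cutoff
    return float(min(Fraction(1), total))


def hypergeom_pmf(k: int, a_plus_b: int, a_plus_c: int, n: int) -> Fraction:
    """P(K = k) drawing a_plus_b marked items out of n with a_plus_c draws."""
    return Fraction(
        comb(a_plus_c, k) * comb(n - a_plus_c, a_plus_b - k), comb(n, a_plus_b)
    )


def fisher_enum_pvalue(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for [[a, b], [c, d]] by enumeration.

    Uses the minlike convention: sum the probabilities of all tables with the
    same margins whose probability does not exceed the observed table's
    (with the customary 1 + 1e-7 relative tie tolerance).
    """
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    k_min = max(0, row1 + col1 - n)
    k_max = min(row1, col1)
    probs = {k: hypergeom_pmf(k, row1, col1, n) for k in range(k_min, k_max + 1)}
    cutoff = probs[a] * Fraction(10**7 + 1, 10**7)
    return float(min(Fraction(1), sum(p for p in probs.values() if p <= cutoff)))


# --- exhaustive banded antisense alignment -------------------------------

MATCHES = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
WOBBLES = {("G", "T"), ("T", "G")}


def _col_penalty(pirna: str, i: int, base: str, params) -> float:
    cls = (
        0.0
        if (pirna[i - 1], base) in MATCHES
        else params.gu_penalty
        if (pirna[i - 1], base) in WOBBLES
        else params.mismatch_penalty
    )
    return cls * params.weight(i)


def enumerate_best_alignment(pirna: str, transcript: str, params):
    """Best banded antisense alignment by plain recursion over columns.

    Considers every target start, every interleaving of pair / piRNA-gap /
    target-gap columns with at most params.max_gaps gaps, full piRNA
    consumption. Returns (score, (start, end)) under the tie-break
    (score, leftmost start, smallest end) in forward transcript coordinates,
    or None if no alignment scores <= max_score.
    """
    rev = transcript[::-1]
    n, L = len(rev), len(pirna)
    results: list[tuple[float, int, int]] = []  # (score, start_fwd, end_fwd)

    def rec(i: int, j: int, gaps: int, cost: float, j0: int):
        if cost > params.max_score + 1e-9:
            return
        if i == L:
            results.append((cost, n - j, n - j0))
            return
        if j < n:  # pair column
            rec(i + 1, j + 1, gaps, cost + _col_penalty(pirna, i + 1, rev[j], params), j0)
        if gaps < params.max_gaps:
            # piRNA base unpaired (gap in target)
            rec(i + 1, j, gaps + 1, cost + params.gap_penalty * params.weight(i + 1), j0)
            # target base unpaired (gap in piRNA)
            if j < n:
                w = params.gap_penalty * params.weight(min(i + 1, L))
                rec(i, j + 1, gaps + 1, cost + w, j0)

    for j0 in range(n + 1):
        rec(0, j0, 0, 0.0, j0)
    if not results:
        return None
    best = min(results, key=lambda r: (round(r[0], 9), r[1], r[2]))
    return best[0], (best[1], best[2])
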