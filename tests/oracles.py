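"""Independent reference implementations used only as test oracles.

These are deliberately naive: a scalar three-matrix Gotoh DP, a brute-force
enumerator over alignment op-strings for tiny instances, and a term-by-term
diploid likelihood evaluator.  They share the package's conventions (glocal
boundary, direct I<->D transitions allowed, each maximal gap run pays its
own open penalty) but none of its code paths.
"""

from __future__ import annotations

import math

NEG = float("-inf")


def gotoh_score(read: str, ref: str, match: int, mismatch: int, gap_open: int, gap_extend: int) -> int:
    """Scalar glocal affine-gap DP; returns the optimal score only."""
    n, m = len(read), len(ref)
    opn = gap_open + gap_extend
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    I = [[NEG] * (m + 1) for _ in range(n + 1)]
    D = [[NEG] * (m + 1) for _ in range(n + 1)]
    for j in range(m + 1):
        M[0][j] = 0
    for i in range(1, n + 1):
        for j in range(m + 1):
            if j > 0:
                s = match if read[i - 1] == ref[j - 1] else -mismatch
                M[i][j] = max(M[i - 1][j - 1], I[i - 1][j - 1], D[i - 1][j - 1]) + s
            I[i][j] = max(M[i - 1][j] - opn, D[i - 1][j] - opn, I[i - 1][j] - gap_extend)
        for j in range(1, m + 1):
            D[i][j] = max(M[i][j - 1] - opn, I[i][j - 1] - opn, D[i][j - 1] - gap_extend)
    return int(max(max(M[n]), max(I[n])))


def score_op_string(ops: str, read: str, ref: str, ref_start: int,
                    match: int, mismatch: int, gap_open: int, gap_extend: int) -> int:
    """Affine score of an explicit op string; each maximal I/D run pays open once."""
    score = 0
    i, j = 0, ref_start
    prev = ""
    for op in ops:
        if op == "M":
            score += match if read[i] == ref[j] else -mismatch
            i += 1
            j += 1
        elif op == "I":
            score -= (gap_open + gap_extend) if prev != "I" else gap_extend
            i += 1
        elif op == "D":
            score -= (gap_open + gap_extend) if prev != "D" else gap_extend
            j += 1
        prev = op
    return score


def enumerate_best_score(read: str, ref: str, match: int, mismatch: int,
                         gap_open: int, gap_extend: int) -> int:
    """Exhaustive search over all glocal alignments of tiny instances."""
    n, m = len(read), len(ref)
    best = NEG

    def recurse(ops: str, i: int, j: int, start: int) -> None:
        nonlocal best
        if i == n:
            s = score_op_string(ops, read, ref, start, match, mismatch, gap_open, gap_extend)
            if s > best:
                best = s
            return
        if j < m:
            recurse(ops + "M", i + 1, j + 1, start)
            recurse(ops + "D", i, j + 1, start)
        recurse(ops + "I", i + 1, j, start)

    for start in range(m + 1):
        recurse("", 0, start, start)
    return int(best)


def diploid_log_likelihoods(
    entries: list[tuple[str, int]], ref: str, alt: str, min_q: int
) -> tuple[float, float, float] | None:
    """Term-by-term diploid likelihood triple (natural log)."""

    def p_base(b: str, allele: str, e: float) -> float:
        return 1.0 - e if b == allele else e / 3.0

    lls = [0.0, 0.0, 0.0]
    used = 0
    for base, q in entries:
        if q < min_q or base not in (ref, alt):
            continue
        used += 1
        e = min(10.0 ** (-q / 10.0), 0.75)  # quality 0 is uninformative, not impossible
        for g, (a1, a2) in enumerate(((ref, ref), (ref, alt), (alt, alt))):
            lls[g] += math.log(0.5 * p_base(base, a1, e) + 0.5 * p_base(base, a2, e))
    if used == 0:
        return None
    return tuple(lls)
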