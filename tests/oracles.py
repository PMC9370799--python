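"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: scores come from a
plain Gotoh dynamic program, SSR loci from exhaustive (start, period)
enumeration, coverage from a per-base bitmask, and BH adjustment from the
naive O(m^2) step-up definition.
"""

from __future__ import annotations

import numpy as np

MATCH = 1.0
MISMATCH = -1.0
GAP_FIRST = -5.0  # open -4 plus first extension -1
GAP_EXTEND = -1.0
NEG = float("-inf")


def gotoh_endsfree_score(a: str, b: str) -> float:
    """Optimal ends-free global alignment score by explicit 3-state DP."""
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in a (consume b)
    Y = np.full((n + 1, m + 1), NEG)  # gap in b (consume a)
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        X[0, j] = 0.0  # free leading gap
    for i in range(1, n + 1):
        Y[i, 0] = 0.0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = MATCH if (ai == b[j - 1] and ai in "ACGT") else MISMATCH
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(
                M[i, j - 1] + GAP_FIRST,
                X[i, j - 1] + GAP_EXTEND,
                Y[i, j - 1] + GAP_FIRST,
            )
            Y[i, j] = max(
                M[i - 1, j] + GAP_FIRST,
                Y[i - 1, j] + GAP_EXTEND,
                X[i - 1, j] + GAP_FIRST,
            )
    best = NEG
    for j in range(m + 1):  # free trailing gap in a
        best = max(best, M[n, j], X[n, j], Y[n, j])
    for i in range(n + 1):  # free trailing gap in b
        best = max(best, M[i, m], X[i, m], Y[i, m])
    return float(best)


def brute_force_ssrs(
    s: str, min_motif: int = 2, max_motif: int = 8, min_repeats: int = 5
) -> set[tuple[int, int, int]]:
    """Every maximal perfect tandem run, by testing each (start, period).

    Returns {(start, end, period)} with end truncated to complete copies;
    a start counts only when the periodicity does not extend one base to
    the left (leftmost convention) and the period-length motif is
    primitive and ACGT-only.
    """
    out = set()
    n = len(s)
    for k in range(min_motif, max_motif + 1):
        for i in range(0, n - k):
            if i >= 1 and s[i - 1] == s[i - 1 + k] and s[i - 1] in "ACGT":
                continue  # extendable left: not the leftmost start
            motif = s[i : i + k]
            if any(c not in "ACGT" for c in motif):
                continue
            if any(
                k % p == 0 and motif == motif[:p] * (k // p)
                for p in range(1, k)
            ):
                continue  # non-primitive period
            j = i
            while j + k < n and s[j] == s[j + k] and s[j] in "ACGT":
                j += 1
            copies = ((j - i) + k) // k
            if j > i and copies >= min_repeats:
                out.add((i, i + copies * k, k))
    return out


def bitmask_union_bp(intervals, seq_len: int) -> int:
    """Covered bases of a set of [start, end) intervals, counted per base."""
    mask = np.zeros(seq_len, dtype=bool)
    for start, end in intervals:
        mask[start:end] = True
    return int(mask.sum())


def naive_bh(pvals) -> np.ndarray:
    """O(m^2) Benjamini-Hochberg step-up straight from the definition."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for pos in range(m):
        i = order[pos]
        best = 1.0
        for pos2 in range(pos, m):  # min over all larger-or-equal ranks
            j = order[pos2]
            best = min(best, m * p[j] / (pos2 + 1))
        adj[i] = best
    return adj


def chi2_2x2(c1: int, n1: int, c2: int, n2: int) -> tuple[float, float]:
    """Two-sample chi-square test of proportions from the textbook formula."""
    from scipy.stats import chi2

    pooled = (c1 + c2) / (n1 + n2)
    stat = 0.0
    for c, n in ((c1, n1), (c2, n2)):
        e1 = n * pooled
        e0 = n * (1 - pooled)
        stat += (c - e1) ** 2 / e1 + ((n - c) - e0) ** 2 / e0
    return stat, float(chi2.sf(stat, 1))
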