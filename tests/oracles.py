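"""Independent reference implementations used only to check the package.

These deliberately re-derive results by different routes (top-down memoised
recursion, closed forms, per-pair scipy calls) than the implementations
they validate.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

import numpy as np
from scipy.special import gammaln
from scipy.stats import pearsonr

MATCH, MISMATCH = 1, -1
OPEN_EXT, EXT = 3, 1  # first gap column costs 3, later columns 1
NEG = -(10**8)


def dp_identity_oracle(seq_a: str, seq_b: str) -> tuple[int, float, int]:
    """Semi-global affine alignment by top-down recursion.

    Returns (score, identity, overlap) under match +1 / mismatch -1, a
    length-L gap costing 2 + L, free end gaps, N never matching, and the
    deterministic tie-break (fewer gap columns, then diagonal preference,
    then scan order).  Values are carried as (score, -gap_columns) tuples
    so the secondary objective rides along the recursion.
    """
    a, b = seq_a.upper(), seq_b.upper()
    n, m = len(a), len(b)
    NEGT = (NEG, NEG)

    def sub(i: int, j: int) -> int:
        return MATCH if (a[i] == b[j] and a[i] != "N") else MISMATCH

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: int) -> tuple[int, int]:
        """(score, -gap columns) of the preferred alignment ending here."""
        if state == 0:  # diagonal
            if i == 0 or j == 0:
                return (0, 0)  # free leading gaps: start here
            s = sub(i - 1, j - 1)
            ps, pg = max(
                best(i - 1, j - 1, 0), best(i - 1, j - 1, 1), best(i - 1, j - 1, 2)
            )
            return (ps + s, pg)
        if state == 1:  # gap in b, consumes a[i-1]
            if i == 0:
                return NEGT
            so, go = best(i - 1, j, 0)
            se, ge = best(i - 1, j, 1)
            return max((so - OPEN_EXT, go - 1), (se - EXT, ge - 1))
        if j == 0:
            return NEGT
        so, go = best(i, j - 1, 0)
        se, ge = best(i, j - 1, 2)
        return max((so - OPEN_EXT, go - 1), (se - EXT, ge - 1))

    ends = [(n, j, st) for j in range(m + 1) for st in (0, 1, 2)]
    ends += [(i, m, st) for i in range(n + 1) for st in (0, 1, 2)]
    top = max(best(i, j, st) for i, j, st in ends)
    # first maximum in scan order, states preferred 0 > 1 > 2 within a cell
    ei, ej, est = next((i, j, st) for i, j, st in ends if best(i, j, st) == top)

    matches = columns = 0
    i, j, st = ei, ej, est
    while True:
        if st == 0:
            if i == 0 or j == 0:
                break
            matches += int(a[i - 1] == b[j - 1] and a[i - 1] != "N")
            columns += 1
            prev = max(
                best(i - 1, j - 1, 0), best(i - 1, j - 1, 1), best(i - 1, j - 1, 2)
            )
            for cand in (0, 1, 2):
                if best(i - 1, j - 1, cand) == prev:
                    break
            i, j, st = i - 1, j - 1, cand
            if i == 0 or j == 0:
                break
        elif st == 1:
            columns += 1
            so, go = best(i - 1, j, 0)
            se, ge = best(i - 1, j, 1)
            nxt = 0 if (so - OPEN_EXT, go - 1) >= (se - EXT, ge - 1) else 1
            i, st = i - 1, nxt
        else:
            columns += 1
            so, go = best(i, j - 1, 0)
            se, ge = best(i, j - 1, 2)
            nxt = 0 if (so - OPEN_EXT, go - 1) >= (se - EXT, ge - 1) else 2
            j, st = j - 1, nxt
    identity = matches / columns if columns else 0.0
    return top[0], identity, columns


def expected_richness(column, depth: int) -> float:
    """Analytic rarefaction: E[S] = sum_i 1 - C(N - n_i, d) / C(N, d)."""
    col = np.asarray(column, dtype=np.int64)
    col = col[col > 0]
    n_total = int(col.sum())

    def log_choose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    total = 0.0
    for ni in col:
        if n_total - ni < depth:
            total += 1.0
        else:
            total += 1.0 - np.exp(
                log_choose(n_total - ni, depth) - log_choose(n_total, depth)
            )
    return float(total)


def brute_force_edges(counts_df, threshold=0.7, min_pairs=9):
    """All-pairs pairwise-complete Pearson edges on log10 counts."""
    edges = {}
    logged = np.log10(counts_df.where(counts_df > 0).to_numpy(dtype=float))
    ids = list(counts_df.index)
    for ia, ib in combinations(range(len(ids)), 2):
        x, y = logged[ia], logged[ib]
        ok = ~np.isnan(x) & ~np.isnan(y)
        if ok.sum() < min_pairs:
            continue
        if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            continue
        r = pearsonr(x[ok], y[ok]).statistic
        if abs(r) >= threshold:
            edges[tuple(sorted((ids[ia], ids[ib])))] = r
    return edges
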