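"""Semi-global (end-gap-free) nucleotide alignment with affine gaps.

This is the reproducible replacement for a BLAST-style similarity search
when matching near-full-length 16S sequences against amplicon
representatives: an explicit overlap alignment whose identity and overlap
length are compared against fixed thresholds.

Scoring: match +1, mismatch -1, and a gap of length L costs
``gap_open + gap_ext * L`` (so 2 + L under the defaults).  Leading and
trailing gaps in either sequence are free and excluded from the aligned
region.  ``N`` aligns like any base for scoring purposes but is always a
mismatch and never counts towards identity.

Tie-breaking is deterministic: among equal-score alignments the one with
fewer gap columns wins (a lexicographic secondary objective carried through
the recursion), then a diagonal step is preferred over a gap, then the
first end cell in scan order.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


MATCH = 1
MISMATCH = -1
GAP_OPEN = 2   # positive costs, subtracted
GAP_EXT = 1

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate("ACGTN"):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i

_NEG = np.int32(-(10**8))

# traceback states
_M, _X, _Y = 0, 1, 2


def encode(seq: str) -> np.ndarray:
    """Encode an A/C/G/T/N string to int8 codes (N = 4)."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = sorted({c for c in seq if _CODE[ord(c)] < 0})
        raise ValueError(f"sequence contains characters outside A/C/G/T/N: {bad}")
    return arr


@njit(cache=True)
def _semiglobal(a, b):  # pragma: no cover - numba-compiled hot path
    n = a.shape[0]
    m = b.shape[0]
    open_ext = GAP_OPEN + GAP_EXT
    big = np.int32(10**8)

    M = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    X = np.full((n + 1, m + 1), _NEG, dtype=np.int32)  # gap in b (consumes a)
    Y = np.full((n + 1, m + 1), _NEG, dtype=np.int32)  # gap in a (consumes b)
    # gap columns along the preferred optimal path per state
    GM = np.full((n + 1, m + 1), big, dtype=np.int32)
    GX = np.full((n + 1, m + 1), big, dtype=np.int32)
    GY = np.full((n + 1, m + 1), big, dtype=np.int32)
    ptrM = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrX = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrY = np.zeros((n + 1, m + 1), dtype=np.int8)

    # free leading gaps: an alignment may start at any border cell
    for i in range(n + 1):
        M[i, 0] = 0
        GM[i, 0] = 0
    for j in range(m + 1):
        M[0, j] = 0
        GM[0, j] = 0

    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = MATCH if (ai == b[j - 1] and ai < 4) else MISMATCH
            # M: diagonal; ties prefer fewer gaps, then M > X > Y
            best = M[i - 1, j - 1]
            gaps = GM[i - 1, j - 1]
            p = _M
            if X[i - 1, j - 1] > best or (
                X[i - 1, j - 1] == best and GX[i - 1, j - 1] < gaps
            ):
                best = X[i - 1, j - 1]
                gaps = GX[i - 1, j - 1]
                p = _X
            if Y[i - 1, j - 1] > best or (
                Y[i - 1, j - 1] == best and GY[i - 1, j - 1] < gaps
            ):
                best = Y[i - 1, j - 1]
                gaps = GY[i - 1, j - 1]
                p = _Y
            M[i, j] = best + s
            GM[i, j] = gaps
            ptrM[i, j] = p
            # X: gap in b, consumes a_i; open from M or extend X
            o = M[i - 1, j] - open_ext
            e = X[i - 1, j] - GAP_EXT
            if o > e or (o == e and GM[i - 1, j] <= GX[i - 1, j]):
                X[i, j] = o
                GX[i, j] = GM[i - 1, j] + 1
                ptrX[i, j] = _M
            else:
                X[i, j] = e
                GX[i, j] = GX[i - 1, j] + 1
                ptrX[i, j] = _X
            # Y: gap in a, consumes b_j
            o = M[i, j - 1] - open_ext
            e = Y[i, j - 1] - GAP_EXT
            if o > e or (o == e and GM[i, j - 1] <= GY[i, j - 1]):
                Y[i, j] = o
                GY[i, j] = GM[i, j - 1] + 1
                ptrY[i, j] = _M
            else:
                Y[i, j] = e
                GY[i, j] = GY[i, j - 1] + 1
                ptrY[i, j] = _Y

    # end cell: best (score, fewer gaps) over the last row then last column,
    # states preferred M > X > Y, first maximum in scan order kept
    best = _NEG
    bgaps = big
    ei = n
    ej = 0
    estate = _M
    for j in range(m + 1):
        for st in range(3):
            if st == _M:
                v, g = M[n, j], GM[n, j]
            elif st == _X:
                v, g = X[n, j], GX[n, j]
            else:
                v, g = Y[n, j], GY[n, j]
            if v > best or (v == best and g < bgaps):
                best, bgaps = v, g
                ei, ej, estate = n, j, st
    for i in range(n + 1):
        for st in range(3):
            if st == _M:
                v, g = M[i, m], GM[i, m]
            elif st == _X:
                v, g = X[i, m], GX[i, m]
            else:
                v, g = Y[i, m], GY[i, m]
            if v > best or (v == best and g < bgaps):
                best, bgaps = v, g
                ei, ej, estate = i, m, st

    # traceback to a border start cell (M-state, score 0)
    matches = 0
    columns = 0
    i, j, st = ei, ej, estate
    while not (st == _M and (i == 0 or j == 0)):
        if st == _M:
            p = ptrM[i, j]
            if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                matches += 1
            columns += 1
            i -= 1
            j -= 1
            if i == 0 or j == 0:
                break
            st = p
        elif st == _X:
            p = ptrX[i, j]
            columns += 1
            i -= 1
            st = p
        else:
            p = ptrY[i, j]
            columns += 1
            j -= 1
            st = p
    return best, matches, columns


def semiglobal_align(seq_a: str, seq_b: str) -> tuple[int, int, int]:
    """Align two sequences; return (score, matches, aligned_columns).

    Aligned columns exclude terminal gaps but include internal gap columns.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    score, matches, columns = _semiglobal(encode(seq_a), encode(seq_b))
    return int(score), int(matches), int(columns)
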