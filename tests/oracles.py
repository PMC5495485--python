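"""Independent brute-force oracles used to validate the implementations.

Each oracle deliberately uses a different algorithmic route than the code
under test (quadratic dynamic programming, exhaustive enumeration, or
all-positions scanning), so agreement is meaningful evidence of
correctness.
"""

import numpy as np

from thermoinv.seqio import reverse_complement
from thermoinv.history import apply_inversion


def lcs_bruteforce(a: str, b: str):
    """Longest common substring by quadratic diagonal dynamic programming.

    Returns ``(length, a_start, b_start)`` with ties broken by smallest
    ``a_start`` then smallest ``b_start``.  ``N`` never matches.
    """
    aa = np.frombuffer(a.replace("N", "!").encode(), dtype=np.uint8)
    bb = np.frombuffer(b.replace("N", "?").encode(), dtype=np.uint8)
    n, m = len(aa), len(bb)
    best = (0, 0, 0)
    for d in range(-(n - 1), m):
        if d >= 0:
            ai, bi, length = 0, d, min(n, m - d)
        else:
            ai, bi, length = -d, 0, min(n + d, m)
        eq = aa[ai : ai + length] == bb[bi : bi + length]
        run = 0
        for k in range(length):
            run = run + 1 if eq[k] else 0
            if run > best[0]:
                best = (run, ai + k - run + 1, bi + k - run + 1)
            elif run == best[0] and run > 0:
                cand = (run, ai + k - run + 1, bi + k - run + 1)
                if (cand[1], cand[2]) < (best[1], best[2]):
                    best = cand
    return best


def maximal_matches_bruteforce(s1: str, s2: str, min_len: int):
    """All maximal exact matches (both orientations of s2) via per-diagonal
    run detection.  Returns a set of (q_start, s_start, orient, length)
    with s coordinates on the forward strand of s2."""

    def runs(a, b):
        aa = np.frombuffer(a.encode(), dtype=np.uint8)
        bb = np.frombuffer(b.encode(), dtype=np.uint8)
        nn = aa == ord("N")
        n, m = len(aa), len(bb)
        out = []
        for d in range(-(n - 1), m):
            if d >= 0:
                ai, bi, length = 0, d, min(n, m - d)
            else:
                ai, bi, length = -d, 0, min(n + d, m)
            eq = (aa[ai : ai + length] == bb[bi : bi + length]) & ~nn[ai : ai + length]
            k = 0
            while k < length:
                if eq[k]:
                    j = k
                    while j < length and eq[j]:
                        j += 1
                    if j - k >= min_len:
                        out.append((ai + k, bi + k, j - k))
                    k = j
                else:
                    k += 1
        return out

    hits = set()
    for i, j, L in runs(s1, s2):
        hits.add((i, j, "+", L))
    s2r = reverse_complement(s2)
    m = len(s2)
    for i, j, L in runs(s1, s2r):
        hits.add((i, m - j - L, "-", L))
    return hits


def bruteforce_map(read: str, ref: str, circular: bool, max_mm: int):
    """All-positions ungapped aligner.

    Returns ``(status, best)`` where best is ``(mm, strand, pos)`` for a
    unique best placement within ``max_mm``; status is 'mapped',
    'ambiguous' or 'unmapped'.
    """
    L = len(read)
    ext = ref + (ref[: L - 1] if circular else "")
    n = len(ref)
    ref_arr = np.frombuffer(ext.encode(), dtype=np.uint8)
    win = np.lib.stride_tricks.sliding_window_view(ref_arr, L)
    limit = n if circular else n - L + 1
    hits = []
    for strand, seq in (("+", read), ("-", reverse_complement(read))):
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        mm = (win[:limit] != arr).sum(axis=1)
        for pos in np.nonzero(mm <= max_mm)[0]:
            hits.append((int(mm[pos]), strand, int(pos)))
    if not hits:
        return "unmapped", None
    hits.sort()
    if len(hits) > 1 and hits[1][0] == hits[0][0]:
        return "ambiguous", hits[0]
    return "mapped", hits[0]


def distance_by_enumeration(source, target, max_depth=3):
    """Minimal inversion count by exhaustive enumeration of all event
    sequences of length <= max_depth (breadth-first over products)."""
    if source == target:
        return 0
    n = len(source)
    moves = [(i, j) for i in range(n) for j in range(i, n)]
    frontier = {source}
    for depth in range(1, max_depth + 1):
        nxt = set()
        for p in frontier:
            for i, j in moves:
                q = apply_inversion(p, i, j)
                if q == target:
                    return depth
                nxt.add(q)
        frontier = nxt
    return None
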