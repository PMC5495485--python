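"""Stage 2 — sequence forensics at synteny breakpoints.

The recombination substrates flanking an inversion are pairs of paralogous
segments sharing a perfectly conserved core, in direct or inverted
orientation.  This module finds the maximal exactly-shared segment between
two flanks (longest common substring, suffix-automaton based, with a
quadratic oracle in the test suite), computes global percent identity of the
paralogous regions, localizes recombination crossovers between informative
mismatches, and characterizes all breakpoint junctions of a comparison by an
all-against-all shared-segment search.

Two different statistics are deliberately reported per repeat pair: the
exact shared-core length (perfect identity) and the global percent identity
of the aligned paralogous regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from Bio import Align

from .seqio import GenomeRecord, Interval, reverse_complement

__all__ = [
    "SharedSegment",
    "RepeatPair",
    "CrossoverCall",
    "longest_shared_segment",
    "percent_identity",
    "localize_crossover",
    "characterize_breakpoints",
    "cross_pair_shared",
]


@dataclass(frozen=True)
class SharedSegment:
    """Maximal exactly-shared segment between two flanks.

    ``b_start`` is in the original coordinates of sequence B; for inverted
    orientation the reported segment of B is the reverse complement of the
    segment of A.
    """

    length: int
    a_start: int
    b_start: int
    orientation: str  # 'direct' or 'inverted'


@dataclass(frozen=True)
class RepeatPair:
    a: Interval
    b: Interval
    orientation: str
    core_len: int
    identity_pct: float
    a_breakpoint: Optional[int] = None
    b_breakpoint: Optional[int] = None


@dataclass(frozen=True)
class CrossoverCall:
    status: str  # 'crossover' or 'no_crossover'
    interval: Optional[tuple] = None  # (l, r]: last A-informative, first B-informative
    left_informative: Optional[int] = None
    right_informative: Optional[int] = None
    matches_parent: Optional[str] = None  # for status 'no_crossover'


class MultipleCrossoverError(ValueError):
    """Recombinant switches parent more than once among informative sites."""


# ---------------------------------------------------------------------------
# longest common substring (suffix automaton)


def _sam_lcs_length(a: str, b: str) -> int:
    """Length of the longest common substring via a suffix automaton over a."""
    # state arrays: transition dict, suffix link, max length
    nxt = [{}]
    link = [-1]
    length = [0]
    last = 0
    for ch in a:
        cur = len(nxt)
        nxt.append({})
        link.append(0)
        length.append(length[last] + 1)
        p = last
        while p != -1 and ch not in nxt[p]:
            nxt[p][ch] = cur
            p = link[p]
        if p != -1:
            q = nxt[p][ch]
            if length[p] + 1 == length[q]:
                link[cur] = q
            else:
                clone = len(nxt)
                nxt.append(dict(nxt[q]))
                link.append(link[q])
                length.append(length[p] + 1)
                while p != -1 and nxt[p].get(ch) == q:
                    nxt[p][ch] = clone
                    p = link[p]
                link[q] = clone
                link[cur] = clone
        last = cur
    v = 0
    l = 0
    best = 0
    for ch in b:
        while v and ch not in nxt[v]:
            v = link[v]
            l = length[v]
        if ch in nxt[v]:
            v = nxt[v][ch]
            l += 1
        else:
            v = 0
            l = 0
        if l > best:
            best = l
    return best


def longest_shared_segment(
    seq_a: str, seq_b: str, orientation: str = "direct"
) -> SharedSegment:
    """Longest exactly-shared segment between two flanks.

    For ``orientation='inverted'`` sequence B is reverse-complemented before
    the search and the reported ``b_start`` is mapped back to the original B
    coordinates.  ``N`` never matches (not even another ``N``).  Ties are
    broken by smallest position in A, then smallest position in the oriented
    frame of B.  Returns length 0 when nothing is shared.
    """
    if orientation not in ("direct", "inverted"):
        raise ValueError(f"bad orientation {orientation!r}")
    if not seq_a or not seq_b:
        raise ValueError("both sequences must be non-empty")
    a = seq_a.upper()
    b_oriented = seq_b.upper()
    if orientation == "inverted":
        b_oriented = reverse_complement(b_oriented)
    # N must never match: map N to distinct sentinels on the two sides
    a_m = a.replace("N", "!")
    b_m = b_oriented.replace("N", "?")
    best = _sam_lcs_length(a_m, b_m)
    if best == 0:
        return SharedSegment(0, 0, 0, orientation)
    for a_start in range(len(a_m) - best + 1):
        sub = a_m[a_start : a_start + best]
        if "!" in sub:
            continue
        j = b_m.find(sub)
        if j >= 0:
            if orientation == "inverted":
                b_start = len(seq_b) - j - best
            else:
                b_start = j
            return SharedSegment(best, a_start, b_start, orientation)
    raise AssertionError("automaton length not realised")  # pragma: no cover


# ---------------------------------------------------------------------------
# percent identity


_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-1,
)


def percent_identity(seq_a: str, seq_b: str) -> float:
    """Global percent identity of two sequences, rounded to 0.1.

    Scoring: match +1, mismatch -1, first gap column -2, each further gap
    column -1 (Needleman-Wunsch via Biopython's PairwiseAligner).  Identity
    is matched columns over total alignment columns x 100.
    """
    if not seq_a or not seq_b:
        raise ValueError("both sequences must be non-empty")
    a, b = seq_a.upper(), seq_b.upper()
    if a == b:
        return 100.0
    aln = _aligner.align(a, b)[0]
    matches = 0
    for (a0, a1), (b0, b1) in zip(*(seg.tolist() for seg in aln.aligned)):
        matches += sum(1 for x, y in zip(a[a0:a1], b[b0:b1]) if x == y)
    return round(matches / aln.length * 100, 1)


# ---------------------------------------------------------------------------
# crossover localization


def localize_crossover(
    parent_a: str, parent_b: str, recombinant: str
) -> CrossoverCall:
    """Localize a single crossover between two gap-free aligned parents.

    Informative positions are the columns where the parents differ.  The
    call is the maximal interval ``(l, r]`` such that the recombinant
    matches parent A at every informative position <= ``l`` and parent B at
    every informative position >= ``r``.  A recombinant identical to one
    parent at all informative positions yields status ``no_crossover``;
    more than one switch raises :class:`MultipleCrossoverError`.
    """
    a, b, r = parent_a.upper(), parent_b.upper(), recombinant.upper()
    if not (len(a) == len(b) == len(r)):
        raise ValueError(
            "parents and recombinant must be equal-length (gap-free frame)"
        )
    informative = [i for i in range(len(a)) if a[i] != b[i]]
    labels = []
    for i in informative:
        if r[i] == a[i]:
            labels.append("A")
        elif r[i] == b[i]:
            labels.append("B")
        else:
            raise ValueError(
                f"recombinant matches neither parent at informative position {i}"
            )
    if not informative or all(x == "A" for x in labels):
        return CrossoverCall(status="no_crossover", matches_parent="A")
    if all(x == "B" for x in labels):
        return CrossoverCall(status="no_crossover", matches_parent="B")
    switches = sum(1 for x, y in zip(labels, labels[1:]) if x != y)
    if switches > 1 or labels[0] != "A":
        raise MultipleCrossoverError(
            f"{switches} switches among informative positions; "
            "single A->B crossover expected"
        )
    k = labels.index("B")
    return CrossoverCall(
        status="crossover",
        interval=(informative[k - 1], informative[k]),
        left_informative=informative[k - 1],
        right_informative=informative[k],
    )


# ---------------------------------------------------------------------------
# breakpoint characterization


def _junction_regions(genome: GenomeRecord, breakpoints, window: int):
    """Clipped windows around each breakpoint junction midpoint."""
    mids = sorted((bp.q_gap.mid, bp) for bp in breakpoints)
    regions = []
    n = len(genome.seq)
    for idx, (mid, bp) in enumerate(mids):
        lo = mid - window
        hi = mid + window
        if idx > 0:
            lo = max(lo, (mids[idx - 1][0] + mid) // 2)
        if idx + 1 < len(mids):
            hi = min(hi, (mid + mids[idx + 1][0]) // 2)
        lo = max(0, lo)
        hi = min(n, hi)
        if hi - lo < 50:
            continue
        regions.append((bp, Interval(lo, hi)))
    return regions


def characterize_breakpoints(
    genome: GenomeRecord,
    breakpoints,
    window: int = 2_000,
    min_core: int = 50,
    flank_pad: int = 100,
) -> list[RepeatPair]:
    """Find the repeat substrates shared by pairs of breakpoint junctions.

    Extracts a window around every breakpoint junction on the reference
    genome (clipped so neighbouring windows never overlap) and searches all
    junction pairs for their maximal exactly-shared segment in both
    orientations.  Pairs whose best core reaches ``min_core`` are reported
    with the core orientation and a global percent identity computed over
    the core padded by ``flank_pad`` bp on each side.

    Junctions are paired all-against-all rather than as the two ends of a
    minus run because nested or overlapping inversion histories pair
    junctions across different runs.
    """
    if window < 200:
        raise ValueError("window must be >= 200")
    regions = _junction_regions(genome, breakpoints, window)
    pairs: list[RepeatPair] = []
    for i in range(len(regions)):
        bp_i, iv_i = regions[i]
        seq_i = genome.fetch(iv_i)
        for j in range(i + 1, len(regions)):
            bp_j, iv_j = regions[j]
            seq_j = genome.fetch(iv_j)
            best = None
            for orient in ("direct", "inverted"):
                seg = longest_shared_segment(seq_i, seq_j, orient)
                if best is None or seg.length > best.length:
                    best = seg
            if best.length < min_core:
                continue
            a_iv = Interval(iv_i.start + best.a_start, iv_i.start + best.a_start + best.length)
            b_iv = Interval(iv_j.start + best.b_start, iv_j.start + best.b_start + best.length)
            pad_a = Interval(
                max(0, a_iv.start - flank_pad), min(len(genome.seq), a_iv.end + flank_pad)
            )
            pad_b = Interval(
                max(0, b_iv.start - flank_pad), min(len(genome.seq), b_iv.end + flank_pad)
            )
            sb = genome.fetch(pad_b)
            if best.orientation == "inverted":
                sb = reverse_complement(sb)
            ident = percent_identity(genome.fetch(pad_a), sb)
            pairs.append(
                RepeatPair(
                    a=a_iv,
                    b=b_iv,
                    orientation=best.orientation,
                    core_len=best.length,
                    identity_pct=ident,
                    a_breakpoint=bp_i.left_block,
                    b_breakpoint=bp_j.left_block,
                )
            )
    pairs.sort(key=lambda p: (p.a.start, p.b.start))
    return pairs


def cross_pair_shared(
    genome: GenomeRecord, pairs: list[RepeatPair], min_len: int = 20
) -> list[tuple]:
    """Exact segments >= ``min_len`` shared between cores of DIFFERENT pairs.

    The paper-scale expectation for independent substrate pairs is an empty
    list; any hit is reported as (pair_i, pair_j, orientation, length).
    """
    hits = []
    cores = [genome.fetch(p.a) for p in pairs]
    for i in range(len(pairs)):
        for j in range(i + 1, len(pairs)):
            for orient in ("direct", "inverted"):
                seg = longest_shared_segment(cores[i], cores[j], orient)
                if seg.length >= min_len:
                    hits.append((i, j, orient, seg.length))
    return hits
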