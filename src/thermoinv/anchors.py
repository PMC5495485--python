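"""Stage 1 — dotplot anchors, synteny blocks and the signed block permutation.

Two closely related genomes are compared by exact-match anchoring (MUM-style):
every maximal exact match of at least ``min_len`` bp between genome 1 and
either strand of genome 2 is an anchor.  Co-oriented anchors are chained
greedily into synteny blocks; the block order and orientation along genome 2,
expressed in genome-1 block ids, is a signed permutation whose non-conserved
adjacencies are the synteny breakpoints and whose maximal runs of minus
blocks are the inversion segments.

Divergent or rearranged sequence simply falls into the breakpoint gaps; the
repeat substrates that sit in those gaps are characterised by
:mod:`thermoinv.forensics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .seqio import GenomeRecord, Interval, reverse_complement, rotate_circular

__all__ = [
    "Anchor",
    "SyntenyBlock",
    "Breakpoint",
    "InversionSegment",
    "PermutationResult",
    "ComparisonResult",
    "find_anchors",
    "chain_to_blocks",
    "blocks_to_permutation",
    "estimate_rotation",
    "compare_genomes",
]


@dataclass(frozen=True)
class Anchor:
    """A maximal exact match; ``q`` is always on the + strand of genome 1."""

    q: Interval
    s: Interval
    orientation: str  # '+' or '-'
    length: int


@dataclass(frozen=True)
class SyntenyBlock:
    id: int
    q: Interval
    s: Interval
    orientation: str
    n_anchors: int
    anchor_bp: int


@dataclass(frozen=True)
class Breakpoint:
    """A non-conserved adjacency between genome-1-adjacent blocks.

    ``q_gap`` is the junction interval between the two blocks on genome 1
    (zero or near-zero length when the flanking blocks meet or slightly
    overlap at a shared repeat).  ``s_gap`` is reported only when the same
    two blocks are also adjacent on genome 2; for inversion junctions the
    genome-2 neighbours differ and ``s_gap`` is ``None``.
    """

    left_block: int
    right_block: int
    q_gap: Interval
    s_gap: Optional[Interval]


@dataclass(frozen=True)
class InversionSegment:
    blocks: tuple
    q_span: Interval
    s_span: Interval


@dataclass(frozen=True)
class PermutationResult:
    permutation: tuple  # signed block ids in genome-2 order
    breakpoints: tuple
    inversions: tuple


@dataclass(frozen=True)
class ComparisonResult:
    anchors: tuple
    blocks: tuple
    permutation: tuple
    breakpoints: tuple
    inversions: tuple
    rotation: int  # rotation applied to genome 2 before comparison


# ---------------------------------------------------------------------------
# maximal exact matches


def _kmer_index(s: str, k: int) -> dict:
    idx: dict = {}
    for i in range(len(s) - k + 1):
        km = s[i : i + k]
        if "N" in km:
            continue
        idx.setdefault(km, []).append(i)
    return idx


def _extend_right(s1, s2, i, j, n1, n2, step=4096):
    while True:
        m = min(step, n1 - i, n2 - j)
        if m <= 0:
            return i, j
        a = s1[i : i + m]
        if a == s2[j : j + m] and "N" not in a:
            i += m
            j += m
            continue
        for t in range(m):
            c = s1[i + t]
            if c == "N" or c != s2[j + t]:
                return i + t, j + t
        i += m  # chunk matched but contained no mismatch (unreachable)
        j += m


def _extend_left(s1, s2, i, j, step=4096):
    while True:
        m = min(step, i, j)
        if m <= 0:
            return i, j
        a = s1[i - m : i]
        if a == s2[j - m : j] and "N" not in a:
            i -= m
            j -= m
            continue
        for t in range(1, m + 1):
            c = s1[i - t]
            if c == "N" or c != s2[j - t]:
                return i - t + 1, j - t + 1
        i -= m
        j -= m


def _maximal_matches(s1: str, s2: str, k: int, min_len: int, max_occ: int):
    """All maximal exact matches of length >= min_len whose seeds are not
    masked (k-mer occurring more than ``max_occ`` times in either sequence).
    """
    idx1 = _kmer_index(s1, k)
    counts2: dict = {}
    for j in range(len(s2) - k + 1):
        km = s2[j : j + k]
        if km in idx1:
            counts2[km] = counts2.get(km, 0) + 1
    covered: dict = {}
    out = []
    n1, n2 = len(s1), len(s2)
    for j in range(n2 - k + 1):
        km = s2[j : j + k]
        hits = idx1.get(km)
        if not hits:
            continue
        if len(hits) > max_occ or counts2[km] > max_occ:
            continue
        for i in hits:
            d = j - i
            if covered.get(d, -1) >= j:
                continue
            li, lj = _extend_left(s1, s2, i, j)
            ri, rj = _extend_right(s1, s2, i + k, j + k, n1, n2)
            covered[d] = rj - k
            if ri - li >= min_len:
                out.append((li, lj, ri - li))
    return out


def find_anchors(
    g1: GenomeRecord,
    g2: GenomeRecord,
    k: int = 16,
    min_len: int = 24,
    max_kmer_occ: int = 10,
) -> list[Anchor]:
    """Maximal exact matches between ``g1`` and both strands of ``g2``.

    Seeding masks k-mers occurring more than ``max_kmer_occ`` times in either
    genome (repeat families are recovered later at the breakpoints); matches
    every k-mer of which is masked are therefore not reported.
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    if min_len < k:
        raise ValueError("min_len must be >= k")
    if k > len(g1.seq) or k > len(g2.seq):
        raise ValueError("k larger than a genome")
    anchors = []
    for li, lj, L in _maximal_matches(g1.seq, g2.seq, k, min_len, max_kmer_occ):
        anchors.append(
            Anchor(Interval(li, li + L), Interval(lj, lj + L, "+"), "+", L)
        )
    s2r = reverse_complement(g2.seq)
    n2 = len(s2r)
    for li, lj, L in _maximal_matches(g1.seq, s2r, k, min_len, max_kmer_occ):
        anchors.append(
            Anchor(
                Interval(li, li + L),
                Interval(n2 - lj - L, n2 - lj, "-"),
                "-",
                L,
            )
        )
    anchors.sort(key=lambda a: (a.q.start, a.q.end, a.s.start, a.orientation))
    return anchors


# ---------------------------------------------------------------------------
# chaining


def chain_to_blocks(
    anchors: list[Anchor],
    max_gap: int = 20_000,
    min_block: int = 5_000,
    overlap_slack: int = 1_000,
    diag_slack: int = 32,
) -> list[SyntenyBlock]:
    """Greedy single-linkage chaining of co-oriented anchors into blocks.

    Consecutive anchors join a chain when both the genome-1 gap and the
    orientation-consistent genome-2 gap are within ``[-overlap_slack,
    max_gap]`` and the diagonal offset is consistent with the chain's
    orientation to within ``diag_slack`` bp (conspecific genomes differ by
    substitutions, not indels, inside a block).  Chains spanning less than
    ``min_block`` bp on genome 1 are discarded; surviving blocks are
    renumbered 1..n along genome 1.  Deterministic: anchors are processed
    left to right and attach to the oldest (leftmost) compatible chain.
    """
    chains: list[dict] = []
    for a in sorted(anchors, key=lambda a: (a.q.start, a.q.end, a.s.start)):
        # diagonal invariant: s - q for '+', s_end + q_start for '-'
        diag = a.s.start - a.q.start if a.orientation == "+" else a.s.end + a.q.start
        target = None
        for c in chains:
            if c["orient"] != a.orientation:
                continue
            if abs(diag - c["diag"]) > diag_slack:
                continue
            qgap = a.q.start - c["q_end"]
            if not -overlap_slack <= qgap <= max_gap:
                continue
            if a.orientation == "+":
                sgap = a.s.start - c["s_end"]
            else:
                sgap = c["s_start"] - a.s.end
            if not -overlap_slack <= sgap <= max_gap:
                continue
            target = c
            break
        if target is None:
            chains.append(
                dict(
                    orient=a.orientation,
                    diag=diag,
                    q_start=a.q.start,
                    q_end=a.q.end,
                    s_start=a.s.start,
                    s_end=a.s.end,
                    n=1,
                    bp=a.length,
                )
            )
        else:
            target["q_end"] = max(target["q_end"], a.q.end)
            target["s_start"] = min(target["s_start"], a.s.start)
            target["s_end"] = max(target["s_end"], a.s.end)
            target["n"] += 1
            target["bp"] += a.length
    kept = [c for c in chains if c["q_end"] - c["q_start"] >= min_block]
    kept.sort(key=lambda c: c["q_start"])
    return [
        SyntenyBlock(
            id=i + 1,
            q=Interval(c["q_start"], c["q_end"]),
            s=Interval(c["s_start"], c["s_end"], c["orient"]),
            orientation=c["orient"],
            n_anchors=c["n"],
            anchor_bp=c["bp"],
        )
        for i, c in enumerate(kept)
    ]


# ---------------------------------------------------------------------------
# permutation, breakpoints, inversion segments


def _check_disjoint(ivs, slack, axis):
    ivs = sorted(ivs, key=lambda t: t[0])
    for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
        if e0 - s1 > slack:
            raise ValueError(
                f"blocks overlap by {e0 - s1} bp on {axis} (> slack {slack}); "
                "re-chain with a larger min_block"
            )


def blocks_to_permutation(
    blocks: list[SyntenyBlock], overlap_slack: int = 1_000
) -> PermutationResult:
    """Signed permutation, breakpoints and inversion segments of a block set.

    The permutation lists blocks in genome-2 order with signs encoding
    orientation.  A genome-1 adjacency (i, i+1) is conserved iff the signed
    permutation contains the signed adjacency (u, u+1); all other genome-1
    adjacencies are breakpoints.  Inversion segments are maximal runs of
    minus blocks in genome-2 order, reported with their genome-1 (q) and
    genome-2 (s) spans.
    """
    if not blocks:
        return PermutationResult((), (), ())
    _check_disjoint([(b.q.start, b.q.end) for b in blocks], overlap_slack, "genome 1")
    _check_disjoint([(b.s.start, b.s.end) for b in blocks], overlap_slack, "genome 2")

    by_q = sorted(blocks, key=lambda b: b.q.start)
    by_s = sorted(blocks, key=lambda b: b.s.start)
    block_of = {b.id: b for b in blocks}
    perm = tuple(b.id if b.orientation == "+" else -b.id for b in by_s)

    conserved = set()
    for u, v in zip(perm, perm[1:]):
        if v - u == 1:  # signed adjacency (u, u+1) is conserved
            conserved.add((min(abs(u), abs(v)), max(abs(u), abs(v))))
    s_neighbours = {
        (min(abs(u), abs(v)), max(abs(u), abs(v))): (abs(u), abs(v))
        for u, v in zip(perm, perm[1:])
    }

    breakpoints = []
    for left, right in zip(by_q, by_q[1:]):
        key = (left.id, right.id)
        if key in conserved:
            continue
        lo, hi = sorted((left.q.end, right.q.start))
        s_gap = None
        if key in s_neighbours:
            u, v = s_neighbours[key]
            bu, bv = block_of[u], block_of[v]
            first, second = (bu, bv) if bu.s.start <= bv.s.start else (bv, bu)
            slo, shi = sorted((first.s.end, second.s.start))
            s_gap = Interval(slo, shi)
        breakpoints.append(Breakpoint(left.id, right.id, Interval(lo, hi), s_gap))

    inversions = []
    run: list[SyntenyBlock] = []
    for b in list(by_s) + [None]:
        if b is not None and b.orientation == "-":
            run.append(b)
        elif run:
            inversions.append(
                InversionSegment(
                    blocks=tuple(x.id for x in run),
                    q_span=Interval(
                        min(x.q.start for x in run), max(x.q.end for x in run)
                    ),
                    s_span=Interval(
                        min(x.s.start for x in run), max(x.s.end for x in run)
                    ),
                )
            )
            run = []
    return PermutationResult(perm, tuple(breakpoints), tuple(inversions))


# ---------------------------------------------------------------------------
# circular handling and the full stage-1 pipeline


def estimate_rotation(
    g1: GenomeRecord, g2: GenomeRecord, k: int = 16, probes: int = 64
) -> int:
    """Estimate the rotation of ``g2`` relative to ``g1`` by diagonal voting.

    Probe k-mers sampled evenly along genome 1 that occur exactly once on
    the forward strand of genome 2 vote for the shift ``(j - i) mod
    len(g2)``.  Preference is given to the shift agreed by probes flanking
    genome 1's origin (position 0) — the comparison convention is to center
    both genomes on the origin, and rearranged interior segments (e.g.
    doubly inverted, hence forward but displaced regions) would otherwise
    be able to outvote the true alignment.  Falls back to the global
    majority (0 when fewer than three probes agree on anything).
    """
    n1, n2 = len(g1.seq), len(g2.seq)
    votes: dict = {}
    near_votes: dict = {}
    step = max(1, n1 // probes)
    edge = max(2 * step, n1 // 20)
    for i in range(0, n1 - k + 1, step):
        km = g1.seq[i : i + k]
        if "N" in km:
            continue
        j = g2.seq.find(km)
        if j < 0 or g2.seq.find(km, j + 1) >= 0:
            continue
        shift = (j - i) % n2
        votes[shift] = votes.get(shift, 0) + 1
        if i < edge or i > n1 - edge:
            near_votes[shift] = near_votes.get(shift, 0) + 1
    if near_votes:
        shift, count = max(near_votes.items(), key=lambda kv: (kv[1], -kv[0]))
        if count >= 2:
            return shift
    if not votes:
        return 0
    shift, count = max(votes.items(), key=lambda kv: (kv[1], -kv[0]))
    return shift if count >= 3 else 0


def compare_genomes(
    g1: GenomeRecord,
    g2: GenomeRecord,
    k: int = 16,
    min_len: int = 24,
    max_gap: int = 20_000,
    min_block: int = 5_000,
    max_kmer_occ: int = 10,
    overlap_slack: int = 1_000,
) -> ComparisonResult:
    """Full stage-1 comparison: anchors -> blocks -> permutation.

    When both genomes are circular, genome 2 is first rotated onto genome 1's
    origin (majority diagonal vote), so the comparison itself is linear and
    the result is invariant under rotation of genome 2.
    """
    rotation = 0
    if g1.circular and g2.circular:
        rotation = estimate_rotation(g1, g2, k=k)
        if rotation:
            g2 = rotate_circular(g2, rotation)
    anchors = find_anchors(g1, g2, k=k, min_len=min_len, max_kmer_occ=max_kmer_occ)
    blocks = chain_to_blocks(
        anchors, max_gap=max_gap, min_block=min_block, overlap_slack=overlap_slack
    )
    res = blocks_to_permutation(blocks, overlap_slack=overlap_slack)
    return ComparisonResult(
        anchors=tuple(anchors),
        blocks=tuple(blocks),
        permutation=res.permutation,
        breakpoints=res.breakpoints,
        inversions=res.inversions,
        rotation=rotation,
    )


# ---------------------------------------------------------------------------
# tabular output (0-based, half-open coordinates)


def anchors_to_frame(anchors) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                q_start=a.q.start,
                q_end=a.q.end,
                s_start=a.s.start,
                s_end=a.s.end,
                orient=a.orientation,
                len=a.length,
            )
            for a in anchors
        ]
    )


def blocks_to_frame(blocks) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                id=b.id,
                q_start=b.q.start,
                q_end=b.q.end,
                s_start=b.s.start,
                s_end=b.s.end,
                orient=b.orientation,
                n_anchors=b.n_anchors,
                anchor_bp=b.anchor_bp,
            )
            for b in blocks
        ]
    )


def breakpoints_to_frame(breakpoints) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                left_block=bp.left_block,
                right_block=bp.right_block,
                q_gap_start=bp.q_gap.start,
                q_gap_end=bp.q_gap.end,
                s_gap_start=bp.s_gap.start if bp.s_gap else pd.NA,
                s_gap_end=bp.s_gap.end if bp.s_gap else pd.NA,
            )
            for bp in breakpoints
        ]
    )
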