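"""Stage 5 — read-level genotyping of inversion breakpoints.

Mirrors the metagenome-style procedure used to follow rearranged genomes in
a serially passaged population: reads are mapped to the ancestral reference
(exact seed + ungapped extension, unique best placement), the unmapped pool
is re-mapped to the derived reference, bases are enumerated at
breakpoint-diagnostic positions, and the inversion-allele fraction per
breakpoint is estimated with a 95% Wilson interval.  Plasmid prevalence is
estimated as the depth over a target region divided by the depth over the
unmasked chromosome (copies per chromosome).

An inversion rewrites sequence in place, so the ancestral and derived
references share one coordinate frame.  Because recombination inside a
perfectly conserved core regenerates both junctions exactly, every
junction-local sequence occurs in both alleles (at mirrored positions):
the only reads that discriminate the alleles are those spanning the whole
conserved core plus a flank anchor on both sides.  Classification
therefore counts bases at the diagnostic positions only for reads whose
alignment covers the full core-spanning window of a breakpoint; read
length must exceed core length + 2 x anchor for a breakpoint to be
genotypeable at all (a physical limit of short-read genotyping of
repeat-bounded inversions, not an implementation choice).  The mapper is
bespoke and ungapped so the whole procedure is self-contained and
desk-testable; externally produced SAM alignments can be imported instead.

Duplicate reads are not collapsed; ambiguous (multi-mapping) reads never
contribute to diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .seqio import GenomeRecord, Interval, reverse_complement

__all__ = [
    "SiteDiagnostic",
    "MixtureEstimate",
    "DepthEstimate",
    "map_reads",
    "two_pass_assign",
    "design_diagnostics",
    "classify_breakpoint_reads",
    "depth_ratio",
    "read_alignments_sam",
]

ALN_COLUMNS = ["read", "ref", "pos", "strand", "mismatches", "status", "aligned_seq"]


@dataclass(frozen=True)
class SiteDiagnostic:
    """Diagnostic positions for one breakpoint junction.

    ``core`` is the conserved-core interval at the junction's repeat copy
    (shared coordinate frame); ``positions`` are two nearby reference
    coordinates on the junction's divergent side at which the ancestral
    and derived references carry different bases (``anc_bases`` /
    ``der_bases``); ``span`` is the window an alignment must fully cover
    to be informative (core + anchors + the diagnostic positions).
    """

    breakpoint_id: int
    core: tuple
    positions: tuple
    anc_bases: tuple
    der_bases: tuple
    span: tuple


@dataclass(frozen=True)
class MixtureEstimate:
    breakpoint_id: int
    n_ancestral: int
    n_derived: int
    n_other: int
    derived_fraction: Optional[float]
    ci95: Optional[tuple]

    @property
    def n_informative(self) -> int:
        return self.n_ancestral + self.n_derived


@dataclass(frozen=True)
class DepthEstimate:
    target_depth: float
    baseline_depth: float
    ratio: float


# ---------------------------------------------------------------------------
# mapping


class _RefIndex:
    def __init__(self, ref: GenomeRecord, seed_k: int, max_read_len: int = 512):
        self.ref = ref
        self.k = seed_k
        self.n = len(ref.seq)
        pad = max_read_len if ref.circular else 0
        self.ext = ref.seq + ref.seq[:pad]
        self.index: dict = {}
        for i in range(self.n):
            km = self.ext[i : i + seed_k]
            if len(km) < seed_k or "N" in km:
                continue
            self.index.setdefault(km, []).append(i)


def _mismatches(ext: str, pos: int, read: str, cap: int) -> int:
    seg = ext[pos : pos + len(read)]
    if seg == read:
        return 0
    mm = 0
    for a, b in zip(seg, read):
        if a != b:
            mm += 1
            if mm > cap:
                return mm
    return mm


def _candidates(idx: _RefIndex, read: str):
    k = idx.k
    cands = set()
    offsets = list(range(0, len(read) - k + 1, k))
    if offsets and offsets[-1] != len(read) - k:
        offsets.append(len(read) - k)
    for off in offsets:
        for h in idx.index.get(read[off : off + k], ()):
            p = h - off
            if idx.ref.circular:
                cands.add(p % idx.n)
            elif 0 <= p <= idx.n - len(read):
                cands.add(p)
    return cands


def map_reads(
    reads,
    ref: GenomeRecord,
    seed_k: int = 21,
    max_mismatch: int = 3,
) -> pd.DataFrame:
    """Map reads to a reference by exact seeding and ungapped extension.

    A read is placed if it has a unique best position (over both strands)
    with at most ``max_mismatch`` mismatches; ties are ``ambiguous``,
    everything else ``unmapped``.  Deterministic.  ``reads`` is an iterable
    of ``(name, seq[, qual])`` tuples.

    Returns a DataFrame with columns read, ref, pos, strand, mismatches,
    status and aligned_seq (the read in reference orientation).
    """
    idx = _RefIndex(ref, seed_k)
    rows = []
    for item in reads:
        name, seq = item[0], item[1].upper()
        if len(seq) < 2 * seed_k:
            rows.append((name, ref.id, -1, ".", -1, "unmapped", ""))
            continue
        best = None  # (mm, strand_order, pos, oriented_seq)
        n_best = 0
        for strand, oriented in (("+", seq), ("-", reverse_complement(seq))):
            for p in _candidates(idx, oriented):
                mm = _mismatches(idx.ext, p, oriented, max_mismatch)
                if mm > max_mismatch:
                    continue
                key = (mm, strand, p)
                if best is None or key[0] < best[0][0]:
                    best = (key, oriented)
                    n_best = 1
                elif key[0] == best[0][0] and (strand, p) != best[0][1:]:
                    n_best += 1
        if best is None:
            rows.append((name, ref.id, -1, ".", -1, "unmapped", ""))
        elif n_best > 1:
            rows.append((name, ref.id, -1, ".", best[0][0], "ambiguous", ""))
        else:
            (mm, strand, p), oriented = best
            rows.append((name, ref.id, p, strand, mm, "mapped", oriented))
    return pd.DataFrame(rows, columns=ALN_COLUMNS)


def two_pass_assign(
    reads,
    ancestral: GenomeRecord,
    derived: GenomeRecord,
    seed_k: int = 21,
    max_mismatch: int = 3,
) -> dict:
    """Two-pass assignment: map to the ancestral reference, then re-map the
    unmapped pool to the derived reference.

    Returns a dict with the two alignment tables (``pass1``, ``pass2``) and
    a ``summary`` of partition sizes; mapped + ambiguous + unmapped always
    equals the read count in each pass.
    """
    reads = list(reads)
    pass1 = map_reads(reads, ancestral, seed_k=seed_k, max_mismatch=max_mismatch)
    unmapped_names = set(pass1.loc[pass1.status == "unmapped", "read"])
    pool = [r for r in reads if r[0] in unmapped_names]
    pass2 = map_reads(pool, derived, seed_k=seed_k, max_mismatch=max_mismatch)
    summary = dict(
        total=len(reads),
        pass1_mapped=int((pass1.status == "mapped").sum()),
        pass1_ambiguous=int((pass1.status == "ambiguous").sum()),
        pass1_unmapped=int((pass1.status == "unmapped").sum()),
        pass2_mapped=int((pass2.status == "mapped").sum()),
        pass2_ambiguous=int((pass2.status == "ambiguous").sum()),
        pass2_unmapped=int((pass2.status == "unmapped").sum()),
    )
    return dict(pass1=pass1, pass2=pass2, summary=summary)


# ---------------------------------------------------------------------------
# diagnostics


def design_diagnostics(
    ancestral: GenomeRecord,
    derived: GenomeRecord,
    cores,
    n_positions: int = 2,
    margin: int = 40,
    anchor: int = 10,
) -> list[SiteDiagnostic]:
    """Choose diagnostic positions next to each breakpoint repeat core.

    ``cores`` lists the conserved-core intervals ``(start, end)`` of the
    breakpoint repeat copies in the shared coordinate frame.  For each
    core, the junction's divergent side is located and the nearest
    ``n_positions`` positions within ``margin`` bp at which the two
    references differ are selected; the informative span is the core
    padded by ``anchor`` bp on the conserved side and extended over the
    chosen positions on the divergent side.  Cores without enough
    discriminating positions are skipped.
    """
    if len(ancestral.seq) != len(derived.seq):
        raise ValueError("references must share one coordinate frame")
    out = []
    n = len(ancestral.seq)
    for bp_id, (cs, ce) in enumerate(cores):
        right = [
            x
            for x in range(ce, min(n, ce + margin))
            if ancestral.seq[x] != derived.seq[x]
        ]
        left = [
            x
            for x in range(cs - 1, max(-1, cs - margin - 1), -1)
            if ancestral.seq[x] != derived.seq[x]
        ]
        use_right = bool(right) and (
            not left or (right[0] - ce) <= (cs - 1 - left[0])
        )
        side = right if use_right else left
        if len(side) < n_positions:
            continue
        pos = tuple(sorted(side[:n_positions]))
        if use_right:
            span = (cs - anchor, pos[-1] + 1)
        else:
            span = (pos[0], ce + anchor)
        out.append(
            SiteDiagnostic(
                breakpoint_id=bp_id,
                core=(cs, ce),
                positions=pos,
                anc_bases=tuple(ancestral.seq[x] for x in pos),
                der_bases=tuple(derived.seq[x] for x in pos),
                span=span,
            )
        )
    return out


def _covers(pos: int, read_len: int, x: int, n: int, circular: bool) -> bool:
    if pos <= x < pos + read_len:
        return True
    return circular and pos <= x + n < pos + read_len


def classify_breakpoint_reads(
    alignments: pd.DataFrame,
    diagnostics,
    ref_len: int,
    circular: bool = True,
) -> list[MixtureEstimate]:
    """Count ancestral vs derived bases at diagnostic positions.

    Only uniquely mapped reads whose alignment fully covers a
    breakpoint's informative span (conserved core + anchor + diagnostic
    positions) are counted — any shorter overlap is present identically
    in both alleles and carries no information.  Bases matching neither
    expectation are excluded from the denominator but reported in
    ``n_other``.  Per breakpoint the two positions are pooled (each
    spanning read contributes a base at each position) and the derived
    fraction is given with a 95% Wilson interval; an uncovered breakpoint
    yields an explicit NA (``derived_fraction=None``).
    """
    mapped = alignments[alignments.status == "mapped"]
    pos_arr = mapped["pos"].to_numpy()
    seqs = mapped["aligned_seq"].to_numpy()
    out = []
    for diag in diagnostics:
        n_anc = n_der = n_other = 0
        lo, hi = diag.span
        for p, s in zip(pos_arr, seqs):
            rl = len(s)
            if not (
                _covers(p, rl, lo % ref_len, ref_len, circular)
                and _covers(p, rl, (hi - 1) % ref_len, ref_len, circular)
            ):
                continue
            for x, ab, db in zip(diag.positions, diag.anc_bases, diag.der_bases):
                off = x - p if x >= p else x + ref_len - p
                base = s[off]
                if base == ab:
                    n_anc += 1
                elif base == db:
                    n_der += 1
                else:
                    n_other += 1
        n_inf = n_anc + n_der
        if n_inf == 0:
            out.append(MixtureEstimate(diag.breakpoint_id, 0, 0, n_other, None, None))
        else:
            frac = n_der / n_inf
            lo, hi = proportion_confint(n_der, n_inf, alpha=0.05, method="wilson")
            out.append(
                MixtureEstimate(
                    diag.breakpoint_id, n_anc, n_der, n_other, frac, (float(lo), float(hi))
                )
            )
    return out


# ---------------------------------------------------------------------------
# depth


def coverage_profile(alignments: pd.DataFrame, ref_len: int, circular: bool = True):
    """Per-base depth from uniquely mapped reads."""
    cov = np.zeros(ref_len + 1, dtype=np.int64)
    mapped = alignments[alignments.status == "mapped"]
    for p, s in zip(mapped["pos"].to_numpy(), mapped["aligned_seq"].to_numpy()):
        end = p + len(s)
        if end <= ref_len:
            cov[p] += 1
            cov[end] -= 1
        elif circular:
            cov[p] += 1
            cov[ref_len] -= 1
            cov[0] += 1
            cov[end - ref_len] -= 1
        else:
            cov[p] += 1
            cov[ref_len] -= 1
    return np.cumsum(cov[:-1])


def depth_ratio(
    alignments: pd.DataFrame,
    ref_len: int,
    target: Interval,
    mask=(),
    circular: bool = True,
) -> DepthEstimate:
    """Mean depth over ``target`` divided by mean depth over the unmasked
    reference (copies per chromosome).

    ``mask`` lists regions excluded from the chromosomal baseline, e.g. an
    integrated copy of the plasmid being quantified (and usually the
    target region itself when it is part of the same reference).  A zero
    baseline raises.
    """
    cov = coverage_profile(alignments, ref_len, circular)
    sel_target = np.zeros(ref_len, dtype=bool)
    sel_target[target.start : target.end] = True
    excluded = np.zeros(ref_len, dtype=bool)
    for iv in mask:
        excluded[iv.start : iv.end] = True
    baseline_sel = ~excluded
    if not baseline_sel.any():
        raise ValueError("mask covers the whole reference: no baseline")
    baseline = float(cov[baseline_sel].mean())
    if baseline == 0:
        raise ValueError("zero baseline depth")
    target_depth = float(cov[sel_target].mean())
    return DepthEstimate(target_depth, baseline, target_depth / baseline)


# ---------------------------------------------------------------------------
# optional SAM import


def read_alignments_sam(path: str, ref: GenomeRecord) -> pd.DataFrame:
    """Import externally produced alignments (SAM) into the alignment-table
    schema.  Requires pysam; only ungapped primary alignments are kept."""
    import pysam

    rows = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                rows.append((rec.query_name, ref.id, -1, ".", -1, "unmapped", ""))
                continue
            if rec.is_secondary or rec.is_supplementary:
                continue
            if any(op != 0 for op, _ in (rec.cigartuples or [])):
                continue  # gapped/clipped alignments are outside the contract
            mm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            rows.append(
                (
                    rec.query_name,
                    ref.id,
                    rec.reference_start,
                    "-" if rec.is_reverse else "+",
                    int(mm),
                    "mapped",
                    rec.query_sequence,
                )
            )
    return pd.DataFrame(rows, columns=ALN_COLUMNS)
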