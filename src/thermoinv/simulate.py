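"""Synthetic-data generators with known truth.

Everything the pipeline consumes can be generated here with a serialized
truth record: circular genomes carrying planted paralogous repeat pairs
(perfectly conserved cores of ~100-620 bp, direct or inverted), derived
genomes produced by a sampled chain of repeat-bounded inversions, short
single-end reads from a two-genome mixture with a per-base substitution
error rate, construct maps for the recombination engine, and a neutral
serial-passage population simulator.

Defaults emulate the natural study conditions this package targets: a
~200 kb genome region with four inverted pairs whose conserved cores are
104/176/284/620 bp, pairwise dissimilar (no shared 20-mer), 100x coverage
of 100 bp reads at 1% substitution error.  Planted cores are made
non-extendable (the bases flanking the second copy are forced to mismatch
the corresponding extension of the first copy), so "planted core length"
is exactly the maximal shared segment the forensics stage should report.

All generators are deterministic per seed; read names carry their truth
(source genome, position, strand) after a reserved ``|`` delimiter that
every consumer ignores.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .seqio import GenomeRecord, Interval, reverse_complement
from .history import (
    PlacedRepeat,
    invert_at_pair,
    remap_pairs_after_inversion,
)
from .recombine import AttSite, Feature, Molecule, digest

__all__ = [
    "TruthSet",
    "DEFAULT_PAIR_SPECS",
    "make_genome_with_repeats",
    "apply_truth_history",
    "simulate_reads",
    "build_construct_map",
    "simulate_passaging",
    "PassageTrajectory",
]

# Core sizes of the four naturally observed paralogous substrate pairs.
DEFAULT_PAIR_SPECS = (
    (104, "inverted"),
    (176, "inverted"),
    (284, "inverted"),
    (620, "inverted"),
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class TruthSet:
    """Parameters and planted truth sufficient to regenerate a dataset."""

    kind: str
    params: dict
    pairs: list = field(default_factory=list)
    events: list = field(default_factory=list)
    derived_pairs: list = field(default_factory=list)

    def to_dict(self) -> dict:
        def ser(pairs):
            return [
                dict(
                    pair_id=p.pair_id,
                    a_start=p.a.start,
                    a_end=p.a.end,
                    b_start=p.b.start,
                    b_end=p.b.end,
                    sign_a=p.sign_a,
                    sign_b=p.sign_b,
                    core_len=p.core_len,
                )
                for p in pairs
            ]

        return dict(
            kind=self.kind,
            params=self.params,
            pairs=ser(self.pairs),
            events=list(self.events),
            derived_pairs=ser(self.derived_pairs),
        )

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @staticmethod
    def from_dict(d: dict) -> "TruthSet":
        def de(rows):
            return [
                PlacedRepeat(
                    r["pair_id"],
                    Interval(r["a_start"], r["a_end"]),
                    Interval(r["b_start"], r["b_end"]),
                    r["sign_a"],
                    r["sign_b"],
                    r["core_len"],
                )
                for r in rows
            ]

        return TruthSet(
            kind=d["kind"],
            params=d["params"],
            pairs=de(d.get("pairs", [])),
            events=list(d.get("events", [])),
            derived_pairs=de(d.get("derived_pairs", [])),
        )


def _random_seq(length: int, gc: float, rng) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def _shares_kmer(core: str, others, k: int = 20) -> bool:
    kmers = {core[i : i + k] for i in range(len(core) - k + 1)}
    rc = reverse_complement(core)
    kmers |= {rc[i : i + k] for i in range(len(rc) - k + 1)}
    for o in others:
        for i in range(len(o) - k + 1):
            if o[i : i + k] in kmers:
                return True
    return False


def _other_base(rng, *avoid) -> bytes:
    choices = [b for b in (b"A", b"C", b"G", b"T") if b not in avoid]
    return choices[int(rng.integers(len(choices)))]


def make_genome_with_repeats(
    length: int = 200_000,
    gc: float = 0.45,
    pair_specs=DEFAULT_PAIR_SPECS,
    min_separation: int = 15_000,
    margin: int = 8_000,
    seed: int = 0,
    genome_id: str = "ancestral",
    interleave: bool = True,
):
    """Random circular genome with planted paralogous repeat pairs.

    ``pair_specs`` is a list of ``(core_len, orientation)`` (an optional
    third element overrides ``min_separation`` for that pair).  Each pair is
    one random core copied (reverse-complemented if inverted) to a second
    locus; with ``interleave=True`` the copy-to-locus assignment is
    shuffled, so pair spans may nest or overlap — exactly what a
    multi-inversion history needs; with ``interleave=False`` the pair
    spans are mutually disjoint (the geometry needed when breakpoints must
    stay at their ancestral coordinates, e.g. for read-level genotyping).
    Cores of different pairs share no 20-mer.  Returns ``(GenomeRecord,
    TruthSet)``; deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    specs = [tuple(s) for s in pair_specs]
    n_loci = 2 * len(specs)
    max_core = max((s[0] for s in specs), default=0)
    seps = [s[2] if len(s) > 2 else min_separation for s in specs]
    sep = max(seps, default=min_separation)
    if n_loci and margin * 2 + n_loci * (sep + max_core) > length:
        raise ValueError("infeasible packing: too many/large pairs for length")

    arr = _random_seq(length, gc, rng)

    # exact spaced placement: sorted uniforms over the slack, plus the
    # mandatory minimum gaps
    gap = sep + max_core
    slack = (length - margin - max_core) - margin - (n_loci - 1) * gap
    if n_loci and slack <= 0:
        raise ValueError("infeasible packing: could not place loci")
    u = np.sort(rng.integers(0, slack + 1, size=n_loci)) if n_loci else []
    loci = [int(margin + u[i] + i * gap) for i in range(n_loci)]

    assignment = [i for i in range(len(specs)) for _ in range(2)]
    if interleave:
        rng.shuffle(assignment)

    pairs = []
    core_strs: list = []
    for pid, (spec, _s) in enumerate(zip(specs, seps)):
        core_len, orientation = spec[0], spec[1]
        idxs = [k for k, a in enumerate(assignment) if a == pid]
        a_pos, b_pos = loci[idxs[0]], loci[idxs[1]]
        for _ in range(100):
            core = "".join(
                c.decode() for c in _random_seq(core_len, gc, rng)
            )
            if not _shares_kmer(core, core_strs):
                break
        else:  # pragma: no cover
            raise ValueError("could not draw dissimilar cores")
        core_strs.append(core)
        sign_b = -1 if orientation == "inverted" else 1
        arr[a_pos : a_pos + core_len] = np.frombuffer(core.encode(), dtype="S1")
        b_core = reverse_complement(core) if sign_b < 0 else core
        arr[b_pos : b_pos + core_len] = np.frombuffer(b_core.encode(), dtype="S1")
        # enforce maximality: the shared segment must not extend past the core
        L = core_len
        if sign_b > 0:
            if arr[b_pos - 1] == arr[a_pos - 1]:
                arr[b_pos - 1] = _other_base(rng, bytes(arr[a_pos - 1]))
            if arr[b_pos + L] == arr[a_pos + L]:
                arr[b_pos + L] = _other_base(rng, bytes(arr[a_pos + L]))
        else:
            comp = {b"A": b"T", b"T": b"A", b"C": b"G", b"G": b"C"}
            if bytes(arr[b_pos + L]) == comp[bytes(arr[a_pos - 1])]:
                arr[b_pos + L] = _other_base(rng, comp[bytes(arr[a_pos - 1])])
            if bytes(arr[b_pos - 1]) == comp[bytes(arr[a_pos + L])]:
                arr[b_pos - 1] = _other_base(rng, comp[bytes(arr[a_pos + L])])
        pairs.append(
            PlacedRepeat(
                pair_id=pid,
                a=Interval(a_pos, a_pos + core_len),
                b=Interval(b_pos, b_pos + core_len),
                sign_a=1,
                sign_b=sign_b,
                core_len=core_len,
            )
        )

    genome = GenomeRecord(id=genome_id, seq=arr.tobytes().decode(), circular=True)
    truth = TruthSet(
        kind="genome_with_repeats",
        params=dict(
            length=length,
            gc=gc,
            pair_specs=[list(s) for s in specs],
            min_separation=min_separation,
            margin=margin,
            seed=int(seed),
        ),
        pairs=pairs,
    )
    return genome, truth


def apply_truth_history(
    genome: GenomeRecord,
    truth: TruthSet,
    n_events: int,
    seed: int = 0,
    derived_id: str = "derived",
):
    """Sample a legal chain of ``n_events`` repeat-bounded inversions.

    At each step one unused pair currently in inverted orientation is drawn
    uniformly (orientations are re-evaluated after every event, so a pair
    planted in direct orientation may become usable after an overlapping
    inversion).  Crossovers sit at the core midpoints.  Returns ``(derived
    GenomeRecord, TruthSet)`` with the ordered truth events and the final
    pair placements.
    """
    last_fail = None
    for attempt in range(200):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), attempt]))
        seq = genome.seq
        pairs = list(truth.pairs)
        used: set = set()
        events = []
        for step in range(n_events):
            legal = sorted(
                p.pair_id
                for p in pairs
                if p.orientation == "inverted" and p.pair_id not in used
            )
            if not legal:
                last_fail = step + 1
                break
            pid = legal[int(rng.integers(len(legal)))]
            seq, pairs, _ = invert_at_pair(seq, pairs, pid)
            used.add(pid)
            events.append(pid)
        else:
            break
    else:
        raise ValueError(
            f"no legal chain of {n_events} inversions found "
            f"(last dead end at step {last_fail})"
        )
    derived = GenomeRecord(id=derived_id, seq=seq, circular=genome.circular)
    out = TruthSet(
        kind="inversion_history",
        params=dict(truth.params, n_events=n_events, history_seed=int(seed)),
        pairs=list(truth.pairs),
        events=events,
        derived_pairs=pairs,
    )
    return derived, out


def make_history_dataset(
    n_events: int,
    length: int = 200_000,
    pair_specs=None,
    core_range=(100, 620),
    seed: int = 0,
    min_separation: int = 15_000,
    **genome_kwargs,
):
    """A feasible ancestral/derived genome pair with a planted history.

    Draws a genome layout (and, when ``pair_specs`` is None, ``n_events``
    inverted pairs with core lengths uniform in ``core_range``) and a legal
    chain of ``n_events`` repeat-bounded inversions; layouts in which the
    pair interleaving admits no such chain (an early event can flip a
    remaining pair to direct) are redrawn from seed-derived attempts, so
    the result is deterministic per seed.  Returns ``(ancestral, derived,
    TruthSet)``.
    """
    for attempt in range(50):
        sub = int(
            np.random.SeedSequence([int(seed), attempt]).generate_state(1)[0]
            % (2**31)
        )
        if pair_specs is None:
            rng = np.random.default_rng(sub)
            specs = [
                (int(rng.integers(core_range[0], core_range[1] + 1)), "inverted")
                for _ in range(n_events)
            ]
        else:
            specs = pair_specs
        try:
            g, truth = make_genome_with_repeats(
                length=length,
                pair_specs=specs,
                min_separation=min_separation,
                seed=sub,
                **genome_kwargs,
            )
            derived, hist = apply_truth_history(g, truth, n_events, seed=sub)
        except ValueError:
            continue
        return g, derived, hist
    raise ValueError(f"no feasible {n_events}-event layout found for seed {seed}")


def simulate_reads(
    genomes,
    coverage: float = 100.0,
    read_len: int = 100,
    err: float = 0.01,
    seed: int = 0,
):
    """Single-end reads from a genome mixture.

    ``genomes`` is a list of ``(GenomeRecord, fraction)``; fractions must
    sum to 1.  Read starts are uniform (circular-aware), strands random,
    substitution errors i.i.d. per base at rate ``err`` (no indels — the
    downstream mapper is ungapped), quality a constant Phred 40 string.
    Total read count is ``round(coverage * len(genome) / read_len)``
    weighted by the fractions.  Returns ``(reads, TruthSet)`` where reads
    are ``(name, seq, qual)`` tuples; names encode source genome, start and
    strand after ``|``.
    """
    fracs = [f for _, f in genomes]
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    qual = "I" * read_len
    total = round(coverage * len(genomes[0][0].seq) / read_len)
    reads = []
    for gidx, (g, frac) in enumerate(genomes):
        n = round(total * frac)
        L = len(g.seq)
        if read_len > L:
            raise ValueError("read_len exceeds genome length")
        if g.circular:
            starts = rng.integers(0, L, size=n)
            doubled = g.seq + g.seq[:read_len]
        else:
            starts = rng.integers(0, L - read_len + 1, size=n)
            doubled = g.seq
        strands = rng.integers(0, 2, size=n)
        err_mask = rng.random((n, read_len)) < err if err > 0 else None
        shifts = rng.integers(1, 4, size=(n, read_len)) if err > 0 else None
        code = {"A": 0, "C": 1, "G": 2, "T": 3}
        bases = "ACGT"
        for i in range(n):
            p = int(starts[i])
            s = doubled[p : p + read_len]
            strand = "-" if strands[i] else "+"
            if strand == "-":
                s = reverse_complement(s)
            if err_mask is not None and err_mask[i].any():
                chars = list(s)
                for j in np.nonzero(err_mask[i])[0]:
                    chars[j] = bases[(code[chars[j]] + int(shifts[i, j])) % 4]
                s = "".join(chars)
            name = f"r{gidx}_{i}|src={g.id}|pos={p}|strand={strand}"
            reads.append((name, s, qual))
    truth = TruthSet(
        kind="reads",
        params=dict(
            sources=[(g.id, f) for g, f in genomes],
            coverage=coverage,
            read_len=read_len,
            err=err,
            seed=int(seed),
            n_reads=len(reads),
        ),
    )
    return reads, truth


# ---------------------------------------------------------------------------
# construct maps


def _stamp(arr: np.ndarray, pos: int, s: str) -> None:
    arr[pos : pos + len(s)] = np.frombuffer(s.encode(), dtype="S1")


def _patch_unwanted(arr, motif: str, keep_at, rng, protected) -> None:
    """Mutate one base inside every unwanted occurrence of ``motif`` (both
    strands), leaving ``keep_at`` positions and ``protected`` ranges alone."""
    n = len(arr)
    keep = set(keep_at)
    motifs = {motif, reverse_complement(motif)}
    changed = True
    while changed:
        changed = False
        seq = arr.tobytes().decode()
        scan = seq + seq[: len(motif) - 1]
        for m in motifs:
            i = scan.find(m)
            while i >= 0:
                p = i % n
                if p not in keep:
                    for off in range(len(m)):
                        q = (p + off) % n
                        if not any(a <= q < b for a, b in protected):
                            arr[q] = _other_base(rng, bytes(arr[q]))
                            changed = True
                            break
                i = scan.find(m, i + 1)


def build_construct_map(template: str, seed: int = 0, **params) -> Molecule:
    """Concrete construct maps for the recombination worked examples.

    Templates:

    * ``pMC479_like`` — circular plasmid carrying, in order, an 87 bp att
      site, a 762 bp spacer and a 43 bp att site in direct orientation, the
      two sites sharing the full 43 bp core as the site prefix; two NdeI
      sites placed so the intact plasmid digests to {3207, 1366}.  Excision
      between the sites releases a circle of spacer + long hybrid site
      (762 + 87 = 849 bp).
    * ``pMC477_like`` — circular plasmid with the same two sites in
      inverted orientation separated by an 892 bp spacer; the two NdeI
      positions are solved exactly from the printed digests
      (pre-inversion ``pre_digest``, post-inversion ``post_digest``).
    * ``TKV4_like`` — a linear host fragment with an integrated element
      flanked by direct att sites and outward-facing primer binding sites;
      the excision circle yields a single amplicon of
      ``excision_amplicon`` bp (no product from the un-excised host).

    Filler sequence is random per seed; unintended recognition-site or
    primer occurrences are patched out, so length arithmetic is exact.
    """
    if template in ("pMC479_like", "pMC477_like"):
        long_site = params.get("long_site", 87)
        core_len = params.get("core", 43)
        enzyme = params.get("enzyme", "CATATG")
        total = params.get("total", 4573)
        gc = params.get("gc", 0.5)
        for attempt in range(20):
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), attempt]))
            core = "".join(c.decode() for c in _random_seq(core_len, gc, rng))
            long_extra = "".join(
                c.decode() for c in _random_seq(long_site - core_len, gc, rng)
            )
            arr = _random_seq(total, gc, rng)
            _stamp(arr, 0, core + long_extra)  # core is the site prefix
            site_a = AttSite(
                "attB_long", Interval(0, long_site), Interval(0, core_len), "+"
            )
            if template == "pMC479_like":
                spacer = params.get("spacer", 762)
                b_start = long_site + spacer
                _stamp(arr, b_start, core)
                site_b = AttSite(
                    "attB_short",
                    Interval(b_start, b_start + core_len),
                    Interval(b_start, b_start + core_len),
                    "+",
                )
                pre = sorted(params.get("pre_digest", (3207, 1366)), reverse=True)
                # one cut just downstream of the short site, the second a
                # short-fragment away, so the excisable region sits inside
                # the long pre-digest fragment and carries no cut
                n1 = b_start + core_len + 100
                cuts = [n1, n1 + pre[1]]
            else:
                spacer = params.get("spacer", 892)
                b_start = long_site + spacer
                _stamp(arr, b_start, reverse_complement(core))
                site_b = AttSite(
                    "attB_short",
                    Interval(b_start, b_start + core_len),
                    Interval(b_start, b_start + core_len),
                    "-",
                )
                pre = sorted(params.get("pre_digest", (2796, 1777)), reverse=True)
                post = sorted(params.get("post_digest", (2358, 2215)), reverse=True)
                x = core_len // 2
                pa = x  # cut point in site A core (strand +)
                pb = b_start + (core_len - x)  # cut point in site B core (strand -)
                # a recognition site at m inside the invertible segment
                # reflects to pa + pb - m - len(enzyme); solve against the
                # two printed digests
                delta = pre[1] - post[1]
                m = (pa + pb - len(enzyme) + delta) // 2
                if not (pa <= m and m + len(enzyme) <= pb):
                    raise ValueError("unsatisfiable digest constraints (inside cut)")
                n2 = m + pre[0]
                if not (pb <= n2 and n2 + len(enzyme) <= total):
                    raise ValueError("unsatisfiable digest constraints (outside cut)")
                cuts = [m, n2]
            if sum(pre) != total:
                raise ValueError("pre-digest fragments must sum to the total length")
            for c in cuts:
                _stamp(arr, c, enzyme)
            protected = [
                (site_a.location.start, site_a.location.end),
                (site_b.location.start, site_b.location.end),
            ] + [(c, c + len(enzyme)) for c in cuts]
            _patch_unwanted(arr, enzyme, cuts, rng, protected)
            mol = Molecule(
                id=template,
                seq=arr.tobytes().decode(),
                circular=True,
                sites=(site_a, site_b),
                features=(Feature("spacer", Interval(long_site, b_start)),),
            )
            if digest(mol, enzyme).cut_positions == tuple(sorted(cuts)):
                return mol
        raise ValueError("could not realise construct without spurious sites")

    if template == "TKV4_like":
        rng = np.random.default_rng(seed)
        gc = params.get("gc", 0.5)
        host_len = params.get("host_len", 12_000)
        elem_start = params.get("element_start", 3_000)
        core_len = params.get("core", 43)
        long_site = params.get("long_site", 87)
        amplicon = params.get("excision_amplicon", 1710)
        primer_len = params.get("primer_len", 20)
        circle_len = params.get("element_len", 5_000)
        arr = _random_seq(host_len, gc, rng)
        core = "".join(c.decode() for c in _random_seq(core_len, gc, rng))
        extra = "".join(c.decode() for c in _random_seq(long_site - core_len, gc, rng))
        x = core_len // 2
        # attL (long) at the element start; attR core_len further than
        # circle_len so the excised circle [pa, pb) is exactly circle_len bp
        _stamp(arr, elem_start, core + extra)
        attl = AttSite(
            "attL", Interval(elem_start, elem_start + long_site),
            Interval(elem_start, elem_start + core_len), "+",
        )
        b_start = elem_start + circle_len
        _stamp(arr, b_start, core)
        attr = AttSite(
            "attR", Interval(b_start, b_start + core_len),
            Interval(b_start, b_start + core_len), "+",
        )
        pa = elem_start + x  # both sites strand +: cuts at core start + x
        # outward-facing primers: fwd near the element's right end pointing
        # out of the element, rev near its left end pointing out; on the
        # excised circle the new junction makes them convergent with a
        # product of exactly `amplicon` bp
        f_c = circle_len - 800
        r_c = (amplicon + f_c - primer_len) % circle_len
        f_pos = pa + f_c
        r_pos = pa + r_c
        fwd = arr[f_pos : f_pos + primer_len].tobytes().decode()
        rev = reverse_complement(
            arr[r_pos : r_pos + primer_len].tobytes().decode()
        )
        mol = Molecule(
            id="TKV4_like_host",
            seq=arr.tobytes().decode(),
            circular=False,
            sites=(attl, attr),
            features=(
                Feature("element", Interval(elem_start, b_start + core_len)),
                Feature("fwd_primer_site", Interval(f_pos, f_pos + primer_len)),
                Feature("rev_primer_site", Interval(r_pos, r_pos + primer_len, "-")),
            ),
        )
        # convenience attribute: the primer sequences of the assay
        object.__setattr__(mol, "primers", dict(fwd=fwd, rev=rev))
        return mol

    raise ValueError(f"unknown template {template!r}")


# ---------------------------------------------------------------------------
# serial passaging


@dataclass
class PassageTrajectory:
    """Per-passage composition of a serially diluted population.

    States are tuples of fired pair ids in order; frequencies sum to 1 at
    every recorded passage.
    """

    records: list  # dicts: passage, state, frequency
    params: dict

    def frame(self):
        import pandas as pd

        return pd.DataFrame(self.records)


def simulate_passaging(
    pairs,
    inv_rate: float = 1e-3,
    generations: int = 60,
    generations_per_passage: int = 6,
    dilution: int = 50,
    pop_size: int = 1000,
    seed: int = 0,
) -> PassageTrajectory:
    """Neutral Wright-Fisher-style inversion dynamics under serial passage.

    Each generation every lineage fires an inversion at each of its
    currently-inverted pairs with probability ``inv_rate``; every
    ``generations_per_passage`` generations the population is bottlenecked
    ``dilution``-fold (multinomial) and regrown to ``pop_size``.  The
    per-generation rate is illustrative scaffolding — the natural system
    constrains the outcome (rearranged genomes arising within tens of
    generations), not the rate.
    """
    rng = np.random.default_rng(seed)
    pair_states = {(): list(pairs)}
    counts = {(): pop_size}
    records = []

    def record(passage):
        for state, c in sorted(counts.items()):
            records.append(
                dict(passage=passage, state=state, frequency=c / pop_size)
            )

    record(0)
    for gen in range(1, generations + 1):
        new_counts = dict(counts)
        for state, c in list(counts.items()):
            if c == 0:
                continue
            legal = [
                p.pair_id
                for p in pair_states[state]
                if p.orientation == "inverted" and p.pair_id not in state
            ]
            for pid in legal:
                k = rng.binomial(c, inv_rate)
                if k == 0:
                    continue
                k = min(k, new_counts[state])
                child = state + (pid,)
                if child not in pair_states:
                    new_pairs, _ = remap_pairs_after_inversion(
                        pair_states[state], pid
                    )
                    pair_states[child] = new_pairs
                new_counts[state] -= k
                new_counts[child] = new_counts.get(child, 0) + k
        counts = {s: c for s, c in new_counts.items() if c > 0}
        if gen % generations_per_passage == 0:
            states = sorted(counts)
            freqs = np.array([counts[s] for s in states], dtype=float)
            freqs /= freqs.sum()
            sample = rng.multinomial(max(pop_size // dilution, 1), freqs)
            keep = [s for s, k in zip(states, sample) if k > 0]
            if keep:
                kf = np.array(
                    [k for k in sample if k > 0], dtype=float
                )
                kf /= kf.sum()
                regrow = rng.multinomial(pop_size, kf)
                counts = {s: int(c) for s, c in zip(keep, regrow) if c > 0}
            record(gen // generations_per_passage)
    return PassageTrajectory(
        records=records,
        params=dict(
            inv_rate=inv_rate,
            generations=generations,
            generations_per_passage=generations_per_passage,
            dilution=dilution,
            pop_size=pop_size,
            seed=int(seed),
        ),
    )
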