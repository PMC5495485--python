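"""Stage 4 — in-silico integrase reactions on DNA maps.

Implements the Campbell-model reaction set of a tyrosine integrase on
explicit molecule maps: intermolecular integration of two circles into a
co-integrate, intramolecular excision between direct sites into two circles,
and intramolecular inversion between inverted sites; plus the
low-sequence-specificity mode in which any pair of exactly shared segments
of at least ``min_core`` bp behaves as a generic site pair (the outcome of
homologous recombination, produced here by the same site machinery).
Restriction-digest and PCR-product prediction reproduce gel and PCR
readouts.

Reactions are conservative: every product set carries exactly the substrate
nucleotides.  Recombination is legal only between sites whose cores are
identical in the oriented frame (the identical-core rule is a deliberate
simplification of substrate compatibility); the crossover defaults to the
core midpoint.  Hybrid sites are composed as the upstream partner's prefix
up to the crossover plus the downstream partner's suffix — this single
convention fixes the partitioning of the site lengths between the two
products (e.g. an 87 bp + 43 bp direct site pair flanking a 762 bp spacer
excises a circle of 762 + 87 = 849 bp, the shorter 43 bp hybrid staying on
the backbone).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .seqio import Interval, reverse_complement
from .anchors import _maximal_matches

__all__ = [
    "AttSite",
    "Feature",
    "Molecule",
    "ReactionResult",
    "DigestResult",
    "Amplicon",
    "site_recombine",
    "homologous_recombine",
    "digest",
    "pcr_predict",
    "IncompatibleSitesError",
    "GeometryError",
    "molecule_to_dict",
    "molecule_from_dict",
]

# Documented constants from the natural system: the attP/attB pair shares a
# 41 bp identical stretch, and the minimal site proficient in dimerization
# (Leu2-44) is 43 bp.  Shipped for fixture construction, not hard-coded
# limits.
ATT_SHARED_STRETCH_BP = 41
MINIMAL_SITE_BP = 43


class IncompatibleSitesError(ValueError):
    """Site cores are not identical in the oriented frame."""


class GeometryError(ValueError):
    """Requested reaction is inconsistent with the site geometry."""


@dataclass(frozen=True)
class AttSite:
    name: str  # attP, attB, attL, attR or generic
    location: Interval
    core: Interval  # absolute coordinates; must lie within location
    strand: str = "+"

    def __post_init__(self):
        if not (self.location.start <= self.core.start and self.core.end <= self.location.end):
            raise ValueError(f"site {self.name}: core outside site location")
        if len(self.core) < 1:
            raise ValueError(f"site {self.name}: empty core")


@dataclass(frozen=True)
class Feature:
    label: str
    location: Interval
    kind: str = "misc"


@dataclass(frozen=True)
class Molecule:
    id: str
    seq: str
    circular: bool = True
    sites: tuple = ()
    features: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "seq", self.seq.upper())
        object.__setattr__(self, "sites", tuple(self.sites))
        object.__setattr__(self, "features", tuple(self.features))
        for s in self.sites:
            if s.location.end > len(self.seq) and not self.circular:
                raise ValueError(f"site {s.name} outside linear molecule")

    def __len__(self):
        return len(self.seq)

    def fetch(self, iv: Interval) -> str:
        if iv.end <= len(self.seq):
            s = self.seq[iv.start : iv.end]
        elif self.circular:
            s = (self.seq + self.seq)[iv.start : iv.end]
        else:
            raise ValueError("interval beyond end of linear molecule")
        return reverse_complement(s) if iv.strand == "-" else s

    def core_seq(self, site: AttSite) -> str:
        """Core sequence in the site's oriented frame."""
        s = self.fetch(Interval(site.core.start, site.core.end))
        return reverse_complement(s) if site.strand == "-" else s

    def site_by_name(self, name: str) -> AttSite:
        hits = [s for s in self.sites if s.name == name]
        if len(hits) != 1:
            raise ValueError(f"{len(hits)} sites named {name!r}")
        return hits[0]


@dataclass(frozen=True)
class ReactionResult:
    products: tuple
    reaction: str  # integration, excision, inversion, homologous
    crossover: int  # offset within the shared core
    core_len: int


def _maybe_site(name, location, core, strand):
    """Hybrid AttSite, or None when a degenerate crossover leaves an empty
    site or core on one side (possible for 1-2 bp generic cores)."""
    if len(location) < 1 or len(core) < 1:
        return None
    if not (location.start <= core.start and core.end <= location.end):
        return None
    return AttSite(name, location, core, strand)


def _hybrid_names(name_a: str, name_b: str) -> tuple:
    canon = {frozenset(("attP", "attB")): ("attL", "attR"),
             frozenset(("attL", "attR")): ("attP", "attB")}
    pair = frozenset((name_a, name_b))
    if pair in canon:
        return canon[pair]
    return (f"{name_a}x{name_b}", f"{name_b}x{name_a}")


def _cut_point(site: AttSite, x: int) -> int:
    """Absolute cut position for crossover offset ``x`` in the oriented core."""
    L = len(site.core)
    return site.core.start + (x if site.strand == "+" else L - x)


def _map_linear(c: int, pa: int, pb: int, n: int):
    """(product index, position) for the excision partition of a circle."""
    if pa <= c < pb:
        return 0, c - pa
    return 1, (c - pb) % n


def _remap_sites_excision(mol, pa, pb, consumed):
    n = len(mol)
    l1 = pb - pa
    out = ([], [])
    for s in mol.sites:
        if s in consumed:
            continue
        seg, start = _map_linear(s.location.start, pa, pb, n)
        seg2, _ = _map_linear(max(s.location.end - 1, s.location.start), pa, pb, n)
        if seg != seg2:
            continue  # site destroyed by the junction
        off = start - s.location.start
        out[seg].append(replace(s, location=s.location.shift(off), core=s.core.shift(off)))
    return out


def _remap_features_split(features, mapper, suffixes=(":5p", ":3p")):
    """Map features through ``mapper(pos) -> (product, pos)``; features whose
    ends land on different products are split with ':5p'/':3p' suffixes."""
    out: dict = {}
    for f in features:
        p0, c0 = mapper(f.location.start)
        p1, c1 = mapper(f.location.end - 1)
        if p0 == p1 and c1 >= c0:
            out.setdefault(p0, []).append(
                replace(f, location=Interval(c0, c1 + 1, f.location.strand))
            )
        else:
            out.setdefault(p0, []).append(
                replace(f, label=f.label + suffixes[0],
                        location=Interval(c0, c0 + 1, f.location.strand))
            )
            out.setdefault(p1, []).append(
                replace(f, label=f.label + suffixes[1],
                        location=Interval(c1, c1 + 1, f.location.strand))
            )
    return out


def site_recombine(
    mol_a: Molecule,
    site_a: AttSite,
    mol_b: Optional[Molecule] = None,
    site_b: Optional[AttSite] = None,
    crossover_offset: Optional[int] = None,
    reaction: Optional[str] = None,
) -> ReactionResult:
    """One conservative site-specific recombination event.

    Two molecules -> co-integrate (integration); one circular molecule with
    co-oriented sites -> two circles (excision; on a linear molecule the
    deletion circle plus the shortened linear molecule); one molecule with
    inverted sites -> the same molecule with the inter-core segment
    reverse-complemented (inversion).  ``reaction`` may be supplied to
    assert the intended geometry; a mismatch raises :class:`GeometryError`.
    Cores must be identical in the oriented frame, else
    :class:`IncompatibleSitesError` (substrate incompatibility — e.g. a
    tRNA-Leu x tRNA-Thr pair is refused).
    """
    if site_b is None:
        raise ValueError("site_b is required")
    # passing the same Molecule object twice means two copies of that
    # molecule (dimerization); only mol_b=None selects the intramolecular
    # geometries
    intramolecular = mol_b is None
    host_b = mol_a if intramolecular else mol_b
    core_a = mol_a.core_seq(site_a)
    core_b = host_b.core_seq(site_b)
    if core_a != core_b:
        raise IncompatibleSitesError(
            f"cores of {site_a.name} and {site_b.name} differ "
            f"({len(core_a)} vs {len(core_b)} bp oriented cores)"
        )
    L = len(core_a)
    x = L // 2 if crossover_offset is None else crossover_offset
    if not 0 <= x <= L:
        raise ValueError("crossover offset outside core")

    if not intramolecular:
        kind = "integration"
    elif site_a.strand == site_b.strand:
        kind = "excision"
    else:
        kind = "inversion"
    if reaction is not None and reaction != kind:
        raise GeometryError(f"{kind} geometry but {reaction} requested")

    if kind == "integration":
        if not (mol_a.circular and mol_b.circular):
            raise GeometryError("integration requires two circular molecules")
        pa = _cut_point(site_a, x)
        pb = _cut_point(site_b, x)
        la, lb = len(mol_a), len(mol_b)
        seq = mol_a.seq[pa:] + mol_a.seq[:pa] + mol_b.seq[pb:] + mol_b.seq[:pb]
        name_l, name_r = _hybrid_names(site_a.name, site_b.name)
        pre_a = pa - site_a.location.start
        suf_a = site_a.location.end - pa
        pre_b = pb - site_b.location.start
        suf_b = site_b.location.end - pb
        hybrid1 = _maybe_site(
            name_l,
            Interval(la - pre_a, la + suf_b),
            Interval(la - (pa - site_a.core.start), la + (site_b.core.end - pb)),
            site_a.strand,
        )
        hybrid2 = _maybe_site(
            name_r,
            Interval(la + lb - pre_b, la + lb + suf_a),
            Interval(la + lb - (pb - site_b.core.start), la + lb + (site_a.core.end - pa)),
            site_b.strand,
        )
        sites = [s for s in (hybrid1, hybrid2) if s is not None]
        for s in mol_a.sites:
            if s is site_a:
                continue
            if s.location.start >= pa or s.location.end <= pa:
                off = -pa if s.location.start >= pa else la - pa
                sites.append(replace(s, location=s.location.shift(off), core=s.core.shift(off)))
        for s in mol_b.sites:
            if s is site_b:
                continue
            if s.location.start >= pb or s.location.end <= pb:
                off = (la - pb) if s.location.start >= pb else (la + lb - pb)
                sites.append(replace(s, location=s.location.shift(off), core=s.core.shift(off)))
        feats: list = []
        def map_a(c):
            return 0, (c - pa) % la
        def map_b(c):
            return 0, la + (c - pb) % lb
        for f in mol_a.features:
            p0 = map_a(f.location.start)[1]
            p1 = map_a(f.location.end - 1)[1]
            if p1 >= p0:
                feats.append(replace(f, location=Interval(p0, p1 + 1, f.location.strand)))
            else:
                feats.append(replace(f, label=f.label + ":5p", location=Interval(p0, la, f.location.strand)))
                feats.append(replace(f, label=f.label + ":3p", location=Interval(0, p1 + 1, f.location.strand)))
        for f in mol_b.features:
            p0 = map_b(f.location.start)[1]
            p1 = map_b(f.location.end - 1)[1]
            if p1 >= p0:
                feats.append(replace(f, location=Interval(p0, p1 + 1, f.location.strand)))
            else:
                feats.append(replace(f, label=f.label + ":5p", location=Interval(p0, la + lb, f.location.strand)))
                feats.append(replace(f, label=f.label + ":3p", location=Interval(la, p1 + 1, f.location.strand)))
        product = Molecule(
            id=f"{mol_a.id}::{mol_b.id}",
            seq=seq,
            circular=True,
            sites=tuple(sites),
            features=tuple(feats),
        )
        result = ReactionResult((product,), "integration", x, L)

    elif kind == "excision":
        first, second = (
            (site_a, site_b)
            if _cut_point(site_a, x) <= _cut_point(site_b, x)
            else (site_b, site_a)
        )
        pa = _cut_point(first, x)
        pb = _cut_point(second, x)
        n = len(mol_a)
        circle_seq = mol_a.seq[pa:pb]
        rest_seq = mol_a.seq[pb:] + mol_a.seq[:pa]
        l1 = pb - pa
        name_l, name_r = _hybrid_names(first.name, second.name)
        # circle hybrid: second's prefix + first's suffix, crossing the origin
        hyb_circle = _maybe_site(
            name_l,
            Interval(max(0, l1 - (pb - second.location.start)), l1 + (first.location.end - pa)),
            Interval(max(0, l1 - (pb - second.core.start)), l1 + (first.core.end - pa)),
            first.strand,
        )
        l2 = n - l1
        hyb_rest = _maybe_site(
            name_r,
            Interval(max(0, l2 - (pa - first.location.start)), l2 + (second.location.end - pb)),
            Interval(max(0, l2 - (pa - first.core.start)), l2 + (second.core.end - pb)),
            first.strand,
        )
        sites_by_product = _remap_sites_excision(mol_a, pa, pb, {site_a, site_b})
        feat_map = _remap_features_split(
            mol_a.features, lambda c: _map_linear(c, pa, pb, n)
        )
        circle = Molecule(
            id=f"{mol_a.id}::excised",
            seq=circle_seq,
            circular=True,
            sites=tuple(
                ([hyb_circle] if hyb_circle else []) + sites_by_product[0]
            ),
            features=tuple(feat_map.get(0, ())),
        )
        if mol_a.circular:
            rest = Molecule(
                id=f"{mol_a.id}*",
                seq=rest_seq,
                circular=True,
                sites=tuple(
                    ([hyb_rest] if hyb_rest else []) + sites_by_product[1]
                ),
                features=tuple(feat_map.get(1, ())),
            )
        else:
            rest = Molecule(
                id=f"{mol_a.id}*",
                seq=mol_a.seq[:pa] + mol_a.seq[pb:],
                circular=False,
                sites=tuple(sites_by_product[1]),
                features=tuple(feat_map.get(1, ())),
            )
        result = ReactionResult((rest, circle), "excision", x, L)

    else:  # inversion
        if site_a.location.start > site_b.location.start:
            site_a, site_b = site_b, site_a
        pa = _cut_point(site_a, x)
        pb = _cut_point(site_b, x)
        if pa > pb:
            raise GeometryError("inverted sites overlap at the crossover")
        seq = mol_a.seq[:pa] + reverse_complement(mol_a.seq[pa:pb]) + mol_a.seq[pb:]
        flip = "-" if site_a.strand == "+" else "+"
        def refl(iv: Interval) -> Interval:
            return Interval(pa + pb - iv.end, pa + pb - iv.start,
                            "+" if iv.strand == "-" else "-")
        sites = []
        name_l, name_r = _hybrid_names(site_a.name, site_b.name)
        sites.append(replace(site_a, name=name_l))
        sites.append(replace(site_b, name=name_r))
        for s in mol_a.sites:
            if s is site_a or s is site_b:
                continue
            if s.location.end <= pa or s.location.start >= pb:
                sites.append(s)
            elif pa <= s.location.start and s.location.end <= pb:
                sites.append(
                    replace(s, location=refl(s.location), core=refl(s.core),
                            strand="+" if s.strand == "-" else "-")
                )
            # sites straddling a cut are destroyed
        feats = []
        for f in mol_a.features:
            if f.location.end <= pa or f.location.start >= pb:
                feats.append(f)
            elif pa <= f.location.start and f.location.end <= pb:
                feats.append(replace(f, location=refl(f.location)))
            else:
                if f.location.start < pa:
                    feats.append(replace(f, label=f.label + ":5p",
                                         location=Interval(f.location.start, pa, f.location.strand)))
                    feats.append(replace(f, label=f.label + ":3p",
                                         location=refl(Interval(pa, f.location.end, f.location.strand))))
                else:
                    feats.append(replace(f, label=f.label + ":5p",
                                         location=refl(Interval(f.location.start, pb, f.location.strand))))
                    feats.append(replace(f, label=f.label + ":3p",
                                         location=Interval(pb, f.location.end, f.location.strand)))
        product = Molecule(
            id=f"{mol_a.id}*",
            seq=seq,
            circular=mol_a.circular,
            sites=tuple(sites),
            features=tuple(feats),
        )
        result = ReactionResult((product,), "inversion", x, L)

    total_in = len(mol_a) + (len(mol_b) if mol_b is not None else 0)
    assert sum(len(p) for p in result.products) == total_in, "nucleotides not conserved"
    return result


# ---------------------------------------------------------------------------
# low-sequence-specificity ("homology-mimicking") recombination


def _self_matches(seq: str, min_core: int, max_occ: Optional[int] = None):
    """Maximal shared segments between distinct, non-overlapping loci of one
    sequence, in both orientations, deduplicated."""
    k = max(1, min(16, min_core))
    if max_occ is None:
        max_occ = max(64, len(seq))  # molecule-scale: no seed masking
    n = len(seq)
    cands = []
    for li, lj, L in _maximal_matches(seq, seq, k, min_core, max_occ):
        if li == lj:
            continue
        a, b = sorted((li, lj))
        if a + L > b:
            continue  # overlapping copies cannot recombine
        cands.append((a, b, L, "direct"))
    rc = reverse_complement(seq)
    for li, lj, L in _maximal_matches(seq, rc, k, min_core, max_occ):
        gi, gj = li, n - lj - L
        a, b = sorted((gi, gj))
        if a + L > b:
            continue
        cands.append((a, b, L, "inverted"))
    return sorted(set(cands))


def homologous_recombine(
    mol_a: Molecule, mol_b: Optional[Molecule] = None, min_core: int = 100
) -> list[ReactionResult]:
    """Low-sequence-specificity reactions between exactly shared segments.

    Finds every maximal shared identical segment of at least ``min_core`` bp
    between (or within) the substrates, synthesizes a generic site pair at
    each, and returns the corresponding :func:`site_recombine` outcome,
    flagged with the core length (a qualitative proxy for the efficiency
    gradient across substrate sizes).  The default threshold of 100 bp is
    the smallest active substrate observed for this reaction mode.  No
    shared segment reaching the threshold yields an empty list.
    """
    if min_core < 1:
        raise ValueError("min_core must be >= 1")
    results = []
    if mol_b is None:
        for a, b, L, orient in _self_matches(mol_a.seq, min_core):
            sa = AttSite("hrA", Interval(a, a + L), Interval(a, a + L), "+")
            sb = AttSite(
                "hrB", Interval(b, b + L), Interval(b, b + L),
                "+" if orient == "direct" else "-",
            )
            res = site_recombine(mol_a, sa, site_b=sb)
            results.append(replace(res, reaction=f"homologous_{res.reaction}"))
        return results
    k = max(1, min(16, min_core))
    max_occ = max(64, len(mol_a.seq), len(mol_b.seq))
    n2 = len(mol_b.seq)
    cands = []
    for li, lj, L in _maximal_matches(mol_a.seq, mol_b.seq, k, min_core, max_occ):
        cands.append((li, lj, L, "+"))
    rc = reverse_complement(mol_b.seq)
    for li, lj, L in _maximal_matches(mol_a.seq, rc, k, min_core, max_occ):
        cands.append((li, n2 - lj - L, L, "-"))
    for li, lj, L, strand in sorted(set(cands)):
        sa = AttSite("hrA", Interval(li, li + L), Interval(li, li + L), "+")
        sb = AttSite("hrB", Interval(lj, lj + L), Interval(lj, lj + L), strand)
        res = site_recombine(mol_a, sa, mol_b, sb)
        results.append(replace(res, reaction=f"homologous_{res.reaction}"))
    return results


# ---------------------------------------------------------------------------
# restriction digest and PCR prediction


@dataclass(frozen=True)
class DigestResult:
    fragments: tuple  # sorted descending
    cut_positions: tuple
    status: str  # 'cut' or 'uncut'


def _find_all(hay: str, needle: str):
    out = []
    i = hay.find(needle)
    while i >= 0:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def digest(mol: Molecule, recognition: str) -> DigestResult:
    """Fragment sizes of a restriction digest.

    Both strands are scanned for the recognition sequence; cut positions are
    taken at the site start (a constant offset, which cancels in fragment
    sizes between sites on a circle).  A circular molecule with s sites
    yields s fragments, a linear one s+1; an uncut circle is reported with
    status ``uncut``.
    """
    rec = recognition.upper()
    if len(rec) < 4:
        raise ValueError("recognition sequence must be >= 4 bp")
    n = len(mol)
    scan = mol.seq + (mol.seq[: len(rec) - 1] if mol.circular else "")
    cuts = set(p % n for p in _find_all(scan, rec))
    rrc = reverse_complement(rec)
    if rrc != rec:
        cuts |= set(p % n for p in _find_all(scan, rrc))
    cuts = sorted(cuts)
    if mol.circular:
        if not cuts:
            return DigestResult((), (), "uncut")
        frags = [b - a for a, b in zip(cuts, cuts[1:])] + [cuts[0] + n - cuts[-1]]
    else:
        frags = [b - a for a, b in zip([0] + cuts, cuts + [n])]
        frags = [f for f in frags if f > 0]
    assert sum(frags) == n
    return DigestResult(tuple(sorted(frags, reverse=True)), tuple(cuts), "cut")


@dataclass(frozen=True)
class Amplicon:
    length: int
    fwd_pos: int
    rev_pos: int


def pcr_predict(
    mol: Molecule, fwd: str, rev: str, max_len: int = 10_000
) -> list[Amplicon]:
    """Amplicons for a primer pair under exact-match binding.

    The forward primer binds the + strand, the reverse primer the - strand;
    a product is reported for every convergent configuration within
    ``max_len``, including across the origin of a circular molecule — so
    outward-facing primers on an integrated element amplify only after
    excision and circularization.  Primers binding at more than 5 loci
    trigger an ambiguity warning (ValueError).
    """
    f, r = fwd.upper(), rev.upper()
    if len(f) < 15 or len(r) < 15:
        raise ValueError("primers must be >= 15 nt")
    n = len(mol)
    f_hits = _find_all(mol.seq + (mol.seq[: len(f) - 1] if mol.circular else ""), f)
    f_hits = sorted(set(p % n for p in f_hits))
    r_site = reverse_complement(r)
    r_hits = _find_all(mol.seq + (mol.seq[: len(r) - 1] if mol.circular else ""), r_site)
    r_hits = sorted(set(p % n for p in r_hits))
    if len(f_hits) > 5 or len(r_hits) > 5:
        raise ValueError(
            f"ambiguous priming: fwd binds {len(f_hits)} loci, rev {len(r_hits)}"
        )
    out = []
    for fp in f_hits:
        for rp in r_hits:
            end = rp + len(r)
            if mol.circular:
                length = (end - fp) % n
                if length == 0:
                    length = n
            else:
                length = end - fp
            if length >= max(len(f), len(r)) and length <= max_len:
                out.append(Amplicon(length, fp, rp))
    out.sort(key=lambda a: (a.length, a.fwd_pos))
    return out


# ---------------------------------------------------------------------------
# JSON map serialization


def molecule_to_dict(mol: Molecule) -> dict:
    return dict(
        id=mol.id,
        seq=mol.seq,
        circular=mol.circular,
        sites=[
            dict(
                name=s.name,
                start=s.location.start,
                end=s.location.end,
                core_start=s.core.start,
                core_end=s.core.end,
                strand=s.strand,
            )
            for s in mol.sites
        ],
        features=[
            dict(
                label=f.label,
                start=f.location.start,
                end=f.location.end,
                strand=f.location.strand,
                kind=f.kind,
            )
            for f in mol.features
        ],
    )


def molecule_from_dict(d: dict) -> Molecule:
    return Molecule(
        id=d["id"],
        seq=d["seq"],
        circular=bool(d.get("circular", True)),
        sites=tuple(
            AttSite(
                s["name"],
                Interval(s["start"], s["end"]),
                Interval(s["core_start"], s["core_end"]),
                s.get("strand", "+"),
            )
            for s in d.get("sites", ())
        ),
        features=tuple(
            Feature(
                f["label"],
                Interval(f["start"], f["end"], f.get("strand", "+")),
                f.get("kind", "misc"),
            )
            for f in d.get("features", ())
        ),
    )
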