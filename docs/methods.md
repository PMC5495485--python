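# Methods

This note documents the models, conventions and numerical choices behind
each stage, what the synthetic data do and do not emulate, and the known
limitations.

## Coordinates and sequence conventions

All coordinates are 0-based, half-open, on the forward strand; reports that
need 1-based output convert at the presentation layer.  Sequences are
upper-case over {A, C, G, T, N}; `N` never matches anything in anchoring or
repeat detection (it is mapped to distinct sentinels on the two sides of
every comparison, so `N` does not even match `N`).  Circular genomes carry
an `origin_offset` recording their rotation; origin positions are user
input, never predicted.

## Stage 1 — anchoring and synteny blocks

Anchors are maximal exact matches (MEMs) of at least `min_len` bp between
genome 1 and either strand of genome 2, found by k-mer seeding (default
k = 16, `min_len` = 24) with per-diagonal coverage skipping, so each
maximal match is reported exactly once with maximality on both ends.
K-mers occurring more than 10 times in either genome are masked from
seeding: repeat families would otherwise blow up seeding quadratically, and
the repeats that matter are recovered at stage 2 anyway.  A maximal match
whose every k-mer is masked is consequently not reported.

Chaining is greedy single-linkage over anchors sorted along genome 1: an
anchor joins the oldest chain with the same orientation whose genome-1 and
orientation-consistent genome-2 gaps both lie in `[-overlap_slack,
max_gap]` and whose diagonal (anti-diagonal for minus chains) agrees within
`diag_slack` = 32 bp — conspecific genomes differ by substitutions, not
indels, inside a block.  **`max_gap` must stay below the smallest inversion
span expected in the data**; otherwise single-linkage bridges straight
across a nested inversion.  The stand-alone default (20 kb) suits genomes
whose inversions are 74–143 kb; the history-recovery pipeline defaults to
2 kb because the bundled generator plants events down to ~15 kb.  Chains
shorter than `min_block` (default 5 kb) are noise or repeat-family matches
and are dropped.

Blocks are numbered 1..n along genome 1; the signed permutation lists them
in genome-2 order with orientation as sign.  A genome-1 adjacency (i, i+1)
is conserved iff the permutation contains the signed adjacency (u, u+1);
all other genome-1 adjacencies are breakpoints.  Because an inversion
junction joins block ends that are far apart on genome 1, breakpoint gap
intervals are reported on the genome-1 axis (the junction between
q-adjacent blocks); the genome-2 gap is attached only when the same two
blocks are also genome-2 neighbours.  Inversion segments are maximal runs
of minus blocks in genome-2 order, reported with both their genome-1
(q) and genome-2 (s) spans — the two sizes an asymmetric comparison prints.

Circularity is handled by origin re-alignment rather than genome doubling:
probe k-mers unique in genome 2 vote for the rotation `(j - i) mod n`, with
preference given to probes flanking genome 1's origin.  The preference
matters: a doubly inverted region is forward but displaced and can outvote
the true alignment in genomes with nested histories.  After rotation the
comparison is purely linear, which makes the rotation-invariance of all
downstream results exact.

## Stage 2 — breakpoint forensics

The substrate of each inversion is the maximal *perfectly* conserved
segment shared by two breakpoint regions, in direct or inverted
orientation.  Longest common substring length is computed with a suffix
automaton (O(n + m)); positions are then recovered by scanning, with ties
broken by smallest position in A, then smallest position in the oriented
frame of B.  A quadratic diagonal dynamic program serves as the oracle in
the test suite.

Junction regions (windows of ±2 kb around each breakpoint midpoint,
clipped so neighbouring windows never overlap) are compared
all-against-all, not as the two ends of a minus run: under nested or
overlapping histories the two copies of one pair bound *different* minus
runs, so run-end pairing would mis-join them.  Two different statistics are
reported deliberately: `core_len` (exact shared-run length, the quantity
that determines substrate activity) and `identity_pct`, a global percent
identity over the core padded by 100 bp of flank — on synthetic genomes the
flanks are random, so `identity_pct` sits near 60–90% depending on core
length, whereas real paralogs would show ~97%.  Percent identity uses
Needleman–Wunsch with match +1, mismatch −1, first gap column −2, further
gap columns −1 (the statistic is standard but no scoring is canonical; this
one is fixed and documented), identity = matches/columns × 100 rounded to
0.1.

Crossover localization assumes gap-free aligned parents (the gapped case is
rejected); informative positions are the columns where the parents differ,
and the call is the maximal interval (l, r] with the recombinant matching
parent A at every informative position ≤ l and parent B at every
informative position ≥ r.  More than one switch raises an error rather
than returning a misleading interval.

## Stage 3 — inversion scenarios

Distance and scenario enumeration are exact breadth-first searches over
signed permutations (guarded to n ≤ 12): the instances of interest have
4–9 blocks, and *all* minimal scenarios are wanted, which a
Hannenhalli–Pevzner distance computation would not give.  Scenario output
is canonically ordered and every scenario is verified by re-application.

Endpoint constraints are expressed on a marker arrangement — blocks
interleaved with oriented repeat-copy markers — because slice indices are
not stable across a scenario while "the two copies of pair P" is.  A legal
move is an inversion between the copies of a pair whose relative
orientation is currently inverted (sign product −1).  Because crossover
happens inside a perfectly conserved core, recombination regenerates both
copies in place: the move reverses and sign-flips strictly interior items
and leaves the bounding markers unchanged, and a pair with exactly one copy
inside the span flips orientation (this is also how a pair planted in
direct orientation becomes usable after an overlapping event).
Unreachability under the constraints is a legitimate outcome and is
reported with a diagnostic, mirroring substrate pairs that do not react.

At sequence level an event cuts at the core midpoints, with complementary
offsets h and L−h in the two copies so that reverse-complementing the
interval between the cuts restores both copies exactly.  The crossover
position within the core is unobservable at block scale, so the midpoint is
a convention, not an inference.

## Stage 4 — recombination engine

Reactions are conservative string surgery on explicit molecule maps:
two circles + compatible sites → one co-integrate; one circle with
co-oriented sites → two circles (the deletion circle carries the spacer and
one hybrid site); one molecule with inverted sites → the same molecule with
the inter-core segment reverse-complemented.  Recombination is legal only
between sites whose cores are identical in the oriented frame — a
deliberate simplification of substrate compatibility that also models the
observed failures between non-identical tRNA gene pairs.  Passing the same
`Molecule` object twice means two copies of that molecule (dimerization);
only omitting the second molecule selects intramolecular geometry.

Hybrid sites are composed as the upstream partner's prefix up to the
crossover plus the downstream partner's suffix.  This single convention
fixes which product inherits which site length: with an 87 bp and a 43 bp
site sharing their full 43 bp core as prefix, flanking a 762 bp spacer in
direct orientation, the excised circle is spacer + the 87 bp hybrid
= 849 bp, never 805 bp.  Crossover defaults to the core midpoint and is
configurable.  Reaction efficiency is not modelled kinetically; the shared
core length is reported as a qualitative proxy for the efficiency gradient
across substrate sizes.  The documented constants `ATT_SHARED_STRETCH_BP`
= 41 (attP/attB shared stretch) and `MINIMAL_SITE_BP` = 43 (smallest site
proficient in dimerization) are shipped for fixture construction, not
enforced as limits.

The low-specificity mode finds every maximal shared identical segment of at
least `min_core` bp (default 100 bp, the smallest substrate active in this
reaction mode) between or within substrates, synthesizes a generic site
pair at each and runs the same machinery; seed masking is disabled at
molecule scale.  Restriction digests scan both strands and cut at the
recognition-site start — a constant offset that cancels in fragment sizes
between sites on a circle; an uncut circle is reported as such rather than
given a fictitious fragment.  PCR prediction uses exact-match primer
binding (v1) and reports convergent configurations within `max_len`,
including across the origin of circles, which is what makes outward-facing
primers on an integrated element diagnostic for excision.

Construct templates are solved exactly from printed constraints: the
pMC477-like map places one recognition site inside the invertible segment
at m = (p_a + p_b − |site| + Δ)/2, where Δ is the change of the short
fragment between the pre- and post-inversion digests and p_a, p_b are the
crossover cut points; random filler is patched free of spurious recognition
sites and the digest is verified before the map is returned.  These maps
are reconstructions constrained to the printed fragment sizes, not the true
(unpublished) construct sequences.

## Stage 5 — population genotyping

The mapper is a bespoke exact-seed (k = 21) + ungapped extension aligner:
a read is placed at a unique best position with ≤ 3 mismatches over both
strands, ties are `ambiguous`, the rest `unmapped`; it exists so the whole
procedure is desk-testable without an external aligner, and SAM import is
provided for real alignments.  For 100 bp reads at these settings a seeded
placement misses only if every seed window carries an error, which already
implies > 3 mismatches — so the mapper agrees exactly with an
all-positions brute-force aligner (asserted in the tests).  Reads are
assigned in two passes: all reads against the ancestral reference, then the
unmapped pool against the derived reference.  Duplicate reads are not
collapsed; ambiguous reads never contribute to diagnostics.

A physical constraint governs breakpoint classification.  An inversion
between copies of a perfectly conserved core regenerates both junctions
exactly, so every junction-local sequence occurs in both alleles (at
mirrored positions): any read that does not span the entire conserved core
plus a flank anchor on both sides is common to both alleles and carries no
information.  Diagnostics are therefore designed per breakpoint copy as:
the core interval, the nearest `n_positions` = 2 reference positions on the
junction's divergent side at which ancestral and derived references differ,
and the informative span (core + 10 bp anchor + the positions) that an
alignment must fully cover to be counted.  Read length must exceed
core + 2 × anchor for a breakpoint to be genotypeable at all — with 100 bp
reads, cores of 104–620 bp are physically out of reach, which is why the
genotyping study conditions use 200 bp reads over cores of 60–120 bp.
Bases matching neither expectation (sequencing errors) are excluded from
the denominator and reported separately.  Per breakpoint the two positions
are pooled and the derived fraction is given with a 95% Wilson interval
(statsmodels); because both positions come from the same spanning reads the
pooled interval is approximate (positions are nearly perfectly correlated),
a caveat that matters when combining across experiments.

Depth ratio is mean per-base depth over a target region divided by mean
depth over the reference minus the masked regions (e.g. an integrated copy
of the plasmid being quantified), i.e. copies per chromosome.

## Synthetic data: what it emulates, and what not

Generated genomes are i.i.d. uniform-GC background with planted repeat
pairs: one random core per pair copied (reverse-complemented if inverted)
to a second locus, cores pairwise dissimilar (no shared 20-mer, enforced by
resampling) and non-extendable (the bases flanking the second copy are
forced to mismatch the corresponding extension of the first copy, so
"planted core length" is exactly the maximal shared segment stage 2 should
report).  Copy-to-locus assignment is shuffled so spans nest and overlap
(`interleave=False` gives disjoint spans, needed when breakpoints must stay
at ancestral coordinates for read-level genotyping).  Histories are sampled
chains of repeat-bounded inversions, each pair used at most once,
orientation re-evaluated after every event; layouts admitting no legal
chain of the requested length are redrawn from seed-derived attempts.
Because every event consumes a distinct pair and each event's two junctions
remain breakpoints, the planted chain length equals the constrained
inversion distance, which is what makes exact event-count recovery a
well-posed check.

Reads are single-end, uniform-start (circular-aware), substitution-only
errors at a flat rate with constant quality — no indels (the mapper is
ungapped), no coverage or GC bias, no realistic error profiles.  Read names
carry the truth (source, position, strand) after a reserved `|` that every
consumer ignores.  Passing tests on these data demonstrate algorithmic
correctness under the stated model, not robustness to real-sequencer
artefacts or to divergent (non-identical) repeat copies.

The serial-passage simulator is a neutral Wright–Fisher-style model
(population 1000, inversion probability per pair per lineage per
generation, 50-fold dilution every 6 generations): invented scaffolding for
exploring dynamics, since the biology constrains the outcome (rearranged
genomes spreading within tens of generations), not the per-generation rate.

## Problem sizes and defaults

The bundled study conditions are: 200 kb genomes, four inverted pairs with
cores 104/176/284/620 bp at ≥ 15 kb separation for detection and scenario
work; 30 kb genomes with four disjoint pairs (cores 60/80/104/120 bp),
100× coverage of 200 bp reads at 1% error for mixture genotyping; 20
seeded history configurations (2–5 events, cores 100–620 bp) and 10 read
seeds per mixture for the recovery checks.  These sizes exercise every
code path at full algorithmic fidelity; nothing in the implementation is
specific to them.

## Known limitations

- Exact-match anchoring: divergent regions fall into breakpoint gaps by
  design, but genuinely indel-rich genomes will fragment into many blocks.
- Greedy single-linkage chaining requires `max_gap` below the smallest
  inversion span; it does not resolve conflicting chains by scoring.
- Scenario search is exhaustive and exponential; it is intended for the
  ≤ 12-block, ≤ 6-event regime this biology occupies.
- The recombination engine models neither synapsis, Holliday intermediates
  nor kinetics, and its identical-core rule is stricter than the real
  enzyme's tolerance (which accepts a few mismatches outside the crossover
  region).
- The genotyper is ungapped and substitution-only; indels near a diagnostic
  position would shift bases out of frame.
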