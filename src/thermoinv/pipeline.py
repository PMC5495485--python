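"""End-to-end history recovery: stages 1-3 glued together.

Given an ancestral and a derived genome, detect synteny blocks and
breakpoints, characterize the repeat substrates at the junctions, build the
marker arrangement and enumerate all minimal repeat-bounded inversion
scenarios reaching the observed block permutation.  When the genomes came
from the bundled generator, the recovered pairs can be matched back to the
planted ones and the truth scenario located among the enumerated minima.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .seqio import GenomeRecord
from .anchors import ComparisonResult, compare_genomes
from .forensics import RepeatPair, characterize_breakpoints
from .history import (
    ScenarioSearchResult,
    ancestral_arrangement,
    constrained_minimal_scenarios,
)

__all__ = ["RecoveryResult", "recover_history", "match_pairs_to_truth"]


@dataclass(frozen=True)
class RecoveryResult:
    comparison: ComparisonResult
    repeat_pairs: tuple
    search: ScenarioSearchResult
    scenario_pair_sequences: tuple  # tuples of detected-pair indices
    detected_to_planted: Optional[dict] = None
    truth_scenario_found: Optional[bool] = None

    @property
    def n_inversions(self) -> int:
        return len(self.comparison.inversions)

    @property
    def core_lengths(self) -> tuple:
        return tuple(sorted(p.core_len for p in self.repeat_pairs))


def match_pairs_to_truth(detected, planted) -> dict:
    """Map detected repeat-pair indices to planted pair ids by coordinate
    overlap of the copies (both in ancestral coordinates)."""
    mapping = {}
    for idx, rp in enumerate(detected):
        for tp in planted:
            hits = 0
            for div in (rp.a, rp.b):
                if div.overlaps(tp.a) or div.overlaps(tp.b):
                    hits += 1
            if hits == 2:
                mapping[idx] = tp.pair_id
                break
    return mapping


def recover_history(
    ancestral: GenomeRecord,
    derived: GenomeRecord,
    truth=None,
    window: int = 2_000,
    min_core: int = 50,
    max_depth: int = 8,
    cap: int = 1_000,
    **compare_params,
) -> RecoveryResult:
    """Run stages 1-3 and, if a truth set is given, check scenario recovery.

    ``max_gap`` defaults to 2 kb here (tighter than the stand-alone
    comparison default): chaining must not bridge across an inversion, so
    the gap tolerance has to stay below the smallest event span expected in
    the dataset.
    """
    compare_params.setdefault("max_gap", 2_000)
    cmp = compare_genomes(ancestral, derived, **compare_params)
    pairs = characterize_breakpoints(
        ancestral, cmp.breakpoints, window=window, min_core=min_core
    )
    markers = []
    for det_idx, rp in enumerate(pairs):
        sign_b = -1 if rp.orientation == "inverted" else 1
        markers.append((rp.a_breakpoint, det_idx, 1))
        markers.append((rp.b_breakpoint, det_idx, sign_b))
    arrangement = ancestral_arrangement(len(cmp.blocks), markers)
    search = constrained_minimal_scenarios(
        arrangement, cmp.permutation, max_depth=max_depth, cap=cap
    )
    sequences = tuple(
        tuple(ev.pair for ev in sc.events) for sc in search.scenarios
    )
    mapping = None
    found = None
    if truth is not None:
        mapping = match_pairs_to_truth(pairs, truth.pairs)
        planted_sequences = {
            tuple(mapping.get(i) for i in seq) for seq in sequences
        }
        found = tuple(truth.events) in planted_sequences
    return RecoveryResult(
        comparison=cmp,
        repeat_pairs=tuple(pairs),
        search=search,
        scenario_pair_sequences=sequences,
        detected_to_planted=mapping,
        truth_scenario_found=found,
    )
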