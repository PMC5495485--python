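#!/usr/bin/env python
"""Detect inversions between the ancestral and derived genomes (stage 1).

Whole-genome dotplot anchoring, synteny-block chaining and the signed block
permutation; reports every breakpoint and inversion segment.  The chaining
gap tolerance is kept below the smallest expected inversion span so that
nested events are never bridged.
"""

import argparse
import os

from thermoinv.seqio import load_genome
from thermoinv.anchors import (
    anchors_to_frame,
    blocks_to_frame,
    breakpoints_to_frame,
    compare_genomes,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", default="results")
    ap.add_argument("--max-gap", type=int, default=2_000)
    args = ap.parse_args()

    anc = load_genome(os.path.join(args.results, "ancestral.fa"), circular=True)
    der = load_genome(os.path.join(args.results, "derived.fa"), circular=True)
    res = compare_genomes(anc, der, max_gap=args.max_gap)

    anchors_to_frame(res.anchors).to_csv(
        os.path.join(args.results, "anchors.tsv"), sep="\t", index=False
    )
    blocks_to_frame(res.blocks).to_csv(
        os.path.join(args.results, "blocks.tsv"), sep="\t", index=False
    )
    breakpoints_to_frame(res.breakpoints).to_csv(
        os.path.join(args.results, "breakpoints.tsv"), sep="\t", index=False
    )
    with open(os.path.join(args.results, "permutation.txt"), "w") as fh:
        fh.write(" ".join(f"{x:+d}" for x in res.permutation) + "\n")

    print(f"{len(res.anchors)} anchors -> {len(res.blocks)} synteny blocks")
    print(f"block permutation along the derived genome: {res.permutation}")
    print(f"{len(res.breakpoints)} breakpoints, {len(res.inversions)} inversion segment(s):")
    for iv in res.inversions:
        print(
            f"  blocks {iv.blocks}: q-span {len(iv.q_span):,} bp "
            f"[{iv.q_span.start:,}-{iv.q_span.end:,}], s-span {len(iv.s_span):,} bp"
        )
    print(f"wrote anchors/blocks/breakpoints TSVs and permutation.txt to {args.results}/")


if __name__ == "__main__":
    main()
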