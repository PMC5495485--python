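#!/usr/bin/env python
"""In-silico reproduction of the integrase reaction readouts (stage 4).

Three worked assays on constraint-solved construct maps:
  * excision on a pMC479-like plasmid (direct 87 + 43 bp sites, 762 bp
    spacer) — releases an 849 bp circle; NdeI digest of the backbone;
  * inversion on a pMC477-like plasmid (inverted sites, 892 bp spacer)
    solved so the intact NdeI digest is {2796, 1777} — the recombinant
    digests to {2358, 2215};
  * excision-PCR on a TKV4-like integrated element with outward-facing
    primers — no product from the host, a single 1710 bp amplicon from the
    excised circle.
"""

import argparse
import json
import os

import pandas as pd

from thermoinv.recombine import digest, molecule_to_dict, pcr_predict, site_recombine
from thermoinv.simulate import build_construct_map


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()
    os.makedirs(args.out, exist_ok=True)
    rows = []

    p479 = build_construct_map("pMC479_like", seed=args.seed)
    pre = digest(p479, "CATATG").fragments
    exc = site_recombine(
        p479, p479.site_by_name("attB_long"), site_b=p479.site_by_name("attB_short")
    )
    circle = [p for p in exc.products if "excised" in p.id][0]
    backbone = [p for p in exc.products if "excised" not in p.id][0]
    rows.append(dict(assay="pMC479 excision", readout="excised circle", value_bp=len(circle)))
    rows.append(dict(assay="pMC479 excision", readout="NdeI pre-digest",
                     value_bp="+".join(map(str, pre))))
    rows.append(dict(assay="pMC479 excision", readout="NdeI backbone digest",
                     value_bp="+".join(map(str, digest(backbone, 'CATATG').fragments))))
    print(f"pMC479-like ({len(p479)} bp): NdeI {pre} -> excised circle {len(circle)} bp, "
          f"backbone digest {digest(backbone, 'CATATG').fragments}")

    p477 = build_construct_map("pMC477_like", seed=args.seed)
    pre = digest(p477, "CATATG").fragments
    inv = site_recombine(
        p477, p477.site_by_name("attB_long"), site_b=p477.site_by_name("attB_short")
    )
    post = digest(inv.products[0], "CATATG").fragments
    rows.append(dict(assay="pMC477 inversion", readout="NdeI pre-digest",
                     value_bp="+".join(map(str, pre))))
    rows.append(dict(assay="pMC477 inversion", readout="NdeI post-digest",
                     value_bp="+".join(map(str, post))))
    print(f"pMC477-like ({len(p477)} bp): NdeI {pre} -> after inversion {post}")

    tkv = build_construct_map("TKV4_like", seed=args.seed)
    fwd, rev = tkv.primers["fwd"], tkv.primers["rev"]
    before = pcr_predict(tkv, fwd, rev, max_len=6_000)
    exc = site_recombine(tkv, tkv.site_by_name("attL"), site_b=tkv.site_by_name("attR"))
    circ = [p for p in exc.products if p.circular][0]
    after = pcr_predict(circ, fwd, rev, max_len=6_000)
    rows.append(dict(assay="TKV4 excision-PCR", readout="host amplicons",
                     value_bp=len(before)))
    rows.append(dict(assay="TKV4 excision-PCR", readout="excised-circle amplicon",
                     value_bp=after[0].length if after else 0))
    print(f"TKV4-like: outward primers give {len(before)} product(s) on the host, "
          f"{[a.length for a in after]} bp after excision/circularization")

    pd.DataFrame(rows).to_csv(os.path.join(args.out, "recombination_assays.tsv"),
                              sep="\t", index=False)
    for name, mol in (("pMC479_like", p479), ("pMC477_like", p477), ("TKV4_like", tkv)):
        with open(os.path.join(args.out, f"{name}.json"), "w") as fh:
            json.dump(molecule_to_dict(mol), fh)
    print(f"wrote recombination_assays.tsv and construct maps to {args.out}/")


if __name__ == "__main__":
    main()
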