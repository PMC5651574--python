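#!/usr/bin/env python
"""Weir-Cockerham FST between all breed pairs (1000-bootstrap significance at
Bonferroni alpha 0.005, suggestive tier 0.01) and one-vs-rest per-locus θ."""

import argparse
from pathlib import Path

from _common import DATA_DIR, OUT_DIR, load_post_qc
from goatpop.differentiation import fst_one_vs_rest, fst_pairwise


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=DATA_DIR)
    ap.add_argument("--out", type=Path, default=OUT_DIR)
    ap.add_argument("--bootstrap", type=int, default=1000)
    ap.add_argument("--alpha", type=float, default=0.005)
    ap.add_argument("--seed", type=int, default=42)
    args = ap.parse_args()

    gm, snps, samples, _ = load_post_qc(args.data, args.out)
    breeds = sorted({s.breed for s in samples})

    pairwise = fst_pairwise(gm, samples, args.bootstrap, args.alpha, args.seed)
    print("pairwise Weir-Cockerham FST:")
    with (args.out / "fst_pairwise.tsv").open("w") as fh:
        fh.write("breed_1\tbreed_2\ttheta\tci_low\tci_high\tsignificant\t"
                 "suggestive\n")
        for (b1, b2), e in pairwise.items():
            mark = "**" if e.significant else ("*" if e.suggestive else "")
            print(f"  {b1}-{b2}: {e.theta:.4f} "
                  f"[{e.ci_low:.4f}, {e.ci_high:.4f}] {mark}")
            fh.write(f"{b1}\t{b2}\t{e.theta:.4f}\t{e.ci_low:.4f}\t"
                     f"{e.ci_high:.4f}\t{e.significant}\t{e.suggestive}\n")

    print("one-vs-rest FST (per-locus θ kept for outlier validation):")
    meta = {s.locus_id: s for s in snps}
    with (args.out / "fst_per_locus.tsv").open("w") as fh:
        cols = {}
        for b in breeds:
            e = fst_one_vs_rest(gm, samples, b, bootstrap_reps=0)
            print(f"  {b} vs rest: {e.theta:.4f}")
            cols[b] = dict(zip(e.locus_ids, e.theta_per_locus))
        fh.write("locus_id\tchromosome\tposition_bp\t"
                 + "\t".join(f"theta_{b}_vs_rest" for b in breeds) + "\n")
        for locus in gm.locus_ids:
            rec = meta[locus]
            vals = [cols[b].get(locus) for b in breeds]
            fh.write(f"{locus}\t{rec.chromosome}\t{rec.position_bp}\t"
                     + "\t".join("NA" if v is None else f"{v:.6f}"
                                 for v in vals) + "\n")
    print(f"wrote {args.out / 'fst_pairwise.tsv'} and fst_per_locus.tsv")


if __name__ == "__main__":
    main()
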