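#!/usr/bin/env python
"""Within-breed diversity table: n, H_E, H_O, F_IS with bootstrap CI,
percent polymorphic loci and the MAF spectrum per breed."""

import argparse
from pathlib import Path

from _common import DATA_DIR, OUT_DIR, load_post_qc
from goatpop.diversity import MAF_CLASS_NAMES, summarize_diversity


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=DATA_DIR)
    ap.add_argument("--out", type=Path, default=OUT_DIR)
    ap.add_argument("--bootstrap", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=42)
    args = ap.parse_args()

    gm, _, samples, _ = load_post_qc(args.data, args.out)
    rows = summarize_diversity(gm, samples, bootstrap_reps=args.bootstrap,
                               seed=args.seed)

    header = ["breed", "n", "H_E", "H_O", "F_IS", "F_IS_ci", "significant",
              "pct_polymorphic", "maf_mean±sd"] + list(MAF_CLASS_NAMES)
    print("\t".join(header))
    with (args.out / "diversity.tsv").open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in rows:
            ci = ("NA" if r.f_is_ci is None
                  else f"[{r.f_is_ci[0]:.4f},{r.f_is_ci[1]:.4f}]")
            line = "\t".join(
                [r.breed, str(r.n), f"{r.h_e:.2f}", f"{r.h_o:.2f}",
                 "NA" if r.f_is is None else f"{r.f_is:.4f}", ci,
                 str(r.f_is_significant), f"{r.pct_polymorphic:.1f}",
                 f"{r.maf_mean:.2f}±{r.maf_sd:.2f}"]
                + [str(c) for c in r.maf_class_counts]
            )
            print(line)
            fh.write(line + "\n")
    print(f"\nwrote {args.out / 'diversity.tsv'}")


if __name__ == "__main__":
    main()
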