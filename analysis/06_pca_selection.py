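#!/usr/bin/env python
"""PCA of the genotype matrix, per-SNP PC1 contributions, selection of SNPs
above 10× the uniform expectation, and validation of the selected set against
one-vs-rest FST mean+2SD thresholds."""

import argparse
import json
from pathlib import Path

from _common import DATA_DIR, OUT_DIR, load_post_qc
from goatpop.differentiation import fst_one_vs_rest
from goatpop.io_formats import as_dict
from goatpop.pca_selection import (
    run_pca,
    select_high_contribution,
    snp_contributions,
    validate_selected_by_fst,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=DATA_DIR)
    ap.add_argument("--out", type=Path, default=OUT_DIR)
    ap.add_argument("--component", type=int, default=1)
    ap.add_argument("--factor", type=float, default=10.0)
    ap.add_argument("--k", type=float, default=2.0)
    args = ap.parse_args()

    gm, snps, samples, _ = load_post_qc(args.data, args.out)
    pca = run_pca(gm)
    print(f"PC1 explains {pca.var_fraction[0] * 100:.1f}% of variance, "
          f"PC2 {pca.var_fraction[1] * 100:.1f}%")

    with (args.out / "pca_scores.tsv").open("w") as fh:
        k = min(10, pca.sdev.size)
        fh.write("sample_id\t" + "\t".join(f"PC{i + 1}" for i in range(k)) + "\n")
        for i, sid in enumerate(pca.sample_ids):
            fh.write(sid + "\t" + "\t".join(f"{v:.6g}" for v in
                                            pca.scores[i, :k]) + "\n")

    con = snp_contributions(pca, args.component)
    sel = select_high_contribution(con, args.factor)
    print(f"expected contribution {sel.expected_pct:.4f}%; threshold "
          f"{sel.threshold_pct:.4f}%; {len(sel.locus_ids)} SNPs selected")

    meta = {s.locus_id: s for s in snps}
    with (args.out / "selected_snps.tsv").open("w") as fh:
        fh.write("locus_id\tchromosome\tposition_bp\tcontribution_pct\n")
        for l, c in zip(sel.locus_ids, sel.contribution_pct):
            rec = meta[l]
            fh.write(f"{l}\t{rec.chromosome}\t{rec.position_bp}\t{c:.6g}\n")

    breeds = sorted({s.breed for s in samples})
    fst = {b: fst_one_vs_rest(gm, samples, b, bootstrap_reps=0) for b in breeds}
    val = validate_selected_by_fst(sel, fst, args.k, pca.locus_ids)
    for b, v in val.items():
        print(f"  {b} vs rest: {v.n_selected_above}/{v.n_selected_with_theta} "
              f"selected SNPs above mean+{args.k:g}SD "
              f"(threshold {v.threshold:.4f})")
    (args.out / "fst_validation.json").write_text(
        json.dumps({b: as_dict(v) for b, v in val.items()}, indent=1)
    )
    print(f"wrote selected_snps.tsv and fst_validation.json in {args.out}")


if __name__ == "__main__":
    main()
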