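#!/usr/bin/env python
"""Inter-individual Nei distances, complete-linkage dendrogram exported as a
Newick tree, AMOVA variance partition and the IBS kinship band."""

import argparse
from pathlib import Path

import numpy as np

from _common import DATA_DIR, OUT_DIR, load_post_qc
from goatpop.distance_amova import (
    amova,
    cap_infinite,
    hierarchical_cluster,
    ibs_kinship,
    nei_distance_matrix,
    tree_to_newick,
)
from goatpop.io_formats import write_distance_matrix, write_newick


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=DATA_DIR)
    ap.add_argument("--out", type=Path, default=OUT_DIR)
    ap.add_argument("--linkage", default="complete")
    ap.add_argument("--permutations", type=int, default=10_000)
    ap.add_argument("--seed", type=int, default=42)
    args = ap.parse_args()

    gm, _, samples, _ = load_post_qc(args.data, args.out)
    nei = nei_distance_matrix(gm)
    write_distance_matrix(nei, args.out / "nei_distances.tsv")
    finite = nei.values[np.isfinite(nei.values)]
    print(f"Nei distances among {gm.n_samples} individuals: "
          f"max {finite.max():.3f}")

    tree = hierarchical_cluster(cap_infinite(nei), args.linkage)
    write_newick(tree_to_newick(tree), args.out / "tree.nwk")
    print(f"wrote {args.linkage}-linkage tree to {args.out / 'tree.nwk'}")

    res = amova(nei, samples, args.permutations, args.seed)
    print(f"AMOVA: {res.pct_among:.2f}% among breeds, "
          f"{res.pct_within:.2f}% within (Phi_ST {res.phi_st:.4f}, "
          f"p {res.p_value:.2g} from {res.permutations} permutations)")
    with (args.out / "amova.tsv").open("w") as fh:
        fh.write("component\tdf\tSS\tsigma2\tpct\n")
        fh.write(f"among_populations\t{res.df_among}\t{res.ss_among:.6f}\t"
                 f"{res.sigma2_among:.6g}\t{res.pct_among:.2f}\n")
        fh.write(f"within_populations\t{res.df_within}\t{res.ss_within:.6f}\t"
                 f"{res.sigma2_within:.6g}\t{res.pct_within:.2f}\n")

    kin = ibs_kinship(gm)
    off = kin.values[~np.eye(gm.n_samples, dtype=bool)]
    print(f"IBS kinship off-diagonal: {off.min():.2f}-{off.max():.2f} "
          f"(mean {off.mean():.2f})")


if __name__ == "__main__":
    main()
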