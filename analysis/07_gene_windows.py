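#!/usr/bin/env python
"""Extract genes inside 500 kb cis-windows around the selected SNPs and
report the deduplicated gene list."""

import argparse
from pathlib import Path

from _common import DATA_DIR, OUT_DIR, load_post_qc
from goatpop.gene_windows import build_windows, extract_genes
from goatpop.io_formats import read_snp_metadata


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=DATA_DIR)
    ap.add_argument("--out", type=Path, default=OUT_DIR)
    ap.add_argument("--window-kb", type=int, default=500,
                    help="total window width in kb")
    args = ap.parse_args()

    _, snps, _, genes = load_post_qc(args.data, args.out)
    selected = [
        line.split("\t")[0]
        for line in (args.out / "selected_snps.tsv").read_text().splitlines()[1:]
    ]
    meta = {s.locus_id: s for s in snps}
    windows = build_windows([meta[l] for l in selected],
                            half_width_bp=args.window_kb * 1000 // 2)
    report = extract_genes(windows, genes)

    with (args.out / "gene_windows.tsv").open("w") as fh:
        fh.write("locus_id\tchromosome\twindow_start\twindow_end\tgene_id\t"
                 "gene_start\tgene_end\n")
        for w, hits in zip(report.windows, report.genes_per_window):
            for g in hits:
                fh.write(f"{w.locus_id}\t{w.chromosome}\t{w.start_bp}\t"
                         f"{w.end_bp}\t{g.gene_id}\t{g.start_bp}\t{g.end_bp}\n")

    print(f"{len(windows)} windows of {args.window_kb} kb around selected SNPs")
    print(f"{report.unique_gene_count} unique genes overlap the windows")
    print(f"wrote {args.out / 'gene_windows.tsv'}")


if __name__ == "__main__":
    main()
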