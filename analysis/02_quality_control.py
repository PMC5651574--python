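#!/usr/bin/env python
"""Sequential locus QC (GenTrain → MAF → missingness → mapping) plus sample
call-rate screening; reports per-step removals and the HWE deviation count."""

import argparse
from pathlib import Path

from _common import DATA_DIR, OUT_DIR, load_dataset
from goatpop.qc import QcConfig, apply_qc


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=DATA_DIR)
    ap.add_argument("--out", type=Path, default=OUT_DIR)
    ap.add_argument("--gentrain-min", type=float, default=0.6)
    ap.add_argument("--maf-min", type=float, default=0.05)
    ap.add_argument("--missing-max", type=float, default=0.05)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    gm, snps, samples, _ = load_dataset(args.data)
    cfg = QcConfig(gentrain_min=args.gentrain_min, maf_min=args.maf_min,
                   missing_max=args.missing_max)
    filtered, report = apply_qc(gm, snps, cfg)

    print(f"{report.initial_loci} loci in; removed per step:")
    for name, count in report.steps:
        print(f"  {name:10s} {count}")
    print(f"{report.surviving_count} loci pass QC; "
          f"{report.hwe_fail_count} deviate from HWE at alpha "
          f"{report.hwe_alpha_used} (reported, not removed)")
    if report.removed_sample_ids:
        print("samples removed for low call rate:", report.removed_sample_ids)

    with (args.out / "qc_report.tsv").open("w") as fh:
        fh.write("step\tremoved\n")
        for name, count in report.steps:
            fh.write(f"{name}\t{count}\n")
    (args.out / "qc_surviving_loci.tsv").write_text(
        "\n".join(report.surviving_locus_ids) + "\n"
    )


if __name__ == "__main__":
    main()
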