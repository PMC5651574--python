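"""Shared plumbing for the numbered analysis drivers: default locations and
loading of the simulated dataset and its post-QC genotype matrix."""

from pathlib import Path

from goatpop.io_formats import (
    read_gene_annotation,
    read_genotypes,
    read_sample_map,
    read_snp_metadata,
)

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "results" / "data"
OUT_DIR = ROOT / "results" / "analysis"


def load_dataset(data_dir: Path = DATA_DIR):
    snps = read_snp_metadata(data_dir / "snps.tsv")
    gm, _ = read_genotypes(data_dir / "genotypes.tsv", "tsv_matrix", snps=snps)
    samples = read_sample_map(data_dir / "samples.tsv")
    genes = read_gene_annotation(data_dir / "genes.tsv")
    return gm, snps, samples, genes


def load_post_qc(data_dir: Path = DATA_DIR, out_dir: Path = OUT_DIR):
    gm, snps, samples, genes = load_dataset(data_dir)
    surviving = (out_dir / "qc_surviving_loci.tsv").read_text().split()
    return gm.subset_loci(surviving), snps, samples, genes
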