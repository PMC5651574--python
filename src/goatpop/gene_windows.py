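"""Genes inside fixed-width cis-windows around selected SNPs.

A window of total width 500 kb (±250 kb, clipped at position 1) is placed
around each selected SNP; a gene overlaps a window when any base is shared
(closed 1-based intervals).  Per-window gene lists keep duplicates across
windows; the global list is deduplicated by gene id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from goatpop.io_formats import GeneRecord, SnpRecord, ValidationError


@dataclass
class Window:
    locus_id: str
    chromosome: str
    start_bp: int
    end_bp: int


@dataclass
class WindowReport:
    windows: list[Window]
    genes_per_window: list[list[GeneRecord]]
    unique_genes: list[GeneRecord]

    @property
    def unique_gene_count(self) -> int:
        return len(self.unique_genes)


def _norm_chrom(chrom: str) -> str:
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c.upper()


def build_windows(
    snps: list[SnpRecord], half_width_bp: int = 250_000
) -> list[Window]:
    """Closed 1-based interval [max(1, pos−half_width), pos+half_width] per SNP.

    SNPs without a usable position are skipped with a warning.
    """
    if half_width_bp < 0:
        raise ValidationError("half_width_bp must be non-negative")
    windows = []
    for s in snps:
        if s.position_bp is None or s.position_bp < 1:
            warnings.warn(f"SNP {s.locus_id} lacks a position; skipped", stacklevel=2)
            continue
        windows.append(
            Window(
                s.locus_id,
                s.chromosome,
                max(1, s.position_bp - half_width_bp),
                s.position_bp + half_width_bp,
            )
        )
    return windows


def extract_genes(
    windows: list[Window], annotation: list[GeneRecord]
) -> WindowReport:
    """Overlap each window with the gene annotation.

    Chromosome labels are normalized ("chr1" ≡ "1", case-insensitive).  The
    global gene list is deduplicated by gene id and ordered by
    (chromosome, start).
    """
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in annotation:
        by_chrom.setdefault(_norm_chrom(g.chromosome), []).append(g)
    starts, ends, genes_sorted = {}, {}, {}
    for chrom, genes in by_chrom.items():
        genes.sort(key=lambda g: (g.start_bp, g.end_bp, g.gene_id))
        genes_sorted[chrom] = genes
        starts[chrom] = np.array([g.start_bp for g in genes])
        # running max of ends lets a binary search bound the overlap scan
        ends[chrom] = np.maximum.accumulate(np.array([g.end_bp for g in genes]))

    per_window: list[list[GeneRecord]] = []
    for w in windows:
        chrom = _norm_chrom(w.chromosome)
        hits: list[GeneRecord] = []
        if chrom in genes_sorted:
            gs = genes_sorted[chrom]
            # genes starting after the window end can never overlap
            hi = int(np.searchsorted(starts[chrom], w.end_bp, side="right"))
            # genes before the first index whose running-max end reaches the
            # window start cannot overlap either
            lo = int(np.searchsorted(ends[chrom], w.start_bp, side="left"))
            hits = [
                g
                for g in gs[lo:hi]
                if g.start_bp <= w.end_bp and g.end_bp >= w.start_bp
            ]
        per_window.append(hits)

    seen: dict[str, GeneRecord] = {}
    for hits in per_window:
        for g in hits:
            seen.setdefault(g.gene_id, g)
    unique = sorted(
        seen.values(), key=lambda g: (_norm_chrom(g.chromosome), g.start_bp, g.gene_id)
    )
    return WindowReport(windows, per_window, unique)
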