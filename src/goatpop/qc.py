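"""Sequential SNP-array quality control with per-step removal bookkeeping.

Filters are applied in a fixed order — GenTrain score, pooled minor allele
frequency, per-locus missingness, unmapped probes, multi-hit probes — and each
step's removal count refers to the loci that survived all previous steps, so
the counts sum exactly to initial − surviving.  Hardy-Weinberg deviation is
computed on the survivors and reported rather than filtered by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from goatpop.io_formats import GenotypeMatrix, MISSING, SnpRecord, ValidationError


class ConfigurationError(ValueError):
    """A filter is enabled but the metadata it needs is absent."""


@dataclass
class QcConfig:
    """Thresholds for the five sequential locus filters plus sample QC.

    ``None`` disables a threshold.  ``hwe_alpha`` is None by default: HWE
    deviation is counted and reported, not filtered.
    """

    gentrain_min: float | None = 0.6
    maf_min: float | None = 0.05
    missing_max: float | None = 0.05
    hwe_alpha: float | None = None
    require_unique_mapping: bool = True
    sample_call_rate_min: float | None = 0.95

    def __post_init__(self) -> None:
        for name in ("gentrain_min", "maf_min", "missing_max", "hwe_alpha",
                     "sample_call_rate_min"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")


@dataclass
class QcReport:
    """Bookkeeping of one sequential QC run; conservation is checked."""

    initial_loci: int
    steps: list[tuple[str, int]]
    surviving_locus_ids: list[str]
    hwe_fail_count: int = 0
    hwe_alpha_used: float | None = None
    removed_sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        removed = sum(n for _, n in self.steps)
        if self.initial_loci - removed != len(self.surviving_locus_ids):
            raise ValidationError(
                f"QC bookkeeping violated: {self.initial_loci} initial − {removed} "
                f"removed != {len(self.surviving_locus_ids)} surviving"
            )

    @property
    def surviving_count(self) -> int:
        return len(self.surviving_locus_ids)


def sequential_survivor_count(initial: int, removed_per_step: Sequence[int]) -> int:
    """Survivors after disjoint sequential removals (integer conservation)."""
    removed = sum(removed_per_step)
    if removed > initial:
        raise ValidationError(f"removed {removed} exceeds initial {initial}")
    return initial - removed


# ---------------------------------------------------------------------------
# per-locus statistics
# ---------------------------------------------------------------------------


def allele_frequency(
    gm: GenotypeMatrix, sample_idx: np.ndarray | None = None
) -> np.ndarray:
    """Per-locus B-allele frequency; NaN where a locus has no calls."""
    d = gm.dosage if sample_idx is None else gm.dosage[sample_idx]
    valid = d != MISSING
    n = valid.sum(axis=0)
    total = np.where(valid, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, total / (2.0 * n), np.nan)


def compute_maf(
    gm: GenotypeMatrix, sample_idx: np.ndarray | None = None
) -> np.ndarray:
    """Per-locus minor allele frequency min(p, 1−p) ∈ [0, 0.5].

    All-missing loci are flagged with a warning and returned as NaN.
    """
    p = allele_frequency(gm, sample_idx)
    if np.isnan(p).any():
        warnings.warn(
            f"{int(np.isnan(p).sum())} loci have no non-missing calls; MAF is NaN",
            stacklevel=2,
        )
    return np.minimum(p, 1.0 - p)


def missing_rate(gm: GenotypeMatrix) -> np.ndarray:
    """Per-locus fraction of missing calls."""
    return gm.missing_mask.mean(axis=0)


def sample_call_rate(gm: GenotypeMatrix) -> np.ndarray:
    """Per-sample fraction of non-missing calls."""
    return 1.0 - gm.missing_mask.mean(axis=1)


def genotype_counts(gm: GenotypeMatrix) -> np.ndarray:
    """(M, 3) counts of genotypes AA, AB, BB per locus."""
    return np.stack([(gm.dosage == k).sum(axis=0) for k in (0, 1, 2)], axis=1)


def hwe_chi2(counts) -> tuple[np.ndarray, np.ndarray]:
    """Chi-square (1 df) test of Hardy-Weinberg proportions per locus.

    ``counts`` is (n_AA, n_AB, n_BB) for one locus or an (M, 3) array.
    Monomorphic loci give chi2 = 0, p = 1.  No continuity correction.
    """
    c = np.atleast_2d(np.asarray(counts, dtype=float))
    n = c.sum(axis=1)
    if (n < 1).any():
        raise ValidationError("HWE test requires at least one genotype")
    p = (c[:, 1] + 2 * c[:, 2]) / (2 * n)
    q = 1.0 - p
    expected = np.stack([n * q * q, 2 * n * p * q, n * p * p], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(expected > 0, (c - expected) ** 2 / expected, 0.0)
    chi2 = terms.sum(axis=1)
    mono = (p == 0) | (p == 1)
    chi2 = np.where(mono, 0.0, chi2)
    pval = stats.chi2.sf(chi2, df=1)
    pval = np.where(mono, 1.0, pval)
    if np.ndim(counts) == 1:
        return float(chi2[0]), float(pval[0])
    return chi2, pval


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def apply_sample_qc(
    gm: GenotypeMatrix, min_call_rate: float
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop samples whose genotype call rate falls below the threshold."""
    rates = sample_call_rate(gm)
    keep = rates >= min_call_rate
    removed = [s for s, k in zip(gm.sample_ids, keep) if not k]
    if not removed:
        return gm, []
    kept_ids = [s for s, k in zip(gm.sample_ids, keep) if k]
    return gm.subset_samples(kept_ids), removed


def apply_qc(
    gm: GenotypeMatrix,
    snps: Sequence[SnpRecord],
    config: QcConfig | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Run the sequential locus filters and (optionally) sample QC.

    Returns the filtered matrix and a :class:`QcReport` whose per-step removal
    counts sum exactly to initial − surviving.
    """
    config = config or QcConfig()
    meta = {s.locus_id: s for s in snps}
    missing_meta = [l for l in gm.locus_ids if l not in meta]
    if missing_meta:
        raise ConfigurationError(
            f"{len(missing_meta)} loci lack SNP metadata (first: {missing_meta[0]!r})"
        )

    removed_samples: list[str] = []
    if config.sample_call_rate_min is not None:
        gm, removed_samples = apply_sample_qc(gm, config.sample_call_rate_min)

    initial = gm.n_loci
    alive = np.ones(initial, dtype=bool)
    steps: list[tuple[str, int]] = []

    def _mark(name: str, fail_among_alive: np.ndarray) -> None:
        fail = alive & fail_among_alive
        steps.append((name, int(fail.sum())))
        alive[fail] = False

    # 1. GenTrain cluster-quality score
    if config.gentrain_min is not None:
        scores = [meta[l].gentrain_score for l in gm.locus_ids]
        if any(s is None for s in scores):
            raise ConfigurationError(
                "GenTrain filter enabled but some loci lack gentrain_score"
            )
        _mark("gentrain", np.asarray(scores, dtype=float) < config.gentrain_min)

    # 2. pooled-sample MAF
    if config.maf_min is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            maf = compute_maf(gm)
        _mark("maf", np.isnan(maf) | (maf < config.maf_min))

    # 3. per-locus missingness
    if config.missing_max is not None:
        _mark("missing", missing_rate(gm) > config.missing_max)

    # 4./5. probe mapping against the reference genome
    if config.require_unique_mapping:
        hits_list = [meta[l].mapping_hits for l in gm.locus_ids]
        if any(h is None for h in hits_list):
            raise ConfigurationError(
                "mapping filter enabled but some loci lack mapping_hits"
            )
        hits = np.asarray(hits_list, dtype=int)
        _mark("unmapped", hits == 0)
        _mark("multi_hit", hits > 1)

    surviving = [l for l, a in zip(gm.locus_ids, alive) if a]
    filtered = gm.subset_loci(surviving)

    # HWE on survivors: counted (and optionally filtered) at the pooled level
    hwe_fail = 0
    hwe_alpha_used = config.hwe_alpha
    if filtered.n_loci:
        alpha = config.hwe_alpha if config.hwe_alpha is not None else 0.05
        _, pvals = hwe_chi2(genotype_counts(filtered))
        hwe_fail = int((pvals < alpha).sum())
        hwe_alpha_used = alpha
        if config.hwe_alpha is not None:
            keep = pvals >= config.hwe_alpha
            steps.append(("hwe", int((~keep).sum())))
            surviving = [l for l, k in zip(surviving, keep) if k]
            filtered = filtered.subset_loci(surviving)

    report = QcReport(
        initial_loci=initial,
        steps=steps,
        surviving_locus_ids=surviving,
        hwe_fail_count=hwe_fail,
        hwe_alpha_used=hwe_alpha_used,
        removed_sample_ids=removed_samples,
    )
    return filtered, report
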