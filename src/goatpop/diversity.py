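"""Within-breed diversity: H_O, H_E, F_IS with bootstrap CI, MAF spectra.

F_IS follows Wright's multilocus ratio-of-means form, 1 − H̄_O/H̄_E, which is
stable against near-monomorphic loci; its confidence interval is a
bias-corrected percentile bootstrap over loci (1000 replicates by default),
and the estimate is called significantly different from zero when the CI
excludes 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from goatpop.io_formats import GenotypeMatrix, MISSING, SampleRecord, ValidationError
from goatpop.qc import allele_frequency

#: MAF class edges: rare [0, 0.05), intermediate [0.05, 0.10),
#: common [0.10, 0.30), frequent [0.30, 0.50]
MAF_CLASS_EDGES = (0.05, 0.10, 0.30)
MAF_CLASS_NAMES = ("rare", "intermediate", "common", "frequent")


@dataclass
class FisResult:
    estimate: float
    ci_low: float
    ci_high: float
    significant: bool
    n_bootstrap: int


@dataclass
class DiversitySummary:
    """One row of a per-breed diversity table."""

    breed: str
    n: int
    h_e: float
    h_o: float
    f_is: float | None
    f_is_ci: tuple[float, float] | None
    f_is_significant: bool | None
    pct_polymorphic: float
    maf_mean: float
    maf_sd: float
    maf_class_counts: tuple[int, int, int, int]


def _subset(gm: GenotypeMatrix, sample_idx) -> np.ndarray:
    d = gm.dosage if sample_idx is None else gm.dosage[np.asarray(sample_idx)]
    if d.shape[0] == 0:
        raise ValidationError("empty sample subset")
    return d


def observed_heterozygosity(
    gm: GenotypeMatrix, sample_idx=None
) -> tuple[np.ndarray, float]:
    """Per-locus heterozygote proportion and its unweighted mean over loci.

    Loci without any non-missing call in the subset are NaN and excluded from
    the mean.
    """
    d = _subset(gm, sample_idx)
    valid = d != MISSING
    n = valid.sum(axis=0)
    het = (d == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = np.where(n > 0, het / n, np.nan)
    return per_locus, float(np.nanmean(per_locus))


def expected_heterozygosity(
    gm: GenotypeMatrix, sample_idx=None, unbiased: bool = True
) -> tuple[np.ndarray, float]:
    """Per-locus gene diversity 2p(1−p) and its mean over loci.

    With ``unbiased`` the per-locus value carries Nei's small-sample factor
    2n/(2n−1), n being the locus's non-missing diploid count.
    """
    d = _subset(gm, sample_idx)
    valid = d != MISSING
    n = valid.sum(axis=0)
    total = np.where(valid, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, total / (2.0 * n), np.nan)
    he = 2.0 * p * (1.0 - p)
    if unbiased:
        with np.errstate(invalid="ignore", divide="ignore"):
            he = np.where(n > 0, he * (2.0 * n) / np.maximum(2.0 * n - 1.0, 1.0), np.nan)
    return he, float(np.nanmean(he))


def _bc_percentile_ci(
    boot: np.ndarray, estimate: float, alpha: float
) -> tuple[float, float]:
    """Bias-corrected (BC, no acceleration) percentile bootstrap interval."""
    boot = boot[np.isfinite(boot)]
    prop = np.mean(boot < estimate)
    prop = min(max(prop, 1.0 / (len(boot) + 1)), 1.0 - 1.0 / (len(boot) + 1))
    z0 = stats.norm.ppf(prop)
    z = stats.norm.ppf([alpha / 2.0, 1.0 - alpha / 2.0])
    adj = stats.norm.cdf(2.0 * z0 + z)
    lo, hi = np.quantile(boot, adj)
    return float(lo), float(hi)


def fis(
    gm: GenotypeMatrix,
    sample_idx=None,
    bootstrap_reps: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    unbiased: bool = True,
) -> FisResult:
    """Wright's F_IS = 1 − H̄_O/H̄_E with a BC percentile bootstrap CI.

    Bootstrap resamples loci with replacement; significance means the
    (1−alpha) CI excludes zero.
    """
    d = _subset(gm, sample_idx)
    if d.shape[0] < 2:
        raise ValidationError("F_IS needs at least 2 samples")
    ho, _ = observed_heterozygosity(gm, sample_idx)
    he, _ = expected_heterozygosity(gm, sample_idx, unbiased=unbiased)
    usable = np.isfinite(ho) & np.isfinite(he)
    ho, he = ho[usable], he[usable]
    if he.size < 2:
        raise ValidationError("F_IS bootstrap needs at least 2 usable loci")
    mean_he = he.mean()
    if mean_he == 0:
        raise ValidationError("mean expected heterozygosity is zero; F_IS undefined")
    estimate = 1.0 - ho.mean() / mean_he

    rng = np.random.default_rng(seed)
    m = he.size
    boot = np.empty(bootstrap_reps)
    for b in range(bootstrap_reps):
        idx = rng.integers(0, m, size=m)
        he_b = he[idx].mean()
        boot[b] = 1.0 - ho[idx].mean() / he_b if he_b > 0 else np.nan
    lo, hi = _bc_percentile_ci(boot, estimate, alpha)
    return FisResult(float(estimate), lo, hi, not (lo <= 0.0 <= hi), bootstrap_reps)


def pct_polymorphic(gm: GenotypeMatrix, sample_idx=None) -> float:
    """Percent of called loci at which both alleles are observed in the subset."""
    d = _subset(gm, sample_idx)
    valid = d != MISSING
    n = valid.sum(axis=0)
    total = np.where(valid, d, 0).sum(axis=0)
    called = n > 0
    if not called.any():
        raise ValidationError("no loci with calls in subset")
    poly = called & (total > 0) & (total < 2 * n)
    return 100.0 * poly.sum() / called.sum()


def maf_class_histogram(mafs) -> np.ndarray:
    """Counts over the four MAF classes (rare/intermediate/common/frequent).

    Bins are [0, 0.05), [0.05, 0.10), [0.10, 0.30), [0.30, 0.50]; the stated
    class endpoints overlap, so boundaries are assigned to the upper class
    except 0.50 which closes the last bin.
    """
    mafs = np.asarray(mafs, dtype=float)
    mafs = mafs[np.isfinite(mafs)]
    if mafs.size == 0:
        return np.zeros(4, dtype=int)
    if (mafs < 0).any() or (mafs > 0.5).any():
        raise ValidationError("MAF outside [0, 0.5]")
    cls = np.searchsorted(np.asarray(MAF_CLASS_EDGES), mafs, side="right")
    return np.bincount(cls, minlength=4).astype(int)


def summarize_diversity(
    gm: GenotypeMatrix,
    samples: list[SampleRecord],
    bootstrap_reps: int = 1000,
    seed: int | None = None,
    unbiased: bool = True,
    include_total: bool = True,
) -> list[DiversitySummary]:
    """Per-breed (plus pooled-total) diversity table.

    The total row carries no F_IS (pooling breeds would fold the Wahlund
    effect into an apparent inbreeding signal).
    """
    by_breed: dict[str, list[str]] = {}
    for rec in samples:
        by_breed.setdefault(rec.breed, []).append(rec.sample_id)
    groups: list[tuple[str, list[str]]] = sorted(by_breed.items())
    if include_total:
        groups.append(("Total", [r.sample_id for r in samples]))

    rows = []
    for breed, ids in groups:
        idx = gm.sample_indices(ids)
        _, mean_ho = observed_heterozygosity(gm, idx)
        _, mean_he = expected_heterozygosity(gm, idx, unbiased=unbiased)
        maf = np.minimum(allele_frequency(gm, idx), 1 - allele_frequency(gm, idx))
        maf = maf[np.isfinite(maf)]
        if breed == "Total":
            f = None
        else:
            f = fis(gm, idx, bootstrap_reps=bootstrap_reps, seed=seed)
        rows.append(
            DiversitySummary(
                breed=breed,
                n=len(ids),
                h_e=mean_he,
                h_o=mean_ho,
                f_is=None if f is None else f.estimate,
                f_is_ci=None if f is None else (f.ci_low, f.ci_high),
                f_is_significant=None if f is None else f.significant,
                pct_polymorphic=pct_polymorphic(gm, idx),
                maf_mean=float(maf.mean()),
                maf_sd=float(maf.std(ddof=1)),
                maf_class_counts=tuple(maf_class_histogram(maf)),
            )
        )
    return rows
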