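"""Weir-Cockerham FST: pairwise and one-vs-rest, with bootstrap significance.

The estimator is Weir & Cockerham's (1984) θ for diploid two-allele data with
unequal sample sizes.  Per-locus variance components a (among populations),
b (among individuals within populations) and c (within individuals) are
combined across loci as a ratio of sums, θ = Σa / Σ(a+b+c), never as a mean
of per-locus ratios.  Negative estimates are legitimate for this estimator
and are reported as-is.  Confidence intervals come from a percentile
bootstrap over loci; a contrast is significant when the (1−alpha) CI
excludes zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from goatpop.io_formats import GenotypeMatrix, MISSING, SampleRecord, ValidationError


@dataclass
class FstEstimate:
    """Multilocus θ for one contrast plus the per-locus vector behind it."""

    contrast: tuple[str, str]
    theta: float
    ci_low: float | None
    ci_high: float | None
    significant: bool | None
    alpha: float | None
    locus_ids: list[str]
    theta_per_locus: np.ndarray = field(repr=False)
    a: np.ndarray = field(repr=False)
    denom: np.ndarray = field(repr=False)
    suggestive: bool | None = None


def wc_components(
    dosage_by_pop: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus WC 1984 variance components (a, b, c) and a usability mask.

    ``dosage_by_pop`` holds one (n_i, M) dosage array per population with
    ``MISSING`` entries allowed.  A locus is unusable when any population has
    no calls there or the total variance a+b+c is zero (monomorphic).
    """
    r = len(dosage_by_pop)
    if r < 2:
        raise ValidationError("need at least 2 populations")
    n_list, p_list, h_list = [], [], []
    for d in dosage_by_pop:
        if d.shape[0] < 1:
            raise ValidationError("population with no samples")
        valid = d != MISSING
        n_i = valid.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(valid, d, 0).sum(axis=0) / (2.0 * n_i)
            h_i = (d == 1).sum(axis=0) / n_i
        n_list.append(n_i)
        p_list.append(p_i)
        h_list.append(h_i)
    n = np.stack(n_list)      # (r, M) per-pop non-missing diploid counts
    p = np.stack(p_list)      # (r, M) per-pop B-allele frequencies
    h = np.stack(h_list)      # (r, M) per-pop observed het proportions

    usable = (n >= 1).all(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_sum = n.sum(axis=0)
        nbar = n_sum / r
        nc = (n_sum - (n**2).sum(axis=0) / n_sum) / (r - 1.0)
        pbar = (n * p).sum(axis=0) / n_sum
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n * h).sum(axis=0) / n_sum

        inner = pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0
        a = nbar / nc * (s2 - inner / (nbar - 1.0))
        b = nbar / (nbar - 1.0) * (
            pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0)
            / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0

    denom = a + b + c
    usable &= np.isfinite(denom) & (denom != 0.0)
    return a, b, c, usable


def wc_theta_per_locus(
    dosage_by_pop: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus θ = a/(a+b+c); NaN where the locus is unusable."""
    a, b, c, usable = wc_components(dosage_by_pop)
    denom = a + b + c
    theta = np.full(a.shape, np.nan)
    theta[usable] = a[usable] / denom[usable]
    return theta, usable


def multilocus_theta(a: np.ndarray, denom: np.ndarray) -> float:
    """θ as the ratio of summed variance components over usable loci."""
    total = denom.sum()
    if total == 0:
        raise ValidationError("no variance at any usable locus")
    return float(a.sum() / total)


def _bootstrap_ci(
    a: np.ndarray,
    denom: np.ndarray,
    reps: int,
    alpha: float,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Percentile CI of multilocus θ from resampling loci with replacement."""
    m = a.size
    boot = np.empty(reps)
    for bb in range(reps):
        idx = rng.integers(0, m, size=m)
        d = denom[idx].sum()
        boot[bb] = a[idx].sum() / d if d != 0 else np.nan
    boot = boot[np.isfinite(boot)]
    lo, hi = np.quantile(boot, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def _estimate(
    contrast: tuple[str, str],
    dosage_by_pop: list[np.ndarray],
    locus_ids: list[str],
    bootstrap_reps: int,
    alpha: float,
    rng: np.random.Generator,
    suggestive_alpha: float | None = 0.01,
) -> FstEstimate:
    a, b, c, usable = wc_components(dosage_by_pop)
    denom = (a + b + c)[usable]
    a_use = a[usable]
    ids = [l for l, u in zip(locus_ids, usable) if u]
    theta = multilocus_theta(a_use, denom)
    per_locus = a_use / denom

    ci_low = ci_high = None
    significant = suggestive = None
    if bootstrap_reps > 0:
        ci_low, ci_high = _bootstrap_ci(a_use, denom, bootstrap_reps, alpha, rng)
        significant = not (ci_low <= 0.0 <= ci_high)
        if suggestive_alpha is not None:
            lo2, hi2 = _bootstrap_ci(
                a_use, denom, bootstrap_reps, suggestive_alpha, rng
            )
            suggestive = not (lo2 <= 0.0 <= hi2)
    return FstEstimate(
        contrast=contrast,
        theta=theta,
        ci_low=ci_low,
        ci_high=ci_high,
        significant=significant,
        alpha=alpha if bootstrap_reps > 0 else None,
        locus_ids=ids,
        theta_per_locus=per_locus,
        a=a_use,
        denom=denom,
        suggestive=suggestive,
    )


def _groups(
    gm: GenotypeMatrix, samples: list[SampleRecord]
) -> dict[str, np.ndarray]:
    by_breed: dict[str, list[str]] = {}
    for rec in samples:
        by_breed.setdefault(rec.breed, []).append(rec.sample_id)
    return {b: gm.sample_indices(ids) for b, ids in sorted(by_breed.items())}


def fst_pairwise(
    gm: GenotypeMatrix,
    samples: list[SampleRecord],
    bootstrap_reps: int = 1000,
    alpha: float = 0.005,
    seed: int | None = None,
) -> dict[tuple[str, str], FstEstimate]:
    """WC θ for every breed pair with bootstrap significance.

    ``alpha`` defaults to 0.005 — a Bonferroni adjustment of 0.05 over the
    pairwise tests among four breeds (with a suggestive tier at 0.01).
    """
    groups = _groups(gm, samples)
    if len(groups) < 2:
        raise ValidationError("pairwise FST needs at least 2 breeds")
    for b, idx in groups.items():
        if idx.size < 2:
            raise ValidationError(f"breed {b!r} has fewer than 2 samples")
    rng = np.random.default_rng(seed)
    out = {}
    for b1, b2 in itertools.combinations(sorted(groups), 2):
        out[(b1, b2)] = _estimate(
            (b1, b2),
            [gm.dosage[groups[b1]], gm.dosage[groups[b2]]],
            gm.locus_ids,
            bootstrap_reps,
            alpha,
            rng,
        )
    return out


def fst_one_vs_rest(
    gm: GenotypeMatrix,
    samples: list[SampleRecord],
    target: str,
    bootstrap_reps: int = 1000,
    alpha: float = 0.005,
    seed: int | None = None,
) -> FstEstimate:
    """WC θ of one breed against the other breeds pooled into one population.

    The per-locus θ vector is retained for outlier thresholding.
    """
    groups = _groups(gm, samples)
    if target not in groups:
        raise ValidationError(f"unknown breed label {target!r}")
    rest_idx = np.concatenate([idx for b, idx in groups.items() if b != target])
    if rest_idx.size == 0:
        raise ValidationError("rest group is empty")
    rng = np.random.default_rng(seed)
    return _estimate(
        (target, "rest"),
        [gm.dosage[groups[target]], gm.dosage[rest_idx]],
        gm.locus_ids,
        bootstrap_reps,
        alpha,
        rng,
    )
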