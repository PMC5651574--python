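"""PCA of the genotype matrix and contribution-based SNP selection.

The decomposition mirrors R's ``prcomp``: per-locus mean imputation of
missing dosages, column centering, no variance scaling by default, thin SVD.
A SNP's contribution to a component is the FactoMineR-style share of squared
variable-component correlations: r = loading × component sd, cos² = r², and
contribution% = 100·cos²/Σcos² — algebraically identical to 100·loading²
because the component sd cancels and loading columns are unit norm.  SNPs
whose contribution exceeds ``factor`` times the uniform expectation 100/M are
selected, and selections are validated against per-locus one-vs-rest FST
using a genome-wide mean + k·SD threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from goatpop.differentiation import FstEstimate
from goatpop.io_formats import GenotypeMatrix, MISSING, ValidationError


@dataclass
class PcaResult:
    sample_ids: list[str]
    locus_ids: list[str]
    scores: np.ndarray          # (N, K)
    loadings: np.ndarray        # (M, K), columns unit norm
    sdev: np.ndarray            # (K,) component standard deviations
    var_fraction: np.ndarray    # (K,) fraction of total variance

    def __post_init__(self) -> None:
        k = self.sdev.size
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(k), atol=1e-8):
            raise ValidationError("loading columns are not orthonormal")
        if (np.diff(self.var_fraction) > 1e-12).any():
            raise ValidationError("variance fractions must be non-increasing")


@dataclass
class ContributionTable:
    """Per-SNP representation quality and contribution for one component."""

    component: int
    locus_ids: list[str]
    correlation: np.ndarray
    cos2: np.ndarray
    contribution_pct: np.ndarray


@dataclass
class SelectedSnpSet:
    component: int
    expected_pct: float
    factor: float
    threshold_pct: float
    locus_ids: list[str]
    contribution_pct: np.ndarray = field(repr=False)


@dataclass
class OutlierValidation:
    """Per-contrast check of selected SNPs against genome-wide FST spread."""

    contrast: str
    theta_mean: float
    theta_sd: float
    threshold: float
    n_selected_above: int
    n_selected_with_theta: int
    n_genomewide_above: int
    n_genomewide: int


def run_pca(
    genotypes: GenotypeMatrix | np.ndarray, scale: bool = False
) -> PcaResult:
    """prcomp-equivalent PCA of samples × loci dosages.

    Missing dosages are mean-imputed per locus before centering.  The sign of
    each component is fixed so its largest-magnitude loading is positive.
    """
    if isinstance(genotypes, GenotypeMatrix):
        x = genotypes.dosage.astype(float)
        x[genotypes.missing_mask] = np.nan
        sample_ids, locus_ids = genotypes.sample_ids, genotypes.locus_ids
    else:
        x = np.asarray(genotypes, dtype=float).copy()
        sample_ids = [f"S{i}" for i in range(x.shape[0])]
        locus_ids = [f"L{j}" for j in range(x.shape[1])]
    n, m = x.shape
    if n < 2 or m < 2:
        raise ValidationError("PCA needs at least 2 samples and 2 loci")
    if np.isnan(x).all(axis=0).any():
        raise ValidationError("locus with no calls at all; run QC first")
    col_mean = np.nanmean(x, axis=0)
    nan_idx = np.where(np.isnan(x))
    x[nan_idx] = col_mean[nan_idx[1]]
    x -= x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValidationError("cannot scale zero-variance loci")
        x /= sd

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # fix component signs: largest-|loading| entry positive
    flip = vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)] < 0
    vt[flip] *= -1.0
    u[:, flip] *= -1.0
    sdev = s / np.sqrt(n - 1.0)
    var = s**2
    return PcaResult(
        sample_ids=list(sample_ids),
        locus_ids=list(locus_ids),
        scores=u * s,
        loadings=vt.T,
        sdev=sdev,
        var_fraction=var / var.sum(),
    )


def snp_contributions(pca: PcaResult, component: int = 1) -> ContributionTable:
    """Correlation, cos² and contribution% of every SNP for one component.

    ``component`` is 1-based.  The contribution is also checked against the
    closed form 100·loading², which must agree to within 1e-9.
    """
    k = component - 1
    if not 0 <= k < pca.sdev.size:
        raise ValidationError(f"component {component} out of range")
    loading = pca.loadings[:, k]
    sd = pca.sdev[k]
    r = loading * sd
    cos2 = r**2
    total = cos2.sum()
    if total == 0:
        import warnings

        warnings.warn(f"component {component} has zero variance", stacklevel=2)
        contrib = np.zeros_like(cos2)
    else:
        contrib = 100.0 * cos2 / total
        assert np.allclose(contrib, 100.0 * loading**2, atol=1e-9), (
            "contribution should equal 100*loading^2 for unit-norm loadings"
        )
    return ContributionTable(component, pca.locus_ids, r, cos2, contrib)


def select_high_contribution(
    contribs: ContributionTable, factor: float = 10.0
) -> SelectedSnpSet:
    """SNPs contributing at least ``factor`` × the uniform expectation 100/M.

    The comparison is inclusive (≥), deterministic, with no tie-breaking.
    """
    m = len(contribs.locus_ids)
    expected = 100.0 / m
    threshold = factor * expected
    sel = contribs.contribution_pct >= threshold
    return SelectedSnpSet(
        component=contribs.component,
        expected_pct=expected,
        factor=factor,
        threshold_pct=threshold,
        locus_ids=[l for l, s in zip(contribs.locus_ids, sel) if s],
        contribution_pct=contribs.contribution_pct[sel],
    )


def individual_contributions(pca: PcaResult, n_components: int = 10) -> np.ndarray:
    """(N, K) percent contribution of each individual to each component:
    100·score²/Σscores²; columns sum to 100."""
    k = min(n_components, pca.sdev.size)
    sc2 = pca.scores[:, :k] ** 2
    totals = sc2.sum(axis=0)
    if (totals == 0).any():
        raise ValidationError("zero-variance component among the first "
                              f"{k} components")
    return 100.0 * sc2 / totals


def validate_selected_by_fst(
    selected: SelectedSnpSet,
    fst_by_contrast: dict[str, FstEstimate],
    k: float = 2.0,
    pca_locus_ids: list[str] | None = None,
) -> dict[str, OutlierValidation]:
    """Check selected SNPs against genome-wide per-locus FST per contrast.

    For each one-vs-rest contrast the threshold is mean(θ) + k·sd(θ) over all
    usable loci; a SNP counts as above when its θ is strictly greater.
    Undefined per-locus θ (including selected SNPs a contrast had to skip) is
    excluded from mean/sd and from the counts.  When ``pca_locus_ids`` is
    given, every contrast's locus universe must derive from it, otherwise the
    locus sets are misaligned and an error is raised.
    """
    pca_set = set(pca_locus_ids) if pca_locus_ids is not None else None
    out = {}
    sel_set = selected.locus_ids
    for name, est in fst_by_contrast.items():
        if pca_set is not None:
            stray = [l for l in est.locus_ids if l not in pca_set]
            if stray:
                raise ValidationError(
                    f"contrast {name!r}: {len(stray)} loci outside the PCA "
                    f"locus set (first: {stray[0]!r}); locus sets misaligned"
                )
        pos = {l: i for i, l in enumerate(est.locus_ids)}
        theta = est.theta_per_locus
        finite = np.isfinite(theta)
        mean = float(theta[finite].mean())
        sd = float(theta[finite].std(ddof=1)) if finite.sum() > 1 else 0.0
        threshold = mean + k * sd
        sel_theta = np.array(
            [theta[pos[l]] if l in pos else np.nan for l in sel_set]
        )
        sel_finite = np.isfinite(sel_theta)
        out[name] = OutlierValidation(
            contrast=name,
            theta_mean=mean,
            theta_sd=sd,
            threshold=threshold,
            n_selected_above=int((sel_theta[sel_finite] > threshold).sum()),
            n_selected_with_theta=int(sel_finite.sum()),
            n_genomewide_above=int((theta[finite] > threshold).sum()),
            n_genomewide=int(finite.sum()),
        )
    return out
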