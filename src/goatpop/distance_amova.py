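"""Genetic distances, hierarchical clustering, AMOVA and IBS kinship.

Distances between individuals treat each individual as a two-allele frequency
profile (B-allele frequency 0, 0.5 or 1 per locus); missing calls are handled
pairwise, not by global locus deletion.  Clustering delegates to
scipy's agglomerative linkage (complete by default, matching R's hclust
default) and can be exported as a Newick string with merge heights as branch
lengths.  AMOVA is the two-level Excoffier (1992) decomposition of squared
distances among and within populations with a permutation test on Φ_ST.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from goatpop.io_formats import (
    DistanceMatrix,
    GenotypeMatrix,
    MISSING,
    SampleRecord,
    ValidationError,
)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def nei_distance(x_freq, y_freq) -> float:
    """Nei's (1972) standard distance between two allele-frequency profiles.

    ``x_freq``/``y_freq`` are per-locus B-allele frequencies over the same
    loci (complete).  D = −ln(J_XY/√(J_X·J_Y)) with the J terms averaged over
    loci; zero shared identity (J_XY = 0) returns +inf.
    """
    x = np.asarray(x_freq, dtype=float)
    y = np.asarray(y_freq, dtype=float)
    if x.shape != y.shape or x.size == 0:
        raise ValidationError("frequency profiles must be same-length and non-empty")
    jxy = np.mean(x * y + (1 - x) * (1 - y))
    jx = np.mean(x**2 + (1 - x) ** 2)
    jy = np.mean(y**2 + (1 - y) ** 2)
    if jx == 0 or jy == 0:
        raise ValidationError("zero within-unit identity; Nei D undefined")
    if jxy == 0:
        return float("inf")
    return float(-np.log(jxy / np.sqrt(jx * jy)))


def nei_distance_matrix(gm: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise Nei (1972) distances between individuals.

    J terms are averaged over each pair's pairwise-complete loci.  Pairs with
    zero shared identity get +inf (reported distinctly; cap before clustering
    with :func:`cap_infinite`).
    """
    x = gm.dosage.astype(float) / 2.0
    m = (~gm.missing_mask).astype(float)
    xm = np.where(m > 0, x, 0.0)
    u = xm * m
    v = (1.0 - xm) * m
    w = (xm**2 + (1.0 - xm) ** 2) * m  # per-locus within-individual identity

    pair_loci = m @ m.T
    if (pair_loci < 1).any():
        i, j = np.argwhere((pair_loci < 1) & ~np.eye(gm.n_samples, dtype=bool))[0]
        raise ValidationError(
            f"no pairwise-complete loci between {gm.sample_ids[i]} and "
            f"{gm.sample_ids[j]}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        jxy = (u @ u.T + v @ v.T) / pair_loci
        jx = (w @ m.T) / pair_loci
        jy = (m @ w.T) / pair_loci
        d = -np.log(jxy / np.sqrt(jx * jy))
    d[jxy == 0] = np.inf
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)  # clamp −0.0 / roundoff on identical profiles
    return DistanceMatrix(gm.sample_ids, (d + d.T) / 2.0)


def reynolds_distance(p1, p2, n1: float, n2: float) -> float:
    """Reynolds-Weir-Cockerham (1983) coancestry distance between two
    populations: the least-squares moment estimator of θ under pure drift,
    summed over loci.

    Per locus, with sample frequencies p̃ and diploid sample sizes n_i, the
    numerator (p̃₁−p̃₂)² − p̃₁q̃₁/(2n₁−1) − p̃₂q̃₂/(2n₂−1) is unbiased for
    2θp̄q̄ and the denominator p̃₁q̃₂ + p̃₂q̃₁ for 2p̄q̄, so the ratio of sums
    estimates the coancestry θ.  Negative estimates are floored at 0; a fixed
    difference gives exactly 1.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape or p1.size == 0:
        raise ValidationError("frequency profiles must be same-length and non-empty")
    q1, q2 = 1.0 - p1, 1.0 - p2
    num = (p1 - p2) ** 2 - p1 * q1 / (2.0 * n1 - 1.0) - p2 * q2 / (2.0 * n2 - 1.0)
    den = p1 * q2 + p2 * q1
    den_sum = den.sum()
    if den_sum == 0:
        return 0.0
    return float(max(num.sum() / den_sum, 0.0))


def reynolds_distance_matrix(
    gm: GenotypeMatrix, samples: list[SampleRecord]
) -> DistanceMatrix:
    """Pairwise Reynolds distances between breeds (population level)."""
    by_breed: dict[str, list[str]] = {}
    for rec in samples:
        by_breed.setdefault(rec.breed, []).append(rec.sample_id)
    labels = sorted(by_breed)
    freqs, sizes = {}, {}
    for b in labels:
        idx = gm.sample_indices(by_breed[b])
        d = gm.dosage[idx]
        valid = d != MISSING
        n = valid.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[b] = np.where(valid, d, 0).sum(axis=0) / (2.0 * n)
        sizes[b] = idx.size
    values = np.zeros((len(labels), len(labels)))
    for i, b1 in enumerate(labels):
        for j in range(i + 1, len(labels)):
            b2 = labels[j]
            ok = np.isfinite(freqs[b1]) & np.isfinite(freqs[b2])
            values[i, j] = values[j, i] = reynolds_distance(
                freqs[b1][ok], freqs[b2][ok], sizes[b1], sizes[b2]
            )
    return DistanceMatrix(labels, values)


def _pairwise_abs_diff(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(Σ|g_i − g_j|, #pairwise-complete loci) for all sample pairs.

    Uses indicator-matrix products so the whole computation is three matmuls.
    """
    m = (~gm.missing_mask).astype(float)
    ind = [((gm.dosage == k) & ~gm.missing_mask).astype(float) for k in (0, 1, 2)]
    s01 = ind[0] @ ind[1].T
    s12 = ind[1] @ ind[2].T
    s02 = ind[0] @ ind[2].T
    total = (s01 + s01.T) + (s12 + s12.T) + 2.0 * (s02 + s02.T)
    return total, m @ m.T


def manhattan_distance_matrix(gm: GenotypeMatrix) -> DistanceMatrix:
    """Mean per-locus |dosage difference| between individuals.

    Normalizing by each pair's complete-locus count keeps missingness
    patterns from scaling distances.
    """
    total, pair_loci = _pairwise_abs_diff(gm)
    if (pair_loci < 1).any():
        raise ValidationError("a sample pair shares no called loci")
    d = total / pair_loci
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(gm.sample_ids, d)


@dataclass
class KinshipMatrix:
    """Symmetric allele-sharing similarity in [0, 1] with unit diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(f"values shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-9, rtol=0.0):
            raise ValidationError("kinship matrix not symmetric within 1e-9")
        if (self.values < -1e-9).any() or (self.values > 1 + 1e-9).any():
            raise ValidationError("kinship values outside [0, 1]")
        self.values = np.clip((self.values + self.values.T) / 2.0, 0.0, 1.0)


def ibs_kinship(gm: GenotypeMatrix) -> KinshipMatrix:
    """Identity-by-state kinship: K_ij = 1 − Σ|g_i−g_j| / (2·L_ij).

    The diagonal is exactly 1 on complete data.  Unrelated individuals typed
    on common biallelic SNPs sit well above 0.5 because allele sharing is
    frequent by chance.
    """
    total, pair_loci = _pairwise_abs_diff(gm)
    if (pair_loci < 1).any():
        raise ValidationError("a sample pair shares no called loci")
    k = 1.0 - total / (2.0 * pair_loci)
    np.fill_diagonal(k, 1.0)
    return KinshipMatrix(gm.sample_ids, k)


# ---------------------------------------------------------------------------
# hierarchical clustering and Newick export
# ---------------------------------------------------------------------------


@dataclass
class HierTree:
    """Agglomerative merge sequence (scipy linkage matrix) with leaf labels."""

    linkage: np.ndarray
    labels: list[str]
    method: str

    def __post_init__(self) -> None:
        heights = self.linkage[:, 2]
        if (np.diff(heights) < -1e-9).any():
            raise ValidationError("merge heights must be non-decreasing")


def cap_infinite(dm: DistanceMatrix, factor: float = 2.0) -> DistanceMatrix:
    """Replace +inf entries by factor × (largest finite distance)."""
    v = dm.values.copy()
    finite = np.isfinite(v)
    if finite.all():
        return dm
    v[~finite] = v[finite].max() * factor
    return DistanceMatrix(dm.labels, v)


def hierarchical_cluster(dm: DistanceMatrix, linkage: str = "complete") -> HierTree:
    """Agglomerative clustering of a distance matrix (complete linkage
    default, matching R's hclust)."""
    if not np.isfinite(dm.values).all():
        bad = np.argwhere(~np.isfinite(dm.values))
        pairs = [(dm.labels[i], dm.labels[j]) for i, j in bad[:5] if i < j]
        raise ValidationError(f"non-finite distances between pairs {pairs}")
    z = hierarchy.linkage(squareform(dm.values, checks=False), method=linkage)
    return HierTree(z, dm.labels, linkage)


def tree_to_newick(tree: HierTree) -> str:
    """Newick string with branch lengths = parent height − child height."""
    root, nodes = hierarchy.to_tree(tree.linkage, rd=True)

    def height(node) -> float:
        return 0.0 if node.is_leaf() else tree.linkage[node.id - len(tree.labels), 2]

    def recurse(node, parent_height: float) -> str:
        length = parent_height - height(node)
        if node.is_leaf():
            return f"{tree.labels[node.id]}:{length:.10g}"
        left = recurse(node.left, height(node))
        right = recurse(node.right, height(node))
        return f"({left},{right}):{length:.10g}"

    h = height(root)
    return f"({recurse(root.left, h)},{recurse(root.right, h)});"


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


@dataclass
class AmovaResult:
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    permutations: int
    p_value: float | None


def _ss_within(d2: np.ndarray, group_indices: list[np.ndarray]) -> float:
    ss = 0.0
    for idx in group_indices:
        sub = d2[np.ix_(idx, idx)]
        ss += sub.sum() / (2.0 * idx.size)
    return ss


def amova(
    dm: DistanceMatrix,
    samples: list[SampleRecord],
    permutations: int = 10000,
    seed: int | None = None,
) -> AmovaResult:
    """Two-level AMOVA (among/within populations) on squared distances.

    Variance components follow Excoffier et al. (1992): SS_total =
    Σ_{i<j} d²_ij/N, SS_within summed per group analogously, σ²_within =
    MS_within, σ²_among = (MS_among − MS_within)/n0.  The p-value is the
    permutation tail probability (1 + #{Φ* ≥ Φ}) / (1 + permutations) under
    random reassignment of individuals to groups of fixed sizes;
    ``permutations=0`` reports p as None.
    """
    pos = {s: i for i, s in enumerate(dm.labels)}
    by_group: dict[str, list[int]] = {}
    for rec in samples:
        if rec.sample_id in pos:
            by_group.setdefault(rec.breed, []).append(pos[rec.sample_id])
    if len(by_group) < 2:
        raise ValidationError("AMOVA needs at least 2 groups")
    sizes = [len(v) for v in by_group.values()]
    if min(sizes) < 2:
        raise ValidationError("AMOVA groups must have at least 2 individuals")
    groups = [np.array(v) for v in by_group.values()]
    all_idx = np.concatenate(groups)
    d2 = dm.values**2

    n_total = all_idx.size
    g = len(groups)
    sub_all = d2[np.ix_(all_idx, all_idx)]
    ss_total = sub_all.sum() / (2.0 * n_total)
    ss_within = _ss_within(d2, groups)
    ss_among = ss_total - ss_within

    df_among = g - 1
    df_within = n_total - g
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n0 = (n_total - sum(s**2 for s in sizes) / n_total) / df_among
    sigma2_within = ms_within
    sigma2_among = (ms_among - ms_within) / n0
    total_var = sigma2_among + sigma2_within
    phi = sigma2_among / total_var

    p_value = None
    if permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        labels_pool = all_idx.copy()
        for _ in range(permutations):
            rng.shuffle(labels_pool)
            start, perm_groups = 0, []
            for s in sizes:
                perm_groups.append(labels_pool[start : start + s])
                start += s
            ssw = _ss_within(d2, perm_groups)
            ssa = ss_total - ssw
            s2w = ssw / df_within
            s2a = (ssa / df_among - s2w) / n0
            phi_perm = s2a / (s2a + s2w)
            if phi_perm >= phi:
                hits += 1
        p_value = (1.0 + hits) / (1.0 + permutations)

    return AmovaResult(
        ss_among=float(ss_among),
        ss_within=float(ss_within),
        df_among=df_among,
        df_within=df_within,
        sigma2_among=float(sigma2_among),
        sigma2_within=float(sigma2_within),
        pct_among=float(100.0 * sigma2_among / total_var),
        pct_within=float(100.0 * sigma2_within / total_var),
        phi_st=float(phi),
        permutations=permutations,
        p_value=p_value,
    )
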