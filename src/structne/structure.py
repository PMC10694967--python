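"""Detecting cryptic population structure and the sampling remedy.

Low migration between demes (or a segregating inversion) leaves a strong
signature in a principal-component decomposition of the genotype matrix:
the cohort separates into groups along the leading components.  When that
happens, the LD-based Ne estimate from the pooled cohort carries admixture
LD and is biased; restricting the estimation to the individuals of a single
inferred group removes the artefact.  This module provides the PCA, a
k-means grouping of the leading components, and the restricted re-estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .genotypes import GenotypeMatrix, subset_individuals
from .ldne import EstimatorConfig, NeTrajectory, estimate_ne


@dataclass
class PCAResult:
    """Principal components of the cohort's standardized dosages."""

    coordinates: np.ndarray               # (n_individuals, k)
    explained_variance_ratio: np.ndarray  # (k,), non-increasing
    loadings: np.ndarray | None = None    # (k, n_snps) SNP loadings
    group_labels: np.ndarray | None = None


def genotype_pca(gm: GenotypeMatrix, k: int = 10) -> PCAResult:
    """Top-``k`` principal components of centered, unit-variance dosages.

    Deterministic up to sign; signs are canonicalized by orienting each
    component so its largest-magnitude SNP loading is positive.  ``k``
    beyond the matrix rank is reduced with a warning.
    """
    if gm.n_individuals < 2 or gm.n_snps < 2:
        raise ValueError("PCA needs at least 2 individuals and 2 SNPs")
    X = gm.dosages.astype(np.float64)
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X /= sd
    max_rank = min(gm.n_individuals - 1, gm.n_snps)
    if k > max_rank:
        warnings.warn(f"k={k} exceeds the matrix rank bound; using k={max_rank}")
        k = max_rank
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    loadings = pca.components_.copy()
    # sign canonicalization: largest-|loading| SNP positive on each component
    for j in range(k):
        if loadings[j, np.argmax(np.abs(loadings[j]))] < 0:
            coords[:, j] *= -1.0
            loadings[j] *= -1.0
    return PCAResult(coords, pca.explained_variance_ratio_.copy(), loadings)


def assign_groups(pca: PCAResult, n_groups: int = 2, rng=None) -> np.ndarray:
    """k-means grouping on the top-2 principal components.

    Labels are canonicalized: group 0 is the largest (ties broken by lower
    PC1 mean), so labelings are stable across runs with the same seed.
    """
    rng = np.random.default_rng() if rng is None else rng
    n = pca.coordinates.shape[0]
    if n < n_groups:
        raise ValueError(f"cannot form {n_groups} groups from {n} individuals")
    if n_groups == 1:
        return np.zeros(n, dtype=np.int64)
    coords = pca.coordinates[:, :2]
    km = KMeans(n_clusters=n_groups, n_init=10,
                random_state=int(rng.integers(2**31 - 1)))
    raw = km.fit_predict(coords)
    order = sorted(range(n_groups),
                   key=lambda g: (-(raw == g).sum(), coords[raw == g, 0].mean()))
    relabel = np.empty(n_groups, dtype=np.int64)
    relabel[order] = np.arange(n_groups)
    return relabel[raw]


def gap_hint(pca: PCAResult, max_groups: int = 5, rng=None) -> int:
    """Heuristic group-count suggestion (never auto-applied): the k with the
    largest drop in within-cluster dispersion relative to a 1-group model."""
    rng = np.random.default_rng() if rng is None else rng
    coords = pca.coordinates[:, :2]
    n = coords.shape[0]
    inertia = []
    for g in range(1, min(max_groups, n) + 1):
        km = KMeans(n_clusters=g, n_init=5,
                    random_state=int(rng.integers(2**31 - 1)))
        km.fit(coords)
        inertia.append(km.inertia_)
    ratios = [inertia[i] / inertia[0] for i in range(len(inertia))]
    drops = np.diff(ratios)
    return int(np.argmin(drops)) + 2 if len(drops) else 1


def restrict_and_reestimate(gm: GenotypeMatrix, labels, chosen_group: int,
                            cfg: EstimatorConfig | None = None,
                            maf_min: float = 0.05,
                            reference=None) -> NeTrajectory:
    """Re-run the LD estimation on the members of one inferred group.

    Subsets the cohort, re-filters monomorphic and low-MAF sites, and
    re-estimates the Ne trajectory -- the structure remedy of sampling
    within a single (inferred) subpopulation.
    """
    labels = np.asarray(labels)
    rows = np.flatnonzero(labels == chosen_group)
    if rows.size < 10:
        raise ValueError(
            f"group {chosen_group} has only {rows.size} individuals (< 10)")
    sub = subset_individuals(gm, rows, maf_min=maf_min)
    return estimate_ne(sub, cfg, reference=reference)
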