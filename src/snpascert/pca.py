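"""EIGENSTRAT-style PCA of typing data pooled across replicates.

Markers for PCA are all candidate sites passing the ascertainment scheme
at a 5% discovery-panel frequency filter (no fixed-size marker draw);
columns from many independent replicates are concatenated so each
haplotype row spans many loci.  Columns are centered by their allele
frequency p and scaled by sqrt(p(1-p)) before eigendecomposition — the
EIGENSTRAT normalization, applied here on haploid units so the diploid
factor-of-2 genotype scaling does not appear.

A centroid-separation ratio quantifies how well the leading components
separate two populations, making "the clusters collapsed" assertable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ascertainment import AscertainmentConfig, candidate_sites
from .replicates import HaplotypeDataset
from .stats import _typed_subset

__all__ = [
    "PcaInput",
    "PcaResult",
    "build_pca_input",
    "patterson_normalize",
    "principal_components",
    "cluster_separation",
    "run_pca",
]

#: sentinel returned by cluster_separation when within-population spread is zero
SEPARATION_SENTINEL = 1e12


@dataclass
class PcaInput:
    """Typing haplotypes x pooled candidate sites, over R replicates."""

    matrix: np.ndarray
    pop_labels: np.ndarray
    site_provenance: np.ndarray  # (n_sites, 2): replicate_id, site index
    scheme: str | None = None
    n_replicates: int = 0
    n_excluded: int = 0

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]


@dataclass
class PcaResult:
    """Principal-component scores and eigenvalues of the sample covariance."""

    coordinates: np.ndarray  # haplotypes x k
    eigenvalues: np.ndarray  # length k, non-increasing
    pop_labels: np.ndarray
    n_sites_used: int
    n_sites_dropped: int = 0
    sign_convention: str = "largest-magnitude loading positive"
    meta: dict = field(default_factory=dict)


def build_pca_input(
    replicates: list[HaplotypeDataset],
    config: AscertainmentConfig | None,
) -> PcaInput:
    """Pool per-replicate candidate sites into one typing matrix.

    ``config=None`` is the no-ascertainment control: every segregating
    site of every replicate is used.  Otherwise each replicate contributes
    its full candidate set under the scheme (typically at a 0.05
    threshold); replicates with zero candidates contribute no columns and
    are counted.  All replicates must share the sampling design so rows
    align.
    """
    blocks, prov = [], []
    pop_labels = None
    n_excluded = 0
    for ds in replicates:
        if config is None:
            sites = np.arange(ds.n_sites)
        else:
            sites = candidate_sites(ds, config)
        if sites.size == 0:
            n_excluded += 1
            continue
        typed = _typed_subset(ds, sites)
        if pop_labels is None:
            pop_labels = typed.pop_labels
        elif not np.array_equal(pop_labels, typed.pop_labels):
            raise ValueError(
                f"replicate {ds.replicate_id}: sampling design differs from the first replicate"
            )
        blocks.append(typed.matrix)
        prov.append(np.column_stack([np.full(sites.size, ds.replicate_id), sites]))
    if not blocks:
        return PcaInput(
            matrix=np.zeros((0, 0), dtype=np.int8),
            pop_labels=np.zeros(0, np.int64),
            site_provenance=np.zeros((0, 2), np.int64),
            scheme=None if config is None else config.scheme,
            n_replicates=len(replicates),
            n_excluded=n_excluded,
        )
    return PcaInput(
        matrix=np.concatenate(blocks, axis=1),
        pop_labels=pop_labels,
        site_provenance=np.concatenate(prov, axis=0),
        scheme=None if config is None else config.scheme,
        n_replicates=len(replicates),
        n_excluded=n_excluded,
    )


def patterson_normalize(matrix: np.ndarray) -> tuple[np.ndarray, int]:
    """Center each column by its frequency p and scale by sqrt(p(1-p)).

    Columns fixed among the rows (p in {0, 1}) carry no information and
    are dropped; the count of dropped columns is returned alongside the
    normalized matrix.
    """
    g = np.asarray(matrix, dtype=float)
    if g.ndim != 2 or g.shape[0] < 2 or g.shape[1] < 1:
        raise ValueError("need a matrix with >= 2 rows and >= 1 column")
    p = g.mean(axis=0)
    keep = (p > 0) & (p < 1)
    n_dropped = int((~keep).sum())
    g = g[:, keep]
    p = p[keep]
    if g.shape[1] == 0:
        return np.zeros((g.shape[0], 0)), n_dropped
    return (g - p) / np.sqrt(p * (1.0 - p)), n_dropped


def principal_components(normalized: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-k scores and eigenvalues of the row-by-row covariance.

    Scores are projections of the rows onto the top right-singular vectors
    (equivalently eigenvectors of X X^T / n_sites scaled to projections).
    Signs are fixed by making each component's largest-magnitude loading
    positive, so results are deterministic across LAPACK builds.
    """
    x = np.asarray(normalized, dtype=float)
    n, m = x.shape
    if not (1 <= k <= min(n - 1, m)):
        raise ValueError(f"k={k} out of range for a {n}x{m} matrix")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    for i in range(k):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    scores = u[:, :k] * s[:k]
    eigenvalues = s[:k] ** 2 / m
    return scores, eigenvalues


def run_pca(pca_input: PcaInput, k: int = 2) -> PcaResult:
    """Normalize, decompose, and package scores for a pooled typing matrix."""
    normalized, n_dropped = patterson_normalize(pca_input.matrix)
    if normalized.shape[1] == 0:
        raise ValueError("all sites fixed among typing haplotypes; nothing to decompose")
    scores, eigenvalues = principal_components(normalized, k)
    return PcaResult(
        coordinates=scores,
        eigenvalues=eigenvalues,
        pop_labels=pca_input.pop_labels,
        n_sites_used=normalized.shape[1],
        n_sites_dropped=n_dropped,
        meta={
            "scheme": pca_input.scheme or "none",
            "n_replicates": pca_input.n_replicates,
            "n_excluded": pca_input.n_excluded,
        },
    )


def cluster_separation(
    result: PcaResult,
    pop_a: int,
    pop_b: int,
    k_dims: int = 2,
) -> float:
    """Centroid distance over the mean within-population RMS spread.

    The numerator is the distance between the two populations' centroids
    in the first ``k_dims`` components.  The denominator is the mean of
    the within-population RMS spreads of *all* populations in the result:
    a common scale for the whole score plot, so that a pair whose
    centroids nearly coincide reads as collapsed even when another
    population's spread is inflated.  Ratios well above 1 mean distinct
    clusters; near or below 1, overlap.  A zero denominator (point
    clusters) returns a large sentinel value rather than infinity.
    """
    coords = result.coordinates[:, :k_dims]
    for pop in (pop_a, pop_b):
        if (result.pop_labels == pop).sum() < 2:
            raise ValueError(f"population {pop} has < 2 members")
    xa = coords[result.pop_labels == pop_a]
    xb = coords[result.pop_labels == pop_b]
    centroid_dist = float(np.linalg.norm(xa.mean(axis=0) - xb.mean(axis=0)))
    spreads = []
    for pop in np.unique(result.pop_labels):
        x = coords[result.pop_labels == pop]
        spreads.append(float(np.sqrt(((x - x.mean(axis=0)) ** 2).sum(axis=1).mean())))
    spread = float(np.mean(spreads))
    if spread == 0.0:
        return SEPARATION_SENTINEL
    return centroid_dist / spread
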