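"""Typing-data and re-sequencing summary statistics.

The quantities of interest are the joint (2D) site-frequency spectrum, the
average number of pairwise differences within (``pi_w``) and between
(``pi_b``) populations over a site set, and the Hudson-style divergence
measure ``FST = 1 - pi_w / pi_b`` where ``pi_w`` for a pair is the
unweighted mean of the two within-population values.

Pi values are totals over the site set (differences per sampled pair), not
per-bp rates: every use here is a ratio (FST, or typing relative to a
random-marker baseline), so the normalization cancels.  All statistics are
defined on haplotypes and computed from per-site derived-allele counts; the
frequency formulas agree exactly with brute-force enumeration of haplotype
pairs (see the test suite's oracle checks).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .ascertainment import MarkerSelectionResult
from .replicates import TYPING, HaplotypeDataset

__all__ = [
    "TypingData",
    "SFS2D",
    "PairwiseStats",
    "DeviationRecord",
    "make_typing_data",
    "reseq_typing_view",
    "sfs_2d",
    "pi_within",
    "pi_between",
    "fst_hudson",
    "pairwise_stats",
    "random_marker_baseline",
    "aggregate_deviations",
]


@dataclass
class TypingData:
    """Genotype states of marker sites in the typing haplotypes.

    Columns correspond 1:1 to the selected markers (sorted by site index);
    markers monomorphic among the typing haplotypes are retained — typing
    observes the state of a chosen site, it does not re-filter.
    """

    matrix: np.ndarray
    pop_labels: np.ndarray
    marker_sites: np.ndarray
    replicate_id: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.ascontiguousarray(self.matrix, dtype=np.int8)
        self.pop_labels = np.asarray(self.pop_labels, dtype=np.int64)
        self.marker_sites = np.asarray(self.marker_sites, dtype=np.int64)
        if self.matrix.shape[1] != self.marker_sites.size:
            raise ValueError("one marker site per matrix column required")
        if self.matrix.shape[0] != self.pop_labels.size:
            raise ValueError("one population label per haplotype required")

    @property
    def n_pops(self) -> int:
        return int(self.pop_labels.max()) + 1 if self.pop_labels.size else 0

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]


def make_typing_data(dataset: HaplotypeDataset, selection: MarkerSelectionResult) -> TypingData:
    """Restrict a replicate to typing-role rows and selected marker columns."""
    if selection.excluded:
        raise ValueError(
            f"replicate {dataset.replicate_id}: marker selection was excluded "
            f"({selection.candidate_sites.size} candidates < "
            f"{selection.config.n_markers} markers)"
        )
    return _typed_subset(dataset, np.sort(selection.selected_markers))


def reseq_typing_view(dataset: HaplotypeDataset) -> TypingData:
    """Typing rows at ALL segregating sites — the re-sequencing baseline.

    Uses the same haplotypes as any typing dataset from this replicate, so
    typing-vs-re-sequencing comparisons differ only in site selection.
    """
    return _typed_subset(dataset, np.arange(dataset.n_sites))


def _typed_subset(dataset: HaplotypeDataset, sites: np.ndarray) -> TypingData:
    if (dataset.role_labels == TYPING).any():
        mask = dataset.role_labels == TYPING
    else:
        # reuse_discovery_as_typing design: discovery rows are typed
        mask = np.ones(dataset.n_haplotypes, dtype=bool)
    return TypingData(
        matrix=dataset.matrix[np.ix_(mask, sites)],
        pop_labels=dataset.pop_labels[mask],
        marker_sites=sites,
        replicate_id=dataset.replicate_id,
    )


@dataclass
class SFS2D:
    """Joint site-frequency spectrum of two populations.

    ``counts[i, j]`` is the number of sites with derived-allele count ``i``
    in population A and ``j`` in population B; the matrix includes the
    corner cells (0, 0) and (nA, nB), which typing data can populate.
    """

    counts: np.ndarray
    pop_pair: tuple[int, int]
    n_sites: int


def _pop_counts(data, pop: int) -> tuple[np.ndarray, int]:
    mask = data.pop_labels == pop
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"population {pop} not present")
    return data.matrix[mask].sum(axis=0), n


def sfs_2d(data, pop_a: int, pop_b: int) -> SFS2D:
    """Tabulate the joint derived-allele-count spectrum of two populations."""
    da, na = _pop_counts(data, pop_a)
    db, nb = _pop_counts(data, pop_b)
    counts = np.zeros((na + 1, nb + 1), dtype=np.int64)
    np.add.at(counts, (da, db), 1)
    return SFS2D(counts=counts, pop_pair=(pop_a, pop_b), n_sites=data.matrix.shape[1])


def pi_within(data, pop: int) -> float:
    """Mean pairwise difference within a population over the site set.

    ``sum_sites d*(n-d) / C(n,2)`` with d the derived count; identical to
    averaging Hamming distance over all within-population haplotype pairs.
    """
    d, n = _pop_counts(data, pop)
    if n < 2:
        raise ValueError(f"population {pop} needs >= 2 haplotypes, has {n}")
    return float((d * (n - d)).sum() / (n * (n - 1) / 2))


def pi_between(data, pop_a: int, pop_b: int) -> float:
    """Mean pairwise difference between two populations over the site set.

    ``sum_sites [dA*(nB-dB) + dB*(nA-dA)] / (nA*nB)``; identical to
    averaging Hamming distance over all cross-population pairs.
    """
    da, na = _pop_counts(data, pop_a)
    db, nb = _pop_counts(data, pop_b)
    return float((da * (nb - db) + db * (na - da)).sum() / (na * nb))


def fst_hudson(data, pop_a: int, pop_b: int) -> tuple[float, bool]:
    """Hudson-style FST = 1 - pi_w/pi_b for one population pair.

    ``pi_w`` is the unweighted mean of the two within-population values
    (deme sizes are equal throughout this study, so weighting is
    immaterial).  Returns ``(value, defined)``; when ``pi_b`` is zero the
    statistic is undefined and ``(nan, False)`` is returned so aggregation
    can drop the replicate with a logged count.
    """
    pw = 0.5 * (pi_within(data, pop_a) + pi_within(data, pop_b))
    pb = pi_between(data, pop_a, pop_b)
    if pb == 0.0:
        return float("nan"), False
    return 1.0 - pw / pb, True


@dataclass
class PairwiseStats:
    """pi_w per population, pi_b and FST per pair, for one site set."""

    pi_w: dict[int, float]
    pi_b: dict[tuple[int, int], float]
    fst: dict[tuple[int, int], float]
    fst_defined: dict[tuple[int, int], bool]
    n_sites: int


def pairwise_stats(data) -> PairwiseStats:
    """All within/between/FST statistics of a typed or re-sequencing site set."""
    pops = sorted(set(int(p) for p in data.pop_labels))
    pi_w = {p: pi_within(data, p) for p in pops}
    pi_b, fst, defined = {}, {}, {}
    for a, b in itertools.combinations(pops, 2):
        pi_b[(a, b)] = pi_between(data, a, b)
        fst[(a, b)], defined[(a, b)] = fst_hudson(data, a, b)
    return PairwiseStats(pi_w, pi_b, fst, defined, n_sites=data.matrix.shape[1])


def random_marker_baseline(
    dataset: HaplotypeDataset,
    n_markers: int,
    seed: int,
    pool: np.ndarray | None = None,
) -> MarkerSelectionResult:
    """Draw markers uniformly from ALL segregating sites of the replicate.

    No panel conditioning and no MAF filter: this is the unascertained
    control against which typing statistics are expressed as ratios.
    Subsampling uniformly is unbiased for per-site averages, so baseline
    pi matches all-site pi in expectation.  ``pool`` restricts the draw to
    an explicit site-index set (e.g. a panel-conditioned pool) instead of
    every site.
    """
    from .ascertainment import AscertainmentConfig, select_markers

    config = AscertainmentConfig(
        scheme="merged_panel", maf_threshold=0.0, n_markers=n_markers, seed=seed
    )
    sites = np.arange(dataset.n_sites) if pool is None else np.asarray(pool, dtype=np.int64)
    return select_markers(sites, config)


@dataclass
class DeviationRecord:
    """Aggregated bias for one (scheme, threshold, population pair) cell.

    ``deviation`` is the difference of replicate means (typing minus
    re-sequencing FST); ``deviation_paired`` is the mean of per-replicate
    differences over the same usable replicates.  ``relative_pi_*`` are
    ratios of mean typing pi to mean random-baseline pi.  Monte-Carlo
    standard errors accompany each headline quantity.
    """

    scheme: str
    threshold: float
    pop_pair: tuple[int, int]
    mean_fst_typing: float
    mean_fst_reseq: float
    deviation: float
    deviation_paired: float
    relative_pi_within: float
    relative_pi_between: float
    se_deviation: float
    se_fst_typing: float
    se_fst_reseq: float
    se_relative_pi_within: float
    se_relative_pi_between: float
    n_replicates_used: int
    n_excluded: int
    n_fst_undefined: int = 0
    extras: dict = field(default_factory=dict)


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, float)
    if x.size < 2:
        return float("nan")
    return float(x.std(ddof=1) / np.sqrt(x.size))


def _ratio_se(num: np.ndarray, den: np.ndarray) -> float:
    """Delta-method SE of mean(num)/mean(den) over paired replicates."""
    num, den = np.asarray(num, float), np.asarray(den, float)
    n = num.size
    if n < 2:
        return float("nan")
    mn, md = num.mean(), den.mean()
    if md == 0:
        return float("nan")
    cov = np.cov(num, den, ddof=1)
    var = (mn / md) ** 2 * (
        cov[0, 0] / mn**2 + cov[1, 1] / md**2 - 2 * cov[0, 1] / (mn * md)
    )
    return float(np.sqrt(max(var, 0.0) / n))


def aggregate_deviations(
    scheme: str,
    threshold: float,
    pop_pair: tuple[int, int],
    fst_typing: np.ndarray,
    fst_reseq: np.ndarray,
    pi_w_typing: np.ndarray,
    pi_w_baseline: np.ndarray,
    pi_b_typing: np.ndarray,
    pi_b_baseline: np.ndarray,
    n_excluded: int,
) -> DeviationRecord:
    """Aggregate per-replicate statistics for one cell into a DeviationRecord.

    Inputs are aligned arrays over the cell's usable replicates (excluded
    replicates already removed).  Replicates where either FST is undefined
    (NaN) are dropped from the FST means with a recorded count; pi ratios
    use every usable replicate.
    """
    fst_typing = np.asarray(fst_typing, float)
    fst_reseq = np.asarray(fst_reseq, float)
    ok = ~(np.isnan(fst_typing) | np.isnan(fst_reseq))
    n_undef = int((~ok).sum())
    ft, fr = fst_typing[ok], fst_reseq[ok]
    if ft.size == 0:
        mean_t = mean_r = dev = dev_paired = float("nan")
        se_dev = se_t = se_r = float("nan")
    else:
        mean_t, mean_r = float(ft.mean()), float(fr.mean())
        dev = mean_t - mean_r
        dev_paired = float((ft - fr).mean())
        se_dev = _sem(ft - fr)
        se_t, se_r = _sem(ft), _sem(fr)
    pi_w_typing = np.asarray(pi_w_typing, float)
    pi_w_baseline = np.asarray(pi_w_baseline, float)
    pi_b_typing = np.asarray(pi_b_typing, float)
    pi_b_baseline = np.asarray(pi_b_baseline, float)
    rel_w = float(pi_w_typing.mean() / pi_w_baseline.mean()) if pi_w_typing.size else float("nan")
    rel_b = float(pi_b_typing.mean() / pi_b_baseline.mean()) if pi_b_typing.size else float("nan")
    return DeviationRecord(
        scheme=scheme,
        threshold=threshold,
        pop_pair=pop_pair,
        mean_fst_typing=mean_t,
        mean_fst_reseq=mean_r,
        deviation=dev,
        deviation_paired=dev_paired,
        relative_pi_within=rel_w,
        relative_pi_between=rel_b,
        se_deviation=se_dev,
        se_fst_typing=se_t,
        se_fst_reseq=se_r,
        se_relative_pi_within=_ratio_se(pi_w_typing, pi_w_baseline),
        se_relative_pi_between=_ratio_se(pi_b_typing, pi_b_baseline),
        n_replicates_used=int(ft.size),
        n_excluded=int(n_excluded),
        n_fst_undefined=n_undef,
    )
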