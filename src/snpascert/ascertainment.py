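"""SNP ascertainment schemes: discovery panels, MAF filtering, marker choice.

Three schemes are implemented.  ``single_population`` discovers variants in
one population's discovery panel; ``merged_panel`` pools every population's
discovery panel into one; ``independent_panel`` builds a per-population
panel in each population and merges the surviving candidates — a site
observed as variable below the minor-allele-frequency (MAF) threshold in
any panel is eliminated.

For the independent scheme, a panel in which a site is entirely invisible
(absent, or fixed derived) cannot evaluate its frequency.  By default such
a panel neither discovers nor vetoes the site ("a panel can only eliminate
what it sees"); discovery then requires passing in at least one panel.
``unseen_vetoes=True`` switches to the stricter variant in which a site
must be variable and pass the threshold in every panel, so absence anywhere
eliminates it.  The default reproduces the scheme's characteristic
behaviour across demographies (strong downward FST bias with migration,
slight upward bias under a recent-split history, workable candidate
counts); the strict variant leaves almost no candidates once populations
are diverged, because it keeps only ancestral variation shared by all
panels.

In all schemes a site must actually segregate in the panel(s) consulted
(a site invisible to the panel cannot be discovered), the MAF filter keeps
sites with MAF >= threshold (ties kept), and a fixed number of markers is
then drawn uniformly without replacement from the candidates.  Replicates
with fewer candidates than markers are flagged excluded, not truncated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .replicates import DISCOVERY, HaplotypeDataset

__all__ = [
    "SCHEMES",
    "AscertainmentConfig",
    "MarkerSelectionResult",
    "minor_allele_frequency",
    "candidate_sites",
    "select_markers",
    "ascertain",
]

SCHEMES = ("single_population", "merged_panel", "independent_panel")


@dataclass(frozen=True)
class AscertainmentConfig:
    """One ascertainment cell: scheme, panel, MAF threshold, marker count.

    ``strict_threshold=True`` switches the filter to MAF > threshold
    (drop ties), a sensitivity variant; the default keeps ties.
    ``unseen_vetoes`` selects the strict all-panels variant of the
    independent scheme (see module docstring); ignored by other schemes.
    """

    scheme: str = "single_population"
    discovery_population: int = 0
    maf_threshold: float = 0.0
    n_markers: int = 50
    seed: int = 0
    strict_threshold: bool = False
    unseen_vetoes: bool = False

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; expected one of {SCHEMES}")
        if not (0 <= self.maf_threshold < 0.5):
            raise ValueError(f"maf_threshold must be in [0, 0.5), got {self.maf_threshold}")
        if self.n_markers < 1:
            raise ValueError(f"n_markers must be >= 1, got {self.n_markers}")


@dataclass(frozen=True)
class MarkerSelectionResult:
    """Candidate and selected marker sites for one replicate and one cell."""

    candidate_sites: np.ndarray
    selected_markers: np.ndarray
    excluded: bool
    config: AscertainmentConfig

    def __post_init__(self) -> None:
        object.__setattr__(self, "candidate_sites", np.asarray(self.candidate_sites, dtype=np.int64))
        object.__setattr__(self, "selected_markers", np.asarray(self.selected_markers, dtype=np.int64))
        if self.excluded:
            if self.selected_markers.size:
                raise ValueError("excluded result must carry no selected markers")
        else:
            if self.selected_markers.size != self.config.n_markers:
                raise ValueError("non-excluded result must select exactly n_markers sites")
            if not np.isin(self.selected_markers, self.candidate_sites).all():
                raise ValueError("selected markers must be a subset of the candidates")


def minor_allele_frequency(derived_count, n_haplotypes):
    """Folded allele frequency min(d/n, 1 - d/n); vectorizes over counts."""
    d = np.asarray(derived_count, dtype=float)
    n = float(n_haplotypes)
    if n < 1:
        raise ValueError("n_haplotypes must be >= 1")
    if np.any(d < 0) or np.any(d > n):
        raise ValueError("derived counts must lie in [0, n_haplotypes]")
    f = d / n
    out = np.minimum(f, 1.0 - f)
    return float(out) if np.isscalar(derived_count) else out


def _panel_pass(counts: np.ndarray, n: int, config: AscertainmentConfig) -> np.ndarray:
    """Sites discovered (segregating) and MAF-passing in one panel."""
    seg = (counts > 0) & (counts < n)
    maf = minor_allele_frequency(counts, n)
    if config.strict_threshold:
        keep = maf > config.maf_threshold
    else:
        keep = maf >= config.maf_threshold
    return seg & keep


def candidate_sites(dataset: HaplotypeDataset, config: AscertainmentConfig) -> np.ndarray:
    """Site indices passing the scheme's discovery-and-MAF filter.

    All schemes require a site to segregate in the panel(s) they consult;
    the MAF threshold then removes rare minor alleles.  Returns sorted
    site indices into ``dataset``'s columns.
    """
    pops = range(dataset.n_pops)
    if config.scheme == "single_population":
        pop = config.discovery_population
        mask = dataset.rows(pop=pop, role=DISCOVERY)
        if not mask.any():
            raise ValueError(f"no discovery panel for population {pop}")
        counts = dataset.matrix[mask].sum(axis=0)
        keep = _panel_pass(counts, int(mask.sum()), config)
    elif config.scheme == "merged_panel":
        mask = dataset.rows(role=DISCOVERY)
        if not mask.any():
            raise ValueError("no discovery haplotypes in dataset")
        counts = dataset.matrix[mask].sum(axis=0)
        keep = _panel_pass(counts, int(mask.sum()), config)
    else:  # independent_panel
        discovered = np.zeros(dataset.n_sites, dtype=bool)
        vetoed = np.zeros(dataset.n_sites, dtype=bool)
        all_pass = np.ones(dataset.n_sites, dtype=bool)
        for pop in pops:
            mask = dataset.rows(pop=pop, role=DISCOVERY)
            if not mask.any():
                raise ValueError(f"no discovery panel for population {pop}")
            counts = dataset.matrix[mask].sum(axis=0)
            n = int(mask.sum())
            passed = _panel_pass(counts, n, config)
            seg = (counts > 0) & (counts < n)
            discovered |= passed
            vetoed |= seg & ~passed
            all_pass &= passed
        if config.unseen_vetoes:
            keep = all_pass
        else:
            keep = discovered & ~vetoed
    return np.flatnonzero(keep)


def select_markers(candidates: np.ndarray, config: AscertainmentConfig) -> MarkerSelectionResult:
    """Draw ``n_markers`` sites uniformly without replacement, or exclude.

    Exclusion (fewer candidates than markers) is a result state recorded on
    the replicate, never an error.  Deterministic given ``config.seed``.
    """
    candidates = np.sort(np.asarray(candidates, dtype=np.int64))
    if candidates.size < config.n_markers:
        return MarkerSelectionResult(candidates, np.empty(0, np.int64), True, config)
    rng = np.random.default_rng(config.seed)
    chosen = rng.choice(candidates, size=config.n_markers, replace=False)
    return MarkerSelectionResult(candidates, np.sort(chosen), False, config)


def ascertain(dataset: HaplotypeDataset, config: AscertainmentConfig) -> MarkerSelectionResult:
    """Full scheme for one replicate: candidate filter then marker draw."""
    return select_markers(candidate_sites(dataset, config), config)


def random_baseline_config(config: AscertainmentConfig) -> AscertainmentConfig:
    """Same marker count and seed, used for the unascertained control draw."""
    return replace(config, maf_threshold=0.0)
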