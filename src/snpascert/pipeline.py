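"""Orchestration of the full factorial experiment and the PCA experiment.

One simulation pass per replicate is shared by every (scheme, threshold)
cell, so scheme comparisons are paired and lower-variance than independent
simulation.  Per-replicate seeds are counter-based, making runs
reproducible replicate-by-replicate and independent of scheduling.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ascertainment import SCHEMES, AscertainmentConfig, ascertain
from .config import pop_name
from .demography import DemographySpec, SimulationParams
from .pca import PcaResult, build_pca_input, cluster_separation, run_pca
from .replicates import HaplotypeDataset, SamplingDesign, replicate_seed, simulate_replicate
from .stats import (
    DeviationRecord,
    aggregate_deviations,
    make_typing_data,
    pairwise_stats,
    random_marker_baseline,
    reseq_typing_view,
)

__all__ = [
    "ExperimentConfig",
    "ExperimentTable",
    "simulate_replicates",
    "run_experiment",
    "run_pca_experiment",
]

logger = logging.getLogger("snpascert")


def _marker_seed(master_seed: int, replicate_id: int, cell: int) -> int:
    """Deterministic seed for a marker draw, distinct per replicate and cell."""
    ss = np.random.SeedSequence([int(master_seed), int(replicate_id), 1000 + cell])
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31 - 1))


@dataclass
class ExperimentConfig:
    """Everything one factorial run needs.

    ``thresholds`` is the marker-selection MAF sweep; ``schemes`` any
    subset of the three ascertainment schemes.  ``n_replicates`` defaults
    to the study-scale 10,000; ``reduced`` mode (1,000) is the desk-scale
    default used by the bundled scripts.
    """

    demography: DemographySpec
    params: SimulationParams = field(default_factory=SimulationParams)
    design: SamplingDesign = field(default_factory=SamplingDesign)
    schemes: tuple[str, ...] = SCHEMES
    thresholds: tuple[float, ...] = (0.0, 0.01, 0.025, 0.05, 0.075, 0.1, 0.15, 0.2)
    n_markers: int = 50
    n_replicates: int = 10_000
    discovery_population: int = 0
    master_seed: int = 1
    strict_threshold: bool = False
    unseen_vetoes: bool = False

    def __post_init__(self) -> None:
        if self.discovery_population >= self.demography.n_pops:
            raise ValueError(
                f"discovery population {self.discovery_population} not in demography "
                f"with {self.demography.n_pops} demes"
            )
        if list(self.thresholds) != sorted(self.thresholds):
            raise ValueError("thresholds must be sorted ascending")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class ExperimentTable:
    """DeviationRecord rows for every (scheme, threshold, pair) cell."""

    records: list[DeviationRecord]
    meta: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            a, b = r.pop_pair
            rows.append(
                {
                    "model": self.meta.get("model", ""),
                    "scheme": r.scheme,
                    "threshold": r.threshold,
                    "pop_pair": f"{pop_name(a)}-{pop_name(b)}",
                    "mean_fst_typing": r.mean_fst_typing,
                    "mean_fst_reseq": r.mean_fst_reseq,
                    "deviation": r.deviation,
                    "deviation_paired": r.deviation_paired,
                    "relative_pi_within": r.relative_pi_within,
                    "relative_pi_between": r.relative_pi_between,
                    "se_deviation": r.se_deviation,
                    "se_fst_typing": r.se_fst_typing,
                    "se_fst_reseq": r.se_fst_reseq,
                    "se_relative_pi_within": r.se_relative_pi_within,
                    "se_relative_pi_between": r.se_relative_pi_between,
                    "n_replicates_used": r.n_replicates_used,
                    "n_excluded": r.n_excluded,
                    "n_fst_undefined": r.n_fst_undefined,
                }
            )
        return pd.DataFrame(rows)

    def get(self, scheme: str, threshold: float, pop_pair: tuple[int, int]) -> DeviationRecord:
        for r in self.records:
            if (
                r.scheme == scheme
                and np.isclose(r.threshold, threshold)
                and r.pop_pair == tuple(pop_pair)
            ):
                return r
        raise KeyError((scheme, threshold, pop_pair))

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6g")


def simulate_replicates(
    demography: DemographySpec,
    design: SamplingDesign,
    params: SimulationParams,
    n_replicates: int,
    master_seed: int,
) -> list[HaplotypeDataset]:
    """Simulate a batch of replicates with counter-based per-replicate seeds."""
    return [
        simulate_replicate(
            demography, design, params, seed=replicate_seed(master_seed, i), replicate_id=i
        )
        for i in range(n_replicates)
    ]


def run_experiment(config: ExperimentConfig, null_scheme: bool = False) -> ExperimentTable:
    """Run the factorial (scheme x threshold) experiment.

    Per replicate: simulate once; compute re-sequencing statistics (typing
    haplotypes, all segregating sites) and random-marker baseline
    statistics once; then for every (scheme, threshold) cell ascertain,
    type, and compute typing statistics.  Aggregation produces one
    DeviationRecord per cell and population pair.

    ``null_scheme=True`` bypasses ascertainment and types the random
    baseline markers themselves in every cell — a calibration mode in
    which all deviations should vanish.
    """
    dem, design, params = config.demography, config.design, config.params
    pairs = list(itertools.combinations(range(dem.n_pops), 2))
    cells = list(itertools.product(config.schemes, config.thresholds))
    # accumulators: cell -> list over usable replicates
    acc: dict[tuple, dict[str, list]] = {
        cell: {"fst_t": [], "fst_r": [], "pi_w_t": [], "pi_w_b": [], "pi_b_t": [],
               "pi_b_b": [], "n_candidates": [], "n_excluded": 0}
        for cell in cells
    }

    for i in range(config.n_replicates):
        seed = replicate_seed(config.master_seed, i)
        ds = simulate_replicate(dem, design, params, seed=seed, replicate_id=i)
        baseline_sel = random_marker_baseline(ds, config.n_markers, _marker_seed(config.master_seed, i, 0))
        if baseline_sel.excluded:
            for cell in cells:
                acc[cell]["n_excluded"] += 1
            logger.debug("replicate %d: < %d segregating sites, excluded", i, config.n_markers)
            continue
        reseq = pairwise_stats(reseq_typing_view(ds))
        base = pairwise_stats(make_typing_data(ds, baseline_sel))
        for ci, (scheme, threshold) in enumerate(cells):
            if null_scheme:
                sel = baseline_sel
            else:
                asc = AscertainmentConfig(
                    scheme=scheme,
                    discovery_population=config.discovery_population,
                    maf_threshold=threshold,
                    n_markers=config.n_markers,
                    seed=_marker_seed(config.master_seed, i, ci + 1),
                    strict_threshold=config.strict_threshold,
                    unseen_vetoes=config.unseen_vetoes,
                )
                sel = ascertain(ds, asc)
            acc[(scheme, threshold)]["n_candidates"].append(sel.candidate_sites.size)
            if sel.excluded:
                acc[(scheme, threshold)]["n_excluded"] += 1
                continue
            typ = pairwise_stats(make_typing_data(ds, sel))
            a = acc[(scheme, threshold)]
            a["fst_t"].append([typ.fst[p] for p in pairs])
            a["fst_r"].append([reseq.fst[p] for p in pairs])
            a["pi_w_t"].append([0.5 * (typ.pi_w[p[0]] + typ.pi_w[p[1]]) for p in pairs])
            a["pi_w_b"].append([0.5 * (base.pi_w[p[0]] + base.pi_w[p[1]]) for p in pairs])
            a["pi_b_t"].append([typ.pi_b[p] for p in pairs])
            a["pi_b_b"].append([base.pi_b[p] for p in pairs])
        if (i + 1) % 500 == 0:
            logger.info("processed %d/%d replicates", i + 1, config.n_replicates)

    records = []
    for scheme, threshold in cells:
        a = acc[(scheme, threshold)]
        mean_candidates = float(np.mean(a["n_candidates"])) if a["n_candidates"] else float("nan")
        logger.info(
            "cell %s/%.3g: mean candidate sites %.1f, %d replicates excluded",
            scheme, threshold, mean_candidates, a["n_excluded"],
        )
        for k, pair in enumerate(pairs):
            def col(name: str) -> np.ndarray:
                rows = a[name]
                return np.array([r[k] for r in rows]) if rows else np.zeros(0)

            records.append(
                aggregate_deviations(
                    scheme=scheme,
                    threshold=threshold,
                    pop_pair=pair,
                    fst_typing=col("fst_t"),
                    fst_reseq=col("fst_r"),
                    pi_w_typing=col("pi_w_t"),
                    pi_w_baseline=col("pi_w_b"),
                    pi_b_typing=col("pi_b_t"),
                    pi_b_baseline=col("pi_b_b"),
                    n_excluded=a["n_excluded"],
                )
            )
            records[-1].extras["mean_candidate_sites"] = mean_candidates
    meta = {
        "model": dem.label,
        "n_replicates": config.n_replicates,
        "master_seed": config.master_seed,
        "n_markers": config.n_markers,
        "null_scheme": null_scheme,
    }
    return ExperimentTable(records=records, meta=meta)


def run_pca_experiment(
    config: ExperimentConfig,
    n_replicates: int = 100,
    k: int = 2,
    pca_threshold: float = 0.05,
) -> tuple[dict[str, PcaResult], pd.DataFrame]:
    """PCA under no ascertainment and each scheme, over shared replicates.

    Pools all candidate sites (threshold ``pca_threshold`` in the
    discovery panel, no fixed-size marker draw) across ``n_replicates``
    replicates of a three-population demography, then decomposes each
    pooled matrix and tabulates pairwise cluster-separation ratios.
    """
    dem = config.demography
    if dem.n_pops < 3:
        raise ValueError("the PCA experiment needs a three-population demography")
    if n_replicates < 2:
        logger.warning("PCA over %d replicate(s): output will be noisy", n_replicates)
    reps = simulate_replicates(dem, config.design, config.params, n_replicates, config.master_seed)
    runs: dict[str, PcaResult] = {}
    for name in ("none",) + tuple(config.schemes):
        if name == "none":
            asc = None
        else:
            asc = AscertainmentConfig(
                scheme=name,
                discovery_population=config.discovery_population,
                maf_threshold=pca_threshold,
                n_markers=1,  # unused: PCA keeps all candidates
                unseen_vetoes=config.unseen_vetoes,
            )
        pca_input = build_pca_input(reps, asc)
        if pca_input.n_sites < k:
            logger.warning(
                "scheme %s: %d candidate site(s) across replicates, fewer than k=%d; skipping PCA",
                name, pca_input.n_sites, k,
            )
            runs[name] = None
            continue
        runs[name] = run_pca(pca_input, k=k)
    rows = []
    pairs = list(itertools.combinations(range(dem.n_pops), 2))
    for name, res in runs.items():
        for a, b in pairs:
            rows.append(
                {
                    "scheme": name,
                    "pop_pair": f"{pop_name(a)}-{pop_name(b)}",
                    "separation": float("nan") if res is None else cluster_separation(res, a, b, k_dims=k),
                    "n_sites_used": 0 if res is None else res.n_sites_used,
                }
            )
    return runs, pd.DataFrame(rows)
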