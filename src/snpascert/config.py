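"""YAML config schema: demography, sampling, ascertainment, experiment.

The config file has four sections::

    demography:
      model: island | stepping_stone | split | custom
      # island:          n_pops, scaled_migration, convention (total|pairwise)
      # stepping_stone:  n_pops, scaled_migration_adjacent
      # split:           f1, f2, t1, t2
      # custom:          deme_sizes, migration_matrix, events
    simulation:  theta, rho, length, N0
    sampling:    n_discovery, n_typing, reuse_discovery_as_typing
    experiment:  schemes, thresholds, n_markers, n_replicates,
                 discovery_population, master_seed, strict_threshold,
                 output_dir

Populations are named I, II, III (1-based) in user-facing output and
indexed 0-based internally.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .demography import (
    DemographyEvent,
    DemographySpec,
    IslandModelSpec,
    SimulationParams,
    SplitModelSpec,
    SteppingStoneSpec,
    build_island,
    build_split,
    build_stepping_stone,
)
from .replicates import SamplingDesign

__all__ = [
    "demography_to_dict",
    "demography_from_dict",
    "build_demography",
    "load_config",
    "dump_config",
]

ROMAN = ("I", "II", "III", "IV", "V")


def pop_name(index: int) -> str:
    """0-based internal index -> 1-based roman label (population-I, ...)."""
    return ROMAN[index] if index < len(ROMAN) else str(index + 1)


def demography_to_dict(spec: DemographySpec) -> dict:
    """Serialize a generic DemographySpec (round-trips exactly)."""
    return {
        "model": "custom",
        "label": spec.label,
        "deme_sizes": [float(s) for s in spec.deme_sizes],
        "migration_matrix": [list(row) for row in spec.migration_matrix],
        "events": [
            {
                "time": e.time,
                "kind": e.kind,
                "source": e.source,
                **({"dest": e.dest} if e.dest is not None else {}),
                **({"size": e.size} if e.size is not None else {}),
            }
            for e in spec.events
        ],
    }


def demography_from_dict(d: dict) -> DemographySpec:
    events = tuple(
        DemographyEvent(
            time=e["time"],
            kind=e["kind"],
            source=e["source"],
            dest=e.get("dest"),
            size=e.get("size"),
        )
        for e in d.get("events", [])
    )
    return DemographySpec(
        deme_sizes=tuple(float(s) for s in d["deme_sizes"]),
        migration_matrix=tuple(tuple(float(x) for x in row) for row in d["migration_matrix"]),
        events=events,
        label=d.get("label", "custom"),
    )


def build_demography(section: dict, params: SimulationParams) -> DemographySpec:
    """Construct a DemographySpec from the config's demography section."""
    model = section.get("model", "island")
    if model == "island":
        spec = IslandModelSpec(
            n_pops=int(section.get("n_pops", 2)),
            scaled_migration=float(section["scaled_migration"]),
            convention=section.get("convention", "total"),
        )
        return build_island(spec, params)
    if model == "stepping_stone":
        spec = SteppingStoneSpec(
            n_pops=int(section.get("n_pops", 3)),
            scaled_migration_adjacent=float(section["scaled_migration_adjacent"]),
        )
        return build_stepping_stone(spec, params)
    if model == "split":
        spec = SplitModelSpec(
            f1=float(section.get("f1", 0.2)),
            f2=float(section.get("f2", 0.1)),
            t1=float(section.get("t1", 0.3)),
            t2=float(section.get("t2", 0.2)),
        )
        return build_split(spec, params)
    if model == "custom":
        return demography_from_dict(section)
    raise ValueError(f"unknown demographic model {model!r}")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "demography" not in cfg:
        raise ValueError(f"{path}: config must be a mapping with a 'demography' section")
    return cfg


def dump_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def simulation_params(cfg: dict) -> SimulationParams:
    sec = cfg.get("simulation", {})
    return SimulationParams(
        theta=float(sec.get("theta", 20.0)),
        rho=float(sec.get("rho", 20.0)),
        length=int(sec.get("length", 50_000)),
        N0=int(sec.get("N0", 10_000)),
    )


def sampling_design(cfg: dict) -> SamplingDesign:
    sec = cfg.get("sampling", {})
    return SamplingDesign(
        n_discovery=int(sec.get("n_discovery", 100)),
        n_typing=int(sec.get("n_typing", 100)),
        reuse_discovery_as_typing=bool(sec.get("reuse_discovery_as_typing", False)),
    )
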