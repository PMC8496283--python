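"""Demographic models for the ascertainment-bias simulation study.

Four demographies are supported: a symmetric two- or three-island model, a
1D stepping-stone model with three demes, and a serial population-split
model in which each daughter population is founded through a one-generation
bottleneck.  All of them are expressed as a generic :class:`DemographySpec`
(deme sizes, a scaled migration matrix in ``4*N0*m`` units, and a
time-ordered event list) that the simulation backend consumes.

Times are in units of ``4*N0`` generations and migration rates in
``4*N0*m`` units throughout, matching the classical coalescent
parameterization of Hudson's ``ms``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimulationParams",
    "IslandModelSpec",
    "SteppingStoneSpec",
    "SplitModelSpec",
    "DemographyEvent",
    "DemographySpec",
    "build_island",
    "build_stepping_stone",
    "build_split",
]


@dataclass(frozen=True)
class SimulationParams:
    """Locus-scale coalescent parameters.

    Parameters
    ----------
    theta : float
        Scaled mutation rate ``4*N0*mu*l`` for the whole locus.
    rho : float
        Scaled recombination rate ``4*N0*r*l`` for the whole locus.
    length : int
        Locus length in base pairs.
    N0 : int
        Reference diploid deme size used to de-scale rates.
    """

    theta: float = 20.0
    rho: float = 20.0
    length: int = 50_000
    N0: int = 10_000

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError(f"theta must be positive, got {self.theta}")
        if self.rho < 0:
            raise ValueError(f"rho must be non-negative, got {self.rho}")
        if self.length < 1:
            raise ValueError(f"length must be >= 1 bp, got {self.length}")
        if self.N0 < 2:
            raise ValueError(f"N0 must be >= 2, got {self.N0}")

    @property
    def mu_per_site(self) -> float:
        """Mutation rate per site per generation implied by theta."""
        return self.theta / (4.0 * self.N0 * self.length)

    @property
    def r_per_site(self) -> float:
        """Recombination rate per site per generation implied by rho."""
        return self.rho / (4.0 * self.N0 * self.length)


@dataclass(frozen=True)
class IslandModelSpec:
    """Symmetric island model: equal constant-size demes, symmetric migration.

    ``scaled_migration`` is ``4*N0*m``.  Under the ``"total"`` (ms ``-I``)
    convention it is the total scaled immigration rate into each deme, split
    equally among the other demes; under ``"pairwise"`` it is the rate of
    each deme pair.  The two conventions coincide for two demes.
    """

    n_pops: int
    scaled_migration: float
    convention: str = "total"

    def __post_init__(self) -> None:
        if self.n_pops < 2:
            raise ValueError(f"island model needs >= 2 demes, got {self.n_pops}")
        if self.scaled_migration < 0:
            raise ValueError(f"negative migration rate: {self.scaled_migration}")
        if self.convention not in ("total", "pairwise"):
            raise ValueError(f"unknown migration convention {self.convention!r}")


@dataclass(frozen=True)
class SteppingStoneSpec:
    """1D stepping-stone: migration only between adjacent demes.

    ``scaled_migration_adjacent`` is the per-pair ``4*N0*m`` between demes
    ``i`` and ``i+1``.
    """

    n_pops: int = 3
    scaled_migration_adjacent: float = 0.3

    def __post_init__(self) -> None:
        if self.n_pops < 3:
            raise ValueError(f"stepping stone needs >= 3 demes, got {self.n_pops}")
        if self.scaled_migration_adjacent < 0:
            raise ValueError(
                f"negative migration rate: {self.scaled_migration_adjacent}"
            )


@dataclass(frozen=True)
class SplitModelSpec:
    """Serial split model: II founded from I at t1, III from II at t2.

    Each founding passes through a one-generation bottleneck at ``f*N0``
    before the daughter recovers to ``N0``.  Times are in ``4*N0``
    generations, counted back from the present; no migration at any time.
    """

    f1: float = 0.2
    f2: float = 0.1
    t1: float = 0.3
    t2: float = 0.2

    def __post_init__(self) -> None:
        for name, f in (("f1", self.f1), ("f2", self.f2)):
            if not (0 < f <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {f}")
        if not (self.t1 > self.t2 > 0):
            raise ValueError(
                f"split times must satisfy t1 > t2 > 0, got t1={self.t1}, t2={self.t2}"
            )


@dataclass(frozen=True)
class DemographyEvent:
    """One backward-in-time event.

    ``kind`` is ``"split"`` (deme ``source`` merges into deme ``dest``) or
    ``"size-change"`` (deme ``source`` changes to ``size`` diploids).
    ``time`` is in ``4*N0`` units; deme indices are 0-based internally.
    """

    time: float
    kind: str
    source: int
    dest: int | None = None
    size: float | None = None

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"event time must be positive, got {self.time}")
        if self.kind not in ("split", "size-change"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "split" and self.dest is None:
            raise ValueError("split event needs a destination deme")
        if self.kind == "size-change" and (self.size is None or self.size <= 0):
            raise ValueError("size-change event needs a positive size")


@dataclass(frozen=True)
class DemographySpec:
    """Generic demography: deme sizes, scaled migration matrix, event list.

    ``migration_matrix[i][j]`` is the scaled (``4*N0*m``) rate at which
    deme ``i`` receives lineages from deme ``j`` (backwards in time); the
    diagonal is zero.  Events are sorted ascending in time.
    """

    deme_sizes: tuple[float, ...]
    migration_matrix: tuple[tuple[float, ...], ...]
    events: tuple[DemographyEvent, ...] = field(default_factory=tuple)
    label: str = "custom"

    def __post_init__(self) -> None:
        n = len(self.deme_sizes)
        mat = np.asarray(self.migration_matrix, dtype=float)
        if mat.shape != (n, n):
            raise ValueError(
                f"migration matrix shape {mat.shape} does not match {n} demes"
            )
        if (mat < 0).any():
            raise ValueError("migration matrix has negative entries")
        if np.diag(mat).any():
            raise ValueError("migration matrix diagonal must be zero")
        if any(s <= 0 for s in self.deme_sizes):
            raise ValueError("deme sizes must be positive")
        times = [e.time for e in self.events]
        if times != sorted(times):
            raise ValueError("events must be sorted ascending in time")

    @property
    def n_pops(self) -> int:
        return len(self.deme_sizes)

    def migration_array(self) -> np.ndarray:
        return np.asarray(self.migration_matrix, dtype=float)


def _matrix_tuple(mat: np.ndarray) -> tuple[tuple[float, ...], ...]:
    return tuple(tuple(float(x) for x in row) for row in mat)


def build_island(spec: IslandModelSpec, params: SimulationParams | None = None) -> DemographySpec:
    """Build a symmetric island model demography.

    Under the default ``"total"`` convention each deme's total scaled
    immigration equals ``spec.scaled_migration``, divided equally among the
    ``n_pops - 1`` source demes (the ms ``-I`` reading of ``4*N0*m``); under
    ``"pairwise"`` each off-diagonal entry equals it directly.
    """
    params = params or SimulationParams()
    n = spec.n_pops
    if spec.convention == "total":
        per_pair = spec.scaled_migration / (n - 1)
    else:
        per_pair = spec.scaled_migration
    mat = np.full((n, n), per_pair)
    np.fill_diagonal(mat, 0.0)
    return DemographySpec(
        deme_sizes=(float(params.N0),) * n,
        migration_matrix=_matrix_tuple(mat),
        events=(),
        label=f"island{n}",
    )


def build_stepping_stone(
    spec: SteppingStoneSpec, params: SimulationParams | None = None
) -> DemographySpec:
    """Build a 1D stepping-stone demography (adjacent-deme migration only)."""
    params = params or SimulationParams()
    n = spec.n_pops
    mat = np.zeros((n, n))
    for i in range(n - 1):
        mat[i, i + 1] = spec.scaled_migration_adjacent
        mat[i + 1, i] = spec.scaled_migration_adjacent
    return DemographySpec(
        deme_sizes=(float(params.N0),) * n,
        migration_matrix=_matrix_tuple(mat),
        events=(),
        label=f"stepping_stone{n}",
    )


def build_split(
    spec: SplitModelSpec, params: SimulationParams | None = None
) -> DemographySpec:
    """Build the serial population-split demography.

    Backward in time: at ``t2`` deme III (index 2) merges into deme II
    (index 1); at ``t1`` deme II merges into deme I (index 0).  Each
    daughter spends its first forward-time generation at ``f * N0``, which
    backwards is a size-change to ``f*N0`` one generation (``1/(4*N0)``
    scaled units) before its merge.  No migration at any time.
    """
    params = params or SimulationParams()
    one_gen = 1.0 / (4.0 * params.N0)
    N0 = float(params.N0)
    events = (
        DemographyEvent(spec.t2 - one_gen, "size-change", source=2, size=spec.f2 * N0),
        DemographyEvent(spec.t2, "split", source=2, dest=1),
        DemographyEvent(spec.t1 - one_gen, "size-change", source=1, size=spec.f1 * N0),
        DemographyEvent(spec.t1, "split", source=1, dest=0),
    )
    mat = np.zeros((3, 3))
    return DemographySpec(
        deme_sizes=(N0, N0, N0),
        migration_matrix=_matrix_tuple(mat),
        events=events,
        label="split3",
    )
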