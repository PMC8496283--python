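"""Coalescent replicate generation and ms-format interchange.

One replicate is a binary haplotype matrix (0 = ancestral, 1 = derived)
with continuous site positions, produced by neutral coalescent simulation
with recombination under a :class:`~snpascert.demography.DemographySpec`.
Each population contributes ``n_discovery`` haplotypes for the discovery
panel followed by ``n_typing`` haplotypes for typing; the two roles are
disjoint samples by default.

An established coalescent engine (msprime) backs the simulation; this
module owns the sampling design, the seeding scheme, and the ms-format
text reader/writer used for interchange with Hudson's ``ms``.
"""

from __future__ import annotations

from dataclasses import dataclass

import msprime
import numpy as np

from .demography import DemographySpec, SimulationParams

__all__ = [
    "SamplingDesign",
    "HaplotypeDataset",
    "simulate_replicate",
    "replicate_seed",
    "parse_ms_output",
    "write_ms_output",
    "write_vcf",
]

DISCOVERY = 0
TYPING = 1


@dataclass(frozen=True)
class SamplingDesign:
    """Per-population sample sizes for discovery and typing panels.

    ``reuse_discovery_as_typing=True`` types the discovery haplotypes
    themselves instead of a disjoint typing sample, the design variant in
    which ascertainment truncation is sharpest.
    """

    n_discovery: int = 100
    n_typing: int = 100
    reuse_discovery_as_typing: bool = False

    def __post_init__(self) -> None:
        if self.n_discovery < 2:
            raise ValueError(f"n_discovery must be >= 2, got {self.n_discovery}")
        if self.n_typing < 2:
            raise ValueError(f"n_typing must be >= 2, got {self.n_typing}")

    @property
    def haplotypes_per_pop(self) -> int:
        if self.reuse_discovery_as_typing:
            return self.n_discovery
        return self.n_discovery + self.n_typing


@dataclass
class HaplotypeDataset:
    """One replicate's binary haplotype matrix with site positions.

    Attributes
    ----------
    matrix : ndarray of shape (n_haplotypes, n_sites), int8
        0 = ancestral, 1 = derived allele.
    positions : ndarray of float
        Per-site relative position in [0, 1), strictly increasing.
    pop_labels : ndarray of int
        0-based population index per haplotype.
    role_labels : ndarray of int
        ``DISCOVERY`` (0) or ``TYPING`` (1) per haplotype.
    """

    matrix: np.ndarray
    positions: np.ndarray
    pop_labels: np.ndarray
    role_labels: np.ndarray
    replicate_id: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.matrix = np.ascontiguousarray(self.matrix, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=float)
        self.pop_labels = np.asarray(self.pop_labels, dtype=np.int64)
        self.role_labels = np.asarray(self.role_labels, dtype=np.int64)
        n_hap, n_sites = self.matrix.shape
        if self.positions.shape != (n_sites,):
            raise ValueError("positions length does not match site count")
        if self.pop_labels.shape != (n_hap,) or self.role_labels.shape != (n_hap,):
            raise ValueError("label vectors must have one entry per haplotype")
        if n_sites and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("haplotype matrix entries must be 0/1")

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_pops(self) -> int:
        return int(self.pop_labels.max()) + 1 if self.n_haplotypes else 0

    def rows(self, pop: int | None = None, role: int | None = None) -> np.ndarray:
        """Boolean row mask for a population and/or role."""
        mask = np.ones(self.n_haplotypes, dtype=bool)
        if pop is not None:
            mask &= self.pop_labels == pop
        if role is not None:
            mask &= self.role_labels == role
        return mask

    def submatrix(self, pop: int | None = None, role: int | None = None) -> np.ndarray:
        return self.matrix[self.rows(pop, role)]

    def derived_counts(self, pop: int | None = None, role: int | None = None) -> np.ndarray:
        """Per-site derived-allele counts over the selected rows."""
        return self.submatrix(pop, role).sum(axis=0)


def replicate_seed(master_seed: int, replicate_id: int) -> int:
    """Derive an independent, reproducible per-replicate seed.

    Counter-based: replicate ``i`` gets the same seed no matter how many
    other replicates run or in what order, so parallel execution is
    deterministic.  Kept in msprime's valid range [1, 2**31 - 2].
    """
    ss = np.random.SeedSequence([int(master_seed), int(replicate_id)])
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31 - 2)) + 1


def _to_msprime_demography(spec: DemographySpec, params: SimulationParams) -> msprime.Demography:
    """De-scale a DemographySpec into an msprime Demography in generations."""
    dem = msprime.Demography()
    for i, size in enumerate(spec.deme_sizes):
        dem.add_population(name=f"pop{i}", initial_size=size)
    # scaled 4*N0*m -> per-generation backwards migration rate
    mat = spec.migration_array() / (4.0 * params.N0)
    n = spec.n_pops
    for i in range(n):
        for j in range(n):
            if i != j and mat[i, j] > 0:
                dem.set_migration_rate(source=f"pop{i}", dest=f"pop{j}", rate=mat[i, j])
    four_n0 = 4.0 * params.N0
    for ev in spec.events:
        t_gen = ev.time * four_n0
        if ev.kind == "size-change":
            dem.add_population_parameters_change(
                time=t_gen, population=f"pop{ev.source}", initial_size=ev.size
            )
        else:  # split: source merges into dest, backwards in time
            dem.add_mass_migration(
                time=t_gen, source=ev.source, dest=ev.dest, proportion=1.0
            )
    dem.sort_events()
    return dem


def simulate_replicate(
    demography: DemographySpec,
    design: SamplingDesign,
    params: SimulationParams,
    seed: int,
    replicate_id: int = 0,
) -> HaplotypeDataset:
    """Simulate one replicate under the given demography.

    Samples ``design.haplotypes_per_pop`` haploid genomes per deme; within
    each deme the first ``n_discovery`` rows are the discovery panel and
    the rest the typing sample.  Mutations follow the infinite-sites
    convention (one derived allele per site, continuous positions);
    recombination acts at rate ``params.rho`` across ``params.length``.
    Deterministic given ``seed``.
    """
    try:
        dem = _to_msprime_demography(demography, params)
        per_pop = design.haplotypes_per_pop
        samples = [
            msprime.SampleSet(per_pop, population=f"pop{i}", ploidy=1)
            for i in range(demography.n_pops)
        ]
        ts = msprime.sim_ancestry(
            samples=samples,
            demography=dem,
            sequence_length=params.length,
            recombination_rate=params.r_per_site,
            ploidy=2,
            random_seed=seed,
        )
        mts = msprime.sim_mutations(
            ts,
            rate=params.mu_per_site,
            model=msprime.BinaryMutationModel(),
            discrete_genome=False,
            random_seed=seed,
        )
    except Exception as exc:  # pragma: no cover - engine failures are rare
        raise RuntimeError(f"simulation failed for replicate {replicate_id}: {exc}") from exc

    n_total = design.haplotypes_per_pop * demography.n_pops
    if mts.num_sites:
        matrix = mts.genotype_matrix().T.astype(np.int8)
        positions = np.array([s.position for s in mts.sites()]) / params.length
        # keep only sites segregating in the full sample
        counts = matrix.sum(axis=0)
        seg = (counts > 0) & (counts < n_total)
        matrix = matrix[:, seg]
        positions = positions[seg]
    else:
        matrix = np.zeros((n_total, 0), dtype=np.int8)
        positions = np.zeros(0)

    pop_labels = np.repeat(np.arange(demography.n_pops), design.haplotypes_per_pop)
    if design.reuse_discovery_as_typing:
        role_labels = np.full(n_total, DISCOVERY)
    else:
        per_pop_roles = np.concatenate(
            [np.full(design.n_discovery, DISCOVERY), np.full(design.n_typing, TYPING)]
        )
        role_labels = np.tile(per_pop_roles, demography.n_pops)
    return HaplotypeDataset(
        matrix=matrix,
        positions=positions,
        pop_labels=pop_labels,
        role_labels=role_labels,
        replicate_id=replicate_id,
        seed=seed,
    )


class MsParseError(ValueError):
    """Malformed ms-format text; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def parse_ms_output(
    text: str,
    design: SamplingDesign,
    pop_sizes: list[int],
) -> list[HaplotypeDataset]:
    """Parse Hudson ms-format text into one dataset per replicate block.

    Rows are assigned to populations in listed order; within each
    population the first ``n_discovery`` rows are the discovery panel and
    the next ``n_typing`` the typing sample (recorded convention).
    ``pop_sizes`` gives haplotype counts per population and must sum to the
    row count of every block.
    """
    for size in pop_sizes:
        if size != design.haplotypes_per_pop:
            raise ValueError(
                f"pop size {size} does not match design "
                f"({design.haplotypes_per_pop} haplotypes per population)"
            )
    n_total = sum(pop_sizes)
    lines = text.splitlines()
    datasets: list[HaplotypeDataset] = []
    i = 0
    # skip everything before the first replicate delimiter (command echo, seeds)
    while i < len(lines) and not lines[i].startswith("//"):
        i += 1
    rep = 0
    while i < len(lines):
        assert lines[i].startswith("//")
        i += 1
        # locate segsites
        while i < len(lines) and lines[i].strip() == "":
            i += 1
        if i >= len(lines) or not lines[i].startswith("segsites:"):
            raise MsParseError("expected 'segsites:' after '//'", i + 1)
        try:
            segsites = int(lines[i].split(":", 1)[1])
        except ValueError:
            raise MsParseError("unparsable segsites count", i + 1) from None
        i += 1
        if segsites == 0:
            matrix = np.zeros((n_total, 0), dtype=np.int8)
            positions = np.zeros(0)
        else:
            while i < len(lines) and lines[i].strip() == "":
                i += 1
            if i >= len(lines) or not lines[i].startswith("positions:"):
                raise MsParseError("expected 'positions:' line", i + 1)
            pos_fields = lines[i].split(":", 1)[1].split()
            if len(pos_fields) != segsites:
                raise MsParseError(
                    f"{len(pos_fields)} positions for {segsites} segsites", i + 1
                )
            positions = np.array([float(p) for p in pos_fields])
            i += 1
            rows = []
            for r in range(n_total):
                if i >= len(lines):
                    raise MsParseError(
                        f"expected {n_total} haplotype rows, got {r}", i
                    )
                row = lines[i].strip()
                if len(row) != segsites:
                    raise MsParseError(
                        f"row length {len(row)} != segsites {segsites}", i + 1
                    )
                if set(row) - {"0", "1"}:
                    raise MsParseError("haplotype row has non-0/1 character", i + 1)
                rows.append(np.frombuffer(row.encode(), dtype=np.uint8) - ord("0"))
                i += 1
            matrix = np.array(rows, dtype=np.int8)
        pop_labels = np.repeat(np.arange(len(pop_sizes)), pop_sizes)
        if design.reuse_discovery_as_typing:
            role_labels = np.full(n_total, DISCOVERY)
        else:
            per_pop_roles = np.concatenate(
                [np.full(design.n_discovery, DISCOVERY), np.full(design.n_typing, TYPING)]
            )
            role_labels = np.tile(per_pop_roles, len(pop_sizes))
        datasets.append(
            HaplotypeDataset(
                matrix=matrix,
                positions=positions,
                pop_labels=pop_labels,
                role_labels=role_labels,
                replicate_id=rep,
            )
        )
        rep += 1
        while i < len(lines) and not lines[i].startswith("//"):
            i += 1
    return datasets


def write_ms_output(datasets: list[HaplotypeDataset], header: str = "snpascert") -> str:
    """Serialize datasets as ms-format text (round-trip partner of the parser)."""
    out = [header, ""]
    for ds in datasets:
        out.append("//")
        out.append(f"segsites: {ds.n_sites}")
        if ds.n_sites:
            out.append("positions: " + " ".join(f"{p:.6f}" for p in ds.positions))
            for row in ds.matrix:
                out.append("".join("1" if x else "0" for x in row))
        out.append("")
    return "\n".join(out)


def write_vcf(
    dataset: HaplotypeDataset,
    path,
    length: int = 50_000,
    site_indices: np.ndarray | None = None,
    rows_mask: np.ndarray | None = None,
    source: str = "snpascert",
) -> None:
    """Write a minimal haploid VCF for a replicate (or a typed subset of it).

    CHROM is ``rep<replicate_id>``, POS is ``floor(position*length)+1``,
    alleles are A/T placeholders (the simulation tracks ancestral/derived
    state, not nucleotides), and GT fields are haploid 0/1.
    """
    sites = np.arange(dataset.n_sites) if site_indices is None else np.asarray(site_indices)
    mask = np.ones(dataset.n_haplotypes, bool) if rows_mask is None else rows_mask
    sub = dataset.matrix[np.ix_(mask, sites)]
    pops = dataset.pop_labels[mask]
    names = [f"pop{p}_hap{k}" for k, p in enumerate(pops)]
    chrom = f"rep{dataset.replicate_id}"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source};seed={dataset.seed}\n")
        fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(names) + "\n")
        for col, s in enumerate(sites):
            pos = int(dataset.positions[s] * length) + 1
            gts = "\t".join(str(int(g)) for g in sub[:, col])
            fh.write(f"{chrom}\t{pos}\tsite{s}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")
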