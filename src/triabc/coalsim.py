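"""Structured-coalescent simulation of multi-locus RAD-like data.

Genealogies are generated with msprime under the three-population model
described in :mod:`triabc.model_space`; mutations are then placed on the
trees in-house under one of two modes:

* ``theta`` — a Poisson number of infinite-sites mutations with intensity
  mu * L * (total branch length in generations), i.e. conditioned on the
  per-locus theta = 4*N*mu*L through the genealogy itself.  Loci that end
  up without any mutation are monomorphic and excluded downstream.
* ``fixed_snp`` — exactly the observed number of SNPs for the locus is
  placed, each mutation landing on a branch with probability proportional
  to its length.  This conditions the simulations on the observed number
  of polymorphic sites, sidestepping the monomorphic-locus ascertainment.

Loci are treated as non-recombining (RAD loci are a few hundred bp), so a
single genealogy underlies each locus.  Derived alleles are encoded as 1
with the simulation root state as 0, which makes ABBA-BABA polarization
exact for simulated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np

from .model_space import (
    ConfigurationError,
    HeterogeneitySubmodel,
    MigrationEpoch,
    ParameterDraw,
    ScenarioCategory,
    SpeciesTrio,
    migration_schedule,
)

__all__ = [
    "LocusSpec",
    "GenomicFactors",
    "SimulatedLocus",
    "draw_genomic_factors",
    "build_demography",
    "simulate_genealogy",
    "mutate_theta",
    "mutate_fixed",
    "simulate_dataset",
    "write_snp_table",
    "read_snp_table",
]

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class LocusSpec:
    """Shape of one locus to simulate."""

    length_bp: int
    observed_snp_count: int = 0  # used only in fixed-SNP mode
    locus_id: str = ""

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError("locus length must be positive")
        if not 0 <= self.observed_snp_count <= self.length_bp:
            raise ValueError("SNP count must be in [0, length]")


@dataclass
class GenomicFactors:
    """Per-locus multiplicative rescalings modelling linked selection.

    ``ne`` rescales effective sizes (mean 1 across loci); ``mig`` rescales
    migration rates (in [0, 1]).  Homogeneous sub-models use all-ones.
    """

    ne: np.ndarray
    mig: np.ndarray

    def __post_init__(self) -> None:
        self.ne = np.asarray(self.ne, dtype=float)
        self.mig = np.asarray(self.mig, dtype=float)
        if (self.ne <= 0).any() or (self.mig < 0).any() or (self.mig > 1).any():
            raise ValueError("invalid factor values")


@dataclass
class SimulatedLocus:
    """Biallelic SNP matrix for one locus (0 = ancestral, 1 = derived)."""

    genotypes: np.ndarray  # (n_sequences, n_sites) int8
    pops: np.ndarray  # population index (0, 1, 2) per row, grouped
    length_bp: int
    positions: np.ndarray  # 0-based site positions within the locus
    locus_id: str = ""

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def pop_matrix(self, pop: int) -> np.ndarray:
        return self.genotypes[self.pops == pop]


def draw_genomic_factors(
    submodel: HeterogeneitySubmodel,
    draw: ParameterDraw,
    n_loci: int,
    rng: np.random.Generator | int | None = None,
) -> GenomicFactors:
    """Draw per-locus rescaling factors for a dataset.

    Ne factors are Beta(ne_shape_a, ne_shape_b) draws rescaled by the
    distribution mean so that E[factor] = 1; migration factors are raw
    Beta(mig_shape_a, mig_shape_b) draws in [0, 1].
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(rng)
    if submodel.ne_hetero:
        a, b = draw.ne_shape_a, draw.ne_shape_b
        ne = rng.beta(a, b, size=n_loci) * (a + b) / a
        ne = np.clip(ne, 1e-4, None)  # keep locus sizes strictly positive
    else:
        ne = np.ones(n_loci)
    if submodel.nm_hetero:
        mig = rng.beta(draw.mig_shape_a, draw.mig_shape_b, size=n_loci)
    else:
        mig = np.ones(n_loci)
    return GenomicFactors(ne=ne, mig=mig)


def build_demography(
    draw: ParameterDraw,
    schedule: list[MigrationEpoch] | None = None,
    ne_factor: float = 1.0,
    mig_factor: float = 1.0,
) -> msprime.Demography:
    """msprime demography for one locus of one parameter draw.

    The Ne factor multiplies every population size in every epoch; the
    migration factor multiplies the locus's scaled migration rates (4Nm),
    so per-generation backward rates are M * h / (4 * N * g) with N the
    recipient lineage's current size.  Epoch boundaries are applied exactly
    at T_trans12 / T_split12 / T_split123 (the boundary belongs to the
    older epoch).
    """
    if schedule is None:
        schedule = migration_schedule(draw.category, draw)
    g = ne_factor
    d = msprime.Demography()
    d.add_population(name="P1", initial_size=draw.N_P1 * g)
    d.add_population(name="P2", initial_size=draw.N_P2 * g)
    d.add_population(name="P3", initial_size=draw.N_P3 * g)
    d.add_population(name="anc12", initial_size=draw.N_anc12 * g)
    d.add_population(name="anc123", initial_size=draw.N_anc123 * g)

    # recent size changes of the modern lineages: founding size applies
    # earlier (backwards in time) than T_change
    for pop, t, nf in (
        ("P1", draw.T_change_P1, draw.N_found_P1),
        ("P2", draw.T_change_P2, draw.N_found_P2),
        ("P3", draw.T_change_P3, draw.N_found_P3),
    ):
        d.add_population_parameters_change(time=t, population=pop,
                                           initial_size=nf * g)

    d.add_population_split(time=draw.T_split12, derived=["P1", "P2"],
                           ancestral="anc12")
    d.add_population_split(time=draw.T_split123, derived=["anc12", "P3"],
                           ancestral="anc123")

    current_size = {"P1": draw.N_P1, "P2": draw.N_P2, "P3": draw.N_P3,
                    "anc12": draw.N_anc12}

    def backward_rate(scaled: float, dest_pop: str) -> float:
        # scaled 4Nm held fixed at the draw's value irrespective of the
        # locus Ne rescaling, so m adapts to the rescaled size
        n = current_size[dest_pop] * g
        return scaled * mig_factor / (4.0 * n) if scaled > 0 else 0.0

    def set_pair(a: str, b: str, scaled: float, start: float, end: float) -> None:
        if scaled <= 0 or end <= start:
            return
        for x, y in ((a, b), (b, a)):
            rate = backward_rate(scaled, x)
            if start == 0.0:
                d.set_migration_rate(source=x, dest=y, rate=rate)
            else:
                d.add_migration_rate_change(time=start, source=x, dest=y,
                                            rate=rate)
            if end < draw.T_split123 and y != "anc12" and x != "anc12":
                # population splits already zero rates at the split times
                if end not in (draw.T_split12, draw.T_split123):
                    d.add_migration_rate_change(time=end, source=x, dest=y,
                                                rate=0.0)

    for ep in schedule:
        a, b = ep.pair
        set_pair(a, b, ep.rate, ep.start, ep.end)
        if b == "P3" and ep.end > draw.T_split12:
            # outer migration persists with the P1/P2 ancestor after the
            # inner merge, at the same scaled rate
            set_pair("anc12", "P3", ep.rate, draw.T_split12, ep.end)

    d.sort_events()
    return d


def _sample_sets(trio: SpeciesTrio) -> list[msprime.SampleSet]:
    return [
        msprime.SampleSet(trio.n_seq_p1, population="P1", ploidy=1),
        msprime.SampleSet(trio.n_seq_p2, population="P2", ploidy=1),
        msprime.SampleSet(trio.n_seq_p3, population="P3", ploidy=1),
    ]


def simulate_genealogy(
    draw: ParameterDraw,
    trio: SpeciesTrio,
    ne_factor: float = 1.0,
    mig_factor: float = 1.0,
    rng: np.random.Generator | int | None = None,
):
    """Simulate one non-recombining genealogy (a tskit tree sequence).

    Branch lengths are in generations.  Sample nodes are ordered by
    population: P1 block first, then P2, then P3.
    """
    rng = np.random.default_rng(rng)
    demog = build_demography(draw, ne_factor=ne_factor, mig_factor=mig_factor)
    seed = int(rng.integers(1, _MAX_SEED))
    return msprime.sim_ancestry(
        samples=_sample_sets(trio),
        demography=demog,
        ploidy=2,
        random_seed=seed,
        record_provenance=False,
    )


def _descendant_masks(ts) -> tuple[list[int], np.ndarray]:
    """Per-edge child sample sets (as bit masks) and branch lengths.

    Assumes a single non-recombining tree, so the edge table is the tree.
    Sample k corresponds to bit k.
    """
    parent = ts.edges_parent
    child = ts.edges_child
    times = ts.nodes_time
    n_samples = ts.num_samples
    masks = [0] * ts.num_nodes
    for k in range(n_samples):
        masks[k] = 1 << k
    # tskit edges are sorted so that children precede their parents
    for p, c in zip(parent.tolist(), child.tolist()):
        masks[p] |= masks[c]
    lengths = times[parent] - times[child]
    return [masks[c] for c in child], lengths


def _make_locus(
    ts,
    edge_masks: list[int],
    edge_idx: np.ndarray,
    length_bp: int,
    pops: np.ndarray,
    rng: np.random.Generator,
    locus_id: str,
) -> SimulatedLocus:
    n = ts.num_samples
    picked = [edge_masks[i] for i in edge_idx]
    # unpack bit masks into a samples x sites 0/1 matrix
    if n <= 63:
        chosen = np.array(picked, dtype=np.uint64)
        bits = (chosen[None, :] >> np.arange(n, dtype=np.uint64)[:, None]) & np.uint64(1)
    else:
        chosen = np.array(picked, dtype=object)
        bits = (chosen[None, :] >> np.arange(n, dtype=object)[:, None]) & 1
    genotypes = bits.astype(np.int8)
    positions = np.sort(rng.choice(length_bp, size=len(edge_idx),
                                   replace=False))
    return SimulatedLocus(
        genotypes=genotypes,
        pops=pops,
        length_bp=length_bp,
        positions=positions,
        locus_id=locus_id,
    )


def _pops_vector(trio: SpeciesTrio) -> np.ndarray:
    return np.repeat([0, 1, 2], trio.n_seq)


def _weighted_edges(lengths: np.ndarray, size: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Sample edge indices with probability proportional to branch length."""
    cum = np.cumsum(lengths)
    return np.searchsorted(cum, rng.random(size) * cum[-1], side="right")


def mutate_theta(
    ts,
    locus: LocusSpec,
    mu: float,
    trio: SpeciesTrio,
    rng: np.random.Generator | int | None = None,
) -> SimulatedLocus | None:
    """Place Poisson infinite-sites mutations; ``None`` marks a monomorphic locus.

    The Poisson intensity is mu * L * total branch length (generations), so
    the expected SNP count follows the locus's coalescent history.  The
    number of segregating sites is capped at L (finite locus length).
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    rng = np.random.default_rng(rng)
    edge_masks, lengths = _descendant_masks(ts)
    total = lengths.sum()
    n_mut = rng.poisson(mu * locus.length_bp * total)
    if n_mut == 0:
        return None
    n_mut = min(int(n_mut), locus.length_bp)
    idx = _weighted_edges(lengths, n_mut, rng)
    return _make_locus(ts, edge_masks, idx, locus.length_bp,
                       _pops_vector(trio), rng, locus.locus_id)


def mutate_fixed(
    ts,
    s_obs: int,
    trio: SpeciesTrio,
    length_bp: int,
    rng: np.random.Generator | int | None = None,
    locus_id: str = "",
) -> SimulatedLocus:
    """Place exactly ``s_obs`` mutations, branches weighted by length."""
    if s_obs < 1:
        raise ValueError("fixed-SNP mode requires at least one SNP per locus")
    rng = np.random.default_rng(rng)
    edge_masks, lengths = _descendant_masks(ts)
    idx = _weighted_edges(lengths, s_obs, rng)
    return _make_locus(ts, edge_masks, idx, length_bp,
                       _pops_vector(trio), rng, locus_id)


def simulate_dataset(
    draw: ParameterDraw,
    locus_specs: list[LocusSpec],
    mode: str = "theta",
    trio: SpeciesTrio | None = None,
    rng: np.random.Generator | int | None = None,
    mu: float = 3e-9,
    factors: GenomicFactors | None = None,
) -> list[SimulatedLocus]:
    """Simulate one multi-locus dataset under a parameter draw.

    In ``theta`` mode monomorphic loci are excluded, so the returned list
    may be shorter than ``locus_specs``; in ``fixed_snp`` mode exactly one
    polymorphic locus per spec is returned.  Homogeneous sub-models share
    a single demography across loci (batched replicates); heterogeneous
    sub-models rebuild it per locus with that locus's factors.
    """
    if not locus_specs:
        raise ValueError("locus_specs must be non-empty")
    if mode not in ("theta", "fixed_snp"):
        raise ValueError(f"unknown mode {mode!r}")
    trio = trio or SpeciesTrio()
    rng = np.random.default_rng(rng)
    n_loci = len(locus_specs)
    if factors is None:
        factors = draw_genomic_factors(draw.submodel, draw, n_loci, rng)
    if mode == "fixed_snp":
        for spec in locus_specs:
            if spec.observed_snp_count < 1:
                raise ValueError(
                    "fixed-SNP mode requires observed_snp_count >= 1 "
                    f"(locus {spec.locus_id!r})"
                )

    homogeneous = bool(np.all(factors.ne == 1.0) and np.all(factors.mig == 1.0))
    out: list[SimulatedLocus] = []

    def finish(ts, spec: LocusSpec) -> None:
        if mode == "theta":
            loc = mutate_theta(ts, spec, mu, trio, rng)
            if loc is not None:
                out.append(loc)
        else:
            out.append(mutate_fixed(ts, spec.observed_snp_count, trio,
                                    spec.length_bp, rng, spec.locus_id))

    if homogeneous:
        demog = build_demography(draw)
        seed = int(rng.integers(1, _MAX_SEED))
        reps = msprime.sim_ancestry(
            samples=_sample_sets(trio), demography=demog, ploidy=2,
            num_replicates=n_loci, random_seed=seed,
            record_provenance=False,
        )
        for spec, ts in zip(locus_specs, reps):
            finish(ts, spec)
    else:
        for i, spec in enumerate(locus_specs):
            ts = simulate_genealogy(draw, trio, factors.ne[i],
                                    factors.mig[i], rng)
            finish(ts, spec)
    return out


def write_snp_table(loci: list[SimulatedLocus], path) -> None:
    """Compact tabular serialization: one row per locus.

    Columns: locus id, length, per-sequence population indices, 0-based
    site positions, and one 0/1 genotype string per sequence.
    """
    lines = ["locus_id\tlength_bp\tpops\tpositions\tgenotypes"]
    for i, loc in enumerate(loci):
        rows = ["".join(map(str, row)) for row in loc.genotypes.tolist()]
        lines.append("\t".join([
            loc.locus_id or f"locus_{i:05d}",
            str(loc.length_bp),
            ",".join(map(str, loc.pops.tolist())),
            ",".join(map(str, np.asarray(loc.positions).tolist())),
            ";".join(rows),
        ]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_snp_table(path) -> list[SimulatedLocus]:
    """Inverse of :func:`write_snp_table`."""
    with open(path) as fh:
        lines = fh.read().strip().splitlines()
    out = []
    for line in lines[1:]:
        locus_id, length, pops, positions, genotypes = line.split("\t")
        geno = np.array([[int(ch) for ch in row]
                         for row in genotypes.split(";")], dtype=np.int8)
        out.append(SimulatedLocus(
            genotypes=geno,
            pops=np.array([int(x) for x in pops.split(",")]),
            length_bp=int(length),
            positions=np.array([int(x) for x in positions.split(",")]),
            locus_id=locus_id,
        ))
    return out
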