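"""Generalist three-population divergence model: scenarios, priors, sampling.

The model describes three extant lineages (P1, P2, P3) produced by two nested
splits: an ancestral population (``anc123``) splits into the ancestor of P3 and
the common ancestor of P1/P2 (``anc12``), which later splits into P1 and P2.
Every split is accompanied by a size change independent of the ancestral size,
and each modern lineage additionally experiences one recent size change at an
independent time.  Gene flow may connect every pair of lineages; its temporal
pattern is what the eight scenario categories encode:

* ``inner_flow`` — migration between the sister pair P1/P2 is either
  *ancestral* (``AM``: flow confined to an early post-split epoch, none at
  present) or *secondary contact* (``SC``: flow resumed after an isolation
  epoch and ongoing at present).
* ``outer_flow`` — which of P1/P2 exchange migrants with P3: none (``SI``),
  P1 only (``P3P1``), P2 only (``P3P2``), or both (``P3BOTH``).

Each category is crossed with four sub-models that allow or forbid
locus-to-locus heterogeneity of effective size and of migration rate
(a reduced model of linked selection), giving 8 x 4 = 32 simulation models.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpeciesTrio",
    "ScenarioCategory",
    "HeterogeneitySubmodel",
    "PriorConfig",
    "ParameterDraw",
    "MigrationEpoch",
    "INNER_FLOWS",
    "OUTER_FLOWS",
    "enumerate_categories",
    "enumerate_submodels",
    "enumerate_models",
    "sample_parameters",
    "migration_schedule",
]

INNER_FLOWS = ("AM", "SC")
OUTER_FLOWS = ("SI", "P3P1", "P3P2", "P3BOTH")

#: pair identifiers used throughout (lexicographic population indices)
PAIRS = (("P1", "P2"), ("P1", "P3"), ("P2", "P3"))


class ConfigurationError(ValueError):
    """Raised for invalid prior bounds or inconsistent model configuration."""


@dataclass(frozen=True)
class SpeciesTrio:
    """Labels and haploid sample sizes for the three sampled lineages.

    ``n_seq_*`` count allele sequences (two per diploid individual).
    """

    label_p1: str = "helenor"
    label_p2: str = "achilles"
    label_p3: str = "deidamia"
    n_seq_p1: int = 20
    n_seq_p2: int = 26
    n_seq_p3: int = 16

    def __post_init__(self) -> None:
        labels = {self.label_p1, self.label_p2, self.label_p3}
        if len(labels) != 3:
            raise ConfigurationError("species labels must be distinct")
        # n >= 2 per species is required for within-species statistics but
        # single-lineage sampling is legitimate for pure genealogy checks
        for n in self.n_seq:
            if n < 1:
                raise ConfigurationError("sample sizes must be positive")

    @property
    def labels(self) -> tuple[str, str, str]:
        return (self.label_p1, self.label_p2, self.label_p3)

    @property
    def n_seq(self) -> tuple[int, int, int]:
        return (self.n_seq_p1, self.n_seq_p2, self.n_seq_p3)


@dataclass(frozen=True, order=True)
class ScenarioCategory:
    """One of the eight temporal gene-flow configurations."""

    inner_flow: str  # "AM" (ancestral migration) | "SC" (secondary contact)
    outer_flow: str  # "SI" | "P3P1" | "P3P2" | "P3BOTH"

    def __post_init__(self) -> None:
        if self.inner_flow not in INNER_FLOWS:
            raise ConfigurationError(f"unknown inner_flow {self.inner_flow!r}")
        if self.outer_flow not in OUTER_FLOWS:
            raise ConfigurationError(f"unknown outer_flow {self.outer_flow!r}")

    @property
    def code(self) -> str:
        """Stable serialization, e.g. ``"AM.SI"``."""
        return f"{self.inner_flow}.{self.outer_flow}"

    @classmethod
    def from_code(cls, code: str) -> "ScenarioCategory":
        inner, outer = code.split(".")
        return cls(inner, outer)

    @property
    def p3_pairs(self) -> tuple[str, ...]:
        """Which outer pairs ("13", "23") carry migration."""
        return {
            "SI": (),
            "P3P1": ("13",),
            "P3P2": ("23",),
            "P3BOTH": ("13", "23"),
        }[self.outer_flow]


@dataclass(frozen=True, order=True)
class HeterogeneitySubmodel:
    """Whether per-locus effective size / migration rescaling is allowed."""

    ne_hetero: bool
    nm_hetero: bool

    @property
    def code(self) -> str:
        ne = "hetNe" if self.ne_hetero else "homNe"
        nm = "hetM" if self.nm_hetero else "homM"
        return f"{ne}-{nm}"

    @classmethod
    def from_code(cls, code: str) -> "HeterogeneitySubmodel":
        ne, nm = code.split("-")
        return cls(ne == "hetNe", nm == "hetM")


@dataclass(frozen=True)
class PriorConfig:
    """Prior distributions of the generalist model.

    Defaults follow the study design: population sizes uniform on
    [0, 1e6] diploid individuals, the older split uniform on [0, 8e6]
    generations, scaled migration rates 4Nm uniform on [0, 50], and the
    P1-P2 migration transition time drawn as a Beta-distributed fraction
    of the P1/P2 split time — Beta(5, 1) under ancestral migration (pushing
    the end of gene flow towards the split) and Beta(1, 5) under secondary
    contact (pushing the restart of gene flow towards the present).
    """

    ne_range: tuple[float, float] = (0.0, 1_000_000.0)
    tsplit_outer_range: tuple[float, float] = (0.0, 8_000_000.0)
    mig_range: tuple[float, float] = (0.0, 50.0)
    beta_ancestral: tuple[float, float] = (5.0, 1.0)
    beta_secondary: tuple[float, float] = (1.0, 5.0)
    #: uniform bounds for the Beta shape hyperparameters of per-locus factors
    hetero_shape_range: tuple[float, float] = (0.0, 20.0)
    #: mutation rate per bp per generation
    mu: float = 3e-9
    #: coalescent degeneracy guard: size draws below this are rejected
    min_size: float = 10.0
    #: at least one shape of a hyperparameter pair must reach this value
    min_shape: float = 0.1

    def __post_init__(self) -> None:
        for name in ("ne_range", "tsplit_outer_range", "mig_range",
                     "hetero_shape_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ConfigurationError(
                    f"invalid prior bounds for {name}: ({lo}, {hi})"
                )
        if self.mu <= 0:
            raise ConfigurationError("mutation rate must be positive")


@dataclass(frozen=True)
class ParameterDraw:
    """One full parameterization of the generalist model.

    Sizes are diploid individuals, times are generations before present and
    migration rates are in 4Nm units.  ``T_trans12`` is the boundary of the
    P1-P2 migration epoch: under ancestral migration flow is active on
    [T_trans12, T_split12]; under secondary contact on [0, T_trans12].
    """

    category: ScenarioCategory
    submodel: HeterogeneitySubmodel
    # current sizes
    N_P1: float
    N_P2: float
    N_P3: float
    # founding sizes and recent size-change times of the modern lineages
    N_found_P1: float
    N_found_P2: float
    N_found_P3: float
    T_change_P1: float
    T_change_P2: float
    T_change_P3: float
    # ancestral sizes
    N_anc12: float
    N_anc123: float
    # split and transition times
    T_split12: float
    T_split123: float
    T_trans12: float
    # scaled migration rates (4Nm)
    M12: float
    M13: float
    M23: float
    # hyperparameters of per-locus factor distributions (Beta shapes)
    ne_shape_a: float = 1.0
    ne_shape_b: float = 1.0
    mig_shape_a: float = 1.0
    mig_shape_b: float = 1.0

    def validate(self) -> None:
        if not (0 <= self.T_trans12 <= self.T_split12 <= self.T_split123):
            raise ConfigurationError(
                "times must satisfy 0 <= T_trans12 <= T_split12 <= T_split123"
            )
        for name in ("N_P1", "N_P2", "N_P3", "N_found_P1", "N_found_P2",
                     "N_found_P3", "N_anc12", "N_anc123"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.T_change_P1 > self.T_split12 or self.T_change_P2 > self.T_split12:
            raise ConfigurationError(
                "P1/P2 size changes cannot predate the P1-P2 split"
            )
        if self.T_change_P3 > self.T_split123:
            raise ConfigurationError(
                "P3 size change cannot predate the outer split"
            )
        if "13" not in self.category.p3_pairs and self.M13 != 0:
            raise ConfigurationError("M13 must be 0 under this category")
        if "23" not in self.category.p3_pairs and self.M23 != 0:
            raise ConfigurationError("M23 must be 0 under this category")

    def asdict(self) -> dict:
        d = dataclasses.asdict(self)
        d["category"] = self.category.code
        d["submodel"] = self.submodel.code
        return d


@dataclass(frozen=True)
class MigrationEpoch:
    """Migration between one pair over one interval (generations, 4Nm)."""

    pair: tuple[str, str]
    rate: float  # 4Nm units
    start: float  # younger bound, generations before present
    end: float  # older bound


def enumerate_categories() -> list[ScenarioCategory]:
    """The eight scenario categories, in stable (inner, outer) order."""
    return [
        ScenarioCategory(i, o)
        for i, o in itertools.product(INNER_FLOWS, OUTER_FLOWS)
    ]


def enumerate_submodels() -> list[HeterogeneitySubmodel]:
    """The four heterogeneity sub-models, homogeneous first."""
    return [
        HeterogeneitySubmodel(ne, nm)
        for ne, nm in itertools.product((False, True), repeat=2)
    ]


def enumerate_models() -> list[tuple[ScenarioCategory, HeterogeneitySubmodel]]:
    """All 32 (category, sub-model) pairs, in stable order."""
    return [
        (cat, sub)
        for cat in enumerate_categories()
        for sub in enumerate_submodels()
    ]


def _uniform_size(rng: np.random.Generator, priors: PriorConfig) -> float:
    """Uniform size draw with rejection of degenerate (tiny) populations."""
    lo, hi = priors.ne_range
    if hi <= priors.min_size:
        raise ConfigurationError(
            "size prior upper bound must exceed the degeneracy guard"
        )
    while True:
        n = rng.uniform(lo, hi)
        if n >= priors.min_size:
            return float(n)


def _shape_pair(rng: np.random.Generator, priors: PriorConfig) -> tuple[float, float]:
    lo, hi = priors.hetero_shape_range
    while True:
        a, b = rng.uniform(lo, hi, size=2)
        # Beta shapes must be strictly positive and not both vanishing
        if max(a, b) >= priors.min_shape and min(a, b) > 0:
            return float(a), float(b)


def sample_parameters(
    category: ScenarioCategory,
    submodel: HeterogeneitySubmodel,
    priors: PriorConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> ParameterDraw:
    """Draw one full parameterization from the priors.

    Times are nested: T_split123 ~ U(tsplit range), T_split12 ~ U(0, T_split123),
    and T_trans12 = T_split12 * B with B Beta-distributed according to the
    inner-flow mode.  Migration rates blocked by the category are exactly 0.
    """
    priors = priors or PriorConfig()
    rng = np.random.default_rng(rng)

    t123 = float(rng.uniform(*priors.tsplit_outer_range))
    t12 = float(rng.uniform(0.0, t123))
    if category.inner_flow == "AM":
        beta = priors.beta_ancestral
    else:
        beta = priors.beta_secondary
    ttrans = t12 * float(rng.beta(*beta)) if t12 > 0 else 0.0

    sizes = {k: _uniform_size(rng, priors) for k in
             ("N_P1", "N_P2", "N_P3", "N_found_P1", "N_found_P2",
              "N_found_P3", "N_anc12", "N_anc123")}

    m12 = float(rng.uniform(*priors.mig_range))
    m13 = float(rng.uniform(*priors.mig_range)) if "13" in category.p3_pairs else 0.0
    m23 = float(rng.uniform(*priors.mig_range)) if "23" in category.p3_pairs else 0.0

    ne_a, ne_b = _shape_pair(rng, priors)
    mg_a, mg_b = _shape_pair(rng, priors)

    draw = ParameterDraw(
        category=category,
        submodel=submodel,
        T_change_P1=float(rng.uniform(0.0, t12)),
        T_change_P2=float(rng.uniform(0.0, t12)),
        T_change_P3=float(rng.uniform(0.0, t123)),
        T_split12=t12,
        T_split123=t123,
        T_trans12=ttrans,
        M12=m12,
        M13=m13,
        M23=m23,
        ne_shape_a=ne_a,
        ne_shape_b=ne_b,
        mig_shape_a=mg_a,
        mig_shape_b=mg_b,
        **sizes,
    )
    draw.validate()
    return draw


def migration_schedule(
    category: ScenarioCategory, draw: ParameterDraw
) -> list[MigrationEpoch]:
    """Active migration epochs implied by a category and a draw.

    Intervals are half-open in the backward-time sense: the boundary time
    belongs to the older epoch.  The P1-P2 pair is active on
    [T_trans12, T_split12] under ancestral migration and on [0, T_trans12]
    under secondary contact; enabled P3 pairs are active on [0, T_split123]
    (carried by the P1/P2 ancestor after the inner merge).
    """
    if draw.category != category:
        raise ConfigurationError(
            f"draw was sampled under {draw.category.code}, not {category.code}"
        )
    draw.validate()
    epochs = []
    if category.inner_flow == "AM":
        epochs.append(MigrationEpoch(("P1", "P2"), draw.M12,
                                     draw.T_trans12, draw.T_split12))
    else:
        epochs.append(MigrationEpoch(("P1", "P2"), draw.M12,
                                     0.0, draw.T_trans12))
    if "13" in category.p3_pairs:
        epochs.append(MigrationEpoch(("P1", "P3"), draw.M13,
                                     0.0, draw.T_split123))
    if "23" in category.p3_pairs:
        epochs.append(MigrationEpoch(("P2", "P3"), draw.M23,
                                     0.0, draw.T_split123))
    return epochs
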