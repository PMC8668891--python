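"""Pseudo-observed datasets (PODs) with known ground truth.

The generator emulates the shape of the empirical RAD dataset: three
species sampled as 10/13/8 diploid males (20/26/16 allele sequences),
2,740 polymorphic biallelic loci of 343-908 bp.  PODs are produced in
theta mode — SNP counts arise from the coalescent history rather than
being imposed — and conditioned on polymorphism the same way the observed
data are: monomorphic simulated loci are discarded and simulation rounds
continue until the target locus count is reached.  A plain-text sidecar
records everything needed to regenerate a dataset byte-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .abc_inference import (
    HierarchicalClassifier,
    ParameterRegressor,
    ReferenceTable,
    RunError,
    build_reference_table,
)
from .coalsim import LocusSpec, SimulatedLocus, simulate_dataset
from .model_space import (
    ConfigurationError,
    HeterogeneitySubmodel,
    ParameterDraw,
    PriorConfig,
    ScenarioCategory,
    SpeciesTrio,
    sample_parameters,
)
from .radseq_io import (
    LocusDataset,
    dataset_from_simulated,
    write_loci_fasta,
    write_locus_table,
    write_vcf,
)
from .sumstats import SummaryVector, dataset_summary, locus_stats

__all__ = [
    "LocusSpecPreset",
    "GroundTruthRecord",
    "EMPIRICAL_SHAPE",
    "FIXED_SNP_SHAPE",
    "make_locus_specs",
    "generate_pseudo_observed",
    "regenerate",
    "pod_summary",
    "recovery_experiment",
    "RecoveryResult",
]


@dataclass(frozen=True)
class LocusSpecPreset:
    """Locus-count, length-range and sample-size preset for a POD."""

    n_loci: int = 2740
    length_range: tuple[int, int] = (343, 908)
    trio: SpeciesTrio = field(default_factory=SpeciesTrio)
    #: optional empirical SNP-count profile to resample (fixed-SNP mode);
    #: counts are clipped into [1, 91]
    snp_profile: tuple[int, ...] | None = None
    #: "uniform" over the length range, or "truncgeom" (truncated
    #: geometric) tilted to match ``target_mean_length``
    length_distribution: str = "uniform"
    target_mean_length: float = 463.12

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise ConfigurationError("invalid locus length bounds")
        if self.n_loci < 1:
            raise ConfigurationError("n_loci must be >= 1")
        if self.length_distribution not in ("uniform", "truncgeom"):
            raise ConfigurationError(
                f"unknown length distribution {self.length_distribution!r}"
            )


#: the empirical dataset shape (theta-conditioned locus lengths)
EMPIRICAL_SHAPE = LocusSpecPreset()
#: the length range quoted for the fixed-SNP conditioning
FIXED_SNP_SHAPE = LocusSpecPreset(length_range=(339, 894))


def _truncgeom_lengths(preset: LocusSpecPreset, n: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Truncated-geometric lengths matched to the target mean.

    P(l) is proportional to q**(l - lo) on [lo, hi]; q is solved so the
    distribution mean equals ``target_mean_length``.
    """
    lo, hi = preset.length_range
    support = np.arange(lo, hi + 1)
    target = preset.target_mean_length
    if not lo < target < (lo + hi) / 2:
        raise ConfigurationError(
            "truncated-geometric lengths require a target mean between the "
            "lower bound and the midpoint of the range"
        )

    def mean_minus_target(log_q: float) -> float:
        w = np.exp(log_q * (support - lo))
        return float((support * w).sum() / w.sum()) - target

    log_q = brentq(mean_minus_target, -1.0, -1e-9)
    w = np.exp(log_q * (support - lo))
    return rng.choice(support, size=n, p=w / w.sum())


def make_locus_specs(
    preset: LocusSpecPreset,
    rng: np.random.Generator | int | None = None,
    n_loci: int | None = None,
) -> list[LocusSpec]:
    """Draw locus specs (lengths, optional SNP counts) from a preset."""
    rng = np.random.default_rng(rng)
    n = n_loci if n_loci is not None else preset.n_loci
    lo, hi = preset.length_range
    if preset.length_distribution == "uniform":
        lengths = rng.integers(lo, hi + 1, size=n)
    else:
        lengths = _truncgeom_lengths(preset, n, rng)
    if preset.snp_profile is not None:
        profile = np.clip(np.asarray(preset.snp_profile, dtype=int), 1, 91)
        snps = rng.choice(profile, size=n)
    else:
        snps = np.zeros(n, dtype=int)
    return [
        LocusSpec(length_bp=int(l), observed_snp_count=int(s),
                  locus_id=f"locus_{i:05d}")
        for i, (l, s) in enumerate(zip(lengths, snps))
    ]


@dataclass
class GroundTruthRecord:
    """Everything needed to regenerate a POD byte-identically."""

    category: str
    submodel: str
    seed: int
    mode: str
    preset: LocusSpecPreset
    draw: ParameterDraw
    mu: float = 3e-9

    def save(self, path) -> None:
        lines = [
            f"category = {self.category}",
            f"submodel = {self.submodel}",
            f"seed = {self.seed}",
            f"mode = {self.mode}",
            f"mu = {self.mu!r}",
            f"n_loci = {self.preset.n_loci}",
            f"length_range = {self.preset.length_range[0]},{self.preset.length_range[1]}",
            f"length_distribution = {self.preset.length_distribution}",
            f"n_seq = {','.join(map(str, self.preset.trio.n_seq))}",
            f"labels = {','.join(self.preset.trio.labels)}",
        ]
        for name, value in self.draw.asdict().items():
            if name in ("category", "submodel"):
                continue
            lines.append(f"param.{name} = {value!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "GroundTruthRecord":
        fields: dict[str, str] = {}
        params: dict[str, float] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            key, _, value = line.partition(" = ")
            if key.startswith("param."):
                params[key[6:]] = float(value)
            else:
                fields[key] = value
        labels = fields["labels"].split(",")
        n_seq = [int(x) for x in fields["n_seq"].split(",")]
        trio = SpeciesTrio(*labels, *n_seq)
        lo, hi = (int(x) for x in fields["length_range"].split(","))
        preset = LocusSpecPreset(
            n_loci=int(fields["n_loci"]), length_range=(lo, hi), trio=trio,
            length_distribution=fields["length_distribution"],
        )
        category = ScenarioCategory.from_code(fields["category"])
        submodel = HeterogeneitySubmodel.from_code(fields["submodel"])
        draw = ParameterDraw(category=category, submodel=submodel, **params)
        return cls(
            category=fields["category"], submodel=fields["submodel"],
            seed=int(fields["seed"]), mode=fields["mode"], preset=preset,
            draw=draw, mu=float(fields["mu"]),
        )


def _simulate_pod_loci(
    draw: ParameterDraw,
    preset: LocusSpecPreset,
    mode: str,
    seed: int,
    mu: float,
    max_rounds: int = 40,
) -> list[SimulatedLocus]:
    """Simulate until ``preset.n_loci`` polymorphic loci are collected.

    In theta mode each round simulates a fresh batch of specs and keeps
    the polymorphic outcomes (the monomorphic-locus conditioning); in
    fixed-SNP mode one round suffices by construction.
    """
    rng = np.random.default_rng(seed)
    collected: list[SimulatedLocus] = []
    if mode == "fixed_snp":
        specs = make_locus_specs(preset, rng)
        for s in specs:
            if s.observed_snp_count < 1:
                raise ConfigurationError(
                    "fixed-SNP PODs need a SNP profile in the preset"
                )
        return simulate_dataset(draw, specs, mode=mode, trio=preset.trio,
                                rng=rng, mu=mu)
    for _ in range(max_rounds):
        need = preset.n_loci - len(collected)
        if need <= 0:
            break
        batch = make_locus_specs(preset, rng, n_loci=need)
        collected.extend(
            simulate_dataset(draw, batch, mode="theta", trio=preset.trio,
                             rng=rng, mu=mu)
        )
    if len(collected) < preset.n_loci:
        raise RunError(
            f"could not collect {preset.n_loci} polymorphic loci in "
            f"{max_rounds} rounds (got {len(collected)}); the draw is too "
            "close to monomorphism"
        )
    loci = collected[: preset.n_loci]
    for i, loc in enumerate(loci):
        loc.locus_id = f"locus_{i:05d}"
    return loci


def generate_pseudo_observed(
    out_dir,
    category: ScenarioCategory,
    submodel: HeterogeneitySubmodel,
    preset: LocusSpecPreset = EMPIRICAL_SHAPE,
    priors: PriorConfig | None = None,
    draw: ParameterDraw | None = None,
    mode: str = "theta",
    seed: int = 0,
) -> tuple[LocusDataset, GroundTruthRecord]:
    """Write a POD (FASTA + VCF + locus table + ground-truth sidecar).

    The parameter draw is taken from the priors under ``seed`` unless an
    explicit ``draw`` is given.  The written dataset is already clean:
    it passes :func:`triabc.radseq_io.filter_loci` unchanged.
    """
    priors = priors or PriorConfig()
    if draw is None:
        draw = sample_parameters(category, submodel, priors,
                                 np.random.default_rng(seed))
    record = GroundTruthRecord(
        category=category.code, submodel=submodel.code, seed=seed,
        mode=mode, preset=preset, draw=draw, mu=priors.mu,
    )
    loci = _simulate_pod_loci(draw, preset, mode, seed, priors.mu)
    dataset = dataset_from_simulated(loci, preset.trio)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_loci_fasta(dataset, out / "pod_loci.fasta")
    write_vcf(dataset, out / "pod_snps.vcf")
    write_locus_table(dataset, out / "pod_locus_table.tsv")
    record.save(out / "pod_ground_truth.txt")
    return dataset, record


def regenerate(record: GroundTruthRecord) -> LocusDataset:
    """Rebuild the dataset a sidecar describes, byte-identically."""
    loci = _simulate_pod_loci(record.draw, record.preset, record.mode,
                              record.seed, record.mu)
    return dataset_from_simulated(loci, record.preset.trio)


def pod_summary(loci: list[SimulatedLocus]) -> SummaryVector:
    """Summary vector of a POD (convenience wrapper)."""
    return dataset_summary([locus_stats(loc) for loc in loci])


@dataclass
class RecoveryResult:
    """Outcome of a model-choice / parameter recovery experiment."""

    categories: list[str]
    confusion: np.ndarray  # rows true category, cols predicted
    mean_posterior_true_inner: float
    mean_posterior_true_outer: float
    inner_accuracy: float
    outer_accuracy: float
    parameter_rank_corr: dict[str, float]


def recovery_experiment(
    design: list[ScenarioCategory],
    n_pods: int,
    table: ReferenceTable,
    preset: LocusSpecPreset,
    priors: PriorConfig | None = None,
    n_trees: int = 500,
    rng: np.random.Generator | int | None = None,
    recovery_parameters: tuple[str, ...] = ("T_split123", "T_split12", "N_P1"),
) -> RecoveryResult:
    """Push PODs with known truth through the full inference.

    For each category in ``design``, ``n_pods`` PODs are drawn from the
    priors (sub-models cycled), classified hierarchically against
    ``table``, and their parameters predicted by regression forests
    trained on the full table; Spearman rank correlations between true
    and estimated values are reported for ``recovery_parameters``.
    """
    from scipy.stats import spearmanr

    if not design or n_pods < 1:
        raise ValueError("recovery design must be non-empty")
    priors = priors or PriorConfig()
    rng = np.random.default_rng(rng)
    clf = HierarchicalClassifier(n_trees=n_trees).fit(table, rng=rng)
    reg = ParameterRegressor(parameters=recovery_parameters,
                             n_trees=n_trees).fit(table, rng=rng)
    codes = [c.code for c in design]
    confusion = np.zeros((len(design), len(design)), dtype=int)
    post_inner, post_outer = [], []
    correct_inner = correct_outer = 0
    truths = {p: [] for p in recovery_parameters}
    estimates = {p: [] for p in recovery_parameters}
    submodels = [HeterogeneitySubmodel(ne, nm)
                 for ne in (False, True) for nm in (False, True)]
    n_total = 0
    for i, cat in enumerate(design):
        made = 0
        while made < n_pods:
            sub = submodels[made % 4]
            draw = sample_parameters(cat, sub, priors, rng)
            seed = int(rng.integers(0, 2**31 - 1))
            try:
                loci = _simulate_pod_loci(draw, preset, "theta", seed,
                                          priors.mu, max_rounds=10)
            except RunError:
                continue  # near-monomorphic draw; redraw
            vec = pod_summary(loci)
            res = clf.predict(vec)
            pred_code = res.winning_category.code
            if pred_code in codes:
                confusion[i, codes.index(pred_code)] += 1
            post_inner.append(res.inner.vote_fractions.get(cat.inner_flow, 0.0))
            post_outer.append(res.outer.vote_fractions.get(cat.outer_flow, 0.0))
            correct_inner += res.inner.winner == cat.inner_flow
            correct_outer += res.outer.winner == cat.outer_flow
            est = reg.predict(vec)
            for p in recovery_parameters:
                truths[p].append(getattr(draw, p))
                estimates[p].append(est.point(p))
            made += 1
            n_total += 1
    rank_corr = {
        p: float(spearmanr(truths[p], estimates[p]).statistic)
        for p in recovery_parameters
    }
    return RecoveryResult(
        categories=codes,
        confusion=confusion,
        mean_posterior_true_inner=float(np.mean(post_inner)),
        mean_posterior_true_outer=float(np.mean(post_outer)),
        inner_accuracy=correct_inner / n_total,
        outer_accuracy=correct_outer / n_total,
        parameter_rank_corr=rank_corr,
    )
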