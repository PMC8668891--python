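"""Random-forest ABC: reference tables, model choice, parameter estimation.

Model choice follows the ABC-RF approach: a random-forest classifier is
trained on simulated summary-statistic vectors labelled by model; the
winning model for an observed vector is the majority vote across trees,
and its posterior probability is estimated by a secondary regression
forest fitted to the out-of-bag correctness of the classifier.  Parameter
estimation uses one regression forest per parameter, with credible
intervals taken from the spread of per-tree predictions.

The hierarchy poses the two gene-flow questions independently on pooled
labels: (1) ancestral migration vs secondary contact between P1 and P2
(pooling over outer flow and heterogeneity sub-models), and (2) which of
P1/P2 exchange migrants with P3 (four-way, pooling over inner flow and
sub-models).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .coalsim import LocusSpec, simulate_dataset
from .model_space import (
    ConfigurationError,
    HeterogeneitySubmodel,
    ParameterDraw,
    PriorConfig,
    ScenarioCategory,
    SpeciesTrio,
    enumerate_categories,
    sample_parameters,
)
from .sumstats import SUMMARY_NAMES, SummaryVector, dataset_summary, locus_stats

__all__ = [
    "ReferenceTable",
    "ModelPosterior",
    "ParameterEstimate",
    "RunError",
    "PARAM_COLUMNS",
    "build_reference_table",
    "classify",
    "ModelChoiceForest",
    "HierarchicalClassifier",
    "hierarchical_inference",
    "HierarchicalResult",
    "INNER_GROUPING",
    "OUTER_GROUPING",
    "ParameterRegressor",
    "estimate_parameters",
    "draw_from_estimates",
    "posterior_predictive_check",
]

_MAX_SEED = 2**31 - 1

#: ParameterDraw fields stored per reference-table row
PARAM_COLUMNS = (
    "N_P1", "N_P2", "N_P3", "N_found_P1", "N_found_P2", "N_found_P3",
    "T_change_P1", "T_change_P2", "T_change_P3", "N_anc12", "N_anc123",
    "T_split12", "T_split123", "T_trans12", "M12", "M13", "M23",
    "ne_shape_a", "ne_shape_b", "mig_shape_a", "mig_shape_b",
)


class RunError(RuntimeError):
    """Raised when too many simulations fail while building a table."""


@dataclass
class ReferenceTable:
    """Simulated summary vectors with model labels and parameter values."""

    df: pd.DataFrame
    mode: str = "theta"
    seed: int | None = None

    def __post_init__(self) -> None:
        missing = [c for c in ("category", "submodel", *SUMMARY_NAMES)
                   if c not in self.df.columns]
        if missing:
            raise ValueError(f"reference table lacks columns: {missing[:4]}...")
        if self.df[list(SUMMARY_NAMES)].isna().any().any():
            raise ValueError("reference table contains missing statistics")

    @property
    def stats(self) -> np.ndarray:
        return self.df[list(SUMMARY_NAMES)].to_numpy(dtype=float)

    @property
    def categories(self) -> np.ndarray:
        return self.df["category"].to_numpy()

    def restrict(self, category: str) -> "ReferenceTable":
        sub = self.df[self.df["category"] == category].reset_index(drop=True)
        return ReferenceTable(sub, mode=self.mode, seed=self.seed)

    def save(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path, mode: str = "theta") -> "ReferenceTable":
        return cls(pd.read_csv(path, sep="\t"), mode=mode)


@dataclass
class ModelPosterior:
    """Outcome of one random-forest model comparison."""

    winner: str
    posterior: float
    vote_fractions: dict[str, float]
    oob_error: float
    n_trees: int

    def __post_init__(self) -> None:
        total = sum(self.vote_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("vote fractions must sum to 1")
        if not 0.0 <= self.posterior <= 1.0:
            raise ValueError("posterior must lie in [0, 1]")


@dataclass
class ParameterEstimate:
    """Per-parameter point estimates with central credible intervals."""

    estimates: dict[str, tuple[float, float, float]]  # name -> (point, lo, hi)
    normalized: bool = False

    def point(self, name: str) -> float:
        return self.estimates[name][0]

    def interval(self, name: str) -> tuple[float, float]:
        _, lo, hi = self.estimates[name]
        return lo, hi


def build_reference_table(
    models: list[tuple[ScenarioCategory, HeterogeneitySubmodel]],
    n_per_model: int,
    locus_specs: list[LocusSpec],
    mode: str = "theta",
    priors: PriorConfig | None = None,
    trio: SpeciesTrio | None = None,
    rng: np.random.Generator | int | None = None,
    failure_tolerance: float = 0.01,
    progress: bool = False,
) -> ReferenceTable:
    """Simulate ``n_per_model`` labelled summary vectors per (category, sub-model).

    A simulation "fails" when no polymorphic locus survives (possible in
    theta mode under extreme draws); failed draws are logged and replaced
    by fresh draws so every model keeps its row count.  If failures exceed
    ``failure_tolerance`` of the attempted simulations a :class:`RunError`
    is raised listing the failed draws.
    """
    if n_per_model < 1:
        raise ValueError("n_per_model must be >= 1")
    priors = priors or PriorConfig()
    trio = trio or SpeciesTrio()
    rng = np.random.default_rng(rng)
    rows: list[dict] = []
    failures: list[dict] = []
    attempts = 0
    for cat, sub in models:
        produced = 0
        while produced < n_per_model:
            attempts += 1
            draw = sample_parameters(cat, sub, priors, rng)
            loci = simulate_dataset(draw, locus_specs, mode=mode, trio=trio,
                                    rng=rng, mu=priors.mu)
            if not loci:
                failures.append(draw.asdict())
                if len(failures) > max(1.0, failure_tolerance * attempts) and \
                        len(failures) / attempts > failure_tolerance:
                    raise RunError(
                        f"{len(failures)}/{attempts} simulations produced no "
                        f"polymorphic locus; failed draws: {failures[:5]}..."
                    )
                continue
            vec = dataset_summary([locus_stats(loc) for loc in loci])
            row = {"category": cat.code, "submodel": sub.code,
                   "n_loci": len(loci)}
            d = draw.asdict()
            row.update({k: d[k] for k in PARAM_COLUMNS})
            row.update(vec.as_dict())
            rows.append(row)
            produced += 1
        if progress:  # pragma: no cover - cosmetic
            print(f"  {cat.code} {sub.code}: {n_per_model} rows")
    return ReferenceTable(pd.DataFrame(rows), mode=mode)


class ModelChoiceForest:
    """ABC-RF model choice: classifier plus posterior-probability forest.

    ``grouping`` maps category codes to comparison labels (e.g. pooling the
    four outer-flow variants of each inner-flow mode); rows map through it
    before training.  The posterior probability of the winning label is the
    prediction of a regression forest fitted to the out-of-bag correctness
    of the classifier (``"oob-regression"``); ``"votes"`` reports the
    winning vote fraction instead (default for tables under 100 rows).
    """

    def __init__(self, n_trees: int = 500, posterior_method: str = "auto"):
        self.n_trees = n_trees
        self.posterior_method = posterior_method
        self._clf: RandomForestClassifier | None = None
        self._reg: RandomForestRegressor | None = None
        self.oob_error_: float | None = None
        self.oob_predictions_: np.ndarray | None = None
        self.labels_: np.ndarray | None = None

    def fit(
        self,
        table: ReferenceTable,
        grouping: dict[str, str] | None = None,
        rng: np.random.Generator | int | None = None,
    ) -> "ModelChoiceForest":
        labels = table.categories.astype(str)
        if grouping is not None:
            labels = np.array([grouping[c] for c in labels])
        if len(np.unique(labels)) < 2:
            raise ValueError("classification requires at least two groups")
        rng = np.random.default_rng(rng)
        seed = int(rng.integers(0, _MAX_SEED))
        X = table.stats
        clf = RandomForestClassifier(
            n_estimators=self.n_trees, random_state=seed, oob_score=True,
            n_jobs=1,
        )
        clf.fit(X, labels)
        oob_votes = clf.oob_decision_function_
        covered = oob_votes.sum(axis=1) > 0
        oob_pred = clf.classes_[np.argmax(oob_votes, axis=1)]
        correct = (oob_pred == labels).astype(float)
        self._clf = clf
        self.labels_ = labels
        self.oob_predictions_ = oob_pred
        self.oob_error_ = float(1.0 - correct[covered].mean())
        method = self.posterior_method
        if method == "auto":
            method = "oob-regression" if len(labels) >= 100 else "votes"
        self._method = method
        if method == "oob-regression":
            # min leaf of 5: regression-forest smoothing of the 0/1 response
            reg = RandomForestRegressor(
                n_estimators=self.n_trees, random_state=seed + 1, n_jobs=1,
                min_samples_leaf=5,
            )
            reg.fit(X[covered], correct[covered])
            self._reg = reg
        elif method != "votes":
            raise ValueError(f"unknown posterior method {method!r}")
        return self

    def _vote_fractions(self, x: np.ndarray) -> dict[str, float]:
        clf = self._clf
        votes = np.array([est.predict(x)[0] for est in clf.estimators_])
        # sub-trees predict encoded class indices; map back defensively
        fractions = {str(lab): float(np.mean(votes == k))
                     for k, lab in enumerate(clf.classes_)}
        if abs(sum(fractions.values()) - 1.0) > 1e-9:
            fractions = {str(lab): float(np.mean(votes == lab))
                         for lab in clf.classes_}
        return fractions

    def predict(self, observed: SummaryVector) -> ModelPosterior:
        if self._clf is None:
            raise RuntimeError("fit the forest before predicting")
        x_obs = observed.values.reshape(1, -1)
        fractions = self._vote_fractions(x_obs)
        winner = max(fractions, key=fractions.get)
        if self._method == "oob-regression":
            posterior = float(np.clip(self._reg.predict(x_obs)[0], 0.0, 1.0))
        else:
            posterior = fractions[winner]
        return ModelPosterior(
            winner=winner, posterior=posterior, vote_fractions=fractions,
            oob_error=self.oob_error_, n_trees=self.n_trees,
        )


def classify(
    table: ReferenceTable,
    observed: SummaryVector,
    grouping: dict[str, str] | None = None,
    n_trees: int = 500,
    rng: np.random.Generator | int | None = None,
    posterior_method: str = "auto",
) -> ModelPosterior:
    """One-shot random-forest model choice (see :class:`ModelChoiceForest`)."""
    forest = ModelChoiceForest(n_trees=n_trees, posterior_method=posterior_method)
    forest.fit(table, grouping=grouping, rng=rng)
    return forest.predict(observed)


INNER_GROUPING = {c.code: c.inner_flow for c in enumerate_categories()}
OUTER_GROUPING = {c.code: c.outer_flow for c in enumerate_categories()}


@dataclass
class HierarchicalResult:
    """Both gene-flow decisions plus the combined winning category."""

    inner: ModelPosterior  # AM vs SC between P1 and P2
    outer: ModelPosterior  # which pairs involving P3 migrate
    winning_category: ScenarioCategory


class HierarchicalClassifier:
    """Both gene-flow questions on one reference table, fit once."""

    def __init__(self, n_trees: int = 500, posterior_method: str = "auto"):
        self.inner_forest = ModelChoiceForest(n_trees, posterior_method)
        self.outer_forest = ModelChoiceForest(n_trees, posterior_method)

    def fit(self, table: ReferenceTable,
            rng: np.random.Generator | int | None = None
            ) -> "HierarchicalClassifier":
        present = set(table.categories.astype(str))
        expected = {c.code for c in enumerate_categories()}
        if present != expected:
            raise ValueError(
                "table must cover all 8 categories; missing "
                f"{sorted(expected - present)}"
            )
        rng = np.random.default_rng(rng)
        self.inner_forest.fit(table, grouping=INNER_GROUPING, rng=rng)
        self.outer_forest.fit(table, grouping=OUTER_GROUPING, rng=rng)
        return self

    def predict(self, observed: SummaryVector) -> HierarchicalResult:
        inner = self.inner_forest.predict(observed)
        outer = self.outer_forest.predict(observed)
        return HierarchicalResult(
            inner=inner, outer=outer,
            winning_category=ScenarioCategory(inner.winner, outer.winner),
        )


def hierarchical_inference(
    table: ReferenceTable,
    observed: SummaryVector,
    n_trees: int = 500,
    rng: np.random.Generator | int | None = None,
) -> HierarchicalResult:
    """Answer the two gene-flow questions independently on pooled labels."""
    clf = HierarchicalClassifier(n_trees=n_trees)
    clf.fit(table, rng=rng)
    return clf.predict(observed)


_SIZE_PARAMS = tuple(p for p in PARAM_COLUMNS if p.startswith("N_"))
_TIME_PARAMS = tuple(p for p in PARAM_COLUMNS if p.startswith("T_"))


class ParameterRegressor:
    """One regression forest per parameter, fit once on a table."""

    def __init__(self, parameters: tuple[str, ...] = PARAM_COLUMNS[:17],
                 n_trees: int = 500,
                 interval: tuple[float, float] = (0.05, 0.95)):
        self.parameters = tuple(parameters)
        self.n_trees = n_trees
        self.interval = interval
        self._forests: dict[str, RandomForestRegressor | float] = {}

    def fit(self, table: ReferenceTable,
            rng: np.random.Generator | int | None = None
            ) -> "ParameterRegressor":
        if len(table.df) == 0:
            raise ValueError("parameter estimation requires a non-empty table")
        rng = np.random.default_rng(rng)
        X = table.stats
        for name in self.parameters:
            y = table.df[name].to_numpy(dtype=float)
            if np.ptp(y) == 0:
                # constant parameter: the forest would be degenerate anyway
                self._forests[name] = float(y[0])
                continue
            seed = int(rng.integers(0, _MAX_SEED))
            reg = RandomForestRegressor(n_estimators=self.n_trees,
                                        random_state=seed, n_jobs=1)
            reg.fit(X, y)
            self._forests[name] = reg
        return self

    def predict(self, observed: SummaryVector,
                normalize: bool = False) -> ParameterEstimate:
        if not self._forests:
            raise RuntimeError("fit the regressor before predicting")
        x_obs = observed.values.reshape(1, -1)
        raw: dict[str, tuple[float, float, float]] = {}
        for name in self.parameters:
            model = self._forests[name]
            if isinstance(model, float):
                raw[name] = (model, model, model)
                continue
            point = float(model.predict(x_obs)[0])
            per_tree = np.array([t.predict(x_obs)[0]
                                 for t in model.estimators_])
            lo, hi = np.quantile(per_tree, self.interval)
            raw[name] = (point, min(float(lo), point), max(float(hi), point))
        if not normalize:
            return ParameterEstimate(estimates=raw, normalized=False)
        n_ref = raw["N_P1"][0]
        if n_ref <= 0:
            raise ValueError("cannot normalize: N_P1 estimate is non-positive")
        scaled = {}
        for name, (point, lo, hi) in raw.items():
            if name in _SIZE_PARAMS:
                s = 1.0 / n_ref
            elif name in _TIME_PARAMS:
                s = 1.0 / (4.0 * n_ref)
            else:
                s = 1.0
            scaled[name] = (point * s, lo * s, hi * s)
        scaled["N_P1"] = (1.0, raw["N_P1"][1] / n_ref, raw["N_P1"][2] / n_ref)
        return ParameterEstimate(estimates=scaled, normalized=True)


def estimate_parameters(
    table: ReferenceTable,
    observed: SummaryVector,
    parameters: tuple[str, ...] = PARAM_COLUMNS[:17],
    normalize: bool = False,
    n_trees: int = 500,
    rng: np.random.Generator | int | None = None,
    interval: tuple[float, float] = (0.05, 0.95),
) -> ParameterEstimate:
    """Regression-forest parameter estimation on a (restricted) table.

    One forest per parameter predicts the observed vector; the credible
    interval is the (5%, 95%) quantile range of per-tree predictions,
    widened if needed to contain the point estimate.  With
    ``normalize=True`` sizes are reported relative to the current P1 size
    (N_P1 = 1 exactly) and times in coalescent units of 4*N_P1 generations;
    migration rates are already scale-free.
    """
    reg = ParameterRegressor(parameters=parameters, n_trees=n_trees,
                             interval=interval)
    reg.fit(table, rng=rng)
    return reg.predict(observed, normalize=normalize)


def draw_from_estimates(
    category: ScenarioCategory,
    submodel: HeterogeneitySubmodel,
    estimates: ParameterEstimate,
    min_size: float = 10.0,
) -> ParameterDraw:
    """Assemble a simulable ParameterDraw from point estimates.

    Independent per-parameter forests can violate the nesting and category
    constraints slightly; times are clipped into the nested order, blocked
    migration rates are zeroed and sizes floored at ``min_size``.
    """
    if estimates.normalized:
        raise ValueError("simulation requires estimates in absolute units")
    e = {k: v[0] for k, v in estimates.estimates.items()}
    t123 = max(e["T_split123"], 0.0)
    t12 = float(np.clip(e["T_split12"], 0.0, t123))
    ttrans = float(np.clip(e["T_trans12"], 0.0, t12))
    kwargs = dict(
        category=category, submodel=submodel,
        T_split123=t123, T_split12=t12, T_trans12=ttrans,
        T_change_P1=float(np.clip(e["T_change_P1"], 0.0, t12)),
        T_change_P2=float(np.clip(e["T_change_P2"], 0.0, t12)),
        T_change_P3=float(np.clip(e["T_change_P3"], 0.0, t123)),
        M12=max(e["M12"], 0.0),
        M13=max(e["M13"], 0.0) if "13" in category.p3_pairs else 0.0,
        M23=max(e["M23"], 0.0) if "23" in category.p3_pairs else 0.0,
    )
    for name in _SIZE_PARAMS:
        kwargs[name] = max(e[name], min_size)
    for name in ("ne_shape_a", "ne_shape_b", "mig_shape_a", "mig_shape_b"):
        kwargs[name] = max(e.get(name, 1.0), 0.1)
    draw = ParameterDraw(**kwargs)
    draw.validate()
    return draw


def posterior_predictive_check(
    draw: ParameterDraw,
    locus_specs: list[LocusSpec],
    observed: SummaryVector,
    n_rep: int = 100,
    mode: str = "theta",
    trio: SpeciesTrio | None = None,
    rng: np.random.Generator | int | None = None,
    mu: float = 3e-9,
) -> dict[str, float]:
    """Two-sided tail probability of each observed statistic.

    ``n_rep`` datasets are simulated at the point estimates; for each
    summary entry the tail probability is 2 * min(P(rep <= obs),
    P(rep >= obs)), capped at 1.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    trio = trio or SpeciesTrio()
    rng = np.random.default_rng(rng)
    reps = []
    for _ in range(n_rep):
        loci = simulate_dataset(draw, locus_specs, mode=mode, trio=trio,
                                rng=rng, mu=mu)
        if not loci:
            continue
        reps.append(dataset_summary([locus_stats(loc) for loc in loci]).values)
    if not reps:
        raise RunError("all posterior-predictive replicates were monomorphic")
    rep = np.array(reps)
    obs = observed.values
    lower = (rep <= obs).mean(axis=0)
    upper = (rep >= obs).mean(axis=0)
    tail = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return dict(zip(SUMMARY_NAMES, tail.tolist()))
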