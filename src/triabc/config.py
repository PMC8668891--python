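"""Plain-text run configuration: priors, species labels, sample sizes, seed."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model_space import ConfigurationError, PriorConfig, SpeciesTrio


@dataclass
class RunConfig:
    """Everything a reproducible run needs; defaults are the study priors."""

    priors: PriorConfig = field(default_factory=PriorConfig)
    trio: SpeciesTrio = field(default_factory=SpeciesTrio)
    seed: int = 0

    def save(self, path) -> None:
        data = {
            "seed": self.seed,
            "species": {
                "labels": list(self.trio.labels),
                "n_seq": list(self.trio.n_seq),
            },
            "priors": {
                "ne_range": list(self.priors.ne_range),
                "tsplit_outer_range": list(self.priors.tsplit_outer_range),
                "mig_range": list(self.priors.mig_range),
                "beta_ancestral": list(self.priors.beta_ancestral),
                "beta_secondary": list(self.priors.beta_secondary),
                "hetero_shape_range": list(self.priors.hetero_shape_range),
                "mu": self.priors.mu,
                "min_size": self.priors.min_size,
            },
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def load(cls, path) -> "RunConfig":
        try:
            data = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"cannot parse config {path}: {exc}") from exc
        kwargs = {}
        pr = data.get("priors", {})
        if pr:
            pairs = {k: tuple(v) for k, v in pr.items()
                     if isinstance(v, list)}
            scalars = {k: v for k, v in pr.items() if not isinstance(v, list)}
            kwargs["priors"] = PriorConfig(**pairs, **scalars)
        sp = data.get("species", {})
        if sp:
            kwargs["trio"] = SpeciesTrio(*sp["labels"], *sp["n_seq"])
        return cls(seed=int(data.get("seed", 0)), **kwargs)
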