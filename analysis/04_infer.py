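"""Hierarchical model choice and parameter estimation on the observed data.

Answers the two gene-flow questions with random forests trained on the
reference table — (1) is migration between the sister pair ongoing
(secondary contact) or confined to the early post-split epoch (ancestral
migration)?  (2) which of the sister species exchange migrants with the
third species? — then estimates the parameters of the winning category,
both in absolute units and relative to the current P1 size set to 1.
Writes results/inference_model_choice.tsv and results/inference_parameters.tsv.
"""

import pathlib

import numpy as np
import pandas as pd

from triabc.abc_inference import (
    HierarchicalClassifier,
    ParameterRegressor,
    ReferenceTable,
)
from triabc.sumstats import SUMMARY_NAMES, SummaryVector

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"
SEED = 20260901


def main():
    table = ReferenceTable.load(ROOT / "reference_table.tsv")
    obs_df = pd.read_csv(ROOT / "observed_summary.tsv", sep="\t")
    observed = SummaryVector(values=obs_df[list(SUMMARY_NAMES)].iloc[0].to_numpy())

    clf = HierarchicalClassifier(n_trees=500).fit(
        table, rng=np.random.default_rng(SEED))
    res = clf.predict(observed)
    rows = []
    for question, post in (("inner_flow", res.inner), ("outer_flow", res.outer)):
        rows.append({
            "question": question, "winner": post.winner,
            "posterior": post.posterior, "oob_error": post.oob_error,
            **{f"votes_{k}": v for k, v in post.vote_fractions.items()},
        })
    pd.DataFrame(rows).to_csv(ROOT / "inference_model_choice.tsv",
                              sep="\t", index=False)
    print(f"question 1 (P1-P2 gene flow): {res.inner.winner} "
          f"(posterior {res.inner.posterior:.2f}, "
          f"OOB error {res.inner.oob_error:.2f})")
    print(f"question 2 (gene flow with P3): {res.outer.winner} "
          f"(posterior {res.outer.posterior:.2f}, "
          f"OOB error {res.outer.oob_error:.2f})")
    print(f"winning category: {res.winning_category.code}")

    restricted = table.restrict(res.winning_category.code)
    reg = ParameterRegressor(n_trees=500).fit(
        restricted, rng=np.random.default_rng(SEED + 1))
    rows = []
    for normalize in (False, True):
        est = reg.predict(observed, normalize=normalize)
        for name, (point, lo, hi) in est.estimates.items():
            rows.append({"parameter": name, "units":
                         "relative" if normalize else "absolute",
                         "point": point, "lo90": lo, "hi90": hi})
    pd.DataFrame(rows).to_csv(ROOT / "inference_parameters.tsv",
                              sep="\t", index=False)
    rel = {r["parameter"]: r for r in rows if r["units"] == "relative"}
    print("relative sizes (N_P1 = 1): "
          + ", ".join(f"{k}={rel[k]['point']:.2f}"
                      for k in ("N_P1", "N_P2", "N_P3")))
    print(f"relative split times (units of 4*N_P1 generations): "
          f"T_split12={rel['T_split12']['point']:.3f}, "
          f"T_split123={rel['T_split123']['point']:.3f}")


if __name__ == "__main__":
    main()
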