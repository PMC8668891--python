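"""Posterior predictive check of the winning model at its point estimates.

Rebuilds a simulable parameter draw from the estimates of 04_infer.py,
simulates replicate datasets and reports the two-sided tail probability
of every observed summary statistic.  Writes results/ppc_tails.tsv.
"""

import argparse
import pathlib

import numpy as np
import pandas as pd

from triabc import HeterogeneitySubmodel, ScenarioCategory
from triabc.abc_inference import (
    ParameterEstimate,
    draw_from_estimates,
    posterior_predictive_check,
)
from triabc.sumstats import SUMMARY_NAMES, SummaryVector
from triabc.synthetic_data import EMPIRICAL_SHAPE, make_locus_specs

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n-rep", type=int, default=50)
    ap.add_argument("--n-loci", type=int, default=200)
    ap.add_argument("--seed", type=int, default=20260901)
    args = ap.parse_args()

    params = pd.read_csv(ROOT / "inference_parameters.tsv", sep="\t")
    absolute = params[params["units"] == "absolute"]
    est = ParameterEstimate(estimates={
        r["parameter"]: (r["point"], r["lo90"], r["hi90"])
        for _, r in absolute.iterrows()})
    choice = pd.read_csv(ROOT / "inference_model_choice.tsv", sep="\t")
    winner = ScenarioCategory(
        choice.loc[choice["question"] == "inner_flow", "winner"].iloc[0],
        choice.loc[choice["question"] == "outer_flow", "winner"].iloc[0])
    draw = draw_from_estimates(winner, HeterogeneitySubmodel(False, False), est)

    obs_df = pd.read_csv(ROOT / "observed_summary.tsv", sep="\t")
    observed = SummaryVector(values=obs_df[list(SUMMARY_NAMES)].iloc[0].to_numpy())
    rng = np.random.default_rng(args.seed)
    specs = make_locus_specs(EMPIRICAL_SHAPE, rng, n_loci=args.n_loci)
    tails = posterior_predictive_check(draw, specs, observed,
                                       n_rep=args.n_rep, rng=rng)
    out = pd.DataFrame(sorted(tails.items()), columns=["statistic", "tail_p"])
    out.to_csv(ROOT / "ppc_tails.tsv", sep="\t", index=False)
    flagged = out[out["tail_p"] < 0.05]
    print(f"{len(flagged)}/{len(out)} statistics with tail probability < 0.05")
    if len(flagged):
        print(flagged.to_string(index=False))


if __name__ == "__main__":
    main()
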