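#!/usr/bin/env python
"""Fit diversity-area models and the random-placement null model.

Builds richness-, abundance- and Shannon-area curves for each treatment
(window sides 1..10 quadrats, i.e. 0.25-25 m2), fits the power, exponential
and logistic families, ranks them by residual sum of squares, and compares
the observed richness curve against the Coleman random-placement expectation
and its 999-replicate randomisation envelope.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import steppediv as sd
from steppediv.pipeline import RunConfig, _by_treatment, load_or_simulate, sar_stage


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    cfg = RunConfig(
        seed=args.seed,
        sar_metrics=["richness", "abundance", "shannon"],
        sar_families=["power_multiplicative", "exponential", "logistic"],
        null_model="both",
        null_reps=999,
    )
    groups = _by_treatment(load_or_simulate(cfg))
    models, curves = sar_stage(groups, cfg)
    args.out.mkdir(parents=True, exist_ok=True)
    models.to_csv(args.out / "sar_models.csv", index=False)
    curves.to_csv(args.out / "sar_curves.csv", index=False)

    for t, grp in models.groupby("treatment"):
        best = grp[grp.metric == "richness"].sort_values("rank").iloc[0]
        print(f"{t}: best richness-area model = {best.family} (SSR {best.ssr:.3f})")

    # is the observed richness curve consistent with random placement?
    obs = curves.query("kind == 'observed' and metric == 'richness'")
    null = curves.query("kind == 'null_mean'")
    for t in sorted(groups):
        o = obs[obs.treatment == t].set_index("area_m2").value
        n = null[null.treatment == t].set_index("area_m2")
        outside = ((o < n.lower95) | (o > n.upper95)).sum()
        print(
            f"{t}: observed richness outside the 95% random-placement envelope "
            f"at {outside}/{len(o)} areas"
        )

    # do the fenced and grazed logistic fits differ?
    fits = {}
    for t, subplots in groups.items():
        fits[t] = sd.fit_model(sd.empirical_curve(subplots, "richness"), "logistic")
    verdict = sd.curves_differ(fits["grazed"], fits["fenced"])
    differing = [k for k, v in verdict.items() if v]
    print(f"logistic parameters with non-overlapping 95% CIs: {differing or 'none'}")
    print(f"tables written to {args.out}/")


if __name__ == "__main__":
    main()
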