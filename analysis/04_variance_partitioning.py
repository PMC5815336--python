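#!/usr/bin/env python
"""Partition diversity variation between environment and space.

For each treatment and diversity variable (richness, abundance, Shannon),
screens collinear environmental variables, forward-selects environmental
predictors and PCNM spatial eigenvectors (alpha = 0.05, 999 permutations,
double stopping), and partitions the variation into pure-environment [a],
spatially structured environment [b], pure-space [c] and residual [d]
fractions on the adjusted-R2 scale.
"""

import argparse
from pathlib import Path

from steppediv.pipeline import (
    RunConfig,
    _by_treatment,
    load_or_simulate,
    varpart_stage,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    cfg = RunConfig(seed=args.seed, n_perm=999)
    groups = _by_treatment(load_or_simulate(cfg))
    parts, selection = varpart_stage(groups, cfg)
    args.out.mkdir(parents=True, exist_ok=True)
    parts.to_csv(args.out / "varpart.csv", index=False)
    selection.to_csv(args.out / "selection.csv", index=False)

    for _, row in parts.iterrows():
        print(
            f"{row.treatment:7s} {row.response:9s}: "
            f"[a] {row.a_pure_env_pct:6.2f}%  [b] {row.b_spatial_env_pct:6.2f}%  "
            f"[c] {row.c_pure_space_pct:6.2f}%  [d] {row.d_residual_pct:6.2f}%  "
            f"(p[a]={row.p_a}, env: {row.env_selected or 'none'})"
        )
    print(f"tables written to {args.out}/")


if __name__ == "__main__":
    main()
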