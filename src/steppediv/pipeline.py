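"""Single-command orchestration of the full survey analysis.

One seeded run chains: load (or simulate) the survey -> per-window diversity
-> diversity-area curves with model fits and the random-placement null model
-> semivariograms of per-quadrat diversity -> environmental/spatial variance
partitioning; and writes the table-shaped CSV reports plus a JSON manifest.

Per-quadrat analyses (variograms, variance partitioning) operate on the
aligned-cell mean of the variable over a treatment's replicate subplots, so
each treatment contributes one value per grid position.

Seed fan-out: the run seed s yields the stage seed
``SeedSequence([s, stage_index]).generate_state(1) % 2**31`` with stage
indices 0=synthesis, 1=SAR null model, 2=variance partitioning, so any stage
can be re-run in isolation reproducibly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import diversity_surface
from .io import SurveyDataset, cellwise_mean, read_survey
from .sar import (
    compare_models,
    empirical_curve,
    expected_sar_coleman,
    fit_model,
    randomization_sar,
)
from .synth import steppe_preset, simulate_community
from .variogram import (
    empirical_variogram,
    fit_variogram,
    spatial_structure_summary,
)
from .varpart import (
    drop_collinear,
    forward_select,
    partition,
    pcnm,
    standardize,
)

logger = logging.getLogger("steppediv")

_STAGES = {"synth": 0, "sar_null": 1, "varpart": 2}


def stage_seed(seed: int, stage: str) -> int:
    """Derive the per-stage child seed from the run seed."""
    idx = _STAGES[stage]
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything one analysis run needs; round-trips through YAML."""

    seed: int = 0
    out_dir: str = "results/run"
    # input: CSV paths, or None to use the default synthetic preset
    abundance_path: str | None = None
    env_path: str | None = None
    species_prefix: str | None = None
    n_species: int = 25
    # analysis settings
    ks: list[int] | None = None
    sar_metrics: list[str] = field(
        default_factory=lambda: ["richness", "abundance", "shannon", "density"]
    )
    sar_families: list[str] = field(
        default_factory=lambda: [
            "power_multiplicative", "power_additive", "exponential", "logistic"
        ]
    )
    null_model: str = "both"  # coleman | randomize | both | none
    null_reps: int = 199
    variogram_variables: list[str] = field(
        default_factory=lambda: ["richness", "abundance", "shannon"]
    )
    variogram_model: str = "exponential"
    lag_width: float = 0.5
    max_lag: float | None = None
    varpart_responses: list[str] = field(
        default_factory=lambda: ["richness", "abundance", "shannon"]
    )
    alpha: float = 0.05
    n_perm: int = 999
    collinearity_threshold: float = 0.8

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def load_or_simulate(config: RunConfig) -> list[SurveyDataset]:
    if config.abundance_path:
        return read_survey(
            config.abundance_path,
            config.env_path,
            species_prefix=config.species_prefix,
        )
    synth_cfg = steppe_preset(
        seed=stage_seed(config.seed, "synth"), n_species=config.n_species
    )
    return simulate_community(synth_cfg)


def _by_treatment(datasets: Sequence[SurveyDataset]) -> dict[str, list[SurveyDataset]]:
    out: dict[str, list[SurveyDataset]] = {}
    for d in datasets:
        out.setdefault(d.treatment, []).append(d)
    return out


def _quadrat_values(dataset: SurveyDataset, variable: str) -> np.ndarray:
    return diversity_surface(dataset, k=1, metric=variable).values


def sar_stage(
    groups: dict[str, list[SurveyDataset]], config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Diversity-area curves, model fits, and the null model, per treatment."""
    model_rows, curve_rows = [], []
    null_seed = stage_seed(config.seed, "sar_null")
    for treatment, subplots in sorted(groups.items()):
        for metric in config.sar_metrics:
            curve = empirical_curve(subplots, metric=metric, ks=config.ks)
            for a, v in zip(curve.areas, curve.values):
                curve_rows.append(
                    {"treatment": treatment, "metric": metric, "kind": "observed",
                     "area_m2": a, "value": v}
                )
            fits = []
            for fam in config.sar_families:
                try:
                    fits.append(fit_model(curve, fam))
                except Exception as exc:  # keep the report complete per family
                    logger.warning("%s/%s %s fit failed: %s", treatment, metric, fam, exc)
            for rank, fit in enumerate(compare_models(fits) if len(fits) > 1 else fits, 1):
                row = {
                    "treatment": treatment, "metric": metric, "family": fit.family,
                    "ssr": fit.ssr, "rank": rank, "n_points": fit.n_points,
                }
                for pname, est, ci in zip(fit.param_names, fit.params, fit.ci_halfwidths):
                    row[pname] = est
                    row[f"{pname}_ci95"] = ci
                model_rows.append(row)
            if metric == "richness" and config.null_model != "none":
                if config.null_model in ("coleman", "both"):
                    exp_curve = expected_sar_coleman(subplots, ks=config.ks)
                    for a, v in zip(exp_curve.areas, exp_curve.values):
                        curve_rows.append(
                            {"treatment": treatment, "metric": metric,
                             "kind": "expected_coleman", "area_m2": a, "value": v}
                        )
                if config.null_model in ("randomize", "both"):
                    null = randomization_sar(
                        subplots, ks=config.ks, n_reps=config.null_reps, seed=null_seed
                    )
                    for a, v, lo, hi in zip(
                        null.curve.areas, null.curve.values, null.lower, null.upper
                    ):
                        curve_rows.append(
                            {"treatment": treatment, "metric": metric,
                             "kind": "null_mean", "area_m2": a, "value": v,
                             "lower95": lo, "upper95": hi}
                        )
    return pd.DataFrame(model_rows), pd.DataFrame(curve_rows)


def variogram_stage(
    groups: dict[str, list[SurveyDataset]], config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Variograms of subplot-mean per-quadrat diversity, per treatment."""
    fit_rows, lag_rows = [], []
    fits_by_var: dict[str, dict] = {}
    for treatment, subplots in sorted(groups.items()):
        coords = subplots[0].quadrat_centers()
        for variable in config.variogram_variables:
            values = cellwise_mean(subplots, lambda d: _quadrat_values(d, variable))
            emp = empirical_variogram(
                values, coords, lag_width=config.lag_width, max_lag=config.max_lag
            )
            fit = fit_variogram(emp, model=config.variogram_model)
            fits_by_var.setdefault(variable, {})[treatment] = fit
            fit_rows.append(
                {
                    "variable": variable, "treatment": treatment, "model": fit.model,
                    "C0": fit.nugget, "sill": fit.sill,
                    "structural_proportion": fit.structural_proportion,
                    "range_a": fit.range_param, "range_A0_m": fit.practical_range,
                    "r_squared": fit.r_squared,
                    "sample_variance": emp.sample_variance,
                }
            )
            for h, g, n in zip(emp.lags, emp.gamma, emp.n_pairs):
                lag_rows.append(
                    {"variable": variable, "treatment": treatment,
                     "lag_m": h, "gamma": g, "n_pairs": n}
                )
    summary = (
        spatial_structure_summary(fits_by_var)
        if all(len(v) == 2 for v in fits_by_var.values()) and fits_by_var
        else pd.DataFrame()
    )
    return pd.DataFrame(fit_rows), pd.DataFrame(lag_rows), summary


def varpart_stage(
    groups: dict[str, list[SurveyDataset]], config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forward selection + variance partitioning per diversity variable."""
    part_rows, sel_rows = [], []
    vp_seed = stage_seed(config.seed, "varpart")
    for treatment, subplots in sorted(groups.items()):
        if subplots[0].env is None:
            logger.warning("%s: no environmental data; skipping partitioning", treatment)
            continue
        coords = subplots[0].quadrat_centers()
        env_mean = pd.DataFrame(
            cellwise_mean(subplots, lambda d: d.env.to_numpy(dtype=float)),
            columns=subplots[0].env.columns,
        )
        env_screened = drop_collinear(env_mean, config.collinearity_threshold)
        env_z = standardize(env_screened)
        basis = pcnm(coords)
        pcnm_df = basis.as_frame()
        for variable in config.varpart_responses:
            y = cellwise_mean(subplots, lambda d: _quadrat_values(d, variable))
            sel_env = forward_select(
                y, env_z, alpha=config.alpha, n_perm=config.n_perm, seed=vp_seed
            )
            sel_pcnm = forward_select(
                y, pcnm_df, alpha=config.alpha, n_perm=config.n_perm, seed=vp_seed + 1
            )
            for source, sel in (("env", sel_env), ("pcnm", sel_pcnm)):
                df = sel.as_frame()
                df.insert(0, "source", source)
                df.insert(0, "response", variable)
                df.insert(0, "treatment", treatment)
                df["global_p"] = sel.global_p
                sel_rows.append(df)
            part = partition(
                y,
                env_z[sel_env.selected_names] if sel_env.selected_names else None,
                pcnm_df[sel_pcnm.selected_names] if sel_pcnm.selected_names else None,
                n_perm=config.n_perm,
                seed=vp_seed + 2,
            )
            pct = part.percentages()
            part_rows.append(
                {
                    "treatment": treatment, "response": variable,
                    "a_pure_env_pct": pct["a"], "b_spatial_env_pct": pct["b"],
                    "c_pure_space_pct": pct["c"], "d_residual_pct": pct["d"],
                    "p_a": part.p_a, "p_c": part.p_c, "p_total": part.p_total,
                    "env_selected": ";".join(part.env_selected),
                    "pcnm_selected": ";".join(part.pcnm_selected),
                }
            )
    selection = (
        pd.concat(sel_rows, ignore_index=True) if sel_rows else pd.DataFrame()
    )
    return pd.DataFrame(part_rows), selection


def run_full_analysis(config: RunConfig) -> dict[str, Path]:
    """Execute every stage and write the report bundle to ``config.out_dir``.

    Identical config + seed produce identical CSV outputs.  Any stage error
    aborts the run with the stage name in the raised exception.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    paths: dict[str, Path] = {"log": log_path}
    try:
        stage = "load/simulate"
        datasets = load_or_simulate(config)
        groups = _by_treatment(datasets)
        logger.info(
            "loaded %d subplots in %d treatment(s)", len(datasets), len(groups)
        )

        stage = "sar"
        sar_df, curves_df = sar_stage(groups, config)
        stage = "variogram"
        vg_df, lag_df, vg_summary = variogram_stage(groups, config)
        stage = "varpart"
        part_df, sel_df = varpart_stage(groups, config)

        stage = "write"
        tables = {
            "sar_models": sar_df, "curves": curves_df, "variograms": vg_df,
            "variogram_lags": lag_df, "variogram_summary": vg_summary,
            "varpart": part_df, "selection": sel_df,
        }
        for name, df in tables.items():
            p = out / f"{name}.csv"
            df.to_csv(p, index=False, float_format="%.10g")
            paths[name] = p
        manifest = {
            "config": asdict(config),
            "seed": config.seed,
            "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES},
            "version": __version__,
            "wall_time_s": round(time.time() - t0, 3),
            "outputs": {k: str(v) for k, v in paths.items()},
        }
        mp = out / "manifest.json"
        mp.write_text(json.dumps(manifest, indent=2))
        paths["manifest"] = mp
        logger.info("run complete in %.1f s", time.time() - t0)
        return paths
    except Exception as exc:
        logger.error("stage %r failed: %s", stage, exc)
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
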