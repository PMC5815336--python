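"""Synthetic quadrat-survey generator.

Emulates the statistical structure the downstream analyses assume: a regular
grid of quadrats per subplot, spatially autocorrelated environmental fields
(exponential-covariance Gaussian random fields), species abundances that
respond log-linearly to the environment plus species-specific fine-scale
aggregation, and grazed/fenced treatment contrasts (palatable forbs suppressed
and the dominant grass released inside the exclosure, so the fenced side
carries fewer species but more individuals).

Counts are Poisson with a log link:

    n_sq ~ Poisson( exp( mu_s + sum_v beta_sv * env_v(q) + cluster_s(q) + t_s ) )

where ``cluster_s`` is a per-species Gaussian random field scaled by the
species' clustering strength and ``t_s`` the log treatment multiplier.
Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cholesky
from scipy.spatial.distance import pdist, squareform

from .io import ENV_SCHEMA, SurveyDataset


@dataclass(frozen=True)
class EnvFieldSpec:
    """Spatial model of one environmental variable: exponential GRF."""

    name: str
    mean: float
    nugget: float
    partial_sill: float
    range_m: float  # correlation length a; covariance psill * exp(-h/a)

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError(f"{self.name}: nugget and partial sill must be >= 0")
        if self.range_m <= 0:
            raise ValueError(f"{self.name}: range must be positive")


@dataclass(frozen=True)
class SpeciesSpec:
    """Per-species abundance model parameters."""

    name: str
    mean_log_abundance: float
    env_response: dict[str, float] = field(default_factory=dict)
    clustering: float = 0.0  # sd of the per-species aggregation field
    cluster_range_m: float = 0.3
    palatable: bool = True


@dataclass
class SyntheticConfig:
    """Full study design for one simulated grazed-vs-fenced survey."""

    grid_shape: tuple[int, int] = (10, 10)
    quadrat_size: float = 0.5
    n_subplots: int = 3
    seed: int = 0
    env_fields: Sequence[EnvFieldSpec] = ()
    species: Sequence[SpeciesSpec] = ()
    # multiplicative abundance modifiers, applied by (treatment, palatability)
    treatment_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "grazed": {"palatable": 1.0, "unpalatable": 1.0},
            "fenced": {"palatable": 0.25, "unpalatable": 2.2},
        }
    )

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("need at least one species")
        for f in self.env_fields:
            pass  # EnvFieldSpec validates itself

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=list)


def gaussian_random_field(
    grid_shape: tuple[int, int],
    quadrat_size: float,
    nugget: float,
    partial_sill: float,
    range_m: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One realisation of a zero-mean exponential-covariance field.

    Covariance between quadrat centres at distance h is
    ``partial_sill * exp(-h / range_m)``; independent N(0, nugget) noise is
    added on top.  Sampled exactly via Cholesky factorisation of the dense
    covariance matrix of all quadrat-centre distances.
    """
    if nugget < 0 or partial_sill < 0:
        raise ValueError("nugget and partial sill must be >= 0")
    if range_m <= 0:
        raise ValueError("range must be positive")
    rows, cols = grid_shape
    n = rows * cols
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    xy = np.column_stack(
        [(cc.ravel() + 0.5) * quadrat_size, (rr.ravel() + 0.5) * quadrat_size]
    )
    z = np.zeros(n)
    if partial_sill > 0:
        h = squareform(pdist(xy))
        cov = partial_sill * np.exp(-h / range_m)
        jitter = 0.0
        for jitter in (0.0, 1e-10, 1e-8, 1e-6):
            try:
                L = cholesky(cov + jitter * np.eye(n), lower=True)
                break
            except np.linalg.LinAlgError:
                continue
        else:  # pragma: no cover - exponential covariance is positive definite
            raise np.linalg.LinAlgError(
                f"covariance not positive definite even with jitter {jitter}"
            )
        z = L @ rng.standard_normal(n)
    if nugget > 0:
        z = z + np.sqrt(nugget) * rng.standard_normal(n)
    return z.reshape(rows, cols)


def _default_env_fields() -> list[EnvFieldSpec]:
    # ranges of ~0.3-1 m: the fine-scale autocorrelation a 0.5 m grid resolves
    return [
        EnvFieldSpec("soil_water", mean=8.0, nugget=0.05, partial_sill=1.0, range_m=0.8),
        EnvFieldSpec("soil_compaction", mean=2.5, nugget=0.02, partial_sill=0.3, range_m=1.0),
        EnvFieldSpec("organic_carbon", mean=5.0, nugget=0.05, partial_sill=0.5, range_m=0.9),
        EnvFieldSpec("clay", mean=6.0, nugget=0.05, partial_sill=0.8, range_m=0.7),
        EnvFieldSpec("silt", mean=30.0, nugget=0.2, partial_sill=4.0, range_m=0.8),
        EnvFieldSpec("fine_sand", mean=40.0, nugget=0.2, partial_sill=4.0, range_m=0.6),
        EnvFieldSpec("coarse_sand", mean=24.0, nugget=0.2, partial_sill=3.0, range_m=0.5),
    ]


def _default_species(rng: np.random.Generator, n_species: int) -> list[SpeciesSpec]:
    """Species pool: one dominant unpalatable bunchgrass + subordinate forbs.

    Mean log-abundances are drawn from a lognormal-type spread so a handful of
    species carry most individuals, as in semi-arid steppe communities; forbs
    respond mainly to soil water and texture.
    """
    species: list[SpeciesSpec] = []
    env_names = ["soil_water", "silt", "coarse_sand", "organic_carbon"]
    for i in range(n_species):
        if i == 0:  # dominant grass: abundant, weakly clustered, unpalatable
            mu, clustering, palatable = np.log(16.0), 0.25, False
        else:
            # subordinate forbs/annuals: mostly rare, strongly aggregated,
            # giving ~8-10 species per 0.25 m^2 quadrat out of a pool of 25
            mu = float(rng.normal(np.log(0.35), 1.3))
            clustering = float(rng.uniform(0.3, 0.8))
            palatable = bool(rng.random() < 0.65)
        # moisture limits nearly everything in a desert steppe, so every
        # species responds positively to soil water; texture/carbon responses
        # are species-specific in sign
        beta = {"soil_water": float(rng.uniform(0.15, 0.55))}
        other = str(rng.choice(env_names[1:]))
        beta[other] = float(rng.normal(0.0, 0.25))
        species.append(
            SpeciesSpec(
                name=f"sp{i:02d}",
                mean_log_abundance=mu,
                env_response=beta,
                clustering=clustering,
                palatable=palatable,
            )
        )
    return species


def steppe_preset(seed: int = 0, n_species: int = 25) -> SyntheticConfig:
    """Default preset: 10x10 grid of 0.5 m quadrats, 3 subplots x 2 treatments."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    return SyntheticConfig(
        grid_shape=(10, 10),
        quadrat_size=0.5,
        n_subplots=3,
        seed=seed,
        env_fields=_default_env_fields(),
        species=_default_species(rng, n_species),
    )


def simulate_community(config: SyntheticConfig) -> list[SurveyDataset]:
    """Simulate every subplot of both treatments; deterministic under seed.

    Returns ``2 * n_subplots`` datasets (grazed then fenced), each passing the
    survey data-model validation, with the simulated environmental fields
    attached (grass cover/density derived from the dominant grass itself).
    """
    env_fields = list(config.env_fields) or _default_env_fields()
    species = list(config.species)
    rows, cols = config.grid_shape
    n = rows * cols
    ss = np.random.SeedSequence([config.seed, 0xC0FFEE])
    datasets: list[SurveyDataset] = []
    index = pd.MultiIndex.from_product(
        [range(rows), range(cols)], names=["row", "col"]
    )

    for treatment in ("grazed", "fenced"):
        effects = config.treatment_effects[treatment]
        for sub in range(config.n_subplots):
            rng = np.random.default_rng(ss.spawn(1)[0])
            env_vals: dict[str, np.ndarray] = {}
            env_std: dict[str, np.ndarray] = {}
            for f in env_fields:
                z = gaussian_random_field(
                    config.grid_shape, config.quadrat_size,
                    f.nugget, f.partial_sill, f.range_m, rng,
                ).ravel()
                env_vals[f.name] = f.mean + z
                sd = np.sqrt(f.partial_sill + f.nugget)
                env_std[f.name] = z / sd if sd > 0 else z
            counts = np.zeros((n, len(species)), dtype=np.int64)
            lam_grass = None
            for j, sp in enumerate(species):
                eta = np.full(n, sp.mean_log_abundance)
                for v, b in sp.env_response.items():
                    if v in env_std:
                        eta = eta + b * env_std[v]
                if sp.clustering > 0:
                    cl = gaussian_random_field(
                        config.grid_shape, config.quadrat_size,
                        0.0, 1.0, sp.cluster_range_m, rng,
                    ).ravel()
                    eta = eta + sp.clustering * cl
                mult = effects["palatable" if sp.palatable else "unpalatable"]
                lam = np.exp(eta) * mult
                if j == 0:
                    lam_grass = lam
                counts[:, j] = rng.poisson(lam)
            # aboveground biotic covariates follow the dominant grass
            env_vals["grass_density"] = counts[:, 0] / config.quadrat_size**2
            cover = 100.0 * (1.0 - np.exp(-0.06 * lam_grass))
            env_vals["grass_cover"] = cover + rng.normal(0.0, 1.0, n)

            ab = pd.DataFrame(counts, index=index, columns=[s.name for s in species])
            env = pd.DataFrame(
                {k: env_vals[k] for k in ENV_SCHEMA if k in env_vals}, index=index
            )
            datasets.append(
                SurveyDataset(
                    subplot_id=f"{treatment}-{sub + 1}",
                    treatment=treatment,
                    grid_shape=config.grid_shape,
                    abundance=ab,
                    env=env,
                    quadrat_size=config.quadrat_size,
                    site_id=f"synthetic-seed{config.seed}",
                )
            )
    return datasets
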