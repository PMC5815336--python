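"""Survey data model and file I/O.

A survey is a set of 5 m x 5 m subplots, each divided into a regular grid of
0.5 m x 0.5 m quadrats (10 x 10 by default).  Every quadrat carries integer
individual counts per species and, optionally, environmental measurements
(soil water content, compaction, organic carbon, particle-size fractions,
dominant-grass cover and density).  Subplots belong to one of two treatments:
``grazed`` (outside the exclosure fence) or ``fenced`` (inside).

Conventions fixed here and used everywhere downstream:

* grid coordinates are 0-based ``(row, col)``;
* the centre of quadrat ``(row, col)`` is at
  ``((col + 0.5) * quadrat_size, (row + 0.5) * quadrat_size)`` metres;
* square analysis windows of side ``k`` quadrats are placed by non-overlapping
  tiling anchored at ``(0, 0)`` by default (leftover quadrats at the far edges
  are dropped for that ``k``); a sliding placement is available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TREATMENTS = ("grazed", "fenced")

#: environmental variables of the standard survey schema
ENV_SCHEMA = (
    "soil_water",
    "soil_compaction",
    "organic_carbon",
    "clay",
    "silt",
    "fine_sand",
    "coarse_sand",
    "grass_cover",
    "grass_density",
)


class SurveyValidationError(ValueError):
    """Raised when a survey table violates the data-model invariants."""


@dataclass(frozen=True)
class Window:
    """A square sampling window: ``k`` x ``k`` quadrats anchored at ``origin``."""

    origin: tuple[int, int]
    k: int
    quadrat_size: float = 0.5

    @property
    def area(self) -> float:
        """Window area in m^2."""
        return (self.k * self.quadrat_size) ** 2

    def cells(self) -> list[tuple[int, int]]:
        r0, c0 = self.origin
        return [(r0 + i, c0 + j) for i in range(self.k) for j in range(self.k)]


@dataclass(frozen=True)
class QuadratRecord:
    """One quadrat: grid position, per-species counts and environment."""

    row: int
    col: int
    abundances: Mapping[str, int]
    env: Mapping[str, float] | None


@dataclass
class SurveyDataset:
    """One subplot's survey: abundance grid + environment + treatment.

    ``abundance`` is a DataFrame indexed by a (row, col) MultiIndex covering
    every grid cell exactly once, with one integer column per species.
    ``env`` shares the same index, one column per environmental variable, or
    is ``None`` when the survey carries no environmental data.
    """

    subplot_id: str
    treatment: str
    grid_shape: tuple[int, int]
    abundance: pd.DataFrame
    env: pd.DataFrame | None = None
    quadrat_size: float = 0.5
    site_id: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise SurveyValidationError(f"grid shape must be positive, got {self.grid_shape}")
        if self.treatment not in TREATMENTS:
            raise SurveyValidationError(
                f"treatment must be one of {TREATMENTS}, got {self.treatment!r}"
            )
        if self.quadrat_size <= 0:
            raise SurveyValidationError("quadrat size must be positive")
        idx = self.abundance.index
        if len(idx) != rows * cols:
            raise SurveyValidationError(
                f"expected {rows * cols} quadrats for grid {self.grid_shape}, got {len(idx)}"
            )
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise SurveyValidationError(f"duplicate quadrat key {tuple(dup)}")
        for r, c in idx:
            if not (0 <= r < rows and 0 <= c < cols):
                raise SurveyValidationError(
                    f"quadrat (row={r}, col={c}) outside declared grid shape {self.grid_shape}"
                )
        vals = self.abundance.to_numpy()
        if not np.isfinite(vals).all():
            raise SurveyValidationError("non-finite abundance value")
        bad = np.argwhere((vals < 0) | (vals != np.floor(vals)))
        if bad.size:
            i, j = bad[0]
            r, c = idx[i]
            raise SurveyValidationError(
                f"abundance must be a non-negative integer; offending cell "
                f"(row {r}, col {c}), species {self.abundance.columns[j]!r}: {vals[i, j]}"
            )
        if self.env is not None:
            if not self.env.index.equals(idx):
                raise SurveyValidationError("env table index does not match abundance index")
            if self.env.isna().any().any():
                # no ragged missingness: a variable is present everywhere or absent
                raise SurveyValidationError(
                    "environmental table contains missing values; drop the variable instead"
                )

    # -- derived views ---------------------------------------------------
    @property
    def species_names(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def quadrats(self) -> list[QuadratRecord]:
        env = self.env
        return [
            QuadratRecord(
                row=r,
                col=c,
                abundances=self.abundance.loc[(r, c)].to_dict(),
                env=None if env is None else env.loc[(r, c)].to_dict(),
            )
            for r, c in self.abundance.index
        ]

    def quadrat_centers(self) -> np.ndarray:
        """(n, 2) array of quadrat centre coordinates (x, y) in metres."""
        rc = np.asarray(list(self.abundance.index), dtype=float)
        x = (rc[:, 1] + 0.5) * self.quadrat_size
        y = (rc[:, 0] + 0.5) * self.quadrat_size
        return np.column_stack([x, y])

    def counts_grid(self) -> np.ndarray:
        """Abundance as a (rows, cols, n_species) integer array."""
        rows, cols = self.grid_shape
        out = np.zeros((rows, cols, len(self.abundance.columns)), dtype=np.int64)
        rc = np.asarray(list(self.abundance.index), dtype=int)
        out[rc[:, 0], rc[:, 1]] = self.abundance.to_numpy(dtype=np.int64)
        return out

    def window_counts(self, window: Window) -> np.ndarray:
        """Pooled per-species counts inside ``window``."""
        grid = self.counts_grid()
        r0, c0 = window.origin
        return grid[r0 : r0 + window.k, c0 : c0 + window.k].sum(axis=(0, 1))

    def with_species(self, species: Sequence[str]) -> "SurveyDataset":
        """Reindex species columns to ``species``; absent species become 0."""
        ab = self.abundance.reindex(columns=list(species), fill_value=0)
        return replace(self, abundance=ab)


def enumerate_windows(
    dataset: SurveyDataset, k: int, mode: str = "tiling"
) -> list[Window]:
    """Square windows of side ``k`` quadrats over the dataset grid.

    ``tiling`` (default) anchors non-overlapping windows at (0, 0), dropping
    leftover quadrats when ``k`` does not divide the grid; ``sliding`` returns
    every possible placement (windows overlap).
    """
    rows, cols = dataset.grid_shape
    if not 1 <= k <= min(rows, cols):
        raise ValueError(f"window side k={k} out of range [1, {min(rows, cols)}]")
    if mode == "tiling":
        origins = [
            (i * k, j * k) for i in range(rows // k) for j in range(cols // k)
        ]
    elif mode == "sliding":
        origins = [(i, j) for i in range(rows - k + 1) for j in range(cols - k + 1)]
    else:
        raise ValueError(f"unknown window mode {mode!r}")
    return [Window(origin=o, k=k, quadrat_size=dataset.quadrat_size) for o in origins]


def subplot_mean(
    datasets: Sequence[SurveyDataset],
    variable: Callable[[SurveyDataset], float | np.ndarray],
) -> float | np.ndarray:
    """Arithmetic mean of a per-subplot quantity over replicate subplots.

    The quantity is evaluated on each subplot first and the results averaged
    — raw counts are never pooled across subplots.  All subplots must share
    grid shape and treatment.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    shapes = {d.grid_shape for d in datasets}
    if len(shapes) > 1:
        raise ValueError(f"mismatched grid shapes: {sorted(shapes)}")
    treats = {d.treatment for d in datasets}
    if len(treats) > 1:
        raise ValueError(f"mismatched treatments: {sorted(treats)}")
    values = [np.asarray(variable(d), dtype=float) for d in datasets]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        out = np.nanmean(np.stack(values), axis=0)
    return float(out) if out.ndim == 0 else out


def union_species(datasets: Iterable[SurveyDataset]) -> list[str]:
    """Shared species universe: ordered union over subplots."""
    seen: dict[str, None] = {}
    for d in datasets:
        for s in d.species_names:
            seen.setdefault(s)
    return list(seen)


def align_species(datasets: Sequence[SurveyDataset]) -> list[SurveyDataset]:
    """Reindex every dataset onto the union species list (absent = 0)."""
    species = union_species(datasets)
    return [d.with_species(species) for d in datasets]


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_KEY_COLS = ["subplot", "row", "col"]
_META_COLS = set(_KEY_COLS) | {"treatment"}


def _read_keyed_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _KEY_COLS if c not in df.columns]
    if missing:
        raise SurveyValidationError(f"{path}: missing key column(s) {missing}")
    dup = df.duplicated(subset=_KEY_COLS)
    if dup.any():
        key = df.loc[dup.idxmax(), _KEY_COLS].tolist()
        raise SurveyValidationError(f"{path}: duplicate (subplot,row,col) key {key}")
    return df


def read_survey(
    abundance_path: str | Path,
    env_path: str | Path | None = None,
    *,
    grid_shape: tuple[int, int] | None = None,
    quadrat_size: float = 0.5,
    treatments: Mapping[str, str] | None = None,
    default_treatment: str = "grazed",
    species_prefix: str | None = None,
    site_id: str = "",
) -> list[SurveyDataset]:
    """Read survey CSV table(s) into validated datasets, one per subplot.

    The abundance table has header ``subplot,row,col,<species...>`` and the
    optional environment table ``subplot,row,col,<var...>``.  Alternatively a
    single wide CSV may carry both, with species columns identified by
    ``species_prefix`` (remaining non-key columns are read as environment);
    pass the same path twice or leave ``env_path=None`` in that case.

    Treatment is taken from a ``treatment`` column if present, else from the
    ``treatments`` mapping (subplot id -> treatment), else ``default_treatment``.
    Grid shape defaults to the bounding extent of the observed (row, col).
    """
    ab = _read_keyed_csv(abundance_path)
    env_df: pd.DataFrame | None = None

    if species_prefix is not None:
        sp_cols = [c for c in ab.columns if c.startswith(species_prefix)]
        if not sp_cols:
            raise SurveyValidationError(
                f"no columns start with species prefix {species_prefix!r}"
            )
        env_cols = [c for c in ab.columns if c not in sp_cols and c not in _META_COLS]
        if env_cols:
            env_df = ab[_KEY_COLS + env_cols]
        species_cols = sp_cols
    else:
        species_cols = [c for c in ab.columns if c not in _META_COLS]
        if env_path is not None:
            env_df = _read_keyed_csv(env_path)

    datasets: list[SurveyDataset] = []
    for sid, grp in ab.groupby("subplot", sort=True):
        rc = grp[["row", "col"]].to_numpy(dtype=int)
        if grid_shape is None:
            shape = (int(rc[:, 0].max()) + 1, int(rc[:, 1].max()) + 1)
        else:
            shape = grid_shape
        index = pd.MultiIndex.from_arrays([rc[:, 0], rc[:, 1]], names=["row", "col"])
        counts = grp[species_cols].copy()
        counts.index = index
        counts = counts.sort_index()

        env_sub = None
        if env_df is not None:
            eg = env_df[env_df["subplot"] == sid]
            if len(eg) != len(grp):
                raise SurveyValidationError(
                    f"subplot {sid!r}: env table has {len(eg)} rows, abundance {len(grp)}"
                )
            e_idx = pd.MultiIndex.from_arrays(
                [eg["row"].to_numpy(int), eg["col"].to_numpy(int)], names=["row", "col"]
            )
            env_sub = eg.drop(columns=[c for c in _META_COLS if c in eg.columns])
            env_sub.index = e_idx
            env_sub = env_sub.sort_index()

        if "treatment" in grp.columns:
            treatment = str(grp["treatment"].iloc[0])
        elif treatments is not None and str(sid) in treatments:
            treatment = treatments[str(sid)]
        else:
            treatment = default_treatment

        datasets.append(
            SurveyDataset(
                subplot_id=str(sid),
                treatment=treatment,
                grid_shape=shape,
                abundance=counts,
                env=env_sub,
                quadrat_size=quadrat_size,
                site_id=site_id,
            )
        )
    return datasets


def write_survey(
    datasets: Sequence[SurveyDataset],
    abundance_path: str | Path,
    env_path: str | Path | None = None,
) -> None:
    """Write datasets to the CSV layout read back by :func:`read_survey`."""
    datasets = align_species(list(datasets)) if len(datasets) > 1 else list(datasets)
    ab_rows = []
    env_rows = []
    for d in datasets:
        for (r, c), counts in d.abundance.iterrows():
            ab_rows.append(
                {"subplot": d.subplot_id, "row": r, "col": c, "treatment": d.treatment}
                | counts.to_dict()
            )
        if d.env is not None:
            for (r, c), vals in d.env.iterrows():
                env_rows.append(
                    {"subplot": d.subplot_id, "row": r, "col": c} | vals.to_dict()
                )
    pd.DataFrame(ab_rows).to_csv(abundance_path, index=False)
    if env_path is not None and env_rows:
        pd.DataFrame(env_rows).to_csv(env_path, index=False)


def cellwise_mean(
    datasets: Sequence[SurveyDataset],
    values: Callable[[SurveyDataset], np.ndarray],
) -> np.ndarray:
    """Mean of a per-quadrat vector across subplots, aligned by (row, col).

    ``values`` must return one value per quadrat in abundance-index order
    (which is sorted (row, col) for datasets built by this module).  This is
    the aggregation used for per-quadrat analyses: each grid position's value
    is averaged over the replicate subplots of a treatment.
    """
    return np.asarray(subplot_mean(datasets, values), dtype=float)
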