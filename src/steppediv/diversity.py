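"""Per-window diversity quantities.

Richness S, abundance N, Shannon H' (natural log), Simpson D = 1 - sum p_i^2,
Pielou evenness J = H'/ln S, and density N/area.  Windows with no individuals
yield NaN (an explicit undefined marker) for the relative-abundance indices
rather than 0, so that downstream curve averaging can skip them instead of
silently biasing diversity-area points downward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio.diversity import alpha as _alpha

from .io import SurveyDataset, Window, enumerate_windows

#: metrics available for diversity surfaces and diversity-area curves
METRICS = ("richness", "abundance", "shannon", "simpson", "pielou", "density")


def _counts(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("counts must be one-dimensional")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    return c


def richness(counts) -> int:
    """Number of species with at least one individual."""
    return int((_counts(counts) > 0).sum())


def abundance(counts) -> int:
    """Total number of individuals."""
    return int(_counts(counts).sum())


def shannon(counts) -> float:
    """Shannon diversity H' = -sum p_i ln p_i; NaN when no individuals."""
    c = _counts(counts)
    if c.sum() == 0:
        return float("nan")
    return float(_alpha.shannon(c.astype(np.int64), base=np.e))


def simpson(counts) -> float:
    """Simpson diversity D = 1 - sum p_i^2; NaN when no individuals."""
    c = _counts(counts)
    if c.sum() == 0:
        return float("nan")
    return float(_alpha.simpson(c.astype(np.int64)))


def pielou(counts) -> float:
    """Pielou evenness J = H'/ln S; NaN when S <= 1 or no individuals."""
    c = _counts(counts)
    if c.sum() == 0 or richness(c) <= 1:
        return float("nan")
    return float(_alpha.pielou_e(c.astype(np.int64)))


def density(counts, area: float) -> float:
    """Individuals per m^2."""
    if area <= 0:
        raise ValueError("area must be positive")
    return abundance(counts) / area


@dataclass
class DiversitySurface:
    """One metric evaluated on every window of one side length ``k``."""

    metric: str
    k: int
    windows: list[Window]
    values: np.ndarray  # aligned to windows; NaN marks undefined

    @property
    def area(self) -> float:
        return self.windows[0].area if self.windows else float("nan")

    @property
    def n_undefined(self) -> int:
        return int(np.isnan(self.values).sum())


def metric_value(metric: str, counts, area: float) -> float:
    if metric == "richness":
        return float(richness(counts))
    if metric == "abundance":
        return float(abundance(counts))
    if metric == "shannon":
        return shannon(counts)
    if metric == "simpson":
        return simpson(counts)
    if metric == "pielou":
        return pielou(counts)
    if metric == "density":
        return density(counts, area)
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


def diversity_surface(
    dataset: SurveyDataset, k: int, metric: str, mode: str = "tiling"
) -> DiversitySurface:
    """Evaluate ``metric`` on the pooled counts of every window of side ``k``."""
    windows = enumerate_windows(dataset, k, mode=mode)
    grid = dataset.counts_grid()
    values = np.empty(len(windows))
    for i, w in enumerate(windows):
        r0, c0 = w.origin
        pooled = grid[r0 : r0 + k, c0 : c0 + k].sum(axis=(0, 1))
        values[i] = metric_value(metric, pooled, w.area)
    return DiversitySurface(metric=metric, k=k, windows=windows, values=values)
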