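"""Diversity-area curves, model fitting and random-placement null models.

The diversity-area curve plots a window-mean diversity value (richness,
abundance, Shannon, density) against window area A, with windows nested from
one quadrat (0.25 m^2) up to the full subplot (25 m^2).  Model families:

======================  ==========================================  ======
family                  formula                                     params
======================  ==========================================  ======
power_multiplicative    S = alpha * A**beta                         2
power_additive          S = alpha + A**beta                         2
exponential             S = alpha * ln A + beta                     2
logistic                S = beta / (1 + exp((delta - log A)/alpha)) 3
parabolic               S = alpha*(ln A)**2 + beta*ln A + delta     3
linear                  S = alpha * A + beta                        2
======================  ==========================================  ======

The ``log`` in the logistic family is the natural log by default (base-10
available); models are ranked by residual sum of squares (SSR) on the
original scale, ties broken in favour of fewer parameters.  The null model is
Coleman random placement: every individual falls uniformly over the subplot,
species totals preserved — available both as the closed-form expectation and
as a seeded randomisation with a 95% envelope.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .diversity import diversity_surface
from .io import SurveyDataset, subplot_mean


@dataclass
class SARCurve:
    """Ordered (area, mean diversity value) pairs for one metric."""

    metric: str
    areas: np.ndarray
    values: np.ndarray
    treatment: str = ""
    n_subplots: int = 1
    window_mode: str = "tiling"

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.areas.shape != self.values.shape or self.areas.ndim != 1:
            raise ValueError("areas and values must be matching 1-d arrays")
        if len(self.areas) and not (np.diff(self.areas) > 0).all():
            raise ValueError("areas must be strictly increasing")

    def digest(self) -> str:
        h = hashlib.sha1()
        h.update(self.areas.tobytes())
        h.update(self.values.tobytes())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# model families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Family:
    name: str
    n_params: int
    param_names: tuple[str, ...]
    linear_in_log: bool  # solvable by linear least squares on a design matrix


FAMILIES = {
    f.name: f
    for f in (
        _Family("power_multiplicative", 2, ("alpha", "beta"), False),
        _Family("power_additive", 2, ("alpha", "beta"), False),
        _Family("exponential", 2, ("alpha", "beta"), True),
        _Family("logistic", 3, ("alpha", "beta", "delta"), False),
        _Family("parabolic", 3, ("alpha", "beta", "delta"), True),
        _Family("linear", 2, ("alpha", "beta"), True),
    )
}


def family_predict(
    family: str, params: Sequence[float], areas: np.ndarray, log_base: float = np.e
) -> np.ndarray:
    """Evaluate a model family at the given areas."""
    A = np.asarray(areas, dtype=float)
    logA = np.log(A) / np.log(log_base)
    p = np.asarray(params, dtype=float)
    if family == "power_multiplicative":
        return p[0] * A ** p[1]
    if family == "power_additive":
        return p[0] + A ** p[1]
    if family == "exponential":
        return p[0] * np.log(A) + p[1]
    if family == "logistic":
        alpha, beta, delta = p
        return beta / (1.0 + np.exp((delta - logA) / alpha))
    if family == "parabolic":
        return p[0] * logA**2 + p[1] * logA + p[2]
    if family == "linear":
        return p[0] * A + p[1]
    raise ValueError(f"unknown family {family!r}")


def _design_matrix(family: str, A: np.ndarray, log_base: float) -> np.ndarray:
    logA = np.log(A) / np.log(log_base)
    if family == "exponential":
        return np.column_stack([np.log(A), np.ones_like(A)])
    if family == "parabolic":
        return np.column_stack([logA**2, logA, np.ones_like(A)])
    if family == "linear":
        return np.column_stack([A, np.ones_like(A)])
    raise ValueError(family)


@dataclass
class ModelFit:
    """A fitted diversity-area model with 95% parameter confidence intervals."""

    family: str
    params: np.ndarray
    ci_halfwidths: np.ndarray  # 95%, from t * SE of the linearised fit
    ssr: float
    converged: bool
    n_points: int
    curve_digest: str
    log_base: float = np.e
    message: str = ""

    @property
    def param_names(self) -> tuple[str, ...]:
        return FAMILIES[self.family].param_names

    def predict(self, areas: np.ndarray) -> np.ndarray:
        return family_predict(self.family, self.params, areas, self.log_base)


class FitConvergenceError(RuntimeError):
    """Nonlinear fit failed to converge; carries the best attempt."""

    def __init__(self, message: str, best: ModelFit | None = None):
        super().__init__(message)
        self.best = best


def _ci_halfwidths(jac: np.ndarray, ssr: float, n: int, p: int) -> np.ndarray:
    """95% CI half-widths from the Jacobian-based parameter covariance."""
    dof = n - p
    if dof <= 0:
        return np.full(p, np.nan)
    jtj = jac.T @ jac
    try:
        cov = np.linalg.inv(jtj) * (ssr / dof)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jtj) * (ssr / dof)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return stats.t.ppf(0.975, dof) * se


def _initial_guesses(family: str, A: np.ndarray, S: np.ndarray, log_base: float):
    """Deterministic multi-start grid of initial parameter vectors."""
    logA = np.log(A) / np.log(log_base)
    smax, smin = float(S.max()), float(S.min())
    if family == "power_multiplicative":
        # log-log slope as beta0 where S > 0
        pos = S > 0
        if pos.sum() >= 2:
            b, a = np.polyfit(np.log(A[pos]), np.log(S[pos]), 1)
            base = [(np.exp(a), b)]
        else:
            base = [(max(smax, 1.0), 0.25)]
        return base + [(max(smax, 1.0), z) for z in (0.1, 0.25, 0.5)]
    if family == "power_additive":
        return [(smin, z) for z in (0.1, 0.25, 0.5, 1.0)] + [(0.0, 0.5)]
    if family == "logistic":
        beta0 = smax * 1.05 if smax > 0 else 1.0
        delta0 = float(np.median(logA))
        return [(a0, beta0, delta0) for a0 in (0.5, 1.0, 2.0, 5.0)]
    raise ValueError(family)


def fit_model(
    curve: SARCurve, family: str, log_base: float = np.e
) -> ModelFit:
    """Least-squares fit of one family to a diversity-area curve.

    Linear-in-parameters families (exponential, parabolic, linear) are solved
    exactly; the others by bounded Levenberg-Marquardt-type minimisation from
    a fixed multi-start grid, so the result is deterministic for a given
    curve.  SSR and CIs are on the original (untransformed) response scale.
    """
    fam = FAMILIES.get(family)
    if fam is None:
        raise ValueError(f"unknown family {family!r}; choose from {sorted(FAMILIES)}")
    mask = np.isfinite(curve.values)
    A, S = curve.areas[mask], curve.values[mask]
    n = len(A)
    if n < fam.n_params + 1:
        raise ValueError(
            f"{family} needs at least {fam.n_params + 1} points, got {n}"
        )
    if (A <= 0).any():
        raise ValueError("areas must be positive")
    digest = curve.digest()

    if np.ptp(S) == 0:
        return _flat_fit(fam, A, S, digest, log_base)

    if fam.linear_in_log:
        X = _design_matrix(family, A, log_base)
        params, *_ = np.linalg.lstsq(X, S, rcond=None)
        resid = S - X @ params
        ssr = float(resid @ resid)
        ci = _ci_halfwidths(X, ssr, n, fam.n_params)
        return ModelFit(family, params, ci, ssr, True, n, digest, log_base)

    best = None
    for x0 in _initial_guesses(family, A, S, log_base):
        def residuals(p):
            with np.errstate(over="ignore", invalid="ignore"):
                pred = family_predict(family, p, A, log_base)
            return np.where(np.isfinite(pred), pred - S, 1e6)

        try:
            sol = optimize.least_squares(
                residuals, x0=np.asarray(x0, float), method="lm",
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=5000,
            )
        except Exception:
            continue
        ssr = float(sol.fun @ sol.fun)
        if best is None or ssr < best[0]:
            best = (ssr, sol)
    if best is None:
        raise FitConvergenceError(f"{family}: all starts failed on curve {digest[:8]}")
    ssr, sol = best
    ci = _ci_halfwidths(sol.jac, ssr, n, fam.n_params)
    fit = ModelFit(
        family, sol.x, ci, ssr, bool(sol.success), n, digest, log_base,
        message=sol.message,
    )
    if not sol.success:
        raise FitConvergenceError(f"{family}: no convergence ({sol.message})", best=fit)
    return fit


def _flat_fit(fam: _Family, A, S, digest, log_base) -> ModelFit:
    """Degenerate all-equal curve: exact flat representation where possible."""
    s = float(S[0])
    flat = {
        "power_multiplicative": (s, 0.0),
        "power_additive": (s - 1.0, 0.0),
        "exponential": (0.0, s),
        "parabolic": (0.0, 0.0, s),
        "linear": (0.0, s),
    }
    if fam.name not in flat:
        raise ValueError(
            f"curve is constant; the {fam.name} family cannot represent a flat curve"
        )
    warnings.warn(f"curve is constant: returning flat {fam.name} fit with zero variance")
    p = np.asarray(flat[fam.name], float)
    return ModelFit(fam.name, p, np.zeros(fam.n_params), 0.0, True, len(A), digest, log_base)


def compare_models(fits: Sequence[ModelFit]) -> list[ModelFit]:
    """Rank fits of one curve by ascending SSR; ties favour fewer parameters."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    digests = {f.curve_digest for f in fits}
    if len(digests) > 1:
        raise ValueError("fits come from different curves")
    return sorted(fits, key=lambda f: (f.ssr, FAMILIES[f.family].n_params, f.family))


def curves_differ(fit1: ModelFit, fit2: ModelFit) -> dict[str, bool]:
    """Per-parameter verdicts: True where the 95% CIs do not overlap."""
    if fit1.family != fit2.family:
        raise ValueError(f"family mismatch: {fit1.family} vs {fit2.family}")
    out = {}
    for name, e1, c1, e2, c2 in zip(
        fit1.param_names, fit1.params, fit1.ci_halfwidths, fit2.params, fit2.ci_halfwidths
    ):
        out[name] = bool(e1 + c1 < e2 - c2 or e2 + c2 < e1 - c1)
    return out


# ---------------------------------------------------------------------------
# curves
# ---------------------------------------------------------------------------

def empirical_curve(
    datasets: Sequence[SurveyDataset],
    metric: str = "richness",
    ks: Sequence[int] | None = None,
    mode: str = "tiling",
) -> SARCurve:
    """Observed diversity-area curve, averaged over subplots at each area.

    For each window side k the metric is averaged over all windows within a
    subplot (undefined windows skipped), then the subplot means are averaged.
    """
    datasets = list(datasets)
    if not datasets:
        raise ValueError("need at least one dataset")
    rows, cols = datasets[0].grid_shape
    if ks is None:
        ks = list(range(1, min(rows, cols) + 1))
    ks = sorted(set(int(k) for k in ks))
    if not ks:
        raise ValueError("empty window-size list")
    q = datasets[0].quadrat_size
    areas, values = [], []
    for k in ks:
        def subplot_value(d, _k=k):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                return np.nanmean(diversity_surface(d, _k, metric, mode).values)

        values.append(subplot_mean(datasets, subplot_value))
        areas.append((k * q) ** 2)
    return SARCurve(
        metric=metric,
        areas=np.asarray(areas),
        values=np.asarray(values),
        treatment=datasets[0].treatment,
        n_subplots=len(datasets),
        window_mode=mode,
    )


def expected_sar_coleman(
    datasets: SurveyDataset | Sequence[SurveyDataset],
    ks: Sequence[int] | None = None,
) -> SARCurve:
    """Closed-form expected richness under random placement of individuals.

    For a subarea fraction a/A_total, E[S] = sum_i (1 - (1 - a/A_total)**N_i)
    with N_i the whole-subplot total of species i.  Evaluated at the same
    areas as the observed curve; subplot expectations are averaged.
    """
    if isinstance(datasets, SurveyDataset):
        datasets = [datasets]
    datasets = list(datasets)
    rows, cols = datasets[0].grid_shape
    if ks is None:
        ks = list(range(1, min(rows, cols) + 1))
    ks = sorted(set(int(k) for k in ks))
    q = datasets[0].quadrat_size
    n_quadrats = rows * cols
    fracs = np.array([k * k / n_quadrats for k in ks])
    if (fracs > 1 + 1e-12).any():
        raise ValueError("window area exceeds total subplot area")

    def subplot_expectation(d):
        totals = d.abundance.to_numpy().sum(axis=0)
        if totals.sum() == 0:
            raise ValueError("total abundance must be positive")
        totals = totals[totals > 0]
        return np.array(
            [np.sum(1.0 - (1.0 - f) ** totals) for f in np.minimum(fracs, 1.0)]
        )

    values = subplot_mean(datasets, subplot_expectation)
    areas = np.array([(k * q) ** 2 for k in ks])
    return SARCurve(
        metric="richness",
        areas=areas,
        values=np.atleast_1d(values),
        treatment=datasets[0].treatment,
        n_subplots=len(datasets),
    )


@dataclass
class NullSAR:
    """Randomisation null model: mean curve with a 95% envelope."""

    curve: SARCurve  # mean over replicates
    lower: np.ndarray  # 2.5% quantile per area
    upper: np.ndarray  # 97.5% quantile per area
    n_reps: int
    seed: int
    rep_sd: np.ndarray = field(default=None)  # sd of per-rep values per area


def randomization_sar(
    datasets: SurveyDataset | Sequence[SurveyDataset],
    ks: Sequence[int] | None = None,
    n_reps: int = 999,
    seed: int = 0,
    metric: str = "richness",
) -> NullSAR:
    """Monte Carlo random placement: individuals dropped uniformly over quadrats.

    Each replicate redistributes every species' whole-subplot total over the
    grid (multinomial with equal cell probabilities), recomputes the tiling
    diversity-area curve, and the replicate curves are summarised by their
    mean and 2.5/97.5% quantiles.
    """
    if isinstance(datasets, SurveyDataset):
        datasets = [datasets]
    datasets = list(datasets)
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows, cols = datasets[0].grid_shape
    if ks is None:
        ks = list(range(1, min(rows, cols) + 1))
    ks = sorted(set(int(k) for k in ks))
    q = datasets[0].quadrat_size
    n_cells = rows * cols
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5A5A]))

    totals_per_ds = [d.abundance.to_numpy().sum(axis=0) for d in datasets]
    rep_curves = np.empty((n_reps, len(ks)))
    from .diversity import metric_value  # local import avoids cycle at module load

    for rep in range(n_reps):
        per_ds = np.empty((len(datasets), len(ks)))
        for di, totals in enumerate(totals_per_ds):
            counts = np.zeros((n_cells, len(totals)), dtype=np.int64)
            p = np.full(n_cells, 1.0 / n_cells)
            for j, N in enumerate(totals):
                if N > 0:
                    counts[:, j] = rng.multinomial(int(N), p)
            grid = counts.reshape(rows, cols, -1)
            for ki, k in enumerate(ks):
                nr, nc = rows // k, cols // k
                pooled = (
                    grid[: nr * k, : nc * k]
                    .reshape(nr, k, nc, k, -1)
                    .sum(axis=(1, 3))
                    .reshape(nr * nc, -1)
                )
                area = (k * q) ** 2
                vals = np.array([metric_value(metric, row, area) for row in pooled])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    per_ds[di, ki] = np.nanmean(vals)
        rep_curves[rep] = per_ds.mean(axis=0)

    areas = np.array([(k * q) ** 2 for k in ks])
    mean_curve = SARCurve(
        metric=metric,
        areas=areas,
        values=rep_curves.mean(axis=0),
        treatment=datasets[0].treatment,
        n_subplots=len(datasets),
    )
    return NullSAR(
        curve=mean_curve,
        lower=np.quantile(rep_curves, 0.025, axis=0),
        upper=np.quantile(rep_curves, 0.975, axis=0),
        n_reps=n_reps,
        seed=seed,
        rep_sd=rep_curves.std(axis=0, ddof=1) if n_reps > 1 else np.zeros(len(ks)),
    )
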