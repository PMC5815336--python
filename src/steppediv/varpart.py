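"""Environmental/spatial variance partitioning of diversity variables.

The response (a univariate diversity variable, or a Hellinger-transformed
community matrix) is regressed on two predictor sets — standardised
environmental variables and PCNM spatial eigenvectors — and the explained
variation is split on the adjusted-R^2 scale into

    [a] pure environment      = adjR2(env+space) - adjR2(space)
    [b] spatially structured environment
    [c] pure space            = adjR2(env+space) - adjR2(env)
    [d] residual              = 1 - adjR2(env+space)

Predictors enter via forward selection with double stopping: a global
permutation pre-test of the full candidate set, then stepwise inclusion
halted when the best candidate's permutation p-value exceeds alpha or the
cumulative adjusted R^2 exceeds the full model's.  Significance of [a] and
[c] uses residual permutation under the reduced (partial) model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def hellinger_transform(X) -> np.ndarray:
    """Row-wise square root of relative abundance: sqrt(x_ij / rowsum_i)."""
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValueError("abundance matrix must be non-negative")
    totals = X.sum(axis=1)
    if (totals == 0).all():
        raise ValueError("at least one row must have positive total")
    if (totals == 0).any():
        warnings.warn(f"{int((totals == 0).sum())} all-zero row(s) left as zeros")
    out = np.zeros_like(X)
    pos = totals > 0
    out[pos] = np.sqrt(X[pos] / totals[pos, None])
    return out


def standardize(X, columns=None):
    """Column z-scores (mean 0, sample SD 1); constant columns are dropped.

    Accepts an array or DataFrame; returns the same kind.  Returns the kept
    column labels alongside when a DataFrame is passed.
    """
    if isinstance(X, pd.DataFrame):
        arr, cols = X.to_numpy(dtype=float), list(X.columns)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        cols = columns or list(range(arr.shape[1]))
    sd = arr.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(cols, keep) if not k]
        warnings.warn(f"dropping zero-variance column(s): {dropped}")
    z = (arr[:, keep] - arr[:, keep].mean(axis=0)) / sd[keep]
    kept = [c for c, k in zip(cols, keep) if k]
    if isinstance(X, pd.DataFrame):
        return pd.DataFrame(z, index=X.index, columns=kept)
    return z


def drop_collinear(env: pd.DataFrame, threshold: float = 0.8) -> pd.DataFrame:
    """Greedy removal of highly correlated environmental variables.

    While any pair has |Pearson r| > threshold, drop the member of the worst
    pair with the larger mean absolute correlation to everything else.
    """
    cols = list(env.columns)
    while len(cols) > 1:
        corr = env[cols].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= threshold:
            break
        drop = i if corr[i].mean() >= corr[j].mean() else j
        cols.pop(drop)
    return env[cols]


# ---------------------------------------------------------------------------
# PCNM
# ---------------------------------------------------------------------------

@dataclass
class PCNMBasis:
    """Positive-eigenvalue spatial eigenvectors of the truncated distance matrix."""

    truncation: float
    eigenvalues: np.ndarray       # descending, all > 0
    vectors: np.ndarray           # (n, n_axes), unit-norm columns, centred
    coords: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.vectors.shape[1]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.vectors, columns=[f"PCNM{i + 1}" for i in range(self.n_axes)]
        )


def pcnm(coords: np.ndarray, truncation: float | None = None) -> PCNMBasis:
    """Principal coordinates of neighbour matrices from point coordinates.

    Distances beyond the truncation threshold t (default: the longest edge of
    the minimum spanning tree, i.e. the smallest t keeping the graph
    connected) are replaced by 4t; the modified matrix is double-centred
    (Gower) and eigendecomposed; axes with eigenvalue > 1e-10 x the largest
    are retained as spatial predictors, broad-scale waves first.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or len(coords) < 3:
        raise ValueError("need at least 3 points with (x, y) coordinates")
    D = squareform(pdist(coords))
    if truncation is None:
        off = D[np.triu_indices_from(D, k=1)]
        if (off == 0).any():
            raise ValueError("coincident points: minimum spanning tree degenerate")
        mst = minimum_spanning_tree(D)
        truncation = float(mst.data.max())
    Dt = np.where(D > truncation, 4.0 * truncation, D)
    np.fill_diagonal(Dt, 0.0)
    G = -0.5 * Dt**2
    n = len(G)
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ G @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > 1e-10 * eigval[0]
    return PCNMBasis(
        truncation=truncation,
        eigenvalues=eigval[keep],
        vectors=eigvec[:, keep],
        coords=coords,
    )


def morans_i(values: np.ndarray, coords: np.ndarray, threshold: float) -> float:
    """Moran's I with binary connectivity (pairs within ``threshold``)."""
    x = np.asarray(values, float)
    x = x - x.mean()
    D = squareform(pdist(np.asarray(coords, float)))
    W = ((D > 0) & (D <= threshold)).astype(float)
    s0 = W.sum()
    if s0 == 0:
        raise ValueError("no neighbour pairs within threshold")
    return float(len(x) / s0 * (x @ W @ x) / (x @ x))


# ---------------------------------------------------------------------------
# RDA machinery
# ---------------------------------------------------------------------------

def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel adjustment: 1 - (1 - R^2)(n - 1)/(n - m - 1)."""
    if n - m - 1 <= 0:
        raise ValueError(f"too few observations (n={n}) for {m} predictors")
    if m == 0:
        return float(r2)
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def _as_matrix(M) -> np.ndarray:
    A = np.asarray(M, dtype=float)
    return A[:, None] if A.ndim == 1 else A


def _orthonormal_basis(X: np.ndarray, warn: bool = True) -> np.ndarray:
    """Orthonormal basis of the centred column space; drops collinear columns."""
    Xc = X - X.mean(axis=0)
    Q, R = np.linalg.qr(Xc, mode="reduced")
    diag = np.abs(np.diag(R))
    tol = max(Xc.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    keep = diag > max(tol, 1e-12)
    if not keep.all():
        if warn:
            warnings.warn(
                f"dropping {int((~keep).sum())} collinear predictor column(s)"
            )
        # re-orthonormalise the independent subset
        Q2, R2 = np.linalg.qr(Xc[:, keep], mode="reduced")
        return Q2
    return Q


def rda_r2(response, predictors) -> float:
    """Redundancy-analysis R^2: share of total response variance explained.

    The column-centred response is projected onto the span of the (centred)
    predictors; R^2 = trace(explained SS) / trace(total SS).  For a single
    response column this is the ordinary multiple-regression R^2.
    """
    Y = _as_matrix(response)
    X = _as_matrix(predictors)
    if X.shape[1] == 0:
        return 0.0
    n = len(Y)
    if X.shape[0] != n:
        raise ValueError("response and predictors disagree on n")
    Yc = Y - Y.mean(axis=0)
    sstot = float(np.sum(Yc**2))
    if sstot == 0:
        return 0.0
    Q = _orthonormal_basis(X)
    if n <= Q.shape[1] + 1:
        raise ValueError(f"n={n} too small for {Q.shape[1]} independent predictors")
    proj = Q @ (Q.T @ Yc)
    return float(np.sum(proj**2)) / sstot


def _r2_and_rank(Y, X) -> tuple[float, int]:
    X = _as_matrix(X)
    if X.shape[1] == 0:
        return 0.0, 0
    Q = _orthonormal_basis(X, warn=False)
    Yc = Y - Y.mean(axis=0)
    sstot = float(np.sum(Yc**2))
    if sstot == 0:
        return 0.0, Q.shape[1]
    proj = Q.T @ Yc
    return float(np.sum(proj**2)) / sstot, Q.shape[1]


# ---------------------------------------------------------------------------
# forward selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionStep:
    name: str
    index: int
    added_r2: float
    cum_r2: float
    cum_adj_r2: float
    f_statistic: float
    p_value: float


@dataclass
class SelectionResult:
    steps: list[SelectionStep]
    global_r2: float
    global_adj_r2: float
    global_p: float | None
    stopped_by: str
    n_perm: int
    seed: int

    @property
    def selected(self) -> list[int]:
        return [s.index for s in self.steps]

    @property
    def selected_names(self) -> list[str]:
        return [s.name for s in self.steps]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variable": s.name,
                    "added_r2": s.added_r2,
                    "cum_r2": s.cum_r2,
                    "cum_adj_r2": s.cum_adj_r2,
                    "F": s.f_statistic,
                    "p": s.p_value,
                }
                for s in self.steps
            ]
        )


def _partial_f(r2_full: float, r2_reduced: float, n: int, m_full: int) -> float:
    denom = (1.0 - r2_full) / (n - m_full - 1)
    if denom <= 0:
        return np.inf
    return (r2_full - r2_reduced) / denom


def forward_select(
    response,
    candidates,
    names: list[str] | None = None,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
    global_adjr2: float | None = None,
    global_test: bool = True,
) -> SelectionResult:
    """Forward selection of predictors with permutation tests and double stopping.

    First a global permutation test of the full candidate model is run; if it
    is not significant at ``alpha`` nothing is selected (this is what keeps
    the procedure's type-I error near ``alpha`` despite testing many
    candidates).  Then candidates are added greedily by added R^2 (ties: the
    lowest column index); each addition is tested by permuting the residuals
    of the current model (Freedman-Lane style conditioning); selection stops
    when p > alpha or the cumulative adjusted R^2 exceeds the full model's
    adjusted R^2 (``global_adjr2`` if supplied).
    """
    Y = _as_matrix(response).astype(float)
    X = _as_matrix(candidates).astype(float)
    n, k = X.shape
    if k == 0:
        raise ValueError("need at least one candidate predictor")
    if names is None:
        names = (
            list(candidates.columns)
            if isinstance(candidates, pd.DataFrame)
            else [f"x{i}" for i in range(k)]
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF5E1]))
    Yc = Y - Y.mean(axis=0)
    sstot = float(np.sum(Yc**2))
    if sstot == 0:
        raise ValueError("response has zero variance")

    g_r2, g_rank = _r2_and_rank(Y, X)
    g_adj = adjusted_r2(g_r2, n, g_rank)
    if global_adjr2 is None:
        global_adjr2 = g_adj

    global_p = None
    if global_test:
        Qg = _orthonormal_basis(X, warn=False)
        f_obs = _partial_f(g_r2, 0.0, n, g_rank) / g_rank
        exceed = 0
        for _ in range(n_perm):
            yp = Yc[rng.permutation(n)]
            r2p = float(np.sum((Qg.T @ yp) ** 2)) / sstot
            fp = _partial_f(r2p, 0.0, n, g_rank) / g_rank
            if fp >= f_obs:
                exceed += 1
        global_p = (exceed + 1) / (n_perm + 1)
        if global_p > alpha:
            return SelectionResult([], g_r2, g_adj, global_p, "global test", n_perm, seed)

    steps: list[SelectionStep] = []
    selected: list[int] = []
    stopped_by = "exhausted candidates"
    while len(selected) < k:
        Qs = (
            _orthonormal_basis(X[:, selected], warn=False)
            if selected
            else np.empty((n, 0))
        )
        r2_sel = float(np.sum((Qs.T @ Yc) ** 2)) / sstot
        # residuals of candidates and response under the current model
        Yres = Yc - Qs @ (Qs.T @ Yc)
        best_j, best_add = -1, -np.inf
        for j in range(k):
            if j in selected:
                continue
            r2j, _ = _r2_and_rank(Y, X[:, selected + [j]])
            add = r2j - r2_sel
            if add > best_add + 1e-14:
                best_add, best_j = add, j
        if best_j < 0 or best_add <= 0:
            stopped_by = "no candidate adds variance"
            break
        m_full = len(selected) + 1
        r2_full = r2_sel + best_add
        f_obs = _partial_f(r2_full, r2_sel, n, m_full)
        # candidate residualised on selected, as an orthonormal direction
        xj = X[:, [best_j]] - X[:, [best_j]].mean(axis=0)
        xj_res = xj - Qs @ (Qs.T @ xj)
        norm = np.linalg.norm(xj_res)
        if norm < 1e-12:
            stopped_by = "remaining candidates collinear with selection"
            break
        u = xj_res / norm
        ss_res = float(np.sum(Yres**2))
        exceed = 0
        for _ in range(n_perm):
            yp = Yres[rng.permutation(n)]
            add_p = float(np.sum((u.T @ yp) ** 2)) / sstot
            denom = (ss_res / sstot - add_p) / (n - m_full - 1)
            fp = np.inf if denom <= 0 else add_p / denom
            if fp >= f_obs - 1e-12:
                exceed += 1
        p = (exceed + 1) / (n_perm + 1)
        if p > alpha:
            stopped_by = "alpha"
            break
        adj = adjusted_r2(r2_full, n, m_full)
        if adj > global_adjr2 + 1e-12:
            stopped_by = "global adjusted R2"
            break
        selected.append(best_j)
        steps.append(
            SelectionStep(
                name=names[best_j], index=best_j, added_r2=best_add,
                cum_r2=r2_full, cum_adj_r2=adj, f_statistic=f_obs, p_value=p,
            )
        )
    return SelectionResult(steps, g_r2, g_adj, global_p, stopped_by, n_perm, seed)


# ---------------------------------------------------------------------------
# partition
# ---------------------------------------------------------------------------

@dataclass
class Partition:
    """Adjusted-R^2 fractions of explained variation and their tests."""

    a: float                  # pure environment
    b: float                  # spatially structured environment
    c: float                  # pure space
    d: float                  # residual
    p_a: float | None
    p_c: float | None
    p_total: float | None
    env_selected: list[str] = field(default_factory=list)
    pcnm_selected: list[str] = field(default_factory=list)
    n_perm: int = 0
    seed: int = 0

    def percentages(self, floor: bool = False) -> dict[str, float]:
        """Fractions as percentages of total variance (raw sum to exactly 100)."""
        vals = {"a": self.a, "b": self.b, "c": self.c, "d": self.d}
        if floor:
            vals = {k: max(v, 0.0) for k, v in vals.items()}
        return {k: 100.0 * v for k, v in vals.items()}


def _partial_permutation_p(
    Y, X_test, X_cond, f_obs, n_perm, rng
) -> float:
    """Permutation p for the partial effect of X_test given X_cond.

    Residuals of the response under the reduced model (X_cond only) are
    permuted and the partial F recomputed each time.
    """
    Y = _as_matrix(Y)
    n = len(Y)
    Yc = Y - Y.mean(axis=0)
    sstot = float(np.sum(Yc**2))
    Qc = _orthonormal_basis(X_cond, warn=False) if _as_matrix(X_cond).shape[1] else np.empty((n, 0))
    fit_red = Qc @ (Qc.T @ Yc)
    res_red = Yc - fit_red
    Xfull = np.hstack([_as_matrix(X_cond), _as_matrix(X_test)]) if _as_matrix(X_cond).shape[1] else _as_matrix(X_test)
    Qf = _orthonormal_basis(Xfull, warn=False)
    m_full, m_red = Qf.shape[1], Qc.shape[1]
    df_num = max(m_full - m_red, 1)
    exceed = 0
    for _ in range(n_perm):
        yp = fit_red + res_red[rng.permutation(n)]
        ypc = yp - yp.mean(axis=0)
        sstot_p = float(np.sum(ypc**2))
        r2f = float(np.sum((Qf.T @ ypc) ** 2)) / sstot_p
        r2r = float(np.sum((Qc.T @ ypc) ** 2)) / sstot_p
        denom = (1.0 - r2f) / (n - m_full - 1)
        fp = np.inf if denom <= 0 else ((r2f - r2r) / df_num) / denom
        if fp >= f_obs - 1e-12:
            exceed += 1
    return (exceed + 1) / (n_perm + 1)


def partition(
    response,
    env_selected,
    pcnm_selected,
    n_perm: int = 999,
    seed: int = 0,
    env_names: list[str] | None = None,
    pcnm_names: list[str] | None = None,
) -> Partition:
    """Partition response variation between environment and space.

    ``env_selected`` / ``pcnm_selected`` are the predictor matrices retained
    by forward selection (either may be empty).  Fractions are computed on the
    adjusted-R^2 scale; [a] and [c] are tested by residual permutation under
    the partial model, [a+b+c] by raw permutation of the response.
    """
    Y = _as_matrix(response).astype(float)
    n = len(Y)
    Xe = _as_matrix(env_selected).astype(float) if env_selected is not None else np.empty((n, 0))
    Xs = _as_matrix(pcnm_selected).astype(float) if pcnm_selected is not None else np.empty((n, 0))
    me, ms = Xe.shape[1], Xs.shape[1]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xAB0DE]))

    if me + ms >= n - 1:
        raise ValueError(f"n={n} too small for {me + ms} combined predictors")

    r2_e, rank_e = _r2_and_rank(Y, Xe)
    r2_s, rank_s = _r2_and_rank(Y, Xs)
    both = np.hstack([Xe, Xs]) if me + ms else np.empty((n, 0))
    r2_es, rank_es = _r2_and_rank(Y, both)

    ab = adjusted_r2(r2_e, n, rank_e) if rank_e else 0.0
    bc = adjusted_r2(r2_s, n, rank_s) if rank_s else 0.0
    abc = adjusted_r2(r2_es, n, rank_es) if rank_es else 0.0
    a = abc - bc
    c = abc - ab
    b = ab + bc - abc
    d = 1.0 - abc

    p_a = p_c = p_total = None
    if me and ms:
        f_a = ((r2_es - r2_s) / max(rank_es - rank_s, 1)) / ((1 - r2_es) / (n - rank_es - 1))
        p_a = _partial_permutation_p(Y, Xe, Xs, f_a, n_perm, rng)
        f_c = ((r2_es - r2_e) / max(rank_es - rank_e, 1)) / ((1 - r2_es) / (n - rank_es - 1))
        p_c = _partial_permutation_p(Y, Xs, Xe, f_c, n_perm, rng)
    elif me:
        f_a = (r2_e / rank_e) / ((1 - r2_e) / (n - rank_e - 1))
        p_a = _partial_permutation_p(Y, Xe, np.empty((n, 0)), f_a, n_perm, rng)
    elif ms:
        f_c = (r2_s / rank_s) / ((1 - r2_s) / (n - rank_s - 1))
        p_c = _partial_permutation_p(Y, Xs, np.empty((n, 0)), f_c, n_perm, rng)
    if rank_es:
        f_t = (r2_es / rank_es) / ((1 - r2_es) / (n - rank_es - 1))
        p_total = _partial_permutation_p(Y, both, np.empty((n, 0)), f_t, n_perm, rng)

    def _names(given, X, prefix):
        if given is not None:
            return list(given)
        if isinstance(X, pd.DataFrame):
            return list(X.columns)
        return [f"{prefix}{i}" for i in range(X.shape[1] if hasattr(X, "shape") else 0)]

    return Partition(
        a=a, b=b, c=c, d=d, p_a=p_a, p_c=p_c, p_total=p_total,
        env_selected=_names(env_names, env_selected, "env"),
        pcnm_selected=_names(pcnm_names, pcnm_selected, "PCNM"),
        n_perm=n_perm, seed=seed,
    )
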