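"""Model fitting engine: OLS, additive hinge-spline (MARS) regression,
k-fold cross-validation, Pearson correlation testing, and BIC.

The MARS implementation is additive (degree 1): the fitted function is
``c0 + Σ_t coef_t · B_t(x_col(t))`` where every basis function is a hinge
``max(0, x − c)`` or ``max(0, c − x)``.  The forward pass greedily adds
reflected hinge pairs at observed-value knots; the backward pass prunes
terms by generalized cross-validation,

    GCV(m) = (RSS/n) / (1 − C(m)/n)²,   C(m) = m + penalty·(m−1)/2,

with m the number of model terms including the intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "LinearFit",
    "MarsTerm",
    "MarsFit",
    "CVResult",
    "ConstantInputError",
    "fit_ols",
    "fit_mars",
    "predict",
    "make_folds",
    "kfold_cv",
    "pearson_with_pvalue",
    "bic_linear",
]


class ConstantInputError(ValueError):
    """A correlation was requested against a constant vector."""


@dataclass
class LinearFit:
    intercept: float
    coef: np.ndarray  # one weight per predictor column
    columns: list[str] | None = None
    n_obs: int = 0
    rss: float = np.nan

    @property
    def weights(self) -> dict[str, float]:
        cols = self.columns or [f"x{i}" for i in range(len(self.coef))]
        return dict(zip(cols, map(float, self.coef)))


@dataclass(frozen=True)
class MarsTerm:
    column: int  # predictor column index
    direction: int  # +1: max(0, x − knot); −1: max(0, knot − x)
    knot: float
    coef: float = 0.0

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        if self.direction > 0:
            return np.maximum(0.0, x - self.knot)
        return np.maximum(0.0, self.knot - x)


@dataclass
class MarsFit:
    intercept: float
    terms: list[MarsTerm]
    gcv: float = np.nan
    n_obs: int = 0
    rss: float = np.nan
    columns: list[str] | None = None

    def term_counts(self) -> dict[int, int]:
        """Number of surviving hinge terms per predictor column."""
        counts: dict[int, int] = {}
        for t in self.terms:
            counts[t.column] = counts.get(t.column, 0) + 1
        return counts


@dataclass
class CVResult:
    target: str
    predictions: np.ndarray
    measured: np.ndarray
    pearson_r: float
    p_value: float
    fold_assignment: np.ndarray
    seed: int | None = None


# ---------------------------------------------------------------------------
# ordinary least squares


def fit_ols(
    X: np.ndarray,
    y: np.ndarray,
    columns: list[str] | None = None,
    ridge: float = 0.0,
) -> LinearFit:
    """Least-squares fit of y on X with an intercept.

    Rank-deficient designs are solved by the minimum-norm pseudoinverse
    solution (with a warning); ``ridge`` adds an optional small L2
    stabiliser on the slopes.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n == 0 or y.size != n:
        raise ValueError("empty design or length mismatch")
    A = np.hstack([np.ones((n, 1)), X])
    if ridge > 0:
        At = np.vstack([A, np.sqrt(ridge) * np.eye(p + 1)[1:]])
        yt = np.concatenate([y, np.zeros(p)])
        beta, _, rank, _ = np.linalg.lstsq(At, yt, rcond=None)
    else:
        beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < min(n, p + 1):
        warnings.warn("rank-deficient design; minimum-norm solution returned")
    resid = y - A @ beta
    return LinearFit(
        intercept=float(beta[0]), coef=beta[1:], columns=columns,
        n_obs=n, rss=float(resid @ resid),
    )


def predict(fit, X: np.ndarray) -> np.ndarray:
    """Evaluate a LinearFit or MarsFit on new rows."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if isinstance(fit, LinearFit):
        if X.shape[1] != len(fit.coef):
            raise ValueError(
                f"X has {X.shape[1]} columns, fit expects {len(fit.coef)}"
            )
        return fit.intercept + X @ fit.coef
    if isinstance(fit, MarsFit):
        needed = max((t.column for t in fit.terms), default=-1)
        if X.shape[1] <= needed:
            raise ValueError(f"X has {X.shape[1]} columns, fit uses column {needed}")
        out = np.full(X.shape[0], fit.intercept, dtype=np.float64)
        for t in fit.terms:
            out += t.coef * t.evaluate(X[:, t.column])
        return out
    raise TypeError(f"cannot predict from {type(fit).__name__}")


# ---------------------------------------------------------------------------
# MARS


def _candidate_knots(x: np.ndarray, max_knots: int) -> np.ndarray:
    u = np.unique(x)
    if u.size <= max_knots:
        return u
    idx = np.unique(np.linspace(0, u.size - 1, max_knots).round().astype(int))
    return u[idx]


def _gcv(rss: float, n: int, m: int, penalty: float) -> float:
    c = m + penalty * (m - 1) / 2.0
    if c >= n:
        return np.inf
    return (rss / n) / (1.0 - c / n) ** 2


def fit_mars(
    X: np.ndarray,
    y: np.ndarray,
    max_terms: int | None = None,
    gcv_penalty: float = 2.0,
    max_knots: int = 256,
    forward_thresh: float = 1e-4,
    columns: list[str] | None = None,
) -> MarsFit:
    """Additive MARS: greedy forward hinge-pair selection, GCV backward prune.

    Knot candidates are observed predictor values (all unique values, or a
    quantile-spaced subset of them when a column has more than ``max_knots``
    distinct values).  Ties in the forward-pass RSS reduction break to the
    lowest (column index, knot value).  Coefficients are refit by OLS on the
    surviving basis.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if y.size != n or n == 0:
        raise ValueError("empty design or length mismatch")
    if max_terms is None:
        max_terms = min(200, max(20, 2 * p))
    if max_terms < 1:
        raise ValueError("max_terms must be >= 1")

    mean_y = float(np.mean(y))
    y_res = y - mean_y
    rss = float(y_res @ y_res)
    rss0 = rss
    if n < 4 or rss0 <= 0:
        return MarsFit(intercept=mean_y, terms=[], gcv=_gcv(rss, n, 1, gcv_penalty),
                       n_obs=n, rss=rss, columns=columns)

    knots = [_candidate_knots(X[:, c], max_knots) for c in range(p)]
    # residualized hinge-plus matrices and predictor columns, kept orthogonal
    # to the span of the accepted basis (updated incrementally per round)
    ones_res_removed = np.full(n, 1.0 / np.sqrt(n))
    H_res = []
    x_res = []
    for c in range(p):
        H = np.maximum(0.0, X[:, c][:, None] - knots[c][None, :])
        H -= ones_res_removed[:, None] * (ones_res_removed @ H)
        H_res.append(H)
        xr = X[:, c] - np.mean(X[:, c])
        x_res.append(xr)

    terms: list[MarsTerm] = []
    q_vectors = []  # orthonormal directions beyond the intercept
    eps = 1e-10

    def _orthonormalize(v: np.ndarray) -> np.ndarray | None:
        v = v - np.mean(v)
        for q in q_vectors:
            v = v - q * (q @ v)
        norm = np.linalg.norm(v)
        if norm < np.sqrt(eps) * np.sqrt(n):
            return None
        return v / norm

    while len(terms) < max_terms:
        best = None  # (reduction, col, knot_idx)
        for c in range(p):
            A = H_res[c]
            xr = x_res[c]
            b1 = y_res @ A
            g11 = np.einsum("ij,ij->j", A, A)
            cross = xr @ A
            xx = float(xr @ xr)
            b2 = b1 - float(xr @ y_res)
            g12 = g11 - cross
            g22 = g11 - 2.0 * cross + xx
            det = g11 * g22 - g12 * g12
            scale = np.maximum(g11 * g22, eps)
            ok = det > eps * scale
            with np.errstate(divide="ignore", invalid="ignore"):
                pair = (g22 * b1**2 - 2.0 * g12 * b1 * b2 + g11 * b2**2) / det
                sp = np.where(g11 > eps, b1**2 / np.maximum(g11, eps), 0.0)
                sm = np.where(g22 > eps, b2**2 / np.maximum(g22, eps), 0.0)
            red = np.where(ok, pair, np.maximum(sp, sm))
            red = np.nan_to_num(red, nan=0.0, posinf=0.0, neginf=0.0)
            j = int(np.argmax(red))  # first max -> lowest knot (knots sorted)
            if best is None or red[j] > best[0] + eps:
                best = (float(red[j]), c, j)
        if best is None or best[0] <= forward_thresh * rss0:
            break
        _, c, j = best
        knot = float(knots[c][j])
        terms.append(MarsTerm(column=c, direction=+1, knot=knot))
        terms.append(MarsTerm(column=c, direction=-1, knot=knot))
        for t in terms[-2:]:
            q = _orthonormalize(t.evaluate(X[:, t.column]))
            if q is None:
                continue
            q_vectors.append(q)
            y_res = y_res - q * (q @ y_res)
            for cc in range(p):
                H_res[cc] -= q[:, None] * (q @ H_res[cc])
                x_res[cc] = x_res[cc] - q * (q @ x_res[cc])
        rss = float(y_res @ y_res)
        if rss <= eps * rss0:
            break

    # backward pass: exhaustive single-term removals on the exact OLS RSS
    B = np.ones((n, 1 + len(terms)))
    for i, t in enumerate(terms):
        B[:, 1 + i] = t.evaluate(X[:, t.column])
    G = B.T @ B
    cvec = B.T @ y
    yy = float(y @ y)

    def _subset_rss(idx: np.ndarray) -> float:
        sol, _, _, _ = np.linalg.lstsq(G[np.ix_(idx, idx)], cvec[idx], rcond=None)
        return max(yy - float(cvec[idx] @ sol), 0.0)

    active = np.arange(1 + len(terms))
    rss_full = _subset_rss(active)
    best_subset = active.copy()
    best_gcv = _gcv(rss_full, n, active.size, gcv_penalty)
    while active.size > 1:
        rss_candidates = [
            _subset_rss(np.delete(active, k)) for k in range(1, active.size)
        ]
        k_best = 1 + int(np.argmin(rss_candidates))
        active = np.delete(active, k_best)
        g = _gcv(rss_candidates[k_best - 1], n, active.size, gcv_penalty)
        if g < best_gcv:
            best_gcv, best_subset = g, active.copy()

    keep = [i - 1 for i in best_subset if i > 0]
    Bk = B[:, [0] + [1 + i for i in keep]]
    beta, _, _, _ = np.linalg.lstsq(Bk, y, rcond=None)
    resid = y - Bk @ beta
    final_terms = [
        MarsTerm(terms[i].column, terms[i].direction, terms[i].knot, float(b))
        for i, b in zip(keep, beta[1:])
    ]
    return MarsFit(
        intercept=float(beta[0]), terms=final_terms, gcv=best_gcv,
        n_obs=n, rss=float(resid @ resid), columns=columns,
    )


# ---------------------------------------------------------------------------
# cross-validation and inference


def make_folds(n: int, k: int, seed: int | None) -> np.ndarray:
    """Uniform random fold assignment: shuffled indices cut into k blocks."""
    if k > n:
        raise ValueError(f"k={k} folds exceed n={n} observations")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=np.int64)
    for f, chunk in enumerate(np.array_split(perm, k)):
        folds[chunk] = f
    return folds


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    model: str = "ols",
    seed: int | None = 0,
    folds: np.ndarray | None = None,
    target: str = "",
    **model_kwargs,
) -> CVResult:
    """Out-of-fold predictions and Pearson r/p for OLS or MARS.

    ``folds`` may be supplied to share the assignment across targets.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.ndim == 1:
        X = X[:, None]
    n = y.size
    if folds is None:
        folds = make_folds(n, k, seed)
    preds = np.empty(n, dtype=np.float64)
    for f in np.unique(folds):
        test = folds == f
        train = ~test
        if model == "ols":
            fit = fit_ols(X[train], y[train], **model_kwargs)
        elif model == "mars":
            fit = fit_mars(X[train], y[train], **model_kwargs)
        else:
            raise ValueError(f"unknown model {model!r}")
        preds[test] = predict(fit, X[test])
    r, p = pearson_with_pvalue(y, preds)
    return CVResult(
        target=target, predictions=preds, measured=y, pearson_r=r,
        p_value=p, fold_assignment=folds, seed=seed,
    )


def pearson_with_pvalue(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-test p-value (df = n − 2)."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    n = x.size
    if n != y.size:
        raise ValueError("length mismatch")
    if n < 3:
        raise ValueError("need at least 3 observations")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.linalg.norm(xd)
    sy = np.linalg.norm(yd)
    if sx == 0 or sy == 0:
        raise ConstantInputError("correlation undefined for a constant vector")
    r = float(np.clip(xd @ yd / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return r, p


def bic_linear(fit: LinearFit) -> float:
    """Gaussian-likelihood BIC: n·ln(rss/n) + (p + 2)·ln(n).

    p slopes + intercept + noise variance count as p + 2 parameters.
    """
    n = fit.n_obs
    if fit.rss <= 0:
        warnings.warn("zero RSS; BIC is -inf")
        return -np.inf
    p = len(fit.coef)
    return n * float(np.log(fit.rss / n)) + (p + 2) * float(np.log(n))
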