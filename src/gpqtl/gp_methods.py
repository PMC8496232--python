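"""Penalized whole-genome regression: ridge, LASSO, elastic net, and their
multi-response (multi-task group) counterparts, with cross-validated tuning.

Objective, on the standardized scale (predictor columns centered and scaled
by their population standard deviation, responses centered):

    (1/2n) ||Yc - Z beta||_F^2
        + lambda * ( alpha * P1(beta) + (1 - alpha)/2 * ||beta||_F^2 )

where P1 is the L1 norm for univariate methods and the row-wise group L2
norm sum_j ||beta_j.||_2 for multi-task methods (a predictor is then zero or
nonzero jointly across traits).  alpha = 0 gives ridge, alpha = 1 LASSO /
group LASSO.  lambda is on the per-observation (glmnet-style) scale.

Coefficients are always returned on the original predictor scale with an
unpenalized per-trait intercept.

Solvers: ridge uses the exact kernel closed form
beta = Z^T (Z Z^T + n lambda I)^-1 Yc (cheap for n << p); L1-containing
penalties use cyclic coordinate descent with group soft-thresholding
(numba-compiled; the univariate case is k = 1), warm-started along the
path and accelerated by sequential strong-rule screening with full KKT
verification, so the returned solution satisfies the stationarity
conditions of the objective on all p predictors regardless of screening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from sklearn.model_selection import KFold

UNIVARIATE_METHODS = ("RR", "LASSO", "EN")
MULTIVARIATE_METHODS = ("MTV_RR", "MTV_LASSO", "MTV_EN")
METHODS = UNIVARIATE_METHODS + MULTIVARIATE_METHODS

#: decades spanned below lambda_max by default grids
LAMBDA_DECADES = 4
#: multiplier putting the ridge grid anchor above the L1 lambda_max
RIDGE_ANCHOR = 1e3


@dataclass
class PenalizedFit:
    """A fitted penalized regression at one (alpha, lambda)."""

    method: str
    alpha: float
    lam: float
    intercept: np.ndarray  # (k,)
    beta: np.ndarray  # (p, k), original predictor scale
    tuning_trace: pd.DataFrame | None = None

    @property
    def selected(self) -> np.ndarray:
        """Boolean mask of predictors with a nonzero effect in any trait."""
        return np.any(self.beta != 0.0, axis=1)

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())


class _Standardizer:
    """Center/scale a predictor block; caches ridge kernels for reuse.

    Zero-variance columns are kept in place with scale 1; their standardized
    column is identically zero, so they receive coefficient 0 without
    disturbing the column indexing.
    """

    def __init__(self, X: np.ndarray):
        X = np.asarray(X, dtype=np.float64)
        self.xm = X.mean(axis=0)
        sd = X.std(axis=0)
        self.active = sd > 0
        self.xs = np.where(self.active, sd, 1.0)
        self.Z = (X - self.xm) / self.xs
        self._kernel = None
        self._test_kernels: dict[bytes, np.ndarray] = {}

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    def transform(self, X_new: np.ndarray) -> np.ndarray:
        return (np.asarray(X_new, float) - self.xm) / self.xs

    def center_response(self, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ym = Y.mean(axis=0)
        return Y - ym, ym

    def original_scale(self, beta_std: np.ndarray, ym: np.ndarray):
        beta = beta_std / self.xs[:, None]
        intercept = ym - self.xm @ beta
        return beta, intercept

    def ridge_kernel(self):
        """Eigendecomposition of Z Z^T (computed once, reused across lambdas)."""
        if self._kernel is None:
            K = self.Z @ self.Z.T
            evals, Q = np.linalg.eigh(K)
            self._kernel = (np.maximum(evals, 0.0), Q)
        return self._kernel

    def test_kernel(self, X_new: np.ndarray, key: bytes | None = None):
        """Z_new @ Z^T, optionally cached under ``key``."""
        if key is not None and key in self._test_kernels:
            return self._test_kernels[key]
        Kte = self.transform(X_new) @ self.Z.T
        if key is not None:
            self._test_kernels[key] = Kte
        return Kte


class FoldCache:
    """Memoizes per-training-subset standardizers of one fixed X.

    Nested cross-validation revisits the same training subsets for every
    method, trait and tuning point; standardization and the ridge kernel
    depend only on the subset, so they are shared.
    """

    def __init__(self, X: np.ndarray):
        self.X = np.asarray(X, dtype=np.float64)
        self._stds: dict[bytes, _Standardizer] = {}

    def std(self, idx: np.ndarray) -> _Standardizer:
        key = np.asarray(idx).tobytes()
        if key not in self._stds:
            self._stds[key] = _Standardizer(self.X[idx])
        return self._stds[key]


def _as_2d(Y) -> np.ndarray:
    Y = np.asarray(Y, dtype=np.float64)
    return Y[:, None] if Y.ndim == 1 else Y


def _check_inputs(X, Y, method):
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    X = np.asarray(X, dtype=np.float64)
    Y = _as_2d(Y)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite values in inputs")
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y row counts differ")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    if np.any(Y.std(axis=0) == 0):
        raise ValueError("zero-variance response")
    if method in UNIVARIATE_METHODS and Y.shape[1] != 1:
        raise ValueError(f"{method} is univariate; fit one trait at a time")
    return X, Y


def _alpha_for(method: str, alpha: float | None) -> float:
    if method in ("RR", "MTV_RR"):
        return 0.0
    if method in ("LASSO", "MTV_LASSO"):
        return 1.0
    if alpha is None:
        raise ValueError("EN methods need an explicit alpha")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    return float(alpha)


def lambda_max(Z: np.ndarray, Yc: np.ndarray, alpha: float, multitask: bool) -> float:
    """Smallest lambda with an all-zero solution (L1-containing penalties).

    For alpha = 0 (ridge) no finite lambda zeroes the solution; a fixed
    large anchor above the alpha = 1 value is returned for grid building.
    """
    n = Z.shape[0]
    C = Z.T @ Yc / n  # (p, k)
    norms = np.linalg.norm(C, axis=1) if multitask else np.abs(C[:, 0])
    base = float(norms.max())
    if base == 0.0:
        base = 1e-3
    if alpha == 0.0:
        return base * RIDGE_ANCHOR
    return base / alpha


def lambda_grid(
    Z, Yc, alpha, multitask, count=100, decades=LAMBDA_DECADES
) -> np.ndarray:
    lmax = lambda_max(Z, Yc, alpha, multitask)
    dec = decades if alpha > 0 else decades + 3  # ridge anchor sits far out
    return np.geomspace(lmax, lmax * 10.0 ** (-dec), count)


# ---------------------------------------------------------------------------
# solvers (standardized scale)
# ---------------------------------------------------------------------------

def _ridge_duals(std: _Standardizer, Yc: np.ndarray, lams) -> np.ndarray:
    """Dual ridge solutions (len(lams), n, k); beta = Z^T dual."""
    evals, Q = std.ridge_kernel()
    QtY = Q.T @ Yc
    n = std.n
    return np.stack(
        [Q @ (QtY / (evals + n * lam)[:, None]) for lam in lams]
    )


def _ridge_coefs(std: _Standardizer, Yc: np.ndarray, lams) -> np.ndarray:
    n, p = std.Z.shape
    if p <= n:  # primal form is better conditioned at tiny lambda
        G = std.Z.T @ std.Z
        ZtY = std.Z.T @ Yc
        return np.stack([
            np.linalg.solve(G + n * lam * np.eye(p), ZtY) for lam in lams
        ])
    duals = _ridge_duals(std, Yc, lams)
    return np.einsum("np,lnk->lpk", std.Z, duals, optimize=True)


def _kkt_scores(Z, R, n, multitask) -> np.ndarray:
    C = Z.T @ R / n
    return np.linalg.norm(C, axis=1) if multitask else np.abs(C[:, 0])


@njit(cache=True, fastmath=True)
def _cd_sweep(Z, col_ss, R, beta, l1, l2, idx):
    """One cyclic coordinate-descent sweep over the features in ``idx``.

    Z is (n, q) Fortran-ordered, R the (n, k) residual updated in place,
    beta the (q, k) coefficients; l1 = lam*alpha, l2 = lam*(1-alpha);
    col_ss[j] = Z_j'Z_j / n.  The group update is the soft-thresholded
    ridge solution of each feature's k-vector; k = 1 reduces to the
    ordinary L1 update.  Returns (max coefficient change, max coefficient
    magnitude).
    """
    n, _ = Z.shape
    k = R.shape[1]
    max_delta = 0.0
    max_beta = 0.0
    c = np.empty(k)
    for jj in range(idx.shape[0]):
        j = idx[jj]
        sj = col_ss[j]
        if sj <= 0.0:
            continue
        cnorm2 = 0.0
        for t in range(k):
            acc = 0.0
            for i in range(n):
                acc += Z[i, j] * R[i, t]
            ct = acc / n + sj * beta[j, t]
            c[t] = ct
            cnorm2 += ct * ct
        cnorm = np.sqrt(cnorm2)
        if cnorm <= l1:
            scale = 0.0
        else:
            scale = (1.0 - l1 / cnorm) / (sj + l2)
        for t in range(k):
            new = c[t] * scale
            d = new - beta[j, t]
            if d != 0.0:
                for i in range(n):
                    R[i, t] -= Z[i, j] * d
                ad = abs(d)
                if ad > max_delta:
                    max_delta = ad
                beta[j, t] = new
            ab = abs(new)
            if ab > max_beta:
                max_beta = ab
    return max_delta, max_beta


@njit(cache=True, fastmath=True)
def _cd_solve(Z, col_ss, R, beta, l1, l2, tol, max_iter):
    """Coordinate descent with active-set iterations.

    Alternates full sweeps with sweeps restricted to the active set until
    the largest coefficient update falls below tol * max(1, max|beta|).
    """
    q = Z.shape[1]
    all_idx = np.arange(q)
    it = 0
    while it < max_iter:
        d, m = _cd_sweep(Z, col_ss, R, beta, l1, l2, all_idx)
        it += 1
        if d <= tol * max(1.0, m):
            return it
        active = np.empty(q, dtype=np.int64)
        na = 0
        for j in range(q):
            nz = False
            for t in range(beta.shape[1]):
                if beta[j, t] != 0.0:
                    nz = True
                    break
            if nz:
                active[na] = j
                na += 1
        act = active[:na]
        while it < max_iter:
            d, m = _cd_sweep(Z, col_ss, R, beta, l1, l2, act)
            it += 1
            if d <= tol * max(1.0, m):
                break
    return it


def _cd_fit(Zs, Yc, alpha, lam, multitask, tol, warm=None):
    """One penalized fit on a screened column subset.

    ``warm`` (q, k) seeds the solver with the previous path solution.
    ``multitask`` is implicit in Yc's column count (k = 1 gives the
    univariate L1 update).
    """
    Zf = np.asfortranarray(Zs)
    n, q = Zf.shape
    k = Yc.shape[1]
    beta = np.zeros((q, k)) if warm is None else np.array(warm, dtype=float)
    R = Yc - Zf @ beta
    col_ss = (Zf**2).sum(axis=0) / n
    it = _cd_solve(Zf, col_ss, np.ascontiguousarray(R), beta,
                   lam * alpha, lam * (1.0 - alpha), tol, 5000)
    if it >= 5000:  # pragma: no cover - safety net
        warnings.warn("coordinate descent hit the iteration limit")
    return beta


def _cd_path(
    Z: np.ndarray,
    Yc: np.ndarray,
    alpha: float,
    lams: np.ndarray,
    multitask: bool,
    tol: float = 1e-6,
    max_active: int | None = None,
) -> np.ndarray:
    """Coordinate-descent path with sequential strong rules + KKT checks.

    Returns (len(lams), p, k) standardized-scale coefficients for a
    decreasing ``lams``.  Screening at lambda_t keeps predictors whose
    gradient score at the previous solution exceeds
    alpha * max(2 lambda_t - lambda_{t-1}, lambda_t / 2) plus everything
    ever active; after each fit the stationarity conditions are verified on
    all p predictors and violators are added until none remain, so screening
    never changes the solution.
    """
    if len(lams) == 0:
        raise ValueError("empty lambda grid")
    lams = np.asarray(lams, dtype=float)
    if np.any(np.diff(lams) > 0):
        lams = np.sort(lams)[::-1]
    n, p = Z.shape
    k = Yc.shape[1]
    out = np.zeros((len(lams), p, k))
    scores = _kkt_scores(Z, Yc, n, multitask)  # at beta = 0
    lam_prev = max(float(lams[0]), float(scores.max()) / max(alpha, 1e-12))
    ever_active = np.zeros(p, dtype=bool)
    beta = np.zeros((p, k))
    cand_cap = max(4096, 5 * n)
    for t, lam in enumerate(lams):
        thresh = alpha * max(2.0 * lam - lam_prev, 0.25 * lam)
        cand = ever_active | (scores >= thresh)
        if cand.sum() > cand_cap:
            # keep the strongest candidates; KKT checks restore any misses
            top = np.argpartition(scores, -cand_cap)[-cand_cap:]
            keep = np.zeros(p, dtype=bool)
            keep[top] = True
            cand = ever_active | (keep & cand)
        idx = np.flatnonzero(cand)
        for _ in range(20):
            if idx.size == 0:
                beta = np.zeros((p, k))
                break
            sub = _cd_fit(Z[:, idx], Yc, alpha, lam, multitask, tol,
                          warm=beta[idx])
            beta = np.zeros((p, k))
            beta[idx] = sub
            R = Yc - Z[:, idx] @ sub
            scores = _kkt_scores(Z, R, n, multitask)
            viol = (scores > alpha * lam * (1 + 1e-6) + 1e-12) & ~cand
            if not viol.any():
                break
            cand |= viol
            idx = np.flatnonzero(cand)
        else:  # pragma: no cover - safety net
            warnings.warn("KKT screening did not settle; using last fit")
        out[t] = beta
        n_active = int(np.any(beta != 0.0, axis=1).sum())
        if max_active is not None and n_active > max_active:
            # saturated tail: freeze the remaining (denser) solutions
            out[t + 1:] = beta
            break
        ever_active |= np.any(beta != 0.0, axis=1)
        lam_prev = lam
    return out


def _path_coefs(std: _Standardizer, Yc, method, alpha, lams, tol=1e-6,
                max_active=None):
    """Standardized-scale path for any method; lams decreasing."""
    multitask = method in MULTIVARIATE_METHODS
    a = _alpha_for(method, alpha)
    if a == 0.0:
        return _ridge_coefs(std, Yc, lams)
    return _cd_path(std.Z, Yc, a, np.asarray(lams, float), multitask,
                    tol=tol, max_active=max_active)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def fit_path(
    X,
    Y,
    method: str,
    alpha: float | None = None,
    lambda_grid_values=None,
    tol: float = 1e-7,
) -> list[PenalizedFit]:
    """Fit the penalized objective along a decreasing lambda grid."""
    X, Y = _check_inputs(X, Y, method)
    a = _alpha_for(method, alpha)
    std = _Standardizer(X)
    Yc, ym = std.center_response(Y)
    if lambda_grid_values is None:
        lams = lambda_grid(std.Z, Yc, a, method in MULTIVARIATE_METHODS)
    else:
        lams = np.sort(np.asarray(lambda_grid_values, float))[::-1]
        if lams.size == 0:
            raise ValueError("empty lambda grid")
    coefs = _path_coefs(std, Yc, method, a, lams, tol=tol)
    fits = []
    for lam, b in zip(lams, coefs):
        beta, intercept = std.original_scale(b, ym)
        fits.append(
            PenalizedFit(method=method, alpha=a, lam=float(lam),
                         intercept=intercept, beta=beta)
        )
    return fits


def predict(fit: PenalizedFit, X_new) -> np.ndarray:
    """intercept + X_new @ beta; returns (n_new, k)."""
    X_new = np.asarray(X_new, dtype=np.float64)
    if X_new.ndim != 2 or X_new.shape[1] != fit.beta.shape[0]:
        raise ValueError(
            f"X_new has {X_new.shape[-1]} columns, fit expects "
            f"{fit.beta.shape[0]}"
        )
    return fit.intercept + X_new @ fit.beta


def default_alpha_grid(method: str, n_alpha: int = 20) -> np.ndarray:
    if method in ("RR", "MTV_RR"):
        return np.array([0.0])
    if method in ("LASSO", "MTV_LASSO"):
        return np.array([1.0])
    return np.linspace(0.0, 1.0, n_alpha)


def cv_folds(n: int, k_folds: int, seed) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded, stratification-free k-fold partition (reusable across methods)."""
    kf = KFold(n_splits=k_folds, shuffle=True,
               random_state=int(np.random.default_rng(seed).integers(2**31)))
    return [(tr, te) for tr, te in kf.split(np.arange(n))]


def tune_by_cv(
    X,
    Y,
    method: str,
    alpha_grid=None,
    lambda_count: int | None = None,
    k_folds: int = 5,
    seed=0,
    folds=None,
    cache: FoldCache | None = None,
    row_index=None,
    tol: float = 1e-6,
    lambda_decades: float = LAMBDA_DECADES,
    max_active: int | None = None,
) -> PenalizedFit:
    """Grid-search (alpha outer, lambda path inner) by k-fold CV.

    The lambda path is 500 values for EN methods and 100 otherwise unless
    ``lambda_count`` overrides it; among ties in mean CV MSE the largest
    (sparsest) lambda wins.  The returned fit is re-estimated on all the
    provided data at the winning (alpha, lambda) and carries the full
    ``tuning_trace``.

    ``cache``/``row_index`` allow an enclosing nested-CV loop to share
    per-fold standardizers across methods and traits: ``X``/``Y`` must then
    be ``cache.X[row_index]`` and the response rows for the same subset.
    """
    X, Y = _check_inputs(X, Y, method)
    multitask = method in MULTIVARIATE_METHODS
    if alpha_grid is None:
        alpha_grid = default_alpha_grid(method)
    alpha_grid = [_alpha_for(method, a) for a in np.atleast_1d(alpha_grid)]
    if lambda_count is None:
        lambda_count = 500 if method in ("EN", "MTV_EN") else 100
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if folds is None:
        folds = cv_folds(X.shape[0], k_folds, seed)
    if cache is not None and row_index is None:
        raise ValueError("cache requires row_index")
    row_index = (np.arange(X.shape[0]) if row_index is None
                 else np.asarray(row_index))

    def _std_for(local_idx):
        if cache is not None:
            return cache.std(row_index[local_idx])
        return _Standardizer(X[local_idx])

    std_full = _std_for(np.arange(X.shape[0]))
    Yc_full, ym_full = std_full.center_response(Y)
    fold_parts = []
    for tr, te in folds:
        if np.any(Y[tr].std(axis=0) == 0):
            raise ValueError("fold with constant response")
        std = _std_for(tr)
        Yc, ym = std.center_response(Y[tr])
        fold_parts.append((tr, te, std, Yc, ym))
    records = []
    best = None
    for a in alpha_grid:
        lams = lambda_grid(std_full.Z, Yc_full, a, multitask,
                           count=lambda_count, decades=lambda_decades)
        sse = np.zeros(len(lams))
        n_val = 0
        for tr, te, std, Yc, ym in fold_parts:
            if a == 0.0:
                # kernel ridge: predictions without forming p-dim coefs
                duals = _ridge_duals(std, Yc, lams)
                key = row_index[te].tobytes() if cache is not None else None
                Kte = std.test_kernel(X[te], key=key)
                preds = ym + np.einsum("tn,lnk->ltk", Kte, duals,
                                       optimize=True)
            else:
                coefs = _cd_path(std.Z, Yc, a, lams, multitask, tol=tol,
                                 max_active=max_active)
                Zte = std.transform(X[te])
                preds = ym + np.einsum("tp,lpk->ltk", Zte, coefs,
                                       optimize=True)
            sse += ((Y[te][None] - preds) ** 2).sum(axis=(1, 2))
            n_val += te.size * Y.shape[1]
        mse = sse / n_val
        for lam, m in zip(lams, mse):
            records.append((a, float(lam), float(m)))
        # lams is decreasing: first index at the minimum = largest lambda
        t_best = int(np.argmin(mse))
        if best is None or mse[t_best] < best[0] - 1e-15:
            best = (float(mse[t_best]), a, float(lams[t_best]))
    _, a_best, lam_best = best
    coef = _path_coefs(std_full, Yc_full, method, a_best,
                       np.array([lam_best]), tol=tol)[0]
    beta, intercept = std_full.original_scale(coef, ym_full)
    trace = pd.DataFrame(records, columns=["alpha", "lambda", "cv_mse"])
    return PenalizedFit(method=method, alpha=a_best, lam=lam_best,
                        intercept=intercept, beta=beta, tuning_trace=trace)


def objective_value(X, Y, fit: PenalizedFit) -> float:
    """Penalized objective of a fit, on the standardized scale."""
    X, Y = _check_inputs(X, Y, fit.method)
    std = _Standardizer(X)
    Yc, _ = std.center_response(Y)
    beta_std = fit.beta * std.xs[:, None]
    R = Yc - std.Z @ beta_std
    n = X.shape[0]
    rss = 0.5 * float((R**2).sum()) / n
    if fit.method in MULTIVARIATE_METHODS:
        p1 = float(np.linalg.norm(beta_std, axis=1).sum())
    else:
        p1 = float(np.abs(beta_std).sum())
    p2 = 0.5 * float((beta_std**2).sum())
    return rss + fit.lam * (fit.alpha * p1 + (1 - fit.alpha) * p2)


__all__ = [
    "METHODS",
    "UNIVARIATE_METHODS",
    "MULTIVARIATE_METHODS",
    "PenalizedFit",
    "FoldCache",
    "lambda_max",
    "lambda_grid",
    "fit_path",
    "predict",
    "tune_by_cv",
    "cv_folds",
    "default_alpha_grid",
    "objective_value",
]
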