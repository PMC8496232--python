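"""Robust marker selection on penalized paths.

Two complementary controls over false selections:

* stability selection — refit the LASSO (or multi-task group LASSO) path on
  many random half-samples; a predictor's selection probability is the
  fraction of half-samples in which it is ever nonzero along the path, and
  only predictors above a probability threshold are retained;
* marginal false discovery rate (mFDR) — along a single LASSO/EN path,
  estimate the expected number of selections among predictors that are
  marginally independent of the outcome, via the normal tail probability
  that a null standardized predictor's inner product with the residual
  exceeds the active L1 threshold, and pick the smallest lambda whose
  estimated mFDR stays below a target level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .encoding import DesignMatrix
from .gp_methods import _alpha_for, _as_2d, _path_coefs, _Standardizer


@dataclass
class SelectionResult:
    """Per-method selected predictors, optionally collapsed to markers."""

    method_label: str
    selected_predictors: np.ndarray  # sorted predictor column indices
    statistic: np.ndarray | None  # per-predictor score (probability or lambda)
    control_parameter: float
    selected_markers: list[str] | None = None

    @property
    def n_selected(self) -> int:
        return len(self.selected_predictors)


def collapse_to_markers(
    predictor_idx: np.ndarray, design: DesignMatrix
) -> list[str]:
    """A marker is selected if any of its 8 columns is selected."""
    markers = design.marker_of_column()[predictor_idx]
    seen: dict = {}
    for m in markers:
        seen.setdefault(m, None)
    order = {m: i for i, m in enumerate(design.map.markers)}
    return sorted(seen, key=order.__getitem__)


def stability_selection(
    X,
    Y,
    method: str = "LASSO",
    lambda_grid_values=None,
    n_subsamples: int = 100,
    pi_threshold: float = 0.6,
    seed=0,
    design: DesignMatrix | None = None,
    tol: float = 1e-5,
) -> SelectionResult:
    """Half-sample stability selection on a LASSO / MTV_LASSO path.

    Each of ``n_subsamples`` random half-samples (floor(n/2) observations,
    without replacement) gets a fresh path fit over ``lambda_grid_values``;
    a predictor counts as selected in a half-sample if it is nonzero for at
    least one lambda of the grid.
    """
    if method not in ("LASSO", "MTV_LASSO"):
        raise ValueError("stability selection supports LASSO and MTV_LASSO")
    if n_subsamples < 20:
        raise ValueError("need at least 20 subsamples")
    if not 0.5 <= pi_threshold <= 1.0:
        raise ValueError("pi_threshold must lie in [0.5, 1]")
    X = np.asarray(X, dtype=np.float64)
    Y = _as_2d(Y)
    n, p = X.shape
    half = n // 2
    rng = np.random.default_rng(seed)
    counts = np.zeros(p)
    for _ in range(n_subsamples):
        rows = rng.choice(n, size=half, replace=False)
        std = _Standardizer(X[rows])
        Yc, _ = std.center_response(Y[rows])
        if lambda_grid_values is None:
            from .gp_methods import lambda_grid

            lams = lambda_grid(std.Z, Yc, 1.0,
                               method == "MTV_LASSO", count=30, decades=2)
        else:
            lams = np.sort(np.asarray(lambda_grid_values, float))[::-1]
        coefs = _path_coefs(std, Yc, method, 1.0, lams, tol=tol)
        ever = np.any(coefs != 0.0, axis=(0, 2))
        counts += ever
    probs = counts / n_subsamples
    idx = np.flatnonzero(probs >= pi_threshold)
    label = f"{method}.SS"
    return SelectionResult(
        method_label=label,
        selected_predictors=idx,
        statistic=probs,
        control_parameter=pi_threshold,
        selected_markers=(collapse_to_markers(idx, design)
                          if design is not None else None),
    )


@dataclass
class MfdrPath:
    """Per-lambda selection counts and mFDR estimates, with selection masks."""

    method: str
    alpha: float
    lambdas: np.ndarray
    n_selected: np.ndarray
    mfdr: np.ndarray
    masks: np.ndarray  # (L, p) bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lambda": self.lambdas, "n_selected": self.n_selected,
             "mfdr": self.mfdr}
        )


def mfdr_path(
    X,
    y,
    method: str = "LASSO",
    alpha: float | None = None,
    lambda_grid_values=None,
    tol: float = 1e-6,
) -> MfdrPath:
    """Estimate the marginal FDR along a univariate LASSO/EN path.

    At each lambda the expected count of false discoveries under the
    marginal null is EF = p * 2 Phi(-lambda alpha sqrt(n) / sigma_hat) —
    the chance that a standardized null predictor's score |z_j' r / n|
    clears the L1 threshold lambda*alpha — with sigma_hat^2 = RSS/(n-S-1);
    mFDR = min(1, EF / S), and 0 where nothing is selected.
    """
    if method not in ("LASSO", "EN"):
        raise ValueError("mFDR is univariate: LASSO or EN")
    a = _alpha_for(method, alpha)
    if a == 0:
        raise ValueError("mFDR needs an L1 component (alpha > 0)")
    X = np.asarray(X, dtype=np.float64)
    y2 = _as_2d(y)
    n, p = X.shape
    std = _Standardizer(X)
    Yc, _ = std.center_response(y2)
    if lambda_grid_values is None:
        from .gp_methods import lambda_grid

        lams = lambda_grid(std.Z, Yc, a, False, count=50)
    else:
        lams = np.asarray(lambda_grid_values, dtype=float)
        if lams.size == 0:
            raise ValueError("empty lambda grid")
        if np.any(np.diff(lams) >= 0):
            raise ValueError("lambda grid must be strictly decreasing")
    coefs = _path_coefs(std, Yc, method, a, lams, tol=tol)  # (L, p, 1)
    masks = coefs[:, :, 0] != 0.0
    n_sel = masks.sum(axis=1)
    mfdr = np.zeros(len(lams))
    p_eff = int(std.active.sum())
    for t, lam in enumerate(lams):
        S = int(n_sel[t])
        if S == 0:
            continue
        resid = Yc[:, 0] - std.Z @ coefs[t, :, 0]
        dof = max(n - S - 1, 1)
        sigma = float(np.sqrt((resid**2).sum() / dof))
        if sigma == 0:
            mfdr[t] = 0.0
            continue
        ef = p_eff * 2.0 * norm.sf(lam * a * np.sqrt(n) / sigma)
        mfdr[t] = min(1.0, ef / S)
    return MfdrPath(method=method, alpha=a, lambdas=lams,
                    n_selected=n_sel, mfdr=mfdr, masks=masks)


def select_at_mfdr(
    path: MfdrPath,
    level: float = 0.10,
    design: DesignMatrix | None = None,
) -> SelectionResult:
    """Selection set at the smallest lambda with estimated mFDR <= level."""
    ok = np.flatnonzero(path.mfdr <= level)
    label = f"{path.method}.mFDR"
    if ok.size == 0:
        return SelectionResult(method_label=label,
                               selected_predictors=np.array([], dtype=int),
                               statistic=None, control_parameter=level,
                               selected_markers=[] if design is not None
                               else None)
    t = int(ok[np.argmin(path.lambdas[ok])])
    idx = np.flatnonzero(path.masks[t])
    return SelectionResult(
        method_label=label,
        selected_predictors=idx,
        statistic=np.full(len(idx), path.lambdas[t]),
        control_parameter=level,
        selected_markers=(collapse_to_markers(idx, design)
                          if design is not None else None),
    )


__all__ = [
    "SelectionResult",
    "MfdrPath",
    "collapse_to_markers",
    "stability_selection",
    "mfdr_path",
    "select_at_mfdr",
]
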