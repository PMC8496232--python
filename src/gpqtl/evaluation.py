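"""Method evaluation: nested cross-validation, prediction metrics,
ROC/pAUC marker-selection scoring, broad-sense heritability, and trait
clustering.

Prediction is assessed by nested CV: an outer k1-fold split estimates the
performance metrics while an inner k2-fold CV on each outer training set
tunes the method; the outer partition is shared across methods and traits.
Marker selection is assessed against the simulated truth with a +/- 2 cM
true-positive window and the partial area under the ROC curve for
FPR in [0, 0.1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from . import gp_methods, interval_mapping
from .cross_sim import GeneticMap
from .gp_methods import FoldCache, cv_folds
from .interval_mapping import GenoProbGrid


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricSet:
    corP: float
    corS: float
    rmspe: float
    model_efficiency: float
    bias_pvalue: float
    slope_pvalue: float
    degenerate: bool = False


def rmspe(obs, pred) -> float:
    obs, pred = np.asarray(obs, float), np.asarray(pred, float)
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def model_efficiency(obs, pred) -> float:
    """1 - SSE/SST; 1 for perfect prediction, 0 for the mean predictor."""
    obs, pred = np.asarray(obs, float), np.asarray(pred, float)
    sst = float(((obs - obs.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("observations have zero variance")
    return 1.0 - float(((obs - pred) ** 2).sum()) / sst


def _is_constant(x: np.ndarray) -> bool:
    return bool(np.ptp(x) == 0
                or np.std(x) < 1e-12 * max(1.0, float(np.abs(x).max())))


def bias_slope_tests(obs, pred) -> tuple[float, float]:
    """t-test p-values for intercept = 0 and slope = 1 of obs ~ pred."""
    obs, pred = np.asarray(obs, float), np.asarray(pred, float)
    n = len(obs)
    if n < 3 or _is_constant(pred):
        return float("nan"), float("nan")
    res = stats.linregress(pred, obs)
    df = n - 2

    def _pval(estimate, target, stderr):
        if stderr > 0:
            return 2 * stats.t.sf(abs((estimate - target) / stderr), df)
        return 1.0 if estimate == target else 0.0  # exact fit

    return (float(_pval(res.intercept, 0.0, res.intercept_stderr)),
            float(_pval(res.slope, 1.0, res.stderr)))


def compute_metrics(obs, pred) -> MetricSet:
    """All prediction metrics for one validation set.

    A constant prediction vector has undefined correlations; they are
    reported as 0 with the ``degenerate`` flag so that aggregation never
    drops cells silently.
    """
    obs, pred = np.asarray(obs, float), np.asarray(pred, float)
    if len(obs) != len(pred) or len(obs) < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    degenerate = _is_constant(pred) or _is_constant(obs)
    if degenerate:
        corp = cors = 0.0
    else:
        corp = float(stats.pearsonr(obs, pred)[0])
        cors = float(stats.spearmanr(obs, pred)[0])
    pb, ps = bias_slope_tests(obs, pred)
    return MetricSet(
        corP=corp, corS=cors, rmspe=rmspe(obs, pred),
        model_efficiency=model_efficiency(obs, pred),
        bias_pvalue=pb, slope_pvalue=ps, degenerate=bool(degenerate),
    )


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvConfig:
    """Nested-CV protocol: k1 outer folds, k2 inner folds, r repetitions.

    One repetition is the convention for simulated data (variation comes
    from simulation replicates); ten for experimental-style data.
    """

    k1: int = 5
    k2: int = 5
    r: int = 1
    seed: int = 0


@dataclass
class PenalizedSpec:
    """A penalized-regression entry for nested CV."""

    method: str
    name: str | None = None
    alpha_grid: np.ndarray | None = None
    lambda_count: int | None = None
    lambda_decades: float = gp_methods.LAMBDA_DECADES
    tol: float = 1e-3
    max_active: int | None = None

    @property
    def label(self) -> str:
        return self.name or self.method

    def fit_predict(self, X, Y, tr, te, inner_folds, cache, rng):
        multitask = self.method in gp_methods.MULTIVARIATE_METHODS
        kw = dict(alpha_grid=self.alpha_grid, lambda_count=self.lambda_count,
                  folds=inner_folds, cache=cache, row_index=tr,
                  tol=self.tol, lambda_decades=self.lambda_decades,
                  max_active=self.max_active)
        if multitask:
            fit = gp_methods.tune_by_cv(X[tr], Y[tr], self.method, **kw)
            return gp_methods.predict(fit, X[te])
        preds = np.empty((len(te), Y.shape[1]))
        for j in range(Y.shape[1]):
            fit = gp_methods.tune_by_cv(X[tr], Y[tr, j], self.method, **kw)
            preds[:, j] = gp_methods.predict(fit, X[te])[:, 0]
        return preds


@dataclass
class IntervalMappingSpec:
    """A SIM or MIM entry for nested CV.

    The tuning parameter is the permutation LOD threshold computed on the
    training fold (10 permutations by default inside CV; use 1000 for
    stand-alone QTL detection).
    """

    kind: str = "SIM"  # "SIM" | "MIM"
    name: str | None = None
    n_perm: int = 10
    fwer: float = 0.05
    max_qtl: int = 4
    n_restarts: int = 2

    @property
    def label(self) -> str:
        return self.name or self.kind

    def fit_predict(self, probgrid: GenoProbGrid, Y, tr, te, rng):
        if self.kind not in ("SIM", "MIM"):
            raise ValueError(f"unknown interval-mapping kind {self.kind!r}")
        grid_tr = probgrid.subset(tr)
        grid_te = probgrid.subset(te)
        preds = np.empty((len(te), Y.shape[1]))
        for j in range(Y.shape[1]):
            y_tr = Y[tr, j]
            seed = int(rng.integers(2**31))
            thr = interval_mapping.permutation_threshold(
                grid_tr, y_tr, n_perm=self.n_perm, fwer=self.fwer, seed=seed
            )
            if self.kind == "SIM":
                scan = interval_mapping.scan_sim(grid_tr, y_tr)
                positions = scan.peaks(threshold=thr)
            else:
                model = interval_mapping.mim_stepwise(
                    grid_tr, y_tr, max_qtl=self.max_qtl, penalty=max(thr, .1),
                    n_restarts=self.n_restarts, seed=seed,
                )
                positions = model.qtl_positions
            preds[:, j] = interval_mapping.im_predict(
                positions, grid_tr, y_tr, grid_te
            )
        return preds


def nested_cv(
    specs,
    Y,
    cv_config: CvConfig,
    X=None,
    probgrid: GenoProbGrid | None = None,
    truth=None,
    cache: FoldCache | None = None,
    trait_names=None,
) -> pd.DataFrame:
    """Run nested CV for several methods on shared fold partitions.

    ``truth`` (same shape as Y) supplies the comparison target for the
    metrics — the true genetic values for simulated data; defaults to Y.
    Returns one row per (method, repetition, outer fold, trait).
    """
    Y = np.asarray(Y, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, k = Y.shape
    truth = Y if truth is None else np.asarray(truth, dtype=np.float64)
    if truth.shape != Y.shape:
        raise ValueError("truth must match Y's shape")
    if trait_names is None:
        trait_names = [f"trait{j + 1}" for j in range(k)]
    needs_X = any(isinstance(s, PenalizedSpec) for s in specs)
    if needs_X:
        X = np.asarray(X, dtype=np.float64)
        if cache is None:
            cache = FoldCache(X)
    if any(isinstance(s, IntervalMappingSpec) for s in specs) and \
            probgrid is None:
        raise ValueError("interval-mapping specs need a probgrid")
    rows = []
    for rep in range(cv_config.r):
        rep_ss = np.random.SeedSequence([cv_config.seed, rep])
        outer = cv_folds(n, cv_config.k1, rep_ss)
        for f, (tr, te) in enumerate(outer):
            if np.intersect1d(tr, te).size:
                raise RuntimeError("outer train/test overlap (leakage)")
            inner = cv_folds(
                len(tr), cv_config.k2,
                np.random.SeedSequence([cv_config.seed, rep, f]),
            )
            for itr, ite in inner:
                # inner folds index into tr only; te never enters tuning
                assert np.union1d(itr, ite).size == len(tr)
            for spec in specs:
                rng = np.random.default_rng(
                    np.random.SeedSequence([cv_config.seed, rep, f, 7])
                )
                if isinstance(spec, IntervalMappingSpec):
                    preds = spec.fit_predict(probgrid, Y, tr, te, rng)
                else:
                    preds = spec.fit_predict(X, Y, tr, te, inner, cache, rng)
                for j, tn in enumerate(trait_names):
                    m = compute_metrics(truth[te, j], preds[:, j])
                    rows.append(
                        {"method": spec.label, "rep": rep, "fold": f,
                         "trait": tn, **m.__dict__}
                    )
    return pd.DataFrame(rows)


def aggregate_metrics(per_fold: pd.DataFrame, by=("method",)) -> pd.DataFrame:
    """Average metric columns over folds/repetitions/traits."""
    metric_cols = ["corP", "corS", "rmspe", "model_efficiency"]
    return per_fold.groupby(list(by), as_index=False)[metric_cols].mean()


# ---------------------------------------------------------------------------
# ROC / pAUC for marker selection
# ---------------------------------------------------------------------------

@dataclass
class RocCurve:
    points: pd.DataFrame  # columns: param, fpr, tpr (sorted by fpr)
    parameter_name: str
    pauc: float


def _selection_rates(selected, truth_markers, chrom, cm, index, tol_cM):
    """TPR/FPR of one marker set against one trait's true QTL markers."""
    q_idx = [index[m] for m in truth_markers]
    windows = [(chrom[i], cm[i]) for i in q_idx]
    inside = np.zeros(len(cm), dtype=bool)
    for c, x in windows:
        inside |= (chrom == c) & (np.abs(cm - x) <= tol_cM)
    n_outside = int((~inside).sum())
    sel_idx = np.array([index[m] for m in selected], dtype=int)
    tp = 0
    for c, x in windows:
        if sel_idx.size and np.any(
            (chrom[sel_idx] == c) & (np.abs(cm[sel_idx] - x) <= tol_cM)
        ):
            tp += 1
    fp = int((~inside[sel_idx]).sum()) if sel_idx.size else 0
    tpr = tp / len(windows)
    fpr = fp / n_outside if n_outside > 0 else 0.0
    return tpr, fpr


def roc_curve(
    selection_sweep,
    truth_qtls,
    genetic_map: GeneticMap,
    tol_cM: float = 2.0,
    parameter_name: str = "",
    fpr_max: float = 0.1,
) -> RocCurve:
    """ROC over a one-parameter selection sweep.

    ``selection_sweep`` is a sequence of (parameter value, per-trait marker
    lists); ``truth_qtls`` the per-trait true QTL marker lists.  A QTL
    counts as found if any selected marker lies within ``tol_cM`` of it on
    the same chromosome; false positives are selected markers outside every
    window, relative to the count of markers outside all windows.
    Per-trait rates are averaged.
    """
    if not truth_qtls or any(len(t) == 0 for t in truth_qtls):
        raise ValueError("empty truth set")
    chrom = genetic_map.df["chrom"].to_numpy()
    cm = genetic_map.df["pos_cM"].to_numpy()
    index = {m: i for i, m in enumerate(genetic_map.markers)}
    rows = []
    for param, per_trait in selection_sweep:
        tprs, fprs = [], []
        for t, selected in enumerate(per_trait):
            tpr, fpr = _selection_rates(
                selected, truth_qtls[t], chrom, cm, index, tol_cM
            )
            tprs.append(tpr)
            fprs.append(fpr)
        rows.append((param, float(np.mean(fprs)), float(np.mean(tprs))))
    points = pd.DataFrame(rows, columns=["param", "fpr", "tpr"])
    points = points.sort_values("fpr", kind="stable").reset_index(drop=True)
    return RocCurve(points=points, parameter_name=parameter_name,
                    pauc=pauc(points["fpr"], points["tpr"], fpr_max))


def pauc(fpr, tpr, fpr_max: float = 0.1) -> float:
    """Trapezoidal partial AUC of TPR over FPR in [0, fpr_max].

    Duplicate FPR values collapse to their maximum TPR; a curve starting at
    FPR > 0 is anchored by a linear segment from (0, 0); a curve ending
    before ``fpr_max`` is extended horizontally at its last TPR.
    """
    fpr = np.asarray(fpr, dtype=float)
    tpr = np.asarray(tpr, dtype=float)
    if fpr.size == 0:
        raise ValueError("empty curve")
    order = np.argsort(fpr, kind="stable")
    fpr, tpr = fpr[order], tpr[order]
    # collapse duplicate FPRs to max TPR
    xs, ys = [], []
    for f, t in zip(fpr, tpr):
        if xs and f == xs[-1]:
            ys[-1] = max(ys[-1], t)
        else:
            xs.append(float(f))
            ys.append(float(t))
    xs, ys = np.array(xs), np.array(ys)
    if xs[0] > 0:
        xs = np.concatenate([[0.0], xs])
        ys = np.concatenate([[0.0], ys])
    if xs[-1] < fpr_max:
        xs = np.concatenate([xs, [fpr_max]])
        ys = np.concatenate([ys, [ys[-1]]])
    keep = xs <= fpr_max
    if not np.all(keep):
        t_at = float(np.interp(fpr_max, xs, ys))
        xs = np.concatenate([xs[keep], [fpr_max]])
        ys = np.concatenate([ys[keep], [t_at]])
    return float(np.trapezoid(ys, xs))


# ---------------------------------------------------------------------------
# small utilities
# ---------------------------------------------------------------------------

@dataclass
class HeritabilityComponents:
    """Variance components for genotype-mean-basis broad-sense heritability."""

    var_G: float
    var_GY: float
    var_e: float
    n_year_bar: float
    n_rep_bar: float


def broad_sense_h2(c: HeritabilityComponents) -> float:
    """H2 = var_G / (var_G + var_GY/n_year + var_e/(n_year * n_rep))."""
    if min(c.var_G, c.var_GY, c.var_e) < 0:
        raise ValueError("variance components must be nonnegative")
    if c.n_year_bar <= 0 or c.n_rep_bar <= 0:
        raise ValueError("replication numbers must be positive")
    denom = (c.var_G + c.var_GY / c.n_year_bar
             + c.var_e / (c.n_year_bar * c.n_rep_bar))
    if denom == 0:
        raise ValueError("zero denominator")
    return c.var_G / denom


def cluster_traits(trait_table: pd.DataFrame, n_groups: int = 3) -> pd.Series:
    """Ward hierarchical clustering of traits on standardized values."""
    if trait_table.shape[1] < n_groups:
        raise ValueError("fewer traits than groups")
    sds = trait_table.std(axis=0, ddof=0)
    if (sds == 0).any():
        bad = sds.index[sds == 0][0]
        raise ValueError(f"constant trait {bad!r} cannot be clustered")
    Z = ((trait_table - trait_table.mean(axis=0)) / sds).to_numpy().T
    labels = fcluster(linkage(Z, method="ward"), n_groups,
                      criterion="maxclust")
    return pd.Series(labels, index=trait_table.columns, name="group")


__all__ = [
    "MetricSet",
    "CvConfig",
    "PenalizedSpec",
    "IntervalMappingSpec",
    "nested_cv",
    "aggregate_metrics",
    "compute_metrics",
    "rmspe",
    "model_efficiency",
    "bias_slope_tests",
    "RocCurve",
    "roc_curve",
    "pauc",
    "HeritabilityComponents",
    "broad_sense_h2",
    "cluster_traits",
]
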