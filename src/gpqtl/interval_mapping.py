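"""Simple and multiple interval mapping for a fully-informative four-way cross.

Genotype-class probabilities on a cM grid come from the exact two-point
Markov bridge under Haldane recombination (no hidden-state machinery is
needed because the data are complete and every marker is fully
informative).  LOD scans use Haley-Knott regression of the trait on the
class probabilities; genome-wide significance is calibrated by permutation;
multiple-QTL models are built by penalized forward/backward stepwise search
with coordinate-wise position refinement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cross_sim import GeneticMap, PhasedGenotypes, haldane_r

#: LOD value reported for numerically perfect fits
LOD_CAP = 300.0


@dataclass
class GenoProbGrid:
    """Genotype-class probabilities at markers and pseudomarkers.

    ``positions`` has columns chrom, pos_cM, is_marker, marker; ``probs`` is
    (n_offspring, n_positions, 4) over classes (ac, ad, bc, bd).  At marker
    positions the probability vector is the unit indicator of the observed
    class.
    """

    positions: pd.DataFrame
    probs: np.ndarray
    offspring: pd.Index

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def subset(self, rows: np.ndarray) -> "GenoProbGrid":
        """Restrict to a subset of offspring (for cross-validation folds)."""
        return GenoProbGrid(self.positions, self.probs[rows],
                            self.offspring[rows])

    def chrom_indices(self, chrom) -> np.ndarray:
        return np.flatnonzero((self.positions["chrom"] == chrom).to_numpy())


@dataclass
class LodScan:
    positions: pd.DataFrame
    lod: np.ndarray
    threshold: float | None = None
    n_permutations: int = 0

    def peaks(self, threshold: float | None = None) -> list[int]:
        """Per-chromosome LOD-peak position indices above the threshold."""
        thr = self.threshold if threshold is None else threshold
        if thr is None:
            raise ValueError("no threshold available")
        out = []
        for chrom in pd.unique(self.positions["chrom"]):
            idx = np.flatnonzero((self.positions["chrom"] == chrom).to_numpy())
            j = idx[int(np.argmax(self.lod[idx]))]
            if self.lod[j] >= thr:
                out.append(int(j))
        return out


@dataclass
class MimModel:
    qtl_positions: list[int]  # indices into the prob grid
    plod: float
    penalty: float
    max_qtl: int
    positions: pd.DataFrame
    fitted_effects: np.ndarray | None = None

    @property
    def n_qtl(self) -> int:
        return len(self.qtl_positions)

    def position_table(self) -> pd.DataFrame:
        return self.positions.iloc[self.qtl_positions][
            ["chrom", "pos_cM", "is_marker", "marker"]
        ].reset_index(drop=True)


# ---------------------------------------------------------------------------
# genotype probabilities
# ---------------------------------------------------------------------------

def _bridge_prob(state_l, state_r, r_l, r_r, r_lr):
    """P(state 0 at x | states at flanking markers), two-state Markov bridge.

    T(s, s'; r) = 1-r if s == s' else r.  Probability of being in state 0 at
    the interior point given the flanking observations.
    """
    t_l0 = np.where(state_l == 0, 1.0 - r_l, r_l)
    t_0r = np.where(state_r == 0, 1.0 - r_r, r_r)
    t_lr = np.where(state_l == state_r, 1.0 - r_lr, r_lr)
    return t_l0 * t_0r / t_lr


def calc_genoprob(
    genotypes: PhasedGenotypes, genetic_map: GeneticMap, step_cM: float = 0.1
) -> GenoProbGrid:
    """Class probabilities at markers and every ``step_cM`` between markers.

    ``step_cM=None`` restricts the grid to marker positions (useful inside
    cross-validation, where pseudomarker resolution matters little).
    """
    if step_cM is not None and step_cM <= 0:
        raise ValueError("step_cM must be positive")
    codes = genotypes.class_codes()  # (n, m): 0 ac, 1 ad, 2 bc, 3 bd
    maternal = codes // 2  # 0 = a
    paternal = codes % 2   # 0 = c
    n = codes.shape[0]
    pos_rows = []
    blocks = []
    eye = np.eye(4)
    for chrom in genetic_map.chromosomes:
        sl = genetic_map.chrom_slice(chrom)
        cm = genetic_map.df["pos_cM"].to_numpy()[sl]
        names = genetic_map.markers[sl]
        for i in range(len(cm)):
            gi = sl.start + i
            pos_rows.append((chrom, float(cm[i]), True, names[i]))
            blocks.append(eye[codes[:, gi]])
            if step_cM is None or i == len(cm) - 1:
                continue
            d = cm[i + 1] - cm[i]
            if d <= 0:
                continue
            n_steps = int(np.ceil(d / step_cM)) - 1
            xs = cm[i] + step_cM * np.arange(1, n_steps + 1)
            xs = xs[xs < cm[i + 1] - 1e-12]
            r_lr = haldane_r(d)
            for x in xs:
                r_l = haldane_r(x - cm[i])
                r_r = haldane_r(cm[i + 1] - x)
                pa = _bridge_prob(maternal[:, gi], maternal[:, gi + 1],
                                  r_l, r_r, r_lr)
                pc = _bridge_prob(paternal[:, gi], paternal[:, gi + 1],
                                  r_l, r_r, r_lr)
                block = np.empty((n, 4))
                block[:, 0] = pa * pc
                block[:, 1] = pa * (1 - pc)
                block[:, 2] = (1 - pa) * pc
                block[:, 3] = (1 - pa) * (1 - pc)
                blocks.append(block)
                pos_rows.append((chrom, float(x), False, None))
    probs = np.stack(blocks, axis=1)  # (n, n_pos, 4); built in cM order
    positions = pd.DataFrame(
        pos_rows, columns=["chrom", "pos_cM", "is_marker", "marker"]
    )
    return GenoProbGrid(positions=positions, probs=probs,
                        offspring=genotypes.df.index)


# ---------------------------------------------------------------------------
# Haley-Knott scanning
# ---------------------------------------------------------------------------

def _hk_design(probs: np.ndarray) -> np.ndarray:
    """Per-position regression design: intercept + first 3 class probs.

    The four probabilities sum to one, so three of them plus an intercept
    span the same space; RSS is invariant to which is dropped.
    """
    n, n_pos, _ = probs.shape
    P = np.empty((n_pos, n, 4))
    P[:, :, 0] = 1.0
    P[:, :, 1:] = probs[:, :, :3].transpose(1, 0, 2)
    return P


def _scan_rss(P: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sums of squares of Y on each position design; (n_pos, q)."""
    G = P.transpose(0, 2, 1) @ P          # (n_pos, 4, 4)
    B = P.transpose(0, 2, 1) @ Y          # (n_pos, 4, q)
    coef = np.linalg.pinv(G) @ B          # least-norm solution
    yty = (Y**2).sum(axis=0)              # (q,)
    rss = yty[None, :] - np.einsum("pij,pij->pj", B, coef)
    return np.maximum(rss, 0.0)


def scan_sim(probgrid: GenoProbGrid, y) -> LodScan:
    """Single-QTL Haley-Knott LOD scan at every grid position."""
    Y = np.asarray(y, dtype=np.float64).ravel()[:, None]
    if not np.all(np.isfinite(Y)):
        raise ValueError("y must be complete")
    n = probgrid.probs.shape[0]
    P = _hk_design(probgrid.probs)
    rss1 = _scan_rss(P, Y)
    rss0 = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    lod = _lod_from_rss(rss0[None, :], rss1, n)
    return LodScan(positions=probgrid.positions, lod=lod[:, 0])


def _lod_from_rss(rss0, rss1, n) -> np.ndarray:
    rss0 = np.broadcast_to(np.asarray(rss0, float), rss1.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            rss0 <= 0,
            1.0,  # constant y: the null already fits perfectly
            np.where(rss1 > 0, rss0 / np.maximum(rss1, 1e-300), np.inf),
        )
        lod = (n / 2.0) * np.log10(ratio)
    if np.any(~np.isfinite(lod)) or np.any(lod > LOD_CAP):
        warnings.warn(f"perfect fit encountered; LOD capped at {LOD_CAP}")
        lod = np.where(np.isfinite(lod), np.minimum(lod, LOD_CAP), LOD_CAP)
    return np.maximum(lod, 0.0)


def permutation_threshold(
    probgrid: GenoProbGrid, y, n_perm: int = 1000, fwer: float = 0.05, seed=0
) -> float:
    """Genome-wide LOD threshold: (1-fwer) quantile of permutation maxima."""
    if n_perm < 10:
        raise ValueError("need at least 10 permutations")
    y = np.asarray(y, dtype=np.float64).ravel()
    rng = np.random.default_rng(seed)
    Yperm = np.column_stack([rng.permutation(y) for _ in range(n_perm)])
    n = probgrid.probs.shape[0]
    P = _hk_design(probgrid.probs)
    rss1 = _scan_rss(P, Yperm)
    rss0 = ((Yperm - Yperm.mean(axis=0)) ** 2).sum(axis=0)
    lod = _lod_from_rss(rss0[None, :], rss1, n)
    maxima = lod.max(axis=0)
    return float(np.quantile(maxima, 1.0 - fwer))


def mim_penalty(
    probgrid: GenoProbGrid, y, n_perm: int = 1000, fwer: float = 0.05, seed=0
) -> float:
    """Per-QTL penalty for the stepwise search.

    Main effects only are modelled, so the penalty is the genome-wide
    single-scan permutation threshold.
    """
    return permutation_threshold(probgrid, y, n_perm=n_perm, fwer=fwer,
                                 seed=seed)


# ---------------------------------------------------------------------------
# multiple interval mapping
# ---------------------------------------------------------------------------

def _model_rss(P4: np.ndarray, positions: list[int], y: np.ndarray) -> float:
    """RSS of y on intercept + class probs of the given positions."""
    n = y.shape[0]
    if not positions:
        return float(((y - y.mean()) ** 2).sum())
    W = np.concatenate(
        [np.ones((n, 1))] + [P4[:, j, :3] for j in positions], axis=1
    )
    coef, *_ = np.linalg.lstsq(W, y, rcond=None)
    resid = y - W @ coef
    return float((resid**2).sum())


def _conditional_scan(P: np.ndarray, P4, positions, y):
    """RSS at every candidate position given fixed QTLs (Frisch-Waugh)."""
    n = y.shape[0]
    if positions:
        W = np.concatenate(
            [np.ones((n, 1))] + [P4[:, j, :3] for j in positions], axis=1
        )
        Q, _ = np.linalg.qr(W)
        y_res = y - Q @ (Q.T @ y)
        # project each candidate block; P is (n_pos, n, 4)
        QtP = np.einsum("nr,pnc->prc", Q, P, optimize=True)
        P_res = P - np.einsum("nr,prc->pnc", Q, QtP, optimize=True)
    else:
        y_res = y - y.mean()
        P_res = P
    return _scan_rss(P_res, y_res[:, None])[:, 0]


def mim_stepwise(
    probgrid: GenoProbGrid,
    y,
    max_qtl: int = 4,
    penalty: float = 3.0,
    n_restarts: int = 10,
    seed=0,
) -> MimModel:
    """Forward/backward penalized stepwise multi-QTL search.

    Model score pLOD = LOD(model) - penalty * n_QTL, LOD from the
    Haley-Knott RSS ratio against the intercept-only model.  Forward steps
    add the position maximizing pLOD; each addition is followed by backward
    sweeps dropping any QTL whose removal improves pLOD, then coordinate-wise
    position refinement.  The search restarts ``n_restarts`` times with
    randomized tie-breaking/refinement order; the best-pLOD model wins.
    """
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    y = np.asarray(y, dtype=np.float64).ravel()
    n = y.shape[0]
    P = _hk_design(probgrid.probs)
    P4 = probgrid.probs  # (n, n_pos, 4)
    rss0 = float(((y - y.mean()) ** 2).sum())

    def plod_of(rss, q):
        if rss <= 0:
            return LOD_CAP - penalty * q
        return (n / 2.0) * np.log10(rss0 / rss) - penalty * q

    def argmax_tiebreak(values, rng):
        vmax = values.max()
        ties = np.flatnonzero(values >= vmax - 1e-9)
        return int(rng.choice(ties))

    best_model: MimModel | None = None
    ss = np.random.SeedSequence(seed) if not isinstance(
        seed, np.random.SeedSequence) else seed
    for child in ss.spawn(max(n_restarts, 1)):
        rng = np.random.default_rng(child)
        positions: list[int] = []
        current_rss = rss0
        current_plod = 0.0
        improved = True
        while improved and len(positions) < max_qtl:
            improved = False
            rss_cand = _conditional_scan(P, P4, positions, y)
            j = argmax_tiebreak(-rss_cand, rng)
            new_plod = plod_of(rss_cand[j], len(positions) + 1)
            if new_plod > current_plod + 1e-9:
                positions.append(j)
                current_rss = rss_cand[j]
                current_plod = new_plod
                improved = True
                # backward sweep
                dropping = True
                while dropping and len(positions) > 1:
                    dropping = False
                    for q in list(positions):
                        rest = [p for p in positions if p != q]
                        rss_rest = _model_rss(P4, rest, y)
                        plod_rest = plod_of(rss_rest, len(rest))
                        if plod_rest > current_plod + 1e-9:
                            positions = rest
                            current_rss = rss_rest
                            current_plod = plod_rest
                            dropping = True
                            break
                # refinement: coordinate-wise re-scan
                for _ in range(10):
                    moved = False
                    order = rng.permutation(len(positions))
                    for qi in order:
                        others = [p for i, p in enumerate(positions)
                                  if i != qi]
                        rss_scan = _conditional_scan(P, P4, others, y)
                        jbest = argmax_tiebreak(-rss_scan, rng)
                        if rss_scan[jbest] < current_rss - 1e-12 and \
                                jbest not in others:
                            positions[qi] = jbest
                            current_rss = rss_scan[jbest]
                            current_plod = plod_of(current_rss,
                                                   len(positions))
                            moved = True
                    if not moved:
                        break
        model = MimModel(qtl_positions=sorted(positions), plod=current_plod,
                         penalty=penalty, max_qtl=max_qtl,
                         positions=probgrid.positions)
        if best_model is None or model.plod > best_model.plod + 1e-12:
            best_model = model
    # final effect estimates
    if best_model.qtl_positions:
        W = np.concatenate(
            [np.ones((n, 1))]
            + [P4[:, j, :3] for j in best_model.qtl_positions],
            axis=1,
        )
        coef, *_ = np.linalg.lstsq(W, y, rcond=None)
        best_model.fitted_effects = coef
    return best_model


# ---------------------------------------------------------------------------
# support intervals and prediction
# ---------------------------------------------------------------------------

def lod_support_interval(
    scan: LodScan, peak: int, drop: float = 1.0
) -> tuple[float, float]:
    """LOD-``drop`` support interval (cM) around a peak position index."""
    chrom = scan.positions["chrom"].iloc[peak]
    idx = np.flatnonzero((scan.positions["chrom"] == chrom).to_numpy())
    lod = scan.lod[idx]
    local = int(np.searchsorted(idx, peak))
    cutoff = scan.lod[peak] - drop
    lo = local
    while lo > 0 and lod[lo - 1] >= cutoff:
        lo -= 1
    hi = local
    while hi < len(idx) - 1 and lod[hi + 1] >= cutoff:
        hi += 1
    cm = scan.positions["pos_cM"].to_numpy()[idx]
    return float(cm[lo]), float(cm[hi])


def nearest_markers(position_table: pd.DataFrame,
                    genetic_map: GeneticMap) -> list[str]:
    """Closest map marker to each (chrom, pos_cM) row (for pseudomarkers)."""
    out = []
    for _, row in position_table.iterrows():
        sub = genetic_map.df[genetic_map.df["chrom"] == row["chrom"]]
        i = (sub["pos_cM"] - row["pos_cM"]).abs().idxmin()
        out.append(genetic_map.df.loc[i, "marker"])
    return out


def im_predict(
    model_positions: list[int],
    probgrid_train: GenoProbGrid,
    y_train,
    probgrid_test: GenoProbGrid,
) -> np.ndarray:
    """OLS on class probabilities at the QTL positions; predict new offspring.

    An empty model predicts the training mean.  Rank deficiency is resolved
    by the pseudo-inverse (minimum-norm coefficients).
    """
    y_train = np.asarray(y_train, dtype=np.float64).ravel()
    n_tr = probgrid_train.probs.shape[0]
    n_te = probgrid_test.probs.shape[0]
    if not model_positions:
        return np.full(n_te, y_train.mean())
    W_tr = np.concatenate(
        [np.ones((n_tr, 1))]
        + [probgrid_train.probs[:, j, :3] for j in model_positions],
        axis=1,
    )
    W_te = np.concatenate(
        [np.ones((n_te, 1))]
        + [probgrid_test.probs[:, j, :3] for j in model_positions],
        axis=1,
    )
    coef = np.linalg.pinv(W_tr) @ y_train
    return W_te @ coef


__all__ = [
    "LOD_CAP",
    "GenoProbGrid",
    "LodScan",
    "MimModel",
    "calc_genoprob",
    "scan_sim",
    "permutation_threshold",
    "mim_penalty",
    "mim_stepwise",
    "lod_support_interval",
    "nearest_markers",
    "im_predict",
]
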