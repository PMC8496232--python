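"""Consensus "highly reliable" QTL intervals across selection methods.

Per-method marker selections are first expanded with linkage
disequilibrium: any same-chromosome marker whose r-squared with a selected
marker reaches the genome-wide threshold (95% quantile of all
within-chromosome pairwise values) counts as selected too.  A marker is
then deemed highly reliable if it is selected by at least five distinct
methods, or by both EN.mFDR and MIM.  Each reliable marker anchors a
+/- 3 cM interval; overlapping intervals merge, genetic bounds are
converted to physical coordinates through a monotone loess fit of bp on cM,
and intervals overlapping across traits are unioned.  The variance
explained by the anchor markers is summarized per trait as the adjusted
R-squared of a joint additive regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .cross_sim import GeneticMap, PhasedGenotypes
from .encoding import dose_matrix


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

@dataclass
class LdMatrix:
    """Within-chromosome marker-pair r-squared values on dose codings."""

    blocks: dict  # chrom -> (marker index array into map, r2 matrix)
    ld_threshold: float
    map: GeneticMap


def compute_ld(genotypes: PhasedGenotypes, quantile: float = 0.95) -> LdMatrix:
    """Pairwise squared correlation of 0/1/2 doses, per chromosome.

    The threshold is the ``quantile`` of all within-chromosome pairwise
    values pooled over chromosomes.
    """
    gmap = genotypes.map
    doses = dose_matrix(genotypes)
    blocks = {}
    pooled = []
    for chrom in gmap.chromosomes:
        sl = gmap.chrom_slice(chrom)
        D = doses[:, sl]
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(D, rowvar=False)
        C = np.nan_to_num(C, nan=0.0)
        np.fill_diagonal(C, 1.0)
        r2 = C**2
        blocks[chrom] = (np.arange(sl.start, sl.stop), r2)
        iu = np.triu_indices(r2.shape[0], k=1)
        pooled.append(r2[iu])
    thr = float(np.quantile(np.concatenate(pooled), quantile))
    return LdMatrix(blocks=blocks, ld_threshold=thr, map=gmap)


def ld_expand(selected, ld: LdMatrix) -> list[str]:
    """Single-pass LD expansion of a marker set (no transitive closure)."""
    gmap = ld.map
    sel_idx = set(gmap.marker_index(list(selected)))
    out = set(sel_idx)
    for chrom, (idx, r2) in ld.blocks.items():
        local = [i for i, g in enumerate(idx) if g in sel_idx]
        if not local:
            continue
        hits = np.any(r2[local, :] >= ld.ld_threshold, axis=0)
        out.update(idx[hits])
    markers = gmap.markers
    return [markers[i] for i in sorted(out)]


# ---------------------------------------------------------------------------
# reliable markers and intervals
# ---------------------------------------------------------------------------

def tally_reliable(
    selections, min_methods: int = 5,
    pair_rule: tuple[str, str] = ("EN.mFDR", "MIM"),
) -> list[str]:
    """Highly reliable markers from per-method (label, marker list) pairs.

    ``selections`` may be a list of SelectionResult-like objects (with
    ``method_label`` and ``selected_markers``) or (label, markers) tuples.
    A marker qualifies if selected by >= ``min_methods`` distinct method
    labels, or by both members of ``pair_rule``.
    """
    per_marker: dict[str, set] = {}
    for sel in selections:
        if isinstance(sel, tuple):
            label, markers = sel
        else:
            label, markers = sel.method_label, sel.selected_markers
        for m in markers or []:
            per_marker.setdefault(m, set()).add(label)
    reliable = [
        m for m, labels in per_marker.items()
        if len(labels) >= min_methods
        or (pair_rule[0] in labels and pair_rule[1] in labels)
    ]
    return reliable


@dataclass
class QTLInterval:
    traits: list[str]
    chrom: str
    cm_start: float
    cm_end: float
    bp_start: int
    bp_end: int
    anchor_markers: list[str]
    supporting_methods: list[str] = field(default_factory=list)
    pve: float | None = None


class CmBpSmoother:
    """Monotone cM <-> bp conversion per chromosome via loess.

    Local regression (span 0.3) of bp on cM, post-processed to be
    nondecreasing, evaluated by interpolation on a dense fitted grid; the
    inverse maps through the same grid.  Chromosomes with fewer than five
    markers fall back to linear interpolation (flagged).
    """

    MIN_MARKERS = 5

    def __init__(self, genetic_map: GeneticMap, frac: float = 0.3):
        self.map = genetic_map
        self.frac = frac
        self.fallback_chroms: list[str] = []
        self._grids = {}
        for chrom in genetic_map.chromosomes:
            sl = genetic_map.chrom_slice(chrom)
            cm = genetic_map.df["pos_cM"].to_numpy()[sl]
            bp = genetic_map.df["pos_bp"].to_numpy()[sl].astype(float)
            if len(cm) < self.MIN_MARKERS:
                self.fallback_chroms.append(chrom)
                grid_cm = cm.astype(float)
                grid_bp = bp
            else:
                grid_cm = np.linspace(cm[0], cm[-1], max(200, 2 * len(cm)))
                fit = lowess(bp, cm, frac=self.frac, xvals=grid_cm)
                grid_bp = np.maximum.accumulate(fit)
            # strictness for invertibility
            grid_bp = grid_bp + np.arange(len(grid_bp)) * 1e-9
            self._grids[chrom] = (grid_cm, grid_bp)

    def bp_at(self, chrom, cm) -> np.ndarray:
        grid_cm, grid_bp = self._grids[chrom]
        return np.interp(np.asarray(cm, float), grid_cm, grid_bp)

    def cm_at(self, chrom, bp) -> np.ndarray:
        grid_cm, grid_bp = self._grids[chrom]
        return np.interp(np.asarray(bp, float), grid_bp, grid_cm)


def fit_cm_bp_smoother(genetic_map: GeneticMap, frac: float = 0.3) -> CmBpSmoother:
    return CmBpSmoother(genetic_map, frac=frac)


def _merge_windows(windows):
    """Union of overlapping/touching (start, end, payload) windows."""
    windows = sorted(windows, key=lambda w: (w[0], w[1]))
    merged = []
    for start, end, payload in windows:
        if merged and start <= merged[-1][1]:
            prev = merged[-1]
            merged[-1] = (prev[0], max(prev[1], end), prev[2] | payload)
        else:
            merged.append((start, end, set(payload)))
    return merged


def build_intervals(
    reliable_markers,
    genetic_map: GeneticMap,
    trait: str,
    smoother: CmBpSmoother | None = None,
    half_width_cM: float = 3.0,
) -> list[QTLInterval]:
    """+/- ``half_width_cM`` intervals around anchors, merged per chromosome."""
    if smoother is None:
        smoother = fit_cm_bp_smoother(genetic_map)
    idx = genetic_map.marker_index(list(reliable_markers))
    df = genetic_map.df
    out = []
    for chrom in genetic_map.chromosomes:
        sl = genetic_map.chrom_slice(chrom)
        cm_all = df["pos_cM"].to_numpy()[sl]
        here = [i for i in idx if sl.start <= i < sl.stop]
        if not here:
            continue
        windows = []
        for i in here:
            x = float(df["pos_cM"].iloc[i])
            lo = max(x - half_width_cM, float(cm_all.min()))
            hi = min(x + half_width_cM, float(cm_all.max()))
            windows.append((lo, hi, {df["marker"].iloc[i]}))
        for lo, hi, anchors in _merge_windows(windows):
            bp_lo, bp_hi = smoother.bp_at(chrom, [lo, hi])
            out.append(
                QTLInterval(
                    traits=[trait], chrom=chrom,
                    cm_start=lo, cm_end=hi,
                    bp_start=int(round(bp_lo)), bp_end=int(round(bp_hi)),
                    anchor_markers=sorted(anchors),
                )
            )
    return out


def merge_across_traits(intervals) -> list[QTLInterval]:
    """Union physical intervals overlapping across traits on one chromosome."""
    by_chrom: dict[str, list[QTLInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged = []
    for chrom, ivs in by_chrom.items():
        ivs = sorted(ivs, key=lambda v: (v.bp_start, v.bp_end))
        cur = None
        for iv in ivs:
            if cur is not None and iv.bp_start <= cur.bp_end:
                cur.bp_end = max(cur.bp_end, iv.bp_end)
                cur.cm_start = min(cur.cm_start, iv.cm_start)
                cur.cm_end = max(cur.cm_end, iv.cm_end)
                cur.traits = sorted(set(cur.traits) | set(iv.traits))
                cur.anchor_markers = sorted(
                    set(cur.anchor_markers) | set(iv.anchor_markers)
                )
                cur.supporting_methods = sorted(
                    set(cur.supporting_methods) | set(iv.supporting_methods)
                )
            else:
                cur = QTLInterval(
                    traits=list(iv.traits), chrom=iv.chrom,
                    cm_start=iv.cm_start, cm_end=iv.cm_end,
                    bp_start=iv.bp_start, bp_end=iv.bp_end,
                    anchor_markers=list(iv.anchor_markers),
                    supporting_methods=list(iv.supporting_methods),
                )
                merged.append(cur)
    return merged


def pve_adjusted_r2(
    genotypes: PhasedGenotypes, anchor_markers, y
) -> float:
    """Adjusted R^2 of the trait on the dose codings of all anchor markers.

    Aliased (collinear) columns are absorbed by a minimum-norm fit with the
    model degrees of freedom taken as the predictor-matrix rank.
    """
    anchors = list(anchor_markers)
    if not anchors:
        raise ValueError("need at least one anchor marker")
    y = np.asarray(y, dtype=np.float64).ravel()
    idx = genotypes.map.marker_index(anchors)
    D = dose_matrix(genotypes)[:, idx]
    n = len(y)
    Dc = D - D.mean(axis=0)
    rank = int(np.linalg.matrix_rank(Dc))
    if n <= rank + 1:
        raise ValueError("too few observations for the anchor count")
    coef = np.linalg.pinv(Dc) @ (y - y.mean())
    resid = (y - y.mean()) - Dc @ coef
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / sst
    return 1.0 - (1.0 - r2) * (n - 1) / (n - rank - 1)


def intervals_to_frame(intervals) -> pd.DataFrame:
    rows = [
        {
            "traits": ";".join(iv.traits), "chrom": iv.chrom,
            "cM_start": iv.cm_start, "cM_end": iv.cm_end,
            "bp_start": iv.bp_start, "bp_end": iv.bp_end,
            "anchors": ";".join(iv.anchor_markers),
            "methods": ";".join(iv.supporting_methods),
            "adjusted_R2": iv.pve,
        }
        for iv in intervals
    ]
    return pd.DataFrame(rows)


__all__ = [
    "LdMatrix",
    "compute_ld",
    "ld_expand",
    "tally_reliable",
    "QTLInterval",
    "CmBpSmoother",
    "fit_cm_bp_smoother",
    "build_intervals",
    "merge_across_traits",
    "pve_adjusted_r2",
    "intervals_to_frame",
]
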