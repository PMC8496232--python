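"""Drivers for the simulation benchmark: parameter-recovery summaries and
the prediction-accuracy grid over QTL architectures and heritabilities.

The grid reproduces the benchmark design: a fully-informative four-way
cross of 188 offspring and 3,961 markers; two correlated traits
(rho_B = 0.8, sigma2_B = 0.1, rho_E = 0) with s QTLs laid out either on
shared ("same") or disjoint ("diff") markers; target narrow-sense
heritabilities {0.1, 0.2, 0.4, 0.8}; seven prediction methods (interval
mapping, ridge, LASSO, elastic net and the three multi-task counterparts)
evaluated by nested cross-validation against the true genetic values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import evaluation as ev
from . import interval_mapping as im
from . import trait_sim
from .cross_sim import CrossSimConfig, simulate_cross
from .encoding import encode_design
from .gp_methods import FoldCache

H2_GRID = (0.1, 0.2, 0.4, 0.8)
S_GRID = (2, 50)
DISTRIBUTIONS = ("same", "diff")


def build_study_cross(seed: int):
    """Full-size synthetic cross + design + marker-level probability grid."""
    cfg = CrossSimConfig(seed=seed)
    gm, geno = simulate_cross(cfg)
    X = encode_design(geno)
    grid = im.calc_genoprob(geno, gm, step_cM=None)
    return gm, geno, X, grid


def default_method_specs(reduced: bool = True):
    """The seven main prediction methods.

    ``reduced`` uses the desk-scale tuning grids (8 lambdas over 2 decades,
    elastic-net alpha in {0.3, 0.7}, CV solver tolerance 1e-3); otherwise
    the full defaults (100/500-value lambda paths, 20 alphas).
    """
    if reduced:
        lasso_kw = dict(lambda_count=8, lambda_decades=2, tol=1e-3,
                        max_active=1000)
        en_kw = dict(alpha_grid=[0.3, 0.7], **lasso_kw)
        rr_kw = dict(lambda_count=30, lambda_decades=2)
    else:
        lasso_kw, en_kw, rr_kw = {}, {"alpha_grid": None}, {}
    return [
        ev.IntervalMappingSpec("SIM", n_perm=10),
        ev.PenalizedSpec("RR", **rr_kw),
        ev.PenalizedSpec("LASSO", **lasso_kw),
        ev.PenalizedSpec("EN", **en_kw),
        ev.PenalizedSpec("MTV_RR", **rr_kw),
        ev.PenalizedSpec("MTV_LASSO", **lasso_kw),
        ev.PenalizedSpec("MTV_EN", **en_kw),
    ]


def effect_recovery_summary(X, gm, n_replicates: int = 100, seed: int = 0,
                            s: int = 50):
    """Mean sample variance of trait-1's nonzero drawn effects."""
    out = []
    for rep in range(n_replicates):
        cfg = trait_sim.SimulationConfig(s=s, base_seed=seed + rep)
        qtl = trait_sim.place_qtls(gm, cfg, seed=seed + rep)
        eff = trait_sim.draw_effects(
            qtl, X, cfg, np.random.SeedSequence([seed + rep, 1])
        )
        out.append(float(np.var(eff.nonzero_effects(0), ddof=1)))
    return float(np.mean(out))


def simulation_recovery_summary(X, gm, n_replicates: int = 30, seed: int = 0,
                                s: int = 50, h2: float = 0.8):
    """Mean realized genetic correlation and heritability over replicates."""
    cors, h2s = [], []
    cfg = trait_sim.SimulationConfig(s=s, h2=h2, base_seed=seed)
    for rep in range(n_replicates):
        panel = trait_sim.simulate_replicate(X, gm, cfg, replicate=rep)
        cors.append(panel.realized_genetic_cor)
        h2s.append(float(np.mean(panel.realized_h2)))
    return float(np.mean(cors)), float(np.mean(h2s))


def run_simulation_grid(
    gm,
    X,
    probgrid,
    specs=None,
    s_values=S_GRID,
    distributions=DISTRIBUTIONS,
    h2_values=H2_GRID,
    t: int = 3,
    k1: int = 5,
    k2: int = 3,
    seed: int = 0,
    progress=None,
) -> pd.DataFrame:
    """Nested-CV prediction accuracy for every grid cell.

    Returns one row per (s, distribution, h2, method) with the accuracy
    (Pearson correlation of predictions with the true genetic values)
    averaged over traits, replicates and outer folds.
    """
    if specs is None:
        specs = default_method_specs()
    cache = FoldCache(X.X)
    rows = []
    for s in s_values:
        for dist in distributions:
            for h2 in h2_values:
                per_rep = []
                for rep in range(t):
                    cfg = trait_sim.SimulationConfig(
                        s=s, distribution=dist, h2=h2,
                        base_seed=seed + 37 * rep,
                    )
                    panel = trait_sim.simulate_replicate(X, gm, cfg,
                                                         replicate=rep)
                    res = ev.nested_cv(
                        specs, panel.Y,
                        ev.CvConfig(k1=k1, k2=k2, r=1, seed=seed + rep),
                        X=X.X, probgrid=probgrid, truth=panel.G,
                        cache=cache,
                    )
                    per_rep.append(res.groupby("method")["corP"].mean())
                    if progress is not None:
                        progress(s, dist, h2, rep)
                cell = pd.concat(per_rep, axis=1).mean(axis=1)
                for method, acc in cell.items():
                    rows.append({"s": s, "distribution": dist, "h2": h2,
                                 "method": method, "accuracy": float(acc)})
    return pd.DataFrame(rows)


__all__ = [
    "H2_GRID",
    "S_GRID",
    "DISTRIBUTIONS",
    "build_study_cross",
    "default_method_specs",
    "effect_recovery_summary",
    "simulation_recovery_summary",
    "run_simulation_grid",
]
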