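"""Matrix-variate simulation of correlated quantitative traits.

Traits follow Y = XB + E where X is the additive+dominance design, B holds
additive allelic effects at s QTL markers (dominance rows are zero) drawn
from a matrix-variate normal with between-trait genetic covariance V_B, and
error rows are i.i.d. multivariate normal with covariance V_E.  The error
variance of each trait is deduced from the realized genetic variance so the
trait hits its target narrow-sense heritability:
sigma2_E = var(G) * (1 - h2) / h2.

Two QTL layouts are supported: "same" (both traits share the s QTL markers,
effects correlated rho_B across traits) and "diff" (disjoint QTL sets per
trait, independent effects, hence no genetic correlation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cross_sim import GeneticMap
from .encoding import DesignMatrix


@dataclass
class SimulationConfig:
    """Trait-simulation parameters.

    Defaults are the benchmark's first simulation set: two traits, genetic
    correlation 0.8, per-trait genetic (effect) variance 0.1, uncorrelated
    errors, target heritabilities in {0.1, 0.2, 0.4, 0.8}, s in {2, 50}.
    The second set (s in {20, 200}, h2 = 0.1/0.5, sigma2_B = 1, rho_B = 0.5,
    "same") runs through the identical code path.
    """

    s: int = 50
    distribution: str = "same"  # "same" | "diff"
    h2: tuple[float, ...] | float = 0.8
    rho_B: float = 0.8
    sigma2_B: tuple[float, ...] | float = 0.1
    rho_E: float = 0.0
    k: int = 2
    t: int = 10
    base_seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        """Build from a study-table-style mapping.

        Accepts the field names used in study configuration files
        (``qtl_number``, ``heritability``, ``genetic_variance``,
        ``genetic_correlation``, ``qtl_distribution``, ``replicates``,
        ``seed``) as well as the dataclass field names.
        """
        alias = {
            "qtl_number": "s", "heritability": "h2",
            "genetic_variance": "sigma2_B",
            "genetic_correlation": "rho_B",
            "residual_correlation": "rho_E",
            "qtl_distribution": "distribution",
            "replicates": "t", "seed": "base_seed",
        }
        kw = {}
        for key, value in d.items():
            name = alias.get(key, key)
            if name not in cls.__dataclass_fields__:
                raise ValueError(f"unknown simulation parameter {key!r}")
            if isinstance(value, list):
                value = tuple(value)
            kw[name] = value
        return cls(**kw)

    def h2_per_trait(self) -> np.ndarray:
        h = np.broadcast_to(np.atleast_1d(np.asarray(self.h2, float)), (self.k,))
        return h.copy()

    def sigma2_B_per_trait(self) -> np.ndarray:
        s2 = np.broadcast_to(
            np.atleast_1d(np.asarray(self.sigma2_B, float)), (self.k,)
        )
        return s2.copy()

    def V_B(self) -> np.ndarray:
        sd = np.sqrt(self.sigma2_B_per_trait())
        V = np.outer(sd, sd) * self.rho_B
        np.fill_diagonal(V, sd**2)
        return V

    def validate(self, n_markers: int | None = None) -> None:
        if self.s <= 0:
            raise ValueError("s must be positive")
        if self.distribution not in ("same", "diff"):
            raise ValueError(f"unknown QTL distribution {self.distribution!r}")
        if not (abs(self.rho_B) <= 1 and abs(self.rho_E) <= 1):
            raise ValueError("correlations must lie in [-1, 1]")
        if np.any((self.h2_per_trait() <= 0) | (self.h2_per_trait() >= 1)):
            raise ValueError("h2 must lie strictly inside (0, 1)")
        if n_markers is not None:
            need = self.s if self.distribution == "same" else self.k * self.s
            if need > n_markers:
                raise ValueError(
                    f"{self.distribution!r} layout needs {need} distinct QTL "
                    f"markers but the map has only {n_markers}"
                )


@dataclass
class EffectsMatrix:
    """True allelic effects: p x k matrix plus QTL bookkeeping."""

    B: np.ndarray
    qtl_markers: list[list[str]]  # per trait
    V_B: np.ndarray

    def nonzero_effects(self, trait: int) -> np.ndarray:
        col = self.B[:, trait]
        return col[col != 0.0]


@dataclass
class TraitPanel:
    """Simulated trait values with their exact decomposition Y = G + E."""

    Y: np.ndarray
    G: np.ndarray
    E_mat: np.ndarray
    sigma2_E: np.ndarray
    realized_h2: np.ndarray
    realized_genetic_cor: float
    effects: EffectsMatrix

    def to_frame(self, offspring=None) -> pd.DataFrame:
        k = self.Y.shape[1]
        return pd.DataFrame(
            self.Y,
            index=offspring,
            columns=[f"trait{i + 1}" for i in range(k)],
        )


def _mvn_factor(V: np.ndarray) -> np.ndarray:
    """Factor L with L L^T = V for any positive semidefinite V (exact at 0)."""
    evals, Q = np.linalg.eigh(V)
    return Q * np.sqrt(np.maximum(evals, 0.0))


def place_qtls(
    genetic_map: GeneticMap, config: SimulationConfig, seed
) -> list[list[str]]:
    """Sample per-trait QTL marker sets uniformly without replacement."""
    config.validate(genetic_map.n_markers)
    rng = np.random.default_rng(seed)
    markers = genetic_map.markers
    if config.distribution == "same":
        chosen = rng.choice(len(markers), size=config.s, replace=False)
        shared = [markers[i] for i in np.sort(chosen)]
        return [list(shared) for _ in range(config.k)]
    chosen = rng.choice(len(markers), size=config.k * config.s, replace=False)
    sets = []
    for trait in range(config.k):
        block = np.sort(chosen[trait * config.s : (trait + 1) * config.s])
        sets.append([markers[i] for i in block])
    return sets


def draw_effects(
    qtl_sets: list[list[str]],
    design: DesignMatrix,
    config: SimulationConfig,
    seed,
) -> EffectsMatrix:
    """Draw additive allelic effects at the QTL markers.

    "same": the 4s additive rows shared by all traits are i.i.d. k-variate
    normal with covariance V_B.  "diff": each trait's 4s entries are i.i.d.
    N(0, sigma2_B) on its own rows, zero elsewhere.  Dominance rows stay 0.
    """
    rng = np.random.default_rng(seed)
    p, k = design.p, config.k
    B = np.zeros((p, k))
    if config.distribution == "same":
        rows = design.columns_for_markers(qtl_sets[0], kind="additive")
        L = _mvn_factor(config.V_B())
        B[rows, :] = rng.standard_normal((len(rows), k)) @ L.T
    else:
        s2 = config.sigma2_B_per_trait()
        for trait in range(k):
            rows = design.columns_for_markers(qtl_sets[trait], kind="additive")
            B[rows, trait] = rng.normal(0.0, np.sqrt(s2[trait]), size=len(rows))
    return EffectsMatrix(B=B, qtl_markers=qtl_sets, V_B=config.V_B())


def deduce_error_variance(G: np.ndarray, h2: float) -> float:
    """Error variance giving a trait with genetic values G heritability h2."""
    if not 0 < h2 < 1:
        raise ValueError("h2 must lie strictly inside (0, 1)")
    v = float(np.var(G, ddof=1))
    if v <= 0:
        raise ValueError(
            "genetic values have zero variance; redraw the effects"
        )
    return v * (1.0 - h2) / h2


def simulate_traits(
    design: DesignMatrix,
    effects: EffectsMatrix,
    config: SimulationConfig,
    seed,
) -> TraitPanel:
    """Simulate Y = XB + E with heritability-deduced error variances."""
    G = design.X @ effects.B
    h2 = config.h2_per_trait()
    sigma2_E = np.array(
        [deduce_error_variance(G[:, j], h2[j]) for j in range(config.k)]
    )
    sd = np.sqrt(sigma2_E)
    V_E = np.outer(sd, sd) * config.rho_E
    np.fill_diagonal(V_E, sigma2_E)
    rng = np.random.default_rng(seed)
    L = _mvn_factor(V_E)
    E = rng.standard_normal((design.n, config.k)) @ L.T
    Y = G + E
    var_g = np.var(G, axis=0, ddof=1)
    var_e = np.var(E, axis=0, ddof=1)
    realized_h2 = var_g / (var_g + var_e)
    if config.k >= 2 and var_g[0] > 0 and var_g[1] > 0:
        cor = float(np.corrcoef(G[:, 0], G[:, 1])[0, 1])
    else:
        cor = float("nan")
    return TraitPanel(
        Y=Y,
        G=G,
        E_mat=E,
        sigma2_E=sigma2_E,
        realized_h2=realized_h2,
        realized_genetic_cor=cor,
        effects=effects,
    )


def simulate_replicate(
    design: DesignMatrix,
    genetic_map: GeneticMap,
    config: SimulationConfig,
    replicate: int = 0,
) -> TraitPanel:
    """One full trait replicate; replicate i uses seed = base_seed + i."""
    seed = config.base_seed + replicate
    qtl_sets = place_qtls(genetic_map, config, seed)
    effects = draw_effects(
        qtl_sets, design, config, np.random.SeedSequence([seed, 1])
    )
    return simulate_traits(
        design, effects, config, np.random.SeedSequence([seed, 2])
    )


__all__ = [
    "SimulationConfig",
    "EffectsMatrix",
    "TraitPanel",
    "place_qtls",
    "draw_effects",
    "deduce_error_variance",
    "simulate_traits",
    "simulate_replicate",
]
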