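"""Simulation and I/O for a fully-informative four-way outbred cross.

A pseudo-F1 progeny arises from crossing two heterozygous parents; at a
fully-informative (abxcd) marker the maternal parent carries alleles a/b and
the paternal parent c/d, so every offspring falls in one of four genotype
classes {ac, ad, bc, bd} and the transmitted parental haplotypes are
unambiguous.  This module simulates a genetic map and such progeny genotypes
under a Markov (Haldane, no-interference) meiosis model, and reads/writes the
delimited formats used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

GENOTYPE_CLASSES = ("ac", "ad", "bc", "bd")

_MAP_COLUMNS = ["marker", "chrom", "pos_cM", "pos_bp"]


class GeneticMap:
    """Ordered marker map with genetic (cM) and physical (bp) coordinates.

    Wraps a :class:`pandas.DataFrame` with columns ``marker``, ``chrom``,
    ``pos_cM``, ``pos_bp``.  Markers are sorted by chromosome (in order of
    first appearance) then genetic position; within a chromosome genetic
    positions must be nondecreasing and physical positions strictly
    increasing; marker names are unique genome-wide.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in _MAP_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"map is missing columns: {missing}")
        df = df[_MAP_COLUMNS].copy()
        # keep chromosome order of first appearance, sort within chromosome
        chrom_order = {c: i for i, c in enumerate(pd.unique(df["chrom"]))}
        df["_c"] = df["chrom"].map(chrom_order)
        df = df.sort_values(["_c", "pos_cM"], kind="stable").drop(columns="_c")
        df = df.reset_index(drop=True)
        if df["marker"].duplicated().any():
            dup = df.loc[df["marker"].duplicated(), "marker"].iloc[0]
            raise ValueError(f"duplicate marker name: {dup!r}")
        if (df["pos_cM"] < 0).any():
            raise ValueError("negative genetic position")
        if (df["pos_bp"] <= 0).any():
            raise ValueError("physical positions must be positive")
        for chrom, sub in df.groupby("chrom", sort=False):
            bp = sub["pos_bp"].to_numpy()
            if np.any(np.diff(bp) <= 0):
                raise ValueError(
                    f"physical positions not strictly increasing on {chrom}"
                )
        self.df = df

    @property
    def n_markers(self) -> int:
        return len(self.df)

    @property
    def markers(self) -> np.ndarray:
        return self.df["marker"].to_numpy()

    @property
    def chromosomes(self) -> list:
        return list(pd.unique(self.df["chrom"]))

    def chrom_slice(self, chrom) -> slice:
        idx = np.flatnonzero((self.df["chrom"] == chrom).to_numpy())
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def marker_index(self, markers: Sequence[str]) -> np.ndarray:
        lookup = {m: i for i, m in enumerate(self.df["marker"])}
        try:
            return np.array([lookup[m] for m in markers], dtype=int)
        except KeyError as exc:
            raise KeyError(f"marker not on map: {exc.args[0]!r}") from None

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"GeneticMap({self.n_markers} markers, "
            f"{len(self.chromosomes)} chromosomes)"
        )


class PhasedGenotypes:
    """Offspring x marker table of four-way genotype classes.

    ``df`` is indexed by offspring id with one column per marker, values in
    {ac, ad, bc, bd}; column order follows the map.  No missing values are
    allowed anywhere (the downstream methods assume complete data).
    """

    def __init__(self, df: pd.DataFrame, genetic_map: GeneticMap):
        if list(df.columns) != list(genetic_map.markers):
            if set(df.columns) == set(genetic_map.markers):
                df = df[list(genetic_map.markers)]
            else:
                raise ValueError("genotype columns do not match the map markers")
        if df.isna().any().any():
            raise ValueError("missing genotype values are not supported")
        values = df.to_numpy(dtype=object)
        bad = ~np.isin(values, GENOTYPE_CLASSES)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"unknown genotype class {values[i, j]!r} at offspring "
                f"{df.index[i]!r}, marker {df.columns[j]!r}"
            )
        self.df = df
        self.map = genetic_map

    @property
    def n_offspring(self) -> int:
        return len(self.df)

    def class_codes(self) -> np.ndarray:
        """Integer codes 0..3 in the order (ac, ad, bc, bd)."""
        code = {g: i for i, g in enumerate(GENOTYPE_CLASSES)}
        return self.df.apply(lambda col: col.map(code)).to_numpy(dtype=np.int8)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhasedGenotypes({self.n_offspring} x {self.df.shape[1]})"


@dataclass
class CrossSimConfig:
    """Configuration for the synthetic cross.

    The defaults emulate the shape of the study population this package
    benchmarks against: 188 offspring genotyped at 3,961 fully-informative
    markers spread over 19 chromosomes (19 x 208 plus nine chromosomes with
    one extra marker).
    """

    n_offspring: int = 188
    n_chromosomes: int = 19
    markers_per_chromosome: int | Sequence[int] = field(
        default_factory=lambda: [209] * 9 + [208] * 10
    )
    chrom_length_cM: float = 80.0
    chrom_length_bp: int = 20_000_000
    spacing: str = "equidistant"  # or "uniform"
    seed: int = 0

    def marker_counts(self) -> list[int]:
        m = self.markers_per_chromosome
        counts = [int(m)] * self.n_chromosomes if np.isscalar(m) else [int(x) for x in m]
        if len(counts) != self.n_chromosomes:
            raise ValueError(
                "markers_per_chromosome length must equal n_chromosomes"
            )
        return counts

    def validate(self) -> None:
        if self.n_offspring <= 0:
            raise ValueError("n_offspring must be positive")
        if self.n_chromosomes <= 0:
            raise ValueError("n_chromosomes must be positive")
        if any(c <= 0 for c in self.marker_counts()):
            raise ValueError("markers_per_chromosome must be positive")
        if self.chrom_length_cM <= 0 or self.chrom_length_bp <= 0:
            raise ValueError("chromosome lengths must be positive")
        if self.spacing not in ("equidistant", "uniform"):
            raise ValueError(f"unknown spacing {self.spacing!r}")


def haldane_r(d_cM) -> np.ndarray | float:
    """Haldane map function: recombination fraction for a distance in cM.

    r = (1 - exp(-2 d / 100)) / 2, in [0, 0.5).  No crossover interference.
    """
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distance must be nonnegative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if np.isscalar(d_cM) else r


def simulate_map(config: CrossSimConfig) -> GeneticMap:
    """Simulate a genetic map per :class:`CrossSimConfig`.

    Genetic positions are equidistant on [0, chrom_length_cM] (or sorted
    uniform draws with ``spacing="uniform"``); physical positions are
    cumulative sums of random positive increments scaled to
    ``chrom_length_bp``, giving a strictly increasing, randomly nonlinear
    cM->bp relation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    for ci, m in enumerate(config.marker_counts()):
        chrom = f"chr{ci + 1:02d}"
        if config.spacing == "equidistant":
            cm = (
                np.linspace(0.0, config.chrom_length_cM, m)
                if m > 1
                else np.array([0.0])
            )
        else:
            cm = np.sort(rng.uniform(0.0, config.chrom_length_cM, size=m))
        incr = rng.gamma(shape=2.0, scale=1.0, size=m)
        bp = np.cumsum(incr)
        bp = np.ceil(bp / bp[-1] * config.chrom_length_bp).astype(np.int64)
        bp = np.maximum.accumulate(bp)  # guard against rounding ties
        bp += np.arange(m)  # enforce strict increase
        for k in range(m):
            rows.append((f"{chrom}_m{k + 1:04d}", chrom, float(cm[k]), int(bp[k])))
    return GeneticMap(pd.DataFrame(rows, columns=_MAP_COLUMNS))


def _simulate_parent_chain(
    rng: np.random.Generator, n: int, d_cM: np.ndarray
) -> np.ndarray:
    """Two-state Markov allele chain along one chromosome for n offspring.

    Returns an (n, m) int8 array of 0/1 parental-allele states; switch
    probability between adjacent markers is the Haldane recombination
    fraction of their distance.
    """
    m = len(d_cM) + 1
    states = np.empty((n, m), dtype=np.int8)
    states[:, 0] = rng.integers(0, 2, size=n)
    if m > 1:
        r = haldane_r(d_cM)
        switches = rng.random((n, m - 1)) < r[None, :]
        states[:, 1:] = states[:, [0]] ^ np.cumsum(switches, axis=1) % 2
    return states


def simulate_progeny(
    genetic_map: GeneticMap, config: CrossSimConfig
) -> PhasedGenotypes:
    """Simulate fully-informative four-way progeny genotypes.

    Maternal (a/b) and paternal (c/d) allele sequences are independent
    two-state Markov chains per chromosome with Haldane switch probabilities;
    chromosomes segregate independently; the genotype class is the allele
    pair.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.n_offspring
    columns = {}
    for chrom in genetic_map.chromosomes:
        sl = genetic_map.chrom_slice(chrom)
        cm = genetic_map.df["pos_cM"].to_numpy()[sl]
        d = np.diff(cm)
        maternal = _simulate_parent_chain(rng, n, d)  # 0=a, 1=b
        paternal = _simulate_parent_chain(rng, n, d)  # 0=c, 1=d
        classes = maternal * 2 + paternal  # 0:ac 1:ad 2:bc 3:bd
        class_labels = np.array(GENOTYPE_CLASSES, dtype=object)
        names = genetic_map.markers[sl]
        for j, name in enumerate(names):
            columns[name] = class_labels[classes[:, j]]
    df = pd.DataFrame(
        columns, index=[f"off{i + 1:03d}" for i in range(n)]
    )
    df.index.name = "offspring"
    return PhasedGenotypes(df, genetic_map)


def simulate_cross(
    config: CrossSimConfig,
) -> tuple[GeneticMap, PhasedGenotypes]:
    """Convenience: simulate map then progeny from one config."""
    genetic_map = simulate_map(config)
    return genetic_map, simulate_progeny(genetic_map, config)


# ---------------------------------------------------------------------------
# Delimited file I/O (TSV)
# ---------------------------------------------------------------------------

def write_map(genetic_map: GeneticMap, path) -> None:
    genetic_map.df.to_csv(path, sep="\t", index=False)


def load_map(path) -> GeneticMap:
    return GeneticMap(pd.read_csv(path, sep="\t"))


def write_genotypes(genotypes: PhasedGenotypes, path) -> None:
    genotypes.df.to_csv(path, sep="\t")


def load_genotypes(path, genetic_map: GeneticMap) -> PhasedGenotypes:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return PhasedGenotypes(df, genetic_map)


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, sep="\t")


def load_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError("missing phenotype values are not supported")
    return df.astype(float)


__all__ = [
    "GENOTYPE_CLASSES",
    "GeneticMap",
    "PhasedGenotypes",
    "CrossSimConfig",
    "haldane_r",
    "simulate_map",
    "simulate_progeny",
    "simulate_cross",
    "write_map",
    "load_map",
    "write_genotypes",
    "load_genotypes",
    "write_phenotypes",
    "load_phenotypes",
]
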