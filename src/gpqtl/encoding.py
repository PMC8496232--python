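"""Design-matrix encoding of four-way genotype classes.

Each marker contributes eight columns: four additive columns counting the
a, b, c, d parental alleles carried by the offspring (each 0/1 here, since
one maternal and one paternal allele are transmitted), and four dominance
columns indicating the genotype class (ac, ad, bc, bd).  For m markers the
design has p = 8m columns; within a marker the additive block row-sums to 2
and the dominance block to 1, a known collinearity absorbed by penalized
fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cross_sim import GENOTYPE_CLASSES, GeneticMap, PhasedGenotypes

ADDITIVE_LABELS = ("a", "b", "c", "d")

# rows: class code (ac, ad, bc, bd); columns: allele counts (a, b, c, d)
_CLASS_TO_ADDITIVE = np.array(
    [
        [1, 0, 1, 0],  # ac
        [1, 0, 0, 1],  # ad
        [0, 1, 1, 0],  # bc
        [0, 1, 0, 1],  # bd
    ],
    dtype=np.float64,
)


@dataclass
class DesignMatrix:
    """n x 8m predictor matrix with per-column metadata.

    ``columns`` has one row per predictor with fields ``marker``, ``kind``
    ("additive" | "dominance") and ``label`` (allele a/b/c/d or class
    ac/ad/bc/bd); columns are grouped by marker in map order, additive block
    first.
    """

    X: np.ndarray
    columns: pd.DataFrame
    map: GeneticMap
    offspring: pd.Index

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def additive_column_index(self) -> np.ndarray:
        return np.flatnonzero((self.columns["kind"] == "additive").to_numpy())

    @property
    def dominance_column_index(self) -> np.ndarray:
        return np.flatnonzero((self.columns["kind"] == "dominance").to_numpy())

    def marker_of_column(self) -> np.ndarray:
        return self.columns["marker"].to_numpy()

    def columns_for_markers(
        self, markers: Sequence[str], kind: str | None = None
    ) -> np.ndarray:
        """Column indices for the requested markers, preserving map order."""
        wanted = set(markers)
        unknown = wanted - set(self.map.markers)
        if unknown:
            raise KeyError(f"markers not on map: {sorted(unknown)[:3]}")
        mask = self.columns["marker"].isin(wanted).to_numpy()
        if kind is not None:
            mask &= (self.columns["kind"] == kind).to_numpy()
        return np.flatnonzero(mask)


def encode_design(genotypes: PhasedGenotypes) -> DesignMatrix:
    """Encode genotype classes into the 8-columns-per-marker design."""
    codes = genotypes.class_codes()  # (n, m) with 0..3
    n, m = codes.shape
    add = _CLASS_TO_ADDITIVE[codes]          # (n, m, 4)
    dom = np.eye(4, dtype=np.float64)[codes]  # (n, m, 4)
    blocks = np.concatenate([add, dom], axis=2)  # (n, m, 8)
    X = blocks.reshape(n, 8 * m)
    meta = pd.DataFrame(
        {
            "marker": np.repeat(genotypes.map.markers, 8),
            "kind": np.tile(
                np.array(["additive"] * 4 + ["dominance"] * 4, dtype=object), m
            ),
            "label": np.tile(
                np.array(list(ADDITIVE_LABELS) + list(GENOTYPE_CLASSES), dtype=object),
                m,
            ),
        }
    )
    return DesignMatrix(X=X, columns=meta, map=genotypes.map,
                        offspring=genotypes.df.index)


def additive_submatrix(design: DesignMatrix, markers: Sequence[str]) -> np.ndarray:
    """The 4 additive columns of each requested marker, in map order."""
    idx = design.columns_for_markers(markers, kind="additive")
    return design.X[:, idx]


def dose_matrix(genotypes: PhasedGenotypes) -> np.ndarray:
    """0/1/2 dose recoding: count of maternal allele a plus paternal allele c.

    A biallelic-style summary used for LD computation and PVE regressions;
    no core fitting step depends on it.
    """
    codes = genotypes.class_codes()
    dose = np.zeros_like(codes, dtype=np.float64)
    dose += (codes <= 1)          # carries maternal a (classes ac, ad)
    dose += (codes % 2 == 0)      # carries paternal c (classes ac, bc)
    return dose


def write_design(design: DesignMatrix, path) -> None:
    header = [
        f"{m}:{k[0]}:{l}"
        for m, k, l in design.columns.itertuples(index=False)
    ]
    pd.DataFrame(design.X, index=design.offspring, columns=header).to_csv(
        path, sep="\t"
    )


__all__ = [
    "ADDITIVE_LABELS",
    "DesignMatrix",
    "encode_design",
    "additive_submatrix",
    "dose_matrix",
    "write_design",
]
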