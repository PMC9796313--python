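"""Confrontation-assay grid analysis.

A co-culture agar plate is cut into a lattice of blocks (the study used
9 columns x 4 rows of 1 cm x 1 cm blocks spanning the zone between the
fungal and bacterial colonies). Each block is assayed for metabolite
concentrations and for yellow-pigment absorbance at 400 nm. This module
reshapes the block table into per-analyte heatmap matrices and
quantifies the spatial association between any analyte and the pigment
signal with Spearman rank correlation (average ranks for ties, t
approximation for p, optional permutation p).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ABSORBANCE = "absorbance_400nm"


@dataclass
class SpatialGrid:
    """Long-format block lattice: one row per (row, col, analyte).

    Row 1 is the top of the plate photograph, column 1 the left. Missing
    blocks are allowed and simply absent from the table. The absorbance
    channel is stored as analyte ``"absorbance_400nm"``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"row", "col", "analyte", "value"}
        if not required <= set(self.data.columns):
            raise ValueError(f"grid table needs columns {sorted(required)}")
        df = self.data.copy()
        df["row"] = df["row"].astype(int)
        df["col"] = df["col"].astype(int)
        df["value"] = df["value"].astype(float)
        if (df["row"] < 1).any() or (df["col"] < 1).any():
            raise ValueError("grid indices are 1-based")
        if (df["value"] < 0).any():
            raise ValueError("concentrations/absorbances must be >= 0")
        if df.duplicated(["row", "col", "analyte"]).any():
            raise ValueError("duplicate (row, col, analyte) entries")
        self.data = df

    @property
    def analytes(self) -> list[str]:
        return sorted(self.data["analyte"].unique())

    @property
    def n_rows(self) -> int:
        return int(self.data["row"].max())

    @property
    def n_cols(self) -> int:
        return int(self.data["col"].max())

    def values(self, analyte: str) -> pd.Series:
        """Values of one analyte indexed by (row, col) block position."""
        if analyte not in set(self.data["analyte"]):
            raise KeyError(f"unknown analyte {analyte!r}")
        sub = self.data[self.data["analyte"] == analyte]
        return sub.set_index(["row", "col"])["value"].sort_index()


@dataclass
class SpatialAssociation:
    """Rank association between one analyte and a reference channel."""

    analyte: str
    reference: str
    n: int
    rho: float
    p: float
    degenerate: bool = False
    perm_p: float | None = None
    n_perm: int = 0


def grid_matrix(grid: SpatialGrid, analyte: str) -> pd.DataFrame:
    """Row x col matrix of one analyte, missing blocks as NaN.

    Rows/columns cover the full 1..max range so exported heatmaps keep
    the plate geometry even around missing blocks.
    """
    vals = grid.values(analyte)
    mat = vals.unstack("col")
    mat = mat.reindex(index=range(1, grid.n_rows + 1), columns=range(1, grid.n_cols + 1))
    mat.index.name = "row"
    mat.columns.name = "col"
    return mat


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(
    grid: SpatialGrid,
    analyte: str,
    reference: str = ABSORBANCE,
    n_perm: int = 0,
    seed: int | None = None,
) -> SpatialAssociation:
    """Spearman rho between an analyte and a reference across blocks.

    Ties receive average ranks; rho is the Pearson correlation of the
    ranks. The parametric p uses ``t = rho*sqrt((n-2)/(1-rho^2))`` on
    n-2 degrees of freedom, two-sided. With ``n_perm > 0`` an add-one
    corrected permutation p over random relabelings of the reference is
    also reported. Blocks missing either value are dropped pairwise.
    """
    x = grid.values(analyte)
    y = grid.values(reference)
    paired = pd.concat([x, y], axis=1, join="inner").dropna()
    n = len(paired)
    if n < 4:
        raise ValueError(f"need >= 4 complete paired blocks, got {n}")
    xv = paired.iloc[:, 0].to_numpy()
    yv = paired.iloc[:, 1].to_numpy()
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return SpatialAssociation(analyte, reference, n, float("nan"), float("nan"),
                                  degenerate=True)
    rho = _spearman_rho(xv, yv)
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    assoc = SpatialAssociation(analyte, reference, n, rho, p)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        rx = stats.rankdata(xv)
        ry = stats.rankdata(yv)
        rxc = rx - rx.mean()
        denom = np.sqrt((rxc**2).sum())
        hits = 0
        for _ in range(n_perm):
            ryp = rng.permutation(ry)
            ryc = ryp - ryp.mean()
            r = float(rxc @ ryc / (denom * np.sqrt((ryc**2).sum())))
            if abs(r) >= abs(rho) - 1e-12:
                hits += 1
        assoc.perm_p = (1 + hits) / (n_perm + 1)
        assoc.n_perm = n_perm
    return assoc


def correlation_matrix(grid: SpatialGrid, analytes=None) -> pd.DataFrame:
    """Symmetric analyte x analyte Spearman rho matrix (unit diagonal)."""
    analytes = list(analytes) if analytes is not None else grid.analytes
    if len(analytes) < 2:
        raise ValueError("need at least two analytes")
    mat = pd.DataFrame(np.eye(len(analytes)), index=analytes, columns=analytes)
    for i, a in enumerate(analytes):
        for b in analytes[i + 1:]:
            va, vb = grid.values(a), grid.values(b)
            paired = pd.concat([va, vb], axis=1, join="inner").dropna()
            xv, yv = paired.iloc[:, 0].to_numpy(), paired.iloc[:, 1].to_numpy()
            if np.ptp(xv) == 0 or np.ptp(yv) == 0:
                rho = float("nan")
            else:
                rho = _spearman_rho(xv, yv)
            mat.loc[a, b] = mat.loc[b, a] = rho
    return mat
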