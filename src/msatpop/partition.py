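"""Coancestry-based partition of gene diversity and leave-one-out breed
contributions (the Caballero–Toro decomposition).

For n breeds with coancestry matrix f, total gene diversity splits
additively into within- and between-breed components:

    GD_T  = 1 - sum_ij f_ij / n^2
    GD_WS = 1 - sum_i  f_ii / n
    GD_BS = sum_ij D_ij / n^2          (D_ij = Nei's minimum distance)

A breed's contribution is the change in each component when it is removed
and the partition recomputed on the remaining n-1 breeds (denominators
use n-1): Delta GD = GD(without breed) - GD(all); negative Delta GD_T
means removing the breed loses total diversity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .distances import CoancestryMatrix, nei_minimum_distance


@dataclass
class PartitionResult:
    """Diversity partition of a breed set plus per-breed removal effects."""

    breeds: list[str]
    n: int
    gd_t: float
    gd_ws: float
    gd_bs: float
    delta_ws: np.ndarray
    delta_bs: np.ndarray
    delta_t: np.ndarray
    he: np.ndarray | None = None  # per-breed expected heterozygosity, if supplied

    def to_frame(self) -> pd.DataFrame:
        """Delta values x10^3, sorted by Delta GD_T ascending (largest loss first)."""
        df = pd.DataFrame({
            "breed": self.breeds,
            "delta_gd_ws_x1000": self.delta_ws * 1e3,
            "delta_gd_bs_x1000": self.delta_bs * 1e3,
            "delta_gd_t_x1000": self.delta_t * 1e3,
        })
        if self.he is not None:
            df["he"] = self.he
        return df.sort_values("delta_gd_t_x1000").reset_index(drop=True)


def diversity_partition(f: CoancestryMatrix) -> tuple[float, float, float]:
    """(GD_T, GD_WS, GD_BS) for a complete coancestry matrix.

    The additive identity GD_T = GD_WS + GD_BS holds exactly because the
    between component is evaluated through Nei's minimum distance.
    """
    vals = f.values
    if np.isnan(vals).any():
        bad = np.argwhere(np.isnan(vals))
        i, j = bad[0]
        raise ValueError(
            f"coancestry undefined for breed pair ({f.breeds[i]}, {f.breeds[j]})"
        )
    n = f.n
    gd_t = 1.0 - vals.sum() / n ** 2
    gd_ws = 1.0 - np.trace(vals) / n
    d = nei_minimum_distance(f).values
    gd_bs = d.sum() / n ** 2
    return float(gd_t), float(gd_ws), float(gd_bs)


def _submatrix(f: CoancestryMatrix, drop: int) -> CoancestryMatrix:
    keep = np.arange(f.n) != drop
    return CoancestryMatrix(
        [b for k, b in zip(keep, f.breeds) if k],
        f.values[np.ix_(keep, keep)],
        f.n_loci_used[np.ix_(keep, keep)],
    )


def breed_contributions(
    f: CoancestryMatrix, he: np.ndarray | None = None
) -> PartitionResult:
    """Leave-one-out contribution of every breed to the diversity partition."""
    if f.n < 2:
        raise ValueError("leave-one-out contributions require at least two breeds")
    gd_t, gd_ws, gd_bs = diversity_partition(f)
    d_ws = np.empty(f.n)
    d_bs = np.empty(f.n)
    d_t = np.empty(f.n)
    for i in range(f.n):
        t_i, ws_i, bs_i = diversity_partition(_submatrix(f, i))
        d_t[i] = t_i - gd_t
        d_ws[i] = ws_i - gd_ws
        d_bs[i] = bs_i - gd_bs
    return PartitionResult(
        breeds=list(f.breeds), n=f.n, gd_t=gd_t, gd_ws=gd_ws, gd_bs=gd_bs,
        delta_ws=d_ws, delta_bs=d_bs, delta_t=d_t,
        he=None if he is None else np.asarray(he, dtype=float),
    )


def contribution_he_correlation(result: PartitionResult) -> dict[str, float]:
    """Pearson correlations of per-breed He with each Delta GD component.

    Returns NaN for a component (or He) with zero variance.
    """
    if result.he is None:
        raise ValueError("PartitionResult carries no per-breed He")
    if result.n < 3:
        raise ValueError("correlation requires at least three breeds")
    out: dict[str, float] = {"n": result.n}
    for key, vec in (
        ("r_he_delta_ws", result.delta_ws),
        ("r_he_delta_bs", result.delta_bs),
        ("r_he_delta_t", result.delta_t),
    ):
        if np.std(result.he) == 0 or np.std(vec) == 0:
            out[key] = float("nan")
        else:
            out[key] = float(sps.pearsonr(result.he, vec).statistic)
    return out
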