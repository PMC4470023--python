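"""Coancestry and genetic distances between breeds.

The breed x breed coancestry f_ij is the per-locus cross-product of allele
frequencies sum_k p_ki * p_kj, averaged over loci (pairwise-complete: loci
undefined in either breed are dropped for that pair).  Nei's minimum
distance and the Reynolds least-squares coancestry distance are derived
from the same frequency table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genodata import AlleleFrequencyTable


@dataclass
class CoancestryMatrix:
    """Mean-over-loci coancestry f_ij; f_ii is breed i's expected homozygosity."""

    breeds: list[str]
    values: np.ndarray          # (n, n) symmetric
    n_loci_used: np.ndarray     # (n, n) shared defined-locus counts

    @property
    def n(self) -> int:
        return len(self.breeds)


@dataclass
class DistanceMatrix:
    breeds: list[str]
    values: np.ndarray
    metric: str  # "nei_minimum" | "reynolds"


def _per_locus_cross(freq: AlleleFrequencyTable):
    """Yield per-locus (cross, selfdot, defined) matrices."""
    for l in range(len(freq.loci)):
        p = freq.frequencies(l)  # (nb, n_alleles), NaN rows undefined
        defined = ~np.isnan(p[:, 0]) if p.shape[1] else np.zeros(freq.n_breeds, bool)
        q = np.where(np.isnan(p), 0.0, p)
        cross = q @ q.T
        yield cross, np.diag(cross).copy(), defined


def coancestry_matrix(freq: AlleleFrequencyTable) -> CoancestryMatrix:
    """Breed x breed coancestry averaged over shared defined loci.

    A pair with no shared defined locus gets NaN (propagates as an explicit
    error into the diversity partition).
    """
    nb = freq.n_breeds
    acc = np.zeros((nb, nb))
    cnt = np.zeros((nb, nb), dtype=np.int64)
    for cross, _, defined in _per_locus_cross(freq):
        mask = np.outer(defined, defined)
        acc[mask] += cross[mask]
        cnt += mask
    with np.errstate(invalid="ignore", divide="ignore"):
        values = acc / cnt
    values[cnt == 0] = np.nan
    return CoancestryMatrix(list(freq.breeds), values, cnt)


def nei_minimum_distance(f: CoancestryMatrix) -> DistanceMatrix:
    """D_ij = (f_ii + f_jj)/2 - f_ij, zero diagonal."""
    d = (np.diag(f.values)[:, None] + np.diag(f.values)[None, :]) / 2.0 - f.values
    np.fill_diagonal(d, 0.0)
    # non-negative up to rounding (Cauchy-Schwarz per locus); clamp tiny noise
    d[(d < 0) & (d > -1e-12)] = 0.0
    return DistanceMatrix(list(f.breeds), d, "nei_minimum")


def reynolds_distance(
    freq: AlleleFrequencyTable, log_transform: bool = False
) -> DistanceMatrix:
    """Reynolds least-squares coancestry distance.

    D_R = [sum_l sum_k (p_ki - p_kj)^2] / [2 sum_l (1 - sum_k p_ki p_kj)],
    loci pooled before the ratio (the PHYLIP convention).  A pair with zero
    denominator (both breeds fixed for the same allele everywhere) is 0 by
    convention.  ``log_transform`` applies -ln(1 - D_R).
    """
    nb = freq.n_breeds
    num = np.zeros((nb, nb))
    den = np.zeros((nb, nb))
    for cross, selfdot, defined in _per_locus_cross(freq):
        mask = np.outer(defined, defined)
        sq = selfdot[:, None] + selfdot[None, :] - 2.0 * cross
        num[mask] += sq[mask]
        den[mask] += (1.0 - cross)[mask]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = num / (2.0 * den)
    d[(den == 0) & (num == 0)] = 0.0
    np.fill_diagonal(d, 0.0)
    d[(d < 0) & (d > -1e-12)] = 0.0
    if log_transform:
        d = -np.log1p(-d)
    return DistanceMatrix(list(freq.breeds), d, "reynolds")


# -- PHYLIP square-matrix text -------------------------------------------


def write_phylip_matrix(
    dist: DistanceMatrix, path: str | Path, strict_names: bool = True
) -> None:
    """Write a square PHYLIP distance matrix (count line + name-padded rows).

    In strict mode names are truncated to 10 characters; a collision after
    truncation is an error.
    """
    names = list(dist.breeds)
    if strict_names:
        short = [n[:10] for n in names]
        if len(set(short)) != len(short):
            clashes = sorted({s for s in short if short.count(s) > 1})
            raise ValueError(f"breed names collide after 10-char truncation: {clashes}")
        names = short
    width = max(10, max(len(n) for n in names))
    lines = [f"{len(names)}"]
    for name, row in zip(names, dist.values):
        vals = " ".join(f"{v:.6f}" for v in row)
        lines.append(f"{name:<{width}} {vals}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_phylip_matrix(path: str | Path, metric: str = "unknown") -> DistanceMatrix:
    lines = Path(path).read_text().splitlines()
    n = int(lines[0].split()[0])
    names, rows = [], []
    for line in lines[1 : n + 1]:
        parts = line.split()
        names.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    return DistanceMatrix(names, np.asarray(rows), metric)
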