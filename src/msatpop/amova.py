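"""Hierarchical analysis of molecular variance (AMOVA) with permutation
significance.

Three strata: among groups (sigma2_a), among breeds within groups
(sigma2_b), within breeds (sigma2_c).  Allele copies are the units, with
0/1 identity distance (same/different allele); the within-individual level
is pooled into the within-breed stratum.  Sums of squared deviations and
variance components are computed per locus (unequal-size moment
coefficients) and components summed over loci; F-statistics come from the
summed components:

    F_CT = sa / (sa + sb + sc)
    F_SC = sb / (sb + sc)
    F_ST = (sa + sb) / (sa + sb + sc)

A one-group design collapses to the two-level AMOVA (among breeds /
within breeds), in which case only F_ST is defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeDataset


@dataclass
class AmovaResult:
    """Variance components, F-statistics and (optionally) permutation p-values."""

    sigma_a: float
    sigma_b: float
    sigma_c: float
    df: dict
    f_ct: float
    f_sc: float
    f_st: float
    n_groups: int
    n_breeds: int
    p_values: dict = field(default_factory=dict)
    n_permutations: int = 0

    def percentages(self) -> dict[str, float]:
        """Components as % of total, negatives truncated to 0 then renormalized."""
        comps = np.array([self.sigma_a, self.sigma_b, self.sigma_c])
        comps = np.clip(comps, 0.0, None)
        tot = comps.sum()
        if tot == 0:
            return {"among_groups": np.nan, "among_breeds_within_groups": np.nan,
                    "within_breeds": np.nan}
        pct = 100.0 * comps / tot
        return {"among_groups": float(pct[0]),
                "among_breeds_within_groups": float(pct[1]),
                "within_breeds": float(pct[2])}

    def to_frame(self, label: str = "") -> pd.DataFrame:
        pct = self.percentages()
        row = {"grouping": label, **pct,
               "f_ct": self.f_ct, "f_sc": self.f_sc, "f_st": self.f_st}
        for k, v in self.p_values.items():
            row[f"p_{k}"] = v
        return pd.DataFrame([row])


def _locus_designs(ds: GenotypeDataset, breeds: list[str]):
    """Per locus: (allele index per copy, breed index per copy) for typed calls."""
    bmap = {b: i for i, b in enumerate(breeds)}
    breed_i = np.asarray([bmap[b] for b in ds.breed_of], dtype=np.intp)
    designs = []
    for l in range(ds.n_loci):
        col = ds.calls[:, l, :]
        typed = np.all(col != MISSING, axis=1)
        if not typed.any():
            continue
        codes, inv = np.unique(col[typed], return_inverse=True)
        designs.append((
            inv.reshape(-1, 2),            # (n_typed, 2) allele index per call
            breed_i[typed],                # (n_typed,) breed per typed individual
            codes.size,
        ))
    return designs


def _ssd(counts: np.ndarray) -> np.ndarray:
    """SSD of sets of allele copies with 0/1 distance.

    ``counts``: (..., n_alleles) copy counts; SSD = (N^2 - sum c^2) / (2N).
    """
    N = counts.sum(axis=-1)
    sq = (counts ** 2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (N.astype(float) ** 2 - sq) / (2.0 * N)
    return np.where(N > 0, out, 0.0)


def _components_one_locus(
    breed_counts: np.ndarray, group_of_breed: np.ndarray, n_groups: int
) -> tuple[np.ndarray, np.ndarray] | None:
    """(sigma_a, sigma_b, sigma_c) and dfs for one locus.

    ``breed_counts``: (n_breeds, n_alleles) allele-copy counts;
    ``group_of_breed``: group index per breed.  Breeds with zero copies at
    this locus are dropped.  Returns None if fewer than two breeds remain.
    """
    N_b = breed_counts.sum(axis=1)
    keep = N_b > 0
    breed_counts = breed_counts[keep]
    gob = group_of_breed[keep]
    N_b = N_b[keep]
    B = len(N_b)
    if B < 2:
        return None
    G = n_groups
    group_counts = np.zeros((G, breed_counts.shape[1]))
    np.add.at(group_counts, gob, breed_counts)
    N_g = group_counts.sum(axis=1)
    present_groups = N_g > 0
    G_eff = int(present_groups.sum())
    total = breed_counts.sum(axis=0)
    N = float(N_b.sum())

    ssd_total = float(_ssd(total[None, :])[0])
    ssd_within_breeds = float(_ssd(breed_counts).sum())
    ssd_within_groups = float(_ssd(group_counts).sum())
    ssd_ab_wg = ssd_within_groups - ssd_within_breeds
    ssd_ag = ssd_total - ssd_within_groups

    df_w = N - B
    sigma_c = ssd_within_breeds / df_w if df_w > 0 else 0.0

    sum_nb2_over_ng = 0.0
    for g in range(G):
        sel = gob == g
        if sel.any():
            sum_nb2_over_ng += float((N_b[sel] ** 2).sum()) / float(N_b[sel].sum())
    sum_nb2_over_n = float((N_b.astype(float) ** 2).sum()) / N
    sum_ng2_over_n = float((N_g[present_groups] ** 2).sum()) / N

    if G_eff < 2:
        # two-level design: among breeds / within breeds
        df_b = B - 1
        n_prime = (N - sum_nb2_over_n) / df_b
        ms_b = ssd_total - ssd_within_breeds
        sigma_b = (ms_b / df_b - sigma_c) / n_prime
        return (np.array([0.0, sigma_b, sigma_c]),
                np.array([0.0, df_b, df_w]))

    df_b = B - G_eff
    df_a = G_eff - 1
    n1 = (N - sum_nb2_over_ng) / df_b if df_b > 0 else np.nan
    n2 = (sum_nb2_over_ng - sum_nb2_over_n) / df_a
    n3 = (N - sum_ng2_over_n) / df_a
    sigma_b = (ssd_ab_wg / df_b - sigma_c) / n1 if df_b > 0 else 0.0
    sigma_a = (ssd_ag / df_a - sigma_c - n2 * sigma_b) / n3
    return (np.array([sigma_a, sigma_b, sigma_c]),
            np.array([df_a, df_b, df_w]))


def _counts_for_assignment(designs, breed_per_ind_per_locus, n_breeds: int):
    """Per-locus (n_breeds, n_alleles) allele-copy counts for an assignment."""
    out = []
    for (alleles, _, n_alleles), breed_i in zip(designs, breed_per_ind_per_locus):
        out.append(np.bincount(
            (np.repeat(breed_i, 2) * n_alleles + alleles.ravel()),
            minlength=n_breeds * n_alleles,
        ).reshape(n_breeds, n_alleles))
    return out


def _components_from_counts(
    counts_list, group_of_breed: np.ndarray, n_groups: int
) -> np.ndarray:
    """Summed-over-loci (sigma_a, sigma_b, sigma_c) from per-locus counts."""
    comp = np.zeros(3)
    for counts in counts_list:
        res = _components_one_locus(counts, group_of_breed, n_groups)
        if res is not None:
            comp += res[0]
    return comp


def amova_components(
    ds: GenotypeDataset, grouping: Mapping[str, str] | None = None
) -> AmovaResult:
    """Variance components and F-statistics (no permutation p-values).

    ``grouping`` maps breed code -> group label; ``None`` (or a single
    group) gives the two-level design.  In the three-level design every
    group must contain at least two breeds: exclude singleton-group breeds
    before calling.
    """
    breeds = ds.breeds
    if grouping is None:
        grouping = {b: "all" for b in breeds}
    missing_b = [b for b in breeds if b not in grouping]
    if missing_b:
        raise ValueError(f"grouping lacks breeds: {missing_b}")
    groups = sorted({grouping[b] for b in breeds})
    gmap = {g: i for i, g in enumerate(groups)}
    gob = np.asarray([gmap[grouping[b]] for b in breeds], dtype=np.intp)
    n_groups = len(groups)
    if n_groups > 1:
        sizes = np.bincount(gob, minlength=n_groups)
        small = [groups[i] for i in range(n_groups) if sizes[i] < 2]
        # all-singleton grouping (each breed its own group) is a valid
        # degenerate hierarchy; a *mixed* design with singleton groups is not
        if small and n_groups != len(breeds):
            raise ValueError(
                f"groups with fewer than two breeds must be excluded: {small}"
            )

    designs = _locus_designs(ds, breeds)
    comp = np.zeros(3)
    dfs = np.zeros(3)
    for alleles, breed_i, n_alleles in designs:
        counts = np.bincount(
            np.repeat(breed_i, 2) * n_alleles + alleles.ravel(),
            minlength=len(breeds) * n_alleles,
        ).reshape(len(breeds), n_alleles)
        res = _components_one_locus(counts, gob, n_groups)
        if res is not None:
            comp += res[0]
            dfs = res[1]  # identical across loci when no locus drops breeds
    sa, sb, sc = comp
    tot = sa + sb + sc
    with np.errstate(invalid="ignore", divide="ignore"):
        f_ct = sa / tot if n_groups > 1 else np.nan
        f_sc = sb / (sb + sc) if n_groups > 1 and (sb + sc) != 0 else np.nan
        f_st = (sa + sb) / tot if tot != 0 else np.nan
    return AmovaResult(
        sigma_a=float(sa), sigma_b=float(sb), sigma_c=float(sc),
        df={"among_groups": float(dfs[0]), "among_breeds": float(dfs[1]),
            "within_breeds": float(dfs[2])},
        f_ct=float(f_ct), f_sc=float(f_sc), f_st=float(f_st),
        n_groups=n_groups, n_breeds=len(breeds),
    )


def amova_test(
    ds: GenotypeDataset,
    grouping: Mapping[str, str] | None = None,
    n_perm: int = 16000,
    seed: int | None = None,
    schemes: tuple[str, ...] = ("f_st", "f_sc", "f_ct"),
) -> AmovaResult:
    """AMOVA with permutation p-values, p = (#{perm >= obs} + 1)/(n_perm + 1).

    Permutation schemes: ``f_st`` shuffles individuals among breeds across
    the whole dataset; ``f_sc`` shuffles individuals among breeds within
    their group; ``f_ct`` shuffles whole breeds among groups.  Genotypes
    stay intact (individuals, not allele copies, are permuted).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    obs = amova_components(ds, grouping)
    breeds = ds.breeds
    nb = len(breeds)
    if grouping is None:
        grouping = {b: "all" for b in breeds}
    groups = sorted({grouping[b] for b in breeds})
    gmap = {g: i for i, g in enumerate(groups)}
    gob = np.asarray([gmap[grouping[b]] for b in breeds], dtype=np.intp)
    n_groups = len(groups)
    bmap = {b: i for i, b in enumerate(breeds)}
    breed_of_ind = np.asarray([bmap[b] for b in ds.breed_of], dtype=np.intp)

    designs = _locus_designs(ds, breeds)
    # per-locus typed-individual positions in the full individual vector
    typed_ix = []
    for l in range(ds.n_loci):
        col = ds.calls[:, l, :]
        t = np.all(col != MISSING, axis=1)
        if t.any():
            typed_ix.append(np.flatnonzero(t))

    def stats_for(breed_assign: np.ndarray, gob_: np.ndarray):
        per_locus_breeds = [breed_assign[ix] for ix in typed_ix]
        counts = _counts_for_assignment(designs, per_locus_breeds, nb)
        sa, sb, sc = _components_from_counts(counts, gob_, n_groups)
        tot = sa + sb + sc
        with np.errstate(invalid="ignore", divide="ignore"):
            return (
                (sa + sb) / tot if tot else np.nan,
                sb / (sb + sc) if (sb + sc) else np.nan,
                sa / tot if tot else np.nan,
            )

    p_values: dict[str, float] = {}
    if "f_st" in schemes and np.isfinite(obs.f_st):
        ge = 0
        for _ in range(n_perm):
            perm = rng.permutation(breed_of_ind)
            f_st_p, _, _ = stats_for(perm, gob)
            if f_st_p >= obs.f_st:
                ge += 1
        p_values["f_st"] = (ge + 1) / (n_perm + 1)
    if n_groups > 1 and "f_sc" in schemes and np.isfinite(obs.f_sc):
        group_of_ind = gob[breed_of_ind]
        ge = 0
        for _ in range(n_perm):
            perm = breed_of_ind.copy()
            for g in range(n_groups):
                sel = np.flatnonzero(group_of_ind == g)
                perm[sel] = perm[sel][rng.permutation(len(sel))]
            _, f_sc_p, _ = stats_for(perm, gob)
            if f_sc_p >= obs.f_sc:
                ge += 1
        p_values["f_sc"] = (ge + 1) / (n_perm + 1)
    if n_groups > 1 and "f_ct" in schemes and np.isfinite(obs.f_ct):
        # whole breeds permuted among groups: breed counts are fixed, so
        # only group-level sums change
        per_locus_breeds = [breed_of_ind[ix] for ix in typed_ix]
        obs_counts = _counts_for_assignment(designs, per_locus_breeds, nb)
        ge = 0
        for _ in range(n_perm):
            gob_p = gob[rng.permutation(nb)]
            sa, sb, sc = _components_from_counts(obs_counts, gob_p, n_groups)
            tot = sa + sb + sc
            f_ct_p = sa / tot if tot else np.nan
            if f_ct_p >= obs.f_ct:
                ge += 1
        p_values["f_ct"] = (ge + 1) / (n_perm + 1)

    obs.p_values = p_values
    obs.n_permutations = n_perm
    return obs
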