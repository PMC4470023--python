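"""Per-breed diversity summaries, rarefaction allelic richness, null-allele
estimation, and permutation tests with sequential-Bonferroni correction.

Conventions
-----------
* Expected heterozygosity is the non-biased (finite-sample corrected) form
  He = 2n/(2n-1) * (1 - sum_k p_k^2) with n the number of typed individuals.
* Per-breed values are arithmetic means over loci with defined cells.
* Permutation p-values use the (b+1)/(m+1) estimator, so they are never 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .genodata import MISSING, AlleleFrequencyTable, GenotypeDataset, allele_frequencies
from .fstats import wc_fstatistics, _single_pop_bc


@dataclass
class DiversitySummary:
    """Per-breed diversity table plus the per-cell per-locus detail."""

    per_breed: pd.DataFrame      # breed, he, ho, mna, ae, f_is, n_mean
    per_cell: pd.DataFrame       # breed, locus, n_typed, he, ho, ae, n_alleles


def breed_summary(
    freq: AlleleFrequencyTable, ds: GenotypeDataset
) -> DiversitySummary:
    """Table-2-style summary: He (non-biased), Ho, MNA, Ae and F_IS per breed.

    Loci with no typed individual in a breed are excluded from that breed's
    means.  F_IS is the per-breed Weir–Cockerham within-population estimator.
    """
    bidx = ds.breed_indices()
    rows = []
    for bi, breed in enumerate(freq.breeds):
        ix = bidx[breed]
        for li, locus in enumerate(freq.loci):
            n = int(freq.n_typed[bi, li])
            if n == 0:
                continue
            p = freq.frequencies(li)[bi]
            p = p[p > 0]
            sum_p2 = float((p ** 2).sum())
            he = 2 * n / (2 * n - 1) * (1 - sum_p2) if n > 0 else np.nan
            calls = ds.calls[ix, li, :]
            typed = np.all(calls != MISSING, axis=1)
            ho = float((calls[typed, 0] != calls[typed, 1]).mean())
            rows.append({
                "breed": breed, "locus": locus, "n_typed": n,
                "he": he, "ho": ho, "ae": 1.0 / sum_p2, "n_alleles": int(p.size),
            })
    per_cell = pd.DataFrame(rows)

    fis = wc_fstatistics(ds, per_breed=True).per_breed_fis if len(freq.breeds) > 1 \
        else {freq.breeds[0]: _single_breed_fis(freq, ds)}
    agg = per_cell.groupby("breed", sort=False).agg(
        he=("he", "mean"), ho=("ho", "mean"), mna=("n_alleles", "mean"),
        ae=("ae", "mean"), n_mean=("n_typed", "mean"),
    ).reset_index()
    agg["f_is"] = agg["breed"].map(fis)
    return DiversitySummary(per_breed=agg, per_cell=per_cell)


def _single_breed_fis(freq: AlleleFrequencyTable, ds: GenotypeDataset) -> float:
    bidx = ds.breed_indices()
    breed = freq.breeds[0]
    ix = bidx[breed]
    bs = cs = 0.0
    for li in range(len(freq.loci)):
        n = int(freq.n_typed[0, li])
        if n < 2:
            continue
        p = freq.frequencies(li)[0]
        calls = ds.calls[ix, li, :]
        typed = np.all(calls != MISSING, axis=1)
        codes = freq.alleles[li]
        a_ix = np.searchsorted(codes, calls[typed])
        het = a_ix[:, 0] != a_ix[:, 1]
        h = np.zeros(codes.size)
        if het.any():
            np.add.at(h, a_ix[het].ravel(), 1)
        h /= n
        b_, c_ = _single_pop_bc(float(n), p, h)
        bs += b_
        cs += c_
    return float(1 - cs / (bs + cs)) if (bs + cs) else float("nan")


# -- rarefaction allelic richness ----------------------------------------


def _rarefied_richness(counts: np.ndarray, g: int) -> float:
    """Expected distinct alleles in a subsample of g copies (hypergeometric).

    Ar = sum_k [1 - C(2N - N_k, g) / C(2N, g)].
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    total = int(counts.sum())
    if g < 2:
        raise ValueError("rarefaction size g must be >= 2")
    if g > total:
        raise ValueError(f"g={g} exceeds the {total} allele copies in the cell")
    rest = total - counts
    with np.errstate(invalid="ignore"):
        log_ratio = (
            gammaln(rest + 1) - gammaln(rest - g + 1)
            - (gammaln(total + 1) - gammaln(total - g + 1))
        )
    prob_absent = np.where(rest >= g, np.exp(log_ratio), 0.0)
    return float((1.0 - prob_absent).sum())


def allelic_richness(
    ds: GenotypeDataset,
    g: int | None = None,
    min_n: int = 18,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rarefaction allelic richness per breed x locus and its per-breed mean.

    Breeds with any locus typed in fewer than ``min_n`` individuals are
    excluded (the standardized comparison keeps only well-sampled breeds).
    ``g`` defaults to the smallest 2*n_typed among included cells, so every
    included cell can be rarefied to the common size.
    """
    freq = allele_frequencies(ds)
    included = [
        bi for bi in range(freq.n_breeds)
        if int(freq.n_typed[bi].min()) >= min_n
    ]
    if not included:
        raise ValueError(f"no breed has every locus typed in >= {min_n} individuals")
    if g is None:
        g = int(2 * freq.n_typed[included].min())
    rows = []
    for bi in included:
        breed = freq.breeds[bi]
        for li, locus in enumerate(freq.loci):
            counts = freq.counts[li][bi]
            rows.append({
                "breed": breed, "locus": locus,
                "ar": _rarefied_richness(counts, g), "g": g,
            })
    per_cell = pd.DataFrame(rows)
    per_breed = per_cell.groupby("breed", sort=False)["ar"].mean().reset_index()
    return per_breed, per_cell


# -- null-allele EM ------------------------------------------------------


@dataclass
class NullAlleleEstimate:
    """EM estimates of the null-allele frequency per breed x locus."""

    table: pd.DataFrame  # breed, locus, r_hat, flag, loglik, iterations, converged
    threshold: float = 0.2


def _null_em_cell(
    het_pairs: np.ndarray, hom_counts: dict[int, int], n_blank: int,
    tol: float = 1e-8, max_iter: int = 1000,
) -> tuple[float, float, int, bool]:
    """EM for one (breed, locus) cell.

    Genotype classes under random mating with a null allele of frequency r:
    visible heterozygote (k,l): 2 q_k q_l; apparent homozygote k:
    q_k^2 + 2 q_k r; blank: r^2; with sum_k q_k + r = 1.
    """
    codes = sorted(
        set(het_pairs.ravel().tolist()) | set(hom_counts)
    )
    if not codes:
        # nothing typed: boundary, all blanks are null homozygotes
        return 1.0, 0.0, 0, False
    idx = {c: i for i, c in enumerate(codes)}
    m = len(codes)
    n_ind = len(het_pairs) + sum(hom_counts.values()) + n_blank
    het_idx = np.asarray([[idx[a], idx[b]] for a, b in het_pairs], dtype=np.intp) \
        if len(het_pairs) else np.zeros((0, 2), dtype=np.intp)
    hom_vec = np.zeros(m, dtype=np.int64)
    for c, k in hom_counts.items():
        hom_vec[idx[c]] += k

    # init: naive frequencies, small r
    q = np.ones(m) / m
    r = max(0.01, n_blank / max(n_ind, 1))
    q *= 1 - r
    prev_ll = -np.inf
    ll = prev_ll
    for it in range(1, max_iter + 1):
        # E-step: expected allele-copy counts
        copies = np.zeros(m)
        if len(het_idx):
            np.add.at(copies, het_idx.ravel(), 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac_true_hom = np.where(q + 2 * r > 0, q / (q + 2 * r), 1.0)
        copies += hom_vec * (1 + frac_true_hom)
        null_copies = float((hom_vec * (1 - frac_true_hom)).sum()) + 2.0 * n_blank
        # M-step
        tot = copies.sum() + null_copies
        q = copies / tot
        r = null_copies / tot
        # log-likelihood
        ll = 0.0
        if len(het_idx):
            ll += float(np.log(2 * q[het_idx[:, 0]] * q[het_idx[:, 1]]).sum())
        with np.errstate(divide="ignore"):
            hom_p = q ** 2 + 2 * q * r
            nz = hom_vec > 0
            ll += float((hom_vec[nz] * np.log(hom_p[nz])).sum())
        if n_blank:
            ll += n_blank * (2 * np.log(r) if r > 0 else -np.inf)
        if abs(ll - prev_ll) < tol:
            return float(r), float(ll), it, True
        prev_ll = ll
    return float(r), float(ll), max_iter, False


def estimate_null_allele_freq(
    ds: GenotypeDataset, threshold: float = 0.2
) -> NullAlleleEstimate:
    """Null-allele frequency r per breed x locus by EM on genotype classes.

    Blank (missing) calls are modelled as null/null homozygotes; apparent
    homozygotes may hide a visible/null heterozygote.  Cells with r above
    ``threshold`` are flagged as potentially problematic; flagged loci are
    reported but never dropped automatically.
    """
    bidx = ds.breed_indices()
    rows = []
    for breed, ix in bidx.items():
        for li, locus in enumerate(ds.loci):
            calls = ds.calls[ix, li, :]
            typed = np.all(calls != MISSING, axis=1)
            het = typed & (calls[:, 0] != calls[:, 1])
            hom = typed & ~het
            het_pairs = calls[het]
            hom_counts: dict[int, int] = {}
            for a in calls[hom, 0]:
                hom_counts[int(a)] = hom_counts.get(int(a), 0) + 1
            n_blank = int((~typed).sum())
            r_hat, ll, iters, conv = _null_em_cell(het_pairs, hom_counts, n_blank)
            rows.append({
                "breed": breed, "locus": locus, "r_hat": r_hat,
                "flag": r_hat > threshold, "loglik": ll,
                "iterations": iters, "converged": conv,
            })
    return NullAlleleEstimate(pd.DataFrame(rows), threshold)


# -- Hardy-Weinberg permutation test -------------------------------------


def _wc_f_single(alleles: np.ndarray) -> float:
    """Within-population f for one cell from a (n, 2) allele array."""
    n = len(alleles)
    codes, inv = np.unique(alleles, return_inverse=True)
    if codes.size < 2:
        return np.nan
    inv = inv.reshape(n, 2)
    cnt = np.bincount(inv.ravel(), minlength=codes.size)
    p = cnt / (2.0 * n)
    het = inv[:, 0] != inv[:, 1]
    h = np.zeros(codes.size)
    if het.any():
        np.add.at(h, inv[het].ravel(), 1)
    h /= n
    b, c = _single_pop_bc(float(n), p, h)
    return 1 - c / (b + c) if (b + c) else np.nan


def hwe_test(
    ds: GenotypeDataset, n_perm: int = 999, seed: int | None = None
) -> pd.DataFrame:
    """Permutation test of Hardy–Weinberg equilibrium per breed x locus.

    Allele copies are shuffled among a breed's typed individuals at the
    locus; the statistic is the Weir–Cockerham within-population f.  Both
    one-sided p-values are reported: deficit (f at least as large) and
    excess (f at least as small), each with the (b+1)/(m+1) estimator.
    Monomorphic cells are NA.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for breed, ix in ds.breed_indices().items():
        for li, locus in enumerate(ds.loci):
            calls = ds.calls[ix, li, :]
            typed = np.all(calls != MISSING, axis=1)
            alleles = calls[typed]
            rec = {"breed": breed, "locus": locus, "n_typed": int(typed.sum())}
            if len(alleles) < 2 or np.unique(alleles).size < 2:
                rec.update({"f": np.nan, "p_deficit": np.nan,
                            "p_excess": np.nan, "direction": "NA",
                            "reason": "monomorphic_or_too_small"})
                rows.append(rec)
                continue
            f_obs = _wc_f_single(alleles)
            pool = alleles.ravel().copy()
            ge = le = 0
            for _ in range(n_perm):
                rng.shuffle(pool)
                f_p = _wc_f_single(pool.reshape(-1, 2))
                if f_p >= f_obs:
                    ge += 1
                if f_p <= f_obs:
                    le += 1
            rec.update({
                "f": f_obs,
                "p_deficit": (ge + 1) / (n_perm + 1),
                "p_excess": (le + 1) / (n_perm + 1),
                "direction": "deficit" if f_obs > 0 else "excess",
                "reason": "",
            })
            rows.append(rec)
    return pd.DataFrame(rows)


# -- pairwise genic differentiation --------------------------------------


def _g_statistic(table: np.ndarray) -> float:
    """Log-likelihood-ratio G for an r x c contingency table of counts."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    if total == 0:
        return 0.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    nz = table > 0
    return float(2.0 * (table[nz] * np.log(table[nz] / expected[nz])).sum())


def genic_differentiation_test(
    ds: GenotypeDataset,
    breed_a: str,
    breed_b: str,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutation G-test of allele-frequency differentiation per locus,
    plus a Fisher's-method combination over loci.

    Individuals (intact genotypes) are shuffled between the two breeds; the
    per-locus statistic is G on the 2 x alleles allele-count table.  The
    returned frame has one row per tested locus plus a ``__combined__``
    row with Fisher's chi-square p over loci.
    """
    rng = np.random.default_rng(seed)
    bidx = ds.breed_indices()
    for b in (breed_a, breed_b):
        if b not in bidx:
            raise ValueError(f"unknown breed {b!r}")
    ix = np.concatenate([bidx[breed_a], bidx[breed_b]])
    n_a = len(bidx[breed_a])
    sub = ds.calls[ix]  # (n, L, 2)
    rows = []

    def locus_tables(order: np.ndarray, li: int):
        calls = sub[order, li, :]
        typed = np.all(calls != MISSING, axis=1)
        grp = (np.arange(len(order)) >= n_a).astype(int)[typed]
        vals = calls[typed]
        codes, inv = np.unique(vals, return_inverse=True)
        inv = inv.reshape(-1, 2)
        tab = np.zeros((2, codes.size))
        np.add.at(tab, (np.repeat(grp, 2), inv.ravel()), 1)
        return tab, typed

    identity = np.arange(len(ix))
    per_locus_p = []
    for li, locus in enumerate(ds.loci):
        tab, typed = locus_tables(identity, li)
        if tab[0].sum() == 0 or tab[1].sum() == 0:
            rows.append({"locus": locus, "g": np.nan, "p": np.nan,
                         "skipped": True})
            continue
        g_obs = _g_statistic(tab)
        ge = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(ix))
            tab_p, _ = locus_tables(perm, li)
            if _g_statistic(tab_p) >= g_obs:
                ge += 1
        p = (ge + 1) / (n_perm + 1)
        per_locus_p.append(p)
        rows.append({"locus": locus, "g": g_obs, "p": p, "skipped": False})
    if per_locus_p:
        chi2 = -2.0 * np.log(per_locus_p).sum()
        p_comb = float(sps.chi2.sf(chi2, 2 * len(per_locus_p)))
    else:
        p_comb = np.nan
    rows.append({"locus": "__combined__", "g": np.nan, "p": p_comb,
                 "skipped": False})
    return pd.DataFrame(rows)


# -- sequential Bonferroni (Holm) ----------------------------------------


def sequential_bonferroni(
    pvalues, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down correction: (reject flags, adjusted p-values).

    Adjusted p is the monotone max of (m-i+1)*p_(i), capped at 1.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return reject, p_adj
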