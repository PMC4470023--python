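"""Weir–Cockerham F-statistics from multi-allelic genotype data.

Variance components a (among populations), b (among individuals within
populations) and c (within individuals) are computed per locus and allele
with the 1984 weighted (n_c-corrected) formulas, then combined across
alleles and loci as ratios of summed components:

    theta (F_ST) = sum(a) / sum(a + b + c)
    f     (F_IS) = 1 - sum(c) / sum(b + c)
    F     (F_IT) = 1 - sum(c) / sum(a + b + c)

Components may be negative; multilocus values are ratios of sums, never
means of per-locus ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genodata import MISSING, GenotypeDataset


@dataclass
class FstatResult:
    """Global F-statistics with their per-locus variance components."""

    f_is: float
    f_it: float
    f_st: float
    loci: list[str]
    components: np.ndarray  # (n_loci, 3) summed-over-alleles a, b, c
    per_breed_fis: dict[str, float] | None = None

    @property
    def a(self) -> float:
        return float(self.components[:, 0].sum())

    @property
    def b(self) -> float:
        return float(self.components[:, 1].sum())

    @property
    def c(self) -> float:
        return float(self.components[:, 2].sum())


def _per_breed_locus_stats(ds: GenotypeDataset):
    """Sufficient statistics per locus: sample sizes, allele frequencies and
    per-allele heterozygote frequencies for every breed.

    Returns (breeds, per-locus list of (n, p, h)) where n is (n_pops,),
    p and h are (n_pops, n_alleles): p allele frequencies, h the fraction of
    typed individuals heterozygous *for* that allele.
    """
    breeds = ds.breeds
    bidx = {b: i for i, b in enumerate(breeds)}
    breed_i = np.asarray([bidx[b] for b in ds.breed_of], dtype=np.intp)
    nb = len(breeds)
    out = []
    for l in range(ds.n_loci):
        col = ds.calls[:, l, :]
        typed = np.all(col != MISSING, axis=1)
        codes = np.unique(col[typed])
        n = np.zeros(nb, dtype=np.int64)
        np.add.at(n, breed_i[typed], 1)
        if codes.size == 0:
            out.append((n, np.zeros((nb, 0)), np.zeros((nb, 0))))
            continue
        a_ix = np.searchsorted(codes, col[typed])  # (n_typed, 2)
        b_ix = breed_i[typed]
        cnt = np.zeros((nb, codes.size), dtype=np.int64)
        np.add.at(cnt, (np.repeat(b_ix, 2), a_ix.ravel()), 1)
        het = a_ix[:, 0] != a_ix[:, 1]
        hcnt = np.zeros((nb, codes.size), dtype=np.int64)
        if het.any():
            hb = np.repeat(b_ix[het], 2)
            np.add.at(hcnt, (hb, a_ix[het].ravel()), 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = cnt / (2.0 * n[:, None])
            h = hcnt / n[:, None].astype(float)
        out.append((n, p, h))
    return breeds, out


def wc_components(n: np.ndarray, p: np.ndarray, h: np.ndarray) -> tuple[float, float, float]:
    """Summed-over-alleles variance components (a, b, c) for one locus.

    Parameters are the per-population sample sizes (individuals), allele
    frequencies and per-allele heterozygote frequencies.  Populations with
    no typed individuals are dropped; fewer than two remaining populations,
    or a monomorphic locus, contribute zero components.
    """
    keep = n > 0
    n = n[keep].astype(float)
    p = p[keep]
    h = h[keep]
    r = len(n)
    if r < 2 or p.shape[1] < 2:
        return 0.0, 0.0, 0.0
    nbar = n.mean()
    nc = (n.sum() - (n ** 2).sum() / n.sum()) / (r - 1)
    pbar = (n[:, None] * p).sum(axis=0) / (r * nbar)
    s2 = (n[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n[:, None] * h).sum(axis=0) / (r * nbar)
    inner = pbar * (1 - pbar) - (r - 1) / r * s2
    a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
    b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return float(a.sum()), float(b.sum()), float(c.sum())


def _single_pop_bc(n: float, p: np.ndarray, h: np.ndarray) -> tuple[float, float]:
    """Within-population components (b, c) for one population at one locus."""
    if n < 2 or p.size < 2:
        return 0.0, 0.0
    b = n / (n - 1) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
    c = h / 2
    return float(b.sum()), float(c.sum())


def wc_fstatistics(ds: GenotypeDataset, per_breed: bool = True) -> FstatResult:
    """Global Weir–Cockerham F_IS, F_IT, F_ST (and per-breed F_IS).

    Requires at least two breeds for F_ST; loci monomorphic over the whole
    dataset contribute zero components.
    """
    breeds, stats = _per_breed_locus_stats(ds)
    if len(breeds) < 2:
        raise ValueError("F_ST requires at least two breeds")
    comp = np.zeros((ds.n_loci, 3))
    for l, (n, p, h) in enumerate(stats):
        comp[l] = wc_components(n, p, h)
    A, B, C = comp.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_st = A / (A + B + C)
        f_is = 1.0 - C / (B + C)
        f_it = 1.0 - C / (A + B + C)
    per_breed_fis = None
    if per_breed:
        per_breed_fis = {}
        for bi, breed in enumerate(breeds):
            bs = cs = 0.0
            for n, p, h in stats:
                if n[bi] > 0:
                    b_, c_ = _single_pop_bc(float(n[bi]), p[bi], h[bi])
                    bs += b_
                    cs += c_
            per_breed_fis[breed] = (
                float(1.0 - cs / (bs + cs)) if (bs + cs) != 0 else float("nan")
            )
    return FstatResult(
        f_is=float(f_is), f_it=float(f_it), f_st=float(f_st),
        loci=list(ds.loci), components=comp, per_breed_fis=per_breed_fis,
    )


def pairwise_fst(ds: GenotypeDataset) -> tuple[list[str], np.ndarray]:
    """Symmetric matrix of pairwise Weir–Cockerham theta over breed pairs.

    theta of a breed with itself is 0; a pair sharing no typed locus gets
    NaN.  Negative estimates are reported as-is.
    """
    breeds, stats = _per_breed_locus_stats(ds)
    nb = len(breeds)
    if nb < 2:
        raise ValueError("pairwise theta requires at least two breeds")
    theta = np.zeros((nb, nb))
    for i in range(nb):
        for j in range(i + 1, nb):
            A = B = C = 0.0
            shared = 0
            for n, p, h in stats:
                if n[i] > 0 and n[j] > 0:
                    shared += 1
                    sel = np.asarray([i, j], dtype=np.intp)
                    a_, b_, c_ = wc_components(n[sel], p[sel], h[sel])
                    A += a_
                    B += b_
                    C += c_
            if shared == 0 or (A + B + C) == 0:
                theta[i, j] = theta[j, i] = np.nan
            else:
                theta[i, j] = theta[j, i] = A / (A + B + C)
    return breeds, theta
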