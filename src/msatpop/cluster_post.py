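"""Post-processing of Bayesian-clustering membership matrices and breed PCA.

Clustering runs are identified only up to a permutation of cluster labels,
so comparing runs requires aligning their columns.  The symmetric
similarity coefficient between two runs is

    SSC(Qa, Qb) = max_P  1 - ||Qa - Qb P||_F / sqrt(2 N),

maximized over cluster-column permutations P (N = individuals).  Identical
matrices score 1; maximally dissimilar hard assignments score 0.  The
exact method enumerates all K! permutations (small K); the greedy method
builds the permutation column-by-column by best residual match and is the
large-K strategy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genodata import AlleleFrequencyTable, GenotypeDataset, allele_frequencies
from .simulate import QRunSet

__all__ = [
    "QRunSet", "RunSimilarity", "AssignmentReport",
    "run_similarity", "select_consensus_runs", "mean_q_matrix",
    "assign_breeds", "breed_pca", "read_q_runs", "write_q_runs",
]


@dataclass
class RunSimilarity:
    """Pairwise SSC matrix over runs with the aligning permutations."""

    ssc: np.ndarray                       # (n_runs, n_runs), 1 on diagonal
    permutations: dict                    # (i, j) -> perm aligning run j onto i
    threshold: float = 0.90

    def partner_counts(self) -> np.ndarray:
        """Per run, number of other runs with SSC above the threshold."""
        above = self.ssc > self.threshold
        np.fill_diagonal(above, False)
        return above.sum(axis=1)


@dataclass
class AssignmentReport:
    """Majority-rule assignment of breeds to clusters from a mean Q-matrix."""

    cluster_of_breed: dict[str, int]      # breed -> home cluster (plurality)
    pct_assigned: dict[str, float]        # breed -> % primarily in home cluster
    overall_pct: float
    shared_clusters: list[tuple[int, list[str]]]  # cluster claimed by >= 2 breeds
    unassignable: list[str]               # breeds with no plurality >= 2


def _ssc_from_perm(qa: np.ndarray, qb: np.ndarray, perm: np.ndarray) -> float:
    n = qa.shape[0]
    return 1.0 - np.linalg.norm(qa - qb[:, perm], ord="fro") / np.sqrt(2.0 * n)


def _align_exact(qa: np.ndarray, qb: np.ndarray) -> tuple[np.ndarray, float]:
    K = qa.shape[1]
    # maximizing SSC == maximizing trace(Qa^T Qb P): enumerate permutations
    best_perm, best = None, -np.inf
    cross = qa.T @ qb  # cross[i, j] = <Qa col i, Qb col j>
    for perm in itertools.permutations(range(K)):
        score = sum(cross[i, perm[i]] for i in range(K))
        if score > best:
            best, best_perm = score, perm
    perm = np.asarray(best_perm, dtype=np.intp)
    return perm, _ssc_from_perm(qa, qb, perm)


def _align_greedy(qa: np.ndarray, qb: np.ndarray) -> tuple[np.ndarray, float]:
    K = qa.shape[1]
    cost = np.empty((K, K))
    for i in range(K):
        diff = qa[:, [i]] - qb
        cost[i] = (diff ** 2).sum(axis=0)
    perm = np.full(K, -1, dtype=np.intp)
    used_a = np.zeros(K, bool)
    used_b = np.zeros(K, bool)
    work = cost.copy()
    for _ in range(K):
        work_masked = np.where(
            used_a[:, None] | used_b[None, :], np.inf, work
        )
        i, j = np.unravel_index(np.argmin(work_masked), work.shape)
        perm[i] = j
        used_a[i] = used_b[j] = True
    return perm, _ssc_from_perm(qa, qb, perm)


def run_similarity(
    runs: QRunSet,
    method: str = "greedy",
    threshold: float = 0.90,
) -> RunSimilarity:
    """Pairwise SSC over all run pairs, maximized over label permutations.

    ``method="exact"`` enumerates all K! permutations (K <= 8 enforced);
    ``method="greedy"`` matches columns by smallest residual, so its SSC is
    a lower bound on the exact value.
    """
    if len(runs.runs) < 2:
        raise ValueError("similarity requires at least two runs")
    if method not in ("exact", "greedy"):
        raise ValueError(f"unknown method {method!r}")
    if method == "exact" and runs.K > 8:
        raise ValueError("exact alignment is limited to K <= 8")
    align = _align_exact if method == "exact" else _align_greedy
    n = len(runs.runs)
    ssc = np.eye(n)
    perms: dict = {}
    for i in range(n):
        perms[(i, i)] = np.arange(runs.K, dtype=np.intp)
        for j in range(i + 1, n):
            perm, s = align(runs.runs[i], runs.runs[j])
            ssc[i, j] = ssc[j, i] = s
            perms[(i, j)] = perm
            inv = np.empty_like(perm)
            inv[perm] = np.arange(runs.K, dtype=np.intp)
            perms[(j, i)] = inv
    return RunSimilarity(ssc=ssc, permutations=perms, threshold=threshold)


def select_consensus_runs(
    sim: RunSimilarity, threshold: float | None = None
) -> list[int]:
    """The run with the most similar partners (SSC > threshold) plus those
    partners; ties broken by lowest run index.  May be a single run."""
    if threshold is not None and threshold != sim.threshold:
        above = sim.ssc > threshold
        np.fill_diagonal(above, False)
    else:
        above = sim.ssc > sim.threshold
        np.fill_diagonal(above, False)
    counts = above.sum(axis=1)
    best = int(np.argmax(counts))  # argmax takes the lowest index on ties
    subset = [best] + [int(j) for j in np.flatnonzero(above[best])]
    return sorted(set(subset))


def mean_q_matrix(
    runs: QRunSet, subset: list[int], sim: RunSimilarity
) -> np.ndarray:
    """Element-wise mean of the subset's matrices after aligning each run's
    columns onto the first subset member; rows renormalized to sum to 1."""
    if not subset:
        raise ValueError("empty run subset")
    ref = subset[0]
    acc = np.zeros_like(runs.runs[ref])
    for j in subset:
        perm = sim.permutations[(ref, j)]
        acc += runs.runs[j][:, perm]
    mean = acc / len(subset)
    return mean / mean.sum(axis=1, keepdims=True)


def assign_breeds(
    mean_q: np.ndarray,
    breed_of: np.ndarray,
    K: int | None = None,
) -> AssignmentReport:
    """Majority-rule breed assignment from a mean Q-matrix.

    Each animal's primary cluster is its argmax membership (ties -> lowest
    cluster index).  A breed's home cluster holds the plurality of its
    animals; animals are "correctly assigned" when their primary cluster is
    the home cluster.  Clusters claimed by two or more breeds are reported
    as shared; a breed whose largest plurality is below two animals is
    flagged unassignable (its animals scatter).
    """
    if K is not None and mean_q.shape[1] != K:
        raise ValueError(f"mean Q has {mean_q.shape[1]} clusters, expected {K}")
    K = mean_q.shape[1]
    primary = np.argmax(mean_q, axis=1)  # argmax -> lowest index on ties
    breed_of = np.asarray(breed_of, dtype=object)
    breeds: list[str] = []
    for b in breed_of:
        if b not in breeds:
            breeds.append(b)

    cluster_of_breed: dict[str, int] = {}
    pct_assigned: dict[str, float] = {}
    unassignable: list[str] = []
    for b in breeds:
        sel = breed_of == b
        counts = np.bincount(primary[sel], minlength=K)
        home = int(np.argmax(counts))
        if counts[home] < 2:
            unassignable.append(b)
            continue
        cluster_of_breed[b] = home
        pct_assigned[b] = 100.0 * counts[home] / sel.sum()

    claims: dict[int, list[str]] = {}
    for b, c in cluster_of_breed.items():
        claims.setdefault(c, []).append(b)
    shared = [(c, sorted(bs)) for c, bs in sorted(claims.items()) if len(bs) >= 2]

    assigned_sel = np.asarray([b in cluster_of_breed for b in breed_of])
    if assigned_sel.any():
        home_of_ind = np.asarray([
            cluster_of_breed.get(b, -1) for b in breed_of
        ])
        overall = 100.0 * float(
            (primary[assigned_sel] == home_of_ind[assigned_sel]).mean()
        )
    else:
        overall = float("nan")
    return AssignmentReport(
        cluster_of_breed=cluster_of_breed,
        pct_assigned=pct_assigned,
        overall_pct=overall,
        shared_clusters=shared,
        unassignable=sorted(unassignable),
    )


# -- breed-level PCA with permutation axis tests -------------------------


def _freq_matrix(freq: AlleleFrequencyTable) -> np.ndarray:
    """Breeds x pooled-allele-frequency matrix (all loci concatenated)."""
    blocks = [freq.frequencies(l) for l in range(len(freq.loci))]
    X = np.hstack(blocks)
    if np.isnan(X).any():
        raise ValueError("PCA requires every breed defined at every locus")
    return X


def _pca_eigvals(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Xc = X - X.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    eig = s ** 2 / max(X.shape[0] - 1, 1)
    scores = u * s
    return eig, scores


def breed_pca(
    freq: AlleleFrequencyTable,
    ds: GenotypeDataset | None = None,
    n_axes: int = 2,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """PCA of breeds on centered pooled allele frequencies, with optional
    permutation tests of axis significance.

    Inertia % is each eigenvalue's share of the total.  When ``ds`` is
    given, individuals are shuffled among breeds ``n_perm`` times,
    frequencies recomputed, and each axis's p-value is the fraction of
    permuted datasets whose axis eigenvalue reaches the observed one,
    estimated as (b + 1)/(m + 1).

    Returns a frame with one row per axis (inertia_pct, eigenvalue, p) and
    attaches the breed scores as ``.attrs["scores"]``.
    """
    X = _freq_matrix(freq)
    if X.shape[0] < 3:
        raise ValueError("PCA requires at least three breeds")
    n_axes = min(n_axes, X.shape[0] - 1)
    eig, scores = _pca_eigvals(X)
    inertia = 100.0 * eig / eig.sum()

    pvals = np.full(n_axes, np.nan)
    if ds is not None and n_perm > 0:
        rng = np.random.default_rng(seed)
        ge = np.zeros(n_axes, dtype=np.int64)
        breed_labels = np.asarray(ds.breed_of, dtype=object)
        for _ in range(n_perm):
            shuffled = breed_labels[rng.permutation(len(breed_labels))]
            ds_p = GenotypeDataset(
                list(ds.individuals), shuffled, list(ds.loci), ds.calls.copy()
            )
            Xp = _freq_matrix(allele_frequencies(ds_p))
            eig_p, _ = _pca_eigvals(Xp)
            for ax in range(n_axes):
                if eig_p[ax] >= eig[ax]:
                    ge[ax] += 1
        pvals = (ge + 1) / (n_perm + 1)

    out = pd.DataFrame({
        "axis": np.arange(1, n_axes + 1),
        "eigenvalue": eig[:n_axes],
        "inertia_pct": inertia[:n_axes],
        "p": pvals,
    })
    out.attrs["scores"] = pd.DataFrame(
        scores[:, :n_axes],
        index=freq.breeds,
        columns=[f"axis{i + 1}" for i in range(n_axes)],
    )
    out.attrs["all_inertia_pct"] = inertia
    return out


# -- CLUMPP-style file I/O -----------------------------------------------


def write_q_runs(runs: QRunSet, out_dir: str | Path, stem: str = "run") -> list[Path]:
    """One whitespace-delimited individuals x K matrix file per run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for r, q in enumerate(runs.runs):
        path = out_dir / f"{stem}_{r + 1:03d}.txt"
        np.savetxt(path, q, fmt="%.6f")
        paths.append(path)
    return paths


def read_q_runs(paths: list[str | Path], individual_ids: list[str] | None = None) -> QRunSet:
    """Read whitespace-delimited Q matrices (same shape and row order)."""
    runs = [np.loadtxt(p, ndmin=2) for p in paths]
    if not runs:
        raise ValueError("no Q-matrix files given")
    n, K = runs[0].shape
    for q in runs:
        if q.shape != (n, K):
            raise ValueError("Q-matrix files have inconsistent dimensions")
    runs = [q / q.sum(axis=1, keepdims=True) for q in runs]
    ids = individual_ids or [f"ind{i + 1:04d}" for i in range(n)]
    return QRunSet(runs, ids, K)
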