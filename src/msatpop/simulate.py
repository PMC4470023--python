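"""Synthetic multi-breed microsatellite data with known truth.

The generative model is Balding–Nichols-style Dirichlet drift: ancestral
per-locus allele frequencies are drawn from a flat Dirichlet; each breed's
frequencies are drawn from Dirichlet(ancestral * (1 - F_i)/F_i), so F_i is
the breed's expected differentiation from the ancestor and the expected
within-breed gene diversity shrinks by the factor (1 - F_i).  Admixture
events replace a target breed's pre-drift base frequencies with a convex
mix of already-realized source-breed frequencies (introgression acts on
breed frequency vectors, not on individuals).  Genotypes are drawn under
within-breed Hardy–Weinberg; everything is seed-deterministic.

The default configuration mirrors the study scale this package targets:
51 breeds sampled 12-55 individuals each, 21 loci with 9-28 alleles, and
per-breed drift centred on a global differentiation of about 0.12.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genodata import MISSING, GenotypeDataset


@dataclass(frozen=True)
class AdmixtureEvent:
    """Replace ``target``'s drift base with a mix of source-breed frequencies."""

    target: int                  # breed index
    sources: tuple[int, ...]     # breed indices
    weights: tuple[float, ...]   # mixing weights, sum to 1

    def __post_init__(self) -> None:
        if len(self.sources) != len(self.weights):
            raise ValueError("sources and weights differ in length")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("admixture weights must sum to 1")
        if any(w < 0 for w in self.weights):
            raise ValueError("admixture weights must be non-negative")


@dataclass
class SimConfig:
    """Configuration of the breed simulator.

    ``divergence`` holds each breed's Balding–Nichols F in (0, 1);
    ``sample_sizes`` defaults to a 12-55 grid cycled over breeds;
    ``divergence`` defaults to an even spread over [0.05, 0.19]
    (mean 0.12, matching the differentiation scale being emulated).
    """

    n_breeds: int = 51
    n_loci: int = 21
    alleles_per_locus: tuple[int, int] = (9, 28)
    sample_sizes: Sequence[int] | None = None
    divergence: Sequence[float] | None = None
    admixture_events: Sequence[AdmixtureEvent] = field(default_factory=tuple)
    null_allele_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def resolved_sample_sizes(self) -> np.ndarray:
        if self.sample_sizes is not None:
            s = np.asarray(self.sample_sizes, dtype=int)
            if len(s) != self.n_breeds:
                raise ValueError("sample_sizes length must equal n_breeds")
            return s
        grid = np.array([12, 20, 27, 34, 36, 40, 47, 55])
        return grid[np.arange(self.n_breeds) % len(grid)]

    def resolved_divergence(self) -> np.ndarray:
        if self.divergence is not None:
            f = np.asarray(self.divergence, dtype=float)
            if len(f) != self.n_breeds:
                raise ValueError("divergence length must equal n_breeds")
        else:
            f = np.linspace(0.05, 0.19, self.n_breeds)
        if np.any((f <= 0) | (f >= 1)):
            raise ValueError("divergence F values must lie in (0, 1)")
        return f

    def validate(self) -> None:
        lo, hi = self.alleles_per_locus
        if lo < 2:
            raise ValueError("loci need at least two alleles")
        if hi < lo:
            raise ValueError("alleles_per_locus range inverted")
        if not (0 <= self.null_allele_rate < 1):
            raise ValueError("null_allele_rate must be in [0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        self.resolved_sample_sizes()
        self.resolved_divergence()
        for ev in self.admixture_events:
            if ev.target >= self.n_breeds or any(
                s >= self.n_breeds for s in ev.sources
            ):
                raise ValueError("admixture event references unknown breed index")


@dataclass
class SimTruth:
    """Ground truth of a simulation run (all frequencies pre-genotype-sampling)."""

    ancestral: list[np.ndarray]        # per locus
    breed_freqs: list[np.ndarray]      # per locus: (n_breeds, n_alleles)
    admixture_bases: dict[int, list[np.ndarray]]  # target -> per-locus base
    allele_codes: list[np.ndarray]     # per locus code registry
    divergence: np.ndarray
    seed: int

    def expected_he(self, breed: int) -> float:
        """Mean over loci of 1 - sum p^2 from the true breed frequencies."""
        vals = [1.0 - float((p[breed] ** 2).sum()) for p in self.breed_freqs]
        return float(np.mean(vals))


def _drift(rng: np.random.Generator, base: np.ndarray, f: float) -> np.ndarray:
    if f < 1e-9:
        return base.copy()
    conc = base * (1.0 - f) / f
    # Dirichlet with very small concentrations can underflow; clip for stability
    return rng.dirichlet(np.clip(conc, 1e-9, None))


def simulate_breeds(cfg: SimConfig) -> tuple[GenotypeDataset, SimTruth]:
    """Simulate a multi-breed genotype dataset and its truth sidecar."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    sizes = cfg.resolved_sample_sizes()
    fdiv = cfg.resolved_divergence()
    lo, hi = cfg.alleles_per_locus
    n_alleles = rng.integers(lo, hi + 1, size=cfg.n_loci)

    ancestral = [rng.dirichlet(np.ones(m)) for m in n_alleles]
    breed_freqs = [np.empty((cfg.n_breeds, m)) for m in n_alleles]
    for l in range(cfg.n_loci):
        for b in range(cfg.n_breeds):
            breed_freqs[l][b] = _drift(rng, ancestral[l], fdiv[b])
    admixture_bases: dict[int, list[np.ndarray]] = {}
    for ev in cfg.admixture_events:
        bases = []
        for l in range(cfg.n_loci):
            base = np.zeros(n_alleles[l])
            for s, w in zip(ev.sources, ev.weights):
                base += w * breed_freqs[l][s]
            bases.append(base)
            breed_freqs[l][ev.target] = _drift(rng, base, fdiv[ev.target])
        admixture_bases[ev.target] = bases

    individuals: list[str] = []
    breed_of: list[str] = []
    calls = np.zeros((int(sizes.sum()), cfg.n_loci, 2), dtype=np.int32)
    row = 0
    for b in range(cfg.n_breeds):
        code = f"B{b + 1:02d}"
        for k in range(sizes[b]):
            individuals.append(f"{code}_{k + 1:03d}")
            breed_of.append(code)
        for l in range(cfg.n_loci):
            draws = rng.choice(
                n_alleles[l], size=(sizes[b], 2), p=breed_freqs[l][b]
            ) + 1
            calls[row:row + sizes[b], l, :] = draws
        row += sizes[b]

    if cfg.missing_rate > 0:
        mask = rng.random((calls.shape[0], cfg.n_loci)) < cfg.missing_rate
        calls[mask] = MISSING

    ds = GenotypeDataset(
        individuals, np.asarray(breed_of, dtype=object),
        [f"L{l + 1:02d}" for l in range(cfg.n_loci)], calls,
    )
    truth = SimTruth(
        ancestral=ancestral, breed_freqs=breed_freqs,
        admixture_bases=admixture_bases,
        allele_codes=[np.arange(1, m + 1) for m in n_alleles],
        divergence=fdiv, seed=cfg.seed,
    )
    if cfg.null_allele_rate > 0:
        ds = inject_null_alleles(
            ds, cfg.null_allele_rate, loci=list(range(cfg.n_loci)),
            seed=int(rng.integers(2 ** 31)),
        )
    return ds, truth


def inject_null_alleles(
    ds: GenotypeDataset,
    rate: float,
    loci: Sequence[int],
    seed: int | None = None,
) -> GenotypeDataset:
    """Add a hidden null allele of frequency ``rate`` at the given loci.

    Each allele copy independently becomes null with probability ``rate``;
    a visible/null genotype shows as a visible homozygote, a null/null
    genotype as a missing call.  ``rate`` is capped at 0.5.
    """
    if not (0 <= rate <= 0.5):
        raise ValueError("null-allele rate must lie in [0, 0.5]")
    calls = ds.calls.copy()
    if rate > 0:
        rng = np.random.default_rng(seed)
        for l in loci:
            col = calls[:, l, :]
            typed = np.all(col != MISSING, axis=1)
            null = rng.random(col.shape) < rate
            null &= typed[:, None]
            one = null[:, 0] ^ null[:, 1]
            both = null[:, 0] & null[:, 1]
            # visible/null -> apparent homozygote for the visible allele
            vis = np.where(null[:, 0], col[:, 1], col[:, 0])
            col[one, 0] = vis[one]
            col[one, 1] = vis[one]
            col[both] = MISSING
    return GenotypeDataset(
        list(ds.individuals), ds.breed_of.copy(), list(ds.loci), calls
    )


def study_config(seed: int = 0) -> SimConfig:
    """Study-scale configuration: 51 breeds (12-55 individuals), 21 loci
    with 9-28 alleles, drift spread around a global differentiation of
    0.12, and an introgression-linked subset of breeds.

    Breeds 42-51 emulate a historically introgressed group: breeds 43-47
    draw 40% of their pre-drift frequencies from breed 42, and 48-51 are
    near-duplicates of 42 with little extra drift.  The drift profile is
    skewed (a few strongly drifted, low-diversity breeds; most mild) so
    that per-breed expected heterozygosity spans a wide range while the
    global differentiation stays near 0.12.
    """
    div = 0.03 + 0.41 * np.linspace(0.0, 1.0, 51) ** 3.5
    div[41] = 0.22          # the introgression hub drifts strongly
    div[47:51] = 0.03       # near-duplicates of the hub
    events = tuple(
        [AdmixtureEvent(target=t, sources=(t, 41), weights=(0.6, 0.4))
         for t in range(42, 47)]
        + [AdmixtureEvent(target=t, sources=(41,), weights=(1.0,))
           for t in range(47, 51)]
    )
    return SimConfig(
        n_breeds=51, n_loci=21, alleles_per_locus=(9, 28),
        divergence=div, admixture_events=events,
        missing_rate=0.02, seed=seed,
    )


def introgression_demo_config(seed: int = 0) -> SimConfig:
    """Ten-breed scenario with one cluster of near-duplicate introgressed
    breeds and four divergent isolates, one of which is both the most
    diverse and the most distinct.

    Breeds 2-6 are near-copies of hub breed 1 (weak extra drift); isolates
    7-9 are partially (40%) introgressed by the hub; isolate 10 is pure,
    with the least drift, hence the top expected heterozygosity and the
    lowest cross-coancestry with the rest.  Removing any cluster member
    gains total diversity; removing the pure isolate loses the most.
    """
    events = tuple(
        [AdmixtureEvent(target=t, sources=(0,), weights=(1.0,))
         for t in range(1, 6)]
        + [AdmixtureEvent(target=t, sources=(t, 0), weights=(0.6, 0.4))
           for t in range(6, 9)]
    )
    div = [0.25] + [0.03] * 5 + [0.12] * 3 + [0.10]
    return SimConfig(
        n_breeds=10, n_loci=21, alleles_per_locus=(9, 28),
        sample_sizes=[40] * 10, divergence=div,
        admixture_events=events, seed=seed,
    )


# -- Q-matrix run simulation ---------------------------------------------


@dataclass
class QRunSet:
    """Membership matrices from repeated clustering runs of one dataset."""

    runs: list[np.ndarray]       # each (n_individuals, K), rows sum to 1
    individual_ids: list[str]
    K: int

    def __post_init__(self) -> None:
        for q in self.runs:
            if q.shape != (len(self.individual_ids), self.K):
                raise ValueError("run dimensions disagree with ids/K")
            if not np.allclose(q.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError("membership rows must sum to 1")


def simulate_q_runs(
    n_runs: int,
    n_individuals: int,
    K: int,
    noise: float = 0.05,
    label_shuffle: bool = True,
    seed: int | None = None,
    truth_q: np.ndarray | None = None,
) -> tuple[QRunSet, np.ndarray, list[np.ndarray]]:
    """Simulate label-switched, noisy replicate Q-matrices.

    A ground-truth membership matrix (block structure with strong home-
    cluster membership unless ``truth_q`` is given) is perturbed per run by
    Dirichlet noise of scale ``noise`` and, if ``label_shuffle``, a random
    column permutation.  Returns (runs, truth, applied permutations).
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    rng = np.random.default_rng(seed)
    if truth_q is None:
        home = np.arange(n_individuals) % K
        truth_q = np.full((n_individuals, K), 0.04 / (K - 1))
        truth_q[np.arange(n_individuals), home] = 0.96
    truth_q = truth_q / truth_q.sum(axis=1, keepdims=True)
    runs = []
    perms = []
    for _ in range(n_runs):
        if noise > 0:
            q = np.vstack([
                rng.dirichlet(np.clip(row / noise, 1e-9, None))
                for row in truth_q
            ])
        else:
            q = truth_q.copy()
        perm = rng.permutation(K) if label_shuffle else np.arange(K)
        perms.append(perm)
        runs.append(q[:, perm])
    ids = [f"ind{i + 1:04d}" for i in range(n_individuals)]
    return QRunSet(runs, ids, K), truth_q, perms
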