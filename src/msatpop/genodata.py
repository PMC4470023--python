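"""Genotype data model, validation, and GenePop / metadata I/O.

Diploid co-dominant multi-allelic genotypes (microsatellites) grouped into
breeds (populations).  Allele codes are opaque positive integers; ``0``
encodes a missing allele and a call is either fully typed or fully missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = 0

BREED_TYPES = frozenset({"M", "D", "P", "H", "Pa"})
BREED_STATUSES = frozenset({1, 2, 3})


class GenePopParseError(ValueError):
    """Malformed GenePop file (message names the offending line)."""


@dataclass
class GenotypeDataset:
    """Diploid genotypes for a set of individuals grouped into breeds.

    Parameters
    ----------
    individuals : list of str
        Ordered individual identifiers.
    breed_of : ndarray of str, shape (n_individuals,)
        Breed code of each individual.
    loci : list of str
        Ordered locus names.
    calls : ndarray of int, shape (n_individuals, n_loci, 2)
        Unordered allele pairs; ``(0, 0)`` is a missing call.
    """

    individuals: list[str]
    breed_of: np.ndarray
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.breed_of = np.asarray(self.breed_of, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int32)
        if self.calls.shape != (len(self.individuals), len(self.loci), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci x 2"
            )
        if len(self.breed_of) != len(self.individuals):
            raise ValueError("breed_of length does not match individuals")
        if np.any(self.calls < 0):
            raise ValueError("allele codes must be non-negative integers")
        # half-calls (one allele typed, one missing) are not representable in
        # any downstream statistic: demote to fully missing, with a warning
        half = (self.calls == MISSING).sum(axis=2) == 1
        if np.any(half):
            warnings.warn(
                f"{int(half.sum())} half-typed call(s) set to missing",
                stacklevel=2,
            )
            self.calls[half] = MISSING
        if len(self.individuals) == 0:
            raise ValueError("dataset has no individuals")
        if len(self.loci) == 0:
            raise ValueError("dataset has no loci")

    # -- basic accessors -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def breeds(self) -> list[str]:
        """Breed codes in order of first appearance."""
        seen: dict[str, None] = {}
        for b in self.breed_of:
            seen.setdefault(b, None)
        return list(seen)

    def breed_indices(self) -> dict[str, np.ndarray]:
        """Map breed code -> integer indices of its individuals."""
        out: dict[str, list[int]] = {b: [] for b in self.breeds}
        for i, b in enumerate(self.breed_of):
            out[b].append(i)
        return {b: np.asarray(ix, dtype=np.intp) for b, ix in out.items()}

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci) mask; True where the call is missing."""
        return np.all(self.calls == MISSING, axis=2)

    def subset_breeds(self, keep: Iterable[str]) -> "GenotypeDataset":
        keep = set(keep)
        sel = np.asarray([b in keep for b in self.breed_of])
        if not sel.any():
            raise ValueError("subset selects no individuals")
        return GenotypeDataset(
            individuals=[ind for ind, s in zip(self.individuals, sel) if s],
            breed_of=self.breed_of[sel],
            loci=list(self.loci),
            calls=self.calls[sel].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and list(self.breed_of) == list(other.breed_of)
            and self.loci == other.loci
            and bool(np.array_equal(np.sort(self.calls, axis=2),
                                    np.sort(other.calls, axis=2)))
        )


@dataclass(frozen=True)
class BreedMetadata:
    """One breed's descriptive record (code, type, status, geography)."""

    code: str
    name: str
    n_sampled: int
    type: str
    status: int
    geo_group: str
    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if self.type not in BREED_TYPES:
            raise ValueError(f"unknown breed type {self.type!r}")
        if self.status not in BREED_STATUSES:
            raise ValueError(f"unknown breed status {self.status!r}")


@dataclass
class AlleleFrequencyTable:
    """Per-breed, per-locus allele counts and frequencies.

    ``alleles[l]`` holds the sorted distinct allele codes at locus ``l``;
    ``counts[l]`` the (n_breeds, n_alleles_l) allele-copy counts; ``n_typed``
    the (n_breeds, n_loci) number of individuals with non-missing calls.
    A (breed, locus) cell with ``n_typed == 0`` is undefined and its
    frequencies are NaN.
    """

    breeds: list[str]
    loci: list[str]
    alleles: list[np.ndarray]
    counts: list[np.ndarray]
    n_typed: np.ndarray

    @property
    def n_breeds(self) -> int:
        return len(self.breeds)

    def frequencies(self, locus: int) -> np.ndarray:
        """(n_breeds, n_alleles) frequency matrix for one locus; NaN rows
        where no individual is typed."""
        tot = 2.0 * self.n_typed[:, locus].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.counts[locus] / tot[:, None]
        p[tot == 0] = np.nan
        return p

    def defined(self) -> np.ndarray:
        """Boolean (n_breeds, n_loci): cell has at least one typed individual."""
        return self.n_typed > 0

    def cell(self, breed: str, locus: str) -> dict[int, float]:
        """allele code -> frequency for one (breed, locus) cell."""
        bi = self.breeds.index(breed)
        li = self.loci.index(locus)
        p = self.frequencies(li)[bi]
        return {int(a): float(f) for a, f in zip(self.alleles[li], p) if f > 0}


def allele_frequencies(ds: GenotypeDataset) -> AlleleFrequencyTable:
    """Tabulate allele-copy counts and frequencies per breed and locus.

    Frequencies are complete-case per locus: an individual missing at a
    locus contributes nothing to that locus in its breed.
    """
    breeds = ds.breeds
    bidx = {b: i for i, b in enumerate(breeds)}
    breed_i = np.asarray([bidx[b] for b in ds.breed_of], dtype=np.intp)
    nb, nl = len(breeds), ds.n_loci

    alleles: list[np.ndarray] = []
    counts: list[np.ndarray] = []
    n_typed = np.zeros((nb, nl), dtype=np.int64)
    for l in range(nl):
        col = ds.calls[:, l, :]  # (n_ind, 2)
        typed = np.all(col != MISSING, axis=1)
        codes = np.unique(col[typed])
        alleles.append(codes.astype(np.int32))
        cnt = np.zeros((nb, len(codes)), dtype=np.int64)
        if codes.size:
            a_ix = np.searchsorted(codes, col[typed])
            b_ix = breed_i[typed]
            np.add.at(cnt, (np.repeat(b_ix, 2), a_ix.ravel()), 1)
        counts.append(cnt)
        np.add.at(n_typed[:, l], breed_i[typed], 1)
    return AlleleFrequencyTable(breeds, list(ds.loci), alleles, counts, n_typed)


# -- GenePop I/O ---------------------------------------------------------


def _split_genotype(token: str, width: int, lineno: int) -> tuple[int, int]:
    if len(token) != 2 * width or not token.isdigit():
        raise GenePopParseError(
            f"line {lineno}: genotype token {token!r} is not {2 * width} digits"
        )
    return int(token[:width]), int(token[width:])


def read_genepop(
    path: str | Path,
    breed_names: Sequence[str] | None = None,
) -> GenotypeDataset:
    """Read a GenePop file (2- or 3-digit allele codes).

    Breed codes are taken from the label of each pop block's *last*
    individual (the conventional GenePop usage), unless ``breed_names``
    supplies one name per pop block explicitly.  Allele code 0 is missing.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise GenePopParseError("line 1: file too short to be GenePop")

    loci: list[str] = []
    i = 1  # skip title line
    while i < len(lines) and lines[i].strip().lower() != "pop":
        raw = lines[i].strip()
        if not raw:
            raise GenePopParseError(f"line {i + 1}: blank line in locus list")
        if "," in raw:
            loci.extend(t.strip() for t in raw.split(",") if t.strip())
        else:
            loci.append(raw)
        i += 1
    if i == len(lines):
        raise GenePopParseError("line 1: no 'pop' separator found")
    if not loci:
        raise GenePopParseError("line 2: empty locus list")

    pops: list[list[tuple[str, list[tuple[int, int]]]]] = []
    width: int | None = None
    while i < len(lines):
        if lines[i].strip().lower() == "pop":
            pops.append([])
            i += 1
            continue
        raw = lines[i]
        if not raw.strip():
            i += 1
            continue
        if "," not in raw:
            raise GenePopParseError(f"line {i + 1}: expected 'label , genotypes'")
        label, _, geno = raw.partition(",")
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise GenePopParseError(
                f"line {i + 1}: {len(tokens)} genotypes for {len(loci)} loci"
            )
        w = len(tokens[0]) // 2 if tokens else 0
        if width is None:
            if w not in (2, 3):
                raise GenePopParseError(
                    f"line {i + 1}: allele digit width {w} not in (2, 3)"
                )
            width = w
        calls = [_split_genotype(t, width, i + 1) for t in tokens]
        pops[-1].append((label.strip(), calls))
        i += 1

    if any(len(p) == 0 for p in pops):
        raise GenePopParseError("empty pop block")
    if breed_names is not None and len(breed_names) != len(pops):
        raise ValueError(
            f"{len(breed_names)} breed names supplied for {len(pops)} pop blocks"
        )

    individuals: list[str] = []
    breed_of: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    for pi, pop in enumerate(pops):
        code = breed_names[pi] if breed_names is not None else pop[-1][0]
        for label, calls in pop:
            individuals.append(label)
            breed_of.append(code)
            rows.append(calls)
    calls_arr = np.asarray(rows, dtype=np.int32)
    return GenotypeDataset(individuals, np.asarray(breed_of, dtype=object),
                           loci, calls_arr)


def write_genepop(
    ds: GenotypeDataset, path: str | Path, title: str = "msatpop export"
) -> None:
    """Write 3-digit GenePop; ``read_genepop`` inverts it exactly."""
    if np.any(ds.calls > 999):
        raise ValueError("allele codes above 999 cannot be written as 3-digit GenePop")
    lines = [title]
    lines.extend(ds.loci)
    bidx = ds.breed_indices()
    for breed, ix in bidx.items():
        lines.append("pop")
        for k, i in enumerate(ix):
            # conventional GenePop: the pop is named by its last label
            label = breed if k == len(ix) - 1 else f"{breed}_{k + 1}"
            geno = " ".join(
                f"{a:03d}{b:03d}" for a, b in ds.calls[i]
            )
            lines.append(f"{label} , {geno}")
    Path(path).write_text("\n".join(lines) + "\n")


# -- metadata ------------------------------------------------------------


def read_breed_metadata(path: str | Path) -> list[BreedMetadata]:
    """Read the breed-metadata table (code,name,n_sampled,type,status,
    geo_group,latitude,longitude; comma-delimited with header)."""
    df = pd.read_csv(path, dtype={"code": str, "type": str, "geo_group": str})
    required = {"code", "name", "n_sampled", "type", "status",
                "geo_group", "latitude", "longitude"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if df["code"].duplicated().any():
        dups = df.loc[df["code"].duplicated(), "code"].tolist()
        raise ValueError(f"duplicate breed codes: {dups}")
    return [
        BreedMetadata(
            code=row.code,
            name=row.name_,
            n_sampled=int(row.n_sampled),
            type=row.type,
            status=int(row.status),
            geo_group=row.geo_group,
            latitude=float(row.latitude),
            longitude=float(row.longitude),
        )
        for row in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def write_breed_metadata(meta: Sequence[BreedMetadata], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "code": m.code, "name": m.name, "n_sampled": m.n_sampled,
                "type": m.type, "status": m.status, "geo_group": m.geo_group,
                "latitude": m.latitude, "longitude": m.longitude,
            }
            for m in meta
        ]
    ).to_csv(path, index=False)


def validate_dataset(
    ds: GenotypeDataset, meta: Sequence[BreedMetadata] | None = None
) -> list[dict]:
    """Cross-check genotypes against metadata; returns machine-readable
    issues (never raises on content problems)."""
    issues: list[dict] = []
    counts = {b: len(ix) for b, ix in ds.breed_indices().items()}
    if meta is not None:
        meta_codes = {m.code for m in meta}
        for b in counts:
            if b not in meta_codes:
                issues.append({"level": "error", "kind": "breed_not_in_metadata",
                               "breed": b})
        for m in meta:
            if m.code not in counts:
                issues.append({"level": "error", "kind": "breed_not_in_genotypes",
                               "breed": m.code})
            elif counts[m.code] != m.n_sampled:
                issues.append({
                    "level": "warning", "kind": "sample_size_mismatch",
                    "breed": m.code, "genotyped": counts[m.code],
                    "n_sampled": m.n_sampled,
                })
    miss = ds.missing_mask()
    for l, locus in enumerate(ds.loci):
        if miss[:, l].all():
            issues.append({"level": "error", "kind": "locus_all_missing",
                           "locus": locus})
    return issues
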