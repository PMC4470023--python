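#!/usr/bin/env python
"""Global Weir-Cockerham F-statistics (multilocus ratio-of-sums), the
pairwise differentiation matrix, and the Reynolds / Nei-minimum distance
matrices, with a PHYLIP export of the Reynolds matrix for external
network/tree tools."""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from msatpop import (
    allele_frequencies,
    coancestry_matrix,
    nei_minimum_distance,
    pairwise_fst,
    read_genepop,
    reynolds_distance,
    wc_fstatistics,
    write_phylip_matrix,
)


def square_csv(breeds, values, path):
    pd.DataFrame(values, index=breeds, columns=breeds).to_csv(path)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1,
                    help="unused; accepted for a uniform driver interface")
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    ds = read_genepop(args.out_dir / "study_genotypes.gen")
    freq = allele_frequencies(ds)

    res = wc_fstatistics(ds)
    pd.DataFrame({
        "locus": res.loci,
        "a": res.components[:, 0],
        "b": res.components[:, 1],
        "c": res.components[:, 2],
    }).to_csv(args.out_dir / "fstat_components.csv", index=False)
    pd.DataFrame([{"f_is": res.f_is, "f_it": res.f_it, "f_st": res.f_st}]
                 ).to_csv(args.out_dir / "fstat_global.csv", index=False)

    breeds, theta = pairwise_fst(ds)
    square_csv(breeds, theta, args.out_dir / "pairwise_fst.csv")

    co = coancestry_matrix(freq)
    square_csv(co.breeds, co.values, args.out_dir / "coancestry.csv")
    nei = nei_minimum_distance(co)
    square_csv(nei.breeds, nei.values, args.out_dir / "nei_minimum.csv")
    rey = reynolds_distance(freq)
    square_csv(rey.breeds, rey.values, args.out_dir / "reynolds.csv")
    write_phylip_matrix(rey, args.out_dir / "reynolds.phy")

    print(f"F_IS={res.f_is:.4f}  F_IT={res.f_it:.4f}  F_ST={res.f_st:.4f}")
    off = theta[~np.eye(len(breeds), dtype=bool)]
    print(f"pairwise theta: {off.min():.3f}-{off.max():.3f}")
    print(f"wrote distance matrices and {args.out_dir}/reynolds.phy")


if __name__ == "__main__":
    main()
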