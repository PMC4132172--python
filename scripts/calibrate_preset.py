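#!/usr/bin/env python
"""Calibration runs behind the study-system synthetic preset.

Sweeps per-site theta and the island migration rate, reporting the pooled
silent-site diversity, multilocus FST/FIS, and the leaf-locus FST contrast
for each candidate, so the preset defaults in ``ivypop.simulate`` can be
anchored to the target values (theta-pi ~ 1.1e-3, FST ~ 0.15, FIS ~ 0.85,
leaf locus in the upper FST tail).

    python scripts/calibrate_preset.py --seeds 4
"""

import argparse

import numpy as np

from ivypop.differentiation import multilocus_fst, snp_fst_distribution, wc_components
from ivypop.diversity import pooled_multilocus
from ivypop.leafshape import leaf_locus_fst
from ivypop.popdata import extract_snps
from ivypop.simulate import generate_dataset, study_preset


def evaluate(theta: float, migration: float, seeds: int) -> dict:
    rows = []
    for seed in range(seeds):
        cfg = study_preset(seed=seed, theta_per_site=theta,
                           migration_rate=migration)
        ds = generate_dataset(cfg)
        est = pooled_multilocus(ds.alignments)
        snps = extract_snps(ds.alignments, ds.meta)
        labels = np.asarray([
            dict(zip(ds.meta["individual_id"], ds.meta["population_id"]))[i]
            for i in snps.individuals], dtype=object)
        a, b, c = wc_components(snps.genotypes, labels)
        ok = np.isfinite(a)
        fst = a[ok].sum() / (a[ok] + b[ok] + c[ok]).sum()
        fis = b[ok].sum() / (b[ok] + c[ok]).sum()
        bg = snp_fst_distribution(snps, ds.meta)
        summ = leaf_locus_fst(ds.meta, background=bg)
        rows.append((est.theta_pi, fst, fis, summ.leaf_fst,
                     summ.percentile_in_background))
    arr = np.asarray(rows)
    return {
        "theta_pi": float(np.median(arr[:, 0])),
        "fst": float(np.median(arr[:, 1])),
        "fis": float(np.median(arr[:, 2])),
        "leaf_fst": float(np.median(arr[:, 3])),
        "leaf_percentile": float(np.median(arr[:, 4])),
    }


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seeds", type=int, default=4)
    parser.add_argument("--thetas", type=float, nargs="+",
                        default=[2e-5, 4e-5, 8e-5])
    parser.add_argument("--migrations", type=float, nargs="+",
                        default=[3.0, 5.0, 8.0])
    args = parser.parse_args()

    for theta in args.thetas:
        for mig in args.migrations:
            out = evaluate(theta, mig, args.seeds)
            print(f"theta={theta:g} M={mig:g} -> "
                  + " ".join(f"{k}={v:.4g}" for k, v in out.items()))


if __name__ == "__main__":
    main()
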