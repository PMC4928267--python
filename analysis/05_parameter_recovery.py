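#!/usr/bin/env python
"""Parameter recovery of the ancestry coefficient across the alpha grid.

Draws 50 admixed individuals per true vinifera fraction alpha in
{0, 0.1, ..., 1.0} from Balding-Nichols population frequencies (FST 0.3,
2,500 sites) and pushes them through the full estimation loop with
30-per-panel fitting samples (large enough that the projection shrinkage
affecting frequency-drawn individuals is small; the cross-derived
cohorts of 04 are unbiased at any panel size — see docs/methods.md).
Writes the per-level recovery table under results/recovery/.
"""

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from vitis_ancestry import GenotypeMatrix, SynthConfig, estimate_all, make_dataset
from vitis_ancestry.simulate import draw_population_frequencies, sample_admixed

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 42


def main() -> None:
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")
    out = ROOT / "recovery"
    out.mkdir(parents=True, exist_ok=True)
    cfg = SynthConfig(n_wild=30, n_vinifera=30, n_hybrids=0, seed=SEED)
    matrix, _ = make_dataset(cfg)
    fw, fv = draw_population_frequencies(cfg)
    rng = np.random.default_rng(SEED + 1)

    alphas = np.round(np.arange(0, 1.01, 0.1), 1)
    samples, labels, blocks, truth = list(matrix.samples), list(matrix.labels), [matrix.dosage], []
    for level, alpha in enumerate(alphas):
        dosage, _ = sample_admixed(fw, fv, float(alpha), 50, rng)
        blocks.append(dosage)
        samples += [f"adm_{level}_{i}" for i in range(50)]
        labels += ["hybrid"] * 50
        truth += [100 * alpha] * 50
    combined = GenotypeMatrix(
        samples=samples, sites=matrix.sites, dosage=np.vstack(blocks), labels=labels
    )
    est, _ = estimate_all(combined, seed=SEED)
    est["truth"] = truth
    per_level = (
        est.groupby("truth")["percent_vinifera"]
        .agg(["mean", "std"])
        .reset_index()
        .rename(columns={"mean": "mean_estimate", "std": "sd_estimate"})
    )
    per_level["abs_error"] = (per_level.mean_estimate - per_level.truth).abs()
    slope, intercept = np.polyfit(est.truth, est.percent_vinifera, 1)
    per_level.round(3).to_csv(out / "alpha_grid_recovery.tsv", sep="\t", index=False)
    print(per_level.round(2).to_string(index=False))
    print(f"regression of estimate on truth: slope={slope:.3f}, "
          f"intercept={intercept:.2f}")


if __name__ == "__main__":
    main()
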