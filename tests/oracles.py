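"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity along a path independent of the
implementation it checks: exact rational arithmetic for the conditional
Hardy-Weinberg distribution, numpy.corrcoef for LD r^2, a literal
sliding-window pruner, and a Gram-matrix eigendecomposition for PCA
scores.
"""

from fractions import Fraction
from math import comb, factorial

import numpy as np


def hwe_excess_pvalue_enumeration(n_hom_ref, n_het, n_hom_alt):
    """Exact heterozygote-excess p-value by exhaustive enumeration.

    Enumerates every genotype configuration compatible with the observed
    allele counts using exact rational weights proportional to the number
    of distinct allele arrangements, then sums the normalised masses of
    configurations with at least the observed heterozygote count.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = n_het + 2 * n_hom_alt
    n_minor = min(n_alt, 2 * n - n_alt)
    weights = {}
    for h in range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2):
        n_mm = (n_minor - h) // 2
        n_other = n - n_mm - h
        if n_other < 0:
            continue
        w = Fraction(
            factorial(n) * 2**h, factorial(n_mm) * factorial(h) * factorial(n_other)
        )
        weights[h] = w
    total = sum(weights.values())
    tail = sum(w for h, w in weights.items() if h >= n_het)
    return float(Fraction(tail, total))


def corrcoef_r2(x, y):
    """r^2 via numpy.corrcoef over pairwise-complete entries."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = (x != -1) & (y != -1)
    if ok.sum() < 2:
        return float("nan")
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        return float("nan")
    return float(np.corrcoef(xs, ys)[0, 1] ** 2)


def brute_force_prune(dosage, sites, window_size=10, step=3, r2_max=0.5):
    """Literal sliding-window pruner, kept independent of the library.

    Maintains a kept set, slides windows per chromosome, and for every
    in-window pair of kept sites with r^2 above the cutoff removes the
    lower-MAF member (ties: the later position).
    """
    dosage = np.asarray(dosage)
    m = dosage.shape[1]

    def maf(j):
        col = dosage[:, j]
        obs = col[col != -1]
        if obs.size == 0:
            return float("nan")
        f = obs.sum() / (2 * obs.size)
        return min(f, 1 - f)

    kept = set(range(m))
    by_chrom = {}
    for j, rec in enumerate(sites):
        by_chrom.setdefault(rec.chrom, []).append(j)
    for idxs in by_chrom.values():
        for start in range(0, len(idxs), step):
            window = idxs[start : start + window_size]
            for a in range(len(window)):
                for b in range(a + 1, len(window)):
                    i, j = window[a], window[b]
                    if i not in kept or j not in kept:
                        continue
                    r2 = corrcoef_r2(dosage[:, i], dosage[:, j])
                    if np.isnan(r2) or r2 <= r2_max:
                        continue
                    mi, mj = maf(i), maf(j)
                    if np.isnan(mi) or np.isnan(mj) or mi == mj:
                        kept.discard(j)
                    elif mi < mj:
                        kept.discard(i)
                    else:
                        kept.discard(j)
    return sorted(kept)


def gram_pca_scores(g, n_components):
    """PC scores via eigendecomposition of the sample-side Gram matrix.

    Normalises exactly as the model specifies ((g - mean)/sqrt(p(1-p)),
    adjusted p) but takes the eigen route rather than the SVD route.
    """
    g = np.asarray(g, float)
    n = g.shape[0]
    mean = g.mean(axis=0)
    p = (1 + g.sum(axis=0)) / (2 + 2 * n)
    z = (g - mean) / np.sqrt(p * (1 - p))
    gram = z @ z.T
    vals, vecs = np.linalg.eigh(gram)
    order = np.argsort(vals)[::-1][:n_components]
    return vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
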