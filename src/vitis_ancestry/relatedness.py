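"""Identity-by-state (IBS) similarity between samples.

IBS counts shared alleles irrespective of descent: at one site two
diploids share 2 - |g1 - g2| alleles, so the pairwise similarity is the
shared-allele fraction over sites where both samples are called. Used to
vet replicate accessions and putative relatives before ancestry
estimation (it runs pre-imputation, so site sets are pairwise-complete).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix


def ibs_pair(g1: np.ndarray, g2: np.ndarray) -> float:
    """IBS similarity of two dosage vectors, in [0, 1].

    NaN when no site is called in both samples.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = (g1 != MISSING) & (g2 != MISSING)
    n = int(ok.sum())
    if n == 0:
        return float("nan")
    shared = (2.0 - np.abs(g1[ok] - g2[ok])).sum()
    return float(shared / (2.0 * n))


def ibs_matrix(
    matrix: GenotypeMatrix, labels: list[str] | None = None
) -> pd.DataFrame:
    """Symmetric pairwise IBS table with unit diagonal.

    ``labels`` optionally restricts to samples whose label is in the list
    (e.g. ``["hybrid"]`` to vet replicate hybrid accessions).
    """
    if labels is None:
        idx = np.arange(matrix.n_samples)
    else:
        idx = np.flatnonzero(np.isin(matrix.labels, list(labels)))
    if idx.size < 2:
        raise ValueError("need at least two samples for an IBS matrix")
    ids = [matrix.samples[i] for i in idx]
    n = idx.size
    out = np.ones((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            v = ibs_pair(matrix.dosage[idx[a]], matrix.dosage[idx[b]])
            out[a, b] = out[b, a] = v
    return pd.DataFrame(out, index=ids, columns=ids)
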