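import numpy as np
import pytest

from vitis_ancestry import GenotypeMatrix, SiteRecord


def make_matrix(dosage, labels=None, depth=None, samples=None, sites=None):
    """Small-matrix helper: dosage rows are samples, columns sites."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    samples = samples or [f"s{i}" for i in range(n)]
    sites = sites or [
        SiteRecord("chr1", 100 * (j + 1), "A", "C") for j in range(m)
    ]
    return GenotypeMatrix(
        samples=samples,
        sites=sites,
        dosage=dosage,
        labels=list(labels) if labels else [],
        depth=None if depth is None else np.asarray(depth),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_matrix(rng, n=6, m=10, missing_rate=0.2, with_depth=False):
    dosage = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    if missing_rate:
        dosage[rng.random((n, m)) < missing_rate] = -1
    depth = rng.poisson(15, size=(n, m)) if with_depth else None
    return make_matrix(dosage, depth=depth)
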