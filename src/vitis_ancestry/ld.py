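"""Linkage-disequilibrium measures and windowed r^2 pruning.

r^2 is the squared Pearson correlation of genotype dosages over
pairwise-complete samples (the composite LD measure used by windowed
genotype pruners), not a haplotype/EM r^2. Pruning slides a fixed-size
window of sites along each chromosome, removes one member of every pair
whose r^2 exceeds the cutoff, then shifts by a step; windows never span
chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix
from .qc import site_maf


@dataclass(frozen=True)
class PruneParams:
    """Windowed-pruning parameters (window and step are site counts)."""

    window_size: int = 10
    step: int = 3
    r2_max: float = 0.5

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if not 1 <= self.step <= self.window_size:
            raise ValueError("step must lie in [1, window_size]")
        if not 0.0 <= self.r2_max <= 1.0:
            raise ValueError("r2_max must lie in [0, 1]")


def dosage_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over entries where both vectors are non-missing. Returns NaN
    when fewer than two complete pairs exist or either vector is constant
    on the complete pairs (no evidence of correlation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return float("nan")
    xs, ys = x[ok], y[ok]
    xs = xs - xs.mean()
    ys = ys - ys.mean()
    vx = (xs**2).sum()
    vy = (ys**2).sum()
    if vx == 0.0 or vy == 0.0:
        return float("nan")
    r = (xs * ys).sum() / np.sqrt(vx * vy)
    return float(min(1.0, r * r))


def pairwise_complete_r2(dosage: np.ndarray) -> np.ndarray:
    """Site x site r^2 matrix under pairwise-complete observation.

    Vectorised over all site pairs; undefined entries (fewer than two
    complete pairs, or zero variance within the complete pairs) are NaN.
    Used by the LD-kNN imputer to rank candidate predictor sites.
    """
    d = np.asarray(dosage, dtype=float).T  # sites x samples
    m = d.shape[0]
    obs = (d != MISSING).astype(float)
    dz = np.where(d == MISSING, 0.0, d)
    n = obs @ obs.T
    s1 = dz @ obs.T            # sum of x over joint support
    s2 = (dz**2) @ obs.T       # sum of x^2 over joint support
    sxy = dz @ dz.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - s1 * s1.T / n
        vx = s2 - s1**2 / n
        vy = vx.T
        r2 = cov**2 / (vx * vy)
    r2 = np.where((n >= 2) & (vx > 0) & (vy > 0), r2, np.nan)
    return np.minimum(r2, 1.0).reshape(m, m)


def _chromosome_runs(matrix: GenotypeMatrix) -> list[np.ndarray]:
    """Contiguous index runs per chromosome, verifying (chrom, pos) order."""
    runs: list[list[int]] = []
    prev_key: tuple[str, int] | None = None
    for i, rec in enumerate(matrix.sites):
        if prev_key is not None and rec.chrom == prev_key[0]:
            if rec.pos < prev_key[1]:
                raise ValueError("sites must be ordered by (chrom, pos)")
            runs[-1].append(i)
        else:
            if any(matrix.sites[j].chrom == rec.chrom for run in runs for j in run):
                raise ValueError("chromosome blocks must be contiguous")
            runs.append([i])
        prev_key = (rec.chrom, rec.pos)
    return [np.array(r) for r in runs]


def window_prune(matrix: GenotypeMatrix, params: PruneParams = PruneParams()) -> list[int]:
    """Indices of sites surviving windowed r^2 pruning, in original order.

    Within each window the currently-kept sites are compared pairwise; when
    r^2 exceeds ``params.r2_max`` the member with the lower MAF is removed
    (ties: the later position goes). The window then shifts by
    ``params.step`` sites. Undefined r^2 never triggers removal. The result
    is deterministic for a fixed input.
    """
    maf = site_maf(matrix)
    removed = np.zeros(matrix.n_sites, dtype=bool)
    for run in _chromosome_runs(matrix):
        m = len(run)
        for start in range(0, m, params.step):
            window = run[start:start + params.window_size]
            if len(window) < 2:
                continue
            for ai in range(len(window)):
                i = window[ai]
                if removed[i]:
                    continue
                for bi in range(ai + 1, len(window)):
                    j = window[bi]
                    if removed[i]:
                        break
                    if removed[j]:
                        continue
                    r2 = dosage_r2(matrix.dosage[:, i], matrix.dosage[:, j])
                    if np.isnan(r2) or r2 <= params.r2_max:
                        continue
                    mi, mj = maf[i], maf[j]
                    if np.isnan(mi) or np.isnan(mj) or mi == mj:
                        removed[j] = True  # tie: drop the later position
                    elif mi < mj:
                        removed[i] = True
                    else:
                        removed[j] = True
    return [int(i) for i in np.flatnonzero(~removed)]


def inter_site_distances(matrix: GenotypeMatrix) -> list[int]:
    """Distances (bp) between consecutive sites on the same chromosome."""
    out: list[int] = []
    for run in _chromosome_runs(matrix):
        pos = [matrix.sites[i].pos for i in run]
        out.extend(int(b - a) for a, b in zip(pos, pos[1:]))
    return out


def median_inter_site_distance(matrix: GenotypeMatrix) -> float:
    """Median of :func:`inter_site_distances` (NaN when no pair exists)."""
    d = inter_site_distances(matrix)
    return float(np.median(d)) if d else float("nan")
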