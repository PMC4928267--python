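"""Genotype curation filters.

Implements the curation chain applied to a GBS dosage matrix before
ancestry estimation: per-cell depth masking, site and sample missingness
filters, minor-allele-frequency filters, and removal of sites showing
heterozygote excess under an exact conditional Hardy-Weinberg test
(Levene-Haldane distribution). Heterozygote excess at a GBS site is the
classic signature of collapsed paralogs, so the test is one-sided by
default.

Boundary semantics are deliberately asymmetric and are pinned by tests:
sites are kept when their missing fraction is strictly below the cutoff,
samples are kept when theirs is at most the cutoff; the genome-wide MAF
filter keeps sites at the threshold while the ancestral-panel MAF filter
drops them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

from .genotype_io import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class CurationConfig:
    """Thresholds of the curation chain (defaults are the analysis defaults)."""

    min_depth: int = 8
    max_site_missing: float = 0.20
    max_sample_missing: float = 0.20
    min_maf: float = 0.05
    hwe_alpha: float = 0.001
    ancestral_min_maf: float = 0.10

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        for name in ("max_site_missing", "max_sample_missing", "min_maf",
                     "hwe_alpha", "ancestral_min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class HweCounts:
    """Genotype counts at one biallelic site."""

    n_hom_ref: int
    n_het: int
    n_hom_alt: int

    def __post_init__(self) -> None:
        if min(self.n_hom_ref, self.n_het, self.n_hom_alt) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt


def mask_low_depth(matrix: GenotypeMatrix, min_depth: int = 8) -> GenotypeMatrix:
    """Set cells with read depth below ``min_depth`` to missing.

    A cell with depth exactly ``min_depth`` is retained; absent DP values
    are treated as depth 0 when ``min_depth > 0``.
    """
    if matrix.depth is None:
        raise ValueError(
            "matrix carries no depth data; skip the depth-masking step"
        )
    out = matrix.copy()
    if min_depth > 0:
        out.dosage[out.depth < min_depth] = MISSING
    return out


def _site_missing_fraction(matrix: GenotypeMatrix) -> np.ndarray:
    return matrix.missing_mask().mean(axis=0)


def filter_sites_by_missingness(
    matrix: GenotypeMatrix, max_missing: float = 0.20
) -> GenotypeMatrix:
    """Keep sites whose missing fraction is strictly below ``max_missing``."""
    keep = np.flatnonzero(_site_missing_fraction(matrix) < max_missing)
    return matrix.take_sites(keep)


def filter_samples_by_missingness(
    matrix: GenotypeMatrix, max_missing: float = 0.20
) -> GenotypeMatrix:
    """Keep samples whose missing fraction is at most ``max_missing``."""
    frac = matrix.missing_mask().mean(axis=1)
    keep = np.flatnonzero(frac <= max_missing)
    if keep.size == 0:
        raise ValueError("sample-missingness filter removed every sample")
    return matrix.take_samples(keep)


def _resolve_subset(
    matrix: GenotypeMatrix, sample_subset: Iterable[str] | None
) -> np.ndarray:
    if sample_subset is None:
        return np.arange(matrix.n_samples)
    wanted = list(sample_subset)
    index = {s: i for i, s in enumerate(matrix.samples)}
    missing = [s for s in wanted if s not in index]
    if missing:
        raise ValueError(f"unknown sample id(s) in subset: {missing}")
    if not wanted:
        raise ValueError("sample subset is empty")
    return np.array([index[s] for s in wanted])


def site_maf(
    matrix: GenotypeMatrix, sample_subset: Iterable[str] | None = None
) -> np.ndarray:
    """Per-site minor allele frequency over the given samples.

    MAF = min(f_alt, 1 - f_alt) with f_alt the ALT-allele frequency among
    non-missing calls. Sites with zero non-missing calls get NaN.
    """
    idx = _resolve_subset(matrix, sample_subset)
    dos = matrix.dosage[idx].astype(float)
    obs = dos != MISSING
    n_obs = obs.sum(axis=0)
    alt = np.where(obs, dos, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_alt = np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)
    return np.minimum(f_alt, 1.0 - f_alt)


def filter_by_maf(
    matrix: GenotypeMatrix,
    min_maf: float,
    sample_subset: Iterable[str] | None = None,
    strict: bool = False,
) -> GenotypeMatrix:
    """Remove sites whose MAF (on ``sample_subset``) fails the threshold.

    ``strict=False`` keeps sites with MAF >= ``min_maf`` (the genome-wide
    filter: "MAF below the cutoff is removed"); ``strict=True`` keeps only
    MAF > ``min_maf`` (the ancestral-panel filter). Sites failing on the
    subset are removed from the whole matrix. Sites with undefined MAF
    (no calls) are removed whenever ``min_maf > 0``.
    """
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must lie in [0, 0.5]")
    maf = site_maf(matrix, sample_subset)
    with np.errstate(invalid="ignore"):
        ok = maf > min_maf if strict else maf >= min_maf
    ok = np.where(np.isnan(maf), min_maf == 0.0 and not strict, ok)
    return matrix.take_sites(np.flatnonzero(ok))


# ---------------------------------------------------------------------------
# Exact Hardy-Weinberg heterozygote-excess test
# ---------------------------------------------------------------------------

def _levene_haldane_log_pmf(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Support and log-probabilities of the heterozygote count.

    Conditional on ``n`` diploids carrying ``n_minor`` copies of the minor
    allele, the heterozygote count h (same parity as ``n_minor``) follows

        P(h) = n! / (n_AA! h! n_aa!) * 2**h * n_minor! n_major! / (2n)!

    with n_AA = (n_minor - h) / 2 and n_aa = n - n_AA - h.
    """
    n_major = 2 * n - n_minor
    h = np.arange(n_minor % 2, min(n_minor, n_major) + 1, 2)
    n_aa_minor = (n_minor - h) // 2
    n_aa_major = n - n_aa_minor - h
    logp = (
        gammaln(n + 1)
        - gammaln(n_aa_minor + 1)
        - gammaln(h + 1)
        - gammaln(n_aa_major + 1)
        + h * np.log(2.0)
        + gammaln(n_minor + 1)
        + gammaln(n_major + 1)
        - gammaln(2 * n + 1)
    )
    return h, logp


def hwe_het_excess_pvalue(
    counts: HweCounts,
    alternative: str = "excess",
    method: str = "exact",
) -> float:
    """P-value of the conditional Hardy-Weinberg test at one site.

    ``alternative="excess"`` (default) sums Levene-Haldane probabilities of
    heterozygote counts at least as large as observed; ``"two_sided"`` sums
    probabilities of all outcomes no more likely than the observed one.
    ``method="asymptotic"`` substitutes the 1-df chi-square goodness-of-fit
    statistic (halved for the one-sided case when heterozygotes are in
    excess; p = 1 otherwise). The exact test is the default.
    """
    if alternative not in ("excess", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n = counts.n
    if n == 0:
        raise ValueError("no genotyped samples at site")
    n_alt = counts.n_het + 2 * counts.n_hom_alt
    n_minor = min(n_alt, 2 * n - n_alt)
    if method == "asymptotic":
        return _hwe_chi2_pvalue(counts, alternative)
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    h_obs = counts.n_het
    h, logp = _levene_haldane_log_pmf(n, n_minor)
    p = np.exp(logp)
    p = p / p.sum()  # guard against rounding in the log-space evaluation
    if alternative == "excess":
        return float(min(1.0, p[h >= h_obs].sum()))
    p_obs = p[h == h_obs]
    if p_obs.size == 0:  # impossible configuration given allele counts
        raise ValueError(
            f"heterozygote count {h_obs} incompatible with allele counts"
        )
    return float(min(1.0, p[p <= p_obs[0] * (1 + 1e-12)].sum()))


def _hwe_chi2_pvalue(counts: HweCounts, alternative: str) -> float:
    n = counts.n
    f_alt = (counts.n_het + 2 * counts.n_hom_alt) / (2 * n)
    exp = np.array(
        [n * (1 - f_alt) ** 2, 2 * n * f_alt * (1 - f_alt), n * f_alt**2]
    )
    obs = np.array([counts.n_hom_ref, counts.n_het, counts.n_hom_alt], float)
    if exp[1] == 0:
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.nansum((obs - exp) ** 2 / np.where(exp > 0, exp, np.nan))
    p_two = float(chi2.sf(stat, df=1))
    if alternative == "two_sided":
        return p_two
    return p_two / 2.0 if obs[1] > exp[1] else 1.0 - p_two / 2.0


def hwe_counts_per_site(matrix: GenotypeMatrix) -> list[HweCounts]:
    """Genotype counts over non-missing calls, one per site."""
    out = []
    for j in range(matrix.n_sites):
        col = matrix.dosage[:, j]
        out.append(
            HweCounts(
                int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
            )
        )
    return out


def filter_hwe(
    matrix: GenotypeMatrix,
    alpha: float = 0.001,
    alternative: str = "excess",
) -> GenotypeMatrix:
    """Remove sites whose exact HWE p-value falls below ``alpha``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    keep = []
    for j, counts in enumerate(hwe_counts_per_site(matrix)):
        if counts.n == 0:
            continue  # no calls: untestable, handled by missingness filters
        if hwe_het_excess_pvalue(counts, alternative) >= alpha:
            keep.append(j)
    return matrix.take_sites(keep)
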