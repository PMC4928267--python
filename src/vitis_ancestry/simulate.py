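"""Synthetic genotype datasets with known ancestry truth.

Generates the data structure the analysis assumes without any download:
two strongly diverged ancestral panels under a Balding-Nichols model,
admixed individuals with a known vinifera fraction, optional
haplotype-block LD, uniform missingness and Poisson read depth. Defaults
emulate the shape of the curated grape GBS dataset: 7 wild + 7 vinifera
ancestral samples, 64 hybrids spanning roughly 10-80% vinifera ancestry,
~2,500 polymorphic biallelic sites (a small fraction of them indels)
spread over 19 chromosomes.

Under the Balding-Nichols model each site has an ancestral frequency p
drawn uniformly from ``base_freq_range``; each population's frequency is
then Beta-distributed with mean p and variance FST * p(1-p). FST defaults
to 0.3, strong enough that the two panels separate cleanly on PC1 as two
grape species do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, SiteRecord

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SynthConfig:
    """Synthetic-dataset parameters (defaults emulate the curated study data)."""

    n_sites: int = 2_500
    n_wild: int = 7
    n_vinifera: int = 7
    n_hybrids: int = 64
    hybrid_alpha_range: tuple[float, float] = (0.10, 0.80)
    fst: float = 0.3
    base_freq_range: tuple[float, float] = (0.1, 0.9)
    indel_fraction: float = 0.022  # ~56 of 2538 curated sites were indels
    n_chromosomes: int = 19
    chromosome_length: int = 5_000_000
    n_blocks: int | None = None
    haplotypes_per_block: int | None = None
    missing_rate: float = 0.0
    depth_mean: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_sites, self.n_wild, self.n_vinifera) < 1:
            raise ValueError("n_sites and panel sizes must be >= 1")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must lie in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        lo, hi = self.base_freq_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("base_freq_range must be an interval within [0, 1]")
        if (self.n_blocks is None) != (self.haplotypes_per_block is None):
            raise ValueError(
                "n_blocks and haplotypes_per_block must be set together"
            )


def draw_population_frequencies(
    config: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (wild, vinifera) allele frequencies under Balding-Nichols.

    Beta shapes are p(1-F)/F and (1-p)(1-F)/F, giving mean p and variance
    F * p(1-p) per population, independently for the two populations.
    """
    rng = rng or np.random.default_rng(config.seed)
    lo, hi = config.base_freq_range
    p = rng.uniform(lo, hi, config.n_sites)
    f = config.fst
    shape1 = p * (1 - f) / f
    shape2 = (1 - p) * (1 - f) / f
    f_wild = rng.beta(shape1, shape2)
    f_vinifera = rng.beta(shape1, shape2)
    return f_wild, f_vinifera


def sample_panel(
    freqs: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Dosage matrix of ``n`` diploids: Binomial(2, f) per site, independent."""
    freqs = np.asarray(freqs, dtype=float)
    return rng.binomial(2, freqs[None, :], size=(n, freqs.size)).astype(np.int8)


def sample_admixed(
    freqs_wild: np.ndarray,
    freqs_vinifera: np.ndarray,
    alpha: float,
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, pd.DataFrame]:
    """``n`` admixed diploids with vinifera fraction ``alpha``.

    Each of the two allele copies at each site independently originates
    from the vinifera frequency with probability ``alpha``, else from the
    wild frequency. Returns the dosage matrix and a truth table.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    fw = np.asarray(freqs_wild, dtype=float)
    fv = np.asarray(freqs_vinifera, dtype=float)
    m = fw.size
    src_v = rng.random((n, m, 2)) < alpha
    f = np.where(src_v, fv[None, :, None], fw[None, :, None])
    dosage = (rng.random((n, m, 2)) < f).sum(axis=2).astype(np.int8)
    truth = pd.DataFrame(
        {"alpha": [alpha] * n, "origin": ["admixed"] * n}
    )
    return dosage, truth


def _haplotype_pool_dosages(
    freqs: np.ndarray,
    n: int,
    blocks: list[np.ndarray],
    pools: list[np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """Diploids drawn as two haplotypes per block from a finite pool."""
    out = np.zeros((n, freqs.size), dtype=np.int8)
    for block, pool in zip(blocks, pools):
        idx = rng.integers(0, pool.shape[0], size=(n, 2))
        out[:, block] = (pool[idx[:, 0]] + pool[idx[:, 1]]).astype(np.int8)
    return out


def _make_sites(config: SynthConfig, rng: np.random.Generator) -> list[SiteRecord]:
    chroms = rng.integers(1, config.n_chromosomes + 1, size=config.n_sites)
    pos = rng.integers(1, config.chromosome_length + 1, size=config.n_sites)
    order = np.lexsort((pos, chroms))
    chroms, pos = chroms[order], pos[order]
    # nudge duplicate positions apart so (chrom, pos) is unique
    for i in range(1, config.n_sites):
        if chroms[i] == chroms[i - 1] and pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    is_indel = rng.random(config.n_sites) < config.indel_fraction
    sites = []
    for c, p, ind in zip(chroms, pos, is_indel):
        ref, alt = rng.choice(4, size=2, replace=False)
        ref_a, alt_a = _BASES[ref], _BASES[alt]
        if ind:
            alt_a = alt_a + "".join(rng.choice(_BASES, size=rng.integers(1, 4)))
        sites.append(SiteRecord(f"chr{int(c)}", int(p), str(ref_a), str(alt_a)))
    return sites


def make_dataset(config: SynthConfig = SynthConfig()) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Assemble a labelled synthetic dataset plus its ancestry truth table.

    Returns a :class:`GenotypeMatrix` (wild + vinifera panels followed by
    admixed hybrids, with labels set) and a truth table with one row per
    sample (columns: sample, label, alpha, origin).
    """
    rng = np.random.default_rng(config.seed)
    fw, fv = draw_population_frequencies(config, rng)
    sites = _make_sites(config, rng)

    if config.n_blocks is not None:
        m = config.n_sites
        bounds = np.linspace(0, m, config.n_blocks + 1).astype(int)
        blocks = [np.arange(a, b) for a, b in zip(bounds, bounds[1:]) if b > a]
        pool_w = [
            (rng.random((config.haplotypes_per_block, len(b))) < fw[b]).astype(np.int8)
            for b in blocks
        ]
        pool_v = [
            (rng.random((config.haplotypes_per_block, len(b))) < fv[b]).astype(np.int8)
            for b in blocks
        ]
        wild = _haplotype_pool_dosages(fw, config.n_wild, blocks, pool_w, rng)
        vin = _haplotype_pool_dosages(fv, config.n_vinifera, blocks, pool_v, rng)
    else:
        wild = sample_panel(fw, config.n_wild, rng)
        vin = sample_panel(fv, config.n_vinifera, rng)

    parts = [wild, vin]
    samples = [f"wild_{i:02d}" for i in range(config.n_wild)] + [
        f"vinifera_{i:02d}" for i in range(config.n_vinifera)
    ]
    labels = ["wild"] * config.n_wild + ["vinifera"] * config.n_vinifera
    truth_rows = [
        {"sample": s, "label": lab, "alpha": 0.0 if lab == "wild" else 1.0,
         "origin": lab}
        for s, lab in zip(samples, labels)
    ]
    if config.n_hybrids > 0:
        lo, hi = config.hybrid_alpha_range
        alphas = np.linspace(lo, hi, config.n_hybrids)
        for i, alpha in enumerate(alphas):
            dos, _ = sample_admixed(fw, fv, float(alpha), 1, rng)
            parts.append(dos)
            sid = f"hybrid_{i:02d}"
            samples.append(sid)
            labels.append("hybrid")
            truth_rows.append(
                {"sample": sid, "label": "hybrid", "alpha": float(alpha),
                 "origin": "admixed"}
            )
    dosage = np.vstack(parts)

    depth = None
    if config.depth_mean is not None:
        depth = rng.poisson(config.depth_mean, size=dosage.shape).astype(np.int32)
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage = np.where(mask, np.int8(MISSING), dosage)

    matrix = GenotypeMatrix(
        samples=samples, sites=sites, dosage=dosage, labels=labels, depth=depth
    )
    return matrix, pd.DataFrame(truth_rows)
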