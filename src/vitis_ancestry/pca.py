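"""PCA-projection ancestry estimation.

The method at the heart of the analysis: principal axes are computed from
two equal-sized ancestral panels (wild *Vitis* and *V. vinifera*) alone;
hybrid samples are then projected onto those axes, and a sample's ancestry
coefficient is the ratio of its PC1 distances to the two panel means,

    % V. vinifera = b / (a + b) * 100,

where a = |PC1 - mean_vinifera| and b = |PC1 - mean_wild|.

Each site is normalised as (g - mean) / sqrt(p(1-p)) with the adjusted
allele-frequency estimate p = (1 + sum g) / (2 + 2n), the standard
normalisation for eigenanalysis of SNP data (the adjustment keeps the
scale strictly positive). PC1 is oriented so the vinifera panel mean
exceeds the wild panel mean, making the coefficient scale-free and
orientation-free. Held-out samples are projected with the fitted loadings
as plain dot products; no shrinkage correction is applied, so hybrids and
simulated offspring are treated identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix
from .ld import PruneParams, window_prune
from .qc import filter_by_maf

logger = logging.getLogger(__name__)


@dataclass
class PCAModel:
    """Fitted ancestral-panel PCA with everything needed for projection."""

    site_means: np.ndarray          # per-site mean dosage over the panels
    norm_factors: np.ndarray        # per-site sqrt(p(1-p)), p adjusted
    loadings: np.ndarray            # (n_pc, n_sites), unit-norm rows
    eigenvalues: np.ndarray         # per retained PC
    variance_explained: np.ndarray  # per retained PC, fraction of total
    ancestral_samples: list[str]
    ancestral_labels: list[str]
    ancestral_scores: np.ndarray    # (n_ancestral, n_pc)
    mean_wild_pc1: float
    mean_vinifera_pc1: float

    @property
    def n_pc(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_sites(self) -> int:
        return self.loadings.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Ancestral PC scores as a tidy table."""
        cols = {f"PC{i+1}": self.ancestral_scores[:, i] for i in range(self.n_pc)}
        return pd.DataFrame(
            {"sample": self.ancestral_samples, "label": self.ancestral_labels, **cols}
        )


@dataclass(frozen=True)
class AncestryEstimate:
    """Per-sample PC1 ancestry coefficient."""

    sample: str
    pc1_score: float
    dist_to_vinifera: float  # a
    dist_to_wild: float      # b
    percent_vinifera: float  # b / (a + b) * 100
    out_of_interval: bool = field(default=False)


def downsample_equal(
    matrix: GenotypeMatrix, seed: int | np.random.Generator = 0
) -> GenotypeMatrix:
    """Randomly downsample the larger ancestral panel to the smaller's size.

    PCA-projection ancestry requires equal ancestral sample sizes so that
    neither panel dominates the axes. Hybrid and unknown samples are
    untouched; removals are logged. Seeded and reproducible.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    wild = matrix.sample_indices("wild")
    vin = matrix.sample_indices("vinifera")
    if wild.size == 0 or vin.size == 0:
        raise ValueError("both ancestral panels must be non-empty")
    if wild.size == vin.size:
        return matrix.copy()
    big, small = (wild, vin) if wild.size > vin.size else (vin, wild)
    drop = rng.choice(big, size=big.size - small.size, replace=False)
    logger.info(
        "downsampling ancestral panel: removing %s",
        [matrix.samples[i] for i in sorted(drop)],
    )
    keep = np.setdiff1d(np.arange(matrix.n_samples), drop)
    return matrix.take_samples(keep)


def fit_pca(matrix: GenotypeMatrix, n_components: int = 10) -> PCAModel:
    """Fit PCA on the ancestral (wild + vinifera) samples of ``matrix``.

    Requires fully observed dosages on the panels and at least two samples
    per panel; sites monomorphic within the panels must be filtered first
    (the ancestral-MAF filter guarantees this) and raise otherwise.
    """
    wild = matrix.sample_indices("wild")
    vin = matrix.sample_indices("vinifera")
    if wild.size < 2 or vin.size < 2:
        raise ValueError("need at least two samples per ancestral panel")
    if wild.size != vin.size:
        raise ValueError(
            f"ancestral panels must be equal-sized (wild={wild.size}, "
            f"vinifera={vin.size}); apply downsample_equal first"
        )
    panel = np.concatenate([wild, vin])
    g = matrix.dosage[panel].astype(float)
    if (g == MISSING).any():
        raise ValueError("ancestral panel contains missing dosages; impute first")
    n = panel.size
    colsum = g.sum(axis=0)
    mono = np.flatnonzero((colsum == 0) | (colsum == 2 * n))
    if mono.size:
        rec = matrix.sites[mono[0]]
        raise ValueError(
            f"site {rec.chrom}:{rec.pos} is monomorphic in the ancestral panel"
            " (apply the ancestral-MAF filter first)"
        )
    means = g.mean(axis=0)
    p_hat = (1.0 + colsum) / (2.0 + 2.0 * n)
    norm = np.sqrt(p_hat * (1.0 - p_hat))
    x = (g - means) / norm
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = (s**2).sum()
    n_pc = int(min(n_components, (s > 1e-9 * s[0]).sum()))
    loadings = vt[:n_pc]
    scores = x @ loadings.T
    eigenvalues = s[:n_pc] ** 2 / max(n - 1, 1)
    var_exp = s[:n_pc] ** 2 / total
    labels = ["wild"] * wild.size + ["vinifera"] * vin.size
    mean_w = scores[: wild.size, 0].mean()
    mean_v = scores[wild.size :, 0].mean()
    if mean_v < mean_w:  # orient PC1: vinifera on the positive side
        loadings[0] = -loadings[0]
        scores[:, 0] = -scores[:, 0]
        mean_w, mean_v = -mean_w, -mean_v
    return PCAModel(
        site_means=means,
        norm_factors=norm,
        loadings=loadings,
        eigenvalues=eigenvalues,
        variance_explained=var_exp,
        ancestral_samples=[matrix.samples[i] for i in panel],
        ancestral_labels=labels,
        ancestral_scores=scores,
        mean_wild_pc1=float(mean_w),
        mean_vinifera_pc1=float(mean_v),
    )


def project(model: PCAModel, genotypes: np.ndarray) -> np.ndarray:
    """Project one or more dosage vectors onto the fitted axes.

    Accepts a 1-D vector or an (n_samples, n_sites) array; returns scores
    of shape (n_pc,) or (n_samples, n_pc). Missing dosages are handled by
    restricting each sample's dot product to its observed sites and
    rescaling by total/observed site counts (unbiased when missingness is
    unrelated to genotype); ancestral fitting samples projected here
    reproduce their stored scores exactly.
    """
    g = np.asarray(genotypes, dtype=float)
    single = g.ndim == 1
    g = np.atleast_2d(g)
    if g.shape[1] != model.n_sites:
        raise ValueError(
            f"genotypes have {g.shape[1]} sites, model expects {model.n_sites}"
        )
    obs = g != MISSING
    z = np.where(obs, (g - model.site_means) / model.norm_factors, 0.0)
    scores = z @ model.loadings.T
    n_obs = obs.sum(axis=1)
    if (n_obs == 0).any():
        raise ValueError("a sample has no observed sites")
    if (n_obs < model.n_sites).any():
        logger.info("projection with missing data: rescaling by observed fraction")
        scores = scores * (model.n_sites / n_obs)[:, None]
    return scores[0] if single else scores


def ancestry_percent(
    model: PCAModel, pc1_score: float, sample: str = ""
) -> AncestryEstimate:
    """PC1 distance-ratio ancestry coefficient for one projected sample.

    Scores outside the interval between the two panel means are reported
    as computed (the ratio stays in [0, 100] because distances are
    absolute values) with ``out_of_interval=True``.
    """
    a = abs(pc1_score - model.mean_vinifera_pc1)
    b = abs(pc1_score - model.mean_wild_pc1)
    if a + b == 0:
        raise ValueError("ancestral panel PC1 means coincide; ratio undefined")
    lo = min(model.mean_wild_pc1, model.mean_vinifera_pc1)
    hi = max(model.mean_wild_pc1, model.mean_vinifera_pc1)
    return AncestryEstimate(
        sample=sample,
        pc1_score=float(pc1_score),
        dist_to_vinifera=float(a),
        dist_to_wild=float(b),
        percent_vinifera=float(b / (a + b) * 100.0),
        out_of_interval=bool(pc1_score < lo or pc1_score > hi),
    )


def estimates_to_frame(estimates: list[AncestryEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [e.sample for e in estimates],
            "pc1": [e.pc1_score for e in estimates],
            "dist_to_vinifera": [e.dist_to_vinifera for e in estimates],
            "dist_to_wild": [e.dist_to_wild for e in estimates],
            "percent_vinifera": [e.percent_vinifera for e in estimates],
            "out_of_interval": [e.out_of_interval for e in estimates],
        }
    )


def prepare_model(
    matrix: GenotypeMatrix,
    n_components: int = 10,
    seed: int | np.random.Generator = 0,
    ancestral_min_maf: float = 0.10,
    prune: PruneParams | None = PruneParams(),
) -> tuple[PCAModel, GenotypeMatrix]:
    """Equalise panels, apply the ancestral-MAF filter, prune LD, fit PCA.

    Returns the fitted model together with the matrix restricted to the
    retained sites (all idempotent steps, so running them on an already
    prepared matrix changes nothing).
    """
    work = downsample_equal(matrix, seed)
    ancestral = [
        s for s, lab in zip(work.samples, work.labels) if lab in ("wild", "vinifera")
    ]
    work = filter_by_maf(work, ancestral_min_maf, sample_subset=ancestral, strict=True)
    if prune is not None:
        work = work.take_sites(window_prune(work, prune))
    model = fit_pca(work, n_components)
    return model, work


def estimate_all(
    matrix: GenotypeMatrix,
    n_components: int = 10,
    seed: int | np.random.Generator = 0,
    ancestral_min_maf: float = 0.10,
    prune: PruneParams | None = PruneParams(),
) -> tuple[pd.DataFrame, PCAModel]:
    """Full ancestry estimation for every hybrid sample in ``matrix``.

    Runs :func:`prepare_model` and projects each hybrid-labelled sample,
    returning a tidy estimate table and the fitted model.
    """
    model, work = prepare_model(
        matrix, n_components, seed, ancestral_min_maf, prune
    )
    hybrids = work.sample_indices("hybrid")
    estimates = []
    if hybrids.size:
        scores = project(model, work.dosage[hybrids])
        for row, i in enumerate(hybrids):
            estimates.append(
                ancestry_percent(model, scores[row, 0], sample=work.samples[i])
            )
    else:
        logger.warning("no hybrid-labelled samples to estimate")
    return estimates_to_frame(estimates), model
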