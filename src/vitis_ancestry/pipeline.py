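"""End-to-end orchestration: curation chain, ancestry run, simulation check.

The curation chain mirrors the order used for the GBS dataset: biallelic
filter (at VCF read), per-cell depth mask, site missingness, sample
missingness, genome-wide MAF, heterozygote-excess HWE, IBS vetting
report, LD-kNN imputation; ancestry preparation then equalises the
ancestral panels, applies the ancestral-MAF filter, prunes LD and fits
the projection PCA. Every step logs before/after sample and site counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crosses import TRUE_EXPECTED, CrossDesign, simulate_cohort, summarize_cohort
from .genotype_io import GenotypeMatrix
from .impute import ImputationParams, impute_all
from .ld import PruneParams
from .pca import PCAModel, ancestry_percent, estimate_all, prepare_model, project
from .qc import (
    CurationConfig,
    filter_by_maf,
    filter_hwe,
    filter_samples_by_missingness,
    filter_sites_by_missingness,
    mask_low_depth,
)
from .relatedness import ibs_matrix

logger = logging.getLogger(__name__)


@dataclass
class CurationResult:
    matrix: GenotypeMatrix
    log: pd.DataFrame
    ibs: pd.DataFrame | None = None


def _logstep(rows: list[dict], step: str, before: GenotypeMatrix, after: GenotypeMatrix) -> None:
    rows.append(
        {
            "step": step,
            "sites_before": before.n_sites,
            "sites_after": after.n_sites,
            "samples_before": before.n_samples,
            "samples_after": after.n_samples,
        }
    )
    logger.info(
        "%s: sites %d -> %d, samples %d -> %d",
        step, before.n_sites, after.n_sites, before.n_samples, after.n_samples,
    )


def run_curation(
    matrix: GenotypeMatrix,
    config: CurationConfig = CurationConfig(),
    impute_params: ImputationParams | None = ImputationParams(),
    compute_ibs: bool = True,
) -> CurationResult:
    """Apply the curation chain to an already-read genotype matrix.

    Depth masking is skipped (with a log line) when the matrix has no
    depth data; imputation is skipped when ``impute_params`` is None. The
    returned log has one row per applied step.
    """
    rows: list[dict] = []
    work = matrix
    if work.depth is not None and config.min_depth > 0:
        nxt = mask_low_depth(work, config.min_depth)
        _logstep(rows, f"depth_mask(minDP={config.min_depth})", work, nxt)
        work = nxt
    elif config.min_depth > 0:
        logger.info("no depth data; skipping depth mask")
    nxt = filter_sites_by_missingness(work, config.max_site_missing)
    _logstep(rows, f"site_missingness(<{config.max_site_missing})", work, nxt)
    work = nxt
    nxt = filter_samples_by_missingness(work, config.max_sample_missing)
    _logstep(rows, f"sample_missingness(<={config.max_sample_missing})", work, nxt)
    work = nxt
    if config.min_maf > 0:
        nxt = filter_by_maf(work, config.min_maf, strict=False)
        _logstep(rows, f"maf(>={config.min_maf})", work, nxt)
        work = nxt
    nxt = filter_hwe(work, config.hwe_alpha)
    _logstep(rows, f"hwe_excess_het(p<{config.hwe_alpha})", work, nxt)
    work = nxt
    ibs = None
    if compute_ibs and work.sample_indices("hybrid").size >= 2:
        ibs = ibs_matrix(work, labels=["hybrid"])
    if impute_params is not None and work.missing_mask().any():
        nxt = impute_all(work, impute_params)
        _logstep(
            rows, f"ldknn_impute(l={impute_params.l},k={impute_params.k})", work, nxt
        )
        work = nxt
    return CurationResult(matrix=work, log=pd.DataFrame(rows), ibs=ibs)


def run_ancestry(
    matrix: GenotypeMatrix,
    n_components: int = 10,
    seed: int = 0,
    config: CurationConfig = CurationConfig(),
    prune: PruneParams | None = PruneParams(),
) -> tuple[pd.DataFrame, pd.DataFrame, PCAModel]:
    """Ancestry estimates plus PC-score table for a curated matrix.

    Refuses unequal ancestral panels only implicitly: the preparation step
    downsamples the larger panel (seeded) before fitting.
    """
    estimates, model = estimate_all(
        matrix,
        n_components=n_components,
        seed=seed,
        ancestral_min_maf=config.ancestral_min_maf,
        prune=prune,
    )
    scores = model.to_frame()
    return estimates, scores, model


def run_simulation_validation(
    matrix: GenotypeMatrix,
    n_offspring: int = 10_000,
    seed: int = 0,
    config: CurationConfig = CurationConfig(),
    prune: PruneParams | None = PruneParams(),
    n_components: int = 10,
) -> tuple[pd.DataFrame, dict[str, np.ndarray], PCAModel]:
    """Simulate F1 / BC_wild / BC_vinifera cohorts and estimate their ancestry.

    Fits the projection model on the (equalised, filtered, pruned)
    ancestral panels of ``matrix``, simulates the three cohorts from the
    retained panel genotypes, projects them, and summarises mean and
    empirical 95% interval per design. The ancestral panels must be fully
    observed (impute first).
    """
    ss = np.random.SeedSequence(seed)
    model_seed, *cohort_seeds = [int(s) for s in ss.generate_state(4) >> 1]
    model, work = prepare_model(
        matrix, n_components=n_components, seed=model_seed,
        ancestral_min_maf=config.ancestral_min_maf, prune=prune,
    )
    wild = work.dosage[work.sample_indices("wild")]
    vin = work.dosage[work.sample_indices("vinifera")]
    rows = []
    per_design: dict[str, np.ndarray] = {}
    for design_name, dseed in zip(("F1", "BC_wild", "BC_vinifera"), cohort_seeds):
        design = CrossDesign(design_name, n_offspring, seed=dseed)
        cohort = simulate_cohort(wild, vin, design)
        scores = project(model, cohort.dosage)
        pct = np.array(
            [ancestry_percent(model, s).percent_vinifera for s in scores[:, 0]]
        )
        mean, lo, hi = summarize_cohort(pct)
        per_design[design_name] = pct
        rows.append(
            {
                "design": design_name,
                "n": n_offspring,
                "expected_percent": TRUE_EXPECTED[design_name] * 100,
                "mean_percent": mean,
                "ci_low": lo,
                "ci_high": hi,
                "seed": dseed,
            }
        )
    return pd.DataFrame(rows), per_design, model


def classify_estimate(percent: float, summary: pd.DataFrame) -> str:
    """Which simulated design's 95% interval (if any) contains ``percent``.

    Mirrors the colouring of per-cultivar estimate bars by consistency
    with F1 or backcross expectations; returns "none" when outside all.
    """
    for _, row in summary.iterrows():
        if row["ci_low"] <= percent <= row["ci_high"]:
            return str(row["design"])
    return "none"
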