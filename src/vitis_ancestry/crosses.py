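"""In-silico F1 and backcross simulation.

Offspring are produced by Mendelian gamete sampling from genotyped
parents: at every site each parent contributes one allele, drawn
uniformly from its two copies, independently across sites (linkage
between sites is ignored). F1 cohorts cross one random wild parent with
one random vinifera parent; backcross cohorts cross a freshly simulated
F1 with a random member of the stated panel, so the expected vinifera
fraction is 0.5, 0.25 (backcross to wild) or 0.75 (backcross to
vinifera). Cohorts are projected through the fitted ancestral PCA to
validate the distance-ratio estimator against these known expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING

DESIGNS = ("F1", "BC_wild", "BC_vinifera", "custom")

#: expected vinifera fraction per design
TRUE_EXPECTED = {"F1": 0.5, "BC_wild": 0.25, "BC_vinifera": 0.75}


@dataclass(frozen=True)
class CrossDesign:
    design: str = "F1"
    n_offspring: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}")
        if self.n_offspring < 1:
            raise ValueError("n_offspring must be >= 1")


@dataclass
class SimulatedCohort:
    """Offspring dosages with their cross design and ancestry truth."""

    dosage: np.ndarray            # (n_offspring, n_sites)
    design: CrossDesign
    true_expected_ancestry: float
    parent_ids: list[tuple[str, str]] = field(default_factory=list)


def gamete(parent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Haploid allele draw from one or many diploid parents.

    Dosage 0 yields allele 0, dosage 2 allele 1, dosage 1 a fair coin;
    sites are independent. Accepts a vector or a (k, n_sites) matrix.
    """
    p = np.asarray(parent)
    if (p == MISSING).any():
        raise ValueError("parent dosages contain missing values; impute first")
    coin = rng.integers(0, 2, size=p.shape, dtype=np.int8)
    return ((p == 2) + (p == 1) * coin).astype(np.int8)


def cross(
    p1: np.ndarray, p2: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Offspring dosage(s): one gamete from each parent, summed per site."""
    p1 = np.asarray(p1)
    p2 = np.asarray(p2)
    if p1.shape != p2.shape:
        raise ValueError("parents must share the same site set")
    return gamete(p1, rng) + gamete(p2, rng)


def _pick_rows(
    panel: np.ndarray, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    idx = rng.integers(0, panel.shape[0], size=n)
    return panel[idx], idx


def simulate_cohort(
    wild_panel: np.ndarray,
    vinifera_panel: np.ndarray,
    design: CrossDesign,
    wild_ids: list[str] | None = None,
    vinifera_ids: list[str] | None = None,
) -> SimulatedCohort:
    """Simulate an offspring cohort from two fully observed ancestral panels.

    Each F1 offspring gets one random parent per panel; each backcross
    offspring crosses a freshly simulated F1 (drawn with replacement) with
    a random individual of the stated panel.
    """
    wild_panel = np.asarray(wild_panel, dtype=np.int8)
    vinifera_panel = np.asarray(vinifera_panel, dtype=np.int8)
    if wild_panel.shape[0] == 0 or vinifera_panel.shape[0] == 0:
        raise ValueError("both ancestral panels must be non-empty")
    if wild_panel.shape[1] != vinifera_panel.shape[1]:
        raise ValueError("panels must share the same site set")
    rng = np.random.default_rng(design.seed)
    n = design.n_offspring
    wid = wild_ids or [f"wild{i}" for i in range(wild_panel.shape[0])]
    vid = vinifera_ids or [f"vinifera{i}" for i in range(vinifera_panel.shape[0])]

    w_rows, w_idx = _pick_rows(wild_panel, n, rng)
    v_rows, v_idx = _pick_rows(vinifera_panel, n, rng)
    f1 = gamete(w_rows, rng) + gamete(v_rows, rng)

    if design.design == "F1":
        dosage = f1
        parents = [(wid[a], vid[b]) for a, b in zip(w_idx, v_idx)]
    elif design.design in ("BC_wild", "BC_vinifera"):
        panel, ids = (
            (wild_panel, wid) if design.design == "BC_wild" else (vinifera_panel, vid)
        )
        bc_rows, bc_idx = _pick_rows(panel, n, rng)
        dosage = gamete(f1, rng) + gamete(bc_rows, rng)
        parents = [(f"F1_{i}", ids[b]) for i, b in enumerate(bc_idx)]
    else:
        raise ValueError("custom designs require explicit parent dosages")
    return SimulatedCohort(
        dosage=dosage,
        design=design,
        true_expected_ancestry=TRUE_EXPECTED[design.design],
        parent_ids=parents,
    )


def summarize_cohort(estimates: np.ndarray) -> tuple[float, float, float]:
    """Mean and empirical 95% interval (2.5th/97.5th percentiles) of
    per-offspring ancestry estimates, linear interpolation."""
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("no estimates to summarise")
    lo, hi = np.percentile(est, [2.5, 97.5], method="linear")
    return float(est.mean()), float(lo), float(hi)
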