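"""Genotype matrix container and VCF / sample-label I/O.

The central object of the analysis is a samples x sites diploid dosage
matrix over biallelic variants: each cell counts copies of the ALT allele
(0, 1 or 2) or is missing. Multi-allelic records are dropped at read time;
all downstream filters, imputation and PCA operate on this matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

#: sentinel for a missing dosage / absent depth cell
MISSING = -1

#: recognised sample labels
VALID_LABELS = ("wild", "vinifera", "hybrid", "unknown")


class GenotypeIOError(ValueError):
    """Raised for malformed VCF or label inputs."""


@dataclass(frozen=True)
class SiteRecord:
    """One biallelic variant site."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("alleles must be non-empty")

    @property
    def variant_class(self) -> str:
        """``"snp"`` iff both alleles have length 1, else ``"indel"``."""
        if len(self.ref_allele) == 1 and len(self.alt_allele) == 1:
            return "snp"
        return "indel"


@dataclass
class GenotypeMatrix:
    """Samples x sites dosage matrix with labels and optional read depth.

    Parameters
    ----------
    samples
        Ordered, unique sample identifiers.
    sites
        Ordered :class:`SiteRecord` list, one per dosage column.
    dosage
        ``(n_samples, n_sites)`` int8 array; entries in {0, 1, 2} or
        :data:`MISSING`.
    labels
        Per-sample label from :data:`VALID_LABELS`; defaults to "unknown".
    depth
        Optional per-cell read depth (same shape as ``dosage``;
        :data:`MISSING` marks an absent DP value).
    """

    samples: list[str]
    sites: list[SiteRecord]
    dosage: np.ndarray
    labels: list[str] = field(default_factory=list)
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.samples)}, {len(self.sites)})"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample identifiers must be unique")
        bad = ~np.isin(self.dosage, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosage entries must be in {0, 1, 2, missing}")
        if not self.labels:
            self.labels = ["unknown"] * len(self.samples)
        if len(self.labels) != len(self.samples):
            raise ValueError("labels must align with samples")
        for lab in self.labels:
            if lab not in VALID_LABELS:
                raise ValueError(f"unknown label {lab!r}")
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=np.int32)
            if self.depth.shape != self.dosage.shape:
                raise ValueError("depth shape must match dosage shape")

    # -- basic geometry ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def missing_mask(self) -> np.ndarray:
        """Boolean mask of missing dosage cells."""
        return self.dosage == MISSING

    def sample_indices(self, label: str) -> np.ndarray:
        """Indices of samples carrying ``label``."""
        return np.flatnonzero(np.array(self.labels) == label)

    def label_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.labels:
            out[lab] = out.get(lab, 0) + 1
        return out

    # -- subsetting ----------------------------------------------------
    def take_samples(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            sites=list(self.sites),
            dosage=self.dosage[idx].copy(),
            labels=[self.labels[i] for i in idx],
            depth=None if self.depth is None else self.depth[idx].copy(),
        )

    def take_sites(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=[self.sites[i] for i in idx],
            dosage=self.dosage[:, idx].copy(),
            labels=list(self.labels),
            depth=None if self.depth is None else self.depth[:, idx].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=list(self.sites),
            dosage=self.dosage.copy(),
            labels=list(self.labels),
            depth=None if self.depth is None else self.depth.copy(),
        )

    def with_labels(self, labels: Sequence[str]) -> "GenotypeMatrix":
        out = self.copy()
        out.labels = list(labels)
        if len(out.labels) != out.n_samples:
            raise ValueError("labels must align with samples")
        return out


def read_vcf(path: str | Path, keep_indels: bool = True) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Only biallelic records are kept (records with zero or more than one ALT
    allele are dropped). Phased and unphased genotypes are treated
    identically; half-calls (one missing allele) become missing. Per-genotype
    DP is captured when present.
    """
    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - htslib error text varies
        raise GenotypeIOError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise GenotypeIOError(f"VCF {path} contains no samples")

    sites: list[SiteRecord] = []
    dosage_rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    any_depth = False
    try:
        for var in vcf:
            if len(var.ALT) != 1:
                continue  # biallelic filter
            rec = SiteRecord(var.CHROM, var.POS, var.REF, var.ALT[0])
            if not keep_indels and rec.variant_class == "indel":
                continue
            gts = var.genotypes  # [[a1, a2, phased], ...]
            dos = np.full(len(samples), MISSING, dtype=np.int8)
            for i, gt in enumerate(gts):
                alleles = gt[:-1]
                if len(alleles) == 2 and alleles[0] >= 0 and alleles[1] >= 0:
                    dos[i] = alleles[0] + alleles[1]
            try:
                dp = var.format("DP")
            except KeyError:  # DP absent from the FORMAT header
                dp = None
            if dp is not None:
                any_depth = True
                dpv = dp.reshape(-1).astype(np.int64)
                dpv = np.where(dpv < 0, MISSING, dpv)
            else:
                dpv = np.full(len(samples), MISSING, dtype=np.int64)
            sites.append(rec)
            dosage_rows.append(dos)
            depth_rows.append(dpv.astype(np.int32))
    except GenotypeIOError:
        raise
    except Exception as exc:
        raise GenotypeIOError(
            f"malformed VCF {path} near record {len(sites) + 1}: {exc}"
        ) from exc

    if dosage_rows:
        dosage = np.stack(dosage_rows, axis=1)
        depth = np.stack(depth_rows, axis=1) if any_depth else None
    else:
        dosage = np.zeros((len(samples), 0), dtype=np.int8)
        depth = None
    return GenotypeMatrix(samples=samples, sites=sites, dosage=dosage, depth=depth)


def read_labels(path: str | Path, matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Attach sample labels from a two-column TSV (sample_id<TAB>label).

    Labels are case-insensitive and normalised to lowercase. Samples absent
    from the file are labelled "unknown"; file entries naming unknown
    samples are logged as warnings.
    """
    path = Path(path)
    assigned: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise GenotypeIOError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            sid, label = parts[0].strip(), parts[1].strip().lower()
            if label not in ("wild", "vinifera", "hybrid"):
                raise GenotypeIOError(
                    f"{path}:{lineno}: label {parts[1]!r} not in "
                    "{wild, vinifera, hybrid}"
                )
            assigned[sid] = label
    known = set(matrix.samples)
    for sid in assigned:
        if sid not in known:
            logger.warning("label file names unknown sample %r", sid)
    labels = [assigned.get(s, "unknown") for s in matrix.samples]
    return matrix.with_labels(labels)


def write_labels(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the sample-label TSV consumed by :func:`read_labels`."""
    with open(path, "w", encoding="utf-8") as fh:
        for sid, lab in zip(matrix.samples, matrix.labels):
            if lab != "unknown":
                fh.write(f"{sid}\t{lab}\n")


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as VCF 4.2 (GT, plus DP when depth is present).

    ``read_vcf(write_vcf(m))`` reproduces samples, sites, dosage and depth
    exactly.
    """
    if matrix.n_samples == 0:
        raise GenotypeIOError("cannot write a VCF with no samples")
    has_depth = matrix.depth is not None
    chroms: list[str] = []
    for rec in matrix.sites:
        if rec.chrom not in chroms:
            chroms.append(rec.chrom)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=vitis_ancestry\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_depth:
            fh.write(
                '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        fmt = "GT:DP" if has_depth else "GT"
        for j, rec in enumerate(matrix.sites):
            fields = [
                rec.chrom,
                str(rec.pos),
                ".",
                rec.ref_allele,
                rec.alt_allele,
                ".",
                "PASS",
                ".",
                fmt,
            ]
            for i in range(matrix.n_samples):
                gt = _GT_STRINGS[int(matrix.dosage[i, j])]
                if has_depth:
                    d = int(matrix.depth[i, j])
                    gt += ":" + ("." if d == MISSING else str(d))
                fields.append(gt)
            fh.write("\t".join(fields) + "\n")
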