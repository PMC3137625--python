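"""Core in-memory containers for phased panels and unphased genotype matrices.

A :class:`HaplotypePanel` stores one row per haplotype (two consecutive rows
per diploid individual) over an ordered list of biallelic SNPs; a
:class:`GenotypeMatrix` stores one row per individual with genotypes coded as
alternate-allele counts (0/1/2) or :data:`MISSING`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: Sentinel for a missing genotype (``./.`` in VCF).
MISSING: int = -1

#: Phenotype codes, following the common GWAS convention (1=control, 2=case).
CONTROL: int = 1
CASE: int = 2


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNP: chromosome, 1-based position, id and its two alleles."""

    chrom: str
    pos: int
    id: str
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError(
                f"variant {self.id} at {self.chrom}:{self.pos} is not a SNP "
                f"({self.ref_allele}>{self.alt_allele})"
            )

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


def _check_sorted_positions(variants: Sequence[VariantRecord]) -> None:
    """Positions must be strictly increasing within each chromosome."""
    last: dict[str, int] = {}
    seen_order: list[str] = []
    for v in variants:
        if v.chrom in last:
            if seen_order[-1] != v.chrom:
                raise ValueError(f"variants for chromosome {v.chrom} are not contiguous")
            if v.pos <= last[v.chrom]:
                raise ValueError(
                    f"positions not strictly increasing on {v.chrom}: "
                    f"{last[v.chrom]} then {v.pos}"
                )
        else:
            seen_order.append(v.chrom)
        last[v.chrom] = v.pos


@dataclass
class HaplotypePanel:
    """Phase-known haplotypes: a binary allele matrix plus variant metadata.

    ``alleles`` has shape (2 * n_individuals, n_sites) with entries in {0, 1};
    rows ``2i`` and ``2i + 1`` are the two haplotypes of individual
    ``sample_ids[i]``. A phase-known panel carries no missing alleles.
    """

    variants: list[VariantRecord]
    alleles: np.ndarray
    sample_ids: list[str]
    phenotype: np.ndarray | None = None  # per-individual {CONTROL, CASE}

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(np.asarray(self.alleles, dtype=np.uint8))
        if self.alleles.ndim != 2:
            raise ValueError("allele matrix must be 2-D")
        n_rows, n_sites = self.alleles.shape
        if n_rows % 2 != 0:
            raise ValueError("haplotype row count must be even (two rows per individual)")
        if n_rows != 2 * len(self.sample_ids):
            raise ValueError("row count must equal 2 x number of individuals")
        if n_sites != len(self.variants):
            raise ValueError("column count must equal number of variants")
        if self.alleles.size and self.alleles.max() > 1:
            raise ValueError("panel alleles must be 0/1 with no missing values")
        _check_sorted_positions(self.variants)
        if self.phenotype is not None:
            self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
            if self.phenotype.shape != (len(self.sample_ids),):
                raise ValueError("phenotype length must equal individual count")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_individuals(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants])

    def take_sites(self, indices: Sequence[int] | np.ndarray) -> "HaplotypePanel":
        """Panel restricted to the given site indices (order preserved)."""
        idx = np.asarray(indices, dtype=np.intp)
        return HaplotypePanel(
            variants=[self.variants[i] for i in idx],
            alleles=self.alleles[:, idx],
            sample_ids=list(self.sample_ids),
            phenotype=None if self.phenotype is None else self.phenotype.copy(),
        )

    def take_individuals(self, indices: Sequence[int] | np.ndarray) -> "HaplotypePanel":
        """Panel restricted to the given individuals, keeping row pairing."""
        idx = np.asarray(indices, dtype=np.intp)
        rows = np.empty(2 * len(idx), dtype=np.intp)
        rows[0::2] = 2 * idx
        rows[1::2] = 2 * idx + 1
        return HaplotypePanel(
            variants=list(self.variants),
            alleles=self.alleles[rows, :],
            sample_ids=[self.sample_ids[i] for i in idx],
            phenotype=None if self.phenotype is None else self.phenotype[idx],
        )

    def individual_pair(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """The two haplotype rows of individual ``i``."""
        return self.alleles[2 * i], self.alleles[2 * i + 1]

    def to_genotypes(self) -> "GenotypeMatrix":
        """Collapse phased haplotypes to unphased alt-allele counts."""
        g = (self.alleles[0::2, :].astype(np.int8) + self.alleles[1::2, :]).astype(np.int8)
        return GenotypeMatrix(
            variants=list(self.variants),
            genotypes=g,
            sample_ids=list(self.sample_ids),
            phenotype=None if self.phenotype is None else self.phenotype.copy(),
        )


@dataclass
class GenotypeMatrix:
    """Unphased genotypes: one row per individual, coded 0/1/2 or MISSING."""

    variants: list[VariantRecord]
    genotypes: np.ndarray
    sample_ids: list[str]
    phenotype: np.ndarray | None = None  # per-individual {CONTROL, CASE}

    def __post_init__(self) -> None:
        self.genotypes = np.ascontiguousarray(np.asarray(self.genotypes, dtype=np.int8))
        if self.genotypes.ndim != 2:
            raise ValueError("genotype matrix must be 2-D")
        if self.genotypes.shape[0] != len(self.sample_ids):
            raise ValueError("row count must equal number of individuals")
        if self.genotypes.shape[1] != len(self.variants):
            raise ValueError("column count must equal number of variants")
        valid = np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if not valid.all():
            raise ValueError("genotypes must be 0/1/2 or MISSING")
        _check_sorted_positions(self.variants)
        if self.phenotype is not None:
            self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
            if self.phenotype.shape != (len(self.sample_ids),):
                raise ValueError("phenotype length must equal individual count")
            if not np.isin(self.phenotype, (CONTROL, CASE)).all():
                raise ValueError("phenotype codes must be 1 (control) or 2 (case)")

    @property
    def n_individuals(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    def take_sites(self, indices: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=np.intp)
        return GenotypeMatrix(
            variants=[self.variants[i] for i in idx],
            genotypes=self.genotypes[:, idx],
            sample_ids=list(self.sample_ids),
            phenotype=None if self.phenotype is None else self.phenotype.copy(),
        )

    def case_control_counts(self) -> tuple[int, int]:
        if self.phenotype is None:
            raise ValueError("genotype matrix carries no phenotype labels")
        return int((self.phenotype == CASE).sum()), int((self.phenotype == CONTROL).sum())
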