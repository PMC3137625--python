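"""VCF / phenotype file I/O and panel-study harmonization.

Reads a phase-known reference panel (phased VCF) and an unphased case/control
study (VCF + two-column phenotype file), restricts both to their shared SNPs,
and writes the simple text formats used throughout the package. All
coordinates are 1-based VCF positions; genomic windows downstream are closed
intervals in bp.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
from cyvcf2 import VCF

from .containers import (
    CASE,
    CONTROL,
    MISSING,
    GenotypeMatrix,
    HaplotypePanel,
    VariantRecord,
)

logger = logging.getLogger(__name__)

#: Strand-ambiguous allele pairs (palindromic SNPs): an apparent ref/alt swap
#: at these sites is indistinguishable from a strand flip, so it is dropped
#: rather than recoded.
_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def _is_biallelic_snp(variant) -> bool:
    return (
        len(variant.ALT) == 1
        and len(variant.REF) == 1
        and len(variant.ALT[0]) == 1
        and variant.REF[0] in "ACGT"
        and variant.ALT[0][0] in "ACGT"
    )


def _record(variant) -> VariantRecord:
    vid = variant.ID if variant.ID else f"{variant.CHROM}:{variant.POS}"
    return VariantRecord(
        chrom=str(variant.CHROM),
        pos=int(variant.POS),
        id=str(vid),
        ref_allele=variant.REF,
        alt_allele=variant.ALT[0],
    )


def read_phased_panel(path: str | Path) -> HaplotypePanel:
    """Load a phase-known reference panel from a phased VCF.

    Only biallelic SNP records are retained (multi-allelic sites and indels
    are skipped with a logged count). Every retained genotype must be phased
    (``|`` separator) and complete; anything else is an error, because a
    phase-known panel admits no ambiguity.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: list[np.ndarray] = []
    variants: list[VariantRecord] = []
    skipped = 0
    for variant in vcf:
        if not _is_biallelic_snp(variant):
            skipped += 1
            continue
        rec = _record(variant)
        col = np.empty(2 * len(samples), dtype=np.uint8)
        for si, gt in enumerate(variant.genotypes):
            a, b, phased = gt[0], gt[1], gt[-1]
            if a < 0 or b < 0:
                raise ValueError(
                    f"missing genotype for sample {samples[si]} at "
                    f"{rec.chrom}:{rec.pos}; a phase-known panel must be complete"
                )
            if not phased:
                raise ValueError(
                    f"unphased genotype for sample {samples[si]} at "
                    f"{rec.chrom}:{rec.pos}; the reference panel must be phased"
                )
            col[2 * si] = a
            col[2 * si + 1] = b
        variants.append(rec)
        columns.append(col)
    if skipped:
        logger.info("read_phased_panel: skipped %d non-biallelic/indel records", skipped)
    alleles = (
        np.stack(columns, axis=1) if columns else np.zeros((2 * len(samples), 0), np.uint8)
    )
    return HaplotypePanel(variants=variants, alleles=alleles, sample_ids=samples)


def read_phenotypes(path: str | Path) -> dict[str, int]:
    """Two-column whitespace file: sample_id then 1 (control) or 2 (case)."""
    labels: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'sample_id 1|2', got {line!r}")
        sid, code = parts
        if code not in ("1", "2"):
            raise ValueError(f"{path}:{lineno}: phenotype must be 1 (control) or 2 (case)")
        labels[sid] = int(code)
    return labels


def read_genotypes(path: str | Path, phenotype_path: str | Path) -> GenotypeMatrix:
    """Load unphased study genotypes plus case/control labels.

    Genotypes are coded as alternate-allele counts; phase separators are
    ignored; ``./.`` is coded MISSING. Every VCF sample must carry a phenotype
    label, and every labelled sample must be present in the VCF.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    labels = read_phenotypes(phenotype_path)
    unlabelled = [s for s in samples if s not in labels]
    if unlabelled:
        raise ValueError(f"samples without a phenotype label: {unlabelled}")
    orphans = [s for s in labels if s not in set(samples)]
    if orphans:
        raise ValueError(f"phenotype entries missing from the VCF: {orphans}")

    columns: list[np.ndarray] = []
    variants: list[VariantRecord] = []
    skipped = 0
    for variant in vcf:
        if not _is_biallelic_snp(variant):
            skipped += 1
            continue
        variants.append(_record(variant))
        col = np.empty(len(samples), dtype=np.int8)
        for si, gt in enumerate(variant.genotypes):
            a, b = gt[0], gt[1]
            col[si] = MISSING if (a < 0 or b < 0) else a + b
        columns.append(col)
    if skipped:
        logger.info("read_genotypes: skipped %d non-biallelic/indel records", skipped)
    genotypes = (
        np.stack(columns, axis=1) if columns else np.zeros((len(samples), 0), np.int8)
    )
    phenotype = np.array([labels[s] for s in samples], dtype=np.int8)
    return GenotypeMatrix(
        variants=variants, genotypes=genotypes, sample_ids=samples, phenotype=phenotype
    )


def harmonize(
    panel: HaplotypePanel, geno: GenotypeMatrix
) -> tuple[HaplotypePanel, GenotypeMatrix]:
    """Restrict panel and study to the SNPs they share.

    Sites match on (chrom, pos, ref, alt). A site matching on position with
    swapped ref/alt alleles is retained after recoding the study genotypes
    (g -> 2-g), unless the allele pair is strand-ambiguous (A/T or C/G), in
    which case it is dropped with a warning.
    """
    panel_index = {v.key: (i, v) for i, v in enumerate(panel.variants)}
    keep_panel: list[int] = []
    keep_geno: list[int] = []
    recoded: list[int] = []
    ambiguous_dropped = 0
    for j, sv in enumerate(geno.variants):
        hit = panel_index.get(sv.key)
        if hit is None:
            continue
        i, pv = hit
        if (sv.ref_allele, sv.alt_allele) == (pv.ref_allele, pv.alt_allele):
            keep_panel.append(i)
            keep_geno.append(j)
        elif (sv.ref_allele, sv.alt_allele) == (pv.alt_allele, pv.ref_allele):
            if (sv.ref_allele, sv.alt_allele) in _AMBIGUOUS_PAIRS:
                ambiguous_dropped += 1
                continue
            keep_panel.append(i)
            keep_geno.append(j)
            recoded.append(j)
    if ambiguous_dropped:
        logger.warning(
            "harmonize: dropped %d strand-ambiguous ref/alt swaps", ambiguous_dropped
        )
    if recoded:
        logger.info("harmonize: recoded %d sites with swapped ref/alt", len(recoded))
    if not keep_panel:
        raise ValueError("no shared SNPs between the reference panel and the study")

    new_panel = panel.take_sites(keep_panel)
    g = geno.genotypes[:, keep_geno].copy()
    recode_cols = {j for j in recoded}
    for local, j in enumerate(keep_geno):
        if j in recode_cols:
            col = g[:, local]
            nonmiss = col != MISSING
            col[nonmiss] = 2 - col[nonmiss]
    new_geno = GenotypeMatrix(
        variants=list(new_panel.variants),  # adopt panel allele coding
        genotypes=g,
        sample_ids=list(geno.sample_ids),
        phenotype=None if geno.phenotype is None else geno.phenotype.copy(),
    )
    return new_panel, new_geno


def _vcf_header(variants: Iterable[VariantRecord], sample_ids: list[str]) -> list[str]:
    chrom_order: list[str] = []
    for v in variants:
        if v.chrom not in chrom_order:
            chrom_order.append(v.chrom)
    lines = ["##fileformat=VCFv4.2", "##source=haploscan"]
    lines += [f"##contig=<ID={c}>" for c in chrom_order]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids)
    )
    return lines


def write_panel(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a phased VCF (GT only, ``|`` separator)."""
    lines = _vcf_header(panel.variants, panel.sample_ids)
    for j, v in enumerate(panel.variants):
        col = panel.alleles[:, j]
        gts = [f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(panel.n_individuals)]
        lines.append(
            f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref_allele}\t{v.alt_allele}\t.\t.\t.\tGT\t"
            + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


_GT_CODES = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write an unphased VCF (GT only, ``/`` separator)."""
    lines = _vcf_header(geno.variants, geno.sample_ids)
    for j, v in enumerate(geno.variants):
        col = geno.genotypes[:, j]
        gts = [_GT_CODES[int(g)] for g in col]
        lines.append(
            f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref_allele}\t{v.alt_allele}\t.\t.\t.\tGT\t"
            + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_phenotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    if geno.phenotype is None:
        raise ValueError("genotype matrix carries no phenotype labels")
    lines = [f"{s}\t{int(p)}" for s, p in zip(geno.sample_ids, geno.phenotype)]
    Path(path).write_text("\n".join(lines) + "\n")
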