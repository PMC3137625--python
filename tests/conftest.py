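import numpy as np
import pytest

from haploscan.containers import GenotypeMatrix, HaplotypePanel, VariantRecord


def make_panel(alleles, positions=None, chrom="1", ref="A", alt="C",
               phenotype=None) -> HaplotypePanel:
    """Build a HaplotypePanel from a row-per-haplotype 0/1 matrix."""
    alleles = np.asarray(alleles, dtype=np.uint8)
    n_sites = alleles.shape[1]
    if positions is None:
        positions = [10 * (j + 1) for j in range(n_sites)]
    variants = [
        VariantRecord(chrom=chrom, pos=int(p), id=f"rs{j}", ref_allele=ref, alt_allele=alt)
        for j, p in enumerate(positions)
    ]
    n_ind = alleles.shape[0] // 2
    return HaplotypePanel(
        variants=variants,
        alleles=alleles,
        sample_ids=[f"s{i}" for i in range(n_ind)],
        phenotype=phenotype,
    )


def make_genotypes(genotypes, positions=None, chrom="1", phenotype=None) -> GenotypeMatrix:
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_sites = genotypes.shape[1]
    if positions is None:
        positions = [10 * (j + 1) for j in range(n_sites)]
    variants = [
        VariantRecord(chrom=chrom, pos=int(p), id=f"rs{j}", ref_allele="A", alt_allele="C")
        for j, p in enumerate(positions)
    ]
    return GenotypeMatrix(
        variants=variants,
        genotypes=genotypes,
        sample_ids=[f"g{i}" for i in range(genotypes.shape[0])],
        phenotype=phenotype,
    )


def random_tree_panel(rng, n_haplotypes, n_sites):
    """A panel whose columns are nested splits of a random mutation tree,
    hence globally four-gamete compatible."""
    haps = np.zeros((n_haplotypes, n_sites), dtype=np.uint8)
    # grow haplotypes by repeatedly splitting an existing class with a new mutation
    classes = [list(range(n_haplotypes))]
    for j in range(n_sites):
        cls = classes[rng.integers(len(classes))]
        if len(cls) < 2:
            continue
        k = int(rng.integers(1, len(cls)))
        carriers = list(rng.permutation(cls)[:k])
        haps[carriers, j] = 1
        rest = [c for c in cls if c not in carriers]
        classes.remove(cls)
        classes.extend([carriers, rest])
    return haps


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def toy_panel():
    """Six haplotypes over two sites showing three of four gametes."""
    return make_panel([[0, 0], [0, 0], [0, 1], [0, 1], [1, 1], [1, 1]])
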