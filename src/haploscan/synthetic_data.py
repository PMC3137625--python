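"""Coalescent simulation of reference panels and case/control cohorts.

Haplotypes are generated by msprime under a constant-size coalescent with
recombination (Ne = 5,000, mu = 2e-8/bp, r = 1.2e-8/bp by default) and an
infinite-sites binary mutation model, then partitioned into a phase-known
reference panel and a study cohort whose chromosomes are randomly assigned
to case/control groups and paired into diploid individuals. Sites are
filtered on minor allele frequency computed over the study chromosomes.

Desk-scale defaults (1 Mb, 600 chromosomes of which 200 form the panel) keep
the full pipeline fast; :meth:`SimulationParams.full_scale` restores the
25 Mb / 2,200-chromosome configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import msprime
import numpy as np

from .containers import CASE, CONTROL, MISSING, GenotypeMatrix, HaplotypePanel, VariantRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationParams:
    """Coalescent and cohort-assembly parameters."""

    Ne: float = 5_000.0
    mu: float = 2e-8  # per bp per generation
    rec: float = 1.2e-8  # per bp per generation
    length_bp: int = 1_000_000
    n_chromosomes: int = 600
    n_reference: int = 200
    maf_min: float = 0.05
    seed: int = 1
    # Optional extension (not part of the null design): multiplicative
    # relative risk attached to the alt allele of one site when assigning
    # chromosomes to the case group.
    risk_site: int | None = None
    relative_risk: float = 1.0

    def __post_init__(self) -> None:
        if self.n_reference >= self.n_chromosomes:
            raise ValueError("reference panel must be smaller than the sample")
        if self.n_reference % 2 != 0 or (self.n_chromosomes - self.n_reference) % 2 != 0:
            raise ValueError("panel and study chromosome counts must be even")
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must lie in [0, 0.5)")
        if self.length_bp < 0 or self.Ne <= 0:
            raise ValueError("invalid region length or population size")
        if self.relative_risk <= 0:
            raise ValueError("relative risk must be positive")

    @classmethod
    def full_scale(cls, seed: int = 1) -> "SimulationParams":
        """The full-scale configuration: 25 Mb, 2,200 chromosomes, 200 panel."""
        return cls(length_bp=25_000_000, n_chromosomes=2_200, n_reference=200, seed=seed)


def scaled_rates(params: SimulationParams) -> tuple[float, float]:
    """Region-wide rates scaled in units of 4*Ne generations: (theta, rho)."""
    theta = 4 * params.Ne * params.mu * params.length_bp
    rho = 4 * params.Ne * params.rec * params.length_bp
    return theta, rho


def simulate_haplotypes(params: SimulationParams) -> HaplotypePanel:
    """Coalescent haplotypes over biallelic SNPs; deterministic under seed.

    Mutations follow an infinite-sites binary model on a continuous genome
    (so each segregating site carries exactly one mutation and a rec = 0 run
    is globally four-gamete compatible); float positions are floored to
    1-based integer bp, dropping the rare collisions.
    """
    # Samples are haploid chromosomes, so the population is specified as the
    # 2*Ne chromosome copies of a diploid population of size Ne; this keeps
    # expected diversity at the diploid-convention theta = 4*Ne*mu per bp.
    ts = msprime.sim_ancestry(
        samples=params.n_chromosomes,
        ploidy=1,
        population_size=2 * params.Ne,
        sequence_length=params.length_bp,
        recombination_rate=params.rec,
        random_seed=params.seed + 1,
    )
    mts = msprime.sim_mutations(
        ts,
        rate=params.mu,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=params.seed + 2,
    )
    matrix = mts.genotype_matrix()  # sites x chromosomes
    positions = np.floor([s.position for s in mts.sites()]).astype(np.int64) + 1

    keep: list[int] = []
    last_pos = -1
    collisions = 0
    for j, pos in enumerate(positions):
        if matrix[j].max() > 1:  # defensive; binary model keeps two states
            continue
        if pos <= last_pos:
            collisions += 1
            continue
        keep.append(j)
        last_pos = pos
    if collisions:
        logger.info("simulate_haplotypes: dropped %d position collisions", collisions)

    variants = [
        VariantRecord(chrom="1", pos=int(positions[j]), id=f"snp{k}", ref_allele="A",
                      alt_allele="C")
        for k, j in enumerate(keep)
    ]
    alleles = matrix[keep].T.astype(np.uint8)
    sample_ids = [f"chr_pair{i}" for i in range(params.n_chromosomes // 2)]
    return HaplotypePanel(variants=variants, alleles=alleles, sample_ids=sample_ids)


def assemble_case_control(
    haps: HaplotypePanel, params: SimulationParams
) -> tuple[HaplotypePanel, GenotypeMatrix, HaplotypePanel]:
    """Partition simulated chromosomes into (reference, study, truth).

    After a seeded shuffle the first ``n_reference`` chromosomes form the
    phase-known panel; the rest are split into equal case and control pools
    and paired without replacement into diploid individuals. The truth panel
    retains the pairing (phenotype-labelled) for accuracy scoring; study
    genotypes are the site-wise sums of each pair.
    """
    rng = np.random.default_rng(params.seed + 3)
    n_rows = haps.n_haplotypes
    if n_rows != params.n_chromosomes:
        raise ValueError("haplotype count does not match params")
    perm = rng.permutation(n_rows)
    ref_rows = perm[: params.n_reference]
    study_rows = perm[params.n_reference:]
    if params.risk_site is not None:
        study_rows = _risk_sorted(haps, study_rows, params, rng)
    half = len(study_rows) // 2
    case_rows, ctrl_rows = study_rows[:half], study_rows[half:]
    if len(case_rows) % 2 or len(ctrl_rows) % 2:
        raise ValueError("case/control pools must pair into diploid individuals")

    reference = HaplotypePanel(
        variants=list(haps.variants),
        alleles=haps.alleles[ref_rows],
        sample_ids=[f"ref{i:04d}" for i in range(len(ref_rows) // 2)],
    )
    order = np.concatenate([case_rows, ctrl_rows])
    truth_alleles = haps.alleles[order]
    n_case_ind = len(case_rows) // 2
    n_ctrl_ind = len(ctrl_rows) // 2
    sample_ids = [f"case{i:04d}" for i in range(n_case_ind)] + [
        f"ctrl{i:04d}" for i in range(n_ctrl_ind)
    ]
    phenotype = np.array([CASE] * n_case_ind + [CONTROL] * n_ctrl_ind, dtype=np.int8)
    truth = HaplotypePanel(
        variants=list(haps.variants),
        alleles=truth_alleles,
        sample_ids=sample_ids,
        phenotype=phenotype,
    )
    study = truth.to_genotypes()
    return reference, study, truth


def _risk_sorted(
    haps: HaplotypePanel, study_rows: np.ndarray, params: SimulationParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Weighted case-pool assignment under a multiplicative allele risk."""
    carriers = haps.alleles[study_rows, params.risk_site].astype(float)
    weights = params.relative_risk**carriers
    probs = weights / weights.sum()
    half = len(study_rows) // 2
    case_idx = rng.choice(len(study_rows), size=half, replace=False, p=probs)
    mask = np.zeros(len(study_rows), dtype=bool)
    mask[case_idx] = True
    return np.concatenate([study_rows[mask], study_rows[~mask]])


def maf_filter(study, maf_min: float, *aligned):
    """Drop sites below the MAF floor; frequency from the study chromosomes.

    ``study`` may be a GenotypeMatrix (alt counts over 2N chromosomes) or a
    HaplotypePanel. Any companion structures in ``aligned`` are filtered with
    the same site mask. Sites at exactly the floor are retained. Returns the
    filtered study alone, or a tuple (study, *aligned).
    """
    if isinstance(study, GenotypeMatrix):
        g = study.genotypes
        nonmiss = g != MISSING
        alt = np.where(nonmiss, g, 0).sum(axis=0)
        total = 2 * nonmiss.sum(axis=0)
    elif isinstance(study, HaplotypePanel):
        alt = study.alleles.sum(axis=0).astype(np.int64)
        total = np.full(study.n_sites, study.n_haplotypes, dtype=np.int64)
    else:
        raise TypeError("study must be a GenotypeMatrix or HaplotypePanel")
    minor = np.minimum(alt, total - alt)
    # integer-count comparison with a float-safe slack at the boundary
    keep = np.flatnonzero(minor >= maf_min * total - 1e-9)
    dropped = study.n_sites - len(keep)
    if dropped:
        logger.info("maf_filter: removed %d sites below MAF %.3g", dropped, maf_min)
    out = [study.take_sites(keep)] + [obj.take_sites(keep) for obj in aligned]
    return out[0] if not aligned else tuple(out)


@dataclass
class SimulatedDataset:
    reference: HaplotypePanel
    study: GenotypeMatrix
    truth: HaplotypePanel
    params: SimulationParams


def simulate_dataset(params: SimulationParams) -> SimulatedDataset:
    """Full generation pipeline: simulate, partition, MAF-filter."""
    haps = simulate_haplotypes(params)
    reference, study, truth = assemble_case_control(haps, params)
    study, reference, truth = maf_filter(study, params.maf_min, reference, truth)
    return SimulatedDataset(reference=reference, study=study, truth=truth, params=params)
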