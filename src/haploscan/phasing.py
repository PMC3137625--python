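"""Rule-based phasing of study genotypes at selected SNP clusters.

Each individual's genotype over a cluster's member sites is decomposed into a
haplotype pair by a three-tier rule against the reference panel's observed
haplotypes:

1. PHASE_KNOWN  — some decomposition consists of two observed haplotypes
                  (a "permitted" genotype); under four-gamete compatibility
                  this decomposition is unique.
2. PREDICTABLE  — some decomposition pairs one observed haplotype with its
                  (unobserved) complement; among multiple such solutions the
                  observed haplotype with the highest panel frequency wins.
3. UNKNOWN      — no decomposition contains an observed haplotype; the two
                  haplotypes join the pooled "unknown" category downstream.

Genotypes with a missing member site are categorised MISSING and excluded.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .containers import MISSING, GenotypeMatrix, HaplotypePanel
from .cluster_selection import ObservedHaplotypeSet, SNPCluster, observed_haplotype_set

logger = logging.getLogger(__name__)


class Category(str, Enum):
    PHASE_KNOWN = "PHASE_KNOWN"
    PREDICTABLE = "PREDICTABLE"
    UNKNOWN = "UNKNOWN"
    MISSING = "MISSING"


@dataclass(frozen=True)
class PhaseCall:
    """The phasing outcome for one (individual, cluster) pair."""

    individual: str
    cluster: SNPCluster
    category: Category
    hap_pair: tuple[str, str] | None  # absent for UNKNOWN / MISSING
    observed_flags: tuple[bool, bool] | None

    def __post_init__(self) -> None:
        if self.category in (Category.UNKNOWN, Category.MISSING):
            if self.hap_pair is not None:
                raise ValueError(f"{self.category} call cannot carry a haplotype pair")
        elif self.hap_pair is None:
            raise ValueError(f"{self.category} call requires a haplotype pair")


def enumerate_decompositions(genotype: Sequence[int]) -> list[tuple[str, str]]:
    """All unordered haplotype pairs consistent with an alt-count genotype.

    With h >= 1 heterozygous sites there are 2**(h-1) pairs; a genotype with
    no heterozygote has exactly one. Missing sites are an error here; callers
    pre-screen them.
    """
    g = [int(x) for x in genotype]
    if any(x not in (0, 1, 2) for x in g):
        raise ValueError("genotype contains a missing or invalid site")
    het = [i for i, x in enumerate(g) if x == 1]
    base = ["0" if x == 0 else "1" if x == 2 else "?" for x in g]
    pairs: set[tuple[str, str]] = set()
    for bits in itertools.product("01", repeat=len(het)):
        h1 = list(base)
        h2 = list(base)
        for pos, b in zip(het, bits):
            h1[pos] = b
            h2[pos] = "1" if b == "0" else "0"
        s1, s2 = "".join(h1), "".join(h2)
        pairs.add((s1, s2) if s1 <= s2 else (s2, s1))
    return sorted(pairs)


def phase_genotype(genotype: Sequence[int], obs: ObservedHaplotypeSet,
                   individual: str = "") -> PhaseCall:
    """Apply the three-tier phasing rule to one genotype."""
    decomps = enumerate_decompositions(genotype)
    freq = obs.freq_of

    fully_observed = [(a, b) for a, b in decomps if a in freq and b in freq]
    if fully_observed:
        if len(fully_observed) > 1:
            # Cannot occur when the cluster passes the four-gamete test; only a
            # non-compatible user-supplied cluster reaches this branch.
            logger.warning(
                "multiple fully observed decompositions for genotype %s; "
                "choosing the maximum-frequency pair", list(genotype)
            )
            fully_observed.sort(key=lambda p: (-(freq[p[0]] * freq[p[1]]), p))
        a, b = fully_observed[0]
        return PhaseCall(individual, obs.cluster, Category.PHASE_KNOWN, (a, b), (True, True))

    partial: list[tuple[float, str, str]] = []
    for a, b in decomps:
        in_a, in_b = a in freq, b in freq
        if in_a != in_b:
            observed, complement = (a, b) if in_a else (b, a)
            partial.append((freq[observed], observed, complement))
    if partial:
        # highest panel frequency wins; ties break on the smallest hap string
        partial.sort(key=lambda t: (-t[0], t[1]))
        _, observed, complement = partial[0]
        return PhaseCall(
            individual, obs.cluster, Category.PREDICTABLE,
            (observed, complement), (True, False),
        )

    return PhaseCall(individual, obs.cluster, Category.UNKNOWN, None, None)


def phase_cohort(
    geno: GenotypeMatrix,
    clusters: Sequence[SNPCluster],
    panel: HaplotypePanel,
) -> tuple[list[list[PhaseCall]], dict[str, int]]:
    """Phase every individual at every cluster.

    Returns cluster-major calls (``calls[c][i]`` is individual ``i`` at
    cluster ``c``) plus overall category tallies. Genotypes with any missing
    member site are categorised MISSING.
    """
    tallies = {c.value: 0 for c in Category}
    all_calls: list[list[PhaseCall]] = []
    for cluster in clusters:
        obs = observed_haplotype_set(panel, cluster)
        members = list(cluster.member_indices)
        sub = geno.genotypes[:, members]
        cache: dict[tuple[int, ...], PhaseCall] = {}
        cluster_calls: list[PhaseCall] = []
        for i, sid in enumerate(geno.sample_ids):
            g = tuple(int(x) for x in sub[i])
            if MISSING in g:
                call = PhaseCall(sid, cluster, Category.MISSING, None, None)
            else:
                proto = cache.get(g)
                if proto is None:
                    proto = phase_genotype(g, obs, individual=sid)
                    cache[g] = proto
                call = PhaseCall(sid, cluster, proto.category, proto.hap_pair,
                                 proto.observed_flags)
            tallies[call.category.value] += 1
            cluster_calls.append(call)
        all_calls.append(cluster_calls)
    n_missing = tallies[Category.MISSING.value]
    if n_missing:
        logger.info("phase_cohort: %d (individual, cluster) genotypes had missing "
                    "member sites and were excluded", n_missing)
    return all_calls, tallies
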