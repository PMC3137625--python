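"""Perfect-phylogeny SNP cluster selection by entropy maximization.

For each anchor SNP the selector enumerates, exhaustively, every subset of
nearby panel SNPs (within a window centered on the anchor) that contains the
anchor, respects the configured size range, and passes the four-gamete test
in the reference panel — i.e. whose reference haplotypes are consistent with
a single mutation tree, so the cluster's haplotypes can be resolved without
invoking recombination. Among qualifying subsets the one with maximum
haplotype (Shannon) entropy in the panel is selected; a classic consequence
of the perfect-phylogeny condition is that a k-SNP cluster carries at most
k + 1 distinct haplotypes.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np

from .containers import HaplotypePanel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterConfig:
    """Cluster-search settings.

    window_bp
        Size of the genomic search region in bp; candidate SNPs must lie
        within ``window_bp / 2`` of the anchor position (closed interval).
    max_cluster_size, min_cluster_size
        Bounds on the number of SNPs per cluster (anchor included).
    entropy_base
        Base of the logarithm in the entropy objective (2 = bits).
    """

    window_bp: int = 20_000
    max_cluster_size: int = 3
    min_cluster_size: int = 2
    entropy_base: float = 2.0

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if not (1 <= self.min_cluster_size <= self.max_cluster_size <= 6):
            raise ValueError("need 1 <= min_cluster_size <= max_cluster_size <= 6")
        if self.entropy_base <= 1:
            raise ValueError("entropy_base must exceed 1")


@dataclass(frozen=True)
class SNPCluster:
    """A selected haplotype marker: anchor SNP plus member SNP columns."""

    anchor_index: int
    member_indices: tuple[int, ...]
    entropy: float

    def __post_init__(self) -> None:
        if self.anchor_index not in self.member_indices:
            raise ValueError("anchor must be a cluster member")
        if tuple(sorted(self.member_indices)) != self.member_indices:
            raise ValueError("member indices must be sorted")

    @property
    def size(self) -> int:
        return len(self.member_indices)


@dataclass
class ObservedHaplotypeSet:
    """Distinct reference haplotypes of a cluster with panel frequencies."""

    cluster: SNPCluster
    haplotypes: list[str]
    counts: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.freq_of = dict(zip(self.haplotypes, self.frequencies.tolist()))

    def __contains__(self, hap: str) -> bool:
        return hap in self.freq_of


def is_polymorphic(panel: HaplotypePanel, site: int) -> bool:
    col = panel.alleles[:, site]
    return bool(col.any() and not col.all())


def four_gamete_compatible(panel: HaplotypePanel, sites) -> bool:
    """True iff no pair of sites shows all four gametes {00,01,10,11}."""
    sites = list(sites)
    if len(sites) < 1:
        raise ValueError("need at least one site")
    sub = panel.alleles[:, sites].astype(bool)
    for a, b in itertools.combinations(range(len(sites)), 2):
        x, y = sub[:, a], sub[:, b]
        if (x & y).any() and (x & ~y).any() and (~x & y).any() and (~x & ~y).any():
            return False
    return True


def haplotype_entropy(freqs, base: float = 2.0) -> float:
    """Shannon entropy -sum f*log_base(f), skipping zero frequencies."""
    f = np.asarray(freqs, dtype=float)
    if (f < 0).any():
        raise ValueError("frequencies must be non-negative")
    f = f[f > 0]
    return float(-(f * (np.log(f) / math.log(base))).sum())


def observed_haplotype_set(panel: HaplotypePanel, cluster: SNPCluster) -> ObservedHaplotypeSet:
    """Distinct panel haplotypes over the cluster's member sites."""
    sub = panel.alleles[:, list(cluster.member_indices)]
    uniq, counts = np.unique(sub, axis=0, return_counts=True)
    haps = ["".join(str(int(a)) for a in row) for row in uniq]
    return ObservedHaplotypeSet(
        cluster=cluster,
        haplotypes=haps,
        counts=counts,
        frequencies=counts / panel.n_haplotypes,
    )


class _PairCompat:
    """Lazy cache of pairwise four-gamete compatibility between panel columns."""

    def __init__(self, panel: HaplotypePanel):
        self._b = panel.alleles.astype(bool)
        self._cache: dict[tuple[int, int], bool] = {}

    def __call__(self, i: int, j: int) -> bool:
        if i > j:
            i, j = j, i
        hit = self._cache.get((i, j))
        if hit is None:
            x, y = self._b[:, i], self._b[:, j]
            hit = not (
                (x & y).any() and (x & ~y).any() and (~x & y).any() and (~x & ~y).any()
            )
            self._cache[(i, j)] = hit
        return hit


def _subset_entropy(panel: HaplotypePanel, members: tuple[int, ...], base: float) -> float:
    sub = panel.alleles[:, list(members)].astype(np.int64)
    codes = sub @ (1 << np.arange(len(members), dtype=np.int64))
    counts = np.bincount(codes)
    counts = np.sort(counts[counts > 0])[::-1]  # deterministic summation order
    return haplotype_entropy(counts / panel.n_haplotypes, base=base)


def select_cluster(
    panel: HaplotypePanel,
    anchor: int,
    cfg: ClusterConfig,
    _compat: _PairCompat | None = None,
) -> SNPCluster | None:
    """Exhaustive max-entropy cluster search for one anchor SNP.

    Returns None when no four-gamete-compatible subset of the required size
    exists in the window. Entropy ties prefer the smaller cluster, then the
    smaller total distance to the anchor, then the lexicographically smallest
    index tuple.
    """
    if not (0 <= anchor < panel.n_sites):
        raise IndexError(f"anchor index {anchor} out of range")
    if not is_polymorphic(panel, anchor):
        raise ValueError(f"anchor site {anchor} is monomorphic in the panel")
    compat = _compat if _compat is not None else _PairCompat(panel)
    apos = panel.variants[anchor].pos
    achrom = panel.variants[anchor].chrom
    half = cfg.window_bp / 2

    candidates = [
        j
        for j in range(panel.n_sites)
        if j != anchor
        and panel.variants[j].chrom == achrom
        and abs(panel.variants[j].pos - apos) <= half
        and is_polymorphic(panel, j)
        and compat(anchor, j)
    ]

    best: tuple[float, tuple, tuple[int, ...]] | None = None
    for size in range(cfg.min_cluster_size, cfg.max_cluster_size + 1):
        for combo in itertools.combinations(candidates, size - 1):
            if not all(compat(a, b) for a, b in itertools.combinations(combo, 2)):
                continue
            members = tuple(sorted((anchor,) + combo))
            ent = _subset_entropy(panel, members, cfg.entropy_base)
            dist = sum(abs(panel.variants[m].pos - apos) for m in members)
            key = (size, dist, members)
            if best is None or ent > best[0] or (ent == best[0] and key < best[1]):
                best = (ent, key, members)
    if best is None:
        return None
    return SNPCluster(anchor_index=anchor, member_indices=best[2], entropy=best[0])


def scan_clusters(
    panel: HaplotypePanel, cfg: ClusterConfig
) -> tuple[list[SNPCluster], list[int]]:
    """One select_cluster call per polymorphic site, in anchor order.

    Returns the cluster list and the list of anchor indices that yielded no
    qualifying cluster (also logged). Clusters may overlap and share members.
    """
    compat = _PairCompat(panel)
    clusters: list[SNPCluster] = []
    skipped: list[int] = []
    for anchor in range(panel.n_sites):
        if not is_polymorphic(panel, anchor):
            continue
        cluster = select_cluster(panel, anchor, cfg, _compat=compat)
        if cluster is None:
            skipped.append(anchor)
        else:
            clusters.append(cluster)
    if skipped:
        logger.info("scan_clusters: %d anchors yielded no cluster", len(skipped))
    return clusters, skipped
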