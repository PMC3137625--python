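import itertools
import math
from collections import Counter

import numpy as np
import pytest

from haploscan.cluster_selection import (
    ClusterConfig,
    SNPCluster,
    four_gamete_compatible,
    haplotype_entropy,
    observed_haplotype_set,
    scan_clusters,
    select_cluster,
)

from conftest import make_panel, random_tree_panel


# -- independent oracles -----------------------------------------------------

def oracle_four_gamete(alleles, sites):
    for a, b in itertools.combinations(sites, 2):
        gametes = {(int(x), int(y)) for x, y in zip(alleles[:, a], alleles[:, b])}
        if len(gametes) == 4:
            return False
    return True


def oracle_entropy(alleles, members):
    counts = Counter(tuple(row) for row in alleles[:, list(members)])
    n = alleles.shape[0]
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def oracle_select(panel, anchor, cfg):
    """Brute-force max-entropy search, replicating the documented tie-break."""
    apos = panel.variants[anchor].pos
    poly = [
        j for j in range(panel.n_sites)
        if panel.alleles[:, j].any() and not panel.alleles[:, j].all()
    ]
    cand = [
        j for j in poly
        if abs(panel.variants[j].pos - apos) <= cfg.window_bp / 2
        and panel.variants[j].chrom == panel.variants[anchor].chrom
    ]
    best = None
    for size in range(cfg.min_cluster_size, cfg.max_cluster_size + 1):
        for members in itertools.combinations(cand, size):
            if anchor not in members:
                continue
            if not oracle_four_gamete(panel.alleles, members):
                continue
            ent = oracle_entropy(panel.alleles, members)
            dist = sum(abs(panel.variants[m].pos - apos) for m in members)
            key = (-ent, size, dist, members)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    return (best[3], -best[0])


# -- four-gamete test --------------------------------------------------------

class TestFourGamete:
    def test_three_gametes_compatible(self, toy_panel):
        assert four_gamete_compatible(toy_panel, [0, 1])

    def test_all_four_gametes_incompatible(self):
        panel = make_panel([[0, 0], [0, 1], [1, 0], [1, 1]])
        assert not four_gamete_compatible(panel, [0, 1])

    def test_single_site_trivially_compatible(self, toy_panel):
        assert four_gamete_compatible(toy_panel, [0])

    def test_empty_site_list_rejected(self, toy_panel):
        with pytest.raises(ValueError):
            four_gamete_compatible(toy_panel, [])

    def test_matches_gamete_enumeration_oracle(self, rng):
        for _ in range(50):
            alleles = rng.integers(0, 2, size=(12, 6))
            panel = make_panel(alleles)
            sites = sorted(rng.choice(6, size=3, replace=False).tolist())
            assert four_gamete_compatible(panel, sites) == oracle_four_gamete(
                panel.alleles, sites
            )


# -- entropy -----------------------------------------------------------------

@pytest.mark.parametrize(
    "freqs, base, expected",
    [
        ([0.25, 0.25, 0.25, 0.25], 2, 2.0),
        ([1.0], 2, 0.0),
        ([0.5, 0.25, 0.25], 2, 1.5),
        ([0.5, 0.5, 0.0], 2, 1.0),  # zero frequencies skipped
    ],
)
def test_entropy_values(freqs, base, expected):
    assert haplotype_entropy(freqs, base) == pytest.approx(expected)


def test_entropy_rejects_negative():
    with pytest.raises(ValueError):
        haplotype_entropy([-0.1, 1.1])


# -- cluster selection -------------------------------------------------------

class TestSelectCluster:
    def test_prefers_independent_snp_over_duplicate(self):
        # site 1 duplicates the anchor (site 0); site 2 is compatible but
        # independent, so {0, 2} carries more haplotype entropy than {0, 1}.
        alleles = np.array(
            [
                [0, 0, 0],
                [0, 0, 0],
                [0, 0, 1],
                [0, 0, 1],
                [1, 1, 1],
                [1, 1, 1],
            ]
        )
        panel = make_panel(alleles, positions=[100, 110, 120])
        cfg = ClusterConfig(window_bp=1000, max_cluster_size=2)
        cluster = select_cluster(panel, 0, cfg)
        assert cluster.member_indices == (0, 2)
        # members {0, 2} show haplotypes 00, 01, 11 in equal thirds
        assert cluster.entropy == pytest.approx(math.log2(3))

    def test_no_compatible_neighbour_gives_none(self):
        # the two sites show all four gametes, so no pair qualifies
        panel = make_panel([[0, 0], [0, 1], [1, 0], [1, 1]])
        cfg = ClusterConfig(window_bp=1000, max_cluster_size=3, min_cluster_size=2)
        assert select_cluster(panel, 0, cfg) is None

    def test_monomorphic_anchor_rejected(self):
        panel = make_panel([[0, 0], [0, 1], [0, 1], [0, 0]])
        with pytest.raises(ValueError, match="monomorphic"):
            select_cluster(panel, 0, ClusterConfig())

    def test_matches_exhaustive_oracle_on_random_panels(self, rng):
        cfg = ClusterConfig(window_bp=60, max_cluster_size=3)
        for _ in range(30):
            alleles = rng.integers(0, 2, size=(16, 10))
            panel = make_panel(alleles)
            for anchor in range(panel.n_sites):
                col = panel.alleles[:, anchor]
                if not (col.any() and not col.all()):
                    continue
                got = select_cluster(panel, anchor, cfg)
                want = oracle_select(panel, anchor, cfg)
                if want is None:
                    assert got is None
                else:
                    assert got.member_indices == want[0]
                    assert got.entropy == pytest.approx(want[1])

    def test_perfect_phylogeny_haplotype_bound(self, rng):
        cfg = ClusterConfig(window_bp=200, max_cluster_size=4)
        for _ in range(20):
            alleles = rng.integers(0, 2, size=(20, 8))
            panel = make_panel(alleles)
            clusters, _ = scan_clusters(panel, cfg)
            for c in clusters:
                obs = observed_haplotype_set(panel, c)
                assert len(obs.haplotypes) <= c.size + 1
                assert obs.counts.sum() == panel.n_haplotypes
                assert obs.frequencies.sum() == pytest.approx(1.0)


class TestScanClusters:
    def test_cluster_count_bounded_by_polymorphic_sites(self, rng):
        panel = make_panel(rng.integers(0, 2, size=(10, 8)))
        clusters, skipped = scan_clusters(panel, ClusterConfig(window_bp=100))
        n_poly = sum(
            1 for j in range(8)
            if panel.alleles[:, j].any() and not panel.alleles[:, j].all()
        )
        assert len(clusters) + len(skipped) == n_poly

    def test_deterministic(self, rng):
        panel = make_panel(rng.integers(0, 2, size=(14, 9)))
        cfg = ClusterConfig(window_bp=100)
        first, _ = scan_clusters(panel, cfg)
        second, _ = scan_clusters(panel, cfg)
        assert first == second

    def test_tree_consistent_panel_clusters_every_anchor(self, rng):
        # globally four-gamete-compatible haplotypes: every polymorphic anchor
        # with a polymorphic neighbour in-window yields a cluster
        alleles = random_tree_panel(rng, 20, 10)
        panel = make_panel(alleles)
        poly = [
            j for j in range(10)
            if panel.alleles[:, j].any() and not panel.alleles[:, j].all()
        ]
        clusters, skipped = scan_clusters(panel, ClusterConfig(window_bp=1000))
        assert not skipped
        assert len(clusters) == len(poly)

    def test_shrinking_window_never_adds_clusters(self, rng):
        panel = make_panel(rng.integers(0, 2, size=(12, 10)))
        wide, _ = scan_clusters(panel, ClusterConfig(window_bp=200))
        narrow, _ = scan_clusters(panel, ClusterConfig(window_bp=60))
        assert {c.anchor_index for c in narrow} <= {c.anchor_index for c in wide}


def test_cluster_invariants_enforced():
    with pytest.raises(ValueError):
        SNPCluster(anchor_index=5, member_indices=(0, 1), entropy=1.0)
    with pytest.raises(ValueError):
        ClusterConfig(min_cluster_size=4, max_cluster_size=2)
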