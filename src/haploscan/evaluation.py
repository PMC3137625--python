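"""Cross-validated phasing accuracy.

Individuals of a phase-known panel are split into k seeded folds; in each
fold the held-out individuals are collapsed to unphased genotypes and phased
against the remaining individuals, with SNP clusters re-selected from that
fold's reference only. Calls are scored against the held-out truth per
haplotype: the called unordered pair is matched to the true pair minimizing
mismatches, UNKNOWN calls contribute two "unknown" haplotypes (not wrong),
and MISSING calls are excluded from the totals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import HaplotypePanel
from .cluster_selection import ClusterConfig, scan_clusters
from .phasing import Category, PhaseCall, phase_cohort

logger = logging.getLogger(__name__)


@dataclass
class CVReport:
    """Per-fold accuracy tallies and the derived percentage metrics."""

    fold_id: int
    total_haplotypes: int
    wrong_haplotypes: int
    unknown_haplotypes: int

    def __post_init__(self) -> None:
        if self.wrong_haplotypes + self.unknown_haplotypes > self.total_haplotypes:
            raise ValueError("wrong + unknown cannot exceed total")

    @property
    def phasing_error_pct(self) -> float:
        return 100.0 * self.wrong_haplotypes / self.total_haplotypes

    @property
    def unknown_pct(self) -> float:
        return 100.0 * self.unknown_haplotypes / self.total_haplotypes

    @property
    def correct_pct(self) -> float:
        # "correct" complements the error rate; unknown calls are reported
        # separately and are not counted as wrong.
        return 100.0 - self.phasing_error_pct

    def summary(self) -> dict[str, float | int]:
        """Display form with percentages rounded to 2 decimals."""
        return {
            "fold_id": self.fold_id,
            "total_haplotypes": self.total_haplotypes,
            "wrong_haplotypes": self.wrong_haplotypes,
            "unknown_haplotypes": self.unknown_haplotypes,
            "phasing_error_pct": round(self.phasing_error_pct, 2),
            "unknown_pct": round(self.unknown_pct, 2),
            "correct_pct": round(self.correct_pct, 2),
        }


def cv_metrics(total: int, wrong: int, unknown: int) -> tuple[float, float, float]:
    """(error%, unknown%, correct%) rounded to 2 decimals from raw counts."""
    report = CVReport(0, total, wrong, unknown)
    return (
        round(report.phasing_error_pct, 2),
        round(report.unknown_pct, 2),
        round(report.correct_pct, 2),
    )


def kfold_split(ids: list[str], k: int, seed: int) -> list[list[str]]:
    """Seeded permutation split into k groups whose sizes differ by <= 1."""
    if k < 2 or k > len(ids):
        raise ValueError("need 2 <= k <= number of individuals")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    groups = np.array_split(perm, k)
    return [[ids[i] for i in g] for g in groups]


def score_fold(
    truth: HaplotypePanel,
    calls: list[list[PhaseCall]],
    fold_id: int = 0,
) -> CVReport:
    """Score phase calls against held-out truth haplotypes.

    ``truth`` individuals must align with the call matrix's individual order.
    """
    total = wrong = unknown = 0
    truth_index = {sid: i for i, sid in enumerate(truth.sample_ids)}
    for cluster_calls in calls:
        cluster = cluster_calls[0].cluster
        members = list(cluster.member_indices)
        for call in cluster_calls:
            if call.category == Category.MISSING:
                continue
            ti = truth_index.get(call.individual)
            if ti is None:
                raise ValueError(f"truth panel does not cover individual {call.individual}")
            total += 2
            if call.category == Category.UNKNOWN:
                unknown += 2
                continue
            h1, h2 = truth.individual_pair(ti)
            t1 = "".join(str(int(x)) for x in h1[members])
            t2 = "".join(str(int(x)) for x in h2[members])
            c1, c2 = call.hap_pair
            wrong += min(
                (c1 != t1) + (c2 != t2),
                (c1 != t2) + (c2 != t1),
            )
    if total == 0:
        raise ValueError("no scorable calls in this fold")
    return CVReport(fold_id, total, wrong, unknown)


def run_crossval(
    panel: HaplotypePanel, k: int, cfg: ClusterConfig, seed: int
) -> list[CVReport]:
    """k-fold CV: per fold, re-select clusters from the fold's reference
    individuals, phase the held-out genotypes and score against truth."""
    if panel.n_individuals < k:
        raise ValueError("panel has fewer individuals than folds")
    folds = kfold_split(list(panel.sample_ids), k, seed)
    index = {sid: i for i, sid in enumerate(panel.sample_ids)}
    reports: list[CVReport] = []
    for fold_id, held_ids in enumerate(folds):
        held = np.array([index[s] for s in held_ids], dtype=np.intp)
        rest = np.array([i for i in range(panel.n_individuals) if i not in set(held)],
                        dtype=np.intp)
        reference = panel.take_individuals(rest)
        truth = panel.take_individuals(held)
        geno = truth.to_genotypes()
        clusters, _ = scan_clusters(reference, cfg)
        if not clusters:
            raise ValueError(f"fold {fold_id}: no clusters could be selected")
        calls, _ = phase_cohort(geno, clusters, reference)
        reports.append(score_fold(truth, calls, fold_id=fold_id))
    return reports
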