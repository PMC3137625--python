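"""Haplotype-based case-control association tests.

For each SNP cluster the phased calls are tallied into an m x 2 contingency
table (haplotype counts by case/control), with every unobserved haplotype —
PREDICTABLE complements and both haplotypes of UNKNOWN calls — pooled into a
single row to limit the degrees of freedom. A Pearson chi-square test (no
continuity correction, df = m - 1) yields the marker p-value. A standard
allelic single-SNP test and the p-value accordance rate used to compare
phasing strategies live here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CASE, CONTROL, MISSING, GenotypeMatrix, HaplotypePanel
from .cluster_selection import SNPCluster, observed_haplotype_set
from .phasing import Category, PhaseCall

logger = logging.getLogger(__name__)

#: Row label for the pooled unobserved-haplotype category.
POOLED = "POOLED_UNOBSERVED"

#: Genome-wide significance threshold used for declaring associations.
DEFAULT_ALPHA = 1e-7


class MarkerSkipped(Exception):
    """Raised when a marker cannot be tested; carries a reason code."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class ContingencyTable:
    """Haplotype counts by group; columns are (case, control)."""

    row_labels: list[str]
    counts: np.ndarray  # shape (m, 2), non-negative ints
    n_case_ind: int
    n_ctrl_ind: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 2:
            raise ValueError("contingency counts must be m x 2")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.row_labels.count(POOLED) > 1:
            raise ValueError("at most one pooled row")

    @property
    def pooled_count(self) -> int:
        if POOLED in self.row_labels:
            return int(self.counts[self.row_labels.index(POOLED)].sum())
        return 0


@dataclass
class AssociationResult:
    anchor_id: str
    chi2: float
    df: int
    p_value: float
    m: int
    table: ContingencyTable | None = None


def build_table(calls: list[PhaseCall], phenotypes: np.ndarray) -> ContingencyTable:
    """Tally one cluster's phase calls into an m x 2 table.

    PHASE_KNOWN calls contribute both observed haplotypes; PREDICTABLE calls
    contribute their observed haplotype plus one pooled count for the
    unobserved complement; UNKNOWN calls contribute two pooled counts;
    MISSING calls contribute nothing.
    """
    if len(calls) != len(phenotypes):
        raise ValueError("one phenotype per call required")
    rows: dict[str, np.ndarray] = {}
    pooled = np.zeros(2, dtype=np.int64)
    n_case = n_ctrl = 0

    def add(label: str, col: int, k: int = 1) -> None:
        if label == POOLED:
            pooled[col] += k
        else:
            rows.setdefault(label, np.zeros(2, dtype=np.int64))[col] += k

    for call, phen in zip(calls, phenotypes):
        if call.category == Category.MISSING:
            continue
        col = 0 if phen == CASE else 1
        if phen == CASE:
            n_case += 1
        else:
            n_ctrl += 1
        if call.category == Category.PHASE_KNOWN:
            add(call.hap_pair[0], col)
            add(call.hap_pair[1], col)
        elif call.category == Category.PREDICTABLE:
            add(call.hap_pair[0], col)
            add(POOLED, col)
        else:  # UNKNOWN
            add(POOLED, col, 2)

    if n_case + n_ctrl == 0:
        raise MarkerSkipped("no non-missing calls")
    labels = sorted(rows)
    counts = [rows[h] for h in labels]
    if pooled.sum() > 0:
        labels.append(POOLED)
        counts.append(pooled)
    return ContingencyTable(
        row_labels=labels,
        counts=np.vstack(counts),
        n_case_ind=n_case,
        n_ctrl_ind=n_ctrl,
    )


def pearson_chi2(table: ContingencyTable, anchor_id: str = "") -> AssociationResult:
    """Pearson chi-square on an m x 2 table, df = m - 1, upper-tail p.

    Rows with zero total are removed first; a marker with fewer than two
    populated rows or an empty case or control column is skipped. No
    continuity correction and no minimum-expected-count rule are applied
    (a warning is logged when any expected count is below 5).
    """
    counts = table.counts
    keep = counts.sum(axis=1) > 0
    counts = counts[keep]
    m = counts.shape[0]
    if m < 2:
        raise MarkerSkipped("fewer than 2 haplotype rows with positive totals")
    if (counts.sum(axis=0) == 0).any():
        raise MarkerSkipped("empty case or control column")
    chi2, p, dof, expected = stats.chi2_contingency(counts, correction=False)
    if (expected < 5).any():
        logger.debug("marker %s: expected count below 5", anchor_id)
    assert dof == m - 1
    return AssociationResult(
        anchor_id=anchor_id, chi2=float(chi2), df=int(dof), p_value=float(p),
        m=m, table=table,
    )


def single_snp_test(geno: GenotypeMatrix, site: int) -> AssociationResult:
    """Allelic 2 x 2 chi-square on alt/ref allele counts by group."""
    if geno.phenotype is None:
        raise ValueError("phenotype labels required")
    g = geno.genotypes[:, site]
    ok = g != MISSING
    counts = np.zeros((2, 2), dtype=np.int64)  # rows alt/ref, cols case/control
    for col, code in ((0, CASE), (1, CONTROL)):
        sel = ok & (geno.phenotype == code)
        alt = int(g[sel].sum())
        counts[0, col] = alt
        counts[1, col] = 2 * int(sel.sum()) - alt
    if counts[0].sum() == 0 or counts[1].sum() == 0:
        raise MarkerSkipped("site monomorphic among phenotyped individuals")
    table = ContingencyTable(
        row_labels=["alt", "ref"],
        counts=counts,
        n_case_ind=int(((geno.phenotype == CASE) & ok).sum()),
        n_ctrl_ind=int(((geno.phenotype == CONTROL) & ok).sum()),
    )
    return pearson_chi2(table, anchor_id=geno.variants[site].id)


def accordance_rate(p_a, p_b, tol: float = 0.0) -> float:
    """Fraction of aligned marker pairs whose p-values agree.

    Agreement means |p_a - p_b| <= tol * max(p_a, p_b); tol = 0 reproduces
    strict equality.
    """
    a = np.asarray(p_a, dtype=float)
    b = np.asarray(p_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("p-value lists must be 1-D and of equal length")
    if a.size == 0:
        raise ValueError("empty p-value lists")
    return float((np.abs(a - b) <= tol * np.maximum(a, b)).mean())


def haplotype_scan(
    calls: list[list[PhaseCall]],
    phenotypes: np.ndarray,
    panel: HaplotypePanel,
) -> tuple[list[AssociationResult], list[tuple[str, str]]]:
    """Chi-square test per cluster from phased calls; returns (results, skips)."""
    results: list[AssociationResult] = []
    skipped: list[tuple[str, str]] = []
    for cluster_calls in calls:
        cluster = cluster_calls[0].cluster
        anchor_id = panel.variants[cluster.anchor_index].id
        try:
            table = build_table(cluster_calls, phenotypes)
            results.append(pearson_chi2(table, anchor_id=anchor_id))
        except MarkerSkipped as exc:
            skipped.append((anchor_id, exc.reason))
    if skipped:
        logger.info("haplotype_scan: skipped %d markers", len(skipped))
    return results, skipped


def truth_haplotype_scan(
    truth: HaplotypePanel,
    clusters: list[SNPCluster],
    panel: HaplotypePanel,
) -> tuple[list[AssociationResult], list[tuple[str, str]]]:
    """The raw-haplotype arm: tables built directly from true haplotypes.

    Haplotypes absent from the reference panel's observed set are pooled the
    same way the phased arm pools them, so the two arms are comparable
    marker-by-marker.
    """
    if truth.phenotype is None:
        raise ValueError("truth panel requires phenotype labels")
    results: list[AssociationResult] = []
    skipped: list[tuple[str, str]] = []
    for cluster in clusters:
        obs = observed_haplotype_set(panel, cluster)
        anchor_id = panel.variants[cluster.anchor_index].id
        members = list(cluster.member_indices)
        sub = truth.alleles[:, members]
        rows: dict[str, np.ndarray] = {}
        pooled = np.zeros(2, dtype=np.int64)
        for r in range(truth.n_haplotypes):
            hap = "".join(str(int(x)) for x in sub[r])
            col = 0 if truth.phenotype[r // 2] == CASE else 1
            if hap in obs:
                rows.setdefault(hap, np.zeros(2, dtype=np.int64))[col] += 1
            else:
                pooled[col] += 1
        labels = sorted(rows)
        counts = [rows[h] for h in labels]
        if pooled.sum() > 0:
            labels.append(POOLED)
            counts.append(pooled)
        n_case = int((truth.phenotype == CASE).sum())
        n_ctrl = int((truth.phenotype == CONTROL).sum())
        table = ContingencyTable(labels, np.vstack(counts), n_case, n_ctrl)
        try:
            results.append(pearson_chi2(table, anchor_id=anchor_id))
        except MarkerSkipped as exc:
            skipped.append((anchor_id, exc.reason))
    return results, skipped


def results_frame(
    results: list[AssociationResult],
    clusters: list[SNPCluster],
    panel: HaplotypePanel,
) -> pd.DataFrame:
    """Results as a tidy frame sorted by (chrom, pos), ready for TSV export."""
    by_anchor = {panel.variants[c.anchor_index].id: c for c in clusters}
    records = []
    for res in results:
        cluster = by_anchor[res.anchor_id]
        anchor = panel.variants[cluster.anchor_index]
        records.append(
            {
                "anchor_id": res.anchor_id,
                "chrom": anchor.chrom,
                "pos": anchor.pos,
                "member_ids": ",".join(
                    panel.variants[m].id for m in cluster.member_indices
                ),
                "m": res.m,
                "chi2": res.chi2,
                "df": res.df,
                "p_value": res.p_value,
                "n_case_ind": res.table.n_case_ind if res.table else np.nan,
                "n_ctrl_ind": res.table.n_ctrl_ind if res.table else np.nan,
                "pooled_count": res.table.pooled_count if res.table else 0,
            }
        )
    frame = pd.DataFrame.from_records(records)
    if not frame.empty:
        frame = frame.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return frame
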