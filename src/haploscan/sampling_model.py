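"""Order-statistic model of reference-panel coverage.

With a panel of n chromosomes, the total frequency p of haplotypes absent
from the panel ("unobserved" haplotypes) is bounded by the minimum of n
independent uniforms: a two-step sampling scheme draws n uniforms and labels
a chromosome "unobserved" exactly when its draw falls at or below p, so no
unobserved haplotype enters the panel precisely when min exceeds p. The
minimum of n uniforms has CDF 1 - (1-x)^n and expectation 1/(n+1), which
serves as the coverage bound. Under Hardy-Weinberg equilibrium, with
e = E(min), the three genotype categories occur in proportions
(1-e)^2 (phase-known), 2e(1-e) (predictable) and e^2 (unknown).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def cdf_min_uniform(x: float, n: int) -> float:
    """CDF of the minimum of n independent U(0,1) draws: 1 - (1-x)^n."""
    if not 0 <= x <= 1:
        raise ValueError("x must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be a positive integer")
    return 1.0 - (1.0 - x) ** n


def expected_min_uniform(n: int) -> float:
    """E[min of n uniforms] = 1/(n+1)."""
    if n < 1:
        raise ValueError("n must be a positive integer")
    return 1.0 / (n + 1)


def category_proportions(n: int) -> tuple[float, float, float]:
    """(phase_known, predictable, unknown) genotype shares for an n-chromosome panel."""
    e = expected_min_uniform(n)
    return ((1 - e) ** 2, 2 * e * (1 - e), e**2)


def two_step_sample(p: float, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Label n sampled chromosomes observed/unobserved at true frequency p.

    A chromosome is "unobserved" iff its uniform draw is <= p. Returns a
    boolean array, True = unobserved.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.uniform(size=n) <= p


@dataclass(frozen=True)
class SamplingModel:
    """Panel-size summary: coverage bound and genotype-category shares."""

    n: int  # panel chromosome count
    p: float = 0.0  # true unobserved-haplotype frequency, for simulation checks

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("panel must contain at least one chromosome")
        if not 0 <= self.p <= 1:
            raise ValueError("p must lie in [0, 1]")

    @property
    def e_min(self) -> float:
        return expected_min_uniform(self.n)

    @property
    def proportions(self) -> tuple[float, float, float]:
        return category_proportions(self.n)


def model_grid(individuals: list[int]) -> pd.DataFrame:
    """Category-share table over a grid of panel sizes (in individuals).

    Each diploid individual contributes two chromosomes.
    """
    records = []
    for ind in individuals:
        n = 2 * ind
        e = expected_min_uniform(n)
        pk, pred, unk = category_proportions(n)
        records.append(
            {
                "individuals": ind,
                "chromosomes": n,
                "e_min": e,
                "phase_known": pk,
                "predictable": pred,
                "unknown": unk,
            }
        )
    return pd.DataFrame.from_records(records)
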