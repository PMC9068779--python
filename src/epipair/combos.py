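"""Genotype-combination prevalence analysis for an interacting SNP pair.

For a significant pair, samples are cross-tabulated over the nine joint
genotype cells separately in the high- and low-BMI groups.  Each cell's
prevalence (count over group total) is compared between groups with a
pooled two-sample z-test for proportions, and carrier enrichment toward the
low-BMI group can be checked with a one-sided binomial test against the
cohort-wide low-BMI proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genio import MISSING

DIRECTIONS = ("enriched_high", "enriched_low", "none")


@dataclass
class CombinationTable:
    """3x3x2 genotype-combination counts plus per-cell z-test annotations."""

    counts: np.ndarray  # (3, 3, 2): [gA, gB, {0: high, 1: low}]
    n_high: int
    n_low: int
    z: np.ndarray | None = None  # (3, 3)
    p: np.ndarray | None = None  # (3, 3)
    direction: np.ndarray | None = None  # (3, 3) of DIRECTIONS strings

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def combination_counts(
    gA: np.ndarray, gB: np.ndarray, bmi_class: np.ndarray
) -> CombinationTable:
    """Exact 3x3x2 cross-tabulation of joint genotypes by BMI class.

    Samples with a missing call at either locus are excluded; counts always
    sum to the number of included samples.
    """
    gA = np.asarray(gA)
    gB = np.asarray(gB)
    cls = np.asarray(bmi_class)
    high = (cls == 1) | (cls == True) | (cls == "high")  # noqa: E712
    ok = (gA != MISSING) & (gB != MISSING)
    counts = np.zeros((3, 3, 2), dtype=np.int64)
    np.add.at(counts, (gA[ok], gB[ok], (~high[ok]).astype(int)), 1)
    n_high = int(high[ok].sum())
    n_low = int(ok.sum() - n_high)
    return CombinationTable(counts=counts, n_high=n_high, n_low=n_low)


def proportion_z_test(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled-variance two-sample z-test for proportions x1/n1 vs x2/n2.

    Returns (z, two-sided normal p).  A degenerate pooled proportion of 0 or
    1 (no variation to test) yields z = 0, p = 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled <= 0.0 or pooled >= 1.0:
        return 0.0, 1.0
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(z), min(1.0, p)


def combination_enrichment(table: CombinationTable, alpha: float = 0.05,
                           bh: bool = False) -> CombinationTable:
    """Annotate each cell with its high-vs-low prevalence z-test.

    Per cell, count/n_high is compared with count/n_low; a direction is
    assigned when p < alpha (``enriched_high`` when the high-BMI prevalence
    is larger).  The nine cells are tested at raw alpha by default; ``bh``
    applies a Benjamini-Hochberg correction across the nine cells instead.
    """
    if table.n_high <= 0 or table.n_low <= 0:
        raise ValueError("both BMI groups must be non-empty")
    z = np.zeros((3, 3))
    p = np.ones((3, 3))
    for a in range(3):
        for b in range(3):
            z[a, b], p[a, b] = proportion_z_test(
                int(table.counts[a, b, 0]), table.n_high,
                int(table.counts[a, b, 1]), table.n_low,
            )
    p_eff = p.copy()
    if bh:
        from statsmodels.stats.multitest import multipletests

        p_eff = multipletests(p.ravel(), method="fdr_bh")[1].reshape(3, 3)
    direction = np.full((3, 3), "none", dtype=object)
    sig = p_eff < alpha
    direction[sig & (z > 0)] = "enriched_high"
    direction[sig & (z < 0)] = "enriched_low"
    table.z, table.p, table.direction = z, p, direction
    return table


def carrier_binomial_test(k_low: int, n_carriers: int, p0: float) -> float:
    """One-sided binomial tail P(X >= k_low) for X ~ Bin(n_carriers, p0).

    ``p0`` is the baseline proportion of low-BMI individuals in the cohort;
    a small p means carriers of the genotype combination fall in the low-BMI
    group more often than the cohort baseline predicts.
    """
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must be in (0,1)")
    if not (0 <= k_low <= n_carriers):
        raise ValueError("need 0 <= k_low <= n_carriers")
    if k_low == 0:
        return 1.0
    return float(stats.binom.sf(k_low - 1, n_carriers, p0))
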