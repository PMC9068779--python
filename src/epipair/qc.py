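"""Variant-level quality control and locus selection.

Filters mirror the usual pre-epistasis pipeline for hard-call panels:
biallelic variants only, genotyping call rate, Hardy-Weinberg equilibrium
exact test, imputation quality (INFO r2) when available, a stratum
allele-frequency bias screen (Fisher exact + Benjamini-Hochberg), and
distance-based pruning of an association-ranked locus list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genio import MISSING, GenotypeMatrix, VariantRecord


@dataclass
class QcConfig:
    """Thresholds for variant-level QC.

    ``min_call_rate=1.0`` reproduces discovery-style strictness (no missing
    genotypes at all); the default 0.99 is the replication-style gate.
    """

    hwe_p_min: float = 1e-6
    min_call_rate: float = 0.99
    min_info_r2: float = 0.7
    require_biallelic: bool = True
    stratum_bias_alpha: float = 0.01
    prune_window_bp: int = 500_000
    assoc_p_max: float = 1e-4

    def __post_init__(self) -> None:
        for name in ("hwe_p_min", "min_call_rate", "min_info_r2",
                     "stratum_bias_alpha", "assoc_p_max"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0,1], got {v}")
        if self.prune_window_bp <= 0:
            raise ValueError("prune_window_bp must be positive")


@dataclass
class QcReport:
    """Per-variant QC metrics plus retained counts after each filter stage."""

    table: pd.DataFrame
    counts: dict[str, int] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg equilibrium test.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed table (the standard, non-mid-p definition).
    Returns a p-value in (0, 1]; monomorphic variants give p = 1.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts) or any(c != int(c) for c in counts):
        raise ValueError("genotype counts must be non-negative integers")
    n_hom_ref, n_het, n_hom_alt = (int(c) for c in counts)
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("total genotype count must be positive")

    # rare-allele count; the conditional distribution of the het count given
    # (n, n_rare) is symmetric in allele labels.
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_rare == 0:
        return 1.0

    # Support: het counts of the same parity as n_rare, from 0/1 up to n_rare.
    # Unnormalized probabilities come from the recurrence
    #   P(h+2)/P(h) = 4 hom_r hom_c / ((h+1)(h+2)),
    # where hom_r = (n_rare - h)/2 and hom_c = n - h - hom_r, started at the
    # distribution mode so values only decay outward (no overflow).
    hets = list(range(n_rare % 2, n_rare + 1, 2))
    index = {h: k for k, h in enumerate(hets)}
    mode = int(round(n_rare * (2 * n - n_rare) / (2.0 * n)))
    if mode % 2 != n_rare % 2:
        mode += 1 if mode < n_rare else -1
    probs = np.zeros(len(hets))
    probs[index[mode]] = 1.0
    for h in range(mode, hets[-1] - 1, 2):  # upward from mode
        if h + 2 > n_rare:
            break
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        probs[index[h + 2]] = probs[index[h]] * 4.0 * hom_r * hom_c / (
            (h + 1.0) * (h + 2.0)
        )
    for h in range(mode, hets[0] + 1, -2):  # downward from mode
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        probs[index[h - 2]] = probs[index[h]] * h * (h - 1.0) / (
            4.0 * (hom_r + 1.0) * (hom_c + 1.0)
        )
    probs /= probs.sum()
    p_obs = probs[index[n_het]]
    # sum all outcomes no more probable than the observed one; a tiny relative
    # tolerance absorbs float ties in the recurrence
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(1.0, p))


def filter_variants(gm: GenotypeMatrix, cfg: QcConfig | None = None) -> tuple[GenotypeMatrix, QcReport]:
    """Apply biallelic / call-rate / HWE / INFO-r2 filters.

    Filters are evaluated in sequence per variant; the report records every
    metric and the first failing filter as the reason code.  Idempotent:
    re-filtering the output changes nothing.
    """
    if gm.n_variants == 0:
        raise ValueError("empty genotype matrix")
    cfg = cfg or QcConfig()

    call_rate = gm.call_rate()
    maf = gm.maf()
    rows = []
    keep = []
    for j, v in enumerate(gm.variants):
        a, b, c = gm.genotype_counts(v.rsid)
        hwe_p = hwe_exact_test(a, b, c) if (a + b + c) > 0 else np.nan
        reason = ""
        biallelic = len(v.ref_allele) >= 1 and len(v.alt_allele) >= 1
        if cfg.require_biallelic and not biallelic:
            reason = "biallelic"
        elif call_rate[j] < cfg.min_call_rate:
            reason = "call_rate"
        elif not (hwe_p > cfg.hwe_p_min):
            reason = "hwe"
        elif v.info_r2 is not None and v.info_r2 < cfg.min_info_r2:
            reason = "info_r2"
        rows.append(
            {
                "rsid": v.rsid,
                "chrom": v.chrom,
                "pos": v.pos,
                "call_rate": call_rate[j],
                "maf": maf[j],
                "hwe_p": hwe_p,
                "info_r2": np.nan if v.info_r2 is None else v.info_r2,
                "pass": reason == "",
                "reason": reason,
            }
        )
        if reason == "":
            keep.append(v.rsid)

    table = pd.DataFrame(rows)
    counts = {"input": gm.n_variants}
    remaining = table.copy()
    for stage in ("biallelic", "call_rate", "hwe", "info_r2"):
        remaining = remaining[remaining["reason"] != stage]
        counts[f"after_{stage}"] = len(remaining)
    return gm.subset_variants(keep), QcReport(table, counts)


def prune_by_distance(
    variants: Sequence[tuple[VariantRecord, float]],
    window_bp: int = 500_000,
) -> list[tuple[VariantRecord, float]]:
    """Greedy distance pruning of an association-ranked variant list.

    Variants are visited in ascending association p-value; one is retained
    iff no already-retained variant on the same chromosome lies within
    ``window_bp`` (inclusive).  The retained list is returned in the original
    input order.  Duplicate (chrom, pos) entries keep the smaller p-value.
    """
    seen: dict[tuple[str, int], int] = {}
    items: list[tuple[VariantRecord, float, int]] = []
    for order, (v, p) in enumerate(variants):
        if not (0.0 < p <= 1.0):
            raise ValueError(f"{v.rsid}: assoc_p must be in (0,1]")
        key = (v.chrom, v.pos)
        if key in seen:
            warnings.warn(f"duplicate position {key} ({v.rsid}); keeping smaller p")
            k = seen[key]
            if p < items[k][1]:
                items[k] = (v, p, items[k][2])
            continue
        seen[key] = len(items)
        items.append((v, p, order))

    retained_idx: list[int] = []
    by_chrom: dict[str, list[int]] = {}
    for k in sorted(range(len(items)), key=lambda k: (items[k][1], items[k][0].sort_key)):
        v = items[k][0]
        positions = by_chrom.get(v.chrom, [])
        if any(abs(v.pos - q) <= window_bp for q in positions):
            continue
        retained_idx.append(k)
        by_chrom.setdefault(v.chrom, []).append(v.pos)
    retained_idx.sort(key=lambda k: items[k][2])
    return [(items[k][0], items[k][1]) for k in retained_idx]


def stratum_af_bias_test(
    gm: GenotypeMatrix,
    strata: Sequence,
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, list[str]]:
    """Screen variants for allele-frequency bias across sample strata.

    For every variant and every pair of strata, a 2x2 allele-count Fisher
    exact test is computed; the per-variant minimum pairwise p-value is then
    Benjamini-Hochberg adjusted across variants.  Variants with adjusted
    p < ``alpha`` are flagged for removal.
    """
    strata = np.asarray(strata)
    if len(strata) != gm.n_samples:
        raise ValueError("strata length must match sample count")
    levels = sorted(set(strata.tolist()))
    if len(levels) < 2:
        raise ValueError("need >=2 strata")

    masks = {lev: strata == lev for lev in levels}
    min_p = np.ones(gm.n_variants)
    for j in range(gm.n_variants):
        col = gm.calls[:, j]
        ok = col != MISSING
        best = 1.0
        for ai in range(len(levels)):
            for bi in range(ai + 1, len(levels)):
                m1 = masks[levels[ai]] & ok
                m2 = masks[levels[bi]] & ok
                alt1, ref1 = int(col[m1].sum()), int(2 * m1.sum() - col[m1].sum())
                alt2, ref2 = int(col[m2].sum()), int(2 * m2.sum() - col[m2].sum())
                if alt1 + ref1 == 0 or alt2 + ref2 == 0:
                    continue  # stratum contributes no alleles at this variant
                _, p = stats.fisher_exact([[alt1, ref1], [alt2, ref2]])
                best = min(best, p)
        min_p[j] = best

    _, p_adj, _, _ = multipletests(min_p, method="fdr_bh")
    table = pd.DataFrame(
        {
            "rsid": gm.rsids,
            "min_pairwise_p": min_p,
            "p_adjusted": p_adj,
            "flagged": p_adj < alpha,
        }
    )
    excluded = table.loc[table["flagged"], "rsid"].tolist()
    return table, excluded
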