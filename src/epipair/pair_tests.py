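"""Closed-form pairwise interaction statistics and the exhaustive scan driver.

Three statistics are provided for a pair of additively coded loci (gA, gB):

* ``regression_epistasis`` -- OLS fit of the interaction model
  Y = b0 + b1*gA + b2*gB + b3*gA*gB (optionally with covariates); the
  interaction coefficient b3 is tested with a two-sided t-test.
* ``fast_epistasis`` -- allelic odds-ratio contrast between the high and low
  phenotype classes: Z = (log R - log S) / sqrt(V_R + V_S), where R and S
  are the 2x2 allele-count odds ratios in cases and controls and V is the
  Woolf variance (sum of reciprocal cell counts).
* ``two_locus_anova`` -- one-way ANOVA of the quantitative trait across the
  occupied cells of the 3x3 joint-genotype grid.

``pairwise_scan`` applies one statistic to all C(m,2) variant pairs.  The
scan is brute-force by design: the intended scale is a pruned panel of at
most a few hundred loci, not a genome-wide matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .genio import MISSING, GenotypeMatrix, PairResult, PhenotypeTable, align

_TINY_P = 5e-324  # smallest subnormal double; keeps p-values in (0, 1]

SCAN_METHODS = ("regression", "fastepi", "anova2")


def _clamp_p(p):
    return np.clip(p, _TINY_P, 1.0)


# ---------------------------------------------------------------------------
# per-pair statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegressionFit:
    """OLS interaction-model fit for one locus pair."""

    beta0: float
    beta1: float
    beta2: float
    beta3: float
    se3: float
    t3: float
    p3: float
    r2_main: float
    r2_full: float
    r2_adj_main: float
    r2_adj_full: float
    n_used: int


@dataclass(frozen=True)
class FastEpiResult:
    log_or_cases: float
    log_or_controls: float
    var_log_or_cases: float
    var_log_or_controls: float
    z: float
    p: float


@dataclass(frozen=True)
class Anova2Result:
    f: float
    df_between: int
    df_within: int
    p: float
    k_cells: int


@dataclass(frozen=True)
class VariancePartition:
    """Nested-model R^2 decomposition: covariates+main vs +interaction."""

    r2_main: float
    r2_full: float
    delta_r2: float
    r2_adj_main: float
    r2_adj_full: float
    delta_r2_adj: float
    n_used: int


def _complete_mask(*arrays: np.ndarray) -> np.ndarray:
    mask = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        a = np.asarray(a)
        if a.ndim == 1:
            a = a[:, None]
        if np.issubdtype(a.dtype, np.integer):
            mask &= (a != MISSING).all(axis=1)
        else:
            mask &= np.isfinite(a).all(axis=1)
    return mask


def regression_epistasis(
    gA: np.ndarray,
    gB: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> RegressionFit:
    """Fit Y ~ 1 (+ covariates) + gA + gB + gA*gB by OLS; test the product term.

    Rows with a missing genotype or non-finite phenotype/covariate are
    dropped (pairwise-complete policy).  Raises ``ValueError('degenerate
    design')`` when the design matrix is rank deficient, e.g. a monomorphic
    locus.
    """
    gA = np.asarray(gA)
    gB = np.asarray(gB)
    y = np.asarray(y, dtype=float)
    arrays = [gA, gB, y] + ([np.asarray(covariates, dtype=float)] if covariates is not None else [])
    mask = _complete_mask(*arrays)
    gA_, gB_, y_ = gA[mask].astype(float), gB[mask].astype(float), y[mask]
    cov_ = None
    if covariates is not None:
        cov_ = np.asarray(covariates, dtype=float)
        if cov_.ndim == 1:
            cov_ = cov_[:, None]
        cov_ = cov_[mask]

    blocks = [np.ones(mask.sum())]
    if cov_ is not None:
        blocks.append(cov_)
    X_main = np.column_stack(blocks + [gA_, gB_])
    X_full = np.column_stack([X_main, gA_ * gB_])
    n, k = X_full.shape
    if n <= k or np.linalg.matrix_rank(X_full) < k:
        raise ValueError("degenerate design")

    fit_full = sm.OLS(y_, X_full).fit()
    fit_main = sm.OLS(y_, X_main).fit()
    return RegressionFit(
        beta0=float(fit_full.params[0]),
        beta1=float(fit_full.params[-3]),
        beta2=float(fit_full.params[-2]),
        beta3=float(fit_full.params[-1]),
        se3=float(fit_full.bse[-1]),
        t3=float(fit_full.tvalues[-1]),
        p3=float(_clamp_p(fit_full.pvalues[-1])),
        r2_main=float(fit_main.rsquared),
        r2_full=float(fit_full.rsquared),
        r2_adj_main=float(fit_main.rsquared_adj),
        r2_adj_full=float(fit_full.rsquared_adj),
        n_used=int(n),
    )


def variance_partition(
    gA: np.ndarray,
    gB: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> VariancePartition:
    """Variance explained by main effects vs main + interaction.

    ``delta_r2`` (raw) is non-negative by nesting; the adjusted delta can be
    negative when the interaction adds no explanatory power, because the
    adjusted R^2 penalizes the extra parameter.
    """
    fit = regression_epistasis(gA, gB, y, covariates)
    return VariancePartition(
        r2_main=fit.r2_main,
        r2_full=fit.r2_full,
        delta_r2=max(0.0, fit.r2_full - fit.r2_main),
        r2_adj_main=fit.r2_adj_main,
        r2_adj_full=fit.r2_adj_full,
        delta_r2_adj=fit.r2_adj_full - fit.r2_adj_main,
        n_used=fit.n_used,
    )


def _allele_table(gA: np.ndarray, gB: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted 2x2 allele-count cross-table [[altA*altB, altA*refB], ...]."""
    a = float(np.dot(w, gA * gB))
    b = float(np.dot(w, gA * (2 - gB)))
    c = float(np.dot(w, (2 - gA) * gB))
    d = float(np.dot(w, (2 - gA) * (2 - gB)))
    return np.array([[a, b], [c, d]])


def _log_or_and_var(table: np.ndarray) -> tuple[float, float]:
    t = table.astype(float)
    if (t == 0).any():
        t = t + 0.5  # Haldane-Anscombe correction on all four cells
    log_or = float(np.log(t[0, 0]) + np.log(t[1, 1]) - np.log(t[0, 1]) - np.log(t[1, 0]))
    var = float((1.0 / t).sum())
    return log_or, var


def fast_epistasis(
    gA: np.ndarray, gB: np.ndarray, bmi_class: np.ndarray
) -> FastEpiResult:
    """Allelic odds-ratio Z test contrasting cases (high) and controls (low).

    Each sample contributes two alleles per locus under an allelic model:
    the per-class 2x2 table cross-tabulates alt-allele count gA vs 2-gA with
    gB vs 2-gB, summed over samples.  Zero cells receive the
    Haldane-Anscombe +0.5 correction before the Woolf variance is formed.
    """
    gA = np.asarray(gA)
    gB = np.asarray(gB)
    cls = np.asarray(bmi_class)
    mask = _complete_mask(gA, gB)
    gA_, gB_, cls_ = gA[mask].astype(float), gB[mask].astype(float), cls[mask]
    case = (cls_ == 1) | (cls_ == True)  # noqa: E712 - accept bool or 0/1
    if not case.any() or case.all():
        raise ValueError("empty class")

    t_case = _allele_table(gA_, gB_, case.astype(float))
    t_ctrl = _allele_table(gA_, gB_, (~case).astype(float))
    log_r, var_r = _log_or_and_var(t_case)
    log_s, var_s = _log_or_and_var(t_ctrl)
    if log_r == log_s:
        z = 0.0
    else:
        z = (log_r - log_s) / np.sqrt(var_r + var_s)
    p = 1.0 if z == 0.0 else float(_clamp_p(2.0 * stats.norm.sf(abs(z))))
    return FastEpiResult(
        log_or_cases=log_r,
        log_or_controls=log_s,
        var_log_or_cases=var_r,
        var_log_or_controls=var_s,
        z=float(z),
        p=p,
    )


def two_locus_anova(gA: np.ndarray, gB: np.ndarray, y: np.ndarray) -> Anova2Result:
    """One-way ANOVA of y across occupied cells of the 3x3 joint-genotype grid."""
    gA = np.asarray(gA)
    gB = np.asarray(gB)
    y = np.asarray(y, dtype=float)
    mask = _complete_mask(gA, gB, y)
    cell = (3 * gA[mask] + gB[mask]).astype(np.int64)
    y_ = y[mask]
    n = len(y_)

    cnt = np.bincount(cell, minlength=9).astype(float)
    occupied = cnt > 0
    k = int(occupied.sum())
    if k < 2:
        raise ValueError("single group")
    if n <= k:
        raise ValueError("need more samples than occupied cells")

    sums = np.bincount(cell, weights=y_, minlength=9)
    grand = y_.sum()
    sst = float(np.dot(y_, y_) - grand * grand / n)
    ssb = float((sums[occupied] ** 2 / cnt[occupied]).sum() - grand * grand / n)
    scale = max(1.0, float(np.dot(y_, y_)))
    if sst <= 1e-12 * scale:  # constant phenotype
        return Anova2Result(f=0.0, df_between=k - 1, df_within=n - k, p=1.0, k_cells=k)
    ssw = max(0.0, sst - ssb)
    ssb = max(0.0, ssb)
    df_b, df_w = k - 1, n - k
    if ssw <= 1e-12 * scale:
        f = np.inf
        p = _TINY_P
    else:
        f = (ssb / df_b) / (ssw / df_w)
        p = float(_clamp_p(stats.f.sf(f, df_b, df_w)))
    return Anova2Result(f=float(f), df_between=df_b, df_within=df_w, p=p, k_cells=k)


# ---------------------------------------------------------------------------
# vectorized scanners (shared by pairwise_scan and permutation testing)
# ---------------------------------------------------------------------------


class _ScannerBase:
    """Common state: complete-data genotype matrix and canonical pair list."""

    def __init__(self, gm: GenotypeMatrix, pairs: Sequence[tuple[str, str]]):
        if (gm.calls == MISSING).any():
            raise ValueError(
                "vectorized scanners require complete genotype data; "
                "run QC with min_call_rate=1.0 or use the per-pair functions"
            )
        self.gm = gm
        self.pairs = list(pairs)
        self.GA = np.stack([gm.column(a) for a, _ in self.pairs]).astype(np.float64)
        self.GB = np.stack([gm.column(b) for _, b in self.pairs]).astype(np.float64)

    @property
    def n(self) -> int:
        return self.gm.n_samples

    def stat_p(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(statistic, p) per pair for one response vector."""
        s, p = self._stat_p_many(np.asarray(y, float)[:, None])
        return s[:, 0], p[:, 0]

    def pvalues(self, Y: np.ndarray) -> np.ndarray:
        """p-values, shape (n_pairs, n_columns), for a response matrix."""
        return self._stat_p_many(np.asarray(Y, float))[1]


class RegressionScanner(_ScannerBase):
    """Batched OLS interaction test across pairs; permutation-friendly.

    The per-pair normal equations are factorized once (the design depends
    only on genotypes), so each additional response column costs one
    matrix-vector product.
    """

    def __init__(self, gm, pairs, covariates: np.ndarray | None = None):
        super().__init__(gm, pairs)
        blocks = [np.ones((self.n, 1))]
        if covariates is not None:
            cov = np.asarray(covariates, float)
            blocks.append(cov[:, None] if cov.ndim == 1 else cov)
        base = np.column_stack(blocks)  # n x c
        P = len(self.pairs)
        k = base.shape[1] + 3
        X = np.empty((P, self.n, k))
        X[:, :, : base.shape[1]] = base[None, :, :]
        X[:, :, -3] = self.GA
        X[:, :, -2] = self.GB
        X[:, :, -1] = self.GA * self.GB
        self.X = X
        self.k = k
        xtx = np.einsum("pnk,pnl->pkl", X, X)
        self.ok = np.ones(P, dtype=bool)
        inv = np.empty_like(xtx)
        for p in range(P):  # per-pair inverse; flag rank-deficient designs
            try:
                if np.linalg.matrix_rank(xtx[p]) < k:
                    raise np.linalg.LinAlgError
                inv[p] = np.linalg.inv(xtx[p])
            except np.linalg.LinAlgError:
                self.ok[p] = False
                inv[p] = np.nan
        self.xtx_inv = inv

    def _stat_p_many(self, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n, k = self.n, self.k
        xty = np.einsum("pnk,nb->pkb", self.X, Y)
        beta = np.einsum("pkl,plb->pkb", self.xtx_inv, xty)
        yty = np.einsum("nb,nb->b", Y, Y)
        rss = yty[None, :] - np.einsum("pkb,pkb->pb", beta, xty)
        dof = n - k
        sigma2 = np.maximum(rss, 0.0) / dof
        with np.errstate(divide="ignore", invalid="ignore"):
            se3 = np.sqrt(self.xtx_inv[:, -1, -1][:, None] * sigma2)
            t3 = beta[:, -1, :] / se3
        p = _clamp_p(2.0 * stats.t.sf(np.abs(t3), dof))
        t3[~self.ok] = np.nan
        p[~self.ok] = np.nan
        return t3, p


class AnovaScanner(_ScannerBase):
    """Batched one-way ANOVA over joint-genotype cells."""

    def __init__(self, gm, pairs):
        super().__init__(gm, pairs)
        cell = (3 * self.GA + self.GB).astype(np.int64)  # P x n in 0..8
        P = len(self.pairs)
        onehot = np.zeros((P, self.n, 9), dtype=np.float32)
        pi = np.repeat(np.arange(P), self.n)
        ni = np.tile(np.arange(self.n), P)
        onehot[pi, ni, cell.ravel()] = 1.0
        self.onehot = onehot
        self.cnt = onehot.sum(axis=1).astype(np.float64)  # P x 9
        self.k = (self.cnt > 0).sum(axis=1).astype(np.int64)  # occupied cells

    def _stat_p_many(self, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n = self.n
        sums = np.einsum("pnc,nb->pcb", self.onehot, Y)
        grand = Y.sum(axis=0)  # b
        yty = np.einsum("nb,nb->b", Y, Y)
        with np.errstate(divide="ignore", invalid="ignore"):
            ssb = np.einsum(
                "pcb,pc->pb", sums**2, np.where(self.cnt > 0, 1.0 / np.maximum(self.cnt, 1), 0.0)
            ) - (grand**2 / n)[None, :]
        sst = (yty - grand**2 / n)[None, :]
        ssw = np.maximum(sst - ssb, 0.0)
        ssb = np.maximum(ssb, 0.0)
        df_b = (self.k - 1)[:, None]
        df_w = (n - self.k)[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ssb / df_b) / (ssw / df_w)
        f = np.where(np.broadcast_to(sst, f.shape) <= 0, 0.0, f)
        p = np.where(
            np.isinf(f), _TINY_P, _clamp_p(stats.f.sf(np.where(np.isinf(f), 1.0, f), df_b, df_w))
        )
        p = np.where(f == 0.0, 1.0, p)
        return f, p


class FastEpiScanner(_ScannerBase):
    """Batched allelic odds-ratio Z test; the response is the binary class."""

    def __init__(self, gm, pairs):
        super().__init__(gm, pairs)
        self.w = np.stack(
            [
                self.GA * self.GB,
                self.GA * (2 - self.GB),
                (2 - self.GA) * self.GB,
                (2 - self.GA) * (2 - self.GB),
            ]
        )  # 4 x P x n
        self.tot = self.w.sum(axis=2)  # 4 x P

    def _stat_p_many(self, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        C = np.asarray(Y, float)  # n x b of 0/1 class indicators
        if ((C != 0) & (C != 1)).any():
            raise ValueError("fastepi scanner expects a binary 0/1 response")
        ncase = C.sum(axis=0)
        if (ncase == 0).any() or (ncase == C.shape[0]).any():
            raise ValueError("empty class")
        case = np.einsum("wpn,nb->wpb", self.w, C)
        ctrl = self.tot[:, :, None] - case

        def log_or_var(t):
            t = np.where((t == 0).any(axis=0, keepdims=True), t + 0.5, t)
            log_or = np.log(t[0]) + np.log(t[3]) - np.log(t[1]) - np.log(t[2])
            var = (1.0 / t).sum(axis=0)
            return log_or, var

        log_r, var_r = log_or_var(case)
        log_s, var_s = log_or_var(ctrl)
        diff = log_r - log_s
        z = np.where(diff == 0.0, 0.0, diff / np.sqrt(var_r + var_s))
        p = np.where(z == 0.0, 1.0, _clamp_p(2.0 * stats.norm.sf(np.abs(z))))
        return z, p


def make_scanner(
    method: str,
    gm: GenotypeMatrix,
    pairs: Sequence[tuple[str, str]] | None = None,
    covariates: np.ndarray | None = None,
) -> _ScannerBase:
    """Build the vectorized scanner for one method over given (or all) pairs."""
    if pairs is None:
        pairs = canonical_pairs(gm)
    if method == "regression":
        return RegressionScanner(gm, pairs, covariates)
    if method == "anova2":
        return AnovaScanner(gm, pairs)
    if method == "fastepi":
        return FastEpiScanner(gm, pairs)
    raise ValueError(f"unknown scan method {method!r}")


def canonical_pairs(gm: GenotypeMatrix) -> list[tuple[str, str]]:
    """All C(m,2) rsid pairs with snp1 < snp2 in (chrom, pos) order."""
    order = gm.canonical_variant_order()
    rsids = [gm.variants[i].rsid for i in order]
    return list(combinations(rsids, 2))


def scan_response(method: str, pheno: PhenotypeTable) -> np.ndarray:
    """The response vector a method consumes: BMI, or the binary class."""
    if method == "fastepi":
        return pheno.bmi_class01.astype(float)
    return pheno.bmi


def pairwise_scan(
    gm: GenotypeMatrix,
    pheno: PhenotypeTable,
    method: str,
    covariates: np.ndarray | None = None,
    use_covariates: bool = False,
) -> list[PairResult]:
    """Apply one interaction statistic to every variant pair.

    Results are sorted by nominal p ascending (ties broken by canonical pair
    order) and carry a Bonferroni-adjusted p over the C(m,2) tests; a
    permutation-based adjustment can replace it downstream.  Covariates are
    accepted for the regression method but default off.
    """
    if method not in SCAN_METHODS:
        raise ValueError(f"unknown scan method {method!r}")
    if gm.n_variants < 2:
        raise ValueError("need at least 2 variants to scan")
    gm, pheno = align(gm, pheno)
    if method == "fastepi" and not pheno.has_class:
        raise ValueError("binary class required")
    cov = None
    if method == "regression" and (use_covariates or covariates is not None):
        cov = covariates if covariates is not None else pheno.covariate_matrix()

    pairs = canonical_pairs(gm)
    y = scan_response(method, pheno)
    if (gm.calls == MISSING).any():
        stat, p = _scan_pairwise_complete(gm, pairs, method, pheno, cov)
    else:
        scanner = make_scanner(method, gm, pairs, covariates=cov)
        stat, p = scanner.stat_p(y)

    n_tests = len(pairs)
    alt = {v.rsid: v.alt_allele for v in gm.variants}
    results = []
    for i, (a, b) in enumerate(pairs):
        if not np.isfinite(p[i]):
            continue  # degenerate design for this pair
        results.append(
            PairResult(
                snp1=a,
                snp2=b,
                method=method,
                statistic=float(stat[i]),
                p_nominal=float(p[i]),
                p_adjusted=float(min(1.0, p[i] * n_tests)),
                effect_alleles=(alt[a], alt[b]),
            )
        )
    order = {pair: i for i, pair in enumerate(pairs)}
    results.sort(key=lambda r: (r.p_nominal, order[(r.snp1, r.snp2)]))
    return results


def _scan_pairwise_complete(gm, pairs, method, pheno, cov):
    """Slow path for matrices with missing calls: per-pair complete cases."""
    y = scan_response(method, pheno)
    stat = np.full(len(pairs), np.nan)
    p = np.full(len(pairs), np.nan)
    for i, (a, b) in enumerate(pairs):
        gA, gB = gm.column(a), gm.column(b)
        try:
            if method == "regression":
                fit = regression_epistasis(gA, gB, y, cov)
                stat[i], p[i] = fit.t3, fit.p3
            elif method == "anova2":
                res = two_locus_anova(gA, gB, y)
                stat[i], p[i] = res.f, res.p
            else:
                res = fast_epistasis(gA, gB, pheno.bmi_class01)
                stat[i], p[i] = res.z, res.p
        except ValueError:
            continue
    return stat, p
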