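"""Multifactor dimensionality reduction (MDR) and its generalized form (GMDR).

MDR collapses the 3x3 joint-genotype grid of a locus pair into a binary
high-risk/low-risk map learned from training data: a cell is high-risk when
its case:control ratio reaches the overall training ratio.  The pair whose
map classifies held-out samples best is selected under 10-fold
cross-validation; cross-validation consistency (CVC) counts the folds that
agreed on the winning pair, and testing balanced accuracy (TBA) is the mean
held-out (sensitivity + specificity)/2.

GMDR replaces case/control counts with per-sample score statistics --
residuals from a covariate-only generalized linear model -- so quantitative
traits and covariate adjustment fit the same machinery: a cell is high-risk
when its training score sum is non-negative.  With a binomial family and no
covariates the score rule reduces exactly to the MDR count rule.

Significance is assessed by permutation: phenotypes (with covariates
attached) are shuffled against genotype rows, the whole search is re-run,
and the observed TBA is referred to the null TBA distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from sklearn.model_selection import StratifiedKFold

from .genio import MISSING, GenotypeMatrix, PhenotypeTable, align
from .pair_tests import canonical_pairs

HIGH, LOW, UNCLASSIFIABLE = 1, 0, -1
_LABEL_NAMES = {HIGH: "high", LOW: "low", UNCLASSIFIABLE: "unclassifiable"}

# Relative tolerance on the score-sum threshold: keeps exact-tie cells
# labelled high-risk even when centered scores carry float rounding.
_TIE_RTOL = 1e-9

CDR_MODES = ("mdr", "gmdr")


@dataclass(frozen=True)
class RiskMap:
    """3x3 grid of cell labels over (gA, gB) genotype values."""

    labels: np.ndarray  # shape (3,3), values in {HIGH, LOW, UNCLASSIFIABLE}

    def label(self, ga: int, gb: int) -> str:
        return _LABEL_NAMES[int(self.labels[ga, gb])]

    def as_strings(self) -> list[list[str]]:
        return [[_LABEL_NAMES[int(v)] for v in row] for row in self.labels]

    def __eq__(self, other) -> bool:
        return isinstance(other, RiskMap) and np.array_equal(self.labels, other.labels)


@dataclass
class CdrModel:
    """Selected pair with CV summary and (optional) permutation calibration."""

    pair: tuple[str, str]
    cvc: int
    train_ba: float
    test_ba: float
    risk_map: RiskMap
    mode: str = "mdr"
    k_folds: int = 10
    perm_cutoff_05: float | None = None
    perm_cutoff_01: float | None = None
    perm_p: float | None = None
    fold_choices: list[tuple[str, str]] = field(default_factory=list)

    def to_text(self, path) -> None:
        """Flat key-value serialization (one `key<TAB>value` per line)."""
        lines = [
            ("snp1", self.pair[0]),
            ("snp2", self.pair[1]),
            ("mode", self.mode),
            ("cvc", self.cvc),
            ("k_folds", self.k_folds),
            ("train_ba", f"{self.train_ba:.12g}"),
            ("test_ba", f"{self.test_ba:.12g}"),
        ]
        for key, val in (
            ("perm_cutoff_05", self.perm_cutoff_05),
            ("perm_cutoff_01", self.perm_cutoff_01),
            ("perm_p", self.perm_p),
        ):
            if val is not None:
                lines.append((key, f"{val:.12g}"))
        for ga in range(3):
            for gb in range(3):
                lines.append((f"cell_{ga}{gb}", self.risk_map.label(ga, gb)))
        with open(path, "w") as fh:
            for k, v in lines:
                fh.write(f"{k}\t{v}\n")


# ---------------------------------------------------------------------------
# cell labelling and accuracy
# ---------------------------------------------------------------------------


def _cells(gA: np.ndarray, gB: np.ndarray) -> np.ndarray:
    """Joint-genotype cell index 0..8; samples with a missing call get 9."""
    gA = np.asarray(gA, dtype=np.int64)
    gB = np.asarray(gB, dtype=np.int64)
    cell = 3 * gA + gB
    cell[(gA == MISSING) | (gB == MISSING)] = 9
    return cell


def _resolve_index(index, n: int) -> np.ndarray:
    if index is None:
        return np.ones(n, dtype=bool)
    index = np.asarray(index)
    if index.dtype == bool:
        return index
    mask = np.zeros(n, dtype=bool)
    mask[index] = True
    return mask


def mdr_cell_labels(
    gA: np.ndarray,
    gB: np.ndarray,
    bmi_class: np.ndarray,
    train_index=None,
) -> RiskMap:
    """Label each 3x3 cell high/low risk from training case:control counts.

    High-risk iff cases/controls >= overall training ratio; exact ties go to
    high-risk; a cell with no controls but some cases is high-risk; an empty
    training cell is unclassifiable.
    """
    cls = np.asarray(bmi_class)
    case = ((cls == 1) | (cls == True)).astype(float)  # noqa: E712
    mask = _resolve_index(train_index, len(case))
    cell = _cells(gA, gB)[mask]
    case_m = case[mask]
    n_case = case_m.sum()
    n_ctrl = len(case_m) - n_case
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("training set must contain both classes")
    ca = np.bincount(cell, weights=case_m, minlength=10)[:9]
    tot = np.bincount(cell, minlength=10)[:9].astype(float)
    co = tot - ca
    # cross-multiplied ratio rule: ca/co >= n_case/n_ctrl
    labels = np.where(ca * n_ctrl >= co * n_case, HIGH, LOW)
    labels[tot == 0] = UNCLASSIFIABLE
    return RiskMap(labels.reshape(3, 3).astype(np.int8))


def gmdr_cell_labels(
    gA: np.ndarray,
    gB: np.ndarray,
    scores: np.ndarray,
    train_index=None,
) -> RiskMap:
    """GMDR cell labels: high-risk iff the training score sum is >= 0.

    Scores are recentred on the training subset before thresholding (a cell
    is high-risk when its score sum exceeds its size-proportional share of
    the training total).  Scores are already centered over the full cohort,
    so with ``train_index=None`` this is the plain score-sum >= 0 rule; on
    a training fold the recentring makes the binomial no-covariate case
    reduce exactly to the MDR count rule.
    """
    scores = np.asarray(scores, dtype=float)
    mask = _resolve_index(train_index, len(scores))
    cell = _cells(gA, gB)[mask]
    s = scores[mask]
    sums = np.bincount(cell, weights=s, minlength=10)[:9]
    tot = np.bincount(cell, minlength=10)[:9]
    tol = _TIE_RTOL * (np.abs(s).sum() / max(1, len(s)) + 1.0)
    labels = np.where(sums - tot * s.mean() >= -tol, HIGH, LOW)
    labels[tot == 0] = UNCLASSIFIABLE
    return RiskMap(labels.reshape(3, 3).astype(np.int8))


def balanced_accuracy(
    risk_map: RiskMap,
    gA: np.ndarray,
    gB: np.ndarray,
    bmi_class: np.ndarray,
    eval_index=None,
) -> float:
    """(sensitivity + specificity)/2, high-risk predicting case.

    Samples falling in unclassifiable cells are excluded from both numerator
    and denominator, keeping 0.5 as the chance level.  If the evaluable part
    of one class is empty its rate contributes 0.5.
    """
    cls = np.asarray(bmi_class)
    case = (cls == 1) | (cls == True)  # noqa: E712
    mask = _resolve_index(eval_index, len(case))
    cell = _cells(gA, gB)[mask]
    case_m = case[mask]
    flat = np.append(risk_map.labels.ravel(), UNCLASSIFIABLE)  # cell 9 -> uncls
    pred = flat[cell]
    usable = pred != UNCLASSIFIABLE
    if not usable.any():
        raise ValueError("all evaluation samples fall in unclassifiable cells")
    tp = float(((pred == HIGH) & case_m & usable).sum())
    fn = float(((pred == LOW) & case_m & usable).sum())
    tn = float(((pred == LOW) & ~case_m & usable).sum())
    fp = float(((pred == HIGH) & ~case_m & usable).sum())
    sens = tp / (tp + fn) if (tp + fn) > 0 else 0.5
    spec = tn / (tn + fp) if (tn + fp) > 0 else 0.5
    return 0.5 * (sens + spec)


# ---------------------------------------------------------------------------
# GLM score statistics
# ---------------------------------------------------------------------------


def gmdr_scores(
    pheno: PhenotypeTable,
    covariates: np.ndarray | None = None,
    family: str = "gaussian",
) -> np.ndarray:
    """Per-sample score statistic: response minus covariate-only GLM fit.

    ``gaussian`` regresses BMI, ``binomial`` the high/low class, each on an
    intercept plus the covariate matrix (identity / logit link).  Scores sum
    to zero and are orthogonal to the covariates by the GLM normal equations.
    """
    if family == "gaussian":
        y = pheno.bmi
        fam = sm.families.Gaussian()
    elif family == "binomial":
        y = pheno.bmi_class01.astype(float)
        fam = sm.families.Binomial()
    else:
        raise ValueError(f"unknown family {family!r}")

    X = np.ones((len(y), 1))
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        X = np.column_stack([X, cov])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    if covariates is None:
        fitted = np.full(len(y), y.mean())
    else:
        fitted = sm.GLM(y, X, family=fam).fit().fittedvalues
    return y - fitted


# ---------------------------------------------------------------------------
# cross-validated search and permutation
# ---------------------------------------------------------------------------


def _search_arrays(
    cells: np.ndarray,  # P x n cell indices (9 = missing)
    weight: np.ndarray,  # per-sample: class indicator (mdr) or score (gmdr)
    is_case: np.ndarray,  # per-sample boolean for accuracy evaluation
    folds: list[tuple[np.ndarray, np.ndarray]],
    mode: str,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-fold best-pair choices plus train/test BA matrices (folds x P)."""
    P, n = cells.shape
    rows = np.arange(P)[:, None]
    n_folds = len(folds)
    train_ba = np.empty((n_folds, P))
    test_ba = np.empty((n_folds, P))
    choice = np.empty(n_folds, dtype=np.int64)

    for f, (tr, te) in enumerate(folds):
        ct = cells[:, tr]
        if mode == "mdr":
            ca = np.zeros((P, 10))
            np.add.at(ca, (rows, ct), is_case[tr].astype(float)[None, :])
            tot = np.zeros((P, 10))
            np.add.at(tot, (rows, ct), 1.0)
            n_case = float(is_case[tr].sum())
            n_ctrl = float(len(tr) - n_case)
            stat = ca * n_ctrl - (tot - ca) * n_case
            labels = np.where(stat >= -tol, HIGH, LOW)
        else:
            sums = np.zeros((P, 10))
            np.add.at(sums, (rows, ct), weight[tr][None, :])
            tot = np.zeros((P, 10))
            np.add.at(tot, (rows, ct), 1.0)
            # recentre on the training fold so the threshold is the fold mean
            labels = np.where(sums - tot * weight[tr].mean() >= -tol, HIGH, LOW)
        labels[tot == 0] = UNCLASSIFIABLE
        labels[:, 9] = UNCLASSIFIABLE

        for which, idx, out in (("train", tr, train_ba), ("test", te, test_ba)):
            pred = labels[rows, cells[:, idx]]  # P x |idx|
            case_e = is_case[idx][None, :]
            usable = pred != UNCLASSIFIABLE
            tp = ((pred == HIGH) & case_e & usable).sum(axis=1)
            fn = ((pred == LOW) & case_e & usable).sum(axis=1)
            tn = ((pred == LOW) & ~case_e & usable).sum(axis=1)
            fp = ((pred == HIGH) & ~case_e & usable).sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                sens = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.5)
                spec = np.where(tn + fp > 0, tn / np.maximum(tn + fp, 1), 0.5)
            out[f] = 0.5 * (sens + spec)
        choice[f] = int(np.argmax(train_ba[f]))  # ties -> lowest canonical index
    return choice, train_ba, test_ba


def cdr_search(
    gm: GenotypeMatrix,
    pheno: PhenotypeTable,
    mode: str = "mdr",
    k_folds: int = 10,
    seed: int = 0,
    covariates: np.ndarray | None = None,
    family: str | None = None,
) -> CdrModel:
    """Cross-validated MDR/GMDR search over all variant pairs.

    In each stratified fold the pair with the best training balanced
    accuracy is chosen; the reported model is the modal pair, its CVC the
    number of folds that chose it, and its TBA the mean held-out balanced
    accuracy across folds.  CVC ties break by higher mean TBA, then
    canonical pair order.
    """
    if mode not in CDR_MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if gm.n_variants < 2:
        raise ValueError("need at least 2 variants")
    gm, pheno = align(gm, pheno)
    n = gm.n_samples
    if n < k_folds:
        raise ValueError(f"n={n} samples < k_folds={k_folds}")

    pairs = canonical_pairs(gm)
    GA = np.stack([gm.column(a) for a, _ in pairs])
    GB = np.stack([gm.column(b) for _, b in pairs])
    cells = _cells(GA.ravel(), GB.ravel()).reshape(GA.shape)

    if mode == "mdr":
        cls = pheno.bmi_class01
        if cls.sum() == 0 or cls.sum() == n:
            raise ValueError("both classes required for MDR")
        is_case = cls.astype(bool)
        weight = cls.astype(float)
        strata = cls
        tol = 0.0
    else:
        fam = family or "gaussian"
        scores = gmdr_scores(pheno, covariates, family=fam)
        is_case = scores > 0
        weight = scores
        strata = is_case.astype(np.int8)
        tol = _TIE_RTOL * (np.abs(scores).mean() + 1.0)
        if is_case.all() or not is_case.any():
            raise ValueError("scores do not split samples into two groups")

    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed % (2**32))
    folds = [(tr, te) for tr, te in skf.split(np.zeros(n), strata)]
    choice, train_ba, test_ba = _search_arrays(cells, weight, is_case, folds, mode, tol)

    counts = np.bincount(choice, minlength=len(pairs))
    cvc_max = counts.max()
    candidates = np.flatnonzero(counts == cvc_max)
    mean_test = test_ba.mean(axis=0)
    best = candidates[np.lexsort((candidates, -mean_test[candidates]))[0]]

    a, b = pairs[best]
    if mode == "mdr":
        rm = mdr_cell_labels(gm.column(a), gm.column(b), pheno.bmi_class01)
    else:
        rm = gmdr_cell_labels(gm.column(a), gm.column(b), weight)
    return CdrModel(
        pair=(a, b),
        cvc=int(cvc_max),
        train_ba=float(train_ba[:, best].mean()),
        test_ba=float(mean_test[best]),
        risk_map=rm,
        mode=mode,
        k_folds=k_folds,
        fold_choices=[pairs[c] for c in choice],
    )


def cdr_permutation(
    gm: GenotypeMatrix,
    pheno: PhenotypeTable,
    mode: str = "mdr",
    B: int = 1000,
    alpha_list: Sequence[float] = (0.05, 0.01),
    seed: int = 0,
    k_folds: int = 10,
    covariates: np.ndarray | None = None,
    family: str | None = None,
) -> tuple[dict[float, float], float, CdrModel]:
    """Permutation calibration of the cross-validated search.

    Phenotype rows (with covariates) are shuffled against genotypes B times
    and the search re-run; cutoffs are empirical (1-alpha) quantiles of the
    null best TBA, and perm_p = (1 + #{null >= observed}) / (1 + B).
    """
    if B < 19:
        raise ValueError("B must be at least 19")
    gm, pheno = align(gm, pheno)
    rng = np.random.default_rng(seed)
    fold_seed = int(rng.integers(2**31))
    observed = cdr_search(
        gm, pheno, mode, k_folds=k_folds, seed=fold_seed, covariates=covariates, family=family
    )
    null = np.empty(B)
    for b in range(B):
        perm = rng.permutation(gm.n_samples)
        pheno_b = pheno.permuted(perm)
        model_b = cdr_search(
            gm,
            pheno_b,
            mode,
            k_folds=k_folds,
            seed=int(rng.integers(2**31)),
            covariates=covariates,
            family=family,
        )
        null[b] = model_b.test_ba

    cutoffs = {
        float(a): float(np.quantile(null, 1.0 - a, method="higher")) for a in alpha_list
    }
    perm_p = float((1 + (null >= observed.test_ba).sum()) / (1 + B))
    observed.perm_cutoff_05 = cutoffs.get(0.05)
    observed.perm_cutoff_01 = cutoffs.get(0.01)
    observed.perm_p = perm_p
    return cutoffs, perm_p, observed
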