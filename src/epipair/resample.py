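"""Permutation-adjusted significance, cross-method consensus and replication.

Family-wise multiplicity over the pair scan is controlled with the
max-statistic (min-p) permutation null: phenotypes are shuffled against
genotypes B times, each permutation is fully re-scanned, and the adjusted
p-value of a pair is the fraction of permutations whose best (smallest)
nominal p is at least as extreme as the pair's observed nominal p, with the
usual +1 correction so p_adjusted >= 1/(B+1).

A consensus report keeps the pairs flagged significant by at least
``min_methods`` distinct methods, and the replication gate re-tests
discovery pairs in an independent cohort: closed-form methods via the same
permutation adjustment, MDR/GMDR via the cross-validated search with the
CVC >= 7/10 gate before permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import cdr
from .genio import GenotypeMatrix, PairResult, PhenotypeTable, align
from .pair_tests import SCAN_METHODS, canonical_pairs, make_scanner, scan_response


def permutation_adjust(
    scan,
    gm: GenotypeMatrix,
    pheno: PhenotypeTable,
    B: int = 1000,
    seed: int = 0,
    covariates: np.ndarray | None = None,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> list[PairResult]:
    """Max-statistic permutation-adjusted p-values for a pair scan.

    ``scan`` is either a method name (``regression``/``fastepi``/``anova2``,
    run through the vectorized scanner) or a callable ``(gm, pheno) ->
    array of nominal p per pair`` evaluated once per permutation.
    """
    if B < 19:
        raise ValueError("B must be at least 19")
    gm, pheno = align(gm, pheno)
    rng = np.random.default_rng(seed)
    n = gm.n_samples

    if callable(scan) and not isinstance(scan, str):
        p_obs = np.asarray(scan(gm, pheno), dtype=float)
        null_min = np.empty(B)
        for b in range(B):
            pheno_b = pheno.permuted(rng.permutation(n))
            null_min[b] = np.nanmin(np.asarray(scan(gm, pheno_b), dtype=float))
        pair_list = pairs or canonical_pairs(gm)
        method = "regression"
        stat_obs = np.full(len(p_obs), np.nan)
    else:
        method = str(scan)
        if method not in SCAN_METHODS:
            raise ValueError(f"unknown scan method {method!r}")
        pair_list = list(pairs) if pairs is not None else canonical_pairs(gm)
        scanner = make_scanner(method, gm, pair_list, covariates=covariates)
        y = scan_response(method, pheno)
        stat_obs, p_obs = scanner.stat_p(y)
        perm_idx = np.stack([rng.permutation(n) for _ in range(B)], axis=1)
        Y = y[perm_idx]  # n x B
        null_p = scanner.pvalues(Y)
        null_min = np.nanmin(null_p, axis=0)

    counts = (null_min[None, :] <= p_obs[:, None]).sum(axis=1)
    p_adj = (1.0 + counts) / (1.0 + B)

    alt = {v.rsid: v.alt_allele for v in gm.variants}
    results = []
    for i, (a, b) in enumerate(pair_list):
        if not np.isfinite(p_obs[i]):
            continue
        results.append(
            PairResult(
                snp1=a,
                snp2=b,
                method=method,
                statistic=float(stat_obs[i]),
                p_nominal=float(p_obs[i]),
                p_adjusted=float(p_adj[i]),
                effect_alleles=(alt.get(a, ""), alt.get(b, "")),
            )
        )
    order = {pair: i for i, pair in enumerate(pair_list)}
    results.sort(key=lambda r: (r.p_nominal, order[(r.snp1, r.snp2)]))
    return results


@dataclass
class ConsensusPair:
    pair: frozenset
    methods: set[str]
    p_by_method: dict[str, float]


@dataclass
class ConsensusReport:
    pairs: list[ConsensusPair]
    min_methods: int = 2

    def pair_sets(self) -> list[frozenset]:
        return [e.pair for e in self.pairs]

    def __len__(self) -> int:
        return len(self.pairs)


def consensus_pairs(
    results: Mapping[str, Sequence[PairResult]] | Sequence[Sequence[PairResult]],
    min_methods: int = 2,
    alpha: float | None = None,
) -> ConsensusReport:
    """Pairs supported by at least ``min_methods`` distinct methods.

    ``results`` maps method name to its significant PairResults (or is a
    plain sequence of such lists, keyed by each result's own method field).
    If ``alpha`` is given, results are first filtered to p_adjusted < alpha.
    Pair identity is order-free.
    """
    if isinstance(results, Mapping):
        lists = list(results.values())
    else:
        lists = list(results)
    if len(lists) < 1:
        raise ValueError("need at least one method result list")

    support: dict[frozenset, dict[str, float]] = {}
    for lst in lists:
        for r in lst:
            if alpha is not None and not (
                r.p_adjusted is not None and r.p_adjusted < alpha
            ):
                continue
            entry = support.setdefault(r.pair, {})
            p = r.p_adjusted if r.p_adjusted is not None else r.p_nominal
            if r.method not in entry or p < entry[r.method]:
                entry[r.method] = p
    out = [
        ConsensusPair(pair=pair, methods=set(pm), p_by_method=dict(pm))
        for pair, pm in support.items()
        if len(pm) >= min_methods
    ]
    out.sort(key=lambda e: (min(e.p_by_method.values()), sorted(e.pair)))
    return ConsensusReport(out, min_methods)


@dataclass
class ReplicationConfig:
    alpha: float = 0.05
    perms: int = 1000
    seed: int = 0
    cvc_min: int = 7
    k_folds: int = 10


@dataclass
class PairReplication:
    pair: frozenset
    status: str  # replicated | non_replicated | untestable
    p_by_method: dict[str, float] = field(default_factory=dict)
    note: str = ""


@dataclass
class ReplicationReport:
    replicated: list[PairReplication]
    non_replicated: list[PairReplication]
    untestable: list[PairReplication]

    def all_entries(self) -> list[PairReplication]:
        return self.replicated + self.non_replicated + self.untestable


def replication_check(
    discovery: ConsensusReport,
    gm2: GenotypeMatrix,
    pheno2: PhenotypeTable,
    cfg: ReplicationConfig | None = None,
) -> ReplicationReport:
    """Re-test discovery pairs in an independent cohort.

    A pair replicates when at least one of its supporting methods yields a
    permutation-adjusted p < alpha in the second cohort.  The MDR/GMDR path
    first requires the cross-validated search over the discovery loci to
    select the pair with CVC >= ``cvc_min`` before permutation testing.
    Pairs with a variant absent from the replication matrix are untestable.
    """
    cfg = cfg or ReplicationConfig()
    if len(discovery) == 0:
        return ReplicationReport([], [], [])

    entries = {e.pair: e for e in discovery.pairs}
    testable: list[frozenset] = []
    untestable: list[PairReplication] = []
    for pair in entries:
        missing = [r for r in pair if r not in gm2]
        if missing:
            untestable.append(
                PairReplication(pair, "untestable", note=f"absent: {','.join(sorted(missing))}")
            )
        else:
            testable.append(pair)
    if not testable:
        import warnings

        warnings.warn("no discovery pair is testable in the replication cohort")
        return ReplicationReport([], [], untestable)

    loci = sorted({r for pair in testable for r in pair})
    gm2r, pheno2r = align(gm2.subset_variants(loci), pheno2)
    order = {v.rsid: i for i, v in enumerate(gm2r.variants)}

    def canonical(pair: frozenset) -> tuple[str, str]:
        a, b = sorted(pair, key=lambda r: gm2r.variants[order[r]].sort_key)
        return a, b

    pair_list = [canonical(p) for p in testable]

    # closed-form methods: one permutation adjustment per method over the
    # family of testable discovery pairs
    p_adj: dict[frozenset, dict[str, float]] = {p: {} for p in testable}
    closed = sorted(
        {m for p in testable for m in entries[p].methods if m in SCAN_METHODS}
    )
    for mi, method in enumerate(closed):
        res = permutation_adjust(
            method, gm2r, pheno2r, B=cfg.perms, seed=cfg.seed + 1000 * (mi + 1),
            pairs=pair_list,
        )
        for r in res:
            if r.pair in p_adj and method in entries[r.pair].methods:
                p_adj[r.pair][method] = r.p_adjusted

    # MDR/GMDR path: cross-validated search over the discovery loci; the
    # selected pair must meet the CVC gate before permutation testing
    cdr_methods = sorted(
        {m for p in testable for m in entries[p].methods if m in cdr.CDR_MODES}
    )
    for mi, mode in enumerate(cdr_methods):
        model = cdr.cdr_search(gm2r, pheno2r, mode, k_folds=cfg.k_folds, seed=cfg.seed)
        sel = frozenset(model.pair)
        if sel in p_adj and mode in entries[sel].methods and model.cvc >= cfg.cvc_min:
            _, perm_p, _ = cdr.cdr_permutation(
                gm2r,
                pheno2r,
                mode,
                B=cfg.perms,
                seed=cfg.seed + 7000 * (mi + 1),
                k_folds=cfg.k_folds,
            )
            p_adj[sel][mode] = perm_p

    replicated, non_replicated = [], []
    for pair in testable:
        pm = p_adj[pair]
        if any(p < cfg.alpha for p in pm.values()):
            replicated.append(PairReplication(pair, "replicated", pm))
        else:
            non_replicated.append(PairReplication(pair, "non_replicated", pm))
    return ReplicationReport(replicated, non_replicated, untestable)
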