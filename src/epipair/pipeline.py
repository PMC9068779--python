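"""End-to-end orchestration: QC -> multi-method discovery scan -> permutation
adjustment -> consensus -> replication -> combination / variance analysis.

``run_discovery`` produces per-method pair results with permutation-adjusted
p-values and the cross-method consensus on cohort 1; ``run_replication``
re-tests the consensus pairs on cohort 2 and attaches the genotype-
combination table and variance partition for every replicated pair.  Both
stages are deterministic given the seed and log every filter count, so the
discovery-to-replication flow can be reconstructed from the log alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cdr, combos, pair_tests, resample
from .genio import GenotypeMatrix, PhenotypeTable, align, load_genotypes, load_phenotypes, write_results
from .qc import QcConfig, QcReport, filter_variants

log = logging.getLogger("epipair")

ALL_METHODS = ("regression", "fastepi", "anova2", "mdr", "gmdr")


@dataclass
class RunConfig:
    genotypes: str
    phenotypes: str
    genotypes2: str | None = None
    phenotypes2: str | None = None
    qc: QcConfig = field(default_factory=QcConfig)
    methods: tuple[str, ...] = ("regression", "fastepi", "anova2", "mdr", "gmdr")
    perms: int = 1000
    min_methods: int = 2
    alpha: float = 0.05
    seed: int = 0
    k_folds: int = 10
    cvc_min: int = 7
    use_covariates: bool = False
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("methods must be non-empty")
        bad = set(self.methods) - set(ALL_METHODS)
        if bad:
            raise ValueError(f"unknown methods: {sorted(bad)}")
        if self.perms < 19:
            raise ValueError("perms must be at least 19")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        qc_raw = raw.pop("qc", {})
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(qc=QcConfig(**qc_raw), **raw)


@dataclass
class DiscoveryResult:
    consensus: resample.ConsensusReport
    per_method: dict[str, list]
    qc_report: QcReport
    cdr_models: dict[str, cdr.CdrModel]


@dataclass
class FinalReport:
    replication: resample.ReplicationReport
    combination_tables: dict[frozenset, combos.CombinationTable]
    variance_partitions: dict[frozenset, pair_tests.VariancePartition]


def _load_cohort(gpath, ppath) -> tuple[GenotypeMatrix, PhenotypeTable]:
    gm = load_genotypes(gpath, format="vcf" if str(gpath).endswith(".vcf") else "raw")
    pheno = load_phenotypes(ppath)
    return align(gm, pheno)


def run_discovery(cfg: RunConfig) -> DiscoveryResult:
    """Discovery stage on cohort 1: QC, per-method scans, consensus."""
    gm, pheno = _load_cohort(cfg.genotypes, cfg.phenotypes)
    log.info("stage=load cohort=1 samples=%d variants=%d dropped_pheno_rows=%d",
             gm.n_samples, gm.n_variants, pheno.n_dropped)
    gm_qc, report = filter_variants(gm, cfg.qc)
    for stage, count in report.counts.items():
        log.info("stage=qc filter=%s retained=%d", stage, count)
    if gm_qc.n_variants == 0:
        raise RuntimeError("zero variants survived QC; see the QC report")

    covs = pheno.covariate_matrix() if cfg.use_covariates else None
    per_method: dict[str, list] = {}
    significant: dict[str, list] = {}
    cdr_models: dict[str, cdr.CdrModel] = {}
    for i, method in enumerate(cfg.methods):
        method_seed = cfg.seed + 101 * (i + 1)
        if method in pair_tests.SCAN_METHODS:
            results = resample.permutation_adjust(
                method, gm_qc, pheno, B=cfg.perms, seed=method_seed,
                covariates=covs if method == "regression" else None,
            )
            per_method[method] = results
            significant[method] = [r for r in results if r.p_adjusted < cfg.alpha]
        else:
            cutoffs, perm_p, model = cdr.cdr_permutation(
                gm_qc, pheno, mode=method, B=cfg.perms, seed=method_seed,
                k_folds=cfg.k_folds,
                covariates=covs if method == "gmdr" else None,
            )
            cdr_models[method] = model
            from .genio import PairResult

            pr = PairResult(
                snp1=model.pair[0], snp2=model.pair[1], method=method,
                statistic=model.test_ba, p_nominal=perm_p, p_adjusted=perm_p,
            )
            per_method[method] = [pr]
            gate = model.cvc >= cfg.cvc_min and perm_p < cfg.alpha
            significant[method] = [pr] if gate else []
            log.info("stage=cdr mode=%s pair=%s/%s cvc=%d tba=%.4f perm_p=%.4g",
                     method, *model.pair, model.cvc, model.test_ba, perm_p)
        log.info("stage=scan method=%s pairs=%d significant=%d",
                 method, len(per_method[method]), len(significant[method]))

    consensus = resample.consensus_pairs(significant, min_methods=cfg.min_methods)
    log.info("stage=consensus min_methods=%d pairs=%d", cfg.min_methods, len(consensus))

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        (out / "qc").mkdir(parents=True, exist_ok=True)
        (out / "scans").mkdir(exist_ok=True)
        report.to_tsv(out / "qc" / "qc_report.tsv")
        for method, results in per_method.items():
            write_results(results, out / "scans" / f"results_{method}.tsv")
        for method, model in cdr_models.items():
            model.to_text(out / "scans" / f"cdr_{method}.txt")
        _write_consensus(consensus, out / "consensus.tsv")
    return DiscoveryResult(consensus, per_method, report, cdr_models)


def _write_consensus(consensus: resample.ConsensusReport, path: Path) -> None:
    rows = []
    for e in consensus.pairs:
        a, b = sorted(e.pair)
        rows.append(
            {
                "snp1": a,
                "snp2": b,
                "n_methods": len(e.methods),
                "methods": ",".join(sorted(e.methods)),
                "min_p_adjusted": min(e.p_by_method.values()),
            }
        )
    pd.DataFrame(
        rows, columns=["snp1", "snp2", "n_methods", "methods", "min_p_adjusted"]
    ).to_csv(path, sep="\t", index=False, float_format="%.12g")


def run_replication(cfg: RunConfig, discovery: DiscoveryResult) -> FinalReport:
    """Replication stage on cohort 2, plus downstream pair characterization."""
    if cfg.genotypes2 is None or cfg.phenotypes2 is None:
        raise ValueError("replication requires genotypes2 and phenotypes2 paths")
    if len(discovery.consensus) == 0:
        log.info("stage=replication pairs=0 (empty discovery)")
        return FinalReport(resample.ReplicationReport([], [], []), {}, {})

    gm2, pheno2 = _load_cohort(cfg.genotypes2, cfg.phenotypes2)
    gm2_qc, rep2 = filter_variants(gm2, cfg.qc)
    log.info("stage=load cohort=2 samples=%d variants=%d (post-QC %d)",
             gm2.n_samples, gm2.n_variants, gm2_qc.n_variants)
    rcfg = resample.ReplicationConfig(
        alpha=cfg.alpha, perms=cfg.perms, seed=cfg.seed + 9001,
        cvc_min=cfg.cvc_min, k_folds=cfg.k_folds,
    )
    replication = resample.replication_check(discovery.consensus, gm2_qc, pheno2, rcfg)
    log.info("stage=replication replicated=%d non_replicated=%d untestable=%d",
             len(replication.replicated), len(replication.non_replicated),
             len(replication.untestable))

    gm2a, pheno2a = align(gm2_qc, pheno2)
    tables: dict[frozenset, combos.CombinationTable] = {}
    partitions: dict[frozenset, pair_tests.VariancePartition] = {}
    for entry in replication.replicated:
        a, b = sorted(entry.pair)
        gA, gB = gm2a.column(a), gm2a.column(b)
        table = combos.combination_counts(gA, gB, pheno2a.bmi_class01)
        tables[entry.pair] = combos.combination_enrichment(table, alpha=cfg.alpha)
        partitions[entry.pair] = pair_tests.variance_partition(
            gA, gB, pheno2a.bmi, pheno2a.covariate_matrix()
        )

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_replication(replication, partitions, out / "replication.tsv")
        cdir = out / "combos"
        cdir.mkdir(exist_ok=True)
        for pair, table in tables.items():
            a, b = sorted(pair)
            _write_combo_table(table, cdir / f"{a}_{b}.tsv")
    return FinalReport(replication, tables, partitions)


def _write_replication(report, partitions, path: Path) -> None:
    rows = []
    for entry in report.all_entries():
        a, b = sorted(entry.pair)
        row = {
            "snp1": a,
            "snp2": b,
            "status": entry.status,
            "methods": ",".join(f"{m}={p:.6g}" for m, p in sorted(entry.p_by_method.items())),
            "note": entry.note,
        }
        vp = partitions.get(entry.pair)
        row["delta_r2"] = f"{vp.delta_r2:.6g}" if vp else ""
        rows.append(row)
    pd.DataFrame(
        rows, columns=["snp1", "snp2", "status", "methods", "delta_r2", "note"]
    ).to_csv(path, sep="\t", index=False)


def _write_combo_table(table: combos.CombinationTable, path: Path) -> None:
    rows = []
    for a in range(3):
        for b in range(3):
            rows.append(
                {
                    "gA": a,
                    "gB": b,
                    "n_high": int(table.counts[a, b, 0]),
                    "n_low": int(table.counts[a, b, 1]),
                    "z": f"{table.z[a, b]:.6g}",
                    "p": f"{table.p[a, b]:.6g}",
                    "direction": table.direction[a, b],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def run(cfg: RunConfig) -> tuple[DiscoveryResult, FinalReport | None]:
    """Full workflow; replication runs only when cohort-2 paths are set."""
    discovery = run_discovery(cfg)
    final = None
    if cfg.genotypes2 and cfg.phenotypes2:
        final = run_replication(cfg, discovery)
    return discovery, final
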