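"""Genotype-phenotype simulator with the structure the analysis assumes.

Genotypes are drawn per variant as the sum of two independent
Bernoulli(MAF) alleles (Hardy-Weinberg proportions, no LD between variants
by default -- the analysis panel is assumed pruned to independent loci).
The BMI-like phenotype follows the interaction regression model:

    bmi = beta0 + beta_age*age + beta_sex*sex + sum_j beta_j g_j
          + interaction_term + N(0, noise_sd^2)

where the planted interaction term is beta3*gA*gB (product model),
beta3*1[gA+gB odd] (xor), or beta3*1[gA=2 and gB=2] (threshold).  Default
nuisance parameters give a middle-aged European-style cohort: age uniform
on 40-80 years, sex ~ Bernoulli(1/2), baseline 21 kg/m^2 with a mild age
trend and a 1 kg/m^2 sex offset, residual SD 3 kg/m^2, so the 25 kg/m^2
class threshold splits the cohort roughly in half.

An optional pairwise-LD knob draws two variants from explicit two-locus
haplotype frequencies, for phantom-epistasis style demonstrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genio import GenotypeMatrix, PhenotypeTable, VariantRecord

INTERACTION_MODELS = ("product", "xor", "threshold")


@dataclass(frozen=True)
class InteractionSpec:
    """Planted two-locus interaction: variant indices, effect size, model."""

    a: int
    b: int
    beta3: float
    model: str = "product"

    def __post_init__(self) -> None:
        if self.model not in INTERACTION_MODELS:
            raise ValueError(f"unknown interaction model {self.model!r}")
        if self.a == self.b:
            raise ValueError("interaction needs two distinct variants")


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 2000
    n_variants: int = 20
    mafs: float | Sequence[float] = 0.3
    beta0: float = 21.0
    beta_age: float = 0.05
    beta_sex: float = 1.0
    main_effects: Mapping[int, float] = field(default_factory=dict)
    interaction: InteractionSpec | None = None
    noise_sd: float = 3.0
    age_range: tuple[float, float] = (40.0, 80.0)
    bmi_threshold: float = 25.0
    ld_pair: tuple[int, int, float] | None = None  # (i, j, r) haplotype LD
    seed: int = 0

    def maf_vector(self) -> np.ndarray:
        mafs = np.broadcast_to(
            np.asarray(self.mafs, dtype=float), (self.n_variants,)
        ).copy()
        if ((mafs <= 0.0) | (mafs > 0.5)).any():
            raise ValueError("mafs must lie in (0, 0.5]")
        return mafs

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_samples < 1 or self.n_variants < 1:
            raise ValueError("n_samples and n_variants must be positive")
        if self.interaction is not None:
            for idx in (self.interaction.a, self.interaction.b):
                if not (0 <= idx < self.n_variants):
                    raise ValueError("interaction variant index out of range")
        for idx in self.main_effects:
            if not (0 <= idx < self.n_variants):
                raise ValueError("main-effect variant index out of range")


def _variant_metadata(m: int) -> list[VariantRecord]:
    """Synthetic rsids with GRCh37-style coordinates, widely spaced.

    Variants cycle through chromosomes 1..22 with >= 50 Mb spacing within a
    chromosome so default distance pruning never collapses them.
    """
    out = []
    for i in range(m):
        chrom = str(i % 22 + 1)
        pos = 10_000_000 + 50_000_000 * (i // 22)
        out.append(
            VariantRecord(f"rs{1000 + i}", chrom, pos, ref_allele="A", alt_allele="G")
        )
    return out


def simulate_genotypes(cfg: SimulationConfig) -> GenotypeMatrix:
    """Draw a samples x variants hard-call matrix under HWE at the given MAFs."""
    mafs = cfg.maf_vector()
    rng = np.random.default_rng(cfg.seed)
    calls = rng.binomial(2, mafs[None, :], size=(cfg.n_samples, cfg.n_variants))
    if cfg.ld_pair is not None:
        i, j, r = cfg.ld_pair
        calls[:, i], calls[:, j] = _ld_pair(rng, cfg.n_samples, mafs[i], mafs[j], r)
    samples = [f"S{k:05d}" for k in range(cfg.n_samples)]
    return GenotypeMatrix(samples, _variant_metadata(cfg.n_variants), calls.astype(np.int8))


def _ld_pair(rng, n, p1, p2, r):
    """Two loci with correlation r via two-locus haplotype frequencies."""
    d = r * np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    hap = np.array(
        [
            (1 - p1) * (1 - p2) + d,  # 00
            (1 - p1) * p2 - d,  # 01
            p1 * (1 - p2) - d,  # 10
            p1 * p2 + d,  # 11
        ]
    )
    if (hap < 0).any():
        raise ValueError("requested LD is infeasible for these allele frequencies")
    draws = rng.choice(4, size=(n, 2), p=hap)  # two haplotypes per sample
    g1 = (draws // 2).sum(axis=1)
    g2 = (draws % 2).sum(axis=1)
    return g1, g2


def _interaction_term(spec: InteractionSpec, gA: np.ndarray, gB: np.ndarray) -> np.ndarray:
    if spec.model == "product":
        return spec.beta3 * gA * gB
    if spec.model == "xor":
        return spec.beta3 * (((gA + gB) % 2) == 1).astype(float)
    return spec.beta3 * ((gA == 2) & (gB == 2)).astype(float)


def simulate_phenotype(gm: GenotypeMatrix, cfg: SimulationConfig) -> PhenotypeTable:
    """BMI-like phenotype with covariate, main and planted interaction effects.

    Height is drawn independently (N(170, 8) cm) and weight back-derived
    from the simulated BMI, so the height/weight -> BMI pipeline is
    exercised end to end.  Deterministic given ``cfg.seed``.
    """
    if gm.n_samples != cfg.n_samples or gm.n_variants != cfg.n_variants:
        raise ValueError("genotype matrix does not match the simulation config")
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    n = cfg.n_samples
    lo, hi = cfg.age_range
    age = rng.uniform(lo, hi, size=n)
    sex = rng.integers(0, 2, size=n)

    bmi = cfg.beta0 + cfg.beta_age * age + cfg.beta_sex * sex
    for idx, beta in cfg.main_effects.items():
        bmi = bmi + beta * gm.calls[:, idx]
    if cfg.interaction is not None:
        gA = gm.calls[:, cfg.interaction.a].astype(float)
        gB = gm.calls[:, cfg.interaction.b].astype(float)
        bmi = bmi + _interaction_term(cfg.interaction, gA, gB)
    bmi = bmi + rng.normal(0.0, cfg.noise_sd, size=n)
    bmi = np.maximum(bmi, 10.0)  # physiological floor

    height = rng.normal(170.0, 8.0, size=n)
    weight = bmi * (height / 100.0) ** 2

    import pandas as pd

    df = pd.DataFrame(
        {
            "sample_id": gm.samples,
            "height_cm": height,
            "weight_kg": weight,
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "bmi_class": np.where(bmi >= cfg.bmi_threshold, "high", "low"),
        }
    )
    return PhenotypeTable(df)


# ---------------------------------------------------------------------------
# named fixtures
# ---------------------------------------------------------------------------

FIXTURES = ("null", "planted_product", "planted_xor", "two_cohort")


def fixture_config(name: str, seed: int = 0) -> SimulationConfig:
    """Study-condition parameter sets for the named fixtures."""
    if name == "null":
        return SimulationConfig(n_samples=1000, n_variants=10, mafs=0.3, seed=seed)
    if name == "planted_product":
        # interaction effect half the residual SD at MAF 0.3
        return SimulationConfig(
            n_samples=2000,
            n_variants=20,
            mafs=0.3,
            interaction=InteractionSpec(0, 1, beta3=1.5, model="product"),
            noise_sd=3.0,
            seed=seed,
        )
    if name == "planted_xor":
        # complete penetrance: the class is exactly the XOR of the pair
        mafs = [0.5, 0.5] + [0.3] * 8
        return SimulationConfig(
            n_samples=900,
            n_variants=10,
            mafs=mafs,
            beta0=20.0,
            beta_age=0.0,
            beta_sex=0.0,
            interaction=InteractionSpec(0, 1, beta3=10.0, model="xor"),
            noise_sd=0.01,
            seed=seed,
        )
    if name == "two_cohort":
        return fixture_config("planted_product", seed)
    raise ValueError(f"unknown fixture {name!r}")


def make_fixture(
    name: str,
    seed: int,
    out_dir: str | Path,
    plant_in_cohort2: bool = True,
) -> dict[str, Path]:
    """Write the named fixture to disk: g.raw (+ .bim) and pheno.tsv.

    ``two_cohort`` additionally writes g2.raw / pheno2.tsv for an
    independent cohort drawn with a shifted seed; ``plant_in_cohort2=False``
    removes the interaction from the second cohort (a non-replicating
    discovery signal).  Byte-identical for identical arguments.
    """
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = fixture_config(name, seed)
    gm = simulate_genotypes(cfg)
    pheno = simulate_phenotype(gm, cfg)
    paths = {"genotypes": out_dir / "g.raw", "phenotypes": out_dir / "pheno.tsv"}
    gm.to_raw(paths["genotypes"])
    pheno.to_tsv(paths["phenotypes"])

    if name == "two_cohort":
        cfg2 = replace(cfg, seed=seed + 7919)
        if not plant_in_cohort2:
            cfg2 = replace(cfg2, interaction=None)
        gm2 = simulate_genotypes(cfg2)
        pheno2 = simulate_phenotype(gm2, cfg2)
        paths["genotypes2"] = out_dir / "g2.raw"
        paths["phenotypes2"] = out_dir / "pheno2.tsv"
        gm2.to_raw(paths["genotypes2"])
        pheno2.to_tsv(paths["phenotypes2"])
    return paths
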