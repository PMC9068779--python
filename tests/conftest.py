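import numpy as np
import pytest

from epipair import (
    GenotypeMatrix,
    PhenotypeTable,
    VariantRecord,
    fixture_config,
    simulate_genotypes,
    simulate_phenotype,
)


def variant(rsid="rs1", chrom="1", pos=1000, ref="A", alt="G", info_r2=None):
    return VariantRecord(rsid, chrom, pos, ref_allele=ref, alt_allele=alt, info_r2=info_r2)


def tiny_matrix(calls, chrom=None, pos=None):
    """GenotypeMatrix from a plain nested list of calls."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    variants = [
        variant(
            rsid=f"rs{j}",
            chrom=(chrom[j] if chrom else "1"),
            pos=(pos[j] if pos else 1000 + 1_000_000 * j),
        )
        for j in range(m)
    ]
    return GenotypeMatrix([f"S{i}" for i in range(n)], variants, calls)


def pheno_from_arrays(sample_ids, bmi, age=None, sex=None, threshold=25.0):
    import pandas as pd

    n = len(sample_ids)
    bmi = np.asarray(bmi, dtype=float)
    df = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "bmi": bmi,
            "bmi_class": np.where(bmi >= threshold, "high", "low"),
            "age": age if age is not None else np.full(n, 60.0),
            "sex": sex if sex is not None else np.zeros(n),
        }
    )
    return PhenotypeTable(df)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def xor_data():
    """Complete-penetrance XOR fixture: class is exactly 1[gA+gB odd]."""
    cfg = fixture_config("planted_xor", seed=11)
    gm = simulate_genotypes(cfg)
    pheno = simulate_phenotype(gm, cfg)
    return gm, pheno


@pytest.fixture(scope="session")
def planted_product_data():
    cfg = fixture_config("planted_product", seed=7)
    gm = simulate_genotypes(cfg)
    pheno = simulate_phenotype(gm, cfg)
    return gm, pheno


@pytest.fixture(scope="session")
def null_data():
    cfg = fixture_config("null", seed=5)
    gm = simulate_genotypes(cfg)
    pheno = simulate_phenotype(gm, cfg)
    return gm, pheno
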