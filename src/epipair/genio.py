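"""Data model and file I/O for genotype matrices, phenotypes and pair results.

Genotypes are hard calls in additive coding: each cell counts copies of the
ALT allele, so 0 = homozygous reference, 1 = heterozygous, 2 = homozygous
alternate.  Missing calls are stored as the sentinel :data:`MISSING` (-1),
never as an imputed value; every downstream operation declares its own
missing-data policy.

Supported on-disk formats:

* PLINK ``.raw`` (additive recode, ``FID IID PAT MAT SEX PHENOTYPE rsid_A ...``),
  with an optional ``.bim`` sidecar supplying chromosome/position/alleles;
* VCF with hard-call GT fields (biallelic records only, via cyvcf2);
* TSV for phenotype/covariate tables and pair-result tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

RESULT_METHODS = ("regression", "fastepi", "anova2", "mdr", "gmdr")


class ParseError(ValueError):
    """Raised on malformed input files; message names the offending line."""


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant: identifier, GRCh37 coordinates and alleles."""

    rsid: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    info_r2: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.rsid}: ref and alt alleles are identical")
        if self.info_r2 is not None and not (0.0 <= self.info_r2 <= 1.0):
            raise ValueError(f"{self.rsid}: info_r2 outside [0,1]")

    @property
    def sort_key(self) -> tuple:
        """Canonical (chromosome, position) ordering key; numeric chromosomes first."""
        c = self.chrom.removeprefix("chr")
        return (0, int(c)) if c.isdigit() else (1, c), self.pos, self.rsid


class GenotypeMatrix:
    """samples x variants table of additive-coded hard calls {0,1,2} / missing."""

    def __init__(
        self,
        samples: Sequence[str],
        variants: Sequence[VariantRecord],
        calls: np.ndarray,
    ) -> None:
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(samples), len(variants)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(samples)} samples x {len(variants)} variants"
            )
        bad = ~np.isin(calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("calls must be in {0,1,2} or missing (-1)")
        rsids = [v.rsid for v in variants]
        if len(set(rsids)) != len(rsids):
            raise ValueError("duplicate rsids in variant list")
        self.samples: list[str] = list(samples)
        self.variants: list[VariantRecord] = list(variants)
        self.calls = calls
        self._index = {r: i for i, r in enumerate(rsids)}

    # -- basic accessors ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def rsids(self) -> list[str]:
        return [v.rsid for v in self.variants]

    def column(self, rsid: str) -> np.ndarray:
        """Calls for one variant, in sample order."""
        return self.calls[:, self._index[rsid]]

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    # -- per-variant summaries --------------------------------------------
    def call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per variant, over non-missing calls."""
        out = np.full(self.n_variants, np.nan)
        for j in range(self.n_variants):
            col = self.calls[:, j]
            ok = col != MISSING
            if ok.any():
                p_alt = col[ok].sum() / (2.0 * ok.sum())
                out[j] = min(p_alt, 1.0 - p_alt)
        return out

    def genotype_counts(self, rsid: str) -> tuple[int, int, int]:
        """(n_hom_ref, n_het, n_hom_alt) over non-missing calls."""
        col = self.column(rsid)
        return int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())

    # -- subsetting --------------------------------------------------------
    def subset_variants(self, rsids: Iterable[str]) -> "GenotypeMatrix":
        idx = [self._index[r] for r in rsids]
        return GenotypeMatrix(
            self.samples, [self.variants[i] for i in idx], self.calls[:, idx]
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in sample_ids]
        return GenotypeMatrix(list(sample_ids), self.variants, self.calls[idx, :])

    def canonical_variant_order(self) -> list[int]:
        """Variant indices sorted by (chromosome, position, rsid)."""
        return sorted(range(self.n_variants), key=lambda i: self.variants[i].sort_key)

    # -- writing -----------------------------------------------------------
    def to_raw(self, path: str | Path, bim: bool = True) -> None:
        """Write PLINK .raw (+ .bim sidecar carrying chrom/pos/alleles)."""
        path = Path(path)
        header = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"] + [
            f"{v.rsid}_{v.alt_allele}" for v in self.variants
        ]
        with open(path, "w") as fh:
            fh.write(" ".join(header) + "\n")
            for i, sid in enumerate(self.samples):
                row = [sid, sid, "0", "0", "0", "-9"]
                row += [
                    "NA" if c == MISSING else str(int(c)) for c in self.calls[i]
                ]
                fh.write(" ".join(row) + "\n")
        if bim:
            with open(path.with_suffix(".bim"), "w") as fh:
                for v in self.variants:
                    fh.write(
                        f"{v.chrom}\t{v.rsid}\t0\t{v.pos}\t{v.alt_allele}\t{v.ref_allele}\n"
                    )


@dataclass(frozen=True)
class PairResult:
    """One SNP pair scored by one interaction method."""

    snp1: str
    snp2: str
    method: str
    statistic: float
    p_nominal: float
    p_adjusted: float | None = None
    effect_alleles: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        if self.method not in RESULT_METHODS:
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def pair(self) -> frozenset:
        return frozenset((self.snp1, self.snp2))


def derive_bmi(
    height_cm: float, weight_kg: float, threshold: float = 25.0
) -> tuple[float, str]:
    """BMI = weight(kg) / height(m)^2; class 'high' iff BMI >= threshold.

    The threshold is inclusive, following the WHO overweight boundary of
    25 kg/m^2 for European populations.
    """
    if not (height_cm > 0 and weight_kg > 0):
        raise ValueError("height and weight must be positive")
    bmi = weight_kg / (height_cm / 100.0) ** 2
    return bmi, ("high" if bmi >= threshold else "low")


class PhenotypeTable:
    """Per-sample quantitative BMI, binary BMI class and covariates (age, sex).

    Thin wrapper over a pandas DataFrame with guaranteed columns
    ``sample_id, bmi, bmi_class, age, sex`` (and optionally
    ``height_cm, weight_kg``).  ``n_dropped`` counts input rows removed for
    missing required fields.
    """

    REQUIRED = ("sample_id", "bmi", "age", "sex")

    def __init__(self, df: pd.DataFrame, n_dropped: int = 0) -> None:
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"phenotype table missing column {col!r}")
        if len(df) == 0:
            raise ValueError("no phenotype rows")
        self.df = df.reset_index(drop=True)
        self.n_dropped = n_dropped

    # -- accessors ---------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].astype(str).tolist()

    @property
    def bmi(self) -> np.ndarray:
        return self.df["bmi"].to_numpy(dtype=float)

    @property
    def has_class(self) -> bool:
        return "bmi_class" in self.df.columns

    @property
    def bmi_class01(self) -> np.ndarray:
        """Binary class vector: 1 = high BMI, 0 = low BMI."""
        if not self.has_class:
            raise ValueError("binary class required but phenotype has no bmi_class")
        return (self.df["bmi_class"].to_numpy() == "high").astype(np.int8)

    @property
    def age(self) -> np.ndarray:
        return self.df["age"].to_numpy(dtype=float)

    @property
    def sex(self) -> np.ndarray:
        return self.df["sex"].to_numpy(dtype=float)

    def covariate_matrix(self, names: Sequence[str] = ("age", "sex")) -> np.ndarray:
        return self.df[list(names)].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.df)

    # -- transforms --------------------------------------------------------
    def reorder(self, sample_ids: Sequence[str]) -> "PhenotypeTable":
        sub = self.df.set_index(self.df["sample_id"].astype(str)).loc[list(sample_ids)]
        return PhenotypeTable(sub.reset_index(drop=True), self.n_dropped)

    def permuted(self, perm: np.ndarray) -> "PhenotypeTable":
        """Permute phenotype + covariates jointly against the sample axis.

        Sample ids stay in place (they index the genotype rows); all data
        columns move together, preserving the covariate-phenotype
        relationship under the null of no genotype effect.
        """
        df = self.df.copy()
        data_cols = [c for c in df.columns if c != "sample_id"]
        df[data_cols] = df[data_cols].to_numpy()[np.asarray(perm)]
        return PhenotypeTable(df, self.n_dropped)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def load_phenotypes(path: str | Path, threshold: float = 25.0) -> PhenotypeTable:
    """Read a phenotype TSV; derive BMI and class; drop incomplete rows.

    The file must contain a sample-id column (``sample_id``/``IID``/``id``),
    ``age``, ``sex``, and either ``bmi`` or both ``height_cm``/``height`` and
    ``weight_kg``/``weight``.  Rows missing any required field are dropped and
    counted in ``n_dropped``.
    """
    df = pd.read_csv(path, sep="\t")
    if len(df) == 0:
        raise ParseError("no phenotype rows")
    cols = {c.lower(): c for c in df.columns}

    def pick(*names):
        for n in names:
            if n in cols:
                return cols[n]
        return None

    sid = pick("sample_id", "iid", "id")
    if sid is None:
        raise ParseError("no sample id column (expected sample_id/IID/id)")
    height = pick("height_cm", "height")
    weight = pick("weight_kg", "weight")
    bmi_col = pick("bmi")
    age = pick("age")
    sex = pick("sex", "gender")
    if age is None or sex is None:
        raise ParseError("phenotype file must contain age and sex columns")
    if bmi_col is None and (height is None or weight is None):
        raise ParseError("phenotype file needs bmi or height+weight columns")

    out = pd.DataFrame({"sample_id": df[sid].astype(str)})
    if height is not None:
        out["height_cm"] = pd.to_numeric(df[height], errors="coerce")
    if weight is not None:
        out["weight_kg"] = pd.to_numeric(df[weight], errors="coerce")
    out["age"] = pd.to_numeric(df[age], errors="coerce")
    out["sex"] = pd.to_numeric(df[sex], errors="coerce")
    if bmi_col is not None:
        out["bmi"] = pd.to_numeric(df[bmi_col], errors="coerce")
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            h = out["height_cm"].to_numpy(dtype=float)
            w = out["weight_kg"].to_numpy(dtype=float)
            bmi = np.where((h > 0) & (w > 0), w / (h / 100.0) ** 2, np.nan)
        out["bmi"] = bmi

    needed = ["bmi", "age", "sex"]
    complete = out[needed].notna().all(axis=1) & (out["bmi"] > 0)
    n_dropped = int((~complete).sum())
    out = out[complete].reset_index(drop=True)
    if len(out) == 0:
        raise ParseError("no phenotype rows")
    out["bmi_class"] = np.where(out["bmi"] >= threshold, "high", "low")
    return PhenotypeTable(out, n_dropped)


def align(gm: GenotypeMatrix, pheno: PhenotypeTable) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Intersect genotype and phenotype samples, keeping genotype order."""
    if gm.samples == pheno.sample_ids:
        return gm, pheno
    pheno_ids = set(pheno.sample_ids)
    shared = [s for s in gm.samples if s in pheno_ids]
    if not shared:
        raise ValueError("no overlap between genotype and phenotype sample ids")
    return gm.subset_samples(shared), pheno.reorder(shared)


# ---------------------------------------------------------------------------
# genotype readers
# ---------------------------------------------------------------------------


def load_genotypes(path: str | Path, format: str = "raw") -> GenotypeMatrix:
    """Load hard-call genotypes from a PLINK .raw or VCF file."""
    if format == "raw":
        return _load_raw(Path(path))
    if format == "vcf":
        return _load_vcf(Path(path))
    raise ValueError(f"unknown genotype format {format!r}")


def _read_bim(path: Path) -> dict[str, VariantRecord] | None:
    bim = path.with_suffix(".bim")
    if not bim.exists():
        return None
    records: dict[str, VariantRecord] = {}
    for lineno, line in enumerate(bim.read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 6:
            raise ParseError(f"{bim}: malformed line {lineno}")
        chrom, rsid, _cm, pos, a1, a2 = parts[:6]
        records[rsid] = VariantRecord(rsid, chrom, int(pos), ref_allele=a2, alt_allele=a1)
    return records


def _load_raw(path: Path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) < 7 or header[:6] != ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]:
            raise ParseError(f"{path}: line 1: not a PLINK .raw header")
        snp_cols = header[6:]
        bim = _read_bim(path)
        variants: list[VariantRecord] = []
        for j, col in enumerate(snp_cols):
            rsid, _, allele = col.rpartition("_")
            if not rsid:
                rsid, allele = col, "A"
            if bim is not None and rsid in bim:
                variants.append(bim[rsid])
            else:
                ref = "N" if allele != "N" else "R"
                variants.append(
                    VariantRecord(rsid, "0", j + 1, ref_allele=ref, alt_allele=allele)
                )
        samples: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + len(snp_cols):
                raise ParseError(
                    f"{path}: line {lineno}: expected {6 + len(snp_cols)} fields, "
                    f"got {len(parts)}"
                )
            samples.append(parts[1])
            row = []
            for tok in parts[6:]:
                if tok in ("NA", "nan", "-9"):
                    row.append(MISSING)
                else:
                    try:
                        val = int(float(tok))
                    except ValueError:
                        raise ParseError(
                            f"{path}: line {lineno}: bad dosage value {tok!r}"
                        ) from None
                    if val not in (0, 1, 2):
                        raise ParseError(
                            f"{path}: line {lineno}: dosage {val} outside {{0,1,2}}"
                        )
                    row.append(val)
            rows.append(row)
    if not rows:
        raise ParseError(f"{path}: no sample rows")
    return GenotypeMatrix(samples, variants, np.array(rows, dtype=np.int8))


def _load_vcf(path: Path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("reading VCF requires the cyvcf2 package") from exc

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    cols: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            warnings.warn(
                f"skipping non-biallelic record {rec.ID or rec.POS} "
                f"(ALT={','.join(rec.ALT)})"
            )
            continue
        calls = np.full(len(samples), MISSING, dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            alleles = gt[:-1]
            if any(a < 0 for a in alleles):
                continue
            calls[i] = sum(1 for a in alleles if a == 1)
        r2 = rec.INFO.get("R2")
        rsid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        variants.append(
            VariantRecord(
                rsid,
                str(rec.CHROM),
                int(rec.POS),
                ref_allele=rec.REF,
                alt_allele=rec.ALT[0],
                info_r2=float(r2) if r2 is not None else None,
            )
        )
        cols.append(calls)
    calls = (
        np.column_stack(cols) if cols else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, variants, calls)


# ---------------------------------------------------------------------------
# pair-result I/O
# ---------------------------------------------------------------------------

_RESULT_COLUMNS = [
    "snp1",
    "snp2",
    "method",
    "statistic",
    "p_nominal",
    "p_adjusted",
    "effect_allele1",
    "effect_allele2",
]


def write_results(results: Sequence[PairResult], path: str | Path) -> None:
    """Write pair results as TSV; round-trips losslessly at 12 sig. digits."""
    rows = [
        {
            "snp1": r.snp1,
            "snp2": r.snp2,
            "method": r.method,
            "statistic": r.statistic,
            "p_nominal": r.p_nominal,
            "p_adjusted": np.nan if r.p_adjusted is None else r.p_adjusted,
            "effect_allele1": r.effect_alleles[0],
            "effect_allele2": r.effect_alleles[1],
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=_RESULT_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def read_results(path: str | Path) -> list[PairResult]:
    df = pd.read_csv(path, sep="\t", dtype={"snp1": str, "snp2": str})
    out = []
    for _, row in df.iterrows():
        padj = row["p_adjusted"]
        out.append(
            PairResult(
                snp1=row["snp1"],
                snp2=row["snp2"],
                method=row["method"],
                statistic=float(row["statistic"]),
                p_nominal=float(row["p_nominal"]),
                p_adjusted=None if pd.isna(padj) else float(padj),
                effect_alleles=(
                    "" if pd.isna(row["effect_allele1"]) else str(row["effect_allele1"]),
                    "" if pd.isna(row["effect_allele2"]) else str(row["effect_allele2"]),
                ),
            )
        )
    return out
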