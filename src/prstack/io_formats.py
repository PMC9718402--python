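"""Readers and writers for the file formats the pipeline consumes.

PLINK-1 bed/bim/fam filesets carry genotypes; GWAS summary statistics and
per-SNP weight files are tab-separated text. Dosages count copies of the
.bim allele-1 (A1), with -1 marking a missing genotype.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

PLINK_MAGIC = b"\x6c\x1b"
SNP_MAJOR = b"\x01"

# PLINK-1 two-bit genotype codes, SNP-major: 00 = hom A1 (two copies of A1),
# 01 = missing, 10 = het, 11 = hom A2.
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}

VARIANT_COLUMNS = ["chrom", "rsid", "pos", "a1", "a2"]


class FormatError(ValueError):
    """Input file violates its declared format (bad magic bytes, etc.)."""


class IntegrityError(ValueError):
    """Dimensions or payload size are internally inconsistent."""


class ConfigurationError(ValueError):
    """A configuration value (column map, threshold, ...) is invalid."""


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix with variant metadata.

    dosages[i, j] counts copies of variants.a1[j] carried by samples[i];
    values are in {0, 1, 2, MISSING}.
    """

    samples: list[str]
    variants: pd.DataFrame  # columns: chrom, rsid, pos, a1, a2
    dosages: np.ndarray  # int8, n_samples x n_variants

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise IntegrityError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.dosages, [0, 1, 2, MISSING])
        if bad.any():
            raise IntegrityError("dosages outside {0, 1, 2, missing}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def dosages_float(self, variant_idx=None) -> np.ndarray:
        """Dosages as float64 with missing encoded as NaN."""
        d = self.dosages if variant_idx is None else self.dosages[:, variant_idx]
        out = d.astype(np.float64)
        out[d == MISSING] = np.nan
        return out

    def subset_variants(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            samples=self.samples,
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
        )

    def subset_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            variants=self.variants,
            dosages=self.dosages[idx, :],
        )


@dataclass
class SumStatRecord:
    """One variant's marginal effect from an external GWAS."""

    rsid: str
    chrom: int
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float


@dataclass
class WeightRecord:
    """Per-allele contribution of one SNP to the final score."""

    rsid: str
    effect_allele: str
    weight: float
    chrom: int = 0
    pos: int = 0


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK-1 bed/bim/fam fileset into a GenotypeMatrix.

    Dosages count the .bim allele-1; variant order follows the .bim file
    exactly. Raises FormatError on bad magic bytes and IntegrityError when
    the .bed payload does not match the .fam/.bim dimensions.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"iid": str},
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "rsid", "cm", "pos", "a1", "a2"],
        dtype={"rsid": str, "a1": str, "a2": str},
    )
    n_samples, n_variants = len(fam), len(bim)

    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:2] != PLINK_MAGIC:
        raise FormatError(f"{prefix}.bed: not a PLINK-1 .bed file (bad magic bytes)")
    if raw[2:3] != SNP_MAJOR:
        raise FormatError(f"{prefix}.bed: only SNP-major layout is supported")
    bytes_per_variant = (n_samples + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != bytes_per_variant * n_variants:
        raise IntegrityError(
            f"{prefix}.bed: payload {payload.size} bytes, expected "
            f"{bytes_per_variant * n_variants} for {n_samples} samples x "
            f"{n_variants} variants"
        )

    blocks = payload.reshape(n_variants, bytes_per_variant)
    # unpack two-bit codes, sample-fastest within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (blocks[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(n_variants, bytes_per_variant * 4)[:, :n_samples]
    dosages = _CODE_TO_DOSAGE[codes].T.copy()  # samples x variants

    variants = bim[["chrom", "rsid", "pos", "a1", "a2"]].copy()
    return GenotypeMatrix(samples=list(fam["iid"]), variants=variants, dosages=dosages)


def write_plink(genotypes: GenotypeMatrix, prefix: str | Path,
                phenotypes: pd.DataFrame | None = None) -> None:
    """Write a GenotypeMatrix as a PLINK-1 bed/bim/fam fileset.

    When a phenotype table with 'id' and 'sex' columns is given, .fam sex is
    filled (1 = male, 2 = female); otherwise it is 0 (unknown).
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    sex_code = {}
    if phenotypes is not None:
        sex_code = {
            str(r.id): (1 if r.sex == "male" else 2)
            for r in phenotypes.itertuples()
        }
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in genotypes.samples:
            fh.write(f"{s} {s} 0 0 {sex_code.get(str(s), 0)} -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for v in genotypes.variants.itertuples():
            fh.write(f"{v.chrom}\t{v.rsid}\t0\t{v.pos}\t{v.a1}\t{v.a2}\n")

    n_samples = genotypes.n_samples
    bytes_per_variant = (n_samples + 3) // 4
    # index by the uint8 view of the dosage so MISSING (-1 -> 255) has a slot
    code_lut = np.zeros(256, dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_CODE.items():
        code_lut[dosage & 0xFF] = code
    codes = code_lut[genotypes.dosages.T.astype(np.int16) & 0xFF]  # variants x samples
    pad = bytes_per_variant * 4 - n_samples
    if pad:
        codes = np.concatenate(
            [codes, np.zeros((codes.shape[0], pad), dtype=np.uint8)], axis=1
        )
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (codes.reshape(codes.shape[0], -1, 4) << shifts).sum(
        axis=2, dtype=np.uint16
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(PLINK_MAGIC + SNP_MAJOR)
        fh.write(packed.tobytes())


DEFAULT_SUMSTAT_COLUMNS = {
    "rsid": "rsid", "chrom": "chrom", "pos": "pos",
    "effect_allele": "effect_allele", "other_allele": "other_allele",
    "beta": "beta", "se": "se", "pvalue": "pvalue",
}


def read_sumstats(path: str | Path,
                  column_map: dict[str, str] | None = None
                  ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Read GWAS summary statistics from delimited text (gzip by suffix).

    column_map maps canonical names (rsid, chrom, pos, effect_allele,
    other_allele, beta, se, pvalue) to the file's header names. Rows with
    non-numeric beta/se/p, or p outside (0, 1], are dropped; the second
    return value counts skipped rows per reason.
    """
    cmap = dict(DEFAULT_SUMSTAT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=None, engine="python",
                     compression="infer", dtype=str)
    missing = [v for v in cmap.values() if v not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: mapped columns absent from header: {missing}"
        )
    out = pd.DataFrame({k: df[v] for k, v in cmap.items()})
    skip_log = {"non_numeric": 0, "pvalue_domain": 0}

    for col in ("beta", "se", "pvalue"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    out["pos"] = pd.to_numeric(out["pos"], errors="coerce")
    out["chrom"] = pd.to_numeric(out["chrom"], errors="coerce")
    numeric_ok = out[["beta", "se", "pvalue", "pos", "chrom"]].notna().all(axis=1)
    skip_log["non_numeric"] = int((~numeric_ok).sum())
    out = out[numeric_ok]
    domain_ok = (out["pvalue"] > 0) & (out["pvalue"] <= 1)
    skip_log["pvalue_domain"] = int((~domain_ok).sum())
    out = out[domain_ok].reset_index(drop=True)
    out["pos"] = out["pos"].astype(np.int64)
    out["chrom"] = out["chrom"].astype(np.int64)
    return out, skip_log


def write_sumstats(sumstats: pd.DataFrame, path: str | Path) -> None:
    cols = list(DEFAULT_SUMSTAT_COLUMNS)
    sumstats.to_csv(path, sep="\t", index=False, columns=cols)


def write_weights(weights: list[WeightRecord], path: str | Path) -> None:
    """Write nonzero per-SNP weights as TSV in (chrom, pos) order.

    Weights are printed in full double precision (scientific notation) so a
    round-trip read reproduces them exactly.
    """
    rows = [w for w in weights if w.weight != 0.0]
    rows.sort(key=lambda w: (w.chrom, w.pos, w.rsid))
    with open(path, "w") as fh:
        fh.write("rsid\teffect_allele\tweight\n")
        for w in rows:
            fh.write(f"{w.rsid}\t{w.effect_allele}\t{w.weight:.17e}\n")


def read_weights(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip",
                       dtype={"rsid": str, "effect_allele": str})


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
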