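"""Readers and writers for the field's standard file formats.

PLINK ped/map text and bed/bim/fam binary genotypes (dosages counted with
respect to the A1 allele; ``0 0`` and the 2-bit code ``01`` mean missing),
tab-separated phenotype/covariate tables in both 0/1 and PLINK 1/2 status
dialects, GCTA-style binary GRM triples plus a plain-text alternative,
per-SNP effect tables compatible in spirit with ``plink --score`` input,
and JSON evaluation reports.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import GenotypeDataset
from .predictors.effects import SnpEffectSet
from .structure import GRMatrix

__all__ = [
    "read_plink_text", "write_plink_text",
    "read_plink_binary", "write_plink_binary",
    "read_phenotypes", "write_phenotypes",
    "read_grm_binary", "write_grm_binary", "write_grm_text",
    "read_snp_effects", "write_snp_effects",
    "write_snp_metadata", "read_snp_metadata",
]

log = logging.getLogger(__name__)

_BED_MAGIC = b"\x6c\x1b"
_BED_SNP_MAJOR = b"\x01"


# ----------------------------------------------------------------------- ped/map
def write_plink_text(dataset: GenotypeDataset, prefix: str | Path) -> None:
    """Write ``<prefix>.ped`` and ``<prefix>.map`` (missing genotype: ``0 0``)."""
    prefix = Path(prefix)
    snps = dataset.snps
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, row in snps.iterrows():
            fh.write(f"{row['chrom']}\t{row['snp']}\t0\t{row['pos']}\n")
    a1 = snps["a1"].to_numpy()
    a2 = snps["a2"].to_numpy()
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i in range(dataset.n_samples):
            fid = dataset.samples["fid"].iat[i]
            iid = dataset.samples["iid"].iat[i]
            fields = [str(fid), str(iid), "0", "0", "0", "-9"]
            row = dataset.dosages[i]
            for j in range(dataset.n_snps):
                d = row[j]
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 2:
                    fields += [a1[j], a1[j]]
                elif d == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a2[j], a2[j]]
            fh.write(" ".join(fields) + "\n")


def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypeDataset:
    """Read ped/map text genotypes; dosage counts the A1 allele.

    A1 is taken as the first allele observed at each SNP (the map format
    carries no allele columns); ``0 0`` denotes missing.  Malformed lines
    raise with their line number.
    """
    snps = pd.read_csv(map_path, sep=r"\s+", header=None,
                       names=["chrom", "snp", "cm", "pos"])
    m = len(snps)
    rows, fids, iids = [], [], []
    allele1 = [None] * m
    allele2 = [None] * m
    raw = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{ped_path}: line {lineno} has {len(parts)} fields, "
                    f"expected {6 + 2 * m}"
                )
            fids.append(parts[0])
            iids.append(parts[1])
            raw.append(parts[6:])
    # first pass fixed allele labels; second pass decodes dosages
    for geno in raw:
        for j in range(m):
            for a in (geno[2 * j], geno[2 * j + 1]):
                if a == "0":
                    continue
                if allele1[j] is None:
                    allele1[j] = a
                elif a != allele1[j] and allele2[j] is None:
                    allele2[j] = a
    for j in range(m):
        if allele1[j] is None:
            allele1[j], allele2[j] = "A", "C"  # all-missing column
        elif allele2[j] is None:
            allele2[j] = "0"  # monomorphic in the file
    dosages = np.empty((len(raw), m))
    for i, geno in enumerate(raw):
        for j in range(m):
            a, b = geno[2 * j], geno[2 * j + 1]
            if a == "0" or b == "0":
                dosages[i, j] = np.nan
            else:
                dosages[i, j] = (a == allele1[j]) + (b == allele1[j])
    # ped carries no A1 declaration; adopt the minor allele as A1
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosages, axis=0) / 2.0
    for j in np.flatnonzero(freq > 0.5):
        allele1[j], allele2[j] = allele2[j], allele1[j]
        dosages[:, j] = 2.0 - dosages[:, j]
    snps_out = pd.DataFrame(
        {
            "snp": snps["snp"], "chrom": snps["chrom"], "pos": snps["pos"],
            "a1": allele1, "a2": allele2,
        }
    )
    samples = pd.DataFrame({"fid": fids, "iid": iids})
    return GenotypeDataset(dosages, samples, snps_out)


# --------------------------------------------------------------------- bed/bim/fam
def write_plink_binary(dataset: GenotypeDataset, prefix: str | Path) -> None:
    """Write SNP-major bed/bim/fam; A1 is the counted allele."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for _, row in dataset.snps.iterrows():
            fh.write(f"{row['chrom']}\t{row['snp']}\t0\t{row['pos']}"
                     f"\t{row['a1']}\t{row['a2']}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for i in range(dataset.n_samples):
            fh.write(f"{dataset.samples['fid'].iat[i]} {dataset.samples['iid'].iat[i]}"
                     " 0 0 0 -9\n")
    n = dataset.n_samples
    # 2-bit codes per individual: 00=hom A1 (dosage 2), 01=missing, 10=het, 11=hom A2
    code = np.empty((dataset.n_snps, n), dtype=np.uint8)
    d = dataset.dosages.T
    code[np.isnan(d)] = 0b01
    code[d == 2] = 0b00
    code[d == 1] = 0b10
    code[d == 0] = 0b11
    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + _BED_SNP_MAJOR)
        padded = np.zeros((dataset.n_snps, n_bytes * 4), dtype=np.uint8)
        padded[:, :n] = code
        packed = (
            padded[:, 0::4]
            | (padded[:, 1::4] << 2)
            | (padded[:, 2::4] << 4)
            | (padded[:, 3::4] << 6)
        )
        fh.write(packed.astype(np.uint8).tobytes())


def read_plink_binary(
    bed_path: str | Path, bim_path: str | Path, fam_path: str | Path
) -> GenotypeDataset:
    """Read SNP-major bed/bim/fam binary genotypes."""
    snps = pd.read_csv(bim_path, sep=r"\s+", header=None,
                       names=["chrom", "snp", "cm", "pos", "a1", "a2"])
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"],
                      dtype={"fid": str, "iid": str})
    n, m = len(fam), len(snps)
    n_bytes = (n + 3) // 4
    blob = Path(bed_path).read_bytes()
    if blob[:2] != _BED_MAGIC:
        raise ValueError(f"{bed_path}: not a bed file (bad magic bytes)")
    if blob[2:3] != _BED_SNP_MAJOR:
        raise ValueError(f"{bed_path}: only SNP-major mode (0x01) is supported")
    body = np.frombuffer(blob[3:], dtype=np.uint8)
    if len(body) != m * n_bytes:
        raise ValueError(
            f"{bed_path}: truncated or oversized payload "
            f"({len(body)} bytes, expected {m * n_bytes})"
        )
    body = body.reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = body & 0b11
    codes[:, 1::4] = (body >> 2) & 0b11
    codes[:, 2::4] = (body >> 4) & 0b11
    codes[:, 3::4] = (body >> 6) & 0b11
    codes = codes[:, :n]
    dosages = np.empty((m, n))
    dosages[codes == 0b00] = 2.0
    dosages[codes == 0b10] = 1.0
    dosages[codes == 0b11] = 0.0
    dosages[codes == 0b01] = np.nan
    snps_out = snps[["snp", "chrom", "pos", "a1", "a2"]].copy()
    samples = fam[["fid", "iid"]].copy()
    return GenotypeDataset(dosages.T, samples, snps_out)


# ------------------------------------------------------------------------ phenotypes
def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> None:
    """Tab-separated phenotype/covariate table (FID, IID, status, ...)."""
    out = phenotypes.copy()
    out = out.rename(columns={"fid": "FID", "iid": "IID"})
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype table with FID/IID/status columns.

    Status coded 1/2 (the PLINK convention) is autodetected and mapped to
    0/1 with a logged notice; ``-9`` and NA mean missing.
    """
    tab = pd.read_csv(path, sep="\t", dtype={"FID": str, "IID": str})
    cols = {c.lower(): c for c in tab.columns}
    for required in ("fid", "iid", "status"):
        if required not in cols:
            raise ValueError(f"{path}: missing column '{required.upper()}'")
    tab = tab.rename(columns={cols["fid"]: "fid", cols["iid"]: "iid",
                              cols["status"]: "status"})
    if tab["iid"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    status = pd.to_numeric(tab["status"], errors="coerce")
    status = status.where(status != -9, np.nan)
    observed = set(status.dropna().unique())
    if observed <= {1.0, 2.0} and 2.0 in observed:
        log.info("%s: status coded 1/2 (PLINK dialect); mapping to 0/1", path)
        status = status - 1.0
    elif not observed <= {0.0, 1.0}:
        raise ValueError(f"{path}: status values {sorted(observed)} not in 0/1 or 1/2 coding")
    if status.isna().all():
        raise ValueError(f"{path}: all status values are missing")
    tab["status"] = status
    return tab


# ----------------------------------------------------------------------------- GRM
def write_grm_binary(grm: GRMatrix, prefix: str | Path) -> None:
    """GCTA-style triple: ``.grm.bin``, ``.grm.N.bin`` (float32 lower
    triangles, row-major with diagonal) and ``.grm.id``."""
    prefix = Path(prefix)
    n = grm.n
    i, j = np.tril_indices(n)
    with open(f"{prefix}.grm.bin", "wb") as fh:
        fh.write(grm.values[i, j].astype("<f4").tobytes())
    with open(f"{prefix}.grm.N.bin", "wb") as fh:
        fh.write(np.full(len(i), grm.m_used, dtype="<f4").tobytes())
    with open(f"{prefix}.grm.id", "w") as fh:
        for s in grm.sample_ids:
            fh.write(f"{s}\t{s}\n")


def read_grm_binary(prefix: str | Path) -> GRMatrix:
    prefix = Path(prefix)
    ids = pd.read_csv(f"{prefix}.grm.id", sep="\t", header=None, names=["fid", "iid"],
                      dtype=str)
    n = len(ids)
    vals = np.frombuffer(Path(f"{prefix}.grm.bin").read_bytes(), dtype="<f4")
    if len(vals) != n * (n + 1) // 2:
        raise ValueError(f"{prefix}.grm.bin: size does not match {n} ids")
    g = np.zeros((n, n))
    i, j = np.tril_indices(n)
    g[i, j] = vals
    g[j, i] = vals
    nvals = np.frombuffer(Path(f"{prefix}.grm.N.bin").read_bytes(), dtype="<f4")
    m_used = int(round(float(nvals[0]))) if len(nvals) else 0
    return GRMatrix(values=g, sample_ids=ids["iid"].to_numpy(), m_used=m_used,
                    freq_source="supplied")


def write_grm_text(grm: GRMatrix, path: str | Path) -> None:
    """Plain-text GRM: iid1, iid2, m, value (lower triangle with diagonal)."""
    ids = grm.sample_ids
    with open(path, "w") as fh:
        fh.write("iid1\tiid2\tm\tvalue\n")
        for i in range(grm.n):
            for j in range(i + 1):
                fh.write(f"{ids[i]}\t{ids[j]}\t{grm.m_used}\t{grm.values[i, j]:.10g}\n")


# --------------------------------------------------------------------- effect sets
def write_snp_effects(effects: SnpEffectSet, path: str | Path) -> None:
    """Tab-separated effect table with intercept/tuning metadata header lines."""
    with open(path, "w") as fh:
        fh.write(f"#method\t{effects.method}\n")
        fh.write(f"#intercept\t{effects.intercept!r}\n")
        for k, v in sorted(effects.metadata.items()):
            fh.write(f"#meta\t{k}\t{v}\n")
        effects.table.to_csv(fh, sep="\t", index=False)


def read_snp_effects(path: str | Path) -> SnpEffectSet:
    method, intercept, meta = "UNKNOWN", 0.0, {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            parts = line[1:].rstrip("\n").split("\t")
            if parts[0] == "method":
                method = parts[1]
            elif parts[0] == "intercept":
                intercept = float(parts[1])
            elif parts[0] == "meta":
                meta[parts[1]] = parts[2]
    table = pd.read_csv(path, sep="\t", skiprows=header_lines)
    return SnpEffectSet(method=method, table=table, intercept=intercept, metadata=meta)


# ------------------------------------------------------------------- SNP metadata
def write_snp_metadata(dataset: GenotypeDataset, path: str | Path) -> None:
    """Sidecar tab-separated SNP table carrying INFO scores and frequencies."""
    dataset.snps.to_csv(path, sep="\t", index=False)


def read_snp_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
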