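"""Core in-memory containers for genotype and phenotype data.

A :class:`GenotypeDataset` holds a samples x SNPs dosage matrix (counts of
the A1 allele, ``NaN`` for missing calls) together with per-sample and
per-SNP metadata tables.  Phenotypes travel as a plain :class:`pandas.DataFrame`
with the column conventions documented in :func:`make_phenotype_table`:
``fid``, ``iid``, ``status`` (0/1 case-control, NaN missing), optionally
``adjusted`` (a continuous ancestry-adjusted phenotype) and clinical
covariate columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["GenotypeDataset", "make_phenotype_table", "align_phenotypes"]

#: complementary base pairs whose alleles cannot be strand-resolved
PALINDROMIC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


@dataclass
class GenotypeDataset:
    """Samples x SNPs dosage matrix with metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_snps)`` float array of A1-allele counts in
        ``{0, 1, 2}``; ``NaN`` marks a missing genotype.
    samples
        DataFrame with at least ``fid`` and ``iid`` columns (``iid`` unique);
        simulated data may carry ``pop`` (subpopulation label).
    snps
        DataFrame with at least ``snp``, ``chrom``, ``pos``, ``a1``, ``a2``;
        optional ``freq`` (generative allele frequency of A1) and ``info``
        (imputation quality score).
    """

    dosages: np.ndarray
    samples: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x SNPs array")
        if len(self.samples) != self.dosages.shape[0]:
            raise ValueError("samples table does not match dosage rows")
        if len(self.snps) != self.dosages.shape[1]:
            raise ValueError("snps table does not match dosage columns")
        if self.samples["iid"].duplicated().any():
            raise ValueError("sample iids must be unique")
        if self.snps["snp"].duplicated().any():
            raise ValueError("SNP ids must be unique")
        self.samples = self.samples.reset_index(drop=True)
        self.snps = self.snps.reset_index(drop=True)

    # ------------------------------------------------------------------ sizes
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def sample_ids(self) -> np.ndarray:
        return self.samples["iid"].to_numpy()

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snps["snp"].to_numpy()

    # ------------------------------------------------------------- statistics
    def allele_freq(self) -> np.ndarray:
        """Sample frequency of the A1 allele per SNP, over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def minor_allele_freq(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate_samples(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=1)

    def missing_rate_snps(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=0)

    def genotype_counts(self, j: int) -> tuple[int, int, int]:
        """(n_A1A1, n_A1A2, n_A2A2) hard-call counts for SNP column ``j``."""
        x = self.dosages[:, j]
        x = x[~np.isnan(x)]
        return int(np.sum(x == 2)), int(np.sum(x == 1)), int(np.sum(x == 0))

    def is_palindromic(self) -> np.ndarray:
        pairs = list(zip(self.snps["a1"].astype(str), self.snps["a2"].astype(str)))
        return np.array([p in PALINDROMIC_PAIRS for p in pairs])

    def standardized(self, freqs: np.ndarray | None = None) -> np.ndarray:
        """Column-standardized dosages ``z = (x - 2p) / sqrt(2p(1-p))``.

        Missing genotypes are mean-imputed to ``2p`` (i.e. ``z = 0``).  With
        ``freqs=None`` the in-sample allele frequencies are used; supplying
        training-fold frequencies avoids leakage when standardizing test data.
        Monomorphic SNPs (``p`` outside ``(0, 1)``) get all-zero columns.
        """
        p = self.allele_freq() if freqs is None else np.asarray(freqs, dtype=float)
        denom = np.sqrt(2.0 * p * (1.0 - p))
        ok = np.isfinite(denom) & (denom > 0)
        z = self.dosages - 2.0 * p
        z[np.isnan(self.dosages)] = 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(ok, z / np.where(ok, denom, 1.0), 0.0)
        return z

    # --------------------------------------------------------------- subsets
    def subset_samples(self, iids: Sequence[str]) -> "GenotypeDataset":
        idx = self.samples.set_index("iid").index.get_indexer(list(iids))
        if np.any(idx < 0):
            missing = [i for i, k in zip(iids, idx) if k < 0]
            raise KeyError(f"unknown sample iids: {missing[:5]}")
        return GenotypeDataset(
            self.dosages[idx, :].copy(),
            self.samples.iloc[idx].reset_index(drop=True),
            self.snps.copy(),
        )

    def subset_snps(self, ids: Sequence[str] | np.ndarray) -> "GenotypeDataset":
        ids = np.asarray(ids)
        if ids.dtype == bool:
            idx = np.flatnonzero(ids)
        else:
            idx = self.snps.set_index("snp").index.get_indexer(list(ids))
            if np.any(idx < 0):
                missing = [i for i, k in zip(ids, idx) if k < 0]
                raise KeyError(f"unknown SNP ids: {missing[:5]}")
        return GenotypeDataset(
            self.dosages[:, idx].copy(),
            self.samples.copy(),
            self.snps.iloc[idx].reset_index(drop=True),
        )

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(self.dosages.copy(), self.samples.copy(), self.snps.copy())


def make_phenotype_table(
    iids: Iterable[str],
    status: Iterable[float],
    fids: Iterable[str] | None = None,
    **extra_columns,
) -> pd.DataFrame:
    """Assemble a phenotype table with the package's column conventions.

    Columns: ``fid``, ``iid``, ``status`` (float 0/1, NaN for missing) plus
    any keyword extras (e.g. ``adjusted``, ``pop``, clinical covariates).
    """
    iids = list(iids)
    table = pd.DataFrame(
        {
            "fid": list(fids) if fids is not None else iids,
            "iid": iids,
            "status": np.asarray(list(status), dtype=float),
        }
    )
    for name, values in extra_columns.items():
        table[name] = values
    return table


def align_phenotypes(dataset: GenotypeDataset, phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Reorder phenotype rows to match ``dataset`` sample order.

    Raises if any dataset sample lacks a phenotype row.
    """
    pheno = phenotypes.set_index("iid")
    idx = pheno.index.get_indexer(dataset.sample_ids)
    if np.any(idx < 0):
        missing = dataset.sample_ids[idx < 0]
        raise KeyError(f"samples without phenotype rows: {list(missing[:5])}")
    return phenotypes.iloc[idx].reset_index(drop=True)
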