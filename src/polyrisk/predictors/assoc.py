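"""Single-marker association scans.

Per-SNP univariate regression of the phenotype on dosage with an intercept:
logistic (Wald test on the log-odds ratio) for 0-1 case-control status,
ordinary linear regression for a continuous adjusted phenotype.  The
logistic scan runs a Newton-Raphson iteration vectorized across blocks of
SNPs, which keeps genome-wide scans fast without per-SNP model objects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm, t as t_dist

from ..datasets import GenotypeDataset

__all__ = ["single_snp_assoc"]

_MAX_ABS_BETA = 30.0  # log-odds beyond this flag (quasi-)separation


def _linear_block(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(y)
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", xc, xc)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (xc.T @ yc) / sxx
        resid = yc[:, None] - xc * beta
        sigma2 = np.einsum("ij,ij->j", resid, resid) / (n - 2)
        se = np.sqrt(sigma2 / sxx)
        p = 2.0 * t_dist.sf(np.abs(beta / se), df=n - 2)
    bad = ~np.isfinite(beta) | ~np.isfinite(se) | (sxx <= 0)
    beta[bad] = np.nan
    se[bad] = np.nan
    p[bad] = np.nan
    return beta, se, p


def _logistic_block(
    x: np.ndarray, y: np.ndarray, max_iter: int = 40, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column logistic regression (intercept + slope), Newton-Raphson."""
    n, m = x.shape
    ybar = y.mean()
    a = np.full(m, np.log(ybar / (1.0 - ybar)))
    b = np.zeros(m)
    active = np.ones(m, dtype=bool)
    det = np.full(m, np.nan)
    s00 = np.full(m, np.nan)
    for _ in range(max_iter):
        eta = a + x * b
        p = expit(eta)
        w = p * (1.0 - p)
        r = y[:, None] - p
        g0 = r.sum(axis=0)
        g1 = np.einsum("ij,ij->j", r, x)
        s00 = w.sum(axis=0)
        s01 = np.einsum("ij,ij->j", w, x)
        s11 = np.einsum("ij,ij,ij->j", w, x, x)
        det = s00 * s11 - s01 * s01
        with np.errstate(divide="ignore", invalid="ignore"):
            da = (s11 * g0 - s01 * g1) / det
            db = (s00 * g1 - s01 * g0) / det
        da = np.clip(np.nan_to_num(da, nan=0.0), -5.0, 5.0)
        db = np.clip(np.nan_to_num(db, nan=0.0), -5.0, 5.0)
        a += np.where(active, da, 0.0)
        b += np.where(active, db, 0.0)
        active &= (np.abs(da) > tol) | (np.abs(db) > tol)
        if not active.any():
            break
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s00 / det)
        p_val = 2.0 * norm.sf(np.abs(b / se))
    bad = ~np.isfinite(b) | ~np.isfinite(se) | (np.abs(b) > _MAX_ABS_BETA) | (det <= 0)
    b = np.where(bad, np.nan, b)
    se = np.where(bad, np.nan, se)
    p_val = np.where(bad, np.nan, p_val)
    return b, se, p_val


def single_snp_assoc(
    dataset: GenotypeDataset,
    y: np.ndarray | pd.Series,
    scale: str = "status",
    block_size: int = 512,
) -> pd.DataFrame:
    """Per-SNP association of phenotype with dosage.

    ``scale='status'`` fits univariate logistic regressions of 0-1 status on
    dosage (Wald p-values); ``scale='adjusted'`` fits ordinary linear
    regressions for the continuous ancestry-adjusted phenotype.  Missing
    dosages are mean-imputed to ``2p``.  SNPs with constant dosage, or with
    (quasi-)separated logistic fits, come back with NaN effect and p-value
    and are excluded downstream.

    Returns a DataFrame with columns ``snp, a1, a2, freq, beta, se, p``.
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y[~np.isnan(y)])) < 2:
        raise ValueError("phenotype must take at least two distinct values")
    if scale not in ("status", "adjusted"):
        raise ValueError("scale must be 'status' or 'adjusted'")
    if scale == "status" and not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("status phenotype must be coded 0/1")

    freqs = dataset.allele_freq()
    m = dataset.n_snps
    beta = np.empty(m)
    se = np.empty(m)
    pval = np.empty(m)
    for start in range(0, m, block_size):
        stop = min(start + block_size, m)
        x = dataset.dosages[:, start:stop].copy()
        nanmask = np.isnan(x)
        if nanmask.any():
            fill = np.broadcast_to(2.0 * freqs[start:stop], x.shape)
            x[nanmask] = fill[nanmask]
        constant = x.std(axis=0) == 0
        if scale == "status":
            b, s, p = _logistic_block(x, y)
        else:
            b, s, p = _linear_block(x, y)
        b[constant] = np.nan
        s[constant] = np.nan
        p[constant] = np.nan
        beta[start:stop], se[start:stop], pval[start:stop] = b, s, p

    return pd.DataFrame(
        {
            "snp": dataset.snp_ids,
            "a1": dataset.snps["a1"].to_numpy(),
            "a2": dataset.snps["a2"].to_numpy(),
            "freq": freqs,
            "beta": beta,
            "se": se,
            "p": pval,
        }
    )
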