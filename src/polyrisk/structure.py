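"""Genomic relationships, population structure and ancestry adjustment.

The genomic relationship matrix (GRM) between individuals j and k is

    G_jk = (1/m) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),

the covariance of standardized dosages over m polymorphic SNPs.  From its
off-diagonal variance follows the effective number of quasi-independent
markers, Me = 1 / Var(G_jk, j<k).  Population structure is captured by a
PCA of a reference panel whose SNP loadings project study samples into the
reference eigenspace; regressing the disease phenotype on the top projected
eigenvectors and keeping the residuals removes ancestry confounding before
model training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import GenotypeDataset

__all__ = [
    "GRMatrix",
    "EigenProjection",
    "compute_grm",
    "effective_marker_count",
    "reference_pca",
    "project_samples",
    "adjust_phenotype",
]

log = logging.getLogger(__name__)


@dataclass
class GRMatrix:
    """Symmetric n x n genomic relationship matrix.

    ``m_used`` counts the polymorphic SNPs entering the average;
    ``freq_source`` records whether standardization used in-sample or
    externally supplied allele frequencies.  Only unrelated, homogeneous
    samples give a meaningful effective marker number.
    """

    values: np.ndarray
    sample_ids: np.ndarray
    m_used: int
    freq_source: str = "in-sample"

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def offdiag(self) -> np.ndarray:
        i, j = np.triu_indices(self.n, k=1)
        return self.values[i, j]


@dataclass
class EigenProjection:
    """Reference-panel PCA usable for out-of-sample projection.

    ``loadings`` (m x k) are right singular vectors of the standardized
    reference matrix; ``scores`` are the reference coordinates U*S, so a
    sample standardized by the *reference* allele frequencies projects as
    ``z @ loadings`` and the reference panel projects exactly onto its own
    scores.
    """

    snp_ids: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    ref_freqs: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    scores: np.ndarray
    sample_ids: np.ndarray


def compute_grm(dataset: GenotypeDataset, freqs: np.ndarray | None = None) -> GRMatrix:
    """GRM from standardized dosages; missing genotypes mean-imputed to 2p.

    Monomorphic SNPs are skipped and ``m`` adjusted accordingly.  With
    in-sample frequencies every row of G sums to zero (centering identity).
    """
    p = dataset.allele_freq() if freqs is None else np.asarray(freqs, dtype=float)
    poly = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    m_used = int(poly.sum())
    if m_used == 0:
        raise ValueError("all SNPs are monomorphic; GRM undefined")
    z = dataset.standardized(p)[:, poly]
    g = (z @ z.T) / m_used
    return GRMatrix(
        values=g,
        sample_ids=dataset.sample_ids.copy(),
        m_used=m_used,
        freq_source="in-sample" if freqs is None else "supplied",
    )


def effective_marker_count(grm: GRMatrix) -> float:
    """Effective number of independent markers, ``Me = 1 / Var(G_jk)``.

    Uses the unbiased sample variance over all j<k pairs.  Valid only for
    unrelated, ancestrally homogeneous samples; related individuals inflate
    the off-diagonal variance and make Me meaningless.
    """
    if grm.n < 2:
        raise ValueError("need at least two samples")
    v = float(np.var(grm.offdiag(), ddof=1))
    if v <= 0:
        raise ValueError("off-diagonal variance is zero; Me undefined (n too small?)")
    return 1.0 / v


def reference_pca(reference: GenotypeDataset, k: int = 10) -> EigenProjection:
    """Top-k PCA of a reference panel, standardized by its own frequencies."""
    p = reference.allele_freq()
    z = reference.standardized(p)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-9)) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds the rank ({rank}) of the reference panel")
    return EigenProjection(
        snp_ids=reference.snp_ids.copy(),
        a1=reference.snps["a1"].to_numpy().copy(),
        a2=reference.snps["a2"].to_numpy().copy(),
        ref_freqs=p,
        loadings=vt[:k].T.copy(),
        eigenvalues=(s[:k] ** 2) / max(reference.n_samples - 1, 1),
        scores=u[:, :k] * s[:k],
        sample_ids=reference.sample_ids.copy(),
    )


def project_samples(
    proj: EigenProjection,
    dataset: GenotypeDataset,
    min_overlap: float = 0.8,
) -> pd.DataFrame:
    """Project study samples onto reference principal components.

    Matches SNPs by id, reconciles allele orientation (a swapped A1/A2 pair
    flips the dosage as ``2 - x``), standardizes by the *reference* allele
    frequencies and multiplies by the reference loadings.  Requires at least
    ``min_overlap`` of the loading SNPs to be present and allele-consistent.
    Projecting the reference panel onto itself returns its own PCA scores.
    """
    pos = pd.Index(dataset.snp_ids).get_indexer(proj.snp_ids)
    usable = (pos >= 0) & (proj.ref_freqs > 0.0) & (proj.ref_freqs < 1.0)
    flip = np.zeros(len(proj.snp_ids), dtype=bool)
    for t, j in enumerate(pos):
        if j < 0:
            continue
        a1, a2 = dataset.snps["a1"].iat[j], dataset.snps["a2"].iat[j]
        if a1 == proj.a1[t] and a2 == proj.a2[t]:
            pass
        elif a1 == proj.a2[t] and a2 == proj.a1[t]:
            flip[t] = True
        else:
            usable[t] = False
    frac = usable.mean() if len(usable) else 0.0
    if frac < min_overlap:
        raise ValueError(
            f"only {frac:.1%} of projection SNPs usable in the dataset "
            f"(minimum {min_overlap:.0%})"
        )

    t_idx = np.flatnonzero(usable)
    cols = pos[t_idx]
    x = dataset.dosages[:, cols].copy()
    x[:, flip[t_idx]] = 2.0 - x[:, flip[t_idx]]
    p = proj.ref_freqs[t_idx]
    denom = np.sqrt(2.0 * p * (1.0 - p))
    z = (x - 2.0 * p)
    z[np.isnan(x)] = 0.0
    z /= denom
    coords = z @ proj.loadings[t_idx]
    return pd.DataFrame(
        coords,
        index=pd.Index(dataset.sample_ids, name="iid"),
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )


def adjust_phenotype(
    y: np.ndarray | pd.Series,
    coords: pd.DataFrame | np.ndarray,
    k: int = 10,
) -> np.ndarray:
    """Residual of the 0-1 phenotype on the top-k projected eigenvectors.

    Ordinary least squares of status on an intercept plus the first ``k``
    coordinates; collinear coordinate columns are handled by the
    minimum-norm solution.  The residuals (a continuous adjusted phenotype)
    are orthogonal to each fitted coordinate and the operation is
    idempotent.
    """
    y = np.asarray(y, dtype=float)
    c = np.asarray(coords, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if k > c.shape[1]:
        raise ValueError(f"k={k} exceeds the {c.shape[1]} available components")
    x = np.column_stack([np.ones(len(y)), c[:, :k]])
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < x.shape[1]:
        log.warning("collinear eigenvector coordinates; using minimum-norm fit")
    return y - x @ beta
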