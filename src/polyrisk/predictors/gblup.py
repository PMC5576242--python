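"""GBLUP: genomic best linear unbiased prediction.

A linear mixed model ``y = mu + g + e`` with ``g ~ N(0, sigma_g2 * G)``
for the genomic relationship matrix G of the training samples.  Variance
components are the exact REML optimum, found by profiling the restricted
likelihood down to a one-dimensional search over the heritability ratio on
the eigendecomposition of the training GRM.  Genetic values for test
individuals come from the train-test GRM block via the mixed-model
equations:

    g_test = G_ts (G_tt + (sigma_e2 / sigma_g2) I)^-1 (y_t - mu).

Case-control status (0-1) is used directly as a linear trait.  The fitted
model also yields its SNP-BLUP equivalent (ridge regression on
standardized genotypes with penalty ``m * sigma_e2 / sigma_g2``), which is
how GBLUP enters the shared per-SNP effect/scoring pathway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from ..datasets import GenotypeDataset
from ..structure import GRMatrix
from .effects import SnpEffectSet

__all__ = ["MixedModelFit", "fit_gblup", "gblup_snp_effects"]

log = logging.getLogger(__name__)

_H2_BOUNDS = (1e-6, 1.0 - 1e-6)
_BOUNDARY = 1e-4


@dataclass
class MixedModelFit:
    """REML variance components and training-sample genetic values."""

    mu: float
    sigma_g2: float
    sigma_e2: float
    h2_hat: float
    loglik: float
    converged: bool
    at_boundary: bool
    train_ids: np.ndarray
    genetic_values: np.ndarray          # BLUP of g for training samples
    alpha: np.ndarray = field(repr=False, default=None)  # (G_tt + delta I)^-1 (y - mu)


def _reml_profile(d: np.ndarray, y_rot: np.ndarray, x_rot: np.ndarray):
    """Restricted log-likelihood profiled over the total variance.

    ``d`` are GRM eigenvalues, ``y_rot``/``x_rot`` the phenotype and
    intercept rotated into the eigenbasis.  Returns a callable of
    h = sigma_g2 / (sigma_g2 + sigma_e2).
    """
    n = len(y_rot)

    def neg_ll(h: float) -> float:
        w = h * d + (1.0 - h)
        xwx = np.sum(x_rot * x_rot / w)
        xwy = np.sum(x_rot * y_rot / w)
        ywy = np.sum(y_rot * y_rot / w)
        rss = max(ywy - xwy * xwy / xwx, 1e-300)
        sigma_p2 = rss / (n - 1)
        ll = -0.5 * ((n - 1) * np.log(sigma_p2) + np.sum(np.log(w)) + np.log(xwx) + (n - 1))
        return -ll

    return neg_ll


def fit_gblup(
    grm: GRMatrix,
    y: pd.Series,
    test_ids,
    h2_fixed: float | None = None,
) -> tuple[MixedModelFit, pd.Series]:
    """Fit GBLUP on the training block and predict the test individuals.

    Parameters
    ----------
    grm
        GRM covering training and test samples (typically standardized with
        training-fold allele frequencies).
    y
        Phenotype indexed by sample iid; only training values are used.
    test_ids
        Samples to predict; all remaining GRM samples form the training set.
    h2_fixed
        Skip REML and use this heritability ratio (0 gives constant
        predictions equal to the intercept).
    """
    ids = list(grm.sample_ids)
    id_pos = {s: i for i, s in enumerate(ids)}
    test_idx = np.array([id_pos[s] for s in test_ids], dtype=int)
    is_test = np.zeros(len(ids), dtype=bool)
    is_test[test_idx] = True
    train_idx = np.flatnonzero(~is_test)
    if len(train_idx) < 3:
        raise ValueError("need at least three training samples")

    y_t = y.reindex(np.asarray(ids)[train_idx]).to_numpy(dtype=float)
    if np.isnan(y_t).any():
        raise ValueError("training phenotypes contain missing values")

    g_tt = grm.values[np.ix_(train_idx, train_idx)]
    d, u = np.linalg.eigh(g_tt)
    d = np.maximum(d, 0.0)
    y_rot = u.T @ y_t
    x_rot = u.T @ np.ones(len(train_idx))

    if h2_fixed is None:
        neg_ll = _reml_profile(d, y_rot, x_rot)
        res = minimize_scalar(neg_ll, bounds=_H2_BOUNDS, method="bounded",
                              options={"xatol": 1e-9})
        h = float(res.x)
        loglik = -float(res.fun)
        converged = bool(res.success)
        if not converged:
            raise RuntimeError(f"REML search did not converge: {res}")
    else:
        h = float(np.clip(h2_fixed, 0.0, 1.0 - 1e-12))
        loglik = -_reml_profile(d, y_rot, x_rot)(max(h, _H2_BOUNDS[0]))
        converged = True

    w = h * d + (1.0 - h)
    xwx = np.sum(x_rot * x_rot / w)
    xwy = np.sum(x_rot * y_rot / w)
    ywy = np.sum(y_rot * y_rot / w)
    mu = xwy / xwx
    sigma_p2 = max(ywy - xwy * xwy / xwx, 0.0) / (len(train_idx) - 1)
    sigma_g2 = h * sigma_p2
    sigma_e2 = (1.0 - h) * sigma_p2

    at_boundary = h <= _BOUNDARY
    if at_boundary:
        log.warning("sigma_g2 at zero boundary; predictions are constant at mu")
        alpha = np.zeros(len(train_idx))
        g_train = np.zeros(len(train_idx))
        g_test = np.zeros(len(test_idx))
    else:
        delta = sigma_e2 / sigma_g2
        alpha = u @ ((u.T @ (y_t - mu)) / (d + delta))
        g_train = g_tt @ alpha
        g_test = grm.values[np.ix_(test_idx, train_idx)] @ alpha

    fit = MixedModelFit(
        mu=float(mu),
        sigma_g2=float(sigma_g2),
        sigma_e2=float(sigma_e2),
        h2_hat=float(h),
        loglik=loglik,
        converged=converged,
        at_boundary=at_boundary,
        train_ids=np.asarray(ids)[train_idx],
        genetic_values=g_train,
        alpha=alpha,
    )
    scores = pd.Series(mu + g_test, index=pd.Index(test_ids, name="iid"), name="score")
    return fit, scores


def gblup_snp_effects(fit: MixedModelFit, train_dataset: GenotypeDataset) -> SnpEffectSet:
    """SNP-BLUP equivalent of a fitted GBLUP model.

    Back-solves per-SNP effects ``b = Z' alpha / m`` on the standardized
    scale (Z the training genotypes standardized with training frequencies)
    and rescales them to the dosage scale, so the GBLUP model can be scored
    on any dataset through the common effect-set pathway.  Identical (up to
    numerical error) to ridge regression with penalty
    ``m * sigma_e2 / sigma_g2``.
    """
    sub = train_dataset.subset_samples(fit.train_ids)
    p = sub.allele_freq()
    z = sub.standardized(p)
    denom = np.sqrt(2.0 * p * (1.0 - p))
    ok = np.isfinite(denom) & (denom > 0)
    b_std = z.T @ fit.alpha / max(int(ok.sum()), 1)  # same divisor as the GRM
    effect = np.where(ok, b_std / np.where(ok, denom, 1.0), 0.0)
    intercept = fit.mu - float(np.sum(effect * 2.0 * p))
    eff = SnpEffectSet.from_training(
        "GBLUP", sub, effect, intercept,
        metadata={"sigma_g2": fit.sigma_g2, "sigma_e2": fit.sigma_e2, "h2_hat": fit.h2_hat},
    )
    return eff
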