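"""Elastic-net risk prediction with association pre-selection.

The model space is first restricted to the ``top_m`` most significant SNPs
from a training-fold single-marker scan (8000 by default), then an
elastic-net penalized regression is fitted over a decreasing penalty path
at fixed mixing parameter, with the penalty chosen by inner K-fold
cross-validation (10 folds by default): a logit link for 0-1 case-control
status, an identity link for the continuous adjusted phenotype.

scikit-learn provides the penalized solvers; this module owns the
pre-selection, standardization and conversion back to dosage-scale allele
effects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logit
from sklearn.linear_model import ElasticNetCV, LogisticRegression, LogisticRegressionCV

from ..datasets import GenotypeDataset
from .effects import SnpEffectSet

__all__ = ["fit_elastic_net"]


def _candidate_snps(assoc: pd.DataFrame, top_m: int) -> np.ndarray:
    p = assoc["p"].to_numpy(dtype=float)
    finite = np.isfinite(p) & np.isfinite(assoc["beta"].to_numpy(dtype=float))
    order = np.argsort(np.where(finite, p, np.inf), kind="stable")
    order = order[finite[order]]
    return assoc["snp"].to_numpy()[order[:top_m]]


def fit_elastic_net(
    dataset: GenotypeDataset,
    y: np.ndarray | pd.Series,
    assoc: pd.DataFrame,
    top_m: int = 8000,
    inner_folds: int = 10,
    scale: str = "status",
    l1_ratio: float = 0.5,
    n_lambdas: int = 15,
    seed: int = 0,
    lambda_override: float | None = None,
) -> SnpEffectSet:
    """Fit an elastic net on the top associated SNPs of the training fold.

    ``assoc`` must come from the same training samples as ``dataset``/``y``
    (selection inside the fold, or cross-validated accuracy is inflated).
    ``lambda_override`` skips the inner tuning and fits at a fixed penalty
    (``np.inf`` gives the fully shrunk model: zero effects and an intercept
    equal to the logit case fraction / phenotype mean).
    """
    if scale not in ("status", "adjusted"):
        raise ValueError("scale must be 'status' or 'adjusted'")
    y = np.asarray(y, dtype=float)

    candidates = _candidate_snps(assoc, top_m)
    if len(candidates) == 0:
        raise ValueError("no usable candidate SNPs in the association scan")
    sub = dataset.subset_snps(candidates)

    p = sub.allele_freq()
    x = sub.dosages.copy()
    nanmask = np.isnan(x)
    if nanmask.any():
        x[nanmask] = np.broadcast_to(2.0 * p, x.shape)[nanmask]
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    xs = (x - mean) / sd
    n = len(y)

    meta: dict = {"top_m": top_m, "l1_ratio": l1_ratio, "inner_folds": inner_folds,
                  "n_candidates": len(candidates), "scale": scale}

    if scale == "status":
        if lambda_override is not None:
            if np.isinf(lambda_override):
                coef_s = np.zeros(xs.shape[1])
                icpt = float(logit(np.clip(y.mean(), 1e-12, 1 - 1e-12)))
                meta["lambda"] = float(lambda_override)
                return _to_effects(sub, coef_s, icpt, mean, sd, p, meta)
            model = LogisticRegression(
                solver="saga", l1_ratio=l1_ratio,
                C=1.0 / (n * lambda_override), max_iter=5000, tol=1e-5,
            ).fit(xs, y)
            meta["lambda"] = float(lambda_override)
        else:
            model = LogisticRegressionCV(
                Cs=n_lambdas, solver="saga",
                l1_ratios=[l1_ratio], cv=inner_folds,
                scoring="neg_log_loss", max_iter=5000, tol=1e-4,
                random_state=seed, n_jobs=1, use_legacy_attributes=False,
            ).fit(xs, y)
            meta["lambda"] = float(1.0 / (n * float(np.atleast_1d(model.C_)[0])))
        coef_s = model.coef_.ravel()
        icpt = float(model.intercept_[0])
    else:
        if lambda_override is not None and np.isinf(lambda_override):
            coef_s = np.zeros(xs.shape[1])
            icpt = float(y.mean())
            meta["lambda"] = float(lambda_override)
            return _to_effects(sub, coef_s, icpt, mean, sd, p, meta)
        model = ElasticNetCV(
            l1_ratio=l1_ratio, cv=inner_folds, n_alphas=n_lambdas * 4,
            random_state=seed, max_iter=5000, tol=1e-5,
        ).fit(xs, y)
        coef_s = model.coef_
        icpt = float(model.intercept_)
        meta["lambda"] = float(model.alpha_)

    return _to_effects(sub, coef_s, icpt, mean, sd, p, meta)


def _to_effects(sub, coef_s, intercept_s, mean, sd, freqs, meta) -> SnpEffectSet:
    # standardized-feature coefficients back to the dosage scale
    effect = coef_s / sd
    intercept = intercept_s - float(np.sum(effect * mean))
    eff = SnpEffectSet.from_training("EN", sub, effect, intercept, metadata=meta)
    return eff
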