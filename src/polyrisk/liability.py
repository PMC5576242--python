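"""Liability-threshold links between AUC, variance explained and decile risk.

Disease arises when a latent standard-normal liability exceeds the
threshold ``t = Phi^-1(1 - K)`` set by the population prevalence K.  For a
risk score explaining a fraction ``v`` of liability variance, truncated-
normal selection gives the mean liabilities of cases and controls,
``i = z/K`` and ``i2 = -z/(1-K)`` with ``z = phi(t)``, and the AUC of the
score follows in closed form:

    AUC = Phi( (i - i2) * v / sqrt( v*(1 - v*i*(i-t)) + v*(1 - v*i2*(i2-t)) ) ).

Inverting this relation for an observed AUC yields ``v``; integrating the
disease probability ``Phi((sqrt(v)*z - t)/sqrt(1-v))`` over deciles of the
standardized score then gives the expected odds ratio of disease between
the top and bottom score deciles — the clinical-utility number a screening
programme cares about.  A Monte-Carlo mode cross-checks the quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "LiabilityModelSpec",
    "liability_auc",
    "auc_to_liability_v",
    "expected_decile_probs",
    "expected_decile_or",
]


@dataclass(frozen=True)
class LiabilityModelSpec:
    """Prevalence-determined constants of the liability-threshold model."""

    K: float                # disease prevalence
    t: float                # liability threshold Phi^-1(1-K)
    z: float                # normal density at the threshold
    i: float                # mean case liability z/K
    i2: float               # mean control liability -z/(1-K)
    v: float = 0.0          # liability variance explained by the score

    @classmethod
    def from_prevalence(cls, K: float, v: float = 0.0) -> "LiabilityModelSpec":
        if not (0.0 < K < 0.5):
            raise ValueError("prevalence K must lie in (0, 0.5)")
        if not (0.0 <= v < 1.0):
            raise ValueError("v must lie in [0, 1)")
        t = float(norm.isf(K))
        z = float(norm.pdf(t))
        return cls(K=K, t=t, z=z, i=z / K, i2=-z / (1.0 - K), v=v)


def liability_auc(v: float, K: float) -> float:
    """AUC of a risk score explaining liability variance ``v`` at prevalence K."""
    if v <= 0.0:
        return 0.5
    s = LiabilityModelSpec.from_prevalence(K, v)
    num = (s.i - s.i2) * v
    den = math.sqrt(
        v * (1.0 - v * s.i * (s.i - s.t)) + v * (1.0 - v * s.i2 * (s.i2 - s.t))
    )
    return float(norm.cdf(num / den))


def auc_to_liability_v(auc: float, K: float) -> LiabilityModelSpec:
    """Solve the liability variance explained by a score of given AUC.

    Bracketed root finding on ``v in [0, 1)``; the AUC is monotone in v, so
    the root is unique.  Scores must already be oriented so cases rank high
    (AUC >= 0.5).
    """
    if not (0.5 <= auc < 1.0):
        raise ValueError("AUC must lie in [0.5, 1); fix score orientation upstream")
    if auc == 0.5:
        return LiabilityModelSpec.from_prevalence(K, 0.0)
    v = brentq(lambda x: liability_auc(x, K) - auc, 1e-12, 1.0 - 1e-9, xtol=1e-12)
    return LiabilityModelSpec.from_prevalence(K, float(v))


def expected_decile_probs(
    auc: float,
    K: float,
    n_groups: int = 10,
    method: str = "quadrature",
    mc_draws: int = 10_000_000,
    seed: int = 0,
) -> np.ndarray:
    """Expected disease probability within each risk-score decile.

    With the score standardized (``z = score / sqrt(v)`` standard normal),
    the probability of disease in decile d is

        P_d = n_groups * integral_{decile d} Phi((sqrt(v) z - t) / sqrt(1-v)) phi(z) dz,

    computed by adaptive quadrature, or by Monte Carlo over ``mc_draws``
    standard-normal scores (``method='mc'``), which serves as an
    independent cross-check of the quadrature.
    """
    spec = auc_to_liability_v(auc, K)
    v, t = spec.v, spec.t
    edges = norm.ppf(np.linspace(0.0, 1.0, n_groups + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    if v == 0.0:
        return np.full(n_groups, K)

    if method == "quadrature":
        sq = math.sqrt(v)
        s1 = math.sqrt(1.0 - v)

        def integrand(x: float) -> float:
            return norm.cdf((sq * x - t) / s1) * norm.pdf(x)

        probs = np.empty(n_groups)
        for d in range(n_groups):
            val, err = quad(integrand, edges[d], edges[d + 1], epsabs=1e-12, epsrel=1e-10)
            if not np.isfinite(val) or err > 1e-6:
                raise RuntimeError(f"quadrature failed to converge in decile {d + 1}")
            probs[d] = n_groups * val
        return probs
    if method == "mc":
        rng = np.random.default_rng(seed)
        probs = np.empty(n_groups)
        done = 0
        sums = np.zeros(n_groups)
        counts = np.zeros(n_groups)
        chunk = 2_000_000
        while done < mc_draws:
            size = min(chunk, mc_draws - done)
            x = rng.standard_normal(size)
            pdis = norm.cdf((math.sqrt(v) * x - t) / math.sqrt(1.0 - v))
            bins = np.clip(np.searchsorted(edges, x) - 1, 0, n_groups - 1)
            sums += np.bincount(bins, weights=pdis, minlength=n_groups)
            counts += np.bincount(bins, minlength=n_groups)
            done += size
        return sums / counts
    raise ValueError("method must be 'quadrature' or 'mc'")


def expected_decile_or(
    auc: float,
    K: float,
    n_groups: int = 10,
    method: str = "quadrature",
    mc_draws: int = 10_000_000,
    seed: int = 0,
) -> float:
    """Expected top-vs-bottom-decile odds ratio of disease.

    ``OR = [P_top / (1 - P_top)] / [P_bottom / (1 - P_bottom)]`` with the
    decile probabilities from :func:`expected_decile_probs`.  Equals 1 at
    AUC 0.5 and increases strictly with AUC at fixed prevalence.
    """
    p = expected_decile_probs(auc, K, n_groups=n_groups, method=method,
                              mc_draws=mc_draws, seed=seed)
    top, bottom = p[-1], p[0]
    return float((top / (1.0 - top)) / (bottom / (1.0 - bottom)))
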