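"""Genotype/phenotype simulator under the liability-threshold model.

The generator emulates the statistical structure of case-control SNP-array
cohorts: biallelic dosages at configurable allele frequencies, sparse
mixture-of-normals genetic architectures, a latent liability that exceeds a
prevalence-determined threshold in cases, case-control ascertainment from a
finite pool, optional two-subpopulation stratification (Balding-Nichols
differentiation) with case/ancestry confounding, per-batch genotyping
artifacts, and clinical covariates correlated with the true genetic score.

SNPs are simulated in linkage equilibrium by default;
:func:`replicate_snps_with_ld` adds correlated duplicate markers where LD
behaviour (e.g. of the effective-marker-number statistic) is under test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._rng import spawn_rng
from .datasets import GenotypeDataset, make_phenotype_table

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "TrueModel",
    "simulate_genotypes",
    "simulate_effect_sizes",
    "simulate_case_control",
    "attach_clinical_covariates",
    "simulate_dataset",
    "genotype_with_batch_errors",
    "replicate_snps_with_ld",
]

_NONPALINDROMIC = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G")]
_PALINDROMIC = [("A", "T"), ("G", "C")]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Defaults describe a desk-scale polygenic case-control study: a sparse
    four-component normal-mixture architecture (component variance
    multipliers 0, 1e-4, 1e-3 and 1e-2 of the genetic variance), liability
    heritability 0.5, and ascertainment of equal cases/controls from a pool
    with 10% prevalence.  Clinical-utility calculations at the very low
    prevalences of real disease (0.005, 0.002) are analytic and do not go
    through the simulator.
    """

    n_pool: int = 20_000
    m: int = 1_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    pi: tuple[float, float, float, float] = (0.95, 0.03, 0.015, 0.005)
    gamma: tuple[float, float, float, float] = (0.0, 1e-4, 1e-3, 1e-2)
    h2: float = 0.5
    prevalence_K: float = 0.1
    n_cases: int = 1_000
    n_controls: int = 1_000
    n_subpops: int = 1
    fst: float = 0.0
    confounding_delta: float = 0.0
    batch_error_rate: float = 0.0
    missing_rate: float = 0.0
    palindromic_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (4,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
            raise ConfigError("pi must be a 4-vector on the simplex")
        gamma = np.asarray(self.gamma, dtype=float)
        if gamma.shape != (4,) or gamma[0] != 0.0 or np.any(gamma < 0):
            raise ConfigError("gamma must be a 4-vector with gamma[0] = 0")
        if not (0.0 <= self.h2 < 1.0):
            raise ConfigError("h2 must lie in [0, 1)")
        if not (0.0 < self.prevalence_K < 0.5):
            raise ConfigError("prevalence_K must lie in (0, 0.5)")
        if self.n_subpops not in (1, 2):
            raise ConfigError("n_subpops must be 1 or 2")
        if not (0.0 <= self.fst < 0.5):
            raise ConfigError("fst must lie in [0, 0.5)")
        if self.n_subpops == 1 and self.fst > 0:
            raise ConfigError("fst > 0 requires n_subpops = 2")
        for name in ("confounding_delta", "batch_error_rate", "missing_rate", "palindromic_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class TrueModel:
    """Generative truth for one simulated architecture.

    ``effects`` are per-SNP liability effects on the standardized-genotype
    scale; the realized variance of ``genetic_scores`` equals ``sigma_g2``
    (the target h2) exactly by construction.  ``liabilities`` and the
    threshold are filled by :func:`simulate_case_control`.
    """

    effects: np.ndarray
    component_labels: np.ndarray  # in {1, 2, 3, 4}
    sigma_g2: float
    genetic_scores: np.ndarray
    liability_threshold_t: float | None = None
    liabilities: np.ndarray | None = None


# --------------------------------------------------------------------------- genotypes
def simulate_genotypes(config: SimulationConfig) -> GenotypeDataset:
    """Draw a pool of unphased biallelic dosages.

    Ancestral A1 frequencies are uniform on ``maf_range``; with two
    subpopulations, each subpopulation frequency is drawn from a
    Balding-Nichols Beta distribution around the ancestral value with
    differentiation ``fst``.  A ``palindromic_fraction`` of SNPs receives
    A/T or G/C allele pairs (for QC exercises), imputation INFO scores are
    drawn in (0, 1], and genotypes go missing independently at
    ``missing_rate``.
    """
    config.validate()
    rng = spawn_rng(config.seed, "genotypes")
    n, m = config.n_pool, config.m

    p_anc = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)

    if config.n_subpops == 2:
        pop = np.repeat([1, 2], [n - n // 2, n // 2])
        if config.fst > 0:
            a = p_anc * (1.0 - config.fst) / config.fst
            b = (1.0 - p_anc) * (1.0 - config.fst) / config.fst
            p_sub = np.stack([rng.beta(a, b), rng.beta(a, b)])
            p_sub = np.clip(p_sub, 1e-4, 1.0 - 1e-4)
        else:
            p_sub = np.stack([p_anc, p_anc])
        dos = np.empty((n, m))
        for s in (1, 2):
            rows = pop == s
            dos[rows] = rng.binomial(2, p_sub[s - 1], size=(rows.sum(), m))
    else:
        pop = np.ones(n, dtype=int)
        dos = rng.binomial(2, p_anc, size=(n, m)).astype(float)
    dos = dos.astype(float)

    if config.missing_rate > 0:
        dos[rng.random((n, m)) < config.missing_rate] = np.nan

    pal = rng.random(m) < config.palindromic_fraction
    alleles = np.empty((m, 2), dtype=object)
    pick_np = rng.integers(0, len(_NONPALINDROMIC), size=m)
    pick_p = rng.integers(0, len(_PALINDROMIC), size=m)
    for j in range(m):
        alleles[j] = _PALINDROMIC[pick_p[j]] if pal[j] else _NONPALINDROMIC[pick_np[j]]

    info = np.clip(rng.beta(8.0, 2.0, size=m), 1e-6, 1.0)

    width = len(str(m))
    snps = pd.DataFrame(
        {
            "snp": [f"snp{j:0{width}d}" for j in range(m)],
            "chrom": 1,
            "pos": 10_000 * (np.arange(m) + 1),
            "a1": alleles[:, 0],
            "a2": alleles[:, 1],
            "freq": p_anc,
            "info": info,
        }
    )
    width_n = len(str(n))
    samples = pd.DataFrame(
        {
            "fid": [f"F{i:0{width_n}d}" for i in range(n)],
            "iid": [f"I{i:0{width_n}d}" for i in range(n)],
            "pop": pop,
        }
    )
    return GenotypeDataset(dos, samples, snps)


# ----------------------------------------------------------------------------- effects
def simulate_effect_sizes(
    genotypes: GenotypeDataset,
    pi: tuple[float, ...],
    gamma: tuple[float, ...],
    h2: float,
    seed: int,
) -> TrueModel:
    """Draw mixture-of-normals SNP effects and rescale to the target h2.

    Each SNP joins component ``c`` with probability ``pi_c`` and receives an
    effect ``N(0, gamma_c)`` on the standardized-genotype scale (component 1
    is a point mass at zero).  The whole effect vector is then rescaled so
    the realized variance of the genetic score over the simulated pool
    equals ``h2`` exactly.
    """
    pi = np.asarray(pi, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if pi.shape != (4,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
        raise ConfigError("pi must be a 4-vector on the simplex")
    if gamma[0] != 0.0:
        raise ConfigError("gamma[0] must be 0 (null component)")
    if not (0.0 <= h2 < 1.0):
        raise ConfigError("h2 must lie in [0, 1)")

    rng = spawn_rng(seed, "effects")
    m = genotypes.n_snps
    labels = rng.choice(4, size=m, p=pi) + 1
    raw = np.where(labels > 1, rng.standard_normal(m) * np.sqrt(gamma[labels - 1]), 0.0)

    if h2 == 0.0:
        zero = np.zeros(m)
        return TrueModel(zero, labels, 0.0, np.zeros(genotypes.n_samples))

    z = genotypes.standardized()
    g_raw = z @ raw
    var_raw = float(np.var(g_raw))
    if var_raw == 0.0:
        raise ConfigError("all effects are null; cannot rescale to h2 > 0 "
                          "(increase the non-null mixture proportions)")
    scale = math.sqrt(h2 / var_raw)
    effects = raw * scale
    g = g_raw * scale
    return TrueModel(effects, labels, h2, g)


# ------------------------------------------------------------------------ case-control
def simulate_case_control(
    genotypes: GenotypeDataset,
    model: TrueModel,
    config: SimulationConfig,
    eligible_ids=None,
) -> pd.DataFrame:
    """Ascertain a case-control sample from the pool by rejection.

    Liability = genetic score + N(0, 1 - h2); an individual is a case when
    liability exceeds ``t = Phi^-1(1 - K)``.  Exactly ``n_cases`` cases and
    ``n_controls`` controls are sampled.  With ``confounding_delta > 0`` and
    two subpopulations, cases are oversampled from subpopulation 2 (target
    subpopulation-2 share ``0.5 + delta/2`` among cases, ``0.5 - delta/2``
    among controls), confounding case status with ancestry.

    Returns a phenotype table for the ascertained individuals with columns
    ``fid, iid, status, pop, true_genetic, true_liability``; subset the
    genotype pool with :meth:`GenotypeDataset.subset_samples` to match.
    ``eligible_ids`` restricts ascertainment to a subset of the pool, which
    lets one pool supply disjoint discovery/validation cohorts and a
    reference panel.
    """
    config.validate()
    if config.n_cases + config.n_controls > config.n_pool:
        raise ConfigError("n_cases + n_controls exceeds the simulated pool")
    rng = spawn_rng(config.seed, "case-control")
    h2 = model.sigma_g2
    t = float(norm.isf(config.prevalence_K))
    liab = model.genetic_scores + rng.standard_normal(genotypes.n_samples) * math.sqrt(1.0 - h2)
    model.liabilities = liab
    model.liability_threshold_t = t
    case = liab > t

    eligible = np.ones(genotypes.n_samples, dtype=bool)
    if eligible_ids is not None:
        eligible = np.isin(genotypes.sample_ids, np.asarray(list(eligible_ids)))

    pop = genotypes.samples.get("pop", pd.Series(np.ones(genotypes.n_samples, dtype=int))).to_numpy()

    def _draw(mask: np.ndarray, n_want: int, share2: float | None) -> np.ndarray:
        idx = np.flatnonzero(mask)
        if len(idx) < n_want:
            raise RuntimeError(
                f"pool contains only {len(idx)} individuals of the required status "
                f"({n_want} requested); increase n_pool or prevalence_K"
            )
        if share2 is None or config.n_subpops == 1:
            return np.sort(rng.choice(idx, size=n_want, replace=False))
        idx2 = idx[pop[idx] == 2]
        idx1 = idx[pop[idx] == 1]
        n2 = int(round(share2 * n_want))
        n2 = min(n2, len(idx2))
        n1 = n_want - n2
        if n1 > len(idx1):  # top up from subpopulation 2 if 1 is exhausted
            n2 += n1 - len(idx1)
            n1 = len(idx1)
            if n2 > len(idx2):
                raise RuntimeError("pool too small for the requested ascertainment")
        chosen = np.concatenate([rng.choice(idx1, size=n1, replace=False),
                                 rng.choice(idx2, size=n2, replace=False)])
        return np.sort(chosen)

    delta = config.confounding_delta
    share_cases = min(1.0, 0.5 + delta / 2.0) if delta > 0 else None
    share_ctrls = max(0.0, 0.5 - delta / 2.0) if delta > 0 else None
    case_idx = _draw(case & eligible, config.n_cases, share_cases)
    ctrl_idx = _draw(~case & eligible, config.n_controls, share_ctrls)
    sel = np.concatenate([case_idx, ctrl_idx])
    sel.sort()

    samples = genotypes.samples
    return make_phenotype_table(
        iids=samples["iid"].to_numpy()[sel],
        status=case[sel].astype(float),
        fids=samples["fid"].to_numpy()[sel],
        pop=pop[sel],
        true_genetic=model.genetic_scores[sel],
        true_liability=liab[sel],
    )


# ------------------------------------------------------------------------- covariates
#: clinical covariates generated for cases: (name, ordered levels, base
#: probabilities, direction of shift with increasing genetic score)
CLINICAL_COVARIATES = [
    ("onset_group", ["1-19", "20-39", ">40"], (0.45, 0.40, 0.15), -1.0),
    ("surgery", ["no", "yes"], (0.60, 0.40), +1.0),
    ("location", ["ileal", "colon", "ileocolonic"], (0.40, 0.30, 0.30), -1.0),
]


def attach_clinical_covariates(
    phenotypes: pd.DataFrame,
    model: TrueModel,
    effect_per_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Add categorical clinical covariates to case rows.

    Categories follow an ordered-logit construction: a latent
    ``direction * effect_per_sd * z + logistic noise`` (``z`` the
    standardized true genetic score among cases) is cut at the logistic
    quantiles of the base category probabilities, so ``effect_per_sd = 0``
    reproduces the base distribution exactly and larger values shift cases
    with high genetic scores toward earlier onset, surgery and ileal
    location.  Controls receive missing values.
    """
    rng = spawn_rng(seed, "covariates")
    out = phenotypes.copy()
    is_case = out["status"].to_numpy() == 1
    n_case = int(is_case.sum())
    g = out.loc[is_case, "true_genetic"].to_numpy()
    sd = g.std()
    z = (g - g.mean()) / sd if sd > 0 else np.zeros(n_case)

    for name, levels, base, direction in CLINICAL_COVARIATES:
        cum = np.cumsum(base)[:-1]
        cuts = np.log(cum / (1.0 - cum))  # logistic quantiles of the base CDF
        u = direction * effect_per_sd * z + rng.logistic(size=n_case)
        cat = np.searchsorted(cuts, u)
        col = np.full(len(out), None, dtype=object)
        col[np.flatnonzero(is_case)] = [levels[c] for c in cat]
        out[name] = col
    return out


# ------------------------------------------------------------------------ convenience
def simulate_dataset(
    config: SimulationConfig,
) -> tuple[GenotypeDataset, pd.DataFrame, TrueModel]:
    """Full chain: genotypes -> effects -> ascertained case-control cohort.

    Returns the ascertained genotype subset, the matching phenotype table
    and the generative truth (whose scores/liabilities cover the full pool).
    """
    pool = simulate_genotypes(config)
    model = simulate_effect_sizes(pool, config.pi, config.gamma, config.h2, config.seed)
    pheno = simulate_case_control(pool, model, config)
    cohort = pool.subset_samples(pheno["iid"])
    if config.batch_error_rate > 0:
        cohort = genotype_with_batch_errors(cohort, config.batch_error_rate, config.seed)
    return cohort, pheno, model


def genotype_with_batch_errors(
    dataset: GenotypeDataset, error_rate: float, seed: int
) -> GenotypeDataset:
    """A second rendering of the same samples with symmetric genotype errors.

    Each non-missing genotype is replaced, with probability ``error_rate``,
    by one of the two other dosage values (uniformly).  Emulates cross-array
    batch artifacts: two noisy genotypings of identical individuals.
    """
    if not (0.0 <= error_rate <= 1.0):
        raise ConfigError("error_rate must lie in [0, 1]")
    rng = spawn_rng(seed, "batch-errors")
    out = dataset.copy()
    dos = out.dosages
    flip = (rng.random(dos.shape) < error_rate) & ~np.isnan(dos)
    shift = rng.integers(1, 3, size=dos.shape)  # +1 or +2 mod 3 => a different value
    dos[flip] = (dos[flip] + shift[flip]) % 3
    return out


def replicate_snps_with_ld(
    dataset: GenotypeDataset, rho: float, seed: int
) -> GenotypeDataset:
    """Append one correlated duplicate of every SNP (block-copy LD).

    The duplicate keeps each genotype with probability ``rho`` and redraws
    it from Binomial(2, p) otherwise, giving pairwise dosage correlation
    close to ``rho`` (exactly a copy at ``rho = 1``).  Used to probe
    redundancy-invariance of the effective marker number.
    """
    if not (0.0 <= rho <= 1.0):
        raise ConfigError("rho must lie in [0, 1]")
    rng = spawn_rng(seed, "ld-copies")
    p = dataset.allele_freq()
    dup = dataset.dosages.copy()
    redraw = rng.random(dup.shape) >= rho
    fresh = rng.binomial(2, np.broadcast_to(p, dup.shape)).astype(float)
    dup[redraw] = fresh[redraw]
    dup[np.isnan(dataset.dosages)] = np.nan

    snps_dup = dataset.snps.copy()
    snps_dup["snp"] = snps_dup["snp"] + "_dup"
    snps_dup["pos"] = snps_dup["pos"] + 1
    return GenotypeDataset(
        np.hstack([dataset.dosages, dup]),
        dataset.samples.copy(),
        pd.concat([dataset.snps, snps_dup], ignore_index=True),
    )
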