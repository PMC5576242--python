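"""Cross-validated evaluation of genomic risk scores.

Everything downstream of model fitting: fold construction, the
Mann-Whitney AUC, decile odds-ratio risk stratification with
cross-validation intervals, calibration, association of scores with
clinical factors, and a scenario-benchmark runner that trains each method
with all selection and tuning inside the training fold, scores the left-out
fold, and optionally validates externally by averaging the K fold-models'
AUCs on an independent cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
import statsmodels.api as sm

from ._rng import spawn_seed
from .datasets import GenotypeDataset, align_phenotypes
from .liability import expected_decile_or  # noqa: F401  (re-exported results layer)
from .predictors import (
    fit_bayesr,
    fit_elastic_net,
    fit_gblup,
    fit_gprs,
    gblup_snp_effects,
    McmcSettings,
    score,
    single_snp_assoc,
)
from .structure import compute_grm

__all__ = [
    "FoldPlan",
    "make_folds",
    "auc",
    "relative_auc_gain",
    "decile_or",
    "aggregate_decile_tables",
    "calibration_slope",
    "score_factor_association",
    "Scenario",
    "EvaluationReport",
    "run_benchmark",
    "expected_decile_or",
]

log = logging.getLogger(__name__)


# -------------------------------------------------------------------------- folds
@dataclass
class FoldPlan:
    """Disjoint, exhaustive assignment of samples to K folds."""

    K: int
    labels: pd.Series  # fold index per sample iid
    stratified: bool
    seed: int

    def test_ids(self, k: int) -> np.ndarray:
        return self.labels.index[self.labels.to_numpy() == k].to_numpy()

    def train_ids(self, k: int) -> np.ndarray:
        return self.labels.index[self.labels.to_numpy() != k].to_numpy()


def make_folds(
    phenotypes: pd.DataFrame, K: int = 5, stratified: bool = True, seed: int = 0
) -> FoldPlan:
    """Random K-fold partition, by default stratified on case status."""
    n = len(phenotypes)
    if n < K:
        raise ValueError(f"cannot make {K} folds from {n} samples")
    rng = np.random.default_rng(spawn_seed(seed, "folds"))
    iids = phenotypes["iid"].to_numpy()
    labels = np.empty(n, dtype=int)
    if stratified:
        status = phenotypes["status"].to_numpy()
        for value in np.unique(status):
            idx = np.flatnonzero(status == value)
            idx = rng.permutation(idx)
            labels[idx] = np.arange(len(idx)) % K
    else:
        labels[rng.permutation(n)] = np.arange(n) % K
    return FoldPlan(K=K, labels=pd.Series(labels, index=pd.Index(iids, name="iid")),
                    stratified=stratified, seed=seed)


# ---------------------------------------------------------------------------- AUC
def auc(scores, labels) -> float:
    """Area under the ROC curve, Mann-Whitney estimator.

    The fraction of (case, control) pairs in which the case outscores the
    control, ties counted half; identical to the trapezoidal ROC area.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    n_case = int((y == 1).sum())
    n_ctrl = int((y == 0).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("AUC needs at least one case and one control")
    r = rankdata(s)
    u = r[y == 1].sum() - n_case * (n_case + 1) / 2.0
    return float(u / (n_case * n_ctrl))


def relative_auc_gain(auc1: float, auc0: float) -> float:
    """Percent gain on the AUC scale, ``100 * (auc1/auc0 - 1)``, one decimal."""
    if auc0 <= 0:
        raise ValueError("reference AUC must be positive")
    return round(100.0 * (auc1 / auc0 - 1.0), 1)


# ------------------------------------------------------------------------- deciles
def decile_or(scores, labels, n_groups: int = 10, sample_ids=None) -> pd.DataFrame:
    """Odds ratio of case status per risk-score decile, lowest decile = 1.

    Samples are ranked by ascending score (ties broken by stable input
    order) and cut into ``n_groups`` near-equal groups, remainders going to
    the top groups.  A decile with zero controls gets an infinite, flagged
    OR rather than an error.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    n = len(s)
    if n < 2 * n_groups:
        raise ValueError(f"need at least {2 * n_groups} samples for {n_groups} groups")
    order = np.argsort(s, kind="stable")
    base = n // n_groups
    extra = n % n_groups
    sizes = np.full(n_groups, base)
    sizes[n_groups - extra:] += 1  # remainders to the top deciles
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    rows = []
    for d in range(n_groups):
        grp = order[bounds[d]:bounds[d + 1]]
        rows.append((d + 1, int((y[grp] == 1).sum()), int((y[grp] == 0).sum())))
    tab = pd.DataFrame(rows, columns=["decile", "n_cases", "n_controls"])
    c1, k1 = tab.loc[0, "n_cases"], tab.loc[0, "n_controls"]
    if c1 == 0:
        ref_odds = np.nan
    else:
        ref_odds = c1 / k1 if k1 > 0 else np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = np.where(tab["n_controls"] > 0,
                        tab["n_cases"] / np.maximum(tab["n_controls"], 1e-300), np.inf)
    tab["odds_ratio"] = odds / ref_odds
    tab.loc[0, "odds_ratio"] = 1.0
    tab["undefined"] = ~np.isfinite(tab["odds_ratio"])
    return tab


def aggregate_decile_tables(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean decile ORs with 95% intervals across cross-validation models.

    Interval convention: ``mean +/- 1.96 * SD / sqrt(K)`` over the K
    fold-models, computed only over folds where the OR is defined.
    """
    ors = np.stack([t["odds_ratio"].to_numpy(dtype=float) for t in tables])
    finite = np.isfinite(ors)
    masked = np.where(finite, ors, np.nan)
    k_eff = finite.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(masked, axis=0)
        sd = np.zeros_like(mean)
        enough = k_eff > 1
        if enough.any():
            sd[enough] = np.nanstd(masked[:, enough], axis=0, ddof=1)
    half = 1.96 * sd / np.sqrt(np.maximum(k_eff, 1))
    out = pd.DataFrame(
        {
            "decile": tables[0]["decile"],
            "odds_ratio": mean,
            "ci_low": mean - half,
            "ci_high": mean + half,
            "n_models": k_eff,
        }
    )
    return out


# ---------------------------------------------------------------- calibration etc.
def calibration_slope(scores, y) -> float:
    """Slope of observed phenotype regressed on predicted score (1 = calibrated)."""
    s = np.asarray(scores, dtype=float)
    yy = np.asarray(y, dtype=float)
    if len(s) < 3:
        raise ValueError("need at least three samples")
    vs = np.var(s)
    if vs == 0:
        raise ValueError("constant scores; calibration slope undefined")
    return float(np.cov(s, yy, ddof=1)[0, 1] / np.var(s, ddof=1))


def score_factor_association(scores, factor) -> dict:
    """Regress the risk score on a categorical clinical factor.

    Ordinary least squares of the (standardized) score on factor dummies;
    reports the overall F-test p-value and per-level mean scores.
    """
    s = np.asarray(scores, dtype=float)
    f = pd.Series(list(factor)).astype("category")
    mask = f.notna().to_numpy() & np.isfinite(s)
    s = s[mask]
    f = f[mask].cat.remove_unused_categories().reset_index(drop=True)
    levels = list(f.cat.categories)
    if len(levels) < 2:
        raise ValueError("factor must have at least two non-empty levels")
    sd = s.std()
    z = (s - s.mean()) / sd if sd > 0 else s - s.mean()
    dummies = pd.get_dummies(f, drop_first=True, dtype=float)
    x = sm.add_constant(dummies.to_numpy())
    fit = sm.OLS(z, x).fit()
    return {
        "p_value": float(fit.f_pvalue),
        "level_means": {lv: float(z[(f == lv).to_numpy()].mean()) for lv in levels},
        "n_levels": len(levels),
        "nobs": int(fit.nobs),
    }


# ------------------------------------------------------------------------ benchmark
@dataclass
class Scenario:
    """One cell of the benchmark grid: which samples, SNPs and phenotype scale."""

    name: str
    sample_ids: np.ndarray | None = None   # None = all
    snp_ids: np.ndarray | None = None      # None = all
    pheno_scale: str = "status"            # 'status' or 'adjusted'


@dataclass
class EvaluationReport:
    """Per-fold AUCs and risk stratification for one scenario x method."""

    scenario: str
    method: str
    pheno_scale: str
    fold_aucs: list[float]
    mean_auc: float
    decile_table: pd.DataFrame | None = None
    calibration: float | None = None
    external_aucs: list[float] | None = None
    mean_external_auc: float | None = None
    metadata: dict = field(default_factory=dict)


def _fit_and_score(
    method: str,
    train: GenotypeDataset,
    y_train: np.ndarray,
    test: GenotypeDataset,
    scale: str,
    seed: int,
    params: dict,
):
    """Train one method on the training fold; return (test scores, effect set)."""
    scale_for_assoc = "status" if scale == "status" else "adjusted"
    if method == "gprs":
        assoc = single_snp_assoc(train, y_train, scale=scale_for_assoc)
        eff = fit_gprs(assoc, params.get("p_cutoff", 1.0))
        return score(eff, test), eff
    if method == "en":
        assoc = single_snp_assoc(train, y_train, scale=scale_for_assoc)
        eff = fit_elastic_net(
            train, y_train, assoc,
            top_m=params.get("top_m", 8000),
            inner_folds=params.get("inner_folds", 10),
            scale=scale_for_assoc,
            l1_ratio=params.get("l1_ratio", 0.5),
            seed=seed,
        )
        return score(eff, test), eff
    if method == "gblup":
        # GRM over train + test, standardized by training-fold frequencies
        combined = GenotypeDataset(
            np.vstack([train.dosages, test.dosages]),
            pd.concat([train.samples, test.samples], ignore_index=True),
            train.snps.copy(),
        )
        grm = compute_grm(combined, freqs=train.allele_freq())
        y_series = pd.Series(y_train, index=pd.Index(train.sample_ids, name="iid"))
        fit, scores = fit_gblup(grm, y_series, test_ids=test.sample_ids)
        eff = gblup_snp_effects(fit, train)
        return scores, eff
    if method == "bayesr":
        mcmc = McmcSettings(
            iterations=params.get("iterations", 10_000),
            burn_in=params.get("burn_in", 5_000),
            thin=params.get("thin", 10),
            seed=seed,
        )
        _, eff = fit_bayesr(train, y_train, mcmc)
        return score(eff, test), eff
    raise ValueError(f"unknown method '{method}'")


def run_benchmark(
    dataset: GenotypeDataset,
    phenotypes: pd.DataFrame,
    methods,
    scenarios=None,
    n_folds: int = 5,
    seed: int = 0,
    external: tuple[GenotypeDataset, pd.DataFrame] | None = None,
    method_params: dict | None = None,
) -> list[EvaluationReport]:
    """Cross-validated benchmark of methods over sample/SNP scenarios.

    For each scenario x method, every fold trains the model on the training
    samples only (association scans, SNP selection and penalty tuning
    included), scores the left-out fold, and records the AUC against case
    status.  With ``external`` supplied, each of the K fold-models also
    scores the external cohort and the mean of the K external AUCs is
    reported — the fold-model-averaging convention for independent
    validation.
    """
    method_params = method_params or {}
    scenarios = scenarios or [Scenario(name="all")]
    reports: list[EvaluationReport] = []

    for sc in scenarios:
        data = dataset
        if sc.snp_ids is not None:
            data = data.subset_snps(sc.snp_ids)
        pheno = phenotypes
        if sc.sample_ids is not None:
            data = data.subset_samples(sc.sample_ids)
            pheno = pheno[pheno["iid"].isin(sc.sample_ids)]
        pheno = align_phenotypes(data, pheno)
        if sc.pheno_scale == "adjusted" and "adjusted" not in pheno.columns:
            raise ValueError(f"scenario '{sc.name}' needs an 'adjusted' phenotype column")
        y_all = pheno[sc.pheno_scale if sc.pheno_scale == "adjusted" else "status"]
        y_all = y_all.to_numpy(dtype=float)
        status_all = pheno["status"].to_numpy(dtype=float)

        plan = make_folds(pheno, K=n_folds, stratified=True, seed=seed)
        pos = {iid: i for i, iid in enumerate(pheno["iid"])}

        for method in methods:
            params = dict(method_params.get(method, {}))
            fold_aucs, ext_aucs, tables, slopes = [], [], [], []
            for k in range(n_folds):
                tr_ids, te_ids = plan.train_ids(k), plan.test_ids(k)
                tr_idx = np.array([pos[i] for i in tr_ids])
                te_idx = np.array([pos[i] for i in te_ids])
                train, test = data.subset_samples(tr_ids), data.subset_samples(te_ids)
                fold_seed = spawn_seed(seed, "benchmark", sc.name, method, k)
                scores, eff = _fit_and_score(
                    method, train, y_all[tr_idx], test, sc.pheno_scale, fold_seed, params
                )
                fold_aucs.append(auc(scores.to_numpy(), status_all[te_idx]))
                if len(te_idx) >= 20:
                    tables.append(decile_or(scores.to_numpy(), status_all[te_idx]))
                s_arr = scores.to_numpy()
                slopes.append(
                    calibration_slope(s_arr, y_all[te_idx]) if np.var(s_arr) > 0 else np.nan
                )
                if external is not None:
                    ext_data, ext_pheno = external
                    ext_pheno = align_phenotypes(ext_data, ext_pheno)
                    ext_scores = score(eff, ext_data)
                    ext_aucs.append(
                        auc(ext_scores.to_numpy(), ext_pheno["status"].to_numpy(dtype=float))
                    )
            reports.append(
                EvaluationReport(
                    scenario=sc.name,
                    method=method,
                    pheno_scale=sc.pheno_scale,
                    fold_aucs=fold_aucs,
                    mean_auc=float(np.mean(fold_aucs)),
                    decile_table=aggregate_decile_tables(tables) if tables else None,
                    calibration=float(np.nanmean(slopes)) if not np.all(np.isnan(slopes)) else None,
                    external_aucs=ext_aucs or None,
                    mean_external_auc=float(np.mean(ext_aucs)) if ext_aucs else None,
                    metadata={"n_samples": data.n_samples, "n_snps": data.n_snps,
                              "seed": seed, "params": params},
                )
            )
            log.info("scenario=%s method=%s mean AUC=%.3f", sc.name, method,
                     reports[-1].mean_auc)
    return reports
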