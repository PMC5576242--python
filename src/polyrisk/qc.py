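"""SNP- and sample-level quality control.

Implements the filters applied to case-control array data before risk
modelling: imputation INFO score, minor allele frequency, an exact test of
Hardy-Weinberg proportions, removal of strand-ambiguous (palindromic A/T and
G/C) SNPs, per-sample missingness, and random-member pruning of related
pairs above a genomic-relationship cutoff.

Filter order is fixed (INFO -> MAF -> HWE -> palindromic) and reported,
since per-filter removal counts depend on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from ._rng import spawn_rng
from .datasets import GenotypeDataset

__all__ = [
    "QcThresholds",
    "QcReport",
    "hwe_exact_p",
    "apply_snp_filters",
    "apply_sample_filters",
    "prune_related",
]

log = logging.getLogger(__name__)


@dataclass
class QcThresholds:
    """Cutoffs for the SNP and sample filters.

    Defaults follow common case-control array practice: INFO > 0.6,
    MAF >= 0.01 (use 0.001 for dense fine-mapping arrays), HWE exact
    p >= 1e-6, at most 2% missing genotypes per sample, relatedness
    cutoff 0.2, and palindromic SNPs dropped.
    """

    min_info: float = 0.6
    min_maf: float = 0.01
    hwe_p_floor: float = 1e-6
    max_sample_missing: float = 0.02
    relatedness_cutoff: float = 0.2
    drop_palindromic: bool = True

    def validate(self) -> None:
        for name in ("min_info", "min_maf", "hwe_p_floor", "max_sample_missing"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1), got {v}")
        if not (0.0 < self.relatedness_cutoff):
            raise ValueError("relatedness_cutoff must be positive")


@dataclass
class QcReport:
    """Per-filter removal counts plus surviving id lists."""

    n_input_snps: int = 0
    n_input_samples: int = 0
    removed: dict = field(default_factory=dict)  # filter name -> count
    surviving_snps: list = field(default_factory=list)
    surviving_samples: list = field(default_factory=list)

    def to_text(self) -> str:
        lines = ["filter\tremoved"]
        lines += [f"{k}\t{v}" for k, v in self.removed.items()]
        lines.append(f"surviving_snps\t{len(self.surviving_snps)}")
        lines.append(f"surviving_samples\t{len(self.surviving_samples)}")
        return "\n".join(lines) + "\n"


# ----------------------------------------------------------------------------- HWE
def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided test of Hardy-Weinberg proportions.

    Conditional on the observed allele counts, the number of heterozygotes
    follows a known exact distribution; the p-value sums the probabilities
    of all heterozygote counts at most as probable as the observed one.
    No mid-p correction is applied.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_aa + n_Aa  # minor-allele count (relabel below if needed)
    n_A = 2 * n_AA + n_Aa
    rare = min(n_A, n_a)
    # heterozygote count shares parity with the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    n_rr = (rare - hets) // 2
    n_cc = n - hets - n_rr
    # log P(het = h | allele counts) up to a constant:
    #   n! / (n_rr! h! n_cc!) * 2^h  (the allele-count term is constant)
    logp = hets * np.log(2.0) - gammaln(n_rr + 1) - gammaln(hets + 1) - gammaln(n_cc + 1)
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[np.flatnonzero(hets == n_Aa)[0]]
    p = float(prob[prob <= obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def _hwe_p_per_snp(dataset: GenotypeDataset) -> np.ndarray:
    out = np.ones(dataset.n_snps)
    for j in range(dataset.n_snps):
        n2, n1, n0 = dataset.genotype_counts(j)
        if n2 + n1 + n0 > 0:
            out[j] = hwe_exact_p(n2, n1, n0)
    return out


# -------------------------------------------------------------------------- filters
def apply_snp_filters(
    dataset: GenotypeDataset, thresholds: QcThresholds
) -> tuple[GenotypeDataset, QcReport]:
    """Remove SNPs failing INFO, MAF, HWE or palindromic-allele filters.

    Filters apply in the fixed order INFO -> MAF -> HWE -> palindromic; MAF
    and HWE are computed from the non-missing genotypes of the current
    sample set.  A dataset without an ``info`` column skips the INFO filter
    with a logged warning.
    """
    thresholds.validate()
    report = QcReport(n_input_snps=dataset.n_snps, n_input_samples=dataset.n_samples)
    current = dataset

    def _drop(keep: np.ndarray, name: str) -> None:
        nonlocal current
        report.removed[name] = int((~keep).sum())
        current = current.subset_snps(keep)

    if thresholds.min_info > 0:
        if "info" in current.snps.columns and current.snps["info"].notna().all():
            _drop(current.snps["info"].to_numpy() >= thresholds.min_info, "info")
        else:
            log.warning("no INFO metadata; INFO filter skipped")
            report.removed["info"] = 0
    else:
        report.removed["info"] = 0

    maf = current.minor_allele_freq()
    _drop(~(maf < thresholds.min_maf), "maf")

    if thresholds.hwe_p_floor > 0:
        _drop(~(_hwe_p_per_snp(current) < thresholds.hwe_p_floor), "hwe")
    else:
        report.removed["hwe"] = 0

    if thresholds.drop_palindromic:
        _drop(~current.is_palindromic(), "palindromic")
    else:
        report.removed["palindromic"] = 0

    if current.n_snps == 0:
        raise ValueError("all SNPs removed by QC filters")
    report.surviving_snps = list(current.snp_ids)
    report.surviving_samples = list(current.sample_ids)
    return current, report


def apply_sample_filters(
    dataset: GenotypeDataset, thresholds: QcThresholds
) -> tuple[GenotypeDataset, QcReport]:
    """Remove samples with missing-genotype fraction above the cutoff."""
    thresholds.validate()
    report = QcReport(n_input_snps=dataset.n_snps, n_input_samples=dataset.n_samples)
    keep = ~(dataset.missing_rate_samples() > thresholds.max_sample_missing)
    report.removed["sample_missing"] = int((~keep).sum())
    out = dataset.subset_samples(dataset.sample_ids[keep])
    if out.n_samples == 0:
        raise ValueError("all samples removed by missingness filter")
    report.surviving_snps = list(out.snp_ids)
    report.surviving_samples = list(out.sample_ids)
    return out, report


# ------------------------------------------------------------------------ relatedness
def prune_related(grm, cutoff: float, seed: int) -> list:
    """Prune one random member of every related pair above ``cutoff``.

    Pairs with off-diagonal relationship > cutoff are visited in ascending
    (i, j) index order; for each pair whose members both survive so far, one
    member is removed uniformly at random (seeded).  The returned sample id
    list contains no pair above the cutoff.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    values = np.asarray(grm.values, dtype=float)
    ids = list(grm.sample_ids)
    n = len(ids)
    rng = spawn_rng(seed, "prune-related")
    alive = np.ones(n, dtype=bool)
    ii, jj = np.triu_indices(n, k=1)
    hits = values[ii, jj] > cutoff
    for i, j in zip(ii[hits], jj[hits]):
        if alive[i] and alive[j]:
            alive[j if rng.random() < 0.5 else i] = False
    return [ids[k] for k in range(n) if alive[k]]
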