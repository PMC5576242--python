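"""Per-SNP effect sets and the common risk scorer.

Every predictor (GPRS, elastic net, GBLUP via its SNP-BLUP equivalent,
BayesR posterior means) reduces to a :class:`SnpEffectSet`: per-SNP allele
effects on the dosage scale plus an intercept.  :func:`score` applies such
a set to any genotype dataset, reconciling allele orientation and imputing
missing dosages from the training-fold allele frequencies, so all methods
share one scoring pathway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..datasets import GenotypeDataset

__all__ = ["SnpEffectSet", "score"]

log = logging.getLogger(__name__)


@dataclass
class SnpEffectSet:
    """Trained per-SNP allele effects.

    ``table`` columns: ``snp``, ``effect_allele``, ``other_allele``,
    ``effect`` (per copy of the effect allele, dosage scale), ``freq``
    (training-fold frequency of the effect allele, used to impute missing
    dosages).  ``metadata`` records tuning choices (p-value cutoff, penalty,
    MCMC settings, ...).
    """

    method: str
    table: pd.DataFrame
    intercept: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"snp", "effect_allele", "other_allele", "effect", "freq"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"effect table lacks columns: {sorted(missing)}")
        if not np.all(np.isfinite(self.table["effect"].to_numpy(dtype=float))):
            raise ValueError("effects must be finite")

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @classmethod
    def from_training(
        cls,
        method: str,
        dataset: GenotypeDataset,
        effects: np.ndarray,
        intercept: float = 0.0,
        metadata: dict | None = None,
    ) -> "SnpEffectSet":
        """Build an effect set aligned to a training dataset's SNP metadata."""
        table = pd.DataFrame(
            {
                "snp": dataset.snp_ids,
                "effect_allele": dataset.snps["a1"].to_numpy(),
                "other_allele": dataset.snps["a2"].to_numpy(),
                "effect": np.asarray(effects, dtype=float),
                "freq": dataset.allele_freq(),
            }
        )
        return cls(method=method, table=table, intercept=intercept, metadata=dict(metadata or {}))


def score(effects: SnpEffectSet, dataset: GenotypeDataset) -> pd.Series:
    """Apply an effect set to a genotype dataset.

    ``score_j = intercept + sum_i beta_i * dosage_ij`` with the dosage of
    the effect allele; SNPs present with swapped A1/A2 labels are counted
    as ``2 - x``.  SNPs absent from the dataset or with irreconcilable
    alleles are dropped (counted in the log); missing dosages are imputed
    to ``2 * freq`` from the training fold.  Fails if fewer than half the
    effect SNPs are scorable.
    """
    tab = effects.table
    pos = pd.Index(dataset.snp_ids).get_indexer(tab["snp"])
    a1 = dataset.snps["a1"].to_numpy()
    a2 = dataset.snps["a2"].to_numpy()

    usable = pos >= 0
    flip = np.zeros(len(tab), dtype=bool)
    ea = tab["effect_allele"].to_numpy()
    oa = tab["other_allele"].to_numpy()
    hit = np.flatnonzero(usable)
    same = a1[pos[hit]] == ea[hit]
    swapped = (a1[pos[hit]] == oa[hit]) & (a2[pos[hit]] == ea[hit])
    ok_alleles = (same & (a2[pos[hit]] == oa[hit])) | swapped
    usable[hit[~ok_alleles]] = False
    flip[hit[swapped & ok_alleles]] = True

    n_drop = int((~usable).sum())
    if usable.sum() < 0.5 * len(tab):
        raise ValueError(
            f"only {int(usable.sum())} of {len(tab)} effect SNPs scorable in the dataset"
        )
    if n_drop:
        log.info("score: dropped %d of %d effect SNPs (absent or allele mismatch)",
                 n_drop, len(tab))

    idx = np.flatnonzero(usable)
    x = dataset.dosages[:, pos[idx]].copy()
    x[:, flip[idx]] = 2.0 - x[:, flip[idx]]
    fill = 2.0 * tab["freq"].to_numpy()[idx]
    nanmask = np.isnan(x)
    if nanmask.any():
        x[nanmask] = np.broadcast_to(fill, x.shape)[nanmask]
    beta = tab["effect"].to_numpy()[idx]
    values = effects.intercept + x @ beta
    return pd.Series(values, index=pd.Index(dataset.sample_ids, name="iid"), name="score")
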