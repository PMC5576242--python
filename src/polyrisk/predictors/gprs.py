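"""Genetic profile risk scores from single-marker effects.

The simplest whole-genome predictor: per-SNP effects estimated one marker
at a time (log-odds ratios for case-control status, linear betas for an
adjusted phenotype), optionally thresholded on the association p-value.
Including all SNPs (``p_cutoff = 1``) is the customary default; a cutoff
grid explores whether marker selection helps.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .effects import SnpEffectSet

__all__ = ["fit_gprs", "fit_gprs_grid"]


def fit_gprs(assoc: pd.DataFrame, p_cutoff: float = 1.0) -> SnpEffectSet:
    """Threshold single-marker effects into a risk score.

    SNPs with a finite effect and ``p < p_cutoff`` keep their estimated
    beta; all others get effect zero (``p_cutoff >= 1`` keeps every finite
    effect).  The association scan must come from the training fold only.
    """
    if p_cutoff <= 0:
        raise ValueError("p_cutoff must be positive (0 selects no SNPs)")
    finite = np.isfinite(assoc["beta"].to_numpy()) & np.isfinite(assoc["p"].to_numpy())
    selected = finite if p_cutoff >= 1.0 else finite & (assoc["p"].to_numpy() < p_cutoff)
    if not selected.any():
        raise ValueError(f"no SNP passes p < {p_cutoff}")
    table = pd.DataFrame(
        {
            "snp": assoc["snp"].to_numpy(),
            "effect_allele": assoc["a1"].to_numpy(),
            "other_allele": assoc["a2"].to_numpy(),
            "effect": np.where(selected, np.nan_to_num(assoc["beta"].to_numpy()), 0.0),
            "freq": assoc["freq"].to_numpy(),
        }
    )
    return SnpEffectSet(
        method="GPRS",
        table=table,
        intercept=0.0,
        metadata={"p_cutoff": p_cutoff, "n_selected": int(selected.sum())},
    )


def fit_gprs_grid(assoc: pd.DataFrame, p_cutoffs) -> dict[float, SnpEffectSet]:
    """One effect set per p-value cutoff (for cutoff-tuning curves)."""
    return {c: fit_gprs(assoc, c) for c in p_cutoffs}
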