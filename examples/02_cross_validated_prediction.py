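"""Benchmark the four whole-genome predictors by 5-fold cross-validation.

Trains GPRS (single-marker log-odds scores), elastic net with association
pre-selection, GBLUP (REML mixed model on the GRM) and BayesR (mixture-
of-normals Gibbs sampler) on a sparse-architecture cohort, with all SNP
selection and tuning inside each training fold, and reports the mean test
AUC and decile odds-ratio stratification of the best method.

Runtime: a couple of minutes on one CPU (BayesR chain shortened for the
example; lengthen `iterations` for production fits).
"""

import polyrisk as pr

cfg = pr.SimulationConfig(
    n_pool=9000, m=1000, n_cases=900, n_controls=900,
    h2=0.5, prevalence_K=0.2, pi=(0.95, 0.02, 0.02, 0.01), seed=2,
)
dataset, pheno, _ = pr.simulate_dataset(cfg)

reports = pr.run_benchmark(
    dataset, pheno,
    methods=["gprs", "en", "gblup", "bayesr"],
    n_folds=5, seed=2,
    method_params={
        "en": {"top_m": 200, "inner_folds": 10},
        "bayesr": {"iterations": 1500, "burn_in": 750, "thin": 5},
    },
)

print("method   mean CV AUC   per-fold")
best = None
for r in reports:
    folds = " ".join(f"{a:.3f}" for a in r.fold_aucs)
    print(f"{r.method:8s} {r.mean_auc:10.3f}   {folds}")
    if best is None or r.mean_auc > best.mean_auc:
        best = r

print(f"\nbest method: {best.method}")
print("decile odds ratios vs lowest decile (mean over CV folds, 95% CI):")
print(best.decile_table.round(2).to_string(index=False))
print("\nAn increasing OR gradient across deciles is the clinical-utility "
      "signal: individuals in the top score decile are many times more "
      "likely to be cases than those in the bottom decile.")
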