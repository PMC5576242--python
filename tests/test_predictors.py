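"""The four predictors: oracle equivalences, selection rules, scoring."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import logit

import polyrisk as pr
from polyrisk.predictors import conditional_effect_moments


# ----------------------------------------------------------------- association
class TestSingleSnpAssoc:
    def test_logistic_matches_statsmodels(self, sparse_cohort):
        _, dataset, pheno, _ = sparse_cohort
        y = pheno["status"].to_numpy(float)
        assoc = pr.single_snp_assoc(dataset, y, scale="status")
        for j in [0, 17, 101, 250]:
            x = sm.add_constant(dataset.dosages[:, j])
            fit = sm.Logit(y, x).fit(disp=0)
            assert assoc["beta"].iat[j] == pytest.approx(fit.params[1], rel=1e-6)
            assert assoc["se"].iat[j] == pytest.approx(fit.bse[1], rel=1e-6)

    def test_linear_matches_statsmodels(self, sparse_cohort):
        _, dataset, pheno, _ = sparse_cohort
        y = pheno["true_liability"].to_numpy(float)
        assoc = pr.single_snp_assoc(dataset, y, scale="adjusted")
        for j in [3, 88]:
            x = sm.add_constant(dataset.dosages[:, j])
            fit = sm.OLS(y, x).fit()
            assert assoc["beta"].iat[j] == pytest.approx(fit.params[1], rel=1e-8)
            assert assoc["p"].iat[j] == pytest.approx(fit.pvalues[1], rel=1e-6)

    def test_null_type_one_error(self, null_cohort):
        _, dataset, pheno, _ = null_cohort
        assoc = pr.single_snp_assoc(dataset, pheno["status"].to_numpy(float))
        rate = float((assoc["p"] < 0.05).mean())
        half = 2.576 * np.sqrt(0.05 * 0.95 / dataset.n_snps)
        assert abs(rate - 0.05) < half + 0.01

    def test_constant_dosage_excluded(self):
        dos = np.column_stack([np.ones(60) * 2, np.random.default_rng(0).binomial(2, 0.4, 60)])
        samples = pd.DataFrame({"fid": [f"f{i}" for i in range(60)],
                                "iid": [f"i{i}" for i in range(60)]})
        snps = pd.DataFrame({"snp": ["s0", "s1"], "chrom": 1, "pos": [1, 2],
                             "a1": "A", "a2": "C"})
        ds = pr.GenotypeDataset(dos, samples, snps)
        y = (np.arange(60) % 2).astype(float)
        assoc = pr.single_snp_assoc(ds, y)
        assert np.isnan(assoc["beta"].iat[0])
        assert np.isfinite(assoc["beta"].iat[1])

    def test_large_single_effect_attains_min_p(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n, m = 1000, 60
            dos = rng.binomial(2, 0.3, size=(n, m)).astype(float)
            liab = 1.2 * (dos[:, 7] - 0.6) + rng.standard_normal(n)
            y = (liab > np.quantile(liab, 0.5)).astype(float)
            samples = pd.DataFrame({"fid": [f"f{i}" for i in range(n)],
                                    "iid": [f"i{i}" for i in range(n)]})
            snps = pd.DataFrame({"snp": [f"s{j}" for j in range(m)], "chrom": 1,
                                 "pos": np.arange(m) + 1, "a1": "A", "a2": "C"})
            assoc = pr.single_snp_assoc(pr.GenotypeDataset(dos, samples, snps), y)
            hits += int(assoc["p"].idxmin() == 7)
        assert hits >= 9

    def test_degenerate_phenotype_errors(self, sparse_cohort):
        _, dataset, _, _ = sparse_cohort
        with pytest.raises(ValueError):
            pr.single_snp_assoc(dataset, np.ones(dataset.n_samples))


# ------------------------------------------------------------------------ GPRS
class TestGprs:
    @staticmethod
    def _assoc(pvals):
        m = len(pvals)
        return pd.DataFrame({
            "snp": [f"s{j}" for j in range(m)], "a1": "A", "a2": "C",
            "freq": 0.3, "beta": np.linspace(0.1, 1.0, m), "se": 0.1,
            "p": np.asarray(pvals, float),
        })

    def test_cutoff_between_order_statistics(self):
        pvals = [0.001, 0.002, 0.003, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]
        eff = pr.fit_gprs(self._assoc(pvals), p_cutoff=0.1)
        assert int((eff.table["effect"] != 0).sum()) == 3

    def test_cutoff_one_keeps_all_finite(self):
        eff = pr.fit_gprs(self._assoc([0.5] * 6 + [1.0] * 4), p_cutoff=1.0)
        assert int((eff.table["effect"] != 0).sum()) == 10

    def test_cutoff_zero_errors(self):
        with pytest.raises(ValueError):
            pr.fit_gprs(self._assoc([0.5]), p_cutoff=0.0)

    def test_grid_returns_one_set_per_cutoff(self):
        grid = pr.fit_gprs_grid(self._assoc([0.001, 0.05, 0.5]), [0.01, 0.1, 1.0])
        assert [int((e.table["effect"] != 0).sum()) for e in grid.values()] == [1, 2, 3]


# ----------------------------------------------------------------------- GBLUP
class TestGblup:
    def test_zero_heritability_gives_constant_predictions(self, sparse_cohort):
        _, dataset, pheno, _ = sparse_cohort
        grm = pr.compute_grm(dataset)
        y = pd.Series(pheno["status"].to_numpy(float),
                      index=pd.Index(dataset.sample_ids, name="iid"))
        fit, scores = pr.fit_gblup(grm, y, dataset.sample_ids[:50], h2_fixed=0.0)
        assert fit.at_boundary
        np.testing.assert_allclose(scores.to_numpy(), fit.mu, atol=1e-12)

    def test_equivalent_to_ridge_snp_blup(self):
        # closed-form identity: GBLUP == ridge on standardized genotypes with
        # penalty lambda = m * sigma_e2 / sigma_g2
        cfg = pr.SimulationConfig(n_pool=1500, m=50, n_cases=100, n_controls=100,
                                  h2=0.4, prevalence_K=0.2, pi=(0.5, 0.2, 0.2, 0.1),
                                  seed=55)
        dataset, pheno, _ = pr.simulate_dataset(cfg)
        y = pheno["status"].to_numpy(float)
        train_ids, test_ids = dataset.sample_ids[:150], dataset.sample_ids[150:]
        train = dataset.subset_samples(train_ids)
        p = train.allele_freq()
        grm = pr.compute_grm(dataset, freqs=p)
        yser = pd.Series(y, index=pd.Index(dataset.sample_ids, name="iid"))
        fit, scores = pr.fit_gblup(grm, yser, test_ids)

        z_t = train.standardized(p)
        z_s = dataset.subset_samples(test_ids).standardized(p)
        lam = z_t.shape[1] * fit.sigma_e2 / fit.sigma_g2
        b = np.linalg.solve(z_t.T @ z_t + lam * np.eye(z_t.shape[1]),
                            z_t.T @ (y[:150] - fit.mu))
        ridge = fit.mu + z_s @ b
        rel = np.abs(ridge - scores.to_numpy()) / (np.abs(ridge).max())
        assert rel.max() < 1e-6

    def test_snp_effect_pathway_matches_grm_pathway(self, sparse_cohort):
        _, dataset, pheno, _ = sparse_cohort
        y = pheno["status"].to_numpy(float)
        train_ids, test_ids = dataset.sample_ids[:600], dataset.sample_ids[600:]
        train = dataset.subset_samples(train_ids)
        grm = pr.compute_grm(dataset, freqs=train.allele_freq())
        yser = pd.Series(y, index=pd.Index(dataset.sample_ids, name="iid"))
        fit, scores = pr.fit_gblup(grm, yser, test_ids)
        eff = pr.gblup_snp_effects(fit, train)
        via_effects = pr.score(eff, dataset.subset_samples(test_ids))
        np.testing.assert_allclose(via_effects.to_numpy(), scores.to_numpy(), atol=1e-8)


# ----------------------------------------------------------------- elastic net
class TestElasticNet:
    def test_full_shrinkage_limit(self, sparse_cohort):
        _, dataset, pheno, _ = sparse_cohort
        y = pheno["status"].to_numpy(float)
        assoc = pr.single_snp_assoc(dataset, y)
        eff = pr.fit_elastic_net(dataset, y, assoc, top_m=50,
                                 lambda_override=np.inf)
        assert np.all(eff.table["effect"] == 0.0)
        assert eff.intercept == pytest.approx(float(logit(y.mean())), abs=1e-10)

    def test_candidate_set_is_smallest_p(self):
        assoc = pd.DataFrame({
            "snp": [f"s{j}" for j in range(10)], "a1": "A", "a2": "C", "freq": 0.3,
            "beta": 0.2, "se": 0.1,
            "p": [0.9, 0.01, 0.5, 0.02, 0.03, 0.6, 0.7, 0.04, 0.05, 0.8],
        })
        from polyrisk.predictors.elastic_net import _candidate_snps
        assert list(_candidate_snps(assoc, 5)) == ["s1", "s3", "s4", "s7", "s8"]

    def test_recovers_signal(self, sparse_cohort):
        _, dataset, pheno, _ = sparse_cohort
        y = pheno["status"].to_numpy(float)
        train = dataset.subset_samples(dataset.sample_ids[:600])
        test = dataset.subset_samples(dataset.sample_ids[600:])
        assoc = pr.single_snp_assoc(train, y[:600])
        eff = pr.fit_elastic_net(train, y[:600], assoc, top_m=60, inner_folds=5,
                                 n_lambdas=8, seed=1)
        assert pr.auc(pr.score(eff, test), y[600:]) > 0.6


# ---------------------------------------------------------------------- BayesR
class TestBayesr:
    def test_conditional_moments_match_closed_form(self):
        # independent derivation: explicit 1-D Bayesian linear regression
        # posterior N(mean, var) with var = (z'z/s2e + 1/v)^-1,
        # mean = var * z'r / s2e
        rng = np.random.default_rng(0)
        z = rng.standard_normal(500)
        r = rng.standard_normal(500)
        s2e, v = 0.7, 0.02
        var_expected = 1.0 / (z @ z / s2e + 1.0 / v)
        mean_expected = var_expected * (z @ r) / s2e
        mean, var = conditional_effect_moments(z, r, s2e, v)
        assert mean == pytest.approx(mean_expected, rel=1e-12)
        assert var == pytest.approx(var_expected, rel=1e-12)

    def test_invalid_settings(self, sparse_cohort):
        _, dataset, pheno, _ = sparse_cohort
        with pytest.raises(ValueError):
            pr.McmcSettings(iterations=100, burn_in=100).validate()

    def test_posterior_concentrates_on_causal_snps(self, sparse_cohort):
        _, dataset, pheno, model = sparse_cohort
        y = pheno["status"].to_numpy(float)
        state, eff = pr.fit_bayesr(
            dataset, y, pr.McmcSettings(iterations=1500, burn_in=750, thin=5, seed=2)
        )
        truth_order = np.argsort(-np.abs(model.effects))
        top_true = set(dataset.snp_ids[truth_order[:3]])
        post_order = np.argsort(-state.comp_prob[:, 1:].sum(axis=1))
        top_post = set(dataset.snp_ids[post_order[:10]])
        assert len(top_true & top_post) >= 2
        assert state.sigma_e2 > 0 and state.sigma_g2 > 0
        assert np.all(state.pi >= 0) and state.pi.sum() == pytest.approx(1.0, abs=1e-8)

    def test_single_component_matches_gblup(self):
        # one shared non-null variance and a disfavored null component turn
        # the mixture into a ridge prior: predictions should track GBLUP
        cfg = pr.SimulationConfig(n_pool=4000, m=500, n_cases=500, n_controls=500,
                                  h2=0.5, prevalence_K=0.3, pi=(0.0, 0.0, 0.0, 1.0),
                                  seed=13)
        dataset, pheno, _ = pr.simulate_dataset(cfg)
        y = pheno["status"].to_numpy(float)
        train = dataset.subset_samples(dataset.sample_ids[:800])
        test = dataset.subset_samples(dataset.sample_ids[800:])
        _, eff = pr.fit_bayesr(
            train, y[:800],
            pr.McmcSettings(iterations=3000, burn_in=1000, thin=5, seed=3),
            gamma=(0.0, 1e-2, 1e-2, 1e-2),
            dirichlet_alpha=(1e-3, 1.0, 1.0, 1.0),
        )
        s_bayes = pr.score(eff, test)
        grm = pr.compute_grm(dataset, freqs=train.allele_freq())
        yser = pd.Series(y, index=pd.Index(dataset.sample_ids, name="iid"))
        _, s_gblup = pr.fit_gblup(grm, yser, test.sample_ids)
        assert np.corrcoef(s_bayes.to_numpy(), s_gblup.to_numpy())[0, 1] > 0.98

    def test_chain_is_seeded_and_reproducible(self, null_cohort):
        _, dataset, pheno, _ = null_cohort
        y = pheno["status"].to_numpy(float)
        mc = pr.McmcSettings(iterations=200, burn_in=100, thin=2, seed=9)
        s1, e1 = pr.fit_bayesr(dataset, y, mc)
        s2, e2 = pr.fit_bayesr(dataset, y, pr.McmcSettings(iterations=200, burn_in=100, thin=2, seed=9))
        np.testing.assert_array_equal(e1.table["effect"], e2.table["effect"])


# ---------------------------------------------------------------------- scorer
class TestScore:
    def test_zero_effects_return_intercept(self, toy_dataset):
        eff = pr.SnpEffectSet.from_training("GPRS", toy_dataset, np.zeros(3), intercept=1.5)
        np.testing.assert_allclose(pr.score(eff, toy_dataset).to_numpy(), 1.5)

    def test_two_snp_hand_arithmetic(self):
        samples = pd.DataFrame({"fid": ["f"], "iid": ["i"]})
        snps = pd.DataFrame({"snp": ["s1", "s2"], "chrom": 1, "pos": [1, 2],
                             "a1": ["A", "G"], "a2": ["C", "T"]})
        ds = pr.GenotypeDataset(np.array([[2.0, 1.0]]), samples, snps)
        eff = pr.SnpEffectSet.from_training("GPRS", ds, np.array([0.5, -1.0]))
        assert pr.score(eff, ds).iat[0] == pytest.approx(0.0, abs=1e-12)

    def test_allele_flip_invariance(self, sparse_cohort):
        _, dataset, pheno, _ = sparse_cohort
        assoc = pr.single_snp_assoc(dataset, pheno["status"].to_numpy(float))
        eff = pr.fit_gprs(assoc)
        baseline = pr.score(eff, dataset)
        flipped = dataset.copy()
        half = flipped.n_snps // 2
        flipped.snps.loc[:half, ["a1", "a2"]] = flipped.snps.loc[:half, ["a2", "a1"]].to_numpy()
        flipped.dosages[:, : half + 1] = 2.0 - flipped.dosages[:, : half + 1]
        np.testing.assert_allclose(pr.score(eff, flipped).to_numpy(),
                                   baseline.to_numpy(), atol=1e-9)

    def test_snp_order_invariance(self, sparse_cohort):
        _, dataset, pheno, _ = sparse_cohort
        assoc = pr.single_snp_assoc(dataset, pheno["status"].to_numpy(float))
        eff = pr.fit_gprs(assoc)
        rng = np.random.default_rng(0)
        perm = rng.permutation(dataset.n_snps)
        shuffled = dataset.subset_snps(dataset.snp_ids[perm])
        np.testing.assert_allclose(pr.score(eff, shuffled).to_numpy(),
                                   pr.score(eff, dataset).to_numpy(), atol=1e-9)

    def test_insufficient_overlap_errors(self, toy_dataset):
        eff = pr.SnpEffectSet.from_training("GPRS", toy_dataset, np.ones(3))
        other = toy_dataset.copy()
        other.snps["snp"] = ["x1", "x2", "x3"]
        with pytest.raises(ValueError, match="scorable"):
            pr.score(eff, other)

    def test_missing_dosage_imputed_from_training_freq(self, toy_dataset):
        eff = pr.SnpEffectSet.from_training("GPRS", toy_dataset, np.array([1.0, 0.0, 0.0]))
        target = toy_dataset.copy()
        target.dosages[0, 0] = np.nan
        s = pr.score(eff, target)
        expected = 2.0 * eff.table["freq"].iat[0]
        assert s.iat[0] == pytest.approx(expected, abs=1e-12)
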