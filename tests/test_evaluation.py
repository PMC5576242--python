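"""Folds, AUC, decile ORs, liability-model utilities, benchmark runner."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import polyrisk as pr


# ---------------------------------------------------------------------- folds
class TestFolds:
    def test_equal_fold_sizes(self):
        pheno = pr.make_phenotype_table([f"i{k}" for k in range(10)], [0, 1] * 5)
        plan = pr.make_folds(pheno, K=5, seed=0)
        sizes = plan.labels.value_counts()
        assert list(sizes.sort_index()) == [2] * 5

    def test_stratification_balances_cases(self):
        status = [1] * 40 + [0] * 60
        pheno = pr.make_phenotype_table([f"i{k}" for k in range(100)], status)
        plan = pr.make_folds(pheno, K=5, stratified=True, seed=1)
        for k in range(5):
            fold_status = pheno.set_index("iid").loc[plan.test_ids(k), "status"]
            assert int(fold_status.sum()) == 8

    def test_partition_property(self):
        pheno = pr.make_phenotype_table([f"i{k}" for k in range(53)],
                                        np.random.default_rng(0).integers(0, 2, 53))
        plan = pr.make_folds(pheno, K=5, seed=2)
        folds = [set(plan.test_ids(k)) for k in range(5)]
        assert set.union(*folds) == set(pheno["iid"])
        for a, b in itertools.combinations(folds, 2):
            assert not (a & b)

    def test_too_few_samples(self):
        pheno = pr.make_phenotype_table(["a", "b"], [0, 1])
        with pytest.raises(ValueError):
            pr.make_folds(pheno, K=5)


# ------------------------------------------------------------------------ AUC
def brute_force_auc(scores, labels):
    """Literal pair counting: concordant pairs plus half the ties."""
    cases = [s for s, y in zip(scores, labels) if y == 1]
    ctrls = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for c in cases:
        for k in ctrls:
            total += 1.0 if c > k else (0.5 if c == k else 0.0)
    return total / (len(cases) * len(ctrls))


class TestAuc:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 1.0),
            ([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0], 0.5),
            ([3, 1, 2, 0], [1, 1, 0, 0], 0.75),
        ],
    )
    def test_reference_values(self, scores, labels, expected):
        assert pr.auc(scores, labels) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(-5, 5), st.booleans()), min_size=4, max_size=40))
    def test_matches_brute_force_pair_counting(self, pairs):
        scores = [s for s, _ in pairs]
        labels = [int(b) for _, b in pairs]
        if sum(labels) in (0, len(labels)):
            return
        assert pr.auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=4, max_size=30))
    def test_orientation_symmetry(self, scores):
        labels = [1, 0] * (len(scores) // 2) + [1] * (len(scores) % 2)
        if sum(labels) in (0, len(labels)):
            return
        assert pr.auc(scores, labels) + pr.auc([-s for s in scores], labels) \
            == pytest.approx(1.0, abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            pr.auc([1, 2], [1, 1])


class TestRelativeGain:
    def test_identity_is_zero(self):
        assert pr.relative_auc_gain(0.7, 0.7) == 0.0

    def test_zero_reference_errors(self):
        with pytest.raises(ValueError):
            pr.relative_auc_gain(0.7, 0.0)


# --------------------------------------------------------------------- deciles
class TestDecileOr:
    def test_hand_arithmetic_extreme_deciles(self):
        # bottom decile 2 cases / 8 controls, top decile 8 cases / 2 controls
        scores = np.arange(100, dtype=float)
        labels = np.zeros(100)
        labels[[0, 1]] = 1
        labels[10:90] = np.tile([0, 1], 40)
        labels[[90, 91, 92, 93, 94, 95, 96, 97]] = 1
        labels[[98, 99]] = 0
        tab = pr.decile_or(scores, labels)
        assert tab["odds_ratio"].iat[0] == 1.0
        assert tab["odds_ratio"].iat[9] == pytest.approx((8 / 2) / (2 / 8), abs=1e-12)

    def test_homogeneous_case_fraction_gives_unit_ors(self):
        scores = np.arange(200, dtype=float)
        labels = np.tile([0, 1], 100)
        tab = pr.decile_or(scores, labels)
        np.testing.assert_allclose(tab["odds_ratio"], 1.0)

    def test_counts_partition_sample(self):
        rng = np.random.default_rng(0)
        scores = rng.standard_normal(237)
        labels = rng.integers(0, 2, 237)
        tab = pr.decile_or(scores, labels)
        assert int((tab["n_cases"] + tab["n_controls"]).sum()) == 237
        sizes = (tab["n_cases"] + tab["n_controls"]).to_numpy()
        assert sizes.max() - sizes.min() <= 1

    def test_zero_control_decile_flagged_not_fatal(self):
        scores = np.arange(40, dtype=float)
        labels = np.zeros(40)
        labels[-4:] = 1  # top decile all cases
        labels[0] = 1    # bottom decile has a case so the reference is defined
        tab = pr.decile_or(scores, labels, n_groups=10)
        assert bool(tab["undefined"].iat[9])

    def test_aggregate_interval_convention(self):
        tables = []
        for shift in (1.0, 2.0, 3.0):
            t = pd.DataFrame({"decile": np.arange(1, 11),
                              "odds_ratio": np.full(10, shift)})
            tables.append(t)
        agg = pr.aggregate_decile_tables(tables)
        assert agg["odds_ratio"].iat[5] == pytest.approx(2.0)
        assert agg["ci_high"].iat[5] - agg["odds_ratio"].iat[5] == pytest.approx(
            1.96 * 1.0 / np.sqrt(3)
        )


# ------------------------------------------------------------------- liability
class TestLiabilityModel:
    def test_spec_constants_consistent(self):
        spec = pr.LiabilityModelSpec.from_prevalence(0.005)
        from scipy.stats import norm
        assert spec.t == pytest.approx(norm.isf(0.005), abs=1e-12)
        assert spec.i == pytest.approx(spec.z / 0.005, abs=1e-12)
        assert spec.i2 == pytest.approx(-spec.z / 0.995, abs=1e-12)

    def test_no_discrimination_gives_zero_variance(self):
        assert pr.auc_to_liability_v(0.5, 0.01).v == 0.0
        assert pr.expected_decile_or(0.5, 0.01) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("auc,K,v_expected", [(0.746, 0.005, 0.099),
                                                  (0.696, 0.002, 0.051)])
    def test_variance_explained_roundtrip(self, auc, K, v_expected):
        spec = pr.auc_to_liability_v(auc, K)
        assert spec.v == pytest.approx(v_expected, abs=0.001)
        assert pr.liability_auc(spec.v, K) == pytest.approx(auc, abs=1e-9)

    def test_expected_or_strictly_increasing_in_auc(self):
        for K in (0.002, 0.005, 0.05):
            ors = [pr.expected_decile_or(a, K) for a in (0.55, 0.6, 0.65, 0.7, 0.75, 0.8)]
            assert np.all(np.diff(ors) > 0)

    def test_quadrature_matches_monte_carlo_grid(self):
        for auc, K in itertools.product((0.6, 0.7, 0.75), (0.002, 0.005, 0.01)):
            quad = pr.expected_decile_or(auc, K)
            mc = pr.expected_decile_or(auc, K, method="mc", mc_draws=2_000_000, seed=0)
            assert mc == pytest.approx(quad, rel=0.02)

    def test_bad_auc_rejected(self):
        with pytest.raises(ValueError):
            pr.auc_to_liability_v(0.4, 0.01)


# ------------------------------------------------------------------ calibration
class TestCalibration:
    def test_identity_scores(self):
        y = np.array([0.0, 1, 0, 1, 1])
        assert pr.calibration_slope(y, y) == pytest.approx(1.0)

    def test_halved_scores_double_slope(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 500).astype(float)
        assert pr.calibration_slope(y / 2, y) == pytest.approx(2.0)

    def test_independent_scores_slope_near_zero(self):
        rng = np.random.default_rng(1)
        near_zero = 0
        for _ in range(100):
            y = rng.integers(0, 2, 10_000).astype(float)
            s = rng.standard_normal(10_000)
            near_zero += abs(pr.calibration_slope(s, y)) < 0.05
        assert near_zero >= 95


# --------------------------------------------------------- factor association
class TestScoreFactorAssociation:
    def test_type_one_error_rate(self):
        rng = np.random.default_rng(2)
        rejections = 0
        reps = 100
        for _ in range(reps):
            scores = rng.standard_normal(300)
            factor = rng.choice(["a", "b", "c"], 300)
            rejections += pr.score_factor_association(scores, factor)["p_value"] < 0.05
        half = 2.576 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rejections / reps - 0.05) <= half + 0.01

    def test_shifted_level_detected(self):
        rng = np.random.default_rng(3)
        detected = 0
        reps = 40
        for _ in range(reps):
            scores = rng.standard_normal(900)
            factor = np.repeat(["a", "b", "c"], 300)
            scores[:300] += 1.0
            detected += pr.score_factor_association(scores, factor)["p_value"] < 0.01
        assert detected >= int(0.95 * reps)

    def test_single_level_errors(self):
        with pytest.raises(ValueError):
            pr.score_factor_association(np.random.randn(10), ["a"] * 10)


# ------------------------------------------------------------------- benchmark
class TestRunBenchmark:
    def test_learning_curve_with_sample_size(self, sparse_cohort):
        _, dataset, pheno, _ = sparse_cohort
        small = pr.Scenario(name="n300", sample_ids=dataset.sample_ids[:300])
        large = pr.Scenario(name="n800")
        reports = pr.run_benchmark(dataset, pheno, methods=["gblup"],
                                   scenarios=[small, large], n_folds=5, seed=3)
        auc_by_scenario = {r.scenario: r.mean_auc for r in reports}
        assert auc_by_scenario["n800"] > auc_by_scenario["n300"] - 0.02

    def test_external_validation_consistency(self, sparse_cohort):
        cfg, dataset, pheno, model = sparse_cohort
        import dataclasses
        cfg_ext = dataclasses.replace(cfg, seed=4242, n_cases=200, n_controls=200)
        pool = pr.simulate_genotypes(cfg)  # same seed -> same pool genotypes
        ext_pheno = pr.simulate_case_control(
            pool, pr.simulate_effect_sizes(pool, cfg.pi, cfg.gamma, cfg.h2, cfg.seed),
            cfg_ext,
            eligible_ids=[i for i in pool.sample_ids if i not in set(dataset.sample_ids)],
        )
        ext = pool.subset_samples(ext_pheno["iid"])
        reports = pr.run_benchmark(dataset, pheno, methods=["gprs"], n_folds=5,
                                   seed=5, external=(ext, ext_pheno))
        r = reports[0]
        assert abs(r.mean_external_auc - r.mean_auc) < 0.05

    def test_unknown_method_rejected(self, null_cohort):
        _, dataset, pheno, _ = null_cohort
        with pytest.raises(ValueError):
            pr.run_benchmark(dataset, pheno, methods=["mystery"], n_folds=2, seed=0)
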