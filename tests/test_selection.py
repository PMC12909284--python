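"""Wrapper fitness, group masks, leakage, and hyperparameter decoding."""

import hashlib
import json

import numpy as np
import pytest

from gsoelm import (
    CVProblem, ElmConfig, FitnessSpec, SwarmConfig, TODDLER_SCHEMA,
    build_design_matrix, cross_validated_score, decode_hyper_position,
    expand_group_mask, fitness, generate, generate_planted, GeneratorConfig,
    select_features, selection_stability, tune_hidden_weights,
    tune_hyperparameters,
)


@pytest.fixture(scope="module")
def planted():
    X, y, informative = generate_planted(n=200, n_features=10, n_informative=3,
                                         effect_size=2.0, seed=8)
    return CVProblem(X=X, y=y), informative


ELM = ElmConfig(L=30, seed=1)
SPEC3 = FitnessSpec(k_folds=3, seed=2)


class TestCrossValidatedScore:
    def test_separable_data_reaches_perfect_auc(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(-4, 0.2, (30, 3)), rng.normal(4, 0.2, (30, 3))])
        y = np.array([0] * 30 + [1] * 30)
        score = cross_validated_score(CVProblem(X=X, y=y), np.ones(3, bool), ELM, SPEC3)
        assert score == pytest.approx(1.0, abs=1e-9)

    def test_permuted_labels_near_chance(self, planted):
        problem, _ = planted
        rng = np.random.default_rng(0)
        scores = []
        for seed in range(10):
            y_perm = rng.permutation(problem.y)
            p = CVProblem(X=problem.X, y=y_perm)
            scores.append(cross_validated_score(
                p, np.ones(problem.d, bool), ELM, FitnessSpec(k_folds=3, seed=seed)))
        assert np.mean(scores) == pytest.approx(0.5, abs=0.1)

    def test_k2_and_k5_agree_on_easy_task(self, planted):
        problem, _ = planted
        mask = np.ones(problem.d, bool)
        s2 = cross_validated_score(problem, mask, ELM, FitnessSpec(k_folds=2, seed=3))
        s5 = cross_validated_score(problem, mask, ELM, FitnessSpec(k_folds=5, seed=3))
        assert 0 <= s2 <= 1 and 0 <= s5 <= 1
        assert abs(s2 - s5) < 0.15

    def test_empty_mask_rejected(self, planted):
        problem, _ = planted
        with pytest.raises(ValueError, match="no columns"):
            cross_validated_score(problem, np.zeros(problem.d, bool), ELM, SPEC3)

    def test_too_few_minority_for_folds_errors(self):
        X = np.random.default_rng(1).normal(size=(20, 2))
        y = np.array([1, 1] + [0] * 18)
        with pytest.raises(ValueError, match="stratified"):
            cross_validated_score(CVProblem(X=X, y=y), np.ones(2, bool), ELM,
                                  FitnessSpec(k_folds=5, seed=0))


class TestFitness:
    def test_zero_alpha_equals_score(self, planted):
        problem, _ = planted
        mask = np.ones(problem.d, bool)
        spec = FitnessSpec(alpha_sparsity=0.0, k_folds=3, seed=2)
        res = fitness(problem, mask, spec, ELM)
        assert res.J == pytest.approx(res.score_cv)

    def test_full_mask_penalty_arithmetic(self, planted):
        problem, _ = planted
        res = fitness(problem, np.ones(problem.d, bool),
                      FitnessSpec(alpha_sparsity=0.1, k_folds=3, seed=2), ELM)
        # full mask: penalty = alpha * d/d = alpha
        assert res.penalty == pytest.approx(0.1)
        assert res.J == pytest.approx(res.score_cv - 0.1)

    def test_empty_mask_scores_minus_one_without_training(self, planted):
        problem, _ = planted
        res = fitness(problem, np.zeros(problem.d, bool), SPEC3, ELM)
        assert res.J == -1.0 and res.n_selected == 0

    def test_ratio_penalty_form_decreases_in_mask_size(self, planted):
        problem, _ = planted
        spec = FitnessSpec(alpha_sparsity=0.2, k_folds=3, seed=2,
                           penalty_form="ratio")
        mask = np.ones(problem.d, bool)
        res = fitness(problem, mask, spec, ELM)
        assert res.J == pytest.approx(res.score_cv / 1.2)

    def test_sparser_mask_wins_at_equal_score(self):
        # penalty monotonicity: J difference equals the penalty difference
        d = 8
        spec = FitnessSpec(alpha_sparsity=0.2, k_folds=3, seed=1)
        m_small = np.zeros(d, bool); m_small[:2] = True
        m_large = np.ones(d, bool)
        pen_small = spec.alpha_sparsity * 2 / d
        pen_large = spec.alpha_sparsity
        assert pen_small < pen_large


class TestGroupMask:
    def test_expand_on_fixture_schema(self, sample_table):
        _, fs = build_design_matrix(sample_table, TODDLER_SCHEMA)
        G = len(fs.groups)
        u = np.zeros(G, dtype=int)
        u[list(fs.groups).index("Ethnicity")] = 1
        m = expand_group_mask(u, fs)
        assert m.sum() == 6  # all six ethnicity columns together
        assert np.all(m[fs.groups["Ethnicity"]] == 1)

    def test_all_ones_and_all_zeros(self, sample_table):
        _, fs = build_design_matrix(sample_table, TODDLER_SCHEMA)
        G = len(fs.groups)
        assert expand_group_mask(np.ones(G, int), fs).sum() == fs.n_features
        assert expand_group_mask(np.zeros(G, int), fs).sum() == 0

    def test_counts_preserved_on_random_masks(self, sample_table, rng):
        _, fs = build_design_matrix(sample_table, TODDLER_SCHEMA)
        for _ in range(20):
            u = rng.integers(0, 2, len(fs.groups))
            m = expand_group_mask(u, fs)
            expected = sum(len(cols) for flag, cols in zip(u, fs.groups.values()) if flag)
            assert m.sum() == expected

    def test_length_mismatch_errors(self, sample_table):
        _, fs = build_design_matrix(sample_table, TODDLER_SCHEMA)
        with pytest.raises(ValueError, match="length"):
            expand_group_mask(np.ones(3, int), fs)


class TestLeakage:
    def test_fold_statistics_independent_of_heldout_rows(self):
        ds = generate(GeneratorConfig(n=60, seed=4))
        problem = CVProblem(raw=ds.table, schema=ds.schema)
        train_idx = np.arange(40)
        val_idx = np.arange(40, 60)

        def stats_hash(problem):
            *_, fs = problem.fold(train_idx, val_idx, return_schema=True)
            payload = json.dumps({"shift": fs.scaler.shift, "scale": fs.scaler.scale,
                                  "means": fs.numeric_means,
                                  "modes": fs.categorical_modes}, sort_keys=True)
            return hashlib.sha256(payload.encode()).hexdigest()

        h_before = stats_hash(problem)
        perturbed = ds.table.copy()
        perturbed.loc[45, "Age_Mons"] = 360
        perturbed.loc[50, "Qchat_10_Score"] = 0
        h_after = stats_hash(CVProblem(raw=perturbed, schema=ds.schema))
        assert h_before == h_after


class TestSelectFeatures:
    def test_informative_columns_selected_more_often(self, planted):
        problem, informative = planted
        report = select_features(problem, SwarmConfig(G=15, T_max=15, seed=6),
                                 SPEC3, ELM, n_runs=5)
        gap = report.frequencies[informative].mean() - report.frequencies[~informative].mean()
        assert gap > 0.0
        assert report.best_mask.sum() >= 1

    def test_group_level_selects_whole_blocks(self):
        ds = generate(GeneratorConfig(n=120, seed=9))
        problem = CVProblem(raw=ds.table, schema=ds.schema)
        report = select_features(problem, SwarmConfig(G=10, T_max=8, seed=1),
                                 SPEC3, ELM, group_level=True)
        fs = problem.feature_schema
        for name, cols in fs.groups.items():
            block = report.best_mask[cols]
            assert block.min() == block.max()  # all-in or all-out

    def test_single_informative_column_found(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 80)
        X = (y[:, None] + rng.normal(0, 0.1, (80, 1)))
        problem = CVProblem(X=X, y=y)
        report = select_features(problem, SwarmConfig(G=10, T_max=10, seed=3),
                                 SPEC3, ELM)
        assert report.best_mask.tolist() == [1]

    def test_deterministic_under_fixed_seed(self, planted):
        problem, _ = planted
        kw = dict(swarm_config=SwarmConfig(G=10, T_max=8, seed=11),
                  fitness_spec=SPEC3, elm_config=ELM)
        r1 = select_features(problem, **kw)
        r2 = select_features(problem, **kw)
        np.testing.assert_array_equal(r1.best_mask, r2.best_mask)
        assert r1.best_J == r2.best_J


class TestHyperTuning:
    def test_decode_endpoints(self):
        low = decode_hyper_position([0, 0, 0, 0])
        high = decode_hyper_position([1, 1, 1, 1])
        assert low["L"] == 20 and high["L"] == 200
        assert low["lam"] == pytest.approx(1e-6)
        assert high["lam"] == pytest.approx(1e2)
        assert low["activation"] == "sigmoid" and high["activation"] == "rbf"

    def test_decode_midpoint_L(self):
        assert decode_hyper_position([0.5, 0, 0, 0])["L"] == 110

    def test_decode_clips_out_of_range(self):
        assert decode_hyper_position([-3, 7, 0, 0])["L"] == 20
        assert decode_hyper_position([-3, 7, 0, 0])["lam"] == pytest.approx(1e2)

    def test_tuned_config_within_ranges(self, planted):
        problem, _ = planted
        cfg, scaler, score, _ = tune_hyperparameters(
            problem, np.ones(problem.d, bool),
            SwarmConfig(G=6, T_max=4, seed=5), ELM, SPEC3)
        assert 20 <= cfg.L <= 200
        assert 1e-6 <= cfg.lam <= 1e2
        assert 0 <= score <= 1

    def test_noisy_labels_prefer_stronger_regularization(self):
        # median tuned lambda under heavy label noise exceeds the clean one
        lams_clean, lams_noisy = [], []
        for seed in range(5):
            X, y, _ = generate_planted(n=150, n_features=5, n_informative=5,
                                       effect_size=1.0, seed=seed)
            rng = np.random.default_rng(100 + seed)
            y_noisy = np.where(rng.random(len(y)) < 0.35, 1 - y, y)
            swarm = SwarmConfig(G=8, T_max=6, seed=seed)
            elm = ElmConfig(L=80, seed=seed)
            spec = FitnessSpec(k_folds=3, seed=seed)
            cfg_c, *_ = tune_hyperparameters(CVProblem(X=X, y=y), np.ones(5, bool),
                                             swarm, elm, spec)
            cfg_n, *_ = tune_hyperparameters(CVProblem(X=X, y=y_noisy), np.ones(5, bool),
                                             swarm, elm, spec)
            lams_clean.append(cfg_c.lam)
            lams_noisy.append(cfg_n.lam)
        assert np.median(lams_noisy) > np.median(lams_clean)

    def test_weight_space_tuning_restricted_to_toy_sizes(self, planted):
        problem, _ = planted
        with pytest.raises(ValueError, match="L <= 10"):
            tune_hidden_weights(problem, np.ones(problem.d, bool), L=50,
                                swarm_config=SwarmConfig(G=5, T_max=3, seed=1),
                                base_config=ELM)

    def test_weight_space_tuning_runs_on_toy_case(self):
        X, y, _ = generate_planted(n=60, n_features=3, n_informative=3, seed=3)
        problem = CVProblem(X=X, y=y)
        params, score, _ = tune_hidden_weights(
            problem, np.ones(3, bool), L=4,
            swarm_config=SwarmConfig(G=6, T_max=4, seed=2),
            base_config=ElmConfig(L=4, seed=0), fitness_spec=SPEC3)
        assert params["W"].shape == (4, 3) and params["b"].shape == (4,)
        assert 0 <= score <= 1


class TestStability:
    def test_identical_seeds_give_degenerate_frequencies(self):
        mask = np.array([1, 0, 1])
        out = selection_stability([mask, mask, mask])
        assert set(out["frequencies"].frequency) <= {0.0, 1.0}

    def test_hand_tally(self):
        masks = [np.array([1, 0, 1]), np.array([1, 1, 0]), np.array([1, 0, 0])]
        out = selection_stability(masks)
        assert out["frequencies"].frequency.tolist() == pytest.approx([1.0, 1 / 3, 1 / 3])

    def test_requires_two_runs(self):
        with pytest.raises(ValueError):
            selection_stability([np.array([1, 0])])
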