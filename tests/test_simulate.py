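import numpy as np
import pytest

from cosmarker import (
    PEER_METHODS,
    SimConfig,
    cot_feature_scores,
    benchmark,
    null_mixture,
    peer_scores,
    roc_eval,
    simulate_dataset,
    standard_settings,
    subtype_means,
)


class TestGenerator:
    def test_mg_bookkeeping(self):
        truth = simulate_dataset(SimConfig(n_features=1000, mg_fraction=0.1, seed=0))
        assert truth.is_mg.sum() == 100
        assert np.all(truth.mg_subtype[truth.is_mg] >= 0)
        assert np.all(truth.mg_subtype[~truth.is_mg] == -1)

    def test_ideal_markers_score_one_without_noise(self):
        truth = simulate_dataset(
            SimConfig(n_features=500, mg_fraction=0.2, mg_deviation=0.0, noise_cv=0.0, seed=1)
        )
        t = cot_feature_scores(truth.data)
        assert np.allclose(t[truth.is_mg], 1.0)

    def test_null_scores_within_theoretical_bounds(self):
        truth = simulate_dataset(SimConfig(n_features=5000, mg_fraction=0.0, seed=2))
        t = cot_feature_scores(truth.data)
        assert np.all(t <= 1.0 + 1e-12)
        assert np.all(t >= 1 / np.sqrt(3) - 1e-12)
        assert t.mean() < 0.99  # concentrates strictly below the marker ideal

    def test_reproducible_from_seed(self):
        cfg = SimConfig(n_features=300, seed=11)
        a, b = simulate_dataset(cfg), simulate_dataset(cfg)
        assert np.array_equal(a.data.values, b.data.values)
        assert np.array_equal(a.is_mg, b.is_mg)

    def test_infeasible_deviation_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(mg_deviation=90.0)

    def test_null_mixture_weights_sum_to_one(self):
        alphas, weights, rotations = null_mixture(4)
        assert sum(weights) == pytest.approx(1.0)
        assert len(alphas) == len(weights) == len(rotations)
        assert all(len(a) == 4 for a in alphas)


class TestPeerScores:
    def test_constant_feature_is_null_for_all(self, tiny_matrix):
        # gC is constant 5 across all samples
        f = peer_scores(tiny_matrix, "anova_f")
        ove = peer_scores(tiny_matrix, "ove_fc")
        assert f[2] == 0.0
        assert ove[2] == pytest.approx(1.0)

    def test_anova_matches_hand_computation(self):
        from cosmarker import ExpressionMatrix

        m = ExpressionMatrix(
            features=["flat", "marker"],
            samples=["A.1", "A.2", "B.1", "B.2", "C.1", "C.2"],
            values=np.array(
                [[1, 2, 1, 2, 1, 2], [10, 10, 0, 0, 0, 0]], dtype=float
            ),
            subtype_of={s: s.split(".")[0] for s in ["A.1", "A.2", "B.1", "B.2", "C.1", "C.2"]},
        )
        f = peer_scores(m, "anova_f")
        assert f[0] == pytest.approx(0.0)
        assert f[1] > 1e6  # zero within-group variance, huge between-group

    def test_fold_change_direction(self):
        from cosmarker import ExpressionMatrix

        m = ExpressionMatrix(
            features=["up"],
            samples=["A.1", "A.2", "B.1", "B.2"],
            values=np.array([[2.0, 2.01, 0.0, 0.001]]),
            subtype_of={"A.1": "A", "A.2": "A", "B.1": "B", "B.2": "B"},
        )
        assert peer_scores(m, "ovr_fc")[0] > 100

    def test_ove_fc_uses_top_two_subtypes(self):
        from cosmarker import ExpressionMatrix

        samples = [f"{k}.{r}" for k in "ABC" for r in (1, 2)]
        m = ExpressionMatrix(
            features=["shared"],
            samples=samples,
            values=np.array([[8.0, 8.0, 7.9, 8.1, 0.0, 0.0]]),
            subtype_of={s: s.split(".")[0] for s in samples},
        )
        # expressed equally in A and B: OVE ratio ~ 1 despite silent C
        assert peer_scores(m, "ove_fc")[0] == pytest.approx(1.0, abs=0.05)
        assert peer_scores(m, "ovr_fc")[0] > 1.5

    def test_unknown_method_rejected(self, tiny_matrix):
        with pytest.raises(ValueError):
            peer_scores(tiny_matrix, "limma")


class TestRocEval:
    def _brute_force(self, scores, y, lo, hi):
        scores, y = np.asarray(scores, float), np.asarray(y, bool)
        thresholds = np.unique(scores)[::-1]
        fpr, tpr = [0.0], [0.0]
        for th in thresholds:
            sel = scores >= th
            fpr.append((sel & ~y).sum() / (~y).sum())
            tpr.append((sel & y).sum() / y.sum())
        fpr, tpr = np.array(fpr), np.array(tpr)
        grid = np.union1d(fpr[(fpr >= lo) & (fpr <= hi)], [lo, hi])
        return float(np.trapezoid(np.interp(grid, fpr, tpr), grid))

    def test_agrees_with_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        for trial in range(20):
            n = rng.integers(40, 200)
            y = np.zeros(n, bool)
            y[rng.permutation(n)[: rng.integers(5, n // 2)]] = True
            scores = np.round(rng.normal(size=n) + y, 2)  # ties on purpose

            class T:
                is_mg = y

            for rng_lo, rng_hi in [(0.01, 0.05), (0.0, 0.05), (0.0, 1.0)]:
                r = roc_eval(scores, T(), (rng_lo, rng_hi))
                assert r.pauc == pytest.approx(
                    self._brute_force(scores, y, rng_lo, rng_hi), abs=1e-12
                )

    def test_perfect_and_random_scores(self):
        rng = np.random.default_rng(4)
        n = 20000
        y = np.zeros(n, bool)
        y[:2000] = True

        class T:
            is_mg = y

        perfect = roc_eval(y.astype(float), T(), (0.01, 0.05))
        assert perfect.pauc == pytest.approx(0.04, abs=1e-12)
        assert perfect.power_at_fpr05 == pytest.approx(1.0)

        chance = roc_eval(rng.uniform(size=n), T(), (0.01, 0.05))
        assert chance.pauc == pytest.approx((0.05**2 - 0.01**2) / 2, rel=0.2)

    def test_degenerate_truth_rejected(self):
        class T:
            is_mg = np.ones(10, bool)

        with pytest.raises(ValueError):
            roc_eval(np.arange(10.0), T(), (0.01, 0.05))


class TestBenchmark:
    def test_noise_free_ideal_markers_are_trivial_for_all(self):
        cfg = {
            "ideal": SimConfig(
                n_features=800, mg_fraction=0.1, mg_deviation=0.0, noise_cv=0.0, seed=5
            )
        }
        tbl = benchmark(cfg, methods=("cot", "ovr_fc", "ove_fc"), n_replicates=2)
        assert (tbl["power_at_fpr05"] > 0.999).all()

    def test_reports_all_methods_and_settings(self):
        tbl = benchmark(
            standard_settings(n_features=400, seed=6), methods=("cot", "anova_f"), n_replicates=1
        )
        assert set(tbl["setting"]) == {"standard", "more_subtype", "more_sample", "complex_null"}
        assert set(tbl["method"]) == {"cot", "anova_f"}
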