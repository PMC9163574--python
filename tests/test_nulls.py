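import numpy as np
import pytest
from scipy.stats import kstest, norm
from sklearn.mixture import GaussianMixture

from cosmarker import (
    FnmNull,
    SimConfig,
    call_markers,
    cot_feature_scores,
    fit_fnm,
    fit_null_fdr_guided,
    mixture_quantile,
    p_value,
    q_values,
    simulate_dataset,
    subtype_means,
)


class TestFitFnm:
    def test_single_component_equals_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.5, 0.01, 20_000)
        fit = fit_fnm(x, n_components=1)
        assert fit.means[0] == pytest.approx(x.mean(), abs=1e-8)
        assert fit.variances[0] == pytest.approx(x.var(), abs=1e-8)

    def test_single_component_parameter_recovery(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.5, 0.01, 20_000)
        fit = fit_fnm(x, n_components=1)
        assert abs(fit.means[0] - 0.5) < 0.005
        assert abs(np.sqrt(fit.variances[0]) - 0.01) < 0.002

    def test_two_component_recovery(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0.45, 0.02, 12_000), rng.normal(0.6, 0.03, 8_000)])
        fit = fit_fnm(x, n_components=2)
        assert abs(fit.weights[0] - 0.6) < 0.05
        assert abs(fit.weights[1] - 0.4) < 0.05
        assert abs(fit.means[0] - 0.45) < 0.01
        assert abs(fit.means[1] - 0.60) < 0.01

    def test_matches_sklearn_gaussian_mixture(self):
        """Independent EM implementation agrees with sklearn on loglik."""
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0.4, 0.03, 5_000), rng.normal(0.65, 0.05, 5_000)])
        ours = fit_fnm(x, n_components=2)
        ref = GaussianMixture(2, covariance_type="spherical", random_state=0, n_init=3).fit(
            x[:, None]
        )
        ll_ref = ref.score(x[:, None]) * x.size
        assert ours.log_likelihood == pytest.approx(ll_ref, rel=1e-3)

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(4)
        x = rng.beta(5, 2, 2_000)
        lls = []
        for iters in (1, 2, 5, 10, 50):
            lls.append(fit_fnm(x, n_components=3, max_inner_iter=iters).log_likelihood)
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError):
            fit_fnm(np.linspace(0, 1, 30), n_components=5)


class TestPValues:
    def test_single_component_closed_form(self):
        null = FnmNull(1, np.array([1.0]), np.array([0.7]), np.array([0.01]))
        for t in (0.5, 0.7, 0.9):
            assert p_value(t, null) == pytest.approx(1 - norm.cdf((t - 0.7) / 0.1))
        assert p_value(0.7, null) == pytest.approx(0.5)

    def test_symmetric_two_component_midpoint(self):
        null = FnmNull(2, np.array([0.5, 0.5]), np.array([0.4, 0.5]), np.array([1e-4, 1e-4]))
        assert p_value(0.45, null) == pytest.approx(0.5, abs=1e-9)

    def test_limits_and_monotonicity(self):
        null = FnmNull(2, np.array([0.3, 0.7]), np.array([0.5, 0.8]), np.array([0.01, 0.02]))
        ts = np.linspace(-5, 5, 201)
        ps = p_value(ts, null)
        assert ps[0] == pytest.approx(1.0, abs=1e-9)
        assert ps[-1] == pytest.approx(0.0, abs=1e-9)
        assert np.all(np.diff(ps) <= 0)

    def test_quantile_inverts_p_value(self):
        null = FnmNull(2, np.array([0.4, 0.6]), np.array([0.5, 0.7]), np.array([0.01, 0.005]))
        for prob in np.linspace(0.01, 0.99, 25):
            t = mixture_quantile(null, prob)
            assert p_value(t, null) == pytest.approx(1 - prob, abs=1e-6)


class TestQValues:
    def test_bh_by_hand(self):
        q = q_values([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_constant_ps(self):
        assert np.allclose(q_values([0.2, 0.2, 0.2]), 0.2)

    def test_q_geq_p_and_order_preserving(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=500)
        q = q_values(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestFdrGuidedFit:
    def test_pure_null_stabilizes_and_matches_plain_fit(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(0.5, 0.03, 6_000), rng.normal(0.62, 0.04, 4_000)])
        guided = fit_null_fdr_guided(x, n_components=3)
        plain = fit_fnm(x, n_components=3)
        assert guided.n_iterations_outer <= 3
        assert kstest(x, lambda v: np.asarray(guided.cdf(v))).statistic < 0.02
        assert np.allclose(guided.means, plain.means)

    def test_planted_contamination_excluded(self):
        """5% of scores planted far above a two-mode null are excised."""
        rng = np.random.default_rng(7)
        null_scores = np.concatenate(
            [rng.normal(0.45, 0.02, 11_400), rng.normal(0.6, 0.03, 7_600)]
        )
        planted = np.clip(rng.normal(0.995, 0.004, 1_000), None, 1.0)
        x = np.concatenate([null_scores, planted])
        fit = fit_null_fdr_guided(x, n_components=5)
        p = p_value(x, fit)
        removed = q_values(p) < 0.01
        assert removed[len(null_scores) :].mean() >= 0.9
        assert removed[: len(null_scores)].mean() < 0.01

    def test_outer_iteration_count_small_on_simulated_data(self, default_sim):
        scores = cot_feature_scores(default_sim.data)
        fit = fit_null_fdr_guided(scores, n_components=5)
        assert 1 <= fit.n_iterations_outer <= 6


class TestCallMarkers:
    def test_sensitivity_on_simulated_markers(self, default_sim):
        """At the largest p threshold keeping empirical FPR <= 0.05, the
        pipeline recovers at least 80% of the planted markers."""
        prof = subtype_means(default_sim.data)
        calls, null, table = call_markers(prof, p_threshold=1.0)
        idx = {f: i for i, f in enumerate(default_sim.data.features)}
        p = np.ones(len(default_sim.data.features))
        for c in calls:
            p[idx[c.feature]] = c.p
        is_mg = default_sim.is_mg
        best = None
        for p_th in np.arange(0.01, 0.21, 0.01):
            if (p[~is_mg] <= p_th).mean() <= 0.05:
                best = p_th
        assert best is not None
        sensitivity = (p[is_mg] <= best).mean()
        assert sensitivity >= 0.8

    def test_assigned_subtype_matches_truth(self, default_sim):
        prof = subtype_means(default_sim.data)
        calls, _, _ = call_markers(prof, p_threshold=0.05)
        idx = {f: i for i, f in enumerate(default_sim.data.features)}
        subtypes = prof.subtypes
        hits = total = 0
        for c in calls:
            i = idx[c.feature]
            if c.accepted and default_sim.is_mg[i]:
                total += 1
                hits += subtypes[default_sim.mg_subtype[i]] == c.k_hat
        assert total > 0 and hits / total > 0.95

    def test_concordance_counts_nested(self, default_sim):
        prof = subtype_means(default_sim.data)
        _, _, table = call_markers(prof)
        tab = table.sort_values("p_threshold")
        assert np.all(np.diff(tab["n_accepted"]) >= 0)
        assert np.all(np.diff(tab["cos_at_threshold"]) <= 1e-12)

    def test_per_subtype_mode_robust_to_marker_imbalance(self):
        """Recall of minority-subtype markers is unchanged when another
        subtype's marker count is inflated tenfold."""
        # same expected number of sub2/sub3 markers; sub1 markers 10x inflated
        balanced = simulate_dataset(SimConfig(n_features=6000, seed=9, mg_fraction=0.03))
        skewed = simulate_dataset(
            SimConfig(
                n_features=6000,
                seed=9,
                mg_fraction=0.12,
                mg_subtype_weights=(10 / 12, 1 / 12, 1 / 12),
            )
        )
        recall = {}
        for name, sim in [("balanced", balanced), ("skewed", skewed)]:
            idx = {f: i for i, f in enumerate(sim.data.features)}
            calls, _, _ = call_markers(
                subtype_means(sim.data), null_mode="per_subtype", p_threshold=0.05
            )
            by_feature = {c.feature: c for c in calls}
            subtypes = ("sub1", "sub2", "sub3")
            for j in (1, 2):
                mg = [
                    f
                    for f in sim.data.features
                    if sim.is_mg[idx[f]] and sim.mg_subtype[idx[f]] == j
                ]
                recall[name, j] = np.mean(
                    [by_feature[f].accepted and by_feature[f].k_hat == subtypes[j] for f in mg]
                )
        for j in (1, 2):
            assert abs(recall["balanced", j] - recall["skewed", j]) <= 0.1

    def test_sdg_statistic_mode(self, default_sim):
        prof = subtype_means(default_sim.data)
        calls, _, _ = call_markers(prof, statistic="sdg")
        from cosmarker import sdg_scores

        k_idx, ts = sdg_scores(prof.means)
        by_feature = {c.feature: c for c in calls}
        for i in range(0, len(prof.features), 500):
            c = by_feature[prof.features[i]]
            assert c.t == pytest.approx(ts[i])
            assert c.k_hat == prof.subtypes[k_idx[i]]
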