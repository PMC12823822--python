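import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ks_2samp, spearmanr

from kg2ml.features import FeatureMatrix
from kg2ml.pulscar import (
    AlphaEstimate,
    CalibratedScores,
    DensityPair,
    PulscarConfig,
    calibrate,
    estimate_alpha,
    estimate_density,
    impute_positives,
    make_density_pair,
    oof_scores,
    rank_genes,
    run_pulscar,
)
from kg2ml.simulate import KGSimSpec, simulate_pu_matrix

FAST = PulscarConfig(n_iterations=3, base_seed=10)


def one_feature_matrix(n_pos=40, n_unl=60, separable=True, seed=0):
    rng = np.random.default_rng(seed)
    x_pos = np.ones(n_pos) if separable else (rng.random(n_pos) < 0.5)
    x_unl = np.zeros(n_unl) if separable else (rng.random(n_unl) < 0.5)
    X = sp.csr_matrix(np.r_[x_pos, x_unl].reshape(-1, 1).astype(int))
    y = np.r_[np.ones(n_pos), np.zeros(n_unl)].astype(int)
    cuis = [f"P{i}" for i in range(n_pos)] + [f"U{i}" for i in range(n_unl)]
    return FeatureMatrix(cuis, ["E0"], X, y)


class TestOofScores:
    def test_separable_data_separates_scores(self):
        ss = oof_scores(one_feature_matrix(), seed=1, config=FAST)
        assert np.all(ss.scores_pos >= 0.5)
        assert np.all(ss.scores_unl < 0.5)

    def test_same_seed_reproduces(self):
        fm = one_feature_matrix(separable=False)
        a = oof_scores(fm, seed=3, config=FAST)
        b = oof_scores(fm, seed=3, config=FAST)
        assert np.array_equal(a.scores_pos, b.scores_pos)
        assert np.array_equal(a.scores_unl, b.scores_unl)
        assert np.array_equal(a.fold_assignment, b.fold_assignment)

    def test_every_instance_scored_once_per_fold(self):
        fm = one_feature_matrix()
        ss = oof_scores(fm, seed=2, config=FAST)
        assert len(ss.scores_pos) == fm.n_positive
        assert len(ss.scores_unl) == fm.n_unlabeled
        assert set(ss.fold_assignment) == set(range(FAST.n_folds))

    def test_label_permutation_gives_indistinguishable_scores(self):
        # features carry no class signal: OOF score distributions of the
        # two groups should agree (two-sample KS)
        rng = np.random.default_rng(8)
        X = sp.csr_matrix((rng.random((600, 12)) < 0.3).astype(int))
        y = np.r_[np.ones(200), np.zeros(400)].astype(int)
        fm = FeatureMatrix([f"G{i}" for i in range(600)],
                           [f"E{j}" for j in range(12)], X, y)
        ss = oof_scores(fm, seed=5, config=FAST)
        assert ks_2samp(ss.scores_pos, ss.scores_unl).pvalue > 0.01

    def test_too_few_positives_raise(self):
        with pytest.raises(ValueError, match="per class"):
            oof_scores(one_feature_matrix(n_pos=3), seed=1, config=FAST)


class TestDensity:
    def test_constant_scores_occupy_single_bin(self):
        grid, f = estimate_density(np.full(50, 0.42), FAST)
        assert (f > 0).sum() == 1
        dx = grid[1] - grid[0]
        assert np.isclose(f.sum() * dx, 1.0, atol=1e-9)

    def test_normalization_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for n in (10, 100, 5000):
            grid, f = estimate_density(rng.random(n), FAST)
            dx = grid[1] - grid[0]
            assert np.all(f >= 0)
            assert np.isclose(f.sum() * dx, 1.0, atol=1e-9)

    def test_uniform_sample_density_is_flat(self):
        # 200 bins at N=1e5 -> ~500 samples/bin, per-bin relative SE ~0.045;
        # the sup over 200 bins stays under a ~4.5 sigma Poisson bound
        rng = np.random.default_rng(12)
        grid, f = estimate_density(rng.random(100_000), FAST)
        assert len(grid) == 200
        assert np.abs(f - 1.0).max() < 0.2

    def test_auto_bin_rule(self):
        cfg = PulscarConfig()
        for n, expected in ((10, 20), (5000, 71), (10**6, 200)):
            grid, _ = estimate_density(np.linspace(0, 1, 50), cfg, n_for_bins=n)
            assert len(grid) == expected

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            estimate_density(np.array([]), FAST)

    def test_out_of_range_scores_raise(self):
        with pytest.raises(ValueError):
            estimate_density(np.array([0.5, 1.2]), FAST)


class TestEstimateAlpha:
    def _pair(self, f_pos, f_unl, bins):
        grid = (np.arange(bins) + 0.5) / bins
        return DensityPair(grid=grid, f_pos=f_pos, f_unl=f_unl)

    def test_identical_densities_give_alpha_one(self):
        f = np.zeros(50)
        f[10:40] = 50 / 30
        assert estimate_alpha(self._pair(f, f.copy(), 50), FAST) == 1.0

    def test_disjoint_supports_give_alpha_zero(self):
        f_unl = np.zeros(50); f_unl[:10] = 5.0
        f_pos = np.zeros(50); f_pos[40:] = 5.0
        est = estimate_alpha(self._pair(f_pos, f_unl, 50), FAST)
        assert est <= 0.01

    def test_beta_mixture_recovers_known_alpha(self):
        # f_unl = 0.3 Beta(8,2) + 0.7 Beta(2,8), histogram densities N=1e5
        rng = np.random.default_rng(1)
        N = 100_000
        cfg = PulscarConfig()
        pos = rng.beta(8, 2, N)
        unl = np.r_[rng.beta(8, 2, int(0.3 * N)), rng.beta(2, 8, int(0.7 * N))]
        ntot = len(pos) + len(unl)
        grid, f_pos = estimate_density(pos, cfg, n_for_bins=ntot)
        _, f_unl = estimate_density(unl, cfg, n_for_bins=ntot)
        est = estimate_alpha(DensityPair(grid, f_pos, f_unl), cfg)
        assert abs(est - 0.3) <= 0.03

    def test_error_curve_is_nondecreasing(self):
        from kg2ml.pulscar import alpha_error_curve

        rng = np.random.default_rng(4)
        f_pos = rng.random(40); f_pos /= f_pos.sum() * (1 / 40)
        f_unl = rng.random(40); f_unl /= f_unl.sum() * (1 / 40)
        _, err = alpha_error_curve(self._pair(f_pos, f_unl, 40), FAST)
        assert np.all(np.diff(err) >= -1e-12)

    def test_zero_mass_densities_raise(self):
        z = np.zeros(20)
        with pytest.raises(ValueError):
            estimate_alpha(self._pair(z, z, 20), FAST)


class TestCalibrate:
    def test_alpha_zero_maps_to_zeros(self):
        assert np.all(calibrate(np.random.default_rng(0).random(20), 0.0) == 0)

    def test_alpha_one_maps_to_ones(self):
        out = calibrate(np.random.default_rng(0).random(20), 1.0)
        assert np.allclose(out.sum(), 20)
        assert np.all(out == 1)

    def test_sum_constraint_and_rank_preservation(self):
        rng = np.random.default_rng(6)
        scores = rng.random(1000)
        out = calibrate(scores, 0.3)
        assert abs(out.sum() - 300) < 1e-3
        assert spearmanr(scores, out).statistic == pytest.approx(1.0)

    def test_sum_constraint_tight_across_alphas(self):
        rng = np.random.default_rng(7)
        scores = rng.beta(2, 5, 500)
        for alpha in (0.05, 0.25, 0.5, 0.9):
            out = calibrate(scores, alpha)
            assert abs(out.sum() - alpha * 500) / (alpha * 500) <= 1e-6
            assert np.all((out >= 0) & (out <= 1))

    def test_extreme_scores_handled(self):
        out = calibrate(np.array([0.0, 0.5, 1.0]), 0.5)
        assert abs(out.sum() - 1.5) < 1e-6

    @given(
        st.lists(st.floats(0.0, 1.0), min_size=2, max_size=50),
        st.floats(0.01, 0.99),
    )
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_sum_and_monotonicity_hold_for_arbitrary_inputs(self, scores, alpha):
        scores = np.asarray(scores)
        out = calibrate(scores, alpha)
        target = alpha * len(scores)
        assert abs(out.sum() - target) <= 1e-6 * target
        assert np.all((out >= 0) & (out <= 1))
        order = np.argsort(scores, kind="stable")
        assert np.all(np.diff(out[order]) >= -1e-12)


class TestRunPulscar:
    def test_no_hidden_positives_gives_near_zero_alpha(self):
        spec = KGSimSpec(n_genes=800, n_labeled_positive=160, true_alpha=0.0,
                         n_signal_efo=20, n_background_efo=60, seed=2)
        fm, _ = simulate_pu_matrix(spec)
        ae, _ = run_pulscar(fm, PulscarConfig(n_iterations=4, base_seed=3))
        assert ae.mean_alpha <= 0.05

    def test_recovers_planted_alpha_small(self):
        spec = KGSimSpec(n_genes=2000, n_labeled_positive=400, true_alpha=0.3,
                         seed=5)
        fm, _ = simulate_pu_matrix(spec)
        ae, cs = run_pulscar(fm, PulscarConfig(n_iterations=5, base_seed=7))
        assert abs(ae.mean_alpha - 0.3) <= 0.07
        assert ae.ci_lower <= ae.mean_alpha <= ae.ci_upper
        # per-iteration conservation: sum of calibrated = alpha_i * |U|
        for i, alpha_i in enumerate(ae.per_iteration_alphas):
            target = alpha_i * fm.n_unlabeled
            assert abs(cs.per_iteration_probs[i].sum() - target) <= 1e-6 * target

    def test_identical_base_seed_reproduces(self):
        spec = KGSimSpec(n_genes=600, n_labeled_positive=120,
                         n_signal_efo=20, n_background_efo=40, seed=9)
        fm, _ = simulate_pu_matrix(spec)
        cfg = PulscarConfig(n_iterations=3, base_seed=21)
        ae1, cs1 = run_pulscar(fm, cfg)
        ae2, cs2 = run_pulscar(fm, cfg)
        assert np.array_equal(ae1.per_iteration_alphas, ae2.per_iteration_alphas)
        assert np.array_equal(cs1.per_iteration_probs, cs2.per_iteration_probs)

    def test_mean_probs_is_arithmetic_mean(self):
        cs = CalibratedScores(["A", "B"], np.array([[0.2, 0.4], [0.6, 0.8]]))
        assert np.allclose(cs.mean_probs, [0.4, 0.6])


class TestImputeAndRank:
    def _scores(self, probs):
        cuis = [f"U{i:02d}" for i in range(len(probs))]
        return CalibratedScores(cuis, np.array([probs]))

    def _alpha(self, a):
        return AlphaEstimate(np.array([a]), a, a, a)

    def test_zero_alpha_imputes_nothing(self):
        imp = impute_positives(self._scores([0.9, 0.1]), self._alpha(0.0))
        assert imp.probable_positive_cuis == set()

    def test_ceiling_rule_picks_top_genes(self):
        probs = [0.1, 0.9, 0.3, 0.8, 0.2, 0.7, 0.4, 0.6, 0.05, 0.5]
        imp = impute_positives(self._scores(probs), self._alpha(0.25))
        assert imp.probable_positive_cuis == {"U01", "U03", "U05"}  # top 3

    def test_tie_break_is_lexicographic(self):
        imp = impute_positives(self._scores([0.5, 0.5, 0.5, 0.1]),
                               self._alpha(0.26))
        # ceil(0.26*4)=2: U00 and U01 win the tie over U02
        assert imp.probable_positive_cuis == {"U00", "U01"}

    def test_imputation_precision_beats_base_rate(self):
        spec = KGSimSpec(n_genes=2000, n_labeled_positive=400, true_alpha=0.3,
                         seed=13)
        fm, truth = simulate_pu_matrix(spec)
        ae, cs = run_pulscar(fm, PulscarConfig(n_iterations=4, base_seed=2))
        imp = impute_positives(cs, ae)
        hits = len(imp.probable_positive_cuis & truth.hidden_positive_cuis)
        precision = hits / len(imp.probable_positive_cuis)
        base_rate = len(truth.hidden_positive_cuis) / fm.n_unlabeled
        assert precision > base_rate

    def test_rank_full_ordering_matches_sort_oracle(self):
        rng = np.random.default_rng(30)
        probs = rng.random(25)
        cs = self._scores(list(probs))
        ranked = rank_genes(cs, k=25)
        oracle = sorted(zip(cs.gene_cuis, probs), key=lambda t: (-t[1], t[0]))
        assert [c for c, _ in ranked] == [c for c, _ in oracle]

    def test_rank_k1_is_argmax(self):
        cs = self._scores([0.2, 0.9, 0.5])
        assert rank_genes(cs, k=1)[0][0] == "U01"

    def test_rank_k_beyond_u_returns_all(self):
        cs = self._scores([0.2, 0.9])
        assert len(rank_genes(cs, k=99)) == 2
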