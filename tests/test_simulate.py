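import numpy as np
import pytest

from essbvs import (
    calibrate_error_variance,
    evaluate_roc,
    make_replicate,
    scenario_presets,
    simulate_genotypes,
    simulate_traits,
)


class TestSimulateGenotypes:
    def test_mafs_within_requested_range(self):
        G = simulate_genotypes(3000, 40, maf_range=(0.1, 0.4), seed=1)
        f = G.values.mean(0) / 2
        se = np.sqrt(0.4 * 0.6 / (2 * 3000))
        assert np.all(f > 0.1 - 3 * se) and np.all(f < 0.4 + 3 * se)

    def test_zero_decay_gives_independent_snps(self):
        n = 2000
        G = simulate_genotypes(n, 30, decay=0.0, seed=2)
        R = np.corrcoef(G.values.T)
        off = np.abs(R[np.triu_indices(30, 1)])
        assert off.mean() <= 2 / np.sqrt(n)

    def test_adjacent_correlation_recovered(self):
        """Adjacent genotype correlation matches the requested decay to
        Monte-Carlo precision at the reference sample size."""
        n, target = 3175, 0.9
        G = simulate_genotypes(n, 20, ld_blocks=1, decay=target, seed=3)
        X = G.values
        r = [
            np.corrcoef(X[:, j], X[:, j + 1])[0, 1]
            for j in range(19)
        ]
        se = (1 - target**2) / np.sqrt(n)
        assert np.mean(r) == pytest.approx(target, abs=3 * se)

    def test_hwe_genotype_frequencies(self):
        G = simulate_genotypes(20000, 5, maf_range=(0.3, 0.3001), seed=4)
        counts = np.array(
            [(G.values == k).mean(0) for k in (0, 1, 2)]
        ).mean(1)
        f = 0.3
        expected = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
        assert np.allclose(counts, expected, atol=0.01)

    def test_map_has_blocks_as_chromosomes(self):
        G = simulate_genotypes(50, 12, ld_blocks=4, decay=0.5, seed=5)
        assert sorted(G.map["chromosome"].unique()) == [1, 2, 3, 4]


class TestCalibrateErrorVariance:
    def test_hand_value_single_snp(self):
        """One causal SNP at MAF 0.5 with effect 0.2 and a 5% cap:
        Var(Xb) = 2 f(1-f) b^2 = 0.02 under HWE, so sigma^2 ~ 0.38."""
        G = simulate_genotypes(60_000, 1, maf_range=(0.4999, 0.5), seed=6)
        sigma = calibrate_error_variance(G, [0], np.array([[0.2]]), max_r2=0.05)
        assert sigma[0] ** 2 == pytest.approx(0.38, rel=0.03)

    def test_null_trait_gets_unit_sigma(self):
        G = simulate_genotypes(500, 3, seed=7)
        B = np.array([[0.2, 0.0], [0.1, 0.0], [0.3, 0.0]])
        sigma = calibrate_error_variance(G, [0, 1, 2], B, max_r2=0.05)
        assert sigma[1] == 1.0

    def test_scale_equivariance(self):
        G = simulate_genotypes(800, 4, seed=8)
        B = np.array([[0.2], [0.1], [0.0], [0.3]])
        s1 = calibrate_error_variance(G, [0, 1, 2, 3], B, max_r2=0.05)
        s2 = calibrate_error_variance(G, [0, 1, 2, 3], 2 * B, max_r2=0.05)
        assert s2[0] ** 2 == pytest.approx(4 * s1[0] ** 2, rel=1e-10)


class TestSimulateTraits:
    def test_null_effects_leave_traits_unassociated(self):
        n = 3175
        G = simulate_genotypes(n, 60, seed=9)
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        Y = simulate_traits(G, [0, 1], np.zeros((2, 2)), R, np.ones(2), seed=10)
        X = G.values - G.values.mean(0)
        X /= np.linalg.norm(X, axis=0)
        for t in range(2):
            y = Y.values[:, t] - Y.values[:, t].mean()
            r = X.T @ y / np.linalg.norm(y)
            assert np.mean(np.abs(r) <= 4 / np.sqrt(n)) >= 0.95
        emp = np.corrcoef(Y.values.T)[0, 1]
        assert emp == pytest.approx(0.5, abs=3 / np.sqrt(n) + 0.01)

    def test_reference_residual_correlations(self):
        """Scenario-one residual correlations (0.95, 0.50, 0.30) are
        reproduced by the matrix-variate error draw."""
        mt1 = next(s for s in scenario_presets() if s.name == "MT1")
        rep = make_replicate(mt1.scaled(p=60, n=3175), seed=11)
        E = rep.Y.values - rep.G.values[:, rep.truth] @ rep.B
        emp = np.corrcoef((E / rep.sigma).T)
        expect = mt1.R
        assert np.allclose(emp, expect, atol=0.02)

    def test_variance_explained_matches_cap(self):
        # per-trait R^2 fluctuates ~0.01 through the error draw even at
        # n=3175, so the +/-0.01 band is checked on the mean over traits
        mt1 = next(s for s in scenario_presets() if s.name == "MT1")
        rep = make_replicate(mt1.scaled(p=60, n=3175), seed=12)
        Xc = rep.G.values[:, rep.truth]
        Xc = np.column_stack([np.ones(rep.G.n), Xc])
        r2s = []
        for t in range(rep.Y.q):
            y = rep.Y.values[:, t]
            beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
            resid = y - Xc @ beta
            r2s.append(1 - resid.var() / y.var())
        assert np.mean(r2s) == pytest.approx(0.05, abs=0.01)

    def test_non_pd_correlation_rejected(self):
        G = simulate_genotypes(100, 4, seed=13)
        R = np.array([[1.0, 1.2], [1.2, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            simulate_traits(G, [0], np.array([[0.2, 0.1]]), R, np.ones(2), seed=1)


class TestScenarioPresets:
    def test_multi_trait_designs(self):
        presets = {s.name: s for s in scenario_presets()}
        mt1, mt2 = presets["MT1"], presets["MT2"]
        assert mt1.B.shape == (8, 3) and mt1.q == 3
        assert mt1.R[0, 1] == 0.95 and mt1.R[1, 2] == 0.50 and mt1.R[0, 2] == 0.30
        assert mt2.R[0, 1] == 0.475 and mt2.R[1, 2] == 0.25 and mt2.R[0, 2] == 0.15
        assert np.allclose(mt1.B, mt2.B)
        for s in presets.values():
            assert s.max_r2 == 0.05 and s.n_replicates == 20 and s.n == 3175

    def test_single_trait_designs(self):
        presets = {s.name: s for s in scenario_presets()}
        st1, st2 = presets["ST1"], presets["ST2"]
        assert st1.q == 1
        assert np.allclose(st1.B[:, 0], [0.2, 0.1, 0.2, 0.1, 0.075, 0.1, 0.075, 0.1])
        assert np.allclose(st2.B[:, 0], [4, 1, 1, 6, 1.5, 3, 4, 0.5])
        assert st2.paired_secondary

    def test_st2_pairs_share_a_block(self):
        st2 = next(s for s in scenario_presets() if s.name == "ST2")
        rep = make_replicate(st2.scaled(p=120, n=300), seed=14)
        chrom = rep.G.map["chromosome"].to_numpy()
        assert len(rep.truth) == 8
        for b in range(4):
            pair = rep.truth[2 * b : 2 * b + 2]
            assert chrom[pair[0]] == chrom[pair[1]] == b + 1
            assert abs(pair[0] - pair[1]) <= 5


class TestEvaluateRoc:
    def test_perfect_scores(self):
        scores = np.zeros(50)
        truth = [3, 17, 40]
        scores[truth] = 1.0
        roc = evaluate_roc(scores, truth)
        at_full_power = roc[roc["power"] == 1.0]
        assert at_full_power["n_false_positives"].min() == 0

    def test_hand_enumerated_toy_curve(self):
        """Ten SNPs, truths at positions 2 and 7 with ranks 1 and 4: the
        power/FP staircase is enumerable by hand."""
        scores = np.array([0.1, 0.5, 0.9, 0.2, 0.05, 0.6, 0.3, 0.7, 0.15, 0.25])
        truth = [2, 7]
        roc = evaluate_roc(scores, truth)
        # score order: 2(T) 7(T) 5 1 6 9 3 8 0 4
        assert roc["power"].tolist() == pytest.approx(
            [0.5, 1, 1, 1, 1, 1, 1, 1, 1, 1]
        )
        assert roc["n_false_positives"].tolist() == [0, 0, 1, 2, 3, 4, 5, 6, 7, 8]

    def test_window_collapses_nearby_hits(self):
        G = simulate_genotypes(50, 20, ld_blocks=2, decay=0.5, seed=15)
        truth = [5]
        scores = np.zeros(20)
        scores[5] = 1.0
        scores[6] = 0.9  # within one 5 kb spacing of the truth
        scores[15] = 0.8  # other block: false positive
        roc = evaluate_roc(
            scores, truth, window_bp=25_000, snp_map=G.map, snp_ids=G.snp_ids
        )
        # the proxy hit at 6 is folded into the true interval, not an FP
        row = roc.iloc[1]
        assert row["power"] == 1.0 and row["n_false_positives"] == 0
        assert roc.iloc[2]["n_false_positives"] == 1

    def test_random_scores_near_diagonal(self):
        rng = np.random.default_rng(16)
        p = 4000
        truth = list(range(40))
        powers = []
        scores = rng.random(p)
        roc = evaluate_roc(scores, truth)
        half = roc[roc["fp_proportion"] >= 0.5].iloc[0]
        assert half["power"] == pytest.approx(0.5, abs=0.25)

    def test_fp_proportion_cap(self):
        scores = np.linspace(1, 0, 100)
        roc = evaluate_roc(scores, [0], fp_proportion_cap=0.1)
        assert roc["fp_proportion"].max() <= 0.1
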