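import numpy as np
import pytest

from cohortnet import synthetic
from cohortnet.network import (
    BootstrapSummary,
    SignificanceConfig,
    bootstrap_network,
    correlation_to_partial,
    edge_confidence_intervals,
    graphical_lasso,
    holm_correlations,
    lambda_grid,
    node_layout,
    occurrence_significance,
    sample_partial_correlations,
    select_lambda_cv,
)


def ggm_data(p=19, n=519, seed=7, density=0.2, rng_range=(0.25, 0.4)):
    spec = synthetic.GGMSpec(p=p, edge_density=density, partial_range=rng_range,
                             n_samples=n, seed=seed)
    x, truth = synthetic.generate_ggm_sample(spec)
    z = (x - x.mean(0)) / x.std(0, ddof=1)
    return z, truth


class TestPartialCorrelations:
    def test_independent_variables_give_zeros(self):
        np.testing.assert_allclose(correlation_to_partial(np.eye(4)), 0.0)

    def test_two_variables_equal_marginal(self):
        S = np.array([[1.0, 0.37], [0.37, 1.0]])
        part = correlation_to_partial(S)
        assert part[0, 1] == pytest.approx(0.37, abs=1e-12)

    def test_three_variable_chain_closed_form(self):
        """r12=r23=0.6, r13=0.36: conditioning removes the 1–3 link entirely
        and shrinks 1–2 to 0.384/0.74636."""
        S = np.array([
            [1.0, 0.6, 0.36],
            [0.6, 1.0, 0.6],
            [0.36, 0.6, 1.0],
        ])
        part = correlation_to_partial(S)
        assert part[0, 2] == pytest.approx(0.0, abs=1e-12)
        expected = (0.6 - 0.36 * 0.6) / np.sqrt((1 - 0.36**2) * (1 - 0.6**2))
        assert part[0, 1] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.5145, abs=2e-4)

    @pytest.mark.parametrize("p", [3, 5, 6])
    def test_matches_regress_out_oracle(self, p):
        """Partial correlations equal residual correlations after regressing
        out all other variables."""
        rng = np.random.default_rng(p)
        x = rng.standard_normal((400, p)) @ rng.standard_normal((p, p))
        est = sample_partial_correlations(x)
        for i in range(p):
            for j in range(i + 1, p):
                others = [c for c in range(p) if c not in (i, j)]
                A = np.column_stack([x[:, others], np.ones(len(x))])
                ri = x[:, i] - A @ np.linalg.lstsq(A, x[:, i], rcond=None)[0]
                rj = x[:, j] - A @ np.linalg.lstsq(A, x[:, j], rcond=None)[0]
                oracle = np.corrcoef(ri, rj)[0, 1]
                assert est[i, j] == pytest.approx(oracle, abs=1e-8)


class TestGraphicalLasso:
    def test_full_shrinkage_gives_empty_network(self):
        z, _ = ggm_data(p=6, n=200, seed=1)
        S = np.corrcoef(z, rowvar=False)
        lam = np.abs(S - np.eye(6)).max() * 1.01
        _, part = graphical_lasso(S, lam)
        assert np.all(part == 0)

    def test_unpenalised_limit_matches_inversion(self):
        z, _ = ggm_data(p=5, n=300, seed=2)
        S = np.corrcoef(z, rowvar=False)
        _, part0 = graphical_lasso(S, 0.0)
        np.testing.assert_allclose(
            part0, sample_partial_correlations(z), atol=1e-6
        )

    def test_kkt_certificate_on_chain(self):
        """The stationarity conditions of the penalised likelihood hold:
        |S − Σ̂| ≤ lam on zero precision entries, equality with the right
        sign on nonzeros."""
        S = np.array([
            [1.0, 0.6, 0.36],
            [0.6, 1.0, 0.6],
            [0.36, 0.6, 1.0],
        ])
        lam = 0.05
        omega, _ = graphical_lasso(S, lam, tol=1e-12, max_iter=2000,
                                   enet_tol=1e-12)
        sigma = np.linalg.inv(omega)
        for i in range(3):
            for j in range(3):
                if i == j:
                    assert sigma[i, j] == pytest.approx(S[i, j], abs=1e-6)
                elif omega[i, j] == 0:
                    assert abs(S[i, j] - sigma[i, j]) <= lam + 1e-6
                else:
                    assert sigma[i, j] - S[i, j] == pytest.approx(
                        lam * np.sign(omega[i, j]), abs=1e-6
                    )

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            graphical_lasso(np.eye(3), -0.1)


class TestLambdaSelection:
    def test_grid_spans_two_decades(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        grid = lambda_grid(S)
        assert len(grid) == 30
        assert grid[0] == pytest.approx(0.5)
        assert grid[-1] == pytest.approx(0.005)

    def test_selection_deterministic_and_interior(self):
        z, _ = ggm_data(p=19, n=500, seed=5)
        grid = lambda_grid(np.corrcoef(z, rowvar=False))
        lam1 = select_lambda_cv(z, seed=11, grid=grid[::3])
        lam2 = select_lambda_cv(z, seed=11, grid=grid[::3])
        assert lam1 == lam2
        assert grid[::3].min() < lam1 < grid[::3].max()


class TestBootstrap:
    def test_single_iteration_probabilities_binary(self):
        z, _ = ggm_data(p=5, n=120, seed=3)
        summ = bootstrap_network(z, B=1, seed=0, lambda_mode="fixed", lam=0.1)
        assert set(np.unique(summ.edge_probability)) <= {0.0, 1.0}

    def test_same_seed_bitwise_identical(self):
        z, _ = ggm_data(p=5, n=120, seed=4)
        s1 = bootstrap_network(z, B=25, seed=8, lambda_mode="fixed", lam=0.1)
        s2 = bootstrap_network(z, B=25, seed=8, lambda_mode="fixed", lam=0.1)
        assert np.array_equal(s1.edge_probability, s2.edge_probability)
        assert np.array_equal(s1.edge_counts, s2.edge_counts)
        assert np.array_equal(s1.ci_low, s2.ci_low)

    def test_strong_edges_highly_probable(self):
        """True edges with sizeable partials survive nearly every resample."""
        z, truth = ggm_data(p=8, n=519, seed=6, density=0.3,
                            rng_range=(0.35, 0.45))
        summ = bootstrap_network(z, B=100, seed=2, lambda_mode="fixed", lam=0.05)
        iu = np.triu_indices(8, 1)
        strong = np.abs(truth[iu]) >= 0.25
        assert np.all(summ.edge_probability[iu][strong] >= 0.9)

    def test_ci_mask_recovers_true_graph(self):
        """Bootstrapped CIs that exclude zero recover the generating edge
        set with high sensitivity and specificity."""
        z, truth = ggm_data(p=10, n=519, seed=12, density=0.2)
        lam = select_lambda_cv(z, seed=1)
        summ = bootstrap_network(z, B=120, seed=3, lambda_mode="fixed", lam=lam)
        iu = np.triu_indices(10, 1)
        tr = truth[iu] != 0
        sig = summ.significant_ci[iu]
        sens = (sig & tr).sum() / max(tr.sum(), 1)
        spec = (~sig & ~tr).sum() / max((~tr).sum(), 1)
        assert sens >= 0.7
        assert spec >= 0.9


class TestOccurrenceSignificance:
    def _summary(self, p, edge_counts, probability):
        return BootstrapSummary(
            n_iterations=len(edge_counts),
            edge_probability=probability,
            ci_low=np.zeros((p, p)),
            ci_high=np.zeros((p, p)),
            edge_counts=np.asarray(edge_counts),
            seed=0,
            lambda_mode="fixed",
        )

    def test_percentiles_follow_linear_interpolation_convention(self):
        p = 19
        rng = np.random.default_rng(0)
        counts = rng.integers(40, 80, size=3000)
        prob = np.zeros((p, p))
        summ = occurrence_significance(self._summary(p, counts, prob))
        assert summ.chance_count_uncorrected == pytest.approx(
            np.percentile(counts, 95.0)
        )
        assert summ.chance_count_bonferroni == pytest.approx(
            np.percentile(counts, 100 * (1 - 0.05 / 171))
        )
        assert summ.chance_fraction_uncorrected == pytest.approx(
            summ.chance_count_uncorrected / 171
        )

    def test_degenerate_bootstrap_constant_graph(self):
        """If every iteration returns the same c-edge graph, the chance
        count is c and edges are significant iff 1 > c/m."""
        p, c = 6, 4
        m = p * (p - 1) // 2
        prob = np.zeros((p, p))
        iu = np.triu_indices(p, 1)
        prob[iu[0][:c], iu[1][:c]] = 1.0
        prob[iu[1][:c], iu[0][:c]] = 1.0
        summ = occurrence_significance(
            self._summary(p, [c] * 50, prob),
            SignificanceConfig(m_edges=m),
        )
        assert summ.chance_count_uncorrected == c
        expected_sig = 1.0 > c / m
        assert bool(summ.significant_uncorrected[iu[0][0], iu[1][0]]) == expected_sig

    def test_bonferroni_mask_nested_in_uncorrected(self):
        z, _ = ggm_data(p=8, n=300, seed=9)
        summ = bootstrap_network(z, B=60, seed=4, lambda_mode="fixed", lam=0.08)
        assert not np.any(
            summ.significant_bonferroni & ~summ.significant_uncorrected
        )


class TestConfidenceIntervals:
    def test_degenerate_weight_distribution(self):
        p = 3
        summ = BootstrapSummary(
            n_iterations=10,
            edge_probability=np.ones((p, p)),
            ci_low=np.full((p, p), 0.4),
            ci_high=np.full((p, p), 0.4),
            edge_counts=np.full(10, 3),
            seed=0,
            lambda_mode="fixed",
        )
        edge_confidence_intervals(summ)
        assert summ.significant_ci.all()

    def test_rare_edge_not_significant(self):
        """An edge present in 1% of iterations has a CI straddling zero."""
        weights = np.zeros(3000)
        weights[:30] = 0.5
        lo, hi = np.percentile(weights, [2.5, 97.5])
        assert lo == 0.0 and hi == 0.0  # mass at zero dominates
        p = 2
        summ = BootstrapSummary(
            n_iterations=3000,
            edge_probability=np.full((p, p), 0.01),
            ci_low=np.full((p, p), lo),
            ci_high=np.full((p, p), hi),
            edge_counts=np.zeros(3000, int),
            seed=0,
            lambda_mode="fixed",
        )
        edge_confidence_intervals(summ)
        assert not summ.significant_ci.any()

    def test_bounds_match_sorting_oracle(self):
        """The stored CI bounds follow the linear-interpolation percentile
        convention, checked against a hand-rolled order-statistic oracle."""
        rng = np.random.default_rng(5)
        w = rng.standard_normal(200)

        def interp_percentile(values, q):
            s = np.sort(values)
            pos = q / 100 * (len(s) - 1)
            lo = int(np.floor(pos))
            hi = min(lo + 1, len(s) - 1)
            return s[lo] + (pos - lo) * (s[hi] - s[lo])

        assert np.percentile(w, 2.5) == pytest.approx(interp_percentile(w, 2.5))
        assert np.percentile(w, 97.5) == pytest.approx(interp_percentile(w, 97.5))


class TestNodeLayout:
    def test_duplicated_variables_nearly_coincide(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(150)
        x = np.column_stack([
            base,
            base,
            rng.standard_normal(150),
            rng.standard_normal(150),
        ])
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        coords = node_layout(z, seed=0)
        d01 = np.linalg.norm(coords[0] - coords[1])
        d02 = np.linalg.norm(coords[0] - coords[2])
        assert d01 < 0.05 * d02

    def test_chain_places_middle_variable_centrally(self):
        """For a 1–2–3 correlation chain the middle variable has the
        smallest summed distance to the others."""
        rng = np.random.default_rng(2)
        n = 600
        v2 = rng.standard_normal(n)
        v1 = 0.8 * v2 + 0.6 * rng.standard_normal(n)
        v3 = 0.8 * v2 + 0.6 * rng.standard_normal(n)
        z = np.column_stack([v1, v2, v3])
        z = (z - z.mean(0)) / z.std(0, ddof=1)
        coords = node_layout(z, seed=0)
        sums = [
            sum(np.linalg.norm(coords[i] - coords[j]) for j in range(3) if j != i)
            for i in range(3)
        ]
        # with only three dissimilarities the monotone regression may pool
        # tied ranks, so the middle node can tie the minimum but never lose it
        assert sums[1] <= min(sums) * 1.001


class TestHolmCorrelations:
    def test_step_down_thresholds(self):
        """Holm compares sorted p-values against α/(m−i): all four of the
        worked p-values clear their thresholds."""
        from statsmodels.stats.multitest import multipletests

        reject, _, _, _ = multipletests(
            [0.001, 0.01, 0.02, 0.04], alpha=0.05, method="holm"
        )
        assert reject.all()

    def test_single_pair_reduces_to_plain_alpha(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        x = rng.standard_normal((60, 2))
        x[:, 1] += 0.5 * x[:, 0]
        corr, mask = holm_correlations(x, alpha=0.05)
        pval = stats.pearsonr(x[:, 0], x[:, 1]).pvalue
        assert bool(mask[0, 1]) == (pval <= 0.05)
        assert corr[0, 1] == pytest.approx(np.corrcoef(x.T)[0, 1])

    def test_strong_signal_survives_null_noise_does_not(self):
        rng = np.random.default_rng(4)
        n = 300
        a = rng.standard_normal(n)
        b = 0.8 * a + 0.6 * rng.standard_normal(n)
        noise = rng.standard_normal((n, 3))
        x = np.column_stack([a, b, noise])
        _, mask = holm_correlations(x, alpha=0.05)
        assert mask[0, 1]
        assert not mask[2, 3] and not mask[2, 4] and not mask[3, 4]
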