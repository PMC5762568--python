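import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from _helpers import beta_regression_grid_oracle, spearman_exact
from habitatmri.associations import (
    bonferroni,
    boundary_transform,
    fit_dirichlet_regression,
    pathway_screen,
    rank_by_magnitude,
    spearman_test,
    subvolume_screen,
)


class TestSpearman:
    def test_monotone_identity_and_antitone(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert spearman_test(x, 2 * x).rho == pytest.approx(1.0)
        assert spearman_test(x, 2 * x).p == 0.0
        assert spearman_test(x, -x).rho == pytest.approx(-1.0)

    def test_tied_sample_matches_exact_permutation_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0])  # one tie
        y = np.array([0.3, 0.1, 0.8, 0.5, 0.9])
        rho_exact, p_exact = spearman_exact(x, y)
        res = spearman_test(x, y)
        assert res.rho == pytest.approx(rho_exact, abs=1e-10)
        # t-approximation vs exact enumeration: same order of magnitude at n=5
        assert abs(res.p - p_exact) < 0.15

    def test_constant_vector_is_flagged_not_fatal(self):
        res = spearman_test(np.ones(6), np.arange(6.0))
        assert not res.valid and np.isnan(res.rho)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="n >= 4"):
            spearman_test(np.arange(3.0), np.arange(3.0))


class TestBoundaryTransform:
    def test_endpoints_and_fixed_point(self):
        assert boundary_transform(np.array(0.0), 85) == pytest.approx(1 / 170)
        assert boundary_transform(np.array(1.0), 85) == pytest.approx(1 - 1 / 170)
        assert boundary_transform(np.array(0.5), 85) == 0.5
        assert boundary_transform(np.array(0.5), 12345) == 0.5

    def test_order_preserving_interior(self):
        y = np.array([0.0, 0.2, 0.5, 0.9, 1.0])
        out = boundary_transform(y, 30)
        assert np.all(np.diff(out) > 0)
        assert np.all((out > 0) & (out < 1))


def _sim_two_part(seed, n=60, slope=0.8, intercepts=(1.0, 1.0)):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n)
    a = np.exp(intercepts[0] + slope * x)
    b = np.exp(intercepts[1])
    y = rng.beta(a, b)
    return boundary_transform(y, n), x


class TestDirichletRegression:
    def test_component_exchange_symmetry(self):
        y1, x = _sim_two_part(0)
        fit = fit_dirichlet_regression(y1, x)
        swapped = fit_dirichlet_regression(1.0 - y1, x)
        np.testing.assert_allclose(swapped.beta, fit.beta[[2, 3, 0, 1]], atol=1e-6)
        # the association coefficient negates exactly under component swap
        assert swapped.coefficient == pytest.approx(-fit.coefficient, abs=1e-6)

    def test_ascent_property_over_all_starts(self):
        for seed in range(5):
            y1, x = _sim_two_part(seed)
            fit = fit_dirichlet_regression(y1, x)
            assert fit.converged
            assert fit.loglik >= max(fit.start_logliks) - 1e-9

    def test_optimum_at_least_null_model_with_refitted_intercepts(self):
        y1, x = _sim_two_part(3)
        fit = fit_dirichlet_regression(y1, x)

        def null_nll(theta):
            a, b = np.exp(theta[0]), np.exp(theta[1])
            return -np.sum(stats.beta.logpdf(y1, a, b))

        null = optimize.minimize(null_nll, np.zeros(2), method="Nelder-Mead")
        assert fit.loglik >= -null.fun - 1e-6

    def test_matches_beta_likelihood_grid_oracle_on_toy_cohort(self):
        y1, x = _sim_two_part(7, n=20, slope=0.6)
        fit = fit_dirichlet_regression(y1, x)
        oracle_slope = beta_regression_grid_oracle(y1, x)
        assert fit.coefficient == pytest.approx(oracle_slope, abs=1e-3)

    def test_degenerate_inputs_rejected(self):
        y1, x = _sim_two_part(1, n=20)
        with pytest.raises(ValueError, match="zero variance"):
            fit_dirichlet_regression(y1, np.zeros(20))
        with pytest.raises(ValueError, match="n >= 10"):
            fit_dirichlet_regression(y1[:5], x[:5])
        with pytest.raises(ValueError, match="boundary_transform"):
            fit_dirichlet_regression(np.linspace(0, 1, 20), x)


class TestScreens:
    def test_bonferroni_arithmetic(self):
        assert bonferroni(0.01, 10) == pytest.approx(0.10)
        assert bonferroni(0.3, 10) == 1.0

    def test_rank_by_magnitude_splits_directions(self):
        table = pd.DataFrame(
            {
                "pathway": list("abcd"),
                "coefficient": [3.0, 2.0, -2.5, 0.1],
                "direction": ["up", "up", "down", "up"],
            }
        )
        ranked = rank_by_magnitude(table).set_index("pathway")
        assert list(ranked.loc[["a", "b", "d"], "rank"]) == [1.0, 2.0, 3.0]
        assert ranked.loc["c", "rank"] == 1.0

    def test_pathway_screen_ranks_planted_linkage_first(self):
        rng = np.random.default_rng(42)
        n = 85
        p_h = rng.dirichlet(np.full(16, 0.5), size=n)[:, 2]
        ids = [f"P{i}" for i in range(n)]
        logit = np.log(
            boundary_transform(p_h, n) / (1 - boundary_transform(p_h, n))
        )
        scores = pd.DataFrame(
            {
                "linked_up": 2.0 * logit + rng.normal(0, 0.4, n),
                "null_a": rng.normal(size=n),
                "null_b": rng.normal(size=n),
                "linked_down": -2.0 * logit + rng.normal(0, 0.4, n),
            },
            index=pd.Index(ids, name="patient_id"),
        )
        table = pathway_screen(
            pd.Series(p_h, index=ids, name="p_2"), scores
        ).set_index("pathway")
        assert table.loc["linked_up", "direction"] == "up"
        assert table.loc["linked_up", "rank"] == 1.0
        assert table.loc["linked_down", "direction"] == "down"
        assert table.loc["linked_down", "rank"] == 1.0
        assert table.loc["linked_up", "bonferroni_p"] < 0.05
        # Bonferroni multiplies by the number of pathways tested (4)
        assert table.loc["null_a", "bonferroni_p"] == pytest.approx(
            min(1.0, table.loc["null_a", "raw_p"] * 4)
        )

    def test_subvolume_screen_mechanical_equality_and_shape(self):
        n = 30
        rng = np.random.default_rng(0)
        comp = pd.DataFrame(
            {f"p_{h}": rng.uniform(0, 1, n) for h in range(16)},
            index=pd.Index([f"P{i}" for i in range(n)], name="patient_id"),
        )
        sub = pd.DataFrame(
            {
                "necrosis": comp["p_2"],  # mechanically identical
                "edema": rng.uniform(0, 1, n),
                "non_enhancing": rng.uniform(0, 1, n),
                "enhancing": rng.uniform(0, 1, n),
            },
            index=comp.index,
        )
        table = subvolume_screen(comp, sub, [2, 7])
        assert len(table) == 8  # 4 sub-volumes per habitat
        row = table[(table.habitat == 2) & (table.subvolume == "necrosis")].iloc[0]
        assert row.rho == pytest.approx(1.0)
        indep = table[(table.habitat == 7)]
        assert np.all(np.abs(indep.rho) < 0.5)
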