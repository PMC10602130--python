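"""Variance-component REML: oracles, boundary LRT, heritability partition."""

import numpy as np
import pytest
from scipy import stats

from feiscan.varcomp import (
    fit_vc,
    heritability_partition,
    lrt_variance_component,
    observed_to_liability,
    _reml_nll_grad,
)


def _family_k(n_pairs, n_singles):
    """Block-diagonal kinship: sib pairs then singletons."""
    n = 2 * n_pairs + n_singles
    k = np.eye(n)
    for i in range(n_pairs):
        k[2 * i, 2 * i + 1] = k[2 * i + 1, 2 * i] = 0.5
    return k


def _simulate_gaussian(k, s2_g, s2_e, rng, beta=()):
    n = k.shape[0]
    x = np.column_stack([np.ones(n)] + [rng.standard_normal(n) for _ in beta])
    g = np.linalg.cholesky(k + 1e-10 * np.eye(n)) @ rng.standard_normal(n) * np.sqrt(s2_g)
    y = x @ np.array([0.5, *beta]) + g + rng.standard_normal(n) * np.sqrt(s2_e)
    return y, x


class TestFitVC:
    def test_collinear_components_rejected(self):
        n = 20
        y = np.random.default_rng(0).standard_normal(n)
        x = np.ones((n, 1))
        with pytest.raises(ValueError, match="collinear"):
            fit_vc(y, x, [np.eye(n), np.eye(n)])

    def test_single_component_matches_grid_search_oracle(self):
        """REML optimum equals a brute-force grid search of the restricted
        likelihood on a 40-subject family fixture."""
        rng = np.random.default_rng(7)
        k = _family_k(15, 10)
        y, x = _simulate_gaussian(k, 0.6, 0.4, rng)
        fit = fit_vc(y, x, [k], component_names=["g"])
        # oracle: dense grid over (s2_g, s2_e)
        grid = np.linspace(1e-4, 2.5, 120)
        best, best_nll = None, np.inf
        for a in grid:
            for b in grid:
                nll = _reml_nll_grad(np.array([a, b]), [k], y, x)[0]
                if nll < best_nll:
                    best, best_nll = (a, b), nll
        assert fit.variances["g"] == pytest.approx(best[0], abs=2e-2)
        assert fit.variances["e"] == pytest.approx(best[1], abs=2e-2)
        # optimizer must do at least as well as the grid
        assert -fit.loglik_reml <= best_nll + 1e-6

    def test_gls_matches_weighted_least_squares(self):
        """At the optimum V, fixed effects equal the closed-form GLS."""
        rng = np.random.default_rng(21)
        k = _family_k(10, 10)
        y, x = _simulate_gaussian(k, 0.5, 0.5, rng, beta=(0.8,))
        fit = fit_vc(y, x, [k], component_names=["g"])
        v = fit.variances["g"] * k + fit.variances["e"] * np.eye(len(y))
        vi = np.linalg.inv(v)
        beta_gls = np.linalg.solve(x.T @ vi @ x, x.T @ vi @ y)
        np.testing.assert_allclose(fit.betas, beta_gls, atol=1e-8)

    def test_rescaling_y_scales_variances(self):
        rng = np.random.default_rng(5)
        k = _family_k(12, 6)
        y, x = _simulate_gaussian(k, 0.5, 0.5, rng)
        f1 = fit_vc(y, x, [k], component_names=["g"])
        f2 = fit_vc(3.0 * y, x, [k], component_names=["g"])
        assert f2.variances["g"] == pytest.approx(9.0 * f1.variances["g"], rel=1e-3, abs=1e-6)
        assert f2.variances["e"] == pytest.approx(9.0 * f1.variances["e"], rel=1e-3)

    def test_null_component_estimated_at_boundary(self):
        """Data generated without a mutation component: the extra component
        lands at the zero boundary in most replicates."""
        rng = np.random.default_rng(13)
        k = _family_k(15, 30)
        n = k.shape[0]
        # mutation-sharing blocks across families
        m = np.kron(np.eye(n // 4), np.ones((4, 4)))[:n, :n]
        np.fill_diagonal(m, 1.0)
        at_zero = 0
        reps = 30
        for _ in range(reps):
            y, x = _simulate_gaussian(k, 0.5, 0.5, rng)
            fit = fit_vc(y, x, [k, m], component_names=["g", "m"])
            at_zero += fit.variances["m"] < 1e-4
        assert at_zero > reps / 2

    def test_local_optimality_on_grid(self):
        """Restricted likelihood at the optimum beats a surrounding 5x5 grid."""
        rng = np.random.default_rng(3)
        k = _family_k(12, 8)
        y, x = _simulate_gaussian(k, 0.4, 0.6, rng)
        fit = fit_vc(y, x, [k], component_names=["g"])
        theta = np.array([fit.variances["g"], fit.variances["e"]])
        nll_opt = -fit.loglik_reml
        for dg in np.linspace(-0.05, 0.05, 5):
            for de in np.linspace(-0.05, 0.05, 5):
                trial = np.maximum(theta + [dg, de], 1e-8)
                assert _reml_nll_grad(trial, [k], y, x)[0] >= nll_opt - 1e-6


class TestPooledREML:
    def test_single_block_matches_plain_fit(self):
        from feiscan.varcomp import fit_vc_pooled

        rng = np.random.default_rng(8)
        k = _family_k(12, 8)
        y, x = _simulate_gaussian(k, 0.5, 0.5, rng)
        plain = fit_vc(y, x, [k], component_names=["g"])
        pooled = fit_vc_pooled([(y, x, [k])], ["g"], n_restarts=2)
        assert pooled.variances["g"] == pytest.approx(plain.variances["g"], abs=1e-4)
        assert pooled.variances["e"] == pytest.approx(plain.variances["e"], abs=1e-4)
        assert pooled.loglik_reml == pytest.approx(plain.loglik_reml, abs=1e-6)

    def test_pooling_tightens_estimates_toward_truth(self):
        from feiscan.varcomp import fit_vc_pooled

        rng = np.random.default_rng(9)
        k = _family_k(20, 0)
        blocks = []
        for _ in range(25):
            y, x = _simulate_gaussian(k, 0.6, 0.4, rng)
            blocks.append((y, x, [k]))
        pooled = fit_vc_pooled(blocks, ["g"], n_restarts=2)
        assert pooled.converged
        tot = pooled.sigma2_total
        # 500 sib pairs: sampling SE of the pooled h2 is under 0.1
        assert pooled.variances["g"] / tot == pytest.approx(0.6, abs=0.15)


class TestLRT:
    def _two_fits(self, rng=None):
        rng = rng or np.random.default_rng(2)
        k = _family_k(10, 10)
        n = k.shape[0]
        m = np.kron(np.eye(n // 3 + 1), np.ones((3, 3)))[:n, :n]
        np.fill_diagonal(m, 1.0)
        y, x = _simulate_gaussian(k, 0.5, 0.5, rng)
        full = fit_vc(y, x, [k, m], component_names=["g", "m"])
        reduced = fit_vc(y, x, [k], component_names=["g"])
        return full, reduced

    def test_boundary_mixture_p_values(self):
        full, reduced = self._two_fits()
        p = lrt_variance_component(full, reduced)
        lam = max(0.0, 2.0 * (full.loglik_reml - reduced.loglik_reml))
        assert p == pytest.approx(0.5 * stats.chi2.sf(lam, 1))
        # closed forms of the 50:50 mixture
        assert 0.5 * stats.chi2.sf(0.0, 1) == pytest.approx(0.5)
        assert 0.5 * stats.chi2.sf(2.706, 1) == pytest.approx(0.05, abs=5e-4)

    def test_mismatched_data_rejected(self):
        full, _ = self._two_fits(np.random.default_rng(2))
        _, other_reduced = self._two_fits(np.random.default_rng(3))
        with pytest.raises(ValueError, match="different data"):
            lrt_variance_component(full, other_reduced)

    def test_type_i_error_at_nominal_level(self):
        """Null simulations (no mutation variance): rejection rate at
        alpha=0.05 stays within the binomial 95% CI."""
        rng = np.random.default_rng(17)
        k = _family_k(25, 50)
        n = k.shape[0]
        m = np.kron(np.eye(n // 5), np.ones((5, 5)))[:n, :n]
        np.fill_diagonal(m, 1.0)
        reps, rejections = 200, 0
        for _ in range(reps):
            y, x = _simulate_gaussian(k, 0.4, 0.6, rng)
            full = fit_vc(y, x, [k, m], component_names=["g", "m"], n_restarts=2)
            reduced = fit_vc(y, x, [k], component_names=["g"], n_restarts=2)
            rejections += lrt_variance_component(full, reduced) < 0.05
        # binomial 95% CI around 0.05 with 200 draws: (0.020, 0.080)
        assert 0.019 <= rejections / reps <= 0.081


class TestHeritability:
    def test_partition_of_reported_components(self):
        """Mutation share of total genetic signal: 0.08/(0.08+0.47) ~ 15%."""
        from feiscan.varcomp import VCFit

        fit = VCFit(
            variances={"g": 0.47, "m": 0.08, "e": 0.45},
            intercept=0.0, betas=np.zeros(1), beta_names=["x0"],
            beta_se=np.zeros(1), loglik_reml=0.0, loglik_ml=0.0,
            converged=True, n_subjects=450, component_names=["g", "m"],
            data_fingerprint="x",
        )
        rep = heritability_partition(fit)
        assert rep.mutation_share == pytest.approx(0.08 / (0.08 + 0.47), abs=1e-12)
        assert round(100 * rep.mutation_share) == 15
        assert rep.h2_g == pytest.approx(0.47)
        assert rep.h2_m == pytest.approx(0.08)

    @pytest.mark.parametrize(
        "s2_m, s2_g, expected",
        [(0.0, 0.3, 0.0), (0.2, 0.2, 0.5)],
    )
    def test_partition_edge_cases(self, s2_m, s2_g, expected):
        from feiscan.varcomp import VCFit

        fit = VCFit(
            variances={"g": s2_g, "m": s2_m, "e": 0.5},
            intercept=0.0, betas=np.zeros(1), beta_names=["x0"],
            beta_se=np.zeros(1), loglik_reml=0.0, loglik_ml=0.0,
            converged=True, n_subjects=10, component_names=["g", "m"],
            data_fingerprint="x",
        )
        assert heritability_partition(fit).mutation_share == pytest.approx(expected)

    def test_zero_genetic_signal_share_undefined(self):
        from feiscan.varcomp import VCFit

        fit = VCFit(
            variances={"g": 0.0, "m": 0.0, "e": 1.0},
            intercept=0.0, betas=np.zeros(1), beta_names=["x0"],
            beta_se=np.zeros(1), loglik_reml=0.0, loglik_ml=0.0,
            converged=True, n_subjects=10, component_names=["g", "m"],
            data_fingerprint="x",
        )
        assert heritability_partition(fit).mutation_share is None


class TestLiabilityScale:
    def test_half_prevalence_multiplier_is_half_pi(self):
        assert observed_to_liability(1.0, 0.5) == pytest.approx(np.pi / 2, rel=1e-12)

    def test_zero_heritability_stays_zero(self):
        assert observed_to_liability(0.0, 0.3) == 0.0

    def test_cohort_prevalence_closed_form(self):
        t = stats.norm.isf(0.185)
        z = stats.norm.pdf(t)
        expected = 0.30 * 0.185 * 0.815 / z**2
        assert observed_to_liability(0.30, 0.185) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("prev", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_prevalence_rejected(self, prev):
        with pytest.raises(ValueError):
            observed_to_liability(0.3, prev)
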