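import numpy as np
import pytest
from scipy.stats import beta as beta_dist
from scipy.stats import chi2

from sreassoc.chi2mix import chi2mix_quantile, chi2mix_sf, liu_sf, spherical_sf
from sreassoc.skato import AssocConfig, fit_null_model, skat_o

from conftest import toy_bin
from oracles import burden_score_test, mc_chi2mix_sf, skato_permutation_p


class TestChi2MixSf:
    def test_single_coefficient_is_chi2(self):
        assert chi2mix_sf(3.841459, [1.0]).p == pytest.approx(0.05, abs=1e-6)

    def test_equal_pair_is_chi2_2df(self):
        assert chi2mix_sf(5.991465, [1.0, 1.0]).p == pytest.approx(0.05, abs=1e-6)

    def test_scale_equivariance(self):
        # P(sum c*lam chi2 > c*q) = P(sum lam chi2 > q)
        lam = [2.3, 1.1, 0.4]
        a = chi2mix_sf(8.0, lam).p
        b = chi2mix_sf(40.0, [5 * l for l in lam]).p
        assert a == pytest.approx(b, rel=1e-7)

    def test_against_monte_carlo(self):
        rng = np.random.default_rng(3)
        for _ in range(4):
            lam = rng.uniform(0.2, 3.0, rng.integers(2, 6))
            q = float(rng.uniform(0.5, 2.0) * lam.sum())
            p = chi2mix_sf(q, lam).p
            p_mc, se = mc_chi2mix_sf(q, lam, 1_000_000, seed=int(q * 1000))
            assert abs(p - p_mc) <= 3 * se

    def test_liu_fallback_close_to_imhof(self):
        lam = [2.0, 1.0, 0.5]
        assert liu_sf(5.0, lam) == pytest.approx(chi2mix_sf(5.0, lam).p, abs=0.01)

    def test_quantile_round_trip(self):
        lam = [1.7, 0.6, 0.2]
        for p in (0.5, 0.05, 1e-4):
            q = chi2mix_quantile(p, lam)
            assert chi2mix_sf(q, lam).p == pytest.approx(p, rel=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            chi2mix_sf(1.0, [])
        with pytest.raises(ValueError):
            chi2mix_sf(1.0, [1.0, -0.5])
        with pytest.raises(ValueError):
            chi2mix_sf(-1.0, [1.0])

    def test_tiny_tail_clipped_positive(self):
        assert 0 < chi2mix_sf(5000.0, [1.0, 0.5]).p < 1e-300 * 10


class TestSphericalSf:
    def test_rank_one_closed_form(self):
        # lambda*u1^2 > c on a dim-d sphere: u1^2 ~ Beta(1/2, (d-1)/2)
        d, lam, c = 47, 2.5, 0.31
        expected = beta_dist.sf(c / lam, 0.5, (d - 1) / 2)
        assert spherical_sf(c, [lam], d) == pytest.approx(expected, rel=1e-9)

    def test_converges_to_chi2_mixture_for_large_dim(self):
        lam = np.array([2.0, 1.0, 0.4])
        q = 5.0
        # T = sum lam z^2 / ||z||^2 with ||z||^2 ~ dim: compare at q/dim
        big = spherical_sf(q / 100_000, lam, 100_000)
        assert big == pytest.approx(chi2mix_sf(q, lam).p, rel=5e-3)

    def test_matches_direct_sphere_monte_carlo(self):
        rng = np.random.default_rng(11)
        lam = np.array([1.8, 0.9, 0.3])
        d = 40
        z = rng.standard_normal((400_000, d))
        t = (lam * z[:, :3] ** 2).sum(1) / (z**2).sum(1)
        for c in (0.05, 0.1, 0.2):
            p_mc = (t > c).mean()
            se = np.sqrt(p_mc * (1 - p_mc) / t.size)
            assert abs(spherical_sf(c, lam, d) - p_mc) <= 3.5 * se

    def test_bounds(self):
        assert spherical_sf(0.0, [1.0, 0.5], 10) == 1.0
        assert spherical_sf(1.01, [1.0, 0.5], 10) < 1e-250


class TestFitNullModel:
    def test_exact_linear_phenotype_zero_residuals(self):
        rng = np.random.default_rng(0)
        age = rng.normal(70, 7, 50)
        sex = rng.binomial(1, 0.5, 50)
        y = 1.0 + 0.5 * age - 2.0 * sex
        null = fit_null_model(y, np.column_stack([age, sex]))
        assert np.abs(null.residuals).max() < 1e-9

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(1)
        age = rng.normal(70, 7, 200)
        sex = rng.binomial(1, 0.5, 200)
        y = rng.normal(size=200)
        null = fit_null_model(y, np.column_stack([age, sex]))
        assert np.abs(null.X.T @ null.residuals).max() < 1e-8

    def test_sigma2_consistent(self):
        rng = np.random.default_rng(2)
        n = 5000
        age = rng.normal(70, 7, n)
        sex = rng.binomial(1, 0.5, n)
        y = 0.02 * age + 0.1 * sex + rng.normal(0, 1, n)
        null = fit_null_model(y, np.column_stack([age, sex]))
        assert 0.9 <= null.sigma2 <= 1.1

    def test_singular_design_names_column(self):
        rng = np.random.default_rng(3)
        age = rng.normal(70, 7, 30)
        sex = np.ones(30)  # constant: collinear with intercept
        y = rng.normal(size=30)
        import pandas as pd

        with pytest.raises(ValueError, match="collinear"):
            fit_null_model(y, pd.DataFrame({"age": age, "sex": sex}))

    def test_missing_samples_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        age = rng.normal(70, 7, 40)
        sex = rng.binomial(1, 0.5, 40)
        y = rng.normal(size=40)
        y[3] = np.nan
        with pytest.warns(UserWarning, match="dropping 1"):
            null = fit_null_model(y, np.column_stack([age, sex]))
        assert null.n == 39
        assert null.kept.sum() == 39


class TestSkatO:
    def test_m1_equals_single_variant_score_test(self):
        b, null = toy_bin(200, 1, seed=1, effect=0.4)
        res = skat_o(b, null)
        # independent closed form: exact spherical single-variant test
        g = b.G[:, 0]
        X = null.X
        g_perp = g - X @ np.linalg.lstsq(X, g, rcond=None)[0]
        r = null.residuals
        u1sq = (g @ r) ** 2 / ((g_perp @ g_perp) * (r @ r))
        d = null.n - X.shape[1]
        p_oracle = float(beta_dist.sf(u1sq, 0.5, (d - 1) / 2))
        assert res.p_skato == pytest.approx(p_oracle, rel=1e-8)
        spread = max(res.per_rho_p.values()) - min(res.per_rho_p.values())
        assert spread < 1e-12

    def test_rho1_equals_weighted_burden_test(self):
        b, null = toy_bin(300, 4, seed=2, effect=0.3)
        res = skat_o(b, null)
        p_burden = burden_score_test(b.G, b.mafs, null)
        assert res.per_rho_p[1.0] == pytest.approx(p_burden, rel=1e-6)

    def test_p_bounds_invariants(self):
        for seed in range(5):
            b, null = toy_bin(150, 4, seed=seed, effect=0.2 * seed)
            res = skat_o(b, null)
            pmin = min(res.per_rho_p.values())
            assert pmin <= res.p_skato <= min(1.0, pmin * len(res.per_rho_p))
            assert all(0 < p <= 1 for p in res.per_rho_p.values())

    def test_invariance_to_phenotype_affine_transform(self):
        rng = np.random.default_rng(9)
        n, m = 180, 3
        mafs = rng.uniform(0.05, 0.3, m)
        G = rng.binomial(2, mafs, size=(n, m)).astype(float)
        age = rng.normal(70, 7, n)
        sex = rng.binomial(1, 0.5, n)
        y = 0.02 * age + 0.3 * G[:, 0] + rng.normal(0, 1, n)
        from sreassoc.binning import GeneBin

        def run(yv):
            null = fit_null_model(yv, np.column_stack([age, sex]))
            b = GeneBin("g", [f"c:{i}" for i in range(m)], [f"r{i}" for i in range(m)], G, mafs, int(G.sum()))
            return skat_o(b, null)

        base = run(y)
        scaled = run(7.3 * y)
        shifted = run(y + 42.0)
        for rho in base.per_rho_p:
            assert scaled.per_rho_p[rho] == pytest.approx(base.per_rho_p[rho], rel=1e-6)
            assert shifted.per_rho_p[rho] == pytest.approx(base.per_rho_p[rho], rel=1e-6)
        assert scaled.p_skato == pytest.approx(base.p_skato, rel=1e-3)
        assert shifted.p_skato == pytest.approx(base.p_skato, rel=1e-3)

    def test_agrees_with_permutation_oracle_small_instances(self):
        cfg = AssocConfig(mc_draws=1_000_000)
        for seed, (n, m, eff) in enumerate([(50, 2, 0.6), (50, 3, 0.8), (60, 5, 0.7)]):
            b, null = toy_bin(n, m, seed=200 + seed, effect=eff)
            res = skat_o(b, null, cfg)
            p_perm, se = skato_permutation_p(b, null, cfg, B=60_000, seed=seed)
            assert abs(res.p_skato - p_perm) <= 4 * se + 1e-4

    def test_duplicated_columns_warn(self):
        b, null = toy_bin(100, 2, seed=3)
        b.G[:, 1] = b.G[:, 0]
        with pytest.warns(UserWarning, match="correlated"):
            skat_o(b, null)

    def test_monomorphic_bin_rejected(self):
        b, null = toy_bin(100, 2, seed=4)
        b.G[:] = 0.0
        with pytest.raises(ValueError, match="polymorphic"):
            skat_o(b, null)

    def test_misaligned_cohort_rejected(self):
        b, null = toy_bin(100, 2, seed=5)
        b.G = b.G[:50]
        with pytest.raises(ValueError, match="do not match"):
            skat_o(b, null)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"rho_grid": (0.0, 0.5)},  # missing 1
            {"rho_grid": (0.5, 1.0)},  # missing 0
            {"rho_grid": (0.0, 1.5, 1.0)},
            {"weight_beta": (0.0, 25.0)},
        ],
    )
    def test_invalid_config(self, kwargs):
        with pytest.raises(ValueError):
            AssocConfig(**kwargs)
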