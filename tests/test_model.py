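"""Decay-model mathematics: scaling, covariance, likelihood, priors,
back-transformation, summaries and the sampling contract."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hetdecay as hd
from hetdecay.model import (
    _ScaledPosterior,
    map_line_given_kernel,
    mvn_logpdf,
    percent_decline_params,
)

from conftest import random_decay_data


class TestGeo:
    def test_one_degree_meridian(self):
        coords = np.array([[0.0, 0.0], [0.0, 1.0]])
        D = hd.geo_distance_matrix(coords, "great_circle_km")
        assert D[0, 1] == pytest.approx(111.195, abs=0.01)

    def test_duplicate_point_and_symmetry(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform([-120, 30], [-90, 60], size=(6, 2))
        coords[1] = coords[0]
        for metric in ("great_circle_km", "euclidean_degrees"):
            D = hd.geo_distance_matrix(coords, metric)
            assert D[0, 1] == 0.0
            assert np.array_equal(D, D.T)
            assert np.all(np.diag(D) == 0)

    def test_out_of_range_coordinates(self):
        with pytest.raises(ValueError):
            hd.geo_distance_matrix(np.array([[200.0, 0.0]]))


class TestScaling:
    def test_h_scaled_by_max(self, small_meta):
        data = hd.build_decay_data(np.array([1e-4, 2e-4, 1.5e-4]), small_meta)
        scaled, rec = hd.scale_inputs(data)
        assert scaled.H.tolist() == pytest.approx([0.5, 1.0, 0.75])
        assert rec.h_max == 2e-4

    def test_t_spans_unit_interval(self, small_meta):
        data = hd.build_decay_data(np.array([1e-4, 2e-4, 1.5e-4]), small_meta)
        scaled, rec = hd.scale_inputs(data)
        assert scaled.T.min() == 0.0 and scaled.T.max() == 1.0
        assert (rec.t_min, rec.t_max) == (1902, 2009)
        assert scaled.D.max() == 1.0

    def test_constant_years_error(self, small_meta):
        meta = [m.__class__(m.sample_id, m.longitude, m.latitude, 1950)
                for m in small_meta]
        data = hd.build_decay_data(np.array([1e-4, 2e-4, 1.5e-4]), meta)
        with pytest.raises(ValueError, match="unidentifiable"):
            hd.scale_inputs(data)


class TestPoweredExpCov:
    def test_zero_distance_gives_sill(self):
        D = np.zeros((3, 3))
        S = hd.powered_exp_cov(D, alpha0=2.0, alpha1=1.0, alpha2=1.0, jitter=0.0)
        assert np.allclose(S, 2.0)

    @pytest.mark.parametrize(
        "a0,a1,a2,d,expected",
        [
            (1.0, 1.0, 1.0, 1.0, np.exp(-1.0)),
            (1.0, 0.5, 2.0 - 1e-12, 2.0, np.exp(-2.0)),
            (3.0, 2.0, 0.5, 4.0, 3.0 * np.exp(-4.0)),
        ],
    )
    def test_off_diagonal_values(self, a0, a1, a2, d, expected):
        D = np.array([[0.0, d], [d, 0.0]])
        S = hd.powered_exp_cov(D, a0, a1, a2, jitter=0.0)
        assert S[0, 1] == pytest.approx(expected, rel=1e-9)

    def test_invalid_params(self):
        D = np.zeros((2, 2))
        for bad in [(-1, 1, 1), (1, 0, 1), (1, 1, 2.5)]:
            with pytest.raises(ValueError):
                hd.powered_exp_cov(D, *bad)


class TestLogLikelihood:
    def test_univariate_closed_form(self):
        # n=1 at the mode: -0.5 log(2 pi sigma^2)
        s2 = 0.3
        val = mvn_logpdf(np.array([1.0]), np.array([1.0]), np.array([[s2]]))
        assert val == pytest.approx(-0.5 * np.log(2 * np.pi * s2))

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            data = random_decay_data(rng, n=3)
            params = hd.DecayParams(
                M=rng.normal(), beta=rng.normal(),
                alpha0=rng.uniform(0.05, 2), alpha1=rng.uniform(0.1, 3),
                alpha2=rng.uniform(0.2, 1.8),
            )
            mu = params.M + params.beta * data.T
            S = hd.powered_exp_cov(data.D, params.alpha0, params.alpha1,
                                   params.alpha2, jitter=1e-10 * params.alpha0)
            # brute force: explicit inverse and determinant
            expected = -0.5 * (
                len(mu) * np.log(2 * np.pi)
                + np.log(np.linalg.det(S))
                + (data.H - mu) @ np.linalg.inv(S) @ (data.H - mu)
            )
            assert hd.log_likelihood(data, params) == pytest.approx(expected, abs=1e-8)

    def test_covariance_scaling_determinant_identity(self):
        rng = np.random.default_rng(1)
        data = random_decay_data(rng, n=4)
        mu = data.H.copy()  # residual zero: only the determinant term changes
        S = hd.powered_exp_cov(data.D, 1.0, 1.0, 1.0, jitter=0.0)
        base = mvn_logpdf(data.H, mu, S)
        scaled = mvn_logpdf(data.H, mu, 4.0 * S)
        assert base - scaled == pytest.approx(len(mu) * np.log(2.0), rel=1e-10)


class TestLogPrior:
    def test_support_boundaries(self):
        assert hd.log_prior(np.array([0, 0, 1, 1, 2.5])) == -np.inf
        assert hd.log_prior(np.array([0, 0, -0.1, 1, 1])) == -np.inf
        assert hd.log_prior(np.array([0, 0, 1, -1, 1])) == -np.inf
        assert np.isfinite(hd.log_prior(np.array([0, 0, 1, 1, 1])))

    def test_standard_normal_contributions(self):
        # M=beta=0 contribute 2 * (-0.5 log 2pi); moving M to 1 costs 0.5
        at0 = hd.log_prior(np.array([0, 0, 1, 1, 1]))
        at1 = hd.log_prior(np.array([1, 0, 1, 1, 1]))
        assert at0 - at1 == pytest.approx(0.5)


class TestBackTransform:
    def test_natural_scale_arithmetic(self):
        scaling = hd.ScalingRecord(h_max=2e-4, t_min=1902, t_max=2009, d_max=1000.0)
        draws = np.array([[0.5, -0.5, 1.0, 3.0, 1.0]])
        out = hd.back_transform_params(draws, scaling)
        assert out[0, 1] == pytest.approx(-9.3458e-7, rel=1e-4)
        assert out[0, 3] == pytest.approx(3.0 / 1000.0)
        assert out[0, 2] == pytest.approx(1.0 * (2e-4) ** 2)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        M=st.floats(-1e-3, 1e-3),
        beta=st.floats(-1e-5, -1e-8),
        alpha0=st.floats(1e-12, 1e-6),
        alpha1=st.floats(1e-4, 1.0),
        alpha2=st.floats(0.1, 1.9),
        h_max=st.floats(1e-5, 1e-3),
        d_max=st.floats(10.0, 5000.0),
    )
    def test_roundtrip_identity(self, M, beta, alpha0, alpha1, alpha2, h_max, d_max):
        params = hd.DecayParams(M, beta, alpha0, alpha1, alpha2)
        scaling = hd.ScalingRecord(h_max=h_max, t_min=1902, t_max=2009, d_max=d_max)
        fwd = hd.forward_scale_params(params, scaling)
        back = hd.back_transform_params(fwd.to_array()[None, :], scaling)[0]
        # the intercept round-trip cancels beta*t_min, so allow a few ulps
        # of that term as the absolute floor
        atol = 1e-12 * abs(beta) * scaling.t_max
        np.testing.assert_allclose(back, params.to_array(), rtol=1e-12, atol=atol)


class TestPercentDecline:
    def test_zero_slope(self):
        assert hd.percent_decline(1e-4, 0.0, 1902, 2009) == 0.0

    def test_positive_slope_negative_value(self):
        assert hd.percent_decline(1e-4, 1e-6, 1900, 2000) < 0

    def test_nonpositive_baseline_errors(self):
        with pytest.raises(ValueError):
            hd.percent_decline(1e-4, -1e-6, 1902, 2009)

    def test_params_wrapper(self):
        p = hd.DecayParams(M=1.2915e-4 + 1.05e-6 * 1902, beta=-1.05e-6,
                           alpha0=1e-10, alpha1=1e-3, alpha2=1.0)
        assert percent_decline_params(p, 1902, 2009) == pytest.approx(87.0, abs=0.5)


class TestSummaries:
    def _fake_samples(self, flat):
        draws = flat.reshape(2, -1, 5)
        scaling = hd.ScalingRecord(h_max=1.0, t_min=0.0, t_max=1.0, d_max=1.0)
        return hd.PosteriorSamples(
            draws_scaled=draws, draws=draws,
            param_names=["M", "beta", "alpha0", "alpha1", "alpha2"],
            scaling=scaling,
        )

    def test_quantile_rule_on_known_draws(self):
        vals = np.arange(1, 1001) / 1000.0
        flat = np.column_stack([np.full(1000, 0.5), vals, np.ones(1000),
                                np.ones(1000), np.ones(1000)])
        summ = hd.summarize_fit(self._fake_samples(flat))
        lo, hi = summ.table.loc["beta", ["ci_low", "ci_high"]]
        assert lo == pytest.approx(0.025, abs=0.005)
        assert hi == pytest.approx(0.975, abs=0.005)

    def test_significance_flags(self):
        neg = np.column_stack([np.full(200, 1.0), -np.linspace(0.1, 1, 200),
                               np.ones(200), np.ones(200), np.ones(200)])
        assert hd.summarize_fit(self._fake_samples(neg)).beta_significant
        sym = np.column_stack([np.full(200, 1.0), np.linspace(-1, 1, 200),
                               np.ones(200), np.ones(200), np.ones(200)])
        assert not hd.summarize_fit(self._fake_samples(sym)).beta_significant

    def test_too_few_draws(self):
        flat = np.ones((10, 5))
        with pytest.raises(ValueError, match="at least"):
            hd.summarize_fit(self._fake_samples(flat))


def _quick_config(seed, iters=2000):
    return hd.FitConfig(n_iterations=iters, thin=2, seed=seed,
                        compute_diagnostics=False)


@pytest.fixture(scope="module")
def scaled_dataset():
    cfg = hd.SimConfig(seed=10)
    meta = hd.gen_metadata(cfg)
    H = hd.simulate_het_field(meta, cfg.params, seed=11)
    data = hd.build_decay_data(H, meta)
    return hd.scale_inputs(data)


class TestSampler:
    def test_seed_reproducibility(self, scaled_dataset):
        scaled, scaling = scaled_dataset
        a = hd.sample_posterior(scaled, _quick_config(5, 600), scaling)
        b = hd.sample_posterior(scaled, _quick_config(5, 600), scaling)
        assert np.array_equal(a.draws_scaled, b.draws_scaled)

    def test_recovers_generating_slope(self, scaled_dataset):
        scaled, scaling = scaled_dataset
        ps = hd.sample_posterior(scaled, _quick_config(6), scaling)
        flat = ps.flat()
        beta_mean, beta_sd = flat[:, 1].mean(), flat[:, 1].std()
        assert abs(beta_mean - (-1.05e-6)) < 3 * beta_sd

    def test_convergence_across_independent_seeds(self, scaled_dataset):
        from hetdecay.mcmc import rhat_ess

        scaled, scaling = scaled_dataset
        cfg1 = hd.FitConfig(n_iterations=10_000, thin=5, seed=101,
                            compute_diagnostics=False)
        cfg2 = hd.FitConfig(n_iterations=10_000, thin=5, seed=202,
                            compute_diagnostics=False)
        a = hd.sample_posterior(scaled, cfg1, scaling)
        b = hd.sample_posterior(scaled, cfg2, scaling)
        combined = np.concatenate([a.draws_scaled, b.draws_scaled], axis=0)
        rhat, _ = rhat_ess(combined, a.param_names)
        assert max(rhat.values()) < 1.02


class TestEstimator:
    def test_sklearn_contract_and_predict(self):
        from sklearn.base import clone

        cfg = hd.SimConfig(seed=20, n_samples=20)
        meta = hd.gen_metadata(cfg)
        H = hd.simulate_het_field(meta, cfg.params, seed=21)
        X = np.array([[m.longitude, m.latitude, m.year] for m in meta])
        est = hd.SpatialDecayModel(n_iterations=800, thin=2, seed=1,
                                   compute_diagnostics=False)
        assert clone(est).get_params()["n_iterations"] == 800
        est.fit(X, H)
        pred = est.predict(X)
        assert pred.shape == (20,)
        # mean line decreasing in year for a declining fit
        order = np.argsort(X[:, 2])
        assert pred[order][0] >= pred[order][-1]

    def test_refit_subset_counts(self):
        cfg = hd.SimConfig(seed=30)
        meta = hd.gen_metadata(cfg)
        # force exactly 4 post-cutoff samples
        years = sorted(m.year for m in meta)
        meta = [
            m.__class__(m.sample_id, m.longitude, m.latitude,
                        1953 + i if i < 4 else min(m.year, 1952))
            for i, m in enumerate(meta)
        ]
        H = hd.simulate_het_field(meta, cfg.params, seed=31)
        summary, n_kept = hd.refit_subset_by_year(
            H, meta, 1952, _quick_config(7, 800))
        assert n_kept == 46

    def test_refit_cutoff_too_early(self, small_meta):
        H = np.array([1e-4, 1.5e-4, 2e-4])
        with pytest.raises(ValueError):
            hd.refit_subset_by_year(H, small_meta, 1800, _quick_config(1, 400))


class TestMapLine:
    def test_map_approaches_gls_line(self):
        # with the kernel effectively diagonal and alpha0 tiny, the MAP of
        # (M, beta) is the ordinary least-squares line
        rng = np.random.default_rng(3)
        n = 30
        T = np.linspace(0, 1, n)
        coords = np.column_stack([np.linspace(-110, -100, n),
                                  np.linspace(35, 45, n)])
        diff = coords[:, None] - coords[None, :]
        D = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(D, 0)
        H = np.clip(0.8 - 0.4 * T + 0.05 * rng.standard_normal(n), 0, 1)
        data = hd.DecayData([f"s{i}" for i in range(n)], H, T, coords, D / D.max())
        M, beta = map_line_given_kernel(data, alpha0=1e-8, alpha1=1000.0, alpha2=1.0)
        X = np.column_stack([np.ones(n), T])
        ols = np.linalg.lstsq(X, H, rcond=None)[0]
        assert M == pytest.approx(ols[0], rel=1e-4)
        assert beta == pytest.approx(ols[1], rel=1e-4)
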