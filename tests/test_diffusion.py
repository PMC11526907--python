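import numpy as np
import pytest

import netspread as ns
from netspread.connectome import Connectome
from netspread.diffusion import predict_map


def two_node_symmetric():
    return Connectome(["A", "B"], np.array([[0.0, 1.0], [1.0, 0.0]]))


def rk4_integrate(L, c, t, x0, step=1e-3):
    """Brute-force fixed-step RK4 oracle for dx/dt = -c L x."""
    n_steps = int(round(t / step))
    A = -c * L
    x = x0.astype(float).copy()
    for _ in range(n_steps):
        k1 = A @ x
        k2 = A @ (x + 0.5 * step * k1)
        k3 = A @ (x + 0.5 * step * k2)
        k4 = A @ (x + step * k3)
        x = x + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return x


class TestPropagate:
    def test_t0_is_identity(self, conn20):
        L_a, _ = ns.build_laplacians(conn20)
        sv = ns.seed_vector(conn20, conn20.region_ids[3])
        np.testing.assert_array_equal(ns.propagate(L_a, 1.3, 0.0, sv), sv.x0)

    def test_two_node_closed_form(self):
        """Symmetric two-state chain: x(t) = [(1+e^{-2ct})/2, (1-e^{-2ct})/2]."""
        conn = two_node_symmetric()
        L_a, _ = ns.build_laplacians(conn)
        x0 = np.array([1.0, 0.0])
        for c, t in [(1.0, 0.3), (1.0, np.log(2) / 2), (0.5, 2.0)]:
            x = ns.propagate(L_a, c, t, x0)
            e = np.exp(-2 * c * t)
            np.testing.assert_allclose(x, [(1 + e) / 2, (1 - e) / 2], atol=1e-10)
        x = ns.propagate(L_a, 1.0, np.log(2) / 2, x0)
        np.testing.assert_allclose(x, [0.75, 0.25], atol=1e-10)

    def test_matches_rk4_oracle(self, conn20):
        L_a, L_r = ns.build_laplacians(conn20)
        x0 = ns.seed_vector(conn20, conn20.region_ids[0]).x0
        for L in (L_a, L_r):
            expm_x = ns.propagate(L, 0.7, 3.0, x0)
            rk4_x = rk4_integrate(L, 0.7, 3.0, x0)
            assert np.abs(expm_x - rk4_x).max() < 1e-6

    def test_mass_conservation_and_nonnegativity(self, conn20):
        L_a, _ = ns.build_laplacians(conn20)
        x0 = ns.seed_vector(conn20, conn20.region_ids[5]).x0
        for t in (0.1, 1.0, 9.0, 50.0):
            x = ns.propagate(L_a, 1.1, t, x0)
            assert abs(x.sum() - 1.0) < 1e-10
            assert x.min() >= 0.0

    def test_semigroup_property(self, conn20):
        _, L_r = ns.build_laplacians(conn20)
        x0 = ns.seed_vector(conn20, conn20.region_ids[2]).x0
        once = ns.propagate(L_r, 0.8, 2.5, x0)
        twice = ns.propagate(L_r, 0.8, 1.5, ns.propagate(L_r, 0.8, 1.0, x0))
        np.testing.assert_allclose(once, twice, atol=1e-10)

    def test_seed_decreases_targets_increase_at_small_t(self, conn20):
        """For small t mass leaves the seed and arrives at direct targets."""
        L_a, _ = ns.build_laplacians(conn20)
        i = 0
        targets = np.flatnonzero(conn20.W[i] > 0)
        x = ns.propagate(L_a, 1.0, 0.01, ns.seed_vector(conn20, conn20.region_ids[i]).x0)
        assert x[i] < 1.0
        assert np.all(x[targets] > 0)

    def test_negative_rate_rejected(self, conn20):
        L_a, _ = ns.build_laplacians(conn20)
        with pytest.raises(ValueError, match=">= 0"):
            ns.propagate(L_a, -1.0, 1.0, np.ones(20) / 20)


class TestPredictLog:
    def test_pure_log10(self):
        yhat, mask = ns.predict_log(np.array([1.0, 10.0, 100.0]), None, 0.0, 1.0, 0.0)
        assert mask.all()
        np.testing.assert_allclose(yhat, [0, 1, 2])

    def test_zero_predictor_excluded(self):
        yhat, mask = ns.predict_log(np.array([0.0, 1.0]), np.array([1.0, 1.0]), 0, 1, 1)
        assert not mask[0] and mask[1]
        assert np.isnan(yhat[0])

    def test_intercept_only(self):
        yhat, mask = ns.predict_log(np.array([1.0, 2.0]), None, 2.0, 0.0, 0.0)
        np.testing.assert_allclose(yhat[mask], 2.0)

    def test_nonpositive_floor_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            ns.predict_log(np.ones(2), None, 0, 1, 0, floor=0)


class TestModelFitStatistic:
    def test_perfect_correlation(self):
        y = np.array([1.0, 2.0, 4.0, 8.0])
        assert ns.model_fit_statistic(y, y) == pytest.approx(1.0)
        assert ns.model_fit_statistic(-y, y) == pytest.approx(-1.0)

    def test_hand_computed_four_points(self):
        yhat = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        # textbook formula: cov / (sd_x sd_y)
        expected = np.cov(yhat, y, ddof=1)[0, 1] / (yhat.std(ddof=1) * y.std(ddof=1))
        assert ns.model_fit_statistic(yhat, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_flagged_undefined(self):
        assert np.isnan(ns.model_fit_statistic(np.ones(5), np.arange(5.0)))

    def test_too_few_points_undefined(self):
        assert np.isnan(ns.model_fit_statistic(np.array([1.0, 2.0]), np.array([1.0, 2.0])))


class TestFitModel:
    def test_noiseless_self_consistency(self, conn40, noiseless_study, noiseless_fit):
        """Data generated by the model is fit with r ~ 1 and tiny residuals."""
        truth, _ = noiseless_study
        fit = noiseless_fit
        for t in fit.timepoints:
            assert fit.fits[t].r > 0.999
            assert np.nanmax(np.abs(fit.fits[t].residuals)) < 1e-6
        assert fit.params.c_a == pytest.approx(truth.c_a, rel=0.10)
        assert fit.params.c_r == pytest.approx(truth.c_r, rel=0.10)

    def test_retrograde_data_prefers_retrograde_mode(self, conn40):
        """Directional discrimination on data planted with retrograde-only spread."""
        truth = ns.default_truth(conn40, rng_seed=31)
        truth.coeffs = {t: (b0, 0.0, b_r) for t, (b0, _, b_r) in truth.coeffs.items()}
        path = ns.synth_pathology(conn40, truth, n_mice=3, noise_sd=0.05, rng_seed=32)
        summ = ns.summarize_pathology(path, conn40)
        fc = ns.FitConfig(grid_size=8, refine=False)
        fit_r = ns.fit_model(summ, conn40, truth.seed_region, "retrograde", fc)
        fit_a = ns.fit_model(summ, conn40, truth.seed_region, "anterograde", fc)
        r_retro = np.mean([fit_r.fits[t].r for t in fit_r.timepoints])
        r_antero = np.mean([fit_a.fits[t].r for t in fit_a.timepoints])
        assert r_retro > r_antero

    def test_bidirectional_never_worse_than_nested(self, conn40, planted_study):
        """The bidirectional model nests both single-direction models (train SSE)."""
        truth, _, summ = planted_study
        fc = ns.FitConfig(grid_size=8, refine=False)
        sse_bi = ns.fit_model(summ, conn40, truth.seed_region, "bidirectional", fc).sse
        for mode in ("anterograde", "retrograde"):
            sse_one = ns.fit_model(summ, conn40, truth.seed_region, mode, fc).sse
            assert sse_bi <= sse_one + 1e-9

    def test_too_few_timepoints_rejected(self, conn20):
        truth = ns.default_truth(conn20, timepoints=(1.0, 3.0), rng_seed=1)
        path = ns.synth_pathology(conn20, truth, timepoints=[1.0], n_mice=2,
                                  noise_sd=0.0, rng_seed=2)
        summ = ns.summarize_pathology(path, conn20)
        with pytest.raises(ValueError, match="2 timepoints"):
            ns.fit_model(summ, conn20, truth.seed_region)


class TestAlternateSeedMaps:
    def test_original_seed_reproduces_fit(self, conn40, noiseless_fit):
        cache = ns.PropagatorCache(conn40)
        maps = ns.predict_alternate_seed_maps(
            noiseless_fit, conn40, [noiseless_fit.seed_region], cache=cache
        )
        for t in noiseless_fit.timepoints:
            got = maps[noiseless_fit.seed_region][t]
            want = noiseless_fit.fits[t].yhat
            m = np.isfinite(want)
            np.testing.assert_allclose(got[m], want[m], atol=1e-9)

    def test_distinct_seeds_give_distinct_maps(self, conn40, noiseless_fit):
        maps = ns.predict_alternate_seed_maps(
            noiseless_fit, conn40, conn40.region_ids[1:3]
        )
        t = noiseless_fit.timepoints[0]
        a = maps[conn40.region_ids[1]][t]
        b = maps[conn40.region_ids[2]][t]
        m = np.isfinite(a) & np.isfinite(b)
        assert np.abs(a[m] - b[m]).max() > 0

    def test_disconnected_component_keeps_mass(self):
        """Block-diagonal Laplacian: mass seeded in one component stays there."""
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        conn = Connectome(["a", "b", "c", "d"], W)
        L_a, _ = ns.build_laplacians(conn)
        x = ns.propagate(L_a, 1.0, 5.0, ns.seed_vector(conn, "a").x0)
        assert x[2] == pytest.approx(0.0, abs=1e-12)
        assert x[3] == pytest.approx(0.0, abs=1e-12)
        assert x[:2].sum() == pytest.approx(1.0, abs=1e-10)

    def test_unknown_seed_rejected(self, conn40, noiseless_fit):
        with pytest.raises(KeyError):
            ns.predict_alternate_seed_maps(noiseless_fit, conn40, ["NOPE"])


def test_parameter_recovery_across_random_datasets():
    """Median relative error of (c_a, c_r) < 10% over noiseless replicates."""
    errs_a, errs_r = [], []
    for i in range(6):
        conn = ns.synth_connectome(30, 0.25, rng_seed=100 + i)
        truth = ns.default_truth(conn, rng_seed=200 + i)
        path = ns.synth_pathology(conn, truth, n_mice=1, noise_sd=0.0,
                                  rng_seed=300 + i)
        summ = ns.summarize_pathology(path, conn)
        fit = ns.fit_model(summ, conn, truth.seed_region,
                           config=ns.FitConfig(grid_size=10))
        errs_a.append(abs(fit.params.c_a - truth.c_a) / truth.c_a)
        errs_r.append(abs(fit.params.c_r - truth.c_r) / truth.c_r)
    assert np.median(errs_a) < 0.10
    assert np.median(errs_r) < 0.10
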