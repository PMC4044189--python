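import numpy as np
import pandas as pd
import pytest

from glasscoherence.design import BlockProtocol
from glasscoherence.glm import (area_coherence_response, betas_to_psc,
                                build_design_matrix, censor_concat,
                                estimate_arma11, fit_glm,
                                legendre_regressors,
                                select_responsive_nodes, whiten_series)
from glasscoherence.simulate import (DEFAULT_PROFILES, NoiseParams,
                                     arma11_noise, random_walk_motion,
                                     simulate_node)


class TestLegendre:
    def test_small_exact_values(self):
        L = legendre_regressors(3, 1)
        assert np.allclose(L[:, 0], [1, 1, 1])
        assert np.allclose(L[:, 1], [-1, 0, 1])

    def test_p2_endpoints(self):
        L = legendre_regressors(100, 3)
        assert L[0, 2] == pytest.approx(1.0)
        assert L[-1, 2] == pytest.approx(1.0)

    def test_asymptotic_orthogonality(self):
        L = legendre_regressors(1000, 3)
        gram = L.T @ L / 1000
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 5e-3

    def test_insufficient_points(self):
        with pytest.raises(ValueError):
            legendre_regressors(3, 3)


@pytest.fixture
def design12(timelines12, protocol):
    rng = np.random.default_rng(21)
    motion = [random_walk_motion(171, rng) for _ in range(12)]
    return build_design_matrix(timelines12, motion, protocol)


class TestDesignMatrix:
    def test_experimental_shape(self, design12):
        assert design12.shape == (2016, 58)
        for sl in design12.run_slices:
            assert sl.stop - sl.start == 168

    def test_single_run_shape(self, timelines12, protocol):
        rng = np.random.default_rng(2)
        X = build_design_matrix(timelines12[:1],
                                [random_walk_motion(171, rng)], protocol)
        assert X.shape == (168, 14)

    def test_no_censoring_keeps_all_volumes(self, timelines12):
        proto = BlockProtocol(censor_volumes_per_run=0)
        rng = np.random.default_rng(3)
        motion = [random_walk_motion(171, rng) for _ in range(12)]
        X = build_design_matrix(timelines12, motion, proto)
        assert X.shape[0] == 12 * 171 == 2052

    def test_drift_columns_zero_outside_own_run(self, design12):
        drift = design12.matrix[:, design12.drift_idx]
        for r, sl in enumerate(design12.run_slices):
            outside = np.ones(drift.shape[0], dtype=bool)
            outside[sl] = False
            assert np.all(drift[outside, 4 * r:4 * r + 4] == 0)
        assert not np.any(np.all(design12.matrix == 0, axis=0))

    def test_mismatched_motion(self, timelines12, protocol):
        with pytest.raises(ValueError):
            build_design_matrix(timelines12, [np.zeros((171, 6))], protocol)


class TestArmaEstimation:
    def test_white_noise_recovers_origin(self):
        x = np.random.default_rng(0).normal(0, 1, 10_000)
        a, b = estimate_arma11(x)
        assert abs(a) < 0.05 and abs(b) < 0.05

    def test_ar1_recovery(self):
        x = arma11_noise(10_000, 0.3, 0.0, 1.0, np.random.default_rng(0))
        a, b = estimate_arma11(x)
        assert a == pytest.approx(0.3, abs=0.05)

    def test_arma_recovery(self):
        x = arma11_noise(10_000, 0.4, -0.2, 1.0, np.random.default_rng(0))
        a, b = estimate_arma11(x)
        assert a == pytest.approx(0.4, abs=0.05)
        assert b == pytest.approx(-0.2, abs=0.05)

    def test_constant_residuals_fall_back(self):
        with pytest.warns(RuntimeWarning):
            assert estimate_arma11(np.ones(100)) == (0.0, 0.0)

    def test_too_short(self):
        with pytest.raises(ValueError):
            estimate_arma11(np.random.default_rng(0).normal(size=20))

    def test_agrees_with_exact_ml(self):
        """CSS estimate tracks statsmodels exact-likelihood ARMA(1,1)."""
        from statsmodels.tsa.arima.model import ARIMA

        x = arma11_noise(5_000, 0.5, -0.3, 1.0, np.random.default_rng(1))
        a, b = estimate_arma11(x)
        ref = ARIMA(x, order=(1, 0, 1), trend="n").fit()
        assert a == pytest.approx(ref.params[0], abs=0.05)
        assert b == pytest.approx(ref.params[1], abs=0.05)


def _simulated_node_y(timelines, protocol, noise, rng, baseline=1000.0,
                      area="V3"):
    runs = np.array([simulate_node(tl, DEFAULT_PROFILES[area], noise,
                                   baseline, rng).values
                     for tl in timelines])
    return censor_concat(runs[None, :, :], protocol)[0]


class TestGlmFit:
    def test_whiten_identity_equals_ols(self, design12, timelines12, protocol):
        rng = np.random.default_rng(4)
        y = _simulated_node_y(timelines12, protocol, NoiseParams(), rng)
        ols = fit_glm(y, design12, whiten=False)
        Xw = whiten_series(design12.matrix, design12.run_slices, 0.0, 0.0)
        yw = whiten_series(y, design12.run_slices, 0.0, 0.0)
        assert np.allclose(Xw, design12.matrix)
        assert np.allclose(yw, y)
        beta_w, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        assert np.allclose(beta_w, ols.betas)

    def test_scale_equivariance(self, design12, timelines12, protocol):
        """Scaling y scales betas and baseline; psc is scale invariant."""
        rng = np.random.default_rng(5)
        y = _simulated_node_y(timelines12, protocol, NoiseParams(), rng)
        f1 = fit_glm(y, design12, whiten=False)
        f2 = fit_glm(3.0 * y, design12, whiten=False)
        assert np.allclose(f2.betas, 3.0 * f1.betas)
        assert f2.baseline_mean == pytest.approx(3.0 * f1.baseline_mean)
        assert np.allclose(betas_to_psc(f2), betas_to_psc(f1))

    def test_constant_offset_moves_baseline_not_betas(self, design12,
                                                      timelines12, protocol):
        rng = np.random.default_rng(6)
        y = _simulated_node_y(timelines12, protocol, NoiseParams(), rng)
        f1 = fit_glm(y, design12, whiten=False)
        f2 = fit_glm(y + 500.0, design12, whiten=False)
        assert np.allclose(f2.condition_betas, f1.condition_betas, atol=1e-8)
        assert f2.baseline_mean == pytest.approx(f1.baseline_mean + 500.0)

    def test_length_mismatch(self, design12):
        with pytest.raises(ValueError):
            fit_glm(np.zeros(10), design12)

    def test_psc_arithmetic(self, design12, timelines12, protocol):
        rng = np.random.default_rng(7)
        y = _simulated_node_y(timelines12, protocol,
                              NoiseParams(innovation_sd=0.0), rng,
                              baseline=100.0)
        fit = fit_glm(y, design12, whiten=False)
        # beta_c = baseline * amp_c / 100; psc = 100 * beta_c / baseline
        assert np.allclose(betas_to_psc(fit),
                           DEFAULT_PROFILES["V3"].condition_amplitudes)

    def test_negative_baseline_rejected(self, design12, timelines12, protocol):
        rng = np.random.default_rng(8)
        y = _simulated_node_y(timelines12, protocol, NoiseParams(), rng)
        fit = fit_glm(-y, design12, whiten=False)
        with pytest.raises(ValueError):
            betas_to_psc(fit)


class TestNodeSelection:
    def test_hand_executed_benjamini_hochberg(self):
        """q = 0.001: 0.0001 <= q/3, 0.0002 <= 2q/3, 0.5 > q -> 2 selected."""
        sel = select_responsive_nodes(np.array([0.0001, 0.0002, 0.5]),
                                      ["L", "L", "L"], q=0.001)
        assert sel.tolist() == [True, True, False]

    def test_all_null_none_selected(self):
        sel = select_responsive_nodes(np.ones(10), ["L"] * 5 + ["R"] * 5,
                                      q=0.001)
        assert not sel.any()

    def test_per_hemisphere_grouping(self):
        p = np.array([1e-6, 0.9, 1e-6, 0.9])
        sel = select_responsive_nodes(p, ["L", "L", "R", "R"], q=0.001)
        assert sel.tolist() == [True, False, True, False]

    def test_null_selection_rate_bounded(self):
        """BH on uniform p-values selects ~<= q among true nulls."""
        rng = np.random.default_rng(0)
        hits = sum(select_responsive_nodes(rng.uniform(size=200),
                                           ["L"] * 200, q=0.05).sum()
                   for _ in range(200))
        assert hits / (200 * 200) <= 0.05 + 0.01


class TestAreaMatrix:
    def test_single_node_normalization(self):
        df = pd.DataFrame({"participant": ["p0"], "c0": [1.0], "c33": [2.0],
                           "c66": [3.0], "c100": [4.0]})
        mat = area_coherence_response(df, "V3")
        assert np.allclose(mat.values.to_numpy(), [[-1.5, -0.5, 0.5, 1.5]])

    def test_identical_nodes_average_to_same(self):
        df = pd.DataFrame({"participant": ["p0"] * 3, "c0": [1.0] * 3,
                           "c33": [2.0] * 3, "c66": [3.0] * 3,
                           "c100": [4.0] * 3})
        mat = area_coherence_response(df, "V3")
        assert np.allclose(mat.values.to_numpy(), [[-1.5, -0.5, 0.5, 1.5]])
        assert mat.n_nodes_selected.tolist() == [3]

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"participant": np.repeat(["p0", "p1", "p2"], 4)})
        for c in ("c0", "c33", "c66", "c100"):
            df[c] = rng.normal(size=len(df))
        mat = area_coherence_response(df, "V3")
        assert np.allclose(mat.values.sum(axis=1), 0.0, atol=1e-12)

    def test_missing_participant_rejected(self):
        df = pd.DataFrame({"participant": ["p0"], "c0": [1.0], "c33": [2.0],
                           "c66": [3.0], "c100": [4.0]})
        with pytest.raises(ValueError):
            area_coherence_response(df, "V3", participants=["p0", "p1"])
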