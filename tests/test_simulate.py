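import numpy as np
import pytest
from scipy import stats

from glasscoherence.design import BLANK, BlockProtocol
from glasscoherence.glm import build_design_matrix, censor_concat, fit_glm
from glasscoherence.hemo import (HemoParams, canonical_hrf,
                                 condition_regressor)
from glasscoherence.simulate import (AREAS, AreaEffectProfile, CohortConfig,
                                     DEFAULT_PROFILES, NoiseParams,
                                     arma11_noise, random_walk_motion,
                                     simulate_behavior_run, simulate_cohort,
                                     simulate_node)


class TestHrf:
    def test_zero_at_onset(self):
        assert canonical_hrf(0.0) == 0.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            canonical_hrf(-1.0)

    def test_peak_near_five_seconds(self):
        t = np.arange(0.0, 32.0, 0.01)
        h = canonical_hrf(t)
        assert t[np.argmax(h)] == pytest.approx(5.0, abs=0.3)
        assert h.sum() * 0.01 > 0  # positive main lobe dominates

    def test_zero_beyond_kernel_length(self):
        assert canonical_hrf(np.array([33.0, 40.0])).tolist() == [0.0, 0.0]


class TestConditionRegressor:
    def test_unknown_condition(self, timeline):
        with pytest.raises(ValueError):
            condition_regressor(timeline, "c50")

    def test_linearity_over_blocks(self, timeline):
        """The multi-block regressor is the sum of single-block ones."""
        from glasscoherence.design import RunTimeline

        blocks = [b for b in timeline.blocks if b[2] == "c0"]
        total = np.zeros(timeline.n_volumes)
        for onset, dur, lab in blocks:
            single = RunTimeline(blocks=[(onset, dur, lab)],
                                 total_duration=timeline.total_duration,
                                 n_volumes=timeline.n_volumes)
            total += condition_regressor(single, "c0")
        assert np.allclose(total, condition_regressor(timeline, "c0"),
                           atol=1e-12)

    def test_against_gamma_cdf_oracle(self):
        """One 16 s block: the convolution equals the closed-form difference
        of gamma CDFs (step-response oracle)."""
        from glasscoherence.design import RunTimeline

        onset, dur = 20.0, 16.0
        tl = RunTimeline(blocks=[(onset, dur, "c0")], total_duration=120.0,
                         n_volumes=60)
        reg = condition_regressor(tl, "c0")
        p = HemoParams()

        def step(t):  # integral of the kernel over [0, t]
            t = np.clip(t, 0.0, p.kernel_length)
            return (stats.gamma.cdf(t, p.peak_delay)
                    - p.undershoot_ratio * stats.gamma.cdf(t, p.undershoot_delay))

        t = np.arange(60) * 2.0
        oracle = step(t - onset) - step(t - onset - dur)
        assert np.allclose(reg, oracle, atol=2e-2)
        # peaks a hemodynamic lag after onset, decays after offset
        assert onset < t[np.argmax(reg)] <= onset + dur + 8
        assert reg[-1] < 0.05


class TestNodeSimulation:
    def test_constant_without_signal_or_noise(self, timeline):
        prof = AreaEffectProfile("V1", (0.0, 0.0, 0.0, 0.0))
        nt = simulate_node(timeline, prof, NoiseParams(innovation_sd=0.0),
                           1000.0, np.random.default_rng(0))
        assert np.allclose(nt.values, 1000.0)

    def test_seed_determinism(self, timeline):
        prof = DEFAULT_PROFILES["V3"]
        a = simulate_node(timeline, prof, NoiseParams(), 1000.0,
                          np.random.default_rng(5))
        b = simulate_node(timeline, prof, NoiseParams(), 1000.0,
                          np.random.default_rng(5))
        assert np.array_equal(a.values, b.values)

    def test_noiseless_glm_recovery_is_exact(self, timelines12, protocol):
        """Forward model then GLM fit is the identity on amplitudes."""
        from glasscoherence.glm import betas_to_psc

        rng = np.random.default_rng(9)
        motion = [random_walk_motion(171, rng) for _ in range(12)]
        X = build_design_matrix(timelines12, motion, protocol)
        prof = DEFAULT_PROFILES["VRA"]
        runs = np.array([
            simulate_node(tl, prof, NoiseParams(innovation_sd=0.0),
                          1000.0, rng).values for tl in timelines12])
        y = censor_concat(runs[None, :, :], protocol)[0]
        fit = fit_glm(y, X, whiten=False)
        assert np.allclose(betas_to_psc(fit), prof.condition_amplitudes,
                           atol=1e-9)


class TestNoise:
    def test_arma_lag1_autocorrelation_matches_theory(self):
        a, b = 0.4, -0.2
        x = arma11_noise(100_000, a, b, 1.0, np.random.default_rng(3))
        x = x - x.mean()
        r1 = (x[1:] @ x[:-1]) / (x @ x)
        rho1 = (1 + a * b) * (a + b) / (1 + 2 * a * b + b * b)
        assert r1 == pytest.approx(rho1, abs=0.02)

    def test_stationarity_validation(self):
        with pytest.raises(ValueError):
            NoiseParams(ar=1.0)


class TestCohort:
    def test_default_truth_differences(self):
        diffs = {a: DEFAULT_PROFILES[a].full_minus_zero for a in AREAS}
        assert diffs == pytest.approx({"V1": 0.0, "V2": 0.0, "V3": 0.153,
                                       "hMT+": 0.101, "DRA": 0.185,
                                       "VRA": 0.246})

    def test_cohort_shapes(self):
        cfg = CohortConfig(n_participants=2,
                           protocol=BlockProtocol(n_runs=3),
                           areas=("V1", "V3"), nodes_per_area_hemi=2,
                           nonresponsive_per_area_hemi=1)
        cohort = simulate_cohort(cfg, np.random.default_rng(0))
        assert cohort.n_runs_total == 6
        part = cohort.participants[0]
        assert part.data.shape == (2 * 2 * 3, 3, 171)
        assert part.truth.shape[0] == len(part.nodes)
        assert part.nodes["meridian_distance"].between(0, 90).all()
        flat = part.truth[~part.nodes["responsive"].to_numpy()]
        assert np.all(flat == 0)

    def test_default_config_run_count(self):
        cfg = CohortConfig()
        assert cfg.n_participants * cfg.protocol.n_runs == 72

    def test_flat_area_amplitudes_equal(self):
        cfg = CohortConfig(n_participants=1, protocol=BlockProtocol(n_runs=1),
                           areas=("V1",), nodes_per_area_hemi=3,
                           nonresponsive_per_area_hemi=0, participant_sd=0.0)
        cohort = simulate_cohort(cfg, np.random.default_rng(1))
        truth = cohort.participants[0].truth
        assert np.allclose(truth, truth[:, :1])  # flat across conditions


class TestBehaviorSimulation:
    def test_perfect_hits_shift_by_lag(self, timeline):
        tr = simulate_behavior_run(timeline, lag=0.5, hit_rate=1.0,
                                   false_alarm_rate=0.0,
                                   rng=np.random.default_rng(0))
        targets = np.flatnonzero(tr.target_bins)
        responses = np.flatnonzero(tr.response_bins)
        expected = targets + 5
        assert set(expected[expected < len(tr.response_bins)]) == set(responses)

    def test_no_hits_no_responses(self, timeline):
        tr = simulate_behavior_run(timeline, hit_rate=0.0,
                                   false_alarm_rate=0.0,
                                   rng=np.random.default_rng(1))
        assert tr.response_bins.sum() == 0

    def test_expected_target_count(self, timeline):
        counts = [simulate_behavior_run(timeline, rng=np.random.default_rng(s)
                                        ).target_bins.sum()
                  for s in range(40)]
        assert np.mean(counts) == pytest.approx(342 * 3 / 20, rel=0.1)

    def test_train_lengths_and_labels(self, timeline):
        tr = simulate_behavior_run(timeline, rng=np.random.default_rng(2))
        assert len(tr.target_bins) == len(tr.response_bins) == 3420
        assert len(tr.condition_bins) == 3420
        assert tr.condition_bins[0] == BLANK  # pre-blank period
        assert (tr.condition_bins == "c100").sum() == 4 * 160  # 4 x 16 s
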