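"""Generator contracts: shapes, determinism, recoverability, distributions."""

import numpy as np
import pytest

from kicksyn.muscles import MUSCLES, PROTOCOLS, TIME_POINTS_MIN
from kicksyn.preprocess import (MovementCycle, PreprocessConfig,
                                bandpass_filter, envelope, rectify,
                                time_normalize)
from kicksyn.synthgen import (GeneratorConfig, GroundTruth,
                              generate_ground_truth, generate_jump_heights,
                              generate_study, synthesize_activation_matrix,
                              synthesize_trial)


class TestGroundTruth:
    def test_shapes_and_invariants(self, ground_truth):
        gt = ground_truth
        assert gt.weights.shape == (15, 3)
        assert gt.coefficients.shape == (3, 100)
        assert (gt.weights >= 0).all() and (gt.coefficients >= 0).all()
        np.testing.assert_allclose(np.linalg.norm(gt.weights, axis=0), 1.0,
                                   atol=1e-9)

    def test_seeded_reproducibility(self):
        a = generate_ground_truth(15, 3, seed=1)
        b = generate_ground_truth(15, 3, seed=1)
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.coefficients, b.coefficients)

    def test_weight_columns_are_distinct(self, ground_truth):
        W = ground_truth.weights
        gram = W.T @ W
        off = gram[~np.eye(3, dtype=bool)]
        assert off.max() < 0.8

    def test_coefficient_bumps_have_distinct_centers(self, ground_truth):
        centers = np.argmax(ground_truth.coefficients, axis=1)
        assert len(set(centers)) == 3

    def test_too_many_synergies_rejected(self):
        with pytest.raises(ValueError):
            generate_ground_truth(3, 3, seed=0)

    def test_impossible_separation_fails_explicitly(self):
        with pytest.raises(RuntimeError, match="cosine"):
            generate_ground_truth(15, 6, seed=0, max_cosine=0.01,
                                  max_attempts=5)


class TestSynthesizeTrial:
    def test_unknown_protocol_names_allowed_labels(self, ground_truth):
        with pytest.raises(ValueError, match="ESG"):
            synthesize_trial(ground_truth, "XXX", 0.0, seed=0)

    def test_event_stamps_strictly_increasing(self, ground_truth):
        trial = synthesize_trial(ground_truth, "SQG", 0.05, seed=2)
        stamps = [trial.events_s[k] for k in "abcde"]
        assert all(b > a for a, b in zip(stamps, stamps[1:]))

    def test_noise_free_preprocessing_recovers_envelope(self, ground_truth):
        """Rectify + low-pass on the synthetic raw trial tracks W·C."""
        E = ground_truth.envelope("SQG")
        cfg = PreprocessConfig(normalization="task_max")
        trial = synthesize_trial(ground_truth, "SQG", 0.0, seed=3)
        x = envelope(rectify(bandpass_filter(trial.emg, cfg)), cfg)
        prof = time_normalize(x, MovementCycle.from_trial(trial), 100)
        for ch in range(15):
            assert np.corrcoef(prof[ch], E[ch])[0, 1] > 0.95

    def test_zeroed_synergy_contributes_nothing(self, ground_truth):
        gt = ground_truth
        C = gt.coefficients.copy()
        C[1] = 0.0
        zeroed = GroundTruth(gt.weights, C, gt.protocol_effects)
        removed = GroundTruth(np.delete(gt.weights, 1, axis=1)
                              / np.linalg.norm(np.delete(gt.weights, 1,
                                                         axis=1), axis=0),
                              np.delete(C, 1, axis=0), {
                                  p: m for p, m in
                                  gt.protocol_effects.items()})
        np.testing.assert_allclose(zeroed.envelope("SQG"),
                                   removed.envelope("SQG"), atol=1e-12)

    def test_mean_recovered_envelope_approaches_truth(self, ground_truth):
        """Distinct seeds share the expected envelope: the mean of many
        preprocessed noise-free trials converges on W·C within 3 SE."""
        E = ground_truth.envelope("SQG")
        cfg = PreprocessConfig(sampling_rate=1000.0)
        profs = []
        for seed in range(50):
            trial = synthesize_trial(ground_truth, "SQG", 0.0, seed=seed,
                                     sampling_rate=1000.0)
            x = envelope(rectify(bandpass_filter(trial.emg, cfg)), cfg)
            profs.append(time_normalize(x, MovementCycle.from_trial(trial),
                                        100))
        profs = np.asarray(profs)
        mean = profs.mean(axis=0)
        se = profs.std(axis=0, ddof=1) / np.sqrt(len(profs))
        interior = slice(5, 95)   # skip filter edge effects at cycle bounds
        dev = np.abs(mean - E)[:, interior]
        bound = (3 * se + 0.01 * E.max())[:, interior]
        assert (dev <= bound).mean() > 0.95


class TestActivationMatrixSurrogate:
    def test_noise_scales_with_mean_amplitude(self, ground_truth):
        D0 = synthesize_activation_matrix(ground_truth, noise_sd=0.0)
        D = synthesize_activation_matrix(ground_truth, noise_sd=0.05, seed=5)
        assert D.shape == D0.shape and (D >= 0).all()
        resid = D - D0
        assert 0.5 * 0.05 * D0.mean() < resid.std() < 2 * 0.05 * D0.mean()


class TestGenerateStudy:
    def test_default_design_dimensions(self):
        """The emulated design: 18 athletes x 3 protocols x 6 trials x 15
        channels, three jumps at three post-intervention time points."""
        ds = generate_study(GeneratorConfig(
            trial_duration_s=0.6, sampling_rate=1000.0, seed=5))
        assert len(ds.subjects) == 18
        subject = ds.subjects[0]
        assert set(subject.sessions) == set(PROTOCOLS)
        session = subject.sessions["ESG"]
        assert len(session.trials) == 6
        assert session.trials[0].emg.shape[0] == 15
        assert session.flight_times_s.shape == (3, 3)
        assert session.time_points_min == TIME_POINTS_MIN
        assert set(session.mvc) == set(MUSCLES)

    def test_small_config_invariants(self, small_study):
        for subject in small_study.subjects:
            for session in subject.sessions.values():
                assert (session.flight_times_s > 0).all()
                for trial in session.trials:
                    stamps = [trial.events_s[k] for k in "abcde"]
                    assert all(b > a for a, b in zip(stamps, stamps[1:]))

    def test_seeded_determinism(self, fast_config):
        a = generate_study(fast_config)
        b = generate_study(fast_config)
        assert np.array_equal(a.ground_truth.weights, b.ground_truth.weights)
        for sa, sb in zip(a.subjects, b.subjects):
            for p in PROTOCOLS:
                assert np.array_equal(sa.sessions[p].flight_times_s,
                                      sb.sessions[p].flight_times_s)
                for ta, tb in zip(sa.sessions[p].trials,
                                  sb.sessions[p].trials):
                    assert np.array_equal(ta.emg, tb.emg)

    def test_non_positive_jump_mean_rejected(self):
        table = {p: {t: (45.0, 3.0) for t in TIME_POINTS_MIN}
                 for p in PROTOCOLS}
        table["ESG"][6] = (-1.0, 3.0)
        with pytest.raises(ValueError, match="positive"):
            GeneratorConfig(jump_means_sds=table)

    def test_jump_heights_match_configured_table(self):
        """Monte-Carlo: mean best jump under h = g t^2/8 hits the configured
        ESG 6-min mean (49.1 cm) within 3 SE at large n."""
        cfg = GeneratorConfig(n_subjects=1000, seed=17)
        rng = np.random.default_rng(99)
        heights = generate_jump_heights(cfg, rng)["ESG"][:, 0]
        se = heights.std(ddof=1) / np.sqrt(heights.size)
        assert abs(heights.mean() - 49.1) < 3 * se
        assert abs(heights.std(ddof=1) - 2.8) < 0.3

    def test_null_config_removes_all_protocol_differences(self, fast_config):
        null = fast_config.without_protocol_effects()
        assert null.effect_magnitude == 0.0
        cells = {ms for tab in null.jump_means_sds.values()
                 for ms in tab.values()}
        assert len(cells) == 1
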