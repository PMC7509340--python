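"""Stimulus trains, AR noise, and the group simulation with known truth."""

import dataclasses

import numpy as np
import pytest

from nirsroi.contrast import tapered_contrast
from nirsroi.forward import compute_forward_matrix
from nirsroi.glm import build_design, fit_glm
from nirsroi.head import mirror_roi, select_spherical_roi
from nirsroi.probe import ProbeLayout
from nirsroi.simulate import (
    DEFAULT_AR_COEFS,
    SimulationConfig,
    ar_noise,
    ar_stationary_sd,
    simulate_group,
    simulate_subject,
    stimulus_train,
)

FAST = SimulationConfig(
    chromophores=(("hbo", 1.0),), duration=150.0, n_subjects=2
)


class TestStimulusTrain:
    def test_gap_mean_law_of_large_numbers(self, rng):
        gaps = np.diff(stimulus_train(3.2e6, 30.0, rng))
        assert len(gaps) > 5e4
        assert gaps.mean() == pytest.approx(30.0, rel=0.01)

    def test_huge_isi_gives_few_onsets(self):
        counts = [
            len(stimulus_train(10.0, 1e4, np.random.default_rng(k)))
            for k in range(200)
        ]
        assert np.mean(counts) < 0.05

    def test_deterministic_under_seed(self):
        a = stimulus_train(600.0, 30.0, np.random.default_rng(3))
        b = stimulus_train(600.0, 30.0, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_onsets_within_duration(self, rng):
        onsets = stimulus_train(100.0, 10.0, rng)
        assert np.all((onsets > 0) & (onsets < 100.0))


class TestARNoise:
    def test_no_coefficients_gives_white_noise(self, rng):
        x = ar_noise(100_000, 1, np.array([]), 2.0, rng)
        assert x.std() == pytest.approx(2.0, rel=0.02)

    def test_ar1_lag_one_autocorrelation(self, rng):
        x = ar_noise(100_000, 1, np.array([0.8]), 1.0, rng)[:, 0]
        acf1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert acf1 == pytest.approx(0.8, abs=0.02)

    def test_stationary_sd_matches_theory(self, rng):
        coefs = np.array(DEFAULT_AR_COEFS)
        x = ar_noise(200_000, 1, coefs, 1.0, rng)
        assert x.std() == pytest.approx(ar_stationary_sd(coefs), rel=0.05)

    def test_channels_independent(self, rng):
        x = ar_noise(20_000, 2, np.array([0.6]), 1.0, rng)
        r = np.corrcoef(x[:, 0], x[:, 1])[0, 1]
        assert abs(r) < 0.05

    def test_nonstationary_rejected(self, rng):
        with pytest.raises(ValueError):
            ar_noise(100, 1, np.array([1.05]), 1.0, rng)

    def test_reproducible(self):
        a = ar_noise(500, 3, np.array([0.5]), 1.0, np.random.default_rng(1))
        b = ar_noise(500, 3, np.array([0.5]), 1.0, np.random.default_rng(1))
        np.testing.assert_array_equal(a, b)


class TestSimulateSubject:
    def test_zero_amplitude_gives_pure_noise(self, head, low_probe, rng):
        cfg = dataclasses.replace(FAST, amplitude=0.0)
        roi = select_spherical_roi(head, 100, 14.0)
        subj = simulate_subject(cfg, head, low_probe, roi, rng)
        np.testing.assert_allclose(subj.evoked, 0.0)

    def test_amplitude_linearity(self, head, low_probe):
        roi = select_spherical_roi(head, 100, 14.0)
        subjects = []
        for amp in (1.0, 2.0):
            cfg = dataclasses.replace(FAST, amplitude=amp, head_sd=0.0, disp_sd=0.0)
            subjects.append(
                simulate_subject(cfg, head, low_probe, roi, np.random.default_rng(9))
            )
        np.testing.assert_allclose(
            subjects[1].evoked, 2.0 * subjects[0].evoked, rtol=1e-12
        )

    def test_negligible_noise_recovers_amplitude_exactly(self, head, low_probe):
        cfg = dataclasses.replace(FAST, snr=1e9, head_sd=0.0, disp_sd=0.0)
        roi = select_spherical_roi(head, 100, 14.0)
        subj = simulate_subject(cfg, head, low_probe, roi, np.random.default_rng(2))
        X, names = build_design(
            subj.onsets, cfg.stim_duration, subj.ts["hbo"].n_samples, cfg.fs
        )
        res = fit_glm(subj.ts["hbo"], X, noise_model="iid", design_names=names)
        spatial = subj.sensitivity.values @ roi.indicator.astype(float)
        np.testing.assert_allclose(res.beta[:, 0], spatial, rtol=1e-4, atol=1e-12)

    def test_snr_definition_consistency(self, head, low_probe):
        # with the subject's own reference, the evoked-to-noise sd ratio at
        # the most sensitive channel matches the configured SNR within 5%
        roi = select_spherical_roi(head, 100, 14.0)
        cfg = dataclasses.replace(
            FAST, duration=600.0, head_sd=0.0, disp_sd=0.0, snr=1.0
        )
        ratios = []
        ss = np.random.SeedSequence(11)
        for child in ss.spawn(60):
            rng = np.random.default_rng(child)
            subj = simulate_subject(cfg, head, low_probe, roi, rng)
            ch = int(np.argmax(np.abs(subj.evoked).max(axis=0)))
            noise = subj.ts["hbo"].data - subj.evoked
            ratios.append(subj.evoked[:, ch].std() / noise[:, ch].std())
        assert np.mean(ratios) == pytest.approx(1.0, rel=0.05)


class TestSimulateGroup:
    def test_deterministic_under_seed(self, head, low_probe):
        a = simulate_group(FAST, head, low_probe, rng=np.random.default_rng(4))
        b = simulate_group(FAST, head, low_probe, rng=np.random.default_rng(4))
        np.testing.assert_array_equal(
            a.subjects[0].ts["hbo"].data, b.subjects[0].ts["hbo"].data
        )
        assert a.active_roi.center_node == b.active_roi.center_node

    def test_zero_error_shares_registration(self, head, low_probe):
        cfg = dataclasses.replace(FAST, head_sd=0.0, disp_sd=0.0)
        ds = simulate_group(cfg, head, low_probe, rng=np.random.default_rng(4))
        p0 = ds.subjects[0].registered.optode_positions
        p1 = ds.subjects[1].registered.optode_positions
        np.testing.assert_allclose(p0, p1, atol=1e-9)

    def test_head_circumference_distribution(self, head, low_probe):
        cfg = dataclasses.replace(FAST, n_subjects=5, duration=60.0)
        circs = []
        ss = np.random.SeedSequence(21)
        for child in ss.spawn(30):
            ds = simulate_group(cfg, head, low_probe, rng=np.random.default_rng(child))
            circs += [s.error.circumference for s in ds.subjects]
        assert np.mean(circs) == pytest.approx(420.0, rel=0.02)

    def test_null_roi_mirrors_active(self, head, low_probe, rng):
        ds = simulate_group(FAST, head, low_probe, rng=rng)
        assert ds.null_roi.size == ds.active_roi.size
        np.testing.assert_array_equal(
            ds.null_roi.indicator,
            mirror_roi(head, ds.active_roi).indicator,
        )

    def test_two_roi_mode(self, head, low_probe, rng):
        cfg = dataclasses.replace(FAST, roi_separation=40.0)
        ds = simulate_group(cfg, head, low_probe, rng=rng)
        d = np.linalg.norm(
            head.cortex_nodes[ds.second_roi.center_node]
            - head.cortex_nodes[ds.active_roi.center_node]
        )
        assert abs(d - 40.0) <= head.node_spacing


class TestHemisphereSeparation:
    def test_null_roi_invisible_to_one_sided_probe(self, head):
        # a probe confined to the left side: the mirrored (right) ROI either
        # projects to nothing or to a tiny fraction of the active effect
        labels, positions, channels = [], [], []
        for k in range(7):  # short left-side chain from the anchor
            x = -25.0 * k
            if k % 2 == 0:
                labels.append(f"S{k // 2 + 1}")
            else:
                labels.append(f"D{(k + 1) // 2}")
            positions.append((x, 0.0))
        for i in range(1, 4):
            channels.append((f"S{i}", f"D{i}"))
            channels.append((f"S{i + 1}", f"D{i}"))
        layout = ProbeLayout(
            optode_labels=tuple(labels),
            optode_positions=np.array(positions),
            channels=tuple(channels[:6]),
            anchors=(((0.0, 0.0), "Fpz"),),
            attractors=(((-150.0, 0.0), "T7"), ((0.0, 100.0), "Cz")),
        )
        from nirsroi.probe import register_probe

        reg = register_probe(layout, head)
        L = compute_forward_matrix(reg, head)
        # active ROI centred under the left arm of the probe
        mid = reg.channel_midpoints[3]
        active_center = int(
            np.argmin(np.linalg.norm(head.cortex_nodes - mid, axis=1))
        )
        active = select_spherical_roi(head, active_center, 14.0)
        null = mirror_roi(head, active)
        act_proj = float((L.values @ active.indicator).sum())
        null_proj = float((L.values @ null.indicator).sum())
        assert null_proj < 1e-3 * act_proj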