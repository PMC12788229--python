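"""Windowed PCA, component quality scoring, and selection."""

import numpy as np
import pytest

from csirr.decompose import (
    AnalysisWindow,
    ComponentSet,
    decompose_window,
    ingest_csi,
    pca_window,
    select_components,
    snr_index,
    spectral_peak_index,
    variance_index,
    window_stream,
)
from csirr.synth import CsiSession, make_schedule, synth_csi, synth_respiratory_waveform

from conftest import tone

FS = 50.0


def make_session(mags, fs=FS):
    t = np.arange(mags.shape[0]) / fs
    return CsiSession(mags, t, {"sampling_rate": fs, "n_subcarriers": mags.shape[1]})


class TestIngest:
    def test_uniform_input_unchanged(self):
        session = make_session(np.abs(np.random.default_rng(0).normal(10, 1, (1600, 4))))
        out = ingest_csi(session)
        assert np.array_equal(out.magnitudes, session.magnitudes)

    def test_jittered_timestamps_regularised(self):
        rng = np.random.default_rng(1)
        n = 1600
        t = np.sort(np.arange(n) / FS + rng.uniform(-0.004, 0.004, n))
        session = CsiSession(np.abs(rng.normal(10, 1, (n, 3))), t,
                            {"sampling_rate": FS})
        out = ingest_csi(session)
        assert np.allclose(np.diff(out.timestamps), 0.02)

    def test_gap_flagged_and_interpolated(self):
        t = np.concatenate([np.arange(800) / FS, 2.0 + 16.0 + np.arange(800) / FS])
        mags = np.abs(np.random.default_rng(2).normal(10, 1, (1600, 2)))
        out = ingest_csi(CsiSession(mags, t, {"sampling_rate": FS}))
        assert len(out.metadata["gaps"]) == 1
        assert np.allclose(np.diff(out.timestamps), 0.02)

    def test_short_session_rejected(self):
        session = make_session(np.ones((int(29 * FS), 2)))
        with pytest.raises(ValueError):
            ingest_csi(session)


class TestWindowStream:
    def test_full_protocol_window_count(self):
        session = make_session(np.ones((60000, 2)))
        wins = list(window_stream(session))
        assert len(wins) == 1171
        assert wins[0].end_time == pytest.approx(30.0)
        assert wins[-1].end_time == pytest.approx(1200.0)

    def test_exactly_one_window(self):
        session = make_session(np.ones((1500, 2)))
        wins = list(window_stream(session))
        assert len(wins) == 1
        assert wins[0].magnitudes.shape[0] == 1500


class TestPca:
    def test_correlated_pair_concentrates_variance(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(1500)
        mags = np.column_stack([base, 2 * base, np.full(1500, 5.0),
                                np.full(1500, 7.0)])
        cset = pca_window(AnalysisWindow(30.0, mags))
        assert cset.explained_variance_ratios[0] > 0.999

    def test_projections_orthogonal(self):
        rng = np.random.default_rng(1)
        mags = rng.standard_normal((1500, 6))
        cset = pca_window(AnalysisWindow(30.0, mags))
        corr = np.corrcoef(cset.projections.T)
        off = corr[~np.eye(len(corr), dtype=bool)]
        assert np.abs(off).max() < 1e-6

    def test_reconstruction_round_trip(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((200, 5))
        Xc = X - X.mean(axis=0)
        cset = pca_window(AnalysisWindow(4.0, X))
        # recover the component basis by least squares and reconstruct
        V, *_ = np.linalg.lstsq(cset.projections, Xc, rcond=None)
        assert np.allclose(cset.projections @ V, Xc, atol=1e-8)

    def test_zero_variance_window_degenerate(self):
        cset = decompose_window(AnalysisWindow(30.0, np.ones((1500, 4))))
        assert cset.degenerate
        assert np.all(cset.cqi == 0.0)
        assert cset.low_quality

    def test_deterministic_sign(self):
        rng = np.random.default_rng(3)
        mags = rng.standard_normal((500, 4))
        a = pca_window(AnalysisWindow(10.0, mags))
        b = pca_window(AnalysisWindow(10.0, mags.copy()))
        assert np.array_equal(a.projections, b.projections)


def cset_with_evr(evr):
    evr = np.asarray(evr, float)
    return ComponentSet(30.0, np.empty((0, len(evr))), evr, np.cumsum(evr),
                        0.0, np.zeros(len(evr)), np.zeros(len(evr)),
                        np.zeros(len(evr)), np.zeros(len(evr)))


class TestVarianceIndex:
    def test_elbow_rule_worked_example(self):
        cset = cset_with_evr([0.60, 0.25, 0.10, 0.04, 0.005, 0.005])
        gamma = variance_index(cset)
        assert np.array_equal(gamma, [1, 1, 1, 1, 0, 0])
        assert cset.sigma_threshold == pytest.approx(0.99)

    def test_at_least_one_component_retained(self):
        cset = cset_with_evr([0.005, 0.005, 0.99])  # pathological ordering
        gamma = variance_index(cset)
        assert gamma[0] == 1.0 and gamma.sum() == 1.0

    def test_all_retained_when_gradient_never_drops(self):
        cset = cset_with_evr([0.4, 0.3, 0.3])
        assert variance_index(cset).sum() == 3.0


class TestSnrIndex:
    def test_in_band_tone_near_one(self):
        assert snr_index(tone(0.3, 30, FS), FS) > 0.95

    def test_out_of_band_tone_near_zero(self):
        assert snr_index(tone(1.5, 30, FS), FS) < 0.05

    def test_white_noise_matches_flat_expectation(self):
        vals = [snr_index(np.random.default_rng(s).standard_normal(1500), FS)
                for s in range(100)]
        assert np.mean(vals) == pytest.approx(0.02, abs=0.005)

    def test_zero_signal(self):
        assert snr_index(np.zeros(1500), FS) == 0.0

    def test_bad_band_rejected(self):
        with pytest.raises(ValueError):
            snr_index(tone(0.3, 30, FS), FS, band_brpm=(35, 5))


class TestSpectralPeakIndex:
    def test_peak_in_band(self):
        assert spectral_peak_index(tone(18 / 60, 30, FS), FS) == 1.0

    def test_peak_below_minimum(self):
        assert spectral_peak_index(tone(3 / 60, 60, FS), FS) == 0.0

    def test_peak_exactly_at_minimum_inclusive(self):
        # 36 s at 50 Hz puts a bin exactly at 5 brpm = 1/12 Hz
        assert spectral_peak_index(tone(5 / 60, 36, FS), FS) == 1.0

    def test_flat_signal(self):
        assert spectral_peak_index(np.zeros(1500), FS) == 0.0


class TestSelection:
    def make_scored(self, cqis):
        n = len(cqis)
        cset = cset_with_evr(np.full(n, 1.0 / n))
        cset.gamma_sigma = np.ones(n)
        cset.gamma_snr = np.asarray(cqis, float)
        cset.gamma_peak = np.ones(n)
        return cset

    def test_top_cqi_selected(self):
        cset = select_components(self.make_scored([0, 0.8, 0, 0, 0.6, 0.1]),
                                 n_keep=2)
        assert cset.selected_indices == [1, 4]

    def test_ties_broken_by_variance_rank(self):
        cset = select_components(self.make_scored([0.5, 0.5, 0.5, 0.5]),
                                 n_keep=2)
        assert cset.selected_indices == [0, 1]

    def test_all_zero_fallback_flagged(self):
        cset = select_components(self.make_scored([0.0, 0.0, 0.0]), n_keep=2)
        assert cset.low_quality
        assert cset.selected_indices == [0, 1]

    def test_cqi_zero_when_any_binary_index_zero(self):
        cset = self.make_scored([0.9, 0.9])
        cset.gamma_peak = np.array([0.0, 1.0])
        select_components(cset, n_keep=1)
        assert cset.cqi[0] == 0.0
        assert np.all((cset.cqi >= 0) & (cset.cqi <= 1))


class TestEndToEndSelection:
    def test_breathing_component_recovered_across_windows(self):
        # coupled subcarriers at a constant 17.1 brpm (0.285 Hz): at least
        # one selected component per window must peak within one FFT bin
        sched = make_schedule(17.1, 3, 17.1, 90)
        wf = synth_respiratory_waveform(sched, FS, jitter=0.0, seed=0)
        hits, total = 0, 0
        for seed in range(3):
            session = synth_csi(wf, n_subcarriers=32, coupled_fraction=0.25,
                                noise_scale=0.3, drift_scale=0.5,
                                motion_events=0, seed=seed)
            for win in window_stream(ingest_csi(session)):
                cset = decompose_window(win)
                total += 1
                freqs = np.fft.rfftfreq(win.magnitudes.shape[0], 1 / FS)
                for j in cset.selected_indices:
                    comp = cset.projections[:, j]
                    mag = np.abs(np.fft.rfft(comp - comp.mean()))
                    if abs(freqs[np.argmax(mag[1:]) + 1] - 17.1 / 60) <= 1 / 30.0:
                        hits += 1
                        break
        assert hits / total >= 0.9

    def test_snr_monotone_under_noise(self):
        sched = make_schedule(15, 3, 15, 60)
        wf = synth_respiratory_waveform(sched, FS, jitter=0.0, seed=0)
        means = []
        for noise in (0.1, 0.5, 1.5, 4.0):
            vals = []
            for seed in range(3):
                session = synth_csi(wf, n_subcarriers=16, coupled_fraction=0.5,
                                    noise_scale=noise, drift_scale=0.0,
                                    motion_events=0, seed=seed)
                win = next(iter(window_stream(ingest_csi(session))))
                cset = decompose_window(win)
                vals.append(cset.gamma_snr[cset.selected_indices[0]])
            means.append(np.mean(vals))
        assert all(a >= b - 1e-9 for a, b in zip(means, means[1:]))
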