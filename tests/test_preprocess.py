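"""Filtering, artifact removal, downsampling, band split, segmentation."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.stats import kurtosis

from mssecnn import preprocess, synthgen
from mssecnn.preprocess import (
    BandSet,
    FilterSpec,
    apply_filter,
    decompose_bands,
    design_filter,
    downsample,
    remove_artifact_components,
    select_bands,
    sliding_segments,
)
from mssecnn.synthgen import RawRecording, SimConfig


def _rec(data, fs=1000.0, n_ch=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    labels = [f"ch{i}" for i in range(data.shape[0])]
    return RawRecording(data=data, fs=fs, channel_labels=labels, label="pre",
                        subject_id="t")


class TestDesignFilter:
    def test_bandpass_response(self):
        c = design_filter(FilterSpec(kind="bandpass-cheby1", edges=(1.0, 100.0),
                                     fs=1000.0))
        assert c.response(50.0)[0] >= 0.7
        assert c.response(0.1)[0] <= 0.1

    def test_notch_response(self):
        c = design_filter(FilterSpec(kind="notch", edges=(50.0,), fs=1000.0))
        assert c.response(50.0)[0] <= 0.1
        assert c.response(40.0)[0] >= 0.9

    def test_edges_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec(kind="bandpass-cheby1", edges=(1.0, 500.0), fs=1000.0)


class TestApplyFilter:
    def test_zero_in_zero_out_and_shape(self):
        c = design_filter(FilterSpec(kind="bandpass-cheby1", edges=(1.0, 100.0),
                                     fs=1000.0))
        rec = _rec(np.zeros((3, 2000)))
        out = apply_filter(rec, c)
        assert out.data.shape == (3, 2000)
        assert np.allclose(out.data, 0.0)

    def test_notch_suppresses_50_hz_tone(self):
        t = np.arange(4000) / 1000.0
        tone = np.sin(2 * np.pi * 50.0 * t)
        c = design_filter(FilterSpec(kind="notch", edges=(50.0,), fs=1000.0))
        out = apply_filter(_rec(tone), c)
        rms_in = np.sqrt(np.mean(tone**2))
        rms_out = np.sqrt(np.mean(out.data[0] ** 2))
        assert rms_out <= 0.1 * rms_in

    def test_zero_phase_keeps_pulse_symmetric(self):
        x = np.zeros(2001)
        x[800:1201] = np.hanning(401)  # symmetric bump centred at 1000
        c = design_filter(FilterSpec(kind="bandpass-cheby1", edges=(1.0, 100.0),
                                     fs=1000.0))
        out = apply_filter(_rec(x), c).data[0]
        assert abs(int(np.argmax(out)) - 1000) <= 1

    def test_too_short_recording_rejected(self):
        c = design_filter(FilterSpec(kind="bandpass-cheby1", edges=(1.0, 100.0),
                                     fs=1000.0))
        with pytest.raises(ValueError):
            apply_filter(_rec(np.zeros((1, 10))), c)


class TestArtifactRemoval:
    def test_blink_removal_reduces_frontal_kurtosis(self):
        cfg = SimConfig(n_channels=8, duration=30.0, coupling_edges=[],
                        artifact_rate=20.0)
        rec = synthgen.simulate_recording(cfg, "pre", seed=4)
        cleaned = remove_artifact_components(rec, seed=0)
        assert kurtosis(cleaned.data[0]) < kurtosis(rec.data[0])

    def test_artifact_free_recording_nearly_unchanged(self):
        cfg = SimConfig(n_channels=8, duration=30.0, coupling_edges=[],
                        artifact_rate=0.0)
        rec = synthgen.simulate_recording(cfg, "pre", seed=4)
        cleaned = remove_artifact_components(rec, seed=0)
        rel = np.sqrt(np.mean((cleaned.data - rec.data) ** 2)) / np.sqrt(
            np.mean(rec.data**2)
        )
        assert rel <= 0.05

    def test_too_many_components_rejected(self):
        cfg = SimConfig(n_channels=4, duration=5.0, coupling_edges=[])
        rec = synthgen.simulate_recording(cfg, "pre", seed=0)
        with pytest.raises(ValueError):
            remove_artifact_components(rec, n_components=5)


class TestDownsample:
    def test_factor_eight_sample_count(self):
        rec = _rec(np.random.default_rng(0).normal(size=(2, 60_000)))
        out = downsample(rec, 125.0)
        assert out.data.shape == (2, 7500)
        assert out.fs == 125.0

    def test_dc_preserved(self):
        rec = _rec(np.full((1, 8000), 3.7))
        out = downsample(rec, 125.0)
        assert np.allclose(out.data, 3.7, atol=1e-6)

    def test_30_hz_tone_amplitude_survives(self):
        t = np.arange(16_000) / 1000.0
        rec = _rec(np.sin(2 * np.pi * 30.0 * t))
        out = downsample(rec, 125.0)
        mid = out.data[0][200:-200]  # away from filter edge effects
        assert mid.max() >= 0.9

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ValueError):
            downsample(_rec(np.zeros((1, 1000))), 300.0)


class TestDecomposeBands:
    def test_seven_canonical_bands(self, rng):
        rec = _rec(rng.normal(size=(2, 4000)), fs=125.0)
        stack = decompose_bands(rec)
        assert len(stack.band_names) == 7
        assert stack.data["Gamma"].shape == (2, 4000)

    def test_alpha2_output_centroid_in_band(self, rng):
        from scipy.signal import periodogram

        rec = _rec(rng.normal(size=(1, 60 * 125)), fs=125.0)
        stack = decompose_bands(rec)
        f, p = periodogram(stack.data["Alpha2"][0], fs=125.0)
        centroid = np.sum(f * p) / np.sum(p)
        assert 10.5 <= centroid <= 13.0

    def test_band_outputs_nearly_uncorrelated(self, rng):
        rec = _rec(rng.normal(size=(1, 60 * 125)), fs=125.0)
        stack = decompose_bands(rec)
        r = np.corrcoef(stack.data["Delta"][0], stack.data["Gamma"][0])[0, 1]
        assert abs(r) <= 0.1

    def test_band_above_nyquist_rejected(self, rng):
        rec = _rec(rng.normal(size=(1, 1000)), fs=60.0)
        with pytest.raises(ValueError):
            decompose_bands(rec)

    def test_empty_bandset_rejected(self, rng):
        rec = _rec(rng.normal(size=(1, 1000)), fs=125.0)
        with pytest.raises(ValueError):
            decompose_bands(rec, BandSet(bands=()))


class TestSlidingSegments:
    @pytest.mark.parametrize("dur_s, expected", [(60, 29), (4, 1), (5, 1), (8, 3)])
    def test_segment_counts(self, rng, dur_s, expected):
        rec = _rec(rng.normal(size=(1, dur_s * 125)), fs=125.0)
        segs = sliding_segments(decompose_bands(rec))
        assert len(segs) == expected

    def test_window_sample_count_and_starts(self, rng):
        rec = _rec(rng.normal(size=(2, 20 * 125)), fs=125.0)
        segs = sliding_segments(decompose_bands(rec))
        assert all(s.data["Delta"].shape == (2, 500) for s in segs)
        assert [s.start_s for s in segs] == [2.0 * i for i in range(len(segs))]

    def test_short_recording_gives_empty_list(self, rng):
        rec = _rec(rng.normal(size=(1, 300)), fs=125.0)
        assert sliding_segments(decompose_bands(rec)) == []


class TestSelectBands:
    def _seg(self, rng):
        rec = _rec(rng.normal(size=(2, 8 * 125)), fs=125.0)
        return sliding_segments(decompose_bands(rec))[0]

    @pytest.mark.parametrize(
        "preset, n",
        [
            ("full", 7),
            ("delta-theta-alpha1-alpha2-beta1-beta2-gamma", 7),
            ("delta-theta-alpha2-beta1-beta2-gamma", 6),
            ("delta-alpha2-beta1-beta2-gamma", 5),
            ("delta-alpha2-beta2-gamma", 4),
            ("delta-alpha2-gamma", 3),
            ("delta-gamma", 2),
        ],
    )
    def test_presets(self, rng, preset, n):
        out = select_bands(self._seg(rng), preset)
        assert len(out.band_names) == n

    def test_explicit_list_reordered_canonically(self, rng):
        out = select_bands(self._seg(rng), ["Gamma", "Delta", "Alpha2"])
        assert out.band_names == ["Delta", "Alpha2", "Gamma"]

    def test_duplicates_and_unknown_names_rejected(self, rng):
        seg = self._seg(rng)
        with pytest.raises(ValueError):
            select_bands(seg, ["Delta", "Delta"])
        with pytest.raises(ValueError):
            select_bands(seg, ["Mu"])
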