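"""Unit and property tests for contour extraction and segmentation."""
import numpy as np
import pytest

from conftest import sine
from tonelab.extract import (
    detect_syllable_peaks,
    estimate_vocal_range,
    intensity_contour,
    refine_f0,
    segment_syllables,
    track_f0,
    window_syllable,
)
from tonelab.synth import TONE1, UtteranceSpec, make_speaker_profile, synthesize_utterance
from tonelab.types import Contour, SegmentationError, VocalRange, Waveform

RATE = 44100.0


# ---------------------------------------------------------------------------
# intensity_contour
# ---------------------------------------------------------------------------

def test_intensity_flat_for_stationary_sine():
    c = intensity_contour(Waveform(sine(220, 0.5, amp=1.0), RATE))
    interior = c.values[8:-8]
    assert interior.max() - interior.min() < 0.1


def test_intensity_halved_amplitude_drops_6db():
    c1 = intensity_contour(Waveform(sine(220, 0.5, amp=1.0), RATE))
    c2 = intensity_contour(Waveform(sine(220, 0.5, amp=0.5), RATE))
    diff = c1.values[8:-8] - c2.values[8:-8]
    assert np.allclose(diff, 20 * np.log10(2), atol=0.01)


def test_intensity_all_zero_signal_hits_floor():
    c = intensity_contour(Waveform(np.zeros(int(RATE * 0.2)), RATE))
    assert np.all(c.values == -100.0)


def test_intensity_programmed_dip_recovered(nh_tone4_utterance):
    wave, truth = nh_tone4_utterance
    c = intensity_contour(wave)
    w1, w2 = segment_syllables(c)
    gap = c.slice_ms(w1.offset_ms, w2.onset_ms)
    dip = min(w1.peak_level_db, w2.peak_level_db) - gap.values.min()
    assert dip == pytest.approx(truth.dip_db, abs=1.0)


# ---------------------------------------------------------------------------
# detect_syllable_peaks
# ---------------------------------------------------------------------------

def _bump_contour(depth_db):
    """Two bumps separated by a dip of ``depth_db`` below the lower peak."""
    t = np.arange(0, 600, 5.0)
    v = np.full_like(t, -60.0)
    v += 35.0 * np.exp(-0.5 * ((t - 150) / 50) ** 2)
    v += 35.0 * np.exp(-0.5 * ((t - 450) / 50) ** 2)
    mid = (t > 250) & (t < 350)
    v[mid] = np.maximum(v[mid], -25.0 - depth_db + 0.001 * (t[mid] - 300) ** 2)
    return Contour(5.0, t, v)


def test_two_prominent_bumps_found_at_default_prominence():
    c = _bump_contour(depth_db=35.0)
    (i1, i2), prom = detect_syllable_peaks(c)
    assert prom == 20.0
    assert c.times_ms[i1] == pytest.approx(150, abs=10)
    assert c.times_ms[i2] == pytest.approx(450, abs=10)


def test_shallow_dip_requires_relaxation():
    # peaks at -40 dB, saddle and edges at -55 dB: 15-dB prominences
    t = np.arange(0, 605, 5.0)
    v = -47.5 + 7.5 * np.cos(2 * np.pi * (t - 150) / 300) + 1e-4 * t
    c = Contour(5.0, t, v)
    (i1, i2), prom = detect_syllable_peaks(c)
    assert prom <= 15.0
    assert t[i1] == pytest.approx(150, abs=10)
    assert t[i2] == pytest.approx(450, abs=10)


def test_single_peak_raises_segmentation_error():
    t = np.arange(0, 300, 5.0)
    v = -60 + 40 * np.exp(-0.5 * ((t - 150) / 40) ** 2)
    with pytest.raises(SegmentationError) as err:
        detect_syllable_peaks(Contour(5.0, t, v))
    assert err.value.contour is not None


def brute_force_peaks_and_prominences(v):
    """Exhaustive-scan oracle: every strict local maximum and its
    prominence (height above the higher of the two bases, each base being
    the minimum between the peak and the nearest higher sample or edge)."""
    peaks, proms = [], []
    for i in range(1, len(v) - 1):
        if not (v[i] > v[i - 1] and v[i] > v[i + 1]):
            continue
        left_base = v[i]
        j = i - 1
        while j >= 0 and v[j] <= v[i]:
            left_base = min(left_base, v[j])
            j -= 1
        right_base = v[i]
        j = i + 1
        while j < len(v) and v[j] <= v[i]:
            right_base = min(right_base, v[j])
            j += 1
        peaks.append(i)
        proms.append(v[i] - max(left_base, right_base))
    return np.array(peaks), np.array(proms)


def test_peak_detection_matches_bruteforce_oracle_on_random_envelopes():
    from scipy.signal import find_peaks

    rng = np.random.default_rng(123)
    for _ in range(100):
        n = 150
        x = np.cumsum(rng.standard_normal(n))
        x = np.convolve(x, np.ones(5) / 5, mode="same")
        x += rng.normal(0, 1e-6, n)  # break any accidental plateaus
        ref_peaks, ref_proms = brute_force_peaks_and_prominences(x)
        got_peaks, props = find_peaks(x, prominence=0)
        assert np.array_equal(got_peaks, ref_peaks)
        assert np.allclose(props["prominences"], ref_proms, atol=1e-9)


def test_detect_selection_matches_oracle_rule():
    """The two returned peaks are the two most prominent by the oracle at
    the prominence level actually used."""
    rng = np.random.default_rng(7)
    checked = 0
    for _ in range(100):
        n = 200
        x = np.convolve(np.cumsum(rng.standard_normal(n)), np.ones(7) / 7, "same")
        x = 30 * (x - x.min()) / (np.ptp(x) + 1e-12) - 50
        c = Contour(5.0, np.arange(n) * 5.0, x)
        try:
            (i1, i2), prom = detect_syllable_peaks(c)
        except SegmentationError:
            continue
        peaks, proms = brute_force_peaks_and_prominences(x)
        qual = peaks[proms >= prom]
        qual_proms = proms[proms >= prom]
        top2 = set(qual[np.argsort(qual_proms)[-2:]]) if len(qual) > 2 else set(qual)
        assert {i1, i2} == top2
        checked += 1
    assert checked >= 50


# ---------------------------------------------------------------------------
# window_syllable
# ---------------------------------------------------------------------------

def _triangle_contour():
    t = np.arange(0, 400, 5.0)
    v = -60 + 40 * np.maximum(0, 1 - np.abs(t - 200) / 150)
    return Contour(5.0, t, v)


def test_triangular_peak_half_height_window():
    c = _triangle_contour()
    peak = int(np.argmax(c.values))
    w = window_syllable(c, peak, cutoff_db=20.0)
    # 40 dB triangle over +-150 ms: -20 dB crossing at half distance
    assert w.onset_ms == pytest.approx(125, abs=5)
    assert w.offset_ms == pytest.approx(275, abs=5)


def test_cutoff_10_strictly_narrower():
    c = _triangle_contour()
    peak = int(np.argmax(c.values))
    w20 = window_syllable(c, peak, cutoff_db=20.0)
    w10 = window_syllable(c, peak, cutoff_db=10.0)
    assert w10.onset_ms > w20.onset_ms
    assert w10.offset_ms < w20.offset_ms


def test_windows_nest_across_cutoffs_on_synthetic(nh_tone4_utterance):
    wave, _ = nh_tone4_utterance
    c = intensity_contour(wave)
    w20a, w20b = segment_syllables(c, cutoff_db=20.0)
    w10a, w10b = segment_syllables(c, cutoff_db=10.0)
    for big, small in ((w20a, w10a), (w20b, w10b)):
        assert small.onset_ms >= big.onset_ms
        assert small.offset_ms <= big.offset_ms


def test_window_clamped_at_edge_is_flagged():
    t = np.arange(0, 200, 5.0)
    v = -5 - 0.05 * t  # peak at the very first interior frame
    v[0] = -6.0
    c = Contour(5.0, t, v)
    w = window_syllable(c, 1, cutoff_db=20.0)
    assert w.clamped_onset
    assert w.onset_ms == t[0]


def test_window_bounds_match_generator_truth(nh_tone4_utterance):
    wave, truth = nh_tone4_utterance
    c = intensity_contour(wave)
    w1, w2 = segment_syllables(c)
    assert w1.onset_ms == pytest.approx(truth.syl1_onset_ms, abs=10)
    assert w1.offset_ms == pytest.approx(truth.syl1_offset_ms, abs=10)
    assert w2.onset_ms == pytest.approx(truth.syl2_onset_ms, abs=10)
    assert w2.offset_ms == pytest.approx(truth.syl2_offset_ms, abs=10)


# ---------------------------------------------------------------------------
# track_f0
# ---------------------------------------------------------------------------

def test_pure_tone_tracked_within_1hz():
    c = track_f0(Waveform(sine(220, 0.5), RATE))
    assert np.median(c.values[c.voiced]) == pytest.approx(220.0, abs=1.0)


def test_log_glide_endpoints_within_2hz():
    dur = 2.0
    t = np.arange(int(RATE * dur)) / RATE
    f0 = 220.0 * 2 ** (-t / dur)
    phase = 2 * np.pi * np.cumsum(f0) / RATE
    c = track_f0(Waveform(0.5 * np.sin(phase), RATE))
    vi = np.flatnonzero(c.voiced)
    assert c.values[vi[0]] == pytest.approx(220.0, abs=2.0)
    assert c.values[vi[-1]] == pytest.approx(110.0, abs=2.0)


def test_white_noise_mostly_unvoiced_at_default_threshold():
    rng = np.random.default_rng(0)
    c = track_f0(Waveform(0.3 * rng.standard_normal(int(RATE * 0.5)), RATE))
    assert np.mean(~c.voiced) >= 0.95


def test_silence_all_unvoiced_without_exception():
    c = track_f0(Waveform(np.zeros(int(RATE * 0.3)), RATE))
    assert not c.voiced.any()


def test_invalid_range_rejected():
    with pytest.raises(ValueError):
        track_f0(Waveform(sine(220, 0.2), RATE), fmin=500, fmax=100)


def test_glide_tracking_unbiased_across_seeds():
    """Mean signed error < 0.2 st across 50 seeded harmonic glides."""
    rng = np.random.default_rng(42)
    errors = []
    for _ in range(50):
        f_start = rng.uniform(150, 300)
        octaves = rng.uniform(-0.5, 0.5)
        dur = rng.uniform(0.4, 0.8)
        t = np.arange(int(RATE * dur)) / RATE
        f0 = f_start * 2 ** (octaves * t / dur)
        phase = 2 * np.pi * np.cumsum(f0) / RATE
        x = sum((1 / k**2) * np.sin(k * phase) for k in range(1, 11))
        x = 0.4 * x / np.abs(x).max()
        c = track_f0(Waveform(x, RATE))
        m = c.voiced.copy()
        true_at = np.interp(c.times_ms / 1000.0, t, f0)
        err_st = 12 * (np.log2(c.values[m]) - np.log2(true_at[m]))
        errors.append(np.mean(err_st))
    assert abs(np.mean(errors)) < 0.2


# ---------------------------------------------------------------------------
# estimate_vocal_range / refine_f0
# ---------------------------------------------------------------------------

def test_vocal_range_robust_to_octave_outliers():
    rng = np.random.default_rng(5)
    main = 250.0 * 2 ** rng.normal(0, 0.1, 950)
    outliers = 500.0 * 2 ** rng.normal(0, 0.05, 50)
    vr = estimate_vocal_range(np.concatenate([main, outliers]))
    assert abs(12 * (vr.center_log2hz - np.log2(250.0))) < 1.0


def test_vocal_range_degenerate_distribution():
    vr = estimate_vocal_range(np.full(100, 200.0))
    assert vr.center_log2hz == pytest.approx(np.log2(200.0))
    assert vr.fmin_hz == pytest.approx(200 * 2 ** -0.5)
    assert vr.fmax_hz == pytest.approx(200 * 2 ** 0.5)


def test_vocal_range_band_for_220():
    vr = estimate_vocal_range(np.full(100, 220.0))
    assert vr.fmin_hz == pytest.approx(155.6, abs=0.1)
    assert vr.fmax_hz == pytest.approx(311.1, abs=0.1)


def test_vocal_range_too_few_samples_names_speaker():
    with pytest.raises(ValueError, match="spk9"):
        estimate_vocal_range(np.full(10, 200.0), speaker="spk9")


def test_refine_matches_track_when_inside_band(nh_tone4_utterance):
    wave, truth = nh_tone4_utterance
    broad = track_f0(wave)
    vr = estimate_vocal_range(broad.values[broad.voiced])
    res = refine_f0(wave, vr)
    assert not res.threshold_lowered and not res.range_expanded
    both = res.contour.voiced & broad.voiced[: len(res.contour)]
    dev = np.abs(np.log2(res.contour.values[both]) - np.log2(broad.values[: len(res.contour)][both]))
    assert np.median(dev) * 12 < 0.1


def test_range_expansion_for_high_tone1():
    """Tone 1 far above the vocal-range center is recovered only after the
    band expands; the expansion is logged."""
    prof = make_speaker_profile("NH", 200.0, seed=3)
    prof.jitter_sd = dict(duration_frac=0.0, intensity_db=0.0, f0_st=0.0)
    prof.tone1_median_rel_st = 8.0
    prof.tone1_movement_st = 0.0
    wave, truth = synthesize_utterance(UtteranceSpec(prof, TONE1, 1))
    ic = intensity_contour(wave)
    w1, w2 = segment_syllables(ic)
    broad = track_f0(wave)
    # center the range on the first syllable only, so syllable 2 sits ~8 st up
    sl1 = broad.slice_ms(w1.onset_ms, w1.offset_ms)
    vr = VocalRange(center_log2hz=float(np.mean(np.log2(sl1.values[sl1.voiced]))))
    res = refine_f0(wave, vr, windows=(w1, w2), reference_contour=broad)
    assert res.range_expanded
    sl2 = res.contour.slice_ms(w2.onset_ms, w2.offset_ms)
    med = 12 * (np.median(np.log2(sl2.values[sl2.voiced])) - vr.center_log2hz)
    assert med == pytest.approx(8.0, abs=1.0)


def test_breathy_syllable_recovered_at_low_threshold(nh_profile):
    spec = UtteranceSpec(nh_profile, TONE1, 1, breathiness=0.55)
    wave, _ = synthesize_utterance(spec)
    ic = intensity_contour(wave)
    w1, w2 = segment_syllables(ic)
    broad = track_f0(wave)
    vr = estimate_vocal_range(np.full(100, nh_profile.f0_center_hz))
    res = refine_f0(wave, vr, windows=(w1, w2))
    assert res.threshold_lowered
    sl = res.contour.slice_ms(w2.onset_ms, w2.offset_ms)
    assert np.mean(sl.voiced) >= 0.6
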