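"""Intensity/F0 contour extraction and intensity-based syllable segmentation.

The segmentation strategy mirrors a common workflow for disyllabic tokens:
an intensity contour sampled every 5 ms, peak detection with a 20-dB
prominence requirement (relaxed stepwise when the inter-syllable dip is
shallow), and per-syllable windows trimmed at a fixed cutoff below each
intensity peak.  F0 is tracked by short-term normalized autocorrelation
with parabolic peak interpolation, optionally constrained to a speaker's
fitted vocal range with documented fallbacks for low voicing and
band-edge saturation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .types import (
    Contour,
    SegmentationError,
    SyllableWindow,
    VocalRange,
    Waveform,
)

logger = logging.getLogger(__name__)

STEP_MS = 5.0
INTENSITY_WINDOW_MS = 30.0
F0_WINDOW_MS = 40.0
DB_FLOOR = -100.0
DEFAULT_FMIN = 75.0
DEFAULT_FMAX = 600.0
DEFAULT_VOICING_THRESHOLD = 0.45
ENERGY_GATE_DB = -65.0  # frames quieter than this are never voiced

PROMINENCE_START_DB = 20.0
PROMINENCE_STEP_DB = 2.0
PROMINENCE_FLOOR_DB = 6.0


def _frame_centers(n_samples: int, rate: float, step_ms: float) -> np.ndarray:
    """Frame-center times in ms, spanning the whole signal from t=0."""
    dur_ms = 1000.0 * n_samples / rate
    n_frames = int(np.floor(dur_ms / step_ms)) + 1
    return np.arange(n_frames) * step_ms


def _windowed_frames(
    x: np.ndarray, rate: float, centers_ms: np.ndarray, win_ms: float
) -> np.ndarray:
    """Stack frames (rows) centered on ``centers_ms``, zero-padded at edges."""
    half = int(round(win_ms / 2000.0 * rate))
    n = 2 * half
    padded = np.pad(x, (half, half))
    starts = np.round(centers_ms / 1000.0 * rate).astype(int)
    idx = starts[:, None] + np.arange(n)[None, :]
    return padded[idx]


def intensity_contour(
    wave: Waveform,
    step_ms: float = STEP_MS,
    window_ms: float = INTENSITY_WINDOW_MS,
) -> Contour:
    """Frame RMS energy in dB re full scale, sampled every ``step_ms``.

    A Hanning-weighted RMS over ``window_ms`` is used per frame.  All-zero
    frames sit at the -100 dB floor rather than raising.
    """
    if len(wave) == 0:
        raise ValueError("empty waveform")
    centers = _frame_centers(len(wave), wave.rate, step_ms)
    frames = _windowed_frames(wave.samples, wave.rate, centers, window_ms)
    w = np.hanning(frames.shape[1])
    wsum = np.sum(w)
    ms = np.sum(frames * frames * w[None, :], axis=1) / wsum
    db = np.full_like(ms, DB_FLOOR)
    nz = ms > 0
    db[nz] = np.maximum(10.0 * np.log10(ms[nz]), DB_FLOOR)
    return Contour(step_ms=step_ms, times_ms=centers, values=db)


# ---------------------------------------------------------------------------
# Peak detection and syllable windowing
# ---------------------------------------------------------------------------

def detect_syllable_peaks(
    contour: Contour,
    prominence_start_db: float = PROMINENCE_START_DB,
    prominence_step_db: float = PROMINENCE_STEP_DB,
    prominence_floor_db: float = PROMINENCE_FLOOR_DB,
) -> tuple[tuple[int, int], float]:
    """Locate the two syllable peaks on an intensity contour.

    Starts at the 20-dB prominence requirement and relaxes it in 2-dB steps
    down to a floor whenever fewer than two peaks qualify.  If more than two
    qualify, the two most prominent are kept and returned in temporal order.

    Returns ``((idx1, idx2), prominence_used_db)`` with frame indices into
    the contour.
    """
    if len(contour) < 3:
        raise SegmentationError("contour too short for peak detection", contour)
    prominence = prominence_start_db
    while True:
        peaks, props = sp_signal.find_peaks(contour.values, prominence=prominence)
        if len(peaks) >= 2:
            if len(peaks) > 2:
                top = np.argsort(props["prominences"])[-2:]
                peaks = np.sort(peaks[top])
            return (int(peaks[0]), int(peaks[1])), prominence
        if prominence <= prominence_floor_db:
            raise SegmentationError(
                f"found {len(peaks)} peak(s) even at minimum prominence "
                f"{prominence_floor_db} dB",
                contour,
            )
        prominence = max(prominence - prominence_step_db, prominence_floor_db)


def _cross_time(
    times: np.ndarray, values: np.ndarray, i_lo: int, i_hi: int, level: float
) -> float:
    """Linearly interpolated time where the contour crosses ``level``
    between adjacent frames ``i_lo`` and ``i_hi``."""
    v0, v1 = values[i_lo], values[i_hi]
    if v1 == v0:
        return float(times[i_lo])
    frac = (level - v0) / (v1 - v0)
    return float(times[i_lo] + frac * (times[i_hi] - times[i_lo]))


def window_syllable(
    contour: Contour,
    peak_idx: int,
    cutoff_db: float = 20.0,
    prominence_used_db: float = PROMINENCE_START_DB,
    limit_lo_ms: Optional[float] = None,
    limit_hi_ms: Optional[float] = None,
) -> SyllableWindow:
    """Trim a syllable window on either side of an intensity peak.

    Onset is the last crossing of ``peak - cutoff_db`` before the peak and
    offset the first crossing after it, both linearly interpolated between
    frames.  ``limit_lo_ms``/``limit_hi_ms`` truncate the search (e.g. at
    the inter-syllable minimum) so neighboring syllables cannot overlap.
    If the cutoff is never reached before a limit/edge the window is
    clamped there and flagged.
    """
    v = contour.values
    t = contour.times_ms
    peak_level = float(v[peak_idx])
    level = peak_level - cutoff_db

    lo_bound = t[0] if limit_lo_ms is None else max(limit_lo_ms, t[0])
    hi_bound = t[-1] if limit_hi_ms is None else min(limit_hi_ms, t[-1])

    onset_ms, clamped_onset = lo_bound, True
    for i in range(peak_idx, 0, -1):
        if t[i - 1] < lo_bound:
            break
        if v[i - 1] <= level < v[i] or v[i - 1] <= level <= v[i]:
            onset_ms, clamped_onset = _cross_time(t, v, i - 1, i, level), False
            break

    offset_ms, clamped_offset = hi_bound, True
    for i in range(peak_idx, len(v) - 1):
        if t[i + 1] > hi_bound:
            break
        if v[i + 1] <= level <= v[i]:
            offset_ms, clamped_offset = _cross_time(t, v, i, i + 1, level), False
            break

    return SyllableWindow(
        peak_time_ms=float(t[peak_idx]),
        peak_level_db=peak_level,
        onset_ms=onset_ms,
        offset_ms=offset_ms,
        cutoff_db=cutoff_db,
        prominence_used_db=prominence_used_db,
        clamped_onset=clamped_onset,
        clamped_offset=clamped_offset,
    )


def segment_syllables(
    contour: Contour, cutoff_db: float = 20.0
) -> tuple[SyllableWindow, SyllableWindow]:
    """Detect both syllable peaks and window each one.

    The two windows are truncated at the inter-syllable intensity minimum
    so they can never overlap.
    """
    (i1, i2), prom = detect_syllable_peaks(contour)
    mid = i1 + int(np.argmin(contour.values[i1 : i2 + 1]))
    t_mid = float(contour.times_ms[mid])
    w1 = window_syllable(contour, i1, cutoff_db, prom, limit_hi_ms=t_mid)
    w2 = window_syllable(contour, i2, cutoff_db, prom, limit_lo_ms=t_mid)
    return w1, w2


# ---------------------------------------------------------------------------
# F0 tracking
# ---------------------------------------------------------------------------

def _amplitude_normalized(x: np.ndarray, rate: float, smooth_ms: float = 10.0) -> np.ndarray:
    """Divide the signal by its own smoothed RMS envelope.

    Removes amplitude-envelope tilt from the autocorrelation analysis:
    without it, rising/falling envelopes skew each window's effective time
    centroid and bias F0 on glides.  A floor at -60 dB re the envelope
    peak keeps silence silent.
    """
    win = max(4, int(round(smooth_ms / 1000.0 * rate)))
    kernel = np.ones(win) / win
    env = np.sqrt(np.maximum(sp_signal.fftconvolve(x * x, kernel, mode="same"), 0.0))
    peak = env.max()
    if peak <= 0:
        return x
    return x / np.maximum(env, 1e-3 * peak)


def track_f0(
    wave: Waveform,
    fmin: float = DEFAULT_FMIN,
    fmax: float = DEFAULT_FMAX,
    voicing_threshold: float = DEFAULT_VOICING_THRESHOLD,
    step_ms: float = STEP_MS,
    window_ms: float = F0_WINDOW_MS,
    normalize_envelope: bool = True,
) -> Contour:
    """Autocorrelation F0 tracker sampled every 5 ms.

    Per frame: mean-removed, Hann-weighted normalized autocorrelation with
    lag-window bias correction; the highest local maximum within the lag
    range [rate/fmax, rate/fmin] is taken, refined by parabolic
    interpolation.  Frames whose normalized peak falls below
    ``voicing_threshold`` (or whose raw energy is below an absolute gate)
    are unvoiced.  Octave glitches (> 6 st between adjacent voiced frames)
    are unvoiced, then a 5-point median smoothing pass runs over voiced
    frames.
    """
    if not (0 < fmin < fmax < wave.rate / 2):
        raise ValueError("need 0 < fmin < fmax < Nyquist")
    centers = _frame_centers(len(wave), wave.rate, step_ms)
    raw_frames = _windowed_frames(wave.samples, wave.rate, centers, window_ms)
    if normalize_envelope:
        x = _amplitude_normalized(wave.samples, wave.rate)
        frames = _windowed_frames(x, wave.rate, centers, window_ms)
    else:
        frames = raw_frames
    n = frames.shape[1]

    frames = frames - frames.mean(axis=1, keepdims=True)
    w = np.hanning(n)
    fw = frames * w[None, :]

    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(fw, nfft)
    ac = np.fft.irfft(spec * np.conj(spec), nfft)[:, :n].real

    # normalized AC corrected for the shrinking overlap of the Hann window
    wac = np.fft.irfft(np.abs(np.fft.rfft(w, nfft)) ** 2, nfft)[:n].real
    wac = wac / wac[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = ac / ac[:, :1]
    r = np.where(np.isfinite(r), r, 0.0)
    valid_lag = wac > 0.1
    r_corr = np.zeros_like(r)
    r_corr[:, valid_lag] = r[:, valid_lag] / wac[valid_lag][None, :]

    lag_min = max(2, int(np.floor(wave.rate / fmax)))
    lag_max = min(n - 2, int(np.ceil(wave.rate / fmin)))
    if lag_max <= lag_min:
        raise ValueError("analysis window too short for fmin")

    energy_db = np.full(len(centers), DB_FLOOR)
    ms_energy = np.mean(raw_frames * raw_frames, axis=1)
    nz = ms_energy > 0
    energy_db[nz] = 10.0 * np.log10(ms_energy[nz])

    f0 = np.zeros(len(centers))
    strength = np.zeros(len(centers))
    band = r_corr[:, lag_min : lag_max + 1]
    # local maxima only: exclude monotonic shoulders of the lag-0 peak
    interior = (band[:, 1:-1] >= band[:, :-2]) & (band[:, 1:-1] >= band[:, 2:])
    has_peak = np.any(interior, axis=1)

    # A periodic signal correlates equally well at every multiple of its
    # period; a small per-octave cost breaks those ties toward the true
    # (shortest-lag) period.  Candidate refinement is vectorized over all
    # interior lags at once.
    octave_cost = 0.05
    y0, y1, y2 = band[:, :-2], band[:, 1:-1], band[:, 2:]
    denom = y0 - 2 * y1 + y2
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(denom != 0, 0.5 * (y0 - y2) / denom, 0.0)
    delta = np.clip(delta, -0.5, 0.5)
    s_all = y1 - 0.25 * (y0 - y2) * delta
    lags = lag_min + 1 + np.arange(band.shape[1] - 2)
    score = np.where(interior, s_all - octave_cost * np.log2(lags / lag_min)[None, :], -np.inf)
    best = np.argmax(score, axis=1)
    rows = np.flatnonzero(has_peak)
    strength[rows] = s_all[rows, best[rows]]
    f0[rows] = wave.rate / (lags[best[rows]] + delta[rows, best[rows]])

    voiced = (
        has_peak
        & (strength >= voicing_threshold)
        & (energy_db > ENERGY_GATE_DB)
        & (f0 >= fmin)
        & (f0 <= fmax)
    )

    f0, voiced = _postprocess_f0(f0, voiced)
    return Contour(step_ms=step_ms, times_ms=centers, values=f0, voiced=voiced)


def _postprocess_f0(f0: np.ndarray, voiced: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop octave glitches (> 6 st jumps), then median-smooth voiced runs.

    Glitch removal must precede smoothing: a median filter smears an
    octave error into its neighbors instead of deleting it.
    """
    f0 = f0.copy()
    voiced = voiced.copy()
    vi = np.flatnonzero(voiced)
    if len(vi) >= 2:
        ref = np.median(np.log2(f0[vi]))
        last = vi[0]
        for b in vi[1:]:
            jump = 12.0 * abs(np.log2(f0[b]) - np.log2(f0[last]))
            if jump > 6.0:
                # drop whichever of the pair sits farther from the contour
                # median; runs of glitches all compare against the last
                # *kept* frame so they cannot shelter each other
                if abs(np.log2(f0[b]) - ref) > abs(np.log2(f0[last]) - ref):
                    voiced[b] = False
                else:
                    voiced[last] = False
                    last = b
            else:
                last = b
    vi = np.flatnonzero(voiced)
    if len(vi) >= 5:
        logs = np.log2(f0[vi])
        smoothed = sp_signal.medfilt(logs, kernel_size=5)
        # keep endpoints unsmoothed (medfilt zero-pads)
        smoothed[:2] = logs[:2]
        smoothed[-2:] = logs[-2:]
        f0[vi] = 2.0 ** smoothed
    return f0, voiced


# ---------------------------------------------------------------------------
# Vocal range estimation and constrained re-tracking
# ---------------------------------------------------------------------------

MIN_RANGE_SAMPLES = 50


def estimate_vocal_range(
    f0_values_hz: Sequence[float] | np.ndarray,
    speaker: str = "<unknown>",
    lower_st: float = -6.0,
    upper_st: float = 6.0,
) -> VocalRange:
    """Fit a normal density to pooled log-F0 and center the vocal range on it.

    A single Gaussian is fitted on the log2 axis; one trimming pass
    (drop > 2.5 sigma, refit) discards octave-jump outliers so the center
    reflects the dominant mode.
    """
    x = np.log2(np.asarray(f0_values_hz, dtype=float))
    x = x[np.isfinite(x)]
    if len(x) < MIN_RANGE_SAMPLES:
        raise ValueError(
            f"vocal range for speaker {speaker!r} needs >= {MIN_RANGE_SAMPLES} "
            f"voiced F0 samples, got {len(x)}"
        )
    mu, sd = sp_stats.norm.fit(x)
    if sd > 0:
        keep = np.abs(x - mu) <= 2.5 * sd
        if keep.sum() >= MIN_RANGE_SAMPLES // 2:
            mu, _ = sp_stats.norm.fit(x[keep])
    return VocalRange(center_log2hz=float(mu), lower_st=lower_st, upper_st=upper_st)


@dataclass
class RefineResult:
    """Constrained F0 contour plus the fallback decisions taken."""

    contour: Contour
    vocal_range: VocalRange
    threshold_lowered: bool = False
    range_expanded: bool = False
    notes: list[str] = field(default_factory=list)


LOW_VOICING_COVERAGE = 0.60
EDGE_SATURATION_ST = 0.25
EDGE_SATURATION_RUN = 3


def _coverage(contour: Contour, windows: Sequence[SyllableWindow]) -> float:
    """Smallest voiced fraction across the syllable windows."""
    fracs = []
    for win in windows:
        sl = contour.slice_ms(win.onset_ms, win.offset_ms)
        if len(sl) == 0:
            fracs.append(0.0)
        else:
            fracs.append(float(np.mean(sl.voiced)))
    return min(fracs) if fracs else 0.0


def _edge_saturated(contour: Contour, vr: VocalRange) -> bool:
    if contour.voiced is None or not contour.voiced.any():
        return False
    st = np.full(len(contour), np.nan)
    pos = contour.voiced & (contour.values > 0)
    st[pos] = 12.0 * (np.log2(contour.values[pos]) - vr.center_log2hz)
    near = pos & (
        (st <= vr.lower_st + EDGE_SATURATION_ST) | (st >= vr.upper_st - EDGE_SATURATION_ST)
    )
    run = 0
    for flag in near:
        run = run + 1 if flag else 0
        if run >= EDGE_SATURATION_RUN:
            return True
    return False


def _octave_disagreement(contour: Contour, reference: Contour) -> bool:
    """True when the constrained track disagrees with the broad-range track
    by > 3 st on >= 3 consecutive frames (the narrow band has folded the
    contour onto a subharmonic)."""
    if reference.voiced is None or contour.voiced is None:
        return False
    n = min(len(contour), len(reference))
    both = contour.voiced[:n] & reference.voiced[:n]
    ok = both & (contour.values[:n] > 0) & (reference.values[:n] > 0)
    diff = np.zeros(n)
    diff[ok] = 12.0 * np.abs(
        np.log2(contour.values[:n][ok]) - np.log2(reference.values[:n][ok])
    )
    run = 0
    for i in range(n):
        run = run + 1 if (ok[i] and diff[i] > 3.0) else 0
        if run >= EDGE_SATURATION_RUN:
            return True
    return False


def refine_f0(
    wave: Waveform,
    vocal_range: VocalRange,
    windows: Optional[Sequence[SyllableWindow]] = None,
    step_ms: float = STEP_MS,
    reference_contour: Optional[Contour] = None,
) -> RefineResult:
    """Re-track F0 constrained to the speaker's vocal range.

    Fallback 1: if voiced coverage of any syllable window is below 60%,
    retry at voicing threshold 0.1.  Fallback 2: if voiced frames saturate
    at a band edge (>= 3 consecutive frames within 0.25 st) — or, when a
    broad-range ``reference_contour`` is supplied, if the constrained track
    disagrees with it by more than 3 st in a sustained way — retry with the
    band expanded to (+12, -9) st.  Decisions are recorded on the result.
    """
    result = RefineResult(contour=None, vocal_range=vocal_range)  # type: ignore[arg-type]

    def _track(vr: VocalRange) -> Contour:
        return track_f0(
            wave,
            fmin=vr.fmin_hz,
            fmax=vr.fmax_hz,
            voicing_threshold=vr.voicing_threshold,
            step_ms=step_ms,
        )

    vr = vocal_range
    contour = _track(vr)

    if windows is not None and _coverage(contour, windows) < LOW_VOICING_COVERAGE:
        vr = vr.with_threshold(0.1)
        contour = _track(vr)
        result.threshold_lowered = True
        result.notes.append("voiced coverage < 60%: voicing threshold lowered to 0.1")

    needs_expansion = _edge_saturated(contour, vr)
    if not needs_expansion and reference_contour is not None:
        needs_expansion = _octave_disagreement(contour, reference_contour)
    if needs_expansion:
        vr = vr.expanded(lower_st=-9.0, upper_st=12.0)
        contour = _track(vr)
        result.range_expanded = True
        result.notes.append(
            "band-edge saturation or broad-track disagreement: "
            "range expanded to (+12, -9) st"
        )

    result.contour = contour
    result.vocal_range = vr
    if windows is not None:
        for win in windows:
            sl = contour.slice_ms(win.onset_ms, win.offset_ms)
            if int(np.sum(sl.voiced)) < 2:
                result.notes.append(
                    f"window at {win.peak_time_ms:.0f} ms has < 2 voiced frames "
                    "after all fallbacks"
                )
    return result
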