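"""The four production descriptors and normalized contour summaries.

All F0 arithmetic happens on the log2 axis; semitones are 12*log2(f/ref).
Syllable 2 is summarized by its median, syllable 1 (the reference) by its
mean — matching how normalized F0 patterns are scaled.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .types import (
    Contour,
    DescriptorUnavailable,
    NormalizedPattern,
    SyllableWindow,
    ToneDescriptors,
)

EDGE_WINDOW_MS = 30.0


def duration_ratio(win1: SyllableWindow, win2: SyllableWindow) -> float:
    """Syllable-2 length over syllable-1 length."""
    if win1.duration_ms <= 0 or win2.duration_ms <= 0:
        raise ValueError("zero-length syllable window")
    return win2.duration_ms / win1.duration_ms


def intensity_peak_difference(win1: SyllableWindow, win2: SyllableWindow) -> float:
    """Syllable-2 intensity peak minus syllable-1 peak, in dB."""
    return win2.peak_level_db - win1.peak_level_db


def _voiced_log2(f0: Contour, win: SyllableWindow) -> tuple[np.ndarray, np.ndarray]:
    sl = f0.slice_ms(win.onset_ms, win.offset_ms)
    if sl.voiced is None:
        raise ValueError("F0 contour lacks voicing flags")
    t = sl.times_ms[sl.voiced]
    v = np.log2(sl.values[sl.voiced])
    return t, v


def f0_median_relative(f0: Contour, win1: SyllableWindow, win2: SyllableWindow) -> float:
    """12*(median log2-F0 of syllable 2 - mean log2-F0 of syllable 1)."""
    _, v1 = _voiced_log2(f0, win1)
    _, v2 = _voiced_log2(f0, win2)
    if len(v1) < 2 or len(v2) < 2:
        raise DescriptorUnavailable("need >= 2 voiced frames in each window")
    return 12.0 * float(np.median(v2) - np.mean(v1))


def f0_movement(
    f0: Contour,
    win2: SyllableWindow,
    edge_ms: float = EDGE_WINDOW_MS,
    voiced_only: bool = True,
) -> float:
    """Mean log2-F0 of the last ``edge_ms`` minus the first ``edge_ms`` of
    the second syllable, in semitones.  Negative = falling.

    With ``voiced_only`` (default) the edges are taken over the first/last
    voiced frames, skipping inward past unvoiced edge frames; otherwise the
    edges are fixed time spans and any unvoiced frame there makes the
    descriptor unavailable.
    """
    if voiced_only:
        t, v = _voiced_log2(f0, win2)
        if len(t) == 0 or (t[-1] - t[0]) < 2 * edge_ms:
            raise DescriptorUnavailable("window holds < 60 ms of voiced material")
        first = v[t <= t[0] + edge_ms - 1e-9]
        last = v[t >= t[-1] - edge_ms + 1e-9]
    else:
        sl = f0.slice_ms(win2.onset_ms, win2.offset_ms)
        if win2.duration_ms < 2 * edge_ms:
            raise DescriptorUnavailable("window shorter than two edge spans")
        m_first = sl.times_ms <= win2.onset_ms + edge_ms
        m_last = sl.times_ms >= win2.offset_ms - edge_ms
        if not (sl.voiced[m_first].all() and sl.voiced[m_last].all()):
            raise DescriptorUnavailable("unvoiced frames inside an edge span")
        first = np.log2(sl.values[m_first])
        last = np.log2(sl.values[m_last])
    if len(first) == 0 or len(last) == 0:
        raise DescriptorUnavailable("empty edge span")
    return 12.0 * float(np.mean(last) - np.mean(first))


def compute_descriptors(
    intensity: Contour,
    f0: Contour,
    win1: SyllableWindow,
    win2: SyllableWindow,
    cutoff_db: float = 20.0,
) -> ToneDescriptors:
    """All four descriptors; F0 descriptors flagged unavailable on failure."""
    try:
        med = f0_median_relative(f0, win1, win2)
    except DescriptorUnavailable:
        med = None
    try:
        mov = f0_movement(f0, win2)
    except DescriptorUnavailable:
        mov = None
    return ToneDescriptors(
        duration_ratio=duration_ratio(win1, win2),
        intensity_peak_diff_db=intensity_peak_difference(win1, win2),
        f0_median_rel_st=med,
        f0_movement_st=mov,
        cutoff_db=cutoff_db,
    )


# ---------------------------------------------------------------------------
# Normalized 100-point patterns
# ---------------------------------------------------------------------------

def normalize_pattern(
    contour: Contour,
    window: SyllableWindow,
    kind: str,
    ref: Optional[float] = None,
    max_unvoiced_frac: float = 0.30,
) -> NormalizedPattern:
    """Resample a windowed contour onto 100 points over 0-100% of the window.

    Intensity patterns are expressed in dB relative to the within-window
    peak; F0 patterns in semitones relative to ``ref`` (the syllable-1 mean
    log2-F0), interpolated across voiced frames only.
    """
    sl = contour.slice_ms(window.onset_ms, window.offset_ms)
    if len(sl) < 2:
        raise ValueError("window too short to resample")
    grid = np.linspace(window.onset_ms, window.offset_ms, NormalizedPattern.N_POINTS)
    if kind == "intensity":
        pts = np.interp(grid, sl.times_ms, sl.values)
        pts = pts - np.max(pts)
    elif kind == "f0":
        if ref is None:
            raise ValueError("f0 patterns need ref = syllable-1 mean log2-F0")
        if sl.voiced is None:
            raise ValueError("F0 contour lacks voicing flags")
        frac_unvoiced = 1.0 - float(np.mean(sl.voiced))
        if frac_unvoiced > max_unvoiced_frac:
            raise DescriptorUnavailable(
                f"{frac_unvoiced:.0%} of the window is unvoiced"
            )
        t = sl.times_ms[sl.voiced]
        v = np.log2(sl.values[sl.voiced])
        pts = 12.0 * (np.interp(grid, t, v) - ref)
    else:
        raise ValueError(f"unknown pattern kind {kind!r}")
    return NormalizedPattern(kind=kind, points=pts)


def aggregate_patterns(
    patterns: Sequence[NormalizedPattern],
    speakers: Optional[Sequence[str]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise (mean, standard error) across speakers.

    Repetitions are averaged within speaker first, then across speakers;
    without speaker labels every pattern counts as its own speaker.
    """
    if len(patterns) < 2:
        raise ValueError("need >= 2 patterns")
    kinds = {p.kind for p in patterns}
    if len(kinds) > 1:
        raise ValueError(f"mixed pattern kinds: {sorted(kinds)}")
    mat = np.stack([p.points for p in patterns])
    if speakers is None:
        speaker_means = mat
    else:
        speakers = np.asarray(speakers)
        if len(speakers) != len(patterns):
            raise ValueError("one speaker label per pattern required")
        speaker_means = np.stack(
            [mat[speakers == s].mean(axis=0) for s in np.unique(speakers)]
        )
    mean = speaker_means.mean(axis=0)
    n = speaker_means.shape[0]
    se = speaker_means.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return mean, se
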