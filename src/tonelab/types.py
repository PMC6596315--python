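"""Shared domain types for waveforms, contours, windows and descriptors."""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

SEMITONES_PER_OCTAVE = 12.0


def hz_to_st(f_hz: np.ndarray | float, ref_hz: float = 1.0) -> np.ndarray | float:
    """Convert frequency to semitones re ``ref_hz``: st = 12*log2(f/ref)."""
    return SEMITONES_PER_OCTAVE * np.log2(np.asarray(f_hz, dtype=float) / ref_hz)


def st_to_hz(st: np.ndarray | float, ref_hz: float = 1.0) -> np.ndarray | float:
    return ref_hz * 2.0 ** (np.asarray(st, dtype=float) / SEMITONES_PER_OCTAVE)


@dataclass
class Waveform:
    """Mono audio signal with samples in [-1, 1]."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.duration_s

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class Contour:
    """Uniformly sampled contour (intensity in dB or F0 in Hz).

    ``times_ms`` are frame centers; ``voiced`` is present for F0 contours
    only.  Unvoiced frames keep their raw candidate value but must be
    masked through ``voiced`` for any statistic.
    """

    step_ms: float
    times_ms: np.ndarray
    values: np.ndarray
    voiced: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.voiced is not None:
            self.voiced = np.asarray(self.voiced, dtype=bool)
            if self.voiced.shape != self.values.shape:
                raise ValueError("voiced mask shape mismatch")
        if self.times_ms.shape != self.values.shape:
            raise ValueError("times/values shape mismatch")

    def __len__(self) -> int:
        return len(self.values)

    def slice_ms(self, start_ms: float, stop_ms: float) -> "Contour":
        m = (self.times_ms >= start_ms) & (self.times_ms <= stop_ms)
        return Contour(
            step_ms=self.step_ms,
            times_ms=self.times_ms[m],
            values=self.values[m],
            voiced=None if self.voiced is None else self.voiced[m],
        )

    def voiced_values(self) -> np.ndarray:
        if self.voiced is None:
            return self.values
        return self.values[self.voiced]


@dataclass
class SyllableWindow:
    """One syllable's span derived from the intensity contour."""

    peak_time_ms: float
    peak_level_db: float
    onset_ms: float
    offset_ms: float
    cutoff_db: float
    prominence_used_db: float
    clamped_onset: bool = False
    clamped_offset: bool = False

    def __post_init__(self) -> None:
        if not (self.onset_ms < self.peak_time_ms < self.offset_ms):
            raise ValueError(
                f"window must bracket its peak: onset={self.onset_ms}, "
                f"peak={self.peak_time_ms}, offset={self.offset_ms}"
            )

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass
class VocalRange:
    """Speaker vocal range: center of log2-F0 with semitone bounds."""

    center_log2hz: float
    lower_st: float = -6.0
    upper_st: float = 6.0
    voicing_threshold: float = 0.45

    def __post_init__(self) -> None:
        if not (self.lower_st < 0 < self.upper_st):
            raise ValueError("bounds must bracket the center")
        if self.lower_st < -9.0 or self.upper_st > 12.0:
            raise ValueError("expansion bounded by (-9, +12) semitones")
        if not (0 < self.voicing_threshold <= 1):
            raise ValueError("voicing threshold must lie in (0, 1]")

    @property
    def center_hz(self) -> float:
        return float(2.0 ** self.center_log2hz)

    @property
    def fmin_hz(self) -> float:
        return float(2.0 ** (self.center_log2hz + self.lower_st / 12.0))

    @property
    def fmax_hz(self) -> float:
        return float(2.0 ** (self.center_log2hz + self.upper_st / 12.0))

    def expanded(self, lower_st: float = -9.0, upper_st: float = 12.0) -> "VocalRange":
        return replace(self, lower_st=lower_st, upper_st=upper_st)

    def with_threshold(self, threshold: float) -> "VocalRange":
        return replace(self, voicing_threshold=threshold)


@dataclass
class ToneDescriptors:
    """The four per-token production measures."""

    duration_ratio: Optional[float]
    intensity_peak_diff_db: Optional[float]
    f0_median_rel_st: Optional[float]
    f0_movement_st: Optional[float]
    cutoff_db: float = 20.0

    def available(self) -> dict[str, bool]:
        return {
            "duration_ratio": self.duration_ratio is not None,
            "intensity_peak_diff_db": self.intensity_peak_diff_db is not None,
            "f0_median_rel_st": self.f0_median_rel_st is not None,
            "f0_movement_st": self.f0_movement_st is not None,
        }


@dataclass
class NormalizedPattern:
    """A contour resampled to 100 points over 0-100% of a window."""

    kind: str  # "intensity" | "f0"
    points: np.ndarray

    N_POINTS = 100

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.kind not in ("intensity", "f0"):
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        if self.points.shape != (self.N_POINTS,):
            raise ValueError(f"pattern must hold exactly {self.N_POINTS} points")


class SegmentationError(RuntimeError):
    """Fewer than two syllable peaks found even at minimum prominence."""

    def __init__(self, message: str, contour: Optional[Contour] = None):
        super().__init__(message)
        self.contour = contour


class DescriptorUnavailable(RuntimeError):
    """A descriptor could not be computed (insufficient voicing etc.)."""
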