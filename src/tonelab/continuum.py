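"""Tone 1 - Tone 4 perception continuum: 8 F0 slopes x 6 durations x 2
F0 heights = 96 tokens per session, RMS-equalized.

Tokens are rendered by regenerating the second syllable from source
parameters (exact F0/duration control): duration is scaled to
``duration_pct`` of the base and F0 follows a line in log2-F0 anchored at
``f0_height_hz`` at the syllable onset, reaching ``f0_height * 2**slope``
at the offset.  The first syllable and the amplitude contour are left
untouched.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .synth import (
    DEFAULT_DIP_DB,
    DEFAULT_RATE,
    SYL1_PEAK_DBFS,
    TONE1,
    assemble_disyllable,
    _harmonic_source,
    _syl1_f0_st,
    _syllable_env_db,
)
from .types import Waveform, st_to_hz

F0_SLOPE_GRID_OCT = (-1.0, -0.8, -0.6, -0.4, -0.3, -0.2, -0.1, 0.0)
DURATION_GRID_PCT = (40.0, 60.0, 80.0, 100.0, 120.0, 140.0)
F0_HEIGHT_GRID_HZ = (120.0, 220.0)


@dataclass(frozen=True)
class ContinuumTokenSpec:
    f0_slope_oct: float
    duration_pct: float
    f0_height_hz: float
    session: int = 1

    @property
    def token_id(self) -> str:
        return (
            f"h{self.f0_height_hz:.0f}_s{self.f0_slope_oct:+.1f}_"
            f"d{self.duration_pct:.0f}"
        )


def build_token_grid(session: int = 1) -> list[ContinuumTokenSpec]:
    """Full factorial 8 x 6 x 2 = 96 unique token specs."""
    return [
        ContinuumTokenSpec(s, d, h, session)
        for h in F0_HEIGHT_GRID_HZ
        for s in F0_SLOPE_GRID_OCT
        for d in DURATION_GRID_PCT
    ]


@dataclass
class BaseSyllable:
    """Parametric base for token rendering: the un-manipulated disyllable."""

    syl1_duration_ms: float = 300.0
    syl2_duration_ms: float = 330.0
    int_peak_diff_db: float = 2.0
    pad_ms: float = 400.0
    seed: int = 0


def render_token(
    base: BaseSyllable, spec: ContinuumTokenSpec, rate: float = DEFAULT_RATE
) -> Waveform:
    """Render one continuum token as a full disyllable.

    Only the second syllable is manipulated: its duration becomes
    ``duration_pct`` of the base and its F0 runs log-linearly from
    ``f0_height_hz`` down (or flat) by ``f0_slope_oct`` octaves.  The first
    syllable (Tone 3 shape around the same F0 height) and the amplitude
    contour are identical across all tokens of a given height.
    """
    if spec.f0_slope_oct not in F0_SLOPE_GRID_OCT or spec.duration_pct not in DURATION_GRID_PCT:
        warnings.warn("token spec off the standard grid", stacklevel=2)
    d2 = base.syl2_duration_ms * spec.duration_pct / 100.0
    if d2 <= 0:
        raise ValueError("non-positive syllable duration")

    n1 = int(round(base.syl1_duration_ms / 1000.0 * rate))
    n2 = int(round(d2 / 1000.0 * rate))
    n_pad = int(round(base.pad_ms / 1000.0 * rate))

    # amplitude contour is not manipulated: same Tone-1-shaped envelope for
    # every token, time-scaled with the duration manipulation
    env1 = _syllable_env_db(n1, rate, None)
    env2 = _syllable_env_db(n2, rate, TONE1)
    st1 = _syl1_f0_st(n1)  # zero-mean dipping shape around the height
    st2 = 12.0 * spec.f0_slope_oct * np.linspace(0.0, 1.0, n2)
    env_amp, st, _bounds = assemble_disyllable(
        env1, env2, SYL1_PEAK_DBFS, SYL1_PEAK_DBFS + base.int_peak_diff_db,
        DEFAULT_DIP_DB, st1, st2, rate,
    )
    f0_hz = st_to_hz(st, ref_hz=spec.f0_height_hz)

    rng = np.random.default_rng([base.seed, int(spec.f0_height_hz), 0x70CE])
    source = _harmonic_source(f0_hz, rate, spec.f0_height_hz, rng)
    voiced = source * env_amp
    if not np.any(np.abs(voiced) > 0):
        raise ValueError("unvoiced base syllable")
    pad = np.zeros(n_pad)
    samples = np.concatenate([pad, voiced, pad])
    if np.max(np.abs(samples)) > 1.0:
        raise ValueError("token clipped")
    return Waveform(samples, rate)


def measure_token(wave: Waveform, fmin: float = 45.0, fmax: float = 500.0) -> dict:
    """Round-trip analysis of a continuum token.

    Returns the measured second-syllable duration (ms) and F0 slope
    (octaves over the syllable, from a linear regression of log2-F0 on
    time over the voiced frames of the syllable window).
    """
    from .extract import intensity_contour, segment_syllables, track_f0

    ic = intensity_contour(wave)
    win1, win2 = segment_syllables(ic)
    f0c = track_f0(wave, fmin=fmin, fmax=fmax)
    sl = f0c.slice_ms(win2.onset_ms, win2.offset_ms)
    t = sl.times_ms[sl.voiced]
    v = np.log2(sl.values[sl.voiced])
    if len(t) < 4:
        raise ValueError("too few voiced frames to measure token")
    rate_oct_s = float(np.polyfit((t - t[0]) / 1000.0, v, 1)[0])
    duration_ms = win2.duration_ms
    return dict(
        duration_ms=float(duration_ms),
        f0_slope_oct=rate_oct_s * duration_ms / 1000.0,
        onset_f0_hz=float(2.0 ** v[0]),
        offset_f0_hz=float(2.0 ** v[-1]),
    )


def rms_db(wave: Waveform, threshold_dbfs: float = -60.0) -> float:
    """RMS in dBFS over the non-silent span of the token."""
    x = wave.samples
    if not np.any(x != 0):
        raise ValueError("silent token")
    frame = int(round(0.005 * wave.rate))
    n = len(x) // frame
    seg = x[: n * frame].reshape(n, frame)
    seg_rms = np.sqrt(np.mean(seg**2, axis=1))
    active = seg_rms > 10.0 ** (threshold_dbfs / 20.0)
    if not active.any():
        raise ValueError("silent token")
    return float(20.0 * np.log10(np.sqrt(np.mean(seg[active] ** 2))))


def equalize_rms(
    tokens: Sequence[Waveform], target_dbfs: Optional[float] = None
) -> list[Waveform]:
    """Scale every token to a common RMS over its non-silent span."""
    if len(tokens) == 0:
        raise ValueError("no tokens to equalize")
    levels = [rms_db(t) for t in tokens]
    if target_dbfs is None:
        target_dbfs = float(np.mean(levels))
    out = []
    for tok, lvl in zip(tokens, levels):
        gain = 10.0 ** ((target_dbfs - lvl) / 20.0)
        scaled = tok.samples * gain
        peak = np.max(np.abs(scaled))
        if peak > 1.0:  # keep 16-bit representable; preserve equal RMS
            raise ValueError("equalization target clips; lower target_dbfs")
        out.append(Waveform(scaled, tok.rate))
    return out


def build_session(
    base: Optional[BaseSyllable] = None,
    session: int = 1,
    seed: int = 0,
    equalize: bool = True,
    target_dbfs: float = -20.0,
) -> tuple[list[ContinuumTokenSpec], list[Waveform], pd.DataFrame]:
    """Render all 96 tokens of one session in seeded random presentation
    order, RMS-equalized, with a manifest."""
    base = base or BaseSyllable()
    grid = build_token_grid(session)
    rng = np.random.default_rng([int(seed), session, 0x5E55])
    order = rng.permutation(len(grid))
    specs = [grid[i] for i in order]
    waves = [render_token(base, s) for s in specs]
    if equalize:
        waves = equalize_rms(waves, target_dbfs=target_dbfs)
    manifest = pd.DataFrame(
        dict(
            token_id=[s.token_id for s in specs],
            session=session,
            f0_slope_oct=[s.f0_slope_oct for s in specs],
            duration_pct=[s.duration_pct for s in specs],
            f0_height_hz=[s.f0_height_hz for s in specs],
            rms_db=[rms_db(w) for w in waves],
        )
    )
    return specs, waves, manifest
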