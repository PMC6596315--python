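"""Seeded synthesis of disyllabic tone utterances and 2AFC listener responses.

Utterances carry a dipping (Tone 3) first syllable and a level/rising
(Tone 1) or falling (Tone 4) second syllable.  The voiced source is a
harmonic pulse train (20 harmonics, -12 dB/oct roll-off, mild vowel-like
resonance) shaped by a dB-domain intensity envelope.  Every generating
parameter is recorded so the analysis pipeline can be validated by
parameter recovery.

Envelope geometry: each syllable has a "core" spanning exactly its
nominal duration between the two (peak - 20 dB) points, with fixed-length
edge ramps outside the core that descend to the inter-syllable floor.
Because the edge ramps are identical in shape and duration for every
syllable, frame-averaging in the intensity analysis displaces both
measured window edges by the same amount, and duration ratios survive the
round trip essentially unchanged.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .types import Waveform, st_to_hz

TONE1 = "Tone1"
TONE4 = "Tone4"
GROUPS = ("NH", "CI")

DEFAULT_RATE = 44100.0
BRIDGE_MS = 12.0  # half-span of the power-linear bridge at each core edge
LEAD_MS = 40.0  # low-level floor before/after the syllable cores
GAP_MS = 100.0  # floor between the two syllable cores
CORE_EDGE_DB = -20.0
BRIDGE_SHOULDER_DB = CORE_EDGE_DB + 10.0 * np.log10(2.0)  # 2x the edge power
CORE_SHOULDER_DB = -6.0
SYL1_PEAK_DBFS = -15.0
DEFAULT_DIP_DB = 30.0
SHALLOW_DIP_DB = 15.0
N_HARMONICS = 20

# Group-level production strategies (means of the speaker distributions).
# NH speakers mark the tones with F0 almost exclusively; CI speakers
# contrast duration (prolonging Tone 1) and produce a flat Tone 1 contour.
GROUP_DEFAULTS: dict[str, dict[str, float]] = {
    "NH": dict(
        dur_ratio_tone1=1.15,
        dur_ratio_tone4=1.15,
        tone1_median_rel_st=4.5,
        tone1_movement_st=2.0,
        tone4_median_rel_st=0.75,
        tone4_movement_st=-4.5,
        int_peak_diff_tone1_db=1.5,
        int_peak_diff_tone4_db=3.5,
        syl1_duration_ms=300.0,
    ),
    "CI": dict(
        dur_ratio_tone1=1.30,
        dur_ratio_tone4=1.00,
        tone1_median_rel_st=3.0,
        tone1_movement_st=0.0,
        tone4_median_rel_st=0.75,
        tone4_movement_st=-4.5,
        int_peak_diff_tone1_db=-1.0,
        int_peak_diff_tone4_db=1.5,
        syl1_duration_ms=350.0,
    ),
}

# Between-speaker SDs around the group means.
BETWEEN_SPEAKER_SD = dict(
    dur_ratio=0.05,
    st=0.5,
    int_db=0.5,
    syl1_duration_frac=0.08,
)

DEFAULT_JITTER_SD = dict(duration_frac=0.05, intensity_db=1.0, f0_st=0.5)


@dataclass
class SpeakerProfile:
    group: str
    f0_center_hz: float
    tone1_median_rel_st: float
    tone1_movement_st: float
    tone4_median_rel_st: float
    tone4_movement_st: float
    dur_ratio_tone1: float
    dur_ratio_tone4: float
    int_peak_diff_tone1_db: float
    int_peak_diff_tone4_db: float
    syl1_duration_ms: float
    jitter_sd: dict = field(default_factory=lambda: dict(DEFAULT_JITTER_SD))
    seed: int = 0
    speaker_id: str = "spk"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if not (75.0 <= self.f0_center_hz <= 600.0):
            raise ValueError("f0_center_hz must lie within [75, 600] Hz")
        if self.dur_ratio_tone1 <= 0 or self.dur_ratio_tone4 <= 0:
            raise ValueError("duration ratios must be positive")
        if self.syl1_duration_ms <= 60.0:
            raise ValueError("syl1_duration_ms must exceed 60 ms")


def make_speaker_profile(
    group: str,
    f0_center_hz: float,
    seed: int,
    speaker_id: Optional[str] = None,
    jitter_sd: Optional[dict] = None,
) -> SpeakerProfile:
    """Group-default production strategy plus seeded between-speaker variation."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    d = GROUP_DEFAULTS[group]
    rng = np.random.default_rng([int(seed), 0x5EED])
    sd = BETWEEN_SPEAKER_SD
    return SpeakerProfile(
        group=group,
        f0_center_hz=float(f0_center_hz),
        tone1_median_rel_st=d["tone1_median_rel_st"] + rng.normal(0, sd["st"]),
        tone1_movement_st=d["tone1_movement_st"] + rng.normal(0, sd["st"]),
        tone4_median_rel_st=d["tone4_median_rel_st"] + rng.normal(0, sd["st"]),
        tone4_movement_st=d["tone4_movement_st"] + rng.normal(0, sd["st"]),
        dur_ratio_tone1=d["dur_ratio_tone1"] + rng.normal(0, sd["dur_ratio"]),
        dur_ratio_tone4=d["dur_ratio_tone4"] + rng.normal(0, sd["dur_ratio"]),
        int_peak_diff_tone1_db=d["int_peak_diff_tone1_db"] + rng.normal(0, sd["int_db"]),
        int_peak_diff_tone4_db=d["int_peak_diff_tone4_db"] + rng.normal(0, sd["int_db"]),
        syl1_duration_ms=d["syl1_duration_ms"]
        * (1 + rng.normal(0, sd["syl1_duration_frac"])),
        jitter_sd=dict(jitter_sd) if jitter_sd is not None else dict(DEFAULT_JITTER_SD),
        seed=int(seed),
        speaker_id=speaker_id or f"{group}{seed:03d}",
    )


@dataclass
class UtteranceSpec:
    profile: SpeakerProfile
    tone: str
    repetition: int = 1
    pad_ms: float = 400.0
    shallow_dip: bool = False
    breathiness: float = 0.0  # 0 = fully periodic source

    def __post_init__(self) -> None:
        if self.tone not in (TONE1, TONE4):
            raise ValueError(f"tone must be {TONE1} or {TONE4}")
        if self.pad_ms < 0:
            raise ValueError("pad_ms must be non-negative")
        if self.repetition < 1:
            raise ValueError("repetition index starts at 1")


@dataclass
class RealizedParams:
    """Post-jitter generating truth for one utterance."""

    tone: str
    syl1_duration_ms: float
    syl2_duration_ms: float
    duration_ratio: float
    syl1_peak_dbfs: float
    int_peak_diff_db: float
    f0_center_hz: float
    f0_median_rel_st: float
    f0_movement_st: float
    dip_db: float
    # nucleus (core) bounds in the final padded signal
    syl1_onset_ms: float = 0.0
    syl1_offset_ms: float = 0.0
    syl2_onset_ms: float = 0.0
    syl2_offset_ms: float = 0.0


def realize_params(spec: UtteranceSpec) -> RealizedParams:
    """Apply seeded repetition jitter to the profile parameters.

    Deterministic per (profile seed, tone, repetition).
    """
    p = spec.profile
    tone_code = 1 if spec.tone == TONE1 else 4
    rng = np.random.default_rng([p.seed, tone_code, spec.repetition, 0xA11D])
    j = p.jitter_sd
    if spec.tone == TONE1:
        ratio = p.dur_ratio_tone1
        int_diff = p.int_peak_diff_tone1_db
        med = p.tone1_median_rel_st
        mov = p.tone1_movement_st
    else:
        ratio = p.dur_ratio_tone4
        int_diff = p.int_peak_diff_tone4_db
        med = p.tone4_median_rel_st
        mov = p.tone4_movement_st
    d1 = p.syl1_duration_ms * (1 + rng.normal(0, j["duration_frac"]))
    ratio = ratio * (1 + rng.normal(0, j["duration_frac"]))
    d2 = d1 * ratio
    if d1 <= 0 or d2 <= 0:
        raise ValueError("parameters produce non-positive syllable duration")
    return RealizedParams(
        tone=spec.tone,
        syl1_duration_ms=d1,
        syl2_duration_ms=d2,
        duration_ratio=ratio,
        syl1_peak_dbfs=SYL1_PEAK_DBFS,
        int_peak_diff_db=int_diff + rng.normal(0, j["intensity_db"]),
        f0_center_hz=p.f0_center_hz,
        f0_median_rel_st=med + rng.normal(0, j["f0_st"]),
        f0_movement_st=mov + rng.normal(0, j["f0_st"]),
        dip_db=SHALLOW_DIP_DB if spec.shallow_dip else DEFAULT_DIP_DB,
    )


# ---------------------------------------------------------------------------
# Envelope and F0 trajectory construction
# ---------------------------------------------------------------------------

def _dome_db(x: np.ndarray, q: float, peak_pos: float = 0.5) -> np.ndarray:
    """Shape of the envelope top on [0, 1]: 0 dB at ``peak_pos``,
    CORE_SHOULDER_DB at both edges.  Larger ``q`` = flatter top."""
    u = np.where(x <= peak_pos, (peak_pos - x) / peak_pos, (x - peak_pos) / (1 - peak_pos))
    return CORE_SHOULDER_DB * np.abs(u) ** q


def _syllable_env_db(n_core: int, rate: float, tone: Optional[str]) -> np.ndarray:
    """Core envelope in dB relative to the syllable peak.

    The core spans exactly the nominal syllable duration between its two
    (peak - 20 dB) points.  Fixed edge zones (bridge shoulder then a linear
    dB ramp up to -6 dB) flank a shape-specific dome: flat-topped for
    Tone 1 (inverse-U intensity), nearly triangular for Tone 4 (inverse-V),
    and an asymmetric dome with the peak at one third of the syllable for
    the Tone 3 carrier (``tone=None``).
    """
    n_bridge = int(round(BRIDGE_MS / 1000.0 * rate))
    # the bridge is fixed in milliseconds (it anchors the -20 dB crossing);
    # the ramp scales with the core so duration-manipulated tokens keep the
    # same normalized amplitude contour
    n_ramp = int(round(0.08 * n_core))
    if 2 * (n_bridge + n_ramp) > int(0.7 * n_core):
        scale = 0.7 * n_core / (2 * (n_bridge + n_ramp))
        n_bridge = int(n_bridge * scale)
        n_ramp = int(n_ramp * scale)
    n_mid = n_core - 2 * (n_bridge + n_ramp)
    x = np.linspace(0.0, 1.0, n_mid)
    if tone == TONE1:
        dome = _dome_db(x, q=4.0, peak_pos=0.5)
    elif tone == TONE4:
        dome = _dome_db(x, q=1.2, peak_pos=0.5)
    else:  # first syllable: peak near one third of the duration
        dome = _dome_db(x, q=1.8, peak_pos=1.0 / 3.0)
    up0 = np.linspace(CORE_EDGE_DB, BRIDGE_SHOULDER_DB, n_bridge, endpoint=False)
    up1 = np.linspace(BRIDGE_SHOULDER_DB, CORE_SHOULDER_DB, n_ramp, endpoint=False)
    down1 = np.linspace(CORE_SHOULDER_DB, BRIDGE_SHOULDER_DB, n_ramp, endpoint=False)
    down0 = np.linspace(BRIDGE_SHOULDER_DB, CORE_EDGE_DB, n_bridge)
    return np.concatenate([up0, up1, dome, down1, down0])


def assemble_disyllable(
    env1_db: np.ndarray,
    env2_db: np.ndarray,
    peak1_db: float,
    peak2_db: float,
    dip_db: float,
    st1: np.ndarray,
    st2: np.ndarray,
    rate: float,
) -> tuple[np.ndarray, np.ndarray, tuple[int, int, int, int]]:
    """Join two syllable cores into one amplitude envelope + F0 track.

    Returns ``(env_amp, st_full, (on1, off1, on2, off2))`` with core
    boundaries in samples.  At each core edge the envelope is made linear
    in *power* over +-BRIDGE_MS so that Hann-weighted RMS analysis is
    unbiased exactly at the (peak - 20 dB) crossing; the measured window
    then matches the nominal core span closely for any core shape.
    """
    n1, n2 = len(env1_db), len(env2_db)
    n_lead = int(round(LEAD_MS / 1000.0 * rate))
    n_gap = int(round(GAP_MS / 1000.0 * rate))
    n_bridge = int(round(BRIDGE_MS / 1000.0 * rate))
    floor_db = min(peak1_db, peak2_db) - dip_db

    total = n_lead + n1 + n_gap + n2 + n_lead
    power = np.full(total, 10.0 ** (floor_db / 10.0))
    on1 = n_lead
    off1 = on1 + n1
    on2 = off1 + n_gap
    off2 = on2 + n2
    power[on1:off1] = 10.0 ** ((peak1_db + env1_db) / 10.0)
    power[on2:off2] = 10.0 ** ((peak2_db + env2_db) / 10.0)
    for edge in (on1, off1, on2, off2):
        i0, i1 = edge - n_bridge, edge + n_bridge
        power[i0:i1] = np.linspace(power[i0], power[i1 - 1], i1 - i0)
    env_amp = np.sqrt(power)

    gap_x = _smoothstep(np.linspace(0.0, 1.0, n_gap))
    st_full = np.concatenate(
        [
            np.full(n_lead, st1[0]),
            st1,
            st1[-1] + (st2[0] - st1[-1]) * gap_x,
            st2,
            np.full(n_lead, st2[-1]),
        ]
    )
    return env_amp, st_full, (on1, off1, on2, off2)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _syl1_f0_st(n: int, minimum_pos: float = 2.0 / 3.0) -> np.ndarray:
    """Tone 3 shape: fall then shallow rise, zero-mean in semitones.

    Spans roughly 2.5 st; the local minimum sits at ``minimum_pos`` of the
    syllable.
    """
    x = np.linspace(0.0, 1.0, n)
    fall = -2.0 * _smoothstep(x / minimum_pos)
    rise = 0.8 * _smoothstep((x - minimum_pos) / (1.0 - minimum_pos)) * (x > minimum_pos)
    shape = fall + rise
    return shape - shape.mean()


def _syl2_f0_st(
    n: int, median_rel_st: float, movement_st: float, plateau_frac: float
) -> np.ndarray:
    """Second-syllable trajectory in st relative to the syllable-1 mean.

    Plateau at (median - movement/2), symmetric smoothstep transition,
    plateau at (median + movement/2).  By symmetry the median over the
    syllable equals ``median_rel_st`` and the difference between the edge
    plateaus equals ``movement_st``.
    """
    a = median_rel_st - movement_st / 2.0
    b = median_rel_st + movement_st / 2.0
    x = np.linspace(0.0, 1.0, n)
    t = _smoothstep((x - plateau_frac) / max(1e-9, 1.0 - 2.0 * plateau_frac))
    return a + (b - a) * t


def _harmonic_source(
    f0_hz: np.ndarray, rate: float, f0_center_hz: float, rng: np.random.Generator,
    breathiness: float = 0.0,
) -> np.ndarray:
    """Pulse-train-like voiced source: 20 harmonics, -12 dB/oct roll-off,
    mild resonance near 600 Hz, unit RMS."""
    phase = 2.0 * np.pi * np.cumsum(f0_hz) / rate
    x = np.zeros_like(f0_hz)
    nyq = rate / 2.0
    for k in range(1, N_HARMONICS + 1):
        fk = k * f0_center_hz
        if fk >= nyq * 0.9:
            break
        res = 1.0 + 2.0 / (1.0 + ((fk - 600.0) / 400.0) ** 2)
        x += (res / k**2) * np.sin(k * phase)
    x /= np.sqrt(np.mean(x**2))
    if breathiness > 0:
        noise = rng.standard_normal(len(x))
        noise /= np.sqrt(np.mean(noise**2))
        x = (1.0 - breathiness) * x + breathiness * noise
        x /= np.sqrt(np.mean(x**2))
    return x


def synthesize_utterance(spec: UtteranceSpec) -> tuple[Waveform, RealizedParams]:
    """Render one disyllabic utterance; returns the waveform and its
    generating truth (post-jitter parameters and nucleus bounds)."""
    rate = DEFAULT_RATE
    params = realize_params(spec)
    p = spec.profile

    n1 = int(round(params.syl1_duration_ms / 1000.0 * rate))
    n2 = int(round(params.syl2_duration_ms / 1000.0 * rate))
    n_pad = int(round(spec.pad_ms / 1000.0 * rate))

    peak1 = params.syl1_peak_dbfs
    peak2 = peak1 + params.int_peak_diff_db
    env1 = _syllable_env_db(n1, rate, None)
    env2 = _syllable_env_db(n2, rate, spec.tone)

    # F0 trajectories in semitones re the speaker's center, voiced
    # throughout the enveloped span.
    st1 = _syl1_f0_st(n1)
    plateau_frac = max(0.18, (55.0 + 0.04 * params.syl2_duration_ms) / params.syl2_duration_ms)
    plateau_frac = min(plateau_frac, 0.40)
    st2 = _syl2_f0_st(n2, params.f0_median_rel_st, params.f0_movement_st, plateau_frac)

    env_amp, st, bounds = assemble_disyllable(
        env1, env2, peak1, peak2, params.dip_db, st1, st2, rate
    )
    f0_hz = st_to_hz(st, ref_hz=params.f0_center_hz)

    rng = np.random.default_rng([p.seed, 1 if spec.tone == TONE1 else 4,
                                 spec.repetition, 0x50FA])
    source = _harmonic_source(f0_hz, rate, params.f0_center_hz, rng,
                              breathiness=spec.breathiness)
    voiced = source * env_amp

    pad = np.zeros(n_pad)
    samples = np.concatenate([pad, voiced, pad])
    if np.max(np.abs(samples)) > 1.0:
        raise ValueError("synthesis clipped after normalization")

    to_ms = 1000.0 / rate
    params.syl1_onset_ms = spec.pad_ms + bounds[0] * to_ms
    params.syl1_offset_ms = spec.pad_ms + bounds[1] * to_ms
    params.syl2_onset_ms = spec.pad_ms + bounds[2] * to_ms
    params.syl2_offset_ms = spec.pad_ms + bounds[3] * to_ms
    return Waveform(samples, rate), params


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortToken:
    token_id: str
    spec: UtteranceSpec


def generate_cohort(
    n_nh: int,
    n_ci: int,
    reps: int = 3,
    seed: int = 0,
    pad_ms: float = 400.0,
    jitter_sd: Optional[dict] = None,
) -> tuple[list[CohortToken], pd.DataFrame]:
    """Build utterance specs for a cohort plus the generating truth table.

    ``n_nh + n_ci`` speakers x 2 tones x ``reps`` repetitions.  Waveforms
    are synthesized lazily (see :func:`synthesize_utterance` /
    :func:`write_cohort`); the truth table carries the realized post-jitter
    parameters of every token.
    """
    if n_nh < 1 or n_ci < 1 or reps < 1:
        raise ValueError("need at least one speaker per group and one repetition")
    root = np.random.default_rng([int(seed), 0xC0417])
    tokens: list[CohortToken] = []
    rows = []
    idx = 0
    for group, n in (("NH", n_nh), ("CI", n_ci)):
        for s in range(n):
            speaker_seed = int(root.integers(0, 2**31 - 1))
            center = float(np.clip(230.0 * 2 ** root.normal(0, 0.10), 80.0, 580.0))
            prof = make_speaker_profile(
                group, center, speaker_seed,
                speaker_id=f"{group}{s + 1:03d}", jitter_sd=jitter_sd,
            )
            for tone in (TONE1, TONE4):
                for rep in range(1, reps + 1):
                    spec = UtteranceSpec(prof, tone, rep, pad_ms=pad_ms)
                    token_id = f"{group}_{prof.speaker_id}_{tone}_{rep}"
                    params = realize_params(spec)
                    row = dict(
                        token_id=token_id,
                        group=group,
                        speaker=prof.speaker_id,
                        tone=tone,
                        repetition=rep,
                        **{
                            k: v
                            for k, v in asdict(params).items()
                            if k != "tone"
                        },
                    )
                    rows.append(row)
                    tokens.append(CohortToken(token_id, spec))
                    idx += 1
    return tokens, pd.DataFrame(rows)


def write_cohort(tokens: Sequence[CohortToken], truth: pd.DataFrame, out_dir) -> None:
    """Synthesize all cohort tokens to 16-bit WAV plus the truth CSV."""
    from pathlib import Path

    from .io import write_wav

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for tok in tokens:
        wave, _ = synthesize_utterance(tok.spec)
        write_wav(wave, out / f"{tok.token_id}.wav")
    truth.to_csv(out / "truth.csv", index=False)


def simulate_production_observations(
    n_nh: int,
    n_ci: int,
    reps: int = 3,
    seed: int = 0,
    overrides: Optional[dict[str, dict[str, float]]] = None,
    jitter_sd: Optional[dict] = None,
) -> pd.DataFrame:
    """Descriptor observations drawn from the generative model, no audio.

    Statistically identical to analyzing a synthesized cohort with a
    perfect extraction stage; used for model power/calibration studies
    where rendering waveforms would dominate the runtime.  ``overrides``
    patches group-default parameters, e.g.
    ``{"CI": {"dur_ratio_tone1": 1.15}}`` builds a null cohort.
    """
    root = np.random.default_rng([int(seed), 0xFA57])
    saved = {g: dict(GROUP_DEFAULTS[g]) for g in GROUPS}
    try:
        if overrides:
            for g, kv in overrides.items():
                GROUP_DEFAULTS[g].update(kv)
        rows = []
        for group, n in (("NH", n_nh), ("CI", n_ci)):
            for s in range(n):
                speaker_seed = int(root.integers(0, 2**31 - 1))
                center = float(np.clip(230.0 * 2 ** root.normal(0, 0.10), 80.0, 580.0))
                prof = make_speaker_profile(
                    group, center, speaker_seed,
                    speaker_id=f"{group}{s + 1:03d}", jitter_sd=jitter_sd,
                )
                for tone in (TONE1, TONE4):
                    for rep in range(1, reps + 1):
                        pr = realize_params(UtteranceSpec(prof, tone, rep))
                        rows.append(
                            dict(
                                participant=prof.speaker_id,
                                group=group,
                                tone=tone,
                                repetition=rep,
                                duration_ratio=pr.duration_ratio,
                                intensity_peak_diff_db=pr.int_peak_diff_db,
                                f0_median_rel_st=pr.f0_median_rel_st,
                                f0_movement_st=pr.f0_movement_st,
                            )
                        )
    finally:
        for g in GROUPS:
            GROUP_DEFAULTS[g].clear()
            GROUP_DEFAULTS[g].update(saved[g])
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Simulated 2AFC listeners
# ---------------------------------------------------------------------------

# Group-level perception strategies: coefficients act on the F0 *drop* in
# octaves (0 = flat, 1 = one-octave fall) and the centered log duration.
LISTENER_DEFAULTS: dict[str, dict[str, float]] = {
    "NH": dict(beta_intercept=3.0, beta_f0slope=-20.0, beta_logdur=6.6,
               beta_f0height=0.0),
    "CI": dict(beta_intercept=1.5, beta_f0slope=-4.3, beta_logdur=6.6,
               beta_f0height=0.0),
}

LISTENER_BETWEEN_SD = dict(beta_intercept=0.5, beta_f0slope=3.0, beta_logdur=2.0,
                           beta_f0height=0.5)


@dataclass
class ListenerProfile:
    group: str
    beta_intercept: float
    beta_f0slope: float  # logit per octave of F0 drop
    beta_logdur: float  # logit per centered log-duration unit
    beta_f0height: float  # logit per height contrast (+-0.5 coding)
    lapse_rate: float = 0.0
    seed: int = 0
    listener_id: str = "lst"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if not (0.0 <= self.lapse_rate <= 0.1):
            raise ValueError("lapse_rate must lie in [0, 0.1]")
        for b in (self.beta_intercept, self.beta_f0slope, self.beta_logdur,
                  self.beta_f0height):
            if not np.isfinite(b):
                raise ValueError("betas must be finite")


def make_listener_profile(
    group: str,
    seed: int,
    lapse_rate: float = 0.0,
    listener_id: Optional[str] = None,
    between_sd: Optional[dict] = None,
) -> ListenerProfile:
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    d = LISTENER_DEFAULTS[group]
    sd = dict(LISTENER_BETWEEN_SD)
    if between_sd:
        sd.update(between_sd)
    rng = np.random.default_rng([int(seed), 0x115E])
    return ListenerProfile(
        group=group,
        beta_intercept=d["beta_intercept"] + rng.normal(0, sd["beta_intercept"]),
        beta_f0slope=d["beta_f0slope"] + rng.normal(0, sd["beta_f0slope"]),
        beta_logdur=d["beta_logdur"] + rng.normal(0, sd["beta_logdur"]),
        beta_f0height=d["beta_f0height"] + rng.normal(0, sd["beta_f0height"]),
        lapse_rate=lapse_rate,
        seed=int(seed),
        listener_id=listener_id or f"{group}L{seed:03d}",
    )


def simulate_coupled_cohort(
    n_nh: int = 35,
    n_ci: int = 40,
    seed: int = 0,
    coupling_gain: float = 2.5,
    coupling_noise: float = 1.0,
    n_sessions: int = 3,
    token_specs: Optional[Sequence] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Listeners whose duration cue weight is tied to their Tone 4 F0 fall.

    CI participants with a shallow Tone 4 movement (small |fall|) receive a
    proportionally larger ``beta_logdur``; NH participants are uncoupled.
    Returns ``(responses, descriptors, truth)`` sharing participant ids, so
    the perception-production correlation stage can be validated against a
    known built-in coupling.
    """
    from .continuum import build_token_grid

    specs = list(token_specs) if token_specs is not None else build_token_grid()
    rng = np.random.default_rng([int(seed), 0xC09B])
    responses, desc_rows, truth_rows = [], [], []
    for group, n in (("NH", n_nh), ("CI", n_ci)):
        d = LISTENER_DEFAULTS[group]
        for i in range(n):
            pid = f"{group}P{i + 1:03d}"
            movement = rng.normal(-4.5, 1.5)
            if group == "CI":
                # shallower fall (movement closer to 0) -> more duration weight
                beta_dur = (
                    d["beta_logdur"]
                    + coupling_gain * (movement + 4.5) / 1.5
                    + rng.normal(0, coupling_noise)
                )
            else:
                beta_dur = d["beta_logdur"] + rng.normal(0, coupling_noise)
            listener = ListenerProfile(
                group=group,
                beta_intercept=d["beta_intercept"] + rng.normal(0, 0.5),
                beta_f0slope=d["beta_f0slope"] + rng.normal(0, 2.0),
                beta_logdur=beta_dur,
                beta_f0height=rng.normal(0, 0.5),
                lapse_rate=0.0,
                seed=int(rng.integers(0, 2**31 - 1)),
                listener_id=pid,
            )
            responses.append(simulate_responses(listener, specs, n_sessions, seed))
            for tone, mov in ((TONE1, rng.normal(1.0, 0.5)), (TONE4, movement)):
                for rep in range(1, 4):
                    desc_rows.append(
                        dict(
                            participant=pid,
                            group=group,
                            tone=tone,
                            repetition=rep,
                            duration_ratio=rng.normal(1.15, 0.05),
                            intensity_peak_diff_db=rng.normal(1.0, 1.0),
                            f0_median_rel_st=rng.normal(3.0, 0.5),
                            f0_movement_st=mov + rng.normal(0, 0.3),
                        )
                    )
            truth_rows.append(
                dict(
                    participant=pid,
                    group=group,
                    tone4_movement_st=movement,
                    beta_logdur=beta_dur,
                    beta_f0slope=listener.beta_f0slope,
                )
            )
    return (
        pd.concat(responses, ignore_index=True),
        pd.DataFrame(desc_rows),
        pd.DataFrame(truth_rows),
    )


def logdur_center(duration_pcts: Iterable[float]) -> float:
    """Centering constant: mean log(duration/100%) over the grid."""
    return float(np.mean(np.log(np.asarray(list(duration_pcts), dtype=float) / 100.0)))


def response_probability(
    listener: ListenerProfile,
    f0_slope_oct: np.ndarray,
    duration_pct: np.ndarray,
    f0_height_hz: np.ndarray,
    dur_center: float,
) -> np.ndarray:
    """P(Tone 1 response) under the lapse-augmented logistic model."""
    drop = -np.asarray(f0_slope_oct, dtype=float)  # octaves of F0 fall, >= 0
    clogdur = np.log(np.asarray(duration_pct, dtype=float) / 100.0) - dur_center
    height = np.where(np.asarray(f0_height_hz, dtype=float) >= 170.0, 0.5, -0.5)
    logit = (
        listener.beta_intercept
        + listener.beta_f0slope * drop
        + listener.beta_logdur * clogdur
        + listener.beta_f0height * height
    )
    base = 1.0 / (1.0 + np.exp(-logit))
    return listener.lapse_rate / 2.0 + (1.0 - listener.lapse_rate) * base


def simulate_responses(
    listener: ListenerProfile,
    token_specs: Sequence,
    n_sessions: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """One Bernoulli Tone-1/Tone-4 draw per token per session.

    ``token_specs`` may be ``ContinuumTokenSpec`` objects or mappings with
    ``f0_slope_oct``, ``duration_pct`` and ``f0_height_hz`` entries.
    """
    if len(token_specs) == 0:
        raise ValueError("empty token set")
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")

    def _get(tok, name):
        return tok[name] if isinstance(tok, dict) else getattr(tok, name)

    slopes = np.array([_get(t, "f0_slope_oct") for t in token_specs], dtype=float)
    durs = np.array([_get(t, "duration_pct") for t in token_specs], dtype=float)
    heights = np.array([_get(t, "f0_height_hz") for t in token_specs], dtype=float)
    dur_center = logdur_center(np.unique(durs))
    prob = response_probability(listener, slopes, durs, heights, dur_center)

    rng = np.random.default_rng([listener.seed, int(seed), 0x2AFC])
    rows = []
    for sess in range(1, n_sessions + 1):
        draws = rng.random(len(prob)) < prob
        for i in range(len(prob)):
            rows.append(
                dict(
                    participant=listener.listener_id,
                    group=listener.group,
                    session=sess,
                    f0_slope_oct=slopes[i],
                    duration_pct=durs[i],
                    f0_height_hz=heights[i],
                    response_tone1=int(draws[i]),
                )
            )
    return pd.DataFrame(rows)
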