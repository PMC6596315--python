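"""WAV and table I/O."""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .types import Waveform

logger = logging.getLogger(__name__)

_PCM_SCALE = {np.dtype("int16"): 2**15, np.dtype("int32"): 2**31}


def read_wav(path) -> Waveform:
    """Read a PCM or float WAV as a mono float waveform in [-1, 1].

    Stereo input is mixed down to mono with a logged warning.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # scipy raises assorted errors on bad headers
        raise ValueError(f"unsupported or corrupt WAV file {path}: {exc}") from exc
    if data.ndim == 2:
        logger.warning("stereo input %s mixed down to mono", path)
        data = data.mean(axis=1)
    if data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    elif data.dtype == np.dtype("uint8"):
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV encoding {data.dtype} in {path}")
    return Waveform(samples, float(rate))


def write_wav(wave: Waveform, path) -> None:
    """Write 16-bit PCM; round-trips within one LSB."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    x = np.clip(wave.samples, -1.0, 1.0)
    # same 2**15 scale as read_wav so the round trip stays within one LSB
    pcm = np.clip(np.round(x * 2**15), -(2**15), 2**15 - 1).astype(np.int16)
    wavfile.write(path, int(wave.rate), pcm)
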