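"""Run configuration with YAML round-trip."""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """End-to-end pipeline settings.

    Defaults mirror the study design: 35 NH + 40 CI speakers, 3
    repetitions per word, 20-dB syllable cutoff, 96-token continuum over
    3 sessions.
    """

    seed: int = 0
    n_nh: int = 35
    n_ci: int = 40
    reps: int = 3
    cutoff_db: float = 20.0
    pad_ms: float = 400.0
    continuum_sessions: int = 3
    n_listeners_nh: int = 35
    n_listeners_ci: int = 40
    write_audio: bool = False
    out_dir: str = "tonelab_out"
    model_options: dict = field(default_factory=dict)

    def save(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
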