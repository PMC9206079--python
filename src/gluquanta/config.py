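"""Pipeline configuration: every numeric convention in one place.

The default profile reproduces the published analysis constants
(calibration, thresholds, inclusion criteria); configs round-trip
losslessly through YAML/JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # calibration
    pixel_size_nm: float = 183.3
    frame_interval_ms: float = 4.0
    tau_ms: float = 68.0
    # detection
    theta_multiplier: float = 4.0
    snr_inclusion: float = 5.0
    bandpass_low_hz: float = 0.5
    bandpass_high_hz: float = 30.0
    # classification / quantization
    sync_window_ms: float = 10.0
    single_quantum_factor: float = 1.25
    # localization / spatial
    delta_threshold_nm: float = 100.0
    cluster_diameter_nm: float = 100.0
    dual_az_distance_nm: float = 700.0
    neighbor_exclusion_px: int = 16
    # inclusion criteria
    min_events_per_bouton: int = 2
    min_events_spatial: int = 5
    min_boutons_train: int = 21
    min_boutons_paired: int = 50
    # protocols
    n_ap_train: int = 51
    train_hz: float = 5.0
    paired_isi_ms: float = 50.0
    n_pairs: int = 10
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        numeric = {
            k: v
            for k, v in dataclasses.asdict(self).items()
            if isinstance(v, (int, float)) and k != "seed"
        }
        bad = [k for k, v in numeric.items() if v <= 0]
        if bad:
            raise ValueError(f"thresholds must be positive: {bad}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = path.read_text()
        data = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]
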