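"""Pipeline configuration: every tunable in one serializable object."""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, fields


@dataclass
class PipelineConfig:
    """Defaults follow the reference analysis protocol.

    sample_rate 4 Hz; 30-s epochs; 90-s windows (3 epochs); Takens embedding
    (p, tau) = (120, 1); epochs with fewer than 5 beats discarded; 5-beat
    median-filter ratio bounds 0.7/1.4; VR homology up to dim 1 with no
    radius cap; linear SVM at C = 1 on raw features; balancing seed 1;
    default task wake/sleep.
    """

    sample_rate: float = 4.0
    epoch_seconds: float = 30.0
    window_epochs: int = 3
    takens_p: int = 120
    takens_tau: int = 1
    min_beats_per_epoch: int = 5
    median_filter_low: float = 0.7
    median_filter_high: float = 1.4
    vr_max_dim: int = 1
    vr_max_scale: float = math.inf
    svm_c: float = 1.0
    standardize_features: bool = False
    seed: int = 1
    task: str = "ws"

    def validate(self) -> None:
        if self.task not in ("ws", "rn", "wrn"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.window_epochs < 1 or self.takens_p < 1 or self.takens_tau < 1:
            raise ValueError("window_epochs, takens_p, takens_tau must be >= 1")
        window_len = int(round(
            self.window_epochs * self.epoch_seconds * self.sample_rate))
        needed = (self.takens_p - 1) * self.takens_tau + 1
        if window_len < needed:
            raise ValueError(
                f"window of {window_len} samples "
                f"({self.window_epochs} x {self.epoch_seconds} s at "
                f"{self.sample_rate} Hz) is shorter than the "
                f"{needed} samples required by the Takens embedding "
                f"(p={self.takens_p}, tau={self.takens_tau})"
            )

    @property
    def window_samples(self) -> int:
        return int(round(
            self.window_epochs * self.epoch_seconds * self.sample_rate))

    def to_dict(self) -> dict:
        d = asdict(self)
        if math.isinf(d["vr_max_scale"]):
            d["vr_max_scale"] = "inf"
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if d.get("vr_max_scale") == "inf":
            d["vr_max_scale"] = math.inf
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
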