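"""Synthetic inputs: worked filtration, noisy circle, stage-labeled R-peak trains.

The recording generator is an integrate-and-fire beat model whose
instantaneous RR interval is the sum of a stage-dependent baseline, a
respiratory sinus-arrhythmia sinusoid, and Gaussian jitter, with random
transient accelerations during wake.  Its stage-dependent defaults encode
the physiology that motivates HRV-based sleep staging: wake is faster and
more variable, NREM slow and strongly respiration-modulated, REM in between
with an irregular respiratory drive.  It emulates the R-peak/label data
contract only -- it is not a model of any particular cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .persistence import Filtration

__all__ = [
    "worked_filtration",
    "noisy_circle",
    "StageParams",
    "SyntheticRecordingSpec",
    "synthetic_recording",
    "random_hypnogram",
    "DEFAULT_STAGE_PARAMS",
]


def worked_filtration() -> Filtration:
    """The five-step worked filtration on four vertices.

    Step 1: two vertices and the edge joining them (one component is born).
    Step 2: a third vertex with one connecting edge.  Step 3: the closing
    edge of the triangle (a 1-cycle is born).  Step 4: a fourth vertex, two
    edges and the filled triangle on vertices {0, 1, 3}.  Step 5: the filled
    triangle on {0, 1, 2} (the 1-cycle dies).
    """
    filt = Filtration()
    filt.add(1, (0,))
    filt.add(1, (1,))
    filt.add(1, (0, 1))
    filt.add(2, (2,))
    filt.add(2, (1, 2))
    filt.add(3, (0, 2))
    filt.add(4, (3,))
    filt.add(4, (0, 3))
    filt.add(4, (1, 3))
    filt.add(4, (0, 1, 3))
    filt.add(5, (0, 1, 2))
    return filt


def noisy_circle(n: int, sigma: float, seed: int) -> np.ndarray:
    """n points on the unit circle with isotropic Gaussian noise of sd sigma."""
    if n < 4:
        raise ValueError("need at least 4 points")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    angles = rng.uniform(0.0, 2.0 * np.pi, size=n)
    pts = np.column_stack([np.cos(angles), np.sin(angles)])
    if sigma > 0:
        pts = pts + sigma * rng.standard_normal((n, 2))
    return pts


@dataclass(frozen=True)
class StageParams:
    """Beat-interval model of one sleep stage."""

    mean_rr: float           # baseline RR, seconds
    sd_rr: float             # Gaussian jitter sd, seconds
    resp_amp: float          # respiratory modulation amplitude, seconds
    resp_freq: float         # respiratory frequency, Hz


DEFAULT_STAGE_PARAMS: dict[str, StageParams] = {
    # wake: fast, irregular, little respiratory coupling
    "W": StageParams(mean_rr=0.8, sd_rr=0.06, resp_amp=0.01, resp_freq=0.30),
    # REM: intermediate rate, irregular breathing
    "R": StageParams(mean_rr=0.85, sd_rr=0.045, resp_amp=0.02, resp_freq=0.30),
    # NREM: slow, stable, strong respiratory sinus arrhythmia
    "N": StageParams(mean_rr=1.0, sd_rr=0.02, resp_amp=0.04, resp_freq=0.25),
}


@dataclass
class SyntheticRecordingSpec:
    """Full description of one synthetic recording (seed fixes the draw)."""

    stages: list                      # one of W/R/N per 30-s epoch
    seed: int = 0
    epoch_seconds: float = 30.0
    stage_params: dict = field(
        default_factory=lambda: dict(DEFAULT_STAGE_PARAMS))
    wake_transient_rate: float = 2.0   # expected transients per wake epoch
    transient_factor: float = 0.8      # RR multiplier during a transient
    transient_seconds: float = 3.0
    min_rr: float = 0.3

    def validate(self) -> None:
        if len(self.stages) == 0:
            raise ValueError("stage sequence must be non-empty")
        bad = sorted({s for s in self.stages} - set(self.stage_params))
        if bad:
            raise ValueError(f"unknown stages {bad}")
        if self.epoch_seconds <= 0:
            raise ValueError("epoch_seconds must be positive")
        for s, par in self.stage_params.items():
            if not (0.4 <= par.mean_rr <= 1.5):
                raise ValueError(f"stage {s}: mean RR {par.mean_rr} outside [0.4, 1.5] s")
            if par.sd_rr < 0 or par.resp_amp < 0:
                raise ValueError(f"stage {s}: negative variability")


def synthetic_recording(spec: SyntheticRecordingSpec
                        ) -> tuple[np.ndarray, list[str]]:
    """Generate (R-peak times, per-epoch labels) from a recording spec.

    Integrate-and-fire: starting at t = 0, each next beat follows after
    RR(t) = mean_rr(stage) + resp_amp * sin(2 pi f t + phase) + jitter,
    where the stage is read off the epoch containing t.  During wake epochs
    a Poisson number of short transient accelerations multiply RR by
    ``transient_factor``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    total = len(spec.stages) * spec.epoch_seconds
    phase = rng.uniform(0.0, 2.0 * np.pi)

    # draw wake transient intervals per epoch up front (seeded, order-stable)
    transients: list[tuple[float, float]] = []
    for j, stage in enumerate(spec.stages):
        if stage == "W" and spec.wake_transient_rate > 0:
            k = rng.poisson(spec.wake_transient_rate)
            starts = j * spec.epoch_seconds + rng.uniform(
                0.0, spec.epoch_seconds, size=k)
            transients.extend(
                (s, s + spec.transient_seconds) for s in np.sort(starts))

    times = [0.0]
    t = 0.0
    while True:
        stage = spec.stages[min(int(t // spec.epoch_seconds),
                                len(spec.stages) - 1)]
        par = spec.stage_params[stage]
        rr = par.mean_rr + par.resp_amp * np.sin(
            2.0 * np.pi * par.resp_freq * t + phase)
        if par.sd_rr > 0:
            rr += par.sd_rr * rng.standard_normal()
        if any(a <= t < b for a, b in transients):
            rr *= spec.transient_factor
        rr = max(rr, spec.min_rr)
        t += rr
        if t >= total:
            break
        times.append(t)
    return np.asarray(times), list(spec.stages)


def random_hypnogram(n_epochs: int, seed: int) -> list[str]:
    """A plausible stage sequence: wake onset, NREM bulk, REM bouts, arousals."""
    rng = np.random.default_rng(seed)
    trans = {
        "W": [("W", 0.70), ("N", 0.30), ("R", 0.0)],
        "N": [("W", 0.05), ("N", 0.85), ("R", 0.10)],
        "R": [("W", 0.05), ("N", 0.15), ("R", 0.80)],
    }
    stages = ["W"]
    for _ in range(n_epochs - 1):
        labels, probs = zip(*[(s, p) for s, p in trans[stages[-1]]])
        stages.append(str(rng.choice(labels, p=probs)))
    return stages
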