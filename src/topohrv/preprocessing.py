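"""From R-peak time stamps to labeled, median-centered 90-s IHR windows.

Pipeline: (1) artifact correction of the R-peak train with a 5-beat running
median rule (ectopic/spurious beats removed, missed beats interpolated);
(2) instantaneous heart rate (IHR, beats per minute) from inverse RR
intervals, resampled to a uniform 4-Hz grid with shape-preserving piecewise
cubic (PCHIP) interpolation; (3) for every labeled 30-s epoch with enough
beats, a 90-s window (the epoch plus its two predecessors, 360 samples at
4 Hz) centered by subtracting its own median.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

logger = logging.getLogger(__name__)

__all__ = [
    "IHRSeries",
    "IHRWindow",
    "clean_rpeaks",
    "compute_ihr",
    "extract_windows",
    "read_rpeaks_csv",
    "write_rpeaks_csv",
    "read_labels_csv",
    "write_labels_csv",
]

VALID_STAGES = ("W", "R", "N")


@dataclass
class IHRSeries:
    """Instantaneous heart rate (bpm) on a uniform grid."""

    values: np.ndarray
    start_time: float
    sample_rate: float = 4.0

    @property
    def end_time(self) -> float:
        return self.start_time + (len(self.values) - 1) / self.sample_rate


@dataclass
class IHRWindow:
    """One median-centered analysis window tied to a labeled epoch."""

    values: np.ndarray          # 360 samples, median-subtracted
    epoch_index: int            # 1-based epoch j
    label: str                  # W / R / N
    end_time: float             # t_j, seconds
    subject_id: str = ""
    raw_median: float = field(default=0.0)


def _check_strictly_increasing(times: np.ndarray) -> None:
    if times.size >= 2 and np.any(np.diff(times) <= 0):
        raise ValueError("R-peak times must be strictly increasing")


def clean_rpeaks(times, low_ratio: float = 0.7, high_ratio: float = 1.4,
                 max_passes: int = 50) -> np.ndarray:
    """Artifact-correct an R-peak train with a 5-beat running median rule.

    Each RR interval is compared to the median of the 5 intervals centered
    on it (window clipped at the borders).  An interval shorter than
    ``low_ratio`` times the median marks a spurious beat, which is removed;
    one longer than ``high_ratio`` times the median marks missed beats, which
    are filled in by evenly spaced interpolated beats.  The rule is re-applied
    until stable, and is idempotent on its own output.

    Trains with fewer than 6 beats are passed through with a warning.
    """
    t = np.asarray(times, dtype=float).ravel().copy()
    _check_strictly_increasing(t)
    if t.size < 6:
        warnings.warn(
            f"R-peak train with {t.size} beats is too short for the 5-beat "
            "median filter; returned unchanged", stacklevel=2
        )
        return t
    for _ in range(max_passes):
        rr = np.diff(t)
        changed = False
        for i in range(rr.size):
            lo = max(0, min(i - 2, rr.size - 5))
            med = float(np.median(rr[lo:lo + 5]))
            if rr[i] < low_ratio * med:
                # spurious beat: drop the later beat of the short interval
                t = np.delete(t, i + 1)
                changed = True
                break
            if rr[i] > high_ratio * med:
                # missed beat(s): split the gap into ~median-length intervals
                k = max(2, int(round(rr[i] / med)))
                fill = t[i] + (np.arange(1, k) / k) * rr[i]
                t = np.insert(t, i + 1, fill)
                changed = True
                break
        if not changed:
            break
    return t


def compute_ihr(times, sample_rate: float = 4.0) -> IHRSeries:
    """IHR series (bpm) on a uniform grid by monotone cubic interpolation.

    Knots sit at each beat r_i (i >= 2) with value 60 / (r_i - r_{i-1});
    PCHIP interpolation preserves local monotonicity, so interpolated values
    never overshoot the surrounding knot range.  The grid is aligned to
    multiples of 1/sample_rate (absolute time), spanning the knot domain.
    """
    t = np.asarray(times, dtype=float).ravel()
    if t.size < 2:
        raise ValueError("at least 2 beats required to compute IHR")
    _check_strictly_increasing(t)
    knots = t[1:]
    rates = 60.0 / np.diff(t)
    if knots.size == 1:
        interp = None
    else:
        interp = PchipInterpolator(knots, rates, extrapolate=False)
    step = 1.0 / sample_rate
    start = np.ceil(knots[0] / step - 1e-9) * step
    stop = np.floor(knots[-1] / step + 1e-9) * step
    grid = start + step * np.arange(int(round((stop - start) / step)) + 1)
    if interp is None:
        values = np.full(grid.size, rates[0])
    else:
        values = interp(grid)
        # guard the grid endpoints against round-off outside the domain
        values[0] = rates[0] if not np.isfinite(values[0]) else values[0]
        values[-1] = rates[-1] if not np.isfinite(values[-1]) else values[-1]
    return IHRSeries(values=values, start_time=float(start),
                     sample_rate=sample_rate)


def extract_windows(series: IHRSeries, labels, train,
                    epoch_seconds: float = 30.0, window_epochs: int = 3,
                    min_beats_per_epoch: int = 5,
                    subject_id: str = "") -> list[IHRWindow]:
    """Labeled, median-centered analysis windows from an IHR series.

    For each labeled epoch j (1-based, starting from ``window_epochs``), the
    window holds the ``window_epochs * epoch_seconds * rate`` samples ending
    at t_j = j * epoch_seconds, minus their median.  Epochs whose own 30-s
    span contains fewer than ``min_beats_per_epoch`` cleaned R peaks are
    discarded, as are epochs whose window is not fully covered by the series.
    """
    labels = list(labels)
    bad = [i + 1 for i, s in enumerate(labels) if s not in VALID_STAGES]
    if bad:
        raise ValueError(
            f"invalid stage labels at epoch indices {bad}; "
            f"expected one of {VALID_STAGES}"
        )
    t = np.asarray(train, dtype=float).ravel()
    rate = series.sample_rate
    n_samples = int(round(window_epochs * epoch_seconds * rate))
    windows: list[IHRWindow] = []
    n_short, n_edge = 0, 0
    for j in range(window_epochs, len(labels) + 1):
        t_j = j * epoch_seconds
        beats = np.searchsorted(t, (t_j - epoch_seconds, t_j), side="right")
        if beats[1] - beats[0] < min_beats_per_epoch:
            n_short += 1
            continue
        t_first = t_j - (n_samples - 1) / rate
        i0 = int(round((t_first - series.start_time) * rate))
        if i0 < 0 or i0 + n_samples > len(series.values):
            n_edge += 1
            continue
        raw = series.values[i0:i0 + n_samples]
        med = float(np.median(raw))
        windows.append(IHRWindow(
            values=raw - med, epoch_index=j, label=labels[j - 1],
            end_time=float(t_j), subject_id=subject_id, raw_median=med,
        ))
    logger.info(
        "extract_windows[%s]: %d windows, %d epochs dropped (<%d beats), "
        "%d dropped at recording edges, first %d epochs have no history",
        subject_id, len(windows), n_short, min_beats_per_epoch, n_edge,
        window_epochs - 1,
    )
    return windows


# ---------------------------------------------------------------------------
# Plain-text I/O
# ---------------------------------------------------------------------------

def read_rpeaks_csv(path) -> np.ndarray:
    """R-peak times from a single-column CSV (seconds, header ``time_s``).

    A two-column variant with header ``rr_s`` (RR intervals, seconds) is
    also accepted and converted to cumulative beat times.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        values = np.array([float(row[0]) for row in reader if row])
    if header and header[0].strip() == "rr_s":
        return np.concatenate([[0.0], np.cumsum(values)])
    return values


def write_rpeaks_csv(path, times) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s"])
        for v in np.asarray(times, dtype=float).ravel():
            writer.writerow([repr(float(v))])


def read_labels_csv(path) -> list[str]:
    """Stage labels from a CSV with columns epoch_index (1-based), label."""
    rows: list[tuple[int, str]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        next(reader)
        for row in reader:
            if row:
                rows.append((int(row[0]), row[1].strip()))
    rows.sort()
    expected = list(range(1, len(rows) + 1))
    if [r[0] for r in rows] != expected:
        raise ValueError(
            f"label epochs must be consecutive 1..n, got {[r[0] for r in rows]}"
        )
    return [r[1] for r in rows]


def write_labels_csv(path, labels) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch_index", "label"])
        for j, s in enumerate(labels, start=1):
            writer.writerow([j, s])
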