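"""Ca2+ wave detection and interval statistics on the bulk trace.

The bulk signal of a regular animal carries one sharp excursion per
defecation cycle (~50 s apart).  Peaks are found on a lightly smoothed
trace with a robust, noise-scaled prominence floor, mirroring the usual
``findpeaks``-style analysis; intervals between successive peaks are then
summarized per animal, including an explicit oscillation-absence call for
recordings long enough to support one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .segmentation import BulkTrace

DEFAULT_MIN_DISTANCE_S = 10.0
DEFAULT_SMOOTH_WINDOW_S = 1.0
DEFAULT_PROMINENCE_MADS = 4.0
DEFAULT_ABSENCE_MIN_DURATION_S = 240.0


@dataclass
class WavePeaks:
    """Detected Ca2+ wave peaks of one recording."""

    peak_frames: np.ndarray  # sorted ints
    peak_times_s: np.ndarray
    amplitudes: np.ndarray  # raw trace value at peak
    prominences: np.ndarray  # topographic prominence on the smoothed trace

    @property
    def n_waves(self) -> int:
        return len(self.peak_frames)


@dataclass
class IntervalSummary:
    """Per-animal inter-wave interval statistics.

    ``cv`` (SD/mean of intervals) needs at least two intervals, i.e. three
    waves, and is NaN otherwise.  ``oscillation_absent`` is only asserted
    when the recording observed the animal long enough that a regular
    rhythm would certainly have produced waves.
    """

    n_waves: int
    intervals_s: np.ndarray
    mean_interval_s: float
    sd_interval_s: float
    cv: float
    oscillation_absent: bool
    recording_duration_s: float


def robust_noise_scale(values: np.ndarray) -> float:
    """Median absolute deviation of the first-differenced trace.

    First-differencing removes the slow physiological component, so the MAD
    of the differences tracks the frame-to-frame noise level regardless of
    how many waves the trace contains.
    """
    d = np.diff(np.asarray(values, dtype=np.float64))
    if len(d) == 0:
        return 0.0
    return float(np.median(np.abs(d - np.median(d))))


def detect_peaks(
    trace: BulkTrace,
    min_prominence: float | None = None,
    min_distance_s: float = DEFAULT_MIN_DISTANCE_S,
    smooth_window_s: float = DEFAULT_SMOOTH_WINDOW_S,
) -> WavePeaks:
    """Find Ca2+ wave peaks in a bulk trace.

    The trace is smoothed with a moving average of ``smooth_window_s``,
    then local maxima are kept if their topographic prominence reaches
    ``min_prominence`` (default 4 x the MAD of the first-differenced raw
    trace) and peaks closer than ``min_distance_s`` are resolved in favor
    of the higher one.
    """
    if min_distance_s <= 0 or smooth_window_s <= 0:
        raise ValueError("min_distance_s and smooth_window_s must be positive")
    if min_prominence is not None and min_prominence <= 0:
        raise ValueError("min_prominence must be positive")
    values = np.asarray(trace.values, dtype=np.float64)
    if int(trace.valid.sum()) < 3:
        raise ValueError("need at least 3 valid frames for peak detection")
    if min_prominence is None:
        scale = robust_noise_scale(values)
        min_prominence = DEFAULT_PROMINENCE_MADS * scale
        if min_prominence == 0:
            min_prominence = 1e-12  # noiseless synthetic traces
    window = max(int(round(smooth_window_s * trace.fps)), 1)
    smoothed = uniform_filter1d(values, size=window, mode="nearest")
    distance = max(int(round(min_distance_s * trace.fps)), 1)
    idx, props = find_peaks(smoothed, prominence=min_prominence, distance=distance)
    return WavePeaks(
        peak_frames=idx,
        peak_times_s=trace.time_s[idx],
        amplitudes=values[idx],
        prominences=props["prominences"],
    )


def compute_intervals(peaks: WavePeaks) -> np.ndarray:
    """Successive differences of peak times; empty below two peaks."""
    return np.diff(peaks.peak_times_s)


def summarize_intervals(
    peaks: WavePeaks,
    duration_s: float,
    absence_min_duration_s: float = DEFAULT_ABSENCE_MIN_DURATION_S,
) -> IntervalSummary:
    """Interval statistics and the oscillation-absence call.

    Sample (n-1) standard deviation throughout.  A recording shorter than
    ``absence_min_duration_s`` can never be called oscillation-absent: too
    little observation time to distinguish absence from a long interval.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    intervals = compute_intervals(peaks)
    n = peaks.n_waves
    mean = float(np.mean(intervals)) if len(intervals) >= 1 else float("nan")
    sd = float(np.std(intervals, ddof=1)) if len(intervals) >= 2 else float("nan")
    cv = sd / mean if n >= 3 and mean > 0 else float("nan")
    absent = n == 0 and duration_s >= absence_min_duration_s
    return IntervalSummary(
        n_waves=n,
        intervals_s=intervals,
        mean_interval_s=mean,
        sd_interval_s=sd,
        cv=cv,
        oscillation_absent=absent,
        recording_duration_s=float(duration_s),
    )
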