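"""Baseline removal, spike detection and summary statistics for recordings.

The stage that turns a raw potential (or temperature) trace into a
per-character response profile: estimate and subtract the baseline, find
peaks by topographic prominence, take inter-peak periods, and summarize
amplitudes and periods as seven-number rows.

Peak semantics
--------------
A sample ``i`` is a peak candidate iff ``v[i] > v[i-1]`` and ``v[i] >= v[i+1]``
(the leftmost sample of a maximal plateau).  Its prominence is its height
minus the higher of the two minima separating it from the nearest higher
sample (or the record edge) on each side — standard topographic prominence.
Candidates below the prominence or height floors are dropped; among surviving
peaks closer than ``min_separation`` the higher wins (ties: the earlier).

The default prominence and height floors are both 5× a robust noise-sd
estimate (normal-consistent median absolute deviation of the first
differences divided by √2).  The height floor matters: in a long record,
prominence alone cannot control false positives, because a tall noise sample
inherits a large prominence from the excursions around it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.stats import median_abs_deviation

from .io import Recording, StatsSummary, CharacterProfile

__all__ = [
    "PeakSet",
    "estimate_noise_sd",
    "remove_baseline",
    "subtract_reference",
    "detect_spikes",
    "peak_periods",
    "summarize",
    "profile_character",
]

QUARTILE_METHODS = {"linear": "linear", "type7": "linear", "midpoint": "midpoint"}


@dataclass(frozen=True)
class PeakSet:
    """Detected spikes: sample indices, times (s), heights and prominences (mV)."""

    indices: np.ndarray
    times: np.ndarray
    heights: np.ndarray
    prominences: np.ndarray

    def __len__(self) -> int:
        return len(self.indices)


def estimate_noise_sd(values: np.ndarray) -> float:
    """Robust noise standard deviation from first differences.

    Uses the normal-consistent MAD of ``diff(values)`` divided by √2 (white
    noise adds in quadrature across the difference); spikes are sparse in the
    difference sequence, so the median is insensitive to them.
    """
    values = np.asarray(values, float)
    if len(values) < 3:
        raise ValueError("need at least 3 samples to estimate noise")
    return float(median_abs_deviation(np.diff(values), scale="normal") / math.sqrt(2.0))


def _replace_values(recording: Recording, values: np.ndarray) -> Recording:
    return Recording(
        recording.times.copy(),
        values,
        recording.channel_kind,
        recording.label,
        sampling_interval=recording.sampling_interval,
    )


def remove_baseline(
    recording: Recording,
    method: str = "moving_median",
    window: float = 500.0,
    prestim_end: Optional[float] = None,
) -> Recording:
    """Subtract a baseline estimate from the recording.

    Parameters
    ----------
    method : {"moving_median", "linear_fit", "prestim_mean"}
        ``moving_median`` — centered rolling median over ``window`` seconds
        (robust to sparse spikes; the recommended detrending before peak
        picking).  ``linear_fit`` — least-squares line through the whole
        trace.  ``prestim_mean`` — mean over ``times < prestim_end``.
    window : float
        Moving-median window in seconds; must span at least 3 samples.
    prestim_end : float
        End of the pre-stimulus interval (required for ``prestim_mean``).
    """
    v = recording.values
    t = recording.times
    if method == "linear_fit":
        if len(v) < 2:
            raise ValueError("linear_fit needs at least 2 samples")
        slope, intercept = np.polyfit(t, v, 1)
        baseline = slope * t + intercept
    elif method == "prestim_mean":
        if prestim_end is None:
            raise ValueError("prestim_mean requires prestim_end")
        pre = v[t < prestim_end]
        if pre.size == 0:
            raise ValueError("no samples before prestim_end")
        baseline = np.full_like(v, pre.mean())
    elif method == "moving_median":
        if window <= 0:
            raise ValueError("window must be positive")
        dt = recording.sampling_interval
        k = int(round(window / dt))
        if k < 3:
            raise ValueError(
                f"moving-median window of {window:g} s spans {k} samples; need >= 3"
            )
        baseline = (
            pd.Series(v).rolling(k, center=True, min_periods=1).median().to_numpy()
        )
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    return _replace_values(recording, v - baseline)


def subtract_reference(recording: Recording, reference: Recording) -> Recording:
    """Elementwise difference of two recordings on the same time grid.

    Used e.g. to subtract a background-temperature co-trace from a stimulated
    temperature trace, leaving the stimulus-locked excursions.
    """
    if len(recording) != len(reference):
        raise ValueError(
            f"length mismatch: {len(recording)} vs {len(reference)} samples"
        )
    if len(recording) and not np.allclose(
        recording.times, reference.times, rtol=1e-9, atol=1e-6
    ):
        raise ValueError("recordings are not on matching time grids")
    return _replace_values(recording, recording.values - reference.values)


def _peak_candidates(v: np.ndarray) -> np.ndarray:
    interior = (v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:])
    return np.nonzero(interior)[0] + 1


def _prune_by_separation(
    times: np.ndarray, heights: np.ndarray, min_separation: float
) -> np.ndarray:
    """Greedy keep-the-higher pruning; ties go to the earlier peak."""
    import bisect

    order = np.lexsort((np.arange(len(times)), -heights))
    kept_times: list[float] = []
    keep = np.zeros(len(times), dtype=bool)
    for j in order:
        tj = times[j]
        pos = bisect.bisect_left(kept_times, tj)
        if pos > 0 and tj - kept_times[pos - 1] < min_separation:
            continue
        if pos < len(kept_times) and kept_times[pos] - tj < min_separation:
            continue
        bisect.insort(kept_times, tj)
        keep[j] = True
    return keep


def detect_spikes(
    recording: Recording,
    min_prominence: Optional[float] = None,
    min_separation: float = 10.0,
    min_height: Optional[float] = None,
) -> PeakSet:
    """Detect peaks in a (preferably detrended) recording.

    ``min_prominence`` and ``min_height`` default to 5× the robust noise-sd
    estimate of the trace; pass explicit values (e.g. 0) to override.
    ``min_separation`` is in seconds and must be at least one sample.
    """
    v = recording.values
    if len(v) < 3:
        raise ValueError("recording shorter than 3 samples")
    if min_separation < recording.sampling_interval:
        raise ValueError("min_separation must be at least the sampling interval")
    if min_prominence is None or min_height is None:
        floor = 5.0 * estimate_noise_sd(v)
        if min_prominence is None:
            min_prominence = floor
        if min_height is None:
            min_height = floor

    cand = _peak_candidates(v)
    if cand.size == 0:
        empty = np.empty(0)
        return PeakSet(np.empty(0, int), empty, empty, empty)
    import warnings

    with warnings.catch_warnings():
        # zero prominence (e.g. a plateau shoulder) is valid here; it is
        # filtered below, so scipy's advisory is noise
        warnings.filterwarnings("ignore", message="some peaks have a prominence of 0")
        prom = sps.peak_prominences(v, cand)[0]
    ok = (prom >= min_prominence) & (v[cand] >= min_height)
    cand, prom = cand[ok], prom[ok]
    times = recording.times[cand]
    keep = _prune_by_separation(times, v[cand], min_separation)
    cand, prom = cand[keep], prom[keep]
    return PeakSet(cand, recording.times[cand], v[cand], prom)


def peak_periods(peaks: PeakSet) -> np.ndarray:
    """Inter-peak intervals in seconds (empty for fewer than 2 peaks)."""
    return np.diff(peaks.times)


def summarize(values, quartile_method: str = "linear") -> StatsSummary:
    """Seven-number summary: quartiles, mean, extremes, sample sd (n−1).

    Quartiles use linear interpolation of order statistics (the type-7
    convention) by default; ``quartile_method="midpoint"`` switches to the
    midpoint convention.
    """
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty sample")
    if quartile_method not in QUARTILE_METHODS:
        raise ValueError(f"unknown quartile_method {quartile_method!r}")
    q1, q2, q3 = np.quantile(
        values, [0.25, 0.5, 0.75], method=QUARTILE_METHODS[quartile_method]
    )
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return StatsSummary(
        q1=float(q1),
        q2=float(q2),
        q3=float(q3),
        mean=float(np.mean(values)),
        max=float(np.max(values)),
        min=float(np.min(values)),
        sd=sd,
        n=int(values.size),
    )


def profile_character(
    recording: Recording,
    label: Optional[str] = None,
    baseline_method: str = "moving_median",
    window: float = 500.0,
    min_prominence: Optional[float] = None,
    min_separation: float = 10.0,
    min_height: Optional[float] = None,
    quartile_method: str = "linear",
) -> CharacterProfile:
    """Full per-recording pipeline: detrend → detect → summarize.

    Returns a :class:`CharacterProfile` with amplitude statistics over the
    detected (detrended) peak heights and period statistics over the
    inter-peak intervals.  Needs at least 2 peaks.
    """
    label = label if label is not None else recording.label
    if label is None:
        raise ValueError("a stimulus label is required")
    detrended = remove_baseline(recording, method=baseline_method, window=window)
    peaks = detect_spikes(
        detrended,
        min_prominence=min_prominence,
        min_separation=min_separation,
        min_height=min_height,
    )
    if len(peaks) < 2:
        raise ValueError(
            f"insufficient spikes for period statistics: {len(peaks)} peak(s)"
        )
    return CharacterProfile(
        label,
        amplitude=summarize(peaks.heights, quartile_method),
        period=summarize(peak_periods(peaks), quartile_method),
    )
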