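"""Event detection and behavioral covariate preprocessing.

Calcium event detection is a pluggable contract: any callable mapping a dF/F
trace to positive-magnitude events at sample resolution can stand behind the
interface.  The built-in default is a smoothed-derivative threshold detector
with a refractory period — a deliberately simple stand-in for dedicated
deconvolution methods, adequate for the sparse, high-SNR transients the
synthetic generator produces.

Locomotion preprocessing follows a fixed order: iterative prominence-based
despiking with linear interpolation, then a zero-phase low-pass Butterworth
filter (order 2 applied forward-backward, i.e. effective order 4) at 1 Hz,
then binarization at 2.5 cm/s for the running fraction.  Pupil diameter is
normalized by its maximum over the full extent of the stimulus blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import butter, filtfilt, find_peaks


@dataclass
class EventRecord:
    cell_id: str
    sample_index: int
    magnitude: float

    def __post_init__(self):
        if self.magnitude <= 0:
            raise ValueError("event magnitude must be > 0")


@dataclass
class BehaviorParams:
    lowpass_cutoff: float = 1.0  # Hz
    filter_order: int = 2  # applied forward-backward => zero phase, order 4
    running_threshold: float = 2.5  # cm/s
    despike_max_passes: int = 10
    despike_prominence: float = 10.0  # session-scale units


def detect_events(
    dff: np.ndarray,
    sample_rate: float = 30.0,
    cell_id: str = "",
    threshold: Optional[float] = None,
    smooth_sigma: float = 1.0,
    refractory_samples: int = 6,
    detector: Optional[Callable[[np.ndarray], list[EventRecord]]] = None,
) -> list[EventRecord]:
    """Detect discrete calcium events in a dF/F trace.

    A custom ``detector`` callable takes precedence.  The default detector
    smooths the trace, thresholds its first difference at ``threshold``
    (default 3 robust SDs of the differenced trace, floored at a small
    absolute rise), and emits one event per suprathreshold onset, separated by
    ``refractory_samples``; the magnitude is the local rise of the smoothed
    trace after the onset.
    """
    if detector is not None:
        return detector(np.asarray(dff, dtype=float))
    dff = np.asarray(dff, dtype=float)
    smooth = gaussian_filter1d(dff, smooth_sigma) if smooth_sigma else dff
    deriv = np.diff(dff, prepend=dff[:1])
    if threshold is None:
        mad = np.median(np.abs(deriv - np.median(deriv)))
        threshold = max(3 * 1.4826 * mad, 1e-3)
    events: list[EventRecord] = []
    above = deriv > threshold
    i = 0
    n = len(dff)
    while i < n:
        if above[i]:
            onset = i
            while i < n and above[i]:  # one event per contiguous rise
                i += 1
            peak_end = min(i + refractory_samples, n)
            magnitude = float(smooth[onset:peak_end].max() - smooth[max(onset - 1, 0)])
            if magnitude > 0:
                events.append(EventRecord(cell_id, onset, magnitude))
            i = max(i, onset + refractory_samples)
        else:
            i += 1
    return events


def events_to_frame(events: list[EventRecord], cell_index: int = 0) -> pd.DataFrame:
    """Tidy frame with (cell_index, sample_index, magnitude) columns."""
    return pd.DataFrame(
        {
            "cell_index": [cell_index] * len(events),
            "sample_index": [e.sample_index for e in events],
            "magnitude": [e.magnitude for e in events],
        }
    )


def despike_velocity(velocity: np.ndarray, params: BehaviorParams) -> np.ndarray:
    """Iteratively remove large positive/negative peaks and interpolate over them.

    Each pass flags peaks of the signal and its negation whose prominence
    exceeds ``despike_prominence`` and refills them by linear interpolation;
    passes repeat until no peak is found or ``despike_max_passes`` is reached.
    Idempotent once clean.
    """
    v = np.asarray(velocity, dtype=float).copy()
    idx = np.arange(len(v))
    for _ in range(params.despike_max_passes):
        pos, _ = find_peaks(v, prominence=params.despike_prominence)
        neg, _ = find_peaks(-v, prominence=params.despike_prominence)
        bad = np.union1d(pos, neg)
        if bad.size == 0:
            break
        good = np.setdiff1d(idx, bad)
        v[bad] = np.interp(bad, good, v[good])
    return v


def lowpass_velocity(
    velocity: np.ndarray, params: BehaviorParams, sample_rate: float = 30.0
) -> np.ndarray:
    """Zero-phase Butterworth low-pass (forward-backward filtering)."""
    velocity = np.asarray(velocity, dtype=float)
    if len(velocity) <= 3 * params.filter_order:
        raise ValueError("trace too short for zero-phase filtering")
    if params.lowpass_cutoff >= sample_rate / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    b, a = butter(params.filter_order, params.lowpass_cutoff / (sample_rate / 2))
    return filtfilt(b, a, velocity)


def preprocess_velocity(
    velocity: np.ndarray, params: BehaviorParams, sample_rate: float = 30.0
) -> np.ndarray:
    """Fixed-order pipeline: despike, then zero-phase low-pass."""
    return lowpass_velocity(despike_velocity(velocity, params), params, sample_rate)


def running_fraction(velocity: np.ndarray, threshold: float = 2.5) -> float:
    """Fraction of samples with (preprocessed) velocity strictly above threshold."""
    velocity = np.asarray(velocity, dtype=float)
    return float(np.mean(velocity > threshold))


def normalize_pupil(pupil: np.ndarray, trials: pd.DataFrame) -> np.ndarray:
    """Divide by the maximum diameter over the full extent of the stimulus blocks.

    The span is [first trial start, last trial end), so gray gaps between
    trials count toward the maximum; samples outside the span may exceed 1
    after normalization.
    """
    pupil = np.asarray(pupil, dtype=float)
    lo = int(trials["start_sample"].min())
    hi = int(trials["end_sample"].max())
    span = pupil[lo:hi]
    if not np.isfinite(span).any():
        raise ValueError("no finite pupil samples within the stimulus blocks")
    peak = np.nanmax(span)
    if peak <= 0:
        raise ValueError("nonpositive maximum pupil diameter in the stimulus blocks")
    return pupil / peak
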