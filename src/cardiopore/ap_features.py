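"""AP / FP feature extraction and culture synchrony.

Features operate on baseline-corrected waveforms (resting level at 0).
Crossings are located with linear interpolation between samples for
sub-sample precision; the peak time uses a first-crossing-of-99%-of-max
convention that is stable on plateau-shaped action potentials.
"""

from __future__ import annotations

import dataclasses
from typing import List, Sequence

import numpy as np

from .errors import FeatureUndefinedError, ParameterError

__all__ = [
    "FeatureConfig",
    "APFeatures",
    "ap_amplitude",
    "apd90",
    "depolarization_time",
    "fp_amplitude",
    "percent_synchronous",
    "extract_all",
]


@dataclasses.dataclass(frozen=True)
class FeatureConfig:
    """Onset/end conventions for duration features.

    ``onset_fraction`` is the threshold (fraction of peak) whose last
    upward crossing before the peak defines the AP onset; it is shared by
    APD90 and the depolarization time so both features use one onset.
    ``end_fraction`` (0.1 = 90% repolarization) defines the APD90 end.
    ``peak_fraction`` defines the plateau-robust peak time (first crossing
    of that fraction of the maximum).
    """

    onset_fraction: float = 0.01
    end_fraction: float = 0.10
    peak_fraction: float = 0.99


@dataclasses.dataclass(frozen=True)
class APFeatures:
    ap_amplitude_mv: float
    apd90_ms: float
    tdep_ms: float
    onset_t_ms: float
    peak_t_ms: float

    def __post_init__(self) -> None:
        if np.isfinite(self.apd90_ms) and np.isfinite(self.tdep_ms):
            if not (self.apd90_ms > self.tdep_ms > 0):
                raise ParameterError("APFeatures require apd90_ms > tdep_ms > 0")


def _peak(waveform: np.ndarray) -> float:
    peak = float(np.max(waveform))
    if peak <= 0:
        raise FeatureUndefinedError("waveform has no positive peak")
    return peak


def _onset_time_idx(w: np.ndarray, peak_idx: int, threshold: float) -> float:
    """Last upward crossing of ``threshold`` before ``peak_idx`` (fractional index)."""
    for i in range(peak_idx, 0, -1):
        if w[i - 1] < threshold <= w[i]:
            return (i - 1) + (threshold - w[i - 1]) / (w[i] - w[i - 1])
    raise FeatureUndefinedError("onset not found: waveform never rises through threshold")


def ap_amplitude(waveform: np.ndarray, input_units: str = "uv") -> float:
    """AP amplitude in mV (peak minus the already-subtracted baseline)."""
    peak = _peak(np.asarray(waveform, dtype=float))
    if input_units == "uv":
        return peak / 1000.0
    if input_units == "mv":
        return peak
    raise ParameterError(f"unknown input units {input_units!r}")


def apd90(
    waveform: np.ndarray, fs_hz: float, config: FeatureConfig = FeatureConfig()
) -> float:
    """AP duration at 90% repolarization (ms); amplitude-scale invariant.

    Onset: last upward crossing of ``onset_fraction * peak`` before the
    peak. End: first downward crossing of ``end_fraction * peak`` after the
    peak. Both interpolated linearly.
    """
    w = np.asarray(waveform, dtype=float)
    peak = _peak(w)
    peak_idx = int(np.argmax(w))
    onset = _onset_time_idx(w, peak_idx, config.onset_fraction * peak)
    end_thr = config.end_fraction * peak
    end = None
    for i in range(peak_idx, w.size - 1):
        if w[i] >= end_thr > w[i + 1]:
            end = i + (w[i] - end_thr) / (w[i] - w[i + 1])
            break
    if end is None:
        raise FeatureUndefinedError("apd90 undefined: waveform never repolarizes to 10%")
    return (end - onset) * 1000.0 / fs_hz


def depolarization_time(
    waveform: np.ndarray, fs_hz: float, config: FeatureConfig = FeatureConfig()
) -> float:
    """Upstroke duration (onset to peak) in ms.

    The peak time is the interpolated first crossing of
    ``peak_fraction * max``; with ``peak_fraction = 1`` it degenerates to
    the argmax sample.
    """
    w = np.asarray(waveform, dtype=float)
    peak = _peak(w)
    peak_idx = int(np.argmax(w))
    onset = _onset_time_idx(w, peak_idx, config.onset_fraction * peak)
    if config.peak_fraction >= 1.0:
        peak_t = float(peak_idx)
    else:
        thr = config.peak_fraction * peak
        peak_t = _first_up_crossing(w, thr, peak_idx)
    return (peak_t - onset) * 1000.0 / fs_hz


def _first_up_crossing(w: np.ndarray, threshold: float, stop_idx: int) -> float:
    for i in range(stop_idx):
        if w[i] < threshold <= w[i + 1]:
            return i + (threshold - w[i]) / (w[i + 1] - w[i])
    return float(stop_idx)


def fp_amplitude(snippet: np.ndarray, fs_hz: float, window_ms: float = 10.0) -> float:
    """Peak-to-peak field-potential amplitude (uV).

    Max minus min of the offset-corrected snippet within +-``window_ms``
    of the largest absolute deflection.
    """
    w = np.asarray(snippet, dtype=float)
    if w.size == 0:
        raise FeatureUndefinedError("empty snippet")
    peak_idx = int(np.argmax(np.abs(w)))
    half = int(round(window_ms * fs_hz / 1000.0))
    lo, hi = max(0, peak_idx - half), min(w.size, peak_idx + half + 1)
    return float(np.max(w[lo:hi]) - np.min(w[lo:hi]))


def extract_all(
    waveform_uv: np.ndarray, fs_hz: float, config: FeatureConfig = FeatureConfig()
) -> APFeatures:
    """All AP features of one baseline-corrected waveform (uV)."""
    w = np.asarray(waveform_uv, dtype=float)
    peak = _peak(w)
    peak_idx = int(np.argmax(w))
    onset = _onset_time_idx(w, peak_idx, config.onset_fraction * peak)
    return APFeatures(
        ap_amplitude_mv=ap_amplitude(w),
        apd90_ms=apd90(w, fs_hz, config),
        tdep_ms=depolarization_time(w, fs_hz, config),
        onset_t_ms=onset * 1000.0 / fs_hz,
        peak_t_ms=peak_idx * 1000.0 / fs_hz,
    )


def percent_synchronous(
    beat_time_lists: Sequence[Sequence[float]],
    tol_ms: float = 50.0,
    min_participation: float = 0.8,
) -> float:
    """Percentage of electrodes beating synchronously with the network.

    Pooled peak times are greedily clustered (a peak joins the current
    cluster while it lies within ``tol_ms`` of the cluster median);
    clusters containing more than half of the active electrodes count as
    network beats. An electrode is synchronous if it participates in at
    least ``min_participation`` of the network beats.
    """
    lists = [np.asarray(lst, dtype=float) for lst in beat_time_lists]
    active = [i for i, lst in enumerate(lists) if lst.size > 0]
    if not active:
        raise ParameterError("no active electrodes: empty input")
    tol_s = tol_ms / 1000.0
    pooled = sorted(
        (t, i) for i in active for t in lists[i]
    )
    clusters: List[List[tuple]] = []
    current: List[tuple] = []
    for t, i in pooled:
        if current and t - float(np.median([c[0] for c in current])) > tol_s:
            clusters.append(current)
            current = []
        current.append((t, i))
    if current:
        clusters.append(current)
    n_active = len(active)
    network = [c for c in clusters if len({i for _, i in c}) > n_active / 2.0]
    if not network:
        return 0.0
    sync = 0
    for i in active:
        part = sum(1 for c in network if any(j == i for _, j in c))
        if part / len(network) >= min_participation:
            sync += 1
    return 100.0 * sync / n_active
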