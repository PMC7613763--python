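"""Beat detection, snippet extraction, classification and averaging.

Turns one channel trace (plus its poration events) into a representative
per-channel waveform: detect beats against a robust noise floor, cut
offset-corrected snippets, label each snippet extracellular vs
intracellular-like by the amplitude/width rule, then average three
consecutive qualifying beats taken after the post-poration settling delay
(or after the amplifier-offset drift has stabilized).
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import ap_features
from .errors import FeatureUndefinedError, ParameterError
from .synth_interface import Recording

__all__ = [
    "ClassifierConfig",
    "BeatSnippet",
    "AveragedWaveform",
    "Exclusion",
    "detect_beats",
    "rolling_baseline",
    "correct_offset",
    "extract_snippets",
    "classify_waveform",
    "select_and_average",
    "normalize_amplitude",
    "analyze_recording",
]

LABEL_EXTRACELLULAR = "extracellular"
LABEL_INTRACELLULAR = "intracellular_like"


@dataclasses.dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds and windows of the waveform pipeline.

    Classification uses strict inequalities: intracellular-like iff peak
    amplitude > ``min_peak_uv`` AND width > ``min_width_ms`` (full width at
    ``width_fraction`` of the peak). Detector thresholds (MAD multiplier,
    absolute floor, refractory period) are implementation choices.
    """

    min_peak_uv: float = 500.0
    min_width_ms: float = 25.0
    width_fraction: float = 0.5
    yield_min_amp_mv: float = 1.0
    snippet_pre_ms: float = 25.0
    snippet_post_ms: float = 600.0
    baseline_ms: float = 5.0
    settle_delay_s: float = 9.0
    stabilization_drift_uv_per_s: float = 50.0
    detect_mad_mult: float = 6.0
    detect_floor_uv: float = 50.0
    refractory_ms: float = 100.0
    peak_fraction: float = 0.99
    baseline_window_s: float = 1.0

    def __post_init__(self) -> None:
        if self.min_peak_uv <= 0 or self.min_width_ms <= 0:
            raise ParameterError("classification thresholds must be > 0")
        if self.snippet_pre_ms + self.snippet_post_ms < self.min_width_ms:
            raise ParameterError("snippet window must cover min_width_ms")


@dataclasses.dataclass
class BeatSnippet:
    """One offset-corrected beat cut around a detected peak."""

    electrode_id: int
    t_peak_s: float
    samples: np.ndarray  # uV, baseline-corrected
    fs_hz: float
    label: Optional[str] = None
    baseline_raw_uv: float = 0.0  # pre-correction baseline, for drift tracking
    provenance: Dict[str, object] = dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class AveragedWaveform:
    """Representative per-channel waveform (pointwise mean of 3 beats)."""

    electrode_id: int
    samples: np.ndarray
    fs_hz: float
    label: str
    n_beats: int
    t_measure_s: float


@dataclasses.dataclass
class Exclusion:
    electrode_id: int
    reason: str


def rolling_baseline(trace: np.ndarray, fs_hz: float, window_s: float = 1.0) -> np.ndarray:
    """Slow baseline via block medians (quarter-window step) interpolated.

    Robust to beats occupying < 50% of each window; tracks exponential
    amplifier-offset decays on the ~1 s scale.
    """
    x = np.asarray(trace, dtype=float)
    step = max(1, int(round(window_s * fs_hz / 4)))
    starts = np.arange(0, x.size, step)
    centers = []
    meds = []
    half = int(round(window_s * fs_hz / 2))
    for s in starts:
        lo = max(0, s - half + step // 2)
        hi = min(x.size, s + half + step // 2)
        centers.append((lo + hi) / 2.0)
        meds.append(np.median(x[lo:hi]))
    return np.interp(np.arange(x.size), centers, meds)


def correct_offset(
    signal: np.ndarray,
    fs_hz: float,
    mode: str = "trace",
    baseline_ms: float = 5.0,
    window_s: float = 1.0,
) -> np.ndarray:
    """Remove amplifier offsets.

    ``mode="trace"``: subtract a running (block-median) baseline.
    ``mode="snippet"``: subtract the median of the leading ``baseline_ms``
    of the snippet; idempotent by construction.
    """
    x = np.asarray(signal, dtype=float)
    if mode == "snippet":
        nb = max(1, int(round(baseline_ms * fs_hz / 1000.0)))
        return x - np.median(x[:nb])
    if mode == "trace":
        return x - rolling_baseline(x, fs_hz, window_s)
    raise ParameterError(f"unknown correction mode {mode!r}")


def detect_beats(
    trace: np.ndarray,
    fs_hz: float,
    config: ClassifierConfig = ClassifierConfig(),
) -> np.ndarray:
    """Detect beat peak times (s, trace-local) in one channel.

    A detrended copy is thresholded at max(mad_mult * sigma_hat,
    floor) with sigma_hat = 1.4826 * MAD; suprathreshold samples within the
    refractory period merge into one event. The event peak is placed at the
    first sample reaching ``peak_fraction`` of the event maximum, which is
    stable on plateau-shaped intracellular-like waveforms where the argmax
    would wander.
    """
    x = np.asarray(trace, dtype=float)
    if x.size < fs_hz:
        raise ParameterError("trace too short (need >= 1 s)")
    d = x - rolling_baseline(x, fs_hz, config.baseline_window_s)
    sigma = 1.4826 * np.median(np.abs(d - np.median(d)))
    thr = max(config.detect_mad_mult * sigma, config.detect_floor_uv)
    above = np.flatnonzero(np.abs(d) > thr)
    if above.size == 0:
        return np.asarray([])
    refractory = int(round(config.refractory_ms * fs_hz / 1000.0))
    breaks = np.flatnonzero(np.diff(above) > refractory)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [above.size - 1]))
    peaks = []
    for s, e in zip(starts, ends):
        lo, hi = above[s], above[e] + 1
        seg = d[lo:hi]
        if seg.max() >= -seg.min():
            target = config.peak_fraction * seg.max()
            idx = np.flatnonzero(seg >= target)[0]
        else:
            target = config.peak_fraction * (-seg.min())
            idx = np.flatnonzero(-seg >= target)[0]
        peaks.append((lo + idx) / fs_hz)
    return np.asarray(peaks)


def extract_snippets(
    trace: np.ndarray,
    peak_times_s: Sequence[float],
    fs_hz: float,
    config: ClassifierConfig = ClassifierConfig(),
    electrode_id: int = 0,
    detrend: bool = True,
) -> List[BeatSnippet]:
    """Cut [peak - pre, peak + post] windows and baseline-correct each.

    The per-snippet baseline is the median of the leading ``baseline_ms``
    of the window (i.e. the quiet segment just before the upstroke); its
    raw value is retained for offset-drift tracking. Beats too close to the
    trace edges are skipped.
    """
    x = np.asarray(trace, dtype=float)
    base = rolling_baseline(x, fs_hz, config.baseline_window_s) if detrend else 0.0
    d = x - base
    pre = int(round(config.snippet_pre_ms * fs_hz / 1000.0))
    post = int(round(config.snippet_post_ms * fs_hz / 1000.0))
    nb = max(1, int(round(config.baseline_ms * fs_hz / 1000.0)))
    snippets = []
    for t in peak_times_s:
        p = int(round(t * fs_hz))
        lo, hi = p - pre, p + post
        if lo < 0 or hi > x.size:
            continue
        seg = d[lo:hi]
        raw_baseline = float(np.median(x[lo : lo + nb]))
        snippets.append(
            BeatSnippet(
                electrode_id=electrode_id,
                t_peak_s=float(t),
                samples=seg - np.median(seg[:nb]),
                fs_hz=fs_hz,
                baseline_raw_uv=raw_baseline,
            )
        )
    return snippets


def _fwhm_ms(samples: np.ndarray, fs_hz: float, fraction: float) -> float:
    """Full width of the positive deflection at ``fraction`` of its peak."""
    peak_idx = int(np.argmax(samples))
    peak = samples[peak_idx]
    if peak <= 0:
        return 0.0
    half = fraction * peak
    left = None
    for i in range(peak_idx, 0, -1):
        if samples[i - 1] < half <= samples[i]:
            frac = (half - samples[i - 1]) / (samples[i] - samples[i - 1])
            left = (i - 1) + frac
            break
    if left is None:
        left = 0.0
    right = None
    for i in range(peak_idx, samples.size - 1):
        if samples[i] >= half > samples[i + 1]:
            frac = (samples[i] - half) / (samples[i] - samples[i + 1])
            right = i + frac
            break
    if right is None:
        right = float(samples.size - 1)
    return (right - left) * 1000.0 / fs_hz


def classify_waveform(snippet: BeatSnippet, config: ClassifierConfig = ClassifierConfig()) -> str:
    """Label one offset-corrected snippet.

    Intracellular-like iff the peak amplitude exceeds ``min_peak_uv``
    (strictly) and the full width at ``width_fraction`` of the peak exceeds
    ``min_width_ms`` (strictly); everything else is extracellular. The
    label is stored on the snippet and returned.
    """
    amp = float(np.max(snippet.samples))
    width = _fwhm_ms(snippet.samples, snippet.fs_hz, config.width_fraction)
    label = (
        LABEL_INTRACELLULAR
        if (amp > config.min_peak_uv and width > config.min_width_ms)
        else LABEL_EXTRACELLULAR
    )
    snippet.label = label
    return label


def _drift_ok(
    snippets: Sequence[BeatSnippet], i: int, tol_uv_per_s: float
) -> bool:
    if i == 0:
        return True
    dt = snippets[i].t_peak_s - snippets[i - 1].t_peak_s
    if dt <= 0:
        return True
    drift = abs(snippets[i].baseline_raw_uv - snippets[i - 1].baseline_raw_uv) / dt
    return drift <= tol_uv_per_s


def select_and_average(
    snippets: Sequence[BeatSnippet],
    poration_end_s: float,
    config: ClassifierConfig = ClassifierConfig(),
    label: str = LABEL_INTRACELLULAR,
) -> Tuple[Optional[AveragedWaveform], Optional[Exclusion]]:
    """Average the first three consecutive qualifying beats of a channel.

    A beat qualifies when it carries the requested label, its peak time is
    at least ``settle_delay_s`` after the poration end, and the local
    amplifier-offset drift is below ``stabilization_drift_uv_per_s`` (the
    operational "channel stabilization" criterion). The three beats must be
    consecutive detections; they are aligned at the peak sample and
    averaged pointwise. Fewer than three qualifying beats yields an
    exclusion record, not an exception.
    """
    snippets = sorted(snippets, key=lambda s: s.t_peak_s)
    eid = snippets[0].electrode_id if snippets else -1
    if not snippets:
        return None, Exclusion(eid, "no_beats")
    ok = []
    for i, sn in enumerate(snippets):
        if sn.label is None:
            classify_waveform(sn, config)
        ok.append(
            sn.label == label
            and sn.t_peak_s >= poration_end_s + config.settle_delay_s
            and _drift_ok(snippets, i, config.stabilization_drift_uv_per_s)
        )
    for i in range(len(snippets) - 2):
        if ok[i] and ok[i + 1] and ok[i + 2]:
            trio = snippets[i : i + 3]
            n = min(s.samples.size for s in trio)
            avg = np.mean([s.samples[:n] for s in trio], axis=0)
            return (
                AveragedWaveform(
                    electrode_id=trio[0].electrode_id,
                    samples=avg,
                    fs_hz=trio[0].fs_hz,
                    label=label,
                    n_beats=3,
                    t_measure_s=trio[0].t_peak_s,
                ),
                None,
            )
    return None, Exclusion(eid, "insufficient_beats")


def normalize_amplitude(waveform: np.ndarray, fs_hz: float = 20000.0, baseline_ms: float = 5.0) -> np.ndarray:
    """Scale a waveform to unit peak after baseline subtraction.

    Raises :class:`FeatureUndefinedError` for a zero-peak waveform.
    """
    x = np.asarray(waveform, dtype=float)
    nb = max(1, int(round(baseline_ms * fs_hz / 1000.0)))
    x = x - np.median(x[:nb])
    peak = np.max(x)
    if peak <= 0:
        raise FeatureUndefinedError("zero peak: cannot normalize amplitude")
    return x / peak


def analyze_recording(
    recording: Recording,
    config: ClassifierConfig = ClassifierConfig(),
    phase: str = "",
    repeat_idx: int = 0,
    feature_config: "ap_features.FeatureConfig" = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Full per-channel analysis of one Recording.

    For every channel: detrend, detect beats, cut and classify snippets,
    build the representative waveform (intracellular-like if possible,
    otherwise extracellular) and extract AP/FP features. Returns the
    feature table (canonical CSV schema) and the exclusion log.
    """
    if feature_config is None:
        feature_config = ap_features.FeatureConfig()
    rows = []
    exclusions = []
    for ci in range(recording.n_channels):
        state = recording.channel_meta[ci] if recording.channel_meta else None
        eid = state.electrode_id if state is not None else ci
        trace = recording.signals[ci].astype(float)
        ev = recording.events_for(eid)
        poration_end_local = max((e.t_end_s - recording.t0_s for e in ev), default=-np.inf)
        try:
            peaks = detect_beats(trace, recording.fs_hz, config)
        except ParameterError:
            exclusions.append({"electrode_id": eid, "reason": "trace_too_short"})
            continue
        snippets = extract_snippets(trace, peaks, recording.fs_hz, config, electrode_id=eid)
        if not snippets:
            exclusions.append({"electrode_id": eid, "reason": "no_beats"})
            rows.append(_row(eid, repeat_idx, phase, "none", np.nan, np.nan, np.nan, np.nan, 0, np.nan))
            continue
        for sn in snippets:
            classify_waveform(sn, config)

        # FP amplitude from extracellular beats before the poration (or all
        # beats on never-porated channels)
        fp_snips = [
            s
            for s in snippets
            if s.label == LABEL_EXTRACELLULAR
            and (not np.isfinite(poration_end_local) or s.t_peak_s < poration_end_local)
        ]
        fp_amp = (
            float(np.median([ap_features.fp_amplitude(s.samples, s.fs_hz) for s in fp_snips]))
            if fp_snips
            else np.nan
        )

        rep, excl = select_and_average(snippets, poration_end_local, config, LABEL_INTRACELLULAR)
        if rep is not None:
            try:
                feats = ap_features.extract_all(rep.samples, rep.fs_hz, feature_config)
                rows.append(
                    _row(
                        eid,
                        repeat_idx,
                        phase,
                        LABEL_INTRACELLULAR,
                        feats.ap_amplitude_mv,
                        feats.apd90_ms,
                        feats.tdep_ms,
                        fp_amp,
                        rep.n_beats,
                        rep.t_measure_s + recording.t0_s,
                    )
                )
                continue
            except FeatureUndefinedError:
                exclusions.append({"electrode_id": eid, "reason": "features_undefined"})
        # fall back to an extracellular representative
        rep_ec, excl_ec = select_and_average(
            snippets, -np.inf, dataclasses.replace(config, settle_delay_s=0.0), LABEL_EXTRACELLULAR
        )
        if rep_ec is not None:
            if not fp_snips:
                fp_amp = ap_features.fp_amplitude(rep_ec.samples, rep_ec.fs_hz)
            rows.append(
                _row(
                    eid,
                    repeat_idx,
                    phase,
                    LABEL_EXTRACELLULAR,
                    np.nan,
                    np.nan,
                    np.nan,
                    fp_amp,
                    rep_ec.n_beats,
                    rep_ec.t_measure_s + recording.t0_s,
                )
            )
        else:
            reason = excl.reason if excl is not None else "insufficient_beats"
            exclusions.append({"electrode_id": eid, "reason": reason})
            rows.append(_row(eid, repeat_idx, phase, "none", np.nan, np.nan, np.nan, fp_amp, 0, np.nan))

    features = pd.DataFrame(
        rows,
        columns=[
            "electrode_id",
            "repeat_idx",
            "phase",
            "label",
            "ap_amplitude_mv",
            "apd90_ms",
            "tdep_ms",
            "fp_amplitude_uv",
            "n_beats_averaged",
            "t_measure_s",
        ],
    )
    return features, pd.DataFrame(exclusions, columns=["electrode_id", "reason"])


def _row(eid, repeat_idx, phase, label, amp, apd90, tdep, fp, nbeats, tmeas):
    return {
        "electrode_id": eid,
        "repeat_idx": repeat_idx,
        "phase": phase,
        "label": label,
        "ap_amplitude_mv": amp,
        "apd90_ms": apd90,
        "tdep_ms": tdep,
        "fp_amplitude_uv": fp,
        "n_beats_averaged": nbeats,
        "t_measure_s": tmeas,
    }
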