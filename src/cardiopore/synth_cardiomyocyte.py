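"""Ground-truth cardiomyocyte membrane-voltage synthesis.

Parametric action-potential (AP) templates, spontaneous beat schedules,
multiplicative drug modulation, and rendering of membrane-voltage traces.
The AP template is a product of two sigmoids with a closed-form
90%-repolarization point, so every downstream feature extractor can be
validated against exact generator parameters.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Union

import numpy as np
from scipy.special import expit

from .errors import ParameterError

LN9 = math.log(9.0)

__all__ = [
    "APParams",
    "BeatSchedule",
    "DrugEffect",
    "CultureModel",
    "DRUG_PRESETS",
    "make_ap_template",
    "schedule_beats",
    "apply_drug_effect",
    "render_membrane_trace",
    "render_membrane_segment",
    "template_duration_ms",
]

RngLike = Union[int, np.random.Generator, None]


def _as_rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclasses.dataclass(frozen=True)
class APParams:
    """Shape parameters of a single action potential.

    The resting level is stored as 0 in the rendered trace; electrode
    offsets are added downstream by the interface model.

    Attributes
    ----------
    amplitude_mv : membrane AP amplitude in mV (0 allowed for a silent cell).
    t_dep_ms : depolarization time, onset to peak, in ms.
    apd90_ms : AP duration at 90% repolarization in ms.
    rep_width_ms : repolarization sigmoid width ``w`` in ms.
    baseline_mv : resting potential label (metadata only).
    """

    amplitude_mv: float = 100.0
    t_dep_ms: float = 10.0
    apd90_ms: float = 300.0
    rep_width_ms: float = 20.0
    baseline_mv: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_mv < 0:
            raise ParameterError("amplitude_mv must be >= 0")
        if self.t_dep_ms <= 0:
            raise ParameterError("t_dep_ms must be > 0")
        if self.rep_width_ms <= 0:
            raise ParameterError("rep_width_ms must be > 0")
        if self.apd90_ms <= self.t_dep_ms:
            raise ParameterError("apd90_ms must exceed t_dep_ms")
        if self.repolarization_midpoint_ms <= self.t_dep_ms:
            raise ParameterError(
                "repolarization midpoint (apd90_ms - rep_width_ms*ln 9) must "
                "lie after the depolarization time"
            )

    @property
    def repolarization_midpoint_ms(self) -> float:
        """Midpoint ``m`` of the repolarization sigmoid (ms after onset)."""
        return self.apd90_ms - self.rep_width_ms * LN9


@dataclasses.dataclass(frozen=True)
class BeatSchedule:
    """Ordered spontaneous beat onsets for one synchronized culture."""

    onset_times_s: np.ndarray
    rate_bpm: float
    cv: float
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onset_times_s, dtype=float)
        object.__setattr__(self, "onset_times_s", onsets)
        if onsets.size > 1 and not np.all(np.diff(onsets) > 0):
            raise ParameterError("beat onsets must be strictly increasing")

    def __len__(self) -> int:
        return int(self.onset_times_s.size)


@dataclasses.dataclass(frozen=True)
class DrugEffect:
    """Multiplicative modulation of AP shape by a compound.

    ``apd90_factor`` / ``tdep_factor`` scale the respective parameters;
    ``cell_sd`` is the per-cell lognormal dispersion of each factor
    (strictly positive multiplicative cell-to-cell variability).
    """

    name: str = "custom"
    apd90_factor: float = 1.0
    tdep_factor: float = 1.0
    cell_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.apd90_factor <= 0 or self.tdep_factor <= 0:
            raise ParameterError("drug factors must be > 0")
        if self.cell_sd < 0:
            raise ParameterError("cell_sd must be >= 0")
        if self.name == "dmso_vehicle" and (
            self.apd90_factor != 1.0 or self.tdep_factor != 1.0
        ):
            raise ParameterError("dmso_vehicle must have unit factors")


#: Preset effects with factors matching the mean percent changes used as
#: simulation ground truth (APD90 -36.9% / tdep +15.5% for the Ca-channel
#: blocker; APD90 +32.7% / tdep +46.4% for the Na/hERG blocker).
DRUG_PRESETS = {
    "nifedipine": DrugEffect("nifedipine", apd90_factor=0.631, tdep_factor=1.155, cell_sd=0.05),
    "quinidine": DrugEffect("quinidine", apd90_factor=1.327, tdep_factor=1.464, cell_sd=0.05),
    "dmso_vehicle": DrugEffect("dmso_vehicle", apd90_factor=1.0, tdep_factor=1.0, cell_sd=0.0),
}


def template_duration_ms(params: APParams) -> float:
    """Window length that comfortably contains one full AP."""
    return params.apd90_ms + 5.0 * params.rep_width_ms + 2.0 * params.t_dep_ms


def make_ap_template(
    params: APParams, fs_hz: float, duration_ms: Optional[float] = None
) -> np.ndarray:
    """Render one AP waveform (mV per sample) with onset at t = 0.

    V(t) = A * r(t) * f(t) with a rising sigmoid
    r(t) = 1 / (1 + exp(-(t - t_dep/2) / (t_dep/10))) and a repolarization
    sigmoid f(t) = 1 / (1 + exp((t - m) / w)), m = apd90 - w*ln 9, so that
    A*f crosses 0.1*A exactly at t = apd90 (where r is ~1).
    """
    if fs_hz < 1000:
        raise ParameterError("fs_hz must be >= 1 kHz")
    if duration_ms is None:
        duration_ms = template_duration_ms(params)
    if duration_ms < params.apd90_ms + 5.0 * params.rep_width_ms:
        raise ParameterError("duration_ms must be >= apd90_ms + 5*rep_width_ms")

    n = int(round(duration_ms * fs_hz / 1000.0))
    t = np.arange(n) * (1000.0 / fs_hz)  # ms
    r = expit((t - params.t_dep_ms / 2.0) / (params.t_dep_ms / 10.0))
    f = expit(-(t - params.repolarization_midpoint_ms) / params.rep_width_ms)
    return params.amplitude_mv * r * f


def schedule_beats(
    rate_bpm: float,
    cv: float,
    duration_s: float,
    seed: RngLike = None,
    min_interval_s: float = 0.45,
) -> BeatSchedule:
    """Draw a spontaneous beat schedule covering ``duration_s``.

    Inter-beat intervals are normal with mean 60/rate and SD cv*mean;
    intervals below ``min_interval_s`` are rejected and redrawn so beats
    never overlap. ``cv = 0`` yields a perfectly periodic train starting
    at t = 0. Deterministic under a fixed seed.
    """
    if not (10.0 <= rate_bpm <= 200.0):
        raise ParameterError("rate_bpm must lie in [10, 200]")
    if duration_s <= 0:
        raise ParameterError("duration_s must be > 0")
    if cv < 0:
        raise ParameterError("cv must be >= 0")
    mean = 60.0 / rate_bpm
    if mean <= min_interval_s:
        raise ParameterError(
            f"mean inter-beat interval {mean:.3f} s does not exceed the "
            f"minimum interval {min_interval_s:.3f} s"
        )
    rng = _as_rng(seed)
    onsets = [0.0]
    t = 0.0
    while True:
        if cv == 0:
            dt = mean
        else:
            dt = rng.normal(mean, cv * mean)
            tries = 0
            while dt <= min_interval_s:
                dt = rng.normal(mean, cv * mean)
                tries += 1
                if tries > 10_000:  # pragma: no cover - pathological cv
                    raise ParameterError("cannot satisfy minimum-interval invariant")
        t += dt
        if t >= duration_s:
            break
        onsets.append(t)
    seed_val = seed if isinstance(seed, int) else None
    return BeatSchedule(np.asarray(onsets), rate_bpm, cv, seed_val)


def apply_drug_effect(params: APParams, effect: DrugEffect, seed: RngLike = None) -> APParams:
    """Apply multiplicative drug factors with per-cell lognormal dispersion.

    apd90' = apd90 * apd90_factor * L1 and t_dep' = t_dep * tdep_factor * L2
    with L1, L2 ~ lognormal(0, cell_sd). Draws violating the APParams
    invariants are resampled; a structurally impossible combination (the
    deterministic part already collapses apd90 below t_dep) raises.
    """
    det_apd90 = params.apd90_ms * effect.apd90_factor
    det_tdep = params.t_dep_ms * effect.tdep_factor
    if det_apd90 - params.rep_width_ms * LN9 <= det_tdep:
        raise ParameterError(
            "drug factors make apd90 structurally incompatible with t_dep"
        )
    rng = _as_rng(seed)
    for _ in range(1000):
        l1 = math.exp(rng.normal(0.0, effect.cell_sd)) if effect.cell_sd else 1.0
        l2 = math.exp(rng.normal(0.0, effect.cell_sd)) if effect.cell_sd else 1.0
        try:
            return dataclasses.replace(
                params, apd90_ms=det_apd90 * l1, t_dep_ms=det_tdep * l2
            )
        except ParameterError:
            continue
    raise ParameterError("could not sample drug-modified parameters")  # pragma: no cover


def render_membrane_segment(
    params: APParams,
    onset_times_s: np.ndarray,
    fs_hz: float,
    t_start_s: float,
    n_samples: int,
) -> np.ndarray:
    """Render the membrane voltage for samples [t_start, t_start + n/fs).

    Beats whose support overlaps the segment are rendered; the trace is 0
    between beats. Used both for whole-trace rendering and for streamed,
    segment-wise generation (segments concatenate exactly).
    """
    out = np.zeros(n_samples, dtype=float)
    if params.amplitude_mv == 0 or len(onset_times_s) == 0:
        return out
    dur_ms = template_duration_ms(params)
    template = make_ap_template(params, fs_hz, dur_ms)
    m = template.size
    start_idx = int(round(t_start_s * fs_hz))
    for onset in np.asarray(onset_times_s, dtype=float):
        o = int(round(onset * fs_hz)) - start_idx
        if o >= n_samples or o + m <= 0:
            continue
        lo = max(o, 0)
        hi = min(o + m, n_samples)
        out[lo:hi] += template[lo - o : hi - o]
    return out


def render_membrane_trace(
    params: APParams,
    schedule: BeatSchedule,
    fs_hz: float,
    duration_s: float,
) -> np.ndarray:
    """Superpose AP templates at the scheduled onsets (mV, length = round(T*fs))."""
    n = int(round(duration_s * fs_hz))
    return render_membrane_segment(params, schedule.onset_times_s, fs_hz, 0.0, n)


@dataclasses.dataclass(frozen=True)
class CultureModel:
    """Parameters of a simulated, synchronously beating culture.

    Per-cell baseline dispersion and (optional) drug modulation are derived
    deterministically from ``seed`` and the electrode id, so repeated
    measurement phases observe the same cells.
    """

    ap: APParams = APParams()
    rate_bpm: float = 30.0
    cv: float = 0.05
    cell_sd: float = 0.05
    drug: Optional[DrugEffect] = None
    seed: int = 0

    def cell_params(self, electrode_id: int, with_drug: bool = True) -> APParams:
        """Baseline (and optionally drug-modified) AP parameters of one cell."""
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, electrode_id]))
        params = self.ap
        if self.cell_sd > 0:
            for _ in range(1000):
                try:
                    params = dataclasses.replace(
                        self.ap,
                        amplitude_mv=self.ap.amplitude_mv
                        * math.exp(rng.normal(0.0, self.cell_sd)),
                        apd90_ms=self.ap.apd90_ms * math.exp(rng.normal(0.0, self.cell_sd)),
                        t_dep_ms=self.ap.t_dep_ms * math.exp(rng.normal(0.0, self.cell_sd)),
                    )
                    break
                except ParameterError:
                    continue
        if with_drug and self.drug is not None:
            drug_rng = np.random.default_rng(
                np.random.SeedSequence([self.seed, electrode_id, 777])
            )
            params = apply_drug_effect(params, self.drug, drug_rng)
        return params

    def beat_schedule(self, duration_s: float, phase_idx: int = 0) -> BeatSchedule:
        """Shared (culture-wide) beat schedule for one measurement phase."""
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 99, phase_idx]))
        return schedule_beats(self.rate_bpm, self.cv, duration_s, rng)
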