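"""Cell-electrode interface model: from membrane voltage to recorded traces.

Implements the phenomenological electroporation outcome model (logistic
success probability driven by delivered charge density and seal quality),
exponential pore resealing, linear extracellular/intracellular signal
mixing, post-stimulation amplifier offsets, noise and saturation, and the
assembly of full multichannel :class:`Recording` objects.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import ConfigurationError, MemoryGuardError, ParameterError
from .synth_cardiomyocyte import (
    APParams,
    CultureModel,
    make_ap_template,
    render_membrane_segment,
)

__all__ = [
    "ElectrodeState",
    "PorationEvent",
    "Recording",
    "PorationModel",
    "DEFAULT_PORATION_MODEL",
    "make_electrode_array",
    "assign_units",
    "select_electrodes",
    "simulate_poration_outcome",
    "pore_coupling",
    "expected_ap_amplitude_mv",
    "couple_to_electrode",
    "assemble_recording",
    "iter_recording_segments",
]

RngLike = Union[int, np.random.Generator, None]

N_STIM_UNITS = 32  #: on-chip stimulation/poration units


def _as_rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclasses.dataclass
class ElectrodeState:
    """Per-electrode coupling parameters.

    ``k_ec`` converts the membrane-voltage time derivative (mV/ms) into the
    recorded extracellular component (uV); ``k_ic`` is the ceiling of the
    intracellular coupling fraction; pore coupling itself is zero until a
    successful poration event and decays with ``tau_reseal_s``.
    """

    electrode_id: int
    x_um: float = 0.0
    y_um: float = 0.0
    seal_quality: float = 0.8
    k_ec: float = 12.0
    k_ic: float = 0.5
    tau_reseal_s: float = 900.0
    noise_sd_uv: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 < self.seal_quality <= 1.0):
            raise ParameterError("seal_quality must lie in (0, 1]")
        if self.tau_reseal_s <= 0:
            raise ParameterError("tau_reseal_s must be > 0")
        if self.noise_sd_uv < 0:
            raise ParameterError("noise_sd_uv must be >= 0")
        if not (0.0 < self.k_ic <= 1.0):
            raise ParameterError("k_ic must lie in (0, 1]")


@dataclasses.dataclass
class PorationEvent:
    """Outcome of delivering one pulse train to one electrode."""

    electrode_id: int
    t_end_s: float
    success: bool
    g0_realized: float
    offset_mv: float = 0.0
    offset_tau_s: float = 1.5

    def __post_init__(self) -> None:
        if not self.success and self.g0_realized != 0.0:
            raise ParameterError("g0_realized must be 0 for unsuccessful porations")
        if not (0.0 <= self.g0_realized <= 1.0):
            raise ParameterError("g0_realized must lie in [0, 1]")
        if self.offset_tau_s <= 0:
            raise ParameterError("offset_tau_s must be > 0")


@dataclasses.dataclass
class Recording:
    """Multichannel voltage recording plus acquisition metadata.

    ``signals`` is channels x samples in uV (float32); ``t0_s`` is the
    absolute start time of the first sample so that poration-event
    timestamps (absolute seconds) can be related to the trace.
    """

    signals: np.ndarray
    fs_hz: float
    t0_s: float = 0.0
    channel_meta: List[ElectrodeState] = dataclasses.field(default_factory=list)
    poration_events: List[PorationEvent] = dataclasses.field(default_factory=list)
    protocol_ref: str = ""
    extra: Dict[str, object] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals)
        if self.signals.ndim != 2:
            raise ParameterError("signals must be 2-D (channels x samples)")
        if self.fs_hz <= 0:
            raise ParameterError("fs_hz must be > 0")
        if not np.all(np.isfinite(self.signals)):
            raise ParameterError("signals must be finite")
        if self.channel_meta and len(self.channel_meta) != self.signals.shape[0]:
            raise ParameterError(
                f"channel_meta lists {len(self.channel_meta)} channels but the "
                f"signal array has {self.signals.shape[0]}"
            )

    @property
    def n_channels(self) -> int:
        return int(self.signals.shape[0])

    @property
    def duration_s(self) -> float:
        return self.signals.shape[1] / self.fs_hz

    def events_for(self, electrode_id: int) -> List[PorationEvent]:
        return [e for e in self.poration_events if e.electrode_id == electrode_id]


@dataclasses.dataclass(frozen=True)
class PorationModel:
    """Constants of the stochastic electroporation-outcome model.

    Success probability: p = expit(a0 + a1*ln(1 + Q/Q_ref) + a2*seal) with
    charge proxy Q = V_eff * t_phase * n_pulses / area, where the effective
    amplitude V_eff = Vpp / (1 + c_load*(n_on_unit - 1)) models slew-rate
    loss from capacitive loading of a shared stimulation unit. On success
    the initial pore-coupling fraction is
    g0 = clip(g_max * (Q/Q_ref)^gamma * seal * jitter, 0, 1].

    Q_ref is Q for the optimized protocol (1 Vpp, 200 us phase, 25,000
    pulses) on an unloaded 12.6 um^2 circular electrode. Constants are
    chosen to reproduce qualitative orderings (yield vs pulse count,
    routing strategy and electrode count), not fitted to data.
    """

    a0: float = -6.0
    a1: float = 9.0
    a2: float = 3.0
    c_load: float = 0.05
    g_max: float = 0.3
    gamma: float = 0.5
    q_ref: float = 1.0 * 200e-6 * 25000 / 12.566370614359172
    g_jitter_sd: float = 0.4
    offset_mv: float = 20.0
    offset_tau_s: float = 1.5
    v_sat_uv: float = 50_000.0


DEFAULT_PORATION_MODEL = PorationModel()


def make_electrode_array(
    n_rows: int = 32,
    n_cols: int = 64,
    pitch_um: float = 17.5,
    seed: RngLike = None,
    seal_base: float = 0.55,
    seal_bump: float = 0.35,
    seal_noise: float = 0.05,
    noise_sd_uv: float = 10.0,
    k_ec: float = 12.0,
    k_ic: float = 0.5,
    tau_reseal_s: float = 900.0,
) -> List[ElectrodeState]:
    """Create a grid of electrodes with a spatially correlated seal field.

    Seal quality combines a smooth Gaussian "hot spot" (mimicking regions
    of well-attached cells, where extracellular amplitudes are large) with
    i.i.d. jitter. Electrodes in the hot spot are what an amplitude-based
    selection strategy would pick, and they concentrate on few stimulation
    units.
    """
    rng = _as_rng(seed)
    cx = rng.uniform(0.2, 0.8) * (n_cols - 1) * pitch_um
    cy = rng.uniform(0.2, 0.8) * (n_rows - 1) * pitch_um
    sx = 0.08 * n_cols * pitch_um
    sy = 0.25 * n_rows * pitch_um
    states: List[ElectrodeState] = []
    eid = 0
    for row in range(n_rows):
        for col in range(n_cols):
            x = col * pitch_um
            y = row * pitch_um
            bump = math.exp(-0.5 * (((x - cx) / sx) ** 2 + ((y - cy) / sy) ** 2))
            seal = seal_base + seal_bump * bump + rng.normal(0.0, seal_noise)
            states.append(
                ElectrodeState(
                    electrode_id=eid,
                    x_um=x,
                    y_um=y,
                    seal_quality=float(np.clip(seal, 0.05, 1.0)),
                    k_ec=k_ec,
                    k_ic=k_ic,
                    tau_reseal_s=tau_reseal_s,
                    noise_sd_uv=noise_sd_uv,
                )
            )
            eid += 1
    return states


def assign_units(
    states: Sequence[ElectrodeState], n_units: int = N_STIM_UNITS
) -> Dict[int, int]:
    """Map electrodes to stimulation units by spatial (column) block.

    Mirrors a switch-matrix routing in which neighbouring columns share a
    unit, so spatially clustered electrode selections load few units.
    """
    xs = sorted({s.x_um for s in states})
    width = (xs[-1] - xs[0]) + 1e-9 if len(xs) > 1 else 1.0
    routing = {}
    for s in states:
        unit = int((s.x_um - xs[0]) / width * n_units)
        routing[s.electrode_id] = min(unit, n_units - 1)
    return routing


def select_electrodes(
    states: Sequence[ElectrodeState],
    n: int,
    strategy: str,
    seed: RngLike = None,
) -> List[int]:
    """Pick ``n`` poration electrodes.

    ``"high_amp"`` takes the top-n by seal quality (the proxy for
    extracellular signal amplitude); ``"random"`` samples uniformly.
    """
    if n > len(states):
        raise ConfigurationError(f"cannot select {n} of {len(states)} electrodes")
    if strategy == "high_amp":
        ranked = sorted(states, key=lambda s: s.seal_quality, reverse=True)
        return [s.electrode_id for s in ranked[:n]]
    if strategy == "random":
        rng = _as_rng(seed)
        idx = rng.choice(len(states), size=n, replace=False)
        return [states[i].electrode_id for i in sorted(idx)]
    raise ConfigurationError(f"unknown selection strategy {strategy!r}")


def simulate_poration_outcome(
    protocol,
    states: Mapping[int, ElectrodeState] | Sequence[ElectrodeState],
    routing: Mapping[int, int],
    seed: RngLike = None,
    t_end_s: float = 0.0,
    model: PorationModel = DEFAULT_PORATION_MODEL,
) -> List[PorationEvent]:
    """Draw the stochastic outcome of one pulse-train delivery.

    Parameters
    ----------
    protocol : :class:`~cardiopore.study_stats.PorationProtocol`
        Pulse-train description including the stimulated electrode ids.
    states : electrode states, by id or as a sequence.
    routing : electrode id -> stimulation unit (0..31).
    t_end_s : absolute end time of the pulse train.
    """
    if not isinstance(states, Mapping):
        states = {s.electrode_id: s for s in states}
    rng = _as_rng(seed)
    loads: Dict[int, int] = {}
    for eid in protocol.electrode_ids:
        if eid not in routing:
            raise ConfigurationError(f"electrode {eid} has no stimulation-unit routing")
        loads[routing[eid]] = loads.get(routing[eid], 0) + 1

    events: List[PorationEvent] = []
    for eid in protocol.electrode_ids:
        state = states.get(eid)
        if state is None:
            raise ConfigurationError(f"electrode {eid} in protocol has no ElectrodeState")
        n_on_unit = loads[routing[eid]]
        v_eff = protocol.vpp_v / (1.0 + model.c_load * (n_on_unit - 1))
        q = v_eff * protocol.phase_us * 1e-6 * protocol.n_pulses / protocol.electrode_area_um2
        q_rel = q / model.q_ref
        logit = model.a0 + model.a1 * math.log1p(q_rel) + model.a2 * state.seal_quality
        p = 1.0 / (1.0 + math.exp(-logit))
        success = bool(rng.random() < p)
        if success:
            jitter = math.exp(rng.normal(0.0, model.g_jitter_sd)) if model.g_jitter_sd else 1.0
            g0 = model.g_max * q_rel**model.gamma * state.seal_quality * jitter
            g0 = float(np.clip(g0, 1e-6, 1.0))
        else:
            g0 = 0.0
        events.append(
            PorationEvent(
                electrode_id=eid,
                t_end_s=t_end_s,
                success=success,
                g0_realized=g0,
                offset_mv=model.offset_mv,
                offset_tau_s=model.offset_tau_s,
            )
        )
    return events


def poration_success_probability(
    protocol,
    state: ElectrodeState,
    n_on_unit: int = 1,
    model: PorationModel = DEFAULT_PORATION_MODEL,
) -> float:
    """Deterministic success probability for one electrode (test hook)."""
    v_eff = protocol.vpp_v / (1.0 + model.c_load * (n_on_unit - 1))
    q = v_eff * protocol.phase_us * 1e-6 * protocol.n_pulses / protocol.electrode_area_um2
    logit = model.a0 + model.a1 * math.log1p(q / model.q_ref) + model.a2 * state.seal_quality
    return 1.0 / (1.0 + math.exp(-logit))


def pore_coupling(
    t_s: Union[float, np.ndarray],
    state: ElectrodeState,
    events: Iterable[PorationEvent],
) -> Union[float, np.ndarray]:
    """Pore-coupling fraction g(t) in [0, 1].

    Sum over past successful events of g0 * exp(-(t - t_end)/tau_reseal),
    clipped at 1; continuous and non-increasing between events.
    """
    t = np.asarray(t_s, dtype=float)
    g = np.zeros_like(t)
    for ev in events:
        if not ev.success:
            continue
        dt = t - ev.t_end_s
        g = g + np.where(dt >= 0, ev.g0_realized * np.exp(-np.maximum(dt, 0) / state.tau_reseal_s), 0.0)
    g = np.clip(g, 0.0, 1.0)
    return float(g) if np.isscalar(t_s) else g


def expected_ap_amplitude_mv(
    state: ElectrodeState,
    events: Iterable[PorationEvent],
    t_s: float,
    membrane_amplitude_mv: float,
) -> float:
    """Noise-free intracellular-like AP amplitude at measurement time ``t_s``."""
    g = pore_coupling(t_s, state, events)
    return float(g * state.k_ic * membrane_amplitude_mv)


def _offset_uv(t_s: np.ndarray, events: Iterable[PorationEvent]) -> np.ndarray:
    off = np.zeros_like(t_s)
    for ev in events:
        if ev.offset_mv == 0:
            continue
        dt = t_s - ev.t_end_s
        off = off + np.where(
            dt >= 0, 1000.0 * ev.offset_mv * np.exp(-np.maximum(dt, 0) / ev.offset_tau_s), 0.0
        )
    return off


def couple_to_electrode(
    membrane_mv: np.ndarray,
    state: ElectrodeState,
    events: Iterable[PorationEvent],
    fs_hz: float,
    seed: RngLike = None,
    t0_s: float = 0.0,
    v_sat_uv: float = DEFAULT_PORATION_MODEL.v_sat_uv,
) -> np.ndarray:
    """Convert a membrane trace (mV) into the recorded trace (uV).

    y(t) = 1000*g(t)*k_ic*V(t) + k_ec*dV/dt(t) + offset(t) + noise, clipped
    at +-v_sat. The derivative (central differences) carries the
    extracellular field-potential component; the g-scaled term carries the
    intracellular-like component after poration.
    """
    v = np.asarray(membrane_mv, dtype=float)
    if v.ndim != 1:
        raise ParameterError("membrane trace must be 1-D")
    n = v.size
    t = t0_s + np.arange(n) / fs_hz
    g = pore_coupling(t, state, list(events))
    dvdt = np.gradient(v, 1000.0 / fs_hz)  # mV per ms, central differences
    y = 1000.0 * g * state.k_ic * v + state.k_ec * dvdt + _offset_uv(t, events)
    if state.noise_sd_uv > 0:
        y = y + _as_rng(seed).normal(0.0, state.noise_sd_uv, size=n)
    return np.clip(y, -v_sat_uv, v_sat_uv)


def _channel_noise_rng(seed: int, electrode_id: int, segment: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, electrode_id, segment]))


def _render_channel_segment(
    state: ElectrodeState,
    params: APParams,
    onsets_s: np.ndarray,
    events: List[PorationEvent],
    fs_hz: float,
    t_local_start_s: float,
    t_abs_start_s: float,
    n_samples: int,
    noise_rng: Optional[np.random.Generator],
    v_sat_uv: float,
) -> np.ndarray:
    # beat onsets are recording-local; poration events are absolute time.
    # one-sample halo so the central-difference derivative is exact at edges
    halo_start = t_local_start_s - 1.0 / fs_hz
    v = render_membrane_segment(params, onsets_s, fs_hz, halo_start, n_samples + 2)
    t = t_abs_start_s + np.arange(n_samples) / fs_hz
    g = pore_coupling(t, state, events)
    dvdt = np.gradient(v, 1000.0 / fs_hz)[1:-1]
    y = 1000.0 * g * state.k_ic * v[1:-1] + state.k_ec * dvdt + _offset_uv(t, events)
    if state.noise_sd_uv > 0 and noise_rng is not None:
        y = y + noise_rng.normal(0.0, state.noise_sd_uv, size=n_samples)
    return np.clip(y, -v_sat_uv, v_sat_uv)


def assemble_recording(
    culture: CultureModel,
    states: Sequence[ElectrodeState],
    protocol_ref: str,
    events: Sequence[PorationEvent],
    duration_s: float,
    fs_hz: float,
    seed: int = 0,
    t0_s: float = 0.0,
    max_elements: float = 2.5e8,
    v_sat_uv: float = DEFAULT_PORATION_MODEL.v_sat_uv,
    segment_s: float = 30.0,
    asynchronous_ids: Sequence[int] = (),
    phase_idx: int = 0,
) -> Tuple[Recording, Dict[int, APParams]]:
    """Assemble a full multichannel Recording.

    One shared beat schedule drives all channels (synchronous culture);
    channels listed in ``asynchronous_ids`` get an independent schedule.
    Generation proceeds segment-wise so memory stays bounded and results
    are identical to :func:`iter_recording_segments` output. Returns the
    recording plus the per-electrode ground-truth AP parameters.

    Raises :class:`MemoryGuardError` if channels x samples exceeds
    ``max_elements``.
    """
    n_samples = int(round(duration_s * fs_hz))
    if len(states) * n_samples > max_elements:
        raise MemoryGuardError(
            f"{len(states)} channels x {n_samples} samples exceeds the cap of "
            f"{int(max_elements)} elements; lower duration/fs or raise max_elements"
        )
    for ev in events:
        if ev.t_end_s > t0_s + duration_s:
            raise ConfigurationError("poration event lies beyond the recording window")

    shared = culture.beat_schedule(duration_s, phase_idx=phase_idx)
    signals = np.empty((len(states), n_samples), dtype=np.float32)
    truth: Dict[int, APParams] = {}
    events_by_id: Dict[int, List[PorationEvent]] = {}
    for ev in events:
        events_by_id.setdefault(ev.electrode_id, []).append(ev)

    seg_len = max(1, int(round(segment_s * fs_hz)))
    for ci, state in enumerate(states):
        params = culture.cell_params(state.electrode_id)
        truth[state.electrode_id] = params
        if state.electrode_id in asynchronous_ids:
            rng = np.random.default_rng(
                np.random.SeedSequence([culture.seed, 55, state.electrode_id, phase_idx])
            )
            from .synth_cardiomyocyte import schedule_beats

            onsets = schedule_beats(culture.rate_bpm, max(culture.cv, 0.2), duration_s, rng).onset_times_s
        else:
            onsets = shared.onset_times_s
        ch_events = events_by_id.get(state.electrode_id, [])
        for seg_idx, lo in enumerate(range(0, n_samples, seg_len)):
            hi = min(lo + seg_len, n_samples)
            noise_rng = _channel_noise_rng(seed, state.electrode_id, seg_idx)
            signals[ci, lo:hi] = _render_channel_segment(
                state,
                params,
                onsets,
                ch_events,
                fs_hz,
                lo / fs_hz,
                t0_s + lo / fs_hz,
                hi - lo,
                noise_rng,
                v_sat_uv,
            )

    # beat onsets are recording-local; store absolute for provenance
    rec = Recording(
        signals=signals,
        fs_hz=fs_hz,
        t0_s=t0_s,
        channel_meta=list(states),
        poration_events=list(events),
        protocol_ref=protocol_ref,
        extra={"beat_onsets_s": shared.onset_times_s + t0_s, "phase_idx": phase_idx},
    )
    return rec, truth


def iter_recording_segments(
    culture: CultureModel,
    states: Sequence[ElectrodeState],
    protocol_ref: str,
    events: Sequence[PorationEvent],
    duration_s: float,
    fs_hz: float,
    seed: int = 0,
    t0_s: float = 0.0,
    segment_s: float = 30.0,
    v_sat_uv: float = DEFAULT_PORATION_MODEL.v_sat_uv,
    phase_idx: int = 0,
) -> Iterator[Recording]:
    """Stream a long recording as consecutive Recording segments.

    Concatenating the yielded segment signals reproduces, sample for
    sample, what :func:`assemble_recording` produces with the same seed.
    """
    n_samples = int(round(duration_s * fs_hz))
    seg_len = max(1, int(round(segment_s * fs_hz)))
    shared = culture.beat_schedule(duration_s, phase_idx=phase_idx)
    params_by_id = {s.electrode_id: culture.cell_params(s.electrode_id) for s in states}
    events_by_id: Dict[int, List[PorationEvent]] = {}
    for ev in events:
        events_by_id.setdefault(ev.electrode_id, []).append(ev)

    for seg_idx, lo in enumerate(range(0, n_samples, seg_len)):
        hi = min(lo + seg_len, n_samples)
        sig = np.empty((len(states), hi - lo), dtype=np.float32)
        for ci, state in enumerate(states):
            noise_rng = _channel_noise_rng(seed, state.electrode_id, seg_idx)
            sig[ci] = _render_channel_segment(
                state,
                params_by_id[state.electrode_id],
                shared.onset_times_s,
                events_by_id.get(state.electrode_id, []),
                fs_hz,
                lo / fs_hz,
                t0_s + lo / fs_hz,
                hi - lo,
                noise_rng,
                v_sat_uv,
            )
        yield Recording(
            signals=sig,
            fs_hz=fs_hz,
            t0_s=t0_s + lo / fs_hz,
            channel_meta=list(states),
            poration_events=list(events),
            protocol_ref=protocol_ref,
            extra={"segment_idx": seg_idx},
        )
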