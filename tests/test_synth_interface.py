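import dataclasses
import math

import numpy as np
import pytest

from cardiopore.errors import ConfigurationError, MemoryGuardError, ParameterError
from cardiopore.study_stats import PorationProtocol
from cardiopore.synth_cardiomyocyte import APParams, BeatSchedule, CultureModel, render_membrane_trace
from cardiopore.synth_interface import (
    DEFAULT_PORATION_MODEL,
    ElectrodeState,
    PorationEvent,
    Recording,
    assemble_recording,
    assign_units,
    couple_to_electrode,
    iter_recording_segments,
    make_electrode_array,
    poration_success_probability,
    pore_coupling,
    select_electrodes,
    simulate_poration_outcome,
)

FS = 20000.0


def protocol_for(ids, **kw):
    defaults = dict(vpp_v=1.0, phase_us=200.0, ipi_ms=1.0, n_pulses=25000)
    defaults.update(kw)
    return PorationProtocol(electrode_ids=tuple(ids), **defaults)


class TestElectrodeState:
    def test_invariants(self):
        with pytest.raises(ParameterError):
            ElectrodeState(0, seal_quality=0.0)
        with pytest.raises(ParameterError):
            ElectrodeState(0, tau_reseal_s=-1.0)
        with pytest.raises(ParameterError):
            ElectrodeState(0, noise_sd_uv=-1.0)

    def test_event_invariants(self):
        with pytest.raises(ParameterError):
            PorationEvent(0, 1.0, success=False, g0_realized=0.2)
        with pytest.raises(ParameterError):
            PorationEvent(0, 1.0, success=True, g0_realized=1.5)


class TestSimulatePorationOutcome:
    def setup_method(self):
        self.states = {
            i: ElectrodeState(i, x_um=i * 17.5, seal_quality=0.8) for i in range(20)
        }
        self.routing = {i: 0 for i in range(20)}

    def test_determinism_under_seed(self):
        prot = protocol_for(range(20))
        a = simulate_poration_outcome(prot, self.states, self.routing, seed=5)
        b = simulate_poration_outcome(prot, self.states, self.routing, seed=5)
        assert a == b

    def test_low_charge_low_probability(self):
        # with few pulses the charge proxy vanishes and p collapses toward
        # the logistic floor expit(a0 + a2*seal)
        state = ElectrodeState(0, seal_quality=0.3)
        prot = protocol_for([0], n_pulses=1)
        p = poration_success_probability(prot, state)
        assert p < 0.01

    def test_unit_loading_lowers_probability(self):
        state = ElectrodeState(0, seal_quality=0.8)
        prot = protocol_for([0])
        p1 = poration_success_probability(prot, state, n_on_unit=1)
        p16 = poration_success_probability(prot, state, n_on_unit=16)
        assert p16 < p1

    def test_monotone_in_drive_parameters(self):
        state = ElectrodeState(0, seal_quality=0.8)
        base = protocol_for([0])
        p0 = poration_success_probability(base, state)
        assert poration_success_probability(protocol_for([0], vpp_v=1.5), state) > p0
        assert poration_success_probability(protocol_for([0], phase_us=400.0), state) > p0
        assert poration_success_probability(protocol_for([0], n_pulses=50000), state) > p0
        bigger = protocol_for([0], electrode_area_um2=50.7)
        assert poration_success_probability(bigger, state) < p0

    def test_missing_state_raises(self):
        prot = protocol_for([99])
        with pytest.raises(ConfigurationError):
            simulate_poration_outcome(prot, self.states, {99: 0}, seed=0)

    def test_missing_routing_raises(self):
        prot = protocol_for([0])
        with pytest.raises(ConfigurationError):
            simulate_poration_outcome(prot, self.states, {}, seed=0)


class TestPoreCoupling:
    def test_no_events_zero(self, quiet_state):
        t = np.linspace(0, 100, 50)
        assert not np.any(pore_coupling(t, quiet_state, []))

    def test_exponential_decay(self):
        state = ElectrodeState(0, tau_reseal_s=600.0)
        ev = PorationEvent(0, t_end_s=0.0, success=True, g0_realized=0.5)
        g = pore_coupling(600.0, state, [ev])
        assert g == pytest.approx(0.5 / math.e, rel=1e-6)

    def test_superposition_of_events(self):
        state = ElectrodeState(0, tau_reseal_s=600.0)
        e1 = PorationEvent(0, t_end_s=0.0, success=True, g0_realized=0.3)
        e2 = PorationEvent(0, t_end_s=100.0, success=True, g0_realized=0.3)
        g_both = pore_coupling(150.0, state, [e1, e2])
        g_second = pore_coupling(150.0, state, [e2])
        assert g_both >= g_second

    def test_clipped_at_one(self):
        state = ElectrodeState(0)
        evs = [PorationEvent(0, 0.0, True, 1.0) for _ in range(3)]
        assert pore_coupling(1.0, state, evs) <= 1.0

    def test_failed_events_ignored(self, quiet_state):
        ev = PorationEvent(0, 0.0, success=False, g0_realized=0.0)
        assert pore_coupling(10.0, quiet_state, [ev]) == 0.0


class TestCoupleToElectrode:
    def test_constant_membrane_gives_offset_plus_noise(self):
        state = ElectrodeState(0, noise_sd_uv=0.0)
        v = np.full(int(FS), 0.0)
        y = couple_to_electrode(v, state, [], FS)
        assert not np.any(y)

    def test_intracellular_scaling(self, default_params):
        state = ElectrodeState(0, noise_sd_uv=0.0, k_ic=1.0)
        sched = BeatSchedule(np.array([0.5]), 30.0, 0.0)
        v = render_membrane_trace(default_params, sched, FS, 2.0)
        ev = PorationEvent(0, t_end_s=0.0, success=True, g0_realized=0.01)
        st = dataclasses.replace(state, tau_reseal_s=1e9)  # no decay over 2 s
        y = couple_to_electrode(v, st, [ev], FS)
        # 0.01 * 1.0 * 100 mV -> ~1 mV positive peak plus derivative overshoot
        assert y.max() == pytest.approx(1000.0, rel=0.35)

    def test_symmetric_pulse_derivative_integrates_to_zero(self):
        state = ElectrodeState(0, noise_sd_uv=0.0)
        v = np.zeros(int(FS))
        tri = np.concatenate([np.linspace(0, 1, 200), np.linspace(1, 0, 200)])
        v[1000:1400] = tri
        y = couple_to_electrode(v, state, [], FS)
        assert abs(np.sum(y[900:1500])) < 1e-6 * np.abs(y).max() * 600

    def test_saturation(self, default_params):
        state = ElectrodeState(0, noise_sd_uv=0.0, k_ic=1.0)
        sched = BeatSchedule(np.array([0.5]), 30.0, 0.0)
        v = render_membrane_trace(default_params, sched, FS, 2.0)
        ev = PorationEvent(0, 0.0, True, 1.0, offset_mv=100.0, offset_tau_s=10.0)
        y = couple_to_electrode(v, state, [ev], FS)
        assert np.abs(y).max() <= DEFAULT_PORATION_MODEL.v_sat_uv


class TestAssembleRecording:
    def test_shape(self, quiet_culture):
        states = [ElectrodeState(i, noise_sd_uv=0.0) for i in range(10)]
        rec, _ = assemble_recording(quiet_culture, states, "p", [], 30.0, FS, seed=0)
        assert rec.signals.shape == (10, 600000)

    def test_identical_states_identical_channels(self, quiet_culture):
        states = [ElectrodeState(i, noise_sd_uv=0.0) for i in range(4)]
        rec, _ = assemble_recording(quiet_culture, states, "p", [], 5.0, FS, seed=0)
        for ch in range(1, 4):
            np.testing.assert_array_equal(rec.signals[ch], rec.signals[0])

    def test_memory_guard(self, quiet_culture):
        states = [ElectrodeState(i) for i in range(10)]
        with pytest.raises(MemoryGuardError):
            assemble_recording(
                quiet_culture, states, "p", [], 30.0, FS, seed=0, max_elements=1e5
            )

    def test_event_outside_window_rejected(self, quiet_culture, quiet_state):
        ev = PorationEvent(0, t_end_s=99.0, success=True, g0_realized=0.2)
        with pytest.raises(ConfigurationError):
            assemble_recording(quiet_culture, [quiet_state], "p", [ev], 5.0, FS, seed=0)

    def test_amplitude_decay_after_poration(self, default_params):
        # per-beat positive peaks must not increase while the pore reseals
        culture = CultureModel(ap=default_params, cell_sd=0.0, cv=0.0, seed=1)
        state = ElectrodeState(0, noise_sd_uv=0.0, tau_reseal_s=60.0)
        ev = PorationEvent(0, t_end_s=1.0, success=True, g0_realized=0.3)
        rec, _ = assemble_recording(culture, [state], "p", [ev], 60.0, 4000.0, seed=0)
        sig = rec.signals[0]
        peaks = [
            sig[int(t * 4000) : int((t + 0.6) * 4000)].max()
            for t in np.arange(2.0, 58.0, 2.0)
        ]
        assert all(b <= a + 1e-3 for a, b in zip(peaks, peaks[1:]))

    def test_segmented_generation_matches_monolithic(self, quiet_culture):
        states = [ElectrodeState(i, noise_sd_uv=5.0) for i in range(3)]
        ev = PorationEvent(1, t_end_s=2.0, success=True, g0_realized=0.1)
        rec, _ = assemble_recording(
            quiet_culture, states, "p", [ev], 13.0, 4000.0, seed=3, segment_s=5.0
        )
        segs = list(
            iter_recording_segments(
                quiet_culture, states, "p", [ev], 13.0, 4000.0, seed=3, segment_s=5.0
            )
        )
        np.testing.assert_array_equal(
            np.concatenate([s.signals for s in segs], axis=1), rec.signals
        )

    def test_saturation_invariant(self, default_params):
        culture = CultureModel(ap=default_params, cell_sd=0.0, seed=2)
        state = ElectrodeState(0, noise_sd_uv=20.0)
        ev = PorationEvent(0, 1.0, True, 1.0, offset_mv=100.0, offset_tau_s=20.0)
        rec, _ = assemble_recording(culture, [state], "p", [ev], 10.0, 4000.0, seed=0)
        assert np.abs(rec.signals).max() <= DEFAULT_PORATION_MODEL.v_sat_uv


class TestRoutingAndSelection:
    def test_assign_units_spatial_blocks(self):
        states = make_electrode_array(n_rows=4, n_cols=64, seed=0)
        routing = assign_units(states)
        assert set(routing.values()) == set(range(32))
        # neighbouring columns share units
        by_x = {}
        for s in states:
            by_x.setdefault(s.x_um, set()).add(routing[s.electrode_id])
        assert all(len(v) == 1 for v in by_x.values())

    def test_high_amp_selection_prefers_seal(self):
        states = make_electrode_array(seed=4)
        top = select_electrodes(states, 50, "high_amp")
        chosen_seal = np.mean([s.seal_quality for s in states if s.electrode_id in set(top)])
        overall = np.mean([s.seal_quality for s in states])
        assert chosen_seal > overall

    def test_random_selection_deterministic(self):
        states = make_electrode_array(seed=4)
        a = select_electrodes(states, 50, "random", seed=1)
        b = select_electrodes(states, 50, "random", seed=1)
        assert a == b

    def test_high_amp_loads_fewer_units(self):
        states = make_electrode_array(seed=4)
        routing = assign_units(states)
        high = select_electrodes(states, 200, "high_amp")
        rand = select_electrodes(states, 200, "random", seed=0)
        n_units_high = len({routing[e] for e in high})
        n_units_rand = len({routing[e] for e in rand})
        assert n_units_high < n_units_rand

    def test_bad_strategy(self):
        states = make_electrode_array(n_rows=2, n_cols=4, seed=0)
        with pytest.raises(ConfigurationError):
            select_electrodes(states, 2, "bogus")


class TestRecordingInvariants:
    def test_rejects_nan(self):
        with pytest.raises(ParameterError):
            Recording(signals=np.array([[np.nan, 0.0]]), fs_hz=FS)

    def test_rejects_meta_mismatch(self):
        with pytest.raises(ParameterError):
            Recording(
                signals=np.zeros((2, 10)),
                fs_hz=FS,
                channel_meta=[ElectrodeState(0)],
            )
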