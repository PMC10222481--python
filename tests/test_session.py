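"""Session state machine: initialization → monitoring, notifications,
event plumbing and determinism."""

import pytest

from smartseat import (
    Direction,
    RawSample,
    ReadoutConfig,
    Session,
    SessionState,
    SessionUser,
    run_session,
)
from smartseat.errors import (
    ConnectionLostError,
    ContractError,
    InitializationError,
    StoreUnavailableError,
)
from smartseat.sensing import SENSOR_ORDER, format_frame
from smartseat.simulator import SimulationConfig, six_posture_protocol


def frames_for_forces(forces_per_tick, cfg):
    """Build exact RawSamples by forward-encoding given forces (no noise)."""
    from smartseat.sensing import force_to_conductance

    out = []
    for tick, forces in enumerate(forces_per_tick):
        counts = {}
        for s in SENSOR_ORDER:
            g = force_to_conductance(forces[s], cfg)
            v = cfg.supply_voltage * g / (cfg.ref_conductance + g)
            counts[s] = int(round(v / cfg.supply_voltage * cfg.adc_max))
        out.append(
            RawSample(tick_index=tick, timestamp=tick * cfg.sampling_interval, counts=counts)
        )
    return out


def symmetric_forces(n, lt=120.0, lb=80.0):
    return [{"Lt": lt, "Lb": lb, "Rt": lt, "Rb": lb} for _ in range(n)]


class RecordingNotifier:
    def __init__(self):
        self.calls = []

    def open_warning(self, message):
        self.calls.append("open")

    def close_warning(self):
        self.calls.append("close")


class TestInitialization:
    def test_reference_is_mean_of_five_constant_frames(self, cfg):
        frames = iter(frames_for_forces(symmetric_forces(10), cfg))
        session = Session(cfg)
        ref = session.run_initialization(frames)
        assert session.state is SessionState.MONITORING
        # quantization keeps decoded forces within one ADC quantum of truth
        assert ref.forces["Lt"] == pytest.approx(120.0, abs=0.6)
        assert ref.forces["Lb"] == pytest.approx(80.0, abs=0.6)
        assert ref.forces["Lt"] == pytest.approx(ref.forces["Rt"], abs=1e-12)
        # exactly queue_length frames consumed: 5 of 10 remain plus the rest
        assert len(list(frames)) == 5

    def test_stuck_sensor_fails_initialization_naming_it(self, cfg):
        forces = symmetric_forces(5)
        for f in forces:
            f["Rb"] = 0.0  # stuck at zero counts
        session = Session(cfg)
        with pytest.raises(InitializationError) as err:
            session.run_initialization(iter(frames_for_forces(forces, cfg)))
        assert err.value.sensors == ("Rb",)
        assert session.state is SessionState.INITIALIZATION
        assert session.sensor_status()["Rb"] is False

    def test_short_stream_is_connection_error(self, cfg):
        session = Session(cfg)
        with pytest.raises(ConnectionLostError):
            session.run_initialization(iter(frames_for_forces(symmetric_forces(3), cfg)))
        assert session.state is SessionState.INITIALIZATION

    def test_no_monitoring_before_initialization(self, cfg):
        session = Session(cfg)
        sample = frames_for_forces(symmetric_forces(1), cfg)[0]
        with pytest.raises(ContractError):
            session.monitoring_step(sample)

    def test_no_reinitialization_mid_session(self, cfg):
        session = Session(cfg)
        session.run_initialization(iter(frames_for_forces(symmetric_forces(5), cfg)))
        with pytest.raises(ContractError):
            session.run_initialization(iter(frames_for_forces(symmetric_forces(5), cfg)))


class TestMonitoring:
    def run(self, forces, cfg, notifier=None):
        frames = frames_for_forces(forces, cfg)
        return run_session(frames, cfg, notifier=notifier, session_id="t")

    def test_symmetric_stream_produces_no_events(self, cfg):
        notifier = RecordingNotifier()
        record = self.run(symmetric_forces(50), cfg, notifier)
        assert record.events == []
        assert notifier.calls == []

    def test_sustained_left_shift_flags_once_within_queue_transit(self, cfg):
        # 30% left shift starting at tick 20: top pair 156/84 instead of 120/120
        forces = symmetric_forces(20) + [
            {"Lt": 156.0, "Lb": 104.0, "Rt": 84.0, "Rb": 56.0} for _ in range(20)
        ]
        record = self.run(forces, cfg)
        asym = [e for e in record.events if e.direction is Direction.TO_ASYMMETRIC]
        assert len(asym) == 1
        assert 20 <= asym[0].tick_index < 25  # within 5 ticks (queue transit)

    def test_shift_and_return_open_then_close_warning(self, cfg):
        notifier = RecordingNotifier()
        forces = (
            symmetric_forces(10)
            + [{"Lt": 156.0, "Lb": 80.0, "Rt": 84.0, "Rb": 80.0} for _ in range(15)]
            + symmetric_forces(15)
        )
        record = self.run(forces, cfg, notifier)
        assert [e.direction for e in record.events] == [
            Direction.TO_ASYMMETRIC,
            Direction.TO_SYMMETRIC,
        ]
        assert notifier.calls == ["open", "close"]

    def test_notification_pairing_never_two_opens(self, cfg):
        notifier = RecordingNotifier()
        record = run_session(
            six_posture_protocol(SimulationConfig(seed=3, noise_fraction=0.0), cfg),
            cfg,
            notifier=notifier,
        )
        assert len(record.events) == 12
        for i, call in enumerate(notifier.calls):
            assert call == ("open" if i % 2 == 0 else "close")

    def test_frame_error_skips_tick_without_state_corruption(self, cfg):
        frames = frames_for_forces(symmetric_forces(20), cfg)
        lines = [format_frame(f) for f in frames]
        lines.insert(10, "garbage,line")
        record = run_session(lines, cfg)
        assert record.frame_errors == 1
        assert record.events == []

    def test_saturated_tick_is_skipped_and_counted(self, cfg):
        frames = frames_for_forces(symmetric_forces(20), cfg)
        bad = dict(frames[10].counts)
        bad["Lt"] = cfg.adc_max
        frames[10] = RawSample(
            tick_index=10, timestamp=5.0, counts=bad
        )
        record = run_session(frames, cfg)
        assert record.frame_errors == 1
        assert record.events == []

    def test_persistent_garbage_is_connection_loss(self, cfg):
        frames = frames_for_forces(symmetric_forces(6), cfg)
        lines = [format_frame(f) for f in frames] + ["x"] * 30
        with pytest.raises(ConnectionLostError):
            run_session(lines, cfg)

    def test_empty_source_is_connection_error(self, cfg):
        with pytest.raises(ConnectionLostError):
            run_session([], cfg)


class TestSessionRecord:
    def test_identical_streams_give_identical_records(self, cfg):
        frames = list(
            six_posture_protocol(SimulationConfig(seed=11), cfg)
        )
        a = run_session(list(frames), cfg, session_id="s")
        b = run_session(list(frames), cfg, session_id="s")
        assert a.events == b.events
        assert a.reference == b.reference
        assert (a.total_ticks, a.frame_errors, a.ended_at) == (
            b.total_ticks,
            b.frame_errors,
            b.ended_at,
        )

    def test_timestamps_derive_from_ticks(self, cfg):
        record = run_session(frames_for_forces(symmetric_forces(21), cfg), cfg)
        assert record.ended_at == pytest.approx(20 * cfg.sampling_interval)
        assert record.total_ticks == 21

    def test_duration_guard_stops_session(self, cfg):
        notifier = RecordingNotifier()
        record = run_session(
            frames_for_forces(symmetric_forces(40), cfg),
            cfg,
            notifier=notifier,
            max_duration_s=10.0,  # 20 ticks at 500 ms
        )
        assert record.total_ticks == 20
        assert notifier.calls == ["open"]  # "session expired" advisory

    def test_stop_signal_ends_monitoring(self, cfg):
        ticks_seen = []

        def stop():
            return len(ticks_seen) >= 3

        frames = frames_for_forces(symmetric_forces(30), cfg)

        def counting(frames):
            for f in frames:
                ticks_seen.append(f.tick_index)
                yield f

        record = run_session(counting(frames), cfg, stop=stop)
        assert record.total_ticks < 30


class FlakySink:
    def __init__(self):
        self.stored = []

    def append_event(self, event):
        raise StoreUnavailableError("db down")


class TestConsentAndSink:
    def protocol_record(self, cfg, user, sink):
        frames = six_posture_protocol(SimulationConfig(seed=5, noise_fraction=0.0), cfg)
        return run_session(frames, cfg, user=user, sink=sink, session_id="p")

    def test_consent_false_processes_but_does_not_persist(self, cfg):
        class CountingSink:
            def __init__(self):
                self.stored = []

            def append_event(self, event):
                self.stored.append(event)

        sink = CountingSink()
        user = SessionUser(user_id=1, consent=False)
        record = self.protocol_record(cfg, user, sink)
        assert len(record.events) == 12  # notifications/events still computed
        assert sink.stored == []

    def test_sink_failure_degrades_to_buffering(self, cfg):
        sink = FlakySink()
        user = SessionUser(user_id=1, consent=True)
        record = self.protocol_record(cfg, user, sink)
        assert len(record.buffered_events) == len(record.events) == 12
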