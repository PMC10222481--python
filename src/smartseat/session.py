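"""Two-state monitoring session: initialization → real-time monitoring.

A session starts in INITIALIZATION: the sitter holds the correct posture
while the first ``queue_length`` frames fill the per-sensor queues; the
resulting moving averages are stored as the per-session reference (a
self-calibration against sensor variability, temperature and humidity
drift).  The session then switches to MONITORING and never back: each
frame is decoded, filtered, normalized and run through the asymmetry
test; flag transitions open/close a warning through the notification
hook and are appended to the event sink.

Wall-clock time is derived (``tick * sampling_interval``) rather than
read from a clock, so sessions are replayable and deterministic.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Protocol

from .config import ReadoutConfig
from .detector import (
    Direction,
    PostureFlag,
    ReferenceProfile,
    ShiftEvent,
    asymmetry_flag,
    detect_transition,
    normalize,
)
from .errors import (
    ConnectionLostError,
    ContractError,
    CountRangeError,
    FrameError,
    InitializationError,
    SaturationError,
    StoreUnavailableError,
)
from .filtering import CircularQueue, push_and_filter
from .sensing import SENSOR_ORDER, RawSample, parse_frame, sample_to_readings

logger = logging.getLogger(__name__)

#: Advised maximum sitting stretch, seconds (soft session-duration guard).
DEFAULT_SESSION_LIMIT_S = 2 * 3600.0


class SessionState(enum.Enum):
    INITIALIZATION = "initialization"
    MONITORING = "monitoring"


class NotificationHook(Protocol):
    """Where a GUI pop-up would attach; bundled backends: console, no-op."""

    def open_warning(self, message: str) -> None: ...

    def close_warning(self) -> None: ...


class NullNotifier:
    def open_warning(self, message: str) -> None:
        pass

    def close_warning(self) -> None:
        pass


class ConsoleNotifier:
    """Prints a warning line on open and a clear line on close."""

    def __init__(self) -> None:
        self.open = False

    def open_warning(self, message: str) -> None:
        self.open = True
        print(f"[WARNING] {message}")

    def close_warning(self) -> None:
        if self.open:
            print("[ok] posture restored — warning closed")
        self.open = False


class EventSink(Protocol):
    """Minimal contract of the persistence layer used by a live session."""

    def append_event(self, event: ShiftEvent) -> None: ...


@dataclass(frozen=True)
class SessionUser:
    """The identity a session runs under; consent gates persistence."""

    user_id: int | None
    consent: bool


@dataclass
class SessionRecord:
    """Replayable summary of one monitoring session."""

    session_id: str
    user_id: int | None
    reference: ReferenceProfile | None
    started_at: float = 0.0
    ended_at: float = 0.0
    total_ticks: int = 0
    frame_errors: int = 0
    events: list[ShiftEvent] = field(default_factory=list)
    buffered_events: list[ShiftEvent] = field(default_factory=list)  # sink was down


class Session:
    """Session context: state machine + per-sensor queues + event plumbing."""

    def __init__(
        self,
        cfg: ReadoutConfig,
        user: SessionUser | None = None,
        notifier: NotificationHook | None = None,
        sink: EventSink | None = None,
        session_id: str = "session",
        frame_error_budget: int = 10,
    ):
        self.cfg = cfg
        self.user = user or SessionUser(user_id=None, consent=False)
        self.notifier = notifier or NullNotifier()
        self.sink = sink
        self.session_id = session_id
        self.frame_error_budget = frame_error_budget
        self.state = SessionState.INITIALIZATION
        self.reference: ReferenceProfile | None = None
        self.frame_errors = 0
        self.events: list[ShiftEvent] = []
        self.buffered_events: list[ShiftEvent] = []
        self.last_flag: PostureFlag | None = None
        self.last_tick: int = -1
        self.warning_open = False
        self._queues = {
            s: CircularQueue(cfg.queue_length, sensor=s) for s in SENSOR_ORDER
        }
        # per-sensor read-out health ("Sensors View" indicator logic)
        self._sensor_ok = {s: True for s in SENSOR_ORDER}

    # -- status ---------------------------------------------------------

    def sensor_status(self) -> dict[str, bool]:
        """Per-sensor health of the most recent read-out."""
        return dict(self._sensor_ok)

    # -- initialization ---------------------------------------------------

    def run_initialization(self, frames: Iterable[RawSample]) -> ReferenceProfile:
        """Consume exactly ``queue_length`` frames and store the reference.

        The sitter is assumed to hold the correct posture.  The reference
        is the per-sensor moving average at the moment the queue fills.
        """
        if self.state is not SessionState.INITIALIZATION:
            raise ContractError("session already initialized")
        filtered = {}
        consumed = 0
        for sample in frames:
            readings = sample_to_readings(sample, self.cfg)  # may raise, aborting init
            for sensor in SENSOR_ORDER:
                filtered[sensor] = push_and_filter(
                    self._queues[sensor], readings[sensor], self.cfg
                )
            self.last_tick = sample.tick_index
            consumed += 1
            if consumed == self.cfg.queue_length:
                break
        if consumed < self.cfg.queue_length:
            raise ConnectionLostError(
                f"stream ended after {consumed} frames; "
                f"{self.cfg.queue_length} needed for initialization"
            )
        reference = ReferenceProfile(
            forces={s: filtered[s].mean for s in SENSOR_ORDER},
            uncertainties={s: filtered[s].uncertainty for s in SENSOR_ORDER},
            created_at=self.last_tick * self.cfg.sampling_interval,
        )
        low = tuple(
            s
            for s in SENSOR_ORDER
            if reference.forces[s] < self.cfg.min_seated_force
        )
        if low:
            for s in low:
                self._sensor_ok[s] = False
            raise InitializationError(
                f"initialization failed: sensors {low} read below "
                f"{self.cfg.min_seated_force} N (user not seated or sensor fault)",
                sensors=low,
            )
        self.reference = reference
        self.state = SessionState.MONITORING
        logger.info("initialization complete at tick %d", self.last_tick)
        return reference

    # -- monitoring -------------------------------------------------------

    def monitoring_step(
        self, sample: RawSample
    ) -> tuple[PostureFlag | None, ShiftEvent | None]:
        """Process one frame in MONITORING; returns (flag, event-or-None).

        Decode errors (saturation, out-of-range counts) increment the
        frame-error counter and skip the tick, returning ``(None, None)``,
        without corrupting the session state.
        """
        if self.state is not SessionState.MONITORING or self.reference is None:
            raise ContractError("monitoring_step before initialization")
        try:
            readings = sample_to_readings(sample, self.cfg)
        except (SaturationError, CountRangeError) as exc:
            self.frame_errors += 1
            if exc.sensor is not None:
                self._sensor_ok[exc.sensor] = False
            logger.warning("tick %d skipped: %s", sample.tick_index, exc)
            return None, None
        normalized = {}
        for sensor in SENSOR_ORDER:
            self._sensor_ok[sensor] = True
            f = push_and_filter(self._queues[sensor], readings[sensor], self.cfg)
            normalized[sensor] = normalize(f, self.reference, self.cfg)
        flag = asymmetry_flag(
            normalized["Lt"], normalized["Lb"], normalized["Rt"], normalized["Rb"]
        )
        event = detect_transition(self.last_flag, flag, self.cfg.sampling_interval)
        self.last_flag = flag
        self.last_tick = sample.tick_index
        if event is not None:
            event = ShiftEvent(
                tick_index=event.tick_index,
                timestamp=event.timestamp,
                direction=event.direction,
                triggered_conditions=event.triggered_conditions,
                session_id=self.session_id,
                user_id=self.user.user_id,
            )
            self._dispatch(event)
        return flag, event

    def _dispatch(self, event: ShiftEvent) -> None:
        self.events.append(event)
        if event.direction is Direction.TO_ASYMMETRIC:
            self.warning_open = True
            self.notifier.open_warning(
                f"asymmetric posture detected at t={event.timestamp:.1f} s "
                f"({', '.join(sorted(event.triggered_conditions))})"
            )
        else:
            self.warning_open = False
            self.notifier.close_warning()
        if self.sink is not None and self.user.consent:
            try:
                self.sink.append_event(event)
            except StoreUnavailableError as exc:
                # mirror of the red "Database connection" indicator:
                # degrade to local buffering, warn, keep monitoring
                self.buffered_events.append(event)
                logger.warning("event sink unavailable, buffering: %s", exc)


def frames_from_lines(
    lines: Iterable[str], cfg: ReadoutConfig, session: Session
) -> Iterator[RawSample]:
    """Parse a line stream, counting malformed lines on the session.

    More than ``frame_error_budget`` consecutive bad lines means the link
    itself is broken and raises :class:`ConnectionLostError`.
    """
    streak = 0
    for line in lines:
        if not line.strip():
            continue
        try:
            sample = parse_frame(line, cfg)
        except FrameError as exc:
            session.frame_errors += 1
            streak += 1
            logger.warning("malformed frame skipped: %s", exc)
            if streak > session.frame_error_budget:
                raise ConnectionLostError(
                    f"{streak} consecutive malformed frames — link lost"
                ) from exc
            continue
        streak = 0
        yield sample


def run_session(
    source: Iterable[str] | Iterable[RawSample],
    cfg: ReadoutConfig,
    user: SessionUser | None = None,
    sink: EventSink | None = None,
    notifier: NotificationHook | None = None,
    session_id: str = "session",
    max_duration_s: float = DEFAULT_SESSION_LIMIT_S,
    stop: Callable[[], bool] | None = None,
) -> SessionRecord:
    """Run a full session over a frame source and return its record.

    ``source`` yields serial dialect lines or :class:`RawSample` directly.
    Stops on stream exhaustion, when ``stop()`` returns True, or when the
    soft duration guard (default 2 h of sitting) expires — prolonged
    sitting itself is what the device is meant to discourage.

    With ``user.consent`` false, events still drive live notifications
    but are not forwarded to the sink.
    """
    session = Session(
        cfg,
        user=user,
        notifier=notifier,
        sink=sink if (user is not None and user.consent) else None,
        session_id=session_id,
    )
    it = iter(source)
    # peek to decide whether the source yields dialect lines or RawSamples
    peek = next(it, None)
    if peek is None:
        raise ConnectionLostError("empty frame source")
    if isinstance(peek, str):
        frames: Iterator[RawSample] = frames_from_lines(
            _chain_one(peek, it), cfg, session
        )
    else:
        frames = _chain_one(peek, it)

    session.run_initialization(frames)
    max_ticks = int(max_duration_s / cfg.sampling_interval)
    expired = False
    for sample in frames:
        if stop is not None and stop():
            break
        if sample.tick_index >= max_ticks:
            expired = True
            break
        session.monitoring_step(sample)
    if expired:
        session.notifier.open_warning(
            "session duration limit reached — please stand up and re-initialize"
        )
    elif session.warning_open:
        session.notifier.close_warning()
    record = SessionRecord(
        session_id=session_id,
        user_id=session.user.user_id,
        reference=session.reference,
        started_at=0.0,
        ended_at=session.last_tick * cfg.sampling_interval,
        total_ticks=session.last_tick + 1,
        frame_errors=session.frame_errors,
        events=list(session.events),
        buffered_events=list(session.buffered_events),
    )
    if sink is not None and session.user.consent and hasattr(sink, "record_session"):
        try:
            sink.record_session(record)  # type: ignore[attr-defined]
        except StoreUnavailableError as exc:
            logger.warning("could not flush session record: %s", exc)
    return record


def _chain_one(first, rest) -> Iterator:
    yield first
    yield from rest
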