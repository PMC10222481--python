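"""Local event store: users, sessions and position-shift events.

A single SQLite file (or in-memory store) with a pluggable-sink contract
replaces the remote monitoring database; what matters here is the
recording semantics — explicit consent gating, strictly alternating
shift events per session, and the sitting-behaviour summaries (time in
balanced vs. unbalanced posture) that the event log supports.

Privacy posture: event queries return ``user_id`` only, never profile
fields; a user can revoke by deletion, which removes their events too.
"""

from __future__ import annotations

import csv
import json
import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

from .detector import Direction, ShiftEvent
from .errors import ConsentError, StoreIntegrityError, UnknownUserError
from .session import SessionRecord

MANDATORY_TAGS = ("name", "surname", "email", "height", "weight", "gender", "consent")


@dataclass(frozen=True)
class UserProfile:
    """The seven registration tags: identity, anthropometry, consent."""

    name: str
    surname: str
    email: str
    height: float  # cm
    weight: float  # kg
    gender: str
    consent: bool
    user_id: int | None = None
    registered_at: str = ""

    def __post_init__(self) -> None:
        for tag in ("name", "surname", "email", "gender"):
            if not getattr(self, tag):
                raise ValueError(f"mandatory profile tag {tag!r} is missing")
        if self.height <= 0 or self.weight <= 0:
            raise ValueError("height and weight must be > 0")
        if not isinstance(self.consent, bool):
            raise ValueError("consent must be an explicit boolean")


@dataclass(frozen=True)
class SessionSummary:
    session_id: str
    total_ticks: int
    asym_ticks: int
    shift_count: int

    @property
    def sym_ticks(self) -> int:
        return self.total_ticks - self.asym_ticks

    @property
    def asym_fraction(self) -> float:
        return self.asym_ticks / self.total_ticks if self.total_ticks else 0.0


@dataclass(frozen=True)
class BehaviorSummary:
    """Per-session and overall balanced/unbalanced sitting-time summary."""

    user_id: int
    sessions: tuple[SessionSummary, ...]
    height: float = 0.0
    weight: float = 0.0
    gender: str = ""

    @property
    def total_ticks(self) -> int:
        return sum(s.total_ticks for s in self.sessions)

    @property
    def asym_ticks(self) -> int:
        return sum(s.asym_ticks for s in self.sessions)

    @property
    def shift_count(self) -> int:
        return sum(s.shift_count for s in self.sessions)

    @property
    def asym_fraction(self) -> float:
        return self.asym_ticks / self.total_ticks if self.total_ticks else 0.0


_SCHEMA = """
CREATE TABLE IF NOT EXISTS users (
    user_id INTEGER PRIMARY KEY AUTOINCREMENT,
    name TEXT NOT NULL, surname TEXT NOT NULL,
    email TEXT NOT NULL UNIQUE,
    height REAL NOT NULL, weight REAL NOT NULL,
    gender TEXT NOT NULL, consent INTEGER NOT NULL,
    registered_at TEXT NOT NULL DEFAULT (datetime('now'))
);
CREATE TABLE IF NOT EXISTS sessions (
    session_id TEXT PRIMARY KEY,
    user_id INTEGER NOT NULL REFERENCES users(user_id) ON DELETE CASCADE,
    total_ticks INTEGER NOT NULL DEFAULT 0,
    started_at REAL NOT NULL DEFAULT 0.0,
    ended_at REAL NOT NULL DEFAULT 0.0,
    frame_errors INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE IF NOT EXISTS events (
    rowid_ INTEGER PRIMARY KEY AUTOINCREMENT,
    session_id TEXT NOT NULL,
    user_id INTEGER NOT NULL REFERENCES users(user_id) ON DELETE CASCADE,
    tick_index INTEGER NOT NULL,
    timestamp REAL NOT NULL,
    direction TEXT NOT NULL,
    triggered_conditions TEXT NOT NULL
);
"""


class EventStore:
    """SQLite-backed store fulfilling the session's event-sink contract."""

    def __init__(self, path: str | Path = ":memory:"):
        self.path = str(path)
        self._conn = sqlite3.connect(self.path)
        self._conn.execute("PRAGMA foreign_keys = ON")
        self._conn.executescript(_SCHEMA)
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()

    # -- users ----------------------------------------------------------

    def register_user(self, profile: UserProfile) -> int:
        """Persist a profile; idempotent on email (returns the existing id)."""
        row = self._conn.execute(
            "SELECT user_id FROM users WHERE email = ?", (profile.email,)
        ).fetchone()
        if row is not None:
            return int(row[0])
        cur = self._conn.execute(
            "INSERT INTO users (name, surname, email, height, weight, gender, consent)"
            " VALUES (?, ?, ?, ?, ?, ?, ?)",
            (
                profile.name,
                profile.surname,
                profile.email,
                profile.height,
                profile.weight,
                profile.gender,
                int(profile.consent),
            ),
        )
        self._conn.commit()
        return int(cur.lastrowid)

    def get_user(self, user_id: int) -> UserProfile:
        row = self._conn.execute(
            "SELECT name, surname, email, height, weight, gender, consent,"
            " user_id, registered_at FROM users WHERE user_id = ?",
            (user_id,),
        ).fetchone()
        if row is None:
            raise UnknownUserError(f"no user with id {user_id}")
        return UserProfile(
            name=row[0], surname=row[1], email=row[2], height=row[3],
            weight=row[4], gender=row[5], consent=bool(row[6]),
            user_id=row[7], registered_at=row[8],
        )

    def delete_user(self, user_id: int) -> None:
        """Consent revocation: remove the profile and all derived records."""
        self.get_user(user_id)  # raises if unknown
        self._conn.execute("DELETE FROM users WHERE user_id = ?", (user_id,))
        self._conn.commit()

    # -- events ----------------------------------------------------------

    def append_event(self, event: ShiftEvent) -> None:
        """Durable append; enforces consent and per-session alternation."""
        if event.user_id is None or event.session_id is None:
            raise ValueError("event must carry user_id and session_id")
        user = self.get_user(event.user_id)
        if not user.consent:
            raise ConsentError(
                f"user {event.user_id} has not consented to data recording"
            )
        last = self._conn.execute(
            "SELECT direction FROM events WHERE session_id = ?"
            " ORDER BY rowid_ DESC LIMIT 1",
            (event.session_id,),
        ).fetchone()
        expected = (
            Direction.TO_ASYMMETRIC.value
            if last is None or last[0] == Direction.TO_SYMMETRIC.value
            else Direction.TO_SYMMETRIC.value
        )
        if event.direction.value != expected:
            raise StoreIntegrityError(
                f"session {event.session_id}: expected {expected}, "
                f"got {event.direction.value} at tick {event.tick_index}"
            )
        self._conn.execute(
            "INSERT INTO events (session_id, user_id, tick_index, timestamp,"
            " direction, triggered_conditions) VALUES (?, ?, ?, ?, ?, ?)",
            (
                event.session_id,
                event.user_id,
                event.tick_index,
                event.timestamp,
                event.direction.value,
                ",".join(sorted(event.triggered_conditions)),
            ),
        )
        self._conn.commit()

    def record_session(self, record: SessionRecord) -> None:
        """Upsert the session row (total ticks, duration, frame errors)."""
        if record.user_id is None:
            raise ValueError("session record must carry a user_id")
        self._conn.execute(
            "INSERT INTO sessions (session_id, user_id, total_ticks, started_at,"
            " ended_at, frame_errors) VALUES (?, ?, ?, ?, ?, ?)"
            " ON CONFLICT(session_id) DO UPDATE SET total_ticks = excluded.total_ticks,"
            " ended_at = excluded.ended_at, frame_errors = excluded.frame_errors",
            (
                record.session_id,
                record.user_id,
                record.total_ticks,
                record.started_at,
                record.ended_at,
                record.frame_errors,
            ),
        )
        self._conn.commit()

    def events_for_session(self, session_id: str) -> list[ShiftEvent]:
        rows = self._conn.execute(
            "SELECT tick_index, timestamp, direction, triggered_conditions,"
            " session_id, user_id FROM events WHERE session_id = ? ORDER BY rowid_",
            (session_id,),
        ).fetchall()
        return [_row_to_event(r) for r in rows]

    def events_for_user(self, user_id: int) -> list[ShiftEvent]:
        rows = self._conn.execute(
            "SELECT tick_index, timestamp, direction, triggered_conditions,"
            " session_id, user_id FROM events WHERE user_id = ? ORDER BY rowid_",
            (user_id,),
        ).fetchall()
        return [_row_to_event(r) for r in rows]

    # -- summaries --------------------------------------------------------

    def behavior_summary(self, user_id: int) -> BehaviorSummary:
        """Balanced/unbalanced sitting time per session and overall.

        Asymmetric ticks are summed over ToAsymmetric→ToSymmetric spans;
        a span still open at session end is closed at the final tick.
        """
        user = self.get_user(user_id)
        session_rows = self._conn.execute(
            "SELECT session_id, total_ticks FROM sessions WHERE user_id = ?"
            " ORDER BY session_id",
            (user_id,),
        ).fetchall()
        summaries = []
        for session_id, total_ticks in session_rows:
            events = self.events_for_session(session_id)
            asym = 0
            open_tick: int | None = None
            shifts = 0
            for ev in events:
                if ev.direction is Direction.TO_ASYMMETRIC:
                    open_tick = ev.tick_index
                    shifts += 1
                elif open_tick is not None:
                    asym += ev.tick_index - open_tick
                    open_tick = None
            if open_tick is not None:
                asym += total_ticks - open_tick
            summaries.append(
                SessionSummary(
                    session_id=session_id,
                    total_ticks=total_ticks,
                    asym_ticks=asym,
                    shift_count=shifts,
                )
            )
        return BehaviorSummary(
            user_id=user_id,
            sessions=tuple(summaries),
            height=user.height,
            weight=user.weight,
            gender=user.gender,
        )

    def summaries_by_group(self, key: str) -> dict[str, list[BehaviorSummary]]:
        """Group all users' summaries by a profile attribute (e.g. gender)."""
        if key not in ("gender", "height", "weight"):
            raise ValueError(f"unsupported grouping key {key!r}")
        rows = self._conn.execute("SELECT user_id FROM users").fetchall()
        grouped: dict[str, list[BehaviorSummary]] = {}
        for (uid,) in rows:
            summary = self.behavior_summary(uid)
            group = str(getattr(self.get_user(uid), key))
            grouped.setdefault(group, []).append(summary)
        return grouped

    # -- exports ----------------------------------------------------------

    def export_events_jsonl(self, path: str | Path, user_id: int | None = None) -> int:
        """Write events as JSON-lines; returns the number of lines."""
        events = (
            self.events_for_user(user_id)
            if user_id is not None
            else [
                _row_to_event(r)
                for r in self._conn.execute(
                    "SELECT tick_index, timestamp, direction,"
                    " triggered_conditions, session_id, user_id"
                    " FROM events ORDER BY rowid_"
                ).fetchall()
            ]
        )
        with open(path, "w") as fh:
            for ev in events:
                fh.write(json.dumps(event_to_dict(ev)) + "\n")
        return len(events)

    def export_summary_csv(self, path: str | Path, user_id: int) -> None:
        summary = self.behavior_summary(user_id)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["user_id", "session_id", "total_ticks", "asym_ticks",
                 "shift_count", "asym_fraction"]
            )
            for s in summary.sessions:
                writer.writerow(
                    [user_id, s.session_id, s.total_ticks, s.asym_ticks,
                     s.shift_count, f"{s.asym_fraction:.6f}"]
                )


def event_to_dict(ev: ShiftEvent) -> dict:
    return {
        "session_id": ev.session_id,
        "user_id": ev.user_id,
        "tick_index": ev.tick_index,
        "timestamp": ev.timestamp,
        "direction": ev.direction.value,
        "triggered_conditions": sorted(ev.triggered_conditions),
    }


def event_from_dict(d: dict) -> ShiftEvent:
    return ShiftEvent(
        tick_index=d["tick_index"],
        timestamp=d["timestamp"],
        direction=Direction(d["direction"]),
        triggered_conditions=frozenset(d["triggered_conditions"]),
        session_id=d["session_id"],
        user_id=d["user_id"],
    )


def _row_to_event(row) -> ShiftEvent:
    conds = frozenset(c for c in row[3].split(",") if c)
    return ShiftEvent(
        tick_index=row[0],
        timestamp=row[1],
        direction=Direction(row[2]),
        triggered_conditions=conds,
        session_id=row[4],
        user_id=row[5],
    )


def iter_jsonl(path: str | Path) -> Iterator[ShiftEvent]:
    for line in Path(path).read_text().splitlines():
        if line.strip():
            yield event_from_dict(json.loads(line))
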