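"""Floor geometry, sensor-event data model, and the on-disk event-log format.

The sensing surface is a corridor of wooden tiles laid out as a 12 x 2
array, each tile 30 cm square and carrying 64 photo-interrupter sensors in
a uniform 8 x 8 grid.  A sensor is binary: it reports *pressed* while a
foot (or any obstacle) is within its detection range and *released*
otherwise, so the raw data stream is a sequence of state-change events.

Coordinate conventions
----------------------
* ``y_idx`` runs along the walking direction (the 12-tile axis, 96 sensor
  rows); ``x_idx`` runs laterally (the 2-tile axis, 16 sensor columns).
* The physical origin is the bottom-left corner of the floor; a sensor's
  physical position is the centre of its grid cell, ``(idx + 0.5) * pitch``.
* Contact intervals are half-open ``[press, release)``.
"""

from __future__ import annotations

import io
import os
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

PRESSED = "pressed"
RELEASED = "released"

_EVENT_LOG_MAGIC = "# floorgait-events v1"
_MANIFEST_MAGIC = "# floorgait-manifest v1"

#: Events still open at the end of a recording are closed this long after
#: the last observed event (truncated recordings happen at floor edges).
AUTO_CLOSE_EPS = 1e-3


class ValidationError(ValueError):
    """Raised when an event stream violates the alternating-state contract."""


@dataclass(frozen=True)
class FloorGeometry:
    """Dimensions of the sensing floor.

    Defaults describe a 3.6 m x 0.6 m corridor: 12 x 2 tiles of 30 cm with
    an 8 x 8 sensor grid per tile, i.e. 96 x 16 sensors at 3.75 cm pitch.
    """

    tiles_along_walk: int = 12
    tiles_across: int = 2
    tile_size: float = 30.0
    sensors_per_tile_side: int = 8

    def __post_init__(self) -> None:
        for name in ("tiles_along_walk", "tiles_across", "sensors_per_tile_side"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.tile_size <= 0:
            raise ValueError(f"tile_size must be positive, got {self.tile_size}")

    @property
    def pitch(self) -> float:
        """Centre-to-centre sensor spacing in cm."""
        return self.tile_size / self.sensors_per_tile_side

    @property
    def n_rows(self) -> int:
        """Sensor rows along the walking direction (y)."""
        return self.tiles_along_walk * self.sensors_per_tile_side

    @property
    def n_cols(self) -> int:
        """Sensor columns across the walking direction (x)."""
        return self.tiles_across * self.sensors_per_tile_side

    @property
    def length(self) -> float:
        """Floor extent along the walking direction in cm."""
        return self.tiles_along_walk * self.tile_size

    @property
    def width(self) -> float:
        """Floor extent across the walking direction in cm."""
        return self.tiles_across * self.tile_size


class SensorEvent(NamedTuple):
    time: float
    x_idx: int
    y_idx: int
    state: str  # PRESSED or RELEASED


def sensor_to_physical(geom: FloorGeometry, x_idx: int, y_idx: int) -> tuple[float, float]:
    """Physical centre ``(X, Y)`` in cm of sensor ``(x_idx, y_idx)``.

    Origin at the floor's bottom-left corner; X lateral, Y along the
    walking direction.
    """
    if not (0 <= x_idx < geom.n_cols):
        raise IndexError(f"x_idx {x_idx} outside [0, {geom.n_cols})")
    if not (0 <= y_idx < geom.n_rows):
        raise IndexError(f"y_idx {y_idx} outside [0, {geom.n_rows})")
    return (x_idx + 0.5) * geom.pitch, (y_idx + 0.5) * geom.pitch


@dataclass
class WalkSample:
    """Timestamped binary sensor events for one traversal of the floor."""

    sample_id: str
    events: list[SensorEvent] = field(default_factory=list)
    user_label: str | None = None
    n_auto_closed: int = 0

    def sorted(self) -> "WalkSample":
        return WalkSample(
            sample_id=self.sample_id,
            events=sorted(self.events, key=lambda e: (e.time, e.y_idx, e.x_idx)),
            user_label=self.user_label,
            n_auto_closed=self.n_auto_closed,
        )

    def validate(self, geom: FloorGeometry | None = None) -> None:
        """Check time ordering, index bounds and per-sensor state alternation."""
        last_time = -float("inf")
        state: dict[tuple[int, int], str] = {}
        for ev in self.events:
            if ev.time < 0:
                raise ValidationError(f"negative event time {ev.time}")
            if ev.time < last_time:
                raise ValidationError(f"events not sorted by time at t={ev.time}")
            last_time = ev.time
            if geom is not None:
                if not (0 <= ev.x_idx < geom.n_cols and 0 <= ev.y_idx < geom.n_rows):
                    raise ValidationError(
                        f"sensor ({ev.x_idx}, {ev.y_idx}) outside the "
                        f"{geom.n_cols} x {geom.n_rows} grid"
                    )
            key = (ev.x_idx, ev.y_idx)
            prev = state.get(key, RELEASED)
            if ev.state not in (PRESSED, RELEASED):
                raise ValidationError(f"unknown state {ev.state!r} at t={ev.time}")
            if ev.state == prev:
                raise ValidationError(
                    f"sensor ({ev.x_idx}, {ev.y_idx}) repeats state "
                    f"{ev.state!r} at t={ev.time}"
                )
            state[key] = ev.state


def pressed_intervals(
    sample: WalkSample,
) -> tuple[dict[tuple[int, int], list[tuple[float, float]]], int]:
    """Per-sensor list of half-open contact intervals ``[press, release)``.

    Contacts still open at the end of the recording are auto-closed at
    ``max event time + AUTO_CLOSE_EPS``; the count of such closures is
    returned alongside (they indicate a truncated recording).
    """
    intervals: dict[tuple[int, int], list[tuple[float, float]]] = {}
    open_press: dict[tuple[int, int], float] = {}
    t_max = 0.0
    for ev in sample.events:
        t_max = max(t_max, ev.time)
        key = (ev.x_idx, ev.y_idx)
        if ev.state == PRESSED:
            if key in open_press:
                raise ValidationError(
                    f"sensor {key} pressed twice without release at t={ev.time}"
                )
            open_press[key] = ev.time
        else:
            if key not in open_press:
                raise ValidationError(
                    f"sensor {key} released without a press at t={ev.time}"
                )
            intervals.setdefault(key, []).append((open_press.pop(key), ev.time))
    n_auto_closed = len(open_press)
    for key, press in open_press.items():
        intervals.setdefault(key, []).append((press, t_max + AUTO_CLOSE_EPS))
    for ivals in intervals.values():
        ivals.sort()
    return intervals, n_auto_closed


def sensor_state_at(sample: WalkSample, x_idx: int, y_idx: int, t: float) -> str:
    """State of one sensor at time ``t``: the last event at time <= t wins.

    A sensor with no event history is released.  Because intervals are
    half-open, a sensor queried exactly at its release time is released.
    """
    times = [ev.time for ev in sample.events if (ev.x_idx, ev.y_idx) == (x_idx, y_idx)]
    states = [ev.state for ev in sample.events if (ev.x_idx, ev.y_idx) == (x_idx, y_idx)]
    i = bisect_right(times, t)
    if i == 0:
        return RELEASED
    # Half-open convention: an event exactly at t takes effect at t, so a
    # release at t means released at t, and a press at t means pressed.
    return states[i - 1]


# ---------------------------------------------------------------------------
# Event-log text format
# ---------------------------------------------------------------------------

def write_event_log(sample: WalkSample, path: str | os.PathLike) -> None:
    """Write one walk to a plain-text event log (one event per line)."""
    with open(path, "w", encoding="utf-8") as fh:
        _write_event_log(sample, fh)


def _write_event_log(sample: WalkSample, fh: io.TextIOBase) -> None:
    fh.write(_EVENT_LOG_MAGIC + "\n")
    fh.write(f"# sample_id: {sample.sample_id}\n")
    if sample.user_label is not None:
        fh.write(f"# user_label: {sample.user_label}\n")
    for ev in sample.events:
        fh.write(f"{ev.time:.6f}\t{ev.x_idx}\t{ev.y_idx}\t{ev.state}\n")


def read_event_log(path: str | os.PathLike) -> WalkSample:
    """Read a walk from an event log, validating the alternation contract.

    Malformed lines are reported with their line number.
    """
    sample_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    user_label = None
    events: list[SensorEvent] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("sample_id:"):
                    sample_id = body.split(":", 1)[1].strip()
                elif body.startswith("user_label:"):
                    user_label = body.split(":", 1)[1].strip()
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValidationError(
                    f"{path}:{lineno}: expected 'time x_idx y_idx state', got {line!r}"
                )
            try:
                t = float(parts[0])
                x = int(parts[1])
                y = int(parts[2])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            if parts[3] not in (PRESSED, RELEASED):
                raise ValidationError(
                    f"{path}:{lineno}: unknown state {parts[3]!r}"
                )
            events.append(SensorEvent(t, x, y, parts[3]))
    sample = WalkSample(sample_id=sample_id, events=events, user_label=user_label)
    sample.validate()
    return sample


# ---------------------------------------------------------------------------
# Dataset manifest
# ---------------------------------------------------------------------------

def write_manifest(
    entries: Iterable[tuple[str, str, str]], path: str | os.PathLike
) -> None:
    """Write a manifest of (sample_id, event-log path, user label) rows."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_MANIFEST_MAGIC + "\n")
        fh.write("sample_id\tpath\tuser_label\n")
        for sample_id, rel_path, label in entries:
            fh.write(f"{sample_id}\t{rel_path}\t{label}\n")


def read_manifest(path: str | os.PathLike) -> list[tuple[str, str, str]]:
    entries = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("sample_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValidationError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
                )
            entries.append((parts[0], parts[1], parts[2]))
    return entries
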