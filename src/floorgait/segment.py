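"""Footstep segmentation and the 8 x 4 footprint model.

A walk's event stream is first reduced to per-sensor contact intervals,
then grouped into footsteps by spatio-temporal connected components: two
contacts belong to the same footstep iff their sensors are grid-adjacent
(8-neighbourhood) and their contact intervals overlap in time or are
separated by less than ``t_link``.  This separates the two feet during
double support — their stance intervals overlap in time but never in
grid space — while keeping a single rolling foot together even though
its heel sensors release before its toe sensors press.

Each footstep's *left footprint* (the static union of its sensors) is
summarised by an 8 x 4 footprint model: an axis-aligned window of 8 cells
along the walking direction by 4 cells across, anchored so the *seed
sensor* — the backmost (minimal-y, then minimal-x) sensor — sits in the
heel row.  Transitional frames sample the instantaneous pressed state of
the model's cells at a uniform interval from heel-strike.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .floor import FloorGeometry, WalkSample, pressed_intervals

logger = logging.getLogger(__name__)

#: Ceiling on a single footstep's duration, seconds. Stance times above it
#: are clipped when sampling transitional frames.
DEFAULT_T_MAX = 0.8


@dataclass(frozen=True)
class SegmentParams:
    """Tunables of the connected-component grouping."""

    t_link: float = 0.05  # s; max temporal gap between linked contacts
    min_sensors: int = 3  # components smaller than this are noise


@dataclass
class Footstep:
    """One foot contact: per-sensor press/release intervals."""

    step_index: int  # 1-based, ordered by heel-strike
    contacts: dict[tuple[int, int], tuple[float, float]]

    @property
    def fStart(self) -> float:
        """Heel-strike time: earliest press among the contacts."""
        return min(p for p, _ in self.contacts.values())

    @property
    def fEnd(self) -> float:
        """Toe-off time: latest release among the contacts."""
        return max(r for _, r in self.contacts.values())

    @property
    def n_sensors(self) -> int:
        return len(self.contacts)


@dataclass
class FootprintModel:
    """8 x 4 binary window anchored at the seed sensor.

    ``grid[i, j]`` is row ``i`` along the foot (0 = heel row, which
    contains the seed) and lateral cell ``j`` (low x to high x); the cell
    maps to sensor ``(x_start + j, y_start + i)``.
    """

    seed: tuple[int, int]
    x_start: int
    y_start: int
    grid: np.ndarray  # bool, shape (8, 4)
    n_clipped: int = 0

    @property
    def n_active(self) -> int:
        return int(self.grid.sum())

    def cell_sensor(self, i: int, j: int) -> tuple[int, int]:
        return (self.x_start + j, self.y_start + i)


@dataclass
class TransitionalFrames:
    """Uniformly sampled instantaneous footprint images of one footstep."""

    dt: float
    n_nominal: int
    frames: list[np.ndarray] = field(default_factory=list)  # each bool (8, 4)


def _contacts_overlap(
    a: tuple[float, float], b: tuple[float, float], t_link: float
) -> bool:
    """True iff the intervals overlap or the gap between them is < t_link."""
    gap = max(a[0], b[0]) - min(a[1], b[1])
    return gap < t_link


def segment_footsteps(
    sample: WalkSample,
    geom: FloorGeometry | None = None,
    params: SegmentParams | None = None,
) -> list[Footstep]:
    """Group a walk's contacts into footsteps.

    Returns footsteps ordered by heel-strike time and indexed 1..n.
    Components with fewer than ``params.min_sensors`` sensors are
    discarded as noise.  An empty result is returned (with a diagnostic
    log entry) when nothing survives.
    """
    params = params or SegmentParams()
    intervals, n_auto_closed = pressed_intervals(sample)
    if n_auto_closed:
        logger.warning(
            "sample %s: auto-closed %d open contacts at end of record",
            sample.sample_id,
            n_auto_closed,
        )
    # Flatten to a contact list: (x, y, press, release).
    contacts: list[tuple[int, int, float, float]] = []
    for (x, y), ivals in intervals.items():
        for press, release in ivals:
            contacts.append((x, y, press, release))
    n = len(contacts)
    if n == 0:
        logger.warning("sample %s: no contacts to segment", sample.sample_id)
        return []

    # Union-find over contacts, joining via the 8-neighbourhood buckets.
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    by_cell: dict[tuple[int, int], list[int]] = {}
    for idx, (x, y, _, _) in enumerate(contacts):
        by_cell.setdefault((x, y), []).append(idx)
    for idx, (x, y, press, release) in enumerate(contacts):
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for jdx in by_cell.get((x + dx, y + dy), ()):
                    if jdx <= idx:
                        continue
                    other = contacts[jdx]
                    if _contacts_overlap(
                        (press, release), (other[2], other[3]), params.t_link
                    ):
                        union(idx, jdx)

    groups: dict[int, list[int]] = {}
    for idx in range(n):
        groups.setdefault(find(idx), []).append(idx)

    footsteps: list[Footstep] = []
    for members in groups.values():
        merged: dict[tuple[int, int], tuple[float, float]] = {}
        for idx in members:
            x, y, press, release = contacts[idx]
            if (x, y) in merged:
                p0, r0 = merged[(x, y)]
                merged[(x, y)] = (min(p0, press), max(r0, release))
            else:
                merged[(x, y)] = (press, release)
        if len(merged) < params.min_sensors:
            continue
        footsteps.append(Footstep(step_index=0, contacts=merged))
    footsteps.sort(key=lambda f: f.fStart)
    for i, f in enumerate(footsteps, start=1):
        f.step_index = i
    if not footsteps:
        logger.warning(
            "sample %s: no footsteps survive the min_sensors=%d filter",
            sample.sample_id,
            params.min_sensors,
        )
    return footsteps


def find_seed(footstep: Footstep) -> tuple[int, int]:
    """The backmost sensor of a footprint: minimal y, tie broken by minimal x."""
    if not footstep.contacts:
        raise ValueError("cannot find the seed of an empty footstep")
    return min(footstep.contacts, key=lambda xy: (xy[1], xy[0]))


def fit_footprint_model(
    footstep: Footstep, geom: FloorGeometry | None = None
) -> FootprintModel:
    """Fit the 8 x 4 window to one footprint.

    The window is axis-aligned to the floor (foot angle shows up in the
    activation pattern, not in the window's orientation).  The seed fixes
    the heel row; laterally the window is centred on the mean x of the
    footprint's sensors and clamped on-floor.  Contacts falling outside
    the window are clipped and counted.
    """
    geom = geom or FloorGeometry()
    seed = find_seed(footstep)
    y_start = seed[1]
    mean_x = float(np.mean([x for x, _ in footstep.contacts]))
    x_start = int(round(mean_x - 1.5))
    x_start = max(0, min(geom.n_cols - 4, x_start))
    y_start = max(0, min(geom.n_rows - 8, y_start))
    grid = np.zeros((8, 4), dtype=bool)
    n_clipped = 0
    for x, y in footstep.contacts:
        i, j = y - y_start, x - x_start
        if 0 <= i < 8 and 0 <= j < 4:
            grid[i, j] = True
        else:
            n_clipped += 1
    if n_clipped:
        logger.warning(
            "footprint model clipped %d of %d contacts", n_clipped, len(footstep.contacts)
        )
    return FootprintModel(
        seed=seed, x_start=x_start, y_start=y_start, grid=grid, n_clipped=n_clipped
    )


def frame_count(t_max: float, dt: float) -> int:
    """Number of transitional frames: floor(t_max / dt).

    A tiny tolerance absorbs binary floating-point error so that exact
    divisions (e.g. 0.8 / 0.04) count as exact while genuinely fractional
    ratios still floor (0.8 / 0.06 -> 13).
    """
    if dt <= 0:
        raise ValueError(f"sampling time must be positive, got {dt}")
    if dt > t_max:
        raise ValueError(f"sampling time {dt} exceeds maximum stepping time {t_max}")
    return int(math.floor(t_max / dt + 1e-9))


def transitional_frames(
    footstep: Footstep,
    model: FootprintModel,
    dt: float,
    t_max: float = DEFAULT_T_MAX,
) -> TransitionalFrames:
    """Sample the model cells' instantaneous pressed state at a uniform dt.

    Frame ``k`` is the state at ``fStart + k * dt`` under the half-open
    contact convention (a cell is active iff press <= t < release).
    Frames after toe-off are all-inactive, so the result always has
    exactly ``frame_count(t_max, dt)`` frames — short footsteps are
    padded by physics, and footsteps longer than ``t_max`` are clipped
    with a warning.
    """
    n_nominal = frame_count(t_max, dt)
    f_start = footstep.fStart
    if footstep.fEnd - f_start > t_max:
        logger.warning(
            "footstep %d lasts %.3f s, beyond the %.2f s sampling horizon; clipped",
            footstep.step_index,
            footstep.fEnd - f_start,
            t_max,
        )
    frames = []
    for k in range(n_nominal):
        t = f_start + k * dt
        grid = np.zeros((8, 4), dtype=bool)
        for i in range(8):
            for j in range(4):
                ival = footstep.contacts.get(model.cell_sensor(i, j))
                if ival is not None and ival[0] <= t < ival[1]:
                    grid[i, j] = True
        frames.append(grid)
    return TransitionalFrames(dt=dt, n_nominal=n_nominal, frames=frames)
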