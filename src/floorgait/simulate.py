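"""Synthetic walking-data generator.

Produces timestamped binary sensor events with the statistical structure a
floor-sensor gait biometric assumes: each user has a stable individual
gait (step length, lateral placement, foot angle, stance/step timing, foot
dimensions, heel-to-toe rollover speed) around which individual walks vary.

The contact model is phenomenological, not biomechanical: a barefoot sole
is a heel disc plus a forefoot ellipse joined by a narrow midfoot band,
and during stance an active contact window (half a foot long) sweeps from
heel to toe over the first ``rollover_fraction`` of stance, so heel
sensors release before toe-off and toe sensors press after heel-strike.
A sensor emits one *pressed* event at its first cover time and one
*released* event at its last.

Reproducibility: one master seed; the profile of user ``u`` is drawn from
``SeedSequence((master_seed, 0, u))`` and walk ``s`` of user ``u`` from
``SeedSequence((master_seed, 1, u, s))``, so any sample can be regenerated
in isolation.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .floor import (
    FloorGeometry,
    SensorEvent,
    WalkSample,
    PRESSED,
    RELEASED,
    sensor_to_physical,
    write_event_log,
    write_manifest,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Trait:
    """Population description of one gait parameter.

    ``between_sd`` separates users (the biometric signal); ``within_sd``
    is walk-to-walk variation of the same user (the noise the classifier
    must see through).  ``lo``/``hi`` clamp drawn user means to the
    physically feasible range.
    """

    mean: float
    between_sd: float
    within_sd: float = 0.0
    lo: float = -math.inf
    hi: float = math.inf

    def draw_user_mean(self, rng: np.random.Generator) -> float:
        return float(np.clip(rng.normal(self.mean, self.between_sd), self.lo, self.hi))


@dataclass(frozen=True)
class PopulationConfig:
    """Cohort-level gait statistics the simulator emulates.

    Defaults describe a small barefoot adult cohort walking at a natural
    pace: ~65 cm steps, ~1.1 s stride time, stance comfortably under the
    0.8 s ceiling the stepping features assume.  The lateral half-
    separation floor (7.5 cm) keeps the two feet at least one empty
    sensor column apart so footsteps remain spatially separable at the
    3.75 cm sensor pitch.
    """

    step_length: Trait = Trait(65.0, 6.0, 2.0, lo=48.0, hi=78.0)
    lateral_offset: Trait = Trait(9.0, 1.0, 0.5, lo=7.5, hi=13.0)
    foot_angle: Trait = Trait(7.0, 3.0, 1.5, lo=0.0, hi=18.0)  # degrees, toe-out
    stance_time: Trait = Trait(0.55, 0.05, 0.02, lo=0.40, hi=0.70)  # s
    step_interval: Trait = Trait(0.55, 0.05, 0.02, lo=0.40, hi=0.80)  # s
    foot_length: Trait = Trait(25.5, 1.3, 0.0, lo=21.0, hi=29.5)  # cm
    foot_width: Trait = Trait(9.5, 0.6, 0.0, lo=7.5, hi=12.0)  # cm
    rollover_fraction: Trait = Trait(0.60, 0.06, 0.0, lo=0.35, hi=0.85)


@dataclass(frozen=True)
class NoiseConfig:
    """Sensor-level imperfections applied when rendering footsteps."""

    dropout: float = 0.02  # probability a covered sensor stays silent
    time_jitter_sd: float = 0.008  # s, Gaussian perturbation of event times

    @classmethod
    def none(cls) -> "NoiseConfig":
        return cls(dropout=0.0, time_jitter_sd=0.0)


@dataclass(frozen=True)
class GaitProfile:
    """One user's characteristic gait parameters."""

    user_id: str
    step_length_mean: float
    step_length_sd: float
    lateral_offset_mean: float
    lateral_offset_sd: float
    foot_angle_mean: float
    foot_angle_sd: float
    stance_time_mean: float
    stance_time_sd: float
    step_interval_mean: float
    step_interval_sd: float
    foot_length: float
    foot_width: float
    rollover_fraction: float

    def validate(self, geom: FloorGeometry) -> None:
        if self.foot_length > 8 * geom.pitch:
            raise ValueError(
                f"foot_length {self.foot_length} exceeds the 8-cell model window "
                f"({8 * geom.pitch} cm)"
            )
        if self.foot_width > 4 * geom.pitch:
            raise ValueError(
                f"foot_width {self.foot_width} exceeds the 4-cell model window "
                f"({4 * geom.pitch} cm)"
            )
        if self.stance_time_mean + 3 * self.stance_time_sd >= 0.8:
            raise ValueError("stance time distribution must stay below 0.8 s")


@dataclass(frozen=True)
class StepPlan:
    """Where and when one footstep lands.

    ``anchor`` is the physical heel point (cm); ``angle`` the toe-out
    angle in degrees, signed positive toward the foot's outer side.
    """

    step_index: int  # 1-based
    side: str  # "left" | "right"
    anchor: tuple[float, float]
    angle: float
    heel_strike: float
    toe_off: float


def sample_profile(
    config: PopulationConfig, user_id: str, rng_seed, geom: FloorGeometry | None = None
) -> GaitProfile:
    """Draw one user's gait profile from the population."""
    rng = np.random.default_rng(rng_seed)
    c = config
    profile = GaitProfile(
        user_id=user_id,
        step_length_mean=c.step_length.draw_user_mean(rng),
        step_length_sd=c.step_length.within_sd,
        lateral_offset_mean=c.lateral_offset.draw_user_mean(rng),
        lateral_offset_sd=c.lateral_offset.within_sd,
        foot_angle_mean=c.foot_angle.draw_user_mean(rng),
        foot_angle_sd=c.foot_angle.within_sd,
        stance_time_mean=c.stance_time.draw_user_mean(rng),
        stance_time_sd=c.stance_time.within_sd,
        step_interval_mean=c.step_interval.draw_user_mean(rng),
        step_interval_sd=c.step_interval.within_sd,
        foot_length=c.foot_length.draw_user_mean(rng),
        foot_width=c.foot_width.draw_user_mean(rng),
        rollover_fraction=c.rollover_fraction.draw_user_mean(rng),
    )
    if geom is not None:
        profile.validate(geom)
    return profile


def plan_steps(
    profile: GaitProfile,
    n_steps: int,
    rng_seed,
    geom: FloorGeometry | None = None,
    start_y: float = 12.0,
    start_time: float = 0.3,
) -> list[StepPlan]:
    """Plan footstep anchors and timing for one traversal.

    Longitudinal advance per step is Normal(step_length_mean, sd); lateral
    position alternates left/right of the centreline by the user's
    lateral offset; heel-strike times advance by step-interval draws and
    stance durations come from the stance-time draws.  Steps that would
    land beyond the floor are dropped with a warning.
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    geom = geom or FloorGeometry()
    rng = np.random.default_rng(rng_seed)
    centerline = geom.width / 2.0
    plans: list[StepPlan] = []
    y = start_y
    t = start_time
    for k in range(1, n_steps + 1):
        side = "left" if k % 2 == 1 else "right"
        sign = -1.0 if side == "left" else 1.0
        offset = rng.normal(profile.lateral_offset_mean, profile.lateral_offset_sd)
        x = centerline + sign * offset
        angle = rng.normal(profile.foot_angle_mean, profile.foot_angle_sd)
        stance = rng.normal(profile.stance_time_mean, profile.stance_time_sd)
        stance = float(np.clip(stance, 0.15, 0.79))
        if y + profile.foot_length > geom.length:
            logger.warning(
                "walk for %s truncated at step %d: heel y=%.1f cm exceeds floor",
                profile.user_id,
                k,
                y,
            )
            break
        plans.append(
            StepPlan(
                step_index=k,
                side=side,
                anchor=(float(x), float(y)),
                angle=float(angle),
                heel_strike=float(t),
                toe_off=float(t + stance),
            )
        )
        y += rng.normal(profile.step_length_mean, profile.step_length_sd)
        t += rng.normal(profile.step_interval_mean, profile.step_interval_sd)
    return plans


def _foot_frame(plan: StepPlan) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors (longitudinal heel->toe, lateral) of the planted foot.

    The toe-out angle rotates the foot axis away from the walking
    direction toward the foot's outer side (-X for a left foot, +X for a
    right foot).
    """
    sign = -1.0 if plan.side == "left" else 1.0
    a = math.radians(sign * plan.angle)
    u = np.array([math.sin(a), math.cos(a)])  # heel -> toe
    v = np.array([math.cos(a), -math.sin(a)])  # lateral
    return u, v


def _sole_mask(s: np.ndarray, w: np.ndarray, foot_length: float, foot_width: float) -> np.ndarray:
    """Which foot-frame points (s longitudinal, w lateral) the sole covers.

    Heel disc + forefoot ellipse + midfoot band; the band guarantees the
    printed footprint is spatially connected at sensor pitch.
    """
    half_w = foot_width / 2.0
    heel_r = half_w
    heel = (s - heel_r) ** 2 + w**2 <= heel_r**2
    fore_c = 0.72 * foot_length
    fore_a = 0.26 * foot_length
    fore = ((s - fore_c) / fore_a) ** 2 + (w / half_w) ** 2 <= 1.0
    mid = (s >= heel_r) & (s <= fore_c) & (np.abs(w) <= 0.62 * half_w)
    return heel | fore | mid


def render_footstep(
    geom: FloorGeometry,
    plan: StepPlan,
    profile: GaitProfile,
    noise: NoiseConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[SensorEvent]:
    """Render one planned footstep into press/release sensor events.

    Rollover: during ``[heel_strike, heel_strike + rollover_fraction *
    stance]`` a contact window of length ``foot_length / 2`` sweeps from
    the heel end to the toe end; afterwards it rests on the forefoot
    until toe-off.  Sensors whose longitudinal coordinate is in the rear
    half are therefore pressed at heel-strike, and sensors in the front
    half release exactly at toe-off.
    """
    noise = noise or NoiseConfig.none()
    rng = rng if rng is not None else np.random.default_rng(0)
    L = profile.foot_length
    stance = plan.toe_off - plan.heel_strike
    roll_dur = profile.rollover_fraction * stance

    # Candidate sensors: bounding box around the foot.
    ax, ay = plan.anchor
    pad = L + geom.pitch
    x_lo = max(0, int((ax - pad) / geom.pitch) - 1)
    x_hi = min(geom.n_cols - 1, int((ax + pad) / geom.pitch) + 1)
    y_lo = max(0, int((ay - pad) / geom.pitch) - 1)
    y_hi = min(geom.n_rows - 1, int((ay + pad) / geom.pitch) + 1)
    xs = np.arange(x_lo, x_hi + 1)
    ys = np.arange(y_lo, y_hi + 1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    px = (gx + 0.5) * geom.pitch - ax
    py = (gy + 0.5) * geom.pitch - ay
    u, v = _foot_frame(plan)
    s = px * u[0] + py * u[1]
    w = px * v[0] + py * v[1]
    covered = _sole_mask(s, w, L, profile.foot_width)

    events: list[SensorEvent] = []
    half = L / 2.0
    for xi, yi, si in zip(gx[covered], gy[covered], s[covered]):
        if noise.dropout > 0 and rng.random() < noise.dropout:
            continue
        si = float(np.clip(si, 0.0, L))
        # Window [c - L/4, c + L/4]; c runs L/4 -> 3L/4 over roll_dur.
        if si <= half:
            press = plan.heel_strike
        else:
            press = plan.heel_strike + ((si - half) / half) * roll_dur
        if si >= half:
            release = plan.toe_off
        else:
            release = plan.heel_strike + (si / half) * roll_dur
        release = max(release, press + 0.02)
        release = min(release, plan.toe_off)
        if noise.time_jitter_sd > 0:
            press += rng.normal(0.0, noise.time_jitter_sd)
            release += rng.normal(0.0, noise.time_jitter_sd)
            press = max(press, 0.0)
            release = max(release, press + 1e-3)
        events.append(SensorEvent(float(press), int(xi), int(yi), PRESSED))
        events.append(SensorEvent(float(release), int(xi), int(yi), RELEASED))
    if not events:
        logger.warning(
            "footstep %d of %s produced no sensor events", plan.step_index, profile.user_id
        )
    return events


def simulate_walk(
    geom: FloorGeometry,
    profile: GaitProfile,
    sample_id: str,
    rng_seed,
    n_steps: int = 6,
    noise: NoiseConfig | None = None,
) -> tuple[WalkSample, list[StepPlan]]:
    """Simulate one traversal: plan steps, render each, merge the events."""
    ss = np.random.SeedSequence(rng_seed) if not isinstance(
        rng_seed, np.random.SeedSequence
    ) else rng_seed
    plan_seed, render_seed = ss.spawn(2)
    plans = plan_steps(profile, n_steps, plan_seed, geom)
    rng = np.random.default_rng(render_seed)
    events: list[SensorEvent] = []
    for plan in plans:
        events.extend(render_footstep(geom, plan, profile, noise, rng))
    sample = WalkSample(
        sample_id=sample_id, events=events, user_label=profile.user_id
    ).sorted()
    return sample, plans


@dataclass
class SimulatedDataset:
    """In-memory cohort: samples with true labels plus per-user profiles."""

    samples: list[WalkSample]
    labels: list[str]
    profiles: dict[str, GaitProfile]
    manifest: list[tuple[str, str, str]] = field(default_factory=list)


def simulate_dataset(
    geom: FloorGeometry,
    n_users: int,
    samples_per_user: int,
    master_seed: int,
    population: PopulationConfig | None = None,
    noise: NoiseConfig | None = None,
    n_steps: int = 6,
    out_dir: str | os.PathLike | None = None,
) -> SimulatedDataset:
    """Simulate a full cohort; optionally write event logs and a manifest.

    Deterministic given ``master_seed``: user ``u``'s profile uses
    ``SeedSequence((master_seed, 0, u))`` and their walk ``s`` uses
    ``SeedSequence((master_seed, 1, u, s))``.
    """
    if n_users < 2:
        raise ValueError(f"n_users must be >= 2, got {n_users}")
    population = population or PopulationConfig()
    noise = noise if noise is not None else NoiseConfig()
    samples: list[WalkSample] = []
    labels: list[str] = []
    profiles: dict[str, GaitProfile] = {}
    manifest: list[tuple[str, str, str]] = []
    for u in range(n_users):
        user_id = f"user{u:02d}"
        profile = sample_profile(
            population, user_id, np.random.SeedSequence((master_seed, 0, u)), geom
        )
        profiles[user_id] = profile
        for s in range(samples_per_user):
            sample_id = f"{user_id}_walk{s:03d}"
            sample, _ = simulate_walk(
                geom,
                profile,
                sample_id,
                np.random.SeedSequence((master_seed, 1, u, s)),
                n_steps=n_steps,
                noise=noise,
            )
            samples.append(sample)
            labels.append(user_id)
            manifest.append((sample_id, f"{sample_id}.events", user_id))
    dataset = SimulatedDataset(samples, labels, profiles, manifest)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for sample, (sample_id, rel_path, _) in zip(samples, manifest):
            write_event_log(sample, os.path.join(out_dir, rel_path))
        write_manifest(manifest, os.path.join(out_dir, "manifest.tsv"))
    return dataset
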