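"""Walking and stepping feature vectors.

Two modalities are extracted from a segmented walk:

* **Walking pattern** — spatiotemporal variation *across* footsteps.
  Per footstep: the seed sensor's physical coordinates (FX, FY), the
  compensated footprint centre (com_FX, com_FY — the physical centroid of
  the active footprint-model cells, which blends stride length, lateral
  placement and foot angle into two numbers), the pressed-sensor count
  (nSensor), and heel-strike/toe-off times (fStart, fEnd).  A case id
  selects which features enter the classifier; sequences over the first
  five footsteps are concatenated feature-major, e.g.
  ``[com_FX_1 .. com_FX_5, com_FY_1 .. com_FY_5, ...]``.

* **Stepping pattern** — temporal variation *within* a footstep.  Each
  8 x 4 transitional frame is scanned heel row to toe row, low x to high
  x within a row, into 32 values of +1 (pressed) / -1 (released); the
  frames of each selected footstep are concatenated in time order, so a
  footstep contributes ``32 * frame_count(T_max, dt)`` inputs.

Walking features are min-max normalised to [-1, 1] with parameters frozen
on the training set; stepping vectors are already +/-1 and need none.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .floor import FloorGeometry, sensor_to_physical
from .segment import (
    DEFAULT_T_MAX,
    Footstep,
    FootprintModel,
    fit_footprint_model,
    frame_count,
    transitional_frames,
)

#: Walking feature-set cases: which per-footstep features feed the classifier.
WALKING_CASES: dict[int, tuple[str, ...]] = {
    1: ("FX", "FY"),
    2: ("com_FX", "com_FY"),
    3: ("com_FX", "com_FY", "nSensor"),
    4: ("com_FX", "com_FY", "fStart", "fEnd"),
    5: ("com_FX", "com_FY", "fStart", "fEnd", "nSensor"),
}

#: Stepping cases: which footsteps (1-based) contribute transitional frames.
STEPPING_CASES: dict[int, tuple[int, ...]] = {
    1: (1, 3),
    2: (2, 4),
    3: (1, 2),
    4: (1, 2, 3, 4),
}

#: Cells in the footprint model, and hence values per transitional frame.
MODEL_CELLS = 32

#: Number of footsteps a walking vector spans.
N_WALKING_STEPS = 5


class FeatureError(ValueError):
    """Raised when a sample cannot yield the requested feature vector."""


@dataclass(frozen=True)
class StepFeatures:
    """The seven walking features of a single footstep."""

    FX: float
    FY: float
    com_FX: float
    com_FY: float
    nSensor: int
    fStart: float
    fEnd: float


def step_features(
    footstep: Footstep, geom: FloorGeometry, model: FootprintModel | None = None
) -> StepFeatures:
    """Compute one footstep's walking features."""
    model = model or fit_footprint_model(footstep, geom)
    fx, fy = sensor_to_physical(geom, *model.seed)
    rows, cols = np.nonzero(model.grid)
    xs = [sensor_to_physical(geom, model.x_start + j, model.y_start + i) for i, j in zip(rows, cols)]
    com_fx = float(np.mean([p[0] for p in xs]))
    com_fy = float(np.mean([p[1] for p in xs]))
    return StepFeatures(
        FX=fx,
        FY=fy,
        com_FX=com_fx,
        com_FY=com_fy,
        nSensor=model.n_active,
        fStart=footstep.fStart,
        fEnd=footstep.fEnd,
    )


def walking_features(
    footsteps: list[Footstep],
    geom: FloorGeometry | None = None,
    n_steps: int = N_WALKING_STEPS,
    sample_id: str = "<sample>",
) -> list[StepFeatures]:
    """Walking features for the first ``n_steps`` footsteps of a walk."""
    geom = geom or FloorGeometry()
    if len(footsteps) < n_steps:
        raise FeatureError(
            f"sample {sample_id}: needs {n_steps} footsteps, found {len(footsteps)}"
        )
    return [step_features(f, geom) for f in footsteps[:n_steps]]


def build_walking_vector(
    features: list[StepFeatures], case_id: int, n_steps: int = N_WALKING_STEPS
) -> np.ndarray:
    """Assemble one walking feature vector (feature-major layout).

    Length is ``len(case features) * n_steps`` — 10/10/15/20/25 for cases
    1-5 at five steps.
    """
    if case_id not in WALKING_CASES:
        raise FeatureError(f"unknown walking case {case_id}; valid: 1-5")
    if len(features) < n_steps:
        raise FeatureError(f"need {n_steps} footsteps of features, got {len(features)}")
    values: list[float] = []
    for name in WALKING_CASES[case_id]:
        values.extend(float(getattr(f, name)) for f in features[:n_steps])
    return np.asarray(values, dtype=float)


# ---------------------------------------------------------------------------
# Min-max normalisation of walking vectors
# ---------------------------------------------------------------------------

@dataclass
class NormalizationParams:
    """Per-coordinate train-set min/max for mapping to [-1, 1]."""

    mins: np.ndarray
    maxs: np.ndarray
    n_clipped: int = 0  # test values outside the train range, clipped


def fit_normalization(X: np.ndarray) -> NormalizationParams:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise FeatureError("normalization requires at least 2 training vectors")
    return NormalizationParams(mins=X.min(axis=0), maxs=X.max(axis=0))


def apply_normalization(X: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Map each coordinate to [-1, 1]; constant coordinates map to 0.

    Values outside the training range are clipped and counted on
    ``params.n_clipped``.
    """
    X = np.asarray(X, dtype=float)
    span = params.maxs - params.mins
    safe = np.where(span > 0, span, 1.0)
    out = 2.0 * (X - params.mins) / safe - 1.0
    out = np.where(span > 0, out, 0.0)
    clipped = np.clip(out, -1.0, 1.0)
    params.n_clipped += int(np.sum(clipped != out))
    return clipped


# ---------------------------------------------------------------------------
# Stepping encodings
# ---------------------------------------------------------------------------

def encode_left_footprint(model: FootprintModel) -> np.ndarray:
    """Encode the static footprint as 32 values of +/-1.

    Scan order: heel row to toe row, low x to high x within a row —
    i.e. row-major over the 8 x 4 grid.
    """
    return np.where(model.grid.reshape(-1), 1.0, -1.0)


def _encode_frames(frames: list[np.ndarray]) -> np.ndarray:
    return np.concatenate([np.where(g.reshape(-1), 1.0, -1.0) for g in frames])


def stepping_vector_length(case_id: int, dt: float, t_max: float = DEFAULT_T_MAX) -> int:
    """Classifier input size for a stepping case at sampling time ``dt``."""
    if case_id not in STEPPING_CASES:
        raise FeatureError(f"unknown stepping case {case_id}; valid: 1-4")
    return MODEL_CELLS * frame_count(t_max, dt) * len(STEPPING_CASES[case_id])


def encode_stepping_vector(
    footsteps: list[Footstep],
    case_id: int,
    dt: float,
    t_max: float = DEFAULT_T_MAX,
    geom: FloorGeometry | None = None,
) -> np.ndarray:
    """Build one stepping feature vector from the selected footsteps.

    For each footstep named by the case, the +/-1 encodings of its padded
    transitional frames are concatenated in time order; footsteps are
    concatenated in case order.  Total length is
    ``32 * frame_count(t_max, dt) * n_steps``.
    """
    if case_id not in STEPPING_CASES:
        raise FeatureError(f"unknown stepping case {case_id}; valid: 1-4")
    geom = geom or FloorGeometry()
    indices = STEPPING_CASES[case_id]
    if len(footsteps) < max(indices):
        raise FeatureError(
            f"stepping case {case_id} needs footstep {max(indices)}, "
            f"found only {len(footsteps)}"
        )
    parts = []
    for idx in indices:
        footstep = footsteps[idx - 1]
        model = fit_footprint_model(footstep, geom)
        frames = transitional_frames(footstep, model, dt, t_max)
        parts.append(_encode_frames(frames.frames))
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# Whole-sample convenience used by the evaluation pipeline and CLI
# ---------------------------------------------------------------------------

def extract_sample_features(
    footsteps: list[Footstep],
    geom: FloorGeometry,
    walking_case: int = 4,
    stepping_case: int = 4,
    dt: float = 0.04,
    t_max: float = DEFAULT_T_MAX,
    sample_id: str = "<sample>",
) -> tuple[np.ndarray, np.ndarray]:
    """Raw (unnormalised) walking vector and stepping vector of one walk."""
    feats = walking_features(footsteps, geom, sample_id=sample_id)
    wvec = build_walking_vector(feats, walking_case)
    svec = encode_stepping_vector(footsteps, stepping_case, dt, t_max, geom)
    return wvec, svec


def export_feature_matrix(
    X: np.ndarray, path, modality: str, case_id: int, dt: float | None = None
) -> None:
    """Write a feature matrix as tab-separated text with a descriptive header."""
    header = f"# floorgait-features v1 modality={modality} case={case_id}"
    if dt is not None:
        header += f" dt={dt}"
    header += " layout=feature-major"
    np.savetxt(path, np.atleast_2d(X), fmt="%.6g", delimiter="\t", header=header, comments="")
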