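"""Skeleton CSV I/O, windowing, normalisation and dataset splitting.

Skeleton activity recordings arrive as plain CSV files: one row per frame,
the joint coordinates in the first ``F = n_joints * dims_per_joint`` columns
and an integer activity label in the last column.  This module turns such a
file into a :class:`FrameTable`, cuts the frame stream into fixed-length
windows (:class:`WindowSet`) that are the actual classifier inputs, and
provides the usual normalisation and stratified-splitting plumbing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SchemaSpec",
    "FrameTable",
    "WindowSet",
    "NormStats",
    "kinect25_schema",
    "mediapipe33_schema",
    "read_skeleton_csv",
    "write_skeleton_csv",
    "make_windows",
    "normalize_windows",
    "split_dataset",
]

# Kinect-V2 joint order as delivered by the sensor SDK.
KINECT_V2_JOINTS = [
    "head", "neck", "spine_shoulder", "spine_mid", "spine_base",
    "shoulder_right", "shoulder_left", "hip_right", "hip_left",
    "elbow_right", "wrist_right", "hand_right", "hand_tip_right",
    "thumb_right", "elbow_left", "wrist_left", "hand_left",
    "hand_tip_left", "thumb_left", "knee_right", "ankle_right",
    "foot_right", "knee_left", "ankle_left", "foot_left",
]

# MediaPipe Pose landmark order (33 landmarks).
MEDIAPIPE_LANDMARKS = [
    "nose", "left_eye_inner", "left_eye", "left_eye_outer",
    "right_eye_inner", "right_eye", "right_eye_outer", "left_ear",
    "right_ear", "mouth_left", "mouth_right", "left_shoulder",
    "right_shoulder", "left_elbow", "right_elbow", "left_wrist",
    "right_wrist", "left_pinky", "right_pinky", "left_index",
    "right_index", "left_thumb", "right_thumb", "left_hip", "right_hip",
    "left_knee", "right_knee", "left_ankle", "right_ankle", "left_heel",
    "right_heel", "left_foot_index", "right_foot_index",
]


class SchemaError(ValueError):
    """Raised when a file or table does not match its declared schema."""


@dataclass(frozen=True)
class SchemaSpec:
    """Layout of one skeleton CSV: joint count, per-joint dimensionality,
    where the label lives and what the joints are called."""

    n_joints: int
    dims_per_joint: int = 2
    label_column: int | str = -1
    joint_names: tuple[str, ...] = ()

    def __post_init__(self):
        if self.n_joints < 1 or self.dims_per_joint < 1:
            raise SchemaError("n_joints and dims_per_joint must be >= 1")
        names = self.joint_names
        if not names:
            names = tuple(f"joint{i}" for i in range(self.n_joints))
            object.__setattr__(self, "joint_names", names)
        if len(names) != self.n_joints:
            raise SchemaError(
                f"joint_names has {len(names)} entries, expected {self.n_joints}"
            )

    @property
    def n_features(self) -> int:
        return self.n_joints * self.dims_per_joint

    def feature_names(self) -> list[str]:
        axes = "xyzw"[: self.dims_per_joint]
        return [f"{j}_{a}" for j in self.joint_names for a in axes]


def kinect25_schema() -> SchemaSpec:
    """Kinect-V2 layout: 25 joints, (x, y) per joint, label last."""
    return SchemaSpec(25, 2, -1, tuple(KINECT_V2_JOINTS))


def mediapipe33_schema(dims_per_joint: int = 3) -> SchemaSpec:
    """MediaPipe Pose layout: 33 landmarks; per-landmark dimensionality is
    configurable (2 = x,y; 3 = x,y,z; 4 adds visibility), default 3."""
    if dims_per_joint not in (2, 3, 4):
        raise SchemaError("dims_per_joint for the MediaPipe layout must be 2, 3 or 4")
    return SchemaSpec(33, dims_per_joint, -1, tuple(MEDIAPIPE_LANDMARKS))


@dataclass
class FrameTable:
    """Ordered per-frame joint coordinates plus a per-frame class label.

    ``labels`` are always contiguous 0-based integers; ``label_mapping``
    remembers the original file labels.  ``groups`` optionally tags each
    frame with the recording it came from so that windowing never spans a
    recording boundary.
    """

    features: np.ndarray  # (n_frames, F) float
    labels: np.ndarray    # (n_frames,) int
    schema: SchemaSpec
    label_mapping: dict = field(default_factory=dict)  # original -> 0-based
    groups: np.ndarray | None = None  # (n_frames,) recording id, optional

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise SchemaError("features must be 2-D (n_frames, F)")
        if self.features.shape[1] != self.schema.n_features:
            raise SchemaError(
                f"feature width {self.features.shape[1]} != schema F = "
                f"{self.schema.n_features}"
            )
        if self.features.shape[0] != self.labels.shape[0]:
            raise SchemaError("features and labels disagree on n_frames")
        if self.features.size and not np.all(np.isfinite(self.features)):
            bad = int(np.argwhere(~np.isfinite(self.features))[0, 0])
            raise SchemaError(f"non-finite feature value at frame {bad}")
        if self.labels.size:
            if self.labels.min() < 0:
                raise SchemaError("labels must be non-negative after remapping")
        if not self.label_mapping:
            self.label_mapping = {int(c): int(c) for c in np.unique(self.labels)}
        if self.groups is not None:
            self.groups = np.asarray(self.groups)
            if self.groups.shape[0] != self.features.shape[0]:
                raise SchemaError("groups length must equal n_frames")

    @property
    def n_frames(self) -> int:
        return self.features.shape[0]

    @property
    def n_classes(self) -> int:
        return len(self.label_mapping)

    def original_labels(self) -> np.ndarray:
        inv = {v: k for k, v in self.label_mapping.items()}
        return np.array([inv[int(c)] for c in self.labels])


@dataclass
class WindowSet:
    """Fixed-length windows of consecutive frames, one label per window."""

    data: np.ndarray    # (n_windows, L, F)
    labels: np.ndarray  # (n_windows,)
    n_classes: int
    window_length: int

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("window data must be 3-D (n_windows, L, F)")
        if self.data.shape[0] != self.labels.shape[0]:
            raise ValueError("data and labels disagree on n_windows")
        if self.data.shape[1] != self.window_length:
            raise ValueError("data.shape[1] != window_length")

    @property
    def n_windows(self) -> int:
        return self.data.shape[0]

    @property
    def onehot(self) -> np.ndarray:
        eye = np.eye(self.n_classes)
        return eye[self.labels]

    def subset(self, idx: np.ndarray) -> "WindowSet":
        return WindowSet(self.data[idx], self.labels[idx],
                         self.n_classes, self.window_length)


def _detect_header(path) -> bool:
    """A file has a header iff the first row does not parse as all-numeric."""
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        return False
    for tok in first.strip().split(","):
        try:
            float(tok)
        except ValueError:
            return True
    return False


def read_skeleton_csv(path, schema: SchemaSpec) -> FrameTable:
    """Read one skeleton CSV into a :class:`FrameTable`.

    The label column (``schema.label_column``, by default the last column)
    holds the activity class; file labels are remapped to contiguous 0-based
    integers and the mapping is recorded on the returned table.
    """
    header = 0 if _detect_header(path) else None
    try:
        df = pd.read_csv(path, header=header, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        return FrameTable(np.zeros((0, schema.n_features)), np.zeros(0, int), schema)
    if df.shape[0] == 0:
        return FrameTable(np.zeros((0, schema.n_features)), np.zeros(0, int), schema)

    expected = schema.n_features + 1
    if df.shape[1] != expected:
        # pandas pads ragged short rows with NaN; find the first one to name it.
        if df.shape[1] > expected:
            raise SchemaError(
                f"{path}: row width {df.shape[1]} != expected {expected} "
                f"(F={schema.n_features} features + 1 label)"
            )
        raise SchemaError(f"{path}: only {df.shape[1]} columns, expected {expected}")

    lc = schema.label_column
    if isinstance(lc, str):
        if header is None or lc not in df.columns:
            raise SchemaError(f"{path}: label column {lc!r} not found")
        label_raw = df[lc]
        feat_df = df.drop(columns=[lc])
    else:
        label_raw = df.iloc[:, lc]
        feat_df = df.drop(columns=[df.columns[lc]])

    feats = feat_df.to_numpy()
    try:
        feats = feats.astype(float)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: non-numeric feature value ({exc})") from exc
    if not np.all(np.isfinite(feats)):
        bad = int(np.argwhere(~np.isfinite(feats))[0, 0])
        raise SchemaError(f"{path}: malformed or non-finite feature in row {bad}")

    raw = np.asarray(label_raw)
    try:
        raw_int = raw.astype(int)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: non-integer label ({exc})") from exc
    classes = np.unique(raw_int)
    mapping = {int(c): i for i, c in enumerate(classes)}
    labels = np.array([mapping[int(c)] for c in raw_int], dtype=int)
    return FrameTable(feats, labels, schema, mapping)


def write_skeleton_csv(table: FrameTable, path, header: bool = True) -> None:
    """Write a FrameTable in the same layout :func:`read_skeleton_csv` reads.

    Floats are written at full repr precision so a read-back round-trips
    bit-for-bit; labels are written using the original file numbering."""
    cols = table.schema.feature_names()
    df = pd.DataFrame(table.features, columns=cols)
    df["label"] = table.original_labels()
    # %.17g round-trips any IEEE double exactly
    df.to_csv(path, index=False, header=header, float_format="%.17g")


def make_windows(frames: FrameTable, length: int, stride: int | None = None,
                 n_classes: int | None = None) -> WindowSet:
    """Cut the frame stream into fixed-length windows of consecutive frames.

    Window starts are 0, stride, 2*stride, ...; a window whose frames do not
    all carry the same label (or that spans a recording boundary, when the
    table carries ``groups``) is discarded, so every emitted window has an
    unambiguous label.  Default stride = length (non-overlapping blocks).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    stride = length if stride is None else stride
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n_classes = frames.n_classes if n_classes is None else n_classes
    F = frames.schema.n_features

    if frames.n_frames < length:
        warnings.warn(
            f"only {frames.n_frames} frames < window length {length}: "
            "empty WindowSet", stacklevel=2)
        return WindowSet(np.zeros((0, length, F)), np.zeros(0, int),
                         n_classes, length)

    wins, labs = [], []
    labels = frames.labels
    groups = frames.groups
    for start in range(0, frames.n_frames - length + 1, stride):
        sl = slice(start, start + length)
        span = labels[sl]
        if span.max() != span.min():
            continue  # straddles an activity change
        if groups is not None:
            g = groups[sl]
            if not np.all(g == g[0]):
                continue  # straddles a recording boundary
        wins.append(frames.features[sl])
        labs.append(int(span[0]))
    if not wins:
        return WindowSet(np.zeros((0, length, F)), np.zeros(0, int),
                         n_classes, length)
    return WindowSet(np.stack(wins), np.array(labs, int), n_classes, length)


@dataclass
class NormStats:
    """Training-set statistics reused verbatim on validation/test windows."""
    method: str
    mean: np.ndarray | None = None
    sd: np.ndarray | None = None
    ref_joint: int | None = None
    dims_per_joint: int | None = None


def normalize_windows(ws: WindowSet, method: str = "zscore",
                      stats: NormStats | None = None,
                      ref_joint: int | None = None,
                      dims_per_joint: int | None = None,
                      ) -> tuple[WindowSet, NormStats]:
    """Normalise window coordinates; returns the new set plus the statistics.

    ``zscore`` standardises each of the F features using statistics computed
    from *this* set (pass the returned ``stats`` back in to apply train-set
    statistics to held-out data).  ``center_on_joint`` subtracts one reference
    joint's coordinates from every joint, per frame.  ``none`` is identity.
    """
    if method not in ("none", "zscore", "center_on_joint"):
        raise ValueError(f"unknown normalisation method {method!r}")

    if method == "none":
        return ws, NormStats("none")

    if ws.n_windows == 0:
        return ws, NormStats(method)

    if method == "zscore":
        if stats is None:
            flat = ws.data.reshape(-1, ws.data.shape[-1])
            mean = flat.mean(axis=0)
            sd = flat.std(axis=0)
            zero = sd == 0
            if np.any(zero):
                warnings.warn(
                    f"{int(zero.sum())} zero-variance feature(s) under zscore: "
                    "passed through centered", stacklevel=2)
            sd = np.where(zero, 1.0, sd)
            stats = NormStats("zscore", mean=mean, sd=sd)
        data = (ws.data - stats.mean) / stats.sd
        return WindowSet(data, ws.labels, ws.n_classes, ws.window_length), stats

    # center_on_joint
    if stats is not None:
        ref_joint = stats.ref_joint
        dims_per_joint = stats.dims_per_joint
    if ref_joint is None or dims_per_joint is None:
        raise ValueError("center_on_joint needs ref_joint and dims_per_joint")
    d = dims_per_joint
    data = ws.data.copy()
    n_joints = data.shape[-1] // d
    ref = data[..., ref_joint * d:(ref_joint + 1) * d]  # (n, L, d)
    data = data.reshape(*data.shape[:-1], n_joints, d) - ref[..., None, :]
    data = data.reshape(ws.data.shape)
    stats = NormStats("center_on_joint", ref_joint=ref_joint, dims_per_joint=d)
    return WindowSet(data, ws.labels, ws.n_classes, ws.window_length), stats


class StratificationError(ValueError):
    pass


def split_dataset(ws: WindowSet, fractions=(0.8, 0.1, 0.1), seed: int = 0,
                  ) -> tuple[WindowSet, WindowSet, WindowSet]:
    """Deterministic stratified train/val/test split.

    Within each class the windows are shuffled with the seeded generator and
    apportioned by largest-remainder rounding, so part sizes are exact and
    every class appears in every part; the parts are disjoint and exhaustive.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("need three positive fractions")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")

    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    for c in range(ws.n_classes):
        idx = np.flatnonzero(ws.labels == c)
        if idx.size == 0:
            continue
        if idx.size < 3:
            raise StratificationError(
                f"class {c} has only {idx.size} window(s); need >= 3 to "
                "stratify into train/val/test")
        rng.shuffle(idx)
        exact = np.array(fractions) * idx.size
        counts = np.floor(exact).astype(int)
        rem = exact - counts
        for _ in range(idx.size - counts.sum()):
            j = int(np.argmax(rem))
            counts[j] += 1
            rem[j] = -1
        counts = np.maximum(counts, 1)  # every part sees every class
        while counts.sum() > idx.size:
            counts[int(np.argmax(counts))] -= 1
        stops = np.cumsum(counts)
        parts[0].extend(idx[:stops[0]])
        parts[1].extend(idx[stops[0]:stops[1]])
        parts[2].extend(idx[stops[1]:stops[2]])
    out = []
    for p in parts:
        p = np.sort(np.array(p, dtype=int))
        out.append(ws.subset(p))
    return tuple(out)
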