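"""Standardization chain turning raw skeleton recordings into 7-frame
spatio-temporal gait-cycle instances.

The fixed order is: joint-outlier reset -> temporal smoothing -> skeleton
normalization -> joint velocities -> gait-cycle segmentation.  Normalization
(root-centering on the mid-hip, uniform rescaling to a fixed torso length)
makes everything downstream invariant to global translation and uniform
scaling of the raw input, de-emphasizing person-specific size variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schema import DEFAULT_SCHEMA, JointSchema
from .types import CYCLE_FRAMES, GaitCycleInstance, SkeletonSequence


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the standardization chain.

    ``outlier_bone_factor`` — a joint is declared an outlier in a frame when
    its distance to *every* schema-connected neighbor exceeds this multiple
    of that bone's median length over the sequence.
    ``smoothing_window`` — odd moving-average width in frames (1 = off).
    ``cycle_length`` — frames per gait-cycle instance (7 by convention: the
    median gait-cycle length in short-form skeleton datasets).
    ``segmentation_mode`` — ``heel_strike`` detects cycle boundaries from
    inter-ankle forward displacement and resamples each cycle to
    ``cycle_length`` frames; ``fixed_stride`` takes non-overlapping windows.
    ``normalization_target`` — median neck-to-mid-hip distance after scaling.
    """

    outlier_bone_factor: float = 3.0
    smoothing_window: int = 3
    cycle_length: int = CYCLE_FRAMES
    segmentation_mode: str = "heel_strike"
    normalization_target: float = 1.0

    def __post_init__(self) -> None:
        if self.cycle_length < 2:
            raise ValueError("cycle_length must be >= 2")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be a positive odd integer")
        if self.segmentation_mode not in ("heel_strike", "fixed_stride"):
            raise ValueError(f"unknown segmentation_mode {self.segmentation_mode!r}")
        if self.outlier_bone_factor <= 1:
            raise ValueError("outlier_bone_factor must exceed 1")


class UnrecoverableJointError(ValueError):
    """A joint is an outlier in every frame and cannot be interpolated."""


def remove_joint_outliers(seq: SkeletonSequence,
                          config: PreprocessConfig = PreprocessConfig(),
                          schema: JointSchema = DEFAULT_SCHEMA) -> SkeletonSequence:
    """Reset joints that are unnaturally far from their connected key-points.

    A joint-frame is an outlier when its distance to every schema neighbor
    exceeds ``outlier_bone_factor`` times the smaller of (a) that bone's
    median length over the sequence and (b) the median torso length — the
    absolute cap catches joints displaced so consistently that they corrupt
    their own bone's median.  Outlying joint-frames are replaced by linear
    interpolation in time from the nearest non-outlier frames of the same
    joint; runs at the sequence ends copy the nearest valid frame.
    """
    pos = seq.positions
    n_frames, n_joints, _ = pos.shape
    # per-bone median length over the sequence
    bones = list(schema.spatial_edges)
    lengths = {b: np.linalg.norm(pos[:, b[0]] - pos[:, b[1]], axis=1) for b in bones}
    medians = {b: float(np.median(v)) for b, v in lengths.items()}
    # absolute plausibility cap: no bone is anywhere near torso length x
    # factor; catches joints displaced consistently enough to corrupt their
    # own bone's median
    r_hip, l_hip, neck = (schema.index("r_hip"), schema.index("l_hip"),
                          schema.index("neck"))
    mid_hip = 0.5 * (pos[:, r_hip] + pos[:, l_hip])
    torso_med = float(np.median(np.linalg.norm(pos[:, neck] - mid_hip, axis=1)))

    outlier = np.zeros((n_frames, n_joints), dtype=bool)
    for j in range(n_joints):
        checks = []
        for b in bones:
            if j in b:
                threshold = config.outlier_bone_factor * min(medians[b],
                                                             torso_med)
                checks.append(lengths[b] > threshold)
        if checks:
            outlier[:, j] = np.logical_and.reduce(checks)

    out = seq.copy()
    new_pos = pos.copy()
    for j in range(n_joints):
        bad = outlier[:, j]
        if not bad.any():
            continue
        if bad.all():
            raise UnrecoverableJointError(
                f"recording {seq.subject_id}/{seq.recording_id}: joint {j} "
                f"({schema.joint_names[j]}) outlying in all {n_frames} frames")
        good = np.flatnonzero(~bad)
        for axis in range(3):
            new_pos[bad, j, axis] = np.interp(
                np.flatnonzero(bad), good, pos[good, j, axis])
    out.positions = new_pos
    out.meta["outlier_mask"] = outlier
    return out


def denoise(seq: SkeletonSequence,
            config: PreprocessConfig = PreprocessConfig()) -> SkeletonSequence:
    """Per-joint, per-axis moving-average smoothing; length preserved.

    Sequence ends are edge-padded so the output has the same number of
    frames as the input.
    """
    w = config.smoothing_window
    if w > seq.n_frames:
        raise ValueError(f"smoothing_window {w} exceeds sequence length {seq.n_frames}")
    out = seq.copy()
    if w == 1:
        return out
    half = w // 2
    padded = np.pad(seq.positions, ((half, half), (0, 0), (0, 0)), mode="edge")
    kernel = np.ones(w) / w
    sm = np.apply_along_axis(lambda m: np.convolve(m, kernel, mode="valid"),
                             0, padded)
    out.positions = sm
    return out


def normalize_skeleton(seq: SkeletonSequence,
                       config: PreprocessConfig = PreprocessConfig(),
                       schema: JointSchema = DEFAULT_SCHEMA) -> SkeletonSequence:
    """Root-center each frame on the mid-hip and rescale the sequence so the
    median neck-to-mid-hip (torso) distance equals ``normalization_target``."""
    r_hip, l_hip = schema.index("r_hip"), schema.index("l_hip")
    neck = schema.index("neck")
    pos = seq.positions
    mid_hip = 0.5 * (pos[:, r_hip] + pos[:, l_hip])
    centered = pos - mid_hip[:, None, :]
    torso = np.linalg.norm(centered[:, neck], axis=1)
    med = float(np.median(torso))
    if med <= 1e-12:
        raise ValueError(f"recording {seq.subject_id}/{seq.recording_id}: "
                         "degenerate skeleton (zero torso length)")
    out = seq.copy()
    out.positions = centered * (config.normalization_target / med)
    return out


def compute_velocities(seq: SkeletonSequence) -> np.ndarray:
    """Forward finite-difference joint velocities, shape (frames-1, 18, 3).

    Units are normalized coordinates per frame; row ``t`` is the
    displacement from frame ``t`` to ``t+1``.
    """
    if seq.n_frames < 2:
        raise ValueError("need at least 2 frames to compute velocities")
    return np.diff(seq.positions, axis=0)


def _resample_cycle(vel: np.ndarray, length: int) -> np.ndarray:
    """Linearly resample a (frames, 18, 3) slab to exactly ``length`` frames."""
    n = vel.shape[0]
    if n == length:
        return vel.copy()
    src = np.arange(n, dtype=float)
    dst = np.linspace(0, n - 1, length)
    out = np.empty((length,) + vel.shape[1:])
    for j in range(vel.shape[1]):
        for a in range(vel.shape[2]):
            out[:, j, a] = np.interp(dst, src, vel[:, j, a])
    return out


def _heel_strike_frames(seq: SkeletonSequence, schema: JointSchema,
                        min_gap: int) -> np.ndarray:
    """Cycle-start frames: local maxima of the left-minus-right ankle
    displacement along its dominant horizontal direction."""
    l_ankle, r_ankle = schema.index("l_ankle"), schema.index("r_ankle")
    d = seq.positions[:, l_ankle] - seq.positions[:, r_ankle]
    horiz = d[:, [0, 2]]  # x (walking) and z (lateral)
    horiz = horiz - horiz.mean(axis=0)
    # project onto the dominant direction of inter-ankle motion
    _, _, vt = np.linalg.svd(horiz, full_matrices=False)
    direction = vt[0]
    # deterministic orientation: largest-magnitude component positive, so
    # "cycle start" consistently means the left ankle at its forward-most
    if direction[np.argmax(np.abs(direction))] < 0:
        direction = -direction
    s = horiz @ direction
    peaks = np.flatnonzero((s[1:-1] > s[:-2]) & (s[1:-1] >= s[2:])) + 1
    # enforce a minimum spacing, keeping the higher peak
    kept: list[int] = []
    for pk in peaks:
        if kept and pk - kept[-1] < min_gap:
            if s[pk] > s[kept[-1]]:
                kept[-1] = pk
        else:
            kept.append(pk)
    return np.asarray(kept, dtype=int)


def segment_gait_cycles(velocities: np.ndarray, seq: SkeletonSequence,
                        config: PreprocessConfig = PreprocessConfig(),
                        schema: JointSchema = DEFAULT_SCHEMA) -> list[GaitCycleInstance]:
    """Cut a velocity array into ``cycle_length``-frame gait-cycle instances."""
    L = config.cycle_length
    n = velocities.shape[0]
    instances: list[GaitCycleInstance] = []

    def make(vel: np.ndarray, k: int) -> GaitCycleInstance:
        return GaitCycleInstance(
            velocities=vel,
            subject_id=seq.subject_id,
            class_label=seq.class_label,
            instance_id=f"{seq.subject_id}/{seq.recording_id}/{k:04d}",
            schema=schema,
        )

    if n < L:
        return instances
    if config.segmentation_mode == "fixed_stride":
        for k in range(n // L):
            instances.append(make(velocities[k * L:(k + 1) * L], k))
    else:
        starts = _heel_strike_frames(seq, schema, min_gap=max(2, L - 3))
        seq.meta["detected_cycle_starts"] = starts
        for k in range(len(starts) - 1):
            a, b = int(starts[k]), int(starts[k + 1])
            if b > n:
                break
            if b - a < 2:
                continue
            instances.append(make(_resample_cycle(velocities[a:b], L), k))
    return instances


def preprocess_sequence(seq: SkeletonSequence,
                        config: PreprocessConfig = PreprocessConfig(),
                        schema: JointSchema = DEFAULT_SCHEMA) -> list[GaitCycleInstance]:
    """Run the full standardization chain on one recording."""
    s = remove_joint_outliers(seq, config, schema)
    s = denoise(s, config)
    s = normalize_skeleton(s, config, schema)
    vel = compute_velocities(s)
    return segment_gait_cycles(vel, s, config, schema)


def preprocess_cohort(seqs: list[SkeletonSequence],
                      config: PreprocessConfig = PreprocessConfig(),
                      schema: JointSchema = DEFAULT_SCHEMA) -> list[GaitCycleInstance]:
    out: list[GaitCycleInstance] = []
    for seq in seqs:
        out.extend(preprocess_sequence(seq, config, schema))
    return out


def instances_to_array(instances: list[GaitCycleInstance]) -> np.ndarray:
    """Stack instances into an (n, 7, 18, 3) velocity tensor."""
    return np.stack([i.velocities for i in instances])
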