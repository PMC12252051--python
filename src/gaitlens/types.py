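"""Core data containers: skeleton sequences, gait-cycle instances, embeddings."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

from .schema import DEFAULT_SCHEMA, JointSchema

CYCLE_FRAMES = 7  # frames per gait-cycle instance


@dataclass
class SkeletonSequence:
    """One walking recording: per-frame 18x3 joint positions plus metadata.

    ``positions`` has shape ``(frames, 18, 3)`` in arbitrary but internally
    consistent length units (normalization later removes scale).  ``meta`` is
    free-form; the synthetic generator stores its ground-truth kinematic
    parameters there so downstream tests can compare against them.
    """

    positions: np.ndarray
    frame_rate: float
    subject_id: str
    class_label: Optional[str] = None
    dataset_tag: str = ""
    recording_id: str = "0"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError(
                f"positions must be (frames, joints, 3), got {self.positions.shape}"
            )

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_joints(self) -> int:
        return self.positions.shape[1]

    def copy(self) -> "SkeletonSequence":
        return SkeletonSequence(
            positions=self.positions.copy(),
            frame_rate=self.frame_rate,
            subject_id=self.subject_id,
            class_label=self.class_label,
            dataset_tag=self.dataset_tag,
            recording_id=self.recording_id,
            meta=dict(self.meta),
        )


@dataclass
class GaitCycleInstance:
    """One 7-frame spatio-temporal gait graph of joint velocities.

    ``velocities`` has shape ``(7, 18, 3)`` in normalized coordinates per
    frame.  Spatial edges come from the schema; temporal edges implicitly
    connect joint *i* at frame *t* to joint *i* at frames *t±1*.
    """

    velocities: np.ndarray
    subject_id: str
    instance_id: str
    class_label: Optional[str] = None
    schema: JointSchema = field(default_factory=lambda: DEFAULT_SCHEMA, repr=False)

    def __post_init__(self) -> None:
        self.velocities = np.asarray(self.velocities, dtype=float)
        exp = (CYCLE_FRAMES, self.schema.n_joints, 3)
        if self.velocities.shape != exp:
            raise ValueError(f"velocities must be {exp}, got {self.velocities.shape}")
        if not np.isfinite(self.velocities).all():
            raise ValueError(f"non-finite velocities in instance {self.instance_id}")

    @property
    def temporal_edges(self) -> list[tuple[tuple[int, int], tuple[int, int]]]:
        """((joint, t), (joint, t+1)) pairs — same joint across adjacent frames."""
        v = self.schema.n_joints
        return [((j, t), (j, t + 1)) for t in range(CYCLE_FRAMES - 1) for j in range(v)]


@dataclass
class EmbeddingVector:
    """Per-instance 18x3 PCA-compressed embedding (54 scalars flattened)."""

    values: np.ndarray
    instance_id: str
    class_label: Optional[str] = None
    subject_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (18, 3):
            raise ValueError(f"embedding must be (18, 3), got {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise ValueError(f"non-finite embedding for instance {self.instance_id}")

    @property
    def flat(self) -> np.ndarray:
        return self.values.reshape(54)


def stack_embeddings(embeddings: list[EmbeddingVector]) -> np.ndarray:
    """Stack embeddings into an ``(n, 54)`` matrix in list order."""
    return np.stack([e.flat for e in embeddings])


@dataclass
class Violation:
    code: str
    message: str


def validate_schema(seq: SkeletonSequence, schema: JointSchema = DEFAULT_SCHEMA) -> list[Violation]:
    """Check a sequence against the schema; empty list iff valid.

    Reports joint-count mismatches, non-finite coordinates (naming frame and
    joint) and sequences too short to yield velocities.
    """
    out: list[Violation] = []
    if seq.n_joints != schema.n_joints:
        out.append(Violation(
            "joint_count",
            f"recording {seq.subject_id}/{seq.recording_id}: "
            f"expected {schema.n_joints} joints, got {seq.n_joints}",
        ))
    if seq.n_frames < 2:
        out.append(Violation(
            "too_few_frames",
            f"recording {seq.subject_id}/{seq.recording_id}: needs >= 2 frames, "
            f"got {seq.n_frames}",
        ))
    bad = np.argwhere(~np.isfinite(seq.positions))
    for frame, joint, _axis in bad[:20]:  # cap the report, not the detection
        out.append(Violation(
            "non_finite",
            f"non-finite coordinate at frame {frame}, joint {joint}",
        ))
    return out
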