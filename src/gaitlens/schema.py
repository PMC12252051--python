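"""18-joint skeleton schema: joint names, bone edges and body-region map.

The joint layout follows the COCO-18 pose convention (nose, neck, shoulders,
elbows, wrists, hips, knees, ankles, eyes, ears) — a full-body key-point set
that deliberately excludes fingers and toes.  Six body regions (head, torso,
left/right arm, left/right leg) partition the joints for interpretable
region-level reporting; the hips are assigned to the torso by default, a
choice that is overridable because conventions differ between labs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_JOINTS = 18
REGIONS = ("head", "torso", "left_arm", "right_arm", "left_leg", "right_leg")

COCO18_NAMES = (
    "nose", "neck",
    "r_shoulder", "r_elbow", "r_wrist",
    "l_shoulder", "l_elbow", "l_wrist",
    "r_hip", "r_knee", "r_ankle",
    "l_hip", "l_knee", "l_ankle",
    "r_eye", "l_eye", "r_ear", "l_ear",
)

# anatomical bone connections (index pairs into COCO18_NAMES)
COCO18_EDGES = (
    (0, 1),            # nose-neck
    (1, 2), (2, 3), (3, 4),      # right arm
    (1, 5), (5, 6), (6, 7),      # left arm
    (1, 8), (8, 9), (9, 10),     # right leg (hip chained from neck)
    (1, 11), (11, 12), (12, 13), # left leg
    (0, 14), (14, 16),           # right eye/ear
    (0, 15), (15, 17),           # left eye/ear
)

_DEFAULT_REGION_MAP = {
    0: "head", 14: "head", 15: "head", 16: "head", 17: "head",
    1: "torso", 8: "torso", 11: "torso",
    5: "left_arm", 6: "left_arm", 7: "left_arm",
    2: "right_arm", 3: "right_arm", 4: "right_arm",
    12: "left_leg", 13: "left_leg",
    9: "right_leg", 10: "right_leg",
}


@dataclass(frozen=True)
class JointSchema:
    """Joint naming, bone topology and region partition for one skeleton layout.

    Parameters
    ----------
    joint_names
        Ordered identifiers, one per joint (length 18).
    spatial_edges
        Bone connections as ``(i, j)`` index pairs; the graph must be connected.
    region_map
        ``joint index -> region name``; must partition all joints into the six
        canonical regions.
    """

    joint_names: tuple[str, ...] = COCO18_NAMES
    spatial_edges: tuple[tuple[int, int], ...] = COCO18_EDGES
    region_map: dict[int, str] = field(default_factory=lambda: dict(_DEFAULT_REGION_MAP))

    def __post_init__(self) -> None:
        n = len(self.joint_names)
        if n != N_JOINTS:
            raise ValueError(f"schema requires exactly {N_JOINTS} joints, got {n}")
        if set(self.region_map) != set(range(n)):
            raise ValueError("region_map must cover every joint index exactly once")
        bad = set(self.region_map.values()) - set(REGIONS)
        if bad:
            raise ValueError(f"unknown regions in region_map: {sorted(bad)}")
        for i, j in self.spatial_edges:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge ({i},{j}) out of range")
        if not self._connected():
            raise ValueError("spatial edge graph must be connected")

    def _connected(self) -> bool:
        adj: dict[int, set[int]] = {i: set() for i in range(len(self.joint_names))}
        for i, j in self.spatial_edges:
            adj[i].add(j)
            adj[j].add(i)
        seen = {0}
        stack = [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == len(self.joint_names)

    @property
    def n_joints(self) -> int:
        return len(self.joint_names)

    def region_joints(self, region: str) -> list[int]:
        """Joint indices belonging to ``region``, in ascending order."""
        return sorted(j for j, r in self.region_map.items() if r == region)

    def neighbors(self, joint: int) -> list[int]:
        """Indices of joints sharing a bone with ``joint``."""
        out = []
        for i, j in self.spatial_edges:
            if i == joint:
                out.append(j)
            elif j == joint:
                out.append(i)
        return sorted(set(out))

    def adjacency(self, self_loops: bool = True, normalized: bool = True) -> np.ndarray:
        """Dense 18x18 adjacency; symmetric degree normalization D^-1/2 (A+I) D^-1/2."""
        n = self.n_joints
        a = np.zeros((n, n))
        for i, j in self.spatial_edges:
            a[i, j] = 1.0
            a[j, i] = 1.0
        if self_loops:
            a += np.eye(n)
        if normalized:
            d = a.sum(axis=1)
            dinv = 1.0 / np.sqrt(np.maximum(d, 1e-12))
            a = a * dinv[:, None] * dinv[None, :]
        return a

    def index(self, name: str) -> int:
        return self.joint_names.index(name)


DEFAULT_SCHEMA = JointSchema()
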