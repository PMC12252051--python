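"""Synthetic multi-subject cohorts of cyclic 18-joint gait with injectable
pathologies.

The generator produces phase-offset sinusoidal limb oscillations about a
steady walking translation.  Per-subject skeleton geometry (limb lengths),
cadence and gait phase are drawn from seeded distributions, so a cohort has
realistic between-subject variation while remaining bitwise reproducible.
Pathologies are parametric transforms of the underlying kinematic model:

* ``limp_left`` / ``limp_right`` — the affected leg's oscillation amplitudes
  shrink by a factor ``1 - 0.6*severity`` and its phase is delayed, giving
  the lateralized asymmetry signature of an antalgic gait;
* ``shuffle`` — step height collapses bilaterally and cadence rises, the
  signature of a shuffling (Parkinsonian-like) gait;
* ``weighted`` — walking speed and arm swing are damped, emulating gait
  under attached weights.

``severity`` in [0, 1] interpolates continuously between identity (0) and
the full transform (1).  The model is a test harness for the analysis
pipeline, not a biomechanically validated simulation: what matters is that
each pathology perturbs a known body region by a known amount, with the
ground-truth kinematic parameters retained in ``SkeletonSequence.meta``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
import numpy as np

from .schema import DEFAULT_SCHEMA, JointSchema
from .types import SkeletonSequence

PATHOLOGY_KINDS = ("none", "limp_left", "limp_right", "shuffle", "weighted")

# joints whose trajectories each pathology directly modifies (COCO-18 indices)
_AFFECTED = {
    "none": frozenset(),
    "limp_left": frozenset({12, 13}),            # l_knee, l_ankle
    "limp_right": frozenset({9, 10}),            # r_knee, r_ankle
    "shuffle": frozenset({9, 10, 12, 13}),       # both knees/ankles
    "weighted": frozenset({3, 4, 6, 7}),         # both elbows/wrists
}

OCCLUSION_SENTINEL_TORSO_MULTIPLE = 5.0


@dataclass(frozen=True)
class PathologySpec:
    """One simulated gait abnormality of controllable severity."""

    kind: str = "none"
    severity: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in PATHOLOGY_KINDS:
            raise ValueError(f"unknown pathology kind {self.kind!r}; "
                             f"choose from {PATHOLOGY_KINDS}")
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError(f"severity must be in [0, 1], got {self.severity}")

    @property
    def affected_joints(self) -> frozenset[int]:
        return _AFFECTED[self.kind]

    @property
    def label(self) -> str:
        if self.kind == "none":
            return "none"
        return f"{self.kind}_s{self.severity:g}"


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generation parameters.

    ``cycle_period`` is the nominal gait-cycle length in frames; each subject
    draws a cadence within ±10% of it.  ``noise_sd`` is the per-coordinate
    Gaussian key-point jitter in the generator's length units (torso length
    is about 0.5 units).  ``occlusion_rate`` is the probability that a
    joint-frame is replaced by a far-displaced sentinel, emulating a pose
    estimator losing track of a key-point.
    """

    n_subjects: int = 10
    frames_per_recording: int = 140
    frame_rate: float = 10.0
    cycle_period: int = 7
    noise_sd: float = 0.005
    occlusion_rate: float = 0.01
    seed: int = 0
    class_list: tuple[PathologySpec, ...] = (
        PathologySpec("none"),
        PathologySpec("limp_left", 0.7),
        PathologySpec("shuffle", 0.7),
        PathologySpec("weighted", 0.7),
    )

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.frames_per_recording < 2:
            raise ValueError("frames_per_recording must be >= 2")
        if self.cycle_period < 4:
            raise ValueError("cycle_period must be >= 4")
        if not 0.0 <= self.occlusion_rate <= 1.0:
            raise ValueError("occlusion_rate must be a probability")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _draw_subject_params(rng: np.random.Generator, config: CohortConfig) -> dict:
    torso = 0.50 * (1 + 0.06 * rng.standard_normal())
    period = config.cycle_period * rng.uniform(0.92, 1.08)
    stride = 0.56 * (1 + 0.10 * rng.standard_normal())
    return {
        "period": period,
        "phase": rng.uniform(0, 2 * np.pi),
        # per-frame speed follows from stride length and cadence, so slower
        # frame-sampled cadences do not imply implausibly long strides
        "speed": stride / period,
        "torso_len": torso,
        "head_h": 0.22 * torso / 0.5,
        "shoulder_w": 0.36 * (1 + 0.05 * rng.standard_normal()),
        "hip_w": 0.24 * (1 + 0.05 * rng.standard_normal()),
        "thigh": 0.42 * (1 + 0.05 * rng.standard_normal()),
        "shank": 0.40 * (1 + 0.05 * rng.standard_normal()),
        "upper_arm": 0.30 * (1 + 0.05 * rng.standard_normal()),
        "forearm": 0.26 * (1 + 0.05 * rng.standard_normal()),
        "bob": 0.015 * (1 + 0.1 * rng.standard_normal()),
        # physiological upper-body motion: lateral trunk sway at stride
        # frequency and a small head nod at step frequency, with their own
        # phases — real heads are not rigidly coupled to the pelvis
        "sway": 0.020 * (1 + 0.15 * rng.standard_normal()),
        "sway_phase": rng.uniform(0, 2 * np.pi),
        "nod": 0.010 * (1 + 0.15 * rng.standard_normal()),
        "nod_phase": rng.uniform(0, 2 * np.pi),
        # pelvic list (vertical, antiphase per side) and rotation (fore-aft):
        # the two sides cancel at the mid-hip, leaving the root untouched
        "pelvis_list": 0.012 * (1 + 0.15 * rng.standard_normal()),
        "pelvis_rot": 0.015 * (1 + 0.15 * rng.standard_normal()),
        "amp": {
            "knee_swing": 0.12 * (1 + 0.08 * rng.standard_normal()),
            "knee_lift": 0.045 * (1 + 0.08 * rng.standard_normal()),
            "ankle_swing": 0.17 * (1 + 0.08 * rng.standard_normal()),
            "step_height": 0.060 * (1 + 0.08 * rng.standard_normal()),
            "arm_swing": 0.10 * (1 + 0.08 * rng.standard_normal()),
            "wrist_swing": 0.14 * (1 + 0.08 * rng.standard_normal()),
        },
        # per-side multiplicative/additive pathology modifiers (identity here)
        "side_amp": {"l": 1.0, "r": 1.0},           # leg oscillation scale
        "side_step_height": {"l": 1.0, "r": 1.0},   # vertical ankle/knee lift scale
        "side_phase_delay": {"l": 0.0, "r": 0.0},   # radians
        "arm_scale": 1.0,
        "speed_scale": 1.0,
        "cadence_scale": 1.0,                        # >1 = faster cadence
    }


def _synthesize(params: dict, n_frames: int,
                t: np.ndarray | None = None) -> np.ndarray:
    """Evaluate the kinematic model at frame times -> (len(t), 18, 3).

    Axes: x = walking direction, y = up, z = lateral (right-handed, y-up).
    ``t`` defaults to the integer frames ``0..n_frames-1``; fractional times
    are allowed (used for ground-truth phase computations).
    """
    p = params
    if t is None:
        t = np.arange(n_frames, dtype=float)
    n_frames = len(t)
    omega = 2 * np.pi * p["cadence_scale"] / p["period"]
    phase = omega * t + p["phase"]
    pos = np.zeros((n_frames, 18, 3))

    hip_y = p["thigh"] + p["shank"]
    root_x = p["speed"] * p["speed_scale"] * t
    root_y = hip_y + p["bob"] * np.sin(2 * phase)

    def put(idx, x, y, z):
        pos[:, idx, 0] = x
        pos[:, idx, 1] = y
        pos[:, idx, 2] = z

    # torso / head column, with lateral trunk sway and head nod
    neck_y = root_y + p["torso_len"]
    sway = p["sway"] * np.sin(phase + p["sway_phase"])
    nod = p["nod"] * np.sin(2 * phase + p["nod_phase"])
    head_y = neck_y + p["head_h"] + nod
    put(1, root_x, neck_y, sway)                                 # neck
    put(0, root_x + 0.05, head_y, 1.5 * sway)                    # nose
    put(14, root_x + 0.03, head_y + 0.02, 1.5 * sway - 0.04)     # r_eye
    put(15, root_x + 0.03, head_y + 0.02, 1.5 * sway + 0.04)     # l_eye
    put(16, root_x - 0.02, head_y - nod / 2, 1.5 * sway - 0.07)  # r_ear
    put(17, root_x - 0.02, head_y - nod / 2, 1.5 * sway + 0.07)  # l_ear

    amp = p["amp"]
    for side, sign, idx in (("r", -1.0, {"hip": 8, "knee": 9, "ankle": 10,
                                         "shoulder": 2, "elbow": 3, "wrist": 4}),
                            ("l", +1.0, {"hip": 11, "knee": 12, "ankle": 13,
                                         "shoulder": 5, "elbow": 6, "wrist": 7})):
        leg_phase = phase + (0.0 if side == "l" else np.pi) - p["side_phase_delay"][side]
        a_scale = p["side_amp"][side]
        h_scale = p["side_step_height"][side]

        hip_x = root_x + sign * p["pelvis_rot"] * np.sin(phase)
        hip_y = root_y + sign * p["pelvis_list"] * np.sin(phase + 0.4)
        hip_z = sign * p["hip_w"] / 2
        put(idx["hip"], hip_x, hip_y, hip_z)

        knee_x = hip_x + a_scale * amp["knee_swing"] * np.sin(leg_phase)
        knee_y = hip_y - p["thigh"] + h_scale * a_scale * amp["knee_lift"] * np.sin(leg_phase + np.pi / 2)
        put(idx["knee"], knee_x, knee_y, hip_z)

        ankle_x = knee_x + a_scale * amp["ankle_swing"] * np.sin(leg_phase - 0.3)
        ankle_y = knee_y - p["shank"] + h_scale * a_scale * amp["step_height"] * np.sin(leg_phase + 0.9)
        put(idx["ankle"], ankle_x, ankle_y, hip_z)

        sh_z = sign * p["shoulder_w"] / 2 + sway
        put(idx["shoulder"], root_x, neck_y, sh_z)
        # arms swing in antiphase with the same-side leg's *base* rhythm;
        # a leg-only pathology (e.g. limp phase delay) does not drag the arm
        arm_phase = phase + (0.0 if side == "l" else np.pi) + np.pi
        elbow_x = root_x + p["arm_scale"] * amp["arm_swing"] * np.sin(arm_phase)
        elbow_y = neck_y - p["upper_arm"]
        put(idx["elbow"], elbow_x, elbow_y, sh_z)
        wrist_x = elbow_x + p["arm_scale"] * amp["wrist_swing"] * np.sin(arm_phase - 0.2)
        put(idx["wrist"], wrist_x, elbow_y - p["forearm"], sh_z)

    return pos


def _apply_pathology(params: dict, spec: PathologySpec) -> dict:
    p = copy.deepcopy(params)
    s = spec.severity
    if spec.kind == "none" or s == 0.0:
        return p
    if spec.kind in ("limp_left", "limp_right"):
        side = "l" if spec.kind == "limp_left" else "r"
        p["side_amp"][side] *= 1 - 0.6 * s
        p["side_phase_delay"][side] += 0.5 * s
    elif spec.kind == "shuffle":
        for side in ("l", "r"):
            p["side_step_height"][side] *= 1 - 0.7 * s
        p["cadence_scale"] *= 1 + 0.3 * s
    elif spec.kind == "weighted":
        p["speed_scale"] *= 1 - 0.4 * s
        p["arm_scale"] *= 1 - 0.5 * s
    return p


def _cycle_starts(params: dict, n_frames: int) -> np.ndarray:
    """Ground-truth cycle-start times (possibly fractional frames): peaks of
    the left-minus-right ankle forward displacement, one per stride."""
    t = np.arange(0, n_frames - 1 + 1e-9, 0.05)
    pos = _synthesize(params, n_frames, t=t)
    signal = pos[:, 13, 0] - pos[:, 10, 0]  # l_ankle x minus r_ankle x
    interior = (signal[1:-1] > signal[:-2]) & (signal[1:-1] >= signal[2:])
    return t[1:-1][interior]


def inject_pathology(seq: SkeletonSequence, spec: PathologySpec) -> SkeletonSequence:
    """Re-synthesize a generated sequence with a pathology applied.

    Requires the kinematic ground truth stored by :func:`generate_cohort` in
    ``seq.meta['gait_params']``; only the transform's target parameters are
    touched, so joints outside the affected set change only through kinematic
    coupling (e.g. a global cadence change).  ``severity == 0`` is exactly
    the identity.
    """
    if "gait_params" not in seq.meta:
        raise ValueError("inject_pathology requires a generator-produced "
                         "sequence carrying meta['gait_params']")
    params = _apply_pathology(seq.meta["gait_params"], spec)
    out = seq.copy()
    out.positions = _synthesize(params, seq.n_frames)
    out.class_label = spec.label
    out.meta["gait_params"] = params
    out.meta["pathology"] = {"kind": spec.kind, "severity": spec.severity,
                             "affected_joints": sorted(spec.affected_joints)}
    out.meta["cycle_starts"] = _cycle_starts(params, seq.n_frames)
    return out


def corrupt(seq: SkeletonSequence, noise_sd: float, occlusion_rate: float,
            seed: int) -> SkeletonSequence:
    """Add key-point jitter and occlusion dropouts to a sequence.

    Gaussian noise of standard deviation ``noise_sd`` is added to every
    coordinate; with probability ``occlusion_rate`` a joint-frame is
    displaced by five torso lengths (an implausible sentinel a downstream
    outlier-repair stage must catch).  The uncorrupted positions are kept in
    ``meta['clean_positions']`` and the occlusion mask in ``meta['occluded']``.
    """
    rng = np.random.default_rng(seed)
    out = seq.copy()
    out.meta["clean_positions"] = seq.positions.copy()
    pos = seq.positions.copy()
    if noise_sd > 0:
        pos = pos + rng.normal(0.0, noise_sd, size=pos.shape)
    occluded = np.zeros(pos.shape[:2], dtype=bool)
    if occlusion_rate > 0:
        from .schema import DEFAULT_SCHEMA

        occluded = rng.random(pos.shape[:2]) < occlusion_rate
        torso = seq.meta.get("gait_params", {}).get("torso_len", 0.5)
        radius = OCCLUSION_SENTINEL_TORSO_MULTIPLE * torso
        clean = pos.copy()
        # each dropout flies off in its own random direction; directions are
        # re-drawn until every sentinel is far (>= 2 torso lengths) from all
        # its connected key-points, including simultaneously occluded
        # neighbors — the sentinel's contract is implausibility
        for frame, joint in np.argwhere(occluded):
            for _attempt in range(50):
                d = rng.standard_normal(3)
                candidate = clean[frame, joint] + radius * d / np.linalg.norm(d)
                ok = all(
                    np.linalg.norm(candidate - pos[frame, nb]) >= 2.0 * torso
                    for nb in DEFAULT_SCHEMA.neighbors(joint))
                if ok:
                    pos[frame, joint] = candidate
                    break
            else:  # pragma: no cover - astronomically unlikely
                pos[frame, joint] = clean[frame, joint] + radius * np.array(
                    [1.0, 0.0, 0.0])
    out.positions = pos
    out.meta["occluded"] = occluded
    return out


def generate_cohort(config: CohortConfig,
                    schema: JointSchema = DEFAULT_SCHEMA) -> list[SkeletonSequence]:
    """Generate one recording per subject x pathology class.

    Deterministic given ``config.seed``: subject geometry and cadence come
    from per-subject child streams, and corruption noise from per-(subject,
    class) child streams, so changing one class's severity never perturbs
    another sequence's draws.
    """
    del schema  # layout is fixed to COCO-18; kept for interface symmetry
    root_ss = np.random.SeedSequence(config.seed)
    subject_seeds = root_ss.spawn(config.n_subjects)
    cohort: list[SkeletonSequence] = []
    for si in range(config.n_subjects):
        subj_ss = subject_seeds[si]
        rng = np.random.default_rng(subj_ss)
        base_params = _draw_subject_params(rng, config)
        class_seeds = subj_ss.spawn(len(config.class_list))
        for ci, spec in enumerate(config.class_list):
            params = _apply_pathology(base_params, spec)
            pos = _synthesize(params, config.frames_per_recording)
            seq = SkeletonSequence(
                positions=pos,
                frame_rate=config.frame_rate,
                subject_id=f"S{si:03d}",
                class_label=spec.label,
                dataset_tag="synthetic",
                recording_id=f"R{ci:02d}",
                meta={
                    "gait_params": params,
                    "pathology": {"kind": spec.kind, "severity": spec.severity,
                                  "affected_joints": sorted(spec.affected_joints)},
                    "cycle_starts": _cycle_starts(params, config.frames_per_recording),
                    "cycle_period_frames": params["period"] / params["cadence_scale"],
                },
            )
            if config.noise_sd > 0 or config.occlusion_rate > 0:
                corrupt_seed = int(class_seeds[ci].generate_state(1)[0] % (2**31))
                seq = corrupt(seq, config.noise_sd, config.occlusion_rate, corrupt_seed)
            cohort.append(seq)
    return cohort
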