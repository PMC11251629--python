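"""Movement definition and the musculoskeletal surrogate.

This module covers three jobs normally delegated to a full musculoskeletal
modelling environment:

1. *Movement definition*: a library of named hand/wrist/forearm poses,
   eased interpolation between pose keyframes on a uniform time grid, range
   checking, and OpenSim-style ``.mot`` motion-file I/O.
2. *Fibre-length tracking*: under the rigid-tendon assumption (tendon held at
   constant slack length) and constant moment arms, the musculotendon length
   is affine in the joint angles and the normalised fibre length follows
   directly.
3. *Activation estimation*: per-sample static optimisation — minimise the sum
   of squared activations subject to the muscles reproducing a demanded joint
   torque through their moment arms and force-length-scaled maximal forces.

Angles are degrees in files and public interfaces, radians inside the
length/torque formulas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .config import SimConfig, MuscleModel, DEFAULT_DOF_RANGES

__all__ = [
    "PoseDefinition", "JointTrajectory", "MuscleTrajectory",
    "load_pose_library", "resolve_pose", "define_movement",
    "check_joint_ranges", "read_mot", "write_mot",
    "fibre_length", "torque_demand", "static_optimization_activations",
]


# ---------------------------------------------------------------------------
# Poses and trajectories
# ---------------------------------------------------------------------------

@dataclass
class PoseDefinition:
    """A named posture: DoF -> angle in degrees; absent DoFs are zero."""

    name: str
    angle_map: dict[str, float] = field(default_factory=dict)

    def combine(self, other: "PoseDefinition") -> "PoseDefinition":
        """Key-wise sum of two poses (the ``a+b`` combination rule)."""
        summed = dict(self.angle_map)
        for dof, ang in other.angle_map.items():
            summed[dof] = summed.get(dof, 0.0) + ang
        return PoseDefinition(f"{self.name}+{other.name}", summed)


@dataclass
class JointTrajectory:
    """Uniformly sampled joint angles (degrees) for every DoF in the schema."""

    dof_names: list[str]
    time: np.ndarray              # (n,) seconds, uniform
    angles: np.ndarray            # (n, n_dof) degrees
    fs_motion: float              # Hz

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.shape != (self.time.size, len(self.dof_names)):
            raise ValueError("angles must be (n_samples, n_dof)")
        if self.time.size > 1:
            dt = np.diff(self.time)
            if not np.all(dt > 0):
                raise ValueError("time must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def dof(self, name: str) -> np.ndarray:
        return self.angles[:, self.dof_names.index(name)]


@dataclass
class MuscleTrajectory:
    """Normalised fibre length (and optionally activation) over a movement."""

    muscle: str
    time: np.ndarray
    fibre_length_norm: np.ndarray
    activation: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)


def load_pose_library() -> dict[str, PoseDefinition]:
    """Eight default poses plus the neutral ``default`` pose (all zeros).

    open/grasp drive the finger joints, flex/ext the wrist flexion DoF,
    rdev/udev the wrist deviation DoF, and pronation/supination the forearm
    rotation DoF.  Poses can be combined with '+': ``open+flex`` sums maps.
    """
    fingers = ("index", "middle", "ring", "little")
    open_map = {"thumb_cmc_abduction": 50.0, "thumb_mp_flexion": -10.0}
    grasp_map = {"thumb_cmc_flexion": 30.0, "thumb_mp_flexion": 40.0,
                 "thumb_ip_flexion": 50.0}
    for f in fingers:
        open_map[f"{f}_mcp_flexion"] = -30.0
        grasp_map[f"{f}_mcp_flexion"] = 70.0
        grasp_map[f"{f}_pip_flexion"] = 90.0
        grasp_map[f"{f}_dip_flexion"] = 60.0
    lib = {
        "default": PoseDefinition("default", {}),
        "open": PoseDefinition("open", open_map),
        "grasp": PoseDefinition("grasp", grasp_map),
        "flex": PoseDefinition("flex", {"wrist_flexion": 60.0}),
        "ext": PoseDefinition("ext", {"wrist_flexion": -60.0}),
        "rdev": PoseDefinition("rdev", {"wrist_deviation": -20.0}),
        "udev": PoseDefinition("udev", {"wrist_deviation": 30.0}),
        "pronation": PoseDefinition("pronation", {"forearm_rotation": 80.0}),
        "supination": PoseDefinition("supination", {"forearm_rotation": -80.0}),
    }
    return lib


def resolve_pose(name: str,
                 library: dict[str, PoseDefinition] | None = None) -> PoseDefinition:
    """Look up a pose by name; ``a+b`` combinations sum angle maps key-wise."""
    library = library if library is not None else load_pose_library()
    parts = [p.strip() for p in name.split("+")]
    try:
        pose = library[parts[0]]
        for p in parts[1:]:
            pose = pose.combine(library[p])
    except KeyError as exc:
        raise KeyError(f"unknown pose {exc.args[0]!r}") from None
    return pose


def define_movement(pose_sequence: list[str],
                    durations: list[float],
                    fs_motion: float,
                    dof_names: list[str] | None = None,
                    library: dict[str, PoseDefinition] | None = None,
                    interpolation: str = "cosine") -> JointTrajectory:
    """Interpolate between pose keyframes on a uniform time grid.

    The default easing is the half-cosine ramp s(u) = (1 - cos(pi u)) / 2,
    which has zero angular velocity at every keyframe and so avoids abrupt
    fibre-length transients at pose changes; ``interpolation="linear"`` gives
    straight-line interpolation.  Keyframe samples reproduce the pose angle
    maps exactly.
    """
    if len(durations) != len(pose_sequence) - 1:
        raise ValueError("need len(durations) == len(pose_sequence) - 1")
    if fs_motion <= 0:
        raise ValueError("fs_motion must be > 0")
    if any(d <= 0 for d in durations):
        raise ValueError("durations must be positive")
    if interpolation not in ("cosine", "linear"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    dof_names = dof_names if dof_names is not None else list(DEFAULT_DOF_RANGES)

    poses = [resolve_pose(n, library) for n in pose_sequence]
    keyframes = np.zeros((len(poses), len(dof_names)))
    for i, pose in enumerate(poses):
        for dof, ang in pose.angle_map.items():
            if dof not in dof_names:
                raise KeyError(f"pose {pose.name!r} uses unknown DoF {dof!r}")
            keyframes[i, dof_names.index(dof)] = ang

    key_times = np.concatenate([[0.0], np.cumsum(durations)])
    n = int(round(key_times[-1] * fs_motion)) + 1
    time = np.arange(n) / fs_motion
    angles = np.empty((n, len(dof_names)))
    seg = np.clip(np.searchsorted(key_times, time, side="right") - 1,
                  0, len(durations) - 1)
    u = (time - key_times[seg]) / np.asarray(durations)[seg]
    u = np.clip(u, 0.0, 1.0)
    s = u if interpolation == "linear" else 0.5 - 0.5 * np.cos(np.pi * u)
    angles = (keyframes[seg] * (1.0 - s[:, None])
              + keyframes[seg + 1] * s[:, None])
    # keyframe samples exactly on the grid reproduce pose maps bit-exactly
    on_grid = np.round(key_times * fs_motion).astype(int)
    exact = np.abs(on_grid / fs_motion - key_times) < 1e-12
    angles[on_grid[exact]] = keyframes[exact]
    return JointTrajectory(dof_names, time, angles, fs_motion)


@dataclass
class RangeViolation:
    dof: str
    sample: int
    value: float
    lower: float
    upper: float


def check_joint_ranges(traj: JointTrajectory,
                       dof_ranges: dict[str, tuple[float, float]] | None = None,
                       ) -> list[RangeViolation]:
    """Report every (DoF, sample) outside its declared closed range."""
    dof_ranges = dof_ranges if dof_ranges is not None else DEFAULT_DOF_RANGES
    report = []
    for d, name in enumerate(traj.dof_names):
        if name not in dof_ranges:
            continue
        lo, hi = dof_ranges[name]
        bad = np.nonzero((traj.angles[:, d] < lo) | (traj.angles[:, d] > hi))[0]
        report.extend(RangeViolation(name, int(i), float(traj.angles[i, d]),
                                     lo, hi) for i in bad)
    return report


# ---------------------------------------------------------------------------
# .mot motion files
# ---------------------------------------------------------------------------

def write_mot(traj: JointTrajectory, path, name: str = "movement") -> None:
    """Write an OpenSim-style .mot file (tab-delimited, angles in degrees)."""
    n, d = traj.angles.shape
    with open(path, "w") as fh:
        fh.write(f"name {name}\n")
        fh.write(f"datacolumns {d + 1}\n")
        fh.write(f"datarows {n}\n")
        fh.write("inDegrees=yes\n")
        fh.write("endheader\n")
        fh.write("time\t" + "\t".join(traj.dof_names) + "\n")
        for i in range(n):
            row = [f"{traj.time[i]:.12g}"] + [f"{a:.12g}" for a in traj.angles[i]]
            fh.write("\t".join(row) + "\n")


def read_mot(path) -> JointTrajectory:
    """Read a .mot file written by :func:`write_mot` (or OpenSim)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = next(j for j, ln in enumerate(lines) if ln.strip() == "endheader")
    header = lines[i + 1].split("\t")
    if header[0].strip().lower() != "time":
        raise ValueError("first data column must be 'time'")
    dof_names = [h.strip() for h in header[1:]]
    data = np.array([[float(x) for x in ln.split("\t")]
                     for ln in lines[i + 2:] if ln.strip()])
    time = data[:, 0]
    fs = 1.0 / np.mean(np.diff(time)) if time.size > 1 else 1.0
    return JointTrajectory(dof_names, time, data[:, 1:], fs)


# ---------------------------------------------------------------------------
# Rigid-tendon fibre lengths
# ---------------------------------------------------------------------------

def fibre_length(muscle: MuscleModel, traj: JointTrajectory,
                 band: tuple[float, float] = (0.5, 1.5)) -> MuscleTrajectory:
    """Normalised fibre length from joint angles, rigid-tendon assumption.

    L_mt(t) = L_mt(0) - sum_d r_d (q_d(t) - q_d(0)) with q in radians, then
    l_norm = (L_mt - tendon_slack) / optimal_fibre_length, clipped to
    ``band``.  Positive moment arms shorten the muscle as the angle grows.
    """
    q = np.deg2rad(traj.angles)
    l_mt = np.full(traj.time.size, muscle.rest_musculotendon_length)
    for dof, r in muscle.moment_arms.items():
        if dof in traj.dof_names:
            d = traj.dof_names.index(dof)
            l_mt = l_mt - r * (q[:, d] - q[0, d])
    l_norm = (l_mt - muscle.tendon_slack_length) / muscle.optimal_fibre_length
    warnings = []
    if np.any(l_norm <= 0):
        warnings.append(
            f"{muscle.name}: non-positive fibre length at "
            f"{int(np.sum(l_norm <= 0))} samples before clipping")
    l_norm = np.clip(l_norm, band[0], band[1])
    return MuscleTrajectory(muscle.name, traj.time, l_norm, warnings=warnings)


def torque_demand(traj: JointTrajectory, dof: str,
                  inertia: float = 0.05, damping: float = 0.3,
                  stiffness: float = 0.0) -> np.ndarray:
    """Joint torque of a single-DoF rigid-body load: I q'' + b q' + k q (N m).

    The elastic term models movement against a spring-like load (k = 0 for a
    free movement); angles enter in radians.
    """
    q = np.deg2rad(traj.dof(dof))
    dt = 1.0 / traj.fs_motion
    dq = np.gradient(q, dt)
    ddq = np.gradient(dq, dt)
    return inertia * ddq + damping * dq + stiffness * q


def _force_length(l_norm: np.ndarray, width: float) -> np.ndarray:
    """Gaussian active force-length factor exp(-((l-1)/w)^2)."""
    return np.exp(-(((l_norm - 1.0) / width) ** 2))


def static_optimization_activations(
        muscles: list[MuscleModel],
        traj: JointTrajectory,
        torques: dict[str, np.ndarray],
        fl_width: float = 0.45,
        band: tuple[float, float] = (0.5, 1.5),
        tol: float = 1e-6):
    """Per-sample minimum-effort activations reproducing demanded torques.

    At each sample solves ``min sum_i a_i^2`` subject to
    ``sum_i a_i F_max,i f_L(l_i) r_i,d = tau_d`` for every demanded DoF d and
    ``0 <= a_i <= 1``.  Samples where the demand is infeasible fall back to
    the bounded least-squares closest point and are flagged.

    Returns ``(activations, infeasible)`` with activations of shape
    (n_samples, n_muscles) and infeasible a boolean (n_samples,) mask.
    """
    dofs = list(torques)
    for d in dofs:
        if not any(d in m.moment_arms for m in muscles):
            raise ValueError(f"no muscle spans demanded DoF {d!r}")
    n = traj.time.size
    m = len(muscles)
    lnorm = np.stack([fibre_length(mus, traj, band).fibre_length_norm
                      for mus in muscles], axis=1)          # (n, m)
    fmax = np.array([mus.max_isometric_force for mus in muscles])
    arms = np.array([[mus.moment_arms.get(d, 0.0) for mus in muscles]
                     for d in dofs])                        # (k, m)
    tau = np.stack([np.asarray(torques[d], dtype=float) for d in dofs])  # (k, n)

    activations = np.zeros((n, m))
    infeasible = np.zeros(n, dtype=bool)
    bounds = [(0.0, 1.0)] * m
    x0 = np.zeros(m)
    for i in range(n):
        # capacity matrix C[d, j]: torque about DoF d at full activation of j
        C = arms * (fmax * _force_length(lnorm[i], fl_width))[None, :]
        t = tau[:, i]
        if np.allclose(t, 0.0):
            x0 = np.zeros(m)
            continue
        res = optimize.minimize(
            lambda a: (a @ a, 2 * a),
            x0=np.clip(x0, 0, 1), jac=True, bounds=bounds,
            constraints=[{"type": "eq", "fun": lambda a, C=C, t=t: C @ a - t,
                          "jac": lambda a, C=C: C}],
            method="SLSQP", options={"maxiter": 200, "ftol": 1e-12})
        a = np.clip(res.x, 0.0, 1.0)
        if not res.success or np.max(np.abs(C @ a - t)) > max(tol, 1e-6 * np.max(np.abs(t))):
            lsq = optimize.lsq_linear(C, t, bounds=(0.0, 1.0))
            a = lsq.x
            infeasible[i] = True
        activations[i] = a
        x0 = a  # warm start the next sample
    return activations, infeasible
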