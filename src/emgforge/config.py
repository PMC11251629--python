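"""Default configuration: degree-of-freedom schema, muscle set, model constants.

The simulator targets the human forearm.  Movements are described over a
24-degree-of-freedom hand/wrist/forearm schema (finger joints, wrist
flexion/extension and radial/ulnar deviation, forearm pronation/supination,
elbow flexion).  Muscles are modelled as constant-moment-arm, rigid-tendon
actuators; the default set is the eight superficial forearm muscles commonly
covered by circumferential high-density EMG grids (the flexor carpi ulnaris
is split into its ulnar and humeral heads, giving nine entries).

All values here are documented defaults, overridable via YAML (`load_config`)
or by constructing :class:`MuscleModel` instances directly.  None of the
constants are hard-coded elsewhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

# ---------------------------------------------------------------------------
# Degree-of-freedom schema
# ---------------------------------------------------------------------------

#: name -> (lower, upper) closed range in degrees.
#: Sign conventions: wrist_flexion > 0 is flexion; wrist_deviation > 0 is
#: ulnar deviation; forearm_rotation > 0 is pronation.
DEFAULT_DOF_RANGES: dict[str, tuple[float, float]] = {
    "wrist_flexion": (-70.0, 70.0),
    "wrist_deviation": (-25.0, 35.0),
    "forearm_rotation": (-90.0, 90.0),
    "elbow_flexion": (0.0, 130.0),
    "thumb_cmc_flexion": (-15.0, 45.0),
    "thumb_cmc_abduction": (0.0, 60.0),
    "thumb_mp_flexion": (-10.0, 55.0),
    "thumb_ip_flexion": (-15.0, 80.0),
}
for _finger in ("index", "middle", "ring", "little"):
    DEFAULT_DOF_RANGES[f"{_finger}_mcp_flexion"] = (-45.0, 90.0)
    DEFAULT_DOF_RANGES[f"{_finger}_mcp_abduction"] = (-20.0, 20.0)
    DEFAULT_DOF_RANGES[f"{_finger}_pip_flexion"] = (0.0, 110.0)
    DEFAULT_DOF_RANGES[f"{_finger}_dip_flexion"] = (0.0, 80.0)

DEFAULT_DOF_NAMES: list[str] = list(DEFAULT_DOF_RANGES)
assert len(DEFAULT_DOF_NAMES) == 24


# ---------------------------------------------------------------------------
# Muscles
# ---------------------------------------------------------------------------

@dataclass
class MuscleModel:
    """Rigid-tendon, constant-moment-arm surrogate of one forearm muscle.

    Parameters
    ----------
    moment_arms
        DoF name -> signed moment arm in metres.  A positive moment arm means
        the musculotendon unit shortens as that joint angle increases, i.e.
        the muscle is an agonist of the positive angle direction.
    territory_centre_depth, territory_radius
        Centre depth below the skin and radius of the (circular) motor-unit
        territory in the muscle cross-section, in millimetres.
    ml_angle
        Circumferential position of the muscle centre around the forearm, in
        degrees (0-360, matching the electrode-grid column coordinate).
    """

    name: str
    optimal_fibre_length: float  # m
    tendon_slack_length: float   # m
    max_isometric_force: float   # N
    moment_arms: dict[str, float] = field(default_factory=dict)
    territory_centre_depth: float = 8.0   # mm
    territory_radius: float = 4.0         # mm
    ml_angle: float = 0.0                 # degrees
    n_units: int = 100
    total_fibres: int = 30000

    def __post_init__(self) -> None:
        if self.optimal_fibre_length <= 0:
            raise ValueError("optimal_fibre_length must be > 0")
        if self.territory_radius <= 0:
            raise ValueError("territory_radius must be > 0")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.total_fibres < self.n_units:
            raise ValueError("total_fibres must be >= n_units")

    @property
    def rest_musculotendon_length(self) -> float:
        """Musculotendon length in the neutral (all-zero) posture, metres."""
        return self.tendon_slack_length + self.optimal_fibre_length


def default_muscles() -> dict[str, MuscleModel]:
    """The default superficial forearm muscle set.

    Moment arms are stand-in constants chosen so that wrist/finger flexors
    shorten during flexion and extensors lengthen (the qualitative pattern the
    rigid-tendon model must reproduce); they are not subject-specific values.
    Extensors sit on the dorsal side of the circumference (small angles),
    flexors on the volar side.
    """
    m = {}
    m["ECRL"] = MuscleModel(
        "ECRL", 0.081, 0.224, 304.0,
        {"wrist_flexion": -0.014, "wrist_deviation": -0.009},
        territory_centre_depth=7.0, territory_radius=4.0, ml_angle=10.0)
    m["ECRB"] = MuscleModel(
        "ECRB", 0.059, 0.222, 100.0,
        {"wrist_flexion": -0.016, "wrist_deviation": -0.004},
        territory_centre_depth=8.0, territory_radius=4.0, ml_angle=35.0)
    m["ED"] = MuscleModel(
        "ED", 0.070, 0.322, 90.0,
        {"wrist_flexion": -0.012,
         "index_mcp_flexion": -0.008, "middle_mcp_flexion": -0.008,
         "ring_mcp_flexion": -0.008, "little_mcp_flexion": -0.008},
        territory_centre_depth=7.5, territory_radius=4.5, ml_angle=62.0)
    m["ECU"] = MuscleModel(
        "ECU", 0.062, 0.228, 94.0,
        {"wrist_flexion": -0.011, "wrist_deviation": 0.012},
        territory_centre_depth=8.0, territory_radius=4.0, ml_angle=95.0)
    m["FCU_h"] = MuscleModel(
        "FCU_h", 0.051, 0.265, 130.0,
        {"wrist_flexion": 0.014, "wrist_deviation": 0.012},
        territory_centre_depth=8.5, territory_radius=3.5, ml_angle=130.0)
    m["FCU_u"] = MuscleModel(
        "FCU_u", 0.053, 0.263, 130.0,
        {"wrist_flexion": 0.015, "wrist_deviation": 0.013},
        territory_centre_depth=8.0, territory_radius=3.5, ml_angle=155.0)
    m["PL"] = MuscleModel(
        "PL", 0.064, 0.269, 27.0,
        {"wrist_flexion": 0.012},
        territory_centre_depth=6.5, territory_radius=3.0, ml_angle=200.0)
    m["FDS"] = MuscleModel(
        "FDS", 0.073, 0.275, 260.0,
        {"wrist_flexion": 0.012,
         "index_mcp_flexion": 0.009, "middle_mcp_flexion": 0.009,
         "ring_mcp_flexion": 0.009, "little_mcp_flexion": 0.009,
         "index_pip_flexion": 0.006, "middle_pip_flexion": 0.006,
         "ring_pip_flexion": 0.006, "little_pip_flexion": 0.006},
        territory_centre_depth=9.0, territory_radius=5.0, ml_angle=235.0)
    m["FCR"] = MuscleModel(
        "FCR", 0.063, 0.244, 74.0,
        {"wrist_flexion": 0.015, "wrist_deviation": -0.007},
        territory_centre_depth=7.0, territory_radius=4.0, ml_angle=275.0)
    return m


# ---------------------------------------------------------------------------
# Motor-unit pool constants
# ---------------------------------------------------------------------------

@dataclass
class PoolConfig:
    """Constants of the motoneuron-pool models.

    The classical (Fuglevand-style) recruitment/rate-coding constants follow
    the canonical parameterisation of that model family: recruitment range
    RR = 30, twitch-force range RP = 100, minimum firing rate 8 Hz, peak
    firing rates 35 Hz (first-recruited) down to 25 Hz (last-recruited),
    inter-spike-interval coefficient of variation 0.2.

    ``gain`` is the rate-coding gain in Hz per unit of *normalised* drive
    (drive in [0, 1], last recruitment threshold at 1.0).  The default of
    30 Hz per unit drive is the classical "1 Hz per excitation unit" once the
    excitation axis (thresholds spanning 1..RR) is rescaled to [1/RR, 1].
    """

    RR: float = 30.0           # recruitment range (last/first threshold)
    RP: float = 100.0          # twitch-force range, classical model
    MFR: float = 8.0           # Hz, minimum firing rate
    PFR_first: float = 35.0    # Hz, peak rate of first-recruited unit
    PFR_last: float = 25.0     # Hz, peak rate of last-recruited unit
    gain: float = 30.0         # Hz per unit normalised drive
    isi_cv: float = 0.2        # ISI coefficient of variation
    min_isi: float = 0.005     # s, refractory floor on inter-spike intervals

    # property distributions
    cv_mean: float = 4.0       # m/s, fibre conduction velocity
    cv_sd: float = 0.35        # m/s
    cv_range: tuple[float, float] = (3.0, 6.0)   # m/s, clamp + LIF size map
    iz_mean: float = 0.5       # innervation-zone position, fraction of fibre
    iz_sd: float = 0.05
    iz_range: tuple[float, float] = (0.3, 0.7)
    fibre_len_sd: float = 5.0  # mm, around the muscle optimal length

    # LIF cohort endpoints (first-recruited -> last-recruited), affine in rank
    lif_R: tuple[float, float] = (2.0, 0.7)       # MOhm
    lif_tau: tuple[float, float] = (6.0, 7.0)     # ms
    lif_v_th: tuple[float, float] = (15.0, 15.0)  # mV
    lif_t_ref: tuple[float, float] = (25.0, 35.0) # ms
    # input scale margin so a unit fires (in finite time) once the drive
    # reaches its nominal recruitment threshold, rather than approaching
    # the voltage threshold asymptotically
    lif_threshold_margin: float = 1.15


# ---------------------------------------------------------------------------
# Electrode grid / MUAP model constants
# ---------------------------------------------------------------------------

@dataclass
class GridSpec:
    """Cylindrical high-density electrode grid around the forearm.

    10 axial rows (proximal -> distal) x 32 circumferential columns on a
    cylinder; channel index = row * n_cols + col (row-major, 0-based).
    """

    n_rows: int = 10
    n_cols: int = 32
    radius_mm: float = 40.0
    ied_mm: float = 10.0      # axial inter-electrode distance
    fs_muap: float = 2048.0   # Hz, MUAP template sampling rate
    n_samples: int = 128      # template length

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols


@dataclass
class ConditionRanges:
    """Affine maps between relative condition values in (0, 1] and physical units.

    The MUAP generator is conditioned on seven relative parameters; these
    ranges define what relative 0 and 1 mean physically.  They are artifact
    configuration, not measured values.
    """

    depth_mm: tuple[float, float] = (2.0, 18.0)
    cv_ms: tuple[float, float] = (3.0, 6.0)
    fibre_length_mm: tuple[float, float] = (40.0, 140.0)
    iz_fraction: tuple[float, float] = (0.25, 0.75)
    # ml_pos: relative value maps linearly to [0, 360) degrees
    # fibre_number and fat_conductivity are already relative amplitudes

    def to_physical(self, name: str, rel: float) -> float:
        lo, hi = getattr(self, name)
        return lo + rel * (hi - lo)

    def to_relative(self, name: str, phys: float) -> float:
        lo, hi = getattr(self, name)
        return (phys - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# Whole-simulation configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    dof_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DOF_RANGES))
    muscles: dict[str, MuscleModel] = field(default_factory=default_muscles)
    pool: PoolConfig = field(default_factory=PoolConfig)
    grid: GridSpec = field(default_factory=GridSpec)
    cond_ranges: ConditionRanges = field(default_factory=ConditionRanges)
    # rigid-body dynamics of the torque-demand helper, per DoF
    inertia: float = 0.05     # kg m^2
    damping: float = 0.3      # N m s / rad
    stiffness: float = 0.0    # N m / rad, elastic load (0 = free movement)
    # force-length relation width and fibre-length clipping band
    fl_width: float = 0.45
    fibre_length_band: tuple[float, float] = (0.5, 1.5)
    # parameter-tracking power laws
    cv_exponent: float = -0.5
    depth_exponent: float = -0.5
    fs_emg: float = 2048.0    # Hz, EMG sampling rate

    @property
    def dof_names(self) -> list[str]:
        return list(self.dof_ranges)


def load_config(path) -> SimConfig:
    """Load a SimConfig from a YAML file; unspecified keys keep defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = SimConfig()
    if "dof_ranges" in raw:
        cfg.dof_ranges = {k: (float(v[0]), float(v[1]))
                          for k, v in raw["dof_ranges"].items()}
    if "muscles" in raw:
        cfg.muscles = {name: MuscleModel(name=name, **spec)
                       for name, spec in raw["muscles"].items()}
    for section, cls in (("pool", PoolConfig), ("grid", GridSpec),
                         ("cond_ranges", ConditionRanges)):
        if section in raw:
            base = asdict(getattr(cfg, section))
            base.update(raw[section])
            # tuples arrive from YAML as lists
            base = {k: tuple(v) if isinstance(v, list) else v
                    for k, v in base.items()}
            setattr(cfg, section, cls(**base))
    for key in ("inertia", "damping", "stiffness", "fl_width",
                "cv_exponent", "depth_exponent", "fs_emg"):
        if key in raw:
            setattr(cfg, key, float(raw[key]))
    if "fibre_length_band" in raw:
        cfg.fibre_length_band = tuple(float(x) for x in raw["fibre_length_band"])
    return cfg


def dump_config(cfg: SimConfig, path) -> None:
    """Write a SimConfig to YAML (muscles serialised field-wise)."""
    raw = {
        "dof_ranges": {k: list(v) for k, v in cfg.dof_ranges.items()},
        "muscles": {
            name: {k: v for k, v in asdict(mus).items() if k != "name"}
            for name, mus in cfg.muscles.items()
        },
        "pool": asdict(cfg.pool),
        "grid": asdict(cfg.grid),
        "cond_ranges": asdict(cfg.cond_ranges),
        "inertia": cfg.inertia,
        "damping": cfg.damping,
        "stiffness": cfg.stiffness,
        "fl_width": cfg.fl_width,
        "fibre_length_band": list(cfg.fibre_length_band),
        "cv_exponent": cfg.cv_exponent,
        "depth_exponent": cfg.depth_exponent,
        "fs_emg": cfg.fs_emg,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
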