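"""Motor-unit pools: property distributions and spike-train generation.

A motoneuron pool is the population of motor units innervating one muscle.
Two discharge models are provided:

* the **classical** recruitment/rate-coding model: each unit has an
  exponentially distributed recruitment threshold; once the normalised drive
  E(t) exceeds the threshold the unit fires at
  ``FR = MFR + gain * (E - theta)`` clipped between the minimum rate and its
  peak rate, with Gaussian inter-spike-interval jitter;
* a **LIF cohort**: one leaky integrate-and-fire motoneuron per unit
  (parallel leaky resistor + capacitor), integrated by forward Euler; a spike
  is emitted when the membrane voltage reaches threshold, followed by an
  absolute refractory period.

Both models obey Henneman's size principle (small units recruit first) and
the onion-skin observation (earlier-recruited units fire faster at any common
drive); both receive the same normalised drive in [0, 1], where 1.0 is the
drive at which the last unit is recruited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
from scipy import stats

from .config import MuscleModel, PoolConfig
from ._seeds import child_rng, child_seed

__all__ = [
    "MotorUnit", "MotorUnitPool", "SpikeTrainSet",
    "twitch_distribution", "allocate_sizes", "init_pool",
    "fuglevand_spikes", "lif_spikes", "drive_profile",
    "write_spikes", "read_spikes",
]


# ---------------------------------------------------------------------------
# Data types
# ---------------------------------------------------------------------------

@dataclass
class MotorUnit:
    rank: int                    # 1-based recruitment rank
    size: int                    # innervated fibre count
    twitch_amp: float            # relative twitch force
    recruitment_threshold: float # fraction of maximal drive, (0, 1]
    cv: float                    # m/s
    depth: float                 # mm below skin surface
    ml_pos: float                # mm, medial-lateral offset in the territory
    iz_pos: float                # innervation zone, fraction of fibre length
    fibre_length: float          # mm
    peak_rate: float             # Hz (classical model)
    latent_seed: int = 0
    # LIF parameters
    R: float = 1.0               # MOhm
    tau: float = 6.0             # ms
    v_th: float = 15.0           # mV
    t_ref: float = 30.0          # ms
    i_max: float = 0.0           # nA at drive 1.0


@dataclass
class MotorUnitPool:
    muscle: str
    model_kind: str              # "classical" | "lif"
    units: list[MotorUnit]
    config: PoolConfig = field(default_factory=PoolConfig)

    @property
    def n_units(self) -> int:
        return len(self.units)

    def thresholds(self) -> np.ndarray:
        return np.array([u.recruitment_threshold for u in self.units])


@dataclass
class SpikeTrainSet:
    fs: float
    trains: list[np.ndarray]     # per-unit sorted spike times, seconds
    drive: np.ndarray            # the input series that produced them

    @property
    def n_units(self) -> int:
        return len(self.trains)

    @property
    def total_spikes(self) -> int:
        return int(sum(t.size for t in self.trains))


# ---------------------------------------------------------------------------
# Property distributions
# ---------------------------------------------------------------------------

def twitch_distribution(model_kind: str, N: int, rp: float = 100.0) -> np.ndarray:
    """Relative peak twitch forces of units 1..N, strictly increasing.

    classical: exponential across ranks, ftw(j) = exp(ln(RP) * j / N) so the
    largest unit's twitch is RP times scale of the distribution.
    lif: the linear-exponential law fitted to human forearm measurements,
    ftw(j) = 0.81 * (18.51 * (j/N) + 104.10 * (j/N)^4.83).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    j = np.arange(1, N + 1, dtype=float)
    if model_kind == "classical":
        return np.exp(np.log(rp) * j / N)
    if model_kind == "lif":
        x = j / N
        return 0.81 * (18.51 * x + 104.10 * x ** 4.83)
    raise ValueError(f"unknown model_kind {model_kind!r}")


def allocate_sizes(twitch_amp: np.ndarray, n_fibres: int) -> np.ndarray:
    """Integer fibre counts proportional to twitch amplitude.

    Largest-remainder rounding of the exact quotas
    ``q_j = twitch_j / sum(twitch) * n_fibres`` so that the sizes sum to
    ``n_fibres`` exactly; every unit keeps at least one fibre (enforced by
    transferring fibres from the largest units if rounding left zeros).
    """
    tw = np.asarray(twitch_amp, dtype=float)
    N = tw.size
    if n_fibres < N:
        raise ValueError("n_fibres must be >= number of units")
    quota = tw / tw.sum() * n_fibres
    sizes = np.floor(quota).astype(int)
    remainder = n_fibres - sizes.sum()
    # ties broken toward lower rank (stable sort on negated fraction)
    order = np.argsort(-(quota - sizes), kind="stable")
    sizes[order[:remainder]] += 1
    while np.any(sizes == 0):
        zero = int(np.argmax(sizes == 0))
        donor = int(np.argmax(sizes))
        sizes[zero] += 1
        sizes[donor] -= 1
    assert sizes.sum() == n_fibres
    return sizes


def _truncated_normal(rng, mean, sd, lo, hi, size):
    if sd <= 0:
        raise ValueError("distribution sd must be > 0")
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def init_pool(muscle: MuscleModel, model_kind: str = "classical",
              config: PoolConfig | None = None, seed: int = 0) -> MotorUnitPool:
    """Initialise a motor-unit pool for one muscle.

    Property distributions:

    * twitch amplitudes from :func:`twitch_distribution`; fibre counts from
      :func:`allocate_sizes` (conserving the muscle's total fibre count);
    * recruitment thresholds exponential in rank, normalised so the last unit
      recruits at drive 1.0: ``theta_j = exp(ln(RR) j / N) / RR``;
    * conduction velocity: classical — Normal(cv_mean, cv_sd) clamped to the
      common range and sorted ascending so CV pairs with ascending size;
      lif — increasing affine map of normalised twitch amplitude onto the
      common CV range (a surrogate for the axonal CV / neuron surface-area
      relation);
    * depth and medial-lateral position uniform in the territory disk;
    * innervation zone and fibre length truncated-Normal within their ranges;
    * peak firing rates affine from PFR_first (rank 1) to PFR_last (rank N);
    * LIF membrane parameters affine between the configured endpoints, and
      the per-unit input scale chosen so the LIF cohort recruits at the same
      exponential thresholds as the classical model:
      ``i_max = margin * v_th / (R theta)`` (the small suprathreshold margin
      makes a unit fire in finite time once the drive reaches its threshold).

    Per-unit random draws come from independent child streams keyed by
    (seed, muscle, rank), so adding a unit never perturbs the others.
    """
    cfg = config if config is not None else PoolConfig()
    N = muscle.n_units
    kinds = ("classical", "lif")
    if model_kind not in kinds:
        raise ValueError(f"model_kind must be one of {kinds}")
    tw = twitch_distribution(model_kind, N, rp=cfg.RP)
    sizes = allocate_sizes(tw, muscle.total_fibres)
    j = np.arange(1, N + 1, dtype=float)
    theta = np.exp(np.log(cfg.RR) * j / N)
    theta /= theta[-1]  # last unit recruits at drive exactly 1.0
    pfr = cfg.PFR_first + (cfg.PFR_last - cfg.PFR_first) * (j - 1) / max(N - 1, 1)

    draws = np.empty((N, 5))
    for r in range(N):
        rng = child_rng(seed, muscle.name, r + 1)
        draws[r] = rng.standard_normal(1)[0], *rng.uniform(size=2), \
            *rng.standard_normal(2)
    # conduction velocity
    if model_kind == "classical":
        cv = np.clip(cfg.cv_mean + cfg.cv_sd * draws[:, 0], *cfg.cv_range)
        cv = np.sort(cv)
    else:
        tw_norm = (tw - tw[0]) / (tw[-1] - tw[0]) if N > 1 else np.array([0.5])
        cv = cfg.cv_range[0] + tw_norm * (cfg.cv_range[1] - cfg.cv_range[0])
    # positions uniform in the territory disk
    rad = muscle.territory_radius * np.sqrt(draws[:, 1])
    phi = 2 * np.pi * draws[:, 2]
    depth = muscle.territory_centre_depth + rad * np.cos(phi)
    ml = rad * np.sin(phi)
    # innervation zone / fibre length, truncated normal
    iz = np.clip(cfg.iz_mean + cfg.iz_sd * draws[:, 3],
                 cfg.iz_range[0], cfg.iz_range[1])
    fl_mean = muscle.optimal_fibre_length * 1000.0
    fl = np.clip(fl_mean + cfg.fibre_len_sd * draws[:, 4],
                 0.5 * fl_mean, 1.5 * fl_mean)

    x = (j - 1) / max(N - 1, 1)
    R = cfg.lif_R[0] + (cfg.lif_R[1] - cfg.lif_R[0]) * x
    tau = cfg.lif_tau[0] + (cfg.lif_tau[1] - cfg.lif_tau[0]) * x
    v_th = cfg.lif_v_th[0] + (cfg.lif_v_th[1] - cfg.lif_v_th[0]) * x
    t_ref = cfg.lif_t_ref[0] + (cfg.lif_t_ref[1] - cfg.lif_t_ref[0]) * x
    i_max = cfg.lif_threshold_margin * v_th / (R * theta)

    units = [MotorUnit(
        rank=r + 1, size=int(sizes[r]), twitch_amp=float(tw[r]),
        recruitment_threshold=float(theta[r]), cv=float(cv[r]),
        depth=float(depth[r]), ml_pos=float(ml[r]), iz_pos=float(iz[r]),
        fibre_length=float(fl[r]), peak_rate=float(pfr[r]),
        latent_seed=child_seed(seed, muscle.name, r + 1, "latent"),
        R=float(R[r]), tau=float(tau[r]), v_th=float(v_th[r]),
        t_ref=float(t_ref[r]), i_max=float(i_max[r]),
    ) for r in range(N)]
    return MotorUnitPool(muscle.name, model_kind, units, cfg)


# ---------------------------------------------------------------------------
# Drive profiles
# ---------------------------------------------------------------------------

def drive_profile(kind: str, amplitude: float, duration: float, fs: float,
                  ramp_frac: float = 0.25, freq: float = 0.5,
                  offset: float = 0.0) -> np.ndarray:
    """Built-in neural-drive profiles, values clipped to [0, 1].

    kinds: ``constant``, ``trapezoid`` (linear up / plateau / linear down,
    ramps each ``ramp_frac`` of the duration), ``triangle`` (up then down),
    ``sinusoid`` (offset + amplitude * sin, rectified into [0, 1]).
    """
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs
    if kind == "constant":
        d = np.full(n, amplitude)
    elif kind == "trapezoid":
        up, down = ramp_frac * duration, (1 - ramp_frac) * duration
        d = amplitude * np.minimum.reduce([
            np.clip(t / up, 0, 1),
            np.clip((duration - t) / (duration - down), 0, 1),
            np.ones(n)])
    elif kind == "triangle":
        half = duration / 2
        d = amplitude * (1 - np.abs(t - half) / half)
    elif kind == "sinusoid":
        d = offset + amplitude * np.sin(2 * np.pi * freq * t)
    else:
        raise ValueError(f"unknown drive kind {kind!r}")
    return np.clip(d, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Spike generation
# ---------------------------------------------------------------------------

def _check_drive(drive: np.ndarray) -> np.ndarray:
    drive = np.asarray(drive, dtype=float)
    if drive.min() < 0.0 or drive.max() > 1.0:
        raise ValueError("drive must lie within [0, 1]")
    return drive


def fuglevand_spikes(pool: MotorUnitPool, drive: np.ndarray, fs: float,
                     seed: int = 0) -> SpikeTrainSet:
    """Classical recruitment / rate-coding spike trains.

    Once the drive exceeds a unit's threshold its instantaneous rate is
    ``MFR + gain * (E - theta)`` clipped to [MFR, PFR_j].  Inter-spike
    intervals are drawn as ``(1/FR) * (1 + isi_cv * z)`` with z standard
    Normal truncated at +/-3.9 sd; a unit falls silent whenever the drive
    drops below its threshold.  Requires fs >= 1000 Hz.
    """
    if fs < 1000:
        raise ValueError("fs must be >= 1000 Hz for spike placement accuracy")
    drive = _check_drive(drive)
    cfg = pool.config
    duration = (drive.size - 1) / fs
    trains = []
    for u in pool.units:
        rng = child_rng(seed, pool.muscle, u.rank, "fuglevand")
        theta = u.recruitment_threshold
        above = drive >= theta
        spikes = []
        idx = int(np.argmax(above)) if above.any() else None
        t = None if idx is None else idx / fs
        while t is not None and t <= duration:
            e = drive[int(round(t * fs))]
            if e < theta:
                # silent: resume at the next threshold crossing
                later = np.nonzero(above[int(round(t * fs)):])[0]
                if later.size == 0:
                    break
                t = (int(round(t * fs)) + later[0]) / fs
                e = drive[int(round(t * fs))]
            spikes.append(t)
            fr = np.clip(cfg.MFR + cfg.gain * (e - theta), cfg.MFR, u.peak_rate)
            z = np.clip(rng.standard_normal(), -3.9, 3.9)
            isi = max((1.0 / fr) * (1.0 + cfg.isi_cv * z), cfg.min_isi)
            t = t + isi
        trains.append(np.array(spikes))
    return SpikeTrainSet(fs=fs, trains=trains, drive=drive)


def lif_spikes(pool: MotorUnitPool, drive: np.ndarray, fs: float,
               seed: int = 0, v_noise: float = 0.0) -> SpikeTrainSet:
    """LIF-cohort spike trains by forward-Euler integration.

    Per unit: ``dV/dt = (R I(t) - V) / tau`` with ``I(t) = drive(t) * i_max``;
    a spike resets V to 0 and holds it there for the absolute refractory
    period.  ``v_noise`` adds white membrane noise (mV per sqrt(step)); the
    default cohort is deterministic.  fs >= 10 kHz is recommended for
    integration accuracy (a warning entry is attached below that).
    """
    import warnings as _warnings
    if fs < 10000:
        _warnings.warn("fs below 10 kHz degrades LIF integration accuracy",
                       stacklevel=2)
    drive = _check_drive(drive)
    n = drive.size
    dt = 1.0 / fs
    N = pool.n_units
    R = np.array([u.R for u in pool.units])
    tau = np.array([u.tau for u in pool.units]) * 1e-3       # s
    v_th = np.array([u.v_th for u in pool.units])
    t_ref = np.array([u.t_ref for u in pool.units]) * 1e-3   # s
    i_max = np.array([u.i_max for u in pool.units])
    rng = child_rng(seed, pool.muscle, "lif")

    V = np.zeros(N)
    ref_until = np.full(N, -1.0)
    spikes: list[list[float]] = [[] for _ in range(N)]
    for i in range(n):
        t = i * dt
        I = drive[i] * i_max
        in_ref = t < ref_until
        dV = dt * (R * I - V) / tau
        if v_noise > 0:
            dV = dV + v_noise * np.sqrt(dt) * rng.standard_normal(N)
        V = np.where(in_ref, 0.0, V + dV)
        fired = (V >= v_th) & ~in_ref
        if fired.any():
            for k in np.nonzero(fired)[0]:
                spikes[k].append(t)
            V[fired] = 0.0
            ref_until[fired] = t + t_ref[fired]
    return SpikeTrainSet(fs=fs, trains=[np.array(s) for s in spikes],
                         drive=drive)


def lif_isi_closed_form(R: float, tau_ms: float, v_th: float,
                        t_ref_ms: float, current: float) -> float:
    """Steady-state inter-spike interval of a LIF neuron at constant input.

    ``ISI = t_ref + tau * ln(R I / (R I - v_th))`` (seconds); the current must
    be suprathreshold (R I > v_th).
    """
    x = R * current
    if x <= v_th:
        raise ValueError("subthreshold input: no steady-state firing")
    return t_ref_ms * 1e-3 + tau_ms * 1e-3 * np.log(x / (x - v_th))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_spikes(spikes: SpikeTrainSet, path, pool: MotorUnitPool | None = None
                 ) -> None:
    """Two-column text (unit_rank, spike_time_s) plus a JSON metadata sidecar."""
    with open(path, "w") as fh:
        fh.write("unit_rank\tspike_time_s\n")
        for rank, train in enumerate(spikes.trains, start=1):
            for t in train:
                fh.write(f"{rank}\t{t:.9f}\n")
    meta = {"fs": spikes.fs, "n_units": spikes.n_units,
            "duration": float((spikes.drive.size - 1) / spikes.fs)}
    if pool is not None:
        meta.update(muscle=pool.muscle, model_kind=pool.model_kind)
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_spikes(path) -> SpikeTrainSet:
    ranks, times = [], []
    with open(path) as fh:
        next(fh)
        for line in fh:
            r, t = line.split("\t")
            ranks.append(int(r))
            times.append(float(t))
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    trains = [np.array([t for r, t in zip(ranks, times) if r == k])
              for k in range(1, meta["n_units"] + 1)]
    n = int(round(meta["duration"] * meta["fs"])) + 1
    return SpikeTrainSet(fs=meta["fs"], trains=trains, drive=np.zeros(n))
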