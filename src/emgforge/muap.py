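"""Motor-unit action potential (MUAP) templates on a cylindrical grid.

Templates are produced by a deterministic analytical line-source
volume-conductor model, conditioned on seven relative physiological
parameters per motor unit:

    fat_conductivity, fibre_number, depth, ml_pos, iz_pos, cv, fibre_length

The source is the equivalent fibre of the unit, placed inside a cylindrical
volume conductor of the forearm.  At discharge, two travelling dipoles leave
the innervation zone (IZ) toward the two fibre ends at the conduction
velocity and extinguish at the ends; each dipole is a leading/trailing pole
pair (depolarisation front followed by repolarisation), which yields the
characteristic biphasic surface waveform.  The electrode potential is the
sum over poles of ``amplitude / (sigma_eff * distance)`` evaluated at the
10 x 32 electrodes on the cylinder surface, then smoothed spatially to mimic
the low-pass effect of the subcutaneous fat layer.

Each unit carries a fixed latent vector (drawn once per unit from a standard
Normal) that perturbs pole amplitudes and the IZ position by a bounded
(+/-10 %) deterministic amount: when a template sequence is morphed along a
movement the latent stays fixed, so the waveforms change only through the
physiological parameters.

This generator intentionally honours the same conditioning interface as
learned MUAP generators, so externally produced template tensors (same
hierarchical container layout) can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict

import numpy as np
import h5py
from scipy import ndimage

from .config import GridSpec, ConditionRanges
from .params import ParameterTrajectory
from ._seeds import child_rng

__all__ = [
    "ConditionVector", "MUAPTemplate", "MUAPSequence",
    "sample_latent", "generate_muap", "morph_sequence",
    "save_muaps", "load_muaps",
]

LATENT_DIM = 16


@dataclass(frozen=True)
class ConditionVector:
    """The seven relative conditioning parameters, each within (0, 1].

    ``iz_pos`` lives in (0, 1) (a fraction of fibre length cannot sit on a
    fibre end).  Physical units are recovered through the affine maps in
    :class:`~emgforge.config.ConditionRanges`.
    """

    fat_conductivity: float
    fibre_number: float
    depth: float
    ml_pos: float
    iz_pos: float
    cv: float
    fibre_length: float

    def __post_init__(self) -> None:
        for name in ("fat_conductivity", "fibre_number", "depth",
                     "ml_pos", "cv", "fibre_length"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} outside (0, 1]")
        if not 0.0 < self.iz_pos < 1.0:
            raise ValueError(f"iz_pos={self.iz_pos} outside (0, 1)")

    def as_array(self) -> np.ndarray:
        return np.array([self.fat_conductivity, self.fibre_number, self.depth,
                         self.ml_pos, self.iz_pos, self.cv, self.fibre_length])


@dataclass
class MUAPTemplate:
    """Potential template on the electrode grid: shape (n_rows, n_cols, T)."""

    values: np.ndarray
    fs: float
    condition: ConditionVector | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("template must be (rows, cols, samples)")

    @property
    def peak_to_peak(self) -> float:
        return float(self.values.max() - self.values.min())


@dataclass
class MUAPSequence:
    """Keyframed template sequence of one unit during a movement."""

    keyframe_times: np.ndarray
    templates: list[MUAPTemplate]
    unit_id: int = 0
    latent_seed: int = 0

    def __post_init__(self) -> None:
        self.keyframe_times = np.asarray(self.keyframe_times, dtype=float)
        if np.any(np.diff(self.keyframe_times) <= 0):
            raise ValueError("keyframe_times must be strictly increasing")
        shapes = {t.values.shape for t in self.templates}
        if len(shapes) > 1:
            raise ValueError("all templates must share one shape")


def sample_latent(unit_id: int, root_seed: int, dim: int = LATENT_DIM
                  ) -> np.ndarray:
    """Fixed per-unit latent: standard Normal, pure function of (unit, seed)."""
    return child_rng(root_seed, "latent", unit_id).standard_normal(dim)


# ---------------------------------------------------------------------------
# Line-source generator
# ---------------------------------------------------------------------------

def _smooth_ramp(x: np.ndarray) -> np.ndarray:
    """Half-cosine ramp from 0 to 1 on x in [0, 1], clamped outside."""
    return 0.5 - 0.5 * np.cos(np.pi * np.clip(x, 0.0, 1.0))


def generate_muap(cond: ConditionVector,
                  latent: np.ndarray | None = None,
                  grid: GridSpec | None = None,
                  ranges: ConditionRanges | None = None,
                  onset_s: float = 0.002) -> MUAPTemplate:
    """One MUAP template from the analytical line-source model.

    The fibre sits at depth ``depth`` below the cylinder surface at
    circumferential angle ``ml_pos * 360 deg``, axially centred, with the IZ
    at fraction ``iz_pos`` of its length.  Two dipoles depart the IZ at
    ``onset_s`` and travel at the conduction velocity until they reach the
    fibre ends, where they extinguish over a short ramp.  Pole amplitude is
    proportional to ``fibre_number`` (the template is exactly linear in it)
    and to ``fat_conductivity``; lower fat conductivity additionally widens
    the spatial smoothing, blurring the surface pattern.
    """
    grid = grid if grid is not None else GridSpec()
    ranges = ranges if ranges is not None else ConditionRanges()
    if latent is None:
        latent = np.zeros(LATENT_DIM)

    depth_mm = ranges.to_physical("depth_mm", cond.depth)
    v_mm_s = ranges.to_physical("cv_ms", cond.cv) * 1000.0
    L = ranges.to_physical("fibre_length_mm", cond.fibre_length)
    iz_frac = ranges.to_physical("iz_fraction", cond.iz_pos)
    phi_f = 2.0 * np.pi * cond.ml_pos

    # bounded deterministic latent perturbations (+/-10 % amplitude,
    # +/-5 % of fibre length on the IZ)
    amp_pert = 1.0 + 0.10 * np.tanh(latent[0])
    iz_frac = float(np.clip(iz_frac + 0.05 * np.tanh(latent[1]), 0.05, 0.95))

    sigma_eff = 1.0 / cond.fat_conductivity          # relative tissue impedance
    amp = cond.fibre_number * amp_pert / sigma_eff

    t = np.arange(grid.n_samples) / grid.fs_muap     # (T,)
    rows = (np.arange(grid.n_rows) - (grid.n_rows - 1) / 2.0) * grid.ied_mm
    cols = 2.0 * np.pi * np.arange(grid.n_cols) / grid.n_cols

    # fibre geometry (axially centred on the grid)
    z_iz = (iz_frac - 0.5) * L
    rho_f = grid.radius_mm - depth_mm
    rho_e = grid.radius_mm
    # chordal electrode-to-fibre-axis distance in the cross-section plane
    cross_d2 = (rho_e ** 2 + rho_f ** 2
                - 2.0 * rho_e * rho_f * np.cos(cols - phi_f))  # (n_cols,)

    dip_sep = max(v_mm_s * 0.0012, 1.0)   # mm, depol->repol pole separation
    ramp_s = 0.0008                       # s, onset/extinction ramp

    vals = np.zeros((grid.n_rows, grid.n_cols, t.size))
    for direction in (+1.0, -1.0):
        end = direction * L / 2.0
        flight = abs(end - z_iz) / v_mm_s
        if flight <= 0:
            continue
        tt = t - onset_s
        z_front = z_iz + direction * v_mm_s * np.clip(tt, 0.0, flight)
        # envelope: ramp in at the IZ, ramp out at the fibre end
        env = (_smooth_ramp(tt / ramp_s)
               * (1.0 - _smooth_ramp((tt - flight) / ramp_s)))
        for pole_amp, lag in ((+amp, 0.0), (-amp, dip_sep)):
            z_p = z_front - direction * lag
            # trailing pole stays within the fibre
            z_p = np.clip(z_p, min(z_iz, end), max(z_iz, end))
            d = np.sqrt(cross_d2[None, :, None]
                        + (rows[:, None, None] - z_p[None, None, :]) ** 2)
            vals += pole_amp * env[None, None, :] / np.maximum(d, 1.0)

    # fat-layer spatial low-pass: wider blur for less conductive fat
    sigma_smooth = 0.35 + 0.6 * (1.0 - cond.fat_conductivity)
    vals = ndimage.gaussian_filter1d(vals, sigma_smooth, axis=1, mode="wrap")
    vals = ndimage.gaussian_filter1d(vals, sigma_smooth, axis=0,
                                     mode="nearest")
    return MUAPTemplate(vals, fs=grid.fs_muap, condition=cond)


def _scaled_condition(base: ConditionVector, ranges: ConditionRanges,
                      length_scale: float, cv_scale: float,
                      depth_scale: float) -> ConditionVector:
    """Apply multiplicative physical scales to length, CV and depth, clamped
    back into the valid relative range."""
    eps = 1e-6

    def scale(name: str, rel: float, s: float) -> float:
        phys = ranges.to_physical(name, rel) * s
        return float(np.clip(ranges.to_relative(name, phys), eps, 1.0))

    return replace(
        base,
        fibre_length=scale("fibre_length_mm", base.fibre_length, length_scale),
        cv=scale("cv_ms", base.cv, cv_scale),
        depth=scale("depth_mm", base.depth, depth_scale),
    )


def morph_sequence(base_cond: ConditionVector,
                   param_traj: ParameterTrajectory,
                   n_keyframes: int = 16,
                   latent: np.ndarray | None = None,
                   grid: GridSpec | None = None,
                   ranges: ConditionRanges | None = None,
                   unit_id: int = 0,
                   latent_seed: int = 0,
                   resample_latent: bool = False) -> MUAPSequence:
    """Template sequence along a parameter trajectory, latent held fixed.

    At each of ``n_keyframes`` times (uniform over the trajectory span) the
    base condition's fibre length, conduction velocity and depth are
    multiplied by the trajectory scales interpolated at that time, clamped to
    the valid range, and a template is generated.  ``resample_latent=True``
    draws a fresh latent per keyframe instead (prior-sampling mode).
    """
    if n_keyframes < 2:
        raise ValueError("n_keyframes must be >= 2")
    ranges = ranges if ranges is not None else ConditionRanges()
    if latent is None:
        latent = sample_latent(unit_id, latent_seed)
    tt = param_traj.time
    times = np.linspace(tt[0], tt[-1], n_keyframes)
    templates = []
    for k, tk in enumerate(times):
        ls = np.interp(tk, tt, param_traj.fibre_length_scale)
        cs = np.interp(tk, tt, param_traj.cv_scale)
        ds = np.interp(tk, tt, param_traj.depth_scale)
        cond_k = _scaled_condition(base_cond, ranges, ls, cs, ds)
        lat_k = (sample_latent(unit_id, latent_seed + 1 + k)
                 if resample_latent else latent)
        templates.append(generate_muap(cond_k, lat_k, grid, ranges))
    return MUAPSequence(times, templates, unit_id=unit_id,
                        latent_seed=latent_seed)


# ---------------------------------------------------------------------------
# Hierarchical container I/O
# ---------------------------------------------------------------------------

def save_muaps(path, sequences: dict[str, dict[int, MUAPSequence]]) -> None:
    """Store ``muscle -> unit -> MUAPSequence`` as /muscle/unit/keyframe
    datasets with condition attributes."""
    with h5py.File(path, "w") as fh:
        for muscle, units in sequences.items():
            g_mus = fh.create_group(muscle)
            for unit_id, seq in units.items():
                g = g_mus.create_group(f"unit_{unit_id:04d}")
                g.attrs["unit_id"] = unit_id
                g.attrs["latent_seed"] = seq.latent_seed
                g.attrs["keyframe_times"] = seq.keyframe_times
                for k, tpl in enumerate(seq.templates):
                    ds = g.create_dataset(f"keyframe_{k:03d}",
                                          data=tpl.values)
                    ds.attrs["fs"] = tpl.fs
                    if tpl.condition is not None:
                        for name, v in asdict(tpl.condition).items():
                            ds.attrs[name] = v


def load_muaps(path) -> dict[str, dict[int, MUAPSequence]]:
    out: dict[str, dict[int, MUAPSequence]] = {}
    cond_fields = ("fat_conductivity", "fibre_number", "depth", "ml_pos",
                   "iz_pos", "cv", "fibre_length")
    with h5py.File(path, "r") as fh:
        for muscle in fh:
            out[muscle] = {}
            for uname in fh[muscle]:
                g = fh[muscle][uname]
                templates = []
                for k in sorted(g):
                    ds = g[k]
                    cond = None
                    if all(f in ds.attrs for f in cond_fields):
                        cond = ConditionVector(
                            **{f: float(ds.attrs[f]) for f in cond_fields})
                    templates.append(MUAPTemplate(ds[()], fs=float(ds.attrs["fs"]),
                                                  condition=cond))
                seq = MUAPSequence(np.asarray(g.attrs["keyframe_times"]),
                                   templates,
                                   unit_id=int(g.attrs["unit_id"]),
                                   latent_seed=int(g.attrs["latent_seed"]))
                out[muscle][seq.unit_id] = seq
    return out
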