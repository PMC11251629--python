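"""Track physiological-parameter changes from fibre length (``len2params``).

During a movement the muscle belly conserves volume, so when the fibres
shorten the cross-section widens.  Writing l_s(t) for the fibre length
relative to rest, the cross-sectional *area* scales as 1 / l_s(t) and the
cross-sectional *radius* as l_s(t)^(-1/2).  Both the fibre conduction
velocity (through the fibre diameter at constant fibre volume) and the depth
of a motor unit below the skin (carried outward with the expanding
cross-section) are taken to scale with the radius, i.e. as l_s^(-1/2) by
default.  The exponents are configurable because only the direction of the
effect is physiologically established, not the exact power law.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ParameterTrajectory", "len2params",
           "write_params", "read_params"]


@dataclass
class ParameterTrajectory:
    """Relative (to rest) trajectories of fibre length, CV and unit depth."""

    time: np.ndarray
    fibre_length_scale: np.ndarray   # l_s(t), dimensionless
    cv_scale: np.ndarray
    depth_scale: np.ndarray

    @property
    def area_scale(self) -> np.ndarray:
        """Cross-sectional area scale; l_s * area_scale == 1 (volume conservation)."""
        return 1.0 / self.fibre_length_scale


def len2params(fibre_length_norm: np.ndarray,
               rest_length_norm: float,
               time: np.ndarray | None = None,
               cv_exponent: float = -0.5,
               depth_exponent: float = -0.5) -> ParameterTrajectory:
    """Conduction-velocity and depth scales from a fibre-length trajectory.

    Parameters
    ----------
    fibre_length_norm
        Normalised fibre length over the movement (any positive series).
    rest_length_norm
        The resting value the series is referenced to (> 0).
    cv_exponent, depth_exponent
        Power of l_s used for each scale; -0.5 scales with the cross-section
        radius, -1.0 with the area.
    """
    fln = np.asarray(fibre_length_norm, dtype=float)
    if np.any(fln <= 0):
        raise ValueError("fibre_length_norm must be positive everywhere")
    if rest_length_norm <= 0:
        raise ValueError("rest_length_norm must be positive")
    l_s = fln / rest_length_norm
    if time is None:
        time = np.arange(fln.size, dtype=float)
    return ParameterTrajectory(
        time=np.asarray(time, dtype=float),
        fibre_length_scale=l_s,
        cv_scale=l_s ** cv_exponent,
        depth_scale=l_s ** depth_exponent,
    )


def write_params(pt: ParameterTrajectory, path, sep: str = "\t") -> None:
    pd.DataFrame({
        "time": pt.time,
        "length_scale": pt.fibre_length_scale,
        "cv_scale": pt.cv_scale,
        "depth_scale": pt.depth_scale,
    }).to_csv(path, sep=sep, index=False, float_format="%.12g")


def read_params(path, sep: str = "\t") -> ParameterTrajectory:
    df = pd.read_csv(path, sep=sep)
    return ParameterTrajectory(
        time=df["time"].to_numpy(),
        fibre_length_scale=df["length_scale"].to_numpy(),
        cv_scale=df["cv_scale"].to_numpy(),
        depth_scale=df["depth_scale"].to_numpy(),
    )
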