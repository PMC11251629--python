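"""Surface-EMG synthesis: spike trains convolved with dynamic MUAP templates.

The interference EMG at channel c is the superposition, over all active
motor units and all their discharges, of the unit's MUAP template evaluated
at the discharge time and placed at the discharge sample:

    emg[c, t] = sum_u sum_k M_u(t_k)[c, t - round(t_k fs)]

where ``M_u(t_k)`` is the template linearly interpolated between the two
keyframes bracketing the spike (``nearest`` mode snaps to the closest
keyframe instead).  Templates running past the record end are truncated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import h5py

from .config import GridSpec
from .muap import MUAPSequence
from .pool import SpikeTrainSet
from ._seeds import child_rng

__all__ = ["EMGRecording", "synthesize", "add_noise", "select_channels",
           "save_emg", "load_emg"]


@dataclass
class EMGRecording:
    """Multi-channel EMG: values (n_channels, n_samples) at fs Hz.

    ``channel_map`` holds the (row, col) grid coordinate of every channel in
    order; ``meta`` carries provenance (seeds, config hash, selections).
    """

    values: np.ndarray
    fs: float
    channel_map: list[tuple[int, int]]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.channel_map):
            raise ValueError("channel_map length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return (self.n_samples - 1) / self.fs


def _default_channel_map(n_rows: int, n_cols: int) -> list[tuple[int, int]]:
    return [(r, c) for r in range(n_rows) for c in range(n_cols)]


def synthesize(spikes: SpikeTrainSet,
               muaps: dict[int, MUAPSequence],
               fs: float,
               duration: float,
               mode: str = "linear") -> EMGRecording:
    """Sum of spike-train / dynamic-template convolutions over all units.

    ``muaps`` maps unit rank (1-based, matching the spike-train order) to its
    keyframed template sequence; every sequence must share the grid shape and
    template sampling rate ``fs``.
    """
    if mode not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation mode {mode!r}")
    n = int(round(duration * fs)) + 1
    shapes = set()
    for rank, train in enumerate(spikes.trains, start=1):
        if train.size and rank not in muaps:
            raise ValueError(f"active unit {rank} has no MUAP sequence")
    for seq in muaps.values():
        for tpl in seq.templates:
            shapes.add(tpl.values.shape)
            if tpl.fs != fs:
                raise ValueError("template fs must match the EMG rate")
    if len(shapes) > 1:
        raise ValueError("all MUAP sequences must share one grid shape")
    if shapes:
        n_rows, n_cols, T = shapes.pop()
    else:
        g = GridSpec()
        n_rows, n_cols, T = g.n_rows, g.n_cols, g.n_samples

    out = np.zeros((n_rows * n_cols, n))
    for rank, train in enumerate(spikes.trains, start=1):
        if train.size == 0:
            continue
        seq = muaps[rank]
        kt = seq.keyframe_times
        flat = [tpl.values.reshape(-1, T) for tpl in seq.templates]
        for t_k in train:
            i0 = int(round(t_k * fs))
            if i0 >= n:
                continue
            j = int(np.clip(np.searchsorted(kt, t_k) - 1, 0, kt.size - 2))
            w = (t_k - kt[j]) / (kt[j + 1] - kt[j])
            w = float(np.clip(w, 0.0, 1.0))
            if mode == "nearest":
                tpl = flat[j + 1] if w >= 0.5 else flat[j]
            elif w == 0.0:
                tpl = flat[j]
            else:
                tpl = (1.0 - w) * flat[j] + w * flat[j + 1]
            span = min(T, n - i0)
            out[:, i0:i0 + span] += tpl[:, :span]
    return EMGRecording(out, fs, _default_channel_map(n_rows, n_cols),
                        meta={"n_rows": n_rows, "n_cols": n_cols})


def add_noise(emg: EMGRecording, snr_db: float | None, seed: int = 0
              ) -> EMGRecording:
    """Additive white Gaussian noise at a prescribed per-channel SNR.

    Each channel receives noise with variance ``P_c * 10^(-snr_db/10)`` where
    P_c is that channel's mean square; zero-power channels stay clean.
    ``snr_db=None`` (or +inf) returns an unchanged copy.
    """
    if snr_db is None or np.isinf(snr_db):
        return EMGRecording(emg.values.copy(), emg.fs, list(emg.channel_map),
                            dict(emg.meta))
    power = np.mean(emg.values ** 2, axis=1)
    if np.all(power == 0):
        raise ValueError("cannot scale noise to a zero-power recording")
    rng = child_rng(seed, "emg-noise")
    sigma = np.sqrt(power * 10.0 ** (-snr_db / 10.0))
    noisy = emg.values + sigma[:, None] * rng.standard_normal(emg.values.shape)
    meta = dict(emg.meta, snr_db=snr_db, noise_seed=seed)
    return EMGRecording(noisy, emg.fs, list(emg.channel_map), meta)


def select_channels(emg: EMGRecording,
                    coords: list[tuple[float, float]]) -> EMGRecording:
    """Subset of channels nearest to the requested (row, col) coordinates.

    Fractional coordinates are matched to the nearest grid channel (columns
    wrap around the circumference); duplicates yield duplicated channels.
    Order is preserved and the mapping is recorded in ``meta``.
    """
    n_rows = emg.meta.get("n_rows", max(r for r, _ in emg.channel_map) + 1)
    n_cols = emg.meta.get("n_cols", max(c for _, c in emg.channel_map) + 1)
    lookup = {rc: i for i, rc in enumerate(emg.channel_map)}
    picked, mapping = [], []
    for row, col in coords:
        r = int(round(row))
        c = int(round(col)) % n_cols
        if not (0 <= r < n_rows) or not np.isfinite(col):
            raise ValueError(f"coordinate ({row}, {col}) outside the grid")
        picked.append(lookup[(r, c)])
        mapping.append({"requested": (float(row), float(col)),
                        "channel": (r, c)})
    values = emg.values[picked]
    meta = dict(emg.meta, channel_selection=mapping)
    return EMGRecording(values, emg.fs,
                        [emg.channel_map[i] for i in picked], meta)


def save_emg(path, emg: EMGRecording) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=emg.values)
        fh.attrs["fs"] = emg.fs
        fh.create_dataset("channel_map", data=np.array(emg.channel_map))
        for k, v in emg.meta.items():
            if isinstance(v, (int, float, str)):
                fh.attrs[f"meta_{k}"] = v


def load_emg(path) -> EMGRecording:
    with h5py.File(path, "r") as fh:
        values = fh["values"][()]
        fs = float(fh.attrs["fs"])
        cmap = [tuple(int(x) for x in rc) for rc in fh["channel_map"][()]]
        meta = {k[5:]: v for k, v in fh.attrs.items() if k.startswith("meta_")}
    return EMGRecording(values, fs, cmap, meta)
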